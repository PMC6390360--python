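"""Inverse expression-methylation pairing and cross-contrast inversion.

A gene-probe pair is "inverse" when, within one contrast, the probe's
methylation and its annotated gene's expression move in opposite
directions: hypo-methylation with up-regulation (``hypo_up``) or
hyper-methylation with down-regulation (``hyper_down``).  The pairing
gate uses the nominal per-feature p-value on both sides by default (a
switch allows the BH-adjusted q instead) together with the delta-beta
magnitude gate; the expression side carries no fold-change gate here.

Separately, probes differentially methylated in both the oxygen contrast
and the HIF1A-silencing contrast are intersected and flagged "inverted"
when their delta-beta signs disagree — the signature of methylation
changes that revert once HIF1A is depleted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def pair_inverse(
    dm: pd.DataFrame,
    de: pd.DataFrame,
    manifest: pd.DataFrame,
    p_threshold: float = 0.05,
    delta_threshold: float = 0.2,
    p_mode: str = "nominal",
) -> pd.DataFrame:
    """Select inverse methylation-expression gene-probe pairs.

    Parameters
    ----------
    dm, de
        Differential methylation / expression tables from the same
        contrast (indexed by probe and gene respectively).
    manifest
        Probe manifest linking probes to their annotated gene; probes
        without a gene link (intergenic) are skipped and counted.
    p_mode
        "nominal" gates on ``p_value``, "fdr" on ``q_value``, both sides.

    Returns a DataFrame with one row per retained pair (columns
    ``probe_id``, ``gene_id``, ``delta_beta``, ``log2fc``,
    ``gene_feature``, ``cgi_feature``, ``relation``) with the skipped
    intergenic-probe count in ``.attrs["n_skipped_intergenic"]``.  A gene
    annotated by several probes yields one row per probe.
    """
    if p_mode not in ("nominal", "fdr"):
        raise ValueError(f"unknown p_mode {p_mode!r}")
    pcol = "p_value" if p_mode == "nominal" else "q_value"

    rows = []
    n_igr = 0
    dm_sig = dm[(dm[pcol] <= p_threshold) & (dm["delta_beta"].abs() > delta_threshold)]
    for probe in dm_sig.index:
        if probe not in manifest.index:
            continue
        gene = manifest.at[probe, "gene_id"]
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            n_igr += 1
            continue
        if gene not in de.index:
            continue
        if de.at[gene, pcol] > p_threshold:
            continue
        delta = float(dm_sig.at[probe, "delta_beta"])
        lfc = float(de.at[gene, "log2fc"])
        if delta * lfc >= 0:  # same direction (or a zero) -> not inverse
            continue
        rows.append(
            (
                probe,
                gene,
                delta,
                lfc,
                manifest.at[probe, "gene_feature"],
                manifest.at[probe, "cgi_feature"],
                "hypo_up" if delta < 0 else "hyper_down",
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "gene_id",
            "delta_beta",
            "log2fc",
            "gene_feature",
            "cgi_feature",
            "relation",
        ],
    ).sort_values(["probe_id", "gene_id"]).reset_index(drop=True)
    out.attrs["n_skipped_intergenic"] = n_igr
    return out


def common_probe_inversion(dm_a: pd.DataFrame, dm_b: pd.DataFrame) -> pd.DataFrame:
    """Intersect two filtered probe sets and flag delta-beta sign inversion.

    Both inputs must carry a ``delta_beta`` column indexed by probe.  The
    result has one row per common probe with ``delta_beta_a``,
    ``delta_beta_b`` and ``inverted`` (opposite nonzero signs); summary
    counts are stored in ``.attrs`` (``n_common``, ``n_inverted``,
    ``n_same_sign``).
    """
    common = sorted(set(dm_a.index) & set(dm_b.index))
    da = dm_a.loc[common, "delta_beta"].to_numpy(dtype=float)
    db = dm_b.loc[common, "delta_beta"].to_numpy(dtype=float)
    inverted = (np.sign(da) != np.sign(db)) & (np.sign(da) != 0) & (np.sign(db) != 0)
    out = pd.DataFrame(
        {"delta_beta_a": da, "delta_beta_b": db, "inverted": inverted},
        index=pd.Index(common, name="probe_id"),
    )
    out.attrs["n_common"] = len(common)
    out.attrs["n_inverted"] = int(inverted.sum())
    out.attrs["n_same_sign"] = int(len(common) - inverted.sum())
    return out
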