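"""Regulatory-region overlap, target linking and HIF1A-dependency calls.

Differentially methylated probes are intersected with regulatory-marker
interval tracks (DNase hypersensitivity, histone-acetylation ChIP and
similar) from several cell lines.  A probe is *active* if any marker
interval covers it in any cell line, and *stringent* if at least 4
distinct markers cover it in every cell line.  Stringent probes are then
linked to candidate target genes whose TSS lies within +/-1 Mb and whose
hypoxia-contrast fold change passes an inclusive |log2FC| >= 0.2 gate.
Each link is finally labelled by whether the probe/target response
pattern is independent of HIF1A (no significant change in the
HIF1A-silencing contrast) or HIF1A-dependent (both probe delta-beta and
target fold change invert when HIF1A is lost).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import format_pct
from .containers import MarkerTrack

MIN_MARKERS = 4


@dataclass
class EnhancerCandidate:
    """Per-probe marker coverage across cell lines."""

    probe_id: str
    chrom: str
    pos: int
    markers_per_cell_line: dict[str, int]
    active: bool
    stringent: bool


def _build_trees(tracks: list[MarkerTrack]) -> dict[tuple[str, str, str], IntervalTree]:
    trees: dict[tuple[str, str, str], IntervalTree] = {}
    for track in tracks:
        for chrom, sub in track.intervals.groupby("chrom"):
            key = (track.cell_line, track.marker, str(chrom))
            tree = trees.setdefault(key, IntervalTree())
            for start, end in zip(sub["start"], sub["end"]):
                tree.addi(int(start), int(end))
    return trees


def overlap_regulatory(
    probes: pd.DataFrame, tracks: list[MarkerTrack], min_markers: int = MIN_MARKERS
) -> tuple[list[EnhancerCandidate], dict]:
    """Count distinct overlapping markers per probe and cell line.

    ``probes`` is indexed by probe id with columns ``chrom`` and ``pos``.
    Returns the candidates plus a summary dict with ``n_probes``,
    ``n_active``, ``active_pct`` (percentage, half-up, 1 decimal) and
    ``n_stringent``.
    """
    if not tracks:
        raise ValueError("need at least one marker track")
    cell_lines = sorted({t.cell_line for t in tracks})
    markers_by_cl: dict[str, set[str]] = {}
    for t in tracks:
        markers_by_cl.setdefault(t.cell_line, set()).add(t.marker)
    trees = _build_trees(tracks)

    candidates = []
    for probe_id, row in probes.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        counts = {}
        for cl in cell_lines:
            n = 0
            for marker in markers_by_cl[cl]:
                tree = trees.get((cl, marker, chrom))
                if tree is not None and tree.overlaps_point(pos):
                    n += 1
            counts[cl] = n
        active = any(n >= 1 for n in counts.values())
        stringent = all(counts[cl] >= min_markers for cl in cell_lines)
        candidates.append(
            EnhancerCandidate(
                probe_id=str(probe_id),
                chrom=chrom,
                pos=pos,
                markers_per_cell_line=counts,
                active=active,
                stringent=stringent,
            )
        )
    n_active = sum(c.active for c in candidates)
    summary = {
        "n_probes": len(candidates),
        "n_active": n_active,
        "active_pct": format_pct(n_active, len(candidates)) if candidates else 0.0,
        "n_stringent": sum(c.stringent for c in candidates),
    }
    return candidates, summary


def link_targets(
    candidates: list[EnhancerCandidate],
    genes: pd.DataFrame,
    de_hypoxia: pd.DataFrame,
    window: int = 1_000_000,
    lfc_gate: float = 0.2,
) -> pd.DataFrame:
    """Link stringent candidate probes to in-window responsive genes.

    ``genes`` is indexed by gene id with columns ``chrom`` and ``tss``.
    A gene is linked when |TSS - probe position| <= window (1 Mb up- or
    down-stream) and its hypoxia-contrast |log2FC| >= ``lfc_gate``
    (inclusive).  Probes with no gene in the window appear with a null
    gene id so they are reported, not dropped.
    """
    rows = []
    by_chrom = {str(c): sub.sort_values("tss") for c, sub in genes.groupby("chrom")}
    for cand in candidates:
        if not cand.stringent:
            continue
        sub = by_chrom.get(cand.chrom)
        linked = 0
        if sub is not None and len(sub):
            tss = sub["tss"].to_numpy(dtype=np.int64)
            lo = np.searchsorted(tss, cand.pos - window, side="left")
            hi = np.searchsorted(tss, cand.pos + window, side="right")
            for gene in sub.index[lo:hi]:
                if gene not in de_hypoxia.index:
                    continue
                lfc = float(de_hypoxia.at[gene, "log2fc"])
                if abs(lfc) < lfc_gate:
                    continue
                rows.append(
                    (
                        cand.probe_id,
                        gene,
                        int(abs(int(sub.at[gene, "tss"]) - cand.pos)),
                        lfc,
                    )
                )
                linked += 1
        if linked == 0:
            rows.append((cand.probe_id, None, None, np.nan))
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "distance", "log2fc_hypoxia"]
    )


def classify_dependency(
    links: pd.DataFrame,
    dm_hypoxia: pd.DataFrame,
    dm_hif1a: pd.DataFrame,
    de_hif1a: pd.DataFrame,
    delta_gate: float = 0.2,
    lfc_gate: float = 0.2,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Label each probe-target link by its HIF1A dependency pattern.

    * ``hif1a_independent`` — the probe shows no significant methylation
      change in the HIF1A-silencing contrast (|delta-beta| <= gate or
      q >= fdr) and the target is not significantly responsive there
      (below the fold-change gate or q >= fdr);
    * ``hif1a_dependent`` — the probe's delta-beta inverts (opposite sign,
      past the gate) and the target's fold change inverts significantly
      as well;
    * anything else — ``ambiguous``, reported rather than dropped.
    """
    if dm_hif1a is None or de_hif1a is None:
        raise ValueError("HIF1A-contrast records are required")
    out = links.copy()
    db_hyp, db_hif, lfc_hif, label = [], [], [], []
    for _, row in links.iterrows():
        probe, gene = row["probe_id"], row["gene_id"]
        d_hyp = float(dm_hypoxia.at[probe, "delta_beta"]) if probe in dm_hypoxia.index else np.nan
        d_hif = float(dm_hif1a.at[probe, "delta_beta"]) if probe in dm_hif1a.index else np.nan
        q_hif = float(dm_hif1a.at[probe, "q_value"]) if (
            probe in dm_hif1a.index and "q_value" in dm_hif1a.columns
        ) else np.nan
        gene_known = gene is not None and not pd.isna(gene) and gene in de_hif1a.index
        l_hif = float(de_hif1a.at[gene, "log2fc"]) if gene_known else np.nan
        q_de_hif = (
            float(de_hif1a.at[gene, "q_value"])
            if gene_known and "q_value" in de_hif1a.columns
            else np.nan
        )
        l_hyp = row["log2fc_hypoxia"]

        probe_ns = np.isnan(d_hif) or abs(d_hif) <= delta_gate or (
            not np.isnan(q_hif) and q_hif >= fdr
        )
        target_sig = (
            not np.isnan(l_hif)
            and abs(l_hif) >= lfc_gate
            and (np.isnan(q_de_hif) or q_de_hif < fdr)
        )
        probe_inverted = (
            not np.isnan(d_hif)
            and not np.isnan(d_hyp)
            and abs(d_hif) > delta_gate
            and d_hif * d_hyp < 0
        )
        target_inverted = (
            target_sig and not pd.isna(l_hyp) and l_hif * float(l_hyp) < 0
        )
        target_ns = not target_sig
        if probe_ns and target_ns:
            dep = "hif1a_independent"
        elif probe_inverted and target_inverted:
            dep = "hif1a_dependent"
        else:
            dep = "ambiguous"
        db_hyp.append(d_hyp)
        db_hif.append(d_hif)
        lfc_hif.append(l_hif)
        label.append(dep)
    out["delta_beta_hypoxia"] = db_hyp
    out["delta_beta_hif1a"] = db_hif
    out["log2fc_hif1a"] = lfc_hif
    out["dependency"] = label
    return out


def summarize_probe_dependency(classified: pd.DataFrame) -> pd.Series:
    """Collapse link-level dependency labels to one label per probe.

    A probe whose methylation inverts can only produce dependent or
    ambiguous links, and a probe untouched by HIF1A only independent or
    ambiguous ones, so taking dependent > independent > ambiguous per
    probe is unambiguous.
    """
    rank = {"hif1a_dependent": 2, "hif1a_independent": 1, "ambiguous": 0}
    inv = {v: k for k, v in rank.items()}
    best = classified.groupby("probe_id")["dependency"].apply(
        lambda s: inv[max(rank[x] for x in s)]
    )
    best.name = "dependency"
    return best
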