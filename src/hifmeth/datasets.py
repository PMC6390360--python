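"""Bundled reference tables.

Two small curated tables of inverse methylation-expression gene-probe
pairs observed in HIF1A-silenced neuroblastoma cells: one for the
HIF1A-silencing contrast under hypoxia (shHIF1A HYP vs shCTR HYP) and one
for the oxygen contrast (shCTR HYP vs shCTR NX).  Each row carries the
probe, its annotated gene, the contrast's delta-beta and log2 fold
change, and the probe's gene-centric and CGI-centric features.  Used as a
known-answer fixture for the inverse-pairing predicate and for the
cross-contrast inversion check (the NAV2 probe cg27262041 appears in both
contrasts with opposite delta-beta signs).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_CONTRASTS = {
    "hif1a": "reference_pairs_hif1a.tsv",
    "hypoxia": "reference_pairs_hypoxia.tsv",
}


def load_reference_pairs(contrast: str) -> pd.DataFrame:
    """Load the reference gene-probe pair table for a contrast.

    ``contrast`` is "hif1a" (HIF1A silencing under hypoxia) or "hypoxia"
    (control cells, hypoxia vs normoxia).
    """
    try:
        fname = _CONTRASTS[contrast]
    except KeyError:
        raise ValueError(f"contrast must be one of {sorted(_CONTRASTS)}") from None
    with resources.files("hifmeth.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_pairs_as_records(contrast: str) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Re-shape a reference pair table into pipeline inputs.

    Returns ``(dm, de, manifest)`` suitable for
    :func:`hifmeth.integration.pair_inverse`: per-probe delta-beta records,
    per-gene expression records and a probe manifest, all with nominal
    p-values set to 0.01 (the published rows all passed the p <= 0.05
    gate; the table itself does not print p-values).
    """
    table = load_reference_pairs(contrast)
    dm = pd.DataFrame(
        {
            "delta_beta": table["delta_beta"].to_numpy(),
            "p_value": 0.01,
            "q_value": 0.01,
        },
        index=pd.Index(table["probe_id"], name="probe_id"),
    )
    de = (
        table[["gene_id", "log2fc"]]
        .drop_duplicates("gene_id")
        .set_index("gene_id")
        .assign(p_value=0.01, q_value=0.01)
    )
    manifest = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": range(len(table)),
            "cgi_feature": table["cgi_feature"].to_numpy(),
            "gene_feature": table["gene_feature"].to_numpy(),
            "gene_id": table["gene_id"].to_numpy(),
        },
        index=pd.Index(table["probe_id"], name="probe_id"),
    )
    return dm, de, manifest
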