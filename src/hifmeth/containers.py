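"""Typed in-memory containers shared across the pipeline.

Matrices are thin wrappers around pandas DataFrames (features x samples)
plus a sample design table mapping each sample to its experimental
condition and replicate.  Differential results are plain DataFrames with a
documented column contract (see :mod:`hifmeth.differential`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four experimental conditions: control / HIF1A-silenced cells, each
#: grown in normoxia (NX) or hypoxia (HYP).
CONDITIONS = ("shCTR_NX", "shCTR_HYP", "shHIF1A_NX", "shHIF1A_HYP")

CGI_FEATURES = ("island", "shore", "shelf", "open_sea")
GENE_FEATURES = (
    "TSS200",
    "TSS1500",
    "five_prime_UTR",
    "first_exon",
    "body",
    "three_prime_UTR",
    "IGR",
)


def _check_design(values: pd.DataFrame, design: pd.DataFrame) -> None:
    if values.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    if values.index.duplicated().any():
        raise ValueError("duplicate feature ids")
    missing = set(values.columns) - set(design.index)
    if missing:
        raise ValueError(f"samples missing from design: {sorted(missing)[:5]}")
    for col in ("condition", "replicate"):
        if col not in design.columns:
            raise ValueError(f"design lacks required column {col!r}")


@dataclass
class ExpressionMatrix:
    """Gene-level abundance matrix (FPKM-like units), genes x samples."""

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        _check_design(self.values, self.design)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def condition_samples(self, condition: str) -> list[str]:
        samples = self.design.index[self.design["condition"] == condition]
        return [s for s in samples if s in self.values.columns]


@dataclass
class BetaMatrix:
    """Methylation beta-value matrix, probes x samples, values in [0, 1]."""

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        _check_design(self.values, self.design)
        arr = self.values.to_numpy()
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def condition_samples(self, condition: str) -> list[str]:
        samples = self.design.index[self.design["condition"] == condition]
        return [s for s in samples if s in self.values.columns]


@dataclass
class MarkerTrack:
    """Regulatory-marker intervals for one (cell line, marker) pair.

    Intervals are 0-based half-open, BED-style.
    """

    cell_line: str
    marker: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        iv = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in iv.columns:
                raise ValueError(f"intervals lack column {col!r}")
        if (iv["start"] >= iv["end"]).any():
            raise ValueError("intervals must satisfy start < end")


@dataclass
class CohortExpression:
    """Patient cohort expression with binary clinical-risk labels."""

    values: pd.DataFrame  # genes x patients
    risk: pd.Series  # patient -> "low" | "high"

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.risk.index)
        if missing:
            raise ValueError(f"patients without a risk label: {sorted(missing)[:5]}")
        bad = set(self.risk.unique()) - {"low", "high"}
        if bad:
            raise ValueError(f"unknown risk labels: {bad}")
        counts = self.risk.loc[self.values.columns].value_counts()
        if counts.get("low", 0) < 2 or counts.get("high", 0) < 2:
            raise ValueError("need at least 2 patients per risk class")


@dataclass
class DirectionalGeneSet:
    """Genes retained by a differential filter, with effect sign retained.

    ``entries`` is indexed by gene id with columns ``log2fc``, ``q_value``
    and ``direction`` ("up"/"down").
    """

    contrast_label: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        if self.entries.index.duplicated().any():
            raise ValueError("duplicate genes in directional set")
        bad = set(self.entries["direction"].unique()) - {"up", "down"}
        if bad:
            raise ValueError(f"invalid directions: {bad}")

    @property
    def genes(self) -> set[str]:
        return set(self.entries.index)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CrossClassification:
    """Directional set-algebra result of crossing two contrasts.

    ``common`` carries both contrasts' fold changes; ``concordant`` and
    ``discordant`` partition the common genes with nonzero fold changes
    once :func:`hifmeth.setops.classify_concordance` has run.  Genes with a
    zero fold change in either contrast are listed in ``zero_sign``.
    """

    label_a: str
    label_b: str
    exclusive_a: list = field(default_factory=list)
    exclusive_b: list = field(default_factory=list)
    common: pd.DataFrame | None = None  # index gene, cols log2fc_a, log2fc_b
    concordant: list | None = None
    discordant: list | None = None
    zero_sign: list | None = None

    @property
    def common_genes(self) -> list:
        return [] if self.common is None else list(self.common.index)
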