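"""Synthetic multi-omics data with planted ground truth.

Emulates the full input universe of the analysis: a 4-condition replicated
RNA abundance matrix for HIF1A-silenced vs control cells in normoxia and
hypoxia, a methylation beta-value matrix with an annotated probe manifest,
multi-cell-line regulatory marker tracks, and a two-risk-class patient
cohort.  Every downstream stage of the pipeline has a planted structure
here that it is expected to recover:

* gene classes realise the defining expression contrasts (exclusive
  normoxia/hypoxia response, concordant/discordant HIF1A targets,
  HIF1A-independent hypoxia response);
* probe classes realise the defining methylation contrasts, including
  "common inverted" probes whose hypoxia shift reverts upon HIF1A loss;
* enhancer probes sit under >= 4 regulatory markers in every cell line and
  have a planted in-window target gene, with either a HIF1A-independent or
  a HIF1A-dependent (inverted) response pattern;
* signature genes separate the low- and high-risk cohort classes.

Expression noise is log-normal around a per-gene baseline drawn
log-uniformly (positive skew, closed-form effect planting); beta values
are Beta-distributed around planted means so the [0, 1] support of the
array statistic is respected.  One master seed drives deterministic
per-stage substreams.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import substreams
from .containers import (
    BetaMatrix,
    CGI_FEATURES,
    CohortExpression,
    CONDITIONS,
    ExpressionMatrix,
    GENE_FEATURES,
    MarkerTrack,
)

GENE_CLASSES = (
    "hif1a_target_concordant",
    "hif1a_target_discordant",
    "exclusive_normoxia",
    "exclusive_hypoxia",
    "hypoxia_independent_target",
)
PROBE_CLASSES = (
    "hypoxia_hyper",
    "hypoxia_hypo",
    "hif1a_hyper",
    "hif1a_hypo",
    "common_inverted",
)

_DEFAULT_GENE_FRACTIONS = MappingProxyType(
    {
        "hif1a_target_concordant": 0.10,
        "hif1a_target_discordant": 0.02,
        "exclusive_normoxia": 0.10,
        "exclusive_hypoxia": 0.05,
        "hypoxia_independent_target": 0.05,
    }
)
_DEFAULT_PROBE_FRACTIONS = MappingProxyType(
    {
        "hypoxia_hyper": 0.04,
        "hypoxia_hypo": 0.02,
        "hif1a_hyper": 0.03,
        "hif1a_hypo": 0.03,
        "common_inverted": 0.03,
    }
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-truth generator.

    Defaults mirror the experimental design being emulated: triplicate
    samples per condition, a 0.3 beta-unit methylation effect against the
    0.2 differential-methylation gate, log2 expression effects of 2, and a
    cohort of 40 low-risk and 56 high-risk patients.
    """

    n_genes: int = 2000
    n_probes: int = 4000
    replicates_per_condition: int = 3
    conditions: tuple[str, ...] = CONDITIONS
    effect_log2fc: float = 2.0
    effect_delta_beta: float = 0.3
    expression_noise_sd: float = 0.5
    #: Beta-distribution concentration; 100 gives sd ~= 0.05 at beta = 0.5.
    beta_concentration: float = 100.0
    genome_length_per_chrom: int = 20_000_000
    n_chromosomes: int = 3
    cohort_n_low: int = 40
    cohort_n_high: int = 56
    signature_separation: float = 3.0
    cohort_noise_sd: float = 1.0
    n_signature_genes: int = 30
    gene_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GENE_FRACTIONS)
    )
    probe_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROBE_FRACTIONS)
    )
    n_enhancer_independent: int = 9
    n_enhancer_dependent: int = 5
    cell_lines: tuple[str, ...] = ("SKNBE2", "CHP134", "SHSY5Y")
    markers: tuple[str, ...] = ("DNase", "H3K27ac", "H3K4me1", "H3K4me3")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_probes", "replicates_per_condition",
                     "genome_length_per_chrom", "n_chromosomes",
                     "cohort_n_low", "cohort_n_high"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(set(self.conditions)) != 4:
            raise ValueError("conditions must be 4 distinct labels")
        if not 0 < self.effect_delta_beta < 1:
            raise ValueError("effect_delta_beta must lie in (0, 1)")
        if self.expression_noise_sd <= 0:
            raise ValueError("expression_noise_sd must be positive")
        for fracs, classes in (
            (self.gene_class_fractions, GENE_CLASSES),
            (self.probe_class_fractions, PROBE_CLASSES),
        ):
            unknown = set(fracs) - set(classes)
            if unknown:
                raise ValueError(f"unknown class names: {sorted(unknown)}")
            if any(f < 0 for f in fracs.values()):
                raise ValueError("class fractions must be nonnegative")
            if sum(fracs.values()) > 1 + 1e-12:
                raise ValueError("class fractions must sum to at most 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth: class labels, coordinates and couplings."""

    gene_class: dict[str, str]  # gene -> class or "null"
    probe_class: dict[str, str]  # probe -> class or "null"
    gene_sign: dict[str, int]  # per planted gene: +1 up / -1 down
    probe_sign: dict[str, int]
    gene_coords: pd.DataFrame  # index gene_id; chrom, tss
    probe_coords: pd.DataFrame  # index probe_id; chrom, pos
    islands: dict[str, np.ndarray]  # chrom -> (k, 2) sorted CGI intervals
    enhancer_probes: set[str] = field(default_factory=set)
    enhancer_dependency: dict[str, str] = field(default_factory=dict)
    enhancer_targets: dict[str, str] = field(default_factory=dict)  # probe -> gene
    probe_gene_link: dict[str, str] = field(default_factory=dict)  # probe -> gene
    signature_genes: set[str] = field(default_factory=set)

    def genes_in_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]

    def probes_in_class(self, cls: str) -> list[str]:
        return [p for p, c in self.probe_class.items() if c == cls]


def _class_sizes(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    return {cls: int(math.floor(f * n + 0.5)) for cls, f in fractions.items()}


def plant_truth(config: SimulationConfig) -> SyntheticTruth:
    """Assign planted classes, coordinates and couplings deterministically.

    Class members are drawn without replacement from a seeded permutation,
    so class sizes equal ``round(fraction * n)`` exactly and classes are
    disjoint.  Enhancer probes are recruited from the hypoxia-responsive
    probe classes (HIF1A-independent pattern) and from the common-inverted
    class (HIF1A-dependent pattern); each receives a dedicated target gene
    re-positioned within +/-0.5 Mb of the probe.
    """
    rng = substreams(config.seed, 8)[0]

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    probes = [f"cgS{i:06d}" for i in range(config.n_probes)]

    gene_class = {g: "null" for g in genes}
    order = rng.permutation(config.n_genes)
    sizes = _class_sizes(config.gene_class_fractions, config.n_genes)
    cursor = 0
    for cls in GENE_CLASSES:
        k = sizes.get(cls, 0)
        for idx in order[cursor : cursor + k]:
            gene_class[genes[idx]] = cls
        cursor += k

    probe_class = {p: "null" for p in probes}
    order = rng.permutation(config.n_probes)
    sizes = _class_sizes(config.probe_class_fractions, config.n_probes)
    cursor = 0
    for cls in PROBE_CLASSES:
        k = sizes.get(cls, 0)
        for idx in order[cursor : cursor + k]:
            probe_class[probes[idx]] = cls
        cursor += k

    gene_sign = {
        g: int(rng.choice([-1, 1])) for g, c in gene_class.items() if c != "null"
    }
    probe_sign = {
        p: int(rng.choice([-1, 1])) for p, c in probe_class.items() if c != "null"
    }

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    gene_coords = pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=config.n_genes),
            "tss": rng.integers(0, config.genome_length_per_chrom, size=config.n_genes),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    probe_coords = pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=config.n_probes),
            "pos": rng.integers(0, config.genome_length_per_chrom, size=config.n_probes),
        },
        index=pd.Index(probes, name="probe_id"),
    )

    # CpG islands: ~1 island per 100 kb, 500-2000 bp long, non-overlapping.
    islands: dict[str, np.ndarray] = {}
    n_isl = max(1, config.genome_length_per_chrom // 100_000)
    for chrom in chroms:
        starts = np.sort(
            rng.choice(
                np.arange(0, config.genome_length_per_chrom - 2000, 10_000),
                size=min(n_isl, config.genome_length_per_chrom // 10_000 - 1),
                replace=False,
            )
        )
        lengths = rng.integers(500, 2000, size=starts.size)
        islands[chrom] = np.column_stack([starts, starts + lengths])

    truth = SyntheticTruth(
        gene_class=gene_class,
        probe_class=probe_class,
        gene_sign=gene_sign,
        probe_sign=probe_sign,
        gene_coords=gene_coords,
        probe_coords=probe_coords,
        islands=islands,
    )

    _plant_enhancers(config, truth, rng)
    _plant_probe_gene_links(config, truth, rng)

    sig = rng.choice(genes, size=min(config.n_signature_genes, len(genes)), replace=False)
    truth.signature_genes = set(str(g) for g in sig)
    return truth


def _plant_enhancers(
    config: SimulationConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> None:
    """Recruit enhancer probes and plant an in-window target gene for each."""
    if config.n_enhancer_independent == 0 and config.n_enhancer_dependent == 0:
        return
    hypoxia_pool = truth.probes_in_class("hypoxia_hyper") + truth.probes_in_class(
        "hypoxia_hypo"
    )
    inverted_pool = truth.probes_in_class("common_inverted")
    if len(hypoxia_pool) < config.n_enhancer_independent:
        raise ValueError("not enough hypoxia-class probes to host independent enhancers")
    if len(inverted_pool) < config.n_enhancer_dependent:
        raise ValueError("not enough common-inverted probes to host dependent enhancers")

    indep = list(rng.choice(hypoxia_pool, size=config.n_enhancer_independent, replace=False))
    dep = list(rng.choice(inverted_pool, size=config.n_enhancer_dependent, replace=False))
    null_genes = [g for g, c in truth.gene_class.items() if c == "null"]
    need = len(indep) + len(dep)
    if len(null_genes) < need:
        raise ValueError("not enough unassigned genes to serve as enhancer targets")
    targets = list(rng.choice(null_genes, size=need, replace=False))

    for probe, dependency in [(p, "independent") for p in indep] + [
        (p, "dependent") for p in dep
    ]:
        gene = targets.pop()
        truth.enhancer_probes.add(probe)
        truth.enhancer_dependency[probe] = dependency
        truth.enhancer_targets[probe] = gene
        truth.gene_sign[gene] = int(rng.choice([-1, 1]))
        # re-position the target inside the +/-1 Mb link window
        chrom = truth.probe_coords.at[probe, "chrom"]
        pos = int(truth.probe_coords.at[probe, "pos"])
        offset = int(rng.integers(10_000, 500_000)) * int(rng.choice([-1, 1]))
        tss = min(max(0, pos + offset), config.genome_length_per_chrom - 1)
        truth.gene_coords.loc[gene, ["chrom", "tss"]] = [chrom, tss]


def _plant_probe_gene_links(
    config: SimulationConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> None:
    """Couple HIF1A-contrast probes to oppositely regulated genes.

    Gives the inverse expression-methylation pairing stage genuine planted
    structure: a probe that gains methylation when HIF1A is lost is
    annotated to a gene that loses expression in the same contrast.
    """
    up_genes = [
        g
        for g, c in truth.gene_class.items()
        if c in ("exclusive_hypoxia", "hif1a_target_concordant")
        and truth.gene_sign[g] > 0
    ]
    down_genes = [
        g
        for g, c in truth.gene_class.items()
        if c in ("exclusive_hypoxia", "hif1a_target_concordant")
        and truth.gene_sign[g] < 0
    ]
    rng.shuffle(up_genes)
    rng.shuffle(down_genes)
    for probe in truth.probes_in_class("hif1a_hyper"):
        if not down_genes:
            break
        truth.probe_gene_link[probe] = down_genes.pop()
        truth.probe_sign[probe] = 1
    for probe in truth.probes_in_class("hif1a_hypo"):
        if not up_genes:
            break
        truth.probe_gene_link[probe] = up_genes.pop()
        truth.probe_sign[probe] = -1
    # linked probes move next to their gene's TSS
    for probe, gene in truth.probe_gene_link.items():
        chrom = truth.gene_coords.at[gene, "chrom"]
        tss = int(truth.gene_coords.at[gene, "tss"])
        shift = int(rng.integers(-1500, 1500))
        pos = min(max(0, tss + shift), config.genome_length_per_chrom - 1)
        truth.probe_coords.loc[probe, ["chrom", "pos"]] = [chrom, pos]


def _condition_log2_offsets(
    config: SimulationConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Per-gene log2 offsets for each condition implementing the classes."""
    e = config.effect_log2fc
    genes = list(truth.gene_class)
    off = pd.DataFrame(0.0, index=genes, columns=list(CONDITIONS))
    for g in genes:
        cls = truth.gene_class[g]
        s = truth.gene_sign.get(g, 1) * e
        if cls == "exclusive_normoxia":
            off.at[g, "shHIF1A_NX"] = s
        elif cls == "exclusive_hypoxia":
            off.at[g, "shHIF1A_HYP"] = s
        elif cls == "hif1a_target_concordant":
            off.at[g, "shHIF1A_NX"] = s
            off.at[g, "shHIF1A_HYP"] = s
        elif cls == "hif1a_target_discordant":
            off.at[g, "shHIF1A_NX"] = s
            off.at[g, "shHIF1A_HYP"] = -s
        elif cls == "hypoxia_independent_target":
            # responds to oxygen in the control background and keeps the
            # same direction of change in the silenced-hypoxia contrast
            off.at[g, "shCTR_HYP"] = s
            off.at[g, "shHIF1A_HYP"] = 2 * s
    for probe, gene in truth.enhancer_targets.items():
        s = truth.gene_sign[gene] * e
        off.at[gene, "shCTR_HYP"] = s
        if truth.enhancer_dependency[probe] == "independent":
            # hypoxia-responsive but untouched by HIF1A loss
            off.at[gene, "shHIF1A_HYP"] = s
        else:
            # response reverts when HIF1A is lost (inverted HIF1A contrast)
            off.at[gene, "shHIF1A_HYP"] = 0.0
    return off


def simulate_expression(
    config: SimulationConfig, truth: SyntheticTruth
) -> ExpressionMatrix:
    """FPKM-like matrix with planted class contrasts.

    Per-gene baselines are log-uniform in [1, 1000]; replicate noise is
    normal on the log2 scale with sd ``expression_noise_sd``.
    """
    if config.replicates_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    rngs = substreams(config.seed, 8)
    rng = rngs[1]
    genes = list(truth.gene_class)
    n = len(genes)
    base_log2 = rng.uniform(0.0, np.log2(1000.0), size=n)
    offsets = _condition_log2_offsets(config, truth)

    cols, data = [], []
    design_rows = []
    for cond in config.conditions:
        for rep in range(1, config.replicates_per_condition + 1):
            sample = f"{cond}_r{rep}"
            noise = rng.normal(0.0, config.expression_noise_sd, size=n)
            log2v = base_log2 + offsets[cond].to_numpy() + noise
            data.append(np.power(2.0, log2v))
            cols.append(sample)
            design_rows.append((sample, cond, rep))
    values = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene_id"), columns=cols
    )
    design = pd.DataFrame(
        design_rows, columns=["sample", "condition", "replicate"]
    ).set_index("sample")
    return ExpressionMatrix(values=values, design=design)


def _beta_condition_means(
    config: SimulationConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> pd.DataFrame:
    d = config.effect_delta_beta
    probes = list(truth.probe_class)
    n = len(probes)
    # baselines kept away from the support edges so planted shifts fit
    base = rng.uniform(0.15, 0.85, size=n)
    means = pd.DataFrame(
        np.repeat(base[:, None], len(CONDITIONS), axis=1),
        index=probes,
        columns=list(CONDITIONS),
    )
    for i, p in enumerate(probes):
        cls = truth.probe_class[p]
        if cls == "null":
            continue
        s = truth.probe_sign[p]
        shift = s * d
        if cls in ("hypoxia_hyper", "hif1a_hyper"):
            shift = d
        elif cls in ("hypoxia_hypo", "hif1a_hypo"):
            shift = -d
        # pull the baseline back so base + shift stays inside the support
        b = base[i]
        if b + shift > 0.95:
            b = 0.95 - shift
        elif b + shift < 0.05:
            b = 0.05 - shift
        means.iloc[i, :] = b
        if cls in ("hypoxia_hyper", "hypoxia_hypo"):
            # oxygen-driven: present in both hypoxic conditions
            means.at[p, "shCTR_HYP"] = b + shift
            means.at[p, "shHIF1A_HYP"] = b + shift
        elif cls in ("hif1a_hyper", "hif1a_hypo"):
            means.at[p, "shHIF1A_HYP"] = b + shift
        elif cls == "common_inverted":
            # shifted in hypoxia, reverted to baseline once HIF1A is lost
            means.at[p, "shCTR_HYP"] = b + shift
            means.at[p, "shHIF1A_HYP"] = b
    clamped = False
    arr = means.to_numpy()
    if (arr <= 0.01).any() or (arr >= 0.99).any():
        clamped = True
    if clamped:
        warnings.warn("planted beta means clamped to (0.01, 0.99)", stacklevel=2)
    means.iloc[:, :] = np.clip(arr, 0.01, 0.99)
    return means


def _annotate_probes(
    config: SimulationConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Build the probe manifest: coordinates, CGI feature, gene feature."""
    from .annotation import assign_cgi_features

    probes = list(truth.probe_class)
    coords = truth.probe_coords.loc[probes]
    cgi = []
    for chrom, sub in coords.groupby("chrom"):
        feats = assign_cgi_features(
            sub["pos"].to_numpy(), truth.islands.get(str(chrom), np.empty((0, 2)))
        )
        cgi.append(pd.Series(feats, index=sub.index))
    cgi_feature = pd.concat(cgi).loc[probes]

    # nearest gene on the same chromosome; beyond 100 kb -> intergenic
    gene_ids: list[str | None] = []
    gene_feature: list[str] = []
    genic_feats = [f for f in GENE_FEATURES if f != "IGR"]
    by_chrom = {
        str(c): sub.sort_values("tss") for c, sub in truth.gene_coords.groupby("chrom")
    }
    for p in probes:
        if p in truth.probe_gene_link:
            gene_ids.append(truth.probe_gene_link[p])
            gene_feature.append(str(rng.choice(["TSS200", "TSS1500", "five_prime_UTR"])))
            continue
        chrom = str(coords.at[p, "chrom"])
        pos = int(coords.at[p, "pos"])
        sub = by_chrom.get(chrom)
        nearest, dist = None, None
        if sub is not None and len(sub):
            tss = sub["tss"].to_numpy()
            i = int(np.clip(np.searchsorted(tss, pos), 0, len(tss) - 1))
            cand = {i, max(0, i - 1)}
            dists = {j: abs(int(tss[j]) - pos) for j in cand}
            j = min(dists, key=dists.get)
            nearest, dist = str(sub.index[j]), dists[j]
        if nearest is None or dist > 100_000:
            gene_ids.append(None)
            gene_feature.append("IGR")
        else:
            gene_ids.append(nearest)
            gene_feature.append(str(rng.choice(genic_feats)))
    return pd.DataFrame(
        {
            "chrom": coords["chrom"].to_numpy(),
            "pos": coords["pos"].to_numpy(),
            "cgi_feature": cgi_feature.to_numpy(),
            "gene_feature": gene_feature,
            "gene_id": gene_ids,
        },
        index=pd.Index(probes, name="probe_id"),
    )


def simulate_methylation(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Beta-value matrix plus probe manifest with planted shifts."""
    if config.replicates_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = substreams(config.seed, 8)[2]
    means = _beta_condition_means(config, truth, rng)
    probes = list(means.index)
    c = config.beta_concentration

    cols, data, design_rows = [], [], []
    for cond in config.conditions:
        m = means[cond].to_numpy()
        a, b = m * c, (1 - m) * c
        for rep in range(1, config.replicates_per_condition + 1):
            sample = f"{cond}_r{rep}"
            data.append(rng.beta(a, b))
            cols.append(sample)
            design_rows.append((sample, cond, rep))
    values = pd.DataFrame(
        np.column_stack(data), index=pd.Index(probes, name="probe_id"), columns=cols
    )
    design = pd.DataFrame(
        design_rows, columns=["sample", "condition", "replicate"]
    ).set_index("sample")
    manifest = _annotate_probes(config, truth, rng)
    return BetaMatrix(values=values, design=design), manifest


def simulate_marker_tracks(
    config: SimulationConfig, truth: SyntheticTruth
) -> list[MarkerTrack]:
    """One interval track per (cell line, marker) with planted active regions.

    Every enhancer probe is covered by all markers in all cell lines;
    background intervals never contain a probe position, and decoy probes
    receive at most 3 markers so the stringent filter has true negatives.
    """
    if not config.cell_lines or not config.markers:
        raise ValueError("need at least one cell line and one marker")
    rng = substreams(config.seed, 8)[3]
    coords = truth.probe_coords
    pos_by_chrom = {
        str(c): np.sort(sub["pos"].to_numpy()) for c, sub in coords.groupby("chrom")
    }

    def touches_probe(chrom: str, start: int, end: int) -> bool:
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            return False
        i = np.searchsorted(pos, start)
        return bool(i < len(pos) and pos[i] < end)

    null_probes = [p for p in coords.index if p not in truth.enhancer_probes]
    n_decoys = min(20, len(null_probes))
    decoys = list(rng.choice(null_probes, size=n_decoys, replace=False)) if n_decoys else []
    n_decoy_markers = min(3, len(config.markers) - 1) if len(config.markers) > 1 else 0

    tracks = []
    for cell_line in config.cell_lines:
        for mi, marker in enumerate(config.markers):
            rows = []
            for p in sorted(truth.enhancer_probes):
                chrom = str(coords.at[p, "chrom"])
                pos = int(coords.at[p, "pos"])
                pad_l = int(rng.integers(200, 1000))
                pad_r = int(rng.integers(200, 1000))
                rows.append((chrom, max(0, pos - pad_l), pos + pad_r))
            if mi < n_decoy_markers:
                for p in decoys:
                    chrom = str(coords.at[p, "chrom"])
                    pos = int(coords.at[p, "pos"])
                    rows.append((chrom, max(0, pos - 300), pos + 300))
            # probe-free background intervals
            placed = 0
            while placed < 50:
                chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
                start = int(rng.integers(0, config.genome_length_per_chrom - 2000))
                end = start + int(rng.integers(500, 2000))
                if not touches_probe(chrom, start, end):
                    rows.append((chrom, start, end))
                    placed += 1
            intervals = pd.DataFrame(rows, columns=["chrom", "start", "end"])
            intervals = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
            tracks.append(MarkerTrack(cell_line=cell_line, marker=marker, intervals=intervals))
    return tracks


def simulate_cohort(
    config: SimulationConfig, truth: SyntheticTruth
) -> CohortExpression:
    """Two-risk-class patient cohort with a planted separating signature.

    Values are on a log-like arbitrary scale: standard normal noise around
    a per-gene baseline, with signature genes shifted by
    ``signature_separation`` in the high-risk class.
    """
    if config.signature_separation > 0 and not truth.signature_genes:
        raise ValueError("signature_separation > 0 requires signature genes")
    rng = substreams(config.seed, 8)[4]
    genes = list(truth.gene_class)
    n = len(genes)
    n_pat = config.cohort_n_low + config.cohort_n_high
    patients = [f"P{i:03d}" for i in range(n_pat)]
    labels = ["low"] * config.cohort_n_low + ["high"] * config.cohort_n_high

    base = rng.uniform(4.0, 10.0, size=n)
    values = base[:, None] + rng.normal(0.0, config.cohort_noise_sd, size=(n, n_pat))
    sig_idx = [i for i, g in enumerate(genes) if g in truth.signature_genes]
    sig_sign = np.where(rng.random(len(sig_idx)) < 0.5, 1.0, -1.0)
    high_cols = np.array([lab == "high" for lab in labels])
    for k, i in enumerate(sig_idx):
        values[i, high_cols] += sig_sign[k] * config.signature_separation
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=patients)
    risk = pd.Series(labels, index=pd.Index(patients, name="patient_id"), name="risk")
    return CohortExpression(values=df, risk=risk)
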