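"""Two-group differential calling for expression and methylation.

Expression contrasts are tested per gene on log2(value + 1) replicate
values, with the fold change computed as
``log2((mean_b + 1) / (mean_a + 1))`` on the raw scale; methylation
contrasts are tested per probe directly on beta values with the effect
reported as the mean beta difference (delta-beta).  Both apply
Benjamini-Hochberg adjustment across all features.  Filtering follows the
study's gates: |log2FC| strictly greater than 0.5 with FDR < 0.05 for
expression, |delta-beta| strictly greater than 0.2 with FDR < 0.05 for
methylation.

The default test is a variance-moderated t-test: per-feature pooled
variances are shrunk toward a common prior fitted across all features by
empirical Bayes (the limma approach), which restores power at triplicate
sample sizes where a purely per-feature test cannot clear a
multiple-testing correction.  A plain per-feature Welch t-test is
available with ``method="welch"``.

Also provides the 2^-ddCT relative-quantification utility for real-time
PCR fold changes against a reference gene and a calibrator condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from ._util import bh_adjust
from .containers import BetaMatrix, DirectionalGeneSet, ExpressionMatrix

#: Pseudocount added before log transform / ratio of mean abundances.
EPSILON = 1.0

EXPRESSION_COLUMNS = ("log2fc", "p_value", "q_value", "direction")
METHYLATION_COLUMNS = ("delta_beta", "p_value", "q_value", "state")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


def _moderated(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Row-wise moderated t-test p-values (empirical-Bayes variance pooling).

    Per-row pooled variances s_g^2 (df d_g = n_a + n_b - 2) are shrunk
    toward a prior (d0, s0^2) fitted by moments on log s_g^2; the
    moderated statistic uses the posterior variance with d0 + d_g degrees
    of freedom.  With homogeneous row variances d0 grows without bound and
    the test approaches a z-test on the pooled scale; with heterogeneous
    variances it falls back toward the per-row test.  Rows left degenerate
    (no positive variance anywhere) use the zero-variance convention of
    :func:`_welch`.
    """
    na, nb = values_a.shape[1], values_b.shape[1]
    dg = na + nb - 2
    va = values_a.var(axis=1, ddof=1)
    vb = values_b.var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / dg
    diff = values_b.mean(axis=1) - values_a.mean(axis=1)

    pos = s2 > 0
    if not pos.any():
        p = np.ones_like(s2)
        p[~np.isclose(diff, 0)] = 0.0
        return p
    z = np.log(s2[pos])
    e = z - float(digamma(dg / 2)) + math.log(dg / 2)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, dg / 2)) if e.size > 1 else 0.0
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(float(np.mean(e)) + float(digamma(d0 / 2)) - math.log(d0 / 2))
    else:
        d0, s0_sq = np.inf, math.exp(float(np.mean(e)))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        eq = np.isclose(values_a.mean(axis=1), values_b.mean(axis=1))
        p = np.where(degenerate & eq, 1.0, np.where(degenerate, 0.0, p))
    return np.asarray(p, dtype=float)


def _welch(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values with the zero-variance convention.

    Rows where both groups are constant get p = 1 when the means agree
    (no evidence of change) and p = 0 when they differ (change observed
    without noise); this avoids NaN propagation downstream.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(values_b, values_a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        mean_eq = np.isclose(values_a.mean(axis=1), values_b.mean(axis=1))
        p[degenerate & mean_eq] = 1.0
        p[degenerate & ~mean_eq] = 0.0
    return p


def _group_values(m, group_a: str, group_b: str) -> tuple[np.ndarray, np.ndarray]:
    samples_a = m.condition_samples(group_a)
    samples_b = m.condition_samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"both groups need >= 2 replicates (got {len(samples_a)} for "
            f"{group_a!r}, {len(samples_b)} for {group_b!r})"
        )
    return (
        m.values[samples_a].to_numpy(dtype=float),
        m.values[samples_b].to_numpy(dtype=float),
    )


_TESTS = {"moderated": _moderated, "welch": _welch}


def contrast_expression(
    m: ExpressionMatrix, group_a: str, group_b: str, method: str = "moderated"
) -> pd.DataFrame:
    """Differential expression of ``group_b`` relative to ``group_a``.

    Returns a DataFrame indexed by gene with columns ``log2fc``,
    ``p_value``, ``q_value`` and ``direction`` ("up"/"down"/"none" by
    fold-change sign).
    """
    va, vb = _group_values(m, group_a, group_b)
    log2fc = np.log2((vb.mean(axis=1) + EPSILON) / (va.mean(axis=1) + EPSILON))
    p = _TESTS[method](np.log2(va + EPSILON), np.log2(vb + EPSILON))
    q = bh_adjust(p)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "q_value": q, "direction": direction},
        index=m.gene_ids.copy(),
    )


def contrast_methylation(
    b: BetaMatrix, group_a: str, group_b: str, method: str = "moderated"
) -> pd.DataFrame:
    """Differential methylation of ``group_b`` relative to ``group_a``.

    Returns a DataFrame indexed by probe with columns ``delta_beta``
    (mean beta of B minus mean beta of A), ``p_value``, ``q_value`` and
    ``state`` ("hyper"/"hypo"/"none" by sign).
    """
    va, vb = _group_values(b, group_a, group_b)
    delta = vb.mean(axis=1) - va.mean(axis=1)
    p = _TESTS[method](va, vb)
    q = bh_adjust(p)
    state = np.where(delta > 0, "hyper", np.where(delta < 0, "hypo", "none"))
    return pd.DataFrame(
        {"delta_beta": delta, "p_value": p, "q_value": q, "state": state},
        index=b.probe_ids.copy(),
    )


def filter_de(
    records: pd.DataFrame,
    lfc_threshold: float = 0.5,
    fdr: float = 0.05,
    contrast_label: str = "",
) -> DirectionalGeneSet:
    """Retain genes with q < fdr and |log2FC| strictly above the threshold.

    The fold-change gate is strict on both sides (> +0.5 up-regulated,
    < -0.5 down-regulated); a gene at exactly the threshold is excluded.
    """
    if len(records) == 0:
        raise ValueError("no records to filter")
    if lfc_threshold < 0 or not 0 < fdr <= 1:
        raise ValueError("thresholds must be nonnegative (lfc) and fdr in (0, 1]")
    keep = (records["q_value"] < fdr) & (records["log2fc"].abs() > lfc_threshold)
    entries = records.loc[keep, ["log2fc", "q_value"]].copy()
    entries["direction"] = np.where(entries["log2fc"] > 0, "up", "down")
    return DirectionalGeneSet(contrast_label=contrast_label, entries=entries)


def filter_dm(
    records: pd.DataFrame, delta_threshold: float = 0.2, fdr: float = 0.05
) -> pd.DataFrame:
    """Retain probes with q < fdr and |delta-beta| strictly above threshold.

    Returns the retained rows with ``state`` set to "hyper"
    (delta-beta > threshold) or "hypo" (delta-beta < -threshold).
    """
    if len(records) == 0:
        raise ValueError("no records to filter")
    if not 0 < delta_threshold < 1:
        raise ValueError("delta_threshold must lie in (0, 1)")
    if not 0 < fdr <= 1:
        raise ValueError("fdr must lie in (0, 1]")
    keep = (records["q_value"] < fdr) & (records["delta_beta"].abs() > delta_threshold)
    out = records.loc[keep].copy()
    out["state"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    return out


@dataclass
class CtTable:
    """Real-time PCR cycle-threshold measurements.

    ``ct`` has one row per measurement with columns ``gene``, ``sample``,
    ``condition`` and ``ct``; the reference gene (housekeeping control,
    beta-actin role) must be measured in every condition.
    """

    ct: pd.DataFrame
    reference_gene: str
    calibrator_condition: str

    def __post_init__(self) -> None:
        required = {"gene", "condition", "ct"}
        if not required <= set(self.ct.columns):
            raise ValueError(f"ct table needs columns {sorted(required)}")
        if (self.ct["ct"] <= 0).any():
            raise ValueError("CT values must be positive")
        for cond in self.ct["condition"].unique():
            sub = self.ct[self.ct["condition"] == cond]
            if self.reference_gene not in set(sub["gene"]):
                raise ValueError(
                    f"reference gene {self.reference_gene!r} missing in {cond!r}"
                )


def ddct_fold_change(ct: CtTable, target_gene: str, test_condition: str) -> float:
    """Relative expression by the 2^-ddCT method.

    dCT = mean CT(target) - mean CT(reference) within each condition;
    ddCT = dCT(test) - dCT(calibrator); fold change = 2^-ddCT.
    """

    def dct(condition: str) -> float:
        sub = ct.ct[ct.ct["condition"] == condition]
        target = sub.loc[sub["gene"] == target_gene, "ct"]
        ref = sub.loc[sub["gene"] == ct.reference_gene, "ct"]
        if target.empty:
            raise ValueError(f"gene {target_gene!r} not measured in {condition!r}")
        return float(target.mean() - ref.mean())

    ddct = dct(test_condition) - dct(ct.calibrator_condition)
    return float(2.0 ** (-ddct))
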