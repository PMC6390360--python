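"""Signature-based cohort clustering and risk-class classification.

Expression of a gene signature across a patient cohort is z-scored per
gene (sample standard deviation), the patients are clustered by
agglomerative hierarchical clustering on Euclidean distances, the
dendrogram is cut into two clusters, and each risk class is scored by the
percentage of its patients falling in the cluster where that class is the
majority.  The cluster-by-risk association is tested by a permutation
test on the 2x2 table's chi-square statistic: shuffling risk labels with
cluster sizes fixed is equivalent to drawing the high-risk count of one
cluster from a hypergeometric distribution, which is how the null is
sampled.  The p-value carries an add-one correction so it is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._util import format_pct
from .containers import CohortExpression

LINKAGE_METHODS = ("complete", "average", "ward")


@dataclass
class ClusteringReport:
    """Two-cluster cut of a cohort scored against its risk labels."""

    assignment: pd.Series  # patient -> 1 | 2
    high_pct: float
    low_pct: float
    p_value: float
    high_majority_cluster: int
    low_majority_cluster: int


def zscore_transform(m: CohortExpression, signature) -> pd.DataFrame:
    """Per-gene z-scores of the signature rows across patients.

    Uses the sample (n-1) standard deviation.  Zero-variance genes are
    dropped with a warning; genes absent from the cohort raise.
    """
    signature = list(dict.fromkeys(signature))
    missing = [g for g in signature if g not in m.values.index]
    if missing:
        raise ValueError(f"signature genes absent from cohort: {missing[:5]}")
    sub = m.values.loc[signature]
    sd = sub.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance signature gene(s)",
            stacklevel=2,
        )
        sub, sd = sub.loc[~flat], sd[~flat]
    if sub.empty:
        raise ValueError("no signature gene with nonzero variance")
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def cluster_two(z: pd.DataFrame, method: str = "complete") -> pd.Series:
    """Cut an agglomerative Euclidean dendrogram of patients into 2 clusters.

    Columns are patients.  Deterministic for a fixed input order; scipy's
    linkage resolves distance ties by merge order.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage method must be one of {LINKAGE_METHODS}")
    if z.shape[1] < 2:
        raise ValueError("need at least 2 patients to cluster")
    link = linkage(z.to_numpy().T, method=method, metric="euclidean")
    labels = fcluster(link, t=2, criterion="maxclust")
    return pd.Series(labels, index=z.columns, name="cluster")


def risk_classification(
    assignment: pd.Series,
    risk: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusteringReport:
    """Score a two-cluster assignment against binary risk labels.

    The high-majority cluster is the one holding most high-risk patients
    (ties go to the smaller cluster); ``high_pct`` is the percentage of
    all high-risk patients inside it, ``low_pct`` the percentage of
    low-risk patients inside the *other* cluster, both half-up to one
    decimal.  The permutation p-value is (1 + #{null >= observed}) /
    (n_perm + 1) for the chi-square statistic of the 2x2 table.
    """
    patients = [p for p in assignment.index if p in risk.index]
    a = assignment.loc[patients]
    r = risk.loc[patients]
    clusters = sorted(a.unique())
    if len(clusters) == 1:
        # degenerate cut: everything in one cluster
        only = int(clusters[0])
        other = 2 if only == 1 else 1
        high_pct = format_pct(int(((a == only) & (r == "high")).sum()), int((r == "high").sum()))
        low_pct = 0.0
        return ClusteringReport(
            assignment=a, high_pct=high_pct, low_pct=low_pct,
            p_value=1.0, high_majority_cluster=only, low_majority_cluster=other,
        )

    n_high = int((r == "high").sum())
    n_low = int((r == "low").sum())
    high_in = {c: int(((a == c) & (r == "high")).sum()) for c in clusters}
    size = {c: int((a == c).sum()) for c in clusters}
    c1, c2 = clusters
    if high_in[c1] == high_in[c2]:
        high_cluster = c1 if size[c1] <= size[c2] else c2
    else:
        high_cluster = c1 if high_in[c1] > high_in[c2] else c2
    low_cluster = c2 if high_cluster == c1 else c1

    high_pct = format_pct(high_in[high_cluster], n_high)
    low_in_low = int(((a == low_cluster) & (r == "low")).sum())
    low_pct = format_pct(low_in_low, n_low)

    def chi2_stat(k: np.ndarray, n1: int) -> np.ndarray:
        # chi-square of the 2x2 table given high-risk count k in cluster 1
        n = n_high + n_low
        e = np.array(
            [
                n1 * n_high / n,
                n1 * n_low / n,
                (n - n1) * n_high / n,
                (n - n1) * n_low / n,
            ]
        )
        obs = np.stack([k, n1 - k, n_high - k, n_low - (n1 - k)])
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = (obs - e[:, None]) ** 2 / e[:, None]
            contrib = np.where(e[:, None] > 0, contrib, 0.0)
        return contrib.sum(axis=0)

    n1 = size[c1]
    observed = float(chi2_stat(np.array([high_in[c1]]), n1)[0])
    rng = np.random.default_rng(seed)
    null_k = rng.hypergeometric(n_high, n_low, n1, size=n_perm)
    null_stats = chi2_stat(null_k, n1)
    p = (1 + int((null_stats >= observed - 1e-12).sum())) / (n_perm + 1)
    return ClusteringReport(
        assignment=a,
        high_pct=high_pct,
        low_pct=low_pct,
        p_value=float(p),
        high_majority_cluster=int(high_cluster),
        low_majority_cluster=int(low_cluster),
    )


def signature_report(
    cohort: CohortExpression,
    signature,
    method: str = "complete",
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusteringReport:
    """Convenience wrapper: z-score, cluster into two, score against risk."""
    z = zscore_transform(cohort, signature)
    assignment = cluster_two(z, method=method)
    return risk_classification(assignment, cohort.risk, n_perm=n_perm, seed=seed)
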