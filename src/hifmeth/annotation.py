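"""Probe annotation and over-representation statistics.

CGI-centric annotation places a probe relative to the nearest CpG island:
inside an island, on a shore (within 2 kb of an island edge), on a shelf
(2-4 kb) or in the open sea (beyond 4 kb).  Band boundaries at exactly
2000/4000 bp fall in the band nearer the island.  Feature distributions
of a probe selection against the manifest background, and gene-set
over-representation against a GMT-style collection, are both tested with
one-sided hypergeometric tails and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust
from .containers import CGI_FEATURES, GENE_FEATURES

SHORE_BP = 2000
SHELF_BP = 4000


def _island_distance(pos: np.ndarray, islands: np.ndarray) -> np.ndarray:
    """Distance (bp) from each position to the nearest island; 0 if inside.

    Islands are half-open [start, end) intervals, assumed non-overlapping.
    """
    islands = np.asarray(islands, dtype=float).reshape(-1, 2)
    if islands.shape[0] == 0:
        return np.full(np.asarray(pos).shape, np.inf)
    order = np.argsort(islands[:, 0])
    starts, ends = islands[order, 0], islands[order, 1]
    pos = np.asarray(pos, dtype=float)
    i = np.searchsorted(starts, pos, side="right")
    dist_prev = np.where(i > 0, pos - ends[np.maximum(i - 1, 0)] + 1, np.inf)
    inside = (i > 0) & (pos < ends[np.maximum(i - 1, 0)])
    dist_next = np.where(i < len(starts), starts[np.minimum(i, len(starts) - 1)] - pos, np.inf)
    dist = np.minimum(np.maximum(dist_prev, 0), np.maximum(dist_next, 0))
    return np.where(inside, 0.0, dist)


def assign_cgi_features(pos, islands) -> np.ndarray:
    """Vectorised CGI-centric feature assignment for positions on one chromosome."""
    d = _island_distance(np.atleast_1d(pos), islands)
    out = np.full(d.shape, "open_sea", dtype=object)
    out[d <= SHELF_BP] = "shelf"
    out[d <= SHORE_BP] = "shore"
    out[d == 0] = "island"
    return out


def assign_cgi_feature(pos: int, islands) -> str:
    """CGI-centric feature of a single position; no islands means open sea."""
    return str(assign_cgi_features([pos], islands)[0])


def _hypergeom_tails(k: int, n_sel: int, n_feat: int, n_bg: int) -> tuple[float, float]:
    """One-sided over- and under-representation p-values for an overlap k."""
    over = float(stats.hypergeom.sf(k - 1, n_bg, n_feat, n_sel))
    under = float(stats.hypergeom.cdf(k, n_bg, n_feat, n_sel))
    return over, under


def feature_distribution(
    selection, manifest: pd.DataFrame, system: str = "cgi", fdr: float = 0.05
) -> pd.DataFrame:
    """Feature counts of a probe selection vs the manifest background.

    ``system`` chooses the annotation column ("cgi" or "gene").  Each
    feature gets selection and background fractions, an odds ratio, the
    smaller of the one-sided hypergeometric tails (doubled, capped at 1,
    as the reported p) with over/under recorded, BH-adjusted across
    features, and a call ("over"/"under"/"none") at q < fdr.
    """
    selection = list(selection)
    if not selection:
        raise ValueError("selection is empty")
    missing = set(selection) - set(manifest.index)
    if missing:
        raise ValueError(f"selection probes absent from manifest: {sorted(missing)[:5]}")
    column = {"cgi": "cgi_feature", "gene": "gene_feature"}.get(system)
    if column is None:
        raise ValueError(f"unknown feature system {system!r}")
    features = CGI_FEATURES if system == "cgi" else GENE_FEATURES

    bg_counts = manifest[column].value_counts()
    sel_counts = manifest.loc[selection, column].value_counts()
    n_bg, n_sel = len(manifest), len(selection)

    rows = []
    for feat in features:
        k = int(sel_counts.get(feat, 0))
        m = int(bg_counts.get(feat, 0))
        over, under = _hypergeom_tails(k, n_sel, m, n_bg)
        side = "over" if over <= under else "under"
        p = min(1.0, 2.0 * min(over, under))
        # feature odds in the selection relative to the whole background
        num, den = k * (n_bg - m), (n_sel - k) * m
        odds = 1.0 if num == den == 0 else (np.inf if den == 0 else num / den)
        rows.append((feat, k, k / n_sel, m / n_bg, odds, p, side))
    out = pd.DataFrame(
        rows,
        columns=["feature", "count", "fraction", "background_fraction",
                 "odds_ratio", "p_value", "side"],
    ).set_index("feature")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["call"] = np.where(out["q_value"] < fdr, out["side"], "none")
    return out


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)


def geneset_enrichment(
    query,
    background,
    collection: GeneSetCollection,
    min_size: int = 10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query against a collection.

    Category members are intersected with the background first; categories
    smaller than ``min_size`` after intersection are not tested.  The
    one-sided p is P(overlap >= observed); BH is applied across tested
    categories and a category is enriched if q <= fdr.  The returned table
    also carries -log10(p) for plotting.
    """
    query, background = set(query), set(background)
    if not query:
        raise ValueError("query is empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    n_bg, n_query = len(background), len(query)
    rows = []
    for name, members in collection.sets.items():
        in_bg = set(members) & background
        if len(in_bg) < min_size:
            continue
        k = len(in_bg & query)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(in_bg), n_query))
        rows.append((name, len(in_bg), k, p))
    out = pd.DataFrame(
        rows, columns=["category", "category_size", "overlap", "p_value"]
    ).set_index("category")
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["neg_log10_p"] = -np.log10(np.maximum(out["p_value"], 1e-300))
        out["enriched"] = out["q_value"] <= fdr
        out = out.sort_values("p_value")
    else:
        out["q_value"] = []
        out["neg_log10_p"] = []
        out["enriched"] = []
    return out
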