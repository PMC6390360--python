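"""Small shared helpers: percentage formatting, seeded substreams, BH wrapper."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from statsmodels.stats.multitest import multipletests


def format_pct(k: int, n: int, decimals: int = 1) -> float:
    """Percentage 100*k/n rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding so 43.45 -> 43.5, matching how such
    fractions are conventionally reported.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(100) * Decimal(k) / Decimal(n)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed.

    Stage-specific substreams keep stages reproducible in isolation while
    still being driven by a single user-facing seed.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
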