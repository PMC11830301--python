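"""Fixed-effect inverse-variance meta-analysis on the estimate's own scale
(log-OR for associations, raw scale for variance shares and correlations)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import DataError

__all__ = ["MetaResult", "fixed_effect_meta"]


@dataclass
class MetaResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    weights: np.ndarray
    n_cohorts: int


def fixed_effect_meta(estimates, ses) -> MetaResult:
    """Pool cohort estimates with inverse-variance weights.

    Pooled estimate = sum(w_i b_i) / sum(w_i), w_i = 1/se_i^2;
    pooled SE = sqrt(1 / sum(w_i)).
    """
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise DataError("no estimates to pool")
    if np.any(s <= 0):
        raise DataError("non-positive standard error in meta-analysis input")
    w = 1.0 / s**2
    est = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = est / se
    return MetaResult(
        estimate=est,
        se=se,
        ci_low=est - 1.959963984540054 * se,
        ci_high=est + 1.959963984540054 * se,
        p_value=float(2.0 * norm.sf(abs(z))),
        weights=w / w.sum(),
        n_cohorts=int(b.size),
    )
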