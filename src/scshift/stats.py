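"""Small shared statistical primitives.

Tippett's minimum-p combiner and the add-one permutation p-value
estimator, used by several analysis modules.
"""

from __future__ import annotations

import numpy as np

from ._utils import ScshiftError


def tippett_meta_p(p_values, k: int | None = None) -> float:
    """Tippett (minimum-p) meta-analysis combiner: 1 - (1 - min p)^k.

    ``k`` defaults to the number of p-values supplied; pass it explicitly
    when the list is a subset of a larger family (e.g. permutation
    replicates). Evaluated as ``-expm1(k * log1p(-min_p))`` for accuracy
    at small p.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ScshiftError("tippett_meta_p needs at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ScshiftError("p-values must lie in (0, 1]")
    if k is None:
        k = p.size
    if k < 1:
        raise ScshiftError("k must be a positive count")
    pmin = p.min()
    if pmin == 1.0:
        return 1.0
    return float(-np.expm1(k * np.log1p(-pmin)))


def empirical_p(null: np.ndarray, observed: float) -> float:
    """Add-one permutation p: (1 + #{null >= observed}) / (1 + n).

    Never returns 0, so downstream multiplicity corrections stay valid.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ScshiftError("empirical_p needs a nonempty null sample")
    return float((1 + np.sum(null >= observed)) / (1 + null.size))
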