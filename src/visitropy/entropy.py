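"""Approximate, Sample, and Fuzzy Entropy for finite scalar sequences.

All three statistics quantify the regularity of a time series by comparing
length-``m`` templates (sub-vectors) under the Chebyshev (maximum absolute
difference) distance with tolerance ``r``:

* **ApEn** counts matches *including* the self-match, averages the natural
  logarithm of per-template match frequencies, and reports
  ``phi^m(r) - phi^(m+1)(r)`` (Pincus' definition).
* **SampEn** excludes self-matches and reports ``-ln(A/B)`` where ``B`` and
  ``A`` are the mean match probabilities at lengths ``m`` and ``m + 1``.
  When either probability is zero the result is *undefined* and reported as
  such (never substituted with an arbitrary number).
* **FuzzyEn** removes each template's own mean (baseline) and replaces hard
  thresholding with the exponential membership ``exp(-(d^n)/r)``, so it is
  defined for every sequence.

``r`` is an *absolute* tolerance applied to the raw values — it is not
rescaled by the series standard deviation.  On odd-integer room codes
(minimum gap 2 between distinct codes) every ``r < 2`` therefore selects
exactly the same template matches for ApEn and SampEn.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

__all__ = [
    "EntropyConfig",
    "EntropyResult",
    "InsufficientLengthError",
    "apen",
    "sampen",
    "fuzzyen",
    "entropy",
    "template_distance",
]

logger = logging.getLogger(__name__)

#: negative results smaller than this in magnitude are floating-point noise
_NEG_CLAMP = 1e-12

Measure = Literal["apen", "sampen", "fuzzyen"]


class InsufficientLengthError(ValueError):
    """Raised when a sequence is shorter than ``m + 2`` samples."""


@dataclass(frozen=True)
class EntropyConfig:
    """Choice of measure plus its parameters.

    Parameters
    ----------
    measure:
        One of ``"apen"``, ``"sampen"``, ``"fuzzyen"``.
    m:
        Embedding dimension (template length), ``>= 1``.
    r:
        Absolute tolerance (same units as the series values), ``> 0``.
    n:
        Gradient of the exponential membership function (FuzzyEn only),
        ``> 0``.  The common choice is 2.
    """

    measure: Measure = "fuzzyen"
    m: int = 2
    r: float = 1.0
    n: float = 2.0

    def __post_init__(self) -> None:
        if self.measure not in ("apen", "sampen", "fuzzyen"):
            raise ValueError(f"unknown entropy measure: {self.measure!r}")
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be > 0")
        if self.n <= 0:
            raise ValueError("fuzzy gradient n must be > 0")


@dataclass(frozen=True)
class EntropyResult:
    """Entropy value with the parameters that produced it.

    ``value`` is ``None`` exactly when the statistic is undefined (SampEn
    with no template matches, a log of zero).
    """

    value: Optional[float]
    measure: Measure
    m: int
    r: float
    n: Optional[float]
    N: int

    @property
    def defined(self) -> bool:
        return self.value is not None


def _as_array(seq: Sequence[float]) -> np.ndarray:
    x = np.asarray(seq, dtype=float)
    if x.ndim != 1:
        raise ValueError("sequence must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("sequence values must be finite")
    return x


def _validate(seq: Sequence[float], m: int, r: float) -> np.ndarray:
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    x = _as_array(seq)
    if x.size < m + 2:
        raise InsufficientLengthError(
            f"need at least m + 2 = {m + 2} samples, got {x.size}"
        )
    return x


def _clamp(v: float, measure: str) -> float:
    if v < 0:
        if -v < _NEG_CLAMP:
            return 0.0
        logger.warning("%s returned a negative value %.3e (kept as-is)", measure, v)
    return v


def template_distance(seq: Sequence[float], i: int, j: int, m: int) -> float:
    """Chebyshev distance between the 1-based length-``m`` templates at ``i``, ``j``.

    Returns ``max_k |a(i+k) - a(j+k)|`` for ``k = 0 .. m-1``.
    """
    x = _as_array(seq)
    n_templates = x.size - m + 1
    if not (1 <= i <= n_templates and 1 <= j <= n_templates):
        raise IndexError(
            f"template indices must lie in [1, {n_templates}], got i={i}, j={j}"
        )
    a = x[i - 1 : i - 1 + m]
    b = x[j - 1 : j - 1 + m]
    return float(np.max(np.abs(a - b)))


def apen(seq: Sequence[float], m: int = 2, r: float = 1.0) -> EntropyResult:
    """Approximate Entropy ApEn(m, r, N) with self-matches included."""
    x = _validate(seq, m, r)

    def phi(mm: int) -> float:
        t = sliding_window_view(x, mm)  # all N - mm + 1 templates
        d = cdist(t, t, "chebyshev")
        c = (d <= r).mean(axis=1)  # self-match keeps every C_i > 0
        return float(np.mean(np.log(c)))

    v = _clamp(phi(m) - phi(m + 1), "ApEn")
    return EntropyResult(v, "apen", m, r, None, x.size)


def sampen(seq: Sequence[float], m: int = 2, r: float = 1.0) -> EntropyResult:
    """Sample Entropy SampEn(m, r, N); undefined when no templates match."""
    x = _validate(seq, m, r)
    nm = x.size - m  # number of (m+1)-templates; the first N-m m-templates

    t_m = sliding_window_view(x, m)[:nm]
    t_m1 = sliding_window_view(x, m + 1)

    def mean_matches(t: np.ndarray) -> float:
        d = cdist(t, t, "chebyshev")
        per_template = ((d <= r).sum(axis=1) - 1) / (nm - 1)  # j != i
        return float(per_template.mean())

    b = mean_matches(t_m)
    a = mean_matches(t_m1)
    if a == 0.0 or b == 0.0:
        logger.debug("SampEn undefined (b=%g, a=%g) for N=%d", b, a, x.size)
        return EntropyResult(None, "sampen", m, r, None, x.size)
    return EntropyResult(float(math.log(b) - math.log(a)), "sampen", m, r, None, x.size)


def fuzzyen(
    seq: Sequence[float], m: int = 2, r: float = 1.0, n: float = 2.0
) -> EntropyResult:
    """Fuzzy Entropy FuzzyEn(m, r, N) with exponential membership exp(-d^n / r)."""
    if n <= 0:
        raise ValueError("fuzzy gradient n must be > 0")
    x = _validate(seq, m, r)
    nm = x.size - m

    def phi(mm: int) -> float:
        t = sliding_window_view(x, mm)[:nm].astype(float)
        t = t - t.mean(axis=1, keepdims=True)  # remove per-template baseline
        d = cdist(t, t, "chebyshev")
        sim = np.exp(-(d**n) / r)
        per_template = (sim.sum(axis=1) - 1.0) / (nm - 1)  # D_ii == 1 excluded
        return float(per_template.mean())

    v = _clamp(math.log(phi(m)) - math.log(phi(m + 1)), "FuzzyEn")
    return EntropyResult(v, "fuzzyen", m, r, n, x.size)


def entropy(seq: Sequence[float], config: EntropyConfig) -> EntropyResult:
    """Compute the entropy measure selected by ``config``."""
    if config.measure == "apen":
        return apen(seq, config.m, config.r)
    if config.measure == "sampen":
        return sampen(seq, config.m, config.r)
    return fuzzyen(seq, config.m, config.r, config.n)
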