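"""Brute-force reference implementations of the entropy measures.

Deliberately naive O(N^2 * m) double loops in pure Python, kept independent
of the vectorized implementations in :mod:`visitropy.entropy` so the two can
cross-check each other.  Besides the entropy value, the oracle returns the
full computation trace (per-template counts, phi terms, similarity degrees),
which the tests use to assert the internal invariants of each definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .entropy import EntropyConfig, EntropyResult, InsufficientLengthError

__all__ = ["ComputationTrace", "entropy_oracle"]


@dataclass
class ComputationTrace:
    """Intermediate quantities of a brute-force entropy computation."""

    # ApEn: per-template match frequencies C_i^m (self-match included)
    c_m: List[float] = field(default_factory=list)
    c_m1: List[float] = field(default_factory=list)
    phi_m: Optional[float] = None
    phi_m1: Optional[float] = None
    # SampEn: per-template match probabilities and their means
    b_i: List[float] = field(default_factory=list)
    a_i: List[float] = field(default_factory=list)
    b_m: Optional[float] = None
    a_m: Optional[float] = None
    # FuzzyEn: template baselines and similarity degrees D_ij^m
    baselines: List[float] = field(default_factory=list)
    d_sim: List[List[float]] = field(default_factory=list)


def _cheb(x: Sequence[float], i: int, j: int, m: int) -> float:
    """Chebyshev distance between 0-based templates at i and j."""
    d = 0.0
    for k in range(m):
        v = abs(x[i + k] - x[j + k])
        if v > d:
            d = v
    return d


def _check(x: Sequence[float], m: int, r: float) -> None:
    if m < 1:
        raise ValueError("m must be >= 1")
    if r <= 0:
        raise ValueError("r must be > 0")
    if len(x) < m + 2:
        raise InsufficientLengthError(
            f"need at least m + 2 = {m + 2} samples, got {len(x)}"
        )


def _apen_oracle(x: Sequence[float], m: int, r: float) -> Tuple[EntropyResult, ComputationTrace]:
    n = len(x)
    trace = ComputationTrace()

    def phi(mm: int) -> Tuple[float, List[float]]:
        nt = n - mm + 1
        cs = []
        for i in range(nt):
            count = 0
            for j in range(nt):  # includes j == i
                if _cheb(x, i, j, mm) <= r:
                    count += 1
            cs.append(count / nt)
        return sum(math.log(c) for c in cs) / nt, cs

    phi_m, trace.c_m = phi(m)
    phi_m1, trace.c_m1 = phi(m + 1)
    trace.phi_m, trace.phi_m1 = phi_m, phi_m1
    v = phi_m - phi_m1
    if v < 0 and -v < 1e-12:
        v = 0.0
    return EntropyResult(v, "apen", m, r, None, n), trace


def _sampen_oracle(x: Sequence[float], m: int, r: float) -> Tuple[EntropyResult, ComputationTrace]:
    n = len(x)
    nm = n - m
    trace = ComputationTrace()

    def mean_matches(mm: int) -> Tuple[float, List[float]]:
        per = []
        for i in range(nm):
            count = 0
            for j in range(nm):
                if j != i and _cheb(x, i, j, mm) <= r:
                    count += 1
            per.append(count / (nm - 1))
        return sum(per) / nm, per

    b, trace.b_i = mean_matches(m)
    a, trace.a_i = mean_matches(m + 1)
    trace.b_m, trace.a_m = b, a
    if a == 0.0 or b == 0.0:
        return EntropyResult(None, "sampen", m, r, None, n), trace
    return EntropyResult(-math.log(a / b), "sampen", m, r, None, n), trace


def _fuzzyen_oracle(
    x: Sequence[float], m: int, r: float, n_grad: float
) -> Tuple[EntropyResult, ComputationTrace]:
    n = len(x)
    nm = n - m
    trace = ComputationTrace()
    trace.baselines = [sum(x[i : i + m]) / m for i in range(nm)]

    def phi(mm: int, keep_sim: bool) -> float:
        base = [sum(x[i : i + mm]) / mm for i in range(nm)]
        total = 0.0
        for i in range(nm):
            s = 0.0
            row = []
            for j in range(nm):
                if j == i:
                    if keep_sim:
                        row.append(1.0)
                    continue
                d = 0.0
                for k in range(mm):
                    v = abs((x[i + k] - base[i]) - (x[j + k] - base[j]))
                    if v > d:
                        d = v
                sim = math.exp(-(d**n_grad) / r)
                if keep_sim:
                    row.append(sim)
                s += sim
            if keep_sim:
                trace.d_sim.append(row)
            total += s / (nm - 1)
        return total / nm

    phi_m = phi(m, keep_sim=True)
    phi_m1 = phi(m + 1, keep_sim=False)
    trace.phi_m, trace.phi_m1 = phi_m, phi_m1
    v = math.log(phi_m) - math.log(phi_m1)
    if v < 0 and -v < 1e-12:
        v = 0.0
    return EntropyResult(v, "fuzzyen", m, r, n_grad, n), trace


def entropy_oracle(
    seq: Sequence[float], config: EntropyConfig
) -> Tuple[EntropyResult, ComputationTrace]:
    """Naive reference computation of the configured entropy measure."""
    x = [float(v) for v in seq]
    _check(x, config.m, config.r)
    if config.measure == "apen":
        return _apen_oracle(x, config.m, config.r)
    if config.measure == "sampen":
        return _sampen_oracle(x, config.m, config.r)
    return _fuzzyen_oracle(x, config.m, config.r, config.n)
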