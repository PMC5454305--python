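"""Closed-form bounds on the rate-distortion function of random environments.

The two scaling regimes are explained by simple codebook constructions:

* Low fidelity (tolerated distortion D above the minimal confound): each
  state has on average ``N P(d < D)`` harmless synonyms, so coding them as
  interchangeable needs about ``log2(1 / P(d < D))`` bits — independent of
  the number of states N.
* High fidelity (D below the minimal confound): a codebook spreading a
  total confusion probability C uniformly off the diagonal gives an upper
  bound, and the optimal code for the easier environment where every
  confusion costs exactly the minimal confound gives a lower bound; both
  scale like ``log2 N``, pinning R(D) to linear growth in complexity.

All rates are in bits.  An infinite bound (zero quantile mass) is returned
as ``math.inf`` so callers can branch on the regime rather than catch
exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .environments import DistortionMatrix

__all__ = [
    "BoundSet",
    "binary_entropy",
    "quantile_upper_bound",
    "synonym_upper_bound",
    "uniform_alloc_bound",
    "uniform_alloc_bound_at_distortion",
    "uniform_env_rd",
    "asymptotic_bounds",
    "required_gain",
    "gaussian_rd",
    "bound_report",
]


def binary_entropy(c: float) -> float:
    """H_b(c) = -c log2 c - (1-c) log2 (1-c), with H_b(0) = H_b(1) = 0."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"argument must be in [0, 1], got {c}")
    return float(-(special.xlogy(c, c) + special.xlogy(1.0 - c, 1.0 - c)) / math.log(2.0))


def quantile_upper_bound(cdf_at_D: float) -> float:
    """Rate ceiling log2(1 / P(d < D)) from the accumulation of synonyms.

    ``cdf_at_D`` is the probability that a single random confusion costs
    less than the tolerated distortion D.  The bound does not involve N:
    it is the constant that perceptual cost asymptotes to in the
    low-fidelity regime.  Returns ``inf`` when the quantile mass is zero
    (D at or below the minimal confound), where the bound diverges.
    """
    if not 0.0 <= cdf_at_D <= 1.0:
        raise ValueError(f"cdf_at_D must be in [0, 1], got {cdf_at_D}")
    if cdf_at_D == 0.0:
        return math.inf
    return -math.log2(cdf_at_D)


def synonym_upper_bound(d: DistortionMatrix, D: float) -> float:
    """Per-matrix synonym-count bound (1/N) sum_x log2(N / N_D(x)).

    ``N_D(x)`` counts percepts whose confusion with ``x`` costs strictly
    less than D; the state itself is always included since d(x, x) = 0.
    Mapping each state uniformly onto its synonyms achieves expected
    distortion below D at exactly this rate, so it upper-bounds R(D).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    n = d.n_states
    counts = (d.costs < D).sum(axis=1)  # diagonal zero always counted
    return float(np.log2(n / counts).mean())


def uniform_alloc_bound(N: int, C: float, mean_off_diag: float) -> tuple[float, float]:
    """(rate, distortion) of the uniform off-diagonal allocation codebook.

    The codebook keeps probability 1 - C on the correct percept and spreads
    C evenly over the N - 1 wrong ones:
    rate = log2 N - H_b(C) - C log2(N - 1), distortion = C * <d>, where
    <d> is the mean off-diagonal distortion.  Sweeping C traces an upper
    bound on the whole curve.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"C must be in [0, 1], got {C}")
    rate = math.log2(N) - binary_entropy(C) - C * math.log2(N - 1)
    return max(rate, 0.0), C * mean_off_diag


def uniform_alloc_bound_at_distortion(N: int, D: float, mean_off_diag: float) -> float:
    """Tightest uniform-allocation rate bound at a given distortion D.

    The allocation achieving distortion D uses C = D / <d>; rate decreases
    in C up to the uniform codebook, so this is the minimum over feasible C.
    """
    if mean_off_diag <= 0:
        raise ValueError("mean_off_diag must be > 0")
    c = min(D / mean_off_diag, (N - 1) / N)
    return uniform_alloc_bound(N, c, mean_off_diag)[0]


def uniform_env_rd(N: int, D: float, d_min: float) -> float:
    """R(D) of the uniform environment where every confusion costs d_min.

    This environment is strictly easier than one whose off-diagonal costs
    all exceed d_min, so its Hamming-type rate-distortion function

        log2 N - H_b(D / d_min) - (D / d_min) log2(N - 1)

    (zero for D >= d_min (N-1)/N) lower-bounds R(D) in the high-fidelity
    regime.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0 for the uniform-environment bound")
    if D < 0:
        raise ValueError("D must be >= 0")
    frac = D / d_min
    if frac >= (N - 1) / N:
        return 0.0
    return max(math.log2(N) - binary_entropy(frac) - frac * math.log2(N - 1), 0.0)


def asymptotic_bounds(N: int, D: float, d_min: float, mean_off_diag: float) -> tuple[float, float]:
    """Large-N leading-order bracket on R(D) in the high-fidelity regime.

    lo = (1 - D/d_min) log2 N, hi = (1 - D/<d>) log2 N; both drop the O(1)
    corrections of the exact bounds.  Valid only for D < d_min <= <d>.
    """
    if not 0.0 <= D < d_min <= mean_off_diag:
        raise ValueError("asymptotic bounds require 0 <= D < d_min <= mean_off_diag")
    lgn = math.log2(N)
    return (1.0 - D / d_min) * lgn, (1.0 - D / mean_off_diag) * lgn


def required_gain(C: float, mean_off_diag: float, D: float, N: int) -> float:
    """Minimal gain for high-fidelity coding to beat not coding at all.

    A non-coding codebook has distortion ~ <d> at zero rate; a high-fidelity
    codebook has distortion D at rate C log2 N.  The latter wins when
    beta >= (C / (<d> - D)) log2 N, so the required gain grows linearly
    with environmental complexity.
    """
    if C <= 0:
        raise ValueError("C must be > 0")
    if D >= mean_off_diag:
        raise ValueError("requires D < mean_off_diag")
    return (C / (mean_off_diag - D)) * math.log2(N)


def gaussian_rd(sigma2: float, D: float) -> float:
    """R(D) of a Gaussian source under squared error: (1/2) log2(sigma^2/D).

    Zero for D >= sigma^2.  A continuum of states with smooth costs has no
    minimal confound, so there is no low-fidelity plateau: increasing the
    signal variance always increases the rate at fixed D.
    """
    if sigma2 <= 0 or D <= 0:
        raise ValueError("sigma2 and D must be > 0")
    if D >= sigma2:
        return 0.0
    return 0.5 * math.log2(sigma2 / D)


@dataclass(frozen=True)
class BoundSet:
    """All bound values for one (matrix, D) pair plus the regime label."""

    D: float
    quantile_ub: float
    synonym_ub: float
    uniform_alloc_ub: float
    uniform_env_lb: float
    asym_lo: float | None
    asym_hi: float | None
    required_beta: float | None
    regime: str  # "high-fidelity" or "low-fidelity"

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "quantile_ub": self.quantile_ub,
            "synonym_ub": self.synonym_ub,
            "uniform_alloc_ub": self.uniform_alloc_ub,
            "uniform_env_lb": self.uniform_env_lb,
            "asym_lo": self.asym_lo,
            "asym_hi": self.asym_hi,
            "required_beta": self.required_beta,
            "regime": self.regime,
        }


def bound_report(d: DistortionMatrix, D: float, cdf_at_D: float | None = None) -> BoundSet:
    """Evaluate every applicable bound for matrix ``d`` at distortion ``D``.

    ``cdf_at_D`` defaults to the matrix's empirical off-diagonal CDF; pass
    the ensemble CDF for the N-independent version of the quantile bound.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    n = d.n_states
    d_min, mean_od = d.d_min, d.mean_off_diag
    if cdf_at_D is None:
        cdf_at_D = float((d.off_diagonal < D).mean())
    high = D < d_min
    lb = uniform_env_rd(n, D, d_min) if d_min > 0 else 0.0
    asym = asymptotic_bounds(n, D, d_min, mean_od) if (high and d_min > 0) else (None, None)
    req = None
    if D < mean_od:
        c = min(D / mean_od, (n - 1) / n)
        req = required_gain(max(c, 1e-300), mean_od, D, n) if c > 0 else None
    return BoundSet(
        D=D,
        quantile_ub=quantile_upper_bound(cdf_at_D),
        synonym_ub=synonym_upper_bound(d, D),
        uniform_alloc_ub=uniform_alloc_bound_at_distortion(n, D, mean_od),
        uniform_env_lb=lb,
        asym_lo=asym[0],
        asym_hi=asym[1],
        required_beta=req,
        regime="high-fidelity" if high else "low-fidelity",
    )
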