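"""Random distortion-matrix ensembles.

An *environment* with ``N`` discrete states is summarized by an ``N x N``
distortion matrix ``d(x, xhat)``: the cost an organism pays for perceiving
state ``x`` as ``xhat``.  The diagonal is zero (a correct percept is free;
the distortion measure is *normal*) and the ``N(N-1)`` off-diagonal entries
are drawn i.i.d. from a shifted exponential or lognormal density, optionally
post-processed into a pairwise-correlated variant.  The shift sets the
*minimal confound* — the cheapest possible confusion — which separates the
low-fidelity regime (tolerated distortion above the minimal confound) from
the high-fidelity regime (below it).

This module generates, characterizes, and (de)serializes such matrices.
Matrices are stored row-major: rows index the true state ``x``, columns the
percept ``xhat``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "InvalidSpecError",
    "CalibrationError",
    "EnvironmentSpec",
    "DistortionMatrix",
    "SourceDistribution",
    "draw_matrix",
    "correlate_matrix",
    "calibrate_lognormal",
    "minimal_confound",
    "max_useful_distortion",
    "ensemble_cdf",
    "save_matrix",
    "load_matrix",
]

FAMILIES = ("exponential", "lognormal", "correlated_exponential")

#: scale parameters each family requires (all strictly positive)
_SCALE_KEYS = {
    "exponential": ("mean",),
    "lognormal": ("log_mean", "log_sd"),
    "correlated_exponential": ("mean",),
}
# log_mean is a location parameter and may legitimately be negative
_SIGN_FREE = {"log_mean"}


class InvalidSpecError(ValueError):
    """Raised for an ensemble specification that cannot generate a matrix."""


class CalibrationError(ValueError):
    """Raised when a requested quantile calibration is infeasible."""


@dataclass(frozen=True)
class EnvironmentSpec:
    """Complete recipe for one random environment draw.

    A spec plus its seed reproduces a bit-identical matrix; it is the unit
    of provenance recorded in run manifests.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    shift : float
        Additive offset of the off-diagonal density; the support is
        ``[shift, inf)``, so ``shift`` is the target minimal confound of
        the ensemble.
    scale_params : dict
        Family-specific scale parameters: ``{"mean": m}`` for the
        exponential families, ``{"log_mean": mu, "log_sd": sigma}`` for
        the lognormal.
    n_states : int
        Environment size ``N`` (>= 2).
    seed : int
        Seed for the pseudo-random draw.
    """

    family: str
    shift: float
    scale_params: dict[str, float]
    n_states: int
    seed: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidSpecError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.shift < 0:
            raise InvalidSpecError(f"shift must be >= 0, got {self.shift}")
        if self.n_states < 2:
            raise InvalidSpecError(f"n_states must be >= 2, got {self.n_states}")
        keys = _SCALE_KEYS[self.family]
        missing = set(keys) - set(self.scale_params)
        if missing:
            raise InvalidSpecError(f"family {self.family!r} needs scale_params {sorted(missing)}")
        for k in keys:
            v = self.scale_params[k]
            if not math.isfinite(v) or (k not in _SIGN_FREE and v <= 0):
                raise InvalidSpecError(f"scale parameter {k}={v} must be finite and positive")

    def to_dict(self) -> dict[str, Any]:
        return {
            "family": self.family,
            "shift": self.shift,
            "scale_params": dict(self.scale_params),
            "n_states": self.n_states,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "EnvironmentSpec":
        return cls(
            family=d["family"],
            shift=float(d["shift"]),
            scale_params={k: float(v) for k, v in d["scale_params"].items()},
            n_states=int(d["n_states"]),
            seed=int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EnvironmentSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


@dataclass
class DistortionMatrix:
    """An environment: nonnegative cost table with exactly zero diagonal.

    Attributes
    ----------
    costs : ndarray of shape (N, N)
        ``costs[x, xhat]`` is the penalty for perceiving ``x`` as ``xhat``.
    spec : EnvironmentSpec, optional
        Provenance of a random draw, if any.
    pairings : ndarray, optional
        For pairwise-correlated matrices, the partner index (into the
        row-major off-diagonal vector) each entry was averaged with.
    """

    costs: np.ndarray
    spec: EnvironmentSpec | None = None
    pairings: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.costs, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"costs must be square, got shape {c.shape}")
        if c.shape[0] < 2:
            raise ValueError("need at least 2 states")
        if not np.all(np.isfinite(c)):
            raise ValueError("costs must be finite")
        if np.any(c < 0):
            raise ValueError("costs must be nonnegative")
        if np.any(np.diagonal(c) != 0):
            raise ValueError("diagonal must be exactly zero (normal distortion)")
        self.costs = c

    @property
    def n_states(self) -> int:
        return self.costs.shape[0]

    @property
    def off_diagonal(self) -> np.ndarray:
        """Row-major vector of the N(N-1) off-diagonal entries."""
        return self.costs[_offdiag_mask(self.n_states)]

    @property
    def d_min(self) -> float:
        """Minimal confound: the cheapest possible confusion."""
        return float(self.off_diagonal.min())

    @property
    def mean_off_diag(self) -> float:
        """Mean off-diagonal distortion, the cost of a random wrong guess."""
        return float(self.off_diagonal.mean())

    @property
    def d_max_useful(self) -> float:
        """Distortion of the best rate-zero codebook under a uniform source.

        Beyond this distortion the optimal rate is exactly zero, so it is
        the right endpoint when tiling the distortion axis.
        """
        return max_useful_distortion(self)


@dataclass
class SourceDistribution:
    """Distribution p(x) over environmental states.

    The analysis takes the uniform source, whose entropy ``log2 N`` is the
    proxy for environmental complexity, but any normalized p(x) is accepted
    by the solver.
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1:
            raise ValueError("probabilities must be a vector")
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probabilities = p / p.sum()

    @classmethod
    def uniform(cls, n: int) -> "SourceDistribution":
        return cls(np.full(n, 1.0 / n))

    @property
    def n_states(self) -> int:
        return self.probabilities.size

    @property
    def entropy_bits(self) -> float:
        p = self.probabilities
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())


def draw_matrix(spec: EnvironmentSpec) -> DistortionMatrix:
    """Draw a random distortion matrix from the ensemble ``spec`` describes.

    Off-diagonal entries are i.i.d. ``shift + family(scale_params)``; the
    diagonal is exactly zero.  For the ``correlated_exponential`` family a
    shifted-exponential base matrix is drawn first and then each entry is
    averaged with one randomly chosen partner entry (pairwise correlation).

    Deterministic: the same spec (including seed) gives a bit-identical
    matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_states
    m = n * (n - 1)
    if spec.family == "lognormal":
        vals = spec.shift + rng.lognormal(
            mean=spec.scale_params["log_mean"], sigma=spec.scale_params["log_sd"], size=m
        )
    else:  # exponential or correlated_exponential base
        vals = spec.shift + rng.exponential(scale=spec.scale_params["mean"], size=m)

    pairings = None
    if spec.family == "correlated_exponential":
        vals, pairings = _pairwise_average(vals, rng)

    costs = np.zeros((n, n))
    costs[_offdiag_mask(n)] = vals
    return DistortionMatrix(costs, spec=spec, pairings=pairings)


def _pairwise_average(off_vals: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Replace each entry by its average with one uniformly chosen other entry.

    Partners are drawn with replacement, each excluding the entry itself;
    all averages use the original values (simultaneous replacement).
    """
    m = off_vals.size
    partner = rng.integers(0, m - 1, size=m)
    partner = partner + (partner >= np.arange(m))  # skip self
    return 0.5 * (off_vals + off_vals[partner]), partner


def correlate_matrix(d: DistortionMatrix, seed: int) -> DistortionMatrix:
    """Return the pairwise-correlated version of ``d``.

    Each off-diagonal entry becomes the average of itself and one other
    off-diagonal entry chosen uniformly at random (recorded in
    ``pairings``); the diagonal stays zero.  Averaging two values that are
    both >= the input's minimal confound cannot go below it, so the output
    support is preserved.
    """
    rng = np.random.default_rng(seed)
    n = d.n_states
    vals, partner = _pairwise_average(d.off_diagonal, rng)
    costs = np.zeros((n, n))
    costs[_offdiag_mask(n)] = vals
    return DistortionMatrix(costs, spec=None, pairings=partner)


def calibrate_lognormal(
    target_prob: float,
    target_distortion: float,
    log_sd: float = 1.0,
    *,
    n_states: int = 2,
    seed: int = 0,
    shift: float = 0.0,
) -> EnvironmentSpec:
    """Solve for the lognormal log-mean matching a tail-probability constraint.

    Returns a lognormal spec whose CDF at ``target_distortion`` equals
    ``target_prob``:  with ``z = Phi^{-1}(target_prob)``,
    ``log_mean = ln(target_distortion - shift) - log_sd * z``.  The quantile
    constraint pins one parameter only, so ``log_sd`` stays free.

    Used to build heavy-tailed ensembles whose probability of a
    near-harmless confusion, P(d < D), matches an exponential reference.
    """
    if not 0.0 < target_prob < 1.0:
        raise CalibrationError(f"target_prob must be in (0, 1), got {target_prob}")
    if target_distortion <= 0:
        raise CalibrationError(f"target_distortion must be > 0, got {target_distortion}")
    if log_sd <= 0:
        raise CalibrationError(f"log_sd must be > 0, got {log_sd}")
    if target_distortion <= shift:
        raise CalibrationError(
            f"target_distortion {target_distortion} is below the support shift {shift}"
        )
    z = stats.norm.ppf(target_prob)
    log_mean = math.log(target_distortion - shift) - log_sd * z
    return EnvironmentSpec(
        family="lognormal",
        shift=shift,
        scale_params={"log_mean": log_mean, "log_sd": log_sd},
        n_states=n_states,
        seed=seed,
    )


def minimal_confound(d: DistortionMatrix) -> float:
    """Minimum over all off-diagonal entries: the cheapest confusion.

    This single number divides the distortion axis into the high-fidelity
    regime (D below it: rate grows like log2 N) and the low-fidelity regime
    (D above it: rate asymptotes in N).
    """
    return d.d_min


def max_useful_distortion(d: DistortionMatrix, p: SourceDistribution | None = None) -> float:
    """Distortion of the best zero-rate codebook.

    A zero-rate codebook maps every state to the same output distribution;
    the best one concentrates on the percept ``xhat`` minimizing
    ``sum_x p(x) d(x, xhat)``.  Rate-distortion curves are tiled on
    ``[0, max_useful_distortion]`` since beyond it R(D) = 0.
    """
    if p is None:
        p = SourceDistribution.uniform(d.n_states)
    if p.n_states != d.n_states:
        raise ValueError("source and matrix size mismatch")
    col_costs = p.probabilities @ d.costs
    return float(col_costs.min())


def ensemble_cdf(spec: EnvironmentSpec, x: float) -> float:
    """P(d < x) for a single off-diagonal entry under the ensemble density.

    Closed forms exist for the exponential and lognormal families; the
    pairwise-correlated family has no elementary CDF and raises.
    """
    if x <= spec.shift:
        return 0.0
    y = x - spec.shift
    if spec.family == "exponential":
        return float(-math.expm1(-y / spec.scale_params["mean"]))
    if spec.family == "lognormal":
        mu, sd = spec.scale_params["log_mean"], spec.scale_params["log_sd"]
        return float(stats.norm.cdf((math.log(y) - mu) / sd))
    raise NotImplementedError(f"no closed-form CDF for family {spec.family!r}")


def save_matrix(d: DistortionMatrix, path: str | Path) -> None:
    """Write the matrix as headerless CSV; spec provenance goes to a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, d.costs, delimiter=",", fmt="%.17g")
    if d.spec is not None:
        d.spec.save(path.with_suffix(".json"))


def load_matrix(path: str | Path) -> DistortionMatrix:
    """Read a matrix CSV written by :func:`save_matrix` (sidecar spec if present)."""
    path = Path(path)
    costs = np.loadtxt(path, delimiter=",", ndmin=2)
    sidecar = path.with_suffix(".json")
    spec = EnvironmentSpec.load(sidecar) if sidecar.exists() else None
    return DistortionMatrix(costs, spec=spec)
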