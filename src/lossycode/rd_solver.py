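"""Blahut-Arimoto solver for discrete rate-distortion curves.

Given a source p(x) and a distortion matrix d(x, xhat), the rate-distortion
function R(D) is the minimal mutual information I(X; Xhat) over codebooks
p(xhat|x) with expected distortion <= D.  It is computed here by the
classical alternating fixed-point iteration: at gain (inverse temperature)
beta, minimize the Lagrangian

    L = I(X; Xhat) + beta * E[d] / ln 2     (bits)

by repeating

    p(xhat|x)  <-  r(xhat) exp(-beta d(x, xhat)) / Z(x)
    r(xhat)    <-  sum_x p(x) p(xhat|x)

until the Lagrangian stabilizes.  Both half-steps are exact coordinate
minimizations of a jointly convex objective, so L never increases.  Sweeping
beta from 0 to large traces the full curve; beta is the Lagrange multiplier,
i.e. minus the slope of R(D) in nats per distortion unit.

Rates are reported in bits throughout; the exponential weight uses the
natural base, so beta is in nats per distortion unit.

Because exp(-beta * d) has its row maximum 1 on the zero diagonal, the
update weights never overflow and each row always keeps at least its
diagonal weight — the iteration is stable for arbitrarily large beta.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .environments import DistortionMatrix, SourceDistribution, max_useful_distortion

__all__ = [
    "LN2",
    "SolverError",
    "NumericalError",
    "SolverConfig",
    "Codebook",
    "RDPoint",
    "RDCurve",
    "ba_step",
    "rate_of",
    "distortion_of",
    "lagrangian_of",
    "solve_rd_point",
    "beta_for_distortion",
    "sweep_curve",
    "save_curve",
    "load_curve",
]

LN2 = math.log(2.0)


class SolverError(RuntimeError):
    """Raised when a distortion target cannot be bracketed or refined."""


class NumericalError(FloatingPointError):
    """Raised when the iteration produces non-finite quantities."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for the fixed-point iteration and the beta search.

    max_iter
        Iteration cap per beta (default 1000).
    tol
        Convergence threshold on the Lagrangian change per iteration, in
        bits.  Set to 0 together with ``fixed_iterations`` to force a fixed
        iteration count.
    fixed_iterations
        If True, always run exactly ``max_iter`` iterations.
    beta_init, beta_cap
        Initial upper bracket for the beta search and the hard cap; the
        bracket doubles until the achieved distortion falls below target.
    d_tol_frac
        Bisection stops once the achieved distortion is within this
        fraction of the zero-rate distortion from the target.
    bracket_tol
        Absolute bracket-width floor for the bisection.
    """

    max_iter: int = 1000
    tol: float = 1e-10
    fixed_iterations: bool = False
    beta_init: float = 1.0
    beta_cap: float = 1e7
    d_tol_frac: float = 1e-4
    bracket_tol: float = 1e-8

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Codebook:
    """Stochastic sensory map p(xhat|x) with its output marginal r(xhat).

    ``conditional[x, xhat]`` is the probability that state ``x`` is
    perceived as ``xhat``; rows are normalized.  The marginal is the
    p-weighted column average of the conditional.
    """

    conditional: np.ndarray
    marginal: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.conditional, dtype=float)
        r = np.asarray(self.marginal, dtype=float)
        if c.ndim != 2 or r.ndim != 1 or c.shape[1] != r.size:
            raise ValueError("conditional/marginal shape mismatch")
        if np.any(c < 0) or not np.allclose(c.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("conditional rows must be distributions")
        self.conditional = c
        self.marginal = r

    @classmethod
    def uniform(cls, n: int) -> "Codebook":
        return cls(np.full((n, n), 1.0 / n), np.full(n, 1.0 / n))

    @classmethod
    def from_conditional(cls, conditional: np.ndarray, p: SourceDistribution) -> "Codebook":
        conditional = np.asarray(conditional, dtype=float)
        return cls(conditional, p.probabilities @ conditional)


@dataclass(frozen=True)
class RDPoint:
    """One converged point on the rate-distortion curve."""

    beta: float
    rate_bits: float
    distortion: float
    iterations: int
    lagrangian: float

    @property
    def n_eff(self) -> float:
        """Effective number of stored states, 2**rate."""
        return 2.0 ** self.rate_bits


@dataclass
class RDCurve:
    """A swept rate-distortion curve: points sorted by distortion.

    The true R(D) is non-increasing and convex in D; :meth:`validate`
    checks both on the swept points up to numerical tolerance.
    """

    points: list[RDPoint]
    env_ref: str | None = None

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda q: q.distortion)

    @property
    def distortions(self) -> np.ndarray:
        return np.array([q.distortion for q in self.points])

    @property
    def rates(self) -> np.ndarray:
        return np.array([q.rate_bits for q in self.points])

    def validate(self, mono_tol: float = 1e-6, convex_tol: float = 1e-6) -> None:
        r, d = self.rates, self.distortions
        if np.any(np.diff(r) > mono_tol):
            raise ValueError("rate must be non-increasing in distortion")
        # discrete convexity: chord slopes dR/dD non-decreasing
        dd = np.diff(d)
        keep = dd > 1e-12
        slopes = np.diff(r)[keep] / dd[keep]
        if slopes.size >= 2 and np.any(np.diff(slopes) < -convex_tol):
            raise ValueError("curve is not convex within tolerance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": [q.beta for q in self.points],
                "rate_bits": [q.rate_bits for q in self.points],
                "distortion": [q.distortion for q in self.points],
                "iterations": [q.iterations for q in self.points],
            }
        )


def matrix_hash(d: DistortionMatrix) -> str:
    """Content hash of a matrix, used to reference it from curve files."""
    return hashlib.sha256(np.ascontiguousarray(d.costs).tobytes()).hexdigest()[:16]


def _check_source(d: DistortionMatrix, p: SourceDistribution | None) -> SourceDistribution:
    if p is None:
        return SourceDistribution.uniform(d.n_states)
    if p.n_states != d.n_states:
        raise ValueError("source and matrix size mismatch")
    return p


def ba_step(
    d: DistortionMatrix, beta: float, cb: Codebook, p: SourceDistribution | None = None
) -> Codebook:
    """One full fixed-point update of the codebook at gain ``beta``.

    Reweights each row of the current output marginal by exp(-beta d),
    renormalizes, and recomputes the marginal.  The Lagrangian
    rate + beta * distortion / ln 2 cannot increase across this step.
    """
    p = _check_source(d, p)
    if beta < 0:
        raise ValueError("beta must be >= 0")
    weights = np.exp(-beta * d.costs)
    return _update(weights, cb.marginal, p)


def _update(weights: np.ndarray, marginal: np.ndarray, p: SourceDistribution) -> Codebook:
    num = marginal * weights
    z = num.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(z)) or np.any(z <= 0):
        raise NumericalError("degenerate row normalizer in fixed-point update")
    cond = num / z
    return Codebook(cond, p.probabilities @ cond)


def rate_of(cb: Codebook, p: SourceDistribution) -> float:
    """Mutual information I(X; Xhat) in bits: H[Xhat] - H[Xhat|X]."""
    joint = p.probabilities[:, None] * cb.conditional
    ii = special.xlogy(joint, cb.conditional).sum() - special.xlogy(joint, cb.marginal[None, :]).sum()
    return max(float(ii) / LN2, 0.0)


def distortion_of(cb: Codebook, d: DistortionMatrix, p: SourceDistribution) -> float:
    """Expected distortion sum_x sum_xhat p(x) p(xhat|x) d(x, xhat)."""
    return float(np.einsum("i,ij,ij->", p.probabilities, cb.conditional, d.costs))


def lagrangian_of(cb: Codebook, d: DistortionMatrix, beta: float, p: SourceDistribution) -> float:
    """Variational objective rate + beta * distortion / ln 2, in bits."""
    return rate_of(cb, p) + beta * distortion_of(cb, d, p) / LN2


def _iterate(
    d: DistortionMatrix, beta: float, p: SourceDistribution, config: SolverConfig
) -> tuple[Codebook, float, float, int, float]:
    """Run the fixed-point iteration from the uniform codebook.

    Returns (codebook, rate_bits, distortion, iterations, lagrangian).
    """
    weights = np.exp(-beta * d.costs)
    cb = Codebook.uniform(d.n_states)
    prev = math.inf
    rate = dist = lag = 0.0
    it = 0
    for it in range(1, config.max_iter + 1):
        cb = _update(weights, cb.marginal, p)
        rate = rate_of(cb, p)
        dist = distortion_of(cb, d, p)
        lag = rate + beta * dist / LN2
        if not config.fixed_iterations and abs(prev - lag) < config.tol:
            break
        prev = lag
    return cb, rate, dist, it, lag


def solve_rd_point(
    d: DistortionMatrix,
    beta: float,
    p: SourceDistribution | None = None,
    max_iter: int | None = None,
    tol: float | None = None,
    config: SolverConfig | None = None,
    return_codebook: bool = False,
):
    """Converge the codebook at a single gain ``beta`` and read off (R, D).

    Iterates from the uniform codebook until the Lagrangian change drops
    below ``tol`` or ``max_iter`` is hit.
    """
    p = _check_source(d, p)
    if beta < 0:
        raise ValueError("beta must be >= 0")
    cfg = config or SolverConfig()
    if max_iter is not None or tol is not None:
        cfg = SolverConfig(
            max_iter=max_iter if max_iter is not None else cfg.max_iter,
            tol=tol if tol is not None else cfg.tol,
            fixed_iterations=cfg.fixed_iterations,
            beta_init=cfg.beta_init,
            beta_cap=cfg.beta_cap,
            d_tol_frac=cfg.d_tol_frac,
            bracket_tol=cfg.bracket_tol,
        )
    if cfg.max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    cb, rate, dist, it, lag = _iterate(d, beta, p, cfg)
    point = RDPoint(beta=beta, rate_bits=rate, distortion=dist, iterations=it, lagrangian=lag)
    return (point, cb) if return_codebook else point


def _bisect_beta(
    d: DistortionMatrix,
    target: float,
    p: SourceDistribution,
    config: SolverConfig,
) -> tuple[RDPoint, RDPoint]:
    """Bisect on beta for a converged distortion near ``target``.

    Distortion is monotone non-increasing in beta.  Returns
    ``(best, upper)`` where ``best`` is the evaluated point closest to the
    target and ``upper`` is the smallest examined beta whose distortion is
    <= target (the empirical minimal gain required for that fidelity).
    """
    dmax = max_useful_distortion(d, p)
    d_tol = config.d_tol_frac * (dmax if dmax > 0 else 1.0)

    lo = 0.0
    pt_lo = solve_rd_point(d, 0.0, p, config=config)  # uniform fixed point
    if pt_lo.distortion <= target:
        return pt_lo, pt_lo

    hi = config.beta_init
    pt_hi = solve_rd_point(d, hi, p, config=config)
    while pt_hi.distortion > target:
        hi *= 2.0
        if hi > config.beta_cap:
            raise SolverError(
                f"target distortion {target:g} not bracketed below beta_cap="
                f"{config.beta_cap:g} (reached D={pt_hi.distortion:g})"
            )
        lo, pt_lo = hi / 2.0, pt_hi
        pt_hi = solve_rd_point(d, hi, p, config=config)

    best = min((pt_lo, pt_hi), key=lambda q: abs(q.distortion - target))
    while abs(best.distortion - target) > d_tol and hi - lo > config.bracket_tol:
        mid = 0.5 * (lo + hi)
        pt = solve_rd_point(d, mid, p, config=config)
        if abs(pt.distortion - target) < abs(best.distortion - target):
            best = pt
        if pt.distortion > target:
            lo = mid
        else:
            hi, pt_hi = mid, pt
    return best, pt_hi


def beta_for_distortion(
    d: DistortionMatrix,
    target: float,
    p: SourceDistribution | None = None,
    config: SolverConfig | None = None,
) -> RDPoint:
    """Locate the curve point whose achieved distortion matches ``target``."""
    p = _check_source(d, p)
    config = config or SolverConfig()
    best, _ = _bisect_beta(d, target, p, config)
    return best


def _zero_rate_point(d: DistortionMatrix, p: SourceDistribution) -> RDPoint:
    """Exact zero-gain endpoint: the best constant codebook, rate exactly 0."""
    return RDPoint(
        beta=0.0,
        rate_bits=0.0,
        distortion=max_useful_distortion(d, p),
        iterations=0,
        lagrangian=0.0,
    )


def sweep_curve(
    d: DistortionMatrix,
    n_points: int = 15,
    p: SourceDistribution | None = None,
    config: SolverConfig | None = None,
    d_targets: Sequence[float] | None = None,
) -> RDCurve:
    """Trace R(D) with distortion targets evenly tiling [0, d_max_useful].

    Each interior target is located by bisection on beta; the D = 0 end is
    the large-beta cap and the maximal-distortion end is the exact best
    constant codebook (rate 0).  Pass ``d_targets`` to override the even
    grid, e.g. to anchor the sweep at specific distortions.
    """
    p = _check_source(d, p)
    config = config or SolverConfig()
    dmax = max_useful_distortion(d, p)
    if dmax <= 0:
        # all useful distortion already zero (e.g. all-zero matrix)
        return RDCurve([RDPoint(0.0, 0.0, 0.0, 0, 0.0)], env_ref=matrix_hash(d))
    if d_targets is None:
        if n_points < 2:
            raise ValueError("n_points must be >= 2")
        d_targets = np.linspace(0.0, dmax, n_points)
    points: list[RDPoint] = []
    for t in d_targets:
        if t < 0 or t > dmax * (1 + 1e-12):
            raise SolverError(f"distortion target {t:g} outside [0, {dmax:g}]")
        if t >= dmax * (1 - 1e-12):
            points.append(_zero_rate_point(d, p))
        elif t <= 0.0:
            points.append(solve_rd_point(d, config.beta_cap, p, config=config))
        else:
            points.append(beta_for_distortion(d, t, p, config=config))
    return RDCurve(points, env_ref=matrix_hash(d))


def save_curve(
    curve: RDCurve, path: str | Path, config: SolverConfig | None = None
) -> None:
    """Write curve CSV (beta,rate_bits,distortion,iterations) plus JSON sidecar."""
    import json

    path = Path(path)
    curve.to_frame().to_csv(path, index=False)
    sidecar = {"env_ref": curve.env_ref, "solver_config": (config or SolverConfig()).to_dict()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def load_curve(path: str | Path) -> RDCurve:
    import json

    path = Path(path)
    df = pd.read_csv(path)
    pts = [
        RDPoint(
            beta=row.beta,
            rate_bits=row.rate_bits,
            distortion=row.distortion,
            iterations=int(row.iterations),
            lagrangian=row.rate_bits + row.beta * row.distortion / LN2,
        )
        for row in df.itertuples()
    ]
    env_ref = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        env_ref = json.loads(sidecar.read_text()).get("env_ref")
    return RDCurve(pts, env_ref=env_ref)
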