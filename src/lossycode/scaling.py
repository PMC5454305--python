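"""Ensemble experiments: how perceptual cost scales with complexity.

Draws many random environments at each size N, solves each for the rate at
fixed distortion targets, and summarizes the cells with bootstrap
confidence intervals and rate-versus-log2(N) slopes.  These experiments
exhibit the two regimes directly: below the minimal confound the mean rate
climbs linearly in log2 N (slope bracketed by the large-N bounds), above
it the rate saturates as N grows.  The minimal gain (beta) needed to reach
a distortion target is recorded alongside, showing the same dichotomy for
metabolic efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cli_io import derive_seed
from .environments import (
    DistortionMatrix,
    EnvironmentSpec,
    SourceDistribution,
    draw_matrix,
    max_useful_distortion,
)
from .rd_solver import RDCurve, SolverConfig, _bisect_beta, _check_source, matrix_hash

__all__ = [
    "ExtrapolationError",
    "InsufficientDataError",
    "EnsembleSummary",
    "rate_at_distortion",
    "bootstrap_ci",
    "run_ensemble",
    "regime_slope",
    "required_gain_empirical",
    "distortion_fraction",
]


class ExtrapolationError(ValueError):
    """Raised when a distortion lies outside the span of a swept curve."""


class InsufficientDataError(ValueError):
    """Raised when too few values or grid points are available."""


def rate_at_distortion(curve: RDCurve, D: float) -> float:
    """Read the rate at distortion ``D`` off a swept curve.

    Piecewise-linear interpolation between swept points; order-preserving,
    so knots are returned exactly.  Raises outside the swept span rather
    than extrapolating.
    """
    d, r = curve.distortions, curve.rates
    lo, hi = d[0], d[-1]
    pad = 1e-9 * max(hi - lo, 1.0)
    if D < lo - pad or D > hi + pad:
        raise ExtrapolationError(f"D={D:g} outside swept span [{lo:g}, {hi:g}]")
    return float(np.interp(np.clip(D, lo, hi), d, r))


def bootstrap_ci(
    values: Sequence[float], level: float = 0.68, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``values``."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("bootstrap needs at least 2 values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def distortion_fraction(
    d: DistortionMatrix, fraction: float, denominator: str = "off_diag"
) -> float:
    """Translate a fraction of the random-guessing cost into absolute units.

    ``denominator`` selects the mean off-diagonal entry (default) or the
    mean over all N^2 entries; the two coincide as N grows.
    """
    if denominator == "off_diag":
        base = d.mean_off_diag
    elif denominator == "all":
        base = float(d.costs.mean())
    else:
        raise ValueError("denominator must be 'off_diag' or 'all'")
    return fraction * base


@dataclass
class EnsembleSummary:
    """Aggregated ensemble results over a (N, D_target) grid.

    ``samples`` holds one row per (N, draw, D_target) with the solved rate
    and minimal gain; ``cells`` aggregates each grid cell with the mean and
    a percentile-bootstrap confidence interval.
    """

    family: str
    shift: float
    cells: pd.DataFrame
    samples: pd.DataFrame
    seed: int
    solver_config: SolverConfig = field(default_factory=SolverConfig)

    def to_csv(self, path: str | Path) -> None:
        cols = [
            "family",
            "shift",
            "N",
            "D_target",
            "mean_rate_bits",
            "ci_low",
            "ci_high",
            "n_samples",
        ]
        self.cells[cols].to_csv(path, index=False, float_format="%.12g")


def run_ensemble(
    spec_family: str,
    shift: float,
    N_list: Sequence[int],
    D_targets: Sequence[float],
    n_samples: int,
    seed: int,
    scale_params: dict[str, float] | None = None,
    config: SolverConfig | None = None,
    level: float = 0.68,
    n_boot: int = 1000,
) -> EnsembleSummary:
    """Monte-Carlo estimate of the expected rate over random environments.

    For each size N, draws ``n_samples`` matrices, solves for the rate and
    the minimal gain at each distortion target (bisection on beta), and
    aggregates per-cell means with bootstrap confidence intervals.  A draw
    whose zero-rate distortion falls below a target contributes rate 0 for
    that target and is flagged.  Fully deterministic under ``seed``: every
    matrix seed and bootstrap seed derives from it by task label.
    """
    if n_samples < 2:
        raise InsufficientDataError("n_samples must be >= 2")
    if any(t <= 0 for t in D_targets):
        raise ValueError("all D_targets must be > 0")
    scale_params = scale_params or {"mean": 1.0}
    config = config or SolverConfig()

    rows = []
    for n in N_list:
        for i in range(n_samples):
            spec = EnvironmentSpec(
                family=spec_family,
                shift=shift,
                scale_params=scale_params,
                n_states=int(n),
                seed=derive_seed(seed, "matrix", spec_family, shift, n, i),
            )
            mat = draw_matrix(spec)
            p = SourceDistribution.uniform(mat.n_states)
            dmax = max_useful_distortion(mat, p)
            h = matrix_hash(mat)
            for t in D_targets:
                if t >= dmax:
                    rows.append(
                        dict(N=n, sample=i, D_target=t, rate_bits=0.0, required_beta=0.0,
                             zero_rate=True, matrix_hash=h, matrix_seed=spec.seed)
                    )
                    continue
                best, upper = _bisect_beta(mat, t, p, config)
                rows.append(
                    dict(N=n, sample=i, D_target=t, rate_bits=best.rate_bits,
                         required_beta=upper.beta, zero_rate=False, matrix_hash=h,
                         matrix_seed=spec.seed)
                )
    samples = pd.DataFrame(rows)

    cell_rows = []
    for (n, t), grp in samples.groupby(["N", "D_target"], sort=True):
        boot_seed = derive_seed(seed, "boot", spec_family, shift, n, t)
        lo, hi = bootstrap_ci(grp["rate_bits"], level=level, n_boot=n_boot, seed=boot_seed)
        blo, bhi = bootstrap_ci(
            grp["required_beta"], level=level, n_boot=n_boot,
            seed=derive_seed(seed, "boot-beta", spec_family, shift, n, t),
        )
        cell_rows.append(
            dict(
                family=spec_family,
                shift=shift,
                N=int(n),
                D_target=float(t),
                mean_rate_bits=float(grp["rate_bits"].mean()),
                ci_low=lo,
                ci_high=hi,
                mean_required_beta=float(grp["required_beta"].mean()),
                beta_ci_low=blo,
                beta_ci_high=bhi,
                n_samples=int(len(grp)),
                n_zero_rate=int(grp["zero_rate"].sum()),
            )
        )
    cells = pd.DataFrame(cell_rows)
    return EnsembleSummary(
        family=spec_family, shift=shift, cells=cells, samples=samples, seed=seed,
        solver_config=config,
    )


def regime_slope(summary: EnsembleSummary, D_target: float) -> tuple[float, float]:
    """Least-squares slope of mean rate versus log2 N at one distortion target.

    In the high-fidelity regime the slope should land inside the large-N
    bracket [1 - D/d_min, 1 - D/<d>]; in the low-fidelity regime it decays
    toward zero as N grows.
    """
    sel = summary.cells[np.isclose(summary.cells["D_target"], D_target)]
    if len(sel) < 3:
        raise InsufficientDataError("slope fit needs at least 3 environment sizes")
    x = np.log2(sel["N"].to_numpy(dtype=float))
    y = sel["mean_rate_bits"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.stderr)


def required_gain_empirical(
    d: DistortionMatrix,
    D_target: float,
    p: SourceDistribution | None = None,
    config: SolverConfig | None = None,
) -> float:
    """Minimal gain beta whose converged distortion is <= ``D_target``.

    Located by bisection on the monotone map beta -> D_beta; this is the
    metabolic efficiency an organism needs to hold its average error at
    the target in this particular environment.
    """
    p = _check_source(d, p)
    dmax = max_useful_distortion(d, p)
    if not 0.0 < D_target < dmax:
        raise ValueError(f"D_target must lie in (0, {dmax:g})")
    _, upper = _bisect_beta(d, D_target, p, config or SolverConfig())
    return float(upper.beta)
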