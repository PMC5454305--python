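"""Tests for the Blahut-Arimoto solver against closed forms and brute force."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lossycode import (
    Codebook,
    DistortionMatrix,
    SourceDistribution,
    SolverConfig,
    ba_step,
    beta_for_distortion,
    distortion_of,
    lagrangian_of,
    rate_of,
    solve_rd_point,
    sweep_curve,
)
from lossycode.rd_solver import load_curve, matrix_hash, save_curve

from conftest import binary_entropy_bits, random_matrix


class TestBaStep:
    def test_zero_gain_uniform_is_fixed_point(self):
        m = random_matrix(4, seed=0)
        cb = Codebook.uniform(4)
        out = ba_step(m, 0.0, cb)
        assert np.allclose(out.conditional, cb.conditional)
        assert np.allclose(out.marginal, cb.marginal)

    def test_hamming_symmetry_preserves_marginal(self, hamming2, uniform2):
        cb = Codebook.uniform(2)
        for beta in (0.5, 2.0, 10.0):
            out = ba_step(hamming2, beta, cb, uniform2)
            assert np.allclose(out.marginal, [0.5, 0.5])

    def test_rejects_negative_gain(self, hamming2):
        with pytest.raises(ValueError):
            ba_step(hamming2, -1.0, Codebook.uniform(2))

    def test_rows_stay_normalized(self):
        m = random_matrix(6, seed=3)
        cb = Codebook.uniform(6)
        for _ in range(20):
            cb = ba_step(m, 3.0, cb)
            assert np.allclose(cb.conditional.sum(axis=1), 1.0, atol=1e-12)
            p = SourceDistribution.uniform(6)
            assert np.allclose(cb.marginal, p.probabilities @ cb.conditional, atol=1e-12)


class TestFixedPoints:
    def test_hamming_log3_closed_form(self, hamming2):
        # fixed point has p(correct) = 1/(1 + e^{-beta}) = 3/4 at beta = ln 3
        pt, cb = solve_rd_point(hamming2, math.log(3.0), return_codebook=True)
        assert cb.conditional[0, 0] == pytest.approx(0.75, abs=1e-8)
        assert pt.distortion == pytest.approx(0.25, abs=1e-8)
        assert pt.rate_bits == pytest.approx(1 - binary_entropy_bits(0.25), abs=1e-8)
        assert pt.n_eff == pytest.approx(2.0 ** pt.rate_bits)

    def test_zero_gain_distortion_is_grand_mean(self):
        m = random_matrix(8, seed=1)
        pt = solve_rd_point(m, 0.0)
        assert pt.rate_bits == pytest.approx(0.0, abs=1e-12)
        assert pt.distortion == pytest.approx(m.costs.mean(), abs=1e-12)

    def test_large_gain_reaches_perfect_code(self, hamming2):
        pt = solve_rd_point(hamming2, 30.0)
        assert pt.rate_bits == pytest.approx(1.0, abs=1e-9)
        assert pt.distortion < 1e-9

    def test_fixed_iteration_mode_matches_converged(self, hamming2):
        cfg = SolverConfig(max_iter=500, fixed_iterations=True)
        a = solve_rd_point(hamming2, math.log(3.0), config=cfg)
        b = solve_rd_point(hamming2, math.log(3.0))
        assert a.iterations == 500
        assert a.rate_bits == pytest.approx(b.rate_bits, abs=1e-9)


class TestInformationMeasures:
    def test_identity_codebook_rate_is_source_entropy(self):
        p = SourceDistribution.uniform(4)
        cb = Codebook.from_conditional(np.eye(4), p)
        assert rate_of(cb, p) == pytest.approx(2.0, abs=1e-12)

    def test_constant_rows_carry_no_information(self):
        p = SourceDistribution.uniform(3)
        cond = np.tile([0.2, 0.5, 0.3], (3, 1))
        cb = Codebook.from_conditional(cond, p)
        assert rate_of(cb, p) == pytest.approx(0.0, abs=1e-12)

    def test_binary_symmetric_channel_rate(self, uniform2):
        cond = np.array([[0.75, 0.25], [0.25, 0.75]])
        cb = Codebook.from_conditional(cond, uniform2)
        assert rate_of(cb, uniform2) == pytest.approx(1 - binary_entropy_bits(0.25), abs=1e-9)

    @pytest.mark.parametrize("cond,expected", [
        (np.eye(2), 0.0),
        (np.full((2, 2), 0.5), 0.5),
        (np.array([[0.75, 0.25], [0.25, 0.75]]), 0.25),
    ])
    def test_distortion_examples(self, hamming2, uniform2, cond, expected):
        cb = Codebook.from_conditional(cond, uniform2)
        assert distortion_of(cb, hamming2, uniform2) == pytest.approx(expected, abs=1e-12)


class TestSweep:
    def test_hamming_curve_matches_closed_form(self, hamming2):
        curve = sweep_curve(hamming2, n_points=11)
        for pt in curve.points:
            assert pt.rate_bits == pytest.approx(
                1 - binary_entropy_bits(min(pt.distortion, 0.5)), abs=1e-3
            )

    def test_endpoint_has_zero_rate(self):
        m = random_matrix(10, seed=5, shift=1.0)
        curve = sweep_curve(m, n_points=9)
        top = curve.points[-1]
        assert top.distortion == pytest.approx(m.d_max_useful, rel=1e-9)
        assert top.rate_bits <= 1e-6

    def test_rates_non_increasing_and_convex(self):
        m = random_matrix(12, seed=8)
        curve = sweep_curve(m, n_points=11)
        curve.validate()
        assert np.all(np.diff(curve.rates) <= 1e-9)

    def test_distortions_tile_target_grid(self):
        m = random_matrix(10, seed=2, shift=1.0)
        curve = sweep_curve(m, n_points=9)
        grid = np.linspace(0.0, m.d_max_useful, 9)
        # interior targets hit within the bisection tolerance
        assert np.allclose(curve.distortions[1:], grid[1:], atol=2e-4 * m.d_max_useful)

    def test_all_zero_matrix_collapses_to_origin(self):
        m = DistortionMatrix(np.zeros((3, 3)))
        curve = sweep_curve(m, n_points=5)
        assert len(curve.points) == 1
        assert curve.points[0].rate_bits == 0.0
        assert curve.points[0].distortion == 0.0

    def test_curve_csv_roundtrip(self, hamming2, tmp_path):
        curve = sweep_curve(hamming2, n_points=5)
        path = tmp_path / "curve.csv"
        save_curve(curve, path)
        back = load_curve(path)
        assert np.allclose(back.rates, curve.rates)
        assert np.allclose(back.distortions, curve.distortions)
        assert back.env_ref == matrix_hash(hamming2)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 6),
    beta=st.floats(0.0, 50.0, allow_nan=False),
    seed=st.integers(0, 10_000),
)
def test_lagrangian_never_increases(n, beta, seed):
    """Each full fixed-point step descends the convex objective."""
    rng = np.random.default_rng(seed)
    costs = rng.exponential(1.0, size=(n, n))
    np.fill_diagonal(costs, 0.0)
    m = DistortionMatrix(costs)
    p = SourceDistribution.uniform(n)
    cb = Codebook.uniform(n)
    prev = lagrangian_of(cb, m, beta, p)
    for _ in range(30):
        cb = ba_step(m, beta, cb, p)
        cur = lagrangian_of(cb, m, beta, p)
        assert cur <= prev + 1e-9
        prev = cur


@pytest.mark.parametrize("n,seed", [(2, 0), (3, 1), (3, 2)])
def test_solver_beats_random_codebook_search(n, seed):
    """No sampled row-stochastic codebook undercuts the solver's rate

    at the distortion the solver achieved (brute-force optimality check
    at tiny N).
    """
    m = random_matrix(n, seed=seed)
    p = SourceDistribution.uniform(n)
    pt = solve_rd_point(m, 2.0, p)
    rng = np.random.default_rng(seed + 100)
    best = math.inf
    for alpha in (0.2, 1.0, 5.0):
        conds = rng.dirichlet(np.full(n, alpha), size=(5000, n))
        for cond in conds:
            cb = Codebook.from_conditional(cond, p)
            if distortion_of(cb, m, p) <= pt.distortion + 1e-9:
                best = min(best, rate_of(cb, p))
    assert pt.rate_bits <= best + 1e-3


def test_beta_for_distortion_hits_target(hamming2):
    pt = beta_for_distortion(hamming2, 0.25)
    assert pt.distortion == pytest.approx(0.25, abs=1e-4 * 0.5)
    assert pt.rate_bits == pytest.approx(1 - binary_entropy_bits(0.25), abs=1e-3)
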