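"""Penalized negative-binomial fitting: closed forms, oracles and properties."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from contness import model_core as mc
from contness.counts_io import GeneCountMatrix
from contness.errors import EssentialGeneError, ValidationError


def _nb_pen_obj(y, X, beta, theta, lam):
    eta = X @ beta
    mu = np.exp(eta)
    ll = (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * np.log(theta)
        + y * eta
        - (y + theta) * np.log(theta + mu)
    ).sum()
    return ll - 0.5 * lam * (beta[1:] ** 2).sum()


@pytest.mark.parametrize("y", [[3, 5, 7, 9], [0, 0, 0, 10]])
def test_intercept_only_mle_is_log_mean(y):
    """The log-link intercept-only NB MLE equals log of the sample mean."""
    y = np.array(y, dtype=float)
    fit = mc.fit_unregularized_nb(y, np.ones((len(y), 1)))
    assert fit.converged
    assert fit.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-5)


def test_infinite_penalty_collapses_to_intercept():
    y = np.array([3, 5, 7, 9])
    X = np.column_stack([np.ones(4), [0.0, 0.0, 1.0, 1.0]])
    fit = mc.fit_penalized_nb(y, X, 1e9)
    assert abs(fit.beta[1]) < 1e-6
    assert fit.beta[0] == pytest.approx(np.log(6.0), abs=1e-4)


def test_unregularized_equals_zero_penalty():
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(12), rng.integers(0, 2, 12)]).astype(float)
    y = rng.poisson(8, 12).astype(float)
    a = mc.fit_unregularized_nb(y, X)
    b = mc.fit_penalized_nb(y, X, 0.0)
    np.testing.assert_array_equal(a.beta, b.beta)
    assert a.theta == b.theta


def test_mle_dominates_penalized_fit_in_likelihood(saturated_design_60):
    rng = np.random.default_rng(5)
    mu = np.exp(saturated_design_60 @ rng.normal(2.0, 0.5, 12))
    y = rng.negative_binomial(5, 5 / (5 + mu)).astype(float)
    free = mc.fit_unregularized_nb(y, saturated_design_60)
    pen = mc.fit_penalized_nb(y, saturated_design_60, 1.0)
    assert free.unpenalized_loglik(y) >= pen.unpenalized_loglik(y) - 1e-6


def test_two_coefficient_fit_beats_dense_grid():
    """Brute-force check: no grid point has a higher penalized objective."""
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
    y = rng.negative_binomial(5, 5 / (5 + np.exp(X @ np.array([1.5, 0.8])))).astype(float)
    lam = 2.0
    fit = mc.fit_penalized_nb(y, X, lam)
    b0 = np.linspace(fit.beta[0] - 1, fit.beta[0] + 1, 101)
    b1 = np.linspace(fit.beta[1] - 1, fit.beta[1] + 1, 101)
    grid_best = -np.inf
    arg = None
    for a in b0:
        for b in b1:
            v = _nb_pen_obj(y, X, np.array([a, b]), fit.theta, lam)
            if v > grid_best:
                grid_best, arg = v, (a, b)
    assert fit.loglik >= grid_best - 1e-8
    assert abs(arg[0] - fit.beta[0]) < 1e-3 and abs(arg[1] - fit.beta[1]) < 1e-3


def test_all_zero_counts_refused():
    with pytest.raises(EssentialGeneError):
        mc.fit_penalized_nb(np.zeros(6, dtype=int), np.ones((6, 1)), 1.0)


def test_penalized_norm_non_increasing_along_path():
    rng = np.random.default_rng(0)
    n = 20
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.integers(0, 2, n)]).astype(float)
    mu = np.exp(X @ np.array([2.0, 0.8, -0.5]))
    Y = rng.negative_binomial(5, 5 / (5 + mu), size=(10, n)).astype(float)
    path = mc.select_lambda_batch(Y, X)
    norms = np.stack([(f.beta[:, 1:] ** 2).sum(axis=1) for f in path.fits])
    # grid is decreasing, so the shrunken norm must be non-decreasing down the path
    assert (np.diff(norms, axis=0) >= -1e-8).all()


def test_select_lambda_shrinks_pure_noise_hard():
    """With no true effects, the BIC pick should sit in the heavy-shrinkage half."""
    rng = np.random.default_rng(11)
    n = 20
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.integers(0, 2, n)]).astype(float)
    Y = rng.negative_binomial(5, 5 / (5 + 10.0), size=(50, n)).astype(float)
    path = mc.select_lambda_batch(Y, X)
    frac = np.mean(path.grid[path.selected] >= np.median(path.grid))
    assert frac >= 0.8


def test_select_lambda_retains_strong_signal():
    rng = np.random.default_rng(11)
    n = 20
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n)]).astype(float)
    mu = np.exp(X @ np.array([np.log(20), np.log(10)]))
    y = rng.negative_binomial(10, 10 / (10 + mu)).astype(float)
    lam, fits = mc.select_lambda(y, X)
    best = fits[int(np.flatnonzero(np.array([f.lam for f in fits]) == lam)[0])]
    assert abs(best.beta[1]) > 1.0


def test_select_lambda_grid_of_length_one():
    y = np.array([3, 5, 7, 9])
    lam, fits = mc.select_lambda(y, np.ones((4, 1)), grid=np.array([2.5]))
    assert lam == 2.5 and len(fits) == 1


def test_zinb_without_zeros_matches_nb():
    rng = np.random.default_rng(2)
    y = rng.negative_binomial(20, 20 / 50.0, size=100).astype(float) + 1
    X = np.ones((100, 1))
    fz = mc.fit_zinb(y, X)
    fn = mc.fit_unregularized_nb(y, X)
    assert fz.zero_prob < 1e-3
    assert fz.beta[0] == pytest.approx(fn.beta[0], abs=1e-3)


def test_zinb_recovers_structural_zero_fraction():
    rng = np.random.default_rng(9)
    mu, th = 20.0, 5.0
    y = rng.negative_binomial(th, th / (th + mu), size=200).astype(float)
    y[rng.random(200) < 0.5] = 0.0
    fit = mc.fit_zinb(y, np.ones((200, 1)))
    assert fit.zero_prob == pytest.approx(0.5, abs=0.1)


def test_zinb_all_zero_is_degenerate():
    fit = mc.fit_zinb(np.zeros(10), np.ones((10, 1)))
    assert fit.zero_prob == pytest.approx(1.0, abs=1e-6)
    assert not fit.converged


def test_residual_variance_examples():
    y = np.array([3.0, 5.0, 7.0, 9.0])
    perfect = mc.NBFit(
        beta=np.zeros(1), theta=1.0, lam=0.0, converged=True, n_iter=1,
        loglik=0.0, fitted=y.copy(),
    )
    assert mc.residual_variance(perfect, y) == 0.0
    intercept = mc.fit_unregularized_nb(y, np.ones((4, 1)))
    assert mc.residual_variance(intercept, y) == pytest.approx(5.0, abs=1e-6)


def test_saturated_fit_never_worse_than_intercept(saturated_design_60):
    rng = np.random.default_rng(7)
    for _ in range(5):
        mu = np.exp(saturated_design_60 @ rng.normal(1.5, 0.4, 12))
        y = rng.negative_binomial(3, 3 / (3 + mu)).astype(float)
        if (y == 0).all():
            continue
        sat = mc.fit_unregularized_nb(y, saturated_design_60)
        icp = mc.fit_unregularized_nb(y, np.ones((60, 1)))
        assert mc.residual_variance(sat, y) <= mc.residual_variance(icp, y) + 1e-8


def test_fit_all_genes_flags_and_determinism(saturated_design_60, nested_design_samples):
    from contness.model_core import build_design

    samples = [
        s for s in nested_design_samples
    ]
    X = build_design(samples, control=("WT", "control"))
    rng = np.random.default_rng(4)
    Y = rng.negative_binomial(5, 5 / (5 + 20.0), size=(10, 24))
    Y[3] = 0  # all-zero gene
    counts = GeneCountMatrix(
        flavor="total",
        values=pd.DataFrame(
            Y, index=[f"g{i}" for i in range(10)], columns=[s.sample_id for s in samples]
        ),
    )
    t1 = mc.fit_all_genes(counts, X, lam=1.0)
    t2 = mc.fit_all_genes(counts, X, lam=1.0)
    assert t1.excluded == {"g3": "excluded: essential-candidate"}
    assert "g3" not in t1.beta.index and len(t1.beta) == 9
    pd.testing.assert_frame_equal(t1.beta, t2.beta)


def test_fit_all_genes_convergence_rate(saturated_design_60):
    rng = np.random.default_rng(2)
    mu = rng.choice([0.5, 2.0, 8.0, 32.0], size=(500, 1)) * np.ones((1, 60))
    Y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu)).astype(int)
    keep = ~(Y == 0).all(axis=1)
    sample_ids = [f"s{i}" for i in range(60)]
    counts = GeneCountMatrix(
        flavor="total",
        values=pd.DataFrame(Y[keep], index=[f"g{i}" for i in range(keep.sum())], columns=sample_ids),
    )
    X = mc.NestedModelMatrix(
        matrix=saturated_design_60,
        labels=[("intercept", "", "")] + [("nested", "g", f"e{j}") for j in range(1, 12)],
        sample_ids=sample_ids,
        control=("g", "e0"),
    )
    table = mc.fit_all_genes(counts, X, lam=1.0)
    assert table.converged.mean() >= 0.95


def test_fit_options_from_file(tmp_path):
    p = tmp_path / "solver.cfg"
    p.write_text("tol = 1e-5\nmax_iter = 50  # fewer outer loops\ntheta_bounds = 0.01,1000\n")
    opts = mc.FitOptions.from_file(p)
    assert opts.tol == 1e-5 and opts.max_iter == 50 and opts.theta_bounds == (0.01, 1000.0)
    (tmp_path / "bad.cfg").write_text("nope = 1\n")
    with pytest.raises(ValidationError):
        mc.FitOptions.from_file(tmp_path / "bad.cfg")
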