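"""Empirical null, local fdr, calling rules and the decision tree."""

import numpy as np
import pandas as pd
import pytest

from contness import discovery as dv
from contness.counts_io import GeneCountMatrix, SampleMeta
from contness.errors import DegenerateDistributionError, TooFewValuesError


def test_empirical_null_recovers_standard_normal():
    rng = np.random.default_rng(1)
    null = dv.empirical_null(rng.normal(0, 1, 4000))
    assert -0.1 < null.delta0 < 0.1
    assert 0.9 < null.sigma0 < 1.1
    assert null.pi0 > 0.95


def test_empirical_null_robust_to_contaminated_tail():
    rng = np.random.default_rng(1)
    betas = np.r_[rng.normal(0, 1, 3800), rng.normal(5, 1, 200)]
    null = dv.empirical_null(betas)
    assert 0.9 < null.sigma0 < 1.2
    assert null.pi0 < 1.0


def test_empirical_null_degenerate_and_too_few():
    with pytest.raises(DegenerateDistributionError):
        dv.empirical_null(np.ones(100))
    with pytest.raises(TooFewValuesError):
        dv.empirical_null(np.arange(10.0))


def test_local_fdr_caps_at_one_at_null_center():
    rng = np.random.default_rng(1)
    betas = rng.normal(0, 1, 4000)
    betas[0] = 0.0  # at the null mode
    null = dv.empirical_null(betas)
    lf = dv.local_fdr(betas, null)
    assert np.all((lf >= 0) & (lf <= 1))
    assert lf[0] > 0.9


def test_local_fdr_small_in_far_tail_of_mixture():
    rng = np.random.default_rng(1)
    betas = np.r_[rng.normal(0, 1, 3800), rng.normal(5, 1, 200), [10.0]]
    null = dv.empirical_null(betas)
    lf = dv.local_fdr(betas, null)
    assert lf[-1] < 0.01


def test_local_fdr_controls_type_one_error_under_pure_null():
    rng = np.random.default_rng(3)
    fracs = []
    for _ in range(10):
        betas = rng.normal(0, 1, 2000)
        null = dv.empirical_null(betas)
        lf = dv.local_fdr(betas, null)
        fracs.append(np.mean(lf <= 0.2))
    assert np.mean(fracs) <= 0.01


@pytest.mark.parametrize(
    "beta,lfdr,expected",
    [(-3.0, 0.01, "beneficial"), (3.0, 0.01, "detrimental"), (-3.0, 0.5, "none")],
)
def test_call_marginal_rule(beta, lfdr, expected):
    calls = dv.call_marginal(np.array([beta]), np.array([lfdr]), threshold=0.2)
    assert calls[0] == expected


def test_call_threshold_monotonicity():
    rng = np.random.default_rng(5)
    betas = rng.normal(0, 1, 500)
    lf = rng.uniform(0, 1, 500)
    loose = (dv.call_marginal(betas, lf, 0.3) != "none").sum()
    tight = (dv.call_marginal(betas, lf, 0.1) != "none").sum()
    assert tight <= loose


@pytest.mark.parametrize(
    "total,unique,expected",
    [
        ("beneficial", "beneficial", "beneficial"),
        ("beneficial", "none", "none"),
        ("beneficial", "detrimental", "none"),
        ("detrimental", "detrimental", "detrimental"),
    ],
)
def test_intersect_requires_agreement(total, unique, expected):
    out = dv.intersect_calls(np.array([total]), np.array([unique]))
    assert out[0] == expected


def test_intersection_is_subset_of_marginals():
    rng = np.random.default_rng(8)
    opts = np.array(["beneficial", "detrimental", "none"], dtype=object)
    t = rng.choice(opts, 300)
    u = rng.choice(opts, 300)
    inter = dv.intersect_calls(t, u)
    called = inter != "none"
    assert (t[called] != "none").all() and (u[called] != "none").all()
    assert called.sum() <= min((t != "none").sum(), (u != "none").sum())


# ---------------------------------------------------------------------------
# decision tree


def _matrices(control_counts, condition_counts):
    samples = [
        SampleMeta("c1", "WT", "ctrl", 1),
        SampleMeta("c2", "WT", "ctrl", 2),
        SampleMeta("e1", "WT", "stress", 1),
        SampleMeta("e2", "WT", "stress", 2),
    ]
    vals = pd.DataFrame(
        [list(control_counts) + list(condition_counts)],
        index=["g1"],
        columns=["c1", "c2", "e1", "e2"],
    )
    total = GeneCountMatrix("total", vals)
    unique = GeneCountMatrix("unique", (vals > 0).astype(np.int64))
    return total, unique, samples


@pytest.mark.parametrize(
    "ctrl,cond,direction,expected",
    [
        ((0, 1), (5, 5), "none", "essential"),  # control mean 0.5 < 1
        ((2, 2), (0, 0), "none", "conditionally_essential"),
        ((5, 5), (9, 9), "none", "neutral"),
        ((5, 5), (1, 2), "beneficial", "beneficial"),
        ((5, 5), (30, 40), "detrimental", "detrimental"),
    ],
)
def test_classify_gene_decision_tree(ctrl, cond, direction, expected):
    total, unique, samples = _matrices(ctrl, cond)
    category = dv.classify_gene(
        "g1", total, unique, ("WT", "stress"), ("WT", "ctrl"), direction, samples
    )
    assert category == expected


def test_classify_genes_partition_is_exhaustive():
    rng = np.random.default_rng(0)
    samples = [
        SampleMeta(f"{arm}{r}", "WT", arm, r)
        for arm in ("ctrl", "stress")
        for r in (1, 2, 3)
    ]
    vals = pd.DataFrame(
        rng.integers(0, 6, size=(40, 6)),
        index=[f"g{i}" for i in range(40)],
        columns=[s.sample_id for s in samples],
    )
    total = GeneCountMatrix("total", vals)
    unique = GeneCountMatrix("unique", (vals > 0).astype(np.int64))
    directions = pd.Series("none", index=vals.index)
    out = dv.classify_genes(
        total, unique, samples, ("WT", "stress"), ("WT", "ctrl"), directions
    )
    assert out["category"].isin(dv.CATEGORIES).all()
    assert out["category"].notna().all()


def test_condition_means_unknown_condition_errors():
    total, _unique, samples = _matrices((1, 1), (1, 1))
    with pytest.raises(Exception, match="absent"):
        dv.condition_means(total, samples, ("WT", "missing"))
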