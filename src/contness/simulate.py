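"""Synthetic Tn-seq count generators and the model-comparison harnesses.

Two simulation frameworks are provided.

**Model-fit benchmark** — emulates a full nested screen: 3 genetic
backgrounds x 4 environments x 5 replicates (60 samples) over 4,000 genes in
8 blocks of 500.  Per background, Gamma hyper-parameters a_g, b_g ~ U(0, 5)
are drawn, then a dispersion theta_{gel} ~ Gamma(shape a_g, rate b_g) per
(background, environment, block).  Unique insertion counts are NB with
block-level means mu = (0.5, 1, 2, 4, 8, 16, 32, 64) and those dispersions;
the total count of a gene in a sample is the sum, over its unique insertion
sites, of independent NB(mean 100, dispersion 1) per-site read counts (so a
sample with zero unique insertions has zero total reads).  No gene has a
true background or environment effect: the data probe how each model family
handles block-structured overdispersion, not signal recovery.

**Power study** — 20 sets of 4,000 genes in a two-arm (control vs condition)
design.  Total counts: null law NB(mean 1000, dispersion 100) in both arms;
in each set, 100 affected genes use a condition-arm mean from
(1, 50, 100, ..., 950).  Unique counts are generated independently with null
mean 20 and affected condition means (1, 2, ..., 20).  Sets thus range from
trivially separable to nearly indistinguishable from the control mean,
mapping out sensitivity/specificity/accuracy per model and count flavor.

Gamma(a, b) is read as shape a, rate b (mean a/b).  Randomness derives from
one master seed with an independent spawned stream per set, so each set is
reproducible regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts_io import (
    GeneCountMatrix,
    GeneTable,
    SampleMeta,
    SiteCountTable,
    write_poolcount,
    write_sample_table,
)
from . import model_core as mc
from . import discovery as dv
from .errors import ValidationError

__all__ = [
    "FitSimParams",
    "PowerSimParams",
    "SimTruth",
    "SimulatedDataset",
    "simulate_fit_benchmark",
    "simulate_power_sets",
    "evaluate_fit_benchmark",
    "evaluate_power",
    "evaluate_power_all",
    "make_fixture_poolcount",
    "nb_draw",
]

POWER_MODELS = ("nb", "rnb", "zinb")
POWER_FLAVORS = ("total", "unique", "intersection")


def nb_draw(rng: np.random.Generator, mu, theta, size=None) -> np.ndarray:
    """NB variates under the mean/dispersion parameterization Var = mu + mu^2/theta."""
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p, size=size)


@dataclass
class FitSimParams:
    """Parameters of the nested-design model-fit benchmark."""

    n_backgrounds: int = 3
    n_conditions: int = 4
    n_replicates: int = 5
    n_blocks: int = 8
    genes_per_block: int = 500
    mu_levels: tuple = (0.5, 1, 2, 4, 8, 16, 32, 64)
    hyper_range: tuple = (0.0, 5.0)
    site_read_mean: float = 100.0
    site_read_dispersion: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.mu_levels) != self.n_blocks:
            raise ValidationError("mu_levels must have one entry per block")

    @property
    def n_genes(self) -> int:
        return self.n_blocks * self.genes_per_block

    @property
    def n_samples(self) -> int:
        return self.n_backgrounds * self.n_conditions * self.n_replicates


@dataclass
class PowerSimParams:
    """Parameters of the 20-set control-vs-condition power study."""

    n_sets: int = 20
    genes_per_set: int = 4000
    n_affected: int = 100
    n_replicates: int = 5
    total_null_mean: float = 1000.0
    total_dispersion: float = 100.0
    total_affected_means: tuple = (1,) + tuple(range(50, 951, 50))
    unique_null_mean: float = 20.0
    unique_dispersion: float = 100.0
    unique_affected_means: tuple = tuple(range(1, 21))
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.total_affected_means) != self.n_sets:
            raise ValidationError("total_affected_means must have n_sets entries")
        if len(self.unique_affected_means) != self.n_sets:
            raise ValidationError("unique_affected_means must have n_sets entries")
        if self.n_affected > self.genes_per_set:
            raise ValidationError("n_affected cannot exceed genes_per_set")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    affected: list[str] = field(default_factory=list)
    true_means: pd.DataFrame | None = None  # per gene, per flavor/arm
    dispersions: pd.DataFrame | None = None
    set_index: int | None = None


@dataclass
class SimulatedDataset:
    """A paired unique/total gene-count simulation with its sample design."""

    total: GeneCountMatrix
    unique: GeneCountMatrix
    samples: list[SampleMeta]
    truth: SimTruth
    control: tuple[str, str] = ("g1", "e1")

    def flavor(self, name: str) -> GeneCountMatrix:
        return {"total": self.total, "unique": self.unique}[name]


# ---------------------------------------------------------------------------
# framework 1: model-fit benchmark


def simulate_fit_benchmark(params: FitSimParams | None = None) -> SimulatedDataset:
    """Draw the nested-design benchmark dataset (see module docstring)."""
    params = params or FitSimParams()
    rng = np.random.default_rng(params.seed)
    G, E, R = params.n_backgrounds, params.n_conditions, params.n_replicates
    L, gpb = params.n_blocks, params.genes_per_block
    n_genes, n_samples = params.n_genes, params.n_samples

    samples = [
        SampleMeta(f"g{g+1}_e{e+1}_r{r+1}", f"g{g+1}", f"e{e+1}", r + 1)
        for g in range(G)
        for e in range(E)
        for r in range(R)
    ]
    cell_of_sample = np.array([g * E + e for g in range(G) for e in range(E) for _ in range(R)])

    lo, hi = params.hyper_range
    a = rng.uniform(lo, hi, size=G)
    b = rng.uniform(lo, hi, size=G)
    # shape a_g, rate b_g; exact zeros clamped
    theta = np.empty((G, E, L))
    for g in range(G):
        with np.errstate(divide="ignore"):
            theta[g] = rng.gamma(shape=max(a[g], 1e-12), scale=1.0 / max(b[g], 1e-12), size=(E, L))
    theta = np.maximum(theta, 1e-6)

    block_of_gene = np.repeat(np.arange(L), gpb)
    mu_gene = np.asarray(params.mu_levels, dtype=float)[block_of_gene]

    # per (gene, sample) dispersion: theta[g, e, block(gene)]
    ge_of_cell = [(c // E, c % E) for c in range(G * E)]
    theta_cell = np.stack(
        [theta[g, e, block_of_gene] for g, e in ge_of_cell], axis=1
    )  # (n_genes, n_cells)
    theta_gs = theta_cell[:, cell_of_sample]  # (n_genes, n_samples)
    mu_gs = np.broadcast_to(mu_gene[:, None], (n_genes, n_samples))

    uniq = nb_draw(rng, mu_gs, theta_gs)

    # totals: sum over u unique sites of iid NB(site_mean, site_theta) reads
    st, sm_ = params.site_read_dispersion, params.site_read_mean
    tot = np.zeros_like(uniq)
    pos = uniq > 0
    r_param = uniq[pos] * st
    p_param = st / (st + sm_)
    tot[pos] = rng.negative_binomial(r_param, p_param)

    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    sample_ids = [s.sample_id for s in samples]
    truth = SimTruth(
        affected=[],
        true_means=pd.DataFrame({"block": block_of_gene, "mu_unique": mu_gene}, index=gene_ids),
        dispersions=pd.DataFrame(
            theta_cell, index=gene_ids, columns=[f"g{g+1}_e{e+1}" for g, e in ge_of_cell]
        ),
    )
    return SimulatedDataset(
        total=GeneCountMatrix("total", pd.DataFrame(tot, index=gene_ids, columns=sample_ids)),
        unique=GeneCountMatrix("unique", pd.DataFrame(uniq, index=gene_ids, columns=sample_ids)),
        samples=samples,
        truth=truth,
        control=("g1", "e1"),
    )


# ---------------------------------------------------------------------------
# framework 2: power study


def simulate_power_sets(params: PowerSimParams | None = None) -> list[SimulatedDataset]:
    """Draw the 20 control-vs-condition power sets (see module docstring)."""
    params = params or PowerSimParams()
    streams = np.random.SeedSequence(params.seed).spawn(params.n_sets)
    out = []
    n_genes, R = params.genes_per_set, params.n_replicates
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    samples = [
        SampleMeta(f"{arm}_r{r+1}", "wt", arm, r + 1)
        for arm in ("control", "condition")
        for r in range(R)
    ]
    sample_ids = [s.sample_id for s in samples]

    for k in range(params.n_sets):
        rng = np.random.default_rng(streams[k])
        affected_idx = rng.choice(n_genes, size=params.n_affected, replace=False)
        affected_mask = np.zeros(n_genes, dtype=bool)
        affected_mask[affected_idx] = True

        def arm_counts(null_mean, disp, affected_mean):
            ctrl = nb_draw(rng, null_mean, disp, size=(n_genes, R))
            mu_cond = np.where(affected_mask, affected_mean, null_mean)[:, None]
            cond = nb_draw(rng, np.broadcast_to(mu_cond, (n_genes, R)), disp)
            return np.hstack([ctrl, cond])

        tot = arm_counts(
            params.total_null_mean,
            params.total_dispersion,
            params.total_affected_means[k],
        )
        uniq = arm_counts(
            params.unique_null_mean,
            params.unique_dispersion,
            params.unique_affected_means[k],
        )
        truth = SimTruth(
            affected=[gene_ids[i] for i in sorted(affected_idx)],
            true_means=pd.DataFrame(
                {
                    "total_condition_mean": np.where(
                        affected_mask, params.total_affected_means[k], params.total_null_mean
                    ),
                    "unique_condition_mean": np.where(
                        affected_mask, params.unique_affected_means[k], params.unique_null_mean
                    ),
                },
                index=gene_ids,
            ),
            set_index=k,
        )
        out.append(
            SimulatedDataset(
                total=GeneCountMatrix("total", pd.DataFrame(tot, index=gene_ids, columns=sample_ids)),
                unique=GeneCountMatrix("unique", pd.DataFrame(uniq, index=gene_ids, columns=sample_ids)),
                samples=samples,
                truth=truth,
                control=("wt", "control"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# evaluation harnesses


@dataclass
class FitBenchmarkResult:
    """Per-gene residual variances and the regularized-vs-unregularized summary."""

    table: pd.DataFrame  # mean_count, resvar_nb, resvar_rnb, resvar_zinb, rnb_converged
    fraction_regularized_better: float
    n_compared: int
    n_nonconverged: int
    n_allzero: int


def evaluate_fit_benchmark(
    data: SimulatedDataset,
    flavor: str = "total",
    opts: mc.FitOptions | None = None,
    models: tuple = ("nb", "rnb", "zinb"),
) -> FitBenchmarkResult:
    """Fit each model family to the benchmark and compare residual variances.

    Residual variance is the variance of raw (response-scale) residuals, so
    the three families share one axis.  All-zero genes cannot be fit and are
    set aside; genes whose regularized fit does not converge are excluded
    from the comparison denominator.  A tie is counted as not-better
    (the comparison is strict).
    """
    opts = opts or mc.FitOptions()
    counts = data.flavor(flavor)
    X = mc.build_design(data.samples, data.control)
    Y = counts.values.to_numpy(dtype=float)
    allzero = np.all(Y == 0, axis=1)
    keep = ~allzero
    Yk = Y[keep]
    kept_ids = [g for g, k in zip(counts.gene_ids, keep) if k]

    res: dict[str, np.ndarray] = {}
    conv: dict[str, np.ndarray] = {}
    for model in models:
        if model == "nb":
            fit = mc.fit_penalized_nb_batch(Yk, X.matrix, 0.0, opts)
        elif model == "rnb":
            fit = mc.select_lambda_batch(Yk, X.matrix, opts=opts).selected_fit()
        elif model == "zinb":
            fit = mc.fit_zinb_batch(Yk, X.matrix, opts)
        else:
            raise ValidationError(f"unknown model {model!r}")
        res[model] = np.var(Yk - fit.fitted, axis=1)
        conv[model] = fit.converged

    table = pd.DataFrame({"mean_count": Yk.mean(axis=1)}, index=kept_ids)
    for model in models:
        table[f"resvar_{model}"] = res[model]
        table[f"{model}_converged"] = conv[model]

    if "nb" in models and "rnb" in models:
        compared = conv["rnb"]
        better = (res["rnb"] < res["nb"]) & compared
        n_compared = int(compared.sum())
        frac = float(better.sum() / n_compared) if n_compared else float("nan")
        n_nonconv = int((~conv["rnb"]).sum())
    else:
        frac, n_compared, n_nonconv = float("nan"), 0, 0

    return FitBenchmarkResult(
        table=table,
        fraction_regularized_better=frac,
        n_compared=n_compared,
        n_nonconverged=n_nonconv,
        n_allzero=int(allzero.sum()),
    )


def _power_marginals(
    data: SimulatedDataset,
    model: str,
    threshold: float,
    opts: mc.FitOptions | None,
) -> dict[str, np.ndarray]:
    """Per-flavor marginal calls (plus intersection) for one power set."""
    opts = opts or mc.FitOptions()
    X = mc.build_design(data.samples, data.control)
    label = [n for n in X.column_names() if n.startswith("env:")][0]
    gene_ids = data.total.gene_ids
    calls: dict[str, np.ndarray] = {}
    for flavor in ("total", "unique"):
        counts = data.flavor(flavor)
        Y = counts.values.to_numpy(dtype=float)
        allzero = np.all(Y == 0, axis=1)
        Yk = Y[~allzero]
        if model == "nb":
            fit = mc.fit_penalized_nb_batch(Yk, X.matrix, 0.0, opts)
        elif model == "rnb":
            fit = mc.fit_batch_policy(Yk, X.matrix, "bic-global", opts)
        elif model == "zinb":
            fit = mc.fit_zinb_batch(Yk, X.matrix, opts)
        else:
            raise ValidationError(f"unknown model {model!r}")
        j = X.column_names().index(label)
        betas = fit.beta[:, j]
        usable = fit.converged & np.isfinite(betas)
        null = dv.empirical_null(betas[usable])
        lf = dv.local_fdr(betas[usable], null)
        sub = dv.call_marginal(betas[usable], lf, threshold, delta0=null.delta0)
        flavor_calls = np.full(len(gene_ids), "none", dtype=object)
        kept_idx = np.flatnonzero(~allzero)
        flavor_calls[kept_idx[usable]] = sub
        calls[flavor] = flavor_calls
    calls["intersection"] = dv.intersect_calls(calls["total"], calls["unique"])
    return calls


def _metrics(calls: np.ndarray, affected_mask: np.ndarray) -> tuple[float, float, float]:
    called = calls != "none"
    n_aff = int(affected_mask.sum())
    n_null = int((~affected_mask).sum())
    tp = int((called & affected_mask).sum())
    tn = int((~called & ~affected_mask).sum())
    sens = tp / n_aff if n_aff else float("nan")
    spec = tn / n_null if n_null else float("nan")
    acc = (tp + tn) / calls.size
    return sens, spec, acc


def evaluate_power_all(
    sets: list[SimulatedDataset],
    models: tuple = POWER_MODELS,
    threshold: float = 0.2,
    opts: mc.FitOptions | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity/accuracy for every model x flavor x set.

    Each model is fit once per set per count flavor; the three flavors
    ("total", "unique", "intersection") share those fits.
    """
    rows = []
    for data in sets:
        gene_ids = data.total.gene_ids
        affected_mask = np.isin(gene_ids, data.truth.affected)
        for model in models:
            calls = _power_marginals(data, model, threshold, opts)
            for flavor in POWER_FLAVORS:
                sens, spec, acc = _metrics(calls[flavor], affected_mask)
                rows.append(
                    {
                        "set": data.truth.set_index,
                        "model": model,
                        "flavor": flavor,
                        "sensitivity": sens,
                        "specificity": spec,
                        "accuracy": acc,
                    }
                )
    return pd.DataFrame(rows)


def evaluate_power(
    sets: list[SimulatedDataset],
    model: str = "rnb",
    flavor: str = "intersection",
    threshold: float = 0.2,
    opts: mc.FitOptions | None = None,
) -> pd.DataFrame:
    """Per-set (sensitivity, specificity, accuracy) for one model and flavor."""
    if model not in POWER_MODELS:
        raise ValidationError(f"unknown model {model!r}")
    if flavor not in POWER_FLAVORS:
        raise ValidationError(f"unknown flavor {flavor!r}")
    df = evaluate_power_all(sets, models=(model,), threshold=threshold, opts=opts)
    return df[df["flavor"] == flavor].reset_index(drop=True)


# ---------------------------------------------------------------------------
# deterministic I/O fixture


def make_fixture_poolcount(seed: int, outdir) -> tuple[Path, Path, Path]:
    """Write a small deterministic poolcount/gene/sample fixture.

    About 20 genes on two scaffolds (one overlapping pair, one gene with all
    counts zero), ~200 insertion sites, and a 2 background x 2 environment x
    2 replicate design.  The same seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    samples = [
        SampleMeta(f"{g}_{e}_r{r}", g, e, r)
        for g in ("WT", "mut")
        for e in ("ctrl", "stress")
        for r in (1, 2)
    ]
    sample_ids = [s.sample_id for s in samples]

    genes = []
    for i in range(10):
        start = 100 + i * 1000
        genes.append((f"cc{i+1:03d}", "chr1", start, start + 500, "+" if i % 2 == 0 else "-"))
    # overlapping pair on chr1
    genes.append(("cc011", "chr1", 1300, 2400, "+"))
    for i in range(9):
        start = 200 + i * 800
        genes.append((f"cc{i+12:03d}", "chr2", start, start + 400, "+"))
    gene_df = pd.DataFrame(genes, columns=["locus", "scaffold", "start", "end", "strand"])

    zero_gene = "cc005"  # all-zero everywhere
    n_sites = 200
    rows = []
    counts = np.zeros((n_sites, len(sample_ids)), dtype=np.int64)
    for j in range(n_sites):
        scaffold = "chr1" if j < 120 else "chr2"
        limit = 10200 if scaffold == "chr1" else 7000
        position = int(rng.integers(1, limit))
        barcode = "".join(rng.choice(list("ACGT"), size=12))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((barcode, scaffold, strand, position))
        mu = rng.uniform(0, 30)
        counts[j] = nb_draw(rng, mu, 2.0, size=len(sample_ids))
    sites = pd.DataFrame(rows, columns=["site_id", "scaffold", "strand", "position"])
    zrow = gene_df[gene_df["locus"] == zero_gene].iloc[0]
    in_zero = (sites["scaffold"] == zrow["scaffold"]) & sites["position"].between(
        zrow["start"], zrow["end"]
    )
    counts[in_zero.to_numpy()] = 0
    # make sure the zero gene has at least one site
    if not in_zero.any():
        sites.loc[0, ["scaffold", "position"]] = [zrow["scaffold"], int(zrow["start"]) + 10]
        counts[0] = 0

    table = SiteCountTable(
        sites=sites,
        counts=pd.DataFrame(counts, columns=sample_ids),
        samples=samples,
    )
    pool_path = outdir / "fixture.poolcount.tsv"
    gene_path = outdir / "fixture.genes.tsv"
    sample_path = outdir / "fixture.samples.tsv"
    write_poolcount(table, pool_path)
    gene_df.to_csv(gene_path, sep="\t", index=False)
    write_sample_table(samples, sample_path)
    return pool_path, gene_path, sample_path
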