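"""Empirical-null local false discovery rates and gene calling.

After per-gene model fitting, each non-intercept coefficient (one per
genetic background and one per background-nested environment) has an
empirical distribution across genes.  Under the assumption that most genes
are conditionally neutral, the center of that distribution reflects the
null scatter of estimates; a Gaussian N(delta0, sigma0^2) is fitted to the
central 50% by quantile matching (central matching), and the proportion of
null genes pi0 is estimated from the mass near the center.

The local false discovery rate of a coefficient value b is

    lfdr(b) = min(1, pi0 * f0(b) / f(b)),

where f0 is the empirical-null density and f is a smooth estimate of the
marginal coefficient density (Lindsey's method: Poisson regression of
histogram counts on a B-spline basis).  Genes with lfdr below threshold are
called conditionally beneficial (coefficient below the null center: gene
disruption depletes insertions, so the intact gene helps growth is *lost*,
i.e. disruption decreases growth) or conditionally detrimental (above the
center).  A final call requires agreement between the fits to total counts
and to unique counts; disagreement of any kind resolves to no call.

The count-based decision tree then assigns each gene one category per
condition: ``essential`` (mean control total count < 1),
``conditionally_essential`` (mean condition total count < 1), else the
intersected direction, else ``neutral``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import norm

from .counts_io import GeneCountMatrix, SampleMeta
from .errors import DegenerateDistributionError, TooFewValuesError, ValidationError

__all__ = [
    "NullEstimate",
    "GeneCallRecord",
    "empirical_null",
    "local_fdr",
    "tail_fdr",
    "call_marginal",
    "intersect_calls",
    "classify_gene",
    "classify_genes",
    "call_condition",
    "condition_means",
]

CATEGORIES = (
    "essential",
    "conditionally_essential",
    "beneficial",
    "detrimental",
    "neutral",
)


@dataclass(frozen=True)
class NullEstimate:
    """Empirical-null Gaussian: center, spread and null proportion."""

    delta0: float
    sigma0: float
    pi0: float

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise DegenerateDistributionError("sigma0 must be positive")
        if not 0 < self.pi0 <= 1:
            raise ValidationError("pi0 must lie in (0, 1]")


@dataclass
class GeneCallRecord:
    """Per-gene, per-condition call with the evidence behind it."""

    gene: str
    coefficient: str
    beta_total: float
    beta_unique: float
    lfdr_total: float
    lfdr_unique: float
    direction: str  # beneficial | detrimental | none
    category: str  # one of CATEGORIES


def empirical_null(betas: np.ndarray, min_values: int = 50) -> NullEstimate:
    """Fit a Gaussian to the center of a coefficient distribution.

    Central matching: delta0 is the median, sigma0 the interquartile range
    divided by the standard-normal IQR (so the central 50% of the data and
    of the fitted Gaussian coincide).  pi0 compares the observed mass within
    two fitted SDs of the center with the Gaussian's 95.45%, truncated to 1.
    """
    betas = np.asarray(betas, dtype=float)
    betas = betas[np.isfinite(betas)]
    if betas.size < min_values:
        raise TooFewValuesError(
            f"need at least {min_values} finite coefficients for empirical-null "
            f"estimation, got {betas.size}"
        )
    q25, q50, q75 = np.quantile(betas, [0.25, 0.5, 0.75])
    sigma0 = (q75 - q25) / (2.0 * norm.ppf(0.75))
    if sigma0 <= 0:
        raise DegenerateDistributionError(
            "coefficient distribution has no central spread"
        )
    central = np.mean(np.abs(betas - q50) <= 2.0 * sigma0)
    pi0 = min(1.0, float(central) / (norm.cdf(2.0) - norm.cdf(-2.0)))
    return NullEstimate(delta0=float(q50), sigma0=float(sigma0), pi0=pi0)


def _lindsey_density(
    betas: np.ndarray, n_bins: int = 120, df: int = 7
) -> tuple[np.ndarray, np.ndarray, float]:
    """Smooth marginal density via Poisson regression on binned counts.

    Returns (bin_centers, density_at_centers, bin_width).  The density is
    floored at half a count per bin so empty tail bins cannot explode the
    lfdr ratio.
    """
    import statsmodels.api as sm

    lo, hi = betas.min(), betas.max()
    span = hi - lo
    lo -= 1e-3 * span + 1e-12
    hi += 1e-3 * span + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(betas, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    # cubic B-spline basis with `df` functions (df-4 evenly spaced interior knots)
    degree = 3
    n_interior = max(df - degree - 1, 0)
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1] if n_interior else np.array([])
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    basis = BSpline.design_matrix(centers, knots, degree).toarray()

    fitted = None
    try:
        fit = sm.GLM(counts, basis, family=sm.families.Poisson()).fit(maxiter=200)
        fitted = np.asarray(fit.fittedvalues)
        if not np.all(np.isfinite(fitted)):
            fitted = None
    except (ValueError, np.linalg.LinAlgError):
        fitted = None
    if fitted is None:
        # fallback: Gaussian-kernel density on the same grid (heavy-tailed or
        # near-degenerate coefficient distributions can defeat the GLM)
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(betas)
        fitted = kde(centers) * betas.size * width
    floor = 0.5
    dens = np.maximum(fitted, floor) / (betas.size * width)
    return centers, dens, width


def local_fdr(
    betas: np.ndarray,
    null: NullEstimate,
    n_bins: int = 120,
    df: int = 7,
) -> np.ndarray:
    """Per-gene local false discovery rate, capped at 1."""
    betas = np.asarray(betas, dtype=float)
    finite = np.isfinite(betas)
    if not finite.any():
        raise ValidationError("no finite coefficients")
    vals = betas[finite]
    centers, dens, width = _lindsey_density(vals, n_bins=n_bins, df=df)
    f_hat = np.interp(vals, centers, dens)
    f0 = norm.pdf(vals, loc=null.delta0, scale=null.sigma0)
    lfdr_vals = np.minimum(1.0, null.pi0 * f0 / f_hat)
    out = np.full(betas.shape, np.nan)
    out[finite] = lfdr_vals
    return out


def tail_fdr(betas: np.ndarray, null: NullEstimate) -> np.ndarray:
    """Two-sided tail-area Fdr (reference statistic; calling uses the local fdr).

    Fdr(b) = pi0 * P0(|B - delta0| >= |b - delta0|) / Fhat(|B - delta0| >= ...),
    with the empirical tail fraction in the denominator.
    """
    betas = np.asarray(betas, dtype=float)
    finite = np.isfinite(betas)
    vals = betas[finite]
    dev = np.abs(vals - null.delta0)
    order = np.argsort(dev)
    # empirical P(|B - d0| >= dev_i), inclusive
    ranks = np.empty(vals.size)
    ranks[order] = np.arange(vals.size)
    emp_tail = (vals.size - ranks) / vals.size
    p0 = 2.0 * norm.sf(dev / null.sigma0)
    out = np.full(betas.shape, np.nan)
    out[finite] = np.minimum(1.0, null.pi0 * p0 / np.maximum(emp_tail, 1.0 / vals.size))
    return out


def call_marginal(
    betas: np.ndarray,
    lfdr: np.ndarray,
    threshold: float = 0.2,
    delta0: float = 0.0,
) -> np.ndarray:
    """Directional call per gene from one flavor's coefficients.

    lfdr <= threshold and beta below the null center means insertions are
    depleted: disrupting the gene decreases growth in that condition, so the
    gene is conditionally beneficial.  Above the center: conditionally
    detrimental.  Otherwise no call.
    """
    betas = np.asarray(betas, dtype=float)
    lfdr = np.asarray(lfdr, dtype=float)
    if betas.shape != lfdr.shape:
        raise ValidationError("betas and lfdr are not aligned")
    out = np.full(betas.shape, "none", dtype=object)
    sig = np.isfinite(lfdr) & (lfdr <= threshold)
    out[sig & (betas < delta0)] = "beneficial"
    out[sig & (betas > delta0)] = "detrimental"
    return out


def intersect_calls(total_calls: np.ndarray, unique_calls: np.ndarray) -> np.ndarray:
    """Final direction: the shared direction when both flavors agree, else none."""
    total_calls = np.asarray(total_calls, dtype=object)
    unique_calls = np.asarray(unique_calls, dtype=object)
    if total_calls.shape != unique_calls.shape:
        raise ValidationError("call vectors are not aligned")
    agree = (total_calls == unique_calls) & (total_calls != "none")
    return np.where(agree, total_calls, "none")


# ---------------------------------------------------------------------------
# count-based categorization


def condition_means(
    counts: GeneCountMatrix, samples: list[SampleMeta], pair: tuple[str, str]
) -> pd.Series:
    """Per-gene mean count over the replicates of one (background, environment)."""
    ids = [
        s.sample_id
        for s in samples
        if s.background == pair[0] and s.environment == pair[1]
    ]
    if not ids:
        raise ValidationError(f"condition {pair!r} absent from the design")
    return counts.values[ids].mean(axis=1)


def classify_gene(
    gene: str,
    counts_total: GeneCountMatrix,
    counts_unique: GeneCountMatrix,
    condition: tuple[str, str],
    control: tuple[str, str],
    final_direction: str,
    samples: list[SampleMeta],
) -> str:
    """Category of one gene in one condition (see module docstring)."""
    table = classify_genes(
        counts_total,
        counts_unique,
        samples,
        condition,
        control,
        pd.Series({gene: final_direction}),
    )
    return str(table.at[gene, "category"])


def classify_genes(
    counts_total: GeneCountMatrix,
    counts_unique: GeneCountMatrix,
    samples: list[SampleMeta],
    condition: tuple[str, str],
    control: tuple[str, str],
    final_directions: pd.Series,
) -> pd.DataFrame:
    """Apply the decision tree to every gene in ``final_directions``.

    The authoritative essential / conditionally-essential criteria use total
    counts (mean over replicates < 1); the unique-count variants are also
    reported so total/unique/overlap tallies can be produced.
    """
    mc_tot = condition_means(counts_total, samples, control)
    me_tot = condition_means(counts_total, samples, condition)
    mc_uni = condition_means(counts_unique, samples, control)
    me_uni = condition_means(counts_unique, samples, condition)

    genes = final_directions.index
    ess_tot = mc_tot.reindex(genes) < 1
    cond_tot = me_tot.reindex(genes) < 1
    ess_uni = mc_uni.reindex(genes) < 1
    cond_uni = me_uni.reindex(genes) < 1

    category = pd.Series("neutral", index=genes, dtype=object)
    has_dir = final_directions.isin(["beneficial", "detrimental"])
    category[has_dir] = final_directions[has_dir]
    category[~ess_tot & cond_tot] = "conditionally_essential"
    category[ess_tot] = "essential"

    return pd.DataFrame(
        {
            "category": category,
            "essential_total": ess_tot,
            "essential_unique": ess_uni,
            "cond_essential_total": ~ess_tot & cond_tot,
            "cond_essential_unique": ~ess_uni & cond_uni,
        }
    )


# ---------------------------------------------------------------------------
# high-level per-condition calling


def call_condition(
    fits_total,
    fits_unique,
    label: str,
    threshold: float = 0.2,
    min_values: int = 50,
) -> pd.DataFrame:
    """Marginal and intersected calls for one coefficient label.

    ``fits_total`` / ``fits_unique`` are :class:`~contness.model_core.GeneFitTable`
    objects.  The empirical null is fitted separately per flavor (and, by
    calling this once per label, separately per coefficient).  Genes that are
    excluded or non-converged in either flavor receive no call.
    """
    frames = {}
    for flavor, fits in (("total", fits_total), ("unique", fits_unique)):
        betas = fits.coefficients(label, converged_only=True)
        null = empirical_null(betas.to_numpy(), min_values=min_values)
        lf = local_fdr(betas.to_numpy(), null)
        calls = call_marginal(betas.to_numpy(), lf, threshold, delta0=null.delta0)
        fdr = tail_fdr(betas.to_numpy(), null)
        frames[flavor] = pd.DataFrame(
            {
                f"beta_{flavor}": betas,
                f"lfdr_{flavor}": lf,
                f"fdr_{flavor}": fdr,
                f"call_{flavor}": calls,
            },
            index=betas.index,
        )
    df = frames["total"].join(frames["unique"], how="outer")
    df[["call_total", "call_unique"]] = df[["call_total", "call_unique"]].fillna("none")
    df["direction"] = intersect_calls(
        df["call_total"].to_numpy(), df["call_unique"].to_numpy()
    )
    return df
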