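"""Per-sgRNA differential abundance statistics.

Counts are median-normalized across samples, low-coverage guides are
removed on raw control counts, a weighted least-squares line is fit to
log-variance vs log-mean over the control (AAV input) samples, and each
guide is tested for under-/over-abundance against a negative binomial
parameterized by its control mean and fitted variance. The log2 fold
change of a guide's treatment mean over its control mean (with a
pseudocount) is its knockdown phenotype phi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import digamma

from .library import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "DispersionFit",
    "SgrnaResult",
    "median_normalize",
    "filter_low_coverage",
    "fit_dispersion",
    "nb_params",
    "nb_test",
    "compute_phenotype",
    "bh_adjust",
    "analyze_sgrnas",
]

VARIANCE_CLAMP_EPS = 1e-6


@dataclass
class NormalizedMatrix:
    """Median-normalized counts plus the per-sample scale factors applied."""

    values: pd.DataFrame
    size_factors: pd.Series  # multiplicative: normalized = raw * size_factor
    target: float


def median_normalize(counts: CountMatrix | pd.DataFrame) -> NormalizedMatrix:
    """Scale each sample so its median count equals the grand median.

    Sample j is multiplied by ``target / median_j`` where ``median_j`` is
    that sample's median over retained sgRNAs and ``target`` is the median
    of the per-sample medians.
    """
    raw = counts.counts if isinstance(counts, CountMatrix) else counts
    medians = raw.median(axis=0)
    if (medians <= 0).any():
        zero = list(medians.index[medians <= 0])
        raise ValueError(
            f"samples with zero median count: {zero}; filter low-coverage "
            "sgRNAs or drop these samples before normalizing"
        )
    target = float(medians.median())
    factors = target / medians
    return NormalizedMatrix(values=raw * factors, size_factors=factors, target=target)


def filter_low_coverage(
    counts: CountMatrix, min_control_reads: int = 100
) -> tuple[CountMatrix, list[str]]:
    """Drop sgRNAs with < ``min_control_reads`` raw reads summed across
    control samples. Returns (filtered matrix, dropped sgrna_ids).
    """
    controls = counts.control_samples
    if not controls:
        raise ValueError("no control samples designated; cannot apply coverage filter")
    control_sum = counts.counts[controls].sum(axis=1)
    keep = control_sum >= min_control_reads
    dropped = list(counts.counts.index[~keep])
    return counts.subset_sgrnas(list(counts.counts.index[keep])), dropped


@dataclass
class DispersionFit:
    """log(variance) = intercept + slope * log(mean), fit on control samples.

    ``log_bias_correction`` is the Jensen correction added to each
    log-sample-variance before fitting (see :func:`fit_dispersion`).
    """

    intercept: float
    slope: float
    weight_scheme: str
    n_points: int = 0
    log_bias_correction: float = 0.0

    def variance(self, mu: np.ndarray) -> np.ndarray:
        return np.exp(self.intercept + self.slope * np.log(mu))


def fit_dispersion(
    controls: pd.DataFrame, weight_scheme: str = "uniform", bias_correct: bool = True
) -> DispersionFit:
    """WLS fit of log sample variance on log mean over control columns.

    ``weight_scheme="mean"`` weights each sgRNA by its control mean
    (variance estimates from abundant guides are more reliable);
    ``"uniform"`` weights equally. Guides with zero sample variance or
    non-positive mean are excluded from the fit.

    The log of a sample variance is biased low: with k replicates and
    nu = k - 1, E[log s^2] = log sigma^2 + psi(nu/2) - log(nu/2) (exact
    under normality, asymptotically for large counts). With few control
    replicates this shifts the intercept by ~-0.58 (k = 3) and makes the
    fitted variances anti-conservative. ``bias_correct=True`` (default)
    adds log(nu/2) - psi(nu/2) to each log-variance so the fitted line
    targets log sigma^2 itself.
    """
    if controls.shape[1] < 2:
        raise ValueError(
            "dispersion fit needs >= 2 control samples; with a single control "
            "use the near-Poisson fallback (single_control_kappa)"
        )
    mean = controls.mean(axis=1).to_numpy()
    var = controls.var(axis=1, ddof=1).to_numpy()
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 sgRNAs with positive mean and variance")
    nu = controls.shape[1] - 1
    correction = float(np.log(nu / 2) - digamma(nu / 2)) if bias_correct else 0.0
    x = np.log(mean[ok])
    y = np.log(var[ok]) + correction
    if weight_scheme == "mean":
        w = mean[ok]
    elif weight_scheme == "uniform":
        w = np.ones(ok.sum())
    else:
        raise ValueError(f"unknown weight scheme: {weight_scheme!r}")
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = model.params
    return DispersionFit(
        intercept=float(intercept),
        slope=float(slope),
        weight_scheme=weight_scheme,
        n_points=int(ok.sum()),
        log_bias_correction=correction,
    )


def nb_params(mu, sigma2):
    """Moment parameterization: r = mu^2/(sigma2-mu), p = mu/sigma2.

    Requires sigma2 > mu elementwise (overdispersed regime after clamping).
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= mu):
        raise ValueError("nb_params requires sigma2 > mu; clamp the variance first")
    r = mu**2 / (sigma2 - mu)
    p = mu / sigma2
    return r, p


def nb_test(mu, sigma2, obs):
    """Directional NB tail probabilities for observed counts.

    p_under = P(X <= obs) and p_over = P(X >= obs); both include the
    probability mass at ``obs`` so p_under + p_over = 1 + pmf(obs).
    """
    r, p = nb_params(mu, sigma2)
    obs = np.asarray(obs)
    p_under = sps.nbinom.cdf(obs, r, p)
    p_over = sps.nbinom.sf(obs - 1, r, p)
    return p_under, p_over


def compute_phenotype(mu_control, mu_treatment, pseudocount: float = 1.0):
    """Guide phenotype phi = log2((mu_treatment + a) / (mu_control + a))."""
    mu_control = np.asarray(mu_control, dtype=float)
    mu_treatment = np.asarray(mu_treatment, dtype=float)
    return np.log2((mu_treatment + pseudocount) / (mu_control + pseudocount))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDRs)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SgrnaResult:
    """Full per-sgRNA analysis output.

    ``table`` columns: sgrna_id (index), gene_group, mu_control, obs, phi,
    p_under, p_over, fdr_under, fdr_over.
    """

    table: pd.DataFrame
    fit: DispersionFit
    size_factors: pd.Series
    dropped: list[str]


def analyze_sgrnas(
    counts: CountMatrix,
    min_control_reads: int = 100,
    pseudocount: float = 1.0,
    weight_scheme: str = "uniform",
    single_control_kappa: float = 0.01,
) -> SgrnaResult:
    """Run the complete per-sgRNA pipeline on a count matrix.

    Stages, in order: low-coverage filter on RAW control counts; median
    normalization; dispersion fit on control columns (or the near-Poisson
    fallback ``sigma2 = mu * (1 + kappa)`` with a single control); NB
    under/over tests of the rounded mean normalized treatment count; BH
    correction per direction.
    """
    controls = counts.control_samples
    treatments = counts.treatment_samples
    if not treatments:
        raise ValueError("no treatment samples designated")

    filtered, dropped = filter_low_coverage(counts, min_control_reads)
    if filtered.counts.empty:
        raise ValueError("all sgRNAs removed by the control coverage filter")
    norm = median_normalize(filtered)

    mu = norm.values[controls].mean(axis=1).to_numpy()
    if np.any(mu <= 0):
        raise ValueError("sgRNAs with zero control mean survived filtering")

    if len(controls) >= 2:
        fit = fit_dispersion(norm.values[controls], weight_scheme=weight_scheme)
        sigma2 = fit.variance(mu)
    else:
        fit = DispersionFit(
            intercept=float(np.log1p(single_control_kappa)),
            slope=1.0,
            weight_scheme="single-control-fallback",
        )
        sigma2 = mu * (1.0 + single_control_kappa)

    clamp = mu * (1.0 + VARIANCE_CLAMP_EPS)
    n_clamped = int((sigma2 <= mu).sum())
    if n_clamped and fit.weight_scheme != "single-control-fallback":
        warnings.warn(
            f"fitted variance at or below the mean for {n_clamped} sgRNAs; "
            "clamped to mu*(1+eps) (near-Poisson regime)",
            stacklevel=2,
        )
    sigma2 = np.maximum(sigma2, clamp)

    mu_treat = norm.values[treatments].mean(axis=1).to_numpy()
    obs = np.rint(mu_treat).astype(np.int64)
    p_under, p_over = nb_test(mu, sigma2, obs)
    phi = compute_phenotype(mu, mu_treat, pseudocount)

    table = pd.DataFrame(
        {
            "gene_group": filtered.gene_group,
            "mu_control": mu,
            "obs": obs,
            "phi": phi,
            "p_under": p_under,
            "p_over": p_over,
            "fdr_under": bh_adjust(p_under),
            "fdr_over": bh_adjust(p_over),
        },
        index=filtered.counts.index,
    )
    return SgrnaResult(
        table=table, fit=fit, size_factors=norm.size_factors, dropped=dropped
    )
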