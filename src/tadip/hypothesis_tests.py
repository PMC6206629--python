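"""Model-choice tests: does each genome need its own mismatch probability?

The null hypothesis is a single shared mismatch probability
``H0: p_1 = ... = p_k = p_0`` (the TAMER model); the alternative is that at
least one genome differs (the TADIP model).  Three score-type tests are
provided:

* a **burden test** that collapses the weighted per-genome deviations
  ``p̂_i − p_0`` into one linear score, standardized by its plug-in null
  variance and referred to chi-square(1) — powerful when deviations share
  a direction;
* a **variance component test** (kernel score test) on the weighted sum of
  squared deviations, whose null distribution is a mixture of chi-square(1)
  variables evaluated by Davies-type numerical inversion; it retains power
  when deviations point in opposite directions and cancel in the burden
  score;
* a **Wald test** requiring an invertible covariance of ``p̂`` — included
  for completeness but typically impractical (the covariance is singular in
  sparse metagenomic data) and underpowered for sparse alternatives.

Per-genome weights are the Beta(a1, a2) density evaluated at ``p̂_i``
(defaults a1 = 96, a2 = 100).  The plug-in null variance of ``p̂_i`` is
``p_0 (1 − p_0) / E_i`` where ``E_i`` is the effective number of aligned
bases attributed to genome i (the posterior-weighted total alignment
length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .alignment_io import AlignmentTable
from .mixture_model import fit_em

__all__ = [
    "WeightConfig",
    "TestResult",
    "null_p0",
    "beta_weights",
    "design_matrix_V",
    "burden_test",
    "vct_test",
    "quadform_pvalue",
    "wald_test",
    "tadip_recommended",
]

_PCLIP = 1e-6


@dataclass(frozen=True)
class WeightConfig:
    """Shape parameters of the Beta density used as per-genome weights."""

    a1: float = 96.0
    a2: float = 100.0

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("Beta shapes must be positive")


@dataclass
class TestResult:
    """Outcome of one model-choice test."""

    statistic: float
    p_value: float
    method: str
    null_description: str
    reject_at: dict[float, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _reject(p: float, alphas: tuple[float, ...] = (0.05, 0.01)) -> dict[float, bool]:
    return {a: bool(p < a) for a in alphas}


def null_p0(data: AlignmentTable, **fit_kwargs) -> tuple[float, np.ndarray]:
    """Common-p EM estimate ``p_0`` and effective base counts ``E``.

    ``E_i = Σ_j T_ji L_j`` at the common-p fit: the posterior-weighted
    number of aligned bases attributed to genome i, i.e. the plug-in
    sample size behind each genome's estimated rate.
    """
    fit = fit_em(data, mode="common_p", **fit_kwargs)
    T = fit.posterior
    L = data.read_length[data.hit_read]
    E = np.bincount(data.hit_genome, weights=T * L, minlength=data.n_genomes)
    return float(fit.params.p[0]), E


def _log_beta_weights(p_hat: np.ndarray, cfg: WeightConfig) -> np.ndarray:
    p = np.clip(np.asarray(p_hat, dtype=float), _PCLIP, 1.0 - _PCLIP)
    return stats.beta.logpdf(p, cfg.a1, cfg.a2)


def beta_weights(p_hat: np.ndarray, cfg: WeightConfig = WeightConfig()) -> np.ndarray:
    """Beta(a1, a2) density evaluated at each estimated mismatch probability.

    Estimates at exactly 0 or 1 are clipped inward before evaluation.
    Note the density can be astronomically small far from the Beta mode;
    the tests below therefore work with weights on the log scale and
    normalize by the largest weight (their statistics are scale-invariant).
    """
    return np.exp(_log_beta_weights(p_hat, cfg))


def design_matrix_V(k: int) -> np.ndarray:
    """Exchangeable design matrix: 1 on the diagonal, 1/(k−1) off it.

    Encodes one shared deviation axis plus genome-specific contrasts in
    the logistic-regression view of the mismatch probabilities.
    """
    if k < 2:
        raise ValueError("the test is undefined for fewer than 2 genomes")
    V = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(V, 1.0)
    return V


def _collapse_weights(p_hat: np.ndarray, cfg: WeightConfig) -> np.ndarray:
    """Collapsing coefficients C_i = w_i × (column sum of V) = 2 w_i,
    with weights normalized by their maximum (scale cancels in both
    tests; the raw Beta density underflows for rates near 0)."""
    lw = _log_beta_weights(p_hat, cfg)
    w = np.exp(lw - lw.max())
    return 2.0 * w


def _check_test_inputs(p_hat, p_0, E):
    p_hat = np.asarray(p_hat, dtype=float)
    E = np.asarray(E, dtype=float)
    if p_hat.ndim != 1 or p_hat.shape != E.shape:
        raise ValueError("p_hat and E must be 1-D arrays of equal length")
    if len(p_hat) < 2:
        raise ValueError("need at least 2 genomes to test")
    if (E <= 0).any():
        bad = int(np.argmax(E <= 0))
        raise ValueError(f"genome index {bad} has zero effective base count")
    if not 0.0 < p_0 < 1.0:
        raise ValueError("p_0 must lie in (0, 1)")
    return p_hat, E


def burden_test(
    p_hat: np.ndarray,
    p_0: float,
    E: np.ndarray,
    cfg: WeightConfig = WeightConfig(),
) -> TestResult:
    """Weighted linear collapsing test of a shared mismatch probability.

    The score ``C^T (p̂ − p_0)`` with ``C_i = 2 w_i`` is squared and
    divided by its plug-in null variance ``Σ C_i² p_0(1−p_0)/E_i`` so the
    statistic is chi-square(1) under the null.  Blind to deviations of
    opposite sign that cancel in the sum.
    """
    p_hat, E = _check_test_inputs(p_hat, p_0, E)
    C = _collapse_weights(p_hat, cfg)
    score = float(C @ (p_hat - p_0))
    var = float(np.sum(C**2 * p_0 * (1.0 - p_0) / E))
    stat = score**2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(
        statistic=stat,
        p_value=p,
        method="burden",
        null_description="chi2(1) after plug-in variance standardization",
        reject_at=_reject(p),
    )


def quadform_pvalue(
    q: float,
    lambdas: np.ndarray,
    return_details: bool = False,
):
    """Upper tail probability ``Pr(Σ λ_i Z_i² > q)`` for standard normals Z.

    Equal eigenvalues reduce analytically to a scaled chi-square.  The
    general case uses Imhof's exact inversion integral (a Davies-type
    characteristic-function method); if the quadrature is unreliable the
    Liu-Tang-Zhang four-moment chi-square approximation is used instead
    and flagged in the returned detail string.
    """
    lam = np.asarray(lambdas, dtype=float)
    if (lam < 0).any():
        raise ValueError("eigenvalues must be non-negative")
    if not np.all(np.isfinite(lam)) or not np.isfinite(q):
        raise FloatingPointError("non-finite eigenvalues or statistic")
    lmax = lam.max(initial=0.0)
    if lmax <= 0.0:
        if q > 0:
            warnings.warn("all eigenvalues are zero with a positive statistic")
            return (0.0, "degenerate") if return_details else 0.0
        return (1.0, "degenerate") if return_details else 1.0
    lam = lam[lam > lmax * 1e-14]  # negligible components
    q = q / lmax
    lam = lam / lmax
    if np.allclose(lam, 1.0, rtol=1e-12, atol=0.0):
        p = float(stats.chi2.sf(q, df=len(lam)))
        detail = f"chi2({len(lam)}) scaled by {lmax:g}"
        return (p, detail) if return_details else p
    if q <= 0.0:
        return (1.0, "imhof") if return_details else 1.0

    def integrand(u: float) -> float:
        lu = lam * u
        theta = 0.5 * np.sum(np.arctan(lu)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p(lu**2)))
        return float(np.sin(theta) / (u * rho))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(integrand, 0.0, np.inf, limit=300)
    p = 0.5 + val / np.pi
    detail = "imhof"
    if not np.isfinite(p) or err > 1e-3 or p < -1e-3 or p > 1 + 1e-3:
        p = _liu_pvalue(q, lam)
        detail = "liu moment-matching fallback"
    p = float(min(max(p, 0.0), 1.0))
    return (p, detail) if return_details else p


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang chi-square moment matching for Σ λ_i χ²₁."""
    c1 = lam.sum()
    c2 = np.sum(lam**2)
    c3 = np.sum(lam**3)
    c4 = np.sum(lam**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    return float(stats.ncx2.sf(t_star * sigma_x + mu_x, df, delta))


def vct_test(
    p_hat: np.ndarray,
    p_0: float,
    E: np.ndarray,
    cfg: WeightConfig = WeightConfig(),
) -> TestResult:
    """Variance component (kernel) score test of a shared mismatch probability.

    The statistic is the weighted sum of squared deviations
    ``Q = Σ_i C_i² (p̂_i − p_0)²`` with ``C_i = 2 w_i`` — the collapsed
    (diagonal) form of the exchangeable-design kernel.  Under the null it
    is distributed as ``Σ λ_i χ²₁`` with ``λ_i = C_i² p_0(1−p_0)/E_i``
    (eigenvalues of ``P0^{1/2} K P0^{1/2}`` for the diagonal kernel and
    null covariance ``P0``); the tail probability comes from
    :func:`quadform_pvalue`.  Unlike the burden test this detects
    deviations of mixed sign.
    """
    p_hat, E = _check_test_inputs(p_hat, p_0, E)
    C = _collapse_weights(p_hat, cfg)
    d = p_hat - p_0
    stat = float(np.sum(C**2 * d**2))
    lam = C**2 * p_0 * (1.0 - p_0) / E
    if not np.all(np.isfinite(lam)):
        raise FloatingPointError("non-finite eigenvalues in variance component test")
    p, detail = quadform_pvalue(stat, lam, return_details=True)
    lam_sorted = np.sort(lam)[::-1]
    return TestResult(
        statistic=stat,
        p_value=float(p),
        method="vct",
        null_description=(
            "mixture of chi2(1); eigenvalues "
            + np.array2string(lam_sorted, precision=3, max_line_width=200)
            + f"; tail via {detail}"
        ),
        reject_at=_reject(float(p)),
    )


def wald_test(
    p_hat: np.ndarray,
    p_0: float,
    Sigma: np.ndarray,
) -> TestResult:
    """Wald test ``(p̂ − p_0)^T Σ⁻¹ (p̂ − p_0)`` against chi-square(k−1).

    Requires a caller-supplied invertible covariance (e.g. a diagonal
    plug-in); with many genomes the estimated covariance is typically
    singular, in which case the burden or variance component test should
    be used instead.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    k = len(p_hat)
    if Sigma.shape != (k, k):
        raise ValueError("Sigma must be k x k")
    d = p_hat - p_0
    try:
        stat = float(d @ np.linalg.solve(Sigma, d))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "Sigma is singular; use the burden or variance component test "
            "instead of the Wald test"
        ) from exc
    cond = np.linalg.cond(Sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "Sigma is numerically singular; use the burden or variance "
            "component test instead of the Wald test"
        )
    warnings.warn(
        "the Wald test often has poor power under sparse alternatives; "
        "prefer the burden or variance component test",
        stacklevel=2,
    )
    p = float(stats.chi2.sf(stat, df=k - 1))
    return TestResult(
        statistic=stat,
        p_value=p,
        method="wald",
        null_description=f"chi2({k - 1})",
        reject_at=_reject(p),
    )


def tadip_recommended(
    burden: TestResult, vct: TestResult, alpha: float = 0.05
) -> bool:
    """Recommend per-genome mismatch probabilities when either test rejects."""
    return bool(burden.p_value < alpha or vct.p_value < alpha)
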