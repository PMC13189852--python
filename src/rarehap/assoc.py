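"""Burden, SKAT, and SKAT-O score tests and a rejection-rate harness.

All three tests are intercept-only (no-covariate) score tests for a binary
phenotype, written in closed form.  With centered phenotype residuals
r_i = y_i - ybar, per-variant scores s_v = sum_i r_i g_iv, variant weights
w_v, and sigma^2 = ybar(1 - ybar):

* **Burden** collapses variants into one score b_i = sum_v w_v g_iv and
  refers U^2 / Var(U) to a 1-df chi-square, with U = sum_i r_i b_i and
  Var(U) = sigma^2 * sum_i (b_i - bbar)^2.
* **SKAT** uses the quadratic form Q = sum_v w_v^2 s_v^2, whose null law is a
  weighted sum of 1-df chi-squares with weights the eigenvalues of
  sigma^2 * W Gc' Gc W (Gc column-centered).  The tail probability is
  computed by three-moment matching (mean/variance/skewness) to a scaled
  noncentral chi-square (Liu-Tang-Zhang).
* **SKAT-O** evaluates Q_rho = (1-rho) * Q_SKAT + rho * (sum_v w_v s_v)^2 on
  a rho grid, takes the minimum per-rho moment-matched p-value as its
  statistic, and calibrates that minimum by permutation of the phenotype
  labels (add-one correction) — exactly valid at any grid size.

For a single variant, Burden and SKAT are the same test and the p-values
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, DegeneratePhenotypeError, DomainError, PairingError
from .io_formats import HaplotypeMatrix

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass
class GenotypeMatrix:
    """Diploid dosages (individuals x variants, entries 0/1/2)."""

    entries: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.entries)
        if a.ndim != 2:
            raise DomainError("genotype matrix must be two-dimensional")
        if a.size and not np.isin(a, (0, 1, 2)).all():
            raise DomainError("genotype entries must be 0, 1 or 2")
        self.entries = a.astype(np.int8, copy=False)

    @property
    def n_individuals(self) -> int:
        return self.entries.shape[0]

    @property
    def n_variants(self) -> int:
        return self.entries.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Alternate-allele frequency per variant (alt is the counted allele)."""
        return self.entries.sum(axis=0, dtype=np.int64) / (2 * self.n_individuals)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_variants_used: int
    flag: str | None = None


def haplotypes_to_genotypes(matrix: HaplotypeMatrix) -> GenotypeMatrix:
    """Pair consecutive haplotype columns (2i, 2i+1) into diploid individuals."""
    if matrix.M % 2 != 0:
        raise PairingError("haplotype matrix has an odd number of columns")
    data = matrix.data
    g = (data[:, 0::2].astype(np.int8) + data[:, 1::2]).T
    return GenotypeMatrix(g)


def variant_weights(maf, scheme: str = "flat") -> np.ndarray:
    """Per-variant test weights: 'flat' (1) or 'beta' (Beta(1,25) density at the MAF)."""
    maf = np.asarray(maf, dtype=float)
    if ((maf <= 0) | (maf >= 1)).any():
        raise DomainError("MAF must lie strictly inside (0, 1)")
    if scheme == "flat":
        return np.ones_like(maf)
    if scheme == "beta":
        return stats.beta.pdf(maf, 1, 25)
    raise DomainError(f"unknown weighting scheme {scheme!r}")


def _prepare(G: GenotypeMatrix, y, weights):
    y = np.asarray(y, dtype=float)
    if y.shape != (G.n_individuals,):
        raise PairingError("phenotype length does not match the genotype matrix")
    if not np.isin(y, (0, 1)).all():
        raise DomainError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise DegeneratePhenotypeError("phenotype is constant")
    if G.n_variants < 1:
        raise DomainError("need at least one variant")
    w = np.ones(G.n_variants) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (G.n_variants,):
        raise DomainError("weights length does not match the variant count")
    return G.entries.astype(float), y, w


def burden_test(G: GenotypeMatrix, y, weights=None) -> TestResult:
    """Weighted burden score test against a 1-df chi-square."""
    X, y, w = _prepare(G, y, weights)
    b = X @ w
    ybar = y.mean()
    r = y - ybar
    u = r @ b
    var = ybar * (1 - ybar) * np.sum((b - b.mean()) ** 2)
    if var <= 0:
        return TestResult(0.0, 1.0, "burden", G.n_variants, flag="zero-burden-variance")
    stat = u * u / var
    return TestResult(float(stat), float(stats.chi2.sf(stat, df=1)), "burden", G.n_variants)


def _liu_sf(q, lambdas):
    """Tail probability of sum(lambdas * chi2_1) at q by three-moment matching.

    Matches mean, variance and skewness of the mixture to a scaled
    (noncentral) chi-square; accepts scalar or vector q.
    """
    lam = np.asarray(lambdas, dtype=float)
    q = np.asarray(q, dtype=float)
    c1 = lam.sum()
    c2 = np.sum(lam**2)
    c3 = np.sum(lam**3)
    c4 = np.sum(lam**4)
    if c2 <= 0:
        return np.ones_like(q) if q.ndim else 1.0
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2 if s2 > 0 else 1.0
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = df + delta, np.sqrt(2 * (df + 2 * delta))
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        p = stats.ncx2.sf(x, df, delta)
    else:
        p = stats.chi2.sf(x, df)
    return p if q.ndim else float(p)


def _skat_eigen_parts(X: np.ndarray, y: np.ndarray):
    """Centered cross-product and phenotype variance shared by SKAT/SKAT-O."""
    ybar = y.mean()
    sigma2 = ybar * (1 - ybar)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc
    return C, sigma2, ybar


def _positive_eigvals(K: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh(K)
    if lam.size == 0:
        return lam
    return lam[lam > max(lam.max(), 0.0) * 1e-12]


def skat_test(G: GenotypeMatrix, y, weights=None) -> TestResult:
    """Variance-component (SKAT) score test with moment-matched p-value."""
    X, y, w = _prepare(G, y, weights)
    C, sigma2, ybar = _skat_eigen_parts(X, y)
    s = X.T @ (y - ybar)
    q = float(np.sum((w * s) ** 2))
    K = sigma2 * (w[:, None] * C * w[None, :])
    lam = _positive_eigvals(K)
    if lam.size == 0 or lam.sum() <= 0:
        return TestResult(q, 1.0, "skat", G.n_variants, flag="zero-variance-kernel")
    return TestResult(q, float(_liu_sf(q, lam)), "skat", G.n_variants)


def skato_test(
    G: GenotypeMatrix,
    y,
    weights=None,
    rho_grid=DEFAULT_RHO_GRID,
    n_perm: int = 500,
    seed=None,
) -> TestResult:
    """Optimal burden/SKAT combination with permutation-calibrated min-p.

    The statistic is the minimum over the rho grid of the moment-matched
    p-value of Q_rho; its null distribution is estimated by ``n_perm``
    phenotype permutations, so the reported p-value is exact up to Monte
    Carlo error regardless of the grid.
    """
    rho_grid = tuple(float(r) for r in rho_grid)
    if len(rho_grid) == 0 or any(not (0 <= r <= 1) for r in rho_grid):
        raise ConfigError("rho grid must be non-empty with values in [0, 1]")
    if n_perm < 100:
        raise ConfigError("n_perm must be at least 100")

    X, y, w = _prepare(G, y, weights)
    C, sigma2, ybar = _skat_eigen_parts(X, y)

    # Per-rho eigenvalues of the null mixture: nonzero spectrum of
    # sigma^2 * A_rho^(1/2) C A_rho^(1/2) with A_rho = (1-rho) W^2 + rho w w'.
    evals, evecs = np.linalg.eigh(C)
    evals = np.clip(evals, 0.0, None)
    C_half = (evecs * np.sqrt(evals)) @ evecs.T
    lams = []
    for rho in rho_grid:
        A = (1 - rho) * np.diag(w**2) + rho * np.outer(w, w)
        lams.append(_positive_eigvals(sigma2 * (C_half @ A @ C_half)))
    if all(l.size == 0 or l.sum() <= 0 for l in lams):
        return TestResult(1.0, 1.0, "skato", G.n_variants, flag="zero-variance-kernel")

    def min_p(S: np.ndarray) -> np.ndarray:
        """Minimum per-rho p for each column of the score matrix S (V x k)."""
        q_skat = (w**2) @ (S**2)
        q_burd = (w @ S) ** 2
        ps = []
        for rho, lam in zip(rho_grid, lams):
            if lam.size == 0 or lam.sum() <= 0:
                ps.append(np.ones_like(q_skat))
                continue
            ps.append(_liu_sf((1 - rho) * q_skat + rho * q_burd, lam))
        return np.min(np.vstack(ps), axis=0)

    s_obs = X.T @ (y - ybar)
    minp_obs = float(min_p(s_obs[:, None])[0])

    rng = np.random.default_rng(seed)
    Yp = np.tile(y, (n_perm, 1))
    Yp = rng.permuted(Yp, axis=1)
    S = X.T @ (Yp.T - ybar)
    minp_perm = min_p(S)
    p_final = (1.0 + np.sum(minp_perm <= minp_obs + 1e-12)) / (n_perm + 1.0)
    return TestResult(minp_obs, float(p_final), "skato", G.n_variants)


_METHODS = {"burden": burden_test, "skat": skat_test, "skato": skato_test}


def run_test(method, G: GenotypeMatrix, y, weights=None, **kwargs) -> TestResult:
    """Dispatch a test by name ('burden' | 'skat' | 'skato') or callable."""
    fn = _METHODS[method] if isinstance(method, str) else method
    return fn(G, y, weights, **kwargs)


def rejection_rate_harness(
    generator,
    method,
    alpha: float = 0.05,
    reps: int = 1000,
    seed=None,
) -> tuple[float, tuple[float, float]]:
    """Empirical rejection rate of ``method`` over ``reps`` generated datasets.

    ``generator(rng)`` may return a p-value, a TestResult, or a
    (GenotypeMatrix, y, weights) triple to be passed to ``method``.  Returns
    the rejection fraction and its exact (Clopper-Pearson) 95% binomial CI.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(reps):
        out = generator(rng)
        if isinstance(out, TestResult):
            p = out.p_value
        elif isinstance(out, (int, float, np.floating)):
            p = float(out)
        else:
            G, y, w = out
            p = run_test(method, G, y, w).p_value
        k += p <= alpha
    ci = stats.binomtest(k, reps).proportion_ci(confidence_level=0.95, method="exact")
    return k / reps, (float(ci.low), float(ci.high))
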