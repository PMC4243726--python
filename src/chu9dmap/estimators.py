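"""The four regression estimators used to fit mapping algorithms.

All four regress observed CHU9D utilities on KIDSCREEN-10 predictors and
report heteroskedasticity-robust standard errors:

* ``fit_ols`` — ordinary least squares with HC1 sandwich errors.
* ``fit_lad`` / ``fit_clad`` — least absolute deviations (median
  regression) solved exactly as a linear programme, and Powell's censored
  LAD for the ceiling of utilities at 1: iteratively refit LAD on the
  subsample whose fitted values lie below the censor point until the
  retained set stabilises.  Standard errors by seeded nonparametric
  bootstrap.
* ``fit_mm`` — the MM-estimator: a high-breakdown S-estimate of scale
  (Tukey bisquare at 50% breakdown, fast-S subset resampling) followed by
  an efficient bisquare M-step (IRWLS at fixed scale, tuning constant
  solved from the requested Gaussian efficiency; c = 4.685 at 95%).
* ``fit_fractional_logit`` — quasi-binomial IRLS with logit link applied
  to the utility directly (no rescaling of the 0.33 floor).  With an
  intercept the fitted mean equals the observed mean at convergence.

The utility distribution these target is left-skewed with a mass of
respondents at full health (1), which motivates the censored and robust
alternatives to OLS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, sparse, stats
from scipy.optimize import linprog

from .instruments import ITEM_LABELS, PairedDataset
from .mapping import MappingModelSpec

# ---------------------------------------------------------------------------
# Design matrices


class RankDeficiencyError(ValueError):
    """The design matrix is not full column rank."""


@dataclass
class Design:
    """A response vector with its design matrix (intercept column first)."""

    X: np.ndarray
    y: np.ndarray
    terms: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError("response length must match design rows")
        if len(self.terms) != p:
            raise ValueError("one term name per design column")
        if n < p:
            raise ValueError(f"need n >= p (got n={n}, p={p})")
        check_full_rank(self.X, self.terms)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def check_full_rank(X: np.ndarray, terms: Sequence[str],
                    tol: float = 1e-8) -> None:
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 0.0
    bad = [terms[j] for j in range(len(terms)) if diag[j] <= tol * max(scale, 1)]
    if bad:
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear terms: {bad}")


def build_design(data: PairedDataset, form: str,
                 items: Optional[Sequence[str]] = None,
                 include_age: bool = False,
                 include_gender: bool = False) -> Design:
    """Design for Model 1 (``index_quadratic``) or Model 2 (``item_linear``).

    Model 1 regresses utility on the KIDSCREEN-10 index and its square;
    Model 2 on the raw scores of the selected items (default: all 10).
    Age and gender enter as optional extra candidates.
    """
    if data.utility is None:
        raise ValueError("estimation needs observed CHU9D utilities")
    cols, terms = [np.ones(data.n)], ["const"]
    if form == "index_quadratic":
        if data.index is None:
            raise ValueError("index_quadratic design needs the KIDSCREEN-10 "
                             "index")
        cols += [data.index, data.index ** 2]
        terms += ["ks_index", "ks_index_sq"]
    elif form == "item_linear":
        for label in (items if items is not None else ITEM_LABELS):
            if label not in ITEM_LABELS:
                raise ValueError(f"unknown item {label!r}")
            cols.append(data.items[:, ITEM_LABELS.index(label)].astype(float))
            terms.append(label)
    else:
        raise ValueError(f"unknown form {form!r}")
    if include_age:
        if data.age is None:
            raise ValueError("dataset has no age column")
        cols.append(data.age)
        terms.append("age")
    if include_gender:
        if data.gender is None:
            raise ValueError("dataset has no gender column")
        cols.append(data.gender)
        terms.append("gender")
    return Design(np.column_stack(cols), data.utility, terms)


# ---------------------------------------------------------------------------
# Fit results


@dataclass
class FitResult:
    """Coefficients, robust inference and convergence metadata for one fit."""

    estimator_label: str
    terms: list[str]
    coefficients: dict[str, float]
    robust_se: dict[str, float]
    p_values: dict[str, float]
    fitted: np.ndarray
    converged: bool = True
    n_iter: int = 0
    objective: Optional[float] = None
    r_squared: Optional[float] = None
    se_method: str = ""
    scale: Optional[float] = None

    @property
    def coef_array(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.terms])

    def to_mapping_spec(self, value_set: str = "AU_adolescent_BWS",
                        truncate_upper_at_1: bool = True,
                        name: str = "") -> MappingModelSpec:
        """Package the fit as a mapping algorithm spec."""
        extra = set(self.terms) - ({"const", "ks_index", "ks_index_sq"}
                                   | set(ITEM_LABELS))
        if extra:
            raise ValueError(
                f"terms {sorted(extra)} have no place in a mapping spec; "
                "published algorithms exclude age/gender")
        link = "logit" if self.estimator_label == "GLM" else "identity"
        if "ks_index" in self.terms:
            return MappingModelSpec(
                form="index_quadratic", link=link,
                intercept=self.coefficients["const"],
                beta1=self.coefficients["ks_index"],
                beta2=self.coefficients.get("ks_index_sq"),
                estimator_label=self.estimator_label, value_set=value_set,
                truncate_upper_at_1=truncate_upper_at_1, name=name,
                source="fitted", robust_se=dict(self.robust_se))
        gammas = {t: c for t, c in self.coefficients.items() if t != "const"}
        return MappingModelSpec(
            form="item_linear", link=link,
            intercept=self.coefficients["const"], gammas=gammas,
            estimator_label=self.estimator_label, value_set=value_set,
            truncate_upper_at_1=truncate_upper_at_1, name=name,
            source="fitted", robust_se=dict(self.robust_se))

    def diagnostics_dict(self) -> dict:
        return {
            "estimator": self.estimator_label,
            "coefficients": self.coefficients,
            "robust_se": self.robust_se,
            "p_values": self.p_values,
            "se_method": self.se_method,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "objective": self.objective,
            "r_squared": self.r_squared,
            "scale": self.scale,
        }


def _wald(terms, coef, se):
    z = np.divide(coef, se, out=np.full_like(coef, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    return (dict(zip(terms, map(float, coef))),
            dict(zip(terms, map(float, se))),
            dict(zip(terms, map(float, p))))


# ---------------------------------------------------------------------------
# OLS with HC1 sandwich errors


def fit_ols(design: Design) -> FitResult:
    """Least squares with HC1 heteroskedasticity-robust standard errors."""
    X, y = design.X, design.y
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    XtX_inv = np.linalg.inv(X.T @ X)
    meat = (X * resid[:, None] ** 2).T @ X
    dof_factor = n / (n - p) if n > p else 1.0
    V = dof_factor * XtX_inv @ meat @ XtX_inv
    se = np.sqrt(np.diag(V))
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    coefs, ses, pvals = _wald(design.terms, beta, se)
    return FitResult("OLS", list(design.terms), coefs, ses, pvals, fitted,
                     converged=True, n_iter=0, objective=ssr,
                     r_squared=(1 - ssr / sst if sst > 0 else 1.0),
                     se_method="HC1")


# ---------------------------------------------------------------------------
# LAD (median regression) via linear programming


def _lad_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact LAD solution: min sum|y - Xb| as an LP with split residuals."""
    n, p = X.shape
    if p == 1 and np.allclose(X[:, 0], X[0, 0]) and X[0, 0] != 0:
        # intercept-only: LAD = median of y; lower median on even n
        return np.array([np.sort(y)[(n - 1) // 2] / X[0, 0]])
    c = np.concatenate([np.zeros(p), np.ones(2 * n)])
    A_eq = sparse.hstack([sparse.csr_matrix(X),
                          sparse.eye(n, format="csr"),
                          -sparse.eye(n, format="csr")], format="csr")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LAD linear programme failed: {res.message}")
    return res.x[:p]


def fit_lad(design: Design, n_boot: int = 200, seed: int = 0) -> FitResult:
    """Least absolute deviations fit (exact, via the HiGHS LP solver).

    Standard errors come from a seeded nonparametric (pairs) bootstrap;
    pass ``n_boot=0`` to skip inference.
    """
    X, y = design.X, design.y
    beta = _lad_coefficients(X, y)
    fitted = X @ beta
    objective = float(np.abs(y - fitted).sum())
    se = _pairs_bootstrap_se(lambda Xb, yb: _lad_coefficients(Xb, yb),
                             X, y, n_boot, seed)
    coefs, ses, pvals = _wald(design.terms, beta, se)
    return FitResult("LAD", list(design.terms), coefs, ses, pvals, fitted,
                     converged=True, n_iter=1, objective=objective,
                     se_method=f"pairs bootstrap (B={n_boot})")


def _pairs_bootstrap_se(solver: Callable, X, y, n_boot: int, seed: int):
    p = X.shape[1]
    if n_boot <= 0:
        return np.full(p, np.nan)
    rng = np.random.default_rng(seed)
    n = len(y)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            draws.append(solver(X[idx], y[idx]))
        except Exception:
            continue            # degenerate resample; recorded via count
    if len(draws) < max(10, n_boot // 2):
        return np.full(p, np.nan)
    return np.std(np.asarray(draws), axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Powell's censored LAD


def _clad_coefficients(X: np.ndarray, y: np.ndarray, upper_censor: float,
                       max_iter: int):
    """Iterative Powell estimator.  Returns (beta, n_iter, converged).

    Each round fits LAD on the currently retained subsample, then retains
    the observations whose fitted value lies at or below the censor point
    (boundary ties are retained; strictly-above is excluded).
    """
    n = len(y)
    active = np.ones(n, dtype=bool)
    beta = None
    for it in range(1, max_iter + 1):
        if active.sum() <= X.shape[1]:
            raise RuntimeError(
                "censored LAD: retained subsample too small to fit")
        beta = _lad_coefficients(X[active], y[active])
        new_active = (X @ beta) <= upper_censor
        if not new_active.any():
            raise RuntimeError("censored LAD: no observations retained")
        if np.array_equal(new_active, active):
            return beta, it, True
        active = new_active
    return beta, max_iter, False


def fit_clad(design: Design, upper_censor: float = 1.0, max_iter: int = 100,
             n_boot: int = 200, seed: int = 0) -> FitResult:
    """Censored least absolute deviations (Powell) for ceiling-censored
    utilities (observed y = min(latent y*, censor)).

    When no fitted value ever reaches the censor point the estimate
    coincides exactly with plain LAD.
    """
    X, y = design.X, design.y
    if not (y < upper_censor).any():
        raise ValueError("all responses at or above the censor point; "
                         "censored LAD is not identified")
    beta, n_iter, converged = _clad_coefficients(X, y, upper_censor, max_iter)
    fitted = X @ beta
    keep = fitted <= upper_censor
    objective = float(np.abs(y[keep] - fitted[keep]).sum())
    se = _pairs_bootstrap_se(
        lambda Xb, yb: _clad_coefficients(Xb, yb, upper_censor, max_iter)[0],
        X, y, n_boot, seed)
    coefs, ses, pvals = _wald(design.terms, beta, se)
    return FitResult("CLAD", list(design.terms), coefs, ses, pvals, fitted,
                     converged=converged, n_iter=n_iter, objective=objective,
                     se_method=f"pairs bootstrap (B={n_boot})")


# ---------------------------------------------------------------------------
# MM-estimator (bisquare S-estimate + efficient M-step)


def _rho_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    """Tukey bisquare rho standardised to max 1."""
    t2 = np.minimum((u / c) ** 2, 1.0)
    return 1.0 - (1.0 - t2) ** 3


def _psi_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    t2 = (u / c) ** 2
    return np.where(t2 <= 1.0, u * (1.0 - t2) ** 2, 0.0)


def _psi_prime_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    t2 = (u / c) ** 2
    return np.where(t2 <= 1.0, (1.0 - t2) * (1.0 - 5.0 * t2), 0.0)


def _bisquare_weights(u: np.ndarray, c: float) -> np.ndarray:
    t2 = (u / c) ** 2
    return np.where(t2 <= 1.0, (1.0 - t2) ** 2, 0.0)


#: 50%-breakdown bisquare tuning: E[rho(Z/c)] = 0.5 for Z ~ N(0,1)
S_TUNING_C = 1.5476449837337868
S_BREAKDOWN_B = 0.5


@lru_cache(maxsize=32)
def bisquare_tuning_constant(efficiency: float) -> float:
    """Solve the bisquare tuning constant for a Gaussian efficiency.

    Efficiency is (E[psi'])^2 / E[psi^2] relative to the normal; 0.95
    yields the conventional c = 4.685.
    """
    if not 0.0 < efficiency < 1.0:
        raise ValueError("efficiency must be in (0, 1)")

    def eff(c):
        num = stats.norm.expect(lambda z: _psi_prime_bisquare(z, c)) ** 2
        den = stats.norm.expect(lambda z: _psi_bisquare(z, c) ** 2)
        return num / den

    return float(optimize.brentq(lambda c: eff(c) - efficiency, 0.5, 40.0,
                                 xtol=1e-6))


def _m_scale(resid: np.ndarray, c: float = S_TUNING_C,
             b: float = S_BREAKDOWN_B, tol: float = 1e-10,
             max_iter: int = 100) -> float:
    """Solve mean(rho(r/s)) = b for s (the bisquare M-scale)."""
    r = np.asarray(resid, dtype=float)
    s = np.median(np.abs(r)) / 0.6745
    if s <= 0:
        s = np.abs(r).max() / c if np.abs(r).max() > 0 else 0.0
    if s == 0:
        return 0.0
    for _ in range(max_iter):
        m = _rho_bisquare(r / s, c).mean()
        s_new = s * math.sqrt(m / b)
        if abs(s_new - s) <= tol * max(s, 1e-30):
            return s_new
        s = s_new
    return s


def _wls(X, y, w):
    Xw = X * w[:, None]
    return np.linalg.solve(Xw.T @ X, Xw.T @ y)


def _s_refine(X, y, beta, c, n_steps, tol=1e-9):
    """IRWLS refinement steps for an S-candidate; returns (beta, scale)."""
    s = None
    for _ in range(n_steps):
        resid = y - X @ beta
        s = _m_scale(resid, c)
        if s == 0:
            return beta, 0.0
        w = _bisquare_weights(resid / s, c)
        if w.sum() <= X.shape[1]:
            return beta, s
        try:
            beta_new = _wls(X, y, w)
        except np.linalg.LinAlgError:
            return beta, s
        if np.max(np.abs(beta_new - beta)) <= tol * (1 + np.max(np.abs(beta))):
            return beta_new, _m_scale(y - X @ beta_new, c)
        beta = beta_new
    return beta, _m_scale(y - X @ beta, c)


def fit_mm(design: Design, efficiency: float = 0.95, n_subsets: int = 500,
           k_refine: int = 2, n_best: int = 5, max_iter: int = 200,
           tol: float = 1e-8, seed: int = 0) -> FitResult:
    """MM robust regression: 50%-breakdown bisquare S-estimate of scale
    (fast-S with seeded p-subset resampling) followed by an IRWLS M-step
    at the tuning constant matching the requested Gaussian efficiency.

    Robust sandwich standard errors use the estimated scale and the
    bisquare psi evaluated at the final residuals.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n <= 2 * p:
        raise ValueError(f"MM-estimator needs n > 2p (got n={n}, p={p})")
    rng = np.random.default_rng(seed)

    # --- stage 1: fast-S
    candidates = []
    attempts = 0
    while len(candidates) < n_subsets and attempts < 4 * n_subsets:
        attempts += 1
        idx = rng.choice(n, size=p, replace=False)
        try:
            beta0 = np.linalg.solve(X[idx], y[idx])
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(beta0)):
            continue
        candidates.append(_s_refine(X, y, beta0, S_TUNING_C, k_refine))
    if len(candidates) < max(n_best, n_subsets // 4):
        raise RuntimeError("MM-estimator: too few non-singular p-subsets")
    candidates.sort(key=lambda bs: bs[1])
    best = []
    for beta0, _ in candidates[:n_best]:
        best.append(_s_refine(X, y, beta0, S_TUNING_C, 50))
    beta_s, scale = min(best, key=lambda bs: bs[1])

    if scale <= 1e-12:          # exact fit on >= half the data
        fitted = X @ beta_s
        coefs, ses, pvals = _wald(design.terms, beta_s, np.zeros(p))
        return FitResult("MM", list(design.terms), coefs, ses, pvals, fitted,
                         converged=True, n_iter=0, objective=0.0,
                         se_method="robust sandwich", scale=0.0)

    # --- stage 2: efficient M-step at fixed scale
    c1 = bisquare_tuning_constant(efficiency)
    beta = beta_s.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = (y - X @ beta) / scale
        w = _bisquare_weights(u, c1)
        if w.sum() <= p:
            break
        beta_new = _wls(X, y, w)
        if np.max(np.abs(beta_new - beta)) <= tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new

    fitted = X @ beta
    u = (y - fitted) / scale
    psi = _psi_bisquare(u, c1)
    psi_p = _psi_prime_bisquare(u, c1)
    A = (X * psi_p[:, None]).T @ X
    B = (X * psi[:, None] ** 2).T @ X
    try:
        A_inv = np.linalg.inv(A)
        V = scale ** 2 * A_inv @ B @ A_inv
        se = np.sqrt(np.maximum(np.diag(V), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    coefs, ses, pvals = _wald(design.terms, beta, se)
    return FitResult("MM", list(design.terms), coefs, ses, pvals, fitted,
                     converged=converged, n_iter=it,
                     objective=float(_rho_bisquare(u, c1).sum()),
                     se_method="robust sandwich", scale=float(scale))


# ---------------------------------------------------------------------------
# Fractional logit (quasi-binomial, logit link)


def _inv_logit(eta):
    return 1.0 / (1.0 + np.exp(-eta))


def fit_fractional_logit(design: Design, max_iter: int = 100,
                         tol: float = 1e-12) -> FitResult:
    """Quasi-binomial IRLS with logit link for fractional responses in (0, 1].

    The utility is modelled directly on its observed scale; the canonical
    link plus intercept makes the mean of the inverse-logit fitted values
    equal the observed mean at convergence.  Sandwich (robust) standard
    errors are reported, as the binomial variance is only a working
    assumption for utilities.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if np.any(y <= 0) or np.any(y > 1):
        raise ValueError("fractional logit requires responses in (0, 1]")
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta = np.zeros(p)
    beta[design.terms.index("const")] = math.log(ybar / (1 - ybar))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _inv_logit(eta)
        W = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / W
        try:
            beta_new = _wls(X, z, W)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(beta_new)):
            break
        if np.max(np.abs(beta_new - beta)) <= tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = X @ beta
    mu = _inv_logit(eta)
    W = np.clip(mu * (1 - mu), 1e-10, None)
    A = (X * W[:, None]).T @ X
    B = (X * ((y - mu) ** 2)[:, None]).T @ X
    A_inv = np.linalg.inv(A)
    V = A_inv @ B @ A_inv
    se = np.sqrt(np.maximum(np.diag(V), 0.0))
    coefs, ses, pvals = _wald(design.terms, beta, se)
    dev = float(np.sum((y - mu) ** 2 / W))      # Pearson-type objective
    return FitResult("GLM", list(design.terms), coefs, ses, pvals, mu,
                     converged=converged, n_iter=it, objective=dev,
                     se_method="GLM sandwich")


#: Dispatch by the labels used throughout the package.
ESTIMATORS: dict[str, Callable[..., FitResult]] = {
    "OLS": fit_ols,
    "CLAD": fit_clad,
    "MM": fit_mm,
    "GLM": fit_fractional_logit,
}
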