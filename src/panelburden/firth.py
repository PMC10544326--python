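"""Firth bias-reduced penalized-likelihood logistic regression.

Ordinary maximum-likelihood logistic regression breaks down on separated
data — the configuration that rare-variant case-control tables produce
routinely (e.g. zero carrier controls): the MLE drifts to infinity and
Wald intervals are useless.  Firth's correction maximizes the Jeffreys-
prior-penalized log-likelihood

    l*(beta) = l(beta) + 1/2 log det I(beta),      I(beta) = X' W X,

with W = diag(pi_i (1 - pi_i)).  The penalized mode always exists for a
full-rank design, is finite even under complete separation, and removes
the O(1/n) bias of the MLE.  The score of l* is the modified score

    U*_r(beta) = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ir,

where h_i is the i-th diagonal of the hat matrix
H = W^{1/2} X (X'WX)^{-1} X' W^{1/2}.

This module solves the modified score equations by Newton-Raphson with
step-halving and provides Wald (and optionally penalized-profile)
inference, plus the gene-by-gene association scans and the carrier-by-age
interaction model used by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "FirthFit",
    "DesignSpec",
    "AssociationResult",
    "AgeTrend",
    "fit_firth",
    "wald_inference",
    "profile_ci",
    "association_scan",
    "fit_age_trend",
]

_Z95 = float(stats.norm.ppf(0.975))


class SeparationWarning(UserWarning):
    """Emitted when a fit fails to converge within the iteration budget."""


@dataclass
class FirthFit:
    """Result of one penalized-likelihood logistic fit.

    Attributes
    ----------
    beta : coefficient vector on the log-odds scale.
    cov : inverse penalized information at the optimum (Wald covariance).
    penalized_loglik : value of l*(beta) at the optimum.
    iterations : Newton iterations used.
    converged : True iff the max-norm of the modified score fell below tol.
    max_score_norm : modified-score max-norm at exit.
    names : column names of the design matrix.
    """

    beta: np.ndarray
    cov: np.ndarray
    penalized_loglik: float
    iterations: int
    converged: bool
    max_score_norm: float
    names: list[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log-likelihood written in a form stable for large |eta|
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    pi = _expit(eta)
    w = pi * (1.0 - pi)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _expit(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Column-standardized copy Z with X = Z @ A, plus log|det A|.

    Non-constant columns are scaled to unit SD and, when a constant
    column is present to absorb the shift, centered as well; constant
    columns are untouched.
    """
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    varying = sd > 0
    const_idx = next((j for j in range(p) if not varying[j] and mu[j] != 0), None)
    Z = X.astype(float).copy()
    A = np.eye(p)
    for j in range(p):
        if not varying[j]:
            continue
        if const_idx is not None:
            Z[:, j] = (X[:, j] - mu[j]) / sd[j]
            A[const_idx, j] = mu[j] / mu[const_idx]
        else:
            Z[:, j] = X[:, j] / sd[j]
        A[j, j] = sd[j]
    logdetA = float(np.sum(np.log(sd[varying]))) if varying.any() else 0.0
    return Z, A, logdetA


def _modified_score(X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    """Firth's modified score U*(beta) and the Cholesky factor of the
    Fisher information at beta."""
    pi = _expit(X @ beta)
    w = pi * (1.0 - pi)
    info = X.T @ (X * w[:, None])
    try:
        chol = cho_factor(info)
    except np.linalg.LinAlgError:  # extreme linear predictors
        info = info + 1e-10 * np.eye(X.shape[1])
        chol = cho_factor(info)
    V = cho_solve(chol, X.T)  # p x n
    h = w * np.einsum("ij,ji->i", X, V)
    score = X.T @ (y - pi + h * (0.5 - pi))
    return score, chol


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    # QR with pivoting identifies which columns are linearly dependent
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[j]] for j in range(len(diag)) if diag[j] <= tol]
    if bad:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def fit_firth(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    tol: float = 1e-6,
    max_iter: int = 100,
    max_halvings: int = 25,
    names: Sequence[str] | None = None,
) -> FirthFit:
    """Maximize the Jeffreys-penalized binomial log-likelihood.

    Parameters
    ----------
    X : design matrix including the intercept column; full column rank.
    y : binary outcomes in {0, 1}.
    tol : convergence tolerance on the max-norm of the modified score.
    max_iter : Newton iteration budget.
    max_halvings : step-halvings allowed per iteration when the penalized
        log-likelihood fails to increase.

    Raises
    ------
    numpy.linalg.LinAlgError : if X is rank deficient (collinear columns
        are named in the message).
    ValueError : if y is not binary or shapes disagree.
    """
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape} vs y {y.shape}")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    _check_full_rank(X, names)

    # standardize internally (exact: the Jeffreys penalty is invariant to
    # a fixed linear reparameterization up to an additive constant), which
    # keeps the score components on comparable scales
    Z, A, logdetA = _standardize(X)
    X_orig = X
    X = Z

    beta = np.zeros(p)
    ll = _penalized_loglik(X, y, beta)
    score_norm = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, chol = _modified_score(X, y, beta)
        score_norm = float(np.max(np.abs(score)))
        if score_norm < tol:
            converged = True
            break
        delta = cho_solve(chol, score)
        step = 1.0
        accepted = False
        for halved in range(max_halvings + 1):
            beta_new = beta + step * delta
            ll_new = _penalized_loglik(X, y, beta_new)
            if ll_new > ll:
                accepted = True
                break
            # near the optimum the l* improvement falls below floating-
            # point resolution; accept on score-norm descent instead
            snew = float(np.max(np.abs(_modified_score(X, y, beta_new)[0])))
            if snew < score_norm:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break  # no progress possible at floating-point resolution
        beta = beta_new
        ll = max(ll_new, ll)

    if not converged:
        # polish with gradient-based quasi-Newton on -l*: the modified
        # score is the exact gradient of the penalized log-likelihood
        res = optimize.minimize(
            lambda b: -_penalized_loglik(X, y, b),
            beta,
            jac=lambda b: -_modified_score(X, y, b)[0],
            method="BFGS",
            options={"gtol": tol * 0.1, "maxiter": 500},
        )
        if np.isfinite(res.fun) and -res.fun >= ll:
            beta = res.x
        score_norm = float(np.max(np.abs(_modified_score(X, y, beta)[0])))
        # under quasi-separation the score's floating-point noise floor
        # can sit above tol even at the optimum; a stalled line search
        # with a small residual score is numerical convergence
        converged = score_norm < max(tol, 4e-9 * n)

    if not converged:
        warnings.warn(
            f"Firth fit did not converge in {max_iter} iterations "
            f"(max |U*| = {score_norm:.2e})",
            SeparationWarning,
            stacklevel=2,
        )

    # back-transform to the original scale; covariance from the
    # penalized information at the exit point
    ll_out = _penalized_loglik(X, y, beta) + logdetA
    beta_orig = np.linalg.solve(A, beta)
    eta = X_orig @ beta_orig
    pi = _expit(eta)
    w = pi * (1.0 - pi)
    info = X_orig.T @ (X_orig * w[:, None])
    cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    return FirthFit(
        beta=beta_orig,
        cov=cov,
        penalized_loglik=ll_out,
        iterations=it,
        converged=converged,
        max_score_norm=score_norm,
        names=names,
    )


def wald_inference(
    fit: FirthFit, index: int, level: float = 0.95
) -> tuple[float, float, float, float]:
    """Odds ratio, CI bounds and two-sided Wald p for one coefficient.

    CI is exp(beta_j +/- z * SE_j); p is from the standard-normal
    reference of beta_j / SE_j.
    """
    if not fit.converged:
        raise ValueError("cannot do Wald inference on a non-converged fit")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    b = float(fit.beta[index])
    se = float(np.sqrt(fit.cov[index, index]))
    or_hat = float(np.exp(b))
    lo = float(np.exp(b - z * se))
    hi = float(np.exp(b + z * se))
    p = float(2.0 * stats.norm.sf(abs(b) / se)) if se > 0 else 0.0
    return or_hat, lo, hi, p


def profile_ci(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    fit: FirthFit,
    index: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Penalized-profile-likelihood CI for one coefficient (optional
    alternative to the default Wald interval).

    Inverts 2*(l*_max - l*_profile(b)) = chi2_{1,level} by bisection,
    maximizing over the remaining coefficients with BFGS at each fixed b.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    target = fit.penalized_loglik - 0.5 * float(stats.chi2.ppf(level, 1))
    others = [j for j in range(X.shape[1]) if j != index]

    def prof(b: float) -> float:
        def neg(bo: np.ndarray) -> float:
            beta = np.empty(X.shape[1])
            beta[index] = b
            beta[others] = bo
            return -_penalized_loglik(X, y, beta)

        res = optimize.minimize(neg, fit.beta[others], method="BFGS", options={"gtol": 1e-8})
        return -res.fun

    b_hat = float(fit.beta[index])
    se = float(np.sqrt(fit.cov[index, index]))

    def solve(direction: float) -> float:
        width = 1.0 * se
        lo_b = b_hat
        hi_b = b_hat + direction * width
        while prof(hi_b) > target:
            width *= 2.0
            hi_b = b_hat + direction * width
            if width > 50 * se + 50:  # pragma: no cover - pathological
                return hi_b
        f = lambda b: prof(b) - target
        return float(optimize.brentq(f, min(lo_b, hi_b), max(lo_b, hi_b), xtol=1e-6))

    return solve(-1.0), solve(+1.0)


# ---------------------------------------------------------------------------
# association scans
# ---------------------------------------------------------------------------

OUTCOMES = ("overall", "er_pos", "er_neg", "triple_negative")


@dataclass
class DesignSpec:
    """One association fit: an outcome definition, an exposure unit and an
    adjustment set.

    ``outcome`` chooses which cases enter (overall, ER+, ER-, triple-
    negative); controls are always the full control group.  ``stratum``
    optionally restricts the case set to a named subject-id partition
    (e.g. family-history strata).
    """

    outcome: str = "overall"
    exposure: str | None = None
    adjustment: tuple[str, ...] = ("age_years", "family_history")
    stratum: tuple[str, frozenset] | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}")


@dataclass
class AssociationResult:
    unit: str
    outcome: str
    n_case_carriers: int
    n_control_carriers: int
    n_cases: int
    n_controls: int
    or_hat: float
    ci_low: float
    ci_high: float
    p_wald: float
    stratum: str = ""
    converged: bool = True
    iterations: int = 0
    error: str = ""


def _case_mask_for_outcome(phenotypes: pd.DataFrame, outcome: str) -> pd.Series:
    from .burden import subtype_labels

    is_case = (phenotypes["status"] == "case").to_numpy()
    if outcome == "overall":
        return pd.Series(is_case, index=phenotypes.index)
    labels = subtype_labels(phenotypes)  # same row order as phenotypes
    key = {"er_pos": "er_pos", "er_neg": "er_neg", "triple_negative": "triple_negative"}[outcome]
    flag = labels[key].fillna(False).to_numpy(dtype=bool)
    return pd.Series(is_case & flag, index=phenotypes.index)


def _build_design(
    carrier: pd.Series,
    phenotypes: pd.DataFrame,
    spec: DesignSpec,
) -> tuple[pd.DataFrame, pd.Series] | None:
    phen = phenotypes.set_index("subject_id") if "subject_id" in phenotypes else phenotypes
    case_mask = _case_mask_for_outcome(phenotypes, spec.outcome)
    case_ids = phenotypes.loc[case_mask, "subject_id"]
    if spec.stratum is not None:
        case_ids = case_ids[case_ids.isin(spec.stratum[1])]
    control_ids = phenotypes.loc[phenotypes["status"] == "control", "subject_id"]
    ids = pd.Index(case_ids).append(pd.Index(control_ids))
    sub = phen.loc[ids]
    y = (sub["status"] == "case").astype(float)
    cols = {"intercept": np.ones(len(sub)), "carrier": carrier.reindex(ids).to_numpy(dtype=float)}
    for cov in spec.adjustment:
        cols[cov] = pd.to_numeric(sub[cov], errors="coerce").to_numpy(dtype=float)
    Xdf = pd.DataFrame(cols, index=ids)
    keep = ~Xdf.isna().any(axis=1)
    Xdf = Xdf.loc[keep]
    y = y.loc[keep]
    if (y == 1).sum() == 0:
        return None
    return Xdf, y


def association_scan(
    cm,
    phenotypes: pd.DataFrame,
    specs: Iterable[DesignSpec],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[AssociationResult]:
    """Firth association of each carrier-matrix unit for each design.

    Units with zero carriers in both cases and controls are skipped (they
    carry no information and the scan convention includes only units with
    at least one carrier detected in either group).  Subjects missing any
    adjustment covariate or a required subtype marker are dropped per fit.
    """
    results: list[AssociationResult] = []
    indicator = cm.indicator
    for spec in specs:
        units = [spec.exposure] if spec.exposure else list(indicator.columns)
        for unit in units:
            carrier = indicator[unit]
            if carrier.sum() == 0:
                continue
            built = _build_design(carrier, phenotypes, spec)
            stratum_name = spec.stratum[0] if spec.stratum else ""
            if built is None:
                results.append(
                    AssociationResult(
                        unit=unit, outcome=spec.outcome,
                        n_case_carriers=0, n_control_carriers=0,
                        n_cases=0, n_controls=0,
                        or_hat=np.nan, ci_low=np.nan, ci_high=np.nan,
                        p_wald=np.nan, stratum=stratum_name, converged=False,
                        error="no eligible cases for outcome",
                    )
                )
                continue
            Xdf, y = built
            carr = Xdf["carrier"]
            ncc = int(carr[(y == 1)].sum())
            nkc = int(carr[(y == 0)].sum())
            if ncc + nkc == 0:
                continue
            try:
                fit = fit_firth(Xdf, y, tol=tol, max_iter=max_iter)
                j = fit.names.index("carrier")
                or_hat, lo, hi, p = wald_inference(fit, j)
                results.append(
                    AssociationResult(
                        unit=unit, outcome=spec.outcome,
                        n_case_carriers=ncc, n_control_carriers=nkc,
                        n_cases=int((y == 1).sum()), n_controls=int((y == 0).sum()),
                        or_hat=or_hat, ci_low=lo, ci_high=hi, p_wald=p,
                        stratum=stratum_name, converged=fit.converged,
                        iterations=fit.iterations,
                    )
                )
            except (np.linalg.LinAlgError, ValueError) as exc:
                results.append(
                    AssociationResult(
                        unit=unit, outcome=spec.outcome,
                        n_case_carriers=ncc, n_control_carriers=nkc,
                        n_cases=int((y == 1).sum()), n_controls=int((y == 0).sum()),
                        or_hat=np.nan, ci_low=np.nan, ci_high=np.nan, p_wald=np.nan,
                        stratum=stratum_name, converged=False, error=str(exc),
                    )
                )
    return results


def results_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# carrier x age interaction
# ---------------------------------------------------------------------------


@dataclass
class AgeTrend:
    """Per-year multiplier on the carrier odds ratio from the model
    outcome ~ carrier + age + family_history + carrier:age (age centered
    at ``age_ref``)."""

    unit: str
    multiplier: float
    ci_low: float
    ci_high: float
    p: float
    beta_carrier: float
    beta_interaction: float
    age_ref: float
    fit: FirthFit

    def or_at(self, age: float | np.ndarray) -> float | np.ndarray:
        """Implied age-specific odds ratio OR(t)."""
        return np.exp(self.beta_carrier + self.beta_interaction * (np.asarray(age) - self.age_ref))


def fit_age_trend(
    cm,
    phenotypes: pd.DataFrame,
    unit: str,
    age_ref: float = 50.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> AgeTrend:
    """Fit the carrier-by-age interaction model for one unit.

    The interaction coefficient, exponentiated, is the per-year
    multiplier on the carrier OR; the returned object also exposes the
    implied OR(t) function used for cumulative-risk estimation.
    """
    carrier = cm.indicator[unit]
    if carrier.sum() < 2:
        raise ValueError(
            f"unit {unit!r} has {int(carrier.sum())} carriers; "
            "age trend is unidentifiable with fewer than 2"
        )
    phen = phenotypes.set_index("subject_id")
    ids = phen.index
    age = pd.to_numeric(phen["age_years"], errors="coerce") - age_ref
    fh = pd.to_numeric(phen["family_history"], errors="coerce")
    carr = carrier.reindex(ids).astype(float)
    Xdf = pd.DataFrame(
        {
            "intercept": 1.0,
            "carrier": carr,
            "age_c": age,
            "family_history": fh,
            "carrier_x_age": carr * age,
        },
        index=ids,
    )
    y = (phen["status"] == "case").astype(float)
    keep = ~Xdf.isna().any(axis=1)
    fit = fit_firth(Xdf.loc[keep], y.loc[keep], tol=tol, max_iter=max_iter)
    j = fit.names.index("carrier_x_age")
    mult, lo, hi, p = wald_inference(fit, j)
    return AgeTrend(
        unit=unit,
        multiplier=mult,
        ci_low=lo,
        ci_high=hi,
        p=p,
        beta_carrier=float(fit.beta[fit.names.index("carrier")]),
        beta_interaction=float(fit.beta[j]),
        age_ref=age_ref,
        fit=fit,
    )
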