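"""Sex-specific Cox proportional-hazards comparator.

Fits the Cox partial likelihood on the pre-specified covariate vector by
Newton iteration with step halving, with Efron (default) or Breslow tie
correction. Standard errors come from the inverse observed information at
the optimum. Efron is the default because day-resolution follow-up
produces many ties.

The low-level array interface (:func:`fit_cox_arrays`) is reused wherever
a partial-likelihood fit on an arbitrary design matrix is needed (e.g. the
single-covariate rankit fit behind the D statistic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .records import (CenteringContext, CohortError, PersonRecord,
                      covariate_matrix, covariate_names)


class CoxFitError(RuntimeError):
    """Fit failure: no events, collinear design, or non-convergence."""


@dataclass
class CoxFitResult:
    """Arrays-level fit: coefficients, SEs, information, diagnostics."""

    beta: np.ndarray
    se: np.ndarray
    information: np.ndarray
    log_likelihood: float
    n_iter: int
    final_grad_norm: float
    ties: str


@dataclass
class CoxModel:
    """A fitted sex-stratum Cox model on the pre-specified predictors."""

    result: CoxFitResult
    names: list[str]
    centering: CenteringContext
    sex: str | None
    predictor_set: str

    @property
    def beta(self) -> np.ndarray:
        return self.result.beta

    @property
    def se(self) -> np.ndarray:
        return self.result.se

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.result.beta)

    def linear_predictor(self, cohort: list[PersonRecord]) -> np.ndarray:
        X = covariate_matrix(cohort, self.centering, self.predictor_set)
        return X @ self.result.beta

    def confidence_intervals(self, level: float = 0.95
                             ) -> tuple[np.ndarray, np.ndarray]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        return (self.result.beta - z * self.result.se,
                self.result.beta + z * self.result.se)

    # -- plain-text serialization -----------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "names": self.names,
            "beta": self.result.beta.tolist(),
            "se": self.result.se.tolist(),
            "log_likelihood": self.result.log_likelihood,
            "n_iter": self.result.n_iter,
            "final_grad_norm": self.result.final_grad_norm,
            "ties": self.result.ties,
            "centering_mean_age": self.centering.mean_age,
            "centering_reference_deprivation":
                self.centering.reference_deprivation,
            "sex": self.sex,
            "predictor_set": self.predictor_set,
        }
        Path(path).write_text(json.dumps(payload, indent=2),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CoxModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        result = CoxFitResult(
            beta=np.array(d["beta"]), se=np.array(d["se"]),
            information=np.empty((0, 0)),
            log_likelihood=d["log_likelihood"], n_iter=d["n_iter"],
            final_grad_norm=d["final_grad_norm"], ties=d["ties"])
        centering = CenteringContext(
            mean_age=d["centering_mean_age"],
            reference_deprivation=d["centering_reference_deprivation"],
            sex=d["sex"])
        return cls(result=result, names=d["names"], centering=centering,
                   sex=d["sex"], predictor_set=d["predictor_set"])


def _check_collinearity(X: np.ndarray, names: list[str] | None) -> None:
    Xc = X - X.mean(axis=0)
    scale = Xc.std(axis=0)
    const = scale < 1e-12
    if const.any():
        bad = [(names[j] if names else str(j))
               for j in np.flatnonzero(const)]
        raise CoxFitError(f"constant covariate columns: {bad}")
    _, R, piv = scipy.linalg.qr(Xc / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps
    deficient = diag < tol
    if deficient.any():
        bad = [(names[piv[j]] if names else str(piv[j]))
               for j in np.flatnonzero(deficient)]
        raise CoxFitError(f"collinear covariate columns: {bad}")


def _loglik_grad_info(beta: np.ndarray, X: np.ndarray, times: np.ndarray,
                      events: np.ndarray, ties: str,
                      want_derivs: bool = True
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """Cox partial log-likelihood with gradient and observed information.

    Iterates over unique times in decreasing order, accumulating risk-set
    sums S0 = sum exp(eta), S1 = sum exp(eta) x, S2 = sum exp(eta) x x'.
    """
    n, p = X.shape
    eta = X @ beta
    shift = eta.max()  # overflow guard; cancels in all ratios and in ll - d*log S0
    r = np.exp(eta - shift)
    rX = r[:, None] * X
    order = np.argsort(-times, kind="stable")
    uniq_times = np.unique(times)[::-1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    pos = 0
    for t in uniq_times:
        while pos < n and times[order[pos]] == t:
            i = order[pos]
            S0 += r[i]
            S1 += rX[i]
            if want_derivs:
                S2 += np.outer(X[i], rX[i])
            pos += 1
        dead = order[:pos][events[order[:pos]] & (times[order[:pos]] == t)]
        d = len(dead)
        if d == 0:
            continue
        ll += eta[dead].sum() - d * shift
        if ties == "breslow":
            ll -= d * np.log(S0)
            if want_derivs:
                m1 = S1 / S0
                grad += X[dead].sum(axis=0) - d * m1
                info += d * (S2 / S0 - np.outer(m1, m1))
        elif ties == "efron":
            s0d = r[dead].sum()
            s1d = rX[dead].sum(axis=0)
            s2d = (X[dead].T @ rX[dead]) if want_derivs else None
            xsum = X[dead].sum(axis=0)
            for ell in range(d):
                c = ell / d
                S0l = S0 - c * s0d
                ll -= np.log(S0l)
                if want_derivs:
                    S1l = S1 - c * s1d
                    m1 = S1l / S0l
                    grad_piece = m1
                    grad -= grad_piece
                    info += (S2 - c * s2d) / S0l - np.outer(m1, m1)
            if want_derivs:
                grad += xsum
        else:
            raise CoxFitError(f"unknown tie correction {ties!r}")
    return ll, grad, info


def fit_cox_arrays(X: np.ndarray, times: np.ndarray, events: np.ndarray,
                   ties: str = "efron", names: list[str] | None = None,
                   max_iter: int = 100, tol_ll: float = 1e-9,
                   tol_grad: float = 1e-6) -> CoxFitResult:
    """Maximize the Cox partial likelihood by Newton iteration.

    Convergence on relative log-likelihood change < ``tol_ll`` or gradient
    max-norm < ``tol_grad``; steps are halved (up to 30 times) whenever
    the likelihood fails to increase.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if X.shape[0] != times.shape[0] or times.shape[0] != events.shape[0]:
        raise CoxFitError("X, times and events must have equal lengths")
    if events.sum() == 0:
        raise CoxFitError("no events in stratum: Cox fit is undefined")
    _check_collinearity(X, names)

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _loglik_grad_info(beta, X, times, events, ties)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxFitError(
                f"singular information matrix at iteration {n_iter}"
            ) from exc
        new_beta, new = beta + step, None
        for _ in range(30):  # step halving on non-increase
            new = _loglik_grad_info(new_beta, X, times, events, ties)
            if new[0] >= ll or not np.isfinite(new[0]):
                if np.isfinite(new[0]):
                    break
            step = step / 2
            new_beta = beta + step
        if new is None or not np.isfinite(new[0]):
            raise CoxFitError(f"non-finite likelihood at iteration {n_iter}")
        delta_ll = new[0] - ll
        beta, (ll, grad, info) = new_beta, new
        if (abs(delta_ll) < tol_ll * max(1.0, abs(ll))
                or np.abs(grad).max() < tol_grad):
            break
    else:
        raise CoxFitError(
            f"no convergence after {max_iter} iterations "
            f"(loglik={ll:.6g}, grad_norm={np.abs(grad).max():.3g})")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxFitError("singular information at the optimum") from exc
    return CoxFitResult(beta=beta, se=np.sqrt(np.diag(cov)),
                        information=info, log_likelihood=float(ll),
                        n_iter=n_iter,
                        final_grad_norm=float(np.abs(grad).max()), ties=ties)


def fit_cox(stratum: list[PersonRecord], predictor_set: str = "full",
            ties: str = "efron",
            centering: CenteringContext | None = None) -> CoxModel:
    """Fit the sex-stratum comparator on the pre-specified predictors.

    ``centering`` must be fitted on training data of the matching stratum;
    when omitted it is fitted on ``stratum`` itself (full-data fits).
    """
    if not stratum:
        raise CoxFitError("empty stratum")
    sexes = {p.sex for p in stratum}
    sex = sexes.pop() if len(sexes) == 1 else None
    if centering is None:
        centering = CenteringContext.fit(stratum, sex=sex)
    names = covariate_names(predictor_set)
    X = covariate_matrix(stratum, centering, predictor_set)
    times = np.array([p.follow_up_days for p in stratum], dtype=float)
    events = np.array([p.cvd_event for p in stratum], dtype=bool)
    result = fit_cox_arrays(X, times, events, ties=ties, names=names)
    return CoxModel(result=result, names=names, centering=centering,
                    sex=sex, predictor_set=predictor_set)
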