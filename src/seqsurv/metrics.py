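"""Survival model assessment: concordance, explained variation, Brier.

All estimators here follow the standard censored-data conventions:

* Harrell's C counts pairs (i, j) as comparable when ``t_i < t_j`` and i
  had the event, or when ``t_i == t_j`` and exactly one of the pair had
  the event; prediction ties count one half.
* The Royston-Sauerbrei D statistic is the Cox coefficient of the scaled
  Blom rankits of the prognostic index; R2_D is its explained-variation
  transform. Both are invariant to strictly increasing transforms of the
  predictions.
* The (integrated) Brier score uses Graf's inverse-probability-of-
  censoring weights with the left-limit convention G(t-) for observed
  events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox import fit_cox_arrays

logger = logging.getLogger(__name__)

KAPPA = np.sqrt(8.0 / np.pi)


class MetricError(ValueError):
    pass


def _as_arrays(predictions, times, events):
    f = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (f.shape == t.shape == e.shape) or f.ndim != 1:
        raise MetricError("predictions, times and events must be equal-"
                          "length 1-D arrays")
    return f, t, e


def harrells_c(predictions, times, events) -> float:
    """Concordance between predicted risk scores and censored outcomes.

    Higher predictions are expected for persons whose event comes earlier.
    """
    f, t, e = _as_arrays(predictions, times, events)
    n = len(f)
    concordant = ties = comparable = 0.0
    block = max(1, int(2e6 // max(n, 1)))
    ev_idx = np.flatnonzero(e)
    for start in range(0, ev_idx.size, block):
        ii = ev_idx[start:start + block]
        ti = t[ii][:, None]
        fi = f[ii][:, None]
        # j comparable to event i: later time, or same time and censored
        later = t[None, :] > ti
        tied_time = (t[None, :] == ti) & ~e[None, :]
        comp = later | tied_time
        # unordered event-event pairs at strictly later times are counted
        # once: both orientations appear, (i earlier) is kept by `later`
        comparable += comp.sum()
        concordant += ((fi > f[None, :]) & comp).sum()
        ties += ((fi == f[None, :]) & comp).sum()
    if comparable == 0:
        raise MetricError("no comparable pairs")
    return float((concordant + 0.5 * ties) / comparable)


@dataclass(frozen=True)
class RoystonD:
    """D statistic and R2_D; ``degenerate`` marks an all-tied predictor."""

    d: float
    r2: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.d, self.r2))


def d_to_r2(d: float) -> float:
    x = d * d / (KAPPA * KAPPA)
    return x / (np.pi ** 2 / 6.0 + x)


def royston_d_r2(predictions, times, events, ties: str = "efron"
                 ) -> RoystonD:
    """Royston-Sauerbrei D and R2 of a prognostic index.

    Ranks the predictions (average ranks on ties), maps them to Blom
    rankits z = Phi^{-1}((rank - 3/8)/(n + 1/4)), scales by kappa =
    sqrt(8/pi), and takes the Cox coefficient of the scaled rankits as D.
    """
    f, t, e = _as_arrays(predictions, times, events)
    if e.sum() < 1:
        raise MetricError("no events")
    if np.all(f == f[0]):
        logger.warning("all predictions identical: D = 0 by convention")
        return RoystonD(d=0.0, r2=0.0, degenerate=True)
    n = len(f)
    ranks = stats.rankdata(f, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25)) / KAPPA
    result = fit_cox_arrays(z[:, None], t, e, ties=ties)
    d = float(result.beta[0])
    return RoystonD(d=d, r2=float(d_to_r2(d)))


# -- Kaplan-Meier helpers -------------------------------------------------
@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function with access to left limits."""

    times: np.ndarray      # strictly increasing jump times
    values: np.ndarray     # value on [times[k], times[k+1])
    initial: float = 1.0   # value before the first jump

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float),
                              side="right")
        return np.where(idx == 0, self.initial,
                        self.values[np.maximum(idx - 1, 0)])

    def left_limit(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float),
                              side="left")
        return np.where(idx == 0, self.initial,
                        self.values[np.maximum(idx - 1, 0)])


def kaplan_meier(times, indicator) -> StepFunction:
    """KM estimate of the survival function of the ``indicator`` process.

    Pass the event flags for the outcome distribution, or their complement
    for the censoring distribution G.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(indicator, dtype=bool)
    uniq = np.unique(t)
    at_risk = np.array([(t >= u).sum() for u in uniq], dtype=float)
    n_jump = np.array([(d & (t == u)).sum() for u in uniq], dtype=float)
    surv = np.cumprod(1.0 - n_jump / at_risk)
    return StepFunction(times=uniq, values=surv)


def censoring_km(times, events) -> StepFunction:
    """KM of the censoring distribution (Graf weighting convention)."""
    return kaplan_meier(times, ~np.asarray(events, dtype=bool))


def default_brier_grid(times, events, horizon: float = 1826.0,
                       max_points: int = 200) -> np.ndarray:
    """Distinct event times up to the horizon, quantile-thinned to
    ``max_points``."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    grid = np.unique(t[e & (t <= horizon)])
    if grid.size == 0:
        raise MetricError("no event times within the horizon")
    if grid.size > max_points:
        qs = np.linspace(0, 1, max_points)
        grid = np.unique(np.quantile(grid, qs, method="lower"))
    return grid


def brier_scores(surv_matrix: np.ndarray, times, events,
                 grid: np.ndarray,
                 censoring: StepFunction | None = None) -> np.ndarray:
    """IPCW Brier score BS(t) on each grid time.

    ``surv_matrix[i, k]`` is person i's predicted survival at ``grid[k]``.
    ``censoring`` is the censoring-distribution KM; by default it is
    estimated from ``times``/``events`` themselves, but cross-validation
    callers should pass the training-half estimate.
    """
    S = np.asarray(surv_matrix, dtype=float)
    _, t, e = _as_arrays(np.zeros(S.shape[0]), times, events)
    grid = np.asarray(grid, dtype=float)
    if S.shape != (len(t), len(grid)):
        raise MetricError("surv_matrix shape must be (n_persons, n_grid)")
    G = censoring if censoring is not None else censoring_km(t, e)
    g_event = G.left_limit(t)           # G(t_i-) for observed events
    g_grid = G(grid)                    # G(t) for still-at-risk persons
    bs = np.empty(len(grid))
    for k, tk in enumerate(grid):
        had_event = (t <= tk) & e
        at_risk = t > tk
        if had_event.any() and np.any(g_event[had_event] <= 0):
            raise MetricError(
                f"censoring survival is zero at an event time <= {tk}")
        if at_risk.any() and g_grid[k] <= 0:
            raise MetricError(f"censoring survival is zero at time {tk}")
        term_event = np.where(had_event,
                              S[:, k] ** 2
                              / np.where(g_event > 0, g_event, 1.0), 0.0)
        term_risk = np.where(at_risk, (1.0 - S[:, k]) ** 2
                             / (g_grid[k] if g_grid[k] > 0 else 1.0), 0.0)
        bs[k] = np.mean(term_event + term_risk)
    return bs


def integrated_brier(surv_matrix: np.ndarray, times, events,
                     grid: np.ndarray,
                     censoring: StepFunction | None = None) -> float:
    """Trapezoidal time-average of BS(t) over the grid."""
    grid = np.asarray(grid, dtype=float)
    bs = brier_scores(surv_matrix, times, events, grid, censoring)
    if grid.size == 1:
        return float(bs[0])
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


@dataclass(frozen=True)
class DecileTable:
    """Calibration/discrimination summary per decile of predicted risk."""

    mean_predicted: np.ndarray     # mean predicted 5-year risk per decile
    observed_proportion: np.ndarray  # KM-adjusted (or raw) event proportion
    event_share: np.ndarray        # share of all observed events
    sizes: np.ndarray


def decile_tables(predicted_risks, times, events, horizon: float = 1826.0,
                  n_groups: int = 10, observed: str = "km") -> DecileTable:
    """Group persons into deciles of predicted risk and summarize each.

    ``observed="km"`` estimates each decile's 5-year event proportion as
    1 - KM(horizon) within the decile (censoring-adjusted); ``"raw"`` uses
    the crude event fraction.
    """
    r, t, e = _as_arrays(predicted_risks, times, events)
    if len(r) < n_groups:
        raise MetricError(f"need at least {n_groups} persons")
    order = np.argsort(r, kind="stable")
    groups = np.array_split(order, n_groups)
    total_events = e.sum()
    mean_pred = np.array([r[g].mean() for g in groups])
    shares = np.array([e[g].sum() / total_events if total_events else 0.0
                       for g in groups])
    obs = np.empty(n_groups)
    for k, g in enumerate(groups):
        if observed == "raw":
            obs[k] = e[g].mean()
        else:
            obs[k] = 1.0 - float(kaplan_meier(t[g], e[g])(horizon))
    return DecileTable(mean_predicted=mean_pred, observed_proportion=obs,
                       event_share=shares,
                       sizes=np.array([len(g) for g in groups]))
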