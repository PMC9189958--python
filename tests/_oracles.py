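"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive quantities from first principles (exhaustive
pair enumeration, dense grid search, literal formula expansion) and never
call the package implementations they are used to check.
"""

import numpy as np


def concordance_bruteforce(f, times, events):
    """O(n^2) pair enumeration of Harrell's C."""
    f = np.asarray(f, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = len(f)
    conc = ties = comp = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i is the event-earlier member of a comparable pair
            if e[i] and (t[i] < t[j] or (t[i] == t[j] and not e[j])):
                comp += 1
                if f[i] > f[j]:
                    conc += 1
                elif f[i] == f[j]:
                    ties += 1
    if comp == 0:
        raise ValueError("no comparable pairs")
    return (conc + 0.5 * ties) / comp


def cox_loglik_single(beta, x, times, events):
    """Breslow partial log-likelihood, one covariate, literal definition."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    ll = 0.0
    for j in np.flatnonzero(e):
        risk = t >= t[j]
        ll += beta * x[j] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_grid_search(x, times, events, lo=-4.0, hi=4.0, step=1e-4):
    """Dense grid maximization of the single-covariate partial likelihood."""
    grid = np.arange(lo, hi + step, step)
    lls = [cox_loglik_single(b, x, times, events) for b in grid]
    return float(grid[int(np.argmax(lls))])


def breslow_cumhaz_bruteforce(f, times, events, t_eval, f_ref=0.0):
    """Literal Breslow sum: Lambda(t) = sum_{t_j <= t} d_j / sum_risk."""
    f = np.asarray(f, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    lam = 0.0
    for tj in np.unique(t[e]):
        if tj > t_eval:
            continue
        d_j = np.sum((t == tj) & e)
        denom = np.sum(np.exp(f[t >= tj] - f_ref))
        lam += d_j / denom
    return lam


def vocabulary_bruteforce(cohort, min_persons):
    """Two-pass distinct-person scan: code -> set of person ids."""
    support = {}
    for person in cohort:
        for ev in person.events:
            support.setdefault(ev.code, set()).add(person.person_id)
    return {c for c, ids in support.items() if len(ids) >= min_persons}
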