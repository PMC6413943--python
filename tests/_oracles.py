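"""Independent reference implementations used to check the package.

These are deliberately written from the rule definitions with different
mechanics than the library (explicit index lists and rescans instead of
incremental state; dense linear algebra and generic optimisation instead
of profiled grouped algebra), so agreement is a meaningful check.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


# --- residence-event segmentation oracle --------------------------------

def segment_oracle(times, stations, min_pings=2, timeout_s=900.0, other_station_pings=2):
    """Replay the residence-event rules over (time, station) pairs.

    Returns a list of dicts (station, start, end, n, reason). State is a
    list of detection indices per station run, rebuilt explicitly.
    """
    times = list(map(float, times))
    stations = list(stations)
    n = len(times)
    events = []

    # runs[st] = list of indices of an unbroken (gap <= timeout) string at st
    runs: dict[str, list[int]] = {}
    open_st = None
    open_members: list[int] = []

    def emit(reason):
        nonlocal open_st, open_members
        events.append(
            {
                "station": open_st,
                "start": times[open_members[0]],
                "end": times[open_members[-1]],
                "n": len(open_members),
                "reason": reason,
            }
        )
        open_st = None
        open_members = []

    for i in range(n):
        t, s = times[i], stations[i]
        if open_st is not None and t - times[open_members[-1]] > timeout_s:
            emit("timeout")
        if open_st is not None:
            if s == open_st:
                open_members.append(i)
                runs = {}
                continue
            lst = runs.get(s, [])
            if lst and t - times[lst[-1]] <= timeout_s:
                lst = lst + [i]
            else:
                lst = [i]
            runs[s] = lst
            if len(lst) >= other_station_pings:
                emit("other_station")
                if len(lst) >= min_pings:
                    open_st = s
                    open_members = list(lst)
                    runs = {}
            continue
        lst = runs.get(s, [])
        if lst and t - times[lst[-1]] <= timeout_s:
            lst = lst + [i]
        else:
            lst = [i]
        runs[s] = lst
        if len(lst) >= min_pings:
            open_st = s
            open_members = list(lst)
            runs = {}
    if open_st is not None:
        emit("stream_end")
    return events


# --- tagging-bias correction oracle --------------------------------------

def bias_correction_oracle(visits, tag_station, absence_h=24.0):
    """Earliest trigger of rule (a) or (b) over a list of visit dicts.

    ``visits``: list of dicts with keys station, start, end (floats, hours),
    already time-ordered. Returns (analysis_start or None, rule).
    """
    candidates = []
    for v in visits:
        if v["station"] != tag_station:
            candidates.append((v["start"], "other_site_first"))
            break
    tagged = [v for v in visits if v["station"] == tag_station]
    for prev, nxt in zip(tagged, tagged[1:]):
        if nxt["start"] - prev["end"] >= absence_h:
            candidates.append((nxt["start"], "absent_24h"))
            break
    if not candidates:
        return None, "none_applicable"
    start, rule = min(candidates)
    return start, rule


# --- LMM exact-likelihood oracle -----------------------------------------

def _dense_loglik(y, X, groups, beta, s2g, s2r, criterion):
    n, p = X.shape
    Z = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
    V = s2g * Z @ Z.T + s2r * np.eye(n)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi_r = np.linalg.solve(V, r)
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + r @ Vi_r)
    if criterion == "ML":
        return float(ll)
    Vi_X = np.linalg.solve(V, X)
    sign2, logdet2 = np.linalg.slogdet(X.T @ Vi_X)
    if sign2 <= 0:
        return -np.inf
    return float(ll - 0.5 * logdet2 + 0.5 * p * np.log(2 * np.pi))


def lmm_oracle(y, X, groups, criterion="REML"):
    """Direct numerical maximisation of the exact (restricted) likelihood.

    Grid over the variance ratio for a start, then Nelder-Mead over the
    full parameter vector (beta, log s2g, log s2r) on the dense likelihood.
    For REML the fixed effects are set to the GLS solution at the optimum.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    n, p = X.shape
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s2 = float(resid @ resid / max(n - p, 1))

    best = None
    for lam in [0.0, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0]:
        for frac in [0.25, 0.5, 0.75]:
            s2r = max(s2 * frac, 1e-8)
            s2g = lam * s2r
            x0 = np.concatenate([beta0, [np.log(max(s2g, 1e-8)), np.log(s2r)]])

            def neg(par):
                b = par[:p]
                return -_dense_loglik(y, X, groups, b, np.exp(par[p]), np.exp(par[p + 1]), criterion)

            res = optimize.minimize(
                neg, x0, method="Nelder-Mead",
                options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
    par = best.x
    beta = par[:p]
    s2g, s2r = float(np.exp(par[p])), float(np.exp(par[p + 1]))
    # near-boundary: also compare against the s2g = 0 (GLS/OLS) solution
    ll0 = _dense_loglik(y, X, groups, beta0, 0.0, s2, criterion)

    def neg0(par):
        return -_dense_loglik(y, X, groups, par[:p], 0.0, np.exp(par[p]), criterion)

    res0 = optimize.minimize(
        neg0, np.concatenate([beta0, [np.log(s2)]]), method="Nelder-Mead",
        options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
    )
    if res0.fun < best.fun:
        beta = res0.x[:p]
        s2g, s2r = 0.0, float(np.exp(res0.x[p]))
        ll = -res0.fun
    else:
        ll = -best.fun
    return {"beta": beta, "sigma2_group": s2g, "sigma2_resid": s2r, "loglik": float(ll)}


# --- misc small oracles ---------------------------------------------------

def interval_member_oracle(ts, windows):
    """Is instant ts inside any half-open [a, b) window? Checked pairwise."""
    return any(a <= ts < b for a, b in windows)


def transfers_oracle(islands):
    """Change points in an island-labelled sequence: list of (i, from, to)."""
    out = []
    for i in range(len(islands) - 1):
        if islands[i] != islands[i + 1]:
            out.append((i, islands[i], islands[i + 1]))
    return out
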