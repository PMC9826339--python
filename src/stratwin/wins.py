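"""Pairwise win indicator rules for prioritized composite endpoints.

A win rule W assigns, for a pair of outcome histories evaluated at horizon t,
indicators (delta_ij, delta_ji) with delta_ij + delta_ji in {0, 1}:

* antisymmetry — at most one of the two subjects wins (A2);
* adaptedness — the comparison at t uses only data observed by t (A1);
* terminal freeze — the status is unchanged after both subjects' death
  (or censoring) times (A3), so death as a competing risk causes no trouble.

All comparisons are evaluated on observed data at the censored horizon
h = min(X_i, X_j, t), which keeps the residuals of the regression model
conditionally unbiased under independent censoring.  An event occurring
exactly at the horizon is observed and counts (the horizon comparison is
inclusive — the horizon is typically one subject's own event time);
between-subject time comparisons are strict, so ties at identical event
times yield (0, 0): with continuous event times ties are measure-zero, and
strict inequalities are what antisymmetry needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf

import numpy as np

from .data import SubjectRecord


@dataclass(frozen=True)
class PairComparison:
    """Win/loss status of an ordered pair at a given horizon."""

    delta_ij: int
    delta_ji: int
    horizon: float

    def __post_init__(self):
        if self.delta_ij + self.delta_ji not in (0, 1):
            raise ValueError("at most one winner per pair")

    @property
    def determinate(self) -> bool:
        return self.delta_ij + self.delta_ji == 1

    @property
    def r(self) -> int:
        """R = delta_ij + delta_ji, the determinacy indicator."""
        return self.delta_ij + self.delta_ji


def _check_t(t: float) -> None:
    if t < 0:
        raise ValueError("horizon t must be nonnegative")


def pocock_win(a: SubjectRecord, b: SubjectRecord, t: float) -> PairComparison:
    """Prioritized death-then-first-nonfatal comparison (Pocock's rule).

    ``a`` wins at horizon h = min(X_a, X_b, t) if ``b`` dies strictly before
    min(a's death, h); failing that, if both are alive at h, ``a`` wins if
    ``b``'s first nonfatal event comes strictly before min(a's first, h).
    """
    _check_t(t)
    h = min(a.followup_time, b.followup_time, t)
    da, db = a.death_time, b.death_time
    ta, tb = a.first_nonfatal, b.first_nonfatal
    alive = min(da, db) > h
    win_ab = (db <= h and db < da) or (alive and tb <= h and tb < ta)
    win_ba = (da <= h and da < db) or (alive and ta <= h and ta < tb)
    return PairComparison(int(win_ab), int(win_ba), h)


def tfe_win(a: SubjectRecord, b: SubjectRecord, t: float) -> PairComparison:
    """Time-to-first-composite-event comparison: earlier composite event loses."""
    _check_t(t)
    h = min(a.followup_time, b.followup_time, t)
    ca, cb = a.first_composite, b.first_composite
    win_ab = cb <= h and cb < ca
    win_ba = ca <= h and ca < cb
    return PairComparison(int(win_ab), int(win_ba), h)


def recurrent_win(a: SubjectRecord, b: SubjectRecord, t: float) -> PairComparison:
    """Cumulative-event-count comparison with death priority.

    Hierarchy at h = min(X_a, X_b, t): an earlier observed death loses; if
    neither subject is dead by h, the subject with fewer nonfatal events by h
    wins; on tied counts (>= 1 event) the later latest occurrence loses.
    """
    _check_t(t)
    h = min(a.followup_time, b.followup_time, t)
    da, db = a.death_time, b.death_time
    if db <= h and db < da:
        return PairComparison(1, 0, h)
    if da <= h and da < db:
        return PairComparison(0, 1, h)
    if min(da, db) > h:
        na = int(np.searchsorted(np.asarray(a.nonfatal_times), h, side="right"))
        nb = int(np.searchsorted(np.asarray(b.nonfatal_times), h, side="right"))
        if na < nb:
            return PairComparison(1, 0, h)
        if nb < na:
            return PairComparison(0, 1, h)
        if na >= 1:
            la, lb = a.nonfatal_times[na - 1], b.nonfatal_times[nb - 1]
            if lb > la:
                return PairComparison(1, 0, h)
            if la > lb:
                return PairComparison(0, 1, h)
    return PairComparison(0, 0, h)


WIN_RULES = {"pocock": pocock_win, "tfe": tfe_win, "recurrent": recurrent_win}


def get_rule(rule):
    if callable(rule):
        return rule
    try:
        return WIN_RULES[rule]
    except KeyError:
        raise ValueError(
            f"unknown win rule {rule!r}; choose from {sorted(WIN_RULES)}"
        ) from None


def win_jump_times(a: SubjectRecord, b: SubjectRecord, rule="pocock") -> np.ndarray:
    """Horizons at which the pair's (delta_ij, delta_ji) status changes.

    The status is a step function of the horizon t that can only jump where
    min(X_a, X_b, t) crosses an event time of either subject; between
    consecutive jump times it is constant.
    """
    rule = get_rule(rule)
    hmax = min(a.followup_time, b.followup_time)
    cand = set()
    for r in (a, b):
        cand.update(r.nonfatal_times)
        if r.death_observed:
            cand.add(r.followup_time)
        cand.add(r.followup_time)
    cand = sorted(c for c in cand if c <= hmax)
    if not cand:
        return np.empty(0)
    # the rules are right-continuous in t (an event at the horizon counts);
    # probing just past each candidate is equivalent and avoids edge cases
    probes = [*(np.nextafter(c, inf) for c in cand)]
    prev = (0, 0)  # status at t = 0
    jumps = []
    for c, probe in zip(cand, probes):
        pc = rule(a, b, probe)
        cur = (pc.delta_ij, pc.delta_ji)
        if cur != prev:
            jumps.append(c)
        prev = cur
    return np.asarray(jumps)


# ---------------------------------------------------------------------------
# vectorized pair evaluation (used by the fitter and diagnostics)
# ---------------------------------------------------------------------------


def _pocock_status_matrix(X, d, t1, tau):
    h = np.minimum(np.minimum.outer(X, X), tau)
    d_i, d_j = d[:, None], d[None, :]
    t_i, t_j = t1[:, None], t1[None, :]
    alive = np.minimum(d_i, d_j) > h
    win = ((d_j <= h) & (d_j < d_i)) | (alive & (t_j <= h) & (t_j < t_i))
    return win


def _tfe_status_matrix(X, d, t1, tau):
    h = np.minimum(np.minimum.outer(X, X), tau)
    c = np.minimum(d, t1)
    return (c[None, :] <= h) & (c[None, :] < c[:, None])


_STATUS_MATRIX = {"pocock": _pocock_status_matrix, "tfe": _tfe_status_matrix}


def pair_table(dataset, idx: np.ndarray, rule, tau: float):
    """Determinate within-stratum pairs for the subjects in ``idx``.

    Returns ``(ii, jj, w)``: local pair indices with ii < jj and the win
    indicator w = delta_{ii, jj}(tau).  Indeterminate pairs are dropped —
    they contribute nothing to the estimating function or the variances.
    """
    name = rule if isinstance(rule, str) else None
    if name in _STATUS_MATRIX:
        X = dataset.followup[idx]
        d = dataset.death_time[idx]
        t1 = dataset.first_nonfatal[idx]
        win = _STATUS_MATRIX[name](X, d, t1, tau)
        iu, ju = np.triu_indices(len(idx), k=1)
        wij = win[iu, ju]
        wji = win[ju, iu]
        det = wij | wji
        return iu[det], ju[det], wij[det].astype(float)
    # generic scalar path (recurrent rule or user-supplied callables)
    func = get_rule(rule)
    recs = [dataset.record(int(i)) for i in idx]
    ii, jj, w = [], [], []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            pc = func(recs[i], recs[j], tau)
            if pc.determinate:
                ii.append(i)
                jj.append(j)
                w.append(float(pc.delta_ij))
    return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int), np.asarray(w)


def pair_histories(dataset, idx: np.ndarray, rule, tau: float):
    """Piecewise status histories of the determinate within-stratum pairs.

    Returns ``(ii, jj, changes)`` where ``changes`` is a list of
    ``(time, delta_ij)`` jumps per pair, in increasing time order.  The
    status starts at (0, 0) and takes value ``delta_ij`` (with
    ``delta_ji = 1 - delta_ij``) from each jump time onward.

    Under the prioritized death-first rule a pair can jump at most twice: a
    first-nonfatal comparison can decide it early, and the first death
    before the pair horizon can overturn that decision (death outranks
    nonfatal events), after which the status is frozen.
    """
    name = rule if isinstance(rule, str) else None
    if name == "pocock":
        iu, ju = np.triu_indices(len(idx), k=1)
        g = idx
        X = dataset.followup[g]
        d = dataset.death_time[g]
        t1 = dataset.first_nonfatal[g]
        H = np.minimum(np.minimum(X[iu], X[ju]), tau)
        di, dj = d[iu], d[ju]
        ti, tj = t1[iu], t1[ju]
        td = np.minimum(di, dj)
        has_death = (td <= H) & (di != dj)
        dwin = (dj < di).astype(float)  # i wins when j dies first
        tn = np.minimum(ti, tj)
        has_nf = (tn <= H) & (tn < td) & (ti != tj)
        nwin = (tj < ti).astype(float)
        det = has_death | has_nf
        ii, jj, changes = [], [], []
        for k in np.flatnonzero(det):
            seg = []
            if has_nf[k]:
                seg.append((float(tn[k]), float(nwin[k])))
            if has_death[k] and (not has_nf[k] or dwin[k] != nwin[k]):
                seg.append((float(td[k]), float(dwin[k])))
            ii.append(iu[k])
            jj.append(ju[k])
            changes.append(seg)
        return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int), changes
    # generic path: probe just past every jump time
    func = get_rule(rule)
    recs = [dataset.record(int(i)) for i in idx]
    ii, jj, changes = [], [], []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            jumps = [t for t in win_jump_times(recs[i], recs[j], rule) if t < tau]
            seg = []
            prev = None
            for t in jumps:
                pc = func(recs[i], recs[j], np.nextafter(t, inf))
                if pc.determinate and (prev is None or pc.delta_ij != prev):
                    seg.append((float(t), float(pc.delta_ij)))
                    prev = pc.delta_ij
            final = func(recs[i], recs[j], tau)
            if final.determinate:
                ii.append(i)
                jj.append(j)
                changes.append(seg)
    return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int), changes
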