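"""Win-rule unit and property tests: the comparison axioms and hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stratwin import (
    Dataset,
    pocock_win,
    recurrent_win,
    tfe_win,
    win_jump_times,
)
from stratwin.wins import WIN_RULES, get_rule, pair_table

from conftest import make_record, random_record


# ---------------------------------------------------------------------------
# hand-oracle examples
# ---------------------------------------------------------------------------


class TestPocock:
    def test_earlier_death_loses(self):
        a = make_record(id="a", followup=3, death=True)
        b = make_record(id="b", followup=2, death=True)
        pc = pocock_win(a, b, 5)
        assert (pc.delta_ij, pc.delta_ji) == (1, 0)

    def test_identical_records_tie(self):
        a = make_record(id="a", followup=4, death=True, events=(1.0,))
        b = make_record(id="b", followup=4, death=True, events=(1.0,))
        pc = pocock_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (0, 0)

    def test_nonfatal_decides_when_both_alive(self):
        # a censored at 4 with no events; b had a nonfatal event at 1
        a = make_record(id="a", followup=4)
        b = make_record(id="b", followup=4, events=(1.0,))
        pc = pocock_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (1, 0)

    def test_death_outranks_nonfatal(self):
        # b dies; a merely had an early nonfatal event
        a = make_record(id="a", followup=6, events=(0.5,))
        b = make_record(id="b", followup=3, death=True)
        pc = pocock_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (1, 0)

    def test_death_at_pair_horizon_counts(self):
        # b dies at b's follow-up end, within a's observation: a win for a
        a = make_record(id="a", followup=5)
        b = make_record(id="b", followup=2, death=True)
        pc = pocock_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (1, 0)

    def test_death_beyond_pair_horizon_is_invisible(self):
        # a censored at 1; b's death at 2 is outside the shared window
        a = make_record(id="a", followup=1)
        b = make_record(id="b", followup=2, death=True)
        pc = pocock_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (0, 0)

    def test_negative_horizon_rejected(self):
        a, b = make_record(id="a"), make_record(id="b")
        with pytest.raises(ValueError):
            pocock_win(a, b, -1.0)


class TestTFE:
    def test_earlier_composite_event_loses(self):
        a = make_record(id="a", followup=5, death=True)
        b = make_record(id="b", followup=2, death=True)
        assert tfe_win(a, b, 10).delta_ij == 1
        # nonfatal and death count alike
        a2 = make_record(id="a2", followup=6, events=(5.0,))
        b2 = make_record(id="b2", followup=6, events=(2.0,))
        assert tfe_win(a2, b2, 10).delta_ij == 1

    def test_censored_before_any_event_is_indeterminate(self):
        a = make_record(id="a", followup=3)
        b = make_record(id="b", followup=4)
        pc = tfe_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (0, 0)

    def test_event_after_shared_horizon_not_used(self):
        # a's composite at 2, b's at 5, but the pair horizon is 3:
        # a's event is observed, b's is not -> a loses
        a = make_record(id="a", followup=3, events=(2.0,))
        b = make_record(id="b", followup=7, events=(5.0,))
        pc = tfe_win(a, b, 3)
        assert (pc.delta_ij, pc.delta_ji) == (0, 1)


class TestRecurrent:
    def test_fewer_events_wins(self):
        a = make_record(id="a", followup=10, events=(1.0,))
        b = make_record(id="b", followup=10, events=(1.0, 2.0, 3.0))
        pc = recurrent_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (1, 0)

    def test_equal_counts_equal_latest_tie(self):
        a = make_record(id="a", followup=10, events=(1.0, 4.0))
        b = make_record(id="b", followup=10, events=(2.0, 4.0))
        pc = recurrent_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (0, 0)

    def test_tied_counts_later_latest_loses(self):
        a = make_record(id="a", followup=10, events=(1.0, 3.0))
        b = make_record(id="b", followup=10, events=(1.0, 5.0))
        pc = recurrent_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (1, 0)

    def test_death_outranks_counts(self):
        a = make_record(id="a", followup=9, events=(1.0, 2.0, 3.0, 4.0))
        b = make_record(id="b", followup=5, death=True)
        pc = recurrent_win(a, b, 10)
        assert (pc.delta_ij, pc.delta_ji) == (1, 0)


def test_unknown_rule_name_rejected():
    with pytest.raises(ValueError, match="unknown win rule"):
        get_rule("bogus")


# ---------------------------------------------------------------------------
# properties (A1)-(A3) on fuzzed pairs
# ---------------------------------------------------------------------------

RULES = sorted(WIN_RULES)


@pytest.mark.parametrize("rule", RULES)
@given(seed=st.integers(0, 10_000), t=st.floats(0.0, 12.0))
@settings(max_examples=120, deadline=None)
def test_antisymmetry_at_most_one_winner(rule, seed, t):
    """(A2): delta_ij + delta_ji is 0 or 1 for every rule and horizon."""
    rng = np.random.default_rng(seed)
    a, b = random_record(rng, id="a"), random_record(rng, id="b")
    pc = WIN_RULES[rule](a, b, t)
    qc = WIN_RULES[rule](b, a, t)
    assert pc.delta_ij + pc.delta_ji in (0, 1)
    # evaluating in either order gives mirrored statuses
    assert (pc.delta_ij, pc.delta_ji) == (qc.delta_ji, qc.delta_ij)


@pytest.mark.parametrize("rule", RULES)
@given(seed=st.integers(0, 10_000))
@settings(max_examples=80, deadline=None)
def test_terminal_freeze(rule, seed):
    """(A3): beyond both subjects' terminal times the status is constant."""
    rng = np.random.default_rng(seed)
    a, b = random_record(rng, id="a"), random_record(rng, id="b")
    tmax = max(a.followup_time, b.followup_time)
    ref = WIN_RULES[rule](a, b, tmax)
    for t in (tmax + 0.5, 2 * tmax + 1, 1e6):
        pc = WIN_RULES[rule](a, b, t)
        assert (pc.delta_ij, pc.delta_ji) == (ref.delta_ij, ref.delta_ji)


@pytest.mark.parametrize("rule", RULES)
@given(seed=st.integers(0, 10_000), t=st.floats(0.1, 10.0))
@settings(max_examples=80, deadline=None)
def test_comparison_ignores_future_data(rule, seed, t):
    """(A1): editing events after the evaluation horizon changes nothing."""
    rng = np.random.default_rng(seed)
    a, b = random_record(rng, id="a"), random_record(rng, id="b")
    ref = WIN_RULES[rule](a, b, t)

    # anything recorded strictly after t is unseen at t: drop those events
    # and push the (unobserved-by-t) terminal time to an arbitrary later one
    def truncate(r):
        if r.followup_time > t:
            return make_record(
                id=r.id,
                followup=t + 3.0,
                death=False,
                events=[e for e in r.nonfatal_times if e <= t],
                z=r.covariates,
            )
        return r

    pc = WIN_RULES[rule](truncate(a), truncate(b), t)
    assert (pc.delta_ij, pc.delta_ji) == (ref.delta_ij, ref.delta_ji)


@given(seed=st.integers(0, 10_000), t1=st.floats(0.0, 12.0), t2=st.floats(0.0, 12.0))
@settings(max_examples=80, deadline=None)
def test_tfe_status_monotone_in_horizon(seed, t1, t2):
    """For the first-composite-event rule, a determined status never reverts."""
    rng = np.random.default_rng(seed)
    a, b = random_record(rng, id="a"), random_record(rng, id="b")
    lo, hi = min(t1, t2), max(t1, t2)
    early, late = tfe_win(a, b, lo), tfe_win(a, b, hi)
    assert late.delta_ij >= early.delta_ij
    assert late.delta_ji >= early.delta_ji


def test_pocock_nonfatal_win_overturned_by_death():
    """Death priority can reverse an earlier first-nonfatal decision."""
    a = make_record(id="a", followup=10, events=())      # alive, no events
    b = make_record(id="b", followup=10, events=(1.0,))  # early nonfatal
    assert pocock_win(a, b, 3).delta_ij == 1             # a ahead at t=3
    a2 = make_record(id="a2", followup=5, death=True)    # ... but a dies at 5
    assert pocock_win(a2, b, 3).delta_ij == 1
    pc = pocock_win(a2, b, 8)
    assert (pc.delta_ij, pc.delta_ji) == (0, 1)          # overturned


@given(seed=st.integers(0, 10_000))
@settings(max_examples=60, deadline=None)
def test_pocock_death_decision_is_absorbing(seed):
    """Once a pair is decided by a death, later horizons never change it."""
    rng = np.random.default_rng(seed)
    a, b = random_record(rng, id="a"), random_record(rng, id="b")
    hmax = min(a.followup_time, b.followup_time)
    d = [
        r.followup_time
        for r in (a, b)
        if r.death_observed and r.followup_time <= hmax
    ]
    if not d:
        return
    td = min(d)
    base = pocock_win(a, b, np.nextafter(td, np.inf))
    if not base.determinate:
        return
    for t in np.linspace(td + 1e-6, hmax + 5, 7):
        pc = pocock_win(a, b, float(t))
        assert (pc.delta_ij, pc.delta_ji) == (base.delta_ij, base.delta_ji)


# ---------------------------------------------------------------------------
# jump times and vectorized agreement
# ---------------------------------------------------------------------------


def test_jump_times_examples():
    a = make_record(id="a", followup=3, death=True)
    b = make_record(id="b", followup=2, death=True)
    assert list(win_jump_times(a, b, "pocock")) == [2.0]
    c = make_record(id="c", followup=4, death=True, events=(1.0,))
    d = make_record(id="d", followup=4, death=True, events=(1.0,))
    assert len(win_jump_times(c, d, "pocock")) == 0


@pytest.mark.parametrize("rule", RULES)
@given(seed=st.integers(0, 5_000))
@settings(max_examples=60, deadline=None)
def test_piecewise_constant_between_jumps(rule, seed):
    """Statuses on a dense grid only change at the reported jump times."""
    rng = np.random.default_rng(seed)
    a, b = random_record(rng, id="a"), random_record(rng, id="b")
    jumps = list(win_jump_times(a, b, rule))
    tmax = min(a.followup_time, b.followup_time) + 1.0
    grid = np.linspace(1e-6, tmax, 160)
    prev = (0, 0)
    prev_t = 0.0
    for t in grid:
        pc = WIN_RULES[rule](a, b, float(t))
        cur = (pc.delta_ij, pc.delta_ji)
        if cur != prev:
            assert any(prev_t < j <= t for j in jumps), (
                f"status changed in ({prev_t}, {t}] with no jump recorded"
            )
        prev, prev_t = cur, t
    # conversely, every jump is visible on a fine enough probe
    for j in jumps:
        before = WIN_RULES[rule](a, b, max(j - 1e-7, 0.0))
        after = WIN_RULES[rule](a, b, j + 1e-7)
        assert (before.delta_ij, before.delta_ji) != (after.delta_ij, after.delta_ji)


@pytest.mark.parametrize("rule", ["pocock", "tfe"])
def test_vectorized_pair_table_matches_scalar(rule, rng):
    """The matrix fast path agrees with the scalar rule, pair by pair."""
    n = 40
    recs = [random_record(rng, id=i) for i in range(n)]
    ds = Dataset.from_records(recs)
    tau = ds.tau
    ii, jj, w = pair_table(ds, np.arange(n), rule, tau)
    fast = {(int(i), int(j)): wv for i, j, wv in zip(ii, jj, w)}
    func = WIN_RULES[rule]
    for i in range(n):
        for j in range(i + 1, n):
            pc = func(recs[i], recs[j], tau)
            if pc.determinate:
                assert fast.get((i, j)) == float(pc.delta_ij)
            else:
                assert (i, j) not in fast
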