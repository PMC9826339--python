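import numpy as np
import pytest

from stratwin import Dataset, SubjectRecord
from stratwin.simulation import gen_three_strata


def make_record(
    id="s",
    stratum="a",
    followup=10.0,
    death=False,
    events=(),
    z=(0.0,),
):
    return SubjectRecord(
        id=id,
        stratum=stratum,
        followup_time=followup,
        death_observed=death,
        nonfatal_times=tuple(events),
        covariates=tuple(z),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset(rng):
    """Moderate three-stratum dataset for fit/variance/diagnostics tests."""
    return gen_three_strata(150, rng=rng)


@pytest.fixture
def two_group_dataset(rng):
    """Single stratum, binary covariate: the two-sample win-ratio setting."""
    n = 60
    z = rng.binomial(1, 0.5, n).astype(float)
    d = rng.exponential(5.0, n) * np.exp(-0.4 * z)
    t = rng.exponential(0.8, n) * np.exp(-0.4 * z)
    c = rng.uniform(0, 6.0, n)
    x = np.minimum(d, c)
    events = [np.array([tt]) if tt <= xx else np.empty(0) for tt, xx in zip(t, x)]
    return Dataset(
        ids=np.arange(n),
        stratum=np.zeros(n, dtype=int),
        Z=z[:, None],
        followup=x,
        death_observed=d <= c,
        events=events,
        covariate_names=["z"],
    )


def random_record(rng, id=0, stratum="a", p=1):
    """Fuzzed subject: random censoring, death and up to 3 nonfatal events."""
    followup = float(rng.uniform(0.2, 8.0))
    death = bool(rng.random() < 0.5)
    k = rng.integers(0, 4)
    events = np.sort(rng.uniform(0.0, followup, size=k))
    return SubjectRecord(
        id=id,
        stratum=stratum,
        followup_time=followup,
        death_observed=death,
        nonfatal_times=tuple(float(e) for e in events),
        covariates=tuple(rng.standard_normal(p)),
    )
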