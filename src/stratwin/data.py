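"""Subject-level data containers and long-format CSV ingestion.

The analysis unit is a subject followed until death or censoring, possibly
experiencing nonfatal events (e.g. hospitalizations) along the way.  Subjects
belong to strata (sex, study center, matched pair, ...) and pairwise win/loss
comparisons are only ever made within a stratum.

Status coding in the long format: 0 = censoring, 1 = death, 2 = nonfatal
event.  Each subject contributes one row per nonfatal event plus exactly one
terminal row (death or censoring) whose time is the follow-up time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CENSOR = 0
DEATH = 1
NONFATAL = 2


class ValidationError(ValueError):
    """Raised when input data violate the long-format contract."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's observed outcome history.

    ``followup_time`` is X = min(death, censoring); if ``death_observed`` the
    subject died exactly at ``followup_time``.  ``nonfatal_times`` are the
    ordered jump times of the (single-type) nonfatal counting process, all at
    or before X.
    """

    id: object
    stratum: object
    followup_time: float
    death_observed: bool
    nonfatal_times: tuple[float, ...] = ()
    covariates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (self.followup_time >= 0):
            raise ValidationError(f"subject {self.id}: negative follow-up time")
        if any(t > self.followup_time for t in self.nonfatal_times):
            raise ValidationError(
                f"subject {self.id}: nonfatal event after follow-up time"
            )
        if list(self.nonfatal_times) != sorted(self.nonfatal_times):
            raise ValidationError(f"subject {self.id}: nonfatal times not ordered")
        if any(not math.isfinite(z) for z in self.covariates):
            raise ValidationError(f"subject {self.id}: non-finite covariate")

    @property
    def death_time(self) -> float:
        """Observed death time, +inf if death was not observed."""
        return self.followup_time if self.death_observed else math.inf

    @property
    def first_nonfatal(self) -> float:
        """First nonfatal event time, +inf if none observed."""
        return self.nonfatal_times[0] if self.nonfatal_times else math.inf

    @property
    def first_composite(self) -> float:
        """Time to first composite event (death or nonfatal), +inf if none."""
        return min(self.death_time, self.first_nonfatal)


class Dataset:
    """A stratified cohort held as column arrays.

    Parameters
    ----------
    ids, stratum : sequences of opaque labels, one per subject.
    Z : (n, p) covariate matrix.
    followup, death_observed : follow-up time X and death indicator I(D <= C).
    events : per-subject sorted arrays of nonfatal event times (<= X).
    covariate_names : labels for the columns of Z.
    tau : analysis horizon; defaults to the maximum follow-up time.
    """

    def __init__(
        self,
        ids: Sequence,
        stratum: Sequence,
        Z: np.ndarray,
        followup: np.ndarray,
        death_observed: np.ndarray,
        events: Sequence[np.ndarray] | None = None,
        covariate_names: Sequence[str] | None = None,
        tau: float | None = None,
    ):
        self.ids = np.asarray(ids, dtype=object)
        self.stratum = np.asarray(stratum, dtype=object)
        self.Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if self.Z.shape[0] != len(self.ids) and self.Z.shape[1] == len(self.ids):
            self.Z = self.Z.T
        self.followup = np.asarray(followup, dtype=float)
        self.death_observed = np.asarray(death_observed, dtype=bool)
        n = len(self.ids)
        if events is None:
            events = [np.empty(0) for _ in range(n)]
        self.events = [np.asarray(e, dtype=float) for e in events]
        p = self.Z.shape[1]
        if covariate_names is None:
            covariate_names = [f"z{k + 1}" for k in range(p)]
        self.covariate_names = list(covariate_names)
        self._validate()
        self.tau = float(tau) if tau is not None else float(self.followup.max())

    def _validate(self) -> None:
        n = self.n
        if n == 0:
            raise ValidationError("empty dataset")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate subject ids")
        for arr, name in [
            (self.stratum, "stratum"),
            (self.followup, "followup"),
            (self.death_observed, "death_observed"),
        ]:
            if len(arr) != n:
                raise ValidationError(f"{name} length mismatch")
        if self.Z.shape != (n, len(self.covariate_names)):
            raise ValidationError("covariate matrix shape mismatch")
        if not np.all(np.isfinite(self.Z)):
            raise ValidationError("non-finite covariates")
        if np.any(self.followup < 0):
            bad = self.ids[self.followup < 0]
            raise ValidationError(f"negative follow-up for ids {list(bad)}")
        for i, e in enumerate(self.events):
            if e.size and (e[-1] > self.followup[i] or np.any(np.diff(e) < 0)):
                raise ValidationError(
                    f"subject {self.ids[i]}: event times exceed follow-up "
                    "or are unordered"
                )

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def death_time(self) -> np.ndarray:
        """Observed death times; +inf where death was censored."""
        d = np.where(self.death_observed, self.followup, np.inf)
        return d

    @property
    def first_nonfatal(self) -> np.ndarray:
        return np.array(
            [e[0] if e.size else np.inf for e in self.events], dtype=float
        )

    def strata(self) -> dict[object, np.ndarray]:
        """Mapping stratum label -> subject index array (insertion order)."""
        codes, labels = pd.factorize(self.stratum)
        return {lab: np.flatnonzero(codes == k) for k, lab in enumerate(labels)}

    def record(self, i: int) -> SubjectRecord:
        return SubjectRecord(
            id=self.ids[i],
            stratum=self.stratum[i],
            followup_time=float(self.followup[i]),
            death_observed=bool(self.death_observed[i]),
            nonfatal_times=tuple(self.events[i]),
            covariates=tuple(self.Z[i]),
        )

    def __iter__(self) -> Iterator[SubjectRecord]:
        return (self.record(i) for i in range(self.n))

    def __len__(self) -> int:
        return self.n

    # -- construction ----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[SubjectRecord],
        covariate_names: Sequence[str] | None = None,
        tau: float | None = None,
    ) -> "Dataset":
        records = list(records)
        return cls(
            ids=[r.id for r in records],
            stratum=[r.stratum for r in records],
            Z=np.array([r.covariates for r in records], dtype=float),
            followup=np.array([r.followup_time for r in records]),
            death_observed=np.array([r.death_observed for r in records]),
            events=[np.asarray(r.nonfatal_times) for r in records],
            covariate_names=covariate_names,
            tau=tau,
        )

    # -- long format I/O -------------------------------------------------

    @classmethod
    def from_long_frame(
        cls,
        frame: pd.DataFrame,
        covariates: Sequence[str],
        id_col: str = "id",
        stratum_col: str = "stratum",
        time_col: str = "time",
        status_col: str = "status",
        tau: float | None = None,
    ) -> "Dataset":
        """Collapse a long-format event table into a Dataset.

        Each subject must have exactly one terminal row (status 0 or 1) at
        its largest time; nonfatal rows (status 2) must not come after it.
        """
        needed = [id_col, stratum_col, time_col, status_col, *covariates]
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        bad_status = ~frame[status_col].isin([CENSOR, DEATH, NONFATAL])
        if bad_status.any():
            ids = sorted(set(frame.loc[bad_status, id_col]))
            raise ValidationError(f"unknown status codes for ids {ids}")

        records = []
        for sid, g in frame.groupby(id_col, sort=False):
            g = g.sort_values(time_col, kind="stable")
            terminal = g[g[status_col] != NONFATAL]
            if len(terminal) != 1:
                raise ValidationError(
                    f"subject {sid}: expected exactly one terminal row, "
                    f"found {len(terminal)}"
                )
            term = terminal.iloc[0]
            nonfatal = g.loc[g[status_col] == NONFATAL, time_col].to_numpy()
            if nonfatal.size and nonfatal.max() > term[time_col]:
                raise ValidationError(
                    f"subject {sid}: nonfatal event after terminal time"
                )
            zvals = g[list(covariates)].iloc[0]
            if g[list(covariates)].nunique().max() > 1:
                raise ValidationError(
                    f"subject {sid}: covariates vary across rows"
                )
            records.append(
                SubjectRecord(
                    id=sid,
                    stratum=term[stratum_col],
                    followup_time=float(term[time_col]),
                    death_observed=bool(term[status_col] == DEATH),
                    nonfatal_times=tuple(np.sort(nonfatal)),
                    covariates=tuple(float(zvals[c]) for c in covariates),
                )
            )
        return cls.from_records(records, covariate_names=list(covariates), tau=tau)

    def to_long_frame(
        self,
        id_col: str = "id",
        stratum_col: str = "stratum",
        time_col: str = "time",
        status_col: str = "status",
    ) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            base = {
                id_col: self.ids[i],
                stratum_col: self.stratum[i],
                **{c: self.Z[i, k] for k, c in enumerate(self.covariate_names)},
            }
            for t in self.events[i]:
                rows.append({**base, time_col: t, status_col: NONFATAL})
            rows.append(
                {
                    **base,
                    time_col: self.followup[i],
                    status_col: DEATH if self.death_observed[i] else CENSOR,
                }
            )
        cols = [id_col, stratum_col, time_col, status_col, *self.covariate_names]
        return pd.DataFrame(rows)[cols]


def read_long_format(
    path,
    covariates: Sequence[str],
    column_map: Mapping[str, str] | None = None,
    tau: float | None = None,
) -> Dataset:
    """Read a long-format CSV file into a :class:`Dataset`.

    ``column_map`` may rename the standard columns, e.g.
    ``{"id": "patid", "time": "years"}``.
    """
    cmap = {"id": "id", "stratum": "stratum", "time": "time", "status": "status"}
    if column_map:
        cmap.update(column_map)
    frame = pd.read_csv(path)
    return Dataset.from_long_frame(
        frame,
        covariates=covariates,
        id_col=cmap["id"],
        stratum_col=cmap["stratum"],
        time_col=cmap["time"],
        status_col=cmap["status"],
        tau=tau,
    )


def write_long_format(dataset: Dataset, path) -> None:
    dataset.to_long_frame().to_csv(path, index=False)
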