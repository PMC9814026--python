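"""Survival data containers, CSV input and risk-set indexing.

The data model is one row per observation: a group identifier (groups share
a frailty), an observed time ``y = min(t, c)``, an event indicator
``d`` (1 = event, 0 = right-censored), any number of covariate columns and
optional planar coordinates.  Tied event times are handled with the Breslow
convention throughout: tied events share the full common risk set, and
censored observations at an event time belong to that event's risk set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Schema",
    "SurvivalRecord",
    "SurvivalDataset",
    "RiskSetIndex",
    "read_dataset",
    "dataset_from_frame",
    "build_risk_sets",
    "load_kidney",
]


@dataclass(frozen=True)
class Schema:
    """Column-name mapping for tabular survival input."""

    time: str = "time"
    event: str = "status"
    group: str = "group"
    coord_x: str = "coord_x"
    coord_y: str = "coord_y"


class SurvivalRecord(NamedTuple):
    group_id: object
    within_group_index: int
    time: float
    event: int
    covariates: dict


class SurvivalDataError(ValueError):
    pass


@dataclass
class SurvivalDataset:
    """Validated survival data in canonical (input) observation order.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per observation, original order preserved.
    times, events : ndarray
        Observed times ``y_ij`` and event indicators ``d_ij``.
    group_codes : ndarray of int
        Dense group index in ``0..n_groups-1``, assigned in order of first
        appearance of each group id.
    group_ids : list
        Original group identifiers, one per dense code.
    covariate_names : list of str
        All columns that are neither time, event, group nor coordinates.
    coords : ndarray of shape (N, 2) or None
    """

    frame: pd.DataFrame
    times: np.ndarray
    events: np.ndarray
    group_codes: np.ndarray
    group_ids: list
    covariate_names: list
    coords: np.ndarray | None = None
    schema: Schema = field(default_factory=Schema)

    @property
    def total(self) -> int:
        return len(self.times)

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_codes, minlength=self.n_groups)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def covariate(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    @property
    def records(self) -> list[SurvivalRecord]:
        within = np.zeros(self.total, dtype=int)
        seen: dict = {}
        for i, g in enumerate(self.group_codes):
            seen[g] = seen.get(g, 0) + 1
            within[i] = seen[g]
        return [
            SurvivalRecord(
                group_id=self.group_ids[self.group_codes[i]],
                within_group_index=int(within[i]),
                time=float(self.times[i]),
                event=int(self.events[i]),
                covariates={c: self.frame[c].iloc[i] for c in self.covariate_names},
            )
            for i in range(self.total)
        ]

    def validate(self) -> None:
        if self.total == 0:
            raise SurvivalDataError("dataset contains no observations")
        bad_t = np.where(~(self.times > 0))[0]
        if bad_t.size:
            raise SurvivalDataError(
                f"non-positive time at row {bad_t[0]}: {self.times[bad_t[0]]!r}"
            )
        bad_d = np.where(~np.isin(self.events, (0, 1)))[0]
        if bad_d.size:
            raise SurvivalDataError(
                f"event indicator not in {{0,1}} at row {bad_d[0]}: "
                f"{self.events[bad_d[0]]!r}"
            )
        if int(self.group_sizes.sum()) != self.total:
            raise SurvivalDataError("group sizes do not sum to total")


def dataset_from_frame(df: pd.DataFrame, schema: Schema | None = None) -> SurvivalDataset:
    """Build a validated :class:`SurvivalDataset` from a DataFrame."""
    schema = schema or Schema()
    for col in (schema.time, schema.event, schema.group):
        if col not in df.columns:
            raise SurvivalDataError(f"missing required column {col!r}")
    df = df.reset_index(drop=True)
    times = df[schema.time].to_numpy(dtype=float)
    events = df[schema.event].to_numpy()
    # group ids may be arbitrary; dense codes in first-appearance order
    raw = df[schema.group].tolist()
    ids: list = []
    index: dict = {}
    codes = np.empty(len(raw), dtype=int)
    for i, g in enumerate(raw):
        if g not in index:
            index[g] = len(ids)
            ids.append(g)
        codes[i] = index[g]
    coords = None
    reserved = {schema.time, schema.event, schema.group}
    if schema.coord_x in df.columns and schema.coord_y in df.columns:
        coords = df[[schema.coord_x, schema.coord_y]].to_numpy(dtype=float)
        reserved |= {schema.coord_x, schema.coord_y}
    covars = [c for c in df.columns if c not in reserved]
    try:
        events_f = np.asarray(events, dtype=float)
    except (TypeError, ValueError) as exc:
        raise SurvivalDataError(f"non-numeric event column: {exc}") from exc
    events = events_f.astype(int)
    if np.any(events != events_f):
        bad = int(np.flatnonzero(events != events_f)[0])
        raise SurvivalDataError(
            f"event indicator not in {{0,1}} at row {bad}: {events_f[bad]!r}")
    ds = SurvivalDataset(
        frame=df,
        times=times,
        events=events,
        group_codes=codes,
        group_ids=ids,
        covariate_names=covars,
        coords=coords,
        schema=schema,
    )
    ds.validate()
    return ds


def read_dataset(path, schema: Schema | None = None) -> SurvivalDataset:
    """Read a survival CSV (header required) into a :class:`SurvivalDataset`."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SurvivalDataError(f"empty input file: {path}") from exc
    return dataset_from_frame(df, schema)


def load_kidney() -> SurvivalDataset:
    """The kidney catheter infection data: 76 times for 38 patients.

    Covariates: ``age``, ``female`` and disease-type indicators
    ``GN``, ``AN``, ``PKD`` (reference level "Other").
    """
    with resources.files("coxagq.data").joinpath("kidney.csv").open() as fh:
        return read_dataset(fh)


# ---------------------------------------------------------------------------
# risk sets


@dataclass
class RiskSetIndex:
    """Risk sets encoded on the time-sorted observation array.

    ``order`` sorts records ascending in time (stable).  The risk set of an
    event at sorted position ``p`` is the contiguous span
    ``order[risk_start[e]:]`` where ``risk_start[e]`` is the first sorted
    position whose time equals the event time — so tied events (and censored
    records tied with them) all fall inside the span (Breslow).
    """

    order: np.ndarray           # input index of sorted position
    sorted_times: np.ndarray
    sorted_events: np.ndarray
    event_positions: np.ndarray  # sorted positions holding events
    risk_start: np.ndarray       # per event, start of its risk-set span
    tie_groups: list             # lists of event positions sharing a time

    @property
    def n_events(self) -> int:
        return len(self.event_positions)

    @property
    def n(self) -> int:
        return len(self.order)

    def risk_set_members(self, e: int) -> np.ndarray:
        """Input-order indices of the ``e``-th event's risk set."""
        return self.order[self.risk_start[e]:]

    def risk_set_sizes(self) -> np.ndarray:
        return self.n - self.risk_start


def build_risk_sets(data: SurvivalDataset, allow_empty: bool = False) -> RiskSetIndex:
    """Index the risk sets R_ij = {(k,l): y_kl >= y_ij} of all events.

    A dataset with no events makes the partial likelihood constant and is
    rejected unless ``allow_empty`` is set (useful for prior-only checks,
    where the log likelihood is identically zero).
    """
    if data.n_events == 0 and not allow_empty:
        raise SurvivalDataError(
            "dataset has no events: the partial likelihood is constant"
        )
    order = np.argsort(data.times, kind="stable")
    st = data.times[order]
    se = data.events[order]
    event_positions = np.flatnonzero(se == 1)
    # first sorted position sharing each event's time (ties share risk sets)
    risk_start = np.searchsorted(st, st[event_positions], side="left")
    tie_groups = []
    for t in np.unique(st[event_positions]):
        grp = event_positions[st[event_positions] == t]
        tie_groups.append(list(grp))
    return RiskSetIndex(
        order=order,
        sorted_times=st,
        sorted_events=se,
        event_positions=event_positions,
        risk_start=risk_start,
        tie_groups=tie_groups,
    )
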