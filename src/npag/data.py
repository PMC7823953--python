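"""Subject-level data containers and the flat event-record CSV dialect.

A population PK dataset is a list of :class:`Subject`, each holding dosing
events (boluses and zero-order infusions), timed concentration observations,
and per-output assay-error polynomial coefficients ``(c0, c1, c2, c3)``.

The on-disk format is one CSV row per event with columns::

    id, time, evid, out, value, dose_amount, rate, duration, compartment,
    c0, c1, c2, c3

``evid=0`` marks an observation (``out``, ``value`` and the c-coefficients
are read), ``evid=1`` a dose (``dose_amount`` for a bolus, or ``rate`` plus
``duration`` for an infusion, plus ``compartment``).  Times are in hours and
compartment indices are 0-based (0 = absorption, 1 = central, 2 = peripheral
for the built-in three-compartment model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Observation",
    "DoseEvent",
    "Subject",
    "read_dataset",
    "write_dataset",
    "DatasetError",
]

_COLUMNS = [
    "id", "time", "evid", "out", "value", "dose_amount", "rate",
    "duration", "compartment", "c0", "c1", "c2", "c3",
]


class DatasetError(ValueError):
    """Raised when an event-record file violates the dialect."""


@dataclass(frozen=True)
class Observation:
    """A single timed measurement of one model output."""

    time: float
    value: float
    output_index: int = 0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if not math.isfinite(self.value):
            raise ValueError("observation value must be finite")


@dataclass(frozen=True)
class DoseEvent:
    """A bolus (instantaneous amount) or a zero-order infusion.

    ``amount`` is the bolus amount in mg; for an infusion, ``rate`` is in
    mg/hour over ``duration`` hours starting at ``time``.
    """

    kind: str  # "bolus" | "infusion"
    time: float
    compartment: int = 0
    amount: float | None = None
    rate: float | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("bolus", "infusion"):
            raise ValueError(f"unknown dose kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.kind == "bolus":
            if self.amount is None or self.amount <= 0:
                raise ValueError("bolus requires amount > 0")
        else:
            if self.rate is None or self.rate <= 0:
                raise ValueError("infusion requires rate > 0")
            if self.duration is None or self.duration <= 0:
                raise ValueError("infusion requires duration > 0")

    @property
    def end_time(self) -> float:
        return self.time if self.kind == "bolus" else self.time + self.duration


@dataclass
class Subject:
    """One subject: dosing history, observations, assay-error coefficients.

    ``error_coeffs`` maps output index -> ``(c0, c1, c2, c3)`` of the assay
    error polynomial; a single tuple is broadcast to all outputs.
    """

    id: str
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    error_coeffs: dict[int, tuple[float, float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"subject {self.id!r} has no observations")
        self.observations = sorted(self.observations, key=lambda o: o.time)
        for c in self.error_coeffs.values():
            if len(c) != 4 or not all(math.isfinite(v) for v in c):
                raise ValueError(
                    f"subject {self.id!r}: error coefficients must be 4 finite numbers"
                )

    def coeffs_for(self, output_index: int) -> tuple[float, float, float, float]:
        if output_index in self.error_coeffs:
            return self.error_coeffs[output_index]
        if len(self.error_coeffs) == 1:
            return next(iter(self.error_coeffs.values()))
        raise KeyError(
            f"subject {self.id!r}: no error coefficients for output {output_index}"
        )

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def regimen_key(self) -> tuple:
        """Hashable signature of dosing + sampling schedule.

        Subjects sharing a key have identical model predictions for any
        parameter vector, which lets the likelihood layer evaluate the
        forward model once per unique regimen.
        """
        return (
            tuple((d.kind, d.time, d.compartment, d.amount, d.rate, d.duration)
                  for d in self.doses),
            tuple((o.time, o.output_index) for o in self.observations),
        )


def read_dataset(path) -> list[Subject]:
    """Read an event-record CSV into a list of subjects.

    Subjects appear in file order; observations are sorted by time within
    each subject.  Raises :class:`DatasetError` naming the offending line
    on malformed input.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")

    subjects: list[Subject] = []
    for sid, grp in df.groupby("id", sort=False):
        doses: list[DoseEvent] = []
        observations: list[Observation] = []
        coeffs: dict[int, tuple[float, float, float, float]] = {}
        for row in grp.itertuples():
            line = row.Index + 2  # header + 1-based
            evid = int(row.evid)
            if evid == 0:
                out = 0 if pd.isna(row.out) else int(row.out)
                if pd.isna(row.value):
                    raise DatasetError(f"{path}:{line}: observation without value")
                observations.append(Observation(float(row.time), float(row.value), out))
                cs = tuple(
                    0.0 if pd.isna(v) else float(v)
                    for v in (row.c0, row.c1, row.c2, row.c3)
                )
                prev = coeffs.setdefault(out, cs)
                if prev != cs:
                    raise DatasetError(
                        f"{path}:{line}: conflicting error coefficients for "
                        f"subject {sid} output {out}"
                    )
            elif evid == 1:
                comp = 0 if pd.isna(row.compartment) else int(row.compartment)
                try:
                    if not pd.isna(row.dose_amount):
                        doses.append(DoseEvent("bolus", float(row.time), comp,
                                               amount=float(row.dose_amount)))
                    elif not pd.isna(row.rate):
                        doses.append(DoseEvent("infusion", float(row.time), comp,
                                               rate=float(row.rate),
                                               duration=float(row.duration)))
                    else:
                        raise ValueError("dose row needs dose_amount or rate")
                except ValueError as exc:
                    raise DatasetError(f"{path}:{line}: {exc}") from exc
            else:
                raise DatasetError(f"{path}:{line}: unknown evid {evid}")
        if not observations:
            raise DatasetError(f"{path}: subject {sid} has no observations")
        subjects.append(Subject(str(sid), doses, observations, coeffs))
    return subjects


def write_dataset(subjects: list[Subject], path) -> None:
    """Write subjects back to the event-record CSV dialect.

    Doses are emitted before observations for each subject, each group in
    time order, so a write/read round trip reproduces the same structures.
    """
    rows = []
    for s in subjects:
        for d in sorted(s.doses, key=lambda d: d.time):
            rows.append({
                "id": s.id, "time": d.time, "evid": 1, "out": None,
                "value": None, "dose_amount": d.amount, "rate": d.rate,
                "duration": d.duration, "compartment": d.compartment,
                "c0": None, "c1": None, "c2": None, "c3": None,
            })
        for o in s.observations:
            c0, c1, c2, c3 = s.coeffs_for(o.output_index)
            rows.append({
                "id": s.id, "time": o.time, "evid": 0, "out": o.output_index,
                "value": o.value, "dose_amount": None, "rate": None,
                "duration": None, "compartment": None,
                "c0": c0, "c1": c1, "c2": c2, "c3": c3,
            })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
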