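"""Dose-effect tables: records, %MPE conversion, delimited-text I/O and bundled fixtures.

A dose-effect table holds one row per animal: a regimen label, the dose
administered at the injection site, and the response expressed as percent of
the maximum possible effect (%MPE).  Doses are carried internally in
nmol/site; pmol/site input is converted at the I/O boundary.

The raw response of an animal is a nociception time ``t_treated`` (seconds);
it is normalised against the mean vehicle-group time ``t_vehicle``:

    %MPE = 100 * (t_vehicle_mean - t_treated) / t_vehicle_mean

so 100 means complete suppression of nociceptive behaviour, 0 means no
effect, and negative values (hyperalgesia) are legal.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ValidationError

NMOL = "nmol/site"
PMOL = "pmol/site"
_UNITS = {NMOL: 1.0, PMOL: 1e-3}  # factor to nmol/site

#: Observation window of the nociception assay, seconds.
MAX_OBSERVATION_S = 300.0

_HEADER = ["regimen", "dose", "unit", "response", "subject_id"]


@dataclass(frozen=True)
class DoseEffectRecord:
    """One animal: dose in nmol/site and response in %MPE."""

    regimen: str
    dose: float
    response: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.dose > 0):
            raise ValidationError(
                f"dose must be > 0, got {self.dose!r} (record {self.subject_id or self.regimen})"
            )
        if not math.isfinite(self.response):
            raise ValidationError(
                f"response must be finite, got {self.response!r} "
                f"(record {self.subject_id or self.regimen})"
            )


@dataclass(frozen=True)
class DoseEffectTable:
    """Ordered per-animal dose-effect records for a single regimen.

    Invariants: all records share one regimen; at least two distinct dose
    levels; at least four records (so the slope t-test has positive degrees
    of freedom with room to spare).
    """

    records: tuple[DoseEffectRecord, ...]
    unit: str = NMOL

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.unit not in _UNITS:
            raise ValidationError(f"unknown dose unit {self.unit!r}")
        if len(self.records) < 4:
            raise ValidationError(
                f"need at least 4 records, got {len(self.records)}"
            )
        regimens = {r.regimen for r in self.records}
        if len(regimens) != 1:
            raise ValidationError(f"records mix regimens: {sorted(regimens)}")
        if len({r.dose for r in self.records}) < 2:
            raise ValidationError("need at least 2 distinct dose levels")

    @classmethod
    def from_arrays(
        cls,
        regimen: str,
        doses: Sequence[float],
        responses: Sequence[float],
        unit: str = NMOL,
    ) -> "DoseEffectTable":
        if len(doses) != len(responses):
            raise ValidationError(
                f"doses ({len(doses)}) and responses ({len(responses)}) differ in length"
            )
        recs = tuple(
            DoseEffectRecord(regimen, float(d), float(y)) for d, y in zip(doses, responses)
        )
        return cls(recs, unit=unit)

    @property
    def regimen(self) -> str:
        return self.records[0].regimen

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def doses(self) -> np.ndarray:
        return np.array([r.dose for r in self.records], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([r.response for r in self.records], dtype=float)

    @property
    def log_doses(self) -> np.ndarray:
        """log10 of dose — always recomputed, never read from a file column."""
        return np.log10(self.doses)

    @property
    def dose_levels(self) -> np.ndarray:
        return np.unique(self.doses)


@dataclass(frozen=True)
class RawNociceptionGroup:
    """Raw nociception times (s) for the vehicle group and one treated group."""

    vehicle_times: tuple[float, ...]
    treated_times: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vehicle_times", tuple(self.vehicle_times))
        object.__setattr__(self, "treated_times", tuple(self.treated_times))
        if not self.vehicle_times:
            raise ValidationError("vehicle group is empty")
        for label, times in (("vehicle", self.vehicle_times), ("treated", self.treated_times)):
            for i, t in enumerate(times):
                if not (0.0 <= t <= MAX_OBSERVATION_S):
                    raise ValidationError(
                        f"{label} time #{i + 1} = {t} s outside [0, {MAX_OBSERVATION_S:g}] s"
                    )
        if not np.mean(self.vehicle_times) > 0:
            raise ValidationError("vehicle mean must be strictly positive")


def compute_mpe(group: RawNociceptionGroup) -> list[float]:
    """Percent of maximum possible effect for each treated animal.

    ``100 * (vehicle_mean - treated) / vehicle_mean``; 100 when the treated
    time is 0, 0 when it equals the vehicle mean, negative when it exceeds it.
    """
    vehicle_mean = float(np.mean(group.vehicle_times))
    return [100.0 * (vehicle_mean - t) / vehicle_mean for t in group.treated_times]


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# Dialect: comma-separated, header "regimen,dose,unit,response[,subject_id]",
# '#' starts a comment line, decimal point, no thousands separators.
# ---------------------------------------------------------------------------

def _parse_rows(lines: Iterable[str], source: str) -> DoseEffectTable:
    reader = csv.reader(
        line for line in lines if line.strip() and not line.lstrip().startswith("#")
    )
    try:
        header = [h.strip().lower() for h in next(reader)]
    except StopIteration:
        raise ValidationError(f"{source}: empty file") from None
    for col in ("regimen", "dose", "response"):
        if col not in header:
            raise ValidationError(f"{source}: missing required column {col!r}")
    idx = {name: header.index(name) for name in header}

    records: list[DoseEffectRecord] = []
    units: set[str] = set()
    for rownum, row in enumerate(reader, start=2):
        try:
            dose = float(row[idx["dose"]])
            response = float(row[idx["response"]])
        except (ValueError, IndexError) as exc:
            raise ValidationError(f"{source}: row {rownum}: {exc}") from None
        unit = row[idx["unit"]].strip() if "unit" in idx else NMOL
        if unit not in _UNITS:
            raise ValidationError(f"{source}: row {rownum}: unknown unit {unit!r}")
        units.add(unit)
        subject = row[idx["subject_id"]].strip() if "subject_id" in idx and len(row) > idx["subject_id"] else None
        try:
            records.append(
                DoseEffectRecord(
                    regimen=row[idx["regimen"]].strip(),
                    dose=dose * _UNITS[unit],  # to nmol/site at the boundary
                    response=response,
                    subject_id=subject or None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{source}: row {rownum}: {exc}") from None
    if not records:
        raise ValidationError(f"{source}: no data rows")
    if len(units) > 1:
        raise ValidationError(f"{source}: records mix units {sorted(units)}")
    return DoseEffectTable(tuple(records), unit=NMOL)


def read_dose_effect(path: str | Path, format: str = "csv") -> DoseEffectTable:
    """Read a dose-effect table from delimited text.

    Doses are converted to nmol/site using each row's ``unit`` column
    (``nmol/site`` or ``pmol/site``); the returned table is always in
    nmol/site.
    """
    if format != "csv":
        raise ValidationError(f"unsupported format {format!r}")
    path = Path(path)
    with path.open(newline="") as fh:
        return _parse_rows(fh, source=str(path))


def write_dose_effect(table: DoseEffectTable, path: str | Path) -> None:
    """Write a table in the canonical dialect.  Round-trips exactly:
    floats are rendered with :func:`repr`, which is lossless for binary64."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for r in table.records:
            writer.writerow([r.regimen, repr(r.dose), table.unit, repr(r.response), r.subject_id or ""])


# ---------------------------------------------------------------------------
# Bundled fixtures (per-animal dose-effect data shipped with the package)
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("sb_ipl", "pha_ipl", "pha_it", "combo_ipl_ipl", "combo_ipl_it")


def load_fixture(name: str) -> DoseEffectTable:
    """Load one of the curated bundled dose-effect tables.

    Names: ``sb_ipl`` (SB366791 intraplantar), ``pha_ipl`` (Phα1β
    intraplantar), ``pha_it`` (Phα1β intrathecal), ``combo_ipl_ipl`` and
    ``combo_ipl_it`` (fixed-ratio combinations; dose = composed pair total).
    Doses are authoritative; transcription corrections are commented inside
    the data files themselves.
    """
    if name not in FIXTURE_NAMES:
        raise ValidationError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}"
        )
    ref = resources.files("isobolo").joinpath(f"data/{name}.csv")
    with ref.open(newline="") as fh:
        return _parse_rows(fh, source=f"fixture:{name}")
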