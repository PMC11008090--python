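"""Data model and CSV round-trip for basket-dissolution absorbance logs.

A dissolution experiment produces two interleaved absorbance series at a
fixed wavelength: the *sample* series (aliquots of the dissolution medium,
read every few minutes with several replicate reads per aliquot) and a
sparser *reference* series (a standard solution of the drug, read
periodically to track instrumental drift).  :class:`KineticSeries` holds
both plus the protocol metadata needed downstream (vessel and aliquot
volumes for the mass balance, calibration slope for Beer's law, label dose
for normalisation).

The on-disk format is a plain CSV with a leading ``# key = value`` metadata
block and columns ``time_min, kind, rep_1..rep_k``.  Numeric values are
written repr-faithfully so that ``read(write(x)) == x`` to machine
precision.
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import NamedTuple, Sequence

__all__ = [
    "SampleKind",
    "ExperimentMeta",
    "AbsorbanceSample",
    "KineticSeries",
    "ReplicateSummary",
    "FormatError",
    "read_kinetics_csv",
    "write_kinetics_csv",
    "summarize_replicates",
]


class FormatError(ValueError):
    """Raised when an absorbance-log CSV violates the expected dialect."""


class SampleKind(str, Enum):
    SAMPLE = "sample"
    REFERENCE = "reference"


@dataclass(frozen=True)
class ExperimentMeta:
    """Protocol metadata for one dissolution run.

    Parameters
    ----------
    vessel_volume : float
        Dissolution medium volume in mL.  The bench protocol fills the
        vessel by mass (900 g of water); at room temperature this maps
        1:1 onto 900 mL.
    aliquot_volume : float
        Volume withdrawn (and replenished with fresh medium) at each
        sampling time, mL.
    wavelength : float
        Monitoring wavelength in nm.
    dose : float
        Label drug mass of the tablet, mg.
    calibration_slope : float
        Beer's-law slope (epsilon * b), AU per (mg/mL).
    sampling_interval : float
        Nominal spacing of the sample series, minutes.
    medium_mass : float
        Mass of medium actually weighed in, grams.
    """

    vessel_volume: float = 900.0
    aliquot_volume: float = 5.0
    wavelength: float = 329.0
    dose: float = 200.0
    calibration_slope: float = 2.0
    sampling_interval: float = 5.0
    medium_mass: float = 900.0

    def __post_init__(self) -> None:
        if not self.vessel_volume > 0:
            raise ValueError("vessel_volume must be > 0")
        if not (0 <= self.aliquot_volume < self.vessel_volume):
            raise ValueError("aliquot_volume must be >= 0 and < vessel_volume")
        if not self.calibration_slope > 0:
            raise ValueError("calibration_slope must be > 0")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be > 0")


@dataclass(frozen=True)
class AbsorbanceSample:
    """One timepoint: replicate absorbance reads of a single aliquot."""

    time: float
    replicates: tuple[float, ...]
    kind: SampleKind = SampleKind.SAMPLE

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicates", tuple(float(r) for r in self.replicates))
        object.__setattr__(self, "kind", SampleKind(self.kind))
        if self.time < 0:
            raise ValueError(f"sample time must be >= 0, got {self.time}")
        if not self.replicates:
            raise ValueError("replicates must be non-empty")
        if not all(math.isfinite(r) for r in self.replicates):
            raise ValueError(f"non-finite replicate at time {self.time}")


@dataclass(frozen=True)
class KineticSeries:
    """A full experiment record: sample series + reference series + metadata."""

    meta: ExperimentMeta
    samples: tuple[AbsorbanceSample, ...]
    references: tuple[AbsorbanceSample, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "references", tuple(self.references))
        times = [s.time for s in self.samples]
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise ValueError(
                    f"sample times must be strictly increasing; "
                    f"row {i} has time {times[i]} after {times[i - 1]}"
                )
        for s in self.samples:
            if s.kind is not SampleKind.SAMPLE:
                raise ValueError("samples list may only hold kind=sample entries")
        ref_times = [r.time for r in self.references]
        for i in range(1, len(ref_times)):
            if ref_times[i] < ref_times[i - 1]:
                raise ValueError("reference times must be non-decreasing")
        if times and ref_times:
            lo, hi = times[0], times[-1]
            for t in ref_times:
                if not (t == 0 or lo <= t <= hi):
                    raise ValueError(
                        f"reference time {t} outside [{lo}, {hi}] and not 0"
                    )
        for r in self.references:
            if r.kind is not SampleKind.REFERENCE:
                raise ValueError("references list may only hold kind=reference entries")

    @property
    def sample_times(self) -> tuple[float, ...]:
        return tuple(s.time for s in self.samples)

    @property
    def reference_times(self) -> tuple[float, ...]:
        return tuple(r.time for r in self.references)


class ReplicateSummary(NamedTuple):
    mean: float
    sd: float
    n: int


def summarize_replicates(sample: AbsorbanceSample) -> ReplicateSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of one aliquot's reads.

    With a single replicate the SD is undefined and reported as NaN, never 0.
    """
    reps = sample.replicates
    if not reps:
        raise ValueError("empty replicate list")
    n = len(reps)
    mean = sum(reps) / n
    sd = statistics.stdev(reps) if n > 1 else math.nan
    return ReplicateSummary(mean=mean, sd=sd, n=n)


_META_FIELDS = (
    "vessel_volume",
    "aliquot_volume",
    "wavelength",
    "dose",
    "calibration_slope",
    "sampling_interval",
    "medium_mass",
)


def write_kinetics_csv(series: KineticSeries, path: str | Path) -> Path:
    """Write a series in the dialect read by :func:`read_kinetics_csv`.

    Values are written with :func:`repr` so the round trip is bit-stable;
    rows with fewer replicates than the widest row leave trailing cells
    empty.
    """
    path = Path(path)
    rows = list(series.samples) + list(series.references)
    k = max((len(r.replicates) for r in rows), default=1)
    with path.open("w", newline="") as fh:
        for name in _META_FIELDS:
            fh.write(f"# {name} = {getattr(series.meta, name)!r}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["time_min", "kind"] + [f"rep_{i + 1}" for i in range(k)])
        for row in rows:
            cells = [repr(row.time), row.kind.value]
            cells += [repr(v) for v in row.replicates]
            cells += [""] * (k - len(row.replicates))
            writer.writerow(cells)
    return path


def read_kinetics_csv(path: str | Path) -> KineticSeries:
    """Read an absorbance log written by :func:`write_kinetics_csv`.

    Empty replicate cells are dropped per row (never zero-filled).  Errors
    name the offending column or row so a malformed log from a bench
    logger is diagnosable.
    """
    path = Path(path)
    meta_kv: dict[str, float] = {}
    with path.open(newline="") as fh:
        # leading metadata block
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                try:
                    meta_kv[key] = float(val.strip())
                except ValueError as exc:
                    raise FormatError(
                        f"unparseable metadata value for '{key}': {val.strip()!r}"
                    ) from exc
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)

        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("file has no header row") from None
        header = [h.strip() for h in header]
        for required in ("time_min", "kind"):
            if required not in header:
                raise FormatError(f"missing required column '{required}'")
        rep_cols = [i for i, h in enumerate(header) if h.startswith("rep_")]
        if not rep_cols:
            raise FormatError("missing required column 'rep_1'")
        i_time = header.index("time_min")
        i_kind = header.index("kind")

        samples: list[AbsorbanceSample] = []
        references: list[AbsorbanceSample] = []
        for rownum, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                t = float(row[i_time])
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"unparseable numeric cell at row {rownum}, column time_min: "
                    f"{row[i_time] if i_time < len(row) else '<missing>'!r}"
                ) from exc
            kind_str = row[i_kind].strip() if i_kind < len(row) else ""
            try:
                kind = SampleKind(kind_str)
            except ValueError as exc:
                raise FormatError(
                    f"unknown kind {kind_str!r} at row {rownum}"
                ) from exc
            reps: list[float] = []
            for ci in rep_cols:
                cell = row[ci].strip() if ci < len(row) else ""
                if not cell:
                    continue  # empty replicate cells dropped per row
                try:
                    reps.append(float(cell))
                except ValueError as exc:
                    raise FormatError(
                        f"unparseable numeric cell at row {rownum}, "
                        f"column {header[ci]}: {cell!r}"
                    ) from exc
            sample = AbsorbanceSample(time=t, replicates=tuple(reps), kind=kind)
            (samples if kind is SampleKind.SAMPLE else references).append(sample)

    meta = ExperimentMeta(**{k: v for k, v in meta_kv.items() if k in _META_FIELDS})
    # KineticSeries validation reports the first offending sample row
    times = [s.time for s in samples]
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise ValueError(
                f"non-monotone sample times at row index {i}: "
                f"time {times[i]} follows {times[i - 1]}"
            )
    return KineticSeries(meta=meta, samples=tuple(samples), references=tuple(references))
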