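"""Spectral data containers and CSV I/O.

The universal currency of the pipeline is the :class:`SpectralDataset`: a
shared axis (wavelength in nm or wavenumber in cm^-1, always stored strictly
increasing), a matrix of spectra (rows) and per-spectrum metadata.
Concentrations are in g solute per 100 g solvent; an unknown concentration
(e.g. a slurry supernatant after nucleation) is ``None``, never 0.

Datasets round-trip losslessly through a small CSV dialect::

    # axis_kind=wavelength_nm preprocessing=absorbance
    sample_id,concentration,temperature,time,replicate,role,<v1>,<v2>,...
    cal_c4_t50,4,50,0,1,calibration,0.0123,...

where ``v1..vp`` are the axis values in increasing order, the decimal
separator is ``.`` and an empty concentration field means "unknown".
Numbers are serialised with shortest round-trip precision (>= 12
significant digits whenever needed), so write -> read is the identity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DatasetValidationError, FormatError

WAVELENGTH_NM = "wavelength_nm"
WAVENUMBER_CM = "wavenumber_cm-1"
AXIS_KINDS = (WAVELENGTH_NM, WAVENUMBER_CM)

ROLES = ("calibration", "validation", "slurry")

#: fixed metadata columns of the CSV dialect, in order
META_COLUMNS = ("sample_id", "concentration", "temperature", "time", "replicate", "role")

TEMPERATURE_LIMITS = (-50.0, 150.0)


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


@dataclass(frozen=True)
class SpectralAxis:
    """A strictly increasing wavelength (nm) or wavenumber (cm^-1) grid."""

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in AXIS_KINDS:
            raise DatasetValidationError(
                f"axis kind must be one of {AXIS_KINDS}, got {self.kind!r}"
            )
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise DatasetValidationError("axis values must be a non-empty 1-D vector")
        if not np.all(np.isfinite(values)):
            raise DatasetValidationError("axis values must be finite")
        if values.size > 1 and not np.all(np.diff(values) > 0):
            raise DatasetValidationError("axis values must be strictly increasing")
        values = values.copy()
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.kind == other.kind and np.array_equal(self.values, other.values)

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.kind, self.values.tobytes()))

    @property
    def spacing(self) -> float:
        """Mean grid spacing (axis units per point)."""
        if len(self) < 2:
            raise DatasetValidationError("spacing undefined for a single-point axis")
        return float(np.mean(np.diff(self.values)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """Whether all spacings agree with the mean within relative tolerance."""
        if len(self) < 2:
            return True
        d = np.diff(self.values)
        h = d.mean()
        return bool(np.max(np.abs(d - h)) <= rtol * abs(h))


@dataclass(frozen=True)
class SpectrumMeta:
    """Per-spectrum metadata.

    concentration
        g solute / 100 g solvent, or ``None`` if unknown.
    temperature
        sample temperature in deg C.
    time
        acquisition time in seconds (>= 0).
    replicate
        1-based replicate index within a sample.
    role
        one of ``calibration``, ``validation``, ``slurry``.
    """

    sample_id: str
    concentration: float | None
    temperature: float
    time: float
    replicate: int
    role: str


@dataclass
class SpectralDataset:
    """Axis + intensity matrix (n_spectra x n_axis) + per-spectrum metadata.

    ``preprocessing`` is a dataset-level tag recording what the intensity
    values are (raw ``absorbance``, a Savitzky-Golay derivative, an
    LSS-corrected variant, ...); downstream models refuse to mix tags.
    """

    axis: SpectralAxis
    intensities: np.ndarray
    meta: list[SpectrumMeta]
    preprocessing: str = "absorbance"

    def __post_init__(self) -> None:
        X = np.asarray(self.intensities, dtype=float)
        if X.ndim != 2:
            raise DatasetValidationError("intensities must be a 2-D matrix")
        if X.shape[1] != len(self.axis):
            raise DatasetValidationError(
                f"intensity columns ({X.shape[1]}) != axis length ({len(self.axis)})"
            )
        if len(self.meta) != X.shape[0]:
            raise DatasetValidationError(
                f"metadata entries ({len(self.meta)}) != spectra rows ({X.shape[0]})"
            )
        self.intensities = X
        self.meta = list(self.meta)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([m.temperature for m in self.meta], dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.meta], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        """Concentrations with ``None`` mapped to NaN."""
        return np.array(
            [np.nan if m.concentration is None else m.concentration for m in self.meta],
            dtype=float,
        )

    def y(self) -> np.ndarray:
        """Known concentrations; raises if any spectrum's is unknown."""
        c = self.concentrations
        if np.any(np.isnan(c)):
            raise DatasetValidationError("dataset contains unknown concentrations")
        return c

    def subset(self, indices: Iterable[int] | np.ndarray) -> "SpectralDataset":
        """Row subset (new dataset sharing the axis and tag)."""
        idx = np.asarray(list(indices) if not isinstance(indices, np.ndarray) else indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectralDataset(
            axis=self.axis,
            intensities=self.intensities[idx].copy(),
            meta=[self.meta[int(i)] for i in idx],
            preprocessing=self.preprocessing,
        )

    def with_tag(self, tag: str) -> "SpectralDataset":
        return replace(self, preprocessing=tag)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (
            self.axis == other.axis
            and np.array_equal(self.intensities, other.intensities)
            and self.meta == other.meta
            and self.preprocessing == other.preprocessing
        )


def validate_dataset(dataset: SpectralDataset) -> list[str]:
    """Check all dataset invariants; return human-readable violations.

    Returns an empty list iff the dataset is valid.  Never raises: this is
    the reporting counterpart of the exceptions the constructors throw.
    """
    violations: list[str] = []
    X = dataset.intensities

    bad = np.argwhere(~np.isfinite(X))
    for i, j in bad:
        violations.append(f"non-finite intensity at spectrum {int(i)}, axis column {int(j)}")

    seen: dict[tuple, int] = {}
    lo, hi = TEMPERATURE_LIMITS
    for i, m in enumerate(dataset.meta):
        if m.role not in ROLES:
            violations.append(f"spectrum {i}: role {m.role!r} not in {ROLES}")
        if not (lo <= m.temperature <= hi):
            violations.append(
                f"spectrum {i}: temperature {m.temperature} outside [{lo}, {hi}] degC"
            )
        if m.time < 0:
            violations.append(f"spectrum {i}: negative time {m.time}")
        if m.replicate < 1:
            violations.append(f"spectrum {i}: replicate {m.replicate} < 1")
        if m.concentration is not None and not (m.concentration >= 0):
            violations.append(f"spectrum {i}: concentration {m.concentration} < 0")
        key = (m.sample_id, m.replicate, m.time)
        if key in seen:
            violations.append(
                f"spectrum {i}: duplicate (sample_id, replicate, time) key {key}"
                f" (first seen at spectrum {seen[key]})"
            )
        else:
            seen[key] = i
    return violations


def write_dataset(dataset: SpectralDataset, path) -> None:
    """Write a dataset in the thermocal CSV dialect (lossless round-trip)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# axis_kind={dataset.axis.kind} preprocessing={dataset.preprocessing}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(META_COLUMNS) + [_fmt(v) for v in dataset.axis.values])
        for m, row in zip(dataset.meta, dataset.intensities):
            writer.writerow(
                [
                    m.sample_id,
                    "" if m.concentration is None else _fmt(m.concentration),
                    _fmt(m.temperature),
                    _fmt(m.time),
                    str(int(m.replicate)),
                    m.role,
                ]
                + [_fmt(v) for v in row]
            )


def read_dataset(path) -> SpectralDataset:
    """Read a dataset written in the thermocal CSV dialect.

    Raises :class:`FormatError` for malformed files and
    :class:`DatasetValidationError` when the parsed content violates an
    invariant (e.g. a decreasing axis).
    """
    with open(path, "r", newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError("line 1 must be a '# axis_kind=...' comment")
        tags: dict[str, str] = {}
        for tok in first[1:].split():
            if "=" not in tok:
                raise FormatError(f"malformed header token {tok!r}")
            k, v = tok.split("=", 1)
            tags[k] = v
        if "axis_kind" not in tags:
            raise FormatError("header comment missing axis_kind")
        if tags["axis_kind"] not in AXIS_KINDS:
            raise FormatError(f"unknown axis_kind {tags['axis_kind']!r}")

        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("missing column header line") from None
        if tuple(header[: len(META_COLUMNS)]) != META_COLUMNS:
            raise FormatError(
                f"column header must start with {','.join(META_COLUMNS)}"
            )
        axis_fields = header[len(META_COLUMNS) :]
        if not axis_fields:
            raise FormatError("column header lists no axis values")
        try:
            axis_values = np.array([float(v) for v in axis_fields])
        except ValueError as exc:
            raise FormatError(f"unparseable axis value: {exc}") from None
        axis = SpectralAxis(kind=tags["axis_kind"], values=axis_values)

        p = len(axis)
        rows: list[np.ndarray] = []
        meta: list[SpectrumMeta] = []
        for lineno, rec in enumerate(reader, start=3):
            if not rec:
                continue
            if len(rec) != len(META_COLUMNS) + p:
                raise FormatError(
                    f"line {lineno}: expected {len(META_COLUMNS) + p} fields, got {len(rec)}"
                )
            try:
                conc = None if rec[1] == "" else float(rec[1])
                meta.append(
                    SpectrumMeta(
                        sample_id=rec[0],
                        concentration=conc,
                        temperature=float(rec[2]),
                        time=float(rec[3]),
                        replicate=int(rec[4]),
                        role=rec[5],
                    )
                )
                rows.append(np.array([float(v) for v in rec[len(META_COLUMNS) :]]))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: unparseable field: {exc}") from None

    intensities = np.vstack(rows) if rows else np.empty((0, p))
    dataset = SpectralDataset(
        axis=axis,
        intensities=intensities,
        meta=meta,
        preprocessing=tags.get("preprocessing", "absorbance"),
    )
    violations = validate_dataset(dataset)
    if violations:
        raise DatasetValidationError("; ".join(violations))
    return dataset
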