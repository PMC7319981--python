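"""Reading and writing spectra, annotations, and tabular records.

The package's native spectra dialect is long-format delimited text: one row
per (spectrum, m/z) sample with provenance columns, chosen for diffability.
mzML and imzML are supported read-only (a minimal built-in mzML reader and
pyimzml, respectively).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("epithelial", "stromal", "reference_stroma")
CLASS_LABELS = ("FA", "LGP", "HGP", "unknown")

_NATIVE_COLUMNS = ["case_id", "spot_id", "compartment", "class_label", "mz", "intensity"]


class SpectraIOError(ValueError):
    """Malformed input file or record."""


class SpectrumValidationError(ValueError):
    """A spectrum violates its invariants (lengths, monotone m/z, finite, >= 0)."""


@dataclass
class Spectrum:
    """One mass spectrum with provenance.

    mz is strictly increasing, intensity is finite and non-negative, and the
    two arrays have equal length >= 2. ``compartment`` identifies which tissue
    component the annotated spot was placed on; ``class_label`` is the
    case-level diagnosis (FA = fibroadenoma, LGP/HGP = low-/high-grade
    phyllodes tumor) and may be None for unlabeled data.
    """

    mz: np.ndarray
    intensity: np.ndarray
    case_id: str
    spot_id: str
    compartment: str | None = None
    class_label: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        ident = f"{self.case_id}/{self.spot_id}"
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumValidationError(f"{ident}: mz and intensity must be 1-D")
        if len(self.mz) != len(self.intensity) or len(self.mz) < 2:
            raise SpectrumValidationError(
                f"{ident}: need equal-length arrays of >= 2 samples "
                f"(got {len(self.mz)} / {len(self.intensity)})"
            )
        if not np.all(np.diff(self.mz) > 0):
            raise SpectrumValidationError(f"{ident}: mz must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise SpectrumValidationError(
                f"{ident}: intensities must be finite and >= 0"
            )
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise SpectrumValidationError(
                f"{ident}: compartment {self.compartment!r} not in {COMPARTMENTS}"
            )
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise SpectrumValidationError(
                f"{ident}: class_label {self.class_label!r} not in {CLASS_LABELS}"
            )

    @property
    def tic(self) -> float:
        """Total ion current: the sum of the intensity vector."""
        return float(self.intensity.sum())

    def with_intensity(self, intensity: np.ndarray, **extra) -> "Spectrum":
        """Copy of this spectrum with a new intensity vector, provenance kept."""
        return Spectrum(
            mz=self.mz.copy(),
            intensity=intensity,
            case_id=self.case_id,
            spot_id=self.spot_id,
            compartment=self.compartment,
            class_label=self.class_label,
            extra={**self.extra, **extra},
        )


@dataclass
class AnnotationMark:
    """A pathologist's circular annotation mark on the scanned H&E image.

    Coordinates are micrometers in slide space (origin top-left); the default
    300 um diameter matches the profiling spot size.
    """

    case_id: str
    spot_id: str
    compartment: str
    x: float
    y: float
    diameter: float = 300.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("annotation diameter must be > 0")


@dataclass
class ProfileDataset:
    """A collection of spot spectra plus a case-level study/validation split."""

    spectra: list
    partition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.spectra:
            self.partition.setdefault(s.case_id, "unassigned")
        by_case: dict[str, set] = {}
        for s in self.spectra:
            by_case.setdefault(s.case_id, set()).add(s.class_label)
        for case_id, labels in by_case.items():
            if len(labels) > 1:
                raise SpectrumValidationError(
                    f"case {case_id} carries conflicting class labels: {sorted(map(str, labels))}"
                )

    @property
    def case_ids(self) -> list:
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.case_id)
        return list(seen)

    def class_of(self, case_id: str) -> str | None:
        for s in self.spectra:
            if s.case_id == case_id:
                return s.class_label
        raise KeyError(case_id)

    def subset(self, compartment: str | None = None, split: str | None = None) -> "ProfileDataset":
        keep = [
            s
            for s in self.spectra
            if (compartment is None or s.compartment == compartment)
            and (split is None or self.partition.get(s.case_id) == split)
        ]
        part = {c: v for c, v in self.partition.items() if any(s.case_id == c for s in keep)}
        return ProfileDataset(spectra=keep, partition=part)


# ---------------------------------------------------------------------------
# native tabular dialect


def write_spectra(spectra: list, path) -> None:
    """Write spectra in the native long-format delimited dialect (CSV)."""
    frames = []
    for s in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "case_id": s.case_id,
                    "spot_id": s.spot_id,
                    "compartment": s.compartment if s.compartment is not None else "",
                    "class_label": s.class_label if s.class_label is not None else "",
                    "mz": s.mz,
                    "intensity": s.intensity,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _read_native(path) -> list:
    df = pd.read_csv(path, dtype={"case_id": str, "spot_id": str})
    missing = [c for c in _NATIVE_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraIOError(f"{path}: missing columns {missing}; expected {_NATIVE_COLUMNS}")
    out = []
    for (case_id, spot_id), grp in df.groupby(["case_id", "spot_id"], sort=False):
        comp = grp["compartment"].iloc[0]
        lab = grp["class_label"].iloc[0]
        try:
            out.append(
                Spectrum(
                    mz=grp["mz"].to_numpy(float),
                    intensity=grp["intensity"].to_numpy(float),
                    case_id=str(case_id),
                    spot_id=str(spot_id),
                    compartment=None if pd.isna(comp) or comp == "" else str(comp),
                    class_label=None if pd.isna(lab) or lab == "" else str(lab),
                )
            )
        except SpectrumValidationError as exc:
            raise SpectraIOError(f"{path}: invalid spectrum {case_id}/{spot_id}: {exc}") from exc
    return out


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(bda, ident):
    """Decode one mzML <binaryDataArray>: base64, optional zlib, 32/64-bit floats."""
    import base64
    import struct
    import zlib

    accessions = {
        cv.get("accession"): cv.get("name", "")
        for cv in bda.iter(f"{_MZML_NS}cvParam")
    }
    if "MS:1000523" in accessions:
        fmt, width = "d", 8
    elif "MS:1000521" in accessions:
        fmt, width = "f", 4
    else:
        raise SpectraIOError(f"{ident}: binary array lacks a float-width cvParam")
    if "MS:1000514" in accessions:
        kind = "mz"
    elif "MS:1000515" in accessions:
        kind = "intensity"
    else:
        kind = None
    node = bda.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((node.text or "").strip()) if node is not None else b""
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    if len(raw) % width:
        raise SpectraIOError(f"{ident}: binary payload is not a whole number of floats")
    values = np.array(struct.unpack(f"<{len(raw) // width}{fmt}", raw))
    return kind, values


def _read_mzml(path) -> list:
    """Minimal reader for profile mzML: uncompressed or zlib-compressed
    little-endian 32/64-bit float m/z and intensity arrays."""
    from lxml import etree

    out = []
    stem = Path(path).stem
    tree = etree.parse(str(path))
    for spec in tree.iter(f"{_MZML_NS}spectrum"):
        sid = spec.get("id", f"index={spec.get('index', len(out))}")
        ident = f"{path}: record {sid!r}"
        arrays = {}
        for bda in spec.iter(f"{_MZML_NS}binaryDataArray"):
            kind, values = _decode_binary_array(bda, ident)
            if kind:
                arrays[kind] = values
        if set(arrays) != {"mz", "intensity"}:
            raise SpectraIOError(f"{ident}: missing m/z or intensity array")
        try:
            out.append(
                Spectrum(
                    mz=arrays["mz"],
                    intensity=arrays["intensity"],
                    case_id=stem,
                    spot_id=str(sid),
                    extra={"source_format": "mzml"},
                )
            )
        except SpectrumValidationError as exc:
            raise SpectraIOError(f"{ident}: {exc}") from exc
    return out


def _read_imzml(path) -> list:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    stem = Path(path).stem
    out = []
    for i, coords in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        spot = "x{}_y{}".format(coords[0], coords[1])
        try:
            out.append(
                Spectrum(
                    mz=np.asarray(mz, dtype=float),
                    intensity=np.asarray(inten, dtype=float),
                    case_id=stem,
                    spot_id=spot,
                    extra={"source_format": "imzml", "coordinates": tuple(coords)},
                )
            )
        except SpectrumValidationError as exc:
            raise SpectraIOError(f"{path}: pixel {spot}: {exc}") from exc
    return out


def read_spectra(path, format: str = "native_tabular") -> list:
    """Read spectra from ``path`` in the named format.

    Formats: ``native_tabular`` (the package dialect), ``mzml``, ``imzml``.
    All readers validate Spectrum invariants and raise on violations rather
    than silently repairing the input.
    """
    readers = {"native_tabular": _read_native, "mzml": _read_mzml, "imzml": _read_imzml}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; choose one of {sorted(readers)}")
    return readers[format](path)


def write_annotations(marks: list, path) -> None:
    pd.DataFrame(
        [
            {
                "case_id": m.case_id,
                "spot_id": m.spot_id,
                "compartment": m.compartment,
                "x_um": m.x,
                "y_um": m.y,
                "diameter_um": m.diameter,
            }
            for m in marks
        ]
    ).to_csv(path, index=False)


def read_annotations(path) -> list:
    df = pd.read_csv(path)
    required = ["case_id", "spot_id", "compartment", "x_um", "y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpectraIOError(f"{path}: missing columns {missing}")
    return [
        AnnotationMark(
            case_id=str(r.case_id),
            spot_id=str(r.spot_id),
            compartment=str(r.compartment),
            x=float(r.x_um),
            y=float(r.y_um),
            diameter=float(getattr(r, "diameter_um", 300.0)),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# peak matrix I/O (PeakMatrix itself lives in maldiprofiler.peaks)

_META_COLUMNS = ["case_id", "spot_id", "compartment", "class_label"]


def write_peak_matrix(matrix, path) -> None:
    """Write a PeakMatrix as delimited text.

    One row per spectrum; metadata columns first, then one column per picked
    peak named by its m/z to 4 decimals. Lossless to that naming precision.
    """
    df = matrix.meta.copy()
    for j, mz in enumerate(matrix.mz):
        df[f"{mz:.4f}"] = matrix.values[:, j]
    df.to_csv(path, index=False)


def read_peak_matrix(path):
    from .peaks import PeakMatrix

    df = pd.read_csv(path, dtype={c: str for c in _META_COLUMNS})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraIOError(f"{path}: missing metadata columns {missing}")
    peak_cols = [c for c in df.columns if c not in _META_COLUMNS]
    mz = np.array([float(c) for c in peak_cols])
    values = df[peak_cols].to_numpy(float) if peak_cols else np.zeros((len(df), 0))
    return PeakMatrix(meta=df[_META_COLUMNS].copy(), mz=mz, values=values)


# ---------------------------------------------------------------------------
# clinical / IHC tables

_CLINICAL_REQUIRED = [
    "case_id",
    "group",
    "age",
    "tumor_size_cm",
    "followup_months",
    "recurrence",
    "death_from_disease",
    "time_to_event_months",
]
_IHC_REQUIRED = ["case_id", "group", "marker", "reader1_pct", "reader2_pct"]


class SchemaError(ValueError):
    """A table is missing mandatory columns or contains untypeable values."""


def _to_bool(v):
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes", "y")
    return bool(v)


def read_clinical_table(path) -> list:
    """Read per-patient outcome records from delimited text."""
    from .clinstats import ClinicalRecord

    df = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; expected {_CLINICAL_REQUIRED}")
    records = []
    for r in df.itertuples():
        try:
            fu = float(r.followup_months) if pd.notna(r.followup_months) else None
            tte = float(r.time_to_event_months) if pd.notna(r.time_to_event_months) else None
            records.append(
                ClinicalRecord(
                    case_id=str(r.case_id),
                    group=str(r.group),
                    age=float(r.age),
                    tumor_size=float(r.tumor_size_cm),
                    followup_months=fu,
                    recurrence=_to_bool(r.recurrence),
                    death_from_disease=_to_bool(r.death_from_disease),
                    time_to_event=tte,
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {r.Index}: {exc}") from exc
    return records


def write_clinical_table(records: list, path) -> None:
    pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "group": r.group,
                "age": r.age,
                "tumor_size_cm": r.tumor_size,
                "followup_months": r.followup_months,
                "recurrence": r.recurrence,
                "death_from_disease": r.death_from_disease,
                "time_to_event_months": r.time_to_event,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_ihc_table(path) -> list:
    """Read two-reader immunohistochemistry scores from delimited text."""
    from .clinstats import IHCRecord

    df = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in _IHC_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; expected {_IHC_REQUIRED}")
    records = []
    for r in df.itertuples():
        try:
            records.append(
                IHCRecord(
                    case_id=str(r.case_id),
                    group=str(r.group),
                    marker=str(r.marker),
                    reader1_pct=float(r.reader1_pct),
                    reader2_pct=float(r.reader2_pct),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {r.Index}: {exc}") from exc
    return records


def write_ihc_table(records: list, path) -> None:
    pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "group": r.group,
                "marker": r.marker,
                "reader1_pct": r.reader1_pct,
                "reader2_pct": r.reader2_pct,
                "mean_pct": r.mean_pct,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
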