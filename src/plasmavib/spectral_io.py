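"""Shared data model and delimited-text I/O for plasma vibrational spectra.

The package stores every acquisition on an ascending wavenumber grid (cm⁻¹).
Instrument exports are often descending; any descending axis is normalised on
read, so all downstream indices refer to the ascending grid.

On-disk format is wide delimited text (comma or tab, auto-detected): one row
per acquisition, leading metadata columns (``patient_id``, ``group``,
``modality``, ``hydration``, ``replicate`` and optional demographics) followed
by one numeric column per wavenumber.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("ATR-FTIR", "Raman")
HYDRATIONS = ("wet", "dry")
GROUPS = ("cancer", "healthy", "pcos")

#: metadata columns written before the wavenumber block, in order
META_COLUMNS = ("patient_id", "group", "modality", "hydration", "replicate")
OPTIONAL_META_COLUMNS = ("age_years", "bmi_category", "bp_status")


class SchemaError(ValueError):
    """A required metadata column is missing or malformed."""


class IntegrityError(ValueError):
    """Dataset content violates an invariant (duplicates, label conflicts...)."""


def class_label_for(group: str) -> str:
    """Two-class label used by the supervised analysis: cancer vs control.

    The control class pools healthy participants and participants with PCOS;
    the three-way ``group`` is retained separately for the PCOS sub-analyses.
    """
    return "cancer" if group == "cancer" else "control"


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one acquisition row (or one patient, pre-acquisition)."""

    patient_id: str
    group: str
    modality: str | None = None
    hydration: str | None = None
    replicate: int = 1
    age_years: float | None = None
    bmi_category: str | None = None
    bp_status: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise IntegrityError(f"unknown group {self.group!r}")
        if self.modality is not None and self.modality not in MODALITIES:
            raise IntegrityError(f"unknown modality {self.modality!r}")
        if self.hydration is not None and self.hydration not in HYDRATIONS:
            raise IntegrityError(f"unknown hydration {self.hydration!r}")
        if self.replicate < 1:
            raise IntegrityError("replicate index must be >= 1")

    @property
    def class_label(self) -> str:
        return class_label_for(self.group)

    def key(self) -> tuple:
        return (self.patient_id, self.modality, self.hydration, self.replicate)


@dataclass(frozen=True)
class Spectrum:
    """One acquisition: ascending wavenumber grid + intensities (a.u.)."""

    grid: np.ndarray
    intensities: np.ndarray
    modality: str
    hydration: str
    sample_ref: str

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "intensities", intens)
        if grid.ndim != 1 or grid.size < 2:
            raise IntegrityError("grid must be 1-D with >= 2 points")
        if intens.shape != grid.shape:
            raise IntegrityError("grid and intensities length mismatch")
        if not np.all(np.diff(grid) > 0):
            raise IntegrityError("grid must be strictly ascending")
        if not np.all(np.isfinite(intens)):
            raise IntegrityError("intensities must be finite")


@dataclass
class SpectralDataset:
    """Intensity matrix on one shared ascending grid + per-row metadata."""

    grid: np.ndarray
    matrix: np.ndarray
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] != len(self.samples):
            raise IntegrityError(
                f"matrix has {self.matrix.shape[0]} rows but "
                f"{len(self.samples)} sample records"
            )
        if self.matrix.shape[1] != self.grid.size:
            raise IntegrityError("matrix width does not match grid length")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def patient_ids(self) -> list[str]:
        """Unique patient ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    @property
    def class_labels(self) -> np.ndarray:
        return np.array([s.class_label for s in self.samples])

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.samples])

    def rows_for_patients(self, patients: Iterable[str]) -> np.ndarray:
        wanted = set(patients)
        return np.array(
            [i for i, s in enumerate(self.samples) if s.patient_id in wanted],
            dtype=int,
        )

    def subset_rows(self, idx: Sequence[int]) -> "SpectralDataset":
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(
            grid=self.grid.copy(),
            matrix=self.matrix[idx].copy(),
            samples=[self.samples[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "patient_id": [s.patient_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "modality": [s.modality for s in self.samples],
                "hydration": [s.hydration for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )
        for col in OPTIONAL_META_COLUMNS:
            vals = [getattr(s, col) for s in self.samples]
            if any(v is not None for v in vals):
                meta[col] = vals
        spec = pd.DataFrame(self.matrix, columns=[f"{w:.6g}" for w in self.grid])
        return pd.concat([meta, spec], axis=1)


def _records_from_frame(meta: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in meta.iterrows():
        kwargs = {}
        for col in OPTIONAL_META_COLUMNS:
            if col in meta.columns and pd.notna(row[col]):
                kwargs[col] = row[col]
        records.append(
            SampleRecord(
                patient_id=str(row["patient_id"]),
                group=str(row["group"]),
                modality=str(row["modality"]),
                hydration=str(row["hydration"]),
                replicate=int(row["replicate"]),
                **kwargs,
            )
        )
    return records


def read_dataset(path) -> SpectralDataset:
    """Read a wide delimited-text spectra table.

    The wavenumber axis is taken from the numeric header columns; a descending
    axis is re-ordered to ascending (columns permuted consistently). Raises
    :class:`SchemaError` for missing metadata columns, ``ValueError`` naming
    the offending cell for non-numeric/non-finite intensities and
    :class:`IntegrityError` for duplicate acquisition keys.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing metadata column(s): {', '.join(missing)}")

    wn_cols = [c for c in df.columns if c not in META_COLUMNS + OPTIONAL_META_COLUMNS]
    try:
        grid = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SchemaError(f"non-numeric wavenumber column header: {exc}") from exc
    if grid.size < 2:
        raise SchemaError("need at least 2 wavenumber columns")

    intens = df[wn_cols].to_numpy()
    try:
        intens = intens.astype(float)
    except (TypeError, ValueError):
        intens = None
    if intens is None or not np.all(np.isfinite(intens)):
        # locate the first offending cell for the error message
        for j, c in enumerate(wn_cols):
            col = pd.to_numeric(df[c], errors="coerce")
            bad = np.flatnonzero(~np.isfinite(col.to_numpy(dtype=float)))
            if bad.size:
                raise ValueError(
                    f"non-numeric or non-finite intensity at row {bad[0]}, "
                    f"wavenumber column {c!r}"
                )
        raise ValueError("non-finite intensity value")  # pragma: no cover

    order = np.argsort(grid, kind="stable")
    if np.any(np.diff(grid[order]) == 0):
        raise IntegrityError("duplicate wavenumber in header")
    grid = grid[order]
    intens = intens[:, order]

    records = _records_from_frame(df[[c for c in df.columns if c not in wn_cols]])
    seen: set[tuple] = set()
    for r in records:
        k = r.key()
        if k in seen:
            raise IntegrityError(f"duplicate acquisition key {k}")
        seen.add(k)
    return SpectralDataset(grid=grid, matrix=intens, samples=records)


def write_dataset(ds: SpectralDataset, path) -> None:
    """Write ``ds`` as wide CSV; ``read_dataset`` round-trips it (≤1e-9 rel)."""
    if ds.n_samples == 0:
        raise ValueError("refusing to serialise an empty dataset")
    df = ds.to_frame()
    spec_cols = [f"{w:.6g}" for w in ds.grid]
    df[spec_cols] = ds.matrix
    df.to_csv(path, index=False, float_format="%.12g")


def validate_dataset(
    ds: SpectralDataset,
    expected_replicates: dict[tuple[str, str], int] | None = None,
    require_fusion_complete: bool = False,
) -> list[str]:
    """Return a list of invariant violations; empty iff the dataset is valid.

    ``expected_replicates`` maps (modality, hydration) -> required row count
    per patient. With ``require_fusion_complete`` (or when the dataset mixes
    modalities) every patient must appear under every modality present.
    """
    report: list[str] = []
    if ds.grid.size < 2:
        report.append("grid has fewer than 2 points")
    diffs = np.diff(ds.grid)
    if np.any(diffs <= 0):
        report.append("grid is not strictly ascending (repeat or disorder)")
    if not np.all(np.isfinite(ds.matrix)):
        bad = np.argwhere(~np.isfinite(ds.matrix))
        report.append(f"non-finite intensity at (row, col) {tuple(bad[0])}")
    for i, s in enumerate(ds.samples):
        if not s.patient_id:
            report.append(f"row {i}: empty patient_id")

    seen: set[tuple] = set()
    for s in ds.samples:
        k = s.key()
        if k in seen:
            report.append(f"duplicate acquisition key {k}")
        seen.add(k)

    modalities = sorted({s.modality for s in ds.samples if s.modality})
    if require_fusion_complete or len(modalities) > 1:
        by_patient: dict[str, set[str]] = {}
        for s in ds.samples:
            by_patient.setdefault(s.patient_id, set()).add(s.modality)
        for pid, mods in sorted(by_patient.items()):
            missing = [m for m in modalities if m not in mods]
            if missing:
                report.append(
                    f"patient {pid} lacks modality {', '.join(missing)} "
                    "(fusion incomplete)"
                )

    if expected_replicates:
        counts: dict[tuple, int] = {}
        for s in ds.samples:
            counts[(s.patient_id, s.modality, s.hydration)] = (
                counts.get((s.patient_id, s.modality, s.hydration), 0) + 1
            )
        for (pid, mod, hyd), n in sorted(counts.items()):
            want = expected_replicates.get((mod, hyd))
            if want is not None and n != want:
                report.append(
                    f"patient {pid} has {n} {mod}/{hyd} rows, expected {want}"
                )
    return report


def datasets_equal(a: SpectralDataset, b: SpectralDataset, rtol: float = 1e-9) -> bool:
    """Equality up to relative tolerance on intensities, exact on metadata."""
    return (
        np.allclose(a.grid, b.grid, rtol=rtol, atol=0)
        and a.matrix.shape == b.matrix.shape
        and np.allclose(a.matrix, b.matrix, rtol=rtol, atol=1e-12)
        and a.samples == b.samples
    )
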