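"""Low-level data fusion: per-patient concatenation of ATR-FTIR and Raman.

Both inputs must have been pre-processed for fusion (vector-normalised rows).
Replicates are averaged per patient per modality and each averaged block is
re-normalised to unit Euclidean norm before concatenation, so the two
modalities enter the combined feature vector on the same intensity scale.
The FTIR block always precedes the Raman block; ``feature_axis`` records the
(modality, wavenumber) identity of every column so that downstream biomarker
reporting can attribute features to their source instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import average_replicates, vector_normalize
from .spectral_io import IntegrityError, SampleRecord, SpectralDataset

__all__ = ["FusedDataset", "concatenate_modalities"]


@dataclass
class FusedDataset:
    """Concatenated per-patient feature matrix with block bookkeeping."""

    feature_axis: list[tuple[str, float]]  # (modality, wavenumber)
    matrix: np.ndarray
    samples: list[SampleRecord]
    n_ftir: int
    n_raman: int

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != self.n_ftir + self.n_raman:
            raise IntegrityError("feature count != FTIR block + Raman block")
        if self.matrix.shape[0] != len(self.samples):
            raise IntegrityError("row count != sample count")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.array([w for _, w in self.feature_axis])

    @property
    def modalities(self) -> np.ndarray:
        return np.array([m for m, _ in self.feature_axis])

    def block(self, modality: str) -> np.ndarray:
        """Columns belonging to one modality, in axis order."""
        if modality == "ATR-FTIR":
            return self.matrix[:, : self.n_ftir]
        if modality == "Raman":
            return self.matrix[:, self.n_ftir :]
        raise ValueError(f"unknown modality {modality!r}")

    @property
    def class_labels(self) -> np.ndarray:
        return np.array([s.class_label for s in self.samples])

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.samples])

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.samples]

    def rows_for_patients(self, patients) -> np.ndarray:
        wanted = set(patients)
        return np.array(
            [i for i, s in enumerate(self.samples) if s.patient_id in wanted],
            dtype=int,
        )


def concatenate_modalities(
    ftir: SpectralDataset, raman: SpectralDataset
) -> FusedDataset:
    """Build the fused per-patient dataset, FTIR block first.

    Every patient must be present in both modalities; missing patients are
    reported collectively rather than silently dropped. Class labels must
    agree across modalities for every patient.
    """
    ftir_avg = average_replicates(ftir)
    raman_avg = average_replicates(raman)

    ftir_by_pid = {s.patient_id: i for i, s in enumerate(ftir_avg.samples)}
    raman_by_pid = {s.patient_id: i for i, s in enumerate(raman_avg.samples)}

    all_pids = sorted(set(ftir_by_pid) | set(raman_by_pid))
    missing = [
        pid
        for pid in all_pids
        if pid not in ftir_by_pid or pid not in raman_by_pid
    ]
    if missing:
        raise IntegrityError(
            "patient(s) missing one modality: " + ", ".join(missing)
        )

    rows, records = [], []
    for pid in all_pids:
        fi, ri = ftir_by_pid[pid], raman_by_pid[pid]
        f_rec, r_rec = ftir_avg.samples[fi], raman_avg.samples[ri]
        if f_rec.group != r_rec.group:
            raise IntegrityError(
                f"patient {pid}: group label disagrees across modalities "
                f"({f_rec.group} vs {r_rec.group})"
            )
        f_row = vector_normalize(ftir_avg.matrix[fi])
        r_row = vector_normalize(raman_avg.matrix[ri])
        rows.append(np.concatenate([f_row, r_row]))
        records.append(
            SampleRecord(
                patient_id=pid,
                group=f_rec.group,
                modality=None,
                hydration=f_rec.hydration,
                replicate=1,
                age_years=f_rec.age_years,
                bmi_category=f_rec.bmi_category,
                bp_status=f_rec.bp_status,
            )
        )

    feature_axis = [("ATR-FTIR", float(w)) for w in ftir_avg.grid] + [
        ("Raman", float(w)) for w in raman_avg.grid
    ]
    return FusedDataset(
        feature_axis=feature_axis,
        matrix=np.array(rows),
        samples=records,
        n_ftir=ftir_avg.grid.size,
        n_raman=raman_avg.grid.size,
    )
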