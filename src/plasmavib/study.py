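"""End-to-end study composition: simulate → pre-process → fuse → evaluate.

Convenience layer joining the individual modules into the full analysis a
study run performs: generate (or accept) the three raw datasets, pre-process
each modality, build the fused representation, and run the shared-split
supervised evaluation on all four representations.
"""

from __future__ import annotations

from typing import Mapping

from .classify_eval import EvalConfig, StudyResult, run_supervised_study
from .fuse import concatenate_modalities
from .preprocess import PreprocessParams, preprocess_modality
from .spectral_io import SpectralDataset
from .synth_plasma import SyntheticConfig, synth_study

__all__ = ["prepare_study_datasets", "run_study_pipeline"]

#: dataset key -> (modality, pre-processing purpose) for the three raw inputs
_SETTINGS = {
    "ftir_wet": ("ATR-FTIR", "single"),
    "ftir_dry": ("ATR-FTIR", "single"),
    "raman_wet": ("Raman", "single"),
}


def prepare_study_datasets(
    raw: Mapping[str, SpectralDataset],
    params: PreprocessParams | None = None,
    include: tuple[str, ...] = ("ftir_wet", "ftir_dry", "raman_wet", "fused"),
) -> dict[str, object]:
    """Pre-process raw datasets and build the fused representation.

    ``raw`` must carry the keys produced by
    :func:`~plasmavib.synth_plasma.synth_study`. The fused dataset is built
    from the wet ATR-FTIR and wet Raman spectra, each re-pre-processed with
    the fusion normalisation (vector norm on both blocks).
    """
    params = params or PreprocessParams()
    out: dict[str, object] = {}
    for key in include:
        if key == "fused":
            continue
        modality, purpose = _SETTINGS[key]
        out[key] = preprocess_modality(raw[key], params, modality, purpose)
    if "fused" in include:
        ftir_f = preprocess_modality(raw["ftir_wet"], params, "ATR-FTIR", "fused")
        raman_f = preprocess_modality(raw["raman_wet"], params, "Raman", "fused")
        out["fused"] = concatenate_modalities(ftir_f, raman_f)
    return out


def run_study_pipeline(
    config: SyntheticConfig,
    eval_cfg: EvalConfig | None = None,
    params: PreprocessParams | None = None,
    include: tuple[str, ...] = ("ftir_wet", "ftir_dry", "raman_wet", "fused"),
) -> tuple[dict[str, object], StudyResult]:
    """Full synthetic study: one call from generator config to summaries."""
    eval_cfg = eval_cfg or EvalConfig(master_seed=config.seed)
    raw = synth_study(config)
    datasets = prepare_study_datasets(raw, params, include)
    result = run_supervised_study(datasets, eval_cfg)
    return datasets, result
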