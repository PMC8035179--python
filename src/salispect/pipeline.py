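"""End-to-end protocol orchestration.

``run_protocol`` ties the stages together the way the clinical protocol
runs: (synthetic) study acquisition -> CT crop -> gland segmentation
(trained network, or truth/manual labels) -> rigid correction of the
40-min SPECT -> per-gland %ID / %EF quantification -> agreement report
against the reference labels.  Every run directory receives a config
snapshot, a log and byte-stable CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .evaluate import AgreementReport, compare_segmentations
from .phantom import PhantomSpec, generate_cohort, simulate_manual_labels
from .quantify import DoseInputs, quant_table, quantify_study
from .registration import apply_alignment, estimate_alignment
from .segmentation import TrainedModel, UNetConfig, segment_study, train
from .preprocess import apply_crop, plan_crop
from .volumes import StudyRecord

log = logging.getLogger("salispect")

__all__ = ["PipelineConfig", "run_protocol"]


@dataclass
class PipelineConfig:
    """One serializable description of a full run."""

    out_dir: str = "run"
    n_studies: int = 10
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    unet: UNetConfig = field(default_factory=lambda: UNetConfig(
        levels=3, base_channels=8, epochs=10))
    segmentation_source: str = "network"  # "network" | "manual" | "truth"
    model_path: Optional[str] = None
    correct_misregistration: bool = True
    decay_correct: bool = True
    sum_lateral: bool = False
    min_component_voxels: int = 10
    dose: DoseInputs = field(default_factory=DoseInputs)
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, default=str)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for k in ("shape", "spacing_mm", "body_semiaxes_mm"):
                if k in ph:
                    ph[k] = tuple(ph[k])
            for k, v in list(ph.items()):
                if isinstance(v, list) and len(v) == 2:
                    ph[k] = tuple(v)
            d["phantom"] = PhantomSpec(**ph)
        if "unet" in d and isinstance(d["unet"], dict):
            un = dict(d["unet"])
            if "input_shape" in un:
                un["input_shape"] = tuple(un["input_shape"])
            d["unet"] = UNetConfig(**un)
        if "dose" in d and isinstance(d["dose"], dict):
            d["dose"] = DoseInputs(**d["dose"])
        return cls(**d)


def _train_model(cohort, cfg: PipelineConfig) -> TrainedModel:
    pairs = []
    for rec in cohort:
        plan = plan_crop(rec.ct20, cfg.unet.input_shape)
        pairs.append((apply_crop(rec.ct20, plan), apply_crop(rec.truth_labels, plan)))
    return train(pairs, cfg.unet)


def run_protocol(config: PipelineConfig) -> tuple[pd.DataFrame, AgreementReport]:
    """Execute the full protocol; returns (quant table, agreement report)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    (out / "config.json").write_text(config.to_json())
    log.info("salispect %s; seed %d; %d studies", __version__, config.seed, config.n_studies)
    try:
        return _run_stages(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path):
    try:
        cohort = generate_cohort(
            dataclasses.replace(config.phantom, seed=config.seed), config.n_studies
        )
    except Exception as e:
        raise RuntimeError(f"[phantom] {e}") from e

    # segmentation source
    try:
        if config.segmentation_source == "network":
            if config.model_path:
                model = TrainedModel.load(config.model_path)
            else:
                model = _train_model(cohort, config)
                model.save(out / "model.npz")
            seg = [
                segment_study(r, model, config.min_component_voxels) for r in cohort
            ]
        elif config.segmentation_source == "manual":
            seg = [
                simulate_manual_labels(
                    r.truth_labels,
                    every_k_slices=config.phantom.rater_slice_step,
                    jitter_prob=config.phantom.rater_jitter_prob,
                    seed=config.seed + 1000 + i,
                )
                for i, r in enumerate(cohort)
            ]
        elif config.segmentation_source == "truth":
            seg = [r.truth_labels for r in cohort]
        else:
            raise ValueError(f"unknown segmentation source {config.segmentation_source!r}")
    except Exception as e:
        raise RuntimeError(f"[segment] {e}") from e

    # misregistration correction + quantification
    tables = []
    try:
        corrected = []
        for rec in cohort:
            s40 = rec.spect40
            if config.correct_misregistration:
                t, ncc = estimate_alignment(s40, rec.spect20)
                s40 = apply_alignment(s40, t)
                log.info("%s: correction %s (ncc %.4f)", rec.study_id, t.to_dict(), ncc)
            corrected.append(
                StudyRecord(
                    study_id=rec.study_id,
                    ct20=rec.ct20,
                    spect20=rec.spect20,
                    spect40=s40,
                    injected_activity_MBq=rec.injected_activity_MBq,
                    truth_labels=rec.truth_labels,
                )
            )
        for rec, labels in zip(corrected, seg):
            q = quantify_study(
                rec.spect20,
                rec.spect40,
                labels,
                rec.injected_activity_MBq,
                decay_correct=config.decay_correct,
                sum_lateral=config.sum_lateral,
            )
            tables.append(quant_table(q, rec.study_id))
    except Exception as e:
        raise RuntimeError(f"[quantify] {e}") from e
    quants = pd.concat(tables, ignore_index=True)
    quants.to_csv(out / "quant.csv", index=False, float_format="%.6g")

    try:
        report = compare_segmentations(
            corrected, [r.truth_labels for r in cohort], seg,
            decay_correct=config.decay_correct,
        )
    except Exception as e:
        raise RuntimeError(f"[evaluate] {e}") from e
    report.to_csv(out / "agreement.csv")
    report.summary().to_csv(out / "agreement_summary.csv", index=False, float_format="%.6g")

    dose = config.dose
    (out / "dose.json").write_text(json.dumps({
        "tracer_mSv": dose.tracer_dose_mSv(),
        "ct_per_session_mSv": dose.ct_dose_mSv() / max(dose.n_ct_sessions, 1),
        "total_mSv": dose.total_mSv(),
    }, indent=1))
    return quants, report
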