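"""End-to-end orchestration and run configuration.

A :class:`PipelineConfig` carries every knob of a full run — study design,
trust structure, missingness, selection configuration, split counts — and a
single master seed that fans out to named per-stage sub-seeds, so any stage
can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from physiotrust.design import StudyDesign
from physiotrust.evaluate import MccvReport, run_mccv
from physiotrust.features import FeatureMatrix, assemble_design_matrix
from physiotrust.model import SelectionConfig
from physiotrust.synth import StudyDataset, generate_study, inject_missingness
from physiotrust.synth.study import TrustSpec

__all__ = ["PipelineConfig", "stage_seed", "simulate", "extract", "evaluate", "run_pipeline"]

_STAGE_OFFSETS = {"simulate": 11, "missingness": 13, "extract": 17, "fit": 19, "evaluate": 23}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic named sub-seed below 2^31."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    trust: TrustSpec = field(default_factory=TrustSpec)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    epoch_drop_p: float = 0.0024
    trial_drop_p: float = 0.0
    session_stream_drop_count: int = 0
    n_splits: int = 10
    run_ica: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trust"]["planted"] = [p.name for p in self.trust.planted]
        return d


def simulate(cfg: PipelineConfig) -> StudyDataset:
    ds = generate_study(cfg.design, cfg.trust, seed=stage_seed(cfg.seed, "simulate"))
    if cfg.epoch_drop_p or cfg.trial_drop_p or cfg.session_stream_drop_count:
        inject_missingness(
            ds,
            epoch_drop_p=cfg.epoch_drop_p,
            trial_drop_p=cfg.trial_drop_p,
            session_stream_drop_count=cfg.session_stream_drop_count,
            seed=stage_seed(cfg.seed, "missingness"),
        )
    return ds


def extract(cfg: PipelineConfig, dataset: StudyDataset) -> FeatureMatrix:
    return assemble_design_matrix(dataset, run_ica=cfg.run_ica)


def evaluate(cfg: PipelineConfig, matrix: FeatureMatrix) -> MccvReport:
    sel = SelectionConfig(
        n_reps_round1=cfg.selection.n_reps_round1,
        n_reps_round2=cfg.selection.n_reps_round2,
        cv_folds=cfg.selection.cv_folds,
        n_lambdas=cfg.selection.n_lambdas,
        lambda_min_ratio=cfg.selection.lambda_min_ratio,
        seed=stage_seed(cfg.seed, "fit"),
    )
    return run_mccv(
        matrix, sel, n_splits=cfg.n_splits, seed=stage_seed(cfg.seed, "evaluate")
    )


def run_pipeline(cfg: PipelineConfig):
    """simulate -> extract -> MCCV; returns (dataset, matrix, report)."""
    ds = simulate(cfg)
    fm = extract(cfg, ds)
    report = evaluate(cfg, fm)
    return ds, fm, report
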