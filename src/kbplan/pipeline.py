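"""End-to-end planning workflow: atlas → train → predict → optimize → evaluate.

Each stage is a thin orchestration of the underlying modules; failures are
re-raised with the stage name attached so a pipeline error is attributable.
All randomness flows from one global seed, split deterministically per
stage, and a run log records per-stage record counts for auditability.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import CriteriaReport, CriteriaTable, MetricSpec, dose_metric
from .features import FeatureMatrix, FeatureSpec, extract_features
from .grids import AtlasLibrary, DoseGrid, ImageVolume, StructureSet
from .optimization import (
    BeamGeometry,
    InfluenceMatrix,
    PlanObjective,
    PlanResult,
    build_influence_matrix,
    deliverability_check,
    optimize_plan,
)
from .prediction import (
    CRFParams,
    CRFResult,
    ForestHyperparams,
    ForestModel,
    SimilarityRanking,
    crf_refine,
    geometry_descriptor,
    predict_unary,
    rank_by_descriptor,
    train_atlas_forests,
)

__all__ = ["RunConfig", "StageError", "TrainedModel", "PlanOutputs",
           "train_model", "plan_case", "stage_seed"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a planning run."""

    prescription_cGy: float = 5400.0
    n_fractions: int = 30
    seed: int = 0
    k_atlases: int = 3
    coverage_headroom: float = 0.015   # prediction calibration above 0.95 Rx
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    forest_hyper: ForestHyperparams = field(default_factory=ForestHyperparams)
    crf_params: CRFParams = field(default_factory=CRFParams)
    beam_geometry: BeamGeometry = field(default_factory=BeamGeometry)
    objective: PlanObjective = field(default_factory=PlanObjective)
    criteria: CriteriaTable | None = None

    def __post_init__(self) -> None:
        if self.prescription_cGy <= 0:
            raise ValueError("prescription must be positive")
        if self.k_atlases < 1:
            raise ValueError("k_atlases must be >= 1")
        if self.coverage_headroom < 0:
            raise ValueError("coverage_headroom must be >= 0")

    def criteria_table(self) -> CriteriaTable:
        if self.criteria is not None:
            return self.criteria
        return CriteriaTable.for_prescription(self.prescription_cGy)


@dataclass(frozen=True)
class TrainedModel:
    """Trained atlas model: per-case forests plus similarity descriptors."""

    forests: dict[str, ForestModel]
    descriptors: dict[str, np.ndarray]
    feature_spec: FeatureSpec
    seed: int


@dataclass(frozen=True)
class PlanOutputs:
    """Everything a planning run produces for one case."""

    ranking: SimilarityRanking
    predicted: DoseGrid          # calibrated CRF-refined prediction
    crf: CRFResult
    plan: PlanResult
    criteria_report: CriteriaReport
    log: dict


def train_model(library: AtlasLibrary, config: RunConfig | None = None) -> TrainedModel:
    """Train per-case atlas forests and record similarity descriptors."""
    if config is None:
        config = RunConfig()
    hyper = replace(config.forest_hyper,
                    seed=stage_seed(config.seed, "train"))
    try:
        forests = train_atlas_forests(library, config.feature_spec, hyper)
        descriptors = {
            case.case_id: geometry_descriptor(case.image, case.structures)
            for case in library
        }
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("train", exc) from exc
    return TrainedModel(forests=forests, descriptors=descriptors,
                        feature_spec=config.feature_spec, seed=config.seed)


def plan_case(image: ImageVolume, structures: StructureSet,
              model: TrainedModel, config: RunConfig | None = None) -> PlanOutputs:
    """Run features → select → predict → CRF → calibrate → optimize → evaluate."""
    if config is None:
        config = RunConfig()
    log: dict = {"stages": {}}

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
        log["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        return result

    features: FeatureMatrix = timed(
        "features", lambda: extract_features(image, structures, model.feature_spec))
    log["stages"]["features"]["n_voxels"] = features.n_voxels

    k = min(config.k_atlases, len(model.descriptors))
    ranking = timed("select", lambda: rank_by_descriptor(
        geometry_descriptor(image, structures), model.descriptors, k))
    log["stages"]["select"]["selected"] = list(ranking.selected_ids)

    unary = timed("predict", lambda: predict_unary(features, ranking, model.forests))
    log["stages"]["predict"]["n_clipped"] = unary.n_clipped

    crf = timed("crf", lambda: crf_refine(unary, image, config.crf_params))
    log["stages"]["crf"]["iterations"] = crf.n_iterations

    def calibrate() -> DoseGrid:
        ptv = structures.require("PTVp_5400")
        d95 = dose_metric(crf.dose, ptv, MetricSpec("Dx", 95))
        if d95 is None or d95 <= 0:
            raise ValueError("predicted PTV D95 is undefined or nonpositive")
        target = 0.95 * config.prescription_cGy * (1.0 + config.coverage_headroom)
        return DoseGrid(dose=crf.dose.dose * (target / d95),
                        prescription_cGy=config.prescription_cGy,
                        n_fractions=config.n_fractions)

    predicted = timed("calibrate", calibrate)

    influence: InfluenceMatrix = timed(
        "influence", lambda: build_influence_matrix(image, structures,
                                                    config.beam_geometry))
    log["stages"]["influence"]["n_beamlets"] = influence.n_beamlets

    plan = timed("optimize", lambda: optimize_plan(
        predicted, influence, config.objective, structures))
    log["stages"]["optimize"]["iterations"] = plan.n_iterations
    log["stages"]["optimize"]["converged"] = plan.converged

    report = timed("evaluate", lambda: deliverability_check(
        plan, structures, config.criteria_table()))
    log["stages"]["evaluate"]["criteria_met"] = report.n_met
    log["stages"]["evaluate"]["criteria_assessed"] = report.n_assessed
    log["seed"] = config.seed

    return PlanOutputs(ranking=ranking, predicted=predicted, crf=crf,
                       plan=plan, criteria_report=report, log=log)
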