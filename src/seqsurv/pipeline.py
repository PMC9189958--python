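"""End-to-end experiment driver: simulate, fit, train, evaluate, compare.

One :class:`ExperimentConfig` fully determines a run: the simulator truth
(or an existing cohort directory), the network configuration, the
evaluation scheme, and a global seed. Outputs are plain-text tables under
the output directory, written together with the config that produced
them, so a run can be reproduced from its own artefacts.

Within every cross-validation fold, the vocabulary, covariate centering,
censoring-distribution estimate and Breslow baseline are computed from
the training half only.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort_io import read_cohort, write_cohort
from .compare import (CoxLearner, DeepLearner, builtin_strata, run_5x2_cv,
                      stratified_metrics)
from .cox import fit_cox
from .inference import standard_perturbations, estimate_local_hr
from .network import ModelConfig
from .records import CenteringContext, PersonRecord, build_vocabulary
from .simulate import SimulationConfig, generate_cohort
from .training import train_ensemble

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    simulation: SimulationConfig | None = None
    cohort_dir: str | None = None          # alternative to simulation
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    sexes: tuple[str, ...] = ("F", "M")
    cv_replications: int = 5
    metrics: tuple[str, ...] = ("c", "d", "r2", "ibs")
    local_hr_replicates: int = 0           # 0 disables the local-HR stage
    local_hr_codes: tuple = ()             # (code, code_type) pairs
    run_cox_comparison: bool = True
    ablation: bool = False                 # also run the reduced set
    min_persons: int = 10
    out_dir: str = "seqsurv_run"

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj
        Path(path).write_text(yaml.safe_dump(plain(self)), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if raw.get("simulation"):
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if raw.get("model"):
            m = raw["model"]
            if "adam_betas" in m:
                m["adam_betas"] = tuple(m["adam_betas"])
            raw["model"] = ModelConfig(**m)
        for key in ("sexes", "metrics", "local_hr_codes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in raw[key])
        return cls(**raw)


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(str(v) for v in row) + "\n")


def run_pipeline(config: ExperimentConfig) -> Path:
    """Execute the full experiment; returns the output directory.

    Stages per sex stratum: Cox fit on the full stratum (hazard-ratio
    table), stratified 5x2 cross-validated comparison of the network
    ensemble against the Cox comparator with combined F tests, optional
    ablation (reduced predictor set), and optional local hazard ratios.
    Each stage logs its wall time; failures abort with the stage name,
    keeping artefacts written so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "experiment.yaml")
    stage = "setup"
    try:
        stage = "cohort"
        t0 = time.time()
        if config.cohort_dir is not None:
            cohort = read_cohort(config.cohort_dir)
        elif config.simulation is not None:
            cohort, truth = generate_cohort(config.simulation)
            write_cohort(cohort, out / "cohort")
            _write_csv(out / "cohort" / "truth.csv", ["person_id", "eta"],
                       [[pid, repr(float(e))] for pid, e in
                        zip(truth.person_ids, truth.eta)])
        else:
            raise ValueError("config needs simulation or cohort_dir")
        logger.info("stage %s done in %.1fs (n=%d)", stage,
                    time.time() - t0, len(cohort))

        metric_rows, ftest_rows, hr_rows, coxhr_rows = [], [], [], []
        for sex in config.sexes:
            stratum = [p for p in cohort if p.sex == sex]
            if not stratum or not any(p.cvd_event for p in stratum):
                logger.warning("stratum %s empty or event-free; skipped",
                               sex)
                continue
            stage = f"cox_full_{sex}"
            t0 = time.time()
            cox_model = fit_cox(stratum,
                                predictor_set=config.model.predictor_set)
            cox_model.to_json(out / f"cox_{sex}.json")
            lo, hi = cox_model.confidence_intervals()
            for j, name in enumerate(cox_model.names):
                coxhr_rows.append([sex, name,
                                   f"{np.exp(cox_model.beta[j]):.4g}",
                                   f"{np.exp(lo[j]):.4g}",
                                   f"{np.exp(hi[j]):.4g}"])
            logger.info("stage %s done in %.1fs", stage, time.time() - t0)

            predictor_sets = [config.model.predictor_set]
            if config.ablation and "reduced" not in predictor_sets:
                predictor_sets.append("reduced")
            for pset in predictor_sets:
                if not config.run_cox_comparison:
                    logger.info("Cox comparison disabled; skipping the "
                                "5x2 stage for %s/%s", sex, pset)
                    continue
                stage = f"cv_{sex}_{pset}"
                t0 = time.time()
                model_cfg = ModelConfig(**{**config.model.__dict__,
                                           "predictor_set": pset,
                                           "seed": config.model.seed
                                           + config.seed})
                cv = run_5x2_cv(
                    stratum,
                    DeepLearner(model_cfg, min_persons=config.min_persons),
                    CoxLearner(predictor_set=pset),
                    seed=config.seed, metrics=config.metrics,
                    n_replications=config.cv_replications)
                for m in config.metrics:
                    for r in range(config.cv_replications):
                        for j in range(2):
                            metric_rows.append(
                                [sex, pset, m, r + 1, j + 1,
                                 f"{cv.metrics_a[m][r, j]:.6f}",
                                 f"{cv.metrics_b[m][r, j]:.6f}"])
                    if config.cv_replications == 5:
                        f_stat, p = cv.f_test(m)
                        ftest_rows.append([sex, pset, m, f"{f_stat:.4f}",
                                           f"{p:.4g}"])
                logger.info("stage %s done in %.1fs", stage,
                            time.time() - t0)

            if config.local_hr_replicates >= 2:
                stage = f"local_hr_{sex}"
                t0 = time.time()
                vocab = build_vocabulary(stratum,
                                         min_persons=config.min_persons)
                centering = CenteringContext.fit(stratum, sex=sex)
                predictors = []
                for k in range(config.local_hr_replicates):
                    cfg_k = ModelConfig(**{**config.model.__dict__,
                                           "ensemble_size": 1,
                                           "seed": config.model.seed
                                           + config.seed + k})
                    ens = train_ensemble(stratum, cfg_k, vocab, centering)
                    predictors.append(ens.predict_log_risk)
                perts = standard_perturbations(
                    [p.age for p in stratum],
                    [p.deprivation for p in stratum],
                    codes=list(config.local_hr_codes))
                for rec in estimate_local_hr(predictors, perts, centering,
                                             sex=sex, vocab=vocab):
                    hr_rows.append([sex, rec.label, f"{rec.hr:.4g}",
                                    f"{rec.ci_low:.4g}",
                                    f"{rec.ci_high:.4g}",
                                    rec.n_replicates])
                logger.info("stage %s done in %.1fs", stage,
                            time.time() - t0)

        _write_csv(out / "cox_hr.csv",
                   ["sex", "predictor", "hr", "ci_low", "ci_high"],
                   coxhr_rows)
        if metric_rows:
            _write_csv(out / "metrics.csv",
                       ["sex", "predictor_set", "metric", "replication",
                        "fold", "deep", "cox"], metric_rows)
            _write_csv(out / "ftest.csv",
                       ["sex", "predictor_set", "metric", "F", "p"],
                       ftest_rows)
        if hr_rows:
            _write_csv(out / "local_hr.csv",
                       ["sex", "predictor", "hr", "ci_low", "ci_high",
                        "replicates"], hr_rows)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}"
                           ) from exc
    return out
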