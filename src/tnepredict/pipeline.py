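"""End-to-end orchestration: cohort -> courses -> features -> labels -> models.

``run_all`` reproduces the full experiment layout on a synthetic cohort:
generate eye states, simulate 52-week treat-and-extend courses, apply the
cohort exclusion rules, render the baseline (M0) and 4-week follow-up (M1)
biomarker maps, extract zonal features, fit the latent-class BCVA model and
merge it into responder labels, derive extendability labels from the
courses, and evaluate both random-forest prediction targets.  All artifacts
are written to an output directory together with a manifest of SHA-256
hashes; a rerun with the same configuration reproduces identical hashes.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import MissingDataError
from . import oct_features as of
from . import predict_eval as pe
from . import synthetic_data as sd
from . import tne_protocol as tp
from . import trajectory_classes as tc

log = logging.getLogger("tnepredict")

#: exclusion rules in application order; each eye is counted once, under the
#: first rule it matches
EXCLUSION_RULES = ("missing_scan", "lost_to_followup", "bad_quality", "protocol_deviation")


@dataclass
class PipelineConfig:
    cohort: sd.CohortConfig = field(default_factory=sd.CohortConfig)
    activity_thresholds: Dict[str, float] = field(
        default_factory=lambda: dict(tp.DEFAULT_ACTIVITY_THRESHOLDS)
    )
    lcmm: tc.LcmmSpec = field(default_factory=tc.LcmmSpec)
    responder_rule: tc.ResponderRule = field(default_factory=tc.ResponderRule)
    rf: pe.RfConfig = field(default_factory=pe.RfConfig)
    k_folds: int = 10
    n_boot: int = 1000
    feature_sets: Tuple[str, ...] = pe.FEATURE_SET_NAMES
    compute_importance: bool = True
    output_dir: str = "tnepredict_out"
    global_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = sd.CohortConfig(**raw["cohort"])
        if "lcmm" in raw:
            kwargs["lcmm"] = tc.LcmmSpec(**raw["lcmm"])
        if "rf" in raw:
            kwargs["rf"] = pe.RfConfig(**raw["rf"])
        if "responder_rule" in raw:
            kwargs["responder_rule"] = tc.ResponderRule(**raw["responder_rule"])
        for key in (
            "activity_thresholds", "k_folds", "n_boot", "feature_sets",
            "compute_importance", "output_dir", "global_seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def exclusion_filter(
    eyes_df: pd.DataFrame, rules: Sequence[str] = EXCLUSION_RULES
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply exclusion rules sequentially; each eye counted once.

    ``eyes_df`` carries one boolean column per rule (or an ``exclusion``
    category column, expanded automatically).  Returns the evaluable subset
    and the per-rule tally in application order.
    """
    df = eyes_df.copy()
    if "exclusion" in df.columns:
        for rule in rules:
            col = df["exclusion"].eq(rule)
            df[rule] = col | df.get(rule, False)
    tally: Dict[str, int] = {}
    excluded = pd.Series(False, index=df.index)
    for rule in rules:
        flag = df[rule].astype(bool) if rule in df.columns else pd.Series(False, index=df.index)
        newly = flag & ~excluded
        tally[rule] = int(newly.sum())
        excluded |= flag
    return eyes_df.loc[~excluded], tally


def extract_features(
    eyes: Sequence[sd.EyeState],
    courses: Dict[str, tp.TreatmentCourse],
    maps_path: Optional[Path] = None,
) -> pd.DataFrame:
    """Render M0/M1 maps, quantify zones, and assemble predictor vectors.

    Eyes flagged as missing a baseline or follow-up scan are skipped (never
    imputed).  If ``maps_path`` is given, rendered maps are also stored in
    one HDF5 container keyed ``eye_id/visit/biomarker``.
    """
    vectors = []
    h5 = h5py.File(maps_path, "w") if maps_path is not None else None
    try:
        for eye in eyes:
            if eye.exclusion == "missing_scan":
                continue
            course = courses[eye.eye_id]
            zonal = {}
            for label, visit_idx in (("M0", 0), ("M1", 1)):
                ms = sd.render_maps(eye, label, course.visits[visit_idx].volumes)
                if h5 is not None:
                    grp = h5.require_group(f"{eye.eye_id}/{label}")
                    for b, arr in ms.maps.items():
                        grp.create_dataset(
                            b, data=arr.astype(np.float32), track_times=False
                        )
                zonal[label] = of.compute_zonal_features(ms)
            change = of.change_features(zonal["M0"], zonal["M1"])
            fv = of.assemble_feature_vector(
                zonal["M0"], zonal["M1"], change,
                bcva_m0=course.visits[0].bcva,
                bcva_m1=course.visits[1].bcva,
                age=eye.age,
                sex=eye.sex,
            )
            vectors.append(fv)
    finally:
        if h5 is not None:
            h5.close()
    return of.feature_table(vectors)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Dict[str, str]:
    """Run every stage end-to-end; returns the artifact manifest (hashes)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: List[Path] = []

    current = {"stage": "init"}

    def _stage(name):
        current["stage"] = name
        log.info("stage %s", name)

    try:
        _stage("simulate")
        eyes = sd.generate_cohort(config.cohort)
        truth = sd.cohort_truth_table(eyes)
        truth.to_csv(out / "cohort_truth.csv")
        artifacts.append(out / "cohort_truth.csv")

        courses = {
            e.eye_id: tp.simulate_course(
                e, config.cohort.horizon_weeks, config.activity_thresholds
            )
            for e in eyes
        }
        visits = tp.courses_to_frame(list(courses.values()))
        visits.to_csv(out / "visits.csv", index=False)
        artifacts.append(out / "visits.csv")

        _stage("exclusions")
        evaluable_truth, tally = exclusion_filter(truth.reset_index())
        evaluable_ids = list(evaluable_truth["eye_id"])
        with open(out / "exclusions.json", "w") as fh:
            json.dump({"tally": tally, "n_evaluable": len(evaluable_ids)}, fh, indent=2)
        artifacts.append(out / "exclusions.json")

        _stage("features")
        eval_eyes = [e for e in eyes if e.eye_id in set(evaluable_ids)]
        features = extract_features(eval_eyes, courses, maps_path=out / "maps.h5")
        artifacts.append(out / "maps.h5")
        of.write_feature_table(
            features, out / "features.csv", out / "features_schema.json"
        )
        artifacts += [out / "features.csv", out / "features_schema.json"]

        _stage("labels")
        labels = tp.label_courses([courses[i] for i in evaluable_ids])
        series = visits[visits["eye_id"].isin(evaluable_ids)].rename(
            columns={"week": "t_weeks"}
        )
        series = pd.DataFrame(
            {
                "eye_id": series["eye_id"],
                "t_months": series["t_weeks"] / sd.WEEKS_PER_MONTH,
                "bcva": series["bcva"],
            }
        )
        _stage("lcmm")
        fit = tc.fit_lcmm(series, config.lcmm)
        fit.to_json(out / "lcmm_fit.json")
        artifacts.append(out / "lcmm_fit.json")
        pd.DataFrame(
            fit.posterior, index=pd.Index(fit.eye_ids, name="eye_id"),
            columns=[f"class_{g}" for g in fit.classes],
        ).to_csv(out / "lcmm_posterior.csv")
        artifacts.append(out / "lcmm_posterior.csv")
        responder = tc.responder_labels(fit, config.responder_rule)
        labels = labels.join(responder, how="left")
        labels.to_csv(out / "labels.csv")
        artifacts.append(out / "labels.csv")

        _stage("predict")
        for target in ("responder", "extendable"):
            y = labels.loc[features.index, target].astype(bool)
            results = pe.run_experiment(
                features,
                y,
                target=target,
                feature_sets=config.feature_sets,
                rf=config.rf,
                k=config.k_folds,
                n_boot=config.n_boot,
                seed=config.global_seed,
                compute_importance=config.compute_importance,
            )
            report = pe.experiment_report(results, target)
            with open(out / f"predict_{target}.json", "w") as fh:
                json.dump(report, fh, indent=2)
            artifacts.append(out / f"predict_{target}.json")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {current['stage']!r}: {exc}") from exc

    manifest = {p.name: _sha256(p) for p in artifacts}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
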