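"""End-to-end pipeline: simulate/ingest -> inclusion -> Nc -> microstates -> prediction.

``run_pipeline`` executes the full analysis and writes every stage output
plus a run manifest with input/output checksums, so any stage can be re-run
and verified bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .erp import ErpWaveform, default_montage
from .io import read_erp_dir, read_montage, write_features, write_maps
from .microstates import CvParams, MicrostateMaps, extract_features, fit_templates, select_n_maps
from .nc import nc_feature_frame
from .prediction import (
    GaParams,
    build_feature_table,
    elasticnet_nested,
    evaluate_classifier,
    ga_select,
    shuffle_test,
    stratified_split,
)
from .synthetic import SimConfig, records_frame, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one full run.

    Analysis windows follow the study design: Nc 300-800 ms (clipped to the
    epoch), microstate clustering 0-794 ms, microstate features 300-794 ms.
    Template maps are learned from the reference group in the reference
    condition. All stage seeds are derived from ``seed`` when not given.
    """

    out_dir: str = "run_output"
    erp_dir: str | None = None  # None with simulate=True
    montage_path: str | None = None
    subjects_path: str | None = None
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    min_trials: int = 10
    nc_window: tuple[float, float] = (300.0, 800.0)
    clustering_window: tuple[float, float] = (0.0, 794.0)
    feature_window: tuple[float, float] = (300.0, 794.0)
    reference_group: str = "noFH-noASD"
    reference_condition: str = "FD"
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    ignore_polarity: bool = False
    map_absence_threshold: float = 0.05  # drop maps absent in > this fraction
    cv: CvParams = field(default_factory=CvParams)
    ga: GaParams = field(default_factory=GaParams)
    train_fraction: float = 0.7
    n_eval_repetitions: int = 1000
    n_shuffles: int = 999
    inner_folds: int = 10
    inner_repeats: int = 10
    run_classifier: bool = True
    run_regression: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # stage seeds: fixed offsets from the master seed, all below 2**31
        base = int(self.seed) % (2**28)
        self.sim = dataclasses.replace(self.sim, seed=self.sim.seed or base)
        self.cv = dataclasses.replace(self.cv, seed=self.cv.seed or base + 1)
        self.ga = dataclasses.replace(self.ga, seed=self.ga.seed or base + 2)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimConfig(**raw["sim"])
        if "cv" in raw and isinstance(raw["cv"], dict):
            raw["cv"] = CvParams(**raw["cv"])
        if "ga" in raw and isinstance(raw["ga"], dict):
            raw["ga"] = GaParams(**raw["ga"])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    checksums: dict[str, str]
    timestamps: dict[str, float]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True, default=str)
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate(config: PipelineConfig, epoch: tuple[float, float]) -> None:
    for name, win in (
        ("clustering_window", config.clustering_window),
        ("feature_window", config.feature_window),
    ):
        if win[0] < epoch[0] - 1e-9 or win[1] > epoch[1] + 1e-9:
            raise ValueError(f"{name} {win} lies outside the epoch {epoch}")
    if config.feature_window[0] < config.clustering_window[0] or \
            config.feature_window[1] > config.clustering_window[1]:
        raise ValueError("feature window must lie inside the clustering window")


def microstate_feature_frame(
    erps: dict[str, dict[str, ErpWaveform]],
    maps: MicrostateMaps,
    clustering_window: tuple[float, float],
    feature_window: tuple[float, float],
    ignore_polarity: bool = False,
) -> pd.DataFrame:
    """Tidy per subject x condition x map duration/GFP feature table."""
    rows = []
    for sid in sorted(erps):
        for cond, erp in erps[sid].items():
            seg = fit_templates(erp, maps, clustering_window, ignore_polarity=ignore_polarity)
            feats = extract_features(seg, maps.k, feature_window, erp.fs)
            for m in range(1, maps.k + 1):
                rows.append(
                    {
                        "subject_id": sid,
                        "condition": cond,
                        "map": m,
                        "duration_ms": feats.duration_ms[m - 1],
                        "mean_gfp": feats.mean_gfp[m - 1],
                        "present": bool(feats.present[m - 1]),
                    }
                )
    return pd.DataFrame(rows)


def retained_maps(ms_features: pd.DataFrame, absence_threshold: float = 0.05) -> list[int]:
    """Maps expressed (duration > 0 in any condition) in enough subjects.

    A map absent in more than ``absence_threshold`` of subjects is dropped
    from the modelling feature set.
    """
    out = []
    n_sub = ms_features["subject_id"].nunique()
    for m, grp in ms_features.groupby("map"):
        present_subjects = grp.loc[grp["present"], "subject_id"].nunique()
        if 1 - present_subjects / n_sub <= absence_threshold:
            out.append(int(m))
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write outputs + manifest into ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timestamps = {"start": time.time()}

    # --- ingest or simulate -------------------------------------------------
    if config.simulate:
        records, erps, truth, true_maps = simulate_cohort(config.sim)
        subjects = records_frame(records)
        epoch = config.sim.epoch
        montage = default_montage(config.sim.n_channels)
        truth.to_csv(out / "ground_truth.csv", index=False)
    else:
        if not config.erp_dir or not config.subjects_path:
            raise ValueError("erp_dir and subjects_path are required without --simulate")
        erps = read_erp_dir(config.erp_dir)
        subjects = pd.read_csv(config.subjects_path)
        any_erp = next(iter(next(iter(erps.values())).values()))
        epoch = (any_erp.t0_offset, float(any_erp.times[-1]))
        montage = (
            read_montage(config.montage_path)
            if config.montage_path
            else default_montage(any_erp.n_channels)
        )
        records = None
    _validate(config, epoch)

    # --- inclusion ----------------------------------------------------------
    trial_cols = [c for c in subjects.columns if c.startswith("trials_")]
    if trial_cols:
        ok = (subjects[trial_cols] >= config.min_trials).all(axis=1)
        subjects = subjects.loc[ok].reset_index(drop=True)
        erps = {s: e for s, e in erps.items() if s in set(subjects["subject_id"])}
        logger.info("inclusion rule kept %d subjects", len(subjects))
    subjects.to_csv(out / "subjects.csv", index=False)

    # --- Nc features --------------------------------------------------------
    nc_df = nc_feature_frame(erps, montage, config.nc_window)
    nc_df.to_csv(out / "nc_features.csv", index=False)

    # --- microstate map learning -------------------------------------------
    ref_ids = subjects.loc[subjects["group"] == config.reference_group, "subject_id"]
    ref_erps = [erps[s][config.reference_condition] for s in ref_ids if s in erps]
    if len(ref_erps) < 4:
        raise RuntimeError("too few reference-group subjects for map learning")
    selection = select_n_maps(
        ref_erps, config.k_range, config.cv,
        window=config.clustering_window, ignore_polarity=config.ignore_polarity,
    )
    write_maps(
        selection.maps, out / "maps",
        meta={
            "window_ms": list(config.clustering_window),
            "reference_group": config.reference_group,
            "reference_condition": config.reference_condition,
            "polarity_sensitive": not config.ignore_polarity,
            "test_ev": {str(k): v for k, v in selection.test_ev.items()},
            "p_values": {str(k): v for k, v in selection.p_values.items()},
        },
    )

    # --- template fitting + features ---------------------------------------
    ms_df = microstate_feature_frame(
        erps, selection.maps, config.clustering_window, config.feature_window,
        config.ignore_polarity,
    )
    write_features(ms_df, out / "features.csv")
    kept_maps = retained_maps(ms_df, config.map_absence_threshold)

    table = build_feature_table(subjects, ms_df, retained_maps=kept_maps)
    table.to_csv(out / "feature_table.csv", index=False)

    results: dict = {
        "k_opt": selection.k_opt,
        "retained_maps": kept_maps,
        "n_subjects": int(len(subjects)),
    }

    # --- categorical outcome: GA + SVM within the family-history group ------
    if config.run_classifier:
        fh = table.loc[table["group"] != config.reference_group].reset_index(drop=True)
        train, holdout = stratified_split(fh, config.train_fraction, seed=config.ga.seed)
        ga = ga_select(train, config.ga)
        pd.DataFrame(
            sorted(ga.incidence.items()), columns=["feature", "incidence"]
        ).to_csv(out / "incidence.csv", index=False)
        reports = {}
        for name, fset in (
            ("optimal", ga.optimal_set),
            ("high_incidence", ga.high_incidence_set or ga.optimal_set),
        ):
            rep = evaluate_classifier(
                train, holdout, fset, config.n_eval_repetitions, seed=config.ga.seed
            )

            def refit(t: pd.DataFrame, fset=fset, n_tr=len(train)) -> float:
                return _holdout_auc(t.iloc[:n_tr], t.iloc[n_tr:], fset, config.ga.seed)

            stacked = pd.concat([train, holdout], ignore_index=True)
            rep.p_value = shuffle_test(
                _holdout_auc(train, holdout, fset, config.ga.seed),
                refit, stacked, config.n_shuffles, seed=config.ga.seed,
            )
            reports[name] = rep.to_dict()
            reports[name]["ga_warnings"] = list(ga.warnings)
        (out / "classifier_report.json").write_text(
            json.dumps(reports, indent=1, sort_keys=True)
        )
        results["classifier"] = {
            name: {m: reports[name]["metrics"][m]["mean"] for m in reports[name]["metrics"]}
            for name in reports
        }

    # --- dimensional outcome: nested elastic net on the whole sample --------
    if config.run_regression:
        reg = elasticnet_nested(
            table, inner_folds=config.inner_folds, inner_repeats=config.inner_repeats,
            seed=config.ga.seed,
        )
        reg.coefficients.to_csv(out / "coefficients.csv", index=False)
        (out / "regression_report.json").write_text(
            json.dumps(reg.to_dict(), indent=1, sort_keys=True)
        )
        results["regression"] = {"rmse": reg.rmse, "relative_error_pct": reg.relative_error}

    (out / "results_summary.json").write_text(json.dumps(results, indent=1, sort_keys=True))

    timestamps["end"] = time.time()
    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=_config_dict(config), version=__version__,
        checksums=checksums, timestamps=timestamps,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _holdout_auc(train: pd.DataFrame, holdout: pd.DataFrame, feature_set, seed: int) -> float:
    """Single-fit holdout AUC used as the shuffle-test statistic."""
    from sklearn.metrics import roc_auc_score

    from .prediction import _fit_svm

    Xtr = train[list(feature_set)].to_numpy(dtype=float)
    ytr = train["asd_outcome"].to_numpy().astype(int)
    Xho = holdout[list(feature_set)].to_numpy(dtype=float)
    yho = holdout["asd_outcome"].to_numpy().astype(int)
    if len(np.unique(ytr)) < 2 or len(np.unique(yho)) < 2:
        return 0.5
    clf, mu, sd = _fit_svm(Xtr, ytr, "linear", seed)
    return float(roc_auc_score(yho, clf.decision_function((Xho - mu) / sd)))


def _jsonable(obj):
    """Recursively convert to JSON-encodable form (tuple keys -> strings)."""
    if isinstance(obj, dict):
        return {
            "|".join(map(str, k)) if isinstance(k, tuple) else str(k): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _config_dict(config: PipelineConfig) -> dict:
    return _jsonable(dataclasses.asdict(config))
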