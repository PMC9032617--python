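"""End-to-end study orchestration.

``run_full_study`` ties the stages together: simulate the adulteration
design, extract the 17-parameter feature table, fit and evaluate the SIMCA
class models, quantify each adulteration series with PLSR (falling back to
SVR when the Durbin-Watson gate detects nonlinearity), and summarise the
fatty-acid composition table. Every tabular intermediate is written as CSV
and a manifest records the seed, a hash of the configuration and library
versions, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    SimcaClassifier,
    classification_metrics,
    confusion_from_labels,
    overall_accuracy,
    roc_auc,
)
from .composition import compare_printed_categories, load_reference_profiles, unsaturation_ordering, viscosity_correlation
from .config import RunConfig
from .regression_models import QuantifyReport, quantify_pipeline
from .relaxometry import FEATURE_COLUMNS, features_table
from .synthetic_oils import (
    OilSpec,
    default_oil_library,
    generate_study_dataset,
    split_calibration_validation,
    write_decays,
)

__all__ = ["StudyReport", "run_full_study", "simca_stage", "features_stage"]

log = logging.getLogger("oilnmr")


@dataclass
class StudyReport:
    """Bundle returned by :func:`run_full_study`."""

    features: pd.DataFrame
    simca_models: pd.DataFrame        # per-class n, PCs, R2X, Q2, AUC
    simca_metrics: pd.DataFrame       # per-class TPR/FNR/PPV/FDR, cal + val
    calibration_accuracy: float
    validation_accuracy: float
    regression: pd.DataFrame          # PLSR/SVR metrics for SO, CO, RO, pooled
    regression_reports: dict[str, QuantifyReport]
    composition: pd.DataFrame
    manifest: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-12s done in %.1f s", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def _library_with_overrides(config: RunConfig) -> dict[str, OilSpec]:
    library = default_oil_library()
    for name, fields in config.oil_overrides.items():
        base = library.get(name)
        kwargs = {
            "name": name,
            "component_T2": tuple(fields.get("component_T2", base.component_T2 if base else ())),
            "component_fraction": tuple(fields.get("component_fraction", base.component_fraction if base else ())),
            "log_width": fields.get("log_width", base.log_width if base else 0.08),
            "specific_amplitude": fields.get("specific_amplitude", base.specific_amplitude if base else 1.0),
        }
        library[name] = OilSpec(**kwargs)
    return library


@_stage("simulate")
def _simulate(config: RunConfig):
    return generate_study_dataset(
        design=config.design, seed=config.seed,
        library=_library_with_overrides(config), settings=config.acquisition,
    )


@_stage("extract")
def features_stage(decays) -> pd.DataFrame:
    return features_table(decays)


@_stage("classify")
def simca_stage(features: pd.DataFrame, config: RunConfig, seed: int | None = None):
    """Fit SIMCA on the calibration split and evaluate both splits.

    Works on the feature table directly: rows are re-split by series label
    and level using the configured calibration counts.
    """
    seed = config.seed if seed is None else seed
    levels = set(config.design.mixture_levels) | {0.0}
    rows = features[features["level"].round(6).isin({round(l, 6) for l in levels})]
    rows = rows[rows["label"].isin(config.simca_calibration_counts)]

    rng = np.random.default_rng(seed)
    cal_idx: list = []
    for label, want in sorted(config.simca_calibration_counts.items()):
        group = rows[rows["label"] == label]
        if want > len(group):
            raise ValueError(f"group {label!r} has only {len(group)} samples, wanted {want}")
        by_level = [g for _, g in group.groupby("level")]
        base_take, extra = divmod(want, len(by_level))
        order = rng.permutation(len(by_level))
        for rank, i in enumerate(order):
            g = by_level[i]
            take = min(base_take + (1 if rank < extra else 0), len(g))
            sel = rng.permutation(len(g))[:take]
            cal_idx.extend(g.index[sel])
    cal = rows.loc[rows.index.isin(cal_idx)]
    val = rows.loc[~rows.index.isin(cal_idx)]

    clf = SimcaClassifier(n_components=config.simca_n_components,
                          alpha=config.simca_alpha, max_components=config.simca_max_components,
                          q2_folds=config.cv_folds,
                          priority="AO" if "AO" in set(rows["label"]) else None)
    clf.fit(cal[FEATURE_COLUMNS], cal["label"])

    pred_cal = clf.predict(cal[FEATURE_COLUMNS])
    pred_val = clf.predict(val[FEATURE_COLUMNS])
    acc_cal = overall_accuracy(cal["label"], pred_cal)
    acc_val = overall_accuracy(val["label"], pred_val)

    model_rows, metric_rows = [], []
    conf_cal = confusion_from_labels(cal["label"], pred_cal)
    conf_val = confusion_from_labels(val["label"], pred_val)
    for label in clf.classes_:
        m = clf.models_[label]
        in_cal = cal[cal["label"] == label][FEATURE_COLUMNS]
        out_cal = cal[cal["label"] != label][FEATURE_COLUMNS]
        model_rows.append({
            "model": f"SIMCA ({label})", "n": m.n_train, "PCs": m.pca.n_components,
            "R2X": m.pca.r2x_, "Q2": m.q2, "AUC": roc_auc(m, in_cal, out_cal),
            "DCrit": m.dcrit,
        })
        for split_name, conf in (("calibration", conf_cal), ("validation", conf_val)):
            mt = classification_metrics(conf[label])
            metric_rows.append({
                "class": label, "set": split_name,
                "TPR": mt.tpr, "FNR": mt.fnr, "PPV": mt.ppv, "FDR": mt.fdr,
            })
    return clf, pd.DataFrame(model_rows), pd.DataFrame(metric_rows), acc_cal, acc_val, cal, val


@_stage("quantify")
def _quantify(features: pd.DataFrame, config: RunConfig) -> dict[str, QuantifyReport]:
    reports = {}
    for series in list(config.design.adulterants) + ["pooled"]:
        reports[series] = quantify_pipeline(
            features, adulterant=series, max_latent=config.plsr_max_latent,
            folds=config.cv_folds, seed=config.seed,
            include_pure=config.include_pure, svr_grid=config.svr_grid,
            always_fit_svr=True,
        )
    return reports


@_stage("composition")
def _composition() -> pd.DataFrame:
    table = compare_printed_categories()
    profiles = load_reference_profiles()
    orderings = unsaturation_ordering(profiles)
    r_mufa, r_pufa = viscosity_correlation(profiles)
    table = table.copy()
    table["unsaturation_pattern"] = table["oil"].map(orderings)
    table.attrs["viscosity_vs_MUFA_r"] = r_mufa
    table.attrs["viscosity_vs_PUFA_r"] = r_pufa
    return table


def run_full_study(config: RunConfig | None = None, outdir: str | Path | None = None) -> StudyReport:
    """Run simulate -> extract -> classify -> quantify -> composition.

    All tabular intermediates are written under ``outdir`` (defaults to
    ``config.outdir``); the manifest records the seed, a SHA-256 hash of the
    configuration and package/library versions.
    """
    config = config or RunConfig()
    config.validate()
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    decays = _simulate(config)
    if config.write_decays:
        write_decays(decays, outdir / "decays")
    features = features_stage(decays)
    features.to_csv(outdir / "features.csv", index=False)

    clf, models, metrics, acc_cal, acc_val, cal, val = simca_stage(features, config)
    models.to_csv(outdir / "simca_models.csv", index=False)
    metrics.to_csv(outdir / "simca_metrics.csv", index=False)

    reports = _quantify(features, config)
    regression = pd.concat([r.as_rows() for r in reports.values()], ignore_index=True)
    regression.to_csv(outdir / "regression.csv", index=False)

    comp = _composition()
    comp.to_csv(outdir / "composition.csv", index=False)

    import scipy
    import sklearn
    payload = {**asdict(config), "design": asdict(config.design),
               "acquisition": asdict(config.acquisition)}
    payload.pop("outdir", None)  # hash covers scientific parameters only
    config_payload = json.dumps(payload, sort_keys=True, default=str)
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_payload.encode()).hexdigest(),
        "n_samples": len(decays),
        "calibration_accuracy": acc_cal,
        "validation_accuracy": acc_val,
        "versions": {
            "oilnmr": __version__, "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "sklearn": sklearn.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return StudyReport(
        features=features, simca_models=models, simca_metrics=metrics,
        calibration_accuracy=acc_cal, validation_accuracy=acc_val,
        regression=regression, regression_reports=reports,
        composition=comp, manifest=manifest,
    )
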