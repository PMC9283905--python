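"""Configuration-driven experiment orchestration.

One experiment = data source -> windowing -> feature construction ->
(metric learning) -> nested cross-validated nu-SVM evaluation -> per-fold
channel-importance maps -> CSV/JSON/PNG exports. ``run_matrix`` sweeps the
learner x feature x window grid and adds fold-paired t-tests between
learners on identical fold assignments.

All randomness flows from the single experiment seed; identical config and
seed give byte-identical CSV outputs.
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

from .classify import CVResult, HyperGrid, make_learner, nested_cv, paired_fold_test
from .data import Recording, SynthConfig, generate_recording, read_freeform_mat
from .features import (
    EpochSet,
    FeatureMatrix,
    TotalVariancePCA,
    extract_windows,
    fourier_cartesian,
    time_vectorize,
)
from .importance import (
    ImportanceMap,
    channel_importance,
    compose_projection,
    sort_projection,
    topomap_export,
)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "run_matrix", "build_features"]

_FEATURES = ("F1A", "F1B", "F2")
_LEARNERS = ("euclidean", "ceml", "egml", "nca")
_WINDOWS = ("pre", "move")
_SVM_KINDS = ("linear", "gaussian")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment cell."""

    data: dict | str = field(default_factory=dict)  # SynthConfig kwargs or MAT path
    window: str = "move"
    feature: str = "F1B"
    learner: str = "euclidean"
    svm: str = "linear"
    seed: int = 0
    out_dir: str = "results"
    d_pc: tuple = (30,)
    p: tuple = (3,)
    nu: tuple = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.8)
    sigma_svm_scales: tuple = (5.0, 1.0, 0.5, 0.25, 0.05)
    n_outer: int = 10
    n_inner: int = 10
    learner_kwargs: dict = field(default_factory=dict)
    render_topomaps: bool = True

    def __post_init__(self):
        if self.window not in _WINDOWS:
            raise ValueError(f"window must be one of {_WINDOWS}, got {self.window!r}")
        if self.feature not in _FEATURES:
            raise ValueError(f"feature must be one of {_FEATURES}, got {self.feature!r}")
        if self.learner not in _LEARNERS:
            raise ValueError(f"learner must be one of {_LEARNERS}, got {self.learner!r}")
        if self.svm not in _SVM_KINDS:
            raise ValueError(f"svm must be one of {_SVM_KINDS}, got {self.svm!r}")

    def grid(self) -> HyperGrid:
        return HyperGrid(
            d_pc=tuple(self.d_pc),
            p=tuple(self.p),
            nu=tuple(self.nu),
            sigma_svm_scales=tuple(self.sigma_svm_scales),
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_recording(cfg: ExperimentConfig) -> Recording:
    if isinstance(cfg.data, str):
        return read_freeform_mat(cfg.data)
    kwargs = dict(cfg.data)
    kwargs.setdefault("seed", cfg.seed)
    return generate_recording(SynthConfig(**kwargs))


def build_features(ep: EpochSet, feature: str) -> FeatureMatrix:
    """Vectorize an epoch set by feature kind (F1A, F1B or F2)."""
    if feature == "F1A":
        return fourier_cartesian(ep, band="full")
    if feature == "F1B":
        return fourier_cartesian(ep, band="0to5")
    if feature == "F2":
        return time_vectorize(ep)
    raise ValueError(f"unknown feature kind {feature!r}")


def _fold_importance(fm: FeatureMatrix, cfg: ExperimentConfig, result: CVResult):
    """Refit the selected pipeline per outer fold and average the importance."""
    from sklearn.model_selection import StratifiedKFold

    outer = StratifiedKFold(
        n_splits=cfg.n_outer, shuffle=True, random_state=cfg.seed
    )
    per_fold = []
    p_ref = None
    for (tr, _), chosen in zip(outer.split(fm.X, fm.labels), result.chosen_params):
        X_tr, y_tr = fm.X[tr], fm.labels[tr]
        d_pc = chosen["d_pc"]
        if d_pc != "rank":
            d_pc = min(int(d_pc), min(X_tr.shape[0] - 1, X_tr.shape[1]))
        pca = TotalVariancePCA(n_components=d_pc).fit(X_tr)
        Z = pca.transform(X_tr)
        if cfg.learner == "euclidean":
            learner = make_learner("euclidean", 0, cfg.seed).fit(Z, y_tr)
        else:
            p_eff = min(int(chosen["p"]), Z.shape[1])
            learner = make_learner(
                cfg.learner, p_eff, cfg.seed, **cfg.learner_kwargs
            ).fit(Z, y_tr)
        sp = sort_projection(compose_projection(pca, learner))
        imp = channel_importance(sp, fm.channel_index_map)
        if p_ref is None:
            p_ref = imp.per_dim.shape[1]
        per_fold.append(imp)
    p_min = min(m.per_dim.shape[1] for m in per_fold)
    per_dim = np.mean([m.per_dim[:, :p_min] for m in per_fold], axis=0)
    return ImportanceMap(
        per_dim=per_dim,
        overall=np.mean([m.overall for m in per_fold], axis=0),
        channels=per_fold[0].channels,
        provenance={"n_folds": len(per_fold), "learner": cfg.learner},
    )


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run one experiment cell and write its result bundle.

    Returns a dict with the ``CVResult``, the fold-averaged importance map
    and the paths written.
    """
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage=data source=%s", cfg.data if isinstance(cfg.data, str) else "synthetic")
    rec = _load_recording(cfg)
    logger.info("stage=windows window=%s", cfg.window)
    ep = extract_windows(rec, cfg.window)
    logger.info("stage=features kind=%s", cfg.feature)
    fm = build_features(ep, cfg.feature)

    logger.info("stage=nested_cv learner=%s svm=%s", cfg.learner, cfg.svm)
    result = nested_cv(
        fm.X,
        fm.labels,
        learner=cfg.learner,
        grid=cfg.grid(),
        svm_kind=cfg.svm,
        seed=cfg.seed,
        n_outer=cfg.n_outer,
        n_inner=cfg.n_inner,
        learner_kwargs=cfg.learner_kwargs,
    )
    logger.info(
        "stage=nested_cv done mean=%.4f sd=%.4f", result.mean, result.sd
    )

    logger.info("stage=importance")
    imp = _fold_importance(fm, cfg, result)

    stem = f"{cfg.learner}_{cfg.feature}_{cfg.window}_{cfg.svm}"
    paths = []
    cv_json = out / f"cv_{stem}.json"
    cv_json.write_text(
        json.dumps(
            {
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
                "learner": cfg.learner,
                "feature": cfg.feature,
                "window": cfg.window,
                "svm": cfg.svm,
                "fold_accuracies": result.fold_accuracies.tolist(),
                "mean": result.mean,
                "sd": result.sd,
                "chosen_params": result.chosen_params,
            },
            indent=2,
        )
    )
    paths.append(cv_json)
    cv_csv = out / f"cv_{stem}.csv"
    pd.DataFrame(
        {
            "fold": np.arange(1, len(result.fold_accuracies) + 1),
            "accuracy": result.fold_accuracies,
            "chosen": [json.dumps(c) for c in result.chosen_params],
        }
    ).to_csv(cv_csv, index=False)
    paths.append(cv_csv)
    if cfg.render_topomaps:
        paths.extend(topomap_export(imp, out, stem=f"importance_{stem}"))
    else:
        table = pd.DataFrame({"channel": list(imp.channels), "overall": imp.overall})
        csv_path = out / f"importance_{stem}.csv"
        table.to_csv(csv_path, index=False)
        paths.append(csv_path)
    logger.info("stage=done elapsed=%.1fs", time.perf_counter() - t0)
    return {"cv": result, "importance": imp, "paths": paths, "config": cfg}


def run_matrix(
    base: ExperimentConfig,
    learners=_LEARNERS,
    features=_FEATURES,
    windows=_WINDOWS,
) -> dict:
    """Sweep learners x features x windows; emit summary + paired t-tests.

    Cells that fail are logged and skipped; the rest continue. Within a
    (feature, window) cell all learners share the fold assignment, so the
    paired test across outer folds is valid.
    """
    from dataclasses import replace

    rows, bundles = [], {}
    for window in windows:
        for feature in features:
            for learner in learners:
                cfg = replace(
                    base, learner=learner, feature=feature, window=window
                )
                try:
                    bundle = run_experiment(cfg)
                except Exception:
                    logger.exception(
                        "cell failed: %s/%s/%s", learner, feature, window
                    )
                    continue
                res = bundle["cv"]
                bundles[(learner, feature, window)] = bundle
                rows.append(
                    {
                        "window": window,
                        "feature": feature,
                        "learner": learner,
                        "svm": base.svm,
                        "mean_accuracy": res.mean,
                        "sd_accuracy": res.sd,
                    }
                )
    summary = pd.DataFrame(rows)

    tests = []
    for window in windows:
        for feature in features:
            present = [
                l for l in learners if (l, feature, window) in bundles
            ]
            for i, la in enumerate(present):
                for lb in present[i + 1 :]:
                    t, p = paired_fold_test(
                        bundles[(la, feature, window)]["cv"],
                        bundles[(lb, feature, window)]["cv"],
                    )
                    tests.append(
                        {
                            "window": window,
                            "feature": feature,
                            "learner_a": la,
                            "learner_b": lb,
                            "t": t,
                            "p_value": p,
                        }
                    )
    paired = pd.DataFrame(tests)

    out = Path(base.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "matrix_summary.csv", index=False)
    paired.to_csv(out / "matrix_paired_tests.csv", index=False)
    return {"summary": summary, "paired_tests": paired, "bundles": bundles}
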