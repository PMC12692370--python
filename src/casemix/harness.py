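"""Desk-scale orchestration of the full case-mix study.

One :class:`RunConfig` drives the pipeline: synthesise (or load) a cohort,
split it into development and validation samples, expand diagnostic
categories into homogeneous groups on the full cohort, build the design, fit
the four statistical models on the development sample, and score everything
on the validation sample with the shared metrics panel.  Sensitivity toggles
(hierarchy imposition, deeper subdivision, alternative splits, sex exclusion)
re-run the same pipeline and report metric deltas.  Gradient-boosting /
random-forest adapters are optional, isolated glue over the same design and
the same metrics code path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import synthetic
from .design import build_design
from .grouper import expand_categories, impose_hierarchy, rank_groups_by_mean_cost
from .metrics import MetricReport, metrics_panel, metrics_row, r_squared
from .models import (FitResult, fit_boxcox, fit_gamma_log, fit_loglinear,
                     fit_ols, smearing_predict, stepwise_select)
from .synthetic import CohortSpec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "split_cohort", "run_statistical_comparison",
           "run_ml_comparison", "run_sensitivity_suite", "StudyReport"]

STATISTICAL_MODELS = ("ols", "gamma_log", "loglinear", "boxcox")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    split_fractions: tuple[float, float] = (0.5, 0.5)
    split_seed: int = 0
    threshold: int | None = None            # absolute distinct-patient threshold
    threshold_fraction: float = 0.003       # used when threshold is None
    max_depth: int = 4
    hierarchy: bool = False
    lambda_grid: tuple[float, ...] | None = None
    lambda_selection: str = "validation_r2_raw"
    smearing_points: int | None = 512
    stepwise: bool = False
    alpha_entry: float = 0.05
    alpha_stay: float = 0.05
    models: tuple[str, ...] = STATISTICAL_MODELS
    include_sex: bool = True
    ml_params: dict = field(default_factory=lambda: {
        # published boosting settings: iterations 1000, lr 0.1, depth 6,
        # squared-error loss
        "iterations": 1000, "learning_rate": 0.1, "depth": 6, "seed": 0,
    })

    def __post_init__(self):
        fr = self.split_fractions
        if any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Panel plus provenance for one run."""

    panel: MetricReport
    n_groups: int
    selected_lambda: float | None
    clamp_counts: dict[str, int]
    dev_val_r2_gap: dict[str, float]
    config_hash: str
    seed: int
    fits: dict[str, FitResult]
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_groups": self.n_groups,
            "selected_lambda": self.selected_lambda,
            "clamp_counts": self.clamp_counts,
            "dev_val_r2_gap": self.dev_val_r2_gap,
            "panel": self.panel.table.to_dict(orient="records"),
        }, indent=2)


def split_cohort(patients: pd.DataFrame, fractions=(0.5, 0.5), seed: int = 0):
    """Random disjoint, exhaustive split; sizes within 1 of n*fraction."""
    n = len(patients)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    fractions = tuple(fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = [int(np.floor(f * n)) for f in fractions]
    for i in range(n - sum(sizes)):  # distribute the remainder
        sizes[i % len(sizes)] += 1
    parts, start = [], 0
    for s in sizes:
        idx = np.sort(perm[start:start + s])
        parts.append(patients.iloc[idx].reset_index(drop=True))
        start += s
    return tuple(parts)


def _prepare(config: RunConfig, cohort=None, code_map=None):
    """Cohort -> grouping -> design, shared by all run_* entry points."""
    if cohort is None:
        code_map = synthetic.build_code_universe(config.cohort_spec)
        cohort, truth = synthetic.sample_cohort(config.cohort_spec, code_map)
    else:
        truth = None
        if code_map is None:
            raise ValueError("a code_map is required with a user-supplied cohort")

    grouping = expand_categories(cohort, code_map, threshold=config.threshold,
                                 max_depth=config.max_depth,
                                 threshold_fraction=config.threshold_fraction)
    dev, val = split_cohort(cohort, config.split_fractions, config.split_seed)
    if config.hierarchy:
        ranking = rank_groups_by_mean_cost(grouping, dev)
        grouping = impose_hierarchy(grouping, ranking)

    design = build_design(cohort, grouping, include_sex=config.include_sex)
    pos = {pid: i for i, pid in enumerate(design.patient_ids)}
    dev_mask = np.zeros(len(cohort), dtype=bool)
    dev_mask[[pos[p] for p in dev["patient_id"]]] = True
    X_dev, X_val = design.subset(dev_mask), design.subset(~dev_mask)
    y_dev = dev["cost"].to_numpy(dtype=float)
    y_val = val["cost"].to_numpy(dtype=float)
    # subset() preserves cohort row order, and dev/val are sorted subsets of it
    assert X_dev.patient_ids == list(dev["patient_id"])
    assert X_val.patient_ids == list(val["patient_id"])
    return cohort, truth, grouping, X_dev, y_dev, X_val, y_val


def _dev_val_gap(fit, X_dev, y_dev, X_val, y_val) -> float:
    """|R² development − R² validation| on the model's own estimation scale.

    OLS: raw dollars; loglinear/boxcox: the transformed outcome; gamma_log:
    deviance pseudo-R² (1 − residual/null deviance), its natural fit
    statistic.  Raw-scale R² for the transformed families is dominated by a
    handful of extreme patients and is not a stable overfitting diagnostic.
    """
    from .models import box_cox

    if fit.family == "ols":
        a = r_squared(y_dev, fit.linpred(X_dev))
        b = r_squared(y_val, fit.linpred(X_val))
    elif fit.family in ("loglinear", "boxcox"):
        lam = 0.0 if fit.family == "loglinear" else float(fit.lam)
        a = r_squared(box_cox(y_dev, lam), fit.linpred(X_dev))
        b = r_squared(box_cox(y_val, lam), fit.linpred(X_val))
    else:  # gamma_log

        def pseudo_r2(y, eta):
            mu = np.exp(eta)
            dev = 2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu)
            mu0 = np.mean(y)
            dev0 = 2.0 * np.sum(-np.log(y / mu0) + (y - mu0) / mu0)
            return 1.0 - dev / dev0

        a = pseudo_r2(y_dev, fit.linpred(X_dev))
        b = pseudo_r2(y_val, fit.linpred(X_val))
    return abs(a - b)


def run_statistical_comparison(config: RunConfig, cohort=None, code_map=None) -> StudyReport:
    """Fit the four statistical models on development, score on validation."""
    cohort, truth, grouping, X_dev, y_dev, X_val, y_val = _prepare(config, cohort, code_map)
    logger.info("run: n=%d, %d groups (T=%d), design %s", len(cohort),
                grouping.n_groups, grouping.threshold_used, X_dev.shape)

    if config.stepwise:
        keep = stepwise_select(X_dev, y_dev, config.alpha_entry, config.alpha_stay)
        drop = [c for c in X_dev.columns if c not in keep]
        X_dev, X_val = X_dev.drop_columns(drop), X_val.drop_columns(drop)
        logger.info("stepwise retained %d of %d columns", len(keep), len(keep) + len(drop))

    fits: dict[str, FitResult] = {}
    for name in config.models:
        if name == "ols":
            fits[name] = fit_ols(X_dev, y_dev)
        elif name == "gamma_log":
            fits[name] = fit_gamma_log(X_dev, y_dev)
        elif name == "loglinear":
            fits[name] = fit_loglinear(X_dev, y_dev)
        elif name == "boxcox":
            fits[name] = fit_boxcox(
                X_dev, y_dev, lambda_grid=config.lambda_grid,
                selection=config.lambda_selection,
                validation_data=(X_val, y_val) if config.lambda_selection != "profile_likelihood" else None,
                smearing_points=config.smearing_points)
        else:
            raise ValueError(f"unknown model {name!r}")

    panel = metrics_panel(fits, X_val, y_val)
    gaps = {name: _dev_val_gap(fit, X_dev, y_dev, X_val, y_val)
            for name, fit in fits.items()}
    lam = fits["boxcox"].lam if "boxcox" in fits else None
    return StudyReport(
        panel=panel, n_groups=grouping.n_groups, selected_lambda=lam,
        clamp_counts={k: f.clamp_count for k, f in fits.items()},
        dev_val_r2_gap=gaps, config_hash=config.config_hash(),
        seed=config.cohort_spec.seed, fits=fits,
        extras={"threshold_used": grouping.threshold_used,
                "design_columns": list(X_dev.columns), "truth": truth},
    )


# ---------------------------------------------------------------------------
# optional machine-learning adapters

def _ml_adapters(params: dict) -> dict:
    """Name -> factory for each available regressor; missing libraries are
    skipped with a logged notice, never an error."""
    seed = int(params.get("seed", 0))
    iters = int(params.get("iterations", 1000))
    lr = float(params.get("learning_rate", 0.1))
    depth = int(params.get("depth", 6))
    adapters = {}
    try:
        from sklearn.ensemble import RandomForestRegressor
        adapters["random_forest"] = lambda: RandomForestRegressor(
            n_estimators=min(iters, 200), max_depth=None, random_state=seed, n_jobs=1)
    except ImportError:
        logger.warning("scikit-learn unavailable; skipping random_forest")
    try:
        import lightgbm
        adapters["lightgbm"] = lambda: lightgbm.LGBMRegressor(
            n_estimators=iters, learning_rate=lr, max_depth=depth,
            objective="regression", random_state=seed, n_jobs=1, verbose=-1)
    except ImportError:
        logger.warning("lightgbm unavailable; skipping lightgbm")
    try:
        import xgboost
        adapters["xgboost"] = lambda: xgboost.XGBRegressor(
            n_estimators=iters, learning_rate=lr, max_depth=depth,
            objective="reg:squarederror", random_state=seed, n_jobs=1,
            verbosity=0)
    except ImportError:
        logger.warning("xgboost unavailable; skipping xgboost")
    try:
        import catboost
        adapters["catboost"] = lambda: catboost.CatBoostRegressor(
            iterations=iters, learning_rate=lr, depth=depth,
            loss_function="RMSE", random_seed=seed, verbose=False)
    except ImportError:
        logger.warning("catboost unavailable; skipping catboost")
    return adapters


def run_ml_comparison(config: RunConfig, cohort=None, code_map=None,
                      perturb: float | None = None) -> StudyReport:
    """Train the available tree-ensemble regressors on the development design
    and raw-dollar outcome; score with the identical metrics code path.

    ``perturb`` optionally varies the numeric hyperparameters by the given
    fraction (e.g. 0.1 for the +/-10% sweep) and keeps, per model, the
    variant with the best validation raw R².
    """
    cohort, truth, grouping, X_dev, y_dev, X_val, y_val = _prepare(config, cohort, code_map)
    variants = [1.0] if not perturb else [1.0 - perturb, 1.0, 1.0 + perturb]

    rows = []
    chosen: dict[str, dict] = {}
    for name, factory in _ml_adapters(config.ml_params).items():
        best = None
        for scale in variants:
            params = dict(config.ml_params)
            params["iterations"] = max(1, int(round(params.get("iterations", 1000) * scale)))
            params["learning_rate"] = params.get("learning_rate", 0.1) * scale
            model = _ml_adapters(params)[name]()
            model.fit(X_dev.values, y_dev)
            yhat = np.asarray(model.predict(X_val.values), dtype=float)
            row = metrics_row(y_val, yhat, p=X_dev.shape[1] - 1)
            if best is None or row["r2"] > best[0]["r2"]:
                best = (row, params, scale)
        row, params, scale = best
        chosen[name] = {"params": params, "variant_scale": scale}
        rows.append({"model": name, "scale": "raw", **row,
                     "n": len(y_val), "p": X_dev.shape[1] - 1,
                     "not_applicable": False})

    panel = MetricReport(table=pd.DataFrame(rows))
    return StudyReport(panel=panel, n_groups=grouping.n_groups,
                       selected_lambda=None, clamp_counts={}, dev_val_r2_gap={},
                       config_hash=config.config_hash(),
                       seed=config.cohort_spec.seed, fits={},
                       extras={"hyperparameters": chosen})


def run_sensitivity_suite(config: RunConfig, cohort=None, code_map=None) -> dict:
    """Base run plus the study's sensitivity toggles, with raw-R² deltas.

    Toggles: hierarchy imposition, subdivision to the fifth character,
    60/40 and 80/20 development/validation splits, and sex exclusion.
    """
    base = run_statistical_comparison(config, cohort, code_map)

    variants = {
        "hierarchy": replace(config, hierarchy=True),
        "max_depth_5": replace(config, max_depth=5),
        "split_60_40": replace(config, split_fractions=(0.6, 0.4)),
        "split_80_20": replace(config, split_fractions=(0.8, 0.2)),
        "exclude_sex": replace(config, include_sex=False),
    }
    out = {"base": base, "variants": {}, "deltas": {}}
    for name, cfg in variants.items():
        rep = run_statistical_comparison(cfg, cohort, code_map)
        out["variants"][name] = rep
        out["deltas"][name] = {
            m: rep.panel.cell(m, "raw", "r2") - base.panel.cell(m, "raw", "r2")
            for m in config.models
        }
    return out
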