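"""Concurrent cost models for heavily skewed healthcare expenditures.

Four model families are supported, all on the same design matrix:

* **OLS** on raw dollars.
* **Gamma GLM with log link**, the textbook choice for positive, right-skewed
  cost data; fitted by IRLS (for the log link the working weights are
  identically one, so each iteration is an OLS solve on the adjusted
  response).  Predictions are ``exp(x'b)`` — the link inverse is the
  conditional mean, no retransformation needed.
* **Log-linear**: OLS on ``ln y``.
* **Box-Cox**: OLS on the power-transformed outcome ``z = (y^l - 1)/l``
  (``ln y`` at ``l = 0``); the transform parameter is chosen by grid search,
  by default maximising validation-sample R-squared on the raw dollar scale.

For the transformed-outcome families, raw-dollar predictions use **Duan's
nonparametric smearing estimator**: the retransformed prediction at x is the
average of the inverse transform of ``x'b + e_i`` over the development-sample
residuals ``e_i``, which corrects the retransformation bias of simply
inverting the fitted value without assuming normal errors.

All fits are exact linear algebra (QR), hence deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .design import DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult", "box_cox", "inv_box_cox", "fit_ols", "fit_loglinear",
    "fit_gamma_log", "fit_boxcox", "smearing_predict", "stepwise_select",
    "default_lambda_grid",
]

FAMILIES = ("ols", "gamma_log", "loglinear", "boxcox")

# floor applied to l*z + 1 before inversion when smearing wanders outside the
# transform's domain; each clamp is counted on the fit
_DOMAIN_FLOOR = 1e-6


@dataclass
class FitResult:
    """A fitted cost model.

    ``residuals`` are transformed-scale development residuals (the smearing
    set) for ols/loglinear/boxcox, and working-scale residuals for gamma_log
    (kept for diagnostics; gamma predictions never smear).
    """

    family: str
    coef: np.ndarray
    columns: list[str]
    lam: float | None
    residuals: np.ndarray
    n_dev: int
    clamp_count: int = 0
    extras: dict = field(default_factory=dict)

    def linpred(self, X) -> np.ndarray:
        values, cols = _unpack(X)
        if cols != self.columns:
            idx = {c: i for i, c in enumerate(cols)}
            missing = [c for c in self.columns if c not in idx]
            if missing:
                raise ValueError(f"design lacks fitted columns {missing[:5]}")
            values = values[:, [idx[c] for c in self.columns]]
        return values @ self.coef


def _unpack(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, DesignMatrix):
        return X.values, X.columns
    values = np.asarray(X, dtype=float)
    return values, [f"x{i}" for i in range(values.shape[1])]


def box_cox(y, lam: float) -> np.ndarray:
    """Box-Cox power transform ``(y^l - 1)/l`` (``ln y`` at ``l = 0``)."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("box_cox requires strictly positive y")
    return special.boxcox(y, lam)


def inv_box_cox(z, lam: float, clamp_counter: list | None = None) -> np.ndarray:
    """Inverse Box-Cox; out-of-domain points (``l*z + 1 <= 0``) are clamped
    to a small positive floor and counted into ``clamp_counter[0]`` if given."""
    z = np.asarray(z, dtype=float)
    if lam == 0.0:
        return np.exp(z)
    base = lam * z + 1.0
    bad = base <= 0.0
    if bad.any():
        if clamp_counter is not None:
            clamp_counter[0] += int(bad.sum())
        base = np.where(bad, _DOMAIN_FLOOR, base)
    return np.power(base, 1.0 / lam)


def _qr_fit(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares via QR with an explicit rank check."""
    q, r = np.linalg.qr(values)
    diag = np.abs(np.diag(r))
    tol = max(values.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if np.any(diag <= tol):
        bad = np.flatnonzero(diag <= tol)
        raise np.linalg.LinAlgError(
            f"design is rank deficient; dependent columns at positions {bad.tolist()}"
        )
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - values @ beta
    return beta, resid


def fit_ols(X, y) -> FitResult:
    """Ordinary least squares on the raw-dollar outcome."""
    values, cols = _unpack(X)
    y = np.asarray(y, dtype=float)
    if values.shape[0] != len(y):
        raise ValueError("X and y have different numbers of rows")
    beta, resid = _qr_fit(values, y)
    return FitResult(family="ols", coef=beta, columns=cols, lam=None,
                     residuals=resid, n_dev=len(y))


def fit_loglinear(X, y) -> FitResult:
    """OLS on ``ln y``; raw-scale predictions go through smearing."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("fit_loglinear requires strictly positive y")
    fit = fit_ols(X, np.log(y))
    fit.family = "loglinear"
    fit.lam = 0.0
    return fit


def fit_gamma_log(X, y, max_iter: int = 100, tol: float = 1e-10) -> FitResult:
    """Gamma GLM with log link via IRLS.

    With a log link the GLM working weights ``1/(V(mu) g'(mu)^2)`` equal one,
    so each IRLS step is an unweighted OLS solve on the working response
    ``eta + (y - mu)/mu``.  Convergence: relative deviance change < ``tol``.
    The Pearson-based dispersion is profiled after convergence; it affects
    neither the coefficients nor the predictions ``exp(x'b)``.
    """
    values, cols = _unpack(X)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("fit_gamma_log requires strictly positive y")

    eta = np.log(np.clip(y, np.percentile(y, 1), None))  # robust start
    q, r = np.linalg.qr(values)
    deviance_trace: list[float] = []
    prev = np.inf
    for it in range(max_iter):
        mu = np.exp(eta)
        work = eta + (y - mu) / mu
        beta = np.linalg.solve(r, q.T @ work)
        eta = values @ beta
        mu = np.exp(eta)
        dev = 2.0 * float(np.sum(-np.log(y / mu) + (y - mu) / mu))
        deviance_trace.append(dev)
        if np.isfinite(prev) and abs(prev - dev) <= tol * (abs(prev) + 1e-12):
            mu = np.exp(values @ beta)
            pearson = float(np.sum(((y - mu) / mu) ** 2) / max(1, len(y) - len(cols)))
            return FitResult(family="gamma_log", coef=beta, columns=cols, lam=None,
                             residuals=np.log(y) - eta, n_dev=len(y),
                             extras={"deviance": dev, "dispersion": pearson,
                                     "iterations": it + 1,
                                     "deviance_trace": deviance_trace})
        prev = dev
    raise RuntimeError(
        f"gamma IRLS did not converge in {max_iter} iterations; "
        f"deviance trace: {deviance_trace[-5:]}"
    )


def default_lambda_grid(step: float = 0.02) -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


def smearing_predict(fit: FitResult, X_new, smearing_points: int | None = None,
                     chunk_elems: int = 5_000_000) -> np.ndarray:
    """Raw-dollar predictions for any fitted family (one entry point).

    For loglinear/boxcox the Duan smearing estimator is used:
    ``yhat_j = mean_i inv_transform(x_j'b + e_i)`` over the development
    residuals.  ``smearing_points`` optionally replaces the full residual set
    by that many empirical quantiles (midpoint grid) — an accuracy-preserving
    reduction used during lambda grid search.  Domain clamps are counted onto
    ``fit.clamp_count``.  OLS returns ``x'b``; gamma_log returns ``exp(x'b)``.
    """
    eta = fit.linpred(X_new)
    if fit.family == "ols":
        return eta
    if fit.family == "gamma_log":
        return np.exp(eta)
    if fit.family not in ("loglinear", "boxcox"):
        raise ValueError(f"unknown family {fit.family!r}")
    e = np.asarray(fit.residuals, dtype=float)
    if e.size == 0:
        raise ValueError("empty smearing residual set")
    if smearing_points is not None and smearing_points < e.size:
        probs = (np.arange(smearing_points) + 0.5) / smearing_points
        e = np.quantile(e, probs)
    lam = 0.0 if fit.family == "loglinear" else float(fit.lam)
    counter = [0]
    out = np.empty(eta.shape[0])
    step = max(1, chunk_elems // max(1, e.size))
    for start in range(0, eta.shape[0], step):
        block = eta[start:start + step, None] + e[None, :]
        out[start:start + step] = inv_box_cox(block, lam, counter).mean(axis=1)
    fit.clamp_count += counter[0]
    return out


def _score_raw(metric: str, y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if metric == "r2":
        sst = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum((y - yhat) ** 2)) / sst
    if metric == "pve":
        return 1.0 - float(np.sum(np.abs(y - yhat))) / float(np.sum(np.abs(y - y.mean())))
    raise ValueError(metric)


def fit_boxcox(X, y, lambda_grid=None, selection: str = "validation_r2_raw",
               validation_data=None, smearing_points: int | None = 512) -> FitResult:
    """Box-Cox regression with data-driven transform parameter.

    For each candidate lambda the outcome is transformed, OLS-fitted on the
    development sample and, for the validation criteria, smearing-predicted
    on the validation sample and scored on the raw dollar scale.  The fit at
    the arg-max lambda is returned (ties to the smaller lambda).  Criteria:
    ``validation_r2_raw`` (default), ``validation_pve_raw``, or
    ``profile_likelihood`` (the classical Box-Cox normal profile
    log-likelihood on the development sample; needs no validation data).
    """
    values, cols = _unpack(X)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("fit_boxcox requires strictly positive y")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda_grid is empty")
    if selection in ("validation_r2_raw", "validation_pve_raw"):
        if validation_data is None:
            raise ValueError(f"selection {selection!r} requires validation_data")
        X_val, y_val = validation_data
        y_val = np.asarray(y_val, dtype=float)
    elif selection != "profile_likelihood":
        raise ValueError(f"unknown selection {selection!r}")

    q, r = np.linalg.qr(values)
    diag = np.abs(np.diag(r))
    tol = max(values.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if np.any(diag <= tol):
        raise np.linalg.LinAlgError("design is rank deficient")
    log_y_sum = float(np.sum(np.log(y)))
    n = len(y)

    best_lam, best_score, best = None, -np.inf, None
    scores: dict[float, float] = {}
    for lam in grid:
        z = box_cox(y, lam)
        beta = np.linalg.solve(r, q.T @ z)
        resid = z - values @ beta
        cand = FitResult(family="boxcox", coef=beta, columns=cols, lam=float(lam),
                         residuals=resid, n_dev=n)
        if selection == "profile_likelihood":
            sse = float(resid @ resid)
            score = -0.5 * n * np.log(sse / n) + (lam - 1.0) * log_y_sum
        else:
            yhat = smearing_predict(cand, X_val, smearing_points=smearing_points)
            metric = "r2" if selection == "validation_r2_raw" else "pve"
            score = _score_raw(metric, y_val, yhat)
        scores[float(lam)] = float(score)
        if score > best_score:  # strict: ties keep the earlier (smaller) lambda
            best_lam, best_score, best = float(lam), float(score), cand
    best.extras = {"lambda_grid": [float(v) for v in grid],
                   "lambda_scores": scores, "selection": selection,
                   "selected_score": best_score,
                   "smearing_points": smearing_points}
    logger.info("boxcox: selected lambda=%.3f (%s=%.4f)", best_lam, selection, best_score)
    return best


def stepwise_select(X, y, alpha_entry: float = 0.05, alpha_stay: float = 0.05,
                    direction: str = "stepwise") -> list[str]:
    """Classical partial-F/t stepwise selection on the OLS fit.

    The intercept is always retained.  Entry picks the candidate with the
    smallest partial-F p-value below ``alpha_entry``; removal drops the
    in-model term with the largest p-value above ``alpha_stay``.  Ties break
    on column order, so the procedure is deterministic.
    """
    if direction not in ("forward", "backward", "stepwise"):
        raise ValueError(f"unknown direction {direction!r}")
    values, cols = _unpack(X)
    y = np.asarray(y, dtype=float)
    if "intercept" in cols:
        base = ["intercept"]
    else:
        base = [cols[0]]  # first column plays the role of the intercept
    candidates = [c for c in cols if c not in base]
    idx = {c: i for i, c in enumerate(cols)}

    def sse_of(sel: list[str]) -> float:
        v = values[:, [idx[c] for c in sel]]
        _, resid = _qr_fit(v, y)
        return float(resid @ resid)

    def partial_f_p(sse_small: float, sse_big: float, df_diff: int, df_resid: int) -> float:
        if sse_big <= 0:
            return 0.0
        f = ((sse_small - sse_big) / df_diff) / (sse_big / df_resid)
        return float(stats.f.sf(max(f, 0.0), df_diff, df_resid))

    n = len(y)
    if direction == "backward":
        selected = base + candidates
    else:
        selected = list(base)

    while True:
        changed = False
        if direction in ("forward", "stepwise"):
            sse_cur = sse_of(selected)
            best_p, best_c = None, None
            for c in candidates:
                if c in selected:
                    continue
                trial = selected + [c]
                try:
                    sse_new = sse_of(trial)
                except np.linalg.LinAlgError:
                    continue
                p = partial_f_p(sse_cur, sse_new, 1, n - len(trial))
                if best_p is None or p < best_p:
                    best_p, best_c = p, c
            if best_c is not None and best_p < alpha_entry:
                selected.append(best_c)
                changed = True
        if direction in ("backward", "stepwise") and len(selected) > len(base):
            sse_cur = sse_of(selected)
            worst_p, worst_c = None, None
            for c in selected:
                if c in base:
                    continue
                trial = [s for s in selected if s != c]
                p = partial_f_p(sse_of(trial), sse_cur, 1, n - len(selected))
                if worst_p is None or p > worst_p:
                    worst_p, worst_c = p, c
            if worst_c is not None and worst_p > alpha_stay:
                selected.remove(worst_c)
                changed = True
        if not changed:
            break
    return [c for c in cols if c in selected]
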