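"""Predictor screening: bidirectional stepwise OLS and a small
L1-penalized tanh network with permutation variable importance.

The stepwise engine mirrors the classic agronomic-statistics procedure:
candidates enter one at a time on the smallest partial-F p-value (if at
most ``entry_p``), retained terms with p above ``stay_p`` are removed,
AIC is tracked after every accepted change, and the minimum-AIC model
on the visited path is returned.  AIC uses the linear-model form
``n*ln(SSE/n) + 2*(k+1)`` (intercept counted), in which constant
offsets cancel across comparisons.  Ties are broken alphabetically by
term name, which makes the procedure invariant to candidate column
order.

The neural predictor is a single hidden layer of tanh units with a
linear output, trained by penalized least squares with an absolute
(L1) weight penalty, multiple random restarts and a random holdback
validation split; the restart with the lowest validation RMSE is kept.
Variable importance is permutation-based: the *main* effect of a
predictor is the share of prediction variance attributable to it alone
(others jointly permuted), the *total* effect the share destroyed when
the predictor itself is permuted, so total >= main by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSelectionError",
    "StepwiseResult",
    "stepwise_select",
    "NeuralModel",
    "fit_neural",
    "variable_importance",
]

logger = logging.getLogger(__name__)

#: Floor on SSE/n inside the AIC log, guarding perfect fits.
_AIC_MSE_FLOOR = 1e-300


class ModelSelectionError(ValueError):
    """Degenerate inputs to selection or network training."""


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepwiseResult:
    """Outcome of a bidirectional stepwise search."""

    selected_terms: tuple[str, ...]
    coefficients: dict[str, float]
    aic_path: tuple[float, ...]
    entry_p: float
    stay_p: float
    final_rmse: float
    final_adj_r2: float
    pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return min(self.aic_path)


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _design(n: int, cols: list[np.ndarray]) -> np.ndarray:
    return np.column_stack([np.ones(n)] + cols)


def _aic(n: int, sse: float, n_terms: int) -> float:
    return n * math.log(max(sse / n, _AIC_MSE_FLOOR)) + 2.0 * (n_terms + 1)


def _partial_f_p(sse_small: float, sse_big: float, df_resid_big: int) -> float:
    """p-value of the 1-df partial F test comparing nested OLS fits."""
    if df_resid_big <= 0:
        return 1.0
    mse_big = sse_big / df_resid_big
    if mse_big <= 0:
        return 0.0
    f = max(sse_small - sse_big, 0.0) / mse_big
    return float(stats.f.sf(f, 1, df_resid_big))


def stepwise_select(
    response,
    candidates: pd.DataFrame,
    entry_p: float = 0.15,
    stay_p: float = 0.15,
    strict: bool = True,
) -> StepwiseResult:
    """Bidirectional stepwise OLS over named candidate columns.

    Repeatedly adds the candidate with the smallest partial-F p-value
    when it is at most ``entry_p``, then removes any retained term
    whose p-value exceeds ``stay_p``; the minimum-AIC model along the
    visited path is refit and returned.  If no candidate ever enters,
    the result is the intercept-only model.

    ``strict=True`` raises when the candidate set is exactly collinear.
    With ``strict=False`` the search runs anyway: a candidate that is
    redundant given the current model reduces the SSE by nothing, gets
    partial-F p ~= 1 and never enters.  The screening predictors of
    harvest quality contain exact identities (the Ve-to-harvest day
    count and GDD sum equal the sums of their sub-intervals), so the
    pipeline uses the non-strict mode.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    names = list(candidates.columns)
    if n <= len(names) + 1:
        raise ModelSelectionError(
            f"need n > n_candidates + 1, got n={n} with {len(names)} candidates"
        )
    cols = {name: candidates[name].to_numpy(dtype=float) for name in names}

    full = _design(n, [cols[name] for name in names])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        involved = [
            name
            for j, name in enumerate(names)
            if np.linalg.matrix_rank(np.delete(full, j + 1, axis=1)) == rank
        ]
        if strict:
            raise ModelSelectionError(
                f"candidate set is collinear; dependency involves: "
                f"{involved or names}"
            )
        logger.info("collinear candidates tolerated (strict=False): %s",
                    involved or names)

    current: list[str] = []

    def sse_of(terms: list[str]) -> float:
        return _sse(y, _design(n, [cols[t] for t in terms]))

    path: list[tuple[tuple[str, ...], float]] = [
        (tuple(), _aic(n, sse_of([]), 0))
    ]
    visited: set[frozenset] = {frozenset()}

    while True:
        sse_cur = sse_of(current)
        # --- entry step: smallest partial-F p among candidates not in model
        entry = []
        for name in names:
            if name in current:
                continue
            sse_new = sse_of(current + [name])
            p = _partial_f_p(sse_cur, sse_new, n - len(current) - 2)
            entry.append((p, name))
        if not entry:
            break
        entry.sort(key=lambda t: (t[0], t[1]))
        best_p, best_name = entry[0]
        if best_p > entry_p:
            break
        current.append(best_name)
        path.append((tuple(current), _aic(n, sse_of(current), len(current))))

        # --- removal sweep: drop worst term with p > stay_p, repeat
        while len(current) > 1:
            sse_mod = sse_of(current)
            drops = []
            for name in current:
                reduced = [t for t in current if t != name]
                p = _partial_f_p(sse_of(reduced), sse_mod, n - len(current) - 1)
                drops.append((p, name))
            drops.sort(key=lambda t: (-t[0], t[1]))
            worst_p, worst_name = drops[0]
            if worst_p <= stay_p:
                break
            current.remove(worst_name)
            path.append((tuple(current), _aic(n, sse_of(current), len(current))))

        state = frozenset(current)
        if state in visited:  # cycle guard
            break
        visited.add(state)

    # minimum-AIC model on the path (earliest on ties)
    best_terms, _ = min(path, key=lambda t: t[1])
    terms = list(best_terms)

    X = _design(n, [cols[t] for t in terms])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    dof = max(n - len(terms) - 1, 1)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof

    pvalues = {}
    for name in terms:
        reduced = [t for t in terms if t != name]
        pvalues[name] = _partial_f_p(sse_of(reduced), sse, n - len(terms) - 1)

    return StepwiseResult(
        selected_terms=tuple(terms),
        coefficients={"intercept": float(beta[0]),
                      **{t: float(b) for t, b in zip(terms, beta[1:])}},
        aic_path=tuple(a for _, a in path),
        entry_p=entry_p,
        stay_p=stay_p,
        final_rmse=float(np.sqrt(sse / dof)),
        final_adj_r2=float(adj_r2),
        pvalues=pvalues,
    )


# ---------------------------------------------------------------------------
# single-hidden-layer tanh network
# ---------------------------------------------------------------------------

_L1_SMOOTH_EPS = 1e-8
_PENALTY_LADDER = (1e-4, 1e-3, 1e-2, 1e-1)


def _unpack(theta: np.ndarray, d: int, h: int):
    W1 = theta[: d * h].reshape(d, h)
    b1 = theta[d * h : d * h + h]
    w2 = theta[d * h + h : d * h + 2 * h]
    b2 = theta[-1]
    return W1, b1, w2, b2


def _net_objective(theta, X, y, h, lam):
    d = X.shape[1]
    W1, b1, w2, b2 = _unpack(theta, d, h)
    Z = np.tanh(X @ W1 + b1)
    yhat = Z @ w2 + b2
    r = yhat - y
    n = len(y)
    mse = float(r @ r) / n
    sW1 = np.sqrt(W1 * W1 + _L1_SMOOTH_EPS)
    sw2 = np.sqrt(w2 * w2 + _L1_SMOOTH_EPS)
    obj = mse + lam * (float(sW1.sum()) + float(sw2.sum()))

    g = 2.0 * r / n
    gb2 = float(g.sum())
    gw2 = Z.T @ g + lam * w2 / sw2
    dA = np.outer(g, w2) * (1.0 - Z * Z)
    gW1 = X.T @ dA + lam * W1 / sW1
    gb1 = dA.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])
    return obj, grad


def _r2_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    resid = y_true - y_pred
    sse = float(resid @ resid)
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return r2, float(np.sqrt(sse / len(y_true)))


@dataclass
class NeuralModel:
    """Single-hidden-layer tanh regression network.

    Inputs are standardized internally; predictions are returned on the
    original response scale.
    """

    feature_names: tuple[str, ...]
    n_nodes: int
    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    penalty_strength: float
    holdback_fraction: float
    train_r2: float
    train_rmse: float
    val_r2: float
    val_rmse: float
    loss_trace: tuple[float, ...]
    importance: pd.DataFrame | None = None

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean) / self.x_sd
        Z = np.tanh(Xs @ self.W1 + self.b1)
        return (Z @ self.w2 + self.b2) * self.y_sd + self.y_mean


def fit_neural(
    response,
    predictors: pd.DataFrame,
    n_nodes: int = 10,
    penalty_strength: float | None = None,
    holdback_fraction: float = 1.0 / 3.0,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
) -> NeuralModel:
    """Train the tanh network with L1 penalty and random restarts.

    When ``penalty_strength`` is None the strength is chosen by
    validation RMSE over a small fixed ladder (1e-4 ... 1e-1).  Each
    restart ("tour") draws fresh random initial weights; the model with
    the lowest RMSE on the random holdback split wins.
    """
    if not 0.0 < holdback_fraction < 1.0:
        raise ModelSelectionError(
            f"holdback_fraction must be in (0, 1), got {holdback_fraction}"
        )
    names = tuple(predictors.columns)
    X = predictors.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, d = X.shape
    if n < 30:
        raise ModelSelectionError(f"need >= 30 observations, got {n}")
    if np.ptp(y) == 0:
        raise ModelSelectionError("response is constant; nothing to fit")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean = float(y.mean())
    y_sd = float(y.std()) or 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(holdback_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, yt = Xs[train_idx], ys[train_idx]
    Xv, yv = Xs[val_idx], ys[val_idx]

    ladder = (penalty_strength,) if penalty_strength is not None else _PENALTY_LADDER

    best = None
    for lam in ladder:
        for _ in range(n_restarts):
            theta0 = np.concatenate(
                [
                    rng.normal(0.0, 1.0 / np.sqrt(d), d * n_nodes),
                    np.zeros(n_nodes),
                    rng.normal(0.0, 1.0 / np.sqrt(n_nodes), n_nodes),
                    [0.0],
                ]
            )
            trace: list[float] = []

            def cb(xk, _trace=trace, _lam=lam):
                _trace.append(_net_objective(xk, Xt, yt, n_nodes, _lam)[0])

            res = optimize.minimize(
                _net_objective,
                theta0,
                args=(Xt, yt, n_nodes, lam),
                jac=True,
                method="L-BFGS-B",
                callback=cb,
                options={"maxiter": max_iter},
            )
            W1, b1, w2, b2 = _unpack(res.x, d, n_nodes)
            yv_hat = np.tanh(Xv @ W1 + b1) @ w2 + b2
            val_rmse = float(np.sqrt(np.mean((yv_hat - yv) ** 2)))
            if best is None or val_rmse < best[0]:
                best = (val_rmse, res.x, lam, tuple(trace))

    _, theta, lam, trace = best
    W1, b1, w2, b2 = _unpack(theta, d, n_nodes)
    model = NeuralModel(
        feature_names=names,
        n_nodes=n_nodes,
        W1=W1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        penalty_strength=float(lam),
        holdback_fraction=holdback_fraction,
        train_r2=0.0,
        train_rmse=0.0,
        val_r2=0.0,
        val_rmse=0.0,
        loss_trace=trace,
    )
    yhat = model.predict(X)
    model.train_r2, model.train_rmse = _r2_rmse(y[train_idx], yhat[train_idx])
    model.val_r2, model.val_rmse = _r2_rmse(y[val_idx], yhat[val_idx])
    logger.info(
        "neural fit: lam=%g train R2=%.3f val R2=%.3f",
        lam, model.train_r2, model.val_r2,
    )
    return model


def variable_importance(
    model: NeuralModel,
    predictors: pd.DataFrame,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-based main and total effects per predictor.

    *Main effect* of predictor j: correlation share of prediction
    variance retained when every other predictor is jointly permuted
    (a Monte-Carlo first-order sensitivity index).  *Total effect*:
    share of prediction variance destroyed when j alone is permuted,
    which also includes j's interactions, so total >= main.  Scores are
    clipped to [0, 1]; rows are ordered by total effect.
    """
    X = predictors[list(model.feature_names)].to_numpy(dtype=float)
    n = len(X)
    rng = np.random.default_rng(seed)
    f = model.predict(X)
    var_f = float(f.var())
    rows = []
    for j, name in enumerate(model.feature_names):
        if var_f == 0:
            rows.append((name, 0.0, 0.0))
            continue
        mains, totals = [], []
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            fp = model.predict(Xp)
            totals.append(float(np.mean((f - fp) ** 2)) / (2.0 * var_f))
            Xq = X[perm].copy()
            Xq[:, j] = X[:, j]
            fq = model.predict(Xq)
            mains.append(float(np.mean((f - f.mean()) * (fq - fq.mean()))) / var_f)
        main = float(np.clip(np.mean(mains), 0.0, 1.0))
        total = float(np.clip(np.mean(totals), 0.0, 1.0))
        rows.append((name, main, max(total, main)))
    out = pd.DataFrame(rows, columns=["predictor", "main_effect", "total_effect"])
    return out.sort_values("total_effect", ascending=False, ignore_index=True)
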