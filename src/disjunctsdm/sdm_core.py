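"""Presence-background suitability modelling on the two PCA axes.

The model is a Maxent-style penalized presence-background estimator: an
exponential-family model over polynomial features of (PC1, PC2), fitted as a
class-balanced logistic regression of presences against background points with
an L1 penalty on the non-intercept coefficients. Class balancing (each class
carries total weight 1/2 regardless of its size) makes the fit invariant to
duplicating background points; the L1 penalty, defaulting to 1/sqrt(n_presence),
guards against separation when a population group has only a few dozen records
while vanishing as data accumulate. Optimization is a monotone FISTA
(proximal gradient with Nesterov acceleration and a monotonicity safeguard),
so the recorded objective trace is non-increasing by construction.

Suitability is the logistic transform of the linear predictor. Downstream
binarization thresholds are rank-based, so the choice of output link does not
affect binary maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_landscape import ClimateStack

__all__ = [
    "DEFAULT_FEATURES",
    "SDMModel",
    "SuitabilityMap",
    "CVRun",
    "build_features",
    "sample_pseudoabsences",
    "fit_presence_background",
    "predict_suitability",
    "cross_validate",
]

#: linear + quadratic + pairwise-product features over the two PCA axes
DEFAULT_FEATURES = ("pc1", "pc2", "pc1^2", "pc2^2", "pc1*pc2")

_FEATURE_FUNCS = {
    "pc1": lambda s: s[:, 0],
    "pc2": lambda s: s[:, 1],
    "pc1^2": lambda s: s[:, 0] ** 2,
    "pc2^2": lambda s: s[:, 1] ** 2,
    "pc1*pc2": lambda s: s[:, 0] * s[:, 1],
}


def build_features(scores: np.ndarray, feature_spec: Sequence[str] = DEFAULT_FEATURES
                   ) -> np.ndarray:
    """Expand (n, 2) PC scores into the (n, p) feature matrix."""
    scores = np.atleast_2d(np.asarray(scores, float))
    try:
        cols = [_FEATURE_FUNCS[name](scores) for name in feature_spec]
    except KeyError as e:
        raise ValueError(f"unknown feature {e.args[0]!r}; "
                         f"known: {sorted(_FEATURE_FUNCS)}") from None
    return np.column_stack(cols)


@dataclass(frozen=True)
class SDMModel:
    """Fitted presence-background model.

    ``coefficients`` holds the intercept first, then one weight per feature,
    on the internally standardized feature scale (``feature_center`` and
    ``feature_scale``, computed on the background, map raw features there).
    """

    feature_spec: tuple[str, ...]
    coefficients: np.ndarray
    regularization: float
    feature_center: np.ndarray
    feature_scale: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_spec) + 1:
            raise ValueError("coefficient count must equal feature count + 1")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    def linear_predictor(self, scores: np.ndarray) -> np.ndarray:
        X = build_features(scores, self.feature_spec)
        Xs = (X - self.feature_center) / self.feature_scale
        return self.coefficients[0] + Xs @ self.coefficients[1:]

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for (n, 2) PC scores (logistic link)."""
        eta = self.linear_predictor(scores)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))

    def implied_optimum(self) -> np.ndarray:
        """Vertex of the fitted quadratic surface, in PC coordinates.

        Defined when the quadratic part is negative definite (a true niche
        optimum); raises otherwise.
        """
        spec = self.feature_spec
        need = {"pc1", "pc2", "pc1^2", "pc2^2"}
        if not need <= set(spec):
            raise ValueError("implied optimum needs linear and quadratic features")
        beta = dict(zip(spec, self.coefficients[1:]))
        # undo feature standardization back to raw-feature coefficients
        raw = {name: beta[name] / self.feature_scale[spec.index(name)] for name in spec}
        dxy = raw.get("pc1*pc2", 0.0)
        H = np.array([[2 * raw["pc1^2"], dxy], [dxy, 2 * raw["pc2^2"]]])
        if np.any(np.linalg.eigvalsh(H) >= 0):
            raise ValueError("fitted quadratic has no interior maximum")
        b = np.array([raw["pc1"], raw["pc2"]])
        return -np.linalg.solve(H, b)


@dataclass(frozen=True)
class SuitabilityMap:
    """Continuous suitability grid for one scenario; NaN on nodata cells."""

    scenario_id: str
    values: np.ndarray
    model_ref: str = ""

    def __post_init__(self) -> None:
        v = self.values[np.isfinite(self.values)]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("suitability values must lie in [0, 1]")


def sample_pseudoabsences(stack: ClimateStack, n: int = 10000, seed: int = 0
                          ) -> pd.DataFrame:
    """Draw ``n`` distinct non-masked cells uniformly as pseudo-absence points.

    Returns a DataFrame with ``row, col, x, y`` (cell centers). Deterministic
    given seed; ``n`` equal to the number of available cells returns exactly
    the full non-masked cell set.
    """
    valid = np.flatnonzero(~stack.nodata_mask.ravel())
    if n > valid.size:
        raise ValueError(f"requested {n} pseudo-absences but only {valid.size} "
                         f"non-masked cells exist; reduce n")
    rng = np.random.default_rng(seed)
    chosen = valid if n == valid.size else rng.choice(valid, size=n, replace=False)
    rows, cols = np.unravel_index(np.sort(chosen), stack.shape)
    X, Y = stack.geometry.cell_centers()
    return pd.DataFrame({"row": rows, "col": cols, "x": X[rows, cols], "y": Y[rows, cols]})


def _loss_grad(beta: np.ndarray, X: np.ndarray, y: np.ndarray, w: np.ndarray
               ) -> tuple[float, np.ndarray]:
    """Weighted logistic negative log-likelihood and its gradient."""
    eta = X @ beta
    # log(1 + e^eta) - y*eta, computed stably
    loss = float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    return loss, X.T @ (w * (p - y))


def fit_presence_background(
    presences: np.ndarray,
    background: np.ndarray,
    feature_spec: Sequence[str] = DEFAULT_FEATURES,
    l1: float | None = None,
    seed: int = 0,
    *,
    tol: float = 1e-6,
    max_iter: int = 5000,
    meta: dict | None = None,
) -> SDMModel:
    """Fit the penalized presence-background model.

    Parameters
    ----------
    presences, background : (n, 2) and (m, 2) PC scores, n >= 10, m >= n.
    l1 : L1 penalty on non-intercept coefficients; default ``0.05/sqrt(n)``.
        The feature space is small (five terms), so the penalty serves
        numerical stability rather than aggressive selection; a strong
        penalty visibly biases the fitted response surface and with it any
        threshold-based range boundary.
    seed : recorded in training metadata (the fit itself is deterministic
        given the data; no randomness is consumed).
    tol : subgradient-optimality tolerance on the penalized objective.

    Convergence failure at ``max_iter`` is flagged in
    ``training_meta["converged"]``, never silent.
    """
    P = np.atleast_2d(np.asarray(presences, float))
    B = np.atleast_2d(np.asarray(background, float))
    n, m = len(P), len(B)
    if n < 10:
        raise ValueError("need at least 10 presences")
    if m < n:
        raise ValueError("background must be at least as large as the presences")
    if l1 is None:
        l1 = 0.05 / np.sqrt(n)

    Xp = build_features(P, feature_spec)
    Xb = build_features(B, feature_spec)
    center, scale = Xb.mean(axis=0), Xb.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    X = np.column_stack([np.ones(n + m), (np.vstack([Xp, Xb]) - center) / scale])
    y = np.concatenate([np.ones(n), np.zeros(m)])
    # balanced weights: each class carries total weight 1/2
    w = np.concatenate([np.full(n, 0.5 / n), np.full(m, 0.5 / m)])

    # exact Lipschitz bound of the smooth part: lam_max(X' diag(w/4) X)
    H = (X * (w / 4.0)[:, None]).T @ X
    L = float(np.linalg.eigvalsh(H)[-1])
    step = 1.0 / L

    def prox(b: np.ndarray) -> np.ndarray:
        out = b.copy()
        out[1:] = np.sign(b[1:]) * np.maximum(np.abs(b[1:]) - step * l1, 0.0)
        return out

    def objective(b: np.ndarray) -> float:
        return _loss_grad(b, X, y, w)[0] + l1 * np.abs(b[1:]).sum()

    beta = np.zeros(X.shape[1])
    z = beta.copy()
    t = 1.0
    f_best = objective(beta)
    trace = [f_best]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        _, g = _loss_grad(z, X, y, w)
        cand = prox(z - step * g)
        f_cand = objective(cand)
        # monotone FISTA: accept the candidate only if it improves
        if f_cand <= f_best:
            beta_new, f_new = cand, f_cand
        else:
            beta_new, f_new = beta, f_best
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = beta_new + (t / t_new) * (cand - beta_new) + ((t - 1.0) / t_new) * (beta_new - beta)
        beta, f_best, t = beta_new, f_new, t_new
        trace.append(f_best)

        _, g_at_beta = _loss_grad(beta, X, y, w)
        opt_err = abs(g_at_beta[0])
        for j in range(1, len(beta)):
            if beta[j] != 0.0:
                opt_err = max(opt_err, abs(g_at_beta[j] + l1 * np.sign(beta[j])))
            else:
                opt_err = max(opt_err, max(abs(g_at_beta[j]) - l1, 0.0))
        if opt_err < tol:
            converged = True
            break

    training_meta = {
        "n_presence": n, "n_background": m, "seed": seed,
        "converged": converged, "n_iter": n_iter,
        "objective_trace": np.asarray(trace),
    }
    if meta:
        training_meta.update(meta)
    return SDMModel(tuple(feature_spec), beta, float(l1), center, scale, training_meta)


def predict_suitability(model: SDMModel, scores: np.ndarray,
                        scenario_id: str = "") -> SuitabilityMap:
    """Project a fitted model onto a (2, nrows, ncols) PC-score grid.

    NaN score cells (nodata) propagate to NaN suitability.
    """
    if scores.ndim != 3 or scores.shape[0] != 2:
        raise ValueError("scores must have shape (2, nrows, ncols)")
    flat = scores.reshape(2, -1).T
    ok = np.all(np.isfinite(flat), axis=1)
    out = np.full(flat.shape[0], np.nan)
    out[ok] = model.predict(flat[ok])
    return SuitabilityMap(scenario_id, out.reshape(scores.shape[1:]),
                          model_ref=str(model.training_meta.get("label", "")))


@dataclass(frozen=True)
class CVRun:
    """One split-sample cross-validation run and its held-out evaluation data."""

    split_id: int
    model: SDMModel
    test_presences: np.ndarray
    test_background: np.ndarray


def cross_validate(
    presences: np.ndarray,
    background: np.ndarray,
    n_rep: int = 10,
    test_frac: float = 0.3,
    seed: int = 0,
    **fit_kwargs,
) -> list[CVRun]:
    """Repeated random split-sample cross-validation.

    ``n_rep`` independent random splits hold out ``test_frac`` of the
    presences (and, likewise, of the background) for evaluation; one model is
    fitted per split on the remaining 70 %. Same seed, same split sequence.
    """
    if not (0.0 < test_frac < 1.0):
        raise ValueError("test_frac must be in (0, 1)")
    P = np.atleast_2d(np.asarray(presences, float))
    B = np.atleast_2d(np.asarray(background, float))
    n_test = int(round(test_frac * len(P)))
    if len(P) - n_test < 10:
        raise ValueError(f"too few presences: training split would keep "
                         f"{len(P) - n_test} < 10 records")
    m_test = int(round(test_frac * len(B)))
    rng = np.random.default_rng(seed)
    runs = []
    for split_id in range(n_rep):
        pi = rng.permutation(len(P))
        bi = rng.permutation(len(B))
        p_test, p_train = pi[:n_test], pi[n_test:]
        b_test, b_train = bi[:m_test], bi[m_test:]
        model = fit_presence_background(P[p_train], B[b_train], seed=seed,
                                        meta={"split_id": split_id}, **fit_kwargs)
        runs.append(CVRun(split_id, model, P[p_test], B[b_test]))
    return runs
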