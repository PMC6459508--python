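"""Per-species distribution models: GLM and a Maxent-style penalized fit.

Both algorithm families operate on the same feature expansion — linear
plus quadratic terms of each (standardized) climate predictor — which
matches unimodal niche responses while keeping fits deterministic:

* ``glm``: binomial logistic regression with a very small ridge penalty
  for numerical stability (near-maximum-likelihood).
* ``maxent_like``: L1-penalized presence-background logistic regression,
  the penalized-binomial formulation of maximum-entropy modelling; the
  penalty strength is chosen by held-out log-likelihood over a small
  fixed grid. This is an explicit approximation: no hinge, product or
  threshold features.

Both fits constrain each quadratic coefficient to be non-positive, so
every fitted single-variable response is concave on the logit scale —
unimodal or monotone, never U-shaped. Unconstrained quadratics can turn
convex when a species' optimum sits at the edge of the sampled climate,
which projects spurious suitability far outside the niche under strong
scenario shifts. Projection additionally clamps predictors to their
training range.

Presence/pseudo-absence design: three background sets, each with ten
times the number of presence points, drawn uniformly at random from
non-presence cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .grid import ClimateStack, GridSpec

#: ridge strength used to stabilize the GLM (spec of the quadratic
#: logistic fit); effectively unpenalized.
GLM_RIDGE = 1e-6
#: candidate L1 penalty strengths for the maxent-like model.
MAXENT_PENALTY_GRID = (0.001, 0.01, 0.1, 1.0)

ALGORITHMS = ("glm", "maxent_like")


@dataclass
class PseudoAbsenceSet:
    """One randomly drawn background set (points in km coordinates)."""
    set_id: int
    points: np.ndarray  # (n, 2) x_km, y_km
    multiplier: int = 10


@dataclass
class FittedModel:
    """A single calibrated model replicate.

    Coefficients are on standardized features: for each input variable v,
    features z_v = (v - mean_v) / sd_v and z_v^2, in layer order.
    """
    algorithm: str
    pa_set_id: int
    repeat_id: int
    layer_names: List[str]
    coef: np.ndarray          # (2 * n_vars,)
    intercept: float
    feature_means: np.ndarray  # per raw variable
    feature_sds: np.ndarray
    converged: bool = True
    penalty: Optional[float] = None
    #: per-variable training range; projections clamp inputs to it so the
    #: quadratic response cannot run away outside the calibrated domain
    train_min: Optional[np.ndarray] = None
    train_max: Optional[np.ndarray] = None

    @property
    def key(self) -> Tuple[str, int, int]:
        return (self.algorithm, self.pa_set_id, self.repeat_id)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "pa_set_id": self.pa_set_id,
            "repeat_id": self.repeat_id,
            "layer_names": self.layer_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "converged": self.converged,
            "penalty": self.penalty,
            "train_min": (self.train_min.tolist()
                          if self.train_min is not None else None),
            "train_max": (self.train_max.tolist()
                          if self.train_max is not None else None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(algorithm=d["algorithm"], pa_set_id=d["pa_set_id"],
                   repeat_id=d["repeat_id"], layer_names=d["layer_names"],
                   coef=np.asarray(d["coef"]), intercept=d["intercept"],
                   feature_means=np.asarray(d["feature_means"]),
                   feature_sds=np.asarray(d["feature_sds"]),
                   converged=d["converged"], penalty=d.get("penalty"),
                   train_min=(np.asarray(d["train_min"])
                              if d.get("train_min") is not None else None),
                   train_max=(np.asarray(d["train_max"])
                              if d.get("train_max") is not None else None))


def sample_pseudo_absences(presence_points: np.ndarray, grid: GridSpec,
                           multiplier: int = 10, n_sets: int = 3,
                           seed: int = 0) -> List[PseudoAbsenceSet]:
    """Draw background sets uniformly from non-presence cells.

    Each of the ``n_sets`` sets contains exactly ``multiplier`` times the
    number of presence points, sampled at cell resolution without
    replacement and excluding every cell that contains a presence;
    points are placed at cell centers.
    """
    from .prep import presence_cells

    pts = np.asarray(presence_points, dtype=float).reshape(-1, 2)
    n_presence = pts.shape[0]
    if n_presence < 1:
        raise ValueError("need at least one presence point")
    occupied = presence_cells(pts, grid)
    candidates = np.flatnonzero(~occupied.ravel())
    n_needed = multiplier * n_presence
    if candidates.size < n_needed:
        raise ValueError(
            f"only {candidates.size} non-presence cells available, "
            f"need {n_needed} for each pseudo-absence set")
    rng = np.random.default_rng(seed)
    sets = []
    for s in range(1, n_sets + 1):
        chosen = rng.choice(candidates, size=n_needed, replace=False)
        rows, cols = np.unravel_index(chosen, grid.shape)
        xy = np.array([grid.cell_center(r, c) for r, c in zip(rows, cols)],
                      dtype=float)
        sets.append(PseudoAbsenceSet(set_id=s, points=xy,
                                     multiplier=multiplier))
    return sets


def _expand(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Standardize then append quadratic terms: [z_1..z_k, z_1^2..z_k^2]."""
    z = (x - means) / sds
    return np.hstack([z, z ** 2])


def _standardizer(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    if np.any(sds == 0):
        raise ValueError("constant feature after expansion; cannot fit")
    return means, sds


def fit_glm(presence_vectors: np.ndarray, absence_vectors: np.ndarray,
            layer_names: Sequence[str], pa_set_id: int = 0,
            repeat_id: int = 0) -> FittedModel:
    """Quadratic logistic regression with a tiny ridge penalty."""
    return _fit_logistic(presence_vectors, absence_vectors, layer_names,
                         algorithm="glm", pa_set_id=pa_set_id,
                         repeat_id=repeat_id)


def fit_maxent_like(presence_vectors: np.ndarray,
                    background_vectors: np.ndarray,
                    layer_names: Sequence[str], pa_set_id: int = 0,
                    repeat_id: int = 0, seed: int = 0) -> FittedModel:
    """L1-penalized presence-background logistic (maximum-entropy analogue).

    The penalty is selected from a fixed grid by log-likelihood on an
    internal 20% holdout of the training data.
    """
    bg = np.asarray(background_vectors, dtype=float)
    if bg.shape[0] >= 2 and np.allclose(bg, bg[0]):
        raise ValueError("all background vectors identical; cannot contrast")
    return _fit_logistic(presence_vectors, background_vectors, layer_names,
                         algorithm="maxent_like", pa_set_id=pa_set_id,
                         repeat_id=repeat_id, seed=seed)


def _neg_log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # -sum[y*eta - log(1 + e^eta)], numerically stable
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def _fit_concave_logistic(feats: np.ndarray, y: np.ndarray,
                          concave_idx: np.ndarray,
                          l2: float = 0.0, l1: float = 0.0
                          ) -> Tuple[float, np.ndarray, bool]:
    """Penalized binomial logistic fit with sign-constrained features.

    Coefficients at ``concave_idx`` (the quadratic features) are bounded
    above by zero. The L1 penalty is handled with the standard
    positive/negative split (beta = u - v, u, v >= 0), which keeps the
    objective smooth so L-BFGS-B applies; the intercept is never
    penalized. Returns (intercept, coefficients, converged).
    """
    n, d = feats.shape
    concave = np.zeros(d, dtype=bool)
    concave[concave_idx] = True

    if l1 == 0.0:
        def obj(w):
            eta = w[0] + feats @ w[1:]
            r = expit(eta) - y
            f = _neg_log_likelihood(eta, y) + 0.5 * l2 * np.sum(w[1:] ** 2)
            g = np.empty(d + 1)
            g[0] = r.sum()
            g[1:] = feats.T @ r + l2 * w[1:]
            return f, g

        bounds = [(None, None)] + [(None, 0.0) if c else (None, None)
                                   for c in concave]
        res = minimize(obj, np.zeros(d + 1), jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 500})
        return float(res.x[0]), res.x[1:].copy(), bool(res.success)

    # beta = u - v with u, v >= 0; concave features have u fixed at 0
    def obj(w):
        u, v = w[1:d + 1], w[d + 1:]
        beta = u - v
        eta = w[0] + feats @ beta
        r = expit(eta) - y
        f = _neg_log_likelihood(eta, y) + l1 * np.sum(u + v)
        gb = feats.T @ r
        g = np.empty(2 * d + 1)
        g[0] = r.sum()
        g[1:d + 1] = gb + l1
        g[d + 1:] = -gb + l1
        return f, g

    bounds = [(None, None)]
    bounds += [(0.0, 0.0) if c else (0.0, None) for c in concave]  # u
    bounds += [(0.0, None)] * d                                    # v
    res = minimize(obj, np.zeros(2 * d + 1), jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": 500})
    beta = res.x[1:d + 1] - res.x[d + 1:]
    # zero out numerically dead coefficients left by the split
    beta[np.abs(beta) < 1e-10] = 0.0
    return float(res.x[0]), beta, bool(res.success)


def _fit_logistic(presence_vectors, absence_vectors, layer_names,
                  algorithm, pa_set_id, repeat_id, seed: int = 0
                  ) -> FittedModel:
    xp = np.asarray(presence_vectors, dtype=float)
    xa = np.asarray(absence_vectors, dtype=float)
    if xp.shape[0] < 2 or xa.shape[0] < 2:
        raise ValueError("need >= 2 samples of each class")
    x = np.vstack([xp, xa])
    y = np.concatenate([np.ones(xp.shape[0]), np.zeros(xa.shape[0])])
    means, sds = _standardizer(x)
    feats = _expand(x, means, sds)
    k = x.shape[1]
    concave_idx = np.arange(k, 2 * k)  # quadratic block

    if algorithm == "glm":
        intercept, coef, converged = _fit_concave_logistic(
            feats, y, concave_idx, l2=GLM_RIDGE)
        penalty = GLM_RIDGE
    else:
        rng = np.random.default_rng(seed)
        n = feats.shape[0]
        perm = rng.permutation(n)
        n_val = max(2, n // 5)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        # guarantee both classes in both internal partitions
        if len(set(y[val_idx])) < 2 or len(set(y[tr_idx])) < 2:
            pos = np.flatnonzero(y == 1)
            neg = np.flatnonzero(y == 0)
            val_idx = np.concatenate([pos[:max(1, len(pos) // 5)],
                                      neg[:max(1, len(neg) // 5)]])
            tr_idx = np.setdiff1d(np.arange(n), val_idx)
        best = None
        for pen in MAXENT_PENALTY_GRID:
            a0, b, _ = _fit_concave_logistic(feats[tr_idx], y[tr_idx],
                                             concave_idx, l1=pen)
            ll = -_neg_log_likelihood(a0 + feats[val_idx] @ b, y[val_idx])
            if best is None or ll > best[0]:
                best = (ll, pen)
        penalty = best[1]
        intercept, coef, converged = _fit_concave_logistic(
            feats, y, concave_idx, l1=penalty)

    model = FittedModel(algorithm=algorithm, pa_set_id=pa_set_id,
                        repeat_id=repeat_id, layer_names=list(layer_names),
                        coef=coef, intercept=intercept,
                        feature_means=means, feature_sds=sds,
                        converged=converged, penalty=penalty,
                        train_min=x.min(axis=0), train_max=x.max(axis=0))
    if not np.all(np.isfinite(coef)):
        model.converged = False
    return model


def predict_vectors(model: FittedModel, raw_vectors: np.ndarray) -> np.ndarray:
    """Suitability in [0, 1] for raw predictor vectors (layer order).

    Inputs are clamped to the per-variable training range before the
    feature expansion (the standard projection practice for fitted
    response curves): outside the calibrated domain the response is held
    at its boundary value instead of extrapolating the quadratic.
    """
    x = np.asarray(raw_vectors, dtype=float)
    if model.train_min is not None and model.train_max is not None:
        x = np.clip(x, model.train_min, model.train_max)
    feats = _expand(x, model.feature_means, model.feature_sds)
    return expit(feats @ model.coef + model.intercept)


def predict_suitability(model: FittedModel,
                        stack: ClimateStack) -> np.ndarray:
    """Project a fitted model onto a climate stack (per-cell suitability)."""
    for name in model.layer_names:
        if name not in stack:
            raise KeyError(f"stack {stack.scenario_id!r} missing layer "
                           f"{name!r} required by the model")
    mat = stack.as_matrix(model.layer_names)
    return predict_vectors(model, mat).reshape(stack.grid.shape)


def permutation_importance(model: FittedModel, samples: np.ndarray,
                           n_perm: int = 5, seed: int = 0) -> Dict[str, float]:
    """Permutation importance per input variable, in [0, 1].

    importance(v) = 1 - Pearson r between predictions on the original
    sample matrix and on copies with column v permuted, averaged over
    ``n_perm`` permutations and clipped to [0, 1]. Constant predictions
    give importance 0 with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("empty sample matrix")
    rng = np.random.default_rng(seed)
    base = predict_vectors(model, x)
    out: Dict[str, float] = {}
    if base.std() == 0:
        warnings.warn("constant predictions; importances set to 0")
        return {n: 0.0 for n in model.layer_names}
    for k, name in enumerate(model.layer_names):
        rs = []
        for _ in range(n_perm):
            xp = x.copy()
            xp[:, k] = rng.permutation(xp[:, k])
            pred = predict_vectors(model, xp)
            if pred.std() == 0:
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(base, pred)[0, 1]))
        out[name] = float(np.clip(1.0 - np.mean(rs), 0.0, 1.0))
    return out


def important_variables(importances: Dict[str, float],
                        threshold: float = 0.30) -> List[str]:
    """Variables whose mean permutation importance exceeds 30%."""
    return [v for v, imp in importances.items() if imp > threshold]


def fitted_optimum(model: FittedModel, variable: str) -> float:
    """Niche optimum implied by the quadratic logistic fit for one variable.

    On the standardized scale the response in z is b1*z + b2*z^2 with
    stationary point z* = -b1 / (2*b2); returns the back-transformed
    optimum on the raw variable scale. Requires b2 < 0 (unimodal fit).
    """
    k = model.layer_names.index(variable)
    n = len(model.layer_names)
    b1, b2 = model.coef[k], model.coef[n + k]
    if b2 >= 0:
        raise ValueError(f"fit for {variable!r} is not unimodal (b2 >= 0)")
    z_star = -b1 / (2.0 * b2)
    return float(model.feature_means[k] + model.feature_sds[k] * z_star)
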