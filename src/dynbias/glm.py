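"""Dynamic Bernoulli GLM of choice with a trials-since-switch bias function.

The probability of a clockwise choice is the logistic transformation of six
linearly combined regressors plus an intercept: stimulus orientation, its
additional effect at high contrast, the context code, the nonlinear bias
function f(S, C) = 1 / (1 + exp(gamma * S * C)) of the trials-since-switch
count S and context C, the previous response, and the previous orientation
(history terms reset at block boundaries). Because f varies nonlinearly with
the shape parameter gamma, fitting uses a two-step grid search: a full
maximum-likelihood logistic fit of the weights at each gamma on a coarse
sign-symmetric grid, then a refined grid around the best coarse value.

The aligned-bias readout with history terms set to zero is

    bias(S) = -(w_C + w_S * (0.5 - 1/(1 + exp(gamma*S)))) / (w_theta + w_e*D_e)

with D_e = 1 at high contrast and 0 at low contrast. Note the convention:
with this design coding a context-appropriate (positive aligned-bias)
observer carries w_C < 0; the sign of w_S is absorbed by the fit.

`DynamicChoiceGLM` follows the statsmodels convention: the model is built
from a choice dataset, `fit()` returns a `DynamicGLMResults` carrying
weights, their uncertainty, the gamma profile and a `summary()`; simulation
(parametric bootstrap) hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .bias import BiasCurve
from .task import ChoiceDataset, TrialSequence, generate_glm_observer_choices

__all__ = [
    "GLMParams",
    "SeparationError",
    "bias_function",
    "build_design",
    "fit_fixed_gamma",
    "default_gamma_grid",
    "DynamicChoiceGLM",
    "DynamicGLMResults",
    "predict_bias_curve",
    "bias_change_10_vs_0",
    "recovery_experiment",
    "cv_dynamic_vs_static",
    "aic_vs_sdt",
]

DESIGN_COLUMNS = ["const", "theta", "theta_high", "context", "f_bias", "prev_resp", "prev_theta"]


class SeparationError(RuntimeError):
    """Raised when the logistic fit detects (quasi-)separation and the
    bounded fallback also fails."""


@dataclass
class GLMParams:
    """Weights of the dynamic Bernoulli GLM.

    ``w_theta`` is the orientation weight at low contrast (per deg), ``w_e``
    the additional orientation weight at high contrast, ``w_C`` the context
    weight, ``w_S`` the weight on the bias function, ``w_r`` and ``w_p`` the
    previous-response and previous-orientation weights, and ``gamma`` the
    bias-function shape parameter.
    """

    w_alpha: float
    w_theta: float
    w_e: float
    w_C: float
    w_S: float
    w_r: float
    w_p: float
    gamma: float

    def weights(self) -> np.ndarray:
        """Weight vector in design-column order (intercept first)."""
        return np.array(
            [self.w_alpha, self.w_theta, self.w_e, self.w_C, self.w_S, self.w_r, self.w_p]
        )

    @classmethod
    def from_weights(cls, w: np.ndarray, gamma: float) -> "GLMParams":
        return cls(*map(float, w), gamma=float(gamma))


def bias_function(S, C, gamma: float) -> np.ndarray:
    """Nonlinear trials-since-switch regressor f = 1/(1 + exp(gamma*S*C)).

    Equals 0.5 whenever S = 0 or C = 0; saturates at 0 or 1 as gamma*S*C
    goes to +/- infinity.
    """
    z = np.clip(gamma * np.asarray(S, dtype=float) * np.asarray(C, dtype=float), -500, 500)
    return 1.0 / (1.0 + np.exp(z))


def _history_columns(dataset: ChoiceDataset) -> tuple[np.ndarray, np.ndarray]:
    """Previous response (-1/+1) and previous orientation, zero at block
    starts (no cross-block leakage)."""
    block = np.asarray(dataset.trials.block)
    start = np.r_[True, block[1:] != block[:-1]]
    prev_r = np.r_[0.0, dataset.choice[:-1].astype(float)]
    prev_th = np.r_[0.0, np.asarray(dataset.trials.orientation, dtype=float)[:-1]]
    prev_r[start] = 0.0
    prev_th[start] = 0.0
    return prev_r, prev_th


def build_design(dataset: ChoiceDataset, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (n, 7) in DESIGN_COLUMNS order and 0/1 response vector
    (1 = clockwise)."""
    tr = dataset.trials
    if tr.s_count is None:
        raise ValueError("dataset must be annotated with s_count")
    theta = np.asarray(tr.orientation, dtype=float)
    de = tr.is_high_contrast.astype(float)
    ctx = np.asarray(tr.context, dtype=float)
    f = bias_function(np.asarray(tr.s_count), ctx, gamma)
    prev_r, prev_th = _history_columns(dataset)
    X = np.column_stack([np.ones(len(tr)), theta, theta * de, ctx, f, prev_r, prev_th])
    y = (dataset.choice == 1).astype(float)
    return X, y


def _bernoulli_llf(eta: np.ndarray, y: np.ndarray) -> float:
    # log p = -log(1 + e^-eta), log(1-p) = -log(1 + e^eta)
    return float(-(np.logaddexp(0.0, -eta) @ y + np.logaddexp(0.0, eta) @ (1.0 - y)))


def fit_fixed_gamma(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """ML logistic-regression weights at a fixed gamma (Newton/IRLS).

    Returns (weights, log-likelihood, covariance, separated). The problem is
    convex; iteration stops when the gradient infinity-norm drops below
    ``tol``. Quasi-separation (diverging weights) is flagged and handled with
    a small-ridge bounded-weight fallback. Collinear designs raise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    # column scaling for conditioning; undone at the end
    scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    Xs = X / scale
    if np.linalg.matrix_rank(Xs) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient (collinear)")
    w_start = np.zeros(p) if w0 is None else np.asarray(w0, dtype=float) * scale
    separated = False
    w = w_start
    for ridge in (0.0, 1e-3, 1e-1):
        w = w_start if ridge == 0.0 else np.zeros(p)
        llf = _bernoulli_llf(Xs @ w, y)
        for _ in range(max_iter):
            eta = np.clip(Xs @ w, -35.0, 35.0)
            mu = expit(eta)
            g = Xs.T @ (y - mu) - ridge * w
            if np.abs(g).max() < tol:
                break
            wdiag = mu * (1.0 - mu) + 1e-12
            H = (Xs * wdiag[:, None]).T @ Xs + (ridge + 1e-12) * np.eye(p)
            step = np.linalg.solve(H, g)
            # step-halving line search (monotone llf)
            new_llf = -np.inf
            for _ in range(40):
                w_new = w + step
                new_llf = _bernoulli_llf(Xs @ w_new, y) - 0.5 * ridge * (w_new @ w_new)
                if new_llf >= llf - 1e-12:
                    break
                step *= 0.5
            w = w + step
            llf = new_llf
        if np.abs(w).max() < 50.0 and np.isfinite(w).all():
            break
        # weights diverging: (quasi-)separation -> retry with a bounded
        # (ridge-penalized) fallback; the flag is reported to the caller
        separated = True
    if not np.isfinite(w).all():
        raise SeparationError("logistic fit diverged even with ridge fallback")
    eta = np.clip(Xs @ w, -35.0, 35.0)
    mu = expit(eta)
    wdiag = mu * (1.0 - mu) + 1e-12
    H = (Xs * wdiag[:, None]).T @ Xs + (ridge + 1e-12) * np.eye(p)
    cov_s = np.linalg.inv(H)
    w_out = w / scale
    cov = cov_s / np.outer(scale, scale)
    return w_out, _bernoulli_llf(np.clip(X @ w_out, -35, 35), y), cov, separated


def default_gamma_grid() -> np.ndarray:
    """Coarse sign-symmetric gamma grid: 0 plus +/- 15 log-spaced magnitudes
    in [0.02, 2.5] (31 points).

    The magnitude range is capped where the model stays identified on
    realistic trials-since-switch supports: for |gamma| >~ 3 the bias
    function is numerically affine in the context code for all S >= 1 (w_S
    and w_C then trade off freely), and below ~0.02 it is constant over the
    observed S range. gamma = 0 itself is handled as the static special
    case. The grid is a tuning range, not a physical constant; pass an
    explicit grid to widen it.
    """
    mags = np.logspace(np.log10(0.02), np.log10(2.5), 15)
    return np.sort(np.concatenate([-mags, [0.0], mags]))


def _refine_grid(grid: np.ndarray, best_idx: int, n: int = 21) -> np.ndarray:
    lo = grid[max(best_idx - 1, 0)]
    hi = grid[min(best_idx + 1, len(grid) - 1)]
    return np.linspace(lo, hi, n)


class DynamicChoiceGLM:
    """Dynamic Bernoulli GLM bound to a choice dataset.

    ``fit()`` runs the two-step gamma grid search; ``fit_static()`` drops the
    bias-function regressor (the static analogue).
    """

    def __init__(self, data: ChoiceDataset):
        if not isinstance(data, ChoiceDataset):
            raise TypeError("DynamicChoiceGLM expects a ChoiceDataset")
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DynamicChoiceGLM":
        seq = TrialSequence.from_frame(df)
        return cls(ChoiceDataset(trials=seq, choice=df["choice"].to_numpy(dtype=int)))

    @property
    def nobs(self) -> int:
        return len(self.data)

    def fit(
        self,
        gamma_grid: np.ndarray | None = None,
        refine: int = 21,
    ) -> "DynamicGLMResults":
        """Two-step grid-search maximum likelihood.

        Step 1 fits the weights at every gamma of the coarse grid; step 2
        refines on a linear grid spanning the two coarse neighbours of the
        optimum and returns the overall best fit.
        """
        grid = default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid, float)
        if len(grid) == 0:
            raise ValueError("gamma_grid must be nonempty")
        profile = []
        best = None
        w_prev = None

        def fit_at(gmm: float, w0):
            # At gamma = 0 the bias-function column is constant (0.5), hence
            # exactly collinear with the intercept: fit without it (w_S = 0);
            # the likelihood is continuous there so the profile is unbroken.
            X, y = build_design(self.data, gmm)
            fcol = DESIGN_COLUMNS.index("f_bias")
            if np.ptp(X[:, fcol]) < 1e-12:
                keep = [i for i in range(X.shape[1]) if i != fcol]
                w0k = None if w0 is None else np.delete(w0, fcol)
                wk, llf, covk, sep = fit_fixed_gamma(X[:, keep], y, w0=w0k)
                w = np.insert(wk, fcol, 0.0)
                cov = np.zeros((X.shape[1], X.shape[1]))
                cov[np.ix_(keep, keep)] = covk
                return w, llf, cov, sep
            return fit_fixed_gamma(X, y, w0=w0)

        for gmm in grid:
            w, llf, cov, sep = fit_at(gmm, w_prev)
            w_prev = w
            profile.append((gmm, llf))
            if best is None or llf > best[1]:
                best = (gmm, llf, w, cov, sep)
        if refine and len(grid) > 1:
            best_idx = int(np.argmin(np.abs(grid - best[0])))
            for gmm in _refine_grid(grid, best_idx, refine):
                w, llf, cov, sep = fit_at(gmm, best[2])
                profile.append((gmm, llf))
                if llf > best[1]:
                    best = (gmm, llf, w, cov, sep)
        gmm, llf, w, cov, sep = best
        if gmm < 0:
            # exact reflection degeneracy: (gamma, w_S, w_alpha) and
            # (-gamma, -w_S, w_alpha + w_S) give identical likelihoods;
            # canonicalize to gamma >= 0
            fcol = DESIGN_COLUMNS.index("f_bias")
            J = np.eye(len(w))
            J[0, fcol] = 1.0
            J[fcol, fcol] = -1.0
            w = J @ w
            cov = J @ cov @ J.T
            gmm = -gmm
        params = GLMParams.from_weights(w, gmm)
        prof = pd.DataFrame(sorted(profile), columns=["gamma", "llf"])
        return DynamicGLMResults(self, params, llf, cov, prof, separated=sep)

    def fit_static(self) -> "StaticGLMResults":
        """Static analogue: the f(S, C) regressor removed (6 parameters)."""
        X, y = build_design(self.data, 0.0)
        keep = [i for i, c in enumerate(DESIGN_COLUMNS) if c != "f_bias"]
        w, llf, cov, sep = fit_fixed_gamma(X[:, keep], y)
        return StaticGLMResults(self, w, llf, cov, separated=sep)


class StaticGLMResults:
    """Results of the static (no bias-function) logistic fit."""

    k_params = 6

    def __init__(self, model, w, llf, cov, separated=False):
        self.model = model
        self.weights = np.asarray(w)
        self.llf = float(llf)
        self.cov = cov
        self.separated = separated
        self.aic = 2.0 * self.k_params - 2.0 * self.llf

    def loglike_on(self, dataset: ChoiceDataset) -> float:
        X, y = build_design(dataset, 0.0)
        keep = [i for i, c in enumerate(DESIGN_COLUMNS) if c != "f_bias"]
        return _bernoulli_llf(np.clip(X[:, keep] @ self.weights, -35, 35), y)


class DynamicGLMResults:
    """Fit results of the dynamic GLM (weights + gamma)."""

    k_params = 8  # seven linear terms (incl. intercept) + gamma

    def __init__(self, model, params: GLMParams, llf, cov, profile, separated=False):
        self.model = model
        self.params = params
        self.llf = float(llf)
        self.cov = cov  # covariance of the weights at the fitted gamma
        self.bse = np.sqrt(np.diag(cov))
        self.gamma_profile = profile
        self.separated = separated
        self.aic = 2.0 * self.k_params - 2.0 * self.llf

    def predict_bias_curve(
        self, high_contrast: bool = True, s_range: Sequence[int] | None = None
    ) -> BiasCurve:
        return predict_bias_curve(self.params, high_contrast, s_range)

    def bias_change_10_vs_0(self, high_contrast: bool = True) -> float:
        return bias_change_10_vs_0(self.params, high_contrast)

    def pse(self, S, context: int, high_contrast: bool = True) -> float:
        """PSE from the fitted linear predictor with history terms at zero."""
        p = self.params
        denom = p.w_theta + p.w_e * (1.0 if high_contrast else 0.0)
        if denom == 0:
            raise ZeroDivisionError("w_theta + w_e*D_e is zero; PSE undefined")
        num = p.w_C * context + p.w_S * bias_function(S, context, p.gamma) + p.w_alpha
        return float(-num / denom)

    def loglike_on(self, dataset: ChoiceDataset) -> float:
        X, y = build_design(dataset, self.params.gamma)
        return _bernoulli_llf(np.clip(X @ self.params.weights(), -35, 35), y)

    def simulate(
        self, trials: TrialSequence | None = None, seed: int = 0
    ) -> ChoiceDataset:
        """Simulate a synthetic dataset from the fitted parameters (on the
        fitted sequence by default)."""
        tr = self.model.data.trials if trials is None else trials
        return generate_glm_observer_choices(tr, self.params, seed)

    def parametric_bootstrap(
        self,
        n_boot: int = 1000,
        seed: int = 0,
        high_contrast: bool = True,
        s_range: Sequence[int] | None = None,
        gamma_grid: np.ndarray | None = None,
        level: float = 68.0,
    ) -> dict:
        """Parametric bootstrap: simulate datasets from the fitted model,
        refit each, and return percentile bands for the bias curve and the
        weights."""
        s_range = np.arange(0, 11) if s_range is None else np.asarray(s_range)
        rng = np.random.default_rng(seed)
        curves = np.empty((n_boot, len(s_range)))
        weights = np.empty((n_boot, 7))
        gammas = np.empty(n_boot)
        for b in range(n_boot):
            sim = self.simulate(seed=rng.integers(2**31 - 1))
            res = DynamicChoiceGLM(sim).fit(gamma_grid=gamma_grid)
            curves[b] = res.predict_bias_curve(high_contrast, s_range).bias
            weights[b] = res.params.weights()
            gammas[b] = res.params.gamma
        a = (100.0 - level) / 2.0
        lo, hi = np.percentile(curves, [a, 100.0 - a], axis=0)
        wlo, whi = np.percentile(weights, [a, 100.0 - a], axis=0)
        return {
            "s_range": s_range,
            "curve_mean": curves.mean(axis=0),
            "curve_lo": lo,
            "curve_hi": hi,
            "curves": curves,
            "weights": weights,
            "gammas": gammas,
            "weight_lo": wlo,
            "weight_hi": whi,
        }

    def summary(self) -> str:
        p = self.params
        lines = [
            "Dynamic Bernoulli choice GLM",
            f"  n trials: {self.model.nobs}   k = {self.k_params}",
            f"  log-likelihood: {self.llf:.3f}   AIC: {self.aic:.3f}",
            f"  gamma (bias-function shape): {p.gamma:.4f}",
            "  weights (+/- 1 SE at fitted gamma):",
        ]
        for name, val, se in zip(DESIGN_COLUMNS, p.weights(), self.bse):
            lines.append(f"    {name:>10s} = {val: .4f} +/- {se:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {
                "w_alpha": p.w_alpha,
                "w_theta": p.w_theta,
                "w_e": p.w_e,
                "w_C": p.w_C,
                "w_S": p.w_S,
                "w_r": p.w_r,
                "w_p": p.w_p,
                "gamma": p.gamma,
            },
            "bse": dict(zip(DESIGN_COLUMNS, map(float, self.bse))),
            "llf": self.llf,
            "k": self.k_params,
            "aic": self.aic,
        }


# ---------------------------------------------------------------------------
# Bias readout
# ---------------------------------------------------------------------------


def predict_bias_curve(
    params: GLMParams,
    high_contrast: bool = True,
    s_range: Sequence[int] | None = None,
) -> BiasCurve:
    """Aligned bias vs trials since switch, history terms at zero:

    bias(S) = -(w_C + w_S*(0.5 - 1/(1+exp(gamma*S)))) / (w_theta + w_e*D_e).
    """
    s = np.arange(0, 11) if s_range is None else np.asarray(s_range, dtype=float)
    denom = params.w_theta + params.w_e * (1.0 if high_contrast else 0.0)
    if denom == 0:
        raise ZeroDivisionError("w_theta + w_e*D_e is zero; bias undefined")
    f = 1.0 / (1.0 + np.exp(np.clip(params.gamma * s, -500, 500)))
    bias = -(params.w_C + params.w_S * (0.5 - f)) / denom
    nan = np.full(len(s), np.nan)
    return BiasCurve(
        s_values=s, bias=bias, se=nan, ci_lo=nan, ci_hi=nan, n_trials=np.zeros(len(s), int)
    )


def bias_change_10_vs_0(params: GLMParams, high_contrast: bool = True) -> float:
    """Model-predicted bias after ten same-context trials minus the bias
    immediately after a context switch (deg)."""
    c = predict_bias_curve(params, high_contrast, s_range=[0, 10])
    return float(c.bias[1] - c.bias[0])


# ---------------------------------------------------------------------------
# Recovery, cross-validation, model comparison
# ---------------------------------------------------------------------------


def recovery_experiment(
    trials: TrialSequence,
    observers: Sequence[GLMParams],
    n_reps: int = 1000,
    seed: int = 0,
    s_range: Sequence[int] | None = None,
    high_contrast: bool = True,
    gamma_grid: np.ndarray | None = None,
    level: float = 68.0,
) -> dict:
    """Simulate-and-refit recovery analysis for a set of model observers.

    For each observer, ``n_reps`` synthetic datasets are generated on the
    given trial sequence and refit with the two-step procedure. The report
    carries, per observer: the truth, mean and SD of every parameter across
    replicates, the distribution of recovered bias curves with its
    percentile band, and the ground-truth curve. Fully seeded.
    """
    s_range = np.arange(0, 11) if s_range is None else np.asarray(s_range)
    rng = np.random.default_rng(seed)
    report = []
    names = ["w_alpha", "w_theta", "w_e", "w_C", "w_S", "w_r", "w_p"]
    for obs_idx, truth in enumerate(observers):
        curves = np.empty((n_reps, len(s_range)))
        weights = np.empty((n_reps, 7))
        gammas = np.empty(n_reps)
        for r in range(n_reps):
            sim = generate_glm_observer_choices(trials, truth, rng.integers(2**31 - 1))
            res = DynamicChoiceGLM(sim).fit(gamma_grid=gamma_grid)
            weights[r] = res.params.weights()
            gammas[r] = res.params.gamma
            curves[r] = res.predict_bias_curve(high_contrast, s_range).bias
        a = (100.0 - level) / 2.0
        lo, hi = np.percentile(curves, [a, 100.0 - a], axis=0)
        truth_curve = predict_bias_curve(truth, high_contrast, s_range).bias
        params_df = pd.DataFrame(
            {
                "param": names,
                "truth": truth.weights(),
                "mean": weights.mean(axis=0),
                "sd": weights.std(axis=0, ddof=1),
            }
        )
        params_df["mean_error"] = params_df["mean"] - params_df["truth"]
        report.append(
            {
                "observer": obs_idx,
                "truth": truth,
                "params": params_df,
                "gammas": gammas,
                "curves": curves,
                "s_range": s_range,
                "band_lo": lo,
                "band_hi": hi,
                "truth_curve": truth_curve,
                "curve_coverage": float(
                    np.mean((truth_curve >= lo) & (truth_curve <= hi))
                ),
            }
        )
    return {"observers": report, "n_reps": n_reps, "seed": seed}


def cv_dynamic_vs_static(dataset: ChoiceDataset) -> dict:
    """Held-out comparison of the dynamic and static GLMs.

    Trials 1-4 after a context switch form the training set; trials 5 and
    later form the test set (a disjoint cover). Both models are fit on the
    training set and scored by total log-likelihood on the test set.
    """
    s = np.asarray(dataset.trials.s_count)
    train_mask = (s >= 1) & (s <= 4)
    test_mask = s >= 5
    if not test_mask.any():
        raise ValueError("empty test set: no trials with s_count >= 5")
    if not train_mask.any():
        raise ValueError("empty training set")

    # History regressors are built on the full sequence, then rows are
    # masked, so each trial keeps its true previous response/orientation.
    fcol = DESIGN_COLUMNS.index("f_bias")

    def fit_masked(gmm: float, w0):
        X, y = build_design(dataset, gmm)
        Xt, yt = X[train_mask], y[train_mask]
        if np.ptp(Xt[:, fcol]) < 1e-12:  # gamma = 0: f constant, w_S = 0
            keep = [i for i in range(X.shape[1]) if i != fcol]
            w0k = None if w0 is None else np.delete(w0, fcol)
            wk, llf, _, _ = fit_fixed_gamma(Xt[:, keep], yt, w0=w0k)
            return np.insert(wk, fcol, 0.0), llf
        w, llf, _, _ = fit_fixed_gamma(Xt, yt, w0=w0)
        return w, llf

    grid = default_gamma_grid()
    best = None
    w_prev = None
    for gmm in grid:
        w, llf = fit_masked(gmm, w_prev)
        w_prev = w
        if best is None or llf > best[1]:
            best = (gmm, llf, w)
    best_idx = int(np.argmin(np.abs(grid - best[0])))
    for gmm in _refine_grid(grid, best_idx):
        w, llf = fit_masked(gmm, best[2])
        if llf > best[1]:
            best = (gmm, llf, w)
    gmm, dyn_train_llf, w_dyn = best
    X, y = build_design(dataset, gmm)
    dyn_test_llf = _bernoulli_llf(np.clip(X[test_mask] @ w_dyn, -35, 35), y[test_mask])

    keep = [i for i, c in enumerate(DESIGN_COLUMNS) if c != "f_bias"]
    X0, y0 = build_design(dataset, 0.0)
    w_st, stat_train_llf, _, _ = fit_fixed_gamma(X0[train_mask][:, keep], y0[train_mask])
    stat_test_llf = _bernoulli_llf(
        np.clip(X0[test_mask][:, keep] @ w_st, -35, 35), y0[test_mask]
    )
    return {
        "gamma": float(gmm),
        "dynamic_train_llf": float(dyn_train_llf),
        "static_train_llf": float(stat_train_llf),
        "dynamic_test_llf": float(dyn_test_llf),
        "static_test_llf": float(stat_test_llf),
        "n_train": int(train_mask.sum()),
        "n_test": int(test_mask.sum()),
    }


def aic_vs_sdt(dataset: ChoiceDataset, seed: int = 0) -> pd.DataFrame:
    """AIC comparison of the dynamic GLM and the full SDT model on the same
    trials (AIC = 2k - 2 lnL; parameter counts reported alongside)."""
    from .sdt import SignalDetectionModel

    glm_res = DynamicChoiceGLM(dataset).fit()
    sdt_res = SignalDetectionModel(dataset).fit(seed=seed)
    return pd.DataFrame(
        [
            {"model": "dynamic_glm", "k": glm_res.k_params, "llf": glm_res.llf, "aic": glm_res.aic},
            {"model": "sdt", "k": sdt_res.k_params, "llf": sdt_res.llf, "aic": sdt_res.aic},
        ]
    )
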