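"""Signal Detection Theory process model of choice.

Each trial yields an internal orientation estimate drawn from a Gaussian
whose mean is the true orientation plus a context-specific constant and whose
spread depends on stimulus contrast; the estimate is compared against a fixed
criterion (absorbed into the uniform-context constant, so the criterion sits
at zero). On a lapse trial the observer instead guesses at random. The full
model has six free parameters: a uniform-context shift, a skew-context shift
applied with the context's sign, two contrast-specific spreads, and two
contrast-specific lapse rates.

`SignalDetectionModel` follows the statsmodels convention: a model object is
built from data, `fit()` returns an `SDTResults` carrying the estimates,
log-likelihood, AIC and a `summary()`, and bootstrap confidence intervals
hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import norm
from scipy.stats import qmc

from .task import ChoiceDataset

__all__ = [
    "SDTParams",
    "SDTFitError",
    "predict_p_cw",
    "SignalDetectionModel",
    "SDTResults",
    "compare_sdt_variants",
]


class SDTFitError(RuntimeError):
    """Raised when no optimizer start converges."""


@dataclass
class SDTParams:
    """Parameters of the SDT process model.

    Shifts are in deg; ``shift_context`` is applied with the context's sign
    (+shift in the positively skewed context, -shift in the negatively skewed
    one), so it equals the model-implied aligned bias. Spreads (deg) and
    lapse rates are contrast-specific; a lapse is an unbiased guess.
    """

    shift_uniform: float
    shift_context: float
    sigma_high: float
    sigma_low: float
    lapse_high: float
    lapse_low: float

    def __post_init__(self) -> None:
        if self.sigma_high <= 0 or self.sigma_low <= 0:
            raise ValueError("sigmas must be positive")
        for lp in (self.lapse_high, self.lapse_low):
            if not 0.0 <= lp <= 1.0:
                raise ValueError("lapse rates must be in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.shift_uniform,
                self.shift_context,
                self.sigma_high,
                self.sigma_low,
                self.lapse_high,
                self.lapse_low,
            ]
        )


def predict_p_cw(theta, is_high, context, params: SDTParams) -> np.ndarray:
    """Probability of a clockwise choice under the SDT process model."""
    theta = np.asarray(theta, dtype=float)
    is_high = np.asarray(is_high, dtype=bool)
    context = np.asarray(context, dtype=float)
    sigma = np.where(is_high, params.sigma_high, params.sigma_low)
    lapse = np.where(is_high, params.lapse_high, params.lapse_low)
    shift = params.shift_uniform + context * params.shift_context
    return lapse * 0.5 + (1.0 - lapse) * ndtr((theta + shift) / sigma)


# Parameter packing for the four supplementary variants: {1,2} shift
# parameters x {1,2} spread parameters, lapses always per-contrast.
_BOUNDS = {
    "shift": (-15.0, 15.0),
    "sigma": (0.05, 60.0),
    "lapse": (0.0, 0.5),
}


def _unpack(x: np.ndarray, n_shift: int, n_sigma: int) -> SDTParams:
    i = 0
    shift_u = x[i]
    i += 1
    shift_c = x[i] if n_shift == 2 else 0.0
    i += n_shift - 1
    sig_h = x[i]
    i += 1
    sig_l = x[i] if n_sigma == 2 else sig_h
    i += n_sigma - 1
    return SDTParams(shift_u, shift_c, sig_h, sig_l, x[i], x[i + 1])


class SignalDetectionModel:
    """SDT choice model bound to a trial dataset.

    Parameters
    ----------
    data : ChoiceDataset or DataFrame
        Trials with orientation_deg, contrast, context and choice columns.
    n_shift, n_sigma : {1, 2}
        Number of free shift / spread parameters (the four supplementary
        variants); the full model is 2/2.
    """

    def __init__(self, data, n_shift: int = 2, n_sigma: int = 2):
        if n_shift not in (1, 2) or n_sigma not in (1, 2):
            raise ValueError("n_shift and n_sigma must be 1 or 2")
        self.n_shift = n_shift
        self.n_sigma = n_sigma
        if isinstance(data, ChoiceDataset):
            df = data.to_frame()
        else:
            df = pd.DataFrame(data)
        self.theta = df["orientation_deg"].to_numpy(dtype=float)
        self.is_high = df["contrast"].to_numpy(dtype=object) == "high"
        self.context = df["context"].to_numpy(dtype=int)
        self.cw = (df["choice"].to_numpy(dtype=int) == 1).astype(float)
        self._build_cells()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "SignalDetectionModel":
        return cls(df, **kw)

    @property
    def k_params(self) -> int:
        return self.n_shift + self.n_sigma + 2

    @property
    def nobs(self) -> int:
        return len(self.cw)

    def _build_cells(self) -> None:
        # Aggregate trials into (theta, contrast, context) cells; the
        # binomial cell likelihood equals the Bernoulli trial likelihood up
        # to a constant and makes each objective evaluation O(#cells).
        keys = np.stack(
            [self.theta, self.is_high.astype(float), self.context.astype(float)]
        ).T
        uniq, self._cell_of_trial = np.unique(keys, axis=0, return_inverse=True)
        self._cell_theta = uniq[:, 0]
        self._cell_high = uniq[:, 1].astype(bool)
        self._cell_ctx = uniq[:, 2]
        self._cell_n = np.bincount(self._cell_of_trial).astype(float)
        self._cell_k = np.bincount(self._cell_of_trial, weights=self.cw)

    def _cell_loglike(self, params: SDTParams, k=None, n=None) -> float:
        p = predict_p_cw(self._cell_theta, self._cell_high, self._cell_ctx, params)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        k = self._cell_k if k is None else k
        n = self._cell_n if n is None else n
        return float(k @ np.log(p) + (n - k) @ np.log1p(-p))

    def loglike(self, x: np.ndarray, k=None, n=None) -> float:
        return self._cell_loglike(_unpack(np.asarray(x, float), self.n_shift, self.n_sigma), k, n)

    def _negloglike_and_grad(self, x: np.ndarray, k, n) -> tuple[float, np.ndarray]:
        """Objective and analytic gradient on the free-parameter vector."""
        params = _unpack(np.asarray(x, float), self.n_shift, self.n_sigma)
        high = self._cell_high
        sigma = np.where(high, params.sigma_high, params.sigma_low)
        lapse = np.where(high, params.lapse_high, params.lapse_low)
        ctx = self._cell_ctx
        z = (self._cell_theta + params.shift_uniform + ctx * params.shift_context) / sigma
        Phi = ndtr(z)
        phi = norm.pdf(z)
        p = np.clip(lapse * 0.5 + (1.0 - lapse) * Phi, 1e-12, 1.0 - 1e-12)
        ll = float(k @ np.log(p) + (n - k) @ np.log1p(-p))
        dl_dp = k / p - (n - k) / (1.0 - p)
        dp_dshift = (1.0 - lapse) * phi / sigma
        dp_dsigma = -(1.0 - lapse) * phi * z / sigma
        dp_dlapse = 0.5 - Phi
        g = [float(dl_dp @ dp_dshift)]
        if self.n_shift == 2:
            g.append(float(dl_dp @ (dp_dshift * ctx)))
        if self.n_sigma == 2:
            g.append(float(dl_dp @ np.where(high, dp_dsigma, 0.0)))
            g.append(float(dl_dp @ np.where(high, 0.0, dp_dsigma)))
        else:
            g.append(float(dl_dp @ dp_dsigma))
        g.append(float(dl_dp @ np.where(high, dp_dlapse, 0.0)))
        g.append(float(dl_dp @ np.where(high, 0.0, dp_dlapse)))
        return -ll, -np.asarray(g)

    def _bounds(self) -> list[tuple[float, float]]:
        b = [_BOUNDS["shift"]] * self.n_shift
        b += [_BOUNDS["sigma"]] * self.n_sigma
        b += [_BOUNDS["lapse"], _BOUNDS["lapse"]]
        return b

    def _fit_counts(
        self, k, n, n_starts: int, seed: int, x0: np.ndarray | None
    ) -> tuple[np.ndarray, float, int]:
        bounds = self._bounds()
        starts: list[np.ndarray] = []
        if x0 is not None:
            starts.append(np.asarray(x0, dtype=float))
        if n_starts > 0:
            # Latin-hypercube starts over a plausible interior sub-box.
            sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
            lo = np.array([-3.0] * self.n_shift + [0.5] * self.n_sigma + [0.0, 0.0])
            hi = np.array([3.0] * self.n_shift + [30.0] * self.n_sigma + [0.2, 0.2])
            starts += list(qmc.scale(sampler.random(n_starts), lo, hi))
        best = None
        n_fail = 0
        for s in starts:
            res = optimize.minimize(
                self._negloglike_and_grad,
                s,
                args=(k, n),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
            )
            if not res.success and not np.isfinite(res.fun):
                n_fail += 1
                continue
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None:
            raise SDTFitError(
                f"no optimizer start converged ({n_fail}/{len(starts)} failures)"
            )
        return best.x, -float(best.fun), n_fail

    def fit(
        self, n_starts: int = 10, seed: int = 0, x0: np.ndarray | None = None
    ) -> "SDTResults":
        """Maximum-likelihood fit via bounded L-BFGS-B with multi-start."""
        x, llf, _ = self._fit_counts(self._cell_k, self._cell_n, n_starts, seed, x0)
        return SDTResults(self, x, llf)


class SDTResults:
    """Fit results for :class:`SignalDetectionModel`."""

    def __init__(self, model: SignalDetectionModel, x: np.ndarray, llf: float):
        self.model = model
        self.x = np.asarray(x, dtype=float)
        self.params = _unpack(self.x, model.n_shift, model.n_sigma)
        self.llf = float(llf)
        self.k_params = model.k_params
        self.aic = 2.0 * self.k_params - 2.0 * self.llf
        self.boot_replicates: np.ndarray | None = None
        self.boot_failures: int = 0

    def bootstrap(
        self,
        n_boot: int = 1000,
        seed: int = 0,
        levels: Sequence[float] = (68.0, 95.0),
    ) -> pd.DataFrame:
        """Non-parametric (trial-resampling) bootstrap percentile CIs.

        Each replicate resamples trials with replacement, re-aggregates the
        cells and refits warm-started from the point estimate. Replicate fit
        failures are counted, not silently dropped.
        """
        m = self.model
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, len(self.x)))
        failures = 0
        nobs = m.nobs
        for b in range(n_boot):
            idx = rng.integers(0, nobs, nobs)
            cells = m._cell_of_trial[idx]
            n = np.bincount(cells, minlength=len(m._cell_n)).astype(float)
            k = np.bincount(cells, weights=m.cw[idx], minlength=len(m._cell_n))
            try:
                x, _, _ = m._fit_counts(k, n, 0, seed, self.x)
            except SDTFitError:
                failures += 1
                x = np.full(len(self.x), np.nan)
            reps[b] = x
        self.boot_replicates = reps
        self.boot_failures = failures
        names = self._param_names()
        rows = []
        for j, name in enumerate(names):
            rec = {"param": name, "estimate": self.x[j]}
            for lv in levels:
                a = (100.0 - lv) / 2.0
                lo, hi = np.nanpercentile(reps[:, j], [a, 100.0 - a])
                rec[f"ci{int(lv)}_lo"] = lo
                rec[f"ci{int(lv)}_hi"] = hi
            rows.append(rec)
        return pd.DataFrame(rows)

    def _param_names(self) -> list[str]:
        names = ["shift_uniform"]
        if self.model.n_shift == 2:
            names.append("shift_context")
        names.append("sigma_high" if self.model.n_sigma == 2 else "sigma")
        if self.model.n_sigma == 2:
            names.append("sigma_low")
        names += ["lapse_high", "lapse_low"]
        return names

    def predict(self, theta=None, is_high=None, context=None) -> np.ndarray:
        m = self.model
        theta = m.theta if theta is None else theta
        is_high = m.is_high if is_high is None else is_high
        context = m.context if context is None else context
        return predict_p_cw(theta, is_high, context, self.params)

    def summary(self) -> str:
        lines = [
            "Signal Detection Theory choice model",
            f"  variant: {self.model.n_shift}-shift / {self.model.n_sigma}-spread"
            f"  (k = {self.k_params})",
            f"  n trials: {self.model.nobs}",
            f"  log-likelihood: {self.llf:.3f}   AIC: {self.aic:.3f}",
            "  parameters:",
        ]
        for name, val in zip(self._param_names(), self.x):
            lines.append(f"    {name:>14s} = {val: .4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": dict(zip(self._param_names(), map(float, self.x))),
            "llf": self.llf,
            "k": self.k_params,
            "aic": self.aic,
        }


def compare_sdt_variants(
    dataset,
    n_holdout: int = 200,
    seed: int = 0,
    contrast: str | None = None,
) -> pd.DataFrame:
    """Compare the four SDT variants by held-out likelihood and AIC.

    The held-out score is a subsampled leave-one-out analysis: for each of
    ``n_holdout`` randomly drawn trials the variant is refit without that
    trial (warm-started from the full fit) and scored on it; the average
    per-trial held-out log-likelihood is reported. Seeded, hence
    deterministic for identical data.
    """
    if isinstance(dataset, ChoiceDataset):
        df = dataset.to_frame()
    else:
        df = pd.DataFrame(dataset)
    if contrast is not None:
        df = df[df["contrast"] == contrast].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    holdout = rng.integers(0, len(df), min(n_holdout, len(df)))
    rows = []
    for n_shift in (1, 2):
        for n_sigma in (1, 2):
            m = SignalDetectionModel(df, n_shift=n_shift, n_sigma=n_sigma)
            res = m.fit(seed=seed)
            ll_out = []
            for t in holdout:
                cell = m._cell_of_trial[t]
                n = m._cell_n.copy()
                k = m._cell_k.copy()
                n[cell] -= 1
                k[cell] -= m.cw[t]
                x, _, _ = m._fit_counts(k, n, 0, seed, res.x)
                p = predict_p_cw(
                    m.theta[t : t + 1],
                    m.is_high[t : t + 1],
                    m.context[t : t + 1],
                    _unpack(x, n_shift, n_sigma),
                )[0]
                p = min(max(p, 1e-12), 1 - 1e-12)
                ll_out.append(np.log(p) if m.cw[t] else np.log1p(-p))
            rows.append(
                {
                    "n_shift": n_shift,
                    "n_sigma": n_sigma,
                    "k": m.k_params,
                    "llf": res.llf,
                    "aic": res.aic,
                    "heldout_ll": float(np.mean(ll_out)),
                }
            )
    return pd.DataFrame(rows)
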