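"""Psychometric summaries of choice data: PSE, aligned bias, bias curves.

The point of subjective equality (PSE) is the orientation eliciting 50%
clockwise choices, obtained from a two-parameter logistic fit (intercept +
slope) to per-orientation choice fractions. The aligned bias is the
context-appropriate shift of the PSE relative to the uniform context,
averaged over the two skewed contexts, with the sign convention that a
positive value means choices are pulled toward each context's likelier
response category. Bias curves resolve the aligned bias by the number of
trials since the most recent context switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .task import ChoiceDataset, annotate_previous_run_length

__all__ = [
    "UndefinedPSEError",
    "BiasCurve",
    "fit_psychometric",
    "estimate_pse",
    "psychometric_summary",
    "aligned_bias",
    "normalized_bias",
    "bias_by_trials_since_switch",
    "bias_matrix",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
]


class UndefinedPSEError(ValueError):
    """Raised when choice data cannot pin down a 50% crossing."""


# ---------------------------------------------------------------------------
# Logistic PSE fitting
# ---------------------------------------------------------------------------


def _logit_irls(
    x: np.ndarray, k: np.ndarray, n: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """ML fit of a binomial logistic model p = expit(a + b x).

    Plain Newton/IRLS on aggregated counts with a tiny ridge for numerical
    safety; returns (beta, covariance). Cross-checked against statsmodels
    GLM(Binomial) in the test suite.
    """
    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, dtype=float)])
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    beta = np.zeros(2)
    H = np.eye(2)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = expit(eta)
        w = n * p * (1.0 - p)
        g = X.T @ (k - n * p)
        H = (X * w[:, None]).T @ X + 1e-10 * np.eye(2)
        step = np.linalg.solve(H, g)
        # step-halving keeps the iteration stable under quasi-separation
        for _ in range(30):
            if np.abs(step).max() < 15.0:
                break
            step *= 0.5
        beta = beta + step
        if np.abs(g).max() < tol and np.abs(step).max() < 1e-10:
            break
    cov = np.linalg.inv(H)
    return beta, cov


def fit_psychometric(
    orientations: np.ndarray, choices: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Fit the logistic psychometric function to trial-level data.

    Returns (intercept, slope, covariance) of logit P(cw) = a + b*theta.
    """
    orientations = np.asarray(orientations, dtype=float)
    cw = np.asarray(choices) == 1
    if cw.all() or (~cw).all():
        raise UndefinedPSEError("all choices identical; PSE undefined")
    levels, inv = np.unique(orientations, return_inverse=True)
    if len(levels) < 2:
        raise UndefinedPSEError("need at least two orientation levels")
    n = np.bincount(inv, minlength=len(levels)).astype(float)
    k = np.bincount(inv, weights=cw.astype(float), minlength=len(levels))
    beta, cov = _logit_irls(levels, k, n)
    return float(beta[0]), float(beta[1]), cov


def estimate_pse(
    orientations: np.ndarray, choices: np.ndarray, with_se: bool = False
):
    """PSE (deg) from the logistic fit, solved at 50% clockwise.

    With ``with_se`` the delta-method standard error is returned as well.
    """
    a, b, cov = fit_psychometric(orientations, choices)
    if b <= 0:
        raise UndefinedPSEError(
            "non-positive psychometric slope; PSE orientation convention violated"
        )
    pse = -a / b
    if not with_se:
        return pse
    grad = np.array([-1.0 / b, a / b**2])
    se = float(np.sqrt(grad @ cov @ grad))
    return pse, se


def psychometric_summary(
    dataset: ChoiceDataset, by: Sequence[str] = ("context", "contrast")
) -> pd.DataFrame:
    """Per-cell choice fractions and fitted PSE/slope.

    Cells are defined by the grouping columns (context, contrast by default).
    Cells whose PSE is undefined are flagged with NaN rather than dropped.
    """
    df = dataset.to_frame()
    rows = []
    for key, g in df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(by, key))
        rec["n_trials"] = len(g)
        rec["frac_cw"] = float((g["choice"] == 1).mean())
        try:
            pse, se = estimate_pse(
                g["orientation_deg"].to_numpy(), g["choice"].to_numpy(), with_se=True
            )
            a, b, _ = fit_psychometric(
                g["orientation_deg"].to_numpy(), g["choice"].to_numpy()
            )
            rec.update(pse_deg=pse, pse_se=se, slope=b)
        except UndefinedPSEError:
            rec.update(pse_deg=np.nan, pse_se=np.nan, slope=np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Aligned bias
# ---------------------------------------------------------------------------


def aligned_bias(
    pse_by_context: Mapping[int, float], mode: str = "both_skew"
) -> float:
    """Context-appropriate PSE shift relative to the uniform context (deg).

    ``both_skew`` (default) averages the two skewed contexts:
    0.5*[(PSE_uniform - PSE_pos) + (PSE_neg - PSE_uniform)]. ``clockwise``
    uses only the positively skewed context: PSE_uniform - PSE_pos. Positive
    values mean choices are pulled toward each context's likelier category.
    """
    if 0 not in pse_by_context:
        raise ValueError("uniform-context (code 0) PSE is required")
    pse_u = pse_by_context[0]
    if mode == "clockwise":
        if 1 not in pse_by_context:
            raise ValueError("clockwise readout needs the positive-skew PSE")
        return float(pse_u - pse_by_context[1])
    terms = []
    if 1 in pse_by_context:
        terms.append(pse_u - pse_by_context[1])
    if -1 in pse_by_context:
        terms.append(pse_by_context[-1] - pse_u)
    if not terms:
        raise ValueError("need at least one skewed-context PSE")
    return float(np.mean(terms))


def normalized_bias(aligned_bias_deg: float, uncertainty_deg: float) -> float:
    """Aligned bias divided by orientation uncertainty (dimensionless)."""
    if uncertainty_deg <= 0:
        raise ValueError("uncertainty must be positive")
    return float(aligned_bias_deg / uncertainty_deg)


@dataclass
class BiasCurve:
    """Aligned bias resolved by trials since the most recent context switch."""

    s_values: np.ndarray  # bin labels (last bin pools s >= its label)
    bias: np.ndarray  # aligned bias (deg), NaN where flagged missing
    se: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_trials: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_bin": self.s_values,
                "aligned_bias_deg": self.bias,
                "se": self.se,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n_trials": self.n_trials,
            }
        )


def _bin_aligned_bias(sub: pd.DataFrame, mode: str) -> tuple[float, float]:
    """Aligned bias and delta-method SE within one subset of trials."""
    pses = {}
    ses = {}
    for ctx, g in sub.groupby("context"):
        try:
            pses[int(ctx)], ses[int(ctx)] = estimate_pse(
                g["orientation_deg"].to_numpy(), g["choice"].to_numpy(), with_se=True
            )
        except UndefinedPSEError:
            pass
    try:
        ab = aligned_bias(pses, mode=mode)
    except ValueError:
        return np.nan, np.nan
    if mode == "clockwise":
        se = float(np.sqrt(ses.get(0, np.nan) ** 2 + ses.get(1, np.nan) ** 2))
    else:
        parts = [ses[c] ** 2 for c in (-1, 1) if c in ses]
        se = float(0.5 * np.sqrt(sum(parts))) if parts else np.nan
    return ab, se


def bias_by_trials_since_switch(
    dataset: ChoiceDataset,
    s_bins: Sequence[int] | None = None,
    contrast: str | None = None,
    mode: str = "both_skew",
    min_trials: int = 50,
) -> BiasCurve:
    """Aligned bias per trials-since-switch bin.

    Bins default to the exact counts 1..9 plus a pooled "10 and later" bin.
    Bins with too few trials, or whose PSEs are undefined, are flagged NaN
    rather than extrapolated.
    """
    if s_bins is None:
        s_bins = list(range(1, 10)) + [10]
    df = dataset.to_frame()
    if contrast is not None:
        df = df[df["contrast"] == contrast]
    bias = np.full(len(s_bins), np.nan)
    se = np.full(len(s_bins), np.nan)
    nt = np.zeros(len(s_bins), dtype=int)
    last = len(s_bins) - 1
    for i, s in enumerate(s_bins):
        sub = df[df["s_count"] >= s] if i == last else df[df["s_count"] == s]
        nt[i] = len(sub)
        if len(sub) < min_trials:
            continue
        bias[i], se[i] = _bin_aligned_bias(sub, mode)
    return BiasCurve(
        s_values=np.asarray(s_bins),
        bias=bias,
        se=se,
        ci_lo=bias - se,
        ci_hi=bias + se,
        n_trials=nt,
    )


def bias_matrix(
    dataset: ChoiceDataset,
    s_bins: Sequence[int] | None = None,
    prev_bins: Sequence[int] | None = None,
    contrast: str | None = None,
    mode: str = "both_skew",
    min_trials: int = 200,
) -> pd.DataFrame:
    """Aligned bias over (previous run length, trials since switch).

    Rows index the length of the context run before the most recent switch
    (last row pools longer runs); columns index trials since the switch.
    Sparse cells are flagged NaN.
    """
    if s_bins is None:
        s_bins = list(range(1, 7)) + [7]
    if prev_bins is None:
        prev_bins = list(range(1, 7)) + [7]
    df = dataset.to_frame()
    df["prev_run"] = annotate_previous_run_length(dataset.trials.context)
    df = df[df["prev_run"] > 0]  # first run of the series has no previous run
    if contrast is not None:
        df = df[df["contrast"] == contrast]
    out = np.full((len(prev_bins), len(s_bins)), np.nan)
    for r, pr in enumerate(prev_bins):
        row = (
            df[df["prev_run"] >= pr]
            if r == len(prev_bins) - 1
            else df[df["prev_run"] == pr]
        )
        for c, s in enumerate(s_bins):
            cell = (
                row[row["s_count"] >= s]
                if c == len(s_bins) - 1
                else row[row["s_count"] == s]
            )
            if len(cell) < min_trials:
                continue
            out[r, c], _ = _bin_aligned_bias(cell, mode)
    return pd.DataFrame(
        out,
        index=pd.Index(prev_bins, name="prev_run_length"),
        columns=pd.Index(s_bins, name="s_count"),
    )


# ---------------------------------------------------------------------------
# Group-comparison utilities
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    x, y=None, alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test (paired); returns (stat, p)."""
    res = stats.wilcoxon(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(x, y, alternative: str = "greater") -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) test; returns (stat, p)."""
    res = stats.mannwhitneyu(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
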