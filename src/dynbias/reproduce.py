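"""Seeded end-to-end reproduction runs.

Three canned simulations: the knowledge ladder (accuracy of the four
observer variants under the training-phase-like generative settings), the
run-length statistics of the context chain at the training- and test-phase
hazard rates, and the bias-evolution surfaces (aligned-bias curves of the
dynamic observer under swept assumptions about hazard rate and cue
reliability, with the static observer as reference).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .bias import BiasCurve, bias_by_trials_since_switch
from .observer import ObserverConfig, make_model_variant, run_observer
from .task import (
    ChoiceDataset,
    TaskConfig,
    annotate_trials_since_switch,
    sample_context_chain,
    sample_measurements,
    simulate_trials,
)

__all__ = [
    "reproduce_ladder",
    "reproduce_run_length_stats",
    "observer_bias_curve",
    "reproduce_bias_surfaces",
]


def reproduce_ladder(
    n_trials: int = 200_000, seed: int = 0, config: TaskConfig | None = None
) -> pd.DataFrame:
    """Accuracy of observer variants 1-4 on a shared simulated task.

    All variants see the same stimuli, cues and sensory measurements, so the
    accuracy increments are paired; the paired Monte-Carlo SE of each
    increment is reported alongside.
    """
    cfg = TaskConfig.ladder(n_trials, seed=seed) if config is None else config
    rng = np.random.default_rng(seed)
    trials = simulate_trials(cfg, rng)
    y = sample_measurements(trials.orientation, trials.contrast, cfg, rng)
    rows = []
    prev_correct = None
    for k in (1, 2, 3, 4):
        obs = make_model_variant(k, cfg, tie_break_seed=seed)
        trace = run_observer(trials, y, obs, np.random.default_rng(seed + 17))
        rec = {
            "variant": k,
            "accuracy": trace.accuracy,
            "se": trace.accuracy_se(),
        }
        if prev_correct is not None:
            d = trace.correct - prev_correct
            rec["step_gain"] = float(d.mean())
            rec["step_se"] = float(d.std() / np.sqrt(len(d)))
        prev_correct = trace.correct
        rows.append(rec)
    return pd.DataFrame(rows)


def reproduce_run_length_stats(
    hazards: Sequence[float] = (0.063, 0.425),
    n_trials: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean trials since the most recent context switch, simulated and in
    closed form.

    Across trials the count S is geometric, P(S=k) = h(1-h)^(k-1), so the
    closed-form mean is 1/h.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for h in hazards:
        chain = sample_context_chain(n_trials, h, rng=rng)
        s = annotate_trials_since_switch(chain)
        rows.append(
            {
                "hazard": h,
                "mean_trials_since_switch": float(s.mean()),
                "closed_form": 1.0 / h if h > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows)


def observer_bias_curve(
    task: TaskConfig,
    observer: ObserverConfig,
    seed: int = 0,
    contrast: str = "low",
    s_bins: Sequence[int] | None = None,
) -> BiasCurve:
    """Simulate one observer on one generated task and return its aligned
    bias resolved by trials since switch."""
    rng = np.random.default_rng(seed)
    trials = simulate_trials(task, rng)
    y = sample_measurements(trials.orientation, trials.contrast, task, rng)
    trace = run_observer(trials, y, observer, np.random.default_rng(seed + 17))
    ds = ChoiceDataset(trials=trials, choice=trace.choice)
    return bias_by_trials_since_switch(ds, s_bins=s_bins, contrast=contrast)


def reproduce_bias_surfaces(
    n_trials: int = 1_000_000,
    seed: int = 0,
    assumed_hazards: Sequence[float] = (0.10, 0.20, 0.50),
    assumed_kappas: Sequence[float] = (0.4, 0.2, 0.025),
    kappa_sweep_hazard: float = 0.10,
    hazard_sweep_kappa: float = 0.4,
    contrast: str = "low",
    include_static: bool = True,
) -> pd.DataFrame:
    """Aligned-bias curves of the dynamic observer under swept assumptions.

    The generative task uses the test-phase settings; the observer's assumed
    hazard (top sweep) or assumed cue concentration (bottom sweep) is varied
    while the generative values stay fixed — the miscalibration studied with
    the ideal observer. The static variant-3 curve is appended as reference.
    """
    cfg = TaskConfig.test_phase(n_trials, seed=seed)
    rows = []

    def add(curve: BiasCurve, sweep: str, value: float, variant: int) -> None:
        df = curve.to_frame()
        df.insert(0, "variant", variant)
        df.insert(0, "value", value)
        df.insert(0, "sweep", sweep)
        rows.append(df)

    for h in assumed_hazards:
        obs = make_model_variant(4, cfg, assumed_hazard=h, assumed_kappa=hazard_sweep_kappa)
        add(observer_bias_curve(cfg, obs, seed=seed, contrast=contrast), "hazard", h, 4)
    for kp in assumed_kappas:
        obs = make_model_variant(4, cfg, assumed_hazard=kappa_sweep_hazard, assumed_kappa=kp)
        add(observer_bias_curve(cfg, obs, seed=seed, contrast=contrast), "kappa", kp, 4)
    if include_static:
        obs = make_model_variant(3, cfg, assumed_kappa=hazard_sweep_kappa)
        add(
            observer_bias_curve(cfg, obs, seed=seed, contrast=contrast),
            "static",
            np.nan,
            3,
        )
    return pd.concat(rows, ignore_index=True)
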