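"""Synthetic task generation for dynamic-context 2AFC orientation discrimination.

The simulated experiment: on every trial a hidden context (one of three)
selects a distribution over a small grid of stimulus orientations; the subject
judges whether the presented orientation is clockwise (+) or counter-clockwise
(-) of vertical. Contexts switch between trials with a fixed hazard rate,
forming a first-order Markov chain. A noisy context cue is shown each trial,
either as a categorical label that is valid with some probability or as an
angle drawn from a von Mises distribution centred on the context's angular
label. Stimuli appear at two contrast levels with contrast-dependent sensory
noise.

This module generates context chains, stimuli, cues, noisy sensory
measurements, and human-like choices (from the SDT or dynamic-GLM process
models), and reads/writes trial tables as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ORIENTATIONS",
    "CONTEXT_CODES",
    "TaskConfig",
    "TrialSequence",
    "ChoiceDataset",
    "default_context_pmfs",
    "sample_context_chain",
    "annotate_trials_since_switch",
    "annotate_previous_run_length",
    "sample_stimuli",
    "sample_cues",
    "sample_measurements",
    "simulate_trials",
    "generate_glm_observer_choices",
    "generate_sdt_observer_choices",
    "write_trials",
    "read_trials",
]

#: Orientation grid used in the experiment (deg, clockwise positive).
DEFAULT_ORIENTATIONS = np.array([-7.5, -5.0, -2.5, 0.0, 2.5, 5.0, 7.5])

#: Context codes: -1 negatively skewed, 0 uniform, +1 positively skewed.
CONTEXT_CODES = np.array([-1, 0, 1])

#: Angular labels of the three contexts for von Mises cues (rad); equally
#: spaced so that every pair of contexts is equally confusable.
DEFAULT_CONTEXT_LABELS = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])

CONTRAST_LEVELS = ("low", "high")


def default_context_pmfs(
    orientations: np.ndarray = DEFAULT_ORIENTATIONS, cw_mass: float = 0.7
) -> np.ndarray:
    """Context-specific orientation pmfs, one row per context code (-1, 0, +1).

    Every context puts 1/n_grid mass on the vertical orientation (theta = 0).
    The remaining mass is split between positive and negative orientations in
    ratio ``cw_mass : 1 - cw_mass`` for the positively skewed context (and the
    mirror image for the negatively skewed one), uniformly within each sign.
    With the default 70:30 split the baseline probability of "clockwise being
    correct" among non-vertical trials is 50/70/30% in the uniform, positively
    and negatively skewed contexts, and the marginal distribution of |theta| is
    identical across contexts (skew changes sign balance, not difficulty).
    """
    th = np.asarray(orientations, dtype=float)
    n = len(th)
    pos = th > 0
    neg = th < 0
    zero = th == 0
    if not pos.any() or not neg.any():
        raise ValueError("orientation grid must contain both signs")
    p_zero = zero.sum() / n
    rest = 1.0 - p_zero

    def skewed(mass_pos: float) -> np.ndarray:
        p = np.zeros(n)
        p[zero] = p_zero / max(zero.sum(), 1)
        p[pos] = rest * mass_pos / pos.sum()
        p[neg] = rest * (1.0 - mass_pos) / neg.sum()
        return p

    return np.vstack([skewed(1.0 - cw_mass), skewed(0.5), skewed(cw_mass)])


@dataclass
class TaskConfig:
    """Generative settings of the simulated task.

    Parameters
    ----------
    n_trials : int
        Number of trials to generate.
    hazard : float
        Per-trial probability h of a context switch (6.3% in the training
        phase, 42.5% in the test phase of the experiment).
    orientations : ndarray
        Orientation grid in deg.
    context_pmfs : ndarray, optional
        One pmf row per context code (-1, 0, +1); defaults to
        :func:`default_context_pmfs`.
    gen_noise : mapping
        Gaussian sensory-noise scale (SD, deg) per contrast level.
    cue_mode : {"von_mises", "categorical"}
        Von Mises cues are angles perturbed around the context's angular
        label; categorical cues equal the true context code with probability
        ``cue_validity``.
    contrast_mode : {"interleaved", "blocked"}
        Interleaved draws contrast independently per trial (as for 9/12
        subjects); blocked alternates contrast in runs of
        ``contrast_block`` trials.
    block_size : int
        Trials per experimental block (history regressors reset at block
        boundaries).
    """

    n_trials: int
    hazard: float = 0.2
    n_contexts: int = 3
    orientations: np.ndarray = field(
        default_factory=lambda: DEFAULT_ORIENTATIONS.copy()
    )
    context_pmfs: np.ndarray | None = None
    gen_noise: Mapping[str, float] = field(
        default_factory=lambda: {"high": 10.0, "low": 20.0}
    )
    cue_mode: str = "von_mises"
    cue_validity: float = 0.8
    cue_kappa: float = 1.5
    context_labels: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONTEXT_LABELS.copy()
    )
    contrast_mode: str = "interleaved"
    contrast_block: int = 8
    block_size: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.context_pmfs is None:
            if self.n_contexts != 3:
                raise ValueError("default context pmfs require n_contexts=3")
            self.context_pmfs = default_context_pmfs(self.orientations)
        self.context_pmfs = np.asarray(self.context_pmfs, dtype=float)
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError(f"hazard must be in [0, 1], got {self.hazard}")
        if self.n_contexts < 2:
            raise ValueError("need at least two contexts")
        if self.context_pmfs.shape != (self.n_contexts, len(self.orientations)):
            raise ValueError("context_pmfs shape must be (n_contexts, n_orientations)")
        if not np.allclose(self.context_pmfs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each context pmf must sum to 1 (within 1e-12)")
        if (self.context_pmfs < 0).any():
            raise ValueError("context pmfs must be nonnegative")
        if any(s <= 0 for s in self.gen_noise.values()):
            raise ValueError("gen_noise scales must be positive")
        if not 0.0 <= self.cue_validity <= 1.0:
            raise ValueError("cue_validity must be in [0, 1]")
        if self.cue_kappa < 0:
            raise ValueError("cue_kappa must be nonnegative")
        if self.cue_mode not in ("von_mises", "categorical"):
            raise ValueError(f"unknown cue_mode {self.cue_mode!r}")
        if self.cue_mode == "von_mises" and self.cue_kappa is None:
            raise ValueError("von Mises cue mode requires cue_kappa")
        if self.contrast_mode not in ("interleaved", "blocked"):
            raise ValueError(f"unknown contrast_mode {self.contrast_mode!r}")

    # Presets for the two simulation regimes studied with the ideal observer.

    @classmethod
    def ladder(cls, n_trials: int, seed: int = 0, **kw) -> "TaskConfig":
        """Training-phase-like settings used for the knowledge-ladder run
        (hazard 20%, cue kappa 1.5, noise SDs 10/20 deg)."""
        return cls(
            n_trials=n_trials,
            hazard=0.2,
            cue_kappa=1.5,
            gen_noise={"high": 10.0, "low": 20.0},
            seed=seed,
            **kw,
        )

    @classmethod
    def test_phase(cls, n_trials: int, seed: int = 0, **kw) -> "TaskConfig":
        """Test-phase-like settings used for the bias-evolution sweeps
        (hazard 42.5%, noise SDs 2/5 deg)."""
        kw.setdefault("cue_kappa", 0.4)
        return cls(
            n_trials=n_trials,
            hazard=0.425,
            gen_noise={"high": 2.0, "low": 5.0},
            seed=seed,
            **kw,
        )

    def replace(self, **kw) -> "TaskConfig":
        return replace(self, **kw)


@dataclass
class TrialSequence:
    """A generated task sequence (no choices).

    ``context`` holds context codes in {-1, 0, +1}; ``cue`` holds either a
    context code (categorical mode) or an angle in radians (von Mises mode);
    ``s_count`` counts trials since the most recent context switch, the first
    trial of a run (and of the whole sequence) counting as 1.
    """

    context: np.ndarray
    orientation: np.ndarray
    contrast: np.ndarray
    cue: np.ndarray
    s_count: np.ndarray
    block: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.context)
        if self.block is None:
            self.block = np.zeros(n, dtype=int)
        for name in ("orientation", "contrast", "cue", "s_count", "block"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match context length")
        if (np.asarray(self.s_count) < 1).any():
            raise ValueError("s_count must be >= 1")

    def __len__(self) -> int:
        return len(self.context)

    @property
    def is_high_contrast(self) -> np.ndarray:
        return np.asarray(self.contrast) == "high"

    def to_frame(self, choice: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "block": self.block,
                "context": self.context,
                "orientation_deg": self.orientation,
                "contrast": self.contrast,
                "cue": self.cue,
                "s_count": self.s_count,
                "choice": choice if choice is not None else [""] * len(self),
            }
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSequence":
        return cls(
            context=df["context"].to_numpy(dtype=int),
            orientation=df["orientation_deg"].to_numpy(dtype=float),
            contrast=df["contrast"].to_numpy(dtype=object),
            cue=df["cue"].to_numpy(),
            s_count=df["s_count"].to_numpy(dtype=int),
            block=df["block"].to_numpy(dtype=int),
        )


@dataclass
class ChoiceDataset:
    """A trial sequence plus per-trial binary choices (+1 cw / -1 ccw)."""

    trials: TrialSequence
    choice: np.ndarray

    def __post_init__(self) -> None:
        self.choice = np.asarray(self.choice, dtype=int)
        if len(self.choice) != len(self.trials):
            raise ValueError("choice length does not match trial count")
        if not np.isin(self.choice, (-1, 1)).all():
            raise ValueError("choices must be -1 or +1")

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return self.trials.to_frame(choice=self.choice)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _choice_rng(seed_or_rng, salt: int) -> np.random.Generator:
    """Seeded generator for choice simulation, decoupled from the task
    stream: passing the same integer to simulate_trials and to a choice
    generator must not reuse the same uniforms (the context-switch draws
    would otherwise be correlated with the simulated choices)."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(np.random.SeedSequence(seed_or_rng, spawn_key=(salt,)))


def sample_context_chain(
    n_trials: int,
    hazard: float,
    n_contexts: int = 3,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Sample the hidden-context Markov chain.

    The first trial is uniform over contexts; each subsequent trial keeps the
    current context with probability ``1 - hazard`` and otherwise jumps to one
    of the remaining ``n_contexts - 1`` contexts with equal probability.
    Returns context codes centred on zero for three contexts ({-1, 0, +1}),
    else indices 0..N-1.
    """
    if not 0.0 <= hazard <= 1.0:
        raise ValueError(f"hazard must be in [0, 1], got {hazard}")
    if n_contexts < 2:
        raise ValueError("need at least two contexts")
    rng = _rng(rng)
    # A switch jumps by a uniform offset in 1..N-1 (mod N), which is uniform
    # over the other contexts and lets the whole chain be cumulated at once.
    switch = rng.random(n_trials) < hazard
    offsets = np.where(switch, rng.integers(1, n_contexts, size=n_trials), 0)
    offsets[0] = 0
    states = (rng.integers(n_contexts) + np.cumsum(offsets)) % n_contexts
    if n_contexts == 3:
        return states.astype(int) - 1
    return states.astype(int)


def annotate_trials_since_switch(context: np.ndarray) -> np.ndarray:
    """Trials since the most recent context switch, current trial included.

    The first trial of each context run gets 1; the first trial of the whole
    series is treated as if a switch preceded it.
    """
    context = np.asarray(context)
    if len(context) == 0:
        raise ValueError("context series must be nonempty")
    n = len(context)
    idx = np.arange(n)
    is_start = np.r_[True, context[1:] != context[:-1]]
    last_start = np.maximum.accumulate(np.where(is_start, idx, 0))
    return idx - last_start + 1


def annotate_previous_run_length(context: np.ndarray) -> np.ndarray:
    """Length of the context run *before* the most recent switch.

    Trials in the first run of the series have no previous run; they get 0
    (callers flag them rather than extrapolate).
    """
    context = np.asarray(context)
    n = len(context)
    is_start = np.r_[True, context[1:] != context[:-1]]
    starts = np.flatnonzero(is_start)
    run_lengths = np.diff(np.r_[starts, n])
    run_id = np.cumsum(is_start) - 1
    prev_len = np.zeros(len(starts), dtype=int)
    prev_len[1:] = run_lengths[:-1]
    return prev_len[run_id]


def sample_stimuli(
    context: np.ndarray,
    config: TaskConfig,
    rng: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-trial orientations from the active context's pmf, and
    contrast levels (independent fair draw, or blocked)."""
    rng = _rng(rng)
    context = np.asarray(context)
    n = len(context)
    pmfs = config.context_pmfs
    if pmfs.shape[1] != len(config.orientations):
        raise ValueError("pmf/orientation length mismatch")
    cdf = np.cumsum(pmfs, axis=1)
    u = rng.random(n)
    ctx_idx = context + 1 if config.n_contexts == 3 else context
    picks = (u[:, None] > cdf[ctx_idx]).sum(axis=1)
    orientation = config.orientations[picks]
    if config.contrast_mode == "interleaved":
        is_high = rng.random(n) < 0.5
    else:
        is_high = (np.arange(n) // config.contrast_block) % 2 == 1
    contrast = np.where(is_high, "high", "low").astype(object)
    return orientation, contrast


def sample_cues(
    context: np.ndarray,
    config: TaskConfig,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Draw the per-trial context cue.

    Categorical mode: the cue equals the true context code with probability
    ``cue_validity``, else one of the other two codes uniformly. Von Mises
    mode: an angle drawn around the context's angular label with
    concentration ``cue_kappa``.
    """
    rng = _rng(rng)
    context = np.asarray(context)
    n = len(context)
    if config.cue_mode == "categorical":
        valid = rng.random(n) < config.cue_validity
        offsets = rng.integers(1, config.n_contexts, size=n)
        idx = context + 1 if config.n_contexts == 3 else context
        wrong = (idx + offsets) % config.n_contexts
        out = np.where(valid, idx, wrong)
        return out - 1 if config.n_contexts == 3 else out
    if config.cue_kappa is None:
        raise ValueError("von Mises cue mode requires cue_kappa")
    labels = config.context_labels[context + 1]
    angles = rng.vonmises(labels, max(config.cue_kappa, 1e-12), size=n)
    return np.mod(angles, 2.0 * np.pi)


def sample_measurements(
    orientation: np.ndarray,
    contrast: np.ndarray,
    config: TaskConfig,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Noisy sensory measurement y = theta + N(0, sigma_contrast^2) (deg)."""
    rng = _rng(rng)
    noise = dict(config.gen_noise)
    sigma = np.where(np.asarray(contrast, dtype=object) == "high", noise["high"], noise["low"])
    return np.asarray(orientation, dtype=float) + rng.normal(0.0, 1.0, len(sigma)) * sigma.astype(float)


def simulate_trials(
    config: TaskConfig, rng: np.random.Generator | int | None = None
) -> TrialSequence:
    """Generate a full trial sequence from the generative settings."""
    rng = _rng(config.seed if rng is None else rng)
    context = sample_context_chain(config.n_trials, config.hazard, config.n_contexts, rng)
    s_count = annotate_trials_since_switch(context)
    orientation, contrast = sample_stimuli(context, config, rng)
    cue = sample_cues(context, config, rng)
    block = np.arange(config.n_trials) // config.block_size
    return TrialSequence(
        context=context,
        orientation=orientation,
        contrast=contrast,
        cue=cue,
        s_count=s_count,
        block=block,
    )


def generate_glm_observer_choices(
    trials: TrialSequence,
    params,
    rng: np.random.Generator | int | None = 0,
) -> ChoiceDataset:
    """Simulate a human-like observer from the dynamic Bernoulli GLM.

    The linear predictor combines the six regressors (orientation, its
    high-contrast interaction, context, the trials-since-switch bias function,
    the previous *generated* response, and the previous orientation) plus an
    intercept; choices are Bernoulli draws through the logistic link. History
    regressors reset to zero at block boundaries.
    """
    from .glm import bias_function  # deferred: glm imports this module's types

    rng = _choice_rng(rng, 1)
    n = len(trials)
    theta = np.asarray(trials.orientation, dtype=float)
    de = trials.is_high_contrast.astype(float)
    ctx = np.asarray(trials.context, dtype=float)
    f = bias_function(np.asarray(trials.s_count), np.asarray(trials.context), params.gamma)
    base = (
        params.w_alpha
        + params.w_theta * theta
        + params.w_e * theta * de
        + params.w_C * ctx
        + params.w_S * f
    )
    block = np.asarray(trials.block)
    block_start = np.r_[True, block[1:] != block[:-1]]
    u = rng.random(n)
    choices = np.empty(n, dtype=int)
    prev_r = 0.0
    prev_theta = 0.0
    for t in range(n):
        if block_start[t]:
            prev_r = 0.0
            prev_theta = 0.0
        eta = base[t] + params.w_r * prev_r + params.w_p * prev_theta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))
        c = 1 if u[t] < p else -1
        choices[t] = c
        prev_r = float(c)
        prev_theta = theta[t]
    return ChoiceDataset(trials=trials, choice=choices)


def generate_sdt_observer_choices(
    trials: TrialSequence,
    params,
    rng: np.random.Generator | int | None = 0,
) -> ChoiceDataset:
    """Simulate choices from the SDT process model (Bernoulli draws from
    its predicted clockwise probability)."""
    from .sdt import predict_p_cw

    rng = _choice_rng(rng, 2)
    p = predict_p_cw(
        trials.orientation, trials.is_high_contrast, trials.context, params
    )
    choices = np.where(rng.random(len(trials)) < p, 1, -1)
    return ChoiceDataset(trials=trials, choice=choices)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_trials(obj: TrialSequence | ChoiceDataset, path) -> None:
    """Write a trial table as CSV (choice column blank for unlabeled
    sequences)."""
    if isinstance(obj, ChoiceDataset):
        df = obj.to_frame()
    else:
        df = obj.to_frame()
    df.to_csv(path, index=False)


def read_trials(path) -> TrialSequence | ChoiceDataset:
    """Read a trial table CSV; returns a ChoiceDataset when the choice
    column is populated, else a TrialSequence."""
    df = pd.read_csv(path)
    seq = TrialSequence.from_frame(df)
    if "choice" in df and df["choice"].notna().all() and (df["choice"].astype(str) != "").all():
        return ChoiceDataset(trials=seq, choice=df["choice"].to_numpy(dtype=int))
    return seq
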