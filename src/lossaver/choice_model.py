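"""Prospect-theory subjective value and softmax choice rule.

A gamble's value is the 50/50 mixture of the power utilities of its gain
and loss branches; the loss branch is scaled by the loss-aversion weight
``lam`` and carries negative sign.  Acceptance probability is a logistic
function of the value difference from the certain option ($0), scaled by
the sensitivity ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task_design import Gamble, TaskDesign

__all__ = [
    "ProspectParams",
    "RTConfig",
    "SubjectChoices",
    "RESPONSE_LABELS",
    "subjective_value",
    "gamble_value",
    "accept_probability",
    "simulate_choices",
    "cohort_to_frame",
    "frame_to_cohort",
]

# 4-level response coding used in trial CSV files.
RESPONSE_LABELS: dict[int, str] = {
    1: "strong_accept",
    2: "weak_accept",
    3: "weak_reject",
    4: "strong_reject",
}

TRIAL_COLUMNS = ["subject_id", "trial_index", "gain", "loss", "response", "rt"]


@dataclass(frozen=True)
class ProspectParams:
    """Subject-level choice parameters.

    lam : loss-aversion weight (> 0); lam > 1 weighs losses more than gains.
    rho : utility curvature (> 0); rho < 1 gives diminishing marginal utility.
    tau : logit sensitivity (>= 0); larger values give more deterministic choice.
    """

    lam: float
    rho: float
    tau: float

    def __post_init__(self) -> None:
        vals = (self.lam, self.rho, self.tau)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"parameters must be finite, got {vals}")
        if self.lam <= 0 or self.rho <= 0:
            raise ValueError(f"lam and rho must be > 0, got {self.lam}, {self.rho}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class RTConfig:
    """Log-normal reaction-time model truncated to (0, rt_max] seconds."""

    mu: float = 0.2
    sigma: float = 0.4
    rt_max: float = 3.0
    timeout_prob: float = 0.0


@dataclass
class SubjectChoices:
    """All trials of one subject.

    ``trials`` columns: trial_index, gain, loss, response (1-4 coded, NaN for
    a timeout), rt (seconds, NaN for a timeout).
    """

    subject_id: str
    trials: pd.DataFrame

    def __len__(self) -> int:
        return len(self.trials)


def subjective_value(x, params: ProspectParams):
    """Power-utility subjective value of a signed dollar amount.

    SV(x) = x**rho for x >= 0 and -lam * (-x)**rho for x < 0.  Losses carry
    negative subjective value; ``lam`` scales how much they loom.
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("amounts must be finite")
    out = np.where(x >= 0, np.abs(x) ** params.rho, -params.lam * np.abs(x) ** params.rho)
    return float(out) if out.ndim == 0 else out


def gamble_value(gamble, params: ProspectParams, *, loss=None) -> float:
    """Subjective value of a 50/50 mixed gamble against the $0 status quo.

    Either pass a :class:`~lossaver.task_design.Gamble`, or a gain with
    ``loss=`` given as a positive magnitude.
    """
    if isinstance(gamble, Gamble):
        gain, loss = gamble.gain, gamble.loss
    else:
        gain = gamble
        if loss is None:
            raise TypeError("pass a Gamble or both gain and loss=")
    return 0.5 * subjective_value(gain, params) + 0.5 * subjective_value(-loss, params)


def accept_probability(sv_gamble, sv_certain, tau):
    """Logistic acceptance probability 1 / (1 + exp(-tau * (sv_g - sv_c)))."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    z = tau * (np.asarray(sv_gamble, dtype=float) - np.asarray(sv_certain, dtype=float))
    out = sps.logistic.cdf(z)
    return float(out) if out.ndim == 0 else out


def _draw_rts(n: int, cfg: RTConfig, rng: np.random.Generator) -> np.ndarray:
    # inverse-CDF sampling of a log-normal truncated at rt_max
    dist = sps.lognorm(s=cfg.sigma, scale=np.exp(cfg.mu))
    u = rng.uniform(0.0, dist.cdf(cfg.rt_max), size=n)
    return dist.ppf(u)


def simulate_choices(
    design: TaskDesign,
    params: ProspectParams,
    seed: int | None = None,
    rt_model: RTConfig = RTConfig(),
    subject_id: str = "sim",
) -> SubjectChoices:
    """Simulate one subject's 4-level responses and RTs on a design.

    Accept/reject is a Bernoulli draw from :func:`accept_probability`;
    strong vs weak variants are split uniformly.  With probability
    ``rt_model.timeout_prob`` a trial times out (response and RT missing).
    """
    rng = np.random.default_rng(seed)
    gains = np.array([g.gain for g in design.trials], dtype=float)
    losses = np.array([g.loss for g in design.trials], dtype=float)
    sv = 0.5 * gains**params.rho - 0.5 * params.lam * losses**params.rho
    p = accept_probability(sv, 0.0, params.tau)
    accept = rng.uniform(size=len(p)) < p
    strong = rng.uniform(size=len(p)) < 0.5
    response = np.where(accept, np.where(strong, 1, 2), np.where(strong, 4, 3)).astype(
        float
    )
    rt = _draw_rts(len(p), rt_model, rng)
    if rt_model.timeout_prob > 0:
        timeout = rng.uniform(size=len(p)) < rt_model.timeout_prob
        response[timeout] = np.nan
        rt[timeout] = np.nan
    df = pd.DataFrame(
        {
            "trial_index": np.arange(1, len(p) + 1),
            "gain": gains,
            "loss": losses,
            "response": response,
            "rt": rt,
        }
    )
    return SubjectChoices(subject_id=subject_id, trials=df)


def cohort_to_frame(cohort: list[SubjectChoices]) -> pd.DataFrame:
    """Stack per-subject trial tables into one long trial CSV frame."""
    frames = []
    for sc in cohort:
        df = sc.trials.copy()
        df.insert(0, "subject_id", sc.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def frame_to_cohort(df: pd.DataFrame) -> list[SubjectChoices]:
    """Split a long trial frame back into per-subject tables."""
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial frame missing columns: {sorted(missing)}")
    return [
        SubjectChoices(subject_id=str(sid), trials=g.drop(columns="subject_id").reset_index(drop=True))
        for sid, g in df.groupby("subject_id", sort=True)
    ]
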