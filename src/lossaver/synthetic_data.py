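"""Synthetic study generator with the structural links the analysis assumes.

One call produces a full cohort: trial-level gamble choices simulated from
the prospect-theory model, a per-subject cortical-thickness table with
scanner batch effects, and demographics.  The structural model couples age,
posterior-cingulate thickness and loss aversion so that the downstream
quadratic-age regression and the causal mediation analysis have known
ground truth:

    thickness_i = t0 + s * age + s2 * age^2 + batch + u_i
    lambda_i    = c + b1 * age + b2 * age^2 + b_th * u_i + eps_i

with s2 = mediated_fraction * b2 / b_th, so the marginal age coefficients
of lambda are exactly (b1, b2), the share ``mediated_fraction`` of the
age^2 effect travels through thickness (true ACME for a treatment contrast
delta in age^2 is mediated_fraction * b2 * delta), and zero noise makes the
age-lambda relation an exact parabola.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .choice_model import ProspectParams, RTConfig, cohort_to_frame, simulate_choices
from .task_design import generate_design

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_worked_fixture",
    "write_cohort",
]

# parcels emitted beyond the ROI constituents, so whole-brain averaging is
# exercised over a wider set
_EXTRA_PARCELS = ("superiorfrontal", "precentral", "lateraloccipital", "precuneus")
_ROI_CONSTITUENTS = (
    "insula",
    "medialorbitofrontal",
    "lateralorbitofrontal",
    "rostralanteriorcingulate",
    "caudalanteriorcingulate",
    "posteriorcingulate",
)
_PARCEL_BASELINES = {
    "insula": 3.0,
    "medialorbitofrontal": 2.5,
    "lateralorbitofrontal": 2.6,
    "rostralanteriorcingulate": 2.9,
    "caudalanteriorcingulate": 2.7,
    "posteriorcingulate": 2.55,
    "superiorfrontal": 2.8,
    "precentral": 2.6,
    "lateraloccipital": 2.2,
    "precuneus": 2.4,
}
_PARCEL_VOLUMES = {
    "insula": 6800.0,
    "medialorbitofrontal": 5200.0,
    "lateralorbitofrontal": 7400.0,
    "rostralanteriorcingulate": 2400.0,
    "caudalanteriorcingulate": 2000.0,
    "posteriorcingulate": 3100.0,
    "superiorfrontal": 21000.0,
    "precentral": 13000.0,
    "lateraloccipital": 11000.0,
    "precuneus": 9800.0,
}


@dataclass
class GeneratorConfig:
    n_subjects: int = 106
    n_trials: int = 128
    age_min: float = 17.0
    age_max: float = 54.0

    lambda_mean: float = 1.58
    lambda_sd: float = 0.35  # residual SD of lambda around its structural mean
    rho_mean: float = 0.60
    rho_sd: float = 0.10
    tau_mean: float = 3.07
    tau_sd: float = 1.2

    age_beta1: float = -0.067  # linear age coefficient of lambda
    age_beta2: float = 0.0010  # quadratic age coefficient of lambda

    pcc_intercept: float = 2.85  # mm at age 0 (linear part)
    pcc_slope: float = -0.0073  # mm per year
    pcc_noise_sd: float = 0.08
    thickness_lambda_coupling: float = -2.0  # lambda units per mm of residual
    mediated_fraction: float = 0.5

    n_scanners: int = 3
    scanner_offsets: tuple[float, ...] = (0.0, 0.12, -0.08)  # mm
    etiv_mean: float = 1.5e6
    etiv_sd: float = 1.2e5

    fast_rt_rate: float = 0.002  # fraction of trials with sub-200 ms RTs
    timeout_prob: float = 0.01
    qc_fail_rate: float = 0.02
    rt_model: RTConfig = field(default_factory=lambda: RTConfig(timeout_prob=0.0))

    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("lambda_sd", "rho_sd", "tau_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.mediated_fraction <= 1.0:
            raise ValueError("mediated_fraction must be in [0, 1]")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.thickness_lambda_coupling == 0 and self.mediated_fraction > 0:
            raise ValueError("nonzero mediated_fraction needs nonzero coupling")
        if len(self.scanner_offsets) < self.n_scanners:
            raise ValueError("need one scanner offset per scanner")
        if not (0 < self.lambda_mean < 5 and 0 < self.rho_mean < 2 and 0 < self.tau_mean < 30):
            raise ValueError("group means must lie inside the fit bounds")


@dataclass
class SyntheticCohort:
    trials: pd.DataFrame  # long trial table: subject_id, trial_index, gain, loss, response, rt
    thickness: pd.DataFrame  # one row per subject, demographics + parcel columns
    truth: pd.DataFrame  # generating per-subject parameters

    @property
    def demographics(self) -> pd.DataFrame:
        cols = ["subject_id", "age", "sex", "race_ethnicity", "iq", "mother_education", "smoking"]
        return self.truth[cols].copy()


def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    bad = (x <= lo) | (x >= hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x <= lo) | (x >= hi)
    return x


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic study from the structural model above."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    ids = [f"S{i + 1:03d}" for i in range(n)]

    age = rng.uniform(cfg.age_min, cfg.age_max, size=n)
    scanner = rng.integers(1, cfg.n_scanners + 1, size=n)
    offsets = np.asarray(cfg.scanner_offsets)[scanner - 1]

    b_th = cfg.thickness_lambda_coupling
    s2 = cfg.mediated_fraction * cfg.age_beta2 / b_th if cfg.mediated_fraction > 0 else 0.0
    u = rng.normal(0.0, cfg.pcc_noise_sd, size=n)
    pcc = cfg.pcc_intercept + cfg.pcc_slope * age + s2 * age**2 + offsets + u

    # intercept chosen so the population mean of lambda matches lambda_mean
    mean_age = 0.5 * (cfg.age_min + cfg.age_max)
    mean_age2 = (cfg.age_max - cfg.age_min) ** 2 / 12.0 + mean_age**2
    c = cfg.lambda_mean - cfg.age_beta1 * mean_age - cfg.age_beta2 * mean_age2
    lam = (
        c
        + cfg.age_beta1 * age
        + cfg.age_beta2 * age**2
        + b_th * u
        + rng.normal(0.0, cfg.lambda_sd, size=n)
    )
    lam = np.clip(lam, 0.05, 4.95)
    rho = _truncated_normal(rng, cfg.rho_mean, cfg.rho_sd, 0.05, 1.95, n)
    tau = _truncated_normal(rng, cfg.tau_mean, cfg.tau_sd, 0.05, 29.0, n)

    design = generate_design(cfg.n_trials, seed=int(rng.integers(2**31)))
    rt_cfg = RTConfig(
        mu=cfg.rt_model.mu,
        sigma=cfg.rt_model.sigma,
        rt_max=cfg.rt_model.rt_max,
        timeout_prob=cfg.timeout_prob,
    )
    subjects = []
    for i, sid in enumerate(ids):
        sc = simulate_choices(
            design,
            ProspectParams(lam=float(lam[i]), rho=float(rho[i]), tau=float(tau[i])),
            seed=int(rng.integers(2**31)),
            rt_model=rt_cfg,
            subject_id=sid,
        )
        if cfg.fast_rt_rate > 0:
            fast = rng.uniform(size=len(sc.trials)) < cfg.fast_rt_rate
            sc.trials.loc[fast, "rt"] = rng.uniform(0.05, 0.19, size=int(fast.sum()))
        subjects.append(sc)
    trials = cohort_to_frame(subjects)

    sex = rng.choice(["F", "M"], size=n)
    race = rng.choice([1, 2, 3, 4], size=n, p=[0.45, 0.25, 0.15, 0.15])
    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "age": age,
            "sex": sex,
            "race_ethnicity": race,
            "iq": rng.normal(108, 10, size=n).round(1),
            "mother_education": rng.normal(14, 2, size=n).round(1),
            "smoking": rng.integers(0, 2, size=n),
            "scanner_id": scanner,
            "lam_true": lam,
            "rho_true": rho,
            "tau_true": tau,
            "pcc_true": pcc,
        }
    )

    thick = {
        "subject_id": ids,
        "age": age,
        "sex": sex,
        "race_ethnicity": race,
        "scanner_id": scanner,
        "etiv": np.clip(rng.normal(cfg.etiv_mean, cfg.etiv_sd, size=n), 8e5, None),
        "qc_pass": rng.uniform(size=n) >= cfg.qc_fail_rate,
    }
    parcels = _ROI_CONSTITUENTS + _EXTRA_PARCELS
    for parcel in parcels:
        for hemi in ("lh", "rh"):
            if parcel == "posteriorcingulate":
                th = pcc + rng.normal(0.0, 0.01, size=n)  # hemispheres nearly identical
            else:
                th = (
                    _PARCEL_BASELINES[parcel]
                    - 0.005 * (age - mean_age)
                    + 0.8 * offsets
                    + rng.normal(0.0, 0.06, size=n)
                )
            thick[f"{parcel}_{hemi}_thickness"] = np.clip(th, 0.6, 4.9)
            thick[f"{parcel}_{hemi}_volume"] = _PARCEL_VOLUMES[parcel] * (
                1.0 + rng.normal(0.0, 0.05, size=n)
            )
    thickness = pd.DataFrame(thick)
    return SyntheticCohort(trials=trials, thickness=thickness, truth=truth)


def generate_worked_fixture() -> SyntheticCohort:
    """Deterministic 5-subject, 20-trial, 2-scanner miniature dataset.

    Subject S005 is an all-accept responder so the consistency screen has a
    guaranteed exclusion; all floats are rounded so the emitted CSV text is
    byte-identical across runs.
    """
    cfg = GeneratorConfig(
        n_subjects=5,
        n_trials=20,
        n_scanners=2,
        scanner_offsets=(0.0, 0.1),
        qc_fail_rate=0.0,
        timeout_prob=0.0,
        fast_rt_rate=0.0,
        seed=20210712,
    )
    cohort = generate_cohort(cfg)
    # rename to a fixed-width scheme and force the last subject degenerate
    mapping = {f"S{i + 1:03d}": f"S{i + 1:03d}" for i in range(5)}
    cohort.trials["subject_id"] = cohort.trials["subject_id"].map(mapping)
    last = cohort.trials["subject_id"] == "S005"
    cohort.trials.loc[last, "response"] = np.tile([1.0, 2.0], 10)
    for df in (cohort.trials, cohort.thickness, cohort.truth):
        for col in df.columns:
            if df[col].dtype == float:
                df[col] = df[col].round(6)
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write trials.csv, thickness.csv and truth.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("trials", cohort.trials),
        ("thickness", cohort.thickness),
        ("truth", cohort.truth),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
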