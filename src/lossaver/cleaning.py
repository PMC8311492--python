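"""Two-stage data-quality procedure for the gamble task.

Stage 1 removes individual trials with implausibly fast reaction times
(< 200 ms) or missing responses.  Stage 2 screens out subjects whose
choices do not track gain magnitude, loss magnitude, or expected value in
the directions a value-based chooser must show.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .choice_model import SubjectChoices

__all__ = [
    "RT_MIN_DEFAULT",
    "MIN_TRIALS_DEFAULT",
    "CleaningReport",
    "collapse_response",
    "collapse_responses",
    "filter_trials",
    "screen_subject",
    "clean_cohort",
]

RT_MIN_DEFAULT = 0.200  # seconds; "< 200 ms" is a strict inequality
MIN_TRIALS_DEFAULT = 64

_ACCEPT_CODES = {1, 2}
_REJECT_CODES = {3, 4}


@dataclass
class CleaningReport:
    n_trials_total: int = 0
    n_trials_removed: int = 0
    excluded_subjects: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def pct_trials_removed(self) -> float:
        """Percentage of trials removed, 0-100."""
        if self.n_trials_total == 0:
            return 0.0
        return 100.0 * self.n_trials_removed / self.n_trials_total

    def to_dict(self) -> dict:
        return {
            "n_trials_total": self.n_trials_total,
            "n_trials_removed": self.n_trials_removed,
            # 4 significant figures, comparable with fractions as small as 0.0048%
            "pct_trials_removed": float(f"{self.pct_trials_removed:.4g}"),
            "excluded_subjects": [
                {"subject_id": sid, "reasons": reasons}
                for sid, reasons in self.excluded_subjects
            ],
        }


def collapse_response(response4) -> float:
    """Collapse the 4-level response to binary: 1 accept, 0 reject, NaN missing."""
    if response4 is None or (isinstance(response4, float) and np.isnan(response4)):
        return np.nan
    code = int(response4)
    if code in _ACCEPT_CODES:
        return 1.0
    if code in _REJECT_CODES:
        return 0.0
    raise ValueError(f"unknown response code {response4!r}")


def collapse_responses(responses: pd.Series) -> pd.Series:
    """Vectorized :func:`collapse_response`."""
    resp = pd.to_numeric(responses, errors="raise")
    bad = resp.dropna()[~resp.dropna().isin([1, 2, 3, 4])]
    if len(bad):
        raise ValueError(f"unknown response codes: {sorted(bad.unique())}")
    return resp.map({1: 1.0, 2: 1.0, 3: 0.0, 4: 0.0})


def filter_trials(
    sc: SubjectChoices, rt_min: float = RT_MIN_DEFAULT
) -> tuple[SubjectChoices, CleaningReport]:
    """Drop trials with rt < rt_min or a missing response.

    A trial at exactly ``rt_min`` is kept.  Idempotent.
    """
    df = sc.trials
    bad = (df["rt"] < rt_min) | df["response"].isna() | df["rt"].isna()
    kept = df.loc[~bad].reset_index(drop=True)
    report = CleaningReport(n_trials_total=len(df), n_trials_removed=int(bad.sum()))
    return SubjectChoices(subject_id=sc.subject_id, trials=kept), report


def _slope_sign_fallback(x: np.ndarray, y: np.ndarray) -> float:
    # acceptance-rate difference between upper and lower halves of the
    # predictor's range; used when the logistic fit separates
    mid = 0.5 * (x.min() + x.max())
    hi, lo = y[x > mid], y[x <= mid]
    if len(hi) == 0 or len(lo) == 0:
        return 0.0
    return float(hi.mean() - lo.mean())


def _logistic_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Point-estimate slope of accept ~ predictor, with a separation fallback."""
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        slope = float(res.params[1])
        if not np.isfinite(slope) or abs(slope) > 50:
            raise ValueError("separation")
    except Exception:
        slope = _slope_sign_fallback(x, y)
    return slope


def screen_subject(
    sc: SubjectChoices, min_trials: int = MIN_TRIALS_DEFAULT
) -> tuple[bool, list[str]]:
    """Preference-consistency screen for one subject (after trial filtering).

    The subject passes iff acceptance increases with gain, decreases with
    loss, and increases with expected value (point-estimate slope signs of
    three univariate logistic regressions; no significance threshold).
    Degenerate all-accept / all-reject subjects and subjects with fewer than
    ``min_trials`` analyzable trials fail.
    """
    df = sc.trials
    accept = collapse_responses(df["response"])
    ok = accept.notna()
    y = accept[ok].to_numpy()
    gains = df.loc[ok, "gain"].to_numpy(dtype=float)
    losses = df.loc[ok, "loss"].to_numpy(dtype=float)

    reasons: list[str] = []
    if len(y) < min_trials:
        reasons.append("too_few_trials")
    if len(y) > 0 and (y.min() == y.max()):
        reasons.append("degenerate_all_same")
        return False, reasons
    if reasons:
        return False, reasons

    ev = 0.5 * (gains - losses)
    checks = [
        ("non_monotone_gain", gains, 1.0),
        ("non_monotone_loss", losses, -1.0),
        ("non_monotone_ev", ev, 1.0),
    ]
    for reason, x, want_sign in checks:
        slope = _logistic_slope(x, y)
        if slope * want_sign <= 0:
            reasons.append(reason)
    return (len(reasons) == 0), reasons


def clean_cohort(
    cohort: list[SubjectChoices],
    rt_min: float = RT_MIN_DEFAULT,
    min_trials: int = MIN_TRIALS_DEFAULT,
) -> tuple[list[SubjectChoices], CleaningReport]:
    """Apply trial filtering then subject screening across a cohort."""
    report = CleaningReport()
    kept: list[SubjectChoices] = []
    for sc in cohort:
        filtered, r = filter_trials(sc, rt_min=rt_min)
        report.n_trials_total += r.n_trials_total
        report.n_trials_removed += r.n_trials_removed
        passed, reasons = screen_subject(filtered, min_trials=min_trials)
        if passed:
            kept.append(filtered)
        else:
            report.excluded_subjects.append((sc.subject_id, reasons))
    return kept, report
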