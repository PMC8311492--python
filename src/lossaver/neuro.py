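"""Cortical-thickness tables: ingestion, scanner harmonization, ROI building.

Consumes a tabular export of a Desikan-Killiany-style parcellation (mean
thickness and gray-matter volume per parcel per hemisphere, plus estimated
intracranial volume), harmonizes thickness across scanners with a
parametric empirical-Bayes location/scale adjustment that preserves
specified biological covariates, and aggregates parcels into volume-weighted
regions of interest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ROI_PARCELS",
    "HEMISPHERES",
    "REQUIRED_COLUMNS",
    "read_thickness_table",
    "write_thickness_table",
    "thickness_columns",
    "combat_harmonize",
    "build_rois",
]

# Constituent Desikan-Killiany parcels of each region of interest.  The
# posterior cingulate ROI uses the posteriorcingulate parcel only (the
# isthmus is not folded in).
ROI_PARCELS: dict[str, tuple[str, ...]] = {
    "insula": ("insula",),
    "ofc": ("medialorbitofrontal", "lateralorbitofrontal"),
    "acc": ("rostralanteriorcingulate", "caudalanteriorcingulate"),
    "pcc": ("posteriorcingulate",),
}

HEMISPHERES = ("lh", "rh")

REQUIRED_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "race_ethnicity",
    "scanner_id",
    "etiv",
    "qc_pass",
]

THICKNESS_RANGE = (0.5, 5.0)  # mm plausibility band


def thickness_columns(df: pd.DataFrame) -> list[str]:
    """Names of all per-parcel mean-thickness columns."""
    return [c for c in df.columns if c.endswith("_thickness")]


def _volume_column(thickness_col: str) -> str:
    return thickness_col[: -len("_thickness")] + "_volume"


def read_thickness_table(path, drop_qc_fail: bool = True) -> pd.DataFrame:
    """Read and validate a per-subject thickness CSV.

    Rows failing quality control (``qc_pass`` false) are dropped with a
    logged count when ``drop_qc_fail`` is set.

    Raises
    ------
    ValueError
        On missing required columns or implausible values.
    """
    df = pd.read_csv(path)
    return validate_thickness_table(df, drop_qc_fail=drop_qc_fail)


def validate_thickness_table(df: pd.DataFrame, drop_qc_fail: bool = True) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"thickness table missing required columns: {missing}")
    th_cols = thickness_columns(df)
    if not th_cols:
        raise ValueError("thickness table has no <parcel>_<hemi>_thickness columns")
    for c in th_cols:
        vol = _volume_column(c)
        if vol not in df.columns:
            raise ValueError(f"thickness column {c} has no matching {vol}")
    if df["scanner_id"].isna().any():
        raise ValueError("scanner_id must not be missing")
    if (df["etiv"] <= 0).any():
        raise ValueError("etiv must be positive")
    th = df[th_cols].to_numpy(dtype=float)
    lo, hi = THICKNESS_RANGE
    if np.any((th <= lo) | (th >= hi)):
        raise ValueError(
            f"thickness values outside the plausibility band ({lo}, {hi}) mm"
        )
    if drop_qc_fail:
        n_fail = int((~df["qc_pass"].astype(bool)).sum())
        if n_fail:
            warnings.warn(f"dropping {n_fail} subjects failing quality control", stacklevel=2)
        df = df[df["qc_pass"].astype(bool)].reset_index(drop=True)
    return df


def write_thickness_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# empirical-Bayes scanner harmonization


def _eb_iterate(s_batch, gamma_hat, delta_hat, gamma_bar, t2, a_prior, b_prior, tol=1e-6):
    """Iterative conditional posterior-mode solution for one batch."""
    n = s_batch.shape[1]
    gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
    for _ in range(200):
        gamma_new = (n * t2 * gamma_hat + delta_star * gamma_bar) / (n * t2 + delta_star)
        sum2 = ((s_batch - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * sum2 + b_prior) / (0.5 * n + a_prior - 1.0)
        change = max(
            np.abs(gamma_new - gamma_star).max(initial=0.0),
            np.abs(delta_new - delta_star).max(initial=0.0),
        )
        gamma_star, delta_star = gamma_new, delta_new
        if change < tol:
            break
    return gamma_star, delta_star


def combat_harmonize(
    table: pd.DataFrame,
    batch_col: str = "scanner_id",
    biological_covariates: list[str] | None = None,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Parametric empirical-Bayes batch harmonization of thickness columns.

    Per feature, the data are standardized on a model that includes batch
    indicators and the biological covariates, per-batch location/scale
    effects are estimated and shrunk toward batch-level priors (normal for
    location; inverse-gamma for scale, hyperparameters by method of
    moments), removed, and the covariate-associated signal restored.
    Variance attributable to the listed covariates (default: age) is
    thereby preserved.

    Raises
    ------
    ValueError
        If any batch has fewer than 3 subjects.
    """
    if biological_covariates is None:
        biological_covariates = ["age"]
    if feature_cols is None:
        feature_cols = thickness_columns(table)
    batches = pd.Categorical(table[batch_col])
    counts = pd.Series(batches).value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"batches with < 3 subjects cannot be harmonized: {small}")
    if len(counts) < 2:
        warnings.warn("single batch: harmonization is the identity", stacklevel=2)
        return table.copy()

    V = table[feature_cols].to_numpy(dtype=float).T  # features x samples
    p, n = V.shape
    B = pd.get_dummies(batches).to_numpy(dtype=float)  # n x n_batch
    X = table[biological_covariates].to_numpy(dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = np.hstack([B, X])
    n_batch = B.shape[1]
    batch_sizes = B.sum(axis=0)

    beta, *_ = np.linalg.lstsq(design, V.T, rcond=None)  # (n_batch+q) x p
    grand_mean = (batch_sizes / n) @ beta[:n_batch]
    var_pooled = ((V - (design @ beta).T) ** 2).mean(axis=1)
    if np.any(var_pooled <= 0):
        raise ValueError("zero residual variance in a feature; cannot standardize")
    stand_mean = grand_mean[:, None] + (X @ beta[n_batch:]).T  # p x n
    s_data = (V - stand_mean) / np.sqrt(var_pooled)[:, None]

    bayes = s_data.copy()
    for j in range(n_batch):
        mask = B[:, j] == 1
        sb = s_data[:, mask]
        gamma_hat = sb.mean(axis=1)
        delta_hat = sb.var(axis=1, ddof=1)
        gamma_bar, t2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        if s2 <= 0 or t2 <= 0 or p < 2:
            gamma_star, delta_star = gamma_hat, delta_hat  # no pooling possible
        else:
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            gamma_star, delta_star = _eb_iterate(
                sb, gamma_hat, delta_hat, gamma_bar, t2, a_prior, b_prior
            )
        bayes[:, mask] = (sb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = bayes * np.sqrt(var_pooled)[:, None] + stand_mean
    result = table.copy()
    result[feature_cols] = out.T
    return result


# ---------------------------------------------------------------------------
# regions of interest


def build_rois(
    table: pd.DataFrame,
    roi_parcels: dict[str, tuple[str, ...]] | None = None,
    weight: str = "volume",
) -> pd.DataFrame:
    """Volume-weighted mean thickness per ROI plus whole-brain thickness.

    Each ROI pools its constituent parcels across both hemispheres:
    sum(thickness * volume) / sum(volume).  ``whole_brain`` uses every
    thickness column in the table.

    Raises
    ------
    ValueError
        If a required parcel column is absent.
    """
    if weight != "volume":
        raise ValueError("only volume weighting is implemented")
    roi_parcels = ROI_PARCELS if roi_parcels is None else roi_parcels
    out = pd.DataFrame({"subject_id": table["subject_id"]})

    def weighted(cols: list[str]) -> pd.Series:
        th = table[cols].to_numpy(dtype=float)
        vol = table[[_volume_column(c) for c in cols]].to_numpy(dtype=float)
        return pd.Series((th * vol).sum(axis=1) / vol.sum(axis=1), index=table.index)

    for roi, parcels in roi_parcels.items():
        cols = [f"{p}_{h}_thickness" for p in parcels for h in HEMISPHERES]
        absent = [c for c in cols if c not in table.columns]
        if absent:
            raise ValueError(f"ROI {roi!r} requires missing parcel columns: {absent}")
        out[roi] = weighted(cols)
    out["whole_brain"] = weighted(thickness_columns(table))
    return out
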