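"""Hand-grip-strength phenotype derivation and normalization utilities.

The analysis phenotype is the maximum grip strength over the two hands, in
kg, measured by dynamometer.  Samples with confounding diagnoses (COPD,
brachial plexus disorder, arm/wrist/hand injury history), with body weight
missing or outside 30-200 kg, or with grip missing for both hands are
excluded, with a per-criterion audit.  Rank-based inverse normal
transformation (INT) uses the Blom offset, the convention in quantitative
trait GWAS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: exclusion flags recognised by apply_exclusions, in the order applied
EXCLUSION_FLAGS = ("copd", "brachial_plexus", "arm_injury")

WEIGHT_WINDOW = (30.0, 200.0)  # kg, closed interval


def derive_hgs(left, right) -> pd.Series:
    """Maximum grip strength over the two hands; missing only if both missing.

    Accepts scalars or aligned Series (kg).  Samples with at least one
    measured hand keep that hand's value; negative inputs are invalid.
    """
    left = pd.Series(left, dtype=float) if not isinstance(left, pd.Series) else left.astype(float)
    right = pd.Series(right, dtype=float) if not isinstance(right, pd.Series) else right.astype(float)
    if ((left.dropna() < 0).any()) or ((right.dropna() < 0).any()):
        raise ValueError("grip strength cannot be negative")
    both = pd.concat([left, right], axis=1)
    return both.max(axis=1, skipna=True)


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the phenotype exclusions and return (filtered table, audit).

    Expects columns ``hgs`` (or ``hgs_left``/``hgs_right``), ``weight``, and
    the 0/1 flags in :data:`EXCLUSION_FLAGS`.  Each sample is removed at most
    once, attributed to the first matching criterion, so that
    ``rows_in == rows_out + audit.n_removed.sum()``.

    Criteria, in order: each diagnosis flag; weight outside the closed
    [30, 200] kg window or missing; grip strength missing for both hands.
    """
    df = table.copy()
    if "hgs" not in df.columns:
        df["hgs"] = derive_hgs(df["hgs_left"], df["hgs_right"])

    removed = pd.Series(False, index=df.index)
    audit_rows = []
    for flag in EXCLUSION_FLAGS:
        if flag not in df.columns:
            audit_rows.append((flag, 0))
            continue
        hit = (df[flag].fillna(0).astype(int) == 1) & ~removed
        audit_rows.append((flag, int(hit.sum())))
        removed |= hit

    lo, hi = WEIGHT_WINDOW
    bad_weight = (df["weight"].isna() | (df["weight"] < lo) | (df["weight"] > hi)) & ~removed
    audit_rows.append(("weight_outside_30_200", int(bad_weight.sum())))
    removed |= bad_weight

    no_hgs = df["hgs"].isna() & ~removed
    audit_rows.append(("hgs_missing_both_hands", int(no_hgs.sum())))
    removed |= no_hgs

    audit = pd.DataFrame(audit_rows, columns=["criterion", "n_removed"])
    return df[~removed], audit


def inverse_normal_transform(values, offset: float = 0.375) -> pd.Series:
    """Rank-based inverse normal transform: z_i = Phi^-1((r_i - c)/(n + 1 - 2c)).

    Uses the Blom offset c = 0.375 and average ranks for ties; missing values
    stay missing and do not consume ranks.  Requires at least two distinct
    non-missing values (degenerate ranks otherwise).
    """
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    obs = s.dropna()
    if len(obs) < 2:
        raise ValueError("inverse normal transform needs >= 2 non-missing values")
    if obs.nunique() == 1:
        raise ValueError("all values identical; ranks are degenerate")
    ranks = stats.rankdata(obs.to_numpy(), method="average")
    n = len(obs)
    z = stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    out = pd.Series(np.nan, index=s.index)
    out.loc[obs.index] = z
    return out


def normalize_residualize(
    hgs: pd.Series,
    height: pd.Series,
    age: pd.Series,
    sex: pd.Series,
    pcs: pd.DataFrame,
) -> pd.Series:
    """Height-normalized, covariate-residualized, inverse-normal z-scores.

    Grip strength is divided by standing height, residualized on age, sex and
    the principal components by least squares, then rank inverse-normal
    transformed.  This is the scale on which carrier vs. non-carrier group
    differences are displayed.
    """
    if (height <= 0).any():
        raise ValueError("height must be positive")
    y = (hgs / height).to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y)), age.to_numpy(dtype=float), sex.to_numpy(dtype=float), pcs.to_numpy(dtype=float)]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns for the error message
        names = ["intercept", "age", "sex"] + list(pcs.columns)
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10]
        raise np.linalg.LinAlgError(f"singular design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return inverse_normal_transform(pd.Series(resid, index=hgs.index))
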