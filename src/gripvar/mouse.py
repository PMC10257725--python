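"""Mouse forelimb grip-strength statistics.

Each animal contributes the mean of three peak pull-force trials (grams)
normalized by femur length (mm).  Normalized grip is Box-Cox transformed to
normality with the experimental cohort as a covariate (lambda restricted to
[-2, 2]), the genotype effect is tested with a double generalized linear
model (a Gaussian mean submodel and a gamma/log dispersion submodel fitted
alternately), and for display the cohort effect is residualized out and
z-scores relative to wild types are compared across genotypes by two-sided
Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

TRIAL_COLS = ("trial1", "trial2", "trial3")


def normalize_grip(table: pd.DataFrame) -> pd.Series:
    """Mean of the 3 trials divided by femur length, per animal."""
    for c in TRIAL_COLS:
        if c not in table.columns or table[c].isna().any():
            raise ValueError(f"every animal needs 3 trials; {c} missing or incomplete")
    if (table["femur"] <= 0).any():
        raise ValueError("femur length must be positive")
    return table[list(TRIAL_COLS)].mean(axis=1) / table["femur"]


def _boxcox_apply(y: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-12:
        return np.log(y)
    return (y**lam - 1.0) / lam


def _cohort_design(cohort: pd.Series) -> np.ndarray:
    dummies = pd.get_dummies(cohort.astype(str), drop_first=True, dtype=float)
    return np.column_stack([np.ones(len(cohort)), dummies.to_numpy()])


def boxcox_profile_loglik(y: np.ndarray, X: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of the Box-Cox linear model at a given lambda."""
    z = _boxcox_apply(y, lam)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    rss = float(((z - X @ beta) ** 2).sum())
    n = len(y)
    return -n / 2.0 * np.log(rss / n) + (lam - 1.0) * float(np.log(y).sum())


def boxcox_transform(
    values: pd.Series,
    cohort: pd.Series,
    lambda_range: tuple[float, float] = (-2.0, 2.0),
) -> tuple[pd.Series, float, bool]:
    """Box-Cox transform with the cohort as a covariate of the profile likelihood.

    Finds the lambda in ``lambda_range`` maximizing the profile
    log-likelihood of ``y^(lambda) ~ cohort`` and returns
    ``(transformed, lambda, at_boundary)``; ``y^(lambda)`` is
    ``(y^lambda - 1)/lambda``, and ``log y`` at lambda = 0.  Values must be
    strictly positive.
    """
    y = values.to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("Box-Cox requires strictly positive values")
    X = _cohort_design(cohort)
    lo, hi = lambda_range
    res = optimize.minimize_scalar(
        lambda lam: -boxcox_profile_loglik(y, X, lam),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(res.x)
    at_boundary = min(lam - lo, hi - lam) < 1e-3
    return pd.Series(_boxcox_apply(y, lam), index=values.index), lam, at_boundary


@dataclass
class DglmResult:
    """Genotype-effect test from the double GLM."""

    beta: float  # mean-submodel genotype effect (per mutant allele, dose coding)
    se: float
    p: float
    mean_params: pd.Series
    dispersion_params: pd.Series
    n_iter: int
    converged: bool


def fit_dglm(
    transformed: pd.Series,
    genotype: pd.Series,
    cohort: pd.Series,
    genotype_coding: str = "dose",
    dispersion_terms: tuple[str, ...] = ("cohort",),
    max_iter: int = 100,
    tol: float = 1e-8,
) -> DglmResult:
    """Double GLM: Gaussian mean submodel + gamma/log dispersion submodel.

    The mean submodel ``y ~ genotype + cohort`` is fit by weighted least
    squares with weights 1/phi_i; the dispersion submodel regresses the
    leverage-adjusted squared residuals ``r_i^2 / (1 - h_i)`` on the
    dispersion covariates with a gamma family and log link (prior weights
    ``(1 - h_i)/2``), giving per-observation phi_i.  The two are alternated
    until the relative change of the extended quasi-likelihood falls below
    ``tol``.  Genotype is coded as mutant-allele dose WT=0, HET=1, HOM=2 by
    default (``'categorical'`` fits separate HET/HOM contrasts and reports
    the HOM one).  Non-convergence raises with the iteration trace.
    """
    import statsmodels.api as sm

    levels = [g for g in ("WT", "HET", "HOM") if g in set(genotype)]
    if len(levels) < 2:
        raise ValueError("need >= 2 genotype levels")
    y = transformed.to_numpy(dtype=float)
    n = len(y)
    dose = genotype.map({"WT": 0.0, "HET": 1.0, "HOM": 2.0}).to_numpy()
    cohort_d = pd.get_dummies(cohort.astype(str), drop_first=True, dtype=float)
    if genotype_coding == "dose":
        geno_cols = {"genotype_dose": dose}
        report_col = "genotype_dose"
    elif genotype_coding == "categorical":
        gd = pd.get_dummies(pd.Categorical(genotype, categories=levels), drop_first=True, dtype=float)
        geno_cols = {f"genotype_{c}": gd[c].to_numpy() for c in gd.columns}
        report_col = f"genotype_{levels[-1]}"
    else:
        raise ValueError("genotype_coding must be 'dose' or 'categorical'")
    Xm = pd.DataFrame({"intercept": np.ones(n), **geno_cols, **{f"cohort_{c}": cohort_d[c].to_numpy() for c in cohort_d.columns}})

    disp_cols = {"intercept": np.ones(n)}
    for term in dispersion_terms:
        if term == "cohort":
            for c in cohort_d.columns:
                disp_cols[f"cohort_{c}"] = cohort_d[c].to_numpy()
        elif term == "genotype":
            disp_cols["genotype_dose"] = dose
        else:
            raise ValueError(f"unknown dispersion term {term!r}")
    Xd = pd.DataFrame(disp_cols)

    phi = np.ones(n)
    eql_old = -np.inf
    trace = []
    converged = False
    wls_res = None
    disp_params = pd.Series({c: 0.0 for c in Xd.columns})
    for it in range(1, max_iter + 1):
        w = 1.0 / phi
        wls_res = sm.WLS(y, Xm, weights=w).fit()
        r = y - wls_res.fittedvalues
        Xw = Xm.to_numpy() * np.sqrt(w)[:, None]
        H = Xw @ np.linalg.solve(Xw.T @ Xw, Xw.T)
        h = np.clip(np.diag(H), 0.0, 0.999)
        d = r**2 / (1.0 - h)
        d = np.maximum(d, 1e-12)
        gam = sm.GLM(d, Xd, family=sm.families.Gamma(link=sm.families.links.Log()),
                     var_weights=(1.0 - h) / 2.0).fit()
        disp_params = gam.params
        phi = np.asarray(gam.fittedvalues)
        phi = np.clip(phi, 1e-10, None)
        eql = float(-0.5 * np.sum(np.log(2 * np.pi * phi) + r**2 / phi))
        trace.append(eql)
        if it > 1 and abs(eql - eql_old) <= tol * (abs(eql_old) + tol):
            converged = True
            break
        eql_old = eql
    if not converged:
        raise RuntimeError(f"double GLM did not converge in {max_iter} iterations; EQL trace: {trace}")

    ix = list(Xm.columns).index(report_col)
    return DglmResult(
        beta=float(wls_res.params.iloc[ix]), se=float(wls_res.bse.iloc[ix]),
        p=float(wls_res.pvalues.iloc[ix]),
        mean_params=wls_res.params, dispersion_params=disp_params,
        n_iter=it, converged=converged,
    )


def genotype_zscores(
    residuals: pd.Series, genotype: pd.Series, equal_var: bool = False
) -> tuple[pd.Series, pd.DataFrame]:
    """Z-scores relative to wild types plus pairwise two-sided t-tests.

    ``z = (residual - mean_WT) / SD_WT``; HET and HOM groups are each
    compared with WT by a two-sided t-test on the z-scores (Welch by
    default).
    """
    wt = residuals[genotype == "WT"]
    if len(wt) == 0:
        raise ValueError("no wild-type animals")
    sd = wt.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("wild-type SD is zero; z-scores undefined")
    z = (residuals - wt.mean()) / sd
    rows = []
    for grp in ("HET", "HOM"):
        sub = z[genotype == grp]
        if len(sub) == 0:
            continue
        t, p = stats.ttest_ind(sub, z[genotype == "WT"], equal_var=equal_var)
        rows.append({"comparison": f"{grp}_vs_WT", "n": len(sub), "mean_z": sub.mean(),
                     "t": float(t), "p": float(p)})
    return z, pd.DataFrame(rows)


def analyze_mouse(table: pd.DataFrame, genotype_coding: str = "dose") -> dict:
    """Full mouse pipeline: normalize, Box-Cox, double-GLM test, z-scores.

    Residuals for the z-score display come from the linear model of the
    transformed values on cohort alone, so the genotype signal stays in the
    residuals and only the cohort effect is removed.
    """
    norm = normalize_grip(table)
    transformed, lam, at_boundary = boxcox_transform(norm, table["cohort"])
    dglm = fit_dglm(transformed, table["genotype"], table["cohort"], genotype_coding=genotype_coding)
    X = _cohort_design(table["cohort"])
    beta, *_ = np.linalg.lstsq(X, transformed.to_numpy(), rcond=None)
    resid = pd.Series(transformed.to_numpy() - X @ beta, index=table.index)
    z, tests = genotype_zscores(resid, table["genotype"])
    return {
        "normalized": norm, "transformed": transformed, "lambda": lam,
        "lambda_at_boundary": at_boundary, "dglm": dglm,
        "zscores": z, "pairwise_tests": tests,
    }
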