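"""Phenome-wide association of a gene's rare-allele burden.

Binary traits (Phecode-style, 0/1) are screened by maximum-likelihood
logistic regression; pairs passing the screen threshold (p < 0.01) are
refitted with Firth's penalized logistic regression, which maximizes
l(beta) + 1/2 log det I(beta) (the Jeffreys prior) and yields finite
estimates even under complete separation — the regime rare-variant PheWAS
lives in.  Quantitative traits are tested by linear regression on both the
raw and the rank inverse-normal transformed scale.

The PheWAS covariate design is 20 PCs, age, sex, age^2, age x sex and
age^2 x sex — deliberately without the height terms of the grip-strength
design, since height is itself a phenome member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import fit_burden_lm, round_sig
from .phenotype import inverse_normal_transform

#: non-intercept covariate columns of the PheWAS design (no height terms)
PHEWAS_DESIGN_COLUMNS = [f"pc{i}" for i in range(1, 21)] + ["age", "sex", "age2", "age_sex", "age2_sex"]


@dataclass
class PhewasConfig:
    """QC and testing thresholds for the phenome-wide scan."""

    screen_p: float = 0.01  # logistic-screen gate before the Firth refit
    min_cases: int = 100  # binary traits need >= 100 cases
    min_obs: int = 100  # quantitative traits need >= 100 observations
    min_distinct: int = 12  # and >= 12 distinct values
    sd_trim: float = 5.0  # drop values > 5 SDs from the pre-trim mean
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("screen_p", "min_cases", "min_obs", "min_distinct", "sd_trim", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.screen_p < 1.0:
            raise ValueError(f"screen_p must be in (0, 1), got {self.screen_p}")


def build_phewas_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + 20 PCs + age/sex polynomial, with age centered."""
    a = covariates["age"] - covariates["age"].mean()
    s = covariates["sex"].astype(float)
    cols = {"intercept": pd.Series(1.0, index=covariates.index)}
    for i in range(1, 21):
        cols[f"pc{i}"] = covariates[f"pc{i}"]
    cols.update({"age": a, "sex": s, "age2": a**2, "age_sex": a * s, "age2_sex": a**2 * s})
    return pd.DataFrame(cols)


def qc_binary(traits: pd.DataFrame, min_cases: int = 100) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep binary traits with >= ``min_cases`` cases; exactly 100 is kept.

    Traits must be coded 0/1 (missing allowed); anything else is an error.
    Returns the retained columns and an audit (trait, n_cases, kept).
    """
    audit_rows = []
    keep = []
    for col in traits.columns:
        vals = traits[col].dropna().unique()
        if not set(vals) <= {0, 1}:
            raise ValueError(f"trait {col!r} is not 0/1 coded")
        n_cases = int((traits[col] == 1).sum())
        kept = n_cases >= min_cases
        audit_rows.append({"trait": col, "n_cases": n_cases, "kept": kept})
        if kept:
            keep.append(col)
    return traits[keep], pd.DataFrame(audit_rows)


def qc_quantitative(
    traits: pd.DataFrame,
    min_obs: int = 100,
    min_distinct: int = 12,
    sd_trim: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantitative-trait QC in the stated order, then a single-pass SD trim.

    Traits with fewer than ``min_obs`` observations or fewer than
    ``min_distinct`` distinct values are dropped; for the survivors,
    individuals more than ``sd_trim`` SDs from the *pre-trim* mean are set
    missing (one pass — the moments are not recomputed after trimming).
    """
    audit_rows = []
    out = {}
    for col in traits.columns:
        s = traits[col].astype(float)
        n_obs = int(s.notna().sum())
        n_distinct = int(s.nunique())
        if n_obs < min_obs or n_distinct < min_distinct:
            audit_rows.append({"trait": col, "n_obs": n_obs, "n_distinct": n_distinct,
                               "n_trimmed": 0, "kept": False})
            continue
        mu, sd = s.mean(), s.std()
        far = (s - mu).abs() > sd_trim * sd if sd > 0 else pd.Series(False, index=s.index)
        trimmed = s.mask(far)
        audit_rows.append({"trait": col, "n_obs": n_obs, "n_distinct": n_distinct,
                           "n_trimmed": int(far.sum()), "kept": True})
        out[col] = trimmed
    return pd.DataFrame(out, index=traits.index), pd.DataFrame(audit_rows)


def _logistic_ml(y: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Plain Newton-Raphson logistic ML; returns (beta, se, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        score = X.T @ (y - mu)
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = (X * (mu * (1 - mu))[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
        converged = False
    return beta, se, converged


def logistic_screen(
    burden: pd.Series, trait: pd.Series, design: pd.DataFrame
) -> tuple[float, bool]:
    """Stage-1 maximum-likelihood logistic fit; Wald p for the burden term.

    Returns ``(p, converged)``.  Non-convergence (including separation, where
    the ML estimate diverges) is reported, not fatal — the pair is forwarded
    to the Firth refit, whose penalty restores finiteness.
    """
    obs = trait.notna()
    y = trait[obs].to_numpy(dtype=float)
    X = np.column_stack([design.loc[obs].to_numpy(dtype=float), burden.loc[obs].to_numpy(dtype=float)])
    beta, se, converged = _logistic_ml(y, X)
    if not converged or not np.isfinite(se[-1]) or se[-1] > 1e3:
        return np.nan, False
    z = beta[-1] / se[-1]
    return float(2 * stats.norm.sf(abs(z))), True


def firth_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-9,
    test: str = "wald",
) -> dict:
    """Firth's penalized logistic regression.

    Maximizes the Jeffreys-prior penalized log-likelihood
    ``l(beta) + 1/2 log det I(beta)`` by Newton iterations on the modified
    score ``U*(beta) = X' (y - mu + h (1/2 - mu))`` where ``h`` are the
    hat-matrix leverages, with step-halving whenever the penalized likelihood
    would decrease.  Estimates are always finite, including under complete
    separation.  Convergence: max |U*| < ``tol`` (tight enough that the slope
    agrees with the 2x2 closed form to 1e-6 even near separation, where the
    likelihood is flat); the iteration cap raises.

    ``test='wald'`` (default) gives Wald p-values from the inverse penalized
    information; ``test='lrt'`` additionally reports a penalized
    likelihood-ratio p for the last column.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("rank-deficient design in Firth regression")

    def penalized_parts(beta):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        info = (X * W[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        ll = float(y @ np.log(mu + 1e-300) + (1 - y) @ np.log(1 - mu + 1e-300))
        return mu, W, info, ll + 0.5 * logdet

    def modified_score(beta, mu, W, info):
        # gradient of the penalized log-likelihood (hat-value adjusted score)
        sqw = np.sqrt(W)
        Xw = X * sqw[:, None]
        try:
            H = Xw @ np.linalg.solve(info, Xw.T)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("singular information matrix in Firth iteration") from err
        h = np.diag(H)
        return X.T @ (y - mu + h * (0.5 - mu))

    beta = np.zeros(p)
    mu, W, info, pll = penalized_parts(beta)
    converged = False
    for _ in range(max_iter):
        score = modified_score(beta, mu, W, info)
        if np.abs(score).max() < tol:
            converged = True
            break
        step = np.linalg.solve(info, score)
        # step-halving on the penalized likelihood (strict ascent; the Fisher
        # direction can 2-cycle around the optimum on tiny tables otherwise)
        for _half in range(40):
            cand = beta + step
            mu_c, W_c, info_c, pll_c = penalized_parts(cand)
            if pll_c > pll:
                beta, mu, W, info, pll = cand, mu_c, W_c, info_c, pll_c
                break
            step = step / 2
        else:
            break
    if not converged:
        # Fisher scoring contracts only linearly (and can cycle) when the
        # penalty curvature rivals the likelihood's; polish with an exact
        # Newton solve of U*(beta) = 0 via a finite-difference Jacobian
        def full_score(b):
            mu_b, W_b, info_b, _ = penalized_parts(b)
            return modified_score(b, mu_b, W_b, info_b)

        for _ in range(50):
            s = full_score(beta)
            if np.abs(s).max() < tol:
                converged = True
                break
            eps = 1e-6
            J = np.empty((p, p))
            for j in range(p):
                e = np.zeros(p)
                e[j] = eps
                J[:, j] = (full_score(beta + e) - full_score(beta - e)) / (2 * eps)
            try:
                beta = beta - np.linalg.solve(J, s)
            except np.linalg.LinAlgError:
                break
        mu, W, info, pll = penalized_parts(beta)
    if not converged:
        raise RuntimeError(f"Firth regression did not converge in {max_iter} iterations")
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    result = {"beta": beta, "se": se, "p": pvals, "converged": True, "loglik_penalized": pll}
    if test == "lrt":
        res0 = firth_logistic(y, X[:, :-1], max_iter=max_iter, tol=tol)
        lr = 2 * (pll - res0["loglik_penalized"])
        result["p_lrt"] = float(stats.chi2.sf(max(lr, 0.0), 1))
    return result


def quantitative_assoc(
    burden: pd.Series, trait: pd.Series, design: pd.DataFrame
) -> dict:
    """Linear burden tests on the raw and the inverse-normal-transformed trait."""
    obs = trait.notna()
    d = design.loc[obs]
    b = burden.loc[obs]
    raw = fit_burden_lm(b, trait[obs], d, unit=str(trait.name), category="quantitative_raw")
    z = inverse_normal_transform(trait[obs])
    int_res = fit_burden_lm(b, z, d, unit=str(trait.name), category="quantitative_int")
    return {"raw": raw, "int": int_res}


def phenome_threshold(n_binary: int, n_quant: int) -> float:
    """Phenome-wide Bonferroni threshold 0.05 / (n_binary + n_quant), at 2 s.f."""
    if n_binary < 0 or n_quant < 0:
        raise ValueError("trait counts must be non-negative")
    total = n_binary + n_quant
    if total < 1:
        raise ValueError("at least one phenotype is required")
    return round_sig(0.05 / total, 2)


def run_phewas(
    burden: pd.Series,
    binary_traits: pd.DataFrame,
    quant_traits: pd.DataFrame,
    covariates: pd.DataFrame,
    config: PhewasConfig | None = None,
) -> pd.DataFrame:
    """Two-step phenome-wide scan of one gene's burden.

    Binary traits: QC, logistic screen, Firth refit of every pair with screen
    p below ``config.screen_p`` (and of every pair whose screen failed to
    converge).  Quantitative traits: QC with SD trimming, then paired raw/INT
    linear tests.  The phenome-wide threshold spans all traits tested.
    """
    config = config or PhewasConfig()
    design = build_phewas_design(covariates)
    rows = []

    bin_kept, _ = qc_binary(binary_traits, config.min_cases) if len(binary_traits.columns) else (binary_traits, None)
    for col in bin_kept.columns:
        trait = bin_kept[col]
        p_screen, converged = logistic_screen(burden, trait, design)
        advance = (not converged) or (p_screen < config.screen_p)
        row = {
            "trait": col, "kind": "binary",
            "n_cases": int((trait == 1).sum()), "n_controls": int((trait == 0).sum()),
            "p_screen": p_screen, "stage": "screen_only", "beta": np.nan, "se": np.nan, "p": p_screen,
        }
        if advance:
            obs = trait.notna()
            y = trait[obs].to_numpy(dtype=float)
            X = np.column_stack(
                [design.loc[obs].to_numpy(dtype=float), burden.loc[obs].to_numpy(dtype=float)]
            )
            fr = firth_logistic(y, X)
            row.update({"stage": "firth_refit", "beta": fr["beta"][-1], "se": fr["se"][-1],
                        "p": fr["p"][-1]})
        rows.append(row)

    quant_kept, _ = (
        qc_quantitative(quant_traits, config.min_obs, config.min_distinct, config.sd_trim)
        if len(quant_traits.columns) else (quant_traits, None)
    )
    for col in quant_kept.columns:
        pair = quantitative_assoc(burden, quant_kept[col], design)
        for kind, res in (("quantitative_raw", pair["raw"]), ("quantitative_int", pair["int"])):
            rows.append(
                {
                    "trait": col, "kind": kind, "n_cases": res.n, "n_controls": 0,
                    "p_screen": np.nan, "stage": "linear",
                    "beta": res.beta, "se": res.se, "p": res.p,
                }
            )

    out = pd.DataFrame(rows)
    n_bin, n_quant = len(bin_kept.columns), len(quant_kept.columns)
    if n_bin + n_quant:
        out["phenome_threshold"] = phenome_threshold(n_bin, n_quant)
    return out
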