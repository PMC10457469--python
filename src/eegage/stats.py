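"""Clinical statistical models.

Two families of analyses accompany the age-prediction models:

1. **Log-power spectrum mixed models.** The channel-mean Welch PSD of every
   patient is converted to dB and regressed on age, log frequency, and their
   interaction with per-patient random intercepts (REML). The two-drug
   variant adds drug type and all drug interactions. Age and log frequency
   are centred at their sample means, so main effects are interpretable at a
   reference patient and frequency (the drug main effect is the power offset
   at the mean log frequency).

2. **Burst-suppression logit model.** The per-patient proportion of the
   recording in burst suppression is modelled with a quasi-binomial GLM
   (logit link): scaled age, scaled brain age, binarised ASA (1–2 vs 3), and
   the ASA interactions. Because age is in the model, the brain-age
   coefficient captures the prediction error of the age model, and exp(β) is
   the odds ratio per standard deviation of brain age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

DB_REF = 1.0  # dB reference: 1 µV²/Hz


def to_db(power: np.ndarray | float) -> np.ndarray | float:
    """10·log10(power / 1 µV²/Hz)."""
    return 10.0 * np.log10(np.asarray(power) / DB_REF)


def from_db(db: np.ndarray | float) -> np.ndarray | float:
    return DB_REF * 10.0 ** (np.asarray(db) / 10.0)


def odds_ratio(beta: float) -> tuple[float, float]:
    """(exp(β), percent change 100·(exp(β) − 1))."""
    orr = float(np.exp(beta))
    return orr, 100.0 * (orr - 1.0)


def build_long_power_table(
    psd_freqs: np.ndarray, psd: np.ndarray, meta: pd.DataFrame,
    fmin: float = 1.0, fmax: float = 30.0, decimate: int = 1,
) -> pd.DataFrame:
    """Long-format table: one row per patient × frequency bin.

    ``psd`` is (n_patients, n_freqs) channel-mean power (µV²/Hz); ``meta``
    must carry patient_id, age_yr and drug aligned row-wise. Zero-power rows
    are dropped (counted in a warning).
    """
    sel = (psd_freqs >= fmin) & (psd_freqs <= fmax)
    f = psd_freqs[sel][::decimate]
    p = psd[:, sel][:, ::decimate]
    n_pat, n_f = p.shape
    tab = pd.DataFrame({
        "patient_id": np.repeat(meta["patient_id"].to_numpy(), n_f),
        "age_yr": np.repeat(meta["age_yr"].to_numpy(), n_f),
        "drug": np.repeat(meta["drug"].to_numpy(), n_f),
        "freq_hz": np.tile(f, n_pat),
        "power": p.ravel(),
    })
    bad = tab["power"] <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} zero-power rows", stacklevel=2)
        tab = tab[~bad]
    tab["log_power_db"] = to_db(tab["power"])
    tab["log_freq"] = np.log(tab["freq_hz"])
    return tab.drop(columns="power").reset_index(drop=True)


@dataclass
class FitResult:
    """Coefficient table plus fit metadata for an LMM or GLM."""

    coef: pd.DataFrame               # term, estimate, se, stat, df, p, ci_low, ci_high
    model: str
    extra: dict

    def __getitem__(self, term: str) -> pd.Series:
        return self.coef.set_index("term").loc[term]


def _coef_table(params, bse, stats, pvals, ci, df) -> pd.DataFrame:
    out = pd.DataFrame({
        "term": params.index,
        "estimate": params.to_numpy(),
        "se": bse.to_numpy(),
        "stat": stats.to_numpy(),
        "df": df,
        "p": pvals.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
    })
    return out.reset_index(drop=True)


def fit_power_lmm(table: pd.DataFrame, with_drug_terms: bool = False) -> FitResult:
    """REML mixed model of log power (dB) with patient random intercepts.

    Fixed effects: centred age, centred log frequency, and their interaction;
    with ``with_drug_terms`` additionally drug type and all drug
    interactions. Falls back to OLS with a warning if the random-intercept
    fit is singular.
    """
    if table["patient_id"].nunique() < 2 or table["freq_hz"].nunique() < 2:
        raise ValueError("need at least 2 patients and 2 frequencies")
    d = table.copy()
    d["age_c"] = d["age_yr"] - d["age_yr"].mean()
    d["logf_c"] = d["log_freq"] - d["log_freq"].mean()
    if with_drug_terms:
        d["sevo"] = (d["drug"] == "sevoflurane").astype(float)
        fixed = "log_power_db ~ age_c * logf_c * sevo"
    else:
        fixed = "log_power_db ~ age_c * logf_c"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(fixed, d, groups=d["patient_id"]).fit(reml=True)
        if not np.isfinite(fit.bse_fe).all():
            raise np.linalg.LinAlgError("singular covariance")
        params = fit.fe_params
        bse = fit.bse_fe
        ci = fit.conf_int().loc[params.index]
        tab = _coef_table(
            params, bse, params / bse,
            pd.Series(fit.pvalues).loc[params.index],
            (ci[0], ci[1]), np.nan,
        )
        extra = {
            "random_intercept_var": float(fit.cov_re.iloc[0, 0]),
            "residual_var": float(fit.scale),
            "converged": bool(fit.converged),
            "estimator": "MixedLM-REML",
        }
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(
            f"random-intercept fit failed ({err}); falling back to OLS "
            "with fixed intercepts only", stacklevel=2,
        )
        fit = smf.ols(fixed, d).fit()
        ci = fit.conf_int()
        tab = _coef_table(
            fit.params, fit.bse, fit.tvalues, fit.pvalues,
            (ci[0], ci[1]), fit.df_resid,
        )
        extra = {"estimator": "OLS-fallback"}
    return FitResult(coef=tab, model=fixed, extra=extra)


def build_bs_table(brain_age: pd.DataFrame) -> pd.DataFrame:
    """Prepare the burst-suppression analysis table from a brain-age table.

    Requires columns patient_id, age_yr, brain_age_yr, asa, bs_proportion.
    Age and brain age are z-scored over the analysis sample; ASA is
    binarised 1–2 vs 3.
    """
    d = brain_age.copy()
    d["age_z"] = (d["age_yr"] - d["age_yr"].mean()) / d["age_yr"].std(ddof=0)
    ba_sd = d["brain_age_yr"].std(ddof=0)
    d["brain_age_z"] = (d["brain_age_yr"] - d["brain_age_yr"].mean()) / ba_sd
    d["asa3"] = (d["asa"] == 3).astype(float)
    d.attrs["brain_age_sd_yr"] = float(ba_sd)
    return d


def fit_bs_model(
    table: pd.DataFrame, weights: np.ndarray | None = None,
    estimator: str = "quasibinomial",
) -> FitResult:
    """Burst-suppression proportion model.

    Default: quasi-binomial GLM with logit link on the proportions (scale
    estimated by Pearson X², t statistics on the residual df), optionally
    weighted by recording duration. Alternative ``estimator='empirical_logit'``
    fits OLS on log((p + ε)/(1 − p + ε)).
    """
    d = table.copy()
    p = d["bs_proportion"].to_numpy(dtype=float)
    if np.all(p <= 0) or np.all(p >= 1):
        eps = 1e-4
        warnings.warn("degenerate proportions; epsilon-adjusted", stacklevel=2)
        p = np.clip(p, eps, 1 - eps)
        d["bs_proportion"] = p
    formula_rhs = "age_z * asa3 + brain_age_z * asa3"
    if estimator == "quasibinomial":
        model = smf.glm(
            f"bs_proportion ~ {formula_rhs}", d,
            family=sm.families.Binomial(),
            var_weights=weights if weights is not None else np.ones(len(d)),
        )
        fit = model.fit(scale="X2")
        df_resid = fit.df_resid
        from scipy import stats as sps

        tvals = fit.params / fit.bse
        pvals = pd.Series(
            2 * sps.t.sf(np.abs(tvals), df_resid), index=fit.params.index
        )
        ci = fit.conf_int()
        tab = _coef_table(fit.params, fit.bse, tvals, pvals, (ci[0], ci[1]), df_resid)
        extra = {"scale": float(fit.scale), "estimator": "quasibinomial-GLM"}
    elif estimator == "empirical_logit":
        n_eff = len(d)
        eps = 0.5 / n_eff
        d["elogit"] = np.log((p + eps) / (1 - p + eps))
        fit = smf.ols(f"elogit ~ {formula_rhs}", d).fit()
        ci = fit.conf_int()
        tab = _coef_table(fit.params, fit.bse, fit.tvalues, fit.pvalues,
                          (ci[0], ci[1]), fit.df_resid)
        extra = {"estimator": "empirical-logit-OLS"}
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    tab["odds_ratio"] = np.exp(tab["estimate"])
    extra["brain_age_sd_yr"] = table.attrs.get("brain_age_sd_yr")
    return FitResult(coef=tab, model=f"logit(bs) ~ {formula_rhs}", extra=extra)
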