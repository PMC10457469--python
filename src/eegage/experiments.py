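"""Reusable simulation experiments: parameter-recovery suites and cohort
builders for model benchmarking.

These functions realise the package's calibration studies: generate a cohort
with known ground truth, run the full preprocessing/feature path, fit the
statistical models, and return per-replicate estimates with confidence
intervals so that coverage of the generating coefficients can be assessed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import models as mdl
from . import stats as st
from .features import FeatureTable
from .pipeline import _synthetic_stream, featurize_cohort
from .synthetic import CohortSpec, GeneratorTruth, draw_cohort_truth


def build_feature_cohort(
    n_patients: int = 170, duration_s: float = 600.0, seed: int = 0,
    prop_propofol: float = 1.0, prop_asa12: float = 1.0,
    truth: GeneratorTruth | None = None, compute_covs: bool = True,
) -> FeatureTable:
    """Generate and featurize a synthetic cohort in one call."""
    spec = CohortSpec(
        n_patients=n_patients, duration_s=duration_s, seed=seed,
        prop_propofol=prop_propofol, prop_asa12=prop_asa12,
    )
    table, _qc = featurize_cohort(
        _synthetic_stream(spec, truth or GeneratorTruth()), compute_covs=compute_covs
    )
    return table


def _meta(table: FeatureTable) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": table.patient_id, "age_yr": table.age_yr, "drug": table.drug,
    })


def lmm_recovery(
    n_reps: int = 20, base_seed: int = 0, two_drug: bool = False,
    n_patients: int = 170, duration_s: float = 360.0,
    truth: GeneratorTruth | None = None,
) -> pd.DataFrame:
    """Replicated recovery of the log-power mixed-model coefficients.

    Each replicate draws a fresh cohort, runs the spectral pipeline, fits the
    (single- or two-drug) mixed model, and records estimate and 95% CI for
    the age slope and, in the two-drug case, the drug main effect and the
    drug × log-frequency interaction.
    """
    truth = truth or GeneratorTruth()
    rows = []
    for rep in range(n_reps):
        table = build_feature_cohort(
            n_patients=n_patients, duration_s=duration_s, seed=base_seed + rep,
            prop_propofol=0.67 if two_drug else 1.0, truth=truth, compute_covs=False,
        )
        long = st.build_long_power_table(table.psd_freqs, table.psd, _meta(table))
        fit = st.fit_power_lmm(long, with_drug_terms=two_drug)
        row = {"rep": rep, "estimator": fit.extra["estimator"]}
        for label, term in (
            ("age_slope", "age_c"),
            ("sevo_offset", "sevo"),
            ("sevo_freq_slope", "logf_c:sevo"),
        ):
            if not two_drug and term != "age_c":
                continue
            r = fit[term]
            row[f"{label}_est"] = r["estimate"]
            row[f"{label}_lo"] = r["ci_low"]
            row[f"{label}_hi"] = r["ci_high"]
        rows.append(row)
    return pd.DataFrame(rows)


def bs_logit_recovery(
    n_reps: int = 20, base_seed: int = 0, n_patients: int = 204,
    truth: GeneratorTruth | None = None,
) -> pd.DataFrame:
    """Replicated recovery of the burst-suppression logit coefficients.

    Uses the generator's latent brain age (ground truth) as the brain-age
    predictor, isolating the GLM estimator from machine-learning prediction
    error; returns estimate and SE for the brain-age main effect and the
    brain-age × ASA interaction.
    """
    truth = truth or GeneratorTruth()
    rows = []
    for rep in range(n_reps):
        spec = CohortSpec(n_patients=n_patients, seed=base_seed + rep)
        df = draw_cohort_truth(spec, truth)
        tab = df.rename(columns={"true_bs_proportion": "bs_proportion"})[
            ["patient_id", "age_yr", "brain_age_yr", "asa", "bs_proportion"]
        ]
        fit = st.fit_bs_model(st.build_bs_table(tab))
        ba, inter = fit["brain_age_z"], fit["brain_age_z:asa3"]
        rows.append({
            "rep": rep,
            "beta_brainage_est": ba["estimate"], "beta_brainage_se": ba["se"],
            "beta_interaction_est": inter["estimate"], "beta_interaction_se": inter["se"],
        })
    return pd.DataFrame(rows)


def nesting_scores(
    table: FeatureTable, cv: mdl.CVConfig,
    model_names: tuple[str, ...] = ("dummy",) + mdl.MODEL_ORDER,
) -> pd.DataFrame:
    """Monte Carlo CV scores for the nested model chain on one cohort."""
    return pd.concat(
        [mdl.crossval_scores(m, table, cv) for m in model_names], ignore_index=True
    )


def nonincreasing_fraction(scores: pd.DataFrame) -> float:
    """Fraction of (split, consecutive-model-pair) comparisons where the more
    complex model is at least as good (per-split paired MAE)."""
    wide = scores.pivot(index="split", columns="model", values="mae")
    wins = [
        (wide[b] <= wide[a]).to_numpy()
        for a, b in zip(mdl.MODEL_ORDER[:-1], mdl.MODEL_ORDER[1:])
    ]
    return float(np.mean(wins))
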