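"""Synthetic anaesthesia-EEG cohort generator.

Emulates the statistical structure that the downstream brain-age analysis
assumes in 4-channel frontal EEG recorded under propofol or sevoflurane
anaesthesia:

* an aperiodic (1/f-like) background whose broadband power declines linearly
  with age (default −0.10 dB per year),
* a frontal alpha oscillation whose peak frequency and amplitude decrease
  with age,
* a sevoflurane power offset (default +3.6 dB at the reference frequency)
  with a drug × log-frequency interaction,
* age-dependent cross-channel spatial mixing of two latent sources
  (broadband and alpha), giving covariance structure beyond the spectrum,
* a latent, Gaussian "brain-age" offset that shifts the spectral age of a
  patient away from the chronological age,
* burst-suppression episodes whose per-patient proportion follows a logistic
  model in scaled age, scaled latent brain age, and binarised ASA status,
* high-voltage biphasic artifact transients, and a per-patient broadband
  gain emulating electrode/skull variability.

Every random element derives from explicit seeds, so a cohort regenerates
bit-identically, and each patient's ground truth is kept in a separate table
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .preprocess import RawRecord

CHANNELS = ("Fp1", "Fp2", "F7", "F8")

#: mean of ln(f) over the 1–30 Hz, 0.25 Hz analysis grid; the sevoflurane
#: main effect is defined at this reference frequency so that a
#: centred-log-frequency regression recovers it directly.
REF_FREQ_HZ = 12.3212


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level sampling design.

    Defaults mirror the clinical cohort the analysis targets: ages spanning
    18–90 years, roughly two thirds propofol, three quarters ASA 1–2, and
    20-minute recordings sampled at 63 Hz.
    """

    n_patients: int = 323
    seed: int = 0
    age_min_yr: float = 18.0
    age_max_yr: float = 90.0
    prop_propofol: float = 0.67
    prop_asa12: float = 0.77
    prop_female: float = 0.65
    duration_s: float = 1200.0
    fs_hz: float = 63.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("prop_propofol", "prop_asa12", "prop_female"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.duration_s < 60.0:
            raise ValueError("duration_s must be >= 60 s")
        if self.fs_hz <= 60.0:
            raise ValueError("fs_hz must exceed 2 x 30 Hz")
        if not self.age_min_yr < self.age_max_yr:
            raise ValueError("age_min_yr must be < age_max_yr")

    @property
    def age_mean_yr(self) -> float:
        return 0.5 * (self.age_min_yr + self.age_max_yr)

    @property
    def age_sd_yr(self) -> float:
        return (self.age_max_yr - self.age_min_yr) / np.sqrt(12.0)


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth coefficients of the generative model.

    Spectral model, in dB (10·log10 of µV²/Hz) at frequency f for effective
    age a = chronological age + latent brain-age offset::

        dB(f) = base_power_db − 10·χ·log10(max(f, 0.5))
                + A(a)·exp(−(f − p(a))² / (2·w²))
                + slope_drug · a + gain_patient
                + [sevo] · (sevo_offset_db + sevo_freq_slope_db·(ln f − ln f_ref))

    Burst-suppression proportion, per patient::

        logit(p_bs) = b0 + β_age·z(age) + β_ba·z(brain age) + β_asa·asa3
                      + β_ba×asa·z(brain age)·asa3 + N(0, σ_logit)

    where z(·) scales by the cohort population moments unless explicit
    centres/scales are given.
    """

    # broadband / age
    power_slope_db_per_yr: float = -0.10
    sevo_age_slope_db_per_yr: float = -0.10
    base_power_db: float = 16.0
    spectral_exponent: float = 1.8
    patient_gain_sd_db: float = 3.5
    # drug effects
    sevo_offset_db: float = 3.6
    sevo_freq_slope_db: float = -1.00   # per unit ln(frequency)
    ref_freq_hz: float = REF_FREQ_HZ
    #: when False, sevoflurane spectra carry no age information: the age
    #: input to alpha peak/amplitude and spatial mixing is frozen at
    #: ``sevo_frozen_age_yr`` (the broadband slope is controlled separately
    #: by ``sevo_age_slope_db_per_yr``). Models the finding that age-related
    #: EEG signatures can be anaesthetic-specific.
    sevo_age_coded: bool = True
    sevo_frozen_age_yr: float = 54.0
    # alpha oscillation
    alpha_peak_hz_at18: float = 11.5
    alpha_peak_slope_hz_per_yr: float = -0.03
    alpha_amp_db_at18: float = 10.0
    alpha_amp_slope_db_per_yr: float = -0.05
    alpha_width_hz: float = 1.0
    # latent brain age
    brainage_offset_sd_yr: float = 8.0
    # spatial mixing: shared-source loadings per channel, young vs old,
    # for the broadband and alpha latent sources
    broad_loading_young: tuple[float, ...] = (0.90, 0.80, 0.55, 0.45)
    broad_loading_old: tuple[float, ...] = (0.50, 0.60, 0.85, 0.90)
    alpha_loading_young: tuple[float, ...] = (0.85, 0.85, 0.40, 0.40)
    alpha_loading_old: tuple[float, ...] = (0.45, 0.50, 0.80, 0.85)
    # burst suppression logistic model
    bs_intercept: float = -2.5
    bs_beta_age: float = 0.30
    bs_beta_brainage: float = 0.85
    bs_beta_asa: float = 0.50
    bs_beta_brainage_asa: float = -0.99
    bs_logit_noise_sd: float = 0.5
    age_center_yr: float | None = None       # None -> population mean
    age_scale_yr: float | None = None        # None -> population sd
    brainage_center_yr: float | None = None
    brainage_scale_yr: float | None = None   # None -> sqrt(age var + offset var)
    # burst-suppression episode realisation
    supp_episode_s: tuple[float, float] = (2.0, 10.0)
    supp_atten: float = 0.015
    # artifacts
    artifact_rate_per_min: float = 0.2
    artifact_ptp_uv: float = 400.0
    artifact_dur_s: tuple[float, float] = (0.2, 1.0)
    # numerical noise floor (µV²/Hz) keeping covariances full rank
    noise_floor_psd: float = 1e-3

    def bs_scales(self, spec: CohortSpec) -> tuple[float, float, float, float]:
        """(age centre, age scale, brain-age centre, brain-age scale)."""
        ac = self.age_center_yr if self.age_center_yr is not None else spec.age_mean_yr
        asc = self.age_scale_yr if self.age_scale_yr is not None else spec.age_sd_yr
        bc = self.brainage_center_yr if self.brainage_center_yr is not None else spec.age_mean_yr
        bsc = self.brainage_scale_yr
        if bsc is None:
            bsc = float(np.hypot(spec.age_sd_yr, self.brainage_offset_sd_yr))
        return ac, asc, bc, bsc

    def alpha_peak_hz(self, age_yr: float) -> float:
        p = self.alpha_peak_hz_at18 + self.alpha_peak_slope_hz_per_yr * (age_yr - 18.0)
        return float(np.clip(p, 8.3, 12.7))

    def alpha_amp_db(self, age_yr: float) -> float:
        a = self.alpha_amp_db_at18 + self.alpha_amp_slope_db_per_yr * (age_yr - 18.0)
        return float(np.clip(a, 1.0, None))

    def shape_age(self, age_yr: float, drug: str) -> float:
        """Age input to the spectral-shape terms (alpha peak/amp, mixing)."""
        if drug == "sevoflurane" and not self.sevo_age_coded:
            return self.sevo_frozen_age_yr
        return age_yr

    def spatial_mixing(self, age_yr: float, drug: str = "propofol") -> np.ndarray:
        """4×2 shared-source loadings (columns: broadband, alpha source).

        Loadings vary smoothly (linearly, clipped) from the "young" to the
        "old" profile over 18–90 years; the complement sqrt(1 − λ²) weights an
        independent per-channel source, so each channel keeps the target
        spectrum exactly while cross-channel correlations encode age.
        """
        t = float(np.clip((self.shape_age(age_yr, drug) - 18.0) / 72.0, 0.0, 1.0))
        by, bo = np.asarray(self.broad_loading_young), np.asarray(self.broad_loading_old)
        ay, ao = np.asarray(self.alpha_loading_young), np.asarray(self.alpha_loading_old)
        lam = np.stack([(1 - t) * by + t * bo, (1 - t) * ay + t * ao], axis=1)
        return np.clip(lam, 0.05, 0.95)


@dataclass(frozen=True)
class PatientTruth:
    """Ground truth for one generated patient."""

    patient_id: str
    age_yr: float
    sex: str
    drug: str
    asa: int
    latent_brainage_offset_yr: float
    gain_db: float
    true_bs_proportion: float
    seed: int

    @property
    def brain_age_yr(self) -> float:
        return self.age_yr + self.latent_brainage_offset_yr


def _validate_freq(freq_hz: np.ndarray | float, fs_hz: float = 63.0) -> np.ndarray:
    f = np.atleast_1d(np.asarray(freq_hz, dtype=float))
    if np.any(f <= 0.0) or np.any(f > fs_hz / 2.0 * (1.0 + 1e-9)):
        raise ValueError(f"frequency must lie in (0, {fs_hz / 2}] Hz")
    return f


def target_spectrum(
    age_yr: float,
    drug: str,
    freq_hz: np.ndarray | float,
    truth: GeneratorTruth,
    gain_db: float = 0.0,
    fs_hz: float = 63.0,
) -> np.ndarray:
    """Noiseless log power spectral density (dB re 1 µV²/Hz).

    ``age_yr`` is the *effective* (spectral) age: callers emulating a latent
    brain-age offset pass chronological age + offset. The aperiodic term is
    flat below 0.5 Hz.
    """
    if drug not in ("propofol", "sevoflurane"):
        raise ValueError(f"unknown drug {drug!r}")
    f = _validate_freq(freq_hz, fs_hz)
    db = truth.base_power_db - 10.0 * truth.spectral_exponent * np.log10(np.maximum(f, 0.5))
    a_shape = truth.shape_age(age_yr, drug)
    peak, width = truth.alpha_peak_hz(a_shape), truth.alpha_width_hz
    db = db + truth.alpha_amp_db(a_shape) * np.exp(-0.5 * ((f - peak) / width) ** 2)
    if drug == "sevoflurane":
        db = db + truth.sevo_age_slope_db_per_yr * age_yr
        db = db + truth.sevo_offset_db + truth.sevo_freq_slope_db * (
            np.log(f) - np.log(truth.ref_freq_hz)
        )
    else:
        db = db + truth.power_slope_db_per_yr * age_yr
    db = db + gain_db
    return db if np.ndim(freq_hz) else float(db[0])


def patient_target_spectrum(
    pt: PatientTruth, truth: GeneratorTruth, freq_hz: np.ndarray | float, fs_hz: float = 63.0
) -> np.ndarray:
    """Realised target spectrum of a generated patient (effective age + gain)."""
    return target_spectrum(pt.brain_age_yr, pt.drug, freq_hz, truth, gain_db=pt.gain_db, fs_hz=fs_hz)


def _component_spectra(
    pt: PatientTruth, truth: GeneratorTruth, freqs: np.ndarray, fs_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear PSDs (µV²/Hz) of the aperiodic and alpha components.

    The alpha component is the *excess* linear power of the dB bump, so the
    two components add exactly to the full target spectrum.
    """
    pos = freqs > 0
    f = np.where(pos, freqs, 1.0)
    full_db = target_spectrum(pt.brain_age_yr, pt.drug, f, truth, pt.gain_db, fs_hz)
    flat = replace(truth, alpha_amp_db_at18=0.0, alpha_amp_slope_db_per_yr=0.0)
    ap_db = target_spectrum(pt.brain_age_yr, pt.drug, f, flat, pt.gain_db, fs_hz)
    p_full = np.where(pos, 10.0 ** (full_db / 10.0), 0.0)
    p_ap = np.where(pos, 10.0 ** (ap_db / 10.0), 0.0)
    return p_ap, np.maximum(p_full - p_ap, 0.0)


def _shaped_noise(rng: np.random.Generator, psd: np.ndarray, n: int, fs: float, k: int) -> np.ndarray:
    """k independent real signals with one-sided target PSD ``psd`` (length n)."""
    nf = psd.shape[0]
    scale = np.sqrt(psd * fs * n / 2.0)
    z = rng.standard_normal((k, nf)) + 1j * rng.standard_normal((k, nf))
    z *= np.sqrt(0.5)
    z[:, 0] = rng.standard_normal(k)          # DC (psd there is 0 anyway)
    if n % 2 == 0:
        z[:, -1] = rng.standard_normal(k)     # Nyquist bin must be real
    return np.fft.irfft(z * scale, n=n, axis=1)


def _inject_burst_suppression(
    x: np.ndarray, fs: float, proportion: float, truth: GeneratorTruth, rng: np.random.Generator
) -> np.ndarray:
    """Attenuate suppression episodes so that `proportion` of samples are
    suppressed (< 2 µV peak-to-peak), with 50 ms cosine ramps.

    Episodes alternate with short bursts inside one contiguous
    burst-suppression region (clinically, BS occurs during periods of
    excessive anaesthetic depth), leaving the rest of the record clean.
    """
    n = x.shape[1]
    target = proportion * n
    if target < 1:
        return x
    lo, hi = truth.supp_episode_s
    lengths: list[int] = []
    acc = 0.0
    while acc < target:
        ln = min(rng.uniform(lo, hi) * fs, target - acc)
        ln = max(int(round(ln)), int(0.5 * fs))
        lengths.append(ln)
        acc += ln
    gaps = [int(rng.uniform(1.0, 4.0) * fs) for _ in lengths]
    region = sum(lengths) + sum(gaps[:-1])
    if region > n:                      # high proportions: shrink burst gaps to fit
        avail = max(n - sum(lengths), 0)
        tot_gap = max(sum(gaps[:-1]), 1)
        gaps = [int(g * avail / tot_gap) for g in gaps]
        region = sum(lengths) + sum(gaps[:-1])
    start0 = int(rng.integers(0, max(n - region, 0) + 1))
    starts, pos = [], start0
    for ln, gap in zip(lengths, gaps):
        starts.append(pos)
        pos += ln + gap
    ramp = int(0.05 * fs)
    for start, ln in zip(starts, lengths):
        ln = min(ln, n - start)
        if ln <= 0:
            break
        seg = x[:, start : start + ln]
        ptp = float(np.max(seg.max(axis=1) - seg.min(axis=1))) if seg.size else 0.0
        factor = min(truth.supp_atten, 1.8 / ptp) if ptp > 0 else truth.supp_atten
        env = np.full(ln, factor)
        r = min(ramp, ln // 2)
        if r > 0:
            taper = factor + (1 - factor) * 0.5 * (1 + np.cos(np.linspace(0, np.pi, r)))
            env[:r] = taper[::-1]
            env[-r:] = taper
        x[:, start : start + ln] = seg * env
    return x


def _inject_artifacts(
    x: np.ndarray, fs: float, duration_s: float, truth: GeneratorTruth, rng: np.random.Generator
) -> np.ndarray:
    """Add biphasic high-voltage transients at the configured rate."""
    n_art = rng.poisson(truth.artifact_rate_per_min * duration_s / 60.0)
    n = x.shape[1]
    for _ in range(n_art):
        dur = rng.uniform(*truth.artifact_dur_s)
        ln = max(int(dur * fs), 4)
        start = rng.integers(0, max(n - ln, 1))
        t = np.linspace(0, 1, ln)
        shape = np.sin(2 * np.pi * t) * np.hanning(ln)
        amp = truth.artifact_ptp_uv / (shape.max() - shape.min())
        gains = rng.uniform(0.8, 1.2, size=x.shape[0])
        x[:, start : start + ln] += np.outer(gains, amp * shape)
    return x


def _draw_patient_row(
    spec: CohortSpec, truth: GeneratorTruth, idx: int, rng: np.random.Generator, seed: int
) -> PatientTruth:
    age = float(rng.uniform(spec.age_min_yr, spec.age_max_yr))
    drug = "propofol" if rng.uniform() < spec.prop_propofol else "sevoflurane"
    asa = int(rng.integers(1, 3)) if rng.uniform() < spec.prop_asa12 else 3
    sex = "F" if rng.uniform() < spec.prop_female else "M"
    offset = float(rng.normal(0.0, truth.brainage_offset_sd_yr))
    gain = float(rng.normal(0.0, truth.patient_gain_sd_db))
    ac, asc, bc, bsc = truth.bs_scales(spec)
    asa3 = float(asa == 3)
    z_age = (age - ac) / asc
    z_ba = (age + offset - bc) / bsc
    eta = (
        truth.bs_intercept
        + truth.bs_beta_age * z_age
        + truth.bs_beta_brainage * z_ba
        + truth.bs_beta_asa * asa3
        + truth.bs_beta_brainage_asa * z_ba * asa3
        + rng.normal(0.0, truth.bs_logit_noise_sd)
    )
    return PatientTruth(
        patient_id=f"P{idx:04d}",
        age_yr=age,
        sex=sex,
        drug=drug,
        asa=asa,
        latent_brainage_offset_yr=offset,
        gain_db=gain,
        true_bs_proportion=float(expit(eta)),
        seed=seed,
    )


def draw_cohort_truth(spec: CohortSpec, truth: GeneratorTruth) -> pd.DataFrame:
    """Sample the per-patient ground-truth table (no signals)."""
    rows = []
    for i in range(spec.n_patients):
        child = np.random.SeedSequence(entropy=spec.seed, spawn_key=(i,))
        seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child)
        rows.append(_draw_patient_row(spec, truth, i, rng, seed).__dict__)
    df = pd.DataFrame(rows)
    df["brain_age_yr"] = df["age_yr"] + df["latent_brainage_offset_yr"]
    return df


def synthesize_record(
    pt: PatientTruth, spec: CohortSpec, truth: GeneratorTruth,
    with_bs: bool = True, with_artifacts: bool = True,
) -> RawRecord:
    """Realise one patient's 4-channel recording from its ground truth."""
    fs = spec.fs_hz
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence(pt.seed))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    p_ap, p_al = _component_spectra(pt, truth, freqs, fs)
    lam = truth.spatial_mixing(pt.brain_age_yr, pt.drug)

    shared = np.vstack([_shaped_noise(rng, p_ap, n, fs, 1), _shaped_noise(rng, p_al, n, fs, 1)])
    indep_ap = _shaped_noise(rng, p_ap, n, fs, 4)
    indep_al = _shaped_noise(rng, p_al, n, fs, 4)
    x = (
        lam[:, :1] * shared[0]
        + np.sqrt(1 - lam[:, :1] ** 2) * indep_ap
        + lam[:, 1:2] * shared[1]
        + np.sqrt(1 - lam[:, 1:2] ** 2) * indep_al
    )
    floor = np.full_like(freqs, truth.noise_floor_psd)
    floor[0] = 0.0
    x += _shaped_noise(rng, floor, n, fs, 4)

    if with_bs and pt.true_bs_proportion > 0:
        x = _inject_burst_suppression(x, fs, pt.true_bs_proportion, truth, rng)
    if with_artifacts:
        x = _inject_artifacts(x, fs, spec.duration_s, truth, rng)
    return RawRecord(signal=x, fs_hz=fs, channel_labels=CHANNELS, patient_id=pt.patient_id)


def generate_patient(
    spec: CohortSpec, truth: GeneratorTruth, patient_index: int = 0,
    with_bs: bool = True, with_artifacts: bool = True,
) -> tuple[RawRecord, PatientTruth]:
    """Draw one patient's ground truth and synthesize its recording."""
    child = np.random.SeedSequence(entropy=spec.seed, spawn_key=(patient_index,))
    seed = int(child.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(child)
    pt = _draw_patient_row(spec, truth, patient_index, rng, seed)
    return synthesize_record(pt, spec, truth, with_bs, with_artifacts), pt


def iter_cohort(
    spec: CohortSpec, truth: GeneratorTruth,
    with_bs: bool = True, with_artifacts: bool = True,
) -> Iterator[tuple[RawRecord, PatientTruth]]:
    """Stream (record, truth) pairs without holding the cohort in memory."""
    for i in range(spec.n_patients):
        yield generate_patient(spec, truth, i, with_bs, with_artifacts)


def truth_to_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Observable per-patient metadata (what a site would export)."""
    meta = df[["patient_id", "age_yr", "sex", "drug", "asa"]].copy()
    meta["bs_annotated"] = True
    return meta


def generate_cohort(
    spec: CohortSpec, truth: GeneratorTruth, out_dir: str | Path,
    with_bs: bool = True, with_artifacts: bool = True,
) -> tuple[list[Path], pd.DataFrame, pd.DataFrame]:
    """Write a full cohort to ``out_dir``: EDF files + metadata/truth CSVs."""
    from .io import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_df = draw_cohort_truth(spec, truth)
    paths = []
    for _, row in truth_df.iterrows():
        pt = PatientTruth(**{k: row[k] for k in PatientTruth.__dataclass_fields__})
        rec = synthesize_record(pt, spec, truth, with_bs, with_artifacts)
        p = out / f"{pt.patient_id}.edf"
        write_edf(rec, p)
        paths.append(p)
    meta = truth_to_metadata(truth_df)
    meta.to_csv(out / "metadata.csv", index=False)
    truth_df.to_csv(out / "truth.csv", index=False)
    return paths, meta, truth_df


def drug_specific_truth(base: GeneratorTruth | None = None) -> GeneratorTruth:
    """Truth variant with drug-specific age coding: under sevoflurane the
    broadband age slope is zeroed and the spectral-shape/mixing age inputs
    are frozen, so no age information transfers between drugs."""
    t = base if base is not None else GeneratorTruth()
    return replace(t, sevo_age_slope_db_per_yr=0.0, sevo_age_coded=False)


def bs_linear_predictor(
    age_yr: np.ndarray, brain_age_yr: np.ndarray, asa3: np.ndarray,
    spec: CohortSpec, truth: GeneratorTruth,
) -> np.ndarray:
    """Noise-free logit of the burst-suppression proportion (for oracles)."""
    ac, asc, bc, bsc = truth.bs_scales(spec)
    z_age = (np.asarray(age_yr) - ac) / asc
    z_ba = (np.asarray(brain_age_yr) - bc) / bsc
    a3 = np.asarray(asa3, dtype=float)
    return (
        truth.bs_intercept
        + truth.bs_beta_age * z_age
        + truth.bs_beta_brainage * z_ba
        + truth.bs_beta_asa * a3
        + truth.bs_beta_brainage_asa * z_ba * a3
    )


__all__ = [
    "CHANNELS", "REF_FREQ_HZ", "CohortSpec", "GeneratorTruth", "PatientTruth",
    "target_spectrum", "patient_target_spectrum", "generate_patient",
    "synthesize_record", "draw_cohort_truth", "iter_cohort", "generate_cohort",
    "truth_to_metadata", "drug_specific_truth", "bs_linear_predictor", "logit",
]
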