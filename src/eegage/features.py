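"""Spectral and spatial feature extraction from the stable-anaesthesia segment.

Per patient: a Welch PSD grid (0–30 Hz, 0.25 Hz resolution, averaged over the
selected epochs), five band-filtered 4×4 channel covariance matrices
(low 0.1–1.5, delta 1.5–4, theta 4–8, alpha 8–15, beta 15–30 Hz), and the
four nested feature vectors used by the age-prediction models:

* ``total_power`` — log of channel-mean power summed over 1–30 Hz (1 feature),
* ``alpha_power`` — log of channel-mean power averaged over 8–13 Hz (1),
* ``spectrum``    — log channel-mean PSD at 16 uniformly spaced frequencies
  in [1, 30] Hz (16),
* ``spatial``     — tangent-space vectorization of the five shrunk band
  covariances, 10 unique entries each (50).

Covariances are regularised with OAS shrinkage toward a scaled identity and
mapped to the tangent space at a reference matrix (the affine-invariant
geometric mean of the training covariances at model-fit time; the identity
for standalone use).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import EpochSet, StableSegment, welch_psd_array

BANDS: tuple[tuple[str, float, float], ...] = (
    ("low", 0.1, 1.5),
    ("delta", 1.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 15.0),
    ("beta", 15.0, 30.0),
)
N_SPECTRUM = 16
TOTAL_BAND = (1.0, 30.0)
ALPHA_BAND = (8.0, 13.0)   # monitoring-band definition for the scalar feature


@dataclass
class PSDGrid:
    freqs_hz: np.ndarray          # grid restricted to [0, 30] Hz
    psd: np.ndarray               # (4, n_freqs) µV²/Hz, epoch-averaged
    patient_id: str = ""

    @property
    def channel_mean(self) -> np.ndarray:
        return self.psd.mean(axis=0)


@dataclass
class BandCovarianceSet:
    cov: np.ndarray               # (5, 4, 4), epoch-averaged, OAS-shrunk
    band_names: tuple[str, ...] = tuple(b[0] for b in BANDS)
    patient_id: str = ""


@dataclass
class FeatureBundle:
    total_power: float
    alpha_power: float
    spectrum: np.ndarray          # (16,)
    spatial: np.ndarray           # (50,)
    patient_id: str = ""
    segment: tuple[int, int] | None = None

    def validate(self) -> "FeatureBundle":
        if self.spectrum.shape != (N_SPECTRUM,) or self.spatial.shape != (50,):
            raise ValueError("feature dimension contract 1/1/16/50 violated")
        vals = np.concatenate(([self.total_power, self.alpha_power], self.spectrum, self.spatial))
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite feature values")
        return self


def _segment_epochs(eset: EpochSet, seg: StableSegment | None) -> np.ndarray:
    eps = eset.epochs if seg is None else eset.epochs[seg.indices()]
    if eps.shape[0] == 0:
        raise ValueError("no epochs in segment; patient excluded")
    return eps


def welch_psd(eset: EpochSet, seg: StableSegment | None = None, fmax: float = 30.0) -> PSDGrid:
    """Epoch-averaged Welch PSD over the stable segment (grid 0–30 Hz)."""
    eps = _segment_epochs(eset, seg)
    freqs, psd = welch_psd_array(eps, eset.fs_hz)
    keep = freqs <= fmax
    return PSDGrid(freqs[keep], psd.mean(axis=0)[:, keep], eset.patient_id)


def _fir_bandpass(f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    """Zero-phase (linear-phase, delay-compensated) FIR band-pass kernel;
    transition width 25% of the band edge, floored at 0.15 Hz."""
    tw = max(0.25 * f_lo, 0.15)
    numtaps = int(np.ceil(3.3 * fs / tw)) | 1
    return signal.firwin(numtaps, [f_lo, f_hi], pass_zero=False, fs=fs, window="hamming")


def bandpass_record(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Filter channels × samples with the symmetric FIR kernel, zero phase."""
    h = _fir_bandpass(f_lo, f_hi, fs)
    return signal.fftconvolve(x, h[np.newaxis, :], mode="same", axes=1)


def oas_shrink(S: np.ndarray, n_samples: int) -> np.ndarray:
    """Oracle Approximating Shrinkage of a covariance toward scaled identity."""
    p = S.shape[0]
    mu = np.trace(S) / p
    tr_s2 = np.sum(S * S)
    tr2 = np.trace(S) ** 2
    num = (1.0 - 2.0 / p) * tr_s2 + tr2
    den = (n_samples + 1.0 - 2.0 / p) * (tr_s2 - tr2 / p)
    rho = 1.0 if den <= 0 else min(num / den, 1.0)
    return (1.0 - rho) * S + rho * mu * np.eye(p)


def band_covariances(
    eset: EpochSet, seg: StableSegment | None = None, record_signal: np.ndarray | None = None,
) -> BandCovarianceSet:
    """Per-band channel covariances, averaged over the segment's epochs.

    Band-pass filtering (zero phase) is applied to the continuous record when
    it is available — epoch slices are then free of filter edge effects —
    otherwise to each 60-s epoch. Per-epoch covariances are averaged and
    OAS-shrunk, which keeps the average strictly positive definite even for
    degenerate (rank-deficient) inputs.
    """
    idx = np.arange(eset.n_epochs) if seg is None else seg.indices()
    if idx.size == 0:
        raise ValueError("no epochs in segment; patient excluded")
    n_ch, n_t = eset.epochs.shape[1], eset.epochs.shape[2]
    covs = []
    for _, lo, hi in BANDS:
        if record_signal is not None:
            filt_rec = bandpass_record(record_signal, eset.fs_hz, lo, hi)
            starts = np.round(eset.onsets_s[idx] * eset.fs_hz).astype(int)
            filt = np.stack([filt_rec[:, s : s + n_t] for s in starts])
        else:
            eps = eset.epochs[idx]
            flat = eps.reshape(idx.size * n_ch, n_t)
            filt = bandpass_record(flat, eset.fs_hz, lo, hi).reshape(idx.size, n_ch, n_t)
        filt = filt - filt.mean(axis=2, keepdims=True)
        per_epoch = np.einsum("eit,ejt->eij", filt, filt) / n_t
        covs.append(oas_shrink(per_epoch.mean(axis=0), idx.size * n_t))
    return BandCovarianceSet(np.stack(covs), patient_id=eset.patient_id)


# ---------------------------------------------------------------------------
# SPD geometry: matrix log/exp, geometric mean, tangent vectorization
# ---------------------------------------------------------------------------

def _eig_fun(mats: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a stack of symmetric
    matrices."""
    w, v = np.linalg.eigh(mats)
    return np.einsum("...ik,...k,...jk->...ij", v, fun(w), v)


def geometric_mean_spd(mats: np.ndarray, tol: float = 1e-8, max_iter: int = 50) -> np.ndarray:
    """Affine-invariant (Karcher) mean of a stack of SPD matrices by the
    standard fixed-point iteration."""
    M = mats.mean(axis=0)
    for _ in range(max_iter):
        M_isqrt = _eig_fun(M, lambda w: 1.0 / np.sqrt(np.maximum(w, 1e-12)))
        M_sqrt = _eig_fun(M, lambda w: np.sqrt(np.maximum(w, 1e-12)))
        logs = _eig_fun(
            M_isqrt @ mats @ M_isqrt, lambda w: np.log(np.maximum(w, 1e-12))
        )
        step = logs.mean(axis=0)
        M = M_sqrt @ _eig_fun(step, np.exp) @ M_sqrt
        if np.linalg.norm(step) < tol:
            break
    return 0.5 * (M + M.T)


_TRIU = np.triu_indices(4)
_OFFDIAG = _TRIU[0] != _TRIU[1]


def _vec_symmetric(L: np.ndarray) -> np.ndarray:
    """Upper triangle with √2 weighting of off-diagonals (10 values for 4×4),
    preserving the Frobenius norm."""
    v = L[..., _TRIU[0], _TRIU[1]]
    return v * np.where(_OFFDIAG, np.sqrt(2.0), 1.0)


def unvec_symmetric(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_vec_symmetric` (utility for round-trip tests)."""
    L = np.zeros(v.shape[:-1] + (4, 4))
    vals = v / np.where(_OFFDIAG, np.sqrt(2.0), 1.0)
    L[..., _TRIU[0], _TRIU[1]] = vals
    L[..., _TRIU[1], _TRIU[0]] = vals
    return L


def tangent_vectors(covs: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Map a stack (..., 4, 4) of SPD matrices to tangent space at
    ``reference`` and vectorize: log(ref^-1/2 C ref^-1/2) → 10 values each."""
    if reference is None:
        whitened = covs
    else:
        R_isqrt = _eig_fun(reference, lambda w: 1.0 / np.sqrt(np.maximum(w, 1e-12)))
        whitened = R_isqrt @ covs @ R_isqrt
    L = _eig_fun(whitened, lambda w: np.log(np.maximum(w, 1e-12)))
    return _vec_symmetric(L)


def make_feature_bundle(
    psd: PSDGrid, covs: BandCovarianceSet,
    tangent_reference: np.ndarray | None = None,
    segment: tuple[int, int] | None = None,
) -> FeatureBundle:
    """Assemble the 1/1/16/50 feature vectors from a patient's PSD grid and
    band covariances.

    ``tangent_reference`` is a (5, 4, 4) stack of per-band reference matrices
    (the training-set geometric means at model-fit time); None means the
    identity.
    """
    f, p = psd.freqs_hz, psd.channel_mean
    df = float(np.median(np.diff(f)))
    lo, hi = TOTAL_BAND
    tot = p[(f >= lo) & (f <= hi)].sum() * df
    alo, ahi = ALPHA_BAND
    alpha = p[(f >= alo) & (f <= ahi)].mean()
    if tot <= 0 or alpha <= 0:
        raise ValueError("non-positive power in total/alpha band")
    targets = np.linspace(lo, hi, N_SPECTRUM)
    idx = np.abs(f[:, None] - targets[None, :]).argmin(axis=0)
    spec_p = p[idx]
    if np.any(spec_p <= 0):
        bad = targets[spec_p <= 0]
        raise ValueError(f"non-positive power at spectrum frequencies {bad}")
    refs = [None] * 5 if tangent_reference is None else tangent_reference
    spatial = np.concatenate(
        [tangent_vectors(covs.cov[b], refs[b]) for b in range(5)]
    )
    return FeatureBundle(
        total_power=float(np.log(tot)),
        alpha_power=float(np.log(alpha)),
        spectrum=np.log(spec_p),
        spatial=spatial,
        patient_id=psd.patient_id,
        segment=segment,
    ).validate()


# ---------------------------------------------------------------------------
# Cohort-level feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Per-patient features for a cohort, in model-ready arrays.

    ``covs`` holds the raw (shrunk, identity-reference) band covariance
    matrices so that the tangent reference can be re-fit inside each training
    fold; ``psd`` holds the channel-mean PSD for the clinical spectrum models.
    """

    patient_id: np.ndarray        # (n,) str
    age_yr: np.ndarray            # (n,)
    drug: np.ndarray              # (n,) str
    asa: np.ndarray               # (n,) int
    bs_proportion: np.ndarray     # (n,)
    total_power: np.ndarray       # (n,)
    alpha_power: np.ndarray       # (n,)
    spectrum: np.ndarray          # (n, 16)
    covs: np.ndarray              # (n, 5, 4, 4)
    psd_freqs: np.ndarray         # (n_freqs,)
    psd: np.ndarray               # (n, n_freqs) channel-mean

    def __len__(self) -> int:
        return self.patient_id.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return FeatureTable(
            self.patient_id[idx], self.age_yr[idx], self.drug[idx], self.asa[idx],
            self.bs_proportion[idx], self.total_power[idx], self.alpha_power[idx],
            self.spectrum[idx], self.covs[idx], self.psd_freqs, self.psd[idx],
        )

    def design_matrix(self) -> np.ndarray:
        """Concatenated feature blocks: total(1) | alpha(1) | spectrum(16) |
        vectorized raw covariances (50). Model code re-maps the covariance
        block through a fold-fitted tangent reference."""
        cov_vec = _vec_symmetric(self.covs).reshape(len(self), 50)
        return np.column_stack(
            [self.total_power, self.alpha_power, self.spectrum, cov_vec]
        )

    _META_COLS = ("patient_id", "age_yr", "drug", "asa", "bs_proportion")

    @staticmethod
    def _feature_cols() -> list[str]:
        return (
            ["total_power", "alpha_power"]
            + [f"spectrum_{i:02d}" for i in range(N_SPECTRUM)]
            + [f"cov_{band}_{i}{j}" for band, *_ in BANDS for i, j in zip(*_TRIU)]
        )

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        df = pd.DataFrame(self.design_matrix(), columns=self._feature_cols())
        for pos, col in enumerate(self._META_COLS):
            df.insert(pos, col, getattr(self, col))
        return df

    def psd_frame(self) -> "pd.DataFrame":
        """Channel-mean PSD as a wide table (columns f_<hz>)."""
        import pandas as pd

        df = pd.DataFrame(self.psd, columns=[f"f_{f:g}" for f in self.psd_freqs])
        df.insert(0, "patient_id", self.patient_id)
        return df

    @classmethod
    def from_frame(
        cls, df: "pd.DataFrame", psd_df: "pd.DataFrame | None" = None
    ) -> "FeatureTable":
        """Rebuild a table from :meth:`to_frame` (and optionally
        :meth:`psd_frame`) output."""
        n = len(df)
        X = df[cls._feature_cols()].to_numpy(dtype=float)
        covs = unvec_symmetric(X[:, 18:68].reshape(n, 5, 10))
        if psd_df is not None:
            psd_df = psd_df.set_index("patient_id").loc[df["patient_id"]]
            freqs = np.array([float(c[2:]) for c in psd_df.columns])
            psd = psd_df.to_numpy(dtype=float)
        else:
            freqs, psd = np.zeros(1), np.zeros((n, 1))
        return cls(
            patient_id=df["patient_id"].to_numpy(),
            age_yr=df["age_yr"].to_numpy(dtype=float),
            drug=df["drug"].to_numpy(),
            asa=df["asa"].to_numpy(dtype=int),
            bs_proportion=df["bs_proportion"].to_numpy(dtype=float),
            total_power=X[:, 0], alpha_power=X[:, 1], spectrum=X[:, 2:18],
            covs=covs, psd_freqs=freqs, psd=psd,
        )


#: column blocks of :meth:`FeatureTable.design_matrix`
BLOCK_SLICES = {
    "total": slice(0, 1),
    "alpha": slice(1, 2),
    "spectrum": slice(2, 18),
    "spatial": slice(18, 68),
}
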