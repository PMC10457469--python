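"""Epoching, artifact rejection, SEF95 stable-segment selection, and
burst-suppression quantification for 4-channel anaesthesia EEG.

The pipeline mirrors standard intraoperative practice: the recording is cut
into 60-s sliding windows shifted by 10 s; epochs with implausibly low
(suppression / disconnection) or high (artifact) peak-to-peak amplitude are
discarded; the spectral edge frequency 95 (SEF95, the frequency below which
95% of power in 0.5–30 Hz lies) is computed per epoch; and the longest run
of consecutive retained epochs whose channel-mean SEF95 stays in the
8–13 Hz band defines the stable-anaesthesia segment used for all features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d

#: Welch settings shared by SEF95 and the features module: 4-s Hann windows,
#: 50% overlap -> 0.25 Hz grid at 63 Hz sampling.
WELCH_SEG_S = 4.0
WELCH_OVERLAP = 0.5

EPOCH_S = 60.0
SHIFT_S = 10.0
SEF_BAND = (8.0, 13.0)


@dataclass
class RawRecord:
    """One patient's multichannel EEG time series (µV)."""

    signal: np.ndarray               # (4, n_samples)
    fs_hz: float
    channel_labels: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F8")
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("signal must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs_hz


def welch_psd_array(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD along the last axis with the package-wide settings."""
    nperseg = int(round(WELCH_SEG_S * fs))
    nperseg = min(nperseg, x.shape[-1])
    return signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * WELCH_OVERLAP), detrend="constant", axis=-1,
    )


@dataclass
class EpochSet:
    """Windowed view of a record with per-epoch QC."""

    epochs: np.ndarray               # (n_epochs, 4, win_samples)
    onsets_s: np.ndarray             # (n_epochs,)
    fs_hz: float
    patient_id: str = ""
    ptp: np.ndarray = field(default=None)        # (n_epochs, 4)
    retained: np.ndarray = field(default=None)   # (n_epochs,) bool
    sef95_hz: np.ndarray = field(default=None)   # (n_epochs, 4)
    sef95_mean_hz: np.ndarray = field(default=None)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass(frozen=True)
class StableSegment:
    """Longest consecutive run of retained epochs with in-band SEF95."""

    first_epoch: int
    last_epoch: int                  # inclusive
    mean_sef95_hz: float

    @property
    def n_epochs(self) -> int:
        return self.last_epoch - self.first_epoch + 1

    def indices(self) -> np.ndarray:
        return np.arange(self.first_epoch, self.last_epoch + 1)


def n_epochs_for(duration_s: float, win_s: float = EPOCH_S, shift_s: float = SHIFT_S) -> int:
    if duration_s < win_s:
        return 0
    return int(np.floor((duration_s - win_s) / shift_s)) + 1


def epoch(record: RawRecord, win_s: float = EPOCH_S, shift_s: float = SHIFT_S) -> EpochSet:
    """Cut a record into sliding windows (default 60 s, 10-s shift).

    A record shorter than one window yields an empty epoch set with a
    warning; downstream stages treat such a patient as unusable.
    """
    fs = record.fs_hz
    win, shift = int(round(win_s * fs)), int(round(shift_s * fs))
    n = n_epochs_for(record.duration_s, win_s, shift_s)
    if n == 0:
        warnings.warn(
            f"record {record.patient_id or '<unnamed>'} shorter than one "
            f"{win_s:g}-s window; no epochs", stacklevel=2,
        )
        eps = np.empty((0, record.signal.shape[0], win))
        return EpochSet(eps, np.empty(0), fs, record.patient_id)
    starts = np.arange(n) * shift
    eps = np.stack([record.signal[:, s : s + win] for s in starts])
    eps = eps.copy()  # decouple storage from the raw record
    es = EpochSet(eps, starts / fs, fs, record.patient_id)
    es.ptp = eps.max(axis=2) - eps.min(axis=2)
    return es


def reject_epochs(eset: EpochSet, low_ptp: float = 0.1, high_ptp: float = 250.0) -> EpochSet:
    """Flag epochs retained iff every channel's peak-to-peak amplitude lies
    strictly inside (low_ptp, high_ptp) µV.

    The low bound removes suppression/disconnection; the high bound removes
    high-voltage artifacts.
    """
    if eset.ptp is None:
        eset.ptp = eset.epochs.max(axis=2) - eset.epochs.min(axis=2)
    eset.retained = np.all((eset.ptp > low_ptp) & (eset.ptp < high_ptp), axis=1)
    return eset


def sef95_from_psd(
    freqs: np.ndarray, psd: np.ndarray, fmin: float = 0.5, fmax: float = 30.0
) -> np.ndarray:
    """SEF95 along the last PSD axis: smallest grid frequency at which the
    cumulative power over [fmin, fmax] reaches 95% of the total.

    Channels with zero in-range power get NaN.
    """
    sel = (freqs >= fmin) & (freqs <= fmax)
    f = freqs[sel]
    p = psd[..., sel]
    tot = p.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.cumsum(p, axis=-1) / tot
    idx = np.argmax(cum >= 0.95, axis=-1)
    out = f[idx]
    return np.where(tot[..., 0] > 0, out, np.nan)


def sef95(eset: EpochSet, fmin: float = 0.5, fmax: float = 30.0) -> EpochSet:
    """Per-epoch, per-channel SEF95 and its 4-channel mean.

    Epochs with an undefined SEF95 on any channel (zero in-range power) are
    marked not retained.
    """
    if eset.n_epochs == 0:
        eset.sef95_hz = np.empty((0, eset.epochs.shape[1]))
        eset.sef95_mean_hz = np.empty(0)
        return eset
    freqs, psd = welch_psd_array(eset.epochs, eset.fs_hz)
    eset.sef95_hz = sef95_from_psd(freqs, psd, fmin, fmax)
    eset.sef95_mean_hz = eset.sef95_hz.mean(axis=1)
    bad = ~np.isfinite(eset.sef95_mean_hz)
    if eset.retained is not None:
        eset.retained = eset.retained & ~bad
    return eset


def select_stable_segment(
    eset: EpochSet, band: tuple[float, float] = SEF_BAND
) -> StableSegment | None:
    """Longest run of consecutive retained epochs with channel-mean SEF95 in
    ``band``; ties broken by earliest onset. Returns None (patient excluded)
    when no epoch qualifies."""
    if eset.retained is None or eset.sef95_mean_hz is None:
        raise ValueError("run reject_epochs and sef95 first")
    ok = (
        eset.retained
        & np.isfinite(eset.sef95_mean_hz)
        & (eset.sef95_mean_hz >= band[0])
        & (eset.sef95_mean_hz <= band[1])
    )
    best_len, best_start, cur = 0, -1, 0
    for i, flag in enumerate(ok):
        cur = cur + 1 if flag else 0
        if cur > best_len:
            best_len, best_start = cur, i - cur + 1
    if best_len == 0:
        return None
    idx = slice(best_start, best_start + best_len)
    return StableSegment(
        first_epoch=best_start,
        last_epoch=best_start + best_len - 1,
        mean_sef95_hz=float(eset.sef95_mean_hz[idx].mean()),
    )


def suppression_mask(
    record: RawRecord, supp_thresh_uv: float = 5.0, min_supp_s: float = 0.5,
    env_win_s: float = 0.2, rel_thresh: float = 0.2, floor_uv: float = 1.0,
) -> np.ndarray:
    """Per-sample burst-suppression mask.

    Suppression is flagged where the rolling peak amplitude (window
    ``env_win_s``) stays below the detection threshold on every channel for
    at least ``min_supp_s``. The threshold adapts to the patient's signal
    level — ``rel_thresh`` × the median envelope, capped at the absolute
    ``supp_thresh_uv`` and floored at ``floor_uv`` — so that low-amplitude
    but continuously active EEG is not mistaken for suppression. This
    amplitude-envelope rule is a stated stand-in for site-specific
    annotation procedures.
    """
    fs = record.fs_hz
    w = max(int(env_win_s * fs), 1)
    env = maximum_filter1d(np.abs(record.signal), size=w, axis=1, mode="nearest")
    thresh = float(np.clip(rel_thresh * np.median(env), floor_uv, supp_thresh_uv))
    quiet = np.all(env < thresh, axis=0)
    min_run = int(min_supp_s * fs)
    mask = np.zeros(quiet.size, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], quiet.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_run:
            mask[start:stop] = True
    return mask


def flag_suppression_epochs(
    eset: EpochSet, record: RawRecord, supp_thresh_uv: float = 5.0,
    min_supp_s: float = 0.5, max_fraction: float = 0.02,
) -> EpochSet:
    """Drop epochs overlapping detected burst suppression.

    Suppressed EEG must never enter model construction, and a 60-s window can
    contain a short near-isoelectric episode without tripping the low
    peak-to-peak bound; epochs whose suppressed-sample fraction exceeds
    ``max_fraction`` are therefore marked not retained.
    """
    if eset.retained is None:
        raise ValueError("run reject_epochs first")
    if eset.n_epochs == 0:
        return eset
    mask = suppression_mask(record, supp_thresh_uv, min_supp_s)
    win = eset.epochs.shape[2]
    starts = np.round(eset.onsets_s * eset.fs_hz).astype(int)
    frac = np.array([mask[s : s + win].mean() for s in starts])
    eset.retained = eset.retained & (frac <= max_fraction)
    return eset


def burst_suppression_ratio(
    record: RawRecord, supp_thresh_uv: float = 5.0, min_supp_s: float = 0.5,
    env_win_s: float = 0.2,
) -> float:
    """Fraction of the recording in burst suppression.

    Fraction of samples flagged by :func:`suppression_mask`.
    """
    mask = suppression_mask(record, supp_thresh_uv, min_supp_s, env_win_s)
    return float(mask.mean())


def qc_summary(eset: EpochSet, seg: StableSegment | None, bs_ratio: float) -> dict:
    """Machine-readable per-patient QC record."""
    return {
        "patient_id": eset.patient_id,
        "n_epochs": int(eset.n_epochs),
        "n_retained": int(eset.retained.sum()) if eset.retained is not None else 0,
        "stable_first": seg.first_epoch if seg else None,
        "stable_last": seg.last_epoch if seg else None,
        "stable_n": seg.n_epochs if seg else 0,
        "stable_mean_sef95_hz": seg.mean_sef95_hz if seg else None,
        "bs_ratio": bs_ratio,
        "excluded_reason": None if seg else "no stable SEF95 segment",
    }
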