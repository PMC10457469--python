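"""EDF input/output, dataset-subset assignment, and config serialization.

EDF (European Data Format) is the raw-signal interchange format: 4 signals
labelled Fp1, Fp2, F7, F8 in µV at 63 Hz. Writing uses a minimal EDF encoder
(16-bit samples, 1-s data records); reading goes through MNE and reorders
channels to the canonical montage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawRecord

CANONICAL_CHANNELS = ("Fp1", "Fp2", "F7", "F8")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(record: RawRecord, path: str | Path) -> Path:
    """Write a record as EDF: 16-bit samples, 1-s data records, physical
    dimension µV. The trailing partial second, if any, is dropped."""
    path = Path(path)
    fs = record.fs_hz
    spr = int(round(fs))                       # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = record.signal
    n_ch = x.shape[0]
    n_rec = x.shape[1] // spr
    x = x[:, : n_rec * spr]

    phys_max = np.maximum(np.abs(x).max(axis=1), 1e-3) * 1.0001
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad(record.patient_id or "X X X X", 80),
        _pad("Startdate 01-JAN-2020", 80),
        _pad("01.01.20", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(lab, 16) for lab in record.channel_labels],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{v:.6g}"[:8], 8) for v in phys_min],
        [_pad(f"{v:.6g}"[:8], 8) for v in phys_max],
        [_pad(str(dig_min), 8)] * n_ch,
        [_pad(str(dig_max), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        # data records: per record, all samples of signal 1, then signal 2, ...
        interleaved = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(interleaved.tobytes())
    return path


def read_edf(path: str | Path) -> RawRecord:
    """Read an EDF file into a RawRecord (µV, canonical channel order).

    Raises a ValueError listing the labels found when a canonical frontal
    channel is missing.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = {ch.lower(): ch for ch in raw.ch_names}
    missing = [ch for ch in CANONICAL_CHANNELS if ch.lower() not in labels]
    if missing:
        raise ValueError(
            f"missing channels {missing}; found {raw.ch_names} in {path}"
        )
    picks = [labels[ch.lower()] for ch in CANONICAL_CHANNELS]
    data = raw.get_data(picks=picks) * 1e6  # Volts -> µV
    return RawRecord(
        signal=data, fs_hz=float(raw.info["sfreq"]),
        channel_labels=CANONICAL_CHANNELS, patient_id=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# Dataset subsets
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    """Named analysis subsets (boolean masks over the metadata rows).

    DS1: propofol, ASA 1–2 (model building). DS2: sevoflurane, ASA 1–2.
    DS3: DS1 with burst-suppression annotation. DS4: ASA 3 with annotation.
    DS5 = DS3 ⊎ DS4 (disjoint).
    """

    ds1: np.ndarray
    ds2: np.ndarray
    ds3: np.ndarray
    ds4: np.ndarray
    ds5: np.ndarray
    excluded: pd.DataFrame

    def counts(self) -> dict[str, int]:
        return {k: int(getattr(self, k).sum()) for k in ("ds1", "ds2", "ds3", "ds4", "ds5")}


def assign_subsets(meta: pd.DataFrame) -> DatasetSplit:
    """Apply the subset rules to a metadata table.

    Requires columns drug, asa, bs_annotated. Rows with unknown drug or ASA
    are excluded (with a reason) from every subset.
    """
    drug = meta["drug"].astype(str)
    asa = pd.to_numeric(meta["asa"], errors="coerce")
    annotated = meta.get("bs_annotated", pd.Series(True, index=meta.index)).astype(bool)
    valid = drug.isin(["propofol", "sevoflurane"]) & asa.isin([1, 2, 3])
    excluded = meta.loc[~valid].copy()
    excluded["reason"] = np.where(
        ~drug.loc[~valid].isin(["propofol", "sevoflurane"]),
        "unknown drug", "unknown ASA",
    )
    ds1 = (valid & (drug == "propofol") & (asa <= 2)).to_numpy()
    ds2 = (valid & (drug == "sevoflurane") & (asa <= 2)).to_numpy()
    ds3 = ds1 & annotated.to_numpy()
    ds4 = (valid & (asa == 3)).to_numpy() & annotated.to_numpy()
    return DatasetSplit(ds1, ds2, ds3, ds4, ds3 | ds4, excluded)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    low_ptp_uv: float = 0.1
    high_ptp_uv: float = 250.0
    sef_band: tuple[float, float] = (8.0, 13.0)
    supp_thresh_uv: float = 5.0
    min_supp_s: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable end-to-end run configuration."""

    input_dir: str = "synthetic"     # "synthetic" or a directory of EDF files
    out_dir: str = "eegage_out"
    seed: int = 0
    cohort: dict = dataclasses.field(default_factory=dict)      # CohortSpec overrides
    truth: dict = dataclasses.field(default_factory=dict)       # GeneratorTruth overrides
    cv: dict = dataclasses.field(default_factory=dict)          # CVConfig overrides
    thresholds: Thresholds = Thresholds()
    model_name: str = "spatial_patterns"
    write_edf_files: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        th = d.pop("thresholds", {})
        th["sef_band"] = tuple(th.get("sef_band", (8.0, 13.0)))
        for k in ("cohort", "truth", "cv"):
            d[k] = {kk: tuple(v) if isinstance(v, list) else v for kk, v in d.get(k, {}).items()}
        return cls(thresholds=Thresholds(**th), **d)
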