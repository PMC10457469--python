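"""End-to-end experiment runner: generate/ingest → preprocess → features →
age-prediction model comparison → brain-age table → burst-suppression model →
drug generalization → spectrum mixed models → report files.

Every stage writes plain-text outputs (CSV/JSON) into the run directory, and
a persisted config + seed reproduces the run.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import features as feat
from . import models as mdl
from . import preprocess as pre
from . import stats as st
from . import synthetic as syn
from .io import RunConfig, Thresholds, assign_subsets, read_edf

log = logging.getLogger("eegage")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def preprocess_record(
    record: pre.RawRecord, th: Thresholds = Thresholds()
) -> tuple[pre.EpochSet, pre.StableSegment | None, float, dict]:
    """Epoch, QC, SEF95, stable-segment selection and BS quantification."""
    es = pre.epoch(record)
    es = pre.reject_epochs(es, th.low_ptp_uv, th.high_ptp_uv)
    es = pre.flag_suppression_epochs(es, record, th.supp_thresh_uv, th.min_supp_s)
    es = pre.sef95(es)
    seg = pre.select_stable_segment(es, th.sef_band) if es.n_epochs else None
    bs = pre.burst_suppression_ratio(record, th.supp_thresh_uv, th.min_supp_s)
    return es, seg, bs, pre.qc_summary(es, seg, bs)


def featurize_cohort(
    records: Iterable[tuple[pre.RawRecord, dict]],
    th: Thresholds = Thresholds(),
    compute_covs: bool = True,
) -> tuple[feat.FeatureTable, pd.DataFrame]:
    """Run preprocessing + feature extraction over (record, metadata) pairs.

    Metadata dicts need patient_id, age_yr, drug, asa. Patients without a
    stable segment are excluded and appear only in the QC table. Spectrum-
    only analyses can skip the band covariances (``compute_covs=False``;
    identity placeholders are stored).
    """
    rows, qc_rows = [], []
    freqs = None
    for record, meta in records:
        es, seg, bs, qc = preprocess_record(record, th)
        qc_rows.append(qc)
        if seg is None:
            log.info("excluding %s: %s", meta.get("patient_id"), qc["excluded_reason"])
            continue
        psd = feat.welch_psd(es, seg)
        if compute_covs:
            covs = feat.band_covariances(es, seg, record_signal=record.signal)
        else:
            covs = feat.BandCovarianceSet(
                np.broadcast_to(np.eye(4), (5, 4, 4)).copy(), patient_id=es.patient_id
            )
        bundle = feat.make_feature_bundle(psd, covs, segment=(seg.first_epoch, seg.last_epoch))
        freqs = psd.freqs_hz
        rows.append({
            "meta": meta, "bs": bs, "bundle": bundle,
            "covs": covs.cov, "psd": psd.channel_mean,
        })
    if not rows:
        raise ValueError("no patient passed preprocessing")
    table = feat.FeatureTable(
        patient_id=np.array([r["meta"]["patient_id"] for r in rows]),
        age_yr=np.array([r["meta"]["age_yr"] for r in rows], dtype=float),
        drug=np.array([r["meta"]["drug"] for r in rows]),
        asa=np.array([r["meta"]["asa"] for r in rows], dtype=int),
        bs_proportion=np.array([r["bs"] for r in rows], dtype=float),
        total_power=np.array([r["bundle"].total_power for r in rows]),
        alpha_power=np.array([r["bundle"].alpha_power for r in rows]),
        spectrum=np.stack([r["bundle"].spectrum for r in rows]),
        covs=np.stack([r["covs"] for r in rows]),
        psd_freqs=freqs,
        psd=np.stack([r["psd"] for r in rows]),
    )
    return table, pd.DataFrame(qc_rows)


def _synthetic_stream(
    spec: syn.CohortSpec, truth: syn.GeneratorTruth
) -> Iterator[tuple[pre.RawRecord, dict]]:
    truth_df = syn.draw_cohort_truth(spec, truth)
    for _, row in truth_df.iterrows():
        pt = syn.PatientTruth(**{k: row[k] for k in syn.PatientTruth.__dataclass_fields__})
        rec = syn.synthesize_record(pt, spec, truth)
        yield rec, {
            "patient_id": pt.patient_id, "age_yr": pt.age_yr,
            "drug": pt.drug, "asa": pt.asa, "bs_annotated": True,
        }


def _edf_stream(input_dir: Path) -> Iterator[tuple[pre.RawRecord, dict]]:
    meta = pd.read_csv(input_dir / "metadata.csv").set_index("patient_id")
    for p in sorted(input_dir.glob("*.edf")):
        rec = read_edf(p)
        row = meta.loc[rec.patient_id]
        yield rec, {
            "patient_id": rec.patient_id, "age_yr": float(row["age_yr"]),
            "drug": str(row["drug"]), "asa": int(row["asa"]),
            "bs_annotated": bool(row.get("bs_annotated", True)),
        }


def run_experiment(config: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict (also written as
    JSON, alongside per-stage CSVs, into ``config.out_dir``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    t0 = time.time()
    summary: dict = {"stages": {}}

    cv = mdl.CVConfig(base_seed=config.seed, **config.cv)

    stage = "ingest+features"
    try:
        if config.input_dir == "synthetic":
            spec = syn.CohortSpec(seed=config.seed, **config.cohort)
            truth = syn.GeneratorTruth(**config.truth)
            if config.write_edf_files:
                syn.generate_cohort(spec, truth, out / "edf")
                stream = _edf_stream(out / "edf")
            else:
                stream = _synthetic_stream(spec, truth)
            syn.draw_cohort_truth(spec, truth).to_csv(out / "truth.csv", index=False)
        else:
            stream = _edf_stream(Path(config.input_dir))
        table, qc = featurize_cohort(stream, config.thresholds)
        qc.to_csv(out / "qc.csv", index=False)
        table.to_frame().to_csv(out / "features.csv", index=False)
        meta = pd.DataFrame({
            "patient_id": table.patient_id, "age_yr": table.age_yr,
            "drug": table.drug, "asa": table.asa, "bs_annotated": True,
        })
        split = assign_subsets(meta)
        summary["stages"][stage] = {"n_featurized": len(table), **split.counts()}
    except Exception as err:  # noqa: BLE001 - stage-named abort per contract
        raise StageError(stage, err) from err

    stage = "model_comparison"
    try:
        ds1 = table.subset(split.ds1)
        scores = pd.concat(
            [mdl.crossval_scores(m, ds1, cv) for m in ("dummy",) + mdl.MODEL_ORDER],
            ignore_index=True,
        )
        scores.to_csv(out / "scores.csv", index=False)
        chain = ("dummy",) + mdl.MODEL_ORDER
        comparisons = [
            mdl.compare(scores[scores["model"] == a], scores[scores["model"] == b]).summary()
            for a, b in zip(chain[:-1], chain[1:])
        ]
        (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))
        med = scores.groupby("model")["mae"].median()
        summary["stages"][stage] = {"median_mae": med.to_dict()}
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "brain_age"
    try:
        ds4 = table.subset(split.ds4)
        ba = mdl.predict_brain_age(ds1, ds4 if len(ds4) else None, config.model_name, cv)
        ba.to_csv(out / "brain_age.csv", index=False)
        summary["stages"][stage] = {"n": len(ba)}
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "bs_model"
    try:
        annotated = set(table.patient_id[split.ds5])
        ds5 = ba[ba["patient_id"].isin(annotated)].reset_index(drop=True)
        bs_fit = st.fit_bs_model(st.build_bs_table(ds5))
        bs_fit.coef.to_csv(out / "bs_model.csv", index=False)
        summary["stages"][stage] = {
            "beta_brain_age": float(bs_fit["brain_age_z"]["estimate"]),
            "beta_brain_age_asa": float(bs_fit["brain_age_z:asa3"]["estimate"]),
        }
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "power_lmm"
    try:
        tab1 = st.build_long_power_table(
            ds1.psd_freqs, ds1.psd,
            pd.DataFrame({"patient_id": ds1.patient_id, "age_yr": ds1.age_yr, "drug": ds1.drug}),
        )
        lmm1 = st.fit_power_lmm(tab1)
        lmm1.coef.to_csv(out / "lmm_single_drug.csv", index=False)
        ds12 = table.subset(split.ds1 | split.ds2)
        tab2 = st.build_long_power_table(
            ds12.psd_freqs, ds12.psd,
            pd.DataFrame({"patient_id": ds12.patient_id, "age_yr": ds12.age_yr, "drug": ds12.drug}),
        )
        lmm2 = st.fit_power_lmm(tab2, with_drug_terms=True)
        lmm2.coef.to_csv(out / "lmm_two_drug.csv", index=False)
        summary["stages"][stage] = {
            "age_slope_db_per_yr": float(lmm1["age_c"]["estimate"]),
            "sevo_offset_db": float(lmm2["sevo"]["estimate"]),
        }
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "drug_generalization"
    try:
        gen = mdl.drug_generalization(ds12, cv, config.model_name)
        gen.to_csv(out / "drug_generalization.csv", index=False)
        summary["stages"][stage] = (
            gen.groupby("cell")["mae"].median().to_dict()
        )
    except Exception as err:
        raise StageError(stage, err) from err

    summary["elapsed_s"] = round(time.time() - t0, 1)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
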