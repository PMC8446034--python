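"""End-to-end screening pipeline on synthetic data.

Stage order mirrors the clinical workflow: landmarks -> ROI -> quality
assessment -> BMD prediction -> T-score / risk -> dual-threshold triage.
Patients failing QA are reported with their reasons, never silently
dropped; per-patient errors (e.g. missing files) become error records and
the run continues.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .morphometry import read_landmark_file, write_landmark_file
from .phantom import (
    CohortRecord,
    Deformity,
    PhantomSpec,
    generate_cohort,
    generate_phantom_roi,
    generate_vertebra_landmarks,
    read_cohort_csv,
    read_roi_image,
    write_cohort_csv,
    write_roi_image,
)
from .qa import QAThresholds, SyntheticDetector, hip_qa, spine_qa
from .regression import BMDEnsemble, ROIImage, predict_bmd
from .triage import (
    ReferenceTable,
    ToyLogisticRiskModel,
    classify_risk,
    convert_device,
    DeviceCalibration,
    lowest_t,
    t_score,
    triage,
)

__all__ = ["simulate_to_dir", "run_screen", "ScreenResult", "load_training_dataset"]

#: phantom rendering geometry: 64 px at 1.2 mm spacing = 76.8 mm extent
PHANTOM_SIZE_PX = 64
PHANTOM_SPACING_MM = 1.2


def _roi_site(roi_id: str) -> str:
    return roi_id if roi_id.startswith("hip") else "vertebra"


def simulate_to_dir(
    out_dir,
    n: int,
    site: str = "hip",
    prevalence: float | None = None,
    seed: int = 0,
    noise_sd: float = 100.0,
    implant_rate: float = 0.03,
    vcf_rate: float = 0.03,
    fracture_rate: float = 0.03,
    deformity_rate: float = 0.05,
) -> pd.DataFrame:
    """Write a complete synthetic study to ``out_dir``.

    Produces ``cohort.csv``, 16-bit PNG ROIs (``<patient>_<roi>.png``),
    per-patient landmark files for spine scans, a ground-truth
    ``labels.csv`` (fracture/implant/VCF flags per ROI, consumed by the
    synthetic detector), and a manifest.  Deformed vertebrae are rendered
    through the wedge landmark family at severity 0.4.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(n, prevalence=prevalence, site=site, rng_seed=seed)
    write_cohort_csv(records, out / "cohort.csv")
    rng = np.random.default_rng(seed + 1)

    label_rows = []
    for rec in records:
        landmark_sets = []
        for i, (roi, bmd) in enumerate(rec.true_bmd.items()):
            flags = {
                "fracture": site == "hip" and rng.random() < fracture_rate,
                "implant": rng.random() < implant_rate,
                "vcf": site == "spine" and rng.random() < vcf_rate,
            }
            deformed = site == "spine" and rng.random() < deformity_rate
            spec = PhantomSpec(
                true_bmd=bmd,
                deformity=Deformity.WEDGE if deformed else Deformity.NONE,
                severity=0.4 if deformed else 0.0,
                noise_sd=noise_sd,
                rng_seed=int(rng.integers(2**31)),
            )
            img = generate_phantom_roi(
                spec,
                size_px=PHANTOM_SIZE_PX,
                site=_roi_site(roi),
                vertebra_level=roi if site == "spine" else None,
                roi_id=roi,
                pixel_spacing=PHANTOM_SPACING_MM,
            )
            write_roi_image(img, out / f"{rec.patient_id}_{roi}.png")
            if site == "spine":
                # landmarks live in the vertebra's own ROI frame, centred in
                # the phantom image (64 px * 1.2 mm = 76.8 mm extent)
                landmark_sets.append(
                    generate_vertebra_landmarks(
                        spec,
                        vertebra_level=roi,
                        origin=(20.0, 38.4),
                        pixel_spacing=PHANTOM_SPACING_MM,
                    )
                )
            label_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "roi_id": roi,
                    **{k: int(v) for k, v in flags.items()},
                    "deformed": int(deformed),
                }
            )
        if site == "spine":
            with open(out / f"{rec.patient_id}_landmarks.txt", "w") as fh:
                write_landmark_file(landmark_sets, fh)

    labels = pd.DataFrame(label_rows)
    labels.to_csv(out / "labels.csv", index=False)
    _write_manifest(
        out,
        {
            "stage": "simulate",
            "n": n,
            "site": site,
            "prevalence": prevalence,
            "seed": seed,
        },
    )
    return labels


def load_training_dataset(data_dir) -> list[tuple[ROIImage, float]]:
    """(ROI image, measured BMD) pairs from a simulation directory, limited
    to clean ROIs (no fracture/implant/VCF/deformity flag)."""
    data = Path(data_dir)
    cohort = pd.read_csv(data / "cohort.csv")
    labels = pd.read_csv(data / "labels.csv")
    flagged = labels[
        labels[["fracture", "implant", "vcf", "deformed"]].sum(axis=1) > 0
    ]
    bad = set(zip(flagged.patient_id, flagged.roi_id))
    dataset = []
    for row in cohort.itertuples():
        if (row.patient_id, row.roi_id) in bad:
            continue
        roi = read_roi_image(
            data / f"{row.patient_id}_{row.roi_id}.png",
            pixel_spacing=PHANTOM_SPACING_MM,
            site=_roi_site(row.roi_id),
            vertebra_level=row.roi_id if row.site == "spine" else None,
            roi_id=f"{row.patient_id}_{row.roi_id}",
        )
        dataset.append((roi, float(row.measured_bmd)))
    return dataset


@dataclass
class ScreenResult:
    report: pd.DataFrame
    qa: pd.DataFrame
    errors: list[dict]


def _full_frame_polygon(shape) -> list[tuple[float, float]]:
    h, w = shape
    return [(0.0, 0.0), (w - 1.0, 0.0), (w - 1.0, h - 1.0), (0.0, h - 1.0)]


def run_screen(config: PipelineConfig, ensemble: BMDEnsemble | None = None) -> ScreenResult:
    """Run the full screen on a simulated study directory.

    For each patient: QA with reasons, per-ROI predicted BMD, the lowest
    T-score over assessable ROIs, osteoporosis and fracture-risk flags,
    and the triage category.  Returns the per-patient report, the per-ROI
    QA table, and the error ledger.
    """
    data = Path(config.paths.data_dir)
    if ensemble is None:
        if config.paths.model_file is None:
            raise ValueError("run_screen needs a trained ensemble or model_file")
        ensemble = BMDEnsemble.load(config.paths.model_file)
    records = read_cohort_csv(data / "cohort.csv")
    labels = pd.read_csv(data / "labels.csv")
    label_map = {
        (r.patient_id, r.roi_id): {
            ch for ch in ("fracture", "implant", "vcf") if getattr(r, ch)
        }
        for r in labels.itertuples()
    }
    thresholds = QAThresholds(
        fracture=config.qa.fracture_threshold,
        implant=config.qa.implant_threshold,
        vcf=config.qa.vcf_threshold,
        neighbor_delta=config.qa.neighbor_delta,
    )
    reference = ReferenceTable(
        {k: (v.mean, v.sd) for k, v in config.reference.items()}
    )
    calib = {
        k: DeviceCalibration(v.slope, v.intercept) for k, v in config.calibration.items()
    }
    risk_model = ToyLogisticRiskModel() if config.risk_model == "toy_logistic" else None

    report_rows, qa_rows, errors = [], [], []
    for rec in records:
        try:
            row = _screen_patient(
                rec, data, label_map, thresholds, reference, calib,
                risk_model, ensemble, config, qa_rows,
            )
            report_rows.append(row)
        except Exception as exc:
            errors.append({"patient_id": rec.patient_id, "error": str(exc)})
    report = pd.DataFrame(report_rows)
    qa_df = pd.DataFrame(qa_rows)
    out_dir = Path(config.paths.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_csv(out_dir / "report.csv", index=False)
    qa_df.to_csv(out_dir / "qa_report.csv", index=False)
    with open(out_dir / "errors.json", "w") as fh:
        json.dump(errors, fh, indent=2)
    _write_manifest(out_dir, {"stage": "screen", "config": config.model_dump()})
    return ScreenResult(report=report, qa=qa_df, errors=errors)


def _screen_patient(
    rec: CohortRecord,
    data: Path,
    label_map,
    thresholds: QAThresholds,
    reference: ReferenceTable,
    calib,
    risk_model,
    ensemble: BMDEnsemble,
    config: PipelineConfig,
    qa_rows: list,
) -> dict:
    site = rec.site
    rois = list(rec.true_bmd)
    images = {}
    for roi in rois:
        path = data / f"{rec.patient_id}_{roi}.png"
        if not path.exists():
            raise FileNotFoundError(f"missing ROI image {path.name}")
        images[roi] = read_roi_image(
            path,
            pixel_spacing=PHANTOM_SPACING_MM,
            site=_roi_site(roi),
            vertebra_level=roi if site == "spine" else None,
            roi_id=roi,
        )

    predictions = {roi: predict_bmd(img, ensemble) for roi, img in images.items()}
    pred_bmd = {roi: p.predicted_bmd for roi, p in predictions.items()}
    if site in calib:
        pred_bmd = {r: convert_device(v, calib[site]) for r, v in pred_bmd.items()}
    pred_t = {
        roi: t_score(v, *reference.get(site, roi if site == "spine" else None))
        for roi, v in pred_bmd.items()
    }

    if site == "hip":
        results = []
        for roi in rois:
            det = SyntheticDetector(label_map.get((rec.patient_id, roi), set()))
            grid = images[roi].grid
            results.append(
                hip_qa(grid, _full_frame_polygon(grid.shape), det, thresholds, roi_id=roi)
            )
        assessable = [r.roi_id for r in results if r.admissible]
    else:
        lm_path = data / f"{rec.patient_id}_landmarks.txt"
        if not lm_path.exists():
            raise FileNotFoundError(f"missing landmark file {lm_path.name}")
        with open(lm_path) as fh:
            landmark_sets = read_landmark_file(fh)
        vertebra_set = []
        for lm in landmark_sets:
            det = SyntheticDetector(
                label_map.get((rec.patient_id, lm.vertebra_level), set())
            )
            grid = images[lm.vertebra_level].grid
            maps = {ch: det.detect(grid, ch) for ch in ("implant", "vcf")}
            vertebra_set.append((lm, maps))
        metric = pred_t if config.qa.neighbor_metric == "t_score" else pred_bmd
        results = spine_qa(vertebra_set, metric, thresholds)
        assessable = [r.roi_id for r in results if r.admissible]

    for r in results:
        qa_rows.append(
            {
                "patient_id": rec.patient_id,
                "roi_id": r.roi_id,
                "admissible": r.admissible,
                "reasons": ";".join(sorted(r.reasons)),
            }
        )

    row = {
        "patient_id": rec.patient_id,
        "site": site,
        "n_rois": len(rois),
        "n_assessable": len(assessable),
        "qa_pass": bool(assessable) if site == "hip" else len(assessable) >= 2,
        "qa_reasons": ";".join(
            sorted({reason for r in results for reason in r.reasons})
        ),
    }
    if not row["qa_pass"]:
        row.update(
            predicted_bmd=np.nan, lowest_t=np.nan, osteoporotic=pd.NA,
            major_risk_pct=np.nan, hip_risk_pct=np.nan, triage=pd.NA,
        )
        return row

    if site == "hip":
        # patient-level hip BMD: mean of available (admissible) sides
        patient_bmd = float(np.mean([pred_bmd[r] for r in assessable]))
        patient_t = t_score(patient_bmd, *reference.get("hip"))
    else:
        patient_t = lowest_t(pred_t, assessable)
        patient_bmd = min(pred_bmd[r] for r in assessable)

    if risk_model is not None:
        major, hip_risk = risk_model.predict(
            rec.age, rec.sex, rec.height_cm, rec.weight_kg, patient_bmd
        )
    else:
        major = hip_risk = None
    assessment = classify_risk(rec.patient_id, patient_t, major, hip_risk)
    value = patient_t if config.triage.scale == "t_score" else patient_bmd
    decision = triage(value, config.triage.t1, config.triage.t2, rec.patient_id)
    row.update(
        predicted_bmd=patient_bmd,
        lowest_t=patient_t,
        osteoporotic=assessment.osteoporotic,
        major_risk_pct=major if major is not None else np.nan,
        hip_risk_pct=hip_risk if hip_risk is not None else np.nan,
        high_major=assessment.high_major,
        high_hip=assessment.high_hip,
        triage=decision.category.value,
    )
    return row


def _write_manifest(out_dir: Path, payload: dict) -> None:
    body = json.dumps(payload, sort_keys=True, default=str)
    manifest = {
        "bonescreen_version": __version__,
        "config_hash": hashlib.sha256(body.encode()).hexdigest()[:16],
        **payload,
    }
    with open(Path(out_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
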