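"""Delimited-text readers/writers for feature tables, studies, batches and
reports.

Everything on disk is header-rowed CSV or JSON so runs, studies and reports
stay diffable and auditable.  Feature tables use the schema
``run_id, species, mz, rt_min, response, fragment_mzs`` with fragment m/z
values semicolon-joined in one field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .identify import FeatureObservation
from .quantify import CalibrationCurve, ScreeningDecision, fit_calibration
from .simulate import Batch, CalibrationSeries, SyntheticRun, ValidationStudy
from .validation import ValidationReport

__all__ = [
    "write_run",
    "read_run",
    "write_calibration",
    "read_calibration",
    "write_study",
    "read_study",
    "write_batch",
    "read_batch",
    "write_validation_report",
    "read_cutoffs",
    "write_screening_report",
]

_FEATURE_COLUMNS = ["run_id", "species", "mz", "rt_min", "response", "fragment_mzs"]

#: Bump when a report schema changes; written into every report file.
REPORT_SCHEMA_VERSION = 1


def write_run(run: SyntheticRun, path: str | Path) -> Path:
    """Write one run's feature table as CSV."""
    rows = [
        {
            "run_id": run.run_id,
            "species": run.species,
            "mz": repr(float(f.mz)),
            "rt_min": repr(float(f.rt_min)),
            "response": repr(float(f.response)),
            "fragment_mzs": ";".join(repr(float(x)) for x in f.fragment_mzs),
        }
        for f in run.features
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=_FEATURE_COLUMNS).to_csv(path, index=False)
    return path


def read_run(path: str | Path, role: str = "sample") -> SyntheticRun:
    """Read a feature table back into a run (ground truth is not persisted)."""
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature-table columns {missing}")
    features = []
    run_id, species = Path(path).stem, "unknown"
    for _, row in df.iterrows():
        run_id, species = row["run_id"], row["species"]
        frags = tuple(
            float(x) for x in str(row["fragment_mzs"]).split(";") if x
        )
        features.append(
            FeatureObservation(
                mz=float(row["mz"]),
                rt_min=float(row["rt_min"]),
                response=float(row["response"]),
                fragment_mzs=frags,
                run_id=run_id,
            )
        )
    return SyntheticRun(run_id, species, {}, features, seed=-1, role=role)


def write_calibration(series: CalibrationSeries, path: str | Path) -> Path:
    rows = []
    for name, responses in series.responses.items():
        for level, response in zip(series.levels, responses):
            rows.append(
                {"compound": name, "level_ug_l": repr(float(level)),
                 "response": repr(float(response))}
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_calibration(path: str | Path) -> dict[str, CalibrationCurve]:
    """Read a calibration table and fit one curve per compound."""
    df = pd.read_csv(Path(path))
    curves = {}
    for name, grp in df.groupby("compound", sort=False):
        curves[str(name)] = fit_calibration(
            grp["level_ug_l"].astype(float).tolist(),
            grp["response"].astype(float).tolist(),
            compound=str(name),
            tag=str(path),
        )
    return curves


def _write_manifest(path: Path, payload: Mapping) -> None:
    with path.open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_study(study: ValidationStudy, out_dir: str | Path) -> Path:
    """Write a validation study (runs + calibration + manifest) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blank_files, spiked_files = [], []
    for run in study.blank_runs:
        blank_files.append(write_run(run, out / f"{run.run_id}.csv").name)
    for run in study.spiked_runs:
        spiked_files.append(write_run(run, out / f"{run.run_id}.csv").name)
    write_calibration(study.calibration, out / "calibration.csv")
    _write_manifest(
        out / "study.json",
        {
            "kind": "validation_study",
            "seed": study.seed,
            "blank_runs": blank_files,
            "spiked_runs": spiked_files,
            "calibration": "calibration.csv",
            "spike_levels_ug_kg": study.spike_levels,
        },
    )
    return out / "study.json"


def read_study(study_dir: str | Path):
    """Read a study directory; returns (blank_runs, spiked_runs, curves, manifest)."""
    study_dir = Path(study_dir)
    manifest_path = study_dir / "study.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no study manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    blanks = [read_run(study_dir / f) for f in manifest["blank_runs"]]
    spiked = [read_run(study_dir / f) for f in manifest["spiked_runs"]]
    curves = read_calibration(study_dir / manifest["calibration"])
    return blanks, spiked, curves, manifest


def write_batch(batch: Batch, out_dir: str | Path) -> Path:
    """Write an analytical batch (ordered roles) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_calibration(batch.calibration, out / "calibration.csv")
    sequence = []
    for i, entry in enumerate(batch.entries):
        if entry.role == "calibration":
            sequence.append({"role": "calibration", "file": "calibration.csv"})
            continue
        fname = f"{i:02d}-{entry.run.run_id}.csv"
        write_run(entry.run, out / fname)
        sequence.append({"role": entry.role, "file": fname})
    _write_manifest(
        out / "batch.json",
        {"kind": "batch", "seed": batch.seed, "sequence": sequence},
    )
    return out / "batch.json"


class LoadedBatch:
    """Disk-backed batch exposing the same surface qc_batch needs."""

    def __init__(self, entries, calibration_curves, manifest):
        self.entries = entries
        self.curves = calibration_curves
        self.manifest = manifest

    def control_run(self, role: str):
        for entry_role, run in self.entries:
            if entry_role == role:
                return run
        return None

    def unknowns(self):
        return [run for role, run in self.entries if role == "unknown"]

    @property
    def calibration(self):  # pragma: no cover - qc_batch uses curves directly
        raise AttributeError("loaded batches carry fitted curves, not raw series")


def read_batch(batch_dir: str | Path) -> LoadedBatch:
    batch_dir = Path(batch_dir)
    manifest_path = batch_dir / "batch.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no batch manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    entries = []
    curves = None
    for item in manifest["sequence"]:
        if item["role"] == "calibration":
            curves = read_calibration(batch_dir / item["file"])
        else:
            entries.append(
                (item["role"], read_run(batch_dir / item["file"], item["role"]))
            )
    if curves is None:
        raise ValueError(f"{batch_dir}: batch manifest has no calibration entry")
    return LoadedBatch(entries, curves, manifest)


def write_validation_report(
    report: ValidationReport,
    path: str | Path,
    config_hash: str = "",
) -> Path:
    """One CSV record per analyte (T, Fm, STC, verdict, CV, limit) plus a
    JSON sidecar with the study-level summary."""
    path = Path(path)
    rows = [
        {
            "analyte": v.analyte,
            "threshold_T_ug_kg": v.threshold,
            "cutoff_Fm_ug_kg": v.cutoff,
            "stc_ug_kg": v.stc,
            "ccbeta_pass": v.passed,
            "cv_r_pct": v.cv_r_pct,
            "cv_limit_pct": v.cv_limit_pct,
            "precision_pass": v.precision_ok,
            "message": v.message,
        }
        for v in report
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_manifest(
        path.with_suffix(".summary.json"),
        {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_blank": report.n_blank,
            "n_spiked": report.n_spiked,
            "n_analytes": len(report.verdicts),
            "all_ccbeta_pass": report.all_pass,
            "all_precision_pass": report.all_precision_ok,
            "seed": report.seed,
            "config_hash": config_hash,
        },
    )
    return path


def read_cutoffs(path: str | Path) -> dict[str, float]:
    """Read per-analyte cut-offs; accepts a validation report CSV or any CSV
    with ``analyte``/``compound`` and ``cutoff_Fm_ug_kg``/``fm_ug_kg`` columns."""
    df = pd.read_csv(Path(path))
    name_col = next((c for c in ("analyte", "compound") if c in df.columns), None)
    val_col = next(
        (c for c in ("cutoff_Fm_ug_kg", "fm_ug_kg") if c in df.columns), None
    )
    if name_col is None or val_col is None:
        raise ValueError(f"{path}: expected analyte/compound and cut-off columns")
    return {str(r[name_col]): float(r[val_col]) for _, r in df.iterrows()}


def write_screening_report(
    decisions_by_run: Mapping[str, Iterable[ScreeningDecision]],
    path: str | Path,
    qc_pass: bool | None = None,
    config_hash: str = "",
) -> Path:
    """One CSV row per (run, compound) with the screening verdict."""
    path = Path(path)
    rows = []
    for run_id, decisions in decisions_by_run.items():
        for d in decisions:
            rows.append(
                {
                    "run_id": run_id,
                    "compound": d.compound,
                    "identified": d.identification.identified,
                    "points": d.identification.points,
                    "sample_ug_kg": d.sample_ug_kg,
                    "cutoff_Fm_ug_kg": d.cutoff_ug_kg,
                    "verdict": d.verdict,
                    "reliable": True if qc_pass is None else qc_pass,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_manifest(
        path.with_suffix(".summary.json"),
        {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_runs": len(decisions_by_run),
            "qc_pass": qc_pass,
            "config_hash": config_hash,
        },
    )
    return path
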