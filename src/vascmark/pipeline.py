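"""End-to-end orchestration: synthesize or load inputs, run the measurement
modules per patient, assemble the cohort table, and produce the association
report, with reproducible seeding and a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import carotid, io, pwv, stenosis, synthetic
from .errors import ConfigurationError, DataError, VascmarkError
from .stats import (
    AssociationReport,
    CohortTable,
    RegressionFit,
    association_matrix,
    fit_linear_model,
    interaction_scan,
)

REGRESSION_MARKERS = ("nwi", "pwv_proximal", "pwv_distal")


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration: cohort generator, waveform, and geometry."""

    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    waveform: synthetic.WaveformParams = field(default_factory=synthetic.WaveformParams)
    path_length_distal: float = 186.0  # mm, thoracic-descending to abdominal
    path_length_proximal: float = 120.0  # mm, ascending to thoracic-descending
    outer_radius_mm: float = 4.0
    n_vertices: int = 64
    center_jitter_mm: float = 0.1
    continue_on_error: bool = False
    outlier_flags: tuple = ()

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = synthetic.CohortConfig.from_dict(kwargs["cohort"])
        if "waveform" in kwargs:
            wf = kwargs["waveform"]
            known_wf = {f.name for f in fields(synthetic.WaveformParams)}
            unknown_wf = set(wf) - known_wf
            if unknown_wf:
                raise ConfigurationError(f"unknown waveform keys: {sorted(unknown_wf)}")
            kwargs["waveform"] = synthetic.WaveformParams(**wf)
        if "outlier_flags" in kwargs:
            kwargs["outlier_flags"] = tuple(
                (str(pid), str(var)) for pid, var in kwargs["outlier_flags"]
            )
        return cls(**kwargs)


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    inputs: dict
    stages: dict
    outputs: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_digest(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def measure_patient_pwv(
    true_pwv: float, path_length: float, waveform: synthetic.WaveformParams,
    site_pair: str = "",
) -> float:
    """Synthesize a curve pair at the latent true PWV and re-estimate it."""
    prox, dist = synthetic.generate_curve_pair(true_pwv, path_length, waveform)
    return pwv.estimate_pwv(prox, dist, path_length, site_pair=site_pair).pwv


def measure_patient_nwi(
    true_nwi: float, outer_radius: float, n_vertices: int, jitter: float, seed: int
) -> float:
    """Build an 8-slice contour stack realizing the latent NWI and measure it."""
    r_in = outer_radius * math.sqrt(1.0 - true_nwi)
    stack = synthetic.generate_carotid_stack(
        np.full(8, r_in), np.full(8, outer_radius),
        n_vertices=n_vertices, center_jitter=jitter, seed=seed,
    )
    return carotid.carotid_nwi(stack).nwi


def _measure_cohort(
    cohort: CohortTable, truth: dict, config: PipelineConfig, stages: dict
) -> CohortTable:
    """Replace latent marker values by per-patient measured values."""
    n = len(cohort)
    measured = cohort.copy()
    errors = []
    pwv_d = np.empty(n)
    pwv_p = np.empty(n)
    nwi = np.empty(n)
    cc = config.cohort
    true_pwv_d = np.clip(truth["true_pwv_distal"], *cc.pwv_distal_range)
    true_pwv_p = np.clip(truth["true_pwv_proximal"], *cc.pwv_proximal_range)
    true_nwi = np.clip(truth["true_nwi"], *cc.nwi_range)
    for i in range(n):
        pid = cohort.data.loc[i, "id"]
        try:
            pwv_d[i] = measure_patient_pwv(
                true_pwv_d[i], config.path_length_distal,
                config.waveform, site_pair="distal",
            )
            pwv_p[i] = measure_patient_pwv(
                true_pwv_p[i], config.path_length_proximal,
                config.waveform, site_pair="proximal",
            )
            nwi[i] = measure_patient_nwi(
                true_nwi[i], config.outer_radius_mm, config.n_vertices,
                config.center_jitter_mm, seed=cc.seed + 7919 * i,
            )
        except VascmarkError as exc:
            if not config.continue_on_error:
                raise VascmarkError(f"measurement failed for patient {pid}: {exc}") from exc
            errors.append({"patient_id": str(pid), "error": str(exc)})
            pwv_d[i] = pwv_p[i] = nwi[i] = np.nan
    measured.data["pwv_distal"] = pwv_d
    measured.data["pwv_proximal"] = pwv_p
    measured.data["nwi"] = nwi
    for col in ("pwv_distal", "pwv_proximal", "nwi"):
        measured.valid[col] = measured.data[col].notna()
    stages["measure"] = {"status": "ok", "n_patients": n, "errors": errors}
    return measured


def _regressions(cohort: CohortTable) -> dict:
    df = cohort.data
    out = {"fits": {}, "interactions": {}}
    for marker in REGRESSION_MARKERS:
        predictors = ("age", "gender", marker)
        fit = fit_linear_model(df, "mean_sc", predictors)
        out["fits"][marker] = {
            "n_obs": fit.n_obs,
            "r_squared": fit.r_squared,
            "coefficients": [dataclasses.asdict(c) for c in fit.coefficients],
        }
        out["interactions"][marker] = {
            f"{a}*{b}": p for (a, b), p in interaction_scan(df, "mean_sc", predictors).items()
        }
    return out


def format_association_text(report: AssociationReport) -> str:
    """Human-readable table mirroring the published correlation layout."""
    lines = []
    for name, entries in (("All patients included", report.full),
                          ("Outliers removed", report.outlier_removed)):
        if entries is None:
            continue
        lines.append(name)
        lines.append(f"{'pair':34s}{'method':10s}{'r':>8s}{'p':>10s}{'N':>5s}")
        for e in entries:
            if e.error:
                lines.append(f"{e.x + ' vs ' + e.y:34s}{e.method:10s}  error: {e.error}")
            else:
                lines.append(
                    f"{e.x + ' vs ' + e.y:34s}{e.method:10s}{e.estimate:8.3f}"
                    f"{e.p:10.4f}{e.n_pairs:5d}"
                )
        lines.append("")
    return "\n".join(lines)


def _write_outputs(
    out_dir: Path, cohort: CohortTable, report: AssociationReport,
    regressions: dict, manifest: RunManifest,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out_dir / "cohort.csv")
    (out_dir / "association.json").write_text(
        json.dumps(report.to_records(), indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "association.txt").write_text(format_association_text(report))
    (out_dir / "regression.json").write_text(
        json.dumps(regressions, indent=2, sort_keys=True, default=float) + "\n"
    )
    for name in ("cohort.csv", "association.json", "association.txt", "regression.json"):
        manifest.outputs[name] = _file_digest(out_dir / name)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n"
    )


def run_synthetic(
    config: PipelineConfig, out_dir, seed: int | None = None,
    n_patients: int | None = None,
) -> RunManifest:
    """Full synthetic run: generate, measure, associate, write, manifest."""
    if seed is not None or n_patients is not None:
        cohort_cfg = replace(
            config.cohort,
            **({"seed": seed} if seed is not None else {}),
            **({"n_patients": n_patients} if n_patients is not None else {}),
        )
        config = replace(config, cohort=cohort_cfg)
    out_dir = Path(out_dir)
    stages: dict = {}
    manifest = RunManifest(
        config_digest=_config_digest(config), seed=config.cohort.seed,
        inputs={}, stages=stages, outputs={},
    )

    cohort, truth = synthetic.generate_cohort(config.cohort)
    stages["simulate"] = {"status": "ok", "n_patients": len(cohort)}

    measured = _measure_cohort(cohort, truth, config, stages)

    flags = list(config.outlier_flags)
    for var, pid in truth["outlier_ids"].items():
        flags.append((pid, var))
    report = association_matrix(measured, outlier_flags=flags or None)
    regressions = _regressions(measured)
    stages["associate"] = {"status": "ok", "n_pairs": len(report.full)}

    _write_outputs(out_dir, measured, report, regressions, manifest)
    return manifest


def run_from_files(paths: dict, config: PipelineConfig, out_dir) -> RunManifest:
    """Run the measurement and association stages on user-supplied files.

    ``paths`` keys (all optional except ``cohort``):

    - ``cohort``: cohort CSV (ids, age, gender, and any already-known markers)
    - ``grades``: long-form stenosis grade CSV; recomputes mean_sc/max_sc
    - ``curves``: manifest CSV (patient_id, site, curve_a, curve_b, and either
      path_length_mm or centerline[, centerline2]); recomputes PWV per site
    - ``contours``: manifest CSV (patient_id, contour_file); recomputes NWI
    """
    if "cohort" not in paths:
        raise DataError("run_from_files requires a 'cohort' path")
    out_dir = Path(out_dir)
    stages: dict = {}
    manifest = RunManifest(
        config_digest=_config_digest(config), seed=config.cohort.seed,
        inputs={}, stages=stages, outputs={},
    )
    for key, p in paths.items():
        p = Path(p)
        if p.exists():
            manifest.inputs[key] = {"path": str(p), "sha256": _file_digest(p)}

    cohort = CohortTable.from_csv(paths["cohort"])
    data = cohort.data.set_index("id", drop=False)

    if "grades" in paths:
        grades = io.read_grades(paths["grades"])
        summaries = stenosis.summarize_grades(grades).set_index("patient_id")
        for pid, row in summaries.iterrows():
            if pid not in data.index:
                raise DataError(f"grades: unknown patient id {pid!r}")
            data.loc[pid, "mean_sc"] = row["mean_sc"]
            data.loc[pid, "max_sc"] = row["max_sc"]
        stages["stenosis"] = {"status": "ok", "n_patients": len(summaries)}

    if "curves" in paths:
        manifest_df = io._read_table(paths["curves"], ("patient_id", "site", "curve_a", "curve_b"))
        for _, row in manifest_df.iterrows():
            pid = str(row["patient_id"])
            site = row["site"]
            if site not in ("proximal", "distal"):
                raise DataError(f"curves manifest: site must be proximal|distal, got {site!r}")
            if pid not in data.index:
                raise DataError(f"curves manifest: unknown patient id {pid!r}")
            if "path_length_mm" in manifest_df.columns and not pd.isna(row.get("path_length_mm")):
                dx = float(row["path_length_mm"])
            elif "centerline" in manifest_df.columns:
                polylines = [io.read_centerline(row["centerline"])]
                if "centerline2" in manifest_df.columns and not pd.isna(row.get("centerline2")):
                    polylines.append(io.read_centerline(row["centerline2"]))
                dx = pwv.aortic_path_length(*polylines)
            else:
                raise DataError("curves manifest needs path_length_mm or centerline")
            try:
                curve_a = io.read_curve(row["curve_a"], site_label="proximal")
                curve_b = io.read_curve(row["curve_b"], site_label="distal")
                result = pwv.estimate_pwv(curve_a, curve_b, dx, site_pair=site)
            except VascmarkError as exc:
                raise VascmarkError(f"stage pwv, patient {pid}: {exc}") from exc
            data.loc[pid, f"pwv_{site}"] = result.pwv
        stages["pwv"] = {"status": "ok", "n_rows": len(manifest_df)}

    if "contours" in paths:
        manifest_df = io._read_table(paths["contours"], ("patient_id", "contour_file"))
        for _, row in manifest_df.iterrows():
            pid = str(row["patient_id"])
            if pid not in data.index:
                raise DataError(f"contours manifest: unknown patient id {pid!r}")
            try:
                stack = io.read_contour_stack(row["contour_file"])
                data.loc[pid, "nwi"] = carotid.carotid_nwi(stack).nwi
            except VascmarkError as exc:
                raise VascmarkError(f"stage nwi, patient {pid}: {exc}") from exc
        stages["nwi"] = {"status": "ok", "n_rows": len(manifest_df)}

    cohort = CohortTable(data.reset_index(drop=True))
    report = association_matrix(cohort, outlier_flags=config.outlier_flags or None)
    regressions = _regressions(cohort)
    stages["associate"] = {"status": "ok", "n_pairs": len(report.full)}

    _write_outputs(out_dir, cohort, report, regressions, manifest)
    return manifest
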