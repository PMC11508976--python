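"""Cohort CSV readers/writers, run configuration, and the end-to-end pipeline.

The cohort schema is two UTF-8 CSV files with header rows:

* ``patients.csv`` — patient_id, age, sex, mechanism, clavicle, scapula,
  thoracic_vertebra, sternum (flags as 0/1);
* ``fractures.csv`` — patient_id, rib, side, percent [optional],
  d1 [optional], d2 [optional].  Side accepts ``left``/``right`` and the
  ``L``/``R`` shorthand.

``run_pipeline`` ties the stages together: read and validate, aggregate
frequency matrices and density profiles, paint the 3D heat map, and write the
statistical report (JSON plus formatted text tables).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import heatmap as hm
from . import stats as st
from .geometry import (
    TemplateConfig,
    ThoraxTemplate,
    build_default_template,
    template_from_csv,
    template_from_ply,
)
from .mapping import (
    Cohort,
    CohortValidationError,
    DEFAULT_BIN_WIDTH,
    DEFAULT_SECTOR_BOUNDS,
    FLAG_NAMES,
    validate_cohort,
)

log = logging.getLogger("ribmap")

PATIENT_COLUMNS = ["patient_id", "age", "sex", "mechanism", *FLAG_NAMES]
FRACTURE_COLUMNS = ["patient_id", "rib", "side", "percent", "d1", "d2"]


# ---------------------------------------------------------------------------
# Cohort CSV round trip
# ---------------------------------------------------------------------------

def read_cohort_csv(patients_path: str | Path, fractures_path: str | Path) -> Cohort:
    """Read and validate the two-file cohort schema.

    A fractures file containing only the header yields an empty-fracture
    cohort with a warning rather than an error.
    """
    patients = pd.read_csv(patients_path, dtype={"patient_id": str})
    if "patient_id" not in patients.columns:
        raise CohortValidationError(
            f"{patients_path}: header must include patient_id"
        )
    fractures = pd.read_csv(
        fractures_path, dtype={"patient_id": str}, float_precision="round_trip"
    )
    if "patient_id" not in fractures.columns:
        raise CohortValidationError(
            f"{fractures_path}: header must include patient_id"
        )
    if fractures.empty:
        log.warning("%s contains no fracture rows", fractures_path)
    cohort = validate_cohort(patients, fractures)
    log.info(
        "read cohort: %d patients, %d fracture lines", len(cohort), cohort.n_fractures
    )
    return cohort


def write_cohort_csv(
    cohort: Cohort, patients_path: str | Path, fractures_path: str | Path
) -> None:
    """Write the cohort back to the two-file schema (percent at full precision)."""
    cohort.patient_frame().to_csv(patients_path, index=False)
    frames = cohort.fracture_frame().rename(columns={"rib": "rib"})
    frames["percent"] = frames["percent"].map(repr)  # full float precision
    frames.to_csv(fractures_path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run depends on; round-trips through YAML."""

    patients_csv: str = "patients.csv"
    fractures_csv: str = "fractures.csv"
    template_source: str = "default"      # "default" | path to .csv/.ply centerlines
    template_scale: float = 1.0
    bin_width: float = DEFAULT_BIN_WIDTH
    sector_bounds: tuple[float, float] = DEFAULT_SECTOR_BOUNDS
    bandwidth: float = 5.0
    side_scope: str = "pooled"
    contingency_method: str = "auto"
    alpha: float = 0.05
    output_dir: str = "ribmap_out"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        self.sector_bounds = tuple(self.sector_bounds)  # type: ignore[assignment]
        b1, b2 = self.sector_bounds
        if not (0 <= b1 < b2 <= 100):
            raise ValueError(f"invalid sector bounds {self.sector_bounds}")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.side_scope not in ("left", "right", "pooled", "mirrored"):
            raise ValueError(f"invalid side_scope {self.side_scope!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sector_bounds"] = list(self.sector_bounds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


def load_template(config: RunConfig) -> ThoraxTemplate:
    src = config.template_source
    if src == "default":
        return build_default_template(TemplateConfig(scale=config.template_scale))
    path = Path(src)
    if path.suffix.lower() == ".ply":
        return template_from_ply(path)
    return template_from_csv(path)


# ---------------------------------------------------------------------------
# Statistical report
# ---------------------------------------------------------------------------

def build_report(cohort: Cohort, config: RunConfig) -> dict:
    """Machine-readable report: cohort summary, rib counts, positional
    comparisons per flag, and the clavicle x upper-rib association."""
    pframe = cohort.patient_frame()
    percents = [f.percent for f in cohort.fracture_records()]
    summary = {
        "n_patients": len(cohort),
        "n_fracture_lines": cohort.n_fractures,
        "mean_fracture_lines_per_patient": (
            round(cohort.n_fractures / len(cohort), 2) if len(cohort) else None
        ),
        "mean_position": round(float(np.mean(percents)), 2) if percents else None,
        "sd_position": (
            round(float(np.std(percents, ddof=1)), 2) if len(percents) > 1 else None
        ),
        "flag_prevalence": {
            name: {
                "n": int(pframe[name].sum()),
                "percent": round(100.0 * pframe[name].mean(), 1) if len(pframe) else None,
            }
            for name in FLAG_NAMES
        },
    }

    table = st.rib_count_table(cohort)
    rib_counts = {
        "per_rib": table.to_frame().to_dict("records"),
        "grand_total": table.grand_total,
        "left_share": round(table.left_share, 2) if table.grand_total else None,
        "right_share": round(table.right_share, 2) if table.grand_total else None,
    }

    comparisons = {}
    for name in FLAG_NAMES:
        try:
            comparisons[name] = st.position_comparison(cohort, name).to_dict()
        except ValueError as exc:
            comparisons[name] = {"note": str(exc)}

    try:
        assoc = st.upper_rib_association(
            cohort, "clavicle", method=config.contingency_method  # type: ignore[arg-type]
        )
        upper = assoc.to_dict()
        upper["rib_range"] = [1, 3]
    except ValueError as exc:
        upper = {"note": str(exc)}

    return {
        "config": {
            "bin_width": config.bin_width,
            "sector_bounds": list(config.sector_bounds),
            "bandwidth": config.bandwidth,
            "side_scope": config.side_scope,
            "alpha": config.alpha,
            "seed": config.seed,
        },
        "summary": summary,
        "rib_counts": rib_counts,
        "position_comparisons": comparisons,
        "upper_rib_association": upper,
    }


def format_report_text(report: dict) -> str:
    """Human-readable text tables mirroring the JSON report."""
    lines: list[str] = []
    s = report["summary"]
    lines.append("COHORT SUMMARY")
    lines.append(f"  patients: {s['n_patients']}   fracture lines: {s['n_fracture_lines']}")
    lines.append(
        f"  mean lines/patient: {s['mean_fracture_lines_per_patient']}   "
        f"mean position: {s['mean_position']}%  (SD {s['sd_position']})"
    )
    lines.append("  associated fractures:")
    for name, d in s["flag_prevalence"].items():
        lines.append(f"    {name:<18} {d['n']:>4}  ({d['percent']}%)")
    lines.append("")
    lines.append("FRACTURE LINES PER RIB")
    lines.append(f"  {'rib':>3} {'left':>6} {'right':>6} {'total':>6} {'percent':>8}")
    for row in report["rib_counts"]["per_rib"]:
        lines.append(
            f"  {row['rib']:>3} {row['left']:>6} {row['right']:>6} "
            f"{row['total']:>6} {row['percent']:>8}"
        )
    rc = report["rib_counts"]
    lines.append(
        f"  total {rc['grand_total']}  left share {rc['left_share']}%  "
        f"right share {rc['right_share']}%"
    )
    lines.append("")
    lines.append("POSITION BY ASSOCIATED FRACTURE (Mann-Whitney, record level)")
    for name, d in report["position_comparisons"].items():
        if "note" in d:
            lines.append(f"  {name:<18} {d['note']}")
            continue
        lines.append(
            f"  {name:<18} yes {d['mean_yes']}% (SD {d['sd_yes']}, n={d['n_yes']})  "
            f"no {d['mean_no']}% (SD {d['sd_no']}, n={d['n_no']})  "
            f"U={d['u_statistic']:.1f}  p={d['p_value']:.4g}"
        )
    lines.append("")
    u = report["upper_rib_association"]
    if "note" in u:
        lines.append(f"UPPER-RIB (1-3) ASSOCIATION: {u['note']}")
    else:
        lines.append(
            "UPPER-RIB (1-3) FRACTURE RATE BY CLAVICLE FLAG: "
            f"yes {u['rate_group0']}%  no {u['rate_group1']}%  "
            f"method={u['method']}  p={u['p_value']:.4g}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Full run: validate, aggregate, paint, report.  Returns the report dict.

    Writes matrix.csv, density.csv, heatmap.ply, histogram.png, report.json
    and report.txt to the configured output directory.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort_csv(config.patients_csv, config.fractures_csv)

    matrix = hm.frequency_matrix(cohort, config.bin_width, config.side_scope)  # type: ignore[arg-type]
    log.info("frequency matrix: %d records in scope", matrix.total)
    matrix.to_frame().to_csv(out / "matrix.csv", index=False)

    profiles = hm.all_density_profiles(
        cohort, config.side_scope, config.bandwidth  # type: ignore[arg-type]
    )
    hm.profiles_to_frame(profiles).to_csv(out / "density.csv", index=False)
    log.info("density profiles: 12 ribs at bandwidth %.1f", config.bandwidth)

    template = load_template(config)
    mesh = hm.paint_heatmap(template, profiles)
    hm.export_heatmap_ply(mesh, out / "heatmap.ply")
    log.info("heat map painted: %d vertices", len(mesh.vertices))

    hm.plot_bin_histogram(matrix, out / "histogram.png")

    report = build_report(cohort, config)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "report.txt").write_text(format_report_text(report), encoding="utf-8")
    log.info("report written to %s", out)
    return report
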