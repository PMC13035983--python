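"""End-to-end orchestration: volumes (or simulated cohorts) in, tables out.

``measure_volume`` runs the full measurement chain on one labeled volume;
``run_pipeline`` maps it over a directory of volumes joined with a metadata
table (or simulates a measurement-level cohort), then produces the standard
report tables: demographic summary, three-group comparisons, EH-grade
correlations and duration-stratified tests.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cochlea import measure_cochlea
from .cohort import CohortSpec, simulate_cohort
from .geometry import fit_plane
from .stats import (
    ALL_METRICS,
    comparison_table,
    duration_stratified_tests,
    eh_correlations,
    summarize_cohort,
)
from .vestibule import measure_vestibule
from .volume_io import LabelVolume, extract_voxel_cloud, read_label_volume

__all__ = ["PipelineConfig", "measure_volume", "run_pipeline"]

log = logging.getLogger("labyrinthometry")

CANAL_NAMES = ("LSC", "PSC", "SSC")


def measure_volume(vol: LabelVolume, **options) -> dict[str, float]:
    """Measure every cochlear and vestibular metric of one label volume.

    Returns a flat metric->value mapping using the standard column names.
    Options are forwarded to the cochlear chain (``bin_width_mm``,
    ``ch_mode``, ``basal_plus_x``) and the vestibular fit (``sample``,
    ``model``).
    """
    canal_fits = {
        name: fit_plane(extract_voxel_cloud(vol, name).points_mm)
        for name in CANAL_NAMES
    }
    coch_opts = {
        k: options[k] for k in ("bin_width_mm", "ch_mode", "basal_plus_x") if k in options
    }
    vest_opts = {k: options[k] for k in ("sample", "model") if k in options}
    mc = measure_cochlea(extract_voxel_cloud(vol, "cochlea"), canal_fits, **coch_opts)
    mv = measure_vestibule(
        extract_voxel_cloud(vol, "vestibule"), canal_fits, **vest_opts
    )
    row = {
        "ch_mm": mc.ch_mm,
        "cochlear_volume_mm3": mc.volume_mm3,
        "bld_mm": mc.bld_mm,
        "bsd_mm": mc.bsd_mm,
        "cdl_mm": mc.cdl_mm,
        "tl2_mm": mc.tl2_mm,
        "btl_mm": mc.btl_mm,
        "angle_modiolus_lsc_deg": mc.angle_modiolus_lsc_deg,
        "angle_modiolus_psc_deg": mc.angle_modiolus_psc_deg,
        "angle_modiolus_ssc_deg": mc.angle_modiolus_ssc_deg,
        "vestibular_volume_mm3": mv.volume_mm3,
        "length_a_mm": mv.length_a_mm,
        "length_b_mm": mv.length_b_mm,
        "length_c_mm": mv.length_c_mm,
    }
    for plane in ("ab", "ac", "bc"):
        row[f"area_{plane}_mm2"] = getattr(mv, f"area_{plane}_mm2")
        for canal in ("lsc", "psc", "ssc"):
            row[f"angle_{plane}_{canal}_deg"] = mv.angles_deg[plane.upper()][
                canal.upper()
            ]
    return row


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one pipeline run.

    ``mode="cohort"`` simulates a measurement-level cohort from
    ``cohort_spec``; ``mode="volumes"`` measures NIfTI label volumes listed
    in ``metadata`` (which must have ``subject_id`` matching the volume file
    stems, plus at least a ``group`` column).
    """

    mode: str = "cohort"
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    volume_dir: str | None = None
    metadata_path: str | None = None
    outdir: str | None = None
    posthoc: str = "bonferroni"
    duration_cutoff_years: float = 5.0
    seed: int = 0


def _measure_directory(config: PipelineConfig) -> pd.DataFrame:
    vdir = Path(config.volume_dir)
    meta = pd.read_csv(config.metadata_path)
    if "subject_id" not in meta.columns:
        raise ValueError("metadata must contain a subject_id column")
    files = {p.name.split(".")[0]: p for p in sorted(vdir.glob("*.nii*"))}
    wanted = set(meta["subject_id"].astype(str))
    missing_files = sorted(wanted - set(files))
    missing_meta = sorted(set(files) - wanted)
    if missing_files or missing_meta:
        raise ValueError(
            "metadata/volume mismatch: "
            f"no volume for {missing_files}; no metadata for {missing_meta}"
        )
    rows = []
    for sid in meta["subject_id"].astype(str):
        vol = read_label_volume(str(files[sid]))
        row = {"subject_id": sid, **measure_volume(vol)}
        rows.append(row)
    measured = pd.DataFrame(rows)
    return meta.assign(subject_id=meta["subject_id"].astype(str)).merge(
        measured, on="subject_id"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return its tables.

    Returns a dict with ``records`` (per-ear metrics + metadata),
    ``summary``, ``group_comparison``, ``eh_correlations`` (affected ears),
    and ``duration_tests``.  With ``config.outdir`` the tables are also
    written as CSV/JSON together with a run log (seed, package version,
    config echo).
    """
    if config.mode == "cohort":
        spec = config.cohort_spec
        if spec.seed != config.seed:
            spec = CohortSpec(**{**asdict_shallow(spec), "seed": config.seed})
        records = simulate_cohort(spec)
    elif config.mode == "volumes":
        records = _measure_directory(config)
    else:
        raise ValueError(f"unknown pipeline mode {config.mode!r}")

    metrics = [m for m in ALL_METRICS if m in records.columns]
    out: dict = {"records": records}
    if "group" in records.columns:
        out["summary"] = summarize_cohort(records)
        counts = records["group"].value_counts()
        if all(counts.get(g, 0) >= 2 for g in ("MDAE", "MDUE", "HC")):
            out["group_comparison"] = comparison_table(
                records, metrics, posthoc=config.posthoc
            )
        mdae = records[records["group"] == "MDAE"]
        corr_frames = []
        for grade_col in ("eh_cochlear_grade", "eh_vestibular_grade"):
            if grade_col in records.columns and mdae[grade_col].notna().any():
                res = eh_correlations(mdae, grade_col, metrics)
                corr_frames.append(
                    pd.DataFrame(
                        {
                            "metric": [r.metric for r in res],
                            "grade_type": grade_col,
                            "spearman_r": [r.spearman_r for r in res],
                            "p": [r.p_value for r in res],
                            "n": [r.n for r in res],
                        }
                    )
                )
        if corr_frames:
            out["eh_correlations"] = pd.concat(corr_frames, ignore_index=True)
        if (
            "duration_years" in records.columns
            and mdae["duration_years"].notna().any()
            and (mdae["duration_years"] > config.duration_cutoff_years).sum() >= 2
            and (mdae["duration_years"] <= config.duration_cutoff_years).sum() >= 2
        ):
            out["duration_tests"] = duration_stratified_tests(
                mdae, cutoff_years=config.duration_cutoff_years, metrics=metrics
            )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records.to_csv(outdir / "records.csv", index=False)
        for key in ("group_comparison", "duration_tests"):
            if key in out:
                out[key].to_csv(outdir / f"{key}.csv")
        if "eh_correlations" in out:
            out["eh_correlations"].to_csv(outdir / "eh_correlations.csv", index=False)
        if "summary" in out:
            (outdir / "summary.json").write_text(json.dumps(out["summary"], indent=2))
        logpath = outdir / "run_log.json"
        logpath.write_text(
            json.dumps(
                {
                    "package_version": __version__,
                    "numpy_version": np.__version__,
                    "pandas_version": pd.__version__,
                    "python_version": sys.version,
                    "seed": config.seed,
                    "mode": config.mode,
                    "posthoc": config.posthoc,
                },
                indent=2,
            )
        )
        log.info("pipeline outputs written to %s", outdir)
    return out


def asdict_shallow(spec: CohortSpec) -> dict:
    """Shallow field dict of a CohortSpec (dataclasses.asdict would recurse
    into nested frozen dataclasses and break re-construction)."""
    from dataclasses import fields

    return {f.name: getattr(spec, f.name) for f in fields(spec)}
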