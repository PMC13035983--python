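"""Measurement-level cohort simulation.

Simulates per-ear inner-ear metric records for three groups — disease-
affected ears (MDAE), the same patients' unaffected ears (MDUE), and
healthy-control ears (HC) — with configurable additive group effects,
within-patient correlation, a disease-duration mixture with late vestibular
enlargement, and ordinal endolymphatic-hydrops (EH) grades linked to
selected angle metrics through a thresholded-latent model.

The default generating parameters are the adult reference scale for each
metric (healthy-ear mean and SD) with the group shifts, duration mixture
and grade distributions of a typical unilateral Meniere cohort of ~105
patients and ~100 control ears.  The simulator draws *measured* values
directly (it does not voxelize phantoms), so it is fast enough for
thousands of replicate cohorts; geometric identities between drawn metrics
(e.g. section areas versus diameters) are not enforced, except that the
duct lengths CDL/2TL/BTL are computed exactly from the drawn BLD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cochlea import derived_lengths

__all__ = [
    "MetricModel",
    "EhGradeModel",
    "DurationModel",
    "CohortSpec",
    "default_metric_params",
    "simulate_cohort",
]

GROUPS = ("MDAE", "MDUE", "HC")

#: Empirical attenuation of the latent-normal correlation when one variable
#: is discretized into the 4-level grade distribution used here: the rank
#: correlation of (metric, grade) is ~0.90 of the latent Pearson correlation.
GRADE_LINK_ATTENUATION = 0.90


@dataclass(frozen=True)
class MetricModel:
    """Gaussian generating model for one metric: HC mean/SD plus additive
    group shifts for affected and unaffected Meniere ears."""

    hc_mean: float
    sd: float
    mdae_shift: float = 0.0
    mdue_shift: float = 0.0


@dataclass(frozen=True)
class EhGradeModel:
    """Thresholded-latent ordinal grade model.

    ``grade_probs`` is the marginal grade distribution (grades 0..k); the
    latent is a unit normal correlated with the z-scores of the driver
    metrics through ``target_spearman`` (per-metric target rank correlation,
    sign included), divided by the discretization attenuation.
    """

    grade_probs: tuple[float, ...]
    target_spearman: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.grade_probs, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError("grade_probs must be a probability vector")
        w2 = sum(
            (r / GRADE_LINK_ATTENUATION) ** 2 for r in self.target_spearman.values()
        )
        if w2 > 1.0:
            raise ValueError("target correlations too large for a unit latent")


@dataclass(frozen=True)
class DurationModel:
    """Mixture of short (<= cutoff) and long (> cutoff) disease duration,
    with additive metric shifts on the affected ear for long duration."""

    p_long: float = 58.0 / 105.0
    cutoff_years: float = 5.0
    short_range_years: tuple[float, float] = (0.2, 5.0)
    long_mean_excess_years: float = 5.0
    long_duration_shifts: dict[str, float] = field(default_factory=dict)


def default_metric_params() -> dict[str, MetricModel]:
    """Reference generating parameters: healthy-ear mean/SD and Meniere
    group shifts for every cochlear and vestibular metric.

    BLD drives CDL/2TL/BTL deterministically, so only BLD appears here.
    """
    return {
        "ch_mm": MetricModel(3.98, 0.22, +0.08, +0.04),
        "cochlear_volume_mm3": MetricModel(73.82, 7.49, +1.19, +0.30),
        "bld_mm": MetricModel(8.98, 0.38, +0.10, +0.05),
        "bsd_mm": MetricModel(6.50, 0.30, +0.05, 0.00),
        "angle_modiolus_lsc_deg": MetricModel(56.02, 5.81, +1.87, +3.05),
        "angle_modiolus_psc_deg": MetricModel(75.73, 11.43, -1.81, +0.28),
        "angle_modiolus_ssc_deg": MetricModel(41.28, 13.27, +0.24, -0.52),
        "vestibular_volume_mm3": MetricModel(55.11, 7.20, -0.99, -1.08),
        "length_a_mm": MetricModel(6.21, 0.53, -0.07, -0.01),
        "length_b_mm": MetricModel(4.61, 0.46, -0.02, -0.07),
        "length_c_mm": MetricModel(2.21, 0.11, -0.02, -0.02),
        "area_ab_mm2": MetricModel(22.55, 3.09, -0.38, -0.38),
        "area_ac_mm2": MetricModel(10.79, 1.10, -0.19, -0.08),
        "area_bc_mm2": MetricModel(8.02, 0.91, -0.09, -0.16),
        "angle_ab_lsc_deg": MetricModel(36.60, 12.62, -5.22, -5.70),
        "angle_ac_lsc_deg": MetricModel(71.51, 14.15, +4.09, +6.04),
        "angle_bc_lsc_deg": MetricModel(62.37, 7.69, +2.99, +1.91),
        "angle_ab_psc_deg": MetricModel(64.65, 19.16, +0.34, +2.38),
        "angle_ac_psc_deg": MetricModel(72.46, 11.38, -1.12, -1.95),
        "angle_bc_psc_deg": MetricModel(35.76, 19.98, +0.41, -0.36),
        "angle_ab_ssc_deg": MetricModel(64.65, 19.16, +0.34, +2.38),
        "angle_ac_ssc_deg": MetricModel(72.46, 11.38, -1.12, -1.95),
        "angle_bc_ssc_deg": MetricModel(35.76, 19.98, +0.41, -0.36),
    }


def _default_eh_models() -> dict[str, EhGradeModel]:
    return {
        # Cochlear EH: no metric driver (no reliable anatomical correlate).
        "eh_cochlear_grade": EhGradeModel(
            grade_probs=(0.076, 0.400, 0.362, 0.162)
        ),
        # Vestibular EH: positively linked to the modiolus-SSC angle and
        # negatively to the AB-plane-to-PSC/SSC angles.
        "eh_vestibular_grade": EhGradeModel(
            grade_probs=(0.1429, 0.4762, 0.2571, 0.1238),
            target_spearman={
                "angle_modiolus_ssc_deg": +0.243,
                "angle_ab_psc_deg": -0.251,
                "angle_ab_ssc_deg": -0.251,
            },
        ),
    }


def _default_duration_model() -> DurationModel:
    return DurationModel(
        long_duration_shifts={
            "vestibular_volume_mm3": +2.73,
            "length_b_mm": +0.19,
            "area_ab_mm2": +1.14,
            "area_bc_mm2": +0.44,
        }
    )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation parameters."""

    n_patients: int = 105
    n_hc: int = 100
    metric_params: dict[str, MetricModel] = field(default_factory=default_metric_params)
    within_patient_rho: float = 0.5
    eh_models: dict[str, EhGradeModel] = field(default_factory=_default_eh_models)
    duration: DurationModel = field(default_factory=_default_duration_model)
    prop_female: float = 60.0 / 105.0
    prop_affected_left: float = 59.0 / 105.0
    age_mean: float = 57.33
    age_sd: float = 10.62
    pta_affected: MetricModel = field(
        default_factory=lambda: MetricModel(65.69, 18.09)
    )
    pta_unaffected: MetricModel = field(
        default_factory=lambda: MetricModel(23.64, 14.09)
    )
    pta_hc: MetricModel = field(default_factory=lambda: MetricModel(15.0, 8.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_hc <= 0:
            raise ValueError("cohort sizes must be positive")
        if not (0.0 <= self.within_patient_rho < 1.0):
            raise ValueError("within_patient_rho must lie in [0, 1)")


def _grades_from_latent(
    df: pd.DataFrame,
    model: EhGradeModel,
    params: dict[str, MetricModel],
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(df)
    w2 = 0.0
    latent = np.zeros(n)
    for metric, r in model.target_spearman.items():
        m = params[metric]
        z = (df[metric].to_numpy() - (m.hc_mean + m.mdae_shift)) / m.sd
        w = r / GRADE_LINK_ATTENUATION
        latent += w * z
        w2 += w * w
    latent += np.sqrt(max(1.0 - w2, 0.0)) * rng.standard_normal(n)
    cuts = sps.norm.ppf(np.cumsum(model.grade_probs)[:-1])
    return np.searchsorted(cuts, latent)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one cohort of per-ear records.

    Returns a DataFrame with one row per ear: patient/subject id, group
    (MDAE / MDUE / HC), ear side, demographics, disease duration, ordinal EH
    grades (Meniere ears only), pure-tone average, and all metric columns.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.metric_params
    rho = spec.within_patient_rho
    n_p, n_hc = spec.n_patients, spec.n_hc

    # Patient-level covariates.
    female = rng.random(n_p) < spec.prop_female
    affected_left = rng.random(n_p) < spec.prop_affected_left
    age = rng.normal(spec.age_mean, spec.age_sd, n_p)
    is_long = rng.random(n_p) < spec.duration.p_long
    lo, hi = spec.duration.short_range_years
    duration = np.where(
        is_long,
        spec.duration.cutoff_years
        + rng.exponential(spec.duration.long_mean_excess_years, n_p),
        rng.uniform(lo, hi, n_p),
    )

    rows: dict[str, dict[str, np.ndarray]] = {}
    for group in GROUPS:
        n = n_p if group in ("MDAE", "MDUE") else n_hc
        rows[group] = {}

    # Metric draws: MD ears share a per-patient random effect (correlation
    # rho between the two ears); HC ears are independent.
    for metric, m in params.items():
        u = rng.standard_normal(n_p)  # shared patient effect
        for group in ("MDAE", "MDUE"):
            shift = m.mdae_shift if group == "MDAE" else m.mdue_shift
            eps = rng.standard_normal(n_p)
            vals = (
                m.hc_mean
                + shift
                + m.sd * (np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps)
            )
            if group == "MDAE" and metric in spec.duration.long_duration_shifts:
                vals = vals + spec.duration.long_duration_shifts[metric] * is_long
            rows[group][metric] = vals
        rows["HC"][metric] = m.hc_mean + m.sd * rng.standard_normal(n_hc)

    frames = []
    for group in GROUPS:
        n = n_p if group != "HC" else n_hc
        df = pd.DataFrame(rows[group])
        if "bld_mm" in df.columns:
            cdl, tl2, btl = np.vectorize(derived_lengths)(df["bld_mm"].to_numpy())
            df["cdl_mm"], df["tl2_mm"], df["btl_mm"] = cdl, tl2, btl
        if group == "HC":
            df.insert(0, "patient_id", [f"HC{i:03d}" for i in range(n)])
            df.insert(1, "group", group)
            df.insert(2, "ear_side", rng.choice(["L", "R"], n))
            df.insert(3, "sex", rng.choice(["F", "M"], n))
            df.insert(4, "age_years", rng.normal(spec.age_mean, spec.age_sd, n))
            df.insert(5, "duration_years", np.nan)
            df["pta_db"] = rng.normal(spec.pta_hc.hc_mean, spec.pta_hc.sd, n)
            df["eh_cochlear_grade"] = pd.array([pd.NA] * n, dtype="Int64")
            df["eh_vestibular_grade"] = pd.array([pd.NA] * n, dtype="Int64")
        else:
            affected = group == "MDAE"
            side = np.where(affected_left == affected, "L", "R")
            df.insert(0, "patient_id", [f"MD{i:03d}" for i in range(n)])
            df.insert(1, "group", group)
            df.insert(2, "ear_side", side)
            df.insert(3, "sex", np.where(female, "F", "M"))
            df.insert(4, "age_years", age)
            df.insert(5, "duration_years", duration)
            pta = spec.pta_affected if affected else spec.pta_unaffected
            df["pta_db"] = rng.normal(pta.hc_mean, pta.sd, n)
            for grade_col, model in spec.eh_models.items():
                if affected:
                    df[grade_col] = pd.array(
                        _grades_from_latent(df, model, params, rng), dtype="Int64"
                    )
                else:
                    # Unaffected ears: same ordinal scale, milder severity.
                    probs = np.asarray(model.grade_probs)
                    mild = probs * np.array([4.0] + [1.0] * (len(probs) - 1))
                    mild /= mild.sum()
                    df[grade_col] = pd.array(
                        rng.choice(len(mild), size=n, p=mild), dtype="Int64"
                    )
        frames.append(df)

    return pd.concat(frames, ignore_index=True)
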