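"""Synthetic multi-cohort generator for the metabolic-subgrouping study design.

The generator emulates a two-axis latent structure over four metabolic
subgroups (TG-rich, TG-poor, High LDL-C, Low lipid):

* axis 1, the *divergence* axis (insulin / triglyceride-like): subgroup
  trajectories share a common intercept at age 24 and separate over time
  through subgroup-specific slopes (SD/decade);
* axis 2, the *progression* axis (LDL-C / WHR-like): subgroups are
  stratified at age 24 but change at a common rate.

Cohorts are longitudinal (several visits at fixed year offsets) or
cross-sectional (one visit, wide age range).  Measures are either
"anchored" named biomarkers with explicit per-subgroup intercept/slope
tables calibrated to published values, or generic panel measures that
load on the two axes in collinear blocks (to emulate the massive
collinearity of an NMR metabolomics panel).

All quantities are generated on a latent z-scale whose pooled variance is
normalised to 1 under the anchor (longitudinal) cohort design, so that a
generative slope of ``b`` SD/decade is recoverable as a standardized
regression slope of ``b``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SUBGROUPS",
    "MeasureSpec",
    "CohortDesign",
    "GeneratorConfig",
    "generate_cohort",
    "paper_calibrated_config",
    "write_cohort",
    "read_cohort",
    "ID_COLUMNS",
]

SUBGROUPS = ("TG-rich", "TG-poor", "High LDL-C", "Low lipid")

#: non-measure columns of a cohort table, in canonical order
ID_COLUMNS = ["cohort_id", "subject_id", "visit_id", "age", "sex", "birth_year"]
#: hidden ground-truth column, present only in synthetic cohorts
TRUTH_COLUMN = "true_subgroup"


@dataclass
class MeasureSpec:
    """One quantitative measure of the panel.

    A measure is defined on a latent z-scale (pooled SD 1 under the anchor
    design).  ``loading_axis1``/``loading_axis2`` are linear loadings on
    the two latent axes.  If ``subgroup_intercepts``/``subgroup_slopes``
    are given they *override* the axis loadings with an explicit
    per-subgroup trajectory table (intercept in SD units at age 24, slope
    in SD/decade) — used for the anchored, natural-scale biomarkers.

    ``center``/``scale`` map latent z to the reported natural scale; for
    ``skewed`` measures the natural value is ``exp(center + scale * z)``.
    ``icc`` splits the residual variance into a subject-stable part and
    per-visit noise.  Measures sharing a ``block`` id share a latent
    block factor with pairwise correlation ``member_corr``.
    """

    name: str
    loading_axis1: float = 0.0
    loading_axis2: float = 0.0
    skewed: bool = False
    center: float = 0.0
    scale: float = 1.0
    subgroup_intercepts: tuple[float, ...] | None = None
    subgroup_slopes: tuple[float, ...] | None = None
    icc: float = 0.5
    block: str | None = None
    member_corr: float = 0.85
    age_effect: float = 0.0  # extra common trend, SD per decade
    sex_effect: float = 0.0  # additive shift for sex == 1, SD units


@dataclass
class CohortDesign:
    """Sampling design of one cohort.

    ``visit_offsets`` are years after baseline; ``baseline_age_range`` is
    the uniform range of baseline ages (equal bounds give a fixed age).
    ``retention`` is the per-visit probability of attending each
    follow-up visit (the baseline visit is always attended).
    """

    name: str
    n_subjects: int
    baseline_age_range: tuple[float, float]
    visit_offsets: tuple[float, ...] = (0.0,)
    baseline_year: int = 2001
    retention: float = 1.0


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic study.

    Axis parameters are per-subgroup tuples ordered as :data:`SUBGROUPS`.
    ``subject_random_intercept_sd`` and ``noise_sd`` are global
    multipliers (default 1) on each measure's subject-stable and
    per-visit noise SDs — set both to 0 for a noise-free cohort.
    """

    cohort_designs: list[CohortDesign]
    measures: list[MeasureSpec]
    subgroup_proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    axis1_intercepts: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    axis1_slopes: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    axis2_intercepts: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    axis2_slopes: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    subject_axis_sd: float = 0.12
    subject_random_intercept_sd: float = 1.0
    noise_sd: float = 1.0
    outlier_rate: float = 0.0
    anchor_cohort: str | None = None  # design used for variance bookkeeping
    age_center: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.subgroup_proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"subgroup_proportions must sum to 1 (got {p.sum():.12g})"
            )
        if (p < 0).any():
            raise ValueError("subgroup_proportions must be non-negative")
        for sd_name in ("subject_axis_sd", "subject_random_intercept_sd", "noise_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        names = [m.name for m in self.measures]
        if len(set(names)) != len(names):
            raise ValueError("duplicate measure names")

    def design(self, cohort_name: str) -> CohortDesign:
        for d in self.cohort_designs:
            if d.name == cohort_name:
                return d
        known = [d.name for d in self.cohort_designs]
        raise KeyError(f"unknown cohort {cohort_name!r}; known: {known}")

    @property
    def anchor_design(self) -> CohortDesign:
        if self.anchor_cohort is not None:
            return self.design(self.anchor_cohort)
        return self.cohort_designs[0]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["cohort_designs"] = [
            c if isinstance(c, CohortDesign) else CohortDesign(**_tuplify(c))
            for c in d["cohort_designs"]
        ]
        d["measures"] = [
            m if isinstance(m, MeasureSpec) else MeasureSpec(**_tuplify(m))
            for m in d["measures"]
        ]
        return cls(**_tuplify(d, shallow=True))


def _tuplify(d: dict, shallow: bool = False) -> dict:
    """JSON/YAML round-trips turn tuples into lists; restore tuples."""
    out = {}
    for k, v in d.items():
        if isinstance(v, list) and (shallow is False or k not in ("cohort_designs", "measures")):
            out[k] = tuple(v)
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# design moments and variance bookkeeping
# ---------------------------------------------------------------------------

def _decade_moments(design: CohortDesign, age_center: float) -> tuple[float, float]:
    """E[d] and E[d^2] of d = (age - age_center)/10 under the design.

    Baseline age is uniform on the design range; visits are equally
    weighted (retention is ignored here — it perturbs the moments only
    mildly and the pooled standardisation is refitted on data anyway).
    """
    lo, hi = design.baseline_age_range
    lo_d, hi_d = (lo - age_center) / 10.0, (hi - age_center) / 10.0
    mean_d0 = 0.5 * (lo_d + hi_d)
    var_d0 = (hi_d - lo_d) ** 2 / 12.0
    offs = np.asarray(design.visit_offsets, dtype=float) / 10.0
    mean_off = offs.mean()
    var_off = offs.var()
    e_d = mean_d0 + mean_off
    var_d = var_d0 + var_off
    return e_d, var_d + e_d**2


def _table_var(
    intercepts: np.ndarray,
    slopes: np.ndarray,
    props: np.ndarray,
    e_d: float,
    e_d2: float,
) -> float:
    """Pooled variance of a_g + b_g * d over subgroups g and ages d."""
    ea = float(props @ intercepts)
    eb = float(props @ slopes)
    ea2 = float(props @ intercepts**2)
    eb2 = float(props @ slopes**2)
    eab = float(props @ (intercepts * slopes))
    ex = ea + eb * e_d
    ex2 = ea2 + 2.0 * eab * e_d + eb2 * e_d2
    return ex2 - ex**2


def _axis_moments(config: GeneratorConfig) -> dict:
    """Variances/covariance of the two axes under the anchor design."""
    props = np.asarray(config.subgroup_proportions, dtype=float)
    e_d, e_d2 = _decade_moments(config.anchor_design, config.age_center)
    a1 = np.asarray(config.axis1_intercepts, float)
    b1 = np.asarray(config.axis1_slopes, float)
    a2 = np.asarray(config.axis2_intercepts, float)
    b2 = np.asarray(config.axis2_slopes, float)
    w2 = config.subject_axis_sd**2
    var1 = _table_var(a1, b1, props, e_d, e_d2) + w2
    var2 = _table_var(a2, b2, props, e_d, e_d2) + w2
    e_x1 = props @ a1 + (props @ b1) * e_d
    e_x2 = props @ a2 + (props @ b2) * e_d
    e_x1x2 = (
        props @ (a1 * a2)
        + (props @ (a1 * b2) + props @ (a2 * b1)) * e_d
        + (props @ (b1 * b2)) * e_d2
    )
    cov = e_x1x2 - e_x1 * e_x2
    return {"var1": float(var1), "var2": float(var2), "cov": float(cov),
            "e_d": e_d, "e_d2": e_d2, "props": props}


def _residual_budget(config: GeneratorConfig, spec: MeasureSpec, mom: dict) -> float:
    """Residual latent variance so that total pooled variance is 1."""
    if spec.subgroup_intercepts is not None:
        fixed = _table_var(
            np.asarray(spec.subgroup_intercepts, float),
            np.asarray(spec.subgroup_slopes, float),
            mom["props"], mom["e_d"], mom["e_d2"],
        )
    else:
        l1, l2 = spec.loading_axis1, spec.loading_axis2
        fixed = l1**2 * mom["var1"] + l2**2 * mom["var2"] + 2 * l1 * l2 * mom["cov"]
    var_d = mom["e_d2"] - mom["e_d"] ** 2
    fixed += spec.age_effect**2 * var_d + spec.sex_effect**2 * 0.25
    resid = 1.0 - fixed
    if resid < 0.05:
        raise ValueError(
            f"measure {spec.name!r}: systematic variance {fixed:.3f} leaves "
            "residual < 0.05; rescale loadings or slopes"
        )
    return resid


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _cohort_rng(seed: int, cohort_name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(cohort_name.encode())])
    )


def generate_cohort(config: GeneratorConfig, cohort_name: str) -> pd.DataFrame:
    """Generate one cohort as a long-format subject-visit table.

    Deterministic given ``config.seed`` and the cohort name.  The table
    carries the hidden ``true_subgroup`` column for validation; analysis
    code must never read it.
    """
    design = config.design(cohort_name)
    rng = _cohort_rng(config.seed, cohort_name)
    n = design.n_subjects
    props = np.asarray(config.subgroup_proportions, float)
    mom = _axis_moments(config)

    g = rng.choice(len(SUBGROUPS), size=n, p=props)
    lo, hi = design.baseline_age_range
    age0 = rng.uniform(lo, hi, n) if hi > lo else np.full(n, float(lo))
    sex = rng.integers(0, 2, n)
    birth_year = design.baseline_year - np.floor(age0).astype(int)
    omega = rng.normal(0.0, config.subject_axis_sd, size=(2, n))

    a1 = np.asarray(config.axis1_intercepts, float)
    b1 = np.asarray(config.axis1_slopes, float)
    a2 = np.asarray(config.axis2_intercepts, float)
    b2 = np.asarray(config.axis2_slopes, float)

    # group measures into blocks (singleton block per unblocked measure)
    blocks: dict[str, list[MeasureSpec]] = {}
    for spec in config.measures:
        key = spec.block if spec.block is not None else f"__solo_{spec.name}"
        blocks.setdefault(key, []).append(spec)

    # subject-stable noise, drawn once per subject
    su = config.subject_random_intercept_sd
    se = config.noise_sd
    block_u: dict[str, np.ndarray] = {}
    block_budget: dict[str, tuple[float, float]] = {}  # (sd_u, sd_e) of block latent
    measure_u: dict[str, np.ndarray] = {}
    for key, members in blocks.items():
        lead = members[0]
        if lead.subgroup_intercepts is not None:
            for spec in members:
                resid = _residual_budget(config, spec, mom)
                measure_u[spec.name] = rng.normal(
                    0.0, su * np.sqrt(spec.icc * resid), n
                )
        else:
            resid = _residual_budget(config, lead, mom)
            sd_u = su * np.sqrt(lead.icc * resid)
            sd_e = se * np.sqrt((1.0 - lead.icc) * resid)
            block_budget[key] = (sd_u, sd_e)
            block_u[key] = rng.normal(0.0, sd_u, n)

    t_bar_d = mom["e_d"]  # centre of the nuisance age trend
    frames = []
    for v, off in enumerate(design.visit_offsets):
        age = age0 + off
        d = (age - config.age_center) / 10.0
        if v == 0 or design.retention >= 1.0:
            keep = np.ones(n, dtype=bool)
        else:
            keep = rng.uniform(size=n) < design.retention
        A1 = a1[g] + b1[g] * d + omega[0]
        A2 = a2[g] + b2[g] * d + omega[1]

        cols: dict[str, np.ndarray] = {}
        for key, members in blocks.items():
            lead = members[0]
            if lead.subgroup_intercepts is None:
                sd_u, sd_e = block_budget[key]
                latent = (
                    lead.loading_axis1 * A1
                    + lead.loading_axis2 * A2
                    + lead.age_effect * (d - t_bar_d)
                    + lead.sex_effect * (sex - 0.5)
                    + block_u[key]
                    + rng.normal(0.0, sd_e, n)
                )
                shared = np.sqrt(lead.member_corr) if len(members) > 1 else 1.0
                uniq = np.sqrt(max(1.0 - lead.member_corr, 0.0)) if len(members) > 1 else 0.0
                for spec in members:
                    z = shared * latent
                    if uniq > 0.0:
                        z = z + uniq * rng.normal(0.0, se, n)
                    if config.outlier_rate > 0.0:
                        hit = rng.uniform(size=n) < config.outlier_rate
                        z = z + hit * rng.choice([-7.0, 7.0], size=n)
                    cols[spec.name] = _to_natural(spec, z)
            else:
                for spec in members:
                    resid = _residual_budget(config, spec, mom)
                    sd_e_m = se * np.sqrt((1.0 - spec.icc) * resid)
                    ai = np.asarray(spec.subgroup_intercepts, float)
                    bi = np.asarray(spec.subgroup_slopes, float)
                    z = (
                        ai[g] + bi[g] * d
                        + spec.age_effect * (d - t_bar_d)
                        + spec.sex_effect * (sex - 0.5)
                        + measure_u[spec.name]
                        + rng.normal(0.0, sd_e_m, n)
                    )
                    cols[spec.name] = _to_natural(spec, z)

        data = {
            "cohort_id": np.full(n, design.name),
            "subject_id": np.array([f"{design.name}_{i:05d}" for i in range(n)]),
            "visit_id": np.full(n, f"v{v + 1}"),
            "age": age,
            "sex": sex,
            "birth_year": birth_year,
            TRUTH_COLUMN: np.asarray(SUBGROUPS)[g],
        }
        # keep measure columns in config order
        data.update({spec.name: cols[spec.name] for spec in config.measures})
        frames.append(pd.DataFrame(data).loc[keep])

    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["subject_id", "visit_id"], kind="stable").reset_index(drop=True)
    return out


def _to_natural(spec: MeasureSpec, z: np.ndarray) -> np.ndarray:
    y = spec.center + spec.scale * z
    return np.exp(y) if spec.skewed else y


# ---------------------------------------------------------------------------
# calibrated configuration
# ---------------------------------------------------------------------------

# printed standardized slopes, SD/decade (High LDL-C insulin slope is a
# documented free default; the Low lipid value -0.0082 is as published)
_INSULIN_SLOPES = (0.35, -0.32, 0.05, -0.0082)
_LDL_SLOPES = (0.40, 0.36, 0.46, 0.29)
_WHR_SLOPES = (0.80, 0.74, 0.78, 0.76)
_GLUCOSE_SLOPES = (0.65, 0.50, 0.71, 0.55)
_TGCHOL_SLOPES = (0.32, -0.28, 0.04, -0.10)

# BMI natural-scale anchors: kg/m^2 at age 24 and kg/m^2 per decade.
_BMI_SD = 3.8
_BMI_INTERCEPTS_NAT = (25.0, 23.0, 24.3, 23.8)
_BMI_SLOPES_NAT = (2.0, 0.5, 1.1, 0.9)

# log-scale SD of insulin chosen so that the model-implied TG-rich:TG-poor
# ratio at age 49 is exactly 3 on the natural scale:
# exp(scale * (0.35 + 0.32) * 2.5) = 3.
_INSULIN_LOG_SCALE = float(np.log(3.0) / ((0.35 + 0.32) * 2.5))

# generic-panel block themes: (name, n axis1, n axis2, n mixed, n null)
_BLOCK_NAMES_AXIS1 = [
    "xxl_vldl_tg", "xl_vldl_tg", "l_vldl_tg", "m_vldl_tg", "s_vldl_tg",
    "vldl_d", "serum_tg", "mufa", "apob_apoa1", "hdl_tg",
    "hdl_c", "xl_hdl_c", "hdl_d", "isoleucine", "leucine", "valine",
]
_BLOCK_NAMES_AXIS2 = [
    "l_ldl_c", "m_ldl_c", "s_ldl_c", "ldl_d", "apob", "serum_c",
    "esterified_c", "free_c", "sphingomyelins", "phosphatidylc",
    "total_pg", "dha", "la", "faw3", "faw6", "remnant_c",
]
_BLOCK_NAMES_MIXED = [
    "glycoprot_ac", "crp", "phenylalanine", "tyrosine",
    "lactate", "pyruvate", "m_hdl_c", "idl_c",
]
_BLOCK_NAMES_NULL = [
    "creatinine", "albumin", "alanine", "glutamine", "histidine", "citrate",
]


def paper_calibrated_config(seed: int = 1) -> GeneratorConfig:
    """Configuration calibrated to the published study conditions.

    Four cohorts: a YFS-like longitudinal cohort (n=1286, baseline ages
    24-39, visits at +0/+6/+10 years, anchoring the variance
    bookkeeping), two FINRISK-like cross-sectional surveys (ages 25-74)
    and an NFBC1966-like birth cohort with fixed-age visits at 31 and 46.

    The six anchored measures carry the published standardized slopes and
    natural-scale anchors; 168 generic panel measures in 47 collinear
    blocks emulate the NMR panel (174 measures in total, collapsing to 53
    features after collinearity merging).
    """
    designs = [
        CohortDesign("yfs", 1286, (24.0, 39.0), (0.0, 6.0, 10.0), baseline_year=2001),
        CohortDesign("finrisk_1997", 5304, (25.0, 74.0), (0.0,), baseline_year=1997),
        CohortDesign("finrisk_2007", 4616, (25.0, 74.0), (0.0,), baseline_year=2007),
        CohortDesign("nfbc1966", 3117, (31.0, 31.0), (0.0, 15.0), baseline_year=1997),
    ]

    measures: list[MeasureSpec] = [
        MeasureSpec(
            "insulin", skewed=True, center=float(np.log(60.0)),
            scale=_INSULIN_LOG_SCALE,
            subgroup_intercepts=(0.0, 0.0, 0.0, 0.0),
            subgroup_slopes=_INSULIN_SLOPES, icc=0.60,
        ),
        MeasureSpec(
            "tg_chol_ratio", skewed=True, center=float(np.log(0.6)), scale=0.45,
            subgroup_intercepts=(0.0, 0.0, 0.0, 0.0),
            subgroup_slopes=_TGCHOL_SLOPES, icc=0.60,
        ),
        MeasureSpec(
            "bmi", center=24.0, scale=_BMI_SD,
            subgroup_intercepts=tuple(
                (x - 24.0) / _BMI_SD for x in _BMI_INTERCEPTS_NAT
            ),
            subgroup_slopes=tuple(x / _BMI_SD for x in _BMI_SLOPES_NAT),
            icc=0.85,
        ),
        MeasureSpec(
            "whr", center=0.88, scale=0.07,
            subgroup_intercepts=(0.9, -0.9, 0.25, -0.25),
            subgroup_slopes=_WHR_SLOPES, icc=0.75,
        ),
        MeasureSpec(
            "ldl_c", center=3.1, scale=0.85,
            subgroup_intercepts=(0.1, -0.1, 0.8, -0.8),
            subgroup_slopes=_LDL_SLOPES, icc=0.70,
        ),
        MeasureSpec(
            "glucose", center=5.3, scale=0.55,
            subgroup_intercepts=(0.55, -0.50, 0.45, -0.50),
            subgroup_slopes=_GLUCOSE_SLOPES, icc=0.65,
        ),
    ]

    config = GeneratorConfig(
        cohort_designs=designs,
        measures=measures,
        axis1_intercepts=(0.0, 0.0, 0.0, 0.0),
        axis1_slopes=_INSULIN_SLOPES,
        axis2_intercepts=(0.2, -0.2, 1.0, -1.0),
        axis2_slopes=(0.37, 0.37, 0.37, 0.37),
        subject_axis_sd=0.12,
        outlier_rate=0.002,
        anchor_cohort="yfs",
        seed=seed,
    )

    mom = _axis_moments(config)
    share = 0.5  # axis-variance share of loaded block latents
    l1_unit = float(np.sqrt(share / mom["var1"]))
    l2_unit = float(np.sqrt(share / mom["var2"]))

    block_plan: list[tuple[str, float, float]] = []
    for i, nm in enumerate(_BLOCK_NAMES_AXIS1):
        sgn = -1.0 if i % 3 == 2 else 1.0  # HDL-like blocks load negatively
        block_plan.append((nm, sgn * l1_unit, 0.0))
    for i, nm in enumerate(_BLOCK_NAMES_AXIS2):
        sgn = -1.0 if i % 5 == 4 else 1.0
        block_plan.append((nm, 0.0, sgn * l2_unit))
    for nm in _BLOCK_NAMES_MIXED:
        block_plan.append((nm, 0.55 * l1_unit, 0.55 * l2_unit))
    for nm in _BLOCK_NAMES_NULL:
        block_plan.append((nm, 0.0, 0.0))

    # 46 themed blocks (28 of size 4, 18 of size 3 -> 166 measures) plus a
    # 2-member blood-pressure block: 168 generic + 6 anchored = 174 measures
    # in 53 collinear groups.
    sizes = [4] * 28 + [3] * 18
    assert len(block_plan) == len(sizes)
    for i, ((bname, l1, l2), size) in enumerate(zip(block_plan, sizes)):
        skew_block = i % 5 == 1
        sex_eff = 0.3 if i % 4 == 0 else 0.0
        age_eff = 0.2 if i % 6 == 3 else 0.0
        for j in range(size):
            measures.append(
                MeasureSpec(
                    f"{bname}_{j + 1}",
                    loading_axis1=l1,
                    loading_axis2=l2,
                    skewed=skew_block,
                    center=0.0,
                    scale=0.6 if skew_block else 1.0,
                    icc=0.5,
                    block=bname,
                    member_corr=0.85,
                    age_effect=age_eff,
                    sex_effect=sex_eff,
                )
            )

    for nm, ctr, scl in (("sbp", 120.0, 14.0), ("dbp", 75.0, 9.0)):
        measures.append(
            MeasureSpec(
                nm,
                loading_axis1=0.50 * l1_unit,
                loading_axis2=0.30 * l2_unit,
                center=ctr,
                scale=scl,
                icc=0.6,
                block="bp",
                member_corr=0.85,
                sex_effect=0.25,
            )
        )

    assert len(measures) == 174
    return config


#: the nine easily available clinical biomarkers used as the comparison panel
CLINICAL9 = [
    "bmi", "whr", "sbp", "dbp", "serum_tg_1", "serum_c_1",
    "ldl_c", "hdl_c_1", "glucose",
]

#: the measures carrying published natural-scale or slope calibration
ANCHORED_MEASURES = [
    "insulin", "tg_chol_ratio", "bmi", "whr", "ldl_c", "glucose",
]


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (missing values as empty cells)."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating schema and measure numeric-ness."""
    df = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required columns: {missing}")
    measure_cols = [c for c in df.columns if c not in ID_COLUMNS + [TRUTH_COLUMN]]
    for c in measure_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = df[c].notna() & coerced.isna()
            if bad.any():
                raise ValueError(
                    f"non-numeric values in measure column {c!r} "
                    f"(first bad row {int(np.flatnonzero(bad)[0])})"
                )
            df[c] = coerced
    dup = df.duplicated(subset=["subject_id", "visit_id"])
    if dup.any():
        raise ValueError("duplicated (subject_id, visit_id) rows")
    return df


def measure_columns(cohort: pd.DataFrame) -> list[str]:
    """Names of the quantitative measure columns of a cohort table."""
    return [c for c in cohort.columns if c not in ID_COLUMNS + [TRUTH_COLUMN]]
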