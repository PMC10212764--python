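"""End-to-end study pipeline.

Stages, in the order the study design requires:

1. load or generate the cohorts;
2. preprocess each training cohort separately (robust standardization,
   age/sex adjustment), interpolating the birth-cohort visits to the
   target age first;
3. merge collinear measures and train the SOM on the combined
   cross-sectional + interpolated training data;
4. project the longitudinal cohort onto the map using only its
   designated (middle) visit;
5. fix the subgroup boundary — from a committee file or the automatic
   partition — *before* any longitudinal modelling;
6. fit per-subgroup trajectories and permutation ANOVAs over all visits;
7. label significance using the effective-number-of-tests threshold;
8. write the TSV/JSON bundle with a run manifest.

The boundary-before-trajectories ordering mirrors the original design,
where subgroup boundaries were committed before longitudinal data were
accessed, making the longitudinal p-values meaningful.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .multiplicity import multiplicity_summary
from .preprocess import (
    PreprocessArtifacts,
    adjust_covariates,
    merge_collinear,
    standardize,
)
from .som import SOMModel, project_cohort, ring_lattice, train_som
from .subgroups import (
    SubgroupBoundary,
    assign_subgroups,
    auto_partition,
    label_partition,
)
from .synthetic import (
    ANCHORED_MEASURES,
    GeneratorConfig,
    generate_cohort,
    measure_columns,
    paper_calibrated_config,
    read_cohort,
)
from .trajectories import (
    fit_trajectory,
    interpolate_to_age,
    mean_anova,
    slope_anova,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "run_calibrated_study", "PipelineError", "BoundaryMissingError"]

log = logging.getLogger("metabotrace")


class PipelineError(RuntimeError):
    pass


class BoundaryMissingError(PipelineError):
    """Raised when the subgroup boundary is unavailable before the
    trajectory stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full run.  Unknown keys are rejected."""

    # inputs: either paths to cohort CSVs or an inline generator config
    cohort_paths: dict[str, str] | None = None
    generator: GeneratorConfig | str | None = None
    training_cohorts: list[str] = field(
        default_factory=lambda: ["finrisk_1997", "finrisk_2007", "nfbc1966"]
    )
    projection_cohort: str = "yfs"
    projection_visit: str | None = None  # default: median visit
    interpolation: dict | None = field(
        default_factory=lambda: {"cohort": "nfbc1966", "target_age": 39.0}
    )
    boundary: str = "auto"  # "auto" or a path to a boundary JSON
    out_dir: str | None = None
    seed: int = 1
    skew_threshold: float = 1.0
    rho_threshold: float = 0.8
    som_rings: int = 5
    som_epochs: int = 50
    trajectory_measures: list[str] | None = None  # default: anchored panel
    n_boot: int = 2000
    n_perm: int = 9999
    variance_target: float = 0.99
    alpha: float = 0.05
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("generator"), dict):
            raw["generator"] = GeneratorConfig.from_dict(raw["generator"])
        return cls(**raw)

    def effective_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.generator, GeneratorConfig):
            d["generator"] = self.generator.to_dict()
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohorts: dict[str, pd.DataFrame]
    som: SOMModel
    boundary: SubgroupBoundary
    assignments: pd.Series  # district per projected subject
    labels: pd.Series  # subgroup per projected subject
    fits: dict[tuple[str, str], object]  # (measure, subgroup) -> TrajectoryFit
    slope_table: pd.DataFrame
    anova_table: pd.DataFrame
    multiplicity: object
    pooled_transform: object  # robust transform of the longitudinal cohort
    manifest: dict
    artifacts_training: PreprocessArtifacts
    out_dir: Path | None = None


def _stage(manifest, name):
    manifest["stages"].append({"stage": name, "t": time.time()})
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; see the module docstring for the order."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "input_hashes": {},
        "config": config.effective_dict(),
    }
    try:
        cohorts = _load_cohorts(config, manifest)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage load_cohorts failed: {e}") from e

    # ----- training preprocessing, per cohort ---------------------------
    _stage(manifest, "preprocess_training")
    try:
        z_frames, train_rows = [], []
        for name in config.training_cohorts:
            df = cohorts[name]
            df_visit = _interpolate_if_configured(config, name, df)
            meas = df_visit[measure_columns(df_visit)]
            z, rec = standardize(meas, skew_threshold=config.skew_threshold)
            z, cov = adjust_covariates(
                z,
                df_visit["age"].to_numpy(float),
                df_visit["sex"].to_numpy(float),
            )
            z_frames.append(z)
            train_rows.append(df_visit)
            log.info("cohort %s: %d rows, %d measures", name, len(z), z.shape[1])
        z_train = pd.concat(z_frames, ignore_index=True)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage preprocess_training failed: {e}") from e

    # ----- collinearity merge + SOM ------------------------------------
    _stage(manifest, "merge_and_train_som")
    try:
        feature_set = merge_collinear(z_train, rho_threshold=config.rho_threshold)
        features_train = feature_set.apply(z_train)
        som = train_som(
            features_train,
            positions=ring_lattice(config.som_rings),
            epochs=config.som_epochs,
            seed=config.seed,
        )
        log.info(
            "SOM: %d districts, %d features, final QE %.4f",
            som.n_districts,
            features_train.shape[1],
            som.metadata["quantization_error"][-1],
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage merge_and_train_som failed: {e}") from e

    # ----- projection of the longitudinal cohort ------------------------
    _stage(manifest, "project_longitudinal")
    try:
        proj_df = cohorts[config.projection_cohort]
        visit = config.projection_visit or _median_visit(proj_df)
        rows = proj_df[proj_df["visit_id"] == visit]
        meas = rows[measure_columns(proj_df)]
        z_proj, rec_proj = standardize(meas, skew_threshold=config.skew_threshold)
        z_proj, cov_proj = adjust_covariates(
            z_proj,
            rows["age"].to_numpy(float),
            rows["sex"].to_numpy(float),
        )
        artifacts_proj = PreprocessArtifacts(rec_proj, cov_proj, feature_set)
        features_proj = feature_set.apply(z_proj)
        from .som import assign_bmu_batch

        assignments = pd.Series(
            assign_bmu_batch(som, features_proj.to_numpy()),
            index=rows["subject_id"].to_numpy(),
            name="district",
        )
        log.info("projected %d subjects at visit %s", len(assignments), visit)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage project_longitudinal failed: {e}") from e

    # ----- subgroup boundary (must precede trajectories) -----------------
    _stage(manifest, "subgroup_boundary")
    if config.boundary == "auto":
        occupancy = np.bincount(
            assignments.to_numpy(), minlength=som.n_districts
        ).astype(float)
        clusters = auto_partition(som, k=4, seed=config.seed, weights=occupancy)
        reference = pd.DataFrame(
            {
                "tg_chol_ratio": z_proj["tg_chol_ratio"].to_numpy(),
                "ldl_c": z_proj["ldl_c"].to_numpy(),
            }
        )
        boundary = label_partition(clusters, assignments, reference)
    else:
        bpath = Path(config.boundary)
        if not bpath.exists():
            raise BoundaryMissingError(
                f"subgroup boundary file {bpath} not found: the boundary must "
                "be fixed before trajectories are computed"
            )
        boundary = SubgroupBoundary.from_json(bpath)
    labels = assign_subgroups(assignments, boundary)
    manifest["boundary_fixed_before_trajectories"] = True
    manifest["subgroup_counts"] = labels.value_counts().to_dict()

    # ----- trajectories --------------------------------------------------
    _stage(manifest, "trajectories")
    try:
        measures = config.trajectory_measures or [
            m for m in ANCHORED_MEASURES if m in proj_df.columns
        ]
        pooled_meas = proj_df[measures]
        _, pooled_transform = standardize(
            pooled_meas, skew_threshold=config.skew_threshold
        )
        fits = {}
        slope_rows = []
        anova_rows = []
        subgroup_names = sorted(pd.unique(labels))
        rng = np.random.SeedSequence(config.seed)
        fit_seeds = iter(rng.generate_state(10 * len(measures) * 4) % (2**31))
        for m in measures:
            for g in subgroup_names:
                fit = fit_trajectory(
                    proj_df,
                    labels,
                    m,
                    g,
                    transform=pooled_transform,
                    n_boot=config.n_boot,
                    seed=int(next(fit_seeds)),
                )
                fits[(m, g)] = fit
                slope_rows.append(
                    {
                        "measure": m,
                        "subgroup": g,
                        "beta_age": fit.beta_age,
                        "ci_low": fit.ci_low,
                        "ci_high": fit.ci_high,
                        "n_subjects": fit.n_subjects,
                        "n_observations": fit.n_observations,
                    }
                )
            sa = slope_anova(
                proj_df, labels, m,
                n_perm=config.n_perm, seed=int(next(fit_seeds)),
                transform=pooled_transform,
            )
            ma = mean_anova(
                proj_df, labels, m,
                n_perm=config.n_perm, seed=int(next(fit_seeds)),
                transform=pooled_transform,
            )
            anova_rows.append(
                {
                    "measure": m,
                    "f_slope_divergence": sa.statistic,
                    "p_slope_divergence": sa.p_value,
                    "f_mean_difference": ma.statistic,
                    "p_mean_difference": ma.p_value,
                    "n_perm": config.n_perm,
                }
            )
        slope_table = pd.DataFrame(slope_rows)
        anova_table = pd.DataFrame(anova_rows)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage trajectories failed: {e}") from e

    # ----- multiplicity ---------------------------------------------------
    _stage(manifest, "multiplicity")
    mult = multiplicity_summary(
        z_train.to_numpy(), config.variance_target, config.alpha
    )
    anova_table["significant_divergence"] = (
        anova_table["p_slope_divergence"] < mult.threshold
    )
    anova_table["significant_means"] = (
        anova_table["p_mean_difference"] < mult.threshold
    )

    _stage(manifest, "write_outputs")
    result = PipelineResult(
        config=config,
        cohorts=cohorts,
        som=som,
        boundary=boundary,
        assignments=assignments,
        labels=labels,
        fits=fits,
        slope_table=slope_table,
        anova_table=anova_table,
        multiplicity=mult,
        pooled_transform=pooled_transform,
        manifest=manifest,
        artifacts_training=PreprocessArtifacts(rec_proj, cov_proj, feature_set),
    )
    if config.out_dir is not None:
        result.out_dir = _write_bundle(result, Path(config.out_dir))
    return result


def _load_cohorts(config: PipelineConfig, manifest) -> dict[str, pd.DataFrame]:
    _stage(manifest, "load_cohorts")
    cohorts: dict[str, pd.DataFrame] = {}
    if config.cohort_paths:
        for name, path in config.cohort_paths.items():
            cohorts[name] = read_cohort(path)
            manifest["input_hashes"][name] = _sha256_file(path)
    elif config.generator is not None:
        gen = config.generator
        if isinstance(gen, str) and gen == "calibrated":
            gen = paper_calibrated_config(seed=config.seed)
        if not isinstance(gen, GeneratorConfig):
            raise PipelineError(f"invalid generator spec: {config.generator!r}")
        for design in gen.cohort_designs:
            df = generate_cohort(gen, design.name)
            cohorts[design.name] = df
            manifest["input_hashes"][design.name] = _sha256_frame(df)
    else:
        raise PipelineError("config needs cohort_paths or a generator")
    needed = set(config.training_cohorts) | {config.projection_cohort}
    missing = needed - set(cohorts)
    if missing:
        raise PipelineError(f"cohorts not available: {sorted(missing)}")
    return cohorts


def _interpolate_if_configured(config, name, df):
    """Collapse a two-visit cohort to a single interpolated pseudo-visit."""
    interp = config.interpolation
    if not interp or interp.get("cohort") != name:
        return df
    visits = sorted(df["visit_id"].unique())
    if len(visits) != 2:
        raise PipelineError(
            f"interpolation of {name!r} needs exactly 2 visits, got {visits}"
        )
    early = df[df["visit_id"] == visits[0]].set_index("subject_id")
    late = df[df["visit_id"] == visits[1]].set_index("subject_id")
    shared = early.index.intersection(late.index)
    early, late = early.loc[shared], late.loc[shared]
    t_early = float(early["age"].mean())
    t_late = float(late["age"].mean())
    target = float(interp.get("target_age", 39.0))
    meas = measure_columns(df)
    w_e, w_l, x = interpolate_to_age(
        early[meas], late[meas], t_early, t_late, target
    )
    base = early.reset_index()
    data = {
        "cohort_id": base["cohort_id"].to_numpy(),
        "subject_id": base["subject_id"].to_numpy(),
        "visit_id": np.full(len(base), "interp"),
        "age": w_e * early["age"].to_numpy() + w_l * late["age"].to_numpy(),
        "sex": base["sex"].to_numpy(),
        "birth_year": base["birth_year"].to_numpy(),
    }
    data.update({c: x[c].to_numpy() for c in meas})
    out = pd.DataFrame(data)
    log.info(
        "interpolated %s to age %.0f with weights (%.2f, %.2f)",
        name, target, w_e, w_l,
    )
    return out


def _median_visit(df: pd.DataFrame) -> str:
    visits = sorted(df["visit_id"].unique())
    return visits[len(visits) // 2]


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_frame(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def _write_bundle(result: PipelineResult, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.som.to_json(out_dir / "som_model.json")
    result.boundary.to_json(out_dir / "boundary.json")
    result.assignments.rename_axis("subject_id").reset_index().to_csv(
        out_dir / "assignments.tsv", sep="\t", index=False
    )
    result.labels.rename_axis("subject_id").reset_index().to_csv(
        out_dir / "subgroups.tsv", sep="\t", index=False
    )
    with open(out_dir / "slopes.tsv", "w") as fh:
        fh.write("# beta_age in population SD per decade (standardized fits)\n")
        result.slope_table.to_csv(fh, sep="\t", index=False)
    result.anova_table.to_csv(out_dir / "anova.tsv", sep="\t", index=False)
    result.multiplicity.to_json(out_dir / "multiplicity.json")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(result.config.effective_dict(), fh, sort_keys=False)
    return out_dir


# ---------------------------------------------------------------------------
# convenience driver for the calibrated study
# ---------------------------------------------------------------------------

def run_calibrated_study(
    seed: int = 1,
    n_boot: int = 200,
    n_perm: int = 999,
    out_dir: str | None = None,
    trajectory_measures: list[str] | None = None,
) -> PipelineResult:
    """Run the full pipeline on the calibrated synthetic study.

    Uses the published cohort sizes (YFS-like n=1286, three visits) and
    the automatic boundary; reduced bootstrap/permutation counts keep
    the run in the minutes range on one CPU.
    """
    config = PipelineConfig(
        generator="calibrated",
        seed=seed,
        n_boot=n_boot,
        n_perm=n_perm,
        out_dir=out_dir,
        trajectory_measures=trajectory_measures,
    )
    return run_pipeline(config)
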