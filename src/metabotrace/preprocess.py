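"""Robust standardization, covariate adjustment and collinearity merging.

The three stages turn a raw measure table into SOM-ready features:

1. :func:`standardize` — empirical z-scores with protection from skewed
   distributions (log transform) and outliers (clamping), recorded in a
   :class:`TransformRecord` so the identical transform can be re-applied
   to new samples;
2. :func:`adjust_covariates` — per-cohort OLS residualization on age and
   sex, with stored coefficients for projection of new cohorts;
3. :func:`merge_collinear` — agglomerative merging of measures whose
   absolute Spearman correlation exceeds a threshold, producing a
   reduced, sign-aligned, re-standardized :class:`FeatureSet`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "TransformRecord",
    "CovariateModel",
    "FeatureSet",
    "standardize",
    "adjust_covariates",
    "merge_collinear",
    "PreprocessArtifacts",
]

CLIP_Z = 4.0  # clamp standardized values at +/- 4 SD


@dataclass
class ColumnTransform:
    name: str
    log_applied: bool
    shift: float
    center: float
    scale: float
    skew_before: float
    skew_after: float
    clip_low: float = -CLIP_Z
    clip_high: float = CLIP_Z
    dropped: bool = False


@dataclass
class TransformRecord:
    """Per-measure robust standardization parameters.

    Sufficient to re-apply the identical transform to new data: the
    stored shift/center/scale are used verbatim, never refitted.
    """

    columns: dict[str, ColumnTransform] = field(default_factory=dict)
    skew_threshold: float = 1.0

    @property
    def kept(self) -> list[str]:
        return [c for c, t in self.columns.items() if not t.dropped]

    def apply(self, df: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
        """Apply the stored transform to (new) raw data."""
        out = {}
        for name in (columns if columns is not None else self.kept):
            t = self.columns[name]
            if name not in df.columns:
                raise KeyError(f"column {name!r} absent from input")
            x = df[name].to_numpy(dtype=float)
            if t.log_applied:
                with np.errstate(invalid="ignore"):
                    x = np.log(x + t.shift)
            z = (x - t.center) / t.scale
            out[name] = np.clip(z, t.clip_low, t.clip_high)
        return pd.DataFrame(out, index=df.index)

    def apply_column(self, name: str, values: np.ndarray) -> np.ndarray:
        return self.apply(pd.DataFrame({name: values}), columns=[name])[name].to_numpy()

    def invert_column(self, name: str, z: np.ndarray) -> np.ndarray:
        """Map standardized values back to the raw scale (ignoring clamping)."""
        t = self.columns[name]
        x = np.asarray(z, dtype=float) * t.scale + t.center
        if t.log_applied:
            x = np.exp(x) - t.shift
        return x

    def to_json(self, path=None) -> str:
        payload = {
            "skew_threshold": self.skew_threshold,
            "columns": {k: vars(v) for k, v in self.columns.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TransformRecord":
        text = _read_maybe_path(text_or_path)
        payload = json.loads(text)
        rec = cls(skew_threshold=payload["skew_threshold"])
        rec.columns = {
            k: ColumnTransform(**v) for k, v in payload["columns"].items()
        }
        return rec


def standardize(
    df: pd.DataFrame, skew_threshold: float = 1.0
) -> tuple[pd.DataFrame, TransformRecord]:
    """Robust empirical z-scores with skew protection and outlier clamping.

    Columns with |sample skewness| above ``skew_threshold`` are shifted
    upward so their minimum is at least 1 and log-transformed before
    centering and scaling; standardized values are clamped at +/-4 SD.
    Constant columns are dropped with a warning.  Missing values are
    preserved as missing.
    """
    record = TransformRecord(skew_threshold=skew_threshold)
    out = {}
    for name in df.columns:
        x = df[name].to_numpy(dtype=float)
        finite = x[np.isfinite(x)]
        if finite.size == 0:
            raise ValueError(f"column {name!r} has no non-missing values")
        if finite.size < 3:
            raise ValueError(f"column {name!r} has fewer than 3 non-missing values")
        if float(finite.std(ddof=1)) < 1e-12:
            warnings.warn(f"dropping zero-variance column {name!r}")
            record.columns[name] = ColumnTransform(
                name, False, 0.0, float(finite.mean()), 1.0, 0.0, 0.0, dropped=True
            )
            continue
        skew_before = float(stats.skew(finite))
        log_applied = abs(skew_before) > skew_threshold
        shift = 0.0
        y = x
        if log_applied:
            shift = float(max(0.0, 1.0 - finite.min()))
            y = np.log(x + shift)
            if not np.all(np.isfinite(y[np.isfinite(x)])):
                raise ValueError(f"column {name!r} non-finite after log transform")
        yf = y[np.isfinite(y)]
        center = float(yf.mean())
        scale = float(yf.std(ddof=1))
        skew_after = float(stats.skew(yf)) if log_applied else skew_before
        if scale < 1e-12:
            warnings.warn(f"dropping zero-variance column {name!r}")
            record.columns[name] = ColumnTransform(
                name, log_applied, shift, center, 1.0, skew_before, skew_after,
                dropped=True,
            )
            continue
        record.columns[name] = ColumnTransform(
            name, log_applied, shift, center, scale, skew_before, skew_after
        )
        out[name] = np.clip((y - center) / scale, -CLIP_Z, CLIP_Z)
    return pd.DataFrame(out, index=df.index), record


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

@dataclass
class CohortFit:
    terms: list[str]
    coef: np.ndarray  # (n_terms, n_cols)
    resid_sd: np.ndarray  # (n_cols,)


@dataclass
class CovariateModel:
    """Stored age/sex regression coefficients, per cohort and column."""

    columns: list[str]
    fits: dict[str, CohortFit] = field(default_factory=dict)

    def apply(
        self,
        z: pd.DataFrame,
        age: np.ndarray,
        sex: np.ndarray,
        cohort: str = "__all__",
    ) -> pd.DataFrame:
        fit = self.fits[cohort]
        design = _design_matrix(np.asarray(age, float), np.asarray(sex, float),
                                fit.terms)
        vals = z[self.columns].to_numpy(dtype=float)
        resid = vals - design @ fit.coef
        resid = resid / fit.resid_sd
        return pd.DataFrame(resid, columns=self.columns, index=z.index)


def _design_matrix(age, sex, terms):
    cols = {"intercept": np.ones_like(age), "age": age, "sex": sex}
    return np.column_stack([cols[t] for t in terms])


def adjust_covariates(
    z: pd.DataFrame,
    age: np.ndarray,
    sex: np.ndarray,
    cohort: np.ndarray | None = None,
    per_cohort: bool = False,
) -> tuple[pd.DataFrame, CovariateModel]:
    """Residualize every column on (age, sex) and re-scale to unit SD.

    With ``per_cohort`` the regression is fitted within each cohort
    separately (batch mitigation).  A single-sex cohort drops the sex
    term with a warning.  Residual columns are exactly uncorrelated with
    the fitted covariates within cohort.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if np.isnan(age).any() or np.isnan(sex).any():
        raise ValueError("age and sex must be complete")
    model = CovariateModel(columns=list(z.columns))
    out = np.empty((len(z), z.shape[1]), dtype=float)
    if per_cohort:
        if cohort is None:
            raise ValueError("per_cohort=True requires a cohort vector")
        groups = pd.Series(np.asarray(cohort)).groupby(
            np.asarray(cohort), sort=True
        ).groups
    else:
        groups = {"__all__": np.arange(len(z))}

    dropped_cols: set[str] = set()
    for gname, idx in groups.items():
        idx = np.asarray(idx)
        a, s = age[idx], sex[idx]
        terms = ["intercept", "age", "sex"]
        if np.unique(s).size < 2:
            warnings.warn(f"cohort {gname!r} is single-sex; dropping sex term")
            terms = ["intercept", "age"]
        design = _design_matrix(a, s, terms)
        vals = z.iloc[idx].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(design, np.nan_to_num(vals), rcond=None)
        # refit columns with missing values individually to avoid bias
        nan_cols = np.flatnonzero(np.isnan(vals).any(axis=0))
        for j in nan_cols:
            ok = np.isfinite(vals[:, j])
            cj, *_ = np.linalg.lstsq(design[ok], vals[ok, j], rcond=None)
            coef[:, j] = cj
        resid = vals - design @ coef
        sd = np.nanstd(resid, axis=0, ddof=1)
        low = sd < 1e-12
        if low.any():
            for j in np.flatnonzero(low):
                dropped_cols.add(z.columns[j])
            sd = np.where(low, 1.0, sd)
        model.fits[str(gname)] = CohortFit(terms, coef, sd)
        out[idx] = resid / sd

    result = pd.DataFrame(out, columns=z.columns, index=z.index)
    if dropped_cols:
        warnings.warn(
            f"dropping zero-residual-variance columns: {sorted(dropped_cols)}"
        )
        keep = [c for c in z.columns if c not in dropped_cols]
        result = result[keep]
        model.columns = keep
        for fit in model.fits.values():
            mask = np.array([c in keep for c in z.columns])
            fit.coef = fit.coef[:, mask]
            fit.resid_sd = fit.resid_sd[mask]
    return result, model


# ---------------------------------------------------------------------------
# collinearity merging
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Merged non-redundant features with stored membership and signs."""

    feature_names: list[str]
    membership: list[list[str]]
    signs: list[list[float]]
    centers: np.ndarray
    scales: np.ndarray
    rho_threshold: float

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def apply(self, z: pd.DataFrame) -> pd.DataFrame:
        """Merge (new) standardized data using stored membership and signs."""
        out = {}
        for k, (fname, members, signs) in enumerate(
            zip(self.feature_names, self.membership, self.signs)
        ):
            vals = np.column_stack(
                [s * z[m].to_numpy(dtype=float) for m, s in zip(members, signs)]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                merged = np.nanmean(vals, axis=1)
            out[fname] = (merged - self.centers[k]) / self.scales[k]
        return pd.DataFrame(out, index=z.index)

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "membership": self.membership,
            "signs": self.signs,
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "rho_threshold": self.rho_threshold,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "FeatureSet":
        payload = json.loads(_read_maybe_path(text_or_path))
        return cls(
            feature_names=payload["feature_names"],
            membership=payload["membership"],
            signs=[[float(s) for s in row] for row in payload["signs"]],
            centers=np.asarray(payload["centers"], float),
            scales=np.asarray(payload["scales"], float),
            rho_threshold=payload["rho_threshold"],
        )


def merge_collinear(z: pd.DataFrame, rho_threshold: float = 0.8) -> FeatureSet:
    """Merge collinear measures by average-linkage on 1 - |Spearman rho|.

    Measure pairs with |rho| >= ``rho_threshold`` end up in the same
    merged feature; each feature is the sign-aligned mean of its member
    z-scores, re-standardized to unit SD.  The partition is invariant to
    column order; the sign convention is the majority orientation of the
    members (ties resolved by the first member in column order).
    """
    if not 0.0 < rho_threshold < 1.0:
        raise ValueError("rho_threshold must be in (0, 1)")
    if z.shape[1] < 2:
        raise ValueError("need at least 2 measures to merge")
    cols = list(z.columns)
    order = np.argsort(cols)  # canonical order for order-invariance
    cols_sorted = [cols[i] for i in order]
    vals = z[cols_sorted].to_numpy(dtype=float)

    rho = _spearman_matrix(vals)
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(link, t=1.0 - rho_threshold, criterion="distance")

    feature_names: list[str] = []
    membership: list[list[str]] = []
    signs_all: list[list[float]] = []
    centers, scales = [], []
    merged_cols = {}
    for lab in np.unique(labels):
        members_idx = np.flatnonzero(labels == lab)
        members = [cols_sorted[i] for i in members_idx]
        # keep members in original column order for determinism
        members = sorted(members, key=cols.index)
        midx = [cols_sorted.index(m) for m in members]
        if len(members) == 1:
            signs = [1.0]
        else:
            sub = rho[np.ix_(midx, midx)]
            ref = int(np.argmax(np.nansum(np.abs(sub), axis=1)))
            signs = [float(np.sign(sub[ref, j]) or 1.0) for j in range(len(members))]
            # canonical overall sign: majority of members enter positively
            pos = sum(s > 0 for s in signs)
            neg = len(signs) - pos
            if neg > pos or (neg == pos and signs[0] < 0):
                signs = [-s for s in signs]
        stacked = np.column_stack(
            [s * z[m].to_numpy(dtype=float) for m, s in zip(members, signs)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            merged = np.nanmean(stacked, axis=1)
        ok = np.isfinite(merged)
        center = float(merged[ok].mean())
        scale = float(merged[ok].std(ddof=1))
        if scale < 1e-12:
            scale = 1.0
        name = members[0] if len(members) == 1 else members[0] + "_merged"
        feature_names.append(name)
        membership.append(members)
        signs_all.append(signs)
        centers.append(center)
        scales.append(scale)
        merged_cols[name] = (merged - center) / scale

    # deterministic feature order: by first member's original column position
    order_feat = np.argsort([cols.index(m[0]) for m in membership])
    return FeatureSet(
        feature_names=[feature_names[i] for i in order_feat],
        membership=[membership[i] for i in order_feat],
        signs=[signs_all[i] for i in order_feat],
        centers=np.asarray(centers, float)[order_feat],
        scales=np.asarray(scales, float)[order_feat],
        rho_threshold=rho_threshold,
    )


def _spearman_matrix(vals: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlations (rank + Pearson; NaNs rank-midded)."""
    ranks = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        r = stats.rankdata(col, nan_policy="omit")
        # replace missing ranks by the mean rank so they are correlation-neutral
        nan = np.isnan(col)
        if nan.any():
            r[nan] = np.nanmean(r[~nan])
        ranks[:, j] = r
    return np.corrcoef(ranks, rowvar=False)


# ---------------------------------------------------------------------------
# bundled artifacts for projection of new cohorts
# ---------------------------------------------------------------------------

@dataclass
class PreprocessArtifacts:
    """Everything needed to map raw new-sample data into SOM feature space.

    Application order: robust transform -> covariate adjustment with the
    stored coefficients -> collinearity merge with the stored membership
    and signs.
    """

    transform: TransformRecord
    covariates: CovariateModel
    features: FeatureSet

    def apply(
        self,
        df: pd.DataFrame,
        age: np.ndarray,
        sex: np.ndarray,
        cohort: str = "__all__",
    ) -> pd.DataFrame:
        z = self.transform.apply(df)
        z = self.covariates.apply(z, age, sex, cohort=cohort)
        return self.features.apply(z)


def _read_maybe_path(text_or_path) -> str:
    text = str(text_or_path)
    if not text.lstrip().startswith("{"):
        with open(text_or_path) as fh:
            return fh.read()
    return text
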