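"""Subgroup-specific longitudinal trajectory modelling.

Linear models of a (standardized) metabolic measure on chronological age
with birth year as a covariate, fitted separately per metabolic
subgroup over all visits of a longitudinal cohort.  Age is centred at 24
years and expressed in decades, so the intercept is the expected value
at age 24 and the age coefficient ``beta_age`` is the rate of change in
population standard deviations per decade (or natural units per decade
when unstandardized).

Confidence intervals use a subject-level (cluster) bootstrap: whole
subjects with all their visits are resampled, respecting the
within-subject correlation of repeated measures.  Between-subgroup
heterogeneity is tested by permutation ANOVA, permuting subgroup labels
at the subject level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import TransformRecord, standardize

__all__ = [
    "interpolate_to_age",
    "TrajectoryFit",
    "fit_trajectory",
    "AnovaResult",
    "slope_anova",
    "mean_anova",
    "trajectory_curves",
    "adjusted_pair",
]

AGE_CENTER = 24.0
DECADE = 10.0


def interpolate_to_age(x_early, x_late, t_early: float, t_late: float,
                       t_target: float):
    """Linear interpolation of two visits to a target age.

    Returns ``(w_early, w_late, x_interp)`` with
    ``w_early = (t_late - t_target) / (t_late - t_early)`` and
    elementwise missing propagation.  For visits at ages 31 and 46
    interpolated to 39 the weights are (7/15, 8/15), i.e. 0.47/0.53 to
    two decimals.
    """
    if not t_early < t_late:
        raise ValueError("t_early must be < t_late")
    if not (t_early <= t_target <= t_late):
        raise ValueError(
            f"t_target {t_target} outside [{t_early}, {t_late}] (no extrapolation)"
        )
    w_early = (t_late - t_target) / (t_late - t_early)
    w_late = 1.0 - w_early
    x_interp = None
    if x_early is not None and x_late is not None:
        x_interp = w_early * np.asarray(x_early, float) + w_late * np.asarray(
            x_late, float
        )
        if isinstance(x_early, pd.DataFrame):
            x_interp = pd.DataFrame(
                x_interp, columns=x_early.columns, index=x_early.index
            )
    return w_early, w_late, x_interp


# ---------------------------------------------------------------------------
# trajectory fits
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFit:
    measure: str
    subgroup: str
    beta_age: float
    intercept: float
    covariates: dict
    ci_low: float
    ci_high: float
    n_subjects: int
    n_observations: int
    standardized: bool
    boot: np.ndarray = field(repr=False, default=None)  # (n_boot, 2): intercept, beta
    transform: TransformRecord | None = field(repr=False, default=None)


def _labels_per_subject(cohort: pd.DataFrame, labels) -> pd.Series:
    """Normalize labels to a subject_id -> label mapping."""
    if isinstance(labels, dict):
        return pd.Series(labels)
    labels = pd.Series(labels)
    if labels.index.dtype == object and set(labels.index) & set(
        cohort["subject_id"]
    ):
        return labels
    subjects = cohort["subject_id"].drop_duplicates().reset_index(drop=True)
    if len(labels) == len(subjects):
        return pd.Series(labels.to_numpy(), index=subjects.to_numpy())
    if len(labels) == len(cohort):
        per = pd.DataFrame(
            {"subject_id": cohort["subject_id"].to_numpy(), "label": labels.to_numpy()}
        ).drop_duplicates("subject_id")
        return pd.Series(per["label"].to_numpy(), index=per["subject_id"].to_numpy())
    raise ValueError("labels length matches neither subjects nor rows")


def _subject_row_groups(subject_ids: np.ndarray) -> list[np.ndarray]:
    """Row indices per subject (each array holds all visits of one subject)."""
    uniq, inverse = np.unique(subject_ids, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    counts = np.bincount(inverse, minlength=uniq.size)
    return np.split(order, np.cumsum(counts)[:-1])


def _cluster_resample(subject_ids: np.ndarray, rng: np.random.Generator):
    """Bootstrap resample of whole subjects; returns row indices.

    Every resample contains complete subjects only — all visits of a
    drawn subject enter together (drawn k times -> visits appear k times).
    """
    groups = _subject_row_groups(subject_ids)
    draw = rng.integers(0, len(groups), size=len(groups))
    return np.concatenate([groups[i] for i in draw])


def fit_trajectory(
    cohort: pd.DataFrame,
    labels,
    measure: str,
    subgroup: str,
    standardize_measure: bool = True,
    transform: TransformRecord | None = None,
    adjust_for: str | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> TrajectoryFit:
    """OLS trajectory of one measure within one subgroup.

    Model: y ~ 1 + (age-24)/10 + centred birth year [+ centred
    adjustment measure], pooling all visits of the subgroup's subjects.
    When ``standardize_measure`` the measure is passed through the robust
    transform fitted on the *whole* cohort (all subgroups, all visits) —
    or through a supplied ``transform`` — so slopes are in population SD
    per decade.  CIs are percentile cluster-bootstrap over subjects
    (``n_boot=0`` skips the bootstrap).
    """
    per_subject = _labels_per_subject(cohort, labels)
    members = per_subject.index[per_subject.to_numpy() == subgroup]
    rows = cohort[cohort["subject_id"].isin(set(members))].copy()
    if rows.empty:
        raise ValueError(f"subgroup {subgroup!r} is empty")

    if standardize_measure:
        if transform is None:
            _, transform = standardize(cohort[[measure]])
        y_all = transform.apply_column(measure, rows[measure].to_numpy(float))
    else:
        y_all = rows[measure].to_numpy(dtype=float)

    d = (rows["age"].to_numpy(float) - AGE_CENTER) / DECADE
    by = rows["birth_year"].to_numpy(float)
    by = by - by.mean()
    design_cols = [np.ones_like(d), d, by]
    names = ["intercept", "age_decades", "birth_year_centred"]
    if adjust_for is not None:
        adj = rows[adjust_for].to_numpy(dtype=float)
        adj = adj - np.nanmean(adj)
        design_cols.append(adj)
        names.append(f"adjusted_{adjust_for}")
    X = np.column_stack(design_cols)

    ok = np.isfinite(y_all) & np.all(np.isfinite(X), axis=1)
    X, y = X[ok], y_all[ok]
    subj = rows["subject_id"].to_numpy()[ok]
    if np.unique(d[ok]).size < 2:
        raise ValueError(f"subgroup {subgroup!r} has a single distinct age")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    n_subjects = int(np.unique(subj).size)

    boot = None
    ci_low = ci_high = float(coef[1])
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        groups = _subject_row_groups(subj)
        boot = np.empty((n_boot, 2))
        for b in range(n_boot):
            draw = rng.integers(0, len(groups), size=len(groups))
            idx = np.concatenate([groups[i] for i in draw])
            cb, *_ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
            boot[b] = (cb[0], cb[1])
        ci_low, ci_high = np.percentile(boot[:, 1], [2.5, 97.5])

    return TrajectoryFit(
        measure=measure,
        subgroup=subgroup,
        beta_age=float(coef[1]),
        intercept=float(coef[0]),
        covariates=dict(zip(names[2:], [float(c) for c in coef[2:]])),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_subjects=n_subjects,
        n_observations=int(y.size),
        standardized=standardize_measure,
        boot=boot,
        transform=transform if standardize_measure else None,
    )


# ---------------------------------------------------------------------------
# permutation ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    measure: str
    statistic: float
    p_value: float
    n_perm: int
    kind: str


def _prepare_anova(cohort, labels, measure, transform):
    per_subject = _labels_per_subject(cohort, labels)
    rows = cohort[cohort["subject_id"].isin(set(per_subject.index))].copy()
    if transform is None:
        _, transform = standardize(cohort[[measure]])
    y = transform.apply_column(measure, rows[measure].to_numpy(float))
    d = (rows["age"].to_numpy(float) - AGE_CENTER) / DECADE
    by = rows["birth_year"].to_numpy(float)
    by = by - by.mean()
    subj = rows["subject_id"].to_numpy()
    ok = np.isfinite(y)
    y, d, by, subj = y[ok], d[ok], by[ok], subj[ok]
    uniq_subj, inverse = np.unique(subj, return_inverse=True)
    subj_labels = per_subject.loc[uniq_subj].to_numpy()
    groups = np.unique(subj_labels)
    if groups.size < 2:
        raise ValueError("need at least 2 subgroups")
    return y, d, by, inverse, subj_labels, groups, transform


def _interaction_f(y, d, by, group_idx, n_groups):
    """F statistic of per-subgroup slopes vs a common slope."""
    n = y.size
    dummies = np.zeros((n, n_groups))
    dummies[np.arange(n), group_idx] = 1.0
    x_reduced = np.column_stack([dummies, d, by])
    x_full = np.column_stack([dummies, dummies * d[:, None], by])
    rss_r = _rss(x_reduced, y)
    rss_f = _rss(x_full, y)
    df1 = n_groups - 1
    df2 = n - x_full.shape[1]
    if rss_f <= 0:
        return np.inf
    return ((rss_r - rss_f) / df1) / (rss_f / df2)


def _rss(x, y):
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ coef
    return float(r @ r)


def slope_anova(
    cohort: pd.DataFrame,
    labels,
    measure: str,
    n_perm: int = 9999,
    seed: int = 0,
    transform: TransformRecord | None = None,
) -> AnovaResult:
    """Permutation ANOVA for between-subgroup slope divergence.

    The statistic is the F of the subgroup-by-age interaction (full
    model with per-subgroup intercepts and slopes vs common-slope
    model, birth year as covariate).  The null distribution permutes
    subgroup labels at the subject level — all of a subject's visits
    move together — and p follows the add-one rule.
    """
    y, d, by, inverse, subj_labels, groups, _ = _prepare_anova(
        cohort, labels, measure, transform
    )
    gmap = {g: i for i, g in enumerate(groups)}
    subj_idx = np.array([gmap[g] for g in subj_labels])
    obs = _interaction_f(y, d, by, subj_idx[inverse], groups.size)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(subj_idx)
        f = _interaction_f(y, d, by, perm[inverse], groups.size)
        if f >= obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AnovaResult(measure, float(obs), float(p), n_perm, "slope_divergence")


def mean_anova(
    cohort: pd.DataFrame,
    labels,
    measure: str,
    n_perm: int = 9999,
    seed: int = 0,
    transform: TransformRecord | None = None,
) -> AnovaResult:
    """Permutation one-way ANOVA on unadjusted subject-mean values."""
    y, d, by, inverse, subj_labels, groups, _ = _prepare_anova(
        cohort, labels, measure, transform
    )
    n_subj = subj_labels.size
    sums = np.bincount(inverse, weights=y, minlength=n_subj)
    counts = np.bincount(inverse, minlength=n_subj)
    subj_means = sums / counts
    gmap = {g: i for i, g in enumerate(groups)}
    subj_idx = np.array([gmap[g] for g in subj_labels])

    def one_way_f(gidx):
        grand = subj_means.mean()
        ssb = ssw = 0.0
        for k in range(groups.size):
            vals = subj_means[gidx == k]
            if vals.size == 0:
                return np.nan
            ssb += vals.size * (vals.mean() - grand) ** 2
            ssw += ((vals - vals.mean()) ** 2).sum()
        df1 = groups.size - 1
        df2 = n_subj - groups.size
        if ssw <= 0:
            return np.inf
        return (ssb / df1) / (ssw / df2)

    obs = one_way_f(subj_idx)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if one_way_f(rng.permutation(subj_idx)) >= obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AnovaResult(measure, float(obs), float(p), n_perm, "mean_difference")


# ---------------------------------------------------------------------------
# curves and mutual adjustment
# ---------------------------------------------------------------------------

def trajectory_curves(
    fit: TrajectoryFit,
    ages: np.ndarray | None = None,
    natural: bool = False,
) -> pd.DataFrame:
    """Model-predicted curve with a bootstrap CI band, covariates at zero.

    Columns: age, yhat, lo, hi.  With ``natural`` (requires a stored
    transform on a standardized fit) predictions are mapped back to the
    measure's raw scale.
    """
    if ages is None:
        ages = np.linspace(24.0, 49.0, 26)
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("empty age grid")
    d = (ages - AGE_CENTER) / DECADE
    yhat = fit.intercept + fit.beta_age * d
    if fit.boot is not None and len(fit.boot):
        preds = fit.boot[:, [0]] + fit.boot[:, [1]] * d[None, :]
        lo, hi = np.percentile(preds, [2.5, 97.5], axis=0)
        lo = np.minimum(lo, yhat)
        hi = np.maximum(hi, yhat)
    else:
        lo = hi = yhat
    out = pd.DataFrame({"age": ages, "yhat": yhat, "lo": lo, "hi": hi})
    if natural:
        if fit.transform is None:
            raise ValueError("natural-scale curve requires a standardized fit")
        for col in ("yhat", "lo", "hi"):
            out[col] = fit.transform.invert_column(fit.measure, out[col].to_numpy())
    return out


def adjusted_pair(
    cohort: pd.DataFrame,
    labels,
    measure: str,
    adjust_for: str,
    subgroups: list[str] | None = None,
    n_boot: int = 500,
    seed: int = 0,
    transform: TransformRecord | None = None,
) -> pd.DataFrame:
    """Per-subgroup fits of ``measure`` with and without mutual adjustment.

    Returns a table (subgroup, beta_unadjusted, beta_adjusted, CIs)
    enabling the attenuation contrast: a divergence pattern driven by a
    shared latent reverts towards a common slope once adjusted for the
    collinear measure, whereas a genuine progression pattern is
    unaffected.
    """
    per_subject = _labels_per_subject(cohort, labels)
    if subgroups is None:
        subgroups = sorted(pd.unique(per_subject))
    rows = []
    for i, g in enumerate(subgroups):
        un = fit_trajectory(
            cohort, labels, measure, g, transform=transform,
            n_boot=n_boot, seed=seed + i,
        )
        ad = fit_trajectory(
            cohort, labels, measure, g, transform=transform,
            adjust_for=adjust_for, n_boot=n_boot, seed=seed + i,
        )
        rows.append(
            {
                "subgroup": g,
                "beta_unadjusted": un.beta_age,
                "ci_low_unadjusted": un.ci_low,
                "ci_high_unadjusted": un.ci_high,
                "beta_adjusted": ad.beta_age,
                "ci_low_adjusted": ad.ci_low,
                "ci_high_adjusted": ad.ci_high,
                "n_subjects": un.n_subjects,
            }
        )
    return pd.DataFrame(rows)
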