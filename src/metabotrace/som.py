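"""Batch Kohonen self-organizing map on a round, ring-structured lattice.

The map is a 2-D lattice of *districts*, each carrying a prototype
vector in feature space.  Subjects are placed on the map by
best-matching-unit (BMU) assignment: the district whose prototype is
nearest in Euclidean distance.  Training uses the deterministic batch
algorithm with a Gaussian neighborhood whose radius shrinks linearly
over the epochs, so the per-epoch quantization error is recorded and
non-increasing.

District *colorings* summarize any per-subject value as district means;
their statistical robustness is assessed by permutation (shuffling the
values across subjects while keeping the map positions fixed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ring_lattice",
    "SOMModel",
    "train_som",
    "assign_bmu",
    "project_cohort",
    "district_coloring",
    "coloring_robustness",
]


def ring_lattice(n_rings: int = 5) -> np.ndarray:
    """Hexagonal concentric-ring lattice positions.

    Ring 0 is the single centre district; ring k (radius k) carries 6k
    districts at equal angles.  ``n_rings=5`` gives 91 districts.
    """
    pos = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        m = 6 * k
        ang = 2.0 * np.pi * np.arange(m) / m
        pos.extend(zip(k * np.cos(ang), k * np.sin(ang)))
    return np.asarray(pos, dtype=float)


def rect_lattice(nx: int, ny: int) -> np.ndarray:
    """Rectangular grid lattice (available via configuration)."""
    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    return np.column_stack([xs.ravel(), ys.ravel()])


@dataclass
class SOMModel:
    """Trained map: lattice positions, prototypes and training metadata."""

    positions: np.ndarray  # (n_districts, 2)
    prototypes: np.ndarray  # (n_districts, n_features)
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def n_districts(self) -> int:
        return self.positions.shape[0]

    def lattice_neighbors(self, max_dist: float = 1.2) -> list[np.ndarray]:
        d = cdist(self.positions, self.positions)
        return [
            np.flatnonzero((d[i] > 0) & (d[i] <= max_dist))
            for i in range(self.n_districts)
        ]

    def to_json(self, path=None) -> str:
        payload = {
            "positions": [[repr(float(v)) for v in row] for row in self.positions],
            "prototypes": [[repr(float(v)) for v in row] for row in self.prototypes],
            "feature_names": self.feature_names,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SOMModel":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text_or_path) as fh:
                text = fh.read()
        payload = json.loads(text)
        return cls(
            positions=np.array(
                [[float(v) for v in row] for row in payload["positions"]]
            ),
            prototypes=np.array(
                [[float(v) for v in row] for row in payload["prototypes"]]
            ),
            feature_names=payload["feature_names"],
            metadata=payload["metadata"],
        )


def train_som(
    features,
    positions: np.ndarray | None = None,
    epochs: int = 50,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> SOMModel:
    """Train a batch Kohonen map.

    ``features`` is a DataFrame (subjects x features) or array; missing
    values are column-mean imputed before training.  Prototypes are
    initialized from distinct random data rows (or an explicit ``init``
    matrix).  The Gaussian neighborhood radius shrinks linearly from
    half the lattice radius to 0.5 over the epochs.  Deterministic given
    the seed; per-epoch quantization error (mean squared distance to the
    BMU) is recorded in the metadata and is non-increasing.
    """
    if isinstance(features, pd.DataFrame):
        names = [str(c) for c in features.columns]
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"f{j}" for j in range(x.shape[1])]
    if positions is None:
        positions = ring_lattice(5)
    n_d = positions.shape[0]
    n, p = x.shape
    if n < n_d:
        raise ValueError(f"fewer subjects ({n}) than districts ({n_d})")

    # column-mean imputation
    col_means = np.nanmean(x, axis=0)
    if np.isnan(col_means).any():
        raise ValueError("feature with all values missing")
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x = np.where(nan_mask, col_means[None, :], x)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in training features")

    rng = np.random.default_rng(seed)
    if init is None:
        # sample distinct profiles where possible so duplicated rows do
        # not collapse several prototypes onto one point
        uniq = np.unique(x, axis=0)
        if uniq.shape[0] >= n_d:
            rows = rng.choice(uniq.shape[0], size=n_d, replace=False)
            prototypes = uniq[rows].copy()
        else:
            rows = rng.choice(n, size=n_d, replace=False)
            prototypes = x[rows].copy()
    else:
        prototypes = np.array(init, dtype=float, copy=True)
        if prototypes.shape != (n_d, p):
            raise ValueError("init shape mismatch")

    lattice_d2 = cdist(positions, positions) ** 2
    radius_max = float(np.max(positions[:, 0] ** 2 + positions[:, 1] ** 2)) ** 0.5
    sigma_final = 0.05  # sharp end phase: the last epochs are pure Lloyd steps
    qe = []
    for t in range(epochs):
        frac = t / max(epochs - 1, 1)
        sigma = radius_max / 2.0 + (sigma_final - radius_max / 2.0) * frac
        d2 = cdist(x, prototypes, "sqeuclidean")
        bmu = np.argmin(d2, axis=1)
        qe_t = float(d2[np.arange(n), bmu].mean())
        h = np.exp(-lattice_d2 / (2.0 * sigma**2))  # (n_d, n_d)
        w = h[bmu]  # (n, n_d): weight of each subject for each district
        denom = w.sum(axis=0)
        new_prot = np.where(
            (denom > 1e-300)[:, None],
            (w.T @ x) / np.maximum(denom, 1e-300)[:, None],
            prototypes,  # districts with no weight keep their prototype
        )
        # accept the update only if it does not increase quantization error
        d2_new = cdist(x, new_prot, "sqeuclidean")
        qe_new = float(d2_new.min(axis=1).mean())
        if qe_new <= qe_t + 1e-12:
            prototypes = new_prot
            qe.append(qe_new)
        else:
            qe.append(qe_t)
    model = SOMModel(
        positions=np.asarray(positions, float),
        prototypes=prototypes,
        feature_names=names,
        metadata={
            "epochs": epochs,
            "seed": seed,
            "neighborhood": "gaussian",
            "radius_schedule": [radius_max / 2.0, sigma_final],
            "quantization_error": qe,
            "init": "data_rows" if init is None else "explicit",
        },
    )
    return model


def assign_bmu(model: SOMModel, profile: np.ndarray) -> int:
    """Best-matching district for one profile (mask-aware distance).

    Distance is Euclidean over the non-missing entries; ties break to
    the lowest district id.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (model.prototypes.shape[1],):
        raise ValueError(
            f"profile length {profile.size} != feature count "
            f"{model.prototypes.shape[1]}"
        )
    ok = np.isfinite(profile)
    if not ok.any():
        raise ValueError("profile has no non-missing entries")
    diff = model.prototypes[:, ok] - profile[ok][None, :]
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def assign_bmu_batch(model: SOMModel, profiles: np.ndarray) -> np.ndarray:
    """Vectorized BMU assignment; rows with missing entries fall back to
    the mask-aware single-profile path."""
    profiles = np.asarray(profiles, dtype=float)
    full = np.all(np.isfinite(profiles), axis=1)
    out = np.empty(profiles.shape[0], dtype=int)
    if full.any():
        d2 = cdist(profiles[full], model.prototypes, "sqeuclidean")
        out[full] = np.argmin(d2, axis=1)
    for i in np.flatnonzero(~full):
        out[i] = assign_bmu(model, profiles[i])
    return out


def project_cohort(
    model: SOMModel,
    artifacts,
    cohort: pd.DataFrame,
    visit_id: str,
    cohort_key: str = "__all__",
) -> pd.Series:
    """Place a cohort on the map using one designated visit.

    Applies the stored preprocessing artifacts (transform, covariate
    coefficients, feature merge) to the rows of ``visit_id`` and assigns
    each subject a district; other visits are untouched.  Returns a
    Series of district ids indexed by subject_id.
    """
    from .synthetic import measure_columns

    rows = cohort[cohort["visit_id"] == visit_id]
    if rows.empty:
        raise ValueError(f"visit {visit_id!r} absent from cohort")
    feats = artifacts.apply(
        rows[measure_columns(cohort)],
        rows["age"].to_numpy(float),
        rows["sex"].to_numpy(float),
        cohort=cohort_key,
    )
    if list(feats.columns) != list(model.feature_names):
        raise ValueError("projected features do not match the trained map")
    districts = assign_bmu_batch(model, feats.to_numpy())
    return pd.Series(districts, index=rows["subject_id"].to_numpy(), name="district")


# ---------------------------------------------------------------------------
# colorings
# ---------------------------------------------------------------------------

def district_coloring(
    model: SOMModel, assignments: np.ndarray, values: np.ndarray
) -> pd.DataFrame:
    """Mean of ``values`` per district.

    Missing values are excluded per district.  Empty districts are
    flagged with ``occupancy`` 0 and NaN mean.  The occupancy-weighted
    mean of district means equals the overall mean exactly (up to float
    tolerance) because no spatial smoothing is applied.
    """
    assignments = np.asarray(assignments)
    values = np.asarray(values, dtype=float)
    if assignments.shape[0] != values.shape[0]:
        raise ValueError("assignments and values length mismatch")
    n_d = model.n_districts
    ok = np.isfinite(values)
    occupancy = np.bincount(assignments, minlength=n_d)
    counts = np.bincount(assignments[ok], minlength=n_d)
    sums = np.bincount(assignments[ok], weights=values[ok], minlength=n_d)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "district": np.arange(n_d),
            "x": model.positions[:, 0],
            "y": model.positions[:, 1],
            "occupancy": occupancy,
            "n_values": counts,
            "mean": means,
        }
    )


def coloring_robustness(
    model: SOMModel,
    assignments: np.ndarray,
    values: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation robustness of a district coloring.

    Values are shuffled across subjects (assignments fixed); for each
    district the robustness z is (observed mean - permutation mean) /
    permutation SD, and the two-sided p follows the add-one rule on the
    permutation-centred statistic.  Empty districts carry NaN z and p.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    base = district_coloring(model, assignments, values)
    assignments = np.asarray(assignments)
    values = np.asarray(values, dtype=float)
    n_d = model.n_districts
    ok = np.isfinite(values)
    a, v = assignments[ok], values[ok]
    counts = np.bincount(a, minlength=n_d).astype(float)
    rng = np.random.default_rng(seed)
    perm_means = np.empty((n_perm, n_d))
    for b in range(n_perm):
        pv = rng.permutation(v)
        sums = np.bincount(a, weights=pv, minlength=n_d)
        with np.errstate(invalid="ignore"):
            perm_means[b] = sums / counts
    mu = np.nanmean(perm_means, axis=0)
    sd = np.nanstd(perm_means, axis=0, ddof=1)
    obs = base["mean"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mu) / sd
        exceed = (np.abs(perm_means - mu[None, :]) >= np.abs(obs - mu)[None, :]).sum(
            axis=0
        )
    p = (1.0 + exceed) / (n_perm + 1.0)
    empty = counts == 0
    z[empty] = np.nan
    p[empty] = np.nan
    out = base.copy()
    out["z"] = z
    out["p"] = p
    return out
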