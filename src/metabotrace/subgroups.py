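"""Metabolic subgroups: map partitioning, labelling, profiles, prediction.

The published subgroups were drawn on the map by a human committee; here
the committee step is emulated by (a) a user-supplied boundary file
(district -> label JSON) or (b) :func:`auto_partition` — k-means on the
prototype vectors with a spatial-contiguity repair — combined with
:func:`label_partition`, which names the regions by their biochemical
signature the way the committee did: the region richest in
triglyceride-to-cholesterol ratio is TG-rich, the poorest is TG-poor,
and of the remaining two the one with higher LDL cholesterol is High
LDL-C, the other Low lipid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .som import SOMModel

__all__ = [
    "SubgroupBoundary",
    "assign_subgroups",
    "auto_partition",
    "label_partition",
    "subgroup_profiles",
    "predict_subgroups",
    "PredictionResult",
]


@dataclass
class SubgroupBoundary:
    """District -> subgroup-label mapping with provenance."""

    mapping: dict[int, str]
    provenance: str = "committee file"

    def __post_init__(self) -> None:
        self.mapping = {int(k): str(v) for k, v in self.mapping.items()}
        labels = set(self.mapping.values())
        if len(labels) > 4:
            raise ValueError(f"more than 4 subgroup labels: {sorted(labels)}")
        if len(labels) < 4:
            import warnings

            warnings.warn(f"boundary uses only {len(labels)} labels")

    def to_json(self, path=None) -> str:
        payload = {
            "provenance": self.provenance,
            "mapping": {str(k): v for k, v in self.mapping.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SubgroupBoundary":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text_or_path) as fh:
                text = fh.read()
        payload = json.loads(text)
        if "mapping" in payload:
            return cls(payload["mapping"], payload.get("provenance", "file"))
        return cls(payload, "file")


def assign_subgroups(assignments, boundary: SubgroupBoundary) -> pd.Series:
    """Map district assignments to subgroup labels (pure function)."""
    if isinstance(assignments, pd.Series):
        index = assignments.index
        districts = assignments.to_numpy()
    else:
        districts = np.asarray(assignments)
        index = pd.RangeIndex(len(districts))
    unmapped = sorted({int(d) for d in districts} - set(boundary.mapping))
    if unmapped:
        raise KeyError(f"districts without a subgroup label: {unmapped}")
    labels = np.array([boundary.mapping[int(d)] for d in districts])
    return pd.Series(labels, index=index, name="subgroup")


# ---------------------------------------------------------------------------
# automatic partition (test stand-in for the committee)
# ---------------------------------------------------------------------------

def auto_partition(
    model: SOMModel,
    k: int = 4,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """K-means on prototypes with spatial-contiguity repair.

    Returns a cluster id per district.  ``weights`` (optional, one per
    district) weight the prototypes in the k-means objective — passing
    the projected cohort's district occupancy focuses the partition on
    the region of the map where that population actually lives, the way
    the committee drew boundaries from colorings of the projected
    participants.  After repair every cluster is a lattice-connected
    region: disconnected fragments (all but the largest component of
    each cluster) are absorbed, district by district, into the majority
    cluster of their lattice neighbors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > model.n_districts:
        raise ValueError("k exceeds the number of districts")
    if k == 1:
        return np.zeros(model.n_districts, dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    sw = None
    if weights is not None:
        sw = np.asarray(weights, dtype=float)
        if sw.shape != (model.n_districts,):
            raise ValueError("weights must have one entry per district")
        sw = sw + 1e-3 * max(sw.max(), 1.0)  # keep empty districts assignable
    clusters = km.fit_predict(model.prototypes, sample_weight=sw)
    neighbors = model.lattice_neighbors()

    def components(lab):
        comp = -np.ones(model.n_districts, dtype=int)
        cid = 0
        for start in range(model.n_districts):
            if comp[start] >= 0:
                continue
            stack = [start]
            comp[start] = cid
            while stack:
                i = stack.pop()
                for j in neighbors[i]:
                    if comp[j] < 0 and lab[j] == lab[i]:
                        comp[j] = cid
                        stack.append(j)
            cid += 1
        return comp

    for _ in range(model.n_districts):
        comp = components(clusters)
        # size of each component and the largest component per cluster
        comp_sizes = np.bincount(comp)
        main = {}
        for c in np.unique(clusters):
            comps_c = np.unique(comp[clusters == c])
            main[c] = comps_c[np.argmax(comp_sizes[comps_c])]
        frag = np.array(
            [comp[i] != main[clusters[i]] for i in range(model.n_districts)]
        )
        if not frag.any():
            break
        changed = False
        for i in np.flatnonzero(frag):
            neigh_lab = clusters[neighbors[i]]
            outside = neigh_lab[neigh_lab != clusters[i]]
            if outside.size:
                vals, counts = np.unique(outside, return_counts=True)
                clusters[i] = vals[np.argmax(counts)]
                changed = True
        if not changed:
            break
    return clusters


def label_partition(
    clusters: np.ndarray,
    assignments,
    reference: pd.DataFrame,
    tg_col: str = "tg_chol_ratio",
    ldl_col: str = "ldl_c",
) -> SubgroupBoundary:
    """Name the partition's regions by their biochemical signature.

    ``reference`` holds per-subject values of the triglyceride-
    cholesterol ratio and LDL cholesterol for the subjects behind
    ``assignments`` (district per subject).  Region means decide:
    highest TG/cholesterol -> TG-rich, lowest -> TG-poor, then higher
    LDL-C of the remaining two -> High LDL-C, the last -> Low lipid.
    """
    districts = (
        assignments.to_numpy() if isinstance(assignments, pd.Series) else np.asarray(assignments)
    )
    region_of_subject = clusters[districts]
    regions = np.unique(clusters)
    if regions.size != 4:
        raise ValueError(f"labelling rule needs 4 regions, got {regions.size}")

    def region_mean(col):
        vals = reference[col].to_numpy(dtype=float)
        return {
            r: np.nanmean(vals[region_of_subject == r]) for r in regions
        }

    tg_mean = region_mean(tg_col)
    ldl_mean = region_mean(ldl_col)
    ranked = sorted(regions, key=lambda r: tg_mean[r])
    tg_poor, tg_rich = ranked[0], ranked[-1]
    middle = [r for r in regions if r not in (tg_poor, tg_rich)]
    middle.sort(key=lambda r: ldl_mean[r])
    low_lipid, high_ldl = middle[0], middle[-1]
    names = {
        tg_rich: "TG-rich",
        tg_poor: "TG-poor",
        high_ldl: "High LDL-C",
        low_lipid: "Low lipid",
    }
    mapping = {int(d): names[clusters[d]] for d in range(len(clusters))}
    return SubgroupBoundary(mapping, provenance="auto-partition")


# ---------------------------------------------------------------------------
# cross-sectional profiles
# ---------------------------------------------------------------------------

def subgroup_profiles(
    values: pd.DataFrame,
    labels,
    measures: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(subgroup, measure) mean with a subject-bootstrap 95% CI.

    ``values`` is one row per subject; ``labels`` aligns with its rows.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    labels = np.asarray(labels)
    if measures is None:
        measures = [c for c in values.columns]
    rng = np.random.default_rng(seed)
    rows = []
    for g in pd.unique(labels):
        mask = labels == g
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty subgroup {g!r}")
        sub = values.loc[mask, measures].to_numpy(dtype=float)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = np.nanmean(sub[idx], axis=1)  # (n_boot, n_measures)
        lo, hi = np.nanpercentile(boot_means, [2.5, 97.5], axis=0)
        means = np.nanmean(sub, axis=0)
        for j, m in enumerate(measures):
            rows.append(
                {
                    "subgroup": g,
                    "measure": m,
                    "mean": means[j],
                    "ci_low": min(lo[j], means[j]),
                    "ci_high": max(hi[j], means[j]),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroup prediction benchmark
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    accuracy: float
    fold_accuracies: np.ndarray
    baseline_accuracy: float
    panel: str
    comparison_accuracy: float | None = None
    comparison_p: float | None = None


def _cv_accuracy(x, y, folds, seed):
    clf = make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=2000, C=1.0),
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(x, y):
        clf.fit(x[tr], y[tr])
        accs.append(float((clf.predict(x[te]) == y[te]).mean()))
    return np.asarray(accs)


def predict_subgroups(
    features: pd.DataFrame,
    labels,
    panel="all",
    comparison_panel=None,
    cv_folds: int = 10,
    seed: int = 0,
    n_comparison_perm: int = 2000,
) -> PredictionResult:
    """Cross-validated multinomial subgroup classification accuracy.

    ``panel`` is a list of measure names or ``"all"``.  The random-label
    baseline permutes the labels and repeats the same CV.  When a
    ``comparison_panel`` is given, the two panels are compared by a
    paired sign-flip permutation test over fold-level accuracy
    differences (a stand-in for the unpublished comparison test).
    """
    labels = np.asarray(labels).astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 subgroup labels")
    if cv_folds > counts.min():
        raise ValueError("cv_folds exceeds the smallest class size")

    def panel_cols(p):
        if isinstance(p, str) and p == "all":
            return list(features.columns)
        missing = [c for c in p if c not in features.columns]
        if missing:
            raise KeyError(f"panel measures not available: {missing}")
        return list(p)

    x = features[panel_cols(panel)].to_numpy(dtype=float)
    x = np.where(np.isfinite(x), x, np.nanmean(x, axis=0))
    fold_acc = _cv_accuracy(x, labels, cv_folds, seed)

    rng = np.random.default_rng(seed)
    perm_labels = rng.permutation(labels)
    baseline = float(_cv_accuracy(x, perm_labels, cv_folds, seed).mean())

    comparison_accuracy = comparison_p = None
    if comparison_panel is not None:
        x2 = features[panel_cols(comparison_panel)].to_numpy(dtype=float)
        x2 = np.where(np.isfinite(x2), x2, np.nanmean(x2, axis=0))
        fold_acc2 = _cv_accuracy(x2, labels, cv_folds, seed)
        comparison_accuracy = float(fold_acc2.mean())
        diff = fold_acc - fold_acc2
        obs = abs(diff.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_comparison_perm, diff.size))
        perm = np.abs((signs * diff[None, :]).mean(axis=1))
        comparison_p = float((1 + (perm >= obs - 1e-15).sum()) / (n_comparison_perm + 1))

    return PredictionResult(
        accuracy=float(fold_acc.mean()),
        fold_accuracies=fold_acc,
        baseline_accuracy=baseline,
        panel=panel if isinstance(panel, str) else ",".join(panel),
        comparison_accuracy=comparison_accuracy,
        comparison_p=comparison_p,
    )
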