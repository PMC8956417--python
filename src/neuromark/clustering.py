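"""Preference clustering: per-subject feature assembly, k-means (k = 2,
squared-Euclidean or city-block), concordance with self-reported preference,
and the two cluster-structure tests (centroid identity by permutation
pseudo-F, dispersion homogeneity by ANOVA on distances to centroid).

Feature tables are long-format DataFrames with columns
``subject_id, stage, band, measure, location, value`` where measure is one
of ``psd`` (band power), ``coherence`` (band-averaged MSC of an electrode
pair, location "Cz-Pz"), or ``dfa`` (envelope scaling exponent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .protocol import FRONTAL_CENTRAL, PROCESSING_STAGES

__all__ = [
    "FeatureEntry",
    "FeatureSpec",
    "FEATURE_PRESETS",
    "assemble_features",
    "ClusteringResult",
    "kmeans_cluster",
    "evaluate_against_selfreport",
    "centroid_identity_test",
    "dispersion_test",
]


@dataclass(frozen=True)
class FeatureEntry:
    measure: str                  # psd | coherence | dfa
    band: str
    locations: tuple[str, ...]    # channels, or "A-B" pairs for coherence
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.measure not in ("psd", "coherence", "dfa"):
            raise ValueError(f"unknown measure {self.measure!r}")


@dataclass(frozen=True)
class FeatureSpec:
    """Which features enter the per-subject vector; columns are z-scored."""

    entries: tuple[FeatureEntry, ...]
    on_constant: str = "error"  # or "drop"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("feature spec must contain at least one entry")


_FRONTAL = ("Fp1", "Fp2", "F3", "F4", "Fz")
_FC_PAIRS = ("Cz-Pz", "Cz-Fp2")
_FC_DFA = ("Fz", "Fp1", "F3", "F4")


def _preset(bands: tuple[str, ...], channels: tuple[str, ...],
            stages: tuple[str, ...]) -> FeatureSpec:
    entries = []
    for band in bands:
        entries.append(FeatureEntry("psd", band, channels, stages))
        if band == "alpha":
            # coherence and scaling exponents are computed in the alpha band,
            # the band the power analysis singles out as discriminative
            entries.append(FeatureEntry("coherence", band, _FC_PAIRS, stages))
            entries.append(FeatureEntry("dfa", band, _FC_DFA, stages))
    return FeatureSpec(tuple(entries))


#: Feature configurations mirroring the study's clustering table: PSD,
#: coherence, and scaling-exponent values in the named band / channel set /
#: stage subset, concatenated into one normalized vector.
FEATURE_PRESETS: dict[str, FeatureSpec] = {
    "frontal_alpha": _preset(("alpha",), _FRONTAL, PROCESSING_STAGES),
    "frontal_central_alpha": _preset(("alpha",), FRONTAL_CENTRAL, PROCESSING_STAGES),
    "frontal_central_alpha_theta": _preset(("alpha", "theta"), FRONTAL_CENTRAL,
                                           PROCESSING_STAGES),
    "frontal_central_alpha_S1_S2": _preset(("alpha",), FRONTAL_CENTRAL, ("S1", "S2")),
    "frontal_central_alpha_D1_D2": _preset(("alpha",), FRONTAL_CENTRAL, ("D1", "D2")),
}


def assemble_features(table: pd.DataFrame, spec: FeatureSpec,
                      ) -> tuple[np.ndarray, list[str], list[str]]:
    """Build the subjects x features matrix from a long feature table.

    Returns ``(X, subject_ids, column_names)``; every column is z-scored
    (mean 0, sd 1 with ddof=0). Band powers are log10-transformed before
    z-scoring (EEG power is approximately lognormal across subjects, and the
    log scale keeps k-means from chasing the skewed tail); coherence and DFA
    values enter on their native scale. A missing (subject, feature) cell
    raises with the subject and feature named; a constant column raises or
    is dropped with a warning, per ``spec.on_constant``.
    """
    subjects = sorted(table["subject_id"].unique())
    cols: list[str] = []
    vecs: list[np.ndarray] = []
    indexed = table.set_index(["measure", "band", "location", "stage"]).sort_index()
    for e in spec.entries:
        for loc in e.locations:
            for stage in e.stages:
                key = (e.measure, e.band, loc, stage)
                try:
                    sub = indexed.loc[key]
                except KeyError:
                    raise ValueError(f"feature table has no rows for {key}") from None
                series = sub.set_index("subject_id")["value"]
                missing = [s for s in subjects if s not in series.index]
                if missing:
                    raise ValueError(
                        f"subject {missing[0]} lacks feature {key}")
                v = series.loc[subjects].to_numpy(dtype=float)
                if e.measure == "psd":
                    if np.any(v <= 0):
                        raise ValueError(f"non-positive band power for {key}")
                    v = np.log10(v)
                name = f"{e.measure}:{e.band}:{loc}:{stage}"
                sd = v.std()
                if sd == 0:
                    if spec.on_constant == "drop":
                        warnings.warn(f"dropping constant feature column {name}",
                                      stacklevel=2)
                        continue
                    raise ValueError(f"feature column {name} is constant")
                vecs.append((v - v.mean()) / sd)
                cols.append(name)
    if not vecs:
        raise ValueError("no usable feature columns")
    return np.column_stack(vecs), subjects, cols


# ---------------------------------------------------------------------------
# k-means

def _distances(X: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        d = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    else:
        d = np.abs(X[:, None, :] - centroids[None, :, :]).sum(axis=2)
    return d


@dataclass
class ClusteringResult:
    assignments: np.ndarray           # subject -> 0/1
    centroids: np.ndarray
    distance: str
    objective: float
    subject_ids: list[str] = field(default_factory=list)
    confusion: np.ndarray | None = None
    accuracy: float | None = None     # percent
    ppv: float | None = None          # percent
    cluster_to_label: dict[int, str] | None = None


def kmeans_cluster(X: np.ndarray, k: int = 2, distance: str = "euclidean",
                   n_init: int = 25, seed=0, max_iter: int = 300,
                   subject_ids: list[str] | None = None) -> ClusteringResult:
    """Lloyd-style k-means under squared-Euclidean or city-block distance.

    The centroid update is the mean (squared Euclidean) or the componentwise
    median (city block — the L1-optimal centroid). An emptied cluster is
    re-seeded at the point farthest from its nearest centroid. Best of
    ``n_init`` random restarts by total within-cluster distance; fully
    deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} subjects, got {n}")
    if distance not in ("euclidean", "cityblock"):
        raise ValueError(f"unknown distance {distance!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best = None
    for _ in range(n_init):
        centroids = X[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            d = _distances(X, centroids, distance)
            new_labels = d.argmin(axis=1)
            for c in range(k):
                if not np.any(new_labels == c):
                    new_labels[d.min(axis=1).argmax()] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                pts = X[labels == c]
                centroids[c] = pts.mean(axis=0) if distance == "euclidean" \
                    else np.median(pts, axis=0)
        obj = float(_distances(X, centroids, distance).min(axis=1).sum())
        if best is None or obj < best[0]:
            best = (obj, labels.copy(), centroids.copy())
    obj, labels, centroids = best
    return ClusteringResult(assignments=labels, centroids=centroids,
                            distance=distance, objective=obj,
                            subject_ids=subject_ids or [])


def evaluate_against_selfreport(result: ClusteringResult,
                                labels: np.ndarray | list[str],
                                positive: str = "A") -> ClusteringResult:
    """Score cluster assignments against self-report groups.

    Cluster numbering is arbitrary, so the cluster -> label mapping that
    maximizes accuracy is chosen; the degenerate mappings (both clusters to
    one label) are allowed, so the score never falls below the majority-class
    prevalence. The confusion matrix is indexed [true, predicted] over
    (positive, other); PPV takes ``positive`` (electric-car preference) as
    the positive class and is NaN when nothing is predicted positive.
    Percentages.
    """
    y = np.asarray(labels)
    if len(y) != len(result.assignments):
        raise ValueError("need one self-report label per clustered subject")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"expected two self-report groups, got {list(classes)}")
    other = [c for c in classes if c != positive][0]
    best = None
    for mapping in ({0: positive, 1: other}, {0: other, 1: positive},
                    {0: positive, 1: positive}, {0: other, 1: other}):
        pred = np.array([mapping[a] for a in result.assignments])
        acc = float((pred == y).mean())
        if best is None or acc > best[0]:
            best = (acc, mapping, pred)
    acc, mapping, pred = best
    tp = int(((y == positive) & (pred == positive)).sum())
    fp = int(((y == other) & (pred == positive)).sum())
    fn = int(((y == positive) & (pred == other)).sum())
    tn = int(((y == other) & (pred == other)).sum())
    result.confusion = np.array([[tp, fn], [fp, tn]])
    result.accuracy = 100.0 * acc
    result.ppv = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
    result.cluster_to_label = mapping
    return result


# ---------------------------------------------------------------------------
# cluster-structure tests

def _pseudo_f(dist2: np.ndarray, groups: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a squared pairwise distance matrix."""
    n = len(groups)
    k = len(np.unique(groups))
    ss_total = dist2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = dist2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def centroid_identity_test(X: np.ndarray, assignments: np.ndarray,
                           distance: str = "euclidean",
                           n_permutations: int = 999, seed=0) -> tuple[float, float]:
    """Permutation test of H0: the two clusters share a centroid.

    A PERMANOVA-style pseudo-F on the pairwise (squared) distance matrix,
    with p from permuting the assignments. Note: when the grouping being
    tested was itself produced by k-means on the same features, the test is
    biased toward rejection (k-means maximizes exactly this separation);
    pass self-report groups for an unbiased test.

    Returns ``(pseudo_F, p)``.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(assignments)
    sizes = pd.Series(groups).value_counts()
    if (sizes < 2).any():
        raise ValueError("each cluster needs at least 2 members")
    metric = "euclidean" if distance == "euclidean" else "cityblock"
    d = squareform(pdist(X, metric=metric))
    d2 = d ** 2
    f_obs = _pseudo_f(d2, groups)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if _pseudo_f(d2, rng.permutation(groups)) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return float(f_obs), float(p)


def dispersion_test(X: np.ndarray, assignments: np.ndarray,
                    distance: str = "euclidean") -> tuple[float, float]:
    """Homogeneity of multivariate group dispersions.

    Each subject's distance to its own cluster centroid (mean or
    componentwise median per the metric) is computed and the two clusters
    are compared by one-way ANOVA on those distances — the beta-dispersion
    recipe. All-zero distances (every point at its centroid) give p = 1 by
    convention. Returns ``(F, p)``.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(assignments)
    uniq = np.unique(groups)
    if len(uniq) < 2 or any((groups == g).sum() < 2 for g in uniq):
        raise ValueError("need two clusters with at least 2 members each")
    dists = []
    for g in uniq:
        pts = X[groups == g]
        if distance == "euclidean":
            c = pts.mean(axis=0)
            dists.append(np.sqrt(((pts - c) ** 2).sum(axis=1)))
        else:
            c = np.median(pts, axis=0)
            dists.append(np.abs(pts - c).sum(axis=1))
    if all(np.allclose(d, 0.0) for d in dists):
        return 0.0, 1.0
    f, p = stats.f_oneway(*dists)
    return float(f), float(p)
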