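"""Habitat typology: ordination, hierarchical clustering, supervised
consolidation and projection, and cluster characterization.

The typology is built from labeled-or-not coastal stations in three
stages.  (1) Station attributes are standardized and ordinated by
principal component analysis; axes covering at least a target share of
the variance (default 90%) are retained.  (2) Agglomerative clustering
with Ward linkage on the retained axes cuts the tree at ``n_clusters``
(default 5); each cluster is named after its *archetypical attribute* —
the cover with the largest standardized positive deviation of the
cluster mean from the global mean — mapped to the five habitat names.
(3) Consolidation: stations whose cluster's archetypical attribute falls
below a threshold (default 15% cover) are set aside, a bagged ensemble
of 1,000 decision trees is trained on the remaining stations, and the
set-aside stations are reassigned to the predicted habitat; the ensemble
out-of-bag (OOB) error is recorded.  A second ensemble trained on the
consolidated typology projects remote or otherwise new stations onto it.

Clusters are characterized by comparing each habitat's attribute means
against the all-station means with two-sided Welch tests, Holm-corrected
within habitat; attributes are tiered as highly significant (p < 1e-50)
or significant (p < 0.05) and sorted by decreasing significance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .stations import (
    BASE_ATTRIBUTES,
    COVER_ATTRIBUTES,
    HABITATS,
    StationRecord,
)

#: Cover attribute -> habitat name for cluster naming.  Composite covers
#: are not candidates; the dominant base cover decides.
ARCHETYPE_TO_HABITAT: dict[str, str] = {
    "seagrass": "Seagrass",
    "erect_algae": "Macroalgae",
    "algal_turf": "Macroalgae",
    "sand": "Sandy",
    "debris": "Debris",
    "boulder": "Debris",
    "rock": "Debris",
    "slab": "Debris",
    "live_coral": "Live Coral",
    "dead_coral": "Live Coral",
}

#: Habitat -> the (possibly composite) attribute whose cover defines the
#: habitat's archetype, used by the consolidation threshold.
HABITAT_ARCHETYPE_ATTRIBUTE: dict[str, str] = {
    "Seagrass": "seagrass",
    "Macroalgae": "algae",
    "Sandy": "sand",
    "Debris": "debris",
    "Live Coral": "live_coral",
}

DEFAULT_N_TREES = 1000
DEFAULT_ARCHETYPE_THRESHOLD = 15.0
HIGHLY_SIGNIFICANT_P = 1e-50
SIGNIFICANT_P = 0.05


class TypologyError(ValueError):
    pass


@dataclass
class TypologyModel:
    """Fitted typology: ordination basis, assignments, classifiers."""

    attributes: list[str]
    scaler: StandardScaler
    pca: PCA
    n_axes: int
    station_ids: list[str]
    labels: list[str]  # habitat per training station, parallel to station_ids
    cluster_names: dict[int, str]
    archetype_threshold: float = DEFAULT_ARCHETYPE_THRESHOLD
    n_trees: int = DEFAULT_N_TREES
    seed: int = 0
    consolidation_forest: RandomForestClassifier | None = None
    consolidation_oob_error: float | None = None
    projection_forest: RandomForestClassifier | None = None
    projection_oob_error: float | None = None
    training_matrix: np.ndarray | None = None
    reassigned_ids: list[str] = field(default_factory=list)

    def label_of(self, station_id: str) -> str:
        return self.labels[self.station_ids.index(station_id)]

    # -- serialization ------------------------------------------------
    def to_json(self, path) -> None:
        """Serialize the model.  Tree ensembles are stored as parameters
        plus the training matrix and refit on load (same seed, exact)."""
        payload = {
            "format_version": 1,
            "attributes": self.attributes,
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
            "pca_components": self.pca.components_.tolist(),
            "pca_mean": self.pca.mean_.tolist(),
            "explained_variance_ratio": self.pca.explained_variance_ratio_.tolist(),
            "n_axes": self.n_axes,
            "station_ids": self.station_ids,
            "labels": self.labels,
            "cluster_names": {str(k): v for k, v in self.cluster_names.items()},
            "archetype_threshold": self.archetype_threshold,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "consolidation_oob_error": self.consolidation_oob_error,
            "projection_oob_error": self.projection_oob_error,
            "training_matrix": (
                self.training_matrix.tolist()
                if self.training_matrix is not None
                else None
            ),
            "reassigned_ids": self.reassigned_ids,
            "has_consolidation_forest": self.consolidation_forest is not None,
            "has_projection_forest": self.projection_forest is not None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TypologyModel":
        with open(path) as fh:
            p = json.load(fh)
        scaler = StandardScaler()
        scaler.mean_ = np.array(p["scaler_mean"])
        scaler.scale_ = np.array(p["scaler_scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = len(scaler.mean_)
        pca = PCA(n_components=len(p["pca_components"]))
        pca.components_ = np.array(p["pca_components"])
        pca.mean_ = np.array(p["pca_mean"])
        pca.explained_variance_ratio_ = np.array(p["explained_variance_ratio"])
        model = cls(
            attributes=p["attributes"],
            scaler=scaler,
            pca=pca,
            n_axes=p["n_axes"],
            station_ids=p["station_ids"],
            labels=p["labels"],
            cluster_names={int(k): v for k, v in p["cluster_names"].items()},
            archetype_threshold=p["archetype_threshold"],
            n_trees=p["n_trees"],
            seed=p["seed"],
            consolidation_oob_error=p["consolidation_oob_error"],
            projection_oob_error=p["projection_oob_error"],
            training_matrix=(
                np.array(p["training_matrix"])
                if p["training_matrix"] is not None
                else None
            ),
            reassigned_ids=p["reassigned_ids"],
        )
        if p["has_projection_forest"] and model.training_matrix is not None:
            model.projection_forest = _fit_forest(
                model.training_matrix, model.labels, model.n_trees, model.seed
            )[0]
        return model


@dataclass
class AttributeEffect:
    attribute: str
    cluster_mean: float
    global_mean: float
    p_value: float
    tier: str  # "highly_significant" or "significant"


@dataclass
class ClusterCharacterization:
    """Per habitat, the attributes with significantly higher/lower cluster
    means than the all-station mean, sorted by decreasing significance."""

    higher: dict[str, list[AttributeEffect]]
    lower: dict[str, list[AttributeEffect]]


def _matrix(stations: list[StationRecord],
            attributes: list[str]) -> np.ndarray:
    return np.array(
        [[s.profile.value(a) for a in attributes] for s in stations], dtype=float
    )


def _fit_forest(X: np.ndarray, y: list[str], n_trees: int, seed: int):
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest, 1.0 - float(forest.oob_score_)


def build_typology(
    stations: list[StationRecord],
    n_clusters: int = 5,
    seed: int = 0,
    *,
    attributes: list[str] | None = None,
    variance_target: float = 0.90,
    archetype_threshold: float = DEFAULT_ARCHETYPE_THRESHOLD,
    n_trees: int = DEFAULT_N_TREES,
) -> TypologyModel:
    """Ordinate, cluster and name habitat clusters from station attributes.

    Attributes are standardized; PCA axes are retained up to
    ``variance_target`` cumulative explained variance; Ward-linkage
    agglomerative clustering on the retained axes is cut at ``n_clusters``.
    Each cluster is named for the cover attribute with the largest
    standardized positive deviation of its mean from the global mean.
    """
    if attributes is None:
        attributes = list(BASE_ATTRIBUTES)
    if len(stations) < n_clusters:
        raise TypologyError(
            f"need at least {n_clusters} stations, got {len(stations)}"
        )
    X = _matrix(stations, attributes)
    constant = [a for a, v in zip(attributes, X.var(axis=0)) if v == 0]
    if constant:
        warnings.warn(f"dropping constant attributes: {constant}", stacklevel=2)
        attributes = [a for a in attributes if a not in constant]
        X = _matrix(stations, attributes)
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    pca = PCA(random_state=seed).fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_axes = int(np.searchsorted(cum, variance_target) + 1)
    scores = pca.transform(Z)[:, :n_axes]

    tree = linkage(scores, method="ward")
    clusters = fcluster(tree, t=n_clusters, criterion="maxclust")

    cluster_names = _name_clusters(stations, clusters, n_clusters)
    labels = [cluster_names[int(c)] for c in clusters]
    return TypologyModel(
        attributes=attributes,
        scaler=scaler,
        pca=pca,
        n_axes=n_axes,
        station_ids=[s.station_id for s in stations],
        labels=labels,
        cluster_names=cluster_names,
        archetype_threshold=archetype_threshold,
        n_trees=n_trees,
        seed=seed,
        training_matrix=X,
    )


def _name_clusters(stations: list[StationRecord], clusters: np.ndarray,
                   n_clusters: int) -> dict[int, str]:
    covers = _matrix(stations, list(COVER_ATTRIBUTES))
    g_mean = covers.mean(axis=0)
    g_sd = covers.std(axis=0)
    g_sd[g_sd == 0] = 1.0
    names: dict[int, str] = {}
    # Assign clusters in order of decreasing peak deviation so the most
    # clear-cut archetype claims its habitat name first.
    order = []
    for c in range(1, n_clusters + 1):
        dev = (covers[clusters == c].mean(axis=0) - g_mean) / g_sd
        order.append((c, dev))
    order.sort(key=lambda t: -t[1].max())
    used: set[str] = set()
    for c, dev in order:
        ranked = np.argsort(-dev)
        for idx in ranked:
            if dev[idx] <= 0:
                break
            habitat = ARCHETYPE_TO_HABITAT[COVER_ATTRIBUTES[idx]]
            if habitat not in used:
                names[c] = habitat
                used.add(habitat)
                break
        if c not in names:
            raise TypologyError(
                f"cluster {c}: no unused habitat name for its archetype; "
                "supply manual names"
            )
    return names


def consolidate(
    model: TypologyModel,
    stations: list[StationRecord],
    threshold: float | None = None,
) -> TypologyModel:
    """Reassign stations whose habitat's archetypical attribute is below
    the threshold, using a forest trained on the remaining stations.

    Stations must carry the model's labels (``station.habitat`` is used
    when set, else the model's stored label).  The ensemble OOB error is
    recorded on the model.  Idempotent: a second pass with the same
    threshold sets nothing aside that the forest itself assigned.
    """
    if threshold is None:
        threshold = model.archetype_threshold
    ids = [s.station_id for s in stations]
    # Label precedence: a station already reassigned by a previous pass
    # keeps the model's label (idempotence); otherwise the station's own
    # label wins, falling back to the model's cluster assignment.
    labels = []
    for s in stations:
        if s.station_id in model.reassigned_ids:
            labels.append(model.label_of(s.station_id))
        elif s.habitat is not None:
            labels.append(s.habitat)
        else:
            labels.append(model.label_of(s.station_id))
    X = _matrix(stations, model.attributes)
    keep, aside = [], []
    for i, (s, lab) in enumerate(zip(stations, labels)):
        attr = HABITAT_ARCHETYPE_ATTRIBUTE[lab]
        if (
            s.profile.value(attr) < threshold
            and s.station_id not in model.reassigned_ids
        ):
            aside.append(i)
        else:
            keep.append(i)
    kept_labels = [labels[i] for i in keep]
    lost = set(HABITATS) & (set(labels) - set(kept_labels))
    if lost:
        raise TypologyError(f"consolidation empties habitat(s): {sorted(lost)}")
    forest, oob = _fit_forest(
        X[keep], kept_labels, model.n_trees, model.seed
    )
    new_labels = list(labels)
    if aside:
        pred = forest.predict(X[aside])
        for j, i in enumerate(aside):
            new_labels[i] = str(pred[j])
    model.consolidation_forest = forest
    model.consolidation_oob_error = oob
    model.station_ids = ids
    model.labels = new_labels
    model.training_matrix = X
    model.archetype_threshold = threshold
    model.reassigned_ids = sorted(
        set(model.reassigned_ids) | {ids[i] for i in aside}
    )
    # Projection ensemble is trained on the consolidated typology.
    model.projection_forest, model.projection_oob_error = _fit_forest(
        X, new_labels, model.n_trees, model.seed
    )
    return model


def project(
    model: TypologyModel, new_stations: list[StationRecord]
) -> tuple[list[str], np.ndarray]:
    """Predict habitat for new stations from the consolidated typology.

    Returns (labels, vote_shares); vote shares are the ensemble's class
    vote fractions, one row per station, summing to 1.
    """
    if model.projection_forest is None:
        raise TypologyError("model not consolidated; call consolidate() first")
    X = _matrix(new_stations, model.attributes)
    labels = [str(v) for v in model.projection_forest.predict(X)]
    shares = model.projection_forest.predict_proba(X)
    return labels, shares


def characterize(
    model: TypologyModel | None,
    stations: list[StationRecord],
    *,
    attributes: list[str] | None = None,
) -> ClusterCharacterization:
    """Welch-test each habitat's attribute means against the global means.

    P-values are Holm-corrected across attributes within each habitat;
    attributes with corrected p < 0.05 enter the higher or lower list by
    the sign of the mean difference, sorted by increasing p.
    """
    if attributes is None:
        attributes = model.attributes if model is not None else list(BASE_ATTRIBUTES)
    labels = [
        s.habitat if s.habitat is not None else model.label_of(s.station_id)
        for s in stations
    ]
    X = _matrix(stations, attributes)
    higher: dict[str, list[AttributeEffect]] = {}
    lower: dict[str, list[AttributeEffect]] = {}
    for habitat in sorted(set(labels)):
        mask = np.array([lab == habitat for lab in labels])
        if mask.sum() < 2:
            warnings.warn(
                f"habitat {habitat!r} has <2 stations; skipped", stacklevel=2
            )
            continue
        pvals, effects = [], []
        for j, attr in enumerate(attributes):
            in_cluster = X[mask, j]
            if np.ptp(X[:, j]) == 0:
                pvals.append(1.0)
                effects.append((attr, float(in_cluster.mean()), float(X[:, j].mean())))
                continue
            t = stats.ttest_ind(in_cluster, X[:, j], equal_var=False)
            pvals.append(float(t.pvalue) if np.isfinite(t.pvalue) else 1.0)
            effects.append((attr, float(in_cluster.mean()), float(X[:, j].mean())))
        _, corrected, _, _ = multipletests(pvals, method="holm")
        hi, lo = [], []
        for (attr, cm, gm), p in zip(effects, corrected):
            if p >= SIGNIFICANT_P:
                continue
            tier = (
                "highly_significant" if p < HIGHLY_SIGNIFICANT_P else "significant"
            )
            eff = AttributeEffect(attr, cm, gm, float(p), tier)
            (hi if cm > gm else lo).append(eff)
        hi.sort(key=lambda e: e.p_value)
        lo.sort(key=lambda e: e.p_value)
        higher[habitat] = hi
        lower[habitat] = lo
    return ClusterCharacterization(higher=higher, lower=lower)
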