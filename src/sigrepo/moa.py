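"""Mode-of-action clustering of treatments from proteomic + phenotypic data.

Treatments (rows) are described by analyte fold changes over matched
controls (phospho-proteins, cytokines, plus lipid and ROS fold changes).
Columns are fraction-normalised to [0, 1], embedded with PCA, and clustered
with k-means; the adjusted Rand index scores concordance against reference
labels, and a silhouette scan proposes k.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score


def fold_change_matrix(raw: pd.DataFrame, control_map: dict[str, str]) -> pd.DataFrame:
    """Per-analyte fold change of each treatment over its designated control.

    ``raw`` is treatments x analytes; ``control_map`` maps each treatment
    row to the control row to divide by. A zero control value is an error
    naming the analyte.
    """
    missing = [t for t in raw.index if t not in control_map]
    if missing:
        raise KeyError(f"treatments without a control mapping: {missing[:5]}")
    unknown = sorted({c for c in control_map.values() if c not in raw.index})
    if unknown:
        raise KeyError(f"control rows absent from the matrix: {unknown[:5]}")
    out = raw.copy().astype(float)
    for t in raw.index:
        ctrl = raw.loc[control_map[t]]
        zero = ctrl[ctrl == 0]
        if len(zero):
            raise ValueError(f"control value 0 for analyte {zero.index[0]!r} "
                             f"(control {control_map[t]!r})")
        out.loc[t] = raw.loc[t] / ctrl
    return out


class FractionNormalizer(BaseEstimator, TransformerMixin):
    """Column-wise min-max scaling to [0, 1] (fraction normalisation).

    Constant columns map to all zeros (deterministic, warned). The
    transform is idempotent on its own output for non-constant columns.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to normalise")
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        span = self.max_ - self.min_
        constant = span == 0
        if constant.any():
            warnings.warn(f"{int(constant.sum())} constant column(s) normalised to 0",
                          stacklevel=2)
        safe = np.where(constant, 1.0, span)
        out = (X - self.min_) / safe
        out[:, constant] = 0.0
        return out


def fraction_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Functional wrapper over :class:`FractionNormalizer` preserving labels."""
    norm = FractionNormalizer().fit(matrix.to_numpy())
    return pd.DataFrame(norm.transform(matrix.to_numpy()),
                        index=matrix.index, columns=matrix.columns)


def pca_embed(matrix: pd.DataFrame, n_components: int = 2
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA scores and explained-variance fractions.

    Component signs are fixed by making the largest-|loading| entry of each
    component positive, so the embedding is deterministic. Columns are not
    re-scaled: fraction normalisation upstream already bounds the scale.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValueError("need more rows than components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return (pd.DataFrame(scores, index=matrix.index, columns=cols),
            pca.explained_variance_ratio_)


def kmeans_cluster(embedding: pd.DataFrame, k: int = 4, n_init: int = 50,
                   seed: int = 0) -> pd.Series:
    """Best-of-``n_init`` k-means labels (1-based), deterministic under seed."""
    X = embedding.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({X.shape[0]})")
    if k == 1:
        return pd.Series(1, index=embedding.index)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return pd.Series(km.fit_predict(X) + 1, index=embedding.index)


def choose_k(embedding: pd.DataFrame, k_range=range(2, 9), n_init: int = 50,
             seed: int = 0) -> int:
    """k maximising the mean silhouette over ``k_range`` (ties -> smaller k)."""
    X = embedding.to_numpy(dtype=float)
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= X.shape[0]:
            break
        labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit_predict(X)
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no k in range produced a valid clustering")
    return best_k


def cluster_concordance(labels, reference) -> float:
    """Adjusted Rand index between two labelings of the same rows."""
    labels = np.asarray(labels)
    reference = np.asarray(reference)
    if labels.shape != reference.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(reference, labels))


class ModeOfActionClusterer(BaseEstimator):
    """Fraction-normalise -> PCA -> k-means, as one estimator.

    Parameters
    ----------
    k : number of clusters (4 by default, the number of signalling modes
        the assay panel distinguishes: negative control, steatosis
        induction, steatosis reduction, compound-alone).
    n_components : PCA components to cluster on (2 by default; set
        ``cluster_on_pcs=False`` to cluster on all normalised features).
    scan_k : also run the silhouette scan and expose ``chosen_k_``.

    Attributes
    ----------
    embedding_ : PC-score frame; variance_fractions_ : per component.
    labels_ : 1-based cluster labels per treatment.
    chosen_k_ : silhouette-selected k (when ``scan_k``).
    """

    def __init__(self, k: int = 4, n_components: int = 2, n_init: int = 50,
                 cluster_on_pcs: bool = True, scan_k: bool = True, seed: int = 0):
        self.k = k
        self.n_components = n_components
        self.n_init = n_init
        self.cluster_on_pcs = cluster_on_pcs
        self.scan_k = scan_k
        self.seed = seed

    def fit(self, matrix: pd.DataFrame, y=None):
        normed = fraction_normalize(matrix)
        self.normalized_ = normed
        self.embedding_, self.variance_fractions_ = pca_embed(normed, self.n_components)
        target = self.embedding_ if self.cluster_on_pcs else normed
        self.labels_ = kmeans_cluster(target, k=self.k, n_init=self.n_init, seed=self.seed)
        if self.scan_k:
            # the k-scan runs on the full normalised matrix: the 2-D
            # embedding is a display projection and can merge clusters
            # that the full feature space keeps apart
            self.chosen_k_ = choose_k(normed, n_init=self.n_init, seed=self.seed)
        return self

    def fit_predict(self, matrix: pd.DataFrame) -> pd.Series:
        return self.fit(matrix).labels_
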