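"""Compositional structure of glucosinolate profiles.

A genotype's GSL profile is compositional: only relative information is
meaningful on the simplex, so multivariate analysis works in centred
log-ratio (clr) coordinates and distances are Aitchison (Euclidean on clr
images). Biological zeros (e.g. gluconasturtiin null genotypes) are handled
by multiplicative replacement before the log-ratio transform: each zero
becomes a small delta tied to that compound's smallest observed positive
value, and the positive parts of the row are shrunk so the row total is
preserved.

Hierarchical clustering (Ward by default) on the Aitchison distance matrix
separates genotype groups; z-scored mean matrices feed heatmaps; Spearman
correlations and PCA describe co-accumulation patterns among compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from skbio.stats.composition import clr as _skbio_clr
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA

from .panels import total_gsl

DEFAULT_DELTA_FRACTION = 0.65


# ---------------------------------------------------------------------------
# zero replacement and log-ratio geometry


def replace_zeros(
    means: pd.DataFrame,
    delta_fraction: float = DEFAULT_DELTA_FRACTION,
    delta=None,
) -> pd.DataFrame:
    """Multiplicative zero replacement with a per-compound delta.

    delta_j = delta_fraction × (smallest positive value in column j), unless
    an explicit ``delta`` (scalar or per-column array) is supplied. Zeros in
    a row become their column deltas and the positive entries are scaled
    down so the row total is unchanged. A compound that is zero in every
    genotype admits no delta and raises.
    """
    if (means < 0).any().any():
        raise ValueError("composition parts must be non-negative")
    x = means.to_numpy(dtype=float)
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("every genotype row needs at least one positive part")
    if delta is None:
        zero_cols = np.where((x > 0).sum(axis=0) == 0)[0]
        if zero_cols.size:
            names = means.columns[zero_cols].tolist()
            raise ValueError(f"compounds with no positive value anywhere: {names}")
        col_min_pos = np.array([x[x[:, j] > 0, j].min() for j in range(x.shape[1])])
        delta = delta_fraction * col_min_pos
    else:
        delta = np.broadcast_to(np.asarray(delta, dtype=float), (x.shape[1],))
    out = x.copy()
    for i in range(x.shape[0]):
        zeros = x[i] == 0
        if not zeros.any():
            continue
        total = x[i].sum()
        added = delta[zeros].sum()
        if added >= total:
            raise ValueError(f"row {means.index[i]}: replacement deltas exceed the row total")
        out[i, zeros] = delta[zeros]
        out[i, ~zeros] *= (total - added) / total
    return pd.DataFrame(out, index=means.index, columns=means.columns)


class ZeroReplacer(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapper around :func:`replace_zeros`."""

    def __init__(self, delta_fraction: float = DEFAULT_DELTA_FRACTION):
        self.delta_fraction = delta_fraction

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return replace_zeros(X, self.delta_fraction)


def clr(x) -> np.ndarray:
    """Centred log-ratio transform of strictly positive parts.

    clr_i = ln x_i − mean_j ln x_j; components of the image sum to zero.
    Accepts a vector or a matrix (row-wise).
    """
    arr = np.asarray(x, dtype=float)
    if (arr <= 0).any():
        raise ValueError("clr requires strictly positive parts")
    return _skbio_clr(arr)


class CLRTransform(BaseEstimator, TransformerMixin):
    def fit(self, X, y=None):
        return self

    def transform(self, X):
        out = clr(np.asarray(X, dtype=float))
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def aitchison_distance(x, y) -> float:
    """Euclidean distance between clr images; scale-invariant per argument."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("compositions must have the same length")
    return float(np.linalg.norm(clr(x) - clr(y)))


def aitchison_distance_matrix(comp: pd.DataFrame) -> pd.DataFrame:
    z = clr(comp.to_numpy(dtype=float))
    d = squareform(pdist(z, metric="euclidean"))
    return pd.DataFrame(d, index=comp.index, columns=comp.index)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusteringResult:
    distances: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series  # flat labels at the requested k


class AitchisonClustering(BaseEstimator, ClusterMixin):
    """Agglomerative clustering of genotypes in Aitchison geometry.

    Fit expects a strictly positive genotype × compound matrix (apply
    :func:`replace_zeros` first if the panel contains biological zeros).
    Ward linkage on the Aitchison distance matrix, cut at ``n_clusters``.

    Attributes
    ----------
    distances_ : symmetric Aitchison distance DataFrame
    linkage_ : scipy condensed linkage array (merge heights)
    labels_ : integer labels, aligned with the input index
    """

    def __init__(self, n_clusters: int = 2, linkage_method: str = "ward"):
        self.n_clusters = n_clusters
        self.linkage_method = linkage_method

    def fit(self, X: pd.DataFrame, y=None) -> "AitchisonClustering":
        if self.n_clusters > len(X):
            raise ValueError(f"k={self.n_clusters} exceeds the {len(X)} genotypes")
        dist = aitchison_distance_matrix(X)
        condensed = squareform(dist.to_numpy(), checks=False)
        Z = hierarchy.linkage(condensed, method=self.linkage_method)
        labels = hierarchy.fcluster(Z, t=self.n_clusters, criterion="maxclust")
        self.distances_ = dist
        self.linkage_ = Z
        self.labels_ = np.asarray(labels)
        self.index_ = X.index
        return self

    def result(self) -> ClusteringResult:
        return ClusteringResult(
            distances=self.distances_,
            linkage=self.linkage_,
            labels=pd.Series(self.labels_, index=self.index_, name="cluster"),
        )


def hierarchical_cluster(
    comp: pd.DataFrame, linkage_method: str = "ward", k: int = 2
) -> ClusteringResult:
    return AitchisonClustering(n_clusters=k, linkage_method=linkage_method).fit(comp).result()


# ---------------------------------------------------------------------------
# standardisation, correlation, PCA


def standardize(means: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Column z-scores (population SD by default, fixed for heatmap stability).

    A zero-variance column cannot be scaled; it is returned as zeros with a
    warning rather than NaN so heatmaps stay renderable.
    """
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=ddof)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance columns set to 0: {means.columns[flat].tolist()}",
            UserWarning,
            stacklevel=2,
        )
    sd = sd.mask(flat, 1.0)
    z = (means - mu) / sd
    z.loc[:, flat] = 0.0
    return z


def spearman_matrix(
    means: pd.DataFrame, include_total: bool = True, total_label: str = "TOTAL"
) -> pd.DataFrame:
    """Pairwise Spearman rank correlations among compounds (+ total column).

    Average ranks for ties. Constant columns have undefined correlations and
    are reported as NaN with a warning.
    """
    if len(means) < 3:
        raise ValueError("Spearman correlation needs at least 3 genotypes")
    data = means.copy()
    if include_total:
        data[total_label] = total_gsl(means)
    const = data.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant columns yield undefined correlations: {data.columns[const].tolist()}",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # constant columns are already reported above via UserWarning
        warnings.filterwarnings("ignore", message="An input array is constant")
        rho = spearmanr(data.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=data.columns, columns=data.columns)
    np.fill_diagonal(out.values, 1.0)
    out.loc[const, :] = np.nan
    out.loc[:, const] = np.nan
    for c in data.columns[const]:
        out.loc[c, c] = np.nan
    return out


@dataclass
class PcaResult:
    variance_fractions: np.ndarray  # non-increasing, sums to ≤ 1
    scores: pd.DataFrame  # genotype × component
    loadings: pd.DataFrame  # compound × component


class CompositionPCA(BaseEstimator, TransformerMixin):
    """PCA of genotype mean profiles.

    ``scale_mode`` selects the pre-treatment: "zscore" (default; PCA of the
    column-standardised means, i.e. the correlation matrix), "clr" (PCA in
    log-ratio coordinates after zero replacement), or "raw".
    """

    def __init__(
        self,
        n_components: int = 4,
        scale_mode: str = "zscore",
        delta_fraction: float = DEFAULT_DELTA_FRACTION,
    ):
        self.n_components = n_components
        self.scale_mode = scale_mode
        self.delta_fraction = delta_fraction

    def _pretreat(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.scale_mode == "zscore":
            return standardize(X)
        if self.scale_mode == "clr":
            return CLRTransform().transform(replace_zeros(X, self.delta_fraction))
        if self.scale_mode == "raw":
            return X
        raise ValueError(f"unknown scale_mode: {self.scale_mode}")

    def fit(self, X: pd.DataFrame, y=None) -> "CompositionPCA":
        if len(X) < 3 or X.shape[1] < 2:
            raise ValueError("PCA needs at least 3 genotypes and 2 compounds")
        k = min(self.n_components, len(X) - 1, X.shape[1])
        if k < self.n_components:
            warnings.warn(
                f"requested {self.n_components} components, truncating to {k}",
                UserWarning,
                stacklevel=2,
            )
        Z = self._pretreat(X)
        self._pca = PCA(n_components=k)
        scores = self._pca.fit_transform(Z.to_numpy(dtype=float))
        comps = [f"PC{i + 1}" for i in range(k)]
        self.variance_fractions_ = self._pca.explained_variance_ratio_
        self.scores_ = pd.DataFrame(scores, index=X.index, columns=comps)
        self.loadings_ = pd.DataFrame(self._pca.components_.T, index=X.columns, columns=comps)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self._pca.transform(self._pretreat(X).to_numpy(dtype=float))

    def result(self) -> PcaResult:
        return PcaResult(
            variance_fractions=self.variance_fractions_,
            scores=self.scores_,
            loadings=self.loadings_,
        )


def pca(means: pd.DataFrame, scale_mode: str = "zscore", n_components: int = 4) -> PcaResult:
    return CompositionPCA(n_components=n_components, scale_mode=scale_mode).fit(means).result()
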