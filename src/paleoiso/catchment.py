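"""Per-site environmental feature extraction and K-means site typology.

Every site is characterised by the raster cells inside a fixed-radius
catchment (default 3000 m): the twelve monthly wCON classes per cell plus a
one-hot encoding of the cell's soil unit. The site-by-feature matrix is
compressed by PCA to the leading components holding 99 % of the variance and
partitioned by K-means; the number of clusters is chosen by the gap
statistic (Tibshirani's uniform reference, firstSEmax rule) and the mean
silhouette.

The stage is exposed both as module functions and as
:class:`CatchmentClusterer`, a scikit-learn compatible estimator usable in
sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples, silhouette_score

from .raster import RasterGrid

__all__ = [
    "SiteRecord",
    "CatchmentFeatures",
    "ClusterResult",
    "extract_catchment",
    "build_feature_matrix",
    "pca_reduce",
    "kmeans_cluster",
    "select_k",
    "cluster_composition",
    "CatchmentClusterer",
]


@dataclass
class SiteRecord:
    site_id: str
    x: float
    y: float
    region: str = ""
    period: str = ""
    culture: str = ""


@dataclass
class CatchmentFeatures:
    """Flattened in-radius raster values for one site."""

    site_id: str
    vector: np.ndarray
    window_shape: tuple[int, int]
    mask: np.ndarray
    feature_names: list[str] = field(default_factory=list)


def _radius_mask(window: int, radius: float, cell_size: float) -> np.ndarray:
    half = window // 2
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    dist = np.hypot(rr, cc) * cell_size
    return dist <= radius


def extract_catchment(
    site: SiteRecord | pd.Series,
    rasters: list[RasterGrid],
    radius: float = 3000.0,
    soil_index: int | None = None,
    one_hot_soil: bool = True,
    soil_codes: tuple[int, ...] = tuple(range(10, 100, 10)),
    edge_policy: str = "error",
) -> CatchmentFeatures:
    """Flatten all raster values within ``radius`` of a site into one vector.

    A fixed square window of ``ceil(2*radius/cell) + 1`` cells is centred on
    the site's cell; cells whose centre lies beyond the radius are dropped
    from the vector, so vectors are identical in length across sites. The
    raster at ``soil_index`` is treated as categorical and one-hot expanded
    per cell (set ``one_hot_soil=False`` to keep raw unit IDs). Sites closer
    than the radius to the raster edge raise by default
    (``edge_policy='error'``) or are zero-padded (``'pad'``).
    """
    if not rasters:
        raise ValueError("at least one raster required")
    ref = rasters[0]
    for g in rasters[1:]:
        if g.shape != ref.shape or g.cell_size != ref.cell_size:
            raise ValueError("rasters are not co-registered")

    site_id = site.site_id if hasattr(site, "site_id") else site["site_id"]
    x = site.x if hasattr(site, "x") else site["x"]
    y = site.y if hasattr(site, "y") else site["y"]
    r0, c0 = ref.index_of(float(x), float(y))
    rows, cols = ref.shape
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"site {site_id} lies outside the raster extent")

    window = int(np.ceil(2 * radius / ref.cell_size)) + 1
    if window % 2 == 0:
        window += 1
    half = window // 2
    in_radius = _radius_mask(window, radius, ref.cell_size)

    lo_r, hi_r = r0 - half, r0 + half + 1
    lo_c, hi_c = c0 - half, c0 + half + 1
    if lo_r < 0 or lo_c < 0 or hi_r > rows or hi_c > cols:
        if edge_policy == "error":
            raise ValueError(
                f"site {site_id} is nearer than the catchment radius to the raster edge"
            )
        if edge_policy != "pad":
            raise ValueError(f"unknown edge_policy {edge_policy!r}")

    pieces: list[np.ndarray] = []
    names: list[str] = []
    flat_mask = in_radius.ravel()
    for i, grid in enumerate(rasters):
        win = np.zeros((window, window), dtype=float)
        sr, sc = max(lo_r, 0), max(lo_c, 0)
        er, ec = min(hi_r, rows), min(hi_c, cols)
        win[sr - lo_r : er - lo_r, sc - lo_c : ec - lo_c] = grid.values[sr:er, sc:ec]
        cells = win.ravel()[flat_mask]
        if i == soil_index and one_hot_soil:
            onehot = (cells[:, None] == np.asarray(soil_codes)[None, :]).astype(float)
            pieces.append(onehot.ravel())
            names.extend(
                f"r{i}_cell{j}_soil{code}"
                for j in range(cells.size)
                for code in soil_codes
            )
        else:
            pieces.append(cells)
            names.extend(f"r{i}_cell{j}" for j in range(cells.size))
    return CatchmentFeatures(
        site_id=str(site_id),
        vector=np.concatenate(pieces),
        window_shape=(window, window),
        mask=in_radius,
        feature_names=names,
    )


def build_feature_matrix(
    sites: pd.DataFrame,
    rasters: list[RasterGrid],
    radius: float = 3000.0,
    soil_index: int | None = None,
    **kwargs,
) -> tuple[np.ndarray, list[str]]:
    """Stack one catchment vector per site into a sites x features matrix."""
    feats = [
        extract_catchment(row, rasters, radius=radius, soil_index=soil_index, **kwargs)
        for row in sites.itertuples(index=False)
    ]
    matrix = np.vstack([f.vector for f in feats])
    return matrix, [f.site_id for f in feats]


def _fit_pca(matrix: np.ndarray, variance_kept: float):
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs at least two sites")
    keep = X.std(axis=0) > 0
    Xk = X[:, keep]
    if Xk.shape[1] == 0:
        # all features constant: a single zero component
        return np.zeros((X.shape[0], 1)), None, keep, 1
    max_comp = min(Xk.shape[0] - 1, Xk.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="full")
    scores = pca.fit_transform(Xk)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_kept) + 1)
    n_comp = min(n_comp, scores.shape[1])
    return scores[:, :n_comp], pca, keep, n_comp


def pca_reduce(matrix: np.ndarray, variance_kept: float = 0.99) -> np.ndarray:
    """Centre, drop zero-variance columns, and keep the leading principal
    components holding at least ``variance_kept`` of the variance."""
    scores, _, _, _ = _fit_pca(matrix, variance_kept)
    return scores


@dataclass
class ClusterResult:
    """Site partition plus k-selection diagnostics."""

    assignments: pd.DataFrame  # site_id, cluster, silhouette
    k: int
    inertia: float
    silhouette_mean: float
    gap_curve: pd.DataFrame | None
    chosen_k_rule: str
    seed: int


def kmeans_cluster(
    matrix: np.ndarray,
    k: int,
    site_ids: list[str] | None = None,
    n_restarts: int = 25,
    seed: int = 0,
) -> ClusterResult:
    """Best-of-restarts K-means partition (k-means++ initialisation)."""
    X = np.asarray(matrix, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of sites")
    km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++", random_state=seed)
    labels = km.fit_predict(X)
    if 2 <= k < X.shape[0]:
        sil = silhouette_samples(X, labels)
        sil_mean = float(sil.mean())
    else:
        sil = np.full(X.shape[0], np.nan)
        sil_mean = float("nan")
    ids = site_ids if site_ids is not None else [f"obs{i}" for i in range(X.shape[0])]
    assignments = pd.DataFrame(
        {"site_id": ids, "cluster": labels + 1, "silhouette": sil}
    )
    return ClusterResult(
        assignments=assignments,
        k=k,
        inertia=float(km.inertia_),
        silhouette_mean=sil_mean,
        gap_curve=None,
        chosen_k_rule="fixed",
        seed=seed,
    )


def _pooled_within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    # W_k of the gap statistic: sum over clusters of within sum of squares
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return max(w, np.finfo(float).tiny)


def select_k(
    matrix: np.ndarray,
    k_max: int = 30,
    method: str = "both",
    B: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
) -> dict:
    """Gap-statistic and silhouette diagnostics over k = 1..k_max.

    The gap statistic compares log within-cluster dispersion against B
    uniform reference draws over the observed feature ranges; the
    recommended k is the smallest with gap(k) >= gap(k+1) - se(k+1)
    (firstSEmax). The silhouette recommendation maximises the mean
    silhouette over k >= 2. Returns the full curves plus both
    recommendations.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be below the number of sites")
    if method not in ("gap", "silhouette", "both"):
        raise ValueError(f"unknown selection method {method!r}")
    if k_max < 2:
        warnings.warn("k_max < 2 is degenerate; returning k = 1", stacklevel=2)
        return {
            "recommended_k": 1,
            "gap_k": 1,
            "silhouette_k": 1,
            "gap_curve": pd.DataFrame(columns=["k", "gap", "se", "log_wk"]),
            "silhouette_curve": pd.DataFrame(columns=["k", "silhouette"]),
            "rule": "degenerate",
        }

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def _wk(data: np.ndarray, k: int, rs: int) -> float:
        if k == 1:
            return _pooled_within_dispersion(data, np.zeros(len(data), dtype=int))
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rs)
        return _pooled_within_dispersion(data, km.fit_predict(data))

    ks = np.arange(1, k_max + 1)
    log_wk = np.array([np.log(_wk(X, k, seed)) for k in ks])
    ref_log = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        rs = int(rng.integers(2**31 - 1))
        ref_log[b] = [np.log(_wk(ref, k, rs)) for k in ks]
    gap = ref_log.mean(axis=0) - log_wk
    se = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    gap_k = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            gap_k = int(ks[i])
            break

    sil_rows = []
    for k in ks[ks >= 2]:
        km = KMeans(n_clusters=int(k), n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        sil_rows.append({"k": int(k), "silhouette": float(silhouette_score(X, labels))})
    sil_curve = pd.DataFrame(sil_rows)
    sil_k = int(sil_curve.loc[sil_curve["silhouette"].idxmax(), "k"]) if not sil_curve.empty else 1

    recommended = {"gap": gap_k, "silhouette": sil_k, "both": gap_k}[method]
    return {
        "recommended_k": recommended,
        "gap_k": gap_k,
        "silhouette_k": sil_k,
        "gap_curve": pd.DataFrame({"k": ks, "gap": gap, "se": se, "log_wk": log_wk}),
        "silhouette_curve": sil_curve,
        "rule": "firstSEmax" if method != "silhouette" else "max-silhouette",
    }


def cluster_composition(
    result: ClusterResult, sites: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Cluster-by-region/period/culture count tables (heatmap-ready)."""
    merged = result.assignments.merge(sites, on="site_id", how="left")
    tables = {}
    for factor in ("region", "period", "culture"):
        if factor in merged.columns:
            tables[factor] = pd.crosstab(merged["cluster"], merged[factor])
    return tables


class CatchmentClusterer(BaseEstimator, ClusterMixin):
    """PCA + K-means site typology as a scikit-learn estimator.

    Parameters
    ----------
    k : int or "auto"
        Number of clusters; ``"auto"`` selects k by the configured method
        up to ``k_max``.
    variance_kept : float
        Cumulative explained-variance threshold of the PCA step.
    k_max, selection, B : gap/silhouette selection settings (used when
        ``k="auto"``).
    n_restarts : K-means restarts (k-means++ initialisation).
    random_state : seed for K-means and the gap reference draws.

    Attributes (after :meth:`fit`)
    ------------------------------
    labels_ : cluster label per site (1..k).
    k_ : the number of clusters used.
    pca_scores_ : the reduced matrix actually clustered.
    inertia_, silhouette_mean_, diagnostics_ : fit quality and k-selection
    curves.
    """

    def __init__(
        self,
        k: int | str = "auto",
        variance_kept: float = 0.99,
        k_max: int = 30,
        selection: str = "both",
        B: int = 50,
        n_restarts: int = 25,
        random_state: int = 0,
    ):
        self.k = k
        self.variance_kept = variance_kept
        self.k_max = k_max
        self.selection = selection
        self.B = B
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        scores, pca, keep, n_comp = _fit_pca(X, variance_kept=self.variance_kept)
        self._pca, self._keep, self._n_comp = pca, keep, n_comp
        if self.k == "auto":
            k_max = min(self.k_max, scores.shape[0] - 1)
            diag = select_k(
                scores, k_max=k_max, method=self.selection, B=self.B,
                seed=self.random_state,
            )
            k = max(diag["recommended_k"], 1)
        else:
            k = int(self.k)
            diag = None
        result = kmeans_cluster(
            scores, k=k, n_restarts=self.n_restarts, seed=self.random_state
        )
        self.pca_scores_ = scores
        self.k_ = k
        self.labels_ = result.assignments["cluster"].to_numpy()
        self.inertia_ = result.inertia
        self.silhouette_mean_ = result.silhouette_mean
        self.diagnostics_ = diag
        self.result_ = result
        # refit a KMeans on scores for predict()
        self._km = KMeans(
            n_clusters=k, n_init=self.n_restarts, random_state=self.random_state
        ).fit(scores)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        """Assign new sites to the fitted clusters (labels 1..k)."""
        if not hasattr(self, "_km"):
            raise RuntimeError("CatchmentClusterer is not fitted")
        X = np.asarray(X, dtype=float)
        if self._pca is None:
            scores = np.zeros((X.shape[0], 1))
        else:
            scores = self._pca.transform(X[:, self._keep])[:, : self._n_comp]
        return self._km.predict(scores) + 1
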