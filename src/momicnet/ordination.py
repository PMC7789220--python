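"""Exploratory and integrative ordination.

Single-table methods (PCA, PCoA on several distance metrics) summarise the
main axes of variation within one omics layer. Multi-table methods find
shared structure across layers:

* **co-inertia analysis (CIA)** of two tables maximises, per axis, the
  covariance between the two tables' sample scores (the SVD of the
  cross-product of the centred tables);
* **multiple co-inertia (MCIA)** of two or three tables maximises the sum
  of squared pairwise covariances between table scores, which reduces
  exactly to CIA when only two tables are given, and additionally returns a
  reference (consensus) score per axis;
* **Procrustes analysis** superimposes two ordinations by optimal
  translation, scaling and rotation, with the PROTEST permutation test of
  the residual statistic m2.

Eigenvalues throughout use uniform row weights 1/n (divisor ``n``), the
multi-table ordination convention, so that self co-inertia reproduces the
squared PCA spectrum exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .preprocess import OmicsLayer

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "CoInertiaResult",
    "ProcrustesResult",
    "pca",
    "distance",
    "pcoa",
    "coinertia",
    "mcia",
    "extract_drivers",
    "procrustes",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        np.fill_diagonal(v, 0.0)
        self.values = v


@dataclass
class OrdinationResult:
    """Sample coordinates on ordered axes plus the eigen-spectrum."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    method: str
    loadings: pd.DataFrame | None = None


@dataclass
class CoInertiaResult:
    """Axes of shared covariance across 2-3 tables.

    ``scores[layer]`` holds each table's sample coordinates (the triangle
    vertices of the co-inertia plot); ``reference_scores`` is the consensus
    coordinate set; ``covariances`` the per-axis total covariance and
    ``pseudo_eigenvalues`` its square.
    """

    layer_names: list[str]
    scores: dict[str, pd.DataFrame]
    reference_scores: pd.DataFrame
    covariances: np.ndarray
    pseudo_eigenvalues: np.ndarray
    loadings: dict[str, pd.DataFrame]
    method: str = "coinertia"
    rv: float | None = None
    n_iterations: list[int] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": np.arange(1, len(self.covariances) + 1),
                "covariance": self.covariances,
                "pseudo_eigenvalue": self.pseudo_eigenvalues,
            }
        )


@dataclass
class ProcrustesResult:
    """Optimal superposition of configuration b onto configuration a."""

    m2: float
    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    permutation_p: float | None
    n_permutations: int
    seed: int | None

    def summary(self) -> str:
        p = "NA" if self.permutation_p is None else f"{self.permutation_p:.4g}"
        return (
            f"Procrustes m2 = {self.m2:.6g}; scale = {self.scale:.4g}; "
            f"PROTEST p = {p} ({self.n_permutations} permutations)"
        )


def _fix_axis_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude element is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def pca(
    layer: OmicsLayer,
    center: bool = True,
    scale: bool = False,
    n_axes: int | None = None,
) -> OrdinationResult:
    """Principal component analysis of one layer (uniform row weights 1/n)."""
    x = layer.values.copy()
    n, p = x.shape
    max_axes = min(n - 1 if center else n, p)
    if n_axes is None:
        n_axes = max_axes
    if n_axes > max_axes:
        raise ValueError(f"n_axes={n_axes} exceeds the rank bound {max_axes}")
    if center:
        x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        if (sd == 0).any():
            j = int(np.argwhere(sd == 0)[0][0])
            raise ValueError(
                f"zero-variance feature {layer.feature_ids[j]!r} cannot be scaled"
            )
        x /= sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / n
    total = eig.sum()
    signs = _fix_axis_signs(vt.T)
    coords = (u * s) * signs
    loadings = vt.T * signs
    coords = coords[:, :n_axes]
    loadings = loadings[:, :n_axes]
    axes = [f"PC{i+1}" for i in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=layer.sample_ids, columns=axes),
        eigenvalues=eig[:n_axes],
        explained_fraction=eig[:n_axes] / total if total > 0 else eig[:n_axes],
        loadings=pd.DataFrame(loadings, index=layer.feature_ids, columns=axes),
        method="pca",
    )


def distance(layer: OmicsLayer, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise sample distances: euclidean, bray-curtis, or jaccard."""
    x = layer.values
    if metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    elif metric == "bray-curtis":
        if (x < 0).any():
            raise ValueError("bray-curtis requires nonnegative values")
        d = squareform(pdist(x, metric="braycurtis"))
        d = np.nan_to_num(d, nan=0.0)  # two all-zero samples: define d = 0
    elif metric == "jaccard":
        if (x < 0).any():
            raise ValueError("jaccard requires nonnegative values")
        d = squareform(pdist(x > 0, metric="jaccard"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(sample_ids=layer.sample_ids, values=d, metric=metric)


def _double_center(d: np.ndarray) -> np.ndarray:
    d2 = d**2
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    return -0.5 * (d2 - row - col + d2.mean())


def pcoa(
    dist: DistanceMatrix, correction: str = "none", n_axes: int | None = None
) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    ``correction="constant-shift"`` adds the smallest constant to every
    off-diagonal distance that makes the embedding eigenvalues nonnegative
    (Cailliez-style, found by bisection on the eigenvalue bound).
    """
    d = dist.values.copy()
    n = d.shape[0]
    if correction not in ("none", "constant-shift"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "constant-shift":
        d = _constant_shift(d)
    b = _double_center(d)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # eigenvalues on the 1/n scale so Euclidean PCoA matches the PCA spectrum
    eigval_scaled = eigval / n
    positive = eigval > max(1e-10 * abs(eigval).max(initial=1.0), 1e-12)
    n_pos = int(positive.sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(np.maximum(eigval[:n_axes], 0.0))
    coords *= _fix_axis_signs(coords) if n_axes else 1.0
    pos_total = eigval_scaled[positive].sum()
    frac = (
        eigval_scaled[:n_axes] / pos_total if pos_total > 0 else np.zeros(n_axes)
    )
    axes = [f"PCo{i+1}" for i in range(n_axes)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.sample_ids, columns=axes),
        eigenvalues=eigval_scaled,
        explained_fraction=frac,
        method="pcoa",
    )


def _constant_shift(d: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Smallest additive constant on off-diagonal distances giving a
    nonnegative embedding spectrum, by bisection."""
    off = ~np.eye(d.shape[0], dtype=bool)

    def min_eig(c: float) -> float:
        dc = d.copy()
        dc[off] += c
        return float(np.linalg.eigvalsh(_double_center(dc)).min())

    if min_eig(0.0) >= -tol:
        return d
    lo, hi = 0.0, 1.0
    while min_eig(hi) < -tol:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("constant-shift search failed to bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if min_eig(mid) < -tol:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(hi, 1.0):
            break
    out = d.copy()
    out[off] += hi
    return out


def _centered_values(layer: OmicsLayer) -> np.ndarray:
    x = layer.values
    return x - x.mean(axis=0)


def coinertia(
    layer_a: OmicsLayer, layer_b: OmicsLayer, n_axes: int = 2
) -> CoInertiaResult:
    """Pairwise co-inertia analysis of two layers on the same samples.

    Axes come from the SVD of the cross-product of the centred tables; the
    axis-k covariance is the k-th singular value divided by n.
    """
    if layer_a.sample_ids != layer_b.sample_ids:
        raise ValueError("layers must share the same samples in the same order")
    xa = _centered_values(layer_a)
    xb = _centered_values(layer_b)
    n = xa.shape[0]
    max_axes = min(xa.shape[1], xb.shape[1], n - 1)
    n_axes = min(n_axes, max_axes)
    u, s, vt = np.linalg.svd(xa.T @ xb, full_matrices=False)
    u, v = u[:, :n_axes], vt[:n_axes].T
    signs = _fix_axis_signs(np.vstack([u, v]))
    u, v = u * signs, v * signs
    cov = s[:n_axes] / n
    axes = [f"Axis{i+1}" for i in range(n_axes)]
    scores = {
        layer_a.name: pd.DataFrame(xa @ u, index=layer_a.sample_ids, columns=axes),
        layer_b.name: pd.DataFrame(xb @ v, index=layer_b.sample_ids, columns=axes),
    }
    ref = _reference_from_scores(
        [scores[nm].to_numpy() for nm in (layer_a.name, layer_b.name)]
    )
    # RV coefficient: global similarity of the two configurations
    rv = _rv_coefficient(xa, xb)
    return CoInertiaResult(
        layer_names=[layer_a.name, layer_b.name],
        scores=scores,
        reference_scores=pd.DataFrame(ref, index=layer_a.sample_ids, columns=axes),
        covariances=cov,
        pseudo_eigenvalues=cov**2,
        loadings={
            layer_a.name: pd.DataFrame(u, index=layer_a.feature_ids, columns=axes),
            layer_b.name: pd.DataFrame(v, index=layer_b.feature_ids, columns=axes),
        },
        method="coinertia",
        rv=rv,
    )


def _rv_coefficient(xa: np.ndarray, xb: np.ndarray) -> float:
    wa, wb = xa @ xa.T, xb @ xb.T
    denom = np.sqrt((wa * wa).sum() * (wb * wb).sum())
    return float((wa * wb).sum() / denom) if denom > 0 else float("nan")


def _reference_from_scores(score_list: list[np.ndarray]) -> np.ndarray:
    """Per axis, the unit vector maximising the summed squared covariance
    with the table scores: leading eigenvector of the scores' outer products."""
    n_axes = score_list[0].shape[1]
    ref = np.empty((score_list[0].shape[0], n_axes))
    for ax in range(n_axes):
        t = np.column_stack([s[:, ax] for s in score_list])
        u, sv, _ = np.linalg.svd(t, full_matrices=False)
        vec = u[:, 0]
        if vec @ t.sum(axis=1) < 0:
            vec = -vec
        ref[:, ax] = vec * sv[0] / np.sqrt(len(score_list))
    return ref


def _inertia_normalize(x: np.ndarray) -> np.ndarray:
    ss = np.sqrt((x**2).sum())
    if ss == 0:
        raise ValueError("table with zero total inertia")
    return x / ss


def mcia(
    layers: list[OmicsLayer],
    n_axes: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> CoInertiaResult:
    """Multiple co-inertia analysis of 2-3 layers.

    Each table is centred and scaled to unit total inertia. Per axis, unit
    feature-weight vectors ``w_k`` maximise the summed squared pairwise
    covariance between table scores ``X_k w_k`` (alternating power updates,
    initialised from the merged-table SVD, deflating each table by its own
    weight vector between axes). With two tables this is exactly pairwise
    co-inertia. The reported per-axis covariance is the root of the summed
    squared pairwise covariances, so the K=2 value equals the CIA covariance.
    """
    if not 2 <= len(layers) <= 3:
        raise ValueError("mcia requires 2 or 3 layers")
    names = [ly.name for ly in layers]
    if len(set(names)) != len(names):
        raise ValueError("layer names must be unique")
    sample_ids = layers[0].sample_ids
    for ly in layers[1:]:
        if ly.sample_ids != sample_ids:
            raise ValueError("layers must share the same samples in the same order")
    tables = [_inertia_normalize(_centered_values(ly)) for ly in layers]
    n = tables[0].shape[0]
    k = len(tables)
    max_axes = min([t.shape[1] for t in tables] + [n - 1])
    n_axes = min(n_axes, max_axes)

    work = [t.copy() for t in tables]
    weights = [np.empty((t.shape[1], n_axes)) for t in tables]
    covs = np.empty(n_axes)
    iters: list[int] = []
    for ax in range(n_axes):
        w = _mcoa_axis(work, tol, max_iter, iters)
        scores = [work[i] @ w[i] for i in range(k)]
        pair_cov2 = sum(
            (scores[i] @ scores[j] / n) ** 2
            for i in range(k)
            for j in range(i + 1, k)
        )
        covs[ax] = np.sqrt(pair_cov2)
        for i in range(k):
            weights[i][:, ax] = w[i]
            # deflate: remove the direction used on this axis
            work[i] = work[i] - (work[i] @ w[i])[:, None] * w[i][None, :]

    axes = [f"Axis{i+1}" for i in range(n_axes)]
    # sign convention per axis over the stacked loadings
    stacked = np.vstack(weights)
    signs = _fix_axis_signs(stacked)
    weights = [w * signs for w in weights]
    scores = {
        names[i]: pd.DataFrame(tables[i] @ weights[i], index=sample_ids, columns=axes)
        for i in range(k)
    }
    ref = _reference_from_scores([scores[nm].to_numpy() for nm in names])
    return CoInertiaResult(
        layer_names=names,
        scores=scores,
        reference_scores=pd.DataFrame(ref, index=sample_ids, columns=axes),
        covariances=covs,
        pseudo_eigenvalues=covs**2,
        loadings={
            names[i]: pd.DataFrame(
                weights[i], index=layers[i].feature_ids, columns=axes
            )
            for i in range(k)
        },
        method="mcia",
        n_iterations=iters,
    )


def _mcoa_axis(
    work: list[np.ndarray], tol: float, max_iter: int, iters: list[int]
) -> list[np.ndarray]:
    """One MAXDIFF axis: alternating updates of the per-table weights."""
    k = len(work)
    n = work[0].shape[0]
    # deterministic init: left singular vector of the merged table, projected
    merged = np.hstack(work)
    u0 = np.linalg.svd(merged, full_matrices=False)[0][:, 0]
    w = []
    for x in work:
        wx = x.T @ u0
        norm = np.linalg.norm(wx)
        if norm < 1e-300:
            wx = np.zeros(x.shape[1])
            wx[0] = 1.0
        else:
            wx = wx / norm
        w.append(wx)
    scores = [work[i] @ w[i] for i in range(k)]
    for it in range(max_iter):
        delta = 0.0
        for i in range(k):
            # weighted sum of the other tables' scores, weights = covariances
            target = np.zeros(n)
            for j in range(k):
                if j == i:
                    continue
                target += (scores[i] @ scores[j] / n) * scores[j]
            wi = work[i].T @ target
            norm = np.linalg.norm(wi)
            if norm > 1e-300:
                wi = wi / norm
                if wi @ w[i] < 0:  # sign-align before measuring the update
                    wi = -wi
                delta = max(delta, np.abs(wi - w[i]).max())
                w[i] = wi
                scores[i] = work[i] @ w[i]
        if delta <= tol:
            break
    iters.append(it + 1)
    return w


def extract_drivers(
    res: CoInertiaResult, layer: str, axis: int = 1, top_n: int | None = None
) -> pd.DataFrame:
    """Features of one layer ranked by |loading| on an axis (1-based).

    Ties in |loading| break by feature id; ``top_n=None`` returns all.
    """
    if layer not in res.loadings:
        raise KeyError(f"unknown layer {layer!r}; have {list(res.loadings)}")
    load = res.loadings[layer]
    if not 1 <= axis <= load.shape[1]:
        raise ValueError(f"axis {axis} out of range 1..{load.shape[1]}")
    col = load.iloc[:, axis - 1]
    order = sorted(col.index, key=lambda f: (-abs(col[f]), str(f)))
    out = pd.DataFrame(
        {"feature": order, "loading": col.loc[order].to_numpy()}
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if top_n is not None:
        out = out.head(top_n)
    return out


def _procrustes_m2(xa: np.ndarray, xb: np.ndarray) -> float:
    s = np.linalg.svd(xa.T @ xb, compute_uv=False)
    denom = (xa**2).sum() * (xb**2).sum()
    if denom == 0:
        return 0.0
    return float(max(0.0, 1.0 - s.sum() ** 2 / denom))


def procrustes(
    ord_a,
    ord_b,
    n_axes: int | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Procrustes superposition of two ordinations and the PROTEST test.

    ``ord_a``/``ord_b`` are :class:`OrdinationResult` objects or coordinate
    DataFrames over the same samples in the same order. ``m2`` is the
    residual after optimal translation, scaling and rotation of b onto a,
    normalised to [0, 1]; the permutation p-value permutes the rows of b.
    """
    a = ord_a.coordinates if isinstance(ord_a, OrdinationResult) else ord_a
    b = ord_b.coordinates if isinstance(ord_b, OrdinationResult) else ord_b
    if list(a.index) != list(b.index):
        raise ValueError("ordinations must cover the same samples in order")
    if len(a.index) < 3:
        raise ValueError("procrustes needs at least 3 samples")
    if n_axes is None:
        n_axes = min(a.shape[1], b.shape[1])
    xa = a.to_numpy(dtype=float)[:, :n_axes]
    xb = b.to_numpy(dtype=float)[:, :n_axes]
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    xa_c, xb_c = xa - mean_a, xb - mean_b
    u, s, vt = np.linalg.svd(xa_c.T @ xb_c)
    rotation = vt.T @ u.T  # maps centred b onto centred a: xb_c @ rotation
    ssb = (xb_c**2).sum()
    scale = s.sum() / ssb if ssb > 0 else 1.0
    translation = mean_a - scale * (mean_b @ rotation)
    m2 = _procrustes_m2(xa_c, xb_c)

    permutation_p = None
    if n_permutations > 0:
        if seed is None:
            raise ValueError("a seed is required for the permutation test")
        rng = np.random.default_rng(seed)
        count = 0
        n = xa_c.shape[0]
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            xb_p = xb[perm] - xb[perm].mean(axis=0)
            if _procrustes_m2(xa_c, xb_p) <= m2:
                count += 1
        permutation_p = (1 + count) / (n_permutations + 1)
    return ProcrustesResult(
        m2=m2,
        rotation=rotation,
        scale=float(scale),
        translation=translation,
        permutation_p=permutation_p,
        n_permutations=n_permutations,
        seed=seed,
    )
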