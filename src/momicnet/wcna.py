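"""Per-layer weighted correlation network analysis.

The workflow mirrors the standard weighted co-expression framework: a
feature-feature correlation matrix is raised to a soft-threshold power
(chosen so the network's degree distribution approximates scale-free
topology), converted to a topological overlap matrix (TOM), and clustered
by average linkage into modules of tightly co-varying features. Each module
is summarised by its eigengene — the first principal component of its
standardized feature profiles — which is then correlated with the external
sample parameters.

The high-level entry point is the :class:`WCNA` model object::

    model = WCNA(layer, params=NetworkParams(network_type="unsigned"))
    result = model.fit(power="auto")
    report = result.trait_correlation(annotation)

while each step is also exposed as a standalone function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._stats import bh_adjust, correlation_pvalues, cross_correlation
from .preprocess import AnnotationTable, OmicsLayer

__all__ = [
    "NetworkParams",
    "SoftThresholdReport",
    "ModulePartition",
    "ModuleTraitReport",
    "WCNA",
    "WCNAResults",
    "feature_correlation",
    "adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "merge_close_modules",
    "module_trait_correlation",
    "sample_contributions",
    "module_membership",
]

# display names for module ids; "grey" is reserved for unassigned (id 0)
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

DEFAULT_POWER_CANDIDATES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20, 22, 24)


@dataclass
class NetworkParams:
    """Tunable knobs of the network construction."""

    correlation: str = "pearson"
    network_type: str = "unsigned"
    power: float = 6.0
    min_module_size: int = 5
    cut_height: float = 0.9999
    merge_cut: float = 0.25

    def __post_init__(self) -> None:
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError(f"unknown network type {self.network_type!r}")
        if self.power < 1:
            raise ValueError("soft-threshold power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValueError("cut_height must be in (0, 1]")
        if not 0.0 <= self.merge_cut < 1.0:
            raise ValueError("merge_cut must be in [0, 1)")


@dataclass
class SoftThresholdReport:
    """Scale-free fit statistics per candidate power."""

    table: pd.DataFrame  # columns: power, r2, slope, mean_k, median_k, max_k
    chosen_power: float | None
    r2_target: float

    def summary(self) -> pd.DataFrame:
        return self.table


@dataclass
class ModulePartition:
    """Module labels per feature; 0 = unassigned ("grey")."""

    feature_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.feature_ids) != len(self.labels):
            raise ValueError("feature_ids and labels length mismatch")

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in np.unique(self.labels) if m > 0)

    @property
    def colors(self) -> list[str]:
        return [self.color_of(m) for m in self.labels]

    @staticmethod
    def color_of(module_id: int) -> str:
        if module_id == 0:
            return "grey"
        return MODULE_COLORS[(module_id - 1) % len(MODULE_COLORS)]

    def members(self, module_id: int) -> list[str]:
        return [f for f, m in zip(self.feature_ids, self.labels) if m == module_id]

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_ids, "module": self.labels, "color": self.colors}
        )


@dataclass
class ModuleTraitReport:
    """Module-eigengene vs trait correlations with t-test p and BH q."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: int

    def to_long(self) -> pd.DataFrame:
        rows = []
        for module in self.r.index:
            for trait in self.r.columns:
                rows.append(
                    {
                        "module": module,
                        "trait": trait,
                        "r": self.r.loc[module, trait],
                        "p": self.p.loc[module, trait],
                        "q": self.q.loc[module, trait],
                        "n": self.n,
                    }
                )
        return pd.DataFrame(rows)


def feature_correlation(layer: OmicsLayer, method: str = "pearson") -> pd.DataFrame:
    """Feature-feature correlation matrix (symmetric, unit diagonal)."""
    if layer.n_samples < 3:
        raise ValueError("need at least 3 samples for feature correlations")
    sd = layer.values.std(axis=0)
    if (sd == 0).any():
        j = int(np.argwhere(sd == 0)[0][0])
        raise ValueError(f"zero-variance feature {layer.feature_ids[j]!r}")
    r = cross_correlation(layer.values, layer.values, method=method)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=layer.feature_ids, columns=layer.feature_ids)


def adjacency(corr, params: NetworkParams) -> np.ndarray:
    """Soft-thresholded adjacency: ``|r|^beta`` (unsigned) or ``((1+r)/2)^beta``."""
    r = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if params.power < 1:
        raise ValueError("power must be >= 1")
    if params.network_type == "unsigned":
        a = np.abs(r) ** params.power
    else:
        a = ((1.0 + r) / 2.0) ** params.power
    np.fill_diagonal(a, 1.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of the log-log degree-distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    are dropped; log10(mean frequency) is regressed on log10(mean bin
    connectivity). The R^2 is signed by the negated slope so networks whose
    frequency *increases* with degree score negatively.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        center = k[mask].mean()
        freq = mask.mean()
        if center <= 0 or freq <= 0:
            continue
        xs.append(np.log10(center))
        ys.append(np.log10(freq))
    if len(xs) < 2:
        return float("nan"), float("nan")
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    corr,
    params: NetworkParams | None = None,
    candidates=DEFAULT_POWER_CANDIDATES,
    r2_target: float = 0.8,
) -> SoftThresholdReport:
    """Scan candidate powers and pick the smallest reaching the scale-free
    fit target (else the best-fitting one, with a warning)."""
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate powers")
    params = params or NetworkParams()
    rows = []
    for beta in candidates:
        a = adjacency(corr, replace(params, power=float(beta)))
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        rows.append(
            {
                "power": float(beta),
                "r2": r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= r2_target]
    if len(ok):
        chosen = float(ok.iloc[0]["power"])
    else:
        finite = table[np.isfinite(table["r2"])]
        if len(finite):
            chosen = float(finite.loc[finite["r2"].idxmax(), "power"])
            warnings.warn(
                f"no candidate power reached scale-free R^2 >= {r2_target}; "
                f"using best fit (power={chosen})",
                stacklevel=2,
            )
        else:
            chosen = None
            warnings.warn(
                "scale-free fit undefined for every candidate power", stacklevel=2
            )
    return SoftThresholdReport(table=table, chosen_power=chosen, r2_target=r2_target)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbour similarity of an adjacency matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` over ``u != i, j`` and ``k_i`` the connectivity
    of node i (diagonal excluded). Diagonal is 1.
    """
    a = np.asarray(adj, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(a - a.T).max(initial=0.0) > 1e-10:
        raise ValueError("adjacency must be symmetric (within 1e-10)")
    if a.min(initial=0.0) < -1e-12 or a.max(initial=0.0) > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # with zero diagonal, u = i and u = j terms vanish
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = num / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray, params: NetworkParams, feature_ids: list[str] | None = None
) -> ModulePartition:
    """Cluster 1-TOM by average linkage and cut the tree at a static height.

    The cut is at ``cut_height`` times the tallest merge. The default
    fraction is high (0.9999) because soft thresholding at large powers
    compresses topological overlap towards zero, pushing all merge heights
    close to 1: module joins still sit visibly above within-module merges,
    but only in the last fraction of the height range. Clusters smaller
    than ``min_module_size`` are left unassigned (label 0); surviving
    clusters are renumbered 1..K by decreasing size (ties by first feature).
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n)]
    if params.min_module_size > n:
        warnings.warn("min_module_size exceeds feature count; all unassigned",
                      stacklevel=2)
        return ModulePartition(feature_ids, np.zeros(n, dtype=int))
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.maximum((diss + diss.T) / 2.0, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    max_height = z[:, 2].max() if len(z) else 0.0
    if max_height == 0.0:
        raw = np.ones(n, dtype=int)
    else:
        raw = fcluster(z, t=params.cut_height * max_height, criterion="distance")
    return _relabel_by_size(raw, params.min_module_size, feature_ids)


def _relabel_by_size(
    raw: np.ndarray, min_size: int, feature_ids: list[str]
) -> ModulePartition:
    labels = np.zeros(len(raw), dtype=int)
    clusters = []
    for c in np.unique(raw):
        members = np.where(raw == c)[0]
        if len(members) >= min_size:
            clusters.append((len(members), members[0], c, members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for new_id, (_, _, _, members) in enumerate(clusters, start=1):
        labels[members] = new_id
    return ModulePartition(feature_ids, labels)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengenes(layer: OmicsLayer, partition: ModulePartition) -> pd.DataFrame:
    """First principal component of each module's standardized profiles.

    Each eigengene is scaled to unit variance and sign-flipped so it
    correlates nonnegatively with the module's mean standardized profile.
    Columns are named ``ME<id>``; module 0 (unassigned) is skipped.
    """
    if partition.feature_ids != layer.feature_ids:
        layer = layer.subset_features(partition.feature_ids)
    cols = {}
    for m in partition.module_ids:
        members = partition.members(m)
        sub = _standardize(layer.data[members].to_numpy(dtype=float))
        if sub.shape[1] == 1:
            eig = sub[:, 0]
        else:
            u, s, _ = np.linalg.svd(sub, full_matrices=False)
            eig = u[:, 0]
        sd = eig.std(ddof=1)
        if sd > 0:
            eig = eig / sd
        mean_profile = sub.mean(axis=1)
        if np.dot(eig, mean_profile - mean_profile.mean()) < 0:
            eig = -eig
        cols[f"ME{m}"] = eig
    return pd.DataFrame(cols, index=layer.sample_ids)


def merge_close_modules(
    layer: OmicsLayer,
    partition: ModulePartition,
    merge_cut: float = 0.25,
) -> tuple[ModulePartition, pd.DataFrame]:
    """Iteratively merge modules whose eigengene dissimilarity 1-r is below
    ``merge_cut``, recomputing eigengenes after every merge.

    Returns the merged partition (ids renumbered by decreasing size) and its
    eigengene matrix.
    """
    labels = partition.labels.copy()
    while True:
        part = ModulePartition(partition.feature_ids, labels)
        eig = module_eigengenes(layer, part)
        ids = part.module_ids
        if len(ids) < 2 or merge_cut <= 0:
            return _renumber(part), eig
        corr = np.corrcoef(eig.to_numpy().T)
        best = None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                diss = 1.0 - corr[i, j]
                if diss < merge_cut and (best is None or diss < best[0]):
                    best = (diss, ids[i], ids[j])
        if best is None:
            return _renumber(part), eig
        _, keep, drop = best
        labels[labels == drop] = keep


def _renumber(part: ModulePartition) -> ModulePartition:
    sizes = part.sizes()
    firsts = {m: np.argmax(part.labels == m) for m in sizes}
    order = sorted(sizes, key=lambda m: (-sizes[m], firsts[m]))
    mapping = {m: i + 1 for i, m in enumerate(order)}
    mapping[0] = 0
    new = np.array([mapping[m] for m in part.labels], dtype=int)
    return ModulePartition(part.feature_ids, new)


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    annotation: AnnotationTable,
    method: str = "pearson",
) -> ModuleTraitReport:
    """Correlate every eigengene with every trait column.

    Quantitative traits are used directly; qualitative traits are expanded
    to one indicator column per level (point-biserial correlation). P-values
    come from the t distribution with n-2 df; BH correction is applied
    jointly across the whole module-by-trait grid. Constant trait columns
    yield NaN.
    """
    if list(eigengenes.index) != list(annotation.sample_ids):
        raise ValueError("eigengenes and annotation must share sample order")
    traits = annotation.numeric_view()
    n = len(eigengenes.index)
    r = cross_correlation(eigengenes.to_numpy(), traits.to_numpy(), method=method)
    p = correlation_pvalues(r, n)
    q = bh_adjust(p)
    idx, cols = list(eigengenes.columns), list(traits.columns)
    return ModuleTraitReport(
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        n=n,
    )


def sample_contributions(
    eigengenes: pd.DataFrame,
    module: int,
    annotation: AnnotationTable | None = None,
    trait: str | None = None,
) -> pd.DataFrame:
    """Per-sample eigengene value of one module, paired with a trait.

    This is the data behind the sample-contribution bar plot: samples with
    positive values drive the module's definition, negative values oppose it.
    """
    col = f"ME{module}"
    if col not in eigengenes.columns:
        raise KeyError(f"unknown module {module}; have {list(eigengenes.columns)}")
    out = pd.DataFrame(
        {"sample": eigengenes.index, "contribution": eigengenes[col].to_numpy()}
    )
    if trait is not None:
        if annotation is None:
            raise ValueError("annotation required when a trait is requested")
        if trait not in annotation.columns:
            raise KeyError(f"unknown trait {trait!r}")
        out[trait] = annotation.data[trait].to_numpy()
    return out


def module_membership(layer: OmicsLayer, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: correlation of each feature with each module eigengene."""
    r = cross_correlation(layer.values, eigengenes.to_numpy())
    return pd.DataFrame(r, index=layer.feature_ids, columns=eigengenes.columns)


class WCNA:
    """Weighted correlation network model for one omics layer.

    Parameters
    ----------
    layer : OmicsLayer
        Transformed sample-by-feature table (CLR'd counts, log'd intensities...).
    params : NetworkParams, optional
        Network construction knobs; defaults follow the unsigned convention.
    """

    def __init__(self, layer: OmicsLayer, params: NetworkParams | None = None):
        self.layer = layer
        self.params = params or NetworkParams()

    def fit(
        self,
        power: float | str = "auto",
        candidates=DEFAULT_POWER_CANDIDATES,
        r2_target: float = 0.8,
        merge: bool = True,
    ) -> "WCNAResults":
        """Run correlation -> adjacency -> TOM -> modules -> eigengenes.

        ``power="auto"`` scans ``candidates`` for the smallest power whose
        degree distribution reaches the scale-free fit target, falling back
        to the default power when the scan is inconclusive.
        """
        corr = feature_correlation(self.layer, self.params.correlation)
        report = None
        params = self.params
        if power == "auto":
            report = pick_soft_threshold(corr, params, candidates, r2_target)
            chosen = report.chosen_power
            params = replace(params, power=chosen if chosen else params.power)
        else:
            params = replace(params, power=float(power))
        adj = adjacency(corr, params)
        tom = tom_similarity(adj)
        partition = detect_modules(tom, params, self.layer.feature_ids)
        if merge and params.merge_cut > 0 and len(partition.module_ids) >= 2:
            partition, eigengenes = merge_close_modules(
                self.layer, partition, params.merge_cut
            )
        else:
            eigengenes = module_eigengenes(self.layer, partition)
        return WCNAResults(
            layer=self.layer,
            params=params,
            correlation=corr,
            adjacency=adj,
            tom=tom,
            partition=partition,
            eigengenes=eigengenes,
            power_report=report,
        )


@dataclass
class WCNAResults:
    """Fitted network for one layer: modules, eigengenes and diagnostics."""

    layer: OmicsLayer
    params: NetworkParams
    correlation: pd.DataFrame
    adjacency: np.ndarray
    tom: np.ndarray
    partition: ModulePartition
    eigengenes: pd.DataFrame
    power_report: SoftThresholdReport | None = None

    def trait_correlation(
        self, annotation: AnnotationTable, method: str = "pearson"
    ) -> ModuleTraitReport:
        return module_trait_correlation(self.eigengenes, annotation, method)

    def membership(self) -> pd.DataFrame:
        return module_membership(self.layer, self.eigengenes)

    def edge_list(self, cutoff: float = 0.0) -> pd.DataFrame:
        """Feature pairs with TOM above ``cutoff`` (upper triangle)."""
        ids = self.layer.feature_ids
        iu, ju = np.triu_indices(len(ids), k=1)
        w = self.tom[iu, ju]
        keep = w > cutoff
        return pd.DataFrame(
            {
                "feature_a": np.asarray(ids)[iu[keep]],
                "feature_b": np.asarray(ids)[ju[keep]],
                "tom": w[keep],
            }
        )

    def summary(self) -> pd.DataFrame:
        sizes = self.partition.sizes()
        rows = [
            {
                "module": m,
                "color": ModulePartition.color_of(m),
                "n_features": sizes[m],
            }
            for m in self.partition.module_ids
        ]
        rows.append(
            {
                "module": 0,
                "color": "grey",
                "n_features": int((self.partition.labels == 0).sum()),
            }
        )
        df = pd.DataFrame(rows)
        df.attrs["power"] = self.params.power
        df.attrs["layer"] = self.layer.name
        return df
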