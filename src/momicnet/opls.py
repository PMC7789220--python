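"""Orthogonal partial least squares (OPLS / OPLS-DA) with VIP scores.

Used to cross-validate a module-trait association: the module's features
predict the trait through a single predictive component after removal of
``n_orth`` components of X-variation orthogonal to the response
(orthogonal signal correction, NIPALS form). Qualitative responses are
dummy-coded (the discriminant variant). Each feature's importance in the
projection (VIP) is reported, normalised so that the squared scores sum to
the number of features.

The entry point follows the endog/exog Model convention::

    model = OPLS(y, X, n_orth=1)
    res = model.fit()
    res.vip()          # VIP per feature
    res.q2(k_folds=7, seed=1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import cross_correlation
from .preprocess import AnnotationTable, OmicsLayer
from .wcna import ModulePartition

__all__ = [
    "OPLS",
    "OPLSResults",
    "opls_fit",
    "vip_scores",
    "opls_cross_validate",
    "module_opls_validation",
]


def _dummy_code(y) -> tuple[np.ndarray, list[str]]:
    series = pd.Series(np.asarray(y).ravel())
    levels = sorted(series.dropna().unique(), key=str)
    if len(levels) < 2:
        raise ValueError("qualitative response needs >= 2 observed levels")
    cols = np.column_stack([(series == lv).to_numpy(float) for lv in levels])
    return cols, [str(lv) for lv in levels]


@dataclass
class _Scaler:
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


def _fit_scaler(x: np.ndarray) -> _Scaler:
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return _Scaler(mean=x.mean(axis=0), sd=sd)


def _predictive_weight(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit y-related weight vector; for multi-column y, the first left
    singular vector of X'Y (the NIPALS PLS2 limit)."""
    c = x.T @ y
    if c.ndim == 1 or c.shape[1] == 1:
        w = c.ravel()
    else:
        w = np.linalg.svd(c, full_matrices=False)[0][:, 0]
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("response is uncorrelated with every feature")
    return w / norm


class OPLS:
    """Orthogonal PLS model with one predictive component.

    Parameters
    ----------
    endog : array-like
        Response: numeric values (quantitative) or labels (qualitative).
    exog : array-like or DataFrame
        Sample-by-feature matrix; standardized internally.
    n_orth : int
        Number of orthogonal (y-unrelated) components to strip from X.
    y_type : str
        ``"quantitative"`` (centred, unit variance) or ``"qualitative"``
        (dummy-coded indicator columns, centred only).
    """

    def __init__(self, endog, exog, n_orth: int = 1, y_type: str = "quantitative"):
        exog = pd.DataFrame(exog)
        self.feature_ids = [str(c) for c in exog.columns]
        self.x_raw = exog.to_numpy(dtype=float)
        if self.x_raw.shape[0] < 5:
            raise ValueError("OPLS needs at least 5 samples")
        if y_type not in ("quantitative", "qualitative"):
            raise ValueError(f"unknown y_type {y_type!r}")
        self.y_type = y_type
        if y_type == "qualitative":
            self.y_raw, self.y_levels = _dummy_code(endog)
        else:
            self.y_raw = np.asarray(endog, dtype=float).reshape(len(exog), -1)
            self.y_levels = None
            if np.ptp(self.y_raw, axis=0).min() == 0:
                raise ValueError("constant response: OPLS undefined")
        if self.y_raw.shape[0] != self.x_raw.shape[0]:
            raise ValueError("endog and exog must have the same sample count")
        if n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        rank = np.linalg.matrix_rank(self.x_raw - self.x_raw.mean(axis=0))
        if n_orth >= rank:
            raise ValueError(f"n_orth={n_orth} must be below rank(X)={rank}")
        self.n_orth = n_orth

    # -- internal fitting on pre-scaled arrays (shared with CV) ------------

    @staticmethod
    def _nipals_osc(x: np.ndarray, y: np.ndarray, n_orth: int):
        """Orthogonal signal correction then one predictive component."""
        orth = []
        for _ in range(n_orth):
            w = _predictive_weight(x, y)
            t = x @ w
            p = x.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:
                break  # no orthogonal variation left
            w_o /= norm
            t_o = x @ w_o
            p_o = x.T @ t_o / (t_o @ t_o)
            x = x - np.outer(t_o, p_o)
            orth.append((w_o, t_o, p_o))
        w = _predictive_weight(x, y)
        t = x @ w
        p = x.T @ t / (t @ t)
        q = y.T @ t / (t @ t)  # per-response regression of y on t
        return x, w, t, p, q, orth

    def fit(self) -> "OPLSResults":
        scaler_x = _fit_scaler(self.x_raw)
        x = scaler_x.apply(self.x_raw)
        y_mean = self.y_raw.mean(axis=0)
        if self.y_type == "quantitative":
            y_sd = self.y_raw.std(axis=0, ddof=1)
            y_sd = np.where(y_sd == 0, 1.0, y_sd)
        else:
            y_sd = np.ones(self.y_raw.shape[1])  # dummies: centre only
        y = (self.y_raw - y_mean) / y_sd
        x_filt, w, t, p, q, orth = self._nipals_osc(x, y, self.n_orth)
        resid = y - np.outer(t, q)
        ssy = (y**2).sum()
        r2y = 1.0 - (resid**2).sum() / ssy if ssy > 0 else 0.0
        return OPLSResults(
            model=self,
            weights=w,
            scores=t,
            loadings=p,
            y_loadings=q,
            orthogonal=orth,
            r2y=float(max(0.0, r2y)),
            _scaler_x=scaler_x,
            _y_mean=y_mean,
            _y_sd=y_sd,
        )


@dataclass
class OPLSResults:
    """Fitted OPLS model: one predictive + ``n_orth`` orthogonal components."""

    model: OPLS
    weights: np.ndarray          # predictive weight vector w (unit norm)
    scores: np.ndarray           # predictive score t
    loadings: np.ndarray         # predictive X-loading p
    y_loadings: np.ndarray       # y-loading q (one per response column)
    orthogonal: list             # [(w_orth, t_orth, p_orth), ...]
    r2y: float
    _scaler_x: _Scaler
    _y_mean: np.ndarray
    _y_sd: np.ndarray

    @property
    def n_orth(self) -> int:
        return len(self.orthogonal)

    @property
    def orthogonal_scores(self) -> np.ndarray:
        if not self.orthogonal:
            return np.empty((len(self.scores), 0))
        return np.column_stack([t for _, t, _ in self.orthogonal])

    def _filter_new(self, x: np.ndarray) -> np.ndarray:
        x = self._scaler_x.apply(x)
        for w_o, _, p_o in self.orthogonal:
            t_o = x @ w_o
            x = x - np.outer(t_o, p_o)
        return x

    def predict(self, exog) -> np.ndarray:
        """Predicted response on the original scale (dummy scale for DA)."""
        x = self._filter_new(np.asarray(pd.DataFrame(exog), dtype=float))
        t = x @ self.weights
        return np.outer(t, self.y_loadings) * self._y_sd + self._y_mean

    def vip(self) -> pd.DataFrame:
        """VIP per feature; with one predictive component the weight-share
        formula collapses to ``sqrt(p) * |w_j| / ||w||``, so sum(VIP^2) = p."""
        w = self.weights
        p_feat = len(w)
        vip = np.sqrt(p_feat) * np.abs(w) / np.linalg.norm(w)
        return pd.DataFrame({"feature": self.model.feature_ids, "vip": vip})

    def q2(self, k_folds: int = 7, seed: int = 0) -> float:
        return opls_cross_validate(
            self.model.x_raw,
            self.model.y_raw if self.model.y_type == "quantitative"
            else np.asarray(self.model.y_raw),
            n_orth=self.model.n_orth,
            k_folds=k_folds,
            seed=seed,
            y_type="preencoded" if self.model.y_type == "qualitative" else "quantitative",
        )

    def summary(self) -> str:
        lines = [
            "OPLS results",
            f"  samples: {self.model.x_raw.shape[0]}, features: {len(self.weights)}",
            f"  predictive components: 1, orthogonal: {self.n_orth}",
            f"  R2Y = {self.r2y:.4f}",
        ]
        if self.model.y_levels:
            lines.append(f"  response levels: {', '.join(self.model.y_levels)}")
        top = self.vip().sort_values("vip", ascending=False).head(5)
        lines.append("  top VIP features: "
                     + ", ".join(f"{f} ({v:.2f})" for f, v in
                                 zip(top["feature"], top["vip"])))
        return "\n".join(lines)


def opls_fit(
    X, y, n_orth: int = 1, y_type: str = "quantitative"
) -> OPLSResults:
    """Functional wrapper: fit an OPLS model and return its results."""
    return OPLS(y, X, n_orth=n_orth, y_type=y_type).fit()


def vip_scores(result: OPLSResults, trait_values=None) -> pd.DataFrame:
    """VIP report, optionally with each feature's correlation to the trait."""
    out = result.vip()
    if trait_values is not None:
        r = cross_correlation(
            result.model.x_raw, np.asarray(trait_values, float).reshape(-1, 1)
        )
        out["trait_r"] = r[:, 0]
    return out


def _fold_indices(n: int, k_folds: int, seed: int, strata=None) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    if strata is None:
        perm = rng.permutation(n)
        return [perm[i::k_folds] for i in range(k_folds)]
    folds: list[list[int]] = [[] for _ in range(k_folds)]
    strata = np.asarray(strata)
    for level in np.unique(strata):
        members = rng.permutation(np.where(strata == level)[0])
        for i, m in enumerate(members):
            folds[i % k_folds].append(m)
    return [np.array(sorted(f), dtype=int) for f in folds]


def opls_cross_validate(
    X,
    y,
    n_orth: int = 1,
    k_folds: int = 7,
    seed: int = 0,
    y_type: str = "quantitative",
) -> float:
    """Q2 = 1 - PRESS/SSY over seeded k-fold cross-validation.

    Qualitative responses are dummy-coded once and folds are stratified by
    class so every training split sees every level. Deterministic for a
    given seed.
    """
    x = np.asarray(pd.DataFrame(X), dtype=float)
    n = x.shape[0]
    if not 2 <= k_folds <= n:
        raise ValueError("k_folds must be in [2, n_samples]")
    strata = None
    if y_type == "qualitative":
        y_enc, _ = _dummy_code(y)
        strata = np.asarray(pd.Series(np.asarray(y).ravel()))
        scale_y = False
    elif y_type == "preencoded":
        y_enc = np.asarray(y, dtype=float).reshape(n, -1)
        strata = np.argmax(y_enc, axis=1)
        scale_y = False
    else:
        y_enc = np.asarray(y, dtype=float).reshape(n, -1)
        scale_y = True
    if y_type in ("qualitative", "preencoded"):
        counts = pd.Series(strata).value_counts()
        if counts.min() < k_folds and counts.min() < 2:
            raise ValueError("a class has too few samples to stratify folds")
    press = 0.0
    ssy = 0.0
    y_grand = y_enc.mean(axis=0)
    for test in _fold_indices(n, k_folds, seed, strata):
        train = np.setdiff1d(np.arange(n), test)
        x_tr, x_te = x[train], x[test]
        y_tr, y_te = y_enc[train], y_enc[test]
        scaler = _fit_scaler(x_tr)
        y_mean = y_tr.mean(axis=0)
        if scale_y:
            y_sd = y_tr.std(axis=0, ddof=1)
            y_sd = np.where(y_sd == 0, 1.0, y_sd)
        else:
            y_sd = np.ones(y_tr.shape[1])
        xt = scaler.apply(x_tr)
        yt = (y_tr - y_mean) / y_sd
        rank = np.linalg.matrix_rank(xt)
        k_orth = min(n_orth, max(rank - 1, 0))
        _, w, t, p, q, orth = OPLS._nipals_osc(xt, yt, k_orth)
        xe = scaler.apply(x_te)
        for w_o, _, p_o in orth:
            t_o = xe @ w_o
            xe = xe - np.outer(t_o, p_o)
        pred = np.outer(xe @ w, q) * y_sd + y_mean
        press += ((y_te - pred) ** 2).sum()
        ssy += ((y_te - y_grand) ** 2).sum()
    return float(1.0 - press / ssy) if ssy > 0 else float("nan")


def module_opls_validation(
    layer: OmicsLayer,
    partition: ModulePartition,
    module: int,
    adjacency: np.ndarray,
    annotation: AnnotationTable,
    trait: str,
    edge_cut: float = 0.1,
    n_orth: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, OPLSResults]:
    """Hive-plot data validating one module against one trait.

    Fits OPLS(-DA) with the module's features as predictors and returns
    (per-feature table with VIP and trait correlation, intra-module network
    edges with adjacency weight above ``edge_cut``, the fitted results).
    For qualitative traits the reported correlation is against the
    max-|r| indicator level.
    """
    members = partition.members(module)
    if len(members) < 3:
        raise ValueError("module must have at least 3 features for validation")
    if trait not in annotation.columns:
        raise KeyError(f"unknown trait {trait!r}")
    if layer.sample_ids != annotation.sample_ids:
        raise ValueError("layer and annotation must share sample order")
    x = layer.data[members]
    y_kind = annotation.kinds[trait]
    y = annotation.data[trait].to_numpy()
    res = OPLS(
        y, x, n_orth=n_orth,
        y_type="qualitative" if y_kind == "qualitative" else "quantitative",
    ).fit()
    table = res.vip()
    if y_kind == "qualitative":
        ind = annotation.indicator_columns(trait)
        r = cross_correlation(x.to_numpy(), ind.to_numpy())
        best = np.abs(np.nan_to_num(r)).mean(axis=0).argmax()
        table["trait_r"] = r[:, best]
        table.attrs["trait_column"] = str(ind.columns[best])
    else:
        r = cross_correlation(x.to_numpy(), y.reshape(-1, 1).astype(float))
        table["trait_r"] = r[:, 0]
        table.attrs["trait_column"] = trait

    # intra-module edges of the weighted network, above the display cutoff
    feat_index = {f: i for i, f in enumerate(layer.feature_ids)}
    idx = [feat_index[f] for f in members]
    sub = np.asarray(adjacency, dtype=float)[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(members), k=1)
    keep = sub[iu, ju] > edge_cut
    edges = pd.DataFrame(
        {
            "feature_a": np.asarray(members)[iu[keep]],
            "feature_b": np.asarray(members)[ju[keep]],
            "weight": sub[iu, ju][keep],
        }
    )
    return table, edges, res
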