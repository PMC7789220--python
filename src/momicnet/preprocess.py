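"""Loading, alignment, filtering and transformation of omics tables.

Every analysis in this package operates on :class:`OmicsLayer` objects —
sample-by-feature real matrices with named samples and features — together
with an :class:`AnnotationTable` of per-sample contextual parameters
(quantitative or qualitative) and, for compositional count layers
(OTU/ASV-like data), an optional :class:`TaxonomyTable` of per-feature
lineages.

The transformations offered here are the standard pre-network steps:
prevalence filtering, the centred log-ratio (CLR) transform for
compositional data, simple normalisations (``log2``, total-sum scaling,
per-feature unit variance), and connectivity-based outlier flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OmicsLayer",
    "AnnotationTable",
    "TaxonomyTable",
    "read_layer",
    "read_annotation",
    "read_taxonomy",
    "align_samples",
    "prevalence_filter",
    "clr_transform",
    "transform",
    "detect_outliers",
    "relative_abundance",
]


@dataclass
class OmicsLayer:
    """One omics table: samples in rows, features in columns.

    Parameters
    ----------
    name : str
        Layer label (e.g. ``"mrna"``, ``"proteins"``, ``"otus"``).
    data : pandas.DataFrame
        Real-valued matrix, index = sample ids, columns = feature ids.
    is_compositional : bool
        True for relative-count data (sequencing counts) that should be
        CLR-transformed before correlation-based analyses.
    """

    name: str
    data: pd.DataFrame
    is_compositional: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"layer {self.name!r}: duplicate sample ids {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"layer {self.name!r}: duplicate feature ids {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(self.data)
            raise ValueError(
                f"layer {self.name!r}: non-numeric value at "
                f"sample {bad[0]!r}, feature {bad[1]!r}"
            )
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"layer {self.name!r}: non-finite value at sample "
                f"{self.data.index[i]!r}, feature {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "OmicsLayer":
        return replace(self, data=self.data.loc[list(sample_ids)])

    def subset_features(self, feature_ids) -> "OmicsLayer":
        return replace(self, data=self.data.loc[:, list(feature_ids)])


def _first_non_numeric(df: pd.DataFrame) -> tuple:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return df.index[bad.to_numpy().argmax()], col
    return df.index[0], df.columns[0]


@dataclass
class AnnotationTable:
    """Per-sample contextual parameters.

    ``kinds`` tags each column ``"quantitative"`` or ``"qualitative"``;
    untagged columns are inferred from dtype (numeric -> quantitative).
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"annotation: duplicate sample ids {dups}")
        inferred = {}
        for col in self.data.columns:
            kind = self.kinds.get(col)
            if kind is None:
                kind = (
                    "quantitative"
                    if pd.api.types.is_numeric_dtype(self.data[col])
                    else "qualitative"
                )
            elif kind not in ("quantitative", "qualitative"):
                raise ValueError(f"annotation column {col!r}: unknown kind {kind!r}")
            inferred[col] = kind
        self.kinds = inferred

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids) -> "AnnotationTable":
        return AnnotationTable(self.data.loc[list(sample_ids)], dict(self.kinds))

    def indicator_columns(self, column: str) -> pd.DataFrame:
        """One 0/1 indicator column per observed level of a qualitative trait.

        Columns are named ``"<trait>=<level>"``; levels in sorted order.
        """
        if column not in self.data.columns:
            raise KeyError(f"unknown annotation column {column!r}")
        if self.kinds[column] == "quantitative":
            raise ValueError(f"column {column!r} is quantitative")
        series = self.data[column]
        levels = sorted(series.dropna().unique(), key=str)
        if len(levels) < 2:
            raise ValueError(
                f"qualitative column {column!r} needs >=2 observed levels, "
                f"found {len(levels)}"
            )
        out = {f"{column}={lv}": (series == lv).astype(float) for lv in levels}
        return pd.DataFrame(out, index=series.index)

    def numeric_view(self) -> pd.DataFrame:
        """All traits as numeric columns: quantitative as-is, qualitative
        expanded to per-level indicators."""
        parts = []
        for col in self.data.columns:
            if self.kinds[col] == "quantitative":
                parts.append(self.data[[col]].astype(float))
            else:
                parts.append(self.indicator_columns(col))
        return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=self.data.index)


@dataclass
class TaxonomyTable:
    """Feature lineages over an ordered list of ranks (Phylum ... Species).

    ``lineages`` is a feature-by-rank DataFrame; missing assignments are NaN
    and aggregate under ``"Unclassified"``.
    """

    lineages: pd.DataFrame
    ranks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ranks:
            self.ranks = list(self.lineages.columns)
        missing = [r for r in self.ranks if r not in self.lineages.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.lineages.index)


def _read_table(path, sep=None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_layer(
    path,
    orientation: str = "samples-in-rows",
    name: str | None = None,
    is_compositional: bool = False,
    sep: str | None = None,
) -> OmicsLayer:
    """Read a delimited omics table into an :class:`OmicsLayer`.

    The first column holds ids; ``orientation`` says whether rows are
    samples or features. The returned layer always has samples in rows.
    """
    if orientation not in ("samples-in-rows", "samples-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, sep=sep)
    if orientation == "samples-in-columns":
        df = df.T
    df.index.name = None
    df.columns.name = None
    if name is None:
        name = str(path)
    return OmicsLayer(name=name, data=df, is_compositional=is_compositional)


def read_annotation(path, kinds: dict[str, str] | None = None, sep=None) -> AnnotationTable:
    return AnnotationTable(_read_table(path, sep=sep), dict(kinds or {}))


def read_taxonomy(path, ranks: list[str] | None = None, sep=None) -> TaxonomyTable:
    return TaxonomyTable(_read_table(path, sep=sep), list(ranks or []))


def align_samples(
    layers: list[OmicsLayer], annotation: AnnotationTable | None = None
) -> tuple[list[OmicsLayer], AnnotationTable | None, dict[str, list[str]]]:
    """Restrict all layers (and the annotation) to their common samples.

    The canonical sample order is the order of appearance in the first
    layer. Returns the aligned objects plus a per-input report of dropped
    sample ids.
    """
    if not layers:
        raise ValueError("need at least one layer")
    common = set(layers[0].sample_ids)
    for layer in layers[1:]:
        common &= set(layer.sample_ids)
    if annotation is not None:
        common &= set(annotation.sample_ids)
    order = [s for s in layers[0].sample_ids if s in common]
    if not order:
        raise ValueError("no samples shared by all inputs")
    dropped: dict[str, list[str]] = {}
    aligned = []
    for layer in layers:
        dropped[layer.name] = [s for s in layer.sample_ids if s not in common]
        aligned.append(layer.subset_samples(order))
    ann_out = None
    if annotation is not None:
        dropped["annotation"] = [s for s in annotation.sample_ids if s not in common]
        ann_out = annotation.subset_samples(order)
    return aligned, ann_out, dropped


def prevalence_filter(layer: OmicsLayer, min_prevalence: float) -> OmicsLayer:
    """Keep features present (value > 0) in at least ``min_prevalence`` of samples."""
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    prevalence = (layer.data > 0).mean(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index
    if len(keep) == 0:
        raise ValueError(
            f"prevalence filter at {min_prevalence} removed every feature of "
            f"layer {layer.name!r}; lower the threshold"
        )
    return layer.subset_features(keep)


def _default_pseudocount(values: np.ndarray) -> float:
    # counts get +1; real-valued compositional tables get half the smallest
    # positive entry so zeros stay below every observed value
    if np.allclose(values, np.round(values)):
        return 1.0
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("all-zero table: CLR undefined")
    return float(positive.min()) / 2.0


def clr_transform(layer: OmicsLayer, pseudocount: float | None = None) -> OmicsLayer:
    """Centred log-ratio transform: ``ln(x+d) - mean_features ln(x+d)`` per sample.

    ``pseudocount`` defaults to 1 for integer counts and to half the minimum
    positive value otherwise; it may be 0 when the table is strictly positive.
    Output rows sum to zero; the compositional flag is cleared.
    """
    values = layer.values
    if (values < 0).any():
        raise ValueError(f"layer {layer.name!r}: negative values, CLR undefined")
    if pseudocount is None:
        pseudocount = 0.0 if (values > 0).all() else _default_pseudocount(values)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = values + pseudocount
    if (shifted <= 0).any():
        raise ValueError("zeros present: supply a positive pseudocount")
    logs = np.log(shifted)
    clr = logs - logs.mean(axis=1, keepdims=True)
    data = pd.DataFrame(clr, index=layer.data.index, columns=layer.data.columns)
    return replace(layer, data=data, is_compositional=False)


def transform(layer: OmicsLayer, name: str, **kwargs) -> OmicsLayer:
    """Dispatch over the supported matrix transforms.

    ``name`` is one of ``clr``, ``log2`` (log2(x+1)), ``tss`` (total-sum
    scaling per sample), ``unit_variance`` (z-score per feature), ``none``.
    """
    if name == "none":
        return layer
    if name == "clr":
        return clr_transform(layer, **kwargs)
    values = layer.values
    if name == "log2":
        if (values < 0).any():
            raise ValueError("log2 transform requires nonnegative values")
        out = np.log2(values + 1.0)
    elif name == "tss":
        if (values < 0).any():
            raise ValueError("total-sum scaling requires nonnegative values")
        sums = values.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        out = values / sums
    elif name == "unit_variance":
        sd = values.std(axis=0, ddof=1, keepdims=True)
        if (sd == 0).any():
            j = int(np.argwhere(sd[0] == 0)[0][0])
            raise ValueError(
                f"zero-variance feature {layer.feature_ids[j]!r} cannot be scaled"
            )
        out = (values - values.mean(axis=0, keepdims=True)) / sd
    else:
        raise ValueError(f"unknown transform {name!r}")
    data = pd.DataFrame(out, index=layer.data.index, columns=layer.data.columns)
    return replace(layer, data=data, is_compositional=layer.is_compositional and name == "tss")


def detect_outliers(layer: OmicsLayer, z_cut: float = -2.5) -> list[str]:
    """Flag samples whose standardized network connectivity falls below ``z_cut``.

    Each sample's connectivity is the summed affinity ``((1+r)/2)^2`` to all
    other samples, where ``r`` is the Pearson correlation between sample
    profiles; connectivities are z-scored and samples with ``z < z_cut``
    (default -2.5) are reported. Deterministic; removal is left to the caller.
    """
    if layer.n_samples < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    profiles = layer.values
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(profiles)
    r = np.nan_to_num(r, nan=0.0)
    affinity = ((1.0 + r) / 2.0) ** 2
    np.fill_diagonal(affinity, 0.0)
    k = affinity.sum(axis=1)
    sd = k.std()
    if sd == 0:
        return []
    z = (k - k.mean()) / sd
    return [s for s, zi in zip(layer.sample_ids, z) if zi < z_cut]


def relative_abundance(
    layer: OmicsLayer, taxonomy: TaxonomyTable, rank: str
) -> pd.DataFrame:
    """Per-sample proportions of lineages at a taxonomic rank.

    Features are summed within their taxon at ``rank`` (features without an
    assignment fall under ``"Unclassified"``) and each row is normalised to
    sum to 1; all-zero samples stay all-zero.
    """
    if rank not in taxonomy.ranks:
        raise ValueError(f"unknown rank {rank!r}; available: {taxonomy.ranks}")
    if (layer.values < 0).any():
        raise ValueError("relative abundance requires nonnegative counts")
    assignment = taxonomy.lineages[rank].reindex(layer.feature_ids)
    assignment = assignment.fillna("Unclassified").astype(str)
    grouped = layer.data.T.groupby(assignment.to_numpy()).sum().T
    totals = grouped.sum(axis=1)
    nonzero = totals > 0
    grouped.loc[nonzero] = grouped.loc[nonzero].div(totals[nonzero], axis=0)
    return grouped
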