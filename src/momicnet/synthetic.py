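"""Synthetic multi-omics data with planted ground truth.

The generator emulates the situation the integration pipeline is built
for: several omics layers measured on the same samples, each containing
blocks of co-varying features ("modules") driven by per-module latent
factors, some factors shared across layers (the cross-layer signal), and
contextual traits that are functions of those factors.

The model is a noisy one-factor block model: feature j of a module with
factor f has

    x_ij = lambda_j * f_i + eps_ij,   eps ~ N(0, noise_sd^2)

with loadings ``lambda_j`` drawn uniformly from [0.8, 1.2] and rescaled so
the expected within-module feature-feature correlation hits the requested
target (for loading lambda and noise sd sigma the correlation of two
module features is lambda^2 / (lambda^2 + sigma^2)). Features outside any
module are pure noise. A shared factor group replaces the member modules'
factors by correlated copies ``corr * g + sqrt(1 - corr^2) * e`` of one
group factor ``g``. Quantitative traits are linear in factors plus noise;
qualitative traits threshold a factor at level quantiles.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import AnnotationTable, OmicsLayer

__all__ = [
    "LayerSpec",
    "SharedFactorGroup",
    "QuantitativeTrait",
    "QualitativeTrait",
    "SyntheticConfig",
    "GroundTruth",
    "generate_multiomics",
    "generate_compositional_counts",
    "make_null",
    "reference_config",
    "shared_pair_config",
]


@dataclass
class LayerSpec:
    """One synthetic layer: planted module sizes and correlation target.

    The default shape (150 features, three modules of 40, so 30 pure-noise
    background features) mirrors a small expression panel: the background
    features are what give the soft-thresholded network its heavy-tailed
    degree distribution.
    """

    name: str
    n_features: int = 150
    module_sizes: tuple[int, ...] = (40, 40, 40)
    within_module_corr: float = 0.7
    compositional: bool = False

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_features:
            raise ValueError(
                f"layer {self.name!r}: module sizes exceed n_features"
            )
        if not 0.0 < self.within_module_corr < 1.0:
            raise ValueError(
                f"layer {self.name!r}: within_module_corr must be in (0, 1)"
            )


@dataclass
class SharedFactorGroup:
    """Modules (layer name, 1-based module index) tied to one latent factor.

    ``corr`` is the correlation between each member module's factor and the
    group factor (1.0 = identical factor in every member).
    """

    members: tuple[tuple[str, int], ...]
    corr: float = 1.0

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a shared factor group needs >= 2 member modules")
        if not 0.0 < self.corr <= 1.0:
            raise ValueError("shared factor corr must be in (0, 1]")


@dataclass
class QuantitativeTrait:
    """Linear trait: sum of effect_size * factor over modules, plus noise."""

    effects: dict[tuple[str, int], float]
    noise_sd: float = 0.5


@dataclass
class QualitativeTrait:
    """Group labels from thresholding one module's factor at quantiles."""

    source: tuple[str, int]
    levels: tuple[str, ...] = ("low", "high")
    quantiles: tuple[float, ...] | None = None  # defaults to equal splits


@dataclass
class SyntheticConfig:
    n_samples: int = 60
    layers: tuple[LayerSpec, ...] = field(
        default_factory=lambda: (
            LayerSpec("layer1"),
            LayerSpec("layer2"),
            LayerSpec("layer3"),
        )
    )
    shared_factors: tuple[SharedFactorGroup, ...] = ()
    quantitative_traits: dict[str, QuantitativeTrait] = field(default_factory=dict)
    qualitative_traits: dict[str, QualitativeTrait] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [ly.name for ly in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for group in self.shared_factors:
            for layer, module in group.members:
                self._check_ref(layer, module)
        for trait in self.quantitative_traits.values():
            for layer, module in trait.effects:
                self._check_ref(layer, module)
        for trait in self.qualitative_traits.values():
            self._check_ref(*trait.source)

    def _check_ref(self, layer: str, module: int) -> None:
        spec = next((ly for ly in self.layers if ly.name == layer), None)
        if spec is None:
            raise ValueError(f"unknown layer {layer!r} in config reference")
        if not 1 <= module <= len(spec.module_sizes):
            raise ValueError(f"layer {layer!r} has no module {module}")


@dataclass
class GroundTruth:
    """What was planted: module maps, latent factors, trait recipes."""

    module_map: dict[str, pd.Series]          # layer -> feature_id -> module id
    factors: pd.DataFrame                     # sample x "<layer>.M<k>" (+ groups)
    shared_groups: list[SharedFactorGroup]
    trait_effects: dict[str, QuantitativeTrait]
    trait_sources: dict[str, QualitativeTrait]
    config: SyntheticConfig


def _module_loadings(rng, size: int, rho: float, noise_sd: float) -> np.ndarray:
    raw = rng.uniform(0.8, 1.2, size=size)
    target_sq = noise_sd**2 * rho / (1.0 - rho)
    return raw * np.sqrt(target_sq / np.mean(raw**2))


def generate_multiomics(
    config: SyntheticConfig,
) -> tuple[list[OmicsLayer], AnnotationTable, GroundTruth]:
    """Draw one multi-layer dataset plus annotation from the block model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i+1:03d}" for i in range(n)]

    # group factors first, then per-module factors (shared ones correlated)
    group_of: dict[tuple[str, int], tuple[int, float]] = {}
    for g, group in enumerate(config.shared_factors):
        for member in group.members:
            group_of[member] = (g, group.corr)
    group_factors = rng.standard_normal((n, len(config.shared_factors)))

    factors: dict[str, np.ndarray] = {}
    for spec in config.layers:
        for k in range(1, len(spec.module_sizes) + 1):
            key = (spec.name, k)
            own = rng.standard_normal(n)
            if key in group_of:
                g, rho = group_of[key]
                f = rho * group_factors[:, g] + np.sqrt(1.0 - rho**2) * own
            else:
                f = own
            factors[f"{spec.name}.M{k}"] = f
    for g in range(len(config.shared_factors)):
        factors[f"shared{g+1}"] = group_factors[:, g]

    layers: list[OmicsLayer] = []
    module_map: dict[str, pd.Series] = {}
    for spec in config.layers:
        x = np.empty((n, spec.n_features))
        labels = np.zeros(spec.n_features, dtype=int)
        feature_ids = [f"{spec.name}_f{j+1:04d}" for j in range(spec.n_features)]
        col = 0
        for k, size in enumerate(spec.module_sizes, start=1):
            lam = _module_loadings(
                rng, size, spec.within_module_corr, config.noise_sd
            )
            f = factors[f"{spec.name}.M{k}"]
            x[:, col : col + size] = (
                np.outer(f, lam)
                + rng.standard_normal((n, size)) * config.noise_sd
            )
            labels[col : col + size] = k
            col += size
        n_bg = spec.n_features - col
        if n_bg:
            x[:, col:] = rng.standard_normal((n, n_bg)) * config.noise_sd
        layers.append(
            OmicsLayer(
                name=spec.name,
                data=pd.DataFrame(x, index=sample_ids, columns=feature_ids),
                is_compositional=spec.compositional,
            )
        )
        module_map[spec.name] = pd.Series(labels, index=feature_ids)

    ann_cols: dict[str, object] = {}
    kinds: dict[str, str] = {}
    for name, trait in config.quantitative_traits.items():
        y = rng.standard_normal(n) * trait.noise_sd
        for (layer, module), effect in trait.effects.items():
            y = y + effect * factors[f"{layer}.M{module}"]
        ann_cols[name] = y
        kinds[name] = "quantitative"
    for name, trait in config.qualitative_traits.items():
        layer, module = trait.source
        f = factors[f"{layer}.M{module}"]
        k = len(trait.levels)
        qs = trait.quantiles or tuple((i + 1) / k for i in range(k - 1))
        cuts = np.quantile(f, qs)
        ann_cols[name] = [trait.levels[int(np.searchsorted(cuts, v))] for v in f]
        kinds[name] = "qualitative"
    annotation = AnnotationTable(
        pd.DataFrame(ann_cols, index=sample_ids), kinds
    )
    truth = GroundTruth(
        module_map=module_map,
        factors=pd.DataFrame(factors, index=sample_ids),
        shared_groups=list(config.shared_factors),
        trait_effects=dict(config.quantitative_traits),
        trait_sources=dict(config.qualitative_traits),
        config=config,
    )
    return layers, annotation, truth


def make_null(
    config: SyntheticConfig,
) -> tuple[list[OmicsLayer], AnnotationTable, GroundTruth]:
    """Matched null: same per-layer module structure, but every factor is
    independent across layers and every trait is independent of all factors."""
    null_cfg = replace(config, shared_factors=())
    layers, annotation, truth = generate_multiomics(null_cfg)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    n = config.n_samples
    cols: dict[str, object] = {}
    kinds: dict[str, str] = {}
    for name, trait in config.quantitative_traits.items():
        scale = np.sqrt(
            trait.noise_sd**2 + sum(e**2 for e in trait.effects.values())
        )
        cols[name] = rng.standard_normal(n) * scale
        kinds[name] = "quantitative"
    for name, trait in config.qualitative_traits.items():
        k = len(trait.levels)
        qs = trait.quantiles or tuple((i + 1) / k for i in range(k - 1))
        f = rng.standard_normal(n)
        cuts = np.quantile(f, qs)
        cols[name] = [trait.levels[int(np.searchsorted(cuts, v))] for v in f]
        kinds[name] = "qualitative"
    annotation = AnnotationTable(
        pd.DataFrame(cols, index=annotation.sample_ids), kinds
    )
    truth = replace(truth, trait_effects={}, trait_sources={})
    return layers, annotation, truth


def generate_compositional_counts(
    layer: OmicsLayer, depth: int, seed: int = 0
) -> OmicsLayer:
    """Multinomial count layer: per sample, softmax of the latent values
    gives taxon proportions and ``depth`` reads are drawn. Rows sum to depth."""
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    rng = np.random.default_rng(seed)
    latent = layer.values
    shifted = latent - latent.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in probs])
    return OmicsLayer(
        name=f"{layer.name}_counts",
        data=pd.DataFrame(
            counts, index=layer.data.index, columns=layer.data.columns
        ),
        is_compositional=True,
    )


def reference_config(seed: int = 0) -> SyntheticConfig:
    """The reference recovery scenario: 3 layers, 60 samples, 150 features
    per layer with 3 planted modules of 40 at within-module correlation 0.7."""
    return SyntheticConfig(
        n_samples=60,
        layers=(
            LayerSpec("layer1", 150, (40, 40, 40), 0.7),
            LayerSpec("layer2", 150, (40, 40, 40), 0.7),
            LayerSpec("layer3", 150, (40, 40, 40), 0.7),
        ),
        quantitative_traits={
            "env": QuantitativeTrait({("layer1", 1): 1.0}, noise_sd=0.5)
        },
        seed=seed,
    )


def shared_pair_config(seed: int = 0, corr: float = 0.8, n_samples: int = 50) -> SyntheticConfig:
    """Cross-layer scenario: layer1 module 1 and layer2 module 2 share a
    latent factor (at the given correlation) that also drives a binary trait."""
    return SyntheticConfig(
        n_samples=n_samples,
        layers=(
            LayerSpec("layer1", 150, (40, 40, 40), 0.7),
            LayerSpec("layer2", 150, (40, 40, 40), 0.7),
            LayerSpec("layer3", 150, (40, 40, 40), 0.7),
        ),
        shared_factors=(
            SharedFactorGroup((("layer1", 1), ("layer2", 2)), corr=corr),
        ),
        qualitative_traits={
            "group": QualitativeTrait(source=("layer1", 1))
        },
        seed=seed,
    )
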