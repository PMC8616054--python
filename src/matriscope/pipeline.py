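"""End-to-end featurization: images -> tiles -> autoencoder -> separation.

One call wires the whole unsupervised workflow together on synthetic
micrographs: generate a balanced image set, tile and filter it,
subsample a fixed-size training set, train the autoencoder, embed every
training tile into its 16-value feature vector, and quantify how well
the learned features separate the four microstructure classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from matriscope.autoencoder import (
    AutoencoderSpec,
    ConvAutoencoder,
    build_autoencoder,
    encode,
    feature_matrix,
)
from matriscope.embedding import (
    SeparationReport,
    knn_loo_accuracy,
    rank_features,
    score_separation,
)
from matriscope.synthetic import GeneratorParams, generate_dataset
from matriscope.tiling import TileSet, filter_tiles, tile_images


@dataclass
class PipelineResult:
    """Artifacts of one featurization run."""

    model: ConvAutoencoder
    loss_history: list[float]
    features: np.ndarray  # (n_tiles, 16)
    tile_ids: list[str]
    labels: np.ndarray  # (n_tiles,)
    n_images: int
    n_tiles_prefilter: int
    n_tiles_filtered: int
    n_tiles_trained: int
    silhouette_all: float
    silhouette_long_fiber_vs_honeycomb: float
    knn_accuracy: float
    separation: SeparationReport = field(repr=False, default=None)


def subsample_tiles(tiles: TileSet, n: int, seed: int) -> TileSet:
    """Seeded uniform subsample (without replacement), order preserved."""
    if n >= len(tiles.tiles):
        return tiles
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(20,)))
    keep = np.sort(rng.choice(len(tiles.tiles), size=n, replace=False))
    return TileSet(
        tiles=[tiles.tiles[i] for i in keep],
        grid_rows=tiles.grid_rows,
        grid_cols=tiles.grid_cols,
        filter_report=tiles.filter_report,
    )


def run_featurization(
    n_images_per_class: int = 12,
    epochs: int = 25,
    seed: int = 0,
    n_train_tiles: int = 2000,
    params: GeneratorParams | None = None,
    batch_size: int = 32,
    learning_rate: float | None = None,
    weight_decay: float | None = None,
    encoder_channels: tuple[int, ...] | None = None,
) -> PipelineResult:
    """Run the full unsupervised pipeline on synthetic micrographs.

    The class-separation scores are computed on the training tiles
    themselves (the workflow is unsupervised; labels are used only for
    scoring).  ``silhouette_long_fiber_vs_honeycomb`` contrasts the two
    morphologically most distinct classes; the two network classes are
    structurally similar and allowed to overlap.
    """
    images = generate_dataset(n_images_per_class, seed, params)
    tiles = tile_images(images)
    filtered = filter_tiles(tiles)
    train_set = subsample_tiles(filtered, n_train_tiles, seed)

    # materialize the training stack and drop the frames: tiles are views
    # into their source images, which would otherwise pin ~1 GB of rasters
    # through training at full study scale
    stack = train_set.pixel_array()
    labels = train_set.labels()
    ids = [t.tile_id for t in train_set.tiles]
    n_images = len(images)
    n_prefilter, n_filtered, n_trained = len(tiles), len(filtered), len(train_set)
    del images, tiles, filtered, train_set

    overrides = {}
    if learning_rate is not None:
        overrides["learning_rate"] = learning_rate
    if weight_decay is not None:
        overrides["weight_decay"] = weight_decay
    if encoder_channels is not None:
        overrides["encoder_channels"] = encoder_channels
    spec = AutoencoderSpec(
        epochs=epochs, seed=seed, batch_size=batch_size, **overrides
    )
    model = build_autoencoder(spec)
    loss_history = model.fit(stack)

    activations = encode(model, stack)
    for act, tile_id in zip(activations, ids):
        act.tile_id = tile_id
    features, tile_ids = feature_matrix(activations, labels)

    two_class = np.isin(labels, ["long_fiber", "honeycomb"])
    return PipelineResult(
        model=model,
        loss_history=loss_history,
        features=features,
        tile_ids=tile_ids,
        labels=labels,
        n_images=n_images,
        n_tiles_prefilter=n_prefilter,
        n_tiles_filtered=n_filtered,
        n_tiles_trained=n_trained,
        silhouette_all=score_separation(features, labels),
        silhouette_long_fiber_vs_honeycomb=score_separation(
            features[two_class], labels[two_class]
        ),
        knn_accuracy=knn_loo_accuracy(features, labels),
        separation=rank_features(features, labels),
    )
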