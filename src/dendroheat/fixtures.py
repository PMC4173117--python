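"""Synthetic data generation: every part of the pipeline is testable offline.

Gaussian blobs stand in for a feature matrix of, e.g., physico-chemical
descriptors: well-separated blobs give a known ground-truth partition that a
correct clustering must recover, while separation 0 collapses everything into
noise.  Generators are pure functions of their seed (a single named
pseudo-random generator, no global state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tabular_io import DataMatrix, MetadataTable

__all__ = ["BlobSpec", "make_blobs", "make_metadata", "make_document"]


@dataclass
class BlobSpec:
    """Gaussian-cluster matrix: centres separated in units of the noise sd."""

    n_rows: int = 60
    n_features: int = 5
    n_clusters: int = 3
    separation: float = 8.0  # min centre distance, in units of noise_sd
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_rows:
            raise ValueError("n_clusters cannot exceed n_rows")
        if self.n_clusters < 1 or self.n_features < 1:
            raise ValueError("need at least one cluster and one feature")
        if self.separation < 0 or self.noise_sd <= 0:
            raise ValueError("separation must be >= 0 and noise_sd > 0")


def make_blobs(spec: BlobSpec) -> tuple[DataMatrix, np.ndarray]:
    """Gaussian clusters around random centres; returns the matrix and true labels.

    Centres are drawn from a standard normal and rescaled so their minimum
    pairwise distance equals ``separation * noise_sd``; labels are assigned
    round-robin then shuffled, so every cluster is non-empty.
    """
    rng = np.random.default_rng(spec.seed)
    k, m = spec.n_clusters, spec.n_features
    centres = rng.standard_normal((k, m))
    if k > 1:
        d_min = min(
            float(np.linalg.norm(centres[i] - centres[j]))
            for i in range(k)
            for j in range(i + 1, k)
        )
        centres = (
            centres * (spec.separation * spec.noise_sd / d_min) if d_min > 0 else centres * 0.0
        )
        if spec.separation == 0:
            centres = np.zeros_like(centres)
    labels = np.array([i % k for i in range(spec.n_rows)])
    rng.shuffle(labels)
    values = centres[labels] + rng.normal(0.0, spec.noise_sd, size=(spec.n_rows, m))
    data = DataMatrix(
        [f"r{i}" for i in range(spec.n_rows)],
        [f"f{j + 1}" for j in range(m)],
        values,
    )
    return data, labels


def make_metadata(row_ids: list[str], seed: int = 0) -> MetadataTable:
    """One numeric column in [0, 1] and one positive/negative class column."""
    if not row_ids:
        raise ValueError("row_ids must be non-empty")
    rng = np.random.default_rng(seed)
    numeric = rng.uniform(0.0, 1.0, size=len(row_ids))
    classes = rng.choice(["positive", "negative"], size=len(row_ids))
    values = [[float(x), str(c)] for x, c in zip(numeric, classes)]
    return MetadataTable(list(row_ids), ["Numeric", "Categoric"], values,
                         ["numeric", "categorical"])


def make_document(
    spec: BlobSpec,
    axis: str = "both",
    normalize: bool = True,
    write_original: bool = False,
    compress: int | None = None,
    with_metadata: bool = True,
    linkage: str = "ward",
    distance: str = "euclidean",
):
    """Run the full pipeline on blob data; the result passes validation."""
    from .cli import RunConfig, api_run

    data, _ = make_blobs(spec)
    meta = make_metadata(data.row_ids, seed=spec.seed + 1) if with_metadata else None
    config = RunConfig(
        axis=axis,
        normalize=normalize,
        write_original=write_original,
        compress=compress,
        linkage=linkage,
        distance=distance,
    )
    return api_run(config, data, meta)
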