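"""3-D spatial feature extraction.

Three parallel per-atom pathways encode an (optionally rotation-augmented)
conformer:

* a coordinate encoder maps raw positions to a d-dimensional space,
* a distance encoder maps each atom's Euclidean distance to the molecular
  centroid to d/2 dimensions (rotation- and translation-invariant), and
* an angle encoder maps the normalized atom→centroid direction cosines to
  d/2 dimensions.

The three are concatenated (width 2d) and fused back to d by a small fusion
network.  Each pathway is the smallest "multilayer" perceptron: two linear
maps with a ReLU + LayerNorm in between; dropout is applied only inside the
coordinate encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chemio import Conformer, random_rotation
from .nn import LayerNorm, Linear, Module


@dataclass
class Spatial3DConfig:
    d: int = 64
    dropout_rate: float = 0.1
    epsilon: float = 1e-8

    def __post_init__(self):
        if self.d % 2:
            raise ValueError("embedding width d must be even")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class SpatialFeatures:
    f_pos: Tensor        # [N, d]
    f_dist: Tensor       # [N, d/2]
    f_angle: Tensor      # [N, d/2]
    f_combined: Tensor   # [N, 2d]
    s: Tensor            # [N, d] fused output
    centroid: np.ndarray     # [G, 3] per-graph centroids
    distances: np.ndarray    # [N]
    directions: np.ndarray   # [N, 3]


def compute_center_and_distances(coords: np.ndarray,
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Geometric centre (row mean) and per-atom distances to it."""
    coords = np.asarray(coords, dtype=np.float64)
    c = coords.mean(axis=0)
    d = np.linalg.norm(coords - c, axis=1)
    return c, d


def compute_directions(coords: np.ndarray, c: np.ndarray,
                       epsilon: float = 1e-8) -> np.ndarray:
    """Unit atom→centroid direction cosines; zero vector at the centroid."""
    diff = np.asarray(coords, dtype=np.float64) - np.asarray(c)
    norms = np.linalg.norm(diff, axis=1, keepdims=True)
    out = np.where(norms > epsilon, diff / np.maximum(norms, epsilon), 0.0)
    return out


class Spatial3DLayer(Module):
    """Coordinate / distance / angle encoders plus the fusion network."""

    def __init__(self, config: Spatial3DConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.d
        self.pos1 = Linear(3, d, rng)
        self.pos_norm = LayerNorm(d)
        self.pos2 = Linear(d, d, rng)
        self.dist1 = Linear(1, d // 2, rng)
        self.dist_norm = LayerNorm(d // 2)
        self.dist2 = Linear(d // 2, d // 2, rng)
        self.angle1 = Linear(3, d // 2, rng)
        self.angle_norm = LayerNorm(d // 2)
        self.angle2 = Linear(d // 2, d // 2, rng)
        self.fuse = Linear(2 * d, d, rng)
        self.fuse_norm = LayerNorm(d)

    def forward(self, coords: np.ndarray,
                graph_ids: np.ndarray | None = None,
                n_graphs: int = 1,
                rng: np.random.Generator | None = None) -> SpatialFeatures:
        """Encode a batch of molecules stacked along the atom axis.

        `graph_ids` assigns every atom row to its molecule so centroids are
        computed per molecule; a single molecule may pass `None`.
        """
        coords = np.asarray(coords, dtype=np.float64)
        n = coords.shape[0]
        if graph_ids is None:
            graph_ids = np.zeros(n, dtype=np.intp)
            n_graphs = 1
        graph_ids = np.asarray(graph_ids, dtype=np.intp)

        # geometry (plain NumPy: coordinates are inputs, not parameters)
        counts = np.bincount(graph_ids, minlength=n_graphs).astype(np.float64)
        sums = np.zeros((n_graphs, 3))
        np.add.at(sums, graph_ids, coords)
        centroids = sums / np.maximum(counts, 1.0)[:, None]
        diff = coords - centroids[graph_ids]
        distances = np.linalg.norm(diff, axis=1)
        eps = self.config.epsilon
        directions = np.where(distances[:, None] > eps,
                              diff / np.maximum(distances[:, None], eps), 0.0)

        f_pos = ad.relu(self.pos1(Tensor(coords)))
        f_pos = self.pos_norm(f_pos)
        f_pos = ad.dropout(f_pos, self.config.dropout_rate, rng, self.training)
        f_pos = self.pos2(f_pos)

        f_dist = ad.relu(self.dist1(Tensor(distances[:, None])))
        f_dist = self.dist2(self.dist_norm(f_dist))

        f_angle = ad.relu(self.angle1(Tensor(directions)))
        f_angle = self.angle2(self.angle_norm(f_angle))

        f_combined = ad.concat([f_pos, f_dist, f_angle], axis=1)
        s = self.fuse_norm(ad.relu(self.fuse(f_combined)))
        return SpatialFeatures(f_pos=f_pos, f_dist=f_dist, f_angle=f_angle,
                               f_combined=f_combined, s=s,
                               centroid=centroids, distances=distances,
                               directions=directions)

    __call__ = forward


def spatial3d_forward(coords: np.ndarray, layer: Spatial3DLayer,
                      rng: np.random.Generator | None = None
                      ) -> SpatialFeatures:
    """Single-molecule convenience wrapper around :meth:`Spatial3DLayer.forward`."""
    return layer.forward(coords, rng=rng)


def make_two_views(conformer: Conformer, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Two independently rotated copies of one conformer (contrastive views)."""
    v1 = random_rotation(conformer, rng).coordinates
    v2 = random_rotation(conformer, rng).coordinates
    return v1, v2
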