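"""Weighted graph measures of connection-density networks.

Connection densities are affinities, so shortest-path computations use the
standard length transform L_ij = 1/W_ij (``-log`` available as an
alternative).  Local measures per node: strength, eccentricity, closeness,
betweenness (Brandes, endpoints excluded, unnormalized), Onnela weighted
clustering, and Crofts-Higham normalized communicability
row-sums of expm(S^-1/2 W S^-1/2) with S = diag(strength), diagonal
included.  Global measures: characteristic path length, radius, diameter,
average clustering, global efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.sparse.csgraph import dijkstra

from .connectome import ConnectomeMatrix
from .errors import ValidationError

__all__ = [
    "TopologyProfile",
    "GlobalTopology",
    "distance_matrix",
    "local_profile",
    "global_profile",
]

LOCAL_MEASURES = ("strength", "eccentricity", "closeness", "betweenness",
                  "clustering", "communicability")
GLOBAL_MEASURES = ("char_path_length", "radius", "diameter",
                   "avg_clustering", "global_efficiency")


@dataclass
class TopologyProfile:
    """Per-node measures; arrays of length N."""

    strength: np.ndarray
    eccentricity: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray
    communicability: np.ndarray
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: getattr(self, m) for m in LOCAL_MEASURES},
            index=pd.Index(self.labels, name="region"))


@dataclass
class GlobalTopology:
    """Network-level measures (radius <= diameter always)."""

    char_path_length: float
    radius: float
    diameter: float
    avg_clustering: float
    global_efficiency: float

    def to_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in GLOBAL_MEASURES}


def _as_matrix(W) -> np.ndarray:
    return W.W if isinstance(W, ConnectomeMatrix) else np.asarray(W, dtype=float)


def _lengths(W: np.ndarray, transform: str) -> np.ndarray:
    with np.errstate(divide="ignore"):
        if transform == "inverse":
            return np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
        if transform == "neglog":
            return np.where(W > 0, -np.log(np.where(W > 0, W, 1.0)), np.inf)
    raise ValidationError(f"unknown length transform {transform!r}")


def distance_matrix(W, transform: str = "inverse") -> np.ndarray:
    """All-pairs weighted shortest-path lengths (Dijkstra) on edge lengths
    L = 1/W; zero weight means no edge, disconnected pairs get inf."""
    Wm = _as_matrix(W)
    L = _lengths(Wm, transform)
    L = np.where(np.isfinite(L), L, 0.0)  # csgraph: 0 = absent edge
    D = dijkstra(L, directed=False)
    np.fill_diagonal(D, 0.0)
    return D


def _require_connected(D: np.ndarray) -> None:
    if not np.all(np.isfinite(D)):
        raise ValidationError(
            "graph is disconnected (infinite shortest-path distances); "
            "apply the backbone mask to a connected average network first")


def local_profile(W, transform: str = "inverse") -> TopologyProfile:
    """All per-node measures of a connected weighted network."""
    m = W if isinstance(W, ConnectomeMatrix) else ConnectomeMatrix(W=np.asarray(W))
    Wm = m.W
    N = Wm.shape[0]
    D = distance_matrix(Wm, transform)
    _require_connected(D)
    strength = Wm.sum(axis=1)
    off = ~np.eye(N, dtype=bool)
    ecc = np.max(np.where(off, D, 0.0), axis=1)
    closeness = (N - 1) / D.sum(axis=1)

    g = nx.from_numpy_array(Wm)
    for i, j, data in g.edges(data=True):
        data["length"] = _lengths(np.array([[data["weight"]]]), transform)[0, 0]
    bet_d = nx.betweenness_centrality(g, weight="length", normalized=False)
    betweenness = np.array([bet_d[i] for i in range(N)])
    # Onnela weighted clustering: hat(w) = w / max(w), binary degree k_i
    clus_d = nx.clustering(g, weight="weight")
    clustering = np.array([clus_d[i] for i in range(N)])

    s_isqrt = 1.0 / np.sqrt(strength)
    Mexp = expm((s_isqrt[:, None] * Wm) * s_isqrt[None, :])
    communicability = Mexp.sum(axis=1)  # diagonal included

    return TopologyProfile(
        strength=strength, eccentricity=ecc, closeness=closeness,
        betweenness=betweenness, clustering=clustering,
        communicability=communicability, labels=list(m.labels))


def global_profile(W, transform: str = "inverse") -> GlobalTopology:
    """Network-level measures of a connected weighted network."""
    Wm = _as_matrix(W)
    N = Wm.shape[0]
    D = distance_matrix(Wm, transform)
    _require_connected(D)
    off = ~np.eye(N, dtype=bool)
    ecc = np.max(np.where(off, D, 0.0), axis=1)
    g = nx.from_numpy_array(Wm)
    clus = np.array(list(nx.clustering(g, weight="weight").values()))
    return GlobalTopology(
        char_path_length=float(D[off].mean()),
        radius=float(ecc.min()),
        diameter=float(ecc.max()),
        avg_clustering=float(clus.mean()),
        global_efficiency=float((1.0 / D[off]).mean()),
    )
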