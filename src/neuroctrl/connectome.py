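"""Weighted anatomical connectivity matrices and synthetic cohorts.

The coupling substrate for the oscillator network is an N x N symmetric
matrix of connection densities: ``W[i, j]`` in [0, 1] quantifies how strongly
regions ``i`` and ``j`` are anatomically connected, with a zero diagonal.
Real matrices of this kind come from diffusion-MRI tractography; this module
generates synthetic stand-ins with comparable statistical structure
(modular, sparse-ish, heterogeneous weights, subject-to-subject variability)
and provides the backbone-masking and file I/O used throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .errors import ValidationError

__all__ = [
    "ConnectomeMatrix",
    "CohortSpec",
    "generate_cohort",
    "twin_symmetric_matrix",
    "mst_backbone",
    "apply_mask",
    "read_matrix",
    "write_matrix",
    "validate_matrix",
]

#: Tolerated asymmetry in input files before symmetrization is refused.
ASYMMETRY_TOL = 1e-9

#: Default mean degree of the backbone mask, typical for MST-plus-strongest-edge
#: masks of structural connectomes.  The threshold used by the original
#: backbone construction is not published, so it is configurable.
DEFAULT_TARGET_MEAN_DEGREE = 6.0


@dataclass
class ConnectomeMatrix:
    """A symmetric connection-density matrix with region labels.

    Invariants (enforced by :func:`validate_matrix`): ``W`` symmetric,
    entries in [0, 1], zero diagonal.
    """

    W: np.ndarray
    labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if not self.labels:
            self.labels = [f"R{i + 1:03d}" for i in range(self.W.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]

    def copy(self) -> "ConnectomeMatrix":
        return replace(self, W=self.W.copy(), labels=list(self.labels))


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    The base network is a stochastic block model (``n_modules`` communities,
    intra-module edges three times denser than inter-module ones) with
    Beta(2, 5)-distributed weights scaled by ``weight_scale``.  Each subject
    is the base network perturbed edge-wise by multiplicative log-normal
    noise of sigma ``subject_noise`` and re-clipped to [0, 1].
    """

    n_subjects: int = 10
    N: int = 78
    density: float = 0.3
    n_modules: int = 4
    weight_scale: float = 1.0
    subject_noise: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.N < 2:
            raise ValidationError("N must be >= 2")
        if not 0.0 < self.density <= 1.0:
            raise ValidationError("density must lie in (0, 1]")
        if self.n_modules < 1:
            raise ValidationError("n_modules must be >= 1")
        if self.weight_scale <= 0:
            raise ValidationError("weight_scale must be positive")
        if self.subject_noise < 0:
            raise ValidationError("subject_noise must be non-negative")


def validate_matrix(W: np.ndarray, *, asym_tol: float = ASYMMETRY_TOL) -> None:
    """Check the connection-density invariants, reporting offending cells.

    Raises :class:`ValidationError` naming row/column indices for any
    violation: non-square shape, asymmetry beyond ``asym_tol``, entries
    outside [0, 1], or a nonzero diagonal.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError(f"matrix is not square: shape {W.shape}")
    if not np.all(np.isfinite(W)):
        bad = np.argwhere(~np.isfinite(W))[:10]
        raise ValidationError(f"non-finite entries at {bad.tolist()}")
    asym = np.abs(W - W.T)
    if asym.max(initial=0.0) > asym_tol:
        bad = np.argwhere(asym > asym_tol)[:10]
        raise ValidationError(
            f"asymmetric beyond tolerance {asym_tol:g} at cells {bad.tolist()}")
    out = (W < 0) | (W > 1)
    if out.any():
        bad = np.argwhere(out)[:10]
        raise ValidationError(f"entries outside [0, 1] at cells {bad.tolist()}")
    diag = np.flatnonzero(np.abs(np.diag(W)) > 0)
    if diag.size:
        raise ValidationError(f"nonzero diagonal at indices {diag.tolist()}")


def _connected(W: np.ndarray) -> bool:
    n = W.shape[0]
    adj = W > 0
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


def _components(W: np.ndarray) -> list[list[int]]:
    g = nx.from_numpy_array(W)
    return [sorted(c) for c in nx.connected_components(g)]


def _base_network(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Stochastic-block-model base with Beta(2, 5) weights, forced connected."""
    N = spec.N
    m = min(spec.n_modules, N)  # tiny networks: fewer modules than asked
    modules = np.repeat(np.arange(m), int(np.ceil(N / m)))[:N]
    same = modules[:, None] == modules[None, :]
    iu = np.triu_indices(N, k=1)
    frac_intra = same[iu].mean()
    # intra-module edges 3x denser than inter-module, overall density as given
    p_inter = spec.density / (3.0 * frac_intra + (1.0 - frac_intra))
    p_intra = min(3.0 * p_inter, 1.0)
    prob = np.where(same[iu], p_intra, p_inter)
    present = rng.random(iu[0].size) < prob
    weights = rng.beta(2.0, 5.0, size=iu[0].size) * spec.weight_scale
    W = np.zeros((N, N))
    W[iu] = np.where(present, weights, 0.0)
    W = W + W.T
    # join any disconnected components with a single strongest-available edge
    comps = _components(W)
    while len(comps) > 1:
        a = rng.choice(comps[0])
        b = rng.choice(comps[1])
        W[a, b] = W[b, a] = float(
            np.clip(rng.beta(2.0, 5.0) * spec.weight_scale, 1e-6, 1.0))
        comps = _components(W)
    np.clip(W, 0.0, 1.0, out=W)
    np.fill_diagonal(W, 0.0)
    return W


def generate_cohort(spec: CohortSpec) -> list[ConnectomeMatrix]:
    """Generate ``spec.n_subjects`` connectomes sharing one modular base.

    Deterministic for a fixed ``spec.seed``.  With ``subject_noise == 0``
    every subject equals the base network.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = _base_network(spec, rng)
    labels = [f"R{i + 1:03d}" for i in range(spec.N)]
    cohort = []
    iu = np.triu_indices(spec.N, k=1)
    for s in range(spec.n_subjects):
        if spec.subject_noise > 0:
            factor = np.exp(spec.subject_noise * rng.standard_normal(iu[0].size))
            W = np.zeros_like(base)
            W[iu] = base[iu] * factor
            W = W + W.T
        else:
            W = base.copy()
        np.clip(W, 0.0, 1.0, out=W)
        np.fill_diagonal(W, 0.0)
        W = (W + W.T) / 2.0
        m = ConnectomeMatrix(W=W, labels=list(labels), subject_id=f"S{s + 1:02d}")
        validate_matrix(m.W)
        cohort.append(m)
    return cohort


def twin_symmetric_matrix(N: int = 8, seed: int = 1,
                          twin_weight: float = 0.3) -> ConnectomeMatrix:
    """Engineered synthetic network containing a structurally twin node pair.

    Nodes 0 and 1 get identical connections to every other node and are
    coupled to each other, so the graph automorphism swapping them commutes
    with the dynamics.  The antisymmetric mode x_0 - x_1 is then invisible to
    any input placed outside the pair, which makes those control tasks
    uncontrollable.  Used as a known-negative test case.
    """
    if N < 4:
        raise ValidationError("twin network needs N >= 4")
    rng = np.random.default_rng(seed)
    W = np.zeros((N, N))
    for i, j in itertools.combinations(range(N), 2):
        if rng.random() < 0.5 or j == i + 1:
            W[i, j] = W[j, i] = rng.beta(2.0, 5.0)
    shared = rng.beta(2.0, 5.0, N - 2) * (rng.random(N - 2) < 0.8)
    W[0, 2:] = W[1, 2:] = shared
    W[2:, 0] = W[2:, 1] = shared
    W[0, 1] = W[1, 0] = twin_weight
    np.clip(W, 0.0, 1.0, out=W)
    np.fill_diagonal(W, 0.0)
    if not _connected(W):  # pragma: no cover - p(connected) ~ 1 at density 0.5
        W[0, 2:] = W[1, 2:] = np.maximum(shared, 0.05)
        W[2:, 0] = W[2:, 1] = W[0, 2:]
    m = ConnectomeMatrix(W=W, subject_id="TWIN")
    validate_matrix(m.W)
    return m


def mst_backbone(cohort: list[ConnectomeMatrix],
                 target_mean_degree: float = DEFAULT_TARGET_MEAN_DEGREE,
                 ) -> np.ndarray:
    """Backbone mask: maximum-weight spanning tree of the cohort-average
    network plus the strongest remaining edges up to a target mean degree.

    The spanning tree guarantees the masked graphs stay connected; the
    descending-weight fill-in keeps the dominant average connections.
    Returns a boolean N x N symmetric mask with a False diagonal.
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    shapes = {m.W.shape for m in cohort}
    if len(shapes) > 1:
        raise ValidationError(f"matrices differ in size: {sorted(shapes)}")
    avg = np.mean([m.W for m in cohort], axis=0)
    N = avg.shape[0]
    if not _connected(avg):
        comps = _components(avg)
        raise ValidationError(
            f"average network is disconnected; components: {comps}")
    g = nx.from_numpy_array(avg)
    tree = nx.maximum_spanning_tree(g, weight="weight")
    mask = np.zeros((N, N), dtype=bool)
    for i, j in tree.edges:
        mask[i, j] = mask[j, i] = True
    remaining = [(avg[i, j], i, j)
                 for i, j in zip(*np.triu_indices(N, k=1))
                 if avg[i, j] > 0 and not mask[i, j]]
    remaining.sort(key=lambda t: (-t[0], t[1], t[2]))
    for w, i, j in remaining:
        if mask.sum() / N >= target_mean_degree:  # mask.sum() counts both triangles
            break
        mask[i, j] = mask[j, i] = True
    return mask


def apply_mask(m: ConnectomeMatrix, mask: np.ndarray) -> ConnectomeMatrix:
    """Zero all entries outside ``mask``; symmetry-preserving and idempotent."""
    mask = np.asarray(mask)
    if mask.shape != m.W.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match matrix {m.W.shape}")
    out = m.copy()
    out.W = np.where(mask.astype(bool), m.W, 0.0)
    return out


def write_matrix(m: ConnectomeMatrix, path) -> None:
    """Write as comma-delimited text with a label header row (UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(m.labels) + "\n")
        for row in m.W:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_matrix(path, subject_id: str = "") -> ConnectomeMatrix:
    """Read a delimited (comma or tab) square matrix, optional label header.

    The matrix is validated (square, symmetric within ``ASYMMETRY_TOL``,
    entries in [0, 1], zero diagonal) and then symmetrized as (W + W.T)/2 to
    remove round-off asymmetry.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    first = [t.strip() for t in lines[0].split(delim)]
    labels: list[str] = []
    if not all(_is_number(t) for t in first):
        labels = first
        lines = lines[1:]
    try:
        rows = [[float(t) for t in ln.split(delim)] for ln in lines]
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric entry ({exc})") from exc
    lens = {len(r) for r in rows}
    if len(lens) != 1:
        raise ValidationError(f"{path}: ragged rows with lengths {sorted(lens)}")
    W = np.array(rows, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValidationError(f"{path}: not square, shape {W.shape}")
    if labels and len(labels) != W.shape[0]:
        raise ValidationError(
            f"{path}: {len(labels)} labels for {W.shape[0]} rows")
    validate_matrix(W)
    W = (W + W.T) / 2.0
    return ConnectomeMatrix(W=W, labels=labels or [], subject_id=subject_id)
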