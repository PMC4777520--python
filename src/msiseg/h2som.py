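"""Hierarchical hyperbolic self-organizing map (H2SOM).

Prototypes live on the rings of a regular hyperbolic lattice: one root,
then rings of 7, 21 and 56 nodes (the vertex rings of the {3,7} triangular
tessellation; ring sizes follow r_{k+1} = 3 r_k - r_{k-1} with r_0 := 0,
r_1 = 7). Training proceeds level by level from the root outward: each
ring is initialized from its parents, then refined by online SOM updates
under the cosine distance, with the search for the winning node restricted
to the children of the best-matching parents (beam search). Sampling is
dataset-balanced so every time point contributes equally regardless of its
pixel count.

Prototypes are kept at unit norm, so the cosine best-matching unit reduces
to a maximal dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import PeakProfileSet

__all__ = [
    "LatticeNode",
    "HyperbolicLattice",
    "H2SOMParams",
    "H2SOMModel",
    "ClusterAssignment",
    "build_lattice",
    "ring_sizes",
    "cosine_distance",
    "sampling_weights",
    "train",
    "best_matching_unit",
    "assign",
]

#: Hyperbolic radius step between consecutive rings.
_RING_RHO_STEP = 1.5


def ring_sizes(n_rings: int) -> list[int]:
    """Ring sizes [1, 7, 21, 56, ...]: r_{k+1} = 3 r_k - r_{k-1}, r_0 := 0."""
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    sizes = [1, 7]
    prev, cur = 0, 7  # the recurrence runs on r_0 = 0, not on the root ring
    for _ in range(n_rings - 1):
        prev, cur = cur, 3 * cur - prev
        sizes.append(cur)
    return sizes[:n_rings + 1]


@dataclass
class LatticeNode:
    id: int
    level: int
    angle: float          # polar angle in the hyperbolic plane
    rho: float            # hyperbolic radial coordinate
    parent: int | None
    children: list[int] = field(default_factory=list)


def _hyperbolic_distance(rho1: float, phi1: float,
                         rho2: float, phi2: float) -> float:
    """Distance via the hyperbolic law of cosines (polar coordinates)."""
    c = (np.cosh(rho1) * np.cosh(rho2)
         - np.sinh(rho1) * np.sinh(rho2) * np.cos(phi1 - phi2))
    return float(np.arccosh(max(c, 1.0)))


@dataclass
class HyperbolicLattice:
    """Ringed node graph with parent/child edges.

    Node ids are dense integers ordered by (level, angle); ring k occupies
    ids ``ring_start[k] .. ring_start[k] + ring_sizes[k] - 1``.
    """

    nodes: list[LatticeNode]
    ring_sizes: list[int]
    ring_start: list[int]

    @property
    def n_rings(self) -> int:
        return len(self.ring_sizes) - 1

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def ring_ids(self, level: int) -> np.ndarray:
        s = self.ring_start[level]
        return np.arange(s, s + self.ring_sizes[level])

    def ancestor(self, node_id: int, level: int) -> int:
        node = self.nodes[node_id]
        if level > node.level:
            raise ValueError("requested level below the node's level")
        while node.level > level:
            node = self.nodes[node.parent]
        return node.id

    def ancestor_table(self) -> np.ndarray:
        """(n_nodes, n_rings+1) array; entry [i, k] = ancestor of i at level
        k, or -1 where the node sits above level k."""
        table = np.full((self.n_nodes, self.n_rings + 1), -1, dtype=np.int64)
        for node in self.nodes:
            table[node.id, node.level] = node.id
            for k in range(node.level):
                table[node.id, k] = self.ancestor(node.id, k)
        return table


def build_lattice(n_rings: int = 3) -> HyperbolicLattice:
    """Construct the ringed lattice with equal-angle nodes per ring.

    Ring k sits at hyperbolic radius ``k * 1.5``; each node is parented to
    the hyperbolically nearest node of the previous ring (ties to the lower
    id).
    """
    sizes = ring_sizes(n_rings)
    starts = list(np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int))
    nodes: list[LatticeNode] = [
        LatticeNode(id=0, level=0, angle=0.0, rho=0.0, parent=None)]
    for level in range(1, n_rings + 1):
        rho = level * _RING_RHO_STEP
        size = sizes[level]
        prev_ids = list(range(starts[level - 1],
                              starts[level - 1] + sizes[level - 1]))
        for j in range(size):
            angle = 2.0 * np.pi * j / size
            nid = starts[level] + j
            dists = [_hyperbolic_distance(rho, angle,
                                          nodes[p].rho, nodes[p].angle)
                     for p in prev_ids]
            best = min(range(len(prev_ids)),
                       key=lambda i: (round(dists[i], 12), prev_ids[i]))
            parent = prev_ids[best]
            node = LatticeNode(id=nid, level=level, angle=angle, rho=rho,
                               parent=parent)
            nodes.append(node)
            nodes[parent].children.append(nid)
    return HyperbolicLattice(nodes=nodes, ring_sizes=sizes,
                             ring_start=starts)


# ---------------------------------------------------------------------------
# distances and sampling
# ---------------------------------------------------------------------------

def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(a, b); undefined (error) for zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(a, b) / (na * nb))


def sampling_weights(profile_counts) -> np.ndarray:
    """Per-spectrum sampling probabilities balancing the datasets.

    Each dataset is drawn with probability 1/|T| and a spectrum uniformly
    within it, so spectrum i of dataset t has probability
    ``1 / (|T| * count_t)``. Returns the concatenated probability vector.
    """
    counts = np.asarray(list(profile_counts), dtype=np.int64)
    if counts.size == 0 or np.any(counts < 1):
        raise ValueError("every dataset needs at least one profile")
    T = len(counts)
    return np.repeat(1.0 / (T * counts.astype(float)), counts)


# ---------------------------------------------------------------------------
# model and training
# ---------------------------------------------------------------------------

@dataclass
class H2SOMParams:
    """Training hyperparameters.

    ``iters_per_level=None`` uses 20× the sample count, capped at
    ``max_iters_per_level``. Learning rate and ring-neighborhood width decay
    exponentially between their (start, end) values over each level.

    The default neighborhood is deliberately narrow: ring-k units then
    specialize competitively, surplus units stay parked near their parent
    direction and win (almost) nothing, and each well-separated data
    cluster keeps a single dominant node per ring — the coarse-to-fine
    reading of the hierarchy. Widen it (e.g. ``(2.0, 0.5)``) to trade that
    for a smoother ring layout with units spread along the data manifold.
    """

    n_rings: int = 3
    beam_width: int = 2
    learning_rate: tuple[float, float] = (0.5, 0.01)
    neighborhood: tuple[float, float] = (0.2, 0.05)
    iters_per_level: int | None = None
    max_iters_per_level: int = 100_000
    init_jitter: float = 0.05

    def resolved_iters(self, n_samples: int) -> int:
        if self.iters_per_level is not None:
            return int(self.iters_per_level)
        return int(min(20 * n_samples, self.max_iters_per_level))


@dataclass
class H2SOMModel:
    lattice: HyperbolicLattice
    prototypes: np.ndarray        # (n_nodes, n_features), unit rows
    params: H2SOMParams
    seed: int
    feature_mz: np.ndarray | None = None

    def save(self, path) -> None:
        np.savez(path,
                 prototypes=self.prototypes,
                 ring_sizes=np.asarray(self.lattice.ring_sizes),
                 seed=self.seed,
                 beam_width=self.params.beam_width,
                 feature_mz=(self.feature_mz
                             if self.feature_mz is not None else np.nan))

    @classmethod
    def load(cls, path) -> "H2SOMModel":
        with np.load(path, allow_pickle=False) as f:
            sizes = f["ring_sizes"]
            lattice = build_lattice(len(sizes) - 1)
            params = H2SOMParams(n_rings=len(sizes) - 1,
                                 beam_width=int(f["beam_width"]))
            feature_mz = f["feature_mz"]
            if feature_mz.ndim == 0:
                feature_mz = None
            return cls(lattice=lattice, prototypes=f["prototypes"],
                       params=params, seed=int(f["seed"]),
                       feature_mz=feature_mz)


@dataclass
class ClusterAssignment:
    """Per-spectrum leaf node and its ancestors at every level."""

    leaf_ids: np.ndarray          # (m,) node ids on the outermost ring
    ancestors: np.ndarray         # (m, n_rings+1) ancestor id per level
    index: pd.DataFrame           # t, r, x, y per row
    n_rings: int

    def at_level(self, level: int) -> np.ndarray:
        if not 0 <= level <= self.n_rings:
            raise ValueError(f"level must be in [0, {self.n_rings}]")
        return self.ancestors[:, level]

    def to_frame(self) -> pd.DataFrame:
        out = self.index.copy()
        out["leaf_id"] = self.leaf_ids
        for k in range(1, self.n_rings + 1):
            out[f"level{k}_id"] = self.ancestors[:, k]
        return out


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 0
    Xn = np.zeros_like(X, dtype=float)
    Xn[ok] = X[ok] / norms[ok, None]
    return Xn, ok


def _as_matrix(X) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(X, PeakProfileSet):
        return np.asarray(X.matrix, dtype=float), X.index
    return np.asarray(X, dtype=float), None


def _ring_distance(size: int) -> np.ndarray:
    """(size, size) circular index distance along a ring."""
    idx = np.arange(size)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, size - d)


def _beam_candidates(lattice: HyperbolicLattice, scores_by_level,
                     target_level: int, beam_width: int) -> np.ndarray:
    """Candidate node ids at ``target_level`` after a beam descent.

    ``scores_by_level[k]`` maps ring-k node ids (1D array aligned with
    ``lattice.ring_ids(k)``) to similarity scores of the query.
    """
    cand = lattice.ring_ids(1)
    for level in range(1, target_level):
        s = scores_by_level[level]
        start = lattice.ring_start[level]
        local = cand - start
        order = np.argsort(-s[local], kind="stable")
        top = cand[order[:beam_width]]
        nxt: list[int] = []
        for nid in np.sort(top):
            nxt.extend(lattice.nodes[nid].children)
        cand = np.array(sorted(nxt), dtype=np.int64)
    return cand


def train(X, lattice: HyperbolicLattice | None = None,
          params: H2SOMParams | None = None, seed: int = 0) -> H2SOMModel:
    """Fit the hierarchy root-outward with beam-restricted online updates.

    ``X`` is a :class:`~msiseg.preprocess.PeakProfileSet` (its ``t`` index
    drives dataset-balanced sampling) or a plain array (treated as one
    dataset). Zero-norm profiles are excluded from sampling. Deterministic
    for a fixed seed.
    """
    Xm, index = _as_matrix(X)
    if Xm.ndim != 2 or Xm.shape[0] == 0:
        raise ValueError("training needs at least one profile")
    if Xm.shape[1] < 2:
        raise ValueError("training needs at least two features")
    params = params or H2SOMParams()
    lattice = lattice or build_lattice(params.n_rings)
    rng = np.random.default_rng(abs(int(seed)) % (2 ** 32))

    Xn, ok = _normalize_rows(Xm)
    if index is not None:
        # equal mass per dataset, uniform within dataset
        t_vals = index["t"].to_numpy()
        probs = np.zeros(len(Xn))
        for t in np.unique(t_vals):
            sel = (t_vals == t) & ok
            if sel.any():
                probs[sel] = 1.0 / sel.sum()
        probs /= probs.sum()
    else:
        probs = ok / ok.sum()

    n_nodes = lattice.n_nodes
    d = Xm.shape[1]
    proto = np.zeros((n_nodes, d))
    root = Xn[ok].mean(axis=0)
    nrm = np.linalg.norm(root)
    proto[0] = root / nrm if nrm > 0 else root

    lr0, lr1 = params.learning_rate
    sg0, sg1 = params.neighborhood

    for level in range(1, lattice.n_rings + 1):
        ring = lattice.ring_ids(level)
        start = lattice.ring_start[level]
        size = len(ring)
        # init from parent prototypes plus seeded jitter
        for nid in ring:
            parent = lattice.nodes[nid].parent
            v = proto[parent] + params.init_jitter * rng.standard_normal(d)
            proto[nid] = v / np.linalg.norm(v)
        iters = params.resolved_iters(int(ok.sum()))
        if iters == 0:
            continue
        ring_d = _ring_distance(size)
        draws = rng.choice(len(Xn), size=iters, p=probs)
        denom = max(iters - 1, 1)
        P_ring = proto[start:start + size]
        for it in range(iters):
            f = it / denom
            lr = lr0 * (lr1 / lr0) ** f
            sg = sg0 * (sg1 / sg0) ** f
            x = Xn[draws[it]]
            if level == 1:
                cand = ring
            else:
                scores = {}
                for k in range(1, level):
                    rk = lattice.ring_ids(k)
                    scores[k] = proto[rk] @ x
                cand = _beam_candidates(lattice, scores, level,
                                        params.beam_width)
            local = cand - start
            win = local[np.argmax(P_ring[local] @ x)]
            h = np.exp(-ring_d[win] ** 2 / (2.0 * sg * sg))
            P_ring += lr * h[:, None] * (x[None, :] - P_ring)
            P_ring /= np.linalg.norm(P_ring, axis=1)[:, None]
    feature_mz = getattr(X, "feature_mz", None)
    return H2SOMModel(lattice=lattice, prototypes=proto, params=params,
                      seed=int(seed), feature_mz=feature_mz)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _batch_leaves(model: H2SOMModel, Xn: np.ndarray,
                  beam_width: int) -> np.ndarray:
    """Leaf best-matching unit per row via a vectorized beam descent."""
    lattice = model.lattice
    proto = model.prototypes
    m = Xn.shape[0]
    scores = {k: Xn @ proto[lattice.ring_ids(k)].T
              for k in range(1, lattice.n_rings + 1)}
    # active[i] = sorted candidate ids at the current level
    cand = np.broadcast_to(lattice.ring_ids(1), (m, lattice.ring_sizes[1]))
    for level in range(1, lattice.n_rings + 1):
        start = lattice.ring_start[level]
        s = np.full((m, lattice.ring_sizes[level]), -np.inf)
        rows = np.repeat(np.arange(m), cand.shape[1])
        cols = (cand - start).ravel()
        valid = cols >= 0
        s[rows[valid], cols[valid]] = scores[level][rows[valid], cols[valid]]
        if level == lattice.n_rings:
            return start + np.argmax(s, axis=1)
        order = np.argsort(-s, axis=1, kind="stable")[:, :beam_width]
        top = start + order
        ring = lattice.ring_ids(level)
        width = max(len(lattice.nodes[n].children) for n in ring)
        child_pad = np.full((lattice.n_nodes, width), -1, dtype=np.int64)
        for n in ring:
            ch = lattice.nodes[n].children
            child_pad[n, :len(ch)] = ch
        nxt = child_pad[top].reshape(m, -1)
        nxt = np.sort(nxt, axis=1)
        cand = nxt
    raise AssertionError("unreachable")


def best_matching_unit(model: H2SOMModel, x: np.ndarray,
                       beam_width: int | None = None) -> int:
    """Leaf node id best matching ``x`` under cosine similarity.

    The descent keeps the ``beam_width`` best nodes per level and expands
    only their children; with a beam at least as wide as every ring the
    result equals an exhaustive scan over all leaves. Ties resolve to the
    lowest node id.
    """
    x = np.asarray(x, dtype=float)
    n = np.linalg.norm(x)
    if n == 0:
        raise ValueError("cannot assign a zero profile")
    if beam_width is None:
        beam_width = model.params.beam_width
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    return int(_batch_leaves(model, (x / n)[None, :], beam_width)[0])


def assign(model: H2SOMModel, X, level: int,
           beam_width: int | None = None) -> ClusterAssignment:
    """Cluster every profile and expose ancestors at ``level``.

    ``level`` 0 is the root (all profiles together); the outermost ring
    returns the leaf ids themselves.
    """
    lattice = model.lattice
    if not 0 <= level <= lattice.n_rings:
        raise ValueError(f"level must be in [0, {lattice.n_rings}]")
    Xm, index = _as_matrix(X)
    Xn, ok = _normalize_rows(Xm)
    if not ok.all():
        raise ValueError("zero profiles cannot be assigned")
    if beam_width is None:
        beam_width = model.params.beam_width
    leaves = _batch_leaves(model, Xn, beam_width)
    table = lattice.ancestor_table()
    ancestors = table[leaves]
    if index is None:
        index = pd.DataFrame({
            "t": np.zeros(len(leaves), dtype=int),
            "r": ["unlabeled"] * len(leaves),
            "x": np.arange(len(leaves)),
            "y": np.zeros(len(leaves), dtype=int)})
    return ClusterAssignment(leaf_ids=leaves, ancestors=ancestors,
                             index=index.reset_index(drop=True),
                             n_rings=lattice.n_rings)
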