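"""Morphological complexity measures and distances between morphologies.

Complexity is measured on the epithelium only, following the idea that a
morphology is complex when the position of a cell is hard to predict from its
neighbors:

- **AV** (angle variation): per epithelial cell, the angles to all other
  epithelial cells are binned into seven distance categories; AV is the mean
  per-cell, per-category angle variance.  A flat sheet or a perfect sphere
  scores ~0; an irregularly folded sheet scores high.
- **OPC** (orientation patch count): cells are assigned to one of eight
  octants by the signs of their apical->basal axis; OPC counts contiguous
  same-octant patches of at least four cells.

Distances:

- **EMD**: symmetrized mean nearest-node distance; homology-free.
- **CMD**: mean absolute difference in local epithelial convexity over
  lineage-homologous nodes.
- **HMD**: Procrustes-style root-sum-square distance over homologous node
  positions (of mean morphologies when twins are averaged first).

EMD satisfies identity and symmetry by construction but is not guaranteed to
satisfy the triangle inequality.  AV, convexity, CMD and HMD (with alignment)
are invariant under rigid motions; OPC is translation- but *not*
rotation-invariant because octants are fixed in the lab frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import APICAL, BASAL, Morphology
from .neighbors import cell_contact_graph, lateral_same_type_pairs

N_CATEGORIES = 7
CATEGORY_RANGE = range(3, 10)  # c in {3, ..., 9}


@dataclass(frozen=True)
class ComplexityScore:
    av: float
    opc: int

    def __post_init__(self):
        if self.av < 0 or self.opc < 0:
            raise ValueError("complexity scores are non-negative")


@dataclass(frozen=True)
class DistanceRecord:
    emd: float
    cmd: float
    hmd: float
    homology: str = "initial_epithelial_labels"
    alignment: str = "procrustes"


def mean_adhesion_distance(m: Morphology) -> float:
    """Average adhesion distance of the epithelial cells (~ mean cell size).

    The adhesion distance of a node pair is the sum of their p_ADD, so the
    epithelial average is twice the mean epithelial p_ADD.
    """
    epi = m.epithelial_mask
    if not epi.any():
        raise ValueError("no epithelial nodes")
    return 2.0 * float(m.prop("p_ADD")[epi].mean())


def _cell_geometry(m: Morphology):
    """(labels, centers, apical positions, basal positions, unit axes)."""
    labels, ap, ba = m.epithelial_cells()
    A, B = m.pos[ap], m.pos[ba]
    axis = B - A
    norms = np.linalg.norm(axis, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate apical-basal axis")
    return labels, 0.5 * (A + B), A, B, axis / norms[:, None]


def angle_variation(m: Morphology, chunk: int = 256,
                    reference: str = "centers") -> float:
    """AV complexity: mean per-cell angle variance over distance categories.

    For each epithelial cell *i* the angle to cell *j* is measured between
    the apical->basal vector of *i* and the vector from the basal node of *j*
    to the apical node of *i*.  Cell pairs are grouped by distance into
    categories ``[c*p, (c+1)*p)`` for c = 3..9, where ``p`` is the mean
    epithelial adhesion distance; AV is the sum of per-category population
    variances divided by 7n.  Categories with fewer than two pairs
    contribute zero.  ``reference`` selects the pair-distance reference
    points: cell centers (the symmetric default) or apical nodes.
    """
    labels, centers, A, B, axes = _cell_geometry(m)
    if reference == "apical":
        centers = A
    elif reference != "centers":
        raise ValueError("reference must be centers|apical")
    n = len(labels)
    if n < 2:
        raise ValueError("AV needs at least two epithelial cells")
    p = mean_adhesion_distance(m)
    total = 0.0
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        # v2[i, j] = apical_i - basal_j ; angle against cell i's axis
        v2 = A[s:e, None, :] - B[None, :, :]
        v2n = np.linalg.norm(v2, axis=2)
        v1 = A[s:e] - B[s:e]
        v1n = np.linalg.norm(v1, axis=1)
        cosang = np.einsum("ik,ijk->ij", v1, v2) / (v1n[:, None] * np.where(
            v2n > 0, v2n, 1.0))
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        d = np.linalg.norm(centers[s:e, None, :] - centers[None, :, :], axis=2)
        cat = np.floor(d / p).astype(np.int64)
        valid = (cat >= 3) & (cat <= 9)
        valid[np.arange(e - s), np.arange(s, e)] = False
        for row in range(e - s):
            cats = cat[row][valid[row]]
            angs = ang[row][valid[row]]
            for c in CATEGORY_RANGE:
                sel = angs[cats == c]
                if len(sel) >= 2:
                    total += float(np.var(sel))
    return total / (N_CATEGORIES * n)


def _octants(m: Morphology) -> tuple[np.ndarray, np.ndarray]:
    """Octant index of each epithelial cell from its apical->basal axis.

    A zero component counts as positive (deterministic tie-break).
    """
    labels, ap, ba = m.epithelial_cells()
    v = m.pos[ba] - m.pos[ap]
    bits = (v >= 0).astype(np.int64)
    return labels, bits[:, 0] * 4 + bits[:, 1] * 2 + bits[:, 2]


def orientation_patch_count(m: Morphology, min_patch: int = 4) -> int:
    """OPC: number of contiguous same-octant cell patches of >= 4 cells."""
    labels, octant = _octants(m)
    n = len(labels)
    if n == 0:
        raise ValueError("no epithelial cells")
    _, ci, cj = cell_contact_graph(m)
    same = octant[ci] == octant[cj]
    ci, cj = ci[same], cj[same]
    adj = coo_matrix((np.ones(len(ci)), (ci, cj)), shape=(n, n))
    ncomp, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp, minlength=ncomp)
    return int(np.sum(sizes >= min_patch))


def complexity(m: Morphology) -> ComplexityScore:
    return ComplexityScore(av=angle_variation(m),
                           opc=orientation_patch_count(m))


# ---------------------------------------------------------------------------
# local convexity and homology-based distances
# ---------------------------------------------------------------------------

def local_convexity(m: Morphology) -> np.ndarray:
    """Per-node local convexity of the epithelium, NaN where undefined.

    For an epithelial node, v1 is the apical->basal unit axis of its cell and
    v_k are unit vectors to the contacting neighbor nodes of the same type
    (apical with apical, basal with basal); the convexity is the mean dot
    product.  It is ~0 on a flat sheet, approaches +1 at the tip of an
    evagination (a fold bulging toward the apical side) and -1 in an
    invagination, independently of the morphology's orientation in space.
    Returns an array over all nodes; non-epithelial or isolated nodes get NaN.
    """
    out = np.full(m.n_nodes, np.nan)
    epi = np.flatnonzero(m.epithelial_mask)
    if len(epi) == 0:
        return out
    axis = np.zeros((m.n_nodes, 3))
    ap = np.flatnonzero(m.kind == APICAL)
    v = m.pos[m.partner[ap]] - m.pos[ap]
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate apical-basal axis")
    v = v / norms[:, None]
    axis[ap] = v
    axis[m.partner[ap]] = v
    i, j = lateral_same_type_pairs(m)
    dots = np.zeros(m.n_nodes)
    counts = np.zeros(m.n_nodes)
    if len(i):
        d = m.pos[j] - m.pos[i]
        d = d / np.linalg.norm(d, axis=1)[:, None]
        np.add.at(dots, i, np.einsum("ij,ij->i", axis[i], d))
        np.add.at(dots, j, -np.einsum("ij,ij->i", axis[j], d))
        np.add.at(counts, i, 1.0)
        np.add.at(counts, j, 1.0)
    has = counts > 0
    out[has & m.epithelial_mask] = (dots[has & m.epithelial_mask]
                                    / counts[has & m.epithelial_mask])
    return out


def _homologous_node_index(m: Morphology) -> dict[tuple[int, int], int]:
    """(initial label, node kind) -> node index, for epithelial nodes whose
    cell carries one of the morphology's initial lineage labels."""
    initial = set(int(x) for x in m.initial_labels)
    out = {}
    for idx in np.flatnonzero(m.epithelial_mask):
        lab = int(m.label[idx])
        if lab in initial:
            out[(lab, int(m.kind[idx]))] = int(idx)
    return out


def cmd(m1: Morphology, m2: Morphology) -> float:
    """Convexity morphological distance over lineage-homologous nodes.

    Mean |convexity difference| over the epithelial nodes whose initial
    lineage labels are present in both morphologies and whose convexity is
    defined in both.  The normalizer is the actual shared homologous node
    count, so the measure is well defined for any initial sheet size.
    """
    h1, h2 = _homologous_node_index(m1), _homologous_node_index(m2)
    shared = sorted(set(h1) & set(h2))
    if not shared:
        raise ValueError("no shared homologous nodes")
    l1, l2 = local_convexity(m1), local_convexity(m2)
    a = np.array([l1[h1[k]] for k in shared])
    b = np.array([l2[h2[k]] for k in shared])
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no homologous nodes with defined convexity")
    return float(np.mean(np.abs(a[ok] - b[ok])))


def emd(m1: Morphology, m2: Morphology) -> float:
    """Euclidean minimal distance between two morphologies.

    Symmetrized mean nearest-node distance: each node of one morphology finds
    its nearest node in the other, in both directions, and the summed
    distances are divided by the total node count.  Needs no homology and
    compares morphologies of unequal size.
    """
    if m1.n_nodes == 0 or m2.n_nodes == 0:
        raise ValueError("empty morphology")
    t1, t2 = cKDTree(m1.pos), cKDTree(m2.pos)
    d12, _ = t2.query(m1.pos)
    d21, _ = t1.query(m2.pos)
    return float((d12.sum() + d21.sum()) / (m1.n_nodes + m2.n_nodes))


def mean_morphology(twins: list[Morphology]) -> Morphology:
    """Average the homologous nodes of stochastic twins.

    Per (initial label, node side) the position -- and, for completeness,
    properties and expression -- is averaged over all twins; the output is
    restricted to the homologous set shared by every twin.
    """
    if not twins:
        raise ValueError("at least one twin required")
    indexes = [_homologous_node_index(t) for t in twins]
    shared = sorted(set.intersection(*(set(ix) for ix in indexes)))
    if not shared:
        raise ValueError("no shared homologous nodes")
    ref = twins[0]
    rows = {k: [ix[k] for ix in indexes] for k in shared}
    n = len(shared)
    pos = np.zeros((n, 3))
    props = np.zeros((n, ref.props.shape[1]))
    expr = np.zeros((n, ref.n_genes))
    kind = np.zeros(n, np.int8)
    label = np.zeros(n, np.int64)
    for r, key in enumerate(shared):
        lab, kd = key
        idxs = rows[key]
        pos[r] = np.mean([t.pos[i] for t, i in zip(twins, idxs)], axis=0)
        props[r] = np.mean([t.props[i] for t, i in zip(twins, idxs)], axis=0)
        expr[r] = np.mean([t.expr[i] for t, i in zip(twins, idxs)], axis=0)
        kind[r], label[r] = kd, lab
    partner = np.full(n, -1, np.int64)
    where = {key: r for r, key in enumerate(shared)}
    for r, (lab, kd) in enumerate(shared):
        other = (lab, BASAL if kd == APICAL else APICAL)
        if other in where:
            partner[r] = where[other]
    labels_present = sorted({lab for lab, kd in shared
                             if (lab, APICAL) in where and (lab, BASAL) in where})
    keep = np.array([partner[r] >= 0 for r in range(n)])
    mm = Morphology(ids=np.arange(1, n + 1), pos=pos, kind=kind, label=label,
                    partner=partner, props=props, expr=expr,
                    phase=np.zeros(n), initial_labels=labels_present,
                    time=ref.time)
    mm.delete_nodes(~keep)
    return mm


def _procrustes_align(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center both point sets and rotate Y onto X (proper rotation, no
    scaling), returning the transformed copies."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Yc.T @ Xc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return Xc, Yc @ R


def hmd(m1: Morphology, m2: Morphology, align: bool = True) -> float:
    """Homologous morphological distance (Procrustes-style).

    Square root of the summed squared position differences over shared
    homologous nodes, after optional superimposition (centroid translation
    plus optimal rotation, no scaling).
    """
    h1, h2 = _homologous_node_index(m1), _homologous_node_index(m2)
    shared = sorted(set(h1) & set(h2))
    if not shared:
        raise ValueError("no shared homologous nodes")
    X = np.array([m1.pos[h1[k]] for k in shared])
    Y = np.array([m2.pos[h2[k]] for k in shared])
    if align:
        X, Y = _procrustes_align(X, Y)
    return float(np.sqrt(np.sum((X - Y) ** 2)))


def distances(m1: Morphology, m2: Morphology, align: bool = True) -> DistanceRecord:
    return DistanceRecord(emd=emd(m1, m2), cmd=cmd(m1, m2),
                          hmd=hmd(m1, m2, align=align),
                          alignment="procrustes" if align else "none")


def count_expression_territories(m: Morphology, genes=None,
                                 min_level: float = 0.05,
                                 min_size: int = 3) -> int:
    """Number of contiguous territories of distinct dominant gene expression.

    Each epithelial cell is assigned to the gene (among ``genes``, default
    all) with the highest mean apical+basal expression, provided that level
    exceeds ``min_level``; territories are connected components of
    same-assignment cells on the cell contact graph with at least
    ``min_size`` cells.
    """
    labels, ap, ba = m.epithelial_cells()
    genes = list(range(m.n_genes)) if genes is None else list(genes)
    expr = 0.5 * (m.expr[ap][:, genes] + m.expr[ba][:, genes])
    assign = np.argmax(expr, axis=1)
    level = expr[np.arange(len(labels)), assign]
    assign[level < min_level] = -1
    _, ci, cj = cell_contact_graph(m)
    same = (assign[ci] == assign[cj]) & (assign[ci] >= 0)
    n = len(labels)
    adj = coo_matrix((np.ones(same.sum()), (ci[same], cj[same])), shape=(n, n))
    ncomp, comp = connected_components(adj, directed=False)
    count = 0
    for c in range(ncomp):
        members = comp == c
        if members.sum() >= min_size and assign[members][0] >= 0:
            count += 1
    return count
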