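"""Contact detection between nodes.

Two nodes are *in contact* when their center distance is below the sum of
their adhesion radii (p_ADD).  The same criterion defines the mechanical
interaction range, the diffusion exchange graph, and the neighbor graphs used
by the morphometric measures.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def contact_pairs(pos: np.ndarray, p_add: np.ndarray,
                  partner: np.ndarray | None = None):
    """Unordered node pairs within adhesion range.

    Returns (i, j, delta, dist) with i < j, ``delta = pos[j] - pos[i]`` and
    ``dist`` the Euclidean center distance.  Apical-basal partner pairs are
    excluded (they interact through the epithelial spring instead).
    """
    if len(pos) < 2:
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros((0, 3)), np.zeros(0)
    cutoff = 2.0 * float(np.max(p_add))
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros((0, 3)), np.zeros(0)
    i, j = pairs[:, 0], pairs[:, 1]
    delta = pos[j] - pos[i]
    dist = np.linalg.norm(delta, axis=1)
    keep = dist < (p_add[i] + p_add[j])
    if partner is not None:
        keep &= partner[i] != j
    i, j, delta, dist = i[keep], j[keep], delta[keep], dist[keep]
    order = np.lexsort((j, i))  # deterministic ordering
    return i[order], j[order], delta[order], dist[order]


def lateral_same_type_pairs(m) -> tuple[np.ndarray, np.ndarray]:
    """Contacting epithelial node pairs of the same side (apical-apical or
    basal-basal), as arrays (i, j) of node indices with i < j."""
    i, j, _, _ = contact_pairs(m.pos, m.prop("p_ADD"), m.partner)
    same = (m.kind[i] == m.kind[j]) & (m.kind[i] <= 1)
    return i[same], j[same]


def cell_contact_graph(m) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Epithelial cell adjacency from lateral same-side node contacts.

    Returns (labels, ci, cj): labels of the epithelial cells (sorted) and
    index pairs into that label array for every contacting cell pair.
    """
    labels, _, _ = m.epithelial_cells()
    pos_of = {int(lab): k for k, lab in enumerate(labels)}
    i, j = lateral_same_type_pairs(m)
    ci = np.array([pos_of[int(m.label[a])] for a in i], dtype=np.int64)
    cj = np.array([pos_of[int(m.label[b])] for b in j], dtype=np.int64)
    keep = ci != cj
    ci, cj = ci[keep], cj[keep]
    lo, hi = np.minimum(ci, cj), np.maximum(ci, cj)
    uniq = np.unique(np.stack([lo, hi], axis=1), axis=0) if len(lo) else \
        np.zeros((0, 2), dtype=np.int64)
    return labels, uniq[:, 0], uniq[:, 1]
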