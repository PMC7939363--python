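"""Core domain types for developmental-mechanism simulations.

A *morphology* is a labelled collection of nodes in 3D: epithelial cells are
two-node cylinders (one apical, one basal node), mesenchymal cells and
extracellular-matrix (ECM) material are single spherical nodes.  Every node
carries mechanical properties and a vector of gene-product concentrations.

A *developmental mechanism* is a signed, weighted gene network together with
per-gene diffusion/degradation rates and couplings from genes to cell
behaviors or mechanical properties.  Its non-zero parameters form the mutable
"genotype" that the screening modules perturb.

Internally a morphology is stored as a structure of NumPy arrays for speed;
:class:`Node` and :class:`Cell` are lightweight views for inspection and
serialization.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# node kind codes
APICAL = 0
BASAL = 1
MESENCHYMAL = 2
ECM = 3

KIND_NAMES = {
    APICAL: "epithelial_apical",
    BASAL: "epithelial_basal",
    MESENCHYMAL: "mesenchymal",
    ECM: "ecm",
}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}

# quiescent mechanical defaults: a flat sheet built with these is at rest
DEFAULT_P_ADD = 0.65
DEFAULT_P_EQD = 0.5
DEFAULT_P_EQS = 0.5
DEFAULT_P_ERP = 1.0
DEFAULT_P_EST = 1.0
DEFAULT_P_PHA = 0.0

PROP_COLUMNS = ("p_ADD", "p_EQD", "p_EQS", "p_ERP", "p_EST", "p_PHA")


@dataclass
class Node:
    """Read-only view of a single node."""

    id: int
    kind: str
    position: np.ndarray
    p_ADD: float
    p_EQD: float
    p_EQS: float
    p_ERP: float
    p_EST: float
    p_PHA: float
    expression: np.ndarray


@dataclass
class Cell:
    """A lineage-labelled cell: an epithelial node pair or a single node."""

    label: int
    kind: str  # "epithelial" | "mesenchymal"
    node_ids: tuple[int, ...]  # (apical, basal) or (node,)


class Morphology:
    """Labelled node set in 3D with mechanics and gene expression.

    Arrays (all aligned on the node axis):

    - ``ids``       unique integer node ids
    - ``pos``       (n, 3) positions, model length units
    - ``kind``      node kind codes (APICAL/BASAL/MESENCHYMAL/ECM)
    - ``label``     lineage label of the owning cell (0 for ECM)
    - ``partner``   array index of the other node of the same epithelial
                    cell, -1 otherwise
    - ``props``     (n, 6) mechanical properties in PROP_COLUMNS order
    - ``expr``      (n, n_genes) gene-product concentrations (>= 0)
    - ``phase``     cell-cycle phase (accumulates on apical/mesenchymal nodes)
    """

    def __init__(self, ids, pos, kind, label, partner, props, expr, phase,
                 initial_labels, time=0.0, next_id=None, next_label=None):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.pos = np.asarray(pos, dtype=np.float64)
        self.kind = np.asarray(kind, dtype=np.int8)
        self.label = np.asarray(label, dtype=np.int64)
        self.partner = np.asarray(partner, dtype=np.int64)
        self.props = np.asarray(props, dtype=np.float64)
        self.expr = np.asarray(expr, dtype=np.float64)
        self.phase = np.asarray(phase, dtype=np.float64)
        self.initial_labels = np.asarray(sorted(initial_labels), dtype=np.int64)
        self.time = float(time)
        self.next_id = int(next_id if next_id is not None
                           else (self.ids.max() + 1 if len(self.ids) else 1))
        self.next_label = int(next_label if next_label is not None
                              else (self.label.max() + 1 if len(self.label) else 1))

    # ------------------------------------------------------------------ views
    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    @property
    def epithelial_mask(self) -> np.ndarray:
        return self.kind <= BASAL

    @property
    def apical_mask(self) -> np.ndarray:
        return self.kind == APICAL

    @property
    def basal_mask(self) -> np.ndarray:
        return self.kind == BASAL

    def prop(self, name: str) -> np.ndarray:
        return self.props[:, PROP_COLUMNS.index(name)]

    def node(self, index: int) -> Node:
        return Node(
            id=int(self.ids[index]), kind=KIND_NAMES[int(self.kind[index])],
            position=self.pos[index].copy(),
            **{c: float(self.props[index, j]) for j, c in enumerate(PROP_COLUMNS)},
            expression=self.expr[index].copy(),
        )

    def cells(self) -> list[Cell]:
        out = []
        seen = set()
        for i in range(self.n_nodes):
            k = int(self.kind[i])
            if k == ECM:
                continue
            lab = int(self.label[i])
            if lab in seen:
                continue
            seen.add(lab)
            if k in (APICAL, BASAL):
                j = int(self.partner[i])
                ap, ba = (i, j) if k == APICAL else (j, i)
                out.append(Cell(lab, "epithelial",
                                (int(self.ids[ap]), int(self.ids[ba]))))
            else:
                out.append(Cell(lab, "mesenchymal", (int(self.ids[i]),)))
        return out

    def epithelial_cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (labels, apical indices, basal indices), label-sorted."""
        ap = np.flatnonzero(self.kind == APICAL)
        order = np.argsort(self.label[ap], kind="stable")
        ap = ap[order]
        return self.label[ap].copy(), ap, self.partner[ap].copy()

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit apical->basal axis per epithelial cell.

        Returns (labels, (m,3) unit vectors) ordered as epithelial_cells().
        """
        labels, ap, ba = self.epithelial_cells()
        v = self.pos[ba] - self.pos[ap]
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("degenerate apical-basal axis (zero length)")
        return labels, v / norms[:, None]

    # -------------------------------------------------------------- mutation
    def copy(self) -> "Morphology":
        return Morphology(self.ids.copy(), self.pos.copy(), self.kind.copy(),
                          self.label.copy(), self.partner.copy(),
                          self.props.copy(), self.expr.copy(),
                          self.phase.copy(), self.initial_labels.copy(),
                          self.time, self.next_id, self.next_label)

    def append_nodes(self, pos, kind, label, partner, props, expr, phase):
        """Append nodes; ``partner`` holds array indices (new rows allowed)."""
        k = len(pos)
        new_ids = np.arange(self.next_id, self.next_id + k, dtype=np.int64)
        self.next_id += k
        self.ids = np.concatenate([self.ids, new_ids])
        self.pos = np.vstack([self.pos, pos])
        self.kind = np.concatenate([self.kind, np.asarray(kind, np.int8)])
        self.label = np.concatenate([self.label, np.asarray(label, np.int64)])
        self.partner = np.concatenate([self.partner, np.asarray(partner, np.int64)])
        self.props = np.vstack([self.props, props])
        self.expr = np.vstack([self.expr, expr])
        self.phase = np.concatenate([self.phase, np.asarray(phase, np.float64)])
        return new_ids

    def delete_nodes(self, index_mask: np.ndarray) -> None:
        """Delete nodes flagged in the boolean mask, remapping partners."""
        keep = ~index_mask
        remap = -np.ones(self.n_nodes, dtype=np.int64)
        remap[keep] = np.arange(keep.sum())
        self.ids = self.ids[keep]
        self.pos = self.pos[keep]
        self.kind = self.kind[keep]
        self.label = self.label[keep]
        old_partner = self.partner[keep]
        new_partner = np.where(old_partner >= 0, remap[old_partner], -1)
        self.partner = new_partner
        self.props = self.props[keep]
        self.expr = self.expr[keep]
        self.phase = self.phase[keep]

    def fresh_label(self) -> int:
        lab = self.next_label
        self.next_label += 1
        return lab

    # ----------------------------------------------------------------- io
    def to_frame(self) -> pd.DataFrame:
        cols = {
            "id": self.ids,
            "cell_label": self.label,
            "kind": [KIND_NAMES[int(k)] for k in self.kind],
            "x": self.pos[:, 0], "y": self.pos[:, 1], "z": self.pos[:, 2],
        }
        for j, c in enumerate(PROP_COLUMNS):
            cols[c] = self.props[:, j]
        cols["partner_id"] = np.where(
            self.partner >= 0, self.ids[np.clip(self.partner, 0, None)], -1)
        cols["phase"] = self.phase
        for g in range(self.n_genes):
            cols[f"g{g + 1}"] = self.expr[:, g]
        return pd.DataFrame(cols)

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# time=%r\n" % self.time)
            fh.write("# initial_labels=%s\n"
                     % ",".join(str(x) for x in self.initial_labels))
            self.to_frame().to_csv(fh, index=False, float_format="%.17g")

    def save_ply(self, path) -> None:
        """ASCII PLY point export (positions + node kind) for viewers."""
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n"
                     f"element vertex {self.n_nodes}\n"
                     "property float x\nproperty float y\nproperty float z\n"
                     "property uchar kind\nend_header\n")
            for p, k in zip(self.pos, self.kind):
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {int(k)}\n")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, initial_labels, time=0.0):
        ids = df["id"].to_numpy(np.int64)
        id_to_idx = {int(v): i for i, v in enumerate(ids)}
        partner = np.array([id_to_idx.get(int(p), -1)
                            for p in df["partner_id"]], dtype=np.int64)
        gcols = [c for c in df.columns if c.startswith("g") and c[1:].isdigit()]
        gcols.sort(key=lambda c: int(c[1:]))
        return cls(
            ids=ids,
            pos=df[["x", "y", "z"]].to_numpy(np.float64),
            kind=np.array([KIND_CODES[k] for k in df["kind"]], np.int8),
            label=df["cell_label"].to_numpy(np.int64),
            partner=partner,
            props=df[list(PROP_COLUMNS)].to_numpy(np.float64),
            expr=df[gcols].to_numpy(np.float64),
            phase=df["phase"].to_numpy(np.float64),
            initial_labels=initial_labels, time=time,
        )

    @classmethod
    def load_csv(cls, path):
        with open(path) as fh:
            header = [fh.readline() for _ in range(2)]
            time = float(header[0].split("=", 1)[1])
            lab_txt = header[1].split("=", 1)[1].strip()
            labels = [int(x) for x in lab_txt.split(",")] if lab_txt else []
            df = pd.read_csv(_io.StringIO(fh.read()),
                             float_precision="round_trip")
        return cls.from_frame(df, labels, time)

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("non-finite node positions")
        if np.any(self.expr < 0):
            raise ValueError("negative gene expression")
        if np.any(self.prop("p_ADD") < self.prop("p_EQD")):
            raise ValueError("p_ADD < p_EQD")
        epi = np.flatnonzero(self.epithelial_mask)
        for i in epi:
            j = self.partner[i]
            if j < 0 or self.partner[j] != i or self.kind[j] == self.kind[i]:
                raise ValueError("broken apical-basal pairing")
            if self.label[j] != self.label[i]:
                raise ValueError("apical-basal pair with mismatched labels")
        non_ecm = self.label[self.kind != ECM]
        labels, counts = np.unique(non_ecm, return_counts=True)
        kinds = {int(self.label[i]): int(self.kind[i])
                 for i in range(self.n_nodes) if self.kind[i] != ECM}
        for lab, cnt in zip(labels, counts):
            expected = 2 if kinds[int(lab)] <= BASAL else 1
            if cnt != expected:
                raise ValueError(f"label {lab} used by {cnt} nodes")


# ---------------------------------------------------------------------------
# gene network / mechanism types
# ---------------------------------------------------------------------------

#: couplings a gene may regulate; rate-like targets get log-uniform strengths
BEHAVIOR_TARGETS = (
    "division",               # cell-cycle phase progression rate (p_PHA)
    "apoptosis",              # shrink p_EQD, remove below minimal radius
    "contraction_apical",     # d(p_EQD)/dt on apical nodes
    "contraction_basal",      # d(p_EQD)/dt on basal nodes
    "contraction_mesenchymal",
    "ecm_secretion",
    "emt",                    # epithelial-to-mesenchymal transition
    "adhesion",               # d(p_ADD)/dt
    "eqs",                    # d(p_EQS)/dt (epithelial spring rest length)
    "erp",                    # d(p_ERP)/dt (bending resistance)
    "est",                    # d(p_EST)/dt (rotational bending resistance)
)
RATE_LIKE_TARGETS = frozenset(
    {"division", "apoptosis", "ecm_secretion", "emt"})


@dataclass(frozen=True)
class GeneSpec:
    """Per-gene transport spec: diffusibility and kinetic rates."""

    diffusible: bool
    diffusion_rate: float
    degradation_rate: float

    def __post_init__(self):
        if self.diffusion_rate < 0 or self.degradation_rate < 0:
            raise ValueError("rates must be >= 0")
        if not self.diffusible and self.diffusion_rate != 0:
            raise ValueError("non-diffusible gene with diffusion_rate != 0")


@dataclass(frozen=True)
class Coupling:
    gene: int
    target: str
    strength: float

    def __post_init__(self):
        if self.target not in BEHAVIOR_TARGETS:
            raise ValueError(f"unknown behavior target {self.target!r}")


@dataclass
class DevMechanism:
    """A gene network plus regulated cell behaviors: the simulated genotype.

    ``T[l, k]`` is the signed strength with which gene product *l* activates
    (positive) or inhibits (negative) transcription of gene product *k*.
    """

    n_genes: int
    T: np.ndarray
    gene_specs: list[GeneSpec]
    couplings: list[Coupling] = field(default_factory=list)
    default_division_rate: float = 0.0

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=np.float64)
        if self.T.shape != (self.n_genes, self.n_genes):
            raise ValueError("T must be n_genes x n_genes")
        if len(self.gene_specs) != self.n_genes:
            raise ValueError("one GeneSpec per gene required")

    # --------------------------------------------------------------- params
    def parameter_descriptors(self) -> list[tuple]:
        """Ordered descriptors of every non-zero parameter (the genotype).

        Descriptors: ("T", l, k), ("coupling", i), ("diffusion", g),
        ("degradation", g) -- only entries currently non-zero are listed.
        """
        out = []
        nz = np.argwhere(self.T != 0.0)
        for l, k in nz:
            out.append(("T", int(l), int(k)))
        for i in range(len(self.couplings)):
            out.append(("coupling", i))
        for g, spec in enumerate(self.gene_specs):
            if spec.diffusion_rate != 0.0:
                out.append(("diffusion", g))
        for g, spec in enumerate(self.gene_specs):
            if spec.degradation_rate != 0.0:
                out.append(("degradation", g))
        return out

    @property
    def parameters(self) -> np.ndarray:
        return np.array([self.get_parameter(d)
                         for d in self.parameter_descriptors()])

    @property
    def n_interactions(self) -> int:
        """N_c: gene-gene interactions plus gene-behavior couplings."""
        return int(np.count_nonzero(self.T)) + len(self.couplings)

    def get_parameter(self, desc) -> float:
        tag = desc[0]
        if tag == "T":
            return float(self.T[desc[1], desc[2]])
        if tag == "coupling":
            return self.couplings[desc[1]].strength
        if tag == "diffusion":
            return self.gene_specs[desc[1]].diffusion_rate
        if tag == "degradation":
            return self.gene_specs[desc[1]].degradation_rate
        raise KeyError(desc)

    def with_parameter(self, desc, value: float) -> "DevMechanism":
        """Return a copy with one parameter set to ``value``.

        Rate-like parameters (diffusion, degradation) are floored at zero;
        interaction strengths and coupling strengths may change sign.
        """
        m = self.copy()
        tag = desc[0]
        if tag == "T":
            m.T[desc[1], desc[2]] = value
        elif tag == "coupling":
            i = desc[1]
            m.couplings[i] = replace(m.couplings[i], strength=value)
        elif tag == "diffusion":
            g = desc[1]
            m.gene_specs[g] = replace(m.gene_specs[g],
                                      diffusion_rate=max(0.0, value))
        elif tag == "degradation":
            g = desc[1]
            m.gene_specs[g] = replace(m.gene_specs[g],
                                      degradation_rate=max(0.0, value))
        else:
            raise KeyError(desc)
        return m

    def without_interaction(self, index: int) -> "DevMechanism":
        """Delete the index-th interaction (T entries first, then couplings)."""
        n_t = int(np.count_nonzero(self.T))
        m = self.copy()
        if index < n_t:
            l, k = np.argwhere(self.T != 0.0)[index]
            m.T[l, k] = 0.0
        else:
            del m.couplings[index - n_t]
        return m

    def copy(self) -> "DevMechanism":
        return DevMechanism(self.n_genes, self.T.copy(),
                            list(self.gene_specs), list(self.couplings),
                            self.default_division_rate)

    # ------------------------------------------------------------------- io
    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# devozoo mechanism\n")
            fh.write("n_genes\t%d\n" % self.n_genes)
            fh.write("default_division_rate\t%r\n" % self.default_division_rate)
            fh.write("# gene\tdiffusible\tdiffusion_rate\tdegradation_rate\n")
            for g, s in enumerate(self.gene_specs):
                fh.write("gene\t%d\t%d\t%r\t%r\n"
                         % (g, int(s.diffusible), s.diffusion_rate,
                            s.degradation_rate))
            fh.write("# source\ttarget\tstrength\n")
            for l, k in np.argwhere(self.T != 0.0):
                fh.write("edge\tg%d\tg%d\t%r\n" % (l, k, float(self.T[l, k])))
            for c in self.couplings:
                fh.write("edge\tg%d\t%s\t%r\n" % (c.gene, c.target, c.strength))

    @classmethod
    def load(cls, path) -> "DevMechanism":
        n_genes = None
        div_rate = 0.0
        specs: dict[int, GeneSpec] = {}
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "n_genes":
                    n_genes = int(parts[1])
                elif parts[0] == "default_division_rate":
                    div_rate = float(parts[1])
                elif parts[0] == "gene":
                    g = int(parts[1])
                    specs[g] = GeneSpec(bool(int(parts[2])),
                                        float(parts[3]), float(parts[4]))
                elif parts[0] == "edge":
                    edges.append((parts[1], parts[2], float(parts[3])))
        T = np.zeros((n_genes, n_genes))
        couplings = []
        for src, dst, w in edges:
            l = int(src[1:])
            if dst.startswith("g") and dst[1:].isdigit():
                T[l, int(dst[1:])] = w
            else:
                couplings.append(Coupling(l, dst, w))
        gene_specs = [specs[g] for g in range(n_genes)]
        return cls(n_genes, T, gene_specs, couplings, div_rate)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def centered_hex_count(rings: int) -> int:
    """Cells in a centered hexagonal sheet of the given ring radius."""
    return 3 * rings * (rings + 1) + 1


def _hex_lattice(rings: int, spacing: float) -> np.ndarray:
    """(m, 2) xy coordinates of a centered hexagonal lattice."""
    pts = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if abs(q + r) <= rings:
                pts.append((spacing * (q + r / 2.0),
                            spacing * r * np.sqrt(3.0) / 2.0))
    return np.array(sorted(pts))


def build_initial_morphology(sheet_rings: int, gradient_gene: int = 0,
                             n_genes: int = 10) -> Morphology:
    """Flat hexagonal epithelial sheet over a matching mesenchymal layer.

    Every simulation starts from this morphology: one apical and one basal
    node per epithelial cell (axes parallel to z), an equal-count mesenchymal
    layer one cell diameter below the basal plane, and ``gradient_gene``
    expressed as a linear gradient along x on the epithelial cells.  All
    mechanical properties take the quiescent defaults, so with an inert
    mechanism nothing moves.
    """
    if sheet_rings < 1:
        raise ValueError("sheet_rings must be >= 1")
    spacing = 2.0 * DEFAULT_P_EQD
    xy = _hex_lattice(sheet_rings, spacing)
    m = len(xy)
    assert m == centered_hex_count(sheet_rings)

    n = 3 * m  # apical + basal + mesenchymal
    pos = np.empty((n, 3))
    pos[:m, :2] = xy
    pos[:m, 2] = 1.0      # apical plane
    pos[m:2 * m, :2] = xy
    pos[m:2 * m, 2] = 0.0  # basal plane
    pos[2 * m:, :2] = xy
    pos[2 * m:, 2] = -1.0  # mesenchymal layer

    kind = np.concatenate([np.full(m, APICAL), np.full(m, BASAL),
                           np.full(m, MESENCHYMAL)]).astype(np.int8)
    epi_labels = np.arange(1, m + 1)
    label = np.concatenate([epi_labels, epi_labels,
                            np.arange(m + 1, 2 * m + 1)])
    partner = np.concatenate([np.arange(m, 2 * m), np.arange(0, m),
                              np.full(m, -1)])
    props = np.tile([DEFAULT_P_ADD, DEFAULT_P_EQD, DEFAULT_P_EQS,
                     DEFAULT_P_ERP, DEFAULT_P_EST, DEFAULT_P_PHA], (n, 1))

    expr = np.zeros((n, n_genes))
    x = pos[:, 0]
    span = x[:m].max() - x[:m].min()
    grad = (x[:2 * m] - x[:m].min()) / span  # epithelial nodes only
    expr[:2 * m, gradient_gene] = grad

    return Morphology(ids=np.arange(1, n + 1), pos=pos, kind=kind,
                      label=label, partner=partner, props=props, expr=expr,
                      phase=np.zeros(n), initial_labels=epi_labels)


def assign_division_labels(mother_label: int, fresh_label: int,
                           rng: np.random.Generator) -> tuple[int, int]:
    """Labels for the two daughters of a division.

    One daughter inherits the mother's lineage label, the other receives the
    fresh label; which daughter keeps the mother's label is a fair coin flip.
    Returns (label of first daughter, label of second daughter).
    """
    if rng.random() < 0.5:
        return mother_label, fresh_label
    return fresh_label, mother_label
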