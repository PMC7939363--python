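"""Coupled mechanics / gene-regulation / behavior dynamics.

The model is an overdamped cell-center model: node velocities are
proportional to the summed forces (no inertia), which is the standard choice
at tissue scale where viscous drag dominates.  Continuous variables --
positions under forces, expression under regulation and diffusion, and
gene-regulated mechanical properties -- are integrated together with a
4th-order Runge-Kutta scheme with step-doubling error control.  Discrete
cell behaviors (division, apoptosis removal, EMT, ECM secretion) and the
developmental noise (a small isotropic Gaussian displacement of every node)
are applied between accepted steps.

Force model (all pairwise forces are equal and opposite):

- sphere-sphere contact: piecewise-linear in the center distance d --
  repulsion ``k_rep * (d_EQD - d)`` below the equilibrium distance, and an
  adhesive pull ``k_adh * (d - d_EQD) * (d_ADD - d) / (d_ADD - d_EQD)`` that
  is continuous at d_EQD and ramps to zero at the adhesion distance d_ADD.
- sphere vs an epithelial apical/basal face acts parallel to the cell's
  apical-basal axis; lateral epithelial contact acts perpendicular to it.
- the two nodes of an epithelial cell are joined by an unbreakable spring
  with rest length d_EQS.
- bending: a restoring force (scaled by p_ERP) drives same-side neighbor
  connection vectors toward right angles with the apical-basal axis, and a
  rotational term (scaled by p_EST) aligns neighboring cell axes.  Both are
  exact gradients of the corresponding energies, so damped relaxation
  decreases the bending energy monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import (diffusion_kernel, epithelial_force_kernel,
                       pair_force_kernel)
from .config import SimConfig
from .core import (APICAL, BASAL, ECM, MESENCHYMAL, DevMechanism,
                   Morphology, assign_division_labels)
from .neighbors import cell_contact_graph, contact_pairs

I_ADD, I_EQD, I_EQS, I_ERP, I_EST, I_PHA = range(6)


@dataclass
class Trajectory:
    """Time-ordered snapshots of one development run."""

    snapshots: list[tuple[float, Morphology]]
    termination_reason: str  # max_steps | max_nodes | aberrant | steady
    aberrant: bool = False
    aberrant_reason: str = ""
    n_steps: int = 0

    @property
    def final(self) -> Morphology:
        return self.snapshots[-1][1]


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def node_axes(m: Morphology) -> np.ndarray:
    """(n, 3) unit apical->basal axis for epithelial nodes, zero elsewhere."""
    axes = np.zeros((m.n_nodes, 3))
    ap = np.flatnonzero(m.kind == APICAL)
    if len(ap):
        v = m.pos[m.partner[ap]] - m.pos[ap]
        n = np.linalg.norm(v, axis=1)
        n[n == 0] = 1.0
        v = v / n[:, None]
        axes[ap] = v
        axes[m.partner[ap]] = v
    return axes


class _StepContext:
    """Topology-dependent index structures, fixed across RK stages.

    Node kinds, partners and the neighbor list do not change within one
    integration step, so the pair classification is computed once.
    """

    def __init__(self, m: Morphology, pairs=None):
        if pairs is None:
            i, j, _, _ = contact_pairs(m.pos, m.props[:, I_ADD], m.partner)
        else:
            i, j = pairs
        self.i, self.j = i, j
        ki, kj = m.kind[i], m.kind[j]
        epi_i, epi_j = ki <= BASAL, kj <= BASAL
        self.epi_i = epi_i
        self.mixed = epi_i ^ epi_j
        self.lateral_mask = epi_i & epi_j & (ki == kj)
        self.lat_i = i[self.lateral_mask]
        self.lat_j = j[self.lateral_mask]
        self.ap = np.flatnonzero(m.kind == APICAL)
        self.ba = m.partner[self.ap]
        n = m.n_nodes
        self.apical_of = np.zeros(n, dtype=np.int64)
        self.basal_of = np.zeros(n, dtype=np.int64)
        self.apical_of[self.ap] = self.ap
        self.apical_of[self.ba] = self.ap
        self.basal_of[self.ap] = self.ba
        self.basal_of[self.ba] = self.ba

    def axes(self, pos: np.ndarray) -> np.ndarray:
        """(n, 3) unit apical->basal axes (zero for non-epithelial nodes)."""
        out = np.zeros_like(pos)
        if len(self.ap):
            v = pos[self.ba] - pos[self.ap]
            nrm = np.linalg.norm(v, axis=1)
            nrm[nrm == 0] = 1.0
            v = v / nrm[:, None]
            out[self.ap] = v
            out[self.ba] = v
        return out


def pair_forces(m: Morphology, cfg: SimConfig, pairs=None, pos=None,
                props=None, ctx: "_StepContext | None" = None,
                axes=None) -> np.ndarray:
    """Sphere-sphere adhesion/repulsion forces for all contacting pairs.

    ``pairs`` (i, j index arrays) or a precomputed step context may be
    supplied to reuse a neighbor list; distances are always recomputed from
    the current positions.
    """
    pos = m.pos if pos is None else pos
    props = m.props if props is None else props
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite positions")
    F = np.zeros_like(pos)
    if ctx is None:
        ctx = _StepContext(m, pairs)
    if len(ctx.i) == 0:
        return F
    if axes is None:
        axes = ctx.axes(pos)
    pair_force_kernel(pos, m.kind, np.ascontiguousarray(props[:, I_EQD]),
                      np.ascontiguousarray(props[:, I_ADD]), axes,
                      ctx.i, ctx.j, cfg.k_repulsion, cfg.k_adhesion, F)
    return F


def epithelial_forces(m: Morphology, cfg: SimConfig, lateral=None, pos=None,
                      props=None, ctx: "_StepContext | None" = None,
                      axes=None) -> np.ndarray:
    """Apical-basal spring plus bending (p_ERP) and torsion (p_EST) forces."""
    pos = m.pos if pos is None else pos
    props = m.props if props is None else props
    F = np.zeros_like(pos)
    if ctx is None:
        ctx = _StepContext(m)
        if lateral is not None:
            ctx.lat_i, ctx.lat_j = lateral
    ap, ba = ctx.ap, ctx.ba
    if len(ap) == 0:
        return F
    if axes is None:
        axes = ctx.axes(pos)
    wlen = np.zeros(m.n_nodes)
    d = np.linalg.norm(pos[ba] - pos[ap], axis=1)
    wlen[ap] = d
    wlen[ba] = d
    epithelial_force_kernel(pos, props, axes, ap, ba, ctx.apical_of,
                            ctx.basal_of, wlen, ctx.lat_i, ctx.lat_j,
                            cfg.k_spring, cfg.k_bending, cfg.k_torsion, F)
    return F


def bending_energy(m: Morphology, cfg: SimConfig) -> float:
    """Orthogonality energy the p_ERP force descends (for diagnostics)."""
    i, j, _, _ = contact_pairs(m.pos, m.prop("p_ADD"), m.partner)
    same = (m.kind[i] == m.kind[j]) & (m.kind[i] <= BASAL)
    i, j = i[same], j[same]
    if len(i) == 0:
        return 0.0
    axes = node_axes(m)
    u = m.pos[j] - m.pos[i]
    uhat = u / np.linalg.norm(u, axis=1)[:, None]
    si = np.einsum("ij,ij->i", axes[i], uhat)
    sj = np.einsum("ij,ij->i", axes[j], uhat)
    p = m.prop("p_ERP")
    return float(0.5 * cfg.k_bending * np.sum(p[i] * si ** 2 + p[j] * sj ** 2))


# ---------------------------------------------------------------------------
# gene dynamics
# ---------------------------------------------------------------------------

def activation(x: np.ndarray, form: str = "saturating") -> np.ndarray:
    """Non-negative transcription response to the summed regulatory input."""
    xp = np.maximum(x, 0.0)
    if form == "saturating":
        return xp / (1.0 + xp)
    if form == "rectifier":
        return xp
    raise ValueError(form)


def regulation_rhs(expr: np.ndarray, mech: DevMechanism,
                   cfg: SimConfig) -> np.ndarray:
    """d(expression)/dt from transcription regulation and degradation.

    Per node i and gene k: ``dg_ik/dt = phi(sum_l T[l,k] g_il) - mu_k g_ik``.
    """
    net = expr @ mech.T
    mu = np.array([s.degradation_rate for s in mech.gene_specs])
    d = activation(net, cfg.activation) - mu[None, :] * expr
    if cfg.clamp_gradient_gene:
        d[:, cfg.gradient_gene] = 0.0
    return d


def regulation_step(m: Morphology, mech: DevMechanism, dt: float,
                    cfg: SimConfig | None = None) -> np.ndarray:
    """One explicit-Euler update of the regulation dynamics (returns expr)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    cfg = cfg or SimConfig()
    return np.maximum(m.expr + dt * regulation_rhs(m.expr, mech, cfg), 0.0)


def diffusion_rhs(m: Morphology, expr: np.ndarray, mech: DevMechanism,
                  cfg: SimConfig, pairs=None, pos=None) -> np.ndarray:
    """d(expression)/dt from extracellular diffusion over the contact graph.

    Diffusible gene products exchange between contacting nodes by a discrete
    Laplacian weighted by the inverse squared pair distance and scaled by the
    per-gene diffusion rate; the total amount is conserved.
    """
    d = np.zeros_like(expr)
    diff = np.array([g for g, s in enumerate(mech.gene_specs)
                     if s.diffusible and s.diffusion_rate > 0
                     and not (cfg.clamp_gradient_gene
                              and g == cfg.gradient_gene)], dtype=np.int64)
    if len(diff) == 0:
        return d
    pos = m.pos if pos is None else pos
    if pairs is None:
        i, j, _, _ = contact_pairs(pos, m.prop("p_ADD"), m.partner)
    else:
        i, j = pairs
    if len(i) == 0:
        return d
    D = np.array([mech.gene_specs[g].diffusion_rate for g in diff])
    diffusion_kernel(pos, expr, i, j, diff, D, d)
    return d


def diffusion_step(m: Morphology, mech: DevMechanism, dt: float,
                   cfg: SimConfig | None = None) -> np.ndarray:
    """One explicit-Euler update of the diffusion dynamics (returns expr)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    cfg = cfg or SimConfig()
    return np.maximum(m.expr + dt * diffusion_rhs(m, m.expr, mech, cfg), 0.0)


# ---------------------------------------------------------------------------
# gene-regulated mechanical properties
# ---------------------------------------------------------------------------

_PROPERTY_TARGETS = {
    "contraction_apical": (I_EQD, APICAL),
    "contraction_basal": (I_EQD, BASAL),
    "contraction_mesenchymal": (I_EQD, MESENCHYMAL),
    "adhesion": (I_ADD, None),
    "eqs": (I_EQS, None),
    "erp": (I_ERP, None),
    "est": (I_EST, None),
}


def property_rhs(m: Morphology, expr: np.ndarray, props: np.ndarray,
                 mech: DevMechanism) -> np.ndarray:
    """d(props)/dt from gene couplings to mechanical properties."""
    d = np.zeros_like(props)
    for c in mech.couplings:
        if c.target not in _PROPERTY_TARGETS:
            continue
        col, kind = _PROPERTY_TARGETS[c.target]
        if kind is None:
            mask = m.kind != ECM
        else:
            mask = m.kind == kind
        d[mask, col] += c.strength * expr[mask, c.gene]
    return d


def _clamp_props(props: np.ndarray, cfg: SimConfig) -> None:
    # regulated contraction saturates at the minimal radius; only apoptosis
    # (applied after this clamp, before the removal check) goes below it
    np.clip(props[:, I_EQD], cfg.min_radius, cfg.p_eqd_max,
            out=props[:, I_EQD])
    np.clip(props[:, I_ADD], 0.05, cfg.p_add_max, out=props[:, I_ADD])
    np.maximum(props[:, I_ADD], props[:, I_EQD], out=props[:, I_ADD])
    np.clip(props[:, I_EQS], 0.05, 1.5, out=props[:, I_EQS])
    np.maximum(props[:, I_ERP], 0.0, out=props[:, I_ERP])
    np.maximum(props[:, I_EST], 0.0, out=props[:, I_EST])


# ---------------------------------------------------------------------------
# discrete behaviors
# ---------------------------------------------------------------------------

def _cell_rate(m: Morphology, mech: DevMechanism, target: str) -> np.ndarray:
    """Per-node behavior rate = sum of coupling strength x local expression."""
    rate = np.zeros(m.n_nodes)
    for c in mech.couplings:
        if c.target == target:
            rate += c.strength * m.expr[:, c.gene]
    return np.maximum(rate, 0.0)


def apply_behaviors(m: Morphology, mech: DevMechanism, dt: float,
                    rng: np.random.Generator, cfg: SimConfig) -> bool:
    """Apply discrete behaviors for one accepted step; mutates ``m``.

    Order (deterministic): apoptosis shrinkage -> division -> EMT -> ECM
    secretion -> apoptotic removal.  Returns True if the node cap was
    exceeded (caller should terminate).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    eqd = m.props[:, I_EQD]

    # apoptosis: regulated shrinkage of the equilibrium radius
    apop = _cell_rate(m, mech, "apoptosis")
    eqd -= dt * apop

    # cell division: phase advances at the regulated rate (stored in p_PHA)
    div_rate = _cell_rate(m, mech, "division") + mech.default_division_rate
    m.props[:, I_PHA] = div_rate
    owner = (m.kind == APICAL) | (m.kind == MESENCHYMAL)
    m.phase[owner] += dt * div_rate[owner]

    dividing = np.flatnonzero(owner & (m.phase >= 1.0))
    for idx in dividing[np.argsort(m.label[dividing], kind="stable")]:
        m.phase[idx] = 0.0
        mother_label = int(m.label[idx])
        fresh = m.fresh_label()
        first, second = assign_division_labels(mother_label, fresh, rng)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        if m.kind[idx] == APICAL:
            ba = int(m.partner[idx])
            axis = m.pos[ba] - m.pos[idx]
            axis /= max(np.linalg.norm(axis), 1e-12)
            ref = np.array([1.0, 0.0, 0.0])
            if abs(axis @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(axis, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            off = cfg.division_offset * (np.cos(theta) * e1 + np.sin(theta) * e2)
            n0 = m.n_nodes
            m.append_nodes(pos=np.vstack([m.pos[idx] + off, m.pos[ba] + off]),
                           kind=[APICAL, BASAL], label=[second, second],
                           partner=[n0 + 1, n0], props=m.props[[idx, ba]],
                           expr=m.expr[[idx, ba]], phase=[0.0, 0.0])
            m.label[idx] = first
            m.label[ba] = first
        else:
            off = cfg.division_offset * np.array(
                [np.cos(theta), np.sin(theta), 0.0])
            m.append_nodes(pos=m.pos[None, idx] + off, kind=[MESENCHYMAL],
                           label=[second], partner=[-1],
                           props=m.props[None, idx], expr=m.expr[None, idx],
                           phase=[0.0])
            m.label[idx] = first

    # epithelial-to-mesenchymal transition: the basal node becomes a sphere
    emt_rate = _cell_rate(m, mech, "emt")
    ap_nodes = np.flatnonzero(m.kind == APICAL)
    drop_apical = []
    for idx in ap_nodes[np.argsort(m.label[ap_nodes], kind="stable")]:
        if rng.random() < -np.expm1(-emt_rate[idx] * dt):
            ba = int(m.partner[idx])
            m.kind[ba] = MESENCHYMAL
            m.partner[ba] = -1
            drop_apical.append(idx)
    if drop_apical:
        mask = np.zeros(m.n_nodes, dtype=bool)
        mask[drop_apical] = True
        m.delete_nodes(mask)

    # ECM secretion: spawn an extracellular node next to the secreting cell
    ecm_rate = _cell_rate(m, mech, "ecm_secretion")
    sources = np.flatnonzero((m.kind == BASAL) | (m.kind == MESENCHYMAL))
    for idx in sources[np.argsort(m.label[sources], kind="stable")]:
        if rng.random() < -np.expm1(-ecm_rate[idx] * dt):
            direction = rng.standard_normal(3)
            direction /= max(np.linalg.norm(direction), 1e-12)
            p = m.props[idx].copy()
            p[I_PHA] = 0.0
            m.append_nodes(
                pos=m.pos[None, idx] + 2.0 * m.props[idx, I_EQD] * direction,
                kind=[ECM], label=[0], partner=[-1], props=p[None, :],
                expr=np.zeros((1, m.n_genes)), phase=[0.0])

    # apoptotic removal below the minimal radius
    small = m.props[:, I_EQD] < cfg.min_radius
    if small.any():
        doomed_labels = set(int(x) for x in np.unique(m.label[small & (m.kind != ECM)]))
        mask = np.array([(int(m.kind[i]) != ECM and int(m.label[i]) in doomed_labels)
                         or (int(m.kind[i]) == ECM and small[i])
                         for i in range(m.n_nodes)])
        m.delete_nodes(mask)

    _clamp_props(m.props, cfg)
    return m.n_nodes >= cfg.max_nodes


# ---------------------------------------------------------------------------
# aberrance detection
# ---------------------------------------------------------------------------

def detect_aberrant(m: Morphology, cfg: SimConfig | None = None
                    ) -> tuple[bool, str]:
    """Flag broken, ruptured, or self-intersecting epithelia."""
    cfg = cfg or SimConfig()
    if not np.all(np.isfinite(m.pos)):
        return True, "nonfinite_positions"
    ap = np.flatnonzero(m.kind == APICAL)
    if len(ap) == 0:
        return True, "no_epithelium"
    ba = m.partner[ap]
    d = np.linalg.norm(m.pos[ba] - m.pos[ap], axis=1)
    rest = m.props[ap, I_EQS] + m.props[ba, I_EQS]
    if np.any(d > cfg.rupture_multiple * rest):
        return True, "ruptured_spring"
    labels, ci, cj = cell_contact_graph(m)
    if len(labels) > 1:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components
        n = len(labels)
        adj = coo_matrix((np.ones(len(ci)), (ci, cj)), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        if ncomp > 1:
            return True, "broken_epithelium"
        axes = node_axes(m)
        lab_axis = {}
        for idx in ap:
            lab_axis[int(m.label[idx])] = axes[idx]
        A = np.array([lab_axis[int(l)] for l in labels])
        dots = np.einsum("ij,ij->i", A[ci], A[cj])
        # self-intersection proxy: a *largely* inverted epithelium -- tight
        # folds legitimately bring a few anti-aligned flanks into contact
        if len(dots) and np.mean(dots < cfg.antialign_threshold) \
                > cfg.antialign_max_fraction:
            return True, "folded_epithelium"
    return False, ""


# ---------------------------------------------------------------------------
# development loop
# ---------------------------------------------------------------------------

def _rhs(m, mech, cfg, pos, expr, props, ctx, frozen):
    dexpr = regulation_rhs(expr, mech, cfg) \
        + diffusion_rhs(m, expr, mech, cfg, pairs=(ctx.i, ctx.j), pos=pos)
    if frozen:
        return np.zeros_like(pos), dexpr, np.zeros_like(props)
    axes = ctx.axes(pos)
    F = pair_forces(m, cfg, pos=pos, props=props, ctx=ctx, axes=axes) \
        + epithelial_forces(m, cfg, pos=pos, props=props, ctx=ctx, axes=axes)
    speed = np.linalg.norm(F, axis=1)
    fast = speed > cfg.max_speed
    if fast.any():
        F[fast] *= (cfg.max_speed / speed[fast])[:, None]
    dprops = property_rhs(m, expr, props, mech)
    return F, dexpr, dprops


def _rk4(m, mech, cfg, pos, expr, props, dt, ctx, frozen):
    k1 = _rhs(m, mech, cfg, pos, expr, props, ctx, frozen)
    k2 = _rhs(m, mech, cfg, pos + 0.5 * dt * k1[0], expr + 0.5 * dt * k1[1],
              props + 0.5 * dt * k1[2], ctx, frozen)
    k3 = _rhs(m, mech, cfg, pos + 0.5 * dt * k2[0], expr + 0.5 * dt * k2[1],
              props + 0.5 * dt * k2[2], ctx, frozen)
    k4 = _rhs(m, mech, cfg, pos + dt * k3[0], expr + dt * k3[1],
              props + dt * k3[2], ctx, frozen)
    out = []
    for comp, a, b, c, d in zip((pos, expr, props), k1, k2, k3, k4):
        out.append(comp + (dt / 6.0) * (a + 2 * b + 2 * c + d))
    return out


def run_development(mech: DevMechanism, initial: Morphology,
                    cfg: SimConfig, freeze_motion: bool = False) -> Trajectory:
    """Integrate a developmental mechanism from an initial morphology.

    Alternates adaptive RK4 integration of the continuous dynamics with
    discrete behavior events and seeded positional noise, and halts on the
    first stop condition: step cap, node cap, aberrance, or a steady state
    (dynamic displacement and expression change below tolerance for a fixed
    window of steps).  With ``freeze_motion`` only cell signaling runs: no
    forces, noise, or behaviors (the signaling-only protocol).

    Identical (mechanism, initial, config) give bit-identical trajectories.
    """
    cfg.validate()
    if initial.n_genes != mech.n_genes:
        raise ValueError("gene count mismatch between morphology and mechanism")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    m = initial.copy()
    snapshots = [(m.time, m.copy())]
    dt = cfg.dt_init
    steady_run = 0
    reason = "max_steps"
    aberrant, ab_reason = False, ""
    has_behaviors = (len(mech.couplings) > 0
                     or mech.default_division_rate > 0) and not freeze_motion

    for step in range(1, cfg.max_steps + 1):
        ctx = _StepContext(m)

        # RK4 with step-doubling error control; the step size is re-assessed
        # periodically (adapt_every) and kept in between, with a non-finite
        # guard forcing re-assessment on any overflow
        adapt = step == 1 or step % cfg.adapt_every == 0
        if not adapt:
            cand = _rk4(m, mech, cfg, m.pos, m.expr, m.props, dt,
                        ctx, freeze_motion)
            adapt = not all(np.all(np.isfinite(c)) for c in cand)
            if not adapt:
                half = cand
        if adapt:
            while True:
                big = _rk4(m, mech, cfg, m.pos, m.expr, m.props, dt,
                           ctx, freeze_motion)
                half = _rk4(m, mech, cfg, m.pos, m.expr, m.props, dt / 2,
                            ctx, freeze_motion)
                half = _rk4(m, mech, cfg, half[0], half[1], half[2], dt / 2,
                            ctx, freeze_motion)
                # expression is held to a 4x tighter tolerance than the
                # mechanics (positions are noise-dominated anyway)
                weights = (1.0, 4.0, 1.0)
                err = max(w * float(np.max(np.abs(b - h))) if b.size else 0.0
                          for w, (b, h) in zip(weights, zip(big, half)))
                if np.isnan(err):
                    err = np.inf
                if err <= cfg.rk_tolerance or dt <= cfg.dt_min:
                    break
                dt = max(dt / 2, cfg.dt_min)
            if not np.isfinite(err):
                # irrecoverably stiff even at dt_min: aberrant blow-up
                aberrant, ab_reason = True, "nonfinite_positions"
                reason = "aberrant"
                break
            # proportional controller (order-4 error scaling)
            if err > 0:
                grow = 0.9 * (cfg.rk_tolerance / err) ** 0.2
                dt = float(np.clip(dt * min(2.0, grow), cfg.dt_min,
                                   cfg.dt_max))
            else:
                dt = cfg.dt_max
        new_pos, new_expr, new_props = half

        dyn_disp = float(np.max(np.linalg.norm(new_pos - m.pos, axis=1))) \
            if m.n_nodes else 0.0
        dyn_expr = float(np.max(np.abs(new_expr - m.expr))) if m.expr.size else 0.0

        m.pos = new_pos
        m.expr = np.maximum(new_expr, 0.0)
        m.props = new_props
        _clamp_props(m.props, cfg)
        m.time += dt

        n_before = m.n_nodes
        capped = False
        if has_behaviors:
            capped = apply_behaviors(m, mech, dt, rng, cfg)
        if not freeze_motion and cfg.noise_amplitude > 0:
            m.pos += cfg.noise_amplitude * rng.standard_normal(m.pos.shape)

        if cfg.record_every and step % cfg.record_every == 0:
            snapshots.append((m.time, m.copy()))

        if capped:
            reason = "max_nodes"
            break
        if (step % cfg.aberrance_check_every == 0) and not freeze_motion:
            aberrant, ab_reason = detect_aberrant(m, cfg)
            if aberrant:
                reason = "aberrant"
                break
        # steady state: maximum dynamic (noise-free) node velocity and
        # expression rate below tolerance for a whole window of steps
        if m.n_nodes == n_before and dyn_disp < cfg.steady_pos_tol * dt \
                and dyn_expr < cfg.steady_expr_tol * dt:
            steady_run += 1
            if steady_run >= cfg.steady_window:
                reason = "steady"
                break
        else:
            steady_run = 0
    else:
        step = cfg.max_steps

    if not aberrant and not freeze_motion:
        aberrant, ab_reason = detect_aberrant(m, cfg)
        if aberrant and reason not in ("max_nodes",):
            reason = "aberrant"

    if not snapshots or snapshots[-1][0] != m.time:
        snapshots.append((m.time, m.copy()))
    return Trajectory(snapshots=snapshots, termination_reason=reason,
                      aberrant=aberrant, aberrant_reason=ab_reason,
                      n_steps=step)
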