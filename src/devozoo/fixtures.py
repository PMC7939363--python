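"""Deterministic test fixtures: reference shapes and hand-wired mechanisms.

Shapes (sphere, plane, crumpled plane, dome) exercise the morphometric
measures on geometries with known answers.  The hand-wired mechanisms
reproduce the classic qualitative regimes of gradient-driven morphogenesis:

- ``fig10a``: a near-uniformly expressed gene drives apical contraction
  everywhere; the sheet buckles in a noise-dependent pattern (complex but
  developmentally unstable).
- ``fig10b``: the maternal gradient itself drives apical contraction; a
  single evagination forms at the high-gradient side (stable).
- ``fig10c``: a spatially non-monotonic expression band drives contraction
  (relatively complex yet stable, because the deformation is partitioned
  into territories).
- ``fig11_cascade``: signaling-only threshold cascade -- a diffusible signal
  sourced from the gradient is read out by competing target genes with
  different sensitivities, producing several distinct stable expression
  territories along the gradient.
- ``knife_edge``: a minimal contraction mechanism whose few parameters are
  all critical, so iso-morphological walk steps are almost never accepted.

Same (name, params, seed) always returns an identical fixture.
"""

from __future__ import annotations

import numpy as np

from .core import (APICAL, BASAL, Coupling, DEFAULT_P_ADD, DEFAULT_P_EQD,
                   DEFAULT_P_EQS, DEFAULT_P_ERP, DEFAULT_P_EST, DevMechanism,
                   GeneSpec, Morphology, build_initial_morphology)

FIXTURE_NAMES = ("sphere", "plane", "crumpled_plane", "dome", "fig10a",
                 "fig10b", "fig10c", "fig11_cascade", "knife_edge")


def _epithelial_shell(basal_pts: np.ndarray, normals: np.ndarray,
                      height: float = 1.0) -> Morphology:
    """Epithelial morphology from basal points and outward unit normals.

    The apical node of each cell sits ``height`` outward along the normal,
    so the apical->basal axis points inward (-normal).
    """
    m = len(basal_pts)
    pos = np.vstack([basal_pts + height * normals, basal_pts])
    kind = np.concatenate([np.full(m, APICAL), np.full(m, BASAL)]).astype(np.int8)
    labels = np.arange(1, m + 1)
    label = np.concatenate([labels, labels])
    partner = np.concatenate([np.arange(m, 2 * m), np.arange(0, m)])
    props = np.tile([DEFAULT_P_ADD, DEFAULT_P_EQD, DEFAULT_P_EQS,
                     DEFAULT_P_ERP, DEFAULT_P_EST, 0.0], (2 * m, 1))
    return Morphology(ids=np.arange(1, 2 * m + 1), pos=pos, kind=kind,
                      label=label, partner=partner, props=props,
                      expr=np.zeros((2 * m, 10)), phase=np.zeros(2 * m),
                      initial_labels=labels)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (deterministic Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


def sphere(n: int = 500, radius: float = 26.0) -> Morphology:
    """Epithelial sphere with radial apical-basal axes (apical outside)."""
    normals = _fibonacci_sphere(n)
    return _epithelial_shell(radius * normals, normals)


def dome(n: int = 200, radius: float | None = None) -> Morphology:
    """Hemispherical dome (upper half-sphere) in canonical orientation.

    The default radius packs cells at roughly unit spacing so that the
    lateral contact graph is connected.
    """
    if radius is None:
        radius = np.sqrt(n) / 2.4
    pts = _fibonacci_sphere(4 * n)  # keep the upper quarter band dense
    upper = pts[pts[:, 2] > 0.0][:n]
    return _epithelial_shell(radius * upper, upper)


def crumpled_plane(sheet_rings: int = 4, amplitude: float = 0.3,
                   seed: int = 0) -> Morphology:
    """Flat sheet with seeded per-cell 3D jitter (axes preserved)."""
    m = build_initial_morphology(sheet_rings)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = np.unique(m.label[m.epithelial_mask])
    for lab in labels:
        off = amplitude * rng.standard_normal(3)
        m.pos[m.label == lab] += off
    return m


# ---------------------------------------------------------------------------
# hand-wired mechanisms (10 genes; gene 1 = clamped maternal gradient)
# ---------------------------------------------------------------------------

def _specs(n_genes=10, diffusible=(), D=2.0, mu=1.0, mu_overrides=None):
    mu_overrides = mu_overrides or {}
    out = []
    for g in range(n_genes):
        dg = g in diffusible
        out.append(GeneSpec(dg, D if dg else 0.0,
                            float(mu_overrides.get(g, mu))))
    return out


def fig10a(contraction: float = -0.15) -> DevMechanism:
    """Near-uniform apical contraction: complex but unstable morphology.

    Gene 2 saturates almost everywhere the maternal gradient is non-zero
    (strong activation through the bounded response), approximating a
    homogeneously expressed contraction regulator.
    """
    T = np.zeros((10, 10))
    T[0, 1] = 12.0
    mech = DevMechanism(10, T, _specs(mu_overrides={1: 1.0}),
                        [Coupling(1, "contraction_apical", contraction)])
    return mech


def fig10b(contraction: float = -0.08) -> DevMechanism:
    """Gradient-driven apical contraction: one evagination, stable."""
    return DevMechanism(10, np.zeros((10, 10)), _specs(),
                        [Coupling(0, "contraction_apical", contraction)])


def _cascade_network() -> np.ndarray:
    """Regulatory matrix of the territory-forming threshold cascade.

    Gene 2 is the diffusible signal A sourced by the clamped gradient (short
    decay length, so its concentration spans a wide range across the sheet);
    gene 3 is a near-step "signal present" marker U that supplies expression
    thresholds; genes 4-6 are territory genes read out at increasing
    sensitivity to A, with cross-repression from the genes expressed at
    higher signal -- each ends up occupying one band of signal level.
    """
    T = np.zeros((10, 10))
    A, U, B, C, D = 1, 2, 3, 4, 5
    T[0, A] = 4.0
    T[A, U] = 30.0
    T[A, B] = 7.5
    T[U, B] = -0.4
    T[A, C] = 43.2
    T[U, C] = -1.5
    T[B, C] = -12.4
    T[A, D] = 68.7
    T[U, D] = -0.4
    T[B, D] = -4.4
    T[C, D] = -31.8
    return T


_CASCADE_SPECS = dict(diffusible=(1,), D=0.3, mu_overrides={1: 3.0})


def fig10c(contraction: float = -0.08) -> DevMechanism:
    """Non-monotonic contraction: a mid-sheet expression band contracts.

    Uses the threshold cascade; gene 4 occupies a band at intermediate
    signal levels and drives apical contraction there, so the deformation is
    partitioned into a territory instead of following the gradient.
    """
    return DevMechanism(10, _cascade_network(), _specs(**_CASCADE_SPECS),
                        [Coupling(3, "contraction_apical", contraction)])


def fig11_cascade() -> DevMechanism:
    """Threshold cascade forming several stable expression territories.

    Signaling-only: run with motion frozen, the cascade partitions the sheet
    into at least three contiguous dominance territories (genes 4, 5, 6)
    along the maternal gradient, and the pattern is temporally stable.
    """
    return DevMechanism(10, _cascade_network(), _specs(**_CASCADE_SPECS), [])


def knife_edge(contraction: float = -0.15,
               division: float = 0.1) -> DevMechanism:
    """Minimal mechanism whose every parameter is morphologically critical.

    The genotype is exactly two couplings of the maternal gradient: apical
    contraction and division.  A +-2x-parental walk step turns contraction
    into growth (or triples it) and silences or triples division, so
    essentially no iso-morphological step is acceptable.  All degradation
    rates are zero (the regulated genes are unused), keeping the parameter
    list free of inert entries.
    """
    return DevMechanism(10, np.zeros((10, 10)), _specs(mu=0.0),
                        [Coupling(0, "contraction_apical", contraction),
                         Coupling(0, "division", division)])


def make_fixture(name: str, params: dict | None = None, seed: int = 0):
    """Build a named fixture; returns a Morphology or a DevMechanism."""
    params = dict(params or {})
    if name == "sphere":
        return sphere(**params)
    if name == "plane":
        return build_initial_morphology(**{"sheet_rings": 3, **params})
    if name == "crumpled_plane":
        return crumpled_plane(seed=seed, **params)
    if name == "dome":
        return dome(**params)
    if name == "fig10a":
        return fig10a(**params)
    if name == "fig10b":
        return fig10b(**params)
    if name == "fig10c":
        return fig10c(**params)
    if name == "fig11_cascade":
        return fig11_cascade(**params)
    if name == "knife_edge":
        return knife_edge(**params)
    raise ValueError(f"unknown fixture {name!r}")
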