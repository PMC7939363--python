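# Methods

`devozoo` simulates the development of simple 3D "embryos" driven by random
gene regulatory networks coupled to cell behaviors, scores the resulting
morphologies for complexity, and characterizes the genotype–phenotype map
(GPM) of each developmental mechanism by mutational screening.  This note
records the model, its assumptions, the parameters that matter, and the
design choices made where the design was genuinely open.

## The cell-center model

Cells are represented by nodes in 3D. An epithelial cell is a two-node
cylinder (an apical and a basal node joined by an unbreakable spring);
mesenchymal cells and extracellular matrix (ECM) material are single
spherical nodes. Dynamics are overdamped — node velocity equals the summed
force (unit mobility) — the standard regime at tissue scale where viscous
drag dominates inertia.

**Units.** Length: the resting epithelial cell spacing is 1 (each node's
equilibrium radius `p_EQD` defaults to 0.5). Time: fixed by unit mobility;
the stiffness constants put mechanical relaxation times at O(1).
Concentrations: the transcription response saturates at 1, so steady
expression levels are O(1/degradation rate).

**Contact forces.** Two nodes interact when their center distance `d` is
below the adhesion distance `d_ADD` (sum of the two adhesion radii
`p_ADD`). The force law is piecewise linear in `d`: repulsion
`k_rep (d_EQD − d)` below the equilibrium distance `d_EQD` (sum of the
`p_EQD`), and an adhesive pull `k_adh (d − d_EQD)(d_ADD − d)/(d_ADD −
d_EQD)` that is continuous at `d_EQD` and ramps to zero at `d_ADD`. The
force is the exact negative gradient of the corresponding pair potential
and all pair contributions are equal and opposite. Contact directions are
anisotropic for cylinders: sphere-versus-face contacts act along the
epithelial cell's apical–basal axis, lateral contacts perpendicular to it,
with a center-to-center fallback when the perpendicular projection becomes
degenerate (below 0.3 of the unit vector) — without the fallback the force
field is discontinuous when cells tumble, and the integrator stalls.

**Epithelial terms.** The apical–basal spring has rest length `d_EQS` (sum
of the two `p_EQS`). Bending resistance is implemented as the exact
gradient of an orthogonality energy `½ k_bend p_ERP (a·û)²` (`a` the cell
axis, `û` the unit vector to a contacting same-side neighbor node), and the
rotational resistance as the gradient of an axis-alignment energy
`k_tor p̄_EST (1 − a_i·a_j)`. Gradient forms guarantee that damped
relaxation decreases the bending energy monotonically; near the flat state
they reduce to a surface-normal restoring force and a force along the
same-side connection vector respectively.

**Speed cap.** Node speeds are capped (default 2 length/time). In dense
folds the pair-force sum can otherwise grow without bound as nodes
interpenetrate, making the ODE system ill-posed for any explicit
integrator.

## Gene dynamics

Per node `i` and gene `k`:
`dg_ik/dt = φ(Σ_l T[l,k] g_il) − μ_k g_ik`, with `φ(x) = max(0,x)/(1 +
max(0,x))` (a rectified, saturating transcription response; a pure
rectifier is available by config). Diffusible gene products additionally
exchange between contacting nodes by a discrete Laplacian weighted by the
inverse squared pair distance and scaled by the per-gene diffusion rate;
the scheme conserves total amount exactly.

**The maternal gradient is clamped.** Gene 1 starts as a linear gradient
across the sheet and is treated as a fixed maternal input: it is neither
regulated, degraded, nor diffused. Without clamping every input gradient
decays and no temporally stable non-trivial pattern can persist, which
would empty the signaling ensemble. This is the one boundary condition of
the model.

## Behaviors

Gene products can be coupled to: division (cell-cycle phase progression,
stored in `p_PHA`), apoptosis (gradual shrinkage of `p_EQD` and removal
below a minimal radius), apical/basal/mesenchymal contraction or growth
(rate of change of `p_EQD`), ECM secretion, epithelial–mesenchymal
transition, adhesion strength (`p_ADD`), and the mechanical properties
`p_EQS`, `p_ERP`, `p_EST`. Property couplings are integrated continuously
with the rest of the dynamics; event-like behaviors (division, removal,
EMT, secretion) fire between accepted integration steps in a fixed,
deterministic order. Regulated contraction saturates at the minimal radius;
only apoptosis can push a cell below it — otherwise strong contraction
would silently delete the epithelium.

At division one daughter keeps the mother's lineage label and the other
receives a fresh one, chosen by a fair coin flip; lineage labels define
node homology for all homology-based measures.

## Integration and stop conditions

A 4th-order Runge–Kutta scheme integrates positions, expression, and
regulated properties together. Step size is controlled by step doubling
(full step versus two half steps) with a proportional controller;
expression is held to a 4× tighter tolerance than the mechanics, whose
error is dominated by the developmental noise anyway. Because the dynamics
change slowly relative to the step, the error estimate runs every 4th step
(with a non-finite guard forcing immediate re-assessment), which roughly
halves the cost of a run. Developmental noise is a per-step isotropic
Gaussian displacement of every node (default amplitude 0.01, i.e. 2% of a
cell radius).

Runs halt on: a step cap; a node cap; aberrance (ruptured apical–basal
springs at 5× rest length, a disconnected epithelial contact graph, or a
*largely* inverted epithelium — more than half of contacting cell pairs
with anti-aligned axes; a few anti-aligned flank contacts are a normal
feature of tight folds, not an error); or a steady state (noise-free node
velocity and expression rate below tolerance for a 12-step window).

## Complexity and distances

- **AV** (angle variation): for each epithelial cell, angles between its
  apical→basal vector and the vectors to the basal nodes of all other
  cells, binned by center–center distance into seven categories
  `[c·p̄, (c+1)·p̄)`, `c = 3..9`, where `p̄` is the mean epithelial adhesion
  distance (twice the mean `p_ADD`); AV is the summed per-category
  population variance divided by `7n`. Flat sheets and spheres score ≈ 0;
  irregular folds score high. Distances use cell centers (midpoint of the
  two nodes), the symmetric choice.
- **OPC** (orientation patch count): each cell is assigned an octant by the
  signs of its apical→basal vector (a zero component counts positive);
  patches are connected same-octant components on the cell contact graph;
  patches under four cells are noise and ignored. OPC is deliberately not
  rotation-invariant (octants are frame-fixed).
- **Local convexity**: per epithelial node, the mean dot product between
  the cell's apical→basal axis and unit vectors to contacting same-side
  neighbors; 0 on a flat sheet, +1 at the tip of a fold bulging toward the
  apical side (an evagination), −1 in an invagination. Using the cell axis
  for both nodes of a cell (rather than each node's vector toward its
  partner) makes the sign consistent on the two surfaces of one fold.
- **EMD**: symmetrized mean nearest-node distance between two morphologies;
  homology-free, defined for unequal node counts. Identity and symmetry
  hold by construction; the triangle inequality is not guaranteed.
- **CMD**: mean absolute convexity difference over lineage-homologous
  nodes, normalized by the actual shared homologous-node count so the
  measure is well defined at any sheet size.
- **HMD**: Procrustes-style root-sum-square distance over homologous node
  positions after centroid translation and optimal rotation (no scaling;
  superimposition can be disabled). Twin sets are averaged into a mean
  morphology (per-label mean positions) before HMD comparisons between
  mechanisms.

## Random mechanisms and the ensemble

Networks have 10 genes; every ordered gene pair (self-pairs included)
receives an interaction with probability 0.2 — so genes average two
efferent and two afferent connections — signed ± with equal chance and
magnitude uniform on (0, t_max = 1). Each gene is diffusible with
probability ½; gene 1 is constrained to directly activate one diffusible
gene product (the edge is added only if absent, which biases mean efferent
connectivity up by ≈ 0.09). Diffusion rates are uniform on (0.2, 2.0) and
degradation rates on (0.1, 1.0). Each gene then has a ½ chance of
regulating one uniformly chosen behavior or property; rate-like behaviors
draw log-uniform strengths (10⁻³–10⁻¹), mechanical properties uniform
signed strengths, and every cell carries a small default division rate.

The default protocol is the *signaling ensemble*: a sampled network first
runs signaling-only (motion, growth and division frozen) and is kept only
if it reaches a steady state whose expression pattern differs from the
initial one beyond a threshold — a temporally stable pattern
transformation. Only then are behaviors attached and the mechanical
simulation run; aberrant outcomes are discarded. The *broad* variant
(no screen) is available behind a config flag. Every member records the
seed of its attempt and can be regenerated bit-identically from it.

## Screens

Developmental instability is the mean pairwise morphological distance
between twins (replicates differing only in noise seed). Mutant acceptance
everywhere uses the same criterion: a mutant is "the same morphology" when
the mean CMD between its twins and the parent's twins is at most the
parent's CMD-instability plus a 0.01 margin; aberrant mutants count as
different. Pruning deletes randomly chosen interactions under this
criterion until a run of consecutive rejections (40 by default). IS
neighborhoods perturb each parameter by ±20..80% of its parental value
(eight mutants per parameter, several twins each). T neighborhoods delete
one interaction at a time and add `N_c` single random interactions drawn
with the ensemble's samplers (resampling on collision). Iso-morphological
walks (only for parents with twin EMD below 0.3) perturb one uniformly
chosen parameter per step by ±2× its *parental* value; steps compound, and
rates (degradation, diffusion, rate-like couplings) are floored at zero
since negative rates are unphysical. The accepted-step count proxies the
parameter-space volume (neutral network size) of the parent's morphology.

GPM regressions take the parent (0% level) plus the eight IS levels of one
parameter; genetic distance between two levels is the absolute difference
of their perturbation percentages; morphological distance is the mean
cross-twin distance (EMD/CMD; twin pairs within a level give the 0% points)
or the distance between mean morphologies (HMD, no 0% level). The slope is
ordinary least squares, unweighted. Cross-parameter level pairs are never
mixed, and parent-versus-mutant pairs at intermediate distances are
included (the parent is simply the 0% member).

## Desk-scale study conditions

The full pipeline runs at desk scale with: a rings-3 sheet (37 epithelial
cells over 37 mesenchymal cells, 111 nodes), 200–300 integration steps
(≈ 10–25 time units), a node cap of 800, behavior couplings up to ±0.1 so
regulated behaviors reshape the sheet within the simulated window, ≈ 150
ensemble members, 8 parents spread evenly over the observed complexity
range, 2–4 twins per condition, 3 screened parameters per parent, and one
15-step walk per parent. These sizes keep the whole study in the
minutes-to-tens-of-minutes range on one core. At this scale AV values live
in ≈ 0–0.01 rather than the 0–1.2 range of large, strongly folded embryos;
all analyses are rank-based or sign-based, so only the ordering of
complexities matters. Because desk-scale AV spans several decades with a
heavy mass near zero, the complexity frequency spectrum is binned
logarithmically (linear bins collapse the whole ensemble into one occupied
bin plus ties).

## What the synthetic data does and does not show

The generator emulates: a polarized epithelial sheet with an underlying
mesenchymal layer, a single maternal gradient as positional input, random
signed gene regulation with saturating response, contact-graph diffusion,
and noisy overdamped morphogenesis driven by regulated behaviors. It does
not emulate: multi-node cells (hence no planar-polarized contraction or
adhesion), a structured basal lamina (bending resistance is the only
stiffness proxy), mesenchymal morphologies worth scoring, realistic gene
numbers, or embryo sizes beyond a few hundred nodes. Passing tests
demonstrate the qualitative relationships between complexity, instability,
mutational asymmetry and GPM slope *within this model class*; they say
nothing quantitative about real tissues.

## Numerical choices and degenerate inputs

- Octant ties (a zero axis component) count as positive — deterministic.
- AV categories with fewer than two pairs contribute zero variance.
- Convexity is undefined (NaN) for isolated nodes; such nodes are excluded
  from CMD.
- Zero-length apical–basal axes raise an error rather than propagate NaNs.
- Division daughters are displaced by 0.2 length units in a random
  in-plane direction (perpendicular to the axis for epithelial cells).
- The division phase accumulates deterministically at the regulated rate;
  the stochastic elements of a run are the positional noise, the daughter
  displacement direction, the label coin flip, and the EMT/secretion event
  draws, all from one per-run seeded generator with substreams derived by
  counter, so execution order cannot change results.

## Known limitations

- The force anisotropy fallback makes the field piecewise-smooth, not
  smooth; the integrator's error control absorbs this but step sizes drop
  in dense folds.
- At desk scale most random mechanisms produce near-flat morphologies, so
  complexity distributions are heavily skewed; the rank statistics on
  8-parent sets have limited power, and single-seed results should be read
  as qualitative.
- CMD's fixed 0.01 acceptance margin is an absolute threshold calibrated
  for clearly folded morphologies; for near-flat parents it makes most
  mutants "the same", which inflates walk acceptance for simple parents
  (this is also what makes the neutral-network-size contrast visible).
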