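# Methods

This note documents the models, numerical choices and limitations behind
`crossbeta`. Units are Å, kcal/mol and degrees throughout; residue
numbers follow the Aβ(1–42) convention (the modelled chain spans 9–42
with the N-terminal acetyl cap stored as residue 8).

## The template chain

The template emulates the sheet–turn–sheet fold of a fibrillar Aβ chain
with a reduced atom set: full backbone (N, H, CA, C, O) plus CB, the
D23 carboxylate tip (CG/OD1/OD2), the K28 ammonium tip (NZ), the
C-terminal carboxylate (OXT) and single side-chain pseudo-atoms (`SCT`)
for the hydrophobic residues that the analyses actually touch
(L17, F19, I31, L34, M35, V36, V39, V40, I41). Every observable in the
package is computable from this set; full rotamers are out of scope.

Construction proceeds in three steps:

1. **Dihedrals → rise.** The requested β-strand dihedrals (default
   φ = −139°, ψ = +135°) are turned into a per-residue helical rise by
   building a short poly-backbone segment in internal coordinates
   (standard Engh–Huber bond lengths/angles, ω = 180°) and measuring the
   CA advance along its principal axis (≈3.35 Å for the default).
   Dihedrals whose implied rise is below 2.6 Å (e.g. helical φ/ψ)
   cannot support the extended U layout and raise a construction error.
2. **CA trace.** The chain is laid out as a planar pleated trace: an
   outgoing leg (residues 9–24) along +x, a circular three-residue cap,
   and a returning leg (28–42) along −x, the legs separated in y by a
   width solved in closed form so that the D23 carboxylate oxygens and
   the K28 NZ meet at the requested salt-bridge gap (default 3.5 Å,
   honoured within the 0.5 Å contract; infeasible gaps raise). The
   pleat amplitude δ = √(3.8² − d²)/2 keeps the CA–CA virtual bond at
   its trans-peptide value while the axis rise is d.
3. **Peptide units.** Between consecutive CA positions, C and N are
   placed by an exact triangle solve at standard bond lengths, with the
   carbonyl normal alternating along ±z (the growth axis) on the legs.
   This guarantees that in-register stacking at ~4.8 Å produces the
   canonical parallel-sheet hydrogen-bond ladder under the
   Kabsch–Sander criterion — verifiable analytically (r_OH ≈ 2.88 Å,
   E ≈ −1.0 kcal/mol per bond). The turn-cap peptide planes lie in the
   sheet plane instead, so stacked turns do not register as β
   structure, matching the sheet/turn distinction of secondary-structure
   assignment.

One structural consequence worth knowing: in a perfectly in-register
stack, A42 has no j+1 partner and can never close a parallel bridge,
while G9 can (the acetyl cap donates its C=O). The C-sheet window
(32–42) therefore tops out at 10/11 ≈ 91% content, giving every
topology a baseline N−C margin of roughly +7 percentage points. Real MD
ensembles blur this edge effect through register disorder; analyses of
the N-vs-C contrast here should compare against a hinge-free baseline
(see the acceptance suite).

## Assemblies

Protofilaments replicate the template along a per-chain step. When the
step is estimated from a structure, the mean translation vector between
chains B and D of a five-chain reference spans **two** stacking steps,
so the applied step is t/2 — the only reading consistent with the
~4.8 Å cross-β spacing; steps outside 3.5–6.5 Å trigger a warning.

Protofilament pairs are built deterministically, not docked: the second
layer is the first rotated 180° about the growth axis, re-registered on
the C-sheet centroid, and offset along the interface normal (the
C-sheet plane normal from an SVD plane fit) by `interface_gap`
(default 11.0 Å between CA planes, which puts the opposing I31/M35/V39/
I41 pseudo-atoms at ~3.8–4.1 Å). The build fails loudly unless the
minimum opposing pseudo-atom distance lands in [3.4, 5.0] Å.
`register_offset` shifts the second layer by whole stacking steps; the
inter-layer register of the real interface is not known numerically, so
it is exposed as a parameter with default 0.

## Synthetic trajectories

The generator emulates the *statistical structure* of an MD ensemble,
not its dynamics. Per frame k (fraction f = k/(n_frames−1)):

- **Twist:** chain j rotates by j·f·`twist_per_monomer` about the
  growth axis through the mean V24 CA column. Anchoring the axis at the
  dihedral probe's pivot makes the measured twist equal the imposed
  cumulative rotation exactly on noise-free ensembles; an
  all-atom-centroid anchor would leave the probe atoms far off-axis and
  bias the dihedral by tens of degrees at large twists. The linear ramp
  emulates relaxation from an untwisted start toward a twisted
  equilibrium.
- **Hinge:** residues ≥ 39 (distal to the G37/G38 hinge) rotate about
  the axis direction through CA(G38), with per-chain random magnitude
  (uniform fraction of `hinge_bend`) and a per-chain random sign. The
  randomness is essential: an identical bend on every chain is a pure
  translation-symmetric deformation that preserves all inter-chain
  hydrogen bonds and would have no effect on sheet content. The hinge
  applies only to single layers — in a pair both C-terminal faces are
  buried by the partner layer, so pairs are bit-identical with the
  hinge on or off.
- **Noise:** iid Gaussian displacement per atom coordinate.
- **Rupture:** optionally, when the applied per-monomer twist exceeds
  `rupture_threshold`, the stack's top half is displaced 8 Å along the
  axis, emulating over-twist breakage (single layers only).

One seeded generator drives all draws; identical parameters give
bit-identical ensembles. Defaults: 5°/monomer twist, 30° hinge, 0.25 Å
noise, 51 frames at 5 ps.

**Known limitation.** Rigid per-chain rotation strains inter-chain
H-bonds in proportion to the distance from the twist axis; at several
degrees per monomer this shreds β content in both sheets, whereas
relaxed MD ensembles twist while preserving local bonding. Sheet-content
analyses that aim to isolate the hinge mechanism should therefore run in
a low-twist regime (≈1°/monomer); the twist observable itself is
unaffected. Gaussian noise is likewise not Boltzmann-relaxed, so
energies are evaluated on idealized geometries (below), never on noisy
frames, where the r⁻¹² wall would dominate.

## Observables

- **Total twist**: signed dihedral of CA(V18), CA(V24) of the second
  monomer and CA(V24), CA(V18) of the penultimate monomer (1-based along
  the stack), positive for right-handed rotation about the growth axis,
  0 for a fresh build, undefined below 4 chains. Frame series are
  unwrapped by nearest-branch continuation so cumulative twists past
  ±180° are tracked (a 48-mer at 7°/monomer reports ≈315°, not −45°).
- **Adjacent-monomer angle**: angle between the V18→V24 vectors of
  consecutive chains, in [0°, 180°]. Because that vector is
  perpendicular to the growth axis in the template, an imposed twist δ
  reads back exactly δ.
- **RMSD**: Kabsch superposition over backbone heavy atoms by default,
  reference = frame 0 (the starting structure).
- **Windows**: trailing-window means (default window 10 ns equivalent)
  use frames with t > t_end − window, uniformly weighted.
- **Salt bridges**: min over OD1/OD2 to NZ, present iff d ≤ 4.2 Å
  (closed cutoff). Intramolecular per chain; intermolecular between
  D23 of chain i and K28 of chain i+1 within a layer (toward the growth
  end — the stagger direction of in-register stacks; the literature does
  not state the direction).
- **β content**: a residue is parallel-β in a frame iff it closes the
  Kabsch–Sander parallel-bridge pattern with a residue on another chain
  (Hbond(a→b) meaning C=O of a to N–H of b, bond iff
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5, overlap
  clamp −9.9 at r < 0.5 Å). Amide hydrogens are reconstructed on the
  C(prev)/CA bisector at 1.01 Å when absent. Only the parallel-bridge
  state is assigned — not the full 8-state alphabet — because the
  quantity of interest is parallel-sheet content specifically.

## Shape complementarity

Surfaces are dot-sampled on probe-expanded spheres (probe 1.7 Å,
density 15 dots/Å², golden-spiral lattice) with occlusion against
neighboring expanded spheres; normals are radial. For two surfaces, each
dot scores S = (n_a · −n_b′)·exp(−w·d²) against its nearest opposing
dot within `interface_cutoff` (1.5 Å; farther dots are peripheral and
trimmed), and Sc = ½(median_a + median_b), the published w = 0.5 Å⁻²
constant. Matched planar surfaces at separation d give exactly
exp(−w d²); the statistic is symmetric, rigid-motion invariant and
median-robust to peripheral surface. The CC-interface of a pair is the
default bipartition; arbitrary chain splits are exposed. Absolute Sc
values of the reduced-representation builds (~0.3) are not comparable to
all-atom interface values; only orderings (e.g. the monotone decrease
with interface gap) are meaningful.

## Energetics

`E_int = [E_MM + G_GB + γ·SASA](complex) − (part A) − (part B)` per
frame, averaged over a trailing window; negative is stabilizing. The
MM cross terms are vacuum Coulomb (332.0636·q_iq_j/r) and
Lorentz–Berthelot Lennard-Jones with no cutoff (finite systems;
r < 0.1 Å raises a singularity error naming the pair). G_GB uses OBC-II
effective radii (pairwise HCT descreening, universal 0.8 screen, tanh
rescaling with α, β, γ = 1.0, 0.8, 4.85, offset 0.09 Å) and a
salt-dependent solvent term: the 1/ε_out contribution is Debye-screened
with κ from a 0.15 M monovalent salt default (with the customary 0.73
empirical scaling). Ionic screening matters here because every chain
carries −2 e: without it the halves of a segmentation accumulate
unscreened monopole repulsion that grows with size and has no physical
counterpart in a neutralized solvated system. SASA is Shrake–Rupley
(960 sphere points, probe 1.4 Å) with γ = 0.0072 kcal/(mol·Å²), the
common MM/GBSA default. Entropy terms are omitted, as usual for
interaction-energy comparisons. Interior dielectric is 1 (the common
GB default).

**The parameter table.** The packaged per-atom set is deliberately
minimal and is *not* a biomolecular force field: backbone charges
(N −0.40, H +0.30, CA +0.10, C +0.50, O −0.50) sum to zero per residue;
formal charges sit on the modelled tips (D23: CG +0.30, OD −0.65 each;
K28: NZ +1.0; C-term: O/OXT −0.75 each) or on CB where the reduced
representation has no tip (E11/E22 −1, K16 +1), so every chain sums to
its −2 e formal charge. LJ wells are atomic by element except CB
(3.9 Å, 0.35) and SCT (3.6 Å, 2.20), which act as united residue-level
contact wells: each absorbs the dispersion of a whole side chain,
compensating the GB desolvation that burying a one-atom-thick polar
sheet face costs. With this table the growth-mode comparison reproduces
the qualitative physics — elongation energy saturates with size while
the thickening energy deepens roughly linearly, producing a crossover
near 11–12 monomers on idealized builds — but absolute values are not
comparable to force-field MM/GBSA numbers, which is why the pipeline
reports them only relative to each other.

Segmentations: *elongation* splits a single layer at its longitudinal
midpoint and requires an even chain count (the segmentation is
symmetric); *thickening* splits a pair into its layers. The crossover
is the smallest total monomer count with E_thick < E_elong, linearly
interpolated between the bracketing sampled sizes (exact for the linear
test model); no sign change reports "no crossover in range".

## Pipeline

`run_study` drives build → ensemble → observables → energetics →
crossover for a ladder of sizes from one YAML-loadable config with a
single seed; the same seed gives byte-identical reports. Default
problem sizes are 4–12 monomers for singles, 2×4–2×6 for pairs, with
energies compared at 8 and 12 total monomers and 11 frames per
ensemble — small enough to run in minutes on one core while exercising
every stage; all sizes scale up by config. Pairs with ≤3 chains per
layer are built but flagged "excluded from systematic analysis" (such
tiny pairs lose their fold in solution). Per-system failures are logged
into the report rather than aborting the run.

## Limitations

- No dynamics, solvent, docking or minimization; the synthetic
  generator reproduces ensemble-level statistics (cumulative twist,
  hinge disorder, noise), not kinetics or thermodynamics.
- The reduced representation cannot reproduce published per-system
  RMSD/twist magnitudes, β-content percentages, Sc values or MM/GBSA
  energies from long explicit-solvent simulations; those quantities are
  produced by the same machinery but their absolute values are
  model-specific.
- In-register stacking is exact; register disorder, N-terminal residues
  1–8, metal ions and water channels are not modelled.
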