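# Methods

`helixfuse` implements the geometric core of a screening protocol for
designing soluble helical fusion-partner proteins that replace the third
intracellular loop (ICL3) of a G-protein-coupled receptor and lock the
relative geometry of transmembrane helices TM5 and TM6, thereby pinning the
receptor in a chosen conformational state. The package covers everything in
that protocol that is a deterministic geometric computation: library
prefiltering, terminal-helix elongation, the sliding-window fusibility
screen, chimera assembly with exclusion gates, sequence-design constraint
generation, the fragment-based local-structure statistic, and the
trajectory fluctuation screen. The heavy external engines the protocol
plugs into — flexible-backbone sequence design, ab initio folding, packing
metrics, molecular dynamics — are treated as hooks: the pipeline exports
their inputs (constraint tables, structures) and consumes their outputs
(designed models, score columns, trajectories).

## Conventions

* "Main chain" is the atom set {N, CA, C, O} everywhere an RMSD or SASA is
  computed; the convention is recorded in every report header.
* Coordinates are in Angstrom, right-handed axes, membrane normal along +z
  (OPM slab convention); the membrane is the closed interval
  z_min ≤ z ≤ z_max, so an atom exactly on a boundary counts as inside.
* Residues are renumbered contiguously 1..L on ingestion; all window ranges
  (N-terminal 2–11, C-terminal last 11 residues, TM5 204–211, TM6 219–229)
  are inclusive pairs in that renumbered frame.
* Insertion codes and altlocs beyond 'A'/blank are rejected, not dropped.

## Stage-by-stage model

**Library prefilter.** A backbone survives iff (1) its longest run of
buried residues is at most 3, where buried means main-chain Shrake–Rupley
SASA < 5.0 Å² with a 3.0 Å probe (radii N 1.55, C 1.70, O 1.52 Å), and
(2) its terminal CA atoms are closer than 12.0 Å (a rough TM5–TM6 gap).
Survivors are sorted by CA radius of gyration (unweighted) and the most
compact `rg_keep_fraction` kept (ceil rounding). The compactness clause is
qualitative in the source protocol, so the fraction is a configuration
knob with default 1.0 (no cut). SASA is computed numerically via biotite's
Shrake–Rupley with per-atom radii; the isolated-atom value agrees with the
analytic 4π(r+probe)² to well under 1%, and the total-model value changes
by < 1% when the sampling density doubles (per-residue values of nearly
buried residues are noisier in relative terms, which is why convergence is
stated on totals).

**Elongation.** Seven residues of ideal α-helix (φ = −57°, ψ = −47°,
ω = 180°, standard bond geometry) are appended beyond each terminus by
internal-coordinate (NeRF) chaining, 100 trials per candidate with
zero-mean Gaussian torsion noise (σ = 3°, seeded). A trial fails if any CA
pair at sequence separation ≥ 5 comes closer than 4.0 Å. A candidate
advances only if *all* trials succeed (a configurable minimum is
available), carrying the superposed-and-averaged ensemble forward.
Existing atoms are never moved; N-side extension shifts numbering up. The
noise magnitude and the clash definition are this package's own choices —
the source protocol used a fragment-based remodeling engine whose
stochastic details are not reproducible — chosen so the construction is
seeded, dependency-free, and geometrically equivalent in intent.

**Fusibility screen.** Every 3-residue window pair from the design's
terminal ranges is *jointly* superposed (one rigid transform fitting the
24 main-chain atoms of both windows simultaneously) onto every window pair
from the receptor's TM5/TM6 ranges, via Kabsch superposition with
reflection excluded. Joint fitting is essential: only a single transform
constraining both windows fixes the TM5–TM6 relative geometry. With the
default ranges on a 123-residue design this is 8·9·6·9 = 3888
combinations, evaluated in a batched SVD formulation (rmsd from singular
values of the cross-covariance, smallest one sign-flipped when the
determinant is negative); the winner's transform is recomputed explicitly.
Ties break to lexicographic enumeration order. The gate is inclusive:
keep iff best RMSD ≤ 0.65 Å (backbone stage) or ≤ 0.4 Å (post-design
stage).

**Assembly gates.** The matched design is placed into the receptor frame.
It is discarded if any non-junction design CA comes within 5.5 Å (strict)
of a receptor CA outside the replaced segment, or if any main-chain atom
lies inside the membrane slab. Exclusion zones are the matched windows and
tails on the design side and the replaced TM5-window..TM6-window segment
on the receptor side, each widened by a configurable ±1 residue margin.
The chimera itself is spliced receptor-1..(TM5 window end) + design
interior + receptor-(TM6 window start)..end, renumbered, with a junction
table making the splice auditable; receptor coordinates win at junctions.

**Design constraints.** Positions are layered by main-chain SASA with a
water-sized 1.4 Å probe: core < 10 Å², surface > 40 Å² (strict
inequalities; the exact cutoffs are this package's choice — the source
protocol states only that restrictions follow buriedness). Base sets are
core {A,F,I,L,M,V,W,Y}, surface {D,E,K,N,Q,R,S,T}, boundary their union;
then: no Cys (disulfide risk) or His (protonation ambiguity) anywhere;
Ser/Thr removed inside helices except at the first/last helix residue
(helix benders); Lys/Arg removed from the first three residues of each
helix; glycine fixed ({G} exactly) at positive-φ (ABEGO 'G') positions and
at helix termini. Every removal records the rule that fired. The ABEGO
bins are: 'O' if |ω| < 90°; else for φ < 0, 'A' if −75° < ψ ≤ 50° and 'B'
otherwise; for φ ≥ 0, 'G' if −100° < ψ ≤ 100° and 'E' otherwise. Terminal
residues with undefined φ or ψ classify with the missing angle at its
helical default. A post-design check flags any change of the ABEGO string
relative to the input backbone.

**Fragment statistic.** For each 9-residue frame (L−8 frames), the
supplied fragment set (nominally 200 fragments, picked externally) is
superposed fragment-by-fragment onto the local main-chain structure; the
frame's pass count is the number with RMSD strictly < 1.5 Å. The design
score is Σ_frames ln((n_pass + c)/(n_total + c)) with pseudocount c = 0.5
(natural log; both are configuration knobs — the source protocol states
the log-ratio but not the base or the zero-pass handling). The score is 0
for a perfect design at c = 0 and strictly negative otherwise; designs are
ranked descending, ties lexicographic.

**Trajectory screen.** For every snapshot of an MD trajectory the matched
terminal windows — fixed at the positions found by the screen, never
re-searched — are jointly superposed onto the receptor windows and the
RMSD recorded. A design is discarded iff the trajectory mean exceeds
0.75 Å (strict). The protocol's companion criterion, visual inspection
for unexpected hydrophilic interactions, is qualitative and not
implemented.

## Synthetic fixtures

All inputs are generated by seeded pure functions, so every stage is
testable offline:

* `make_bundle` builds an antiparallel helix bundle on a ring
  (six 18-residue ideal helices, 3-residue loops, 123 residues by
  default). Helices are placed by their exact screw axis; the two terminal
  helices are splayed outward by 8° about their centroids so terminal
  elongations diverge rather than collide, and their phases are aimed so
  the terminal CAs face each other (terminal distance ≈ spacing minus two
  helix radii, ~10 Å at the default 11 Å spacing).
* `make_mock_receptor` is a minimal TM5/TM6 stand-in: one chosen design
  window pair, rigidly moved, becomes the receptor windows (ground truth
  recorded); surrounding TM residues are displaced away from the design so
  no other combination matches; remaining residues are far-away filler;
  the slab sits a margin above the placed design. Planting is verified at
  generation (exact zero for the positive construction, > 0.65 Å for the
  perturbed negative control) and resampled on violation.
* `make_library` mixes rigid copies of a template (planted fusible) with
  copies whose N-terminal segment is rigidly twisted 35–80° (planted
  non-fusible), each verified against the screen unless planted on
  pre-elongation backbones.
* `make_screen_dataset` wires these together in protocol order: the
  receptor is planted on the *elongated* template while the library holds
  raw backbones, so an end-to-end run must itself prefilter, elongate and
  screen to recover the planted positives.
* `make_fragment_sets` plants an exact per-frame pass count
  (floor(fraction·n)); passing fragments are noisy rigid copies verified
  under the cutoff, failing ones carry an alternating ±4 Å distortion
  verified above it. `make_trajectory` adds i.i.d. per-atom Gaussian noise.

What the fixtures deliberately do **not** emulate: real receptor topology
(seven-helix bundle, loop connectivity), side chains, realistic packing
or membrane physics, sequence-dependent fragment libraries, or correlated
MD dynamics. Passing tests therefore demonstrate the correctness of the
geometric computations and gate logic, not that the thresholds select
experimentally well-behaved designs.

## Numerical choices and problem sizes

Kabsch degeneracy (collinear or < 3 points) raises rather than returning a
spurious fit. Batched RMSDs clamp tiny negative round-off before the
square root. Determinism is end-to-end: every random draw flows from a
`numpy` Generator seeded from the configuration, and reruns with the same
seed produce byte-identical reports. The default test suite and the
acceptance script use scaled-down problem sizes (libraries of 6–60
models, 30–200 fragments per frame, 5–8 snapshot trajectories) chosen to
exercise every code path with planted ground truth; all thresholds remain
at their protocol defaults.

## Known limitations

* Sequence design itself is out of scope; the constraints module emits
  restriction tables and validates backbone-pattern preservation only.
* The elongation stochastic model (ideal torsions + Gaussian noise) is a
  stand-in for fragment-based remodeling; absolute success rates are not
  comparable to the original engine's.
* The radius-of-gyration clause needs a user-chosen keep fraction; there
  is no principled default beyond "keep all".
* Packing-quality columns (holes/packstat-style scores) are consumed if
  provided but never computed.
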