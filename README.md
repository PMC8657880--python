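# helixfuse

Geometric screening for designing **fusion-partner proteins** for
G-protein-coupled receptors. Replacing a GPCR's third intracellular loop
(ICL3) with a rigid soluble domain that clamps transmembrane helices TM5
and TM6 can lock the receptor in one conformational state — invaluable for
crystallography and biophysics. Finding a de novo helical bundle whose
terminal helices happen to match the TM5/TM6 geometry of the target state
is a pure 3D-screening problem, and that is what this package does.

## The screening funnel

Given a library of all-α backbone models and a receptor structure with
declared TM5/TM6 windows and an OPM-style membrane slab, `helixfuse` runs:

1. **Prefilter** — keep backbones whose longest buried-residue run is < 4
   (main-chain Shrake–Rupley SASA < 5 Å², probe 3.0 Å) and whose terminal
   Cα–Cα distance is < 12 Å; rank survivors by radius of gyration.
2. **Elongate** — append 7 ideal helical residues per terminus, 100 noisy
   trials; keep a candidate only if every trial is clash-free, and carry
   the trial-averaged structure forward.
3. **Screen** — superpose every pair of 3-residue terminal windows
   (N-terminal residues 2–11, C-terminal last 11) *jointly* onto every
   window pair on the cytoplasmic ends of TM5 (204–211) and TM6 (219–229).
   The screening statistic is the minimum main-chain RMSD over all
   combinations (3888 for a 123-mer):

   keep ⟺ min over window pairs of RMSD_Kabsch(design windows → receptor windows) ≤ 0.65 Å

4. **Constraints** — emit per-position allowed amino-acid sets for an
   external sequence-design engine (layer rules by buriedness, no Cys/His,
   Gly at helix termini and positive-φ positions, no Ser/Thr mid-helix, no
   Lys/Arg in the first three helix residues), plus an ABEGO
   backbone-pattern preservation check on its output.
5. **Re-screen** designed models at 0.4 Å, **assemble** the ICL3 chimera
   (discard on any design–receptor Cα pair < 5.5 Å or any atom inside the
   membrane slab), **rank** by the fragment statistic
   Σ_frames ln(n_pass/n_total) over 9-residue frames at a 1.5 Å cutoff, and
   **gate on MD trajectories** (discard if the mean terminal-window RMSD
   over snapshots exceeds 0.75 Å).

Everything external (Rosetta-style design, folding, MD) is a hook: the
pipeline writes their inputs and reads their outputs. A seeded synthetic
module (`helixfuse.fixtures`) generates planted libraries, mock receptors,
fragment sets and trajectories so the whole funnel runs and is tested
without any downloads.

## Worked example

```bash
helixfuse simulate --out demo/in --seed 11 --n-models 6 --fraction-fusible 0.5
helixfuse run --in demo/in --out demo/out --seed 11
```

prints

```
wrote 6 library models and mock receptor to demo/in
pipeline finished: 3 candidates kept -> demo/out
```

and `demo/out/report.tsv` records one verdict per candidate per stage:

```
label   stage        rmsd      passed  reason
lib004  prefilter              False   terminal_distance
lib003  screen       1.215089  False   rmsd_gate
lib001  screen       0.017283  True
lib000  screen       0.014438  True
lib002  screen       0.013732  True
```

Here `lib004`/`lib005` die at the terminal-distance clause, `lib003`
passes prefilter and elongation but its best window-pair RMSD (1.22 Å) is
over the 0.65 Å fusibility gate, and the three planted-fusible designs
(best RMSD ≈ 0.014–0.017 Å) survive every stage — exactly matching
`demo/in/truth.tsv`. The output directory also contains the spliced
chimera PDBs, their sequences (`chimeras.fasta`), per-design constraint
tables, and `matches.json` with each winning window combination and its
rigid transform.

The same operations are available as a library:

```python
from helixfuse.fixtures import make_screen_dataset
from helixfuse.fusion_screen import best_fusion_match

ds = make_screen_dataset(n_models=8, seed=4)
match = best_fusion_match(ds.elongated_template, ds.receptor.scaffold, ds.receptor.ranges)
print(match.n_start, match.tm5_start, round(match.rmsd, 3))
```

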