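# xldock

Crosslinking-derived distance restraints, restrained Monte Carlo peptide
docking, and restraint-satisfaction validation for peptide–receptor
complexes.

## The problem

Peptide hormones that act on class B G-protein-coupled receptors bind
with their C-terminus to the extracellular domain and insert their
N-terminus into the seven-helix transmembrane bundle. Crystallography
rarely captures these flexible full-length complexes, but two live-cell
crosslinking experiments constrain them tightly:

* **photo-crosslink scanning** — a genetically encoded p-azido-Phe (Azi)
  probe placed at successive receptor positions captures the bound ligand
  whenever any ligand heavy atom lies within ~9 Å of the probe's Cβ,
  yielding a per-ligand *footprint* of receptor positions;
* **pair-wise chemical crosslinking** — a chloroacetamide (ClAc)
  electrophile carried on a ligand lysine (or on the ligand N-terminus)
  reacts with a cysteine placed in the receptor, pinning one ligand
  position to one receptor position.

The chemistry of the crosslinked product bounds the anchor–anchor
distance: the Lys(ClAc)–Cys product spans Cβ–Cγ–Cδ–Cε–Nζ–C(O)–CH2–S–Cβ
and limits the Cβ–Cβ distance to ≈10 Å; the N-terminal product
Nα–C(O)–CH2–S–Cβ limits the Nα–Cβ distance to ≈5 Å. `xldock` turns such
observations into **upper-bound flat-bottom harmonic restraints**

```
E(d) = 0            for d ≤ d0
E(d) = k (d − d0)²  for d > d0        (default k = 10 energy/Å²)
```

and provides everything around them: hit calling from band-intensity
tables (a position is a hit when its signal exceeds 50% of the ligand's
maximum), Monte Carlo estimation of each linker's sterically possible
reach, a desk-scale restrained flexible-peptide docking sampler, model
validation (pair-wise anchors and the 9 Å photo radius against the
nearest ligand heavy atom), mutual cross-validation of restraint sets
between homologous complexes, and distance time-series over multi-model
trajectories. A fully ground-truthed synthetic generator (helical bundle
+ planted peptide + simulated scans) makes every stage testable end to
end.

## Worked example

```python
import numpy as np
from xldock import datasets
from xldock.restraints import default_registry, linker_reach, build_restraints
from xldock.synthetic import BundleConfig, make_bundle, plant_peptide, simulate_pairwise
from xldock.docking import dock, DockingConfig

# 1. How far can the Lys(ClAc)-Cys crosslinker reach?
reach = linker_reach(default_registry()["LYS_CLAC_CYS"], 100_000, seed=0)
print(f"Lys(ClAc)-Cys max Cβ-Cβ reach: {reach.max:.2f} Å "
      f"(median {reach.percentiles[50.0]:.2f} Å)")

# 2. Restraints from the packaged antagonist pair-wise hit list
rs = build_restraints(datasets.pairwise_hits("antagonist"))
n_nterm = sum(1 for r in rs if r.anchor_a == "N")
print(f"antagonist restraints: {len(rs)} total, {n_nterm} Nα-Cβ at 5.0 Å")

# 3. Recover a planted pose from simulated crosslinks
bundle = make_bundle(BundleConfig())
cx, truth = plant_peptide(bundle, "SNREKLLA", pose="helical")
sim = build_restraints(simulate_pairwise(cx, truth))
start = truth.peptide.copy()
start.translation = start.translation + np.array([4.0, -3.0, 2.0])
best = dock(bundle, start, sim, DockingConfig(n_steps=50_000, seed=0))[0]
print(f"docked pose: restraint energy {best.restraint_energy:.1f}, "
      f"clash {best.clash_energy:.1f}, "
      f"{best.report.n_satisfied}/{best.report.n_total} satisfied")
```

Output:

```
Lys(ClAc)-Cys max Cβ-Cβ reach: 10.13 Å (median 6.72 Å)
antagonist restraints: 15 total, 3 Nα-Cβ at 5.0 Å
docked pose: restraint energy 0.0, clash 0.0, 123/123 satisfied
```

The reach maximum sits at the ~10 Å crosslinking cutoff; the packaged
antagonist hit list yields its 15 restraints with the three N-terminal
entries at the tighter 5 Å bound; and the sampler drives a displaced
peptide back to a pose satisfying every simulated restraint.

A command-line interface mirrors the library:

```bash
xldock reach --spec LYS_CLAC_CYS --n 100000 --seed 0
xldock callhits --intensities scan.csv --numbering-map map.csv
xldock restraints --hits hits.csv --out restraints.csv
xldock dock --receptor receptor.pdb --peptide-seq SNREKLLA --restraints restraints.csv
xldock validate --model complex.pdb --restraints restraints.csv
xldock trajstats --traj traj.pdb --restraints restraints.csv --plot traces.png
xldock simulate bundle --out bundle.pdb
```

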