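# loxmd

MD trajectory post-analysis for lipoxygenase catalysis, built around the
question: *how often does a bound fatty-acid substrate visit a geometry from
which the enzyme can actually abstract its bisallylic hydrogen?*

Mammalian arachidonate 15-lipoxygenase (ALOX15) initiates catalysis by
abstracting a hydrogen from the bisallylic carbon of the substrate — C13 of
arachidonic acid (AA), C11 of linoleic acid (LA) — with the hydroxide of its
Fe³⁺–OH cofactor as acceptor. Point mutations at the dimer interface (e.g.
Trp181Glu, His585Glu in the rabbit enzyme) change catalytic efficiency, and
simulations explain this through the geometry of the enzyme–substrate
complex. `loxmd` implements the post-processing such studies need, for
people who have trajectories (or want controlled synthetic stand-ins) and
want reproducible numbers out.

## What it computes

**Reactive-geometry classification.** For each frame, the distances
d(C–OH), d(H<sub>proS</sub>–OH) and d(H<sub>proR</sub>–OH) from the
bisallylic carbon and its two prochiral hydrogens to the hydroxide oxygen.
A hydrogen is *well-oriented* when d(H–OH) < d(C–OH) (the C–H bond points at
the acceptor) and the frame is *pre-catalytic* for that hydrogen when
additionally d(H–OH) ≤ 3 Å. Summaries report per-frame means and the
percentage of frames with at least one hydrogen in each class, plus fold
changes and distance shifts between two systems (mutant vs. wild type).

**Binding-mode clustering.** Pairwise heavy-atom RMSD after Kabsch
superposition, neighbour-counting (Daura/GROMOS-style) clustering at a 0.5 Å
cutoff, and the centroid frame of the most populated cluster — the
"most representative binding mode".

**Structure metrics.** Carboxylate anchor hydrogen bonds
(d(H···A) ≤ 3.5 Å and ∠D–H···A ≥ 120° by default) with per-pair occupancies;
α-helical content from the i→i+4 backbone hydrogen bond
(d(O(i)···H–N(i+4)) ≤ 2.7 Å) with turn counts at 3.6 residues/turn;
inter-monomer contact distance series (leucine-zipper pairs, Glu181–His585).

**Kinetics and hydrodynamics.** Michaelis–Menten fits
v = k<sub>cat</sub>·S/(K<sub>M</sub>+S) with standard errors and catalytic
efficiency k<sub>cat</sub>/K<sub>M</sub>; SEC calibration
K<sub>av</sub> = (V<sub>e</sub>−V<sub>o</sub>)/(V<sub>t</sub>−V<sub>o</sub>),
(−log₁₀K<sub>av</sub>)<sup>1/2</sup> linear in hydrodynamic radius R<sub>h</sub>,
inverted to estimate R<sub>h</sub> of an unknown.

**Synthetic data.** Since production trajectories of a solvated dimer cannot
ship with a package, `loxmd.synth` generates every input at desk scale with
analytic ground truth attached: frame streams with controlled distance
distributions, planted binding-mode clusters, idealized/partially unwound
helices, noisy rate data, exact SEC calibration lines.

Trajectories are read from multi-model PDB (MDAnalysis) or a plain TSV frame
table; all selections are by `(monomer, residue_number, atom_name)` in a
schema-validated YAML config. Coordinates are Å throughout.

## Worked example

Simulate a mutant-like system whose carbon–hydroxide distance fluctuates
around 3.4 Å and classify it:

```bash
loxmd simulate reactive --out sim --n 2000 --seed 11 --d-mean 3.4 --d-sd 0.4
loxmd classify --traj sim/reactive.tsv --topology sim/reactive_topology.yaml \
    --out out --name Trp181Glu-AA
```

```
System                d(C-OH)(Å)  d(HproS-OH)(Å)  d(HproR-OH)(Å)  Well-Oriented(%)  Pre-Catalytic(%)
Trp181Glu-AA                3.40            2.31            2.31            100.00             96.15
```

With the hydrogens pointing straight at the hydroxide (the generator's
default), every frame is well-oriented and 96 % also satisfy the 3 Å
criterion — the closed-form expectation for this distance distribution is
95.8 %, and the per-frame CSV/JSON written to `out/` carries the full
precision values.

The same arithmetic applied to published trajectory averages for rabbit
ALOX15 (shipped as reference data) quantifies the mutant/wild-type contrast:

```python
>>> from loxmd.refdata import load_reference_geometry
>>> from loxmd.reactive import compare_summaries
>>> ref = load_reference_geometry()
>>> cmp = compare_summaries(ref[("Trp181Glu", "AA")], ref[("WT", "AA")])
>>> cmp.fold_precatalytic, cmp.display_fold_precatalytic
(16.37941176470588, 16)
>>> cmp.display_delta_mean_d_C_OH
1.5
```

i.e. with arachidonic acid the Trp181Glu interface mutant samples
pre-catalytic geometries 16× more often than wild type, and its mean
C13–hydroxide distance is 1.5 Å shorter. Kinetics from a rate table:

```bash
loxmd simulate mm --out kin --noise-cv 0 --seed 1
loxmd kinetics --csv kin/kinetics.csv --out kinout
```

```
Substrate       kcat(s-1)     KM(uM)  kcat/KM(s-1 uM-1)
LA                  47.20      21.40                2.2
```

A full multi-system run (geometry + comparison + kinetics + SEC in one
report bundle with a reproducibility manifest) is driven by a YAML config:
`loxmd run --config run.yaml`, rendered with `loxmd report --bundle <dir>`.

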