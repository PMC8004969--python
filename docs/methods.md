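# Methods

This note documents the models and conventions behind `loxmd`, the design
choices made where several were defensible, and what the synthetic-data
tests do and do not demonstrate about real trajectories.

## Reactive-geometry classification

Lipoxygenase catalysis begins with hydrogen abstraction from the bisallylic
carbon of the bound fatty acid (C13 of arachidonic acid, C11 of linoleic
acid) by the hydroxide of the Fe³⁺–OH cofactor. A frame is scored by three
distances: d(C–OH) and d(H–OH) for each of the two prochiral hydrogens. Two
criteria are applied per hydrogen X:

* **well-oriented**: d(HX–OH) < d(CX–OH). Strict inequality; since the
  hydrogen is covalently bound to the carbon, this holds exactly when the
  C–H bond vector has a positive component along C→O, i.e. the bond points
  toward the acceptor.
* **pre-catalytic**: well-oriented and d(HX–OH) ≤ 3.0 Å. The cutoff
  comparison is inclusive: a frame at exactly 3.000 Å counts. The 3 Å value
  is the conventional donor-acceptor proximity for abstraction-competent
  geometry; it is a parameter (`cutoff`) everywhere it appears.

Percentages are aggregated as "at least one hydrogen satisfies the
criterion", the convention used when such statistics are tabulated per
system; per-hydrogen percentages are computed alongside because the
aggregate alone cannot be decomposed after the fact. Percentages run over
all supplied frames; `discard_ns` (default 0) drops an initial
equilibration window first. Means are arithmetic, unweighted.

System comparisons report fold changes of the percentages (system a over
reference b) and the shift of the mean C–OH distance (b − a, positive when
system a sits closer to the cofactor). Report rendering rounds folds to the
nearest integer when ≥ 10 and one decimal otherwise, distances and
percentages to two decimals, efficiencies to one decimal — all rounding is
half-up and happens only at render time; CSV/JSON outputs keep full
precision so rounding discrepancies remain diagnosable.

## Prochiral hydrogen assignment

The two hydrogens on the bisallylic carbon are prochiral: promoting one
above the other in priority would create an R or S centre. The recommended
path is an explicit map in the selection config (force-field atom names are
stable along a trajectory, and the assignment is chemistry, not geometry).
The geometric fallback (`AUTO`) needs the carbon's bond list (PDB CONECT or
config) and a declared ranking of its two carbon branches
(`branch_priority`): with unit bond vectors u₁ = C→C_high, u₂ = C→C_low,
u₃ = C→H, the hydrogen with det[u₁,u₂,u₃] < 0 is pro-R. A full CIP priority
engine is deliberately out of scope — for the substrates of interest a
single declared branch ranking is sufficient and unambiguous. Assignment is
made once, on the first frame, and held fixed: chemical identity does not
fluctuate. Labels are rigid-motion invariant and flip under reflection
(both property-tested).

## Superposition and binding-mode clustering

Optimal rigid superposition is Kabsch via
`scipy.spatial.transform.Rotation.align_vectors` (proper rotations only);
the reported RMSD is evaluated directly from the transformed coordinates,
which is numerically cleaner than the solver's internal residual. Collinear
point sets are rejected rather than silently resolved: the in-line rotation
is undetermined and reflection-ambiguous. Tests check the result against an
independent rotation-scan oracle (dense random rotation sampling plus
derivative-free refinement) to 10⁻³ Å.

The pairwise matrix entry M[i,j] superposes frame j onto frame i on the fit
selection and measures RMSD over the measurement selection; with distinct
selections the map is not exactly symmetric, so M is symmetrized as
(M+Mᵀ)/2. Two first-class modes: fit on the substrate heavy atoms
themselves (pure ligand-conformation clustering, the default) or fit on a
reference selection such as pocket backbone and measure the ligand without
refit. RMSD is mass-unweighted heavy-atom RMSD.

Clustering is the neighbour-counting (Daura/GROMOS) algorithm at a 0.5 Å
cutoff: repeatedly the frame with the most remaining neighbours within the
cutoff becomes a centre, centre plus neighbours are removed as a cluster.
The determinism choices are: ties on neighbour count
break to the lowest frame index; final cluster ids are assigned by size
descending, size ties by earliest member; the cutoff is a neighbour cutoff
(not a cluster radius). The representative structure is the centroid of the
most populated cluster — the member minimizing summed RMSD to all other
members, ties to the lowest frame index. An exhaustive pure-python
re-implementation serves as the oracle in tests.

## Hydrogen-bond anchors

A donor–hydrogen/acceptor triple counts as bonded when d(H···A) ≤ 3.5 Å and
∠(D–H···A) ≥ 120°. The distance cutoff is deliberately permissive so that
long but persistent carboxylate contacts (≈3.3 Å H···A) register as anchors;
both cutoffs are exposed parameters. Occupancy is events/frames per
(donor, acceptor) pair, exactly.

## Helix content and turn counting

A residue stretch is helical through the canonical α-helical i→i+4 backbone
hydrogen bond, tested geometrically: d(O(i)···H(i+4)) ≤ 2.7 Å on the amide
hydrogen (fallback d(O(i)···N(i+4)) ≤ 3.5 Å when the topology has no amide
hydrogens; the fallback is logged). Every existing bond marks the residue
span i..i+4 as helical; a residue is helical iff it lies in at least one
such span. Span-marking (rather than flagging only donors) is what makes a
fully bonded n-residue helix come out as n helical residues and an
unwound-N-terminus helix lose exactly the unwound residues. Turns are
counted from the longest contiguous helical run at 3.6 residues per turn,
rounded half-up — so an 18-residue ideal helix has 5 turns, 25 residues
7 turns, a 7-residue remnant 2 turns. This is a single-criterion
assignment, testable on constructed geometry; it is not DSSP and does not
distinguish 3₁₀/π helices.

## Michaelis–Menten kinetics

Initial rates v (s⁻¹ per enzyme, already normalized) at substrate
concentrations S (µM) are fitted to v = k_cat·S/(K_M+S) by nonlinear least
squares (`scipy.optimize.curve_fit`), initialized at k_cat⁰ = max(v) and
K_M⁰ = S at half-maximal rate (linear interpolation between bracketing
points), tight tolerances (xtol 10⁻¹⁰), standard errors from the Jacobian at
the optimum. At least 4 distinct concentrations are required; replicates
enter as individual points. Degenerate data (all rates ≤ 0) and
inadmissible estimates (non-positive parameters) raise instead of being
clamped. Catalytic efficiency is k_cat/K_M in s⁻¹µM⁻¹.

Residual weighting is a parameter: `"none"` (ordinary least squares, the
default for external data, where the error structure is unknown) or
`"relative"` (residuals scaled by 1/v). When measurement error is
proportional to the rate — the constant-CV situation typical of
spectrophotometric initial-rate assays, and exactly how the synthetic
generator adds noise — relative weighting is the maximum-likelihood
estimator and materially sharpens K_M: under 5 % proportional noise with
3 replicates on a 2–160 µM grid, the K_M sampling error drops from ≈6.4 % to
≈4.2 % (relative sd), which is why the Monte-Carlo recovery tests fit with
`weights="relative"`.

## SEC calibration

K_av = (V_e − V_o)/(V_t − V_o); (−log K_av)^{1/2} is regressed on the
hydrodynamic radius R_h over ≥ 3 standards (ordinary least squares), and the
line is inverted to estimate R_h from an elution volume. The logarithm is
base 10 by default (chromatography convention; the base is a parameter).
K_av = 0 (co-elution with the void) makes the transform undefined and is an
error, as are ordering violations V_o < V_e ≤ V_t. The classical standard
set — chymotrypsinogen A (20.9 Å), bovine serum albumin (35.5 Å), catalase
(52.2 Å) — is the default fixture of the generator.

## Synthetic generators: what they emulate, and what they don't

Each generator draws from one seeded `numpy.random.default_rng`; identical
arguments and seed give byte-identical output (hash-checked in tests), and
every output carries a `GenSpec` record with the parameters and enough
ground truth to verify the paired analysis without re-derivation.

* **Reactive frames** place the hydroxide oxygen at the origin, the carbon
  at distance d ~ Normal(μ, σ) truncated to d > b (rejection sampling;
  b = 1.09 Å C–H bond), and both hydrogens at a controlled angle φ to the
  C→O direction (one in-plane, one rotated out of plane; both share the
  analytic d_H). Expected well-oriented and pre-catalytic fractions follow
  in closed form from the truncated-normal CDF: well-oriented iff
  cos φ > b/(2d); d_H ≤ c iff d ∈ [b·cosφ ± √(c² − b²sin²φ)]. For φ = 0 the
  pre-catalytic fraction reduces to Φ((c + b − μ)/σ), truncation-corrected.
  Default study contrast used in examples and pipeline tests: a mutant-like
  system at μ = 3.4 Å and a wild-type-like system at μ = 4.6 Å, σ = 0.4 Å,
  φ = 0 — distance scales matching the tabulated trajectory averages for
  the two complexes.
* **Clustered frames** plant K random conformer templates rescaled so every
  template pair is ≥ `separation` (5 Å default) apart in superposed RMSD,
  then add isotropic jitter (0.05 Å default); clean recovery at cutoff c
  requires separation > 6·jitter + 2·c, which is validated. Labels are
  recorded.
* **Helices** are geometric idealizations, not stereochemically correct
  peptides: backbone atoms sit on coaxial helices (100°/1.5 Å per residue)
  arranged so every i→i+4 O···H distance is exactly 2.4 Å; unwound residues
  are displaced far off-axis with per-residue offsets so all their bonds
  break. Ground-truth flags follow the span rule from the planted range.
* **Kinetics** data are the exact forward model times (1 + ε),
  ε ~ N(0, cv); defaults (k_cat 47.2 s⁻¹, K_M 21.4 µM, S ∈ {2…160} µM,
  cv 0.05, 3 replicates) match linoleate oxygenation by the wild-type
  enzyme and a realistic assay design.
* **SEC** standards are back-computed to lie exactly on a calibration line,
  so calibrate→estimate must be the identity.

What passing these tests shows: the classification, clustering, helix,
kinetics and calibration code paths are correct against independent
oracles, deterministic, and statistically calibrated at desk scale. What
they do not show: anything about force-field accuracy, sampling convergence
of 100 ns production runs, solvent effects, or the absolute percentages a
real trajectory would give — those depend on simulation inputs a
post-analysis package cannot certify. Trajectory-scale absolute
percentages from the literature are therefore shipped as reference *inputs*
(see `loxmd.refdata`) for the arithmetic layers, not regenerated.

## Pipeline and reproducibility

The `loxmd run` pipeline validates its YAML config against a strict schema
(unknown keys rejected), runs the requested analyses per system, and writes
a bundle of full-precision CSV/JSON plus a manifest with the config and
SHA-256 of every input, sufficient to re-run. Reruns are byte-identical
(tested by hashing the output directory). Exit codes: 2 configuration
error, 3 input error, 4 analysis failure; logs go to stderr, results to
files/stdout only.

Problem sizes in the shipped tests and the acceptance script — 10,000
frames for distribution checks, 100 frames for planted clustering, 100
Monte-Carlo fits — were chosen so statistical assertions have useful power
(binomial 99 % intervals of ±1 % or less) while the whole suite stays
interactive-fast.

## Known limitations

* PDB parsing trusts the file's residue numbering and chain IDs verbatim;
  no renumbering, no altloc/occupancy handling beyond what MDAnalysis does.
* Binary trajectory formats (DCD/XTC) are not read natively; convert to
  multi-model PDB or the TSV frame table first.
* The helix criterion is a single H-bond test; turn counts for heavily
  distorted helices are approximate by construction.
* The geometric prochirality fallback covers only the
  two-carbon/two-hydrogen bisallylic pattern; other stereocentres need the
  explicit config map.
* Unweighted SEC regression over three standards has no leverage
  diagnostics; r² is reported but with three points it is nearly always
  close to 1.
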