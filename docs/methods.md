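# Methods

`rdcsas` determines dynamic ensembles of bulge-containing RNAs by selecting
small sub-ensembles from a large conformer pool so that ensemble-averaged
residual dipolar couplings (RDCs) match multi-construct NMR measurements,
and then characterizes the selected ensembles structurally. This note
records the models, conventions, parameters, and numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## RDC model

A residual dipolar coupling for a bonded pair with unit bond vector **u**
in the molecular frame is

    D = D_max * u^T S u   [Hz]

with `S` the symmetric, traceless 3x3 Saupe order matrix and `D_max` the
rigid-limit dipolar constant of the pair type, computed from gyromagnetic
ratios and effective bond lengths (C-H 1.104 A, N-H 1.041 A). Only ratios
between pair types matter downstream because each construct carries a free
scale factor; absolute values are kept physical so predictions land on the
tens-of-Hz experimental scale. Supported pair types are the sugar
C1'-H1'...C4'-H4', base C2-H2/C5-H5/C6-H6/C8-H8, and imino N1-H1/N3-H3
vectors; unsupported pairs are rejected by name at load time, never skipped
silently.

### Steric alignment (shape) prediction

Alignment by a dilute obstruction medium (e.g. filamentous-phage liquid
crystal) is predicted from molecular shape with a planar-obstruction
approximation. For each direction **n** of the obstruction normal on a
deterministic golden-spiral grid (default 10^4 directions, configurable),
the accessible fraction is `f(n) = max(0, 1 - extent(n)/d)`, where
`extent(n)` is the molecule's heavy-atom span along **n** and `d` is the
barrier spacing derived from the medium concentration (effective barrier
thickness 60 A over the volume fraction; 0.022 g/mL gives d ~ 2.7e3 A). The
order matrix is the f-weighted orientational average of
`(3 n n^T - I)/2`, normalized by `<f>`; in a rod medium the field-frame
tensor is -1/2 of the normal-frame average. The prefactor is absorbed by
the per-construct scales, so only the tensor's shape matters. Verified
properties: a rigid rod gives an axially symmetric tensor (asymmetry
eta ~ 0.02) with its unique axis along the rod; a spherical shell gives a
tensor three orders of magnitude smaller; the prediction is equivariant
under rotation of the molecule to grid tolerance (~1e-4 relative).

### Order-tensor (SVD) fit

Where measured couplings are fit directly, the five independent Saupe
elements solve `D/D_max = A s` with the standard direction-cosine design
matrix, via SVD; the condition number is reported and a rank below 5
raises an error. Noise-free forward-predict/re-fit round trips recover the
generating tensor to machine precision.

## Sample-and-select (SAS)

Given a precomputed conformer x record prediction matrix, SAS minimizes

    chi^2 = sum_j sum_i (L_j D_ij_calc - D_ij_exp)^2

over N-member subsets, where the per-construct scales `L_j` have the
closed-form least-squares solution `sum(exp*calc)/sum(calc^2)` and are
refit at every cost evaluation by default (the cost then has the closed
form `sum exp^2 - sum_j (sum exp*calc)^2/(sum calc^2)`, evaluated
incrementally per proposed swap). Members of one ensemble are distinct;
pooled ensembles across runs may repeat members.

The chain: initialize with N distinct uniform draws; each step proposes
replacing one uniformly chosen member by a uniformly chosen non-member and
accepts with probability `min(1, exp(-d(chi^2/N_rec)/T))` (the mean-squared
scale, so the default initial temperature 100 is commensurate with typical
costs). The temperature is multiplied by 0.9 every step (block cadence
configurable) down to a floor of 1e-12, and by default is then *reheated*
to the initial temperature, giving cyclic annealing: one 5x10^5-step run
behaves like ~1600 short quenches from successively perturbed states while
the best-ever ensemble is retained. A strictly monotone per-step schedule
reaches the floor after ~640 steps and degenerates to single-swap greedy
descent, which we measured to recover a noise-free planted 4-member
ensemble from a 200-conformer pool in only ~30-40% of runs; with reheating
recovery is essentially certain under the same step budget. Set
`reheat=False` for the strictly monotone schedule. The final reported chi^2
and RMSD are always recomputed from scratch for the returned member set.

Ensemble size is chosen by `size_scan` (independent replicates per N with
derived seeds); the plateau is flagged at the first N whose mean-RMSD
improvement over its predecessor falls below a tolerance (default 0.2 Hz).
Large analysis ensembles are built by `pool_runs`, pooling total/N
independent runs with counter-derived seeds (run 0 reuses the master seed,
so pooling a single run reduces exactly to one selection).

## Cross-validation

Two modes test for over-fitting. *Record hold-out*: a random 10% of
records is removed (10 repeats by default), selection runs on the rest,
and the held-out records are scored with the training-fit scales.
*Leave-one-construct-out*: each construct's dataset is dropped in turn;
because alignment magnitude is construct-specific, the held-out construct
gets one free scale fit post hoc on its own data, so only the relative RDC
pattern is tested. On pure-noise data with a deliberately oversized
ensemble, held-out error exceeds training error in >= 8/10 repeats — the
signature of over-fitting the method is designed to expose.

## Structural analytics

* **Torsions / pucker.** Backbone dihedrals (alpha..zeta), glycosidic chi,
  and the ribose pseudorotation phase P and amplitude nu_max obtained by
  least-squares fit of `nu_j = nu_max cos(P + 144 deg (j-2))` to the five
  ring torsions (exact on an ideal pseudorotation path and well
  conditioned at every phase, unlike the nu2/cos P form). C2'-endo is
  called for P in [90, 270), C3'-endo otherwise; amplitudes below 10 deg
  give an explicit "ambiguous" call. Missing atoms yield NaN angles and a
  per-residue report, never an exception.
* **Chemical-shift pucker mapping.** Percent C2'-endo is linear in the C1'
  shift between 86 ppm (100%) and 94 ppm (0%), clamped by default.
* **Inter-helical Euler angles.** An idealized A-form reference helix is
  least-squares superposed (heavy atoms) onto >= 2 bp of each helix; the
  relative rotation `R_lower^T R_upper` — expressed in the lower-helix
  frame, hence invariant under rigid motion of the conformer — is
  decomposed as ZYZ Euler angles with beta in [0, 180]. The signs of
  alpha_h and gamma_h are inverted so that a positive twist
  (alpha_h + gamma_h) means junction over-twisting. Near beta = 0 the
  alpha/gamma split is degenerate; alpha absorbs the full z-rotation and
  the twist remains the stable quantity. Bend classes: linear
  (|beta_h| <= 45), intermediate (45 < |beta_h| <= 70), kinked (> 70);
  boundary values deliberately fall in the lower-bend class.
* **Stacking / coaxiality / flips.** Two bases stack when their ring
  centroids are within 4.5 A, their plane normals within 30 deg, and the
  centroid offset perpendicular to the mean normal is at most 2.5 A (all
  three thresholds configurable). A junction is coaxial when any
  configured cross-junction pair of closing base pairs has a stacked base
  combination. A bulge residue is extra-helical when its base stacks with
  no base of either flanking closing pair; note that interior residues of
  long flipped-in bulges stack with neighboring bulge residues rather than
  the closing pairs, so for bulges longer than ~2 nt the flanking set
  should include the neighbors if "tucked-in" middle residues are to be
  recognized.
* **Cooperativity.** Per-residue independent flip-out probabilities are
  conditional frequencies among conformers whose other bulge residues are
  all flipped in; their product is compared with the observed all-out
  fraction via `dG = -RT ln(P_obs/P_indep)` at T = 298 K (R in
  kcal/(mol K)); negative dG is favorable cooperativity and the magnitude
  is also reported. Zero denominators raise with diagnostic counts.
* **Superposition / ensemble distance.** Kabsch least-squares rigid
  superposition (proper rotation enforced). The lower-bound distance
  between ensembles A and B is the root mean square over A of each
  member's minimum RMSD to B, symmetrized by taking the smaller of the two
  directions.

## Idealized A-form geometry

Helices are built from rigid idealized nucleotide templates placed by a
screw operator (twist 32.7 deg/bp, rise 2.81 A/bp — fiber-diffraction
A-RNA values; both live in one editable parameter table together with the
template pose). Templates are constructed from internal coordinates: the
ribose ring from a pseudorotation-parameterized out-of-plane displacement
model, numerically calibrated so the realized Altona-Sundaralingam phase
equals the requested one; planar bases with standard bond lengths;
D-ribose handedness checked against the reference nucleotide geometry in
the chemical component dictionary. The rigid pose of the level-0
nucleotide (glycosidic-nitrogen position, N->C1' axis, spin) was fit once
by least squares against backbone O3'-P closure under the screw operator
(resulting contact 1.67 A), Watson-Crick hydrogen-bond distances across
the pair dyad (2.87-2.96 A), sequential stacking overlap, and moderate
base tilt. This rigid-residue screw idealization settles at a high-anti
glycosidic torsion (chi ~ -92 deg) and a base tilt of ~34 deg — a known
departure from refined A-RNA geometry (chi ~ -160 deg, inclination
~ 19 deg) that is immaterial here because every consumer (Euler frames,
stacking calls, RDC prediction, elongation) uses the same self-consistent
templates, and per-construct scaling absorbs residual geometry effects on
predicted couplings. In-silico elongation appends pairs with the same
operator at a chosen terminal base pair, numbering new residues outward.

## Synthetic data generator

The generator emulates the statistical structure of a two-helix bulge
junction ensemble: two idealized helices joined by a 1-7 nt bulge; the
inter-helical bend |beta_h| drawn from a weighted mixture of Gaussian
modes (default a narrow ~20 deg near-coaxial mode and a broad ~75 deg
kinked mode, weights 0.5/0.5 — the bimodal character expected for bulge
junctions); twist deviations Gaussian (sd 20 deg); per-bulge-residue
C2'-endo probability (default 0.5, mid-range of experimentally estimated
bulge pucker populations) realized by swapping the ribose template phase;
per-residue extra-helical flips (default probability 0.5) with an optional
coupling that boosts flipping in the near-coaxial mode, reproducing the
co-occurrence of coaxial stacking and cooperative flipping. Flipped-in
residues occupy intermediate helical steps (the helices separate
accordingly, so any flipped-in residue breaks the coaxial stacking
contact); flipped-out residues are placed analytically ~13 A off-axis with
a clash check and capped retries. Each conformer receives a random global
orientation, since every structure in a real library defines its own
alignment frame. Datasets are simulated per construct as equal-weight
averages over the true members under construct-specific random alignment
tensors (entries ~6e-4, giving couplings of tens of Hz), multiplied by
per-construct scales drawn in [0.7, 1.3], plus Gaussian noise of sd 2 Hz —
the experimental RDC uncertainty the method is designed around. Construct
differentiation by distinct fixed lab-frame tensors is the fast test mode;
the steric mode recomputes a shape tensor per conformer (with optional
in-silico elongation per construct) and is exercised separately.

What the generator does **not** emulate: sequence-dependent energetics and
realistic backbone conformational variety (bulge placement is analytic,
not physical), non-canonical pairing or register shifts, loop regions,
internal motions within a conformer, or medium-specific electrostatic
alignment. Passing the benchmarks therefore demonstrates the correctness
and statistical behavior of the selection and analysis machinery under the
assumed data model, not the accuracy of ensembles for any real RNA.

## Benchmark problem sizes and numerical choices

The standard desk-scale experiments (also run by `scripts/acceptance.py`)
use: a 200-conformer library with a planted 4-member ensemble and 3
constructs x 40 records for recovery and noise-floor runs (10 repeats,
all seeds derived from one master via `SeedSequence`); 20 bond vectors
for the SVD round trip; 10^4-direction grids (1.6x10^5 for the dense
oracle) for the steric checks; 1000 random rotations for the Euler
recomposition; and a 100-conformer library with 25-member ensembles on
pure-noise data for the over-fitting check. Success in recovery means the
selected ensemble's cost is no worse than the exhaustively evaluated cost
of the generating set; with noise the generating set need not be the
minimizer, so member overlap is reported without a hard threshold
(degenerate solutions are expected and real).

Numerical details worth knowing: the incremental closed-form cost can go
slightly negative (~-1e-15) through cancellation — final results are
always recomputed directly; per-construct scale fits guard against
all-zero predictions; the PDB writer quantizes coordinates to 1e-3 A, the
round-trip tolerance; the bend-class boundaries and the pucker amplitude
floor (10 deg) are explicit tie-break choices; temperature underflow in
the annealer is clamped at the configured floor.

## Known limitations

Idealized template geometry as described above; the extra-helical rule for
long bulges needs neighbor-aware flanking sets; flip/stack calls on real
ensembles will differ from visual classification, so published flip counts
are reproduced at the formula level (observed fractions in, free energy
out), not at the structure-annotation level; no Bayesian or
maximum-entropy reweighting — selection is hard subset choice with equal
weights; deposited-ensemble comparisons require external data and are out
of the download-free benchmark scope.
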