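# Methods

This package analyses the interior architecture of β-carboxysomes — the
polyhedral bacterial microcompartments that concentrate Rubisco and
carbonic anhydrase for CO₂ fixation — from two kinds of downstream data:
per-particle Rubisco poses (the by-product of cryoET subtomogram
averaging) and peptide-level QconCAT quantification tables (the
by-product of isotope-dilution LC-MS). Neither raw tomograms nor raw
spectra are touched; everything upstream of poses and peak areas is out
of scope.

## The concentric-layer model and its simulator

Rubiscos inside a β-carboxysome form concentric layers parallel to the
shell, spaced d = 120 Å apart, with a single complex at the core. The
simulator realizes an idealized version of this organization:

* **Layer radii.** Layer ℓ sits at radius r_ℓ = (ℓ−1)·d. The number of
  layers in an organelle of vertex-to-vertex diameter D is the largest ℓ
  with r_ℓ ≤ f·(D/2) − c, where f = 0.76 is the inradius/circumradius
  ratio of an icosahedron (converting the polyhedral diameter to a
  usable lumen radius) and c = 90 Å is a clearance for shell thickness
  plus the Rubisco half-height. With D = 169 nm this yields five layers,
  the modal organization; the gap between the outermost cargo layer and
  the shell is not measurable from cargo poses alone, so c is a
  modelling choice, exposed in the config.
* **In-layer density.** Each layer ℓ ≥ 2 holds N_ℓ = round(4πr_ℓ²/a)
  particles, with the area-per-particle a = 4π·(360 Å)²/174 ≈ 9360 Ų
  calibrated once so that layer 4 holds 174 particles, matching the
  measured per-layer counts (1, 20, 71, 174, 308, 407 for layers 1–6).
  Note this density implies an in-layer contact spacing (~92–105 Å)
  tighter than the 120 Å radial spacing — see *Neighbour distances*.
* **Placement.** Particles are placed on a golden-angle (Fibonacci)
  spiral — deterministic and density-exact; realism comes from isotropic
  Gaussian positional jitter (default SD 15 Å). The spiral is iteratively
  re-centred so each layer's centroid is the origin to ~10⁻¹² Å;
  without this the raw spiral's small azimuthal imbalance would shift a
  noiseless organelle's centre of mass off its geometric centre and
  break exact parameter recovery.
* **Orientation.** Each particle's 4-fold axis is set to its radial
  direction, tilted by an angle |Normal(0, σ)| about a uniformly random
  perpendicular axis (default σ = 10°; the angular spread of the real
  alignment is not published, so this is a realistic-looking choice, not
  a measured one), with uniform in-plane rotation — symmetric under the
  D4 point group of Rubisco. Poses are emitted as intrinsic ZYZ Euler
  angles in degrees.
* **Population.** Diameters are drawn from Normal(169.0, 11.8) nm;
  draws below the one-layer feasibility minimum are redrawn, not
  clipped, so no degenerate organelle is emitted. Under these defaults a
  200-organelle population is ~6% four-layer, ~79% five-layer, ~15%
  six-layer, with ~620 ± 184 Rubiscos per organelle.

What the simulator does **not** emulate: polyhedral (non-spherical)
shells, missing-wedge anisotropy, template-matching false positives or
missed particles, partial outermost layers, or inter-organelle
variation in lattice spacing. Passing tests therefore demonstrate that
the analysis recovers the parameters of this idealized generative
model, not that it is robust to every artefact of real tomograms.

## Spatial statistics

* **Core** = arithmetic mean of all particle positions in the
  organelle; radial distances are Euclidean norms from it.
* **Layer assignment** is 1-D clustering of radii: a Gaussian KDE with
  bandwidth d/4, whose local maxima are candidate layer radii (peaks
  closer than d/2 are merged). Two refinements proved necessary:
  (1) counts grow as r², so the KDE is weighted by the inverse shell
  area 1/(r² + (d/4)²), giving every layer — including the one-particle
  core layer — comparable mass; (2) peaks are labelled by their nearest
  core-anchored lattice index round(peak/d̂)+1 (d̂ = median peak
  spacing) rather than by rank, so a core particle jittered under a
  neighbouring peak costs one particle, not a whole-organelle label
  shift. Particles farther than d/2 from every peak seed a new peak at
  their nearest lattice radius. With fewer than 20 particles the
  fallback is the lattice rule ℓ = round(r/d)+1. Noiseless input is
  recovered exactly; at 15 Å jitter, agreement with generator truth is
  ≥ 99.9% of particles.
* **Neighbour distances.** Two statistics are computed. The
  *first-nearest-neighbour* distance (closest companion per particle)
  and the *neighbour-pair* distance (all pairs within a 160 Å cutoff,
  each counted once). The headline "distance between neighbouring
  Rubiscos" is the neighbour-pair mean: at the calibrated in-layer
  density a mean first-NN of ~120 Å is geometrically impossible (the
  hexagonal packing bound at 9360 Ų/particle is ~104 Å, and the
  measured first-NN of the simulation is ~78 Å), whereas the
  neighbour-pair mean — which pools in-layer contacts with the 120 Å
  cross-layer contacts — measures 124.6 ± 24.6 Å on the default
  population, consistent with the ~120 Å (121.9 ± 31.4 Å) scale of the
  real organelles and with the 120 Å inter-layer spacing. Both numbers
  are reported in every summary.
* **Axis–radial angle** θ = arccos(|u·r̂|) ∈ [0°, 90°] between the
  undirected 4-fold axis u and the radial unit vector r̂; radially
  aligned = 0°. A particle at the core has no radial direction; its θ is
  missing, not an error.
* **Population summaries** report per-organelle particle count, layer
  count, radial extent (2·max r — the shell itself is unobservable from
  cargo), and pooled histograms; organelles with fewer than 4 particles
  are summarized but excluded from layer-count histograms.

## Packing model

With a reference layer (ℓ_ref, N_ref), predicted counts follow the
sphere-surface-area law N_ℓ = N_ref·((ℓ−1)/(ℓ_ref−1))²; layer 1 is
pinned to exactly 1. Totals are 1 + Σ_{ℓ≥2} N_ℓ, and organelle capacity
versus diameter applies the same feasibility rule as the simulator.
Anchored at layer 4 = 174, the model predicts 19.3, 77.3 and 309.3 for
layers 2, 3 and 5 (measured 20, 71, 308), a five-layer total of 581
(~600 reported for the common five-layer organelle) and a sixth layer
appearing at D ≈ 193 nm. Predictions are kept as reals — rounding
happens only in reports — and the same quadratic law is applied to the
outermost layers even though real ones are less regular, so the
capacity curve is an upper-bound-style idealization.

## QconCAT stoichiometry

Per peptide, pmol = (light area / heavy area) × spiked pmol; a
protein's per-replicate amount is the mean of its (two) Q-peptides,
with >4-fold peptide disagreement flagged but kept, and rows with
non-positive heavy area rejected. Copies per organelle anchor the
relative amounts to the cryoET Rubisco count: RbcL = 639 × 8 = 5112
monomers (anchor and value overridable). Replicates are aggregated as
mean ± SD. If a table carries Q-peptides for the CcmM35/58 shared
region (total CcmM) alongside CcmM58-specific ones, CcmM35 = shared −
CcmM58, floored at zero.

Functional units divide monomer copies by the oligomer size (hexamer 6,
pentamer 5, pseudohexamer 6, dimer 2, L₈S₈ subunits 8, monomer 1) and
round to the nearest integer with exact halves rounded **down** — the
only rule consistent with both printed half-integer cases (11853/6 →
1975, 7/2 → 3). The quotient is rounded to 6 decimals first so
floating-point dust cannot flip an exact half. Masses are monomer
copies × monomer MW; the reference composition sums to 529.5 MDa, with
Rubisco ≈ 68% and the CcmK shell hexamers ≈ 25% of the total. Mass
fractions are recomputed from mean copies, so they can differ from
per-replicate-averaged percentages by a few tenths.

The peptide simulator draws multiplicative lognormal noise exp(N(0,
CV)) on each light/heavy ratio (per-peptide response factors cancel in
the ratio, as in the real measurement). The ratio of two such terms
biases recovered copies upward by ≈ e^{CV²} − 1 ≈ 4% at CV 0.2 — below
the 3-SE resolution of a four-replicate design and within the 5% bias
tolerance verified in tests.

## Numerical and interface choices

* Determinism: every stochastic step flows from a single integer seed
  through `numpy` SeedSequence spawning; identical seeds give
  byte-identical serialized outputs, and `report.json` floats are
  rounded to 6 decimals before writing.
* Problem sizes: analyses and tests use 200 simulated organelles
  (~124k poses), matching the scale of the real 185-tomogram dataset;
  the full suite runs in well under a minute.
* Interchange formats: poses and truth as TSV, peptide tables as CSV,
  population summaries as JSON; a minimal STAR importer maps
  RELION-style columns (`_rlnCoordinate*`, `_rlnAngle*`) onto the pose
  schema, multiplying by a user-supplied pixel size when coordinates
  are in pixels.
* Degenerate inputs: empty pose sets, single-particle organelles,
  zero-radius particles, all-rejected proteins and missing anchors all
  have defined behaviour (error or missing value), exercised in tests.

## Known limitations

* The layer-assignment labelling assumes layers sit near multiples of
  the supplied spacing (core-anchored); organizations with an
  irregular first shell would need the rank-based reading.
* The capacity curve and layer predictor treat the outermost layer as
  fully packed and regular; real outermost layers are partial, so
  six-plus-layer totals overestimate.
* The stoichiometry pipeline consumes peptide-level areas; it cannot
  correct upstream biases (digestion efficiency, peptide-specific
  ionization differences between sample and standard).
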