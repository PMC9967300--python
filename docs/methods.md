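# Methods

## Model

The package treats a dye pair as two *extended dipoles*. For each dye,
the centre c is the mass-weighted centre of the four squarate carbons
(all carbon, so equal weights), and the transition-dipole direction μ̂
is the unit vector from c to the centre of the terminal benzene ring
furthest from the covalent linker — the dye long axis. The
π-conjugation bridge termini r and s are the two ring centres
(unweighted geometric centres of the configured ring atoms), with
bridge length l = |r − s|. Which ring is "far" is static configuration,
not inferred per frame: covalent topology does not change along a
trajectory, and frame-wise inference could flip μ̂ and corrupt the
packing sign κ′.

The exciton hopping parameter is the four-point-charge form

    J_mn = J_o (1/|r1−r2| − 1/|r1−s2| − 1/|s1−r2| + 1/|s1−s2|)
    J_o  = μ_m μ_n / (4π ε0 n² l_m l_n)

equivalent to charges ±μ_i/l_i at r_i/s_i interacting by screened
Coulomb terms. The prefactor uses the product μ_m μ_n so heterodimers
are covered; it reduces to the |μ|² homodimer form exactly when the
dyes are identical. Endpoints r/s are used directly in the four terms
(not c ± (l/2)μ̂): r − s may deviate slightly from μ̂ in a distorted
frame, and both are retained. With this sign convention a cofacial
H-pair has J > 0 and a head-to-tail J-pair J < 0, consistent with the
point-dipole limit

    J_pt = K μ_m μ_n (μ̂_m·μ̂_n − 3(μ̂_m·R̂)(μ̂_n·R̂)) / (n² R³),

which the extended form approaches as l/R → 0 (verified at
l/R = 10⁻¹…10⁻³; relative error ~7×10⁻⁵ at l = R/100).

Orientation metrics per frame: R and R̂ from the two centres, oblique
angle α = arccos(μ̂_m·μ̂_n), slip angles θ_i = arccos(R̂·μ̂_i) reported
per dye (the summary convention is configurable because either dye, or
an average, could be headlined), κ² = (μ̂_m·μ̂_n − 3(μ̂_m·R̂)(μ̂_n·R̂))²
and κ′ = μ̂_m·μ̂_n. The identity κ² = (κ′ − 3 cosθ_m cosθ_n)² holds
algebraically and is property-tested to 10⁻¹².

## Units and constants

Internal lengths are nm everywhere (the analysis cutoffs — 1.2 nm
contacts, 0.05 nm RMSD — are natural in nm); Å→nm conversion happens
only in file readers/writers. Times are ns. Dipoles are in Debye and
couplings default to cm⁻¹ (meV available). The conversion constant —
1 D²/nm³ against 4πε0, ≈ 5.0341 cm⁻¹ — is evaluated from CODATA values
in `scipy.constants` at import rather than hard-coded. The refractive
index defaults to 1.33 (aqueous buffer) and enters as 1/n²; because the
medium's effective n for a dye pocket in DNA is not well defined, all
couplings state their n and absolute J values should be read with that
caveat.

## Angle folding

Angles above 90° are folded into [0°, 90°] for reporting. The default
`as_printed` convention applies |x − 90| for x > 90 — the rule used by
the optical-modelling reference data this analysis is compared against.
It maps 180° → 90°, which is physically odd for antiparallel dipoles,
so the usual line-direction fold `reflect_180` (min(x, 180 − x),
mapping 180° → 0°) is available as an explicit alternative; the two
differ only for angles beyond 90°. Dot products are clipped to [−1, 1]
before arccos so numerical boundary cases cannot produce NaN.

## Contact maps

Residues are in contact in a frame when their mass-weighted centres of
mass are within the cutoff, boundary inclusive (a measure-zero choice,
fixed and documented). The default 1.2 nm matches the electrostatic
cutoff of the production simulations this analysis targets. The
probability matrix keeps its diagonal at 1 (plots mask it). Residue
CoM uses all atoms present in the file, hydrogens included; a
heavy-atom-only variant can be had by configuring the residue map's
atom lists, since nothing downstream assumes complete residues — the
map is the single source of truth for which atoms belong to a residue.

## GROMOS clustering and ensemble summaries

Pairwise RMSD over the dye-atom selection is computed, by default,
after optimal rigid superposition (unweighted Kabsch) of each frame
pair over that same selection; raw-coordinate RMSD is available with
`superpose=False` since the original workflow's fit group is not
pinned down. The implementation never materialises rotated
coordinates: with both frames centred,
rmsd² = (|X|² + |Y|² − 2 trΣ′)/n_atoms where trΣ′ is the
reflection-corrected sum of singular values of XᵀY, evaluated in
row-batches of 3×3 SVDs. Numerical cancellation leaves a ~10⁻⁷ nm
floor on pairs that are exactly superposable, far below any physical
RMSD.

Clustering is the greedy neighbour-count algorithm: repeatedly take
the frame with the most neighbours within the 0.05 nm cutoff (ties →
lowest frame index, for determinism), remove it and its neighbours as
a cluster, continue. Clusters with strictly more than 5 % of total
frames are retained; "5 % of the total cluster amount" is read as a
fraction of frames, the only reading under which discarded clusters
are plausibly transition states. If everything is discarded the error
advises reviewing the cutoff.

Two summaries are reported per metric and for J_mn:

* **time_series** — mean and *population* standard deviation over all
  analysed frames (the estimand is the spread of the sampled ensemble
  itself, not an inference to a larger population; ddof = 0,
  documented).
* **gromos** — within each retained cluster, centres and bridge
  endpoints are averaged over member frames and mean dipole directions
  renormalised (a near-zero mean direction, |·| < 10⁻⁶, raises rather
  than silently normalising); metrics and the coupling are evaluated
  on each cluster-average geometry; mean/sd are then taken across
  cluster values, unweighted by default with fraction-weighting
  available — the across-cluster spread is what distinguishes genuine
  multi-state ensembles from frame noise.

Equilibration is expressed as a frame fraction (default 0.05, the
analogue of skipping 0.1 μs of a 2 μs run) so the rule applies to
trajectories of any length, with an integer stride for subsampling.
Because the RMSD matrix is quadratic in frames, the end-to-end
pipeline clusters on an evenly strided subset capped at 2,000 frames
when the sliced trajectory is longer (noted in its warnings); the
time-series route always uses every sliced frame. Problem sizes used
in the shipped tests and reference script — up to 10,000 frames for
time-series statistics, 2,000 for clustering — are the package's
standard working scale.

## Synthetic generator

The generator emulates only the *statistical* structure of a dye-pair
trajectory: a rigid planar template dye (four squarate carbons in a
0.2 nm square, two hexagonal rings centred ±0.7 nm along the long
axis so l = 1.4 nm, a linker-side marker), dye 2 stacked cofacially
above dye 1 at separation R ~ Normal(mean_R, sd_R) truncated at
0.3 nm (protecting the coupling's endpoint-distance precondition),
rotated 180° about the stacking normal for AB packing, both dyes then
perturbed by small random rotations (uniform axis, Normal(0, jitter)
angle). An optional planted conformer re-bases a trailing contiguous
block of frames on a second geometry. Defaults are the reference
study conditions: 10,000 frames at 0.2 ns/frame (a 2 μs trajectory),
mean_R 0.6 nm, sd_R 0.1 nm, jitter 10°, AA packing, SQ-H2 dipole,
seed 1234.

The mock junction is four arms of single-pseudo-atom residues
(strands A–D at 45°/135°/225°/315° in the dye plane, 8 residues per
arm at 0.5 nm per residue, per-frame positional noise sd 0.05 nm).
The 0.5 nm rise is chosen so residues beyond the third sit ≥ 2 nm from
the junction — far enough that the noise cannot carry them inside the
1.2 nm cutoff (≈18σ margin), making the "distal residues never touch
the dyes" construction guarantee deterministic rather than merely
probable. `junction_core` placement leaves the dimer at the origin
(transverse-like, touching all arms); `displaced` shifts it 1.5 nm
out along arm A (adjacent-like, fewer scaffold contacts).

All draws come from one `numpy` Generator seeded from the config, in
a fixed documented order (separations, then dye-1 rotations, then
dye-2 rotations; scaffold noise from a separately derived stream), so
outputs are bit-reproducible. Ground truth (sampled R, conformer
labels, planted packing signs) is recorded apart from anything the
pipeline reads. What the generator does **not** emulate: force-field
energetics, solvent, DNA structure, dye internal flexibility, or
kinetics — passing tests show the *analysis* is correct and
statistically calibrated, not that real dye–DNA systems behave this
way.

## Degenerate inputs and tie-breaks

Coincident dye centres, bridge endpoints closer than 10⁻⁴ nm (the
offending pair is named), far-ring centres within 10⁻⁶ nm of the
squarate centre, empty selections, and empty slice results all raise
with specific messages. Cluster-count ties go to the lowest frame
index; the 5 % filter is strictly-greater; the contact boundary is
inclusive. A multi-model PDB is pre-scanned so a frame with a missing
atom is rejected by frame index before parsing.

## Known limitations

* Absolute J values depend on the unstated effective refractive index
  of the dye pocket; trends and limits are robust, absolute scales are
  conditional on n.
* The extended-dipole model ignores transition-charge detail and any
  polarisation beyond the scalar 1/n² screening.
* Binary trajectory formats are supported only through the
  reader-callable contract; the core reads text formats (multi-model
  PDB, GRO, XYZ) via MDAnalysis.
* Periodic-boundary unwrapping is not performed; inputs are assumed
  whole-molecule.
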