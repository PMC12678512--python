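# Methods

`sapflex` implements the desk-side conformational-analysis chain for
saposin-fold flap dynamics — the kind of analysis applied to microsecond MD
ensembles of surfactant protein B (SP-B) — together with a synthetic
ground-truth generator that makes every stage testable without MD output.
This note records the models, conventions and numerical choices, and what
the synthetic tests do and do not demonstrate about real trajectories.

## System and order parameters

SP-B's mature chain has 79 residues with four semi-conserved helical regions
(helix 1: 9–19, helix 2: 27–33, helix 3: 46–61, helix 4: 69–72) and three
conserved disulfides (Cys8–Cys77, Cys11–Cys71, Cys35–Cys46) that hold the N-
and C-terminal helices together in the saposin fold; a seventh cysteine
(Cys48) is unpaired. The fold's two flaps (helices 1+4 versus 2+3) open and
close about inter-helical hinges. Flap geometry is tracked by two residue
separations:

* d1 = TYR7–VAL34 (helix 1 flap to helix 2 flap)
* d2 = ILE45–VAL70 (helix 3 flap to helix 4 flap)

plus the family-conserved CYS8–CYS35 distance. Separations default to
residue center-of-mass distances (matching the mask-distance convention of
common MD post-processing tools); a CA mode is available for sensitivity
checks. Frames are classified with inclusive bounds and closed-first
precedence: *closed* when both separations lie in 12–17 Å, *open* when both
lie in 20–40 Å, *partially open* when d1 is in the closed band while d2
exceeds it (the helix-3/4 flap has separated while helices 1/2 stay
packed), otherwise *other*. "Other" is deliberately an explicit label so
state fractions remain honest rather than forcing every frame into the
nearest class.

## Superposition, RMSD, RMSF

The optimal rigid superposition is the weighted Kabsch solution (SVD of the
mass-weighted cross-covariance with the reflection branch excluded). The
test suite cross-checks it against an independent Horn quaternion-eigenvalue
implementation to 1e-8 Å on random instances. RMSD series superpose every
frame freshly onto the reference on the backbone selection {N, CA, C}
(whether a carbonyl O belongs to "backbone" varies between tools; the
selection is configurable).

RMSF uses the two-pass scheme: an iterated average structure (align all
frames to the current average, re-average; max 10 iterations, tolerance
1e-4 Å — convergence is fast in practice), then per-residue mass-weighted
fluctuations about the time-average positions of the aligned frames. With
alignment disabled, i.i.d. per-coordinate Gaussian noise of width sigma has
the closed-form RMSF sigma·sqrt(3), which the generator recovery tests use.
High-flexibility (hinge-candidate) regions are maximal runs of residues
strictly above the profile mean plus one standard deviation, with no gap
tolerance.

Published aligned-backbone RMSF magnitudes for this system (profile means
near 10–11 Å) are far larger than the values this two-pass definition
produces on any plausibly converged trajectory; they likely reflect a
different normalization that cannot be reconstructed from the description.
The implementation follows the literal two-pass definition and treats those
printed magnitudes as non-reproducible; only the *relative* peak structure
(mean + sd thresholding) is used downstream.

## Free-energy landscapes

The (d1, d2) series — after discarding equilibration by keeping only the
final window (500 ns by default) — is histogrammed on half-open bins
[edge, edge + w) of width 0.1 Å by default, with edges anchored at integer
multiples of the width so that bin identity is data-independent and
replicate grids pool exactly. Pooled counts give state probabilities
P_i = n_i / N, and the relative free energy is the Boltzmann inversion

    dG_i = −R·T·ln(P_i),  R = 1.9872e-3 kcal/(mol·K), T = 310 K,

shifted so the occupied minimum is zero (the inversion fixes dG only up to
the normalization choice, and only relative values are meaningful).
Unoccupied bins are undefined — NaN plus an occupancy mask, rendered at the
top of the colour scale — never infinities, keeping exports finite. Minima
are occupied bins strictly below all occupied neighbours (8-connected by
default). Note that with sparse statistics an isolated occupied bin is
trivially a minimum; meaningful minima counts require the histogram to be
dense relative to the bin width, which is why the desk-scale end-to-end
checks use 1 Å bins over a few thousand frames rather than the 0.1 Å
production convention.

## Frame clustering

k-means over conformations with an RMSD metric is formally ill-posed (RMSD
is not Euclidean), so the standard surrogate is used: all frames are rigidly
superposed onto the trajectory's iterated average structure on the backbone
selection and the flattened superposed coordinates are clustered by Lloyd
iteration with k-means++ seeding, best of 10 restarts, 300 iterations max,
k = 5 by default, fixed seed. For frames within a few Å of a common
reference this Euclidean distance closely approximates pairwise RMSD.
Clusters are reported in descending size order ("the k largest clusters"),
each with the member frame closest to its center as representative;
replicates are clustered separately by default (pooled clustering is a
caller choice). A degenerate dataset can leave a cluster empty, in which
case its representative index is −1.

## Secondary structure

The Kabsch–Sander (DSSP) algorithm is implemented natively: backbone
hydrogen bonds from the electrostatic model
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond
below −0.5 kcal/mol, an energy floor at −9.9 kcal/mol, an overlap clamp for
distances under 0.5 Å, a 9 Å CA prefilter, at most two acceptors per donor,
prolines as non-donors, and amide hydrogens reconstructed at 1.01 Å from N
along the preceding C=O direction (the original program's convention — a
bisector placement is sometimes described in the literature, but the C=O
convention is what the reference implementations use, and matching the
oracle is what makes the ≥95% agreement criterion meaningful). Chains split
where C(i)–N(i+1) exceeds 2.5 Å or CA–CA exceeds 4.5 Å. Pattern rules
follow the original priority: alpha (two consecutive 4-turn starts)
overrides strand; bridges/ladders (with single-gap bulge linking) give E/B;
then 3-10, pi, hydrogen-bonded turn T, and bend S (CA-chain curvature above
70°). Agreement with the independent mdtraj port of DSSP-2.2.0 is 100% on
ideal helices and the stand-in models, and ≥95% is asserted throughout.

Helicity is binarized as class ∈ {H, G, I} (alpha, 3-10, pi). Occupancy
maps average the binarized maps across replicates on a common
fraction-of-trajectory axis (default 100 bins), since replicate durations
differ; entry (bin, residue) is the fraction of (replicate, frame) samples
that are helical, rendered white (1) / gray / black (0).

## Radial solvent distributions

Solvent reference sites (water oxygen, chloroform carbon — configurable;
molecule COM versus single-atom counting is a convention choice) are binned
into spherical shells (default 0.5 Å up to 25 Å) about a region's center of
mass under the orthorhombic minimum-image convention, requiring
r_max ≤ half the shortest box edge. Shell densities are normalized by the
bulk density N/V averaged over frames, so g(r) → 1 far from the protein and
profiles from solvents of different density are directly comparable; shell
Poisson standard errors are propagated into profile differences. Only
orthorhombic (cubic, for the synthetic systems) boxes are supported;
truncated-octahedron production boxes are out of scope.

## The synthetic hinge-protein generator

The generator supplies ground truth, not physics. It builds a backbone-only
(N, CA, C, O) 79-residue model carrying the real mature SP-B sequence: four
ideal alpha helices (NeRF-constructed at phi = −57°, psi = −47°, so they
genuinely hydrogen-bond as helices) placed on a fixed scaffold, joined by
deterministic coiled linkers whose arc length absorbs the chain's excess
contour while keeping consecutive CA spacing in the no-chain-break regime,
and SG pseudo-atoms on all seven cysteines arranged so exactly the three
saposin disulfides are detectable at the 2.5 Å SG–SG cutoff (single S–S
bonds are ~2.05 Å). The two flaps hinge about a fixed axis; three rigid
angles of the helix-2/3 flap are solved numerically (least squares) so the
measured (d1, d2) match the requested closed (15, 14 Å) and open (25, 27 Å)
geometries — the representative starting-model separations — to within
0.5 Å, erroring if a requested geometry is unreachable.

Trajectories are a two-state Markov chain over the two reference frames
(per-frame switch probabilities, default 0.01 each; stationary law
pi_open = r_co/(r_co + r_oc)) plus i.i.d. isotropic Gaussian positional
noise (default sigma = 0.75 Å, which keeps the diagnostic separations well
inside their class bands while giving non-trivial classification noise).
All randomness flows from one seed through one generator; identical seeds
give bit-identical output. Uniform single-site solvent is placed by
rejection sampling outside an exclusion radius of every protein atom in a
cubic periodic box centered on the protein.

What the generator does *not* emulate — and hence what passing tests do not
show about real MD: continuous diffusive dynamics (noise is white, so
switching is instantaneous and autocorrelation comes only from the chain),
side chains and their packing, solvent structure (no first-shell peak; the
RDF ground truth is a flat profile with an excluded core), and any coupling
between noise and secondary structure. In particular i.i.d. noise of
sigma ≳ 0.3 Å destroys backbone hydrogen-bond geometry long before it moves
residue centers of mass, so DSSP-level checks use low-noise (sigma ≤ 0.1 Å)
trajectories while classification/landscape checks use the default noise.

Statistical recovery tests use fast switching (rates 0.5/0.5), where the
state sequence is nearly i.i.d. and plain binomial standard errors apply;
at slow physical-looking rates the dwell-time autocorrelation would inflate
the variance of occupancy estimates well beyond the binomial bound.

## Problem sizes

The published analyses rest on ~1 µs × 20 production simulations and are
not reproducible at desk scale; all statistical checks here run on
generated data at desk-scale sizes chosen for tight closed-form error
bounds: 10,000-frame chains for occupancy recovery, 100–200 frame ensembles
for RMSF closed forms, 2,000-frame two-basin runs (1 Å bins) for the
end-to-end pipeline, and a few thousand solvent sites for RDF calibrations.

## Charge bookkeeping

The pH 7.4 census counts Arg/Lys positive and Asp/Glu negative with His
neutral — the assignment that reproduces the mature chain's published
9 positive / 2 negative / net +7 census — and models the free termini as
+1/−1, which cancel. Neutralizing counterions are |net| anions for a
positive peptide (7 chlorides for SP-B), symmetric for negative.

## Stand-in starting models

The published starting structures ship as supplementary PDBs that are not
redistributable here; the worked-example inputs are therefore the
generator's stand-in models (`spb_standin_models()`): synthetic geometric
surrogates built from the published sequence and printed structural facts
(sequence census, disulfide topology, helix regions, starting separations).
Every deterministic worked example — census, disulfide detection, starting
separations, DSSP agreement — runs on these stand-ins, and they are labelled
synthetic wherever they appear. Conclusions about the real models' fine
geometry (e.g. exact helicity percentages) should not be read off the
stand-ins, though the closed stand-in's DSSP helicity (~35%) happens to sit
near the low end of the experimentally reported 40–50% overall helicity.

## Known limitations

* No mmCIF/DCD/XTC/NetCDF readers; multi-model PDB and a plain coordinate
  table are the only trajectory formats.
* DSSP bulge linking merges ladders with the standard one-and-four gap
  rule but sheets are otherwise minimal (no sheet topology graphs); strand
  content in this system is negligible.
* The landscape is a plain histogram inversion: no kernel density
  estimation, reweighting, or enhanced-sampling estimators.
* Pairwise-RMSD k-means is approximated by the superposed-coordinate
  surrogate; for heterogeneous ensembles far from the average structure the
  approximation degrades.
* The RMSF magnitudes printed in the source analyses are treated as
  non-reproducible (see above); only their thresholding logic is modelled.
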