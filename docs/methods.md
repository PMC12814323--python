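# Methods

## The statistical model behind the pipeline

The pipeline treats an MD study as a set of labeled ensembles (one label
per binding state, several replica trajectories per label) and asks two
discrete-state questions: (i) what conformational microstates does the
backbone visit within each ensemble, and (ii) which side chains' rotamer
states carry information about the backbone microstate.

Both questions reduce to categorical per-frame series, so the coupling
statistic is an entropy ratio. With empirical state frequencies
p_i and Shannon entropy S = −Σ p_i ln p_i, the entropy-based
cross-correlation of the backbone series and a side-chain series is

    ECC = 2 (S_BB + S_SC − S_total) / (S_BB + S_SC),

where S_total is the entropy of the paired series. This is a normalized
mutual information: the numerator is 2·I(BB; SC). ECC is exactly 0 for
empirically independent series and exactly 1 when each series determines
the other. The Boltzmann prefactor conventionally attached to S cancels
in the ratio, as does the logarithm base; we use natural logs and test
the base invariance. No finite-sample bias correction is applied; for a
pair of independent series the plug-in estimator's bias is
approximately (|A|−1)(|B|−1)/(2N ln-units) in the numerator, which the
test suite verifies decays toward 0 with frame count. An optional
shuffle-null (permutation of one series) is available to quantify this
floor for a given series pair, and is off by default.

### Degenerate cases

If both series are constant, every entropy is 0 and the ratio is 0/0;
we define ECC = 0 and set a `degenerate` flag. ECC values are clipped to
[0, 1] to absorb float rounding at the exact endpoints.

## Superposition and shared-basis PCA

PCA variance must reflect internal motion, not rigid-body drift, so all
frames of all ensembles are least-squares fitted (Kabsch, proper
rotations only, no mass weighting — backbone atoms have similar masses)
to a single common reference before one PCA is fitted to the pooled
matrix. The reference is the coordinate-wise mean of the combined
dataset after one pass of fitting to the first frame; a single shared
reference and a single PCA are what make scores comparable across
ensembles. Components have a fixed sign convention (largest-magnitude
entry positive) so plots and archives are reproducible run to run.

Columns are ordered residue-major with N, CA, C within each residue;
coordinates are Angstrom internally.

## Microstate clustering

The clustering algorithm is a design choice (nothing about the data
dictates one): k-means with 10 seeded restarts on the first 5 PCs, with
k selected from {4, 5, 6} by mean silhouette (subsampled at 2,000
frames, seeded, for large ensembles). Five PCs rather than two because
clusters that overlap in the PC0/PC1 plane separate in higher
components; histograms are still drawn in PC0/PC1 (default 100×100 bins
on edges shared across ensembles). Clusters are canonically ordered by
descending population with ties broken by center PC0, so labels are
invariant to frame order. Cluster centers are reported in full PC
space; the medoid is the member frame nearest the center in the
clustering subspace, ties broken toward the lowest (replica, frame).
Gaussian-mixture/BIC selection would be a reasonable alternative; it is
not implemented.

Cluster-center RMSDs are computed by back-projecting each center to
coordinate space and superposing pairs. Note that for a translation-only
displacement of m of M atoms by d, least-squares fitting leaves
d·sqrt(r(1−r)) with r = m/M (the translation fit absorbs the mean
shift); the test suite pins this value against an independent
superposition routine.

## Rotamer discretization

Only χ1 and χ2 are used. χ1 is binned into the three staggered wells
with edges at −120°, 0°, +120°, labeled g− (−60°), g+ (+60°), t (180°);
this edge choice keeps the trans well contiguous after wrapping to
(−180°, 180°]. χ2 uses the same staggered wells for sp3 branches and a
two-well ±90° split for aromatic rings and planar amide/acid groups,
whose flip symmetry leaves only "face" and "flipped" states. The
resulting counts are Val/Ser/Thr/Cys 3, Leu/Ile 9, Trp/Phe/Tyr/His/
Asn/Asp 6. Side chains longer than two χ angles (Met, Gln, Glu, Lys,
Arg) are truncated at χ2 and reported as 9 states — a documented
simplification wherever their counts appear. Ala/Gly/Pro carry no
rotameric states and are excluded from coupling scans. The state index
is the mixed-radix combination (χ1 major), and reported state numbering
("state 1" etc.) is by descending population within the analyzed
series.

Dihedrals follow the standard sign convention (verified against two
independent MD libraries) and are wrapped to (−180°, 180°]. Circular
means are used for per-state average angles.

Dwell segments — maximal windows in which one state's occupancy stays
above a dominance threshold — are found greedily left to right, taking
at each position the longest qualifying window of length ≥ min_length.
Defaults: dominance 0.9, min_length one third of a replica, which
selects long "mostly fixed" stretches while tolerating brief excursions.
The occupancy criterion is evaluated with exact integer prefix counts so
boundary cases do not depend on float accumulation order.

## Conditional histograms and contacts

Conditioning partitions an ensemble's frames by the rotamer state of one
residue and histograms each partition on shared edges as raw counts, so
the per-state histograms sum to the unconditioned histogram bin for bin
— an exact integer identity, asserted in tests, not an approximation.
Per-state fractions equal the rotamer populations by construction.
States under the minor threshold (default 5%) still get histograms but
are flagged: such populations are too sparse to interpret. The oblique
1-D histogram projects PC0/PC1 scores onto the axis at a given angle
(default 60°) counterclockwise from PC0 — useful when a population
shift runs diagonally in the plane. Overlay tables report the bin-wise
min-sum overlap coefficient between normalized grids. Contact shells
count heavy atoms only (the toy topologies carry no hydrogens, and
heavy-atom contacts are the conventional report), measured from the
conditioning residue's side-chain atoms, default cutoff 4 Å.

## Conformational-selection kinetics

The kinetic model formalizes the qualitative claim that microstate
populations tune binding kinetics more than affinity. Unbound
microstates interconvert with rates k_ij = ν·p_j, which satisfy detailed
balance with the stated populations p; binding occurs only from the
competent subset at intrinsic rate k_on*·[L]; unbinding returns to
competent states in proportion to their equilibrium weights. Under fast
exchange (ν much larger than binding flux) the closed form is
k_on,eff = p_competent·k_on*, k_off,eff = k_off, K_d = k_off/k_on,eff.
The numerical mode builds the full generator, extracts the slowest
relaxation rate at several ligand concentrations, and fits
k_obs = k_on,eff·[L] + k_off,eff; it agrees with the closed form to
within 1% when interconversion exceeds binding flux by ~10³ and deviates
(correctly, as verified by an event-driven simulation) when exchange is
slow. The fine-tuning curve rescales the competent population across a
range under two scenarios: on-only modulation (K_d strictly decreasing
in p_competent) and proportional on/off modulation (K_d invariant).
Parameters are deliberately exposed rather than fixed: the model is a
formalization of a mechanism, not a fit to any experiment.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not the physics that produces it. Residues sit on an idealized α-helix
(1.5 Å rise, 100° turn); each ensemble displaces a trailing contiguous
segment (default the last 35% of residues, a "TM6-like" rigid tilt) by
an ensemble-specific offset (default 6 Å spacing), and each hidden
microstate adds its own offset (default 2 Å) on the same segment;
isotropic Gaussian noise (default σ = 0.5 Å, a typical within-state
backbone fluctuation) is added to every backbone atom. Microstate
offsets use octahedron (K ≤ 6) or icosahedron (K ≤ 12) vertex
directions: a planar polygon would leave some state pairs several times
closer than others after rigid-body superposition, which is not the
"distinct sub-clusters" structure being emulated. Hidden microstates
follow a sticky Markov chain (default self-transition 0.98, uniform
otherwise, hence a uniform stationary distribution); microstate counts
default to a draw from {4, 5, 6} per ensemble.

Rotamer emission for a residue with coupling strength κ interpolates
between a uniform distribution over its states (κ = 0) and the
deterministic map state = microstate mod n_states (κ = 1). With κ = 1
and a residue whose state count is at least the microstate count (e.g.
leucine, 9), the rotamer series is an injective relabeling of the
microstate series and the true ECC is 1. χ-defining atoms are placed by
internal coordinates so the emitted state's bin-center angle plus
wrapped-Gaussian jitter (σ = 15°, ≥ 4σ from every bin edge) is realized
exactly; state re-assignment from coordinates therefore recovers the
emitted states with probability ≈ 1 − 6×10⁻⁵ per frame while still
exercising angle wrapping.

Defaults mirror a 12-trajectory study design — 4 ensembles × 3 replicas
× 20,000 frames — at desk scale; time is abstract (frames × frame_dt).

What the generator does **not** emulate: force-field energetics,
solvent and membrane, correlated (non-isotropic) thermal motion,
backbone–side-chain mechanical coupling (the coupling is statistical,
injected through the emission table), state-dependent kinetics of χ
transitions, and realistic microstate free-energy differences. Passing
tests therefore demonstrate that the *analysis* recovers planted
statistical structure at realistic signal-to-noise, not that real
receptors have such structure.

Trajectories are written as DCD (float32, round-trips Å coordinates to
~10⁻⁶) with a PDB topology; XTC output is supported but its fixed
0.001-nm precision bounds round-trips at 0.01 Å. Output is byte-stable:
identical specs (including seed) give byte-identical files.

## Problem sizes used in the test suite

Unit tests run on hundreds of frames. The end-to-end recovery test uses
one ensemble of 3 × 20,000 frames with 5 microstates, one fully coupled
leucine and five uncoupled side chains, repeated over 20 generator
seeds (pass bar 19/20): large enough that the uncoupled ECC floor
(~10⁻³) and the clustering accuracy (ARI > 0.99) are far from the
0.1 / 0.95 thresholds, small enough to run on a laptop in ~1–2 minutes.

## Reproducibility

Every stochastic step takes a seed; the pipeline fans one global seed
out per stage as (seed + crc32(stage)) mod 2³¹, so adding a stage never
shifts earlier stages' randomness. The pipeline manifest records SHA-256
hashes of all artifacts; identical configs reproduce identical hashes.

## Known limitations

- k-means assumes roughly isotropic clusters in PC space; strongly
  anisotropic or nested microstates would need a mixture model.
- ECC is symmetric and instantaneous: it measures association, not
  direction or lag. Time-lagged couplings are out of scope.
- Long side chains truncated at χ2 understate their true rotamer space.
- The kinetic model's microstate populations are inputs; mapping rotamer
  populations to p_competent (the pipeline default uses the share of
  frames outside the dominant rotamer state) is a modeling choice, not
  an estimate.
- The activation-pathway narrative (stepwise transitions between
  conditioned histograms across ensembles) is an interpretive overlay of
  the computed histograms; the package computes the histograms and
  overlap coefficients but does not detect transition frames.
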