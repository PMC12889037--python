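# Methods

`wmkdiv` quantifies how a family of two-domain (two-HTH) DNA-binding
homologs diverges, at the sequence level and at the level of conformational
ensembles sampled from molecular dynamics. This note records the models,
conventions and numerical choices behind each stage, what the synthetic
family generator does and does not emulate, and the known limitations.

## Input model

All structural analysis is Cα-based. A conformation is an ordered Cα trace
with 1-based residue numbering; an ensemble is a time-stamped sequence of
such traces sharing one residue set. Trajectories enter as multi-model PDB
(binary MD formats must be converted upstream); frame times come from a
sidecar JSON because PDB has no standard time field. Residue ranges are
1-based inclusive throughout (a domain "21–75" has 55 residues).

## Trajectory preprocessing

The first 20 ns of every trajectory are discarded as the equilibration
offset (frames at exactly 20 ns are kept). Cross-homolog structural
comparisons use eight conformations sampled on the 25–95 ns grid at 10 ns
intervals; each grid time takes the nearest frame within half a step
(tolerant of trajectory writing cadence), and a grid time with no frame in
tolerance is an error rather than a silent gap.

## Geometry

Superposition is the weighted Kabsch algorithm (SVD of the weighted
cross-covariance, reflection branch corrected so det(R) = +1). Collinear or
coincident point clouds, where the optimal rotation is not unique, raise
instead of returning an arbitrary solution. RMSD without superposition is a
separate primitive so that the two operations compose explicitly.

Radius of gyration is unweighted and Cα-only, reported in nm. The usual MD
tool computes a mass-weighted all-atom Rg, so absolute values here are a
proxy; only relative comparisons across ensembles are meaningful, and no
numeric parity with all-atom values is claimed.

## Ensemble descriptors and tests

Per-ensemble descriptor series (RMSD to a reference conformation after
per-frame superposition; Rg per frame) are summarized as median and
*unscaled* median absolute deviation (no 1.4826 consistency factor); the
even-length median is the mean of the central order statistics.

Distribution comparisons use the Wilcoxon rank-sum test: exact null
enumeration when n₁+n₂ ≤ 12 and the pooled sample is tie-free, otherwise
the normal approximation with tie and continuity corrections (via
`scipy.stats.mannwhitneyu`). Pairwise testing across homologs adjusts with
Holm by default (configurable: none, Bonferroni, Benjamini–Hochberg);
two-sided alternatives are the default since the direction of a difference
between homologs is not prespecified. Groups with fewer than two values are
flagged and skipped rather than tested.

## Within-ensemble dynamics

The dynamic cross-correlation matrix uses the isotropic scalar-product
estimator C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over superposed
frames. Residues with zero positional fluctuation would divide by zero;
their entries are set to 0 and the residues flagged. Negative C between the
two HTH domains after whole-chain superposition is the signature of
hinge-like, anti-correlated domain motion.

Trajectory PCA eigendecomposes the 3N×3N covariance of superposed frame
coordinates with 1/(F−1) normalization, computed through an SVD of the
centered frame matrix (cheaper than forming the covariance when frames ≪
3N). Eigenvector signs are fixed so the largest-magnitude loading is
positive, making projections reproducible. Principal motions are
visualized as mean + t·σ_k·PC_k for t ∈ [−3, +3] (the range is a
convention; ±3σ covers the ensemble almost entirely).

Superposition targets: either a user-supplied representative conformation
or the iterated mean (fit all frames to the running mean until it shifts
< 1e-6 Å, at most 50 iterations). DCCM and single-homolog PCA default to
the iterated mean; all frames after the offset are used rather than only
the eight sampled ones, since more frames stabilize both estimators.

## Cross-homolog structural comparison

TM-scores are computed over a **fixed residue correspondence taken from the
MSA** (columns where neither sequence is gapped), normalized by the shorter
chain by default. This deliberately differs from a structure-alignment
search, which optimizes the correspondence itself; absolute values are
therefore not comparable to search-based tools, and the pipeline's claims
are orderings and group contrasts, which are robust to the choice. The
score is (1/L)Σ 1/(1+(d_i/d0)²) with d0 = max(1.24·(L−15)^⅓ − 1.8, 0.5);
the 0.5 Å floor covers short chains where the formula is small or
undefined. The score is maximized over rigid superpositions
deterministically: seed fits on contiguous fragments (lengths n, n/2, n/4
at half-fragment offsets; every fragment for n ≤ 12), each refined by
iteratively reweighted Kabsch fitting with the TM weights
w_i = 1/(1+d_i²/d0²)², keeping the best superposition seen. On small
structures this matches a multi-start 6-dof direct maximization to < 5e-3.

Core residues — positions of minimal positional variability across
superposed conformations from many homologs — are found greedily:
superpose all conformations (to an iterated mean) on the current position
set, compute each position's variance about its across-conformation mean,
remove the worst, repeat. The removal trace is the analogue of a core
identification graph. The default stopping rule cuts after the **last**
removal that drops the remaining maximal variance by at least a factor of
three: the core is the terminal low-variance plateau, and in data with
several rigidity tiers (mobile domain ≫ flexible linker ≫ anchor domain)
the largest single drop would stop one tier too early. A fixed target
count is available as an override, and an all-identical input short-circuits
to "everything is core".

Joint PCA superposes all sampled conformations on the core set and runs the
same PCA over the shared ungapped columns. Outlier homologs are ranked by
the distance of their projection centroid (first 3 PCs) from the global
medoid centroid, with mean within-homolog projection distance as a
secondary key. Progressive removal greedily removes, at each step, the
homolog whose removal maximizes the median of the remaining
between-homolog TM-scores (ties broken by lexicographic id), reporting the
median after each removal.

## Sequence divergence

Pairwise identity is global alignment (BLOSUM62, gap open 11 / extend 1 via
Biopython's PairwiseAligner) with identity = identical aligned pairs /
alignment columns (double-gap columns cannot occur pairwise). Published
identity values from similarity-search tools use subtly different
denominators, so absolute parity with them is not claimed.

Classification: identity to the reference ≥ 0.72 → type-I; otherwise
identity ≥ 0.35 to at least one seed distant homolog → distant; otherwise
unassigned (sequences divergent to both classes are excluded from typing).

Conservation per MSA column is 1 − H/log₂20 with Shannon entropy H over
the residue frequencies, gaps excluded from the frequencies (not a 21st
symbol); columns over 50% gaps are flagged. The conservation differential
maps the scores of two alignments (all homologs vs. a subset with the
distant sequences removed) onto reference numbering through the reference
row's ungapped positions and reports score_subset − score_all inside a
window (default 10–268, clipped to the reference length) that excludes
alignment-end ambiguities.

Indel blocks are maximal runs ≥ 3 columns where exactly one of
reference/query is gapped; deletions are positioned at the first deleted
reference position, insertions anchored to the preceding reference
position; columns gapped in both rows are skipped without breaking runs.

Motif scanning classifies 3-mers against residue classes — small
{G,A,S,C,T}, hydrophobic {A,V,L,I,M,F,W,Y,C}, polar
{S,T,N,Q,H,K,R,D,E,Y,W} — with one violation allowed by default, because
the canonical HTH fingerprint examples (e.g. ELS as "shs", QAE as "phs")
sit one violation outside strict membership. The classes are configurable;
there is no universally agreed set. The charge profile is a sliding sum of
formal charges (K,R = +1; D,E = −1; His = 0 — near-neutral at physiological
pH), a sequence-level proxy for surface electrostatics, not a Poisson–
Boltzmann calculation.

## Synthetic family generator

The generator produces a homolog family with full ground truth so every
stage has a recovery test without external data. Defaults emulate the
study conditions: a 222-residue reference (20-residue N-extension, two
55-residue four-helix domains separated by a 62-residue linker, 30-residue
C-extension with accessory helices); five type-I homologs
(substitution-only, targets drawn in the 72–100% identity band); two
distant homologs with a 32–36-residue linker deletion adjacent to the
C-domain, a 7–9-residue insertion immediately downstream of it, identity
targets in the 26–50% band and correlated substitutions so the two distant
sequences stay well above the 35% mutual-identity threshold; and 21-frame
ensembles on 0–100 ns at 5 ns spacing, so the 20 ns offset and the
25–95/10 sampling grid both apply cleanly.

Geometry: domains are ideal-helix bundles (rise 1.5 Å, twist 100°, radius
2.3 Å) connected by 3.8 Å steps, so chain connectivity holds by
construction. Hinge motion rotates everything past a linker-midpoint hinge
by A·sin(2πt/period + φ) about an axis perpendicular to both domain
directions, with per-atom Gaussian jitter (0.15 Å). Base folds are accepted
only if both domains lie ≥ 20 Å from the hinge (both blocks must have a
real lever arm for an open/close hinge; folds without one are degenerate
for this architecture and redrawn), and each homolog's fold is normalized
to a 60° inter-domain V at its hinge — the closing-hinge geometry in which
whole-chain superposition exhibits the anti-correlated domain signature.
Across homologs, flexible parts are *not* shared rigid bodies: each homolog
gets its own static linker and C-extension backbone conformation (σ = 2 Å),
its own C-extension orientation (±60°), a pose wobble of the post-hinge
block (±18° about a random axis), and a small static internal deformation
of the mobile domain (σ = 1 Å, well under the TM distance scale d0 ≈ 5 Å).
Per-frame loop noise (σ = 0.9 Å) on extensions and linker, and softer
noise (σ = 0.8 Å) on the mobile domain, emulate the flexibility hierarchy
of real trajectories. Together these make the N-terminal anchor block the
unique minimal-variance region, which is the planted "stable domain" truth
that core finding must recover.

Sequences are mutated toward their identity targets by an iterative loop
measured with the package's own `pairwise_identity` (substitutions
preferentially BLOSUM62-similar), converging within ±0.02 and raising if a
target is unattainable; the second distant homolog preferentially reuses
the first's mutated positions and substitutions, the way shared ancestry
correlates real paralogs. The ground-truth MSA is emitted by construction
(no aligner involved).

What the generator does **not** emulate: force-field physics, side chains,
solvent, correlated (non-white) thermal fluctuations, sequence-dependent
structure, or realistic loop packing. Passing recovery tests therefore
shows the pipeline's statistics and geometry are correct on data with known
truth of the right shape and scale — not that any biological conclusion
about real proteins is reproduced.

## Problem sizes

Recovery tests and the acceptance script run the default family (8
homologs × 21 frames, 222 residues; 8 sampled conformations per homolog →
64 conformations, ~2,000 pairwise TM-scores), brute-force oracle
comparisons on small instances (6-point Kabsch clouds, 7-residue TM pairs,
rank-sum enumeration up to n = 12), and a 1,000-replicate null calibration
of the rank-sum test at n = 30 vs 30. These sizes keep every check
exhaustive or well-powered while the whole suite stays fast.

## Known limitations

- Cα-only: no all-atom RMSD/Rg parity; no side-chain contacts.
- MSA-fixed TM correspondence: absolute TM-scores are conservative
  relative to a correspondence-optimizing aligner.
- The greedy core finder can in principle anchor on any internally
  consistent rigid block; the knee rule assumes the rigidity tiers are
  separated by about a factor of three in variance.
- Flexible-alignment similarity (twist-allowing aligners) is out of scope.
- The conservation differential assumes the reference is present and
  ungapped enough in both alignments to carry the mapping.
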