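# Methods

## Contact definition and extraction

A contact is defined at residue level: the center of geometry (unweighted
mean of heavy-atom coordinates) of an amino-acid side chain and of a
nucleobase moiety closer than a cutoff radius, strictly (`<`, a pair at
exactly the cutoff is not a contact). Side chains exclude the backbone atoms
N, CA, C, O and the terminal carboxyl oxygen OXT; base moieties exclude the
ribose (C1′–C5′, O2′–O5′) and phosphate (P, OP1–OP3, legacy O1P–O3P) atoms.
Only protein-chain vs RNA-chain pairs are considered, across all chain
combinations; intra-molecular proximities and backbone-mediated contacts
never count. The default cutoff is 8 Å, with a 6–10 Å sweep (0.25 Å grid
helper) for sensitivity analysis.

Structure parsing (via gemmi) makes the following choices where residue-level
potentials leave room:

- **Multi-model (NMR) files**: first model only.
- **Hydrogens**: discarded everywhere.
- **Glycine** has no side-chain heavy atom; its CA is used as a one-atom
  surrogate center (standard practice for residue-level potentials),
  configurable to exclude glycine instead (`glycine='exclude'`).
- **Alternate conformations**: per atom name, the conformer with the highest
  occupancy is kept; ties go to altloc 'A'.
- **Modified residues**: MSE is treated as Met; all other non-canonical
  residues, deoxyribonucleotides and modified bases are skipped and counted
  in `StructureModel.skipped`.
- **Distance ties** (relevant to set `2`) break deterministically on the
  base's (chain, residue number, insertion code).

Neighbor search uses a k-d tree; the test suite checks it exactly against a
brute-force all-pairs implementation, and checks rigid-motion invariance of
all derived tables. The three neighbor-set rules nest by construction:
records(2) ⊆ records(2+) ⊆ records(1+), and totals for `1+`/`2+` are
non-decreasing in the cutoff.

## Preference scales

Preferences use the distance-independent contact potential with a
quasi-chemical reference state,
P(i, c) = −ln[(N_obs(i, c) + pc) / N_exp(i, c)] with
N_exp(i, c) = x_i · x_c · N_total, in dimensionless pseudo-energy units.
Mole fractions are computed over *observed contacts*, on the partition the
class belongs to: the four single bases for G/A/C/U scales, and a fresh
two-class partition for PUR/PYR. Merged scales are therefore genuinely
independent derivations — the PYR scale need not be the negative (or any
function) of the PUR scale.

- **Gauge**: values are reported raw (no centering). Pearson correlations are
  shift/scale invariant, so downstream results are gauge-free; tests compare
  centered values wherever only the gauge differs.
- **Sparse tables**: amino acids with a zero contact margin carry no
  information and are omitted from the scale (all 20 are present for any
  realistic table). A zero observed count for a present amino acid is a hard
  error naming the (amino acid, class) cell; an explicit pseudocount
  (`pc > 0`, default 0) regularizes sparse synthetic tables and is never
  applied silently.
- The derivation round-trips: exp(−P)·N_exp reproduces N_obs to 1e-9
  relative, tables with independent margins give identically zero scales,
  and scales are invariant under uniform count multiplication.

## Cognate pairs and profiles

A cognate pair is validated by the length relation |CDS| = 3L + 3 (terminal
stop codon included), canonical alphabets only (T normalized to U), and
L ≥ window; violations are logged per identifier, never fatal. The optional
translation-consistency check verifies the CDS against the protein under the
standard code.

Per-pair profiles are codon-indexed base-class content (count/3 per codon,
stop excluded) and residue-indexed preference values, aligned 1:1. Smoothing
is a centered moving average over full windows only (output length
L − w + 1, default w = 21, odd); a "shrink" edge mode is available for
sensitivity checks but is not used in any default. Pairs whose smoothed
content or preference profile is constant are excluded from distributions
with a logged reason rather than assigned R = 0.

Because PUR and PYR content sum to 1 at every codon and smoothing is linear,
per-pair R against PUR content is exactly −R against PYR content; the suite
asserts this to 1e-12.

Codon-content scales come in two forms: usage-weighted (mean over all codon
instances in a corpus; amino acids absent from the corpus are flagged
`missing`) and standard-table (unweighted mean over each amino acid's codons
in the genetic code).

## Randomization significance

The null randomly permutes the 20 scale values over the amino acids
(independent uniform permutations; repeats possible — exhaustive enumeration
of 20! is not). Empirical p-values count strict exceedances,
p = #{|stat_shuffled| > |stat_original|}/n_shuffles, with a 1e-12 guard so a
re-drawn identity permutation (mathematically tied with the original) is
never counted through last-ulp differences between code paths. A raw p of 0
is reported as "< 1/n_shuffles". Given (seed, n_shuffles) results are
bit-reproducible; the permutation stream is generated in fixed-size chunks so
the sequence is independent of the consumer.

Profile-mode nulls avoid rebuilding sequence profiles per shuffle. For each
pair, with M the window-averaged one-hot residue matrix, C the centering
projector and y the smoothed content profile, per-shuffle correlation is
R(s) = a·s / √(sᵀQs) with a = MᵀCy/‖Cy‖ and Q = MᵀCM — algebraically
identical to the direct recomputation, which the tests verify to 1e-10.
Default n_shuffles is 1,000 in profile mode (an optional pair subsample, an
explicit approximation, is recorded in the output provenance); codon mode
defaults to 10,000 and scales to 10⁶ in chunks.

The "typical randomized scale" is the shuffle whose per-pair R mean and
standard deviation lie nearest — in Euclidean (mean, sd) distance, ties to
the first shuffle — to the average mean and average sd over all shuffles.

## Cohorts

Pairs are sorted by (R, id); the top cohort is the floor(fraction·n) most
negative-R pairs (best matching under the pseudo-energy sign convention),
the bottom cohort the most positive. The id tie-break makes membership a
pure function of the correlation table. At fraction 0.10 on a 17,083-protein
set floor gives 1,708; a published count of 1,707 for the same convention
reflects a one-off rounding ambiguity that the floor rule resolves
deterministically.

Score comparison offers two rank tests: a two-sided Mann-Whitney rank-sum of
cohort vs non-cohort scores (default — the natural unpaired test for a
subset-vs-background design) and a one-sample Wilcoxon signed-rank of cohort
scores against the background mean (provided because signed-rank tests are
sometimes reported for this design even though it is unpaired; the flag makes
the choice explicit). Cohort members without a score are reported, never
silently dropped. Rank tests are invariant under strictly monotone score
transforms.

## Synthetic data: what is emulated, and what is not

**Planted potentials.** A planted potential is built from a normalized joint
contact distribution q(i, j): margins x are the margins of q and
P* = −ln(q/(x_i·x_j)). This makes p ∝ x_i·x_j·e^(−P*) equal q exactly, so
re-deriving scales from samples converges to P* with pure multinomial noise —
an arbitrary (P*, margins) triple would only be recoverable up to row/column
gauge terms. The default random potential uses Dirichlet(100) margins and a
Gaussian log-interaction spread sigma = 0.3, giving planted preferences
spanning roughly ±0.9 (comparable to derived contact scales) while keeping
every cell populous enough that recovery error at 10⁶ sampled contacts stays
below 0.03 after per-class centering.

**Toy structures.** Minimal residues and single-atom bases placed at exact
center-of-geometry distances (3-decimal PDB precision), with backbone, sugar
and phosphate decoy atoms that the parser must strip. Geometry is not
realistic by design — only center-of-geometry distances matter to the
method. A random-structure generator produces multi-residue, multi-atom
clouds for oracle cross-checks.

**Cognate pairs with planted complementarity.** Proteins are built from
alternating blocks (default length 21, matching the smoothing window so the
planted signal survives smoothing); strength s ∈ [0, 1] simultaneously biases
block residue composition toward the planting scale's preferring/avoiding
ends (log-weight κ·s·z, κ = 1.2) and synonymous codon choice toward
high/low target-class content in anti-phase (log-weight λ·s·count, λ = 4,
near-deterministic at s = 1). At s = 0 both biases vanish: residues and
synonymous codons are uniform and the pairs are exactly null. Block phase and
starting sign are randomized per pair so that re-pairing mRNAs with
non-cognate proteins (`gen_null_pairs`, lengths preserved) genuinely destroys
the signal. κ was fixed at a moderate value deliberately: stronger
composition bias concentrates blocks on few amino acids, which makes the
shuffle null heavy-tailed without strengthening the planted signal.

Two planting scales are provided. The *default* is a seeded random vector
with the standard-table content component projected out (uniform amino-acid
weighting — exactly the s = 0 sampling measure), so strength-0 pair sets are
a genuine null for profile correlations against the scale: the genetic code
itself correlates content with composition, and an unprojected scale would
leak that correlation into "null" data. The *code-aligned* scale
(`code_aligned_scale`) is the negated standardized standard-table content —
the regime empirically derived scales occupy. The distinction matters for
significance: with a code-orthogonal scale the code caps achievable codon
content per amino acid, some scale permutations ride the code's own content
direction, and the shuffle-null p of even strongly planted sets bottoms out
around 10⁻². With the code-aligned scale the original is the optimal
alignment and 10³ shuffles produce zero exceedances.

What the generators do **not** emulate: real codon-usage bias (an optional
per-codon weight table is accepted), RNA secondary structure, protein folds,
length variation within a generated set, and the compositional
idiosyncrasies of real proteomes. Passing tests therefore demonstrate the
*correctness of the machinery* — contact counting, the reference state,
profile algebra, null calibration — not the empirical existence or size of
mRNA/protein complementarity in any real proteome, which requires the
curated structure set and proteome the pipeline is designed to consume.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: 20–50 synthetic
structures per oracle check; 10⁶ contacts × 20 replicates for potential
recovery; 200 pairs of length 300 for planted-complementarity conditions;
10³–10⁴ shuffles for nulls (10⁶ remains a parameter); 200 replicate
experiments for type-I calibration with n_shuffles = 199, chosen so the
nominal rejection threshold p < 0.05 corresponds to an exact uniform-rank
count. Tolerances: exact identities (complement antisymmetry, reference-state
null, count-scaling) at 1e-12; algebraic equivalences across code paths at
1e-9–1e-10; stochastic bounds at 3σ of the corresponding binomial or
multinomial noise. Degenerate inputs (constant profiles, empty tables,
all-excluded pair sets, sub-window proteins) raise explicit errors or are
logged exclusions, never silent zeros.

## Known limitations

- The potential is residue-level and distance-independent; no
  distance-dependent, atom-level, or solvent/secondary-structure-conditioned
  reference states.
- Contact curation (resolution cutoffs, exclusion of dsRNA/tRNA complexes)
  is upstream of this package; the manifest is taken as given.
- mmCIF input is not implemented; PDB text is the reference dialect.
- Profile-mode nulls at 10⁶ shuffles over a full proteome are computationally
  heavy even with the algebraic fast path; the subsample option trades
  exactness for time and is flagged in provenance when used.
- The synthetic complementarity construction is one concrete mechanism
  (block-structured synonymous bias); real signals need not be
  block-structured, though any smoothing-scale signal behaves equivalently
  under the window-21 analysis.
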