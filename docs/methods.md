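# Methods

This note documents the models and procedures implemented in
`genedesign`, the defaults and why they were chosen, the numerical
conventions, and the known limitations.

## Sequence model and conventions

All sequences are stored internally in the DNA alphabet; RNA input is
accepted anywhere and normalized (U→T) on entry, with the original
alphabet recorded so folding output can display RNA again. A single
canonical alphabet avoids double bookkeeping in every downstream
operation. Ambiguity codes (N, R, Y, ...) are rejected rather than
silently dropped: an unnoticed character deletion would shift the reading
frame of everything that follows.

Coordinates are 0-based half-open internally; every user-facing report
(repeat occurrences, query hits, profile rows, change logs) is 1-based
inclusive and says so. Only the standard genetic code (translation table
1) is wired in by default, but the `GeneticCode` object is injectable
everywhere.

Zero-length sequences are legal: a gene construct may contain null
(invisible) components, and the concatenation identity must still hold.

## Codon-usage statistics

**RSCU and w.** RSCU_ij = X_ij · k_i / Σ_j X_ij within each synonymous
family; w_ij = RSCU_ij / RSCU_i,max. The 0.01 floor on w is applied once,
at `AdaptivenessTable` construction, so every consumer (CAI, look-up
tables, reports) sees the same floored values — a single source of truth.
A family with zero total count in the reference set gets uniform RSCU = 1
and w = 1 with a warning: with no information, no synonymous codon can be
preferred, and a hard error would make small reference sets unusable.
Stop codons are excluded from RSCU, w and the look-up table throughout;
codon families are an amino-acid-level concept and the optimizers never
touch stops.

**CAI.** Geometric mean of w over the gene's codons, excluding stops and
the single-codon amino acids Met (ATG) and Trp (TGG) from both the sum
and the length L; they carry no choice and would only dilute the index.
A sequence with L = 0 after exclusions has no defined CAI and is
reported as an error rather than a default value.

**Nc.** Codon homozygosity F̂ = (n·Σp² − 1)/(n − 1) per amino acid;
amino acids observed fewer than twice are undefined (the denominator
vanishes) and are excluded from their class average. Class averages F̄_m
(m = 2, 3, 4, 6) feed Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. Since
isoleucine is the standard code's only 3-fold amino acid, F̄₃ rests on a
single family; when Ile occurs fewer than 5 times (threshold
configurable; 5 observations is where the single-family estimate becomes
less noisy than the cross-class reconstruction) F̄₃ is replaced by
Fuglsang's estimator

    F̄₃ = [ (2/F̄₂ − 1)⁻¹ + ((2/3)/F̄₄ + 1/3)⁻¹ + ((2/5)/F̄₆ + 3/5)⁻¹ ] / 3,

whose three terms each map the uniform-usage limit (1/m) to 1/3 and the
single-codon limit (1) to 1. The finite-sample estimator can exceed 61
(at n observations of a k-fold family, uniform usage gives
F̂ = (n/k − 1)/(n − 1) > 1/k), so the result is capped at 61, the
definitional ceiling; the cap is switchable off for diagnostic use. If
any of the 2-, 4- or 6-fold class averages is undefined (or exactly
zero, which would divide by zero), Nc is reported as undefined with the
offending class named.

**Variant-space size.** Assuming equal amino-acid frequencies, 18 of 20
residues are degenerate with an average of 3.28 synonymous codons, so an
n-residue protein admits 3.28^(0.9·n) coding variants. The count is kept
in log10 space (`VariantCount`) because it overflows doubles near
n ≈ 580.

## Moving-window profiles

Windows start at 1, 1+step, 1+2·step, ... while a full window fits
(defaults 60 nt / 10 nt). The trailing partial window is dropped by
default — mixing window sizes silently would make profile values
incomparable — with an explicit `clip_tail` opt-in. A window longer than
the sequence degrades to a single clipped window with a warning rather
than an error, so batch runs over mixed-length records keep going.

## Repeat search and the smart filter

A seed window of `min_len` bases (default 8; floor 4, below which
findings saturate on random sequence) slides over the input; each seed's
occurrence set (direct matches plus reverse-complement matches) is
jointly extended left and right to maximal length — extension stops as
soon as any occurrence disagrees on the added base. Palindromic motifs
(equal to their own reverse complement) collapse both orientations onto
one occurrence and are reportable from a single site; a lone palindromic
seed is reported unextended, since a single occurrence has nothing to
co-vary with (its maximal palindromic extension is still discovered, via
seeds pairing a direct and a reverse-complement occurrence). Tandem
repeats are flagged when occurrences abut exactly.

The smart filter removes a finding when every one of its occurrence
intervals lies inside an occurrence interval of a single longer finding.
With the filter on, the output provably matches (and is tested against)
a full enumeration over all motif lengths followed by the same
containment rule. Occurrences may overlap; overlapping matches are all
counted and reported.

Query search resolves restriction-enzyme names through a packaged table
of ~58 enzymes with unambiguous recognition sites (ambiguity codes are
out of scope, matching the sequence model); unknown names produce a
per-token error entry without aborting the remaining tokens.

## mRNA folding

The built-in engine is interval dynamic programming that minimizes a
weighted pair pseudo-energy — GC −1.0, AU −0.8, GU −0.5 (configurable),
minimum hairpin loop of 3 unpaired bases — i.e. a Nussinov-style maximum
weighted matching, deliberately *not* a thermodynamic nearest-neighbor
model. The choice buys exact testability (the engine is verified against
exhaustive enumeration of all valid structures on short sequences) and
zero external dependencies; its energies are unitless pseudo-energies
that rank structures sensibly but are not kcal/mol. Real thermodynamics
is available through the `RNAfoldEngine` adapter (ViennaRNA's `RNAfold`
subprocess) satisfying the same contract; the pipeline and the optimizers
are engine-agnostic. Traceback prefers pairing the leftmost base with
the smallest admissible partner and prefers pairing over leaving a base
unpaired on energy ties, making output deterministic as the contract
requires. Pair probabilities and suboptimal structures are out of scope;
the capability flag on the contract advertises their absence.

## Optimizers

All three optimizers share two invariants, enforced at exit: the
translated protein is bit-identical to the input's (on success *and*
failure), and a fixed seed reproduces the outcome exactly.

**Monte-Carlo codon optimization.** Expected within-family fractions are
discretized into a slot array of granularity 1000 per amino acid
(largest-remainder rounding; remainder slots go to the largest fractions
first, ties alphabetically, so construction is deterministic). Each codon
position is independently replaced by a uniformly drawn slot; sampling
frequencies therefore converge to the target fractions, which is tested
by chi-square goodness of fit.

**Silent removal.** Each target occurrence is truncated to the codons it
fully covers (falling back to the overlapping codons when a short motif
covers none — otherwise such sites would be unreachable); random
synonymous replacements drawn from the look-up table are applied inside
that region until the occurrence disappears, up to `max_attempts`
(default 100) draws per site. After every removal the entire sequence is
re-scanned, because a substitution can create a new site elsewhere;
occurrences are processed left to right. Sites admitting no synonymous
break (e.g. a motif spanning only Met/Trp codons) are reported as
irremovable with `success=False` and the sequence otherwise intact.

**Energy-range optimization.** A proposal applies k random synonymous
substitutions to the best sequence so far and is accepted if its folding
energy enters the target range or moves strictly toward it; k starts at
1 and increases by one after a stall (default 50 consecutive rejections)
— escalating the mutation count only when smaller steps stop helping.
The windowed variant processes windows left to right, mutating only
codons overlapping the current window and accepting only proposals that
do not push an already-satisfied earlier window back out of range; a
final verification pass re-folds every window, and failure lists the
offending window starts.

## Optimization pipeline

A strategy is an ordered module list (five kinds: Sequence optimization,
mRNA structure optimization, Gene manipulation, Constraint, Search
strategy — at most one of the last). Sequence-modifying modules act only
on components whose type declares `Original AA`; fixed elements
(restriction sites, spacers) pass through untouched. Constraints always
evaluate the full concatenated sequence, so sites spanning component
boundaries are caught at screening even though no optimizer would create
or remove them piecewise. Discarded candidates are retained in the output
with their verdicts and the first failing constraint named — deleting
them would destroy the audit trail the lineage model exists for. Parent
selection defaults to "always mutate the original input"; a
"best-so-far by metric" policy is available for stepwise refinement. The
component-type schema follows Coding sequence = {Original AA, Original
DNA, Modified DNA} and Non-coding sequence = {Original DNA, Modified
DNA}, with `Modified DNA` mandatory in every schema.

Batch analysis scores one row per FASTA record (CAI, Nc, GC, folding
energy), logging per-record failures in an error column rather than
aborting, with optional local process-pool parallelism that preserves
input order.

## Neural network module

A plain feedforward network with logistic activations, uniform(−0.5, 0.5)
initialization, per-sample SGD in fixed row order with optional momentum
— chosen for reproducibility, not speed. Backpropagation is verified
against central finite differences (relative error ≤ 1e-4). Trained
networks serialize to a plain-text map file using full-precision float
reprs, so save → load → predict is bit-exact.

## Synthetic data

The fixture generator draws amino acids uniformly and codons from a
usage table's within-family distribution via the same look-up table the
optimizer uses, and can plant repeats, restriction sites, or
polyadenylation motifs at chosen positions. Its default reference table
(`biased_reference_table`) weights family codons geometrically (2^r), a
clearly non-uniform pattern with a unique maximal codon per family —
qualitatively like a biased microbial reference set, but synthetic: it
reproduces no real organism's usage, carries no correlation structure
along the sequence, and uniform amino-acid composition is itself
unrealistic. Tests passing on these fixtures therefore validate the
algorithms' contracts (distributional convergence, removal completeness,
protein preservation, determinism), not host-specific design outcomes.

Test and demonstration problem sizes — 200-codon genes, 10,000-codon
resampling checks, 200-base repeat-search fixtures, ≤14-base exhaustive
folding checks — were chosen as the smallest sizes at which the
statistical assertions are well powered.

## Known limitations

- Built-in folding energies are pseudo-energies; absolute thresholds
  tuned for kcal/mol do not transfer to the built-in engine.
- Restriction sites with ambiguity codes (e.g. GGTNACC) are unsupported.
- Repeat search is O(L²) and intended for gene-scale sequences, not
  genomes.
- Nc is undefined (by design, with explanation) on short sequences where
  a degeneracy class has no observable homozygosity.
- No built-in database of organism codon-usage tables; tables are read
  from CUTG-format or codon/count TSV files supplied by the user.
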