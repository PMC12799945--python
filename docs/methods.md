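# Methods

## The biological model

Poly(A) cleavage sites are modeled by three sequence features, reflecting
the canonical architecture of 3′-end processing:

1. the cleavage base itself is an adenosine (pre-mRNA is cleaved
   immediately downstream of an A);
2. the base immediately 5′ is C or G (cleavage favors CA/GA dinucleotides,
   which position the CPSF complex);
3. a PAS hexamer lies 10–35 nt upstream. Eighteen variants are recognized;
   AATAAA and ATTAAA are canonical and dominate functional sites, the other
   sixteen collectively account for a substantial minority.

All coordinates are 0-based half-open. Within a 101-nt window the cleavage
base is index 50 (the biological "51st nucleotide"); "10–35 nt upstream"
is interpreted as the motif's **start** index s satisfying
10 ≤ 50 − s ≤ 35, i.e. s ∈ [15, 40], so the hexamer lies fully upstream of
the cleavage base. The same convention is used everywhere (scanner, dataset
rules, generator), so the modules are mutually consistent by construction.
Windows that would cross a chromosome boundary are skipped, never padded;
windows with `N` in the tested span never qualify, since the filter is
undefined over ambiguity codes.

## Candidate scanning

Every genomic position with a full window is tested on the forward strand;
the minus strand is tested by applying the identical filter to the reverse
complement of the window. A minus-strand candidate is reported at the
forward coordinate of the base complementary to the cleavage adenine, which
round-trips through BED cleanly. When several motif starts qualify, the one
closest to the cleavage base is reported (deterministic; proximal signals
dominate functionally). Stage 2 attaches a probability from any
deterministic callable `101-nt window -> [0, 1]` and applies an inclusive
threshold; raising the threshold can only shrink the candidate set.

## Dataset construction

Positives force the cleavage base to `A` even when the reference differs
(removing a trivial single-base cue and fixing the coordinate frame);
negatives require a **reference** `A` plus a canonical PAS in the band, and
their windows must not overlap any annotated site's window — overlap is
tested at the full 101-nt level, which is stricter than necessary but
prevents near-duplicate leakage. Gene-gene negatives come from gene
regions, gene-intergene negatives from the complement; both apply the same
sequence criteria, differing only in sourcing. Negative loci are sampled
uniformly without replacement from the full qualifying set (motif-first
enumeration keeps this linear in region size), seeded. Classes are
balanced by downsampling the majority, then split by rotating stratified
folds: fold i tests on chunk i, validates on chunk i+1 (mod 5), trains on
the remaining three — 60/20/20 with each split class-balanced to ±1.

## Few-shot prototype classification

Prototypes average the mean-pooled embeddings of two support examples per
class; a query's two cosine similarities pass through a softmax,
`P = exp(sim_poly) / (exp(sim_poly) + exp(sim_non))`, and `P > 0.5`
(strict) calls a positive. The published similarity expression reads
`1 − cosine(q, p)`; if `cosine` meant similarity, larger distance would
raise the class probability, contradicting the stated decision rule. The
default convention therefore reads `cosine` as cosine *distance* (so the
score is plain cosine similarity); `convention="literal"` computes the
verbatim expression for comparison. Scores are scale-invariant in the
query, always in (0, 1), and swap to 1 − P when the classes swap. The
protocol repeats the prototype draw 10 times (without replacement within a
draw, independent across draws, seeded) and reports mean accuracy,
precision, recall, F1 and AUC, with P as the AUC ranking score.

## Training mathematics

`t_total = n_epochs · ceil(n_train / batch)`; warmup is 10 % of that,
rounded half-even. The rate ramps linearly from 0 to `eta_base` (default
1e-6) over `t_warmup` steps, then follows cosine annealing
`eta_base · ½(1 + cos(π(t − T_w)/(T_t − T_w)))` to 0; the decay branch is
used at `t = T_warmup` itself (both branches agree there, so the schedule
is continuous). Probabilities are clipped to `[1e-12, 1 − 1e-12]` before
logs. Token labeling marks exactly the annotated cleavage coordinates; the
positive-class weight defaults to the empirical negative/positive ratio,
capped at 1e4 (the cap is also the fallback when an interval has no
positives). The early-stopping harness (patience 5 checks, check every 200
steps by default) is model-agnostic: it drives arbitrary train/eval
callables through the schedule and is validated with scripted metric
sequences.

## Perturbation and attention probes

Perturbation finds canonical-motif occurrences greedily left-to-right
without overlap, pooled across both motifs, and replaces each with a
uniform random hexamer with probability equal to the level. Replacements
exclude the original motif by resampling (drawing the same hexamer back
would silently lower the effective level; `allow_identity` restores the
literal uniform draw). In the multi-level curve, one uniform variate is
drawn per occurrence and compared against every level — the literal reading
of a single r per motif — which makes the perturbed sets nested across
levels and the dose-response monotone up to scorer noise. All windows count
toward N at every level; a misprediction is strictly `P < 0.5`.

Attention analysis ranks tokens by attention *received* (column mean of a
provider-supplied token×token matrix, already head-averaged — the provider
owns its aggregation), takes the top-k (default 1, exposed as a parameter),
maps them to k-mers via non-overlapping tokenization, and aggregates counts
across samples; ties break to the leftmost token.

## Evaluation

AUC uses the Mann–Whitney rank-sum formulation with midrank ties (equal to
pairwise win counting with ties worth ½; verified against a brute-force
oracle and scikit-learn). Enrichment is precision/prevalence — the fold
improvement over calling positions uniformly at random, the meaningful
summary under ~1:4500 imbalance. Overlap validation counts a prediction as
confirmed when a reference site lies within ±tol nt (inclusive) on the
same chromosome, strand-aware only when both records carry strand;
implemented by per-chromosome sorted bisection. Percentages are rounded
half-even at reporting. PFM construction excludes (and counts) N-bearing
sequences so column sums are constant; information content is 2 bits minus
the column Shannon entropy.

## The synthetic generator

The generator is the test bed's definition of "a genome like the ones this
pipeline targets": i.i.d. background at GC 0.41 (human-like; note A+G vs
T+C symmetry makes the downstream T/G fraction 0.5 in expectation
regardless of GC), one central gene region per chromosome covering half its
length, and planted sites on a spaced grid (≥110 nt apart, so 101-nt
windows never overlap) with ≥61 nt clearance from region edges. Functional
sites get the full architecture: canonical PAS (AATAAA 70 % / ATTAAA 30 %,
roughly their observed ratio), a C/G-A cleavage dinucleotide, and a
T/G-rich downstream sequence element (DSE; T 55 %, G 30 % over +5..+29) —
the element real cleavage machinery binds. Decoys carry the identical
PAS arrangement but no DSE: they pass the full Stage-1 sequence filter and
differ only in context, which is exactly what makes them hard negatives.
Defaults are 2 × 50 kb chromosomes with 40 functional + 40 decoy sites
(decoys split between genic and intergenic space so both negative regimes
are exercised); metric-level checks use 250–500 sites. All sites are
planted on the forward strand; minus-strand code paths are exercised by
scanning reverse-complemented genomes, where exact mirror symmetry is
asserted.

What the toys do and do not show: the embedder (mono-/di-nucleotide
frequencies, positional centers of mass, quarter-wise A density, 64-dim)
and the scorer (logistic in PAS presence and downstream T/G fraction) are
deterministic featurizations with no learning, and the attention provider
simply boosts canonical-PAS tokens. Passing tests therefore demonstrate
that the *pipeline machinery* — filters, protocols, metrics, probes — is
correct and self-consistent, not that any particular learned model
performs at any level on real genomes; real-data performance depends on
the plugged-in model and is out of scope here. Real-genome features the
generator does not emulate include repeat structure, isochores, chromatin
context, alternative PAS spacing distributions, and cleavage
micro-heterogeneity.

## Numerical and design choices

- Seeds: every stochastic routine takes an explicit seed or rng;
  `numpy.random.default_rng` throughout. Identical seeds give bit-identical
  genomes, splits, draws and curves.
- Tie-breaks: closest motif to cleavage (scanner); leftmost token
  (attention); strict `> 0.5` positive calls everywhere a threshold is
  stated.
- Degenerate inputs: ratios with zero denominators report `None` rather
  than raising; a zero-length decay phase returns the base rate; zero-norm
  embedding vectors are rejected rather than silently scored.
- Problem sizes in tests (10 × 100 kb scanner-oracle genomes, 1 Mb dataset
  genome, 500-site few-shot and perturbation bundles) were chosen as the
  smallest scales at which the statistical assertions are stable across
  seeds.

## Known limitations

- The pipeline never fine-tunes a genome language model; the training
  module provides the mathematics and harness only, and all model-dependent
  published quantities (fine-tuned AUCs, perturbation counts from a trained
  model) are not reproduced here.
- BED is the only annotation format; GFF users should convert.
- The scanner emits all qualifying positions, including overlapping
  candidate clusters; deduplication is left to consumers.
- Gene-intergene negatives apply the full sequence rule (A + canonical PAS);
  if one wanted A-only intergenic negatives the rule is a one-line change in
  `_negative_rule_ok`.
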