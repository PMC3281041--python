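# Methods

## The measurement model

Digital gene expression (DGE) tag sequencing quantifies a transcriptome by
counting short, restriction-anchored cDNA tags rather than full reads. In the
NlaIII/MmeI protocol, NlaIII cuts cDNA at every `CATG`; bead precipitation
retains the 3′-most fragment of each transcript; MmeI then cuts 17 bp
downstream of the anchor, releasing a 21-nt tag (`CATG` + 17 nt) that
identifies its transcript. Expression is the count of tags per gene, and a
library is characterized by its total clean-tag count. Two consequences shape
everything downstream:

- a transcript with no `CATG` site followed by ≥ 17 nt produces no tag and is
  invisible ("untaggable");
- a *physical* library samples only the 3′-most site per transcript, while an
  *observed* tag may also come from internal sites via incomplete digestion —
  so the reference index must enumerate every site even though the simulator
  emits only the 3′-most.

## Pipeline stages and their assumptions

**Virtual tag index** (`tagdge.virtual_tags`). Every `CATG`+17-nt window of
every reference transcript is indexed with its owning genes; identical
sequences across genes merge into one ambiguous entry. Lookup prefers exact
matches and otherwise probes the 51 one-substitution variants of the 17-nt
variable region. The `CATG` anchor is never mismatched: it is defined by the
restriction chemistry, and a read with a corrupted anchor would not have been
recognized as a tag. Site ranks count from the 3′ end (1 = 3′-most).

**Cleaning** (`tagdge.cleaning`). Filter order: adaptor-only records →
N-containing reads → copy-number-1 tags, with singleton status judged on the
sequences remaining after the first two removals (singletons are judged on
sequences, not artifacts; the order is explicit because it is not uniquely
determined by convention). Reads of the wrong length or anchor go to a
malformed bucket rather than being silently dropped; the five buckets sum
exactly to the raw total, and this conservation is asserted on every run.
Percentages are rounded half-up to two decimals wherever reported;
zero-denominator ratios are reported as undefined (`NA`), never as 0.

**Mapping** (`tagdge.mapping`). Categories partition the clean library:
gene-mapped (with the unambiguous subset), genome-mapped, unknown. Precedence
is gene > genome > unknown — a tag hitting both a gene tag and a genome
21-mer counts as gene-mapped. Ambiguity is judged only within the best
distance stratum, so an exact unique hit is never demoted because a
one-mismatch neighbor exists in another gene; hits to several sites of the
same gene count once. Genome mapping is membership (≤ 1 mismatch) in a
21-mer set built from genome FASTA; by default only tags that hit no gene are
tested against it (`genome_mode="remainder"`), with an overlapping-count mode
selectable, since published category tables are ambiguous about which
convention they use.

**Expression** (`tagdge.expression`). TPM_g = copies_g × 10⁶ / clean_total
with the *full* clean-tag total as denominator (not the unambiguous-mapped
total), configurable. No gene-length correction is applied: the protocol
yields one tag per transcript copy regardless of length. Copy-number
distributions default to bins [2,5), [5,10), [10,20), [20,50), [50,100),
≥100 on both the total-copy and distinct-tag bases. Saturation curves
subsample tag copies without replacement (multivariate hypergeometric over
the distinct-tag copy vector), re-map, and average 3 seeded replicates per
grid size.

**Differential expression** (`tagdge.differential`). For counts x (library
size N₁) and y (size N₂) the conditional law of y given x under equal
expression is

    p(y|x) = (N₂/N₁)^y (x+y)! / ( x! y! (1+N₂/N₁)^(x+y+1) ),

a negative-binomial mass with x+1 successes and success probability
N₁/(N₁+N₂). Tails are therefore regularized incomplete beta functions
(`scipy.special.betainc`), stable and vectorized for counts up to millions;
the two-sided p doubles the smaller tail, capped at 1. The test conditions on
the first library's count and is consequently only *asymptotically* symmetric
under exchanging the libraries (the point mass is exactly symmetric when
N₁ = N₂); the log₂ ratio negates exactly under exchange, and decisive calls
flip. Significance: Benjamini–Hochberg q < 0.001 (default) or raw p ≤ 0.001
(`sig_mode="p"`), both combined with |log₂ ratio| ≥ 1; both modes exist
because both threshold conventions circulate for this test. Ratios use the
normalized proportions (equivalent to a TPM ratio), oriented later-stage over
earlier-stage, with pseudocount 0.5 applied only when a count is zero — the
exact test itself handles zeros natively and uses raw counts.

**Enrichment** (`tagdge.enrichment`). Background N = genes with ≥ 1
annotation (not all detected genes; configurable by supplying a different
universe). Upper tail includes the observed overlap m. The correction method
is BH by default with Bonferroni selectable, and the significance threshold
is corrected p < 0.05. DE genes without annotation are dropped with a logged
warning rather than an error.

**Validation arithmetic** (`tagdge.validation`). ΔCT = CT_target −
CT_reference per sample; ΔΔCT subtracts the *control-group mean* ΔCT (a group
mean generalizes the single-control formulation to n > 1); fold = 2^−ΔΔCT.
Knockdown strength is 100 × mean(treatment)/mean(control) with an
equal-variance Student's t-test by default (Welch selectable). Both are
invariant to the transformations they should be invariant to (global CT
shifts; positive rescaling of both groups), and the tests assert this.

## The simulator and what it does (not) emulate

`tagdge.simulate` emulates the protocol end to end with complete per-tag
provenance, at desk scale. Defaults (the study conditions of the package's
own experiments): 2000 genes of 300–2000 nt at GC 0.40, three stage
libraries, 5×10⁵ tags per library, 10% DE genes at 4-fold (direction
up/down with equal probability, applied from the second stage onward),
per-base substitution rate 0.01 on the 17-nt variable region, 1% adaptor-only
and 0.5% N-containing reads. Baseline expression is exponential
(Gamma shape 1), giving the long-tailed abundance spectrum tag libraries
show; abundances are normalized per library. Sample sizes in the package's
experiments (depth 5×10⁵, 2000 genes; 10⁵-tag libraries for the conservation
and saturation checks) keep every experiment in seconds while leaving
hundreds of expected copies per gene — the regime where the exact count test
is informative.

Choices worth making explicit:

- Source genes are sampled among *taggable* genes with renormalized
  abundance, so each of the `depth` draws yields exactly one record and
  provenance conservation is exact. An untaggable-transcript dropout channel
  would only shrink the effective depth without exercising anything new.
- Errors apply only to the 17-nt variable region (an anchor-corrupted read
  would not be a tag); the per-read error count is drawn from
  Binomial(17, e) conditioned on ≥ 1 for reads selected as erroneous — the
  exact conditional law of independent per-base errors.
- Singletons are emergent (error variants or genuinely rare tags), not
  injected: copy-number-1 filtering is meaningful only if singletons arise
  the way the protocol produces them.
- Tags are sense-strand only (oligo-dT capture makes the protocol
  strand-specific).
- Not modeled: PCR amplification or GC bias, indels, quality-score
  structure, paired ends, incomplete digestion (the simulator emits 3′-most
  tags only). Passing tests therefore demonstrate correctness of the
  *analysis* under a clean protocol model, not robustness to those real-data
  artifacts.

One consequence visible in simulated data: when DE is not perfectly balanced,
per-library normalization shifts every null gene's relative abundance
slightly, so raw null p-values exceed their nominal level in DE-containing
designs (composition bias); the fold-change filter absorbs this. Type-I
calibration is therefore checked on all-null designs.

## Numerical choices

- Count-test tails via `betainc` rather than explicit log-sum loops: exact
  tails in O(1) per gene, vectorized; the unit and acceptance tests pin them
  against exact `Fraction` summation to < 10⁻⁹ relative error.
- p-values are floored at the smallest positive float before BH so that
  underflowed zeros never violate the (0,1] domain.
- BH is the plain step-up with stable sorting; cross-checked against
  statsmodels.
- Percentages use decimal half-up rounding (matching how such tables are
  conventionally printed), not float banker's rounding.
- Eligibility for the sensitivity figure: taggable DE genes whose *mean*
  expected tag count across the two compared libraries is ≥ 20 — below
  that, a 4-fold change is not reliably resolvable at FDR 0.001 by any exact
  two-library test.
- Reference text note: the protocol literature occasionally prints the anchor
  as "CAGT"; this package treats the anchor as `CATG` throughout, consistent
  with the NlaIII recognition site.

## Known limitations

- One-mismatch lookup is exact-neighborhood based (51 probes per tag); it
  does not scale to mismatch tolerances beyond 1, which the method does not
  use anyway.
- The genome side is a k-mer membership check, not an aligner; coordinates
  are out of scope.
- Multi-library designs are handled as all pairwise two-library comparisons;
  there is no dispersion modeling (negative-binomial GLMs and friends are a
  different method family).
- Enrichment treats terms as flat labels: no GO DAG propagation or ancestry.
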