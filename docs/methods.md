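# Methods

## Scope and model

spongenet infers competing-endogenous-RNA (ceRNA) relationships from
two-group (control "NHS" vs heat-stressed "HS") abundance matrices of
three RNA classes. The inference itself is deliberately simple and fully
specified: differential-expression gating, two correlation filters, and a
hypergeometric sharing test, each with a strict published cutoff
(|log₂FC| > 1, FDR < 0.05, SCC < −0.7, PCC > 0.9, p < 0.05). The package's
job is to implement those rules exactly and make them testable; it does
not attempt negative-binomial DE modelling or sequence-based target
prediction.

## Differential expression

Fold change is log₂((mean_HS + c)/(mean_NHS + c)) with pseudocount
c = 1 FPKM (configurable). HS is the numerator, so "up-regulated" means
higher under heat stress. The per-transcript test is a two-sided Welch
*t*-test on log₂(x + 1). This is a documented substitute for count-based
DE tools (DESeq2/edgeR): those require integer counts and dispersion
estimation that FPKM-like inputs don't support, and the downstream ceRNA
logic consumes only the threshold decisions, not the p-values themselves.
Degenerate transcripts (zero variance in both groups) get p = 1 when group
means agree and p = 0 otherwise — the variance→0 limits of the statistic.
BH adjustment (statsmodels' step-up implementation behind a validating
wrapper) is applied per matrix, i.e. the multiple-testing family is one
RNA class in one tissue, matching a tissue-by-tissue analysis. A raw-p
mode (`use_raw_p`) replaces FDR with the unadjusted p in the threshold for
volcano-style calls.

## The three ceRNA filters

Filters run in order and only over DE transcripts:

1. An annotated miRNA→target pair survives iff both members are DE and
   Spearman SCC < −0.7 (mid-ranks for ties; a constant vector has no
   defined rank correlation and is excluded rather than scored 0).
2. A (lncRNA, mRNA) pair is a candidate iff Pearson PCC > 0.9 and at least
   one miRNA is connected to both by surviving negative pairs.
3. The shared count k is tested against the upper-tail hypergeometric law
   P(X ≥ k) with K = miRNAs sponging the lncRNA, n = miRNAs targeting the
   mRNA, N = the universe; edges with p < 0.05 are kept.

Correlations are computed on log₂(x + 1)-transformed abundances. FPKM-like
data are approximately log-normal; on the raw scale the product-moment
correlation of two strongly coupled transcripts is attenuated by skew
(heaviest samples dominate), which defeats a fixed PCC > 0.9 rule.
Spearman is invariant to the transform, so only the Pearson filter is
affected.

K, n and k are counted **after** the negative-correlation filter
(`count_mode="postfilter"`, default): the test asks whether the *surviving*
shared sponges are more than expected, which is the only population in
which "common miRNA sponges" exist. A `"prefilter"` mode (counts straight
from the annotation restricted to DE miRNAs) is available for sensitivity
analysis.

The universe N is configurable (`universe_policy`): `"de_targets"`
(default) counts distinct DE miRNAs present in the target annotation —
the miRNAs actually eligible to be shared; `"table"` counts all annotated
miRNAs; `"matrix"` counts all profiled miRNAs. A structural consequence of
the strict p < α rule: a pair sharing its only sponged miRNA
(k = K = n = 1) has p = 1/N, so no singleton-sharing edge can ever be
significant unless N > 1/α (N > 20 at α = 0.05). Study designs (and
simulator defaults) must provide a universe comfortably above that bound,
as any real miRNA catalog does.

No correction is applied across sponge pairs by default (the rule is raw
p < 0.05); BH across pairs can be switched on (`adjust_sponge_p=True`).

Sub-network extraction keeps the sponge edges whose mRNA belongs to a gene
set (pathway membership, GMT input) plus their supporting miRNA edges —
the "ceRNA network of pathway X" view. Over-representation of a hit list
in gene sets reuses the same hypergeometric upper tail with BH across
sets.

### Numerical notes

The hypergeometric tail is computed with exact integer combinatorics
(`math.comb`), a single float division at the end; it agrees with full
draw enumeration to < 1e-12 for every feasible (k, K, n, N) and with
scipy's survival function to 1e-9 relative at large N. Correlation uses
scipy's `spearmanr`/`pearsonr`; vectors shorter than 3 are rejected.

## The planted-truth simulator

The simulator generates, per tissue, log₂-scale values (sample s,
h(s) = 1 for HS):

- miRNA i: m_i(s) = μ_i + δ_i·h(s) + u_i(s), u ~ N(0, signal_sd²);
  observed value m_i(s) + ε, ε ~ N(0, noise_sd²).
- coupled target t of i (triplet members): x_t(s) = μ_t − β·z_i(s) + d_t·h(s) + ε,
  where z_i is the within-matrix standardization of m_i and β = `coupling_beta`.
- uncoupled transcript: x_t(s) = μ_t + δ_t·h(s) + ε.

Abundances are emitted as 2^x, hence strictly positive. Baselines
μ ~ N(6, 1²) in log₂ FPKM emulate transcripts that survived the usual
low-abundance filtering of a DE pipeline; planting effects on transcripts
near zero abundance would only measure pseudocount attenuation, not the
inference.

Two deliberate design choices:

- **signal_sd (default 0.8)** is the latent per-sample miRNA activity SD —
  the biological signal that sponge coupling propagates — and is separate
  from the measurement noise `noise_sd` (default 0.3). It must exist:
  with no latent variation the standardization z is undefined and no
  coupling is possible. 0.8 was chosen by power analysis: large enough
  that a planted coupling at β = 1.5 yields |correlations| ≈ 0.96 (well
  past the 0.7/0.9 cutoffs at n = 10 + 10), small enough that a Welch
  test detects a 2-unit log₂ group shift in a miRNA with power ≈ 0.99.
- **Group-shift compensation.** A coupled target inherits a group shift
  through the miRNA channel (−β·Δz ≈ 2 log₂ units at the defaults) in
  addition to any direct shift. The direct term d_t is set so the *total*
  realized group shift equals the planted true log₂FC — otherwise planted
  effect sizes would be uninterpretable. When neither the target nor its
  miRNA carries a group effect the compensation is skipped entirely,
  preserving the exact zero-noise limit: with noise_sd = 0 and no group
  effects every planted miRNA-target pair attains SCC = −1 and every
  lncRNA–mRNA pair PCC = +1 exactly.

Triplet members are always marked DE (the network filters require it),
with the lncRNA/mRNA shifted opposite to their miRNA; beyond that,
⌊de_fraction·n⌋ transcripts per class are DE with random sign at
±`lfc_magnitude`. Decoy miRNA→target annotations (default 200) are drawn
uniformly and receive *no* expression coupling, so the correlation filters
have realistic material to reject. Defaults are n = 10 per group (3 + 3,
as small animal studies use, is supported but leaves correlation
thresholds severely underpowered), 150/100/150 lnc/mir/mRNA, 20 triplets.

Determinism: all randomness flows from `SimulationParams.seed` through
`numpy` SeedSequences; identical parameters give byte-identical output
files.

### What the simulator does not emulate

Read-level artifacts (library size, gene length bias, zero inflation),
count noise (values are log-normal, not negative-binomial), correlated
decoys (real miRNA families share targets), inter-tissue correlation, and
many-to-many triplet overlap (each planted lncRNA/mRNA belongs to one
triplet). Passing recovery tests therefore demonstrates correctness of the
inference logic under its own assumptions, not performance on real
sequencing data.

## Verification conditions

- *Zero-noise exactness*: noise_sd = 0, signal_sd = 0.5, de_fraction = 0
  (planted triplet members are then the only DE transcripts), 5 triplets,
  ≥ 50 decoys, universe_policy = "table". Expected outcome: the network is
  exactly the planted edge set. de_fraction = 0 isolates the filters from
  DE-calling noise; the "table" universe is used because with only five DE
  miRNAs the default DE-restricted universe is degenerate (N = 5 ⇒
  p = 0.2 for singleton sharing — the N > 1/α bound above).
- *Stochastic recovery*: defaults (n = 10/group, β = 1.5, noise 0.3,
  20 triplets, 200 decoys); expected precision/recall ≥ 0.8 on sponge
  edges and sensitivity/specificity ≥ 0.9 on DE calls at any seed.

## lncRNA identification and positional classes

lncRNAs are the intersection of two upstream non-coding call sets (the
scoring tools themselves are out of scope) with spliced length ≥ 200 nt —
the standard lncRNA length convention, configurable. Classification
against a reference GTF uses a fixed cascade (1-based inclusive
coordinates, overlap = ≥ 1 shared base): no gene-span overlap →
intergenic; exon overlap on the opposite / same strand → antisense_exonic
/ sense_overlapping (antisense checked first); otherwise fully inside an
intron → intronic_sense / intronic_antisense by strand. A transcript that
overlaps a gene span without touching an exon but straddles the gene
boundary is not fully intronic; it takes the exonic-overlap class of its
strand relation, on the rationale that locus overlap outranks intronic
containment. Transcripts on chromosomes absent from the annotation are
intergenic by definition (logged). Divergent/bidirectional promoter
lncRNAs are not a separate category.

## qPCR and environment utilities

`ddct_relative_expression` implements 2^−ΔΔCt: ΔCt = Ct_target −
Ct_reference, ΔΔCt relative to the mean ΔCt of the calibrator group
(default NHS), so the calibrator's geometric mean is exactly 1.
`compute_thi` implements the NRC-style cattle heat-stress index; RH is a
*fraction* in [0, 1] — the percent form printed in husbandry tables must
be divided by 100, and the function rejects values above 1 to make the
convention unmissable (the CLI accepts `--percent`).

## Known limitations

- The Welch substitute changes p-values relative to count-based DE tools;
  only the thresholded decisions are comparable.
- With n = 3 per group (the minimal animal-study design) |SCC| > 0.7 is
  frequently achieved by chance; the package runs at any n ≥ 2 but the
  thresholds carry little evidence below n ≈ 10.
- The hypergeometric test conditions on the post-filter counts; K, n and
  N are themselves noisy at small universes.
- Edge attributes store shared miRNAs as a semicolon-joined string (a
  GraphML-portable encoding), which callers must split.
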