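# Methods

## The problem

In a mutation-accumulation experiment, replicate bacterial lineages fix
thousands of base-pair substitutions (BPSs) under a strongly biased
mutational process (for example UV mutagenesis, which is dominated by
GC→AT transitions). To ask whether selection shaped which substitutions
fixed — in particular whether highly expressed genes are under stronger
purifying selection (the E–R anticorrelation) — raw per-gene substitution
counts are useless: genes differ in length, in codon usage, and hence in
how many of the mutations a biased spectrum offers them are synonymous.
`codonsel` implements the codon-level normalization machinery that makes
such counts comparable, plus the statistics built on it.

## Substitution classes and the mutational spectrum

On double-stranded DNA the 12 ordered single-base changes collapse into 6
strand-symmetric classes, in the fixed order

```
AT→TA, GC→CG, AT→GC, AT→CG, GC→AT, GC→TA
```

(e.g. AT→GC = {A→G, T→C}). A mutational spectrum `P(sub_j)` is a
probability vector over these classes. `estimate_spectrum` normalizes
observed class counts, conventionally taken from synonymous BPSs because
they are closest to selectively neutral.

**Caveat (estimator bias).** The class distribution *among synonymous
substitutions* is not the mutational spectrum: it is tilted by opportunity,
`q_j ∝ P_j · syn_j/tot_j`, where `syn_j/tot_j` is the genome's synonymy
fraction for class j. Classes rich in synonymous outcomes (third-position
transitions, for instance) are over-represented. Feeding the raw synonymous
class counts into the `P_S` formula below therefore inflates `P_S` and,
under our default UV-like spectrum, biases neutral genome-wide dN/dS upward
by roughly 14%. The package keeps the raw-count estimator because it is the
field's convention, but `rates_table`, `lineage_ratios` and
`genome_wide_ratio` all accept an explicit spectrum; when the true spectrum
is known (simulations; independent mutation-rate assays) it should be
passed in. The acceptance calibration uses the known generating spectrum
for exactly this reason.

## P_S: the probability a substitution is synonymous

For gene *i* with codon usage `P(cod_k,i)` and class-j triplet counts
`n(sub_j|cod_k)` (number of positions in codon k carrying a base of class
j's source pair; each yields one mutant triplet) and `n(S|sub_j∩cod_k)`
(how many of those mutant triplets are synonymous),

```
P(cod_k,i|sub_j) = P(cod_k,i)·n(sub_j|cod_k) / Σ_x P(cod_x,i)·n(sub_j|cod_x)
P_S,i = Σ_j P(sub_j) Σ_k P(cod_k,i|sub_j) · n(S|sub_j∩cod_k)/n(sub_j|cod_k)
```

which reduces to the spectrum-weighted fraction of synonymous class-j
events among all class-j events the gene offers. `prob_synonymous` is
verified against exhaustive enumeration of all `L×3` single-base changes
to 1e-12.

Degenerate inputs: a class with zero opportunity in a gene (no base of its
source pair) contributes 0 without renormalizing the spectrum — the formula
taken literally; `renormalize_infeasible=True` renormalizes over feasible
classes instead. Stop-gaining changes count as nonsynonymous (substitutions
are dichotomized as synonymous/nonsynonymous only). Ambiguous bases (N) in
a CDS reject the gene rather than guessing. All codon frequencies and
annotations use the *ancestral* sequence throughout; multi-hit codons are
annotated independently per BPS and logged.

## dN/dS for de novo evolution

Opportunity sites are `L_i·P_S,i` (synonymous) and `L_i·(1−P_S,i)`
(nonsynonymous). Then

```
dN_novo = M_N / (L·(1−P_S)),  dS_novo = M_S / (L·P_S)
```

per gene, and genome-wide `(ΣM_N/ΣL(1−P_S)) / (ΣM_S/ΣL·P_S)`. Counts are
pooled over lineages by default; `lineage_ratios` gives per-replicate
values. The construction is pinned by its calibration property: under
neutral accumulation from any spectrum, genome-wide dN/dS → 1 (tested at
6×20,000 BPSs, satisfied within 3 Monte-Carlo SE per lineage). No
multiple-hit (Jukes–Cantor) correction is applied — substitution counts per
site are far below saturation in this regime — and no tree-based rates are
computed; externally computed rate tables can enter the association stage
via a plain gene-keyed join.

## G scores

To screen genes with few counts, observed counts are compared to neutral
expectations anchored on the genome-wide synonymous total:

```
E_S,i = L_i·P_S,i/⟨P_S⟩ · ΣM_S/ΣL,   E_N,i = (1−P_S,i)/P_S,i · E_S,i
G_S,i = M_S,i/(L_i·P_S,i) · ln(M_S,i/E_S,i)
G_N,i = M_N,i/(L_i·(1−P_S,i)) · ln(M_N,i/E_N,i)
```

`⟨P_S⟩` is the unweighted mean over genes (a length-weighted switch is
provided). The expectation is deliberately *not* count-conserving
(`ΣE_S ≠ ΣM_S` in heterogeneous genomes), and `E_N` inherits the neutral
assumption from the synonymous anchor. `G = 0` at `M = 0` by the
`x·ln x → 0` limit; the sign of G equals the sign of `M − E`. Genes with
`P_S = 0` are excluded with a warning.

## CAI

Relative adaptiveness `w = f/max f` within each synonymous family, with
codon frequencies `f` pooled over the 40 most-expressed genes (ranked by
the mean of quantile-normalized expression; ties at the boundary broken by
gene id and logged). Sense codons absent from the reference get 0.5
pseudocounts so every `ln w` is finite (required by the C score). CAI is
the geometric mean of `w` over a gene's codons.

**Caveat (reference inflation).** Reference genes score high CAI partly by
construction — their own codons define `w`. With 40 reference genes in a
genome of hundreds this induces a noticeable spurious CAI–expression
correlation even without any real coupling; at genomic scale (40 of
several thousand genes) it is negligible. Tests of the null coupling
exclude the reference set.

## C score

For a synonymous change a→m, with `S_a` the synonymous single-step
neighbors of a and `P(a→n)` the spectrum probability of the class of the
change a→n:

```
W_a = Σ_{n∈S_a} P(a→n)·ln w_n / Σ_{n∈S_a} P(a→n)
C(a→m) = ln w_m − W_a
```

Positive C means the mutation moved the codon toward codons favored in
highly expressed genes, relative to the neutral expectation. By
construction the P-weighted mean of C over `S_a` is exactly 0 for every
codon, and `|S_a| = 1` forces C = 0; the empirical mean over neutrally
fixed synonymous BPSs is 0 within Monte-Carlo error.

## Association battery

- **Spearman** correlations (scipy) with pairwise-complete observations;
  constant vectors yield an undefined (NaN) rho with a warning.
- **Partial Spearman**: all vectors rank-transformed (average ranks), x and
  y residualized on covariate ranks plus intercept by least squares,
  Pearson correlation of residuals, t-test on `n−2−k` degrees of freedom.
  Binary confounders (essentiality, duplicability) enter as 0/1. An empty
  covariate set reduces exactly to Spearman; collinear covariates raise an
  error naming the pair. Cross-checked against pingouin's rank-based
  partial correlation.
- **Optimality classes**: among mutated genes, bottom/top `floor(f·n)` by
  CAI are unoptimized/optimized (f = 0.10 by default, 0.05 supported),
  ties broken by gene id; pairwise two-sided Mann–Whitney tests across the
  classes with Benjamini–Hochberg adjustment over the pairs, star labels
  ns >0.05, * <0.05, *** <0.001, **** <0.0001.
- **Enrichment**: hypergeometric upper tail per term against a
  user-supplied flat term map, BH q-values across terms, significance
  screen p<0.01 and q<0.05. GO-DAG ancestor roll-up is out of scope.

## Mutation filters and expression normalization

Sequencing post-filters use the literal boundary semantics: Phred quality
strictly > 100 kept; mutant-read frequency < 0.90 removed (so exactly 0.90
is kept). Filtering is order-preserving and idempotent, with per-criterion
removal counts logged. Expression matrices are quantile-normalized (columns
mapped to the row-wise mean of sorted columns; ties receive the average of
the reference values across tied ranks) and summarized by the per-gene
mean.

## The synthetic generator

`SimulationConfig` defaults define the study conditions:

| parameter | default | why |
|---|---|---|
| n_genes | 500 | enough genes for stable rank correlations at desk scale |
| mean_codons / length_log_sd | 300 / 0.25 | typical bacterial CDS length distribution |
| expression_log_sd | 1.5 (natural log) | ~3 orders of magnitude of expression, as in microarray summaries |
| usage_coupling κ | 5 | strong, realistic CAI–expression coupling (Spearman > 0.5) |
| spectrum | (0.05, 0.05, 0.20, 0.05, 0.50, 0.15) | UV-like: GC→AT dominant, AT→GC substantial; a stated config value, not a measured spectrum |
| n_lineages × n_mutations | 6 × 3000 | replicate lineages each fixing thousands of BPSs |
| s_N | 0.8 | strong expression-dependent purifying selection on nonsynonymous changes |
| s_S | 0 | codon-level synonymous selection off unless studied |

Genomes: lognormal lengths, uniform amino-acid composition, one preferred
codon per family (chosen per genome); a gene at expression percentile q
samples the preferred codon with weight `exp(κ·q)` against 1. Expression is
observed as a small lognormal-noise sample matrix and summarized through
the same quantile-normalization path the analysis uses. Confounders
(dispensability, essentiality, duplicability, PPI degree) are generated
with plausible expression dependence.

Mutations: each proposal draws a class from the spectrum and a target site
uniformly among the genome's bases of that class's source pair;
nonsynonymous proposals are purged with probability `s_N·q(gene)`;
synonymous proposals, when `s_S > 0`, with probability
`min(1, s_S·scale·max(0, −C))`. Proposals are applied to the ancestral
sequence only; per lineage each site fixes at most once and
`proposed = purged + fixed` exactly. Quality/allele-frequency fields are
filled to pass the standard filters. Same (config, seed) ⇒ bit-identical
outputs.

What the generator does **not** emulate: clonal interference, hitchhiking
and drift dynamics (fixation is an i.i.d. purging filter, not a
population process), context-dependent mutation, indels, transcriptome
evolution, or gene-length/composition correlations. Passing tests
therefore validate the *estimators* under known generative conditions, not
claims about any particular organism's data.

A second-order subtlety: conditional on hitting a given codon, the class
mix of proposals is proportional to `P_j / N_pair(j)` (sites are drawn
within source-pair pools), not exactly `P_j`. For most codons all
synonymous neighbors share one source pair, so C-score neutrality is
unaffected; mixed-pair synonymous families (Leu, Arg first positions)
deviate at second order, which the 3-SE empirical check absorbs.

## Problem sizes and runtimes

The default test suite runs in about half a minute on one CPU: neutral
calibration at 6×20,000 BPSs, C-score neutrality at 2×25,000 BPSs
(≥10,000 synonymous), detection power at 20 default-config replicates per
arm (s_N = 0.8 detected with negative Spearman at p<0.05 in ≥90% of
replicates; null rejection rate within binomial error of 5%).
`scripts/acceptance.py` regenerates the neutral calibration from scratch
in a few seconds.

## Known limitations

- The syn-count spectrum estimator's opportunity bias (above) is inherited
  from the field's convention; an opportunity-corrected estimator would be
  a natural extension.
- dN/dS here is a count-ratio statistic without evolutionary-distance
  correction; it is meaningful for low per-site substitution densities.
- The minimal VCF reader covers only the plain-text single-allelic subset
  with `lineage`/`AF` INFO keys plus a gene-coordinate map.
- Partial correlation with binary covariates uses 0/1 rank coding; a
  stratified alternative is not implemented.
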