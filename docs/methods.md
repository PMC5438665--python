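# Methods

This note documents the statistical model behind `pairmir`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## The matched-pair design and the discovery test

Each individual contributes one arterial and one venous plasma sample, so
every between-compartment comparison can be made within an individual.
For miRNA *g* with per-individual log2 differences
d_i = x_{g,A_i} − x_{g,V_i}, the discovery statistic is the one-sample
*t* on d (df = n−1), two-sided, with a raw-P threshold `alpha_de` (default
0.025; no multiplicity adjustment — a BH option exists but defaults off).
The rationale for the raw threshold is that with three pairs the design
has essentially no power after FDR control over ~758 tests; instead of
adjusting per-miRNA P-values, the *count* of discoveries is calibrated
against an empirical null (below). Fold changes are reported on the linear
scale as larger-mean over smaller-mean: for log2 inputs FC = 2^|mean(d)|
(a geometric-mean ratio), with the compartment of the larger mean as the
group label; equal means yield a "tie" and are excluded from discovery
output. The consistency flag is true iff all d_i share one strict sign; a
zero difference counts as inconsistent. Degenerate rows with zero-variance
differences get t = 0, P = 1 — conservative and division-free.

Quantile normalization follows the standard construction: each column's
sorted values are replaced by the across-column mean of sorted values, and
tied values within a column receive the mean of the reference quantiles
the tie spans. The profile-level similarity of the two compartments is the
Spearman correlation between mean arterial and mean venous profiles
(a pooled per-sample variant is available by flag).

## Shuffle null for the discovery count

With n = 3 pairs a sample-label permutation test has only 2^3 = 8
arrangements, so the null for the discovery count is built by permuting
values across miRNA labels independently within each sample — each
sample's value distribution is preserved exactly while miRNA identity (and
hence any pairing structure) is destroyed — and re-running the full
discovery procedure, 100 iterations by default. Null hits are assigned to
compartments by fold-change direction exactly as in the real pipeline, and
the summary reports per-group mean and SE = sd/√n_iter. A paired-shuffle
variant (one shared permutation for all columns) is available by flag but
is not the default: it preserves within-row relationships and therefore
produces a much weaker null. On iid data the expected null count is
α·m (18.95 for α = 0.025, m = 758), which the acceptance test verifies.

## Over-representation analysis and empirical calibration

ORA is the one-sided hypergeometric upper tail: for a query of size s and
a term of size K inside a universe of size M, with overlap k, the raw P is
P(X ≥ k), X ~ Hypergeom(M, K, s). Terms are intersected with the universe
before testing. The default universe is the union of all annotation
members ("annotated universe"), configurable to the full array list.
miRNA queries are first mapped from rat to human identifiers — explicit
table entries win, otherwise the species prefix is substituted
(`rno-` → `hsa-`); unmapped ids are excluded from testing but always
reported. An optional family-collapse flag strips -5p/-3p arm suffixes for
annotation sources indexed at family level.

Gene-level (target-set) ORA uses BH-corrected significance at
`alpha_gene_bh` (default 0.05). The BH step-up is implemented directly
(and cross-checked against statsmodels in the tests) because the
random-set calibration needs it row-vectorised across thousands of
re-analyses. Redundant gene terms are removed by a best-per-parent filter:
among significant terms sharing an ontology parent only the smallest-raw-P
term (term id as tie-break) survives; terms with several parents survive
if they win any of their sibling groups; parentless terms always survive.

Every significant term is then calibrated empirically: N (default 1000)
uniform-random sets of the same size are drawn from the universe, the same
test (including BH when applicable) is re-run for each, and the term's
`random_hit_count` is how many random sets reproduce its significance.
The empirical P uses the add-one rule (c+1)/(N+1), which never reports
zero. For raw-P mode this reduces to a per-term critical overlap and is
computed by indicator-matrix multiplication; for BH mode the full P matrix
is corrected per random set.

Targets enter the analysis only if experimentally validated or supported
by at least `min_predictions` (default 3) independent predictions; the
passing targets of the arterial and venous miRNA groups are partitioned
into arterial-exclusive, venous-exclusive and shared sets, which are
analysed separately.

## Plasma–tissue correlation

Each compartment's mean profile is correlated (Spearman) with every tissue
row of a tissue × miRNA atlas over the intersection of miRNA identifiers,
with the intersection size reported; tissues are ordered by descending
rho, ties broken by tissue id. P-values use the t approximation, replaced
by an exact permutation enumeration when fewer than 10 miRNAs are shared.
Discovered miRNAs are also intersected with the atlas's per-tissue
enriched lists; miRNAs in no list are omitted from that table.

## qPCR relative quantification

Per sample, ΔCt = Ct(target) − Ct(spike-in); per individual,
ΔΔCt = ΔCt(test) − ΔCt(reference compartment); the per-individual fold is
2^−ΔΔCt and the group fold is the geometric mean (folds are log-scale
quantities). Significance is a two-sided paired t on the per-individual
ΔCt pairs — the matched design makes the paired test the defensible
default; an unpaired flag exists. Direction is the compartment with the
smaller mean ΔCt. Folds are exactly invariant to any per-sample global Ct
shift, since such shifts cancel in ΔCt.

## Sample clustering report

Samples are clustered by average-linkage agglomeration on 1 − Pearson
correlation distance (the classic expression-analysis default), computed
over a miRNA subset (the discoveries, in the pipeline). Rows constant
across samples are dropped with a warning; the report table is row-scaled
to mean 0 and unit variance. The expected signature of a matched design is
that the two samples of each individual are mutual nearest neighbours.

## The synthetic-data generator

The generator exists so that every pipeline property can be tested against
known ground truth. The log2 value of miRNA g, individual i, compartment c
is

    mu_g + a_{g,i} + (delta_g / 2) * s_c + eps,

with baseline mu_g ~ N(8, 2) (a plausible log2 microarray intensity
range), individual effect a_{g,i} ~ N(0, sigma_ind = 0.5) shared by both
samples of individual i, planted signed effect delta_g (zero for non-DE
miRNAs; s_c = ±1), and independent per-measurement noise
eps ~ N(0, sigma_eps).

**Noise calibration.** The default planted effects are 10 arterial and 14
venous fold changes in the 1.01–1.44 range, matching the discovery table
this pipeline is designed to produce. For such effects to be significant —
and sign-consistent — in three pairs, the per-pair difference noise must
be small: a (FC, P) pair observed under this design implies
sigma_d = √n·log2(FC)/t_quantile(P/2, df = n−1), and the median implied
per-sample sd across the 24 default effects is 0.009. The default
sigma_eps = 0.01 adopts this calibration. A per-sample sd of 0.05, for
comparison, gives a closed-form paired-t power of only 65% at FC 1.2
(noncentral t, df 2, ncp 6.44 vs critical value 6.21) and makes FC ≈ 1.01
discoveries impossible, contradicting the design conditions the generator
is meant to emulate.

The individual effect sigma_ind = 0.5 ≫ sigma_eps reproduces the
clustering-by-individual signature while leaving the paired test powerful
— exactly the regime the matched design exploits.

Annotation collections plant enrichment by over-sampling a designated
query set by a stated excess over the uniform expectation; tissue atlases
draw each tissue from a Gaussian copula against the plasma profile's
normal scores with latent Pearson r = 2·sin(π·rho/6), so the realized
Spearman correlation targets the requested rho (±0.1 for ≥500 miRNAs),
with a liver-like maximum (0.60) and brain-like tissues and testicle
lowest (0.27–0.32) by default; qPCR tables are constructed so the expected
2^−ΔΔCt equals the planted linear fold change, with independent
N(0, ct_noise) noise on every Ct well including the spike-in.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-level artifacts, background correction and
dye effects; heavy-tailed and intensity-dependent microarray noise;
miRNA–miRNA correlation (values are independent across miRNAs given the
individual); compartment-wide composition shifts; hemolysis and other
pre-analytical plasma artifacts. One visible consequence: the synthetic
arterial/venous profile correlation is ≈0.999, higher than the ~0.86
typical of real matched plasma profiles, because all profile-level
variance is shared by construction.

## Numerical conventions and problem sizes

- P-values are clipped to [tiny, 1]; empirical P-values never report 0 by
  the add-one rule.
- Fold-change ties (equal means) are labelled "tie" and excluded from
  discovery output.
- All stochastic stages derive their streams from one master seed via
  `numpy.random.SeedSequence`, making every pipeline run bit-reproducible.
- The test suite and the acceptance script run the statistical property
  checks at the design scale of the study (758 miRNAs × 3 pairs; 8
  individuals for qPCR) with replicate counts chosen for tight Monte-Carlo
  error at interactive runtimes: 10 × 20 shuffle-null iterations, 100
  recovery replicates, 100 clustering replicates, 2000–5000 random sets
  for calibration checks.
- The acceptance script's qPCR concordance panel takes the 3 arterial and
  2 venous planted miRNAs with the largest effects — the clearest
  confirmation candidates, as a real validation panel would prioritise;
  for near-zero planted effects direction concordance is noise-dominated
  and measures nothing about the quantification machinery.

## Known limitations

- With three pairs the paired t has df = 2; its heavy tails make
  single-miRNA P-values fragile, which is why the pipeline's inferential
  weight rests on the count-level shuffle null and the set-level empirical
  calibrations.
- The best-per-parent rule is one reasonable formalisation of redundancy
  filtering; ontology-aware alternatives (e.g. elim/weight algorithms) are
  out of scope.
- The ortholog prefix fallback assumes identifier parity between species;
  genuinely diverged families need an explicit mapping table.
- Tier-two reproduction against the deposited accession data (public
  repository download) is intentionally not part of the test surface;
  all checks run on generated data.
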