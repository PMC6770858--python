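# Methods

## Design and data model

The package targets a three-tissue bulk design — tiller primordia (TP),
stem tips (ST), young spikes (YS) — with r ≥ 2 biological replicates per
tissue (default 3). Expression is carried as a features × samples grid with
an explicit sample design (tissue, replicate) and a unit tag (`counts`,
`FPKM`, `TPM`); all values must be finite and non-negative. Sequences live
on the RNA alphabet; DNA input is accepted anywhere and T→U-normalized at
parse time, because mature-miRNA tables are conventionally printed in DNA
while duplex scoring is defined on RNA pairing. miRNA records must be
18–30 nt, the small-RNA read-validity window.

## Normalization and QC

* TPM: per sample, value·10⁶/column-total; used for miRNA counts (no length
  term — mature miRNAs are effectively equal length). Column sums are
  exactly 10⁶ up to rounding, which the tests assert.
* FPKM: count·10⁹/(length · library size), for when mRNA quantification
  starts from raw counts.
* Replicate QC: Pearson correlation over all sample pairs. A zero-variance
  sample yields NaN against every partner — flagged undefined rather than
  silently zero.

## Differential expression

Per feature, a two-sided Student's *t*-test (pooled variance) on
log₂(value+1), then Benjamini–Hochberg across all tested features of the
comparison (never per subset). Fold change is computed on the original
abundance scale, log₂((mean_b+ε)/(mean_a+ε)) with ε = 0.01 by default —
small against the FPKM > 1 validity floor, so it guards zeros without
moving reportable fold changes.

Numerical conventions: a feature constant in both groups gets p = 1 (not
NaN); groups need ≥ 2 replicates or the call errors out. Threshold
defaults follow the study design: genes |log₂FC| ≥ 1 and FDR ≤ 0.01;
miRNAs raw p ≤ 0.05 with no fold-change floor (the fold-change gate for
miRNAs arrives later, at network admission).

The pooled-variance test rather than the unpooled (Welch) variant is a
deliberate choice: at n = 3 per group the Welch–Satterthwaite approximation
is measurably conservative (null rejection ≈ 0.03 at α = 0.05 in our
simulations), while the pooled test is exact under the lognormal noise
model and holds its nominal size — which the null-calibration test
(2000-feature null, p ≤ 0.05 fraction within 0.05 ± 0.02) verifies.

No negative-binomial GLM or dispersion shrinkage is attempted; the package
documents its DE caller as exactly what it is.

## Filter rules

* **Valid gene:** abundance strictly above 1 in *every* replicate of a
  tissue; per-tissue sets plus the derived Venn counts (per-tissue
  exclusive, shared-by-all) are reported.
* **Tissue-specific:** mean in one tissue strictly greater than 2× the mean
  in *each* other tissue. Strictness makes the rule mutually exclusive: a
  feature can win for at most one tissue (if mean_t > 2·mean_u and
  mean_u > 2·mean_t, then mean_t > 4·mean_t — impossible unless zero, and
  all-zero features yield no call).

Both rules are verified against naive per-cell re-evaluation on random
fixtures.

## Co-expression clustering

Screening keeps genes with |log₂FC| ≥ 2 (inclusive) in at least one of the
three pairwise tissue comparisons — the union, since trend clustering wants
every gene with a strong contrast somewhere. Profiles are per-feature
z-scores (population sd) of log₂(tissue mean + 1) across the three tissues,
so clusters group by trend, not level; zero-variance profiles are flagged
constant and excluded.

Clustering is Lloyd's k-means (default k = 6, the number of coarse trend
shapes a three-point profile supports) with k-means++ seeding from a seeded
RNG, Euclidean distance, ties broken toward the lowest cluster index, and
an emptied cluster repaired by re-seeding it with the point farthest from
its centroid. This in-package implementation exists because the contract
demands determinism given a seed, a per-iteration inertia history
(asserted non-increasing), and guaranteed non-empty clusters;
scikit-learn's KMeans is used in the tests as an independent cross-check
(identical partition and inertia on separated data), never as the
implementation.

Per-cluster term enrichment is an upper-tail hypergeometric test
P(X ≥ k | N, K, n) over a user-supplied feature→term map with BH across
terms — a generic replacement for database-backed GO/KEGG enrichment, whose
term content is out of scope.

## Target-site scoring

The scanner slides every length-L window of the transcript against the
L-nt miRNA, pairing antiparallel: miRNA position i (1-based from the 5′
end) with site position L−i+1 (site read 5′→3′ on the sense strand,
coordinates 0-based half-open). Penalties per position: Watson–Crick 0,
G:U/U:G wobble 0.5, mismatch 1; doubled when i ∈ [2, 13] (the seed region,
bounds inclusive). A site is retained when its total is strictly below 4,
and by default only the best (minimum-score, then leftmost) site per
(miRNA, transcript) pair survives.

Choices worth noting:

* Scores are held as integer half-points internally, so the `< 4` threshold
  comparison is exact — no floating-point edge cases at 4.0.
* Whether the seed doubling applies to wobbles as well as mismatches is
  genuinely ambiguous in the penalty tradition this scheme descends from;
  it is exposed as `double_wobble_in_seed` (default True, so an in-seed G:U
  costs 1.0). All planted-budget bookkeeping honours the switch's default.
* The scan is ungapped: bulges and gaps are not modelled, since the penalty
  scheme defines no cost for them. No thermodynamic (ΔG) term and no
  conservation filter.
* The production scan is vectorized (penalty lookup table over all windows);
  tests hold it to exact equality with an independently coded per-position
  brute-force scorer on hundreds of random instances.

## Network integration

A negative miRNA–mRNA pair must satisfy all four of: (1) the miRNA is DE
with linear fold change strictly above 4, i.e. |log₂FC| > 2; (2) the gene
passes the gene DE thresholds; (3) the two log₂FCs have opposite signs;
(4) a retained duplex hit links the pair (transcript ids map to gene ids —
identity by default, or a user map). "Negative" is defined on tissue-level
DE direction, not per-sample correlation, because the integration operates
on two-tissue DE sets where three replicates per tissue give a sign, not a
stable correlation coefficient. Summaries count pairs by the gene's
direction without privileging either tissue. Transcription factors are
flagged from a user-supplied id list; no TF database is bundled.

## qPCR quantification

2^−ΔΔCT: ΔCt = Ct(target) − Ct(reference gene) within a sample,
ΔΔCt = ΔCt(sample) − ΔCt(calibrator). Technical replicates are averaged on
the Ct (cycle) scale before subtraction. No amplification-efficiency
(Pfaffl) correction.

## Synthetic data: what it emulates, and what it does not

The generator produces the full input surface — transcripts and miRNAs
(FASTA), FPKM and count matrices (TSV), annotation map, TF list — plus a
ground-truth manifest of everything planted, in TSV sections. All
randomness descends from one seed through named substreams (one per
component), so regenerating with the same seed is byte-identical and
changing one component's internals does not perturb another's draws.

Model: baseline means are lognormal (genes: log-mean log 20, sigma 1.5,
leaving a realistic low-expression tail below the FPKM > 1 validity floor;
planted features are overridden to ~80 so their effects are detectable);
tissue effects are multiplicative (a DE spec with true log₂FC f multiplies
group b by 2^(f/2) and group a by 2^(−f/2)); replicate noise is
multiplicative lognormal with sd 0.15 on the log scale (~15% CV, typical of
well-behaved bulk RNA-seq replicates). miRNA lengths follow the observed
mature-length mixture (21 nt: 43%, 24 nt: 37%, remainder uniform over
18–30). Planted target sites are the reverse complement of the miRNA with
an exact, chosen recipe of seed/non-seed mismatches and wobbles, so the
engineered penalty budget equals the scanner's reported score to the
half-point; after planting, transcripts are rescanned and backgrounds
re-randomized if a chance sub-threshold window appears.

The default dataset plants: 12 tissue-specific genes (ratio 5), 60 trend
genes across the six archetypal three-tissue shapes (|log₂FC| 4), 8
negative pairs (gene |log₂FC| 4, miRNA |log₂FC| 3.5, budgets stepping
0–3.5), and 4 decoy pairs each violating exactly one network admission
condition (same direction; gene below DE thresholds; miRNA fold change
~2.3 < 4; site budget exactly 4). Planted effect sizes sit well past the
thresholds deliberately: the features this method is built to recover are
strong tissue contrasts, and the decoy design — one violated condition
each — localizes any pipeline bug to a specific admission rule.

What the generator does *not* emulate: count overdispersion and
mean–variance coupling of real RNA-seq, read-level artifacts, mapping
ambiguity, transcript isoforms, miRNA precursor structure, or biologically
realistic sequence composition. Passing recovery tests therefore
demonstrates the correctness of the filtering, scoring, and integration
logic under the stated noise model — not the field performance of the
thresholds on real libraries.

## Problem sizes

Default generator sizes (300 genes, 40 miRNAs, transcripts 250–500 nt) are
chosen so a full pipeline run completes in about a second while every stage
still has non-trivial structure: a low-expression tail for the validity
rule, six recoverable trend families for clustering, and a scan space large
enough that chance sub-threshold sites are vanishingly rare.

## Known limitations

* The DE caller is a t-test on transformed abundances, not a count model;
  with very low counts its behaviour differs from negative-binomial
  callers.
* Tissue-specificity and negativity are defined on means/signs, so they
  inherit the noise of three-replicate means; the generator's recovery
  guarantees hold at the planted effect sizes, not near the thresholds.
* Enrichment p-values assume exchangeable features (no gene-length or
  expression bias correction).
* The scanner reports all windows at or below the reporting threshold;
  overlapping sites are resolved only by the best-per-pair rule, not
  merged.
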