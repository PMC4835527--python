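# Methods

## Model and test

At a heterozygous SNP covered by one ChIP-seq dataset, conditional on the
total depth n = G1 + G2, the reference-allele count is modelled as
G1 ~ Binomial(n, p₀) under the no-imbalance null. The two-sided p-value is
the *minimum-likelihood* sum: Σ Pr(X = k) over all k with
Pr(X = k) ≤ Pr(X = G1)·(1 + ε), ε = 1e−12. The tolerance only absorbs
floating-point ties; for a symmetric null the statistic reduces to the
doubled tail capped at 1, and the implementation agrees with an exhaustive
exact-rational enumeration to < 1e−10 for every split up to depth 30 (and
with `scipy.stats.binomtest` to machine precision). Because the test
conditions on depth, the depth distribution (negative binomial by default)
does not enter the null.

Zero-allele records (G1 = 0 or G2 = 0) are discarded before testing: a
single read on each allele is required as minimal evidence that both
alleles are assayable. No further depth cutoff is imposed — at low depth
the exact test is conservative by construction.

## CNV-adjusted nulls

Copy-number variation distorts the 1:1 expectation without any binding
difference. The null resolver assigns:

| SNP context                                   | null p₀ | verdict |
|-----------------------------------------------|---------|---------|
| outside any CNV, or 2-copy region              | 1/2     | testable |
| resolved 3-copy, duplicated haplotype carries G1 | 2/3   | testable |
| resolved 3-copy, duplicated haplotype carries G2 | 1/3   | testable |
| unresolved 3-copy                              | —       | excluded |
| ≥ 4 copies                                     | —       | excluded |
| CNV without genotyped copy number              | —       | excluded |
| copy number 0/1 (inconsistent with het call)   | —       | excluded (treated as ungenotyped) |

Overlapping CNV annotations covering one SNP with conflicting copy numbers
are a hard error rather than a silent choice.

## Multiple testing and the AS call

Benjamini–Hochberg is applied within each dataset (TF × cell line) family
by default; a global family over all pairs is selectable
(`bh_family="global"`). Per-dataset correction matches how detection is
reported per TF; since the method's own framing leaves the family open,
both modes are first-class. A SNP is an AS-SNP when q < 0.05 (strict) in
≥ 1 dataset; multiplicity across datasets is reported as
`n_supporting_datasets` but not re-corrected, and no cross-dataset
direction consistency is required.

## Region filtering

Filtering runs on the candidate AS-SNPs after testing (the funnel order),
with gap intervals widened ± 1 Mb and blacklist intervals ± 100 bp,
clamped at chromosome bounds and merged. Containment is half-open
([start, end)); a SNP at exactly `end + flank` survives. Removal
attribution is deterministic — gap, then blacklist, then CNV verdict — so
`input = output + Σ removed` holds exactly on every run and is asserted on
every synthetic bundle.

## Effects and frequency classes

The per-SNP allelic effect is max(G1, G2)/(G1 + G2) taken from the
dataset with the smallest q-value (ties broken by dataset id); selecting
the deepest dataset instead is available via `ratio_from="max_depth"`. The
aggregation to one ratio per SNP is a genuinely open design point; best-q
is the default because it uses the same dataset that drove the call.
Common vs rare groups are compared with Welch's unequal-variance t test —
the safer default when group sizes and spreads differ. A SNP is common iff
its AF is present and ≥ 0.01 (the threshold itself inclusive); absence
from the frequency reference alone classifies it rare, so "absent" is
represented as a missing entry, never as AF = 0.

## LD and enrichment

Proxies are attached to catalog index SNPs at r² strictly > 0.8 (a planted
link at exactly 0.80 must not survive; one at 0.81 must). r² can be taken
from a supplied proxy table or computed from phased haplotypes as
D²/(pA pa pB pb). Index hits are grouped into loci by single-linkage
chaining of positions within 1 Mb per (trait, chromosome) — the simplest
rule consistent with "within 1 Mb", and the window is a parameter.
Permutation enrichment redraws |AS| SNPs from the non-AS heterozygous pool
without replacement (optionally within AF deciles), and reports
fold = observed/mean(null) and the add-one empirical p
(1 + #{null ≥ obs})/(1 + N), which can never be zero. All permutations are
reproducible under the supplied seed.

## Heterozygote-discovery power

Under HWE a variant with AF p is heterozygous in one person with
probability 2p(1−p); in ≥ 1 of n unrelated people, 1 − (1 − 2p(1−p))ⁿ.
Averaged over a uniform AF density the covered fraction is
1 − Σₖ C(n,k)(−2)ᵏ (k!)²/(2k+1)!, evaluated in exact rational arithmetic
and cross-checked against adaptive quadrature to ≤ 1e−9 for n ≤ 50. The
uniform measure is the one that reproduces the 1/3, 66 %, 79 %, 90 %
sequence for n = 1, 3, 5, 10; other AF densities can be integrated
numerically from `prob_any_het`. Report rounding is half-away-from-zero to
integer percent (0.875 → 88).

## The synthetic-data generator

The generator emulates, per cell line: uniform unique SNP placement on a
configurable toy genome; allele frequencies with a rare (AF < 1 %)
fraction of 0.14 by default, matching the heterozygous-SNP background;
rare AFs missing from the frequency table with probability 0.5 to exercise
the "absent ⇒ rare" branch; overdispersed depths (negative binomial, mean
30, dispersion 5 — ChIP-seq-like; Poisson selectable for analytic checks);
binomial allelic counts at a true G1 fraction θ (exactly 0.5 for non-AS
SNPs); non-overlapping CNV, gap and blacklist geometry; and catalogs with
planted proxy links above the r² threshold plus decoys below it.

AS-SNPs draw |θ − 0.5| uniformly from [0.10, 0.25] (common) or
[0.20, 0.45] (rare) with random sign; the rare range stochastically
dominates, encoding the larger regulatory effect of rare variants, and
0.1 of SNPs are AS by default — large enough to yield a few hundred
positives at desk scale. Inside a CNV the realised read fraction is
rescaled by haplotype copy numbers, θ_eff = c₁θ/(c₁θ + c₂(1−θ)), so a
balanced SNP in a resolved 3-copy region sits exactly at 2/3 or 1/3.
SNPs in unresolved or high-copy regions still receive counts — excluding
them is the pipeline's job — with the simulator privately choosing the
haplotype split. Reference bias is off by default (θ multiplier 1.0),
reflecting well-controlled allele-aware alignment; a multiplier is exposed
for robustness experiments.

What the generator does **not** emulate: read-level artifacts
(mappability, PCR duplicates, allele-aware alignment errors), spatial
clustering of binding sites, realistic LD from population history
(proxy links are planted, not simulated from haplotypes), or beta-binomial
overdispersion of the allelic fraction itself. Passing tests therefore
demonstrate correctness of the statistics and plumbing under the stated
generative model, not robustness to every artifact of real ChIP-seq data.

Determinism: each generation stage uses its own `default_rng([seed, k])`
stream, so identical configs give byte-identical bundles (asserted via
SHA-256 manifests) and stages remain individually reproducible.

## Numerical and degenerate-input choices

* p-value tie tolerance 1e−12 (relative); pmf vectors cached per
  (depth, null) pair, making ~10⁶ tests a few seconds of work.
* BH on an empty vector returns an empty vector; a single p is its own q.
* Welch comparison refuses groups of < 2 ratios or two zero-variance
  groups instead of returning NaN.
* r² is a hard error at monomorphic sites.
* Chi-square sharing comparison drops multiplicity columns empty in both
  universes; a single surviving column yields χ² = 0, p = 1.
* Region placement in the generator is rejection sampling with a
  1000-attempt cap and a hard error on failure — never silent truncation.
* Simulated θ is clipped to [1e−6, 1 − 1e−6] so degenerate
  fully-monoallelic fractions remain representable without 0/0.

## Problem sizes

Desk-scale defaults are 500–2500 SNPs × 3–5 datasets per bundle; the
null-calibration and rare-effect studies use 100 seeded replicates of
10⁴ and 3×10³ SNP–dataset pairs respectively, and enrichment uses 10⁴
permutations. These sizes give Monte-Carlo errors comfortably inside the
asserted bounds while keeping the whole suite fast.

## Known limitations

* No beta-binomial model for biological overdispersion of allelic
  fractions; the binomial null is the method's stated model.
* No read realignment or allele-aware bias correction — counts are taken
  as given.
* Indels and multiallelic sites are skipped at VCF input; the analysis is
  SNV-only.
* ChromHMM-style chromatin-state annotation and catalog retrieval are out
  of scope; catalogs, proxies and target interval sets are user-supplied.
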