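# Methods

This note documents the models and algorithms behind `strainpair`, the
parameter choices that matter, and what the synthetic benchmarks do and do
not demonstrate. Coordinates are 0-based half-open everywhere internally;
only the GFF3, VCF and AGP writers emit 1-based coordinates.

## Synthetic two-strain genomes

**Ancestor.** Chromosomes are i.i.d. draws over {A,C,G,T} at a requested GC
fraction (default 0.36, the AT-rich composition typical of lepidopteran
genomes). Sequences below 1 kb are rejected; realized GC converges to the
request by the law of large numbers (±2 percentage points is already
guaranteed at 100 kb).

**Divergence.** Two strain genomes, C and R, evolve independently from the
ancestor. Each branch receives substitutions at `snp_rate/2` per site (so
the expected aligned divergence between strains equals `snp_rate`,
default 0.005) and small 1–10 bp indels at `small_indel_rate/2` per site
(default 2×10⁻⁴ total). Structural events are planted on exactly one branch
each, drawn from five classes — insertion of novel sequence, deletion,
tandem duplication (adjacent copies, default 2), inversion, transposition
(cut-and-paste, moved ≥ 5 kb) — with non-overlapping placements separated
by a 500 bp pad so events remain individually scorable. Sizes default to
uniform 500–2,000 bp and are configurable per class; real SV length
distributions are not claimed.

Every event is recorded in a `TruthSet` in the coordinate frame of the
strain carrying its footprint (deletions in the frame of the strain that
*kept* the sequence), with the homologous partner interval in the other
strain where one exists. This makes recovery scoring exact: planted
segments verify against sequence content (duplication copies identical,
inversions reverse-complement their partner, etc.) in the unit tests.

**Collapsed-duplication decoys.** A decoy plants a tandem duplication in
both real genomes but collapses one strain's *assembly* to a single copy.
Alignment then sees a spurious copy-number difference; only read depth can
reject it (the collapsed copy carries ~2× depth). Decoys exist to prove the
depth-validation rules do real work.

**Depth tracks.** Windowed (100 bp) expected depth is `mean_depth`
(default 30×) times the copy-number ratio implied by truth: 0 over
assembly-specific sequence when mapping the other strain's reads, 1/k per
copy over a k-copy duplication mapped by the single-copy strain's reads, k
over a collapsed copy. Gaussian noise with σ = `noise_sd · √ratio`
(default 2) is added and depths clip at zero. Read-level simulation
(mapping ambiguity, GC bias, insert sizes) is deliberately out of scope, so
depth validation is tested against idealized but correctly copy-number-
scaled coverage.

**Populations.** Nuclear sites follow a Balding–Nichols model: ancestral
frequency ~ U(0.05, 0.95); per-population frequencies ~
Beta(p(1−F)/F, (1−p)(1−F)/F) with F the differentiation target; diploid
genotypes ~ Binomial(2, p_pop). This gives the Weir–Cockerham estimator a
closed-form target: the benchmark shows the mean estimate lands within
±0.02 of F ∈ {0, 0.02, 0.1, 0.3} at 9+9 diploids × 10,000 sites. Sites are
unlinked; linkage and demography beyond the two-population split are not
modelled. An optional mtDNA-like locus is haploid (written as homozygous
diploid genotypes) with a configurable count of fixed differences plus
shared polymorphism, reproducing the characteristic
mtDNA-Fst ≫ nuclear-Fst contrast.

**Genes.** Single-exon gene models (300–1,500 bp, multiple of 3) are placed
uniformly without overlap. Inside SV intervals the odds of the designated
category are multiplied by `sv_enrichment_factor`, so the expected in/out
odds ratio equals the factor exactly — the natural null/power dial for the
enrichment stage.

## Whole-genome alignment (anchors → chains → nets)

Anchors are maximal merged runs of exact k-mer matches (k = 21, odd so a
k-mer cannot be its own reverse complement) that occur at most `max_occ`
times in each genome, both strands scanned via canonical codes. With the
default `max_occ = 1` this doubles as a repeat filter, replacing seeded
gapped alignment and repeat masking at desk scale; a secondary pass with
`max_occ = 3` supplies the multi-mapping matches needed to see copy-number
differences. Sensitivity below ~k-spaced SNP density is lost by design.

Chains maximize Σ anchor length − Σ gap costs with gap cost
`50 + 0.5·(q_gap + t_gap)` and both gaps ≤ 10 kb, by sparse DP over anchors
sorted by query start; the best chain is extracted, its anchors removed,
and the DP repeats, so each anchor joins at most one chain. The gap
parameters are chosen so SNP-scale divergence never breaks a chain while
separate events ≥ 500 bp still score as their own chains. Optimality of the
best chain against exhaustive colinear-subset enumeration is verified on
random instances of ≤ 12 anchors.

Nets place chains greedily by descending score (ties: query chromosome,
query start, chain id — fully deterministic). A chain becomes level 1 when
its target span overlaps every placed level-1 span by ≤ 50 bp
(`overlap_tol`, absorbing anchor-end jitter); otherwise it nests (level =
parent + 1) inside the first placed chain whose inter-anchor target gap
contains it, else it is discarded. Chains at level 1 in both orientations
form the reciprocal-best one-to-one set. On SNP-only divergence at rate
0.005 this set covers ≥ 95% of both genomes.

## Reference-guided scaffolding

Only reciprocal-best chains with query span strictly greater than 800 bp
vote. Each query scaffold is assigned to the guide scaffold with the
highest aggregate chain score; orientation is the strand carrying most
score, position the score-weighted guide start. Scaffolds sharing a guide
scaffold are ordered by guide coordinate and merged with 100 N gaps
(AGP-representable placeholder; gap-size estimation from alignment
distances is out of scope); guide-interval conflicts drop the lower-scoring
scaffold to a singleton rather than discarding it. Joining conserves non-N
base pairs exactly and can only raise N50. Misassembly detection/breaking
is not attempted.

## Structural-variant classification and validation

With C as the reporting reference: *insertions* are maximal C intervals
≥ 100 bp (`min_len`, safely above the ~2k bp anchor holes that isolated
SNPs leave) not covered by any reciprocal-best anchor; *deletions* are the
same scan with R as reference. *Duplication groups* are regions of one
strain aligned by ≥ 2 distinct multi-occurrence chains (disjoint partner
copies; multiplicities give the copy numbers; gain/loss by comparing C vs
R copies; one count per group regardless of copies). *Inversions* are
blocks inside an enclosing chain's inter-anchor gap with opposite strand
and target interval in the corresponding gap; *transpositions* match strand
but violate the enclosing target order. Containment tests carry a 100 bp
tolerance because anchors cannot cross event breakpoints and therefore
jitter by up to ~k bp.

Classification precedence: strain-specific candidates overlapping a
balanced or copy-number call by ≥ 50% are dropped, since nested block
chains are never reciprocal-best and would otherwise surface as fake
coverage gaps.

Depth validation mirrors the two rules the calls must survive: a
strain-specific candidate validates iff the *median* per-window depth of
the other strain's reads over it is strictly below 10× (median rather than
mean for robustness to edge windows; the strict inequality is a documented
boundary decision); a duplication group validates iff, in each strain, the
mean depth of that strain's own reads over its copies lies within the
closed band [0.5, 1.5] × genome-median — symmetric, and tight enough to
catch 2-fold collapse. Candidates without overlapping depth data stay
`untested`, and summaries count validated-or-untested events with union-bp
coverage per class. Insertion-versus-deletion polarity is reported per
reference frame; no ancestral-state inference is attempted.

Benchmark conditions: 2 Mb genomes (two 1 Mb chromosomes), 10 events per
class of 500–2,000 bp, 4 decoys, 30× depth; matching requires reciprocal
overlap ≥ 0.5. Precision and recall reach 1.0 per class under these
conditions and the contract asserts ≥ 0.9.

## Synteny anchoring

Ortholog pairs are reciprocal best hits on global CDS identity
(1 − edit distance / max length, via edlib's Needleman–Wunsch distance),
ties broken toward the lexicographically smallest id so identical paralogs
retain at most one pair; the all-vs-all scan is quadratic and intended for
the hundreds-of-genes scale of the synthetic benchmarks. Marker position is
the gene midpoint. Blocks are maximal runs of consecutive markers with
constant reference chromosome and relative orientation and strictly
monotone reference positions in the implied direction; runs shorter than
2 markers are discarded. Scaffolds anchor to the chromosome holding the
plurality of their block markers (ties lexicographic); scaffolds with
blocks on several chromosomes are flagged conflicted, and anchored-bp
fractions are reported both with and without them, since either convention
is defensible.

## Population genetics

**Diversity.** θ̂_W = S/(a_n·L) with S the sites segregating within the
group, a_n = Σ_{i<n} 1/i, n = 2 × diploids; π is the mean per-site unbiased
expected heterozygosity (2·a·(n−a)/(n(n−1)) summed over sites, divided by
L). Both are reported side by side: under neutrality they estimate the same
quantity, and the benchmark checks both against neutral coalescent
simulations (msprime as the independent generator) at θ = 0.01/site,
within 3 standard errors over 50 replicates.

**Fst.** Per-site Weir–Cockerham (1984) two-population variance components
(a, b, c) with per-site sample-size adjustment for missing genotypes;
sites need ≥ 2 genotyped diploids per population and overall polymorphism.
Weighted Fst = Σa / Σ(a+b+c), genome-wide and in 1 kb windows; negative
estimates are reported as computed, never clamped. The tests hold the
implementation to a scalar transcription of the published formulas on
printed genotype tables.

**Permutation null.** Individual population labels are permuted (group
sizes preserved; the permutation unit is the individual), the weighted Fst
recomputed, and p = (#{perm ≥ obs} + 1)/(R + 1) with R = 200 by default, so
the smallest attainable p is 1/201. Type-I error at α = 0.05 over 200
unstructured datasets falls in [0.02, 0.09] — slightly conservative due to
the discreteness of the statistic.

**Trees.** Pairwise distance = mean over sites called in both samples of
|dosage_i − dosage_j|/2 (pairwise deletion; a pair with zero shared sites
is an error naming the pair). Neighbour joining uses scikit-bio's
Saitou–Nei implementation; exact additivity is preserved (topology and
path lengths). Bootstrap resamples site columns with replacement
(1,000 replicates by default), and each internal edge of the full-data tree
receives the fraction of replicate trees containing the same bipartition —
majority-rule consensus supports.

**dN/dS.** Nei–Gojobori (1986): per-codon synonymous site fractions
(mutations to stop codons count as nonsynonymous), observed differences
averaged over all substitution pathways with pathways through intermediate
stops excluded unless none remain, Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3). The ratio is undefined (NaN) when dS = 0, and
p ≥ 3/4 is flagged as saturated. This pairwise counting proxy deliberately
replaces likelihood-based site models, and outputs are labelled NG86.

## Enrichment

A gene is "inside SV" iff it shares at least one base pair with the region
union (half-open, so abutting genes are outside). Each category's 2×2 table
is tested with a one-sided Fisher exact test (over-representation only) and
Benjamini–Hochberg adjusted across categories; labels follow q < 0.001 →
`***`, q ≥ 0.05 → `ns`, otherwise `other`. An empty partition side
degenerates to p = q = 1. Calibration: with no planted enrichment, ≤ 8% of
category tests reach q < 0.05 across 100 simulations (empirically ~0–2%,
Fisher being conservative); a 4-fold enriched category with ≥ 40 genes in
SV regions is detected in ≥ 90% of 50 simulations.

## Benchmark problem sizes

The standard study conditions used by `scripts/acceptance.py` and the
end-to-end tests: 100 random chaining instances of ≤ 12 anchors; 20 seeded
1 Mb genomes fragmented into 4 pieces for the scaffolder; one 2 Mb SV
dataset with 10 events/class at 30×; 50 neutral 20 kb coalescent replicates
for θ̂/π; 20 seeds × 10,000 sites per Fst target; 200 null datasets × 200
permutations; 20 tree seeds at 1,500 sites with 200 bootstraps; 100 null
and 50 power enrichment simulations of 300 genes over 600 kb. These sizes
make the whole benchmark run in a few minutes on one CPU while keeping
every stochastic bound several standard errors away from its threshold.

## Known limitations

* Anchors require exact unique 21-mers: highly repetitive or
  high-divergence (> ~2–3%) regions drop out of the one-to-one map, and
  copy numbers above `max_occ` are invisible to the CNV scan.
* Depth tracks are idealized Gaussian-noise coverage, not read mappings;
  conclusions about real-data validation thresholds do not follow.
* The population model has free recombination between sites and no
  demography beyond one split parameter; mtDNA is a fixed-difference
  caricature.
* The ortholog pairing is all-vs-all and quadratic in gene count.
* Transpositions are detected only within a chromosome pair (inter-
  chromosomal moves would surface as insertion/deletion pairs instead).
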