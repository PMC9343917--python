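# Methods

## Data model

A panel is a cultivars × markers matrix of biallelic SNP calls in
{HOM1, HET, HOM2, MISSING}, stored as an `int8` array with codes
{0, 1, 2, −1}. HOM1 means homozygous for the marker's `allele1` as listed in
the metadata — for endpoint-PCR platforms that report XX/YY/XY cluster
calls, `allele1` is whichever allele the assay labels "X", not necessarily a
reference-genome allele. Coordinates are 1-based throughout; any half-open
interval arithmetic is internal to the annotation code. Multiallelic VCF
records are excluded on input (the model is strictly biallelic), as are
indels. Missing tokens `NA`, `./.`, `NoCall`, `No Call` and the empty string
are normalised at parse time.

Residual heterozygous calls in an inbred panel can be kept, masked to
missing, or recoded to the majority homozygote at the marker
(`recode_heterozygotes`). The majority-homozygote reading is one plausible
way to emulate manual curation of auto-called heterozygotes; it is not
guaranteed to match any particular lab's curation, which is why the policy
is explicit rather than a default.

## QC filtering

Markers are retained when missingness < `max_missing` (default 0.30,
strict), MAF > `min_maf` (default 0.05, strict), and — only when a
read-depth matrix is present — per-call depth lies in
[`min_depth`, `max_depth`] (defaults 3 and 190, inclusive) for at least
`min_depth_fraction` of called entries (default 1.0). The strict/inclusive
mix follows the conventional statement of these thresholds ("MAF > 5%,
missing < 30%, depth ≥ 3 and ≤ 190"). Rules are evaluated in the order
missing → MAF → depth and the report records each dropped marker's first
failing rule, so retained + dropped always partitions the input. The
missingness denominator is all cultivars in the matrix. Filtering is
idempotent by construction.

Allele frequencies are always estimated from called genotypes, a
heterozygote contributing one copy of each allele. An all-missing marker
has undefined MAF; inside `apply_filters` it fails the MAF rule rather than
raising.

## Annotation

Genomic context uses interval sets from a GFF3-like table with precedence
CDS > UTR > intron > upstream/downstream > intergenic; a gene-interval hit
outside CDS/UTR counts as intronic even without explicit intron features.
Upstream/downstream spans extend 1 kb beyond the gene on the
strand-appropriate side (configurable; 1 kb is a conventional
promoter-proximal window, the choice is not derivable from the data).
A position inside both an upstream and a downstream span (two adjacent
genes) classifies as `up_downstream`. Coding effect substitutes both
alleles into the affected codon (reverse-complemented on the minus strand,
phase-trimmed) and translates with the standard genetic code; stop-gain
counts as nonsynonymous since no separate nonsense class is kept.

## Diversity statistics

PIC = 1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ²; for a biallelic locus this is
He − 2p²q² with He = 2pq, so 0 ≤ PIC ≤ He ≤ 1 and PIC ≤ 0.375 with the
maximum at p = 0.5. PIC is strictly increasing in MAF on (0, 0.5].
"Heterozygosity" in reports means expected heterozygosity (gene diversity);
observed heterozygosity (#HET / #called) is reported alongside, because the
two are routinely conflated in published summaries and cannot be
disambiguated after the fact. Report tables round half-up to two decimals,
matching how such tables are printed; all internal values keep full
precision, and tests against printed values allow ±0.005.

## Discrimination and core-panel selection

Two cultivars are separated by a panel when at least `min_diff` mutually
called loci differ; loci missing in either cultivar are ignored. The
default `min_diff` = 1 (one discordant locus distinguishes); it is
configurable because genotyping error argues for ≥ 2 in regulatory use.
Under the missing-ignore rule separation is monotone in panel growth, so
identification counts can only improve as markers are added.

"Identified" means a unique multilocus profile. Because missingness can
make "not separated" non-transitive, duplicate groups are the connected
components of the not-separated graph (transitive closure), with a logged
warning when the relation is genuinely non-transitive. This is the
conservative choice for DUS screening: a candidate is only declared
identified when nothing links it to any other cultivar.

Selection strategies:

* `pic_rank` — descending PIC, optionally round-robin over chromosomes in
  metadata order with a minimum physical spacing between chosen markers on
  the same chromosome; ties break by (chromosome order, position, id).
* `set_cover` — greedy: repeatedly add the marker separating the most
  not-yet-separated comparable pairs (ties by PIC, then position). With no
  target size it stops when every pair separable by any single marker is
  covered, which equals the full panel's separation under the one-locus
  rule; the classical ln(m)+1 approximation bound applies versus the
  optimal panel.

Nested panels re-run the strategy restricted to the next larger panel, so
nesting holds by construction for any strategy. Reference-variety
suggestion ranks other cultivars by 1 − simple-matching distance over
mutually called loci, ties by id; cultivars sharing no called locus with
the query are excluded rather than given a fabricated similarity.

## Distances, trees, ordination

Jaccard similarity operates on the 1/0 allelic matrix (each marker two
allele-presence columns; HET = (1,1), missing = NaN in both): with M11 the
shared 1s and M10+M01 the mismatches over pairwise non-missing positions,
d = 1 − M11/(M11+M10+M01). Pairwise-complete exclusion of missing data is
the package's chosen dialect; binary-similarity software differs here and
no single convention is canonical.

Neighbor joining is the Saitou–Nei agglomeration with the standard
Q-criterion, reimplemented for determinism: ties on Q break on the
lexicographically smallest pair of clade labels (a clade is labelled by its
smallest leaf). Negative branch-length estimates are clamped to zero with
the deficit moved to the sister edge, preserving the pair's total — the
usual practical convention. The decisive correctness property, asserted in
tests over random trees, is exact recovery of additive matrices: tip-to-tip
path lengths reproduce the input within 1e−9. Topology is also
cross-checked against an independent library implementation. Newick output
quotes labels containing metacharacters and round-trips topology and
lengths at the chosen precision (default 6 digits).

PCA codes genotypes as allele2 dosage 0/1/2, imputes missing calls with the
marker mean, centers columns and takes the SVD; variance shares are
relative to total variance and component signs are fixed by making the
largest-magnitude loading positive, so results are invariant to cultivar
order up to that convention.

## Mixture validation

`expected_mixture_call` is the deterministic mixing table (opposite
homozygotes → HET; any HET parent → HET; missing propagates). The
simulation miscalls each informative locus (parents opposite homozygotes)
as a random parental homozygote with probability `assay_failure_rate` —
real shortfalls are lab-dependent (incomplete fixation, seed purity,
chemistry) and carry no mechanistic model, so a single independent failure
probability is used. Pooled heterozygote concordance therefore converges to
1 − failure rate; the tests check agreement within three Monte-Carlo
standard errors. A published figure of ~93% concordance is a plausibility
anchor for the default failure-rate choice in examples, not a target the
simulation could or should reproduce exactly.

## Synthetic panel generator

`generate_panel` emulates a selfing-crop diversity panel: per marker an
ancestral allele frequency uniform on [0.05, 0.50]; per subpopulation a
Balding–Nichols draw `Beta(p(1−F)/F, (1−p)(1−F)/F)`; cultivars are fully
homozygous draws from their subpopulation frequency. Defaults are the
study conditions the package targets: 95 cultivars in 3 subpopulations
(32/32/31), 500 markers on 9 chromosomes, FST 0.2, residual
heterozygous-call rate 0.25%, missing rate 2% (comfortably under the 30%
QC ceiling). Duplicate groups copy a progenitor's profile before noise, so
at zero noise the planted groups are exactly the duplicate groups the
discrimination module must recover; with noise enabled a single stray
heterozygous call can separate two copies, which is a realistic property,
not an artifact. HET and MISSING are planted independently per entry, with
MISSING taking precedence when both fire. Marker positions are uniform
without replacement per chromosome, then sorted.

Deliberately not modelled: linkage disequilibrium along chromosomes, read
depth, allele-frequency ascertainment from a real discovery cohort, and
assay manufacturability (cluster separation, primer design). Passing tests
on synthetic panels therefore demonstrate correctness of the algorithms
under the stated statistical model, not performance on any particular real
collection.

All generator randomness flows through the single `seed` field of
`PanelSpec` via `numpy.random.default_rng`; no global RNG state is used or
mutated, and regeneration with the same spec is bit-identical.

## Bundled core-24 panel and the acceptance computation

The package bundles the published 24-marker lettuce core panel's metadata
(ids, coordinates, alleles, genomic context, printed MAF and PIC).
`fixture_table4` realises the printed MAFs as an all-homozygous genotype
matrix: the minor-homozygote count is the printed MAF times the cultivar
count rounded to the nearest achievable integer (at n = 95 the realised
MAFs sit within 1/190 of the printed values), and the seed only shuffles
the genotype-to-cultivar assignment, so realised allele counts — and every
statistic derived from them — are seed-independent. `scripts/acceptance.py`
runs this realisation and recomputes the panel PIC summary (mean 0.33,
range 0.23–0.37, 2-decimal half-up) and the biallelic PIC ceiling at
MAF 0.5 (0.375 → 0.38) through the ordinary QC/diversity code path.

Problem sizes used by the test suite — 95 × 500 synthetic panels, 100
random 4–10-taxon trees for NJ additivity, 200 random panels for
monotonicity, 200 mixture replicates of 20 pairs × 24 markers — were chosen
so the whole suite exercises every guarantee at study scale while staying
fast enough to run routinely.

## Known limitations

* Identification counts on any *real* published collection depend on that
  collection's genotype calls; the package validates the rule on synthetic
  panels with planted truth instead of shipping third-party data.
* The greedy set-cover bound is the classical approximation guarantee;
  minimal panels are only certified minimal on instances small enough for
  exhaustive search (the tests do exactly that).
* `select_set_cover` optimises the one-discordant-locus rule; for
  `min_diff` > 1 use `pic_rank` and verify with `separation_summary`.
* The NJ tie-break and negative-length policy are deterministic choices;
  other implementations may emit different but equally valid trees when
  the input is far from additive.
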