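# Methods

This note documents the models, parameter choices and numerical decisions
behind `otupipe`, and what the synthetic validation does and does not show.

## Pipeline model

The pipeline reproduces a 454-era 16S V1–V2 amplicon workflow in its
original stage order:

1. **Demultiplexing.** Exact prefix match of fixed-length barcodes; the
   barcode is stripped. Exact matching is deliberate: with barcodes at
   pairwise Hamming distance ≥3, a single sequencing error never reassigns
   a read, it only de-assigns it.
2. **Primer check.** Forward primer at the 5′ end and the reverse
   complement of the reverse primer at the 3′ end, each within
   `max_primer_mismatch = 2` substitutions (no indels). By default a read
   must carry **both** primers; a `require="either"` switch implements the
   laxer reading. Reads failing the rule are still kept when the
   barcode-stripped read exceeds 400 bp — the exception that protects rare
   species with long V1–V2 regions (e.g. Campylobacter-like, ~493 bp) —
   and any primer that was found is trimmed regardless.
3. **Quality filter.** A read is removed iff its mean Phred score is
   strictly below 25; a mean of exactly 25.0 is kept, because the removal
   rule is stated as "< 25".
4. **Chimera removal.** A read whose best database hit covers < 90% of the
   read is removed (see *Alignment* below for how coverage is measured).
   Reads with no database hit at all are removed too but counted
   separately.
5. **Rarefaction.** Each sample is subsampled to `depth = 3000` reads
   without replacement; samples below depth are excluded (sampling with
   replacement would fabricate reads). Reads are ordered by read id before
   drawing and each sample gets its own seed stream, so the subsample is
   invariant to input file order.
6. **Clustering.** The pooled rarefied reads are sorted by descending mean
   quality (ties: longer read, then lexicographic id) and clustered
   greedily at 96% identity. A read joins the first existing OTU — in
   shared-k-mer candidate order, founding order breaking ties — whose
   representative it matches at ≥96%; otherwise it founds a new OTU. The
   quality sort makes every representative the highest-quality member of
   its OTU, which is the point of sorting before clustering. OTU ids are
   assigned in founding order and are stable across reruns. Clustering is
   pooled across samples, not per sample.
7. **Taxonomy.** Best-hit assignment for each OTU representative: species
   at ≥0.97 identity, genus at ≥0.95, phylum ("higher") at ≥0.80, else
   unclassified. Only the 95% genus threshold is inherited from the
   original workflow; 0.97/0.80 are the conventional values.

## Alignment

Read-vs-reference and read-vs-representative comparisons use **edlib** in
glocal ("HW") mode: the read aligns end to end, the reference contributes
an infix, so terminal reference overhangs are free. Identity is
`matches / alignment columns` = `1 − edit_distance / columns`, with gap
columns counting as non-matching. Candidate references are ranked by
shared 8-mers (non-overlapping query words against a full inverted index),
ties broken by database/founding order; the top 5 candidates are aligned.
This replaces a hand-rolled banded affine-gap aligner: unit-cost edit
distance and affine scoring give indistinguishable identities on amplicon
data (homopolymer slips are single-base), and the C implementation is what
makes a ~0.5M-alignment run take minutes. The scoring reported alongside
hits is the linear-gap score `columns − 3·distance`, i.e. match +1,
mismatch/gap −2.

**Chimera coverage** needs a genuinely local alignment (the glocal mode
always covers the whole read), so it uses Biopython's `PairwiseAligner`
with match +1, mismatch −2, gap open −5, gap extend −2; coverage is the
aligned query span divided by read length. With these scores, local
extension is profitable only below ~33% divergence, so an alignment stops
at a chimera breakpoint into a foreign genus (~50% divergent) and the best
single parent covers roughly its own half. Reads whose glocal identity is
already ≥ 0.93 skip the local alignment and are assigned coverage 1.0: at
that identity a full-coverage local alignment is guaranteed in practice
(any 10% tail of such a read is far too similar to score negatively), and
the screen is what keeps the affine aligner off the ~99% of reads that
cannot be chimeric. Cross-genus two-parent splices top out near identity
0.90, comfortably below the screen. The "match length < 90%" rule is
interpreted relative to the **query** (a chimera half covers ~half the
read); a config switch for the subject-relative variant is deliberately not
offered because subject-relative coverage cannot detect chimeras against
full-length references.

## Trees, UniFrac, ordination

The OTU tree is neighbor joining (scikit-bio) on pairwise distances
`1 − identity` from global edlib alignments of representatives, negative
branch lengths clamped to zero, midpoint rooted. The original study never
specifies its tree method; this choice is the package's own and is the main
reason ordination figures are comparable only qualitatively.

Weighted UniFrac is computed by branch traversal: for each branch `b` with
length `l_b`, `p_b^X` is the fraction of sample X's reads on leaves below
`b`; the raw distance is `Σ l_b |p_b^A − p_b^B|`, normalized (the default,
making the metric range 0–1) by `Σ_leaf d_leaf (p^A_leaf + p^B_leaf)` with
`d_leaf` the root-to-leaf distance. Unweighted UniFrac is unique branch
length over union branch length on presence/absence. Proportions come from
the rarefied OTU table, so the metric is invariant to scaling a sample's
counts.

PCoA is classical metric scaling: `B = −½ J D² J`, symmetric
eigendecomposition, coordinates `v_i √λ_i` for positive eigenvalues.
Negative eigenvalues are reported but excluded from the variance fractions
(fractions are over the positive sum; scikit-bio divides by the full sum,
which is the one place the two implementations differ numerically).
Eigenvector signs are fixed by making the largest-magnitude loading
positive. The UPGMA dendrogram is scipy average linkage; node heights are
half the merge distance, so cophenetic distances reproduce ultrametric
inputs exactly.

## Statistics

`compare_groups` routes by normality: Shapiro–Wilk on each group at
α = 0.05 → two-sample t if both pass, otherwise Mann–Whitney U (normal
approximation with tie correction). Forced modes (`student`, `welch`,
`mwu`) exist because the original analysis itself mixes Student's t (for
UniFrac distance comparisons) and Welch's t (for genus abundances). Groups
that are both constant short-circuit to p = 1 (identical) — the degenerate
case a t statistic cannot represent. UniFrac group comparisons treat
pairwise distances as observations under Student's t; the pairs are not
independent, and the resulting p-values should be read as descriptive, not
inferential.

Benjamini–Hochberg is the step-up `q_(i) = min_{j≥i} p_(j)·m/j`, capped at
1. The correction family is: all genus × biomarker cells jointly for the
correlation matrix; the 14 dominant genera within each group contrast for
the abundance tests.

Biomarker correlations are Pearson on genus relative abundance vs
biomarker level divided by the subject's total protein, over the 39
assayed subjects. `linear_fit` is OLS whose slope p-value equals the
Pearson p-value by identity. qPCR concordance is Pearson after the inverse
hyperbolic sine `ln(x + √(x²+1))` on both read counts and copy numbers —
log-like but defined at zero, which both quantities can be.

## Synthetic-study generator

The generator emulates the study's structure, not its sequences:

* **Reference database** (default 14 genera × 3 species): genus consensus
  sequences of 300–431 nt are independent random DNA (mutual identity
  ≈50%, far below the 92% bound that keeps 96% clustering meaningful);
  species diverge 2.5–3.5% from their consensus, putting congeneric
  species ~5–7% apart — outside the 96% OTU radius, inside the 95% genus
  radius. The last genus is a 493 nt outlier exercising the long-read
  exception. Real 16S V1–V2 regions share conserved blocks across genera;
  random sequences do not, which makes chimera detection and genus
  assignment *easier* here than on real data (see *Limitations*).
* **Profiles**: healthy-control genus proportions are Dirichlet draws
  around a Streptococcus-dominated salivary baseline (total concentration
  120, giving ~3–4 point between-subject scatter for the dominant genus);
  species within a genus split by a second Dirichlet. IBD (CD and UC)
  profiles multiply the six effect genera by their fold changes —
  defaults: Prevotella 2.2, Veillonella 2.0, Streptococcus 0.62,
  Haemophilus 0.45, Neisseria 0.50, Gemella 0.45 — then renormalize.
* **Reads**: `barcode + forward primer + template + revcomp(reverse
  primer)`, with substitutions at 0.5%/base and single-base
  homopolymer-context indels at 0.2% applied to the template (454's
  signature error mode). 0.46% of reads are chimeras: two parents from
  different genera spliced at a breakpoint uniform in the middle 60% of
  the template, so the best single-parent coverage is ≤~80% by
  construction. Mean read quality follows a two-component mixture with
  the low component weighted at 0.75%; components are truncated away from
  the QV-25 threshold (good ≥26, bad ≤24) so the sub-threshold fraction is
  exactly binomial in the configured weight rather than inflated by the
  good component's tail. Per-base qualities jitter around the read mean
  (sd 1.5, clipped to [2, 40]).
* **Biomarkers** (39 subjects: 15/14/10 per group, mirroring the assayed
  subset): each biomarker has one driver genus and a target correlation;
  the level is `sign(r)·x + ε` with the noise variance solved from
  `r² = var(x)/(var(x)+σ²)`, then affinely mapped to plausible assay units
  and multiplied by the subject's total protein (lognormal, σ=0.25), so
  that protein normalization in the analysis recovers the correlated
  scale exactly. Defaults include the three headline strengths 0.63
  (Streptococcus–lysozyme), 0.58 (Prevotella–IL-1β) and −0.54
  (Streptococcus–IgA). One driver per biomarker is a deliberate
  simplification: with compositionally coupled abundances, several exact
  multi-genus targets per biomarker are not simultaneously satisfiable,
  while the secondary correlations (e.g. Prevotella vs lysozyme negative)
  emerge from the composition itself.
* **qPCR**: per-sample copy number `scale × true proportion × lognormal
  noise` for Prevotella melaninogenica and Haemophilus parainfluenzae;
  zero when absent. The default noise σ = 0.4 was chosen so the asinh-scale
  concordance lands in the high-0.7s/0.8s regime the original measurements
  report; note the attainable r is capped by the ratio of the species'
  asinh-scale abundance spread (≈0.5 sd here) to the noise.

Everything is driven by one integer seed through per-component
`SeedSequence` streams; identical configs produce byte-identical output
files.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that the pipeline's machinery is correct and
calibrated: read accounting is exact, constructed chimeras are detected by
the coverage rule, clustering resolves species-level structure at the
configured divergences, the estimators match their formulas to 1e−10,
UniFrac/PCoA match independent oracles, configured effects and
correlations are recovered at the study's sample sizes. They do **not**
show that the original study's printed values are reproduced: those depend
on real 454 reads (DRA000984–DRA000986) and three external databases, on
real 16S sequence structure (conserved regions, variable-length
homopolymers), and on unspecified details (tree method, UniFrac variant,
package versions). Diversity means on the synthetic 42-species community
(e.g. HC Shannon ≈ 3.1, Simpson ≈ 0.93) are of the right order but are
properties of the generator, not replications of the study's Table.

## Test and acceptance problem sizes

The unit suite runs on small studies (10 samples × 600 reads, depth 300;
an error-free 6 × 200 study for exactness checks). The end-to-end recovery
checks and the acceptance script use the full design — 59 samples × 5000
reads rarefied to 3000 — which completes in a few minutes on one CPU.
Statistical calibration uses 1000 null replicates; estimator and UniFrac
oracles sweep 1000 random vectors and 100 random trees respectively.

## Known limitations

* Random reference sequences lack 16S conserved blocks; chimera detection
  and taxonomy are correspondingly easier than on real amplicons. There is
  no PCR bias, no flowgram-level noise model, and chimeras always join
  different genera.
* UCLUST's exact candidate heuristics are not reproduced; the greedy
  clusterer shares its contract (sorted input, first-match-wins, 96%
  threshold) but may tie-break differently on borderline reads.
* The NJ/midpoint tree is a stand-in for the study's unspecified
  phylogeny; UniFrac values are internally consistent but not comparable
  in absolute terms.
* Distance-based group tests inherit the non-independence caveat above.
* Threshold boundary cases (identity exactly 0.96, coverage exactly 0.90,
  mean QV exactly 25) follow the strict-inequality readings documented in
  the module docstrings.
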