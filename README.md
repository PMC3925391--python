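# otupipe

A tested re-implementation of a classic 454-pyrosequencing analysis of
salivary microbiota in inflammatory bowel disease (IBD): 16S rRNA V1–V2
amplicon quality control, reference-based chimera removal, quality-sorted
greedy OTU clustering, alpha diversity, UniFrac beta diversity with
ordination, and statistics linking the microbiota to salivary immunological
biomarkers and qPCR measurements.

The package is aimed at microbiome researchers and method developers who
want the complete analysis chain as an importable, unit-tested library
rather than a collection of external tools. Because the original deposited
reads and reference databases are not desk-reproducible, the package ships a
first-class **synthetic-study generator** that emulates the study design —
59 subjects (24 healthy controls, 21 Crohn's disease, 14 ulcerative
colitis), barcoded primer-flanked reads with 454-like qualities and errors,
a chimeric fraction, genus-level disease effects, and correlated biomarker
panels — with a per-read ground-truth manifest, so every stage can be
validated quantitatively.

## The analysis

Reads are demultiplexed by exact barcode match, checked for both the
forward (27F-class) and reverse (338R-class) primer within ≤2 substitutions
(reads longer than 400 bp are spared this check, protecting rare long V1–V2
species), and removed when the mean Phred quality `Q̄ = (1/L) Σ Qᵢ < 25`.
A read is called **chimeric** when the best local alignment against the
reference database covers less than 90% of the read. Each sample is rarefied
to 3000 reads; the pooled 59 × 3000 = 177,000 reads are sorted by descending
`Q̄` and clustered greedily at 96% identity, so every OTU representative is
the highest-quality read of its cluster. Taxonomy is assigned by best hit:
species at ≥97% identity, genus at ≥95%, phylum at ≥80%.

Per-sample alpha diversity covers the classic panel: Shannon
`H = −Σ pᵢ ln pᵢ`, Simpson `1 − λ` and inverse Simpson `1/λ` with
`λ = Σ pᵢ²`, Pielou `J = H / ln S`, bias-corrected Chao1
`S + F₁(F₁−1)/(2(F₂+1))`, ACE with rare cutoff 10, and Fisher's α solving
`S = α ln(1 + N/α)`. Beta diversity is weighted and unweighted **UniFrac**
over a neighbor-joining tree of OTU representatives
(`d_w = Σ_b l_b |p_b^A − p_b^B| / Σ_leaf d_leaf (p^A + p^B)`), ordinated by
principal coordinates analysis (Gower double-centering) and average-linkage
clustering. Group contrasts use Shapiro-routed t / Mann-Whitney tests (or
Welch's t for genus abundances) with Benjamini–Hochberg correction; genus ×
biomarker associations are Pearson correlations of relative abundances
against total-protein-normalized biomarker levels; and 16S read counts are
validated against qPCR copy numbers on the inverse-hyperbolic-sine scale.

## Worked example

```python
from otupipe import StudyConfig, simulate_and_run

study, result, report = simulate_and_run(StudyConfig(seed=1))
print(result.manifest.stage_counts)
print(report["chimera_recall"], report["otu_count"])
```

On the default study (seed 1) this prints, among others:

```
{'input': 295000, 'assigned': 295000, 'primer_fail_removed': 0,
 'low_quality_removed': 2284, 'passed_qc': 292716, 'chimera_removed': 1394,
 'no_hit_removed': 0, 'passed_chimera': 291322, 'rarefied_samples': 59,
 'pooled_rarefied_reads': 177000, 'otus': 44}
1.0 44
```

meaning: of 295,000 reads, 0.77% were removed for mean quality below 25
(0.75% was configured) and 0.48% as chimeras (0.46% configured, recalled at
100%); the 177,000 rarefied reads clustered into 44 OTUs from a 42-species
reference. In the same run all six configured effect genera (Prevotella and
Veillonella up in IBD; Streptococcus, Haemophilus, Neisseria, Gemella down)
are recovered at q < 0.05 (most far below 0.001) with the correct
direction, the recovered
Streptococcus–lysozyme correlation is r = 0.55 against a generated 0.63
(inside its Fisher-z 95% interval at n = 39), and the first three PCoA axes
of the weighted UniFrac matrix explain 60.7% of the variance.

## Repository layout

* `src/otupipe/` — the library: `simulate` (synthetic studies), `qc`,
  `search` (alignment/chimera/taxonomy), `cluster`, `diversity`, `beta`
  (tree/UniFrac/PCoA/UPGMA), `stats`, `pipeline`, `cli`.
* `analysis/01…08_*.py` — numbered drivers that run the study step by step
  (simulate → QC → chimera screen → clustering → alpha → beta → group
  statistics → biomarkers/qPCR), printing what each stage found and writing
  tables under `results/analysis/`.
* `otupipe` console script — the same stages as CLI subcommands
  (`simulate`, `qc`, `search`, `cluster`, `diversity`, `beta`, `stats`,
  `all`).
* `docs/methods.md` — model, parameter and design documentation.

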