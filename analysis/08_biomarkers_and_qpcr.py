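"""Biomarker-taxon correlations and qPCR concordance.

Correlates genus relative abundances with total-protein-normalized biomarker
levels over the assayed subjects (Pearson, BH-adjusted across the matrix),
validates the strongest pairs by linear regression, and computes the
concordance between 16S read counts and qPCR copy numbers on the
inverse-hyperbolic-sine scale for the two target species.
"""

import argparse
from pathlib import Path

import pandas as pd

from otupipe.io import read_tsv, write_tsv
from otupipe.simulate import StudyConfig
from otupipe.stats import linear_fit, pearson_matrix, qpcr_concordance


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--studydir", default="scratch/study", type=Path)
    ap.add_argument("--results", default="results/analysis", type=Path)
    args = ap.parse_args()

    cfg = StudyConfig.from_yaml(args.studydir / "config.yaml")
    genus_ab = read_tsv(args.results / "genus_abundance.tsv", index_col=0)
    biomarkers = read_tsv(args.studydir / "biomarkers.tsv", index_col=0)
    named = [g for g in genus_ab.columns if g != "unclassified"]
    corr = pearson_matrix(genus_ab[named], biomarkers)

    args.results.mkdir(parents=True, exist_ok=True)
    write_tsv(corr.r, args.results / "biomarker_correlation_r.tsv")
    write_tsv(corr.q, args.results / "biomarker_correlation_q.tsv")
    write_tsv(corr.stars, args.results / "biomarker_correlation_stars.tsv")

    print("configured genus-biomarker targets:")
    shared = genus_ab.index.intersection(biomarkers.index)
    norm = biomarkers.loc[shared].drop(columns=["group"]).div(
        biomarkers.loc[shared, "total_protein"], axis=0)
    for (genus, marker), target in cfg.biomarker_correlations.items():
        r = corr.r.loc[genus, marker]
        slope, intercept, p = linear_fit(genus_ab.loc[shared, genus],
                                         norm[marker])
        print(f"  {genus:14s} vs {marker:8s} r = {r:+.2f} "
              f"(target {target:+.2f}), regression slope p = {p:.1e}")

    qpcr = read_tsv(args.studydir / "qpcr.tsv", index_col=0)
    taxonomy = read_tsv(args.results / "otu_taxonomy.tsv", index_col=0)
    counts = read_tsv(args.results / "otu_table.tsv", index_col=0)
    lineage = read_tsv(args.studydir / "lineage.tsv", index_col=0)
    rows = []
    print("\nqPCR concordance (asinh scale):")
    for target in [c for c in qpcr.columns if c != "group"]:
        label = lineage.loc[target, "species"]
        otu_ids = taxonomy.index[taxonomy["species"] == label]
        reads = counts.loc[otu_ids].sum(axis=0)
        shared = reads.index.intersection(qpcr.index)
        r, p = qpcr_concordance(reads.loc[shared], qpcr.loc[shared, target])
        rows.append({"target": target, "r": r, "p": p, "n": len(shared)})
        print(f"  {target:28s} r = {r:.2f} (p = {p:.1e}, n = {len(shared)})")
    write_tsv(pd.DataFrame(rows).set_index("target"),
              args.results / "qpcr_concordance.tsv")


if __name__ == "__main__":
    main()
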