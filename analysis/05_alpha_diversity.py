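"""Per-sample alpha-diversity panel and group comparisons.

Computes the richness/evenness/diversity estimates (observed OTUs, Chao1,
ACE, Shannon, Simpson, inverse Simpson, Fisher's alpha, Pielou) per sample,
summarizes them as mean +- s.e.m. per group, and tests the three group
contrasts with normality-dependent tests and BH correction.
"""

import argparse
from pathlib import Path

from otupipe.diversity import group_summary, per_sample_diversity
from otupipe.io import read_tsv, write_tsv
from otupipe.pipeline import CONTRASTS
from otupipe.stats import compare_feature_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--studydir", default="scratch/study", type=Path)
    ap.add_argument("--results", default="results/analysis", type=Path)
    args = ap.parse_args()

    counts = read_tsv(args.results / "otu_table.tsv", index_col=0)
    groups = read_tsv(args.studydir / "metadata.tsv", index_col=0)["group"]
    div = per_sample_diversity(counts)
    summary = group_summary(div, groups)
    metrics = [c for c in div.columns if c != "n_reads"]
    tests = compare_feature_table(div[metrics], groups, CONTRASTS, mode="auto")

    args.results.mkdir(parents=True, exist_ok=True)
    write_tsv(div, args.results / "diversity.tsv")
    write_tsv(summary, args.results / "diversity_group_summary.tsv")
    write_tsv(tests, args.results / "diversity_tests.tsv", index=False)

    print("group mean +- s.e.m.:")
    wide = summary["mean"].unstack(0).round(3)
    sem = summary["sem"].unstack(0).round(3)
    for metric in metrics:
        cells = "  ".join(f"{g}: {wide.loc[metric, g]} +- {sem.loc[metric, g]}"
                          for g in ("HC", "CD", "UC"))
        print(f"  {metric:14s} {cells}")
    sig = tests[tests.q < 0.05]
    print(f"{len(sig)} of {len(tests)} diversity contrasts significant at "
          "q < 0.05" + ("" if sig.empty else f":\n{sig.to_string(index=False)}"))


if __name__ == "__main__":
    main()
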