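"""UniFrac beta diversity, PCoA ordination and UPGMA dendrogram.

Builds a neighbor-joining tree over OTU representatives, computes weighted
(normalized) and unweighted UniFrac between all sample pairs, ordinates the
weighted matrix by PCoA, clusters it by average linkage, and compares
within- vs between-group distances (Student's t).
"""

import argparse
from pathlib import Path

import pandas as pd

from otupipe import beta as beta_mod
from otupipe.io import read_fasta, read_tsv, write_tsv
from otupipe.pipeline import _distance_tests


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--studydir", default="scratch/study", type=Path)
    ap.add_argument("--results", default="results/analysis", type=Path)
    args = ap.parse_args()

    counts = read_tsv(args.results / "otu_table.tsv", index_col=0)
    groups = read_tsv(args.studydir / "metadata.tsv", index_col=0)["group"]
    reps = [r for r in read_fasta(args.results / "representatives.fasta")
            if r[0] in set(counts.index)]
    tree = beta_mod.build_tree(reps)
    wu = beta_mod.unifrac_matrix(tree, counts, "weighted", normalized=True)
    uu = beta_mod.unifrac_matrix(tree, counts, "unweighted")
    ordination = beta_mod.pcoa(wu, axes=3)
    upgma_nwk, _ = beta_mod.upgma_dendrogram(wu)
    tests, _ = _distance_tests(wu, groups)

    args.results.mkdir(parents=True, exist_ok=True)
    for name, dm in (("weighted", wu), ("unweighted", uu)):
        df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        df.index.name = "sample_id"
        write_tsv(df, args.results / f"unifrac_{name}.tsv")
    write_tsv(ordination.coordinates, args.results / "pcoa_coordinates.tsv")
    (args.results / "otu_tree.nwk").write_text(
        beta_mod.tree_to_newick(tree) + "\n")
    (args.results / "upgma_dendrogram.nwk").write_text(upgma_nwk + "\n")
    write_tsv(tests, args.results / "distance_tests.tsv", index=False)

    var3 = 100 * ordination.proportion_explained.sum()
    print(f"PCoA of weighted UniFrac: first three axes explain {var3:.2f}% "
          "of the variance "
          f"({', '.join(f'{100 * v:.1f}%' for v in ordination.proportion_explained)})")
    print("within- vs between-group weighted UniFrac (Student's t):")
    print(tests[["feature", "group_a", "group_b", "statistic", "p", "q"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
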