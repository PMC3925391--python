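"""Flag and remove chimeric reads by the reference-coverage rule.

A read whose best database hit covers <90% of its length is called chimeric.
Scored against the generator's manifest, which records the true two-parent
splices.
"""

import argparse
from pathlib import Path

import pandas as pd

from otupipe.io import read_fastq, write_fastq, write_tsv, read_tsv
from otupipe.pipeline import load_reference
from otupipe.search import ReferenceIndex, screen_chimeras


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--studydir", default="scratch/study", type=Path)
    ap.add_argument("--results", default="results/analysis", type=Path)
    args = ap.parse_args()

    db = load_reference(args.studydir / "reference.fasta",
                        args.studydir / "lineage.tsv")
    index = ReferenceIndex(db)
    by_sample = {}
    for path in sorted((args.studydir / "qc").glob("*.fastq")):
        sample_reads = list(read_fastq(path))
        for read in sample_reads:
            read.sample_id = path.stem
        by_sample[path.stem] = sample_reads
    cleaned, counts, chim_ids, nohit_ids = screen_chimeras(by_sample, index)

    outdir = args.studydir / "clean"
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, sample_reads in sorted(cleaned.items()):
        write_fastq(sample_reads, outdir / f"{sample}.fastq")
    flagged = chim_ids | nohit_ids
    args.results.mkdir(parents=True, exist_ok=True)
    write_tsv(pd.DataFrame(sorted(flagged), columns=["read_id"]),
              args.results / "chimera_reads.tsv", index=False)

    n_screened = sum(len(v) for v in by_sample.values())
    manifest = read_tsv(args.studydir / "manifest.tsv")
    truth = set(manifest.loc[manifest.is_chimera, "read_id"])
    reachable = truth & {r.read_id for v in by_sample.values() for r in v}
    tp = len(truth & flagged)
    print(f"screened {n_screened} reads: {counts['chimera_removed']} chimeric "
          f"({100 * counts['chimera_removed'] / n_screened:.2f}%), "
          f"{counts['no_hit_removed']} without any hit")
    print(f"vs ground truth: recall {tp / len(reachable):.3f} "
          f"({tp}/{len(reachable)} QC-surviving chimeras), "
          f"precision {tp / max(len(flagged), 1):.3f}")


if __name__ == "__main__":
    main()
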