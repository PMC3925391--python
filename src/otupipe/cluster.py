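"""Quality-sorted greedy OTU clustering of rarefied reads.

Samples are rarefied to a common depth (3000 reads by default), pooled,
sorted by descending mean quality, and clustered greedily at 96% identity:
each read joins the first existing OTU (in shared-k-mer candidate order)
whose representative it matches at or above the threshold, otherwise it
founds a new OTU with itself as representative. Because the reads are
quality-sorted, every representative is the highest-quality member of its
OTU -- the property that motivates sorting before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Read
from .search import ReferenceIndex, TaxonomyAssignment, assign_taxonomy, \
    best_hits, glocal_identity

logger = logging.getLogger(__name__)


@dataclass
class OTU:
    otu_id: str
    representative: Read
    members: list[Read] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def rarefy(reads_by_sample: dict[str, list[Read]], depth: int = 3000,
           seed: int = 0) -> dict[str, list[Read]]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` filter-passed reads are excluded with a
    warning. Reads are ordered by read_id before drawing and each sample gets
    its own seed stream, so the result is invariant to input file order.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    out: dict[str, list[Read]] = {}
    for i, sample in enumerate(sorted(reads_by_sample)):
        reads = sorted(reads_by_sample[sample], key=lambda r: r.read_id)
        if len(reads) < depth:
            logger.warning(
                "sample %s has %d < %d reads; excluded from rarefaction",
                sample, len(reads), depth)
            continue
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7, i]))
        idx = rng.choice(len(reads), size=depth, replace=False)
        out[sample] = [reads[j] for j in np.sort(idx)]
    return out


def sort_by_quality(reads: list[Read]) -> list[Read]:
    """Descending mean QV; ties broken by (longer read, then read_id)."""
    return sorted(reads, key=lambda r: (-r.mean_qv, -len(r), r.read_id))


def greedy_cluster(sorted_reads: list[Read], identity_threshold: float = 0.96,
                   k: int = 8) -> list[OTU]:
    """Greedy incremental clustering against OTU representatives.

    Candidate representatives are ordered by shared k-mer count (founding
    order breaks ties); the read joins the first one matched at
    ``identity_threshold`` or better under the glocal aligner, else founds a
    new OTU. Assumes reads are already sorted highest quality first.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    otus: list[OTU] = []
    kmer_map: dict[str, list[int]] = {}

    def index_rep(seq: str, idx: int) -> None:
        seen: set[str] = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if kmer not in seen:
                seen.add(kmer)
                kmer_map.setdefault(kmer, []).append(idx)

    for read in sorted_reads:
        seq = read.sequence
        counts: dict[int, int] = {}
        get = kmer_map.get
        for i in range(0, len(seq) - k + 1, k):
            for idx in get(seq[i:i + k], ()):
                counts[idx] = counts.get(idx, 0) + 1
        placed = False
        max_dist = int((1.0 - identity_threshold) * (len(seq) + 12)) + 1
        for idx in sorted(counts, key=lambda j: (-counts[j], j)):
            rep = otus[idx].representative
            identity, dist, _ = glocal_identity(seq, rep.sequence, max_dist)
            if dist >= 0 and identity >= identity_threshold:
                otus[idx].members.append(read)
                placed = True
                break
        if not placed:
            otu = OTU(f"OTU_{len(otus) + 1:04d}", read, [read])
            otus.append(otu)
            index_rep(seq, len(otus) - 1)
    return otus


@dataclass
class OTUTable:
    """Sample x OTU count matrix with representative taxonomy."""

    counts: pd.DataFrame  # index: otu_id, columns: sample_id
    taxonomy: pd.DataFrame  # index: otu_id; rank, taxon, phylum, genus, species

    @property
    def sample_depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)

    def collapse(self, level: str) -> pd.DataFrame:
        """Sum OTU counts sharing a genus or phylum label.

        OTUs without a label at the requested level are pooled under
        ``unclassified``.
        """
        if level not in ("genus", "phylum"):
            raise ValueError("level must be 'genus' or 'phylum'")
        labels = self.taxonomy[level].fillna("unclassified")
        labels = labels.where(labels != "", "unclassified")
        return self.counts.groupby(labels).sum()

    def genus_relative_abundance(self) -> pd.DataFrame:
        """samples x genera relative abundance (transposed for stats use)."""
        genus = self.collapse("genus")
        return (genus / genus.sum(axis=0)).T


def build_otu_table(otus: list[OTU], sample_ids: list[str],
                    assignments: dict[str, TaxonomyAssignment] | None = None,
                    ) -> OTUTable:
    """Tabulate member counts by (OTU, sample) and attach taxonomy."""
    known = set(sample_ids)
    counts = pd.DataFrame(0, index=[o.otu_id for o in otus],
                          columns=list(sample_ids), dtype=int)
    for otu in otus:
        for read in otu.members:
            if read.sample_id not in known:
                raise ValueError(
                    f"read {read.read_id} has unknown sample "
                    f"{read.sample_id!r}")
            counts.loc[otu.otu_id, read.sample_id] += 1
    tax_rows = []
    for otu in otus:
        a = (assignments or {}).get(otu.otu_id)
        if a is None:
            tax_rows.append(("unclassified", "unclassified", "", "", ""))
        else:
            phylum, genus, species = a.lineage or ("", "", "")
            # label resolution consistent with the assignment rank
            if a.assigned_rank == "higher":
                genus, species = "", ""
            elif a.assigned_rank == "genus":
                species = ""
            elif a.assigned_rank == "unclassified":
                phylum = genus = species = ""
            tax_rows.append((a.assigned_rank, a.taxon, phylum, genus, species))
    taxonomy = pd.DataFrame(
        tax_rows, index=counts.index,
        columns=["rank", "taxon", "phylum", "genus", "species"])
    counts.index.name = taxonomy.index.name = "otu_id"
    return OTUTable(counts, taxonomy)


def assign_representative_taxonomy(otus: list[OTU], index: ReferenceIndex,
                                   species_identity: float = 0.97,
                                   genus_identity: float = 0.95,
                                   phylum_identity: float = 0.80,
                                   ) -> dict[str, TaxonomyAssignment]:
    """Best-hit taxonomy for each OTU's representative sequence."""
    out: dict[str, TaxonomyAssignment] = {}
    for otu in otus:
        hits = best_hits(otu.representative.sequence, index,
                         query_id=otu.otu_id)
        out[otu.otu_id] = assign_taxonomy(
            hits, index, query_id=otu.otu_id,
            species_identity=species_identity,
            genus_identity=genus_identity, phylum_identity=phylum_identity)
    return out


def cluster_pipeline(reads_by_sample: dict[str, list[Read]],
                     index: ReferenceIndex, depth: int = 3000, seed: int = 0,
                     identity_threshold: float = 0.96,
                     ) -> tuple[OTUTable, list[OTU]]:
    """rarefy -> pool -> quality sort -> greedy cluster -> tabulate."""
    rarefied = rarefy(reads_by_sample, depth=depth, seed=seed)
    pooled = [r for sample in sorted(rarefied) for r in rarefied[sample]]
    otus = greedy_cluster(sort_by_quality(pooled),
                          identity_threshold=identity_threshold)
    assignments = assign_representative_taxonomy(otus, index)
    table = build_otu_table(otus, sorted(rarefied), assignments)
    return table, otus
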