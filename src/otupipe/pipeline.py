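"""End-to-end orchestration of the amplicon analysis.

Stage order follows the original pyrosequencing workflow: demultiplex and QC
the reads, remove chimeras against the reference database, rarefy each
sample to a common depth, quality-sort and greedily cluster the pooled reads
into OTUs, then branch into alpha diversity, UniFrac beta diversity with
ordination, group statistics on genus/phylum abundances, biomarker
correlations, and qPCR concordance. A run is fully determined by
(config, seed); outputs are plain-text TSV/FASTA/newick/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta as beta_mod
from . import cluster as cluster_mod
from . import diversity as div_mod
from . import stats as stats_mod
from .io import Read, read_fasta, read_fastq, read_tsv, write_fasta, write_tsv
from .qc import QCReport, run_qc
from .search import ReferenceIndex, screen_chimeras
from .simulate import (ReferenceRecord, StudyConfig, SyntheticStudy,
                       generate_study)

logger = logging.getLogger(__name__)

CONTRASTS = [("HC", "CD"), ("HC", "UC"), ("CD", "UC")]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name and an exit code."""

    def __init__(self, stage: str, message: str, exit_code: int = 1):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """Thresholds and paths of a pipeline run."""

    seed: int = 0
    depth: int = 3000
    identity: float = 0.96
    qv_threshold: float = 25.0
    chimera_coverage: float = 0.90
    length_exception: int = 400
    species_identity: float = 0.97
    genus_identity: float = 0.95
    phylum_identity: float = 0.80
    max_primer_mismatch: int = 2
    primer_require: str = "both"
    fwd_primer: str = ""
    rev_primer: str = ""
    n_dominant_genera: int = 14
    paths: dict[str, str] = field(default_factory=dict)
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for name in ("identity", "chimera_coverage", "species_identity",
                     "genus_identity", "phylum_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.qv_threshold < 0:
            raise ValueError("qv_threshold must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunManifest:
    """Reproducibility record: seed, parameters, per-stage read counts and
    output digests. Stage timings are logged but kept out of the serialized
    manifest so reruns with the same seed are byte-identical."""

    seed: int
    parameters: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def reconcile(self) -> None:
        c = self.stage_counts
        if c.get("assigned", 0) != (c.get("passed_qc", 0)
                                    + c.get("primer_fail_removed", 0)
                                    + c.get("low_quality_removed", 0)):
            raise PipelineError("manifest", "QC stage counts do not reconcile")
        if c.get("passed_qc", 0) != (c.get("passed_chimera", 0)
                                     + c.get("chimera_removed", 0)
                                     + c.get("no_hit_removed", 0)):
            raise PipelineError("manifest",
                                "chimera stage counts do not reconcile")

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "parameters": self.parameters,
                   "stage_counts": self.stage_counts, "digests": self.digests}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: QCReport
    chimera_counts: dict[str, int]
    chimera_ids: set[str]
    otu_table: cluster_mod.OTUTable
    otus: list[cluster_mod.OTU]
    diversity: pd.DataFrame
    diversity_summary: pd.DataFrame
    diversity_tests: pd.DataFrame
    tree_newick: str
    unifrac_weighted: "beta_mod.DistanceMatrix"
    unifrac_unweighted: "beta_mod.DistanceMatrix"
    pcoa: beta_mod.PCoAResult
    upgma_newick: str
    distance_tests: pd.DataFrame
    genus_abundance: pd.DataFrame
    genus_tests: pd.DataFrame
    phylum_tests: pd.DataFrame
    groups: pd.Series
    correlation: stats_mod.CorrelationMatrix | None = None
    qpcr_results: pd.DataFrame | None = None
    manifest: RunManifest | None = None


def load_reference(fasta_path: str, lineage_path: str) -> list[ReferenceRecord]:
    lineage = read_tsv(lineage_path, index_col=0)
    records = []
    for ref_id, seq in read_fasta(fasta_path):
        if ref_id not in lineage.index:
            raise PipelineError("load", f"no lineage for {ref_id}", 3)
        row = lineage.loc[ref_id]
        records.append(ReferenceRecord(
            ref_id, seq, (row["phylum"], row["genus"], row["species"])))
    return records


def _distance_tests(dm, groups: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within/between comparisons of pairwise distances (Student's t on
    pooled pairwise distances; pair non-independence is a documented caveat)."""
    long = beta_mod.distance_long_table(dm, groups)
    rows = []
    ibd = long.assign(kind2=np.where(
        (long.group_a == "HC") ^ (long.group_b == "HC"), "HC-vs-IBD",
        np.where((long.group_a == "HC") & (long.group_b == "HC"),
                 "HC-within", "IBD-within")))
    def _append(a, b, name_a, name_b):
        if len(a) < 2 or len(b) < 2:  # degenerate design (tiny studies)
            return
        r = stats_mod.compare_groups(a, b, mode="student",
                                     feature="weighted_unifrac",
                                     group_a=name_a, group_b=name_b)
        rows.append(dataclasses.asdict(r))

    _append(ibd.loc[ibd.kind2 == "HC-within", "distance"],
            ibd.loc[ibd.kind2 == "HC-vs-IBD", "distance"],
            "HC-within", "HC-vs-IBD")
    for ga, gb in CONTRASTS:
        _append(long.loc[long.contrast.isin([f"{ga}-{ga}", f"{gb}-{gb}"]),
                         "distance"],
                long.loc[long.contrast == "-".join(sorted((ga, gb))),
                         "distance"],
                f"{ga}/{gb}-within", f"{ga}-vs-{gb}")
    tests = pd.DataFrame(rows)
    tests["q"] = stats_mod.bh_adjust(tests["p"])
    return tests, long


def run_pipeline(config: PipelineConfig, *,
                 reads: list[Read] | None = None,
                 reference: list[ReferenceRecord] | None = None,
                 barcode_map: dict[str, str] | None = None,
                 metadata: pd.DataFrame | None = None,
                 biomarkers: pd.DataFrame | None = None,
                 qpcr: pd.DataFrame | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute all stages; any failure raises a stage-named PipelineError.

    Inputs may be passed in memory or resolved from ``config.paths``
    (keys: reads, reference, lineage, barcodes, metadata, biomarkers, qpcr).
    """
    timings: dict[str, float] = {}
    paths = config.paths

    def _load(stage: str):
        nonlocal reads, reference, barcode_map, metadata, biomarkers, qpcr
        try:
            if reads is None:
                reads = list(read_fastq(paths["reads"]))
            if reference is None:
                reference = load_reference(paths["reference"], paths["lineage"])
            if barcode_map is None:
                bc = read_tsv(paths["barcodes"], index_col=0)
                barcode_map = bc["barcode"].to_dict()
            if metadata is None:
                metadata = read_tsv(paths["metadata"], index_col=0)
            if biomarkers is None and "biomarkers" in paths:
                biomarkers = read_tsv(paths["biomarkers"], index_col=0)
            if qpcr is None and "qpcr" in paths:
                qpcr = read_tsv(paths["qpcr"], index_col=0)
        except FileNotFoundError as e:
            raise PipelineError(stage, f"missing input: {e}", 2) from e
        except (KeyError, ValueError) as e:
            raise PipelineError(stage, f"bad input: {e}", 3) from e

    t0 = time.perf_counter()
    _load("load")
    if not config.fwd_primer or not config.rev_primer:
        raise PipelineError("load", "primers must be configured", 3)
    groups = metadata["group"]
    timings["load"] = time.perf_counter() - t0

    manifest = RunManifest(seed=config.seed, parameters={
        k: v for k, v in dataclasses.asdict(config).items()
        if k not in ("paths", "outdir")})

    # --- QC ---------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        by_sample, qc_report = run_qc(
            reads, barcode_map, config.fwd_primer, config.rev_primer,
            max_mismatch=config.max_primer_mismatch,
            qv_threshold=config.qv_threshold,
            length_exception=config.length_exception,
            require=config.primer_require)
    except ValueError as e:
        raise PipelineError("qc", str(e), 3) from e
    timings["qc"] = time.perf_counter() - t0
    manifest.stage_counts.update(
        input=qc_report.input, assigned=qc_report.assigned,
        primer_fail_removed=qc_report.primer_fail_removed,
        low_quality_removed=qc_report.low_quality_removed,
        passed_qc=qc_report.passed)

    # --- chimera screen ---------------------------------------------------
    t0 = time.perf_counter()
    index = ReferenceIndex(reference)
    cleaned, chim_counts, chim_ids, nohit_ids = screen_chimeras(
        by_sample, index, coverage_threshold=config.chimera_coverage)
    timings["chimera"] = time.perf_counter() - t0
    manifest.stage_counts.update(
        chimera_removed=chim_counts["chimera_removed"],
        no_hit_removed=chim_counts["no_hit_removed"],
        passed_chimera=sum(len(v) for v in cleaned.values()))

    # --- rarefaction + clustering -----------------------------------------
    t0 = time.perf_counter()
    otu_table, otus = cluster_mod.cluster_pipeline(
        cleaned, index, depth=config.depth, seed=config.seed,
        identity_threshold=config.identity)
    if otu_table.counts.shape[1] == 0:
        raise PipelineError("cluster", "no sample survived rarefaction", 4)
    timings["cluster"] = time.perf_counter() - t0
    manifest.stage_counts.update(
        rarefied_samples=otu_table.counts.shape[1],
        pooled_rarefied_reads=int(otu_table.counts.to_numpy().sum()),
        otus=len(otus))

    # --- alpha diversity --------------------------------------------------
    t0 = time.perf_counter()
    diversity = div_mod.per_sample_diversity(otu_table.counts)
    div_summary = div_mod.group_summary(diversity, groups)
    metrics = [c for c in diversity.columns if c != "n_reads"]
    div_tests = stats_mod.compare_feature_table(
        diversity[metrics], groups, CONTRASTS, mode="auto")
    timings["diversity"] = time.perf_counter() - t0

    # --- beta diversity ---------------------------------------------------
    t0 = time.perf_counter()
    reps = [(o.otu_id, o.representative.sequence) for o in otus]
    tree = beta_mod.build_tree(reps)
    wu = beta_mod.unifrac_matrix(tree, otu_table.counts, "weighted",
                                 normalized=True)
    uu = beta_mod.unifrac_matrix(tree, otu_table.counts, "unweighted")
    ordination = beta_mod.pcoa(wu, axes=3)
    upgma_nwk, _ = beta_mod.upgma_dendrogram(wu)
    dist_tests, _ = _distance_tests(wu, groups)
    timings["beta"] = time.perf_counter() - t0

    # --- genus / phylum statistics ----------------------------------------
    t0 = time.perf_counter()
    genus_ab = otu_table.genus_relative_abundance()
    named = [g for g in genus_ab.columns if g != "unclassified"]
    dominant = (genus_ab[named].mean().sort_values(ascending=False)
                .head(config.n_dominant_genera).index.tolist())
    genus_tests = stats_mod.compare_feature_table(
        genus_ab[dominant], groups, CONTRASTS, mode="welch")
    phylum = otu_table.collapse("phylum")
    phylum_ab = (phylum / phylum.sum(axis=0)).T
    phylum_named = [p for p in phylum_ab.columns if p != "unclassified"]
    phylum_tests = stats_mod.compare_feature_table(
        phylum_ab[phylum_named], groups, CONTRASTS, mode="welch")
    timings["group_stats"] = time.perf_counter() - t0

    # --- biomarker correlations -------------------------------------------
    correlation = None
    if biomarkers is not None:
        t0 = time.perf_counter()
        correlation = stats_mod.pearson_matrix(genus_ab[dominant], biomarkers)
        timings["biomarkers"] = time.perf_counter() - t0

    # --- qPCR concordance ---------------------------------------------------
    qpcr_results = None
    if qpcr is not None:
        t0 = time.perf_counter()
        rows = []
        species_label = {r.ref_id: r.species for r in reference}
        for target in [c for c in qpcr.columns if c != "group"]:
            label = species_label.get(target, target)
            otu_ids = otu_table.taxonomy.index[
                otu_table.taxonomy["species"] == label]
            counts = otu_table.counts.loc[otu_ids].sum(axis=0)
            shared = counts.index.intersection(qpcr.index)
            r, p = stats_mod.qpcr_concordance(
                counts.loc[shared].to_numpy(),
                qpcr.loc[shared, target].to_numpy())
            rows.append({"target": target, "r": r, "p": p,
                         "n": len(shared), "n_otus": len(otu_ids)})
        qpcr_results = pd.DataFrame(rows).set_index("target")
        timings["qpcr"] = time.perf_counter() - t0

    manifest.timings = timings
    manifest.reconcile()
    for stage, dt in timings.items():
        logger.info("stage %s: %.2f s", stage, dt)

    result = PipelineResult(
        config=config, qc_report=qc_report, chimera_counts=chim_counts,
        chimera_ids=chim_ids | nohit_ids, otu_table=otu_table, otus=otus,
        diversity=diversity, diversity_summary=div_summary,
        diversity_tests=div_tests, tree_newick=beta_mod.tree_to_newick(tree),
        unifrac_weighted=wu, unifrac_unweighted=uu, pcoa=ordination,
        upgma_newick=upgma_nwk, distance_tests=dist_tests,
        genus_abundance=genus_ab, genus_tests=genus_tests,
        phylum_tests=phylum_tests, groups=groups, correlation=correlation,
        qpcr_results=qpcr_results, manifest=manifest)
    if outdir or config.outdir:
        write_outputs(result, Path(outdir or config.outdir))
    return result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = result.config.seed
    write_tsv(result.qc_report.to_frame(), outdir / "qc_report.tsv", seed=seed)
    chim = pd.DataFrame(sorted(result.chimera_ids), columns=["read_id"])
    write_tsv(chim, outdir / "chimera_reads.tsv", seed=seed, index=False)
    write_tsv(result.otu_table.counts, outdir / "otu_table.tsv", seed=seed)
    triplets = (result.otu_table.counts.stack().rename("count")
                .reset_index().rename(columns={"level_1": "sample_id"}))
    write_tsv(triplets[triplets["count"] > 0],
              outdir / "otu_table_triplets.tsv", seed=seed, index=False)
    write_tsv(result.otu_table.taxonomy, outdir / "otu_taxonomy.tsv", seed=seed)
    write_fasta(((o.otu_id, o.representative.sequence) for o in result.otus),
                outdir / "representatives.fasta", seed=seed)
    membership = pd.DataFrame(
        [(o.otu_id, m.read_id, m.sample_id) for o in result.otus
         for m in o.members],
        columns=["otu_id", "read_id", "sample_id"])
    write_tsv(membership, outdir / "otu_membership.tsv", seed=seed, index=False)
    write_tsv(result.genus_abundance, outdir / "genus_abundance.tsv", seed=seed)
    write_tsv(result.diversity, outdir / "diversity.tsv", seed=seed)
    write_tsv(result.diversity_summary, outdir / "diversity_group_summary.tsv",
              seed=seed)
    write_tsv(result.diversity_tests, outdir / "diversity_tests.tsv",
              seed=seed, index=False)
    (outdir / "otu_tree.nwk").write_text(result.tree_newick + "\n")
    for name, dm in (("weighted", result.unifrac_weighted),
                     ("unweighted", result.unifrac_unweighted)):
        df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        df.index.name = "sample_id"
        write_tsv(df, outdir / f"unifrac_{name}.tsv", seed=seed)
    write_tsv(result.pcoa.coordinates, outdir / "pcoa_coordinates.tsv",
              seed=seed)
    eig = pd.DataFrame({"eigenvalue": result.pcoa.eigenvalues})
    eig["proportion_explained"] = [
        *result.pcoa.proportion_explained,
        *[np.nan] * (len(eig) - len(result.pcoa.proportion_explained))]
    write_tsv(eig, outdir / "pcoa_eigenvalues.tsv", seed=seed, index=False)
    (outdir / "upgma_dendrogram.nwk").write_text(result.upgma_newick + "\n")
    write_tsv(result.distance_tests, outdir / "distance_tests.tsv", seed=seed,
              index=False)
    write_tsv(result.genus_tests, outdir / "genus_tests.tsv", seed=seed,
              index=False)
    write_tsv(result.phylum_tests, outdir / "phylum_tests.tsv", seed=seed,
              index=False)
    if result.correlation is not None:
        write_tsv(result.correlation.r,
                  outdir / "biomarker_correlation_r.tsv", seed=seed)
        write_tsv(result.correlation.q,
                  outdir / "biomarker_correlation_q.tsv", seed=seed)
        write_tsv(result.correlation.stars,
                  outdir / "biomarker_correlation_stars.tsv", seed=seed)
    if result.qpcr_results is not None:
        write_tsv(result.qpcr_results, outdir / "qpcr_concordance.tsv",
                  seed=seed)
    if result.manifest is not None:
        for path in sorted(outdir.iterdir()):
            if path.name != "run_manifest.json" and path.is_file():
                result.manifest.digests[path.name] = _sha256(path)
        result.manifest.to_json(outdir / "run_manifest.json")


# ---------------------------------------------------------------------------
# Synthetic mode: generate, run, score against ground truth
# ---------------------------------------------------------------------------

def pipeline_config_for_study(study_cfg: StudyConfig, depth: int = 3000,
                              **overrides) -> PipelineConfig:
    return PipelineConfig(seed=study_cfg.seed, depth=depth,
                          fwd_primer=study_cfg.fwd_primer,
                          rev_primer=study_cfg.rev_primer, **overrides)


def ground_truth_report(study: SyntheticStudy,
                        result: PipelineResult) -> dict:
    """Score the recovered study against the generator's ground truth."""
    manifest = study.manifest
    true_genus = study.true_genus_abundance()
    recovered = result.genus_abundance
    shared = recovered.index.intersection(true_genus.index)
    genera = [g for g in true_genus.columns if g in recovered.columns]
    diff = (recovered.loc[shared, genera] - true_genus.loc[shared, genera])
    major = true_genus.loc[shared].mean() > 0.05
    major_genera = [g for g in genera if major.get(g, False)]

    truth_ids = set(manifest.loc[manifest.is_chimera, "read_id"])
    # only reads that reached the chimera stage can be flagged
    flagged = result.chimera_ids
    reachable = truth_ids - {
        rid for rid in truth_ids
        if rid in set(manifest.loc[manifest.is_low_quality, "read_id"])}
    tp = len(truth_ids & flagged)
    recall = tp / len(reachable) if reachable else float("nan")
    precision = tp / len(flagged) if flagged else float("nan")

    effects = {}
    gt = result.genus_tests
    for genus, fold in study.config.effect_sizes.items():
        sub = gt[(gt.feature == genus) & (gt.group_a == "HC")]
        means_hc = recovered.loc[result.groups.reindex(shared) == "HC", genus].mean() \
            if genus in recovered.columns else float("nan")
        entry = {}
        for _, row in sub.iterrows():
            other = row.group_b
            means_other = recovered.loc[
                result.groups.reindex(shared) == other, genus].mean()
            direction_ok = ((means_other > means_hc) == (fold > 1.0))
            entry[other] = {"q": float(row.q),
                            "direction_recovered": bool(direction_ok)}
        effects[genus] = entry

    biomarker = {}
    if result.correlation is not None:
        for (genus, marker), target in \
                study.config.biomarker_correlations.items():
            if genus in result.correlation.r.index \
                    and marker in result.correlation.r.columns:
                r = float(result.correlation.r.loc[genus, marker])
                n = study.biomarkers.shape[0]
                lo, hi = stats_mod.fisher_z_interval(target, n)
                biomarker[f"{genus}:{marker}"] = {
                    "target_r": target, "recovered_r": r, "n": n,
                    "within_fisher_ci": bool(lo <= r <= hi)}

    qpcr = {}
    if result.qpcr_results is not None:
        for target, row in result.qpcr_results.iterrows():
            qpcr[target] = {"r": float(row.r), "p": float(row.p)}

    return {
        "n_samples": int(len(shared)),
        "otu_count": len(result.otus),
        "n_reference_species": len(study.db),
        "genus_abundance_max_abs_error_major": float(
            diff[major_genera].abs().max().max()) if major_genera else None,
        "genus_abundance_mean_abs_error": float(diff.abs().mean().mean()),
        "chimera_recall": recall,
        "chimera_precision": precision,
        "effect_recovery": effects,
        "biomarker_recovery": biomarker,
        "qpcr_concordance": qpcr,
    }


def simulate_and_run(study_cfg: StudyConfig | None = None,
                     pipe_cfg: PipelineConfig | None = None,
                     outdir: str | Path | None = None,
                     ) -> tuple[SyntheticStudy, PipelineResult, dict]:
    """Generate a synthetic study, run the full pipeline on it, and score
    the result against ground truth."""
    study_cfg = study_cfg or StudyConfig()
    study = generate_study(study_cfg)
    if pipe_cfg is None:
        pipe_cfg = pipeline_config_for_study(study_cfg)
    result = run_pipeline(
        pipe_cfg, reads=study.reads, reference=study.db,
        barcode_map=study.barcode_map, metadata=study.metadata,
        biomarkers=study.biomarkers, qpcr=study.qpcr, outdir=outdir)
    report = ground_truth_report(study, result)
    if outdir is not None:
        with open(Path(outdir) / "ground_truth_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return study, result, report
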