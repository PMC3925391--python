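"""Tests of the synthetic-study generator against its stated guarantees."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats as sps

from otupipe.search import ReferenceIndex, detect_chimera
from otupipe.simulate import (StudyConfig, _linear_with_target_r,
                              generate_biomarkers, generate_profiles,
                              generate_qpcr, generate_reads,
                              generate_reference_db, generate_study,
                              make_barcodes)
from otupipe.beta import alignment_distance


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------

def test_reference_db_is_deterministic():
    a = generate_reference_db(14, 3, seed=1)
    b = generate_reference_db(14, 3, seed=1)
    assert [(r.ref_id, r.sequence, r.lineage) for r in a] \
        == [(r.ref_id, r.sequence, r.lineage) for r in b]
    c = generate_reference_db(14, 3, seed=2)
    assert [r.sequence for r in a] != [r.sequence for r in c]


def test_reference_db_genus_separation():
    """Cross-genus identity stays below 92% (exhaustive pairwise check);
    congeneric species stay close enough to share a genus call."""
    db = generate_reference_db(14, 3, seed=1)
    for i, a in enumerate(db):
        for b in db[i + 1:]:
            identity = 1.0 - alignment_distance(a.sequence, b.sequence)
            if a.genus != b.genus:
                assert identity < 0.92
            else:
                assert 0.90 <= identity < 0.99


def test_reference_db_agrees_with_affine_alignment_oracle():
    """Edit-distance identities match an independent affine-gap global
    alignment on homologous (within-genus) pairs, where the alignment is
    unambiguous."""
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-2, open_gap_score=-5,
                                    extend_gap_score=-2)
    db = generate_reference_db(6, 3, seed=4)
    pairs = [(a, b) for i, a in enumerate(db) for b in db[i + 1:]
             if a.genus == b.genus]
    assert pairs
    for a, b in pairs:
        aln = aligner.align(a.sequence, b.sequence)[0]
        counts = aln.counts()
        oracle = counts.identities / (counts.identities + counts.mismatches
                                      + counts.gaps)
        mine = 1.0 - alignment_distance(a.sequence, b.sequence)
        assert mine == pytest.approx(oracle, abs=0.01)


def test_reference_db_contains_long_record():
    db = generate_reference_db(14, 3, seed=1)
    lengths = [len(r.sequence) for r in db]
    assert max(lengths) > 431
    assert all(300 <= n for n in lengths)


def test_reference_db_rejects_bad_sizes():
    with pytest.raises(ValueError):
        generate_reference_db(1, 3, seed=0)
    with pytest.raises(ValueError):
        generate_reference_db(5, 0, seed=0)


# ---------------------------------------------------------------------------
# community profiles
# ---------------------------------------------------------------------------

def _group_means(profiles, db, genus):
    by_group = {}
    for p in profiles:
        by_group.setdefault(p.group, []).append(
            p.genus_proportions(db).get(genus, 0.0))
    return {g: np.mean(v) for g, v in by_group.items()}


def test_profiles_sum_to_one_and_null_effects_balance():
    cfg = StudyConfig(n_per_group=(25, 25, 25), effect_sizes={},
                      biomarker_correlations={}, seed=2)
    db = generate_reference_db(seed=2)
    profiles = generate_profiles(cfg, db)
    for p in profiles:
        assert sum(p.proportions.values()) == pytest.approx(1.0, abs=1e-9)
    means = _group_means(profiles, db, "Prevotella")
    assert abs(means["CD"] - means["HC"]) < 0.03
    assert abs(means["UC"] - means["HC"]) < 0.03


def test_profiles_fold_change_shifts_group_means():
    db = generate_reference_db(seed=2)
    cfg = StudyConfig(n_per_group=(24, 21, 14),
                      effect_sizes={"Prevotella": 3.0},
                      biomarker_correlations={}, seed=2)
    means = _group_means(generate_profiles(cfg, db), db, "Prevotella")
    assert means["CD"] > means["HC"]
    assert means["UC"] > means["HC"]


def test_profiles_effect_size_monotonicity():
    """Larger configured fold change -> larger realized group difference."""
    db = generate_reference_db(seed=2)
    gaps = []
    for fold in (1.5, 2.5, 4.0):
        cfg = StudyConfig(n_per_group=(24, 21, 14),
                          effect_sizes={"Prevotella": fold},
                          biomarker_correlations={}, seed=2)
        means = _group_means(generate_profiles(cfg, db), db, "Prevotella")
        gaps.append(means["CD"] - means["HC"])
    assert gaps[0] < gaps[1] < gaps[2]


def test_profiles_reject_unknown_genus():
    db = generate_reference_db(seed=1)
    cfg = StudyConfig(effect_sizes={"Klebsiella": 2.0},
                      biomarker_correlations={})
    with pytest.raises(ValueError, match="unknown genera"):
        generate_profiles(cfg, db)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def test_reads_zero_chimera_rate(clean_study):
    assert not clean_study.manifest.is_chimera.any()
    assert not clean_study.manifest.is_low_quality.any()


def test_read_structure_matches_template(clean_study):
    """Error-free reads are exactly barcode + primer + template + primer."""
    cfg = clean_study.config
    by_ref = {r.ref_id: r.sequence for r in clean_study.db}
    from otupipe.io import reverse_complement

    rev_site = reverse_complement(cfg.rev_primer)
    lookup = {r.read_id: r for r in clean_study.reads}
    for row in clean_study.manifest.head(50).itertuples():
        read = lookup[row.read_id]
        bc = clean_study.barcode_map[row.sample_id]
        expected = bc + cfg.fwd_primer + by_ref[row.source] + rev_site
        assert read.sequence == expected


def test_chimera_and_lowq_fractions_within_binomial_interval(default_run):
    """Observed chimeric and sub-QV25 fractions sit in the exact binomial
    99% interval of their configured rates (0.46% / 0.75%)."""
    study, _, _ = default_run
    m = study.manifest
    n = len(m)
    for column, rate in (("is_chimera", study.config.chimera_rate),
                         ("is_low_quality", study.config.low_quality_fraction)):
        k = int(m[column].sum())
        lo, hi = sps.binom.ppf([0.005, 0.995], n, rate)
        assert lo <= k <= hi, f"{column}: {k} outside [{lo}, {hi}]"
    # mean-QV < 25 is exactly the manifest's low-quality flag by construction
    flagged = {r.read_id for r in study.reads if r.mean_qv < 25.0}
    truth = set(m.loc[m.is_low_quality, "read_id"])
    assert flagged == truth


def test_manifest_one_row_per_read(small_study):
    ids = [r.read_id for r in small_study.reads]
    assert sorted(ids) == sorted(small_study.manifest.read_id)
    assert small_study.manifest.read_id.is_unique


def test_chimeras_cover_each_parent_below_90pct(small_study):
    """Constructed chimeras align to either parent over <90% of their length
    (checked with the coverage oracle of the reference search)."""
    index = ReferenceIndex(small_study.db)
    chim = small_study.manifest[small_study.manifest.is_chimera]
    lookup = {r.read_id: r for r in small_study.reads}
    cfg = small_study.config
    n_bc = len(next(iter(small_study.barcode_map.values())))
    for row in chim.head(10).itertuples():
        read = lookup[row.read_id]
        insert = read.sequence[n_bc + len(cfg.fwd_primer):
                               len(read.sequence) - len(cfg.rev_primer)]
        for parent in (row.parent_a, row.parent_b):
            assert index.local_coverage(insert, parent) < 0.90


def test_reads_fully_deterministic(tmp_path):
    cfg = StudyConfig(n_per_group=(2, 2, 2), reads_per_sample=100, seed=9,
                      biomarker_n_per_group=(2, 2, 2))
    digests = []
    for sub in ("a", "b"):
        study = generate_study(cfg)
        outdir = tmp_path / sub
        study.write(outdir)
        digests.append({
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(outdir).iterdir())})
    assert digests[0] == digests[1]


def test_barcodes_unique_with_min_distance():
    codes = make_barcodes(59, seed=0)
    assert len(set(codes)) == 59
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            assert sum(x != y for x, y in zip(a, b)) >= 3


def test_generate_reads_rejects_empty():
    db = generate_reference_db(seed=1)
    cfg = StudyConfig()
    with pytest.raises(ValueError):
        generate_reads([], db, cfg)


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------

def test_biomarker_zero_target_r_gives_near_zero_sample_r():
    """Null target: sample correlations at n=39 center on 0 well within the
    +-0.15 band (averaged over replicates; a single draw has sd ~ 0.16)."""
    rng = np.random.default_rng(5)
    rs = []
    for _ in range(200):
        x = rng.dirichlet(np.ones(5), size=39)[:, 0]
        y = _linear_with_target_r(x, 0.0, None, rng)
        rs.append(np.corrcoef(x, y)[0, 1])
    assert abs(np.mean(rs)) < 0.15
    assert np.percentile(np.abs(rs), 50) < 0.15


def test_biomarker_zero_noise_gives_exact_unit_r():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    for r in (1.0, -1.0):
        y = _linear_with_target_r(x, r, 0.0, rng)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(r, abs=1e-12)


def test_biomarker_headline_correlation_recovered(default_run):
    """Streptococcus vs lysozyme generated at r = 0.63 lands inside the
    Fisher-z 95% interval at n = 39, on the true abundances."""
    from otupipe.stats import fisher_z_interval

    study, _, _ = default_run
    from otupipe.simulate import biomarker_subjects

    subjects = biomarker_subjects(study.profiles,
                                  study.config.biomarker_n_per_group)
    x = np.array([p.genus_proportions(study.db)["Streptococcus"]
                  for p in subjects])
    bio = study.biomarkers
    y = (bio["lysozyme"] / bio["total_protein"]).to_numpy()
    r = np.corrcoef(x, y)[0, 1]
    lo, hi = fisher_z_interval(0.63, len(subjects))
    assert lo <= r <= hi


def test_biomarker_config_validation():
    with pytest.raises(ValueError, match=r"\|r\| < 1"):
        StudyConfig(biomarker_correlations={("Prevotella", "IL-6"): 1.0})
    with pytest.raises(ValueError, match="more than one driver"):
        StudyConfig(biomarker_correlations={
            ("Prevotella", "IL-6"): 0.3, ("Streptococcus", "IL-6"): 0.4})


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def test_qpcr_zero_noise_concordant_with_true_proportions():
    from otupipe.stats import qpcr_concordance

    db = generate_reference_db(seed=6)
    cfg = StudyConfig(seed=6, qpcr_lognormal_sd=0.0,
                      n_per_group=(10, 10, 10))
    profiles = generate_profiles(cfg, db)
    table = generate_qpcr(profiles, db, cfg)
    target = cfg.qpcr_targets[0]
    reads = 3000 * np.array([p.proportions.get(target, 0.0)
                             for p in profiles])
    r, _ = qpcr_concordance(reads, table[target].to_numpy())
    assert r > 0.999


def test_qpcr_noise_envelope():
    """Lognormal noise with sd 0.5 keeps asinh concordance within the
    simulation-derived envelope (0.35, 0.95), mean above 0.55, over 50
    replicates. The envelope reflects the configured abundance spread: the
    target species' asinh-scale signal sd (~0.5) is comparable to the noise
    sd, capping attainable concordance well below the noiseless limit."""
    from otupipe.stats import qpcr_concordance

    db = generate_reference_db(seed=6)
    base = StudyConfig(seed=6, n_per_group=(24, 21, 14))
    profiles = generate_profiles(base, db)
    target = base.qpcr_targets[0]
    reads = 3000 * np.array([p.proportions.get(target, 0.0)
                             for p in profiles])
    rs = []
    for rep in range(50):
        cfg = StudyConfig(seed=1000 + rep, qpcr_lognormal_sd=0.5,
                          n_per_group=(24, 21, 14))
        table = generate_qpcr(profiles, db, cfg)
        r, _ = qpcr_concordance(reads, table[target].to_numpy())
        rs.append(r)
    assert 0.35 < min(rs) and max(rs) < 0.95
    assert np.mean(rs) > 0.55


def test_qpcr_absent_taxon_and_bad_scale():
    db = generate_reference_db(seed=6)
    cfg = StudyConfig(seed=6, n_per_group=(2, 2, 2))
    profiles = generate_profiles(cfg, db)
    target = cfg.qpcr_targets[0]
    for p in profiles:
        p.proportions[target] = 0.0
    assert (generate_qpcr(profiles, db, cfg)[target] == 0).all()
    with pytest.raises(ValueError):
        generate_qpcr(profiles, db, StudyConfig(qpcr_scale=0.0))
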