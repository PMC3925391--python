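"""Synthetic salivary-microbiota study generator with known ground truth.

The generator emulates the structure of a barcoded 454-style 16S rRNA V1-V2
amplicon survey of three subject groups (healthy controls and two IBD groups,
Crohn's disease and ulcerative colitis): a small reference database of
oral genera, per-subject community profiles with configurable disease effect
sizes, barcoded error-containing reads with a chimeric fraction, a salivary
biomarker panel correlated with genus abundances at configurable strengths,
and a qPCR quantification table for selected species. Every output is fully
determined by the configured seed, and a per-read manifest records the true
template (or chimera parents) of every read so each downstream pipeline stage
can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import Read, reverse_complement, write_fasta, write_fastq, write_tsv

# 27F-class forward / 338R-class reverse primer defaults. These are
# configurable placeholders with the right lengths and positions, not a claim
# about the study oligos (which are cited by name only in the source work).
DEFAULT_FWD_PRIMER = "AGAGTTTGATCCTGGCTCAG"
DEFAULT_REV_PRIMER = "TGCTGCCTCCCGTAGGAGT"

#: The 14 dominant salivary genera with their phyla.
DEFAULT_GENERA: list[tuple[str, str]] = [
    ("Streptococcus", "Firmicutes"),
    ("Prevotella", "Bacteroidetes"),
    ("Rothia", "Actinobacteria"),
    ("Neisseria", "Proteobacteria"),
    ("Granulicatella", "Firmicutes"),
    ("Actinomyces", "Actinobacteria"),
    ("Haemophilus", "Proteobacteria"),
    ("Veillonella", "Firmicutes"),
    ("Gemella", "Firmicutes"),
    ("Leptotrichia", "Fusobacteria"),
    ("Fusobacterium", "Fusobacteria"),
    ("Porphyromonas", "Bacteroidetes"),
    ("Lachnospiraceae", "Firmicutes"),
    ("Oribacterium", "Firmicutes"),
]

_NOTABLE_SPECIES = {
    "Streptococcus": "mitis",
    "Prevotella": "melaninogenica",
    "Rothia": "mucilaginosa",
    "Neisseria": "mucosa",
    "Granulicatella": "adiacens",
    "Actinomyces": "odontolyticus",
    "Haemophilus": "parainfluenzae",
    "Veillonella": "atypica",
    "Gemella": "sanguinis",
    "Leptotrichia": "buccalis",
    "Fusobacterium": "nucleatum",
    "Porphyromonas": "gingivalis",
    "Lachnospiraceae": "oral_taxon",
    "Oribacterium": "sinus",
}

#: Healthy-control mean genus composition (salivary-like, Streptococcus
#: dominated); renormalized over the genera actually present in the database.
DEFAULT_HC_GENUS_MEANS = {
    "Streptococcus": 0.33,
    "Prevotella": 0.13,
    "Rothia": 0.08,
    "Neisseria": 0.08,
    "Granulicatella": 0.03,
    "Actinomyces": 0.05,
    "Haemophilus": 0.07,
    "Veillonella": 0.06,
    "Gemella": 0.025,
    "Leptotrichia": 0.03,
    "Fusobacterium": 0.025,
    "Porphyromonas": 0.02,
    "Lachnospiraceae": 0.02,
    "Oribacterium": 0.015,
}

#: Multiplicative fold changes applied to IBD (CD and UC) profiles for the six
#: key genera: Prevotella and Veillonella up, the other four down.
DEFAULT_EFFECT_SIZES = {
    "Prevotella": 2.2,
    "Veillonella": 2.0,
    "Streptococcus": 0.62,
    "Haemophilus": 0.45,
    "Neisseria": 0.50,
    "Gemella": 0.45,
}

#: (driver genus, biomarker) -> target population Pearson r on the
#: total-protein-normalized scale. One driver genus per biomarker; further
#: genus-biomarker correlations arise from the compositional structure.
DEFAULT_BIOMARKER_CORRELATIONS = {
    ("Streptococcus", "lysozyme"): 0.63,
    ("Prevotella", "IL-1b"): 0.58,
    ("Streptococcus", "IgA"): -0.54,
    ("Streptococcus", "IL-8"): -0.51,
    ("Prevotella", "IL-6"): 0.45,
    ("Prevotella", "MCP-1"): 0.40,
    ("Veillonella", "TNF-a"): 0.40,
    ("Haemophilus", "LL-37"): -0.45,
}

#: Plausible central levels per biomarker on the total-protein-normalized
#: scale (arbitrary assay units); purely cosmetic, affine in the generated
#: values and therefore irrelevant to correlations.
_BIOMARKER_LEVELS = {
    "lysozyme": 80.0,
    "IgA": 120.0,
    "LL-37": 5.0,
    "IL-1b": 50.0,
    "IL-6": 10.0,
    "IL-8": 300.0,
    "TNF-a": 8.0,
    "MCP-1": 60.0,
}

GROUPS = ("HC", "CD", "UC")


@dataclass(slots=True)
class ReferenceRecord:
    """One 16S V1-V2-like reference sequence with a 3-rank lineage."""

    ref_id: str
    sequence: str
    lineage: tuple[str, str, str]  # (phylum, genus, species)

    @property
    def phylum(self) -> str:
        return self.lineage[0]

    @property
    def genus(self) -> str:
        return self.lineage[1]

    @property
    def species(self) -> str:
        return self.lineage[2]


@dataclass(slots=True)
class CommunityProfile:
    """True species-level composition of one subject's community."""

    sample_id: str
    group: str
    proportions: dict[str, float]  # ref_id -> fraction

    def genus_proportions(self, db: list[ReferenceRecord]) -> dict[str, float]:
        genus_of = {r.ref_id: r.genus for r in db}
        out: dict[str, float] = {}
        for ref_id, p in self.proportions.items():
            out[genus_of[ref_id]] = out.get(genus_of[ref_id], 0.0) + p
        return out


@dataclass
class StudyConfig:
    """All knobs of the synthetic study; the seed fully determines output."""

    n_per_group: tuple[int, int, int] = (24, 21, 14)
    reads_per_sample: int = 5000
    chimera_rate: float = 0.0046
    error_rate: float = 0.005
    homopolymer_indel_rate: float = 0.002
    low_quality_fraction: float = 0.0075
    n_genera: int = 14
    n_species_per_genus: int = 3
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    hc_genus_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HC_GENUS_MEANS))
    biomarker_correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_CORRELATIONS))
    biomarker_n_per_group: tuple[int, int, int] = (15, 14, 10)
    qpcr_targets: tuple[str, ...] = (
        "Prevotella_melaninogenica", "Haemophilus_parainfluenzae")
    qpcr_scale: float = 1e5
    qpcr_lognormal_sd: float = 0.4
    dirichlet_concentration: float = 120.0
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    barcode_length: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chimera_rate", "error_rate", "homopolymer_indel_rate",
                     "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.n_genera < 2:
            raise ValueError("need at least 2 genera")
        if self.n_species_per_genus < 1:
            raise ValueError("need at least 1 species per genus")
        seen_markers: set[str] = set()
        for (genus, marker), r in self.biomarker_correlations.items():
            if abs(r) >= 1.0:
                raise ValueError(
                    f"target correlation for ({genus}, {marker}) must have "
                    f"|r| < 1, got {r}")
            if marker in seen_markers:
                raise ValueError(
                    f"biomarker {marker!r} has more than one driver genus")
            seen_markers.add(marker)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        d["biomarker_n_per_group"] = list(self.biomarker_n_per_group)
        d["qpcr_targets"] = list(self.qpcr_targets)
        d["biomarker_correlations"] = [
            {"genus": g, "biomarker": m, "r": float(r)}
            for (g, m), r in self.biomarker_correlations.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["n_per_group"] = tuple(d["n_per_group"])
        if "biomarker_n_per_group" in d:
            d["biomarker_n_per_group"] = tuple(d["biomarker_n_per_group"])
        if "qpcr_targets" in d:
            d["qpcr_targets"] = tuple(d["qpcr_targets"])
        corr = d.get("biomarker_correlations")
        if isinstance(corr, list):
            d["biomarker_correlations"] = {
                (e["genus"], e["biomarker"]): float(e["r"]) for e in corr
            }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def generate_reference_db(n_genera: int = 14, n_species_per_genus: int = 3,
                          seed: int = 0) -> list[ReferenceRecord]:
    """Generate a V1-V2-like reference database with known lineages.

    Genus consensus sequences are drawn independently (mutual identity is
    that of unrelated random DNA, far below the 92% bound that keeps 96%
    clustering and 95% genus assignment meaningful). Each species diverges
    from its genus consensus by ~2.5-3.5% substitutions, so congeneric
    species sit ~5-7% apart -- resolvable as separate OTUs at the 96%
    threshold while still collapsing at the genus rank. The last genus is a
    long-V1-V2 outlier (493 nt ancestor) emulating the rare species
    (Campylobacter-like) that motivate the >400 bp primer-check exception.
    """
    if n_genera < 2:
        raise ValueError("n_genera must be >= 2")
    if n_species_per_genus < 1:
        raise ValueError("n_species_per_genus must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    for gi in range(n_genera):
        if gi < len(DEFAULT_GENERA):
            genus, phylum = DEFAULT_GENERA[gi]
        else:
            genus, phylum = f"Genus{gi + 1:02d}", f"Phylum{gi % 5 + 1:02d}"
        # the last genus is a long-V1-V2 outlier (Campylobacter-like 493 nt),
        # exercising the >400 bp primer-check exception downstream
        length = 493 if gi == n_genera - 1 else int(rng.integers(300, 432))
        ancestor = _random_sequence(rng, length)
        for si in range(n_species_per_genus):
            if si == 0 and genus in _NOTABLE_SPECIES:
                epithet = _NOTABLE_SPECIES[genus]
            else:
                epithet = f"sp{si + 1}"
            rate = rng.uniform(0.025, 0.035)
            n_sub = max(1, int(round(rate * length)))
            seq = ancestor.copy()
            pos = rng.choice(length, n_sub, replace=False)
            for p in pos:
                alt = _BASES[_BASES != seq[p]]
                seq[p] = alt[rng.integers(0, 3)]
            records.append(ReferenceRecord(
                ref_id=f"{genus}_{epithet}",
                sequence=_to_str(seq),
                lineage=(phylum, genus, f"{genus} {epithet}"),
            ))
    ids = [r.ref_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ref_ids in generated database")
    return records


# ---------------------------------------------------------------------------
# Community profiles
# ---------------------------------------------------------------------------

def _sample_ids(n_per_group: tuple[int, int, int]) -> list[tuple[str, str]]:
    out = []
    for group, n in zip(GROUPS, n_per_group):
        out.extend((f"{group}{i + 1:02d}", group) for i in range(n))
    return out


def generate_profiles(config: StudyConfig,
                      db: list[ReferenceRecord]) -> list[CommunityProfile]:
    """Draw per-subject species compositions around a Streptococcus-dominated
    healthy baseline, applying the configured IBD fold changes to CD/UC."""
    genera = sorted({r.genus for r in db})
    unknown = set(config.effect_sizes) - set(genera)
    if unknown:
        raise ValueError(f"effect_sizes reference unknown genera: {sorted(unknown)}")
    base = np.array([config.hc_genus_means.get(g, 0.01) for g in genera])
    base = base / base.sum()
    species_by_genus = {
        g: sorted(r.ref_id for r in db if r.genus == g) for g in genera}
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    profiles: list[CommunityProfile] = []
    for sample_id, group in _sample_ids(config.n_per_group):
        genus_p = rng.dirichlet(base * config.dirichlet_concentration)
        if group != "HC":
            fold = np.array([config.effect_sizes.get(g, 1.0) for g in genera])
            genus_p = genus_p * fold
            genus_p = genus_p / genus_p.sum()
        proportions: dict[str, float] = {}
        for g, gp in zip(genera, genus_p):
            refs = species_by_genus[g]
            w = 0.55 ** np.arange(len(refs))
            w = w / w.sum()
            split = rng.dirichlet(w * 30.0) if len(refs) > 1 else np.array([1.0])
            for ref_id, frac in zip(refs, split):
                proportions[ref_id] = float(gp * frac)
        total = sum(proportions.values())
        if abs(total - 1.0) > 1e-9:
            proportions = {k: v / total for k, v in proportions.items()}
        profiles.append(CommunityProfile(sample_id, group, proportions))
    return profiles


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def make_barcodes(n: int, seed: int, length: int = 8,
                  min_distance: int = 3) -> list[str]:
    """Fixed-length barcodes with pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    codes: list[np.ndarray] = []
    while len(codes) < n:
        cand = _random_sequence(rng, length)
        if all(int((cand != c).sum()) >= min_distance for c in codes):
            codes.append(cand)
    return [_to_str(c) for c in codes]


def _mutate(template: str, rng: np.random.Generator, sub_rate: float,
            hp_indel_rate: float) -> str:
    """Apply substitution and homopolymer-context single-base indel errors."""
    arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8).copy()
    n = len(arr)
    n_sub = rng.binomial(n, sub_rate) if sub_rate > 0 else 0
    if n_sub:
        pos = rng.choice(n, n_sub, replace=False)
        for p in pos:
            alt = _BASES[_BASES != arr[p]]
            arr[p] = alt[rng.integers(0, 3)]
    if hp_indel_rate > 0:
        eligible = np.flatnonzero(arr[1:] == arr[:-1]) + 1
        n_ind = rng.binomial(len(eligible), hp_indel_rate) if len(eligible) else 0
        if n_ind:
            pos = np.sort(rng.choice(eligible, n_ind, replace=False))
            insert = rng.random(n_ind) < 0.5
            s = _to_str(arr)
            pieces: list[str] = []
            last = 0
            for p, ins in zip(pos.tolist(), insert.tolist()):
                if ins:  # duplicate the homopolymer base
                    pieces.append(s[last:p + 1])
                    pieces.append(s[p])
                    last = p + 1
                else:  # drop one base of the run
                    pieces.append(s[last:p])
                    last = p + 1
            pieces.append(s[last:])
            return "".join(pieces)
    return _to_str(arr)


def generate_reads(profiles: list[CommunityProfile],
                   db: list[ReferenceRecord],
                   config: StudyConfig,
                   barcode_map: dict[str, str] | None = None,
                   ) -> tuple[list[Read], pd.DataFrame, dict[str, str]]:
    """Emit barcoded, primer-flanked, error-containing reads plus a manifest.

    Each read is ``barcode + fwd_primer + template + revcomp(rev_primer)``;
    substitution and homopolymer-indel errors are applied to the template. A
    ``chimera_rate`` fraction of reads splice two parents from *different*
    genera at a breakpoint uniform in the middle 60% of the template, so the
    best single-parent match covers well under 90% of the read. Mean read
    quality follows a two-component mixture truncated away from the QV-25
    threshold (good >= 26, bad <= 24) with mixing weight
    ``low_quality_fraction``, making the sub-25 fraction exactly binomial.
    """
    if not profiles or config.reads_per_sample <= 0:
        raise ValueError("need at least one profile and a positive read count")
    if barcode_map is None:
        codes = make_barcodes(len(profiles), config.seed, config.barcode_length)
        barcode_map = {p.sample_id: c for p, c in zip(profiles, codes)}
    ref_ids = [r.ref_id for r in db]
    ref_seqs = [r.sequence for r in db]
    ref_genus = [r.genus for r in db]
    fwd = config.fwd_primer.upper()
    rev_site = reverse_complement(config.rev_primer.upper())
    ss = np.random.SeedSequence([int(config.seed), 3])
    reads: list[Read] = []
    manifest_rows: list[tuple] = []
    for prof, child in zip(profiles, ss.spawn(len(profiles))):
        rng = np.random.default_rng(child)
        bc = barcode_map[prof.sample_id]
        p_vec = np.array([prof.proportions.get(r, 0.0) for r in ref_ids])
        p_vec = p_vec / p_vec.sum()
        n = config.reads_per_sample
        source = rng.choice(len(ref_ids), size=n, p=p_vec)
        is_chim = rng.random(n) < config.chimera_rate
        is_low = rng.random(n) < config.low_quality_fraction
        means = np.where(
            is_low,
            np.clip(rng.normal(20.0, 3.0, n), 3.0, 24.0),
            np.clip(rng.normal(32.0, 2.0, n), 26.0, 40.0),
        )
        for i in range(n):
            a = int(source[i])
            if is_chim[i]:
                b = a
                for _ in range(64):
                    b = int(rng.choice(len(ref_ids), p=p_vec))
                    if ref_genus[b] != ref_genus[a]:
                        break
                else:
                    b = next(j for j in range(len(ref_ids))
                             if ref_genus[j] != ref_genus[a])
                u = rng.uniform(0.2, 0.8)
                template = (ref_seqs[a][: round(u * len(ref_seqs[a]))]
                            + ref_seqs[b][round(u * len(ref_seqs[b])):])
                parent_a, parent_b = ref_ids[a], ref_ids[b]
                source_id = f"{parent_a}|{parent_b}"
            else:
                template = ref_seqs[a]
                parent_a, parent_b = ref_ids[a], ""
                source_id = parent_a
            template = _mutate(template, rng, config.error_rate,
                               config.homopolymer_indel_rate)
            seq = bc + fwd + template + rev_site
            qual = np.clip(
                np.rint(means[i] + rng.normal(0.0, 1.5, len(seq))),
                2, 40).astype(np.int16)
            read_id = f"{prof.sample_id}_r{i:05d}"
            reads.append(Read(read_id, seq, qual))
            manifest_rows.append((read_id, prof.sample_id, source_id,
                                  parent_a, parent_b, bool(is_chim[i]),
                                  bool(is_low[i])))
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["read_id", "sample_id", "source", "parent_a", "parent_b",
                 "is_chimera", "is_low_quality"],
    )
    return reads, manifest, barcode_map


# ---------------------------------------------------------------------------
# Biomarkers and qPCR
# ---------------------------------------------------------------------------

def _linear_with_target_r(x: np.ndarray, r: float, noise_sd: float | None,
                          rng: np.random.Generator) -> np.ndarray:
    """y = sign(r)*x + noise with noise variance solved so that the population
    Pearson correlation (conditional on x) equals r. ``noise_sd=0`` gives the
    degenerate r = +-1 line."""
    sx = float(np.std(x))
    if sx == 0:
        raise ValueError("driver abundances have zero variance")
    if noise_sd is None:
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1")
        if r == 0.0:
            return rng.normal(0.0, 1.0, len(x))
        noise_sd = sx * np.sqrt(1.0 / r**2 - 1.0)
    return np.sign(r) * x + rng.normal(0.0, noise_sd, len(x))


def biomarker_subjects(profiles: list[CommunityProfile],
                       n_per_group: tuple[int, int, int]) -> list[CommunityProfile]:
    """The subset of subjects with enough saliva for the biomarker assays
    (first n per group, 15/14/10 by default)."""
    out: list[CommunityProfile] = []
    for group, n in zip(GROUPS, n_per_group):
        out.extend([p for p in profiles if p.group == group][:n])
    return out


def generate_biomarkers(profiles: list[CommunityProfile],
                        db: list[ReferenceRecord],
                        config: StudyConfig) -> pd.DataFrame:
    """Biomarker panel for the assayed subjects.

    For each configured (driver genus, biomarker, r), the normalized level is
    an affine function of the genus's true relative abundance plus Gaussian
    noise sized so the population correlation equals r. Emitted values are
    de-normalized (multiplied by the subject's total protein), so dividing by
    the ``total_protein`` column recovers the correlated scale exactly.
    """
    subjects = biomarker_subjects(profiles, config.biomarker_n_per_group)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4]))
    genus_ab = pd.DataFrame(
        [p.genus_proportions(db) for p in subjects],
        index=[p.sample_id for p in subjects]).fillna(0.0)
    total_protein = rng.lognormal(0.0, 0.25, len(subjects))
    table = pd.DataFrame({
        "group": [p.group for p in subjects],
        "total_protein": total_protein,
    }, index=pd.Index([p.sample_id for p in subjects], name="sample_id"))
    markers = sorted(_BIOMARKER_LEVELS)
    drivers = {m: (g, r) for (g, m), r in config.biomarker_correlations.items()}
    for marker in markers:
        level = _BIOMARKER_LEVELS[marker]
        if marker in drivers:
            genus, r = drivers[marker]
            if genus not in genus_ab.columns:
                raise ValueError(f"driver genus {genus!r} absent from profiles")
            y = _linear_with_target_r(genus_ab[genus].to_numpy(), r, None, rng)
            z = (y - y.mean()) / y.std()
            normalized = level * (1.0 + 0.25 * z)
        else:
            normalized = level * rng.lognormal(0.0, 0.25, len(subjects))
        table[marker] = normalized * total_protein
    return table


def generate_qpcr(profiles: list[CommunityProfile],
                  db: list[ReferenceRecord],
                  config: StudyConfig) -> pd.DataFrame:
    """Per-sample qPCR copy numbers for the configured target species:
    ``scale * true_proportion * lognormal noise`` (0 when absent)."""
    if config.qpcr_scale <= 0:
        raise ValueError("qpcr_scale must be positive")
    known = {r.ref_id for r in db}
    for t in config.qpcr_targets:
        if t not in known:
            raise ValueError(f"qPCR target {t!r} not in reference database")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 5]))
    table = pd.DataFrame({
        "group": [p.group for p in profiles],
    }, index=pd.Index([p.sample_id for p in profiles], name="sample_id"))
    for target in config.qpcr_targets:
        props = np.array([p.proportions.get(target, 0.0) for p in profiles])
        noise = rng.lognormal(0.0, config.qpcr_lognormal_sd, len(profiles))
        table[target] = np.where(
            props > 0, config.qpcr_scale * props * noise, 0.0)
    return table


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: StudyConfig
    db: list[ReferenceRecord]
    profiles: list[CommunityProfile]
    barcode_map: dict[str, str]
    reads: list[Read]
    manifest: pd.DataFrame
    biomarkers: pd.DataFrame
    qpcr: pd.DataFrame

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": [p.group for p in self.profiles]},
            index=pd.Index([p.sample_id for p in self.profiles],
                           name="sample_id"))

    def true_genus_abundance(self) -> pd.DataFrame:
        """samples x genera matrix of true relative abundances."""
        return pd.DataFrame(
            [p.genus_proportions(self.db) for p in self.profiles],
            index=[p.sample_id for p in self.profiles]).fillna(0.0)

    def lineage_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.ref_id, *r.lineage) for r in self.db],
            columns=["ref_id", "phylum", "genus", "species"],
        ).set_index("ref_id")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed = self.config.seed
        write_fasta(((r.ref_id, r.sequence) for r in self.db),
                    outdir / "reference.fasta", seed=seed)
        write_tsv(self.lineage_table(), outdir / "lineage.tsv", seed=seed)
        write_fastq(self.reads, outdir / "reads.fastq")
        write_tsv(pd.DataFrame(
            {"barcode": pd.Series(self.barcode_map)}).rename_axis("sample_id"),
            outdir / "barcodes.tsv", seed=seed)
        write_tsv(self.metadata, outdir / "metadata.tsv", seed=seed)
        prof = pd.DataFrame(
            [p.proportions for p in self.profiles],
            index=pd.Index([p.sample_id for p in self.profiles],
                           name="sample_id")).fillna(0.0)
        write_tsv(prof, outdir / "profiles.tsv", seed=seed)
        write_tsv(self.biomarkers, outdir / "biomarkers.tsv", seed=seed)
        write_tsv(self.qpcr, outdir / "qpcr.tsv", seed=seed)
        write_tsv(self.manifest.set_index("read_id"),
                  outdir / "manifest.tsv", seed=seed)
        self.config.to_yaml(outdir / "config.yaml")


def generate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate the complete synthetic study (database, profiles, reads,
    biomarkers, qPCR) from one config; fully deterministic in the seed."""
    config = config or StudyConfig()
    db = generate_reference_db(config.n_genera, config.n_species_per_genus,
                               seed=config.seed)
    profiles = generate_profiles(config, db)
    reads, manifest, barcode_map = generate_reads(profiles, db, config)
    biomarkers = generate_biomarkers(profiles, db, config)
    qpcr = generate_qpcr(profiles, db, config)
    return SyntheticStudy(config, db, profiles, barcode_map, reads, manifest,
                          biomarkers, qpcr)
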