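"""Read quality control for barcoded 454-style amplicon runs.

Stages, in order: exact-match barcode demultiplexing (barcode stripped),
primer presence check with a length exception for rare long V1-V2 templates
(reads lacking primers are kept anyway when the barcode-stripped read exceeds
400 bp), and a mean-quality filter that removes reads with average Phred
score strictly below 25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import Read, reverse_complement


@dataclass
class QCReport:
    """Per-stage read counts; fractions are relative to assigned reads."""

    input: int = 0
    assigned: int = 0
    primer_fail_removed: int = 0
    length_exception_kept: int = 0
    low_quality_removed: int = 0
    passed: int = 0
    extra: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.input >= self.assigned >= self.passed >= 0):
            raise ValueError("QC counts are not monotone across stages")
        if (self.assigned - self.primer_fail_removed - self.low_quality_removed
                != self.passed):
            raise ValueError("QC stage counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.input),
            ("assigned", self.assigned),
            ("primer_fail_removed", self.primer_fail_removed),
            ("length_exception_kept", self.length_exception_kept),
            ("low_quality_removed", self.low_quality_removed),
            ("passed", self.passed),
        ] + sorted(self.extra.items())
        denom = self.assigned or 1
        df = pd.DataFrame(rows, columns=["stage", "count"])
        df["fraction_of_assigned"] = df["count"] / denom
        return df.set_index("stage")


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming mismatches between equal-length strings, short-circuited."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def demultiplex(reads: list[Read], barcode_map: dict[str, str],
                ) -> tuple[list[Read], int]:
    """Assign reads to samples by exact barcode prefix match.

    The barcode is stripped from assigned reads (sequence and qualities);
    non-matching reads are returned unassigned in the count only. Duplicate
    or ragged-length barcodes are an error.
    """
    if not barcode_map:
        raise ValueError("empty barcode map")
    codes = list(barcode_map.values())
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate barcodes in barcode map")
    lengths = {len(c) for c in codes}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    bc_len = lengths.pop()
    lookup = {code: sample for sample, code in barcode_map.items()}
    assigned: list[Read] = []
    n_unassigned = 0
    for read in reads:
        sample = lookup.get(read.sequence[:bc_len])
        if sample is None:
            n_unassigned += 1
            continue
        assigned.append(Read(read.read_id, read.sequence[bc_len:],
                             read.qualities[bc_len:], sample_id=sample))
    return assigned, n_unassigned


def check_primers(read: Read, fwd_primer: str, rev_primer: str,
                  max_mismatch: int = 2, length_exception: int = 400,
                  require: str = "both") -> tuple[bool, bool, Read]:
    """Primer presence check with trimming and the long-read exception.

    Returns ``(keep, kept_by_length_exception, trimmed_read)``. The forward
    primer is sought at the 5' end and the reverse complement of the reverse
    primer at the 3' end, each within ``max_mismatch`` substitutions (no
    indels). With ``require="both"`` a read must carry both primers;
    ``require="either"`` keeps reads with at least one. Reads failing the
    primer rule are still kept when their barcode-stripped length (before
    primer trimming) exceeds ``length_exception``; any primer that *was*
    found is trimmed either way.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    if require not in ("both", "either"):
        raise ValueError("require must be 'both' or 'either'")
    seq = read.sequence
    fwd = fwd_primer.upper()
    rev_site = reverse_complement(rev_primer.upper())
    found_f = (len(seq) >= len(fwd)
               and _mismatches(seq[:len(fwd)], fwd, max_mismatch) <= max_mismatch)
    found_r = (len(seq) >= len(rev_site)
               and _mismatches(seq[-len(rev_site):], rev_site,
                               max_mismatch) <= max_mismatch)
    if len(seq) < len(fwd) + len(rev_site):
        found_f = found_r = False
    primer_ok = (found_f and found_r) if require == "both" else (found_f or found_r)
    by_length = not primer_ok and len(seq) > length_exception
    keep = primer_ok or by_length
    if not keep:
        return False, False, read
    start = len(fwd) if found_f else 0
    end = len(seq) - len(rev_site) if found_r else len(seq)
    trimmed = Read(read.read_id, seq[start:end], read.qualities[start:end],
                   sample_id=read.sample_id)
    return True, by_length, trimmed


def quality_filter(reads: list[Read], threshold: float = 25.0,
                   ) -> tuple[list[Read], int]:
    """Keep reads with mean QV >= threshold (removal rule is strict '<')."""
    passed: list[Read] = []
    removed = 0
    for read in reads:
        if len(read.qualities) == 0:
            raise ValueError(f"read {read.read_id} has no quality values")
        if read.mean_qv >= threshold:
            passed.append(read)
        else:
            removed += 1
    return passed, removed


def run_qc(reads: list[Read], barcode_map: dict[str, str], fwd_primer: str,
           rev_primer: str, max_mismatch: int = 2, qv_threshold: float = 25.0,
           length_exception: int = 400, require: str = "both",
           ) -> tuple[dict[str, list[Read]], QCReport]:
    """Demultiplex -> primer check/trim -> quality filter.

    Returns filter-passed reads grouped by sample plus the stage report.
    """
    report = QCReport(input=len(reads))
    assigned, _ = demultiplex(reads, barcode_map)
    report.assigned = len(assigned)
    primer_ok: list[Read] = []
    for read in assigned:
        keep, by_length, trimmed = check_primers(
            read, fwd_primer, rev_primer, max_mismatch=max_mismatch,
            length_exception=length_exception, require=require)
        if keep:
            primer_ok.append(trimmed)
            report.length_exception_kept += int(by_length)
        else:
            report.primer_fail_removed += 1
    passed, n_lowq = quality_filter(primer_ok, qv_threshold)
    report.low_quality_removed = n_lowq
    report.passed = len(passed)
    report.validate()
    by_sample: dict[str, list[Read]] = {}
    for read in passed:
        by_sample.setdefault(read.sample_id, []).append(read)
    return by_sample, report
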