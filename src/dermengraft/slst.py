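"""Single-locus sequence typing (SLST) of *Cutibacterium acnes* amplicon reads.

SLST resolves *C. acnes* strains by one discriminatory locus; each database
record is the allele of a named type (A1, D1, H1, L1, C3, A5, ...).  Because
SLST databases hold only tens of short alleles, reads are typed by an
exhaustive best-Hamming-match scan (ungapped sliding comparison of the
shorter sequence along the longer) rather than a heuristic mapper: the read
is assigned to the unique allele with minimum mismatch count at its best
offset, provided that count does not exceed ``max_mismatch``.  Equidistant
ties are reported as ``ambiguous`` and excluded from counts; reads with no
allele in range are ``unassigned``.  Upstream, reads failing a mean-quality
or N-content gate are dropped as ``low_quality``.
"""

from __future__ import annotations

import dataclasses
import gzip
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SLSTDatabase",
    "AmpliconRead",
    "TypingConfig",
    "TypingResult",
    "quality_filter",
    "assign_read",
    "type_sample",
    "read_fastq",
]

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclasses.dataclass
class AmpliconRead:
    read_id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


class SLSTDatabase:
    """Allele id -> uppercase nucleotide sequence.

    IUPAC ambiguity codes are tolerated in database records (they count as
    mismatches during assignment) but the typing tool never emits them.
    """

    def __init__(self, alleles: dict[str, str]):
        if not alleles:
            raise ValueError("empty SLST database")
        clean: dict[str, str] = {}
        for aid, seq in alleles.items():
            if aid in clean:
                raise ValueError(f"duplicate allele id {aid}")
            s = str(seq).upper()
            if not s:
                raise ValueError(f"allele {aid}: empty sequence")
            clean[aid] = s
        self.alleles = clean
        self._ids = list(clean)
        self._arrays = {aid: np.frombuffer(s.encode(), dtype=np.uint8)
                        for aid, s in clean.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SLSTDatabase":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            records = {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(s), id=aid, description="") for aid, s in self.alleles.items()]
        SeqIO.write(recs, str(path), "fasta")

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)


@dataclasses.dataclass
class TypingConfig:
    min_mean_q: float = 20.0
    max_n_frac: float = 0.10
    max_mismatch: int = 3
    min_overlap: int = 50
    both_strands: bool = False


@dataclasses.dataclass
class TypingResult:
    """Per-sample typing outcome; read counts are conserved across buckets."""

    counts: Counter            # allele_id -> assigned reads
    n_reads: int
    n_unassigned: int
    n_ambiguous: int
    n_low_quality: int
    assignments: list[tuple[str, str]]  # (read_id, allele_id | outcome code)
    discard_reasons: Counter

    def check_conservation(self) -> None:
        total = sum(self.counts.values()) + self.n_unassigned + self.n_ambiguous + self.n_low_quality
        if total != self.n_reads:
            raise AssertionError(f"read-count conservation violated: {total} != {self.n_reads}")

    def proportions(self) -> dict[str, float]:
        tot = sum(self.counts.values())
        return {a: 100.0 * c / tot for a, c in self.counts.items()} if tot else {}


def quality_filter(
    read: AmpliconRead,
    min_mean_q: float = 20.0,
    max_n_frac: float = 0.10,
) -> tuple[bool, str]:
    """Gate a read on mean Phred quality and N-base fraction.

    Returns ``(passed, reason)``; the reason is one of ``""`` (pass),
    ``"empty"``, ``"low_quality"`` or ``"n_content"``.
    """
    if len(read.sequence) == 0:
        return False, "empty"
    if float(np.mean(read.qualities)) < min_mean_q:
        return False, "low_quality"
    n_frac = read.sequence.upper().count("N") / len(read.sequence)
    if n_frac > max_n_frac:
        return False, "n_content"
    return True, ""


def _best_hamming(read_arr: np.ndarray, allele_arr: np.ndarray) -> int:
    """Minimum mismatch count of an ungapped sliding comparison.

    The shorter sequence slides along the longer; at each offset the full
    shorter length is compared (overlap = min length).  N and ambiguity
    bytes simply fail the equality test, i.e. count as mismatches.
    """
    short, long_ = (read_arr, allele_arr) if len(read_arr) <= len(allele_arr) else (allele_arr, read_arr)
    ls, ll = len(short), len(long_)
    if ls == ll:
        return int((short != long_).sum())
    windows = np.lib.stride_tricks.sliding_window_view(long_, ls)
    return int((windows != short).sum(axis=1).min())


def assign_read(
    read: AmpliconRead | str,
    db: SLSTDatabase,
    max_mismatch: int = 3,
    min_overlap: int = 50,
    both_strands: bool = False,
) -> str:
    """Assign one (quality-passed) read to its nearest SLST allele.

    Returns the allele id, or ``"unassigned"`` (no allele within
    ``max_mismatch``, or read shorter than ``min_overlap``), or
    ``"ambiguous"`` (two or more alleles tie at the minimum distance).
    """
    seq = read if isinstance(read, str) else read.sequence
    seq = seq.upper()
    if len(seq) < min_overlap:
        return "unassigned"
    arrs = [np.frombuffer(seq.encode(), dtype=np.uint8)]
    if both_strands:
        rc = seq.translate(_COMPLEMENT)[::-1]
        arrs.append(np.frombuffer(rc.encode(), dtype=np.uint8))
    best_d = None
    best_id = None
    tie = False
    for aid in db._ids:
        allele = db._arrays[aid]
        d = min(_best_hamming(a, allele) for a in arrs)
        if best_d is None or d < best_d:
            best_d, best_id, tie = d, aid, False
        elif d == best_d:
            tie = True
    if best_d is None or best_d > max_mismatch:
        return "unassigned"
    if tie:
        return "ambiguous"
    return best_id


def type_sample(
    reads: Iterable[AmpliconRead],
    db: SLSTDatabase,
    config: TypingConfig | None = None,
) -> TypingResult:
    """Type every read of one sample and aggregate per-allele counts.

    Every input read lands in exactly one bucket (assigned to an allele,
    unassigned, ambiguous, or low_quality); the conservation invariant is
    asserted before returning.  An empty read iterator yields empty counts
    with a warning rather than an error.
    """
    cfg = config or TypingConfig()
    counts: Counter = Counter()
    reasons: Counter = Counter()
    assignments: list[tuple[str, str]] = []
    n = n_un = n_amb = n_lq = 0
    for read in reads:
        n += 1
        ok, reason = quality_filter(read, cfg.min_mean_q, cfg.max_n_frac)
        if not ok:
            n_lq += 1
            reasons[reason] += 1
            assignments.append((read.read_id, "low_quality"))
            continue
        hit = assign_read(read, db, cfg.max_mismatch, cfg.min_overlap, cfg.both_strands)
        if hit == "unassigned":
            n_un += 1
            reasons["unassigned"] += 1
        elif hit == "ambiguous":
            n_amb += 1
            reasons["ambiguous"] += 1
        else:
            counts[hit] += 1
        assignments.append((read.read_id, hit))
    if n == 0:
        import warnings

        warnings.warn("type_sample: empty read set")
    result = TypingResult(counts, n, n_un, n_amb, n_lq, assignments, reasons)
    result.check_conservation()
    return result


def read_fastq(path: str | Path) -> list[AmpliconRead]:
    """Load single-end reads from a FASTQ (Sanger/Phred+33) file, gzip ok."""
    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            out.append(AmpliconRead(rec.id, str(rec.seq),
                                    rec.letter_annotations["phred_quality"]))
    return out
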