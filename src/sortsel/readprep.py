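"""Quality filtering and merging of paired-end reads.

Read pairs are filtered on mean Phred quality (a pair is dropped when either
mate falls below the cutoff) and then merged into a single full-length
sequence by an overlap scan in the style of FLASH: among all candidate
overlap lengths the one minimizing the mismatch density wins, ties going to
the longer overlap. In the overlap, the consensus base is the one with the
higher Phred score (read 1 wins ties); the consensus quality is the maximum
of the two scores on agreement and their absolute difference on
disagreement.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadPair",
    "MergedRead",
    "MergeParams",
    "ReadQCStats",
    "mean_quality_filter",
    "merge_pair",
    "process_read_files",
    "write_fastq",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: sequences plus per-base Phred scores."""

    id: str
    read1_seq: str
    read1_qual: np.ndarray
    read2_seq: str
    read2_qual: np.ndarray

    def __post_init__(self) -> None:
        for seq, qual, mate in (
            (self.read1_seq, self.read1_qual, 1),
            (self.read2_seq, self.read2_qual, 2),
        ):
            if len(seq) == 0:
                raise ValueError(f"read {self.id!r}: empty mate {mate}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"read {self.id!r}: mate {mate} has {len(seq)} bases "
                    f"but {len(qual)} quality scores"
                )


@dataclass(frozen=True)
class MergedRead:
    """Consensus sequence assembled from one read pair."""

    id: str
    seq: str
    qual: np.ndarray
    overlap_len: int


@dataclass(frozen=True)
class MergeParams:
    """Overlap-merge parameters (FLASH-style defaults).

    max_overlap of None means "up to the shorter mate length".
    """

    min_overlap: int = 10
    max_overlap: int | None = None
    max_mismatch_density: float = 0.25
    min_mean_quality: float = 20.0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 < self.max_mismatch_density < 1.0:
            raise ValueError("max_mismatch_density must be in (0, 1)")


@dataclass
class ReadQCStats:
    """Per-run accounting; every input pair lands in exactly one bin."""

    n_pairs_in: int = 0
    n_fail_quality: int = 0
    n_fail_merge: int = 0
    n_merged: int = 0

    @property
    def fraction_passed(self) -> float:
        return self.n_merged / self.n_pairs_in if self.n_pairs_in else 0.0

    def to_dict(self) -> dict:
        return {
            "n_pairs_in": self.n_pairs_in,
            "n_fail_quality": self.n_fail_quality,
            "n_fail_merge": self.n_fail_merge,
            "n_merged": self.n_merged,
            "fraction_passed": self.fraction_passed,
        }


def mean_quality_filter(pair: ReadPair, min_mean_q: float = 20.0) -> bool:
    """True (keep) unless either mate's mean Phred is below ``min_mean_q``."""
    return (
        float(np.mean(pair.read1_qual)) >= min_mean_q
        and float(np.mean(pair.read2_qual)) >= min_mean_q
    )


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def merge_pair(pair: ReadPair, params: MergeParams = MergeParams()) -> MergedRead | None:
    """Merge a read pair into a consensus sequence, or None on failure.

    Read 2 is reverse-complemented, then every candidate overlap length L in
    [min_overlap, max_overlap] (comparing the 3' tail of read 1 with the
    5' head of the flipped read 2) is scored by mismatch density; the
    minimum-density overlap wins, ties to the longer L. Fails when the best
    density exceeds ``max_mismatch_density`` or no candidate exists.
    """
    a = _as_bytes(pair.read1_seq.upper())
    b_seq = reverse_complement(pair.read2_seq.upper())
    b = _as_bytes(b_seq)
    qa = np.asarray(pair.read1_qual)
    qb = np.asarray(pair.read2_qual)[::-1]

    n1, n2 = len(a), len(b)
    hi = min(n1, n2)
    if params.max_overlap is not None:
        hi = min(hi, params.max_overlap)
    if hi < params.min_overlap:
        return None

    best_len = 0
    best_mm = -1
    # longest first: the first zero-mismatch hit is globally optimal
    for length in range(hi, params.min_overlap - 1, -1):
        mm = int(np.count_nonzero(a[n1 - length :] != b[:length]))
        if mm == 0:
            best_len, best_mm = length, 0
            break
        if best_mm < 0 or mm / length < best_mm / best_len:
            best_len, best_mm = length, mm
    if best_len == 0 or best_mm / best_len > params.max_mismatch_density:
        return None

    L = best_len
    ova, ovb = a[n1 - L :], b[:L]
    ova_q, ovb_q = qa[n1 - L :], qb[:L]
    agree = ova == ovb
    take_a = agree | (ova_q >= ovb_q)
    cons = np.where(take_a, ova, ovb)
    cons_q = np.where(agree, np.maximum(ova_q, ovb_q), np.abs(ova_q - ovb_q))

    seq = pair.read1_seq.upper()[: n1 - L] + cons.tobytes().decode("ascii") + b_seq[L:]
    qual = np.concatenate([qa[: n1 - L], cons_q, qb[L:]]).astype(int)
    return MergedRead(id=pair.id, seq=seq, qual=qual, overlap_len=L)


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _phred_from_ascii(qual_str: str) -> np.ndarray:
    return np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8).astype(int) - 33


def iter_read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream mates from two FASTQ files (Phred+33, gzip-transparent)."""
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError(
                    f"mate-count mismatch: {r1_path} has more records than {r2_path}"
                ) from None
            title1, seq1, q1 = rec1
            title2, seq2, q2 = rec2
            yield ReadPair(
                id=title1.split()[0],
                read1_seq=seq1,
                read1_qual=_phred_from_ascii(q1),
                read2_seq=seq2,
                read2_qual=_phred_from_ascii(q2),
            )
        try:
            next(it2)
        except StopIteration:
            pass
        else:
            raise ValueError(
                f"mate-count mismatch: {r2_path} has more records than {r1_path}"
            )


def process_read_pairs(
    pairs: Iterable[ReadPair], params: MergeParams = MergeParams()
) -> tuple[list[MergedRead], ReadQCStats]:
    """Apply the mean-quality filter then overlap merging to a pair stream."""
    stats = ReadQCStats()
    merged: list[MergedRead] = []
    for pair in pairs:
        stats.n_pairs_in += 1
        if not mean_quality_filter(pair, params.min_mean_quality):
            stats.n_fail_quality += 1
            continue
        m = merge_pair(pair, params)
        if m is None:
            stats.n_fail_merge += 1
        else:
            stats.n_merged += 1
            merged.append(m)
    return merged, stats


def process_read_files(
    r1_path: str | Path,
    r2_path: str | Path,
    params: MergeParams = MergeParams(),
) -> tuple[list[MergedRead], ReadQCStats]:
    """Filter and merge two mate FASTQ files; see :func:`process_read_pairs`."""
    return process_read_pairs(iter_read_pairs(r1_path, r2_path), params)


def write_fastq(reads: Iterable[MergedRead], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for r in reads:
            qual = "".join(chr(min(int(q), 60) + 33) for q in r.qual)
            out.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_qc_stats(stats: ReadQCStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=2) + "\n")
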