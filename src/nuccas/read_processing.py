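"""Paired-end read processing: quality trimming, overlap merging, primer
removal, length filtering and library assignment.

The stages run in a fixed order — 3' quality trim, pair merge, primer
removal, length filter, identity-based assignment — with thresholds
defaulting to the assay's published settings (q30 trim; >=20-nt overlap with
<=2 mismatches; 174-220-nt merged length kept; assignment requires >=150
aligned columns and >=98.5% identity, best hit only with ties discarded).
Every input pair ends in exactly one terminal status, so stage tallies in
the run report always sum to the input size.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import edlib
import numpy as np

from .library_design import Library, revcomp

__all__ = [
    "Read",
    "MergedRead",
    "MergeRejection",
    "MatchResult",
    "PipelineParams",
    "quality_trim_3prime",
    "merge_pair",
    "trim_primers",
    "length_filter",
    "match_read",
    "count_reads",
    "process_read_pairs",
    "read_fastq_pairs",
]


@dataclass(frozen=True)
class Read:
    """A sequencing read: bases plus per-base Phred qualities."""

    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("seq and qual lengths differ")
        if any(q < 0 for q in self.qual):
            raise ValueError("qualities must be non-negative")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MergedRead:
    seq: str
    qual: tuple[int, ...]
    overlap_len: int
    n_diffs: int


@dataclass(frozen=True)
class MergeRejection:
    """Merge failure as a value: reason in {no_overlap, too_many_diffs,
    too_short_overlap}."""

    reason: str


@dataclass(frozen=True)
class MatchResult:
    """Assignment of one processed read against the library."""

    member_id: str | None
    identity: float
    aligned_cols: int
    status: str  # assigned | ambiguous | no_hit | too_short_alignment | low_identity


def quality_trim_3prime(read: Read, q_cutoff: int = 30) -> Read:
    """Trim low-quality 3' bases by the running-partial-sum rule.

    Starting from the 3' end, accumulate ``q_cutoff - q``; cut at the index
    where the partial sum is maximal, stopping once the sum goes negative
    (the BWA rule used by standard adapter/quality trimmers). A read whose
    3' bases are all above the cutoff is returned unchanged.
    """
    s = 0
    max_s = 0
    cut = len(read)
    for i in range(len(read) - 1, -1, -1):
        s += q_cutoff - read.qual[i]
        if s < 0:
            break
        if s > max_s:
            max_s = s
            cut = i
    return Read(read.seq[:cut], read.qual[:cut])


def _overlap_at(s1: str, s2: str, shift: int) -> tuple[int, int, int]:
    """Overlap [a, b) on s1 coordinates when s2 starts at ``shift``."""
    a = max(0, shift)
    b = min(len(s1), shift + len(s2))
    return a, b, b - a


def merge_pair(
    r1: Read,
    r2: Read,
    min_overlap: int = 20,
    max_diffs: int = 2,
) -> MergedRead | MergeRejection:
    """Merge a read pair into a consensus over their best overlap.

    ``r2`` is given in sequencing orientation and reverse-complemented
    internally. Among all relative placements with at most ``max_diffs``
    mismatches, the one maximizing overlap length wins (ties: fewer
    mismatches, then leftmost placement of read 2). At a mismatch the
    higher-quality base is kept; an equal-quality disagreement becomes N
    with quality 2. Matching bases keep the higher of the two qualities.
    """
    if len(r1) == 0 or len(r2) == 0:
        return MergeRejection("no_overlap")
    s1 = r1.seq
    s2 = revcomp(r2.seq)
    q1 = np.asarray(r1.qual)
    q2 = np.asarray(r2.qual)[::-1]
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)

    all_shifts = range(-(len(s2) - 1), len(s1))

    def diffs_at(shift: int) -> tuple[int, int]:
        a, b, ov = _overlap_at(s1, s2, shift)
        return ov, int(np.count_nonzero(a1[a:b] != a2[a - shift : b - shift]))

    best = None  # (overlap, -diffs, -shift) maximized
    # Enumerate placements in descending overlap so the scan can stop early.
    shifts = sorted(all_shifts, key=lambda sh: (-_overlap_at(s1, s2, sh)[2], sh))
    for shift in shifts:
        ov = _overlap_at(s1, s2, shift)[2]
        if (best is not None and ov < best[0]) or ov < min_overlap:
            break
        diffs = diffs_at(shift)[1]
        if diffs > max_diffs:
            continue
        cand = (ov, -diffs, -shift)
        if best is None or cand > best:
            best = cand
    if best is None:
        # No acceptable placement at or above min_overlap. Diagnose with the
        # highest-scoring placement overall (matches minus twice mismatches,
        # robust against short spurious overlaps): a convincing overlap that
        # is simply short reports too_short_overlap, a long overlap with too
        # many mismatches reports too_many_diffs.
        diag = max(
            all_shifts,
            key=lambda sh: (
                diffs_at(sh)[0] - 3 * diffs_at(sh)[1],
                diffs_at(sh)[0],
                -sh,
            ),
        )
        ov_d, diffs_d = diffs_at(diag)
        if ov_d >= min_overlap or diffs_d > max_diffs:
            return MergeRejection("too_many_diffs")
        return MergeRejection("too_short_overlap")
    ov, ndiffs, shift = best[0], -best[1], -best[2]

    a, b, _ = _overlap_at(s1, s2, shift)
    seq = []
    qual = []
    lo = min(0, shift)
    hi = max(len(s1), shift + len(s2))
    for pos in range(lo, hi):
        in1 = 0 <= pos < len(s1)
        in2 = 0 <= pos - shift < len(s2)
        if in1 and in2:
            c1, c2 = s1[pos], s2[pos - shift]
            v1, v2 = int(q1[pos]), int(q2[pos - shift])
            if c1 == c2:
                seq.append(c1)
                qual.append(max(v1, v2))
            elif v1 > v2:
                seq.append(c1)
                qual.append(v1)
            elif v2 > v1:
                seq.append(c2)
                qual.append(v2)
            else:
                seq.append("N")
                qual.append(2)
        elif in1:
            seq.append(s1[pos])
            qual.append(int(q1[pos]))
        else:
            seq.append(s2[pos - shift])
            qual.append(int(q2[pos - shift]))
    return MergedRead("".join(seq), tuple(qual), overlap_len=ov, n_diffs=ndiffs)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_primers(
    seq: str, primer_5: str, primer_3: str, max_error_rate: float = 0.1
) -> str:
    """Remove terminal primer matches from a merged read.

    A primer is removed when the corresponding terminal window matches it
    with at most ``floor(max_error_rate * len(primer))`` mismatches; the
    sequence is untouched where no match is found.
    """
    if not primer_5 or not primer_3:
        raise ValueError("primers must be non-empty")
    out = seq
    k5 = len(primer_5)
    if len(out) >= k5 and _hamming(out[:k5], primer_5) <= int(max_error_rate * k5):
        out = out[k5:]
    k3 = len(primer_3)
    if len(out) >= k3 and _hamming(out[-k3:], primer_3) <= int(max_error_rate * k3):
        out = out[:-k3]
    return out


def length_filter(seq: str, min_len: int = 174, max_len: int = 220) -> bool:
    """Keep iff min_len <= len(seq) <= max_len (bounds inclusive)."""
    return min_len <= len(seq) <= max_len


def _identity_from_alignment(result: dict, query: str, target: str) -> tuple[float, int]:
    """Identity = matching columns / alignment columns; N is a wildcard."""
    nice = edlib.getNiceAlignment(result, query, target)
    qa = nice["query_aligned"]
    ta = nice["target_aligned"]
    cols = len(qa)
    matches = sum(
        1 for cq, ct in zip(qa, ta) if cq == ct or cq == "N" or ct == "N"
    )
    return (matches / cols if cols else 0.0), cols


def match_read(
    seq: str,
    library: Library | Mapping[str, str],
    min_identity: float = 0.985,
    min_cols: int = 150,
) -> MatchResult:
    """Assign a processed read to its best library member.

    Each member is aligned end-free (the read must align in full, terminal
    overhangs on the member are unpenalized and excluded from the column
    count). The hit with the highest identity wins; an exact identity tie
    between distinct members is reported as ambiguous rather than resolved
    arbitrarily, since adjacent tiling members are near-duplicates.
    """
    seqs = library.sequences() if isinstance(library, Library) else dict(library)
    if not seqs:
        raise ValueError("library is empty")
    if not seq:
        return MatchResult(None, 0.0, 0, "no_hit")
    best_id: str | None = None
    best_identity = -1.0
    best_cols = 0
    tie = False
    for member_id, member_seq in seqs.items():
        res = edlib.align(seq, member_seq, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        identity, cols = _identity_from_alignment(res, seq, member_seq)
        if identity > best_identity:
            best_id, best_identity, best_cols, tie = member_id, identity, cols, False
        elif identity == best_identity:
            tie = True
    if best_id is None:
        return MatchResult(None, 0.0, 0, "no_hit")
    if best_cols < min_cols:
        return MatchResult(None, best_identity, best_cols, "too_short_alignment")
    if best_identity < min_identity:
        return MatchResult(None, best_identity, best_cols, "low_identity")
    if tie:
        return MatchResult(None, best_identity, best_cols, "ambiguous")
    return MatchResult(best_id, best_identity, best_cols, "assigned")


def count_reads(results: Iterable[MatchResult]) -> tuple[dict[str, int], dict[str, int]]:
    """Tally assigned reads per member and non-assigned reads per status.

    Returns ``(counts, rejections)``; their totals sum to the input size.
    """
    counts: dict[str, int] = {}
    rejections: dict[str, int] = {}
    for r in results:
        if r.status == "assigned":
            counts[r.member_id] = counts.get(r.member_id, 0) + 1
        else:
            rejections[r.status] = rejections.get(r.status, 0) + 1
    return counts, rejections


@dataclass(frozen=True)
class PipelineParams:
    """All pipeline thresholds, defaulting to the assay's published values."""

    q_cutoff: int = 30
    min_overlap: int = 20
    max_diffs: int = 2
    min_len: int = 174
    max_len: int = 220
    min_identity: float = 0.985
    min_cols: int = 150
    primer_5: str | None = None
    primer_3: str | None = None
    primer_error_rate: float = 0.1


def process_read_pairs(
    pairs: Iterable[tuple[Read, Read]],
    library: Library | Mapping[str, str],
    params: PipelineParams = PipelineParams(),
) -> tuple[dict[str, int], dict[str, int]]:
    """Run trim -> merge -> primer removal -> length filter -> match.

    Returns per-member assigned counts and a per-stage rejection tally; the
    two totals together equal the number of input pairs.
    """
    counts: dict[str, int] = {}
    report: dict[str, int] = {}

    def reject(reason: str) -> None:
        report[reason] = report.get(reason, 0) + 1

    for r1, r2 in pairs:
        r1t = quality_trim_3prime(r1, params.q_cutoff)
        r2t = quality_trim_3prime(r2, params.q_cutoff)
        merged = merge_pair(r1t, r2t, params.min_overlap, params.max_diffs)
        if isinstance(merged, MergeRejection):
            reject(f"merge_{merged.reason}")
            continue
        seq = merged.seq
        if params.primer_5 and params.primer_3:
            seq = trim_primers(
                seq, params.primer_5, params.primer_3, params.primer_error_rate
            )
        if not length_filter(seq, params.min_len, params.max_len):
            reject("length_filter")
            continue
        result = match_read(seq, library, params.min_identity, params.min_cols)
        if result.status == "assigned":
            counts[result.member_id] = counts.get(result.member_id, 0) + 1
        else:
            reject(result.status)
    return counts, report


def _phred_decode(qual_str: str) -> tuple[int, ...]:
    return tuple(ord(c) - 33 for c in qual_str)


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(path1, path2) -> Iterator[tuple[Read, Read]]:
    """Iterate paired reads from two (optionally gzipped) FASTQ files."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gzip(path1) as f1, _open_maybe_gzip(path2) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            yield Read(s1, _phred_decode(q1)), Read(s2, _phred_decode(q2))
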