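"""Per-base-pair MNase protection from fragment intervals.

MNase digests DNA not shielded by the histone octamer, so the fragments
that survive digestion pile up over the nucleosome core. Protection at a
base is the fraction of a member's reads whose fragment covers that base:
``coverage[bp] / total_reads``, computed per member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .library_design import NucleosomeFrame

__all__ = [
    "Fragment",
    "coverage",
    "mnase_protection",
    "windowed_mean",
    "align_profiles",
    "read_fragments_tsv",
    "write_fragments_tsv",
]


@dataclass(frozen=True)
class Fragment:
    """A sequenced fragment on one member, 0-based half-open [start, end)."""

    member_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def coverage(fragments: Sequence[Fragment], member_len: int) -> np.ndarray:
    """Per-bp count of fragments covering each position.

    Total coverage mass equals the summed fragment lengths.
    """
    cov = np.zeros(member_len, dtype=np.int64)
    for i, frag in enumerate(fragments):
        if frag.end > member_len:
            raise ValueError(
                f"fragment {i} [{frag.start}, {frag.end}) exceeds member length "
                f"{member_len}"
            )
        cov[frag.start : frag.end] += 1
    return cov


def mnase_protection(cov: np.ndarray, total_reads: int) -> np.ndarray:
    """Per-bp protection fraction: coverage / total reads for the member."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    return np.asarray(cov, dtype=float) / float(total_reads)


def windowed_mean(track: np.ndarray, center: int, half_width: int) -> float:
    """Mean of a per-bp track in [center-half_width, center+half_width]."""
    lo = max(0, center - half_width)
    hi = min(len(track), center + half_width + 1)
    if lo >= hi:
        raise ValueError("window falls outside the track")
    return float(np.mean(track[lo:hi]))


def align_profiles(
    cas9_profile: pd.DataFrame,
    mnase_track: np.ndarray,
    frame: NucleosomeFrame,
) -> pd.DataFrame:
    """Join a Cas9 protection profile with an MNase track by position.

    ``cas9_profile`` needs ``shl`` and ``mean`` columns (as produced by
    ``quantification.profile_by_position``); the MNase track is indexed by
    backbone bp via the shared frame. Positions carrying only one of the two
    measures get NaN for the other.
    """
    rows = {}
    for _, row in cas9_profile.iterrows():
        bp = frame.dyad_offset + frame.offset_of_shl(row["shl"])
        rows[bp] = {"shl": row["shl"], "cas9_protection": row["mean"]}
    for bp in range(len(mnase_track)):
        entry = rows.setdefault(
            bp, {"shl": frame.shl_of_offset(bp - frame.dyad_offset)}
        )
        entry["mnase_protection"] = float(mnase_track[bp])
    out = pd.DataFrame(
        [
            {"bp": bp, **vals}
            for bp, vals in sorted(rows.items())
        ]
    )
    for col in ("cas9_protection", "mnase_protection"):
        if col not in out.columns:
            out[col] = np.nan
    return out[["bp", "shl", "cas9_protection", "mnase_protection"]]


def read_fragments_tsv(path) -> list[Fragment]:
    """Read BED-like TSV fragments (member_id, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    return [
        Fragment(str(r.member_id), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_fragments_tsv(fragments: Sequence[Fragment], path) -> None:
    pd.DataFrame(
        [{"member_id": f.member_id, "start": f.start, "end": f.end} for f in fragments]
    ).to_csv(path, sep="\t", index=False)
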