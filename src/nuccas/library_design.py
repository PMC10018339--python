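"""Design of tiled nucleosome libraries and the SHL coordinate model.

A library is built from a nucleosome-positioning backbone (by default the
canonical 147-bp Widom 601 core embedded in fixed flanks, 230 bp total). A
target+PAM motif is substituted into the backbone at every position of a
tiling window, producing one library member per position. Each member is
annotated with the superhelical location (SHL) of its PAM center: the signed
distance from the nucleosome dyad in units of 10 bp, negative upstream and
positive downstream, with the dyad itself at SHL 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "WIDOM_601_CORE",
    "DEFAULT_BACKBONE",
    "NucleosomeFrame",
    "TargetMotif",
    "LibraryMember",
    "Library",
    "shl_of_offset",
    "offset_of_shl",
    "tile_motif",
    "make_background_fillers",
    "build_library",
    "default_design",
    "write_library_fasta",
    "read_library_fasta",
    "write_manifest",
]

#: Canonical 147-bp Widom 601 nucleosome positioning sequence (Watson strand).
WIDOM_601_CORE = (
    "CTGGAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTACGCG"
    "CTGTCCCCCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGATATATACATCCTGT"
)

# Fixed synthetic flanks bringing the construct to 230 bp; the amplification
# primers anneal to the outermost bases of these flanks.
LEFT_FLANK = "CTTAGGCTATCGGGGTACTTTCGCATCTGCAGCGTTTCCGT"
RIGHT_FLANK = "GAACACTAATACAAGCCGTACATAAACCGTATAGAGCTGCTT"

#: 230-bp default backbone: 41-bp flank + 147-bp Widom 601 core + 42-bp flank.
DEFAULT_BACKBONE = LEFT_FLANK + WIDOM_601_CORE + RIGHT_FLANK

_DNA_RE = re.compile(r"^[ACGT]+$")

ROLES = ("forward_target", "reverse_target", "nontarget", "control", "background")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleosomeFrame:
    """Coordinate system of a positioned nucleosome on a backbone.

    Parameters
    ----------
    dyad_offset:
        0-based index of the dyad base within the backbone.
    core_span:
        Length of the nucleosome-forming region in bp (odd, centered on the
        dyad; 147 for a canonical nucleosome).
    bp_per_shl:
        Base pairs per superhelical location (10 for B-form nucleosomal DNA).
    """

    dyad_offset: int
    core_span: int = 147
    bp_per_shl: int = 10

    def __post_init__(self) -> None:
        if self.dyad_offset < 0:
            raise ValueError("dyad_offset must be non-negative")
        if self.core_span < 1 or self.core_span % 2 == 0:
            raise ValueError("core_span must be a positive odd integer")
        if self.bp_per_shl <= 0:
            raise ValueError("bp_per_shl must be positive")

    @property
    def half_core(self) -> int:
        return (self.core_span - 1) // 2

    @property
    def core_start(self) -> int:
        """0-based inclusive start of the core (dyad - (core_span-1)/2)."""
        return self.dyad_offset - self.half_core

    @property
    def core_end(self) -> int:
        """0-based exclusive end of the core."""
        return self.dyad_offset + self.half_core + 1

    def shl_of_offset(self, offset_bp: int) -> float:
        return offset_bp / self.bp_per_shl

    def offset_of_shl(self, shl: float) -> int:
        off = Fraction(str(shl)) * self.bp_per_shl
        if off.denominator != 1:
            raise ValueError(f"SHL {shl} is not an integer number of bp")
        return int(off)


#: Frame of the default backbone: dyad at the center of the 601 core.
DEFAULT_FRAME = NucleosomeFrame(dyad_offset=len(LEFT_FLANK) + 73)


def shl_of_offset(offset_bp: int, frame: NucleosomeFrame = DEFAULT_FRAME) -> float:
    """SHL coordinate of a dyad-relative bp offset (signed decimal)."""
    return frame.shl_of_offset(offset_bp)


def offset_of_shl(shl: float, frame: NucleosomeFrame = DEFAULT_FRAME) -> int:
    """Dyad-relative bp offset of an SHL coordinate. Inverse of shl_of_offset."""
    return frame.offset_of_shl(shl)


@dataclass(frozen=True)
class TargetMotif:
    """A Cas9 target+PAM motif to tile through the backbone.

    ``forward`` orientation places the PAM 3' of the target on the Watson
    strand; ``reverse`` places it 5' of the target. The stored sequence is
    always the Watson strand as drawn; the strand engaged by Cas9 is implied
    by the role, not by a sequence transformation.
    """

    target_seq: str
    pam_seq: str = "TGG"
    orientation: str = "forward"
    role: str = "forward_target"

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.target_seq):
            raise ValueError("target_seq must be non-empty ACGT")
        if not _DNA_RE.match(self.pam_seq):
            raise ValueError("pam_seq must be non-empty ACGT")
        if not (len(self.pam_seq) == 3 and self.pam_seq[1:] == "GG"):
            raise ValueError("pam_seq must match the 3-bp NGG pattern")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if self.role not in ("forward_target", "reverse_target", "nontarget"):
            raise ValueError("role must be forward_target/reverse_target/nontarget")

    @property
    def motif(self) -> str:
        """Full motif placed into the backbone (target+PAM in drawn order)."""
        if self.orientation == "forward":
            return self.target_seq + self.pam_seq
        return self.pam_seq + self.target_seq

    def __len__(self) -> int:
        return len(self.target_seq) + len(self.pam_seq)

    @property
    def pam_center_in_motif(self) -> int:
        """Index of the PAM's center base within the motif."""
        if self.orientation == "forward":
            return len(self.target_seq) + 1
        return 1


@dataclass(frozen=True)
class LibraryMember:
    """One designed library sequence with its tiling metadata."""

    member_id: str
    sequence: str
    role: str
    tile_start: int | None = None
    pam_center_offset: int | None = None
    shl: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class Library:
    """A designed library: members plus the shared backbone and frame."""

    members: list[LibraryMember]
    backbone: str
    frame: NucleosomeFrame

    def __post_init__(self) -> None:
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate member ids: {dup}")
        self._by_id = {m.member_id: m for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, member_id: str) -> LibraryMember:
        return self._by_id[member_id]

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._by_id

    @property
    def member_ids(self) -> list[str]:
        return [m.member_id for m in self.members]

    def by_role(self, role: str) -> list[LibraryMember]:
        return [m for m in self.members if m.role == role]

    @property
    def control_id(self) -> str:
        ctrl = self.by_role("control")
        if len(ctrl) != 1:
            raise ValueError(f"library has {len(ctrl)} control members, expected 1")
        return ctrl[0].member_id

    @property
    def background_ids(self) -> list[str]:
        return [m.member_id for m in self.by_role("background")]

    def sequences(self) -> dict[str, str]:
        return {m.member_id: m.sequence for m in self.members}


def tile_motif(
    backbone: str,
    motif: TargetMotif,
    window: tuple[int, int],
    frame: NucleosomeFrame = DEFAULT_FRAME,
    id_prefix: str | None = None,
) -> list[LibraryMember]:
    """Tile a motif at every bp position of ``window`` = [start, end).

    Each member replaces ``backbone[p : p+len(motif)]`` by the motif; length
    is always conserved (substitution, never insertion).
    """
    start, end = window
    m = len(motif)
    if start < 0:
        raise ValueError(f"window start {start} out of bounds")
    if end > len(backbone) - m + 1:
        raise ValueError(
            f"window end {end} out of bounds: last valid tile start is "
            f"{len(backbone) - m}"
        )
    prefix = id_prefix or motif.role
    members = []
    for p in range(start, end):
        seq = backbone[:p] + motif.motif + backbone[p + m:]
        pam_center = p + motif.pam_center_in_motif - frame.dyad_offset
        members.append(
            LibraryMember(
                member_id=f"{prefix}_p{p:03d}",
                sequence=seq,
                role=motif.role,
                tile_start=p,
                pam_center_offset=pam_center,
                shl=frame.shl_of_offset(pam_center),
            )
        )
    return members


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def make_background_fillers(
    n: int,
    length: int,
    rng: np.random.Generator,
    gc: float = 0.5,
    forbidden_seqs: Sequence[str] = (),
    k: int = 17,
) -> list[LibraryMember]:
    """Generate nonspecific background sequences.

    Fillers share no ``k``-nt window (either strand) with any forbidden
    sequence (the configured sgRNA targets), so they behave as nonspecific
    background for Z-score normalization.
    """
    forbidden: set[str] = set()
    for s in forbidden_seqs:
        if len(s) >= k:
            forbidden |= _kmers(s, k) | _kmers(revcomp(s), k)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    members = []
    i = 0
    while len(members) < n:
        seq = "".join(rng.choice(bases, size=length, p=probs))
        if forbidden and (_kmers(seq, k) & forbidden):
            continue  # rare collision; redraw
        members.append(
            LibraryMember(member_id=f"background_{i:03d}", sequence=seq, role="background")
        )
        i += 1
    return members


def build_library(
    motifs: Sequence[TargetMotif] = (),
    windows: Sequence[tuple[int, int]] | None = None,
    backbone: str = DEFAULT_BACKBONE,
    frame: NucleosomeFrame = DEFAULT_FRAME,
    n_fillers: int = 10,
    seed: int = 0,
    control_id: str = "widom601_control",
) -> Library:
    """Assemble tilings of every motif, one native-backbone control and
    seeded background fillers into a single library.

    ``windows`` gives one [start, end) tiling window per motif; ``None``
    tiles every valid position of the backbone.
    """
    if windows is None:
        windows = [(0, len(backbone) - len(m) + 1) for m in motifs]
    if len(windows) != len(motifs):
        raise ValueError("one tiling window required per motif")
    members: list[LibraryMember] = [
        LibraryMember(member_id=control_id, sequence=backbone, role="control")
    ]
    role_counts: dict[str, int] = {}
    for motif, window in zip(motifs, windows):
        idx = role_counts.get(motif.role, 0)
        role_counts[motif.role] = idx + 1
        prefix = motif.role if idx == 0 else f"{motif.role}{idx + 1}"
        members.extend(tile_motif(backbone, motif, window, frame, id_prefix=prefix))
    rng = np.random.default_rng(seed)
    gc = (backbone.count("G") + backbone.count("C")) / len(backbone)
    members.extend(
        make_background_fillers(
            n_fillers,
            len(backbone),
            rng,
            gc=gc,
            forbidden_seqs=[m.target_seq for m in motifs],
        )
    )
    seqs: dict[str, str] = {}
    for m in members:
        if m.sequence in seqs:
            raise ValueError(
                f"duplicate sequences: {seqs[m.sequence]!r} and {m.member_id!r}"
            )
        seqs[m.sequence] = m.member_id
    return Library(members=members, backbone=backbone, frame=frame)


def default_design(seed: int = 601, n_fillers: int = 20) -> Library:
    """Full default design: forward, reverse and nontarget motifs tiled at
    every backbone position, plus control and background fillers.

    Target sequences are drawn from a seeded RNG (the assay's conclusions do
    not depend on the particular 20-mer, only on its position), with the
    nontarget sharing no complementarity with the sgRNA targets.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def draw(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    fwd = TargetMotif(draw(20), "TGG", orientation="forward", role="forward_target")
    rev = TargetMotif(draw(20), "AGG", orientation="reverse", role="reverse_target")
    non = TargetMotif(draw(18), "CGG", orientation="forward", role="nontarget")
    return build_library(
        motifs=[fwd, rev, non], n_fillers=n_fillers, seed=seed + 1
    )


# ---------------------------------------------------------------------------
# Serialization


def _member_header(m: LibraryMember) -> str:
    parts = [f"role={m.role}"]
    if m.tile_start is not None:
        parts.append(f"tile_start={m.tile_start}")
    if m.pam_center_offset is not None:
        parts.append(f"pam_center_offset={m.pam_center_offset}")
    if m.shl is not None:
        parts.append(f"shl={m.shl}")
    return " ".join(parts)


def write_library_fasta(library: Library, path) -> None:
    """Write the library as FASTA with metadata as key=value header fields.

    Frame parameters are carried on the control record so the file round-trips
    to an identical Library.
    """
    records = []
    for m in library.members:
        desc = _member_header(m)
        if m.role == "control":
            f = library.frame
            desc += f" dyad={f.dyad_offset} core_span={f.core_span} bp_per_shl={f.bp_per_shl}"
        records.append(SeqRecord(Seq(m.sequence), id=m.member_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_library_fasta(path) -> Library:
    """Read a library written by :func:`write_library_fasta`."""
    members = []
    frame = None
    backbone = None
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        fields = {}
        for tok in rec.description.split()[1:]:
            if "=" not in tok:
                raise ValueError(f"malformed header field {tok!r} in record {i}")
            key, val = tok.split("=", 1)
            fields[key] = val
        if "role" not in fields:
            raise ValueError(f"record {i} header lacks a role field")
        role = fields["role"]
        member = LibraryMember(
            member_id=rec.id,
            sequence=str(rec.seq),
            role=role,
            tile_start=int(fields["tile_start"]) if "tile_start" in fields else None,
            pam_center_offset=(
                int(fields["pam_center_offset"])
                if "pam_center_offset" in fields
                else None
            ),
            shl=float(fields["shl"]) if "shl" in fields else None,
        )
        members.append(member)
        if role == "control":
            backbone = member.sequence
            if "dyad" in fields:
                frame = NucleosomeFrame(
                    dyad_offset=int(fields["dyad"]),
                    core_span=int(fields.get("core_span", 147)),
                    bp_per_shl=int(fields.get("bp_per_shl", 10)),
                )
    if backbone is None:
        raise ValueError("library FASTA lacks a control record")
    return Library(members=members, backbone=backbone, frame=frame or DEFAULT_FRAME)


def write_manifest(library: Library, path) -> None:
    """Write a TSV manifest (member_id, role, tile_start, pam_center_offset, shl)."""
    import pandas as pd

    rows = [
        {
            "member_id": m.member_id,
            "role": m.role,
            "tile_start": m.tile_start,
            "pam_center_offset": m.pam_center_offset,
            "shl": m.shl,
        }
        for m in library.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
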