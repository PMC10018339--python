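"""Rigid superposition of a nuclease onto a nucleosome and steric-clash
counting.

The workflow mirrors how structural modeling of Cas9/nucleosome encounters
is done interactively: align the nontarget DNA chain of the nuclease
structure onto the corresponding nucleosomal DNA chain (sequence-aligned
with Needleman-Wunsch, one backbone phosphorus per paired residue,
least-squares rigid fit), then count van-der-Waals overlaps >= a cutoff
between the transformed nuclease atoms and the nucleosome atoms, with a
caller-supplied exclusion (e.g. the directly bound duplex).
"""

from __future__ import annotations

from dataclasses import dataclass
import gemmi
import numpy as np
from Bio import Align
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "VDW_RADII",
    "AtomSet",
    "Superposition",
    "load_structure",
    "write_structure",
    "chain_sequence",
    "pair_chains",
    "kabsch_superpose",
    "superpose_by_chains",
    "count_clashes",
]

#: Van der Waals radii in angstroms (Bondi's consensus values plus common
#: extensions); used whenever an atom carries no explicit radius override.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.31, "ZN": 1.39,
    "MN": 1.97, "FE": 1.94, "SE": 1.90,
}

_NUC_ONE = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "U",
}


@dataclass
class AtomSet:
    """A set of atoms as parallel arrays (coordinates in angstroms)."""

    coords: np.ndarray  # (n, 3) float
    element: np.ndarray  # str
    chain: np.ndarray  # str
    resid: np.ndarray  # int
    resname: np.ndarray  # str
    atom_name: np.ndarray  # str
    radius_override: np.ndarray | None = None  # float, NaN = use table

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        for name in ("element", "chain", "resid", "resname", "atom_name"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} atoms")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.coords)

    def radii(self) -> np.ndarray:
        """Per-atom vdW radius: override where given, else the element table."""
        out = np.empty(len(self), dtype=float)
        for i, el in enumerate(self.element):
            key = str(el).upper()
            if key not in VDW_RADII:
                raise ValueError(f"no vdW radius for element {el!r} (atom {i})")
            out[i] = VDW_RADII[key]
        if self.radius_override is not None:
            ov = np.asarray(self.radius_override, dtype=float)
            out = np.where(np.isnan(ov), out, ov)
        return out

    def select(self, mask: np.ndarray) -> "AtomSet":
        mask = np.asarray(mask)
        return AtomSet(
            self.coords[mask],
            self.element[mask],
            self.chain[mask],
            self.resid[mask],
            self.resname[mask],
            self.atom_name[mask],
            None if self.radius_override is None else self.radius_override[mask],
        )

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(str(c))
        return list(seen)

    def transformed(self, sup: "Superposition") -> "AtomSet":
        out = self.select(np.ones(len(self), dtype=bool))
        out.coords = sup.apply(self.coords)
        return out


def load_structure(path) -> AtomSet:
    """Read ATOM/HETATM records of a PDB-format file into an AtomSet."""
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    coords, element, chain, resid, resname, name = [], [], [], [], [], []
    model = st[0]
    for ch in model:
        for res in ch:
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                element.append(atom.element.name)
                chain.append(ch.name)
                resid.append(res.seqid.num)
                resname.append(res.name.strip())
                name.append(atom.name)
    if not coords:
        raise ValueError(f"no atoms in {path}")
    return AtomSet(
        np.array(coords),
        np.array(element),
        np.array(chain),
        np.array(resid, dtype=int),
        np.array(resname),
        np.array(name),
    )


def write_structure(atoms: AtomSet, path) -> None:
    """Write an AtomSet as a PDB file (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.name = "atomset"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for i in range(len(atoms)):
        cid = str(atoms.chain[i])
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        key = (cid, int(atoms.resid[i]))
        if key not in residues:
            res = gemmi.Residue()
            res.name = str(atoms.resname[i])
            res.seqid = gemmi.SeqId(int(atoms.resid[i]), " ")
            chains[cid].add_residue(res)
            residues[key] = chains[cid][-1]
        atom = gemmi.Atom()
        atom.name = str(atoms.atom_name[i])
        atom.element = gemmi.Element(str(atoms.element[i]))
        x, y, z = atoms.coords[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        residues[key].add_atom(atom)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def chain_sequence(atoms: AtomSet, chain_id: str) -> tuple[str, list[int]]:
    """One-letter nucleotide sequence of a chain plus its residue numbers."""
    mask = atoms.chain == chain_id
    if not mask.any():
        raise ValueError(f"chain {chain_id!r} not found")
    resids: list[int] = []
    letters: list[str] = []
    for rid, rname in zip(atoms.resid[mask], atoms.resname[mask]):
        rid = int(rid)
        if rid in resids:
            continue
        resids.append(rid)
        rname = str(rname)
        if rname not in _NUC_ONE:
            raise ValueError(f"residue {rname!r} in chain {chain_id!r} is not nucleic")
        letters.append(_NUC_ONE[rname])
    return "".join(letters), resids


def pair_chains(
    ref: AtomSet,
    ref_chain: str,
    mov: AtomSet,
    mov_chain: str,
    atom_name: str = "P",
) -> list[tuple[int, int]]:
    """Pair backbone atoms of two nucleic chains by sequence alignment.

    The chains' residue sequences are globally aligned (Needleman-Wunsch);
    for every aligned, non-gap column the named backbone atom (phosphorus by
    default, one per nucleotide) of each residue is paired. Residues lacking
    that atom (e.g. 5'-terminal nucleotides) are skipped. Returns index
    pairs into the two AtomSets.
    """
    seq_r, resids_r = chain_sequence(ref, ref_chain)
    seq_m, resids_m = chain_sequence(mov, mov_chain)
    if len(seq_r) < 3 or len(seq_m) < 3:
        raise ValueError("chains must have >= 3 residues")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=-1.0,
        open_gap_score=-2.0,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(seq_r, seq_m)[0]

    def atom_index(atoms: AtomSet, chain_id: str, resid: int) -> int | None:
        mask = (
            (atoms.chain == chain_id)
            & (atoms.resid == resid)
            & (atoms.atom_name == atom_name)
        )
        idx = np.nonzero(mask)[0]
        return int(idx[0]) if len(idx) else None

    pairs = []
    for (r0, r1), (m0, m1) in zip(*aln.aligned):
        for i, j in zip(range(r0, r1), range(m0, m1)):
            ia = atom_index(ref, ref_chain, resids_r[i])
            ib = atom_index(mov, mov_chain, resids_m[j])
            if ia is not None and ib is not None:
                pairs.append((ia, ib))
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} atom pairs; superposition is underdetermined"
        )
    return pairs


@dataclass(frozen=True)
class Superposition:
    """A rigid transform (proper rotation + translation) with its fit RMSD."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(ref_coords: np.ndarray, mov_coords: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired coordinates (Kabsch).

    Returns the transform minimizing the RMSD of ``mov`` onto ``ref`` over
    the given pairs. Degenerate (collinear or coincident) pairings are
    rejected since the rotation about the common axis is then undetermined.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("paired coordinate arrays must both be (n, 3)")
    if len(ref) < 3:
        raise ValueError("need >= 3 pairs")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    sv = np.linalg.svd(mov_c.T @ ref_c, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) atom pairs")
    rot, _ = Rotation.align_vectors(ref_c, mov_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mov.mean(axis=0)
    moved = mov @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def superpose_by_chains(
    ref: AtomSet, ref_chain: str, mov: AtomSet, mov_chain: str
) -> Superposition:
    """Chain-guided superposition: pair the two DNA chains, then fit."""
    pairs = pair_chains(ref, ref_chain, mov, mov_chain)
    ia = [a for a, _ in pairs]
    ib = [b for _, b in pairs]
    return kabsch_superpose(ref.coords[ia], mov.coords[ib])


def _apply_exclusion(atoms: AtomSet, exclude) -> AtomSet:
    if exclude is None:
        return atoms
    mask = exclude(atoms) if callable(exclude) else np.asarray(exclude)
    return atoms.select(~mask.astype(bool))


def count_clashes(
    set_a: AtomSet,
    set_b: AtomSet,
    overlap_cutoff: float = 0.6,
    exclude_a=None,
    exclude_b=None,
) -> int:
    """Count van-der-Waals clashes between two atom sets.

    A clash is an unordered cross pair (a, b) with
    ``r_a + r_b - d(a, b) >= overlap_cutoff``. ``exclude_a``/``exclude_b``
    drop atoms before counting — either a boolean mask or a predicate on the
    AtomSet returning one (e.g. the duplex directly bound by the nuclease,
    or everything beyond a chosen SHL). Candidate pairs come from a KD-tree;
    the overlap test itself is evaluated exactly.
    """
    a = _apply_exclusion(set_a, exclude_a)
    b = _apply_exclusion(set_b, exclude_b)
    if len(a) == 0 or len(b) == 0:
        return 0
    ra = a.radii()
    rb = b.radii()
    tree = cKDTree(b.coords)
    max_rb = rb.max()
    count = 0
    neighbors = tree.query_ball_point(
        a.coords, r=np.maximum(ra + max_rb - overlap_cutoff, 0.0)
    )
    for i, nbrs in enumerate(neighbors):
        if not nbrs:
            continue
        d = np.linalg.norm(b.coords[nbrs] - a.coords[i], axis=1)
        count += int(np.count_nonzero(ra[i] + rb[nbrs] - d >= overlap_cutoff))
    return count
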