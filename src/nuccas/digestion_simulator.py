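"""Synthetic digestion of a designed nucleosome library.

A parametric protection model stands in for the biology the assay measures:
cleavage probability of a member rises logistically as its PAM center moves
from the dyad past the nucleosome edge (~73 bp), with forward-orientation
targets protected for an extra stretch because their 20-nt target must clear
the octamer before the R-loop can complete, and sgRNA/target mismatches
scaling cleavage down multiplicatively. The model is deliberately simple —
monotone, few parameters, recoverable by a grid fit — rather than a kinetic
account of Cas9.

From the model the module simulates count tables (multinomial undigested
pools, binomially thinned digested pools), paired FASTQ reads with an
Illumina-like positional error/quality profile, and MNase fragment sets.
"""

from __future__ import annotations

import dataclasses
import gzip
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library_design import Library, LibraryMember, revcomp
from .mnase_footprint import Fragment
from .quantification import CountTable
from .read_processing import Read

__all__ = [
    "DigestionModel",
    "SimConfig",
    "cleavage_probability",
    "simulate_counts",
    "simulate_read_pairs",
    "write_paired_fastq",
    "simulate_mnase_fragments",
    "error_quality_profile",
    "fit_edge_offset",
]


@dataclass(frozen=True)
class DigestionModel:
    """Cleavage probability of a member as a function of PAM position.

    ``edge_offset`` is the bp distance from the dyad where accessibility
    transitions (the nucleosome edge, 73 bp for a 147-bp core);
    ``steepness`` the logistic slope (1/bp); ``max_cleavage`` the plateau
    probability for fully accessible targets; ``orientation_shift`` the
    extra bp of protection for forward-orientation targets whose 20-nt
    target trails the PAM into the nucleosome; ``mismatch_penalty`` maps
    sgRNA mismatch positions (1-based from the PAM-distal end of the
    target) to multiplicative cleavage factors <= 1; members the sgRNA does
    not engage (nontarget, control, background) cleave at
    ``nontarget_cleavage``.
    """

    edge_offset: int = 73
    steepness: float = 0.8
    max_cleavage: float = 0.9
    orientation_shift: int = 6
    mismatch_penalty: Mapping[int, float] = field(default_factory=dict)
    nontarget_cleavage: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.max_cleavage <= 1 and 0 <= self.nontarget_cleavage <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if any(not 0 <= f <= 1 for f in self.mismatch_penalty.values()):
            raise ValueError("mismatch penalties must lie in [0, 1]")

    @property
    def penalty_product(self) -> float:
        out = 1.0
        for f in self.mismatch_penalty.values():
            out *= f
        return out


def cleavage_probability(member: LibraryMember, model: DigestionModel) -> float:
    """Probability that Cas9 cleaves this member during the digestion.

    Logistic in the distance of the PAM center from the dyad, shifted
    ``orientation_shift`` bp outward for forward members; deterministic and
    monotone non-decreasing in that distance.
    """
    if member.role in ("nontarget", "control", "background"):
        return model.nontarget_cleavage
    if member.pam_center_offset is None:
        raise ValueError(f"member {member.member_id!r} lacks PAM position metadata")
    d = abs(member.pam_center_offset)
    mid = model.edge_offset
    if member.role == "forward_target":
        mid += model.orientation_shift
    top = model.max_cleavage * model.penalty_product
    base = model.nontarget_cleavage
    sig = 1.0 / (1.0 + math.exp(-model.steepness * (d - mid)))
    return base + (top - base) * sig


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-simulation settings.

    ``error_rate`` is the mean per-base substitution rate of the raw reads.
    Errors follow an Illumina-like positional profile: a low body rate
    (error_rate/20) with the remaining error mass concentrated in the final
    ``tail_frac`` of cycles, and per-base Phred qualities encode each
    base's true error probability, so the 3'-quality trimmer sees (and
    removes) the error-dense tail exactly as it does on real data.
    """

    seed: int
    n_reads: int = 100_000
    error_rate: float = 0.0
    read_length: int = 150
    n_replicates: int = 3
    tail_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


def error_quality_profile(
    read_length: int, error_rate: float, tail_frac: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle error probabilities and the Phred scores encoding them."""
    e = np.zeros(read_length)
    if error_rate > 0:
        tail = max(1, round(tail_frac * read_length))
        body = read_length - tail
        e_body = error_rate / 20.0
        e_tail = (error_rate * read_length - e_body * body) / tail
        if e_tail > 0.75:
            e_tail = 0.75
            e_body = (error_rate * read_length - e_tail * tail) / max(body, 1)
        e[:body] = e_body
        e[body:] = e_tail
    with np.errstate(divide="ignore"):
        q = np.where(e > 0, -10.0 * np.log10(np.maximum(e, 1e-12)), 41.0)
    return e, np.clip(np.round(q), 2, 41).astype(int)


def simulate_counts(
    library: Library,
    model: DigestionModel,
    config: SimConfig,
    abundance: Mapping[str, float] | None = None,
) -> tuple[CountTable, pd.DataFrame]:
    """Simulate digested/undigested count tables for all replicates.

    Per replicate the undigested sample is a multinomial draw over members
    (uniform unless ``abundance`` is given); the digested sample is an
    independent multinomial aliquot of the same pool, binomially thinned per
    member by its survival probability ``1 - cleavage_probability``. The two
    aliquots are drawn independently, as in a real split of one nucleosome
    pool, so even zero-cleavage members carry sampling noise. Returns the
    count table and a truth frame (member_id, cleavage_probability).
    """
    ids = library.member_ids
    if abundance is None:
        probs = np.full(len(ids), 1.0 / len(ids))
    else:
        w = np.array([abundance[m] for m in ids], dtype=float)
        probs = w / w.sum()
    p_cleave = np.array([cleavage_probability(library[m], model) for m in ids])
    tables: dict[tuple[str, int], dict[str, int]] = {}
    for rep in range(1, config.n_replicates + 1):
        rng = np.random.default_rng([config.seed, rep])
        und = rng.multinomial(config.n_reads, probs)
        aliquot = rng.multinomial(config.n_reads, probs)
        dig = rng.binomial(aliquot, 1.0 - p_cleave)
        tables[("undigested", rep)] = dict(zip(ids, und.tolist()))
        tables[("digested", rep)] = dict(zip(ids, dig.tolist()))
    truth = pd.DataFrame({"member_id": ids, "cleavage_probability": p_cleave})
    return CountTable.from_arrays(tables), truth


def simulate_read_pairs(
    counts: Mapping[str, int],
    library: Library,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[Read, Read]]:
    """Paired reads for one sample: R1 from the 5' end of each member's
    amplicon, R2 from the 3' end (sequencing orientation), overlapping in
    the middle, with substitution errors per the config's error profile."""
    e_prof, q_prof = error_quality_profile(
        config.read_length, config.error_rate, config.tail_frac
    )
    qual = tuple(int(q) for q in q_prof)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    pairs: list[tuple[Read, Read]] = []

    def with_errors(template: str) -> str:
        if config.error_rate == 0:
            return template
        arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(len(arr)) < e_prof)[0]
        for i in hits:
            choices = bases[bases != arr[i]]
            arr[i] = rng.choice(choices)
        return arr.tobytes().decode()

    L = config.read_length
    for member_id in sorted(counts):
        seq = library[member_id].sequence
        if L > len(seq):
            raise ValueError("read_length exceeds member length")
        t1 = seq[:L]
        t2 = revcomp(seq)[:L]
        for _ in range(counts[member_id]):
            pairs.append(
                (Read(with_errors(t1), qual), Read(with_errors(t2), qual))
            )
    return pairs


def write_paired_fastq(pairs: Sequence[tuple[Read, Read]], path1, path2) -> None:
    """Write read pairs to two FASTQ files (gzipped iff the path ends .gz)."""

    def dump(path, idx):
        op = gzip.open if str(path).endswith(".gz") else open
        with op(str(path), "wt") as fh:
            for i, pair in enumerate(pairs):
                r = pair[idx]
                q = "".join(chr(33 + v) for v in r.qual)
                fh.write(f"@read{i}/{idx + 1}\n{r.seq}\n+\n{q}\n")

    dump(path1, 0)
    dump(path2, 1)


def simulate_mnase_fragments(
    cut_probs: Sequence[float],
    n_fragments: int,
    seed: int | np.random.Generator,
    member_id: str = "member",
) -> list[Fragment]:
    """Simulate MNase fragments for one member.

    ``cut_probs[i]`` is the cut probability at inter-base boundary ``i`` of
    a molecule of length ``len(cut_probs) - 1``; boundaries 0 and L (the
    molecule ends) always cut. Each molecule is cut independently at every
    boundary and yields its longest resulting piece (ties: leftmost) — the
    octamer-protected stretch survives while accessible flanks are chewed
    away, so a zero-cut core produces a full-height coverage plateau.
    """
    p = np.asarray(cut_probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("cut probabilities must lie in [0, 1]")
    length = len(p) - 1
    if length < 1:
        raise ValueError("need at least a length-1 molecule")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    fragments = []
    for _ in range(n_fragments):
        cut = rng.random(len(p)) < p
        cut[0] = cut[-1] = True
        sites = np.nonzero(cut)[0]
        lengths = np.diff(sites)
        j = int(np.argmax(lengths))
        fragments.append(Fragment(member_id, int(sites[j]), int(sites[j + 1])))
    return fragments


def fit_edge_offset(
    library: Library,
    protection: "pd.Series",
    model: DigestionModel,
    grid: Iterable[int],
    loc: float = 0.0,
    scale: float = 1.0,
    pseudocount: float = 0.0,
    mean_count: float | None = None,
) -> int:
    """Grid-search the nucleosome edge from a measured protection profile.

    For each candidate edge, predicts each target member's raw protection
    ``log2((1 - p) / (1 - p_control))`` under the model with that edge and
    scores the sum of squared deviations from the measured values; returns
    the candidate with the smallest score. To fit a Z-normalized profile,
    pass the background mean/SD used for the Z transform as ``loc`` and
    ``scale`` so predictions land on the same scale; the recovered edge is
    then identical to a raw-scale fit. If the measured profile was computed
    with a pseudocount, pass it together with the expected per-member read
    depth ``mean_count`` so the prediction carries the same small-count
    compression instead of biasing the fitted edge outward.
    """
    members = [
        library[m]
        for m in protection.index
        if m in library and library[m].pam_center_offset is not None
    ]
    if not members:
        raise ValueError("no positional members in the profile")
    meas = protection.loc[[m.member_id for m in members]].to_numpy(dtype=float)
    best_edge, best_sse = None, math.inf
    for e in grid:
        cand = dataclasses.replace(model, edge_offset=int(e))
        p_con = cand.nontarget_cleavage

        def predict(p: float) -> float:
            if mean_count is None:
                return math.log2((1.0 - p) / (1.0 - p_con))
            num = mean_count * (1.0 - p) + pseudocount
            den = mean_count * (1.0 - p_con) + pseudocount
            return math.log2(num / den)

        pred = np.array([predict(cleavage_probability(m, cand)) for m in members])
        pred = (pred - loc) / scale
        sse = float(np.sum((meas - pred) ** 2))
        if sse < best_sse:
            best_edge, best_sse = int(e), sse
    return best_edge
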