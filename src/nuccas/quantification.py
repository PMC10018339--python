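"""Protection-from-Cas9 statistics.

The central statistic compares uncleaved read counts between a digested and
an undigested sample, each normalized to the native backbone control carried
in the library::

    protection = log2( (D_N / D_CON) / (U_N / U_CON) )

where ``D``/``U`` are digested/undigested counts of member N and of the
control. Cleaved molecules lose a primer site and drop out of the digested
pool, so protected (nucleosome-occluded) members score near 0 while
accessible targets score strongly negative. Control normalization cancels
depth and amplification differences between the two pools.

Per replicate, raw values are Z-normalized against the nonspecific
background members (mean/SD over the background set), then averaged across
replicates with a standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library_design import Library

__all__ = [
    "protection_from_cas9",
    "CountTable",
    "protection_table",
    "zscore_normalize",
    "profile_by_position",
    "replicate_correlation",
]


def protection_from_cas9(
    rd_n: float,
    rd_con: float,
    ru_n: float,
    ru_con: float,
    pseudocount: float = 1.0,
) -> float:
    """Protection-from-Cas9 log2 ratio-of-ratios for one member.

    ``pseudocount`` is added to all four counts; with pseudocount 0 any zero
    count is an error (the statistic is undefined), so exact checks can run
    unperturbed while real tables use the default of 1.
    """
    if min(rd_n, rd_con, ru_n, ru_con) < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    vals = [v + pseudocount for v in (rd_n, rd_con, ru_n, ru_con)]
    if min(vals) <= 0:
        raise ValueError(
            "zero count with pseudocount 0; pass a positive pseudocount"
        )
    a, b, c, d = vals
    return math.log2((a / b) / (c / d))


@dataclass
class CountTable:
    """Per-member uncleaved read counts for digested/undigested samples.

    Backed by a long-format DataFrame with columns
    ``member_id, condition, replicate, count`` where condition is
    ``digested`` or ``undigested``.
    """

    df: pd.DataFrame

    REQUIRED = ("member_id", "condition", "replicate", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table lacks columns {missing}")
        if (self.df["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.df["condition"]) - {"digested", "undigested"}
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")

    @classmethod
    def from_arrays(
        cls, counts: Mapping[tuple[str, int], Mapping[str, int]]
    ) -> "CountTable":
        """Build from {(condition, replicate): {member_id: count}}."""
        rows = [
            {"member_id": m, "condition": cond, "replicate": rep, "count": c}
            for (cond, rep), table in counts.items()
            for m, c in table.items()
        ]
        return cls(pd.DataFrame(rows))

    @property
    def replicates(self) -> list[int]:
        return sorted(self.df["replicate"].unique())

    def counts(self, condition: str, replicate: int) -> pd.Series:
        sub = self.df[
            (self.df["condition"] == condition) & (self.df["replicate"] == replicate)
        ]
        return sub.set_index("member_id")["count"]

    def wide(self) -> pd.DataFrame:
        """members x (condition, replicate) matrix, absent counts as 0."""
        return (
            self.df.pivot_table(
                index="member_id",
                columns=["condition", "replicate"],
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
        )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        return cls(pd.read_csv(path, sep="\t"))


def protection_table(
    counts: CountTable,
    control_id: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Raw protection per member and replicate (members x replicates)."""
    wide = counts.wide()
    if control_id not in wide.index:
        raise ValueError(f"control member {control_id!r} missing from counts")
    out = {}
    for rep in counts.replicates:
        dig = wide[("digested", rep)]
        und = wide[("undigested", rep)]
        d_con = dig.loc[control_id]
        u_con = und.loc[control_id]
        out[rep] = pd.Series(
            [
                protection_from_cas9(dig.loc[m], d_con, und.loc[m], u_con, pseudocount)
                for m in wide.index
            ],
            index=wide.index,
        )
    return pd.DataFrame(out)


def zscore_normalize(
    raw: pd.Series, background_ids: Sequence[str]
) -> pd.Series:
    """Z-score members against the nonspecific background distribution.

    Uses the population mean/SD of the background members' values, so the
    background itself renormalizes to mean 0, SD 1.
    """
    bg = raw.loc[[b for b in background_ids if b in raw.index]].astype(float)
    bg = bg[np.isfinite(bg)]
    if len(bg) < 2:
        raise ValueError("need >= 2 background members with finite values")
    sd = float(bg.std(ddof=0))
    if sd == 0:
        raise ValueError("background SD is zero; Z-score undefined")
    return (raw - float(bg.mean())) / sd


def profile_by_position(
    z_by_replicate: pd.DataFrame,
    library: Library,
    roles: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble an SHL-indexed profile with replicate mean and SEM.

    ``z_by_replicate`` is a members x replicates frame (raw or Z values);
    the result has one row per tiling position, ordered by SHL, with columns
    member_id, role, tile_start, shl, mean, sem and the per-replicate values.
    """
    rows = []
    for member_id, vals in z_by_replicate.iterrows():
        if member_id not in library:
            raise ValueError(f"member {member_id!r} missing from library metadata")
        m = library[member_id]
        if roles is not None and m.role not in roles:
            continue
        if m.shl is None:
            continue
        v = vals.to_numpy(dtype=float)
        n = len(v)
        sem = float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        row = {
            "member_id": member_id,
            "role": m.role,
            "tile_start": m.tile_start,
            "shl": m.shl,
            "mean": float(v.mean()),
            "sem": sem,
        }
        row.update({f"rep{r}": float(x) for r, x in vals.items()})
        rows.append(row)
    prof = pd.DataFrame(rows).sort_values(["role", "shl"], kind="mergesort")
    return prof.reset_index(drop=True)


def replicate_correlation(counts: CountTable) -> pd.DataFrame:
    """Pairwise Pearson correlation of samples on log2(count+1) scale.

    Symmetric with unit diagonal; a constant sample yields NaN against every
    other sample (correlation undefined).
    """
    wide = counts.wide()
    log = np.log2(wide.astype(float) + 1.0)
    log.columns = [f"{cond}_rep{rep}" for cond, rep in log.columns]
    return log.corr(method="pearson")
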