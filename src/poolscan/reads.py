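"""Aligned pooled-read containers and pileup construction.

A :class:`ReadStack` holds the reads of one library (pool x sequencing
replicate) aligned to one amplicon, in per-gene 1-based coordinates, plus the
base carried by each read at every candidate SNP position.  Pileup columns
aggregate base counts per replicate and strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

PLUS, MINUS = 0, 1


@dataclass
class ReadStack:
    """Reads of one library aligned to one locus.

    ``snp_calls`` maps a SNP position to ``(read_indices, base_codes)``:
    the indices of reads covering that position and the 0..3 (ACGT) code of
    the base each read carries there.
    """

    locus_id: str
    locus_length: int
    pool: str
    replicate: int
    start: np.ndarray
    length: np.ndarray
    strand: np.ndarray
    snp_calls: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.start)
        if not (len(self.length) == n == len(self.strand)):
            raise ValueError("start, length and strand must have equal length")
        if n and (self.start.min() < 1 or (self.start + self.length - 1).max() > self.locus_length):
            raise ValueError(f"reads extend outside locus {self.locus_id}")

    @property
    def n_reads(self) -> int:
        return len(self.start)

    @property
    def end(self) -> np.ndarray:
        """Inclusive 1-based end positions."""
        return self.start + self.length - 1

    def covering(self, position: int) -> np.ndarray:
        """Boolean mask of reads covering a 1-based position."""
        return (self.start <= position) & (self.end >= position)

    def depth_profile(self) -> np.ndarray:
        """Total depth at every position 1..locus_length."""
        delta = np.zeros(self.locus_length + 1, dtype=np.int64)
        np.add.at(delta, self.start - 1, 1)
        np.add.at(delta, np.minimum(self.end, self.locus_length), -1)
        return np.cumsum(delta)[:-1]

    def subset(self, keep: np.ndarray) -> "ReadStack":
        """Return a new stack with the reads selected by a boolean mask,
        remapping the SNP base-call read indices."""
        keep = np.asarray(keep, dtype=bool)
        idx = np.flatnonzero(keep)
        remap = np.full(self.n_reads, -1, dtype=np.int64)
        remap[idx] = np.arange(len(idx))
        calls = {}
        for pos, (ridx, codes) in self.snp_calls.items():
            m = keep[ridx]
            if m.any():
                calls[pos] = (remap[ridx[m]], codes[m])
        return ReadStack(
            locus_id=self.locus_id,
            locus_length=self.locus_length,
            pool=self.pool,
            replicate=self.replicate,
            start=self.start[idx],
            length=self.length[idx],
            strand=self.strand[idx],
            snp_calls=calls,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular form used by the plain-text reads file."""
        calls_col = [""] * self.n_reads
        parts: dict[int, list[str]] = {}
        for pos, (ridx, codes) in sorted(self.snp_calls.items()):
            for r, c in zip(ridx, codes):
                parts.setdefault(int(r), []).append(f"{pos}:{BASES[c]}")
        for r, items in parts.items():
            calls_col[r] = ",".join(items)
        return pd.DataFrame(
            {
                "locus": self.locus_id,
                "pool": self.pool,
                "replicate": self.replicate,
                "start": self.start,
                "length": self.length,
                "strand": np.where(self.strand == PLUS, "+", "-"),
                "snp_calls": calls_col,
            }
        )


def stack_from_frame(df: pd.DataFrame, locus_id: str, locus_length: int) -> ReadStack:
    """Rebuild a ReadStack from the tabular reads format (one library)."""
    n = len(df)
    calls: dict[int, tuple[list, list]] = {}
    for r, spec in enumerate(df["snp_calls"].fillna("")):
        if not spec:
            continue
        for item in spec.split(","):
            p, b = item.split(":")
            calls.setdefault(int(p), ([], []))
            calls[int(p)][0].append(r)
            calls[int(p)][1].append(BASE_INDEX[b])
    return ReadStack(
        locus_id=locus_id,
        locus_length=locus_length,
        pool=str(df["pool"].iloc[0]) if n else "",
        replicate=int(df["replicate"].iloc[0]) if n else 0,
        start=df["start"].to_numpy(dtype=np.int64),
        length=df["length"].to_numpy(dtype=np.int64),
        strand=np.where(df["strand"].to_numpy() == "+", PLUS, MINUS).astype(np.int8),
        snp_calls={
            p: (np.array(r, dtype=np.int64), np.array(c, dtype=np.int8))
            for p, (r, c) in calls.items()
        },
    )


@dataclass
class PileupColumn:
    """Per-position, per-replicate, per-strand base counts for one pool."""

    locus_id: str
    position: int
    counts: np.ndarray  # shape (n_replicates, 2 strands, 4 bases)

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("negative base counts")

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    def replicate_base_counts(self) -> np.ndarray:
        """Counts per replicate summed over strands, shape (n_rep, 4)."""
        return self.counts.sum(axis=1)


def build_pileup(stacks: list[ReadStack]) -> list[PileupColumn]:
    """Pileup columns for one pool from its replicate read stacks.

    Only positions with recorded SNP base calls appear (monomorphic
    positions carry no information for SNP calling).
    """
    if not stacks:
        return []
    locus = stacks[0].locus_id
    n_rep = max(s.replicate for s in stacks) + 1
    by_pos: dict[int, np.ndarray] = {}
    for s in stacks:
        if s.locus_id != locus:
            raise ValueError("all stacks must belong to the same locus")
        for pos, (ridx, codes) in s.snp_calls.items():
            cnt = by_pos.setdefault(pos, np.zeros((n_rep, 2, 4), dtype=np.int64))
            strands = s.strand[ridx]
            np.add.at(cnt, (s.replicate, strands, codes), 1)
    return [
        PileupColumn(locus_id=locus, position=pos, counts=cnt)
        for pos, cnt in sorted(by_pos.items())
    ]
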