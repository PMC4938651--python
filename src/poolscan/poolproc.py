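"""Read processing downstream of alignment.

Implements the study's processing chain: library-level downsampling to a
common size, the per-gene 5'->3' sweep that caps retained reads per strand,
replicate-concordance SNP validation, pooled allele-frequency estimation,
outgroup polarization, and minor-allele-frequency subsetting.

Coordinates are 1-based and per-gene throughout.  Sample sizes default to
two pools of 48 diploids, i.e. 96 chromosomes each.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import FilterConfig
from .reads import BASES, PLUS, MINUS, PileupColumn, ReadStack

logger = logging.getLogger(__name__)

SNP_TABLE_COLUMNS = [
    "locus", "pos", "ref", "alt", "anc", "site_class", "p_fen", "p_alp",
    "reads_fen_a", "reads_fen_b", "reads_alp_a", "reads_alp_b",
    "depth_fen", "depth_alp", "rare", "private_fen", "private_alp", "polarized",
]


@dataclass
class SnpCall:
    """A validated biallelic SNP with per-pool pooled frequency estimates.

    ``p_fen``/``p_alp`` are the frequencies of ``alt`` (the minor allele at
    calling time; the derived allele once polarized with ``anc == ref``).
    ``reads_*`` are alt-supporting read counts per replicate.
    """

    locus_id: str
    position: int
    ref: str
    alt: str
    anc: str | None
    p_fen: float
    p_alp: float
    reads_fen: tuple[int, int]
    reads_alp: tuple[int, int]
    depth_fen: int
    depth_alp: int
    site_class: str | None = None
    rare: bool = False
    private_fen: bool = False
    private_alp: bool = False
    polarized: bool = False

    def __post_init__(self) -> None:
        for p in (self.p_fen, self.p_alp):
            if not 0.0 <= p <= 1.0:
                raise ValueError("frequencies must lie in [0, 1]")


def downsample_library(
    stacks: list[ReadStack], target_size: int, seed: int = 0
) -> list[ReadStack]:
    """Randomly retain exactly ``target_size`` reads across a library.

    Reads are picked uniformly without replacement over the whole library
    (all loci of one pool x replicate), matching downsampling every library
    to the size of the smallest one.
    """
    total = sum(s.n_reads for s in stacks)
    if target_size > total:
        name = f"{stacks[0].pool}/rep{stacks[0].replicate}" if stacks else "<empty>"
        raise ValueError(
            f"target_size {target_size} exceeds library {name} size {total}"
        )
    rng = np.random.default_rng(seed)
    keep_global = np.zeros(total, dtype=bool)
    keep_global[rng.choice(total, size=target_size, replace=False)] = True
    out, offset = [], 0
    for s in stacks:
        out.append(s.subset(keep_global[offset : offset + s.n_reads]))
        offset += s.n_reads
    return out


def downsample_gene_coverage(
    stack: ReadStack, cap_per_strand: int = 100, seed: int = 0
) -> ReadStack:
    """5'->3' sweep capping the retained per-strand depth at each position.

    Starting at the gene's first base and moving toward the 3' end, at each
    position reads covering it are randomly retained (without replacement,
    per strand) until the retained depth at that position reaches the cap;
    the remaining reads covering the position are discarded.  Positions
    whose available depth is below the cap keep all their reads.
    """
    n = stack.n_reads
    if n == 0:
        return stack
    rng = np.random.default_rng(seed)
    # random per-read priority makes "retain random reads at each position"
    # a single pass: at each position, undecided covering reads are accepted
    # in priority order until the cap is met
    priority = rng.permutation(n)
    order = np.lexsort((priority, stack.start))
    starts = stack.start[order]
    ends = stack.end[order]
    strands = stack.strand[order]
    status = np.zeros(n, dtype=np.int8)  # 0 undecided, 1 retained, -1 discarded
    ptr = 0
    # per-strand min-heaps of end positions of retained reads still covering
    # the current position: heap size == retained depth at that position
    heaps: list[list[int]] = [[], []]
    for pos in range(1, stack.locus_length + 1):
        for s in (PLUS, MINUS):
            h = heaps[s]
            while h and h[0] < pos:
                heapq.heappop(h)
        # reads starting at this position become candidates in priority order
        while ptr < n and starts[ptr] == pos:
            s = strands[ptr]
            if len(heaps[s]) < cap_per_strand:
                status[ptr] = 1
                heapq.heappush(heaps[s], ends[ptr])
            else:
                status[ptr] = -1
            ptr += 1
        if ptr >= n:
            break
    keep = np.zeros(n, dtype=bool)
    keep[order[status == 1]] = True
    return stack.subset(keep)


def pileups_from_sync(
    path, pools: tuple[str, ...] = ("FEN", "ALP"), n_replicates: int = 2
) -> dict[str, list[PileupColumn]]:
    """Read a sync-style TSV into per-pool pileup columns.

    Expected layout: locus, pos, ref, then two colon-separated
    A:C:G:T:N:del count fields (plus strand, then minus strand) per
    library, libraries ordered pool-major then replicate.
    """
    df = pd.read_csv(path, sep="\t")
    lib_cols = df.columns[3:]
    expected = 2 * n_replicates * len(pools)
    if len(lib_cols) != expected:
        raise ValueError(
            f"sync file has {len(lib_cols)} count fields, expected {expected}"
        )
    out: dict[str, list[PileupColumn]] = {p: [] for p in pools}
    for row in df.itertuples(index=False):
        fields = list(row)[3:]
        for pi, pool in enumerate(pools):
            counts = np.zeros((n_replicates, 2, 4), dtype=np.int64)
            for rep in range(n_replicates):
                for strand in (PLUS, MINUS):
                    raw = fields[(pi * n_replicates + rep) * 2 + strand]
                    counts[rep, strand, :] = [int(x) for x in str(raw).split(":")[:4]]
            out[pool].append(
                PileupColumn(locus_id=row[0], position=int(row[1]), counts=counts)
            )
    return out


def _support(counts: np.ndarray, allele: int) -> np.ndarray:
    """Per-replicate read counts for one base, summed over strands."""
    return counts[:, :, allele].sum(axis=1)


def call_snps(
    columns_fen: list[PileupColumn],
    columns_alp: list[PileupColumn],
    cfg: FilterConfig | None = None,
    reference: dict[tuple[str, int], str] | None = None,
) -> list[SnpCall]:
    """Replicate-concordance SNP calling on paired pools.

    An allele is accepted as a genuine minor allele only if (i) it is seen
    in both sequencing replicates of at least one pool and (ii) it has at
    least two supporting reads in each of those replicates, or at least
    five supporting reads in total across the two pools.  Sites where more
    than one minor allele passes are dropped with a warning (downstream
    statistics are biallelic).
    """
    cfg = cfg or FilterConfig()
    by_key_alp = {(c.locus_id, c.position): c for c in columns_alp}
    calls: list[SnpCall] = []
    for col_f in columns_fen:
        key = (col_f.locus_id, col_f.position)
        col_a = by_key_alp.get(key)
        shape_f = col_f.counts.shape
        n_rep = shape_f[0]
        if cfg.require_both_replicates and n_rep < 2:
            raise ValueError(f"pool FEN has {n_rep} replicate(s) at {key}")
        counts_a = col_a.counts if col_a is not None else np.zeros_like(col_f.counts)
        if cfg.require_both_replicates and counts_a.shape[0] < 2:
            raise ValueError(f"pool ALP has {counts_a.shape[0]} replicate(s) at {key}")
        rep_f = col_f.counts.sum(axis=1)  # (n_rep, 4)
        rep_a = counts_a.sum(axis=1)
        tot = rep_f.sum(axis=0) + rep_a.sum(axis=0)  # per-base totals
        if tot.sum() == 0:
            continue
        major = int(tot.argmax())
        passing = []
        for allele in range(4):
            if allele == major or tot[allele] == 0:
                continue
            ok = False
            for rep in (rep_f, rep_a):
                sup = rep[:, allele]
                if cfg.require_both_replicates and (sup == 0).any():
                    continue
                if (sup >= cfg.min_minor_reads_per_replicate).all() or (
                    tot[allele] >= cfg.min_minor_reads_total
                ):
                    ok = True
                    break
            if ok:
                passing.append(allele)
        if not passing:
            continue
        if len(passing) > 1:
            logger.warning(
                "site %s:%d has %d passing minor alleles; dropped",
                col_f.locus_id, col_f.position, len(passing),
            )
            continue
        minor = passing[0]
        pair_f = rep_f[:, [major, minor]]
        pair_a = rep_a[:, [major, minor]]
        depth_f = int(pair_f.sum())
        depth_a = int(pair_a.sum())
        p_fen = pair_f[:, 1].sum() / depth_f if depth_f else 0.0
        p_alp = pair_a[:, 1].sum() / depth_a if depth_a else 0.0
        pooled = (pair_f[:, 1].sum() + pair_a[:, 1].sum()) / max(depth_f + depth_a, 1)
        ref_base = (
            reference.get(key, BASES[major]) if reference is not None else BASES[major]
        )
        calls.append(
            SnpCall(
                locus_id=col_f.locus_id,
                position=col_f.position,
                ref=ref_base,
                alt=BASES[minor],
                anc=None,
                p_fen=float(p_fen),
                p_alp=float(p_alp),
                reads_fen=(int(pair_f[0, 1]), int(pair_f[1, 1]) if n_rep > 1 else 0),
                reads_alp=(int(pair_a[0, 1]), int(pair_a[1, 1]) if pair_a.shape[0] > 1 else 0),
                depth_fen=depth_f,
                depth_alp=depth_a,
                rare=bool(pooled < cfg.rare_freq_flag),
                private_fen=bool(p_fen > 0 and p_alp == 0),
                private_alp=bool(p_alp > 0 and p_fen == 0),
            )
        )
    return calls


def polarize(
    calls: list[SnpCall],
    outgroup: dict[tuple[str, int], str] | pd.DataFrame,
) -> list[SnpCall]:
    """Polarize frequencies using an outgroup allele table.

    Where the outgroup base matches one of the two alleles it is taken as
    ancestral and the reported frequencies become derived-allele
    frequencies.  Otherwise (mismatch or missing) the call keeps its
    minor-allele-folded frequencies with ``polarized=False``.
    """
    if isinstance(outgroup, pd.DataFrame):
        outgroup = {
            (r.locus, int(r.pos)): str(r.outgroup) for r in outgroup.itertuples()
        }
    out = []
    for c in calls:
        og = outgroup.get((c.locus_id, c.position))
        if og == c.ref:
            out.append(replace(c, anc=og, polarized=True))
        elif og == c.alt:
            # the alternate allele is ancestral: derived = ref allele
            out.append(
                replace(
                    c,
                    anc=og,
                    ref=c.alt,
                    alt=c.ref,
                    p_fen=1.0 - c.p_fen,
                    p_alp=1.0 - c.p_alp,
                    polarized=True,
                    private_fen=bool(1.0 - c.p_fen > 0 and 1.0 - c.p_alp == 0),
                    private_alp=bool(1.0 - c.p_alp > 0 and 1.0 - c.p_fen == 0),
                )
            )
        else:
            out.append(replace(c, anc=None, polarized=False))
    return out


def minor_allele_frequency(call: SnpCall) -> float:
    """Pooled minor-allele frequency from the two pools' combined reads."""
    alt_reads = sum(call.reads_fen) + sum(call.reads_alp)
    depth = call.depth_fen + call.depth_alp
    if depth == 0:
        return 0.0
    f = alt_reads / depth
    return min(f, 1.0 - f)


def apply_frequency_cutoff(
    calls: list[SnpCall], cutoff: float | None
) -> tuple[list[SnpCall], dict]:
    """Subset SNPs whose pooled minor-allele frequency is >= cutoff.

    ``cutoff`` must be None (keep everything), 0.01 or 0.1 — the two
    sensitivity thresholds used throughout the analysis.
    """
    if cutoff not in (None, 0.01, 0.1):
        raise ValueError(f"cutoff must be one of None, 0.01, 0.1; got {cutoff!r}")
    if cutoff is None:
        kept = list(calls)
    else:
        kept = [c for c in calls if minor_allele_frequency(c) >= cutoff]
    report = {"cutoff": cutoff, "n_input": len(calls), "n_retained": len(kept)}
    return kept, report


def annotate_site_classes(
    calls: list[SnpCall], annotation: pd.DataFrame
) -> list[SnpCall]:
    """Attach site-class labels from an annotation table (locus, pos, site_class)."""
    lookup = {
        (r.locus, int(r.pos)): str(r.site_class) for r in annotation.itertuples()
    }
    return [
        replace(c, site_class=lookup.get((c.locus_id, c.position), c.site_class))
        for c in calls
    ]


def calls_to_frame(calls: list[SnpCall]) -> pd.DataFrame:
    """SNP table in the documented TSV layout."""
    rows = [
        {
            "locus": c.locus_id, "pos": c.position, "ref": c.ref, "alt": c.alt,
            "anc": c.anc if c.anc is not None else ".",
            "site_class": c.site_class if c.site_class is not None else ".",
            "p_fen": c.p_fen, "p_alp": c.p_alp,
            "reads_fen_a": c.reads_fen[0], "reads_fen_b": c.reads_fen[1],
            "reads_alp_a": c.reads_alp[0], "reads_alp_b": c.reads_alp[1],
            "depth_fen": c.depth_fen, "depth_alp": c.depth_alp,
            "rare": c.rare, "private_fen": c.private_fen,
            "private_alp": c.private_alp, "polarized": c.polarized,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=SNP_TABLE_COLUMNS)
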