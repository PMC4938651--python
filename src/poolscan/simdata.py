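"""Synthetic two-pool amplicon data under the IM coalescent.

This module is both the fixture generator for the rest of the pipeline and
the null-model engine for demographic inference and the divergence scan.  It
produces (i) true derived-allele counts per locus from the structured
coalescent, (ii) site-class labels (noncoding / synonymous / nonsynonymous),
and (iii) pooled sequencing read stacks with a simple binomial sampling +
error noise model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import random as _random
import yaml

from . import __version__
from .coalescent import simulate_locus_counts
from .models import DemographicModel, LocusSpec, PoolReadProfile, default_loci
from .reads import BASES, MINUS, PLUS, ReadStack

SITE_CLASSES = ("noncoding", "synonymous", "nonsynonymous")
#: observed site-class totals used as default labelling proportions
DEFAULT_CLASS_PROPORTIONS = (1600, 546, 632)
POOLS = ("FEN", "ALP")


def _spawn(seed: int, *path: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(p) for p in path))


def _rngs(ss: np.random.SeedSequence) -> tuple[_random.Random, np.random.Generator]:
    state = ss.generate_state(2)
    return _random.Random(int(state[0])), np.random.default_rng(int(state[1]))


@dataclass
class TrueFrequencyTable:
    """True derived-allele counts of every simulated polymorphic site.

    ``snps`` columns: locus, pos, anc, der, count_fen, count_alp and,
    after labelling, site_class.  Counts are out of ``n1`` (FEN) and ``n2``
    (ALP) sampled chromosomes.
    """

    snps: pd.DataFrame
    n1: int
    n2: int
    loci: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c1 = self.snps["count_fen"].to_numpy()
        c2 = self.snps["count_alp"].to_numpy()
        if ((c1 < 0) | (c1 > self.n1) | (c2 < 0) | (c2 > self.n2)).any():
            raise ValueError("derived counts outside [0, n] range")
        total = c1 + c2
        if ((total == 0) | (total == self.n1 + self.n2)).any():
            raise ValueError("monomorphic site in frequency table")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.snps["count_fen"].to_numpy() / self.n1,
            self.snps["count_alp"].to_numpy() / self.n2,
        )


def simulate_genealogy_counts(
    model: DemographicModel,
    loci: list[LocusSpec],
    n1: int = 96,
    n2: int = 96,
    seed: int = 0,
) -> TrueFrequencyTable:
    """Simulate derived-allele counts for every locus under the IM model.

    One genealogy is drawn per locus (amplicons are non-recombining and
    unlinked); infinite-sites mutations are placed on branches at rate
    ``mu_per_generation * length``.  The master seed is split per locus so
    individual loci are reproducible in isolation.
    """
    model.validate()
    if n1 + n2 < 2 or n1 < 0 or n2 < 0:
        raise ValueError("need at least two chromosomes in total")
    rows = []
    for i, spec in enumerate(loci):
        rng, np_rng = _rngs(_spawn(seed, 0, i))
        pos, c1, c2 = simulate_locus_counts(model, spec.length, n1, n2, rng, np_rng)
        if len(pos) == 0:
            continue
        anc_codes = np_rng.integers(0, 4, size=len(pos))
        der_codes = (anc_codes + np_rng.integers(1, 4, size=len(pos))) % 4
        rows.append(
            pd.DataFrame(
                {
                    "locus": spec.locus_id,
                    "pos": pos,
                    "anc": [BASES[c] for c in anc_codes],
                    "der": [BASES[c] for c in der_codes],
                    "count_fen": c1,
                    "count_alp": c2,
                }
            )
        )
    snps = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["locus", "pos", "anc", "der", "count_fen", "count_alp"])
    )
    return TrueFrequencyTable(
        snps=snps, n1=n1, n2=n2, loci={s.locus_id: s.length for s in loci}
    )


def simulate_site_classes(
    freq_table: TrueFrequencyTable,
    proportions: tuple[float, float, float] = DEFAULT_CLASS_PROPORTIONS,
    seed: int = 0,
    afd_bias: float = 0.0,
) -> TrueFrequencyTable:
    """Label every SNP noncoding / synonymous / nonsynonymous.

    With ``afd_bias == 0`` labels are multinomial with the given
    proportions, independent of frequencies.  With ``afd_bias > 0``
    nonsynonymous labels are preferentially assigned to SNPs with small
    allele-frequency difference (weight ``exp(-afd_bias * AFD)``),
    emulating purifying selection holding constrained sites back from
    diverging; class totals keep the same expected proportions.
    """
    props = np.asarray(proportions, dtype=float)
    if (props < 0).any():
        raise ValueError("negative class proportions")
    if props.sum() <= 0:
        raise ValueError("class proportions must sum to a positive value")
    props = props / props.sum()
    n = freq_table.n_snps
    _, np_rng = _rngs(_spawn(seed, 1))
    counts = np_rng.multinomial(n, props)
    labels = np.empty(n, dtype=object)
    order = np_rng.permutation(n)
    if afd_bias == 0.0:
        lab_pool = np.repeat(np.array(SITE_CLASSES, dtype=object), counts)
        labels[order] = lab_pool
    else:
        p1, p2 = freq_table.frequencies()
        afd = np.abs(p1 - p2)
        w = np.exp(-afd_bias * afd)
        nonsyn = np_rng.choice(n, size=counts[2], replace=False, p=w / w.sum())
        rest = np.setdiff1d(np.arange(n), nonsyn)
        rest = np_rng.permutation(rest)
        labels[nonsyn] = "nonsynonymous"
        labels[rest[: counts[0]]] = "noncoding"
        labels[rest[counts[0]:]] = "synonymous"
    snps = freq_table.snps.copy()
    snps["site_class"] = labels
    return TrueFrequencyTable(
        snps=snps, n1=freq_table.n1, n2=freq_table.n2, loci=dict(freq_table.loci)
    )


def sample_pooled_reads(
    freq_table: TrueFrequencyTable,
    profile: PoolReadProfile,
    seed: int = 0,
) -> dict[tuple[str, int], dict[str, ReadStack]]:
    """Draw pooled sequencing reads for every locus and library.

    Returns ``{(pool, replicate): {locus_id: ReadStack}}``.  Per library and
    amplicon, mean coverage is gamma-distributed around ``target_depth``;
    reads of fixed length are placed uniformly (clipped to the locus) on
    both strands; at each covered SNP the read's base is the derived allele
    with probability equal to the pool's true frequency, then flipped to the
    site's other allele with probability ``error_rate``.
    """
    out: dict[tuple[str, int], dict[str, ReadStack]] = {}
    snp_by_locus = dict(tuple(freq_table.snps.groupby("locus", sort=False)))
    pool_n = {"FEN": freq_table.n1, "ALP": freq_table.n2}
    count_col = {"FEN": "count_fen", "ALP": "count_alp"}
    for pi, pool in enumerate(POOLS):
        for rep in range(profile.n_replicates):
            stacks: dict[str, ReadStack] = {}
            for li, (locus_id, length) in enumerate(freq_table.loci.items()):
                _, np_rng = _rngs(_spawn(seed, 2, pi, rep, li))
                read_len = min(profile.read_length, length)
                mean_depth = np_rng.gamma(
                    profile.depth_dispersion, profile.target_depth / profile.depth_dispersion
                )
                span = length + read_len - 1
                n_reads = np_rng.poisson(mean_depth * span / read_len)
                raw_start = np_rng.integers(1 - (read_len - 1), length + 1, size=n_reads)
                start = np.maximum(raw_start, 1)
                end = np.minimum(raw_start + read_len - 1, length)
                strand = np.where(
                    np_rng.random(n_reads) < profile.strand_balance, PLUS, MINUS
                ).astype(np.int8)
                calls: dict[int, tuple[np.ndarray, np.ndarray]] = {}
                sub = snp_by_locus.get(locus_id)
                if sub is not None and n_reads:
                    n_chr = pool_n[pool]
                    for pos, anc, der, cnt in zip(
                        sub["pos"], sub["anc"], sub["der"], sub[count_col[pool]]
                    ):
                        cover = np.flatnonzero((start <= pos) & (end >= pos))
                        if len(cover) == 0:
                            continue
                        derived = np_rng.random(len(cover)) < cnt / n_chr
                        if profile.error_rate > 0:
                            flip = np_rng.random(len(cover)) < profile.error_rate
                            derived = derived ^ flip
                        codes = np.where(
                            derived, BASES.index(der), BASES.index(anc)
                        ).astype(np.int8)
                        calls[int(pos)] = (cover, codes)
                stacks[locus_id] = ReadStack(
                    locus_id=locus_id,
                    locus_length=length,
                    pool=pool,
                    replicate=rep,
                    start=start.astype(np.int64),
                    length=(end - start + 1).astype(np.int64),
                    strand=strand,
                    snp_calls=calls,
                )
            out[(pool, rep)] = stacks
    return out


def _reference_sequences(freq_table: TrueFrequencyTable, seed: int) -> dict[str, str]:
    """Random reference sequences whose bases agree with SNP ancestral alleles."""
    refs = {}
    for li, (locus_id, length) in enumerate(freq_table.loci.items()):
        _, np_rng = _rngs(_spawn(seed, 3, li))
        seq = np.array(list(BASES))[np_rng.integers(0, 4, size=length)]
        sub = freq_table.snps[freq_table.snps["locus"] == locus_id]
        seq[sub["pos"].to_numpy() - 1] = sub["anc"].to_numpy()
        refs[locus_id] = "".join(seq)
    return refs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_dataset(
    model: DemographicModel,
    loci: list[LocusSpec] | None = None,
    profile: PoolReadProfile | None = None,
    out_dir: str | Path = ".",
    seed: int = 0,
    n1: int = 96,
    n2: int = 96,
    class_proportions: tuple[float, float, float] = DEFAULT_CLASS_PROPORTIONS,
    afd_bias: float = 0.0,
) -> dict:
    """Simulate a complete synthetic dataset and write it as plain text.

    Emits: reads.tsv (aligned read stacks), sync.tsv (per-position strand-
    split base counts per library), truth_frequencies.tsv, annotation.tsv,
    outgroup.tsv, reference.fasta, model.yaml and manifest.json.  Re-running
    with identical arguments reproduces byte-identical files.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    loci = loci if loci is not None else default_loci()
    profile = profile if profile is not None else PoolReadProfile()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = simulate_genealogy_counts(model, loci, n1=n1, n2=n2, seed=seed)
    table = simulate_site_classes(table, class_proportions, seed=seed, afd_bias=afd_bias)
    stacks = sample_pooled_reads(table, profile, seed=seed)
    refs = _reference_sequences(table, seed)

    files: list[Path] = []

    reads_path = out / "reads.tsv"
    frames = [
        stacks[(pool, rep)][locus_id].to_frame()
        for pool in POOLS
        for rep in range(profile.n_replicates)
        for locus_id in table.loci
    ]
    pd.concat(frames, ignore_index=True).to_csv(reads_path, sep="\t", index=False)
    files.append(reads_path)

    sync_path = out / "sync.tsv"
    write_sync(sync_path, stacks, refs, table, profile.n_replicates)
    files.append(sync_path)

    truth_path = out / "truth_frequencies.tsv"
    table.snps.to_csv(truth_path, sep="\t", index=False)
    files.append(truth_path)

    ann_path = out / "annotation.tsv"
    table.snps[["locus", "pos", "site_class"]].to_csv(ann_path, sep="\t", index=False)
    files.append(ann_path)

    outgroup_path = out / "outgroup.tsv"
    table.snps[["locus", "pos", "anc"]].rename(columns={"anc": "outgroup"}).to_csv(
        outgroup_path, sep="\t", index=False
    )
    files.append(outgroup_path)

    fasta_path = out / "reference.fasta"
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in refs.items()]
    SeqIO.write(records, str(fasta_path), "fasta")
    files.append(fasta_path)

    model_path = out / "model.yaml"
    params = {
        "model": model.to_dict(),
        "loci": [{"locus_id": s.locus_id, "length": s.length} for s in loci],
        "profile": profile.__dict__,
        "n1": n1,
        "n2": n2,
        "class_proportions": list(class_proportions),
        "afd_bias": afd_bias,
    }
    model_path.write_text(yaml.safe_dump(params, sort_keys=True))
    files.append(model_path)

    manifest = {
        "seed": int(seed),
        "version": __version__,
        "n_snps": int(table.n_snps),
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_sync(
    path: Path,
    stacks: dict[tuple[str, int], dict[str, ReadStack]],
    refs: dict[str, str],
    table: TrueFrequencyTable,
    n_replicates: int,
) -> None:
    """Sync-style TSV: locus, position, reference base, then two
    colon-separated A:C:G:T:N:del count fields (plus then minus strand) per
    library, libraries ordered FEN replicates then ALP replicates."""
    libraries = [(pool, rep) for pool in POOLS for rep in range(n_replicates)]
    lines = ["locus\tpos\tref\t" + "\t".join(
        f"{pool}{rep + 1}_{s}" for pool, rep in libraries for s in ("plus", "minus")
    )]
    for locus_id in table.loci:
        sub = table.snps[table.snps["locus"] == locus_id]
        for pos in sub["pos"]:
            fields = [locus_id, str(int(pos)), refs[locus_id][int(pos) - 1]]
            for pool, rep in libraries:
                stack = stacks[(pool, rep)][locus_id]
                counts = np.zeros((2, 4), dtype=np.int64)
                if int(pos) in stack.snp_calls:
                    ridx, codes = stack.snp_calls[int(pos)]
                    np.add.at(counts, (stack.strand[ridx], codes), 1)
                for strand in (PLUS, MINUS):
                    fields.append(":".join(str(c) for c in counts[strand]) + ":0:0")
            lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
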