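"""Divergence scan combining F_ST and allele-frequency difference.

Each SNP is placed on orthogonal coordinates of Hudson F_ST and absolute
allele-frequency difference (AFD); its Euclidean distance to the origin,

    divD = sqrt(F_ST^2 + AFD^2),

summarizes its divergence.  Significance envelopes come from null datasets
simulated under the fitted demographic history: within each null dataset the
95% / 97.5% / 99% divD quantiles are taken (for SNPs, and for gene averages
over the observed gene-size layout), and the final cutoff at each level is
the maximum of that quantile across all null datasets — a deliberately
conservative rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import DemographicModel
from .sumstats import hudson_fst_arrays

LEVELS = (0.95, 0.975, 0.99)


def divergence_distance(fst: np.ndarray | float, afd: np.ndarray | float):
    """divD = sqrt(fst^2 + afd^2).  Negative F_ST enters via its square."""
    fst = np.asarray(fst, dtype=float)
    afd = np.asarray(afd, dtype=float)
    if not (np.isfinite(fst).all() and np.isfinite(afd).all()):
        raise ValueError("divD requires finite F_ST and AFD")
    out = np.sqrt(fst**2 + afd**2)
    return float(out) if out.ndim == 0 else out


def score_snps(
    p1: np.ndarray, p2: np.ndarray, n1: int = 96, n2: int = 96
) -> pd.DataFrame:
    """Per-SNP F_ST, AFD and divD.  SNPs with undefined F_ST (zero Hudson
    denominator) get divD from AFD alone with fst recorded as NaN."""
    num, den, fst = hudson_fst_arrays(p1, p2, n1, n2)
    afd = np.abs(np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float))
    divd = np.sqrt(np.where(np.isnan(fst), 0.0, fst) ** 2 + afd**2)
    return pd.DataFrame(
        {"fst": fst, "afd": afd, "divd": divd, "fst_num": num, "fst_den": den}
    )


def gene_divd(scores: pd.DataFrame, genes: np.ndarray | pd.Series) -> pd.Series:
    """Gene-level divD: the arithmetic mean of SNP divD within each gene."""
    genes = np.asarray(genes)
    if len(genes) != len(scores):
        raise ValueError("gene labels must match the score table")
    if len(scores) == 0:
        raise ValueError("no SNPs to average")
    return scores.groupby(genes)["divd"].mean()


@dataclass
class EnvelopeCutoffs:
    """Outlier cutoffs: max across null datasets of per-dataset quantiles."""

    levels: tuple[float, ...]
    snp_cutoffs: dict[float, float]
    gene_cutoffs: dict[float, float] | None
    n_null_datasets: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lv = sorted(self.levels)
        for lo, hi in zip(lv, lv[1:]):
            if self.snp_cutoffs[hi] < self.snp_cutoffs[lo] - 1e-12:
                raise ValueError("cutoffs must be non-decreasing in level")


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """ceil(q*n)-th order statistic of the ranked values."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty score set")
    k = min(max(int(np.ceil(q * n)), 1), n)
    return float(v[k - 1])


def draw_null_frequencies(
    expected_sfs_counts: np.ndarray,
    n_snps: int,
    n1: int,
    n2: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw SNP frequency pairs from an expected full-size joint SFS.

    Cells are sampled multinomially with probability proportional to the
    expected SFS mass (monomorphic corners excluded); counts (i, j) become
    frequencies (i/n1, j/n2).
    """
    w = np.asarray(expected_sfs_counts, dtype=float).copy()
    if w.shape != (n1 + 1, n2 + 1):
        raise ValueError("expected SFS shape does not match sample sizes")
    w[0, 0] = 0.0
    w[n1, n2] = 0.0
    p = w.ravel() / w.sum()
    cells = rng.choice(len(p), size=n_snps, p=p)
    i, j = np.unravel_index(cells, w.shape)
    return i / n1, j / n2


def simulate_null_scores(
    models: DemographicModel | list[DemographicModel],
    n_snps: int,
    gene_sizes: np.ndarray,
    n_datasets: int = 1000,
    n1: int = 96,
    n2: int = 96,
    seed: int = 0,
    n_sim_snps: int = 100_000,
) -> list[dict]:
    """Null divD score sets under the fitted demographic history.

    For each null dataset the expected full-size joint SFS under the (per
    dataset) model is used to draw ``n_snps`` frequency pairs; per-SNP
    F_ST/AFD/divD are computed and SNPs are randomly grouped into genes
    matching the observed gene-size multiset.  Passing one model reuses a
    single expected SFS for all datasets; passing a list (e.g. bootstrap
    parameter sets) cycles through per-replicate models, mirroring
    envelope construction from bootstrap-estimated histories.
    """
    from .demog import expected_sfs as _expected_sfs

    gene_sizes = np.asarray(gene_sizes, dtype=int)
    if gene_sizes.sum() != n_snps:
        raise ValueError(
            f"gene sizes sum to {gene_sizes.sum()}, expected n_snps={n_snps}"
        )
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    model_list = models if isinstance(models, list) else [models]
    # one expected SFS per distinct model, simulated at full sample size
    sfs_cache: dict[int, np.ndarray] = {}
    gene_labels = np.repeat(np.arange(len(gene_sizes)), gene_sizes)
    out = []
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(23,)))
    for d in range(n_datasets):
        mi = d % len(model_list)
        if mi not in sfs_cache:
            exp = _expected_sfs(
                model_list[mi], n1=n1, n2=n2, n_sim=n_sim_snps,
                seed=int(seed) + 7919 * mi, smoothing=0.0,
            )
            sfs_cache[mi] = exp.proportions
        p1, p2 = draw_null_frequencies(sfs_cache[mi], n_snps, n1, n2, rng)
        scores = score_snps(p1, p2, n1, n2)
        out.append(
            {
                "snp_divd": scores["divd"].to_numpy(),
                "gene_divd": gene_divd(scores, rng.permutation(gene_labels)).to_numpy(),
            }
        )
    return out


def envelope_cutoffs(
    null_scores: list[dict],
    levels: tuple[float, ...] = LEVELS,
    provenance: dict | None = None,
) -> EnvelopeCutoffs:
    """Max-rule envelope cutoffs from null score sets.

    Within each null dataset the level-q envelope is the nearest-rank
    empirical q-quantile of divD (separately for SNP and gene scores); the
    cutoff at each level is the maximum of that quantile across datasets.
    """
    if len(null_scores) < 2:
        raise ValueError("need at least two null datasets")
    snp_cut = {
        q: max(_nearest_rank_quantile(ds["snp_divd"], q) for ds in null_scores)
        for q in levels
    }
    have_genes = all("gene_divd" in ds and ds["gene_divd"] is not None for ds in null_scores)
    gene_cut = (
        {
            q: max(_nearest_rank_quantile(ds["gene_divd"], q) for ds in null_scores)
            for q in levels
        }
        if have_genes
        else None
    )
    return EnvelopeCutoffs(
        levels=tuple(levels),
        snp_cutoffs=snp_cut,
        gene_cutoffs=gene_cut,
        n_null_datasets=len(null_scores),
        provenance=provenance or {},
    )


def call_outliers(
    scores: pd.DataFrame,
    cutoffs: EnvelopeCutoffs,
    p1: np.ndarray | None = None,
    p2: np.ndarray | None = None,
    genes: np.ndarray | None = None,
) -> dict:
    """Flag SNP (and optionally gene) outliers against envelope cutoffs.

    A SNP is flagged at level q iff divD strictly exceeds the level-q
    cutoff; flagging nests (1% outliers are 2.5% and 5% outliers).
    Frequency regimes are annotated per pool: near fixation or loss
    (p >= 0.99 or p <= 0.01) and intermediate (0.3-0.7).
    """
    divd = scores["divd"].to_numpy()
    snp_tbl = pd.DataFrame({"divd": divd})
    levels_desc = sorted(cutoffs.levels)  # ascending stringency
    smallest = np.full(len(divd), np.nan)
    for q in levels_desc:
        flag = divd > cutoffs.snp_cutoffs[q]
        snp_tbl[f"outlier_{q}"] = flag
        smallest = np.where(flag, q, smallest)
    snp_tbl["most_stringent_level"] = smallest
    if p1 is not None and p2 is not None:
        p1 = np.asarray(p1, dtype=float)
        p2 = np.asarray(p2, dtype=float)
        snp_tbl["near_fixation_fen"] = (p1 >= 0.99) | (p1 <= 0.01)
        snp_tbl["near_fixation_alp"] = (p2 >= 0.99) | (p2 <= 0.01)
        snp_tbl["intermediate_fen"] = (p1 >= 0.3) & (p1 <= 0.7)
        snp_tbl["intermediate_alp"] = (p2 >= 0.3) & (p2 <= 0.7)
    result = {"snps": snp_tbl}
    if genes is not None and cutoffs.gene_cutoffs is not None:
        g = gene_divd(scores, genes)
        gene_tbl = pd.DataFrame({"gene": g.index, "divd": g.to_numpy()})
        for q in levels_desc:
            gene_tbl[f"outlier_{q}"] = gene_tbl["divd"] > cutoffs.gene_cutoffs[q]
        result["genes"] = gene_tbl
    return result


def sensitivity_reanalysis(
    scores_full: pd.DataFrame,
    maf: np.ndarray,
    cutoffs: EnvelopeCutoffs,
    maf_cutoffs: tuple[float, ...] = (0.01, 0.1),
) -> dict:
    """Re-run the outlier scan on minor-allele-frequency subsets.

    For each MAF cutoff, reports outlier counts per level, the overlap with
    the full-set outliers, and the Pearson correlation of divD between the
    full analysis and the subset (on the SNPs common to both).
    """
    maf = np.asarray(maf, dtype=float)
    full_calls = call_outliers(scores_full, cutoffs)
    report: dict = {"full": {"n_snps": len(scores_full)}}
    for q in cutoffs.levels:
        report["full"][f"n_outliers_{q}"] = int(
            full_calls["snps"][f"outlier_{q}"].sum()
        )
    for mc in maf_cutoffs:
        keep = maf >= mc
        sub = scores_full.loc[keep]
        sub_calls = call_outliers(sub, cutoffs)
        entry = {"n_snps": int(keep.sum())}
        for q in cutoffs.levels:
            sub_flag = sub_calls["snps"][f"outlier_{q}"].to_numpy()
            full_flag = full_calls["snps"][f"outlier_{q}"].to_numpy()[keep]
            entry[f"n_outliers_{q}"] = int(sub_flag.sum())
            entry[f"overlap_{q}"] = int((sub_flag & full_flag).sum())
        if keep.sum() >= 2:
            # on SNPs common to both analyses divD is unchanged
            entry["pearson_r"] = float(
                np.corrcoef(
                    scores_full["divd"].to_numpy()[keep], sub["divd"].to_numpy()
                )[0, 1]
            )
            # distribution-level similarity: correlate matched quantiles
            qs = np.linspace(0.01, 0.99, 99)
            entry["pearson_r_quantiles"] = float(
                np.corrcoef(
                    np.quantile(scores_full["divd"].to_numpy(), qs),
                    np.quantile(sub["divd"].to_numpy(), qs),
                )[0, 1]
            )
        report[f"maf>={mc}"] = entry
    return report
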