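"""Self-consistency evaluations under the fitted demographic model.

Each function regenerates its inputs from scratch under the fitted
constant-size IM model (modal estimates) and recomputes one headline
quantity of the analysis: overall Hudson F_ST, per-pool nucleotide
diversity, the post-downsampling read depth, the multinomial goodness of
fit of the projected joint SFS, and the null false-positive behaviour of
the divD envelope scan.
"""

from __future__ import annotations

import numpy as np

from .demog import anscombe_residuals, expected_sfs
from .divscan import call_outliers, envelope_cutoffs, score_snps, simulate_null_scores
from .models import default_loci, fitted_constant_model
from .poolproc import downsample_gene_coverage
from .reads import ReadStack
from .simdata import simulate_genealogy_counts
from .sumstats import (
    build_joint_sfs,
    combine_fst,
    hudson_fst_arrays,
    nucleotide_diversity,
    project_sfs,
)


def _sub_seeds(seed: int, key: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(key),))
    return [int(s) % 2**31 for s in ss.generate_state(n)]


def fst_and_diversity(seed: int = 1, n_reps: int = 10) -> dict:
    """Overall Hudson F_ST (ratio of sums) and mean per-site pi per pool on
    replicate 88-locus datasets simulated under the fitted model."""
    model = fitted_constant_model()
    loci = default_loci()
    fsts, pis_fen, pis_alp, n_snps = [], [], [], 0
    for rep_seed in _sub_seeds(seed, 1, n_reps):
        tbl = simulate_genealogy_counts(model, loci, seed=rep_seed)
        p1, p2 = tbl.frequencies()
        num, den, _ = hudson_fst_arrays(p1, p2)
        fsts.append(combine_fst(num, den, "ratio_of_sums"))
        n_snps += tbl.n_snps
        for locus_id, length in tbl.loci.items():
            sub = tbl.snps[tbl.snps["locus"] == locus_id]
            pis_fen.append(
                nucleotide_diversity(sub["count_fen"].to_numpy() / 96, 96, length)
            )
            pis_alp.append(
                nucleotide_diversity(sub["count_alp"].to_numpy() / 96, 96, length)
            )
    return {
        "fst_ratio_of_sums": float(np.mean(fsts)),
        "pi_fen": float(np.mean(pis_fen)),
        "pi_alp": float(np.mean(pis_alp)),
        "n_snps_total": int(n_snps),
        "n_reps": n_reps,
    }


def saturated_gene_depth(
    seed: int = 1,
    n_reps: int = 10,
    per_strand_depth: int = 400,
    locus_length: int = 1000,
    read_length: int = 109,
    cap_per_strand: int = 100,
) -> dict:
    """Mean per-position depth of one library after the 5'->3' per-gene
    downsampling sweep on a saturated synthetic gene."""
    means = []
    for rep_seed in _sub_seeds(seed, 2, n_reps):
        rng = np.random.default_rng(rep_seed)
        n_per_strand = int(
            per_strand_depth * (locus_length + read_length - 1) / read_length
        )
        starts, strands = [], []
        for s in (0, 1):
            raw = rng.integers(
                1 - (read_length - 1), locus_length + 1, size=n_per_strand
            )
            starts.append(raw)
            strands.append(np.full(n_per_strand, s, dtype=np.int8))
        raw = np.concatenate(starts)
        start = np.maximum(raw, 1)
        end = np.minimum(raw + read_length - 1, locus_length)
        stack = ReadStack(
            locus_id="synthetic", locus_length=locus_length, pool="FEN", replicate=0,
            start=start.astype(np.int64), length=(end - start + 1).astype(np.int64),
            strand=np.concatenate(strands),
        )
        out = downsample_gene_coverage(stack, cap_per_strand, seed=rep_seed)
        means.append(out.depth_profile().mean())
    return {"mean_depth": float(np.mean(means)), "n_reps": n_reps}


def anscombe_self_fit(
    seed: int = 1, n_datasets: int = 10, n_expected_snps: int = 100_000
) -> dict:
    """Median over datasets of the maximum |Anscombe residual| comparing
    88-locus datasets simulated under the fitted model with the same
    model's expected projected SFS."""
    model = fitted_constant_model()
    loci = default_loci()
    exp_seed, *data_seeds = _sub_seeds(seed, 3, n_datasets + 1)
    exp = expected_sfs(model, 10, 10, n_sim=n_expected_snps, seed=exp_seed)
    maxes = []
    for ds in data_seeds:
        tbl = simulate_genealogy_counts(model, loci, seed=ds)
        p1, p2 = tbl.frequencies()
        obs = project_sfs(build_joint_sfs(p1, p2), 10, 10)
        maxes.append(anscombe_residuals(obs, exp).max_abs_residual)
    return {
        "median_max_abs_residual": float(np.median(maxes)),
        "per_dataset": [float(x) for x in maxes],
        "n_datasets": n_datasets,
    }


def null_false_positive_rate(
    seed: int = 1,
    n_null: int = 200,
    n_fresh: int = 20,
    n_snps: int = 2791,
    n_genes: int = 88,
    n_sim_snps: int = 200_000,
) -> dict:
    """Percentage of SNPs flagged at the 5% divD envelope when the analysed
    data are themselves generated under the null demographic model.

    Envelopes use the max rule over ``n_null`` null datasets of ``n_snps``
    SNPs drawn from the model's expected joint SFS; the fresh datasets are
    independent coalescent simulations of the 88-locus panel.
    """
    model = fitted_constant_model()
    loci = default_loci()
    s_gene, s_null, *fresh_seeds = _sub_seeds(seed, 4, n_fresh + 2)
    rng = np.random.default_rng(s_gene)
    lengths = np.array([s.length for s in loci], dtype=float)
    gene_sizes = rng.multinomial(n_snps, lengths / lengths.sum())
    null = simulate_null_scores(
        model, n_snps, gene_sizes, n_datasets=n_null, seed=s_null,
        n_sim_snps=n_sim_snps,
    )
    cutoffs = envelope_cutoffs(null)
    rates = []
    for fs in fresh_seeds:
        tbl = simulate_genealogy_counts(model, loci, seed=fs)
        p1, p2 = tbl.frequencies()
        out = call_outliers(score_snps(p1, p2), cutoffs)["snps"]
        rates.append(100.0 * out["outlier_0.95"].mean())
    return {
        "false_positive_percent": float(np.mean(rates)),
        "snp_cutoffs": {str(q): float(c) for q, c in cutoffs.snp_cutoffs.items()},
        "n_null": n_null,
        "n_fresh": n_fresh,
    }


def split_time_recovery(
    seed: int = 1,
    n_repeats: int = 10,
    ci_years: tuple[float, float] = (3.6e6, 14e6),
    n_sim: int = 20_000,
    max_cycles: int = 3,
) -> dict:
    """Bootstrap-style refits on data simulated at the modal estimates:
    how often the refitted split time stays inside the published 95% CI."""
    from .demog import OptimizerConfig, fit_model

    model = fitted_constant_model()
    loci = default_loci()
    hits = 0
    estimates = []
    for i, rep_seed in enumerate(_sub_seeds(seed, 5, n_repeats)):
        tbl = simulate_genealogy_counts(model, loci, seed=rep_seed)
        p1, p2 = tbl.frequencies()
        obs = project_sfs(build_joint_sfs(p1, p2), 10, 10)
        fit = fit_model(
            obs, "constant",
            OptimizerConfig(max_cycles=max_cycles, n_sim=n_sim, search_maxiter=8),
            seed=rep_seed % 2**31, init=model,
        )
        t_years = fit.model.t_div * model.gen_time
        estimates.append(t_years)
        if ci_years[0] <= t_years <= ci_years[1]:
            hits += 1
    return {
        "hits": hits,
        "n_repeats": n_repeats,
        "t_div_years": [float(t) for t in estimates],
    }
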