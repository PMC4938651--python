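"""Stage orchestration: simulate -> process -> stats -> demog-fit -> divd-scan -> report.

Every stage reads and writes plain-text files under the run directory, so
any stage can be re-run from its persisted inputs or fed user-supplied data
in place of the synthetic fixtures.  A run manifest records parameters,
seeds and SHA-256 checksums of all inputs and outputs per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, divscan, demog, poolproc, simdata, sumstats
from .models import (
    DemographicModel,
    FilterConfig,
    LocusSpec,
    PoolReadProfile,
    default_loci,
    fitted_constant_model,
)
from .reads import build_pileup, stack_from_frame

logger = logging.getLogger("poolscan")

STAGES = ("simulate", "process", "stats", "demog-fit", "divd-scan", "report")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _model_from_config(cfg: dict) -> DemographicModel:
    spec = cfg.get("model", "fitted_constant")
    if spec == "fitted_constant":
        return fitted_constant_model()
    if isinstance(spec, dict):
        return DemographicModel.from_dict(spec)
    raise ValueError(f"unrecognized model spec {spec!r}")


def _loci_from_config(cfg: dict) -> list[LocusSpec]:
    if "loci" in cfg:
        return [LocusSpec(d["locus_id"], int(d["length"])) for d in cfg["loci"]]
    return default_loci(
        n_loci=int(cfg.get("n_loci", 88)),
        total_length=int(cfg.get("total_length", 111_297)),
    )


class PipelineRunner:
    """Executes pipeline stages against one output directory."""

    def __init__(self, config: dict, out_dir: str | Path, seed: int | None = None):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(seed if seed is not None else config.get("seed", 0))
        self.manifest: dict = {
            "version": __version__,
            "seed": self.seed,
            "stages": {},
        }

    # -- manifest plumbing -------------------------------------------------
    def _record(self, stage: str, params: dict, inputs: list[Path], outputs: list[Path],
                failed: bool = False) -> None:
        self.manifest["stages"][stage] = {
            "params": params,
            "seed": self.seed,
            "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
            "outputs": {str(p): _sha256(p) for p in outputs if Path(p).exists()},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
            "failed": failed,
        }
        (self.out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )

    def run(self, stages: list[str]) -> dict:
        for stage in stages:
            logger.info("stage %s: start (seed=%d)", stage, self.seed)
            method = getattr(self, "stage_" + stage.replace("-", "_"))
            try:
                method()
            except Exception:
                self._record(stage, {}, [], [], failed=True)
                logger.exception("stage %s failed", stage)
                raise
            logger.info("stage %s: done", stage)
        return self.manifest

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config.get("simulate", {})
        model = _model_from_config(cfg)
        loci = _loci_from_config(cfg)
        profile = PoolReadProfile(**cfg.get("profile", {}))
        sim_dir = self.out / "sim"
        man = simdata.write_fixture_dataset(
            model,
            loci,
            profile,
            sim_dir,
            seed=self.seed,
            n1=int(cfg.get("n1", 96)),
            n2=int(cfg.get("n2", 96)),
            class_proportions=tuple(
                cfg.get("class_proportions", simdata.DEFAULT_CLASS_PROPORTIONS)
            ),
            afd_bias=float(cfg.get("afd_bias", 0.0)),
        )
        outputs = [sim_dir / name for name in man["files"]]
        self._record("simulate", cfg, [], outputs + [sim_dir / "manifest.json"])

    def stage_process(self) -> None:
        from Bio import SeqIO

        cfg = self.config.get("process", {})
        sim_dir = Path(cfg.get("input_dir", self.out / "sim"))
        reads_path = sim_dir / "reads.tsv"
        ref_path = sim_dir / "reference.fasta"
        for p in (reads_path, ref_path):
            if not p.exists():
                raise FileNotFoundError(f"process stage input missing: {p}")
        refs = {r.id: str(r.seq) for r in SeqIO.parse(str(ref_path), "fasta")}
        reads = pd.read_csv(reads_path, sep="\t")
        filters = FilterConfig(**cfg.get("filters", {}))
        cap = int(cfg.get("cap_per_strand", filters.strand_cap))

        libraries: dict[tuple[str, int], dict[str, object]] = {}
        for (pool, rep), lib_df in reads.groupby(["pool", "replicate"]):
            stacks = {
                locus: stack_from_frame(sub, locus, len(refs[locus]))
                for locus, sub in lib_df.groupby("locus")
            }
            libraries[(pool, int(rep))] = stacks

        accounting = []
        target = cfg.get("library_target_size")
        if target is not None:
            sizes = {
                key: sum(s.n_reads for s in stacks.values())
                for key, stacks in libraries.items()
            }
            tgt = min(sizes.values()) if target == "min" else int(target)
            for i, (key, stacks) in enumerate(sorted(libraries.items())):
                order = sorted(stacks)
                ds = poolproc.downsample_library(
                    [stacks[k] for k in order], tgt, seed=self.seed + 31 * i
                )
                libraries[key] = dict(zip(order, ds))

        for i, (key, stacks) in enumerate(sorted(libraries.items())):
            before = sum(s.n_reads for s in stacks.values())
            libraries[key] = {
                k: poolproc.downsample_gene_coverage(s, cap, seed=self.seed + 97 * i + j)
                for j, (k, s) in enumerate(sorted(stacks.items()))
            }
            after = sum(s.n_reads for s in libraries[key].values())
            accounting.append(
                {"pool": key[0], "replicate": key[1],
                 "reads_in": before, "reads_after_gene_downsampling": after}
            )

        reference_lookup = {
            (locus, pos + 1): base
            for locus, seq in refs.items()
            for pos, base in enumerate(seq)
        }
        calls = []
        for locus in sorted(refs):
            cols = {}
            for pool in simdata.POOLS:
                stacks = [
                    libraries[key][locus]
                    for key in sorted(libraries)
                    if key[0] == pool and locus in libraries[key]
                ]
                cols[pool] = build_pileup(stacks)
            calls.extend(
                poolproc.call_snps(cols["FEN"], cols["ALP"], filters, reference_lookup)
            )
        outgroup_path = sim_dir / "outgroup.tsv"
        if outgroup_path.exists():
            calls = poolproc.polarize(calls, pd.read_csv(outgroup_path, sep="\t"))
        ann_path = sim_dir / "annotation.tsv"
        if ann_path.exists():
            calls = poolproc.annotate_site_classes(calls, pd.read_csv(ann_path, sep="\t"))

        snp_path = self.out / "snp_table.tsv"
        poolproc.calls_to_frame(calls).to_csv(snp_path, sep="\t", index=False)
        acc_path = self.out / "read_accounting.tsv"
        pd.DataFrame(accounting).to_csv(acc_path, sep="\t", index=False)
        self._record(
            "process", cfg, [reads_path, ref_path], [snp_path, acc_path]
        )

    def _snp_table(self) -> pd.DataFrame:
        path = self.out / "snp_table.tsv"
        if not path.exists():
            raise FileNotFoundError(f"stats stage requires {path}")
        return pd.read_csv(path, sep="\t")

    def _loci_lengths(self) -> dict[str, int]:
        from Bio import SeqIO

        ref = self.out / "sim" / "reference.fasta"
        if ref.exists():
            return {r.id: len(r.seq) for r in SeqIO.parse(str(ref), "fasta")}
        return {s.locus_id: s.length for s in _loci_from_config(self.config.get("simulate", {}))}

    def stage_stats(self) -> None:
        cfg = self.config.get("stats", {})
        df = self._snp_table()
        n1 = int(cfg.get("n1", 96)) if "n1" in cfg else int(self.config.get("simulate", {}).get("n1", 96))
        n2 = int(self.config.get("simulate", {}).get("n2", 96))
        loci = self._loci_lengths()
        summaries = sumstats.locus_summaries(df, loci, n=n1)
        sum_path = self.out / "locus_summaries.tsv"
        summaries.to_csv(sum_path, sep="\t", index=False)

        p1 = df["p_fen"].to_numpy(dtype=float)
        p2 = df["p_alp"].to_numpy(dtype=float)
        scores = divscan.score_snps(p1, p2, n1, n2)
        fst_tbl = pd.concat(
            [df[["locus", "pos", "site_class"]].reset_index(drop=True), scores], axis=1
        )
        fst_path = self.out / "snp_fst.tsv"
        fst_tbl.to_csv(fst_path, sep="\t", index=False)

        overall = {
            "fst_ratio_of_sums": sumstats.combine_fst(
                scores["fst_num"], scores["fst_den"], "ratio_of_sums"
            ),
            "fst_mean_of_ratios": sumstats.combine_fst(
                scores["fst_num"], scores["fst_den"], "mean_of_ratios"
            ),
            "accounting": sumstats.classify_and_count(df),
        }
        silent = df["site_class"].isin(["noncoding", "synonymous"]) & df["polarized"]
        if silent.sum() >= 2:
            ns = df.loc[~df["site_class"].isin(["noncoding", "synonymous"])]
            if len(ns) >= 2 and silent.sum() >= 2:
                overall["class_comparison_divd"] = sumstats.compare_site_classes(
                    scores["divd"].to_numpy(),
                    np.where(
                        df["site_class"].isin(["noncoding", "synonymous"]),
                        "silent", "nonsynonymous",
                    ),
                    "silent", "nonsynonymous",
                )
        stats_path = self.out / "overall_stats.json"
        stats_path.write_text(json.dumps(overall, indent=2, sort_keys=True, default=float) + "\n")

        sfs_outputs = []
        if silent.any():
            sfs = sumstats.build_joint_sfs(p1[silent], p2[silent], n1, n2)
            proj = sumstats.project_sfs(sfs, 10, 10)
            raw_path = self.out / "joint_sfs_raw.txt"
            proj_path = self.out / "joint_sfs_projected.txt"
            sumstats.write_sfs_text(sfs, raw_path)
            sumstats.write_sfs_text(proj, proj_path)
            sfs_outputs = [raw_path, proj_path]
        self._record(
            "stats", cfg, [self.out / "snp_table.tsv"],
            [sum_path, fst_path, stats_path, *sfs_outputs],
        )

    def stage_demog_fit(self) -> None:
        cfg = self.config.get("demog", {})
        sfs_path = Path(cfg.get("sfs", self.out / "joint_sfs_projected.txt"))
        if not sfs_path.exists():
            raise FileNotFoundError(f"demog-fit requires {sfs_path}")
        observed = sumstats.read_sfs_text(sfs_path)
        scenarios = cfg.get("scenarios", ["constant"])
        opt = demog.OptimizerConfig(
            max_cycles=int(cfg.get("max_cycles", 10)),
            n_sim=int(cfg.get("n_sim", 20_000)),
            tolerance=float(cfg.get("tolerance", 0.01)),
        )
        init = fitted_constant_model() if cfg.get("init", "fitted") == "fitted" else None
        fits = []
        for s in scenarios:
            s_init = None
            if init is not None:
                s_init = dc_replace(
                    init,
                    ancestral_scenario=s,
                    growth_rate=1e-5 if s == "growth" else 0.0,
                    t_bot=init.t_div * 1.5 if s == "bottleneck" else None,
                )
            fits.append(
                demog.fit_model(observed, s, opt, seed=self.seed, init=s_init)
            )
        if len(fits) > 1:
            demog.akaike_weights(fits)
        else:
            fits[0].akaike_weight = 1.0
        best = min(fits, key=lambda f: f.aic)
        diag_exp = demog.expected_sfs(
            best.model, observed.n1, observed.n2,
            n_sim=int(cfg.get("n_sim_diagnostics", 100_000)), seed=self.seed + 1,
        )
        diag = demog.anscombe_residuals(observed, diag_exp)
        res_path = self.out / "anscombe_residuals.tsv"
        pd.DataFrame(diag.residuals).to_csv(res_path, sep="\t", index=False, header=False)

        gen_time = best.model.gen_time
        report = {
            "best_scenario": best.scenario,
            "max_abs_anscombe_residual": diag.max_abs_residual,
            "fits": [
                {
                    "scenario": f.scenario,
                    "log_cl": f.log_cl,
                    "k": f.k,
                    "aic": f.aic,
                    "akaike_weight": f.akaike_weight,
                    "converged": f.converged,
                    "parameters": f.model.to_dict(),
                    "t_div_years": f.model.t_div * gen_time,
                }
                for f in fits
            ],
        }
        fit_path = self.out / "demog_fit.json"
        fit_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

        outputs = [fit_path, res_path]
        n_boot = int(cfg.get("n_boot", 0))
        if n_boot >= 2:
            df = self._snp_table()
            silent = df["site_class"].isin(["noncoding", "synonymous"]) & df["polarized"]
            boot = demog.bootstrap_parameters(
                df.loc[silent, "p_fen"].to_numpy(dtype=float),
                df.loc[silent, "p_alp"].to_numpy(dtype=float),
                n_boot=n_boot,
                scenarios=tuple(scenarios),
                config=opt,
                seed=self.seed + 2,
                init=best.model,
            )
            boot_path = self.out / "bootstrap.tsv"
            boot.estimates.to_csv(boot_path, sep="\t", index=False)
            boot_sum = self.out / "bootstrap_summary.json"
            boot_sum.write_text(json.dumps(
                {"modes": boot.modes, "ci_low": boot.ci_low,
                 "ci_high": boot.ci_high, "support": boot.support},
                indent=2, sort_keys=True) + "\n")
            outputs += [boot_path, boot_sum]
        self._record("demog-fit", cfg, [sfs_path], outputs)

    def stage_divd_scan(self) -> None:
        cfg = self.config.get("divscan", {})
        df = self._snp_table()
        n1 = int(self.config.get("simulate", {}).get("n1", 96))
        n2 = int(self.config.get("simulate", {}).get("n2", 96))
        p1 = df["p_fen"].to_numpy(dtype=float)
        p2 = df["p_alp"].to_numpy(dtype=float)
        scores = divscan.score_snps(p1, p2, n1, n2)
        genes = df["locus"].to_numpy()
        gene_sizes = df.groupby("locus").size().to_numpy()

        fit_path = Path(cfg.get("model", self.out / "demog_fit.json"))
        if fit_path.exists():
            report = json.loads(fit_path.read_text())
            best = next(
                f for f in report["fits"] if f["scenario"] == report["best_scenario"]
            )
            model = DemographicModel.from_dict(best["parameters"])
        else:
            model = _model_from_config(self.config.get("simulate", {}))
        levels = tuple(float(x) for x in cfg.get("levels", divscan.LEVELS))
        null = divscan.simulate_null_scores(
            model,
            n_snps=len(df),
            gene_sizes=gene_sizes,
            n_datasets=int(cfg.get("n_null", 200)),
            n1=n1, n2=n2,
            seed=self.seed + 5,
            n_sim_snps=int(cfg.get("n_sim_snps", 100_000)),
        )
        cut = divscan.envelope_cutoffs(
            null, levels,
            provenance={"model": model.to_dict(), "seed": self.seed + 5,
                        "n_null": len(null)},
        )
        calls = divscan.call_outliers(scores, cut, p1, p2, genes)
        snp_out = pd.concat(
            [df[["locus", "pos", "site_class"]].reset_index(drop=True),
             calls["snps"]], axis=1,
        )
        out_path = self.out / "outliers_snp.tsv"
        snp_out.to_csv(out_path, sep="\t", index=False)
        outputs = [out_path]
        if "genes" in calls:
            gene_path = self.out / "outliers_gene.tsv"
            calls["genes"].to_csv(gene_path, sep="\t", index=False)
            outputs.append(gene_path)
        cut_path = self.out / "envelope_cutoffs.json"
        cut_path.write_text(json.dumps(
            {"levels": list(cut.levels),
             "snp_cutoffs": {str(k): v for k, v in cut.snp_cutoffs.items()},
             "gene_cutoffs": {str(k): v for k, v in (cut.gene_cutoffs or {}).items()},
             "n_null_datasets": cut.n_null_datasets,
             "provenance": cut.provenance},
            indent=2, sort_keys=True) + "\n")
        outputs.append(cut_path)

        scatter = pd.concat(
            [df[["locus", "pos", "site_class"]].reset_index(drop=True),
             scores[["fst", "afd", "divd"]]], axis=1)
        scat_path = self.out / "divd_scatter.tsv"
        scatter.to_csv(scat_path, sep="\t", index=False)
        outputs.append(scat_path)

        maf = np.minimum.reduce([
            (df["reads_fen_a"] + df["reads_fen_b"] + df["reads_alp_a"] + df["reads_alp_b"])
            / np.maximum(df["depth_fen"] + df["depth_alp"], 1),
        ])
        maf = np.minimum(maf, 1 - maf)
        sens = divscan.sensitivity_reanalysis(scores, maf, cut)
        sens_path = self.out / "sensitivity.json"
        sens_path.write_text(json.dumps(sens, indent=2, sort_keys=True) + "\n")
        outputs.append(sens_path)
        self._record("divd-scan", cfg, [self.out / "snp_table.tsv"], outputs)

    def stage_report(self) -> None:
        cfg = self.config.get("report", {})
        expected = {
            "read_accounting": self.out / "read_accounting.tsv",
            "locus_summaries": self.out / "locus_summaries.tsv",
            "overall_stats": self.out / "overall_stats.json",
            "demog_fit": self.out / "demog_fit.json",
            "outliers_snp": self.out / "outliers_snp.tsv",
            "envelope_cutoffs": self.out / "envelope_cutoffs.json",
        }
        missing = [str(p) for p in expected.values() if not p.exists()]
        if missing:
            raise FileNotFoundError(
                "report stage missing upstream outputs: " + ", ".join(missing)
            )
        bundle: dict = {"version": __version__, "seed": self.seed}
        bundle["overall_stats"] = json.loads(expected["overall_stats"].read_text())
        fit = json.loads(expected["demog_fit"].read_text())
        bundle["model_fit_table"] = [
            {k: f[k] for k in ("scenario", "log_cl", "aic", "akaike_weight")}
            for f in fit["fits"]
        ]
        bundle["max_abs_anscombe_residual"] = fit["max_abs_anscombe_residual"]
        out_snp = pd.read_csv(expected["outliers_snp"], sep="\t")
        bundle["outlier_counts"] = {
            c: int(out_snp[c].sum()) for c in out_snp.columns if c.startswith("outlier_")
        }
        report_path = self.out / "report.json"
        report_path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
        self._record("report", cfg, list(expected.values()), [report_path])


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    stages: list[str] | None = None,
    seed: int | None = None,
) -> dict:
    """Run the requested stages (default: all) and return the manifest."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    runner = PipelineRunner(cfg, out_dir, seed=seed)
    return runner.run(list(stages) if stages else list(STAGES))
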