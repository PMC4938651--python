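"""Composite-likelihood demographic inference on the projected joint SFS.

Three isolation-with-migration scenarios (constant, growing or bottlenecked
ancestral population) are fitted to the 10x10 projected joint SFS of silent
SNPs.  The expected SFS under a parameter set is estimated by coalescent
simulation; the likelihood is multinomial over unmasked cells; maximization
cycles through the parameters with a bounded one-dimensional search, reusing
the same genealogy seeds across evaluations so the simulated surface is
smooth (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import random as _random
from scipy.optimize import minimize_scalar

from .coalescent import simulate_locus_genealogy
from .models import DemographicModel, LocusSpec
from .sumstats import JointSFS, build_joint_sfs

PROPORTION_FLOOR = 1e-12

#: free parameters per ancestral scenario (bottleneck depth/duration fixed)
FREE_PARAMETERS = {
    "constant": ("n_anc", "n_fen", "n_alp", "t_div", "mig_fen_alp", "mig_alp_fen"),
    "growth": ("n_anc", "n_fen", "n_alp", "t_div", "mig_fen_alp", "mig_alp_fen",
               "growth_rate"),
    "bottleneck": ("n_anc", "n_fen", "n_alp", "t_div", "mig_fen_alp", "mig_alp_fen",
                   "t_bot"),
}

#: search bounds; sizes and times are explored on a log scale
DEFAULT_BOUNDS = {
    "n_anc": (1e2, 1e7), "n_fen": (1e2, 1e7), "n_alp": (1e2, 1e7),
    "t_div": (1e2, 1e6), "t_bot": (1e2, 1e6),
    "mig_fen_alp": (0.0, 50.0), "mig_alp_fen": (0.0, 50.0),
    "growth_rate": (0.0, 1e-2),
}
LOG_SCALE = {"n_anc", "n_fen", "n_alp", "t_div", "t_bot"}


@dataclass
class ExpectedSFS:
    """Expected proportions over the projected joint SFS under one model."""

    model: DemographicModel
    proportions: np.ndarray
    n_sim_snps: int
    seed: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any():
            raise ValueError("expected proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("expected proportions must sum to 1")
        self.proportions = p


@dataclass
class FitResult:
    model: DemographicModel
    scenario: str
    log_cl: float
    k: int
    aic: float
    akaike_weight: float | None = None
    converged: bool = True
    trace: list = field(default_factory=list)


@dataclass
class FitDiagnostics:
    residuals: np.ndarray
    max_abs_residual: float


def expected_sfs(
    model: DemographicModel,
    n1: int = 10,
    n2: int = 10,
    n_sim: int = 20_000,
    seed: int = 0,
    locus_length: int = 1_265,
    smoothing: float = 0.5,
) -> ExpectedSFS:
    """Estimate the expected projected SFS by coalescent simulation.

    Simulates non-recombining loci directly at the projected sample size
    (n1, n2): by coalescent subsampling consistency this equals simulating
    the full pooled sample and projecting hypergeometrically, and is much
    cheaper.  Loci are simulated until the accumulated expected number of
    SNPs (total branch length times the per-locus mutation rate) reaches
    ``n_sim``; a fixed seed reproduces the estimate bit-wise, and reusing
    one seed across optimizer evaluations yields a smooth likelihood
    surface.

    ``smoothing`` adds a pseudo-count to every unmasked cell before
    normalizing.  Rare tail cells that happen to receive no simulated SNP
    would otherwise hit the likelihood floor and swamp the composite
    likelihood with Monte-Carlo noise; the pseudo-count vanishes relative
    to the data as n_sim grows, so the estimator stays consistent.
    """
    model.validate()
    counts = np.zeros((n1 + 1, n2 + 1))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(17,))
    state = ss.generate_state(2)
    rng = _random.Random(int(state[0]))
    mu_locus = model.mu_per_generation * locus_length
    got = 0.0
    # branch mode: each branch contributes its expected mutation count
    # (length * mu * L) to its (d1, d2) cell, integrating out the Poisson
    # mutation noise (Rao-Blackwellization); only genealogical noise remains
    while got < n_sim:
        gen = simulate_locus_genealogy(model, n1, n2, rng)
        for d1, d2, length in gen.branches:
            counts[d1, d2] += length * mu_locus
        got += gen.total_length * mu_locus
    sfs = JointSFS(counts)
    if smoothing > 0:
        counts = np.where(sfs.corner_mask(), counts + smoothing, counts)
        sfs = JointSFS(counts)
    return ExpectedSFS(
        model=model, proportions=sfs.normalized(), n_sim_snps=int(round(got)), seed=seed
    )


def composite_log_likelihood(observed: JointSFS, expected: ExpectedSFS) -> float:
    """Multinomial composite log-likelihood of the observed projected SFS."""
    if observed.counts.shape != expected.proportions.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.counts.shape}, "
            f"expected {expected.proportions.shape}"
        )
    mask = observed.corner_mask()
    obs = observed.counts[mask]
    p = np.maximum(expected.proportions[mask], PROPORTION_FLOOR)
    return float(np.sum(obs * np.log(p)))


def _get_param(model: DemographicModel, name: str) -> float:
    v = getattr(model, name)
    return float(v) if v is not None else DEFAULT_BOUNDS[name][0]


def _with_param(model: DemographicModel, name: str, value: float) -> DemographicModel:
    return dc_replace(model, **{name: value})


def _default_init(scenario: str) -> DemographicModel:
    m = DemographicModel(
        n_anc=1e5, n_fen=5e4, n_alp=5e4, t_div=1e5,
        mig_fen_alp=1.0, mig_alp_fen=1.0, ancestral_scenario=scenario,
        growth_rate=1e-5 if scenario == "growth" else 0.0,
        t_bot=2e5 if scenario == "bottleneck" else None,
    )
    return m


@dataclass
class OptimizerConfig:
    max_cycles: int = 20
    tolerance: float = 0.01
    n_sim: int = 20_000
    search_maxiter: int = 10
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))


def fit_model(
    observed: JointSFS,
    scenario: str = "constant",
    config: OptimizerConfig | None = None,
    seed: int = 0,
    init: DemographicModel | None = None,
) -> FitResult:
    """Cyclic coordinate maximization of the composite likelihood.

    Each free parameter in turn is maximized by a bounded scalar search
    (log scale for sizes and times) with all other parameters held at their
    current values; a cycle that improves the log-likelihood by less than
    the tolerance stops the fit.  The returned point never has a lower
    log-likelihood than the initialization.
    """
    if scenario not in FREE_PARAMETERS:
        raise ValueError(f"unknown scenario {scenario!r}")
    cfg = config or OptimizerConfig()
    names = FREE_PARAMETERS[scenario]
    m1, m2 = observed.n1, observed.n2
    current = init if init is not None else _default_init(scenario)
    if current.ancestral_scenario != scenario:
        current = dc_replace(current, ancestral_scenario=scenario)
    current.validate()

    def loglik(model: DemographicModel) -> float:
        exp = expected_sfs(model, n1=m1, n2=m2, n_sim=cfg.n_sim, seed=seed)
        return composite_log_likelihood(observed, exp)

    best_ll = loglik(current)
    trace = [("init", best_ll)]
    converged = False
    for cycle in range(cfg.max_cycles):
        cycle_start_ll = best_ll
        for name in names:
            lo, hi = cfg.bounds[name]
            if scenario == "bottleneck" and name == "t_bot":
                # the bottleneck must predate the split
                lo = max(lo, current.t_div * (1 + 1e-6))
                if lo >= hi:
                    continue
            log_scale = name in LOG_SCALE

            def neg(x: float) -> float:
                v = math.exp(x) if log_scale else x
                try:
                    cand = _with_param(current, name, v)
                except ValueError:
                    return math.inf
                return -loglik(cand)

            lo_x, hi_x = (math.log(lo), math.log(hi)) if log_scale else (lo, hi)
            res = minimize_scalar(
                neg, bounds=(lo_x, hi_x), method="bounded",
                options={"maxiter": cfg.search_maxiter, "xatol": 1e-3 * (hi_x - lo_x)},
            )
            cand_val = math.exp(res.x) if log_scale else float(res.x)
            cand_ll = -res.fun
            if cand_ll > best_ll:
                current = _with_param(current, name, cand_val)
                best_ll = cand_ll
            trace.append((name, best_ll))
        if best_ll - cycle_start_ll < cfg.tolerance:
            converged = True
            break
    k = len(names)
    aic = 2 * k - 2 * best_ll
    return FitResult(
        model=current, scenario=scenario, log_cl=best_ll, k=k, aic=aic,
        converged=converged, trace=trace,
    )


def akaike_weights(fits: list[FitResult]) -> np.ndarray:
    """Akaike weights of evidence: w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)."""
    if len(fits) < 2:
        raise ValueError("need at least two models to compare")
    aic = np.array([f.aic for f in fits], dtype=float)
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.akaike_weight = float(wi)
    return w


@dataclass
class BootstrapSet:
    estimates: "object"  # DataFrame: one row per replicate, parameter columns
    modes: dict
    ci_low: dict
    ci_high: dict
    support: dict  # scenario -> fraction of replicates with top Akaike weight


def binomial_resample_sfs(
    p1: np.ndarray, p2: np.ndarray, n1: int, n2: int,
    m1: int, m2: int, rng: np.random.Generator,
) -> JointSFS:
    """One bootstrap dataset: per SNP, redraw the derived count in each pool
    as Binomial(n, p-hat)/n, then rebuild and project the joint SFS."""
    from .sumstats import project_sfs

    b1 = rng.binomial(n1, np.asarray(p1, dtype=float)) / n1
    b2 = rng.binomial(n2, np.asarray(p2, dtype=float)) / n2
    return project_sfs(build_joint_sfs(b1, b2, n1, n2), m1, m2)


def bootstrap_parameters(
    p1: np.ndarray,
    p2: np.ndarray,
    n1: int = 96,
    n2: int = 96,
    n_boot: int = 100,
    scenarios: tuple[str, ...] = ("constant",),
    config: OptimizerConfig | None = None,
    seed: int = 0,
    m1: int = 10,
    m2: int = 10,
    init: DemographicModel | None = None,
) -> BootstrapSet:
    """Binomial bootstrap of allele frequencies with per-replicate refits.

    Reports per-parameter kernel-density modes and 2.5%/97.5% percentile
    intervals across replicates, and per-scenario Akaike support fractions
    when several scenarios are fitted.
    """
    import pandas as pd
    from scipy.stats import gaussian_kde

    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    import hashlib as _hashlib

    rng = np.random.default_rng(seed)
    rows = []
    support = {s: 0 for s in scenarios}
    for b in range(n_boot):
        sfs_b = binomial_resample_sfs(p1, p2, n1, n2, m1, m2, rng)
        # per-replicate simulation seed derived from the resampled data:
        # fresh noise for distinct replicates, identical fits for identical
        # (e.g. degenerate) replicates
        digest = _hashlib.sha256(np.ascontiguousarray(sfs_b.counts).tobytes()).digest()
        fit_seed = (int(seed) * 1_000_003 + int.from_bytes(digest[:4], "big")) % 2**31
        fits = [
            fit_model(sfs_b, scenario=s, config=config, seed=fit_seed, init=init)
            for s in scenarios
        ]
        if len(fits) > 1:
            w = akaike_weights(fits)
            support[fits[int(w.argmax())].scenario] += 1
            best = fits[int(np.argmin([f.aic for f in fits]))]
        else:
            support[fits[0].scenario] += 1
            best = fits[0]
        row = {"replicate": b, "scenario": best.scenario, "log_cl": best.log_cl}
        for name in FREE_PARAMETERS[best.scenario]:
            row[name] = _get_param(best.model, name)
        rows.append(row)
    est = pd.DataFrame(rows)
    modes, lo, hi = {}, {}, {}
    for name in est.columns:
        if name in ("replicate", "scenario", "log_cl"):
            continue
        vals = est[name].dropna().to_numpy(dtype=float)
        lo[name] = float(np.quantile(vals, 0.025))
        hi[name] = float(np.quantile(vals, 0.975))
        if len(np.unique(vals)) > 1:
            kde = gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), 512)
            modes[name] = float(grid[int(np.argmax(kde(grid)))])
        else:
            modes[name] = float(vals[0])
    return BootstrapSet(
        estimates=est, modes=modes, ci_low=lo, ci_high=hi,
        support={s: c / n_boot for s, c in support.items()},
    )


def anscombe_residuals(observed: JointSFS, expected: ExpectedSFS) -> FitDiagnostics:
    """Variance-stabilized (Poisson-family Anscombe) residuals per SFS cell.

    Expected proportions are scaled to the observed total over unmasked
    cells to give expected counts m; the residual is
    r = (3/2) (y^(2/3) - m^(2/3)) / m^(1/6).  Cells with m = 0 and y > 0
    are flagged infinite.
    """
    mask = observed.corner_mask()
    y = np.where(mask, observed.counts, 0.0)
    total = y.sum()
    m = expected.proportions * total
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.5 * (np.power(y, 2.0 / 3.0) - np.power(m, 2.0 / 3.0)) / np.power(m, 1.0 / 6.0)
    r = np.where((m == 0) & (y > 0), np.inf, r)
    r = np.where((m == 0) & (y == 0), 0.0, r)
    r = np.where(mask, r, 0.0)
    finite = r[np.isfinite(r)]
    max_abs = float(np.max(np.abs(r))) if np.isinf(r).any() else float(np.max(np.abs(finite)))
    return FitDiagnostics(residuals=r, max_abs_residual=max_abs)
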