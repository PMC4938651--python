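"""Structured-coalescent engine for the two-deme IM model.

Simulates per-locus genealogies backward in time under the demographic model
and drops infinite-sites mutations on branches.  Because only derived-allele
counts are needed downstream, each lineage carries the number of sampled
chromosomes beneath it in each pool instead of an explicit tree: a mutation on
a branch subtending (d1, d2) leaves yields a SNP with those derived counts.

Rates follow the standard diploid scaling: with k lineages in a deme of
diploid size N, pairs coalesce at total rate k(k-1)/(4N) per generation;
a lineage sampled in ALP migrates (backward) to FEN at rate M12/(2*N_ALP),
where M12 = 2*N_ALP*m is the forward-time number of FEN->ALP migrants.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from .models import DemographicModel

__all__ = ["LocusGenealogy", "simulate_locus_genealogy", "simulate_locus_counts"]


@dataclass
class LocusGenealogy:
    """Branches of one simulated genealogy.

    ``branches`` holds (d1, d2, length) triples: the numbers of sampled
    chromosomes from pool 1 (FEN) and pool 2 (ALP) below the branch, and its
    length in generations.  The root branch is not included.
    """

    branches: list[tuple[int, int, float]]
    tmrca: float
    total_length: float
    n1: int
    n2: int


def _ancestral_waiting_time(model: DemographicModel, k: int, t0: float, rng: random.Random) -> float:
    """Waiting time to the next coalescence among k lineages in the ancestral
    population, starting from absolute time t0 >= t_div."""
    e = rng.expovariate(1.0)
    n0 = model.n_anc
    pair = k * (k - 1)
    scen = model.ancestral_scenario
    if scen == "constant" or (scen == "growth" and model.growth_rate == 0.0):
        return e * 4.0 * n0 / pair
    if scen == "growth":
        # backward size N0*exp(-alpha*s), s = t - t_div; integrate the rate
        a = model.growth_rate
        lam0 = pair / (4.0 * n0)
        s0 = t0 - model.t_div
        # solve lam0*(exp(a*(s0+tau)) - exp(a*s0))/a = e  (log-space, overflow-safe)
        x = a * s0
        y = math.log(a * e / lam0)
        hi, lo = (x, y) if x >= y else (y, x)
        return (hi + math.log1p(math.exp(lo - hi))) / a - s0
    # bottleneck: piecewise-constant ancestral size
    t = t0
    while True:
        if t < model.t_bot:
            n, bound = n0, model.t_bot
        elif t < model.t_bot + model.bot_duration:
            n, bound = n0 * model.bot_factor, model.t_bot + model.bot_duration
        else:
            n, bound = n0, math.inf
        rate = pair / (4.0 * n)
        dt = e / rate
        if t + dt <= bound:
            return t + dt - t0
        e -= rate * (bound - t)
        t = bound


def simulate_locus_genealogy(
    model: DemographicModel, n1: int, n2: int, rng: random.Random
) -> LocusGenealogy:
    """Simulate one genealogy of n1 FEN + n2 ALP chromosomes."""
    if n1 + n2 < 2:
        raise ValueError("need at least two sampled chromosomes in total")
    if n1 < 0 or n2 < 0:
        raise ValueError("sample sizes must be non-negative")

    # lineage state stored in parallel lists, indexed by lineage id
    d1 = [1] * n1 + [0] * n2
    d2 = [0] * n1 + [1] * n2
    birth = [0.0] * (n1 + n2)
    demes: list[list[int]] = [list(range(n1)), list(range(n1, n1 + n2))]

    branches: list[tuple[int, int, float]] = []
    total_length = 0.0
    t = 0.0

    coal0 = 1.0 / (4.0 * model.n_fen)
    coal1 = 1.0 / (4.0 * model.n_alp)
    # backward migration rates per lineage
    mig0 = model.mig_alp_fen / (2.0 * model.n_fen)  # FEN lineage -> ALP
    mig1 = model.mig_fen_alp / (2.0 * model.n_alp)  # ALP lineage -> FEN
    t_div = model.t_div
    rexp = rng.expovariate
    runif = rng.random

    def record_coalescence(pool: list[int], when: float) -> None:
        i = int(runif() * len(pool))
        j = int(runif() * (len(pool) - 1))
        if j >= i:
            j += 1
        a, b = pool[i], pool[j]
        # remove the two (swap-pop, order-safe)
        hi, lo = (i, j) if i > j else (j, i)
        pool[hi] = pool[-1]
        pool.pop()
        pool[lo] = pool[-1]
        pool.pop()
        branches.append((d1[a], d2[a], when - birth[a]))
        branches.append((d1[b], d2[b], when - birth[b]))
        d1.append(d1[a] + d1[b])
        d2.append(d2[a] + d2[b])
        birth.append(when)
        pool.append(len(birth) - 1)

    # --- descendant epoch: two demes, constant sizes, migration ---
    while t < t_div and len(demes[0]) + len(demes[1]) > 1:
        k0, k1 = len(demes[0]), len(demes[1])
        r_c0 = k0 * (k0 - 1) * coal0
        r_c1 = k1 * (k1 - 1) * coal1
        r_m0 = k0 * mig0
        r_m1 = k1 * mig1
        total = r_c0 + r_c1 + r_m0 + r_m1
        if total <= 0.0:
            t = t_div
            break
        dt = rexp(total)
        if t + dt >= t_div:
            t = t_div
            break
        t += dt
        u = runif() * total
        if u < r_c0:
            record_coalescence(demes[0], t)
        elif u < r_c0 + r_c1:
            record_coalescence(demes[1], t)
        elif u < r_c0 + r_c1 + r_m0:
            i = int(runif() * len(demes[0]))
            lin = demes[0][i]
            demes[0][i] = demes[0][-1]
            demes[0].pop()
            demes[1].append(lin)
        else:
            i = int(runif() * len(demes[1]))
            lin = demes[1][i]
            demes[1][i] = demes[1][-1]
            demes[1].pop()
            demes[0].append(lin)

    # --- ancestral epoch: single merged population ---
    pool = demes[0] + demes[1]
    while len(pool) > 1:
        t += _ancestral_waiting_time(model, len(pool), t, rng)
        record_coalescence(pool, t)

    total_length = sum(b[2] for b in branches)
    return LocusGenealogy(
        branches=branches, tmrca=t, total_length=total_length, n1=n1, n2=n2
    )


def simulate_locus_counts(
    model: DemographicModel,
    length: int,
    n1: int,
    n2: int,
    rng: random.Random,
    np_rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one locus and drop mutations.

    Returns (positions, counts1, counts2): 1-based positions of polymorphic
    sites within the locus and the derived-allele counts per pool.  Infinite
    sites on a discrete grid: mutation positions are drawn without
    replacement, and mutations in excess of the locus length are discarded.
    """
    gen = simulate_locus_genealogy(model, n1, n2, rng)
    mu_locus = model.mu_per_generation
    lengths = np.array([b[2] for b in gen.branches])
    n_mut = np_rng.poisson(mu_locus * length * lengths)
    total = int(n_mut.sum())
    if total == 0:
        return (np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0, dtype=int))
    c1 = np.repeat(np.array([b[0] for b in gen.branches]), n_mut)
    c2 = np.repeat(np.array([b[1] for b in gen.branches]), n_mut)
    if total > length:  # multiple hits impossible under infinite sites: drop extras
        keep = np_rng.permutation(total)[:length]
        keep.sort()
        c1, c2 = c1[keep], c2[keep]
        total = length
    pos = np_rng.choice(length, size=total, replace=False) + 1
    pos.sort()
    return pos, c1, c2
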