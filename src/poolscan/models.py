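"""Core parameter containers shared across the pipeline.

The two-population isolation-with-migration (IM) model describes an ancestral
population of diploid effective size ``n_anc`` that splits ``t_div``
generations ago into two descendants (sizes ``n_fen`` and ``n_alp``, for the
Fennoscandian and Alpine domains) which afterwards exchange migrants at scaled
rates M = 2Nm.  Three variants of the ancestral epoch are supported: constant
size, exponential growth, and a bottleneck.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

ANCESTRAL_SCENARIOS = ("constant", "growth", "bottleneck")


@dataclass
class DemographicModel:
    """Parameters of the two-deme IM model.

    Sizes are diploid effective sizes; times are in generations before
    present.  ``mig_fen_alp`` (M12) is the scaled number of migrants moving
    FEN -> ALP per generation in forward time (M = 2Nm); backward in time a
    lineage sampled in ALP therefore jumps to FEN at rate M12 / (2 * n_alp)
    per generation, and symmetrically for ``mig_alp_fen`` (M21).
    """

    n_anc: float
    n_fen: float
    n_alp: float
    t_div: float
    mig_fen_alp: float = 0.0
    mig_alp_fen: float = 0.0
    ancestral_scenario: str = "constant"
    growth_rate: float = 0.0
    t_bot: float | None = None
    bot_factor: float = 0.001
    bot_duration: float = 100.0
    mu_per_year: float = 1.1e-9
    gen_time: float = 25.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_anc", "n_fen", "n_alp"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite size, got {v!r}")
        if not (math.isfinite(self.t_div) and self.t_div >= 0):
            raise ValueError(f"t_div must be >= 0, got {self.t_div!r}")
        for name in ("mig_fen_alp", "mig_alp_fen"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be >= 0 and finite, got {v!r}")
        if self.ancestral_scenario not in ANCESTRAL_SCENARIOS:
            raise ValueError(
                f"ancestral_scenario must be one of {ANCESTRAL_SCENARIOS}, "
                f"got {self.ancestral_scenario!r}"
            )
        if self.ancestral_scenario == "growth":
            if not (math.isfinite(self.growth_rate) and self.growth_rate >= 0):
                raise ValueError(f"growth_rate must be >= 0, got {self.growth_rate!r}")
        if self.ancestral_scenario == "bottleneck":
            if self.t_bot is None:
                raise ValueError("bottleneck scenario requires t_bot")
            # the bottleneck belongs to the ancestral population
            if not self.t_bot > self.t_div:
                raise ValueError(
                    f"t_bot ({self.t_bot}) must lie before the split, i.e. "
                    f"t_bot > t_div ({self.t_div})"
                )
        if not (0 < self.bot_factor <= 1):
            raise ValueError(f"bot_factor must be in (0, 1], got {self.bot_factor!r}")
        if not (math.isfinite(self.mu_per_year) and self.mu_per_year > 0):
            raise ValueError("mu_per_year must be positive")
        if not (math.isfinite(self.gen_time) and self.gen_time > 0):
            raise ValueError("gen_time must be positive")

    @property
    def mu_per_generation(self) -> float:
        return self.mu_per_year * self.gen_time

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(**d)


def fitted_constant_model(sizes_are_gene_copies: bool = True) -> DemographicModel:
    """The fitted constant-ancestral-size IM model (modal estimates).

    Composite-likelihood SFS fits of this kind are carried out in
    fastsimcoal2's native units, where population sizes count gene copies
    (haploid genomes).  By default the published sizes are therefore
    interpreted as gene-copy counts and halved to the diploid sizes the
    coalescent engine expects; this convention reproduces the study's
    observed SNP density, which the diploid reading overshoots twofold.
    Pass ``sizes_are_gene_copies=False`` to read them as diploid counts.
    """
    ploidy = 2.0 if sizes_are_gene_copies else 1.0
    return DemographicModel(
        n_anc=397_000 / ploidy,
        n_fen=41_000 / ploidy,
        n_alp=51_000 / ploidy,
        t_div=5.2e6 / 25.0,  # 5.2 Myr at 25 yr/generation
        mig_fen_alp=14.6,
        mig_alp_fen=1.6,
        ancestral_scenario="constant",
        mu_per_year=1.1e-9,
        gen_time=25.0,
    )


@dataclass
class LocusSpec:
    """A single non-recombining amplicon locus."""

    locus_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"locus length must be positive, got {self.length}")


def default_loci(n_loci: int = 88, total_length: int = 111_297) -> list[LocusSpec]:
    """Amplicon panel emulating the study layout: 88 loci, ~111 kb in total.

    Lengths are spread evenly with the remainder distributed one base at a
    time so the total is exact.
    """
    base = total_length // n_loci
    rem = total_length - base * n_loci
    return [
        LocusSpec(locus_id=f"gene{i + 1:03d}", length=base + (1 if i < rem else 0))
        for i in range(n_loci)
    ]


@dataclass
class PoolReadProfile:
    """Noise model for pooled sequencing read generation."""

    target_depth: float = 200.0
    depth_dispersion: float = 10.0  # gamma shape for per-amplicon mean coverage
    error_rate: float = 0.0
    read_length: int = 109
    n_replicates: int = 2
    strand_balance: float = 0.5

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not (0 < self.strand_balance < 1):
            raise ValueError("strand_balance must be in (0, 1)")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")


@dataclass
class FilterConfig:
    """Thresholds of the replicate-concordance SNP validation rules."""

    min_minor_reads_per_replicate: int = 2
    min_minor_reads_total: int = 5
    require_both_replicates: bool = True
    strand_cap: int = 100
    library_target_size: int | None = None
    freq_cutoffs: tuple[float, ...] = (0.01, 0.1)
    rare_freq_flag: float = 0.01

    def __post_init__(self) -> None:
        if self.min_minor_reads_per_replicate < 0 or self.min_minor_reads_total < 0:
            raise ValueError("read-count thresholds must be >= 0")
        if self.strand_cap < 0:
            raise ValueError("strand_cap must be >= 0")
        if not (0 <= self.rare_freq_flag < 1):
            raise ValueError("rare_freq_flag must be in [0, 1)")
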