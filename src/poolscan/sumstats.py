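"""Population-genetic summary statistics from pooled allele frequencies.

Implements per-SNP and combined Hudson F_ST, per-locus nucleotide diversity
and Tajima's D, shared/private SNP accounting, joint-SFS construction with
hypergeometric projection, and distributional site-class comparisons.

Pool-seq yields frequencies rather than genotypes: classical count-based
statistics reconstruct integer derived counts as ``round(p * n)`` with
n = 96 chromosomes per pool by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import hypergeom

from .poolproc import SnpCall


@dataclass
class SnpFrequencyPair:
    """The (p1, p2, n1, n2) of the two-sample Hudson estimator."""

    p1: float
    p2: float
    n1: int = 96
    n2: int = 96

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("sample sizes must be >= 2")


def hudson_fst(pair: SnpFrequencyPair) -> tuple[float, float, float]:
    """Hudson's two-population F_ST estimator for one SNP.

    Returns (numerator, denominator, fst).  The numerator subtracts the
    within-sample sampling variance of each frequency; the denominator is
    the between-sample heterozygosity.  When the denominator is zero (both
    samples fixed for the same allele) fst is NaN and the SNP is excluded
    from combined estimates.
    """
    p1, p2, n1, n2 = pair.p1, pair.p2, pair.n1, pair.n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    fst = num / den if den > 0 else float("nan")
    return num, den, fst


def hudson_fst_arrays(
    p1: np.ndarray, p2: np.ndarray, n1: int = 96, n2: int = 96
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Hudson numerator/denominator/fst over SNP arrays."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return num, den, fst


def combine_fst(
    numerators: np.ndarray, denominators: np.ndarray, method: str = "ratio_of_sums"
) -> float:
    """Combine per-SNP Hudson components into one estimate.

    ``ratio_of_sums`` divides the summed numerators by the summed
    denominators (dominated by the more polymorphic SNPs); ``mean_of_ratios``
    averages per-SNP ratios (more sensitive to low-MAF SNPs).  SNPs with a
    zero denominator are excluded from both.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    ok = den > 0
    if not ok.any():
        raise ValueError("no SNP with a defined F_ST")
    if method == "ratio_of_sums":
        return float(num[ok].sum() / den[ok].sum())
    if method == "mean_of_ratios":
        return float(np.mean(num[ok] / den[ok]))
    raise ValueError(f"unknown method {method!r}")


def nucleotide_diversity(freqs: np.ndarray, n: int, length: float) -> float:
    """Unbiased per-site pairwise diversity over one locus.

    pi = sum_sites [n/(n-1)] * 2 p (1-p) / length.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if length <= 0:
        raise ValueError("length must be positive")
    p = np.asarray(freqs, dtype=float)
    return float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1) / length)


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d(freqs: np.ndarray, n: int) -> float:
    """Tajima's D from allele frequencies at the segregating sites of a locus.

    theta_pi uses derived counts reconstructed as round(p*n); theta_W = S/a1.
    Undefined (NaN) when there are no segregating sites.
    """
    if n < 4:
        raise ValueError("n must be >= 4 for Tajima's D")
    p = np.asarray(freqs, dtype=float)
    counts = np.rint(p * n).astype(int)
    counts = counts[(counts > 0) & (counts < n)]
    s = len(counts)
    if s == 0:
        return float("nan")
    k = _tajima_constants(n)
    theta_pi = float(np.sum(2.0 * counts * (n - counts) / (n * (n - 1))))
    theta_w = s / k["a1"]
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    return (theta_pi - theta_w) / np.sqrt(var)


def locus_summaries(
    calls: list[SnpCall] | pd.DataFrame,
    loci: dict[str, int],
    n: int = 96,
) -> pd.DataFrame:
    """Per-locus S, pi and Tajima's D for each pool.

    ``loci`` maps locus id to length in bp; loci without SNPs get S=0,
    pi=0 and undefined D.
    """
    df = calls if isinstance(calls, pd.DataFrame) else _calls_frame(calls)
    rows = []
    for locus, length in loci.items():
        sub = df[df["locus"] == locus]
        row = {"locus": locus, "length": length}
        for pool, col in (("fen", "p_fen"), ("alp", "p_alp")):
            p = sub[col].to_numpy(dtype=float)
            seg = (np.rint(p * n) > 0) & (np.rint(p * n) < n)
            row[f"S_{pool}"] = int(seg.sum())
            row[f"pi_{pool}"] = nucleotide_diversity(p, n, length)
            row[f"tajima_d_{pool}"] = tajimas_d(p, n) if seg.any() else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _calls_frame(calls: list[SnpCall]) -> pd.DataFrame:
    from .poolproc import calls_to_frame

    return calls_to_frame(calls)


def classify_and_count(calls: list[SnpCall] | pd.DataFrame) -> dict:
    """Shared/private SNP accounting and per-class counts.

    Private-SNP mean frequencies are computed within the pool where the SNP
    segregates.
    """
    df = calls if isinstance(calls, pd.DataFrame) else _calls_frame(calls)
    if len(df) == 0:
        return {
            "n_snps": 0, "shared": 0, "private_fen": 0, "private_alp": 0,
            "mean_freq_private_fen": float("nan"),
            "mean_freq_private_alp": float("nan"),
            "class_counts": {},
        }
    p1 = df["p_fen"].to_numpy(dtype=float)
    p2 = df["p_alp"].to_numpy(dtype=float)
    seg1 = (p1 > 0) & (p1 < 1)
    seg2 = (p2 > 0) & (p2 < 1)
    priv1 = seg1 & (p2 == 0)
    priv2 = seg2 & (p1 == 0)
    shared = seg1 & seg2
    class_counts = (
        df["site_class"].value_counts().to_dict() if "site_class" in df else {}
    )
    return {
        "n_snps": int(len(df)),
        "shared": int(shared.sum()),
        "private_fen": int(priv1.sum()),
        "private_alp": int(priv2.sum()),
        "mean_freq_private_fen": float(p1[priv1].mean()) if priv1.any() else float("nan"),
        "mean_freq_private_alp": float(p2[priv2].mean()) if priv2.any() else float("nan"),
        "class_counts": class_counts,
    }


@dataclass
class JointSFS:
    """Two-dimensional derived-allele-count spectrum.

    ``counts[i, j]`` is the number (possibly fractional after projection)
    of SNPs with derived count i in pool 1 (FEN) and j in pool 2 (ALP).
    The monomorphic corners (0,0) and (n1,n2) are masked for likelihood
    work but kept in the matrix.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("joint SFS must be a 2-D matrix")
        if (self.counts < -1e-9).any():
            raise ValueError("joint SFS entries must be non-negative")

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    def corner_mask(self) -> np.ndarray:
        """True for the cells used in likelihoods (corners excluded)."""
        mask = np.ones_like(self.counts, dtype=bool)
        mask[0, 0] = False
        mask[-1, -1] = False
        return mask

    def total(self, masked: bool = False) -> float:
        if masked:
            return float(self.counts[self.corner_mask()].sum())
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Proportions over unmasked cells (corners zeroed)."""
        mask = self.corner_mask()
        p = np.where(mask, self.counts, 0.0)
        tot = p.sum()
        if tot <= 0:
            raise ValueError("empty SFS")
        return p / tot


def build_joint_sfs(
    p1: np.ndarray, p2: np.ndarray, n1: int = 96, n2: int = 96
) -> JointSFS:
    """Raw joint SFS from derived-allele frequencies (counts = round(p*n))."""
    c1 = np.rint(np.asarray(p1, dtype=float) * n1).astype(int)
    c2 = np.rint(np.asarray(p2, dtype=float) * n2).astype(int)
    if (c1 < 0).any() or (c1 > n1).any() or (c2 < 0).any() or (c2 > n2).any():
        raise ValueError("derived counts outside sample-size range")
    counts = np.zeros((n1 + 1, n2 + 1))
    np.add.at(counts, (c1, c2), 1.0)
    return JointSFS(counts)


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """W[i, k] = P(k derived in a subsample of m | i derived among n)."""
    if m > n:
        raise ValueError(f"cannot project {n} chromosomes up to {m}")
    i = np.arange(n + 1)[:, None]
    k = np.arange(m + 1)[None, :]
    return hypergeom.pmf(k, n, i, m)


def project_sfs(sfs: JointSFS, m1: int = 10, m2: int = 10) -> JointSFS:
    """Hypergeometric down-projection of the joint SFS to (m1+1) x (m2+1).

    Each raw cell distributes its mass to the expected subsample counts;
    projected entries are expected (fractional) SNP counts.  Total mass is
    conserved before corner masking.
    """
    w1 = _projection_matrix(sfs.n1, m1)
    w2 = _projection_matrix(sfs.n2, m2)
    return JointSFS(w1.T @ sfs.counts @ w2)


def write_sfs_text(sfs: JointSFS, path) -> None:
    """dadi/fastsimcoal2-style plain-text 2-D SFS (one header line, then
    the matrix row by row)."""
    with open(path, "w") as fh:
        fh.write(f"{sfs.n1 + 1} {sfs.n2 + 1}\n")
        for row in sfs.counts:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_sfs_text(path) -> JointSFS:
    with open(path) as fh:
        d1, d2 = (int(x) for x in fh.readline().split())
        counts = np.loadtxt(fh, ndmin=2)
    if counts.shape != (d1, d2):
        raise ValueError(f"SFS shape {counts.shape} does not match header ({d1}, {d2})")
    return JointSFS(counts)


def compare_site_classes(
    scores: np.ndarray, labels: np.ndarray, class_a: str, class_b: str
) -> dict:
    """Two-sample distributional comparison of a per-SNP score between
    site classes: Kolmogorov-Smirnov, Wilcoxon rank-sum and a variance-ratio
    (Levene) test, plus class means and variances."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    xa = scores[labels == class_a]
    xb = scores[labels == class_b]
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each class needs at least two SNPs")
    ks = sps.ks_2samp(xa, xb, method="asymp")
    rs = sps.ranksums(xa, xb)
    lev = sps.levene(xa, xb)
    return {
        "class_a": class_a, "class_b": class_b,
        "n_a": int(len(xa)), "n_b": int(len(xb)),
        "mean_a": float(xa.mean()), "mean_b": float(xb.mean()),
        "var_a": float(xa.var(ddof=1)), "var_b": float(xb.var(ddof=1)),
        "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
        "ranksum_stat": float(rs.statistic), "ranksum_p": float(rs.pvalue),
        "levene_stat": float(lev.statistic), "levene_p": float(lev.pvalue),
    }
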