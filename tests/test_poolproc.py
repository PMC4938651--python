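"""Read processing: downsampling, replicate-concordance calling, cutoffs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from poolscan.models import FilterConfig
from poolscan.poolproc import (
    apply_frequency_cutoff,
    call_snps,
    downsample_gene_coverage,
    downsample_library,
    minor_allele_frequency,
    polarize,
    SnpCall,
)
from poolscan.reads import MINUS, PLUS, PileupColumn, ReadStack


def uniform_stack(locus_len=1000, read_len=109, per_strand_depth=400, seed=0,
                  strands=(PLUS, MINUS)):
    rng = np.random.default_rng(seed)
    n_per_strand = int(per_strand_depth * (locus_len + read_len - 1) / read_len)
    starts, lens, strs = [], [], []
    for s in strands:
        raw = rng.integers(1 - (read_len - 1), locus_len + 1, size=n_per_strand)
        st = np.maximum(raw, 1)
        en = np.minimum(raw + read_len - 1, locus_len)
        starts.append(st)
        lens.append(en - st + 1)
        strs.append(np.full(n_per_strand, s, dtype=np.int8))
    return ReadStack(
        locus_id="g", locus_length=locus_len, pool="FEN", replicate=0,
        start=np.concatenate(starts).astype(np.int64),
        length=np.concatenate(lens).astype(np.int64),
        strand=np.concatenate(strs),
    )


def column(fen_counts, alp_counts, pos=5):
    """Build one pileup column pair; counts given per replicate per base."""
    def expand(per_rep):
        return np.stack(
            [np.stack([np.array(r, dtype=np.int64), np.zeros(4, dtype=np.int64)])
             for r in per_rep]
        )
    return (
        [PileupColumn("g", pos, expand(fen_counts))],
        [PileupColumn("g", pos, expand(alp_counts))],
    )


class TestLibraryDownsampling:
    def test_identity_at_full_size(self):
        stack = uniform_stack(per_strand_depth=20)
        (out,) = downsample_library([stack], stack.n_reads, seed=1)
        assert out.n_reads == stack.n_reads
        assert np.array_equal(np.sort(out.start), np.sort(stack.start))

    def test_all_libraries_reach_smallest_size(self):
        sizes = [3_615_090, 11_063_898, 7_108_922, 9_804_776]
        # scaled 1:1000 to keep the check cheap; proportions preserved
        scaled = [s // 1000 for s in sizes]
        stacks = [uniform_stack(per_strand_depth=1, seed=i) for i in range(4)]
        libs = []
        for s, stack in zip(scaled, stacks):
            reps = int(np.ceil(s / stack.n_reads))
            big = ReadStack(
                "g", stack.locus_length, "FEN", 0,
                np.tile(stack.start, reps)[:s], np.tile(stack.length, reps)[:s],
                np.tile(stack.strand, reps)[:s],
            )
            libs.append(big)
        target = min(scaled)
        for i, lib in enumerate(libs):
            (out,) = downsample_library([lib], target, seed=i)
            assert out.n_reads == target

    def test_oversized_target_rejected(self):
        stack = uniform_stack(per_strand_depth=2)
        with pytest.raises(ValueError, match="FEN"):
            downsample_library([stack], stack.n_reads + 1)

    def test_retention_probability_uniform(self):
        # each read tagged by its start so retained identities are traceable
        n, n_trials = 1000, 200
        marker = ReadStack(
            "g", n + 1, "FEN", 0,
            np.arange(1, n + 1, dtype=np.int64),
            np.ones(n, dtype=np.int64), np.zeros(n, dtype=np.int8),
        )
        kept = np.zeros(n)
        for seed in range(n_trials):
            (out,) = downsample_library([marker], n // 2, seed=seed)
            kept[out.start - 1] += 1
        lo, hi = sps.binom.ppf([1e-4, 1 - 1e-4], n_trials, 0.5)
        assert ((kept >= lo) & (kept <= hi)).mean() > 0.995


class TestGeneCoverageDownsampling:
    def test_identity_below_cap(self):
        stack = uniform_stack(per_strand_depth=50)
        out = downsample_gene_coverage(stack, cap_per_strand=100, seed=0)
        assert out.n_reads == stack.n_reads

    def test_saturated_gene_mean_depth_near_two_hundred(self):
        means = []
        for seed in range(5):
            stack = uniform_stack(per_strand_depth=400, seed=seed)
            out = downsample_gene_coverage(stack, cap_per_strand=100, seed=seed)
            means.append(out.depth_profile().mean())
        assert np.mean(means) == pytest.approx(200, rel=0.10)

    def test_single_strand_cap_exact_at_first_base(self):
        rng = np.random.default_rng(5)
        start = np.ones(300, dtype=np.int64)
        stack = ReadStack(
            "g", 200, "FEN", 0, start,
            np.full(300, 100, dtype=np.int64), np.zeros(300, dtype=np.int8),
        )
        out = downsample_gene_coverage(stack, cap_per_strand=100, seed=1)
        assert int((out.start <= 1).sum()) == 100

    def test_subset_property(self):
        stack = uniform_stack(per_strand_depth=300, seed=9)
        out = downsample_gene_coverage(stack, cap_per_strand=100, seed=2)
        pairs_in = set(zip(stack.start.tolist(), stack.length.tolist(),
                           stack.strand.tolist()))
        for s, l, st in zip(out.start, out.length, out.strand):
            assert (s, l, st) in pairs_in
        assert out.n_reads <= stack.n_reads


class TestSnpCalling:
    def test_two_reads_in_each_replicate_accepted(self):
        cf, ca = column([[50, 2, 0, 0], [50, 2, 0, 0]],
                        [[50, 0, 0, 0], [50, 0, 0, 0]])
        assert len(call_snps(cf, ca)) == 1

    def test_five_reads_total_accepted(self):
        cf, ca = column([[50, 1, 0, 0], [50, 4, 0, 0]],
                        [[50, 0, 0, 0], [50, 0, 0, 0]])
        assert len(call_snps(cf, ca)) == 1

    def test_single_replicate_support_rejected(self):
        cf, ca = column([[50, 9, 0, 0], [50, 0, 0, 0]],
                        [[50, 0, 0, 0], [50, 0, 0, 0]])
        assert len(call_snps(cf, ca)) == 0

    def test_monotone_in_evidence(self):
        """Adding supporting reads to an accepted allele never rejects it."""
        base = [[50, 2, 0, 0], [50, 2, 0, 0]]
        cf, ca = column(base, [[50, 0, 0, 0], [50, 0, 0, 0]])
        assert len(call_snps(cf, ca)) == 1
        for extra in (1, 5, 50):
            boosted = [[50, 2 + extra, 0, 0], [50, 2 + extra, 0, 0]]
            cf, ca = column(boosted, [[50, 1, 0, 0], [50, 1, 0, 0]])
            assert len(call_snps(cf, ca)) == 1

    def test_triallelic_site_dropped(self):
        cf, ca = column([[50, 5, 5, 0], [50, 5, 5, 0]],
                        [[50, 0, 0, 0], [50, 0, 0, 0]])
        assert call_snps(cf, ca) == []

    def test_frequencies_and_flags(self):
        cf, ca = column([[96, 4, 0, 0], [96, 4, 0, 0]],
                        [[100, 0, 0, 0], [100, 0, 0, 0]])
        (call,) = call_snps(cf, ca)
        assert call.p_fen == pytest.approx(8 / 200)
        assert call.p_alp == 0.0
        assert call.private_fen and not call.private_alp
        assert not call.rare  # pooled 8/400 = 0.02 >= 0.01
        cfg = FilterConfig(rare_freq_flag=0.05)
        (call,) = call_snps(cf, ca, cfg)
        assert call.rare


class TestPolarization:
    def make_call(self, **kw):
        base = dict(
            locus_id="g", position=5, ref="A", alt="C", anc=None,
            p_fen=0.3, p_alp=0.1, reads_fen=(3, 3), reads_alp=(1, 1),
            depth_fen=20, depth_alp=20,
        )
        base.update(kw)
        return SnpCall(**base)

    def test_outgroup_matches_reference(self):
        (out,) = polarize([self.make_call()], {("g", 5): "A"})
        assert out.polarized and out.anc == "A"
        assert out.p_fen == pytest.approx(0.3)

    def test_outgroup_matches_alternate(self):
        (out,) = polarize([self.make_call()], {("g", 5): "C"})
        assert out.polarized and out.anc == "C"
        assert out.p_fen == pytest.approx(0.7)
        assert out.ref == "C" and out.alt == "A"

    def test_outgroup_mismatch_or_missing(self):
        (a, b) = polarize(
            [self.make_call(), self.make_call(position=6)], {("g", 5): "G"}
        )
        assert not a.polarized and a.p_fen == pytest.approx(0.3)
        assert not b.polarized


class TestFrequencyCutoff:
    def make_calls(self, freqs):
        calls = []
        for i, f in enumerate(freqs):
            alt = int(round(f * 400))
            calls.append(
                SnpCall(
                    locus_id="g", position=i + 1, ref="A", alt="C", anc=None,
                    p_fen=f, p_alp=f,
                    reads_fen=(alt // 2, alt - alt // 2), reads_alp=(0, 0),
                    depth_fen=200, depth_alp=200,
                )
            )
        return calls

    def test_cutoffs(self):
        calls = self.make_calls([0.005, 0.02, 0.15, 0.5])
        kept, rep = apply_frequency_cutoff(calls, None)
        assert len(kept) == 4 and rep["n_retained"] == 4
        kept, _ = apply_frequency_cutoff(calls, 0.01)
        assert len(kept) == 3
        kept, _ = apply_frequency_cutoff(calls, 0.1)
        assert len(kept) == 2
        with pytest.raises(ValueError):
            apply_frequency_cutoff(calls, 0.05)

    def test_maf_folds_high_frequencies(self):
        call = self.make_calls([0.995])[0]
        assert minor_allele_frequency(call) == pytest.approx(0.005, abs=0.002)


class TestSyncRoundTrip:
    def test_sync_pileups_match_read_stacks(self, tmp_path, fitted_model):
        """SNPs called from a sync file equal those called from the read
        stacks the file was derived from."""
        from poolscan.models import LocusSpec, PoolReadProfile
        from poolscan.simdata import write_fixture_dataset
        from poolscan.poolproc import pileups_from_sync

        loci = [LocusSpec(f"g{i}", 400) for i in range(3)]
        write_fixture_dataset(
            fitted_model, loci, PoolReadProfile(target_depth=80),
            tmp_path, seed=21,
        )
        pileups = pileups_from_sync(tmp_path / "sync.tsv")
        calls = call_snps(pileups["FEN"], pileups["ALP"])
        assert len(calls) > 0
        truth = pd.read_csv(tmp_path / "truth_frequencies.tsv", sep="\t")
        keys = {(c.locus_id, c.position) for c in calls}
        assert keys <= set(zip(truth["locus"], truth["pos"]))
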