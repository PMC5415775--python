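"""Copy-number module: counting oracle, correction, log ratios, calls."""
import numpy as np
import pytest

from panelpipe.align import Alignment, align_reads
from panelpipe.cnv import (AmpliconCounts, count_amplicons, coverage_correction,
                           log_ratios)
from panelpipe.errors import ConfigError
from panelpipe.sim import CnvSpec, LesionSpec, simulate_sample


def counts_from_truth(sample, sample_id="s"):
    return AmpliconCounts(sample_id, dict(sample.amplicon_counts))


class TestCountAmplicons:
    def test_reads_inside_amplicon_counted(self, reference, panel):
        amp = panel.target_amplicons[0]
        alns = [Alignment(f"r{i}", "aligned", amp.chrom, amp.start, "+", 0)
                for i in range(100)]
        counts = count_amplicons(alns, panel)
        assert counts.counts[amp.amplicon_id] == 100

    def test_conservation(self, reference, panel, kmer_index):
        s = simulate_sample(reference, panel, depth=10, seed=3)
        alns = align_reads(s.reads, reference, index=kmer_index)
        counts = count_amplicons(alns, panel)
        n_aligned = sum(a.aligned for a in alns)
        assert sum(counts.counts.values()) + counts.n_unassigned == n_aligned

    def test_brute_force_interval_lookup_on_twenty_reads(self, reference, panel, rng):
        alns = []
        for i in range(20):
            chrom = str(rng.choice(reference.names))
            pos = int(rng.integers(0, reference.length(chrom) - 1))
            alns.append(Alignment(f"r{i}", "aligned", chrom, pos, "+", 0))
        counts = count_amplicons(alns, panel)
        expected = {a.amplicon_id: 0 for a in panel}
        unassigned = 0
        for aln in alns:
            containing = [a for a in panel
                          if a.chrom == aln.chrom and a.start <= aln.pos < a.end]
            if not containing:
                unassigned += 1
            else:
                best = max(containing, key=lambda a: a.start)
                expected[best.amplicon_id] += 1
        assert counts.counts == expected
        assert counts.n_unassigned == unassigned

    def test_duplicates_excluded_when_deduping(self, panel):
        amp = panel.target_amplicons[0]
        alns = [Alignment("r1", "aligned", amp.chrom, amp.start, "+", 0,
                          is_duplicate=True)]
        assert count_amplicons(alns, panel).counts[amp.amplicon_id] == 0
        assert count_amplicons(alns, panel, dedupe=False).counts[amp.amplicon_id] == 1


class TestCoverageCorrection:
    def test_constant_controls(self, panel):
        counts = AmpliconCounts("s", {a.amplicon_id: 200 for a in panel})
        assert coverage_correction(counts, panel) == 200.0

    def test_doubling_counts_doubles_factor(self, reference, panel):
        s = simulate_sample(reference, panel, depth=50, seed=10)
        c1 = counts_from_truth(s)
        c2 = AmpliconCounts("s2", {k: 2 * v for k, v in c1.counts.items()})
        f1 = coverage_correction(c1, panel)
        assert coverage_correction(c2, panel) == 2 * f1

    def test_factor_tracks_depth_poisson_oracle(self, reference, panel):
        depth = 300
        for seed in range(5):
            s = simulate_sample(reference, panel, depth=depth, seed=seed)
            f = coverage_correction(counts_from_truth(s), panel)
            assert abs(f - depth) < 3 * np.sqrt(depth)

    def test_all_zero_controls_rejected(self, panel):
        counts = AmpliconCounts("s", {a.amplicon_id: 0 for a in panel})
        with pytest.raises(ConfigError):
            coverage_correction(counts, panel)


class TestLogRatios:
    def test_identity_gives_zero_ratios_and_neutral_calls(self, reference, panel):
        s = simulate_sample(reference, panel, depth=100, seed=20)
        c = counts_from_truth(s)
        prof = log_ratios(c, c, panel)
        assert all(abs(r) < 1e-12 for r in prof.log2_ratios.values())
        assert all(g.call == "neutral" for g in prof.gene_calls.values())

    def test_global_rescaling_leaves_ratios_unchanged(self, reference, panel):
        t = counts_from_truth(simulate_sample(reference, panel, depth=200, seed=21))
        b = counts_from_truth(simulate_sample(reference, panel, depth=200, seed=22))
        base = log_ratios(t, b, panel)
        scaled = AmpliconCounts("s", {k: 7 * v for k, v in t.counts.items()})
        rescaled = log_ratios(scaled, b, panel)
        # exact when no zero counts are involved (pseudocount untouched)
        assert min(t.counts.values()) > 0
        for k in base.log2_ratios:
            assert rescaled.log2_ratios[k] == pytest.approx(base.log2_ratios[k],
                                                            abs=1e-12)

    def test_spiked_half_ratio_called_loss(self, reference, panel):
        lesions = LesionSpec(cnvs=[CnvSpec("GENE2", 0.5)])
        for seed in range(3):
            t = counts_from_truth(simulate_sample(reference, panel, lesions,
                                                  depth=500, seed=30 + seed))
            b = counts_from_truth(simulate_sample(reference, panel, depth=500,
                                                  seed=60 + seed))
            prof = log_ratios(t, b, panel)
            gc = prof.gene_calls["GENE2"]
            assert gc.call == "loss"
            assert abs(gc.median_log2_ratio + 1.0) < 0.3
            assert prof.gene_calls["GENE1"].call == "neutral"

    def test_deep_deletion_called_loss(self, reference, panel):
        lesions = LesionSpec(cnvs=[CnvSpec("GENE1", 0.1)])
        t = counts_from_truth(simulate_sample(reference, panel, lesions,
                                              depth=500, seed=70))
        b = counts_from_truth(simulate_sample(reference, panel, depth=500, seed=71))
        assert log_ratios(t, b, panel).gene_calls["GENE1"].call == "loss"

    def test_monotone_in_spiked_ratio(self, reference, panel):
        medians = []
        b = counts_from_truth(simulate_sample(reference, panel, depth=400, seed=80))
        for i, ratio in enumerate([0.25, 0.5, 1.0, 2.0, 4.0]):
            lesions = LesionSpec(cnvs=[CnvSpec("GENE1", ratio)])
            t = counts_from_truth(simulate_sample(reference, panel, lesions,
                                                  depth=400, seed=90 + i))
            medians.append(log_ratios(t, b, panel).gene_calls["GENE1"].median_log2_ratio)
        assert medians == sorted(medians)

    def test_control_amplicons_never_get_gene_calls(self, reference, panel):
        t = counts_from_truth(simulate_sample(reference, panel, depth=100, seed=95))
        prof = log_ratios(t, t, panel)
        assert set(prof.gene_calls) == {"GENE1", "GENE2"}

    def test_missing_amplicon_rejected(self, reference, panel):
        t = counts_from_truth(simulate_sample(reference, panel, depth=100, seed=96))
        bad = AmpliconCounts("b", dict(list(t.counts.items())[:-1]))
        with pytest.raises(ConfigError):
            log_ratios(t, bad, panel)

    def test_neutral_genes_tight_at_depth(self, reference, panel):
        # median |r| < 0.2 for neutral genes at depth >= 300
        ok = 0
        for seed in range(20):
            t = counts_from_truth(simulate_sample(reference, panel, depth=300,
                                                  seed=200 + seed))
            b = counts_from_truth(simulate_sample(reference, panel, depth=300,
                                                  seed=300 + seed))
            prof = log_ratios(t, b, panel)
            if all(abs(g.median_log2_ratio) < 0.2 for g in prof.gene_calls.values()):
                ok += 1
        assert ok >= 19
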