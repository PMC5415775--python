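"""Read simulator: determinism, conservation, lesion spike-ins, noise model."""
import numpy as np
import pytest
from scipy import stats

from panelpipe.errors import ConfigError
from panelpipe.sim import (CnvSpec, FusionSpec, LesionSpec, SnvSpec,
                           simulate_sample)


def snv_at(reference, chrom, pos, vaf):
    ref_base = reference.sequence(chrom)[pos]
    alt = "A" if ref_base != "A" else "C"
    return SnvSpec(chrom, pos, ref_base, alt, vaf)


def test_same_seed_identical_reads(reference, panel):
    a = simulate_sample(reference, panel, depth=30, seed=5, base_error_rate=0.01)
    b = simulate_sample(reference, panel, depth=30, seed=5, base_error_rate=0.01)
    assert [(r.read_id, r.seq) for r in a.reads] == [(r.read_id, r.seq) for r in b.reads]


def test_no_noise_reads_are_exact_reference_substrings(reference, panel):
    s = simulate_sample(reference, panel, depth=20, base_error_rate=0.0, seed=2)
    for read in s.reads:
        assert read.seq == reference.sequence(read.chrom)[read.start:read.end]
        assert read.seq in reference.sequence(read.chrom)


def test_read_lengths_equal_configured(reference, panel):
    s = simulate_sample(reference, panel, depth=10, read_length=120, seed=3)
    assert {len(r.seq) for r in s.reads} == {120}


def test_total_reads_conservation(reference, panel):
    lesions = LesionSpec(fusions=[FusionSpec("GENE1-seg", 300, "GENE2-seg", 600,
                                             n_reads=25)])
    s = simulate_sample(reference, panel, lesions, depth=25, seed=4)
    assert len(s.reads) == sum(s.amplicon_counts.values()) + s.n_junction_reads
    assert s.n_junction_reads == 25


def test_snv_allele_fraction_binomial_oracle(reference, panel):
    # ~1000 overlapping reads at vaf 0.2: observed fraction within the
    # central 99% binomial interval
    vaf = 0.2
    pos = 500
    snv = snv_at(reference, "GENE1-seg", pos, vaf)
    s = simulate_sample(reference, panel, LesionSpec(snvs=[snv]), depth=500,
                        base_error_rate=0.0, seed=9)
    covering = [r for r in s.reads
                if r.chrom == "GENE1-seg" and r.start <= pos < r.end]
    n = len(covering)
    assert n > 500
    alt = sum(r.seq[pos - r.start] == snv.alt for r in covering)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, vaf)
    assert lo <= alt <= hi


def test_fusion_reads_contain_junction_sequence_exactly(reference, panel):
    fus = FusionSpec("GENE1-seg", 300, "GENE2-seg", 600, n_reads=25)
    s = simulate_sample(reference, panel, LesionSpec(fusions=[fus]), depth=30,
                        base_error_rate=0.0, seed=6)
    junction = (reference.sequence("GENE1-seg")[290:300]
                + reference.sequence("GENE2-seg")[600:610])
    hits = [r for r in s.reads if junction in r.seq]
    assert len(hits) == 25
    assert all(r.is_junction for r in hits)


def test_junction_reads_have_thirty_bases_each_side(reference, panel):
    fus = FusionSpec("GENE1-seg", 300, "GENE2-seg", 600, n_reads=5)
    s = simulate_sample(reference, panel, LesionSpec(fusions=[fus]), depth=10,
                        read_length=60, base_error_rate=0.0, seed=6)
    for r in s.reads:
        if not r.is_junction:
            continue
        assert r.seq[:30] == reference.sequence("GENE1-seg")[270:300]
        assert r.seq[30:] == reference.sequence("GENE2-seg")[600:630]


def test_truth_record_completeness(reference, panel):
    lesions = LesionSpec(
        snvs=[snv_at(reference, "GENE1-seg", 400, 0.3)],
        fusions=[FusionSpec("GENE1-seg", 300, "GENE2-seg", 600, n_reads=10)],
        cnvs=[CnvSpec("GENE2", 0.5)])
    s = simulate_sample(reference, panel, lesions, depth=20, seed=1)
    assert s.truth.snvs == lesions.snvs
    assert s.truth.fusions == lesions.fusions
    assert s.truth.cnvs == lesions.cnvs


def test_unobservable_snv_warns_and_drops_from_truth():
    from panelpipe.sim import ReferenceConfig, build_reference, design_panel
    # long control chromosomes -> gaps between control amplicons
    ref = build_reference(ReferenceConfig(chromosomes={
        "chr5": 10_000, "chr8": 10_000, "chr11": 10_000, "chr18": 10_000,
        "G-seg": 600}), seed=4)
    sparse = design_panel(ref, {"G": "G-seg"}, control_spec=14)
    uncovered = next(p for p in range(10_000)
                     if not any(a.chrom == "chr5" and a.start <= p < a.end
                                for a in sparse))
    snv = snv_at(ref, "chr5", uncovered, 0.3)
    with pytest.warns(UserWarning, match="unobservable"):
        s = simulate_sample(ref, sparse, LesionSpec(snvs=[snv]), depth=10, seed=1)
    assert s.truth.snvs == []


def test_negative_depth_rejected(reference, panel):
    with pytest.raises(ConfigError):
        simulate_sample(reference, panel, depth=-1, seed=0)


def test_short_reads_with_fusion_rejected(reference, panel):
    lesions = LesionSpec(fusions=[FusionSpec("GENE1-seg", 300, "GENE2-seg", 600,
                                             n_reads=5)])
    with pytest.raises(ConfigError, match="read_length"):
        simulate_sample(reference, panel, lesions, depth=10, read_length=59, seed=0)


def test_bad_snv_ref_base_rejected(reference, panel):
    ref_base = reference.sequence("GENE1-seg")[100]
    wrong = "A" if ref_base != "A" else "C"
    with pytest.raises(ConfigError, match="mismatch"):
        simulate_sample(reference, panel,
                        LesionSpec(snvs=[SnvSpec("GENE1-seg", 100, wrong, "G", 0.5)]),
                        depth=10, seed=0)


def test_copy_ratio_scales_poisson_mean(reference, panel):
    lesions = LesionSpec(cnvs=[CnvSpec("GENE1", 3.0)])
    s = simulate_sample(reference, panel, lesions, depth=100, seed=8)
    gene1 = [s.amplicon_counts[a.amplicon_id] for a in panel.by_gene()["GENE1"]]
    gene2 = [s.amplicon_counts[a.amplicon_id] for a in panel.by_gene()["GENE2"]]
    assert np.mean(gene1) > 2 * np.mean(gene2)


def test_per_amplicon_counts_poisson_gof_across_seeds(reference, panel):
    # chi-squared GOF against Poisson(depth) passes at alpha=0.01 in >=95% of seeds
    depth = 100
    n_seeds = 60
    support = np.arange(0, 200)
    pmf = stats.poisson.pmf(support, depth)
    # merge bins so every expected count is >= ~5 given 80 amplicons
    edges = [0]
    acc = 0.0
    for k, p in enumerate(pmf):
        acc += p
        if acc * len(list(reference.names)) * 14 >= 5:  # rough, recomputed below
            edges.append(k + 1)
            acc = 0.0
    passed = 0
    for seed in range(n_seeds):
        s = simulate_sample(reference, panel, depth=depth, seed=seed)
        counts = np.array(list(s.amplicon_counts.values()))
        n_amp = len(counts)
        bin_p, bin_obs = [], []
        lo = 0
        for hi in edges[1:]:
            bin_p.append(pmf[lo:hi].sum())
            bin_obs.append(((counts >= lo) & (counts < hi)).sum())
            lo = hi
        bin_p.append(1.0 - np.sum(bin_p))
        bin_obs.append((counts >= lo).sum())
        bin_p = np.array(bin_p)
        bin_obs = np.array(bin_obs, dtype=float)
        stat = ((bin_obs - n_amp * bin_p) ** 2 / (n_amp * bin_p)).sum()
        if stats.chi2.sf(stat, df=len(bin_p) - 1) >= 0.01:
            passed += 1
    assert passed >= int(0.95 * n_seeds)
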