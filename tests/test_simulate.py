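import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from mitodip.refgenome import tile_windows
from mitodip.simulate import (
    DmrSpec,
    NumtSpec,
    SimulationConfig,
    evaluate_triage,
    simulate_fragment_positions,
    simulate_medip_reads,
    simulate_methylomes,
    simulate_reference,
    simulate_window_counts,
    write_fastq_pair,
)
from mitodip.triage import RetainedReadSet


class TestSimulateReference:
    def test_zero_divergence_numt_is_identical_to_source(self):
        cfg = replace(SimulationConfig(), numts=(NumtSpec(1001, 2000, "chr1", 5001, 0.0),))
        full, nuclear, truth = simulate_reference(cfg, np.random.default_rng(1))
        mito = full.mito_sequence
        numt = nuclear.records["chr1"][5000:6000]
        assert numt == mito[1000:2000]

    def test_divergence_rate_matches_binomial_expectation(self):
        cfg = replace(SimulationConfig(), numts=(NumtSpec(1001, 2000, "chr1", 5001, 0.10),))
        full, nuclear, truth = simulate_reference(cfg, np.random.default_rng(1))
        mito = full.mito_sequence
        numt = nuclear.records["chr1"][5000:6000]
        mism = sum(a != b for a, b in zip(numt, mito[1000:2000]))
        sd = math.sqrt(1000 * 0.1 * 0.9)
        assert abs(mism - 100) < 3 * sd

    def test_same_seed_reproduces_genomes(self):
        cfg = SimulationConfig()
        a = simulate_reference(cfg, np.random.default_rng(42))
        b = simulate_reference(cfg, np.random.default_rng(42))
        assert a[0].records == b[0].records
        assert a[1].records == b[1].records

    def test_overlapping_insertions_rejected(self):
        cfg = replace(
            SimulationConfig(),
            numts=(NumtSpec(1, 1000, "chr1", 5001, 0.0), NumtSpec(2001, 3000, "chr1", 5500, 0.0)),
        )
        with pytest.raises(ValueError, match="overlapping"):
            simulate_reference(cfg, np.random.default_rng(1))

    def test_truth_records_homology_windows(self):
        cfg = SimulationConfig()
        _, _, truth = simulate_reference(cfg, np.random.default_rng(1))
        identical = truth.mito_homology_windows(max_divergence=0.0)
        spec = cfg.numts[0]
        assert min(identical) == (spec.source_start - 1) // 100
        assert max(identical) == (spec.source_stop - 1) // 100


class TestSimulateMethylomes:
    def test_zero_noise_no_dmrs_identical_tissues(self):
        cfg = replace(SimulationConfig(), noise_sd=0.0, dmrs=())
        meth = simulate_methylomes(cfg, np.random.default_rng(1))
        vals = list(meth.values())
        for v in vals[1:]:
            np.testing.assert_array_equal(v, vals[0])

    def test_planted_effect_is_exact_without_noise(self):
        cfg = replace(
            SimulationConfig(),
            noise_sd=0.0,
            dmrs=(DmrSpec(16101, 16500, ("BA8",), +0.3),),
        )
        meth = simulate_methylomes(cfg, np.random.default_rng(1))
        diff = meth[("ind1", "BA8")] - meth[("ind1", "CER")]
        grid = tile_windows(cfg.mito_length, 100)
        lo, hi = grid.window_of(16101), grid.window_of(16500)
        np.testing.assert_allclose(diff[lo : hi + 1], 0.3)
        assert np.all(diff[:lo] == 0) and np.all(diff[hi + 1 :] == 0)

    def test_noise_sd_calibrated(self):
        cfg = replace(SimulationConfig(), noise_sd=0.05, dmrs=())
        meth = simulate_methylomes(cfg, np.random.default_rng(1))
        stacked = np.vstack(list(meth.values()))
        sd = stacked.std(axis=0).mean()
        assert abs(sd - 0.05) / 0.05 < 0.2

    def test_values_stay_in_unit_interval(self):
        cfg = replace(SimulationConfig(), noise_sd=0.4)
        meth = simulate_methylomes(cfg, np.random.default_rng(1))
        for v in meth.values():
            assert (v >= 0).all() and (v <= 1).all()


class TestFragmentSampling:
    def test_uniform_when_slope_zero(self):
        """With no enrichment, interior midpoint windows are uniform
        (chi-square goodness of fit, p > 0.001)."""
        cfg = replace(SimulationConfig(), enrichment_slope=0.0)
        grid = tile_windows(cfg.mito_length, 100)
        meth = np.full(len(grid), 0.5)
        rng = np.random.default_rng(1)
        starts, lengths = simulate_fragment_positions(meth, cfg, rng, 50_000)
        mids = starts + lengths // 2
        widx = (mids - 1) // 100
        interior = (widx >= 2) & (widx <= 162)
        obs = np.bincount(widx[interior], minlength=166)[2:163]
        res = stats.chisquare(obs)
        assert res.pvalue > 0.001

    def test_enrichment_ratio_tracks_methylation(self):
        """Windows at methylation 0.8 receive about 4x the fragments of
        windows at 0.2 when weight is proportional to methylation."""
        cfg = replace(SimulationConfig(), base_weight=0.0, enrichment_slope=1.0)
        grid = tile_windows(cfg.mito_length, 100)
        meth = np.where(np.arange(len(grid)) % 2 == 0, 0.2, 0.8)
        rng = np.random.default_rng(1)
        starts, lengths = simulate_fragment_positions(meth, cfg, rng, 50_000)
        mids = starts + lengths // 2
        widx = np.clip((mids - 1) // 100, 0, 165)
        interior = (widx >= 2) & (widx <= 162)
        hi = np.isin(widx[interior] % 2, [1]).sum()
        lo = interior.sum() - hi
        p_hi = hi / (hi + lo)
        sd = math.sqrt(0.8 * 0.2 / (hi + lo))
        assert abs(p_hi - 0.8) < 3 * sd

    def test_fragment_range_exceeding_genome_rejected(self):
        with pytest.raises(ValueError, match="fragment length"):
            replace(SimulationConfig(), mito_length=200, nuclear_lengths={"chr1": 1000})

    def test_fragments_fit_inside_genome(self):
        cfg = SimulationConfig()
        meth = np.full(166, 0.3)
        starts, lengths = simulate_fragment_positions(meth, cfg, np.random.default_rng(1), 5000)
        assert (starts >= 1).all()
        assert (starts + lengths - 1 <= cfg.mito_length).all()
        assert lengths.min() >= 220 and lengths.max() <= 320


class TestSimulateReads:
    def test_same_seed_gives_identical_fastq_bytes(self, tmp_path):
        cfg = replace(SimulationConfig(), n_fragments=200)
        outs = []
        for run in ("a", "b"):
            rng = np.random.default_rng(9)
            full, nuclear, truth = simulate_reference(cfg, rng)
            meth = simulate_methylomes(cfg, rng)
            pairs, _ = simulate_medip_reads(full, meth[("ind1", "BA8")], cfg, rng, truth=truth)
            p1, p2 = tmp_path / f"{run}_1.fq.gz", tmp_path / f"{run}_2.fq.gz"
            write_fastq_pair(pairs, p1, p2)
            import gzip

            outs.append((gzip.open(p1).read(), gzip.open(p2).read()))
        assert outs[0] == outs[1]

    def test_mates_are_fragment_ends(self):
        cfg = replace(SimulationConfig(), n_fragments=50, error_rate=0.0, numt_fraction=0.0)
        rng = np.random.default_rng(2)
        full, nuclear, truth = simulate_reference(cfg, rng)
        meth = simulate_methylomes(cfg, rng)
        pairs, origins = simulate_medip_reads(full, meth[("ind1", "BA8")], cfg, rng, truth=truth)
        from mitodip.triage import revcomp

        mito = full.mito_sequence
        for p in pairs[:10]:
            _, start = origins[p.read_id]
            assert mito[start - 1 : start - 1 + 50] == p.seq1
            # mate 2 is the reverse complement of the fragment's 3' end
            assert revcomp(p.seq2) in mito

    def test_numt_fraction_labelled_in_truth(self):
        cfg = replace(SimulationConfig(), n_fragments=1000, numt_fraction=0.2)
        rng = np.random.default_rng(3)
        full, nuclear, truth = simulate_reference(cfg, rng)
        meth = simulate_methylomes(cfg, rng)
        _, origins = simulate_medip_reads(full, meth[("ind1", "CER")], cfg, rng, truth=truth)
        n_numt = sum(1 for o in origins.values() if o[0] == "numt")
        assert n_numt == 200


class TestEvaluateTriage:
    def test_perfect_retention(self):
        origins = {"a": ("mito", 5), "b": ("mito", 9), "c": ("numt", "chr1", 3)}
        rs = RetainedReadSet(mito_name="chrM")
        rs.fragments = {"a": ("chrM", 5, 270), "b": ("chrM", 9, 270)}
        precision, recall, _ = evaluate_triage(origins, rs)
        assert precision == 1.0 and recall == 1.0

    def test_empty_retained(self):
        origins = {"a": ("mito", 5)}
        precision, recall, _ = evaluate_triage(origins, RetainedReadSet(mito_name="chrM"))
        assert precision is None and recall == 0.0

    def test_unknown_read_is_an_error(self):
        rs = RetainedReadSet(mito_name="chrM")
        rs.fragments = {"ghost": ("chrM", 1, 100)}
        with pytest.raises(KeyError):
            evaluate_triage({}, rs)


def test_window_counts_fast_path_conserves_totals():
    cfg = replace(SimulationConfig(), n_fragments=5000)
    counts, meth = simulate_window_counts(cfg, np.random.default_rng(1))
    assert set(counts) == set(cfg.samples)
    for v in counts.values():
        assert v.sum() == 5000
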