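"""Generator behavior: determinism, calibrated distributions, mixture
structure, RNA-seq shape, and PCR spike injection."""

import numpy as np
import pandas as pd
import pytest

from polpause import tag_processing as tp
from _helpers import single_gene
from polpause.synthetic_cohort import (CohortConfig, ConfigurationError,
                                       generate_cohort,
                                       inject_pcr_duplicates,
                                       simulate_polII_tags,
                                       simulate_rnaseq_coverage, truth_table)




class TestGenerateCohort:
    def test_seeded_determinism(self):
        cfg = CohortConfig(n_genes=30, seed=42)
        t1 = truth_table(generate_cohort(cfg)[0])
        t2 = truth_table(generate_cohort(cfg)[0])
        pd.testing.assert_frame_equal(t1, t2)
        t3 = truth_table(generate_cohort(CohortConfig(n_genes=30, seed=43))[0])
        assert not t1.equals(t3)

    def test_interpeak_distance_hyperparameter(self):
        truths, _ = generate_cohort(CohortConfig(n_genes=1000, seed=1))
        d = np.array([g.interpeak_d for g in truths])
        assert abs(d.mean() - 110.0) < 2.0
        assert np.all((d >= 60) & (d <= 180))

    def test_seventy_percent_positive_escape_index(self):
        # fraction of genes whose upstream Gaussian area exceeds the
        # downstream one (r * sigma_u > sigma_d) should be ~70%
        truths, _ = generate_cohort(CohortConfig(n_genes=1000, seed=2))
        rho_pos = np.array([g.height_ratio_r * g.sigma_u > g.sigma_d
                            for g in truths])
        assert 0.65 <= rho_pos.mean() <= 0.75

    def test_gene_spacing_and_bidirectional_distances(self):
        cfg = CohortConfig(n_genes=200, seed=3, fraction_bidirectional=0.4)
        truths, _ = generate_cohort(cfg)
        paired = {g.gene_id for g in truths if g.opposite_tss is not None}
        by_id = {g.gene_id: g for g in truths}
        tss = sorted((g.true_tss, g.gene_id) for g in truths)
        for (a_pos, a_id), (b_pos, b_id) in zip(tss, tss[1:]):
            if a_id in paired and b_id in paired and \
                    abs(by_id[a_id].true_tss - by_id[b_id].true_tss) < 1000:
                continue  # designated head-to-head pair
            assert b_pos - a_pos >= 3000

    def test_annotation_error_capped(self):
        truths, _ = generate_cohort(CohortConfig(n_genes=300, seed=4))
        errs = np.array([g.annotated_tss - g.true_tss for g in truths])
        assert np.all(np.abs(errs) <= 200)
        assert errs.std() > 20  # errors actually present

    @pytest.mark.parametrize("kwargs", [
        dict(n_genes=0, seed=1),
        dict(n_genes=10, seed=1, depth=-1.0),
        dict(n_genes=10, seed=1, background_rate=-0.1),
        dict(n_genes=10, seed=1, fraction_bidirectional=1.5),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kwargs)


class TestSimulateTags:
    def test_depth_linearity(self):
        truth = single_gene()
        base = CohortConfig(n_genes=1, seed=9, background_rate=0.0,
                            depth=3000, expr_ref=7.5)
        double = CohortConfig(n_genes=1, seed=9, background_rate=0.0,
                              depth=6000, expr_ref=7.5)
        n1 = simulate_polII_tags(truth, base,
                                 rng=np.random.default_rng(0))[0].total()
        n2 = simulate_polII_tags(truth, double,
                                 rng=np.random.default_rng(0))[0].total()
        assert 1.9 < n2 / n1 < 2.1

    def test_zero_depth_gives_empty_track(self):
        cfg = CohortConfig(n_genes=1, seed=9, depth=0.0, background_rate=0.0)
        track, frags = simulate_polII_tags(single_gene(), cfg,
                                           rng=np.random.default_rng(0))
        assert track.total() == 0 and len(frags) == 0

    def test_midpoint_mixture_recovery(self):
        """With no background, fragment midpoints reproduce the analytic
        two-Gaussian density (two maxima d apart, r > 0.99 correlation)."""
        truth = single_gene(interpeak_d=120.0, sigma_u=40.0, sigma_d=20.0,
                             height_ratio_r=1.5)
        cfg = CohortConfig(n_genes=1, seed=9, depth=150_000,
                           background_rate=0.0, expr_ref=7.5)
        _, frags = simulate_polII_tags(truth, cfg,
                                       rng=np.random.default_rng(1))
        assert len(frags) >= 100_000
        mids = (frags[:, 0] + frags[:, 1]) // 2
        rel = mids - truth.true_tss
        grid = np.arange(-200, 320)
        hist = np.histogram(rel, bins=np.append(grid, 320))[0].astype(float)
        mu = truth.upstream_peak_offset
        analytic = (truth.height_ratio_r
                    * np.exp(-0.5 * ((grid - mu) / truth.sigma_u) ** 2)
                    + np.exp(-0.5 * ((grid - mu - truth.interpeak_d)
                                     / truth.sigma_d) ** 2))
        assert np.corrcoef(hist, analytic)[0, 1] > 0.99
        # two local maxima separated by d +/- 5 on the smoothed histogram
        from scipy.ndimage import gaussian_filter1d
        from scipy.signal import argrelmax
        smooth = gaussian_filter1d(hist, 5)
        peaks = grid[argrelmax(smooth, order=25)[0]]
        assert len(peaks) == 2
        assert abs((peaks[1] - peaks[0]) - truth.interpeak_d) <= 5

    def test_minus_strand_mirror(self):
        cfg = CohortConfig(n_genes=1, seed=9, depth=50_000,
                           background_rate=0.0, expr_ref=7.5)
        profiles = {}
        for strand in "+-":
            truth = single_gene(strand=strand)
            track, _ = simulate_polII_tags(truth, cfg,
                                           rng=np.random.default_rng(2))
            positions = tp.apply_shifts(track, read_len=0, half_fragment=74)
            profiles[strand] = tp.pileup(positions, truth.annotated_tss,
                                         strand, (-300, 400)).values
        r = np.corrcoef(profiles["+"], profiles["-"])[0, 1]
        assert r > 0.99


class TestSimulateRna:
    def test_sharp_limit_is_exact_rectangle(self):
        truth = single_gene()
        cfg = CohortConfig(n_genes=1, seed=9, rna_onset_sigma=0.0,
                           rna_depth=30.0, expr_ref=7.5)
        prof = simulate_rnaseq_coverage(truth, cfg, noise=False)
        x = prof.rel_coords()
        inside = (x >= truth.rna_onset_offset) & (x < 600)
        assert np.allclose(prof.values[inside], 30.0)
        assert np.allclose(prof.values[~inside], 0.0)

    def test_body_mean_matches_amplitude_and_downstream_zero(self):
        truth = single_gene()
        cfg = CohortConfig(n_genes=1, seed=9, rna_depth=25.0, expr_ref=7.5)
        prof = simulate_rnaseq_coverage(truth, cfg,
                                        rng=np.random.default_rng(3))
        x = prof.rel_coords()
        body = prof.values[(x >= 200) & (x < 600)]
        assert abs(body.mean() - 25.0) < 2.0
        assert prof.values[x >= 600].sum() == 0

    def test_junction_upstream_of_tss_rejected(self):
        with pytest.raises(Exception):
            single_gene(first_junction=49_000)


class TestPcrSpikes:
    def _track(self):
        truth = single_gene()
        cfg = CohortConfig(n_genes=1, seed=9, depth=2000, expr_ref=7.5)
        return simulate_polII_tags(truth, cfg,
                                   rng=np.random.default_rng(4))[0]

    def test_zero_spikes_is_identity(self):
        track = self._track()
        out = inject_pcr_duplicates(track, 0, 100, seed=5)
        assert out.plus == track.plus and out.minus == track.minus

    def test_spikes_removed_by_filter_and_original_untouched(self):
        track = self._track()
        before = track.total()
        spiked = inject_pcr_duplicates(track, 5, 50, seed=5)
        assert track.total() == before  # input not modified
        assert spiked.total() == before + 5 * 50
        cleaned = tp.pcr_filter(spiked)
        assert cleaned.total() <= before
        # genuine promoter signal survives: peak region retained
        prof = tp.pileup(tp.apply_shifts(cleaned, 0, 74), 50_000, "+",
                         (-300, 400))
        assert prof.values.sum() > 0.5 * before

    def test_seeded_determinism(self):
        track = self._track()
        a = inject_pcr_duplicates(track, 3, 40, seed=6)
        b = inject_pcr_duplicates(track, 3, 40, seed=6)
        assert a.plus == b.plus and a.minus == b.minus

    def test_low_spike_height_rejected(self):
        with pytest.raises(ValueError):
            inject_pcr_duplicates(self._track(), 1, 10, seed=0)
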