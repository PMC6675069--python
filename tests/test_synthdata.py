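"""Generators: determinism, planted effects, and generative-model checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colitis_metasig.openfield import compute_metrics
from colitis_metasig.synthdata import (
    BeamSimConfig,
    BiosetSimConfig,
    CountSimConfig,
    simulate_beam_stream,
    simulate_biosets,
    simulate_counts,
    simulate_ortholog_map,
)


class TestCounts:
    def test_deterministic_under_seed(self):
        a, ta = simulate_counts(CountSimConfig(n_genes=100, seed=5))
        b, tb = simulate_counts(CountSimConfig(n_genes=100, seed=5))
        assert a.counts.equals(b.counts) and ta == tb

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            CountSimConfig(n_genes=0)
        with pytest.raises(ValueError):
            CountSimConfig(n_genes=10, n_perturbed=11)

    def test_null_config_groups_balanced(self):
        m, truth = simulate_counts(
            CountSimConfig(n_genes=2000, n_perturbed=0, library_size_cv=0, seed=1)
        )
        assert truth == {}
        ctrl = m.counts.loc[:, m.groups == "control"].mean(axis=1)
        dss = m.counts.loc[:, m.groups == "dss"].mean(axis=1)
        # no planted effect: mean log-ratio over genes ~ 0
        ratio = np.log2((dss.mean() + 1) / (ctrl.mean() + 1))
        assert abs(ratio) < 0.05

    def test_zero_dispersion_is_poisson(self):
        m, _ = simulate_counts(
            CountSimConfig(
                n_genes=2000,
                n_perturbed=0,
                dispersion=0.0,
                baseline_log_sd=0.0,
                library_size_cv=0,
                seed=2,
            )
        )
        x = m.counts.to_numpy()
        vmr = x.var(axis=1, ddof=1) / x.mean(axis=1)
        assert np.mean(vmr) == pytest.approx(1.0, abs=0.05)

    def test_planted_mean_ratio_near_two(self):
        cfg = CountSimConfig(
            n_genes=1000, n_perturbed=100, lfc_magnitude=1.0, library_size_cv=0, seed=7
        )
        m, truth = simulate_counts(cfg)
        ctrl = m.counts.loc[:, m.groups == "control"].mean(axis=1)
        dss = m.counts.loc[:, m.groups == "dss"].mean(axis=1)
        ratios = [
            (dss[g] / ctrl[g]) if d == "up" else (ctrl[g] / dss[g])
            for g, d in truth.items()
        ]
        assert 1.8 <= np.mean(ratios) <= 2.2


class TestBiosets:
    def test_full_penetrance_no_noise_recovers_signature(self):
        cfg = BiosetSimConfig(planted_penetrance=1.0, noise_rate=0.0, seed=3)
        biosets, sig = simulate_biosets(cfg)
        for b in biosets:
            assert set(b.records["gene"]) == set(sig)

    def test_zero_penetrance_never_appears(self):
        cfg = BiosetSimConfig(planted_penetrance=0.0, noise_rate=0.05, seed=4)
        biosets, sig = simulate_biosets(cfg)
        for b in biosets:
            assert not set(b.records["gene"]) & set(sig)

    def test_appearance_count_matches_binomial_expectation(self):
        cfg = BiosetSimConfig(
            n_genes_universe=1000,
            n_signature=500,
            planted_penetrance=0.6,
            noise_rate=0.0,
            seed=5,
        )
        biosets, sig = simulate_biosets(cfg)
        appearances = pd.concat([b.records["gene"] for b in biosets]).value_counts()
        mean_votes = appearances.reindex(sorted(sig)).fillna(0).mean()
        # 500 genes x Binom(18, 0.6): CI for the mean of means
        se = np.sqrt(18 * 0.6 * 0.4 / 500)
        assert abs(mean_votes - 10.8) < 4 * se

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            BiosetSimConfig(n_genes_universe=0)

    def test_deterministic(self):
        a, _ = simulate_biosets(BiosetSimConfig(seed=9))
        b, _ = simulate_biosets(BiosetSimConfig(seed=9))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.records, y.records)


class TestBeams:
    def test_zero_rates_empty_session(self):
        cfg = BeamSimConfig(rear_rate=0, ambulation_rate=0, fine_rate=0, seed=1)
        stream, truth = simulate_beam_stream(cfg)
        assert len(stream.events) == 0
        assert truth["rears"] == 0 and truth["rearing_time"] == 0
        assert truth["rest_time"] == cfg.session_length

    def test_no_vertical_without_rears(self):
        cfg = BeamSimConfig(rear_rate=0, seed=2)
        stream, truth = simulate_beam_stream(cfg)
        assert truth["rears"] == 0
        assert (stream.events["kind"] == "horizontal").all()

    def test_rear_count_in_poisson_interval(self):
        cfg = BeamSimConfig(rear_rate=2.0, session_length=3600, seed=3)
        _, truth = simulate_beam_stream(cfg)
        lo, hi = stats.poisson.interval(0.99, 2.0 * 60)
        assert lo <= truth["rears"] <= hi

    @pytest.mark.parametrize("seed", range(5))
    def test_truth_panel_matches_computed_metrics(self, seed):
        stream, truth = simulate_beam_stream(BeamSimConfig(seed=seed))
        panel = compute_metrics(stream)
        for key in [
            "basic_movements",
            "fine_movements",
            "xy_ambulation",
            "rears",
            "rearing_time",
            "immobility_time",
            "rest_time",
            "distance",
        ]:
            assert panel.session[key] == truth[key], key
        assert panel.normalized_rears == truth["normalized_rears"]
        assert panel.avg_rear_duration == truth["avg_rear_duration"]

    def test_zero_length_session_rejected(self):
        with pytest.raises(ValueError):
            BeamSimConfig(session_length=0)


class TestOrthologs:
    def test_partial_map_fraction(self):
        genes = [f"mg{i:05d}" for i in range(200)]
        omap = simulate_ortholog_map(genes, mapped_fraction=0.8, seed=1)
        assert len(omap.pairs) == 160
        assert set(omap.pairs["source"]) <= set(genes)
        # deterministic lookup, unmapped genes absent
        mapping = omap.map_genes(genes)
        assert len(mapping) == 160
        assert all(len(v) == 1 for v in mapping.values())
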