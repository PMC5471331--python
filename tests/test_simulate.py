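"""Planted-truth properties of the synthetic multi-omics generator."""

import numpy as np
import pandas as pd
import pytest

from drynet.methylome import MethylomeProfile, call_dmcs, call_dmrs
from drynet.simulate import (SimSpec, generate_all, make_annotation,
                             make_compendium, make_methylome, make_mirna,
                             make_timeseries, preset)


def tiny_spec(**kw):
    defaults = dict(
        module_sizes=(12, 12, 12, 12, 12),
        module_tfs=3,
        n_background_blocks=4,
        background_block_size=8,
        n_compendium_samples=120,
        cpgs_per_chrom=300,
        rng_seed=7,
    )
    defaults.update(kw)
    return SimSpec(**defaults)


class TestSpecValidation:
    def test_too_many_de_mirnas_rejected(self):
        with pytest.raises(ValueError, match="n_de_mirnas"):
            tiny_spec(n_mirnas=4, n_de_mirnas=5, n_decoy_pairs=0)

    def test_module_corr_must_exceed_background(self):
        with pytest.raises(ValueError, match="within_module_corr"):
            tiny_spec(within_module_corr=0.1, background_corr=0.5)

    def test_run_longer_than_promoter_rejected(self):
        with pytest.raises(ValueError, match="promoter"):
            tiny_spec(planted_dmc_runs=(60,))


class TestCompendium:
    def test_seeded_determinism_bit_identical(self):
        spec = tiny_spec()
        a = make_compendium(spec)
        b = make_compendium(spec)
        assert a.equals(b)

    def test_within_module_correlation_matches_factor_model(self):
        # closed form corr = a^2/(a^2 + sigma^2) = rho, planted at 0.8
        spec = tiny_spec(n_compendium_samples=200)
        comp = make_compendium(spec)
        members = [g for g, lab in spec.assignment().items()
                   if lab == "module_1"]
        sub = comp.loc[members].T.corr().to_numpy()
        iu = np.triu_indices_from(sub, 1)
        assert 0.7 <= sub[iu].mean() <= 0.9

    def test_cross_module_correlation_near_zero(self):
        spec = tiny_spec(n_compendium_samples=200)
        comp = make_compendium(spec)
        assign = spec.assignment()
        m1 = [g for g, lab in assign.items() if lab == "module_1"]
        m2 = [g for g, lab in assign.items() if lab == "module_2"]
        cross = comp.loc[m1 + m2].T.corr().loc[m1, m2].to_numpy()
        assert abs(cross.mean()) < 0.15

    def test_vanishing_noise_limit_gives_perfect_correlation(self):
        spec = tiny_spec(within_module_corr=0.998, corr_jitter=0.001)
        comp = make_compendium(spec)
        members = [g for g, lab in spec.assignment().items()
                   if lab == "module_2"][:6]
        sub = comp.loc[members].T.corr().to_numpy()
        assert sub[np.triu_indices_from(sub, 1)].min() > 0.99


class TestTimeseries:
    def test_noise_free_module_one_log_ratios_are_exact(self):
        spec = tiny_spec(noise_sd=0.0)
        ts = make_timeseries(spec)
        members = [g for g, lab in spec.assignment().items()
                   if lab == "module_1"]
        w1 = spec.module_logfc_profiles["module_1"]["W"][0]
        e1 = spec.module_logfc_profiles["module_1"]["E"][0]
        lw = np.log2(ts.loc[members, "W1"] / ts.loc[members, "W0"])
        le = np.log2(ts.loc[members, "E1"] / ts.loc[members, "E0"])
        assert np.allclose(lw, w1, atol=1e-9)
        assert np.allclose(le, e1, atol=1e-9)

    def test_module5_between_genotype_contrast_is_negative(self):
        spec = tiny_spec()
        ts = make_timeseries(spec)
        members = [g for g, lab in spec.assignment().items()
                   if lab == "module_5"]
        lw = np.log2(ts.loc[members, "W1"] / ts.loc[members, "W0"])
        le = np.log2(ts.loc[members, "E1"] / ts.loc[members, "E0"])
        assert float((le - lw).mean()) < 0.0

    def test_between_contrast_means_match_planted_profiles(self):
        spec = tiny_spec()
        ts = make_timeseries(spec)
        assign = spec.assignment()
        for label, prof in spec.module_logfc_profiles.items():
            members = [g for g, lab in assign.items() if lab == label]
            want = prof["E"][0] - prof["W"][0]
            lw = np.log2(ts.loc[members, "W1"] / ts.loc[members, "W0"])
            le = np.log2(ts.loc[members, "E1"] / ts.loc[members, "E0"])
            assert float((le - lw).mean()) == pytest.approx(want, abs=0.35)

    def test_seeded_determinism(self):
        spec = tiny_spec()
        assert make_timeseries(spec).equals(make_timeseries(spec))

    def test_values_are_positive_fpkm(self):
        ts = make_timeseries(tiny_spec())
        assert (ts.to_numpy() > 0).all()


class TestMethylome:
    def test_no_planted_runs_and_flat_background_gives_zero_dmcs(self):
        spec = tiny_spec(planted_dmc_runs=(), dmc_background_rate=0.0)
        ann = make_annotation(spec)
        long, _ = make_methylome(spec, ann)
        prof = MethylomeProfile.from_long(long)
        levels = prof.levels(3)
        assert int(call_dmcs(levels, 0.7).sum()) == 0

    def test_planted_runs_recovered_exactly(self):
        spec = tiny_spec(planted_dmc_runs=(10, 10, 10))
        ann = make_annotation(spec)
        long, truth = make_methylome(spec, ann)
        prof = MethylomeProfile.from_long(long)
        levels = prof.levels(3)
        covered = ~np.isnan(levels).any(axis=1)
        dmrs = call_dmrs(prof.chrom, prof.pos, call_dmcs(levels, 0.7),
                         covered, min_run=9)
        assert len(dmrs) == 3
        called = {(d.chrom, d.start, d.end) for d in dmrs}
        assert called == {(c, s, e) for c, s, e, _ in truth.expected_dmrs}

    def test_subthreshold_run_not_called(self):
        spec = tiny_spec(planted_dmc_runs=(8,))
        ann = make_annotation(spec)
        long, truth = make_methylome(spec, ann)
        prof = MethylomeProfile.from_long(long)
        levels = prof.levels(3)
        covered = ~np.isnan(levels).any(axis=1)
        dmrs = call_dmrs(prof.chrom, prof.pos, call_dmcs(levels, 0.7),
                         covered, min_run=9)
        assert truth.expected_dmrs == []
        assert dmrs == []

    def test_levels_within_unit_interval(self):
        spec = tiny_spec()
        long, _ = make_methylome(spec, make_annotation(spec))
        prof = MethylomeProfile.from_long(long)
        levels = prof.levels(3)
        finite = levels[~np.isnan(levels)]
        assert ((0.0 <= finite) & (finite <= 1.0)).all()

    def test_background_dmc_rate_within_half_band(self):
        spec = tiny_spec(cpgs_per_chrom=800, planted_dmc_runs=())
        long, _ = make_methylome(spec, make_annotation(spec))
        prof = MethylomeProfile.from_long(long)
        levels = prof.levels(3)
        covered = ~np.isnan(levels).any(axis=1)
        rate = call_dmcs(levels, 0.7).sum() / covered.sum()
        assert 0.5 * spec.dmc_background_rate <= rate <= 1.5 * spec.dmc_background_rate


class TestMirna:
    def test_planted_pairs_survive_filter_and_decoys_do_not(self):
        from drynet.mirna import filter_targets

        spec = tiny_spec()
        ts = make_timeseries(spec)
        expr, candidates, truth = make_mirna(spec, ts)
        kept = {(i.mirna_id, i.gene_id)
                for i in filter_targets(candidates, expr, ts, -0.67)}
        assert kept == set(truth.planted_pairs)

    def test_planted_de_mirnas_flagged(self):
        from drynet.mirna import call_demirnas

        spec = tiny_spec()
        ts = make_timeseries(spec)
        expr, _, truth = make_mirna(spec, ts)
        de = set()
        for pair in (("W0", "W1"), ("W0", "W6"), ("E0", "E1"), ("E0", "E6")):
            de |= call_demirnas(expr, pair, 2.0)
        assert set(truth.de_mirnas) <= de

    def test_seeded_determinism(self):
        spec = tiny_spec()
        ts = make_timeseries(spec)
        e1, c1, _ = make_mirna(spec, ts)
        e2, c2, _ = make_mirna(spec, ts)
        assert e1.equals(e2) and c1.equals(c2)


class TestBundle:
    def test_generate_all_is_deterministic(self):
        spec1 = tiny_spec()
        spec2 = tiny_spec()
        d1 = generate_all(spec1)
        d2 = generate_all(spec2)
        assert d1.compendium.equals(d2.compendium)
        assert d1.timeseries.equals(d2.timeseries)
        assert d1.methylome.equals(d2.methylome)
        assert d1.mirna_expr.equals(d2.mirna_expr)

    def test_presets_are_valid(self):
        assert preset("small").n_modules == 5
        assert preset("study-scale").module_sizes == (71, 136, 54, 159, 160)
        with pytest.raises(ValueError):
            preset("huge")
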