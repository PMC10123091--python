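"""Selection-campaign, read, and measurement-series simulators."""

import numpy as np
import pytest

from guideselect.library import BASES, GuideLibrarySpec
from guideselect.simulate import (
    PAPER_TIME_GRID,
    EditingModel,
    ReadSimConfig,
    SelectionConfig,
    SelectionExtinctionError,
    SimulatedPool,
    default_editing_model,
    four_pl,
    one_phase_association,
    pool_to_reads,
    run_campaign,
    run_selection_round,
    sample_initial_pool,
    simulate_dose_response,
    simulate_editing_amplicon,
    simulate_kinetics,
)
from collections import Counter


def _point_spec(spec21):
    """A degenerate spec: every position fixed except the C/T control."""
    special = {0: {"C": 0.5, "T": 0.5}}
    for label in spec21.coords.labels():
        if label == 0:
            continue
        dist = spec21.position_distribution(label)
        comp = max(dist, key=dist.get)
        special[label] = {comp: 1.0}
    return GuideLibrarySpec(
        spec21.target_sequence,
        spec21.loop_sequence,
        spec21.flank_5,
        spec21.flank_3,
        special_positions=special,
    )


class TestInitialPool:
    def test_degenerate_spec_yields_one_backbone(self, spec21):
        pool = sample_initial_pool(_point_spec(spec21), 10, seed=0)
        i0 = spec21.coords.label_to_guide_index(0)
        backbones = {g[:i0] + g[i0 + 1 :] for g in pool.counts}
        assert len(backbones) == 1
        assert pool.total_molecules == 10

    def test_design_frequencies_at_large_n(self, spec21):
        n = 40000
        pool = sample_initial_pool(spec21, n, seed=3)
        guides = pool.expand()
        i0 = spec21.coords.label_to_guide_index(0)
        c_frac = sum(g[i0] == "C" for g in guides) / n
        sigma = np.sqrt(0.25 / n)
        assert abs(c_frac - 0.5) < 3 * sigma
        # complement fraction at one randomized position
        label = spec21.randomized_positions[0]
        i = spec21.coords.label_to_guide_index(label)
        comp = spec21.perfect_guide[i]
        frac = sum(g[i] == comp for g in guides) / n
        sigma = np.sqrt(0.91 * 0.09 / n)
        assert abs(frac - 0.91) < 3 * sigma

    def test_bit_reproducible(self, spec21):
        a = sample_initial_pool(spec21, 500, seed=11)
        b = sample_initial_pool(spec21, 500, seed=11)
        assert a.counts == b.counts

    def test_bias_override(self, spec21):
        label = spec21.randomized_positions[0]
        i = spec21.coords.label_to_guide_index(label)
        pool = sample_initial_pool(
            spec21, 2000, seed=0, bias={label: {"A": 1.0}}
        )
        assert all(g[i] == "A" for g in pool.counts)

    def test_invalid_n(self, spec21):
        with pytest.raises(ValueError):
            sample_initial_pool(spec21, 0)


class TestSelectionRound:
    def _config(self, spec, **kw):
        kw.setdefault("pool_size", 1000)
        return SelectionConfig(spec=spec, **kw)

    def test_deterministic_fitness_keeps_only_winner(self, spec21):
        g_star = spec21.control_guide
        other = spec21.perfect_guide
        pool = SimulatedPool(Counter({g_star: 50, other: 50}))
        model = EditingModel(score_lookup={g_star: 1.0}, p_max=1.0, k_half=0.0)
        res = run_selection_round(pool, model, 1.0, self._config(spec21))
        assert set(res.selected.counts) == {g_star}
        assert res.selected.counts[g_star] == 50
        assert res.edited_fraction == 0.5

    def test_leak_one_preserves_pool(self, spec21):
        pool = SimulatedPool(Counter({spec21.control_guide: 30, spec21.perfect_guide: 70}))
        model = EditingModel(score_lookup={}, p_max=1.0)  # nothing edits
        res = run_selection_round(
            pool, model, 1.0, self._config(spec21, arms_leak=1.0)
        )
        assert res.selected.counts == pool.counts

    def test_constant_fitness_preserves_frequencies(self, spec21, rng):
        pool = sample_initial_pool(spec21, 4000, seed=5)
        model = EditingModel(
            factor_matrix=np.ones((4, 21)), p_max=0.4, k_half=0.0
        )  # score 1 for every guide -> p = 0.4 everywhere
        res = run_selection_round(
            pool, model, 1.0, self._config(spec21, pool_size=4000), rng
        )
        assert res.edited_fraction == pytest.approx(0.4, abs=3 * np.sqrt(0.24 / 4000))
        # uniform fitness: expected guide frequencies unchanged; check pos-0 C
        i0 = spec21.coords.label_to_guide_index(0)
        before = sum(c for g, c in pool.counts.items() if g[i0] == "C") / 4000
        after = sum(
            c for g, c in res.regenerated.counts.items() if g[i0] == "C"
        ) / res.regenerated.total_molecules
        assert abs(after - before) < 0.05

    def test_extinction_signal(self, spec21):
        pool = SimulatedPool(Counter({spec21.perfect_guide: 10}))
        model = EditingModel(score_lookup={}, p_max=1.0)
        with pytest.raises(SelectionExtinctionError):
            run_selection_round(pool, model, 1.0, self._config(spec21))

    def test_pcr_errors_mutate_some_molecules(self, spec21, rng):
        pool = SimulatedPool(Counter({spec21.control_guide: 2000}))
        model = EditingModel(score_lookup={spec21.control_guide: 1.0}, p_max=1.0, k_half=0.0)
        res = run_selection_round(
            pool,
            model,
            1.0,
            self._config(spec21, pool_size=2000, pcr_substitution_rate=0.01),
            rng,
        )
        assert len(res.regenerated.counts) > 1  # mutants appeared
        assert res.regenerated.total_molecules == 2000


class TestCampaign:
    def test_single_round_structure(self, spec21):
        cfg = SelectionConfig(spec=spec21, n_rounds=1, pool_size=2000, seed=2)
        model = default_editing_model(spec21)
        res = run_campaign(cfg, model)
        assert len(res.pools()) == 2
        assert res.rounds[0].pool.round_index == 1
        assert set(res.rounds[0].readout_edited_fraction) == set(cfg.enzyme_levels)

    def test_constant_fitness_leaves_profile_unchanged(self, spec21):
        from guideselect.pool import profile_pool

        cfg = SelectionConfig(
            spec=spec21, n_rounds=4, pool_size=20000, seed=9,
            enzyme_levels=(1.0,), selection_enzyme_level=1.0,
        )
        model = EditingModel(factor_matrix=np.ones((4, 21)), p_max=0.5, k_half=0.0)
        res = run_campaign(cfg, model)
        first = profile_pool(res.pools()[0].expand(), spec21).base_frequency_matrix
        last = profile_pool(res.pools()[-1].expand(), spec21).base_frequency_matrix
        assert float(np.abs(first.to_numpy() - last.to_numpy()).max()) < 0.03

    def test_default_model_enriches_winner_over_control(self, spec21):
        cfg = SelectionConfig(
            spec=spec21, n_rounds=4, pool_size=30000, seed=17,
            selection_enzyme_level=0.5,
        )
        res = run_campaign(cfg, default_editing_model(spec21))
        ctrl = spec21.control_guide
        i10 = spec21.coords.label_to_guide_index(10)
        winner = ctrl[:i10] + "T" + ctrl[i10 + 1 :]
        pools = res.pools()
        assert pools[-1].frequency(winner) > pools[0].frequency(winner)
        assert pools[-1].frequency(ctrl) < pools[1].frequency(ctrl)


class TestReadSimulation:
    def test_error_free_reconstruction(self, spec21):
        pool = sample_initial_pool(spec21, 200, seed=1)
        reads = pool_to_reads(pool, spec21, ReadSimConfig(substitution_rate=0.0))
        rebuilt = Counter(
            r.sequence[spec21.guide_slice()] for r in reads
        )
        assert rebuilt == pool.counts

    def test_error_rate_mean_mismatches(self, spec21, rng):
        pool = SimulatedPool(Counter({spec21.perfect_guide: 3000}))
        ref = spec21.reference_construct()
        reads = pool_to_reads(
            pool, spec21, ReadSimConfig(substitution_rate=0.001), rng
        )
        total_mm = sum(
            sum(a != b for a, b in zip(r.sequence, ref)) for r in reads
        )
        lam = 0.001 * len(ref) * len(reads)
        assert abs(total_mm - lam) < 3 * np.sqrt(lam)

    def test_indel_injection_changes_length(self, spec21, rng):
        pool = SimulatedPool(Counter({spec21.perfect_guide: 200}))
        reads = pool_to_reads(
            pool, spec21, ReadSimConfig(substitution_rate=0.0, indel_rate=1.0), rng
        )
        L = spec21.construct_length
        assert all(len(r.sequence) in (L - 1, L + 1) for r in reads)


class TestEditingAmpliconSimulation:
    REF = "CCGGT" * 10 + "A" + "GGTCC" * 10  # 101 nt, A at centre

    def test_no_editing_no_error(self):
        reads, n_edited = simulate_editing_amplicon(
            self.REF, 0.0, 50, ReadSimConfig(substitution_rate=0.0)
        )
        assert n_edited == 0
        site = len(self.REF) // 2
        assert all(r.sequence[6 + site] == "A" for r in reads)

    def test_editing_rate_recovered(self):
        _, n_edited = simulate_editing_amplicon(
            self.REF, 0.5, 4000, ReadSimConfig(substitution_rate=0.0, seed=4)
        )
        assert abs(n_edited / 4000 - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_non_a_site_rejected(self):
        with pytest.raises(ValueError):
            simulate_editing_amplicon(self.REF, 0.1, 10, target_site=0)


class TestMeasurementSeries:
    def test_kinetics_boundary_behaviour(self):
        s = simulate_kinetics(emax=0.8, k=0.1, noise_sd=0.0)
        assert s.values[0, 0] == 0.0  # t = 0
        long = simulate_kinetics(emax=0.8, k=0.1, times=[0, 1e6], noise_sd=0.0)
        assert long.values[0, -1] == pytest.approx(0.8, abs=1e-9)
        np.testing.assert_array_equal(s.times, PAPER_TIME_GRID)

    def test_kinetics_reproducible_and_clamped(self):
        a = simulate_kinetics(0.9, 0.1, noise_sd=0.2, n_reps=3, seed=6)
        b = simulate_kinetics(0.9, 0.1, noise_sd=0.2, n_reps=3, seed=6)
        np.testing.assert_array_equal(a.values, b.values)
        assert (a.values >= 0).all() and (a.values <= 1).all()

    def test_dose_series_zero_noise_matches_model(self):
        s = simulate_dose_response(0.0, 0.56, 1.5, 15.0, noise_sd=0.0)
        np.testing.assert_allclose(
            s.values[0], four_pl(s.doses, 0.0, 0.56, 1.5, 15.0), atol=1e-12
        )
        # bottom approached at low dose, top at high dose
        lo = four_pl(np.array([1e-6]), 0.0, 0.56, 1.5, 15.0)[0]
        hi = four_pl(np.array([1e9]), 0.0, 0.56, 1.5, 15.0)[0]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(0.56, abs=1e-6)

    def test_one_phase_closed_form(self):
        t = np.array([0.0, 5.0])
        np.testing.assert_allclose(
            one_phase_association(t, 1.0, 0.2), [0.0, 1 - np.exp(-1.0)]
        )
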