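"""Synthetic cohort generator: design fidelity, noise structure, determinism."""

import io

import numpy as np
import pytest

import forcematch as fm
from forcematch.simulate import _latent_output


def _noiseless_participant(c=0.0, mean_K=1.5, sd_K=0.0):
    return fm.ParticipantTruth(
        participant_id="P000",
        attenuation=fm.AttenuationParams(mean_K, sd_K),
        pathway=fm.PathwayParams(0.0, c, 0.0, 0.0, 0.0),
    )


class TestDrawParticipants:
    def test_degenerate_population(self):
        pop = fm.PopulationTruth(
            mean_K_sd=0.0, sd_K_scale=0.0,
            pathway_spread=fm.PathwayParams(0, 0, 0, 0, 0),
        )
        ps = fm.draw_participants(pop, 5, np.random.default_rng(0))
        assert all(p.attenuation.mean_K == pop.mean_K_mean for p in ps)
        assert all(p.attenuation.sd_K == 0.0 for p in ps)
        assert all(p.pathway == pop.pathway for p in ps)

    def test_population_mean_recovered(self):
        pop = fm.PopulationTruth(mean_K_mean=1.6, mean_K_sd=0.2)
        ps = fm.draw_participants(pop, 500, np.random.default_rng(1))
        mks = np.array([p.attenuation.mean_K for p in ps])
        assert mks.mean() == pytest.approx(1.6, abs=3 * 0.2 / np.sqrt(500))

    def test_seed_determinism(self):
        pop = fm.PopulationTruth()
        a = fm.draw_participants(pop, 10, np.random.default_rng(9))
        b = fm.draw_participants(pop, 10, np.random.default_rng(9))
        assert a == b


class TestIndirect:
    def test_noiseless_veridical(self, study1_design):
        ds = fm.simulate_indirect(
            _noiseless_participant(c=0.0), study1_design, np.random.default_rng(0)
        )
        assert np.allclose(ds["matching_force_N"], ds["target_force_N"])

    def test_full_contraction(self, study1_design):
        ds = fm.simulate_indirect(
            _noiseless_participant(c=1.0), study1_design, np.random.default_rng(0)
        )
        assert np.allclose(ds["matching_force_N"], study1_design.levels.mean())

    def test_contraction_slope(self, study1_design):
        """c=0.3 gives slope 0.7 and intercept 0.3 * level mean."""
        p = fm.ParticipantTruth(
            "P000",
            fm.AttenuationParams(1.0, 0.0),
            fm.PathwayParams(0.05, 0.3, 0.05, 0.05, 0.0),
        )
        targets = np.tile(study1_design.levels, 2000)
        out = _latent_output(
            p, targets, float(study1_design.levels.mean()), np.random.default_rng(2)
        )
        slope, intercept = np.polyfit(targets, out, 1)
        assert slope == pytest.approx(0.7, abs=0.01)
        assert intercept == pytest.approx(0.3 * study1_design.levels.mean(), abs=0.03)


class TestDirect:
    def test_noiseless_divisive_scaling(self, study1_design):
        ds = fm.simulate_direct(
            _noiseless_participant(mean_K=1.5), study1_design, "divisive",
            np.random.default_rng(0),
        )
        assert np.allclose(ds["matching_force_N"], 1.5 * ds["target_force_N"])

    def test_mean_matches_closed_form(self, study1_design):
        p = fm.ParticipantTruth(
            "P000", fm.AttenuationParams(1.6, 0.15), fm.PathwayParams()
        )
        design = fm.StudyDesign(2.0, 2.0, 1, 10**5, conditions=("direct",))
        ds = fm.simulate_direct(p, design, "divisive", np.random.default_rng(3))
        x = ds["matching_force_N"].to_numpy()
        # latent output at a single level: expectation from the pathway
        c = p.pathway.memory_contraction
        lat_mean = (1 - c) * 2.0 + c * 2.0
        assert x.mean() == pytest.approx(1.6 * lat_mean, abs=3 * x.std() / np.sqrt(x.size))

    def test_direct_sd_exceeds_indirect_sd(self, divisive_cohort):
        """Per-level SD in the direct condition exceeds the indirect condition
        for participants with sd_K > 0 — the excess-variability signature."""
        ds, truth = divisive_cohort
        summ = fm.summarize_levels(ds)
        wide = summ.pivot_table(
            index=["participant_id", "target_force"],
            columns="condition",
            values="sd_match",
        )
        frac = float((wide["direct"] > wide["indirect"]).mean())
        assert frac > 0.8


class TestStudySimulation:
    def test_published_cohort_shape(self):
        pop = fm.PopulationTruth()
        ds, truth = fm.simulate_study(
            pop, fm.DESIGN_PRESETS["study1"], "divisive", 121, seed=0
        )
        assert len(ds) == 121 * 72
        assert fm.validate(ds, fm.DESIGN_PRESETS["study1"]) == []
        assert len(truth["participants"]) == 121

    def test_study3_design(self):
        pop = fm.PopulationTruth()
        ds, _ = fm.simulate_study(
            pop, fm.DESIGN_PRESETS["study3"], "divisive", 19, seed=0
        )
        assert len(ds) == 19 * 160
        assert fm.validate(ds, fm.DESIGN_PRESETS["study3"]) == []

    def test_byte_identical_under_seed(self):
        pop = fm.PopulationTruth()
        bufs = []
        for _ in range(2):
            ds, _ = fm.simulate_study(
                pop, fm.DESIGN_PRESETS["study2"], "divisive", 3, seed=11
            )
            buf = io.StringIO()
            fm.write_trials(ds, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]


class TestGainStudy:
    def test_active_force_relation(self):
        pop = fm.PopulationTruth(mean_K_mean=1.2, mean_K_sd=0.1, sd_K_scale=0.1)
        ds, _ = fm.simulate_gain_study(
            pop, fm.DESIGN_PRESETS["study4"], seed=2, n_participants=4
        )
        for gain in (0.5, 1.0, 2.0):
            sub = ds[ds["gain"] == gain]
            assert np.allclose(
                sub["active_force_N"], sub["matching_force_N"] / gain
            )
        g1 = ds[ds["gain"] == 1.0]
        assert np.array_equal(g1["active_force_N"], g1["matching_force_N"])

    def test_requires_direct_only_design(self):
        with pytest.raises(ValueError, match="direct-only"):
            fm.simulate_gain_study(
                fm.PopulationTruth(), fm.DESIGN_PRESETS["study1"], seed=0
            )


class TestTrace:
    def test_window_mean_exact_without_noise(self):
        tr = fm.simulate_trace(2.3, 100, np.random.default_rng(0))
        assert len(tr) == 300
        got = fm.extract_matching_force(tr["time_s"], tr["force_N"])
        assert got == pytest.approx(2.3, abs=1e-9)

    def test_noise_is_centered_in_window(self):
        tr = fm.simulate_trace(
            2.3, 100, np.random.default_rng(1), plateau_noise_sd=0.1
        )
        got = fm.extract_matching_force(tr["time_s"], tr["force_N"])
        assert got == pytest.approx(2.3, abs=1e-9)

    def test_minimum_rate(self):
        with pytest.raises(ValueError, match="rate"):
            fm.simulate_trace(2.0, 10, np.random.default_rng(0))
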