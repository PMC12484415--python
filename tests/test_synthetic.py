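"""Synthetic-study generator: determinism, distributions, QC coupling."""

from dataclasses import replace

import numpy as np
import pytest

from fiberfv.hill import HillParameters, FiberMorphology
from fiberfv.pipeline import analyze_fibers
from fiberfv.synthetic import (
    FiberGroundTruth,
    GroupSpec,
    NoiseSpec,
    PopulationSpec,
    ReleaseProtocol,
    StudyConfig,
    default_population_spec,
    generating_means,
    make_study,
    read_study,
    sample_population,
    simulate_release_experiment,
    truncated_mean,
    write_study,
)
from fiberfv.traces import apply_qc


def small_group(species="human", ftype="I", n=3, **kw):
    base = dict(
        fcsa_mean=6000.0, fcsa_sd=0.0, vmax_mean=0.4, vmax_sd=0.0,
        a_over_po_mean=0.08, a_over_po_sd=0.0, st_mean=14.0, st_sd=0.0,
    )
    base.update(kw)
    return GroupSpec(species=species, fiber_type=ftype, n=n, **base)


class TestSamplePopulation:
    def test_default_design_sizes(self, default_spec):
        pop = sample_population(default_spec, seed=0)
        species = [t.species for t in pop]
        assert species.count("human") == 85
        assert species.count("bonobo") == 49
        by_group = {}
        for t in pop:
            by_group[(t.species, t.fiber_type)] = by_group.get(
                (t.species, t.fiber_type), 0) + 1
        assert by_group == {("human", "I"): 39, ("human", "II"): 46,
                            ("bonobo", "I"): 18, ("bonobo", "II"): 31}

    def test_zero_sd_yields_group_means(self):
        spec = PopulationSpec(groups=(small_group(n=4),), couple_st_fcsa=False,
                              rundown_sd=0.0, sl_drift_sd=0.0)
        pop = sample_population(spec, seed=5)
        for t in pop:
            assert t.morph.fcsa == pytest.approx(6000.0)
            assert t.true_params.vmax == pytest.approx(0.4)
            assert t.true_params.a_over_po == pytest.approx(0.08)
            assert 100 * t.true_params.po / t.morph.fcsa == pytest.approx(14.0)

    def test_law_of_large_numbers(self, default_spec):
        """Grand means over 20 seeds match the analytic truncated-normal
        means within 3 standard errors."""
        spec = replace(default_spec, couple_st_fcsa=False)
        samples = {}
        for seed in range(20):
            for t in sample_population(spec, seed):
                key = (t.species, t.fiber_type)
                samples.setdefault(key, {"fcsa": [], "vmax": [], "a_over_po": [],
                                         "st": []})
                samples[key]["fcsa"].append(t.morph.fcsa)
                samples[key]["vmax"].append(t.true_params.vmax)
                samples[key]["a_over_po"].append(t.true_params.a_over_po)
                samples[key]["st"].append(100 * t.true_params.po / t.morph.fcsa)
        gm = generating_means(spec)
        for key, vars_ in samples.items():
            for var, vals in vars_.items():
                vals = np.asarray(vals)
                sem = vals.std(ddof=1) / np.sqrt(vals.size)
                assert abs(vals.mean() - gm[key][var]) < 3 * sem, (key, var)

    def test_truncation_bounds_respected(self, default_spec):
        pop = sample_population(default_spec, seed=3)
        for t in pop:
            k = t.true_params.a_over_po
            assert 0 < k < 2
            assert t.morph.fiber_length >= 0.70
            assert t.morph.fiber_length <= 3.97

    def test_deterministic(self, default_spec):
        p1 = sample_population(default_spec, seed=12)
        p2 = sample_population(default_spec, seed=12)
        assert all(
            a.true_params == b.true_params and a.morph == b.morph
            and a.muscle == b.muscle
            for a, b in zip(p1, p2)
        )

    def test_bonobo_muscles_spread(self, default_spec):
        pop = sample_population(default_spec, seed=0)
        muscles = {t.muscle for t in pop if t.species == "bonobo"}
        assert muscles.issubset({"VL", "BB", "SOL", "ADD", "HAM"})
        assert len(muscles) >= 3
        assert {t.muscle for t in pop if t.species == "human"} == {"VL"}

    def test_negative_size_tension_coupling(self, default_spec):
        pop = sample_population(default_spec, seed=1)
        fcsa = np.array([t.morph.fcsa for t in pop])
        st = np.array([100 * t.true_params.po / t.morph.fcsa for t in pop])
        assert np.corrcoef(fcsa, st)[0, 1] < 0


def _truth(rundown=0.0, drift=0.0, vmax=0.4, k=0.08):
    po = 800.0
    return FiberGroundTruth(
        fiber_id="F0001", species="human", muscle="VL", fiber_type="I",
        morph=FiberMorphology(fcsa=6000.0, fiber_length=2.0,
                              sarcomere_length=2.6),
        true_params=HillParameters(po=po, a=k * po, b=vmax * k),
        rundown_rate=rundown, sl_drift=drift,
    )


class TestSimulateExperiment:
    def test_zero_noise_recovery(self):
        exp = simulate_release_experiment(_truth(), noise=NoiseSpec.zero(),
                                          seed=0)
        table = analyze_fibers([exp])
        assert table.loc[0, "a_over_po"] == pytest.approx(0.08, rel=1e-3)
        assert table.loc[0, "vmax"] == pytest.approx(0.4, rel=1e-3)
        assert table.loc[0, "accepted"]

    def test_rundown_trips_po_drop_rule(self):
        """4%/series rundown over 4 series gives a ~11.5% drop -> rejected."""
        exp = simulate_release_experiment(_truth(rundown=0.04),
                                          noise=NoiseSpec.zero(), seed=0)
        drop_expected = 1 - 0.96**3  # decay between consecutive series
        res = apply_qc(exp.po_readings, exp.sl_readings, 1.0)
        assert res.po_drop_observed == pytest.approx(drop_expected, rel=1e-9)
        assert not res.accepted and "po_drop" in res.reasons

    def test_sl_drift_trips_rule(self):
        exp = simulate_release_experiment(_truth(drift=0.07),
                                          noise=NoiseSpec.zero(), seed=0)
        res = apply_qc(exp.po_readings, exp.sl_readings, 1.0)
        assert res.sl_change_observed == pytest.approx(0.21, rel=1e-9)
        assert "sl_change" in res.reasons

    def test_bit_determinism(self):
        t = _truth()
        e1 = simulate_release_experiment(t, seed=77)
        e2 = simulate_release_experiment(t, seed=77)
        assert e1.po_readings == e2.po_readings
        for a, b in zip(e1.releases, e2.releases):
            assert np.array_equal(a.length_mm, b.length_mm)
            assert np.array_equal(a.force_uN, b.force_uN)

    def test_protocol_shape(self):
        proto = ReleaseProtocol()
        exp = simulate_release_experiment(_truth(), protocol=proto, seed=0)
        assert len(exp.releases) == proto.n_series * proto.releases_per_series
        assert len(exp.po_readings) == proto.n_series
        tr = exp.releases[0]
        assert tr.duration == pytest.approx(proto.trace_duration_s)
        assert 1.0 / tr.dt == pytest.approx(proto.sampling_hz)

    def test_clamp_level_validation(self):
        proto = ReleaseProtocol(clamp_levels=(0.05, 0.15, 0.30, 0.50))
        with pytest.raises(ValueError):
            ReleaseProtocol(clamp_levels=(0.1, 0.5, 0.9, 1.0))
        assert proto.clamp_levels[0] == 0.05


class TestMakeStudy:
    def test_single_fiber_study(self):
        spec = PopulationSpec(groups=(small_group(n=1),), couple_st_fcsa=False)
        study = make_study(StudyConfig(spec), seed=4)
        assert len(study.fibers) == 1 and len(study.ground_truth) == 1

    def test_study_determinism(self):
        spec = PopulationSpec(groups=(small_group(n=2),))
        s1 = make_study(StudyConfig(spec), seed=9)
        s2 = make_study(StudyConfig(spec), seed=9)
        for f1, f2 in zip(s1.fibers, s2.fibers):
            assert f1.po_readings == f2.po_readings
            for a, b in zip(f1.releases, f2.releases):
                assert np.array_equal(a.length_mm, b.length_mm)

    def test_default_acceptance_fraction_strictly_inside_unit_interval(
            self, default_study):
        table = analyze_fibers(default_study.fibers)
        frac = table["accepted"].mean()
        assert 0.0 < frac < 1.0

    def test_write_read_round_trip(self, tmp_path):
        spec = PopulationSpec(groups=(small_group(n=2),))
        study = make_study(StudyConfig(spec), seed=2)
        write_study(study, tmp_path)
        fibers = read_study(tmp_path)
        assert [f.fiber_id for f in fibers] == [f.fiber_id for f in study.fibers]
        orig = analyze_fibers(study.fibers)
        loaded = analyze_fibers(fibers)
        assert loaded["a_over_po"].values == pytest.approx(
            orig["a_over_po"].values, rel=1e-6
        )


class TestTruncatedMean:
    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        from scipy.stats import truncnorm

        mean, sd = 0.119, 0.08
        a, b = (0.05 * mean - mean) / sd, (3 * mean - mean) / sd
        draws = truncnorm.rvs(a, b, loc=mean, scale=sd, size=200000,
                              random_state=rng)
        assert truncated_mean(mean, sd) == pytest.approx(draws.mean(), abs=3e-4)

    def test_zero_sd(self):
        assert truncated_mean(5.0, 0.0) == 5.0
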