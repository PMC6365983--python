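"""Synthetic oddball generator: paradigm, single subjects, cohorts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from mmnloc import synth
from mmnloc.forward import load_region_table


class TestParadigm:
    def test_study_scale_counts(self):
        p = synth.OddballParadigm(3, 500, 0.1, seed=7)
        labels = synth.generate_paradigm(p)
        assert (labels == "standard").sum() == 1350
        assert (labels == "deviant").sum() == 150

    def test_separation_constraint_holds(self):
        p = synth.OddballParadigm(1, 200, 0.2, min_standards_between_deviants=2, seed=3)
        labels = synth.generate_paradigm(p)
        dev = np.flatnonzero(labels == "deviant")
        assert np.diff(dev).min() >= 3  # at least 2 standards in between

    def test_zero_fraction_all_standard(self):
        labels = synth.generate_paradigm(synth.OddballParadigm(1, 50, 0.0))
        assert np.all(labels == "standard")

    def test_seeded_determinism(self):
        p = synth.OddballParadigm(1, 300, 0.1, seed=9)
        a = synth.generate_paradigm(p)
        b = synth.generate_paradigm(p)
        assert np.array_equal(a, b)
        c = synth.generate_paradigm(synth.OddballParadigm(1, 300, 0.1, seed=10))
        assert not np.array_equal(a, c)
        assert (c == "deviant").sum() == (a == "deviant").sum()

    def test_unsatisfiable_raises(self):
        with pytest.raises(ValueError):
            synth.generate_paradigm(
                synth.OddballParadigm(1, 10, 0.9, min_standards_between_deviants=2)
            )


@pytest.fixture(scope="module")
def one_component():
    return [synth.ComponentSpec("STG-L", "both", 150.0, 20.0, 25.0)]


class TestSimulateSubject:
    def test_noiseless_standard_trials_identical(self, lead32, grid20, one_component):
        par = synth.OddballParadigm(1, 30, 0.1, seed=1)
        e = synth.simulate_subject(one_component, {}, par, lead32, grid20, 0.0, seed=0)
        std = e.data[e.condition == "standard"]
        assert np.all(std == std[0])
        dev = e.data[e.condition == "deviant"]
        assert np.allclose(dev[0], std[0])  # "both" scope: same waveform

    def test_noiseless_mmn_equals_deviant_only_projection(self, lead32, grid20):
        comps = [
            synth.ComponentSpec("STG-L", "both", 100.0, 15.0, 30.0),
            synth.ComponentSpec("IFG-L", "deviant-only", 170.0, 30.0, 20.0),
        ]
        par = synth.OddballParadigm(1, 30, 0.1, seed=2)
        e = synth.simulate_subject(comps, {}, par, lead32, grid20, 0.0, seed=0)
        diff = (
            e.data[e.condition == "deviant"].mean(axis=0)
            - e.data[e.condition == "standard"].mean(axis=0)
        )
        table, rad = load_region_table()
        j, ori = synth._component_source(comps[1], grid20, table, rad)
        topo = (lead32.source_block(j) @ ori) * 1e6
        t = e.times
        wave = 20.0 * 1e-9 * np.exp(-0.5 * ((t - 170.0) / 30.0) ** 2)
        assert np.allclose(diff, topo[:, None] * wave[None, :], atol=1e-10)
        # baseline: only the far Gaussian tail (~1e-7 of peak) remains
        assert (
            np.abs(diff[:, : e.sample_index(0.0)]).max() < 1e-6 * np.abs(diff).max()
        )

    def test_common_average_holds_with_noise(self, lead32, grid20, one_component):
        par = synth.OddballParadigm(1, 20, 0.1, seed=3)
        e = synth.simulate_subject(one_component, {}, par, lead32, grid20, 5.0, seed=4)
        assert np.abs(e.data.mean(axis=1)).max() < 1e-9

    def test_seeded_determinism_bitwise(self, lead32, grid20, one_component):
        par = synth.OddballParadigm(1, 20, 0.1, seed=5)
        a = synth.simulate_subject(one_component, {}, par, lead32, grid20, 5.0, seed=6)
        b = synth.simulate_subject(one_component, {}, par, lead32, grid20, 5.0, seed=6)
        assert np.array_equal(a.data, b.data)

    def test_unknown_region_raises(self, lead32, grid20):
        bad = [synth.ComponentSpec("NOWHERE", "both", 150.0, 20.0, 10.0)]
        par = synth.OddballParadigm(1, 10, 0.0)
        with pytest.raises(ValueError):
            synth.simulate_subject(bad, {}, par, lead32, grid20, 0.0, seed=0)

    def test_averaged_snr_matches_analytic_target(self, lead32, grid20):
        comps = synth.default_components()
        par = synth.OddballParadigm(1, 300, 0.1, seed=11)
        noise_sd = 2.0
        clean = synth.simulate_subject(comps, {}, par, lead32, grid20, 0.0, seed=0)
        sig = clean.data[clean.condition == "deviant"][0]
        sl = clean.window_slice((100.0, 300.0))
        sig_rms = np.sqrt((sig[:, sl] ** 2).mean())
        n_dev = int((clean.condition == "deviant").sum())
        analytic = sig_rms / (noise_sd / np.sqrt(n_dev))
        ratios = []
        for seed in (1, 2, 3):
            e = synth.simulate_subject(comps, {}, par, lead32, grid20, noise_sd, seed)
            erp = e.data[e.condition == "deviant"].mean(axis=0)
            base = erp[:, : e.sample_index(0.0)]
            ratios.append(
                np.sqrt((erp[:, sl] ** 2).mean()) / np.sqrt((base**2).mean())
            )
        assert abs(np.mean(ratios) - analytic) < 0.25 * analytic


class TestCohort:
    @pytest.fixture(scope="class")
    def tiny_cohort(self, lead32, grid20):
        spec = synth.CohortSpec(n_controls=15, n_patients=20, noise_sd=1.0, seed=42)
        par = synth.OddballParadigm(1, 20, 0.1)
        return synth.simulate_cohort(spec, lead32, grid20, paradigm=par)

    def test_group_gain_structure(self, tiny_cohort):
        gains = {"control": [], "patient": []}
        for rec in tiny_cohort:
            gains[rec.group].append(rec.true_gains)
        for region in ("IFG-L", "IFG-R", "STG-L"):
            c = np.mean([g[region] for g in gains["control"]])
            p = np.mean([g[region] for g in gains["patient"]])
            assert p < c
        for region in ("PPC-L", "M1-L", "DLPFC-L"):
            c = np.mean([g[region] for g in gains["control"]])
            p = np.mean([g[region] for g in gains["patient"]])
            assert p > c

    def test_covariates_ranges(self, tiny_cohort):
        for rec in tiny_cohort:
            assert 25 <= rec.covariates["age"] <= 85
            assert rec.covariates["speech_score"] in range(5)
            cw = rec.covariates["cwit_inhib_switch_s"]
            if rec.group == "control":
                assert np.isnan(cw)
            else:
                assert cw >= 10.0

    def test_cwit_tracks_generating_dlpfc_gain(self, lead32, grid20):
        rhos = []
        for seed in range(10):
            spec = synth.CohortSpec(
                n_controls=2, n_patients=40, noise_sd=0.0, seed=seed
            )
            par = synth.OddballParadigm(1, 10, 0.1)
            recs = synth.simulate_cohort(spec, lead32, grid20, paradigm=par)
            g = [r.true_gains["DLPFC-L"] for r in recs if r.group == "patient"]
            c = [
                r.covariates["cwit_inhib_switch_s"]
                for r in recs
                if r.group == "patient"
            ]
            rhos.append(spearmanr(g, c).statistic)
        assert np.mean(rhos) > 0.3

    def test_reproducible_from_seed(self, lead32, grid20):
        spec = synth.CohortSpec(n_controls=2, n_patients=2, noise_sd=2.0, seed=5)
        par = synth.OddballParadigm(1, 15, 0.1)
        a = synth.simulate_cohort(spec, lead32, grid20, paradigm=par)
        b = synth.simulate_cohort(spec, lead32, grid20, paradigm=par)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.epochs.data, rb.epochs.data)
            assert ra.covariates == rb.covariates
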