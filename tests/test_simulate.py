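"""Stochastic simulator: molecule walks, CRAC read emission, abortive
spectra, probe signal tables, and their agreement with the closed form."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polone.annotation import default_annotation, default_probe_catalog
from polone.model import PauseTerminationModel, steady_state
from polone.simulate import (FULL_LENGTH, SimulationConfig,
                             emit_abortive_spectrum, emit_crac_reads,
                             emit_probe_signals, simulate_condition,
                             simulate_molecules, simulate_replicate)


class TestSimulateMolecules:
    def test_zero_hazard_all_full_length(self, rng):
        model = PauseTerminationModel(np.ones(20), 0.0, 1.0)
        out = simulate_molecules(model, 1000, rng)
        assert out.n_full_length == 1000
        np.testing.assert_array_equal(out.terminated_at, FULL_LENGTH)
        np.testing.assert_array_equal(out.n_reached, 1000)

    def test_full_length_fraction_matches_closed_form(self, worked_model, rng):
        """Binomial check at the worked model: F = 1/8, n = 10,000."""
        out = simulate_molecules(worked_model, 10000, rng)
        se = np.sqrt(0.125 * 0.875 / 10000)
        assert abs(out.full_length_fraction - 0.125) < 3 * se

    def test_same_seed_reproduces_outcomes(self, worked_model):
        a = simulate_molecules(worked_model, 500, np.random.default_rng(7))
        b = simulate_molecules(worked_model, 500, np.random.default_rng(7))
        np.testing.assert_array_equal(a.terminated_at, b.terminated_at)
        np.testing.assert_array_equal(a.total_dwell, b.total_dwell)

    def test_reach_counts_are_consistent_with_terminations(self, worked_model, rng):
        out = simulate_molecules(worked_model, 2000, rng)
        # molecules reaching site x+1 = reaching x minus terminating at x
        term = np.bincount(
            out.terminated_at[out.terminated_at != FULL_LENGTH] - 1,
            minlength=3)
        np.testing.assert_array_equal(np.diff(out.n_reached), -term[:-1])
        assert out.n_reached[0] == 2000

    def test_dwell_totals_track_visitor_counts(self, rng):
        """Total dwell at x is a sum of n_reached(x) unit-mean exponentials."""
        model = PauseTerminationModel(np.ones(5), 0.1, 1.0)
        out = simulate_molecules(model, 20000, rng)
        # Gamma(n, 1) has mean n and SD sqrt(n)
        dev = (out.total_dwell - out.n_reached) / np.sqrt(out.n_reached)
        assert np.all(np.abs(dev) < 4)


class TestAbortiveSpectrum:
    def test_zero_hazard_gives_empty_spectrum(self, rng):
        model = PauseTerminationModel(np.ones(10), 0.0, 1.0)
        spectrum = emit_abortive_spectrum(simulate_molecules(model, 100, rng))
        assert spectrum.n_abortive == 0

    def test_conservation_in_counts(self, worked_model, rng):
        out = simulate_molecules(worked_model, 3456, rng)
        spectrum = emit_abortive_spectrum(out)
        assert spectrum.n_abortive + spectrum.n_full_length == 3456

    def test_proportions_match_closed_form(self, worked_model, rng):
        """Oracle: A(x)/sum A = (0.5, 0.25, 0.125)/0.875 at the worked model."""
        out = simulate_molecules(worked_model, 10000, rng)
        spectrum = emit_abortive_spectrum(out)
        expected = np.array([0.5, 0.25, 0.125]) / 0.875
        n = spectrum.n_abortive
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(spectrum.proportions - expected) < 3 * se)

    def test_default_landscape_mode_in_early_5ets(self, rng):
        """With the packaged pause landscape the dominant abortive species
        falls in the first 300 nt."""
        from polone.presets import preset_model

        out = simulate_molecules(preset_model("wt"), 20000, rng)
        spectrum = emit_abortive_spectrum(out)
        assert 1 <= spectrum.dominant_mode <= 300


class TestEmitCracReads:
    def _uniform_outcomes(self, L, n, rng):
        model = PauseTerminationModel(np.ones(L), 0.0, 1.0)
        return simulate_molecules(model, n, rng)

    def test_no_duplication_preserves_event_count(self, rng):
        out = self._uniform_outcomes(100, 200, rng)
        config = SimulationConfig(n_crac_events=500, pcr_duplication=0.0)
        reads = emit_crac_reads(out, config, rng)
        assert len(reads) == 500

    def test_read_geometry_and_strand(self, rng):
        out = self._uniform_outcomes(100, 200, rng)
        config = SimulationConfig(n_crac_events=300, pcr_duplication=0.0,
                                  read_length=30)
        reads = emit_crac_reads(out, config, rng)
        assert (reads["strand"] == "+").all()
        assert (reads["start"] == np.maximum(1, reads["end"] - 29)).all()
        assert reads["umi"].str.len().eq(5).all()

    def test_uniform_model_gives_uniform_3p_histogram(self, rng):
        """Chi-square against uniform for kappa = 0, constant tau."""
        L = 50
        out = self._uniform_outcomes(L, 2000, rng)
        config = SimulationConfig(n_crac_events=50000, pcr_duplication=0.0)
        reads = emit_crac_reads(out, config, rng)
        counts = np.bincount(reads["end"] - 1, minlength=L)
        # dwell realization wobbles around uniform; allow for both multinomial
        # and Gamma-dwell variance by testing against the realized dwell too
        chi2 = stats.chisquare(counts).pvalue
        assert chi2 > 1e-4 or stats.chisquare(
            counts, out.total_dwell / out.total_dwell.sum() * counts.sum()
        ).pvalue > 1e-3

    def test_region_shares_match_steady_state(self, rng):
        """Expected per-region read shares equal region-summed O(x)/sum O
        (within 3 SE at 50,000 events)."""
        from polone.presets import preset_model

        model = preset_model("wt")
        annotation = default_annotation()
        ss = steady_state(model)
        out = simulate_molecules(model, 20000, rng)
        config = SimulationConfig(n_crac_events=50000, pcr_duplication=0.0)
        reads = emit_crac_reads(out, config, rng)
        ends = reads["end"].to_numpy()
        n = ends.size
        for reg in annotation.regions:
            share = float(ss.occupancy[reg.start - 1:reg.end].sum()
                          / ss.occupancy.sum())
            observed = np.mean((ends >= reg.start) & (ends <= reg.end))
            # 3 SE multinomial + allowance for the finite-molecule dwell draw
            se = np.sqrt(share * (1 - share) * (1 / n + 1 / 20000))
            assert abs(observed - share) < 4 * se, reg.name

    def test_pcr_duplicates_share_key_and_rate(self, rng):
        """Duplicate copies reuse coordinates+UMI; the mean removable fraction
        is m/(1+m) for Geometric extra copies with mean m."""
        out = self._uniform_outcomes(500, 500, rng)
        m = 1.5
        config = SimulationConfig(n_crac_events=2000, pcr_duplication=m)
        reads = emit_crac_reads(out, config, rng)
        n_unique = len(reads.drop_duplicates(["start", "end", "strand", "umi"]))
        frac_removed = 1 - n_unique / len(reads)
        expected = m / (1 + m)
        # small excess removal from chance key collisions between events
        assert abs(frac_removed - expected) < 0.025

    def test_deterministic_files(self, tmp_path, worked_model):
        from polone.annotation import write_reads

        config = SimulationConfig(n_molecules=200, n_crac_events=500, seed=42)
        for name in ("a.tsv", "b.tsv"):
            reads = simulate_condition(
                PauseTerminationModel(np.ones(40), 0.01, 1.0), config)
            write_reads(reads, tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


class TestProbeSignals:
    def test_noise_free_ratios_equal_between_identical_conditions(self, annotation):
        from polone.presets import preset_model
        from polone.quant import normalize_to_5s

        catalog = default_probe_catalog()
        ss = steady_state(preset_model("wt"))
        t1 = emit_probe_signals(ss, catalog, annotation, noise_cv=0.0,
                                condition="A")
        t2 = emit_probe_signals(ss, catalog, annotation, noise_cv=0.0,
                                condition="B")
        r1 = normalize_to_5s(t1, catalog)
        r2 = normalize_to_5s(t2, catalog)
        merged = r1.merge(r2, on=["replicate", "probe"])
        np.testing.assert_allclose(merged["ratio_x"], merged["ratio_y"])

    def test_scaled_flux_scales_poli_ratio_not_igs2(self, annotation):
        """1.5x profile scaling propagates exactly through the 5S ratio."""
        from polone.presets import preset_model
        from polone.quant import normalize_to_5s

        catalog = default_probe_catalog()
        ss = steady_state(preset_model("wt"))
        base = normalize_to_5s(
            emit_probe_signals(ss, catalog, annotation, condition="C"), catalog)
        scaled = normalize_to_5s(
            emit_probe_signals(ss, catalog, annotation, condition="C",
                               scale=1.5), catalog)
        merged = base.merge(scaled, on=["replicate", "probe"],
                            suffixes=("_1", "_15"))
        poli = merged[merged["probe"] == "18S.1"]
        np.testing.assert_allclose(poli["ratio_15"], 1.5 * poli["ratio_1"])
        igs2 = merged[merged["probe"] == "IGS2"]
        np.testing.assert_allclose(igs2["ratio_15"], igs2["ratio_1"])

    def test_igs2_is_near_zero_background(self, annotation):
        from polone.presets import preset_model

        catalog = default_probe_catalog()
        table = emit_probe_signals(steady_state(preset_model("wt")), catalog,
                                   annotation)
        igs2 = table.loc[table["probe"] == "IGS2", "intensity"].max()
        poli_min = table.loc[
            table["probe"].isin([p.name for p in catalog.with_role("polI_signal")]),
            "intensity"].min()
        assert igs2 < poli_min / 100

    def test_unknown_target_region_rejected(self, annotation):
        from polone.annotation import Probe, ProbeCatalog
        from polone.presets import preset_model

        catalog = ProbeCatalog((
            Probe("mystery", "nonexistent", "polI_signal"),
            Probe("5S.1", "external", "control_5S"),
            Probe("5S.2", "external", "control_5S"),
            Probe("IGS2", "external", "background_IGS2")))
        with pytest.raises(ValueError, match="unknown region"):
            emit_probe_signals(steady_state(preset_model("wt")), catalog,
                               annotation)
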