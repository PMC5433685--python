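"""Assay quantifications: melt fits, ddCt, efficiency, arrays, proportions."""

import numpy as np
import pandas as pd
import pytest

from silentspeed.assay_synth import (boltzmann, generate_melt_curve,
                                     generate_microarray,
                                     generate_qpcr_table)
from silentspeed.errors import ValidationError
from silentspeed.quant import (classification_proportion, ddct,
                               decay_timecourse, efficiency_from_slope,
                               fit_boltzmann, microarray_relative_abundance,
                               normalize_expression)

TEMPS = np.arange(37.0, 101.0, 7.0)


class TestMeltGenerator:
    def test_midpoint_is_half_span(self):
        m = generate_melt_curve(70.0, 3.0, np.array([40.0, 70.0, 100.0]))
        at_t50 = m.loc[m["temperature_c"] == 70.0, "soluble_fraction"].iloc[0]
        assert at_t50 == pytest.approx(0.5)

    def test_replicate_noise_realized(self):
        m = generate_melt_curve(70.0, 3.0, TEMPS, noise_sd=0.1,
                                n_replicates=200, seed=1)
        sds = m.groupby("temperature_c")["soluble_fraction"].std()
        assert sds.mean() == pytest.approx(0.1, rel=0.1)

    def test_nonmonotone_temps_rejected(self):
        with pytest.raises(ValidationError):
            generate_melt_curve(70.0, 3.0, [40.0, 39.0, 50.0])


class TestBoltzmannFit:
    def test_noiseless_sigmoid_recovered_exactly(self):
        m = generate_melt_curve(70.0, 3.0, TEMPS)
        fit = fit_boltzmann(m)
        assert fit.ta_c == pytest.approx(70.0, abs=1e-6)
        assert fit.slope_c == pytest.approx(3.0, abs=1e-6)
        assert fit.top == pytest.approx(1.0, abs=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)
        assert not fit.flagged

    def test_monte_carlo_ta_within_one_degree(self):
        # 200-replicate study at the assay's noise scale
        errs = []
        for rep in range(200):
            m = generate_melt_curve(70.0, 3.0, TEMPS, noise_sd=0.05,
                                    n_replicates=5, seed=rep)
            errs.append(fit_boltzmann(m).ta_c - 70.0)
        assert np.mean(np.abs(errs)) < 1.0
        assert abs(np.mean(errs)) < 0.2

    def test_non_sigmoidal_data_flagged(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame({"temperature_c": TEMPS,
                          "soluble_fraction": rng.normal(0.5, 0.3,
                                                         len(TEMPS))})
        fit = fit_boltzmann(m)
        assert fit.flagged

    def test_too_few_temperatures_rejected(self):
        m = generate_melt_curve(70.0, 3.0, [50.0, 60.0, 70.0, 80.0])
        with pytest.raises(ValidationError):
            fit_boltzmann(m)


class TestDecayTimecourse:
    def test_t0_is_hundred_and_halving_is_fifty(self):
        df = pd.DataFrame({"time": [0, 6, 24], "signal": [8.0, 4.0, 2.0]})
        out = decay_timecourse(df)
        assert out["percent_remaining"].tolist() == [100.0, 50.0, 25.0]

    def test_monotone_preserved(self):
        df = pd.DataFrame({"time": [0, 1, 2, 3],
                           "signal": [5.0, 4.0, 2.5, 1.0]})
        out = decay_timecourse(df)
        assert np.all(np.diff(out["percent_remaining"]) < 0)

    def test_zero_t0_rejected(self):
        df = pd.DataFrame({"time": [0, 1], "signal": [0.0, 1.0]})
        with pytest.raises(ValidationError):
            decay_timecourse(df)


class TestNormalizeExpression:
    def band_table(self):
        return pd.DataFrame({
            "sample": ["wt", "mut"],
            "band_b": [2.0, 1.0], "band_c": [4.0, 2.0],
            "npt": [1.0, 1.0], "actb": [1.0, 1.0]})

    def test_reference_is_hundred(self):
        out = normalize_expression(self.band_table(), "wt")
        by = {r.sample: r for r in out}
        assert by["wt"].percent_of_reference == pytest.approx(100.0)
        assert by["mut"].percent_of_reference == pytest.approx(50.0)

    def test_global_gain_invariance(self):
        t = self.band_table()
        t2 = t.copy()
        t2[["band_b", "band_c", "npt", "actb"]] *= 7.3
        a = {r.sample: r.percent_of_reference
             for r in normalize_expression(t, "wt")}
        b = {r.sample: r.percent_of_reference
             for r in normalize_expression(t2, "wt")}
        assert a == pytest.approx(b)

    def test_c_over_b_ratio(self):
        out = normalize_expression(self.band_table(), "wt")
        assert out[0].c_over_b == pytest.approx(2.0)

    def test_zero_normalizer_rejected(self):
        t = self.band_table()
        t.loc[0, "npt"] = 0.0
        with pytest.raises(ValidationError):
            normalize_expression(t, "wt")


class TestDdct:
    def test_zero_ddct_gives_hundred_percent(self):
        ct = generate_qpcr_table({"wt": 1.0}, "wt")
        out = ddct(ct, "CFTR", "NPT", "wt")
        assert out["percent_of_reference"].iloc[0] == pytest.approx(100.0)

    def test_one_cycle_lower_is_twofold(self):
        ct = generate_qpcr_table({"wt": 1.0, "up": 2.0}, "wt")
        out = ddct(ct, "CFTR", "NPT", "wt").set_index("sample")
        assert out.loc["up", "fold_change"] == pytest.approx(2.0)
        assert out.loc["up", "delta_delta_ct"] == pytest.approx(-1.0)

    def test_generated_fold_recovered(self):
        ct = generate_qpcr_table({"wt": 1.0, "mut": 0.75}, "wt",
                                 ct_noise_sd=0.05, n_wells=2, seed=4)
        out = ddct(ct, "CFTR", "NPT", "wt").set_index("sample")
        assert out.loc["mut", "percent_of_reference"] == pytest.approx(
            75.0, abs=8.0)

    def test_missing_reference_rejected(self):
        ct = generate_qpcr_table({"wt": 1.0}, "wt")
        with pytest.raises(ValidationError):
            ddct(ct, "CFTR", "NPT", "nonexistent")

    def test_scale_invariance_in_ct_offset(self):
        # adding a constant to every Ct leaves fold changes unchanged
        ct = generate_qpcr_table({"wt": 1.0, "mut": 0.6}, "wt")
        shifted = ct.assign(ct=ct["ct"] + 3.0)
        a = ddct(ct, "CFTR", "NPT", "wt")["fold_change"]
        b = ddct(shifted, "CFTR", "NPT", "wt")["fold_change"]
        assert a.tolist() == pytest.approx(b.tolist())


class TestEfficiency:
    @pytest.mark.parametrize("slope,expected", [
        (3.345, 99),          # CFTR standard curve
        (3.145, 108),         # NPT standard curve
    ])
    def test_worked_standard_curves(self, slope, expected):
        assert efficiency_from_slope(slope) == expected

    def test_doubling_slope_is_exactly_hundred(self):
        assert efficiency_from_slope(1.0 / np.log10(2.0)) == 100

    def test_strictly_decreasing_in_slope(self):
        slopes = np.linspace(2.5, 4.5, 9)
        effs = [efficiency_from_slope(s) for s in slopes]
        assert np.all(np.diff(effs) < 0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValidationError):
            efficiency_from_slope(0.0)


class TestMicroarray:
    def test_identical_channels_give_unit_ratios(self):
        arr = generate_microarray({"t1": 1.0, "t2": 1.0}, noise_cv=0.0)
        out = microarray_relative_abundance(arr)
        assert np.allclose(out["ratio"], 1.0)

    def test_spike_in_rescaling_removes_global_gain(self):
        a = generate_microarray({"t1": 0.5, "t2": 1.5}, global_gain=1.0,
                                noise_cv=0.0, seed=5)
        b = generate_microarray({"t1": 0.5, "t2": 1.5}, global_gain=2.0,
                                noise_cv=0.0, seed=5)
        ra = microarray_relative_abundance(a).set_index("trna")["ratio"]
        rb = microarray_relative_abundance(b).set_index("trna")["ratio"]
        assert ra.tolist() == pytest.approx(rb.tolist())

    def test_rare_trna_ratio_recovered_under_noise(self):
        arr = generate_microarray({"rare": 0.3, "common": 1.0},
                                  n_probes=24, noise_cv=0.10, seed=6)
        out = microarray_relative_abundance(arr).set_index("trna")
        assert out.loc["rare", "ratio"] == pytest.approx(0.3, rel=0.15)

    def test_zero_spike_signal_rejected(self):
        arr = generate_microarray({"t1": 1.0}, noise_cv=0.0)
        arr.loc[arr["is_spike_in"], "cy3"] = 0.0
        with pytest.raises(ValidationError):
            microarray_relative_abundance(arr)


class TestClassificationProportion:
    def test_worked_staining_counts(self):
        out = classification_proportion({"intracellular": 12, "membrane": 15})
        assert out == {"intracellular": 44, "membrane": 55}

    @pytest.mark.parametrize("counts,expected", [
        ({"a": 0, "b": 10}, {"a": 0, "b": 100}),
        ({"a": 27}, {"a": 100}),
    ])
    def test_edge_proportions(self, counts, expected):
        assert classification_proportion(counts) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            classification_proportion({"a": 0})
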