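"""Spore/cystidium summaries against hand-computed oracles and the protocol's
statistical conventions."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hebkeys.morphometrics import (CystidiumMeasurement, MeasurementError,
                                   SporeMeasurement, parse_opd,
                                   summarize_cheilocystidia, summarize_spores)


def spores(pairs):
    return [SporeMeasurement(l, w) for l, w in pairs]


class TestSporeSummary:
    def test_degenerate_identical_input(self):
        s = summarize_spores(spores([(11.0, 6.0)] * 50))
        assert s.n == 50
        assert s.mean_length == 11.0 and s.mean_width == 6.0
        assert s.sd_length == 0.0 and s.sd_width == 0.0
        assert s.median_length == 11.0 and s.median_width == 6.0
        assert s.mean_q == pytest.approx(11 / 6, abs=1e-4)
        assert s.p5_length == s.p95_length == 11.0
        assert s.warnings == ()

    def test_hand_arithmetic_oracle(self):
        # per-spore Q = 2.0, 1.8333, 2.4, 2.1667; sample SD of lengths
        s = summarize_spores(spores([(10, 5), (11, 6), (12, 5), (13, 6)]))
        assert s.mean_length == pytest.approx(11.5)
        assert s.mean_width == pytest.approx(5.5)
        assert s.mean_q == pytest.approx(2.1, abs=1e-4)
        assert s.sd_length == pytest.approx(1.2910, abs=1e-4)
        assert "n_below_protocol" in s.warnings  # n=4 < 50 warns, not errors

    def test_mean_q_is_mean_of_ratios_not_ratio_of_means(self):
        s = summarize_spores(spores([(10, 4), (12, 8)]))
        assert s.mean_q == pytest.approx((2.5 + 1.5) / 2)
        assert s.mean_q != pytest.approx(s.mean_length / s.mean_width)

    def test_holotype_parameter_recovery(self):
        # 102 lengths from a truncated normal at the published location/scale
        # recover the mean within 3 standard errors and the 5-95% envelope
        rng = np.random.default_rng(1729)
        mu, sd, n = 11.9, 0.84, 102
        lengths = stats.truncnorm.rvs(-4, 4, loc=mu, scale=sd, size=n,
                                      random_state=rng)
        s = summarize_spores(spores([(l, 6.5) for l in lengths]))
        assert abs(s.mean_length - mu) < 3 * sd / np.sqrt(n)
        assert s.p5_length == pytest.approx(10.4, abs=0.5)
        assert s.p95_length == pytest.approx(13.2, abs=0.5)

    def test_empty_input_errors(self):
        with pytest.raises(MeasurementError, match="no measurements"):
            summarize_spores([])

    def test_nonpositive_measurement_errors(self):
        with pytest.raises(MeasurementError, match="invalid"):
            SporeMeasurement(0.0, 6.0)
        with pytest.raises(MeasurementError, match="invalid"):
            SporeMeasurement(11.0, -1.0)

    @given(st.lists(st.tuples(st.floats(5, 20), st.floats(3, 10)),
                    min_size=2, max_size=40),
           st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariance(self, pairs, rnd):
        a = summarize_spores(spores(pairs))
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        b = summarize_spores(spores(shuffled))
        for f in ("mean_length", "median_width", "sd_q", "p5_length", "p95_q"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-9)

    @given(st.lists(st.tuples(st.floats(5, 20), st.floats(3, 10)),
                    min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_order_statistics_bounded_and_sd_zero_iff_constant(self, pairs):
        s = summarize_spores(spores(pairs))
        lengths = [l for l, _ in pairs]
        eps = 1e-9
        assert min(lengths) - eps <= s.p5_length <= s.median_length + eps
        assert s.median_length <= s.p95_length + eps
        assert s.p95_length <= max(lengths) + eps
        assert min(lengths) - eps <= s.mean_length <= max(lengths) + eps
        if len(pairs) > 1:
            assert (s.sd_length == 0) == (len(set(lengths)) == 1)

    def test_mu_recovered_within_four_sigma_over_seeds(self):
        # protocol-scale samples recover the generating mean within
        # 4*sigma/sqrt(n) in at least 99% of 200 seeded replicates
        mu, sd, n = 11.9, 0.84, 60
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            lengths = rng.normal(mu, sd, size=n)
            s = summarize_spores(spores([(l, 6.0) for l in lengths]))
            hits += abs(s.mean_length - mu) <= 4 * sd / np.sqrt(n)
        assert hits >= 198


class TestCystidiaSummary:
    def test_equal_widths_give_unit_ratios(self):
        s = summarize_cheilocystidia([CystidiumMeasurement(45, 7, 7, 7)])
        assert s.mean_ratio_am == s.mean_ratio_ab == s.mean_ratio_bm == 1.0

    def test_hand_arithmetic_oracle(self):
        s = summarize_cheilocystidia([CystidiumMeasurement(40, 8, 4, 4),
                                      CystidiumMeasurement(60, 6, 4, 8)])
        assert s.mean_ratio_am == pytest.approx(1.75)
        assert s.mean_ratio_ab == pytest.approx(1.375)
        assert s.mean_ratio_bm == pytest.approx(1.5)
        assert "n_full_below_protocol" in s.warnings

    def test_ratio_of_means_is_diagnostic_only(self):
        # aggregate means 7.4 (apex) / 5 (middle) give ratio-of-means 1.48,
        # which can fall outside a mean-of-ratios range; both are reported
        # but the keys only ever see the mean of per-cystidium ratios
        cyst = [CystidiumMeasurement(45, 9.4, 4, 6.5),
                CystidiumMeasurement(45, 5.4, 6, 6.5)]
        s = summarize_cheilocystidia(cyst)
        assert s.ratio_of_means_am == pytest.approx(s.mean_a / s.mean_m)
        assert s.mean_ratio_am == pytest.approx((9.4 / 4 + 5.4 / 6) / 2)

    def test_apex_widths_drive_mean_a(self):
        s = summarize_cheilocystidia([CystidiumMeasurement(45, 7, 5, 6)],
                                     apex_widths=[8.0, 9.0])
        assert s.mean_a == pytest.approx(8.5)
        assert s.n_apex_only == 2
        assert "n_apex_below_protocol" in s.warnings

    def test_empty_full_list_errors(self):
        with pytest.raises(MeasurementError):
            summarize_cheilocystidia([], apex_widths=[7.0])


class TestParseOPD:
    @pytest.mark.parametrize("code,orn,par", [
        ("O1O2", {"O1", "O2"}, set()),
        ("O1O2 (O3)", {"O1", "O2", "O3"}, {"O3"}),
        ("(O1) O2", {"O1", "O2"}, {"O1"}),
    ])
    def test_ornamentation_with_parenthetical_states(self, code, orn, par):
        c = parse_opd(code)
        assert c.ornamentation == orn
        assert {t for t in orn if c.is_parenthetical(t)} == par

    def test_dextrinoidity_rare_states(self):
        c = parse_opd("(D2) D3 (D4)")
        assert c.dextrinoidity == {"D2", "D3", "D4"}
        assert c.is_parenthetical("D2") and c.is_parenthetical("D4")
        assert c.has_many("D3") and not c.has_many("D2")

    def test_order_insensitive(self):
        assert parse_opd("O2O1").ornamentation == parse_opd("O1O2").ornamentation

    def test_mixed_dimensions(self):
        c = parse_opd("P0P1")
        assert c.perispore == {"P0", "P1"} and not c.ornamentation

    def test_empty_errors(self):
        with pytest.raises(MeasurementError, match="no classes"):
            parse_opd("")

    @pytest.mark.parametrize("bad", ["O9", "X1", "O1 Q2", "D"])
    def test_unknown_token_named(self, bad):
        with pytest.raises(MeasurementError, match="unknown token"):
            parse_opd(bad)
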