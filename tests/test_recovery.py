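"""Bit-score recovery statistics and the associated significance tests."""

import math

import numpy as np
import pytest

import polyspec as ps
from polyspec.constants import LOG2_20
from polyspec.recovery import RecoveryError


class TestProfile:
    def test_unanimous_column(self, ensemble_factory):
        ens = ensemble_factory((5,), ["S"] * 100)
        (p,) = ps.profile(ens)
        assert p.p("S") == 1.0 and p.n == 100

    def test_even_split(self, ensemble_factory):
        ens = ensemble_factory((5,), ["S"] * 50 + ["D"] * 50)
        (p,) = ps.profile(ens)
        assert p.p("S") == p.p("D") == 0.5
        assert p.frequencies.sum() == pytest.approx(1.0)

    def test_uniform_ensemble_near_background(self, ensemble_factory):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list(ps.AMINO_ACIDS), size=3)) for _ in range(4000)]
        ens = ensemble_factory((1, 2, 3), seqs)
        for p in ps.profile(ens):
            assert np.all(np.abs(p.frequencies - 0.05) < 0.02)


class TestSelfInformation:
    def test_certain_residue_gives_log2_20(self):
        assert ps.self_information(1.0) == pytest.approx(4.321928094887363, abs=1e-12)

    def test_background_probability_gives_zero(self):
        assert ps.self_information(0.05) == pytest.approx(0.0, abs=1e-12)

    def test_half_probability(self):
        assert ps.self_information(0.5) == pytest.approx(1.660964047443681, abs=1e-12)

    def test_zero_limit_convention(self):
        assert ps.self_information(0.0) == 0.0

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(RecoveryError):
            ps.self_information(bad)

    def test_formula_on_grid(self):
        for p in np.linspace(0.01, 1.0, 100):
            assert ps.self_information(p) == pytest.approx(
                p * math.log2(20 * p), abs=1e-12)


class TestRecovery:
    def test_perfect_recovery_normalizes_to_one(self, ensemble_factory):
        ens = ensemble_factory((1, 2), ["SD"] * 10)
        sc = ps.recovery(ps.profile(ens), "SD", "germline")
        assert sc.normalized == pytest.approx(1.0)

    def test_zero_recovery(self, ensemble_factory):
        ens = ensemble_factory((1, 2), ["SD"] * 10)
        sc = ps.recovery(ps.profile(ens), "AA", "germline")
        assert sc.normalized == 0.0

    def test_hand_computed_two_column_case(self, ensemble_factory):
        ens = ensemble_factory((1, 2), ["SD"] * 50 + ["SA"] * 50)
        sc = ps.recovery(ps.profile(ens), "SD", "germline")
        assert sc.total == pytest.approx(5.9828921423310435, abs=1e-9)
        assert sc.normalized == pytest.approx(0.6921554467100601, abs=1e-9)

    def test_negative_raw_clamped_but_reported(self, ensemble_factory):
        seqs = ["S"] * 2 + ["D"] * 98  # p(ref)=0.02 < background
        ens = ensemble_factory((1,), seqs)
        sc = ps.recovery(ps.profile(ens), "S", "germline")
        assert sc.per_column_raw[0] == pytest.approx(0.02 * math.log2(0.4))
        assert sc.per_column_bit[0] == 0.0

    def test_reference_gap_skips_column(self, ensemble_factory):
        ens = ensemble_factory((1, 2), ["SD"] * 10)
        sc = ps.recovery(ps.profile(ens), "S-", "germline")
        assert sc.skipped_columns == (2,)
        assert sc.normalized == pytest.approx(1.0)  # denominator reduced

    def test_invariant_under_trajectory_reordering(self, ensemble_factory):
        seqs = ["SD"] * 30 + ["TA"] * 70
        a = ps.recovery(ps.profile(ensemble_factory((1, 2), seqs)), "SD", "g")
        b = ps.recovery(ps.profile(ensemble_factory((1, 2), seqs[::-1])), "SD", "g")
        assert a.total == pytest.approx(b.total)

    def test_bounds_hold_for_random_ensembles(self, ensemble_factory):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seqs = ["".join(rng.choice(list(ps.AMINO_ACIDS), size=4))
                    for _ in range(30)]
            ens = ensemble_factory((1, 2, 3, 4), seqs)
            profs = ps.profile(ens)
            g = ps.recovery(profs, "ACDE", "germline")
            m = ps.recovery(profs, seqs[0], "mature")
            assert 0.0 <= g.normalized <= 1.0
            assert 0.0 <= m.normalized <= 1.0
            assert all(0.0 <= b <= LOG2_20 for b in g.per_column_bit)


class TestDeltaAndCorrelation:
    def test_delta_sign_convention(self, ensemble_factory):
        ens = ensemble_factory((1,), ["S"] * 10)
        profs = ps.profile(ens)
        mat = ps.recovery(profs, "S", "mature")
        germ = ps.recovery(profs, "D", "germline")
        assert ps.delta(mat, germ, "c1").value == pytest.approx(1.0)
        assert ps.delta(germ, germ, "c1").value == 0.0

    def test_perfect_linear_correlation(self):
        x = [4.0, 8.0, 12.0, 16.0]
        y = [0.1, 0.2, 0.3, 0.4]
        res = ps.maturation_correlation(y, x)
        assert res.r2 == pytest.approx(1.0)
        assert res.statistic > 0

    def test_permuted_pairing_destroys_correlation(self):
        rng = np.random.default_rng(2)
        x = np.arange(30.0)
        y = 0.01 * x
        rs = []
        for _ in range(50):
            perm = rng.permutation(len(y))
            rs.append(ps.maturation_correlation(y[perm], x).r2)
        assert np.mean(rs) < 0.15

    def test_zero_variance_rejected(self):
        with pytest.raises(RecoveryError):
            ps.maturation_correlation([0.1, 0.1, 0.1], [1.0, 2.0, 3.0])


class TestOccurrenceBins:
    def test_binning_rule(self):
        bits = {10: 1.0, 11: 2.0, 12: 3.0, 13: 4.0}
        interfaces = {f"c{i}": set() for i in range(8)}
        for i in range(3):  # column 11 interfacial in 3 of 8 complexes
            interfaces[f"c{i}"].add(11)
        for i in range(5):
            interfaces[f"c{i}"].add(12)
        interfaces["c0"].add(13)
        bins = {b.label: b for b in ps.bin_by_interface_occurrence(bits, interfaces)}
        assert bins["0"].columns == (10,)
        assert bins["1"].columns == (13,)
        assert bins["2-4"].columns == (11,)
        assert bins[">=5"].columns == (12,)
        assert bins["2-4"].mean == pytest.approx(2.0)
        assert bins["2-4"].sd is None  # single column

    def test_no_interfaces_puts_everything_in_bin_zero(self):
        bits = {1: 0.5, 2: 1.5}
        bins = {b.label: b for b in ps.bin_by_interface_occurrence(bits, {"c": set()})}
        assert bins["0"].columns == (1, 2)
        assert bins["1"].mean is None  # empty, not zero


class TestPairedTests:
    def test_constant_shift_exact_wilcoxon(self):
        rng = np.random.default_rng(3)
        b = rng.normal(size=10)
        res = ps.paired_tests(b + 5.0, b)
        assert res.wilcoxon.pvalue == pytest.approx(2 / 2**10)

    def test_identical_samples_flagged_degenerate(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = ps.paired_tests(a, a)
        assert res.wilcoxon.degenerate and res.wilcoxon.pvalue == 1.0

    def test_planted_effect_is_significant(self):
        rng = np.random.default_rng(4)
        b = rng.normal(size=12)
        a = b + 1.0 + 0.1 * rng.normal(size=12)
        res = ps.paired_tests(a, b)
        assert res.wilcoxon.pvalue < 0.01
        assert res.paired_t.pvalue < 0.01


def test_logo_counts_matrix(ensemble_factory):
    ens = ensemble_factory((1, 2), ["SD"] * 30 + ["SA"] * 70)
    df = ps.logo_counts(ps.profile(ens))
    assert df.loc[1, "S"] == 100
    assert df.loc[2, "D"] == 30 and df.loc[2, "A"] == 70
    assert df.to_numpy().sum() == 200
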