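"""Hypnogram/CAP parsing, binary indicators, avalanche density, phi
coefficients, occupancy, CAP metrics and group statistics."""

import numpy as np
import pandas as pd
import pytest

import sleepcrit as sc
from sleepcrit.coupling import (
    BinaryIndicator,
    CapAnnotation,
    Hypnogram,
    avalanche_density,
    build_indicators,
    cap_metrics,
    group_comparison,
    interval_jaccard,
    occupancy_fraction,
    phi_correlation,
    read_cap_annotations,
    read_hypnogram,
    stage_density_summary,
    write_cap_annotations,
    write_hypnogram,
)
from sleepcrit.detect import extract_avalanches
from sleepcrit.ingest import MultichannelRecording


def zrec(sig, fs=100.0, mask=None):
    rec = MultichannelRecording(np.asarray(sig, dtype=float), fs, mask=mask)
    rec.is_zscored = True
    return rec


def make_indicator(values, fs=100.0, retained=None, name="x"):
    values = np.asarray(values, dtype=bool)
    if retained is None:
        retained = np.ones_like(values)
    return BinaryIndicator(values, retained, name, fs)


class TestHypnogramIO:
    def test_duration(self):
        assert Hypnogram(["N2"] * 10).duration_s == 300.0

    def test_unknown_label_rejected(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("epoch_index\tstage\n0\tN2\n1\tN4\n")
        with pytest.raises(ValueError, match="N4"):
            read_hypnogram(str(p))

    def test_round_trip(self, tmp_path, coupled_surrogate):
        p = tmp_path / "h.tsv"
        write_hypnogram(coupled_surrogate["hyp"], str(p))
        back = read_hypnogram(str(p))
        assert back.epoch_stages == coupled_surrogate["hyp"].epoch_stages


class TestCapIO:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("onset_s,duration_s,label\n")
        assert read_cap_annotations(str(p)).phases == []

    def test_long_phase_warned_but_kept(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("onset_s,duration_s,label\n10,70,B\n")
        with pytest.warns(UserWarning, match="outside"):
            cap = read_cap_annotations(str(p))
        assert len(cap.phases) == 1

    def test_phase_outside_nrem_dropped(self, tmp_path):
        hyp = Hypnogram(["REM"] * 2 + ["N2"] * 2)
        p = tmp_path / "c.csv"
        p.write_text("onset_s,duration_s,label\n10,10,A1\n70,10,A1\n")
        with pytest.warns(UserWarning, match="outside NREM"):
            cap = read_cap_annotations(str(p), hyp)
        assert len(cap.phases) == 1 and cap.phases[0][0] == 70

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CapAnnotation([(0, 10, "A1"), (5, 10, "B")])

    def test_round_trip(self, tmp_path, coupled_surrogate):
        p = tmp_path / "c.csv"
        write_cap_annotations(coupled_surrogate["cap"], str(p))
        back = read_cap_annotations(str(p))
        assert np.allclose(
            [x[:2] for x in back.phases],
            [x[:2] for x in coupled_surrogate["cap"].phases],
        )


class TestIndicators:
    def _setup(self):
        hyp = Hypnogram(["W"] * 2 + ["N2"] * 10 + ["REM"] * 4)
        rec = zrec(np.zeros((1, 48000)), fs=100.0)
        return hyp, rec

    def test_stage_partition(self):
        hyp, rec = self._setup()
        ind = build_indicators(None, hyp, None, rec)
        total = np.zeros(rec.n_samples, dtype=int)
        for stage in ("W", "N1", "N2", "N3", "REM"):
            total += ind[stage].values.astype(int)
        assert np.array_equal(total, rec.mask.astype(int))

    def test_a_is_union_of_subtypes(self, coupled_surrogate,
                                    detected_surrogate):
        ind = build_indicators(
            detected_surrogate["catalog"], coupled_surrogate["hyp"],
            coupled_surrogate["cap"], detected_surrogate["z"],
        )
        union = ind["A1"].values | ind["A2"].values | ind["A3"].values
        assert np.array_equal(ind["A"].values, union)

    def test_toy_cap_sequence_rule(self):
        # one A1 (10 s) + one B (20 s) inside a 300-s N2 block: a single
        # cycle, so with min_cycles=2 everything is NCAP; with min_cycles=1
        # the CAP sequence spans 30 s and NCAP gets the remaining 270 s.
        hyp = Hypnogram(["N2"] * 10)
        rec = zrec(np.zeros((1, 30000)), fs=100.0)
        phases = [(100.0, 10.0, "A1"), (110.0, 20.0, "B")]
        ind2 = build_indicators(None, hyp, CapAnnotation(phases), rec)
        assert ind2["CAP"].values.sum() == 0
        assert ind2["NCAP"].values.sum() == 30000
        ind1 = build_indicators(
            None, hyp, CapAnnotation(phases, min_cycles=1), rec
        )
        assert ind1["CAP"].values.sum() == 3000  # 30 s at 100 Hz
        assert ind1["NCAP"].values.sum() == 27000

    def test_recording_shorter_than_hypnogram_rejected(self):
        hyp = Hypnogram(["N2"] * 10)
        rec = zrec(np.zeros((1, 1000)), fs=100.0)
        with pytest.raises(ValueError):
            build_indicators(None, hyp, None, rec)


class TestDensity:
    def _catalog(self, sig, fs=100.0):
        rec = zrec(sig, fs=fs)
        return extract_avalanches(sc.detect_excursions(rec), rec), rec

    def test_empty_catalog_zero_density(self):
        cat, rec = self._catalog(np.zeros((1, 5000)))
        d = avalanche_density(cat, rec, u0=10.0, stride=1.0)
        assert np.all(d.Fav == 0)
        assert np.all(d.Nav == 0)

    def test_saturated_window(self):
        sig = np.zeros((1, 5000))
        sig[0, 1000:4000] = 3.0
        cat, rec = self._catalog(sig)
        d = avalanche_density(cat, rec, u0=10.0, stride=1.0)
        assert d.Fav.max() == pytest.approx(1.0)

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(17)
        sig = rng.standard_normal((2, 4000)) * 1.8
        cat, rec = self._catalog(sig)
        u0, stride = 2.0, 0.37
        d = avalanche_density(cat, rec, u0=u0, stride=stride)
        in_av = np.zeros(4000)
        onsets = []
        for a in cat.avalanches:
            in_av[a.onset_sample : a.offset_sample] = 1
            onsets.append((a.onset_sample, a.duration))
        w = int(u0 * 100)
        step = int(round(stride * 100))
        for j, start in enumerate(range(0, 4000 - w + 1, step)):
            assert d.Fav[j] == pytest.approx(in_av[start : start + w].mean())
            n_on = sum(1 for o, _ in onsets if start <= o < start + w)
            assert d.Nav[j] == n_on

    def test_conservation_over_tiling_windows(self):
        rng = np.random.default_rng(23)
        sig = rng.standard_normal((2, 40_000)) * 1.8
        cat, rec = self._catalog(sig)
        u0 = 4.0
        d = avalanche_density(cat, rec, u0=u0, stride=u0)  # non-overlapping
        total_from_density = d.Fav.sum() * u0
        assert total_from_density == pytest.approx(
            cat.total_avalanche_time, abs=u0
        )

    def test_masked_windows_invalid(self):
        sig = np.zeros((1, 5000))
        rec = zrec(sig)
        rec.mask[2000:2100] = False
        cat = extract_avalanches(sc.detect_excursions(rec), rec)
        d = avalanche_density(cat, rec, u0=5.0, stride=1.0)
        assert not d.valid.all() and d.valid.any()
        bad_centers = d.t[~d.valid]
        assert bad_centers.min() > 20.0 - 5.0 and bad_centers.max() < 21.0 + 5.0

    def test_too_short_window_rejected(self):
        cat, rec = self._catalog(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            avalanche_density(cat, rec, u0=0.005)


class TestStageDensitySummary:
    def test_constructed_stage_means(self):
        hyp = Hypnogram(["N3"] * 4 + ["N2"] * 4 + ["N3"] * 4)
        sig = np.zeros((1, 36000))
        # dense avalanches in N3 epochs, sparse in N2
        for start in range(0, 12000, 100):
            sig[0, start : start + 80] = 3.0
        for start in range(24000, 36000, 100):
            sig[0, start : start + 80] = 3.0
        for start in range(12000, 24000, 100):
            sig[0, start : start + 20] = 3.0
        rec = zrec(sig)
        cat = extract_avalanches(sc.detect_excursions(rec), rec)
        d = avalanche_density(cat, rec, u0=10.0, stride=1.0)
        rep = stage_density_summary(d, hyp)
        assert rep["stage_means"]["N3"] == pytest.approx(0.8, abs=0.05)
        assert rep["stage_means"]["N2"] == pytest.approx(0.2, abs=0.05)
        cmp_ = rep["first_vs_last_N3"]
        assert cmp_ is not None and np.isfinite(cmp_["t"])

    def test_no_n3_missing(self):
        hyp = Hypnogram(["N2"] * 12)
        rec = zrec(np.zeros((1, 36000)))
        cat = extract_avalanches(sc.detect_excursions(rec), rec)
        d = avalanche_density(cat, rec, u0=10.0, stride=1.0)
        rep = stage_density_summary(d, hyp)
        assert np.isnan(rep["stage_means"]["N3"])
        assert rep["first_vs_last_N3"] is None


class TestPhi:
    def test_identity_and_complement(self):
        rng = np.random.default_rng(1)
        x = make_indicator(rng.random(1000) > 0.7)
        y = make_indicator(~x.values, name="y")
        assert phi_correlation(x, x) == pytest.approx(1.0)
        assert phi_correlation(x, y) == pytest.approx(-1.0)

    def test_contingency_closed_form(self):
        # n11=40, n10=10, n01=10, n00=40 -> phi = 0.6
        x = make_indicator([1] * 50 + [0] * 50)
        y = make_indicator([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40, name="y")
        phi = phi_correlation(x, y)
        n11, n10, n01, n00 = 40, 10, 10, 40
        closed = (n11 * n00 - n10 * n01) / np.sqrt(
            (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
        )
        assert phi == pytest.approx(closed) == pytest.approx(0.6)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x = make_indicator(rng.random(500) > 0.5)
        y = make_indicator(rng.random(500) > 0.3, name="y")
        assert phi_correlation(x, y) == pytest.approx(phi_correlation(y, x))

    def test_constant_rejected(self):
        x = make_indicator(np.ones(100))
        y = make_indicator(np.arange(100) < 50, name="y")
        with pytest.raises(ValueError):
            phi_correlation(x, y)


class TestOccupancy:
    def test_identical_and_disjoint(self):
        a = make_indicator([1] * 50 + [0] * 50)
        b = make_indicator([0] * 50 + [1] * 50, name="b")
        assert occupancy_fraction(a, a) == 1.0
        assert occupancy_fraction(a, b) == 0.0

    def test_fraction_arithmetic(self):
        b = make_indicator([1] * 100 + [0] * 100, name="b")
        a = make_indicator([1] * 42 + [0] * 158)
        assert occupancy_fraction(a, b) == pytest.approx(0.42)

    def test_empty_reference_rejected(self):
        a = make_indicator(np.ones(10))
        b = make_indicator(np.zeros(10), name="b")
        with pytest.raises(ValueError):
            occupancy_fraction(a, b)


class TestIntervalJaccard:
    def test_perfect_and_partial(self):
        truth = np.array([[0.0, 1.0], [5.0, 6.0]])
        assert interval_jaccard(truth, [(0, 1), (5, 6)]) == pytest.approx(1.0)
        assert interval_jaccard(truth, [(0, 1)]) == pytest.approx(0.5)
        # unmatched detections are excluded from the union
        assert interval_jaccard(truth, [(0, 1), (5, 6), (20, 30)]) == 1.0
        # boundary smearing is penalized
        assert interval_jaccard(truth, [(0, 2), (5, 6)]) == pytest.approx(2 / 3)


class TestCapMetrics:
    def test_no_cap_zero_rate(self):
        hyp = Hypnogram(["N2"] * 10)
        m = cap_metrics(CapAnnotation([]), hyp)
        assert m["cap_rate"] == 0.0

    def test_toy_rate(self):
        hyp = Hypnogram(["N2"] * 10)  # 300 s NREM
        phases = []
        t = 0.0
        while t < 150.0:  # 5 cycles of A1(10)+B(20) = 150 s CAP
            phases.append((t, 10.0, "A1"))
            phases.append((t + 10.0, 20.0, "B"))
            t += 30.0
        m = cap_metrics(CapAnnotation(phases), hyp)
        assert m["cap_rate"] == pytest.approx(0.5)
        assert m["n_cycles"] == 5

    def test_generator_hits_rate_target(self):
        arch = sc.ArchitectureConfig(n_cycles=12, seed=31)
        hyp = sc.simulate_hypnogram(arch)
        cap = sc.simulate_cap_annotations(hyp, arch)
        m = cap_metrics(cap, hyp)
        # stage-weighted target of the per-stage rates is ~0.49
        assert abs(m["cap_rate"] - 0.49) < 0.05

    def test_no_nrem_rejected(self):
        with pytest.raises(ValueError):
            cap_metrics(CapAnnotation([]), Hypnogram(["REM"] * 5))


class TestGroupComparison:
    def test_hand_computed_anova(self):
        rep = group_comparison([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        # SSB = 6 (df 2), SSW = 6 (df 6) -> F = 3 / 1 = 3
        assert rep["test"] == "one-way ANOVA"
        assert rep["statistic"] == pytest.approx(3.0)

    def test_identical_groups(self):
        rep = group_comparison([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert rep["statistic"] == pytest.approx(0.0)
        assert rep["p"] == pytest.approx(1.0)

    def test_kruskal_matches_rank_formula(self):
        # force the nonparametric branch with a clearly non-normal group
        g1, g2 = [1, 1, 1, 1, 1, 1, 1, 8], [4, 5, 6, 7, 9, 10, 11, 12]
        rep = group_comparison([g1, g2])
        assert rep["test"] == "Kruskal-Wallis"
        from scipy.stats import kruskal

        assert rep["statistic"] == pytest.approx(kruskal(g1, g2).statistic)

    def test_paired_two_groups(self):
        rep = group_comparison([[1, 2, 3, 4], [2, 3, 4, 6]], paired=True)
        assert rep["test"] == "paired t"
        assert rep["p"] < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparison([[1, 2], [3, 4]])
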