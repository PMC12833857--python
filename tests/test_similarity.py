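"""Similarity metrics, Kuhn-Munkres barcodes and candidate ranking."""

import itertools
import math

import numpy as np
import pytest

from vibmatch.errors import ValidationError, VibmatchError
from vibmatch.preprocess import lorentzian_convolve, normalize_intensities
from vibmatch.records import ModeClass, Peak, Scheme, SpectrumRecord
from vibmatch.scaling import ScalingFactorSet
from vibmatch.similarity import (
    Barcode,
    MatchConfig,
    average_distance,
    cost_matrix,
    cross_correlate,
    distance_uncertainty,
    kuhn_munkres,
    ot_distance,
    rank_candidates,
)


def record(peaks, source="experimental", conformer="", mode_classes=None):
    meta = {"mode_classes": mode_classes} if mode_classes else {}
    return SpectrumRecord(
        species="s", conformer=conformer, source=source,
        peaks=tuple(Peak(f, i) for f, i in peaks), metadata=meta,
    )


def convolved(peaks, **kwargs):
    kwargs.setdefault("grid_start", 400.0)
    kwargs.setdefault("grid_end", 2000.0)
    return lorentzian_convolve(record(peaks), **kwargs)


def brute_force_assignment(entries):
    """Oracle: minimal total cost over all injections of rows into columns."""
    m, c = entries.shape
    best = math.inf
    for cols in itertools.permutations(range(c), m):
        best = min(best, sum(entries[i, j] for i, j in enumerate(cols)))
    return best


class TestCrossCorrelate:
    def test_self_correlation_is_one_at_zero_lag(self):
        spec = convolved([(800.0, 1.0), (1200.0, 0.5)])
        score = cross_correlate(spec, spec, max_lag=10.0)
        assert score.score == pytest.approx(1.0)
        assert score.lag == 0.0

    def test_shifted_copy_recovered_at_matching_lag(self):
        from vibmatch.preprocess import ContinuousSpectrum

        base = convolved([(800.0, 1.0), (1200.0, 0.5), (1600.0, 0.8)])
        # exact translation: same values, grid origin moved +5 cm-1
        translated = ContinuousSpectrum(base.grid_start + 5.0, base.grid_step,
                                        base.values)
        score = cross_correlate(base, translated, max_lag=10.0)
        # zero-padding at the displaced edges costs a sliver of overlap
        assert score.score == pytest.approx(1.0, abs=1e-3)
        # calculated spectrum sits 5 cm-1 too high; it must move down
        assert score.lag == -5.0

    def test_reconvolved_shift_recovered(self):
        base = [(800.0, 1.0), (1200.0, 0.5), (1600.0, 0.8)]
        shifted = [(f + 5.0, i) for f, i in base]
        score = cross_correlate(convolved(base), convolved(shifted), max_lag=10.0)
        # edge truncation of the Lorentzian wings costs a little overlap
        assert score.score == pytest.approx(1.0, abs=1e-3)
        assert score.lag == -5.0

    def test_disjoint_peaks_near_zero(self):
        a = convolved([(600.0, 1.0)])
        b = convolved([(1800.0, 1.0)])
        score = cross_correlate(a, b, max_lag=20.0)
        assert abs(score.score) < 0.05

    def test_flat_spectrum_errors(self):
        flat = convolved([])
        peaky = convolved([(800.0, 1.0)])
        with pytest.raises(VibmatchError):
            cross_correlate(peaky, flat)

    def test_mismatched_grid_step_errors(self):
        a = convolved([(800.0, 1.0)], grid_step=1.0)
        b = convolved([(800.0, 1.0)], grid_step=2.0)
        with pytest.raises(ValidationError):
            cross_correlate(a, b)


class TestCostMatrix:
    def test_identical_lists_zero_diagonal(self):
        rec = record([(800.0, 1.0), (1200.0, 0.4)])
        for metric in ("euclid_1d", "euclid_2d", "manhattan_2d"):
            cm = cost_matrix(rec, rec, metric)
            assert np.diag(cm.entries) == pytest.approx([0.0, 0.0])

    def test_hand_arithmetic(self):
        meas = record([(1000.0, 1.0)])
        calc = record([(600.0, 1.0), (1003.0, 0.5)])
        e2 = cost_matrix(meas, calc, "euclid_2d", weight=10.0)
        m2 = cost_matrix(meas, calc, "manhattan_2d", weight=10.0)
        assert e2.entries[0, 1] == pytest.approx(math.sqrt(9 + 25))
        assert m2.entries[0, 1] == pytest.approx(3 + 5)

    def test_metric_ordering_entrywise(self):
        rng = np.random.default_rng(5)
        meas = record([(f, i) for f, i in
                       zip(rng.uniform(500, 1900, 6), rng.uniform(0.1, 1.0, 6))])
        calc = record([(f, i) for f, i in
                       zip(rng.uniform(500, 1900, 9), rng.uniform(0.1, 1.0, 9))])
        meas, calc = normalize_intensities(meas), normalize_intensities(calc)
        e1 = cost_matrix(meas, calc, "euclid_1d", 10.0).entries
        e2 = cost_matrix(meas, calc, "euclid_2d", 10.0).entries
        m2 = cost_matrix(meas, calc, "manhattan_2d", 10.0).entries
        assert np.all(m2 >= e2 - 1e-12)
        assert np.all(e2 >= e1 - 1e-12)

    def test_unnormalized_rejected(self):
        meas = record([(1000.0, 2.0)])
        calc = record([(1000.0, 1.0)])
        with pytest.raises(ValidationError, match="normalized"):
            cost_matrix(meas, calc, "euclid_2d")


class TestKuhnMunkres:
    def test_identity_like_matrix(self):
        entries = np.ones((3, 3)) - np.eye(3)
        barcode = kuhn_munkres(_as_cost_matrix(entries))
        assert [(i, j) for i, j, _ in barcode.pairs] == [(0, 0), (1, 1), (2, 2)]
        assert barcode.total_cost == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            m = int(rng.integers(1, 5))
            c = int(rng.integers(m, 7))
            entries = rng.integers(0, 50, size=(m, c)).astype(float)
            barcode = kuhn_munkres(_as_cost_matrix(entries))
            assert barcode.total_cost == pytest.approx(
                brute_force_assignment(entries)
            )

    def test_rectangular_leaves_surplus_unmatched(self):
        entries = np.array([[1.0, 0.0, 9.0, 9.0]])
        barcode = kuhn_munkres(_as_cost_matrix(entries))
        assert barcode.pairs == ((0, 1, 0.0),)
        assert set(barcode.unmatched_calc) == {0, 2, 3}

    def test_more_measured_than_calc_transposes(self):
        entries = np.array([[0.0], [5.0]])
        barcode = kuhn_munkres(_as_cost_matrix(entries))
        assert barcode.transposed
        assert len(barcode.pairs) == 1

    def test_intensity_disambiguates_assignment(self):
        """2-D metric picks the intensity-consistent peak, 1-D the nearest.

        A strong measured band flanked by a near calculated peak of very
        different intensity and a slightly farther one of matching
        intensity: frequency-only assignment takes the near peak, the
        joint (frequency, weighted intensity) cost takes the consistent
        one.  Verified against exhaustive enumeration.
        """
        meas = record([(1000.0, 1.0), (1040.0, 0.2)])
        calc = record([(1003.0, 0.15), (1008.0, 1.0), (1041.0, 0.2)])
        b1 = kuhn_munkres(cost_matrix(meas, calc, "euclid_1d", 10.0))
        b2 = kuhn_munkres(cost_matrix(meas, calc, "euclid_2d", 10.0))
        assign1 = {i: j for i, j, _ in b1.pairs}
        assign2 = {i: j for i, j, _ in b2.pairs}
        assert assign1[0] == 0  # nearest in frequency
        assert assign2[0] == 1  # consistent in intensity
        for metric, barcode in (("euclid_1d", b1), ("euclid_2d", b2)):
            entries = cost_matrix(meas, calc, metric, 10.0).entries
            assert barcode.total_cost == pytest.approx(
                brute_force_assignment(entries)
            )

    def test_beats_greedy_nearest_neighbor(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            entries = rng.uniform(0, 30, size=(5, 7))
            barcode = kuhn_munkres(_as_cost_matrix(entries))
            greedy_total, used = 0.0, set()
            for i in range(5):
                j = min((j for j in range(7) if j not in used),
                        key=lambda j: entries[i, j])
                used.add(j)
                greedy_total += entries[i, j]
            assert barcode.total_cost <= greedy_total + 1e-12

    def test_empty_matrix_errors(self):
        with pytest.raises(ValidationError):
            kuhn_munkres(_as_cost_matrix(np.empty((0, 0))))


def _as_cost_matrix(entries):
    from vibmatch.similarity import CostMatrix

    entries = np.asarray(entries, dtype=float)
    return CostMatrix(entries=entries, metric="euclid_1d", weight=0.0,
                      dnu=entries.copy(), dintensity=np.zeros_like(entries))


class TestAverageDistance:
    def test_simple_mean(self):
        barcode = Barcode(pairs=((0, 0, 2.0), (1, 1, 4.0)), total_cost=6.0,
                          unmatched_calc=(), metric="euclid_1d", weight=0.0)
        assert average_distance(barcode) == pytest.approx(3.0)

    def test_self_match_zero(self):
        rec = normalize_intensities(record([(800.0, 1.0), (900.0, 0.5)]))
        barcode = kuhn_munkres(cost_matrix(rec, rec, "euclid_2d"))
        assert average_distance(barcode) == 0.0

    def test_duplication_invariance(self):
        """Repeating the pair structure leaves the average unchanged."""
        rec = normalize_intensities(record([(800.0, 1.0), (950.0, 0.5)]))
        calc = normalize_intensities(record([(803.0, 1.0), (953.0, 0.5)]))
        one = average_distance(kuhn_munkres(cost_matrix(rec, calc, "euclid_1d")))
        rec2 = normalize_intensities(
            record([(800.0, 1.0), (950.0, 0.5), (1800.0, 1.0), (1950.0, 0.5)])
        )
        calc2 = normalize_intensities(
            record([(803.0, 1.0), (953.0, 0.5), (1803.0, 1.0), (1953.0, 0.5)])
        )
        two = average_distance(kuhn_munkres(cost_matrix(rec2, calc2, "euclid_1d")))
        assert two == pytest.approx(one)


def lp_transport(freq_a, mass_a, freq_b, mass_b):
    """Independent LP oracle for the 1-D transport problem."""
    from scipy.optimize import linprog

    mass_a = np.asarray(mass_a) / np.sum(mass_a)
    mass_b = np.asarray(mass_b) / np.sum(mass_b)
    na, nb = len(freq_a), len(freq_b)
    cost = np.abs(np.subtract.outer(freq_a, freq_b)).ravel()
    a_eq = []
    for i in range(na):
        row = np.zeros((na, nb))
        row[i, :] = 1.0
        a_eq.append(row.ravel())
    for j in range(nb):
        row = np.zeros((na, nb))
        row[:, j] = 1.0
        a_eq.append(row.ravel())
    b_eq = np.concatenate([mass_a, mass_b])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, method="highs")
    assert res.success
    return res.fun


class TestOptimalTransport:
    def test_identical_distributions_zero(self):
        rec = record([(800.0, 1.0), (1200.0, 0.3)])
        assert ot_distance(rec, rec) == 0.0

    def test_two_unit_peaks_closed_form(self):
        a = record([(1000.0, 1.0)])
        b = record([(1010.0, 1.0)])
        assert ot_distance(a, b) == pytest.approx(10.0)

    def test_matches_lp_oracle(self):
        a = record([(700.0, 1.0), (1000.0, 2.0), (1500.0, 0.5)])
        b = record([(800.0, 1.5), (1400.0, 1.0)])
        expected = lp_transport(
            [700.0, 1000.0, 1500.0], [1.0, 2.0, 0.5],
            [800.0, 1400.0], [1.5, 1.0],
        )
        assert ot_distance(a, b) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        recs = [
            record([(f, i) for f, i in
                    zip(rng.uniform(500, 1900, 4), rng.uniform(0.2, 1.0, 4))])
            for _ in range(3)
        ]
        d01 = ot_distance(recs[0], recs[1])
        d10 = ot_distance(recs[1], recs[0])
        d12 = ot_distance(recs[1], recs[2])
        d02 = ot_distance(recs[0], recs[2])
        assert d01 == pytest.approx(d10)
        assert d02 <= d01 + d12 + 1e-9

    def test_zero_mass_errors(self):
        a = record([(800.0, 0.0)])
        b = record([(900.0, 1.0)])
        with pytest.raises(ValidationError):
            ot_distance(a, b)


def _unit_factor_set():
    classes = (ModeClass.OH, ModeClass.NH, ModeClass.CH_RING,
               ModeClass.CH_ETHYL, ModeClass.MID, ModeClass.LOW)
    return ScalingFactorSet(
        scheme=Scheme.MODE_DEPENDENT, theory=None,
        factors={c: (0.95, 0.0, 2) for c in classes},
    )


class TestRankCandidates:
    CONFIG = MatchConfig(grid_start=400.0, grid_end=2400.0)

    def test_exact_copy_wins_all_methods(self):
        meas = record([(950.0, 1.0), (1425.0, 0.5), (1900.0, 0.8)])
        # candidate whose 0.95-scaled spectrum reproduces the measurement
        copy = record([(1000.0, 1.0), (1500.0, 0.5), (2000.0, 0.8)],
                      source="computed", conformer="copy",
                      mode_classes=("mid", "mid", "CH_ethyl"))
        shifted = record([(1031.6, 1.0), (1531.6, 0.5), (2031.6, 0.8)],
                         source="computed", conformer="shifted",
                         mode_classes=("mid", "mid", "CH_ethyl"))
        result = rank_candidates(meas, [copy, shifted], _unit_factor_set(),
                                 self.CONFIG)
        for method in result.METHODS:
            assert result.best(method) == "copy", method

    def test_candidate_order_invariance(self):
        meas = record([(950.0, 1.0), (1425.0, 0.5)])
        cands = [
            record([(1000.0, 1.0), (1500.0, 0.5)], source="computed",
                   conformer="good", mode_classes=("mid", "mid")),
            record([(1020.0, 1.0), (1520.0, 0.5)], source="computed",
                   conformer="off", mode_classes=("mid", "mid")),
        ]
        fwd = rank_candidates(meas, cands, _unit_factor_set(), self.CONFIG)
        rev = rank_candidates(meas, cands[::-1], _unit_factor_set(), self.CONFIG)
        for method in fwd.METHODS:
            assert fwd.best(method) == rev.best(method)

    def test_failed_candidate_still_ranks_others(self):
        meas = record([(950.0, 1.0), (1425.0, 0.5)])
        good = record([(1000.0, 1.0), (1500.0, 0.5)], source="computed",
                      conformer="good", mode_classes=("mid", "mid"))
        # 2500 cm-1 with no stretch label cannot be classified -> fails
        bad = record([(2500.0, 1.0)], source="computed", conformer="bad")
        result = rank_candidates(meas, [bad, good], _unit_factor_set(),
                                 self.CONFIG)
        by_label = {c.label: c for c in result.candidates}
        assert by_label["bad"].failed
        assert by_label["good"].ranks["avg_euclid"] == 1

    def test_intensity_redistribution_fools_ot_only(self):
        """Adversary: intensity shuffled between adjacent peaks.

        The true candidate reproduces intensities but each scaled peak
        lands ~1.5 cm-1 off.  The adversary nails every frequency while
        trading intensity between two peaks only 2 cm-1 apart — cheap
        for transport, expensive for the per-feature metrics.
        """
        base = [(1000.0, 1.0), (1300.0, 0.7), (1308.0, 0.4),
                (1600.0, 0.9), (1900.0, 0.5)]
        meas = record(base)
        truth_peaks = [(f + 1.5, i) for f, i in base]
        adversary_peaks = [(1000.0, 1.0), (1300.0, 0.25), (1308.0, 0.85),
                           (1600.0, 0.9), (1900.0, 0.5)]
        unit = ScalingFactorSet(scheme=Scheme.GLOBAL, theory=None,
                                factors={ModeClass.GLOBAL: (1.0, 0.0, 2)})
        truth = record(truth_peaks, source="computed", conformer="truth")
        adversary = record(adversary_peaks, source="computed", conformer="adv")
        result = rank_candidates(meas, [truth, adversary], unit, self.CONFIG)
        assert result.best("ot_dist") == "adv"
        assert result.best("avg_euclid") == "truth"
        assert result.best("avg_manhattan") == "truth"


class TestDistanceUncertainty:
    def test_zero_sigmas_zero(self):
        barcode = Barcode(pairs=((0, 0, 3.0),), total_cost=3.0,
                          unmatched_calc=(), metric="euclid_1d", weight=10.0,
                          pair_dnu=(3.0,), pair_dintensity=(0.0,))
        assert distance_uncertainty(barcode, 0.0, 0.0) == 0.0

    def test_single_pair_closed_form(self):
        barcode = Barcode(pairs=((0, 0, 3.0),), total_cost=3.0,
                          unmatched_calc=(), metric="euclid_1d", weight=10.0,
                          pair_dnu=(3.0,), pair_dintensity=(0.0,))
        sigma = 0.4
        assert distance_uncertainty(barcode, sigma) == pytest.approx(
            sigma * math.sqrt(2)
        )

    @pytest.mark.parametrize("metric", ["euclid_1d", "euclid_2d", "manhattan_2d"])
    def test_agrees_with_monte_carlo(self, metric):
        rng = np.random.default_rng(31)
        nu_m = np.array([800.0, 1200.0, 1600.0])
        nu_c = nu_m + np.array([4.0, -6.0, 5.0])
        # both already normalized (max intensity exactly 1)
        i_m = np.array([1.0, 0.5, 0.8])
        i_c = np.array([0.85, 0.3, 1.0])
        w, sf, si = 10.0, 0.5, 0.03

        meas = record(list(zip(nu_m, i_m)))
        calc = record(list(zip(nu_c, i_c)))
        barcode = kuhn_munkres(cost_matrix(meas, calc, metric, w))
        predicted = distance_uncertainty(barcode, sf, si)

        draws = []
        for _ in range(10_000):
            dm = nu_m + rng.normal(0, sf, 3)
            dc = nu_c + rng.normal(0, sf, 3)
            jm = i_m + rng.normal(0, si, 3)
            jc = i_c + rng.normal(0, si, 3)
            dnu = dm - dc
            di = jm - jc
            if metric == "euclid_1d":
                cost = np.abs(dnu)
            elif metric == "euclid_2d":
                cost = np.sqrt(dnu**2 + w**2 * di**2)
            else:
                cost = np.abs(dnu) + w * np.abs(di)
            draws.append(cost.mean())
        mc = float(np.std(draws, ddof=1))
        assert predicted == pytest.approx(mc, rel=0.10)

    def test_negative_sigma_rejected(self):
        barcode = Barcode(pairs=((0, 0, 3.0),), total_cost=3.0,
                          unmatched_calc=(), metric="euclid_1d", weight=10.0,
                          pair_dnu=(3.0,), pair_dintensity=(0.0,))
        with pytest.raises(ValidationError):
            distance_uncertainty(barcode, -1.0)
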