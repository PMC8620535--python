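"""Region decomposition, peak picking, matching and assignment tables."""

import itertools

import numpy as np
import pytest

from vibspec import (
    BandFeature,
    LineShapeParams,
    Spectrum,
    Transition,
    TransitionClass,
    TransitionLedger,
    assignment_table,
    format_assignment_table,
    integrate_class_fractions,
    intensity_label,
    match_peaks,
    pick_peaks,
)
from vibspec.lineshape import band_profile, synthesize_spectrum
from vibspec import datasets


def _ledger(entries):
    return TransitionLedger(
        [Transition(position=p, intensity=i, transition_class=TransitionClass(c))
         for p, i, c in entries]
    )


# --------------------------------------------------------------------------
# Region decomposition
# --------------------------------------------------------------------------


def test_single_fundamental_fraction_one(mir_lineshape):
    ledger = _ledger([(1500.0, 3.0, "fundamental")])
    report = integrate_class_fractions(ledger, mir_lineshape, (1000.0, 2000.0))
    assert report.fraction("fundamental") == pytest.approx(1.0, abs=1e-9)
    assert report.defined


def test_equal_bands_split_half(mir_lineshape):
    ledger = _ledger([(1400.0, 2.0, "fundamental"), (1600.0, 2.0, "binary_combination")])
    report = integrate_class_fractions(ledger, mir_lineshape, (1000.0, 2000.0))
    assert report.fraction("fundamental") == pytest.approx(0.5, abs=1e-6)
    assert report.fraction("binary_combination") == pytest.approx(0.5, abs=1e-6)


def test_fractions_sum_to_one_and_match_intensity_sums(rng):
    """Broadened fractions equal intensity-sum ratios for enclosed bands."""
    classes = ["fundamental", "first_overtone", "binary_combination"]
    entries = [
        (float(rng.uniform(1200, 2800)), float(rng.uniform(0.5, 20.0)), classes[int(rng.integers(3))])
        for _ in range(25)
    ]
    ledger = _ledger(entries)
    sums = {c: sum(i for _, i, cc in entries if cc == c) for c in classes}
    total = sum(sums.values())
    for fwhm in (4.0, 8.0, 16.0):
        params = LineShapeParams(fwhm, fwhm, "area-proportional")
        report = integrate_class_fractions(ledger, params, (200.0, 3800.0))
        assert sum(report.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        for c in classes:
            assert report.fraction(c) == pytest.approx(sums[c] / total, abs=1e-6)


def test_empty_region_flagged(mir_lineshape):
    ledger = _ledger([(3000.0, 1.0, "fundamental")])
    report = integrate_class_fractions(ledger, mir_lineshape, (5000.0, 6000.0))
    assert not report.defined
    assert report.total_integral == 0.0
    with pytest.raises(ValueError, match="undefined"):
        report.fraction("fundamental")


def test_published_ch_region_fundamental_share(mir_lineshape):
    """Flagged fundamental rows carry 237.4 of the table's 518.6 total."""
    ledger = datasets.table_ledger("ch_region")
    report = integrate_class_fractions(ledger, mir_lineshape, (2600.0, 3600.0))
    assert report.fraction("fundamental") == pytest.approx(237.4 / 518.6, abs=1e-6)
    by_sum = integrate_class_fractions(ledger, mir_lineshape, (2600.0, 3600.0), method="sum")
    assert by_sum.fraction("fundamental") == pytest.approx(237.4 / 518.6, abs=1e-9)


# --------------------------------------------------------------------------
# Peak picking
# --------------------------------------------------------------------------


def test_single_band_peak_position(mir_lineshape):
    grid = np.arange(1300.0, 1700.0, 1.0)
    y = band_profile(1500.3, 2.0, mir_lineshape, grid)
    peaks = pick_peaks(Spectrum(grid, y), min_prominence=0.01 * y.max())
    assert len(peaks) == 1
    assert peaks[0].position == pytest.approx(1500.3, abs=0.5)


def test_flat_spectrum_yields_no_peaks():
    grid = np.arange(400.0, 1000.0, 1.0)
    assert pick_peaks(Spectrum(grid, np.ones_like(grid)), min_prominence=0.1) == []


def test_resolved_doublet_gives_two_peaks(mir_lineshape):
    grid = np.arange(1300.0, 1800.0, 1.0)
    y = (band_profile(1500.0, 2.0, mir_lineshape, grid)
         + band_profile(1550.0, 2.0, mir_lineshape, grid))
    peaks = pick_peaks(Spectrum(grid, y), min_prominence=0.1 * y.max(), min_separation=20.0)
    assert len(peaks) == 2
    assert peaks[0].position == pytest.approx(1500.0, abs=1.0)
    assert peaks[1].position == pytest.approx(1550.0, abs=1.0)


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------


def test_greedy_match_single_pair_within_tolerance():
    result = match_peaks([3310.0], [3360.0], tolerance=60.0)
    assert len(result.records) == 1
    assert result.records[0].difference == pytest.approx(-50.0)


def test_exact_position_match_gives_zero_difference():
    result = match_peaks([1500.0], [1500.0], tolerance=10.0)
    assert result.records[0].difference == 0.0


def test_out_of_tolerance_reported_unmatched():
    result = match_peaks([1000.0], [1100.0], tolerance=60.0)
    assert result.records == []
    assert result.unmatched_exp == [1000.0]
    assert result.unmatched_calc == [1100.0]


def test_matching_invariant_under_input_permutation(rng):
    exp = list(rng.uniform(1000, 2000, 8))
    calc = list(rng.uniform(1000, 2000, 8))
    base = match_peaks(exp, calc, tolerance=80.0, strategy="greedy")
    base_set = {(r.exp_position, r.calc_position) for r in base.records}
    for _ in range(5):
        pe = list(rng.permutation(exp))
        pc = list(rng.permutation(calc))
        again = match_peaks(pe, pc, tolerance=80.0, strategy="greedy")
        assert {(r.exp_position, r.calc_position) for r in again.records} == base_set


def test_greedy_against_exhaustive_enumeration(rng):
    """For <= 6 x 6 problems, compare greedy with brute-force assignment.

    The oracle enumerates all injective pairings within tolerance and
    maximizes cardinality then minimizes total |difference|.  Greedy must
    match the optimal cardinality-and-cost whenever peaks are separated by
    more than twice the tolerance (each peak then has a private candidate
    set); in general it must never beat the optimum.
    """

    def brute_force(exp, calc, tol):
        best = (0, 0.0)
        n, m = len(exp), len(calc)
        for k in range(min(n, m), -1, -1):
            found_cost = None
            for exp_idx in itertools.combinations(range(n), k):
                for calc_idx in itertools.permutations(range(m), k):
                    diffs = [abs(exp[i] - calc[j]) for i, j in zip(exp_idx, calc_idx)]
                    if all(d <= tol for d in diffs):
                        cost = sum(diffs)
                        if found_cost is None or cost < found_cost:
                            found_cost = cost
            if found_cost is not None:
                return k, found_cost
        return 0, 0.0

    for trial in range(20):
        n = int(rng.integers(2, 6))
        exp = sorted(rng.uniform(1000, 2000, n))
        calc = sorted(rng.uniform(1000, 2000, n))
        tol = 60.0
        greedy = match_peaks(exp, calc, tolerance=tol, strategy="greedy")
        optimal = match_peaks(exp, calc, tolerance=tol, strategy="optimal")
        k_star, cost_star = brute_force(exp, calc, tol)
        assert len(optimal.records) == k_star
        assert optimal.total_abs_difference() == pytest.approx(cost_star, abs=1e-9)
        assert greedy.total_abs_difference() >= cost_star - 1e-9 or len(greedy.records) < k_star
        # well-separated instances: greedy attains the optimum
        sep_exp = [1000.0 + 200.0 * i for i in range(n)]
        sep_calc = [p + float(rng.uniform(-20, 20)) for p in sep_exp]
        g = match_peaks(sep_exp, sep_calc, tolerance=tol, strategy="greedy")
        k2, c2 = brute_force(sep_exp, sep_calc, tol)
        assert len(g.records) == k2
        assert g.total_abs_difference() == pytest.approx(c2, abs=1e-9)


def test_split_feature_shares_calculated_partner():
    """An unresolved doublet pairs both components to one transition."""
    result = match_peaks([BandFeature((3046.0, 3038.0))], [3037.0],
                         tolerance=65.0, strategy="ordered")
    assert [r.difference for r in result.records] == [9.0, 1.0]
    assert all(r.calc_position == 3037.0 for r in result.records)


def test_one_peak_two_calculated_partners():
    """Two overlapped calculated transitions under one experimental band."""
    result = match_peaks([2008.0], [BandFeature((2009.0, 1997.0))],
                         tolerance=40.0, strategy="ordered")
    assert [r.difference for r in result.records] == [-1.0, 11.0]


def test_ordered_matching_follows_systematic_shift():
    """Order-preserving alignment keeps row pairing under a uniform offset
    where nearest-first would cross-pair."""
    exp = [1664.0, 1652.0]
    calc = [1692.0, 1679.0]
    ordered = match_peaks(exp, calc, tolerance=40.0, strategy="ordered")
    assert [r.difference for r in ordered.records] == [-28.0, -27.0]
    greedy = match_peaks(exp, calc, tolerance=40.0, strategy="greedy")
    assert [round(r.difference) for r in greedy.records] != [-28, -27]


def test_invalid_tolerance():
    with pytest.raises(ValueError):
        match_peaks([1000.0], [1000.0], tolerance=0.0)


# --------------------------------------------------------------------------
# Labels and tables
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "height,label",
    [(1.0, "vs"), (0.75, "vs"), (0.5, "s"), (0.49, "m"), (0.25, "m"),
     (0.1, "w"), (0.05, "w"), (0.01, "vw"), (0.0, "vw")],
)
def test_intensity_labels(height, label):
    assert intensity_label(height) == label


def test_intensity_label_range_check():
    with pytest.raises(ValueError):
        intensity_label(1.5)
    with pytest.raises(ValueError):
        intensity_label(-0.1)


def test_assignment_table_normalizes_to_hundred():
    """The strongest calculated band reads 100.0 after renormalization."""
    inputs = datasets.table_match_inputs("fingerprint", method="gatti")
    result = match_peaks(inputs["exp"], inputs["calc"],
                         tolerance=inputs["tolerance"], strategy="ordered")
    table = assignment_table(result.records)
    assert table["calc_intensity"].max() == pytest.approx(100.0)
    row = table[table["calc_position"] == 1679.0]
    assert row["calc_intensity"].iloc[0] == pytest.approx(100.0)
    assert row["exp_position"].iloc[0] == 1652.0


def test_assignment_table_without_intensities():
    records = match_peaks([1500.0], [1498.0], tolerance=10.0).records
    table = assignment_table(records)
    assert table["calc_intensity"].isna().all() or (table["calc_intensity"] == 100.0).all()
    text = format_assignment_table(table)
    assert "1500" in text


def test_assignment_table_unicode_minus_option():
    records = match_peaks([1500.0], [1510.0], tolerance=20.0).records
    table = assignment_table(records)
    ascii_text = format_assignment_table(table)
    uni_text = format_assignment_table(table, unicode_minus=True)
    assert "−" not in ascii_text
    assert "−10" in uni_text
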