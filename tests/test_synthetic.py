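"""Synthetic study generator: determinism, study conditions, recovery."""

import numpy as np
import pytest

from vibspec import (
    LineShapeParams,
    SyntheticConfig,
    TransitionClass,
    WLSParams,
    apply_wls,
    build_transition_ledger,
    constant_intensity,
    generate_anharmonicity,
    generate_intensities,
    generate_mode_basis,
    generate_observed_spectrum,
    generate_study,
    integrate_class_fractions,
    write_study,
)
from vibspec.io import read_spectrum, read_transitions


def test_mode_basis_ranges_and_counts():
    basis = generate_mode_basis(5, 2, 10, seed=42)
    assert len(basis) == 17
    for mode in basis:
        w = mode.harmonic_wavenumber
        if mode.character.startswith("nu") and "C=O" not in mode.character:
            assert 2950.0 <= w <= 3200.0
        elif mode.character.startswith("("):
            assert (1600.0 <= w <= 1750.0) or (1000.0 <= w <= 1600.0)
        elif mode.character.startswith("delta"):
            assert 1000.0 <= w <= 1750.0
        else:
            assert 400.0 <= w <= 1000.0


def test_single_ring_mode_in_range():
    basis = generate_mode_basis(0, 1, 0, seed=7)
    assert len(basis) == 1
    assert 1600.0 <= basis[0].harmonic_wavenumber <= 1750.0


def test_mode_basis_deterministic():
    a = generate_mode_basis(8, 3, 20, seed=5)
    b = generate_mode_basis(8, 3, 20, seed=5)
    assert np.array_equal(a.wavenumbers, b.wavenumbers)
    assert a.characters == b.characters


def test_zero_modes_rejected():
    with pytest.raises(ValueError):
        generate_mode_basis(0, 0, 0, seed=1)


def test_anharmonicity_zero_scales_is_harmonic():
    basis = generate_mode_basis(2, 1, 4, seed=3)
    chi = generate_anharmonicity(basis, 0.0, 0.0, seed=3)
    assert not chi.chi.any()


def test_anharmonicity_symmetric_and_softening():
    """Diagonal-dominated negative chi pulls every fundamental below omega."""
    basis = generate_mode_basis(8, 3, 20, seed=11)
    chi = generate_anharmonicity(basis, 30.0, 3.0, seed=11)
    assert np.array_equal(chi.chi, chi.chi.T)
    ledger = build_transition_ledger(basis, chi, constant_intensity(), max_order=1)
    for t in ledger:
        mode_id = next(iter(t.quanta))
        assert t.position < basis[mode_id].harmonic_wavenumber


def test_intensity_class_decay_ratio(rng):
    basis = generate_mode_basis(8, 3, 20, seed=2)
    chi = generate_anharmonicity(basis, 30.0, 3.0, seed=2)
    ledger = build_transition_ledger(basis, chi, constant_intensity())
    ledger = generate_intensities(ledger, 50.0, 0.02, 0.05, seed=2)
    means = {}
    for cls in (TransitionClass.FUNDAMENTAL, TransitionClass.BINARY_COMBINATION):
        means[cls] = np.mean([t.intensity for t in ledger if t.transition_class is cls])
    ratio = means[TransitionClass.BINARY_COMBINATION] / means[TransitionClass.FUNDAMENTAL]
    assert 0.05 / 3 < ratio < 0.05 * 3


def test_intensity_factor_bounds():
    basis = generate_mode_basis(1, 1, 1, seed=0)
    ledger = build_transition_ledger(basis, generate_anharmonicity(basis, 1, 1, seed=0),
                                     constant_intensity())
    with pytest.raises(ValueError):
        generate_intensities(ledger, 50.0, 0.0, 0.05, seed=0)
    with pytest.raises(ValueError):
        generate_intensities(ledger, 50.0, 0.02, 1.5, seed=0)


def test_observed_spectrum_noiseless_identity(small_ledger, mir_lineshape):
    """b=0, no noise, no baseline reproduces the plain synthesis exactly."""
    from vibspec import synthesize_spectrum

    grid = np.arange(400.0, 7000.0, 2.0)
    observed = generate_observed_spectrum(small_ledger, 0.0, mir_lineshape, 0.0,
                                          (0.0, 0.0), grid, seed=9)
    plain = synthesize_spectrum(small_ledger, mir_lineshape, grid)
    assert np.allclose(observed.values, plain.values, atol=1e-12)


def test_observed_spectrum_deterministic(small_ledger, mir_lineshape):
    grid = np.arange(400.0, 7000.0, 2.0)
    a = generate_observed_spectrum(small_ledger, -8e-6, mir_lineshape, 0.005,
                                   (0.02, 1e-6), grid, seed=4)
    b = generate_observed_spectrum(small_ledger, -8e-6, mir_lineshape, 0.005,
                                   (0.02, 1e-6), grid, seed=4)
    assert np.array_equal(a.values, b.values)


def test_observed_band_shift_matches_wls(mir_lineshape):
    """A band at calculated 3000 cm^-1 appears at 3000*(1+b*3000)."""
    from vibspec import Transition, TransitionLedger, pick_peaks

    ledger = TransitionLedger([
        Transition(position=3000.0, intensity=5.0,
                   transition_class=TransitionClass.FUNDAMENTAL, quanta={0: 1})
    ])
    grid = np.arange(2700.0, 3100.0, 0.5)
    b = -8e-6
    observed = generate_observed_spectrum(ledger, b, mir_lineshape, 0.0, (0.0, 0.0),
                                          grid, seed=0)
    peaks = pick_peaks(observed, min_prominence=0.1 * observed.values.max())
    assert len(peaks) == 1
    assert peaks[0].position == pytest.approx(3000.0 * (1.0 + b * 3000.0), abs=0.1)


def test_study_deterministic_and_truth_recorded():
    a = generate_study(seed=3)
    b = generate_study(seed=3)
    assert np.array_equal(a.observed.values, b.observed.values)
    assert np.array_equal(a.ledger.positions, b.ledger.positions)
    assert a.truth["wls_b"] == b.truth["wls_b"] == a.config.wls_b
    assert a.truth["seed"] == 3
    assert "ch_stretch" in a.truth["class_fractions"]


def test_harmonic_equal_intensity_fractions_are_count_ratios():
    """chi = 0 and factors 1: class fractions equal transition-count ratios."""
    config = SyntheticConfig(diag_scale=0.0, offdiag_scale=0.0,
                             overtone_factor=1.0, combination_factor=1.0,
                             fundamental_mean=50.0)
    basis = generate_mode_basis(config.n_ch_stretch, config.n_ring, config.n_bend, seed=1)
    chi = generate_anharmonicity(basis, 0.0, 0.0, seed=1)
    ledger = build_transition_ledger(basis, chi, constant_intensity(5.0))
    n = len(basis)
    report = integrate_class_fractions(ledger, LineShapeParams(8, 8), (100.0, 8000.0),
                                       method="sum")
    total = n + n + n * (n - 1) // 2
    assert report.fraction("fundamental") == pytest.approx(n / total, abs=1e-12)
    assert report.fraction("binary_combination") == pytest.approx((n * (n - 1) // 2) / total, abs=1e-12)


def test_truth_fractions_match_broadened_integrals():
    """Intensity-sum truth equals broadened integrals for enclosed regions."""
    study = generate_study(seed=12)
    for name, region in study.config.regions.items():
        truth = study.truth["class_fractions"][name]
        if truth is None:
            continue
        report = integrate_class_fractions(study.ledger, study.config.lineshape(),
                                           region, method="broadened")
        assert report.fractions["fundamental"] == pytest.approx(
            truth["fundamental"], abs=0.01
        )


def test_study_serialization_roundtrip(tmp_path):
    study = generate_study(seed=6)
    out = write_study(study, tmp_path / "study")
    back_ledger = read_transitions(out / "ledger.csv")
    assert len(back_ledger) == len(study.ledger)
    back_obs = read_spectrum(out / "observed.jdx")
    assert np.allclose(back_obs.grid, study.observed.grid, atol=1e-9)
    assert np.allclose(back_obs.values, study.observed.values, atol=1e-9)
    assert (out / "truth.json").exists() and (out / "config.yaml").exists()
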