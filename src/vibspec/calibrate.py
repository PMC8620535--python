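"""Wavenumber linear scaling (WLS), ATR correction and normalization.

WLS models the calculated-to-observed frequency scale factor as a linear
function of wavenumber, ``nu_scaled = nu * (a + b * nu)``; the common
single-parameter variant fixes the intercept ``a`` at 1 and fits only the
slope ``b`` (per cm^-1).  Harmonic DFT wavenumbers overestimate observed
band positions increasingly towards higher wavenumber, which a small
negative ``b`` captures.

ATR correction compensates the wavelength-dependent penetration depth of
the evanescent wave, ``d_p ~ 1/nu``, by multiplying absorbance by nu and
rescaling to the original maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lineshape import Spectrum

__all__ = [
    "WLSParams",
    "apply_wls",
    "fit_wls",
    "ATRConfig",
    "ATR_PRESETS",
    "penetration_depth",
    "atr_correct",
    "normalize_spectrum",
]


@dataclass(frozen=True)
class WLSParams:
    """Scale-factor line: factor(nu) = a + b * nu.

    ``mode`` is "single-parameter" (a fixed at 1) or "two-parameter".
    """

    a: float = 1.0
    b: float = 0.0
    mode: str = "single-parameter"

    def __post_init__(self) -> None:
        if self.mode not in ("single-parameter", "two-parameter"):
            raise ValueError(f"unknown WLS mode {self.mode!r}")
        if self.mode == "single-parameter" and self.a != 1.0:
            raise ValueError("single-parameter WLS fixes a = 1")

    def factor(self, positions: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.asarray(positions, dtype=float)


def apply_wls(positions: Sequence[float] | np.ndarray, params: WLSParams) -> np.ndarray:
    """Map each position nu to nu * (a + b * nu)."""
    positions = np.asarray(positions, dtype=float)
    factor = params.factor(positions)
    if np.any(factor <= 0):
        bad = positions[factor <= 0]
        raise ValueError(
            f"WLS scale factor non-positive at wavenumbers {bad[:3]}... "
            f"(a={params.a}, b={params.b})"
        )
    return positions * factor


def fit_wls(
    matched_pairs: Sequence[tuple[float, float]],
    mode: str = "single-parameter",
) -> WLSParams:
    """Least-squares WLS fit from (calculated, experimental) position pairs.

    Minimizes ``sum (exp - calc*(a + b*calc))^2`` in wavenumber; requires at
    least one pair for the single-parameter mode and two for two-parameter.
    """
    pairs = np.asarray(matched_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("matched_pairs must be a sequence of (calc, exp) tuples")
    calc, exp = pairs[:, 0], pairs[:, 1]
    if np.any(calc <= 0):
        raise ValueError("calculated positions must be positive")
    if mode == "single-parameter":
        if len(pairs) < 1:
            raise ValueError("single-parameter WLS needs at least one pair")
        # residual: exp - calc - b*calc^2, linear in b
        c2 = calc**2
        b = float(np.dot(c2, exp - calc) / np.dot(c2, c2))
        return WLSParams(a=1.0, b=b, mode=mode)
    if mode == "two-parameter":
        if len(pairs) < 2:
            raise ValueError("two-parameter WLS needs at least two pairs")
        design = np.column_stack([calc, calc**2])
        coef, *_ = np.linalg.lstsq(design, exp, rcond=None)
        return WLSParams(a=float(coef[0]), b=float(coef[1]), mode=mode)
    raise ValueError(f"unknown WLS mode {mode!r}")


@dataclass(frozen=True)
class ATRConfig:
    """Internal reflection element, sample index and incidence angle.

    Total internal reflection requires ``sin^2(angle) > (n_sample/n_crystal)^2``.
    """

    n_crystal: float
    n_sample: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (self.n_crystal > self.n_sample > 0):
            raise ValueError(
                f"need n_crystal > n_sample > 0, got {self.n_crystal}, {self.n_sample}"
            )
        s2 = np.sin(np.radians(self.angle_deg)) ** 2
        if s2 <= (self.n_sample / self.n_crystal) ** 2:
            raise ValueError(
                "evanescent condition violated: sin^2(angle) must exceed "
                f"(n_sample/n_crystal)^2 = {(self.n_sample / self.n_crystal) ** 2:.4f}"
            )


#: named presets; "diamond-45" is the single-reflection diamond IRE geometry
#: with a typical organic-solid sample index.
ATR_PRESETS = {
    "diamond-45": ATRConfig(n_crystal=2.4, n_sample=1.5, angle_deg=45.0),
}


def penetration_depth(wavenumbers: np.ndarray | float, config: ATRConfig) -> np.ndarray | float:
    """Evanescent-wave penetration depth d_p in micrometres.

    d_p = 1 / (2 pi nu n_crystal sqrt(sin^2(theta) - (n_sample/n_crystal)^2))
    with nu in cm^-1; the 1e4 factor converts cm to um.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumbers must be positive")
    s2 = np.sin(np.radians(config.angle_deg)) ** 2
    root = np.sqrt(s2 - (config.n_sample / config.n_crystal) ** 2)
    dp_cm = 1.0 / (2.0 * np.pi * nu * config.n_crystal * root)
    dp_um = dp_cm * 1.0e4
    return float(dp_um) if np.isscalar(wavenumbers) else dp_um


def atr_correct(spectrum: Spectrum, config: ATRConfig, force: bool = False) -> Spectrum:
    """Divide absorbance by the (relative) penetration depth.

    Since ``d_p`` is proportional to 1/nu, this multiplies absorbance by nu
    and rescales so the corrected maximum equals the input maximum.  The
    correction is not idempotent, so a metadata flag guards against double
    application (override with ``force=True``).
    """
    if spectrum.metadata.get("atr_corrected") and not force:
        raise ValueError("spectrum is already ATR-corrected (pass force=True to reapply)")
    if np.any(spectrum.grid <= 0):
        raise ValueError("ATR correction requires positive wavenumbers")
    penetration_depth(spectrum.grid[0], config)  # validates config vs usage
    corrected = spectrum.values * spectrum.grid
    peak_in = np.max(np.abs(spectrum.values))
    peak_out = np.max(np.abs(corrected))
    if peak_out > 0 and peak_in > 0:
        corrected = corrected * (peak_in / peak_out)
    return spectrum.copy(values=corrected, atr_corrected=True)


def normalize_spectrum(spectrum: Spectrum, method: str = "max") -> Spectrum:
    """Scale a spectrum to unit maximum ("max") or unit Euclidean norm ("vector")."""
    if method == "max":
        scale = np.max(np.abs(spectrum.values))
    elif method == "vector":
        scale = float(np.linalg.norm(spectrum.values))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if scale == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return spectrum.copy(values=spectrum.values / scale, normalized=method)
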