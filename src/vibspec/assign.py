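"""Regional intensity decomposition and experimental/calculated band matching.

Two questions drive this module.  First: in a wavenumber window, what share
of the integrated absorbance comes from fundamentals versus first overtones
versus binary combinations?  (:func:`integrate_class_fractions`.)  Second:
which calculated transition explains which experimental band, and with what
signed position difference?  (:func:`pick_peaks` + :func:`match_peaks` +
:func:`assignment_table`.)

Matching strategies
-------------------
``greedy``   nearest-first pairing within tolerance (default): transparent
             and order-stable, each side used at most once.
``optimal``  minimum-total-|difference| bipartite assignment of maximum
             cardinality (scipy Hungarian solver).
``ordered``  order-preserving alignment of band *features* as they appear
             in the input (max matches first, then min total |difference|).
             Published assignment tables list bands in spectral order and
             pair them sequentially, with unresolved features grouped; this
             strategy reproduces such tables, which nearest-first pairing
             does not whenever the calculated positions carry a systematic
             shift larger than the local band spacing.

A *feature* is one or several positions treated as a unit (an unresolved
split band, or several calculated transitions under one experimental
envelope).  A matched pair of features expands into records pairwise when
the two groups have equal size, otherwise as a full cross product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks

from .lineshape import LineShapeParams, Spectrum, synthesize_spectrum
from .transitions import Transition, TransitionClass, TransitionLedger

__all__ = [
    "RegionReport",
    "AssignmentRecord",
    "BandFeature",
    "Peak",
    "MatchResult",
    "integrate_class_fractions",
    "pick_peaks",
    "match_peaks",
    "assignment_table",
    "format_assignment_table",
    "intensity_label",
    "DEFAULT_LABEL_THRESHOLDS",
]

CLASSES = (
    TransitionClass.FUNDAMENTAL,
    TransitionClass.FIRST_OVERTONE,
    TransitionClass.BINARY_COMBINATION,
    TransitionClass.HIGHER_ORDER,
)


# --------------------------------------------------------------------------
# Region decomposition
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionReport:
    """Per-class integrated-intensity shares over one wavenumber window."""

    region: tuple[float, float]
    fractions: dict | None  # class value -> fraction in [0, 1]; None if empty
    integrals: dict  # class value -> integral (absorbance * cm^-1)
    total_integral: float
    method: str = "broadened"

    @property
    def defined(self) -> bool:
        return self.fractions is not None

    def fraction(self, tclass: TransitionClass | str) -> float:
        if self.fractions is None:
            raise ValueError(f"region {self.region} contains no intensity; fractions undefined")
        return self.fractions[TransitionClass(tclass).value]

    @property
    def non_fundamental_fraction(self) -> float:
        return 1.0 - self.fraction(TransitionClass.FUNDAMENTAL)


def integrate_class_fractions(
    ledger: TransitionLedger,
    params: LineShapeParams,
    region: tuple[float, float],
    method: str = "broadened",
    grid_step: float | None = None,
) -> RegionReport:
    """Decompose the integrated intensity in ``region`` by transition class.

    ``method="broadened"`` synthesizes each class's sub-spectrum and
    integrates it over the region with the trapezoid rule; ``method="sum"``
    adds up calculated intensities of transitions inside the region.  In
    area-proportional mode the two agree whenever every band lies entirely
    inside the window.
    """
    low, high = region
    if not low < high:
        raise ValueError(f"region must satisfy low < high, got {region}")
    width = max(params.fwhm_gauss, params.fwhm_lorentz)
    pad = 50.0 * width
    # transitions whose bands can reach into the region
    contributing = ledger.filter(region=(low - pad, high + pad))
    integrals: dict[str, float] = {c.value: 0.0 for c in CLASSES}
    if method == "sum":
        for t in contributing.filter(region=(low, high)):
            integrals[t.transition_class.value] += t.intensity
    elif method == "broadened":
        if grid_step is None:
            grid_step = min(params.fwhm_gauss, params.fwhm_lorentz) / 8.0
        n = max(2, int(np.ceil((high - low) / grid_step)) + 1)
        grid = np.linspace(low, high, n)
        for c in CLASSES:
            sub = contributing.filter(classes=[c])
            if len(sub) == 0:
                continue
            spec = synthesize_spectrum(sub, params, grid)
            integrals[c.value] = float(np.trapezoid(spec.values, grid))
    else:
        raise ValueError(f"unknown method {method!r}")
    total = sum(integrals.values())
    fractions = {k: v / total for k, v in integrals.items()} if total > 0 else None
    return RegionReport(region=(low, high), fractions=fractions, integrals=integrals,
                        total_integral=total, method=method)


# --------------------------------------------------------------------------
# Peak picking
# --------------------------------------------------------------------------


class Peak(NamedTuple):
    position: float
    height: float


def pick_peaks(
    spectrum: Spectrum,
    min_prominence: float,
    min_separation: float = 0.0,
) -> list[Peak]:
    """Local maxima above a prominence threshold, apex refined parabolically.

    ``min_separation`` is in cm^-1 and is converted to a sample distance on
    the spectrum's grid.
    """
    y = spectrum.values
    x = spectrum.grid
    if x.size < 3:
        return []
    step = float(np.median(np.diff(x)))
    distance = max(1, int(round(min_separation / step))) if min_separation > 0 else 1
    idx, _ = find_peaks(y, prominence=min_prominence, distance=distance)
    peaks = []
    for i in idx:
        if 0 < i < y.size - 1:
            ym1, y0, yp1 = y[i - 1], y[i], y[i + 1]
            denom = ym1 - 2.0 * y0 + yp1
            delta = 0.5 * (ym1 - yp1) / denom if denom != 0 else 0.0
            pos = x[i] + delta * (x[i + 1] - x[i - 1]) / 2.0
            height = y0 - 0.25 * (ym1 - yp1) * delta
        else:  # pragma: no cover - find_peaks excludes endpoints
            pos, height = x[i], y[i]
        peaks.append(Peak(float(pos), float(height)))
    return peaks


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BandFeature:
    """One band feature: a single position or an unresolved group of them."""

    positions: tuple[float, ...]
    intensities: tuple[float, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("a band feature needs at least one position")

    @property
    def center(self) -> float:
        return float(np.mean(self.positions))


@dataclass(frozen=True)
class AssignmentRecord:
    """A matched experimental/calculated pair with its signed difference."""

    exp_position: float
    calc_position: float
    difference: float  # exp - calc, exactly
    calc_intensity: float | None = None
    exp_intensity: float | None = None
    exp_intensity_label: str | None = None
    assignment_label: str = ""


@dataclass
class MatchResult:
    records: list[AssignmentRecord]
    unmatched_exp: list[float] = field(default_factory=list)
    unmatched_calc: list[float] = field(default_factory=list)

    @property
    def differences(self) -> list[float]:
        return [r.difference for r in self.records]

    def total_abs_difference(self) -> float:
        return float(sum(abs(d) for d in self.differences))


def _as_features(items, intensity_attr: bool = False) -> list[BandFeature]:
    """Normalize heterogeneous inputs into a feature list (order preserved)."""
    if isinstance(items, TransitionLedger):
        return [
            BandFeature((t.position,), (t.intensity,), t.label) for t in items
        ]
    feats = []
    for item in items:
        if isinstance(item, BandFeature):
            feats.append(item)
        elif isinstance(item, Transition):
            feats.append(BandFeature((item.position,), (item.intensity,), item.label))
        elif isinstance(item, Peak):
            feats.append(BandFeature((item.position,), (item.height,)))
        elif np.isscalar(item):
            feats.append(BandFeature((float(item),)))
        else:
            raise TypeError(f"cannot interpret {item!r} as a band feature")
    return feats


def _expand(exp: BandFeature, calc: BandFeature) -> list[AssignmentRecord]:
    """Expand a matched feature pair into records (zip if equal size, else cross)."""
    m, k = len(exp.positions), len(calc.positions)
    if m == k:
        pairs = list(zip(range(m), range(k)))
    else:
        pairs = [(i, j) for i in range(m) for j in range(k)]
    records = []
    for i, j in pairs:
        e, c = exp.positions[i], calc.positions[j]
        records.append(
            AssignmentRecord(
                exp_position=e,
                calc_position=c,
                difference=e - c,
                calc_intensity=None if calc.intensities is None else calc.intensities[min(j, len(calc.intensities) - 1)],
                exp_intensity=None if exp.intensities is None else exp.intensities[min(i, len(exp.intensities) - 1)],
                assignment_label=calc.label or exp.label,
            )
        )
    return records


def _feasible(exp: BandFeature, calc: BandFeature, tolerance: float) -> bool:
    return all(abs(r.difference) <= tolerance for r in _expand(exp, calc))


def _pair_cost(exp: BandFeature, calc: BandFeature) -> float:
    return sum(abs(r.difference) for r in _expand(exp, calc))


def _match_greedy(exp: list[BandFeature], calc: list[BandFeature], tol: float):
    # sort candidate pairs by |difference|; tie-break on positions so the
    # result does not depend on input ordering
    candidates = sorted(
        (
            (_pair_cost(e, c) / max(len(e.positions), len(c.positions)), e.center, c.center, ie, ic)
            for ie, e in enumerate(exp)
            for ic, c in enumerate(calc)
            if _feasible(e, c, tol)
        ),
    )
    used_e: set[int] = set()
    used_c: set[int] = set()
    matched = []
    for _, _, _, ie, ic in candidates:
        if ie in used_e or ic in used_c:
            continue
        used_e.add(ie)
        used_c.add(ic)
        matched.append((ie, ic))
    return matched


def _match_optimal(exp: list[BandFeature], calc: list[BandFeature], tol: float):
    big = 1.0e9  # dominates any feasible total cost; enforces max cardinality
    cost = np.full((len(exp), len(calc)), big)
    for ie, e in enumerate(exp):
        for ic, c in enumerate(calc):
            if _feasible(e, c, tol):
                cost[ie, ic] = _pair_cost(e, c)
    n = max(cost.shape)
    square = np.full((n, n), big)
    square[: cost.shape[0], : cost.shape[1]] = cost
    rows, cols = linear_sum_assignment(square)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < cost.shape[0] and c < cost.shape[1] and cost[r, c] < big
    ]


def _match_ordered(exp: list[BandFeature], calc: list[BandFeature], tol: float):
    """Order-preserving alignment: maximize matches, then minimize total cost.

    Dynamic program over the two feature sequences in their given order
    (assignment tables run monotonically in wavenumber).  Cost ties are
    broken towards the more negative signed differences: harmonic and
    VPT2 calculations tend to overestimate positions, so when two
    alignments explain the data equally well the one keeping calculated
    positions above experimental ones is preferred.
    """
    ne, nc = len(exp), len(calc)
    # best[i][j] = (matches, -cost, -signed_sum) over exp[:i], calc[:j]
    best = [[(0, 0.0, 0.0)] * (nc + 1) for _ in range(ne + 1)]
    choice = [[None] * (nc + 1) for _ in range(ne + 1)]
    for i in range(ne + 1):
        for j in range(nc + 1):
            if i == 0 and j == 0:
                continue
            options = []
            if i > 0:
                options.append((best[i - 1][j], "skip_exp"))
            if j > 0:
                options.append((best[i][j - 1], "skip_calc"))
            if i > 0 and j > 0 and _feasible(exp[i - 1], calc[j - 1], tol):
                m, c, s = best[i - 1][j - 1]
                records = _expand(exp[i - 1], calc[j - 1])
                cost = sum(abs(r.difference) for r in records)
                signed = sum(r.difference for r in records)
                options.append(((m + 1, c - cost, s - signed), "match"))
            (best[i][j], choice[i][j]) = max(options)
    matched = []
    i, j = ne, nc
    while i > 0 or j > 0:
        move = choice[i][j]
        if move == "match":
            matched.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif move == "skip_exp":
            i -= 1
        else:
            j -= 1
    matched.reverse()
    return matched


def match_peaks(
    exp_peaks,
    calc,
    tolerance: float,
    strategy: str = "greedy",
) -> MatchResult:
    """Pair experimental band features with calculated transitions.

    Parameters
    ----------
    exp_peaks
        Sequence of positions, :class:`Peak` objects or :class:`BandFeature`
        groups (a split feature like "3075; 3070" is one group).
    calc
        A :class:`TransitionLedger`, or a sequence like ``exp_peaks``.
    tolerance
        Maximum allowed |exp - calc| for a pairing, in cm^-1.
    strategy
        "greedy" (default), "optimal" or "ordered"; see the module docstring.

    Each experimental feature receives at most one calculated feature and
    vice versa; unmatched items are reported separately.  Differences are
    always ``exp - calc``.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    exp_feats = _as_features(exp_peaks)
    calc_feats = _as_features(calc)
    if strategy == "greedy":
        matched = _match_greedy(exp_feats, calc_feats, tolerance)
    elif strategy == "optimal":
        matched = _match_optimal(exp_feats, calc_feats, tolerance)
    elif strategy == "ordered":
        matched = _match_ordered(exp_feats, calc_feats, tolerance)
    else:
        raise ValueError(f"unknown matching strategy {strategy!r}")
    matched.sort(key=lambda ij: ij[0])
    records: list[AssignmentRecord] = []
    for ie, ic in matched:
        records.extend(_expand(exp_feats[ie], calc_feats[ic]))
    used_e = {ie for ie, _ in matched}
    used_c = {ic for _, ic in matched}
    unmatched_exp = [p for i, f in enumerate(exp_feats) if i not in used_e for p in f.positions]
    unmatched_calc = [p for i, f in enumerate(calc_feats) if i not in used_c for p in f.positions]
    return MatchResult(records, unmatched_exp, unmatched_calc)


# --------------------------------------------------------------------------
# Assignment tables and intensity labels
# --------------------------------------------------------------------------

#: relative-height cutoffs for the conventional vs/s/m/w/vw strength labels.
#: The labels themselves are standard; the numeric cutoffs are this
#: package's configuration values.
DEFAULT_LABEL_THRESHOLDS = {"vs": 0.75, "s": 0.50, "m": 0.25, "w": 0.05}


def intensity_label(relative_height: float, thresholds: dict | None = None) -> str:
    """Map a relative band height (0..1 of spectrum maximum) to vs/s/m/w/vw."""
    if not 0.0 <= relative_height <= 1.0:
        raise ValueError(f"relative height must lie in [0, 1], got {relative_height}")
    thresholds = DEFAULT_LABEL_THRESHOLDS if thresholds is None else thresholds
    ordered = sorted(thresholds.items(), key=lambda kv: -kv[1])
    values = [v for _, v in ordered]
    if values != sorted(values, reverse=True) or len(set(values)) != len(values):
        raise ValueError("label thresholds must be strictly decreasing")
    for name, cutoff in ordered:
        if relative_height >= cutoff:
            return name
    return "vw"


def assignment_table(
    records: Sequence[AssignmentRecord],
    normalize_calc: bool = True,
    label_thresholds: dict | None = None,
) -> pd.DataFrame:
    """Tabulate assignment records in conventional column order.

    Calculated intensities are renormalized so the most intense entry reads
    100.0; experimental strength labels (vs..vw) are attached where
    experimental intensities are present.
    """
    if len(records) == 0:
        raise ValueError("no assignment records to tabulate")
    rows = []
    calc_int = [r.calc_intensity for r in records]
    have_calc = any(v is not None for v in calc_int)
    scale = 1.0
    if normalize_calc and have_calc:
        peak = max(v for v in calc_int if v is not None)
        scale = 100.0 / peak if peak > 0 else 1.0
    exp_int = [r.exp_intensity for r in records]
    have_exp = any(v is not None for v in exp_int)
    exp_max = max((v for v in exp_int if v is not None), default=0.0)
    for r in records:
        label = r.exp_intensity_label
        if label is None and have_exp and r.exp_intensity is not None and exp_max > 0:
            label = intensity_label(min(1.0, r.exp_intensity / exp_max), label_thresholds)
        rows.append(
            {
                "exp_position": r.exp_position,
                "exp_label": label if label is not None else "",
                "calc_position": r.calc_position,
                "calc_intensity": None if r.calc_intensity is None else round(r.calc_intensity * scale, 1),
                "difference": r.difference,
                "assignment": r.assignment_label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["exp_position", "exp_label", "calc_position", "calc_intensity", "difference", "assignment"],
    )


def format_assignment_table(frame: pd.DataFrame, unicode_minus: bool = False) -> str:
    """Aligned-text rendering; ASCII hyphens by default."""
    text = frame.to_string(index=False, na_rep="-")
    if unicode_minus:
        import re

        text = re.sub(r"-(?=\d)", "−", text)
    return text
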