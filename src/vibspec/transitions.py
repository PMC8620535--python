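"""Vibrational transition model and second-order (VPT2-style) arithmetic.

A molecule's normal modes are described by a :class:`ModeBasis` (harmonic
wavenumbers ``omega_i`` plus character labels in the conventional
nu/delta/gamma/rho notation) and a symmetric matrix of anharmonicity
constants ``chi_ij``.  Transition positions follow the standard
second-order vibrational energy expression

    E(v) = sum_i omega_i (v_i + 1/2) + sum_{i<=j} chi_ij (v_i + 1/2)(v_j + 1/2)

so a fundamental sits at ``omega_i + 2 chi_ii + 1/2 sum_{j!=i} chi_ij``, a
first overtone deviates from twice its fundamental by exactly ``2 chi_ii``
and a binary combination deviates from the sum of its fundamentals by
``chi_ij``.  No resonance (deperturbation threshold) handling is applied:
constants are taken as given.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransitionClass",
    "Mode",
    "ModeBasis",
    "AnharmonicConstants",
    "Transition",
    "TransitionLedger",
    "classify_transition",
    "vpt2_transition_position",
    "build_transition_ledger",
    "constant_intensity",
    "class_decay_intensity",
]

# Unicode minus occasionally appears in published tables; accept it anywhere
# a number is read.
_UNICODE_MINUS = "−"


def _ascii_minus(text: str) -> str:
    return text.replace(_UNICODE_MINUS, "-")


class TransitionClass(str, Enum):
    """Taxonomy of vibrational transitions by total excitation quanta."""

    FUNDAMENTAL = "fundamental"
    FIRST_OVERTONE = "first_overtone"
    BINARY_COMBINATION = "binary_combination"
    HIGHER_ORDER = "higher_order"


def classify_transition(quanta: Mapping[int, int]) -> TransitionClass:
    """Classify a transition from its excitation quanta.

    Parameters
    ----------
    quanta
        Sparse map ``mode_id -> quanta`` of the excited state relative to
        the ground state.  Must be non-empty with all counts >= 1.

    Returns
    -------
    TransitionClass
        ``FUNDAMENTAL`` for one mode raised by one quantum,
        ``FIRST_OVERTONE`` for one mode raised by two,
        ``BINARY_COMBINATION`` for two modes raised by one each,
        ``HIGHER_ORDER`` for everything else.  The four classes partition
        all valid inputs.
    """
    if not quanta:
        raise ValueError("quanta map must be non-empty")
    counts = list(quanta.values())
    if any((not isinstance(c, (int, np.integer))) or c < 1 for c in counts):
        raise ValueError(f"all quanta must be integers >= 1, got {dict(quanta)}")
    if len(counts) == 1:
        if counts[0] == 1:
            return TransitionClass.FUNDAMENTAL
        if counts[0] == 2:
            return TransitionClass.FIRST_OVERTONE
        return TransitionClass.HIGHER_ORDER
    if len(counts) == 2 and counts[0] == 1 and counts[1] == 1:
        return TransitionClass.BINARY_COMBINATION
    return TransitionClass.HIGHER_ORDER


@dataclass(frozen=True)
class Mode:
    """A single normal mode: index, harmonic wavenumber (cm^-1), character.

    ``character`` follows the conventional notation: nu = stretching,
    delta = in-plane bending, gamma = out-of-plane bending, rho = rocking,
    suffixed with a fragment tag, e.g. ``"nuCH"`` or ``"deltaring"``.
    Greek letters are equally accepted.
    """

    mode_id: int
    harmonic_wavenumber: float
    character: str

    def __post_init__(self) -> None:
        if self.harmonic_wavenumber <= 0:
            raise ValueError(
                f"mode {self.mode_id}: harmonic wavenumber must be > 0, "
                f"got {self.harmonic_wavenumber}"
            )
        if not self.character:
            raise ValueError(f"mode {self.mode_id}: character label must be non-empty")


class ModeBasis:
    """Ordered collection of normal modes with unique contiguous ids."""

    def __init__(self, modes: Sequence[Mode]):
        modes = sorted(modes, key=lambda m: m.mode_id)
        ids = [m.mode_id for m in modes]
        if ids != list(range(len(modes))):
            raise ValueError(f"mode ids must be unique and contiguous from 0, got {ids}")
        self.modes: tuple[Mode, ...] = tuple(modes)

    @classmethod
    def from_wavenumbers(
        cls, wavenumbers: Sequence[float], characters: Sequence[str] | None = None
    ) -> "ModeBasis":
        if characters is None:
            characters = [f"mode{i}" for i in range(len(wavenumbers))]
        return cls(
            [Mode(i, float(w), c) for i, (w, c) in enumerate(zip(wavenumbers, characters))]
        )

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, mode_id: int) -> Mode:
        return self.modes[mode_id]

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.array([m.harmonic_wavenumber for m in self.modes])

    @property
    def characters(self) -> list[str]:
        return [m.character for m in self.modes]

    def __repr__(self) -> str:  # pragma: no cover
        return f"ModeBasis({len(self)} modes)"


class AnharmonicConstants:
    """Symmetric matrix of anharmonicity constants chi_ij in cm^-1."""

    def __init__(self, chi: np.ndarray | Sequence[Sequence[float]]):
        chi = np.asarray(chi, dtype=float)
        if chi.ndim != 2 or chi.shape[0] != chi.shape[1]:
            raise ValueError(f"chi must be a square matrix, got shape {chi.shape}")
        if not np.array_equal(chi, chi.T):
            raise ValueError("chi must be exactly symmetric")
        self.chi = chi

    @classmethod
    def zeros(cls, n_modes: int) -> "AnharmonicConstants":
        return cls(np.zeros((n_modes, n_modes)))

    @property
    def n_modes(self) -> int:
        return self.chi.shape[0]

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return float(self.chi[ij])


def _quanta_vector(quanta: Mapping[int, int], n_modes: int) -> np.ndarray:
    v = np.zeros(n_modes)
    for mode_id, count in quanta.items():
        if not 0 <= mode_id < n_modes:
            raise ValueError(f"quanta refer to unknown mode {mode_id} (n_modes={n_modes})")
        v[mode_id] = count
    return v


def vpt2_transition_position(
    modes: ModeBasis, chi: AnharmonicConstants, quanta: Mapping[int, int]
) -> float:
    """Transition wavenumber E(v) - E(0) from the second-order energy expression.

    Evaluates ``sum_i omega_i (v_i+1/2) + sum_{i<=j} chi_ij (v_i+1/2)(v_j+1/2)``
    for the excited state and subtracts the zero-point value.
    """
    if chi.n_modes != len(modes):
        raise ValueError(
            f"chi dimension {chi.n_modes} does not match mode count {len(modes)}"
        )
    classify_transition(quanta)  # validates the quanta map
    v = _quanta_vector(quanta, len(modes))
    omega = modes.wavenumbers

    def energy(vv: np.ndarray) -> float:
        x = vv + 0.5
        # sum_{i<=j} chi_ij x_i x_j = (x' C x + sum_i chi_ii x_i^2) / 2
        quad = 0.5 * (x @ chi.chi @ x + np.sum(np.diag(chi.chi) * x * x))
        return float(omega @ x + quad)

    return energy(v) - energy(np.zeros_like(v))


IntensityRule = Callable[[Mapping[int, int], TransitionClass, float], float]


def constant_intensity(value: float = 1.0) -> IntensityRule:
    """Intensity rule assigning the same intensity to every transition."""

    def rule(quanta, tclass, position):
        return value

    return rule


def class_decay_intensity(
    fundamental: float = 1.0, overtone_factor: float = 0.02, combination_factor: float = 0.05
) -> IntensityRule:
    """Intensity rule scaling non-fundamental transitions by per-class factors."""

    factors = {
        TransitionClass.FUNDAMENTAL: 1.0,
        TransitionClass.FIRST_OVERTONE: overtone_factor,
        TransitionClass.BINARY_COMBINATION: combination_factor,
        TransitionClass.HIGHER_ORDER: overtone_factor * combination_factor,
    }

    def rule(quanta, tclass, position):
        return fundamental * factors[tclass]

    return rule


_GREEK = {"nu": "ν", "delta": "δ", "gamma": "γ", "rho": "ρ"}


@dataclass(frozen=True)
class Transition:
    """One vibrational excitation.

    ``quanta`` may be ``None`` for transitions imported from published
    assignment tables, where only position, intensity and a label are known;
    in that case ``transition_class`` is carried explicitly.
    """

    position: float
    intensity: float
    transition_class: TransitionClass
    quanta: Mapping[int, int] | None = None
    label: str = ""
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"transition position must be > 0, got {self.position}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.quanta is not None:
            expected = classify_transition(self.quanta)
            if expected is not self.transition_class:
                raise ValueError(
                    f"class {self.transition_class.value} inconsistent with quanta "
                    f"{dict(self.quanta)} (expected {expected.value})"
                )

    def involves_mode(self, mode_id: int) -> bool:
        return self.quanta is not None and mode_id in self.quanta


def _default_label(modes: ModeBasis, quanta: Mapping[int, int]) -> str:
    tclass = classify_transition(quanta)
    ids = sorted(quanta, key=lambda i: modes[i].harmonic_wavenumber)
    if tclass is TransitionClass.FUNDAMENTAL:
        return modes[ids[0]].character
    if tclass is TransitionClass.FIRST_OVERTONE:
        return f"2{modes[ids[0]].character}"
    if tclass is TransitionClass.BINARY_COMBINATION:
        # low-frequency partner first, as assignment tables conventionally do
        return " + ".join(modes[i].character for i in ids)
    parts = []
    for i in ids:
        n = quanta[i]
        parts.append((f"{n}" if n > 1 else "") + modes[i].character)
    return " + ".join(parts)


class TransitionLedger:
    """Transitions of one calculation, kept sorted by ascending position."""

    def __init__(
        self,
        transitions: Iterable[Transition],
        modes: ModeBasis | None = None,
        provenance: str = "",
    ):
        transitions = sorted(transitions, key=lambda t: t.position)
        if modes is not None:
            n = len(modes)
            for t in transitions:
                if t.quanta is not None:
                    for mode_id in t.quanta:
                        if not 0 <= mode_id < n:
                            raise ValueError(
                                f"transition at {t.position} refers to unknown mode {mode_id}"
                            )
        self.transitions: tuple[Transition, ...] = tuple(transitions)
        self.modes = modes
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.transitions)

    def __iter__(self):
        return iter(self.transitions)

    def __getitem__(self, idx: int) -> Transition:
        return self.transitions[idx]

    @property
    def positions(self) -> np.ndarray:
        return np.array([t.position for t in self.transitions])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([t.intensity for t in self.transitions])

    def filter(
        self,
        classes: Iterable[TransitionClass | str] | None = None,
        region: tuple[float, float] | None = None,
    ) -> "TransitionLedger":
        """Sub-ledger restricted to the given classes and/or wavenumber window."""
        wanted = None
        if classes is not None:
            wanted = {TransitionClass(c) for c in classes}
        out = []
        for t in self.transitions:
            if wanted is not None and t.transition_class not in wanted:
                continue
            if region is not None and not (region[0] <= t.position <= region[1]):
                continue
            out.append(t)
        return TransitionLedger(out, modes=self.modes, provenance=self.provenance)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.transitions:
            quanta = (
                ";".join(f"{i}:{n}" for i, n in sorted(t.quanta.items()))
                if t.quanta is not None
                else ""
            )
            rows.append(
                {
                    "quanta": quanta,
                    "position_cm1": t.position,
                    "intensity": t.intensity,
                    "class": t.transition_class.value,
                    "label": t.label,
                }
            )
        return pd.DataFrame(rows, columns=["quanta", "position_cm1", "intensity", "class", "label"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str | None:
        doc = {
            "provenance": self.provenance,
            "modes": [
                {"mode_id": m.mode_id, "harmonic_wavenumber": m.harmonic_wavenumber, "character": m.character}
                for m in (self.modes or [])
            ],
            "transitions": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(doc, indent=1, ensure_ascii=False)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @staticmethod
    def _parse_quanta(text: str) -> Mapping[int, int] | None:
        text = _ascii_minus(str(text)).strip()
        if not text or text in {"nan", "None"}:
            return None
        quanta = {}
        for part in re.split(r"[;,]\s*", text):
            i, n = part.split(":")
            quanta[int(i)] = int(n)
        return quanta

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, modes: ModeBasis | None = None, provenance: str = ""
    ) -> "TransitionLedger":
        required = {"position_cm1", "intensity"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"transition table missing columns: {sorted(missing)}")
        transitions = []
        for _, row in frame.iterrows():
            quanta = cls._parse_quanta(row.get("quanta", "")) if "quanta" in frame.columns else None
            label = str(row.get("label", "")) if "label" in frame.columns else ""
            if label == "nan":
                label = ""
            if "class" in frame.columns and str(row["class"]).strip():
                tclass = TransitionClass(str(row["class"]).strip())
            elif quanta is not None:
                tclass = classify_transition(quanta)
            else:
                from .io import infer_class_from_label  # deferred: io depends on us

                tclass = infer_class_from_label(label)
            transitions.append(
                Transition(
                    position=float(_ascii_minus(str(row["position_cm1"]))),
                    intensity=float(_ascii_minus(str(row["intensity"]))),
                    transition_class=tclass,
                    quanta=quanta,
                    label=label,
                )
            )
        return cls(transitions, modes=modes, provenance=provenance)

    @classmethod
    def from_csv(cls, path, modes: ModeBasis | None = None, provenance: str = "") -> "TransitionLedger":
        return cls.from_frame(pd.read_csv(path), modes=modes, provenance=provenance)

    @classmethod
    def from_json(cls, path) -> "TransitionLedger":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        modes = None
        if doc.get("modes"):
            modes = ModeBasis(
                [Mode(m["mode_id"], m["harmonic_wavenumber"], m["character"]) for m in doc["modes"]]
            )
        return cls.from_frame(
            pd.DataFrame(doc["transitions"]), modes=modes, provenance=doc.get("provenance", "")
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"TransitionLedger({len(self)} transitions, provenance={self.provenance!r})"


def build_transition_ledger(
    modes: ModeBasis,
    chi: AnharmonicConstants,
    intensity_rule: IntensityRule | None = None,
    max_order: int = 2,
    provenance: str = "VPT2 enumeration",
) -> TransitionLedger:
    """Enumerate fundamentals (+ first overtones and binary combinations).

    With ``max_order=2`` this yields ``n + n + n(n-1)/2`` transitions for
    ``n`` modes; with ``max_order=1`` only the ``n`` fundamentals.  Positions
    come from :func:`vpt2_transition_position`; intensities from the supplied
    rule (default: constant 1.0).
    """
    if max_order not in (1, 2):
        raise ValueError(f"max_order must be 1 or 2, got {max_order}")
    if intensity_rule is None:
        intensity_rule = constant_intensity()
    n = len(modes)
    quanta_sets: list[dict[int, int]] = [{i: 1} for i in range(n)]
    if max_order == 2:
        quanta_sets += [{i: 2} for i in range(n)]
        quanta_sets += [{i: 1, j: 1} for i in range(n) for j in range(i + 1, n)]
    transitions = []
    for quanta in quanta_sets:
        tclass = classify_transition(quanta)
        position = vpt2_transition_position(modes, chi, quanta)
        intensity = intensity_rule(quanta, tclass, position)
        transitions.append(
            Transition(
                position=position,
                intensity=intensity,
                transition_class=tclass,
                quanta=quanta,
                label=_default_label(modes, quanta),
            )
        )
    return TransitionLedger(transitions, modes=modes, provenance=provenance)
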