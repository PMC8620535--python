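"""Readers/writers for spectra, transition tables, studies and run configs.

Spectra: JCAMP-DX (``##XYDATA=(X++(Y..Y))`` in AFFN or PAC form, plus
``##XYPOINTS=(XY..XY)``) and plain two-column text.  Published tables often
carry the typographic Unicode minus; it is accepted everywhere on read and
replaced by the ASCII hyphen on write unless typographic fidelity is
requested.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .lineshape import Spectrum
from .transitions import TransitionClass, TransitionLedger

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_transitions",
    "write_transitions",
    "infer_class_from_label",
    "RunConfig",
    "menadione_study_config",
    "write_study",
]

_UNICODE_MINUS = "−"
_NUMBER_RE = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _numbers(line: str, path: str, lineno: int) -> list[float]:
    line = line.replace(_UNICODE_MINUS, "-").replace(",", " ")
    found = _NUMBER_RE.findall(line)
    if not found:
        raise ValueError(f"{path}:{lineno}: no numeric data in line {line!r}")
    try:
        return [float(tok) for tok in found]
    except ValueError as err:  # pragma: no cover - regex guarantees floats
        raise ValueError(f"{path}:{lineno}: {err}") from None


# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------


def _detect_format(path: Path) -> str:
    if path.suffix.lower() in {".jdx", ".dx", ".jcm"}:
        return "jcamp-dx"
    head = path.read_text(encoding="utf-8", errors="replace")[:200]
    return "jcamp-dx" if head.lstrip().startswith("##") else "two-column-text"


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a spectrum; grids are returned ascending regardless of file order."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "jcamp-dx":
        grid, values, meta = _read_jcamp(path)
    elif fmt == "two-column-text":
        grid, values, meta = _read_two_column(path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.size > 1 and grid[0] > grid[-1]:
        grid, values = grid[::-1].copy(), values[::-1].copy()
    return Spectrum(grid, values, meta)


def _read_two_column(path: Path):
    grid, values = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "//", ";")):
                continue
            nums = _numbers(line, str(path), lineno)
            if len(nums) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            grid.append(nums[0])
            values.append(nums[1])
    return grid, values, {"technique": "unknown", "source": str(path)}


def _read_jcamp(path: Path):
    header: dict[str, str] = {}
    data_mode = None
    ys: list[float] = []
    xy: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: malformed JCAMP header {line!r}")
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XYDATA":
                    data_mode = "xydata"
                elif key == "XYPOINTS":
                    data_mode = "xypoints"
                elif key == "END":
                    break
                else:
                    header[key] = value
                continue
            if data_mode == "xydata":
                nums = _numbers(line, str(path), lineno)
                ys.extend(nums[1:])  # first token is the line's leading X
            elif data_mode == "xypoints":
                nums = _numbers(line, str(path), lineno)
                if len(nums) % 2:
                    raise ValueError(f"{path}:{lineno}: odd token count in XY pairs")
                xy.extend(zip(nums[::2], nums[1::2]))

    def _get(key: str, default=None) -> float:
        if key in header:
            return float(header[key].replace(_UNICODE_MINUS, "-"))
        if default is None:
            raise ValueError(f"{path}: missing required JCAMP field ##{key}")
        return default

    xfactor = _get("XFACTOR", 1.0)
    yfactor = _get("YFACTOR", 1.0)
    meta = {
        "technique": header.get("DATATYPE", "unknown"),
        "title": header.get("TITLE", ""),
        "xunits": header.get("XUNITS", "1/CM"),
        "yunits": header.get("YUNITS", "ABSORBANCE"),
        "source": str(path),
    }
    if "RESOLUTION" in header:
        meta["resolution"] = float(header["RESOLUTION"])
    if data_mode == "xypoints":
        grid = [x * xfactor for x, _ in xy]
        values = [y * yfactor for _, y in xy]
        return grid, values, meta
    if data_mode != "xydata":
        raise ValueError(f"{path}: no XYDATA/XYPOINTS block found")
    npoints = int(_get("NPOINTS"))
    firstx, lastx = _get("FIRSTX"), _get("LASTX")
    if len(ys) != npoints:
        raise ValueError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values read")
    grid = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    values = np.asarray(ys) * yfactor
    return grid, values, meta


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> None:
    """Write a spectrum as JCAMP-DX (uniform grids) or two-column text."""
    path = Path(path)
    fmt = format
    if fmt is None:
        fmt = "jcamp-dx" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "two-column-text"
    if fmt == "two-column-text":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# wavenumber_cm-1  absorbance\n")
            for x, y in zip(spectrum.grid, spectrum.values):
                fh.write(f"{x:.10g} {y:.10g}\n")
        return
    if fmt != "jcamp-dx":
        raise ValueError(f"unknown spectrum format {fmt!r}")
    grid, values = spectrum.grid, spectrum.values
    uniform = grid.size < 2 or np.allclose(np.diff(grid), grid[1] - grid[0], rtol=0, atol=1e-9)
    lines = [
        f"##TITLE={spectrum.metadata.get('title', 'vibspec spectrum')}",
        "##JCAMP-DX=4.24",
        f"##DATA TYPE={spectrum.metadata.get('technique', 'INFRARED SPECTRUM')}",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={grid[0]:.10g}",
        f"##LASTX={grid[-1]:.10g}",
        f"##NPOINTS={grid.size}",
        f"##FIRSTY={values[0]:.10g}",
    ]
    if uniform:
        lines.append("##XYDATA=(X++(Y..Y))")
        per_line = 6
        for i in range(0, grid.size, per_line):
            chunk = values[i : i + per_line]
            lines.append(f"{grid[i]:.10g} " + " ".join(f"{y:.10g}" for y in chunk))
    else:
        lines.append("##XYPOINTS=(XY..XY)")
        for x, y in zip(grid, values):
            lines.append(f"{x:.10g}, {y:.10g}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Transition tables and the assignment-label grammar
# --------------------------------------------------------------------------


def _split_top_level(text: str, sep: str) -> list[str]:
    parts, depth, current = [], 0, []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        if depth == 0 and text.startswith(sep, i):
            parts.append("".join(current).strip())
            current = []
            i += len(sep)
            continue
        current.append(ch)
        i += 1
    parts.append("".join(current).strip())
    return [p for p in parts if p]


def infer_class_from_label(label: str) -> TransitionClass:
    """Classify from assignment-label grammar.

    ``2X`` (X a mode character, possibly parenthesized and mixed) is a first
    overtone, ``X + Y`` a binary combination, ``3X``/``X + Y + Z`` higher
    order, anything else a fundamental.  Parenthesized mixed characters
    like ``(deltaring, nuC=O)`` denote a single mode, never a combination.
    When a label lists alternatives separated by ``;`` the first is used.
    """
    label = str(label).strip()
    if not label:
        return TransitionClass.FUNDAMENTAL
    first = _split_top_level(label, ";")[0].strip()
    terms = _split_top_level(first, "+")
    if len(terms) == 2:
        return TransitionClass.BINARY_COMBINATION
    if len(terms) > 2:
        return TransitionClass.HIGHER_ORDER
    term = terms[0]
    m = re.match(r"^(\d+)\s*\D", term)
    if m:
        n = int(m.group(1))
        if n == 2:
            return TransitionClass.FIRST_OVERTONE
        if n > 2:
            return TransitionClass.HIGHER_ORDER
    return TransitionClass.FUNDAMENTAL


def read_transitions(path, provenance: str = "") -> TransitionLedger:
    """Read a transition table (CSV or JSON) into a ledger.

    Requires ``position_cm1`` and ``intensity`` columns; class is taken
    from a ``class`` column, else from ``quanta``, else inferred from the
    ``label`` grammar.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return TransitionLedger.from_json(path)
    return TransitionLedger.from_csv(path, provenance=provenance or str(path))


def write_transitions(ledger: TransitionLedger, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        ledger.to_json(path)
    else:
        ledger.to_csv(path)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline settings: windows, widths, tolerances, labels, seed."""

    regions: dict = field(default_factory=dict)  # name -> (low, high) cm^-1
    lineshape: dict = field(default_factory=dict)  # technique -> (fwhm_G, fwhm_L)
    wls_mode: str = "single-parameter"
    tolerance_fingerprint: float = 40.0
    tolerance_high: float = 65.0
    tolerance_boundary: float = 2600.0
    label_thresholds: dict = field(
        default_factory=lambda: {"vs": 0.75, "s": 0.50, "m": 0.25, "w": 0.05}
    )
    output_dir: str = "vibspec-out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (low, high) in self.regions.items():
            if not low < high:
                raise ValueError(f"region {name!r} must satisfy low < high, got ({low}, {high})")
        order = [k for k in ("vs", "s", "m", "w") if k in self.label_thresholds]
        values = [self.label_thresholds[k] for k in order]
        extras = [v for k, v in self.label_thresholds.items() if k not in order]
        if sorted(values, reverse=True) != values or len(set(values + extras)) != len(values + extras):
            raise ValueError("label thresholds must be strictly decreasing (vs > s > m > w)")

    def tolerance_for(self, wavenumber: float) -> float:
        """Matching tolerance: looser above the fingerprint/CH boundary."""
        return self.tolerance_high if wavenumber > self.tolerance_boundary else self.tolerance_fingerprint

    def region(self, name: str) -> tuple[float, float]:
        if name not in self.regions:
            raise KeyError(f"unknown region {name!r}; known: {sorted(self.regions)}")
        low, high = self.regions[name]
        return float(low), float(high)

    def to_yaml(self, path=None) -> str | None:
        doc = asdict(self)
        doc["regions"] = {k: [float(v[0]), float(v[1])] for k, v in doc["regions"].items()}
        doc["lineshape"] = {k: [float(v[0]), float(v[1])] for k, v in doc["lineshape"].items()}
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is None:
            return text
        Path(path).write_text(text, encoding="utf-8")
        return None

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        doc = yaml.safe_load(text)
        doc["regions"] = {k: tuple(v) for k, v in doc.get("regions", {}).items()}
        doc["lineshape"] = {k: tuple(v) for k, v in doc.get("lineshape", {}).items()}
        return cls(**doc)


def menadione_study_config() -> RunConfig:
    """The shipped study configuration for crystalline menadione.

    Windows: the CH-stretching region (3600-2600), the two fundamental-free
    MIR windows (4000-3600 and 2800-1800), the fingerprint (1800-400) and
    the NIR range (7000-4000 cm^-1).
    """
    return RunConfig(
        regions={
            "ch_stretch": (2600.0, 3600.0),
            "above_ch": (3600.0, 4000.0),
            "fundamental_free_mir": (1800.0, 2800.0),
            "fingerprint": (400.0, 1800.0),
            "nir": (4000.0, 7000.0),
        },
        lineshape={"ATR": (8.0, 8.0), "DRIFT": (8.0, 8.0), "MIR": (8.0, 8.0), "NIR": (16.0, 16.0)},
    )


# --------------------------------------------------------------------------
# Study bundles
# --------------------------------------------------------------------------


def write_study(study, directory) -> Path:
    """Serialize a synthetic study: ledger CSV, spectrum JCAMP-DX, truth JSON, config YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study.ledger.to_csv(directory / "ledger.csv")
    write_spectrum(study.observed, directory / "observed.jdx", format="jcamp-dx")
    with open(directory / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(study.truth, fh, indent=1)
    cfg = asdict(study.config)
    cfg["regions"] = {k: [float(v[0]), float(v[1])] for k, v in cfg["regions"].items()}
    with open(directory / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return directory
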