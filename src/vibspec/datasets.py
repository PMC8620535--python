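"""Bundled transcriptions of published menadione assignment tables.

Four tables ship with the package as plain CSV, covering the fingerprint
fundamentals (two periodic harmonic methods), the CH-stretching region
(anharmonic, with the fundamental rows flagged) and the two fundamental-free
MIR windows.  Semicolon-separated cells reproduce the tables' grouping of
unresolved band features ("3075; 3070" is one experimental feature; "2009;
1997" two calculated transitions under one experimental envelope); that
grouping is part of the data and is preserved as :class:`BandFeature`
groups.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .assign import BandFeature
from .io import infer_class_from_label, _split_top_level
from .transitions import Transition, TransitionClass, TransitionLedger

__all__ = [
    "TABLES",
    "load_table",
    "table_features",
    "table_match_inputs",
    "table_ledger",
]

TABLES = {
    "fingerprint": "table1_fingerprint.csv",
    "ch_region": "table2_ch_region.csv",
    "above3600": "table3_above3600.csv",
    "mir_1800_2800": "table4_1800_2800.csv",
}

#: matching tolerance (cm^-1) appropriate for each table's spectral range
TABLE_TOLERANCES = {
    "fingerprint": 40.0,
    "ch_region": 65.0,
    "above3600": 65.0,
    "mir_1800_2800": 40.0,
}


def load_table(name: str) -> pd.DataFrame:
    """Raw transcription as a DataFrame (cells kept as strings)."""
    if name not in TABLES:
        raise KeyError(f"unknown table {name!r}; available: {sorted(TABLES)}")
    ref = resources.files("vibspec.data") / TABLES[name]
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype=str, keep_default_na=False)


def _cell_values(cell: str) -> tuple[float, ...]:
    cell = str(cell).replace("−", "-").strip().lstrip("~")
    if not cell:
        return ()
    return tuple(float(tok.strip().lstrip("~")) for tok in cell.split(";") if tok.strip())


def table_features(name: str, side: str, method: str | None = None) -> list[BandFeature]:
    """Band features for one column of a table, in printed (spectral) order.

    ``side`` is "exp" or "calc"; for the fingerprint table ``method``
    selects the harmonic variant ("gatti" or "tzvp").
    """
    frame = load_table(name)
    feats: list[BandFeature] = []
    if name == "fingerprint":
        if side == "exp":
            for _, row in frame.iterrows():
                feats.append(BandFeature(_cell_values(row["exp_position"]), label=row["assignment"]))
            return feats
        if method not in ("gatti", "tzvp"):
            raise ValueError("fingerprint table needs method='gatti' or 'tzvp'")
        for _, row in frame.iterrows():
            positions = _cell_values(row[f"{method}_position"])
            if not positions:
                continue
            feats.append(
                BandFeature(positions, _cell_values(row[f"{method}_intensity"]), row["assignment"])
            )
        return feats
    pos_col = "exp_positions" if side == "exp" else "calc_positions"
    int_col = "exp_intensity" if side == "exp" else "calc_intensity"
    for _, row in frame.iterrows():
        positions = _cell_values(row[pos_col])
        if not positions:
            continue
        intensities = _cell_values(row[int_col]) if int_col in frame.columns else ()
        feats.append(
            BandFeature(positions, intensities or None, row["assignment"])
        )
    return feats


def table_match_inputs(name: str, method: str | None = None) -> dict:
    """Everything needed to rerun and check a table's peak matching.

    Returns exp/calc features, the tolerance for the table's spectral
    range, and the printed signed differences flattened in row order.
    """
    frame = load_table(name)
    diff_col = {"gatti": "diff_gatti", "tzvp": "diff_tzvp"}.get(method or "", "difference")
    expected: list[int] = []
    for _, row in frame.iterrows():
        expected.extend(int(v) for v in _cell_values(row[diff_col]))
    return {
        "exp": table_features(name, "exp"),
        "calc": table_features(name, "calc", method=method),
        "tolerance": TABLE_TOLERANCES[name],
        "expected_differences": expected,
    }


def _class_for_row(label: str, fundamental_flag: str | None) -> TransitionClass:
    if fundamental_flag is not None and str(fundamental_flag).strip() == "1":
        return TransitionClass.FUNDAMENTAL
    alternatives = _split_top_level(str(label), ";") or [""]
    classes = [infer_class_from_label(a) for a in alternatives]
    if fundamental_flag is not None and str(fundamental_flag).strip() == "0":
        # an overlapped feature not flagged as fundamental keeps its
        # non-fundamental reading (e.g. the dual-assigned 3063 cm^-1 band)
        for c in classes:
            if c is not TransitionClass.FUNDAMENTAL:
                return c
    return classes[0]


def table_ledger(name: str, method: str | None = None) -> TransitionLedger:
    """Calculated transitions of a table as a ledger (no quanta available)."""
    frame = load_table(name)
    flag_col = "fundamental" if "fundamental" in frame.columns else None
    transitions = []
    if name == "fingerprint":
        if method not in ("gatti", "tzvp"):
            raise ValueError("fingerprint table needs method='gatti' or 'tzvp'")
        pos_col, int_col = f"{method}_position", f"{method}_intensity"
    else:
        pos_col, int_col = "calc_positions", "calc_intensity"
    for _, row in frame.iterrows():
        positions = _cell_values(row[pos_col])
        intensities = _cell_values(row[int_col])
        if not positions:
            continue
        if len(intensities) < len(positions):
            intensities = intensities + (intensities[-1],) * (len(positions) - len(intensities)) if intensities else (0.0,) * len(positions)
        label = str(row["assignment"])
        alternatives = _split_top_level(label, ";")
        for k, (p, i) in enumerate(zip(positions, intensities)):
            if name == "fingerprint":
                tclass = TransitionClass.FUNDAMENTAL
            elif len(positions) > 1 and len(alternatives) == len(positions):
                # one alternative per calculated transition (e.g. "2009; 1997")
                tclass = infer_class_from_label(alternatives[k])
            else:
                tclass = _class_for_row(label, row[flag_col] if flag_col else None)
            transitions.append(
                Transition(position=p, intensity=i, transition_class=tclass, label=label)
            )
    return TransitionLedger(transitions, provenance=f"published table: {name}" + (f" ({method})" if method else ""))
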