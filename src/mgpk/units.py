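"""Unit conversions for serum magnesium and magnesium sulfate doses.

All model-internal concentrations are mg/L of elemental magnesium; the
clinical literature reports serum magnesium in mmol/L and doses as labeled
grams of the magnesium sulfate salt. Conversion constants live here so that
every module agrees on them.
"""

from __future__ import annotations

#: molar mass of elemental magnesium, g/mol — 1 mmol/L of Mg2+ is this many mg/L
MG_PER_MMOL: float = 24.305

#: mg of elemental Mg per labeled gram of salt, by hydration state
SALT_MG_PER_G: dict[str, float] = {
    # MgSO4·7H2O, MW 246.47 — the form used in clinical injection solutions
    "heptahydrate": 1000.0 * 24.305 / 246.47,
    # anhydrous MgSO4, MW 120.366
    "anhydrous": 1000.0 * 24.305 / 120.366,
}

#: default salt factor (mg elemental Mg per labeled gram), heptahydrate
DEFAULT_SALT_FACTOR: float = SALT_MG_PER_G["heptahydrate"]

#: therapeutic window for seizure prophylaxis, mmol/L total serum magnesium
THERAPEUTIC_WINDOW_MMOL: tuple[float, float] = (2.0, 3.5)

#: typical baseline (endogenous) serum magnesium in preeclampsia, mmol/L
DEFAULT_BASELINE_MMOL: float = 0.76


def mmol_to_mg(x):
    """mmol/L of Mg2+ -> mg/L of elemental Mg."""
    return x * MG_PER_MMOL


def mg_to_mmol(x):
    """mg/L of elemental Mg -> mmol/L of Mg2+."""
    return x / MG_PER_MMOL


def grams_to_mg_elemental(grams, salt_factor: float = DEFAULT_SALT_FACTOR):
    """Labeled grams of MgSO4 dose -> mg of elemental magnesium."""
    return grams * salt_factor
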