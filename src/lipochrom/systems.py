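"""Chromatographic system descriptions and the 13-system study design.

Systems are labelled ``<T|C>-<PHASE>-<MOD>`` (T = planar HPTLC, C = column
HPLC; modifier codes MET/ACN/ACE/DIO); the buffered biomimetic columns
(IAM, cholesterol) omit the modifier code.  Coefficient columns derived
from a system append ``-R`` (intercept) or ``-S`` (slope), e.g.
``T-C18-MET-R`` or ``C-CHOL-S``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ChromSystem", "STUDY_SYSTEMS", "systems_frame"]

_TECHNIQUES = {"HPTLC", "HPLC"}
_PHASES = {"C8", "C18", "IAM", "Chol"}
_MODIFIERS = {"MeOH", "ACN", "acetone", "dioxane"}
_AQUEOUS = {"water", "buffer"}
_MOD_CODE = {"MeOH": "MET", "ACN": "ACN", "acetone": "ACE", "dioxane": "DIO"}


@dataclass(frozen=True)
class ChromSystem:
    """One isocratic reversed-phase system with its modifier grid.

    ``phi_min``/``phi_max``/``phi_step`` define the organic-modifier volume
    fractions at which retention is measured (all within (0, 1)); a buffered
    aqueous phase must carry its pH.
    """

    id: str
    technique: str
    stationary_phase: str
    modifier: str
    aqueous_phase: str = "water"
    pH: float | None = None
    phi_min: float = 0.4
    phi_max: float = 0.9
    phi_step: float = 0.05

    def __post_init__(self) -> None:
        if self.technique not in _TECHNIQUES:
            raise ValueError(f"{self.id}: unknown technique {self.technique!r}")
        if self.stationary_phase not in _PHASES:
            raise ValueError(f"{self.id}: unknown phase {self.stationary_phase!r}")
        if self.modifier not in _MODIFIERS:
            raise ValueError(f"{self.id}: unknown modifier {self.modifier!r}")
        if self.aqueous_phase not in _AQUEOUS:
            raise ValueError(f"{self.id}: unknown aqueous phase {self.aqueous_phase!r}")
        if not (0.0 < self.phi_min <= self.phi_max < 1.0):
            raise ValueError(f"{self.id}: phi range must lie inside (0, 1)")
        if self.aqueous_phase == "buffer" and self.pH is None:
            raise ValueError(f"{self.id}: buffered aqueous phase requires a pH")

    def phi_grid(self) -> np.ndarray:
        """Modifier volume fractions of the design, inclusive of both ends."""
        n = int(round((self.phi_max - self.phi_min) / self.phi_step)) + 1
        return np.round(self.phi_min + self.phi_step * np.arange(n), 10)

    def column_label(self, coefficient: str) -> str:
        """Fig-style coefficient label, coefficient in {'R', 'S'}."""
        if coefficient not in ("R", "S"):
            raise ValueError("coefficient must be 'R' or 'S'")
        return f"{self.id}-{coefficient}"


def _label(technique: str, phase: str, modifier: str) -> str:
    t = "T" if technique == "HPTLC" else "C"
    if phase in ("IAM", "Chol"):
        return f"C-{phase.upper()}"
    return f"{t}-{phase}-{_MOD_CODE[modifier]}"


def _sys(technique, phase, modifier, lo, hi, step, aqueous="water", pH=None):
    return ChromSystem(_label(technique, phase, modifier), technique, phase,
                       modifier, aqueous, pH, lo, hi, step)


#: The 13 systems of the study design, in report order: eight planar
#: (C18 / C8 plates with four modifiers), then five column systems
#: including the buffered pH 7.4 C18, IAM and cholesterol phases.
STUDY_SYSTEMS: tuple[ChromSystem, ...] = (
    _sys("HPTLC", "C18", "MeOH", 0.60, 0.90, 0.05),
    _sys("HPTLC", "C18", "ACN", 0.50, 0.90, 0.05),
    _sys("HPTLC", "C18", "acetone", 0.50, 0.90, 0.05),
    _sys("HPTLC", "C18", "dioxane", 0.40, 0.80, 0.05),
    _sys("HPTLC", "C8", "MeOH", 0.50, 0.90, 0.05),
    _sys("HPTLC", "C8", "ACN", 0.45, 0.70, 0.05),
    _sys("HPTLC", "C8", "acetone", 0.50, 0.80, 0.05),
    _sys("HPTLC", "C8", "dioxane", 0.50, 0.80, 0.05),
    _sys("HPLC", "C18", "MeOH", 0.40, 0.90, 0.10, "buffer", 7.4),
    _sys("HPLC", "C8", "MeOH", 0.60, 0.90, 0.05),
    _sys("HPLC", "C8", "ACN", 0.35, 0.90, 0.05),
    _sys("HPLC", "IAM", "ACN", 0.05, 0.40, 0.05, "buffer", 7.4),
    _sys("HPLC", "Chol", "MeOH", 0.30, 0.80, 0.10, "buffer", 7.4),
)


def systems_frame(systems=STUDY_SYSTEMS) -> pd.DataFrame:
    """System metadata as a DataFrame (the ``systems.csv`` dialect)."""
    rows = [{
        "system_id": s.id,
        "technique": s.technique,
        "stationary_phase": s.stationary_phase,
        "modifier": s.modifier,
        "aqueous_phase": s.aqueous_phase,
        "pH": s.pH,
        "phi_min": s.phi_min,
        "phi_max": s.phi_max,
        "phi_step": s.phi_step,
    } for s in systems]
    return pd.DataFrame(rows)
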