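"""Registry of assigned lipid resonances in 1D proton spectra.

Each entry ties a chemical-shift window to a fatty-acyl or head-group
functional group and, where the proton count contributing to the signal is
determined, to a lipid class that can be quantified absolutely:

====== ======================== ============================ =========
ppm    functional group         lipid class                  protons
====== ======================== ============================ =========
5.30   -CH=CH- (olefinic)       unsaturated chains           2 per C=C
4.21   glycerol C1/C3 H2        triglycerides (TG)           4
3.48   -N(CH3)3 (choline)       PC + LPC                     9
3.40   -CH2-NH3+                phosphatidylethanolamine     2
2.80   =CH-CH2-CH= (diallylic)  polyunsaturated chains       2 per pair
2.25   alpha-carboxyl -CH2-     all acyl chains              2
2.02   allylic -CH2-            unsaturated chains           4 per chain
1.58   beta-carboxyl -CH2-      all acyl chains              2
1.30   bulk (-CH2-)n            all acyl chains              variable
0.98   terminal -CH3            omega-3 fatty acids          3
0.90   terminal -CH3            fatty acids (non omega-3)    3
0.68   C18 -CH3                 total cholesterol (TC)       3
====== ======================== ============================ =========

The TG glycerol window is 4.12-4.30 ppm; the two terminal-methyl windows
are split at 0.94 ppm. Windows are pairwise non-overlapping (shared
endpoints carry zero measure under trapezoidal integration).
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectra import PeakWindow

__all__ = [
    "LipidAssignment",
    "lipid_line_catalog",
    "catalog_windows",
    "catalog_window",
    "QUANTIFIED_CLASS_PEAKS",
    "ACYL_PEAK_IDS",
]


@dataclass(frozen=True)
class LipidAssignment:
    """A catalogued resonance: window, functional group, class, protons.

    ``protons`` is the number of protons contributing to the signal per
    molecule of the assigned lipid class, or ``None`` when the count is
    not determined (signal reported as relative abundance only).
    """

    window: PeakWindow
    functional_group: str
    lipid_class: str
    protons: int | None = None

    @property
    def peak_id(self) -> str:
        return self.window.peak_id


_CATALOG: tuple[LipidAssignment, ...] = (
    LipidAssignment(
        PeakWindow("TC_0.68", 0.62, 0.74, 0.68), "(-CH3) C18", "TC", 3
    ),
    LipidAssignment(
        PeakWindow("CH3_0.90", 0.86, 0.94, 0.90), "(-CH3) terminal", "FA", 3
    ),
    LipidAssignment(
        PeakWindow("CH3_0.98", 0.94, 1.02, 0.98), "(-CH3) terminal", "OMEGA3", 3
    ),
    LipidAssignment(
        PeakWindow("CH2_1.3", 1.15, 1.45, 1.30), "(-CH2-)n bulk", "acyl_chain", None
    ),
    LipidAssignment(
        PeakWindow("CH2_1.6", 1.50, 1.70, 1.58), "(-CH2-CH2-COO) beta", "acyl_chain", None
    ),
    LipidAssignment(
        PeakWindow("CH2_2.0", 1.92, 2.12, 2.02), "(-CH2-CH=) allylic", "acyl_chain", None
    ),
    LipidAssignment(
        PeakWindow("CH2_2.25", 2.16, 2.34, 2.25), "(-CH2-COO) alpha", "acyl_chain", None
    ),
    LipidAssignment(
        PeakWindow("CH2_2.8", 2.70, 2.90, 2.80), "(=CH-CH2-CH=) diallylic", "acyl_chain", None
    ),
    LipidAssignment(
        PeakWindow("PE_3.40", 3.35, 3.44, 3.40), "(-CH2-NH3+)", "PE", 2
    ),
    LipidAssignment(
        PeakWindow("choline_3.48", 3.44, 3.52, 3.48), "(-N(CH3)3)", "PC_LPC", 9
    ),
    LipidAssignment(
        PeakWindow("TG_glycerol_4.2", 4.12, 4.30, 4.21), "(-C1H2);(-C3H2) glycerol", "TG", 4
    ),
    LipidAssignment(
        PeakWindow("olefinic_5.3", 5.20, 5.40, 5.30), "(-CH=CH-) olefinic", "acyl_chain", None
    ),
)

#: Marker peak used for the absolute quantification of each lipid class.
QUANTIFIED_CLASS_PEAKS: dict[str, str] = {
    "TG": "TG_glycerol_4.2",
    "PC_LPC": "choline_3.48",
    "PE": "PE_3.40",
    "OMEGA3": "CH3_0.98",
    "FA": "CH3_0.90",
    "TC": "TC_0.68",
}

#: Peaks fed by fatty-acyl chain protons (the FA pool).
ACYL_PEAK_IDS: tuple[str, ...] = (
    "olefinic_5.3",
    "CH2_2.8",
    "CH2_2.25",
    "CH2_2.0",
    "CH2_1.6",
    "CH2_1.3",
    "CH3_0.98",
    "CH3_0.90",
)


def lipid_line_catalog() -> list[LipidAssignment]:
    """Return the fixed registry of assigned lipid resonances."""
    return list(_CATALOG)


def catalog_windows() -> dict[str, PeakWindow]:
    """Map peak id -> integration window for every catalogued resonance."""
    return {a.peak_id: a.window for a in _CATALOG}


def catalog_window(peak_id: str) -> PeakWindow:
    """Window for a single catalogued peak id."""
    for a in _CATALOG:
        if a.peak_id == peak_id:
            return a.window
    raise KeyError(f"unknown catalog peak {peak_id!r}")
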