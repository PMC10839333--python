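"""In vivo liver MRS measurands.

Four quantities are extracted from a water-suppressed / unsuppressed
voxel spectrum pair acquired at 7 T:

* **IHLC** -- intrahepatic lipid content, the ratio of the bulk methylene
  peak area (~1.3 ppm) to the water peak area (~4.7 ppm) in the
  *unsuppressed* spectrum;
* **TG index** -- ``(A_4.3 + A_4.1) / 4``, the triglyceride glycerol
  signal of the *suppressed* spectrum divided by its 4 contributing
  protons;
* **FA composition indices** -- ratio-form indices (SI, ndb, UFA, SFA,
  PUFA, MUFA, MCL) computed from the acyl peak areas of the suppressed
  spectrum;
* **water FWHM** -- the water linewidth in Hz, an indirect proxy for
  hepatic iron load (paramagnetic iron shortens T2 and broadens the
  line).

Index definitions are configuration data (:class:`IndexDefinition`); the
shipped defaults are forced by acyl-chain proton stoichiometry with 3
methyl protons per chain and A_x the area at x ppm:

========  =================================================
ndb       1.5 * A5.3 / A0.9
SI        A1.3 / A5.3
UFA       0.75 * A2.0 / A0.9
SFA       1 - UFA
PUFA      1.5 * A2.8 / A0.9
MUFA      UFA - PUFA (floored at 0)
MCL       1.5 * (A1.3 + A1.6 + A2.0 + A2.25 + A2.8 + 2*A5.3) / A0.9 + 2
========  =================================================

The MCL numerator counts the olefinic area twice because each olefinic
CH carries one proton where a saturated chain would carry a CH2: the
identity 2L - 4 = (non-methyl protons) + (olefinic protons) makes the
formula exact for any methylene-interrupted chain. On pure 16:0 / 18:1 /
18:2 chains the defaults return ndb = 0/1/2, UFA = 0/1/1, PUFA = 0/0/1
and MCL = 16/18/18 exactly. Undefined indices (zero denominator)
propagate as missing values, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import catalog_window, catalog_windows
from .errors import AcquisitionError, ConfigurationError
from .spectra import FwhmEstimate, PeakTable, PeakWindow, Spectrum1D, integrate, peak_fwhm

__all__ = [
    "IndexDefinition",
    "MrsMeasurands",
    "WATER_WINDOW",
    "METHYLENE_WINDOW",
    "GLYCEROL_41_WINDOW",
    "GLYCEROL_43_WINDOW",
    "default_index_definitions",
    "compute_ihlc",
    "compute_tg_index",
    "compute_fa_indices",
    "water_fwhm_iron_proxy",
    "acyl_peak_table",
    "measure_liver_pair",
]

#: Water peak window, 4.7 +/- 0.5 ppm.
WATER_WINDOW = PeakWindow("water_4.7", 4.2, 5.2, 4.7)
#: Bulk methylene window, 1.3 +/- 0.15 ppm.
METHYLENE_WINDOW = PeakWindow("CH2_1.3", 1.15, 1.45, 1.30)
#: TG glycerol windows of the in vivo spectrum.
GLYCEROL_41_WINDOW = PeakWindow("TG_glycerol_4.1", 4.05, 4.15, 4.10)
GLYCEROL_43_WINDOW = PeakWindow("TG_glycerol_4.3", 4.25, 4.35, 4.30)


@dataclass(frozen=True)
class IndexDefinition:
    """A ratio-form fatty-acid index: offset + num / den over peak areas.

    ``numerator`` and ``denominator`` are lists of ``(peak_id, coeff)``;
    ``clip_min`` optionally floors the result (used by MUFA).
    """

    name: str
    numerator: tuple[tuple[str, float], ...]
    denominator: tuple[tuple[str, float], ...]
    offset: float = 0.0
    clip_min: float | None = None

    def __post_init__(self) -> None:
        if not self.denominator:
            raise ValueError(f"index {self.name}: empty denominator")
        for _, c in (*self.numerator, *self.denominator):
            if not np.isfinite(c):
                raise ValueError(f"index {self.name}: non-finite coefficient")

    def evaluate(self, peaks: PeakTable) -> float:
        num = sum(c * peaks[pid] for pid, c in self.numerator)
        den = sum(c * peaks[pid] for pid, c in self.denominator)
        if den == 0:
            return math.nan
        val = self.offset + num / den
        if self.clip_min is not None:
            val = max(val, self.clip_min)
        return val


def default_index_definitions() -> tuple[IndexDefinition, ...]:
    """The stoichiometric default index set (see module docstring)."""
    A09 = (("CH3_0.90", 1.0),)
    mcl_num = (
        ("CH2_1.3", 1.5),
        ("CH2_1.6", 1.5),
        ("CH2_2.0", 1.5),
        ("CH2_2.25", 1.5),
        ("CH2_2.8", 1.5),
        ("olefinic_5.3", 3.0),
    )
    return (
        IndexDefinition("SI", (("CH2_1.3", 1.0),), (("olefinic_5.3", 1.0),)),
        IndexDefinition("ndb", (("olefinic_5.3", 1.5),), A09),
        IndexDefinition("UFA", (("CH2_2.0", 0.75),), A09),
        IndexDefinition("SFA", (("CH2_2.0", -0.75),), A09, offset=1.0),
        IndexDefinition("PUFA", (("CH2_2.8", 1.5),), A09),
        IndexDefinition(
            "MUFA", (("CH2_2.0", 0.75), ("CH2_2.8", -1.5)), A09, clip_min=0.0
        ),
        IndexDefinition("MCL", mcl_num, A09, offset=2.0),
    )


@dataclass
class MrsMeasurands:
    """Per-voxel liver measurands: lipid content, TG, indices, linewidth."""

    ihlc: float
    tg_index: float
    indices: dict[str, float]
    water_fwhm_hz: float

    def __post_init__(self) -> None:
        if self.ihlc < 0 or self.tg_index < 0:
            raise ValueError("ihlc and tg_index must be >= 0")


def _require_modality(spec: Spectrum1D, modality: str, op: str) -> None:
    if spec.modality != modality:
        raise ConfigurationError(
            f"{op} requires a {modality} spectrum, got {spec.modality!r}"
        )


def compute_ihlc(unsuppressed: Spectrum1D) -> float:
    """Intrahepatic lipid content: CH2 (1.3 ppm) over water (4.7 ppm)
    baseline-corrected integral areas of the unsuppressed spectrum."""
    _require_modality(unsuppressed, "mrs_unsuppressed", "compute_ihlc")
    water = integrate(unsuppressed, WATER_WINDOW, baseline=True)
    if water <= 0:
        raise AcquisitionError("water peak area is zero: failed acquisition")
    lipid = integrate(unsuppressed, METHYLENE_WINDOW, baseline=True)
    return lipid / water

def compute_tg_index(suppressed: Spectrum1D) -> float:
    """Triglyceride signal of the suppressed spectrum:
    (A_4.3ppm + A_4.1ppm) / 4, the divisor being the number of glycerol
    protons behind the two peaks."""
    _require_modality(suppressed, "mrs_suppressed", "compute_tg_index")
    a41 = integrate(suppressed, GLYCEROL_41_WINDOW, baseline=True)
    a43 = integrate(suppressed, GLYCEROL_43_WINDOW, baseline=True)
    return (a43 + a41) / 4.0


def compute_fa_indices(
    peaks: PeakTable,
    defs: tuple[IndexDefinition, ...] | None = None,
) -> dict[str, float]:
    """Evaluate FA composition indices on a peak table.

    Returns NaN for an index whose denominator evaluates to zero
    (reported as missing, not as 0).
    """
    if defs is None:
        defs = default_index_definitions()
    for d in defs:
        for pid, _ in (*d.numerator, *d.denominator):
            if pid not in peaks.entries:
                raise ConfigurationError(
                    f"index {d.name} references missing peak {pid!r}"
                )
    return {d.name: d.evaluate(peaks) for d in defs}


def water_fwhm_iron_proxy(unsuppressed: Spectrum1D) -> FwhmEstimate:
    """Water linewidth of the unsuppressed spectrum (iron-load proxy)."""
    _require_modality(unsuppressed, "mrs_unsuppressed", "water_fwhm_iron_proxy")
    return peak_fwhm(unsuppressed, WATER_WINDOW)


def acyl_peak_table(suppressed: Spectrum1D) -> PeakTable:
    """Integrate every catalog window of a suppressed voxel spectrum."""
    _require_modality(suppressed, "mrs_suppressed", "acyl_peak_table")
    entries = {
        pid: integrate(suppressed, w, baseline=True)
        for pid, w in catalog_windows().items()
    }
    return PeakTable(entries=entries, source=suppressed.label)


def measure_liver_pair(
    suppressed: Spectrum1D,
    unsuppressed: Spectrum1D,
    defs: tuple[IndexDefinition, ...] | None = None,
) -> MrsMeasurands:
    """All liver measurands from a voxel spectrum pair."""
    return MrsMeasurands(
        ihlc=compute_ihlc(unsuppressed),
        tg_index=compute_tg_index(suppressed),
        indices=compute_fa_indices(acyl_peak_table(suppressed), defs),
        water_fwhm_hz=water_fwhm_iron_proxy(unsuppressed).fwhm_hz,
    )
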