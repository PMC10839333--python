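"""Ex vivo absolute and relative lipid quantification against external
standards.

A metabolite area integrated from a tissue-extract spectrum is converted
to a millimolar concentration through a reference compound of known
concentration acquired separately::

    Conc_met = Conc_st * A_met * m / (A_st * m_st),    m = T * P1 / (RG * NS)

where ``m`` and ``m_st`` are the acquisition factors of the sample and
standard spectra (temperature, 90-degree pulse length, receiver gain,
number of scans). Concentrations are then normalised to tissue weight --
dry weight for liver, fresh weight for adipose tissue -- giving
mM per mg. Standards are reconstituted at 10 mM (36.7 mM for the TG
standard).

The shipped standards registry (``data/standards_synthetic.tsv``) is a
synthetic stand-in with the 21-molecule / 11-class structure of an
in-house lipid database; reference areas are not stored but computed at
load time by simulating each representative standard solution
noiselessly and integrating its marker window, so registry and simulator
can never drift apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .catalog import QUANTIFIED_CLASS_PEAKS, catalog_window, catalog_windows
from .errors import ConfigurationError, MetadataError, UndefinedStatisticError
from .spectra import (
    AcquisitionParams,
    PeakTable,
    Spectrum1D,
    integrate,
    total_area,
)
from .synthetic import (
    DEFAULT_EXTRACT_ACQ,
    DEFAULT_SPECIES,
    LipidMixture,
    simulate_extract_spectrum,
)

__all__ = [
    "StandardRecord",
    "SampleMeta",
    "QuantResult",
    "acquisition_factor",
    "concentration_from_standard",
    "quantify_lipid_classes",
    "relative_abundances",
    "total_lipid_content",
    "load_standards_registry",
    "build_standard_records",
]


def acquisition_factor(acq: AcquisitionParams) -> float:
    """The normalisation factor m = T * P1 / (RG * NS)."""
    return acq.T * acq.P1 / (acq.RG * acq.NS)


@dataclass(frozen=True)
class StandardRecord:
    """An external standard: molecule, class, concentration, reference
    area and the acquisition under which that area was measured."""

    molecule: str
    lipid_class: str
    conc_st: float
    acq_st: AcquisitionParams
    area_st: float
    peak_id: str

    def __post_init__(self) -> None:
        if not self.conc_st > 0:
            raise ValueError("conc_st must be > 0")
        if not self.area_st > 0:
            raise ValueError("area_st must be > 0")


@dataclass(frozen=True)
class SampleMeta:
    """Per-animal sample metadata and the weight basis for normalisation.

    Liver concentrations are reported per mg dry weight, adipose tissue
    per mg fresh weight; ``weight_basis`` defaults accordingly.
    """

    animal_id: str
    genotype: str
    age_months: int
    tissue: str
    fresh_weight_mg: float | None = None
    dry_weight_mg: float | None = None
    weight_basis: str | None = None

    def __post_init__(self) -> None:
        if self.tissue not in ("liver", "perigonadal_AT"):
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.weight_basis is None:
            basis = "dry" if self.tissue == "liver" else "fresh"
            object.__setattr__(self, "weight_basis", basis)
        if self.weight_basis not in ("fresh", "dry"):
            raise ValueError(f"weight_basis must be fresh|dry, got {self.weight_basis!r}")

    def weight(self) -> float:
        w = self.dry_weight_mg if self.weight_basis == "dry" else self.fresh_weight_mg
        if w is None or not w > 0:
            raise MetadataError(
                f"{self.animal_id}: {self.weight_basis} weight missing or <= 0 "
                f"for declared basis"
            )
        return float(w)


@dataclass
class QuantResult:
    """Absolute per-class concentrations (mM per mg on the declared
    basis), relative abundances over catalog peaks, and total lipid."""

    class_concentrations: dict[str, float]
    relative_abundance: dict[str, float] | None
    total_lipid: float
    weight_basis: str


def concentration_from_standard(
    area_met: float,
    acq_met: AcquisitionParams,
    std: StandardRecord,
) -> float:
    """Conc_met = Conc_st * A_met * m / (A_st * m_st), in mM."""
    if area_met < 0:
        raise ValueError("area_met must be >= 0")
    m = acquisition_factor(acq_met)
    m_st = acquisition_factor(std.acq_st)
    return std.conc_st * area_met * m / (std.area_st * m_st)


def relative_abundances(peaks: PeakTable) -> dict[str, float]:
    """Fraction of the summed peak area carried by each peak."""
    total = sum(peaks.entries.values())
    if total <= 0:
        raise UndefinedStatisticError("all peak areas are zero")
    return {pid: a / total for pid, a in peaks.entries.items()}


def total_lipid_content(spec: Spectrum1D, meta: SampleMeta) -> float:
    """Total spectrum area (reference line excluded) per mg of tissue."""
    return total_area(spec) / meta.weight()


def quantify_lipid_classes(
    spec: Spectrum1D,
    meta: SampleMeta,
    standards: dict[str, StandardRecord],
) -> QuantResult:
    """Quantify the six marker lipid classes of an extract spectrum.

    The spectrum must already be referenced to chloroform at 7.26 ppm.
    Each class marker window is integrated (linear edge baseline), the
    external-standard formula applied, and the result divided by the
    tissue weight on the declared basis. Relative abundances over all
    catalog peaks and the weight-normalised total area are also
    returned; an all-zero spectrum yields zero concentrations and a
    flagged (``None``) relative-abundance map.
    """
    if spec.acquisition is None:
        raise MetadataError("spectrum has no acquisition metadata (m undefined)")
    missing = [c for c in QUANTIFIED_CLASS_PEAKS if c not in standards]
    if missing:
        raise ConfigurationError(f"no standard for classes: {', '.join(missing)}")

    concentrations: dict[str, float] = {}
    weight = meta.weight()
    for cls, pid in QUANTIFIED_CLASS_PEAKS.items():
        std = standards[cls]
        if std.peak_id != pid:
            raise ConfigurationError(
                f"standard for {cls} integrates {std.peak_id!r}, expected {pid!r}"
            )
        area = integrate(spec, catalog_window(pid), baseline=True)
        concentrations[cls] = concentration_from_standard(area, spec.acquisition, std) / weight

    all_areas = PeakTable(
        entries={
            pid: integrate(spec, w, baseline=True)
            for pid, w in catalog_windows().items()
        },
        source=spec.label,
    )
    try:
        rel = relative_abundances(all_areas)
    except UndefinedStatisticError:
        warnings.warn("zero-signal spectrum: relative abundances undefined", stacklevel=2)
        rel = None
    return QuantResult(
        class_concentrations=concentrations,
        relative_abundance=rel,
        total_lipid=total_lipid_content(spec, meta),
        weight_basis=meta.weight_basis,
    )


# ---------------------------------------------------------------------------
# standards registry
# ---------------------------------------------------------------------------

def load_standards_registry() -> pd.DataFrame:
    """Load the packaged 21-molecule / 11-class standards registry."""
    with resources.files("lipospec.data").joinpath("standards_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def _standard_mixture(cls: str, conc: float) -> LipidMixture:
    """Single-compound solution of the representative standard of a class."""
    if cls == "FA":
        return LipidMixture({DEFAULT_SPECIES["oleate"]: 1.0}, {"FA": conc})
    if cls == "OMEGA3":
        return LipidMixture({DEFAULT_SPECIES["alpha_linolenate"]: 1.0}, {"FA": conc})
    return LipidMixture({}, {cls: conc})


def build_standard_records(
    acq_st: AcquisitionParams = DEFAULT_EXTRACT_ACQ,
    base_scale: float = 1.0,
) -> dict[str, StandardRecord]:
    """Reference records for the six quantified classes.

    Each representative standard solution is simulated noiselessly under
    ``acq_st`` and its marker window integrated to obtain ``area_st``.
    """
    registry = load_standards_registry()
    reps = registry[registry["representative"] == 1]
    records: dict[str, StandardRecord] = {}
    for _, row in reps.iterrows():
        cls = row["lipid_class"]
        if cls not in QUANTIFIED_CLASS_PEAKS:
            continue
        conc = float(row["conc_mM"])
        spec = simulate_extract_spectrum(
            _standard_mixture(cls, conc), acq=acq_st, base_scale=base_scale
        )
        pid = QUANTIFIED_CLASS_PEAKS[cls]
        area = integrate(spec, catalog_window(pid), baseline=True)
        records[cls] = StandardRecord(
            molecule=row["molecule"],
            lipid_class=cls,
            conc_st=conc,
            acq_st=acq_st,
            area_st=area,
            peak_id=pid,
        )
    return records
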