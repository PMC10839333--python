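"""Synthetic spectra and cohorts with analytic oracles.

The generator produces the three kinds of input the analysis pipeline
consumes, at realistic parameter values, so every downstream stage is
testable without any instrument data:

* **tissue-extract spectra** (600 MHz, chloroform-referenced) whose line
  areas follow exact proton stoichiometry (:func:`expected_peak_areas`),
  so window integration can be checked against a closed form;
* **liver voxel spectra** (7 T), a water-suppressed / unsuppressed pair
  with a dominant water line of tunable width and lipid lines of tunable
  saturation profile;
* **two-genotype, two-age cohorts** whose per-animal measurands are drawn
  from group means and SDs (truncated normal, floored at zero).

Simulator conventions
---------------------
Lines are rendered as area-normalised Gaussians by default (the
Gaussian-apodised processing used on real extract spectra produces
near-Gaussian lines, and Gaussian tails keep essentially all line area
inside the narrow catalog windows); a Lorentzian option exists. The
overall extract signal is scaled by ``RG*NS/(T*P1)`` -- the reciprocal of
the acquisition factor m -- so that external-standard quantification has
to apply the m-correction non-trivially. This is a simulator convention,
not a physical model of the receiver chain.

Acyl-chain proton stoichiometry (per chain of length L with d
methylene-interrupted double bonds): olefinic 2d, diallylic 2*max(d-1,0),
allylic 4 if d>=1 else 0, alpha-CH2 2, beta-CH2 2, terminal CH3 3 (at
0.98 ppm for omega-3 chains, 0.90 ppm otherwise), bulk CH2 the remainder
of 2L-1-2d. Head-group markers contribute 4 (TG glycerol), 9 (choline),
2 (PE) and 3 (cholesterol C18) protons per molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ACYL_PEAK_IDS, QUANTIFIED_CLASS_PEAKS, catalog_windows, lipid_line_catalog
from .spectra import (
    CHLOROFORM_PPM,
    HR_NMR_FREQ_MHZ,
    MRS_FREQ_MHZ,
    AcquisitionParams,
    PeakTable,
    Spectrum1D,
)

__all__ = [
    "FattyAcylSpecies",
    "LipidMixture",
    "CohortGroup",
    "CohortSpec",
    "CohortResult",
    "DEFAULT_SPECIES",
    "DEFAULT_EXTRACT_ACQ",
    "DEFAULT_MRS_ACQ",
    "expected_peak_areas",
    "marker_concentrations",
    "simulate_extract_spectrum",
    "simulate_liver_mrs_pair",
    "simulate_cohort",
    "lipid_line_catalog",
]


# ---------------------------------------------------------------------------
# species and mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FattyAcylSpecies:
    """A fatty-acyl chain: length, unsaturation, omega-3 flag.

    Double bonds are assumed methylene-interrupted (the biological
    arrangement), so the number of diallylic CH2 groups is
    ``max(n_double_bonds - 1, 0)``.
    """

    name: str
    chain_length: int
    n_double_bonds: int = 0
    omega3: bool = False

    def __post_init__(self) -> None:
        if self.chain_length < 4:
            raise ValueError("chain_length must be >= 4")
        if self.n_double_bonds < 0:
            raise ValueError("n_double_bonds must be >= 0")
        if self._bulk_protons() < 0:
            raise ValueError(
                f"{self.name}: unsaturation too high for chain length "
                f"(negative bulk CH2 count)"
            )

    @property
    def n_diallylic_CH2(self) -> int:
        return max(self.n_double_bonds - 1, 0)

    @property
    def total_protons(self) -> int:
        """Chain protons from C2 to the terminal methyl: 2L - 1 - 2d."""
        return 2 * self.chain_length - 1 - 2 * self.n_double_bonds

    def _bulk_protons(self) -> int:
        d = self.n_double_bonds
        assigned = (
            2 * d                       # olefinic CH
            + 2 * max(d - 1, 0)         # diallylic CH2
            + (4 if d >= 1 else 0)      # outer allylic CH2
            + 2                         # alpha CH2
            + 2                         # beta CH2
            + 3                         # terminal CH3
        )
        return self.total_protons - assigned

    def proton_counts(self) -> dict[str, int]:
        """Protons contributed to each catalog peak, per chain."""
        d = self.n_double_bonds
        counts = {
            "olefinic_5.3": 2 * d,
            "CH2_2.8": 2 * max(d - 1, 0),
            "CH2_2.0": 4 if d >= 1 else 0,
            "CH2_2.25": 2,
            "CH2_1.6": 2,
            "CH2_1.3": self._bulk_protons(),
            "CH3_0.98": 3 if self.omega3 else 0,
            "CH3_0.90": 0 if self.omega3 else 3,
        }
        return counts


#: Default acyl species: the abundant chains of mammalian tissue lipids.
DEFAULT_SPECIES: dict[str, FattyAcylSpecies] = {
    s.name: s
    for s in (
        FattyAcylSpecies("palmitate", 16, 0),
        FattyAcylSpecies("stearate", 18, 0),
        FattyAcylSpecies("oleate", 18, 1),
        FattyAcylSpecies("linoleate", 18, 2),
        FattyAcylSpecies("alpha_linolenate", 18, 3, omega3=True),
    )
}

#: Lipid classes carrying a concentration in a mixture.
MIXTURE_CLASSES = ("TG", "PC_LPC", "PE", "TC", "FA")


@dataclass
class LipidMixture:
    """Composition of a lipid extract: class concentrations (mM) and the
    acyl-species mole fractions of the free fatty-acid pool."""

    species_fractions: dict[FattyAcylSpecies, float]
    class_concentrations: dict[str, float]

    def __post_init__(self) -> None:
        for cls, c in self.class_concentrations.items():
            if cls not in MIXTURE_CLASSES:
                raise ValueError(f"unknown lipid class {cls!r}")
            if c < 0:
                raise ValueError(f"concentration of {cls} must be >= 0")
        for cls in MIXTURE_CLASSES:
            self.class_concentrations.setdefault(cls, 0.0)
        fracs = np.array(list(self.species_fractions.values()), dtype=float)
        if np.any(fracs < 0):
            raise ValueError("species fractions must be >= 0")
        if self.class_concentrations["FA"] > 0:
            if fracs.size == 0 or not math.isclose(fracs.sum(), 1.0, rel_tol=1e-9):
                raise ValueError("species fractions must sum to 1 when FA > 0")

    @property
    def omega3_fraction(self) -> float:
        return sum(f for s, f in self.species_fractions.items() if s.omega3)


def expected_peak_areas(mix: LipidMixture, scale: float = 1.0) -> PeakTable:
    """Closed-form peak areas for a mixture: area-per-proton-mM times the
    proton-weighted concentration feeding each catalog peak.

    This is the analytic oracle the spectrum simulator must reproduce
    under window integration; no lineshape is involved.
    """
    areas = {a.peak_id: 0.0 for a in lipid_line_catalog()}
    conc_fa = mix.class_concentrations["FA"]
    if conc_fa > 0:
        for species, frac in mix.species_fractions.items():
            for pid, protons in species.proton_counts().items():
                areas[pid] += scale * conc_fa * frac * protons
    areas["TG_glycerol_4.2"] += scale * mix.class_concentrations["TG"] * 4
    areas["choline_3.48"] += scale * mix.class_concentrations["PC_LPC"] * 9
    areas["PE_3.40"] += scale * mix.class_concentrations["PE"] * 2
    areas["TC_0.68"] += scale * mix.class_concentrations["TC"] * 3
    return PeakTable(entries=areas, source="expected_peak_areas")


def marker_concentrations(mix: LipidMixture) -> dict[str, float]:
    """Ground-truth concentration behind each quantified marker window.

    The free fatty-acid pool splits between the 0.90 ppm (non omega-3)
    and 0.98 ppm (omega-3) terminal-methyl markers.
    """
    w3 = mix.omega3_fraction
    fa = mix.class_concentrations["FA"]
    return {
        "TG": mix.class_concentrations["TG"],
        "PC_LPC": mix.class_concentrations["PC_LPC"],
        "PE": mix.class_concentrations["PE"],
        "TC": mix.class_concentrations["TC"],
        "FA": fa * (1.0 - w3),
        "OMEGA3": fa * w3,
    }


# ---------------------------------------------------------------------------
# lineshapes
# ---------------------------------------------------------------------------

def _add_line(
    y: np.ndarray,
    x: np.ndarray,
    center: float,
    area: float,
    hwhm: float,
    lineshape: str,
) -> None:
    """Add an area-normalised line in place."""
    if area == 0.0:
        return
    if lineshape == "gaussian":
        sigma = hwhm / math.sqrt(2.0 * math.log(2.0))
        y += area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
            -0.5 * ((x - center) / sigma) ** 2
        )
    elif lineshape == "lorentzian":
        y += area / math.pi * hwhm / ((x - center) ** 2 + hwhm**2)
    else:
        raise ValueError(f"unknown lineshape {lineshape!r}")


#: Acquisition defaults: 298 K, 128 transients, 10 us 90-degree pulse.
DEFAULT_EXTRACT_ACQ = AcquisitionParams(T=298.0, NS=128, P1=10.0, RG=64.0)
#: In vivo voxel acquisition: body temperature, 12 averaged scans.
DEFAULT_MRS_ACQ = AcquisitionParams(T=310.0, NS=12, P1=10.0, RG=1.0)


def simulate_extract_spectrum(
    mix: LipidMixture,
    acq: AcquisitionParams = DEFAULT_EXTRACT_ACQ,
    noise_sd: float = 0.0,
    axis_points: int = 16384,
    seed: int | None = None,
    hwhm_ppm: float = 0.005,
    lineshape: str = "gaussian",
    base_scale: float = 1.0,
    chloroform_area: float = 1.0,
) -> Spectrum1D:
    """Render a 600 MHz tissue-extract spectrum of a lipid mixture.

    One line per catalog peak at its nominal shift, with area
    ``expected_peak_areas(mix, base_scale) / m(acq)`` where
    ``m = T*P1/(RG*NS)``, plus a chloroform reference line at 7.26 ppm
    (same acquisition scaling). ``noise_sd`` is a fraction of the maximum
    noiseless signal; the noise is Gaussian and seed-deterministic.
    """
    if axis_points < 2048:
        raise ValueError("axis_points must be >= 2048")
    x = np.linspace(-1.0, 11.0, axis_points)
    y = np.zeros_like(x)
    gain = (acq.RG * acq.NS) / (acq.T * acq.P1)  # = 1/m
    windows = catalog_windows()
    areas = expected_peak_areas(mix, scale=base_scale)
    for pid, area in areas.entries.items():
        _add_line(y, x, windows[pid].nominal_center, area * gain, hwhm_ppm, lineshape)
    _add_line(y, x, CHLOROFORM_PPM, chloroform_area * gain, hwhm_ppm, lineshape)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd * y.max(), size=y.shape)
    return Spectrum1D(
        ppm=x,
        intensity=y,
        spectrometer_freq=HR_NMR_FREQ_MHZ,
        acquisition=acq,
        label="simulated extract",
        modality="hr_nmr",
    )


def simulate_liver_mrs_pair(
    lipid_fraction: float,
    mix: LipidMixture,
    water_fwhm_hz: float,
    seed: int | None = None,
    noise_sd: float = 1e-5,
    axis_points: int = 8192,
    lipid_fwhm_ppm: float = 0.02,
    lineshape: str = "gaussian",
    water_suppression_factor: float = 1000.0,
    acq: AcquisitionParams = DEFAULT_MRS_ACQ,
) -> tuple[Spectrum1D, Spectrum1D]:
    """Render a (suppressed, unsuppressed) liver voxel spectrum pair at 7 T.

    The unsuppressed spectrum has a unit-area water line at 4.7 ppm with
    the requested linewidth, plus lipid lines scaled so that the bulk
    methylene area (1.3 ppm) over the water area equals
    ``lipid_fraction``. TG glycerol signal is split between 4.10 and
    4.30 ppm. The suppressed spectrum attenuates water by
    ``water_suppression_factor``. ``noise_sd`` is a fraction of the
    unsuppressed maximum.
    """
    if lipid_fraction < 0:
        raise ValueError("lipid_fraction must be >= 0")
    if water_fwhm_hz <= 0:
        raise ValueError("water_fwhm_hz must be > 0")
    # 15 ppm spectral width centred near the water resonance
    x = np.linspace(4.7 - 7.5, 4.7 + 7.5, axis_points)
    water = np.zeros_like(x)
    water_hwhm_ppm = 0.5 * water_fwhm_hz / MRS_FREQ_MHZ
    _add_line(water, x, 4.7, 1.0, water_hwhm_ppm, lineshape)

    lipid = np.zeros_like(x)
    if lipid_fraction > 0:
        areas = expected_peak_areas(mix).entries
        bulk = areas["CH2_1.3"]
        if bulk <= 0:
            raise ValueError(
                "lipid_fraction > 0 requires a mixture with bulk CH2 signal"
            )
        k = lipid_fraction / bulk  # water area is 1
        hw = lipid_fwhm_ppm / 2.0
        windows = catalog_windows()
        for pid in ACYL_PEAK_IDS:
            _add_line(lipid, x, windows[pid].nominal_center, k * areas[pid], hw, lineshape)
        tg_area = k * areas["TG_glycerol_4.2"]
        _add_line(lipid, x, 4.10, tg_area / 2.0, hw, lineshape)
        _add_line(lipid, x, 4.30, tg_area / 2.0, hw, lineshape)

    unsup = water + lipid
    sup = water / water_suppression_factor + lipid
    rng = np.random.default_rng(seed)
    scale = noise_sd * unsup.max() if noise_sd > 0 else 0.0
    if scale > 0:
        unsup = unsup + rng.normal(0.0, scale, size=x.shape)
        sup = sup + rng.normal(0.0, scale, size=x.shape)

    common = dict(spectrometer_freq=MRS_FREQ_MHZ, acquisition=acq)
    return (
        Spectrum1D(ppm=x, intensity=sup, modality="mrs_suppressed",
                   label="simulated liver voxel (water-suppressed)", **common),
        Spectrum1D(ppm=x, intensity=unsup, modality="mrs_unsuppressed",
                   label="simulated liver voxel (unsuppressed)", **common),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortGroup:
    """One experimental group: genotype, age, size, and the group mean and
    SD of every measurand."""

    genotype: str
    age_months: int
    n: int
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group n must be >= 2")
        for name, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"SD of {name} must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Group structure of a simulated study (genotype x age, n per group)."""

    groups: tuple[CohortGroup, ...]
    seed: int = 0

    def measurands(self) -> list[str]:
        names: list[str] = []
        for g in self.groups:
            for m in g.means:
                if m not in names:
                    names.append(m)
        return names


@dataclass
class CohortResult:
    """Tidy per-animal table plus (optionally) the rendered spectra."""

    table: pd.DataFrame
    spectra: dict[str, dict[str, Spectrum1D]]


def _draw_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal(mean, sd) draws truncated at zero (resampled, floor 0)."""
    if sd == 0:
        return np.full(n, float(mean))
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = out < 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, 0.0)


#: Measurands the renderer knows how to realise in a spectrum.
_EXTRACT_CLASSES = ("TG", "PC_LPC", "PE", "TC", "FA", "OMEGA3")


def _mixture_from_row(row: pd.Series) -> LipidMixture | None:
    """Build a mixture matching the class concentrations drawn for one
    animal, splitting the FA pool into omega-3 / non-omega-3 chains."""
    if not any(c in row for c in _EXTRACT_CLASSES):
        return None
    conc = {c: float(row.get(c, 0.0)) for c in ("TG", "PC_LPC", "PE", "TC")}
    fa = float(row.get("FA", 0.0))
    w3 = float(row.get("OMEGA3", 0.0))
    total_fa = fa + w3
    fractions: dict[FattyAcylSpecies, float] = {}
    if total_fa > 0:
        w3_frac = w3 / total_fa
        oleate = DEFAULT_SPECIES["oleate"]
        linolenate = DEFAULT_SPECIES["alpha_linolenate"]
        fractions = {oleate: 1.0 - w3_frac, linolenate: w3_frac}
        if fractions[oleate] == 0:
            fractions = {linolenate: 1.0}
        elif fractions[linolenate] == 0:
            fractions = {oleate: 1.0}
    conc["FA"] = total_fa
    return LipidMixture(species_fractions=fractions, class_concentrations=conc)


def simulate_cohort(
    spec: CohortSpec,
    render_spectra: bool = True,
    noise_sd: float = 1e-4,
    axis_points: int = 8192,
) -> CohortResult:
    """Draw a cohort and (optionally) render per-animal spectra.

    Measurands are drawn per animal from the group Normal(mean, SD)
    truncated at zero; SD = 0 gives degenerate draws equal to the mean.
    When rendering, each animal gets an extract spectrum consistent with
    its drawn class concentrations (if any are specified) and an MRS pair
    consistent with its drawn ``IHLC``, ``water_fwhm_hz`` and TG level
    (if specified). Statistical measurands with no constructive spectral
    counterpart (the FA indices) appear in the table only.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for g in spec.groups:
        draws = {
            name: _draw_truncated_normal(rng, g.means[name], g.sds.get(name, 0.0), g.n)
            for name in g.means
        }
        for i in range(g.n):
            row = {
                "animal_id": f"{g.genotype}_{g.age_months}m_{i + 1:02d}",
                "genotype": g.genotype,
                "age_months": g.age_months,
            }
            row.update({name: float(vals[i]) for name, vals in draws.items()})
            rows.append(row)
    table = pd.DataFrame(rows)

    spectra: dict[str, dict[str, Spectrum1D]] = {}
    if render_spectra:
        for _, row in table.iterrows():
            per_animal: dict[str, Spectrum1D] = {}
            sub_seed = int(rng.integers(0, 2**31 - 1))
            mix = _mixture_from_row(row)
            if mix is not None:
                per_animal["extract"] = simulate_extract_spectrum(
                    mix, noise_sd=noise_sd, axis_points=axis_points, seed=sub_seed
                )
            if "IHLC" in row and "water_fwhm_hz" in row:
                mrs_mix = mix if mix is not None else LipidMixture(
                    species_fractions={DEFAULT_SPECIES["oleate"]: 1.0},
                    class_concentrations={"FA": 10.0, "TG": 1.0},
                )
                sup, unsup = simulate_liver_mrs_pair(
                    lipid_fraction=float(row["IHLC"]),
                    mix=mrs_mix,
                    water_fwhm_hz=float(row["water_fwhm_hz"]),
                    seed=sub_seed + 1,
                    noise_sd=noise_sd,
                )
                per_animal["mrs_suppressed"] = sup
                per_animal["mrs_unsuppressed"] = unsup
            if per_animal:
                spectra[row["animal_id"]] = per_animal
    return CohortResult(table=table, spectra=spectra)
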