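import numpy as np
import pytest

from lipospec import LipidMixture, Spectrum1D
from lipospec.synthetic import DEFAULT_SPECIES


def lorentzian(x, center, gamma, area=None, height=None):
    """Lorentzian line; give either total area or peak height."""
    if area is not None:
        return area / np.pi * gamma / ((x - center) ** 2 + gamma**2)
    return height * gamma**2 / ((x - center) ** 2 + gamma**2)


def gaussian(x, center, sigma, area=1.0):
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - center) / sigma) ** 2)


@pytest.fixture
def hr_axis():
    """Dense 600 MHz-style axis, ascending ppm."""
    return np.linspace(-1.0, 11.0, 24001)


@pytest.fixture
def mixed_lipids():
    """A realistic liver-extract-like mixture of all five species and
    five lipid classes."""
    return LipidMixture(
        species_fractions={
            DEFAULT_SPECIES["palmitate"]: 0.25,
            DEFAULT_SPECIES["stearate"]: 0.10,
            DEFAULT_SPECIES["oleate"]: 0.35,
            DEFAULT_SPECIES["linoleate"]: 0.20,
            DEFAULT_SPECIES["alpha_linolenate"]: 0.10,
        },
        class_concentrations={
            "TG": 2.0, "PC_LPC": 0.4, "PE": 0.3, "TC": 0.2, "FA": 6.0
        },
    )


def random_mixture(rng):
    """Random positive mixture over the default species set."""
    names = list(DEFAULT_SPECIES)
    fracs = rng.dirichlet(np.ones(len(names)))
    return LipidMixture(
        species_fractions={DEFAULT_SPECIES[n]: f for n, f in zip(names, fracs)},
        class_concentrations={
            "TG": float(rng.uniform(0.1, 5.0)),
            "PC_LPC": float(rng.uniform(0.05, 1.0)),
            "PE": float(rng.uniform(0.05, 1.0)),
            "TC": float(rng.uniform(0.05, 1.0)),
            "FA": float(rng.uniform(0.5, 10.0)),
        },
    )
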