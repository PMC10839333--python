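"""Simulate a liver-extract spectrum and quantify its lipid classes.

Builds a lipid mixture at liver-like concentrations, renders its 600 MHz
proton spectrum, references it to chloroform (7.26 ppm) and converts the
six marker peak areas to absolute concentrations against external
standards, normalised to dry tissue weight.
"""

from lipospec import (
    SampleMeta,
    LipidMixture,
    quantify_lipid_classes,
    reference_to_anchor,
    simulate_extract_spectrum,
)
from lipospec.quant import build_standard_records
from lipospec.synthetic import DEFAULT_SPECIES, marker_concentrations

# a 30 mg (dry) liver sample: TG at 0.2011 mM per mg DW, an acyl pool of
# mixed saturation with 15% omega-3 chains
mix = LipidMixture(
    species_fractions={
        DEFAULT_SPECIES["palmitate"]: 0.30,
        DEFAULT_SPECIES["oleate"]: 0.40,
        DEFAULT_SPECIES["linoleate"]: 0.15,
        DEFAULT_SPECIES["alpha_linolenate"]: 0.15,
    },
    class_concentrations={"TG": 6.033, "PC_LPC": 0.108, "PE": 0.807,
                          "TC": 0.558, "FA": 20.6},
)
spectrum = simulate_extract_spectrum(mix, noise_sd=1e-5, seed=1)
spectrum, shift = reference_to_anchor(spectrum, 7.26)
print(f"chloroform referencing shift: {shift:+.4f} ppm")

meta = SampleMeta(animal_id="sim01", genotype="CpKO", age_months=10,
                  tissue="liver", dry_weight_mg=30.0)
result = quantify_lipid_classes(spectrum, meta, build_standard_records())

truth = {c: v / 30.0 for c, v in marker_concentrations(mix).items()}
print(f"\n{'class':8s} {'recovered':>12s} {'injected':>12s}   (mM per mg DW)")
for cls, conc in result.class_concentrations.items():
    print(f"{cls:8s} {conc:12.4f} {truth[cls]:12.4f}")
print(f"\ntotal lipid area per mg DW: {result.total_lipid:.3f}")
# The external-standard formula cancels the acquisition scaling exactly;
# residual differences (largest for the minor classes PE, PC+LPC, TC)
# come from integrating small peaks on a noisy baseline.
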