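"""Physical constants and alphabets shared across the package."""

GAS_CONSTANT_KJ = 8.314e-3
"""Ideal gas constant R in kJ/(mol*K)."""

DEFAULT_TEMPERATURE_K = 295.0
"""Temperature of the binding experiments the defaults are tuned for."""

DNA_ALPHABET = ("A", "C", "G", "T")

AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")


def rt(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT in kJ/mol at the given temperature (2.4527 kJ/mol at 295 K)."""
    return GAS_CONSTANT_KJ * temperature_K
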