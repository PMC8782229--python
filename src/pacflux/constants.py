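"""Physical constants and gas metadata used throughout the package."""

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.3145

#: Celsius -> Kelvin offset.
KELVIN_OFFSET = 273.15

#: hPa -> kPa conversion factor.
HPA_TO_KPA = 0.1

#: Minutes in a day; appears in the volumetric-flux -> daily-mass extrapolation.
MINUTES_PER_DAY = 1440

#: Canonical gas identifiers.
GASES = ("ch4", "o2", "co2")

#: Molar masses, g/mol.
MOLAR_MASS = {"ch4": 16.0, "co2": 44.0, "o2": 32.0}

#: Divisor converting the concentration scale of each gas to a volume
#: fraction: CH4 is read in ppm (1e6), O2 and CO2 in percent (100).
SCALE_DIVISOR = {"ch4": 1_000_000.0, "o2": 100.0, "co2": 100.0}

#: Reading order (x, y) used in the two-point slope.  Production gases use
#: (last, first) so accumulation gives a positive flux; O2 uses
#: (first, last) so consumption (declining concentration) is positive.
CONSUMED_GASES = frozenset({"o2"})

#: Default chamber internal volume, liters.
CHAMBER_VOLUME_L = 853.0


def check_gas(gas: str) -> str:
    """Normalize and validate a gas identifier."""
    g = str(gas).lower()
    if g not in GASES:
        raise ValueError(f"unknown gas {gas!r}; expected one of {GASES}")
    return g
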