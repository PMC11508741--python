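"""Unit conventions shared across the package.

Concentrations are carried internally in mol/cm^3 so that rate coefficients
printed in the field's customary units (1/s for unimolecular, cm^3/(mol s)
for bimolecular) apply without any conversion factor.  User-facing tables
and range files are in nM; 1 nM = 1e-9 mol/dm^3 = 1e-12 mol/cm^3.
"""

#: mol/cm^3 per nM
NM_TO_MOLCM3 = 1e-12
#: nM per mol/cm^3
MOLCM3_TO_NM = 1e12

#: seconds per hour (the simulation grid is hourly)
HOUR = 3600.0

#: single-cell reference volume in litres (context for count -> concentration
#: conversions in range curation; not used by the solver)
CELL_VOLUME_L = 1e-12


def nm_to_internal(value_nm: float) -> float:
    """Convert a concentration in nM to the internal mol/cm^3 unit."""
    return value_nm * NM_TO_MOLCM3


def internal_to_nm(value: float) -> float:
    """Convert a concentration in mol/cm^3 to nM."""
    return value * MOLCM3_TO_NM
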