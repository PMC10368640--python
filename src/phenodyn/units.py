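"""Centralised length-unit conversion.

Coordinates are stored in Å (native PDB); every reported trajectory
statistic is in nm.  All conversions go through these two constants so the
factor exists in exactly one place.
"""

ANGSTROM_PER_NM = 10.0
NM_PER_ANGSTROM = 0.1


def ang_to_nm(x):
    return x * NM_PER_ANGSTROM


def nm_to_ang(x):
    return x * ANGSTROM_PER_NM
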