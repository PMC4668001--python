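"""Physical constants and the published reference geometry of the insulin
hydrophobic core.

The seven residue pairs below track the detachment of the B-chain C-terminal
(BC-CT, residues G20-T30) from the B-chain alpha-helix.  Each BC-CT residue is
paired with the closest alpha-carbon in the helix (L15, V12 or G8).  Pairs are
listed in zipper order: the hinge pair F24-L15 first, the freely moving
C-terminal pair T30-G8 last.
"""

from __future__ import annotations

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_MOL_K = 0.0019872041

#: Simulation / analysis temperature in K.
DEFAULT_TEMPERATURE = 300.0

#: kT at the default temperature, kcal/mol.
KT_DEFAULT = KB_KCAL_MOL_K * DEFAULT_TEMPERATURE

#: Trajectory frames are recorded every this many picoseconds.
DEFAULT_FRAME_INTERVAL_PS = 10.0

#: Langevin friction (thermostat damping), ps^-1.
DEFAULT_FRICTION_PS = 5.0

#: Radius of the hydration-counting sphere around L15 C-gamma, Angstrom.
CORE_SPHERE_RADIUS = 9.0

#: Number of sphere waters attributable to the outside of the core in the
#: closed state; subtracted from the raw in-sphere count.
WATER_BASELINE = 9

#: Half-harmonic hinge-breaking restraint: default force constant
#: (kcal/mol/A^2) and the offset added to the closed-state mean distance to
#: obtain the target distance r0 (Angstrom).
RESTRAINT_K = 30.0
RESTRAINT_R0_OFFSET = 9.8

# (pair label, BC-CT residue number, helix residue number,
#  crystal distance A, closed-state mean A, closed-state SD A)
# Chain B throughout; residue numbering follows the B1-B30 convention.
TABLE1_PAIRS = [
    ("F24-L15", 24, 15, 6.7, 7.0, 0.4),
    ("F25-L15", 25, 15, 8.5, 9.4, 0.5),
    ("Y26-V12", 26, 12, 7.2, 8.1, 0.9),
    ("T27-V12", 27, 12, 10.2, 10.5, 1.1),
    ("P28-G8", 28, 8, 9.1, 9.8, 2.1),
    ("L29-G8", 29, 8, 12.2, 12.3, 2.4),
    ("T30-G8", 30, 8, 14.5, 13.8, 2.7),
]

#: Pair labels in zipper order (hinge first).
PAIR_LABELS = [row[0] for row in TABLE1_PAIRS]

# Aromatic-contact reference values: ring-centre of the aromatic residue to
# the nearest carbon atom of the partner residue.
# (label, aromatic chain, aromatic resid, partner chain, partner resid,
#  crystal distance A, closed-state mean A, closed-state SD A)
TABLE2_CONTACTS = [
    ("F24/L15", "B", 24, "B", 15, 5.2, 4.6, 0.5),
    ("Y26/I2A", "B", 26, "A", 2, 5.2, 5.5, 2.1),
    ("Y26/L11", "B", 26, "B", 11, 5.2, 5.8, 1.3),
    ("Y26/V12", "B", 26, "B", 12, 3.8, 4.5, 1.0),
]

#: Conformational-state thresholds (theta_open, theta_wide) in Angstrom for
#: the two indicator coordinates.  Distances below theta_open are closed,
#: between the two are open, at or above theta_wide are wide-open.
STATE_THRESHOLDS = {
    "Y26-V12": (8.7, 10.7),
    "P28-G8": (9.5, 15.0),
}

#: The primary opening criterion is the Y26(CA)-V12(CA) distance.
PRIMARY_PAIR = "Y26-V12"

STATE_NAMES = ("closed", "open", "wide_open")
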