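"""Concentration ↔ molecule-count arithmetic for solute/octanol boxes.

The apparent saturated solubility of an aromatic pollutant in n-octanol is
obtained from its water solubility and octanol/water partition coefficient,

    S_O = S_W · 10^(log K_OW),

since K_OW = C_O/C_W = S_O/S_W at distribution equilibrium.  Simulation box
compositions then follow from the molarity of pure n-octanol
(ρ = 0.8262 g/cm³, M = 130.23 g/mol → 6.344 mol/L): a solute concentration c
in a box of n octanol molecules corresponds to round(c / 6.344 · n) solute
molecules, assuming the dilute solute does not change the solvent volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._util import round_half_up
from .registry import ChemicalRecord

#: Molarity of pure n-octanol (mol/L) from density 0.8262 g/cm^3 and
#: molar mass 130.23 g/mol.  Reproduces every reported solute:octanol
#: molecule ratio with nearest-integer rounding.
OCTANOL_MOLARITY = 6.344

#: The dilution ladder used in the concentration study: saturation down to
#: one-thirty-second of saturation by successive halving.
DEFAULT_DILUTION_DIVISORS = (1, 2, 4, 8, 16, 32)


@dataclass(frozen=True)
class BoxComposition:
    """One simulation box: a solute count dissolved in an octanol count."""

    chemical_id: str
    n_solute: int
    n_octanol: int
    concentration: float  # mol/L

    def __post_init__(self) -> None:
        if self.n_solute < 0:
            raise ValueError("n_solute must be >= 0")
        if self.n_octanol <= 0:
            raise ValueError("n_octanol must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def ratio(self) -> tuple[int, int]:
        return (self.n_solute, self.n_octanol)


def saturated_octanol_solubility(s_w: float, log_kow: float) -> float:
    """Apparent saturated octanol solubility S_O = S_W * 10**log_kow, mol/L."""
    if s_w <= 0:
        raise ValueError(f"s_w must be positive, got {s_w}")
    return s_w * 10.0 ** log_kow


def molecule_count(concentration: float, n_octanol: int = 1000,
                   octanol_molarity: float = OCTANOL_MOLARITY) -> int:
    """Solute molecule count for a target concentration in an octanol box.

    Uses nearest-integer (half-up) rounding of c / [octanol] * n_octanol.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if n_octanol <= 0:
        raise ValueError("n_octanol must be positive")
    if octanol_molarity <= 0:
        raise ValueError("octanol_molarity must be positive")
    return int(round_half_up(concentration / octanol_molarity * n_octanol))


def dilution_series(s_o: float, divisors: Sequence[float] = DEFAULT_DILUTION_DIVISORS,
                    ndigits: int | None = 3) -> list[float]:
    """Concentrations s_o/d for each divisor, half-up rounded for display.

    Pass ``ndigits=None`` for full precision (used internally when the values
    feed further arithmetic).
    """
    if s_o < 0:
        raise ValueError("s_o must be >= 0")
    out = []
    for d in divisors:
        if d <= 0:
            raise ValueError(f"divisor must be positive, got {d}")
        c = s_o / d
        out.append(c if ndigits is None else round_half_up(c, ndigits))
    return out


def compose_box(record: ChemicalRecord, n_octanol: int = 1000,
                concentration: float | None = None,
                octanol_molarity: float = OCTANOL_MOLARITY) -> BoxComposition:
    """Box composition for a chemical at a concentration (default: saturation)."""
    if concentration is None:
        concentration = saturated_octanol_solubility(record.s_w, record.log_kow)
    n = molecule_count(concentration, n_octanol, octanol_molarity)
    return BoxComposition(chemical_id=record.id, n_solute=n,
                          n_octanol=n_octanol, concentration=concentration)
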