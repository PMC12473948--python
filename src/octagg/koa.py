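"""Octanol–air partition thermodynamics and the aggregation correction.

The link between the partition coefficient and the gas→octanol solvation
free energy is

    log K_OA = −ΔG_OA / (2.303 · R · T),    R = 8.314 J mol⁻¹ K⁻¹.

The constant 2.303 is used literally rather than ln 10 to full precision;
the difference is below 0.01% and keeps reported values consistent with the
conventional form of the relation.

When the octanol phase holds aggregates as well as monomers, a bulk
measurement sees an *apparent* K_OA.  Two estimators are provided:

``fraction-weighted-log`` (default)
    apparent log K_OA = Σ_s f_s · log K_OA(ΔG_s per molecule), the
    molecule-fraction-weighted mean of per-species coefficients, with an
    s-mer's ΔG divided by s unless flagged as already per molecule.

``monomer-fraction``
    apparent log K_OA = log K_OA,monomer − log10(f_monomer), the
    thermodynamic correction obtained by attributing the whole octanol
    burden to a gas phase that exchanges only monomers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .registry import ChemicalRecord, SpeciesThermo

GAS_CONSTANT = 8.314       # J mol^-1 K^-1
LOG10_FACTOR = 2.303       # conventional 2.303 RT form
DEFAULT_TEMPERATURE = 298.15


@dataclass(frozen=True)
class KoaEstimate:
    """An apparent log K_OA with the species fractions and mode that produced it."""

    chemical_id: str
    apparent_log_koa: float
    fractions: Mapping[int, float]       # species size -> molecule fraction (0..1)
    contributions: Mapping[int, float]   # species size -> per-molecule log K_OA
    temperature: float
    mode: str

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions sum to {total}, expected 1")


def logkoa_from_dg(dg_oa: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """log K_OA from a gas→octanol solvation free energy in kJ/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -dg_oa * 1000.0 / (LOG10_FACTOR * GAS_CONSTANT * temperature)


def dg_from_logkoa(log_koa: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`logkoa_from_dg`; returns ΔG_OA in kJ/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -log_koa * LOG10_FACTOR * GAS_CONSTANT * temperature / 1000.0


def apparent_logkoa(fractions: Mapping[int, float], thermo: Sequence[SpeciesThermo],
                    temperature: float = DEFAULT_TEMPERATURE,
                    mode: str = "fraction-weighted-log",
                    chemical_id: str = "") -> KoaEstimate:
    """Aggregation-corrected apparent log K_OA from a species census.

    ``fractions`` maps aggregate size to percent of molecules (summing to
    100 within 0.1, as census tables report them).
    """
    total = sum(fractions.values())
    if abs(total - 100.0) > 0.1:
        raise ValueError(f"fractions must sum to 100 (+-0.1), got {total}")
    thermo_by_species = {t.species: t for t in thermo}
    frac = {s: f / total for s, f in fractions.items() if f > 0}
    contributions: dict[int, float] = {}
    for s in frac:
        if s not in thermo_by_species:
            raise ValueError(f"no SpeciesThermo entry for species of size {s}")
        contributions[s] = logkoa_from_dg(thermo_by_species[s].dg_per_molecule, temperature)

    if mode == "fraction-weighted-log":
        value = sum(frac[s] * contributions[s] for s in frac)
    elif mode == "monomer-fraction":
        if 1 not in thermo_by_species:
            raise ValueError("monomer-fraction mode needs a monomer SpeciesThermo entry")
        f1 = frac.get(1, 0.0)
        if f1 <= 0:
            raise ValueError("monomer-fraction mode needs a nonzero monomer fraction")
        mono = logkoa_from_dg(thermo_by_species[1].dg_per_molecule, temperature)
        contributions.setdefault(1, mono)
        value = mono - float(np.log10(f1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return KoaEstimate(chemical_id=chemical_id, apparent_log_koa=float(value),
                       fractions=frac, contributions=contributions,
                       temperature=temperature, mode=mode)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Apparent log K_OA across a concentration ladder, with a trend check."""

    estimates: tuple[KoaEstimate, ...]
    concentrations: tuple[float, ...]
    monotone_violated: bool


def concentration_profile(chemical: ChemicalRecord | str,
                          rows: Sequence[tuple[float, Mapping[int, float]]],
                          thermo: Sequence[SpeciesThermo],
                          temperature: float = DEFAULT_TEMPERATURE,
                          mode: str = "fraction-weighted-log") -> ConcentrationProfile:
    """One apparent-log K_OA estimate per (concentration, species fractions) row.

    Rows must be sorted by decreasing concentration (the dilution ladder).
    When the dimer's per-molecule ΔG is more favorable than the monomer's,
    the apparent coefficient should fall monotonically with dilution; a
    violation of that expectation is flagged (single rows carry no trend).
    """
    if not rows:
        raise ValueError("empty concentration table")
    concs = [r[0] for r in rows]
    if any(c2 > c1 for c1, c2 in zip(concs, concs[1:])):
        raise ValueError("rows must be sorted by decreasing concentration")
    chem_id = chemical if isinstance(chemical, str) else chemical.id
    estimates = tuple(
        apparent_logkoa(fracs, thermo, temperature=temperature, mode=mode, chemical_id=chem_id)
        for _, fracs in rows)

    violated = False
    thermo_by_species = {t.species: t for t in thermo}
    if len(estimates) > 1 and 1 in thermo_by_species and 2 in thermo_by_species:
        dimer_favored = (thermo_by_species[2].dg_per_molecule
                         < thermo_by_species[1].dg_per_molecule)
        if dimer_favored:
            vals = [e.apparent_log_koa for e in estimates]
            violated = any(v2 > v1 + 1e-9 for v1, v2 in zip(vals, vals[1:]))
    return ConcentrationProfile(estimates=estimates, concentrations=tuple(concs),
                                monotone_violated=violated)
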