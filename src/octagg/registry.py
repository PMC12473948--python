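"""Registry of pollutant physicochemical records and species-level thermodynamics.

The registry holds, per chemical, the measured water solubility S_W, the
n-octanol/water partition coefficient K_OW, the molar mass, and the list of
experimentally reported log K_OA values.  A packaged YAML fixture ships the
five aromatic pollutants the downstream analysis exercises (two PCB/PCN/PCDD
congeners, phenanthrene, one PBDE congener).

``SpeciesThermo`` carries the gas→octanol solvation free energy ΔG_OA for an
aggregate species (monomer, dimer, ...).  Those free energies come from the
user (typically quantum-chemistry continuum-solvation calculations); they are
inputs here, never computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from ._util import round_half_up

logger = logging.getLogger(__name__)

KCAL_TO_KJ = 4.184

_REQUIRED_FIELDS = ("id", "s_w", "log_kow", "molar_mass")
_KNOWN_FIELDS = _REQUIRED_FIELDS + ("exp_log_koa", "n_aromatic_rings", "name", "reference")


class RegistryError(ValueError):
    """A chemical record failed validation."""


@dataclass(frozen=True)
class ChemicalRecord:
    """Physicochemical constants for one aromatic pollutant.

    Parameters
    ----------
    id : short identifier, e.g. ``"PCB-4"``.
    s_w : saturated water solubility, mol/L.
    log_kow : log10 n-octanol/water partition coefficient.
    molar_mass : g/mol.
    exp_log_koa : experimentally reported log K_OA values (may be several
        literature sources).
    n_aromatic_rings : number of aromatic rings in the molecule.
    reference : reported values kept for comparison output only.
    """

    id: str
    s_w: float
    log_kow: float
    molar_mass: float
    exp_log_koa: tuple[float, ...] = ()
    n_aromatic_rings: int = 1
    name: str = ""
    reference: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.s_w <= 0:
            raise RegistryError(f"{self.id}: s_w must be positive, got {self.s_w}")
        if self.n_aromatic_rings < 1:
            raise RegistryError(f"{self.id}: n_aromatic_rings must be >= 1")


@dataclass(frozen=True)
class SpeciesThermo:
    """Gas→octanol solvation free energy for one aggregate species.

    ``species`` is the aggregate size (1 = monomer, 2 = dimer, ...).
    ``dg_oa`` is ΔG_OA in kJ/mol with the convention that favorable transfer
    into octanol is negative.  If ``per_molecule`` is False the value refers
    to the whole s-mer and is divided by ``species`` when a per-constituent
    free energy is needed.
    """

    species: int
    dg_oa: float
    per_molecule: bool = False

    def __post_init__(self) -> None:
        if self.species < 1:
            raise RegistryError(f"species size must be >= 1, got {self.species}")

    @classmethod
    def from_value(cls, species: int, value: float, unit: str = "kJ/mol",
                   per_molecule: bool = False) -> "SpeciesThermo":
        """Build a record from a value with an explicit unit tag.

        Accepted units: ``kJ/mol`` (canonical) and ``kcal/mol`` (converted
        with 4.184 kJ/kcal).
        """
        unit_norm = unit.replace(" ", "").lower()
        if unit_norm == "kj/mol":
            dg = float(value)
        elif unit_norm == "kcal/mol":
            dg = float(value) * KCAL_TO_KJ
        else:
            raise RegistryError(f"unknown energy unit {unit!r}")
        return cls(species=species, dg_oa=dg, per_molecule=per_molecule)

    @property
    def dg_per_molecule(self) -> float:
        """ΔG_OA per constituent molecule, kJ/mol."""
        return self.dg_oa if self.per_molecule else self.dg_oa / self.species


def _record_from_mapping(raw: Mapping[str, Any]) -> ChemicalRecord:
    for key in _REQUIRED_FIELDS:
        if key not in raw:
            name = raw.get("id", "<unnamed>")
            raise RegistryError(f"record {name!r}: missing mandatory field {key!r}")
    unknown = sorted(set(raw) - set(_KNOWN_FIELDS))
    if unknown:
        logger.warning("record %r: ignoring unknown fields %s", raw["id"], unknown)
    return ChemicalRecord(
        id=str(raw["id"]),
        s_w=float(raw["s_w"]),
        log_kow=float(raw["log_kow"]),
        molar_mass=float(raw["molar_mass"]),
        exp_log_koa=tuple(float(v) for v in raw.get("exp_log_koa", ())),
        n_aromatic_rings=int(raw.get("n_aromatic_rings", 1)),
        name=str(raw.get("name", "")),
        reference=dict(raw.get("reference", {})),
    )


def load_registry(source: str | Path | Mapping[str, Any] | None = None) -> dict[str, ChemicalRecord]:
    """Load chemical records keyed by id.

    ``source`` may be a YAML path, an already-parsed mapping with a
    ``chemicals`` list, or None for the packaged fixture of the five study
    pollutants.
    """
    if source is None:
        with resources.files("octagg.data").joinpath("chemicals.yaml").open() as fh:
            data = yaml.safe_load(fh)
    elif isinstance(source, Mapping):
        data = source
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    if not data:
        return {}
    records = [_record_from_mapping(raw) for raw in data.get("chemicals", [])]
    return {rec.id: rec for rec in records}


def dump_registry(records: Iterable[ChemicalRecord], path: str | Path) -> None:
    """Serialize records back to the fixture YAML schema (round-trip safe)."""
    payload = {"chemicals": []}
    for rec in records:
        entry: dict[str, Any] = {
            "id": rec.id,
            "s_w": rec.s_w,
            "log_kow": rec.log_kow,
            "molar_mass": rec.molar_mass,
            "exp_log_koa": list(rec.exp_log_koa),
            "n_aromatic_rings": rec.n_aromatic_rings,
        }
        if rec.name:
            entry["name"] = rec.name
        if rec.reference:
            entry["reference"] = dict(rec.reference)
        payload["chemicals"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def average_experimental_logkoa(record: ChemicalRecord) -> float:
    """Arithmetic mean of the reported log K_OA values, half-up to 2 decimals.

    Several literature values may exist per chemical; their plain mean is the
    representative experimental value used for comparisons.
    """
    if not record.exp_log_koa:
        raise RegistryError(f"{record.id}: no experimental log K_OA values to average")
    return round_half_up(sum(record.exp_log_koa) / len(record.exp_log_koa), 2)
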