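"""End-to-end orchestration: regenerate the study's printed tables from
planted fixtures and compare.

The reported MD end states are defined by cluster counts (e.g. "seven dimers
and one trimer" among 34 PCDD-1 molecules at saturation).  Those counts are
inputs here: planted conformations realizing them are generated, pushed
through the full detection → clustering → census pipeline, and the resulting
percentages are compared cell-by-cell against the published tables.  The
composition, dilution and experimental-averaging layers are recomputed from
the physicochemical constants directly.

Two published cells are knowingly excluded from pass/fail: the equal-
concentration PCN-5 row prints 60.0/40.0 where 12 dimers among 61 molecules
give 60.7/39.3, and the two transient excursion cells in the equilibrium
grid (which a cluster-count-conserving generator does not produce).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .census import StackingCriteria, census, census_timeseries, cluster_frame
from .composition import compose_box, dilution_series, saturated_octanol_solubility
from .registry import average_experimental_logkoa, load_registry
from .synth import ClusterPlant, PlantSpec, build_conformation, build_equilibrium_trajectory

CHEMICAL_ORDER = ("PCB-4", "Phenanthrene", "PBDE-28", "PCN-5", "PCDD-1")

#: Reported solute:octanol ratios at saturation in a 1000-octanol box.
RATIOS_PRINTED = {"PCB-4": 24, "Phenanthrene": 35, "PBDE-28": 24, "PCN-5": 15, "PCDD-1": 34}

#: Cluster inventory of the reported 50 ps saturation end states:
#: (N molecules, dimer count, trimer count).
SATURATION_STATE = {
    "PCB-4": (24, 3, 0),
    "Phenanthrene": (35, 5, 0),
    "PBDE-28": (24, 4, 0),
    "PCN-5": (15, 3, 0),
    "PCDD-1": (34, 7, 1),
}

#: Published aggregate percentages at the 50 ps saturation state
#: (monomer, dimer, trimer).
TABLE_SATURATION_PRINTED = {
    "PCB-4": (75.0, 25.0, 0.0),
    "Phenanthrene": (71.4, 28.6, 0.0),
    "PBDE-28": (66.7, 33.3, 0.0),
    "PCN-5": (60.0, 40.0, 0.0),
    "PCDD-1": (50.0, 41.2, 8.8),
}

#: Cluster inventory at the shared 9.67e-2 mol/L concentration (61 solutes
#: in 4000 octanol): dimer counts per chemical.
EQUAL_CONC_DIMERS = {"PCB-4": 4, "Phenanthrene": 4, "PBDE-28": 8, "PCN-5": 12, "PCDD-1": 6}
EQUAL_CONC_N = 61
EQUAL_CONC_MOLARITY = 9.67e-2

#: Published equal-concentration percentages (monomer, dimer, trimer).
TABLE_EQUAL_PRINTED = {
    "PCB-4": (86.9, 13.1, 0.0),
    "Phenanthrene": (86.9, 13.1, 0.0),
    "PBDE-28": (73.8, 26.2, 0.0),
    "PCN-5": (60.0, 40.0, 0.0),   # inconsistent with 12 dimers/61 -> 60.7/39.3; excluded
    "PCDD-1": (80.3, 19.7, 0.0),
}

#: Dilution divisor at which each chemical becomes fully monomeric, with the
#: published threshold concentration (mol/L).
MONOMERIC_THRESHOLDS = {
    "PCB-4": (4, 0.038),
    "Phenanthrene": (16, 0.014),
    "PBDE-28": (8, 0.019),
    "PCN-5": (4, 0.024),
    "PCDD-1": (32, 0.007),
}

#: Published representative (averaged) experimental log K_OA values.
AVG_LOGKOA_PRINTED = {"PCB-4": 7.18, "Phenanthrene": 7.65, "PBDE-28": 9.50,
                      "PCN-5": 6.93, "PCDD-1": 7.86}

EQUILIBRIUM_CHECKPOINTS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)

SATURATION_BOX = 40.0
EQUAL_CONC_BOX = 50.0


@dataclass(frozen=True)
class Comparison:
    """One computed-vs-published cell of the reproduction report."""

    name: str
    expected: Any
    computed: Any
    match: bool
    excluded: bool = False
    note: str = ""


@dataclass
class ReportBundle:
    """All regenerated tables plus the cell-by-cell comparison record."""

    tables: dict[str, pd.DataFrame]
    comparisons: list[Comparison]

    @property
    def passed(self) -> bool:
        return all(c.match for c in self.comparisons if not c.excluded)

    def failures(self) -> list[Comparison]:
        return [c for c in self.comparisons if not c.match and not c.excluded]


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    subcommand: str
    config: Mapping[str, Any]
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    seed: int | None = None
    version: str = __version__
    timestamp: str = field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _plants(dimers: int, trimers: int) -> tuple[ClusterPlant, ...]:
    return (tuple(ClusterPlant(size=2) for _ in range(dimers))
            + tuple(ClusterPlant(size=3) for _ in range(trimers)))


def saturation_spec(chemical_id: str, seed: int, box_edge: float = SATURATION_BOX) -> PlantSpec:
    """Planted spec realizing a chemical's reported 50 ps saturation state."""
    n, dimers, trimers = SATURATION_STATE[chemical_id]
    return PlantSpec(n_molecules=n, box_edge=box_edge,
                     clusters=_plants(dimers, trimers), seed=seed)


def equal_concentration_spec(chemical_id: str, seed: int,
                             box_edge: float = EQUAL_CONC_BOX) -> PlantSpec:
    """Planted spec for the shared 9.67e-2 mol/L (61:4000) condition."""
    return PlantSpec(n_molecules=EQUAL_CONC_N, box_edge=box_edge,
                     clusters=_plants(EQUAL_CONC_DIMERS[chemical_id], 0), seed=seed)


def census_of_spec(spec: PlantSpec, criteria: StackingCriteria = StackingCriteria()):
    """Full pipeline on a planted spec: generate → classify → cluster → census."""
    traj = build_conformation(spec)
    return census(cluster_frame(traj.frames[0], traj.topology, criteria))


def run_paper_fixture(seed: int = 0, out_dir: str | Path | None = None,
                      criteria: StackingCriteria = StackingCriteria()) -> ReportBundle:
    """Regenerate the composition, census, dilution and averaging tables.

    Every number is recomputed by running the pipeline; published values
    serve only as comparison targets in the report.
    """
    registry = load_registry()
    comparisons: list[Comparison] = []
    tables: dict[str, pd.DataFrame] = {}

    # --- composition layer -------------------------------------------------
    comp_rows = []
    for i, cid in enumerate(CHEMICAL_ORDER):
        rec = registry[cid]
        s_o = saturated_octanol_solubility(rec.s_w, rec.log_kow)
        box = compose_box(rec, n_octanol=1000)
        comp_rows.append({"chemical": cid, "s_w": rec.s_w, "log_kow": rec.log_kow,
                          "s_o": s_o, "n_solute": box.n_solute, "n_octanol": 1000})
        comparisons.append(Comparison(
            name=f"composition/ratio/{cid}", expected=RATIOS_PRINTED[cid],
            computed=box.n_solute, match=box.n_solute == RATIOS_PRINTED[cid]))
    tables["composition"] = pd.DataFrame(comp_rows)

    eq_box = compose_box(registry["PCN-5"], n_octanol=4000,
                         concentration=EQUAL_CONC_MOLARITY)
    comparisons.append(Comparison(
        name="composition/equal-concentration-count", expected=EQUAL_CONC_N,
        computed=eq_box.n_solute, match=eq_box.n_solute == EQUAL_CONC_N))

    # --- averaging layer ---------------------------------------------------
    avg_rows = []
    for cid in CHEMICAL_ORDER:
        avg = average_experimental_logkoa(registry[cid])
        avg_rows.append({"chemical": cid, "avg_log_koa": avg})
        comparisons.append(Comparison(
            name=f"experimental-average/{cid}", expected=AVG_LOGKOA_PRINTED[cid],
            computed=avg, match=abs(avg - AVG_LOGKOA_PRINTED[cid]) < 5e-3))
    tables["experimental_averages"] = pd.DataFrame(avg_rows)

    # --- census layer: saturation state ------------------------------------
    species = ("monomer", "dimer", "trimer")
    sat_rows = []
    for i, cid in enumerate(CHEMICAL_ORDER):
        c = census_of_spec(saturation_spec(cid, seed=seed * 1000 + i), criteria)
        pct = c.percentages
        sat_rows.append({"chemical": cid, **{s: pct[s] for s in species}})
        for s, exp_val in zip(species, TABLE_SATURATION_PRINTED[cid]):
            comparisons.append(Comparison(
                name=f"census-saturation/{cid}/{s}", expected=exp_val,
                computed=pct[s], match=abs(pct[s] - exp_val) < 0.05))
    tables["census_saturation"] = pd.DataFrame(sat_rows)

    # --- census layer: equilibrium grid ------------------------------------
    grid_rows = []
    for i, cid in enumerate(CHEMICAL_ORDER):
        spec = saturation_spec(cid, seed=seed * 1000 + 100 + i)
        traj = build_equilibrium_trajectory(spec, n_frames=6, exchange_rate=1)
        series = census_timeseries(traj, EQUILIBRIUM_CHECKPOINTS, criteria)
        stationary = TABLE_SATURATION_PRINTED[cid]
        for t, c in zip(EQUILIBRIUM_CHECKPOINTS, series):
            pct = c.percentages
            grid_rows.append({"chemical": cid, "time": t, **{s: pct[s] for s in species}})
        for s, exp_val in zip(species, stationary):
            vals = [c.percentages[s] for c in series]
            constant = max(vals) - min(vals) < 1e-9
            comparisons.append(Comparison(
                name=f"census-equilibrium/{cid}/{s}", expected=exp_val,
                computed=vals[0],
                match=constant and abs(vals[0] - exp_val) < 0.05,
                note="published grid shows transient excursions for PCN-5 at one "
                     "checkpoint and PCDD-1 at another; a cluster-count-conserving "
                     "trajectory reproduces only the stationary value"))
    tables["census_equilibrium"] = pd.DataFrame(grid_rows)

    # --- census layer: equal concentration ----------------------------------
    eqc_rows = []
    for i, cid in enumerate(CHEMICAL_ORDER):
        c = census_of_spec(equal_concentration_spec(cid, seed=seed * 1000 + 200 + i), criteria)
        pct = c.percentages
        eqc_rows.append({"chemical": cid, **{s: pct[s] for s in species}})
        excluded = cid == "PCN-5"
        note = ("published row (60.0/40.0) is inconsistent with its stated cluster "
                "count: 12 dimers among 61 molecules give 60.7/39.3" if excluded else "")
        for s, exp_val in zip(species, TABLE_EQUAL_PRINTED[cid]):
            comparisons.append(Comparison(
                name=f"census-equal-concentration/{cid}/{s}", expected=exp_val,
                computed=pct[s], match=abs(pct[s] - exp_val) < 0.05,
                excluded=excluded, note=note))
    tables["census_equal_concentration"] = pd.DataFrame(eqc_rows)

    # --- dilution layer ------------------------------------------------------
    dil_rows = []
    for cid in CHEMICAL_ORDER:
        rec = registry[cid]
        s_o = saturated_octanol_solubility(rec.s_w, rec.log_kow)
        divisor, printed = MONOMERIC_THRESHOLDS[cid]
        threshold = dilution_series(s_o, [divisor])[0]
        dil_rows.append({"chemical": cid, "divisor": divisor,
                         "threshold_mol_per_l": threshold})
        comparisons.append(Comparison(
            name=f"dilution/monomeric-threshold/{cid}", expected=printed,
            computed=threshold, match=abs(threshold - printed) < 5e-4))
    tables["monomeric_thresholds"] = pd.DataFrame(dil_rows)

    bundle = ReportBundle(tables=tables, comparisons=comparisons)
    if out_dir is not None:
        write_bundle(bundle, out_dir, seed=seed, criteria=criteria)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path, seed: int,
                 criteria: StackingCriteria) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    for name, df in bundle.tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.4g")
        outputs.append(str(path))
    comp_path = out / "comparison.tsv"
    pd.DataFrame([dataclasses.asdict(c) for c in bundle.comparisons]).to_csv(
        comp_path, sep="\t", index=False)
    outputs.append(str(comp_path))
    manifest = RunManifest(subcommand="paper-fixture",
                           config=dataclasses.asdict(criteria),
                           outputs=outputs, seed=seed)
    manifest.write(out / "manifest.json")
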