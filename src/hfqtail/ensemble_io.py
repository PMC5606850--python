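"""Multi-model ensemble I/O, residue selections and solvent accessibility.

A structural ensemble is an ordered set of conformations of one hexamer
(or other homo-oligomeric ring), each carrying a total energy used for
low-energy subset selection.  Ensembles are exchanged as standard
multi-MODEL PDB files; per-model energies travel either in
``REMARK 250 MODEL_ENERGY`` header lines or in a two-column sidecar CSV.

Solvent-accessible surface area is computed with the Shrake-Rupley
algorithm (via :mod:`biotite.structure`) on a fixed Fibonacci point
lattice, so results are deterministic for a given point count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import biotite.structure as struc
from biotite.structure.info import vdw_radius_single
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Conformation",
    "ModelEnsemble",
    "SelectionSets",
    "EnsembleError",
    "TopologyMismatchError",
    "read_ensemble",
    "write_ensemble",
    "load_selections",
    "available_species",
    "residue_sasa",
    "flag_buried",
]

_ENERGY_REMARK = re.compile(
    r"^REMARK 250 MODEL_ENERGY\s+(-?\d+)\s+(-?[\d.eE+-]+)\s*$"
)


class EnsembleError(ValueError):
    """Malformed ensemble input."""


class TopologyMismatchError(EnsembleError):
    """Models in one ensemble do not share chain/residue topology."""


@dataclass
class Conformation:
    """One model of the ring: coordinates plus its total energy (REU)."""

    model_id: int
    total_energy: float
    chain_ids: np.ndarray  # (n_atoms,) str
    res_ids: np.ndarray    # (n_atoms,) int
    res_names: np.ndarray  # (n_atoms,) str
    atom_names: np.ndarray # (n_atoms,) str
    coord: np.ndarray      # (n_atoms, 3) float, Å

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise EnsembleError(
                f"model {self.model_id}: non-finite coordinates"
            )
        if not np.isfinite(self.total_energy):
            raise EnsembleError(f"model {self.model_id}: non-finite energy")

    @property
    def n_atoms(self) -> int:
        return len(self.res_ids)

    def topology(self) -> tuple:
        """Hashable chain/residue/atom identity, coordinates excluded."""
        return (
            tuple(self.chain_ids),
            tuple(int(r) for r in self.res_ids),
            tuple(self.res_names),
            tuple(self.atom_names),
        )

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def to_atom_array(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coord.astype(np.float32)
        arr.chain_id = np.asarray(self.chain_ids, dtype="U4")
        arr.res_id = np.asarray(self.res_ids, dtype=int)
        arr.res_name = np.asarray(self.res_names, dtype="U5")
        arr.atom_name = np.asarray(self.atom_names, dtype="U6")
        arr.element = np.array(
            [_element_of(a) for a in self.atom_names], dtype="U2"
        )
        return arr


@dataclass
class ModelEnsemble:
    """Ordered conformations of one ring with per-model energies."""

    models: list[Conformation]
    n_subunits: int = 6
    species_label: str = ""

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise EnsembleError("n_subunits must be >= 1")
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise EnsembleError("duplicate model ids in ensemble")
        if self.models:
            ref = self.models[0].topology()
            for m in self.models[1:]:
                if m.topology() != ref:
                    raise TopologyMismatchError(
                        f"model {m.model_id} does not match the topology "
                        f"of model {self.models[0].model_id}"
                    )

    def __len__(self) -> int:
        return len(self.models)

    @property
    def model_ids(self) -> list[int]:
        return [m.model_id for m in self.models]


@dataclass(frozen=True)
class SelectionSets:
    """Core (C), tail (T) and basic-core (B) residue number sets."""

    core: frozenset[int]
    tail: frozenset[int]
    basic_core: frozenset[int]
    numbering_scheme: str = "E. coli"

    def __post_init__(self) -> None:
        if not (self.core and self.tail and self.basic_core):
            raise ValueError("core, tail and basic_core must be non-empty")
        if not self.basic_core <= self.core:
            raise ValueError(
                "basic_core must be a subset of core; offending residues: "
                f"{sorted(self.basic_core - self.core)}"
            )
        if self.core & self.tail:
            # Legitimate in cross-species numbering: a tail that starts
            # where the reference core ends (e.g. S. aureus, whose CTD
            # begins at position 65 in E. coli numbering).
            warnings.warn(
                "core and tail selections overlap: "
                f"{sorted(self.core & self.tail)}",
                stacklevel=2,
            )

    @property
    def off_target(self) -> frozenset[int]:
        return self.core - self.basic_core


def _element_of(atom_name: str) -> str:
    """Element symbol from a PDB atom name (first alphabetic character)."""
    stripped = str(atom_name).strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise EnsembleError(f"cannot infer element for atom name {atom_name!r}")


# ---------------------------------------------------------------------------
# Ensemble reading / writing


def read_ensemble(
    path: str | Path,
    energy_source: str = "remark",
    sidecar: str | Path | None = None,
    n_subunits: int | None = None,
    species_label: str = "",
) -> ModelEnsemble:
    """Read a multi-MODEL PDB file into a :class:`ModelEnsemble`.

    Parameters
    ----------
    path
        Multi-model PDB file (MODEL/ENDMDL delimited).
    energy_source
        ``"remark"`` expects ``REMARK 250 MODEL_ENERGY <id> <value>``
        header lines; ``"sidecar"`` reads a two-column CSV
        (``model_id,energy``) given via *sidecar*.
    n_subunits
        Number of ring subunits; defaults to the chain count of model 1.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise EnsembleError(f"{path}: no MODEL records found")

    model_serials = [
        int(line.split()[1]) for line in pdb.lines if line.startswith("MODEL")
    ]
    if len(model_serials) != n_models:
        model_serials = list(range(1, n_models + 1))

    if energy_source == "remark":
        energies: dict[int, float] = {}
        for line in pdb.lines:
            m = _ENERGY_REMARK.match(line)
            if m:
                energies[int(m.group(1))] = float(m.group(2))
    elif energy_source == "sidecar":
        if sidecar is None:
            raise EnsembleError("energy_source='sidecar' requires a path")
        tab = pd.read_csv(sidecar)
        if not {"model_id", "energy"} <= set(tab.columns):
            raise EnsembleError(
                f"{sidecar}: sidecar table needs columns model_id, energy"
            )
        energies = dict(
            zip(tab["model_id"].astype(int), tab["energy"].astype(float))
        )
    else:
        raise ValueError(f"unknown energy_source {energy_source!r}")

    missing = [s for s in model_serials if s not in energies]
    if missing:
        raise EnsembleError(
            f"{path}: missing energies for model(s) {missing}"
        )

    models = []
    for i, serial in enumerate(model_serials, start=1):
        arr = pdb.get_structure(model=i)
        models.append(
            Conformation(
                model_id=serial,
                total_energy=energies[serial],
                chain_ids=arr.chain_id.astype(str),
                res_ids=arr.res_id.astype(int),
                res_names=arr.res_name.astype(str),
                atom_names=arr.atom_name.astype(str),
                coord=np.asarray(arr.coord, dtype=float),
            )
        )

    ref = models[0].topology()
    for m in models[1:]:
        if m.topology() != ref:
            raise TopologyMismatchError(
                f"{path}: model {m.model_id} does not match the "
                f"chain/residue topology of model {models[0].model_id}"
            )

    if n_subunits is None:
        n_subunits = len(models[0].chains())
    return ModelEnsemble(
        models=models, n_subunits=n_subunits, species_label=species_label
    )


def write_ensemble(ensemble: ModelEnsemble, path: str | Path) -> None:
    """Write a multi-MODEL PDB with MODEL_ENERGY remark lines."""
    if not ensemble.models:
        raise EnsembleError("cannot write an empty ensemble")
    stack = struc.stack([m.to_atom_array() for m in ensemble.models])
    pdb = PDBFile()
    pdb.set_structure(stack)
    # biotite numbers MODEL records 1..n; rewrite serials so they match
    # the ensemble's model ids (which sidecar tables may refer to).
    lines = []
    k = 0
    for line in pdb.lines:
        if line.startswith("MODEL"):
            lines.append(f"MODEL     {ensemble.models[k].model_id:4d}")
            k += 1
        else:
            lines.append(line)
    remarks = [
        f"REMARK 250 MODEL_ENERGY {m.model_id} {m.total_energy:.6f}"
        for m in ensemble.models
    ]
    pdb.lines = remarks + lines
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections


def _expand(entries) -> frozenset[int]:
    out: set[int] = set()
    for e in entries:
        if isinstance(e, str) and "-" in e:
            lo, hi = e.split("-")
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(e))
    return frozenset(out)


def _default_config_path() -> Path:
    return Path(__file__).parent / "data" / "selections.yaml"


def available_species(path: str | Path | None = None) -> list[str]:
    with open(path or _default_config_path()) as fh:
        return sorted(yaml.safe_load(fh))


def load_selections(
    species: str, path: str | Path | None = None
) -> SelectionSets:
    """Load the residue selections for *species* from a YAML config.

    The shipped default config encodes the five bacterial Hfq rows
    (E. coli numbering) plus the coarse-grained ``toy`` system.
    """
    cfg_path = Path(path) if path is not None else _default_config_path()
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    lookup = {k.lower(): k for k in cfg}
    key = lookup.get(species.lower())
    if key is None:
        raise KeyError(
            f"unknown species {species!r}; available: {sorted(cfg)}"
        )
    entry = cfg[key]
    return SelectionSets(
        core=_expand(entry["core"]),
        tail=_expand(entry["tail"]),
        basic_core=_expand(entry["basic_core"]),
        numbering_scheme=str(entry.get("numbering", "E. coli")),
    )


# ---------------------------------------------------------------------------
# Solvent accessibility


def residue_sasa(
    conformation: Conformation,
    probe_radius: float = 1.4,
    point_number: int = 1000,
    include_residues: set[int] | None = None,
    aggregate: str = "mean",
) -> dict[int, float]:
    """Per-residue-number solvent-accessible surface area (Å²).

    Shrake-Rupley accessible surface with single-atom van der Waals
    radii and a deterministic Fibonacci sphere lattice of
    *point_number* points per atom.  Atom areas are summed per
    (chain, residue) and then aggregated across chains per residue
    number (``mean`` by default, ``sum`` optionally) so the result is
    indexed the same way as the residue selections.

    *include_residues* restricts the computation to those residue
    numbers (e.g. the core set, to assess core burial with the tails
    removed); excluded atoms neither receive nor occlude area.
    """
    mask = np.ones(conformation.n_atoms, dtype=bool)
    if include_residues is not None:
        mask = np.isin(conformation.res_ids, sorted(include_residues))
        if not mask.any():
            raise EnsembleError("include_residues selects no atoms")
    arr = conformation.to_atom_array()[mask]
    for name, elem in zip(arr.atom_name, arr.element):
        if vdw_radius_single(elem) is None:
            raise EnsembleError(
                f"no van der Waals radius for atom {name!r} "
                f"(element {elem!r})"
            )
    areas = struc.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii="Single",
    )
    df = pd.DataFrame(
        {
            "chain": arr.chain_id.astype(str),
            "res": arr.res_id.astype(int),
            "area": areas,
        }
    )
    per_chain = df.groupby(["chain", "res"])["area"].sum()
    agg = per_chain.groupby("res").agg(aggregate)
    return {int(r): float(a) for r, a in agg.items()}


def flag_buried(
    sasa_map: dict[int, float],
    core: set[int] | frozenset[int],
    cutoff: float = 2.0,
) -> frozenset[int]:
    """Core residues whose accessible area falls below *cutoff* (Å²)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    missing = sorted(r for r in core if r not in sasa_map)
    if missing:
        raise KeyError(
            f"core residue(s) {missing} absent from the SASA map"
        )
    return frozenset(x for x in core if sasa_map[x] < cutoff)
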