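"""Pairwise tail/core interaction energies.

The analysis needs one number per (model, subunit, core residue, tail
residue) pair: an interaction energy in REU-like units, negative when
favorable.  Such tables can be produced by any external full-atom
scorer and loaded from CSV, or computed here with a declared two-term
surrogate potential

    E(x, y) = k * q_x * q_y / (s * r**2) + c * max(0, r_rep - r)**2

i.e. a Coulomb term with distance-dependent dielectric eps(r) = s*r
plus a soft-sphere overlap penalty.  With the defaults (k = 332
kcal*Å/(mol*e²), s = 4) a +1/-1 salt-bridge-range contact at 5 Å
scores -3.32 and the -1.0 favorability threshold is crossed near
9 Å separation, so the electrostatic logic of an acidic tail tip
docking onto a basic core patch is preserved without any full-atom
physics.

Pairs with E >= 0 are never stored ("unfavorable" by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_io import Conformation, ModelEnsemble, SelectionSets

logger = logging.getLogger(__name__)

__all__ = [
    "SurrogateParams",
    "PairEnergyTable",
    "DEFAULT_CHARGES",
    "pair_energy_surrogate",
    "pair_energy_from_distance",
    "score_ensemble",
    "load_energy_table",
    "is_favorable",
    "FAVORABILITY_THRESHOLD",
]

#: Default favorability threshold (REU); interactions are "favorable"
#: when strictly below it.
FAVORABILITY_THRESHOLD = -1.0

#: Formal side-chain charges by 3-letter residue name.
DEFAULT_CHARGES: dict[str, float] = {
    "ASP": -1.0,
    "GLU": -1.0,
    "ARG": +1.0,
    "LYS": +1.0,
}

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

TABLE_COLUMNS = ["model_id", "subunit", "core_residue", "tail_residue", "energy"]


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the two-term surrogate potential."""

    charge_map: tuple = tuple(sorted(DEFAULT_CHARGES.items()))
    dielectric_slope: float = 4.0     # s in eps(r) = s*r, 1/Å
    coulomb_constant: float = 332.0   # k, kcal*Å/(mol*e²)
    repulsion_radius: float = 3.0     # r_rep, Å
    repulsion_strength: float = 10.0  # c, REU/Å²
    energy_unit_scale: float = 1.0    # kcal/mol-like -> REU-like
    #: Coulomb saturation distance (Å): below it the electrostatic term
    #: is evaluated at this distance, modelling the finite size of the
    #: charge centers and bounding contact energies near -5 REU so a
    #: salt-bridge-range contact scores roughly -2 to -4.
    coulomb_saturation: float = 4.0
    #: interaction cutoff (Å): pairs farther apart score exactly zero
    #: (the residual Coulomb term there is ~0.2 REU, well below the
    #: -1.0 favorability threshold).
    cutoff: float = 20.0

    def __post_init__(self) -> None:
        if self.dielectric_slope <= 0:
            raise ValueError("dielectric_slope must be positive")
        if self.repulsion_radius <= 0:
            raise ValueError("repulsion_radius must be positive")

    def charge_of(self, res_name: str) -> float:
        return dict(self.charge_map).get(str(res_name).upper(), 0.0)


def pair_energy_from_distance(
    q_x: float | np.ndarray,
    q_y: float | np.ndarray,
    r: float | np.ndarray,
    params: SurrogateParams = SurrogateParams(),
):
    """Evaluate the surrogate potential at separation *r* (Å)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    r_el = np.maximum(r, params.coulomb_saturation)
    coulomb = (
        params.coulomb_constant * np.asarray(q_x) * np.asarray(q_y)
        / (params.dielectric_slope * r_el**2)
    )
    overlap = np.maximum(0.0, params.repulsion_radius - r)
    rep = params.repulsion_strength * overlap**2
    out = params.energy_unit_scale * (coulomb + rep)
    out = np.where(r > params.cutoff, 0.0, out)
    return float(out) if out.ndim == 0 else out


def interaction_site(
    conf: Conformation, chain: str, res_id: int
) -> np.ndarray:
    """Side-chain charge-center pseudo-atom of one residue.

    Mean position of the side-chain heavy atoms; falls back to the
    alpha carbon for glycine or bead-only (CA) models.
    """
    sel = (conf.chain_ids == chain) & (conf.res_ids == res_id)
    if not sel.any():
        raise KeyError(f"residue {res_id} not found on chain {chain}")
    names = conf.atom_names[sel]
    coords = conf.coord[sel]
    side = np.array(
        [
            not (n.strip().upper() in _BACKBONE_ATOMS or n.strip().startswith("H"))
            for n in names
        ]
    )
    if side.any():
        return coords[side].mean(axis=0)
    ca = np.array([n.strip().upper() == "CA" for n in names])
    if ca.any():
        return coords[ca][0]
    return coords.mean(axis=0)


def pair_energy_surrogate(
    conf: Conformation,
    x: int,
    y: int,
    params: SurrogateParams = SurrogateParams(),
    x_chain: str | None = None,
    y_chain: str | None = None,
) -> float:
    """Surrogate energy between core residue *x* and tail residue *y*.

    Chains default to the first chain carrying each residue number.
    """
    def first_chain(res: int) -> str:
        for c in conf.chains():
            if ((conf.chain_ids == c) & (conf.res_ids == res)).any():
                return c
        raise KeyError(f"residue {res} not present in model {conf.model_id}")

    cx = x_chain or first_chain(x)
    cy = y_chain or first_chain(y)
    sx = interaction_site(conf, cx, x)
    sy = interaction_site(conf, cy, y)
    qx = params.charge_of(_res_name_of(conf, cx, x))
    qy = params.charge_of(_res_name_of(conf, cy, y))
    r = float(np.linalg.norm(sx - sy))
    return pair_energy_from_distance(qx, qy, r, params)


def _res_name_of(conf: Conformation, chain: str, res_id: int) -> str:
    sel = (conf.chain_ids == chain) & (conf.res_ids == res_id)
    return str(conf.res_names[sel][0])


@dataclass
class PairEnergyTable:
    """Sparse favorable-pair records for one ensemble.

    Only records with E < 0 are stored; at most one record exists per
    (model, subunit, core residue, tail residue) key.  ``model_ids``
    lists every model of the underlying ensemble, including models
    that contributed no favorable pair, because resampling statistics
    must draw from the full model set.
    """

    records: pd.DataFrame
    model_ids: tuple[int, ...]
    n_subunits: int

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=TABLE_COLUMNS).copy()
        df = df.astype(
            {
                "model_id": int,
                "subunit": int,
                "core_residue": int,
                "tail_residue": int,
                "energy": float,
            }
        )
        n_nonneg = int((df["energy"] >= 0).sum())
        if n_nonneg:
            logger.info(
                "dropping %d record(s) with non-negative energy", n_nonneg
            )
            df = df[df["energy"] < 0]
        if not np.isfinite(df["energy"]).all():
            raise ValueError("non-finite energies in table")
        keys = df[TABLE_COLUMNS[:4]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(
                f"duplicate (model, subunit, core, tail) record: {dup}"
            )
        unknown = set(df["model_id"]) - set(int(m) for m in self.model_ids)
        if unknown:
            raise ValueError(
                f"records refer to unknown model id(s) {sorted(unknown)}"
            )
        self.records = df.reset_index(drop=True)
        self.model_ids = tuple(int(m) for m in self.model_ids)
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")

    @property
    def n_models(self) -> int:
        return len(self.model_ids)

    def __len__(self) -> int:
        return len(self.records)

    def restrict_to_models(self, keep: list[int]) -> "PairEnergyTable":
        keep_set = set(keep)
        df = self.records[self.records["model_id"].isin(keep_set)]
        return PairEnergyTable(
            records=df, model_ids=tuple(keep), n_subunits=self.n_subunits
        )


def score_ensemble(
    ensemble: ModelEnsemble,
    selections: SelectionSets,
    params: SurrogateParams = SurrogateParams(),
) -> PairEnergyTable:
    """Score every (model, subunit, core x, tail y) pair of an ensemble.

    Each tail residue y belongs to the subunit whose chain carries it;
    the core residue x is identified by residue number only, because a
    tail can reach the rim of a neighboring subunit.  When several
    chains carry a copy of residue x, the most favorable (lowest)
    energy against y is kept so the (model, subunit, x, y) key stays
    unique.  Records with E >= 0 are discarded.
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    core = sorted(selections.core)
    tail = sorted(selections.tail)
    if not core or not tail:
        raise ValueError("empty selections")

    rows = []
    for conf in ensemble.models:
        chains = conf.chains()
        # Per-chain core sites and charges.
        core_sites: dict[str, np.ndarray] = {}
        core_res: dict[str, list[int]] = {}
        core_q: dict[str, np.ndarray] = {}
        for c in chains:
            present = [
                x for x in core
                if ((conf.chain_ids == c) & (conf.res_ids == x)).any()
            ]
            if not present:
                continue
            core_res[c] = present
            core_sites[c] = np.array(
                [interaction_site(conf, c, x) for x in present]
            )
            core_q[c] = np.array(
                [params.charge_of(_res_name_of(conf, c, x)) for x in present]
            )
        for subunit, c in enumerate(chains):
            tail_here = [
                y for y in tail
                if ((conf.chain_ids == c) & (conf.res_ids == y)).any()
            ]
            for y in tail_here:
                sy = interaction_site(conf, c, y)
                qy = params.charge_of(_res_name_of(conf, c, y))
                best: dict[int, float] = {}
                for cc in core_sites:
                    r = np.linalg.norm(core_sites[cc] - sy, axis=1)
                    e = pair_energy_from_distance(core_q[cc], qy, r, params)
                    for x, ex in zip(core_res[cc], np.atleast_1d(e)):
                        if x not in best or ex < best[x]:
                            best[x] = float(ex)
                for x, ex in best.items():
                    if ex < 0:
                        rows.append((conf.model_id, subunit, x, y, ex))
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return PairEnergyTable(
        records=df,
        model_ids=tuple(ensemble.model_ids),
        n_subunits=ensemble.n_subunits,
    )


def load_energy_table(
    path: str | Path,
    n_subunits: int = 6,
    model_ids: list[int] | None = None,
) -> PairEnergyTable:
    """Load a pair-energy CSV (model_id, subunit, core_residue,
    tail_residue, energy); rows with E >= 0 are dropped with a logged
    count, duplicate keys are a hard error."""
    df = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        ids = tuple(model_ids or ())
        return PairEnergyTable(
            records=df, model_ids=ids, n_subunits=n_subunits
        )
    keys = df[TABLE_COLUMNS[:4]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"{path}: duplicate record key {dup}")
    if model_ids is None:
        model_ids = sorted(df["model_id"].astype(int).unique())
    return PairEnergyTable(
        records=df, model_ids=tuple(model_ids), n_subunits=n_subunits
    )


def is_favorable(
    energy: float | np.ndarray,
    threshold: float = FAVORABILITY_THRESHOLD,
):
    """Favorability indicator: 1 iff E < threshold (strict)."""
    out = (np.asarray(energy, dtype=float) < threshold).astype(int)
    return int(out) if out.ndim == 0 else out
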