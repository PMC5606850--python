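"""Synthetic inputs with known ground truth.

Two families of generators feed the pipeline:

* a coarse-grained bead hexamer whose six disordered tails are
  sampled by Metropolis Monte Carlo under the same surrogate
  potential the scorer uses, standing in for full-atom disordered-
  region sampling.  Its only job is to produce multi-model ensembles
  with a *tunable* tail-tip/core contact propensity (acidic tip
  charges are attracted to the basic rim beads; neutralized tips are
  not), so the downstream statistics can be exercised against a known
  truth;
* noisy titration, competition, anisotropy-release and progress-curve
  datasets generated directly from the binding models with recorded
  true parameters.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .binding_fits import AnisotropyPhases, ProgressCurve, TitrationDataset
from .ensemble_io import Conformation, ModelEnsemble
from .surrogate_energy import SurrogateParams

__all__ = [
    "ToyHexamerSpec",
    "SyntheticGroundTruth",
    "sample_tail_ensemble",
    "generate_titration",
    "generate_competition",
    "generate_release_timecourse",
    "generate_progress_curve",
]

_CHAIN_IDS = "ABCDEF"

#: bead residue name by formal charge, chosen so the scorer's default
#: charge map reproduces the generator's charges.
_RESNAME_BY_CHARGE = {-1.0: "GLU", 0.0: "SER", 1.0: "LYS"}


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """True parameters of a generated dataset, serialized alongside it."""

    kind: str
    params: dict
    seed: int

    def to_dict(self) -> dict:
        return {"kind": self.kind, "seed": self.seed, "params": self.params}


@dataclass(frozen=True)
class ToyHexamerSpec:
    """Geometry and charges of the coarse-grained bead hexamer.

    Six subunits sit on a ring; each carries 12 core beads (residues
    1-12) of which residues 3, 5, 7 form the basic (+1) rim patch and
    residue 9 is acidic (-1), plus a freely jointed tail of
    ``tail_length`` beads (residues 13 onward) grafted at a rim
    anchor.  The tip charges default to four acidic residues, the
    configuration whose tail-core statistics the analysis is meant to
    detect; passing zeros gives the neutralized-tip control.
    """

    ring_radius: float = 30.0
    bond_length: float = 3.8
    tail_length: int = 12
    tip_charges: tuple[float, ...] = (-1.0, -1.0, -1.0, -1.0)
    kT: float = 1.0
    seed: int = 0
    energy_params: SurrogateParams = SurrogateParams()

    def __post_init__(self) -> None:
        if self.tail_length < 5:
            raise ValueError("tail_length must be >= 5")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")
        if len(self.tip_charges) > self.tail_length:
            raise ValueError("more tip charges than tail residues")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    # -- residue bookkeeping -------------------------------------------------

    @property
    def core_residues(self) -> tuple[int, ...]:
        return tuple(range(1, 13))

    @property
    def tail_residues(self) -> tuple[int, ...]:
        return tuple(range(13, 13 + self.tail_length))

    @property
    def tip_residues(self) -> tuple[int, ...]:
        """Last len(tip_charges) tail residues (the selection 'tail' set)."""
        return self.tail_residues[-len(self.tip_charges):]

    def core_charge(self, res: int) -> float:
        return {3: 1.0, 5: 1.0, 7: 1.0, 9: -1.0}.get(res, 0.0)

    def tail_charge(self, res: int) -> float:
        tips = self.tip_residues
        if res in tips:
            return float(self.tip_charges[tips.index(res)])
        return 0.0

    # -- geometry ------------------------------------------------------------

    def _subunit_frame(self, j: int):
        theta = math.radians(60.0 * j)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])  # radial
        v = np.array([-math.sin(theta), math.cos(theta), 0.0])  # tangent
        w = np.array([0.0, 0.0, 1.0])
        center = self.ring_radius * u
        return center, u, v, w

    def core_bead_positions(self, j: int) -> np.ndarray:
        """(12, 3) bead coordinates of subunit j."""
        center, u, v, w = self._subunit_frame(j)
        pos = []
        for i in range(1, 13):
            row = 0 if i <= 6 else 1
            col = (i - 1) % 6
            a, b = 2.0, -7.5 + 3.0 * col
            c = 2.0 if row == 0 else -2.0
            pos.append(center + a * u + b * v + c * w)
        return np.array(pos)

    def anchor_position(self, j: int) -> np.ndarray:
        center, u, _, _ = self._subunit_frame(j)
        return center + 6.0 * u


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _beads_core_energy(
    pos: np.ndarray,
    q: np.ndarray,
    core_pos: np.ndarray,
    core_q: np.ndarray,
    params: SurrogateParams,
) -> float:
    """Total surrogate energy of tail beads against all core beads."""
    d = np.linalg.norm(pos[:, None, :] - core_pos[None, :, :], axis=2)
    d = np.maximum(d, 1e-6)
    coulomb = (
        params.coulomb_constant * np.outer(q, core_q)
        / (params.dielectric_slope * d**2)
    )
    rep = params.repulsion_strength * np.maximum(
        0.0, params.repulsion_radius - d
    ) ** 2
    return float(params.energy_unit_scale * (coulomb + rep).sum())


def _sample_one_tail(
    spec: ToyHexamerSpec,
    anchor: np.ndarray,
    outward: np.ndarray,
    core_pos: np.ndarray,
    core_q: np.ndarray,
    n_moves: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Metropolis pivot sampling of one freely jointed tail.

    The first tail bead is fixed at the graft anchor; each move picks
    a joint and rotates the downstream beads about a random axis.
    """
    L = spec.tail_length
    q = np.array([spec.tail_charge(r) for r in spec.tail_residues])
    # straight radial start, pointing away from the core
    pos = anchor[None, :] + np.arange(L)[:, None] * spec.bond_length * outward
    energy = _beads_core_energy(pos, q, core_pos, core_q, spec.energy_params)
    if not np.isfinite(energy):
        raise RuntimeError(
            "tail cannot avoid core overlap at the given bond_length"
        )
    params = spec.energy_params
    for _ in range(n_moves):
        joint = int(rng.integers(0, L - 1))
        axis = rng.normal(size=3)
        while np.linalg.norm(axis) < 1e-12:
            axis = rng.normal(size=3)
        angle = rng.normal(0.0, 1.0)
        R = _rotation_matrix(axis, angle)
        pivot = pos[joint]
        suffix = pos[joint + 1:]
        new_suffix = (suffix - pivot) @ R.T + pivot
        e_old = _beads_core_energy(
            suffix, q[joint + 1:], core_pos, core_q, params
        )
        e_new = _beads_core_energy(
            new_suffix, q[joint + 1:], core_pos, core_q, params
        )
        delta = e_new - e_old
        if delta <= 0 or rng.random() < math.exp(-delta / spec.kT):
            pos = pos.copy()
            pos[joint + 1:] = new_suffix
            energy += delta
    return pos, energy


def sample_tail_ensemble(
    spec: ToyHexamerSpec,
    n_models: int,
    moves_per_residue: int = 500,
) -> tuple[ModelEnsemble, SyntheticGroundTruth]:
    """Sample an ensemble of bead-hexamer conformations.

    Each model equilibrates all six tails independently with
    ``moves_per_residue * tail_length`` Metropolis moves per tail; the
    per-model total energy is the summed tail-core surrogate energy.
    The output serializes as a multi-model PDB whose residue numbers
    match the shipped ``toy`` selections entry.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if moves_per_residue < 1:
        raise ValueError("moves_per_residue must be >= 1")
    rng = np.random.default_rng(spec.seed)
    core_pos_all = np.vstack([spec.core_bead_positions(j) for j in range(6)])
    core_q_all = np.tile(
        [spec.core_charge(r) for r in spec.core_residues], 6
    ).astype(float)
    n_moves = moves_per_residue * spec.tail_length

    core_names = [
        _RESNAME_BY_CHARGE[spec.core_charge(r)] for r in spec.core_residues
    ]
    tail_names = [
        _RESNAME_BY_CHARGE[spec.tail_charge(r)] for r in spec.tail_residues
    ]

    models = []
    for m in range(1, n_models + 1):
        chain_ids, res_ids, res_names, coords = [], [], [], []
        total = 0.0
        for j in range(6):
            cpos = spec.core_bead_positions(j)
            chain_ids += [_CHAIN_IDS[j]] * 12
            res_ids += list(spec.core_residues)
            res_names += core_names
            coords.append(cpos)
            center, u, _, _ = spec._subunit_frame(j)
            tail_pos, e = _sample_one_tail(
                spec, spec.anchor_position(j), u,
                core_pos_all, core_q_all, n_moves, rng,
            )
            total += e
            chain_ids += [_CHAIN_IDS[j]] * spec.tail_length
            res_ids += list(spec.tail_residues)
            res_names += tail_names
            coords.append(tail_pos)
        n_atoms = len(res_ids)
        models.append(
            Conformation(
                model_id=m,
                total_energy=total,
                chain_ids=np.array(chain_ids),
                res_ids=np.array(res_ids, dtype=int),
                res_names=np.array(res_names),
                atom_names=np.array(["CA"] * n_atoms),
                coord=np.vstack(coords),
            )
        )
    ensemble = ModelEnsemble(models=models, n_subunits=6, species_label="toy")
    gt = SyntheticGroundTruth(
        kind="tail_ensemble",
        params={
            "tip_charges": list(spec.tip_charges),
            "tail_length": spec.tail_length,
            "ring_radius": spec.ring_radius,
            "bond_length": spec.bond_length,
            "kT": spec.kT,
            "n_models": n_models,
            "moves_per_residue": moves_per_residue,
        },
        seed=spec.seed,
    )
    return ensemble, gt


# ---------------------------------------------------------------------------
# Tabular datasets


def generate_titration(
    true_kd: float,
    hill_n: float = 1.0,
    n_points: int = 12,
    x_span: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
    unit: str = "µM",
    basis: str = "monomer",
) -> tuple[TitrationDataset, SyntheticGroundTruth]:
    """Noisy saturation titration from the Hill/single-site model.

    y = xⁿ/(Kdⁿ + xⁿ) plus i.i.d. Gaussian noise; with *replicates*
    the stored signal is the replicate mean and ``y_sd`` the
    replicate SD, mirroring duplicate-measurement practice.
    """
    if true_kd <= 0:
        raise ValueError("true_kd must be positive")
    if x_span is None:
        x_span = (true_kd / 50.0, true_kd * 50.0)
    if not (x_span[0] < true_kd < x_span[1]):
        raise ValueError("x_span must bracket true_kd")
    rng = np.random.default_rng(seed)
    x = np.geomspace(x_span[0], x_span[1], n_points)
    clean = x**hill_n / (true_kd**hill_n + x**hill_n)
    draws = clean[None, :] + rng.normal(0, noise_sd, size=(replicates, n_points))
    y = draws.mean(axis=0)
    y_sd = draws.std(axis=0, ddof=1) if replicates > 1 else None
    data = TitrationDataset(
        x=x, y=y, y_sd=y_sd, unit=unit, basis=basis, replicates=replicates
    )
    gt = SyntheticGroundTruth(
        kind="titration",
        params={
            "Kd": true_kd, "n": hill_n, "noise_sd": noise_sd,
            "unit": unit, "basis": basis,
        },
        seed=seed,
    )
    return data, gt


def generate_competition(
    true_ic50: float,
    n: float = 1.0,
    min_y: float = 1.0,
    max_y: float = 1.6,
    n_points: int = 12,
    x_span: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    unit: str = "µM",
    basis: str = "competitor",
) -> tuple[TitrationDataset, SyntheticGroundTruth]:
    """Noisy competition curve y = minY + (maxY − minY)/(1 + (x/IC50)ⁿ)."""
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be positive")
    if x_span is None:
        x_span = (true_ic50 / 50.0, true_ic50 * 50.0)
    if not (x_span[0] < true_ic50 < x_span[1]):
        raise ValueError("x_span must bracket true_ic50")
    rng = np.random.default_rng(seed)
    x = np.geomspace(x_span[0], x_span[1], n_points)
    clean = min_y + (max_y - min_y) / (1.0 + (x / true_ic50) ** n)
    y = clean + rng.normal(0, noise_sd, size=n_points)
    data = TitrationDataset(x=x, y=y, unit=unit, basis=basis)
    gt = SyntheticGroundTruth(
        kind="competition",
        params={
            "IC50": true_ic50, "n": n, "minY": min_y, "maxY": max_y,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return data, gt


def generate_release_timecourse(
    phases: AnisotropyPhases,
    true_fractions: tuple[float, float, float],
    noise_sd: float = 0.0,
    n_points: int = 10,
    dt: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, AnisotropyPhases, SyntheticGroundTruth]:
    """Endpoint anisotropy series for given (χ_dr, χ_hdr, χ_hd).

    The noiseless r_AP is the fraction-weighted mix of the three
    species' anisotropies; K_rel is set to χ_hd/χ_hdr so the
    deconvolution applied to the noiseless output returns the true
    fractions exactly.  Returns (times, values, phases_out, truth)
    where ``phases_out`` carries the consistent r_AP and K_rel.
    """
    chi_dr, chi_hdr, chi_hd = (float(v) for v in true_fractions)
    total = chi_dr + chi_hdr + chi_hd
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {total})")
    if min(chi_dr, chi_hdr, chi_hd) < 0:
        raise ValueError("fractions must be non-negative")
    if chi_hdr == 0 and chi_hd > 0:
        raise ValueError("chi_hd > 0 requires chi_hdr > 0 (finite K_rel)")
    k_rel = chi_hd / chi_hdr if chi_hdr > 0 else 0.0
    r_ap = (
        chi_dr * phases.r_Mdr
        + chi_hdr * phases.r_Mhdr
        + chi_hd * phases.r_hd
    )
    phases_out = replace(phases, r_AP=r_ap, K_rel=k_rel)
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt
    values = r_ap + rng.normal(0, noise_sd, size=n_points)
    gt = SyntheticGroundTruth(
        kind="release_timecourse",
        params={
            "chi_dr": chi_dr, "chi_hdr": chi_hdr, "chi_hd": chi_hd,
            "K_rel": k_rel, "r_AP": r_ap, "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return t, values, phases_out, gt


def generate_progress_curve(
    k: float = 0.5,
    amplitude: float = 1.0,
    offset: float = 0.0,
    n_points: int = 100,
    t_max: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ProgressCurve, SyntheticGroundTruth]:
    """Single-exponential annealing trace y = A(1 − e^{−kt}) + c."""
    if k <= 0:
        raise ValueError("rate must be positive")
    if t_max is None:
        t_max = 5.0 / k
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    y = amplitude * (1.0 - np.exp(-k * t)) + offset
    y = y + rng.normal(0, noise_sd, size=n_points)
    curve = ProgressCurve(t=t, y=y)
    gt = SyntheticGroundTruth(
        kind="progress_curve",
        params={"k": k, "A": amplitude, "c": offset, "noise_sd": noise_sd},
        seed=seed,
    )
    return curve, gt
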