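"""Ensemble interaction statistics: <N_x>, <E_x:T>, EEC and ΔEEC.

For every core residue x the analysis reports

* ``<N_x>`` — mean number of favorable tail contacts per tail and
  model: sum over models, subunits and tail residues of the indicator
  δ(x, y) = [E(x, y) < threshold], divided by N_subunits * N_models;
* ``<E_x:T>`` — mean favorable interaction energy on the same
  normalization (zero cells included), with a population SD taken over
  the per-(model, subunit) summed qualifying energies;
* a bootstrap SD for ``<N_x>`` from B resamples-with-replacement of
  the model set (the energy SD needs no resampling: energies vary
  within a model set, contact presence only varies across resamples).

The Expected Energetic Contribution of a residue set is
``EEC = sum_x <N_x> * <E_x:T>``; its variance adds, per residue,
``σ_E²σ_N² + σ_E²<N>² + σ_N²<E>²`` assuming independent errors.
ΔEEC is EEC over the basic (on-target) set minus EEC over the
remaining (off-target) core; more negative means the tail binds the
basic patch specifically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble_io import ModelEnsemble, SelectionSets
from .surrogate_energy import FAVORABILITY_THRESHOLD, PairEnergyTable

__all__ = [
    "InteractionSummary",
    "select_low_energy",
    "mean_counts",
    "mean_energy",
    "bootstrap_sd_counts",
    "eec",
    "delta_eec",
    "summarize",
]

COUNT_MODES = ("as-printed", "binary")


def select_low_energy(
    ensemble: ModelEnsemble, fraction: float = 0.01
) -> ModelEnsemble:
    """The lowest-energy max(1, floor(fraction*M)) models.

    Ties are broken by ascending model id; the returned subset keeps
    the energy ordering, so the selection is deterministic.
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, math.floor(fraction * len(ensemble)))
    ranked = sorted(
        ensemble.models, key=lambda m: (m.total_energy, m.model_id)
    )
    return ModelEnsemble(
        models=ranked[:k],
        n_subunits=ensemble.n_subunits,
        species_label=ensemble.species_label,
    )


def _favorable(table: PairEnergyTable, threshold: float) -> pd.DataFrame:
    return table.records[table.records["energy"] < threshold]


def _per_model_counts(
    fav: pd.DataFrame, x: int, model_ids: tuple[int, ...], count_mode: str
) -> np.ndarray:
    """Qualifying-contact count of residue x in each model (ordered)."""
    sub = fav[fav["core_residue"] == x]
    if count_mode == "as-printed":
        counts = sub.groupby("model_id").size()
    elif count_mode == "binary":
        counts = (
            sub.groupby(["model_id", "subunit"]).size()
            .groupby("model_id").size()
        )
    else:
        raise ValueError(f"count_mode must be one of {COUNT_MODES}")
    return np.array([counts.get(m, 0) for m in model_ids], dtype=float)


def mean_counts(
    table: PairEnergyTable,
    selections: SelectionSets,
    threshold: float = FAVORABILITY_THRESHOLD,
    count_mode: str = "as-printed",
) -> dict[int, float]:
    """<N_x> for every core residue (zero where nothing qualifies).

    ``as-printed`` sums δ over all tail residues, so one tail touching
    a core residue with two of its tip residues counts twice;
    ``binary`` counts at most one contact per (model, subunit).
    """
    if count_mode not in COUNT_MODES:
        raise ValueError(f"count_mode must be one of {COUNT_MODES}")
    fav = _favorable(table, threshold)
    denom = table.n_subunits * table.n_models
    if count_mode == "as-printed":
        counts = fav.groupby("core_residue").size()
    else:
        counts = (
            fav.groupby(["core_residue", "model_id", "subunit"]).size()
            .groupby("core_residue").size()
        )
    return {
        int(x): float(counts.get(x, 0)) / denom for x in sorted(selections.core)
    }


def mean_energy(
    table: PairEnergyTable,
    x: int,
    threshold: float = FAVORABILITY_THRESHOLD,
) -> tuple[float, float]:
    """(<E_x:T>, σ_E) for core residue x.

    The mean divides the summed qualifying energies by
    N_subunits * N_models (cells without a qualifying contact count as
    zero); σ_E is the population SD of the per-(model, subunit) summed
    qualifying energy around that mean.
    """
    fav = _favorable(table, threshold)
    sub = fav[fav["core_residue"] == x]
    n_cells = table.n_subunits * table.n_models
    if n_cells == 0:
        raise ValueError("table covers no models")
    cell_sums = sub.groupby(["model_id", "subunit"])["energy"].sum()
    mean = float(cell_sums.sum()) / n_cells
    n_zero = n_cells - len(cell_sums)
    ss = float(((cell_sums - mean) ** 2).sum()) + n_zero * mean**2
    sd = math.sqrt(ss / n_cells)
    return mean, sd


def bootstrap_sd_counts(
    table: PairEnergyTable,
    x: int,
    B: int = 1000,
    seed: int = 0,
    threshold: float = FAVORABILITY_THRESHOLD,
    count_mode: str = "as-printed",
) -> float:
    """Bootstrap SD of <N_x> over B resamples of the model set.

    The model list is resampled with replacement B times, <N_x> is
    recomputed on each replicate multiset, and the SD of the B
    replicate values is returned.  The replicate stream is derived
    deterministically from (seed, x) so per-residue results do not
    depend on evaluation order.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    M = table.n_models
    if M == 0:
        raise ValueError("table covers no models")
    if M == 1:
        warnings.warn("single-model table: bootstrap SD is 0", stacklevel=2)
        return 0.0
    fav = _favorable(table, threshold)
    per_model = _per_model_counts(fav, x, table.model_ids, count_mode)
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(x)]))
    idx = rng.integers(0, M, size=(B, M))
    replicates = per_model[idx].sum(axis=1) / (table.n_subunits * M)
    return float(replicates.std(ddof=0))


def eec(
    counts: dict[int, float],
    energies: dict[int, float],
    sd_counts: dict[int, float],
    sd_energies: dict[int, float],
    residue_set: set[int] | frozenset[int],
    core: set[int] | frozenset[int] | None = None,
) -> tuple[float, float]:
    """EEC = sum_x <N_x><E_x:T> over *residue_set*, with propagated SD.

    Per residue the variance is σ_E²σ_N² + σ_E²<N>² + σ_N²<E>²;
    variances add across residues (independent errors).
    """
    if core is not None:
        outside = sorted(set(residue_set) - set(core))
        if outside:
            raise ValueError(f"residues {outside} are outside the core set")
    total = 0.0
    var = 0.0
    for x in residue_set:
        n = counts.get(x, 0.0)
        e = energies.get(x, 0.0)
        sn = sd_counts.get(x, 0.0)
        se = sd_energies.get(x, 0.0)
        total += n * e
        var += se**2 * sn**2 + se**2 * n**2 + sn**2 * e**2
    return total, math.sqrt(var)


@dataclass
class InteractionSummary:
    """Per-residue statistics plus EEC/ΔEEC for one scored ensemble."""

    per_residue: pd.DataFrame  # residue, mean_count, sd_count, mean_energy, sd_energy
    eec_on: float
    eec_on_sd: float
    eec_off: float
    eec_off_sd: float
    delta_eec: float
    delta_eec_sd: float
    n_models_used: int
    threshold: float
    bootstrap_B: int
    seed: int
    count_mode: str
    excluded_buried: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "per_residue": self.per_residue.to_dict(orient="records"),
            "eec": {
                "on_target": self.eec_on,
                "on_target_sd": self.eec_on_sd,
                "off_target": self.eec_off,
                "off_target_sd": self.eec_off_sd,
                "delta": self.delta_eec,
                "delta_sd": self.delta_eec_sd,
            },
            "settings": {
                "n_models_used": self.n_models_used,
                "threshold": self.threshold,
                "bootstrap_B": self.bootstrap_B,
                "seed": self.seed,
                "count_mode": self.count_mode,
                "excluded_buried": list(self.excluded_buried),
            },
        }


def delta_eec(
    table: PairEnergyTable,
    selections: SelectionSets,
    threshold: float = FAVORABILITY_THRESHOLD,
    buried: set[int] | frozenset[int] | None = None,
    exclude_buried: bool = False,
    B: int = 1000,
    seed: int = 0,
    count_mode: str = "as-printed",
) -> tuple[float, float]:
    """ΔEEC = EEC(basic core) − EEC(other core), with propagated SD."""
    s = summarize(
        table,
        selections,
        threshold=threshold,
        buried=buried,
        exclude_buried=exclude_buried,
        B=B,
        seed=seed,
        count_mode=count_mode,
    )
    return s.delta_eec, s.delta_eec_sd


def summarize(
    table: PairEnergyTable,
    selections: SelectionSets,
    threshold: float = FAVORABILITY_THRESHOLD,
    buried: set[int] | frozenset[int] | None = None,
    exclude_buried: bool = False,
    B: int = 1000,
    seed: int = 0,
    count_mode: str = "as-printed",
) -> InteractionSummary:
    """Full per-residue and EEC/ΔEEC summary of a scored ensemble."""
    on = set(selections.basic_core)
    off = set(selections.off_target)
    if exclude_buried:
        if buried is None:
            raise ValueError("exclude_buried requires a buried set")
        off -= set(buried)
    if not off:
        raise ValueError("off-target residue set is empty")

    counts = mean_counts(table, selections, threshold, count_mode)
    energies: dict[int, float] = {}
    sd_energies: dict[int, float] = {}
    sd_counts: dict[int, float] = {}
    for x in sorted(selections.core):
        e, se = mean_energy(table, x, threshold)
        energies[x], sd_energies[x] = e, se
        if counts[x] > 0 and table.n_models > 1:
            sd_counts[x] = bootstrap_sd_counts(
                table, x, B=B, seed=seed,
                threshold=threshold, count_mode=count_mode,
            )
        else:
            sd_counts[x] = 0.0

    per_residue = pd.DataFrame(
        {
            "residue": sorted(selections.core),
            "mean_count": [counts[x] for x in sorted(selections.core)],
            "sd_count": [sd_counts[x] for x in sorted(selections.core)],
            "mean_energy": [energies[x] for x in sorted(selections.core)],
            "sd_energy": [sd_energies[x] for x in sorted(selections.core)],
        }
    )
    eec_on, sd_on = eec(
        counts, energies, sd_counts, sd_energies, on, selections.core
    )
    eec_off, sd_off = eec(
        counts, energies, sd_counts, sd_energies, off, selections.core
    )
    d = eec_on - eec_off
    d_sd = math.sqrt(sd_on**2 + sd_off**2)
    return InteractionSummary(
        per_residue=per_residue,
        eec_on=eec_on,
        eec_on_sd=sd_on,
        eec_off=eec_off,
        eec_off_sd=sd_off,
        delta_eec=d,
        delta_eec_sd=d_sd,
        n_models_used=table.n_models,
        threshold=threshold,
        bootstrap_B=B,
        seed=seed,
        count_mode=count_mode,
        excluded_buried=tuple(sorted(buried)) if (exclude_buried and buried) else (),
    )
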