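"""Ensemble statistics: counts, energies, EEC/ΔEEC, bootstrap errors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfqtail.ensemble_io import ModelEnsemble, SelectionSets
from hfqtail.interaction_stats import (
    bootstrap_sd_counts,
    delta_eec,
    eec,
    mean_counts,
    mean_energy,
    select_low_energy,
    summarize,
)
from hfqtail.surrogate_energy import PairEnergyTable

from conftest import make_bead_conformation

COLUMNS = ["model_id", "subunit", "core_residue", "tail_residue", "energy"]


def make_table(rows, model_ids, n_subunits=6):
    return PairEnergyTable(
        records=pd.DataFrame(rows, columns=COLUMNS),
        model_ids=tuple(model_ids),
        n_subunits=n_subunits,
    )


SEL = SelectionSets(
    core=frozenset({16, 17, 47}),
    tail=frozenset({97, 99}),
    basic_core=frozenset({16, 17}),
)


# ---------------------------------------------------------------------------
# Independent enumeration oracle


def oracle_stats(rows, model_ids, n_subunits, core, threshold=-1.0):
    """Direct triple-loop evaluation of <N_x>, <E_x:T> and sigma_E."""
    M, S = len(model_ids), n_subunits
    out = {}
    for x in core:
        count = 0
        cell_sum = {(m, s): 0.0 for m in model_ids for s in range(S)}
        for (m, s, cx, ty, e) in rows:
            if cx == x and e < threshold:
                count += 1
                cell_sum[(m, s)] += e
        mean_n = count / (S * M)
        mean_e = sum(cell_sum.values()) / (S * M)
        var_e = sum((v - mean_e) ** 2 for v in cell_sum.values()) / (S * M)
        out[x] = (mean_n, mean_e, math.sqrt(var_e))
    return out


# ---------------------------------------------------------------------------


def _energy_ensemble(energies):
    models = [
        make_bead_conformation(
            i + 1, e, [("A", 1, "GLY", (float(i), 0.0, 0.0))]
        )
        for i, e in enumerate(energies)
    ]
    return ModelEnsemble(models=models, n_subunits=1)


class TestSelectLowEnergy:
    def test_one_percent_of_300_gives_3_smallest(self):
        energies = list(range(300))
        ens = _energy_ensemble(energies)
        sub = select_low_energy(ens, 0.01)
        assert [m.total_energy for m in sub.models] == [0, 1, 2]

    def test_small_ensemble_clamps_to_one_model(self):
        ens = _energy_ensemble([5.0, -1.0, 3.0] + [10.0] * 47)
        sub = select_low_energy(ens, 0.01)
        assert len(sub) == 1
        assert sub.models[0].total_energy == -1.0

    def test_equal_energies_break_ties_by_model_id(self):
        ens = _energy_ensemble([7.0] * 200)
        sub = select_low_energy(ens, 0.01)
        assert sub.model_ids == [1, 2]

    def test_empty_ensemble_is_error(self):
        with pytest.raises(ValueError):
            select_low_energy(ModelEnsemble(models=[], n_subunits=6), 0.01)

    def test_fraction_one_keeps_everything(self):
        ens = _energy_ensemble([3.0, 1.0, 2.0])
        assert len(select_low_energy(ens, 1.0)) == 3


class TestMeanCounts:
    def test_full_symmetric_occupancy(self):
        rows = [(1, s, 16, 97, -2.0) for s in range(6)]
        table = make_table(rows, [1])
        assert mean_counts(table, SEL)[16] == pytest.approx(1.0)

    def test_partial_occupancy_two_of_twelve(self):
        rows = [(1, 0, 16, 97, -2.0), (1, 1, 16, 97, -2.0)]
        table = make_table(rows, [1, 2])
        assert mean_counts(table, SEL)[16] == pytest.approx(2 / 12)

    def test_two_tail_residues_one_subunit_count_modes(self):
        # one subunit where residue 16 touches both tail residues:
        # summing over tail residues counts 2, the per-subunit binary
        # variant counts 1
        rows = [(1, 0, 16, 97, -2.0), (1, 0, 16, 99, -3.0)]
        table = make_table(rows, [1])
        assert mean_counts(table, SEL, count_mode="as-printed")[16] == pytest.approx(2 / 6)
        assert mean_counts(table, SEL, count_mode="binary")[16] == pytest.approx(1 / 6)

    def test_empty_table_gives_all_zeros(self):
        table = make_table([], [1, 2])
        counts = mean_counts(table, SEL)
        assert set(counts) == set(SEL.core)
        assert all(v == 0.0 for v in counts.values())

    def test_raising_threshold_magnitude_never_increases_counts(self):
        rows = [
            (1, 0, 16, 97, -2.0), (1, 1, 16, 97, -1.2),
            (1, 2, 16, 99, -4.0), (2, 0, 17, 97, -1.05),
        ]
        table = make_table(rows, [1, 2])
        for x in SEL.core:
            prev = mean_counts(table, SEL, threshold=-1.0)[x]
            for thr in (-1.5, -2.5, -5.0):
                cur = mean_counts(table, SEL, threshold=thr)[x]
                assert cur <= prev
                prev = cur


class TestMeanEnergy:
    def test_symmetric_case_constant_energy(self):
        rows = [(1, s, 16, 97, -2.0) for s in range(6)]
        table = make_table(rows, [1])
        e, sd = mean_energy(table, 16)
        assert e == pytest.approx(-2.0)
        assert sd == pytest.approx(0.0)

    def test_single_qualifying_pair_in_one_subunit(self):
        rows = [(1, 0, 16, 97, -2.0)]
        table = make_table(rows, [1])
        e, sd = mean_energy(table, 16)
        assert e == pytest.approx(-2.0 / 6.0)
        # population SD over cells {-2, 0, 0, 0, 0, 0}
        cells = np.array([-2.0, 0, 0, 0, 0, 0])
        assert sd == pytest.approx(cells.std(ddof=0))

    def test_no_qualifying_pairs(self):
        table = make_table([], [1])
        assert mean_energy(table, 16) == (0.0, 0.0)


class TestBootstrap:
    def test_identical_models_have_zero_sd(self):
        rows = [(m, 0, 16, 97, -2.0) for m in (1, 2, 3, 4)]
        table = make_table(rows, [1, 2, 3, 4])
        assert bootstrap_sd_counts(table, 16, B=500, seed=0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(7)
        rows = [
            (m, s, 16, 97, -2.0)
            for m in range(1, 21) for s in range(6)
            if rng.random() < 0.4
        ]
        table = make_table(rows, list(range(1, 21)))
        a = bootstrap_sd_counts(table, 16, B=300, seed=11)
        b = bootstrap_sd_counts(table, 16, B=300, seed=11)
        assert a == b
        assert bootstrap_sd_counts(table, 16, B=300, seed=12) != a

    def test_matches_analytic_standard_error_of_mean(self):
        # i.i.d. per-model counts: bootstrap SE of the mean ~ sd/sqrt(M)
        rng = np.random.default_rng(3)
        M = 50
        per_model = rng.poisson(3.0, size=M)
        rows = []
        for m, c in enumerate(per_model, start=1):
            for i in range(int(c)):
                rows.append((m, i % 6, 16, 97 + 2 * (i // 6 % 2), -2.0))
        table = make_table(rows, list(range(1, M + 1)))
        got = bootstrap_sd_counts(table, 16, B=1000, seed=5)
        expected = per_model.std(ddof=0) / np.sqrt(M) / 6
        assert got == pytest.approx(expected, rel=0.15)

    def test_single_model_warns_and_returns_zero(self):
        table = make_table([(1, 0, 16, 97, -2.0)], [1])
        with pytest.warns(UserWarning):
            assert bootstrap_sd_counts(table, 16, B=100, seed=0) == 0.0


class TestEEC:
    def test_single_residue_no_error(self):
        v, sd = eec({16: 1.0}, {16: -2.0}, {16: 0.0}, {16: 0.0}, {16}, {16})
        assert (v, sd) == (-2.0, 0.0)

    def test_hand_sum_two_residues(self):
        v, _ = eec(
            {16: 0.5, 17: 0.25}, {16: -1.0, 17: -2.0},
            {16: 0.0, 17: 0.0}, {16: 0.0, 17: 0.0},
            {16, 17}, {16, 17},
        )
        assert v == pytest.approx(-1.0)

    def test_empty_set_gives_zero(self):
        assert eec({}, {}, {}, {}, set(), {16}) == (0.0, 0.0)

    def test_residue_outside_core_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            eec({16: 1.0}, {16: -2.0}, {16: 0.0}, {16: 0.0}, {99}, {16})

    def test_variance_propagation_formula(self):
        n, e, sn, se = 0.5, -2.0, 0.1, 0.3
        _, sd = eec({16: n}, {16: e}, {16: sn}, {16: se}, {16}, {16})
        expected = math.sqrt(se**2 * sn**2 + se**2 * n**2 + sn**2 * e**2)
        assert sd == pytest.approx(expected)


class TestDeltaEEC:
    def test_all_records_on_target(self):
        rows = [(1, s, 16, 97, -2.0) for s in range(6)]
        table = make_table(rows, [1])
        d, _ = delta_eec(table, SEL, B=50)
        s = summarize(table, SEL, B=50)
        assert d == pytest.approx(s.eec_on)
        assert d < 0
        assert s.eec_off == 0.0

    def test_symmetric_split_gives_zero(self):
        rows = [(1, 0, 16, 97, -2.0), (1, 1, 47, 97, -2.0)]
        table = make_table(rows, [1])
        d, _ = delta_eec(table, SEL, B=50)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_basic_equal_core_is_error(self):
        sel = SelectionSets(
            core=frozenset({16, 17}),
            tail=frozenset({97}),
            basic_core=frozenset({16, 17}),
        )
        table = make_table([(1, 0, 16, 97, -2.0)], [1])
        with pytest.raises(ValueError, match="off-target"):
            delta_eec(table, sel, B=50)

    def test_buried_exclusion_removes_off_target_contribution(self):
        sel = SelectionSets(
            core=frozenset({16, 17, 47, 50}),
            tail=frozenset({97, 99}),
            basic_core=frozenset({16, 17}),
        )
        rows = [(1, 0, 16, 97, -2.0), (1, 1, 47, 97, -2.0)]
        table = make_table(rows, [1])
        d_with, _ = delta_eec(table, sel, B=50)
        d_excl, _ = delta_eec(
            table, sel, buried={47}, exclude_buried=True, B=50
        )
        assert d_with == pytest.approx(0.0, abs=1e-12)
        assert d_excl < 0  # off-target residue 47 no longer counted


random_rows = st.lists(
    st.tuples(
        st.integers(1, 5),            # model
        st.integers(0, 5),            # subunit
        st.sampled_from([16, 17, 47]),
        st.sampled_from([97, 99]),
        st.floats(min_value=-8.0, max_value=-0.01),
    ),
    max_size=40,
    unique_by=lambda r: r[:4],
)


class TestOracleEquivalence:
    @given(rows=random_rows)
    @settings(max_examples=60)
    def test_exact_agreement_with_enumeration(self, rows):
        model_ids = [1, 2, 3, 4, 5]
        table = make_table(rows, model_ids)
        expected = oracle_stats(rows, model_ids, 6, SEL.core)
        counts = mean_counts(table, SEL)
        for x in SEL.core:
            e, sd = mean_energy(table, x)
            exp_n, exp_e, exp_sd = expected[x]
            assert counts[x] == pytest.approx(exp_n, abs=1e-12)
            assert e == pytest.approx(exp_e, abs=1e-12)
            assert sd == pytest.approx(exp_sd, abs=1e-12)
        # EEC from oracle quantities
        s = summarize(table, SEL, B=20, seed=0)
        exp_on = sum(expected[x][0] * expected[x][1] for x in SEL.basic_core)
        exp_off = sum(expected[x][0] * expected[x][1] for x in SEL.off_target)
        assert s.eec_on == pytest.approx(exp_on, abs=1e-12)
        assert s.delta_eec == pytest.approx(exp_on - exp_off, abs=1e-12)
        assert s.eec_on <= 1e-12  # qualifying energies are negative

    @given(rows=random_rows, perm_seed=st.integers(0, 100))
    @settings(max_examples=30)
    def test_model_and_subunit_relabeling_invariance(self, rows, perm_seed):
        model_ids = [1, 2, 3, 4, 5]
        rng = np.random.default_rng(perm_seed)
        mperm = dict(zip(model_ids, rng.permutation(model_ids)))
        sperm = dict(zip(range(6), rng.permutation(6)))
        permuted = [
            (mperm[m], int(sperm[s]), x, y, e) for (m, s, x, y, e) in rows
        ]
        t1 = make_table(rows, model_ids)
        t2 = make_table(permuted, model_ids)
        c1, c2 = mean_counts(t1, SEL), mean_counts(t2, SEL)
        assert c1 == pytest.approx(c2)
        for x in SEL.core:
            assert mean_energy(t1, x) == pytest.approx(mean_energy(t2, x))
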