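import numpy as np
import pandas as pd
import pytest

from flockdiv.pedigree import (PedigreeError, SubgroupSpec, generation_interval,
                               generation_stats, load_pedigree, resolve_subgroup)

from conftest import random_pedigree
from oracles import equivalent_generations_direct


class TestLoading:
    def test_minimal_trio(self, trio):
        assert len(trio) == 3
        assert set(trio.animals[trio.is_founder]) == {"A", "B"}

    def test_implied_parent_materialised_as_founder(self):
        ped = load_pedigree([("B", "X", None, 2001, "F1", "f")])
        assert set(ped.animals) == {"B", "X"}
        rec = ped.to_frame().set_index("animal").loc["X"]
        assert rec["sire"] is None and pd.isna(rec["birth_year"])
        assert rec["sex"] == "male"  # used as a sire

    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            load_pedigree([("A", "B", None, None, None, "m"),
                           ("B", "A", None, None, None, "m")])

    def test_duplicate_id_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            load_pedigree([("A", None, None, None, None, "m"),
                           ("A", None, None, None, None, "m")])

    def test_animal_as_both_sire_and_dam_rejected(self):
        with pytest.raises(PedigreeError, match="both sire and dam"):
            load_pedigree([("C", "A", None, None, None, "m"),
                           ("D", None, "A", None, None, "f")])

    def test_topological_order_property(self):
        ped = random_pedigree(300, seed=11)
        idx = np.arange(len(ped))
        assert np.all(ped.sire_idx < idx)
        assert np.all(ped.dam_idx < idx)


class TestGenerationStats:
    def test_parents_founders(self, trio):
        gs = generation_stats(trio)
        i = trio.index["C"]
        assert gs.max_generations[i] == 1
        assert gs.complete_generations[i] == 1
        assert gs.equivalent_generations[i] == 1.0

    def test_two_full_generations(self):
        ped = load_pedigree([("G1", None, None, None, None, "m"),
                             ("G2", None, None, None, None, "f"),
                             ("G3", None, None, None, None, "m"),
                             ("G4", None, None, None, None, "f"),
                             ("S", "G1", "G2", None, None, "m"),
                             ("D", "G3", "G4", None, None, "f"),
                             ("O", "S", "D", None, None, "f")])
        gs = generation_stats(ped)
        i = ped.index["O"]
        assert gs.equivalent_generations[i] == pytest.approx(2.0)
        assert gs.complete_generations[i] == 2
        assert gs.max_generations[i] == 2

    def test_one_known_parent(self):
        ped = load_pedigree([("S", None, None, None, None, "m"),
                             ("O", "S", None, None, None, "f")])
        gs = generation_stats(ped)
        i = ped.index["O"]
        assert gs.max_generations[i] == 1
        assert gs.complete_generations[i] == 0
        assert gs.equivalent_generations[i] == pytest.approx(0.5)

    def test_founders_all_zero(self, trio):
        gs = generation_stats(trio)
        f = trio.is_founder
        assert np.all(gs.max_generations[f] == 0)
        assert np.all(gs.equivalent_generations[f] == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recursive_equals_direct_path_sum(self, seed):
        ped = random_pedigree(60, n_founders=12, seed=seed)
        gs = generation_stats(ped)
        for i in range(len(ped)):
            direct = equivalent_generations_direct(ped, i)
            assert gs.equivalent_generations[i] == pytest.approx(direct, abs=1e-12)

    def test_invariant_ordering(self):
        ped = random_pedigree(200, seed=3)
        gs = generation_stats(ped)
        assert np.all(gs.complete_generations <= gs.max_generations)
        assert np.all(gs.equivalent_generations <= gs.max_generations + 1e-12)


class TestGenerationInterval:
    def test_single_path(self):
        ped = load_pedigree([("S", None, None, 2000, None, "m"),
                             ("O", "S", None, 2003, None, "m")])
        gi = generation_interval(ped)
        assert gi["sire_son"]["mean"] == pytest.approx(3.0)
        assert gi["overall"]["mean"] == pytest.approx(3.0)

    def test_constant_offset_pedigree(self):
        rows = [("S", None, None, 2000, None, "m"), ("D", None, None, 2000, None, "f"),
                ("O1", "S", "D", 2002, None, "m"), ("O2", "S", "D", 2002, None, "f"),
                ("O3", "O1", "O2", 2004, None, "m"), ("O4", "O1", "O2", 2004, None, "f")]
        gi = generation_interval(load_pedigree(rows))
        for path in ("sire_son", "sire_daughter", "dam_son", "dam_daughter"):
            assert gi[path]["mean"] == pytest.approx(2.0)
        assert gi["overall"]["mean"] == pytest.approx(2.0)

    def test_no_usable_path_errors(self, trio):
        ped = load_pedigree([("A", None, None, None, None, "m"),
                             ("C", "A", None, None, None, "m")])
        with pytest.raises(PedigreeError):
            generation_interval(ped)

    def test_overall_is_count_weighted(self):
        # 3 sire-son pairs at 2 y, 1 dam-son pair at 6 y -> overall (3*2+6)/4 = 3
        rows = [("S", None, None, 2000, None, "m"), ("D", None, None, 1996, None, "f"),
                ("O1", "S", None, 2002, None, "m"), ("O2", "S", None, 2002, None, "m"),
                ("O3", "S", "D", 2002, None, "m")]
        gi = generation_interval(load_pedigree(rows))
        assert gi["overall"]["mean"] == pytest.approx(3.0)


class TestSubgroups:
    def test_birth_year_filter(self):
        ped = random_pedigree(50, seed=5)
        spec = SubgroupSpec("recent", birth_year_range=(2002, 2003))
        ids = resolve_subgroup(ped, spec)
        y = ped.birth_year[ped.positions(ids)]
        assert np.all((y >= 2002) & (y <= 2003))
        assert len(ids) > 0

    def test_sires_of(self, full_sib_pedigree):
        spec = SubgroupSpec("sires", sires_of=SubgroupSpec(
            "kids", birth_year_range=(2002, 2002)))
        assert resolve_subgroup(full_sib_pedigree, spec) == {"A"}

    def test_complete_generation_filter_no_op_on_complete_pedigree(self):
        # 6 discrete complete generations: adding min_complete_generations=4
        # to a last-generation year filter must not change the result
        from flockdiv.sim import simulate_random_mating_pedigree

        ped = simulate_random_mating_pedigree(10, 6, seed=1)
        base = SubgroupSpec("late", birth_year_range=(2006, 2006))
        both = SubgroupSpec("late+", birth_year_range=(2006, 2006),
                            min_complete_generations=4)
        assert resolve_subgroup(ped, base) == resolve_subgroup(ped, both)

    def test_resolution_idempotent_and_filter_order_free(self):
        ped = random_pedigree(120, seed=7)
        stats = generation_stats(ped)
        spec = SubgroupSpec("s", birth_year_range=(2003, 2008),
                            min_complete_generations=1)
        a = resolve_subgroup(ped, spec, stats)
        b = resolve_subgroup(ped, spec, stats)
        assert a == b
        year_only = resolve_subgroup(ped, SubgroupSpec("y", birth_year_range=(2003, 2008)))
        cg_only = resolve_subgroup(ped, SubgroupSpec("c", min_complete_generations=1))
        assert a == year_only & cg_only
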