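"""Genotype QC: thresholds, exact HWE, Mendel checks, LD pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_panel, make_table
from oracles import hwe_exact_fraction, naive_ld_prune
from pedlink.qc import (QCConfig, apply_qc, filter_individuals, hwe_test,
                        ld_prune, ld_r2, mendel_error_rate)
from pedlink.simulate import (MarkerSpec, SimConfig, build_marker_panel,
                              gene_drop_genotypes, simulate_pedigree)
from pedlink.types import (FEMALE, MALE, GenotypeTable, Individual, Pedigree,
                           UNKNOWN)


def simple_family(n_children=4):
    inds = [Individual("f", None, None, MALE),
            Individual("m", None, None, FEMALE)]
    inds += [Individual(f"c{k}", "f", "m", MALE if k % 2 else FEMALE)
             for k in range(n_children)]
    return Pedigree(inds)


class TestFilterIndividuals:
    def test_below_threshold_removed(self):
        ped = simple_family(1)
        panel = make_panel(100)
        geno = {"f": [(0, 1)] * 100,
                "m": [(0, 1)] * 96 + [None] * 4,   # 96% call rate
                "c0": [(0, 1)] * 100}
        table = make_table(ped, panel.markers, geno)
        kept, removed = filter_individuals(table, 0.97)
        assert kept.ids == ["f", "c0"]
        assert removed["iid"].tolist() == ["m"]
        assert removed["call_rate"].iloc[0] == pytest.approx(0.96)

    def test_complete_data_keeps_everyone(self):
        ped = simple_family(2)
        panel = make_panel(10)
        geno = {i: [(0, 1)] * 10 for i in ped.members}
        table = make_table(ped, panel.markers, geno)
        kept, removed = filter_individuals(table, 0.97)
        assert kept.ids == ped.members and removed.empty

    def test_known_missing_counts(self):
        """10 individuals with hand-planted missingness: exact removal set."""
        ids = [f"i{k}" for k in range(10)]
        inds = [Individual(i, None, None, MALE) for i in ids]
        ped = Pedigree(inds)
        n_missing = [0, 1, 2, 3, 4, 0, 1, 5, 0, 2]  # of 20 markers
        geno = {i: [(0, 1)] * (20 - k) + [None] * k
                for i, k in zip(ids, n_missing)}
        table = make_table(ped, [f"m{j}" for j in range(20)], geno)
        kept, removed = filter_individuals(table, floor=0.9)
        expect_removed = {i for i, k in zip(ids, n_missing) if (20 - k) / 20 < 0.9}
        assert set(removed["iid"]) == expect_removed

    def test_all_removed_is_error(self):
        ped = simple_family(0)
        table = make_table(ped, ["m1"], {"f": [None], "m": [None]})
        with pytest.raises(ValueError):
            filter_individuals(table, 0.97)


class TestMendel:
    def test_impossible_transmission(self):
        ped = simple_family(1)
        table = make_table(ped, ["m1"], {"f": [(0, 0)], "m": [(0, 0)],
                                         "c0": [(0, 1)]})
        assert mendel_error_rate(ped, table, "m1") == 1.0

    def test_untyped_parents_rate_zero_by_convention(self):
        ped = simple_family(1)
        table = make_table(ped, ["m1"], {"f": [None], "m": [None],
                                         "c0": [(0, 1)]})
        assert mendel_error_rate(ped, table, "m1") == 0.0

    def test_planted_error_rate(self):
        """10 informative trios, 2 planted errors: rate exactly 0.2."""
        inds, geno = [], {}
        for k in range(10):
            inds += [Individual(f"f{k}", None, None, MALE),
                     Individual(f"m{k}", None, None, FEMALE),
                     Individual(f"c{k}", f"f{k}", f"m{k}", MALE)]
        # disjoint trios in one (forest) pedigree
        ped = Pedigree(inds)
        for k in range(10):
            geno[f"f{k}"] = [(0, 0)]
            geno[f"m{k}"] = [(0, 0)]
            geno[f"c{k}"] = [(1, 1) if k < 2 else (0, 0)]
        table = make_table(ped, ["m1"], geno)
        assert mendel_error_rate(ped, table, "m1") == pytest.approx(0.2)

    def test_duo_check(self):
        inds = [Individual("f", None, None, MALE),
                Individual("m", None, None, FEMALE),
                Individual("c", "f", "m", MALE)]
        ped = Pedigree(inds)
        table = make_table(ped, ["m1"], {"f": [(0, 0)], "m": [None],
                                         "c": [(1, 1)]})
        assert mendel_error_rate(ped, table, "m1") == 1.0


class TestHWE:
    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (50, 0, 50), (13, 21, 6), (3, 4, 5), (100, 10, 1),
        (0, 5, 95),
    ])
    def test_matches_exact_fraction_oracle(self, counts):
        assert hwe_test(*counts) == pytest.approx(
            hwe_exact_fraction(*counts), rel=1e-9)

    def test_equilibrium_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == 1.0

    def test_extreme_het_deficit(self):
        assert hwe_test(50, 0, 50) < 1e-6

    def test_monomorphic_is_one(self):
        assert hwe_test(0, 0, 60) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_property_matches_rational_oracle(self, naa, nab, nbb):
        if naa + nab + nbb == 0:
            return
        p = hwe_test(naa, nab, nbb)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(hwe_exact_fraction(naa, nab, nbb), rel=1e-9)


class TestLDr2:
    def ped_table(self, dosages):
        ids = [f"i{k}" for k in range(len(dosages))]
        ped = Pedigree([Individual(i, None, None, MALE) for i in ids])
        to_geno = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        geno = {i: [to_geno[d] for d in row] for i, row in zip(ids, dosages)}
        markers = [f"m{j}" for j in range(len(dosages[0]))]
        return make_table(ped, markers, geno)

    def test_duplicated_marker_r2_one(self):
        t = self.ped_table([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]])
        assert ld_r2(t, "m0", "m1") == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        dos = [[0, 1], [1, 1], [2, 2], [0, 0], [1, 2], [2, 1]]
        t = self.ped_table(dos)
        x = np.array([d[0] for d in dos], float)
        y = np.array([d[1] for d in dos], float)
        expect = np.corrcoef(x, y)[0, 1] ** 2
        assert ld_r2(t, "m0", "m1") == pytest.approx(expect)

    def test_too_few_pairs_error(self):
        t = self.ped_table([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            ld_r2(t, "m0", "m1")

    def test_null_r2_small_at_large_n(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(1000, 20))
        t = self.ped_table(dos.tolist())
        vals = [ld_r2(t, f"m{2 * k}", f"m{2 * k + 1}") for k in range(10)]
        assert np.mean(vals) < 0.01  # E[r^2] ~ 1/(n-1) = 0.001


class TestLDPrune:
    def test_independent_markers_all_retained(self):
        rng = np.random.default_rng(5)
        ids = [f"i{k}" for k in range(300)]
        ped = Pedigree([Individual(i, None, None, MALE) for i in ids])
        to_geno = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        dos = rng.binomial(2, 0.4, size=(300, 10))
        geno = {i: [to_geno[d] for d in row] for i, row in zip(ids, dos)}
        panel = make_panel(10)
        table = make_table(ped, panel.markers, geno)
        cfg = QCConfig(prune_r2_ceiling=0.05)
        assert ld_prune(table, panel, cfg) == panel.markers

    def test_identical_markers_keep_one(self):
        ids = [f"i{k}" for k in range(50)]
        ped = Pedigree([Individual(i, None, None, MALE) for i in ids])
        rng = np.random.default_rng(1)
        to_geno = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        col = rng.binomial(2, 0.5, size=50)
        geno = {i: [to_geno[col[k]]] * 3 for k, i in enumerate(ids)}
        panel = make_panel(3)
        table = make_table(ped, panel.markers, geno)
        retained = ld_prune(table, panel, QCConfig())
        assert len(retained) == 1

    def test_matches_naive_oracle(self):
        """20-marker toy equals an independently coded greedy pruner."""
        rng = np.random.default_rng(77)
        n, m = 120, 20
        base = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        # force some correlated pairs
        base[:, 5] = base[:, 4]
        base[:, 11] = np.clip(base[:, 10] + rng.binomial(1, 0.1, n), 0, 2)
        ids = [f"i{k}" for k in range(n)]
        ped = Pedigree([Individual(i, None, None, MALE) for i in ids])
        to_geno = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        geno = {i: [to_geno[int(d)] for d in row] for i, row in zip(ids, base)}
        panel = make_panel(m)
        table = make_table(ped, panel.markers, geno)
        cfg = QCConfig(prune_window=8, prune_step=3, prune_r2_ceiling=0.3)
        mine = ld_prune(table, panel, cfg)
        oracle_idx = naive_ld_prune(base.copy(), [1] * m, 8, 3, 0.3,
                                    np.zeros(m))
        assert mine == [panel.markers[k] for k in oracle_idx]

    def test_no_retained_pair_exceeds_ceiling(self):
        rng = np.random.default_rng(9)
        n, m = 150, 15
        dos = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        dos[:, 3] = dos[:, 2]
        ids = [f"i{k}" for k in range(n)]
        ped = Pedigree([Individual(i, None, None, MALE) for i in ids])
        to_geno = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        geno = {i: [to_geno[int(d)] for d in row] for i, row in zip(ids, dos)}
        panel = make_panel(m)
        table = make_table(ped, panel.markers, geno)
        cfg = QCConfig(prune_window=15, prune_step=5, prune_r2_ceiling=0.4)
        retained = ld_prune(table, panel, cfg)
        for a in range(len(retained)):
            for b in range(a + 1, len(retained)):
                assert ld_r2(table, retained[a], retained[b]) <= 0.4


class TestFullQC:
    def test_clean_simulated_data_only_pruned(self):
        """Error-free data with common alleles loses markers only to pruning."""
        cfg = SimConfig(seed=31, markers=MarkerSpec(
            n_chromosomes=1, markers_per_chromosome=20, maf_low=0.3))
        fam = simulate_pedigree(cfg)
        panel = build_marker_panel(cfg.markers, cfg.rng(10))
        table = gene_drop_genotypes(fam, panel, cfg)
        res = apply_qc(fam.pedigree, panel, table, QCConfig())
        assert res.marker_report["filter_pass"].all()
        assert res.removed_individuals.empty

    def test_config_defaults(self):
        cfg = QCConfig()
        assert (cfg.call_rate_floor, cfg.maf_floor, cfg.missingness_ceiling,
                cfg.mendel_rate_ceiling, cfg.hwe_p_floor, cfg.prune_window,
                cfg.prune_step, cfg.prune_r2_ceiling) == \
            (0.97, 0.05, 0.05, 0.10, 1e-6, 50, 5, 0.01)
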