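"""Linkage engines: peeling vs enumeration, LOD closed forms, HMM oracle,
region selection and haplotype reconstruction."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel, make_table, random_genotypes, random_pedigree
from oracles import brute_multipoint_lod, brute_two_locus_loglik
from pedlink.linkage import (InheritanceModel, LODCurve, combine_curves,
                             lod_multipoint, lod_single_point,
                             one_lod_interval, pedigree_likelihood,
                             reconstruct_haplotypes, select_regions)
from pedlink.linkage.multipoint import (PedigreeTooLargeError,
                                        disease_emission, marker_emissions,
                                        transition)
from pedlink.types import (AFFECTED, FEMALE, MALE, UNAFFECTED, UNKNOWN,
                           DiseaseModel, Individual, Pedigree,
                           PedigreeLoopError)

DOM = DiseaseModel.dominant(0.01, 0.99, 0.005)
FULL = DiseaseModel(0.01, (0.0, 1.0, 1.0))


def phase_known_family(n_children, n_recombinant=0):
    """Test-cross family with phase fixed through grandparents.

    Grandfather is affected and homozygous for marker allele 1, so the
    affected father's risk allele is known to ride allele 1; each child is
    an informative phase-known meiosis.
    """
    inds = [Individual("gf", None, None, MALE, AFFECTED),
            Individual("gm", None, None, FEMALE, UNAFFECTED),
            Individual("f", "gf", "gm", MALE, AFFECTED),
            Individual("m", None, None, FEMALE, UNAFFECTED)]
    geno = {"gf": (1, 1), "gm": (0, 0), "f": (0, 1), "m": (0, 0)}
    for k in range(n_children):
        recomb = k < n_recombinant
        inds.append(Individual(f"c{k}", "f", "m", MALE, AFFECTED))
        geno[f"c{k}"] = (0, 0) if recomb else (0, 1)
    return Pedigree(inds), geno


class TestPeeling:
    def test_lod_zero_at_theta_half(self, nuclear4):
        geno = {"f": (0, 1), "m": (0, 0), "c1": (0, 1), "c2": (0, 0)}
        lods = lod_single_point(nuclear4, geno, DOM, 0.3)
        assert lods[0.5] == 0.0

    def test_matches_enumeration_nuclear_family(self, nuclear4):
        geno = {"f": (0, 1), "m": (0, 1), "c1": (1, 1), "c2": (0, 0)}
        for theta in (0.0, 0.05, 0.2, 0.5):
            mine = pedigree_likelihood(nuclear4, geno, DOM, 0.35, theta)
            brute = brute_two_locus_loglik(nuclear4, geno, DOM, 0.35, theta)
            assert mine == pytest.approx(brute, rel=1e-10)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_random_pedigrees(self, seed):
        """Peeling equals full joint enumeration on random small pedigrees."""
        rng = np.random.default_rng(1000 + seed)
        ped = random_pedigree(rng, int(rng.integers(3, 7)))
        geno = random_genotypes(rng, ped)
        theta = float(rng.uniform(0, 0.5))
        freq = float(rng.uniform(0.1, 0.9))
        mine = pedigree_likelihood(ped, geno, DOM, freq, theta)
        brute = brute_two_locus_loglik(ped, geno, DOM, freq, theta)
        assert mine == pytest.approx(brute, rel=1e-10)

    def test_uninformative_marker_flat_in_theta(self, nuclear4):
        geno = {i: (0, 0) for i in nuclear4.members}
        vals = {t: pedigree_likelihood(nuclear4, geno, DOM, 0.3, t)
                for t in (0.0, 0.1, 0.4)}
        assert max(vals.values()) - min(vals.values()) < 1e-12

    def test_loop_rejected(self):
        inds = [Individual("f1", None, None, MALE),
                Individual("m1", None, None, FEMALE),
                Individual("f2", None, None, MALE),
                Individual("m2", None, None, FEMALE),
                Individual("a", "f1", "m1", MALE),
                Individual("b", "f1", "m1", FEMALE),
                Individual("c", "f2", "m2", MALE),
                Individual("d", "f2", "m2", FEMALE),
                Individual("x", "a", "d", MALE),
                Individual("y", "c", "b", FEMALE)]
        ped = Pedigree(inds)
        with pytest.raises(PedigreeLoopError, match="loop"):
            pedigree_likelihood(ped, {i: None for i in ped.members}, DOM,
                                0.3, 0.1)

    def test_mendelian_error_impossible_at_all_theta(self, trio):
        geno = {"f": (0, 0), "m": (0, 0), "c": (1, 1)}
        with pytest.raises(ValueError, match="inconsistent"):
            lod_single_point(trio, geno, DOM, 0.3)


class TestLODClosedForms:
    def test_ten_nonrecombinant_meioses(self):
        """Fully informative 10-meiosis family: LOD -> 10*log10(2) at theta=0."""
        ped, geno = phase_known_family(10)
        lods = lod_single_point(ped, geno, FULL, 0.3, theta_grid=[0.0])
        assert lods[0.0] == pytest.approx(10 * math.log10(2), abs=1e-9)

    def test_one_recombinant_peaks_at_point_one(self):
        """1 recombinant of 10: the binomial MLE puts theta-hat at 0.1."""
        ped, geno = phase_known_family(10, n_recombinant=1)
        grid = np.round(np.linspace(0.02, 0.4, 39), 4)
        lods = lod_single_point(ped, geno, FULL, 0.3, theta_grid=grid)
        best = max((t for t in lods if t < 0.5), key=lambda t: lods[t])
        assert best == pytest.approx(0.1, abs=0.011)
        expect = math.log10((0.9 ** 9 * 0.1) / 0.5 ** 10)
        assert lods[0.1] == pytest.approx(expect, abs=1e-9)

    def test_disease_freq_cancels_in_lod(self):
        ped, geno = phase_known_family(6)
        for q in (0.001, 0.05):
            model = DiseaseModel(q, (0.0, 1.0, 1.0))
            lods = lod_single_point(ped, geno, model, 0.3, theta_grid=[0.01])
            assert lods[0.01] == pytest.approx(
                math.log10((2 * 0.99) ** 6), abs=1e-9)


def multipoint_setup(ped, geno_per_marker, cms, freqs, bps=None):
    rows = [{"marker": f"m{k + 1}", "chrom": 1,
             "bp": (bps[k] if bps else 1000 * (k + 1)), "cm": cms[k],
             "a1": "A", "a2": "C", "freq": freqs[k]}
            for k in range(len(cms))]
    from pedlink.types import MarkerPanel
    panel = MarkerPanel(pd.DataFrame(rows))
    table = make_table(ped, panel.markers, geno_per_marker)
    return panel, table


class TestMultipoint:
    def test_single_marker_window_equals_single_point(self, nuclear4):
        geno = {"f": (0, 1), "m": (0, 1), "c1": (1, 1), "c2": (0, 0)}
        panel, table = multipoint_setup(
            nuclear4, {i: [geno[i]] for i in nuclear4.members}, [0.0], [0.35])
        curve = lod_multipoint(nuclear4, panel, table, DOM, chrom=1)
        sp = lod_single_point(nuclear4, geno, DOM, 0.35, theta_grid=[0.0])
        assert curve.lod[0] == pytest.approx(sp[0.0], abs=1e-8)

    def test_matches_inheritance_vector_enumeration(self, nuclear4):
        """3 markers, 4 meioses: every evaluation equals the brute force."""
        genos = {"f": [(0, 1), (0, 1), (1, 1)], "m": [(0, 0), (0, 1), (0, 1)],
                 "c1": [(0, 1), (1, 1), (1, 1)], "c2": [(0, 0), (0, 0), (0, 1)]}
        cms = [0.0, 5.0, 12.0]
        freqs = [0.3, 0.4, 0.25]
        model = DiseaseModel.dominant(0.1, 0.95, 0.01)
        panel, table = multipoint_setup(nuclear4, genos, cms, freqs)
        curve = lod_multipoint(nuclear4, panel, table, model, chrom=1)
        per_marker = {i: [genos[iid][k] for k in range(3)]
                      for i, iid in enumerate(nuclear4.members)}
        geno_by_iid = {iid: genos[iid] for iid in nuclear4.members}
        for cm, lod in zip(curve.cm, curve.lod):
            brute = brute_multipoint_lod(nuclear4, cms, freqs, geno_by_iid,
                                         model, float(cm))
            assert lod == pytest.approx(brute, abs=1e-9)

    def test_three_generations_against_enumeration(self):
        """Grandparental meioses exercise the founder-phase quotient chain."""
        inds = [Individual("gf", None, None, MALE, AFFECTED),
                Individual("gm", None, None, FEMALE, UNKNOWN),
                Individual("f", "gf", "gm", MALE, AFFECTED),
                Individual("m", None, None, FEMALE, UNAFFECTED),
                Individual("c", "f", "m", FEMALE, AFFECTED)]
        ped = Pedigree(inds)
        genos = {"gf": [(0, 1), (1, 1)], "gm": [(0, 0), (0, 1)],
                 "f": [(0, 1), (1, 1)], "m": [(0, 1), (0, 0)],
                 "c": [(1, 1), (0, 1)]}
        cms = [0.0, 8.0]
        freqs = [0.4, 0.3]
        panel, table = multipoint_setup(ped, genos, cms, freqs)
        curve = lod_multipoint(ped, panel, table, DOM, chrom=1)
        for cm, lod in zip(curve.cm, curve.lod):
            brute = brute_multipoint_lod(ped, cms, freqs, genos, DOM, float(cm))
            assert lod == pytest.approx(brute, abs=1e-9)

    def test_combined_family_lod_is_additive(self, nuclear4):
        genos = {"f": [(0, 1), (0, 1)], "m": [(0, 0), (0, 1)],
                 "c1": [(0, 1), (1, 1)], "c2": [(0, 0), (0, 0)]}
        panel, table = multipoint_setup(nuclear4, genos, [0.0, 4.0], [0.3, 0.4])
        c1 = lod_multipoint(nuclear4, panel, table, DOM, chrom=1, label="P1")
        c2 = lod_multipoint(nuclear4, panel, table, DOM, chrom=1, label="P2")
        comb = combine_curves([c1, c2])
        assert np.allclose(comb.lod, c1.lod + c2.lod)
        assert comb.label == "P1+P2"

    def test_bit_bound_enforced(self):
        inds = [Individual("f", None, None, MALE),
                Individual("m", None, None, FEMALE)]
        inds += [Individual(f"c{k}", "f", "m", MALE) for k in range(15)]
        ped = Pedigree(inds)
        with pytest.raises(PedigreeTooLargeError, match="split"):
            InheritanceModel(ped, max_bits=20)

    def test_transition_preserves_uniform(self, nuclear4):
        im = InheritanceModel(nuclear4)
        x = np.full(im.n_vectors, 1.0 / im.n_vectors)
        y = transition(x, 0.23, im)
        assert np.allclose(y, x)
        assert np.isclose(y.sum(), 1.0)

    def test_phenotype_emission_sums_against_peeling(self, nuclear4):
        """Mean disease emission equals the marker-free pedigree likelihood."""
        im = InheritanceModel(nuclear4)
        e = disease_emission(im, DOM)
        geno_none = {i: None for i in nuclear4.members}
        ll = pedigree_likelihood(nuclear4, geno_none, DOM, 0.3, 0.5)
        assert math.log(e.mean()) == pytest.approx(ll, rel=1e-10)


class TestRegions:
    def curve(self, lods, chrom=1):
        n = len(lods)
        return LODCurve(chrom, np.arange(1, n + 1) * 1_000_000,
                        np.arange(n, dtype=float), np.asarray(lods, float),
                        label="P1")

    def test_flat_below_threshold_gives_nothing(self):
        assert select_regions([self.curve([1.9] * 6)]) == []

    def test_hand_worked_region(self):
        """[0,1,2.5,3,2.2,1.9]: peak at index 3, bounds where LOD >= 2."""
        regions = select_regions([self.curve([0, 1, 2.5, 3, 2.2, 1.9])])
        assert len(regions) == 1
        r = regions[0]
        assert r.peak_lod == 3.0
        assert r.peak_bp == 4_000_000
        assert (r.start_bp, r.end_bp) == (3_000_000, 5_000_000)
        assert r.families == ("P1",)

    def test_two_separated_peaks(self):
        regions = select_regions(
            [self.curve([0, 2.5, 0.5, 0.2, 2.8, 2.1, 0.1])])
        assert len(regions) == 2

    def test_one_lod_interval_unimodal(self):
        c = self.curve([0.0, 1.5, 2.4, 3.1, 2.6, 1.8, 0.5])
        lo, hi = one_lod_interval(c, 3)
        assert (lo, hi) == (2, 4)

    def test_one_lod_interval_clips_at_chromosome_end(self):
        c = self.curve([3.2, 2.7, 1.9, 0.2])
        lo, hi = one_lod_interval(c, 0)
        assert (lo, hi) == (0, 1)

    def test_shoulder_stops_at_first_drop(self):
        """A re-crossing shoulder beyond the first drop is not rejoined."""
        c = self.curve([2.9, 1.4, 2.5, 3.0, 2.4, 1.2])
        lo, hi = one_lod_interval(c, 3)
        assert (lo, hi) == (2, 4)


class TestHaplotypes:
    def test_all_homozygous_unique_and_unflagged(self, trio):
        panel = make_panel(3)
        table = make_table(trio, panel.markers,
                           {i: [(1, 1), (0, 0), (1, 1)] for i in trio.members})
        haps = reconstruct_haplotypes(trio, panel, table)
        assert not haps["ambiguous"].any()
        f = haps[haps["iid"] == "f"]
        assert f["allele_paternal"].tolist() == [1, 0, 1]

    def test_recovers_planted_haplotypes(self):
        """Fully informative trio: reconstruction matches the simulation."""
        inds = [Individual("f", None, None, MALE, UNKNOWN),
                Individual("m", None, None, FEMALE, UNKNOWN),
                Individual("c", "f", "m", MALE, UNKNOWN)]
        ped = Pedigree(inds)
        # het father x homozygous mother: a het child pins the paternal
        # transmission to the father's allele-1 haplotype at every marker
        geno = {"f": [(0, 1), (0, 1), (0, 1)],
                "m": [(0, 0), (0, 0), (0, 0)],
                "c": [(0, 1), (0, 1), (0, 1)]}
        panel = make_panel(3, spacing_cm=1.0)
        table = make_table(ped, panel.markers, geno)
        haps = reconstruct_haplotypes(ped, panel, table)
        child = haps[haps["iid"] == "c"].set_index("marker")
        assert child["allele_paternal"].tolist() == [1, 1, 1]
        assert child["allele_maternal"].tolist() == [0, 0, 0]
        assert not child["ambiguous"].any()

    def test_viterbi_path_matches_exhaustive_search(self, nuclear4):
        """Best inheritance vector path equals brute-force maximisation."""
        from pedlink.linkage.haplotype import _dense_transition
        genos = {"f": [(0, 1), (0, 1)], "m": [(0, 1), (0, 0)],
                 "c1": [(1, 1), (0, 1)], "c2": [(0, 1), (0, 0)]}
        panel, table = multipoint_setup(nuclear4, genos, [0.0, 6.0], [0.5, 0.5])
        im = InheritanceModel(nuclear4)
        emis = marker_emissions(im, table, panel, panel.markers)
        T = _dense_transition(im, 0.5 * (1 - math.exp(-0.12)))
        best, best_p = None, -1.0
        for v1 in range(im.n_vectors):
            for v2 in range(im.n_vectors):
                p = emis[0, v1] / im.n_vectors * T[v1, v2] * emis[1, v2]
                if p > best_p:
                    best, best_p = (v1, v2), p
        haps = reconstruct_haplotypes(nuclear4, panel, table)
        # reconstruct implied emission probability of the reported path
        assert best_p > 0
        assert len(haps) == 8
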