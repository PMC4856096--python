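import math

import numpy as np
import pandas as pd
import pytest

from pollenkiller.model_core import ContractError, KillerSystem, LocusDef
from pollenkiller.popsim import (
    CrossDesign,
    GeneticMap,
    GeneticMapEntry,
    Individual,
    f1_hybrid,
    founder_pair,
    haldane,
    homozygous_line,
    make_gamete,
    make_gametes,
    simulate_population,
    two_locus_association,
)
from pollenkiller.segregation import selfing_freq, ssd_recursion


def build_map(ink_s35):
    entries = [
        GeneticMapEntry(ink_s35.killer, 12.0),
        GeneticMapEntry(ink_s35.partner, 6.8),
        GeneticMapEntry(LocusDef(name="nA", chrom="chr3", pos_bp=1_000_000), 0.0),
        GeneticMapEntry(LocusDef(name="nB", chrom="chr4", pos_bp=2_000_000), 50.0),
    ]
    return GeneticMap(entries)


@pytest.fixture(scope="module")
def gmap(ink_s35):
    return build_map(ink_s35)


def freq_of(table, marker, code):
    return float((table[marker] == code).mean())


def binom_se(p, n):
    return math.sqrt(p * (1 - p) / n)


class TestHaldane:
    def test_zero_distance(self):
        assert haldane(0.0) == 0.0

    def test_unlinked_limit(self):
        assert haldane(1e6) == pytest.approx(0.5)

    def test_monotone(self):
        d = np.linspace(0, 200, 50)
        r = [haldane(x) for x in d]
        assert all(a < b for a, b in zip(r, r[1:]))
        assert all(0 <= x <= 0.5 for x in r)

    def test_negative_distance(self):
        with pytest.raises(ContractError):
            haldane(-1.0)


class TestMakeGametes:
    def test_active_killer_empirical_k(self, gmap, ink_s35, rng):
        f1 = f1_hybrid(gmap)
        gam = make_gametes(f1, gmap, [ink_s35], "male", rng, n=100_000)
        p_i = float((gam[:, gmap.index("S35")] == 0).mean())
        assert p_i == pytest.approx(ink_s35.k, abs=0.003)

    def test_inactive_killer_is_mendelian(self, gmap, ink_s35, rng):
        # parent homozygous JJ at the activator: killer silent
        hap_j = np.ones(len(gmap), dtype=np.int8)
        hap_i = np.zeros(len(gmap), dtype=np.int8)
        hap_i[gmap.index("INK")] = 1
        parent = Individual(hap_i, hap_j)
        gam = make_gametes(parent, gmap, [ink_s35], "male", rng, n=100_000)
        p_i = float((gam[:, gmap.index("S35")] == 0).mean())
        assert p_i == pytest.approx(0.5, abs=0.005)

    def test_female_side_is_mendelian_despite_active_killer(self, gmap, ink_s35, rng):
        f1 = f1_hybrid(gmap)
        gam = make_gametes(f1, gmap, [ink_s35], "female", rng, n=100_000)
        p_i = float((gam[:, gmap.index("S35")] == 0).mean())
        assert p_i == pytest.approx(0.5, abs=0.005)

    def test_unlinked_neutral_loci_independent(self, gmap, rng):
        f1 = f1_hybrid(gmap)
        gam = make_gametes(f1, gmap, [], "male", rng, n=100_000)
        a = gam[:, gmap.index("nA")]
        b = gam[:, gmap.index("nB")]
        for va in (0, 1):
            for vb in (0, 1):
                freq = float(((a == va) & (b == vb)).mean())
                assert freq == pytest.approx(0.25, abs=0.005)

    def test_single_gamete_shape(self, gmap, ink_s35, rng):
        gam = make_gamete(f1_hybrid(gmap), gmap, [ink_s35], "male", rng)
        assert gam.shape == (len(gmap),)
        assert set(np.unique(gam)) <= {0, 1}

    def test_activation_is_sporophytic(self, gmap, ink_s35, rng):
        # parent het at S35 but JJ at INK: no gamete carries a donor INK allele,
        # yet the S35 ratio is what matters — it must stay Mendelian.
        hap_a = np.ones(len(gmap), dtype=np.int8)
        hap_b = np.ones(len(gmap), dtype=np.int8)
        hap_a[gmap.index("S35")] = 0
        parent = Individual(hap_a, hap_b)
        gam = make_gametes(parent, gmap, [ink_s35], "male", rng, n=50_000)
        p_i = float((gam[:, gmap.index("S35")] == 0).mean())
        assert p_i == pytest.approx(0.5, abs=0.01)


class TestSimulatePopulation:
    def test_f2_inactive_matches_mendelian(self, gmap, ink_s35, rng):
        # donor line lacking the activator allele: killer never fires
        donor = homozygous_line(
            gmap, {n: ("J" if n == "INK" else "I") for n in gmap.names}
        )
        recurrent = homozygous_line(gmap, {n: "J" for n in gmap.names})
        design = CrossDesign(type="F2", n_offspring=10_000)
        table = simulate_population((donor, recurrent), design, gmap, [ink_s35], rng)
        expected = selfing_freq(0.5)
        for code, p in zip(("II", "H", "JJ"), expected.as_tuple()):
            assert abs(freq_of(table, "S35", code) - p) <= 3 * binom_se(p, 10_000)

    def test_f2_active_matches_selfing_freq(self, gmap, ink_s35, rng):
        founders = founder_pair(gmap)
        design = CrossDesign(type="F2", n_offspring=10_000)
        table = simulate_population(founders, design, gmap, [ink_s35], rng)
        expected = selfing_freq(ink_s35.k)
        for code, p in zip(("II", "H", "JJ"), expected.as_tuple()):
            assert abs(freq_of(table, "S35", code) - p) <= 3 * binom_se(p, 10_000)

    def test_testcross_matches_k(self, gmap, ink_s35, rng):
        founders = founder_pair(gmap)
        design = CrossDesign(type="testcross", n_offspring=10_000)
        table = simulate_population(founders, design, gmap, [ink_s35], rng)
        p_h = freq_of(table, "S35", "H")
        assert abs(p_h - ink_s35.k) <= 3 * binom_se(ink_s35.k, 10_000)
        assert freq_of(table, "S35", "II") == 0.0

    def test_backcross_is_mendelian(self, gmap, ink_s35, rng):
        founders = founder_pair(gmap)
        design = CrossDesign(type="backcross", n_offspring=10_000)
        table = simulate_population(founders, design, gmap, [ink_s35], rng)
        assert abs(freq_of(table, "S35", "H") - 0.5) <= 3 * binom_se(0.5, 10_000)

    def test_ssd_fixed_activator_reproduces_ri_projection(self, gmap, ink_s35, rng):
        # NIL founders: segregating killer, activator fixed donor
        donor = homozygous_line(gmap, {n: "I" for n in gmap.names})
        nil = homozygous_line(gmap, {n: ("J" if n == "S35" else "I") for n in gmap.names})
        design = CrossDesign(type="SSD_RI", n_offspring=148, generations=12)
        jj_counts = [
            int((simulate_population((donor, nil), design, gmap, [ink_s35], rng)["S35"] == "JJ").sum())
            for _ in range(30)
        ]
        assert np.mean(jj_counts) == pytest.approx(16, abs=4)

    def test_ssd_heterozygosity_decays(self, gmap, ink_s35, rng):
        founders = founder_pair(gmap)
        design = CrossDesign(type="SSD_RI", n_offspring=2_000, generations=10)
        table = simulate_population(founders, design, gmap, [ink_s35], rng)
        expected_h = ssd_recursion(ink_s35.k, 10).p_H
        assert freq_of(table, "S35", "H") <= expected_h + 3 * binom_se(2 ** -10, 2_000)

    def test_seed_reproducibility(self, gmap, ink_s35):
        founders = founder_pair(gmap)
        design = CrossDesign(type="F2", n_offspring=500)
        t1 = simulate_population(founders, design, gmap, [ink_s35], np.random.default_rng(42))
        t2 = simulate_population(founders, design, gmap, [ink_s35], np.random.default_rng(42))
        pd.testing.assert_frame_equal(t1, t2)

    def test_no_systems_reduces_to_neutral(self, gmap, rng):
        founders = founder_pair(gmap)
        design = CrossDesign(type="F2", n_offspring=10_000)
        table = simulate_population(founders, design, gmap, [], rng)
        for marker in gmap.names:
            assert abs(freq_of(table, marker, "H") - 0.5) <= 3 * binom_se(0.5, 10_000)

    def test_identical_founders_rejected(self, gmap, ink_s35, rng):
        donor = homozygous_line(gmap, {n: "I" for n in gmap.names})
        with pytest.raises(ContractError, match="identical"):
            simulate_population(
                (donor, donor), CrossDesign(type="F2", n_offspring=10), gmap, [ink_s35], rng
            )

    def test_heterozygous_founder_rejected(self, gmap, ink_s35, rng):
        founders = (f1_hybrid(gmap), homozygous_line(gmap, {n: "J" for n in gmap.names}))
        with pytest.raises(ContractError, match="homozygous"):
            simulate_population(
                founders, CrossDesign(type="F2", n_offspring=10), gmap, [ink_s35], rng
            )

    def test_bad_design(self):
        with pytest.raises(ContractError):
            CrossDesign(type="F9", n_offspring=10)
        with pytest.raises(ContractError):
            CrossDesign(type="F2", n_offspring=0)
        with pytest.raises(ContractError):
            CrossDesign(type="SSD_RI", n_offspring=10, generations=0)


class TestTwoLocusAssociation:
    def test_pseudolinkage_positive_under_active_killer(self, gmap, ink_s35, rng):
        founders = founder_pair(gmap)
        design = CrossDesign(type="SSD_RI", n_offspring=300, generations=8)
        stats = []
        for _ in range(20):
            table = simulate_population(founders, design, gmap, [ink_s35], rng)
            stats.append(two_locus_association(table, "S35", "INK").statistic)
        assert np.mean(stats) > 0
        assert sum(s > 0 for s in stats) >= 18

    def test_no_killing_centers_at_zero(self, gmap, ink_s35, rng):
        neutral = KillerSystem(
            killer=ink_s35.killer,
            partner=ink_s35.partner,
            partner_mode="activator",
            targeted_allele="J",
            survival_s=1.0,  # every targeted gamete survives
        )
        founders = founder_pair(gmap)
        design = CrossDesign(type="SSD_RI", n_offspring=300, generations=8)
        stats = [
            two_locus_association(
                simulate_population(founders, design, gmap, [neutral], rng), "S35", "INK"
            ).statistic
            for _ in range(20)
        ]
        se = np.std(stats, ddof=1) / math.sqrt(len(stats))
        assert abs(np.mean(stats)) <= 3 * max(se, 1e-3)

    def test_perfectly_linked_loci(self, rng):
        a = LocusDef(name="A", chrom="chr1", pos_bp=100)
        b = LocusDef(name="B", chrom="chr1", pos_bp=200)
        gmap = GeneticMap([GeneticMapEntry(a, 10.0), GeneticMapEntry(b, 10.0)])
        founders = founder_pair(gmap)
        design = CrossDesign(type="SSD_RI", n_offspring=100, generations=12)
        table = simulate_population(founders, design, gmap, [], rng)
        result = two_locus_association(table, "A", "B")
        assert result.statistic == 1.0
        assert result.n_recombinant == 0

    def test_too_few_informative_lines(self):
        table = pd.DataFrame({"A": ["H", "H"], "B": ["II", "JJ"]})
        with pytest.raises(ContractError, match="fewer than 2"):
            two_locus_association(table, "A", "B")

    def test_missing_locus(self):
        table = pd.DataFrame({"A": ["II", "JJ"]})
        with pytest.raises(ContractError, match="'B'"):
            two_locus_association(table, "A", "B")


class TestGeneticMap:
    def test_chromosome_boundary_is_free_recombination(self, gmap):
        # nA (chr3) follows INK/S35 block chromosomes in sorted order
        r = gmap.recomb
        assert r[0] == 0.5
        chroms = [e.locus.chrom for e in gmap.entries]
        for i in range(1, len(chroms)):
            if chroms[i] != chroms[i - 1]:
                assert r[i] == 0.5

    def test_duplicate_names_rejected(self, s35_locus):
        with pytest.raises(ContractError):
            GeneticMap([GeneticMapEntry(s35_locus, 0.0), GeneticMapEntry(s35_locus, 1.0)])

    def test_unknown_locus_index(self, gmap):
        with pytest.raises(ContractError):
            gmap.index("nope")
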