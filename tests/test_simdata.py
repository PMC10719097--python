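"""Simulator unit tests: haplotypes, meiosis, conceptus assembly, rendering."""

import numpy as np
import pytest

import haplarith as h
from haplarith.genome import CENTROMERES
from haplarith.simdata import CellLine, call_genotype, default_crossovers


def test_probe_map_invariants():
    pm = h.make_probe_map(50, ["1", "2"])
    assert len(pm) == 100
    assert len(set(pm.probe_id)) == 100
    for chrom in ("1", "2"):
        pos = pm.position[pm.chrom_mask(chrom)]
        assert np.all(np.diff(pos) > 0)
    with pytest.raises(ValueError, match="empty"):
        h.ProbeMap(np.array([]), np.array([]), np.array([]), np.array([]))


class TestParentHaplotypes:
    def test_degenerate_frequency_gives_all_a(self):
        pm = h.make_probe_map(100, ["1"], pop_baf=0.0)
        mother, father = h.simulate_parent_haplotypes(pm, seed=1)
        assert not mother.haplotypes["1"].any()
        assert not father.haplotypes["1"].any()

    def test_same_seed_is_deterministic(self):
        pm = h.make_probe_map(200, ["1", "2"])
        a = h.simulate_parent_haplotypes(pm, seed=42)
        b = h.simulate_parent_haplotypes(pm, seed=42)
        for g1, g2 in zip(a, b):
            for chrom in ("1", "2"):
                assert np.array_equal(g1.haplotypes[chrom], g2.haplotypes[chrom])

    def test_allele_share_matches_frequency(self):
        pm = h.make_probe_map(10_000, ["1"], pop_baf=0.5)
        mother, _ = h.simulate_parent_haplotypes(pm, seed=3)
        share = mother.haplotypes["1"].mean()
        assert abs(share - 0.5) < 0.02


@pytest.fixture(scope="module")
def parent():
    pm = h.make_probe_map(2000, ["2"])
    # force the two homologs to differ everywhere so origin is readable
    hap = np.zeros((2, len(pm)), dtype=np.uint8)
    hap[1] = 1
    return h.ParentalGenome(pm, {"2": hap})


class TestMeiosis:

    def test_no_error_no_crossover_returns_parental_homolog(self, parent):
        out = h.simulate_meiosis(parent, "2", [], error="none", seed=5)
        assert len(out) == 1
        assert np.array_equal(out[0], parent.haplotypes["2"][0]) or \
            np.array_equal(out[0], parent.haplotypes["2"][1])

    def test_mi_centromeric_segments_differ(self, parent):
        pm = parent.probe_map
        cen = CENTROMERES["2"]
        pos = pm.position[pm.chrom_mask("2")]
        near = np.argmin(np.abs(pos - cen))
        for seed in range(10):
            g1, g2 = h.simulate_meiosis(
                parent, "2", [50_000_000, 150_000_000], error="MI", seed=seed
            )
            assert g1[near] != g2[near]

    def test_mii_shares_centromere_but_differs_distally(self, parent):
        pm = parent.probe_map
        pos = pm.position[pm.chrom_mask("2")]
        near = np.argmin(np.abs(pos - CENTROMERES["2"]))
        for seed in range(10):
            g1, g2 = h.simulate_meiosis(
                parent, "2", [50_000_000], error="MII", seed=seed
            )
            assert g1[near] == g2[near]
            assert np.any(g1 != g2)

    def test_mii_without_crossover_is_an_error(self, parent):
        with pytest.raises(ValueError, match="MII"):
            h.simulate_meiosis(parent, "2", [], error="MII", seed=0)

    def test_crossover_outside_span_is_an_error(self, parent):
        with pytest.raises(ValueError, match="span"):
            h.simulate_meiosis(parent, "2", [10**10], error="none", seed=0)


def _gametes(pm, seed=0):
    mother, father = h.simulate_parent_haplotypes(pm, seed)
    rng = np.random.default_rng(seed)
    mg, pg = {}, {}
    for chrom in pm.chromosomes():
        xo = default_crossovers(chrom, rng, (0.5, 0.5))
        mg[chrom] = h.simulate_meiosis(mother, chrom, xo, "none", seed)
        pg[chrom] = h.simulate_meiosis(father, chrom, xo, "none", seed + 1)
    return mother, father, mg, pg


class TestAssembleConceptus:
    pm = h.make_probe_map(300, ["1", "2"])

    def test_none_spec_gives_single_diploid_line(self):
        _, _, mg, pg = _gametes(self.pm)
        eu, ab = h.assemble_conceptus(mg, pg, h.AberrationSpec(type="none"), self.pm)
        assert ab is None
        for chrom in ("1", "2"):
            assert np.all(eu.copy_number(chrom) == 2)

    def test_mitotic_trisomy_duplicates_transmitted_homolog(self):
        _, _, mg, pg = _gametes(self.pm)
        spec = h.AberrationSpec(
            type="trisomy", chromosome="2", parent_of_origin="maternal",
            segregational_origin="mitotic",
        )
        eu, ab = h.assemble_conceptus(mg, pg, spec, self.pm)
        maternal = [a for p, a, m in ab.copies["2"] if p == "maternal"]
        assert len(maternal) == 2
        assert np.array_equal(maternal[0], maternal[1])
        assert np.all(ab.copy_number("2") == 3)

    def test_upd_iso_has_two_identical_maternal_copies(self):
        _, _, mg, pg = _gametes(self.pm)
        spec = h.AberrationSpec(
            type="upd_iso", chromosome="1", parent_of_origin="maternal",
        )
        eu, ab = h.assemble_conceptus(mg, pg, spec, self.pm)
        parents = [p for p, a, m in ab.copies["1"]]
        assert parents == ["maternal", "maternal"]
        a1, a2 = (a for p, a, m in ab.copies["1"])
        assert np.array_equal(a1, a2)
        assert np.all(ab.copy_number("1") == 2)

    def test_trisomy_with_partial_interval_is_rejected(self):
        with pytest.raises(ValueError, match="whole chromosome"):
            h.AberrationSpec(
                type="trisomy", chromosome="2", interval=(1, 10_000_000),
                parent_of_origin="maternal", segregational_origin="mitotic",
            )

    def test_meiotic_trisomy_requires_two_gametes(self):
        _, _, mg, pg = _gametes(self.pm)
        spec = h.AberrationSpec(
            type="trisomy", chromosome="2", parent_of_origin="maternal",
            segregational_origin="MI",
        )
        with pytest.raises(ValueError, match="gamete count"):
            h.assemble_conceptus(mg, pg, spec, self.pm)


class TestAberrationSpecValidation:
    def test_segmental_below_100kb_rejected(self):
        with pytest.raises(ValueError, match="100 kb"):
            h.AberrationSpec(
                type="segmental_loss", chromosome="2",
                interval=(1_000_000, 1_050_000), parent_of_origin="maternal",
            )

    def test_triploidy_must_be_genome_wide_and_meiotic(self):
        with pytest.raises(ValueError, match="genome-wide"):
            h.AberrationSpec(type="triploidy", chromosome="1",
                             segregational_origin="MI")
        with pytest.raises(ValueError, match="meiotic"):
            h.AberrationSpec(type="triploidy", segregational_origin="mitotic")

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="fraction"):
            h.AberrationSpec(type="trisomy", chromosome="1",
                             parent_of_origin="maternal",
                             segregational_origin="mitotic",
                             mosaic_fraction_cv=1.2)


class TestRenderArray:
    pm = h.make_probe_map(400, ["1"])

    def _lines(self, spec=None, seed=2):
        mother, father, mg, pg = _gametes(self.pm, seed)
        spec = spec or h.AberrationSpec(type="none")
        eu, ab = h.assemble_conceptus(mg, pg, spec, self.pm)
        return mother, eu, ab

    def test_trisomy_het_band_is_two_thirds_and_logr_058(self):
        spec = h.AberrationSpec(
            type="trisomy", chromosome="1", parent_of_origin="maternal",
            segregational_origin="mitotic",
        )
        mother, eu, ab = self._lines(spec)
        arr = h.render_array([ab], [1.0], mother, h.NoiseModel(0.0, 0.0, 0.0, 0))
        b = ab.b_count("1")
        t = ab.copy_number("1")
        het = (b == 2) & (t == 3)
        assert het.any()
        assert np.allclose(arr.baf[het], 2 / 3)
        assert np.allclose(arr.logr, np.log2(3 / 2))
        assert round(float(arr.logr.mean()), 2) == 0.58

    def test_half_mosaic_monosomy_band_is_one_third(self):
        spec = h.AberrationSpec(
            type="monosomy", chromosome="1", parent_of_origin="maternal",
            segregational_origin="mitotic", mosaic_fraction_cv=0.5,
        )
        mother, eu, ab = self._lines(spec)
        arr = h.render_array(
            [eu, ab], [0.5, 0.5], mother, h.NoiseModel(0.0, 0.0, 0.0, 0)
        )
        # heterozygous SNPs that lose their B homolog: (1-0.5)/(2-0.5) = 1/3
        b_eu, b_ab = eu.b_count("1"), ab.b_count("1")
        sel = (b_eu == 1) & (b_ab == 0)
        assert sel.any()
        assert np.allclose(arr.baf[sel], 1 / 3)

    def test_zero_noise_bands_match_allele_count_enumeration(self):
        spec = h.AberrationSpec(
            type="trisomy", chromosome="1", parent_of_origin="paternal",
            segregational_origin="mitotic", mosaic_fraction_cv=0.3,
        )
        mother, eu, ab = self._lines(spec)
        fr = [0.7, 0.3]
        arr = h.render_array([eu, ab], fr, mother, h.NoiseModel(0.0, 0.0, 0.0, 0))
        # independent enumeration straight from the homolog copies
        num = np.zeros(len(self.pm))
        den = np.zeros(len(self.pm))
        for w, line in zip(fr, (eu, ab)):
            for parent, alleles, present in line.copies["1"]:
                num += w * alleles * present
                den += w * present
        assert np.allclose(arr.baf, num / den)
        assert np.allclose(arr.logr, np.log2(den / 2))

    def test_render_is_reproducible_bit_for_bit(self):
        mother, eu, _ = self._lines()
        noise = h.NoiseModel(0.05, 0.1, 0.0, seed=9)
        a = h.render_array([eu], [1.0], mother, noise)
        b = h.render_array([eu], [1.0], mother, noise)
        assert np.array_equal(a.baf, b.baf)
        assert np.array_equal(a.logr, b.logr)
        assert np.array_equal(a.genotype, b.genotype)

    def test_bad_fractions_rejected(self):
        mother, eu, _ = self._lines()
        with pytest.raises(ValueError, match="sum to 1"):
            h.render_array([eu], [0.5], mother, h.NoiseModel())
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            h.render_array([eu, eu], [1.5, -0.5], mother, h.NoiseModel())

    def test_mean_logr_converges_with_noise(self):
        mother, eu, _ = self._lines()
        for sd, tol in ((0.2, 0.05), (0.02, 0.005)):
            arr = h.render_array(
                [eu], [1.0], mother, h.NoiseModel(0.0, sd, 0.0, seed=4)
            )
            assert abs(arr.logr.mean()) < tol


def test_genotype_thresholds():
    baf = np.array([0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 0.8, 0.9, 1.0])
    assert list(call_genotype(baf)) == [
        "AA", "AA", "NC", "AB", "AB", "AB", "NC", "BB", "BB"
    ]


def test_noise_model_validation():
    with pytest.raises(ValueError):
        h.NoiseModel(baf_sd=-0.1)
    with pytest.raises(ValueError):
        h.NoiseModel(maternal_contamination=1.5)
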