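"""Phasing, mirroring, PCF segmentation and haplarithm construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import haplarith as h
from haplarith.core import MIN_SNPS_PER_SERIES, PhasingError, robust_sigma
from tests.conftest import chrom_interval


class TestClassifyInformativeSnps:
    @pytest.mark.parametrize(
        "mother, father, expected",
        [
            ("AB", "AA", "maternal_informative"),
            ("AB", "BB", "maternal_informative"),
            ("AA", "AB", "paternal_informative"),
            ("BB", "AB", "paternal_informative"),
            ("AA", "AA", "uninformative"),
            ("AA", "BB", "uninformative"),
            ("AB", "AB", "both_het"),
            ("NC", "AB", "missing"),
            ("AB", "NC", "missing"),
        ],
    )
    def test_genotype_table(self, mother, father, expected):
        out = h.classify_informative_snps(np.array([mother]), np.array([father]))
        assert out[0] == expected


def _mini_quartet(m_gt, f_gt, cv_gt):
    n = len(m_gt)
    pm = h.ProbeMap(
        probe_id=np.array([f"rs{i}" for i in range(n)], dtype=object),
        chromosome=np.array(["1"] * n, dtype=object),
        position=np.arange(1, n + 1) * 1000,
        pop_baf=np.full(n, 0.5),
    )
    def arr(gt, role):
        baf = {"AA": 0.0, "AB": 0.5, "BB": 1.0, "NC": 0.5}
        return h.SampleArray(
            np.array(gt, dtype="<U2"),
            np.array([baf[g] for g in gt]),
            np.zeros(n), role,
        )
    return h.TrioQuartet(pm, arr(m_gt, "mother"), arr(f_gt, "father"),
                         arr(cv_gt, "CV"))


class TestPhaseWithSeed:
    def test_mendelian_forced_transmissions(self):
        # father AB, mother AA, CV AA -> father transmitted A;
        # father AB, mother BB, CV AB -> father transmitted A
        q = _mini_quartet(["AA", "BB"], ["AB", "AB"], ["AA", "AB"])
        phase = h.phase_with_seed(q)
        assert list(phase.transmitted) == [0, 0]
        assert list(phase.subcategory) == ["P1", "P2"]
        assert not phase.mirror.any()

    def test_transmitted_b_sets_mirror(self):
        q = _mini_quartet(["AA", "BB"], ["AB", "AB"], ["AB", "BB"])
        phase = h.phase_with_seed(q)
        assert list(phase.transmitted) == [1, 1]
        assert phase.mirror.all()

    def test_nc_seed_leaves_snp_unphased(self):
        q = _mini_quartet(["AA"], ["AB"], ["NC"])
        phase = h.phase_with_seed(q)
        assert phase.transmitted[0] == -1
        assert phase.subcategory[0] == "none"

    def test_impossible_cv_genotype_is_flagged(self):
        # CV BB with mother AA cannot happen in a disomic child
        q = _mini_quartet(["AA"] * 30, ["AB"] * 30, ["AA"] * 29 + ["BB"])
        phase = h.phase_with_seed(q)
        assert phase.inconsistent.sum() == 1
        assert phase.subcategory[-1] == "none"

    def test_non_paternity_raises(self, quartet_factory, small_probe_map):
        q, _ = quartet_factory(seed=5)
        # replace the father by an unrelated genome: half the paternal
        # informative SNPs become Mendelian-impossible on every chromosome
        other, _ = h.simulate_parent_haplotypes(small_probe_map, seed=999)
        import dataclasses
        fake = h.render_array(
            [_parent_line(other)], [1.0], other, h.NoiseModel(0, 0, 0, 1),
            "father",
        )
        bad = dataclasses.replace(q, father=fake)
        with pytest.raises(PhasingError, match="inconsistent"):
            h.phase_with_seed(bad)


def _parent_line(genome):
    from haplarith.simdata import _parent_cell_line
    return _parent_cell_line(genome, "paternal")


class TestMirrorBaf:
    @pytest.mark.parametrize("baf, flag, expected",
                             [(0.3, True, 0.7), (0.5, True, 0.5),
                              (1.0, True, 0.0), (0.3, False, 0.3)])
    def test_reflection(self, baf, flag, expected):
        assert h.mirror_baf(baf, flag) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_double_mirror_is_identity(self, values, flag):
        v = np.array(values)
        flags = np.full(len(v), flag)
        assert np.allclose(h.mirror_baf(h.mirror_baf(v, flags), flags), v)


def brute_force_pcf_cost(y, gamma, sigma=1.0):
    """Exhaustive minimum of the penalized segmentation cost (oracle)."""
    n = len(y)
    best = np.inf
    for k in range(n):
        for cuts in itertools.combinations(range(1, n), k):
            b = [0, *cuts, n]
            cost = sum(
                float(((y[s:e] - y[s:e].mean()) ** 2).sum())
                for s, e in zip(b, b[1:])
            ) / sigma**2 + gamma * k
            best = min(best, cost)
    return best


def _dp_cost(segments, y, gamma, sigma=1.0):
    sse = sum(
        float(((y[s.start:s.end + 1] - y[s.start:s.end + 1].mean()) ** 2).sum())
        for s in segments
    )
    return sse / sigma**2 + gamma * (len(segments) - 1)


class TestPcfSegment:
    def test_constant_series_is_one_segment(self):
        segs = h.pcf_segment(np.full(9, 0.4), gamma=14.0)
        assert len(segs) == 1
        assert segs[0].mean == pytest.approx(0.4)

    def test_two_level_series_splits_at_the_step(self):
        y = np.array([0.0] * 6 + [1.0] * 6)
        segs = h.pcf_segment(y, gamma=0.5, sigma=1.0)
        assert [(s.start, s.end) for s in segs] == [(0, 5), (6, 11)]
        assert [s.mean for s in segs] == [0.0, 1.0]

    def test_huge_gamma_returns_single_segment(self):
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        segs = h.pcf_segment(y, gamma=1e6, sigma=1.0)
        assert len(segs) == 1

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            h.pcf_segment(np.ones(3), gamma=-1.0)

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            h.pcf_segment(np.array([]), gamma=1.0)
        with pytest.raises(ValueError):
            h.pcf_segment(np.array([1.0, np.nan]), gamma=1.0)

    def test_segments_tile_series_without_overlap(self):
        rng = np.random.default_rng(7)
        y = rng.random(200)
        segs = h.pcf_segment(y, gamma=3.0, sigma=1.0)
        assert segs[0].start == 0 and segs[-1].end == 199
        for a, b in zip(segs, segs[1:]):
            assert b.start == a.end + 1

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(11)
        for _ in range(250):
            n = int(rng.integers(1, 11))
            y = rng.random(n)
            gamma = float(rng.uniform(0, 3))
            segs = h.pcf_segment(y, gamma, sigma=1.0)
            assert _dp_cost(segs, y, gamma) == pytest.approx(
                brute_force_pcf_cost(y, gamma), abs=1e-9
            )

    def test_sigma_floor_keeps_noise_free_series_segmentable(self):
        assert robust_sigma(np.zeros(50)) > 0


class TestBuildHaplarithm:
    def test_disomy_band_separation_is_half_everywhere(self, euploid_quartet):
        haps = h.build_haplarithm(euploid_quartet, "CV")
        for chrom, hap in haps.items():
            iv = chrom_interval(euploid_quartet.probe_map, chrom)
            dv = h.compute_d_values(hap, iv)
            assert dv.d_pat == pytest.approx(0.5)
            assert dv.d_mat == pytest.approx(0.5)

    def test_disomy_segment_means_are_exact_bands(self, euploid_quartet):
        haps = h.build_haplarithm(euploid_quartet, "CV")
        for hap in haps.values():
            for s in hap.series.values():
                for seg in s.segments:
                    assert seg.mean in (0.0, 0.5, 1.0)

    def test_maternal_trisomy_paternal_separation(self, maternal_trisomy_quartet):
        haps = h.build_haplarithm(maternal_trisomy_quartet, "CV")
        iv = chrom_interval(maternal_trisomy_quartet.probe_map, "2")
        dv = h.compute_d_values(haps["2"], iv)
        assert dv.d_pat == pytest.approx(2 / 3)
        assert dv.d_mat == pytest.approx(1 / 3)

    def test_all_nc_target_chromosome_is_uninformative(self, euploid_quartet):
        import dataclasses
        q = euploid_quartet
        gt = q.cv.genotype.copy()
        gt[q.probe_map.chrom_mask("3")] = "NC"
        q2 = dataclasses.replace(
            q, cv=dataclasses.replace(q.cv, genotype=gt)
        )
        haps = h.build_haplarithm(q2, "CV")
        assert not any(s.informative for s in haps["3"].series.values())

    def test_sparse_series_has_no_segments(self, euploid_quartet):
        haps = h.build_haplarithm(
            euploid_quartet, "CV", min_snps=10**6
        )
        for hap in haps.values():
            for s in hap.series.values():
                assert not s.informative and s.segments == []

    def test_segment_means_invariant_to_uninformative_padding(self):
        # append SNPs at which both parents are homozygous: they must not
        # enter any series, leaving the fitted segments untouched
        import dataclasses
        pm = h.make_probe_map(600, ["1"])
        noise = h.NoiseModel(0.0, 0.0, 0.0, seed=13)
        q, _ = h.simulate_quartet(
            h.AberrationSpec(type="none"), probe_map=pm, noise=noise, seed=13
        )

        def series_means(quartet):
            haps = h.build_haplarithm(quartet, "CV")
            return {
                name: [seg.mean for seg in s.segments]
                for name, s in haps["1"].series.items()
            }

        base_means = series_means(q)

        n_extra = 100
        last = int(pm.position.max())
        pm2 = h.ProbeMap(
            np.concatenate([pm.probe_id,
                            np.array([f"pad{i}" for i in range(n_extra)],
                                     dtype=object)]),
            np.concatenate([pm.chromosome,
                            np.array(["1"] * n_extra, dtype=object)]),
            np.concatenate([pm.position,
                            last + 1000 * np.arange(1, n_extra + 1)]),
            np.concatenate([pm.pop_baf, np.zeros(n_extra)]),
        )

        def pad(sample):
            return dataclasses.replace(
                sample,
                genotype=np.concatenate(
                    [sample.genotype, np.array(["AA"] * n_extra, dtype="<U2")]
                ),
                baf=np.concatenate([sample.baf, np.zeros(n_extra)]),
                logr=np.concatenate([sample.logr, np.zeros(n_extra)]),
            )

        q2 = h.TrioQuartet(pm2, pad(q.mother), pad(q.father), pad(q.cv),
                           pad(q.em))
        assert series_means(q2) == base_means


def test_export_haplarithm_tsv(tmp_path, euploid_quartet):
    import pandas as pd
    haps = h.build_haplarithm(euploid_quartet, "CV")
    out = tmp_path / "hap.tsv"
    h.export_haplarithm_tsv({"1": haps["1"]}, out)
    df = pd.read_csv(out, sep="\t")
    assert set(df.columns) == {
        "chromosome", "position", "series", "baf", "segment_mean"
    }
    assert set(df["series"]) == {"P1", "P2", "M1", "M2"}
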