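"""Tests for sampling, encoding, widths, VCF ingestion and summary stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from sigmanet import (SampleSpec, SiteSet, encode_genotypes,
                      place_sampling_window, sample_individuals,
                      sampling_width, read_vcf_filtered, summary_stats,
                      write_vcf, GenotypeMatrix)
from sigmanet.preprocess import MonomorphicSiteError, segregating_site_indices

from conftest import make_pop


def _siteset(haps, rows=None):
    haps = np.asarray(haps, dtype=np.uint8)
    n = haps.shape[1] // 2
    rows = np.arange(n) if rows is None else np.asarray(rows)
    return SiteSet(m=haps.shape[0], positions=np.arange(haps.shape[0], dtype=float),
                   haplotypes=haps, sample_rows=rows)


class TestWindowPlacement:
    def test_full_habitat_deterministic(self):
        spec = SampleSpec(n=2, width_fraction=1.0, edge_crop=0.0)
        rng = np.random.default_rng(0)
        assert place_sampling_window(50.0, spec, rng) == (0.0, 0.0, 50.0)

    def test_cropped_full_width_window(self):
        spec = SampleSpec(n=2, width_fraction=1.0, edge_crop=3.0)
        rng = np.random.default_rng(0)
        x0, y0, side = place_sampling_window(50.0, spec, rng)
        assert (x0, y0, side) == (3.0, 3.0, 44.0)  # the [3, 47]^2 square

    def test_positions_uniform_on_feasible_region(self):
        spec = SampleSpec(n=2, width_fraction=0.3, edge_crop=2.0)
        rng = np.random.default_rng(1)
        W = 50.0
        lo, hi = 2.0, 48.0
        slack = (hi - lo) - 0.3 * W
        xs = np.array([place_sampling_window(W, spec, rng)[0] for _ in range(10_000)])
        u = (xs - lo) / slack
        assert kstest(u, "uniform").pvalue > 0.01

    def test_impossible_window_errors(self):
        spec = SampleSpec(n=2, width_fraction=1.0, edge_crop=5.0)
        with pytest.raises(ValueError):
            place_sampling_window(10.0, spec, np.random.default_rng(0))


class TestIndividualSampling:
    def _pop(self, n=60, W=10.0, seed=0):
        rng = np.random.default_rng(seed)
        return make_pop(rng.uniform(0, W, size=(n, 2)), W=W)

    def test_window_with_exactly_n_returns_all(self):
        pop = make_pop([(1, 1), (2, 2), (1.5, 1.8)], W=10)
        spec = SampleSpec(n=3)
        got = sample_individuals(pop, (0.0, 0.0, 3.0), spec, np.random.default_rng(0))
        assert sorted(got) == [0, 1, 2]

    def test_uniform_inclusion_probabilities(self):
        pop = self._pop(n=12)
        spec = SampleSpec(n=5)
        counts = np.zeros(12)
        rng = np.random.default_rng(2)
        reps = 10_000
        for _ in range(reps):
            counts[sample_individuals(pop, (0, 0, 10.0), spec, rng)] += 1
        expected = reps * 5 / 12
        chi2 = np.sum((counts - expected) ** 2 / expected)
        # chi-square with 11 dof: 99.9% quantile ~ 31.3
        assert chi2 < 31.3

    def test_transect_band_geometry(self):
        pop = self._pop(n=400)
        spec = SampleSpec(n=10, strategy="transect")
        got = sample_individuals(pop, (0, 0, 10.0), spec, np.random.default_rng(3))
        assert np.all(np.abs(pop.y[got] - 5.0) <= 0.5)

    def test_half_biased_split(self):
        pop = self._pop(n=400)
        spec = SampleSpec(n=20, strategy="half-biased")
        got = sample_individuals(pop, (0, 0, 10.0), spec, np.random.default_rng(4))
        assert np.sum(pop.x[got] <= 5.0) == 16  # 80% from the left half

    def test_point_takes_nearest(self):
        pop = self._pop(n=100)
        spec = SampleSpec(n=8, strategy="point")
        rng = np.random.default_rng(5)
        got = sample_individuals(pop, (0, 0, 10.0), spec, rng)
        assert len(set(got)) == 8

    def test_insufficient_individuals_names_strategy(self):
        pop = self._pop(n=4)
        spec = SampleSpec(n=10, strategy="transect")
        with pytest.raises(ValueError, match="transect"):
            sample_individuals(pop, (0, 0, 10.0), spec, np.random.default_rng(6))


class TestEncoding:
    def test_single_heterozygote_unphased(self):
        haps = np.zeros((1, 8), dtype=np.uint8)
        haps[0, 0] = 1  # one het individual among homozygous-major
        gm = encode_genotypes([0, 1, 2, 3], _siteset(haps), phased=False,
                              pad_to=None, rng=np.random.default_rng(0))
        row = gm.values[0]
        assert row.tolist() == [1, 0, 0, 0]

    def test_phased_heterozygote_random_order(self):
        haps = np.zeros((1, 6), dtype=np.uint8)
        haps[0, 0] = 1
        seen = set()
        for s in range(30):
            gm = encode_genotypes([0, 1, 2], _siteset(haps), phased=True,
                                  pad_to=None, rng=np.random.default_rng(s))
            seen.add(tuple(gm.values[0, :2]))
        assert seen == {(0, 1), (1, 0)}

    def test_zero_padding_on_right(self):
        haps = np.array([[1, 0, 0, 0, 1, 0]], dtype=np.uint8)
        gm = encode_genotypes([0, 1, 2], _siteset(haps), phased=False,
                              pad_to=100, rng=np.random.default_rng(0))
        assert gm.values.shape == (1, 100)
        assert np.all(gm.values[:, 3:] == 0)
        assert gm.unpadded.shape == (1, 3)

    def test_major_allele_flipped_to_minor(self):
        haps = np.array([[1, 1, 1, 1, 0, 1]], dtype=np.uint8)  # allele 1 at 5/6
        gm = encode_genotypes([0, 1, 2], _siteset(haps), phased=False,
                              pad_to=None, rng=np.random.default_rng(0))
        assert gm.values[0].tolist() == [0, 0, 1]  # counts of the rarer allele

    def test_monomorphic_site_rejected(self):
        haps = np.ones((1, 6), dtype=np.uint8)
        with pytest.raises(MonomorphicSiteError):
            encode_genotypes([0, 1, 2], _siteset(haps), phased=False,
                             pad_to=None, rng=np.random.default_rng(0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_minor_allele_frequency_at_most_half(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(12, 10)).astype(np.uint8)
        ss = _siteset(haps)
        rows = np.arange(5)
        seg = segregating_site_indices(ss, rows)
        if seg.size == 0:
            return
        sub = _siteset(haps[seg])
        gm = encode_genotypes(rows, sub, phased=False, pad_to=None, rng=rng)
        freq = gm.unpadded.sum(axis=1) / 10.0
        assert np.all(freq <= 0.5)


class TestSamplingWidth:
    def test_three_four_five(self):
        assert sampling_width(np.array([[0, 0], [3, 4]])) == pytest.approx(5.0)

    def test_equilateral_triangle(self):
        s = 2.0
        pts = np.array([[0, 0], [s, 0], [s / 2, s * np.sqrt(3) / 2]])
        assert sampling_width(pts) == pytest.approx(s)

    def test_permutation_and_rotation_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5, size=(15, 2))
        w = sampling_width(pts)
        assert sampling_width(pts[::-1]) == pytest.approx(w)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert sampling_width(pts @ R.T) == pytest.approx(w)

    def test_geodesic_meridian_degree(self):
        # one degree of latitude along the prime meridian on WGS84
        w = sampling_width(np.array([[0.0, 0.0], [1.0, 0.0]]), metric="geodesic")
        assert w == pytest.approx(110.574, abs=0.1)

    def test_identical_points_error(self):
        with pytest.raises(ValueError):
            sampling_width(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestVCF:
    def _write_toy(self, path):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\td\te",
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\t0/0",
            "1\t200\t.\tA\tAT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\t0/0",   # indel
            "1\t300\t.\tA\tT,C\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\t0/0\t0/0",  # triallelic
            "1\t400\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\t0/0\t0/0",
            "1\t500\t.\tC\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t./.\t0/0\t0/0",    # 80% typed
            "1\t600\t.\tT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0",    # monomorphic
        ]
        path.write_text("\n".join(lines) + "\n")

    def _locs(self, ids=("a", "b", "c", "d", "e")):
        return pd.DataFrame({"id": ids, "x": [0, 1, 2, 3, 4], "y": [0, 0, 0, 0, 0]})

    def test_filters_keep_biallelic_snps_only(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_toy(vcf)
        gm, loc = read_vcf_filtered(str(vcf), self._locs(), missing_fraction_allowed=0.0)
        # indel, triallelic, the 80%-typed site and the monomorphic site drop
        assert gm.m == 2
        assert gm.n_individuals == 5

    def test_missingness_threshold_semantics(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_toy(vcf)
        gm, _ = read_vcf_filtered(str(vcf), self._locs(), missing_fraction_allowed=0.15)
        assert gm.m == 2  # 80% genotyped < 85% required -> still dropped
        gm, _ = read_vcf_filtered(str(vcf), self._locs(), missing_fraction_allowed=0.25)
        assert gm.m == 3  # now retained, missing imputed with the major allele

    def test_id_mismatch_lists_offenders(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_toy(vcf)
        bad = self._locs(ids=("a", "b", "c", "d", "zzz"))
        with pytest.raises(ValueError, match="zzz"):
            read_vcf_filtered(str(vcf), bad)

    def test_duplicate_location_deterministic_choice(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_toy(vcf)
        locs = self._locs()
        locs.loc[1, ["x", "y"]] = [0, 0]  # b shares a's location
        picks = {read_vcf_filtered(str(vcf), locs, seed=3)[0].n_individuals
                 for _ in range(3)}
        assert picks == {4}
        a = read_vcf_filtered(str(vcf), locs, seed=3)[1]["id"].tolist()
        b = read_vcf_filtered(str(vcf), locs, seed=3)[1]["id"].tolist()
        assert a == b

    def test_roundtrip_simulated_sites(self, tmp_path, site_pool):
        pop, sample, pool = site_pool
        sub = SiteSet(m=200, positions=pool.positions[:200],
                      haplotypes=pool.haplotypes[:200], sample_rows=pool.sample_rows)
        names = [f"ind{r}" for r in sample]
        path = tmp_path / "sim.vcf"
        write_vcf(sub, names, str(path), phased=True)
        locs = pd.DataFrame({"id": names, "x": pop.x[sample], "y": pop.y[sample]})
        gm, _ = read_vcf_filtered(str(path), locs, missing_fraction_allowed=0.0)
        rng = np.random.default_rng(0)
        seg = segregating_site_indices(sub, sample)
        keep = SiteSet(m=seg.size, positions=sub.positions[seg],
                       haplotypes=sub.haplotypes[seg], sample_rows=sub.sample_rows)
        direct = encode_genotypes(sample, keep, phased=False, pad_to=None, rng=rng)
        order = np.argsort(keep.positions, kind="stable")
        np.testing.assert_array_equal(gm.values, direct.values[order])


class TestSummaryStats:
    def _gm(self, values):
        v = np.asarray(values, dtype=np.int16)
        return GenotypeMatrix(values=v, phased=False, n_individuals=v.shape[1],
                              pad_to=v.shape[1])

    def test_identical_homozygotes(self):
        stats = summary_stats(self._gm(np.zeros((5, 4))))
        assert stats.pi == 0.0 and stats.h_obs == 0.0
        assert np.isnan(stats.tajima_d)

    def test_two_diploids_one_shared_het_site(self):
        stats = summary_stats(self._gm([[1, 1]]))
        assert stats.h_obs == 1.0
        # H_exp = 2 * 0.5 * 0.5 * 4/3 = 2/3 -> F_IS = 1 - 1.5 = -0.5
        assert stats.h_exp == pytest.approx(2 / 3)
        assert stats.f_is == pytest.approx(-0.5)
        assert stats.f_is < 0

    def test_pi_hand_case(self):
        # one site, minor count 2 of 8 copies: pi = 2*2*6/(8*7)
        stats = summary_stats(self._gm([[2, 0, 0, 0]]))
        assert stats.pi == pytest.approx(2 * 2 * 6 / 56)

    def test_tajimas_d_near_zero_for_neutral_data(self):
        """Neutral constant-size coalescent: mean D over replicates ~ 0."""
        import msprime

        ds = []
        for rep in range(200):
            ts = msprime.sim_ancestry(samples=5, population_size=100,
                                      sequence_length=4e7, recombination_rate=1e-8,
                                      random_seed=1000 + rep)
            ts = msprime.sim_mutations(ts, rate=2.5e-7, random_seed=2000 + rep)
            geno = np.zeros((ts.num_sites, 5), dtype=np.int16)
            for k, var in enumerate(ts.variants()):
                g = var.genotypes
                gg = g[0::2] + g[1::2]
                geno[k] = gg
            keep = (geno.sum(axis=1) > 0) & (geno.sum(axis=1) < 10)
            gm = self._gm(geno[keep])
            if gm.m < 5:
                continue
            d = summary_stats(gm).tajima_d
            if np.isfinite(d):
                ds.append(d)
        assert len(ds) > 150
        assert abs(np.mean(ds)) < 0.15
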