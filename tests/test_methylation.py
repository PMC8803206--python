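"""Methylation ingestion, Pearson statistics, representative CpGs, profiles."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apmeth.gene_models import Promoter
from apmeth.methylation import (MethylationMatrix, activity_quartile_profiles,
                                delta_beta, pearson, promoter_region_mean,
                                read_beta_matrix, read_wgbs_ratios,
                                select_representative_cpg,
                                signed_tss_distance, tss_methylation_profile,
                                wgbs_cohort)


def promoter(pid="pr1", chrom="chr1", strand="+", tss=5000):
    return Promoter(promoter_id=pid, gene_id="g", chrom=chrom, strand=strand,
                    tss=tss, member_transcripts=("t",),
                    donor_sites=frozenset({tss + 300}),
                    cluster_start=tss, cluster_end=tss + 300)


def meth_at(positions, betas, samples=None, chrom="chr1"):
    samples = samples or [f"s{i}" for i in range(np.atleast_2d(betas).shape[1])]
    beta = pd.DataFrame(np.atleast_2d(np.asarray(betas, dtype=float)),
                        columns=samples,
                        index=pd.Index([f"cg{i}" for i in range(len(positions))],
                                       name="probe_id"))
    probes = pd.DataFrame({"chrom": chrom, "pos": positions}, index=beta.index)
    return MethylationMatrix(probes=probes, beta=beta)


class TestReaders:
    def test_beta_matrix_join(self):
        matrix = "probe_id\ts1\ts2\ncgA\t0.1\t0.2\ncgB\t0.5\t0.6\ncgC\t0.9\t1.0\n"
        manifest = "probe_id\tchrom\tpos\ncgA\tchr1\t100\ncgB\tchr1\t200\ncgC\tchr2\t50\n"
        m = read_beta_matrix(io.StringIO(matrix), io.StringIO(manifest))
        assert len(m.probes) == 3
        assert m.probes.loc["cgA", "pos"] == 99  # 1-based -> 0-based

    def test_probe_missing_from_manifest_dropped(self):
        matrix = "probe_id\ts1\ncgA\t0.1\ncgZ\t0.2\n"
        manifest = "probe_id\tchrom\tpos\ncgA\tchr1\t100\n"
        with pytest.warns(UserWarning, match="missing from manifest"):
            m = read_beta_matrix(io.StringIO(matrix), io.StringIO(manifest))
        assert list(m.beta.index) == ["cgA"]

    def test_beta_out_of_range_errors(self):
        matrix = "probe_id\ts1\ncgA\t1.2\n"
        manifest = "probe_id\tchrom\tpos\ncgA\tchr1\t100\n"
        with pytest.raises(ValueError, match="outside"):
            read_beta_matrix(io.StringIO(matrix), io.StringIO(manifest))

    def test_wgbs_four_lines(self):
        text = "chr1\t100\t101\t0.5\nchr1\t200\t201\t0.7\n" \
               "chr1\t300\t301\t0.0\nchr2\t100\t101\t1.0\n"
        m = read_wgbs_ratios(io.StringIO(text), sample_id="v1")
        assert len(m.probes) == 4 and m.source == "wgbs"
        assert m.locate("chr1", 200) == "chr1:200"

    def test_wgbs_coverage_retained(self):
        m = read_wgbs_ratios(io.StringIO("chr1\t100\t101\t0.5\t12\n"))
        assert m.coverage.iloc[0, 0] == 12

    def test_wgbs_duplicate_position_errors(self):
        text = "chr1\t100\t101\t0.5\nchr1\t100\t101\t0.6\n"
        with pytest.raises(ValueError, match="duplicated"):
            read_wgbs_ratios(io.StringIO(text))

    def test_wgbs_ratio_out_of_range_errors(self):
        with pytest.raises(ValueError, match="line 1"):
            read_wgbs_ratios(io.StringIO("chr1\t100\t101\t1.5\n"))

    def test_wgbs_cohort_outer_join(self):
        a = io.StringIO("chr1\t100\t101\t0.2\n")
        b = io.StringIO("chr1\t100\t101\t0.4\nchr1\t200\t201\t0.9\n")
        m = wgbs_cohort({"sA": a, "sB": b})
        assert m.beta.shape == (2, 2)
        assert np.isnan(m.beta.loc["chr1:200", "sA"])


class TestDeltaBeta:
    design = pd.DataFrame({"sample_id": ["t1", "t2", "n1", "n2"],
                           "condition": ["tumor", "tumor",
                                         "normal", "normal"],
                           "pair_id": ["p1", "p2", "p1", "p2"]})

    def test_hypermethylated(self):
        m = meth_at([100], [[0.7, 0.5, 0.4, 0.4]],
                    samples=["t1", "t2", "n1", "n2"])
        assert delta_beta(m, self.design)["cg0"] == pytest.approx(0.2)

    def test_equal_means_zero(self):
        m = meth_at([100], [[0.5, 0.5, 0.5, 0.5]],
                    samples=["t1", "t2", "n1", "n2"])
        assert delta_beta(m, self.design)["cg0"] == 0.0

    def test_group_all_na_gives_na(self):
        m = meth_at([100], [[np.nan, np.nan, 0.5, 0.5]],
                    samples=["t1", "t2", "n1", "n2"])
        assert np.isnan(delta_beta(m, self.design)["cg0"])

    def test_antisymmetric_and_bounded(self, rng):
        beta = rng.uniform(0, 1, size=(20, 4))
        m = meth_at(list(range(20)), beta, samples=["t1", "t2", "n1", "n2"])
        d = delta_beta(m, self.design)
        flipped = self.design.assign(
            condition=self.design["condition"].map(
                {"tumor": "normal", "normal": "tumor"}))
        assert np.allclose(delta_beta(m, flipped), -d)
        assert d.abs().max() <= 1.0


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(5.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_worked_three_point_example(self):
        r, p = pearson([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5, abs=1e-12)
        assert p == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_constant_vector_na(self):
        r, p = pearson([1, 2, 3], [4, 4, 4])
        assert np.isnan(r) and np.isnan(p)

    def test_matches_covariance_formula_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p = pearson(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            r0 = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            t = r0 * np.sqrt((n - 2) / (1 - r0 ** 2))
            p0 = 2 * stats.t.sf(abs(t), n - 2)
            assert abs(r - r0) < 1e-12
            assert abs(p - p0) < 1e-12


class TestRepresentativeCpG:
    def activity(self, values, samples):
        return pd.Series(values, index=samples, dtype=float)

    def test_argmin_p_selected(self, rng):
        samples = [f"s{i}" for i in range(10)]
        act = self.activity(np.linspace(1, 4, 10), samples)
        noise = rng.normal(0, 1, (3, 10))
        betas = np.vstack([
            noise[0],                       # weak
            0.9 - 0.2 * act.to_numpy() + 0.01 * noise[1],   # strong negative
            noise[2],
        ])
        m = meth_at([4500, 5100, 5900], betas, samples=samples)
        link = select_representative_cpg(promoter(), m, act)
        assert link.probe_id == "cg1"
        assert link.r < 0 and link.p < 0.01
        assert link.dist_to_tss == 100

    def test_no_cpg_in_window_none(self):
        samples = ["s0", "s1", "s2"]
        m = meth_at([9000], [[0.1, 0.5, 0.9]], samples=samples)
        assert select_representative_cpg(
            promoter(), m, self.activity([1, 2, 3], samples)) is None

    def test_window_boundary_inclusive(self):
        samples = ["s0", "s1", "s2", "s3"]
        act = self.activity([1, 2, 3, 4], samples)
        m = meth_at([4000, 6000], [[0.8, 0.6, 0.4, 0.2],
                                   [0.1, 0.2, 0.3, 0.41]], samples=samples)
        link = select_representative_cpg(promoter(), m, act, window=1000)
        assert link is not None                  # +-1000 includes both
        m2 = meth_at([3999], [[0.8, 0.6, 0.4, 0.2]], samples=samples)
        assert select_representative_cpg(promoter(), m2, act,
                                         window=1000) is None

    def test_strand_aware_signed_distance(self):
        assert signed_tss_distance(np.array([4800]), 5000, "+")[0] == -200
        assert signed_tss_distance(np.array([5200]), 5000, "-")[0] == -200

    def test_sample_order_invariant(self, rng):
        samples = [f"s{i}" for i in range(8)]
        act = self.activity(rng.normal(2, 1, 8), samples)
        m = meth_at([4600, 5400], rng.uniform(0, 1, (2, 8)), samples=samples)
        l1 = select_representative_cpg(promoter(), m, act)
        perm = list(rng.permutation(samples))
        m2 = MethylationMatrix(probes=m.probes, beta=m.beta[perm])
        l2 = select_representative_cpg(promoter(), m2, act)
        assert l1.probe_id == l2.probe_id
        assert l1.r == pytest.approx(l2.r)

    def test_all_constant_returns_none_logged(self):
        samples = ["s0", "s1", "s2"]
        m = meth_at([5000], [[0.5, 0.5, 0.5]], samples=samples)
        with pytest.warns(UserWarning, match="undefined"):
            assert select_representative_cpg(
                promoter(), m, self.activity([1, 2, 3], samples)) is None


class TestProfiles:
    def test_single_probe_fills_windows_containing_it(self):
        m = meth_at([5000], [[0.5]], samples=["s"])
        prof = tss_methylation_profile(m, [promoter()], ["s"])
        containing = (prof["window_start"] <= 0) & \
            (prof["window_start"] + 50 >= 0)
        assert np.allclose(prof.loc[containing, "mean_beta"], 0.5)
        assert prof.loc[~containing, "mean_beta"].isna().all()

    def test_two_probes_average(self):
        m = meth_at([5010, 5020], [[0.2], [0.4]], samples=["s"])
        prof = tss_methylation_profile(m, [promoter()], ["s"])
        w = prof[prof["window_start"] == 0].iloc[0]
        assert w["mean_beta"] == pytest.approx(0.3)

    def test_matches_bruteforce_windowing(self, rng):
        samples = ["a", "b"]
        pos = rng.integers(3000, 7000, 60)
        betas = rng.uniform(0, 1, (60, 2))
        m = meth_at(pos, betas, samples=samples)
        prof = tss_methylation_profile(m, [promoter()], samples)
        dist = pos - 5000
        for _, row in prof.iloc[::13].iterrows():
            s = row["window_start"]
            mask = (dist >= s) & (dist <= s + 50)
            if mask.any():
                assert row["mean_beta"] == pytest.approx(
                    betas[mask].mean())
            else:
                assert np.isnan(row["mean_beta"])

    def test_quartiles_of_eight_promoters(self, rng):
        proms = {f"pr{i}": promoter(pid=f"pr{i}", tss=5000 + 3000 * i)
                 for i in range(8)}

        class Cat:
            def __getitem__(self, k):
                return proms[k]
        act = pd.Series(np.arange(8.0), index=list(proms))
        m = meth_at([5000], [[0.5]], samples=["s"])
        profs = activity_quartile_profiles(act, m, Cat(), ["s"])
        assert set(profs) == {1, 2, 3, 4}

    def test_fewer_than_four_promoters_errors(self):
        m = meth_at([5000], [[0.5]], samples=["s"])
        with pytest.raises(ValueError):
            activity_quartile_profiles(pd.Series([1.0]), m, None, ["s"])


class TestRegionMean:
    def test_single_cpg(self):
        m = meth_at([5100], [[0.4, 0.6]], samples=["a", "b"])
        s = promoter_region_mean(m, promoter())
        assert s["a"] == 0.4 and s["b"] == 0.6

    def test_full_coverage_excludes_partial_probes(self):
        m = meth_at([5100, 5200], [[0.4, np.nan], [0.8, 0.6]],
                    samples=["a", "b"])
        s = promoter_region_mean(m, promoter(), require_full_coverage=True)
        assert s["a"] == 0.8 and s["b"] == 0.6

    def test_matches_direct_mean_oracle(self, rng):
        pos = rng.integers(4000, 6001, 20)
        betas = rng.uniform(0, 1, (20, 3))
        m = meth_at(pos, betas, samples=["a", "b", "c"])
        s = promoter_region_mean(m, promoter())
        keep = np.abs(pos - 5000) <= 1000
        assert np.allclose(s.to_numpy(), betas[keep].mean(axis=0))

    def test_no_cpg_gives_na(self):
        m = meth_at([9000], [[0.5]], samples=["s"])
        assert promoter_region_mean(m, promoter()).isna().all()
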