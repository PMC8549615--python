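"""epiRAD count filtering, TMM, NB GLM dispersion/DM tests, annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transloc.containers import CountMatrix
from transloc.methylation import (annotate_loci, batch_blacklist, dm_test,
                                  estimate_dispersion, filter_informative,
                                  log_transform, tmm_normalize)
from transloc.utils import bh_adjust


def make_counts(n, L, phi=0.2, lfc_idx=None, lfc=0.0, batch=None,
                batch_idx=None, batch_fc=1.0, seed=1, groups=None):
    r = np.random.default_rng(seed)
    mu = 80 * r.lognormal(0, 0.7, L)
    s = r.lognormal(0, 0.2, n)
    if groups is None:
        groups = np.repeat(["a", "b"], n // 2)
    beta = np.zeros(L)
    if lfc_idx is not None:
        beta[np.asarray(lfc_idx)] = lfc
    m = s[:, None] * mu[None, :] * np.exp2(beta[None, :] * (groups == "b")[:, None])
    if batch is not None and batch_idx is not None:
        m[np.ix_(batch == batch[-1], np.asarray(batch_idx))] *= batch_fc
    lam = r.gamma(1 / phi, phi * m) if phi > 1e-8 else m
    counts = r.poisson(lam)
    samples = pd.DataFrame({"id": [f"i{k}" for k in range(n)],
                            "population": groups})
    if batch is not None:
        samples["batch"] = batch
    loci = pd.DataFrame({"locus_id": [f"l{j}" for j in range(L)], "chrom": "chr1",
                         "start": np.arange(L) * 100, "end": np.arange(L) * 100 + 50})
    return CountMatrix(counts, samples, loci)


class TestFilterInformative:
    def test_sparse_locus_removed(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[0, 0] = 5
        counts[:, 1] = 3
        cm = CountMatrix(counts, pd.DataFrame({"id": [f"i{k}" for k in range(10)]}),
                         pd.DataFrame({"locus_id": ["a", "b"], "chrom": "chr1",
                                       "start": [0, 100], "end": [50, 150]}))
        out = filter_informative(cm, 0.33)
        assert list(out.loci["locus_id"]) == ["b"]

    def test_dense_matrix_unchanged(self):
        cm = make_counts(10, 20, seed=2)
        cm.counts = cm.counts + 1  # guarantee all nonzero
        out = filter_informative(CountMatrix(cm.counts, cm.samples, cm.loci), 0.33)
        assert out.n_loci == 20

    def test_hand_counted_patterns(self):
        n = 9  # threshold ceil(0.33*9) = 3 individuals
        patterns = [1, 2, 3, 4, 9, 0, 3, 2]
        counts = np.zeros((n, len(patterns)), dtype=int)
        for j, k in enumerate(patterns):
            counts[:k, j] = 7
        cm = CountMatrix(counts, pd.DataFrame({"id": [f"i{k}" for k in range(n)]}),
                         pd.DataFrame({"locus_id": [f"l{j}" for j in range(8)],
                                       "chrom": "chr1", "start": np.arange(8),
                                       "end": np.arange(8) + 1}))
        out = filter_informative(cm, 0.33)
        assert list(out.loci["locus_id"]) == ["l2", "l3", "l4", "l6"]


class TestTMM:
    def test_identical_columns_unit_factors(self):
        base = np.tile(np.arange(1, 51), (4, 1))
        cm = CountMatrix(base, pd.DataFrame({"id": list("abcd")}),
                         pd.DataFrame({"locus_id": [f"l{j}" for j in range(50)],
                                       "chrom": "chr1", "start": np.arange(50),
                                       "end": np.arange(50) + 1}))
        f = tmm_normalize(cm)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_unit_factors(self):
        base = np.arange(1, 101)
        counts = np.vstack([base, 2 * base, base])
        cm = CountMatrix(counts, pd.DataFrame({"id": list("abc")}),
                         pd.DataFrame({"locus_id": [f"l{j}" for j in range(100)],
                                       "chrom": "chr1", "start": np.arange(100),
                                       "end": np.arange(100) + 1}))
        f = tmm_normalize(cm)
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_composition_bias_matches_stepwise_oracle(self):
        rng = np.random.default_rng(3)
        L = 400
        mu = 100 * rng.lognormal(0, 0.5, L)
        a = rng.poisson(mu)
        biased = mu.copy()
        biased[:40] *= 8.0  # 10% of loci 8-fold up in sample b
        b = rng.poisson(biased)
        counts = np.vstack([a, b]).astype(int)
        cm = CountMatrix(counts, pd.DataFrame({"id": ["a", "b"]}),
                         pd.DataFrame({"locus_id": [f"l{j}" for j in range(L)],
                                       "chrom": "chr1", "start": np.arange(L),
                                       "end": np.arange(L) + 1}))
        f = tmm_normalize(cm, ref=0)

        # independent step-by-step computation with explicit sorting
        na, nb = a.sum(), b.sum()
        both = (a > 0) & (b > 0)
        pa, pb = a[both] / na, b[both] / nb
        M = np.log2(pb / pa)
        A = 0.5 * np.log2(pb * pa)
        w = (na - a[both]) / (na * a[both]) + (nb - b[both]) / (nb * b[both])
        nn = M.size
        kM = int(np.floor(nn * 0.3))
        kA = int(np.floor(nn * 0.05))
        ordM = np.argsort(np.argsort(M, kind="stable"), kind="stable")
        ordA = np.argsort(np.argsort(A, kind="stable"), kind="stable")
        keep = (ordM >= kM) & (ordM < nn - kM) & (ordA >= kA) & (ordA < nn - kA)
        lf = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        fb = 2.0 ** lf
        expected = np.array([1.0, fb])
        expected /= np.exp(np.mean(np.log(expected)))
        assert abs(f[1] - expected[1]) / expected[1] < 0.05
        # the composition-inflated sample gets a factor < 1 (its effective
        # library size shrinks, removing the spurious depth excess)
        assert f[1] < f[0]

    def test_zero_library_rejected(self):
        cm = CountMatrix(np.zeros((2, 5), dtype=int), pd.DataFrame({"id": ["a", "b"]}),
                         pd.DataFrame({"locus_id": list("abcde"), "chrom": "chr1",
                                       "start": np.arange(5), "end": np.arange(5) + 1}))
        with pytest.raises(ValueError, match="library"):
            tmm_normalize(cm)


class TestDispersion:
    def test_poisson_counts_small_dispersion(self):
        cm = make_counts(40, 500, phi=1e-9, seed=4)
        X = np.column_stack([np.ones(40),
                             (cm.samples["population"] == "b").astype(float)])
        common, _ = estimate_dispersion(cm.counts.T.astype(float), X,
                                        np.log(cm.lib_sizes))
        assert common < 0.01

    def test_recovers_planted_dispersion(self):
        cm = make_counts(40, 2000, phi=0.4, seed=5)
        X = np.column_stack([np.ones(40),
                             (cm.samples["population"] == "b").astype(float)])
        common, tagwise = estimate_dispersion(cm.counts.T.astype(float), X,
                                              np.log(cm.lib_sizes))
        assert 0.32 <= common <= 0.48

    def test_shrinkage_reduces_spread(self):
        cm = make_counts(30, 500, phi=0.3, seed=6)
        X = np.column_stack([np.ones(30),
                             (cm.samples["population"] == "b").astype(float)])
        Y = cm.counts.T.astype(float)
        off = np.log(cm.lib_sizes)
        _, tagwise = estimate_dispersion(Y, X, off, prior_df=10.0)
        _, raw = estimate_dispersion(Y, X, off, prior_df=0.0)
        assert np.var(np.log(tagwise)) < np.var(np.log(raw))


class TestDMTest:
    def test_planted_power_with_tmm(self):
        # |log2FC| = 2 at 100 loci, phi = 0.2, n = 15/group
        cm = make_counts(30, 1000, phi=0.2, lfc_idx=np.arange(100), lfc=2.0, seed=7)
        cm.norm_factors = tmm_normalize(cm)
        res = dm_test(cm, "a", "b")
        assert res.table["dm"][:100].mean() >= 0.80
        assert res.table["dm"][100:].mean() <= 0.05

    def test_null_p_approximately_uniform(self):
        cm = make_counts(30, 2000, phi=0.2, seed=8)
        cm.norm_factors = tmm_normalize(cm)
        res = dm_test(cm, "a", "b")
        frac = (res.table["p"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_group_relabel_flips_log2fc(self):
        cm = make_counts(20, 200, phi=0.2, lfc_idx=[0], lfc=1.5, seed=9)
        cm.norm_factors = tmm_normalize(cm)
        r1 = dm_test(cm, "a", "b")
        r2 = dm_test(cm, "b", "a")
        assert np.allclose(r1.table["log2fc"], -r2.table["log2fc"], atol=1e-4)
        assert np.allclose(r1.table["lrt"], r2.table["lrt"], atol=1e-4)

    def test_self_contrast_all_p_one(self):
        cm = make_counts(20, 100, phi=0.2, seed=10)
        res = dm_test(cm, "a", "a", dispersion=0.2)
        assert (res.table["p"] == 1.0).all()

    def test_methylation_direction_sign(self):
        cm = make_counts(30, 300, phi=0.1, lfc_idx=[0], lfc=-3.0, seed=11)
        cm.norm_factors = tmm_normalize(cm)
        res = dm_test(cm, "a", "b")
        row = res.table.iloc[0]
        assert row["log2fc"] < 0  # fewer reads in refuge-like group
        assert row["methylation_direction"] == 1.0  # read as methylation gain


class TestBatchBlacklist:
    def test_planted_library_effect_recovered(self):
        batch = np.repeat(["lib1", "lib2", "lib3"], 20)
        cm = make_counts(60, 800, phi=0.2, batch=batch,
                         batch_idx=np.arange(100), batch_fc=2.0, seed=12)
        flagged, tab = batch_blacklist(cm, "batch", dispersion=0.25)
        assert np.isin(np.arange(100), flagged).mean() >= 0.80
        assert np.isin(np.arange(100, 800), flagged).mean() <= 0.02

    def test_no_batch_effect_small_blacklist(self):
        batch = np.repeat(["lib1", "lib2", "lib3"], 20)
        cm = make_counts(60, 1000, phi=0.2, batch=batch, seed=13)
        flagged, _ = batch_blacklist(cm, "batch", dispersion=0.25)
        assert len(flagged) <= 0.02 * 1000

    def test_single_level_noop(self):
        cm = make_counts(10, 50, seed=14)
        cm.samples["batch"] = "lib1"
        flagged, tab = batch_blacklist(cm, "batch")
        assert len(flagged) == 0
        assert "single batch" in tab.attrs.get("warning", "")


class TestLogTransform:
    def test_zero_count_maps_to_zero(self):
        cm = make_counts(4, 10, seed=15)
        cm.counts[0, 0] = 0
        cm.lib_sizes = np.full(4, cm.lib_sizes.mean())
        assert log_transform(cm)[0, 0] == 0.0

    def test_equal_libraries_raw_scale(self):
        counts = np.full((3, 5), 7, dtype=int)
        cm = CountMatrix(counts, pd.DataFrame({"id": list("abc")}),
                         pd.DataFrame({"locus_id": list("vwxyz"), "chrom": "chr1",
                                       "start": np.arange(5), "end": np.arange(5) + 1}))
        assert np.allclose(log_transform(cm), 3.0)  # log2(7 + 1)

    def test_library_size_offset_arithmetic(self):
        counts = np.full((4, 6), 10, dtype=int)
        cm = CountMatrix(counts, pd.DataFrame({"id": list("abcd")}),
                         pd.DataFrame({"locus_id": list("uvwxyz"), "chrom": "chr1",
                                       "start": np.arange(6), "end": np.arange(6) + 1}))
        norm1 = 2 ** log_transform(cm) - 1
        cm.lib_sizes = cm.lib_sizes.copy()
        cm.lib_sizes[0] *= 2
        norm2 = 2 ** log_transform(cm) - 1
        ratio = (norm2[0] / norm1[0]) / (cm.lib_sizes.mean() / np.full(4, 60.0).mean())
        assert np.allclose(ratio, 0.5)


class TestAnnotation:
    GENES = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                          "start": [10_000, 50_000, 5_000],
                          "end": [12_000, 55_000, 6_000]})

    @staticmethod
    def _loci(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_genic_near_and_intergenic_boundaries(self):
        loci = self._loci([
            ("chr1", 10_500, 10_600),   # inside gene
            ("chr1", 6_900, 7_000),     # ends exactly 3000 bp before gene start
            ("chr1", 6_899, 6_999),     # 3001 bp away -> intergenic
            ("chr3", 100, 200),         # unknown chromosome
        ])
        out = annotate_loci(loci, self.GENES, flank=3000)
        assert list(out["context"]) == ["genic", "near_gene", "intergenic", "unplaced"]

    def test_matches_quadratic_scan_oracle(self, rng):
        chroms = rng.choice(["chr1", "chr2"], 200)
        starts = rng.integers(0, 70_000, 200)
        loci = self._loci(list(zip(chroms, starts, starts + 120)))
        out = annotate_loci(loci, self.GENES, flank=3000)

        def oracle(row):
            lab = "intergenic"
            hit_chrom = False
            for _, g in self.GENES.iterrows():
                if g["chrom"] != row["chrom"]:
                    continue
                hit_chrom = True
                if row["start"] < g["end"] and row["end"] > g["start"]:
                    return "genic"
                if row["start"] <= g["end"] + 3000 and row["end"] >= g["start"] - 3000:
                    lab = "near_gene"
            return lab if hit_chrom or row["chrom"] in set(self.GENES["chrom"]) else "unplaced"

        expected = [oracle(row) for _, row in loci.iterrows()]
        assert list(out["context"]) == expected


def test_bh_matches_step_up_definition(rng):
    for _ in range(10):
        p = rng.uniform(size=rng.integers(5, 40))
        adj = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            expected[i] = prev
        assert np.allclose(adj, expected)
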