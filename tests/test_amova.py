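"""AMOVA Phi-st against a from-scratch double-summation oracle."""

import math

import numpy as np
import pytest

from ystrkit.amova import (
    HaplotypeMetric,
    IDENTITY,
    REPEAT_SSD,
    amova_two_pop,
    haplotype_distance,
    metric_by_name,
    pairwise_matrix,
    permutation_pvalue,
)
from ystrkit.markers import YFILER17

from conftest import make_hap, make_sample


def brute_force_phi(groups, dist):
    """Definitional two-level AMOVA by explicit double summation.

    Kept deliberately naive and independent of the package's linear
    algebra: every sum of squared deviations is written out directly.
    """
    all_items = [x for g in groups for x in g]
    N = len(all_items)
    k = len(groups)

    def ssd(items):
        s = 0.0
        for a in items:
            for b in items:
                s += dist(a, b)
        return s / (2 * len(items))

    ssd_total = ssd(all_items)
    ssd_within = sum(ssd(g) for g in groups)
    ssd_among = ssd_total - ssd_within
    sigma2_w = ssd_within / (N - k)
    n0 = (N - sum(len(g) ** 2 for g in groups) / N) / (k - 1)
    sigma2_a = (ssd_among / (k - 1) - sigma2_w) / n0
    return sigma2_a / (sigma2_a + sigma2_w)


def _vec_sample(label, vectors):
    # encode small integer test vectors into four real single-copy loci
    loci = ("DYS19", "DYS390", "DYS391", "DYS393")
    haps = [
        make_hap(
            f"{label}{i}",
            **{l: 10.0 + float(v) for l, v in zip(loci, vec)},
        )
        for i, vec in enumerate(vectors)
    ]
    return make_sample(label, haps), loci


class TestMetric:
    def test_equal_haplotypes_distance_zero(self):
        h = make_hap("a")
        for metric in (IDENTITY, REPEAT_SSD):
            assert haplotype_distance(h, make_hap("b"), metric, YFILER17) == 0.0

    def test_one_step_difference(self):
        h1, h2 = make_hap("a"), make_hap("b", DYS391=11.0)
        assert haplotype_distance(h1, h2, IDENTITY, YFILER17) == 1.0
        assert haplotype_distance(h1, h2, REPEAT_SSD, YFILER17) == 1.0

    def test_squared_steps_add(self):
        h1 = make_hap("a")
        h2 = make_hap("b", DYS391=12.0, DYS393=13.0)  # +2 and +1
        assert haplotype_distance(h1, h2, REPEAT_SSD, YFILER17) == 5.0

    def test_dys385_minimum_pairing(self):
        m = HaplotypeMetric(name="repeat_ssd", include_dys385=True)
        h1 = make_hap("a", DYS385=(11.0, 14.0))
        h2 = make_hap("b", DYS385=(12.0, 14.0))
        assert haplotype_distance(h1, h2, m, YFILER17) == 1.0

    def test_dys389_delta_avoids_double_count(self):
        # a +1 step in the DYS389I stretch also shifts DYS389II
        h1 = make_hap("a", DYS389I=13.0, DYS389II=29.0)
        h2 = make_hap("b", DYS389I=14.0, DYS389II=30.0)
        assert haplotype_distance(h1, h2, REPEAT_SSD, YFILER17) == 1.0

    def test_null_on_active_locus_rejected(self):
        h1, h2 = make_hap("a"), make_hap("b", DYS392=None)
        with pytest.raises(ValueError, match="DYS392"):
            haplotype_distance(h1, h2, REPEAT_SSD, YFILER17)


class TestAmova:
    def test_identical_fixed_samples_phi_zero(self):
        a = make_sample("A", [make_hap(f"a{i}") for i in range(4)])
        b = make_sample("B", [make_hap(f"b{i}") for i in range(4)])
        assert amova_two_pop(a, b, REPEAT_SSD).phi == 0.0

    def test_disjoint_fixed_samples_phi_one(self):
        a = make_sample("A", [make_hap(f"a{i}") for i in range(4)])
        b = make_sample("B", [make_hap(f"b{i}", DYS390=26.0) for i in range(4)])
        for metric in (IDENTITY, REPEAT_SSD):
            assert math.isclose(amova_two_pop(a, b, metric).phi, 1.0)

    def test_toy_vectors_match_brute_force(self):
        va = [(0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0),
              (0, 0, 0, 0), (2, 0, 1, 0), (1, 1, 0, 0)]
        vb = [(3, 2, 0, 1), (3, 2, 1, 1), (4, 2, 0, 1),
              (3, 3, 0, 1), (3, 2, 0, 2), (5, 2, 0, 1)]
        a, loci = _vec_sample("A", va)
        b, _ = _vec_sample("B", vb)
        metric = HaplotypeMetric(name="repeat_ssd", loci=loci)

        def sq(u, v):
            return sum((x - y) ** 2 for x, y in zip(u, v))

        expected = brute_force_phi([va, vb], sq)
        assert math.isclose(amova_two_pop(a, b, metric).phi, expected, abs_tol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_groups_match_brute_force_both_metrics(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 13, size=2)
        va = [tuple(rng.integers(0, 4, size=4)) for _ in range(na)]
        vb = [tuple(rng.integers(0, 5, size=4)) for _ in range(nb)]
        a, loci = _vec_sample("A", va)
        b, _ = _vec_sample("B", vb)

        def sq(u, v):
            return sum((x - y) ** 2 for x, y in zip(u, v))

        def ident(u, v):
            return 0.0 if u == v else 1.0

        for name, dist in (("repeat_ssd", sq), ("identity", ident)):
            metric = HaplotypeMetric(name=name, loci=loci)
            expected = brute_force_phi([list(va), list(vb)], dist)
            assert math.isclose(
                amova_two_pop(a, b, metric).phi, expected, abs_tol=1e-9
            )

    def test_identity_phi_equals_frequency_based_form(self, rng):
        # with 0/1 distances the pair sums reduce to haplotype counts:
        # sum_{i<j in g} d_ij = (n_g^2 - sum_k c_gk^2) / 2
        va = [tuple(rng.integers(0, 3, size=2)) for _ in range(10)]
        vb = [tuple(rng.integers(0, 3, size=2)) for _ in range(12)]
        loci = ("DYS19", "DYS390")
        a, _ = _vec_sample("A", [v + (0, 0) for v in va])
        b, _ = _vec_sample("B", [v + (0, 0) for v in vb])
        metric = HaplotypeMetric(name="identity")

        def counts(vs):
            c = {}
            for v in vs:
                c[v] = c.get(v, 0) + 1
            return c

        N = len(va) + len(vb)
        ca, cb = counts(va), counts(vb)
        call = counts(va + vb)
        sw = sum(
            (len(vs) ** 2 - sum(x * x for x in c.values())) / (2 * len(vs))
            for vs, c in ((va, ca), (vb, cb))
        )
        stot = (N**2 - sum(x * x for x in call.values())) / (2 * N)
        s2w = sw / (N - 2)
        n0 = N - (len(va) ** 2 + len(vb) ** 2) / N
        s2a = ((stot - sw) - s2w) / n0
        assert math.isclose(
            amova_two_pop(a, b, metric).phi, s2a / (s2a + s2w), abs_tol=1e-12
        )

    def test_rst_invariant_to_allele_translation(self, rng):
        va = [tuple(rng.integers(0, 4, size=4)) for _ in range(8)]
        vb = [tuple(rng.integers(0, 4, size=4)) for _ in range(9)]
        a, loci = _vec_sample("A", va)
        b, _ = _vec_sample("B", vb)
        metric = HaplotypeMetric(name="repeat_ssd", loci=loci)
        shift = [tuple(v[0] + 3 if i == 0 else v[i] for i in range(4)) for v in va]
        shift_b = [tuple(v[0] + 3 if i == 0 else v[i] for i in range(4)) for v in vb]
        a2, _ = _vec_sample("A", shift)
        b2, _ = _vec_sample("B", shift_b)
        assert math.isclose(
            amova_two_pop(a, b, metric).phi,
            amova_two_pop(a2, b2, metric).phi,
            rel_tol=1e-12,
        )

    def test_ssd_decomposition_consistent(self, small_cohort):
        res = amova_two_pop(small_cohort[0], small_cohort[1], REPEAT_SSD)
        assert math.isclose(
            res.ssd_total, res.ssd_within + res.ssd_among, rel_tol=1e-9
        )
        assert res.sigma2_within >= 0
        assert res.phi <= 1


class TestPairwiseMatrix:
    def test_identical_fixed_samples_zero_matrix(self):
        a = make_sample("A", [make_hap(f"a{i}") for i in range(6)])
        b = make_sample("B", [make_hap(f"b{i}") for i in range(6)])
        dm = pairwise_matrix([a, b], REPEAT_SSD)
        assert np.allclose(dm.values, 0.0)

    def test_four_samples_shape_and_symmetry(self, rng):
        samples = []
        for label in "ABCD":
            vs = [tuple(rng.integers(0, 4, size=4)) for _ in range(6)]
            samples.append(_vec_sample(label, vs)[0])
        dm = pairwise_matrix(samples, REPEAT_SSD)
        assert dm.values.shape == (4, 4)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)

    def test_label_permutation_permutes_matrix(self, rng):
        samples = []
        for label in "ABC":
            vs = [tuple(rng.integers(0, 4, size=4)) for _ in range(6)]
            samples.append(_vec_sample(label, vs)[0])
        dm = pairwise_matrix(samples, REPEAT_SSD)
        dm2 = pairwise_matrix(samples[::-1], REPEAT_SSD)
        for x in "ABC":
            for y in "ABC":
                if x != y:
                    assert math.isclose(dm.value(x, y), dm2.value(x, y), rel_tol=1e-12)


class TestPermutation:
    def test_same_seed_same_pvalue(self, small_cohort):
        a, b = small_cohort
        p1 = permutation_pvalue(a, b, REPEAT_SSD, n_perm=99, seed=5)
        p2 = permutation_pvalue(a, b, REPEAT_SSD, n_perm=99, seed=5)
        assert p1 == p2

    def test_fixed_distinct_haplotypes_significant(self):
        a = make_sample("A", [make_hap(f"a{i}") for i in range(10)])
        b = make_sample("B", [make_hap(f"b{i}", DYS390=27.0) for i in range(10)])
        p = permutation_pvalue(a, b, REPEAT_SSD, n_perm=999, seed=1)
        assert p <= 0.01

    def test_null_pvalues_roughly_uniform(self):
        # exchangeable pooled data: KS distance to U(0,1) stays small;
        # 8 per group keeps the exact permutation distribution fine
        # enough for the continuous-uniform comparison to be meaningful
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(200):
            vs = [tuple(rng.integers(0, 6, size=4)) for _ in range(16)]
            a, loci = _vec_sample("A", vs[:8])
            b, _ = _vec_sample("B", vs[8:])
            metric = HaplotypeMetric(name="repeat_ssd", loci=loci)
            pvals.append(
                permutation_pvalue(a, b, metric, n_perm=99,
                                   seed=int(rng.integers(2**31)))
            )
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").statistic < 0.1

    def test_metric_aliases(self):
        assert metric_by_name("rst").name == "repeat_ssd"
        assert metric_by_name("Fst").name == "identity"
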