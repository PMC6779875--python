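"""Statistical layer: exact tests vs brute-force oracles, regression
behaviour and feature counting."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_gene
from xnddcnv.annotate import GeneIndex, annotate_gene_impact
from xnddcnv.burden import (SampleBurdenFeatures, StatError, bh_fdr,
                            burden_features, fisher_enrichment, gig_analysis,
                            logistic_burden, rank_burden_test)
from xnddcnv.callset import StringentCnv
from xnddcnv.genome import GenomicInterval
from xnddcnv.io_formats import FEMALE, MALE, PedigreeRecord


# ---------------------------------------------------------------- oracles

def hypergeom_pmf(a, r1, r2, c1):
    """P(top-left cell = a) under fixed margins (central hypergeometric)."""
    n = r1 + r2
    return (math.comb(r1, a) * math.comb(r2, c1 - a)) / math.comb(n, c1)


def fisher_p_oracle(table):
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = hypergeom_pmf(a, r1, r2, c1)
    return sum(hypergeom_pmf(k, r1, r2, c1)
               for k in range(lo, hi + 1)
               if hypergeom_pmf(k, r1, r2, c1) <= p_obs * (1 + 1e-9))


def mwu_exact_oracle(a, b):
    """Two-sided p by full enumeration of group assignments."""
    pooled = list(a) + list(b)
    n = len(a)
    def ustat(idx):
        grp = [pooled[i] for i in idx]
        other = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = 0.0
        for x in grp:
            for y in other:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u
    u_obs = ustat(range(n))
    mean_u = n * (len(pooled) - n) / 2
    dev_obs = abs(u_obs - mean_u)
    total = more = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(ustat(idx) - mean_u) >= dev_obs - 1e-9:
            more += 1
    return more / total


def bh_oracle(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


# ---------------------------------------------------------------- tests

class TestFisher:
    def test_example_table_matches_oracle(self):
        res = fisher_enrichment([[10, 10], [5, 20]])
        assert res.p_value == pytest.approx(fisher_p_oracle([[10, 10], [5, 20]]))
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_zero_margin(self):
        res = fisher_enrichment([[0, 5], [0, 7]])
        assert res.p_value == 1.0
        assert math.isnan(res.estimate)

    def test_simultaneous_transpose_invariance(self):
        t = [[3, 9], [7, 2]]
        swapped = [[2, 7], [9, 3]]  # swap rows AND columns
        assert fisher_enrichment(t).p_value == \
            pytest.approx(fisher_enrichment(swapped).p_value)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            t = rng.integers(0, 12, size=(2, 2)).tolist()
            if min(sum(t[0]), sum(t[1]), t[0][0] + t[1][0], t[0][1] + t[1][1]) == 0:
                continue
            assert fisher_enrichment(t).p_value == \
                pytest.approx(fisher_p_oracle(t), rel=1e-9)


class TestRankTest:
    def test_identical_groups_p_one(self):
        res = rank_burden_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)

    def test_u_zero_exact_p(self):
        res = rank_burden_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2/20 configurations

    @pytest.mark.parametrize("na,nb", [(3, 4), (5, 5), (4, 8)])
    def test_exact_p_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(size=na).tolist()
        b = rng.normal(0.5, size=nb).tolist()
        res = rank_burden_test(a, b)
        assert res.p_value == pytest.approx(mwu_exact_oracle(a, b), abs=1e-9)

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(0)
        rejections = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            hits = 0
            for _ in range(60):
                a = rng.normal(size=30)
                b = rng.normal(shift, size=30)
                if rank_burden_test(a, b).p_value < 0.05:
                    hits += 1
            rejections.append(hits)
        assert rejections[0] < rejections[-1]
        assert rejections == sorted(rejections)

    def test_empty_group_rejected(self):
        with pytest.raises(StatError):
            rank_burden_test([], [1, 2])


class TestBhFdr:
    def test_textbook_vector(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    @pytest.mark.parametrize("seed", range(4))
    def test_random_vectors_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        assert bh_fdr(p) == pytest.approx(bh_oracle(p))
        q = bh_fdr(p)
        assert np.all(q >= p) and np.all(q <= 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatError):
            bh_fdr([0.5, 1.5])


def _sim_features(rng, n=300, beta=0.0):
    feats = []
    for i in range(n):
        x = rng.poisson(1.2)
        logit = -0.2 + beta * x + 0.1 * rng.normal()
        case = rng.random() < 1 / (1 + np.exp(-logit))
        feats.append(SampleBurdenFeatures(
            sample_id=str(i), is_case=case, sex=MALE if i % 2 else FEMALE,
            pc1=rng.normal(), pc2=rng.normal(), pc3=rng.normal(),
            total_rare_cnv_length=float(rng.normal(200_000, 20_000)),
            protein_coding_del=int(x)))
    return feats


class TestLogistic:
    def test_affine_covariate_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        feats = _sim_features(rng, n=500, beta=0.4)
        base = logistic_burden(feats, "protein_coding_del")
        for f in feats:
            f.total_rare_cnv_length = f.total_rare_cnv_length * 1e-6 + 3.0
            f.pc1 = f.pc1 * 10 - 2
        rescaled = logistic_burden(feats, "protein_coding_del")
        assert rescaled.estimate == pytest.approx(base.estimate, abs=1e-6)
        assert rescaled.p_value == pytest.approx(base.p_value, abs=1e-8)

    def test_constant_predictor_is_singular(self):
        rng = np.random.default_rng(0)
        feats = _sim_features(rng)
        for f in feats:
            f.protein_coding_del = 0
        with pytest.raises(StatError, match="singular"):
            logistic_burden(feats, "protein_coding_del")

    def test_collinear_design_reported(self):
        rng = np.random.default_rng(0)
        feats = _sim_features(rng)
        for f in feats:
            f.pc2 = f.pc1  # exact collinearity
        with pytest.raises(StatError, match="collinear"):
            logistic_burden(feats, "protein_coding_del")

    def test_perfect_separation_detected(self):
        feats = []
        for i in range(60):
            case = i < 30
            feats.append(SampleBurdenFeatures(
                sample_id=str(i), is_case=case, sex=MALE,
                pc1=float(i % 7), pc2=float(i % 5), pc3=float(i % 3),
                total_rare_cnv_length=float(i),
                protein_coding_del=10 if case else 0))
        with pytest.raises(StatError):
            logistic_burden(feats, "protein_coding_del")

    def test_one_outcome_class_rejected(self):
        rng = np.random.default_rng(0)
        feats = _sim_features(rng)
        for f in feats:
            f.is_case = True
        with pytest.raises(StatError):
            logistic_burden(feats, "protein_coding_del")

    def test_multivariate_returns_per_predictor(self):
        rng = np.random.default_rng(5)
        feats = _sim_features(rng, n=500, beta=0.4)
        for f in feats:
            f.lncrna_del = int(rng.poisson(0.7))
        results = logistic_burden(feats, ["protein_coding_del", "lncrna_del"])
        assert len(results) == 2
        assert all("multivariate" in r.name for r in results)


class TestBurdenFeatures:
    def test_counts_split_by_class_and_brain(self):
        genes = GeneIndex([
            make_gene("BRAINY", "1", 1_000_000, 1_100_000, brain_expressed=True,
                      pli=0.9),
            make_gene("PLAIN", "1", 1_050_000, 1_250_000, brain_expressed=False),
            make_gene("LNC", "1", 2_000_000, 2_050_000, coding=False,
                      brain_expressed=True, is_lncrna=True),
        ])
        ped = [
            PedigreeRecord("F", "CASE", "FA", "MO", MALE, "case", "ASD"),
            PedigreeRecord("F", "FA", None, None, MALE, "unaffected"),
            PedigreeRecord("F", "MO", None, None, FEMALE, "unaffected"),
        ]
        iv = GenomicInterval("1", 1_040_000, 1_160_000)  # hits both coding genes
        cnv = StringentCnv("CASE", iv, iv, "DEL", frozenset("ab"), 10)
        cnv.annotations["impacts"] = annotate_gene_impact(iv, "DEL", genes)
        lnc_iv = GenomicInterval("1", 2_000_000, 2_050_000)
        lnc = StringentCnv("CASE", lnc_iv, lnc_iv, "DUP", frozenset("ab"), 10)
        lnc.annotations["impacts"] = annotate_gene_impact(lnc_iv, "DUP", genes)
        feats = {f.sample_id: f for f in burden_features([cnv, lnc], ped, genes)}
        case = feats["CASE"]
        assert case.is_case
        assert case.protein_coding_del == 2
        assert case.brain_protein_coding_del == 1
        assert case.lncrna_dup == 1 and case.brain_lncrna_dup == 1
        assert case.n_rare_cnvs == 2
        assert not feats["FA"].is_case  # parents are the controls

    def test_zero_cnv_sample_all_zero(self):
        ped = [PedigreeRecord("F", "CASE", None, None, MALE, "case", "ASD")]
        genes = GeneIndex([])
        [f] = burden_features([], ped, genes)
        assert f.n_rare_cnvs == 0 and f.protein_coding_del == 0

    def test_missing_covariates_reported(self):
        ped = [PedigreeRecord("F", "CASE", None, None, MALE, "case", "ASD")]
        with pytest.raises(StatError, match="CASE"):
            burden_features([], ped, GeneIndex([]), covariates={})


class TestGigAnalysis:
    def _features(self, rng, n=400, multiplier=1.0):
        feats = []
        for i in range(n):
            gig = rng.random() < 0.15
            rate = 2.0 * (multiplier if gig else 1.0)
            k = rng.poisson(rate)
            feats.append(SampleBurdenFeatures(
                sample_id=str(i), is_case=True, sex=MALE,
                n_rare_cnvs=k + int(gig), n_rare_cnvs_excl_gig=k,
                total_rare_cnv_length=float(k) * 100_000,
                total_length_excl_gig=float(k) * 100_000,
                has_gig_cnv=gig, has_ndd_cnv=rng.random() < 0.1))
        return feats

    def test_no_gig_carriers_is_degenerate(self):
        rng = np.random.default_rng(0)
        feats = self._features(rng)
        for f in feats:
            f.has_gig_cnv = False
        with pytest.raises(StatError):
            gig_analysis(feats)

    def test_implanted_burden_effect_detected(self):
        rng = np.random.default_rng(1)
        feats = self._features(rng, n=2000, multiplier=1.5)
        results = {r.name: r for r in gig_analysis(feats)}
        assert results["gig_burden_count_cases_exclGIG"].p_value < 0.01

    def test_null_roughly_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 40
        for _ in range(reps):
            feats = self._features(rng, n=300, multiplier=1.0)
            res = {r.name: r for r in gig_analysis(feats)}
            if res["gig_burden_count_cases_exclGIG"].p_value < 0.05:
                rejections += 1
        assert rejections <= 8  # ~binomial(40, 0.05) upper tail
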