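"""Statistical layer: burden regressions, rank tests, exact enrichment, FDR.

The global burden model is a logistic regression of case status on a
gene-hit count (deletions or duplications of protein-coding CDS or lncRNA
exons, optionally restricted to brain-expressed elements), adjusted for sex,
the first three ancestry principal components and the total length of rare
CNVs per sample. Controls are parents of cases. Group comparisons of CNV
counts and cumulative lengths use the Mann-Whitney U test; carrier
enrichment uses Fisher's exact test with a conditional-MLE odds ratio and
exact CI; multiplicity control is Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .annotate import CDS_DISRUPTED, EXON_ONLY, GeneIndex
from .callset import StringentCnv
from .inheritance import DE_NOVO
from .io_formats import MALE, PedigreeRecord


class StatError(ValueError):
    """Degenerate statistical input (separation, singular design, empty group)."""


@dataclass
class TestResult:
    name: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    fdr_q: Optional[float] = None
    note: str = ""

    @property
    def nearly_significant(self) -> bool:
        """The reporting convention flags 0.05 < p < 0.1 as nearly significant."""
        return 0.05 < self.p_value < 0.1


@dataclass
class SampleBurdenFeatures:
    sample_id: str
    is_case: bool
    sex: str
    pc1: float = 0.0
    pc2: float = 0.0
    pc3: float = 0.0
    total_rare_cnv_length: float = 0.0
    n_rare_cnvs: int = 0
    protein_coding_del: int = 0
    protein_coding_dup: int = 0
    lncrna_del: int = 0
    lncrna_dup: int = 0
    brain_protein_coding_del: int = 0
    brain_protein_coding_dup: int = 0
    brain_lncrna_del: int = 0
    brain_lncrna_dup: int = 0
    has_gig_cnv: bool = False
    has_ndd_cnv: bool = False
    has_de_novo_gig_cnv: bool = False
    has_aneuploidy: bool = False
    gig_ndd_same_cnv: bool = False
    parent_has_gig_cnv: Optional[bool] = None
    n_rare_cnvs_excl_gig: int = 0
    total_length_excl_gig: float = 0.0


def burden_features(rare_cnvs: Iterable[StringentCnv],
                    pedigree: Iterable[PedigreeRecord],
                    genes: GeneIndex,
                    covariates: Mapping[str, Mapping[str, float]] | None = None,
                    ) -> list[SampleBurdenFeatures]:
    """One feature row per case and per parent-of-a-case (the controls).

    Gene-hit counting: CDS overlap for protein-coding genes, any-exon
    overlap for lncRNAs, split by DEL/DUP with brain-expressed sub-counts.
    ``covariates`` maps sample -> {pc1, pc2, pc3}; a sample included in the
    model without covariates is an error reported by name.
    """
    peds = list(pedigree)
    by_id = {p.sample_id: p for p in peds}
    cases = [p for p in peds if p.affected == "case"]
    parent_ids = {pid for p in cases for pid in (p.father_id, p.mother_id) if pid}
    included = [p.sample_id for p in cases] + sorted(
        pid for pid in parent_ids if pid in by_id and by_id[pid].affected != "case"
    )
    if covariates is not None:
        missing = [s for s in included if s not in covariates]
        if missing:
            raise StatError(f"missing covariates for samples: {missing[:10]}")

    cnvs_by_sample: dict[str, list[StringentCnv]] = {}
    for c in rare_cnvs:
        cnvs_by_sample.setdefault(c.sample_id, []).append(c)

    feats = []
    for sid in included:
        ped = by_id[sid]
        f = SampleBurdenFeatures(
            sample_id=sid,
            is_case=(ped.affected == "case"),
            sex=ped.sex,
            **(dict(zip(("pc1", "pc2", "pc3"),
                        (covariates[sid].get("pc1", 0.0),
                         covariates[sid].get("pc2", 0.0),
                         covariates[sid].get("pc3", 0.0))))
               if covariates else {}),
        )
        for cnv in cnvs_by_sample.get(sid, ()):  # one row per rare CNV
            f.n_rare_cnvs += 1
            f.total_rare_cnv_length += cnv.size_bp
            is_del = cnv.cnv_type == "DEL"
            cnv_gig = cnv_ndd = False
            for imp in cnv.annotations.get("impacts", ()):
                gene = genes[imp.gene_id]
                if gene.is_lncrna:
                    if imp.impact_class in (CDS_DISRUPTED, EXON_ONLY):
                        if is_del:
                            f.lncrna_del += 1
                            f.brain_lncrna_del += gene.brain_expressed
                        else:
                            f.lncrna_dup += 1
                            f.brain_lncrna_dup += gene.brain_expressed
                elif imp.impact_class == CDS_DISRUPTED:
                    if is_del:
                        f.protein_coding_del += 1
                        f.brain_protein_coding_del += gene.brain_expressed
                    else:
                        f.protein_coding_dup += 1
                        f.brain_protein_coding_dup += gene.brain_expressed
                    if gene.is_gig:
                        cnv_gig = True
                    if gene.is_ndd:
                        cnv_ndd = True
            if cnv_gig:
                f.has_gig_cnv = True
                origin = cnv.annotations.get("origin")
                if origin is not None and origin.origin == DE_NOVO:
                    f.has_de_novo_gig_cnv = True
            else:
                f.n_rare_cnvs_excl_gig += 1
                f.total_length_excl_gig += cnv.size_bp
            if cnv_ndd:
                f.has_ndd_cnv = True
            if cnv_gig and cnv_ndd:
                f.gig_ndd_same_cnv = True
            if cnv.annotations.get("aneuploidy") is not None:
                f.has_aneuploidy = True
        feats.append(f)

    # parent-carrier flag for cases
    gig_by_sample = {f.sample_id: f.has_gig_cnv for f in feats}
    for f in feats:
        ped = by_id[f.sample_id]
        if f.is_case and ped.father_id in gig_by_sample and ped.mother_id in gig_by_sample:
            f.parent_has_gig_cnv = (gig_by_sample[ped.father_id]
                                    or gig_by_sample[ped.mother_id])
    return feats


def _design(features: Sequence[SampleBurdenFeatures],
            predictors: Sequence[str]) -> tuple[np.ndarray, pd.DataFrame]:
    y = np.array([int(f.is_case) for f in features])
    X = pd.DataFrame({
        **{p: [getattr(f, p) for f in features] for p in predictors},
        "sex_male": [int(f.sex == MALE) for f in features],
        "pc1": [f.pc1 for f in features],
        "pc2": [f.pc2 for f in features],
        "pc3": [f.pc3 for f in features],
        "total_rare_cnv_length": [f.total_rare_cnv_length for f in features],
    })
    return y, sm.add_constant(X, has_constant="add")


def logistic_burden(features: Sequence[SampleBurdenFeatures],
                    predictor: str | Sequence[str],
                    multivariate: bool = False) -> TestResult | list[TestResult]:
    """Wald estimate/CI/p for the burden predictor(s) in the logistic model.

    ``multivariate=True`` (or a list of predictors) fits them jointly and
    returns one result per predictor.
    """
    predictors = [predictor] if isinstance(predictor, str) else list(predictor)
    if len(predictors) > 1:
        multivariate = True
    y, X = _design(features, predictors)
    if len(np.unique(y)) < 2:
        raise StatError("both outcome classes must be present")
    # drop constant-zero or collinear columns deliberately -> error, not silent
    for col in predictors:
        if X[col].nunique() <= 1:
            raise StatError(f"singular design: predictor {col!r} is constant")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = X.loc[:, X.nunique() > 1].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise StatError(f"singular design: collinear columns {worst}")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            raise StatError(
                f"logistic fit failed ({exc}); consider an exact/penalized "
                "alternative"
            ) from exc
    if not np.isfinite(fit.bse[predictors]).all() or (fit.bse[predictors] > 1e3).any():
        raise StatError("perfect separation detected; use an exact alternative")
    results = []
    ci = fit.conf_int()
    for p in predictors:
        results.append(TestResult(
            name=f"logistic_burden[{p}]{'(multivariate)' if multivariate else ''}",
            estimate=float(fit.params[p]),
            ci_low=float(ci.loc[p, 0]),
            ci_high=float(ci.loc[p, 1]),
            p_value=float(fit.pvalues[p]),
        ))
    return results if multivariate else results[0]


def rank_burden_test(values_a: Sequence[float], values_b: Sequence[float],
                     name: str = "mann_whitney") -> TestResult:
    """Two-sided Mann-Whitney U; exact enumeration when both n <= 8."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise StatError("rank test needs two non-empty groups")
    if a.size <= 8 and b.size <= 8:
        method = "exact"  # scipy falls back to a permutation-exact null
    else:
        method = "asymptotic"  # normal approximation with tie correction
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    shift = float(np.median(a) - np.median(b))
    return TestResult(
        name=name,
        estimate=shift,
        ci_low=float("nan"),
        ci_high=float("nan"),
        p_value=float(min(1.0, res.pvalue)),
        note=f"U={float(res.statistic):g};method={method}",
    )


def fisher_enrichment(table: Sequence[Sequence[int]],
                      name: str = "fisher_exact") -> TestResult:
    """Two-sided Fisher exact test with conditional-MLE OR and exact 95% CI.

    A zero margin yields p = 1 with the odds ratio flagged undefined.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise StatError("fisher_enrichment needs a non-negative 2x2 table")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return TestResult(name=name, estimate=float("nan"),
                          ci_low=float("nan"), ci_high=float("nan"),
                          p_value=1.0, note="zero margin; OR undefined")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    orr = stats.contingency.odds_ratio(t, kind="conditional")
    ci = orr.confidence_interval(confidence_level=0.95)
    return TestResult(
        name=name,
        estimate=float(orr.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(p),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def attach_fdr(results: list[TestResult]) -> list[TestResult]:
    """BH-correct a family of univariate burden tests together."""
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.fdr_q = float(q)
    return results


def gig_analysis(features: Sequence[SampleBurdenFeatures]) -> list[TestResult]:
    """Genomic-instability-gene (GIG) CNV burden analyses.

    (i) case-control comparison of GIG-CNV carriage; (ii) rank tests of CNV
    count and cumulative length, GIG carriers vs non-carriers among cases,
    with the GIG-CNVs themselves excluded from the burden; (iii) enrichment
    of NDD-CNV carriage among GIG-CNV carriers (cases), with a sensitivity
    rerun excluding aneuploid samples and samples where one CNV supplies
    both flags; (iv) burden in cases whose parents carry a GIG-CNV,
    excluding cases with de novo GIG-CNVs.
    """
    feats = list(features)
    cases = [f for f in feats if f.is_case]
    controls = [f for f in feats if not f.is_case]
    gig_cases = [f for f in cases if f.has_gig_cnv]
    non_gig_cases = [f for f in cases if not f.has_gig_cnv]
    if not gig_cases or not non_gig_cases:
        raise StatError("need GIG carriers and non-carriers among cases")
    results: list[TestResult] = []

    # (i) carriage proportion, cases vs controls
    if controls:
        tab = [[sum(f.has_gig_cnv for f in cases),
                sum(not f.has_gig_cnv for f in cases)],
               [sum(f.has_gig_cnv for f in controls),
                sum(not f.has_gig_cnv for f in controls)]]
        results.append(fisher_enrichment(tab, name="gig_carriage_case_control"))

    # (ii) burden among cases, GIG-CNVs excluded from the measure
    results.append(rank_burden_test(
        [f.n_rare_cnvs_excl_gig for f in gig_cases],
        [f.n_rare_cnvs_excl_gig for f in non_gig_cases],
        name="gig_burden_count_cases_exclGIG"))
    results.append(rank_burden_test(
        [f.total_length_excl_gig for f in gig_cases],
        [f.total_length_excl_gig for f in non_gig_cases],
        name="gig_burden_length_cases_exclGIG"))

    # (iii) NDD-CNV x GIG-CNV enrichment among cases
    tab = [[sum(f.has_ndd_cnv for f in gig_cases),
            sum(not f.has_ndd_cnv for f in gig_cases)],
           [sum(f.has_ndd_cnv for f in non_gig_cases),
            sum(not f.has_ndd_cnv for f in non_gig_cases)]]
    results.append(fisher_enrichment(tab, name="gig_ndd_enrichment"))
    strict = [f for f in cases if not f.has_aneuploidy and not f.gig_ndd_same_cnv]
    sg = [f for f in strict if f.has_gig_cnv]
    sn = [f for f in strict if not f.has_gig_cnv]
    if sg and sn:
        tab = [[sum(f.has_ndd_cnv for f in sg), sum(not f.has_ndd_cnv for f in sg)],
               [sum(f.has_ndd_cnv for f in sn), sum(not f.has_ndd_cnv for f in sn)]]
        results.append(fisher_enrichment(tab, name="gig_ndd_enrichment_strict"))

    # (iv) parental GIG carriage vs case burden, de novo GIG cases excluded
    informative = [f for f in cases
                   if f.parent_has_gig_cnv is not None and not f.has_de_novo_gig_cnv]
    with_p = [f for f in informative if f.parent_has_gig_cnv]
    without_p = [f for f in informative if not f.parent_has_gig_cnv]
    if with_p and without_p:
        results.append(rank_burden_test(
            [f.n_rare_cnvs for f in with_p],
            [f.n_rare_cnvs for f in without_p],
            name="parent_gig_burden_count"))
        results.append(rank_burden_test(
            [f.n_rare_cnvs_excl_gig for f in with_p],
            [f.n_rare_cnvs_excl_gig for f in without_p],
            name="parent_gig_burden_count_exclGIG"))
    return results
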