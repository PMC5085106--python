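"""Single-locus association statistics.

Covers Hardy-Weinberg goodness of fit, 2x2 odds ratios with Woolf
confidence intervals and uncorrected Pearson chi-square p-values, the four
genetic-model encodings, covariate-adjusted odds ratios via an in-house
iteratively reweighted least squares (IRLS) logistic fit, the three-way
case/control comparison design, and subgroup stratification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConvergenceError,
    SeparationError,
    ValidationError,
)
from .genotype_data import MISSING, CohortDataset, dose_matrix

MODELS = ("allelic", "codominant", "dominant", "recessive")

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class GenotypeCounts(NamedTuple):
    """Counts of dose-0/1/2 carriers within one group."""

    n0: int
    n1: int
    n2: int

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b exposed/unexposed cases, c/d exposed/unexposed controls."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or not math.isfinite(cell):
                raise ValidationError(f"negative or non-finite cell count: {cell}")

    def swapped(self) -> "ContingencyTable":
        """Exchange case and control rows (inverts the odds ratio)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    """One table row: OR with 95% CI, p-value, model, adjustment, effective N."""

    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str
    adjusted_for: tuple[str, ...] = ()
    effective_n: int = 0
    term: str = ""
    degenerate: bool = False
    note: str = ""

    def __post_init__(self):
        if not self.degenerate:
            if not (self.ci_low <= self.or_point <= self.ci_high):
                raise ValidationError("CI must bracket the point estimate")
            if not (0.0 <= self.p_value <= 1.0) and not math.isnan(self.p_value):
                raise ValidationError("p-value outside [0, 1]")


class HweResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonDesign:
    """Pair of disjoint subject groups; group1 plays the 'case' role."""

    group1: str
    group2: str

    _VALID = ("all-cases", "hereditary-cases", "non-hereditary-cases", "controls")

    def __post_init__(self):
        for g in (self.group1, self.group2):
            if g not in self._VALID:
                raise ValidationError(f"unknown group {g!r}")
        if self.group1 == self.group2:
            raise ValidationError("comparison groups must be disjoint")
        if {self.group1, self.group2} == {"all-cases", "hereditary-cases"} or {
            self.group1,
            self.group2,
        } == {"all-cases", "non-hereditary-cases"}:
            raise ValidationError("comparison groups overlap")

    def masks(self, ds: CohortDataset) -> tuple[np.ndarray, np.ndarray]:
        return ds.status_mask(self.group1), ds.status_mask(self.group2)


#: The three comparison columns of the single-locus analysis.
STANDARD_DESIGNS: dict[str, ComparisonDesign] = {
    "cases-vs-controls": ComparisonDesign("all-cases", "controls"),
    "casesA-vs-controls": ComparisonDesign("hereditary-cases", "controls"),
    "casesA-vs-casesB": ComparisonDesign("hereditary-cases", "non-hereditary-cases"),
}


# ---------------------------------------------------------------------------
# Hardy-Weinberg

def hwe_chi_square(g: GenotypeCounts) -> HweResult:
    """1-df chi-square goodness of fit of genotype counts to HWE proportions.

    Expected counts come from the sample allele frequency; a monomorphic
    sample returns statistic 0 with the degenerate flag set.
    """
    g = GenotypeCounts(*g)
    n = g.total
    if n < 1:
        raise ValidationError("need at least one genotyped subject")
    p = (2 * g.n0 + g.n1) / (2 * n)  # frequency of the allele homozygous in n0
    if p in (0.0, 1.0):
        return HweResult(0.0, 1.0, degenerate=True)
    expected = np.array([p * p * n, 2 * p * (1 - p) * n, (1 - p) * (1 - p) * n])
    observed = np.array(g, dtype=float)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    return HweResult(statistic, float(stats.chi2.sf(statistic, df=1)), False)


# ---------------------------------------------------------------------------
# 2x2 odds ratios

def pearson_chi2(t: ContingencyTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (1 df) and its upper-tail p-value.

    Returns (nan, nan) when a margin is empty and the statistic is undefined.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return (float("nan"), float("nan"))
    statistic, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(statistic), float(p)


def odds_ratio(t: ContingencyTable, correction: str = "none") -> AssociationResult:
    """Cross-product odds ratio with Woolf 95% CI and Pearson chi-square p.

    The p-value always comes from the uncorrected table; ``haldane`` adds 0.5
    to every cell before the point estimate and CI when any cell is zero.
    """
    if correction not in ("none", "haldane"):
        raise ValidationError(f"unknown correction {correction!r}")
    cells = (t.a, t.b, t.c, t.d)
    has_zero = any(c == 0 for c in cells)
    if has_zero and correction == "none":
        raise ValidationError(
            "zero cell in 2x2 table; retry with correction='haldane'"
        )
    _, p = pearson_chi2(t)
    a, b, c, d = ((x + 0.5 for x in cells) if has_zero else cells)
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_point)
    return AssociationResult(
        or_point=or_point,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        p_value=p,
        model="contingency",
        effective_n=int(round(sum(cells))),
        note="haldane" if has_zero else "",
    )


# ---------------------------------------------------------------------------
# Genetic-model encodings

def allelic_counts(g: GenotypeCounts) -> tuple[int, int]:
    """(risk, non-risk) allele counts from genotype counts: each subject
    contributes two alleles."""
    g = GenotypeCounts(*g)
    return (2 * g.n2 + g.n1, 2 * g.n0 + g.n1)


def allelic_table(cases: GenotypeCounts, controls: GenotypeCounts) -> ContingencyTable:
    ra, na = allelic_counts(cases)
    rc, nc = allelic_counts(controls)
    return ContingencyTable(ra, na, rc, nc)


def encode_model(doses: Sequence[int], model: str) -> np.ndarray:
    """Design column(s) for a dose vector under a genetic model.

    allelic -> the dose itself (per-allele trend term); dominant -> carrier
    indicator; recessive -> homozygote indicator; codominant -> two columns
    (dose==1, dose==2) against the dose-0 reference.
    """
    doses = np.asarray(doses, dtype=np.int64)
    if doses.size and (doses.min() < 0 or doses.max() > 2):
        raise ValidationError(
            "doses must be in {0,1,2}; drop MISSING entries before encoding"
        )
    if model == "allelic":
        return doses.reshape(-1, 1).astype(float)
    if model == "dominant":
        return (doses >= 1).astype(float).reshape(-1, 1)
    if model == "recessive":
        return (doses == 2).astype(float).reshape(-1, 1)
    if model == "codominant":
        return np.column_stack([(doses == 1), (doses == 2)]).astype(float)
    raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")


# ---------------------------------------------------------------------------
# In-house logistic regression (IRLS)

SEPARATION_BOUND = 15.0
MAX_ITER = 50
SCORE_TOL = 1e-8


def fit_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = MAX_ITER, tol: float = SCORE_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic fit by IRLS (Newton-Raphson on the score).

    Returns (coefficients, covariance).  Convergence requires the maximum
    absolute score below ``tol``; any coefficient exceeding
    ``SEPARATION_BOUND`` in absolute value aborts with a separation error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    trace = []
    for it in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        trace.append((it, float(np.max(np.abs(score))), beta.copy()))
        if np.max(np.abs(score)) < tol:
            w = mu * (1.0 - mu)
            info = (X * w[:, None]).T @ X
            return beta, np.linalg.inv(info)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix (collinear or degenerate design)"
            )
        beta = beta + delta
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                f"coefficient exceeded {SEPARATION_BOUND} during iteration; "
                "data are (quasi-)separated"
            )
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations", trace=trace
    )


def _design_columns(
    ds: CohortDataset,
    idx: Sequence[int],
    covariates: Sequence[str],
    age_coding: str,
) -> tuple[list[np.ndarray], list[str]]:
    cols, names = [], []
    subs = [ds.subjects[i] for i in idx]
    for cov in covariates:
        if cov == "sex":
            cols.append(np.array([1.0 if s.sex == "M" else 0.0 for s in subs]))
            names.append("sex")
        elif cov == "age":
            if age_coding == "continuous":
                cols.append(np.array([float(s.age) for s in subs]))
            elif age_coding == "banded":
                cols.append(np.array([1.0 if s.age > 40 else 0.0 for s in subs]))
            else:
                raise ValidationError(f"unknown age coding {age_coding!r}")
            names.append("age")
        else:
            raise ValidationError(f"unknown covariate {cov!r}")
    return cols, names


def fit_logistic_or(
    ds: CohortDataset,
    snp: str,
    model: str,
    design: ComparisonDesign | str,
    covariates: Sequence[str] = (),
    age_coding: str = "continuous",
) -> AssociationResult | list[AssociationResult]:
    """Adjusted odds ratio(s) for one SNP via unconditional logistic regression.

    Complete-case on the SNP; OR is exp of the genetic coefficient with a
    Wald 95% CI.  Codominant returns one result per indicator (het, hom).
    """
    if isinstance(design, str):
        design = STANDARD_DESIGNS[design]
    j = ds.snp_index(snp)
    doses = dose_matrix(ds)[:, j]
    m1, m2 = design.masks(ds)
    include = (m1 | m2) & (doses != MISSING)
    idx = np.flatnonzero(include)
    if not (m1 & include).any() or not (m2 & include).any():
        raise ValidationError(
            f"{design.group1} vs {design.group2}: a group is empty after "
            "complete-case filtering"
        )
    y = m1[idx].astype(float)
    genetic = encode_model(doses[idx], model)
    cov_cols, _ = _design_columns(ds, idx, covariates, age_coding)
    X = np.column_stack([np.ones(len(idx)), genetic, *cov_cols])
    beta, cov = fit_logistic(X, y)
    results = []
    term_names = (
        ["het", "hom"] if model == "codominant" else [model]
    )
    for t in range(genetic.shape[1]):
        coef = beta[1 + t]
        se = math.sqrt(cov[1 + t, 1 + t])
        z = coef / se
        results.append(
            AssociationResult(
                or_point=math.exp(coef),
                ci_low=math.exp(coef - Z_95 * se),
                ci_high=math.exp(coef + Z_95 * se),
                p_value=float(2.0 * stats.norm.sf(abs(z))),
                model=model,
                adjusted_for=tuple(covariates),
                effective_n=len(idx),
                term=term_names[t],
            )
        )
    return results if model == "codominant" else results[0]


def run_comparisons(
    ds: CohortDataset,
    snp: str,
    model: str = "allelic",
    covariates: Sequence[str] = ("sex", "age"),
    age_coding: str = "continuous",
) -> dict[str, AssociationResult | list[AssociationResult] | None]:
    """Sex/age-adjusted results for the three standard comparison designs.

    Without any hereditary-background cases only cases-vs-controls is
    computed; the other keys map to None.
    """
    if not ds.status_mask("controls").any():
        raise ValidationError("cohort has no controls")
    out: dict[str, AssociationResult | list[AssociationResult] | None] = {}
    have_hered = ds.status_mask("hereditary-cases").any()
    for name, design in STANDARD_DESIGNS.items():
        if name != "cases-vs-controls" and not have_hered:
            out[name] = None
            continue
        out[name] = fit_logistic_or(
            ds, snp, model, design, covariates, age_coding
        )
    return out


# ---------------------------------------------------------------------------
# Subgroup stratification

SUBGROUP_FACTORS = ("sex", "age-band", "location", "lauren")

#: Adjustment convention: stratify by sex -> adjust age only, by age -> sex
#: only, by tumour location or pathology -> both.
_FACTOR_COVARIATES = {
    "sex": ("age",),
    "age-band": ("sex",),
    "location": ("sex", "age"),
    "lauren": ("sex", "age"),
}


def _factor_levels(factor: str) -> list[str]:
    return {
        "sex": ["M", "F"],
        "age-band": ["<=40", ">40"],
        "location": ["noncardia", "cardia"],
        "lauren": ["diffuse", "intestinal", "mixed"],
    }[factor]


def _level_mask(ds: CohortDataset, factor: str, level: str) -> np.ndarray:
    if factor == "sex":
        return np.array([s.sex == level for s in ds.subjects])
    if factor == "age-band":
        if level == "<=40":
            return np.array([s.age <= 40 for s in ds.subjects])
        return np.array([s.age > 40 for s in ds.subjects])
    if factor == "location":
        return np.array([s.location == level for s in ds.subjects])
    if factor == "lauren":
        return np.array([s.lauren == level for s in ds.subjects])
    raise ValidationError(f"unknown factor {factor!r}")


def subgroup_analysis(
    ds: CohortDataset,
    snp: str,
    factor: str,
    design: ComparisonDesign | str = "casesA-vs-controls",
    model: str = "allelic",
    age_coding: str = "continuous",
) -> list[tuple[str, AssociationResult]]:
    """One adjusted result per factor level.

    Sex and age stratify both groups; tumour location and Lauren type are
    case-only attributes, so those levels restrict cases and compare against
    all controls.  A level whose fit degenerates (separation, no dose
    variation) yields a flagged placeholder result instead of an estimate.
    """
    if factor not in SUBGROUP_FACTORS:
        raise ValidationError(
            f"unknown factor {factor!r}; choose from {SUBGROUP_FACTORS}"
        )
    if isinstance(design, str):
        design = STANDARD_DESIGNS[design]
    covariates = _FACTOR_COVARIATES[factor]
    results = []
    control_like = ds.status_mask(design.group2)
    for level in _factor_levels(factor):
        lm = _level_mask(ds, factor, level)
        if factor in ("location", "lauren"):
            keep = lm | control_like  # stratify cases only
        else:
            keep = lm
        sub = ds.subset(keep)
        try:
            res = fit_logistic_or(
                ds=sub,
                snp=snp,
                model=model,
                design=design,
                covariates=covariates,
                age_coding=age_coding,
            )
        except (SeparationError, ValidationError, ConvergenceError) as exc:
            res = AssociationResult(
                or_point=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                p_value=float("nan"),
                model=model,
                adjusted_for=tuple(covariates),
                effective_n=int(keep.sum()),
                degenerate=True,
                note=str(exc),
            )
        if isinstance(res, list):  # codominant: report the hom term
            res = res[-1]
        results.append((level, res))
    return results
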