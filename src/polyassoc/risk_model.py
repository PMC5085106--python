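"""Multiplicative polygenic risk model.

Per-locus log-risk variance contributions, fraction of familial genetic
risk explained, log-normal risk-percentile ratios, and screening-benefit
arithmetic.  Conventions: relative risk is mean-one normalized (log-risk
mean -V/2), total polygenic variance is anchored to the familial relative
risk via V = 2 ln(lambda), and per-allele odds ratios are accepted as
relative-risk approximations (flagged when any OR exceeds 3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from scipy import integrate, stats

from .errors import ValidationError


@dataclass(frozen=True)
class LocusEffect:
    rs_id: str
    p_risk: float
    rr_per_allele: float

    def __post_init__(self):
        if not 0.0 <= self.p_risk <= 1.0:
            raise ValidationError(f"{self.rs_id}: p_risk {self.p_risk} outside [0,1]")
        if not (self.rr_per_allele > 0 and math.isfinite(self.rr_per_allele)):
            raise ValidationError(
                f"{self.rs_id}: per-allele relative risk must be finite and > 0"
            )


@dataclass(frozen=True)
class PolygenicModelSpec:
    loci: tuple[LocusEffect, ...]
    lambda_familial: float
    screening_reduction: float = 0.40

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))
        if not 0.0 <= self.screening_reduction <= 1.0:
            raise ValidationError("screening_reduction outside [0,1]")


class ScreeningBenefit(NamedTuple):
    screened_share: float  # share of population screened (= top_fraction)
    case_share: float  # share of cases arising in the screened group
    risk_averted: float  # absolute population risk averted


def locus_variance(e: LocusEffect) -> float:
    """Log relative-risk variance contributed by one locus.

    Under HWE the risk-allele count is Binomial(2, p) and the locus log
    relative risk is (ln rr) * dose, giving variance 2 p (1-p) (ln rr)^2.
    """
    return 2.0 * e.p_risk * (1.0 - e.p_risk) * math.log(e.rr_per_allele) ** 2


def total_variance(lambda_familial: float) -> float:
    """Total polygenic log-risk variance implied by the familial relative
    risk: first-degree relatives share half the log-risk variance, so
    V = 2 ln(lambda)."""
    if lambda_familial <= 1.0:
        raise ValidationError(
            "lambda_familial must exceed 1 (no familial excess to apportion)"
        )
    return 2.0 * math.log(lambda_familial)


def fraction_explained(spec: PolygenicModelSpec) -> float:
    """Share of the familial log-risk variance captured by the listed loci.

    Capped at 1 with a warning when the locus sum exceeds the familial
    total.  An empty locus list explains nothing.
    """
    v_total = total_variance(spec.lambda_familial)
    if any(e.rr_per_allele > 3.0 for e in spec.loci):
        warnings.warn(
            "per-allele OR > 3: the rare-disease relative-risk "
            "approximation may be poor",
            stacklevel=2,
        )
    explained = sum(locus_variance(e) for e in spec.loci)
    fraction = explained / v_total
    if fraction > 1.0:
        warnings.warn(
            f"locus variance sum {explained:.4g} exceeds familial total "
            f"{v_total:.4g}; capping fraction at 1",
            stacklevel=2,
        )
        return 1.0
    return fraction


def risk_percentile_ratio(V: float, q: float) -> float:
    """Relative risk at population risk percentile ``q`` versus the median.

    Log risk is Normal(-V/2, V) (mean-one convention); the ratio to the
    median risk exp(-V/2) is exp(z_q sqrt(V)).
    """
    if V < 0:
        raise ValidationError("variance must be non-negative")
    if not 0.0 < q < 1.0:
        raise ValidationError("percentile must lie strictly inside (0, 1)")
    return math.exp(stats.norm.ppf(q) * math.sqrt(V))


def case_share_in_top(V: float, top_fraction: float) -> float:
    """Share of cases arising in the top ``top_fraction`` of the risk
    distribution, by adaptive quadrature of the mean-one log-normal risk
    density over its upper tail."""
    if V < 0:
        raise ValidationError("variance must be non-negative")
    if not 0.0 < top_fraction <= 1.0:
        raise ValidationError("top_fraction must lie in (0, 1]")
    if top_fraction == 1.0:
        return 1.0
    if V == 0.0:
        return top_fraction  # no risk heterogeneity
    mu, sd = -V / 2.0, math.sqrt(V)
    x_cut = stats.norm.ppf(1.0 - top_fraction, loc=mu, scale=sd)
    # mean relative risk is 1, so the case share is the raw tail integral;
    # evaluate exp(x) * pdf(x) in a single exponent to avoid overflow
    def integrand(x: float) -> float:
        return math.exp(x + stats.norm.logpdf(x, loc=mu, scale=sd))

    share, _ = integrate.quad(integrand, x_cut, math.inf, epsabs=1e-9)
    return float(min(share, 1.0))


def screening_benefit(
    V: float,
    top_fraction: float,
    reduction: float,
    baseline_risk: float,
) -> ScreeningBenefit:
    """Population yield of screening the top risk fraction.

    ``risk_averted`` is the absolute population risk removed: the screening
    reduction applied to the share of cases concentrated in the screened
    group, scaled by the baseline disease risk.
    """
    if not 0.0 <= reduction <= 1.0:
        raise ValidationError("reduction outside [0,1]")
    if not 0.0 <= baseline_risk <= 1.0:
        raise ValidationError("baseline_risk outside [0,1]")
    share = case_share_in_top(V, top_fraction)
    return ScreeningBenefit(
        screened_share=top_fraction,
        case_share=share,
        risk_averted=reduction * share * baseline_risk,
    )
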