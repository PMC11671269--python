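"""Disproportionality statistics for drug-event signal detection.

Four frequentist/Bayesian measures over a 2x2 table (a, b, c, d), N = a+b+c+d:

* ROR, the reporting odds ratio ad/(bc), with the Wald interval
  exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).  The interval is
  log-symmetric: ci_low * ci_high = ROR^2.
* PRR, the proportional reporting ratio (a/(a+b)) / (c/(c+d)), Wald
  interval on the log scale with SE sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)),
  plus the 2x2 chi-square statistic (Yates-corrected by default, the
  usual convention for sparse pharmacovigilance tables).
* The BCPNN information component.  The crude IC is
  log2[a*N / ((a+b)(a+c))], i.e. log2 of the observed-to-expected
  reporting ratio.  The Bayesian version puts Dirichlet priors on the
  margins (alpha1 = beta1 = gamma11 = 1, alpha = beta = 2) giving a
  posterior expectation E(IC) and variance V(IC); the lower signal bound
  is IC025 = E(IC) - 2*sqrt(V(IC)).
* EBGM, here the crude relative reporting ratio a*N/((a+b)(a+c)) — the
  maximum-likelihood observed/expected ratio, without gamma-Poisson
  shrinkage — with the one-sided 5% bound
  EBGM05 = exp(ln EBGM - 1.64 * sqrt(1/a + 1/b + 1/c + 1/d)).
  (A full DuMouchel empirical-Bayes fit is a documented extension hook,
  deliberately not implemented; see docs/methods.md.)

Note the exact identity IC = log2(EBGM) under the crude definitions:
both are the same observed/expected ratio on different scales.

Joint positivity requires all four criteria at once: ROR and PRR lower
95% bounds above 1 with a >= 3, IC025 > 0, and EBGM05 > 2 with a > 0.
IC025 also grades signal strength: <=0 none, (0, 1.5] low, (1.5, 3]
medium, > 3 high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

from .contingency import ContingencyTable

Z_TWO_SIDED_95 = 1.96   # fixed constants of the method, not configurable
Z_ONE_SIDED_95 = 1.64
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class BcpnnPriors:
    """Dirichlet prior counts for the BCPNN posterior moments."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def gamma(self, t: ContingencyTable) -> float:
        a, b, c, _ = t.cells
        n = t.n
        return (
            self.gamma11 * (n + self.alpha) * (n + self.beta)
            / ((a + b + self.alpha1) * (a + c + self.beta1))
        )


DEFAULT_PRIORS = BcpnnPriors()


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float
    se_log: float


class PrrResult(NamedTuple):
    prr: float
    ci_low: float
    ci_high: float
    chi2: float


class IcResult(NamedTuple):
    ic: float
    e_ic: float
    v_ic: float
    ic_025: float


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float


def ror_stats(t: ContingencyTable) -> RorResult:
    t = t.for_statistics()
    a, b, c, d = t.cells
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = Z_TWO_SIDED_95 * se
    return RorResult(ror, ror * math.exp(-half), ror * math.exp(half), se)


def prr_stats(t: ContingencyTable, chi2_variant: str = "yates") -> PrrResult:
    if chi2_variant not in ("yates", "pearson"):
        raise ValueError(f"unknown chi2 variant: {chi2_variant!r}")
    t = t.for_statistics()
    a, b, c, d = t.cells
    n = t.n
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    half = Z_TWO_SIDED_95 * se
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    diff = abs(a * d - b * c)
    if chi2_variant == "yates":
        diff = max(diff - n / 2, 0.0)
    chi2 = n * diff * diff / denom
    return PrrResult(prr, prr * math.exp(-half), prr * math.exp(half), chi2)


def ic_stats(
    t: ContingencyTable,
    priors: BcpnnPriors = DEFAULT_PRIORS,
    mode: str = "crude",
) -> IcResult:
    """Information component with prior-based lower bound.

    ``ic`` is the crude IC (the headline "BCPNN value" in report
    output); ``e_ic``/``v_ic`` are the posterior moments under
    ``priors`` and ``ic_025 = e_ic - 2*sqrt(v_ic)`` regardless of mode.
    ``mode="prior"`` reports E(IC) as the headline value instead.
    """
    if mode not in ("crude", "prior"):
        raise ValueError(f"unknown IC mode: {mode!r}")
    t = t.for_statistics()
    a, b, c, _ = t.cells
    n = t.n
    crude = math.log2(a * n / ((a + b) * (a + c)))
    g = priors.gamma(t)
    e_ic = math.log2(
        (a + priors.gamma11) * (n + priors.alpha) * (n + priors.beta)
        / ((n + g) * (a + b + priors.alpha1) * (a + c + priors.beta1))
    )
    v_ic = (1 / _LN2**2) * (
        (n - a + g - priors.gamma11) / ((a + priors.gamma11) * (1 + n + g))
        + (n - (a + b) + priors.alpha - priors.alpha1)
        / ((a + b + priors.alpha1) * (1 + n + priors.alpha))
        + (n - (a + c) + priors.beta - priors.beta1)
        / ((a + c + priors.beta1) * (1 + n + priors.beta))
    )
    ic_025 = e_ic - 2.0 * math.sqrt(v_ic)
    headline = crude if mode == "crude" else e_ic
    return IcResult(headline, e_ic, v_ic, ic_025)


def ebgm_stats(t: ContingencyTable) -> EbgmResult:
    t = t.for_statistics()
    a, b, c, d = t.cells
    n = t.n
    ebgm = a * n / ((a + b) * (a + c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EbgmResult(ebgm, math.exp(math.log(ebgm) - Z_ONE_SIDED_95 * se))


# ---------------------------------------------------------------------------
# Joint classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalCriteria:
    """Positivity thresholds for the four algorithms."""

    min_a: int = 3                 # ROR/PRR report floor
    ror_ci_low_gt: float = 1.0
    prr_ci_low_gt: float = 1.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    tier_low_max: float = 1.5      # IC025 risk-tier cut points
    tier_medium_max: float = 3.0


DEFAULT_CRITERIA = SignalCriteria()


@dataclass
class SignalResult:
    """All four statistics for one drug, with flags and risk tier."""

    drug: str
    a: int
    b: int
    c: int
    d: int
    ror: float = math.nan
    ror_ci_low: float = math.nan
    ror_ci_high: float = math.nan
    se_log: float = math.nan
    prr: float = math.nan
    prr_ci_low: float = math.nan
    prr_ci_high: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    e_ic: float = math.nan
    v_ic: float = math.nan
    ic_025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    corrected: bool = False
    flags: dict[str, bool] = field(default_factory=dict)
    joint_signal: bool = False
    tier: str = "none"


def compute_signal(
    t: ContingencyTable,
    priors: BcpnnPriors = DEFAULT_PRIORS,
    chi2_variant: str = "yates",
    ic_mode: str = "crude",
    criteria: SignalCriteria = DEFAULT_CRITERIA,
) -> SignalResult:
    """Compute all four statistics for one table and classify the result."""
    ts = t.for_statistics()
    ror = ror_stats(ts)
    prr = prr_stats(ts, chi2_variant)
    ic = ic_stats(ts, priors, ic_mode)
    ebgm = ebgm_stats(ts)
    result = SignalResult(
        drug=t.drug, a=int(t.a), b=int(t.b), c=int(t.c), d=int(t.d),
        ror=ror.ror, ror_ci_low=ror.ci_low, ror_ci_high=ror.ci_high,
        se_log=ror.se_log,
        prr=prr.prr, prr_ci_low=prr.ci_low, prr_ci_high=prr.ci_high,
        chi2=prr.chi2,
        ic=ic.ic, e_ic=ic.e_ic, v_ic=ic.v_ic, ic_025=ic.ic_025,
        ebgm=ebgm.ebgm, ebgm05=ebgm.ebgm05,
        corrected=ts.corrected,
    )
    return classify_signal(result, criteria)


def risk_tier(ic_025: float, criteria: SignalCriteria = DEFAULT_CRITERIA) -> str:
    if ic_025 <= criteria.ic025_gt:
        return "none"
    if ic_025 <= criteria.tier_low_max:
        return "low"
    if ic_025 <= criteria.tier_medium_max:
        return "medium"
    return "high"


def classify_signal(
    result: SignalResult, criteria: SignalCriteria = DEFAULT_CRITERIA
) -> SignalResult:
    """Apply the four positivity rules and the IC025 risk tier in place."""
    result.flags = {
        "ror": result.a >= criteria.min_a
        and result.ror_ci_low > criteria.ror_ci_low_gt,
        "prr": result.a >= criteria.min_a
        and result.prr_ci_low > criteria.prr_ci_low_gt,
        "bcpnn": result.ic_025 > criteria.ic025_gt,
        "mgps": result.ebgm05 > criteria.ebgm05_gt and result.a > 0,
    }
    result.joint_signal = all(result.flags.values())
    result.tier = risk_tier(result.ic_025, criteria)
    return result


def rank_signals(results: list[SignalResult]) -> list[SignalResult]:
    """Rank by descending IC025, ties by descending ROR, then name."""
    return sorted(results, key=lambda r: (-r.ic_025, -r.ror, r.drug))


def round_half_up(x: float, places: int = 3) -> float:
    """Half-up decimal rounding used for report tables."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
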