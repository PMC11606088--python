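"""Analytic power engine for genetic-by-age interaction and change designs.

The engine compares three discovery strategies for genetic effects on annual
trait change:

``gxage_1stage``
    A genome-wide cross-sectional GxAge interaction scan. Power is the union
    of (i) the direct genome-wide interaction test at ``alpha_gws`` and
    (ii) a 2-step route that first requires a genome-wide significant marginal
    effect and then tests the interaction at ``0.05 / n_indep_2step``:
    ``PWR = PWR_gws + PWR_2step - PWR_gws * PWR_2step``.
``change_1stage``
    The same union composition applied to the annual-change association test
    in the (smaller) longitudinal sample.
``gxagechange_2stage``
    The 1-stage GxAge power multiplied by the power of a one-sided
    annual-change validation test at ``0.05 / n_indep_validation`` in
    independent longitudinal data.

All single tests are 1-df Wald tests with noncentrality
``ncp = n * r2 / (1 - r2)`` where ``r2`` is the fraction of (covariate
adjusted) outcome variance explained by the tested term: a per-allele effect
``beta`` at allele frequency ``p`` explains ``beta^2 * 2p(1-p)`` of the trait
variance (times ``Var(Age)`` for the interaction term, because the
orthogonalised interaction regressor has variance ``2p(1-p) * Var(Age)``).
Discovery-stage tests are two-sided (noncentral chi-square), the validation
stage one-sided (shifted normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .designs import AlphaScheme, TraitDesign

__all__ = [
    "PowerResult",
    "KippingPoint",
    "DominanceResult",
    "r2_explained",
    "power_single",
    "power_1stage",
    "power_2stage",
    "power_approach",
    "min_detectable_effect",
    "required_n",
    "kipping_point",
    "dominance_condition",
    "recover_var_age_from_r2",
    "recover_var_age_from_min_effect",
]

Term = Literal["marginal", "gxage", "change"]
Approach = Literal["gxage_1stage", "change_1stage", "gxagechange_2stage"]

APPROACHES: tuple[str, ...] = ("gxage_1stage", "change_1stage", "gxagechange_2stage")

_REL_TOL = 1e-6
_MAX_EXPAND = 200


@dataclass(frozen=True)
class PowerResult:
    """Power of one approach at one effect size.

    ``components`` holds (genome-wide route, 2-step route, validation stage);
    the validation component is ``None`` for 1-stage approaches. ``r2`` and
    ``ncp`` describe the focal (interaction or change) genome-wide test.
    """

    approach: str
    power: float
    power_gws: float
    power_2step: float
    power_validation: float | None
    r2: float
    ncp: float

    @property
    def components(self) -> tuple[float, float, float | None]:
        return (self.power_gws, self.power_2step, self.power_validation)


@dataclass(frozen=True)
class KippingPoint:
    """Longitudinal-to-total ratio where the two 1-stage approaches cross.

    ``f`` is None when the power difference does not change sign on (0, 1);
    ``dominant`` then names the uniformly more powerful approach.
    """

    f: float | None
    dominant: str | None
    power_at_f: float | None


@dataclass(frozen=True)
class DominanceResult:
    """Outcome of the controlled-scenario dominance condition.

    With equal sample sizes, equal alpha and equal effect sizes, the GxAge
    interaction test beats the annual-change test iff
    ``2 * Var(Age) > age_diff^2 / (1 - r_y1y2)``.
    """

    gxage_wins: bool
    lhs: float
    rhs: float
    degenerate: bool = False


def r2_explained(beta: float, design: TraitDesign, term: Term) -> float:
    """Fraction of outcome variance explained by a per-allele effect.

    The outcome variance is ``sd_y**2`` for marginal and interaction terms
    and ``sd_change**2`` for the annual-change term; the interaction term's
    explained variance carries the extra factor ``Var(Age)``.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    vg = design.dosage_variance
    if term == "marginal":
        return beta**2 * vg / design.sd_y**2
    if term == "gxage":
        return beta**2 * vg * design.var_age / design.sd_y**2
    if term == "change":
        return beta**2 * vg / design.sd_change**2
    raise ValueError(f"unknown term {term!r}")


def power_single(r2: float, n: float, alpha: float, sided: int = 2) -> float:
    """Power of a single 1-df Wald test.

    Two-sided tests use the noncentral chi-square form, one-sided tests the
    shifted-normal form; both with noncentrality ``n * r2 / (1 - r2)``.
    Effects explaining the full outcome variance (``r2 >= 1``) are detected
    with certainty.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    if r2 < 0:
        raise ValueError("r2 must be non-negative")
    if r2 >= 1:
        return 1.0
    ncp = n * r2 / (1.0 - r2)
    if sided == 2:
        crit = stats.chi2.isf(alpha, df=1)
        return float(stats.ncx2.sf(crit, df=1, nc=ncp))
    if sided == 1:
        return float(stats.norm.sf(stats.norm.isf(alpha) - np.sqrt(ncp)))
    raise ValueError("sided must be 1 or 2")


def _union(a: float, b: float) -> float:
    return a + b - a * b


def power_1stage(
    design: TraitDesign,
    beta: float,
    approach: Literal["gxage", "change"],
    scheme: AlphaScheme | None = None,
    n_marginal: float | None = None,
) -> PowerResult:
    """Union power of a 1-stage approach (genome-wide route or 2-step route).

    ``beta`` is the focal per-allele effect: the interaction effect in trait
    units per year of age for ``approach="gxage"``, the annual-change effect
    in trait units per year for ``approach="change"``. The 2-step route
    multiplies the power to detect the design's medium marginal effect at
    ``alpha_gws`` (in ``n_marginal`` individuals, default ``n_cross``) by the
    power of the focal test at ``alpha_2step``.
    """
    scheme = scheme or AlphaScheme()
    if approach == "gxage":
        term: Term = "gxage"
        n_term = design.n_cross
    elif approach == "change":
        term = "change"
        n_term = design.n_long
    else:
        raise ValueError(f"unknown 1-stage approach {approach!r}")
    if n_term <= 0:
        raise ValueError(f"approach {approach!r} requires a non-empty sample")

    r2 = r2_explained(beta, design, term)
    p_gws = power_single(r2, n_term, scheme.alpha_gws, sided=2)
    n_marg = design.n_cross if n_marginal is None else n_marginal
    r2_marg = r2_explained(design.medium_marginal, design, "marginal")
    p_marg = power_single(r2_marg, n_marg, scheme.alpha_gws, sided=2)
    p_2step = p_marg * power_single(r2, n_term, scheme.alpha_2step, sided=2)
    ncp = n_term * r2 / (1.0 - r2) if r2 < 1 else np.inf
    return PowerResult(
        approach=f"{approach}_1stage",
        power=_union(p_gws, p_2step),
        power_gws=p_gws,
        power_2step=p_2step,
        power_validation=None,
        r2=r2,
        ncp=ncp,
    )


def power_2stage(
    design: TraitDesign,
    beta: float,
    scheme: AlphaScheme | None = None,
    n_marginal: float | None = None,
) -> PowerResult:
    """Power of the 2-stage approach: GxAge discovery then change validation.

    The product of the 1-stage GxAge union power (same ``beta`` interpreted
    as interaction effect) and the one-sided annual-change validation power
    at ``alpha_validation`` in the independent longitudinal sample.
    """
    scheme = scheme or AlphaScheme()
    if design.n_long <= 0:
        raise ValueError("2-stage validation requires longitudinal data")
    stage1 = power_1stage(design, beta, "gxage", scheme, n_marginal=n_marginal)
    r2_ch = r2_explained(beta, design, "change")
    p_val = power_single(r2_ch, design.n_long, scheme.alpha_validation, sided=1)
    return PowerResult(
        approach="gxagechange_2stage",
        power=stage1.power * p_val,
        power_gws=stage1.power_gws,
        power_2step=stage1.power_2step,
        power_validation=p_val,
        r2=stage1.r2,
        ncp=stage1.ncp,
    )


def power_approach(
    design: TraitDesign,
    beta: float,
    approach: Approach,
    scheme: AlphaScheme | None = None,
    n_marginal: float | None = None,
) -> PowerResult:
    """Dispatch to the requested approach's power calculation."""
    if approach == "gxage_1stage":
        return power_1stage(design, beta, "gxage", scheme, n_marginal=n_marginal)
    if approach == "change_1stage":
        return power_1stage(design, beta, "change", scheme, n_marginal=n_marginal)
    if approach == "gxagechange_2stage":
        return power_2stage(design, beta, scheme, n_marginal=n_marginal)
    raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")


def min_detectable_effect(
    design: TraitDesign,
    approach: Approach,
    scheme: AlphaScheme | None = None,
    target_power: float = 0.8,
) -> float:
    """Smallest per-allele effect detectable at ``target_power``.

    Found by bracket expansion plus Brent root finding on the (asserted
    monotone) power curve, to a relative tolerance of 1e-6.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    scheme = scheme or AlphaScheme()

    def pw(beta: float) -> float:
        return power_approach(design, beta, approach, scheme).power

    lo, hi = 0.0, design.medium_marginal or 1.0
    for _ in range(_MAX_EXPAND):
        if pw(hi) >= target_power:
            break
        lo, hi = hi, hi * 2.0
        # once the focal term saturates the outcome variance, no larger
        # effect can help: the design cannot reach the target power
        if r2_explained(hi, design, "change" if "change" in approach else "gxage") >= 1 and pw(hi) < target_power:
            raise ValueError(
                f"target power {target_power} unattainable for {approach} "
                f"with n_cross={design.n_cross}, n_long={design.n_long}"
            )
    else:
        raise ValueError("bracket expansion failed")
    if pw(lo) > pw(hi):
        raise AssertionError("power is not monotone increasing in |beta|")
    beta = brentq(lambda b: pw(b) - target_power, lo, hi, rtol=_REL_TOL, maxiter=200)
    return float(beta)


def required_n(
    design: TraitDesign,
    beta: float,
    term: Term = "change",
    alpha: float = 0.05,
    sided: int = 1,
    target_power: float = 0.8,
) -> int:
    """Smallest sample size at which a single test reaches ``target_power``.

    Inverse-consistent with :func:`power_single`: the returned ``n`` achieves
    at least the target power and ``n - 1`` does not.
    """
    if beta == 0:
        raise ValueError("no finite sample size detects a null effect")
    r2 = r2_explained(beta, design, term)
    if power_single(r2, 1, alpha, sided) >= target_power:
        return 1
    n_cont = brentq(
        lambda n: power_single(r2, n, alpha, sided) - target_power,
        1.0,
        1e12,
        rtol=1e-12,
        maxiter=200,
    )
    n = int(np.ceil(n_cont))
    while power_single(r2, n, alpha, sided) < target_power:  # guard rounding
        n += 1
    while n > 1 and power_single(r2, n - 1, alpha, sided) >= target_power:
        n -= 1
    return n


def kipping_point(
    design: TraitDesign,
    beta: float | None = None,
    scheme: AlphaScheme | None = None,
    n_total: int | None = None,
    n_marginal: float | None = None,
) -> KippingPoint:
    """Ratio ``f = n_long / n_total`` where the 1-stage approaches' power cross.

    The total sample is held fixed (default ``n_cross + n_long`` of the
    design) and re-split as ``n_long = f * n_total``; the focal effect
    defaults to 10% of the medium marginal effect. Found by bisection on the
    signed power difference; if the difference does not change sign the
    dominant approach is reported instead.
    """
    scheme = scheme or AlphaScheme()
    if beta is None:
        beta = 0.1 * design.medium_marginal
    total = design.n_total if n_total is None else n_total

    def diff(f: float) -> float:
        n_long = f * total
        n_cross = total - n_long
        d = TraitDesign(
            trait_name=design.trait_name,
            n_cross=int(round(n_cross)),
            n_long=int(round(n_long)),
            sd_y=design.sd_y,
            sd_change=design.sd_change,
            medium_marginal=design.medium_marginal,
            allele_freq=design.allele_freq,
            var_age=design.var_age,
            age_diff=design.age_diff,
            r_y1y2=design.r_y1y2,
        )
        pg = power_1stage(d, beta, "gxage", scheme, n_marginal=n_marginal).power
        pc = power_1stage(d, beta, "change", scheme, n_marginal=n_marginal).power
        return pg - pc

    eps = 1e-4
    d_lo, d_hi = diff(eps), diff(1 - eps)
    if d_lo * d_hi > 0:
        dominant = "gxage_1stage" if d_lo > 0 else "change_1stage"
        return KippingPoint(f=None, dominant=dominant, power_at_f=None)
    f = brentq(diff, eps, 1 - eps, rtol=_REL_TOL, maxiter=200)
    d_at = design.with_split(f)
    p_at = power_1stage(d_at, beta, "gxage", scheme, n_marginal=n_marginal).power
    return KippingPoint(f=float(f), dominant=None, power_at_f=p_at)


def dominance_condition(var_age: float, age_diff: float, r_y1y2: float) -> DominanceResult:
    """Controlled-scenario comparison of the GxAge and change tests.

    Applies to equal sample sizes, equal alpha and equal effect sizes: the
    interaction test is more powerful iff
    ``2 * Var(Age) > age_diff^2 / (1 - r_y1y2)``. A test-retest correlation
    of exactly 1 makes the change test noiseless (degenerate comparison).
    """
    if age_diff < 0:
        raise ValueError("age_diff must be non-negative")
    if r_y1y2 > 1:
        raise ValueError("r_y1y2 must be <= 1")
    lhs = 2.0 * var_age
    if r_y1y2 == 1.0:
        return DominanceResult(gxage_wins=age_diff == 0, lhs=lhs, rhs=np.inf, degenerate=True)
    rhs = age_diff**2 / (1.0 - r_y1y2)
    return DominanceResult(gxage_wins=lhs > rhs, lhs=lhs, rhs=rhs)


def recover_var_age_from_r2(
    design: TraitDesign, r2_gxage: float, beta: float | None = None
) -> float:
    """Age variance implied by a known interaction-explained variance.

    Inverts ``r2 = beta^2 * 2p(1-p) * Var(Age) / sd_y^2`` at ``beta``
    (default 10% of the medium marginal effect). Published tables often print
    ``r2`` to one significant digit only, which propagates into the recovered
    variance; see :func:`recover_var_age_from_min_effect` for a sharper
    alternative.
    """
    if beta is None:
        beta = 0.1 * design.medium_marginal
    if beta == 0:
        raise ValueError("cannot recover var_age from a null effect")
    return r2_gxage * design.sd_y**2 / (beta**2 * design.dosage_variance)


def recover_var_age_from_min_effect(
    design: TraitDesign,
    min_effect: float,
    scheme: AlphaScheme | None = None,
    target_power: float = 0.8,
) -> float:
    """Age variance implied by a known minimum detectable interaction effect.

    Finds the ``Var(Age)`` at which the 1-stage GxAge union power of
    ``min_effect`` equals ``target_power``. Because minimum detectable
    effects are typically published with two significant digits, this
    recovery is sharper than inverting a one-digit explained-variance figure.
    """
    scheme = scheme or AlphaScheme()

    def gap(va: float) -> float:
        d = TraitDesign(
            trait_name=design.trait_name,
            n_cross=design.n_cross,
            n_long=design.n_long,
            sd_y=design.sd_y,
            sd_change=design.sd_change,
            medium_marginal=design.medium_marginal,
            allele_freq=design.allele_freq,
            var_age=va,
            age_diff=design.age_diff,
            r_y1y2=design.r_y1y2,
        )
        return power_1stage(d, min_effect, "gxage", scheme).power - target_power

    return float(brentq(gap, 0.1, 5000.0, rtol=1e-10, maxiter=200))
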