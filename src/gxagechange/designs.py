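"""Trait design configurations driving the analytic power machinery.

A :class:`TraitDesign` bundles everything the power engine needs to know about
one trait in a two-sample discovery design: the cross-sectional sample size
available for genetic-by-age (GxAge) interaction testing, the independent
longitudinal sample size available for annual-change testing, the trait and
annual-change standard deviations, a "medium" marginal per-allele effect used
by the 2-step screening route, the effect-allele frequency, and the moments of
the age/follow-up structure (age variance, mean follow-up gap, test-retest
correlation).

Eight UK-Biobank-like configurations (weight, BMI, DBP, SBP, pulse pressure,
log HDL-C, LDL-C, log triglycerides) ship with the package and are loaded with
:func:`ukb_trait_designs`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "TraitDesign",
    "AlphaScheme",
    "load_design_table",
    "ukb_trait_designs",
]


@dataclass(frozen=True)
class TraitDesign:
    """Per-trait configuration for analytic power calculations.

    Parameters
    ----------
    trait_name:
        Label for the trait.
    n_cross, n_long:
        Cross-sectional and longitudinal sample sizes. The two samples are
        assumed disjoint (longitudinal individuals are excluded from the
        cross-sectional discovery sample).
    sd_y:
        Trait standard deviation (trait units) in the cross-sectional sample,
        after covariate adjustment.
    sd_change:
        Standard deviation of annual trait change (trait units / year).
    medium_marginal:
        Medium marginal per-allele effect (trait units); the 2-step screening
        route assumes candidate variants carry a marginal effect of this size.
    allele_freq:
        Effect-allele frequency, in (0, 1).
    var_age:
        Variance of age in the cross-sectional sample (years^2).
    age_diff:
        Mean follow-up gap between the two longitudinal visits (years).
    r_y1y2:
        Test-retest correlation of the trait across the two visits.
    """

    trait_name: str
    n_cross: int
    n_long: int
    sd_y: float
    sd_change: float
    medium_marginal: float
    allele_freq: float
    var_age: float
    age_diff: float = 7.5
    r_y1y2: float = 0.9

    def __post_init__(self) -> None:
        if self.n_cross < 0 or self.n_long < 0:
            raise ValueError("sample sizes must be non-negative")
        if self.sd_y <= 0 or self.sd_change <= 0:
            raise ValueError("trait SDs must be positive")
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele_freq must be in (0, 1)")
        if self.var_age <= 0:
            raise ValueError("var_age must be positive")
        if abs(self.r_y1y2) > 1:
            raise ValueError("|r_y1y2| must be <= 1")

    @property
    def dosage_variance(self) -> float:
        """Variance of the allelic dosage under Hardy-Weinberg, 2p(1-p)."""
        p = self.allele_freq
        return 2.0 * p * (1.0 - p)

    @property
    def n_total(self) -> int:
        return self.n_cross + self.n_long

    def with_split(self, f: float) -> "TraitDesign":
        """Re-split the total sample: ``n_long = f * n_total``.

        Used for longitudinal-to-total ratio sweeps at fixed total sample
        size; all other fields are unchanged.
        """
        if not 0 <= f <= 1:
            raise ValueError("f must be in [0, 1]")
        n_long = int(round(f * self.n_total))
        return replace(self, n_cross=self.n_total - n_long, n_long=n_long)


@dataclass(frozen=True)
class AlphaScheme:
    """Significance levels for the discovery and validation stages.

    ``alpha_gws`` is the genome-wide level used for both the direct
    genome-wide route and the marginal screen of the 2-step route.
    ``alpha_2step = 0.05 / n_indep_2step`` is the Bonferroni level applied to
    the focal (interaction or change) test among marginally associated
    variants, and ``alpha_validation = 0.05 / n_indep_validation`` is the
    one-sided level of the longitudinal validation stage.
    """

    alpha_gws: float = 5e-8
    n_indep_2step: int = 1000
    n_indep_validation: int = 10

    def __post_init__(self) -> None:
        for a in (self.alpha_gws, self.alpha_2step, self.alpha_validation):
            if not 0 < a < 1:
                raise ValueError("all alpha levels must lie in (0, 1)")

    @property
    def alpha_2step(self) -> float:
        return 0.05 / self.n_indep_2step

    @property
    def alpha_validation(self) -> float:
        return 0.05 / self.n_indep_validation


def load_design_table() -> pd.DataFrame:
    """Return the packaged trait-design table as a DataFrame.

    Besides the :class:`TraitDesign` columns the table carries the published
    per-trait reference quantities used to recover the unprinted age variance:
    ``r2_gxage_pct``/``r2_change_pct`` (percent of outcome variance explained
    by an interaction/change effect of 10% of the medium marginal effect) and
    ``min_gxage`` (the minimum 1-stage detectable interaction effect at 80%
    power).
    """
    ref = importlib.resources.files("gxagechange.data") / "trait_designs.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def ukb_trait_designs(var_age: float | None = None) -> dict[str, TraitDesign]:
    """Load the eight packaged UKB-like trait designs.

    ``var_age`` overrides the age variance for every trait; by default it is
    recovered per trait from the published configuration (see
    :func:`gxagechange.power.recover_var_age_from_min_effect`).
    """
    from . import power  # deferred: power imports TraitDesign from here

    table = load_design_table()
    designs: dict[str, TraitDesign] = {}
    for row in table.itertuples(index=False):
        base = TraitDesign(
            trait_name=row.trait,
            n_cross=int(row.n_cross),
            n_long=int(row.n_long),
            sd_y=row.sd_y,
            sd_change=row.sd_change,
            medium_marginal=row.medium_marginal,
            allele_freq=row.allele_freq,
            var_age=1.0,  # placeholder, replaced below
            age_diff=row.age_diff,
            r_y1y2=row.r_y1y2,
        )
        if var_age is not None:
            va = var_age
        else:
            va = power.recover_var_age_from_min_effect(base, row.min_gxage)
        designs[row.trait] = replace(base, var_age=va)
    return designs
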