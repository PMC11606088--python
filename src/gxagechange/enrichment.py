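"""Directional and validation enrichment statistics.

After aligning every variant's effects to its marginally trait-increasing
allele, an interaction effect above zero means the genetic effect is
*intensified* with age and one below zero *attenuated*. Whether one direction
dominates among nominally significant interactions is judged by an exact
two-sided binomial test against 1/2 (2 * min tail, capped at 1 — equivalent
to the minimal-likelihood definition at p = 1/2). Validation enrichment (are
more selected variants change-significant than a nominal level would
produce?) uses the exact one-sided upper binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DirectionTally",
    "align_directions",
    "direction_binomial",
    "validation_enrichment",
    "tally_directions",
]


@dataclass(frozen=True)
class DirectionTally:
    """Counts of age-intensified vs age-attenuated interaction effects."""

    n_total: int
    n_intensified: int
    n_attenuated: int
    median_gxage: float
    median_marginal: float

    def __post_init__(self) -> None:
        if self.n_intensified + self.n_attenuated > self.n_total:
            raise ValueError("direction counts exceed the total")

    @property
    def n_nominal(self) -> int:
        return self.n_intensified + self.n_attenuated

    @property
    def median_pct_of_marginal(self) -> float:
        """Median |interaction| as a percentage of the median |marginal|."""
        return 100.0 * self.median_gxage / self.median_marginal

    @property
    def p_binomial(self) -> float:
        return direction_binomial(self.n_intensified, self.n_attenuated)


_BETA_COLS = ("beta_marginal", "beta_gxage", "beta_change", "beta_g_at_mean")


def align_directions(records: pd.DataFrame) -> pd.DataFrame:
    """Sign effects to the marginally trait-increasing allele.

    Rows with a negative marginal effect have effect/other alleles swapped,
    the frequency complemented, and every beta negated; the operation is
    idempotent. Exact-zero marginal effects are left unflipped and flagged.
    """
    out = records.copy()
    flip = out["beta_marginal"] < 0
    out["aligned_flip"] = flip
    out["ambiguous_direction"] = out["beta_marginal"] == 0
    if flip.any():
        if {"ea", "oa"} <= set(out.columns):
            ea = out.loc[flip, "ea"].copy()
            out.loc[flip, "ea"] = out.loc[flip, "oa"]
            out.loc[flip, "oa"] = ea
        if "eaf" in out.columns:
            out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
        for col in _BETA_COLS:
            if col in out.columns:
                out.loc[flip, col] = -out.loc[flip, col]
    return out


def direction_binomial(k_intensified: int, k_attenuated: int) -> float:
    """Exact two-sided binomial test of intensified vs attenuated at 1/2."""
    k1, k2 = int(k_intensified), int(k_attenuated)
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    n = k1 + k2
    if n == 0:
        raise ValueError("no directed effects to test")
    k = min(k1, k2)
    lower = stats.binom.cdf(k, n, 0.5)
    return float(min(1.0, 2.0 * lower))


def validation_enrichment(k_significant: int, n_tested: int, p0: float = 0.05) -> float:
    """Exact one-sided binomial tail P(X >= k) under Binomial(n, p0)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    k, n = int(k_significant), int(n_tested)
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p0))


def tally_directions(records: pd.DataFrame, nominal_alpha: float = 0.05) -> DirectionTally:
    """Tally interaction directions among nominally significant records.

    ``records`` must be direction-aligned (see :func:`align_directions`).
    The medians of |interaction| and |marginal| effects are reported over
    nominal records and over all records respectively, matching how
    trait-level interaction summaries are usually tabulated.
    """
    nominal = records[records["p_gxage"] < nominal_alpha]
    n_int = int((nominal["beta_gxage"] > 0).sum())
    n_att = int((nominal["beta_gxage"] < 0).sum())
    med_gx = float(np.median(np.abs(nominal["beta_gxage"]))) if len(nominal) else np.nan
    med_marg = float(np.median(np.abs(records["beta_marginal"])))
    return DirectionTally(
        n_total=len(records),
        n_intensified=n_int,
        n_attenuated=n_att,
        median_gxage=med_gx,
        median_marginal=med_marg,
    )
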