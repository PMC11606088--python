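"""Synthetic two-visit cohort generator.

The generator emulates a middle-aged population cohort with a baseline visit
and an optional follow-up visit: Hardy-Weinberg genotypes at configurable
allele frequencies, baseline ages uniform on a configurable range (default
40-69 years), and person-level linear trait trajectories

    Y_i(age) = beta0 + beta_g * G_i + beta_age * age_c + beta_gxage * G_i * age_c
               + sex_effect * sex_i + b_i

observed with independent visit-level noise, where ``age_c`` is age centered
at the cross-sectional mean and ``b_i`` is a person-level random intercept.
The (intercept SD, visit SD) split is calibrated in closed form so that the
correlation between the two visits' trait values hits a target test-retest
correlation ``r_y1y2``.

Assumption-violation switches (calendar-time trend, birth-cohort effects on
genotype or trait, genotype-dependent dropout, curvature of the
genotype-dependent trajectory) let tests demonstrate which assumptions the
cross-sectional-interaction / longitudinal-change equivalence actually needs.
A genotype-shared quadratic age term is orthogonal to the centered
interaction regressor and biases neither estimator, so the
``quadratic_age_effect`` switch bends the genotype-dependent trajectory
component (``magnitude * G * age_c^2``); a shared curvature knob is exposed
separately for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConfig",
    "CohortTable",
    "simulate_cohort",
    "calibrate_noise",
    "fixed_effect_variance",
    "apply_violation",
    "monte_carlo_power",
    "config_to_design",
]

VIOLATION_SWITCHES = (
    "calendar_time_effect",
    "birthyear_effect_on_g",
    "birthyear_effect_on_y",
    "genotype_dependent_dropout",
    "quadratic_age_effect",
    "quadratic_age_shared",
)


@dataclass(frozen=True)
class SimConfig:
    """Generative configuration for a synthetic cohort.

    ``followup_fraction`` of individuals receive a second visit after a gap
    drawn from N(followup_gap_mean, followup_gap_sd), truncated positive.
    Noise is specified either directly (``intercept_sd``/``visit_sd``) or via
    a target total trait SD ``sd_y`` plus test-retest correlation
    ``r_y1y2``, from which the split is calibrated (see
    :func:`calibrate_noise`). ``violations`` maps switch names (see
    ``VIOLATION_SWITCHES``) to magnitudes applied after base generation.
    """

    n_individuals: int = 10_000
    n_variants: int = 1
    allele_freq: float | tuple[float, ...] = 0.30
    age_range: tuple[float, float] = (40.0, 69.0)
    beta0: float = 0.0
    beta_g: float = 0.0
    beta_age: float = 0.0
    beta_gxage: float = 0.0
    sex_effect: float = 0.0
    sex_age_effect: float = 0.0
    sd_y: float = 1.0
    r_y1y2: float | None = 0.91
    intercept_sd: float | None = None
    visit_sd: float | None = None
    followup_gap_mean: float = 7.5
    followup_gap_sd: float = 0.8
    followup_fraction: float = 0.2
    recruitment_start: float = 2006.0
    recruitment_window: float = 4.0
    violations: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.atleast_1d(np.asarray(self.allele_freq, dtype=float))
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if not 0 <= self.followup_fraction <= 1:
            raise ValueError("followup_fraction must be in [0, 1]")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be increasing")
        for k in self.violations:
            if k not in VIOLATION_SWITCHES:
                raise ValueError(f"unknown violation switch {k!r}")

    @property
    def freqs(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.allele_freq, dtype=float))
        if f.size == 1:
            f = np.repeat(f, self.n_variants)
        if f.size != self.n_variants:
            raise ValueError("allele_freq length must match n_variants")
        return f

    @property
    def var_age(self) -> float:
        lo, hi = self.age_range
        return (hi - lo) ** 2 / 12.0


@dataclass
class CohortTable:
    """A simulated (or ingested) cohort.

    ``samples`` has one row per individual (id, sex, age, birthyear,
    assess_date); ``genotypes`` is an (n_individuals, n_variants) dosage
    matrix on the 0-2 scale; ``variants`` carries variant metadata; and
    ``visits`` is long-format with one row per (individual, visit): columns
    id, visit ("baseline"/"first_repeat"), time (calendar years), age, y.
    """

    samples: pd.DataFrame
    genotypes: np.ndarray
    variants: pd.DataFrame
    visits: pd.DataFrame
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        if np.any((self.genotypes < 0) | (self.genotypes > 2)):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.samples)

    def baseline(self) -> pd.DataFrame:
        """Per-individual baseline view (samples joined with baseline visit)."""
        base = self.visits[self.visits["visit"] == "baseline"]
        # baseline age lives in `samples`; only time and trait come from the visit
        return self.samples.merge(base[["id", "time", "y"]], on="id")

    def longitudinal(self) -> pd.DataFrame:
        """Individuals with both visits; adds annual change (y2-y1)/(t2-t1)."""
        wide = self.visits.pivot(index="id", columns="visit", values=["y", "time", "age"])
        if "first_repeat" not in wide["y"].columns:
            return pd.DataFrame(
                columns=["id", "y1", "y2", "t1", "t2", "age1", "annual_change"]
            )
        out = pd.DataFrame(
            {
                "id": wide.index,
                "y1": wide[("y", "baseline")].to_numpy(),
                "y2": wide[("y", "first_repeat")].to_numpy(),
                "t1": wide[("time", "baseline")].to_numpy(),
                "t2": wide[("time", "first_repeat")].to_numpy(),
                "age1": wide[("age", "baseline")].to_numpy(),
            }
        ).dropna(subset=["y2"])
        out["annual_change"] = (out["y2"] - out["y1"]) / (out["t2"] - out["t1"])
        return out.reset_index(drop=True)

    def longitudinal_ids(self) -> np.ndarray:
        rep = self.visits.loc[self.visits["visit"] == "first_repeat", "id"]
        return rep.to_numpy()

    def cross_sectional(self, exclude_longitudinal: bool = True) -> pd.DataFrame:
        """Baseline rows, by default excluding the longitudinal subset.

        This mirrors the two-sample discovery design: interaction testing in
        individuals with only a baseline visit, change testing in the
        (disjoint) longitudinal subset.
        """
        base = self.baseline()
        if exclude_longitudinal:
            base = base[~base["id"].isin(self.longitudinal_ids())]
        return base.reset_index(drop=True)

    def dosages(self, ids: pd.Series | np.ndarray, variant: int = 0) -> np.ndarray:
        idx = self.samples.set_index("id").index.get_indexer(np.asarray(ids))
        if np.any(idx < 0):
            raise KeyError("unknown individual id")
        return self.genotypes[idx, variant]


def calibrate_noise(
    target_r: float, gap: float, signal_var: float, total_var: float = 1.0
) -> tuple[float, float]:
    """Split residual variance so corr(Y1, Y2) hits ``target_r``.

    With a shared person intercept ``b`` and independent visit noise ``e``,
    ``corr(Y1, Y2) = (signal_var + var_b) / total_var`` (the fixed trajectory
    is common to both visits up to a mean shift of the gap), so
    ``var_b = target_r * total_var - signal_var`` and
    ``var_e = (1 - target_r) * total_var``. The gap does not enter because
    the trajectory slopes carry no independent person-level randomness.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    var_b = target_r * total_var - signal_var
    var_e = (1.0 - target_r) * total_var
    if var_b < 0:
        raise ValueError(
            f"target r_y1y2={target_r} incompatible with fixed signal variance "
            f"{signal_var:.4g} out of total {total_var:.4g} "
            f"(upper bound r={1 - var_e / total_var + var_b / total_var:.3f})"
        )
    return float(np.sqrt(var_b)), float(np.sqrt(var_e))


def fixed_effect_variance(config: SimConfig) -> float:
    """Analytic baseline variance of the fixed trajectory part.

    Uses the first variant; age centered, genotype Hardy-Weinberg, sex
    Bernoulli(1/2) independent of both.
    """
    p = float(config.freqs[0])
    vg = 2 * p * (1 - p)
    eg2 = vg + (2 * p) ** 2
    va = config.var_age
    var = (
        config.beta_g**2 * vg
        + config.beta_age**2 * va
        + config.beta_gxage**2 * eg2 * va
        + 2 * config.beta_age * config.beta_gxage * (2 * p) * va
        + config.sex_effect**2 * 0.25
        + config.sex_age_effect**2 * 0.25 * va
    )
    return float(var)


def _noise_sds(config: SimConfig) -> tuple[float, float]:
    if config.intercept_sd is not None and config.visit_sd is not None:
        return config.intercept_sd, config.visit_sd
    if config.r_y1y2 is None:
        raise ValueError("provide either intercept_sd/visit_sd or r_y1y2")
    return calibrate_noise(
        config.r_y1y2,
        config.followup_gap_mean,
        fixed_effect_variance(config),
        total_var=config.sd_y**2,
    )


def simulate_cohort(config: SimConfig, seed: int | None = None) -> CohortTable:
    """Draw a cohort from the generative model; deterministic given the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_individuals
    freqs = config.freqs

    genotypes = rng.binomial(2, freqs, size=(n, freqs.size)).astype(float)
    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    assess = config.recruitment_start + rng.uniform(0, config.recruitment_window, size=n)
    birthyear = assess - age

    sd_b, sd_e = _noise_sds(config)
    b = rng.normal(0.0, sd_b, size=n)
    mean_age = age.mean()
    g = genotypes[:, 0]

    def trajectory(age_at: np.ndarray) -> np.ndarray:
        age_c = age_at - mean_age
        y = (
            config.beta0
            + config.beta_g * g
            + config.beta_age * age_c
            + config.beta_gxage * g * age_c
            + config.sex_effect * sex
            + config.sex_age_effect * sex * age_c
            + b
        )
        v = config.violations
        if "quadratic_age_effect" in v:
            y = y + v["quadratic_age_effect"] * g * age_c**2
        if "quadratic_age_shared" in v:
            y = y + v["quadratic_age_shared"] * age_c**2
        if "birthyear_effect_on_y" in v:
            y = y + v["birthyear_effect_on_y"] * (birthyear - birthyear.mean())
        return y

    t1 = assess
    y1 = trajectory(age) + rng.normal(0.0, sd_e, size=n)

    n_rep = int(round(config.followup_fraction * n))
    rep_idx = rng.choice(n, size=n_rep, replace=False) if n_rep else np.array([], int)
    gap = rng.normal(config.followup_gap_mean, config.followup_gap_sd, size=n_rep)
    gap = np.clip(gap, 0.1, None)
    age2 = age[rep_idx] + gap
    t2 = t1[rep_idx] + gap
    age_f = age.copy()
    age_f[rep_idx] = age2
    y2 = trajectory(age_f)[rep_idx] + rng.normal(0.0, sd_e, size=n_rep)

    v = config.violations
    if "calendar_time_effect" in v:
        kappa = v["calendar_time_effect"]
        ref = config.recruitment_start
        y1 = y1 + kappa * (t1 - ref)
        y2 = y2 + kappa * (t2 - ref)

    ids = np.arange(n)
    samples = pd.DataFrame(
        {"id": ids, "sex": sex.astype(int), "age": age, "birthyear": birthyear, "assess_date": assess}
    )
    variants = pd.DataFrame(
        {
            "variant": [f"sim{j + 1}" for j in range(freqs.size)],
            "chrom": "1",
            "pos": 1_000_000 * (np.arange(freqs.size) + 1),
            "ea": "A",
            "oa": "G",
            "eaf": freqs,
        }
    )
    visits = pd.concat(
        [
            pd.DataFrame({"id": ids, "visit": "baseline", "time": t1, "age": age, "y": y1}),
            pd.DataFrame(
                {"id": ids[rep_idx], "visit": "first_repeat", "time": t2, "age": age2, "y": y2}
            ),
        ],
        ignore_index=True,
    )
    cohort = CohortTable(samples=samples, genotypes=genotypes, variants=variants, visits=visits, config=config)

    if "birthyear_effect_on_g" in v:
        cohort = apply_violation(cohort, "birthyear_effect_on_g", v["birthyear_effect_on_g"], rng=rng)
    if "genotype_dependent_dropout" in v:
        cohort = apply_violation(
            cohort, "genotype_dependent_dropout", v["genotype_dependent_dropout"], rng=rng
        )
    return cohort


def apply_violation(
    cohort: CohortTable,
    switch: str,
    magnitude: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> CohortTable:
    """Apply one assumption violation to an existing cohort.

    ``birthyear_effect_on_g`` re-draws dosages with the allele frequency
    drifting linearly over birthyear (trait columns untouched — intended for
    genotype-age sensitivity calibration). ``genotype_dependent_dropout``
    removes older effect-allele carriers with probability
    ``1 - exp(-magnitude * G * max(age - mean_age, 0))``. The deterministic
    trait-level switches (calendar trend, birthyear trait effect, trajectory
    curvature) add the corresponding term to the visit values in place.
    A magnitude of zero always returns the cohort unchanged.
    """
    if switch not in VIOLATION_SWITCHES:
        raise ValueError(f"unknown violation switch {switch!r}")
    if magnitude == 0:
        return cohort
    rng = rng or np.random.default_rng(seed)
    samples = cohort.samples.copy()
    visits = cohort.visits.copy()
    genotypes = cohort.genotypes.copy()

    if switch == "birthyear_effect_on_g":
        by = samples["birthyear"].to_numpy()
        by_c = by - by.mean()
        for j, p0 in enumerate(cohort.variants["eaf"].to_numpy()):
            p = np.clip(p0 + magnitude * by_c, 1e-4, 1 - 1e-4)
            genotypes[:, j] = rng.binomial(2, p).astype(float)
        return CohortTable(samples, genotypes, cohort.variants.copy(), visits, cohort.config)

    if switch == "genotype_dependent_dropout":
        age = samples["age"].to_numpy()
        g = genotypes[:, 0]
        p_drop = 1.0 - np.exp(-magnitude * g * np.clip(age - age.mean(), 0, None))
        keep = rng.uniform(size=len(samples)) >= p_drop
        kept_ids = samples.loc[keep, "id"]
        return CohortTable(
            samples.loc[keep].reset_index(drop=True),
            genotypes[keep],
            cohort.variants.copy(),
            visits[visits["id"].isin(kept_ids)].reset_index(drop=True),
            cohort.config,
        )

    idx = samples.set_index("id")
    vis_ids = visits["id"].to_numpy()
    if switch == "calendar_time_effect":
        ref = visits.loc[visits["visit"] == "baseline", "time"].min()
        visits["y"] = visits["y"] + magnitude * (visits["time"] - ref)
    elif switch == "birthyear_effect_on_y":
        by = idx.loc[vis_ids, "birthyear"].to_numpy()
        visits["y"] = visits["y"] + magnitude * (by - by.mean())
    else:  # quadratic switches
        mean_age = samples["age"].mean()
        age_c = visits["age"].to_numpy() - mean_age
        if switch == "quadratic_age_effect":
            pos = idx.index.get_indexer(vis_ids)
            visits["y"] = visits["y"] + magnitude * genotypes[pos, 0] * age_c**2
        else:
            visits["y"] = visits["y"] + magnitude * age_c**2
    return CohortTable(samples, genotypes, cohort.variants.copy(), visits, cohort.config)


def config_to_design(config: SimConfig, trait_name: str = "simulated"):
    """Analytic :class:`~gxagechange.designs.TraitDesign` matching a config.

    ``sd_y`` is set so that the single-test noncentrality implied by the
    design equals the exact OLS noncentrality of the generative model: the
    residual variance of the fitted interaction model (person intercept plus
    visit noise) plus the focal term's own contribution. ``sd_change``
    follows from the visit-noise variance: Var((Y2-Y1)/gap) at the mean gap
    is ``2 * var_e / gap^2`` around the genotype-dependent slope.
    """
    from .designs import TraitDesign

    sd_b, sd_e = _noise_sds(config)
    var_resid = sd_b**2 + sd_e**2
    p = float(config.freqs[0])
    vg = 2 * p * (1 - p)
    gap = config.followup_gap_mean
    var_change_resid = 2 * sd_e**2 / gap**2
    n = config.n_individuals
    n_long = int(round(config.followup_fraction * n))
    return TraitDesign(
        trait_name=trait_name,
        n_cross=n - n_long,
        n_long=n_long,
        sd_y=float(np.sqrt(var_resid + config.beta_gxage**2 * vg * config.var_age)),
        sd_change=float(np.sqrt(var_change_resid + config.beta_gxage**2 * vg)),
        medium_marginal=config.beta_g,
        allele_freq=p,
        var_age=config.var_age,
        age_diff=gap,
        r_y1y2=config.r_y1y2 if config.r_y1y2 is not None else 0.9,
    )


def monte_carlo_power(
    config: SimConfig,
    analysis: str,
    reps: int,
    alpha: float = 5e-8,
    alpha_validation: float = 5e-3,
    seed: int = 0,
) -> dict:
    """Empirical power of an analysis route over simulated replicates.

    ``analysis`` is one of ``gxage`` (two-sided interaction test in the
    cross-sectional-only subset), ``change`` (two-sided annual-change test in
    the longitudinal subset) or ``2stage`` (interaction test at ``alpha``
    followed by a direction-consistent one-sided change test at
    ``alpha_validation``). Returns the rejection fraction with an exact 95%
    binomial confidence interval.
    """
    from .assoc import fit_change, fit_gxage

    if reps < 1:
        raise ValueError("reps must be positive")
    if analysis not in ("gxage", "change", "2stage"):
        raise ValueError(f"unknown analysis {analysis!r}")
    if analysis in ("change", "2stage") and config.followup_fraction == 0:
        raise ValueError("analysis requires longitudinal data in the config")

    ss = np.random.SeedSequence([seed, config.seed])
    hits = 0
    for child in ss.spawn(reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cohort = simulate_cohort(config, seed=rep_seed)
        if analysis in ("gxage", "2stage"):
            cross = cohort.cross_sectional(exclude_longitudinal=True)
            rec = fit_gxage(cross, cohort.dosages(cross["id"]))
            sig = rec["p_gxage"] < alpha
        if analysis in ("change", "2stage"):
            long = cohort.longitudinal()
            ch = fit_change(long, cohort.dosages(long["id"]))
            if analysis == "change":
                sig = ch["p_change"] < alpha
            else:
                one_sided = (
                    ch["p_change"] / 2
                    if np.sign(ch["beta_change"]) == np.sign(rec["beta_gxage"])
                    else 1 - ch["p_change"] / 2
                )
                sig = sig and one_sided < alpha_validation
        hits += bool(sig)
    ci = stats.binomtest(hits, reps).proportion_ci(0.95)
    return {
        "power": hits / reps,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "hits": hits,
        "reps": reps,
    }
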