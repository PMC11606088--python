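"""Locus definition, effective-test counting, and two-level selection.

Significant variants are first merged into regions separated by more than a
base-pair distance threshold (default 500 kb, measured between nearest member
variants); within each region, loci are peeled off greedily: the most
significant remaining variant becomes an index variant and absorbs every
remaining variant correlated with it at r^2 >= 0.01. Selection routes are the
direct genome-wide interaction test or the 2-step route (genome-wide marginal
significance, then interaction at 0.05 / M_eff); validated loci are tiered by
the one-sided annual-change p value against nominal (0.05) and
Bonferroni (0.05 / M_GxAge) levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import one_sided_p

__all__ = [
    "LocusSet",
    "pairwise_r2",
    "clump",
    "estimate_meff",
    "two_step_select",
    "validate_change",
]

DISTANCE_BP = 500_000
R2_THRESHOLD = 0.01


@dataclass
class LocusSet:
    """Clumped regions and their LD-pruned index variants.

    ``regions``: one row per region (region_id, chrom, start, end,
    n_variants). ``loci``: one row per locus (region_id, locus_id,
    index_variant, chrom, pos, p, members, route).
    """

    regions: pd.DataFrame
    loci: pd.DataFrame
    m_eff: float | None = None
    thresholds: dict = field(
        default_factory=lambda: {"distance_bp": DISTANCE_BP, "r2": R2_THRESHOLD}
    )

    @property
    def m_gxage(self) -> int:
        """Number of loci (trait-level Bonferroni divisor for validation)."""
        return len(self.loci)

    def to_bed(self) -> pd.DataFrame:
        """Regions as 0-based half-open BED intervals."""
        bed = self.regions[["chrom", "start", "end", "region_id"]].copy()
        bed["start"] = bed["start"] - 1
        return bed


def pairwise_r2(panel: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns of a panel."""
    g = np.asarray(panel, dtype=float)
    sd = g.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic variant in the r2 reference panel")
    return np.corrcoef(g, rowvar=False) ** 2


def _order(records: pd.DataFrame, p_col: str) -> pd.DataFrame:
    # ties in p broken by ascending position then allele lexical order
    keys = [p_col, "pos"] + [c for c in ("ea", "oa") if c in records.columns]
    return records.sort_values(keys, kind="mergesort")


def clump(
    records: pd.DataFrame,
    r2: np.ndarray | pd.DataFrame,
    p_col: str = "p_gxage",
    distance_bp: int = DISTANCE_BP,
    r2_threshold: float = R2_THRESHOLD,
) -> LocusSet:
    """Two-level clumping of significant association records.

    ``records`` must carry variant / chrom / pos / ``p_col`` columns; ``r2``
    is a square pairwise-r^2 matrix aligned with (or labelled by, if a
    DataFrame) the records' variants. Region merging is greedy at
    ``distance_bp`` between nearest members; index selection within regions
    is by smallest p value with deterministic tie-breaking.
    """
    req = {"variant", "chrom", "pos", p_col}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if records["pos"].isna().any():
        raise ValueError("missing positions")
    if isinstance(r2, pd.DataFrame):
        missing = set(records["variant"]) - set(r2.index)
        if missing:
            raise ValueError(f"missing r2 entries for variants: {sorted(missing)}")
        r2 = r2.loc[records["variant"], records["variant"]].to_numpy()
    r2 = np.asarray(r2, dtype=float)
    if r2.shape != (len(records), len(records)):
        raise ValueError("r2 matrix must be square and aligned with records")

    recs = records.reset_index(drop=True).copy()
    recs["_i"] = np.arange(len(recs))

    region_rows, locus_rows = [], []
    region_id = 0
    for chrom, sub in recs.groupby("chrom", sort=True):
        sub = sub.sort_values(["pos", "variant"])
        pos = sub["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > distance_bp)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(sub)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            members = sub.iloc[s:e]
            region_id += 1
            region_rows.append(
                {
                    "region_id": region_id,
                    "chrom": chrom,
                    "start": int(members["pos"].min()),
                    "end": int(members["pos"].max()),
                    "n_variants": len(members),
                }
            )
            remaining = _order(members, p_col)
            locus_n = 0
            while len(remaining):
                index = remaining.iloc[0]
                ii = int(index["_i"])
                corr = r2[ii, remaining["_i"].to_numpy()] >= r2_threshold
                corr[0] = True  # the index variant always belongs to its locus
                absorbed = remaining[corr]
                locus_n += 1
                locus_rows.append(
                    {
                        "region_id": region_id,
                        "locus_id": f"{region_id}.{locus_n}",
                        "index_variant": index["variant"],
                        "chrom": chrom,
                        "pos": int(index["pos"]),
                        "p": float(index[p_col]),
                        "members": ",".join(absorbed["variant"].tolist()),
                        "n_members": int(corr.sum()),
                    }
                )
                remaining = remaining.loc[~corr]
    regions = pd.DataFrame(region_rows)
    loci = pd.DataFrame(locus_rows)
    _assert_postconditions(regions, loci, recs, r2, distance_bp, r2_threshold)
    return LocusSet(
        regions=regions,
        loci=loci,
        thresholds={"distance_bp": distance_bp, "r2": r2_threshold},
    )


def _assert_postconditions(regions, loci, recs, r2, distance_bp, r2_threshold):
    for chrom, sub in regions.groupby("chrom"):
        sub = sub.sort_values("start")
        gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
        if np.any(gaps <= distance_bp):
            raise AssertionError("regions closer than the distance threshold")
    by_variant = recs.set_index("variant")["_i"]
    for _, sub in loci.groupby("region_id"):
        idx = by_variant[sub["index_variant"]].to_numpy()
        if len(idx) > 1:
            cross = r2[np.ix_(idx, idx)]
            off = cross[~np.eye(len(idx), dtype=bool)]
            if np.any(off >= r2_threshold):
                raise AssertionError("correlated index variants within a region")
    n_assigned = sum(len(m.split(",")) for m in loci["members"])
    if n_assigned != len(recs):
        raise AssertionError("variants not partitioned into loci exactly once")


def estimate_meff(panel: np.ndarray, criterion: str = "evd", variance_explained: float = 0.995) -> float:
    """Effective number of independent tests among a set of variants.

    ``criterion="evd"``: smallest number of leading eigenvalues of the
    dosage correlation matrix explaining at least ``variance_explained`` of
    the total variance. ``criterion="li-ji"``: the Li-Ji estimator
    ``sum(I(ev >= 1) + frac(ev))`` over the eigenvalues.
    """
    g = np.asarray(panel, dtype=float)
    if g.ndim != 2 or g.shape[1] == 0:
        return 0.0
    m = g.shape[1]
    if m == 1:
        return 1.0
    corr = np.corrcoef(g, rowvar=False)
    ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
    ev = np.clip(ev, 0.0, None)
    if criterion == "evd":
        cum = np.cumsum(ev) / ev.sum()
        return float(np.searchsorted(cum, variance_explained) + 1)
    if criterion == "li-ji":
        return float(np.sum((ev >= 1).astype(float) + (ev - np.floor(ev))))
    raise ValueError(f"unknown criterion {criterion!r}")


def two_step_select(
    records: pd.DataFrame,
    m_eff: float,
    alpha_gws: float = 5e-8,
    p_col: str = "p_gxage",
    p_marginal_col: str = "p_marginal",
) -> pd.DataFrame:
    """Select significant interaction variants and record the route.

    A variant is selected when ``p_gxage < alpha_gws`` (genome-wide route) or
    when it is marginally genome-wide significant and ``p_gxage <
    0.05 / m_eff`` (2-step route).
    """
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    gw = records[p_col] < alpha_gws
    two_step = (records[p_marginal_col] < alpha_gws) & (records[p_col] < 0.05 / m_eff)
    out = records[gw | two_step].copy()
    out["route"] = np.where(gw[gw | two_step], "genome-wide", "2-step")
    return out.reset_index(drop=True)


def validate_change(
    selected: pd.DataFrame,
    change_records: pd.DataFrame,
    m_gxage: int,
    gxage_col: str = "beta_gxage",
) -> pd.DataFrame:
    """Tier selected index variants by longitudinal change validation.

    One-sided change p values are taken in the direction of the discovery
    interaction effect (effects must already be aligned to the marginally
    trait-increasing allele). Tiers: ``bonferroni`` (p < 0.05 / M_GxAge),
    ``nominal`` (p < 0.05), ``none`` otherwise, ``untested`` when the variant
    has no longitudinal record.
    """
    if m_gxage < 1:
        raise ValueError("m_gxage must be >= 1")
    ch = change_records.set_index("variant")
    rows = []
    for rec in selected.itertuples(index=False):
        row = rec._asdict()
        if rec.variant not in ch.index:
            row.update({"p_change_1sided": np.nan, "tier": "untested"})
            rows.append(row)
            continue
        c = ch.loc[rec.variant]
        ref = getattr(rec, gxage_col)
        p1 = one_sided_p(float(c["p_change"]), float(c["beta_change"]), ref)
        consistent = np.sign(c["beta_change"]) == np.sign(ref)
        if consistent and p1 < 0.05 / m_gxage:
            tier = "bonferroni"
        elif consistent and p1 < 0.05:
            tier = "nominal"
        else:
            tier = "none"
        row.update(
            {
                "beta_change": float(c["beta_change"]),
                "se_change": float(c["se_change"]),
                "p_change_1sided": p1,
                "tier": tier,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
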