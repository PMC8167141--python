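"""Epigenome-wide association of methylation with chronological age.

For one (species, tissue) cell the scan computes, per probe, the Pearson
correlation r between beta values and untransformed chronological age on
pairwise-complete observations, the Fisher z statistic

    z = atanh(r) * sqrt(n - 3)

and a two-sided p-value from the standard normal.  Downstream utilities
reproduce the usual multi-species summaries: per-direction capped top-CpG
sets, exclusive intersection (upset) counts across species/tissues,
distribution of selected CpGs over TSS-relative region classes, and the
CpG-island versus non-island contrast of z scores.

Nominal thresholds are used throughout (no multiple-testing correction):
selection thresholds and per-direction caps, not FDR, define the reported
sets.  z for a perfect |r| = 1 is capped at +/-40 to keep rankings finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import REGION_CLASSES, Cohort

__all__ = [
    "EwasResult",
    "TopSet",
    "fisher_z",
    "ewas_age",
    "select_top",
    "overlap_counts",
    "region_distribution",
    "island_contrast",
    "top_loci",
]

Z_CAP = 40.0


@dataclass
class EwasResult:
    species: str
    tissue: str
    table: pd.DataFrame  # index probe_id; columns n, r, z, p, direction

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TopSet:
    species: str
    tissue: str
    probe_ids: list
    p_threshold: float
    cap: int

    @property
    def label(self) -> str:
        return f"{self.species}/{self.tissue}"

    def __len__(self) -> int:
        return len(self.probe_ids)


def fisher_z(r, n):
    """Fisher z statistic atanh(r) * sqrt(n - 3), capped at +/-40."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1.0, 1.0)) * np.sqrt(np.maximum(n - 3.0, 0.0))
    return np.clip(z, -Z_CAP, Z_CAP)


def ewas_age(
    cohort: Cohort, species: str, tissue: str, transformed: bool = False
) -> EwasResult:
    """Per-probe age association in one (species, tissue) cell.

    Probes with a constant beta profile (or fewer than 4 paired
    observations) have undefined correlation; they are kept in the table
    with NaN statistics and excluded from any ranking.  Set
    ``transformed=True`` to correlate against transformed age instead of
    chronological years.
    """
    mask = (cohort.sheet["species"] == species) & (cohort.sheet["tissue"] == tissue)
    mask &= cohort.sheet["age_years"].notna()
    ids = cohort.sheet.loc[mask, "sample_id"].tolist()
    if len(ids) < 4:
        raise ValueError(
            f"need >= 4 aged samples for EWAS in ({species}, {tissue}); got {len(ids)}"
        )
    ages = cohort.sheet.set_index("sample_id").loc[ids, "age_years"].to_numpy(float)
    if transformed:
        tr = cohort.transform_for(species)
        ages = np.asarray(tr(ages))
    x = cohort.beta[ids].to_numpy(dtype=float)

    obs = ~np.isnan(x)
    n = obs.sum(axis=1).astype(float)
    a = np.where(obs, ages[None, :], 0.0)
    xs = np.where(obs, x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = xs.sum(axis=1) / n
        mean_a = a.sum(axis=1) / n
        cov = (xs * a).sum(axis=1) / n - mean_x * mean_a
        var_x = (xs**2).sum(axis=1) / n - mean_x**2
        var_a = (a**2).sum(axis=1) / n - mean_a**2
        r = cov / np.sqrt(np.clip(var_x, 0, None) * np.clip(var_a, 0, None))
    undefined = (n < 4) | ~np.isfinite(r)
    r = np.clip(r, -1.0, 1.0)
    # snap numerically-perfect correlations so they hit the z cap
    r = np.where(np.abs(r) > 1 - 1e-12, np.sign(r), r)
    r = np.where(undefined, np.nan, r)
    z = np.where(undefined, np.nan, fisher_z(np.nan_to_num(r), n))
    p = np.where(undefined, np.nan, 2.0 * stats.norm.sf(np.abs(np.nan_to_num(z))))
    p = np.where(np.isnan(p), np.nan, np.maximum(p, np.finfo(float).tiny))
    table = pd.DataFrame(
        {
            "n": n.astype(int),
            "r": r,
            "z": z,
            "p": p,
            "direction": np.where(np.isnan(r), 0, np.sign(r)).astype(int),
        },
        index=cohort.beta.index,
    )
    return EwasResult(species=species, tissue=tissue, table=table)


def select_top(res: EwasResult, p_thresh: float = 1e-4, cap: int = 500) -> TopSet:
    """Significant probes, at most ``cap`` per direction ranked by |z|.

    Ties in |z| are broken by probe id (ascending) for determinism.
    """
    t = res.table.dropna(subset=["z", "p"])
    sig = t[t["p"] < p_thresh]
    chosen: list = []
    for direction in (1, -1):
        d = sig[np.sign(sig["z"]) == direction]
        order = np.lexsort((d.index.to_numpy(), -d["z"].abs().to_numpy()))
        chosen.extend(d.index[order][:cap].tolist())
    return TopSet(
        species=res.species,
        tissue=res.tissue,
        probe_ids=sorted(chosen),
        p_threshold=p_thresh,
        cap=cap,
    )


def overlap_counts(sets: list[TopSet]) -> pd.DataFrame:
    """Exclusive intersection-region counts (upset-plot counts).

    For every non-empty subset of the input sets, counts the probes that
    belong to exactly those sets and no others.  Counts over the disjoint
    regions sum to the size of the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets for overlap counts")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        labels = [f"{s.label}#{i}" for i, s in enumerate(sets)]
    members = {lab: set(s.probe_ids) for lab, s in zip(labels, sets)}
    universe = set().union(*members.values())
    region_of: dict[frozenset, int] = {}
    for probe in universe:
        region = frozenset(lab for lab in labels if probe in members[lab])
        region_of[region] = region_of.get(region, 0) + 1
    rows = []
    for size in range(1, len(labels) + 1):
        for combo in combinations(labels, size):
            key = frozenset(combo)
            rows.append(
                {"region": "&".join(combo), "degree": size, "count": region_of.get(key, 0)}
            )
    return pd.DataFrame(rows)


def region_distribution(top: TopSet, ann: pd.DataFrame) -> pd.Series:
    """Proportion of selected CpGs in each TSS-relative region class."""
    if len(top) == 0:
        warnings.warn(f"empty top set for {top.label}; no distribution", stacklevel=2)
        return pd.Series(dtype=float)
    ann = ann.set_index("probe_id")
    missing = [p for p in top.probe_ids if p not in ann.index]
    if missing:
        raise ValueError(f"unannotated probe(s): {missing[:10]}")
    counts = (
        ann.loc[top.probe_ids, "region_class"]
        .value_counts()
        .reindex(REGION_CLASSES, fill_value=0)
    )
    return counts / counts.sum()


def island_contrast(res: EwasResult, ann: pd.DataFrame) -> dict:
    """CpG-island vs non-island contrast of the age-association z scores.

    Returns the two stratum medians, the percent difference
    100 * (median_island - median_nonisland) / |median_nonisland|, and a
    two-sided Mann-Whitney p-value.
    """
    ann = ann.set_index("probe_id")
    t = res.table.dropna(subset=["z"])
    status = ann.reindex(t.index)["island_status"]
    z_island = t.loc[status == "island", "z"].to_numpy()
    z_non = t.loc[status == "non-island", "z"].to_numpy()
    if len(z_island) == 0 or len(z_non) == 0:
        raise ValueError("both island and non-island strata must be non-empty")
    med_i, med_n = float(np.median(z_island)), float(np.median(z_non))
    if med_n == 0:
        pct = float("inf") if med_i != 0 else 0.0
    else:
        pct = 100.0 * (med_i - med_n) / abs(med_n)
    if np.array_equal(np.sort(z_island), np.sort(z_non)):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(z_island, z_non, alternative="two-sided").pvalue)
    return {
        "median_z_island": med_i,
        "median_z_nonisland": med_n,
        "percent_difference": pct,
        "p_value": p,
    }


def top_loci(
    res: EwasResult, ann: pd.DataFrame, p_thresh: float = 1e-3, k: int = 10
) -> pd.DataFrame:
    """Top-k probes by |z| at a nominal threshold, labeled by nearest gene."""
    t = res.table.dropna(subset=["z", "p"])
    sig = t[t["p"] < p_thresh].copy()
    order = np.lexsort((sig.index.to_numpy(), -sig["z"].abs().to_numpy()))
    sig = sig.iloc[order].head(k)
    ann = ann.set_index("probe_id")
    out = sig.copy()
    out["nearest_gene"] = ann.reindex(sig.index)["nearest_gene"]
    out["region_class"] = ann.reindex(sig.index)["region_class"]
    out.index.name = "probe_id"
    return out.reset_index()
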