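"""Calling and summarising sizable regions of homozygosity disequilibrium.

A region of HD is a maximal run of consecutive anchors whose intensity is at
or above a threshold (default 0.9) spanning at least a minimum length
(default 5 Mb), measured anchor-to-anchor from the first to the last
qualifying anchor. Regions are per individual; overlap among relatives is a
reporting matter, never a merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intensity import HomozygosityProfile

HD_INTENSITY_THRESHOLD = 0.9
HD_MIN_LENGTH_MB = 5.0

REGION_COLUMNS = [
    "individual", "chrom", "start_bp", "end_bp", "length_mb", "mean_intensity", "n_anchors",
]


def call_hd_regions(
    profile: HomozygosityProfile,
    threshold: float = HD_INTENSITY_THRESHOLD,
    min_length_mb: float = HD_MIN_LENGTH_MB,
) -> pd.DataFrame:
    """Call HD regions from an intensity profile.

    Both rules are inclusive: anchors qualify at intensity >= ``threshold``
    and a run is emitted when its span reaches ``min_length_mb``. Anchors
    with missing intensity break runs. Returns one row per (individual,
    region) with 1-based inclusive bp bounds.
    """
    records = []
    for chrom in profile.anchors["chrom"].drop_duplicates():
        sub = profile.for_chromosome(chrom)
        pos = sub.anchors["pos"].to_numpy()
        for i, individual in enumerate(sub.individuals):
            vals = sub.intensity[i]
            qual = (~np.isnan(vals)) & (vals >= threshold)
            for start, stop in _runs(qual):
                span_mb = (pos[stop - 1] - pos[start]) / 1e6
                if span_mb >= min_length_mb:
                    records.append(
                        (
                            individual, chrom, int(pos[start]), int(pos[stop - 1]),
                            span_mb, float(np.mean(vals[start:stop])), stop - start,
                        )
                    )
    return pd.DataFrame(records, columns=REGION_COLUMNS)


def _runs(mask: np.ndarray):
    """Yield (start, stop) half-open index bounds of maximal True runs."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.where(padded == 1)[0]
    stops = np.where(padded == -1)[0]
    yield from zip(starts, stops)


@dataclass
class RegionSummary:
    """Cohort-level summary of called HD regions."""

    n_individuals: int
    n_regions: int
    carrier_fraction: float
    length_quantiles: pd.Series  # min/q1/median/q3/max over region lengths (Mb)
    total_length_quantiles: pd.Series  # same over per-carrier total lengths (Mb)
    per_individual: pd.DataFrame  # individual, n_regions, total_length_mb


_QUANTILE_NAMES = ["min", "q1", "median", "q3", "max"]


def _five_number(values: np.ndarray) -> pd.Series:
    if values.size == 0:
        return pd.Series([np.nan] * 5, index=_QUANTILE_NAMES, dtype=float)
    # linear interpolation (type 7), numpy's default
    q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0])
    return pd.Series(q, index=_QUANTILE_NAMES)


def summarize_regions(regions: pd.DataFrame, n_individuals: int) -> RegionSummary:
    """Summarise region lengths, per-individual totals, and carrier fraction."""
    if regions.empty:
        per_ind = pd.DataFrame(columns=["individual", "n_regions", "total_length_mb"])
        return RegionSummary(
            n_individuals=n_individuals, n_regions=0, carrier_fraction=0.0,
            length_quantiles=_five_number(np.array([])),
            total_length_quantiles=_five_number(np.array([])),
            per_individual=per_ind,
        )
    per_ind = (
        regions.groupby("individual", sort=False)
        .agg(n_regions=("length_mb", "size"), total_length_mb=("length_mb", "sum"))
        .reset_index()
    )
    return RegionSummary(
        n_individuals=n_individuals,
        n_regions=len(regions),
        carrier_fraction=len(per_ind) / n_individuals,
        length_quantiles=_five_number(regions["length_mb"].to_numpy()),
        total_length_quantiles=_five_number(per_ind["total_length_mb"].to_numpy()),
        per_individual=per_ind,
    )


def regions_to_bed(regions: pd.DataFrame, path: str) -> None:
    """Write regions as BED (0-based half-open), individual ID in the name column."""
    if regions.empty:
        with open(path, "w"):
            pass
        return
    bed = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start_bp"] - 1,
            "end": regions["end_bp"],
            "name": regions["individual"],
            "score": np.minimum(
                1000, (regions["mean_intensity"].astype(float) * 1000).round().astype(int)
            ),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def overlap_report(regions: pd.DataFrame, pedigrees: pd.Series | dict) -> pd.DataFrame:
    """Pairs of individuals in the same pedigree with overlapping HD regions.

    ``pedigrees`` maps individual ID -> pedigree label. Reports one row per
    overlapping pair of regions (familial-aggregation view); regions are
    never merged across individuals.
    """
    ped = pd.Series(pedigrees)
    rows = []
    df = regions.assign(ped=regions["individual"].map(ped))
    for (chrom, pedigree), sub in df.groupby(["chrom", "ped"]):
        recs = sub.to_dict("records")
        for a in range(len(recs)):
            for b in range(a + 1, len(recs)):
                r1, r2 = recs[a], recs[b]
                if r1["individual"] == r2["individual"]:
                    continue
                lo = max(r1["start_bp"], r2["start_bp"])
                hi = min(r1["end_bp"], r2["end_bp"])
                if lo <= hi:
                    rows.append(
                        (chrom, pedigree, r1["individual"], r2["individual"],
                         lo, hi, (hi - lo) / 1e6)
                    )
    return pd.DataFrame(
        rows,
        columns=["chrom", "ped", "individual_a", "individual_b",
                 "overlap_start_bp", "overlap_end_bp", "overlap_mb"],
    )
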