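"""Region-level 4C profile comparison and rank-based statistics.

Quantifies smoothed (optionally decay-corrected) fragment scores inside
named regions of interest (regulatory islands, zones), computes log2 fold
changes of a sample against the mean of wild-type replicates, and tests
group differences with the two-sided Wilcoxon rank-sum test followed by
Benjamini–Hochberg correction across the tested region family.  For three
or more groups a Kruskal–Wallis test with Dunn's pairwise post-hoc z tests
(BH-adjusted) is provided.

Small tie-free samples (both n <= 8 by default) use the exact rank-sum
null distribution; larger or tied samples use the normal approximation
with tie and continuity corrections.  Significance thresholds are reported
alongside the statistics, never used to filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant4c import FragmentProfile


@dataclass
class RegionSet:
    """Named half-open genomic intervals: name -> (chrom, start, end)."""

    regions: Dict[str, Tuple[str, int, int]]

    def __post_init__(self) -> None:
        for name, (chrom, start, end) in self.regions.items():
            if start >= end:
                raise ValueError(f"region {name!r}: start must be < end")

    def __iter__(self):
        return iter(self.regions.items())

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        regions: Dict[str, Tuple[str, int, int]] = {}
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"region_{i}"
                if name in regions:
                    raise ValueError(f"duplicate region name {name!r}")
                regions[name] = (chrom, start, end)
        return cls(regions)


def quantify_region(
    profile: FragmentProfile, region: Tuple[str, int, int]
) -> np.ndarray:
    """Scores of non-excluded fragments whose midpoint lies in ``region``,
    in genomic order."""
    chrom, start, end = region
    if chrom != profile.viewpoint.chrom:
        raise ValueError("region is on a different chromosome than the profile")
    mids = profile.midpoints()
    sel = (mids >= start) & (mids < end) & ~profile.excluded_mask
    if not sel.any():
        raise ValueError(f"region {chrom}:{start}-{end} overlaps no usable fragment")
    return profile.scores[sel]


def log2_ratio(
    sample: FragmentProfile, wt_profiles: Sequence[FragmentProfile]
) -> np.ma.MaskedArray:
    """Per-fragment log2(sample / mean of wild-type replicates).

    Fragments where either term is 0 (or excluded) are masked rather than
    pseudocounted.
    """
    if not wt_profiles:
        raise ValueError("need at least one wild-type profile")
    wt_mean = np.mean([p.scores for p in wt_profiles], axis=0)
    if len(wt_mean) != len(sample.scores):
        raise ValueError("profiles must share the fragment map")
    defined = (sample.scores > 0) & (wt_mean > 0)
    ratios = np.zeros_like(sample.scores)
    ratios[defined] = np.log2(sample.scores[defined] / wt_mean[defined])
    return np.ma.MaskedArray(ratios, mask=~defined)


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], exact_threshold: int = 8
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both samples have <= ``exact_threshold``
    observations and no ties; otherwise the normal approximation with tie
    and continuity corrections.  Fully tied data yields p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(a) <= exact_threshold and len(b) <= exact_threshold:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR q-values (delegated to statsmodels)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_bh(
    group_a: Dict[str, Sequence[float]],
    group_b: Dict[str, Sequence[float]],
    alpha: float = 0.05,
    exact_threshold: int = 8,
) -> pd.DataFrame:
    """Per-region rank-sum tests with BH correction across the region family.

    ``group_a`` and ``group_b`` map region name -> score vector; the same
    region names must appear in both.  Returns one row per region with
    group sizes, means, log2 fold change (A over B; NaN when a mean is 0),
    raw p, BH q, and a significance call at ``alpha`` (reported, not used
    to filter).
    """
    if set(group_a) != set(group_b):
        raise ValueError("group_a and group_b must cover the same regions")
    rows = []
    names = list(group_a)
    for name in names:
        a = np.asarray(group_a[name], dtype=float)
        b = np.asarray(group_b[name], dtype=float)
        p = rank_sum_test(a, b, exact_threshold=exact_threshold)
        mean_a, mean_b = a.mean(), b.mean()
        log2fc = (
            float(np.log2(mean_a / mean_b)) if mean_a > 0 and mean_b > 0 else np.nan
        )
        rows.append(
            dict(
                region=name,
                n_a=len(a),
                n_b=len(b),
                mean_a=mean_a,
                mean_b=mean_b,
                log2fc=log2fc,
                p_value=p,
            )
        )
    df = pd.DataFrame(rows)
    df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] < alpha
    df.attrs["alpha"] = alpha
    return df


def quantify_and_test(
    profiles_a: Sequence[FragmentProfile],
    profiles_b: Sequence[FragmentProfile],
    regions: RegionSet,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pool region scores across replicates of each condition and run
    :func:`wilcoxon_bh` over the region family."""
    ga = {
        name: np.concatenate([quantify_region(p, r) for p in profiles_a])
        for name, r in regions
    }
    gb = {
        name: np.concatenate([quantify_region(p, r) for p in profiles_b])
        for name, r in regions
    }
    return wilcoxon_bh(ga, gb, alpha=alpha)


def kruskal_dunn(
    groups: Dict[str, Sequence[float]], alpha: float = 0.05
) -> Tuple[float, float, pd.DataFrame]:
    """Kruskal–Wallis H (tie-corrected) plus Dunn's pairwise post-hoc tests.

    Dunn's z for groups i, j compares mean ranks in the pooled ranking:
    z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) (1/n_i + 1/n_j)) with the tie
    term T = Σ(t³−t) / (12(N−1)).  Pairwise two-sided normal p-values are
    BH-adjusted across all pairs.

    Returns (H, kruskal_p, pairwise DataFrame).
    """
    if len(groups) < 3:
        raise ValueError("kruskal_dunn requires >= 3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        names = list(arrays)
        pairs = pd.DataFrame(
            [
                dict(group_1=i, group_2=j, z=0.0, p_value=1.0)
                for i, j in combinations(names, 2)
            ]
        )
        pairs["p_adjusted"] = 1.0
        pairs["significant"] = False
        return 0.0, 1.0, pairs

    h_stat, kw_p = stats.kruskal(*arrays.values())

    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: Dict[str, float] = {}
    offset = 0
    for k, v in arrays.items():
        mean_ranks[k] = float(ranks[offset : offset + len(v)].mean())
        offset += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in combinations(arrays, 2):
        se = np.sqrt(var_base * (1 / len(arrays[i]) + 1 / len(arrays[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append(dict(group_1=i, group_2=j, z=float(z), p_value=float(p)))
    pairs = pd.DataFrame(rows)
    pairs["p_adjusted"] = benjamini_hochberg(pairs["p_value"].to_numpy())
    pairs["significant"] = pairs["p_adjusted"] < alpha
    return float(h_stat), float(kw_p), pairs


def write_region_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
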