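"""Standard 4C-seq fragment-level quantification.

Turns a single-end 4C library into a per-fragment contact profile of one
viewpoint: reads are assigned to the restriction fragment whose ligation
junction they capture, fragments directly surrounding the viewpoint are
excluded, counts are normalized to reads-per-million of mapped reads,
smoothed with an 11-fragment running mean, rescaled so the mean score in a
bait ± 1 Mb window is 1, and optionally corrected for the power-law decay
of contact frequency with genomic distance (slope −1 in log-log scale).
Replicates are combined by averaging the resulting signal densities.

Profiles advance through explicit stages (normalized → smoothed →
bait_normalized → corrected → averaged) so downstream quantification knows
what it is looking at.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .fragmap import FragmentMap, Genome
from .reads import RawRead
from .seqindex import GenomeIndex

STAGES = ("normalized", "smoothed", "bait_normalized", "corrected", "averaged")


@dataclass(frozen=True)
class ViewpointSpec:
    """Bait locus of a 4C experiment.

    ``primer_tag`` is the constant 5' sequence preceding the captured CATG
    in every read; ``exclusion_radius`` is the +/- window around the bait
    whose fragments are removed from the analysis (2 kb by default).
    """

    name: str
    chrom: str
    bait_start: int
    bait_end: int
    primer_tag: str
    exclusion_radius: int = 2_000

    def __post_init__(self) -> None:
        if self.bait_start >= self.bait_end:
            raise ValueError("bait_start must be < bait_end")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")

    @property
    def bait_midpoint(self) -> float:
        return (self.bait_start + self.bait_end) / 2.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ViewpointSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class FragmentCounts:
    viewpoint: ViewpointSpec
    fragment_map: FragmentMap
    counts: np.ndarray  # per fragment of viewpoint.chrom
    total_mapped: int
    excluded_mask: np.ndarray = field(default=None)
    qc: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.fragment_map.n_fragments(self.viewpoint.chrom)
        if len(self.counts) != n:
            raise ValueError("counts length must equal the number of fragments")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() > self.total_mapped:
            raise ValueError("counts exceed total_mapped")
        if self.excluded_mask is None:
            self.excluded_mask = np.zeros(n, dtype=bool)


@dataclass
class FragmentProfile:
    viewpoint: ViewpointSpec
    fragment_map: FragmentMap
    scores: np.ndarray
    stage: str
    excluded_mask: np.ndarray
    window: int = 0  # smoothing window, 11 when smoothed

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores[self.excluded_mask] != 0).any():
            raise ValueError("excluded fragments must carry score 0")

    def midpoints(self) -> np.ndarray:
        frags = self.fragment_map.fragments[self.viewpoint.chrom]
        return np.array([f.midpoint for f in frags])

    def distances(self) -> np.ndarray:
        """Fragment-midpoint to bait-midpoint distance (bp)."""
        return np.abs(self.midpoints() - self.viewpoint.bait_midpoint)

    def _advance(self, new_stage: str, **kw) -> "FragmentProfile":
        if STAGES.index(new_stage) <= STAGES.index(self.stage):
            raise ValueError(
                f"stage may only advance ({self.stage!r} -> {new_stage!r})"
            )
        return replace(self, stage=new_stage, **kw)


def assign_reads(
    reads: Sequence[RawRead],
    fmap: FragmentMap,
    genome: Genome,
    vp: ViewpointSpec,
    index: Optional[GenomeIndex] = None,
) -> FragmentCounts:
    """Count reads per restriction fragment by exact-unique matching.

    Each read must contain the viewpoint primer tag; the captured sequence
    from the first CATG after the tag is searched on both strands of the
    genome.  A unique hit increments the fragment containing the match
    start; ambiguous (>=2 loci) and unmatched reads are discarded with a QC
    tally, as are hits on other chromosomes (cis-only quantification).
    """
    if index is None:
        index = GenomeIndex(genome)
    n = fmap.n_fragments(vp.chrom)
    counts = np.zeros(n, dtype=float)
    qc = {"no_primer": 0, "no_capture": 0, "unmatched": 0, "ambiguous": 0, "trans": 0}
    assigned = 0
    for read in reads:
        i = read.sequence.find(vp.primer_tag)
        if i == -1:
            qc["no_primer"] += 1
            continue
        j = read.sequence.find("CATG", i + len(vp.primer_tag))
        if j == -1:
            qc["no_capture"] += 1
            continue
        captured = read.sequence[j:]
        hits = index.find_all(captured)
        if not hits:
            qc["unmatched"] += 1
            continue
        if len(hits) > 1:
            qc["ambiguous"] += 1
            continue
        hit = hits[0]
        if hit.chrom != vp.chrom:
            qc["trans"] += 1
            continue
        counts[fmap.locate(hit.chrom, hit.pos)] += 1
        assigned += 1
    return FragmentCounts(
        viewpoint=vp,
        fragment_map=fmap,
        counts=counts,
        total_mapped=assigned,
        qc=qc,
    )


def exclude_viewpoint(counts: FragmentCounts, vp: Optional[ViewpointSpec] = None) -> FragmentCounts:
    """Zero every fragment overlapping bait +/- exclusion_radius.

    total_mapped is recomputed over the remaining fragments, so the
    subsequent per-million normalization refers to reads kept for analysis.
    """
    vp = vp or counts.viewpoint
    lo = vp.bait_start - vp.exclusion_radius
    hi = vp.bait_end + vp.exclusion_radius
    frags = counts.fragment_map.fragments[vp.chrom]
    mask = np.array([f.start < hi and f.end > lo for f in frags])
    new = counts.counts.copy()
    new[mask] = 0
    return FragmentCounts(
        viewpoint=vp,
        fragment_map=counts.fragment_map,
        counts=new,
        total_mapped=int(new.sum()),
        excluded_mask=counts.excluded_mask | mask,
        qc=dict(counts.qc, viewpoint_excluded=int(counts.counts[mask].sum())),
    )


def normalize_total(counts: FragmentCounts) -> FragmentProfile:
    """Reads-per-million of mapped reads."""
    if counts.total_mapped <= 0:
        raise ValueError("cannot normalize: total_mapped is 0")
    scores = counts.counts / counts.total_mapped * 1e6
    return FragmentProfile(
        viewpoint=counts.viewpoint,
        fragment_map=counts.fragment_map,
        scores=scores,
        stage="normalized",
        excluded_mask=counts.excluded_mask.copy(),
    )


def smooth(profile: FragmentProfile, window: int = 11) -> FragmentProfile:
    """Running mean over ``window`` fragments, shrinking at chromosome edges.

    Excluded fragments contribute 0 to their neighbours' means and stay at
    score 0 themselves.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    sm = (
        pd.Series(profile.scores)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    sm[profile.excluded_mask] = 0.0
    return profile._advance("smoothed", scores=sm, window=window)


def bait_normalize(
    profile: FragmentProfile, vp: Optional[ViewpointSpec] = None, half_width: int = 1_000_000
) -> FragmentProfile:
    """Divide by the mean score of non-excluded fragments whose midpoint
    lies within bait +/- ``half_width``; that window's mean becomes 1."""
    vp = vp or profile.viewpoint
    mids = profile.midpoints()
    in_window = (
        (mids >= vp.bait_start - half_width)
        & (mids < vp.bait_end + half_width)
        & ~profile.excluded_mask
    )
    if not in_window.any():
        raise ValueError("no non-excluded fragment in the bait window")
    mean = profile.scores[in_window].mean()
    if mean == 0:
        raise ValueError("bait-window mean is 0")
    return profile._advance("bait_normalized", scores=profile.scores / mean)


def profile_correction(
    profile: FragmentProfile,
    vp: Optional[ViewpointSpec] = None,
    alpha: float = 1.0,
    fit_range: tuple = (5_000, 2_000_000),
) -> FragmentProfile:
    """Divide out the expected power-law decay E(d) = exp(c) * d^(-alpha).

    The intercept c is the least-squares fit of log score on log distance
    with the slope fixed at -alpha — i.e. the mean of
    (log score + alpha*log d) over fragments with positive score and
    distance inside ``fit_range``.  Zero-score fragments stay 0.
    """
    vp = vp or profile.viewpoint
    d = profile.distances()
    scores = profile.scores
    eligible = (scores > 0) & (d >= fit_range[0]) & (d < fit_range[1])
    if eligible.sum() < 2:
        raise ValueError("not enough positive-score fragments in fit_range")
    c = np.mean(np.log(scores[eligible]) + alpha * np.log(d[eligible]))
    expected = np.exp(c) * np.maximum(d, 1.0) ** (-alpha)
    corrected = np.where(scores > 0, scores / expected, 0.0)
    return profile._advance("corrected", scores=corrected)


def average_replicates(profiles: List[FragmentProfile]) -> FragmentProfile:
    """Element-wise mean of replicate profiles; masks are unioned."""
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if p.stage != first.stage:
            raise ValueError("profiles must share the same stage")
        if p.viewpoint.name != first.viewpoint.name or len(p.scores) != len(
            first.scores
        ):
            raise ValueError("profiles must share viewpoint and fragment map")
    mask = np.logical_or.reduce([p.excluded_mask for p in profiles])
    mean = np.mean([p.scores for p in profiles], axis=0)
    mean[mask] = 0.0
    return FragmentProfile(
        viewpoint=first.viewpoint,
        fragment_map=first.fragment_map,
        scores=mean,
        stage="averaged",
        excluded_mask=mask,
        window=first.window,
    )


def decay_slope(
    profile: FragmentProfile, fit_range: tuple = (5_000, 2_000_000)
) -> float:
    """Free-slope least-squares fit of log score on log distance; the
    diagnostic counterpart of :func:`profile_correction`."""
    d = profile.distances()
    s = profile.scores
    eligible = (s > 0) & (d >= fit_range[0]) & (d < fit_range[1])
    if eligible.sum() < 2:
        raise ValueError("not enough positive-score fragments in fit_range")
    slope = np.polyfit(np.log(d[eligible]), np.log(s[eligible]), 1)[0]
    return float(slope)


def write_bedgraph(profile: FragmentProfile, path) -> None:
    frags = profile.fragment_map.fragments[profile.viewpoint.chrom]
    with open(path, "w") as fh:
        for f, score in zip(frags, profile.scores):
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{score:.6g}\n")


def write_profile_table(
    counts: FragmentCounts, stages: Dict[str, FragmentProfile], path
) -> None:
    """TSV with fragment coordinates, distance, raw counts and stage scores."""
    vp = counts.viewpoint
    frags = counts.fragment_map.fragments[vp.chrom]
    df = pd.DataFrame(
        {
            "chrom": [f.chrom for f in frags],
            "start": [f.start for f in frags],
            "end": [f.end for f in frags],
            "index": [f.index for f in frags],
            "distance": [abs(f.midpoint - vp.bait_midpoint) for f in frags],
            "raw_count": counts.counts.astype(int),
            "excluded": counts.excluded_mask.astype(int),
        }
    )
    for name, prof in stages.items():
        df[name] = prof.scores
    df.to_csv(path, sep="\t", index=False)


def write_stats(counts: FragmentCounts, path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(counts.qc, total_mapped=counts.total_mapped), fh, indent=2)


def quantify(
    reads: Sequence[RawRead],
    fmap: FragmentMap,
    genome: Genome,
    vp: ViewpointSpec,
    window: int = 11,
    bait_half_width: int = 1_000_000,
    correct_decay: bool = False,
    index: Optional[GenomeIndex] = None,
) -> Dict[str, object]:
    """Full single-replicate chain; returns counts and every stage profile."""
    raw = assign_reads(reads, fmap, genome, vp, index=index)
    excl = exclude_viewpoint(raw)
    normalized = normalize_total(excl)
    smoothed = smooth(normalized, window=window)
    out: Dict[str, object] = {
        "counts": excl,
        "normalized": normalized,
        "smoothed": smoothed,
        "bait_normalized": bait_normalize(smoothed, half_width=bait_half_width),
    }
    if correct_decay:
        out["corrected"] = profile_correction(smoothed)
    return out
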