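"""Disomy and segmental-duplication calling from normalized binned coverage.

A chromosome is called disomic when its median normalized coverage reaches
~2; local duplications are found by recursive binary segmentation of the
log2 coverage profile with a seeded permutation test at each candidate
split.  Whole-chromosome gains are reported as disomy calls, never as
chromosome-spanning segments: segmentation runs only on chromosomes not
called disomic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .coverage import BinnedTrack

logger = logging.getLogger(__name__)

EUPLOID_MAX_MEDIAN = 1.25
DISOMIC_MIN_MEDIAN = 1.75


@dataclass
class DisomyCall:
    sequence: str
    median: float
    status: str  # euploid / disomic / ambiguous
    euploid_max: float = EUPLOID_MAX_MEDIAN
    disomic_min: float = DISOMIC_MIN_MEDIAN


@dataclass
class SegmentCall:
    """A called coverage segment; coordinates are 0-based half-open and
    bin-aligned."""

    sequence: str
    start: int
    end: int
    start_bin: int
    end_bin: int
    mean_normalized: float
    copy_factor: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.end_bin <= self.start_bin:
            raise ValueError("segment must be non-empty")


def call_disomy(
    profile: BinnedTrack,
    euploid_max: float = EUPLOID_MAX_MEDIAN,
    disomic_min: float = DISOMIC_MIN_MEDIAN,
    min_bins: int = 20,
) -> DisomyCall:
    """Classify a chromosome from the median of its normalized coverage."""
    if profile.n_bins < min_bins:
        raise ValueError(
            f"{profile.sequence}: need >= {min_bins} bins, got {profile.n_bins}"
        )
    m = float(np.median(profile.means))
    if m < euploid_max:
        status = "euploid"
    elif m >= disomic_min:
        status = "disomic"
    else:
        status = "ambiguous"
    return DisomyCall(profile.sequence, m, status, euploid_max, disomic_min)


# ---------------------------------------------------------------------------
# binary segmentation


def _max_t_split(x: np.ndarray) -> Tuple[int, float]:
    """Best split index k (left = x[:k]) maximizing |two-sample t|."""
    n = x.size
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    k = np.arange(1, n)
    n1 = k.astype(float)
    n2 = n - n1
    s1 = cs[k - 1]
    s2 = cs[-1] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = cs2[k - 1] - n1 * m1 * m1
    ss2 = (cs2[-1] - cs2[k - 1]) - n2 * m2 * m2
    pooled = np.maximum((ss1 + ss2) / np.maximum(n - 2, 1), 0.0)
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2)) + 1e-12
    t = np.abs(m1 - m2) / denom
    best = int(np.argmax(t))
    return best + 1, float(t[best])


def _max_t_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise max |t| over all splits (vectorized permutation null)."""
    n = mat.shape[1]
    cs = np.cumsum(mat, axis=1)
    cs2 = np.cumsum(mat * mat, axis=1)
    k = np.arange(1, n)
    n1 = k.astype(float)
    n2 = n - n1
    s1 = cs[:, k - 1]
    s2 = cs[:, -1:] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = cs2[:, k - 1] - n1 * m1 * m1
    ss2 = (cs2[:, -1:] - cs2[:, k - 1]) - n2 * m2 * m2
    pooled = np.maximum((ss1 + ss2) / max(n - 2, 1), 0.0)
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2)) + 1e-12
    return np.max(np.abs(m1 - m2) / denom, axis=1)


def _posterior_median_split(x: np.ndarray, k0: int, margin: int = 3) -> int:
    """Posterior median of a single changepoint within ``x``.

    Side levels and variances are plug-in estimates from the current
    segments (``k0`` is the working boundary), trimmed ``margin`` bins away
    from it; the flat-prior posterior over split positions comes from the
    two-sided Gaussian likelihood.  More stable than the argmax when the
    two sides have unequal variances.
    """
    n = x.size
    if n < 4:
        return k0
    left = x[: max(k0 - margin, 2)]
    right = x[min(k0 + margin, n - 2):]
    mu1, v1 = float(left.mean()), float(left.var()) + 1e-12
    mu2, v2 = float(right.mean()), float(right.var()) + 1e-12
    ll1 = -0.5 * np.log(v1) - (x - mu1) ** 2 / (2.0 * v1)
    ll2 = -0.5 * np.log(v2) - (x - mu2) ** 2 / (2.0 * v2)
    c1 = np.concatenate([[0.0], np.cumsum(ll1)])
    c2 = np.concatenate([[0.0], np.cumsum(ll2)])
    ks = np.arange(1, n)
    total = c1[ks] + (c2[-1] - c2[ks])
    w = np.exp(total - total.max())
    cdf = np.cumsum(w)
    return int(ks[np.searchsorted(cdf, 0.5 * cdf[-1])])


def _split_significant(
    x: np.ndarray,
    k: int,
    t_obs: float,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> bool:
    perms = np.tile(x, (n_permutations, 1))
    rng.permuted(perms, axis=1, out=perms)
    null = _max_t_rows(perms)
    p = (1.0 + float(np.sum(null >= t_obs))) / (n_permutations + 1.0)
    return p < alpha


def segment(
    profile: BinnedTrack,
    min_bins: int = 5,
    min_abs_log2: float = 0.4,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_factor: float = 1.5,
    seed: int = 0,
    eps: Optional[float] = None,
    include_losses: bool = False,
) -> List[SegmentCall]:
    """Recursive binary segmentation of a normalized coverage profile.

    Splits maximize the two-sample t-statistic on log2(coverage + eps) and
    are accepted when a seeded permutation test gives p < ``alpha``.
    Boundaries are then refined (posterior-median relocation), adjacent
    segments whose log2 means differ by less than ``min_abs_log2`` are
    re-merged (this is where the contrast threshold applies — testing it at
    the first recursive split would dilute a mid-chromosome event's step),
    and segments shorter than ``min_bins`` are merged into the neighbor
    with the closer mean.  Only gain segments with copy factor >=
    ``min_factor`` are returned (symmetric losses at factor <=
    1/min_factor too, when ``include_losses``).
    """
    values = profile.means
    if not np.any(values > 0):
        logger.warning("%s: all-zero profile; no segment calls", profile.sequence)
        return []
    if eps is None:
        eps = 1.0 / profile.genome_mean if profile.genome_mean else 1e-3
    x = np.log2(values + eps)
    rng = np.random.default_rng(seed)

    boundaries = [0, x.size]

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2:
            return
        k_rel, t_obs = _max_t_split(x[lo:hi])
        if _split_significant(x[lo:hi], k_rel, t_obs, alpha, n_permutations, rng):
            boundaries.append(lo + k_rel)
            recurse(lo, lo + k_rel)
            recurse(lo + k_rel, hi)

    recurse(0, x.size)
    bounds = sorted(set(boundaries))

    # refine each internal boundary between its neighbors: recursion
    # conditions later splits on earlier (noisy) ones, so re-locate each
    # boundary by the posterior median of a heteroscedastic Gaussian
    # changepoint likelihood (levels/variances estimated per side)
    def refine(bounds: List[int]) -> List[int]:
        for _ in range(5):
            new = [bounds[0]]
            for i in range(1, len(bounds) - 1):
                lo, hi = new[-1], bounds[i + 1]
                new.append(lo + _posterior_median_split(x[lo:hi], bounds[i] - lo))
            new.append(bounds[-1])
            new = sorted(set(new))
            if new == bounds:
                break
            bounds = new
        return bounds

    bounds = refine(bounds)
    segs = list(zip(bounds[:-1], bounds[1:]))

    def seg_mean(s: Tuple[int, int]) -> float:
        return float(values[s[0] : s[1]].mean())

    def seg_logmean(s: Tuple[int, int]) -> float:
        return float(x[s[0] : s[1]].mean())

    # merge adjacent segments whose log2 means are closer than the split
    # threshold (a mid-event first split leaves such twins behind)
    i = 0
    while i < len(segs) - 1:
        if abs(seg_logmean(segs[i]) - seg_logmean(segs[i + 1])) < min_abs_log2:
            segs[i : i + 2] = [(segs[i][0], segs[i + 1][1])]
        else:
            i += 1

    # merge short segments into the neighbor with the closer mean
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i, (lo, hi) in enumerate(segs):
            if hi - lo < min_bins:
                m = seg_mean((lo, hi))
                left = abs(seg_mean(segs[i - 1]) - m) if i > 0 else np.inf
                right = abs(seg_mean(segs[i + 1]) - m) if i < len(segs) - 1 else np.inf
                j = i - 1 if left <= right else i + 1
                a, b = min(i, j), max(i, j)
                segs[a : b + 1] = [(segs[a][0], segs[b][1])]
                changed = True
                break

    calls: List[SegmentCall] = []
    for lo, hi in segs:
        factor = seg_mean((lo, hi))
        gain = factor >= min_factor
        loss = include_losses and factor <= 1.0 / min_factor
        if gain or loss:
            calls.append(
                SegmentCall(
                    profile.sequence,
                    int(profile.starts[lo]),
                    int(profile.ends[hi - 1]),
                    lo,
                    hi,
                    factor,
                    factor,
                    hi - lo,
                )
            )
    return calls


def compare_boundaries(a: SegmentCall, b: SegmentCall, tol_bins: int = 2) -> bool:
    """True iff both boundaries agree within ``tol_bins`` bins on the same
    sequence."""
    if a.sequence != b.sequence:
        logger.warning(
            "comparing segments on different sequences (%s vs %s)",
            a.sequence, b.sequence,
        )
        return False
    return (
        abs(a.start_bin - b.start_bin) <= tol_bins
        and abs(a.end_bin - b.end_bin) <= tol_bins
    )


def call_chromosome_cnv(
    profiles: Iterable[BinnedTrack],
    seed: int = 0,
    **segment_kwargs,
) -> Tuple[List[DisomyCall], List[SegmentCall]]:
    """Per-chromosome disomy calls, then segmentation of non-disomic
    chromosomes only (a whole-chromosome gain is a DisomyCall, not a
    chromosome-spanning SegmentCall)."""
    disomies: List[DisomyCall] = []
    segments: List[SegmentCall] = []
    for profile in profiles:
        call = call_disomy(profile)
        disomies.append(call)
        if call.status != "disomic":
            segments.extend(segment(profile, seed=seed, **segment_kwargs))
    return disomies, segments


def write_segments_bed(calls: Iterable[SegmentCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.sequence}\t{c.start}\t{c.end}\tfactor={c.copy_factor:.3f}\n"
            )


def write_disomy_csv(calls: Iterable[DisomyCall], path, strain: str = ".") -> None:
    with open(path, "w") as fh:
        fh.write("strain,sequence,median,status\n")
        for c in calls:
            fh.write(f"{strain},{c.sequence},{c.median:.4f},{c.status}\n")
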