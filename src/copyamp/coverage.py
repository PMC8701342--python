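"""Depth tracks: reading, binning, masking and normalization.

Internal coordinates are 0-based half-open.  The samtools-depth TSV dialect
(sequence, 1-based position, depth) converts at the I/O boundary; bedGraph
is already 0-based half-open.  All copy-number ratios downstream are
anchored on :func:`genome_mean_depth`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np

from .regions import RegionMask

logger = logging.getLogger(__name__)


@dataclass
class DepthTrack:
    """Per-base depth along one named sequence.

    ``positions`` are 1-based and strictly increasing; absent positions are
    depth 0.  ``depth`` is non-negative.
    """

    sequence: str
    positions: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.positions.shape != self.depth.shape:
            raise ValueError("positions and depth must have equal length")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError(f"{self.sequence}: positions not strictly increasing")
            if self.positions[0] < 1:
                raise ValueError(f"{self.sequence}: positions must be >= 1")
        if np.any(self.depth < 0):
            raise ValueError(f"{self.sequence}: negative depth")

    def __len__(self) -> int:
        return int(self.positions.size)

    def to_dense(self, length: int) -> np.ndarray:
        """Per-base depth array over [0, length); missing positions are 0."""
        if self.positions.size and int(self.positions.max()) > length:
            raise ValueError(
                f"{self.sequence}: observed position {int(self.positions.max())} "
                f"exceeds declared length {length}"
            )
        dense = np.zeros(length, dtype=float)
        dense[self.positions - 1] = self.depth
        return dense

    @classmethod
    def from_dense(cls, sequence: str, dense: np.ndarray) -> "DepthTrack":
        dense = np.asarray(dense, dtype=float)
        return cls(sequence, np.arange(1, dense.size + 1), dense)


@dataclass
class BinnedTrack:
    """Fixed-width bins tiling a sequence; the trailing bin may be partial.

    ``means`` holds the mean depth per bin (absent positions count as 0);
    ``widths`` carries each bin's true width so weighted statistics are
    exact on the partial trailing bin.
    """

    sequence: str
    starts: np.ndarray
    ends: np.ndarray
    means: np.ndarray
    bin_size: int
    genome_mean: Optional[float] = None  # set by normalize()

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.means = np.asarray(self.means, dtype=float)
        if not (self.starts.size == self.ends.size == self.means.size):
            raise ValueError("starts, ends, means must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("empty or inverted bin")

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def n_bins(self) -> int:
        return int(self.starts.size)

    @property
    def length(self) -> int:
        return int(self.ends[-1]) if self.ends.size else 0


# ---------------------------------------------------------------------------
# readers / writers


def _clean_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_depth(path, format: str = "depth-tsv") -> Dict[str, DepthTrack]:
    """Read depth from a samtools-depth TSV or a bedGraph file.

    Returns a mapping sequence name -> :class:`DepthTrack`.  Malformed rows
    raise :class:`ValueError` naming the line number.
    """
    if format not in ("depth-tsv", "bedgraph"):
        raise ValueError(f"unknown depth format {format!r}")
    per_seq_pos: Dict[str, List[int]] = {}
    per_seq_depth: Dict[str, List[float]] = {}
    for lineno, line in _clean_lines(path):
        parts = line.split("\t")
        if format == "depth-tsv":
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            seq = parts[0]
            try:
                pos, depth = int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed depth row") from exc
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth")
            per_seq_pos.setdefault(seq, []).append(pos)
            per_seq_depth.setdefault(seq, []).append(depth)
        else:
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            seq = parts[0]
            try:
                start, end, depth = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph row") from exc
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty interval")
            per_seq_pos.setdefault(seq, []).extend(range(start + 1, end + 1))
            per_seq_depth.setdefault(seq, []).extend([depth] * (end - start))
    tracks: Dict[str, DepthTrack] = {}
    for seq in per_seq_pos:
        pos = np.array(per_seq_pos[seq], dtype=np.int64)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError(f"{path}: {seq}: positions not strictly increasing")
        tracks[seq] = DepthTrack(seq, pos, np.array(per_seq_depth[seq]))
    if not tracks:
        logger.warning("%s: no depth rows found; empty track set", path)
    return tracks


def write_depth_tsv(tracks: Iterable[DepthTrack], path) -> None:
    """Write per-base depth as samtools-depth TSV (1-based positions)."""
    with open(path, "w") as fh:
        for track in tracks:
            for pos, d in zip(track.positions, track.depth):
                fh.write(f"{track.sequence}\t{pos}\t{_fmt(d)}\n")


def write_binned_tsv(tracks: Iterable[BinnedTrack], path) -> None:
    """Write binned depth as TSV rows at each bin's midpoint (1-based)."""
    with open(path, "w") as fh:
        for track in tracks:
            mids = (track.starts + track.ends) // 2 + 1
            for mid, m in zip(mids, track.means):
                fh.write(f"{track.sequence}\t{mid}\t{_fmt(m)}\n")


def write_bedgraph(tracks: Iterable[BinnedTrack], path) -> None:
    with open(path, "w") as fh:
        for track in tracks:
            for s, e, m in zip(track.starts, track.ends, track.means):
                fh.write(f"{track.sequence}\t{s}\t{e}\t{_fmt(m)}\n")


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:.6g}"


# ---------------------------------------------------------------------------
# binning and normalization


def bin_track(track: DepthTrack, bin_size: int, sequence_length: int) -> BinnedTrack:
    """Bin a per-base track into fixed-width bins tiling [0, sequence_length).

    Bin mean = sum of observed depths in the bin / true bin width, so absent
    positions count as depth 0.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if sequence_length < 1:
        raise ValueError("sequence_length must be >= 1")
    if track.positions.size and int(track.positions.max()) > sequence_length:
        raise ValueError(
            f"{track.sequence}: position {int(track.positions.max())} exceeds "
            f"declared sequence length {sequence_length}"
        )
    n_bins = -(-sequence_length // bin_size)
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    ends = np.minimum(starts + bin_size, sequence_length)
    sums = np.zeros(n_bins)
    if track.positions.size:
        idx = (track.positions - 1) // bin_size
        np.add.at(sums, idx, track.depth)
    means = sums / (ends - starts)
    return BinnedTrack(track.sequence, starts, ends, means, bin_size)


def genome_mean_depth(
    tracks: Iterable[BinnedTrack],
    exclude: Optional[RegionMask] = None,
) -> float:
    """Width-weighted mean depth over all bins, minus excluded intervals.

    Each bin's weight is its unmasked width; bins wholly inside the mask drop
    out.  Plasmid sequences must not be passed in — the caller decides what
    counts as "genome".
    """
    total = 0.0
    weight = 0.0
    for track in tracks:
        w = track.widths.astype(float)
        if exclude is not None:
            masked = np.array(
                [exclude.overlap(track.sequence, int(s), int(e))
                 for s, e in zip(track.starts, track.ends)],
                dtype=float,
            )
            w = w - masked
        total += float(np.sum(track.means * w))
        weight += float(np.sum(w))
    if weight <= 0:
        raise ValueError("no unmasked bins: cannot compute genome mean depth")
    return total / weight


def normalize(track: BinnedTrack, genome_mean: float) -> BinnedTrack:
    """Divide bin means by the genome mean; euploid expectation becomes 1.0."""
    if genome_mean <= 0:
        raise ValueError("genome_mean must be > 0")
    return BinnedTrack(
        track.sequence,
        track.starts.copy(),
        track.ends.copy(),
        track.means / genome_mean,
        track.bin_size,
        genome_mean=genome_mean,
    )
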