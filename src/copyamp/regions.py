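"""Interval masks over named sequences (0-based, half-open).

A :class:`RegionMask` is the package's single representation of "a set of
genomic intervals": excluded regions for the genome mean, plasmid/genome
shared sequence, backbone annotations, and so on.  Intervals are stored
merged and sorted per sequence.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"invalid interval ({s}, {e}): end < start")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class RegionMask:
    """A merged, sorted set of (sequence, start, end) intervals."""

    def __init__(self, intervals: Iterable[Tuple[str, int, int]] = ()) -> None:
        by_seq: Dict[str, List[Interval]] = {}
        for seq, s, e in intervals:
            by_seq.setdefault(str(seq), []).append((int(s), int(e)))
        self._ivs: Dict[str, List[Interval]] = {
            seq: merge_intervals(ivs) for seq, ivs in by_seq.items()
        }

    # -- construction -----------------------------------------------------

    @classmethod
    def from_bed(cls, path) -> "RegionMask":
        """Read a BED3+ file (``#`` headers and CRLF tolerated)."""
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\r\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
                try:
                    rows.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed BED row") from exc
        return cls(rows)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for seq, s, e in self:
                fh.write(f"{seq}\t{s}\t{e}\n")

    # -- queries ----------------------------------------------------------

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for seq in sorted(self._ivs):
            for s, e in self._ivs[seq]:
                yield seq, s, e

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivs.values())

    def __bool__(self) -> bool:
        return any(self._ivs.values())

    def sequences(self) -> List[str]:
        return sorted(self._ivs)

    def intervals(self, sequence: str) -> List[Interval]:
        return list(self._ivs.get(sequence, []))

    def total_length(self, sequence: str | None = None) -> int:
        if sequence is not None:
            return sum(e - s for s, e in self._ivs.get(sequence, []))
        return sum(e - s for ivs in self._ivs.values() for s, e in ivs)

    def contains(self, sequence: str, position: int) -> bool:
        """True if the 0-based ``position`` falls inside the mask."""
        ivs = self._ivs.get(sequence)
        if not ivs:
            return False
        starts = np.array([s for s, _ in ivs])
        idx = int(np.searchsorted(starts, position, side="right")) - 1
        return idx >= 0 and position < ivs[idx][1]

    def membership(self, sequence: str, length: int) -> np.ndarray:
        """Boolean array of length ``length``: True where masked."""
        out = np.zeros(length, dtype=bool)
        for s, e in self._ivs.get(sequence, []):
            out[max(s, 0) : min(e, length)] = True
        return out

    def overlap(self, sequence: str, start: int, end: int) -> int:
        """Number of masked bases in [start, end)."""
        n = 0
        for s, e in self._ivs.get(sequence, []):
            n += max(0, min(e, end) - max(s, start))
        return n

    def complement(self, sequence: str, length: int) -> List[Interval]:
        """Unmasked intervals of ``sequence`` within [0, length)."""
        out: List[Interval] = []
        pos = 0
        for s, e in self._ivs.get(sequence, []):
            if s > pos:
                out.append((pos, min(s, length)))
            pos = max(pos, e)
            if pos >= length:
                break
        if pos < length:
            out.append((pos, length))
        return [(s, e) for s, e in out if e > s]

    def validate_within(self, lengths: Dict[str, int]) -> None:
        """Raise if any interval lies outside its declared sequence."""
        for seq, ivs in self._ivs.items():
            if seq not in lengths:
                raise ValueError(f"mask sequence {seq!r} not declared")
            for s, e in ivs:
                if s < 0 or e > lengths[seq]:
                    raise ValueError(
                        f"interval ({s}, {e}) outside {seq!r} of length {lengths[seq]}"
                    )

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionMask({len(self)} intervals on {len(self._ivs)} sequences)"
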