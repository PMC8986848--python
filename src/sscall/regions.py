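"""Target-panel intervals and reference access helpers.

Coordinates are 0-based, half-open everywhere in this package; 1-based
coordinates appear only in exported TSV/VCF files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Iterator


@dataclass(frozen=True, order=True)
class Interval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


class Panel:
    """An ordered set of target intervals (BED semantics)."""

    def __init__(self, intervals: Iterable[Interval]):
        self.intervals = sorted(intervals)
        self._by_chrom: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        if not self.intervals:
            raise ValueError("empty panel")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def n_positions(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        for iv in self._by_chrom.get(chrom, ()):
            if iv.start <= pos < iv.end:
                return True
        return False

    def positions(self) -> Iterator[tuple[str, int]]:
        """Yield every (chrom, pos) covered by the panel, in order."""
        for iv in self.intervals:
            for pos in range(iv.start, iv.end):
                yield iv.chrom, pos

    def checksum(self) -> str:
        h = hashlib.sha256()
        for iv in self.intervals:
            h.update(f"{iv.chrom}\t{iv.start}\t{iv.end}\n".encode())
        return h.hexdigest()[:16]

    @classmethod
    def from_bed(cls, path: str) -> "Panel":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                ivs.append(Interval(fields[0], int(fields[1]), int(fields[2])))
        return cls(ivs)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


class PositionMask:
    """A set of masked (chrom, pos) sites, e.g. known germline SNPs.

    Built from BED intervals; membership is per single position.
    """

    def __init__(self, intervals: Iterable[Interval] = ()):
        self._sites: set[tuple[str, int]] = set()
        for iv in intervals:
            for pos in range(iv.start, iv.end):
                self._sites.add((iv.chrom, pos))

    def __contains__(self, site: tuple[str, int]) -> bool:
        return site in self._sites

    def __len__(self) -> int:
        return len(self._sites)

    @classmethod
    def from_bed(cls, path: str) -> "PositionMask":
        mask = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                for pos in range(int(fields[1]), int(fields[2])):
                    mask._sites.add((fields[0], pos))
        return mask

    @classmethod
    def from_sites(cls, sites: Iterable[tuple[str, int]]) -> "PositionMask":
        mask = cls()
        mask._sites.update(sites)
        return mask
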