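"""Coordinate-exact genomic interval algebra.

All coordinates are 0-based, half-open (BED convention). Counting is
element-level: an element of a region set is one interval, and a single
base of overlap is enough to select it. Base-level operations (subtraction,
intersection, merged length) are provided separately and never implicitly
mixed with element-level ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomicIntervalSet",
    "ChromosomeNamingError",
    "select_overlapping_elements",
    "subtract_portions",
    "intersect_portions",
    "merged_length",
    "trim_to_midpoint",
    "subsample_by_score",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]


class ChromosomeNamingError(ValueError):
    """Two region sets use different chromosome naming conventions."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional name/score."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")


class GenomicIntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Iteration order is deterministic: (chrom lexicographic, start, end, name).
    The set may contain overlapping or duplicate elements; element count and
    merged base length are independent notions.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._intervals: list[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomicIntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"GenomicIntervalSet({len(self)} intervals)"

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def coords(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome, in iteration order."""
        ivs = [iv for iv in self._intervals if iv.chrom == chrom]
        if not ivs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )

    def merged(self) -> "GenomicIntervalSet":
        """Union of covered bases as maximal disjoint intervals (names dropped)."""
        out = []
        for chrom, ivs in self.by_chrom().items():
            cur_s, cur_e = None, None
            for iv in ivs:  # already sorted by start
                if cur_s is None:
                    cur_s, cur_e = iv.start, iv.end
                elif iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            if cur_s is not None:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
        return GenomicIntervalSet(out)

    def validate_against_sizes(self, chrom_sizes: Mapping[str, int]) -> None:
        for iv in self._intervals:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"chromosome {iv.chrom!r} not in sizes table")
            if iv.end > chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {chrom_sizes[iv.chrom]}"
                )


def _check_naming(a: GenomicIntervalSet, b: GenomicIntervalSet) -> None:
    """Raise if the two sets plainly use different chromosome conventions.

    Triggered when a chromosome of one set is absent from the other but its
    'chr'-prefixed or -stripped variant is present ('chr1' vs '1').
    """
    ca, cb = set(a.chroms), set(b.chroms)
    if not ca or not cb:
        return
    for c in ca:
        if c in cb:
            continue
        alias = c[3:] if c.startswith("chr") else "chr" + c
        if alias in cb:
            raise ChromosomeNamingError(
                f"chromosome naming mismatch: {c!r} vs {alias!r}"
            )


def select_overlapping_elements(
    elements: GenomicIntervalSet, selector: GenomicIntervalSet
) -> GenomicIntervalSet:
    """Elements of `elements` overlapping >= 1 bp with any selector interval.

    Elements are returned whole (no trimming); each at most once.
    """
    _check_naming(elements, selector)
    merged_sel = selector.merged().by_chrom()
    kept: list[GenomicInterval] = []
    for chrom, ivs in elements.by_chrom().items():
        sel = merged_sel.get(chrom)
        if not sel:
            continue
        ms = np.array([s.start for s in sel], dtype=np.int64)
        me = np.array([s.end for s in sel], dtype=np.int64)
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        # first merged interval ending after the element's start
        idx = np.searchsorted(me, starts, side="right")
        hit = (idx < len(ms)) & (ms[np.minimum(idx, len(ms) - 1)] < ends)
        kept.extend(iv for iv, h in zip(ivs, hit) if h)
    return GenomicIntervalSet(kept)


def count_overlapping_elements(
    elements: GenomicIntervalSet, selector: GenomicIntervalSet
) -> int:
    """len(select_overlapping_elements(...)) without materialising the set."""
    return len(select_overlapping_elements(elements, selector))


def subtract_portions(
    a: GenomicIntervalSet, b: GenomicIntervalSet
) -> GenomicIntervalSet:
    """Base-level difference A \\ B as maximal surviving pieces.

    Each piece inherits the name/score of its source interval in `a`;
    zero-length remnants are dropped.
    """
    _check_naming(a, b)
    merged_b = b.merged().by_chrom()
    out: list[GenomicInterval] = []
    for chrom, ivs in a.by_chrom().items():
        holes = merged_b.get(chrom, [])
        hs = np.array([h.start for h in holes], dtype=np.int64)
        he = np.array([h.end for h in holes], dtype=np.int64)
        for iv in ivs:
            if len(holes) == 0:
                out.append(iv)
                continue
            lo = int(np.searchsorted(he, iv.start, side="right"))
            pos = iv.start
            for j in range(lo, len(holes)):
                if hs[j] >= iv.end:
                    break
                if hs[j] > pos:
                    out.append(replace(iv, start=pos, end=int(hs[j])))
                pos = max(pos, int(he[j]))
                if pos >= iv.end:
                    break
            if pos < iv.end:
                out.append(replace(iv, start=pos, end=iv.end))
    return GenomicIntervalSet(out)


def intersect_portions(
    a: GenomicIntervalSet, b: GenomicIntervalSet
) -> GenomicIntervalSet:
    """Base-level intersection of the covered bases (merged, names dropped)."""
    _check_naming(a, b)
    ma, mb = a.merged().by_chrom(), b.merged().by_chrom()
    out: list[GenomicInterval] = []
    for chrom in set(ma) & set(mb):
        xs, ys = ma[chrom], mb[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return GenomicIntervalSet(out)


def merged_length(a: GenomicIntervalSet) -> int:
    """Number of distinct bases covered (overlaps counted once)."""
    return sum(iv.length for iv in a.merged())


def trim_to_midpoint(a: GenomicIntervalSet, max_len: int) -> GenomicIntervalSet:
    """Cap element length at `max_len`, preserving each element's midpoint.

    An element longer than max_len becomes [c - floor(max_len/2),
    c + ceil(max_len/2)) where c = floor((start+end)/2). Shorter elements
    pass through unchanged.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    out = []
    for iv in a:
        if iv.length <= max_len:
            out.append(iv)
        else:
            c = (iv.start + iv.end) // 2
            out.append(
                replace(iv, start=c - max_len // 2, end=c + (max_len + 1) // 2)
            )
    return GenomicIntervalSet(out)


def subsample_by_score(
    a: GenomicIntervalSet, fraction: float, seed: int
) -> GenomicIntervalSet:
    """Keep the top round(fraction*n) elements by descending score.

    Elements tied at the cutoff score are chosen uniformly at random
    (reproducibly, per seed). Rounding is half-up.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ivs = list(a)
    if any(iv.score is None for iv in ivs):
        raise ValueError("subsample_by_score requires a score on every element")
    n = len(ivs)
    n_keep = int(np.floor(fraction * n + 0.5))
    if n_keep >= n:
        return GenomicIntervalSet(ivs)
    # descending score, deterministic secondary order before any tie-breaking
    ivs.sort(key=lambda iv: (-iv.score, iv.sort_key()))
    cutoff = ivs[n_keep - 1].score if n_keep > 0 else None
    if n_keep == 0:
        return GenomicIntervalSet()
    above = [iv for iv in ivs if iv.score > cutoff]
    ties = [iv for iv in ivs if iv.score == cutoff]
    need = n_keep - len(above)
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(ties), size=need, replace=False)
    kept = above + [ties[i] for i in sorted(chosen_idx)]
    return GenomicIntervalSet(kept)


# ---------------------------------------------------------------------------
# BED / chrom-sizes IO
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> GenomicIntervalSet:
    """Read a BED3/BED6 file (tab-separated, 0-based half-open)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = (
                float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            )
            out.append(GenomicInterval(chrom, start, end, name, score))
    return GenomicIntervalSet(out)


def write_bed(a: GenomicIntervalSet, path: str | Path) -> None:
    """Write BED; emits 6 columns when any element carries a name or score."""
    six = any(iv.name is not None or iv.score is not None for iv in a)
    with open(path, "w") as fh:
        for iv in a:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t.\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column (chrom, length) TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
    return sizes
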