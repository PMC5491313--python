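"""Genome layout and exact interval algebra.

Coordinates are 1-based inclusive throughout: the genome is the discrete
locus set ``G = {1, ..., L}``, a disjoint union of chromosomes, and an
interval ``[a, b]`` occupies the loci ``{a, ..., b}``.  BED input/output
(0-based half-open) is converted at the I/O boundary (:mod:`overlapmodel.io`),
never here.

The operations in this module are the substrate for everything downstream:

* ``dilate_left(S, y)`` is the set of start positions ``x`` such that a query
  ``q(x, y) = {x, ..., x+y-1}`` would overlap ``S`` (each ``[a, b]`` grows to
  ``[a-y+1, b]``, clipped at the chromosome start);
* ``start_domain(M, y)`` (erosion) is the set of starts whose query lies
  entirely inside ``M`` (each ``[a, b]`` shrinks to ``[a, b-y+1]`` and blocks
  shorter than ``y`` vanish).

Intervals never span chromosomes; every chromosome is an independent segment
of G and dilation/erosion clip at its boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "GenomeLayout",
    "IntervalSet",
    "Query",
    "QueryCollection",
    "merge_normalize",
    "dilate_left",
    "start_domain",
    "intersect",
    "complement",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Named chromosomes with lengths; defines the locus space G of size L.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs.  Names must be unique and lengths
        positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise InputError("duplicate chromosome names in genome layout")
        for n, l in chroms:
            if l < 1:
                raise InputError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        """L, the total number of loci in the genome."""
        return sum(l for _, l in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise InputError(f"unknown chromosome {chrom!r}") from None


def _normalize_arrays(
    starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping or exactly-adjacent intervals."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # Merge wherever the next start is <= current running end + 1 (adjacency
    # merges too: [5,10]+[11,12] -> [5,12], indistinguishable as locus sets).
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + 1:
            if e > out_e[-1]:
                out_e[-1] = int(e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class IntervalSet:
    """Normalized disjoint 1-based inclusive intervals on a :class:`GenomeLayout`.

    Internally, per chromosome, two sorted int64 arrays (starts, ends) with a
    gap of at least one base between consecutive intervals.  Instances are
    immutable by convention; all operations return new sets.
    """

    __slots__ = ("layout", "_data")

    def __init__(
        self,
        layout: GenomeLayout,
        per_chrom: Mapping[str, Sequence[tuple[int, int]]] | None = None,
        *,
        _validated: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    ):
        self.layout = layout
        if _validated is not None:
            self._data = _validated
            return
        data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per_chrom = per_chrom or {}
        for chrom, pairs in per_chrom.items():
            clen = layout.length_of(chrom)
            pairs = list(pairs)
            if not pairs:
                continue
            starts = np.asarray([p[0] for p in pairs], dtype=np.int64)
            ends = np.asarray([p[1] for p in pairs], dtype=np.int64)
            bad = (starts < 1) | (ends > clen) | (starts > ends)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise InputError(
                    f"interval [{starts[i]}, {ends[i]}] out of bounds on "
                    f"{chrom!r} (length {clen})"
                )
            data[chrom] = _normalize_arrays(starts, ends)
        self._data = data

    # -- construction helpers -------------------------------------------------

    @classmethod
    def empty(cls, layout: GenomeLayout) -> "IntervalSet":
        return cls(layout, {})

    @classmethod
    def whole_genome(cls, layout: GenomeLayout) -> "IntervalSet":
        return cls(layout, {n: [(1, l)] for n, l in layout.chromosomes})

    @classmethod
    def _from_arrays(
        cls, layout: GenomeLayout, data: dict[str, tuple[np.ndarray, np.ndarray]]
    ) -> "IntervalSet":
        data = {c: v for c, v in data.items() if v[0].size > 0}
        return cls(layout, _validated=data)

    # -- inspection -----------------------------------------------------------

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for a chromosome; empty arrays if none."""
        if chrom in self._data:
            return self._data[chrom]
        e = np.empty(0, dtype=np.int64)
        return e, e

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(c for c in self.layout.names if c in self._data)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        s, e = self.arrays(chrom)
        return [(int(a), int(b)) for a, b in zip(s, e)]

    def to_dict(self) -> dict[str, list[tuple[int, int]]]:
        return {c: self.intervals(c) for c in self.chroms}

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for c in self.chroms:
            for a, b in self.intervals(c):
                yield c, a, b

    def cardinality(self) -> int:
        """|S| = total number of loci covered."""
        return int(
            sum((e - s + 1).sum() for s, e in self._data.values())
        )

    def is_empty(self) -> bool:
        return not self._data

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.layout != other.layout or set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[c][0], other._data[c][0])
            and np.array_equal(self._data[c][1], other._data[c][1])
            for c in self._data
        )

    def __repr__(self) -> str:
        n = sum(s.size for s, _ in self._data.values())
        return f"IntervalSet({n} intervals, |S|={self.cardinality()})"

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership test for 1-based positions."""
        starts, ends = self.arrays(chrom)
        if starts.size == 0:
            return np.zeros(np.shape(positions), dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(np.shape(positions), dtype=bool)
        res[ok] = positions[ok] <= ends[idx[ok]]
        return res


def merge_normalize(
    raw: Mapping[str, Sequence[tuple[int, int]]], layout: GenomeLayout
) -> IntervalSet:
    """Build a normalized IntervalSet from raw (possibly overlapping) intervals.

    Overlapping or exactly-adjacent intervals are merged; the covered locus
    set is preserved.  Raises :class:`InputError` naming the offending record
    if any interval leaves its chromosome's bounds.
    """
    return IntervalSet(layout, raw)


def dilate_left(s: IntervalSet, y: int, layout: GenomeLayout | None = None) -> IntervalSet:
    """Start positions whose length-``y`` query would overlap ``s``.

    D(y) = union of [a-y+1, b] over intervals [a, b], clipped at base 1.
    ``dilate_left(s, 1) == s``.
    """
    if y < 1:
        raise InputError(f"query length must be >= 1, got {y}")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (starts, ends) in s._data.items():
        new_starts = np.maximum(starts - (y - 1), 1)
        out[chrom] = _normalize_arrays(new_starts, ends.copy())
    return IntervalSet._from_arrays(s.layout, out)


def start_domain(
    mappable: IntervalSet, y: int, layout: GenomeLayout | None = None
) -> IntervalSet:
    """Erode: start positions whose length-``y`` query lies inside ``mappable``.

    Each block [a, b] with b-a+1 >= y contributes [a, b-y+1]; shorter blocks
    vanish.  An empty result means no valid start exists (callers raise
    :class:`DegenerateNullError` where that matters).
    """
    if y < 1:
        raise InputError(f"query length must be >= 1, got {y}")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (starts, ends) in mappable._data.items():
        keep = (ends - starts + 1) >= y
        if keep.any():
            out[chrom] = (starts[keep].copy(), ends[keep] - (y - 1))
    return IntervalSet._from_arrays(mappable.layout, out)


def _check_same_layout(a: IntervalSet, b: IntervalSet) -> None:
    if a.layout != b.layout:
        raise InputError("interval sets live on different genome layouts")


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Exact locus-set intersection."""
    _check_same_layout(a, b)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in a._data:
        if chrom not in b._data:
            continue
        as_, ae = a._data[chrom]
        bs, be = b._data[chrom]
        # classic two-pointer sweep
        i = j = 0
        rs: list[int] = []
        re: list[int] = []
        while i < as_.size and j < bs.size:
            lo = max(as_[i], bs[j])
            hi = min(ae[i], be[j])
            if lo <= hi:
                rs.append(int(lo))
                re.append(int(hi))
            if ae[i] < be[j]:
                i += 1
            else:
                j += 1
        if rs:
            out[chrom] = (
                np.asarray(rs, dtype=np.int64),
                np.asarray(re, dtype=np.int64),
            )
    return IntervalSet._from_arrays(a.layout, out)


def complement(a: IntervalSet, layout: GenomeLayout | None = None) -> IntervalSet:
    """Loci of G not in ``a``; |a| + |complement(a)| = L."""
    layout = layout or a.layout
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, clen in layout.chromosomes:
        starts, ends = a.arrays(chrom)
        rs: list[int] = []
        re: list[int] = []
        prev_end = 0
        for s, e in zip(starts, ends):
            if s > prev_end + 1:
                rs.append(prev_end + 1)
                re.append(int(s) - 1)
            prev_end = int(e)
        if prev_end < clen:
            rs.append(prev_end + 1)
            re.append(clen)
        if rs:
            out[chrom] = (
                np.asarray(rs, dtype=np.int64),
                np.asarray(re, dtype=np.int64),
            )
    return IntervalSet._from_arrays(layout, out)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Exact locus-set union (normalizing merge of both sets)."""
    _check_same_layout(a, b)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in set(a._data) | set(b._data):
        as_, ae = a.arrays(chrom)
        bs, be = b.arrays(chrom)
        out[chrom] = _normalize_arrays(
            np.concatenate([as_, bs]), np.concatenate([ae, be])
        )
    return IntervalSet._from_arrays(a.layout, out)


@dataclass(frozen=True)
class Query:
    """One query interval q(x, y) = {x, ..., x+y-1} on a chromosome."""

    chrom: str
    x: int
    y: int

    def validate(self, layout: GenomeLayout) -> None:
        if self.y < 1:
            raise InputError(f"query length must be >= 1, got {self.y}")
        clen = layout.length_of(self.chrom)
        if not (1 <= self.x and self.x + self.y - 1 <= clen):
            raise InputError(
                f"query [{self.x}, {self.x + self.y - 1}] out of bounds on "
                f"{self.chrom!r} (length {clen})"
            )

    @property
    def end(self) -> int:
        return self.x + self.y - 1


@dataclass
class QueryCollection:
    """A list of query intervals; duplicates allowed (records never merge)."""

    queries: list[Query] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.queries)

    def __iter__(self) -> Iterator[Query]:
        return iter(self.queries)

    def __len__(self) -> int:
        return len(self.queries)

    def lengths(self) -> list[int]:
        return sorted({q.y for q in self.queries})

    def by_length(self) -> dict[int, list[Query]]:
        out: dict[int, list[Query]] = {}
        for q in self.queries:
            out.setdefault(q.y, []).append(q)
        return out

    def validate(self, layout: GenomeLayout) -> None:
        for q in self.queries:
            q.validate(layout)
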