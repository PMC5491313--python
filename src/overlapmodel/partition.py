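"""Overlap-pattern partition of the mappable start domain.

For a query length ``y`` the N dilated reference sets D_i(y) cut the start
domain G0(y) into at most 2^N disjoint *cells*, one per overlap pattern
``v in {0,1}^N`` (v_i = 1 iff a query starting in the cell overlaps R_i).
Cell sizes m_v(y) are the only geometry the model needs: the genome-wide
normalizer collapses to a sum over realized cells.

Patterns are stored as integer bitmasks (bit i set <=> overlap with R_i,
i = 0-based internally); only realized cells (m_v > 0) are kept.  The cell
construction is a sorted-boundary sweep over dilated-set endpoints per
chromosome — never a per-base scan (per-base scans live only in the test
oracles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateNullError, InputError
from .intervals import (
    GenomeLayout,
    IntervalSet,
    Query,
    QueryCollection,
    dilate_left,
    start_domain,
)

__all__ = [
    "OverlapPartition",
    "TermDesign",
    "SufficientStats",
    "build_partition",
    "pattern_of",
    "term_design",
    "sufficient_statistics",
    "canonical_terms",
    "MAX_REFERENCE_SETS",
]

# Cap on N: bounds pattern enumeration (2^N) and keeps bitmasks cheap.
MAX_REFERENCE_SETS = 20


def pattern_to_tuple(mask: int, n: int) -> tuple[int, ...]:
    return tuple((mask >> i) & 1 for i in range(n))


def tuple_to_pattern(v: Sequence[int]) -> int:
    return sum(1 << i for i, b in enumerate(v) if b)


@dataclass
class OverlapPartition:
    """Disjoint constant-pattern cells of G0(y) for one query length.

    Attributes
    ----------
    y : query length this partition conditions on.
    n_refs : number of reference sets N.
    masks : int64 array of realized pattern bitmasks, sorted ascending.
    sizes : int64 array of cell sizes m_v(y), aligned with ``masks``.
    cells : per realized mask, the cell's intervals as ``{chrom: (starts, ends)}``.
    g0_size : |G0(y)|; always equals ``sizes.sum()``.
    """

    y: int
    n_refs: int
    masks: np.ndarray
    sizes: np.ndarray
    cells: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]]
    g0_size: int

    def size_of(self, mask: int) -> int:
        idx = np.searchsorted(self.masks, mask)
        if idx < len(self.masks) and self.masks[idx] == mask:
            return int(self.sizes[idx])
        return 0

    def as_table(self) -> list[tuple[tuple[int, ...], int]]:
        """(pattern tuple, size) rows for inspection/TSV dumps."""
        return [
            (pattern_to_tuple(int(m), self.n_refs), int(s))
            for m, s in zip(self.masks, self.sizes)
        ]


def build_partition(
    refs: Sequence[IntervalSet],
    mappable: IntervalSet,
    y: int,
    layout: GenomeLayout,
) -> OverlapPartition:
    """Partition G0(y) by the joint overlap pattern of the dilated references.

    Runs a sorted-boundary sweep per chromosome: segment boundaries are the
    endpoints of G0(y) and of every D_i(y); within a segment the pattern is
    constant and is read off by membership of the segment's first base.
    """
    n = len(refs)
    if n < 1:
        raise InputError("at least one reference set is required")
    if n > MAX_REFERENCE_SETS:
        raise InputError(
            f"{n} reference sets exceeds the configured cap "
            f"({MAX_REFERENCE_SETS})"
        )
    g0 = start_domain(mappable, y)
    if g0.is_empty():
        raise DegenerateNullError(
            f"no valid start position exists for query length y={y}: "
            "every mappable block is shorter than y"
        )
    dil = [dilate_left(r, y) for r in refs]

    acc_sizes: dict[int, int] = {}
    acc_cells: dict[int, dict[str, tuple[list[int], list[int]]]] = {}
    for chrom in g0.chroms:
        g0s, g0e = g0.arrays(chrom)
        # breakpoints: starts and (end+1) of G0 blocks and of all dilated sets
        bps = [g0s, g0e + 1]
        for d in dil:
            ds, de = d.arrays(chrom)
            bps.extend([ds, de + 1])
        pts = np.unique(np.concatenate(bps))
        # keep only segment starts inside G0
        inside = g0.contains(chrom, pts)
        seg_starts = pts[inside]
        if seg_starts.size == 0:
            continue
        # segment end = next breakpoint - 1 (every G0 block end+1 is a
        # breakpoint, so segments never cross a G0 gap)
        nxt = pts[np.searchsorted(pts, seg_starts, side="right")]
        seg_ends = nxt - 1
        # pattern of each segment from membership of its first base
        masks = np.zeros(seg_starts.size, dtype=np.int64)
        for i, d in enumerate(dil):
            masks |= d.contains(chrom, seg_starts).astype(np.int64) << i
        for m, a, b in zip(masks, seg_starts, seg_ends):
            m = int(m)
            acc_sizes[m] = acc_sizes.get(m, 0) + int(b - a + 1)
            cell = acc_cells.setdefault(m, {})
            ss, ee = cell.setdefault(chrom, ([], []))
            ss.append(int(a))
            ee.append(int(b))

    masks_arr = np.asarray(sorted(acc_sizes), dtype=np.int64)
    sizes_arr = np.asarray([acc_sizes[int(m)] for m in masks_arr], dtype=np.int64)
    cells = {
        m: {
            c: (np.asarray(ss, dtype=np.int64), np.asarray(ee, dtype=np.int64))
            for c, (ss, ee) in per.items()
        }
        for m, per in acc_cells.items()
    }
    g0_size = g0.cardinality()
    assert int(sizes_arr.sum()) == g0_size
    return OverlapPartition(
        y=y, n_refs=n, masks=masks_arr, sizes=sizes_arr, cells=cells, g0_size=g0_size
    )


def pattern_of(
    q: Query, dilations: Sequence[IntervalSet]
) -> tuple[int, ...]:
    """Overlap pattern of one query against pre-dilated reference sets.

    ``dilations[i]`` must be ``dilate_left(R_i, q.y)``; then v_i = 1 iff
    q overlaps R_i, consistent with the cell containing q's start.
    """
    pos = np.asarray([q.x], dtype=np.int64)
    return tuple(int(d.contains(q.chrom, pos)[0]) for d in dilations)


def canonical_terms(terms: Sequence[Sequence[int]]) -> tuple[frozenset[int], ...]:
    """Validate and canonically order model terms (by |pi|, then lexicographic).

    Terms are non-empty subsets of {1..N} (1-based reference indices).
    """
    out: list[frozenset[int]] = []
    seen: set[frozenset[int]] = set()
    for t in terms:
        fs = frozenset(int(i) for i in t)
        if not fs:
            raise InputError("empty model term")
        if any(i < 1 for i in fs):
            raise InputError(f"term {sorted(fs)} has non-positive reference index")
        if fs in seen:
            raise InputError(f"duplicate model term {sorted(fs)}")
        seen.add(fs)
        out.append(fs)
    return tuple(sorted(out, key=lambda f: (len(f), sorted(f))))


@dataclass
class TermDesign:
    """Binary design matrix of model terms over realized overlap patterns.

    Row per pattern, column per term: S[v, pi] = prod_{i in pi} v_i.
    The all-zero (background) pattern maps to a zero row.
    """

    terms: tuple[frozenset[int], ...]
    masks: np.ndarray  # realized pattern bitmasks (row order)
    S: np.ndarray  # shape (len(masks), d), float64 in {0, 1}

    @property
    def d(self) -> int:
        return len(self.terms)


def _term_masks(terms: Sequence[frozenset[int]]) -> np.ndarray:
    return np.asarray(
        [sum(1 << (i - 1) for i in t) for t in terms], dtype=np.int64
    )


def term_design(
    terms: Sequence[Sequence[int]] | Sequence[frozenset[int]],
    masks: np.ndarray,
) -> TermDesign:
    """Build the design matrix S for the given terms and realized patterns."""
    cterms = canonical_terms([sorted(t) for t in terms])
    tmasks = _term_masks(cterms)
    masks = np.asarray(masks, dtype=np.int64)
    if len(cterms) == 0:
        S = np.zeros((masks.size, 0))
    else:
        # s(v)_pi = 1 iff the term's bits are all set in the pattern
        S = ((masks[:, None] & tmasks[None, :]) == tmasks[None, :]).astype(float)
    return TermDesign(terms=cterms, masks=masks, S=S)


@dataclass
class SufficientStats:
    """Per-term counts t_pi of queries overlapping all sets in pi at once."""

    terms: tuple[frozenset[int], ...]
    t: np.ndarray  # int64, len d
    n: int  # number of queries counted

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)

    def as_dict(self) -> dict[tuple[int, ...], int]:
        return {tuple(sorted(f)): int(v) for f, v in zip(self.terms, self.t)}


def query_patterns(
    queries: QueryCollection,
    refs: Sequence[IntervalSet],
    layout: GenomeLayout,
    mappable: IntervalSet | None = None,
    *,
    on_outside: str = "error",
) -> tuple[np.ndarray, int]:
    """Bitmask pattern per query (vectorized per distinct length).

    Queries whose start falls outside the mappable start domain G0(y) are
    handled per ``on_outside``: ``"error"`` (default) raises, ``"drop"``
    removes them with a count returned as the second element.
    """
    if on_outside not in ("error", "drop"):
        raise InputError(f"on_outside must be 'error' or 'drop', got {on_outside!r}")
    queries.validate(layout)
    n_refs = len(refs)
    masks_out: list[int] = []
    dropped = 0
    for y, qs in queries.by_length().items():
        dil = [dilate_left(r, y) for r in refs]
        g0 = start_domain(mappable, y) if mappable is not None else None
        by_chrom: dict[str, list[Query]] = {}
        for q in qs:
            by_chrom.setdefault(q.chrom, []).append(q)
        for chrom, cqs in by_chrom.items():
            pos = np.asarray([q.x for q in cqs], dtype=np.int64)
            if g0 is not None:
                ok = g0.contains(chrom, pos)
                if not ok.all():
                    if on_outside == "error":
                        bad = cqs[int(np.flatnonzero(~ok)[0])]
                        raise InputError(
                            f"query start {bad.x} (length {bad.y}) on "
                            f"{chrom!r} lies outside the mappable start "
                            "domain G0(y)"
                        )
                    dropped += int((~ok).sum())
                    pos = pos[ok]
            m = np.zeros(pos.size, dtype=np.int64)
            for i in range(n_refs):
                m |= dil[i].contains(chrom, pos).astype(np.int64) << i
            masks_out.extend(int(v) for v in m)
    return np.asarray(masks_out, dtype=np.int64), dropped


def sufficient_statistics(
    queries: QueryCollection,
    terms: Sequence[Sequence[int]] | Sequence[frozenset[int]],
    refs: Sequence[IntervalSet],
    layout: GenomeLayout,
    mappable: IntervalSet | None = None,
    *,
    on_outside: str = "error",
) -> SufficientStats:
    """Sufficient statistics T: t_pi = #{queries overlapping every R_i, i in pi}.

    Order-independent and integral; monotone over nested terms
    (t_pitilde >= t_pi whenever pitilde is a subset of pi).
    """
    cterms = canonical_terms([sorted(t) for t in terms])
    qmasks, _dropped = query_patterns(
        queries, refs, layout, mappable, on_outside=on_outside
    )
    tmasks = _term_masks(cterms)
    if len(cterms) == 0:
        t = np.zeros(0, dtype=np.int64)
    else:
        t = (
            ((qmasks[:, None] & tmasks[None, :]) == tmasks[None, :])
            .sum(axis=0)
            .astype(np.int64)
        )
    return SufficientStats(terms=cterms, t=t, n=int(qmasks.size))
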