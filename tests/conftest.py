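"""Shared fixtures and brute-force per-base oracles.

The oracles enumerate every locus of a small genome and compute overlap
patterns, cell counts and the model density directly from the definitions,
independently of the package's sweep/partition code paths.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import overlapmodel as om

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# TOY1: one chromosome of length 100, fully mappable,
# R1 = [11,20] u [41,50], R2 = [16,30]


@pytest.fixture(scope="session")
def toy1():
    layout = om.GenomeLayout([("chr1", 100)])
    r1 = om.merge_normalize({"chr1": [(11, 20), (41, 50)]}, layout)
    r2 = om.merge_normalize({"chr1": [(16, 30)]}, layout)
    mappable = om.IntervalSet.whole_genome(layout)
    return layout, r1, r2, mappable


@pytest.fixture(scope="session")
def toy1_single_fit(toy1):
    """Single-term data on TOY1: n=10 queries of length 1, t_{1}=5."""
    layout, r1, _, mappable = toy1
    xs = [11, 12, 13, 41, 42, 1, 2, 3, 4, 5]
    queries = om.QueryCollection([om.Query("chr1", x, 1) for x in xs])
    return layout, r1, mappable, queries


# ---------------------------------------------------------------------------
# brute-force oracles


def loci_of(s: om.IntervalSet, chrom: str) -> set[int]:
    return {
        x for a, b in s.intervals(chrom) for x in range(a, b + 1)
    }


def brute_overlaps(x: int, y: int, ref_loci: set[int]) -> bool:
    """Does q(x, y) = {x..x+y-1} intersect the reference locus set?"""
    return any((x + k) in ref_loci for k in range(y))


def brute_start_domain(mappable_loci: set[int], y: int, clen: int) -> set[int]:
    return {
        x
        for x in range(1, clen - y + 2)
        if all((x + k) in mappable_loci for k in range(y))
    }


def brute_cells(
    refs: list[om.IntervalSet],
    mappable: om.IntervalSet,
    y: int,
    layout: om.GenomeLayout,
) -> dict[tuple[int, ...], int]:
    """Per-base enumeration of overlap-pattern cell sizes over G0(y)."""
    counts: dict[tuple[int, ...], int] = {}
    for chrom, clen in layout.chromosomes:
        ref_loci = [loci_of(r, chrom) for r in refs]
        g0 = brute_start_domain(loci_of(mappable, chrom), y, clen)
        for x in g0:
            v = tuple(int(brute_overlaps(x, y, rl)) for rl in ref_loci)
            counts[v] = counts.get(v, 0) + 1
    return counts


def brute_log_normalizer(
    theta: np.ndarray,
    spec: om.ModelSpec,
    refs: list[om.IntervalSet],
    mappable: om.IntervalSet,
    y: int,
    layout: om.GenomeLayout,
) -> float:
    """-log sum_x (1/|G0|) exp(h(x|y)) by direct per-base summation."""
    total = 0.0
    g0_size = 0
    for chrom, clen in layout.chromosomes:
        ref_loci = [loci_of(r, chrom) for r in refs]
        g0 = brute_start_domain(loci_of(mappable, chrom), y, clen)
        g0_size += len(g0)
        for x in g0:
            v = tuple(int(brute_overlaps(x, y, rl)) for rl in ref_loci)
            total += np.exp(om.enrichment(theta, spec, v))
    return -float(np.log(total / g0_size))


def random_layout_and_sets(
    rng: np.random.Generator,
    *,
    max_len: int = 400,
    n_refs: int = 2,
    n_chroms: int = 1,
):
    layout = om.GenomeLayout(
        [
            (f"chr{i + 1}", int(rng.integers(50, max_len + 1)))
            for i in range(n_chroms)
        ]
    )
    refs = []
    for _ in range(n_refs):
        raw = {}
        for chrom, clen in layout.chromosomes:
            k = int(rng.integers(1, 6))
            ivs = []
            for _ in range(k):
                a = int(rng.integers(1, clen + 1))
                b = min(clen, a + int(rng.integers(0, max(2, clen // 8))))
                ivs.append((a, b))
            raw[chrom] = ivs
        refs.append(om.merge_normalize(raw, layout))
    return layout, refs
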