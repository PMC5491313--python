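"""Model-faithful simulation and power/recovery studies.

Two samplers draw query starts i.i.d. from the log-linear density given the
length y:

* ``acceptance_rejection`` — propose x uniform on G0(y), accept with
  probability exp(h(x|y) - h_max) where h_max is the largest enrichment over
  realized patterns.  The acceptance probability is bounded below by
  exp(h_min - h_max) > 0, so all-rejection pathologies cannot occur.
* ``exact_cell`` (default) — draw a pattern cell with probability
  proportional to m_v(y) * exp(theta . s(v)), then a start uniform within
  the cell.  Identical law, no rejections, and much faster.

The study drivers replay the estimation / selection / convergence protocols
on any geometry: simulate many replicate datasets at a known theta, fit or
select per replicate, and summarize.  ``synth_references`` generates seeded
random reference geometries (verified identifiable) so no real genomic
tracks are ever required.

All randomness flows from one master seed through
``numpy.random.SeedSequence.spawn`` — child streams for geometry, sampling,
and each replicate are independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import OverlapDataset
from .errors import ConvergenceError, InputError
from .intervals import (
    GenomeLayout,
    IntervalSet,
    Query,
    QueryCollection,
    merge_normalize,
    start_domain,
)
from .model import ModelSpec, check_identifiability
from .partition import OverlapPartition, build_partition, term_design
from .inference import stepwise_select

__all__ = [
    "SimOptions",
    "StudyResult",
    "sample_queries",
    "estimation_study",
    "selection_study",
    "convergence_rate",
    "required_sample_size",
    "synth_references",
    "reference_summary",
    "benchmark_geometry",
]


@dataclass
class SimOptions:
    """Options shared by the samplers and study drivers.

    ``lengths`` is either a single fixed query length (default 1, matching
    the convention of conditioning on Y = y) or a list sampled uniformly
    with replacement per query.
    """

    seed: int = 0
    mode: str = "exact_cell"  # or "acceptance_rejection"
    lengths: int | Sequence[int] = 1
    n: int = 1000
    reps: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("exact_cell", "acceptance_rejection"):
            raise InputError(f"unknown sampler mode {self.mode!r}")
        if self.n < 1 or self.reps < 1:
            raise InputError("n and reps must be >= 1")


@dataclass
class StudyResult:
    """Summaries produced by the study drivers (fields used as relevant)."""

    terms: tuple[tuple[int, ...], ...] = ()
    mean_theta: np.ndarray | None = None
    std_theta: np.ndarray | None = None
    n_converged: int = 0
    n_diverged: int = 0
    reps: int = 0
    config_percent: dict[tuple[tuple[int, ...], ...], float] = field(
        default_factory=dict
    )
    term_rate: dict[tuple[int, ...], float] = field(default_factory=dict)
    exact_percent: float | None = None
    all_true_percent: float | None = None
    convergence_rate: float | None = None
    required_n: int | None = None
    achieved: bool | None = None

    def to_json_dict(self) -> dict:
        out: dict = {"reps": self.reps}
        if self.mean_theta is not None:
            out["terms"] = [list(t) for t in self.terms]
            out["mean_theta"] = [float(v) for v in self.mean_theta]
            out["std_theta"] = [float(v) for v in self.std_theta]
            out["n_converged"] = self.n_converged
            out["n_diverged"] = self.n_diverged
        if self.config_percent:
            out["config_percent"] = {
                " | ".join("{" + ",".join(map(str, t)) + "}" for t in k): v
                for k, v in sorted(
                    self.config_percent.items(), key=lambda kv: -kv[1]
                )
            }
            out["term_rate"] = {
                "{" + ",".join(map(str, t)) + "}": v
                for t, v in sorted(self.term_rate.items())
            }
            out["exact_percent"] = self.exact_percent
            out["all_true_percent"] = self.all_true_percent
        if self.convergence_rate is not None:
            out["convergence_rate"] = self.convergence_rate
        if self.required_n is not None or self.achieved is not None:
            out["required_n"] = self.required_n
            out["achieved"] = self.achieved
        return out


# ---------------------------------------------------------------------------
# cell machinery


def _cell_weights(
    partition: OverlapPartition, spec: ModelSpec, theta: np.ndarray
) -> np.ndarray:
    """Unnormalized cell probabilities m_v * exp(theta . s(v))."""
    des = term_design(spec.terms, partition.masks)
    h = des.S @ np.asarray(theta, dtype=float)
    w = partition.sizes.astype(float) * np.exp(h - h.max())
    return w / w.sum()


def _sample_cell_counts(
    partition: OverlapPartition,
    spec: ModelSpec,
    theta: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    return rng.multinomial(n, _cell_weights(partition, spec, theta))


def _positions_in_cell(
    partition: OverlapPartition, mask: int, k: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """k uniform start positions within one pattern cell."""
    cell = partition.cells[int(mask)]
    chroms: list[str] = []
    starts_all: list[np.ndarray] = []
    lens_all: list[np.ndarray] = []
    for chrom, (ss, ee) in cell.items():
        chroms.extend([chrom] * ss.size)
        starts_all.append(ss)
        lens_all.append(ee - ss + 1)
    starts = np.concatenate(starts_all)
    lens = np.concatenate(lens_all)
    cum = np.cumsum(lens)
    total = int(cum[-1])
    u = rng.integers(0, total, size=k)
    idx = np.searchsorted(cum, u, side="right")
    offs = u - (cum[idx] - lens[idx])
    return [
        (chroms[int(i)], int(starts[int(i)] + int(o))) for i, o in zip(idx, offs)
    ]


def _h_per_cell(
    partition: OverlapPartition, spec: ModelSpec, theta: np.ndarray
) -> np.ndarray:
    des = term_design(spec.terms, partition.masks)
    return des.S @ np.asarray(theta, dtype=float)


def sample_queries(
    theta: np.ndarray,
    spec: ModelSpec,
    refs: Sequence[IntervalSet],
    mappable: IntervalSet,
    layout: GenomeLayout,
    options: SimOptions,
) -> QueryCollection:
    """Draw n i.i.d. query intervals from the model given their lengths."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.d,):
        raise InputError(f"theta has shape {theta.shape}, expected ({spec.d},)")
    rng = np.random.default_rng(np.random.SeedSequence(options.seed))
    if isinstance(options.lengths, int):
        ys = np.full(options.n, options.lengths, dtype=np.int64)
    else:
        ys = rng.choice(np.asarray(list(options.lengths), dtype=np.int64), size=options.n)
    queries: list[Query] = []
    for y in np.unique(ys):
        k_y = int((ys == y).sum())
        part = build_partition(refs, mappable, int(y), layout)
        if options.mode == "exact_cell":
            counts = _sample_cell_counts(part, spec, theta, k_y, rng)
            for mask, k in zip(part.masks, counts):
                if k:
                    for chrom, x in _positions_in_cell(part, int(mask), int(k), rng):
                        queries.append(Query(chrom, x, int(y)))
        else:
            queries.extend(
                _sample_ar(part, spec, theta, k_y, int(y), mappable, rng)
            )
    # i.i.d. sample: order carries no information, shuffle for hygiene
    perm = rng.permutation(len(queries))
    return QueryCollection([queries[int(i)] for i in perm])


def _sample_ar(
    partition: OverlapPartition,
    spec: ModelSpec,
    theta: np.ndarray,
    k: int,
    y: int,
    mappable: IntervalSet,
    rng: np.random.Generator,
) -> list[Query]:
    """Acceptance/rejection: uniform proposals on G0(y), accept prob e^(h - h_max)."""
    g0 = start_domain(mappable, y)
    chroms: list[str] = []
    starts_all: list[np.ndarray] = []
    lens_all: list[np.ndarray] = []
    for chrom in g0.chroms:
        ss, ee = g0.arrays(chrom)
        chroms.extend([chrom] * ss.size)
        starts_all.append(ss)
        lens_all.append(ee - ss + 1)
    starts = np.concatenate(starts_all)
    lens = np.concatenate(lens_all)
    cum = np.cumsum(lens)
    total = int(cum[-1])
    h = _h_per_cell(partition, spec, theta)
    h_max = float(h.max())
    # pattern lookup per proposal via the cell intervals, flattened per chrom
    cell_lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for mask in partition.masks:
        hi = h[np.searchsorted(partition.masks, mask)]
        for chrom, (ss, ee) in partition.cells[int(mask)].items():
            entry = cell_lookup.setdefault(chrom, ([], [], []))  # type: ignore[arg-type]
            entry[0].extend(ss.tolist())  # type: ignore[attr-defined]
            entry[1].extend(ee.tolist())  # type: ignore[attr-defined]
            entry[2].extend([float(hi)] * ss.size)  # type: ignore[attr-defined]
    lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, (ss, ee, hh) in cell_lookup.items():
        ss = np.asarray(ss, dtype=np.int64)
        ee = np.asarray(ee, dtype=np.int64)
        hh = np.asarray(hh, dtype=float)
        order = np.argsort(ss)
        lookup[chrom] = (ss[order], ee[order], hh[order])
    out: list[Query] = []
    while len(out) < k:
        batch = max(64, int(1.5 * (k - len(out)) * np.exp(h_max - h.min())))
        batch = min(batch, 4 * k + 1024)
        u = rng.integers(0, total, size=batch)
        idx = np.searchsorted(cum, u, side="right")
        offs = u - (cum[idx] - lens[idx])
        pos = starts[idx] + offs
        accept_u = rng.random(batch)
        for i in range(batch):
            chrom = chroms[int(idx[i])]
            ss, ee, hh = lookup[chrom]
            j = int(np.searchsorted(ss, pos[i], side="right") - 1)
            h_here = float(hh[j])
            if accept_u[i] < np.exp(h_here - h_max):
                out.append(Query(chrom, int(pos[i]), y))
                if len(out) == k:
                    break
    return out


# ---------------------------------------------------------------------------
# study drivers


def _study_partition(
    refs: Sequence[IntervalSet],
    mappable: IntervalSet,
    layout: GenomeLayout,
    options: SimOptions,
) -> OverlapPartition:
    if not isinstance(options.lengths, int):
        raise InputError("study drivers require a fixed query length")
    return build_partition(refs, mappable, options.lengths, layout)


def estimation_study(
    true_theta: np.ndarray,
    spec: ModelSpec,
    refs: Sequence[IntervalSet],
    mappable: IntervalSet,
    layout: GenomeLayout,
    options: SimOptions,
    *,
    max_divergence_fraction: float = 0.5,
) -> StudyResult:
    """Empirical distribution of the MLE when fitting the true model.

    Per replicate: simulate n queries at ``true_theta``, fit ``spec``, record
    theta_hat.  Non-convergent replicates are counted and excluded.  Aborts
    if the divergence fraction exceeds ``max_divergence_fraction``.
    """
    true_theta = np.asarray(true_theta, dtype=float)
    part = _study_partition(refs, mappable, layout, options)
    ident = check_identifiability(spec, [part])
    if not ident:
        raise InputError(
            f"true model is not identifiable on this geometry "
            f"(rank {ident.rank} < d={ident.d})"
        )
    child_seeds = np.random.SeedSequence(options.seed).spawn(options.reps)
    thetas: list[np.ndarray] = []
    n_div = 0
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        counts = _sample_cell_counts(part, spec, true_theta, options.n, rng)
        data = OverlapDataset.from_cell_counts(part, counts)
        fit = data.fit(spec)
        if fit.converged:
            thetas.append(fit.theta_hat)
        else:
            n_div += 1
    if n_div > max_divergence_fraction * options.reps:
        raise ConvergenceError(
            f"{n_div}/{options.reps} replicates diverged; increase n or "
            "check feasibility of the true model on this geometry"
        )
    arr = np.asarray(thetas)
    return StudyResult(
        terms=tuple(tuple(sorted(t)) for t in spec.terms),
        mean_theta=arr.mean(axis=0),
        std_theta=arr.std(axis=0, ddof=1),
        n_converged=len(thetas),
        n_diverged=n_div,
        reps=options.reps,
    )


def selection_study(
    true_theta: np.ndarray,
    spec: ModelSpec,
    candidates: Sequence[Sequence[int]],
    refs: Sequence[IntervalSet],
    mappable: IntervalSet,
    layout: GenomeLayout,
    options: SimOptions,
) -> StudyResult:
    """Stepwise-selection performance over replicate simulated datasets.

    Tabulates the percentage of replicates per selected configuration, the
    per-term selection rate, the rate at which all true terms are recovered,
    and the rate of exact recovery (true configuration and nothing else).
    """
    true_theta = np.asarray(true_theta, dtype=float)
    part = _study_partition(refs, mappable, layout, options)
    true_terms = {tuple(sorted(t)) for t in spec.terms}
    child_seeds = np.random.SeedSequence(options.seed).spawn(options.reps)
    config_counts: dict[tuple[tuple[int, ...], ...], int] = {}
    term_counts: dict[tuple[int, ...], int] = {}
    exact = 0
    all_true = 0
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        counts = _sample_cell_counts(part, spec, true_theta, options.n, rng)
        data = OverlapDataset.from_cell_counts(part, counts)
        sel = stepwise_select(data, candidates, compute_tests=False)
        picked = tuple(sorted(sel.selected_terms(), key=lambda t: (len(t), t)))
        config_counts[picked] = config_counts.get(picked, 0) + 1
        for t in picked:
            term_counts[t] = term_counts.get(t, 0) + 1
        if set(picked) == true_terms:
            exact += 1
        if true_terms <= set(picked):
            all_true += 1
    reps = options.reps
    return StudyResult(
        terms=tuple(sorted(true_terms, key=lambda t: (len(t), t))),
        reps=reps,
        config_percent={k: 100.0 * v / reps for k, v in config_counts.items()},
        term_rate={k: v / reps for k, v in term_counts.items()},
        exact_percent=100.0 * exact / reps,
        all_true_percent=100.0 * all_true / reps,
    )


def convergence_rate(
    true_theta: np.ndarray,
    spec: ModelSpec,
    refs: Sequence[IntervalSet],
    mappable: IntervalSet,
    layout: GenomeLayout,
    n: int,
    reps: int,
    *,
    seed: int = 0,
    threshold: float = 5.0,
    lengths: int = 1,
) -> float:
    """Proportion of replicates whose MLE has every |theta_hat| < threshold."""
    true_theta = np.asarray(true_theta, dtype=float)
    options = SimOptions(seed=seed, n=n, reps=reps, lengths=lengths)
    part = _study_partition(refs, mappable, layout, options)
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    good = 0
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        counts = _sample_cell_counts(part, spec, true_theta, n, rng)
        data = OverlapDataset.from_cell_counts(part, counts)
        fit = data.fit(spec, divergence_threshold=threshold)
        if fit.converged:
            good += 1
    return good / reps


def required_sample_size(
    true_theta: np.ndarray,
    spec: ModelSpec,
    refs: Sequence[IntervalSet],
    mappable: IntervalSet,
    layout: GenomeLayout,
    *,
    target: float = 0.99,
    reps: int = 1000,
    n_grid: Sequence[int] = (10, 20, 30, 44, 60, 80, 120, 200, 400, 800),
    seed: int = 0,
    threshold: float = 5.0,
) -> StudyResult:
    """Smallest n on the grid achieving the target convergence rate."""
    for i, n in enumerate(sorted(n_grid)):
        rate = convergence_rate(
            true_theta, spec, refs, mappable, layout, int(n), reps,
            seed=seed + i, threshold=threshold,
        )
        if rate >= target:
            return StudyResult(
                reps=reps, convergence_rate=rate, required_n=int(n), achieved=True
            )
    return StudyResult(reps=reps, convergence_rate=rate, required_n=None, achieved=False)


# ---------------------------------------------------------------------------
# synthetic reference geometries


def synth_references(
    layout: GenomeLayout,
    n_sets: int,
    n_intervals: int | Sequence[int],
    mean_length: float | Sequence[float],
    seed: int = 0,
    *,
    ensure_identifiable: bool = True,
    query_length: int = 1,
    max_retries: int = 50,
    nested_pair: tuple[int, int] | None = None,
) -> list[IntervalSet]:
    """Seeded random reference sets, verified identifiable for the full model.

    Interval starts are uniform on each chromosome (weighted by length);
    interval lengths are geometric with the requested mean.  Generated sets
    are resampled (up to ``max_retries``) until every one of the 2^N overlap
    pattern cells is realized at the given query length, so the full model
    is identifiable on the output.  ``nested_pair=(i, j)`` instead forces
    R_j inside R_i (1-based), producing a deliberately non-identifiable
    geometry for negative tests — identifiability is then not enforced.
    """
    if n_sets < 1:
        raise InputError("n_sets must be >= 1")
    counts = (
        [int(n_intervals)] * n_sets
        if isinstance(n_intervals, (int, np.integer))
        else [int(c) for c in n_intervals]
    )
    means = (
        [float(mean_length)] * n_sets
        if isinstance(mean_length, (int, float, np.integer, np.floating))
        else [float(m) for m in mean_length]
    )
    if len(counts) != n_sets or len(means) != n_sets:
        raise InputError("per-set counts/lengths must match n_sets")
    chrom_names = list(layout.names)
    chrom_lens = np.asarray([layout.lengths[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    master = np.random.SeedSequence(seed)
    for attempt, ss in enumerate(master.spawn(max_retries)):
        rng = np.random.default_rng(ss)
        refs: list[IntervalSet] = []
        for i in range(n_sets):
            raw: dict[str, list[tuple[int, int]]] = {}
            ci = rng.choice(len(chrom_names), size=counts[i], p=chrom_p)
            for c in ci:
                chrom = chrom_names[int(c)]
                clen = int(chrom_lens[int(c)])
                length = min(int(rng.geometric(1.0 / max(means[i], 1.0))), clen)
                start = int(rng.integers(1, clen - length + 2))
                raw.setdefault(chrom, []).append((start, start + length - 1))
            refs.append(merge_normalize(raw, layout))
        if nested_pair is not None:
            i, j = nested_pair
            refs[j - 1] = _nested_inside(refs[i - 1], rng, layout)
            return refs
        if not ensure_identifiable:
            return refs
        part = build_partition(
            refs, IntervalSet.whole_genome(layout), query_length, layout
        )
        if part.masks.size == (1 << n_sets):
            return refs
    raise InputError(
        f"could not realize all {1 << n_sets} overlap pattern cells in "
        f"{max_retries} attempts; use a larger genome, fewer sets, or "
        "denser reference sets"
    )


def benchmark_geometry(
    seed: int = 11,
) -> tuple[GenomeLayout, list[IntervalSet], IntervalSet]:
    """The package's standard synthetic benchmark geometry.

    Five reference sets on a single 1 Mb chromosome, each built from 400
    intervals of mean length 600 b (≈ 20% coverage apiece after merging),
    fully mappable, and verified identifiable for the full 31-term model
    (all 32 overlap-pattern cells realized at y = 1).  Used by the recovery
    and selection studies as a stand-in for a real chromosome-scale track
    collection: the coverages and mutual overlap fractions are in the range
    typical of broad chromatin-domain annotations.
    """
    layout = GenomeLayout([("chr1", 1_000_000)])
    refs = synth_references(layout, 5, 400, 600.0, seed=seed)
    mappable = IntervalSet.whole_genome(layout)
    return layout, refs, mappable


def _nested_inside(
    outer: IntervalSet, rng: np.random.Generator, layout: GenomeLayout
) -> IntervalSet:
    """A set strictly inside ``outer`` (one sub-interval per outer interval)."""
    raw: dict[str, list[tuple[int, int]]] = {}
    for chrom, a, b in outer:
        if b - a + 1 >= 3:
            lo = int(rng.integers(a, b))
            hi = int(rng.integers(lo, b + 1))
            raw.setdefault(chrom, []).append((lo, hi))
    return merge_normalize(raw, layout)


def reference_summary(
    refs: Sequence[IntervalSet], layout: GenomeLayout
) -> dict:
    """Coverage and pairwise-overlap fractions of a reference collection."""
    from .intervals import intersect

    L = layout.total_length
    cov = [r.cardinality() / L for r in refs]
    pairwise = {}
    for i in range(len(refs)):
        for j in range(len(refs)):
            if i == j:
                continue
            inter = intersect(refs[i], refs[j]).cardinality()
            denom = refs[i].cardinality()
            pairwise[(i + 1, j + 1)] = inter / denom if denom else 0.0
    return {"coverage": cov, "fraction_of_i_inside_j": pairwise}
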