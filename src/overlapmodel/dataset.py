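"""Preprocessed dataset: partitions plus per-cell query counts.

All likelihood quantities depend on the data only through (a) the cell sizes
m_v(y) of the overlap partition and (b) the number of queries falling in each
cell.  :class:`OverlapDataset` caches exactly that, so fitting many candidate
models to one dataset (stepwise selection, likelihood-ratio tests) or many
simulated datasets on one geometry (power studies) never touches interval
arithmetic again.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .intervals import GenomeLayout, IntervalSet, QueryCollection
from .model import FitResult, ModelSpec, _LengthBlock, _lse, _newton, DIVERGENCE_THRESHOLD
from .partition import (
    OverlapPartition,
    SufficientStats,
    build_partition,
    query_patterns,
)

__all__ = ["OverlapDataset"]


@dataclass
class _LengthData:
    partition: OverlapPartition
    qcounts: np.ndarray  # queries per realized cell, aligned with partition.masks


class OverlapDataset:
    """Partitions and per-cell query counts for one query set on one geometry."""

    def __init__(
        self,
        n_refs: int,
        per_length: Mapping[int, _LengthData],
    ):
        self.n_refs = n_refs
        self.per_length = dict(per_length)
        self.n = int(sum(ld.qcounts.sum() for ld in self.per_length.values()))

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_queries(
        cls,
        queries: QueryCollection,
        refs: Sequence[IntervalSet],
        mappable: IntervalSet,
        layout: GenomeLayout,
        *,
        on_outside: str = "error",
    ) -> "OverlapDataset":
        per_length: dict[int, _LengthData] = {}
        for y, qs in queries.by_length().items():
            part = build_partition(refs, mappable, y, layout)
            sub = QueryCollection(qs)
            masks, _ = query_patterns(
                sub, refs, layout, mappable, on_outside=on_outside
            )
            counts = np.zeros(part.masks.size, dtype=np.int64)
            idx = np.searchsorted(part.masks, masks)
            # every in-domain query start lies in a realized cell
            np.add.at(counts, idx, 1)
            per_length[y] = _LengthData(partition=part, qcounts=counts)
        return cls(len(refs), per_length)

    @classmethod
    def from_cell_counts(
        cls,
        partition: OverlapPartition,
        counts: np.ndarray,
    ) -> "OverlapDataset":
        """Build directly from per-cell counts on a single-length partition."""
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != partition.masks.shape:
            raise InputError("counts must align with partition cells")
        return cls(
            partition.n_refs,
            {partition.y: _LengthData(partition=partition, qcounts=counts)},
        )

    # -- likelihood plumbing --------------------------------------------------

    def _term_masks(self, spec: ModelSpec) -> np.ndarray:
        return np.asarray(
            [sum(1 << (i - 1) for i in t) for t in spec.terms], dtype=np.int64
        )

    def sufficient_stats(self, spec: ModelSpec) -> SufficientStats:
        tmasks = self._term_masks(spec)
        t = np.zeros(spec.d, dtype=np.int64)
        for ld in self.per_length.values():
            cm = ld.partition.masks
            if spec.d:
                hit = (cm[:, None] & tmasks[None, :]) == tmasks[None, :]
                t += (ld.qcounts[:, None] * hit).sum(axis=0)
        return SufficientStats(terms=spec.terms, t=t, n=self.n)

    def _blocks(self, spec: ModelSpec) -> list[_LengthBlock]:
        tmasks = self._term_masks(spec)
        blocks = []
        for y in sorted(self.per_length):
            ld = self.per_length[y]
            part = ld.partition
            cm = part.masks
            if spec.d:
                S = ((cm[:, None] & tmasks[None, :]) == tmasks[None, :]).astype(float)
            else:
                S = np.zeros((cm.size, 0))
            log_w = np.log(part.sizes.astype(float)) - np.log(float(part.g0_size))
            blocks.append(
                _LengthBlock(log_w=log_w, S=S, n_y=int(ld.qcounts.sum()))
            )
        return blocks

    # -- fast path for repeated fits (stepwise, GLRT, studies) ----------------
    #
    # Terms are identified by bitmask; per-term design columns and sufficient
    # statistics are computed once per dataset and reused by every candidate
    # model.  Results are identical to ``fit`` (same _newton core).

    def _col(self, y: int, tmask: int) -> np.ndarray:
        cache = getattr(self, "_col_cache", None)
        if cache is None:
            cache = self._col_cache = {}
        key = (y, tmask)
        if key not in cache:
            cm = self.per_length[y].partition.masks
            cache[key] = ((cm & tmask) == tmask).astype(float)
        return cache[key]

    def _t_of(self, tmask: int) -> int:
        cache = getattr(self, "_t_cache", None)
        if cache is None:
            cache = self._t_cache = {}
        if tmask not in cache:
            tot = 0
            for ld in self.per_length.values():
                cm = ld.partition.masks
                tot += int(ld.qcounts[(cm & tmask) == tmask].sum())
            cache[tmask] = tot
        return cache[tmask]

    def _log_w(self, y: int) -> np.ndarray:
        cache = getattr(self, "_logw_cache", None)
        if cache is None:
            cache = self._logw_cache = {}
        if y not in cache:
            part = self.per_length[y].partition
            lw = np.log(part.sizes.astype(float)) - np.log(float(part.g0_size))
            cache[y] = lw - _lse(lw)
        return cache[y]

    def fit_masks(
        self,
        tmasks: Sequence[int],
        *,
        divergence_threshold: float = DIVERGENCE_THRESHOLD,
        tol: float = 1e-8,
    ) -> tuple[np.ndarray, float, bool]:
        """MLE for the model whose terms are the given bitmasks.

        Returns (theta_hat, loglik, converged).  Used by stepwise selection
        where thousands of candidate models share one dataset.
        """
        T = np.asarray([self._t_of(m) for m in tmasks], dtype=float)
        blocks = []
        for y in sorted(self.per_length):
            ld = self.per_length[y]
            if tmasks:
                S = np.column_stack([self._col(y, m) for m in tmasks])
            else:
                S = np.zeros((ld.partition.masks.size, 0))
            blocks.append(
                _LengthBlock(log_w=self._log_w(y), S=S, n_y=int(ld.qcounts.sum()))
            )
        theta, ll, grad, info, num_ok, _ = _newton(
            T, blocks, tol=tol, divergence_threshold=divergence_threshold
        )
        ok = bool(num_ok and not np.any(np.abs(theta) >= divergence_threshold))
        return theta, ll, ok

    def fit(
        self,
        spec: ModelSpec,
        *,
        tol: float = 1e-8,
        max_iter: int = 200,
        divergence_threshold: float = DIVERGENCE_THRESHOLD,
        with_ci: bool = False,
        alpha: float = 0.05,
    ) -> FitResult:
        """MLE of ``spec`` on this dataset (fast path, no interval work)."""
        stats = self.sufficient_stats(spec)
        blocks = self._blocks(spec)
        theta, ll, grad, info, num_ok, n_iter = _newton(
            stats.t.astype(float),
            blocks,
            tol=tol,
            max_iter=max_iter,
            divergence_threshold=divergence_threshold,
        )
        diverged = [
            tuple(sorted(t))
            for t, v in zip(spec.terms, theta)
            if abs(v) >= divergence_threshold
        ]
        fit = FitResult(
            spec=spec,
            theta_hat=theta,
            loglik=ll,
            score_norm=float(np.max(np.abs(grad))) if grad.size else 0.0,
            observed_information=info,
            converged=bool(num_ok and not diverged),
            diverged_terms=diverged,
            n_obs=self.n,
            n_iter=n_iter,
        )
        if with_ci and fit.converged and spec.d > 0:
            from .model import wald_ci
            from .errors import IdentifiabilityError

            try:
                fit.ci = wald_ci(fit, alpha)
            except IdentifiabilityError:
                pass
        return fit

    def partitions(self) -> list[OverlapPartition]:
        return [ld.partition for _, ld in sorted(self.per_length.items())]

    def parts_mapping(self) -> dict[int, tuple[OverlapPartition, int]]:
        """The ``{y: (partition, n_y)}`` mapping used by the model-module API."""
        return {
            y: (ld.partition, int(ld.qcounts.sum()))
            for y, ld in self.per_length.items()
        }
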