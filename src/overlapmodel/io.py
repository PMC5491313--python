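"""File I/O: BED3, chrom.sizes, and report writing.

BED uses 0-based half-open coordinates; internally everything is 1-based
inclusive, so a BED record ``chrom  10  20`` becomes the locus interval
[11, 20].  Reference BEDs are merged/normalized on read; query BEDs keep
every record as an individual (x, y) observation, duplicates included.
BED scores/strands are ignored (the model is strandless); a one-time
warning is emitted if such columns are present.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

from .errors import InputError
from .intervals import (
    GenomeLayout,
    IntervalSet,
    Query,
    QueryCollection,
    merge_normalize,
)

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "read_query_bed",
    "write_bed",
    "write_query_bed",
    "write_report",
]

logger = logging.getLogger(__name__)


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Parse a tab-separated ``name<TAB>length`` chrom.sizes file."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 'name<TAB>length'")
            name = parts[0]
            if name in seen:
                raise InputError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            try:
                length = int(parts[1])
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: length {parts[1]!r} is not an integer"
                ) from None
            chroms.append((name, length))
    if not chroms:
        raise InputError(f"{path}: no chromosomes found")
    return GenomeLayout(chroms)


def _parse_bed_lines(path: str | Path, layout: GenomeLayout, on_unknown: str):
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields"
                )
            if len(parts) > 3 and not warned_extra:
                logger.warning(
                    "%s: columns beyond chrom/start/end (scores, strands) are "
                    "ignored — the model is strandless",
                    path,
                )
                warned_extra = True
            chrom = parts[0]
            try:
                bed_start, bed_end = int(parts[1]), int(parts[2])
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: non-integer coordinates {parts[1:3]}"
                ) from None
            if bed_start >= bed_end:
                raise InputError(
                    f"{path}:{lineno}: start {bed_start} >= end {bed_end} "
                    "(BED is 0-based half-open)"
                )
            if chrom not in layout.lengths:
                if on_unknown == "skip":
                    logger.warning(
                        "%s:%d: skipping unknown chromosome %r", path, lineno, chrom
                    )
                    continue
                raise InputError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            # 0-based half-open -> 1-based inclusive
            yield lineno, chrom, bed_start + 1, bed_end


def read_bed(
    path: str | Path, layout: GenomeLayout, *, on_unknown: str = "error"
) -> IntervalSet:
    """Read a reference/mappability BED as a normalized interval set."""
    if on_unknown not in ("error", "skip"):
        raise InputError("on_unknown must be 'error' or 'skip'")
    raw: dict[str, list[tuple[int, int]]] = {}
    for lineno, chrom, start, end in _parse_bed_lines(path, layout, on_unknown):
        if end > layout.length_of(chrom):
            raise InputError(
                f"{path}:{lineno}: interval end {end} beyond chromosome "
                f"{chrom!r} length {layout.length_of(chrom)}"
            )
        raw.setdefault(chrom, []).append((start, end))
    return merge_normalize(raw, layout)


def read_query_bed(
    path: str | Path, layout: GenomeLayout, *, on_unknown: str = "error"
) -> QueryCollection:
    """Read a query BED; each record becomes one (x, y) observation, unmerged."""
    if on_unknown not in ("error", "skip"):
        raise InputError("on_unknown must be 'error' or 'skip'")
    queries: list[Query] = []
    for lineno, chrom, start, end in _parse_bed_lines(path, layout, on_unknown):
        q = Query(chrom, start, end - start + 1)
        try:
            q.validate(layout)
        except InputError as e:
            raise InputError(f"{path}:{lineno}: {e}") from None
        queries.append(q)
    if not queries:
        raise InputError(f"{path}: no query intervals found")
    return QueryCollection(queries)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write an interval set as BED3 (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, a, b in s:
            fh.write(f"{chrom}\t{a - 1}\t{b}\n")


def write_query_bed(queries: QueryCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for q in queries:
            fh.write(f"{q.chrom}\t{q.x - 1}\t{q.end}\n")


def write_report(
    result,
    out_dir: str | Path,
    *,
    names: Sequence[str] | None = None,
    stem: str = "selection",
) -> dict[str, Path]:
    """Write a SelectionResult (or FitResult) as JSON + TSV files.

    The JSON is schema-versioned; the TSV mirrors the standard report table
    (Model Term, Primary Effect, theta_hat, p-value).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    json_path = out_dir / f"{stem}.json"
    payload = (
        result.to_json_dict()
        if hasattr(result, "to_json_dict")
        else dict(result)
    )
    if "schema_version" not in payload:
        payload = {"schema_version": 1, **payload}
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    paths["json"] = json_path
    if hasattr(result, "to_tsv"):
        tsv_path = out_dir / f"{stem}.tsv"
        tsv_path.write_text(result.to_tsv(names))
        paths["tsv"] = tsv_path
    return paths
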