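"""Catalog cleaning: mitochondrial/length filters, breakpoint merging,
and the minimum split-read filter, applied in that fixed order.

Merging is single-linkage clustering of circles on the same chromosome
under the breakpoint distance d(a, b) = max(|a.start - b.start|,
|a.end - b.end|), with link condition d < d_min. Each cluster is
replaced by the member with the most split reads (ties: smallest start,
then smallest end), carrying the summed split reads of the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import CircleCall, CircleCatalog, PipelineParams

logger = logging.getLogger(__name__)


@dataclass
class FilterTrace:
    """Per-stage call counts, the debugging surface for the chain."""

    n_input: int
    n_after_mito_length: int
    n_after_merge: int
    n_after_split_reads: int


def filter_mito_and_length(catalog: CircleCatalog, params: PipelineParams) -> CircleCatalog:
    """Drop mitochondrial circles and circles longer than ``l_max``.

    The length cut is strict: a circle of length exactly ``l_max`` is
    kept.
    """
    kept = [
        c
        for c in catalog
        if c.chrom not in params.mito_names and c.length <= params.l_max
    ]
    return catalog.replace_calls(kept)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _representative(members: list[CircleCall]) -> CircleCall:
    # highest support wins; ties resolved leftmost, then shortest
    best = min(members, key=lambda c: (-c.split_reads, c.start, c.end))
    total = sum(c.split_reads for c in members)
    return CircleCall(best.chrom, best.start, best.end, total)


def merge_circles(catalog: CircleCatalog, d_min: int) -> CircleCatalog:
    """Merge clusters of near-identical circles, summing split reads.

    Single-linkage under the breakpoint distance (see module docstring);
    total split reads are conserved. Implemented as a sorted sweep: a
    link requires |delta start| < d_min, so only calls within a d_min
    window of starts need pairwise checks.
    """
    merged: list[CircleCall] = []
    by_chrom: dict[str, list[CircleCall]] = {}
    for c in catalog:
        by_chrom.setdefault(c.chrom, []).append(c)

    for chrom in sorted(by_chrom):
        calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        uf = _UnionFind(len(calls))
        for i, a in enumerate(calls):
            for j in range(i + 1, len(calls)):
                b = calls[j]
                if b.start - a.start >= d_min:
                    break
                if abs(b.end - a.end) < d_min:
                    uf.union(i, j)
        clusters: dict[int, list[CircleCall]] = {}
        for i, c in enumerate(calls):
            clusters.setdefault(uf.find(i), []).append(c)
        merged.extend(_representative(members) for members in clusters.values())

    return catalog.replace_calls(merged)


def filter_split_reads(catalog: CircleCatalog, jt_min: int) -> CircleCatalog:
    """Keep only circles supported by at least ``jt_min`` split reads."""
    return catalog.replace_calls([c for c in catalog if c.split_reads >= jt_min])


def run_filter_chain(
    catalog: CircleCatalog, params: PipelineParams
) -> tuple[CircleCatalog, FilterTrace]:
    """Apply filter -> merge -> filter in the fixed pipeline order."""
    n0 = len(catalog)
    stage1 = filter_mito_and_length(catalog, params)
    stage2 = merge_circles(stage1, params.d_min)
    stage3 = filter_split_reads(stage2, params.jt_min)
    trace = FilterTrace(n0, len(stage1), len(stage2), len(stage3))
    logger.info(
        "sample %s: %d calls -> %d after mito/length -> %d after merge -> %d after JT filter",
        catalog.sample_id, n0, trace.n_after_mito_length, trace.n_after_merge,
        trace.n_after_split_reads,
    )
    return stage3, trace
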