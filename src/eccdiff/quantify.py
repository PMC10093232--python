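"""Gene annotation of circles and per-gene circle production (PpGC).

raw[g, s] sums the split reads of every circle in sample s that
overlaps gene g by at least 1 bp (half-open intervals). Scaling
multiplies by L_Max / L_i, where L_Max is the longest gene observed
with nonzero raw signal in the run; equalization is log2(x + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    CircleCall,
    CircleCatalog,
    EccdiffError,
    GeneAnnotation,
    GeneRecord,
    SampleManifest,
    groups_of,
)

logger = logging.getLogger(__name__)

Assignment = list[tuple[CircleCall, list[GeneRecord]]]


@dataclass
class PpGCMatrix:
    """Genes-by-samples circle-production matrix in three layers."""

    raw: pd.DataFrame
    scaled: pd.DataFrame
    equalized: pd.DataFrame
    gene_lengths: pd.Series
    groups: dict[str, str]
    l_max: int

    @property
    def genes(self) -> list[str]:
        return list(self.raw.index)

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]


@dataclass
class WholeGeneReport:
    """Genes fully contained in at least one circle, per sample."""

    per_sample: dict[str, list[str]]
    recurrent: pd.DataFrame  # columns: gene, N, L, samples


def annotate_circles(catalog: CircleCatalog, genes: GeneAnnotation) -> Assignment:
    """Assign to each circle every gene it overlaps by >= 1 bp.

    Chromosomes present in the catalog but absent from the annotation
    yield empty assignments and are logged once each.
    """
    missing_logged: set[str] = set()
    out: Assignment = []
    for circle in catalog:
        chrom_genes = genes.by_chrom(circle.chrom)
        if not chrom_genes and circle.chrom not in genes.chroms:
            if circle.chrom not in missing_logged:
                logger.info("chromosome %s absent from annotation", circle.chrom)
                missing_logged.add(circle.chrom)
        hits = [
            g for g in chrom_genes
            if g.start < circle.end and circle.start < g.end
        ]
        out.append((circle, hits))
    return out


def compute_ppgc(
    assignments: Mapping[str, Assignment],
    manifest: SampleManifest | Mapping[str, str],
    attribution: str = "full",
) -> PpGCMatrix:
    """Build the PpGC matrix from per-sample circle->gene assignments.

    With the default ``attribution="full"`` a circle overlapping k genes
    contributes its full split-read count to each of them; with
    ``"proportional"`` the count is apportioned by overlap length.
    Genes with zero raw signal in every sample are dropped; L_Max is the
    longest gene remaining in the matrix.
    """
    if attribution not in {"full", "proportional"}:
        raise ValueError(f"unknown attribution mode {attribution!r}")
    groups = groups_of(manifest)
    samples = [s for s in groups if s in assignments]
    if set(assignments) - set(groups):
        raise EccdiffError("assignments contain samples missing from the manifest")
    if set(groups) - set(assignments):
        raise EccdiffError("manifest samples missing from assignments")

    gene_lengths: dict[str, int] = {}
    raw: dict[str, dict[str, float]] = {s: {} for s in samples}
    for sample in samples:
        acc = raw[sample]
        for circle, hits in assignments[sample]:
            if not hits:
                continue
            if attribution == "full":
                for g in hits:
                    acc[g.name] = acc.get(g.name, 0) + circle.split_reads
                    gene_lengths[g.name] = g.length
            else:
                overlaps = np.array(
                    [min(circle.end, g.end) - max(circle.start, g.start) for g in hits],
                    dtype=float,
                )
                weights = overlaps / overlaps.sum()
                for g, w in zip(hits, weights):
                    acc[g.name] = acc.get(g.name, 0) + circle.split_reads * w
                    gene_lengths[g.name] = g.length

    gene_names = sorted(gene_lengths)
    if not gene_names:
        raise EccdiffError("no genic eccDNA: no gene overlapped by any circle")
    dtype = int if attribution == "full" else float
    raw_df = pd.DataFrame(0, index=gene_names, columns=samples, dtype=dtype)
    for sample in samples:
        for gene, v in raw[sample].items():
            raw_df.loc[gene, sample] = v
    raw_df = raw_df.loc[raw_df.sum(axis=1) > 0]
    if raw_df.empty:
        raise EccdiffError("no genic eccDNA: all per-gene counts are zero")
    gene_names = list(raw_df.index)

    lengths = pd.Series({g: gene_lengths[g] for g in gene_names}, name="length")
    l_max = int(lengths.max())
    scaled = raw_df.mul(l_max / lengths, axis=0)
    equalized = np.log2(scaled + 1.0)
    return PpGCMatrix(
        raw=raw_df,
        scaled=scaled,
        equalized=equalized,
        gene_lengths=lengths,
        groups={s: groups[s] for s in samples},
        l_max=l_max,
    )


def quantify_catalogs(
    catalogs: Mapping[str, CircleCatalog],
    genes: GeneAnnotation,
    manifest: SampleManifest | Mapping[str, str],
    attribution: str = "full",
) -> PpGCMatrix:
    """Convenience: annotate every catalog and build the PpGC matrix."""
    assignments = {s: annotate_circles(cat, genes) for s, cat in catalogs.items()}
    return compute_ppgc(assignments, manifest, attribution=attribution)


def whole_gene_carriage(
    catalogs: Mapping[str, CircleCatalog], genes: GeneAnnotation
) -> WholeGeneReport:
    """Find genes fully contained in a circle, per sample and recurrent.

    A gene is whole-carried in a sample iff some circle spans it
    completely (circle.start <= gene.start and circle.end >= gene.end on
    the same chromosome). Recurrent genes are those whole-carried in at
    least two samples.
    """
    per_sample: dict[str, list[str]] = {}
    for sample_id, catalog in catalogs.items():
        carried: set[str] = set()
        for circle in catalog:
            for g in genes.by_chrom(circle.chrom):
                if circle.start <= g.start and circle.end >= g.end:
                    carried.add(g.name)
        per_sample[sample_id] = sorted(carried)

    counts: dict[str, list[str]] = {}
    for sample_id in sorted(per_sample):
        for gene in per_sample[sample_id]:
            counts.setdefault(gene, []).append(sample_id)
    lengths = genes.lengths()
    rows = [
        {"gene": g, "N": len(ss), "L": lengths[g], "samples": ",".join(ss)}
        for g, ss in sorted(counts.items())
        if len(ss) >= 2
    ]
    recurrent = pd.DataFrame(rows, columns=["gene", "N", "L", "samples"])
    if not recurrent.empty:
        recurrent = recurrent.sort_values(
            ["N", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return WholeGeneReport(per_sample=per_sample, recurrent=recurrent)
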