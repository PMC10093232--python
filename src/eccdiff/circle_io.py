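"""Readers and writers for every external format the pipeline touches.

Formats are all plain text: circle call tables and gene annotations are
tab-separated BED dialects, gene sets are GMT, manifests are TSV or YAML.
All writers produce byte-identical output for identical input (rows are
ordered deterministically, floats are printed with a round-trip format).
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .model import (
    CircleCall,
    CircleCatalog,
    EccdiffError,
    GeneAnnotation,
    GeneRecord,
    GeneSet,
    ManifestEntry,
    SampleManifest,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: float format that survives a write/read round trip exactly
FLOAT_FMT = "%.17g"


class ParseError(EccdiffError):
    """A malformed line in an input file; message names file and line."""


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_circle_table(path: str | os.PathLike, sample_id: str, group: str) -> CircleCatalog:
    """Read a circle call table (TSV: chrom, start, end, split_reads).

    Lines starting with ``#`` are treated as comments/headers. Exact
    duplicate intervals are collapsed by summing split reads; output is
    sorted by (chrom, start, end).
    """
    path = Path(path)
    calls: list[CircleCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_fields(line)
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end, split_reads = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            try:
                calls.append(CircleCall(chrom, start, end, split_reads))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not calls:
        warnings.warn(f"circle table {path} is empty", stacklevel=2)
    return CircleCatalog(sample_id=sample_id, group=group, calls=calls)


def write_circle_table(catalog: CircleCatalog, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsplit_reads\n")
        for c in catalog:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.split_reads}\n")


def read_gene_bed(path: str | os.PathLike) -> GeneAnnotation:
    """Read a BED4 gene annotation.

    Duplicate gene names are disambiguated by suffixing ``#k`` in input
    order (both copies are renamed: ``GENE#1``, ``GENE#2``, ...).
    """
    path = Path(path)
    raw: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_fields(line)
            if len(fields) < 4 or not fields[3]:
                raise ParseError(f"{path}:{lineno}: gene BED needs 4 columns incl. name")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: zero/negative-length gene interval")
            raw.append((fields[0], start, end, fields[3]))
    if not raw:
        raise ParseError(f"{path}: no genes")

    counts: dict[str, int] = {}
    for _, _, _, name in raw:
        counts[name] = counts.get(name, 0) + 1
    seen: dict[str, int] = {}
    genes: list[GeneRecord] = []
    for chrom, start, end, name in raw:
        if counts[name] > 1:
            seen[name] = seen.get(name, 0) + 1
            name = f"{name}#{seen[name]}"
        genes.append(GeneRecord(chrom, start, end, name))
    return GeneAnnotation(genes)


def write_gene_bed(annotation: GeneAnnotation, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in sorted(annotation.genes):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Read a GMT gene-set collection; member symbols are upper-cased."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                warnings.warn(f"{path}:{lineno}: GMT line with <3 fields skipped", stacklevel=2)
                continue
            members = frozenset(m.upper() for m in fields[2:] if m)
            if not members:
                warnings.warn(f"{path}:{lineno}: GMT line with no members skipped", stacklevel=2)
                continue
            sets.append(GeneSet(term_id=fields[0], term_name=fields[1], members=members))
    return sets


def read_manifest(path: str | os.PathLike) -> SampleManifest:
    """Read a sample manifest: TSV (sample_id, path, group) or YAML list.

    Relative circle-table paths are resolved against the manifest's
    directory.
    """
    path = Path(path)
    entries: list[ManifestEntry] = []
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, list):
            raise ParseError(f"{path}: YAML manifest must be a list of entries")
        for item in data:
            entries.append(ManifestEntry(str(item["sample_id"]), str(item["path"]), str(item["group"])))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = _split_fields(line)
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: manifest needs sample_id, path, group")
                entries.append(ManifestEntry(fields[0], fields[1], fields[2]))
    resolved = [
        ManifestEntry(e.sample_id, str((path.parent / e.path).resolve())
                      if not os.path.isabs(e.path) else e.path, e.group)
        for e in entries
    ]
    return SampleManifest(resolved)


def write_manifest(
    manifest: SampleManifest, path: str | os.PathLike, relative: bool = True
) -> None:
    """Write a manifest TSV; with ``relative`` circle-table paths are
    stored relative to the manifest's directory (relocatable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("#sample_id\tpath\tgroup\n")
        for e in manifest:
            p = os.path.relpath(e.path, path.parent) if relative else e.path
            fh.write(f"{e.sample_id}\t{p}\t{e.group}\n")


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    """Write a result table as TSV with a header and round-trip floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes-by-samples matrix TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_results(
    outdir: str | os.PathLike,
    *,
    catalogs: Iterable[CircleCatalog] | None = None,
    ppgc_raw: pd.DataFrame | None = None,
    ppgc_scaled: pd.DataFrame | None = None,
    ppgc_equalized: pd.DataFrame | None = None,
    dppgc: pd.DataFrame | None = None,
    enrichment: pd.DataFrame | None = None,
) -> list[Path]:
    """Write whichever result tables are given; returns written paths.

    DPpGC rows are ordered by ascending p, then descending |diff|, then
    gene symbol; all other tables keep their (already deterministic)
    order. Matrices are written with genes as the index column.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if catalogs is not None:
        for cat in catalogs:
            p = outdir / f"circles_{cat.sample_id}.tsv"
            write_circle_table(cat, p)
            written.append(p)
    for name, df in (
        ("ppgc_raw", ppgc_raw),
        ("ppgc_scaled", ppgc_scaled),
        ("ppgc_equalized", ppgc_equalized),
    ):
        if df is not None:
            p = outdir / f"{name}.tsv"
            out = df.copy()
            out.index.name = "gene"
            write_table(out, p, index=True)
            written.append(p)
    if dppgc is not None:
        p = outdir / "dppgc.tsv"
        out = dppgc.copy()
        if not out.empty:
            out["_absdiff"] = out["diff"].abs()
            out = out.sort_values(
                ["p_value", "_absdiff", "gene"], ascending=[True, False, True]
            ).drop(columns="_absdiff")
        write_table(out, p)
        written.append(p)
    if enrichment is not None:
        p = outdir / "enrichment.tsv"
        write_table(enrichment, p)
        written.append(p)
    return written
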