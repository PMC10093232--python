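"""Core domain types shared by every pipeline stage.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``; an interval's length is ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

DEFAULT_MITO_NAMES = frozenset({"chrM", "chrMT", "MT", "M"})


class EccdiffError(Exception):
    """Base class for all package errors."""


class ValidationError(EccdiffError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True, order=True)
class CircleCall:
    """One detected eccDNA: a genomic interval plus its split-read support."""

    chrom: str
    start: int
    end: int
    split_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid circle interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.split_reads < 0:
            raise ValidationError(
                f"negative split_reads {self.split_reads} for "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class CircleCatalog:
    """Per-sample collection of circle calls, sorted and deduplicated.

    Exact-duplicate intervals are collapsed at construction by summing
    their split reads, so every (chrom, start, end) appears once.
    """

    sample_id: str
    group: str
    calls: list[CircleCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: dict[tuple[str, int, int], int] = {}
        for call in self.calls:
            key = call.interval
            merged[key] = merged.get(key, 0) + call.split_reads
        self.calls = [
            CircleCall(chrom, start, end, sr)
            for (chrom, start, end), sr in sorted(merged.items())
        ]

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CircleCall]:
        return iter(self.calls)

    @property
    def total_split_reads(self) -> int:
        return sum(c.split_reads for c in self.calls)

    def replace_calls(self, calls: Iterable[CircleCall]) -> "CircleCatalog":
        return CircleCatalog(self.sample_id, self.group, list(calls))


@dataclass(frozen=True, order=True)
class GeneRecord:
    """A named gene interval; length feeds the per-gene scale factor."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid gene interval {self.name} {self.chrom}:{self.start}-{self.end}"
            )
        if not self.name:
            raise ValidationError("gene name must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneAnnotation:
    """Ordered collection of genes with unique names."""

    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene names in annotation")
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        for g in sorted(self.genes):
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def by_chrom(self, chrom: str) -> list[GeneRecord]:
        return self._by_chrom.get(chrom, [])

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def lengths(self) -> dict[str, int]:
        return {g.name: g.length for g in self.genes}


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line)."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.term_id} has no members")


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    path: str
    group: str


@dataclass
class SampleManifest:
    """Assignment of samples to circle tables and to the two study groups."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in manifest")
        if len(self.group_labels) != 2:
            raise ValidationError(
                f"manifest must define exactly two groups, got {sorted(self.group_labels)}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ManifestEntry]:
        return iter(self.entries)

    @property
    def group_labels(self) -> set[str]:
        return {e.group for e in self.entries}

    @property
    def groups(self) -> dict[str, str]:
        """Mapping sample_id -> group label, in manifest order."""
        return {e.sample_id: e.group for e in self.entries}

    def samples_in(self, group: str) -> list[str]:
        return [e.sample_id for e in self.entries if e.group == group]


@dataclass
class PipelineParams:
    """Tunable thresholds of the catalog-cleaning and selection chain."""

    l_max: int = 10_000
    d_min: int = 10
    jt_min: int = 2
    mito_names: frozenset[str] = DEFAULT_MITO_NAMES
    theta_dppgc: float = 5.0
    alpha_dppgc: float = 0.01
    alpha_wilcoxon: float = 0.01

    def __post_init__(self) -> None:
        self.mito_names = frozenset(self.mito_names)
        if self.l_max <= 0:
            raise ValidationError("l_max must be > 0")
        if self.d_min < 0:
            raise ValidationError("d_min must be >= 0")
        if self.jt_min < 1:
            raise ValidationError("jt_min must be >= 1")
        if not (0 < self.alpha_dppgc < 1):
            raise ValidationError("alpha_dppgc must lie in (0, 1)")
        if self.theta_dppgc < 0:
            raise ValidationError("theta_dppgc must be >= 0")


def groups_of(manifest_or_mapping: "SampleManifest | Mapping[str, str]") -> dict[str, str]:
    """Accept either a SampleManifest or a plain sample->group mapping."""
    if isinstance(manifest_or_mapping, SampleManifest):
        return manifest_or_mapping.groups
    return dict(manifest_or_mapping)
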