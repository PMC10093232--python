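"""Synthetic two-group eccDNA cohorts with ground truth.

Cohorts emulate the structure the analysis assumes: per-sample circle
counts that differ between groups, nucleosome-periodic length mixtures
(peaks near 200 and 350 bp) with a heavier long tail in the case group,
genic circle placement, a planted set of case-specific genes, and noise
circles (single split read, mitochondrial, oversize) that exercise
every filter. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import circle_io
from .model import (
    CircleCall,
    CircleCatalog,
    EccdiffError,
    GeneAnnotation,
    GeneRecord,
    ManifestEntry,
    SampleManifest,
)

logger = logging.getLogger(__name__)

_MIN_CIRCLE_LEN = 50


@dataclass
class SynthConfig:
    """Knobs of the cohort generator; defaults give the desk-scale profile.

    The desk-scale profile scales the target per-sample circle counts
    down about tenfold (control ~55, case ~1700 at a ~1:31 ratio) so the
    full suite stays fast; :func:`paper_scale_config` restores the
    printed magnitudes.
    """

    seed: int
    n_control: int = 6
    n_case: int = 4
    control_label: str = "HC"
    case_label: str = "SLE"
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 20_000_000),
        ("chr2", 15_000_000),
        ("chrM", 16_569),
    )
    mito_chroms: tuple[str, ...] = ("chrM",)
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1_000, 5_000)
    count_mean_control: float = 55.0
    count_mean_case: float = 1_700.0
    count_dispersion: float = 0.25
    peak_means: tuple[float, float] = (200.0, 350.0)
    peak_sigma: float = 15.0
    tail_weight_control: float = 0.05
    tail_weight_case: float = 0.20
    tail_offset: float = 650.0
    tail_scale: float = 1_500.0
    genic_fraction: float = 0.7
    n_planted: int = 5
    planted_reads_per_sample: int = 400
    planted_circles_per_gene: int = 4
    frac_singleton: float = 0.10
    frac_mito: float = 0.02
    frac_oversize: float = 0.02
    l_max: int = 10_000
    jt_min: int = 2

    def __post_init__(self) -> None:
        for name in ("genic_fraction", "tail_weight_control", "tail_weight_case",
                     "frac_singleton", "frac_mito", "frac_oversize"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise EccdiffError(f"{name} must lie in [0, 1], got {v}")
        if self.n_planted > self.n_genes:
            raise EccdiffError("n_planted cannot exceed n_genes")
        if self.n_control < 1 or self.n_case < 1:
            raise EccdiffError("need at least one sample per group")
        if not any(c not in self.mito_chroms for c, _ in self.genome):
            raise EccdiffError("genome needs at least one non-mitochondrial chromosome")

    def mixture_weights(self, group: str) -> np.ndarray:
        """Length-mixture weights (peak1, peak2, tail); they sum to 1."""
        tail = self.tail_weight_case if group == self.case_label else self.tail_weight_control
        return np.array([(1 - tail) / 2, (1 - tail) / 2, tail])

    @property
    def sample_ids(self) -> list[str]:
        controls = [f"{self.control_label}{i+1}" for i in range(self.n_control)]
        cases = [f"{self.case_label}{i+1}" for i in range(self.n_case)]
        return controls + cases

    @property
    def groups(self) -> dict[str, str]:
        out = {f"{self.control_label}{i+1}": self.control_label for i in range(self.n_control)}
        out.update({f"{self.case_label}{i+1}": self.case_label for i in range(self.n_case)})
        return out


def paper_scale_config(seed: int) -> SynthConfig:
    """Profile reproducing the printed per-sample count magnitudes."""
    return SynthConfig(seed=seed, count_mean_control=550.0, count_mean_case=17_000.0)


def recovery_config(seed: int, n_planted: int = 5, n_genes: int = 200) -> SynthConfig:
    """Profile for planted-gene recovery: null genes share one count model."""
    return SynthConfig(
        seed=seed,
        n_planted=n_planted,
        n_genes=n_genes,
        count_mean_control=300.0,
        count_mean_case=300.0,
        tail_weight_case=0.05,
    )


@dataclass
class CohortTruth:
    """Ground truth recorded alongside a generated cohort."""

    planted_genes: list[str]
    true_counts: dict[str, int]
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def generate_annotation(config: SynthConfig) -> GeneAnnotation:
    """Place non-overlapping genes on the non-mitochondrial chromosomes."""
    rng = _rng(config.seed, 0)
    chroms = [(c, ln) for c, ln in config.genome if c not in config.mito_chroms]
    total_len = sum(ln for _, ln in chroms)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)

    # assign genes to chromosomes proportionally to length
    per_chrom: list[int] = []
    assigned = 0
    for i, (_, ln) in enumerate(chroms):
        k = (
            config.n_genes - assigned
            if i == len(chroms) - 1
            else int(round(config.n_genes * ln / total_len))
        )
        per_chrom.append(k)
        assigned += k

    genes: list[GeneRecord] = []
    idx = 0
    gene_no = 0
    for (chrom, chrom_len), k in zip(chroms, per_chrom):
        if k == 0:
            continue
        chrom_lengths = lengths[idx:idx + k]
        idx += k
        occupied = int(chrom_lengths.sum())
        free = chrom_len - occupied
        if free < k + 1:
            raise EccdiffError(
                f"chromosome {chrom} too small for {k} genes totalling {occupied} bp"
            )
        gaps = rng.multinomial(free - (k + 1), np.full(k + 1, 1 / (k + 1))) + 1
        pos = 0
        for j, glen in enumerate(chrom_lengths):
            pos += int(gaps[j])
            gene_no += 1
            genes.append(GeneRecord(chrom, pos, pos + int(glen), f"GENE{gene_no:04d}"))
            pos += int(glen)
    return GeneAnnotation(genes)


def _overlaps_any(chrom: str, start: int, end: int, genes: list[GeneRecord]) -> bool:
    return any(g.chrom == chrom and g.start < end and start < g.end for g in genes)


def _draw_lengths(
    rng: np.random.Generator, config: SynthConfig, weights: np.ndarray, n: int
) -> np.ndarray:
    """Vector of circle lengths from the group's three-component mixture."""
    comps = rng.choice(3, size=n, p=weights)
    lengths = np.empty(n)
    for c in (0, 1):
        mask = comps == c
        lengths[mask] = rng.normal(config.peak_means[c], config.peak_sigma, mask.sum())
    mask = comps == 2
    lengths[mask] = config.tail_offset + rng.exponential(config.tail_scale, mask.sum())
    return np.clip(np.round(lengths), _MIN_CIRCLE_LEN, config.l_max).astype(int)


class _Placer:
    """Pre-indexed circle placement that avoids the planted genes."""

    def __init__(self, config: SynthConfig, genes: list[GeneRecord],
                 planted: list[GeneRecord]) -> None:
        self.config = config
        self.chrom_sizes = {c: ln for c, ln in config.genome}
        planted_set = set(planted)
        self.planted = planted
        self.open_genes = [g for g in genes if g not in planted_set]
        self.nonmito = [(c, ln) for c, ln in config.genome if c not in config.mito_chroms]
        self.probs = np.array([ln for _, ln in self.nonmito], dtype=float)
        self.probs /= self.probs.sum()

    def place(self, rng: np.random.Generator, length: int, genic: bool) -> tuple[str, int] | None:
        for _ in range(100):
            if genic and self.open_genes:
                g = self.open_genes[rng.integers(len(self.open_genes))]
                chrom = g.chrom
                lo = max(0, g.start - length + 1)
                hi = min(self.chrom_sizes[chrom] - length, g.end - 1)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
            else:
                chrom = self.nonmito[rng.choice(len(self.nonmito), p=self.probs)][0]
                start = int(rng.integers(0, self.chrom_sizes[chrom] - length))
            if not _overlaps_any(chrom, start, start + length, self.planted):
                return chrom, start
        return None


def sample_circle_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Per-sample circle count: log-normal with the given median and sigma."""
    return max(1, int(round(rng.lognormal(math.log(mean), dispersion))))


def generate_catalogs(
    config: SynthConfig,
) -> tuple[dict[str, CircleCatalog], GeneAnnotation, CohortTruth]:
    """Generate the cohort in memory: catalogs, annotation, and truth."""
    annotation = generate_annotation(config)
    planted_idx = sorted(
        _rng(config.seed, 1).choice(len(annotation.genes), config.n_planted, replace=False)
    )
    planted = [annotation.genes[i] for i in planted_idx]
    planted_names = sorted(g.name for g in planted)
    rng = _rng(config.seed, 2)

    mito = [(c, ln) for c, ln in config.genome if c in config.mito_chroms]
    placer = _Placer(config, annotation.genes, planted)
    catalogs: dict[str, CircleCatalog] = {}
    true_counts: dict[str, int] = {}
    for sample_id, group in config.groups.items():
        is_case = group == config.case_label
        mean = config.count_mean_case if is_case else config.count_mean_control
        n_circles = sample_circle_count(rng, mean, config.count_dispersion)
        true_counts[sample_id] = n_circles
        weights = config.mixture_weights(group)

        calls: list[CircleCall] = []
        lengths = _draw_lengths(rng, config, weights, n_circles)
        genic_draws = rng.random(n_circles) < config.genic_fraction
        reads_draws = config.jt_min + rng.geometric(0.5, n_circles) - 1
        for length, genic, reads in zip(lengths, genic_draws, reads_draws):
            placed = placer.place(rng, int(length), bool(genic))
            if placed is None:
                continue
            chrom, start = placed
            calls.append(CircleCall(chrom, start, start + int(length), int(reads)))

        # noise: sub-threshold, mitochondrial, oversize circles
        n_singleton = int(round(config.frac_singleton * n_circles))
        for length in _draw_lengths(rng, config, weights, n_singleton):
            placed = placer.place(rng, int(length), False)
            if placed is None:
                continue
            chrom, start = placed
            calls.append(CircleCall(chrom, start, start + int(length), 1))
        if mito:
            mchrom, mlen = mito[0]
            for _ in range(int(round(config.frac_mito * n_circles))):
                length = int(rng.integers(100, min(1_000, mlen - 1)))
                start = int(rng.integers(0, mlen - length))
                calls.append(CircleCall(mchrom, start, start + length,
                                        config.jt_min + int(rng.geometric(0.5)) - 1))
        for _ in range(int(round(config.frac_oversize * n_circles))):
            length = int(rng.integers(config.l_max + 1, 2 * config.l_max))
            placed = placer.place(rng, length, False)
            if placed is None:
                continue
            chrom, start = placed
            calls.append(CircleCall(chrom, start, start + length,
                                    config.jt_min + int(rng.geometric(0.5)) - 1))

        # planted case-specific signal, fragments strictly inside each gene
        if is_case:
            k = config.planted_circles_per_gene
            for g in planted:
                base, extra = divmod(config.planted_reads_per_sample, k)
                for j in range(k):
                    max_len = min(1_000, g.length)
                    length = int(rng.integers(150, max_len + 1)) if max_len > 150 else max_len
                    start = int(rng.integers(g.start, g.end - length + 1))
                    reads = base + (1 if j < extra else 0)
                    calls.append(CircleCall(g.chrom, start, start + length, reads))

        catalogs[sample_id] = CircleCatalog(sample_id, group, calls)

    truth = CohortTruth(
        planted_genes=planted_names,
        true_counts=true_counts,
        config={"seed": config.seed, **{
            k: v for k, v in dataclasses.asdict(config).items() if k != "seed"
        }},
    )
    return catalogs, annotation, truth


def generate_cohort(
    config: SynthConfig, outdir: str | Path
) -> tuple[SampleManifest, CohortTruth]:
    """Generate a cohort and write it as plain-text files.

    Writes one circle table per sample, the gene BED, a manifest TSV,
    and the truth JSON; returns the manifest and truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalogs, annotation, truth = generate_catalogs(config)

    entries = []
    for sample_id, catalog in catalogs.items():
        path = outdir / f"{sample_id}.circles.tsv"
        circle_io.write_circle_table(catalog, path)
        entries.append(ManifestEntry(sample_id, str(path.resolve()), catalog.group))
    circle_io.write_gene_bed(annotation, outdir / "genes.bed")
    manifest = SampleManifest(entries)
    circle_io.write_manifest(manifest, outdir / "manifest.tsv")
    truth.to_json(outdir / "truth.json")
    logger.info("cohort written to %s (%d samples)", outdir, len(entries))
    return manifest, truth
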