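"""End-to-end pipeline driver: read -> filter/merge -> quantify ->
differential -> length statistics -> enrichment -> reports.

Identical configuration and inputs produce byte-identical outputs; a
run-manifest JSON records parameters, the observed L_Max, input
checksums, and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, circle_io, differential, enrichment, filtermerge, lengthstats, quantify
from .model import EccdiffError, PipelineParams, SampleManifest

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    manifest: Path
    gene_bed: Path
    outdir: Path
    case_group: str
    control_group: str
    gmt: list[Path] = field(default_factory=list)
    params: PipelineParams = field(default_factory=PipelineParams)
    bandwidth: float = 10.0
    length_range: tuple[int, int] = (0, 1_000)
    cdf_range: tuple[int, int] = (0, 10_000)
    attribution: str = "full"
    bh: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        base = path.parent

        def _resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else (base / q)

        params = PipelineParams(**(data.get("params") or {}))
        return cls(
            manifest=_resolve(data["manifest"]),
            gene_bed=_resolve(data["gene_bed"]),
            outdir=_resolve(data["outdir"]),
            case_group=str(data["case_group"]),
            control_group=str(data["control_group"]),
            gmt=[_resolve(p) for p in data.get("gmt", [])],
            params=params,
            bandwidth=float(data.get("bandwidth", 10.0)),
            length_range=tuple(data.get("length_range", (0, 1_000))),
            cdf_range=tuple(data.get("cdf_range", (0, 10_000))),
            attribution=str(data.get("attribution", "full")),
            bh=bool(data.get("bh", False)),
            seed=int(data.get("seed", 0)),
        )

    def validate(self) -> None:
        for p in [self.manifest, self.gene_bed, *self.gmt]:
            if not Path(p).exists():
                raise EccdiffError(f"input path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write all result tables under outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = circle_io.read_manifest(config.manifest)
    if {config.case_group, config.control_group} != manifest.group_labels:
        raise EccdiffError(
            f"configured groups {config.case_group}/{config.control_group} do not match "
            f"manifest groups {sorted(manifest.group_labels)}"
        )
    genes = circle_io.read_gene_bed(config.gene_bed)

    # --- filter chain, per sample ---
    catalogs = {}
    traces = {}
    for entry in manifest:
        raw_catalog = circle_io.read_circle_table(entry.path, entry.sample_id, entry.group)
        catalogs[entry.sample_id], traces[entry.sample_id] = filtermerge.run_filter_chain(
            raw_catalog, config.params
        )
    filtered_dir = outdir / "filtered"
    for cat in catalogs.values():
        circle_io.write_circle_table(cat, filtered_dir / f"circles_{cat.sample_id}.tsv")

    # --- length statistics ---
    counts = {s: lengthstats.count_unique(c) for s, c in catalogs.items()}
    counts_df = pd.DataFrame(
        {
            "sample_id": list(counts),
            "group": [manifest.groups[s] for s in counts],
            "n_unique": [counts[s] for s in counts],
        }
    )
    circle_io.write_table(counts_df, outdir / "counts.tsv")

    comparison = lengthstats.compare_group_counts(
        counts, manifest, config.case_group, config.control_group
    )
    comp_df = pd.DataFrame(
        [
            {
                "case_group": config.case_group,
                "control_group": config.control_group,
                "mu_case": comparison.mu[config.case_group],
                "sem_case": comparison.sem[config.case_group],
                "mu_control": comparison.mu[config.control_group],
                "sem_control": comparison.sem[config.control_group],
                "p_one_sided": comparison.p_one_sided,
                "p_two_sided": comparison.p_two_sided,
                "one_sided_direction": comparison.one_sided_direction,
                "fold_ratio": comparison.fold_ratio,
            }
        ]
    )
    circle_io.write_table(comp_df, outdir / "group_comparison.tsv")

    summary = lengthstats.length_density(
        catalogs, manifest, bandwidth=config.bandwidth, length_range=config.length_range
    )
    dens_cols: dict[str, np.ndarray] = {"length": summary.grid}
    for group in sorted(summary.density):
        if summary.density[group].size:
            dens_cols[f"density_{group}"] = summary.density[group]
            dens_cols[f"band_{group}"] = summary.band[group]
    circle_io.write_table(pd.DataFrame(dens_cols), outdir / "length_density.tsv")
    peak_rows = [
        {"group": group, "peak_bp": int(p)}
        for group in sorted(summary.peaks)
        for p in summary.peaks[group]
    ]
    circle_io.write_table(
        pd.DataFrame(peak_rows, columns=["group", "peak_bp"]), outdir / "length_peaks.tsv"
    )

    cdf_cols: dict[str, np.ndarray] = {}
    for sample_id in catalogs:
        curve = lengthstats.cumulative_curve(catalogs[sample_id], config.cdf_range)
        cdf_cols.setdefault("length", curve.grid)
        cdf_cols[sample_id] = curve.values
    circle_io.write_table(pd.DataFrame(cdf_cols), outdir / "length_cdf.tsv")

    rhomboid = lengthstats.rhomboid_summary(catalogs, manifest)
    rhomboid_df = pd.DataFrame(
        [
            {"group": g, **dataclasses.asdict(v)}
            for g, v in sorted(rhomboid.items())
        ]
    )
    circle_io.write_table(rhomboid_df, outdir / "rhomboid.tsv")

    # --- quantification ---
    matrix = quantify.quantify_catalogs(
        catalogs, genes, manifest, attribution=config.attribution
    )
    circle_io.write_results(
        outdir,
        ppgc_raw=matrix.raw,
        ppgc_scaled=matrix.scaled,
        ppgc_equalized=matrix.equalized,
    )

    whole = quantify.whole_gene_carriage(catalogs, genes)
    circle_io.write_table(whole.recurrent, outdir / "whole_genes_recurrent.tsv")
    per_sample_rows = [
        {"sample_id": s, "gene": g}
        for s in sorted(whole.per_sample)
        for g in whole.per_sample[s]
    ]
    circle_io.write_table(
        pd.DataFrame(per_sample_rows, columns=["sample_id", "gene"]),
        outdir / "whole_genes_per_sample.tsv",
    )

    # --- differential ---
    selection = differential.select_dppgc(
        matrix, config.params, config.case_group, config.control_group, bh=config.bh
    )
    selection = differential.fragment_vs_whole_summary(
        selection, whole, manifest.groups, config.case_group, config.control_group
    )
    circle_io.write_table(selection, outdir / "dppgc.tsv")

    # --- enrichment (signal: up-in-case genes; background: assayed genes) ---
    signal = selection.loc[selection["direction"] == "up_in_case", "gene"].tolist()
    background = matrix.genes
    for gmt_path in config.gmt:
        sets = circle_io.read_gmt(gmt_path)
        name = Path(gmt_path).stem
        if not signal:
            logger.info("no up-in-case genes; skipping enrichment for %s", name)
            circle_io.write_table(
                pd.DataFrame(columns=enrichment.ENRICHMENT_COLUMNS),
                outdir / f"enrichment_{name}.tsv",
            )
            continue
        table = enrichment.enrich(signal, background, sets)
        circle_io.write_table(table, outdir / f"enrichment_{name}.tsv")

    # --- run manifest ---
    run_manifest = {
        "version": __version__,
        "params": {
            **{k: (sorted(v) if isinstance(v, frozenset) else v)
               for k, v in dataclasses.asdict(config.params).items()},
        },
        "case_group": config.case_group,
        "control_group": config.control_group,
        "l_max_gene": matrix.l_max,
        "n_selected": int(len(selection)),
        "seed": config.seed,
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [config.manifest, config.gene_bed, *config.gmt]
        },
        "filter_traces": {s: dataclasses.asdict(t) for s, t in sorted(traces.items())},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
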