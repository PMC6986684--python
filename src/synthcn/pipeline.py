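"""End-to-end orchestration: CN estimation -> group statistics -> PGLS ->
family characterization -> expression, from a single plain-text config.

Each stage reads the text dialects in :mod:`synthcn.io` and writes TSV
outputs into the run directory.  A manifest records package version,
parameters and SHA-256 checksums of every input consumed, so any silent
input change is detectable.  A stage failure aborts the run with the stage
named, leaving earlier outputs in place next to a ``FAILED`` marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .depth import CopyNumberTable, collapse_family_cn, estimate_cn_table
from .errors import ConfigurationError, StageFailure
from .expression import DEFAULT_PSEUDOCOUNT, expression_report
from .family import distance_matrix, dnds_table, nj_tree, truncation_table
from .io import (
    read_bed,
    read_chemotype,
    read_depth_tsv,
    read_expression_inputs,
    read_fasta,
    read_sample_sheet,
    read_tree,
    write_tree,
)
from .pgls import DECARBOXYLATION_FACTOR, correlate_cn_chemotype

logger = logging.getLogger(__name__)

STAGES = ("cn", "stats", "pgls", "family", "expression")


@dataclass
class RunConfig:
    """Validated paths and parameters of one pipeline run.

    Stage toggles select which analyses execute; validation checks only the
    inputs the enabled stages need, and fails before any compute.
    """

    output_dir: str
    depth_dir: str | None = None
    bed: str | None = None
    sample_sheet: str | None = None
    tree: str | None = None
    chemotype: str | None = None
    fasta: str | None = None
    counts: str | None = None
    library_sizes: str | None = None
    collapsed_depth_dir: str | None = None
    collapsed_region: str | None = None  # region name acting as family representative
    stages: tuple[str, ...] = STAGES
    cannabinoids: tuple[str, ...] = ("THC", "CBD", "total")
    decarb_factor: float = DECARBOXYLATION_FACTOR
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    distance_metric: str = "p"
    count_stops_in_dnds: bool = False
    bh_correct: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "cannabinoids" in raw:
            raw["cannabinoids"] = tuple(raw["cannabinoids"])
        return cls(**raw)

    def validate(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigurationError(f"unknown stages: {sorted(bad)}")
        requirements = {
            "cn": ["depth_dir", "bed", "sample_sheet"],
            "stats": ["depth_dir", "bed", "sample_sheet"],
            "pgls": ["depth_dir", "bed", "sample_sheet", "tree", "chemotype"],
            "family": ["fasta"],
            "expression": ["counts", "library_sizes"],
        }
        for stage in self.stages:
            for attr in requirements[stage]:
                value = getattr(self, attr)
                if value is None:
                    raise ConfigurationError(
                        f"stage '{stage}' enabled but '{attr}' is not configured"
                    )
                if not Path(value).exists():
                    raise ConfigurationError(
                        f"stage '{stage}': path for '{attr}' does not exist: {value}"
                    )
        if not (0 <= self.decarb_factor <= 1.5):
            raise ConfigurationError("decarb_factor outside documented range [0, 1.5]")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0")
        if self.distance_metric not in ("p", "jc"):
            raise ConfigurationError(f"unknown distance metric {self.distance_metric!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_paths(config: RunConfig) -> list[Path]:
    paths = []
    for attr in ("bed", "sample_sheet", "tree", "chemotype", "fasta", "counts",
                 "library_sizes"):
        value = getattr(config, attr)
        if value is not None and Path(value).exists():
            paths.append(Path(value))
    for dir_attr in ("depth_dir", "collapsed_depth_dir"):
        value = getattr(config, dir_attr)
        if value is not None and Path(value).is_dir():
            paths.extend(sorted(Path(value).glob("*.depth.tsv")))
    return paths


def _load_cn_table(config: RunConfig) -> CopyNumberTable:
    regions = read_bed(config.bed)
    metadata, models = read_sample_sheet(config.sample_sheet)
    depth_files = sorted(Path(config.depth_dir).glob("*.depth.tsv"))
    if not depth_files:
        raise ConfigurationError(f"no *.depth.tsv files in {config.depth_dir}")
    profiles = [read_depth_tsv(p, p.name.removesuffix(".depth.tsv")) for p in depth_files]
    logger.info("cn: %d samples, %d regions", len(profiles), len(regions))
    return estimate_cn_table(profiles, regions, models, metadata)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages; returns the run directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    cn_table: CopyNumberTable | None = None
    current = "setup"
    try:
        if {"cn", "stats", "pgls"} & set(config.stages):
            current = "cn"
            cn_table = _load_cn_table(config)

        if "cn" in config.stages:
            current = "cn"
            cn_table.to_tsv(outdir / "cn_table.tsv")
            if config.collapsed_depth_dir and config.collapsed_region:
                _run_collapsed(config, outdir)

        if "stats" in config.stages:
            current = "stats"
            from .stats import lineage_anova_tables, replicate_cultivar_tests

            anova, posthoc = lineage_anova_tables(cn_table, bh_correct=config.bh_correct)
            anova.to_csv(outdir / "anova_by_lineage.tsv", sep="\t", index=False)
            posthoc.to_csv(outdir / "posthoc_pairwise.tsv", sep="\t", index=False)
            replicate_cultivar_tests(cn_table).to_csv(
                outdir / "replicate_cultivar_tests.tsv", sep="\t", index=False
            )

        if "pgls" in config.stages:
            current = "pgls"
            tree = read_tree(config.tree)
            chemotypes = read_chemotype(config.chemotype)
            frames = [
                correlate_cn_chemotype(cn_table, chemotypes, tree, compound)
                for compound in config.cannabinoids
            ]
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "cn_chemotype_associations.tsv", sep="\t", index=False
            )

        if "family" in config.stages:
            current = "family"
            sequences = read_fasta(config.fasta)
            logger.info("family: %d sequences", len(sequences))
            dm = distance_matrix(sequences, config.distance_metric)
            dm.to_frame().to_csv(outdir / "distance_matrix.tsv", sep="\t")
            dnds_table(sequences, config.count_stops_in_dnds).to_csv(
                outdir / "distance_dnds_table.tsv", sep="\t"
            )
            truncation_table(sequences).to_csv(
                outdir / "truncation_report.tsv", sep="\t", index=False
            )
            if len(sequences) >= 3:
                write_tree(nj_tree(dm), outdir / "family_nj.nwk")

        if "expression" in config.stages:
            current = "expression"
            table = read_expression_inputs(config.counts, config.library_sizes)
            report = expression_report(table, config.pseudocount)
            with open(outdir / "expression_report.tsv", "w") as fh:
                fh.write(f"# fold-change pseudocount (FPKM): {config.pseudocount}\n")
                report.to_csv(fh, sep="\t")
    except Exception as exc:
        failed_marker.write_text(f"stage: {current}\nerror: {exc}\n")
        raise StageFailure(current, exc) from exc

    _write_manifest(config, outdir)
    return outdir


def _run_collapsed(config: RunConfig, outdir: Path) -> None:
    """Total family CN from profiles aligned to a one-representative reference."""
    regions = {r.name: r for r in read_bed(config.bed)}
    if config.collapsed_region not in regions:
        raise ConfigurationError(
            f"collapsed_region '{config.collapsed_region}' not in {config.bed}"
        )
    representative = regions[config.collapsed_region]
    _, models = read_sample_sheet(config.sample_sheet)
    rows = []
    for path in sorted(Path(config.collapsed_depth_dir).glob("*.depth.tsv")):
        sid = path.name.removesuffix(".depth.tsv")
        if sid not in models:
            raise ConfigurationError(f"no coverage model for collapsed sample '{sid}'")
        profile = read_depth_tsv(path, sid)
        rows.append(
            {
                "sample_id": sid,
                "family_cn": collapse_family_cn(profile, representative, models[sid]),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "family_total_cn.tsv", sep="\t", index=False)


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    manifest = {
        "package": "synthcn",
        "version": __version__,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, (dict,))
        },
        "inputs": {str(p): _sha256(p) for p in _input_paths(config)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
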