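"""Readers and writers for the plain-text dialects the pipeline consumes.

Depth tables are ``contig<TAB>pos<TAB>depth`` with 1-based positions (the
``samtools depth`` dialect).  Regions are BED 3+ with the locus name in
column 4 and a family label in column 5.  The sample sheet, chemotype table
and expression counts are tab-delimited with headers.  Sequences go through
Biopython FASTA; trees through dendropy Newick.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .depth import CoverageModel, DepthProfile, RegionAnnotation
from .errors import InvalidInputError
from .expression import ExpressionTable
from .family import CodingSequence

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "cultivar", "lineage", "total_aligned_bases", "genome_size",
]
CHEMOTYPE_COLUMNS = ["cultivar", "cannabinoid", "percent", "provenance"]


def read_depth_tsv(path, sample_id: str | None = None) -> DepthProfile:
    """Load a 3-column depth table; sample id defaults to the file stem."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "pos", "depth"],
                     dtype={"contig": str, "pos": int, "depth": int})
    records = list(df.itertuples(index=False, name=None))
    return DepthProfile(sample_id=sample_id or path.stem, records=records)


def write_depth_tsv(profile: DepthProfile, path) -> None:
    with open(path, "w") as fh:
        for contig, pos, depth in profile.records:
            fh.write(f"{contig}\t{pos}\t{depth}\n")


def read_bed(path) -> list[RegionAnnotation]:
    """BED 3+ regions; column 4 = name, column 5 = family label when present."""
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(f"{path}:{i + 1}: fewer than 3 BED columns")
            regions.append(
                RegionAnnotation(
                    contig=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3] if len(fields) > 3 else f"region_{i + 1}",
                    family=fields[4] if len(fields) > 4 else "unknown",
                )
            )
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        raise InvalidInputError(f"{path}: duplicate region names")
    return regions


def write_bed(regions: Iterable[RegionAnnotation], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\t{r.family}\n")


def read_sample_sheet(path) -> tuple[pd.DataFrame, dict[str, CoverageModel]]:
    """Sample metadata plus one CoverageModel per sample.

    Columns: sample_id, cultivar, lineage, total_aligned_bases, genome_size.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cultivar": str})
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    models = {
        row.sample_id: CoverageModel(
            total_aligned_bases=float(row.total_aligned_bases),
            genome_size=float(row.genome_size),
        )
        for row in df.itertuples()
    }
    return df[["sample_id", "cultivar", "lineage"]].copy(), models


def read_chemotype(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cultivar": str, "cannabinoid": str,
                                            "provenance": str})
    missing = set(CHEMOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: chemotype table lacks columns {sorted(missing)}")
    if (df["percent"] < 0).any():
        raise InvalidInputError(f"{path}: negative chemotype percentages")
    bad = set(df["provenance"]) - {"individual", "average"}
    if bad:
        raise InvalidInputError(f"{path}: unknown provenance labels {sorted(bad)}")
    return df


def read_fasta(path, frame: int = 0) -> list[CodingSequence]:
    return [
        CodingSequence(name=rec.id, nucleotides=str(rec.seq), frame=frame)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences: Iterable[CodingSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.nucleotides), id=s.name, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_expression_inputs(counts_path, library_sizes_path) -> ExpressionTable:
    """Counts TSV (transcript, length, one column per condition) + size sheet."""
    counts = pd.read_csv(counts_path, sep="\t", dtype={"transcript": str})
    for col in ("transcript", "length"):
        if col not in counts.columns:
            raise InvalidInputError(f"{counts_path}: missing column '{col}'")
    sizes = pd.read_csv(library_sizes_path, sep="\t", dtype={"condition": str})
    if not {"condition", "library_size"} <= set(sizes.columns):
        raise InvalidInputError(
            f"{library_sizes_path}: need columns condition, library_size"
        )
    counts = counts.set_index("transcript")
    return ExpressionTable(
        counts=counts.drop(columns="length"),
        lengths=counts["length"],
        library_sizes=sizes.set_index("condition")["library_size"],
    )
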