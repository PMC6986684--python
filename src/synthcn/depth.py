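"""Read-depth based gene copy-number estimation.

The copy number (CN) of a locus is estimated as the mean read depth across the
locus divided by the expected single-copy coverage of the library, where the
expected coverage is the total number of aligned bases divided by the genome
size.  Because reads from near-identical paralogs co-map, aligning against a
reference carrying a single family representative turns the same scaled-depth
statistic into an estimate of the *total* family copy number.

Coordinate conventions: depth records are 1-based (the convention of
``samtools depth``); regions are 0-based half-open (BED).  The conversion
happens exactly once, when a region is intersected with a profile.  Positions
absent from a depth profile count as depth zero, matching depth emitters that
omit zero rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

#: Female and male genome sizes (bp) used as the expected-coverage denominator.
FEMALE_GENOME_SIZE = 818_000_000
MALE_GENOME_SIZE = 843_000_000

LINEAGES = ("broad-leaf", "narrow-leaf", "hemp", "unassigned")


@dataclass
class DepthProfile:
    """Per-base depth of one sequencing library.

    Parameters
    ----------
    sample_id:
        Library identifier.
    records:
        Iterable of ``(contig, position, depth)`` with 1-based positions and
        non-negative integer depths.  ``(contig, position)`` pairs must be
        unique; positions need not be contiguous.
    """

    sample_id: str
    records: Sequence[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_contig: dict[str, dict[int, int]] = {}
        seen = set()
        for contig, pos, depth in self.records:
            pos = int(pos)
            depth = int(depth)
            if depth < 0:
                raise InvalidInputError(
                    f"{self.sample_id}: negative depth {depth} at {contig}:{pos}"
                )
            if pos < 1:
                raise InvalidInputError(
                    f"{self.sample_id}: position {pos} is not 1-based"
                )
            key = (contig, pos)
            if key in seen:
                raise InvalidInputError(
                    f"{self.sample_id}: duplicate depth record at {contig}:{pos}"
                )
            seen.add(key)
            self._by_contig.setdefault(contig, {})[pos] = depth

    def region_depths(self, contig: str, start: int, end: int) -> np.ndarray:
        """Depth per position over a 0-based half-open region; absent = 0."""
        out = np.zeros(end - start, dtype=float)
        contig_depths = self._by_contig.get(contig)
        if contig_depths:
            # depth positions are 1-based: BED position p covers depth p+1
            for i, pos in enumerate(range(start + 1, end + 1)):
                out[i] = contig_depths.get(pos, 0)
        return out


@dataclass(frozen=True)
class CoverageModel:
    """Expected single-copy coverage of a library: aligned bases / genome size."""

    total_aligned_bases: float
    genome_size: float = FEMALE_GENOME_SIZE

    def __post_init__(self) -> None:
        if self.total_aligned_bases <= 0:
            raise InvalidInputError("total_aligned_bases must be > 0")
        if self.genome_size <= 0:
            raise InvalidInputError("genome_size must be > 0")

    @property
    def expected_coverage(self) -> float:
        return self.total_aligned_bases / self.genome_size


@dataclass(frozen=True)
class RegionAnnotation:
    """A named locus in 0-based half-open coordinates with a family label."""

    contig: str
    start: int
    end: int
    name: str
    family: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidInputError(
                f"region {self.name}: require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyNumberTable:
    """Sample x paralog matrix of CN estimates with cultivar/lineage metadata."""

    samples: pd.DataFrame  # columns: sample_id, cultivar, lineage
    values: pd.DataFrame  # index: sample_id, columns: paralog names

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise InvalidInputError("CN table contains negative entries")
        bad = set(self.samples["lineage"]) - set(LINEAGES)
        if bad:
            raise InvalidInputError(f"unknown lineage labels: {sorted(bad)}")

    @property
    def paralogs(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


def expected_coverage(total_aligned_bases: float, genome_size: float) -> float:
    """Genome-wide expected depth at single-copy sites.

    ``total_aligned_bases / genome_size`` — strictly increasing in the
    numerator, strictly decreasing in the denominator.
    """
    return CoverageModel(total_aligned_bases, genome_size).expected_coverage


def mean_region_depth(profile: DepthProfile, region: RegionAnnotation) -> float:
    """Mean depth over every position of ``region`` (absent positions = 0)."""
    if region.length < 1:
        raise InvalidInputError(f"region {region.name} is empty")
    return float(profile.region_depths(region.contig, region.start, region.end).mean())


def estimate_cn(
    profile: DepthProfile, region: RegionAnnotation, model: CoverageModel
) -> float:
    """Copy number of ``region``: mean region depth / expected coverage.

    Invariant under jointly scaling every depth and the aligned-base total by
    the same factor.
    """
    return mean_region_depth(profile, region) / model.expected_coverage


def collapse_family_cn(
    profile_on_collapsed_reference: DepthProfile,
    representative: RegionAnnotation,
    model: CoverageModel,
) -> float:
    """Total family CN from a profile aligned to a one-representative reference.

    When the reference retains a single family member, reads from every
    paralog co-map onto it, so the scaled depth of the representative estimates
    the summed CN of the whole family.  The caller is responsible for the
    profile having been produced against such a collapsed reference.
    """
    return estimate_cn(profile_on_collapsed_reference, representative, model)


def estimate_cn_table(
    profiles: Iterable[DepthProfile],
    regions: Sequence[RegionAnnotation],
    models: Mapping[str, CoverageModel],
    metadata: pd.DataFrame,
) -> CopyNumberTable:
    """CN estimates for every sample x region pair, in stable input order.

    ``metadata`` must carry one row per sample with columns ``sample_id``,
    ``cultivar`` and ``lineage``.  A sample without a coverage model or a
    metadata row raises :class:`ConfigurationError` naming the sample.
    """
    profiles = list(profiles)
    meta = metadata.set_index("sample_id", drop=False)
    rows = {}
    sample_rows = []
    for profile in profiles:
        sid = profile.sample_id
        if sid not in models:
            raise ConfigurationError(f"no coverage model for sample '{sid}'")
        if sid not in meta.index:
            raise ConfigurationError(f"no metadata row for sample '{sid}'")
        model = models[sid]
        rows[sid] = [estimate_cn(profile, region, model) for region in regions]
        sample_rows.append(meta.loc[sid, ["sample_id", "cultivar", "lineage"]])
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=[r.name for r in regions]
    )
    values.index.name = "sample_id"
    samples = pd.DataFrame(sample_rows).reset_index(drop=True)
    return CopyNumberTable(samples=samples, values=values)
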