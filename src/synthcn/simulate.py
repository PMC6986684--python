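"""Synthetic data with known truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes rather
than the sequencing process itself: per-base depth is Poisson around
``true CN x expected coverage``; cultivar relatedness is a Yule (pure-birth)
tree; copy number and chemotype co-evolve by Brownian motion with a linear
link; coding-sequence pairs diverge by logged point substitutions accepted at
a target dN/dS, optionally with premature stops planted at known codons.

Every generator is a pure function of its scenario and the seed: rerunning
with the same arguments reproduces identical artifacts.  A single global seed
fans out to per-generator child streams through fixed offsets, so adding a
generator never perturbs the draws of an existing one.

The default cohort mirrors a realistic resequencing study of this kind in
shape: 67 libraries in three lineages of 15/31/16 plus 5 unassigned, 11
paralog regions of ~1.6 kb, planted integer copy numbers between 1 and 10,
and 20x expected single-copy coverage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .depth import (
    FEMALE_GENOME_SIZE,
    CoverageModel,
    DepthProfile,
    RegionAnnotation,
)
from .errors import InvalidInputError
from .family import GENETIC_CODE, STOP_CODONS, CodingSequence

# child-stream offsets: each generator seeds default_rng((seed, OFFSET))
DEPTH_STREAM = 1
TREE_STREAM = 2
CODON_STREAM = 3
EXPRESSION_STREAM = 4

LINEAGE_SIZES = {"broad-leaf": 15, "narrow-leaf": 31, "hemp": 16, "unassigned": 5}


@dataclass(frozen=True)
class TraitModel:
    """Linear CN -> chemotype link evolving on the tree."""

    slope: float = 1.5
    intercept: float = 1.0
    bm_sigma: float = 1.0  # BM sd of the predictor per unit branch length
    bm_sigma_resid: float = 1.0  # BM sd of the phylogenetic residual
    iid_sigma_resid: float = 0.0  # sd of the non-phylogenetic residual


@dataclass(frozen=True)
class CodonModel:
    ancestor_codons: int = 300
    n_substitutions: int = 30
    omega: float = 0.5  # target acceptance ratio of nonsynonymous proposals
    planted_stop_codons: tuple[int, ...] = ()  # 1-based codon indices in the derived copy


@dataclass
class SyntheticScenario:
    """Shared knobs of one synthetic study; see module docstring for defaults."""

    seed: int = 0
    n_samples: int = 67
    lineage_sizes: dict = field(default_factory=lambda: dict(LINEAGE_SIZES))
    n_regions: int = 11
    region_length: int = 1600
    cn_range: tuple[int, int] = (1, 10)
    expected_coverage: float = 20.0
    noise: str = "poisson"  # or "none"
    genome_size: float = FEMALE_GENOME_SIZE
    n_tips: int = 50
    birth_rate: float = 1.0
    trait_model: TraitModel = TraitModel()
    codon_model: CodonModel = CodonModel()

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "none"):
            raise InvalidInputError(f"unknown noise model {self.noise!r}")
        if self.cn_range[0] < 1 or self.cn_range[1] < self.cn_range[0]:
            raise InvalidInputError("cn_range must be 1 <= low <= high")
        if self.n_tips < 3:
            raise InvalidInputError("need at least 3 tree tips")
        if sum(self.lineage_sizes.values()) != self.n_samples:
            raise InvalidInputError("lineage sizes must sum to n_samples")


def _rng(scenario: SyntheticScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng((scenario.seed, stream))


def default_regions(scenario: SyntheticScenario) -> list[RegionAnnotation]:
    """Evenly spaced single-contig loci labelled by synthase-family group."""
    families = ["CBDAS-like", "CBDAS-like", "CBDAS-like", "THCAS-like",
                "THCAS-like", "CBCAS-like", "CBCAS-like", "CBCAS-like"]
    regions = []
    for i in range(scenario.n_regions):
        start = i * (scenario.region_length + 400)
        regions.append(
            RegionAnnotation(
                contig="contig_1",
                start=start,
                end=start + scenario.region_length,
                name=f"paralog_{i + 1:03d}",
                family=families[i] if i < len(families) else "unknown",
            )
        )
    return regions


def simulate_depth(
    regions: list[RegionAnnotation],
    true_cn: dict[str, float],
    expected_coverage: float,
    noise: str = "poisson",
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
) -> tuple[DepthProfile, pd.DataFrame]:
    """Per-base depth over ``regions`` with planted copy numbers.

    Depth at each position is Poisson(true_cn * expected_coverage)
    independently (``noise="none"`` emits the exact mean).  Returns the
    profile and the truth table of planted CN per region.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    records = []
    truth_rows = []
    for region in regions:
        cn = true_cn[region.name]
        if cn <= 0:
            raise InvalidInputError(f"true CN for {region.name} must be > 0")
        lam = cn * expected_coverage
        length = region.length
        if noise == "poisson":
            depths = rng.poisson(lam, size=length)
        else:
            depths = np.full(length, int(round(lam)))
        records.extend(
            (region.contig, region.start + 1 + offset, int(d))
            for offset, d in enumerate(depths)
        )
        truth_rows.append({"region": region.name, "true_cn": cn})
    profile = DepthProfile(sample_id=sample_id, records=records)
    return profile, pd.DataFrame(truth_rows)


def simulate_cohort(
    scenario: SyntheticScenario,
) -> tuple[list[DepthProfile], list[RegionAnnotation], dict[str, CoverageModel],
           pd.DataFrame, pd.DataFrame]:
    """Depth profiles for a whole cohort with lineage labels and planted CN.

    Returns (profiles, regions, coverage models, metadata, truth) where truth
    has one row per sample x region.  Cultivars repeat every few samples so
    replicate-cultivar statistics have material to work on.
    """
    rng = _rng(scenario, DEPTH_STREAM)
    regions = default_regions(scenario)
    lineages = [
        lineage
        for lineage, size in scenario.lineage_sizes.items()
        for _ in range(size)
    ]
    profiles, meta_rows, truth_frames = [], [], []
    models: dict[str, CoverageModel] = {}
    lo, hi = scenario.cn_range
    for i, lineage in enumerate(lineages):
        sid = f"s{i + 1:03d}"
        cultivar = f"cv{(i // 2) + 1:03d}"  # two libraries per cultivar
        true_cn = {r.name: int(rng.integers(lo, hi + 1)) for r in regions}
        profile, truth = simulate_depth(
            regions, true_cn, scenario.expected_coverage, scenario.noise, rng, sid
        )
        truth.insert(0, "sample_id", sid)
        profiles.append(profile)
        truth_frames.append(truth)
        models[sid] = CoverageModel(
            total_aligned_bases=scenario.expected_coverage * scenario.genome_size,
            genome_size=scenario.genome_size,
        )
        meta_rows.append({"sample_id": sid, "cultivar": cultivar, "lineage": lineage})
    metadata = pd.DataFrame(meta_rows)
    truth = pd.concat(truth_frames, ignore_index=True)
    return profiles, regions, models, metadata, truth


def yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0, prefix: str = "t"
) -> dendropy.Tree:
    """Pure-birth tree with ``n_tips`` extant leaves labelled ``{prefix}1..``.

    The simulator stops at the n-th birth, which leaves the newest sister
    pair with zero-length terminal edges; the tree is observed a further
    Exponential(n * birth_rate) waiting time later (the time to the next,
    unobserved, birth), so every terminal branch is strictly positive and
    the implied trait covariance is positive definite.
    """
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    extension = rng.expovariate(n_tips * birth_rate)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"{prefix}{i + 1}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extension
    return tree


def brownian_trait(
    tree: dendropy.Tree, sigma: float, rng: np.random.Generator, root_value: float = 0.0
) -> dict[str, float]:
    """One Brownian-motion realization; returns trait value per tip label."""
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            edge = node.edge.length or 0.0
            step = rng.normal(0.0, sigma * np.sqrt(edge)) if sigma > 0 and edge > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
    return {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}


def simulate_tree_and_traits(
    scenario: SyntheticScenario, star: bool = False
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Yule tree plus co-evolving (cn, chemotype) tip traits with known truth.

    The predictor evolves by BM; the response is
    ``intercept + slope * cn + BM residual + iid residual``.  With
    ``star=True`` the tree is a star with unit terminal branches, making tip
    traits independent.
    """
    rng = _rng(scenario, TREE_STREAM)
    if star:
        newick = "(" + ",".join(f"t{i + 1}:1.0" for i in range(scenario.n_tips)) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
    else:
        tree = yule_tree(
            scenario.n_tips, scenario.birth_rate, seed=int(rng.integers(2**31))
        )
    tm = scenario.trait_model
    x = brownian_trait(tree, tm.bm_sigma, rng)
    resid = brownian_trait(tree, tm.bm_sigma_resid, rng)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    rows = []
    for tip in tips:
        iid = rng.normal(0.0, tm.iid_sigma_resid) if tm.iid_sigma_resid > 0 else 0.0
        rows.append(
            {
                "tip": tip,
                "cn": x[tip],
                "chemotype": tm.intercept + tm.slope * x[tip] + resid[tip] + iid,
                "bm_residual": resid[tip],
            }
        )
    return tree, pd.DataFrame(rows)


def two_clade_fixture(
    n_per_clade: int = 8, seed: int = 7, clade_depth: float = 10.0
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Deterministic confounding fixture: clades differ, tips within do not.

    Two clades separated by long internal branches; both the predictor and
    the response differ between clades by a large offset but vary
    independently within each clade (within-clade slope zero).  A naive
    correlation across tips is strongly significant, while the
    phylogenetically corrected one is not — the classic relatedness
    confound.
    """
    rng = np.random.default_rng((seed, TREE_STREAM))
    half = ",".join(f"A{i + 1}:1.0" for i in range(n_per_clade))
    other = ",".join(f"B{i + 1}:1.0" for i in range(n_per_clade))
    newick = f"(({half}):{clade_depth},({other}):{clade_depth});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    rows = []
    for i in range(n_per_clade):
        rows.append({"tip": f"A{i + 1}", "cn": rng.normal(2.0, 0.5),
                     "chemotype": rng.normal(1.0, 0.5)})
    for i in range(n_per_clade):
        rows.append({"tip": f"B{i + 1}", "cn": rng.normal(8.0, 0.5),
                     "chemotype": rng.normal(9.0, 0.5)})
    return tree, pd.DataFrame(rows)


_NONSTOP_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)


def simulate_codon_pair(
    scenario: SyntheticScenario,
) -> tuple[CodingSequence, CodingSequence, pd.DataFrame]:
    """An ancestor sequence and a diverged copy with a substitution log.

    Substitutions are proposed as random single-nucleotide changes; proposals
    creating stop codons are rejected, synonymous proposals are always
    accepted and nonsynonymous ones with probability min(1, omega) (for
    omega > 1 the roles flip), steering the realized class ratio toward the
    target.  Premature stops are then planted by overwriting the stated
    codons of the derived copy with TAA; the truth table logs every change.
    """
    cm = scenario.codon_model
    rng = _rng(scenario, CODON_STREAM)
    n_codons = cm.ancestor_codons
    for pos in cm.planted_stop_codons:
        if not (1 <= pos <= n_codons):
            raise InvalidInputError(
                f"planted stop position {pos} outside 1..{n_codons}"
            )
    codons = [
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))] for _ in range(n_codons)
    ]
    ancestor = "".join(codons)
    derived, log_rows = _substitute(codons, cm.n_substitutions, cm.omega, rng)
    for pos in cm.planted_stop_codons:
        log_rows.append(
            {
                "codon_index": pos,
                "position_in_codon": 0,
                "from": derived[pos - 1],
                "to": "TAA",
                "class": "planted_stop",
            }
        )
        derived[pos - 1] = "TAA"

    a = CodingSequence(name="ancestor", nucleotides=ancestor)
    b = CodingSequence(name="derived", nucleotides="".join(derived))
    return a, b, pd.DataFrame(
        log_rows,
        columns=["codon_index", "position_in_codon", "from", "to", "class"],
    )


def _substitute(
    codons: list[str],
    n_substitutions: int,
    omega: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[dict]]:
    """Apply logged point substitutions at a target dN/dS to a codon list."""
    derived = list(codons)
    log_rows: list[dict] = []
    accepted = 0
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega) if omega > 1 else 1.0
    while accepted < n_substitutions:
        ci = int(rng.integers(len(derived)))
        within = int(rng.integers(3))
        codon = derived[ci]
        new_nt = "ACGT"[rng.integers(4)]
        if new_nt == codon[within]:
            continue
        mutant = codon[:within] + new_nt + codon[within + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
        if rng.random() >= (p_syn if synonymous else p_nonsyn):
            continue
        derived[ci] = mutant
        accepted += 1
        log_rows.append(
            {
                "codon_index": ci + 1,
                "position_in_codon": within + 1,
                "from": codon[within],
                "to": new_nt,
                "class": "synonymous" if synonymous else "nonsynonymous",
            }
        )
    return derived, log_rows


def simulate_family_alignment(
    scenario: SyntheticScenario,
    n_sequences: int = 8,
    planted_stops: dict[str, tuple[int, ...]] | None = None,
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """A gapless alignment of paralogs diverged from one ancestor.

    Each member accumulates the scenario's substitution count independently
    from the same ancestor, so all sequences stay aligned by construction.
    ``planted_stops`` maps a member name (``member_1`` ...) to 1-based codon
    indices overwritten with TAA, emulating truncated pseudogene copies.
    """
    cm = scenario.codon_model
    rng = _rng(scenario, CODON_STREAM)
    ancestor = [
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
        for _ in range(cm.ancestor_codons)
    ]
    planted_stops = planted_stops or {}
    sequences, truth_frames = [], []
    for i in range(n_sequences):
        name = f"member_{i + 1}"
        derived, log_rows = _substitute(ancestor, cm.n_substitutions, cm.omega, rng)
        for pos in planted_stops.get(name, ()):
            if not (1 <= pos < cm.ancestor_codons):
                raise InvalidInputError(
                    f"{name}: planted stop {pos} outside 1..{cm.ancestor_codons - 1}"
                )
            log_rows.append(
                {"codon_index": pos, "position_in_codon": 0,
                 "from": derived[pos - 1], "to": "TAA", "class": "planted_stop"}
            )
            derived[pos - 1] = "TAA"
        sequences.append(CodingSequence(name=name, nucleotides="".join(derived)))
        truth = pd.DataFrame(
            log_rows,
            columns=["codon_index", "position_in_codon", "from", "to", "class"],
        )
        truth.insert(0, "name", name)
        truth_frames.append(truth)
    return sequences, pd.concat(truth_frames, ignore_index=True)


def simulate_expression_counts(
    scenario: SyntheticScenario,
    n_transcripts: int = 12,
    conditions: tuple[str, ...] = ("flower_a", "flower_b", "root_a"),
    fold_changes: dict[str, dict[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Poisson fragment counts with planted per-condition expression levels.

    Returns (counts, lengths, library sizes, truth-FPKM) in the shapes
    :class:`synthcn.expression.ExpressionTable` consumes.  ``fold_changes``
    maps transcript -> condition -> multiplier on the base expression level.
    """
    rng = _rng(scenario, EXPRESSION_STREAM)
    names = [f"tx{i + 1:03d}" for i in range(n_transcripts)]
    lengths = pd.Series(
        rng.integers(900, 2400, size=n_transcripts), index=names, name="length"
    )
    library_size = 2_000_000
    base_fpkm = rng.uniform(1.0, 200.0, size=n_transcripts)
    truth_rows, count_cols = [], {}
    for cond in conditions:
        counts = []
        for i, name in enumerate(names):
            mult = (fold_changes or {}).get(name, {}).get(cond, 1.0)
            target_fpkm = base_fpkm[i] * mult
            lam = target_fpkm * lengths[name] * library_size / 1e9
            counts.append(int(rng.poisson(lam)) if lam > 0 else 0)
            truth_rows.append(
                {"transcript": name, "condition": cond, "true_fpkm": target_fpkm}
            )
        count_cols[cond] = counts
    counts = pd.DataFrame(count_cols, index=names)
    counts.index.name = "transcript"
    sizes = pd.Series(
        {c: library_size for c in conditions}, name="library_size", dtype=float
    )
    return counts, lengths, sizes, pd.DataFrame(truth_rows)


def write_study_files(scenario: SyntheticScenario, outdir) -> Path:
    """Emit a complete synthetic study in the pipeline's input dialects.

    Writes depth TSVs (one per sample), the region BED, the sample sheet, a
    relatedness tree over the samples, a chemotype table generated from the
    planted CN of the first region via the trait model, a family FASTA with
    three planted truncations, expression counts, and truth tables for every
    generated quantity.  Returns the output directory.
    """
    from .io import write_bed, write_depth_tsv, write_fasta, write_tree

    outdir = Path(outdir)
    (outdir / "depth").mkdir(parents=True, exist_ok=True)

    profiles, regions, models, metadata, truth = simulate_cohort(scenario)
    for profile in profiles:
        write_depth_tsv(profile, outdir / "depth" / f"{profile.sample_id}.depth.tsv")
    write_bed(regions, outdir / "regions.bed")
    sheet = metadata.copy()
    sheet["total_aligned_bases"] = [models[s].total_aligned_bases for s in sheet["sample_id"]]
    sheet["genome_size"] = [models[s].genome_size for s in sheet["sample_id"]]
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth_cn.tsv", sep="\t", index=False)

    # relatedness tree over the cohort samples + chemotypes from the focal region
    rng = _rng(scenario, TREE_STREAM)
    tree = yule_tree(scenario.n_samples, scenario.birth_rate,
                     seed=int(rng.integers(2**31)), prefix="s")
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = metadata["sample_id"].iloc[i]
    write_tree(tree, outdir / "cultivars.nwk")

    tm = scenario.trait_model
    focal = regions[0].name
    focal_cn = truth[truth["region"] == focal].set_index("sample_id")["true_cn"]
    resid = brownian_trait(tree, tm.bm_sigma_resid, rng)
    chem_rows = []
    for sid in metadata["sample_id"]:
        iid = rng.normal(0.0, tm.iid_sigma_resid) if tm.iid_sigma_resid > 0 else 0.0
        value = tm.intercept + tm.slope * focal_cn[sid] + resid[sid] + iid
        chem_rows.append({"cultivar": sid, "cannabinoid": "THC",
                          "percent": max(value, 0.0), "provenance": "individual"})
        chem_rows.append({"cultivar": sid, "cannabinoid": "CBD",
                          "percent": max(10.0 - value, 0.0), "provenance": "individual"})
    pd.DataFrame(chem_rows).to_csv(outdir / "chemotypes.tsv", sep="\t", index=False)

    planted = {"member_1": (40,), "member_2": (75,), "member_3": (40, 120)}
    sequences, seq_truth = simulate_family_alignment(scenario, 8, planted)
    write_fasta(sequences, outdir / "family.fasta")
    seq_truth.to_csv(outdir / "truth_substitutions.tsv", sep="\t", index=False)

    counts, lengths, sizes, expr_truth = simulate_expression_counts(scenario)
    counts_out = counts.copy()
    counts_out.insert(0, "length", lengths)
    counts_out.to_csv(outdir / "counts.tsv", sep="\t")
    sizes.rename_axis("condition").reset_index().to_csv(
        outdir / "library_sizes.tsv", sep="\t", index=False
    )
    expr_truth.to_csv(outdir / "truth_fpkm.tsv", sep="\t", index=False)
    return outdir
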