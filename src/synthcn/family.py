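"""Sequence characterization of a synthase paralog family.

Pairwise genetic distance (p-distance, optionally Jukes-Cantor corrected),
counting-based dN/dS after Nei & Gojobori, premature-stop (truncation)
scanning, and a neighbor-joining tree utility over a distance matrix.

The dN/dS estimator works codon by codon: each codon position contributes a
synonymous-site fraction computed from the standard genetic code, and codons
differing at more than one position are resolved by averaging the synonymous /
nonsynonymous step counts over all minimal mutational pathways.  Mutational
pathways passing through a stop codon are excluded, and mutations *to* stop
codons are excluded when counting sites — the convention of the SNAP tool —
unless ``count_stops=True`` reverts to plain all-pathway counting.  Raw
proportions are corrected for multiple hits with the Jukes-Cantor formula.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDistanceMatrix
from skbio.tree import nj as _skbio_nj

from .errors import FrameError, InvalidInputError, SaturationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# standard genetic code, DNA alphabet
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

NUCLEOTIDES = "ACGT"
_AMBIGUOUS = set("N-")


@dataclass(frozen=True)
class CodingSequence:
    """A named nucleotide sequence with a 0-based reading-frame offset."""

    name: str
    nucleotides: str
    frame: int = 0

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise InvalidInputError(f"{self.name}: empty sequence")
        if self.frame not in (0, 1, 2):
            raise InvalidInputError(f"{self.name}: frame must be 0, 1 or 2")
        bad = set(self.nucleotides.upper()) - set(NUCLEOTIDES) - _AMBIGUOUS
        if bad:
            raise InvalidInputError(f"{self.name}: unexpected characters {sorted(bad)}")
        object.__setattr__(self, "nucleotides", self.nucleotides.upper())

    def codons(self) -> list[str]:
        """Complete in-frame codons; a trailing partial codon is dropped."""
        seq = self.nucleotides[self.frame:]
        return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


@dataclass(frozen=True)
class DnDsResult:
    """Nei-Gojobori site and difference counts with corrected distances.

    ``ratio`` is ``None`` (undefined) when dS is zero — neither 0 nor
    infinity conveys "no synonymous divergence to normalize by".
    """

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    ds: float
    dn: float
    ratio: float | None
    codons_compared: int


@dataclass(frozen=True)
class TruncationReport:
    """In-frame stop codons of one sequence; truncated if any stop precedes the last codon."""

    name: str
    in_frame_stop_positions: tuple[int, ...]  # 1-based codon indices, ascending
    n_codons: int
    is_truncated: bool


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise InvalidInputError("distance matrix shape does not match names")
        if not np.allclose(v, v.T):
            raise InvalidInputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise InvalidInputError("distance matrix diagonal is not zero")
        if not np.isfinite(v).all():
            raise InvalidInputError("distance matrix has non-finite entries")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


def _comparable_sites(a: CodingSequence, b: CodingSequence) -> tuple[str, str]:
    if len(a.nucleotides) != len(b.nucleotides):
        raise InvalidInputError(
            f"{a.name} vs {b.name}: aligned sequences must have equal length"
        )
    xs, ys = [], []
    for x, y in zip(a.nucleotides, b.nucleotides):
        if x in _AMBIGUOUS or y in _AMBIGUOUS:
            continue
        xs.append(x)
        ys.append(y)
    if not xs:
        raise InvalidInputError(f"{a.name} vs {b.name}: no comparable sites")
    return "".join(xs), "".join(ys)


def p_distance(a: CodingSequence, b: CodingSequence) -> float:
    """Proportion of mismatching sites after pairwise removal of gaps and Ns."""
    x, y = _comparable_sites(a, b)
    mismatches = sum(cx != cy for cx, cy in zip(x, y))
    return mismatches / len(x)


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction, -(3/4) ln(1 - 4p/3).

    Defined for ``0 <= p < 0.75``; at or beyond 3/4 the expected distance
    diverges (saturation).
    """
    if p < 0:
        raise InvalidInputError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} is at or beyond saturation (3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def codon_site_fractions(codon: str, count_stops: bool = False) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; they sum to 3.

    At each position the three possible point mutations are classified against
    the standard code.  With ``count_stops=False`` mutants that create a stop
    codon are dropped before taking the fraction; with ``count_stops=True``
    they count as nonsynonymous.
    """
    if codon in STOP_CODONS or codon not in GENETIC_CODE:
        raise InvalidInputError(f"cannot take site fractions of codon {codon!r}")
    aa = GENETIC_CODE[codon]
    syn_sites = 0.0
    for i in range(3):
        syn = nonsyn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[i]:
                continue
            mutant = codon[:i] + nt + codon[i + 1 :]
            if mutant in STOP_CODONS:
                if count_stops:
                    nonsyn += 1
                continue
            if GENETIC_CODE[mutant] == aa:
                syn += 1
            else:
                nonsyn += 1
        total = syn + nonsyn
        syn_sites += syn / total if total else 0.0
    return syn_sites, 3.0 - syn_sites


def codon_path_diffs(
    codon_a: str, codon_b: str, count_stops: bool = False
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    All minimal mutational pathways (orderings of the differing positions) are
    enumerated; each step is classified by whether the amino acid changes, and
    the counts are averaged with equal weight.  Pathways whose intermediate
    codons are stops are excluded unless ``count_stops=True`` or every pathway
    is excluded, in which case all pathways are used.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def classify_path(order: tuple[int, ...]) -> tuple[float, float] | None:
        syn = nonsyn = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and not count_stops and nxt != codon_b:
                return None  # pathway passes through a stop
            aa_from = GENETIC_CODE[current]
            aa_to = GENETIC_CODE[nxt]
            if aa_from == aa_to:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    paths = [classify_path(order) for order in itertools.permutations(diff_positions)]
    valid = [p for p in paths if p is not None]
    if not valid:  # all pathways blocked by stops: fall back to unrestricted counting
        valid = [
            c
            for order in itertools.permutations(diff_positions)
            for c in [_classify_unrestricted(codon_a, codon_b, order)]
        ]
    syn = sum(p[0] for p in valid) / len(valid)
    nonsyn = sum(p[1] for p in valid) / len(valid)
    return syn, nonsyn


def _classify_unrestricted(
    codon_a: str, codon_b: str, order: tuple[int, ...]
) -> tuple[int, int]:
    syn = nonsyn = 0
    current = codon_a
    for pos in order:
        nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
        if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
            syn += 1
        else:
            nonsyn += 1
        current = nxt
    return syn, nonsyn


def nei_gojobori(
    a: CodingSequence, b: CodingSequence, count_stops: bool = False
) -> DnDsResult:
    """Counting-based dN/dS between two aligned coding sequences.

    Codons containing a gap or N in either sequence are dropped pairwise; the
    remaining alignment must be codon-complete.  Site counts S and N are the
    averages of the two sequences' per-codon fractions, differences are
    pathway-averaged, and dS/dN apply the Jukes-Cantor correction to
    pS = Sd/S and pN = Nd/N.  The result is symmetric in sequence order.
    """
    if len(a.nucleotides) != len(b.nucleotides):
        raise FrameError(f"{a.name} vs {b.name}: aligned lengths differ")
    if a.frame != b.frame:
        raise FrameError(f"{a.name} vs {b.name}: frames differ")
    seq_a = a.nucleotides[a.frame :]
    seq_b = b.nucleotides[b.frame :]
    usable = len(seq_a) - len(seq_a) % 3
    codon_pairs = []
    for i in range(0, usable, 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if set(ca) & _AMBIGUOUS or set(cb) & _AMBIGUOUS:
            continue  # pairwise deletion, whole codon
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue  # stop codons carry no site fractions
        codon_pairs.append((ca, cb))
    tail = seq_a[usable:] + seq_b[usable:]
    if set(tail) - _AMBIGUOUS:
        # a non-ambiguous trailing partial codon means the alignment is out of frame
        raise FrameError(f"{a.name} vs {b.name}: compared portion not divisible by 3")
    if not codon_pairs:
        raise InvalidInputError(f"{a.name} vs {b.name}: all codons dropped")

    S = N = Sd = Nd = 0.0
    for ca, cb in codon_pairs:
        sa, na = codon_site_fractions(ca, count_stops)
        sb, nb = codon_site_fractions(cb, count_stops)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds_, dn_ = codon_path_diffs(ca, cb, count_stops)
        Sd += ds_
        Nd += dn_

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    # saturated proportions (>= 3/4) have no finite corrected distance
    ds = jukes_cantor(ps) if ps < 0.75 else math.nan
    dn = jukes_cantor(pn) if pn < 0.75 else math.nan
    ratio = (dn / ds) if math.isfinite(ds) and math.isfinite(dn) and ds > 0 else None
    return DnDsResult(
        syn_sites=S,
        nonsyn_sites=N,
        syn_diffs=Sd,
        nonsyn_diffs=Nd,
        ps=ps,
        pn=pn,
        ds=ds,
        dn=dn,
        ratio=ratio,
        codons_compared=len(codon_pairs),
    )


def detect_premature_stop(s: CodingSequence) -> TruncationReport:
    """Scan in-frame codons for stops; truncated iff a stop precedes the final codon."""
    codons = s.codons()
    if not codons:
        raise InvalidInputError(f"{s.name}: fewer than 3 nucleotides from frame offset")
    stops = tuple(i + 1 for i, c in enumerate(codons) if c in STOP_CODONS)
    is_truncated = any(pos < len(codons) for pos in stops)
    return TruncationReport(
        name=s.name,
        in_frame_stop_positions=stops,
        n_codons=len(codons),
        is_truncated=is_truncated,
    )


def distance_matrix(
    sequences: Sequence[CodingSequence], metric: str = "p"
) -> DistanceMatrix:
    """All-pairs distance matrix; ``metric`` is ``"p"`` or ``"jc"``."""
    if metric not in ("p", "jc"):
        raise InvalidInputError(f"unknown distance metric {metric!r}")
    n = len(sequences)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(sequences[i], sequences[j])
            if metric == "jc":
                d = jukes_cantor(d)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(names=[s.name for s in sequences], values=values)


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    On an additive matrix the tip-to-tip path lengths of the result reproduce
    the input distances.  Negative branch lengths are clamped to zero with the
    deficit transferred to the adjacent branch, so the output is usable as a
    phylogeny.  Joining is deterministic for a given input.
    """
    if len(d.names) < 3:
        raise InvalidInputError("neighbor joining requires at least 3 taxa")
    dm = _SkbioDistanceMatrix(d.values, ids=d.names)
    newick = str(_skbio_nj(dm, neg_as_zero=True))
    return dendropy.Tree.get(data=newick, schema="newick")


def dnds_table(
    sequences: Sequence[CodingSequence], count_stops: bool = False
) -> pd.DataFrame:
    """Square table: genetic distance in the upper triangle, dN/dS in the lower.

    Mirrors the conventional paired presentation of family-wide divergence and
    selection summaries; undefined dN/dS ratios appear as NaN.
    """
    names = [s.name for s in sequences]
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, j in itertools.combinations(range(len(sequences)), 2):
        out.iloc[i, j] = p_distance(sequences[i], sequences[j])
        res = nei_gojobori(sequences[i], sequences[j], count_stops)
        out.iloc[j, i] = np.nan if res.ratio is None else res.ratio
    np.fill_diagonal(out.values, 0.0)
    return out


def truncation_table(sequences: Iterable[CodingSequence]) -> pd.DataFrame:
    """One row per sequence: stop positions (comma-joined) and the truncation flag."""
    rows = []
    for s in sequences:
        rep = detect_premature_stop(s)
        rows.append(
            {
                "name": rep.name,
                "n_codons": rep.n_codons,
                "stop_codon_positions": ",".join(map(str, rep.in_frame_stop_positions)),
                "is_truncated": rep.is_truncated,
            }
        )
    return pd.DataFrame(rows)
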