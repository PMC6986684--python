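"""FPKM computation and cross-condition expression comparison tables.

FPKM = fragments per kilobase of transcript per million mapped fragments:
count * 1e9 / (length_bp * library_size).  The report lists per-transcript
FPKM for every condition plus pairwise log2 fold changes; zeros are handled
with a fixed FPKM pseudocount and flagged.  Differential-expression testing
is out of scope here — the significance column is carried empty so the
report keeps the conventional layout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

#: FPKM pseudocount applied on both sides of a fold change involving a zero.
DEFAULT_PSEUDOCOUNT = 0.1


def fpkm(count: float, length: float, library_size: float) -> float:
    """FPKM of one transcript: count * 1e9 / (length * library_size)."""
    if length <= 0:
        raise InvalidInputError(f"transcript length must be > 0, got {length}")
    if library_size <= 0:
        raise InvalidInputError(f"library size must be > 0, got {library_size}")
    if count < 0:
        raise InvalidInputError(f"fragment count must be >= 0, got {count}")
    return count * 1e9 / (length * library_size)


@dataclass
class ExpressionTable:
    """Transcript fragment counts across conditions with per-condition library sizes.

    ``counts`` is indexed by transcript name with one column per condition;
    ``lengths`` maps transcript name to bp; ``library_sizes`` maps condition
    to total mapped fragments (which must be at least the column sum).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise InvalidInputError(f"duplicate transcript names: {dupes}")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidInputError("negative fragment counts")
        missing = set(self.counts.index) - set(self.lengths.index)
        if missing:
            raise InvalidInputError(f"transcripts without length: {sorted(missing)}")
        missing_ls = set(self.counts.columns) - set(self.library_sizes.index)
        if missing_ls:
            raise InvalidInputError(f"conditions without library size: {sorted(missing_ls)}")
        for cond in self.counts.columns:
            if self.library_sizes[cond] < self.counts[cond].sum():
                raise InvalidInputError(
                    f"library size of '{cond}' is below its assigned fragment total"
                )

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns)

    def fpkm_matrix(self) -> pd.DataFrame:
        """FPKM per transcript (rows) and condition (columns)."""
        lengths = self.lengths.loc[self.counts.index].to_numpy()[:, None]
        sizes = self.library_sizes.loc[self.counts.columns].to_numpy()[None, :]
        values = self.counts.to_numpy(dtype=float) * 1e9 / (lengths * sizes)
        return pd.DataFrame(values, index=self.counts.index, columns=self.counts.columns)


def expression_report(
    table: ExpressionTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-transcript FPKM by condition plus pairwise log2 fold changes.

    For each ordered condition pair (i, j) with i before j in input order the
    report carries log2((fpkm_i + c) / (fpkm_j + c)) where c is applied only
    when either side is zero, with a companion flag column; the significance
    column is left empty.  The report is invariant to transcript row order.
    """
    if len(table.conditions) < 2:
        raise InvalidInputError("expression report needs at least 2 conditions")
    fm = table.fpkm_matrix().sort_index()
    out = fm.copy()
    out.columns = [f"fpkm_{c}" for c in fm.columns]
    for a, b in itertools.combinations(fm.columns, 2):
        fa, fb = fm[a].to_numpy(), fm[b].to_numpy()
        zero = (fa == 0) | (fb == 0)
        num = np.where(zero, fa + pseudocount, fa)
        den = np.where(zero, fb + pseudocount, fb)
        out[f"log2fc_{a}_vs_{b}"] = np.log2(num / den)
        out[f"pseudocount_used_{a}_vs_{b}"] = zero
    out["significance"] = ""
    out.index.name = "transcript"
    return out
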