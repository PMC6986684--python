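"""Independent brute-force oracles used by the test suite.

These reimplement the codon-level counting from scratch on top of
Biopython's translation table, deliberately sharing no code with the
package, so that agreement is evidence rather than tautology.
"""

import itertools

from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return translate(codon) == "*"


def site_fractions_oracle(codon: str) -> tuple[float, float]:
    """Per-codon (synonymous, nonsynonymous) sites; stop mutants excluded."""
    aa = translate(codon)
    syn_total = 0.0
    for i in range(3):
        outcomes = []
        for nt in NUCLEOTIDES:
            if nt == codon[i]:
                continue
            mutant = codon[:i] + nt + codon[i + 1 :]
            if is_stop(mutant):
                continue
            outcomes.append(translate(mutant) == aa)
        if outcomes:
            syn_total += sum(outcomes) / len(outcomes)
    return syn_total, 3.0 - syn_total


def path_counts_oracle(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) step counts; stop-passing paths dropped."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = nonsyn = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if is_stop(nxt) and not allow_stops and nxt != codon_b:
                return None
            if translate(nxt) == translate(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    results = [walk(o, False) for o in itertools.permutations(diffs)]
    valid = [r for r in results if r is not None]
    if not valid:
        valid = [walk(o, True) for o in itertools.permutations(diffs)]
    return (
        sum(r[0] for r in valid) / len(valid),
        sum(r[1] for r in valid) / len(valid),
    )


def all_nonstop_codons() -> list[str]:
    return [
        a + b + c
        for a in NUCLEOTIDES
        for b in NUCLEOTIDES
        for c in NUCLEOTIDES
        if not is_stop(a + b + c)
    ]
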