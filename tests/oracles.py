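"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own algorithms: the Fisher tail is
enumerated over all tables with the observed margins using exact rationals,
and pedigree inbreeding is computed by Wright's path-counting formula over
exhaustively enumerated ancestor paths.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from rohmap.types import Pedigree


def fisher_upper_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """P(X >= a) for the hypergeometric with margins of the 2x2 table,
    enumerated term by term with exact rationals."""
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    total = comb(n, row1)
    tail = 0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        if x >= a:
            tail += comb(col1, x) * comb(n - col1, row1 - x)
    return Fraction(tail, total)


def wright_path_inbreeding(pedigree: Pedigree, animal: str) -> float:
    """Wright's F by explicit common-ancestor path counting.

    F(x) = sum over common ancestors A and over pairs of ancestor paths
    (sire -> A, dam -> A) sharing no animal besides A of
    (1/2)^(n1 + n2 + 1) * (1 + F(A)), with path lengths in edges.
    """

    def paths_up(node: str) -> list[list[str]]:
        out = [[node]]
        for parent in pedigree.parents(node):
            if parent is not None:
                out.extend([node] + p for p in paths_up(parent))
        return out

    sire, dam = pedigree.parents(animal)
    if sire is None or dam is None:
        return 0.0
    f = 0.0
    for ps in paths_up(sire):
        for pd in paths_up(dam):
            if ps[-1] != pd[-1]:
                continue
            if set(ps[:-1]) & set(pd[:-1]):
                continue
            ancestor = ps[-1]
            n1, n2 = len(ps) - 1, len(pd) - 1
            f += 0.5 ** (n1 + n2 + 1) * (
                1.0 + wright_path_inbreeding(pedigree, ancestor)
            )
    return f
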