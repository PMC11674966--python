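"""Independent brute-force oracles used to verify the implementation.

These deliberately share no code with the package: plain-Python
enumeration over dictionaries, math.comb hypergeometrics, and explicit
rank-split / sign-assignment enumeration.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def brute_force_burden(
    cells: dict[tuple[str, str], int | None],
    gene_to_arm: dict[str, str],
    arms: list[str],
    cases: list[str],
    threshold: Fraction = Fraction(2, 3),
) -> dict[str, tuple[int, int]]:
    """Recount altered/evaluable arms per case straight from the cells.

    ``cells`` maps (gene, case) -> call or None.  Returns
    case -> (altered_arms, evaluable_arms).
    """
    out: dict[str, tuple[int, int]] = {}
    for case in cases:
        altered = evaluable = 0
        for arm in arms:
            values = [
                cells[(g, case)]
                for g in gene_to_arm
                if gene_to_arm[g] == arm and cells.get((g, case)) is not None
            ]
            n = len(values)
            if n == 0:
                continue
            evaluable += 1
            k_del = sum(1 for v in values if v in (-1, -2))
            k_amp = sum(1 for v in values if v in (1, 2))
            if Fraction(k_del, n) >= threshold or Fraction(k_amp, n) >= threshold:
                altered += 1
        out[case] = (altered, evaluable)
    return out


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration
    (point-probability rule)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x: int) -> Fraction:
        return Fraction(
            math.comb(row1, x) * math.comb(row2, col1 - x), math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = prob(a)
    total = sum(
        (p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + Fraction(1, 10**9))),
        Fraction(0),
    )
    return float(min(total, 1))


def mann_whitney_exact_oracle(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann–Whitney p by enumerating every split of the
    pooled sample into groups of sizes |x| and |y| (tie-free inputs)."""
    pooled = sorted(x + y)
    n1 = len(x)

    def u_of(group: tuple[float, ...]) -> float:
        rest = list(pooled)
        for v in group:
            rest.remove(v)
        return sum(1 for xv in group for yv in rest if xv > yv)

    u_obs = u_of(tuple(x))
    n2 = len(y)
    u_obs = min(u_obs, n1 * n2 - u_obs)
    count = total = 0
    for group in itertools.combinations(pooled, n1):
        u = u_of(group)
        u = min(u, n1 * n2 - u)
        total += 1
        if u <= u_obs:
            count += 1
    return count / total


def wilcoxon_exact_oracle(diffs: list[float]) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments
    over the nonzero differences (tie-free absolute values)."""
    nz = [d for d in diffs if d != 0]
    n = len(nz)
    ranks = {abs(d): r for r, d in enumerate(sorted(nz, key=abs), start=1)}
    w_obs = sum(ranks[abs(d)] for d in nz if d > 0)
    total_rank = n * (n + 1) // 2
    w_obs = min(w_obs, total_rank - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks.values(), signs) if s)
        w = min(w, total_rank - w)
        if w <= w_obs:
            count += 1
    return count / 2**n
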