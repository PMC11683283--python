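"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the duplex oracle
enumerates every monotone pair set recursively and scores it with the same
arithmetic order as the DP accumulates (first-pair terminal penalty, then
left-to-right step terms, then last-pair terminal penalty, then initiation),
so agreement can be asserted with exact float equality.
"""

from __future__ import annotations

import math
from itertools import combinations

from trfscreen.energy import ALLOWED_PAIRS, EnergyModel


def _legal(x: str, y: str) -> bool:
    return (x, y) in ALLOWED_PAIRS


def enumerate_duplex_mfe(trf: str, site: str, model: EnergyModel) -> float:
    """Exhaustive minimum over all legal monotone pair sets (lengths <= ~8).

    Pairs are (i, j) 0-based with i strictly increasing and j strictly
    decreasing; consecutive-pair gaps are limited by ``model.max_loop``.
    Returns +inf when no pair is legal.
    """
    n, m = len(trf), len(site)
    best = math.inf

    def term(i: int, j: int) -> float:
        return (
            model.terminal_au_gu_penalty
            if model.is_terminal_penalized(trf[i], site[j])
            else 0.0
        )

    def extend(i: int, j: int, acc: float) -> None:
        nonlocal best
        # close the duplex here
        total = (acc + term(i, j)) + model.duplex_init
        if total < best:
            best = total
        # or add one more pair
        for i2 in range(i + 1, min(n, i + 2 + model.max_loop)):
            g1 = i2 - i - 1
            for j2 in range(j - 1, max(-1, j - 2 - (model.max_loop - g1)), -1):
                if not _legal(trf[i2], site[j2]):
                    continue
                g2 = j - j2 - 1
                if g1 == 0 and g2 == 0:
                    step = model.stack_energy[(trf[i] + trf[i2], site[j] + site[j2])]
                elif g1 == 0 or g2 == 0:
                    step = model.bulge_penalty(g1 + g2)
                else:
                    step = model.internal_loop_penalty(g1 + g2)
                extend(i2, j2, acc + step)

    for i in range(n):
        for j in range(m):
            if _legal(trf[i], site[j]):
                extend(i, j, term(i, j))
    return best


def hypergeom_upper_tail(universe: int, set_size: int, selected: int, overlap: int) -> float:
    """P(overlap >= k) by counting combinations (universes <= ~25)."""
    total = math.comb(universe, selected)
    count = 0
    for k in range(overlap, min(set_size, selected) + 1):
        count += math.comb(set_size, k) * math.comb(universe - set_size, selected - k)
    return count / total


def gsea_running_sum(ranked_in_set: list[bool], weights: list[float], p: float) -> float:
    """Direct running-sum ES: explicit loop, no numpy, for tiny N."""
    n = len(ranked_in_set)
    k = sum(ranked_in_set)
    assert 0 < k < n
    w = [abs(x) ** p for x in weights]
    denom = sum(wi for wi, hit in zip(w, ranked_in_set) if hit)
    if denom == 0:
        w = [1.0] * n
        denom = float(k)
    running = 0.0
    best = 0.0
    for wi, hit in zip(w, ranked_in_set):
        running += wi / denom if hit else -1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best
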