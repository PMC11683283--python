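"""Intermolecular RNA:RNA duplex minimum free energy (MFE).

A two-sequence dynamic program over query/target prefixes, in the style of
hybridization tools for small-RNA target prediction: the query (tRF) and
target (3'UTR site) may pair with each other through Watson-Crick and G·U
wobble pairs, consecutive pairs are scored as nearest-neighbor stacks, and
unpaired stretches between pairs cost bulge or internal-loop penalties.
Intramolecular structure is forbidden, so the pair list is strictly
increasing on the query and strictly decreasing on the target (a duplex has
no pseudoknots).

Energies are ΔG37 in kcal/mol; lower is more stable.  ``math.inf`` is the
"no legal pair" sentinel.

Tie-breaking in the traceback is deterministic: stack beats bulge beats
internal loop, then the 5'-most pairing on the query (and the 3'-most target
position, which keeps the helix contiguous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .energy import ALLOWED_PAIRS, EnergyModel
from .library import TRFRecord, SeqRecordLike

__all__ = [
    "DuplexResult",
    "SiteHit",
    "pair_allowed",
    "duplex_mfe",
    "complementarity_rate",
    "scan_utr",
]

_BASES = "ACGU"


def pair_allowed(x: str, y: str) -> bool:
    """True iff x·y is a Watson-Crick or G·U wobble pair."""
    if x not in _BASES or y not in _BASES:
        raise ValueError(f"bases must be one of A,C,G,U; got {x!r}, {y!r}")
    return (x, y) in ALLOWED_PAIRS


@dataclass(frozen=True)
class DuplexResult:
    """Optimal duplex of a query with a target site.

    ``pairs`` holds 1-based (query position, target position) tuples,
    increasing on the query and decreasing on the target.  ``comp_rate`` is
    100 x paired query positions / query length, to one decimal.
    """

    mfe: float
    pairs: tuple[tuple[int, int], ...]
    comp_rate: float
    structure_string: str = ""


@dataclass(frozen=True)
class SiteHit:
    """A scored binding site on a UTR (coordinates 1-based inclusive)."""

    utr_id: str
    start: int
    end: int
    result: DuplexResult


def _check_rna(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"{name} contains non-RNA characters {sorted(bad)}")


def complementarity_rate(n_paired: int, trf_len: int) -> float:
    """Percent of query positions paired (WC or G·U), one decimal."""
    if trf_len < 1:
        raise ValueError("trf_len must be >= 1")
    return round(100.0 * n_paired / trf_len, 1)


def duplex_mfe(trf: str, site: str, model: EnergyModel) -> DuplexResult:
    """Minimum-free-energy duplex of `trf` (query) with `site` (target).

    Both sequences are given 5'->3'.  The optimum minimizes
    ``duplex_init + terminal penalties + sum(stack/loop terms)`` over all
    monotone pair sets whose inter-pair gaps respect ``model.max_loop``.
    Returns the +inf sentinel with an empty pair list if no pair is legal.
    """
    _check_rna(trf, "query")
    _check_rna(site, "target")
    if len(trf) > 60 or len(site) > 60:
        raise ValueError("duplex_mfe is meant for site windows (<= 60 nt per strand)")

    n, m = len(trf), len(site)
    max_loop = model.max_loop
    stack = model.stack_energy
    term_pen = model.terminal_au_gu_penalty

    legal = [[pair_allowed(trf[i], site[j]) for j in range(m)] for i in range(n)]
    term = [
        [term_pen if model.is_terminal_penalized(trf[i], site[j]) else 0.0 for j in range(m)]
        for i in range(n)
    ]

    INF = math.inf
    # E[i][j]: best energy of a duplex ending with pair (i, j): first-pair
    # terminal penalty plus all stack/loop steps up to (i, j).
    E = [[INF] * m for _ in range(n)]
    # backpointer: (i2, j2) of the previous pair, or None for a helix start
    back: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]

    bulge = [model.bulge_penalty(s) for s in range(1, max_loop + 1)]
    internal = [model.internal_loop_penalty(s) for s in range(2, 2 * max_loop + 1)]

    for i in range(n):
        ti = trf[i]
        for j in range(m - 1, -1, -1):
            if not legal[i][j]:
                continue
            best = term[i][j]
            best_bp: tuple[int, int] | None = None
            best_prio = (3, 0, 0)  # (loop-type priority, i2 rank, j2 rank)
            sj = site[j]
            i2_lo = max(0, i - 1 - max_loop)
            for i2 in range(i - 1, i2_lo - 1, -1):
                g1 = i - i2 - 1
                row = E[i2]
                j2_hi = min(m - 1, j + 1 + (max_loop - g1))
                for j2 in range(j + 1, j2_hi + 1):
                    e_prev = row[j2]
                    if e_prev == INF:
                        continue
                    g2 = j2 - j - 1
                    if g1 == 0 and g2 == 0:
                        step = stack[(trf[i2] + ti, site[j2] + sj)]
                        prio = (0, i2, -j2)
                    elif g1 == 0 or g2 == 0:
                        step = bulge[g1 + g2 - 1]
                        prio = (1, i2, -j2)
                    else:
                        step = internal[g1 + g2 - 2]
                        prio = (2, i2, -j2)
                    cand = e_prev + step
                    if cand < best or (cand == best and prio < best_prio):
                        best = cand
                        best_bp = (i2, j2)
                        best_prio = prio
            E[i][j] = best
            back[i][j] = best_bp

    # close the duplex: add last-pair terminal penalty and initiation
    mfe = INF
    last: tuple[int, int] | None = None
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if E[i][j] == INF:
                continue
            total = (E[i][j] + term[i][j]) + model.duplex_init
            if total < mfe or (total == mfe and last is not None and (i, -j) < (last[0], -last[1])):
                mfe = total
                last = (i, j)

    if last is None:
        return DuplexResult(mfe=INF, pairs=(), comp_rate=0.0, structure_string="")

    pairs_rev: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = last
    while cur is not None:
        pairs_rev.append(cur)
        cur = back[cur[0]][cur[1]]
    pairs0 = tuple(reversed(pairs_rev))
    pairs = tuple((i + 1, j + 1) for i, j in pairs0)
    rate = complementarity_rate(len(pairs), n)
    structure = _render_structure(trf, site, pairs0)
    return DuplexResult(mfe=mfe, pairs=pairs, comp_rate=rate, structure_string=structure)


def _render_structure(trf: str, site: str, pairs0: list | tuple) -> str:
    """Two-line alignment of the paired region (query 5'->3' on top)."""
    if not pairs0:
        return ""
    top: list[str] = []
    mid: list[str] = []
    bot: list[str] = []
    (pi, pj) = pairs0[0]
    top.append(trf[pi])
    mid.append("|")
    bot.append(site[pj])
    for (i, j) in pairs0[1:]:
        g1 = i - pi - 1
        g2 = pj - j - 1
        width = max(g1, g2)
        top.extend(list(trf[pi + 1 : i]) + ["-"] * (width - g1))
        bot.extend(list(site[j + 1 : pj][::-1]) + ["-"] * (width - g2))
        mid.extend([" "] * width)
        top.append(trf[i])
        mid.append("|")
        bot.append(site[j])
        pi, pj = i, j
    return (
        f"5'-{''.join(top)}-3'\n"
        f"   {''.join(mid)}   \n"
        f"3'-{''.join(bot)}-5'"
    )


def scan_utr(
    trf: TRFRecord | SeqRecordLike,
    utr: SeqRecordLike,
    model: EnergyModel,
    window: int = 40,
    step: int = 10,
) -> list[SiteHit]:
    """Scan a 3'UTR with sliding windows and score each with the duplex DP.

    Overlapping hits are merged keeping the lowest-MFE representative
    (leftmost start on ties).  Hits are returned best-first (ascending MFE,
    then leftmost).  A UTR shorter than the window is scored as a single
    whole-UTR window.
    """
    qseq = trf.sequence
    if window < len(qseq):
        raise ValueError("window must be at least the fragment length")
    useq = utr.sequence
    if len(useq) <= window:
        starts = [0]
    else:
        starts = list(range(0, len(useq) - window + 1, step))
        if starts[-1] != len(useq) - window:
            starts.append(len(useq) - window)

    raw: list[SiteHit] = []
    for s in starts:
        wseq = useq[s : s + window]
        res = duplex_mfe(qseq, wseq, model)
        if not res.pairs:
            continue
        site_positions = [j for _, j in res.pairs]
        start = s + min(site_positions)
        end = s + max(site_positions)
        raw.append(SiteHit(utr_id=utr.id, start=start, end=end, result=res))

    raw.sort(key=lambda h: (h.result.mfe, h.start, h.end))
    merged: list[SiteHit] = []
    for hit in raw:
        if any(hit.start <= kept.end and kept.start <= hit.end for kept in merged):
            continue
        merged.append(hit)
    return merged
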