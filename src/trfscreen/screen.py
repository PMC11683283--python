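"""Library-vs-UTR screening: score every candidate tRF against a target
3'UTR, filter by MFE and complementarity-rate thresholds, and rank.

This is the discovery step of the pipeline: the tRF whose best 3'UTR site is
both thermodynamically stable (low MFE) and highly complementary is the
silencing candidate.  Default thresholds (MFE <= -20 kcal/mol,
complementarity >= 72 %) admit a canonical 22-nt siRNA-like hit with margin
and are prominently configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .duplex import scan_utr
from .energy import EnergyModel
from .library import SeqRecordLike, TRFRecord

logger = logging.getLogger(__name__)

__all__ = ["ScreenHit", "run_screen", "write_screen_report", "read_screen_report",
           "DEFAULT_MFE_MAX", "DEFAULT_COMP_MIN"]

DEFAULT_MFE_MAX = -20.0  # kcal/mol
DEFAULT_COMP_MIN = 72.0  # percent


@dataclass(frozen=True)
class ScreenHit:
    trf_id: str
    utr_id: str
    site_start: int  # 1-based inclusive
    site_end: int
    mfe: float
    comp_rate: float
    rank: int = 0
    structure: str = ""


def run_screen(
    frags: Sequence[TRFRecord | SeqRecordLike],
    utr: SeqRecordLike,
    model: EnergyModel,
    mfe_max: float = DEFAULT_MFE_MAX,
    comp_min: float = DEFAULT_COMP_MIN,
    window: int = 40,
    step: int = 10,
    all_sites: bool = False,
) -> list[ScreenHit]:
    """Score each fragment's binding sites on `utr` and keep those passing
    ``mfe <= mfe_max`` and ``comp_rate >= comp_min``.

    By default only each fragment's best site is considered (``all_sites``
    retains every merged site).  Hits are sorted by (MFE ascending,
    comp_rate descending, trf_id) and densely ranked from 1.  The result is
    a pure function of the inputs: permuting the library changes nothing.
    """
    if not frags:
        logger.warning("run_screen called with an empty fragment library")
        return []
    rows: list[ScreenHit] = []
    for frag in frags:
        sites = scan_utr(frag, utr, model, window=window, step=step)
        if not sites:
            logger.debug("fragment %s: no pairable site", frag.id)
            continue
        for hit in sites if all_sites else sites[:1]:
            keep = hit.result.mfe <= mfe_max and hit.result.comp_rate >= comp_min
            logger.debug(
                "fragment %s site %d-%d mfe=%.2f comp=%.1f -> %s",
                frag.id, hit.start, hit.end, hit.result.mfe, hit.result.comp_rate,
                "kept" if keep else "filtered",
            )
            if keep:
                rows.append(
                    ScreenHit(
                        trf_id=frag.id,
                        utr_id=hit.utr_id,
                        site_start=hit.start,
                        site_end=hit.end,
                        mfe=hit.result.mfe,
                        comp_rate=hit.result.comp_rate,
                        structure=hit.result.structure_string,
                    )
                )
    rows.sort(key=lambda h: (h.mfe, -h.comp_rate, h.trf_id))
    return [
        ScreenHit(
            trf_id=h.trf_id, utr_id=h.utr_id, site_start=h.site_start,
            site_end=h.site_end, mfe=h.mfe, comp_rate=h.comp_rate,
            rank=k + 1, structure=h.structure,
        )
        for k, h in enumerate(rows)
    ]


_COLUMNS = ["rank", "trf_id", "utr_id", "site_start", "site_end", "mfe_kcal_mol", "comp_rate_pct"]


def write_screen_report(
    hits: Sequence[ScreenHit],
    path: str | Path,
    library_size: int | None = None,
    mfe_max: float | None = None,
    comp_min: float | None = None,
) -> str:
    """Write hits as TSV and return a human-readable summary string."""
    df = pd.DataFrame(
        [
            {
                "rank": h.rank,
                "trf_id": h.trf_id,
                "utr_id": h.utr_id,
                "site_start": h.site_start,
                "site_end": h.site_end,
                "mfe_kcal_mol": h.mfe,
                "comp_rate_pct": h.comp_rate,
            }
            for h in hits
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    lines = [f"screen: {len(hits)} hit(s)"]
    if library_size is not None:
        lines.append(f"library size: {library_size}")
    if mfe_max is not None or comp_min is not None:
        lines.append(f"thresholds: mfe <= {mfe_max} kcal/mol, comp_rate >= {comp_min} %")
    summary = "\n".join(lines)
    logger.info(summary)
    return summary


def read_screen_report(path: str | Path) -> list[ScreenHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        ScreenHit(
            trf_id=str(r.trf_id), utr_id=str(r.utr_id), site_start=int(r.site_start),
            site_end=int(r.site_end), mfe=float(r.mfe_kcal_mol),
            comp_rate=float(r.comp_rate_pct), rank=int(r.rank),
        )
        for r in df.itertuples()
    ]
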