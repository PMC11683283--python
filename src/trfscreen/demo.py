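"""End-to-end rehearsal of the whole pipeline on synthetic data.

``run_demo`` stitches every stage together — simulate, fragment, screen,
differential expression, enrichment, IC50 recovery — with a built-in sanity
check per stage, and writes a JSON report.  Sizes are scaled down from the
generator defaults (a 12-tRNA library, 600 genes, 200 permutations) so the
demo finishes in seconds; the checks exercised are the same ones the test
suite runs at full size.
"""

from __future__ import annotations

import json
from pathlib import Path

from .assays import fit_4pl
from .expression import call_degs, gsea_es, tpm_normalize
from .energy import load_default_model
from .library import make_fragments
from .screen import run_screen
from .simulate import (
    SimConfig,
    generate_counts,
    generate_dose_response,
    generate_trna_library,
    plant_target_site,
)

__all__ = ["run_demo", "DemoCheckError"]


class DemoCheckError(RuntimeError):
    """A pipeline stage's built-in check failed; the message names the stage."""


def run_demo(seed: int = 42, outdir: str | Path | None = None, n_perm: int = 200) -> dict:
    cfg = SimConfig(seed=seed, n_trnas=12, n_genes=600, utr_len=200,
                    planted_site=SimConfig().planted_site)
    report: dict[str, object] = {"seed": seed}

    # stage 1: simulate library + planted UTR site
    trnas = generate_trna_library(cfg)
    planted_parent = trnas[cfg.planted_site.trf_index]
    planted_seq = planted_parent.sequence[: cfg.frag_len]
    utr, (site_start, site_end) = plant_target_site(cfg, planted_seq)
    report["simulate"] = {"n_trnas": len(trnas), "planted_site": [site_start, site_end]}

    # stage 2: fragments
    frags = make_fragments(trnas, lengths=[cfg.frag_len])
    if len(frags) != len(trnas):
        raise DemoCheckError(f"fragments: expected {len(trnas)} fragments, got {len(frags)}")
    report["fragments"] = {"n": len(frags)}

    # stage 3: screen — the planted tRF must rank first
    model = load_default_model()
    hits = run_screen(frags, utr, model, mfe_max=-15.0, comp_min=72.0)
    if not hits or not hits[0].trf_id.startswith(planted_parent.id):
        raise DemoCheckError("screen: planted tRF is not rank 1")
    report["screen"] = {
        "rank1": hits[0].trf_id, "mfe": hits[0].mfe, "comp_rate": hits[0].comp_rate,
        "site": [hits[0].site_start, hits[0].site_end], "n_hits": len(hits),
    }
    if not (hits[0].site_start <= site_start and hits[0].site_end >= site_start):
        raise DemoCheckError("screen: best hit does not cover the planted site")

    # stage 4: counts -> DEG -> GSEA on the planted pathway
    counts, truth, lengths, gene_sets = generate_counts(cfg)
    tpm = tpm_normalize(counts, lengths)
    groups = {s: ("treated" if s.startswith("treated") else "control") for s in tpm.columns}
    degs = call_degs(tpm, groups)
    by_gene = {r.gene_id: r for r in degs}
    planted_down = truth[truth.direction == "down"].gene_id
    recovered = sum(by_gene[g].call == "down" for g in planted_down)
    if recovered < 0.7 * len(planted_down):
        raise DemoCheckError(
            f"deg: only {recovered}/{len(planted_down)} planted down-genes recovered"
        )
    report["deg"] = {"planted_down": int(len(planted_down)), "recovered_down": int(recovered)}

    ranked = sorted(degs, key=lambda r: r.log2fc, reverse=True)
    enr = gsea_es(
        [r.gene_id for r in ranked], [r.log2fc for r in ranked],
        gene_sets["PI3K_AKT_LIKE"], set_id="PI3K_AKT_LIKE",
        n_perm=n_perm, seed=seed,
    )
    if not (enr.es < 0 and enr.p_perm < 0.05):
        raise DemoCheckError(
            f"gsea: planted pathway not suppressed (es={enr.es:.3f}, p={enr.p_perm:.3f})"
        )
    report["gsea"] = {"es": enr.es, "p_perm": enr.p_perm}

    # stage 5: IC50 recovery on the HCT-8 preset
    dr = generate_dose_response("hct8_trf36", cfg)
    fit = fit_4pl(dr["dose_nM"], dr["viability_pct"], n_boot=0)
    # wiring sanity check, deliberately looser than the fit's seed-to-seed
    # spread (~7% SD) so the demo is meaningful at any seed
    target = cfg.dose_presets["hct8_trf36"].ic50
    if not fit.converged or abs(fit.ic50 - target) / target > 0.25:
        raise DemoCheckError(f"ic50: recovered {fit.ic50:.2f} nM vs preset {target} nM")
    report["ic50"] = {"fitted_nM": fit.ic50, "preset_nM": target}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "demo_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
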