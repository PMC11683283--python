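"""Quantify the remaining assay panel from synthetic tables.

qPCR knockdown (2^-ddCT), wound-healing rates per condition, caspase-3
fold activity, and xenograft growth (caliper volumes, final treated/control
ratio).  Writes results/assay_panel.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from trfscreen.assays import ddct_fold, fold_activity, growth_summary, wound_healing_rate
from trfscreen.simulate import (
    SimConfig,
    generate_caspase_activity,
    generate_qpcr_ct,
    generate_tumor_growth,
    generate_wound_areas,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=args.seed)
    out: dict[str, object] = {"seed": args.seed}

    ct = generate_qpcr_ct(cfg, planted_ddct=2.0)
    cts = lambda g, gene: ct[(ct.group == g) & (ct.gene == gene)].ct.to_numpy()
    q = ddct_fold(cts("treated", "target"), cts("treated", "reference"),
                  cts("control", "target"), cts("control", "reference"))
    out["qpcr"] = {"ddct": round(q.ddct, 3), "fold": round(q.fold, 3)}
    print(f"qPCR: ddCT = {q.ddct:.2f} -> target at {100 * q.fold:.1f}% of control")

    wounds = generate_wound_areas(cfg)
    whr = {
        cond: round(float(pd.Series(
            [wound_healing_rate(r.area_t0, r.area_t) for r in sub.itertuples()]
        ).mean()), 1)
        for cond, sub in wounds.groupby("condition")
    }
    out["wound_healing_rate_pct"] = whr
    print("wound healing rates (%):", json.dumps(whr, indent=2))

    casp = generate_caspase_activity(cfg, fold=2.0)
    f = fold_activity(casp[casp.group == "treated"].signal.mean(),
                      casp[casp.group == "control"].signal.mean())
    out["caspase_fold"] = round(f, 2)
    print(f"caspase-3 activity fold (treated/control): {f:.2f}")

    growth = generate_tumor_growth(cfg, multiplier=0.5)
    summary = growth_summary(growth)
    curves = summary.pop("curves")
    curves.to_csv(args.outdir / "tumor_curves.tsv", sep="\t", index=False)
    out["tumor"] = {k: (round(v, 3) if isinstance(v, float) else v)
                    for k, v in summary.items()}
    print(f"tumor final volume ratio (treated/control, day {summary['final_day']}): "
          f"{summary['final_volume_ratio']:.2f}")

    (args.outdir / "assay_panel.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
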