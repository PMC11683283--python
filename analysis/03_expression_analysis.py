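"""Characterize the knockdown transcriptome: DEGs, clustering, enrichment.

TPM-normalizes the simulated count matrix, calls DEGs (|log2FC| > 1,
p < 0.05, Welch t on log2 TPM), bi-clusters samples and the top variable
genes, and tests the planted PI3K-Akt-like set by GSEA (gene-label
permutation) and hypergeometric over-representation.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from trfscreen.expression import (
    call_degs,
    degs_to_frame,
    gsea_es,
    hierarchical_bicluster,
    ora_table,
    tpm_normalize,
)
from trfscreen.simulate import read_gmt


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-perm", type=int, default=1000)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.simdir / "counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(args.simdir / "gene_lengths.tsv", sep="\t", index_col=0).iloc[:, 0]
    truth = pd.read_csv(args.simdir / "de_truth.tsv", sep="\t")
    sets = read_gmt(args.simdir / "gene_sets.gmt")

    tpm = tpm_normalize(counts, lengths)
    groups = {s: ("treated" if s.startswith("treated") else "control") for s in tpm.columns}
    degs = call_degs(tpm, groups)
    deg_df = degs_to_frame(degs)
    deg_df.to_csv(args.outdir / "deg_table.tsv", sep="\t", index=False)
    n_up, n_down = (deg_df.call == "up").sum(), (deg_df.call == "down").sum()
    print(f"DEGs at |log2FC| > 1, p < 0.05: {n_down} down, {n_up} up of {len(deg_df)}")

    planted_down = set(truth.loc[truth.direction == "down", "gene_id"])
    called_down = set(deg_df.loc[deg_df.call == "down", "gene_id"])
    print(f"planted down-regulated genes recovered: "
          f"{len(planted_down & called_down)}/{len(planted_down)}")

    clust = hierarchical_bicluster(tpm)
    (args.outdir / "cluster_orderings.json").write_text(
        json.dumps({"row_order": clust["row_order"][:50], "col_order": clust["col_order"]},
                   indent=2) + "\n")
    print(f"sample dendrogram order: {clust['col_order']}")

    ranked = deg_df.sort_values("log2fc", ascending=False)
    rows = []
    for name, members in sets.items():
        r = gsea_es(ranked.gene_id.tolist(), ranked.log2fc.tolist(), members,
                    set_id=name, n_perm=args.n_perm, seed=args.seed)
        rows.append({"set_id": name, "es": r.es, "p_perm": r.p_perm,
                     "overlap_k": r.overlap_k, "set_size": r.set_size})
        print(f"GSEA {name}: ES = {r.es:+.3f}, permutation p = {r.p_perm:.4f}")
    pd.DataFrame(rows).to_csv(args.outdir / "gsea.tsv", sep="\t", index=False)

    ora = ora_table(deg_df.loc[deg_df.call == "down", "gene_id"].tolist(), sets,
                    deg_df.gene_id.tolist())
    ora.to_csv(args.outdir / "ora.tsv", sep="\t", index=False)
    print(ora.to_string(index=False))


if __name__ == "__main__":
    main()
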