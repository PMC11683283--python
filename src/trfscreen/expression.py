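"""Knockdown characterization: TPM normalization, differential expression,
hierarchical bi-clustering, GSEA and hypergeometric over-representation.

Conventions
-----------
``log2fc`` is always treated minus control on the log2 scale, so a silenced
gene has a *negative* log2fc (volcano plots elsewhere sometimes invert this;
the mapping here is fixed and documented).  Per-gene p-values come from a
two-tailed Welch t-test on log2(TPM + pseudocount); Benjamini-Hochberg FDR
is reported alongside the raw p the calls filter on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEGRecord",
    "EnrichmentResult",
    "tpm_normalize",
    "call_degs",
    "hierarchical_bicluster",
    "gsea_es",
    "hypergeom_ora",
    "ora_table",
]


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    mean_treated: float
    mean_control: float
    log2fc: float
    p: float
    fdr: float
    call: str  # up / down / ns


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    es: float | None = None
    nes: float | None = None
    p_perm: float | None = None
    overlap_k: int | None = None
    set_size: int | None = None
    universe: int | None = None
    p_hyper: float | None = None


def tpm_normalize(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalize, then scale columns to 1e6."""
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length for {missing[0]!r}"
                         + (f" (+{len(missing) - 1} more)" if len(missing) > 1 else ""))
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def call_degs(
    tpm: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    log2fc_thresh: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> list[DEGRecord]:
    """Differential expression: Welch t on log2(TPM+pc), BH FDR alongside.

    `groups` maps sample name -> "treated" | "control" (>= 2 samples each).
    A gene constant across all samples gets p = 1 by convention.  Calls:
    up iff log2fc > thresh and p < alpha; down iff log2fc < -thresh and
    p < alpha; ns otherwise.
    """
    groups = pd.Series(dict(groups))
    treated = [s for s in tpm.columns if groups.get(s) == "treated"]
    control = [s for s in tpm.columns if groups.get(s) == "control"]
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >= 2 samples per group")

    log_tpm = np.log2(tpm + pseudocount)
    xt = log_tpm[treated].to_numpy()
    xc = log_tpm[control].to_numpy()

    mean_t = tpm[treated].mean(axis=1).to_numpy()
    mean_c = tpm[control].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_t + pseudocount) - np.log2(mean_c + pseudocount)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    constant = (np.ptp(np.hstack([xt, xc]), axis=1) == 0)
    p = np.where(constant | ~np.isfinite(p), 1.0, p)

    _, fdr, _, _ = multipletests(p, method="fdr_bh")

    records = []
    for g, mt, mc, lfc, pv, fv in zip(tpm.index, mean_t, mean_c, log2fc, p, fdr):
        if pv < alpha and lfc > log2fc_thresh:
            call = "up"
        elif pv < alpha and lfc < -log2fc_thresh:
            call = "down"
        else:
            call = "ns"
        records.append(
            DEGRecord(gene_id=str(g), mean_treated=float(mt), mean_control=float(mc),
                      log2fc=float(lfc), p=float(pv), fdr=float(fv), call=call)
        )
    return records


def degs_to_frame(records: Sequence[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def hierarchical_bicluster(
    tpm: pd.DataFrame, pseudocount: float = 1.0
) -> dict[str, object]:
    """Complete-linkage hierarchical bi-clustering on log2(TPM+pc).

    Euclidean distance, complete linkage on both genes (rows) and samples
    (columns); leaf order is scipy's deterministic dendrogram order.
    Returns a JSON-serializable dict with row/column orderings and linkage
    matrices.
    """
    if tpm.isna().any().any():
        raise ValueError("TPM matrix contains NaN")
    if tpm.shape[0] < 2 or tpm.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    x = np.log2(tpm.to_numpy(dtype=float) + pseudocount)
    row_link = hierarchy.linkage(pdist(x, metric="euclidean"), method="complete")
    col_link = hierarchy.linkage(pdist(x.T, metric="euclidean"), method="complete")
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    return {
        "row_order": [str(tpm.index[i]) for i in row_order],
        "col_order": [str(tpm.columns[i]) for i in col_order],
        "row_linkage": row_link.tolist(),
        "col_linkage": col_link.tolist(),
    }


def _running_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed max deviation of the weighted Kolmogorov-Smirnov running sum."""
    n = in_set.size
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the ranking")
    if k == n:
        raise ValueError("gene set covers the whole ranking (N - k = 0)")
    hit_w = np.where(in_set, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all overlapping genes have zero ranking statistic: fall back to
        # unweighted hits so the running sum is still defined
        hit_w = in_set.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~in_set).astype(float) / (n - k)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_es(
    ranked_genes: Sequence[str],
    statistic: Sequence[float],
    gene_set: Sequence[str],
    set_id: str = "set",
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Gene-set enrichment score with a gene-label permutation p-value.

    `ranked_genes` must be ordered by `statistic` (descending: most
    up-regulated first).  Hits are weighted by |statistic|^p normalized to
    sum 1; misses contribute -1/(N-k).  ES is the signed maximum deviation
    of the running sum.  The permutation p-value is the fraction of
    label-permuted |ES| >= |observed|, with a +1 pseudo-observation.
    """
    genes = np.asarray(ranked_genes)
    stat = np.asarray(statistic, dtype=float)
    if genes.size != stat.size:
        raise ValueError("ranked_genes and statistic lengths differ")
    in_set = np.isin(genes, list(gene_set))
    weights = np.abs(stat) ** weight_p
    es = _running_es(in_set, weights)

    rng = np.random.default_rng(seed)
    k = int(in_set.sum())
    hits_template = np.zeros(genes.size, dtype=bool)
    more_extreme = 0
    for _ in range(n_perm):
        hits = hits_template.copy()
        hits[rng.choice(genes.size, size=k, replace=False)] = True
        if abs(_running_es(hits, weights)) >= abs(es):
            more_extreme += 1
    p_perm = (more_extreme + 1) / (n_perm + 1)
    return EnrichmentResult(
        set_id=set_id, es=es, nes=None, p_perm=p_perm,
        overlap_k=k, set_size=len(set(gene_set)), universe=int(genes.size),
    )


def hypergeom_ora(
    selected: Sequence[str],
    gene_set: Sequence[str],
    universe: Sequence[str],
    set_id: str = "set",
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation of `gene_set` in `selected`.

    p = P(overlap >= k) drawing |selected| genes from the universe without
    replacement, of which |set ∩ universe| are marked.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected) & uni
    members = set(gene_set) & uni
    k = len(sel & members)
    M, n, N = len(uni), len(members), len(sel)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    return EnrichmentResult(
        set_id=set_id, overlap_k=k, set_size=n, universe=M, p_hyper=min(p, 1.0)
    )


def ora_table(
    selected: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Over-representation across sets with BH correction."""
    results = [hypergeom_ora(selected, members, universe, set_id=name)
               for name, members in gene_sets.items()]
    df = pd.DataFrame(
        [{"set_id": r.set_id, "overlap_k": r.overlap_k, "set_size": r.set_size,
          "universe": r.universe, "p_hyper": r.p_hyper} for r in results]
    )
    if len(df):
        _, fdr, _, _ = multipletests(df["p_hyper"].to_numpy(), method="fdr_bh")
        df["fdr"] = fdr
    return df
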