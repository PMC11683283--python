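# Methods

This note documents the models, parameter choices and numerical conventions
behind `trfscreen`, and what the synthetic-data tests do and do not
establish.

## Duplex energy model

The screen's core statistic is the minimum free energy (MFE) of the
bimolecular tRF:site duplex, in the hybridization-tool tradition: only
intermolecular pairs (Watson-Crick and G·U wobble), no intramolecular
structure, no partition function or target-accessibility correction.

A structure is a set of pairs strictly increasing on the query strand and
strictly decreasing on the target (no pseudoknots exist in a two-strand
duplex).  Its energy is

```
ΔG = ΔG_init + Σ_steps + terminal penalties
```

* **Stacks** — consecutive pairs with no gap score the published
  nearest-neighbor ΔG°37 (kcal/mol, 37 °C): the Watson-Crick set of Xia et
  al. (1998) plus the Mathews/Turner G·U wobble set, shipped as a
  checksummed TSV (`data/stack_dg37.tsv`, 21 distinct stacks after
  rotational symmetry, expanded to 36 ordered entries).  A deliberate
  anchor: the GG/CC stack is −3.26, so a 5-bp G:C helix scores
  4 × (−3.26) + 4.09 = −8.95 kcal/mol.
* **Loops** — a gap on one strand is a bulge, on both an internal loop;
  size-dependent initiation penalties use the published tables up to size 6
  (bulge 3.8/2.8/3.2/3.6/4.0/4.4; internal 1.5/1.6/1.7/1.8/2.0) with
  Jacobson-Stockmayer extrapolation `ΔG(n) = ΔG(6) + 1.75·RT·ln(n/6)` above
  that, and a combined gap limit `max_loop = 15` nt.  The published bulge
  table is not monotone between sizes 1 and 2; we ship it as published.
  Loop-closing stacks, asymmetry penalties, dangling ends and coaxial
  stacking are excluded — this keeps the enumeration oracle exact and the
  DP simple; the effect on *ranking* is second order.
* **Ends** — duplex initiation +4.09 kcal/mol once, and +0.45 for each
  helix end closed by an A·U or G·U pair (a single-pair duplex is closed by
  the same pair at both ends and pays the penalty twice).

Temperature is fixed at 37 °C (ΔG°37 only; no enthalpy/entropy
rescaling).

**Algorithm.** `duplex_mfe` is an O(n·m·max_loop²) dynamic program over
"last pair = (i, j)" states.  Traceback ties prefer stack over bulge over
internal loop, then the 5'-most query pairing, so output is deterministic.
The optimum *energy* is symmetric under swapping strand roles; the reported
co-optimal *structure* may differ between degenerate ties.  Exactness is
established against a brute-force enumerator of all monotone pair sets
(identical summation order, exact float equality) on thousands of random
pairs of lengths 4–8.

**Complementarity rate** is 100 × paired query positions / query length,
reported to one decimal.  G·U wobbles count as paired (they are
hydrogen-bonded); the denominator is the tRF length, under which the
"over 72 %" criterion at 22 nt corresponds to ≥ 16 paired positions
(16/22 = 72.7 %).

## Screening

`scan_utr` slides a window (default 40 nt, step 10, plus a final flush
window) over the UTR, scores each with the DP, merges overlapping sites
keeping the lowest-MFE representative (leftmost on ties), and `run_screen`
keeps each fragment's best site passing `mfe ≤ mfe_max` and
`comp_rate ≥ comp_min`.  Default thresholds (−20 kcal/mol, 72 %) admit a
canonical 22-nt siRNA-like hit with margin; both are exposed because the
original screening thresholds behind such analyses are typically not
published.  Hits sort by (MFE ascending, complementarity descending,
fragment id) with dense ranks; the screen is a pure function of its inputs.

## Differential expression and enrichment

* **TPM**: counts / gene length, scaled per sample to 1e6.
* **DEG calls**: log2FC = log2((mean TPM treated + 1)/(mean TPM control + 1));
  p from a two-tailed Welch t-test on log2(TPM + 1); BH FDR reported
  alongside, while calls filter on raw p (matching the usual
  "|log2FC| > 1, p < 0.05" rule).  log2FC is *always* treated − control;
  a knocked-down gene is negative.  A gene constant across all samples gets
  p = 1.  On null negative-binomial data the Welch t on log-counts is
  slightly conservative for low-count genes; at the default world
  (2,000 genes, n = 6 per group, dispersion 0.1) the realized type-I rate
  sits inside the 99 % binomial band around 0.05.
* **Clustering**: Euclidean distance on log2(TPM+1), complete linkage,
  scipy's deterministic leaf order, applied to genes and samples.
* **GSEA**: classic weighted running-sum ES — hits add |statistic|^p
  normalized to sum 1 (p = 1 default; if all overlapping weights are zero
  the hits fall back to uniform), misses subtract 1/(N−k); ES is the signed
  maximum |deviation| (first occurrence on ties).  The null is gene-label
  permutation (appropriate at a few samples per group), seeded, with a +1
  pseudo-observation on the p-value.  ES is bounded in [−1, 1] and is
  exactly negated by reversing the ranking at p = 0.
* **ORA**: exact upper-tail hypergeometric via scipy, BH across sets;
  verified against combinatorial enumeration for universes ≤ 25.

## Assay quantification

* **4PL**: `y = bottom + (top − bottom)/(1 + (x/IC50)^hill)`, fitted by
  unweighted least squares in log-dose parameterization with a multi-start
  grid (7 log-IC50 starts × hill ∈ {0.5, 1, 2}) and box bounds framed by
  the data; the reported IC50 is the *relative* (inflection) IC50, with an
  absolute-IC50 helper (`absolute_ic50`).  Convergence is refused when the
  fitted IC50 falls outside the tested doses or the response span is
  indistinguishable from residual noise.  The bootstrap CI resamples
  observations within each dose (seeded).  The fit is scale-equivariant:
  scaling doses by c scales IC50 by c.  At the default synthetic design
  (8 doses log-spaced 0.1–1000 nM, triplicates, 5 % CV, hill 1) the IC50
  estimate carries an intrinsic ~7 % relative SD — an information limit of
  that design, not an optimizer artifact.
* **Fold ratios**: concentrations are converted to nM via explicit unit
  tags (nM/µM/pM/mM) before dividing; rounding is round-half-even to the
  requested digits.
* **2^−ΔΔCT**: ΔΔCT = (CT_target − CT_ref)_treated − (CT_target −
  CT_ref)_control on replicate means; swapping conditions inverts the fold
  exactly.
* **Wound healing rate**: 100 × (area_t0 − area_t)/area_t0; negative
  values (wound growth) are allowed with a warning.
* **Tumor volume**: V = width² × length / 2; width > length is swapped
  with a warning.  `growth_summary` reports per-group mean ± SD volume
  curves and the final-day treated/control ratio; tumor *weight* is proxied
  by volume (constant-density assumption), since only caliper data enter.

## Synthetic data: the stated world

One integer seed drives everything through named substreams
(`SeedSequence(seed, spawn_key=(stream_id,))`, one id per generator, plus a
CRC32-derived key per dose preset), so outputs are byte-identical per seed
and independent of call order.  Defaults encode the experimental design the
pipeline assumes:

| parameter | default | why |
|---|---|---|
| fragment length | 22 nt | the headline 5'-tRF length |
| tRNA library | 50 seqs, 70–90 nt, GC 0.55 | only pairing structure matters to the screen |
| planted site | perfect RC at UTR offset 100/300 | mismatch & G·U budgets configurable |
| RNA-seq | 2,000 genes, n = 6/group, NB dispersion 0.1 | matches the assumed design; standard dispersion |
| planted DE | 10 % of genes at ±2 log2 | comfortably beyond the |log2FC| > 1 call threshold |
| planted pathway | 30 genes at −1.5 log2 | a coordinately suppressed PI3K-Akt-like set |
| dose-response | 8 doses 0.1–1000 nM, 3 reps, CV 5 %, hill 1, top 100, bottom 0 | presets at the published cell-line IC50s (10.0, 27.54, 9.49, 216.5, 103.8, 167.0, 1550 nM) |
| qPCR | CT sd 0.15, ΔΔCT 2 planted | typical instrument noise |
| xenograft | V₀ = 50 mm³, r = 0.12/day, 21 days, ratio 0.5 | treatment modeled as a growth-rate reduction |

Noise models are the standard choice per assay class: multiplicative
log-normal (mean 1) for viability/ELISA/volumes, Gaussian for CT values,
negative binomial for counts.

**What a green test does not establish.** The generators emulate pairing
structure and group-level statistics, not biology: tRNAs are i.i.d. random
(no cloverleaf), counts have no library-size or GC artifacts, no
batch effects, and gene sets are planted, not curated.  Recovery of planted
signal therefore validates the *implementations* (scorer, caller,
enrichment, fitter), not the original study's specific gene lists or IC50s;
the published tRF/UTR duplex values can only be checked externally by
supplying the real sequences to `trfscreen screen`, and depend on the
thermodynamic parameter version.

## Degenerate inputs and conventions

Internal coordinates are 0-based half-open; every report is 1-based
inclusive.  "No legal pair" returns a +inf MFE sentinel with an empty pair
list.  FASTA reading normalizes T→U, disambiguates duplicate ids with a
logged suffix, and rejects empty or non-nucleotide records by name.
Configuration files reject unknown keys; every CLI run writes a provenance
record (config echo, versions, input SHA-256s) and checksum mismatches on
re-verification are hard errors.
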