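"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes:

* a tRNA library over {A,C,G,U} with isotype-like ids, from which a 22-nt
  5' fragment is taken as the "planted" silencing tRF;
* a 3'UTR embedding the reverse complement of that tRF with a configurable
  number of mismatches and G·U wobbles (the target site the screen must
  find);
* negative-binomial count matrices with planted differentially expressed
  genes and one coordinately down-shifted pathway (a "PI3K-Akt-like" set);
* 4-parameter-logistic dose-response readouts at named presets calibrated
  to published IC50s, with multiplicative log-normal noise;
* qPCR CT tables, scratch-wound areas, caspase activity signals and caliper
  tumor-growth curves.

Everything is a pure function of :class:`SimConfig`: one global integer seed
governs all substreams through a documented derivation rule
(``SeedSequence(seed, spawn_key=(stream_id,))`` with a fixed per-generator
stream id), so repeated calls are byte-identical and generators are
independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import SeqRecordLike, write_fasta

__all__ = [
    "SimConfig",
    "DosePreset",
    "PlantedSite",
    "rng_for",
    "generate_trna_library",
    "plant_target_site",
    "generate_counts",
    "generate_dose_response",
    "generate_qpcr_ct",
    "generate_tumor_growth",
    "generate_wound_areas",
    "generate_caspase_activity",
    "write_gmt",
    "DEFAULT_DOSE_PRESETS",
    "WOUND_PRESETS",
]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: named substreams of the global seed (documented derivation rule)
_STREAMS = {
    "trna": 1,
    "utr": 2,
    "counts": 3,
    "dose": 4,
    "qpcr": 5,
    "tumor": 6,
    "wound": 7,
    "caspase": 8,
}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the global seed: one stream per generator."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class DosePreset:
    """4PL dose-response preset (viability %, doses in nM)."""

    ic50: float
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    cv: float = 0.05
    doses: tuple[float, ...] = tuple(np.logspace(-1, 3, 8))
    replicates: int = 3


# IC50 presets (nM) calibrated to the published cell-line values:
# tRF-T36 mimic: 10.0 (HCT-8), 27.54 (LoVo), 9.49 (taxol-resistant HCT-8);
# taxol: 216.5 (HCT-8), 103.8 (LoVo), 167.0 (HCoEpiC), 1550 (resistant HCT-8).
DEFAULT_DOSE_PRESETS: dict[str, DosePreset] = {
    "hct8_trf36": DosePreset(ic50=10.0),
    "lovo_trf36": DosePreset(ic50=27.54),
    "hct8r_trf36": DosePreset(ic50=9.49),
    "hct8_taxol": DosePreset(ic50=216.5, doses=tuple(np.logspace(0, 4, 8))),
    "lovo_taxol": DosePreset(ic50=103.8, doses=tuple(np.logspace(0, 4, 8))),
    "hcoepic_taxol": DosePreset(ic50=167.0, doses=tuple(np.logspace(0, 4, 8))),
    "hct8r_taxol": DosePreset(ic50=1550.0, doses=tuple(np.logspace(1, 5, 8))),
}

# Scratch-wound healing-rate presets (%): treated wells close slower than
# the liposomal control; values follow the published per-condition means.
WOUND_PRESETS: dict[str, float] = {
    "hct8_control": 63.5,
    "hct8_trf36_5nM": 23.1,
    "hct8_trf36_10nM": 13.7,
    "hct8_taxol": 22.8,
    "lovo_control": 58.9,
    "lovo_trf36_10nM": 53.5,
    "lovo_trf36_20nM": 21.3,
    "lovo_taxol": 27.3,
}


@dataclass(frozen=True)
class PlantedSite:
    trf_index: int = 0
    mismatches: int = 0
    gu_wobbles: int = 0
    utr_offset: int = 100  # 0-based start of the planted site in the UTR


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the synthetic experiment.

    Defaults follow the published experimental design where one exists
    (22-nt 5' fragment, n = 6 RNA-seq samples per group, |log2FC| = 1 DEG
    threshold exceeded by planted genes at 2, triplicate assays) and field
    conventions elsewhere (NB dispersion 0.1, GC bias 0.55, CT sd 0.15).
    """

    seed: int = 42
    n_trnas: int = 50
    trna_len_range: tuple[int, int] = (70, 90)
    frag_len: int = 22
    planted_site: PlantedSite = field(default_factory=PlantedSite)
    utr_len: int = 300
    gc_bias: float = 0.55
    n_genes: int = 2000
    n_samples_per_group: int = 6
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    pathway_size: int = 30
    pathway_shift: float = -1.5  # log2 units, applied to the planted pathway
    dose_presets: Mapping[str, DosePreset] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_PRESETS)
    )

    def __post_init__(self) -> None:
        lo, hi = self.trna_len_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid tRNA length range {self.trna_len_range}")
        if self.frag_len > lo:
            raise ValueError(
                f"frag_len {self.frag_len} exceeds minimum tRNA length {lo}"
            )
        if not (0.0 <= self.de_fraction < 1.0):
            raise ValueError("de_fraction must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name, p in self.dose_presets.items():
            if p.ic50 <= 0 or any(d <= 0 for d in p.doses):
                raise ValueError(f"preset {name}: concentrations must be positive")


def _random_seq(rng: np.random.Generator, length: int, gc_bias: float) -> str:
    p_gc = gc_bias / 2.0
    p_at = (1.0 - gc_bias) / 2.0
    return "".join(rng.choice(list("ACGU"), size=length, p=[p_at, p_gc, p_gc, p_at]))


_ISOTYPES = [
    ("Ala", "AGC"), ("Arg", "ACG"), ("Asn", "GUU"), ("Asp", "GUC"),
    ("Cys", "GCA"), ("Gln", "UUG"), ("Glu", "UUC"), ("Gly", "GCC"),
    ("His", "GUG"), ("Ile", "AAU"), ("Leu", "AAG"), ("Lys", "UUU"),
    ("Met", "CAU"), ("Phe", "GAA"), ("Pro", "AGG"), ("Ser", "AGA"),
    ("Thr", "AGU"), ("Trp", "CCA"), ("Tyr", "GUA"), ("Val", "AAC"),
]


def generate_trna_library(cfg: SimConfig) -> list[SeqRecordLike]:
    """Uniform-random tRNA-like sequences with isotype-flavored ids."""
    rng = rng_for(cfg.seed, "trna")
    lo, hi = cfg.trna_len_range
    records = []
    for k in range(cfg.n_trnas):
        aa, anticodon = _ISOTYPES[k % len(_ISOTYPES)]
        length = int(rng.integers(lo, hi + 1))
        records.append(
            SeqRecordLike(
                id=f"tRNA-{aa}-{anticodon}-like-{k + 1:03d}",
                sequence=_random_seq(rng, length, cfg.gc_bias),
            )
        )
    return records


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def plant_target_site(cfg: SimConfig, trf_sequence: str) -> tuple[SeqRecordLike, tuple[int, int]]:
    """Embed a (possibly imperfect) binding site for `trf_sequence` in a UTR.

    The site is the reverse complement of the tRF with exactly
    ``planted_site.mismatches`` non-pairing substitutions and
    ``planted_site.gu_wobbles`` positions converted to G·U pairs, placed at
    ``planted_site.utr_offset``.  Returns the UTR record and the site's
    1-based inclusive coordinates.
    """
    ps = cfg.planted_site
    L = len(trf_sequence)
    if L != cfg.frag_len:
        raise ValueError(f"tRF length {L} != configured frag_len {cfg.frag_len}")
    if ps.mismatches + ps.gu_wobbles >= L:
        raise ValueError("mismatches + gu_wobbles must be < fragment length")
    if ps.utr_offset < 0 or ps.utr_offset + L > cfg.utr_len:
        raise ValueError(
            f"planted site [{ps.utr_offset}, {ps.utr_offset + L}) outside UTR of {cfg.utr_len} nt"
        )

    rng = rng_for(cfg.seed, "utr")
    site = list(reverse_complement(trf_sequence))
    # site position k (0-based, 5'->3' on the UTR) pairs tRF position L-1-k
    wobble_eligible = [k for k in range(L) if trf_sequence[L - 1 - k] in "GU"]
    if ps.gu_wobbles > len(wobble_eligible):
        raise ValueError(
            f"only {len(wobble_eligible)} positions can form G·U wobbles; "
            f"{ps.gu_wobbles} requested"
        )
    wob = sorted(rng.choice(wobble_eligible, size=ps.gu_wobbles, replace=False).tolist())
    remaining = [k for k in range(L) if k not in set(wob)]
    mis = sorted(rng.choice(remaining, size=ps.mismatches, replace=False).tolist())

    for k in wob:
        trf_base = trf_sequence[L - 1 - k]
        site[k] = "U" if trf_base == "G" else "G"  # G·U or U·G pair
    for k in mis:
        trf_base = trf_sequence[L - 1 - k]
        forbidden = {_COMPLEMENT[trf_base], trf_base}
        if trf_base == "G":
            forbidden.add("U")
        if trf_base == "U":
            forbidden.add("G")
        choices = sorted(set("ACGU") - forbidden)
        site[k] = str(rng.choice(choices))

    utr = list(_random_seq(rng, cfg.utr_len, cfg.gc_bias))
    utr[ps.utr_offset : ps.utr_offset + L] = site
    record = SeqRecordLike(id="UTR3-NUCKS1-like", sequence="".join(utr))
    return record, (ps.utr_offset + 1, ps.utr_offset + L)


def generate_counts(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Two-group negative-binomial count matrix with planted DE genes.

    Returns ``(counts, truth, gene_lengths, gene_sets)``:

    * counts — genes x samples (control_1.. then treated_1..);
    * truth — every planted gene with its direction and log2 shift;
    * gene_lengths — nt, for TPM normalization;
    * gene_sets — the planted down-shifted "PI3K-Akt-like" pathway plus a
      same-size unshifted control set, GMT-writable.
    """
    if cfg.n_samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = rng_for(cfg.seed, "counts")
    G, S = cfg.n_genes, cfg.n_samples_per_group
    genes = [f"GENE{i + 1:05d}" for i in range(G)]
    samples = [f"control_{k + 1}" for k in range(S)] + [f"treated_{k + 1}" for k in range(S)]

    base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=G)
    gene_lengths = pd.Series(rng.integers(500, 3001, size=G), index=genes, name="length_nt")

    # planted pathway genes are disjoint from the +/- de_log2fc DE genes
    perm = rng.permutation(G)
    pathway_idx = perm[: cfg.pathway_size]
    n_de = int(round(cfg.de_fraction * G))
    de_idx = perm[cfg.pathway_size : cfg.pathway_size + n_de]
    control_set_idx = perm[cfg.pathway_size + n_de : 2 * cfg.pathway_size + n_de]
    de_sign = rng.choice([-1.0, 1.0], size=n_de)

    shift = np.zeros(G)
    shift[pathway_idx] = cfg.pathway_shift
    shift[de_idx] = de_sign * cfg.de_log2fc

    mu_control = base_mean
    mu_treated = base_mean * np.power(2.0, shift)

    n_param = 1.0 / cfg.nb_dispersion  # NB: var = mu + dispersion * mu^2

    def _draw(mu: np.ndarray, n_samples: int) -> np.ndarray:
        p = n_param / (n_param + mu)
        return rng.negative_binomial(n_param, p[:, None], size=(G, n_samples))

    counts = pd.DataFrame(
        np.hstack([_draw(mu_control, S), _draw(mu_treated, S)]),
        index=genes,
        columns=samples,
    )

    truth_rows = [
        {"gene_id": genes[i], "log2fc_planted": float(shift[i]),
         "direction": "up" if shift[i] > 0 else "down",
         "source": "pathway" if i in set(pathway_idx) else "de"}
        for i in sorted(set(pathway_idx) | set(de_idx))
        if shift[i] != 0.0
    ]
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "log2fc_planted", "direction", "source"])

    gene_sets = {
        "PI3K_AKT_LIKE": [genes[i] for i in sorted(pathway_idx)],
        "UNSHIFTED_CONTROL_SET": [genes[i] for i in sorted(control_set_idx)],
    }
    return counts, truth, gene_lengths, gene_sets


def four_pl(dose: np.ndarray | float, top: float, bottom: float, ic50: float, hill: float):
    """4-parameter logistic viability curve, decreasing in dose for hill > 0."""
    return bottom + (top - bottom) / (1.0 + np.power(np.asarray(dose, dtype=float) / ic50, hill))


def generate_dose_response(preset: str, cfg: SimConfig) -> pd.DataFrame:
    """Viability table (dose_nM, replicate, viability_pct) for a named preset.

    Points are drawn from the preset's 4PL curve with multiplicative
    log-normal noise of the stated CV (cv = 0 gives exact curve values).
    The noise stream is seeded per preset name, so different presets from
    one config are independent but each is reproducible.
    """
    try:
        p = cfg.dose_presets[preset]
    except KeyError:
        raise KeyError(
            f"unknown dose-response preset {preset!r}; available: {sorted(cfg.dose_presets)}"
        ) from None
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(_STREAMS["dose"], _preset_key(preset)))
    )
    rows = []
    for dose in p.doses:
        y0 = float(four_pl(dose, p.top, p.bottom, p.ic50, p.hill))
        for rep in range(1, p.replicates + 1):
            if p.cv > 0:
                sigma = float(np.sqrt(np.log1p(p.cv**2)))
                noise = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
            else:
                noise = 1.0
            rows.append({"dose_nM": dose, "replicate": rep, "viability_pct": y0 * noise})
    return pd.DataFrame(rows)


def _preset_key(name: str) -> int:
    # stable small-int hash of the preset name (zlib.crc32 & 0x7fffffff)
    import zlib

    return zlib.crc32(name.encode()) & 0x7FFFFFFF


def generate_qpcr_ct(
    cfg: SimConfig,
    planted_ddct: float = 2.0,
    replicates: int = 3,
    ct_sd: float = 0.15,
    ct_ref: float = 18.0,
    ct_target_control: float = 24.0,
) -> pd.DataFrame:
    """CT table (group, replicate, gene, ct) with a planted ΔΔCT.

    The reference gene (GAPDH-like) sits at the same CT in both groups; the
    target gene is shifted by `planted_ddct` cycles in the treated group, so
    downstream relative quantification yields ``2^-planted_ddct``.
    ``ct_sd = 0`` produces noise-free CTs.
    """
    rng = rng_for(cfg.seed, "qpcr")
    rows = []
    means = {
        ("control", "reference"): ct_ref,
        ("treated", "reference"): ct_ref,
        ("control", "target"): ct_target_control,
        ("treated", "target"): ct_target_control + planted_ddct,
    }
    for group in ("control", "treated"):
        for gene in ("target", "reference"):
            for rep in range(1, replicates + 1):
                noise = float(rng.normal(0.0, ct_sd)) if ct_sd > 0 else 0.0
                rows.append(
                    {"group": group, "replicate": rep, "gene": gene,
                     "ct": means[(group, gene)] + noise}
                )
    return pd.DataFrame(rows)


def generate_tumor_growth(
    cfg: SimConfig,
    multiplier: float = 0.5,
    n_mice: int = 6,
    days: Sequence[int] = (0, 3, 6, 9, 12, 15, 18, 21),
    v0_mm3: float = 50.0,
    growth_rate: float = 0.12,
    cv: float = 0.15,
    aspect: float = 1.3,
) -> pd.DataFrame:
    """Caliper table (group, mouse, day, width_mm, length_mm).

    Control tumors grow exponentially from ``v0_mm3``; the treated group's
    rate is reduced so the expected final treated/control volume ratio
    equals `multiplier`.  Volumes get multiplicative log-normal noise (CV),
    then are converted to width/length via ``V = width^2 * length / 2`` with
    a fixed length/width aspect.
    """
    if v0_mm3 <= 0 or multiplier <= 0:
        raise ValueError("volumes and multipliers must be positive")
    rng = rng_for(cfg.seed, "tumor")
    t_end = float(days[-1])
    r_treated = growth_rate + np.log(multiplier) / t_end
    sigma = float(np.sqrt(np.log1p(cv**2))) if cv > 0 else 0.0
    rows = []
    for group, rate in (("control", growth_rate), ("treated", r_treated)):
        for mouse in range(1, n_mice + 1):
            for day in days:
                v = v0_mm3 * float(np.exp(rate * day))
                if sigma > 0:
                    v *= float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
                width = (2.0 * v / aspect) ** (1.0 / 3.0)
                rows.append(
                    {"group": group, "mouse": mouse, "day": day,
                     "width_mm": width, "length_mm": aspect * width}
                )
    return pd.DataFrame(rows)


def generate_wound_areas(
    cfg: SimConfig,
    conditions: Mapping[str, float] | None = None,
    area_t0: float = 100.0,
    replicates: int = 3,
    sd_pct: float = 3.0,
) -> pd.DataFrame:
    """Scratch areas (condition, replicate, area_t0, area_t) from WHR presets.

    ``area_t = area_t0 * (1 - WHR/100)`` plus Gaussian noise of `sd_pct`
    (percent of the initial area) on the later time point.
    """
    conditions = dict(WOUND_PRESETS if conditions is None else conditions)
    rng = rng_for(cfg.seed, "wound")
    rows = []
    for cond, whr in conditions.items():
        for rep in range(1, replicates + 1):
            noise = float(rng.normal(0.0, sd_pct)) if sd_pct > 0 else 0.0
            area_t = area_t0 * (1.0 - whr / 100.0) + noise * area_t0 / 100.0
            rows.append(
                {"condition": cond, "replicate": rep,
                 "area_t0": area_t0, "area_t": max(area_t, 0.0)}
            )
    return pd.DataFrame(rows)


def generate_caspase_activity(
    cfg: SimConfig,
    fold: float = 2.0,
    control_signal: float = 1.0,
    replicates: int = 3,
    cv: float = 0.1,
) -> pd.DataFrame:
    """Caspase-3 ELISA-style signals with a planted treated/control fold."""
    rng = rng_for(cfg.seed, "caspase")
    sigma = float(np.sqrt(np.log1p(cv**2))) if cv > 0 else 0.0
    rows = []
    for group, mean in (("control", control_signal), ("treated", control_signal * fold)):
        for rep in range(1, replicates + 1):
            noise = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)) if sigma > 0 else 1.0
            rows.append({"group": group, "replicate": rep, "signal": mean * noise})
    return pd.DataFrame(rows)


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    """Write gene sets in GMT format (set, description, members...)."""
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Write every synthetic input under `outdir`; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    trnas = generate_trna_library(cfg)
    write_fasta(trnas, outdir / "trna_library.fa")
    paths["trna_fasta"] = str(outdir / "trna_library.fa")

    planted = trnas[cfg.planted_site.trf_index].sequence[: cfg.frag_len]
    utr, (start, end) = plant_target_site(cfg, planted)
    write_fasta([utr], outdir / "target_utr.fa")
    paths["utr_fasta"] = str(outdir / "target_utr.fa")
    pd.DataFrame(
        [{"utr_id": utr.id, "site_start": start, "site_end": end,
          "planted_trf": trnas[cfg.planted_site.trf_index].id}]
    ).to_csv(outdir / "planted_site.tsv", sep="\t", index=False)
    paths["planted_site"] = str(outdir / "planted_site.tsv")

    counts, truth, lengths, gene_sets = generate_counts(cfg)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    truth.to_csv(outdir / "de_truth.tsv", sep="\t", index=False)
    lengths.to_csv(outdir / "gene_lengths.tsv", sep="\t")
    write_gmt(gene_sets, outdir / "gene_sets.gmt")
    paths.update(
        counts=str(outdir / "counts.tsv"),
        de_truth=str(outdir / "de_truth.tsv"),
        gene_lengths=str(outdir / "gene_lengths.tsv"),
        gmt=str(outdir / "gene_sets.gmt"),
    )

    for preset in cfg.dose_presets:
        df = generate_dose_response(preset, cfg)
        p = outdir / f"dose_response_{preset}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"dose_{preset}"] = str(p)

    generate_qpcr_ct(cfg).to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    generate_tumor_growth(cfg).to_csv(outdir / "tumor_growth.tsv", sep="\t", index=False)
    generate_wound_areas(cfg).to_csv(outdir / "wound_areas.tsv", sep="\t", index=False)
    generate_caspase_activity(cfg).to_csv(outdir / "caspase.tsv", sep="\t", index=False)
    paths.update(
        qpcr=str(outdir / "qpcr_ct.tsv"),
        tumor=str(outdir / "tumor_growth.tsv"),
        wound=str(outdir / "wound_areas.tsv"),
        caspase=str(outdir / "caspase.tsv"),
    )
    return paths


def config_with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Convenience: same stated world, different seed."""
    return replace(cfg, seed=seed)
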