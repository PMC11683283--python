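"""Synthetic-data generators: determinism, contracts, planted structure."""

import numpy as np
import pandas as pd
import pytest

from trfscreen.duplex import duplex_mfe, pair_allowed
from trfscreen.library import write_fasta
from trfscreen.simulate import (
    PlantedSite,
    SimConfig,
    generate_caspase_activity,
    generate_counts,
    generate_dose_response,
    generate_qpcr_ct,
    generate_trna_library,
    generate_tumor_growth,
    generate_wound_areas,
    plant_target_site,
    reverse_complement,
)


class TestConfigValidation:
    def test_invalid_length_range(self):
        with pytest.raises(ValueError):
            SimConfig(trna_len_range=(90, 70))

    def test_frag_longer_than_min_trna(self):
        with pytest.raises(ValueError):
            SimConfig(frag_len=80, trna_len_range=(70, 90))

    def test_frag22_min70_ok(self):
        SimConfig(frag_len=22, trna_len_range=(70, 90))  # no error

    def test_de_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(de_fraction=1.5)

    def test_dispersion_positive(self):
        with pytest.raises(ValueError):
            SimConfig(nb_dispersion=0.0)


class TestTrnaLibrary:
    def test_same_seed_identical_fasta_bytes(self, tmp_path, cfg):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(generate_trna_library(cfg), p1)
        write_fasta(generate_trna_library(SimConfig(seed=cfg.seed)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_counts_and_length_range(self):
        cfg = SimConfig(n_trnas=50, trna_len_range=(70, 90))
        recs = generate_trna_library(cfg)
        assert len(recs) == 50
        assert all(70 <= len(r) <= 90 for r in recs)
        assert all(set(r.sequence) <= set("ACGU") for r in recs)

    def test_isotype_like_ids(self, cfg):
        recs = generate_trna_library(cfg)
        assert all(r.id.startswith("tRNA-") for r in recs)
        assert len({r.id for r in recs}) == len(recs)

    def test_different_seeds_differ(self, cfg):
        a = generate_trna_library(cfg)
        b = generate_trna_library(SimConfig(seed=cfg.seed + 1))
        assert any(x.sequence != y.sequence for x, y in zip(a, b))


class TestPlantTargetSite:
    def _trf(self, seed=0, length=22):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGU"), length))

    def test_perfect_site_is_reverse_complement(self, model):
        cfg = SimConfig()
        trf = self._trf()
        utr, (start, end) = plant_target_site(cfg, trf)
        site = utr.sequence[start - 1 : end]
        assert site == reverse_complement(trf)
        r = duplex_mfe(trf, site, model)
        assert r.comp_rate == 100.0

    @pytest.mark.parametrize("mism,wob", [(2, 0), (0, 3), (3, 2), (6, 0)])
    def test_planted_positions_pair_as_stated(self, mism, wob):
        cfg = SimConfig(planted_site=PlantedSite(mismatches=mism, gu_wobbles=wob))
        trf = self._trf(seed=4)
        utr, (start, end) = plant_target_site(cfg, trf)
        site = utr.sequence[start - 1 : end]
        L = len(trf)
        wc = sum(site[k] == reverse_complement(trf)[k] for k in range(L))
        pairable = sum(pair_allowed(trf[L - 1 - k], site[k]) for k in range(L))
        assert wc == L - mism - wob
        assert pairable == L - mism

    def test_six_mismatches_cap_comp_rate(self, model):
        # 6 mismatches on a 22-mer leave at most 16/22 = 72.7 % pairable
        cfg = SimConfig(planted_site=PlantedSite(mismatches=6))
        trf = self._trf(seed=8)
        utr, (start, end) = plant_target_site(cfg, trf)
        r = duplex_mfe(trf, utr.sequence[start - 1 : end], model)
        assert r.comp_rate <= 72.7

    def test_offset_bounds_error(self):
        cfg = SimConfig(utr_len=100, planted_site=PlantedSite(utr_offset=90))
        with pytest.raises(ValueError):
            plant_target_site(cfg, self._trf())

    def test_wrong_trf_length_rejected(self):
        with pytest.raises(ValueError):
            plant_target_site(SimConfig(), self._trf(length=20))


class TestGenerateCounts:
    def test_zero_de_fraction_empty_truth(self):
        cfg = SimConfig(de_fraction=0.0, pathway_shift=0.0, n_genes=200)
        _, truth, _, _ = generate_counts(cfg)
        assert truth.empty

    def test_same_seed_identical_matrix(self, cfg):
        a, _, _, _ = generate_counts(cfg)
        b, _, _, _ = generate_counts(SimConfig(seed=cfg.seed))
        pd.testing.assert_frame_equal(a, b)

    def test_planted_log2fc_recovered_at_n20(self):
        # Monte-Carlo check of the generator: empirical log2 ratio of group
        # means within +/-0.3 of the planted value at n=20 per group
        cfg = SimConfig(n_samples_per_group=20, de_log2fc=2.0, n_genes=500)
        counts, truth, _, _ = generate_counts(cfg)
        treated = [c for c in counts.columns if c.startswith("treated")]
        control = [c for c in counts.columns if c.startswith("control")]
        de = truth[truth.source == "de"]
        ratios = np.log2(
            (counts.loc[de.gene_id, treated].mean(axis=1) + 0.5)
            / (counts.loc[de.gene_id, control].mean(axis=1) + 0.5)
        )
        err = ratios.to_numpy() - de.log2fc_planted.to_numpy()
        assert np.median(np.abs(err)) < 0.3

    def test_pathway_disjoint_from_de_and_shifted_down(self):
        cfg = SimConfig(n_genes=500)
        _, truth, _, sets = generate_counts(cfg)
        pathway = set(sets["PI3K_AKT_LIKE"])
        assert len(pathway) == cfg.pathway_size
        pw_rows = truth[truth.gene_id.isin(pathway)]
        assert (pw_rows.direction == "down").all()
        assert (pw_rows.source == "pathway").all()
        assert not (set(truth[truth.source == "de"].gene_id) & pathway)


class TestDoseResponse:
    def test_cv_zero_points_on_curve(self):
        from trfscreen.simulate import DosePreset, four_pl

        cfg = SimConfig(dose_presets={"exact": DosePreset(ic50=50.0, cv=0.0)})
        df = generate_dose_response("exact", cfg)

        expected = four_pl(df["dose_nM"].to_numpy(), 100.0, 0.0, 50.0, 1.0)
        assert np.allclose(df["viability_pct"], expected, atol=0)

    def test_midpoint_at_ic50(self):
        from trfscreen.simulate import DosePreset

        cfg = SimConfig(dose_presets={"mid": DosePreset(ic50=50.0, cv=0.0, doses=(50.0, 1.0, 10.0, 100.0))})
        df = generate_dose_response("mid", cfg)
        mid = df[df.dose_nM == 50.0]["viability_pct"].iloc[0]
        assert mid == pytest.approx(50.0)  # (top + bottom) / 2

    def test_unknown_preset(self, cfg):
        with pytest.raises(KeyError):
            generate_dose_response("nope", cfg)

    def test_deterministic_and_mean_preserving(self, cfg):
        a = generate_dose_response("hct8_trf36", cfg)
        b = generate_dose_response("hct8_trf36", SimConfig(seed=cfg.seed))
        pd.testing.assert_frame_equal(a, b)
        # multiplicative log-normal noise is mean-1: high-dose tail small
        assert a["viability_pct"].min() >= 0.0


class TestQpcrAndGrowthGenerators:
    def test_zero_noise_ct_gives_planted_fold(self, cfg):
        from trfscreen.assays import ddct_fold

        df = generate_qpcr_ct(cfg, planted_ddct=1.0, ct_sd=0.0)

        def cts(group, gene):
            return df[(df.group == group) & (df.gene == gene)]["ct"].to_numpy()

        res = ddct_fold(cts("treated", "target"), cts("treated", "reference"),
                        cts("control", "target"), cts("control", "reference"))
        assert res.fold == pytest.approx(0.5)

    def test_tumor_multiplier_final_ratio(self, cfg):
        # Monte-Carlo: average final treated/control volume ratio near 0.5
        from trfscreen.assays import growth_summary

        ratios = [
            growth_summary(generate_tumor_growth(SimConfig(seed=s), multiplier=0.5, n_mice=8))[
                "final_volume_ratio"
            ]
            for s in range(1, 9)
        ]
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.07)

    def test_tables_deterministic(self, cfg):
        for gen in (generate_qpcr_ct, generate_tumor_growth, generate_wound_areas,
                    generate_caspase_activity):
            pd.testing.assert_frame_equal(gen(cfg), gen(SimConfig(seed=cfg.seed)))

    def test_negative_dimensions_rejected(self, cfg):
        with pytest.raises(ValueError):
            generate_tumor_growth(cfg, v0_mm3=-5.0)

    def test_wound_presets_preserve_ordering(self, cfg):
        # treated wells close slower than the liposomal control
        from trfscreen.assays import wound_healing_rate

        df = generate_wound_areas(cfg)
        whr = {
            cond: np.mean([wound_healing_rate(r.area_t0, r.area_t)
                           for r in sub.itertuples()])
            for cond, sub in df.groupby("condition")
        }
        assert whr["hct8_trf36_10nM"] < whr["hct8_trf36_5nM"] < whr["hct8_control"]
        assert whr["lovo_trf36_20nM"] < whr["lovo_control"]

    def test_caspase_planted_fold(self):
        from trfscreen.assays import fold_activity

        df = generate_caspase_activity(SimConfig(seed=5), fold=2.0, replicates=50)
        t = df[df.group == "treated"].signal.mean()
        c = df[df.group == "control"].signal.mean()
        assert fold_activity(t, c) == pytest.approx(2.0, rel=0.1)
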