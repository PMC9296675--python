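"""Generator contracts: determinism, planted-quantity bookkeeping, and the
statistical shape of the simulated cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pimohet import sigscore as ss
from pimohet.config import (
    ExpressionModelConfig,
    HypoxiaFieldConfig,
    SimulationConfig,
    StainModelConfig,
    SurvivalModelConfig,
)
from pimohet.errors import ConfigurationError, GeometryError
from pimohet.synthgen import (
    generate_cohort,
    generate_truth,
    render_sections,
    simulate_expression,
    simulate_outcomes,
)


class TestConfigValidation:
    def test_bad_fields_named_in_error(self):
        with pytest.raises(ConfigurationError, match="n_patients"):
            SimulationConfig(n_patients=0).validate()
        with pytest.raises(ConfigurationError, match="target_median_hf"):
            SimulationConfig(hypoxia_field=HypoxiaFieldConfig(target_median_hf=1.5)).validate()
        with pytest.raises(ConfigurationError, match="n_signature_genes"):
            SimulationConfig(
                expression_model=ExpressionModelConfig(n_genes=10, n_signature_genes=32)
            ).validate()
        with pytest.raises(ConfigurationError, match="baseline_rate"):
            SimulationConfig(survival_model=SurvivalModelConfig(baseline_rate=0.0)).validate()

    def test_biopsy_must_fit_lesion(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(pixel_size_um=40.0).validate()  # 75 px punch radius


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        cfg = SimulationConfig(n_patients=4, seed=3)
        a = generate_cohort(cfg)
        b = generate_cohort(SimulationConfig(n_patients=4, seed=3))
        assert a.content_hash() == b.content_hash()

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(n_patients=4, seed=3))
        b = generate_cohort(SimulationConfig(n_patients=4, seed=4))
        assert a.content_hash() != b.content_hash()

    def test_render_sections_standalone_matches_cohort(self, small_cohort):
        rec = small_cohort.truth[3]
        images = render_sections(rec, small_cohort.config)
        by_id = {img.section_id: img for img in small_cohort.images}
        for img in images:
            np.testing.assert_array_equal(img.pixels, by_id[img.section_id].pixels)


class TestTruth:
    def test_fractions_in_unit_interval(self, small_cohort):
        for rec in small_cohort.truth:
            assert 0.0 <= rec.true_hf_wholemount <= 1.0
            for b in rec.biopsies:
                assert 0.0 <= b.true_hf_biopsy <= 1.0

    def test_order_labels_unique_and_mapped(self, small_cohort):
        seen = set()
        for rec in small_cohort.truth:
            labels = [b.order_label for b in rec.biopsies]
            assert len(labels) == len(set(labels))
            for b in rec.biopsies:
                assert b.biopsy_id not in seen
                seen.add(b.biopsy_id)
                assert b.biopsy_id.startswith(rec.patient_id)

    def test_fraction_paired_respected(self):
        truths = generate_truth(SimulationConfig(n_patients=20, fraction_paired=0.5, seed=1))
        n_paired = sum(1 for t in truths if len(t.biopsies) == 2)
        assert n_paired == 10

    def test_target_median_hf_recovered(self):
        """Monte-Carlo check of the generator against its own parameter."""
        truths = generate_truth(SimulationConfig(n_patients=200, seed=17))
        median = np.median([t.true_hf_wholemount for t in truths])
        assert median == pytest.approx(0.27, abs=0.05)

    def test_homogeneous_field_biopsies_match_wholemount(self):
        truths = generate_truth(
            SimulationConfig(
                n_patients=20, fraction_paired=1.0, seed=2,
                hypoxia_field=HypoxiaFieldConfig(within_lesion_sd=0.0),
            )
        )
        for t in truths:
            for b in t.biopsies:
                assert b.true_hf_biopsy == pytest.approx(t.true_hf_wholemount, abs=0.02)

    def test_geometry_error_when_punch_cannot_fit(self):
        from pimohet.synthgen import _place_biopsies

        rng = np.random.default_rng(0)
        with pytest.raises(GeometryError):
            _place_biopsies(rng, (50.0, 50.0), lesion_radius=10.0, biopsy_radius=15.0, n_biopsies=1)


class TestRenderedSections:
    def test_biopsy_footprints_inside_lesion(self, small_cohort):
        for rec in small_cohort.truth:
            for b in rec.biopsies:
                dist = np.hypot(
                    b.center_px[0] - rec.lesion_center_px[0],
                    b.center_px[1] - rec.lesion_center_px[1],
                )
                assert dist + small_cohort.config.biopsy_radius_px <= rec.lesion_radius_px + 1e-9

    def test_planted_fraction_matches_noiseless_quantification(self):
        """With zero stain noise the fraction of lesion pixels above the
        generating threshold equals the recorded whole-mount HF."""
        from pimohet import histoquant as hq

        cfg = SimulationConfig(
            n_patients=4, seed=9,
            stain_model=StainModelConfig(od_noise_sd=0.0),
        )
        cohort = generate_cohort(cfg)
        thr = hq.HypoxiaThreshold(value=cfg.stain_model.od_threshold, protocol="whole_mount")
        for rec in cohort.truth:
            img = next(i for i in cohort.images if i.section_id == f"{rec.patient_id}-WM")
            m = hq.compute_stain_map(img)
            res = hq.quantify_hf(m, thr, img.lesion_mask, region="lesion")
            assert res.fraction == pytest.approx(rec.true_hf_wholemount, abs=0.01)

    def test_zero_hf_section_has_no_supra_threshold_stain(self):
        from pimohet import histoquant as hq

        cfg = SimulationConfig(n_patients=2, seed=9, stain_model=StainModelConfig(od_noise_sd=0.0))
        truths = generate_truth(cfg)
        truths[0].field_cut = 1e9  # force a fully normoxic lesion
        images = render_sections(truths[0], cfg)
        wm = images[0]
        m = hq.compute_stain_map(wm)
        assert (m.values[wm.lesion_mask] > cfg.stain_model.od_threshold).mean() == 0.0


class TestExpression:
    def test_noiseless_single_probe_model_exact(self):
        cfg = SimulationConfig(
            n_patients=6, fraction_paired=1.0, seed=4,
            expression_model=ExpressionModelConfig(
                n_genes=9, n_signature_genes=3, gene_noise_sd=0.0, kit_offset=0.0,
            ),
        )
        truths = generate_truth(cfg)
        matrix, sheet, signature = simulate_expression(truths, cfg)
        latent = {b.biopsy_id: b.latent_hypoxia for t in truths for b in t.biopsies}
        # single-probe signature gene: value = baseline + effect * latent exactly
        gene = signature.gene_ids[0]
        probe = f"{gene}_p1"
        row = matrix.values.loc[probe]
        effect = cfg.expression_model.effect_size
        baseline = row[sheet["sample_id"].iloc[0]] - effect * latent[sheet["sample_id"].iloc[0]]
        for sid in sheet["sample_id"]:
            assert row[sid] == pytest.approx(baseline + effect * latent[sid])

    def test_planted_kit_offset_recovered(self):
        cfg = SimulationConfig(
            n_patients=30, fraction_paired=1.0, seed=8,
            expression_model=ExpressionModelConfig(n_genes=60, n_signature_genes=5, kit_offset=1.0),
        )
        truths = generate_truth(cfg)
        matrix, sheet, _ = simulate_expression(truths, cfg)
        a = matrix.values.loc[:, (matrix.kit == "A").to_numpy()]
        b = matrix.values.loc[:, (matrix.kit == "B").to_numpy()]
        offsets = a.median(axis=1) - b.median(axis=1)
        assert offsets.mean() == pytest.approx(1.0, abs=0.1)

    def test_lower_noise_probe_has_smaller_iqr(self, tableonly_cohort):
        """Among multi-probe genes with clearly different planted noise
        scales, the lower-noise probe shows the smaller across-sample IQR in
        at least 90% of genes (this is what the IQR probe collapse relies
        on).  Non-signature genes only, so noise is the sole spread."""
        matrix = tableonly_cohort.expression
        info = matrix.probe_info
        iqr = matrix.values.quantile(0.75, axis=1) - matrix.values.quantile(0.25, axis=1)
        sig = set(tableonly_cohort.signature.gene_ids)
        wins = total = 0
        for gene, grp in info.groupby("gene_id"):
            if len(grp) < 2 or gene in sig:
                continue
            scales = grp["noise_scale"]
            lo, hi = scales.idxmin(), scales.idxmax()
            if scales[hi] - scales[lo] < 0.3:
                continue  # too close to call at this sample size
            total += 1
            wins += iqr[lo] < iqr[hi]
        assert total >= 20
        assert wins / total >= 0.9

    def test_signature_probe_correlates_with_latent(self, tableonly_cohort):
        matrix = tableonly_cohort.expression
        sig_gene = tableonly_cohort.signature.gene_ids[0]
        latent = pd.Series(
            {b.biopsy_id: b.latent_hypoxia for t in tableonly_cohort.truth for b in t.biopsies}
        )
        row = matrix.values.loc[f"{sig_gene}_p1"].reindex(latent.index)
        r = stats.pearsonr(row, latent).statistic
        assert r > 0.3

    def test_null_effect_size_gives_null_score(self):
        """With effect_size = 0 the downstream gene score carries no
        information about latent hypoxia (mean correlation ~ 0 over 20
        replicates)."""
        rs = []
        for k in range(20):
            cfg = SimulationConfig(
                n_patients=12, fraction_paired=1.0, seed=600 + k,
                expression_model=ExpressionModelConfig(
                    n_genes=40, n_signature_genes=8, effect_size=0.0
                ),
            )
            truths = generate_truth(cfg)
            matrix, sheet, signature = simulate_expression(truths, cfg)
            genes = ss.collapse_probes(ss.harmonize_kits(matrix))
            score = ss.compute_gene_score(genes, signature).scores
            latent = pd.Series(
                {b.biopsy_id: b.latent_hypoxia for t in truths for b in t.biopsies}
            )
            rs.append(stats.pearsonr(score.reindex(latent.index), latent).statistic)
        t_stat, p = stats.ttest_1samp(rs, 0.0)
        assert p > 0.01


class TestOutcomes:
    def test_no_censoring_all_events(self):
        cfg = SimulationConfig(
            n_patients=30, seed=5,
            survival_model=SurvivalModelConfig(censoring_rate=0.0, max_follow_up=np.inf),
        )
        truths = generate_truth(cfg)
        scores = pd.Series(0.0, index=[t.patient_id for t in truths])
        _, surv = simulate_outcomes(truths, scores, cfg)
        assert (surv["event"] == 1).all()

    def test_null_hazard_gives_uniform_logrank_p(self):
        from pimohet import prognosis as prog

        ps = []
        for k in range(15):
            cfg = SimulationConfig(
                n_patients=60, seed=700 + k,
                survival_model=SurvivalModelConfig(log_hr_per_unit_score=0.0, censoring_rate=0.0),
            )
            truths = generate_truth(cfg)
            rng = np.random.default_rng(k)
            scores = pd.Series(rng.standard_normal(60), index=[t.patient_id for t in truths])
            _, surv = simulate_outcomes(truths, scores, cfg)
            grouping = (scores > scores.median()).map({True: "hi", False: "lo"})
            ps.append(prog.km_logrank(surv, grouping).p)
        assert sum(p < 0.05 for p in ps) <= 3
        assert 0.2 < np.mean(ps) < 0.8

    def test_clinical_marginals_plausible(self, tableonly_cohort):
        clin = tableonly_cohort.clinical
        assert clin["lymph_node"].isin(["pos", "neg"]).all()
        assert clin["isup_group"].between(1, 5).all()
        assert clin["pt_stage"].between(2, 4).all()
        assert (clin["isup_high"] == (clin["isup_group"] >= 3)).all()
        assert (clin["pt_high"] == (clin["pt_stage"] >= 3)).all()

    def test_clinical_markers_track_true_hf(self):
        """Higher true whole-mount HF raises the node-positive probability."""
        cfg = SimulationConfig(n_patients=400, seed=21)
        truths = generate_truth(cfg)
        scores = pd.Series(0.0, index=[t.patient_id for t in truths])
        clin, _ = simulate_outcomes(truths, scores, cfg)
        hf = pd.Series({t.patient_id: t.true_hf_wholemount for t in truths})
        pos = clin["lymph_node_positive"]
        assert hf[pos].mean() > hf[~pos].mean()


class TestCohortAssembly:
    def test_every_expression_sample_has_truth_and_sheet_row(self, small_cohort):
        truth_ids = {b.biopsy_id for t in small_cohort.truth for b in t.biopsies}
        assert set(small_cohort.expression.sample_ids) == truth_ids
        assert set(small_cohort.sample_sheet["sample_id"]) == truth_ids

    def test_every_survival_patient_in_clinical(self, small_cohort):
        assert set(small_cohort.survival.index) <= set(small_cohort.clinical.index)

    def test_every_biopsy_has_an_image(self, small_cohort):
        image_ids = {i.section_id for i in small_cohort.images}
        for t in small_cohort.truth:
            assert f"{t.patient_id}-WM" in image_ids
            for b in t.biopsies:
                assert b.biopsy_id in image_ids

    def test_write_cohort_round_trips_tables(self, small_cohort, tmp_path):
        from pimohet.io import read_expression_tsv, read_sample_sheet
        from pimohet.synthgen import write_cohort

        write_cohort(small_cohort, tmp_path, write_images=False)
        sheet = read_sample_sheet(tmp_path / "samples.csv")
        matrix = read_expression_tsv(tmp_path / "expression.tsv", tmp_path / "probe_map.tsv", sheet)
        np.testing.assert_allclose(
            matrix.values.to_numpy(), small_cohort.expression.values.to_numpy(), rtol=1e-9
        )
        pd.testing.assert_series_equal(
            matrix.probe_map, small_cohort.expression.probe_map, check_names=False
        )
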