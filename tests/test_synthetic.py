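"""Generator contracts: determinism, planted effects, distributional shape."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prebioresponse import synthetic
from prebioresponse.da import nb_wald_test
from prebioresponse.synthetic import PlantedCgcSpec, SimParams


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(n_subjects=0)
        with pytest.raises(ValueError):
            SimParams(timepoints_h=())
        with pytest.raises(ValueError):
            SimParams(nb_dispersion=0.0)
        with pytest.raises(ValueError):
            SimParams(responder_prevalence=1.5)
        with pytest.raises(ValueError):
            SimParams(qpcr_slope=1.0)
        with pytest.raises(ValueError):
            SimParams(delta_ab_responder=0.0, delta_ab_nonresponder=5.0)

    def test_planted_spec_wider_than_contig_rejected(self):
        wide = PlantedCgcSpec("XOS", tuple(["GH43", "TC"] * 20), gap=3)
        with pytest.raises(ValueError, match="wider"):
            SimParams(genes_per_contig=30, planted_cgc_specs=(wide,))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = SimParams(n_subjects=6, n_contigs=5, genes_per_contig=20, seed=42)
        a = synthetic.simulate_cohort(p)
        b = synthetic.simulate_cohort(p)
        for key in ("scfa", "catalog", "counts", "samples", "wells", "standards"):
            assert a[key].to_csv() == b[key].to_csv()
        pd.testing.assert_frame_equal(a["truth"].phenotype, b["truth"].phenotype)

    def test_different_seeds_differ(self):
        a, _ = synthetic.simulate_scfa(SimParams(n_subjects=6, seed=1))
        b, _ = synthetic.simulate_scfa(SimParams(n_subjects=6, seed=2))
        assert not a.equals(b)


class TestScfa:
    def test_grid_is_complete_and_unique(self, small_cohort, small_params):
        scfa = small_cohort["scfa"]
        expected = (
            small_params.n_subjects
            * (len(small_params.substrates) + 1)
            * small_params.replicates
            * len(small_params.timepoints_h)
        )
        assert len(scfa) == expected
        key = ["subject_id", "treatment", "replicate", "timepoint_h"]
        assert not scfa.duplicated(key).any()
        assert (scfa[["acetate_mM", "butyrate_mM", "propionate_mM"]] >= 0).all().all()

    def test_responder_delta_matches_generating_mean(self):
        params = SimParams(n_subjects=40, delta_ab_responder=20.0, seed=1)
        scfa, truth = synthetic.simulate_scfa(params)
        scfa = scfa.assign(ab=scfa["acetate_mM"] + scfa["butyrate_mM"])
        per_arm = scfa.groupby(["subject_id", "treatment"])["ab"].mean()
        deltas = []
        for subject in truth.phenotype.index:
            for sub in params.substrates:
                if truth.phenotype.loc[subject, sub] == "R":
                    deltas.append(
                        per_arm.loc[(subject, sub)] - per_arm.loc[(subject, "NP")]
                    )
        assert np.mean(deltas) == pytest.approx(20.0, abs=1.0)

    def test_no_effect_symmetry(self):
        """With zero deltas everywhere, R and NR deltas are indistinguishable."""
        deltas_r, deltas_nr = [], []
        for seed in range(12):
            params = SimParams(
                n_subjects=10, delta_ab_responder=0.0, delta_ab_nonresponder=0.0,
                seed=seed,
            )
            scfa, truth = synthetic.simulate_scfa(params)
            scfa = scfa.assign(ab=scfa["acetate_mM"] + scfa["butyrate_mM"])
            per_arm = scfa.groupby(["subject_id", "treatment"])["ab"].mean()
            for subject in truth.phenotype.index:
                for sub in params.substrates:
                    d = per_arm.loc[(subject, sub)] - per_arm.loc[(subject, "NP")]
                    (deltas_r if truth.phenotype.loc[subject, sub] == "R"
                     else deltas_nr).append(d)
        assert stats.ks_2samp(deltas_r, deltas_nr).pvalue > 0.01

    def test_ph_and_fermentation_correlation_signs(self, default_cohort):
        scfa = default_cohort["scfa"]
        ab = scfa["acetate_mM"] + scfa["butyrate_mM"]
        assert stats.spearmanr(ab, scfa["pH"])[0] < -0.5
        assert stats.spearmanr(ab, scfa["pct_fermented"])[0] > 0.5


class TestCatalog:
    def test_coordinates_sorted_and_disjoint(self, small_cohort):
        cat = small_cohort["catalog"]
        assert (cat["start_bp"] <= cat["end_bp"]).all()
        for _, grp in cat.groupby("contig_id"):
            starts, ends = grp["start_bp"].to_numpy(), grp["end_bp"].to_numpy()
            assert np.all(np.diff(starts) > 0)
            assert np.all(starts[1:] > ends[:-1])
            assert np.all(np.diff(grp["order_index"]) == 1)

    def test_planted_layout_emitted(self, small_cohort):
        cat = small_cohort["catalog"].set_index("gene_id")
        truth = small_cohort["truth"]
        for planted in truth.planted_cgcs:
            sigs = cat.loc[planted["target_gene_ids"], "signature"]
            assert (sigs != "NONE").all()
            assert (sigs == "CAZYME").sum() >= 1 and (sigs == "TC").sum() >= 1

    def test_planted_genes_unique_and_present(self, small_cohort):
        cat_ids = set(small_cohort["catalog"]["gene_id"])
        truth = small_cohort["truth"]
        all_planted = [g for gids in truth.planted_genes.values() for g in gids]
        assert len(all_planted) == len(set(all_planted))
        assert set(all_planted) <= cat_ids
        assert set(truth.decoy_genes) <= cat_ids

    def test_zero_planted_specs_flag_nothing(self):
        params = SimParams(n_subjects=4, n_contigs=4, genes_per_contig=15,
                           planted_cgc_specs=(), n_decoy_targets=2, seed=5)
        _, truth = synthetic.simulate_gene_catalog(params)
        assert all(not g for g in truth.planted_genes.values())

    def test_decoy_cazymes_carry_blacklisted_names(self, default_cohort):
        from prebioresponse.cgc import EC_NAME_BLACKLIST

        cat = default_cohort["catalog"]
        cazymes = cat[cat["signature"] == "CAZYME"]
        assert cazymes["ec_names"].isin(set(EC_NAME_BLACKLIST)).any()


class TestCounts:
    def test_poisson_limit_of_dispersion(self):
        # fixed depth and no planted fold change isolate the count noise:
        # as dispersion -> 0 the per-gene variance/mean ratio -> 1
        params = SimParams(n_subjects=30, n_contigs=6, genes_per_contig=30,
                           nb_dispersion=1e-9, planted_log2fc=0.0,
                           count_depth_range=(1.0, 1.0), seed=2)
        cohort_cat, truth = synthetic.simulate_gene_catalog(params)
        counts, _ = synthetic.simulate_counts(cohort_cat, truth, params)
        mat = counts.to_numpy(dtype=float)  # 180 genes x 90 samples
        ratio = mat.var(axis=1, ddof=1) / np.maximum(mat.mean(axis=1), 1e-9)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)
        over = SimParams(**{**params.__dict__, "nb_dispersion": 0.5})
        counts_over, _ = synthetic.simulate_counts(cohort_cat, truth, over)
        mat_o = counts_over.to_numpy(dtype=float)
        ratio_o = mat_o.var(axis=1, ddof=1) / np.maximum(mat_o.mean(axis=1), 1e-9)
        assert np.median(ratio_o) > 3.0

    def test_planted_fold_change_recovered_by_estimator(self, default_cohort):
        truth = default_cohort["truth"]
        counts, meta = default_cohort["counts"], default_cohort["samples"]
        lfcs = []
        for sub in ("FOS", "INU", "XOS"):
            meta_s = meta[meta["substrate"] == sub]
            labels = truth.phenotype.loc[meta_s["subject_id"], sub].to_numpy()
            res = nb_wald_test(counts[meta_s["sample_id"]], list(labels))
            lfcs.extend(res.loc[truth.planted_genes[sub], "log2fc"].tolist())
        assert np.median(lfcs) == pytest.approx(2.0, abs=0.3)

    def test_null_fold_change_rejects_at_nominal_rate(self):
        params = SimParams(n_subjects=30, n_contigs=6, genes_per_contig=30,
                           planted_log2fc=0.0, seed=9)
        cat, truth = synthetic.simulate_gene_catalog(params)
        counts, meta = synthetic.simulate_counts(cat, truth, params)
        meta_s = meta[meta["substrate"] == "XOS"]
        labels = truth.phenotype.loc[meta_s["subject_id"], "XOS"].to_numpy()
        res = nb_wald_test(counts[meta_s["sample_id"]], list(labels))
        ok = res["status"] == "ok"
        assert (res.loc[ok, "p"] < 0.05).mean() == pytest.approx(0.05, abs=0.03)


class TestQpcr:
    def test_all_nonresponder_wells_nondetect_at_zero_detect_prob(self):
        params = SimParams(n_subjects=10, n_contigs=5, genes_per_contig=25,
                           nonresponder_detect_prob=0.0, n_decoy_targets=0, seed=3)
        _, truth = synthetic.simulate_gene_catalog(params)
        copies, wells, _ = synthetic.simulate_qpcr(truth, params)
        gene_sub = {g: s for s, gs in truth.planted_genes.items() for g in gs}
        for _, w in wells.iterrows():
            sub = gene_sub[w["target_gene"]]
            if truth.phenotype.loc[w["sample_id"], sub] == "NR":
                assert np.isnan(w["ct"])

    def test_noiseless_roundtrip_recovers_planted_copies(self):
        from prebioresponse.pipeline import quantify_copy_numbers

        params = SimParams(n_subjects=6, n_contigs=5, genes_per_contig=25,
                           qpcr_ct_sd=0.0, seed=4)
        _, truth = synthetic.simulate_gene_catalog(params)
        copies, wells, standards = synthetic.simulate_qpcr(truth, params)
        est = quantify_copy_numbers(wells, standards)
        est = est.loc[copies.index, copies.columns]
        np.testing.assert_allclose(est.to_numpy(), copies.to_numpy(), rtol=1e-9)

    def test_responder_copies_centre_on_mu(self):
        params = SimParams(seed=7)
        _, truth = synthetic.simulate_gene_catalog(params)
        copies, _, _ = synthetic.simulate_qpcr(truth, params)
        logs = []
        gene_sub = {g: s for s, gs in truth.planted_genes.items() for g in gs}
        for g, sub in gene_sub.items():
            r_subj = truth.phenotype.index[truth.phenotype[sub] == "R"]
            logs.extend(np.log10(copies.loc[r_subj, g]))
        se = params.qpcr_sd / np.sqrt(len(logs))
        assert np.mean(logs) == pytest.approx(params.qpcr_mu_log10_responder,
                                              abs=3 * se)
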