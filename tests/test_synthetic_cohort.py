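"""Simulator: Balding–Nichols moments, HWE carriers, database sampling,
determinism, truth bookkeeping, and object-vs-vectorized equivalence.

Monte-Carlo checks compare sample moments against closed forms with bounds
a few standard errors wide; all draws are seeded.
"""

import numpy as np
import pytest

from tmburden.somatic_filtering import CANONICAL_CRITERIA
from tmburden.synthetic_cohort import (
    SimulationConfig,
    balding_nichols,
    build_public_db,
    draw_db_counts,
    draw_site_panel,
    simulate_cohort,
    simulate_cohort_tmb,
    simulate_patient,
)
from tmburden.tmb_calculator import cohort_tmb
from tmburden.variant_core import ConfigError


class TestBaldingNichols:
    def test_moments_match_closed_form(self):
        """E[p_k] = p, Var[p_k] = F p (1-p), by Monte Carlo at fixed p."""
        rng = np.random.default_rng(5)
        p_anc, fst, n = 0.3, 0.2, 10_000
        draws = balding_nichols(np.full(n, p_anc), fst, rng)
        se_mean = np.sqrt(fst * p_anc * (1 - p_anc) / n)
        assert draws.mean() == pytest.approx(p_anc, abs=4 * se_mean)
        assert draws.var() == pytest.approx(fst * p_anc * (1 - p_anc),
                                            rel=0.1)

    def test_fst_zero_is_point_mass(self):
        rng = np.random.default_rng(5)
        p = np.array([0.1, 0.5, 0.9])
        assert np.array_equal(balding_nichols(p, 0.0, rng), p)

    def test_fst_one_rejected(self):
        with pytest.raises(ConfigError):
            balding_nichols(np.array([0.5]), 1.0, np.random.default_rng(0))


class TestSitePanel:
    def test_fst_zero_everywhere_copies_ancestral(self):
        cfg = SimulationConfig(n_sites=300, fst_by_pop={"EUR": 0.0, "AFR": 0.0},
                               private_rate_by_pop={}, seed=1)
        panel = draw_site_panel(cfg)
        for pop in ("EUR", "AFR"):
            shared = panel.owner == -1
            assert np.array_equal(panel.p_by_pop[pop][shared],
                                  panel.p_anc[shared])

    def test_fully_private_population_zeroes_the_other(self):
        cfg = SimulationConfig(n_sites=200,
                               private_rate_by_pop={"EUR": 0.0, "AFR": 1.0},
                               seed=2)
        panel = draw_site_panel(cfg)
        assert (panel.p_by_pop["EUR"] == 0.0).all()
        # own-population frequencies may underflow to 0 for ultra-rare sites,
        # but the panel as a whole must be polymorphic in AFR only
        assert (panel.p_by_pop["AFR"] > 0.0).any()

    def test_unique_keys_and_impact_fractions(self):
        cfg = SimulationConfig(n_sites=5_000, seed=3)
        panel = draw_site_panel(cfg)
        keys = {(c, p) for c, p in zip(panel.chrom, panel.pos)}
        assert len(keys) == cfg.n_sites
        counted_frac = panel.counted.mean()
        assert counted_frac == pytest.approx(cfg.p_counted_impact, abs=0.03)


class TestPublicDatabase:
    def test_unsampled_private_sites_absent(self):
        cfg = SimulationConfig(n_sites=300,
                               private_rate_by_pop={"EUR": 0.0, "AFR": 1.0},
                               db_samples_by_pop={"EUR": 100, "AFR": 0},
                               seed=4)
        panel = draw_site_panel(cfg)
        table = build_public_db(panel, cfg.db_samples_by_pop, seed=cfg.seed)
        assert len(table) == 0

    def test_common_site_concentrates_near_half(self):
        cfg = SimulationConfig(n_sites=400, fst_by_pop={"EUR": 0.0},
                               private_rate_by_pop={},
                               group_to_pop={"White": "EUR"},
                               n_patients_by_group={"White": 1},
                               db_samples_by_pop={"EUR": 1000},
                               sfs_alpha=50.0, sfs_beta=50.0, seed=5)
        panel = draw_site_panel(cfg)
        panel.p_by_pop["EUR"][:] = 0.5
        table = build_public_db(panel, cfg.db_samples_by_pop, seed=cfg.seed)
        afs = [recs["SIMDB"].af for _, recs in table.items()]
        assert len(afs) == 400
        # binomial sd at 2N=2000 draws is ~0.011
        assert np.mean(afs) == pytest.approx(0.5, abs=0.005)

    def test_missing_fraction_matches_analytic_expectation(self):
        """P(site absent) = (1-p_pooled)^(2N); compare against one cohort draw."""
        rng = np.random.default_rng(6)
        cfg = SimulationConfig(n_sites=20_000, fst_by_pop={"EUR": 0.0},
                               private_rate_by_pop={},
                               group_to_pop={"White": "EUR"},
                               n_patients_by_group={"White": 1},
                               db_samples_by_pop={"EUR": 50},
                               sfs_alpha=0.2, sfs_beta=5.0, seed=6)
        panel = draw_site_panel(cfg)
        ac, an = draw_db_counts(panel, cfg.db_samples_by_pop, rng)
        expected_absent = np.sum((1 - panel.p_by_pop["EUR"]) ** (2 * 50))
        observed_absent = np.sum(ac == 0)
        sd = np.sqrt(np.sum(
            (1 - panel.p_by_pop["EUR"]) ** 100
            * (1 - (1 - panel.p_by_pop["EUR"]) ** 100)))
        assert abs(observed_absent - expected_absent) < 5 * sd

    def test_empty_database_rejected(self):
        cfg = SimulationConfig(n_sites=10, seed=1)
        panel = draw_site_panel(cfg)
        with pytest.raises(ConfigError):
            draw_db_counts(panel, {"EUR": 0, "AFR": 0},
                           np.random.default_rng(0))


class TestSimulatePatient:
    def test_somatic_count_mean_matches_poisson_rate(self):
        """Rate 2/Mb on 75 Mb with negligible dispersion: mean count ~ 150."""
        cfg = SimulationConfig(
            n_sites=10, somatic_rate_mean=2.0, somatic_dispersion=np.inf,
            n_patients_by_group={"White": 1}, group_to_pop={"White": "EUR"},
            fst_by_pop={"EUR": 0.0}, private_rate_by_pop={},
            db_samples_by_pop={"EUR": 10}, seed=7)
        panel = draw_site_panel(cfg)
        counts = []
        for i in range(600):
            _, somatic, _ = simulate_patient(panel, "White", cfg,
                                             patient_index=i)
            counts.append(len(somatic))
        # SE of the mean of 600 Poisson(150) draws ~ 0.5
        assert np.mean(counts) == pytest.approx(150.0, abs=2.5)

    def test_full_sensitivity_gives_tumor_superset_of_germline(self, small_config):
        panel = draw_site_panel(small_config)
        sample, somatic, germ_truth = simulate_patient(panel, "Black",
                                                       small_config)
        assert sample.germline_variants == germ_truth
        assert set(sample.germline_variants) <= set(sample.tumor_variants)

    def test_carrier_count_matches_hwe_expectation(self):
        """E[#carried] = sum_sites 1-(1-p)^2 under Hardy-Weinberg."""
        cfg = SimulationConfig(
            n_sites=3_000, n_patients_by_group={"White": 1},
            group_to_pop={"White": "EUR"}, fst_by_pop={"EUR": 0.1},
            private_rate_by_pop={}, db_samples_by_pop={"EUR": 10},
            somatic_rate_mean=0.01, seed=8)
        panel = draw_site_panel(cfg)
        p = panel.p_by_pop["EUR"]
        expected = np.sum(1 - (1 - p) ** 2)
        var = np.sum((1 - (1 - p) ** 2) * (1 - p) ** 2)
        n_rep = 400
        carried = [len(t) for _, _, t in
                   (simulate_patient(panel, "White", cfg, patient_index=i)
                    for i in range(n_rep))]
        se = np.sqrt(var / n_rep)
        assert np.mean(carried) == pytest.approx(expected, abs=4 * se)

    def test_unknown_group_rejected(self, small_config):
        panel = draw_site_panel(small_config)
        with pytest.raises(ConfigError):
            simulate_patient(panel, "Martian", small_config)


class TestSimulateCohort:
    def test_same_seed_identical_cohorts(self, small_config):
        c1 = simulate_cohort(small_config)
        c2 = simulate_cohort(small_config)
        assert [p.patient_id for p in c1.patients] == [
            p.patient_id for p in c2.patients]
        for p1, p2 in zip(c1.patients, c2.patients):
            assert p1.tumor_variants == p2.tumor_variants
            assert p1.germline_variants == p2.germline_variants
        assert dict(c1.db_table.items()) == dict(c2.db_table.items())

    def test_group_counts_and_labels(self, small_config):
        cohort = simulate_cohort(small_config)
        groups = [p.group for p in cohort.patients]
        assert len(groups) == 10
        assert groups.count("White") == 6 and groups.count("Black") == 4

    def test_truth_partitions_tumor_set(self, small_config):
        cohort = simulate_cohort(small_config)
        for p in cohort.patients:
            somatic, germ = cohort.truth[p.patient_id]
            assert not (somatic & germ)
            for v in p.tumor_variants:
                assert (v in somatic) != (v in germ)

    def test_database_excludes_cohort_patients(self, small_config):
        """DB allele counts come from separate simulated individuals: a
        site can be carried by a patient yet absent from the database."""
        cohort = simulate_cohort(small_config)
        carried_keys = {v.key for p in cohort.patients
                        for v in (p.germline_variants or ())}
        db_keys = {k for k, _ in cohort.db_table.items()}
        assert carried_keys - db_keys, "every carried site found in db"

    def test_vectorized_path_equals_object_pipeline_exactly(self, small_config):
        """The fast counting path and the set-based filter/count pipeline
        consume the same draws and must agree record-for-record."""
        cohort = simulate_cohort(small_config)
        regions = (small_config.region, small_config.panel_region())
        obj = cohort_tmb(cohort.patients, cohort.db_table,
                         CANONICAL_CRITERIA, regions)
        fast = simulate_cohort_tmb(small_config)
        assert obj == fast

    def test_config_yaml_round_trip(self, tmp_path, small_config):
        import yaml
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(small_config.to_dict()))
        cfg2 = SimulationConfig.from_yaml(p)
        assert cfg2.to_dict() == small_config.to_dict()

    def test_bad_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(fst_by_pop={"EUR": 1.0, "AFR": 0.1})
        with pytest.raises(ConfigError):
            SimulationConfig(group_to_pop={"White": "MARS", "Black": "AFR"})
        with pytest.raises(ConfigError):
            SimulationConfig(private_rate_by_pop={"EUR": 0.6, "AFR": 0.6})

    def test_emitted_files_reload_into_same_tmb_table(self, tmp_path,
                                                      small_config):
        """VCF/TSV emission round-trips: reading the emitted cohort yields
        the same TMB table as the in-memory objects."""
        from tmburden.pipeline import RunConfig, run_pipeline
        from tmburden.variant_core import read_tmb_table, write_tmb_table

        cohort = simulate_cohort(small_config)
        paths = cohort.emit(tmp_path / "cohort")
        rc = RunConfig(mode="vcf", out_dir=tmp_path / "out",
                       metadata_path=paths["metadata"],
                       frequency_table_path=paths["frequency_table"],
                       panel_genes_path=paths["panel_genes"])
        out = run_pipeline(rc)
        df = read_tmb_table(out["tmb_table"])

        regions = (small_config.region, small_config.panel_region())
        expected = cohort_tmb(cohort.patients, cohort.db_table,
                              CANONICAL_CRITERIA, regions)
        epath = tmp_path / "expected.tsv"
        write_tmb_table(expected, epath)
        edf = read_tmb_table(epath)
        pd_sorted = lambda d: d.sort_values(
            ["patient_id", "region", "criterion"]).reset_index(drop=True)
        import pandas as pd
        pd.testing.assert_frame_equal(pd_sorted(df), pd_sorted(edf))
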