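"""The synthetic cohort generator and its planted ground truth."""

import numpy as np
import pandas as pd
import pytest

import drugsurv as ds
from drugsurv.synthetic import patient_hazards, synonym_map_from_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_patients", 0),
            ("baseline_hazard", -1.0),
            ("bimodal_fraction", 1.5),
            ("block_flip_prob", -0.1),
            ("n_signal_genes", 10_000),
            ("low_mean", 9.0),  # above high_mean
            ("cancer_labels", ()),
        ],
    )
    def test_invalid_field_raises_naming_it(self, field, value):
        cfg = ds.SimConfig(**{field: value})
        with pytest.raises(ds.ConfigError):
            cfg.validate()


class TestSimulateExpression:
    def test_dimensions_forced_by_config(self):
        cfg = ds.SimConfig(n_genes=500, n_patients=200, seed=7)
        expr, _ = ds.simulate_expression(cfg)
        assert expr.shape == (500, 200)
        assert expr.scale == "linear"
        assert (expr.values.to_numpy() >= 0).all()

    def test_zero_signal_zero_blocks(self):
        cfg = ds.SimConfig(n_signal_genes=0, n_blocks=0, n_patients=30,
                           n_genes=40, seed=1)
        _, truth = ds.simulate_expression(cfg)
        assert truth.signal_gene_ids == frozenset()
        assert truth.block_membership == {}

    def test_component_separation_on_log_scale(self):
        """High-state minus low-state sample means recover the planted
        component gap for a bimodal gene."""
        cfg = ds.SimConfig(n_patients=200, n_genes=50, low_mean=2,
                           high_mean=8, component_sd=0.5, seed=3)
        expr, truth = ds.simulate_expression(cfg)
        logv = ds.log_transform(expr).values
        gene = next(iter(truth.signal_gene_ids))
        state = truth.gene_latent.loc[gene]
        gap = logv.loc[gene][state].mean() - logv.loc[gene][~state].mean()
        assert 5 <= gap <= 7

    def test_block_genes_share_factor_with_flip_noise(self):
        cfg = ds.SimConfig(n_patients=200, n_genes=100, n_blocks=2,
                           block_size=15, block_flip_prob=0.05, seed=4)
        _, truth = ds.simulate_expression(cfg)
        for gene, b in truth.block_membership.items():
            agree = (
                truth.gene_latent.loc[gene] == truth.block_factors.loc[b]
            ).mean()
            assert agree > 0.85  # 5% flips

    def test_same_seed_identical_output(self):
        cfg = ds.SimConfig(n_patients=40, n_genes=60, seed=5, n_blocks=1,
                           block_size=10)
        e1, t1 = ds.simulate_expression(cfg)
        e2, t2 = ds.simulate_expression(cfg)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        pd.testing.assert_frame_equal(t1.gene_latent, t2.gene_latent)


class TestSimulateSurvival:
    def test_no_censoring_all_events(self):
        cfg = ds.SimConfig(n_patients=50, n_genes=30, censor_rate=0.0,
                           seed=6, n_blocks=1, block_size=5)
        _, truth = ds.simulate_expression(cfg)
        recs = ds.simulate_survival(truth, cfg)
        assert len(recs) == 50
        assert all(r.event for r in recs)
        assert all(r.time > 0 for r in recs)

    def test_null_hazard_is_flat(self):
        cfg = ds.SimConfig(n_patients=80, n_genes=40, signal_hazard_ratio=1.0,
                           block_hazard_ratio=1.0, n_blocks=1, block_size=5,
                           seed=7)
        _, truth = ds.simulate_expression(cfg)
        h = patient_hazards(truth, cfg)
        assert np.allclose(h, cfg.baseline_hazard)

    def test_event_rate_ratio_tracks_planted_hr(self):
        """Person-time tabulation: events per person-time in the high vs.
        low state of a single HR=3 signal gene lands near 3."""
        cfg = ds.SimConfig(
            n_patients=400, n_genes=20, n_signal_genes=1, n_blocks=0,
            signal_hazard_ratio=3.0, seed=8,
        )
        _, truth = ds.simulate_expression(cfg)
        recs = ds.simulate_survival(truth, cfg)
        gene = next(iter(truth.signal_gene_ids))
        state = truth.gene_latent.loc[gene]
        by_pid = {r.patient_id: r for r in recs}
        rate = {}
        for s in (True, False):
            pids = state.index[state == s]
            events = sum(by_pid[p].event for p in pids)
            person_time = sum(by_pid[p].time for p in pids)
            rate[s] = events / person_time
        assert 2.0 <= rate[True] / rate[False] <= 4.5


@pytest.fixture(scope="module")
def cohort():
    return ds.simulate_cohort(ds.SimConfig(seed=9, n_genes=50))


class TestClinicalTables:

    def test_vital_status_matches_event_flag(self, cohort):
        clin = cohort.clinical.set_index("patient_id")
        for rec in cohort.survival:
            row = clin.loc[rec.patient_id]
            if rec.event:
                assert row["vital_status"] == "Dead"
                assert row["days_to_death"] != ""
                assert row["days_to_last_followup"] == ""
            else:
                assert row["vital_status"] == "Alive"
                assert row["days_to_death"] == ""

    def test_raw_names_come_from_variant_pools(self, cohort):
        pools = {
            raw
            for canonical, variants in ds.SimConfig().drug_names
            for raw in (canonical, *variants)
        }
        assert set(cohort.exposures["drug_name"]) <= pools

    def test_dedup_bound(self, cohort):
        std = ds.standardize_drug_names(cohort.exposures,
                                        cohort.synonym_map)
        dedup = std[["patient_id", "drug"]].drop_duplicates()
        assert len(dedup) <= len(cohort.exposures)

    def test_synonym_map_covers_all_variants(self):
        cfg = ds.SimConfig()
        m = synonym_map_from_config(cfg)
        for canonical, variants in cfg.drug_names:
            assert m[canonical] == canonical.strip().lower()
            for v in variants:
                assert m[v] == canonical.strip().lower()


class TestWriteCohort:
    def test_round_trip_through_ingest(self, tmp_path):
        cfg = ds.SimConfig(n_patients=60, n_genes=40, seed=10,
                           n_blocks=1, block_size=8)
        cohort = ds.simulate_cohort(cfg)
        paths = ds.write_cohort(cohort, tmp_path)
        model = ds.DrugSurvivalScreen.from_files(
            paths["expression"], paths["clinical"], paths["exposures"],
            synonyms=paths["synonyms"],
        )
        assert model.expression.shape == (40, 60)
        assert len(model.survival) == len(cohort.survival)
        truth = pd.read_csv(paths["truth"], sep="\t")
        assert set(truth["role"]) <= {"signal", "block", "bimodal"}
        assert (truth["role"] == "signal").sum() == cfg.n_signal_genes

    def test_byte_identical_across_runs(self, tmp_path):
        cfg = ds.SimConfig(n_patients=30, n_genes=25, seed=11, n_blocks=1,
                           block_size=5)
        p1 = ds.write_cohort(ds.simulate_cohort(cfg), tmp_path / "a")
        p2 = ds.write_cohort(ds.simulate_cohort(cfg), tmp_path / "b")
        for key in p1:
            b1 = open(p1[key], "rb").read()
            b2 = open(p2[key], "rb").read()
            assert b1 == b2, key


class TestPlantedAssociationStrength:
    def test_within_block_chi2_exceeds_random_pairs(self):
        """True latent states: within-block pairwise chi-square beats
        random gene pairs in >= 99% of sampled pairs."""
        rng = np.random.default_rng(12)
        cfg = ds.SimConfig(n_patients=200, n_genes=300, n_blocks=2,
                           block_size=20, block_flip_prob=0.05, seed=12)
        _, truth = ds.simulate_expression(cfg)
        latent = truth.gene_latent
        block_genes = [
            [g for g, b in truth.block_membership.items() if b == k]
            for k in range(cfg.n_blocks)
        ]
        others = [g for g in latent.index
                  if g not in truth.block_membership]
        within = []
        for genes in block_genes:
            for _ in range(100):
                g1, g2 = rng.choice(genes, size=2, replace=False)
                within.append(
                    ds.chi2_pair(latent.loc[g1], latent.loc[g2])
                )
        rand = []
        for _ in range(200):
            g1, g2 = rng.choice(others, size=2, replace=False)
            rand.append(ds.chi2_pair(latent.loc[g1], latent.loc[g2]))
        cutoff = np.quantile(rand, 0.99)
        assert np.mean(np.asarray(within) > cutoff) >= 0.99
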