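import dataclasses

import numpy as np
import pandas as pd
import pytest

import _oracles
from conftest import random_raw_matrix
from orbiscan.model import CountMatrix, RunConfig, Stage
from orbiscan.normalization import (
    StageError,
    background_filter,
    background_threshold,
    biological_normalize,
    normalize_pipeline,
    subtract_background,
    technical_normalize,
)


def _matrix(small_panel, data: dict, stage=Stage.RAW) -> CountMatrix:
    df = pd.DataFrame(data, index=small_panel.names(), dtype=float)
    return CountMatrix(df, stage, small_panel)


class TestTechnicalNormalize:
    def test_hand_computed_factors(self, small_panel):
        # positive-probe sums 100 and 200 -> mean 150 -> factors 1.5 and 0.75
        data = {
            "L1": [10, 10, 10, 10, 10, 10, 60, 40, 1, 2, 3],
            "L2": [10, 10, 10, 10, 10, 10, 150, 50, 1, 2, 3],
        }
        m = _matrix(small_panel, data)
        out, factors = technical_normalize(m, small_panel)
        assert factors["L1"] == pytest.approx(1.5)
        assert factors["L2"] == pytest.approx(0.75)
        sums = out.values.loc[small_panel.positive].sum(axis=0)
        assert sums.to_numpy() == pytest.approx([150.0, 150.0])
        assert out.stage is Stage.TECH_NORMALIZED

    def test_identical_lanes_are_left_unchanged(self, small_panel):
        data = {"L1": [5] * 11, "L2": [5] * 11}
        m = _matrix(small_panel, data)
        out, factors = technical_normalize(m, small_panel)
        assert (factors == 1.0).all()
        assert out.values.equals(m.values)

    def test_equalizes_positive_sums_on_random_matrices(self, small_panel, rng):
        for _ in range(50):
            m = random_raw_matrix(small_panel, int(rng.integers(2, 8)), rng)
            out, _ = technical_normalize(m, small_panel)
            sums = out.values.loc[small_panel.positive].sum(axis=0).to_numpy()
            assert np.all(np.abs(sums - sums.mean()) <= 1e-9 * sums.mean())

    def test_zero_positive_lane_named(self, small_panel):
        data = {"L1": [5] * 11, "L2": [5, 5, 5, 5, 5, 5, 0, 0, 5, 5, 5]}
        with pytest.raises(ValueError, match="L2"):
            technical_normalize(_matrix(small_panel, data), small_panel)

    def test_requires_raw_stage(self, small_panel):
        m = _matrix(small_panel, {"L1": [5] * 11}, Stage.TECH_NORMALIZED)
        with pytest.raises(StageError):
            technical_normalize(m, small_panel)


class TestBackgroundThreshold:
    def test_hand_computed(self, small_panel):
        # negatives {1,2,3}: mean 2, sample SD 1 -> threshold 4
        data = {"L1": [10, 10, 10, 10, 10, 10, 60, 40, 1, 2, 3]}
        m = _matrix(small_panel, data, Stage.TECH_NORMALIZED)
        thr = background_threshold(m, small_panel)
        assert thr["L1"] == pytest.approx(4.0)

    def test_constant_negatives_give_their_value(self, small_panel):
        data = {"L1": [10, 10, 10, 10, 10, 10, 60, 40, 7, 7, 7]}
        m = _matrix(small_panel, data, Stage.TECH_NORMALIZED)
        assert background_threshold(m, small_panel)["L1"] == pytest.approx(7.0)

    def test_matches_two_pass_oracle_on_random_lanes(self, small_panel, rng):
        for _ in range(100):
            m = random_raw_matrix(small_panel, 1, rng)
            m = dataclasses.replace(m, stage=Stage.TECH_NORMALIZED)
            thr = background_threshold(m, small_panel)
            negs = m.values.loc[small_panel.negative].iloc[:, 0]
            mean, sd = _oracles.two_pass_mean_sd(negs)
            assert thr.iloc[0] == pytest.approx(mean + 2 * sd, rel=1e-12)


class TestSubtractBackground:
    def test_subtraction_and_clamp(self, small_panel):
        data = {"L1": [10, 3, 5, 4, 10, 10, 60, 40, 1, 2, 3]}
        m = _matrix(small_panel, data, Stage.TECH_NORMALIZED)
        thr = pd.Series({"L1": 4.0})
        out = subtract_background(m, thr)
        assert out.values.loc["GENE_A", "L1"] == 6.0   # 10 - 4
        assert out.values.loc["GENE_B", "L1"] == 0.0   # 3 - 4 clamped
        # control probes untouched
        assert out.values.loc["POS_A(128)", "L1"] == 60.0
        assert out.values.loc["NEG_01", "L1"] == 1.0
        assert out.stage is Stage.BACKGROUND_SUBTRACTED

    def test_zero_threshold_is_identity(self, small_panel, rng):
        m = random_raw_matrix(small_panel, 3, rng)
        m = dataclasses.replace(m, stage=Stage.TECH_NORMALIZED)
        thr = pd.Series(0.0, index=m.sample_names)
        out = subtract_background(m, thr)
        assert out.values.equals(m.values)


class TestBiologicalNormalize:
    def test_hand_computed_factors(self, small_panel):
        # housekeeping geometric means 10 and 40 -> mean 25 -> 2.5 and 0.625
        data = {
            "L1": [10, 10, 10, 10, 5, 20, 60, 40, 1, 2, 3],   # gm = 10
            "L2": [10, 10, 10, 10, 20, 80, 60, 40, 1, 2, 3],  # gm = 40
        }
        m = _matrix(small_panel, data, Stage.BACKGROUND_SUBTRACTED)
        out, factors = biological_normalize(m, small_panel)
        assert factors["L1"] == pytest.approx(2.5)
        assert factors["L2"] == pytest.approx(0.625)
        assert out.stage is Stage.BIO_NORMALIZED

    def test_identical_lanes_give_unit_factors(self, small_panel):
        data = {"L1": [5] * 11, "L2": [5] * 11}
        m = _matrix(small_panel, data, Stage.BACKGROUND_SUBTRACTED)
        _, factors = biological_normalize(m, small_panel)
        assert (factors == 1.0).all()

    def test_equalizes_housekeeping_geomeans_on_random_matrices(self, small_panel, rng):
        hk = small_panel.housekeeping
        for _ in range(50):
            m = random_raw_matrix(small_panel, int(rng.integers(2, 8)), rng)
            m = dataclasses.replace(m, stage=Stage.BACKGROUND_SUBTRACTED)
            out, _ = biological_normalize(m, small_panel)
            gms = np.exp(np.log(out.values.loc[hk]).mean(axis=0)).to_numpy()
            assert np.all(np.abs(gms - gms.mean()) <= 1e-9 * gms.mean())

    def test_all_zero_housekeeping_is_an_error(self, small_panel):
        data = {"L1": [5, 5, 5, 5, 0, 0, 60, 40, 1, 2, 3],
                "L2": [5, 5, 5, 5, 5, 0, 60, 40, 1, 2, 3]}
        m = _matrix(small_panel, data, Stage.BACKGROUND_SUBTRACTED)
        with pytest.raises(ValueError, match="background subtraction"):
            biological_normalize(m, small_panel)


class TestBackgroundFilter:
    def test_clearly_expressed_gene_retained(self, small_panel):
        data = {
            "L1": [100, 0, 1, 2, 50, 50, 60, 40, 1, 2, 3],
            "L2": [110, 0, 2, 1, 50, 50, 60, 40, 2, 1, 2],
            "L3": [90, 0, 3, 2, 50, 50, 60, 40, 1, 2, 2],
            "L4": [105, 0, 1, 1, 50, 50, 60, 40, 2, 2, 1],
        }
        m = _matrix(small_panel, data, Stage.BIO_NORMALIZED)
        retained, excluded = background_filter(m, small_panel, alpha=0.05)
        assert "GENE_A" in retained
        assert "GENE_B" in dict(excluded)

    def test_all_zero_gene_excluded(self, small_panel):
        data = {"L1": [0, 5, 5, 5, 5, 5, 60, 40, 1, 2, 3],
                "L2": [0, 5, 5, 5, 5, 5, 60, 40, 2, 1, 2]}
        m = _matrix(small_panel, data, Stage.BIO_NORMALIZED)
        retained, excluded = background_filter(m, small_panel)
        assert "GENE_A" not in retained

    def test_type_i_rate_near_alpha_for_null_genes(self, small_panel, rng):
        # genes drawn from the same Poisson as the negatives are retained
        # at about the nominal 5% rate
        from orbiscan.model import PanelDefinition, Probe, ProbeClass

        n_genes, n_samples = 1000, 12
        probes = [Probe(f"G{i}", ProbeClass.ENDOGENOUS) for i in range(n_genes)]
        probes += [Probe(f"N{i}", ProbeClass.NEGATIVE) for i in range(8)]
        probes += [Probe("HK", ProbeClass.HOUSEKEEPING),
                   Probe("P1(128)", ProbeClass.POSITIVE, 128.0),
                   Probe("P2(32)", ProbeClass.POSITIVE, 32.0)]
        panel = PanelDefinition(tuple(probes))
        lam = 30.0
        values = pd.DataFrame(
            rng.poisson(lam, size=(len(probes), n_samples)).astype(float),
            index=[p.name for p in probes],
            columns=[f"S{i}" for i in range(n_samples)],
        )
        m = CountMatrix(values, Stage.BIO_NORMALIZED, panel)
        retained, _ = background_filter(m, panel, alpha=0.05)
        rate = len(retained) / n_genes
        assert 0.02 <= rate <= 0.08  # 99% binomial band around 0.05


class TestNormalizePipeline:
    def test_identity_on_identical_lanes_with_zero_background(self, small_panel):
        data = {"L1": [500, 400, 300, 200, 100, 100, 60, 40, 0, 0, 0],
                "L2": [500, 400, 300, 200, 100, 100, 60, 40, 0, 0, 0]}
        m = _matrix(small_panel, data)
        out, report = normalize_pipeline(m, small_panel, RunConfig())
        # identical lanes, zero negatives: factors 1, thresholds 0
        assert (report.technical_factors == 1.0).all()
        assert (report.background_thresholds == 0.0).all()
        assert (report.biological_factors == 1.0).all()
        for g in out.gene_names:
            assert out.values.loc[g].to_numpy() == pytest.approx(
                m.values.loc[g].to_numpy()
            )

    def test_reduces_lane_effect_on_housekeeping_totals(self):
        from orbiscan.simulate import SimulationDesign, simulate_counts, simulate_panel

        improved = 0
        for seed in range(100):
            d = SimulationDesign(
                n_endogenous=20, n_housekeeping=6, n_positive=4, n_negative=8,
                groups={"A": 4, "B": 4}, baseline_log2_mean_range=(6.0, 9.0),
                nb_dispersion=0.05, lane_factor_sd=0.4, background_mean=5.0,
                seed=seed,
            )
            panel = simulate_panel(d)
            m, _, _ = simulate_counts(panel, d)
            out, _ = normalize_pipeline(m, panel, RunConfig())
            hk_before = m.values.loc[panel.housekeeping].sum(axis=0)
            # housekeeping survive in the bio-normalized full matrix; recompute
            # CV on the retained endogenous totals as the lane-effect readout
            tot_before = m.values.loc[out.gene_names].sum(axis=0)
            tot_after = out.values.sum(axis=0)
            cv = lambda s: s.std(ddof=1) / s.mean()
            if cv(tot_after) < cv(tot_before):
                improved += 1
        assert improved >= 95

    def test_chain_is_idempotent_on_factors(self, small_panel, rng):
        # a second pass over already-normalized data finds nothing to fix:
        # its technical and biological factors are all within 1e-9 of 1
        for _ in range(10):
            m = random_raw_matrix(small_panel, 5, rng)
            tech, _ = technical_normalize(m, small_panel)
            thr = background_threshold(tech, small_panel)
            sub = subtract_background(tech, thr)
            bio, _ = biological_normalize(sub, small_panel)

            pos_sums = tech.values.loc[small_panel.positive].sum(axis=0)
            second_tech = pos_sums.mean() / pos_sums
            assert np.allclose(second_tech, 1.0, atol=1e-9)

            hk = bio.values.loc[small_panel.housekeeping]
            gms = np.exp(np.log(hk).mean(axis=0))
            second_bio = gms.mean() / gms
            assert np.allclose(second_bio, 1.0, atol=1e-9)

    def test_monotone_order_preserved_within_lane(self, small_panel, rng):
        for _ in range(20):
            m = random_raw_matrix(small_panel, 4, rng)
            out, report = normalize_pipeline(m, small_panel, RunConfig(alpha=0.999999))
            for lane in out.sample_names:
                before = m.values.loc[out.gene_names, lane].to_numpy()
                after = out.values[lane].to_numpy()
                order = np.argsort(before, kind="stable")
                diffs = np.diff(after[order])
                assert np.all(diffs >= -1e-9)

    def test_partition_and_no_controls_in_output(self, small_panel, rng):
        m = random_raw_matrix(small_panel, 4, rng)
        out, report = normalize_pipeline(m, small_panel, RunConfig())
        excluded = {g for g, _ in report.excluded_genes}
        retained = set(report.retained_genes)
        assert excluded | retained == set(small_panel.endogenous)
        assert excluded & retained == set()
        assert set(out.gene_names) <= set(small_panel.endogenous)

    def test_subtract_before_technical_variant_runs(self, small_panel, rng):
        m = random_raw_matrix(small_panel, 4, rng)
        cfg = RunConfig(subtract_before_technical=True, alpha=0.5)
        out, report = normalize_pipeline(m, small_panel, cfg)
        assert (report.technical_factors > 0).all()
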