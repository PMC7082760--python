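"""CV protocol, paired comparisons, GRS mapping and report tables."""

import numpy as np
import pandas as pd
import pytest

from dlvm import DGPParams, DLVMConfig, generate_cohort
from dlvm.experiment import (
    CVPlan,
    GRSMappingError,
    compare_races,
    make_cv_plan,
    map_gs_to_grs,
    paired_t_test,
    run_aberration_experiment,
    summarize_experiment,
    write_report,
)


class TestCVPlan:
    def test_default_protocol_yields_thirty_triples(self, small_cohort):
        plan = CVPlan(master_seed=1)
        triples = make_cv_plan(small_cohort, plan)
        assert len(triples) == 30  # 10 replications x 3 folds

    def test_test_folds_partition_each_replication(self, small_cohort):
        plan = CVPlan(n_replications=4, master_seed=2)
        triples = make_cv_plan(small_cohort, plan)
        n = small_cohort.n
        for rep in range(4):
            tests = [triples[rep * 3 + f][2] for f in range(3)]
            union = np.concatenate(tests)
            assert len(union) == n and len(np.unique(union)) == n

    def test_triples_are_disjoint_within_fold(self, small_cohort):
        for tr, va, te in make_cv_plan(small_cohort, CVPlan(n_replications=2, master_seed=3)):
            assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
            assert len(tr) + len(va) + len(te) == small_cohort.n

    def test_split_fractions_near_protocol(self, small_cohort):
        plan = CVPlan(n_replications=5, master_seed=4)
        fr = np.array([
            [len(tr), len(va), len(te)] for tr, va, te in make_cv_plan(small_cohort, plan)
        ]) / small_cohort.n
        mean = fr.mean(axis=0)
        assert abs(mean[0] - 0.47) <= 0.03
        assert abs(mean[1] - 0.20) <= 0.03
        assert abs(mean[2] - 0.33) <= 0.03

    def test_deterministic_given_master_seed(self, small_cohort):
        a = make_cv_plan(small_cohort, CVPlan(master_seed=7))
        b = make_cv_plan(small_cohort, CVPlan(master_seed=7))
        for (t1, v1, s1), (t2, v2, s2) in zip(a, b):
            assert np.array_equal(t1, t2) and np.array_equal(v1, v2) and np.array_equal(s1, s2)

    def test_too_small_cohort_reports_minimum(self, small_cohort):
        with pytest.raises(ValueError, match="9"):
            make_cv_plan(small_cohort.subset(range(5)), CVPlan())

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            CVPlan(train_fraction=0.6, valid_fraction=0.3, test_fraction=0.3)


class TestPairedTTest:
    def test_identical_samples(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0 and r.p_value == 1.0 and not r.reject
        assert r.degenerate

    def test_textbook_example(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.4641
        r = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], alpha=0.05)
        assert r.t_statistic == pytest.approx(3.4641, abs=1e-4)
        assert r.p_value == pytest.approx(0.0742, abs=1e-3)
        assert not r.reject

    def test_ci_contains_mean_difference(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=8), rng.normal(size=8)
            r = paired_t_test(a, b)
            md = float(np.mean(a - b))
            assert r.ci_low <= md <= r.ci_high
            assert r.reject == (r.p_value < r.alpha)

    def test_zero_variance_nonzero_mean_is_degenerate(self):
        r = paired_t_test([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert r.degenerate and r.p_value == 0.0 and np.isinf(r.t_statistic)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])


class TestGRSMapping:
    def test_default_logistic_midpoint(self):
        assert map_gs_to_grs(7.5) == pytest.approx(0.5)

    def test_output_in_unit_interval_and_monotone(self):
        gs = np.linspace(-5, 25, 200)
        out = map_gs_to_grs(gs)
        assert ((out >= 0) & (out <= 1)).all()
        assert (np.diff(out) >= 0).all()

    def test_custom_mapping_clipped(self):
        out = map_gs_to_grs(np.array([6.0, 10.0]), mapping=lambda g: 0.2 * g - 1.0)
        assert out[0] == pytest.approx(0.2)
        assert out[1] == 1.0  # 1.0 clipped

    def test_non_monotone_mapping_rejected(self):
        with pytest.raises(GRSMappingError):
            map_gs_to_grs(7.0, mapping=lambda g: -g)


@pytest.fixture(scope="module")
def tiny_experiment():
    cohort = generate_cohort(DGPParams(n=240, seed=13))
    plan = CVPlan(n_replications=2, master_seed=5)
    cfg = DLVMConfig.desk_scale(seed=0, dim_Z=6, dim_z1=6, dim_z2=6,
                                hidden_sizes=(24, 12), epochs=5, batch_size=64)
    estimates = []
    results = run_aberration_experiment(cohort, "aberration", plan, cfg,
                                        collect_estimates=estimates)
    return cohort, results, estimates


class TestRunAberrationExperiment:
    def test_replicate_vectors_have_protocol_length(self, tiny_experiment):
        _, results, _ = tiny_experiment
        for gm in results.values():
            assert len(gm.replicate_values) == 2
            assert len(gm.replicate_mean_ice) == 2

    def test_every_patient_contributes_once_per_replication(self, tiny_experiment):
        cohort, _, estimates = tiny_experiment
        df = pd.DataFrame(estimates)
        for (race, rep), grp in df.groupby(["race", "replication"]):
            n_race = int((cohort.race == race).sum())
            assert len(grp) == n_race
            assert grp["row"].nunique() == n_race

    def test_cells_cover_races_and_grades(self, tiny_experiment):
        _, results, _ = tiny_experiment
        races = {r for r, _ in results}
        assert races == {"EA", "AA"}
        assert ("EA", "all") in results and ("AA", "all") in results

    def test_aice_increases_with_effect_size(self):
        """Zero-effect cohorts should show smaller AICE than tau=2 cohorts of
        identical size and noise (monotonicity in the true effect)."""
        plan = CVPlan(n_replications=1, master_seed=9)
        cfg = DLVMConfig.desk_scale(seed=0, dim_Z=6, dim_z1=6, dim_z2=6,
                                    hidden_sizes=(24, 12), epochs=10, batch_size=64)
        vals = {}
        for label, model in (("zero", "zero"), ("tau2", "constant")):
            c = generate_cohort(DGPParams(n=240, seed=17, effect_model=model, tau=2.0))
            res = run_aberration_experiment(c, "aberration", plan, cfg, races=("EA",))
            vals[label] = res[("EA", "all")].aice
        assert vals["zero"] < vals["tau2"]


class TestSummarize:
    def test_report_round_trip_preserves_values(self, tiny_experiment, tmp_path):
        _, results, _ = tiny_experiment
        comps = compare_races(results, "aice")
        mdf, cdf = summarize_experiment({"aberration": results}, comps)
        paths = write_report(mdf, cdf, tmp_path)
        back = pd.read_csv(paths["metrics"], sep="\t")
        assert len(back) == len(mdf)
        assert np.allclose(back["value"], mdf["value"], atol=1e-9)

    def test_row_count_matches_cells_times_metrics(self, tiny_experiment):
        _, results, _ = tiny_experiment
        mdf, _ = summarize_experiment({"aberration": results}, [])
        # 4 metrics x 2 replications per populated cell
        assert len(mdf) == 8 * len(results)

    def test_reject_flags_passed_through(self, tiny_experiment):
        _, results, _ = tiny_experiment
        comps = compare_races(results, "aice") + compare_races(results, "rmse")
        _, cdf = summarize_experiment({}, comps)
        assert list(cdf["reject"]) == [c.reject for c in comps]
        assert "p_value_bh" in cdf.columns
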