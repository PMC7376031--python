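"""Presence-stratified folds, the CV pipeline, aggregation, ΔRMSE."""
import numpy as np
import pandas as pd
import pytest

import raresdm as rs
from raresdm import crossval
from raresdm.metrics import MetricRecord
from raresdm.models import ModelSpec


class TestStratifiedFolds:
    def test_equal_presences_force_one_per_fold(self):
        occ = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        a = rs.stratified_folds(occ, k=4, seed=0)
        for f in range(1, 5):
            assert occ[a.test_sites(f)].sum() == 1

    def test_round_robin_counts_118_sites_10_presences(self):
        occ = np.zeros(118, bool)
        occ[:10] = True
        a = rs.stratified_folds(occ, k=4, seed=3)
        counts = sorted(int(occ[a.test_sites(f)].sum()) for f in range(1, 5))
        assert counts == [2, 2, 3, 3]
        sizes = sorted(a.test_sites(f).size for f in range(1, 5))
        assert sizes == [29, 29, 30, 30]

    def test_partition_properties(self, rng):
        occ = rng.uniform(size=60) < 0.15
        occ[0] = True
        a = rs.stratified_folds(occ, k=4, seed=7)
        all_sites = np.concatenate([a.test_sites(f) for f in range(1, 5)])
        assert sorted(all_sites) == list(range(60))  # disjoint cover

    def test_balance_invariant_many_seeds(self, rng):
        # presence and absence counts differ by <= 1 across folds
        for s in range(300):
            n_pres = int(rng.integers(1, 20))
            occ = np.zeros(97, bool)
            occ[rng.choice(97, n_pres, replace=False)] = True
            a = rs.stratified_folds(occ, k=4, seed=s)
            pres = [int(occ[a.test_sites(f)].sum()) for f in range(1, 5)]
            absn = [int((~occ[a.test_sites(f)]).sum()) for f in range(1, 5)]
            assert max(pres) - min(pres) <= 1
            assert max(absn) - min(absn) <= 1

    def test_errors(self):
        with pytest.raises(ValueError):
            rs.stratified_folds(np.ones(3, bool), k=4, seed=0)
        with pytest.raises(ValueError):
            rs.stratified_folds(np.zeros(10, bool), k=4, seed=0)


class TestRunCV:
    def test_oracle_model_scores_perfectly(self, small_dataset, monkeypatch):
        d = small_dataset
        # inject an oracle: fit memorizes nothing, predict returns the
        # observed abundance for the requested sites by matching rows
        target = d.target_names[0]
        j = d.species_index(target)
        lookup = {tuple(np.round(d.covariates[i], 12)): d.abundance[i, j]
                  for i in range(d.n_sites)}

        def fake_fit(X, y, spec):
            def _pred(Xn):
                return np.array([lookup[tuple(np.round(row, 12))] for row in Xn])
            return rs.FittedModel(spec=spec, n_features=X.shape[1],
                                  training_summary={}, _predictor=_pred)

        monkeypatch.setattr(crossval.models, "fit",
                            lambda X, y, spec: fake_fit(X, y, spec))
        cfg = rs.CVConfig(k=4, n_repetitions=2, seed=1,
                          models=[ModelSpec("rf")], treatments=("baseline",),
                          targets=[target])
        records = rs.run_cv(d, cfg)
        frame = rs.records_to_frame(records)
        assert (frame["rmse"] == 0.0).all()
        assert (frame["auc"] == 1.0).all()
        assert (frame["kappa"] == 1.0).all()

    def test_record_bookkeeping_and_determinism(self, small_dataset):
        d = small_dataset
        cfg = rs.CVConfig(k=4, n_repetitions=2, seed=5,
                          models=[ModelSpec("rf", hyperparameters={"trees": 20})],
                          treatments=("baseline", "conditional_obs"))
        records = rs.run_cv(d, cfg)
        # 4 folds x 2 reps x 1 model x 2 targets x 2 treatments
        assert len(records) == 4 * 2 * 1 * 2 * 2
        again = rs.run_cv(d, cfg)
        pd.testing.assert_frame_equal(rs.records_to_frame(records),
                                      rs.records_to_frame(again))

    def test_incompatible_treatments_skipped(self, small_dataset):
        cfg = rs.CVConfig(k=4, n_repetitions=1, seed=2,
                          models=[ModelSpec("rf", hyperparameters={"trees": 10})],
                          treatments=("baseline", "LV3"),
                          targets=[small_dataset.target_names[0]])
        records = rs.run_cv(small_dataset, cfg)
        assert {r.treatment for r in records} == {"baseline"}

    def test_no_leakage_audit(self, small_dataset):
        events = []
        cfg = rs.CVConfig(k=4, n_repetitions=1, seed=8,
                          models=[ModelSpec("rf", hyperparameters={"trees": 10})],
                          treatments=("baseline",),
                          targets=[small_dataset.target_names[0]])
        rs.run_cv(small_dataset, cfg, audit_hook=events.append)
        splits = [e for e in events if e["stage"] == "split"]
        fits = [e for e in events if e["stage"] == "fit"]
        assert splits and fits
        for e in splits:
            assert len(np.intersect1d(e["train_sites"], e["test_sites"])) == 0
            assert len(e["train_sites"]) + len(e["test_sites"]) \
                == small_dataset.n_sites
        for e in fits:
            # fitting only ever sees training sites
            assert len(e["train_sites"]) < small_dataset.n_sites

    def test_multi_model_families_run(self, small_dataset):
        cfg = rs.CVConfig(
            k=4, n_repetitions=1, seed=3,
            models=[ModelSpec("mrf", hyperparameters={"trees": 10}),
                    ModelSpec("mann", hyperparameters={"restarts": 1,
                                                       "max_iter": 100})],
            treatments=("LV1", "LV3"),
            targets=[small_dataset.target_names[1]])
        records = rs.run_cv(small_dataset, cfg)
        frame = rs.records_to_frame(records)
        assert set(frame["model"]) == {"mrf", "mann"}
        assert set(frame["treatment"]) == {"LV1", "LV3"}
        assert not frame["failed"].any()


class TestAggregate:
    def _records(self):
        return [
            MetricRecord("rf", "Sp1", "baseline", 0, f, auc=0.4 + 0.2 * (f % 2),
                         kappa=0.1, tss=0.2, rmse=0.5, prb=-0.3)
            for f in range(1, 5)
        ]

    def test_mean_of_metrics(self):
        out = rs.aggregate(self._records())
        row = out[(out["model"] == "rf") & (out["species"] == "Sp1")]
        assert row["auc_mean"].iloc[0] == pytest.approx(0.5)
        assert row["rmse_mean"].iloc[0] == pytest.approx(0.5)

    def test_single_record_equals_itself(self):
        one = self._records()[:1]
        out = rs.aggregate(one)
        assert out["auc_mean"].iloc[0] == one[0].auc

    def test_zero_baseline_row(self, small_dataset):
        recs = [MetricRecord("rf", small_dataset.target_names[0], "baseline",
                             0, 1, 0.5, 0.1, 0.1, 0.4, -0.5)]
        out = rs.aggregate(recs, dataset=small_dataset)
        zero = out[out["model"] == "zero"]
        j = small_dataset.species_index(small_dataset.target_names[0])
        expected = rs.zero_baseline_rmse(small_dataset.abundance[:, j])
        assert zero["rmse_mean"].iloc[0] == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rs.aggregate([])


class TestDeltaRMSE:
    def _mk(self, treatment, rmse_values):
        return [MetricRecord("rf", "Sp1", treatment, rep, fold, 0.5, 0.1,
                             0.1, v, -0.2)
                for (rep, fold), v in rmse_values.items()]

    def test_identical_records_give_zero(self):
        vals = {(0, 1): 0.4, (0, 2): 0.6}
        tab = rs.delta_rmse(self._mk("enh", vals), self._mk("base", vals))
        assert tab["mean"].iloc[0] == pytest.approx(0.0)

    def test_improvement_direction(self):
        base = self._mk("base", {(0, 1): 0.6})
        enh = self._mk("enh", {(0, 1): 0.5})
        tab = rs.delta_rmse(enh, base)
        assert tab["mean"].iloc[0] == pytest.approx(0.1)

    def test_key_mismatch_rejected(self):
        base = self._mk("base", {(0, 1): 0.6})
        enh = self._mk("enh", {(0, 2): 0.5})
        with pytest.raises(ValueError, match="unmatched"):
            rs.delta_rmse(enh, base)
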