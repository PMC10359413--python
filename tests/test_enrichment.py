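"""Group-sampling enrichment and repeated random forests."""

import numpy as np
import pandas as pd
import pytest

from lipidsig.enrichment import (
    DEFAULT_RF_PARAMS,
    EnrichmentError,
    enrich,
    importance_by_group,
    train_rf,
)
from lipidsig.profiles import ZMatrix, zscore
from lipidsig.synthetic import SynthSpec, generate


def make_z(values: dict, diagnosis: list) -> ZMatrix:
    df = pd.DataFrame(values, dtype=float)
    df.index = [f"s{i}" for i in range(len(df))]
    meta = pd.DataFrame({"diagnosis": diagnosis}, index=df.index)
    return ZMatrix(df, meta)


class TestEnrich:
    def test_row_count_is_iterations_times_samples(self, study_fixture):
        pm, truth = study_fixture
        z = zscore(pm)
        enr = enrich(z, truth.groups, iterations=1000, seed=3)
        assert enr.features.shape == (16000, 5)
        assert len(enr.labels) == 16000
        # per-iteration class proportions equal the source proportions
        lab = enr.labels.to_numpy().reshape(1000, 16)
        assert (np.sum(lab == "RA", axis=1) == 8).all()

    @pytest.mark.parametrize("b,n", [(1, 4), (7, 4), (13, 6)])
    def test_row_count_conservation(self, b, n):
        z = make_z(
            {"a": range(n), "b": range(n)}, ["OA", "RA"] * (n // 2)
        )
        groups = pd.Series({"a": 1, "b": 2})
        assert enrich(z, groups, iterations=b, seed=0).features.shape[0] == b * n

    def test_singleton_groups_give_stacked_copies(self):
        z = make_z({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]}, ["OA", "OA", "RA", "RA"])
        enr = enrich(z, pd.Series({"a": 1, "b": 2}), iterations=5, seed=0)
        block = z.values.to_numpy()
        assert np.allclose(enr.features.to_numpy(), np.tile(block, (5, 1)))

    def test_provenance_traces_to_source_cells(self, study_fixture):
        pm, truth = study_fixture
        z = zscore(pm)
        enr = enrich(z, truth.groups, iterations=2, seed=9)
        for row_i, prow in enr.provenance.iterrows():
            for slot in enr.features.columns:
                assert (
                    enr.features.loc[row_i, slot]
                    == z.values.loc[prow["sample"], prow[slot]]
                )

    def test_empty_group_rejected(self):
        z = make_z({"a": [1, 2, 3, 4]}, ["OA", "OA", "RA", "RA"])
        with pytest.raises(EnrichmentError):
            enrich(z, pd.Series({"a": 1, "missing": 2}), iterations=2)


class TestTrainRF:
    def test_parameter_record_reproduces_block(self):
        z, truth = generate(SynthSpec(seed=0, closure=False))
        enr = enrich(zscore(z), truth.groups, iterations=10, seed=0)
        run = train_rf(enr.features, enr.labels, repeats=1, seed=0)
        for key, val in DEFAULT_RF_PARAMS.items():
            if key == "random_state":
                continue
            assert run.params[key] == val

    def test_importances_normalized(self, study_fixture):
        pm, truth = study_fixture
        z = zscore(pm)
        enr = enrich(z, truth.groups, iterations=50, seed=1)
        run = train_rf(enr.features, enr.labels, repeats=2, seed=1)
        assert np.allclose(run.importances.sum(axis=1), 1.0, atol=1e-9)
        assert ((run.accuracies >= 0) & (run.accuracies <= 1)).all()

    def test_perfect_separator_dominates(self):
        """One group slot separates the classes; it must rank first and
        accuracy must be ~1 (checked over several seeds)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 400
            y = np.repeat(["OA", "RA"], n // 2)
            X = pd.DataFrame(
                {
                    "group_1": np.where(y == "RA", 5.0, -5.0),
                    "group_2": rng.standard_normal(n),
                    "group_3": rng.standard_normal(n),
                }
            )
            run = train_rf(X, pd.Series(y), repeats=4, seed=seed)
            assert run.mean_accuracy >= 0.99
            assert run.mean_importance.idxmax() == "group_1"

    def test_permuted_labels_give_chance_accuracy(self, study_fixture):
        pm, truth = study_fixture
        z = zscore(pm)
        rng = np.random.default_rng(5)
        enr = enrich(z, truth.groups, iterations=100, seed=5)
        y = pd.Series(rng.permutation(enr.labels.to_numpy()))
        run = train_rf(enr.features, y, repeats=5, seed=5)
        # 3 sigma of a binomial mean over 5 x 320 test rows
        assert abs(run.mean_accuracy - 0.5) < 3 * 0.5 / np.sqrt(5 * 320)

    def test_duplicating_rows_keeps_ranking(self):
        z, truth = generate(SynthSpec(seed=4, closure=False))
        zz = zscore(z)
        run1 = train_rf(zz.values, zz.diagnosis, repeats=5, seed=4)
        dup_X = pd.concat([zz.values, zz.values], ignore_index=True)
        dup_y = pd.concat([zz.diagnosis, zz.diagnosis], ignore_index=True)
        run2 = train_rf(dup_X, dup_y, repeats=5, seed=4)
        top1 = set(run1.mean_importance.nlargest(5).index)
        top2 = set(run2.mean_importance.nlargest(5).index)
        assert len(top1 & top2) >= 3  # stable top features under duplication

    def test_bit_for_bit_reproducibility(self, study_fixture):
        pm, truth = study_fixture
        z = zscore(pm)
        enr = enrich(z, truth.groups, iterations=50, seed=7)
        r1 = train_rf(enr.features, enr.labels, repeats=3, seed=7)
        r2 = train_rf(enr.features, enr.labels, repeats=3, seed=7)
        assert (r1.accuracies == r2.accuracies).all()
        assert r1.importances.equals(r2.importances)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4]})
        with pytest.raises(EnrichmentError):
            train_rf(X, pd.Series(["OA"] * 4), repeats=1)


class TestImportanceByGroup:
    def test_enriched_run_reports_one_row_per_group(self, study_fixture):
        pm, truth = study_fixture
        z = zscore(pm)
        enr = enrich(z, truth.groups, iterations=50, seed=2)
        run = train_rf(enr.features, enr.labels, repeats=2, seed=2)
        table = importance_by_group(run)
        assert list(table.index) == [1, 2, 3, 4, 5]
        assert table["importance"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_importances_give_uniform_groups(self):
        run = type(
            "R", (), {
                "mean_importance": pd.Series(
                    0.25, index=[f"group_{g}" for g in range(1, 5)]
                )
            },
        )()
        table = importance_by_group(run)
        assert np.allclose(table["importance"], 0.25)

    def test_full_run_reports_variables_and_derived_flag(self, study_fixture):
        pm, truth = study_fixture
        z = zscore(pm)
        run = train_rf(z.values, z.diagnosis, repeats=2, seed=3)
        table = importance_by_group(run, truth.groups, z.variable_kind)
        assert sorted(table.index) == sorted(z.values.columns)
        assert not table["derived"].any()  # fixture has raw chains only

    def test_mismatched_groups_rejected(self, study_fixture):
        pm, truth = study_fixture
        z = zscore(pm)
        run = train_rf(z.values, z.diagnosis, repeats=1, seed=3)
        with pytest.raises(EnrichmentError):
            importance_by_group(run, truth.groups.iloc[:10])
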