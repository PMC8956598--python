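"""Cross-validation geometries, model contracts, metrics, ablation,
titration, and the design-bias check."""

import numpy as np
import pandas as pd
import pytest

import fibromorph as fm
from fibromorph.tasks import (ModelSpec, SplitError, SplitSpec,
                              accuracy_and_rank, aggregate_line_predictions,
                              cellline_splits, channel_ablation,
                              design_bias_check, disease_folds, donor_splits,
                              fit_predict, line_level_roc_auc,
                              partition_pairs, predicted_ranks, roc_auc,
                              titrate_training, well_position_covariates)
from tests.conftest import make_well_table


def bruteforce_auc(scores, labels):
    """Oracle: exhaustive pair counting with 0.5 credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCelllineSplits:
    def test_four_batches_two_layouts_give_8_splits(self):
        t = make_well_table(n_batches=4, n_layouts=2)
        splits = cellline_splits(t)
        assert len(splits) == 8
        for sp in splits:
            meta = t.set_index(
                pd.MultiIndex.from_frame(t[["batch", "plate", "well"]]))
            train_rows = t[[tuple(r) in sp.train_wells
                            for r in t[["batch", "plate", "well"]].values]]
            test_rows = t[[tuple(r) in sp.test_wells
                           for r in t[["batch", "plate", "well"]].values]]
            assert not set(train_rows.batch) & set(test_rows.batch)
            assert not set(train_rows.layout) & set(test_rows.layout)

    def test_two_by_two_enumerated_exhaustively(self):
        t = make_well_table(n_batches=2, n_layouts=2)
        splits = cellline_splits(t)
        assert len(splits) == 4
        held = {(sp.held_out["batch"], sp.held_out["layout"]) for sp in splits}
        assert held == {(1, 1), (1, 2), (2, 1), (2, 2)}

    def test_single_axis_raises_naming_it(self):
        with pytest.raises(SplitError, match="batch"):
            cellline_splits(make_well_table(n_batches=1))
        t = make_well_table(n_batches=2, n_layouts=1)
        with pytest.raises(SplitError, match="layout"):
            cellline_splits(t)


class TestDonorSplits:
    def test_default_study_yields_16_splits_of_5_lines(self, micro_study):
        meta = micro_study.manifest.drop_duplicates(["batch", "plate", "well"])
        splits = donor_splits(meta)
        assert len(splits) == 2 * 2 * 2  # roles x batches x layouts
        full = fm.SyntheticStudy(fm.CohortSpec(), fm.full_plan(), seed=0)
        fsplits = donor_splits(
            full.manifest.drop_duplicates(["batch", "plate", "well"]))
        assert len(fsplits) == 16
        for sp in fsplits:
            test_lines = {w for w in sp.test_wells}
            meta_f = full.manifest.drop_duplicates(["batch", "plate", "well"])
            sel = meta_f[[tuple(r) in sp.test_wells
                          for r in meta_f[["batch", "plate", "well"]].values]]
            assert sel.line_id.nunique() == 5

    def test_each_donor_at_most_once_in_training(self, micro_study):
        meta = micro_study.manifest.drop_duplicates(["batch", "plate", "well"])
        for sp in donor_splits(meta):
            sel = meta[[tuple(r) in sp.train_wells
                        for r in meta[["batch", "plate", "well"]].values]]
            lines_per_donor = sel.drop_duplicates("line_id").groupby(
                "donor_id").size()
            assert (lines_per_donor == 1).all()

    def test_toy_two_repeat_donors_test_two_lines(self):
        t = make_well_table(n_lines=10)
        # donors 1 and 2 get second-biopsy lines 9, 10
        t.loc[t.line_id == 9, ["donor_id", "biopsy_index"]] = [1, 2]
        t.loc[t.line_id == 10, ["donor_id", "biopsy_index"]] = [2, 2]
        splits = donor_splits(t)
        for sp in splits:
            sel = t[[tuple(r) in sp.test_wells
                     for r in t[["batch", "plate", "well"]].values]]
            assert sel.line_id.nunique() == 2


class TestDiseaseFolds:
    def test_37_pairs_partition_into_8_8_7_7_7(self, default_cohort):
        _, pairs = default_cohort
        part = partition_pairs(pairs, n_folds=5, include_gba=False, seed=0)
        sizes = sorted(part.fold.value_counts().tolist(), reverse=True)
        assert sizes == [8, 8, 7, 7, 7]

    def test_lrrk2_pairs_balanced_within_one(self, default_cohort):
        _, pairs = default_cohort
        part = partition_pairs(pairs, n_folds=5, seed=0)
        counts = part[part.mutation_group == "LRRK2"].fold.value_counts()
        full = counts.reindex(range(5), fill_value=0)
        assert full.max() - full.min() <= 1

    def test_no_line_in_both_train_and_test(self, micro_study):
        meta = micro_study.manifest.drop_duplicates(["batch", "plate", "well"])
        for sp in disease_folds(micro_study.pairs, meta, seed=0):
            train_lines = set(meta[[tuple(r) in sp.train_wells
                                    for r in meta[["batch", "plate", "well"]].values]].line_id)
            test_lines = set(meta[[tuple(r) in sp.test_wells
                                   for r in meta[["batch", "plate", "well"]].values]].line_id)
            assert not train_lines & test_lines

    def test_pairs_never_split_across_folds(self, default_cohort):
        _, pairs = default_cohort
        part = partition_pairs(pairs, n_folds=5, seed=3)
        assert part.groupby("pair_id").fold.nunique().eq(1).all()


class TestFitPredict:
    @pytest.mark.parametrize("kind", ["logistic_regression_cv", "ridge_cv",
                                      "random_forest", "mlp"])
    def test_separable_toy_reaches_full_accuracy(self, kind):
        t = make_well_table(n_batches=2, n_layouts=2, n_lines=4, wells_per=3,
                            n_dims=3, seed=1)
        t["disease_state"] = np.where(t.line_id <= 2, "healthy", "PD")
        t["v0"] += np.where(t.line_id <= 2, 0.0, 4.0)  # explicit margin
        keys = list(map(tuple, t[["batch", "plate", "well"]].values))
        train = frozenset(k for k, b in zip(keys, t.batch) if b == 1)
        test = frozenset(k for k, b in zip(keys, t.batch) if b == 2)
        sp = SplitSpec("toy", train, test, "disease_state")
        preds = fit_predict(sp, ModelSpec(kind, seed=0), t)
        pcols = [c for c in preds.columns if c.startswith("p_")]
        assert np.allclose(preds[pcols].sum(axis=1), 1.0, atol=1e-9)
        assert accuracy_and_rank(preds)["accuracy"] == 1.0

    def test_deterministic_given_seed(self, toy_well_table):
        t = toy_well_table
        keys = list(map(tuple, t[["batch", "plate", "well"]].values))
        sp = SplitSpec("d", frozenset(k for k, b in zip(keys, t.batch) if b == 1),
                       frozenset(k for k, b in zip(keys, t.batch) if b == 2),
                       "line_id")
        p1 = fit_predict(sp, ModelSpec("random_forest", seed=5), t)
        p2 = fit_predict(sp, ModelSpec("random_forest", seed=5), t)
        pd.testing.assert_frame_equal(p1, p2)

    def test_test_only_class_raises(self, toy_well_table):
        t = toy_well_table.copy()
        keys = list(map(tuple, t[["batch", "plate", "well"]].values))
        t.loc[(t.batch == 2) & (t.line_id == 1), "line_id"] = 99
        sp = SplitSpec("bad", frozenset(k for k, b in zip(keys, t.batch) if b == 1),
                       frozenset(k for k, b in zip(keys, t.batch) if b == 2),
                       "line_id")
        with pytest.raises(ValueError, match="99"):
            fit_predict(sp, ModelSpec("ridge_cv"), t)


class TestAggregationAndRanks:
    def test_mean_of_two_wells(self):
        preds = pd.DataFrame({
            "line_id": [1, 1], "true_label": ["PD", "PD"],
            "p_PD": [0.6, 0.2], "p_healthy": [0.4, 0.8],
        })
        agg = aggregate_line_predictions(preds)
        assert agg.p_PD.iloc[0] == pytest.approx(0.4)
        assert agg.p_healthy.iloc[0] == pytest.approx(0.6)
        assert (agg[["p_PD", "p_healthy"]].sum(axis=1) == 1.0).all()

    def test_rank_1_when_true_class_has_max_probability(self):
        preds = pd.DataFrame({"true_label": ["b"], "p_a": [0.2], "p_b": [0.5],
                              "p_c": [0.3]})
        assert predicted_ranks(preds).tolist() == [1]

    def test_uniform_tie_rank_equals_index_position(self):
        # oracle: brute-force ordering with ties broken by class index
        n = 8
        for true_idx in range(n):
            preds = pd.DataFrame({
                "true_label": [f"c{true_idx}"],
                **{f"p_c{i}": [1.0 / n] for i in range(n)},
            })
            assert predicted_ranks(preds)[0] == true_idx + 1

    def test_accuracy_is_mean_rank1_indicator(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(5), size=40)
        preds = pd.DataFrame({f"p_c{i}": probs[:, i] for i in range(5)})
        preds["true_label"] = [f"c{i % 5}" for i in range(40)]
        out = accuracy_and_rank(preds)
        assert out["accuracy"] == (out["ranks"] == 1).mean()
        assert out["rank_histogram"].sum() == 40

    def test_unknown_label_raises(self):
        preds = pd.DataFrame({"true_label": ["zz"], "p_a": [1.0]})
        with pytest.raises(ValueError, match="zz"):
            predicted_ranks(preds)


class TestRocAuc:
    def test_worked_example_0875(self):
        # 4 PD/control pairs: wins 3.5 of 4
        assert roc_auc([0.9, 0.8, 0.8, 0.3], [1, 1, 0, 0]) == 0.875

    def test_perfect_separation_and_chance(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        rng = np.random.default_rng(1)
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.5
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_agrees_with_bruteforce_pair_counting_up_to_12_lines(self):
        rng = np.random.default_rng(2)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, size=max(1, n // 2), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                bruteforce_auc(scores, labels), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auc([0.5, 0.6], [1, 1])

    def test_subgroup_filtering_keeps_all_controls(self):
        preds = pd.DataFrame({
            "line_id": range(6), "true_label": ["PD", "PD", "PD", "healthy",
                                                "healthy", "healthy"],
            "mutation_group": ["sporadic", "LRRK2", "GBA", "none", "none", "none"],
            "p_PD": [0.9, 0.8, 0.1, 0.3, 0.2, 0.4],
        })
        # LRRK2-only: one PD (0.8) vs three controls, all ranked below
        assert line_level_roc_auc(preds, "LRRK2_only") == 1.0
        assert line_level_roc_auc(preds, "GBA_only") == 0.0


class TestChannelAblation:
    def test_embedding_block_arithmetic(self, micro_wells):
        omit = channel_ablation(micro_wells, "omit", "RNA")
        only = channel_ablation(micro_wells, "only", "RNA")
        n_e = lambda t: sum(c.startswith("e") and c[1:].isdigit()
                            for c in t.columns)
        assert n_e(omit) == 256 and n_e(only) == 64
        omitted = set(micro_wells.columns) - set(omit.columns)
        kept_only = {c for c in only.columns if c.startswith("e")}
        assert omitted | kept_only == {f"e{i:03d}" for i in range(128, 192)} | kept_only
        assert not (omitted & kept_only) or omitted == kept_only

    def test_omit_and_only_partition_channel_columns(self):
        t = pd.DataFrame({
            "batch": [1], "layout": [1],
            "Cells_AreaShape_Area": [1.0],
            "Cells_Intensity_RNA_MeanIntensity": [2.0],
            "Nuclei_Intensity_DAPI_MeanIntensity": [3.0],
        })
        omit = channel_ablation(t, "omit", "RNA")
        only = channel_ablation(t, "only", "RNA")
        assert "Cells_Intensity_RNA_MeanIntensity" not in omit.columns
        assert "Cells_AreaShape_Area" in omit.columns  # channel-free kept
        assert list(c for c in only.columns if "_" in c and "Intensity" in c) == \
            ["Cells_Intensity_RNA_MeanIntensity"]
        assert "Cells_AreaShape_Area" not in only.columns

    def test_unknown_channel_rejected(self, toy_well_table):
        with pytest.raises(ValueError, match="unknown channel"):
            channel_ablation(toy_well_table, "omit", "GFP")


class TestTitration:
    def test_full_request_is_noop(self, toy_well_table):
        t = toy_well_table
        splits = cellline_splits(t)
        sp = splits[0]
        red, tiles = titrate_training(sp, t, wells_per_line=1,
                                      tiles_per_well=None)
        # toy table has exactly 1 training well per line already
        assert red.train_wells == sp.train_wells
        assert tiles is None

    def test_one_well_per_line_gives_one_row_per_class(self, signal_wells):
        splits = cellline_splits(signal_wells)
        red, _ = titrate_training(splits[0], signal_wells, wells_per_line=1,
                                  seed=0)
        meta = signal_wells
        sel = meta[[tuple(r) in red.train_wells
                    for r in meta[["batch", "plate", "well"]].values]]
        assert len(sel) == 96 and sel.line_id.nunique() == 96

    def test_nested_subsets_for_increasing_k(self, signal_wells):
        splits = cellline_splits(signal_wells)
        prev = None
        for k in (1, 2):
            red, _ = titrate_training(splits[0], signal_wells,
                                      wells_per_line=k, seed=3)
            if prev is not None:
                assert prev <= red.train_wells
            prev = red.train_wells

    def test_requesting_too_many_raises_with_counts(self, toy_well_table):
        splits = cellline_splits(toy_well_table)
        with pytest.raises(ValueError, match="only"):
            titrate_training(splits[0], toy_well_table, wells_per_line=5)

    def test_tile_subsampling_is_nested(self, toy_well_table):
        splits = cellline_splits(toy_well_table)
        r1, m1 = titrate_training(splits[0], toy_well_table, tiles_per_well=2,
                                  n_tiles_available=6, seed=1)
        r2, m2 = titrate_training(splits[0], toy_well_table, tiles_per_well=4,
                                  n_tiles_available=6, seed=1)
        for k in m1:
            assert set(m1[k]) <= set(m2[k])


class TestDesignBiasCheck:
    def test_permuted_labels_select_nothing_in_most_seeds(self):
        """Null simulation: independent replicates of random design covariates
        with permuted labels select no covariate in >= 9 of 10 seeds."""
        clean = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cov = pd.DataFrame(
                rng.integers(0, 2, size=(96, 8)).astype(float),
                columns=[f"c{i}" for i in range(8)])
            labels = rng.permutation([0, 1] * 48)
            report = design_bias_check(cov, labels, seed=seed)
            if not report.selected.any():
                clean += 1
        assert clean >= 9

    def test_planted_confound_is_selected(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame(rng.integers(0, 2, size=(96, 6)).astype(float),
                           columns=[f"c{i}" for i in range(6)])
        labels = cov["c2"].to_numpy()  # disease identical to covariate 2
        report = design_bias_check(cov, labels, seed=0)
        assert report.loc[report.covariate == "c2", "selected"].iloc[0]

    def test_balanced_default_design_has_no_plate_location_bias(
            self, default_cohort, default_layouts):
        lines, _ = default_cohort
        l1, l2 = default_layouts
        rows = []
        for ln in lines:
            pos = well_position_covariates(
                pd.Series([l1.well_of(ln.line_id), l2.well_of(ln.line_id)]))
            merged = pos.mean()  # across the two layouts
            rows.append({**merged.to_dict(),
                         "age_over_64": float(ln.age > 64),
                         "sex_M": float(ln.sex == "M"),
                         "y": float(ln.disease_state == "PD")})
        df = pd.DataFrame(rows)
        report = design_bias_check(df.drop(columns="y"), df.y, seed=0)
        pos_cols = [c for c in report.covariate
                    if c.startswith(("pos_", "row_", "col_"))]
        sel = report[report.covariate.isin(pos_cols)]
        assert not sel.selected.any()

    def test_constant_covariates_dropped_with_zero_weight(self):
        cov = pd.DataFrame({"c0": [1.0] * 20,
                            "c1": np.r_[np.zeros(10), np.ones(10)]})
        labels = np.r_[np.zeros(10), np.ones(10)]
        report = design_bias_check(cov, labels, seed=0)
        row = report[report.covariate == "c0"].iloc[0]
        assert row.weight == 0.0 and not row.selected
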