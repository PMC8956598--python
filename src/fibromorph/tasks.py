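"""Classification tasks over well-level profiles.

Three tasks mirror the study design:

* 96-way **cell line identification** with held-out batch *and* plate layout
  (train on the other batches with the other layout) — measures whether
  line-specific morphology generalizes across acquisition conditions.
* 91-way **biopsy donor identification**: train on one biopsy per donor, test
  on the repeat donors' counterpart biopsies in a held-out batch+layout.
* Binary **disease classification** over demographically matched PD/control
  pairs assigned whole to 5 balanced folds, scored by line-level ROC AUC.

Predictions are probability vectors per test well; line-level predictions are
the per-line mean of well probability vectors.  The module also provides
channel ablation, training-set titration and the lasso design-bias check, and
exposes statsmodels-style Model/Results wrappers (:class:`LineIdentification`,
:class:`DonorIdentification`, :class:`DiseaseClassification`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import (LassoCV, LogisticRegression,
                                  LogisticRegressionCV, RidgeClassifierCV)
from sklearn.neural_network import MLPClassifier

from .cohort import CHANNELS, well_coords
from .embeddings import channel_block, embedding_columns
from .features import FeatureName
from .profiles import value_columns

WELL_KEY = ["batch", "plate", "well"]


def well_key(row) -> tuple:
    return (int(row["batch"]), int(row["plate"]), row["well"])


def _keys(df: pd.DataFrame) -> pd.Series:
    return pd.Series(list(map(tuple, df[WELL_KEY].itertuples(index=False))),
                     index=df.index)


@dataclass(frozen=True)
class SplitSpec:
    """A named train/test partition of wells with its task labels."""

    name: str
    train_wells: frozenset
    test_wells: frozenset
    label_col: str
    held_out: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.train_wells & self.test_wells:
            raise ValueError(f"split {self.name}: train and test wells overlap")


class SplitError(ValueError):
    pass


def cellline_splits(well_meta: pd.DataFrame) -> list[SplitSpec]:
    """One split per (held-out batch, held-out layout): test on that batch and
    layout, train on the other batches with the other layout."""
    batches = sorted(well_meta["batch"].unique())
    layouts = sorted(well_meta["layout"].unique())
    if len(batches) < 2:
        raise SplitError("cell line task needs >= 2 batches; only one present")
    if len(layouts) < 2:
        raise SplitError("cell line task needs >= 2 plate layouts; only one present")
    keys = _keys(well_meta)
    splits = []
    for b in batches:
        for l in layouts:
            test = (well_meta["batch"] == b) & (well_meta["layout"] == l)
            train = (well_meta["batch"] != b) & (well_meta["layout"] != l)
            splits.append(SplitSpec(
                name=f"line_heldout_b{b}_l{l}",
                train_wells=frozenset(keys[train]),
                test_wells=frozenset(keys[test]),
                label_col="line_id",
                held_out={"batch": int(b), "layout": int(l)},
            ))
    return splits


def donor_splits(well_meta: pd.DataFrame) -> list[SplitSpec]:
    """Held-out-line donor splits: for each biopsy role r and each held-out
    (batch, layout), train on every donor's biopsy-r line (other batches,
    other layout) and test on the repeat donors' counterpart-biopsy lines in
    the held-out batch+layout."""
    lines = well_meta[["line_id", "donor_id", "biopsy_index"]].drop_duplicates()
    per_donor = lines.groupby("donor_id")["line_id"].nunique()
    repeat_donors = set(per_donor[per_donor > 1].index)
    if not repeat_donors:
        raise SplitError("no repeat-biopsy donors present in metadata")
    batches = sorted(well_meta["batch"].unique())
    layouts = sorted(well_meta["layout"].unique())
    if len(batches) < 2 or len(layouts) < 2:
        raise SplitError("donor task needs >= 2 batches and >= 2 layouts")
    keys = _keys(well_meta)
    splits = []
    for role, counter in ((1, 2), (2, 1)):
        train_lines = set(
            lines.loc[
                (~lines.donor_id.isin(repeat_donors) & (lines.biopsy_index == 1))
                | (lines.donor_id.isin(repeat_donors) & (lines.biopsy_index == role)),
                "line_id"]
        )
        test_lines = set(
            lines.loc[lines.donor_id.isin(repeat_donors)
                      & (lines.biopsy_index == counter), "line_id"]
        )
        # guard: a donor must never appear twice among training lines
        tl = lines[lines.line_id.isin(train_lines)]
        if tl["donor_id"].duplicated().any():
            raise SplitError("a donor has both biopsies in the training lines")
        for b in batches:
            for l in layouts:
                train = ((well_meta["batch"] != b) & (well_meta["layout"] != l)
                         & well_meta["line_id"].isin(train_lines))
                test = ((well_meta["batch"] == b) & (well_meta["layout"] == l)
                        & well_meta["line_id"].isin(test_lines))
                splits.append(SplitSpec(
                    name=f"donor_biopsy{role}_heldout_b{b}_l{l}",
                    train_wells=frozenset(keys[train]),
                    test_wells=frozenset(keys[test]),
                    label_col="donor_id",
                    held_out={"batch": int(b), "layout": int(l),
                              "test_biopsy": counter},
                ))
    return splits


def partition_pairs(pairs: pd.DataFrame, n_folds: int = 5,
                    include_gba: bool = False, seed: int = 0) -> pd.DataFrame:
    """Greedy balanced assignment of whole matched pairs to folds.

    Familial-PD pairs are dealt first so per-fold mutation counts differ by at
    most one; remaining pairs go to the emptiest fold, tie-broken by sex then
    age-mean balance.  Returns ``pairs`` with a ``fold`` column.
    """
    sel = pairs if include_gba else pairs[pairs.mutation_group != "GBA"]
    sel = sel.copy()
    rng = np.random.default_rng(seed)
    folds = {k: [] for k in range(n_folds)}

    def fold_stats(k):
        rows = folds[k]
        n = len(rows)
        n_m = sum(1 for r in rows if r.sex == "M")
        ages = [r.age_pd for r in rows]
        return n, n_m, (np.mean(ages) if ages else 0.0)

    for grp in ("LRRK2", "GBA", "sporadic"):
        rows = [r for r in sel.itertuples(index=False) if r.mutation_group == grp]
        order = rng.permutation(len(rows))
        for i in order:
            r = rows[i]
            counts = {k: sum(1 for x in folds[k] if x.mutation_group == grp)
                      for k in folds}
            sizes = {k: len(folds[k]) for k in folds}
            best = min(folds, key=lambda k: (
                counts[k], sizes[k],
                abs(fold_stats(k)[1] - sizes[k] / 2),
                k))
            folds[best].append(r)
    assign = {}
    for k, rows in folds.items():
        for r in rows:
            assign[r.pair_id] = k
    out = sel.copy()
    out["fold"] = out["pair_id"].map(assign)
    return out


def disease_folds(pairs: pd.DataFrame, well_meta: pd.DataFrame,
                  n_folds: int = 5, include_gba: bool = False,
                  seed: int = 0) -> list[SplitSpec]:
    """5-fold cross-validation over matched pairs: test on the held-out fold's
    lines (all batches and layouts), train on the rest.  Second-biopsy lines
    are excluded so held-out donors never leak into training."""
    part = partition_pairs(pairs, n_folds, include_gba, seed)
    line_fold = {}
    for r in part.itertuples(index=False):
        line_fold[r.healthy_line_id] = r.fold
        line_fold[r.pd_line_id] = r.fold
    usable = well_meta[(well_meta["biopsy_index"] == 1)
                       & well_meta["line_id"].isin(line_fold)]
    keys = _keys(usable)
    fold_of = usable["line_id"].map(line_fold)
    splits = []
    for k in range(n_folds):
        test = fold_of == k
        train = ~test
        splits.append(SplitSpec(
            name=f"disease_fold{k}",
            train_wells=frozenset(keys[train.to_numpy()]),
            test_wells=frozenset(keys[test.to_numpy()]),
            label_col="disease_state",
            held_out={"fold": k},
        ))
    return splits


# ---------------------------------------------------------------------------
# models

MODEL_KINDS = ("logistic_regression_cv", "ridge_cv", "random_forest", "mlp")


@dataclass(frozen=True)
class ModelSpec:
    kind: str = "logistic_regression_cv"
    seed: int = 0

    def build(self, min_class_count: int | None = None):
        if self.kind == "logistic_regression_cv":
            # the inner CV for the penalty needs >= 2 examples per class;
            # with fewer, fall back to a fixed unit penalty
            inner = min(3, min_class_count or 3)
            if inner < 2:
                return LogisticRegression(C=1.0, max_iter=1_000_000,
                                          random_state=self.seed)
            return LogisticRegressionCV(Cs=np.logspace(-2, 2, 5), cv=inner,
                                        max_iter=1_000_000, random_state=self.seed)
        if self.kind == "ridge_cv":
            return RidgeClassifierCV(alphas=np.logspace(-2, 3, 6))
        if self.kind == "random_forest":
            return RandomForestClassifier(n_estimators=100, random_state=self.seed)
        if self.kind == "mlp":
            return MLPClassifier(hidden_layer_sizes=(200,), max_iter=100_000,
                                 random_state=self.seed)
        raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def fit_predict(split: SplitSpec, model: ModelSpec, table: pd.DataFrame,
                return_model: bool = False):
    """Fit on the split's train wells, emit class-probability rows for the
    test wells.

    Ridge decision values are mapped to probabilities by a softmax over the
    per-class scores.  Returns a DataFrame with the metadata columns, a
    ``true_label`` column and one ``p_<class>`` column per training class.
    """
    keys = _keys(table)
    train = table[keys.isin(split.train_wells)]
    test = table[keys.isin(split.test_wells)]
    if train.empty or test.empty:
        raise ValueError(f"split {split.name}: empty train or test set")
    vcols = value_columns(table)
    classes = np.array(sorted(train[split.label_col].unique()))
    missing = set(test[split.label_col].unique()) - set(classes.tolist())
    if missing:
        raise ValueError(
            f"split {split.name}: labels {sorted(missing)} in test but not train")
    min_count = int(train[split.label_col].value_counts().min())
    est = model.build(min_class_count=min_count)
    est.fit(train[vcols].to_numpy(), train[split.label_col].to_numpy())
    X = test[vcols].to_numpy()
    if hasattr(est, "predict_proba"):
        probs = est.predict_proba(X)
    else:
        scores = est.decision_function(X)
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
        probs = _softmax(scores)
    order = np.argsort(est.classes_)
    # est.classes_ are sorted already for numeric/str labels; keep aligned
    probs = probs[:, order]
    classes = est.classes_[order]
    out = test[[c for c in table.columns if c not in vcols]].copy()
    out["true_label"] = test[split.label_col].to_numpy()
    for i, c in enumerate(classes):
        out[f"p_{c}"] = probs[:, i]
    if return_model:
        return out, est
    return out


def prob_columns(preds: pd.DataFrame) -> list[str]:
    return [c for c in preds.columns if c.startswith("p_")]


def aggregate_line_predictions(preds: pd.DataFrame,
                               by: str = "line_id") -> pd.DataFrame:
    """Per-line (or per-donor) elementwise mean of well probability vectors."""
    pcols = prob_columns(preds)
    agg = {c: "mean" for c in pcols}
    agg["true_label"] = "first"
    keep = [c for c in ("donor_id", "disease_state", "mutation_group", "pair_id")
            if c in preds.columns and c != by]
    agg.update({c: "first" for c in keep})
    return preds.groupby(by, as_index=False).agg(agg)


def predicted_ranks(preds: pd.DataFrame) -> np.ndarray:
    """Predicted rank of the true class per row: 1 + the number of classes
    with strictly greater probability, plus the number of equal-probability
    classes that precede the true class in class-index order (deterministic
    tie-break)."""
    pcols = prob_columns(preds)
    class_names = [c[2:] for c in pcols]
    probs = preds[pcols].to_numpy()
    ranks = np.zeros(len(preds), dtype=int)
    for i, true in enumerate(preds["true_label"].astype(str)):
        if true not in class_names:
            raise ValueError(f"unknown label {true!r}")
        j = class_names.index(true)
        p = probs[i]
        greater = int((p > p[j]).sum())
        tied_before = int(sum(1 for k in range(j) if p[k] == p[j]))
        ranks[i] = 1 + greater + tied_before
    return ranks


def accuracy_and_rank(preds: pd.DataFrame) -> dict:
    """Accuracy (fraction with rank 1) and the predicted-rank histogram."""
    ranks = predicted_ranks(preds)
    n_classes = len(prob_columns(preds))
    hist = np.bincount(ranks, minlength=n_classes + 1)[1:]
    return {"accuracy": float((ranks == 1).mean()),
            "ranks": ranks, "rank_histogram": hist}


def roc_auc(scores, labels) -> float:
    """ROC AUC by midrank: equals exhaustive pair counting with 0.5 credit
    for ties.  Raises if only one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC AUC undefined: only one class present")
    r = rankdata(scores)
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


SUBGROUPS = ("all_PD", "sporadic_only", "LRRK2_only", "GBA_only")


def line_level_roc_auc(line_preds: pd.DataFrame, subgroup: str = "all_PD") -> float:
    """Line-level AUC of P(PD) scores; PD lines restricted to the subgroup,
    all controls retained."""
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    is_pd = line_preds["true_label"].astype(str) == "PD"
    grp = line_preds["mutation_group"].astype(str)
    if subgroup == "all_PD":
        keep = ~is_pd | grp.isin(["sporadic", "LRRK2"])
    elif subgroup == "sporadic_only":
        keep = ~is_pd | (grp == "sporadic")
    elif subgroup == "LRRK2_only":
        keep = ~is_pd | (grp == "LRRK2")
    else:
        keep = ~is_pd | (grp == "GBA")
    sel = line_preds[keep]
    return roc_auc(sel["p_PD"].to_numpy(), sel["true_label"].astype(str) == "PD")


# ---------------------------------------------------------------------------
# ablation / titration / bias check


def channel_ablation(table: pd.DataFrame, mode: str, channel: str) -> pd.DataFrame:
    """Drop (``omit``) or isolate (``only``) one Cell Painting channel.

    Embedding tables lose/keep the channel's 64-block (320 -> 256 or 64);
    engineered tables lose/keep the columns whose FeatureName channel matches.
    Channel-free columns (e.g. shape) are kept under ``omit`` and dropped
    under ``only``.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if mode not in ("omit", "only"):
        raise ValueError("mode must be 'omit' or 'only'")
    vcols = value_columns(table)
    ecols = embedding_columns()
    if set(ecols) <= set(vcols):
        block = channel_block(channel)
        block_cols = ecols[block.start:block.stop]
        drop = block_cols if mode == "omit" else [c for c in ecols
                                                  if c not in block_cols]
        return table.drop(columns=drop)
    drop = []
    for c in vcols:
        try:
            fn = FeatureName.parse(c)
        except ValueError:
            continue
        if mode == "omit" and fn.channel == channel:
            drop.append(c)
        elif mode == "only" and fn.channel != channel:
            drop.append(c)
    return table.drop(columns=drop)


def titrate_training(split: SplitSpec, well_meta: pd.DataFrame,
                     wells_per_line: int | None = None,
                     tiles_per_well: int | None = None,
                     n_tiles_available: int | None = None,
                     seed: int = 0):
    """Seeded reduction of the training side of a split.

    Training wells are subsampled per line through a fixed seeded permutation
    (so the k-well set is nested in the (k+1)-well set for the same seed);
    ``tiles_per_well`` likewise selects a nested subset of the tile indices
    contributing to each retained training well's mean.  The test side is
    untouched.  Returns ``(reduced split, {well_key: [tile indices]})``;
    the tile map is ``None`` when tiles are not subsampled.
    """
    keys = _keys(well_meta)
    train_meta = well_meta[keys.isin(split.train_wells)]
    new_train = set(split.train_wells)
    if wells_per_line is not None:
        new_train = set()
        for line, grp in train_meta.groupby("line_id"):
            wells = sorted(map(tuple, grp[WELL_KEY].itertuples(index=False)))
            if wells_per_line > len(wells):
                raise ValueError(
                    f"requested {wells_per_line} wells/line but line {line} has "
                    f"only {len(wells)} training wells")
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(int(line),)))
            order = rng.permutation(len(wells))
            new_train |= {wells[i] for i in order[:wells_per_line]}
    tile_map = None
    if tiles_per_well is not None:
        if n_tiles_available is None:
            raise ValueError("tiles_per_well requires n_tiles_available")
        if tiles_per_well > n_tiles_available:
            raise ValueError(
                f"requested {tiles_per_well} tiles/well but only "
                f"{n_tiles_available} are available")
        tile_map = {}
        for wk in sorted(new_train):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(hash(wk) % (2 ** 31),)))
            order = rng.permutation(n_tiles_available)
            tile_map[wk] = sorted(order[:tiles_per_well].tolist())
    reduced = SplitSpec(
        name=f"{split.name}_titrated",
        train_wells=frozenset(new_train),
        test_wells=split.test_wells,
        label_col=split.label_col,
        held_out=dict(split.held_out),
    )
    return reduced, tile_map


def well_position_covariates(wells: pd.Series) -> pd.DataFrame:
    """Plate-location one-hots for a series of well names: edge/corner/center
    flags plus row-pair and column-triplet groups."""
    rows, cols = zip(*(well_coords(w) for w in wells))
    rows = np.array(rows)
    cols = np.array(cols)
    edge = (rows == 0) | (rows == 7) | (cols == 0) | (cols == 11)
    corner = ((rows == 0) | (rows == 7)) & ((cols == 0) | (cols == 11))
    out = pd.DataFrame({
        "pos_edge": edge.astype(float),
        "pos_corner": corner.astype(float),
        "pos_center": (~edge).astype(float),
    }, index=wells.index)
    for i, pair in enumerate(("AB", "CD", "EF", "GH")):
        out[f"row_{pair}"] = np.isin(rows // 2, [i]).astype(float)
    for i in range(4):
        out[f"col_{3 * i + 1}to{3 * i + 3}"] = np.isin(cols // 3, [i]).astype(float)
    return out


def design_bias_check(covariates: pd.DataFrame, labels, seed: int = 0) -> pd.DataFrame:
    """Cross-validated L1-regularized linear regression of disease state on
    design covariates; returns the covariate weight report (a balanced design
    should select nothing).

    The penalty follows the one-standard-error rule — the largest alpha whose
    cross-validated error is within one SE of the minimum — the conservative
    convention for variable selection, so pure-noise covariates are selected
    only rarely while a genuine confound survives easily.
    """
    from sklearn.linear_model import Lasso

    X = covariates.copy()
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    X = X[keep]
    y = np.asarray(labels, dtype=float)
    cvm = LassoCV(cv=5, random_state=seed)
    cvm.fit(X.to_numpy(), y)
    mean_mse = cvm.mse_path_.mean(axis=1)
    se = cvm.mse_path_.std(axis=1, ddof=1) / np.sqrt(cvm.mse_path_.shape[1])
    i_min = int(np.argmin(mean_mse))
    within = mean_mse <= mean_mse[i_min] + se[i_min]
    alpha_1se = float(cvm.alphas_[within].max())
    model = Lasso(alpha=alpha_1se, max_iter=100_000)
    model.fit(X.to_numpy(), y)
    report = pd.DataFrame({
        "covariate": keep,
        "weight": model.coef_,
        "selected": model.coef_ != 0,
    })
    for c in dropped:
        report.loc[len(report)] = [c, 0.0, False]
    report.attrs["alpha"] = alpha_1se
    return report


# ---------------------------------------------------------------------------
# statsmodels-style task models


@dataclass
class SplitResult:
    name: str
    well_accuracy: float
    line_accuracy: float
    rank_histogram: np.ndarray
    line_ranks: np.ndarray
    predictions: pd.DataFrame


class _TaskResults:
    """Base Results object: per-split metrics + mean/SD summaries."""

    def __init__(self, model, splits_results):
        self.model = model
        self.splits = splits_results

    def summary(self) -> str:  # pragma: no cover - formatting
        raise NotImplementedError


class LineIdentificationResults(_TaskResults):
    @property
    def well_accuracies(self):
        return np.array([s.well_accuracy for s in self.splits])

    @property
    def line_accuracies(self):
        return np.array([s.line_accuracy for s in self.splits])

    @property
    def rank_histogram(self):
        return np.sum([s.rank_histogram for s in self.splits], axis=0)

    def summary(self) -> str:
        la, wa = self.line_accuracies, self.well_accuracies
        lines = [
            "Cell line identification (held-out batch + plate layout)",
            f"  model: {self.model.model_spec.kind}   splits: {len(self.splits)}",
            f"  line-level accuracy: {la.mean():.3f} ({la.std():.3f} SD)",
            f"  well-level accuracy: {wa.mean():.3f} ({wa.std():.3f} SD)",
            f"  chance: {1.0 / max(len(self.splits[0].rank_histogram), 1):.4f}",
        ]
        return "\n".join(lines)


class LineIdentification:
    """96-way line identification with held-out batch and layout.

    Parameters
    ----------
    table : well-level profile table (metadata + value columns).
    model : ModelSpec or model-kind string.
    """

    def __init__(self, table: pd.DataFrame, model="logistic_regression_cv",
                 seed: int = 0):
        self.table = table
        self.model_spec = (model if isinstance(model, ModelSpec)
                           else ModelSpec(model, seed))
        self.splits = cellline_splits(table)

    def fit(self) -> LineIdentificationResults:
        results = []
        for sp in self.splits:
            preds = fit_predict(sp, self.model_spec, self.table)
            well = accuracy_and_rank(preds)
            line_preds = aggregate_line_predictions(preds, by="line_id")
            line = accuracy_and_rank(line_preds)
            results.append(SplitResult(sp.name, well["accuracy"], line["accuracy"],
                                       line["rank_histogram"], line["ranks"],
                                       preds))
        return LineIdentificationResults(self, results)


class DonorIdentificationResults(_TaskResults):
    @property
    def line_accuracies(self):
        return np.array([s.line_accuracy for s in self.splits])

    @property
    def heldout_ranks(self) -> np.ndarray:
        """Predicted ranks of every held-out counterpart biopsy, all splits."""
        return np.concatenate([s.line_ranks for s in self.splits])

    def summary(self) -> str:
        r = self.heldout_ranks
        la = self.line_accuracies
        return "\n".join([
            "Biopsy donor identification (held-out lines, batch and layout)",
            f"  model: {self.model.model_spec.kind}   splits: {len(self.splits)}",
            f"  line-level accuracy: {la.mean():.3f} ({la.std():.3f} SD)",
            f"  held-out biopsy mean predicted rank: {r.mean():.1f} of "
            f"{len(prob_columns(self.splits[0].predictions))} (chance "
            f"{(len(prob_columns(self.splits[0].predictions)) + 1) / 2:.1f})",
        ])


class DonorIdentification:
    """91-way donor identification tested on held-out repeat biopsies."""

    def __init__(self, table: pd.DataFrame, model="logistic_regression_cv",
                 seed: int = 0):
        self.table = table
        self.model_spec = (model if isinstance(model, ModelSpec)
                           else ModelSpec(model, seed))
        self.splits = donor_splits(table)

    def fit(self) -> DonorIdentificationResults:
        results = []
        for sp in self.splits:
            preds = fit_predict(sp, self.model_spec, self.table)
            well = accuracy_and_rank(preds)
            line_preds = aggregate_line_predictions(preds, by="line_id")
            line = accuracy_and_rank(line_preds)
            results.append(SplitResult(sp.name, well["accuracy"], line["accuracy"],
                                       line["rank_histogram"], line["ranks"], preds))
        return DonorIdentificationResults(self, results)


class DiseaseClassificationResults(_TaskResults):
    def __init__(self, model, fold_aucs: pd.DataFrame, predictions):
        super().__init__(model, [])
        self.fold_aucs = fold_aucs
        self.predictions = predictions

    def mean_auc(self, subgroup: str = "all_PD") -> float:
        return float(self.fold_aucs[subgroup].mean())

    def sd_auc(self, subgroup: str = "all_PD") -> float:
        return float(self.fold_aucs[subgroup].std(ddof=0))

    def summary(self) -> str:
        lines = ["PD vs healthy classification (held-out matched pairs, "
                 f"{len(self.fold_aucs)} folds)",
                 f"  model: {self.model.model_spec.kind}"]
        for sg in self.fold_aucs.columns:
            vals = self.fold_aucs[sg].dropna()
            if len(vals):
                lines.append(f"  line-level ROC AUC [{sg}]: {vals.mean():.3f} "
                             f"({vals.std(ddof=0):.3f} SD)")
        return "\n".join(lines)


class DiseaseClassification:
    """Matched-pair PD vs healthy classification scored by line-level AUC."""

    def __init__(self, table: pd.DataFrame, pairs: pd.DataFrame,
                 model="logistic_regression_cv", n_folds: int = 5,
                 include_gba: bool = False, seed: int = 0):
        self.table = table
        self.pairs = pairs
        self.model_spec = (model if isinstance(model, ModelSpec)
                           else ModelSpec(model, seed))
        self.splits = disease_folds(pairs, table, n_folds, include_gba, seed)

    def fit(self) -> DiseaseClassificationResults:
        rows = []
        all_preds = []
        subgroups = ["all_PD", "sporadic_only", "LRRK2_only"]
        for sp in self.splits:
            preds = fit_predict(sp, self.model_spec, self.table)
            line_preds = aggregate_line_predictions(preds, by="line_id")
            all_preds.append(line_preds)
            row = {"fold": sp.held_out["fold"]}
            for sg in subgroups:
                try:
                    row[sg] = line_level_roc_auc(line_preds, sg)
                except ValueError:
                    row[sg] = np.nan
            rows.append(row)
        fold_aucs = pd.DataFrame(rows).set_index("fold")
        return DiseaseClassificationResults(self, fold_aucs, all_preds)
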