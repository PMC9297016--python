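"""Random-forest tests for group and individual vocal signatures.

Two leakage-proof cross-validation schemes over a per-call feature table:

* clan scheme — hold out one randomly chosen caller per clan, so no caller's
  calls appear in both train and test; accuracy then reflects only features
  that generalize across individuals within a clan (a true group signature).
* individual scheme — hold out one whole bout per caller, so within-bout
  autocorrelation cannot leak identity; accuracy reflects stable
  between-bout individual signatures.

Chance performance is the weighted expectation (WE): the accuracy of a
guesser drawing labels from the training class distribution, evaluated on
the test composition, WE = sum_c f_train(c) * f_test(c). Feature importance
is test-set permutation importance (mean decrease in held-out accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES

__all__ = [
    "SplitSpec",
    "RepeatResult",
    "CVSummary",
    "filter_adults",
    "prepare_individual_dataset",
    "subset_types",
    "clan_split",
    "bout_split",
    "train_forest",
    "VoteForest",
    "weighted_expectation",
    "run_repeats",
    "feature_importance",
]


@dataclass(frozen=True)
class SplitSpec:
    """Cross-validation scheme settings."""

    scheme: str = "individual"    # "clan" | "individual"
    n_repeats: int = 1000
    n_trees: int = 500
    seed: int = 0
    #: None -> composition-weighted WE (default); "uniform" -> 1/K chance
    we_mode: str = "weighted"

    def __post_init__(self):
        if self.scheme not in ("clan", "individual"):
            raise ValueError("scheme must be 'clan' or 'individual'")
        if self.n_repeats < 1 or self.n_trees < 1:
            raise ValueError("n_repeats and n_trees must be >= 1")
        if self.we_mode not in ("weighted", "uniform"):
            raise ValueError("we_mode must be 'weighted' or 'uniform'")


@dataclass
class RepeatResult:
    index: int
    accuracy: float
    weighted_expectation: float
    confusion: pd.DataFrame
    per_class_accuracy: pd.Series
    #: optional per-bout vote fractions for redundancy analysis:
    #: {bout_id: (true_caller, votes[n_whoops, n_classes] in bout order)}
    bout_votes: Optional[dict] = None
    classes: Optional[np.ndarray] = None


@dataclass
class CVSummary:
    scheme: str
    target: str
    n_repeats: int
    mean_accuracy: float
    sd_accuracy: float
    mean_we: float
    pooled_confusion: pd.DataFrame
    per_class_accuracy: pd.Series
    accuracies: np.ndarray
    we_values: np.ndarray
    repeats: Optional[list] = None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "target": self.target,
            "n_repeats": int(self.n_repeats),
            "mean_accuracy": float(self.mean_accuracy),
            "sd_accuracy": float(self.sd_accuracy) if self.n_repeats > 1 else None,
            "mean_we": float(self.mean_we),
            "per_class_accuracy": {str(k): float(v)
                                   for k, v in self.per_class_accuracy.items()},
        }


# ---------------------------------------------------------------- filters

def _require_columns(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")


def drop_failed(table: pd.DataFrame) -> pd.DataFrame:
    """Remove failure-flagged rows and rows with missing feature values."""
    out = table
    if "failed" in out.columns:
        out = out[~out["failed"].astype(bool)]
    feats = [c for c in FEATURE_NAMES if c in out.columns]
    return out.dropna(subset=feats)


def filter_adults(table: pd.DataFrame, min_age_months: int = 24) -> pd.DataFrame:
    """Keep calls from animals at least ``min_age_months`` old (inclusive)."""
    _require_columns(table, ["age_months"])
    out = table[table["age_months"] >= min_age_months]
    if out.empty:
        warnings.warn("adult filter removed every row", stacklevel=2)
    return out


def prepare_individual_dataset(
    table: pd.DataFrame, min_bouts: int = 2, min_whoops_per_bout: int = 3
) -> pd.DataFrame:
    """Keep bouts of >= min_whoops_per_bout calls, then callers with
    >= min_bouts surviving bouts (the individual-scheme entry requirement)."""
    _require_columns(table, ["bout_id", "caller_id"])
    bout_sizes = table.groupby("bout_id")["caller_id"].size()
    good_bouts = bout_sizes[bout_sizes >= min_whoops_per_bout].index
    out = table[table["bout_id"].isin(good_bouts)]
    bouts_per_caller = out.groupby("caller_id")["bout_id"].nunique()
    good_callers = bouts_per_caller[bouts_per_caller >= min_bouts].index
    out = out[out["caller_id"].isin(good_callers)]
    if out["caller_id"].nunique() < 2:
        raise ValueError(
            "classification undefined: fewer than 2 callers survive the "
            f"bout filters (min_bouts={min_bouts}, "
            f"min_whoops_per_bout={min_whoops_per_bout})"
        )
    return out


def subset_types(table: pd.DataFrame, keep: set = frozenset({"A", "S"})) -> pd.DataFrame:
    """Row filter on whoop type."""
    if not keep:
        raise ValueError("keep set must be non-empty")
    _require_columns(table, ["whoop_type"])
    return table[table["whoop_type"].isin(keep)]


# ---------------------------------------------------------------- splits

def clan_split(
    table: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out one randomly selected caller per clan as the test set."""
    _require_columns(table, ["clan_id", "caller_id"])
    test_callers = []
    for clan, grp in table.groupby("clan_id", sort=True):
        callers = np.sort(grp["caller_id"].unique())
        if len(callers) < 2:
            raise ValueError(f"clan {clan!r} has a single caller; cannot split")
        test_callers.append(callers[rng.integers(len(callers))])
    in_test = table["caller_id"].isin(test_callers)
    train, test = table[~in_test], table[in_test]
    assert not set(train["caller_id"]) & set(test["caller_id"]), "caller leakage"
    return train, test


def bout_split(
    table: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out one randomly selected bout per caller as the test set."""
    _require_columns(table, ["bout_id", "caller_id"])
    test_bouts = []
    for caller, grp in table.groupby("caller_id", sort=True):
        bouts = np.sort(grp["bout_id"].unique())
        if len(bouts) < 2:
            raise ValueError(f"caller {caller!r} has a single bout; filter first")
        test_bouts.append(bouts[rng.integers(len(bouts))])
    in_test = table["bout_id"].isin(test_bouts)
    train, test = table[~in_test], table[in_test]
    assert not set(train["bout_id"]) & set(test["bout_id"]), "bout leakage"
    assert set(test["caller_id"]) <= set(train["caller_id"]), "caller missing from train"
    return train, test


# ---------------------------------------------------------------- forest

class VoteForest:
    """Random forest exposing majority-vote predictions and per-class
    tree-vote fractions (fraction of trees voting each class)."""

    def __init__(self, forest: RandomForestClassifier, feature_names: list):
        self.forest = forest
        self.feature_names = list(feature_names)
        self.classes_ = forest.classes_
        # per-tree leaf -> majority-class lookup, so votes come from one
        # vectorised apply() instead of per-tree predict calls
        self._leaf_class = [
            t.tree_.value[:, 0, :].argmax(axis=1) for t in forest.estimators_
        ]

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        return table[self.feature_names].to_numpy(dtype=float)

    def vote_fractions(self, table: pd.DataFrame) -> np.ndarray:
        """[n_rows, n_classes] fraction of trees voting each class."""
        X = self._matrix(table)
        n = X.shape[0]
        counts = np.zeros((n, len(self.classes_)))
        leaves = self.forest.apply(X)  # [n, n_trees]
        rows = np.arange(n)
        for t, lookup in enumerate(self._leaf_class):
            counts[rows, lookup[leaves[:, t]]] += 1
        return counts / len(self._leaf_class)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        votes = self.vote_fractions(table)
        return self.classes_[np.argmax(votes, axis=1)]


def train_forest(
    train: pd.DataFrame,
    spec: SplitSpec,
    target: str,
    random_state: Optional[int] = None,
    feature_names: Optional[list] = None,
) -> VoteForest:
    """Fit the ensemble: n_trees trees, max leaf count = training-set size,
    standard per-split feature subsampling and bootstrap resampling."""
    feats = feature_names or [c for c in FEATURE_NAMES if c in train.columns]
    y = train[target].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set")
    rf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_leaf_nodes=max(len(train), 2),
        max_features="sqrt",
        bootstrap=True,
        random_state=random_state if random_state is not None else spec.seed,
        n_jobs=1,
    )
    rf.fit(train[feats].to_numpy(dtype=float), y)
    return VoteForest(rf, feats)


def weighted_expectation(
    train_labels: Sequence, test_labels: Sequence, mode: str = "weighted"
) -> float:
    """Chance accuracy of a guesser drawing from the training label
    distribution, evaluated on the test composition."""
    tr = pd.Series(list(train_labels))
    te = pd.Series(list(test_labels))
    if tr.empty or te.empty:
        raise ValueError("empty label set")
    if not set(te.unique()) <= set(tr.unique()):
        raise ValueError("test classes must be a subset of train classes")
    if mode == "uniform":
        return 1.0 / tr.nunique()
    f_tr = tr.value_counts(normalize=True)
    f_te = te.value_counts(normalize=True)
    return float((f_tr * f_te).dropna().sum())


# ---------------------------------------------------------------- repeats

def _canonical(table: pd.DataFrame) -> pd.DataFrame:
    """Sort rows by whoop_id so results do not depend on input row order."""
    if "whoop_id" in table.columns:
        return table.sort_values("whoop_id", kind="mergesort").reset_index(drop=True)
    return table.reset_index(drop=True)


def _split(table, scheme, rng):
    return clan_split(table, rng) if scheme == "clan" else bout_split(table, rng)


def run_repeats(
    table: pd.DataFrame,
    spec: SplitSpec,
    target: str,
    collect_votes: bool = False,
    permute_labels: bool = False,
    keep_repeats: bool = False,
) -> CVSummary:
    """Repeat (split -> train -> evaluate -> WE) ``spec.n_repeats`` times.

    ``permute_labels`` shuffles the target within the table once per repeat
    (type-I-error control experiments). ``collect_votes`` stores per-bout
    tree-vote fractions of the test rows, in natural within-bout order, for
    the redundancy analysis. Fully reproducible from (table, spec).
    """
    table = _canonical(drop_failed(table))
    classes = np.sort(table[target].unique())
    class_index = {c: i for i, c in enumerate(classes)}
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    accs = np.empty(spec.n_repeats)
    wes = np.empty(spec.n_repeats)
    repeats: list[RepeatResult] = []
    children = np.random.SeedSequence([spec.seed, 0xC1A55]).spawn(spec.n_repeats)
    for r in range(spec.n_repeats):
        rng = np.random.default_rng(children[r])
        work = table
        if permute_labels:
            # permute the group->label mapping (caller->clan, or bout->caller)
            # so grouping structure survives but labels carry no information
            group = "caller_id" if spec.scheme == "clan" else "bout_id"
            work = table.copy()
            units = table.groupby(group)[target].first()
            new = pd.Series(rng.permutation(units.to_numpy()), index=units.index)
            work[target] = work[group].map(new).to_numpy()
        train, test = _split(work, spec.scheme, rng)
        rf_seed = int(rng.integers(0, 2**31 - 1))
        model = train_forest(train, spec, target, random_state=rf_seed)
        votes = model.vote_fractions(test)
        pred = model.classes_[np.argmax(votes, axis=1)]
        true = test[target].to_numpy()
        accs[r] = float(np.mean(pred == true))
        wes[r] = weighted_expectation(train[target], true, mode=spec.we_mode)
        conf = np.zeros_like(pooled)
        for t, p in zip(true, pred):
            conf[class_index[t], class_index[p]] += 1
        pooled += conf
        if keep_repeats or collect_votes:
            bout_votes = None
            if collect_votes:
                bout_votes = {}
                order = test.sort_values(["bout_id", "position_in_bout"])
                ov = model.vote_fractions(order)
                for bout, grp in order.groupby("bout_id", sort=True):
                    idx = order.index.get_indexer(grp.index)
                    bout_votes[bout] = (grp[target].iloc[0], ov[idx])
            row_sum = conf.sum(axis=1)
            per_class = pd.Series(
                np.divide(np.diag(conf), row_sum, out=np.full(len(classes), np.nan),
                          where=row_sum > 0),
                index=classes,
            )
            repeats.append(RepeatResult(
                index=r, accuracy=accs[r], weighted_expectation=wes[r],
                confusion=pd.DataFrame(conf, index=classes, columns=classes),
                per_class_accuracy=per_class,
                bout_votes=bout_votes, classes=model.classes_,
            ))
    row_sum = pooled.sum(axis=1)
    per_class = pd.Series(
        np.divide(np.diag(pooled), row_sum, out=np.full(len(classes), np.nan),
                  where=row_sum > 0),
        index=classes,
    )
    return CVSummary(
        scheme=spec.scheme,
        target=target,
        n_repeats=spec.n_repeats,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if spec.n_repeats > 1 else 0.0,
        mean_we=float(wes.mean()),
        pooled_confusion=pd.DataFrame(pooled, index=classes, columns=classes),
        per_class_accuracy=per_class,
        accuracies=accs,
        we_values=wes,
        repeats=repeats if (keep_repeats or collect_votes) else None,
    )


def feature_importance(
    table: pd.DataFrame,
    spec: SplitSpec,
    target: str = "caller_id",
    feature_names: Optional[list] = None,
    mode: str = "permutation",
) -> pd.DataFrame:
    """Mean decrease in held-out accuracy per feature, averaged over repeats.

    ``permutation`` (default) shuffles each feature column within the test
    set; ``retrain`` refits the forest without the feature (slower
    cross-check). Returns a table with importance, its standard error over
    repeats and the rank (1 = most important).
    """
    if mode not in ("permutation", "retrain"):
        raise ValueError("mode must be 'permutation' or 'retrain'")
    table = _canonical(drop_failed(table))
    feats = feature_names or [c for c in FEATURE_NAMES if c in table.columns]
    drops = np.zeros((spec.n_repeats, len(feats)))
    children = np.random.SeedSequence([spec.seed, 0x1119]).spawn(spec.n_repeats)
    for r in range(spec.n_repeats):
        rng = np.random.default_rng(children[r])
        train, test = _split(table, spec.scheme, rng)
        rf_seed = int(rng.integers(0, 2**31 - 1))
        model = train_forest(train, spec, target, random_state=rf_seed,
                             feature_names=feats)
        true = test[target].to_numpy()
        base = float(np.mean(model.predict(test) == true))
        for j, f in enumerate(feats):
            if mode == "permutation":
                perm = test.copy()
                perm[f] = rng.permutation(perm[f].to_numpy())
                acc = float(np.mean(model.predict(perm) == true))
            else:
                sub = [c for c in feats if c != f]
                m2 = train_forest(train, spec, target, random_state=rf_seed,
                                  feature_names=sub)
                acc = float(np.mean(m2.predict(test) == true))
            drops[r, j] = base - acc
    imp = pd.DataFrame({
        "feature": feats,
        "importance": drops.mean(axis=0),
        "se": drops.std(axis=0, ddof=1) / np.sqrt(spec.n_repeats)
              if spec.n_repeats > 1 else 0.0,
    })
    imp["rank"] = imp["importance"].rank(ascending=False, method="first").astype(int)
    return imp.sort_values("rank").reset_index(drop=True)
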