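"""Random-Forest tumor-line classification and paired model comparison.

The evaluation design mirrors the study: a forest (default 20,000 trees,
``sqrt(p)`` candidate variables per split) scored by its out-of-bag (OOB)
accuracy, plus repeated 75/25 train/test splits whose train/test membership
is shared across all compared models so that per-split accuracies can be
compared with a paired t-test.  Median imputation fills sporadic missing
cells before modelling.  An exhaustive sweep evaluates every combination of
1..8 of the 9 IHC parameters.

All accuracies are expressed in percent (0-100).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "IHC_PARAMETERS",
    "PET_PARAMETERS",
    "CVScheme",
    "ModelResult",
    "ComparisonResult",
    "median_impute",
    "fit_forest",
    "oob_permutation_importance",
    "make_cv_scheme",
    "evaluate_model",
    "compare_models",
    "parameter_importance",
    "subset_sweep",
]

#: the nine IHC parameters used for the exhaustive subset sweep
IHC_PARAMETERS = ("PIMO", "BrdU", "pAKT", "EGFR", "MCT4", "CA9", "GLUT1",
                  "VD", "PF")

PET_PARAMETERS = ("PET_SUVmax", "PET_SUVmean", "PET_TM")

DEFAULT_N_TREES = 20_000


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def median_impute(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Fill missing cells with the per-column median of observed values.

    Applied to the full table before cross validation, replicating the
    study's order of operations.  Raises on a fully missing column.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in out.columns
                   if c not in ("sample_id", "line")
                   and pd.api.types.is_numeric_dtype(out[c])]
    for col in columns:
        observed = out[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} is fully missing; cannot impute")
        out[col] = out[col].fillna(observed.median())
    return out


# ---------------------------------------------------------------------------
# forests
# ---------------------------------------------------------------------------

def _seed_to_int(seed) -> int | None:
    if seed is None:
        return None
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31 - 1))
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))


def _build_forest(n_trees: int, seed, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",  # floor(sqrt(p)) candidate variables per split
        bootstrap=True,
        oob_score=oob,
        random_state=_seed_to_int(seed),
        n_jobs=1,
    )


def _design(table: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, np.ndarray]:
    missing_cols = [c for c in columns if c not in table.columns]
    if missing_cols:
        raise ValueError(f"columns not in table: {missing_cols}")
    X = table[list(columns)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values; impute first")
    y = table["line"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    return X, y


def fit_forest(table: pd.DataFrame, columns: list[str],
               n_trees: int = DEFAULT_N_TREES, seed: int | None = 0
               ) -> tuple[RandomForestClassifier, float]:
    """Fit a classification forest and return it with its OOB accuracy (%)."""
    if not columns:
        raise ValueError("column set is empty")
    X, y = _design(table, columns)
    forest = _build_forest(n_trees, seed, oob=True)
    forest.fit(X, y)
    return forest, 100.0 * float(forest.oob_score_)


def _oob_indices(tree, n_samples: int) -> np.ndarray:
    """Out-of-bag sample indices for one fitted tree.

    Replays scikit-learn's bootstrap draw (``randint(0, n, n)`` from the
    tree's random state) to find the samples the tree never saw.
    """
    rng = np.random.RandomState(tree.random_state)
    sampled = rng.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


def oob_permutation_importance(forest: RandomForestClassifier, X: np.ndarray,
                               y: np.ndarray, seed: int | None = 0) -> np.ndarray:
    """Mean decrease in OOB accuracy when permuting each column.

    For every tree, accuracy on its out-of-bag samples is compared with the
    accuracy after permuting one column among those samples; the decrease is
    averaged over trees (the forest-native importance estimator).  Returned
    in percentage points, one value per column.
    """
    n_samples, n_cols = X.shape
    rng = np.random.default_rng(seed)
    decreases = np.zeros((len(forest.estimators_), n_cols))
    counted = np.zeros(len(forest.estimators_), dtype=bool)
    for t, tree in enumerate(forest.estimators_):
        oob = _oob_indices(tree, n_samples)
        if oob.size == 0:
            continue
        counted[t] = True
        y_oob = y[oob]
        # trees are trained on class indices; map back through classes_
        pred = forest.classes_[tree.predict(X[oob]).astype(int)]
        base = np.mean(pred == y_oob)
        for j in range(n_cols):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            perm_pred = forest.classes_[tree.predict(Xp).astype(int)]
            decreases[t, j] = base - np.mean(perm_pred == y_oob)
    if not counted.any():
        raise ValueError("no tree has out-of-bag samples")
    return 100.0 * decreases[counted].mean(axis=0)


def parameter_importance(table: pd.DataFrame, columns: list[str],
                         n_trees: int = DEFAULT_N_TREES, seed: int | None = 0
                         ) -> pd.Series:
    """Per-parameter decrease in classification accuracy (Fig 2E analog).

    Fits one forest and computes OOB permutation importance; returns a
    Series (percentage points) indexed by column name.
    """
    forest, _ = fit_forest(table, columns, n_trees=n_trees, seed=seed)
    X, y = _design(table, columns)
    imp = oob_permutation_importance(forest, X, y, seed=seed)
    return pd.Series(imp, index=list(columns), name="accuracy_decrease")


# ---------------------------------------------------------------------------
# shared-split cross validation
# ---------------------------------------------------------------------------

@dataclass
class CVScheme:
    """An ordered list of train/test partitions shared across models."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    n_repeats: int
    train_fraction: float
    seed: int | None
    stratified: bool = True

    def fingerprint(self) -> str:
        """Stable digest of the split membership, used to verify pairing."""
        import hashlib

        h = hashlib.sha256()
        for train, test in self.splits:
            h.update(np.asarray(train, dtype=np.int64).tobytes())
            h.update(b"|")
            h.update(np.asarray(test, dtype=np.int64).tobytes())
            h.update(b";")
        return h.hexdigest()

    def to_json(self) -> str:
        return json.dumps({
            "n_repeats": self.n_repeats,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "stratified": self.stratified,
            "splits": [[train.tolist(), test.tolist()] for train, test in self.splits],
        })

    @classmethod
    def from_json(cls, text: str) -> "CVScheme":
        obj = json.loads(text)
        splits = [(np.asarray(tr, dtype=int), np.asarray(te, dtype=int))
                  for tr, te in obj["splits"]]
        return cls(splits=splits, n_repeats=obj["n_repeats"],
                   train_fraction=obj["train_fraction"], seed=obj["seed"],
                   stratified=obj["stratified"])


def _stratified_split(labels: np.ndarray, n_train: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Largest-remainder proportional allocation of the train quota across
    classes, with at least one training sample per class."""
    classes, inverse = np.unique(labels, return_inverse=True)
    counts = np.bincount(inverse)
    exact = counts * n_train / counts.sum()
    base = np.maximum(np.floor(exact).astype(int), 1)
    base = np.minimum(base, counts)
    shortfall = n_train - base.sum()
    order = np.argsort(-(exact - np.floor(exact)))
    i = 0
    while shortfall != 0 and i < 10 * len(classes):
        c = order[i % len(classes)]
        if shortfall > 0 and base[c] < counts[c]:
            base[c] += 1
            shortfall -= 1
        elif shortfall < 0 and base[c] > 1:
            base[c] -= 1
            shortfall += 1
        i += 1
    train_idx = []
    for c in range(len(classes)):
        members = np.flatnonzero(inverse == c)
        perm = rng.permutation(members)
        train_idx.append(perm[:base[c]])
    train = np.sort(np.concatenate(train_idx))
    test = np.setdiff1d(np.arange(len(labels)), train)
    return train, test


def make_cv_scheme(table: pd.DataFrame, n_repeats: int = 1000,
                   train_fraction: float = 0.75, seed: int | None = 0,
                   stratified: bool = True) -> CVScheme:
    """Draw repeated random train/test partitions (default 75%/25%, 1000x).

    With ``stratified=True`` (default) the train quota is spread
    proportionally over the tumor lines so every line appears in training;
    ``stratified=False`` reproduces plain random splitting.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be positive")
    labels = table["line"].to_numpy()
    n = len(labels)
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("train_fraction leaves an empty train or test set")
    if stratified and n_train < len(np.unique(labels)):
        raise ValueError("too few training samples to cover every line")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        if stratified:
            splits.append(_stratified_split(labels, n_train, rng))
        else:
            perm = rng.permutation(n)
            splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return CVScheme(splits=splits, n_repeats=n_repeats,
                    train_fraction=train_fraction, seed=seed,
                    stratified=stratified)


@dataclass
class ModelResult:
    """Accuracy record of one model evaluated on one CV scheme."""

    model_name: str
    columns: tuple[str, ...]
    cv_accuracies: np.ndarray
    oob_accuracy: float | None = None
    scheme_fingerprint: str = ""
    n_trees: int = DEFAULT_N_TREES
    seed: int | None = None

    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.cv_accuracies = np.asarray(self.cv_accuracies, dtype=float)
        if np.any((self.cv_accuracies < 0) | (self.cv_accuracies > 100)):
            raise ValueError("accuracies must lie in [0, 100]")
        self.mean = float(self.cv_accuracies.mean())
        self.sd = float(self.cv_accuracies.std(ddof=1)) if len(self.cv_accuracies) > 1 else 0.0


def evaluate_model(table: pd.DataFrame, columns: list[str], scheme: CVScheme,
                   n_trees: int = DEFAULT_N_TREES, seed: int | None = 0,
                   model_name: str = "model", compute_oob: bool = False) -> ModelResult:
    """Test-set accuracy of a forest on every split of a shared CV scheme.

    One forest per split is trained on the training rows and scored as the
    percentage of test rows classified correctly; lines absent from a
    training split simply score as errors when they occur in the test set.
    The per-split forest seeds derive from ``seed`` and the split index, so
    a rerun with the same scheme and seed is identical.
    """
    if not columns:
        raise ValueError("column subset is empty")
    X, y = _design(table, columns)
    accuracies = np.empty(len(scheme.splits))
    child_seeds = np.random.SeedSequence(seed).spawn(len(scheme.splits))
    for i, (train, test) in enumerate(scheme.splits):
        forest = _build_forest(n_trees, child_seeds[i], oob=False)
        forest.fit(X[train], y[train])
        accuracies[i] = 100.0 * float(np.mean(forest.predict(X[test]) == y[test]))
    oob = None
    if compute_oob:
        _, oob = fit_forest(table, columns, n_trees=n_trees, seed=seed)
    return ModelResult(model_name=model_name, columns=tuple(columns),
                       cv_accuracies=accuracies, oob_accuracy=oob,
                       scheme_fingerprint=scheme.fingerprint(),
                       n_trees=n_trees, seed=seed)


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Paired t-test of two models' per-split accuracy distributions."""

    model_a: str
    model_b: str
    mean_difference: float  # b - a, percentage points
    ci95: tuple[float, float]
    p_value: float
    t_statistic: float
    n_splits: int
    degenerate: bool = False  # zero-variance differences (e.g. self-comparison)

    def to_dict(self) -> dict:
        return {
            "model_a": self.model_a,
            "model_b": self.model_b,
            "mean_difference": self.mean_difference,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "t_statistic": self.t_statistic,
            "n_splits": self.n_splits,
            "degenerate": self.degenerate,
        }


def compare_models(a: ModelResult, b: ModelResult) -> ComparisonResult:
    """Two-sided paired t-test of per-split accuracies (b minus a).

    Refuses models evaluated on different CV schemes, since pairing would
    then be meaningless.
    """
    if a.scheme_fingerprint != b.scheme_fingerprint:
        raise ValueError("models were evaluated on different CV schemes; "
                         "paired comparison is invalid")
    if len(a.cv_accuracies) != len(b.cv_accuracies):
        raise ValueError("accuracy vectors differ in length")
    diff = b.cv_accuracies - a.cv_accuracies
    n = len(diff)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return ComparisonResult(a.model_name, b.model_name, mean, (mean, mean),
                                p_value=float("nan"), t_statistic=float("nan"),
                                n_splits=n, degenerate=True)
    tstat, p = stats.ttest_rel(b.cv_accuracies, a.cv_accuracies)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return ComparisonResult(a.model_name, b.model_name, mean,
                            (mean - half, mean + half), p_value=float(p),
                            t_statistic=float(tstat), n_splits=n)


# ---------------------------------------------------------------------------
# exhaustive subset sweep
# ---------------------------------------------------------------------------

def subset_sweep(table: pd.DataFrame, ihc_columns: tuple[str, ...] = IHC_PARAMETERS,
                 k_range: range | tuple[int, ...] = range(1, 9),
                 scheme: CVScheme | None = None, n_trees: int = 500,
                 seed: int | None = 0,
                 n_repeats: int = 100) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Accuracy of every k-combination of the IHC parameters (Fig 2F analog).

    For each ``k`` in ``k_range`` all ``C(p, k)`` column combinations are
    evaluated on the shared CV scheme.  Returns three frames:

    ``per_model``
        one row per combination (k, columns, mean, sd over splits);
    ``per_k``
        mean and SD over combination-level mean accuracies, plus the mean
        within-combination SD over splits;
    ``tests``
        Welch two-sample t-test between consecutive k levels on the
        combination-level mean accuracies.
    """
    p = len(ihc_columns)
    for k in k_range:
        if not 1 <= k <= p - 1:
            raise ValueError(f"k={k} outside 1..{p - 1}")
    if scheme is None:
        scheme = make_cv_scheme(table, n_repeats=n_repeats, seed=seed)
    records = []
    for k in k_range:
        for combo in itertools.combinations(ihc_columns, k):
            result = evaluate_model(table, list(combo), scheme,
                                    n_trees=n_trees, seed=seed,
                                    model_name="+".join(combo))
            records.append({"k": k, "columns": "+".join(combo),
                            "mean_accuracy": result.mean, "sd_accuracy": result.sd})
    per_model = pd.DataFrame(records)

    per_k = (per_model.groupby("k")
             .agg(n_models=("columns", "size"),
                  mean_accuracy=("mean_accuracy", "mean"),
                  sd_over_combinations=("mean_accuracy", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
                  mean_sd_over_splits=("sd_accuracy", "mean"))
             .reset_index())

    tests = []
    ks = sorted(set(k_range))
    for k_prev, k_next in zip(ks[:-1], ks[1:]):
        prev = per_model.loc[per_model["k"] == k_prev, "mean_accuracy"]
        nxt = per_model.loc[per_model["k"] == k_next, "mean_accuracy"]
        if len(prev) > 1 and len(nxt) > 1:
            tstat, pval = stats.ttest_ind(nxt, prev, equal_var=False)
        else:
            tstat, pval = float("nan"), float("nan")
        tests.append({"k_prev": k_prev, "k_next": k_next,
                      "mean_diff": float(nxt.mean() - prev.mean()),
                      "t_statistic": float(tstat), "p_value": float(pval)})
    return per_model, per_k, pd.DataFrame(tests)
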