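"""Group-sampling data enrichment and repeated random-forest classification.

With K collinear variable groups, the 16-sample profile can be expanded
into a much larger pseudo-dataset: in each of B iterations one variable
is drawn uniformly per group and every sample is emitted with those K
Z-scores and its copied diagnosis, giving B x n rows with K features.
Repeated random forests (fresh stratified 80/20 split per repeat) then
estimate prediction accuracy and impurity-based feature importance,
averaged over repeats.  The same training loop runs without enrichment
on the full variable set for per-variable importances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

__all__ = [
    "DEFAULT_RF_PARAMS",
    "EnrichedDataset",
    "RFRunResult",
    "enrich",
    "train_rf",
    "importance_by_group",
]


class EnrichmentError(ValueError):
    pass


#: Random-forest parameter block used for every forest.
DEFAULT_RF_PARAMS: dict = {
    "n_estimators": 100,
    "criterion": "entropy",
    "max_depth": 16,
    "min_samples_split": 2,
    "min_samples_leaf": 1,
    "min_weight_fraction_leaf": 0.0,
    "max_features": 5,
    "max_leaf_nodes": None,
    "min_impurity_decrease": 0.0,
    "bootstrap": True,
    "oob_score": False,
    "n_jobs": -1,
    "random_state": None,
    "verbose": 0,
    "warm_start": False,
    "class_weight": None,
    "ccp_alpha": 0.0,
    "max_samples": None,
}


@dataclass
class EnrichedDataset:
    """B x n pseudo-samples with one feature per FA group.

    ``features`` has columns ``group_1..group_K``; ``provenance`` records,
    for every row, the iteration, source sample and the variable drawn
    for each group slot, so every cell is traceable to a source Z-score.
    """

    features: pd.DataFrame
    labels: pd.Series
    provenance: pd.DataFrame
    n_iterations: int
    n_source_samples: int


def enrich(z, groups: pd.Series, iterations: int = 1000, seed=None) -> EnrichedDataset:
    """Build the enriched dataset by repeated group sampling.

    For each of ``iterations`` draws, one variable per group is sampled
    uniformly (with replacement across iterations) and all n samples are
    emitted with the K drawn Z-scores and their copied diagnosis.
    """
    if iterations < 1:
        raise EnrichmentError("iterations must be >= 1")
    groups = pd.Series(groups)
    missing = set(groups.index) - set(z.values.columns)
    if missing:
        raise EnrichmentError(f"group variables absent from matrix: {sorted(missing)}")
    members = {g: sorted(groups.index[groups == g]) for g in sorted(groups.unique())}
    empty = [g for g, mem in members.items() if not mem]
    if empty:
        raise EnrichmentError(f"empty groups: {empty}")
    rng = np.random.default_rng(seed)
    n = len(z.values.index)
    gids = list(members)
    cols = [f"group_{g}" for g in gids]
    blocks = []
    prov = []
    for it in range(iterations):
        drawn = {g: members[g][rng.integers(len(members[g]))] for g in gids}
        block = z.values[[drawn[g] for g in gids]].to_numpy(float)
        blocks.append(block)
        for s in z.values.index:
            prov.append({"iteration": it, "sample": s,
                         **{c: drawn[g] for c, g in zip(cols, gids)}})
    X = pd.DataFrame(np.vstack(blocks), columns=cols)
    y = pd.Series(
        np.tile(z.diagnosis.to_numpy(), iterations), name="diagnosis"
    )
    return EnrichedDataset(
        features=X,
        labels=y,
        provenance=pd.DataFrame(prov),
        n_iterations=iterations,
        n_source_samples=n,
    )


@dataclass
class RFRunResult:
    """Accuracy and feature importance averaged over repeated forests."""

    accuracies: np.ndarray  # per-repeat test accuracy
    importances: pd.DataFrame  # repeats x features (impurity, normalized)
    params: dict
    seeds: list
    permutation_importances: pd.DataFrame | None = None
    split_retries: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_importance(self) -> pd.Series:
        return self.importances.mean(axis=0).rename("importance")


def _resolve_params(params: dict | None, n_features: int) -> dict:
    p = dict(DEFAULT_RF_PARAMS)
    if params:
        p.update(params)
    mf = p.get("max_features")
    if isinstance(mf, (int, np.integer)) and mf > n_features:
        p["max_features"] = int(n_features)
    return p


def train_rf(
    X: pd.DataFrame,
    y: pd.Series,
    repeats: int = 100,
    train_fraction: float = 0.8,
    params: dict | None = None,
    seed=None,
    stratify: bool = True,
    compute_permutation_importance: bool = False,
    max_split_retries: int = 20,
) -> RFRunResult:
    """Repeatedly fit the forest on fresh train/test splits.

    Per repeat: stratified ``train_fraction`` split, one forest fitted
    with the parameter block, test accuracy recorded, and impurity-based
    feature importances (normalized to sum to 1, estimated from the
    training data only).  A single ``seed`` fans out to per-repeat seeds
    via a counter so repeats are independent but reproducible.
    """
    if not 0 < train_fraction < 1:
        raise EnrichmentError("train_fraction must be in (0, 1)")
    y = pd.Series(y).reset_index(drop=True)
    X = pd.DataFrame(X).reset_index(drop=True)
    classes = np.unique(y)
    if len(classes) < 2:
        raise EnrichmentError("need at least 2 classes")
    p = _resolve_params(params, X.shape[1])
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 10**6))
    accs = np.empty(repeats)
    imps = np.empty((repeats, X.shape[1]))
    perm = np.empty((repeats, X.shape[1])) if compute_permutation_importance else None
    seeds = []
    retries = 0
    for r in range(repeats):
        split_seed = base + 2 * r
        for attempt in range(max_split_retries):
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=train_fraction,
                random_state=(split_seed + attempt) % (2**31),
                stratify=y if stratify else None,
            )
            if len(np.unique(ytr)) == len(classes):
                break
            retries += 1
        else:
            raise EnrichmentError(
                f"could not draw a split containing all classes in "
                f"{max_split_retries} attempts"
            )
        rf_seed = (base + 2 * r + 1) % (2**31)
        rf = RandomForestClassifier(**{**p, "random_state": rf_seed})
        rf.fit(Xtr, ytr)
        accs[r] = rf.score(Xte, yte)
        imps[r] = rf.feature_importances_
        if perm is not None:
            pi = permutation_importance(
                rf, Xtr, ytr, n_repeats=10, random_state=rf_seed
            )
            perm[r] = pi.importances_mean
        seeds.append((split_seed, rf_seed))
    return RFRunResult(
        accuracies=accs,
        importances=pd.DataFrame(imps, columns=X.columns),
        params=p,
        seeds=seeds,
        permutation_importances=(
            pd.DataFrame(perm, columns=X.columns) if perm is not None else None
        ),
        split_retries=retries,
    )


def importance_by_group(
    result: RFRunResult,
    groups: pd.Series | None = None,
    variable_kind: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate mean feature importances.

    For an enriched run the features *are* the group slots
    (``group_<id>``) and the table has one row per group.  For a
    full-dataset run, per-variable importances are returned (optionally
    summed per group when ``groups`` maps variables to group ids), and a
    ``derived`` column marks sum/ratio/index variables so a variant
    excluding them can be reported.
    """
    mean_imp = result.mean_importance
    feats = list(mean_imp.index)
    if all(str(f).startswith("group_") for f in feats):
        table = pd.DataFrame(
            {"group": [int(str(f).split("_", 1)[1]) for f in feats],
             "importance": mean_imp.to_numpy()}
        ).set_index("group").sort_index()
        table["rank"] = table["importance"].rank(ascending=False).astype(int)
        return table
    table = mean_imp.to_frame()
    if groups is not None:
        groups = pd.Series(groups)
        unknown = set(feats) - set(groups.index)
        if unknown:
            raise EnrichmentError(
                f"result features missing from group assignment: {sorted(unknown)}"
            )
        table["group"] = groups.loc[feats].to_numpy()
    if variable_kind is not None:
        table["derived"] = (
            pd.Series(variable_kind).loc[feats] != "raw_fa"
        ).to_numpy()
    table["rank"] = table["importance"].rank(ascending=False).astype(int)
    return table.sort_values("importance", ascending=False)
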