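"""FA profile data model and per-variable statistics.

A :class:`ProfileMatrix` holds a samples x variables table of fatty-acid
relative abundances (mol-% of total lipid side chains) together with
per-sample metadata (diagnosis, tissue) and a per-variable kind tag
(``raw_fa`` for measured chains, ``sum``/``ratio``/``index`` for derived
variables).  Operations: appending derived sums/ratios/indices
(:func:`compute_derived`), per-variable Z-score standardisation
(:func:`zscore`), and between-diagnosis comparisons with the
Mann-Whitney U test (:func:`compare_groups`).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .names import FAName, FANameError, parse_fa_name

__all__ = [
    "ProfileMatrix",
    "ZMatrix",
    "DerivedRecipe",
    "default_recipes",
    "compute_derived",
    "zscore",
    "compare_groups",
    "fisher_exact_2x2",
]

VARIABLE_KINDS = ("raw_fa", "sum", "ratio", "index")

#: per-sample mol-% closure tolerance; published tables round to 2 decimals
CLOSURE_TOL = 0.5


class ProfileError(ValueError):
    pass


@dataclass
class ProfileMatrix:
    """Samples x variables mol-% table with sample metadata.

    Parameters
    ----------
    values : DataFrame
        Rows = samples, columns = variables.  Raw FA columns are mol-%,
        derived columns are sums (mol-%) or dimensionless ratios/indices.
    meta : DataFrame
        Indexed like ``values``; must contain a ``diagnosis`` column
        (``RA``/``OA``) and may contain ``tissue`` (``synovium``/``IFP``).
    variable_kind : Series
        One of :data:`VARIABLE_KINDS` per column of ``values``.
        Defaults to ``raw_fa`` everywhere.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    variable_kind: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.variable_kind is None:
            self.variable_kind = pd.Series(
                "raw_fa", index=self.values.columns, name="variable_kind"
            )
        self.variable_kind = self.variable_kind.reindex(self.values.columns)
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ProfileError(f"duplicated variable labels: {dupes}")
        if self.values.index.duplicated().any():
            raise ProfileError("duplicated sample IDs")
        if not self.meta.index.equals(self.values.index):
            self.meta = self.meta.reindex(self.values.index)
        if self.meta.isna().any().any():
            raise ProfileError("metadata missing for some samples")
        unknown = set(self.variable_kind) - set(VARIABLE_KINDS)
        if unknown:
            raise ProfileError(f"unknown variable kinds: {sorted(unknown)}")
        if (self.raw_values() < 0).any().any():
            raise ProfileError("negative mol-% values in raw FA columns")

    # -- accessors ---------------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def variables(self) -> pd.Index:
        return self.values.columns

    @property
    def diagnosis(self) -> pd.Series:
        return self.meta["diagnosis"]

    def raw_labels(self) -> list[str]:
        return [v for v in self.variables if self.variable_kind[v] == "raw_fa"]

    def raw_values(self) -> pd.DataFrame:
        return self.values[self.raw_labels()]

    def parsed_names(self) -> dict[str, FAName]:
        """Parse every raw FA column label; raises on unparseable labels."""
        return {lab: parse_fa_name(lab) for lab in self.raw_labels()}

    # -- validation --------------------------------------------------------
    def closure_deviation(self) -> pd.Series:
        """Per-sample deviation of the raw mol-% sum from 100."""
        return self.raw_values().sum(axis=1) - 100.0

    def check_closure(self, tol: float = CLOSURE_TOL, warn: bool = True) -> pd.Index:
        """Samples whose raw mol-% do not sum to 100 within ``tol``."""
        dev = self.closure_deviation()
        bad = dev.index[dev.abs() > tol]
        if warn and len(bad):
            warnings.warn(
                f"mol-% sums deviate from 100 by more than {tol} for samples: "
                f"{list(bad)}",
                stacklevel=2,
            )
        return bad

    def renormalize(self) -> "ProfileMatrix":
        """Rescale raw FA columns so each sample sums to exactly 100."""
        out = self.values.copy()
        raw = self.raw_labels()
        out[raw] = out[raw].div(out[raw].sum(axis=1), axis=0) * 100.0
        return ProfileMatrix(out, self.meta.copy(), self.variable_kind.copy())

    def drop_derived(self) -> "ProfileMatrix":
        raw = self.raw_labels()
        return ProfileMatrix(
            self.values[raw].copy(), self.meta.copy(), self.variable_kind[raw].copy()
        )

    def copy(self) -> "ProfileMatrix":
        return ProfileMatrix(
            self.values.copy(), self.meta.copy(), self.variable_kind.copy()
        )


@dataclass
class ZMatrix:
    """Per-variable Z-scores on the same axes as a :class:`ProfileMatrix`."""

    values: pd.DataFrame
    meta: pd.DataFrame
    variable_kind: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.variable_kind is None:
            self.variable_kind = pd.Series(
                "raw_fa", index=self.values.columns, name="variable_kind"
            )

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def variables(self) -> pd.Index:
        return self.values.columns

    @property
    def diagnosis(self) -> pd.Series:
        return self.meta["diagnosis"]


def zscore(profiles: ProfileMatrix | ZMatrix, ddof: int = 0) -> ZMatrix:
    """Standardise every variable to mean 0, SD 1 across samples.

    Z_i = (x_i - <x>_samples) / sigma_samples, with the population
    standard deviation (``ddof=0``) by default.

    Raises
    ------
    ProfileError
        With fewer than 2 samples or when a variable has zero variance
        (no NaN columns are ever emitted).
    """
    x = profiles.values
    if len(x.index) < 2:
        raise ProfileError("Z-scores require at least 2 samples")
    sd = x.std(axis=0, ddof=ddof)
    dead = sd.index[(sd == 0) | sd.isna()].tolist()
    if dead:
        raise ProfileError(f"zero-variance variables cannot be standardised: {dead}")
    z = (x - x.mean(axis=0)) / sd
    return ZMatrix(z, profiles.meta.copy(), profiles.variable_kind.copy())


# ---------------------------------------------------------------------------
# Derived variables
# ---------------------------------------------------------------------------

_SELECTOR_FIELDS = {
    "labels",
    "min_carbons",
    "max_carbons",
    "double_bonds",
    "min_double_bonds",
    "max_double_bonds",
    "series",
    "is_dma",
}


@dataclass
class DerivedRecipe:
    """One derived column: a class sum, a ratio of sums, or a weighted index."""

    name: str
    kind: str  # sum | ratio | index
    select: Mapping | None = None
    numerator: Mapping | None = None
    denominator: Mapping | None = None
    weight: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sum", "ratio", "index"):
            raise ProfileError(f"recipe {self.name!r}: unknown kind {self.kind!r}")
        for sel in (self.select, self.numerator, self.denominator):
            if sel is not None and not set(sel) <= _SELECTOR_FIELDS:
                raise ProfileError(
                    f"recipe {self.name!r}: unknown selector fields "
                    f"{sorted(set(sel) - _SELECTOR_FIELDS)}"
                )
        if self.kind == "index" and self.weight not in ("double_bonds", "carbons"):
            raise ProfileError(f"recipe {self.name!r}: weight must be a FAName field")


def _matches(name: FAName, sel: Mapping) -> bool:
    if "labels" in sel and name.label not in sel["labels"]:
        return False
    if "min_carbons" in sel and name.carbons < sel["min_carbons"]:
        return False
    if "max_carbons" in sel and name.carbons > sel["max_carbons"]:
        return False
    if "double_bonds" in sel and name.double_bonds != sel["double_bonds"]:
        return False
    if "min_double_bonds" in sel and name.double_bonds < sel["min_double_bonds"]:
        return False
    if "max_double_bonds" in sel and name.double_bonds > sel["max_double_bonds"]:
        return False
    if "series" in sel and name.series not in sel["series"]:
        return False
    if "is_dma" in sel and name.is_dma != sel["is_dma"]:
        return False
    return True


def _select_columns(
    sel: Mapping, parsed: Mapping[str, FAName], recipe: str, missing: str
) -> list[str]:
    if "labels" in sel:
        absent = [lab for lab in sel["labels"] if lab not in parsed]
        if absent and missing == "error":
            raise ProfileError(
                f"recipe {recipe!r} references FAs absent from the profile: {absent}"
            )
    return [lab for lab, nm in parsed.items() if _matches(nm, sel)]


def load_recipes(path=None) -> list[DerivedRecipe]:
    """Load derived-variable recipes from YAML (package default if no path)."""
    if path is None:
        ref = importlib.resources.files("lipidsig.data") / "derived_recipes.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return [DerivedRecipe(**entry) for entry in raw]


def default_recipes() -> list[DerivedRecipe]:
    return load_recipes(None)


def compute_derived(
    profiles: ProfileMatrix,
    recipes: Sequence[DerivedRecipe] | None = None,
    missing: str = "error",
) -> ProfileMatrix:
    """Append derived sums/ratios/indices to a raw mol-% profile.

    Raw columns are returned unchanged; derived columns are recomputed
    from the raw columns only (existing derived columns are ignored as
    inputs).  ``missing="zero"`` treats recipe FAs absent from the table
    as zero instead of rejecting.
    """
    if missing not in ("error", "zero"):
        raise ProfileError("missing must be 'error' or 'zero'")
    if recipes is None:
        recipes = default_recipes()
    parsed = profiles.parsed_names()
    raw = profiles.raw_values()
    out = {}
    kinds = {}
    for rec in recipes:
        if rec.kind == "sum":
            cols = _select_columns(rec.select or {}, parsed, rec.name, missing)
            out[rec.name] = raw[cols].sum(axis=1) if cols else pd.Series(0.0, raw.index)
        elif rec.kind == "ratio":
            num_cols = _select_columns(rec.numerator or {}, parsed, rec.name, missing)
            den_cols = _select_columns(rec.denominator or {}, parsed, rec.name, missing)
            num = raw[num_cols].sum(axis=1) if num_cols else pd.Series(0.0, raw.index)
            den = raw[den_cols].sum(axis=1) if den_cols else pd.Series(0.0, raw.index)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = num / den
            if (den == 0).any():
                warnings.warn(
                    f"recipe {rec.name!r}: zero denominator for some samples; "
                    "emitting NaN",
                    stacklevel=2,
                )
                ratio[den == 0] = np.nan
            out[rec.name] = ratio
        else:  # index
            weights = np.array([getattr(parsed[lab], rec.weight) for lab in raw.columns])
            out[rec.name] = raw.mul(weights, axis=1).sum(axis=1) / 100.0
        kinds[rec.name] = rec.kind
    derived = pd.DataFrame(out, index=raw.index)
    clash = derived.columns.intersection(raw.columns)
    if len(clash):
        raise ProfileError(f"derived names clash with raw columns: {list(clash)}")
    values = pd.concat([raw, derived], axis=1)
    kind = pd.concat(
        [profiles.variable_kind[raw.columns], pd.Series(kinds)]
    ).rename("variable_kind")
    return ProfileMatrix(values, profiles.meta.copy(), kind)


# ---------------------------------------------------------------------------
# Between-diagnosis statistics
# ---------------------------------------------------------------------------

#: both group sizes at or below this use the exact Mann-Whitney null
EXACT_MW_MAX_N = 12


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples,
    otherwise the normal approximation with continuity and tie correction."""
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= EXACT_MW_MAX_N and len(b) <= EXACT_MW_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    profiles: ProfileMatrix | ZMatrix,
    by: str = "diagnosis",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-group comparison (GroupStatsTable).

    Returns one row per variable with mean and SE per group, the
    Mann-Whitney U statistic (of the first group, alphabetically) and
    two-sided p, a significance flag at ``alpha``, and a Benjamini-
    Hochberg adjusted p (reported alongside, not used for the flag).
    """
    groups = profiles.meta[by]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ProfileError(f"expected exactly two {by} levels, got {levels}")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ProfileError(f"each {by} level needs >= 2 samples, got {dict(counts)}")
    g0 = profiles.values[groups == levels[0]]
    g1 = profiles.values[groups == levels[1]]
    rows = {}
    for var in profiles.values.columns:
        a = g0[var].to_numpy(float)
        b = g1[var].to_numpy(float)
        u, p = _mannwhitney(a, b)
        rows[var] = {
            f"mean_{levels[0]}": a.mean(),
            f"se_{levels[0]}": a.std(ddof=1) / np.sqrt(len(a)),
            f"mean_{levels[1]}": b.mean(),
            f"se_{levels[1]}": b.std(ddof=1) / np.sqrt(len(b)),
            "U": u,
            "p": p,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "variable"
    table["significant"] = table["p"] <= alpha
    table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def fisher_exact_2x2(table: Iterable[Iterable[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums the hypergeometric probabilities of all tables (with the same
    margins) no more likely than the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ProfileError("Fisher test requires a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ProfileError("Fisher test requires nonnegative integer counts")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])
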