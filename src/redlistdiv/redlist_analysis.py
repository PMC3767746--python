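"""Category-by-scale Red List diversity analysis.

Given a trait table, a cladogram, nested species pools (national ⊇
regional ⊇ local) and one or more Red List assignments, this module
scores every (unit, list, category) cell: functional diversity against
a UPGMA dendrogram built from the unit's own trait submatrix, and
phylogenetic diversity against the cladogram pruned to the unit's
pool, each compared with a tip-shuffle null drawn from that unit's
pool.  Cells are summarised per scale as the percentage of units
classified lower / equal / higher than chance, and Mann-Whitney tests
compare observed values against mean null values across units.

Categories follow the four threat levels Near Threatened (NT),
Vulnerable (VU), Endangered (EN) and Critically Endangered (CR).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .dendrogram import upgma
from .diversity import SubtreeCalculator
from .null_models import (
    DEFAULT_N_REPS,
    DEFAULT_P_HIGH,
    DEFAULT_P_LOW,
    EQUAL,
    HIGHER,
    LOWER,
    NullResult,
    tip_shuffle_null,
)
from .trait_space import TraitTable, gower_distance_matrix

__all__ = [
    "CATEGORIES",
    "METRICS",
    "RedListAssignment",
    "ScaleHierarchy",
    "AnalysisConfig",
    "CellResult",
    "CategoryProfile",
    "MWResult",
    "run_category_analysis",
    "summarize_profiles",
    "mann_whitney_obs_vs_nullmean",
    "mann_whitney_table",
    "category_overlap_report",
    "derive_cell_seed",
]

CATEGORIES = ("NT", "VU", "EN", "CR")
METRICS = ("FD", "PD")
SCALES = ("national", "regional", "local")


@dataclass(frozen=True)
class RedListAssignment:
    """One Red List: a mapping species -> threat category.

    ``region`` restricts a regional list to units inside that region;
    ``None`` means the list applies everywhere (global/national lists).
    Species absent from the mapping are unassessed or of least concern
    and take no part in the category analysis.
    """

    name: str
    categories: Mapping[str, str]
    region: str | None = None

    def __post_init__(self) -> None:
        bad = {c for c in self.categories.values() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"list {self.name!r}: unknown categories {sorted(bad)}")

    def species_in(self, category: str) -> frozenset[str]:
        return frozenset(s for s, c in self.categories.items() if c == category)


@dataclass(frozen=True)
class ScaleHierarchy:
    """Strictly nested species pools: national ⊇ regions ⊇ local units."""

    national: frozenset[str]
    regions: Mapping[str, frozenset[str]]
    local_units: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        overlap = set(self.regions) & set(self.local_units)
        if overlap or "national" in self.regions or "national" in self.local_units:
            raise ValueError(f"unit names must be unique across scales: {sorted(overlap)}")
        for name, sp in self.regions.items():
            if not sp <= self.national:
                raise ValueError(f"region {name!r} is not nested in the national pool")
        for name, (parent, sp) in self.local_units.items():
            if parent not in self.regions:
                raise ValueError(f"local unit {name!r} has unknown region {parent!r}")
            if not sp <= self.regions[parent]:
                raise ValueError(f"local unit {name!r} is not nested in region {parent!r}")

    def units(self) -> Iterator[tuple[str, str, str | None, frozenset[str]]]:
        """Yield (unit_name, scale, region, species) in deterministic order."""
        yield "national", "national", None, self.national
        for name in sorted(self.regions):
            yield name, "regional", name, self.regions[name]
        for name in sorted(self.local_units):
            parent, sp = self.local_units[name]
            yield name, "local", parent, sp


@dataclass(frozen=True)
class AnalysisConfig:
    n_reps: int = DEFAULT_N_REPS
    min_size: int = 2
    p_low: float = DEFAULT_P_LOW
    p_high: float = DEFAULT_P_HIGH
    gower_mode: str = "pavoine_mixed"
    log_mass: bool = False
    cladogram_method: str = "grafen"
    consensus_threshold: float = 0.5
    dendrogram_source: str = "rebuild"  # or "prune"
    include_root: bool = True
    ties: str = "midrank"
    master_seed: int = 0


def derive_cell_seed(master_seed: int, unit: str, red_list: str, category: str, metric: str) -> int:
    """Stable per-cell seed (< 2**31), independent of iteration order."""
    key = f"{master_seed}|{unit}|{red_list}|{category}|{metric}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") & 0x7FFFFFFF


@dataclass
class CellResult:
    unit: str
    scale: str
    red_list: str
    category: str
    metric: str
    n_species: int
    result: NullResult


@dataclass
class CategoryProfile:
    cells: list[CellResult] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    config: AnalysisConfig | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "unit": c.unit,
                "scale": c.scale,
                "red_list": c.red_list,
                "category": c.category,
                "metric": c.metric,
                "n_species": c.n_species,
                "observed": c.result.observed,
                "null_mean": c.result.null_mean,
                "null_sd": c.result.null_sd,
                "p": c.result.p,
                "ses": c.result.ses,
                "classification": c.result.classification,
                "n_reps": c.result.n_reps,
                "seed": c.result.seed,
            }
            for c in self.cells
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "unit", "scale", "red_list", "category", "metric", "n_species",
                "observed", "null_mean", "null_sd", "p", "ses",
                "classification", "n_reps", "seed",
            ],
        )


def _prune_to(tree: dendropy.Tree, species: frozenset[str]) -> dendropy.Tree:
    tip_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = species - tip_labels
    if missing:
        raise ValueError(f"species missing from tree: {sorted(missing)[:5]}")
    if species == tip_labels:
        return tree
    return tree.extract_tree_with_taxa_labels(labels=species)


def run_category_analysis(
    traits: TraitTable,
    cladogram: dendropy.Tree,
    hierarchy: ScaleHierarchy,
    assignments: Sequence[RedListAssignment],
    config: AnalysisConfig | None = None,
) -> CategoryProfile:
    """Score every (unit, Red List, category) cell for FD and PD.

    Functional dendrograms are rebuilt per unit from the unit's trait
    submatrix (``config.dendrogram_source == "rebuild"``, the default)
    or pruned from the national dendrogram (``"prune"``).  The
    cladogram is always pruned to the unit's pool.  Cells with fewer
    than ``config.min_size`` assessed species in the unit are skipped
    and logged on the profile.
    """
    config = config or AnalysisConfig()
    names = [a.name for a in assignments]
    if len(set(names)) != len(names):
        raise ValueError("Red List names must be unique")
    profile = CategoryProfile(config=config)

    national_dendrogram = None
    if config.dendrogram_source == "prune":
        dm = gower_distance_matrix(
            traits.subset(sorted(hierarchy.national)),
            mode=config.gower_mode, log_mass=config.log_mass,
        )
        national_dendrogram = upgma(dm)
    elif config.dendrogram_source != "rebuild":
        raise ValueError(f"unknown dendrogram_source: {config.dendrogram_source!r}")

    for unit, scale, region, species in hierarchy.units():
        applicable = [a for a in assignments if a.region is None or a.region == region]
        cell_members: dict[tuple[str, str], list[str]] = {}
        any_analysable = False
        for a in applicable:
            for cat in CATEGORIES:
                members = sorted(a.species_in(cat) & species)
                if 0 < len(members) < config.min_size:
                    profile.skipped.append(
                        {"unit": unit, "red_list": a.name, "category": cat,
                         "n_species": len(members),
                         "reason": f"below min_size={config.min_size}"}
                    )
                elif len(members) >= config.min_size:
                    cell_members[(a.name, cat)] = members
                    any_analysable = True
        if not any_analysable:
            continue

        if config.dendrogram_source == "rebuild":
            dm = gower_distance_matrix(
                traits.subset(sorted(species)),
                mode=config.gower_mode, log_mass=config.log_mass,
            )
            fd_tree = upgma(dm)
        else:
            fd_tree = _prune_to(national_dendrogram, species)
        pd_tree = _prune_to(cladogram, species)
        calcs = {"FD": SubtreeCalculator(fd_tree), "PD": SubtreeCalculator(pd_tree)}

        for a in applicable:
            for cat in CATEGORIES:
                members = cell_members.get((a.name, cat))
                if members is None:
                    continue
                for metric in METRICS:
                    seed = derive_cell_seed(config.master_seed, unit, a.name, cat, metric)
                    res = tip_shuffle_null(
                        calcs[metric], members, pool=species,
                        n_reps=config.n_reps, seed=seed,
                        include_root=config.include_root, ties=config.ties,
                        p_low=config.p_low, p_high=config.p_high,
                    )
                    profile.cells.append(
                        CellResult(unit, scale, a.name, cat, metric, len(members), res)
                    )
    return profile


def summarize_profiles(
    profile: CategoryProfile | pd.DataFrame, scale: str, metric: str
) -> pd.DataFrame:
    """Percentage of analysed units classified lower/equal/higher.

    One row per (red_list, category) present for the scale; rows with
    no analysed units carry NA percentages and N = 0.
    """
    df = profile.to_dataframe() if isinstance(profile, CategoryProfile) else profile
    df = df[(df["scale"] == scale) & (df["metric"] == metric)]
    lists = sorted(df["red_list"].unique())
    rows = []
    for rl in lists:
        for cat in CATEGORIES:
            sub = df[(df["red_list"] == rl) & (df["category"] == cat)]
            n = len(sub)
            if n == 0:
                rows.append({"red_list": rl, "category": cat, "pct_lower": np.nan,
                             "pct_equal": np.nan, "pct_higher": np.nan, "n_units": 0})
                continue
            counts = sub["classification"].value_counts()
            rows.append({
                "red_list": rl,
                "category": cat,
                "pct_lower": round(100.0 * counts.get(LOWER, 0) / n, 1),
                "pct_equal": round(100.0 * counts.get(EQUAL, 0) / n, 1),
                "pct_higher": round(100.0 * counts.get(HIGHER, 0) / n, 1),
                "n_units": n,
            })
    return pd.DataFrame(rows, columns=["red_list", "category", "pct_lower",
                                       "pct_equal", "pct_higher", "n_units"])


class MWResult(NamedTuple):
    U: float
    p: float
    n: int


def mann_whitney_obs_vs_nullmean(
    observed: Sequence[float], null_means: Sequence[float], mode: str = "auto"
) -> MWResult:
    """Two-sided Mann-Whitney U comparing observed diversity values
    with mean null values across units (treated as independent
    samples).

    ``mode="exact"`` enumerates the null distribution of U (valid
    without ties); ``"normal_approx"`` uses the tie- and
    continuity-corrected normal approximation; ``"auto"`` picks exact
    when n1 + n2 <= 16 and there are no ties.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(null_means, dtype=float)
    if len(x) != len(y):
        raise ValueError("observed and null_means must have the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 units per sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (len(pooled) <= 16 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return MWResult(U=float(res.statistic), p=float(min(res.pvalue, 1.0)), n=len(x))


def mann_whitney_table(
    profile: CategoryProfile | pd.DataFrame, scale: str, metric: str,
    min_units: int = 3, mode: str = "auto",
) -> pd.DataFrame:
    """Mann-Whitney U per (red_list, category): observed vs mean null
    across the scale's units; NA where fewer than ``min_units`` units."""
    df = profile.to_dataframe() if isinstance(profile, CategoryProfile) else profile
    df = df[(df["scale"] == scale) & (df["metric"] == metric)]
    rows = []
    for rl in sorted(df["red_list"].unique()):
        for cat in CATEGORIES:
            sub = df[(df["red_list"] == rl) & (df["category"] == cat)]
            n = len(sub)
            if n < min_units:
                rows.append({"red_list": rl, "category": cat,
                             "U": np.nan, "p": np.nan, "n_units": n})
                continue
            mw = mann_whitney_obs_vs_nullmean(
                sub["observed"].to_numpy(), sub["null_mean"].to_numpy(), mode=mode
            )
            rows.append({"red_list": rl, "category": cat,
                         "U": mw.U, "p": mw.p, "n_units": mw.n})
    return pd.DataFrame(rows, columns=["red_list", "category", "U", "p", "n_units"])


def category_overlap_report(assignments: Sequence[RedListAssignment]) -> pd.DataFrame:
    """Pairwise composition similarity of matching categories.

    For each category shared by two lists: Jaccard similarity
    (|∩| / |∪|) and overlap coefficient (|∩| / min(|A|, |B|)).
    """
    if len(assignments) < 2:
        raise ValueError("need at least two Red Lists to compare")
    rows = []
    for i, a in enumerate(assignments):
        for b in assignments[i + 1:]:
            for cat in CATEGORIES:
                sa, sb = a.species_in(cat), b.species_in(cat)
                if not sa and not sb:
                    continue
                inter = len(sa & sb)
                union = len(sa | sb)
                smaller = min(len(sa), len(sb))
                rows.append({
                    "list_a": a.name, "list_b": b.name, "category": cat,
                    "n_a": len(sa), "n_b": len(sb),
                    "n_shared": inter,
                    "jaccard": inter / union if union else np.nan,
                    "overlap_coef": inter / smaller if smaller else np.nan,
                })
    return pd.DataFrame(rows, columns=["list_a", "list_b", "category", "n_a", "n_b",
                                       "n_shared", "jaccard", "overlap_coef"])
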