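"""Mixed-type trait tables and Gower-style dissimilarities.

Species are described by groups of presence/absence traits (e.g. diet
items) plus continuous variables (body mass).  Two dissimilarity modes
are provided:

``classic``
    Gower's original coefficient: every trait is an independent
    variable.  Binary traits contribute a simple mismatch (0 if equal,
    1 if different); quantitative traits contribute the absolute
    difference divided by the observed range.  The distance is the mean
    contribution over variables defined for both species.

``pavoine_mixed``
    A mixed-data variant in which each presence/absence group is
    treated as one block scored by the Ochiai complement
    ``1 - a / sqrt((a + b) * (a + c))`` (``a`` shared presences,
    ``b``/``c`` presences private to either species), and quantitative
    traits contribute range-normalised differences as in classic mode.
    The distance is the unweighted mean over blocks that are defined
    for the pair; a binary block is undefined when either species has
    no presence among the traits scored for both.

Missing values are excluded pairwise in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "TraitGroup",
    "TraitSchema",
    "TraitTable",
    "ValidationReport",
    "BIRD_TRAIT_SCHEMA",
    "validate_traits",
    "gower_distance_matrix",
]

BINARY_SET = "binary_set"
QUANTITATIVE = "quantitative"


@dataclass(frozen=True)
class TraitGroup:
    """A named block of traits sharing one kind (binary set or quantitative)."""

    name: str
    traits: tuple[str, ...]
    kind: str
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (BINARY_SET, QUANTITATIVE):
            raise ValueError(f"unknown group kind: {self.kind!r}")
        if len(self.traits) < 1:
            raise ValueError(f"group {self.name!r} has no traits")


@dataclass(frozen=True)
class TraitSchema:
    """Ordered collection of trait groups with unique group and trait names."""

    groups: tuple[TraitGroup, ...]

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names in schema")
        traits = self.trait_names
        if len(set(traits)) != len(traits):
            raise ValueError("duplicate trait names across groups")

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(t for g in self.groups for t in g.traits)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def group(self, name: str) -> TraitGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


#: Default schema: 21 ecological traits — 20 presence/absence traits in
#: four groups (diet, foraging method, foraging substrate, activity
#: period) plus continuous body mass in grams.
BIRD_TRAIT_SCHEMA = TraitSchema(
    groups=(
        TraitGroup(
            "diet",
            ("vertebrates", "invertebrates", "leaves", "fruits", "grains", "nectar"),
            BINARY_SET,
        ),
        TraitGroup(
            "foraging_method",
            ("pursuit", "gleaning", "pouncing", "grazing", "pecking", "scavenging", "probing"),
            BINARY_SET,
        ),
        TraitGroup(
            "foraging_substrate",
            ("water", "mud", "ground", "vegetation", "air"),
            BINARY_SET,
        ),
        TraitGroup("activity_period", ("diurnal", "nocturnal"), BINARY_SET),
        TraitGroup("body_mass", ("body_mass",), QUANTITATIVE, unit="g"),
    )
)


class TraitTable:
    """Species-by-trait value matrix conforming to a :class:`TraitSchema`.

    Values are held in a pandas DataFrame indexed by species label;
    missing entries are NaN.
    """

    def __init__(self, data: pd.DataFrame, schema: TraitSchema):
        if data.index.has_duplicates:
            dups = sorted(data.index[data.index.duplicated()].unique())
            raise ValueError(f"duplicate species labels: {dups}")
        if len(data) < 2:
            raise ValueError("a trait table needs at least 2 species")
        missing_cols = [t for t in schema.trait_names if t not in data.columns]
        if missing_cols:
            raise ValueError(f"trait columns missing from table: {missing_cols}")
        if any(not isinstance(s, str) or not s for s in data.index):
            raise ValueError("species labels must be non-empty strings")
        self.data = data.loc[:, list(schema.trait_names)].astype(float)
        self.schema = schema

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, species: list[str] | tuple[str, ...]) -> "TraitTable":
        """Restrict to a species pool (order follows the given list)."""
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise KeyError(f"species not in trait table: {missing}")
        return TraitTable(self.data.loc[list(species)], self.schema)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_traits(table: TraitTable, schema: TraitSchema | None = None) -> ValidationReport:
    """Check trait values against the schema.

    Errors: binary values outside {0, 1}; non-positive quantitative
    values.  Warnings: species with an all-zero binary group (a species
    that scores no state in e.g. the diet block is ecologically
    suspect but not ill-formed).  Duplicate labels are rejected at
    table construction.
    """
    schema = schema or table.schema
    report = ValidationReport()
    for g in schema.groups:
        block = table.data.loc[:, list(g.traits)]
        if g.kind == BINARY_SET:
            bad = ~(block.isna() | (block == 0) | (block == 1))
            for sp in block.index[bad.any(axis=1)]:
                vals = block.loc[sp][bad.loc[sp]].to_dict()
                report.errors.append(
                    f"species {sp!r}: non-binary value(s) in group {g.name!r}: {vals}"
                )
            observed = block == 1
            allzero = (~observed).all(axis=1) & ~block.isna().all(axis=1) & ~bad.any(axis=1)
            for sp in block.index[allzero]:
                report.warnings.append(
                    f"species {sp!r}: all-zero {g.name!r} group (no state scored)"
                )
        else:
            bad = block.le(0) & ~block.isna()
            for sp in block.index[bad.any(axis=1)]:
                vals = block.loc[sp][bad.loc[sp]].to_dict()
                report.errors.append(
                    f"species {sp!r}: non-positive quantitative value(s): {vals}"
                )
    return report


def _quant_contrib(col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Range-normalised |xi - xj| and its pairwise defined-mask."""
    valid = ~np.isnan(col)
    pair_valid = np.outer(valid, valid)
    finite = col[valid]
    rng = finite.max() - finite.min() if finite.size else 0.0
    if rng <= 0:
        # constant (or absent) variable: undefined contribution
        return np.zeros((col.size, col.size)), np.zeros((col.size, col.size), dtype=bool)
    x = np.where(valid, col, 0.0)
    diff = np.abs(x[:, None] - x[None, :]) / rng
    return np.where(pair_valid, diff, 0.0), pair_valid


def gower_distance_matrix(
    table: TraitTable,
    schema: TraitSchema | None = None,
    mode: str = "pavoine_mixed",
    log_mass: bool = False,
) -> DistanceMatrix:
    """Pairwise species dissimilarities in [0, 1].

    Parameters
    ----------
    mode:
        ``"classic"`` or ``"pavoine_mixed"`` (default), see module
        docstring.
    log_mass:
        Apply log10 to quantitative traits before range normalisation.

    Raises
    ------
    ValueError
        If some pair of species shares no defined variable or block,
        or on an unknown mode.
    """
    schema = schema or table.schema
    if mode not in ("classic", "pavoine_mixed"):
        raise ValueError(f"unknown mode: {mode!r}")
    n = len(table)
    labels = table.species
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))

    for g in schema.groups:
        block = table.data.loc[:, list(g.traits)].to_numpy(dtype=float)
        if g.kind == QUANTITATIVE:
            for j in range(block.shape[1]):
                col = block[:, j]
                if log_mass:
                    col = np.log10(col)
                contrib, defined = _quant_contrib(col)
                num += contrib
                cnt += defined
        elif mode == "classic":
            valid = ~np.isnan(block)
            x = np.where(valid, block, 0.0)
            # mismatches per pair, counted over traits defined for both
            a = x @ x.T
            b = x @ valid.T - a  # i has, j lacks
            c = valid @ x.T - a
            num += b + c
            cnt += (valid.astype(float) @ valid.T.astype(float))
        else:  # pavoine_mixed: whole group is one Ochiai-complement block
            valid = ~np.isnan(block)
            x = np.where(valid, block, 0.0)
            a = x @ x.T
            b = x @ valid.T - a
            c = valid @ x.T - a
            defined = ((a + b) > 0) & ((a + c) > 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                d_block = 1.0 - a / np.sqrt((a + b) * (a + c))
            num += np.where(defined, d_block, 0.0)
            cnt += defined

    np.fill_diagonal(cnt, np.maximum(np.diag(cnt), 1.0))  # diagonal is 0/!0-safe
    off = ~np.eye(n, dtype=bool)
    if np.any(cnt[off] == 0):
        i, j = np.argwhere((cnt == 0) & off)[0]
        raise ValueError(
            f"species pair ({labels[i]!r}, {labels[j]!r}) shares no defined trait/block"
        )
    d = num / cnt
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return DistanceMatrix(d, ids=labels)
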