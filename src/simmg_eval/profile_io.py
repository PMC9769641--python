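"""Read, validate, merge and write the tabular formats the pipeline touches.

The central container is :class:`FunctionalProfile`, a feature x sample
abundance table at one functional level (KEGG orthology, enzyme commission
number, or MetaCyc pathway) produced by tools such as HUMAnN2 (shotgun
metagenomes/metatranscriptomes) or PICRUSt2 (16S-derived simulated
metagenomes).  Stratified rows of the form ``K00001|g__Escherichia.s__coli``
attribute part of a feature's abundance to a taxon and are kept alongside
the community totals.

Also implements the per-ASV reliability filter: amplicon sequence variants
whose nearest-sequenced taxon index (NSTI) exceeds a cutoff are discarded
as too divergent from any reference genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

METHOD_LABELS = ("MG", "MT", "simMG")
LEVELS = ("KO", "EC", "pathway")

#: Bookkeeping rows emitted by HUMAnN2-style tools; excluded from the
#: feature set but their mass is retained as a diagnostic.
SPECIAL_ROWS = frozenset({"UNMAPPED", "UNGROUPED", "UNINTEGRATED"})


class ProfileError(ValueError):
    """Malformed or empty profile table."""


class LevelMismatchError(ValueError):
    """Profiles at different functional levels cannot be merged."""


def _split_stratified(feature: str) -> tuple[str, str | None]:
    """Split ``FEATURE|g__Genus.s__species`` on the first ``|``."""
    if "|" in feature:
        base, taxon = feature.split("|", 1)
        return base, taxon
    return feature, None


def parse_genus(taxon: str) -> str | None:
    """Extract the genus token from a ``g__Genus.s__species`` string."""
    for part in taxon.split("."):
        if part.startswith("g__"):
            genus = part[len("g__"):]
            return genus or None
    return None


@dataclass
class FunctionalProfile:
    """A method-labelled feature x sample abundance table at one level.

    Parameters
    ----------
    method_label : {"MG", "MT", "simMG"}
    level : {"KO", "EC", "pathway"}
    abundance : pandas.DataFrame
        Features (index) x samples (columns), nonnegative reals.  Community
        totals only; stratified rows live in ``stratified``.
    stratified : pandas.DataFrame or None
        MultiIndex (feature, taxon) x samples; taxon strings keep the
        full ``g__Genus.s__species`` token.
    unmapped_mass : pandas.Series or None
        Summed per-sample mass of UNMAPPED/UNGROUPED/UNINTEGRATED rows.
    """

    method_label: str
    level: str
    abundance: pd.DataFrame
    stratified: pd.DataFrame | None = None
    unmapped_mass: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.method_label not in METHOD_LABELS:
            raise ValueError(f"unknown method_label {self.method_label!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if (self.abundance.to_numpy() < 0).any():
            raise ProfileError("negative abundance")
        if self.abundance.columns.duplicated().any():
            raise ProfileError("duplicate sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def features(self) -> list[str]:
        return list(self.abundance.index)

    def copy(self) -> "FunctionalProfile":
        return FunctionalProfile(
            self.method_label,
            self.level,
            self.abundance.copy(),
            None if self.stratified is None else self.stratified.copy(),
            None if self.unmapped_mass is None else self.unmapped_mass.copy(),
        )

    def genus_abundance(self, feature: str) -> dict[str, pd.Series]:
        """Per-genus abundance vectors attributed to ``feature``."""
        out: dict[str, pd.Series] = {}
        if self.stratified is None or feature not in self.stratified.index.get_level_values(0):
            return out
        block = self.stratified.loc[feature]
        for taxon, row in block.iterrows():
            genus = parse_genus(str(taxon))
            if genus is None:
                continue
            out[genus] = out.get(genus, pd.Series(0.0, index=row.index)) + row
        return out


@dataclass(frozen=True)
class AsvRecord:
    """An amplicon sequence variant with its read count and NSTI."""

    asv_id: str
    read_count: int
    nsti: float

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError(f"{self.asv_id}: negative read_count")
        if self.nsti < 0:
            raise ValueError(f"{self.asv_id}: negative NSTI")


@dataclass
class NstiFilterResult:
    retained: list[AsvRecord]
    discarded: list[AsvRecord]
    asv_fraction_discarded: float
    read_fraction_discarded: float


def read_profile(path: str | Path, method_label: str, level: str) -> FunctionalProfile:
    """Read a tab-delimited feature x sample table.

    First column = feature ID (header ``# Gene Family`` / ``# Pathway``
    tolerated), remaining columns = samples.  Stratified rows are split on
    the first ``|``; UNMAPPED/UNGROUPED/UNINTEGRATED rows are excluded from
    the feature set but summed into a diagnostic.  Duplicate feature rows
    are summed.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ProfileError(f"{path}: empty table") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ProfileError(f"{path}: empty table")
    try:
        values = raw.astype(float)
    except ValueError:
        # locate the offending cell for the error message
        for j, col in enumerate(raw.columns):
            for i, v in enumerate(raw[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ProfileError(
                        f"{path}: non-numeric cell at row {i + 2}, column {j + 2} ({v!r})"
                    ) from None
        raise
    values.index = values.index.astype(str)

    base = values.index.map(lambda f: _split_stratified(f)[0])
    special = base.isin(SPECIAL_ROWS)
    unmapped_mass = values.loc[special].sum(axis=0) if special.any() else None
    values = values.loc[~special]

    strat_mask = values.index.str.contains(r"\|", regex=True)
    plain = values.loc[~strat_mask]
    plain = plain.groupby(level=0, sort=True).sum()

    stratified = None
    if strat_mask.any():
        srows = values.loc[strat_mask]
        idx = pd.MultiIndex.from_tuples(
            [_split_stratified(f) for f in srows.index], names=["feature", "taxon"]
        )
        stratified = srows.set_axis(idx).groupby(level=[0, 1], sort=True).sum()
        # features that only appear stratified still belong to the feature set
        missing = stratified.index.get_level_values(0).unique().difference(plain.index)
        if len(missing):
            totals = stratified.loc[list(missing)].groupby(level=0).sum()
            plain = pd.concat([plain, totals]).sort_index()

    if plain.shape[0] == 0:
        if unmapped_mass is not None:
            plain = pd.DataFrame(
                np.empty((0, values.shape[1])), columns=values.columns
            )
        else:
            raise ProfileError(f"{path}: no features")
    plain.index.name = None
    return FunctionalProfile(method_label, level, plain, stratified, unmapped_mass)


def write_profile(profile: FunctionalProfile, path: str | Path) -> None:
    """Write a profile (community rows then stratified rows) as TSV."""
    path = Path(path)
    frames = [profile.abundance]
    if profile.stratified is not None and len(profile.stratified):
        flat = profile.stratified.copy()
        flat.index = [f"{f}|{t}" for f, t in flat.index]
        frames.append(flat)
    out = pd.concat(frames)
    out.index.name = "# Gene Family" if profile.level != "pathway" else "# Pathway"
    out.to_csv(path, sep="\t", float_format="%.10g")


def merge_profiles(profiles: Sequence[FunctionalProfile]) -> dict[str, FunctionalProfile]:
    """Align profiles from different methods on shared samples and the union feature set.

    Samples not present under every method are dropped (a simulated
    metagenome without a complementary sequenced sample cannot be
    compared); missing features are zero-filled.
    """
    if not profiles:
        raise ProfileError("no profiles to merge")
    levels = {p.level for p in profiles}
    if len(levels) != 1:
        raise LevelMismatchError(f"mixed levels: {sorted(levels)}")

    by_method: dict[str, FunctionalProfile] = {}
    for p in profiles:
        if p.method_label in by_method:
            # same-method tables are concatenated sample-wise
            prev = by_method[p.method_label]
            merged = prev.abundance.join(p.abundance, how="outer").fillna(0.0)
            by_method[p.method_label] = FunctionalProfile(
                p.method_label, p.level, merged, prev.stratified, prev.unmapped_mass
            )
        else:
            by_method[p.method_label] = p.copy()

    shared = None
    for p in by_method.values():
        s = set(p.sample_ids)
        shared = s if shared is None else shared & s
    shared_sorted = sorted(shared or set())
    if not shared_sorted:
        raise ProfileError("no samples shared by every method")

    union_features = sorted(set().union(*(p.features for p in by_method.values())))
    out: dict[str, FunctionalProfile] = {}
    for label, p in by_method.items():
        ab = p.abundance.reindex(index=union_features, columns=shared_sorted).fillna(0.0)
        strat = None
        if p.stratified is not None:
            strat = p.stratified.reindex(columns=shared_sorted).fillna(0.0)
        out[label] = FunctionalProfile(label, p.level, ab, strat, p.unmapped_mass)
    return out


def filter_by_nsti(
    records: Iterable[AsvRecord], cutoff: float = 2.0
) -> NstiFilterResult:
    """Discard ASVs with NSTI strictly greater than ``cutoff``.

    Returns retained and discarded records plus the fraction of ASVs and
    the read-weighted fraction discarded.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    records = list(records)
    if not records:
        warnings.warn("empty ASV table: fractions undefined, reported as 0")
        return NstiFilterResult([], [], 0.0, 0.0)
    discarded = [r for r in records if r.nsti > cutoff]
    retained = [r for r in records if r.nsti <= cutoff]
    total_reads = sum(r.read_count for r in records)
    read_frac = (
        sum(r.read_count for r in discarded) / total_reads if total_reads else 0.0
    )
    return NstiFilterResult(
        retained, discarded, len(discarded) / len(records), read_frac
    )


def read_asv_table(path: str | Path) -> list[AsvRecord]:
    """Read a 3-column TSV (asv_id, read_count, NSTI)."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 3:
        raise ProfileError(f"{path}: expected 3 columns (asv_id, read_count, nsti)")
    cols = df.columns[:3]
    return [
        AsvRecord(str(r[cols[0]]), int(r[cols[1]]), float(r[cols[2]]))
        for _, r in df.iterrows()
    ]


def write_asv_table(records: Sequence[AsvRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "asv_id": [r.asv_id for r in records],
            "read_count": [r.read_count for r in records],
            "nsti": [r.nsti for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_lineage_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping feature_id -> lineage text."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_lineage_map(lineage: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"feature_id": list(lineage), "lineage": [lineage[k] for k in lineage]}
    ).to_csv(path, sep="\t", index=False)


def read_geneset_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-set TSV: feature_id, set_name, optional class/product label."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ProfileError(f"{path}: expected >= 2 columns")
    return df
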