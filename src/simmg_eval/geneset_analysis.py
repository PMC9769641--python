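"""Curated gene-set cross-referencing and prevalence statistics.

Three curated sets matter for a folivorous host: antimicrobial-resistance
(AMR) KEGG orthologies grouped into antibiotic classes, cellulolytic and
hemicellulolytic enzymes from the CAZy glycoside hydrolase families
(GH5/6/7), and the MetaCyc short-chain fatty acid (SCFA) fermentation
pathways producing acetate, butyrate, lactate or propionate.  For each set
the module counts, per method, in how many samples every member occurs
(prevalence), filters to majority-supported members, and computes the
percent-more and coverage statistics used to judge over- or
under-prediction by the simulated metagenomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .profile_io import read_geneset_table
from .set_comparison import PresenceMatrix


def _round2(x: float) -> float:
    """Round half-up to two decimals (the convention used for reporting)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class GeneSet:
    """A named list of feature IDs, each with one or more class labels.

    Class labels are antibiotic groups for AMR sets, GH-family origins for
    CAZy sets, or fermentation products for SCFA pathway sets (a pathway
    may yield several products).
    """

    name: str
    members: dict[str, tuple[str, ...]]  # feature_id -> class labels

    def __post_init__(self) -> None:
        for fid, labels in self.members.items():
            if not labels:
                raise ValueError(f"{self.name}: member {fid} has no class label")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.members)

    @property
    def class_labels(self) -> list[str]:
        seen: list[str] = []
        for labels in self.members.values():
            for lab in labels:
                if lab not in seen:
                    seen.append(lab)
        return seen

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        """Load from a 2–3 column TSV (feature_id, set_name, class labels).

        Multiple class labels for one feature may be given either as
        repeated rows or comma-separated in the third column.
        """
        df = read_geneset_table(path)
        members: dict[str, list[str]] = {}
        set_name = name or str(df.iloc[0, 1])
        for _, row in df.iterrows():
            fid = str(row.iloc[0])
            labels = (
                [s.strip() for s in str(row.iloc[2]).split(",") if s.strip()]
                if df.shape[1] >= 3 and not pd.isna(row.iloc[2])
                else [str(row.iloc[1])]
            )
            members.setdefault(fid, [])
            for lab in labels:
                if lab not in members[fid]:
                    members[fid].append(lab)
        return cls(set_name, {k: tuple(v) for k, v in members.items()})

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "feature_id": list(self.members),
                "set_name": self.name,
                "class_label": [",".join(v) for v in self.members.values()],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class PrevalenceTable:
    """Gene-set features x methods; cells count samples containing the feature."""

    counts: pd.DataFrame  # features x methods, int
    n_samples: int
    gene_set: GeneSet | None = None

    def __post_init__(self) -> None:
        if ((self.counts < 0) | (self.counts > self.n_samples)).to_numpy().any():
            raise ValueError("prevalence cells must lie in [0, n_samples]")


def prevalence(
    presences: Mapping[str, PresenceMatrix], gene_set: GeneSet
) -> PrevalenceTable:
    """Per-method sample counts for every gene-set member.

    Members absent from every profile are retained as all-zero rows, so a
    set's recovery can be read off directly.
    """
    if not gene_set.members:
        warnings.warn(f"gene set {gene_set.name!r} is empty")
    n_samples = None
    cols = {}
    for label, pm in presences.items():
        if n_samples is None:
            n_samples = len(pm.sample_ids)
        elif len(pm.sample_ids) != n_samples:
            raise ValueError("methods have different sample counts")
        counts = pm.presence.reindex(gene_set.feature_ids, fill_value=False).sum(axis=1)
        cols[label] = counts.astype(int)
    table = pd.DataFrame(cols, index=gene_set.feature_ids)
    return PrevalenceTable(table, n_samples or 0, gene_set)


def majority_filter(
    table: PrevalenceTable,
    threshold: int = 5,
    scope: str = "any-method",
    method: str | None = None,
) -> PrevalenceTable:
    """Keep features present in >= ``threshold`` samples.

    ``scope="any-method"`` keeps a feature iff its count reaches the
    threshold under at least one method; ``scope="per-method"`` looks only
    at ``method``'s column.
    """
    if not 1 <= threshold <= table.n_samples:
        raise ValueError(f"threshold {threshold} outside [1, {table.n_samples}]")
    if scope == "any-method":
        keep = table.counts.max(axis=1) >= threshold
    elif scope == "per-method":
        if method is None:
            raise ValueError("per-method scope requires a method")
        keep = table.counts[method] >= threshold
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return PrevalenceTable(table.counts.loc[keep], table.n_samples, table.gene_set)


def percent_more(count_a: int, count_b: int) -> float:
    """How many percent more features method A identified than method B.

    (a - b)/b x 100, rounded half-up to two decimals; negative when A
    found fewer.
    """
    if count_b <= 0:
        raise ValueError("reference count must be positive")
    if count_a < 0:
        raise ValueError("count must be nonnegative")
    return _round2((count_a - count_b) / count_b * 100.0)


def coverage_fraction(n_shared: int, n_reference: int) -> float:
    """Percent of a reference repertoire recovered: shared/reference x 100."""
    if n_reference <= 0:
        raise ValueError("reference count must be positive")
    if not 0 <= n_shared <= n_reference:
        raise ValueError("n_shared must lie in [0, n_reference]")
    return _round2(n_shared / n_reference * 100.0)


@dataclass
class ScfaPresence:
    """SCFA pathway x method sample counts plus a per-product rollup."""

    pathway_counts: pd.DataFrame  # pathways x methods
    product_rollup: pd.DataFrame  # products x methods: n pathways with >=1 sample
    n_samples: int


def scfa_presence(
    presences: Mapping[str, PresenceMatrix], scfa_set: GeneSet
) -> ScfaPresence:
    """Heat-map style table of SCFA pathway prevalence per method.

    A pathway counts toward a product if at least one sample of that method
    contains it; multi-product pathways count toward each of their products.
    """
    for pm in presences.values():
        if pm.level != "pathway":
            raise ValueError("SCFA analysis requires pathway-level profiles")
    table = prevalence(presences, scfa_set)
    products = scfa_set.class_labels
    rollup = pd.DataFrame(0, index=products, columns=list(table.counts.columns))
    for fid, labels in scfa_set.members.items():
        for method in table.counts.columns:
            if table.counts.loc[fid, method] >= 1:
                for product in labels:
                    rollup.loc[product, method] += 1
    return ScfaPresence(table.counts, rollup, table.n_samples)
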