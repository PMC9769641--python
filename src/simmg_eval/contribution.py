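"""Taxon-specific contributions to the functional repertoire.

From a genus x sample 16S relative-abundance table the abundant genera are
selected (relative abundance strictly above a threshold, default 5%, in at
least one sample).  From a genus-stratified KO profile each genus's
contribution to a sample's repertoire is the number of distinct KOs
attributed to that genus divided by the total number of distinct KOs
detected in the sample — a count of identifiers, not an abundance-weighted
share (a weighted variant is available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile_io import FunctionalProfile, parse_genus


@dataclass
class GenusAbundance:
    """Genus x sample relative abundances in [0, 1]."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("negative relative abundance")
        sums = vals.sum(axis=0)
        if (sums > 1 + 1e-9).any():
            bad = self.table.columns[sums > 1 + 1e-9]
            raise ValueError(f"per-sample abundances exceed 1: {list(bad)}")


@dataclass
class ContributionReport:
    """Per-sample distinct-KO totals and per-genus contribution fractions."""

    total_kos: pd.Series  # per sample
    genus_kos: pd.DataFrame  # genus x sample distinct-KO counts
    genus_fraction: pd.DataFrame  # genus x sample fractions
    combined_fraction: pd.Series  # per sample, selected genera jointly

    def to_frame(self) -> pd.DataFrame:
        out = self.genus_fraction.T.copy()
        out.insert(0, "total_KOs", self.total_kos)
        out["combined"] = self.combined_fraction
        return out


def abundant_genera(
    abund: GenusAbundance | pd.DataFrame, threshold: float = 0.05
) -> list[str]:
    """Genera whose relative abundance strictly exceeds ``threshold`` in
    at least one sample, ordered by maximum abundance descending."""
    table = abund.table if isinstance(abund, GenusAbundance) else abund
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if table.empty:
        return []
    peak = table.max(axis=1)
    selected = peak[peak > threshold]
    return list(selected.sort_values(ascending=False, kind="stable").index)


def genus_contribution(
    profile: FunctionalProfile,
    genera: list[str],
    abundance_weighted: bool = False,
) -> ContributionReport:
    """Quantify each genus's share of the KO repertoire per sample.

    For each sample: genus-specific KOs are the distinct feature IDs with
    any stratified abundance > 0 attributed to the genus; the total is the
    distinct feature IDs with community abundance > 0; fractions are the
    quotients.  The combined fraction counts KOs attributed to at least
    one selected genus, so overlapping attributions are not double-counted.
    KOs stratified only to unclassified taxa stay in the denominator.

    With ``abundance_weighted`` the counts are replaced by abundance sums.
    """
    samples = profile.sample_ids
    genera = [g[3:] if g.startswith("g__") else g for g in genera]

    if abundance_weighted:
        total = profile.abundance.sum(axis=0)
    else:
        total = (profile.abundance > 0).sum(axis=0).astype(float)
    total.name = "total"

    genus_counts = pd.DataFrame(0.0, index=genera, columns=samples)
    combined = pd.Series(0.0, index=samples)

    if profile.stratified is None or not len(profile.stratified):
        warnings.warn("profile has no stratified rows; all genus fractions are 0")
    else:
        strat = profile.stratified
        genus_of_row = np.array(
            [parse_genus(str(t)) or "" for t in strat.index.get_level_values(1)]
        )
        for g in genera:
            rows = strat[genus_of_row == g]
            if not len(rows):
                continue
            feats = rows.index.get_level_values(0)
            if abundance_weighted:
                genus_counts.loc[g] = rows.groupby(level=0).sum().sum(axis=0)
            else:
                present = rows.groupby(level=0).sum() > 0
                genus_counts.loc[g] = present.sum(axis=0).astype(float)
        sel_mask = np.isin(genus_of_row, genera)
        sel_rows = strat[sel_mask]
        if len(sel_rows):
            per_feat = sel_rows.groupby(level=0).sum()
            if abundance_weighted:
                combined = per_feat.sum(axis=0)
            else:
                combined = (per_feat > 0).sum(axis=0).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = genus_counts.div(total.replace(0, np.nan), axis=1).fillna(0.0)
        comb_frac = (combined / total.replace(0, np.nan)).fillna(0.0)
    return ContributionReport(total, genus_counts, frac, comb_frac)
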