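"""Presence/absence set comparison of the three data types.

Given functional profiles for shotgun metagenomes (MG), metatranscriptomes
(MT) and 16S-derived simulated metagenomes (simMG), this module computes:

* per-sample presence (a feature is present iff its abundance is > 0);
* the 7-region exclusive decomposition of the MG/MT/simMG set triple, the
  data behind an UpSet plot, plus cross-sample averages;
* percent similarity, 2I/(2I + R) x 100 with I the intersection count and
  R the counts outside it — identically the Sorensen–Dice coefficient for
  pairwise comparisons;
* the change in percent similarity between the total and the
  prokaryote-only data sets, in percentage points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile_io import FunctionalProfile

#: Fixed region labels, in canonical order.
REGIONS = (
    "MG-only",
    "MT-only",
    "sim-only",
    "MG∩MT-only",
    "MG∩sim-only",
    "MT∩sim-only",
    "MG∩MT∩sim",
)

#: Which methods contain a feature assigned to each region.
REGION_MEMBERS: dict[str, frozenset[str]] = {
    "MG-only": frozenset({"MG"}),
    "MT-only": frozenset({"MT"}),
    "sim-only": frozenset({"simMG"}),
    "MG∩MT-only": frozenset({"MG", "MT"}),
    "MG∩sim-only": frozenset({"MG", "simMG"}),
    "MT∩sim-only": frozenset({"MT", "simMG"}),
    "MG∩MT∩sim": frozenset({"MG", "MT", "simMG"}),
}

#: Supported comparison keys.
PAIRWISE = ("simMG:MG", "simMG:MT", "MG:MT")
THREE_WAY = "simMG:MG:MT"
COMPARISONS = PAIRWISE + (THREE_WAY,)

_METHOD_REGION = {"MG": 0, "MT": 1, "simMG": 2}

# region index -> (bit pattern MG, MT, sim); order matches REGIONS
_REGION_BITS = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
    (1, 1, 1),
)


@dataclass
class PresenceMatrix:
    """Binary feature x sample occurrence derived from a profile."""

    method_label: str
    level: str
    presence: pd.DataFrame  # bool

    @property
    def sample_ids(self) -> list[str]:
        return list(self.presence.columns)

    def sample_set(self, sample: str) -> set[str]:
        col = self.presence[sample]
        return set(col.index[col])

    def per_sample_counts(self) -> pd.Series:
        return self.presence.sum(axis=0)


@dataclass
class IntersectionDecomposition:
    """Per-sample counts of the 7 exclusive regions, plus cross-sample means."""

    per_sample: pd.DataFrame  # samples x 7 regions
    averaged: pd.Series  # 7 regions

    def __post_init__(self) -> None:
        assert tuple(self.per_sample.columns) == REGIONS


@dataclass
class SimilaritySummary:
    """Percent similarity per comparison, for one dataset scope."""

    comparisons: dict[str, float]
    dataset_scope: str = "total"  # or "prokaryote-only"


def binarize(profile: FunctionalProfile) -> PresenceMatrix:
    """Present iff abundance strictly > 0."""
    return PresenceMatrix(profile.method_label, profile.level, profile.abundance > 0)


def decompose_sets(
    mg: PresenceMatrix | pd.DataFrame,
    mt: PresenceMatrix | pd.DataFrame,
    sim: PresenceMatrix | pd.DataFrame,
) -> IntersectionDecomposition:
    """Exclusive 7-region decomposition of the MG/MT/simMG triple, per sample.

    The three presence matrices must share sample ordering; features are
    aligned on the union.  For every sample the 7 counts partition the
    union of the three per-sample feature sets.
    """
    mats = []
    for m in (mg, mt, sim):
        mats.append(m.presence if isinstance(m, PresenceMatrix) else m)
    samples = list(mats[0].columns)
    for m in mats[1:]:
        if list(m.columns) != samples:
            raise ValueError("sample ordering mismatch between presence matrices")
    features = sorted(set().union(*(m.index for m in mats)))
    aligned = [
        m.reindex(index=features, fill_value=False).to_numpy(dtype=bool) for m in mats
    ]
    code = aligned[0].astype(int) + 2 * aligned[1].astype(int) + 4 * aligned[2].astype(int)
    counts = np.zeros((len(samples), 7), dtype=float)
    for ridx, (a, b, c) in enumerate(_REGION_BITS):
        key = a + 2 * b + 4 * c
        counts[:, ridx] = (code == key).sum(axis=0)
    per_sample = pd.DataFrame(counts, index=samples, columns=list(REGIONS))
    return IntersectionDecomposition(per_sample, per_sample.mean(axis=0))


def decompose_feature_sets(
    mg: set[str], mt: set[str], sim: set[str]
) -> dict[str, int]:
    """Region counts for one triple of raw feature sets."""
    counts = {}
    for region, (a, b, c) in zip(REGIONS, _REGION_BITS):
        members = set.intersection(
            *[s for s, bit in ((mg, a), (mt, b), (sim, c)) if bit]
        )
        for s, bit in ((mg, a), (mt, b), (sim, c)):
            if not bit:
                members = members - s
        counts[region] = len(members)
    return counts


def _counts_vector(decomp) -> pd.Series:
    if isinstance(decomp, IntersectionDecomposition):
        return decomp.averaged
    if isinstance(decomp, pd.Series):
        return decomp.reindex(list(REGIONS))
    if isinstance(decomp, dict):
        return pd.Series(decomp).reindex(list(REGIONS))
    raise TypeError(f"cannot interpret {type(decomp)} as region counts")


def percent_similarity(
    decomp,
    comparison: str,
    pairwise_universe: str = "pair",
) -> float:
    """Percent similarity 2I/(2I + R) x 100 over region counts.

    Pairwise ``X:Y``: I is the full two-set intersection (the exclusive
    pair region plus the triple region); R counts features in exactly one
    of X, Y — by default relative to the pair's two-set universe, so
    features found only by the third method are ignored
    (``pairwise_universe="pair"``).  With ``pairwise_universe="triple"``
    third-method-only features are added to R (a stricter variant).
    Three-way: I is the triple region, R the other six regions.

    For pairs this is identically the Sorensen–Dice coefficient x 100.
    """
    c = _counts_vector(decomp)
    if comparison == THREE_WAY:
        inter = c["MG∩MT∩sim"]
        rem = float(c.sum()) - inter
    elif comparison in PAIRWISE:
        x, y = comparison.split(":")
        inter = rem = 0.0
        for region, members in REGION_MEMBERS.items():
            if x in members and y in members:
                inter += c[region]
            elif x in members or y in members:
                rem += c[region]
            elif pairwise_universe == "triple":
                rem += c[region]  # third-method-only region
    else:
        raise KeyError(f"unknown comparison {comparison!r}")
    denom = 2.0 * inter + rem
    if denom == 0:
        warnings.warn(f"{comparison}: all region counts zero; similarity undefined")
        return math.nan
    return 2.0 * inter / denom * 100.0


def similarity_summary(
    decomp,
    dataset_scope: str = "total",
    pairwise_universe: str = "pair",
) -> SimilaritySummary:
    """All four comparisons from one decomposition."""
    return SimilaritySummary(
        {
            cmp: percent_similarity(decomp, cmp, pairwise_universe)
            for cmp in COMPARISONS
        },
        dataset_scope,
    )


def per_sample_similarity(
    decomp: IntersectionDecomposition, comparison: str, **kw
) -> pd.Series:
    """Similarity computed per sample (sensitivity variant: the default
    pipeline averages region counts first, then applies the formula once)."""
    return pd.Series(
        {
            s: percent_similarity(decomp.per_sample.loc[s], comparison, **kw)
            for s in decomp.per_sample.index
        }
    )


def similarity_change(
    total: SimilaritySummary | dict[str, float],
    prok_only: SimilaritySummary | dict[str, float],
) -> dict[str, float]:
    """Signed change (prokaryote-only minus total), in percentage points.

    Reported to two decimals, matching how such deltas are printed.
    """
    t = total.comparisons if isinstance(total, SimilaritySummary) else dict(total)
    p = prok_only.comparisons if isinstance(prok_only, SimilaritySummary) else dict(prok_only)
    missing = set(t).symmetric_difference(p)
    if missing:
        raise KeyError(f"comparisons not present in both summaries: {sorted(missing)}")
    return {k: round(p[k] - t[k], 2) for k in t}
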