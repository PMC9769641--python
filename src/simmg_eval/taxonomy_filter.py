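"""Prokaryote vs non-prokaryote classification of functional features.

Simulated metagenomes derived from 16S amplicons can only contain bacteria
and archaea, while shotgun metagenomes and metatranscriptomes also pick up
viral and eukaryotic sequences.  For a fair comparison the non-prokaryotic
features must be removed from the sequenced data.  The classification works
offline from a feature -> lineage-text map (built, e.g., from saved
MetaCyc/UniProt record text) in two steps:

1. any MG/MT feature also present in the simulated metagenome is assumed
   prokaryotic (the simulation cannot produce anything else);
2. remaining features are classified from lineage text: a feature whose
   lineage contains the token "Bacteria" or "Archaea" is prokaryotic even
   if eukaryotic or viral tokens are also present (the "liberal" rule).

Features that cannot be certified prokaryotic are removed by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .profile_io import FunctionalProfile

PROKARYOTIC = "prokaryotic"
NONPROKARYOTIC = "nonprokaryotic"
UNKNOWN = "unknown"

#: Case-sensitive whole-token rank names recognised in lineage text.
PROK_TOKENS = ("Bacteria", "Archaea")
NONPROK_TOKENS = (
    "Eukaryota",
    "Viruses",
    "Viroids",
    "Viridiplantae",
    "Metazoa",
    "Fungi",
    "Opisthokonta",
)

#: Rank keywords scanned for by the lineage extractor.
DEFAULT_RANK_KEYWORDS = ("Superclasses", "Taxonomic Range", "Organism", "Taxonomy")


@dataclass(frozen=True)
class DomainCall:
    """The domain decision for one feature, with its evidence."""

    feature_id: str
    call: str  # prokaryotic | nonprokaryotic | unknown
    evidence: str  # shared_with_simulated | lineage_text | unresolvable

    def __post_init__(self) -> None:
        if self.evidence == "shared_with_simulated" and self.call != PROKARYOTIC:
            raise ValueError("shared_with_simulated evidence implies a prokaryotic call")


def _has_token(text: str, tokens: tuple[str, ...]) -> bool:
    return any(re.search(rf"\b{re.escape(t)}\b", text) for t in tokens)


def classify_lineage(lineage_text: str) -> str:
    """Classify free lineage text as prokaryotic / nonprokaryotic / unknown.

    Prokaryotic iff the text contains the whole token "Bacteria" or
    "Archaea" (case-sensitive); the match is liberal, so mixed
    prokaryote/eukaryote lineages stay prokaryotic.  Text with no
    recognised rank tokens is unknown.
    """
    if _has_token(lineage_text, PROK_TOKENS):
        return PROKARYOTIC
    if _has_token(lineage_text, NONPROK_TOKENS):
        return NONPROKARYOTIC
    return UNKNOWN


def extract_lineage(
    record_text: str, rank_keywords: tuple[str, ...] = DEFAULT_RANK_KEYWORDS
) -> str:
    """Pull the taxonomy-bearing spans out of a saved record's text.

    Concatenates the remainder of every line whose head matches one of the
    rank keywords (``Keyword: value`` or ``Keyword value``).  Deterministic
    for fixed patterns; no match yields an empty string, which downstream
    classifies as unknown.
    """
    spans: list[str] = []
    pattern = re.compile(
        rf"^\s*({'|'.join(re.escape(k) for k in rank_keywords)})\s*[:=]?\s*(.+)$"
    )
    for line in record_text.splitlines():
        m = pattern.match(line)
        if m and m.group(2).strip():
            spans.append(m.group(2).strip())
    return "; ".join(spans)


def filter_prokaryotic(
    profiles: Mapping[str, FunctionalProfile],
    lineage_map: Mapping[str, str],
    keep_unknown: bool = False,
) -> tuple[dict[str, FunctionalProfile], pd.DataFrame]:
    """Remove non-prokaryotic features from the MG and MT profiles.

    ``profiles`` maps method labels (must include "MG", "MT", "simMG") to
    aligned profiles at one level.  Features shared with the simulated
    metagenome are called prokaryotic outright; the rest are classified
    from ``lineage_map``.  Unknown features are removed unless
    ``keep_unknown``.  The simulated profile is returned unchanged.

    Returns the filtered profiles and an audit table with one row per
    MG/MT feature (feature_id, call, evidence, removed).
    """
    for label in ("MG", "MT", "simMG"):
        if label not in profiles:
            raise KeyError(f"missing {label} profile")
    levels = {p.level for p in profiles.values()}
    if len(levels) != 1:
        raise ValueError(f"profiles at mixed levels: {sorted(levels)}")

    sim = profiles["simMG"]
    sim_present = set(sim.abundance.index[(sim.abundance > 0).any(axis=1)])

    calls: list[DomainCall] = []
    seen: set[str] = set()
    for label in ("MG", "MT"):
        prof = profiles[label]
        present = prof.abundance.index[(prof.abundance > 0).any(axis=1)]
        for feat in present:
            if feat in seen:
                continue
            seen.add(feat)
            if feat in sim_present:
                calls.append(DomainCall(feat, PROKARYOTIC, "shared_with_simulated"))
            elif feat in lineage_map:
                call = classify_lineage(lineage_map[feat])
                evidence = "lineage_text" if call != UNKNOWN else "unresolvable"
                calls.append(DomainCall(feat, call, evidence))
            else:
                calls.append(DomainCall(feat, UNKNOWN, "unresolvable"))

    keep_calls = {PROKARYOTIC} | ({UNKNOWN} if keep_unknown else set())
    removed = {c.feature_id for c in calls if c.call not in keep_calls}

    out: dict[str, FunctionalProfile] = {}
    for label, prof in profiles.items():
        if label == "simMG":
            out[label] = prof.copy()
            continue
        keep = [f for f in prof.features if f not in removed]
        ab = prof.abundance.loc[keep]
        strat = prof.stratified
        if strat is not None and len(strat):
            strat = strat[strat.index.get_level_values(0).isin(set(keep))]
        out[label] = FunctionalProfile(
            prof.method_label, prof.level, ab, strat, prof.unmapped_mass
        )

    audit = pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "call": [c.call for c in calls],
            "evidence": [c.evidence for c in calls],
            "removed": [c.feature_id in removed for c in calls],
        }
    ).sort_values("feature_id", ignore_index=True)
    return out, audit
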