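"""Synthetic multi-omics studies with planted, recoverable structure.

Generates coupled MG/MT/simMG functional-profile tables over a shared
feature pool in which every feature is planted into one of the 7 exclusive
regions of the three-set decomposition, so downstream set statistics can be
checked against known truth.  Also emulates the nuisance structure of real
studies: independent per-feature/sample/method presence noise, a
non-prokaryotic (viral/eukaryotic) contaminant fraction that appears in the
sequenced data but never in the simulated metagenome, whole-feature
transcription dropout in the metatranscriptome, genus-stratified
attribution of metagenome features, a genus x sample 16S relative-abundance
table, and a per-ASV NSTI table.

Feature IDs live in synthetic namespaces (K9xxxx, 9.9.x.x, SYN-PWY-n) that
are syntactically valid but disjoint from real catalogue IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .contribution import GenusAbundance
from .geneset_analysis import GeneSet
from .profile_io import (
    AsvRecord,
    FunctionalProfile,
    write_asv_table,
    write_lineage_map,
    write_profile,
)
from .set_comparison import REGION_MEMBERS, REGIONS

#: Default region counts: a scaled-down feature pool with the triple
#: region largest, MG∩sim second, and MT∩sim smallest — the qualitative
#: structure of three-way comparisons of sequenced vs simulated data.
DEFAULT_REGION_COUNTS: dict[str, int] = {
    "MG-only": 40,
    "MT-only": 8,
    "sim-only": 25,
    "MG∩MT-only": 12,
    "MG∩sim-only": 45,
    "MT∩sim-only": 4,
    "MG∩MT∩sim": 90,
}

#: Default genus pool: the recurrent high-abundance genera of a wild
#: goose-type gut community, with plausible mean relative abundances.
DEFAULT_GENUS_POOL: dict[str, float] = {
    "Bacteroides": 0.18,
    "Faecalibacterium": 0.16,
    "Subdoligranulum": 0.14,
    "Megamonas": 0.12,
    "Turicibacter": 0.10,
    "Helicobacter": 0.09,
    "Escherichia": 0.08,
    "Campylobacter": 0.07,
    "Curtobacterium": 0.06,
}

_PROK_LINEAGES = (
    "cellular organisms; Bacteria; Firmicutes; Clostridia",
    "cellular organisms; Bacteria; Bacteroidetes",
    "cellular organisms; Bacteria; Proteobacteria; Gammaproteobacteria",
    "cellular organisms; Bacteria; Actinobacteria",
    "cellular organisms; Archaea; Euryarchaeota",
)

_CONTAMINANT_LINEAGES = (
    "Viruses; Riboviria; Bromoviridae",
    "Viruses; Retroviridae",
    "Viruses; Alphaflexiviridae",
    "Eukaryota; Viridiplantae; Streptophyta",
    "Eukaryota; Opisthokonta; Fungi",
    "Eukaryota; Metazoa; Chordata",
)


class ConfigError(ValueError):
    """Invalid synthetic-study configuration; message names the field."""


@dataclass
class SyntheticConfig:
    """Parameters of a planted synthetic study.

    Defaults describe the emulated study design: nine paired samples, a
    224-feature pool with the region structure above, a dozen
    non-prokaryotic contaminants in the sequenced tables, and an ASV
    table of 1,129 variants of which 71 exceed the NSTI reliability
    cutoff of 2.
    """

    n_samples: int = 9
    region_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_COUNTS)
    )
    presence_noise: float = 0.0
    mt_dropout: float = 0.0
    contaminant_count: int = 12
    genus_pool: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENUS_POOL)
    )
    stratified_fraction: float = 0.6
    level: str = "KO"
    n_asvs: int = 1129
    n_high_nsti: int = 71
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        unknown = set(self.region_counts) - set(REGIONS)
        if unknown:
            raise ConfigError(f"region_counts has unknown regions: {sorted(unknown)}")
        for region, count in self.region_counts.items():
            if count < 0:
                raise ConfigError(f"region_counts[{region!r}] must be >= 0")
        for name in ("presence_noise", "mt_dropout", "stratified_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.contaminant_count < 0:
            raise ConfigError("contaminant_count must be >= 0")
        if self.genus_pool:
            weights = np.array(list(self.genus_pool.values()), dtype=float)
            if (weights < 0).any():
                raise ConfigError("genus_pool weights must be >= 0")
            if abs(weights.sum() - 1.0) > 1e-9:
                raise ConfigError("genus_pool weights must sum to 1")
        if self.level not in ("KO", "EC", "pathway"):
            raise ConfigError(f"level must be KO, EC or pathway, not {self.level!r}")
        if self.n_asvs < 0 or self.n_high_nsti < 0 or self.n_high_nsti > self.n_asvs:
            raise ConfigError("n_high_nsti must lie in [0, n_asvs]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        """Load from a YAML mapping or a flat ``key=value`` file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if isinstance(data, str):  # flat key=value lines
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                k, v = line.split("=", 1)
                data[k.strip()] = yaml.safe_load(v.strip())
        if not isinstance(data, dict):
            raise ConfigError(f"cannot parse config file {path}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class SyntheticStudy:
    """A generated study plus the planted truth needed to verify it."""

    profiles: dict[str, FunctionalProfile]
    lineage_map: dict[str, str]
    truth: dict[str, str]  # feature -> region after any MT dropout
    contaminants: list[str]
    attribution: dict[str, list[str]]  # genus -> features attributed to it
    asv_records: list[AsvRecord]
    genus_abundance: GenusAbundance
    config: SyntheticConfig

    def planted_region_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in REGIONS}
        for region in self.truth.values():
            if region in counts:
                counts[region] += 1
        return counts


def _feature_id(level: str, i: int) -> str:
    if level == "KO":
        return f"K9{i:04d}"
    if level == "EC":
        return f"9.9.{1 + i // 100}.{1 + i % 100}"
    return f"SYN-PWY-{i + 1}"


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a coupled MG/MT/simMG study from a validated config.

    Identical configs (including the seed) yield identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    methods = ("MG", "MT", "simMG")

    # --- plant features into regions ------------------------------------
    features: list[str] = []
    truth: dict[str, str] = {}
    planted: dict[str, set[str]] = {}
    counter = 0
    for region in REGIONS:
        for _ in range(config.region_counts.get(region, 0)):
            fid = _feature_id(config.level, counter)
            counter += 1
            features.append(fid)
            truth[fid] = region
            planted[fid] = set(REGION_MEMBERS[region])

    contaminants: list[str] = []
    for _ in range(config.contaminant_count):
        fid = _feature_id(config.level, counter)
        counter += 1
        features.append(fid)
        truth[fid] = "MG∩MT-only"
        planted[fid] = {"MG", "MT"}
        contaminants.append(fid)

    # --- metatranscriptome dropout (whole features, truth updated) ------
    if config.mt_dropout > 0:
        for fid in features:
            if fid in contaminants or "MT" not in planted[fid]:
                continue
            if rng.random() < config.mt_dropout:
                planted[fid].discard("MT")
                truth[fid] = _region_of(planted[fid])

    # --- presence with independent noise, then abundances ---------------
    presence = {
        m: pd.DataFrame(False, index=features, columns=samples) for m in methods
    }
    for fid in features:
        for m in planted[fid]:
            keep = rng.random(config.n_samples) >= config.presence_noise
            presence[m].loc[fid] = keep

    profiles: dict[str, FunctionalProfile] = {}
    abundances: dict[str, pd.DataFrame] = {}
    for m in methods:
        mask = presence[m].to_numpy()
        ab = np.where(mask, np.round(rng.lognormal(5.0, 1.0, mask.shape), 4), 0.0)
        abundances[m] = pd.DataFrame(ab, index=features, columns=samples)

    # --- genus-stratified attribution of MG features ---------------------
    attribution: dict[str, list[str]] = {g: [] for g in config.genus_pool}
    stratified = None
    if config.genus_pool and config.stratified_fraction > 0:
        genera = list(config.genus_pool)
        weights = np.array(list(config.genus_pool.values()), dtype=float)
        rows = []
        for fid in features:
            if fid in contaminants or "MG" not in planted[fid]:
                continue
            if rng.random() >= config.stratified_fraction:
                continue
            genus = genera[rng.choice(len(genera), p=weights)]
            attribution[genus].append(fid)
            share = rng.uniform(0.4, 0.9)
            taxon = f"g__{genus}.s__{genus}_unclassified"
            rows.append(
                pd.Series(
                    np.round(abundances["MG"].loc[fid].to_numpy() * share, 4),
                    index=samples,
                    name=(fid, taxon),
                )
            )
        if rows:
            stratified = pd.DataFrame(rows)
            stratified.index = pd.MultiIndex.from_tuples(
                stratified.index, names=["feature", "taxon"]
            )

    for m in methods:
        profiles[m] = FunctionalProfile(
            m,
            config.level,
            abundances[m],
            stratified if m == "MG" else None,
        )

    # --- lineage map ------------------------------------------------------
    lineage_map: dict[str, str] = {}
    for fid in features:
        if fid in contaminants:
            lineage_map[fid] = _CONTAMINANT_LINEAGES[
                rng.integers(len(_CONTAMINANT_LINEAGES))
            ]
        else:
            lineage_map[fid] = _PROK_LINEAGES[rng.integers(len(_PROK_LINEAGES))]

    # --- genus x sample relative abundances ------------------------------
    if config.genus_pool:
        weights = np.array(list(config.genus_pool.values()), dtype=float)
        draws = rng.dirichlet(weights * 60.0, size=config.n_samples).T
        genus_abundance = GenusAbundance(
            pd.DataFrame(draws, index=list(config.genus_pool), columns=samples)
        )
    else:
        genus_abundance = GenusAbundance(pd.DataFrame(columns=samples))

    # --- ASV table with planted NSTI structure ----------------------------
    asv_records: list[AsvRecord] = []
    high = set(
        rng.choice(config.n_asvs, size=config.n_high_nsti, replace=False).tolist()
        if config.n_asvs
        else []
    )
    for i in range(config.n_asvs):
        nsti = (
            float(np.round(2.0 + rng.uniform(0.05, 8.0), 4))
            if i in high
            else float(np.round(rng.uniform(0.0, 2.0), 4))
        )
        asv_records.append(
            AsvRecord(f"ASV{i + 1:05d}", int(rng.integers(50, 20000)), nsti)
        )

    return SyntheticStudy(
        profiles,
        lineage_map,
        truth,
        contaminants,
        {g: sorted(f) for g, f in attribution.items()},
        asv_records,
        genus_abundance,
        config,
    )


def _region_of(methods: set[str]) -> str:
    for region, members in REGION_MEMBERS.items():
        if members == frozenset(methods):
            return region
    return "absent"


#: SCFA pathways named in curated fermentation references, with products.
NAMED_SCFA_PATHWAYS: dict[str, tuple[str, ...]] = {
    "P161-PWY": ("acetate",),
    "P162-PWY": ("acetate", "butyrate"),
    "P163-PWY": ("acetate", "butyrate"),
    "P124-PWY": ("acetate", "lactate"),
    "P461-PWY": ("acetate", "lactate"),
    "PWY-5100": ("acetate", "lactate"),
    "GLUDEG-II-PWY": ("butyrate",),
    "PWY-5677": ("butyrate",),
    "PROPFERM-PWY": ("propionate",),
    "ANAEROFRUCAT-PWY": ("lactate",),
}

#: Synthetic stand-ins completing the 16-pathway fixture with product
#: multiplicities acetate 6, butyrate 7, lactate 5, propionate 3.
_SYNTHETIC_SCFA_PATHWAYS: dict[str, tuple[str, ...]] = {
    "SYN-SCFA-PWY-1": ("butyrate",),
    "SYN-SCFA-PWY-2": ("butyrate",),
    "SYN-SCFA-PWY-3": ("butyrate",),
    "SYN-SCFA-PWY-4": ("lactate",),
    "SYN-SCFA-PWY-5": ("propionate",),
    "SYN-SCFA-PWY-6": ("propionate",),
}

#: The 11 antibiotic classes an AMR KO may resist, with the size of each
#: class in the curated catalogue (181 assignments over 162 unique KOs;
#: 19 KOs carry two classes).
AMR_CLASS_SIZES: dict[str, int] = {
    "aminoglycosides": 39,
    "fosfomycin": 5,
    "macrolide-lincosamide-streptogramin": 19,
    "penicillin": 66,
    "phenicol": 8,
    "quinolone": 2,
    "rifamycin": 4,
    "sulfonamide": 3,
    "tetracycline": 11,
    "trimethoprim": 6,
    "vancomycin": 18,
}

AMR_UNIQUE_KOS = 162
CAZY_EC_COUNT = 102


def scfa_geneset(
    extra: Mapping[str, tuple[str, ...]] | None = None
) -> GeneSet:
    """The 16-pathway SCFA fixture.

    ``extra`` replaces the synthetic stand-ins with a user-supplied list of
    pathway -> products when the real identities are known.
    """
    members = dict(NAMED_SCFA_PATHWAYS)
    members.update(extra if extra is not None else _SYNTHETIC_SCFA_PATHWAYS)
    return GeneSet("SCFA", members)


def amr_geneset() -> GeneSet:
    """162 unique synthetic AMR KOs over the 11 antibiotic classes.

    Class sizes follow the curated catalogue; the 19 assignments beyond
    162 are distributed as second classes, deterministically.
    """
    assignments: list[str] = []
    for cls, size in AMR_CLASS_SIZES.items():
        assignments.extend([cls] * size)
    members: dict[str, list[str]] = {}
    kos = [f"K99{i:03d}" for i in range(AMR_UNIQUE_KOS)]
    for ko, cls in zip(kos, assignments[:AMR_UNIQUE_KOS]):
        members[ko] = [cls]
    extra = assignments[AMR_UNIQUE_KOS:]
    i = 0
    for cls in extra:
        while members[kos[i % AMR_UNIQUE_KOS]][0] == cls or len(members[kos[i % AMR_UNIQUE_KOS]]) > 1:
            i += 1
        members[kos[i % AMR_UNIQUE_KOS]].append(cls)
        i += 1
    return GeneSet("AMR", {k: tuple(v) for k, v in members.items()})


def cazy_geneset() -> GeneSet:
    """Placeholder set of 102 cellulolytic/hemicellulolytic ECs (GH5/6/7)."""
    families = ("GH5", "GH6", "GH7")
    return GeneSet(
        "CAZy",
        {
            f"9.2.1.{i + 1}": (families[i % 3],)
            for i in range(CAZY_EC_COUNT)
        },
    )


def generate_geneset_fixtures() -> list[GeneSet]:
    """The three curated gene-set fixtures: SCFA, AMR, CAZy."""
    return [scfa_geneset(), amr_geneset(), cazy_geneset()]


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture of a study as TSV; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for label, profile in study.profiles.items():
        p = outdir / f"{label}_{profile.level}.tsv"
        write_profile(profile, p)
        paths[label] = p
    paths["lineage_map"] = outdir / "lineage_map.tsv"
    write_lineage_map(study.lineage_map, paths["lineage_map"])
    paths["asv_table"] = outdir / "asv_nsti.tsv"
    write_asv_table(study.asv_records, paths["asv_table"])
    paths["genus_abundance"] = outdir / "genus_abundance.tsv"
    study.genus_abundance.table.to_csv(
        paths["genus_abundance"], sep="\t", index_label="genus"
    )
    paths["truth"] = outdir / "truth_regions.tsv"
    pd.Series(study.truth, name="region").to_csv(
        paths["truth"], sep="\t", index_label="feature_id"
    )
    for gs in generate_geneset_fixtures():
        p = outdir / f"geneset_{gs.name.lower()}.tsv"
        gs.to_tsv(p)
        paths[f"geneset_{gs.name.lower()}"] = p
    return paths
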