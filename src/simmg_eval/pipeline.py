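"""End-to-end orchestration: load, align, compare, filter, repeat, report.

The pipeline mirrors a full comparative analysis: align the three data
types per functional level; on the total data set compute per-sample
feature counts, the 7-region decomposition, percent-similarity summaries
and pairwise Wilcoxon count comparisons; remove non-prokaryotic features
and repeat; difference the two similarity summaries; then run the gene-set
prevalence analyses, Jaccard/PCoA/PERMANOVA ordination, the NSTI filter
report and the genus-contribution report.  Everything is deterministic
under a fixed seed and is written as TSV plus one JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .contribution import GenusAbundance, abundant_genera, genus_contribution
from .geneset_analysis import (
    GeneSet,
    coverage_fraction,
    majority_filter,
    percent_more,
    prevalence,
    scfa_presence,
)
from .ordination_stats import jaccard_distances, pcoa, permanova, wilcoxon_rank_sum
from .profile_io import (
    FunctionalProfile,
    filter_by_nsti,
    merge_profiles,
    read_asv_table,
    read_lineage_map,
    read_profile,
)
from .set_comparison import (
    COMPARISONS,
    PAIRWISE,
    binarize,
    decompose_sets,
    per_sample_similarity,
    similarity_change,
    similarity_summary,
)
from .taxonomy_filter import filter_prokaryotic

logger = logging.getLogger(__name__)

_KO_RE = r"^K\d{5}$"
_EC_RE = r"^\d+\.[\d\-]+\.[\d\-]+\.[\d\-]+$"


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    profile_paths: dict[str, dict[str, str]] = field(default_factory=dict)
    # level -> {MG, MT, simMG} -> path
    lineage_map_path: str | None = None
    geneset_paths: dict[str, str] = field(default_factory=dict)
    # set name ("AMR", "CAZy", "SCFA") -> path
    asv_table_path: str | None = None
    genus_abundance_path: str | None = None
    nsti_cutoff: float = 2.0
    prevalence_threshold: int = 5
    genus_threshold: float = 0.05
    n_permutations: int = 999
    seed: int = 0
    output_dir: str = "simmg_eval_out"
    keep_unknown: bool = False
    per_sample_similarity: bool = False
    abundance_weighted_contribution: bool = False
    pairwise_universe: str = "pair"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def content_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir", None)  # where results land is not what they are
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Check file existence, table alignment and ID syntax per level.

    Warnings are non-fatal (e.g. unpaired samples that will be dropped);
    errors are fatal (missing files, no shared samples, a prokaryote
    filter requested without a lineage map).
    """
    report = ValidationReport()
    for level, methods in config.profile_paths.items():
        samples: dict[str, set[str]] = {}
        for method, path in methods.items():
            if not Path(path).exists():
                report.errors.append(f"{level}/{method}: missing file {path}")
                continue
            try:
                prof = read_profile(path, method, level)
            except Exception as exc:  # parse problems are fatal
                report.errors.append(f"{level}/{method}: {exc}")
                continue
            samples[method] = set(prof.sample_ids)
            pattern = _KO_RE if level == "KO" else _EC_RE if level == "EC" else None
            if pattern is not None and len(prof.features):
                bad = [f for f in prof.features if not pd.Series([f]).str.match(pattern)[0]]
                if bad:
                    report.warnings.append(
                        f"{level}/{method}: {len(bad)} feature IDs do not look like "
                        f"{level} identifiers (e.g. {bad[0]!r})"
                    )
        if len(samples) >= 2:
            shared = set.intersection(*samples.values())
            for method, s in samples.items():
                unpaired = sorted(s - shared)
                if unpaired:
                    report.warnings.append(
                        f"{level}/{method}: {len(unpaired)} unpaired samples will be "
                        f"dropped: {', '.join(unpaired)}"
                    )
            if not shared:
                report.errors.append(f"{level}: no samples shared by all methods")
    if config.lineage_map_path is None and config.profile_paths:
        report.errors.append(
            "prokaryote filtering requested but no lineage map provided"
        )
    elif config.lineage_map_path and not Path(config.lineage_map_path).exists():
        report.errors.append(f"missing lineage map {config.lineage_map_path}")
    for name, path in config.geneset_paths.items():
        if not Path(path).exists():
            report.errors.append(f"gene set {name}: missing file {path}")
    for label, path in (
        ("ASV table", config.asv_table_path),
        ("genus abundance", config.genus_abundance_path),
    ):
        if path is not None and not Path(path).exists():
            report.errors.append(f"missing {label} {path}")
    return report


def _scope_analysis(
    profiles: Mapping[str, FunctionalProfile],
    scope: str,
    pairwise_universe: str,
    want_per_sample: bool,
) -> dict[str, Any]:
    presences = {m: binarize(p) for m, p in profiles.items()}
    decomp = decompose_sets(presences["MG"], presences["MT"], presences["simMG"])
    counts = pd.DataFrame(
        {m: pm.per_sample_counts() for m, pm in presences.items()}
    )
    summary = similarity_summary(decomp, scope, pairwise_universe)
    out = {
        "presences": presences,
        "decomposition": decomp,
        "per_sample_counts": counts,
        "similarity": summary,
    }
    if want_per_sample:
        out["per_sample_similarity"] = pd.DataFrame(
            {
                cmp: per_sample_similarity(decomp, cmp, pairwise_universe=pairwise_universe)
                for cmp in COMPARISONS
            }
        )
    wilcox = {}
    for cmp in PAIRWISE:
        a, b = cmp.split(":")
        stat, p = wilcoxon_rank_sum(counts[a], counts[b])
        wilcox[cmp] = {"statistic": stat, "p_value": p}
    out["wilcoxon"] = pd.DataFrame(wilcox).T
    return out


def analyze_level(
    profiles: Mapping[str, FunctionalProfile],
    lineage_map: Mapping[str, str],
    seed: int = 0,
    n_permutations: int = 999,
    keep_unknown: bool = False,
    pairwise_universe: str = "pair",
    want_per_sample: bool = False,
) -> dict[str, Any]:
    """Full total + prokaryote-only comparison for one functional level."""
    aligned = merge_profiles(list(profiles.values()))
    total = _scope_analysis(aligned, "total", pairwise_universe, want_per_sample)
    filtered, audit = filter_prokaryotic(aligned, lineage_map, keep_unknown)
    prok = _scope_analysis(filtered, "prokaryote-only", pairwise_universe, want_per_sample)
    deltas = similarity_change(total["similarity"], prok["similarity"])

    # pooled ordination: sample x method points on the union feature universe
    pooled = pd.concat(
        {m: pm.presence for m, pm in total["presences"].items()}, axis=1
    )
    pooled.columns = [f"{m}:{s}" for m, s in pooled.columns]
    dm = jaccard_distances(pooled)
    groups = [lbl.split(":", 1)[0] for lbl in dm.labels]
    ordination = pcoa(dm)
    perma = permanova(dm, groups, n_permutations=n_permutations, seed=seed)

    return {
        "aligned": aligned,
        "total": total,
        "prokaryote_only": prok,
        "audit": audit,
        "similarity_change": deltas,
        "distance_matrix": dm,
        "ordination": ordination,
        "permanova": perma,
    }


def analyze_genesets(
    presences_by_level: Mapping[str, Mapping[str, Any]],
    gene_sets: Mapping[str, GeneSet],
    prevalence_threshold: int = 5,
) -> dict[str, Any]:
    """AMR / CAZy / SCFA prevalence analyses on binarized profiles.

    ``presences_by_level`` maps level -> method -> PresenceMatrix.  AMR
    runs at KO level, CAZy at EC level, SCFA at pathway level; a set whose
    level is absent is skipped.
    """
    out: dict[str, Any] = {}
    level_of = {"AMR": "KO", "CAZy": "EC", "SCFA": "pathway"}
    for name, gs in gene_sets.items():
        level = level_of.get(name, "KO")
        if level not in presences_by_level:
            continue
        presences = presences_by_level[level]
        if name == "SCFA":
            out[name] = scfa_presence(presences, gs)
            continue
        table = prevalence(presences, gs)
        detected = (table.counts >= 1).sum(axis=0)
        entry: dict[str, Any] = {"prevalence": table, "detected_per_method": detected}
        thr = min(prevalence_threshold, table.n_samples) if table.n_samples else 1
        if table.n_samples:
            entry["majority"] = majority_filter(table, thr)
        if detected.get("MG", 0) > 0:
            entry["percent_more_sim_vs_mg"] = percent_more(
                int(detected["simMG"]), int(detected["MG"])
            )
        if detected.get("MT", 0) > 0:
            entry["percent_more_sim_vs_mt"] = percent_more(
                int(detected["simMG"]), int(detected["MT"])
            )
        if "majority" in entry:
            maj = entry["majority"].counts
            mg_majority = set(maj.index[maj["MG"] >= thr])
            if mg_majority:
                shared = sum(
                    1 for f in mg_majority if table.counts.loc[f, "simMG"] >= 1
                )
                entry["coverage_sim_of_mg_majority"] = coverage_fraction(
                    shared, len(mg_majority)
                )
        out[name] = entry
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis described by ``config``.

    Outputs are written under ``config.output_dir`` (TSV tables plus a
    ``manifest.json``); partial outputs are removed on failure.  Returns
    the in-memory result bundle.
    """
    report = validate_inputs(config)
    for w in report.warnings:
        logger.warning(w)
    if not report.ok:
        raise PipelineError("validation failed: " + "; ".join(report.errors))

    stage = "load"
    try:
        lineage_map = (
            read_lineage_map(config.lineage_map_path)
            if config.lineage_map_path
            else {}
        )
        profiles_by_level = {
            level: {
                m: read_profile(path, m, level) for m, path in methods.items()
            }
            for level, methods in config.profile_paths.items()
        }
        gene_sets = {
            name: GeneSet.from_tsv(path, name)
            for name, path in config.geneset_paths.items()
        }

        results: dict[str, Any] = {"levels": {}, "genesets": {}}
        for level, profs in profiles_by_level.items():
            stage = f"compare[{level}]"
            logger.info("analysing level %s (%d profiles)", level, len(profs))
            results["levels"][level] = analyze_level(
                profs,
                lineage_map,
                seed=config.seed,
                n_permutations=config.n_permutations,
                keep_unknown=config.keep_unknown,
                pairwise_universe=config.pairwise_universe,
                want_per_sample=config.per_sample_similarity,
            )

        stage = "genesets"
        presences_by_level = {
            level: res["total"]["presences"]
            for level, res in results["levels"].items()
        }
        results["genesets"] = analyze_genesets(
            presences_by_level, gene_sets, config.prevalence_threshold
        )

        stage = "nsti"
        if config.asv_table_path:
            records = read_asv_table(config.asv_table_path)
            results["nsti"] = filter_by_nsti(records, config.nsti_cutoff)

        stage = "contribution"
        if config.genus_abundance_path and "KO" in results["levels"]:
            table = pd.read_csv(
                config.genus_abundance_path, sep="\t", index_col=0
            )
            genera = abundant_genera(GenusAbundance(table), config.genus_threshold)
            mg = results["levels"]["KO"]["aligned"]["MG"]
            results["contribution"] = {
                "selected_genera": genera,
                "report": genus_contribution(
                    mg, genera, config.abundance_weighted_contribution
                ),
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    _write_bundle(results, config)
    return results


def _write_bundle(results: Mapping[str, Any], config: RunConfig) -> None:
    """Write the TSV bundle atomically (stage in a temp dir, then move)."""
    outdir = Path(config.output_dir)
    tmp = Path(tempfile.mkdtemp(prefix="simmg_eval_"))
    files: list[str] = []

    def save(df: pd.DataFrame | pd.Series, name: str, **kw) -> None:
        path = tmp / name
        df.to_csv(path, sep="\t", **kw)
        files.append(name)

    try:
        for level, res in results["levels"].items():
            for scope_key, scope_name in (("total", "total"), ("prokaryote_only", "prok")):
                sres = res[scope_key]
                save(sres["decomposition"].per_sample, f"{level}_{scope_name}_regions.tsv")
                save(
                    sres["decomposition"].averaged.rename("mean_count"),
                    f"{level}_{scope_name}_regions_avg.tsv",
                )
                save(sres["per_sample_counts"], f"{level}_{scope_name}_counts.tsv")
                save(
                    pd.Series(sres["similarity"].comparisons, name="percent"),
                    f"{level}_{scope_name}_similarity.tsv",
                )
                save(sres["wilcoxon"], f"{level}_{scope_name}_wilcoxon.tsv")
            save(
                pd.Series(res["similarity_change"], name="delta_points"),
                f"{level}_similarity_change.tsv",
            )
            save(res["audit"], f"{level}_prokaryote_audit.tsv", index=False)
            dm = res["distance_matrix"]
            save(
                pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels),
                f"{level}_jaccard.tsv",
            )
            ordn = res["ordination"]
            coords = pd.DataFrame(
                ordn.coordinates,
                index=dm.labels,
                columns=[f"PCo{i + 1}" for i in range(ordn.coordinates.shape[1])],
            )
            save(coords, f"{level}_pcoa.tsv")
            perma = res["permanova"]
            save(
                pd.DataFrame(
                    [
                        {
                            "pseudo_F": perma.pseudo_F,
                            "R2": perma.r_squared,
                            "p_value": perma.p_value,
                            "permutations": perma.n_permutations,
                            "seed": perma.seed,
                        }
                    ]
                ),
                f"{level}_permanova.tsv",
                index=False,
            )
        for name, entry in results.get("genesets", {}).items():
            if hasattr(entry, "pathway_counts"):  # SCFA
                save(entry.pathway_counts, f"geneset_{name}_pathways.tsv")
                save(entry.product_rollup, f"geneset_{name}_products.tsv")
            else:
                save(entry["prevalence"].counts, f"geneset_{name}_prevalence.tsv")
                stats = {
                    k: v
                    for k, v in entry.items()
                    if isinstance(v, (int, float))
                }
                stats.update(
                    {f"detected_{m}": int(c) for m, c in entry["detected_per_method"].items()}
                )
                save(pd.Series(stats, name="value"), f"geneset_{name}_stats.tsv")
        if "nsti" in results:
            r = results["nsti"]
            save(
                pd.DataFrame(
                    [
                        {
                            "n_input": len(r.retained) + len(r.discarded),
                            "n_discarded": len(r.discarded),
                            "asv_fraction_discarded": r.asv_fraction_discarded,
                            "read_fraction_discarded": r.read_fraction_discarded,
                        }
                    ]
                ),
                "nsti_filter.tsv",
                index=False,
            )
        if "contribution" in results:
            save(
                results["contribution"]["report"].to_frame(),
                "contribution.tsv",
            )
        manifest = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
            "files": sorted(files),
        }
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        files.append("manifest.json")

        outdir.mkdir(parents=True, exist_ok=True)
        for name in files:
            shutil.move(str(tmp / name), str(outdir / name))
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
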