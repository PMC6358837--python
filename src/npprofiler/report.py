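"""Multi-library profiling runs: configuration, orchestration, reporting.

:func:`run_profile` stitches the individual stages — curation, property
profiling, scaffold diversity, fingerprint diversity, CD plot — into one
reproducible bundle of CSV/JSON/SVG artifacts plus a Markdown summary. Every
artifact embeds the seed and the module decisions in force (descriptor
engine, fingerprint dictionary, scaling scope, diversity statistic) so a
number can always be traced to the conventions that produced it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from . import chemspace, consensus, descriptors, fingerprints, library_io, scaffolds

logger = logging.getLogger("npprofiler")

ALL_STAGES = ("curate", "properties", "scaffolds", "fpdiv", "cdplot")


@dataclass
class RunConfig:
    """One profiling run over one or more labelled libraries."""

    libraries: list[tuple[str, str]]  # (label, path) pairs; CSV schema files
    out_dir: str = "profile_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    format: str = "csv"
    diversity_statistic: str = "mean"
    scaling_scope: str = "union"

    def validate(self) -> None:
        labels = [lbl for lbl, _ in self.libraries]
        if len(labels) != len(set(labels)):
            raise ValueError("library labels must be unique")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _metadata(config: RunConfig) -> dict:
    return {
        "npprofiler_version": __version__,
        "seed": config.seed,
        "descriptor_engine": descriptors.ENGINE_METADATA,
        "fingerprint_engine": fingerprints.ENGINE_METADATA,
        "scaling_scope": config.scaling_scope,
        "property_diversity_statistic": config.diversity_statistic,
    }


def run_profile(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns a dict of the key computed quantities per library. Re-running
    with an identical config reproduces every output (stochastic stages are
    seeded). Any stage failure aborts with the stage and library named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _metadata(config)
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))

    curated: dict[str, library_io.CuratedLibrary] = {}
    results: dict = {"metadata": meta, "libraries": {}}
    summary_lines = [
        "# Library profiling report", "",
        f"seed: {config.seed}", "",
    ]

    for label, path in config.libraries:
        t0 = time.time()
        try:
            records = library_io.parse_library(path, format=config.format)
            lib, rep = library_io.curate(records, name=label)
        except Exception as exc:
            raise RuntimeError(f"stage curate failed for library {label!r}: {exc}") from exc
        curated[label] = lib
        results["libraries"][label] = {"curation": rep.as_dict()}
        if "curate" in config.stages:
            library_io.write_library(lib, format="csv", path=out / f"{label}_curated.csv")
            (out / f"{label}_curation_report.json").write_text(
                json.dumps(rep.as_dict(), indent=2)
            )
        logger.info("curate[%s]: %d -> %d records (%.2fs)",
                    label, rep.n_input, rep.n_output, time.time() - t0)

    tables = {}
    if {"properties", "cdplot"} & set(config.stages):
        for label, lib in curated.items():
            t0 = time.time()
            try:
                tables[label] = descriptors.property_table(lib)
            except Exception as exc:
                raise RuntimeError(
                    f"stage properties failed for library {label!r}: {exc}"
                ) from exc
            if "properties" in config.stages:
                tables[label].to_csv(out / f"{label}_properties.csv")
                summaries = descriptors.summarize_table(tables[label])
                (out / f"{label}_property_summary.json").write_text(
                    json.dumps({k: v.as_dict() for k, v in summaries.items()}, indent=2)
                )
                results["libraries"][label]["property_medians"] = {
                    k: v.median for k, v in summaries.items()
                }
            logger.info("properties[%s] (%.2fs)", label, time.time() - t0)
        if "properties" in config.stages and tables:
            descriptors.plot_boxplots(tables, path=str(out / "property_boxplots.svg"))

    profiles = {}
    if {"scaffolds", "cdplot"} & set(config.stages):
        for label, lib in curated.items():
            t0 = time.time()
            try:
                profiles[label] = scaffolds.scaffold_frequencies(lib)
            except Exception as exc:
                raise RuntimeError(
                    f"stage scaffolds failed for library {label!r}: {exc}"
                ) from exc
            p = profiles[label]
            if "scaffolds" in config.stages:
                scaffolds.scaffold_table_frame(p).to_csv(
                    out / f"{label}_scaffolds.csv", index=False
                )
                (out / f"{label}_recovery.json").write_text(json.dumps({
                    "curve": p.curve.tolist(), "auc": p.auc,
                    "n_scaffolds": p.n_scaffolds, "n_acyclic": p.n_acyclic,
                    "seed": config.seed,
                }, indent=2))
            results["libraries"][label]["scaffold_auc"] = p.auc
            results["libraries"][label]["n_scaffolds"] = p.n_scaffolds
            logger.info("scaffolds[%s]: %d scaffolds, AUC %.3f (%.2fs)",
                        label, p.n_scaffolds, p.auc, time.time() - t0)

    fps = {}
    if {"fpdiv", "cdplot"} & set(config.stages):
        for label, lib in curated.items():
            t0 = time.time()
            try:
                fps[label] = fingerprints.FingerprintSet.from_library(lib)
                stats = fingerprints.pairwise_similarity_stats(
                    fps[label], seed=config.seed
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stage fpdiv failed for library {label!r}: {exc}"
                ) from exc
            if "fpdiv" in config.stages:
                (out / f"{label}_similarity.json").write_text(
                    json.dumps(stats.as_dict(), indent=2)
                )
            results["libraries"][label]["median_tanimoto"] = stats.median
            logger.info("fpdiv[%s]: median T %.3f (%.2fs)",
                        label, stats.median, time.time() - t0)

    if "cdplot" in config.stages and len(curated) >= 1:
        t0 = time.time()
        scaled = chemspace.minmax_scale(tables, scope=config.scaling_scope)
        points = []
        for label in curated:
            points.append(consensus.cd_point(
                fps[label], profiles[label],
                scaled.library(label),
                statistic=config.diversity_statistic,
                seed=config.seed,
            ))
        data = consensus.cd_plot(points, path=str(out / "cd_plot.svg"))
        frame = data.frame()
        frame.to_csv(out / "cd_points.csv", index=False)
        (out / "cd_points.json").write_text(json.dumps({
            "points": [p.as_dict() for p in points],
            "x_threshold": data.x_threshold,
            "y_threshold": data.y_threshold,
            "quadrants": data.quadrants,
            "metadata": {**data.metadata, "seed": config.seed},
        }, indent=2))
        results["cd_plot"] = {
            p.library_name: p.as_dict() for p in points
        }
        logger.info("cdplot: %d libraries (%.2fs)", len(points), time.time() - t0)

    for label, entry in results["libraries"].items():
        summary_lines.append(f"## {label}")
        summary_lines.append("```json")
        summary_lines.append(json.dumps(entry, indent=2))
        summary_lines.append("```")
        summary_lines.append("")
    (out / "report.md").write_text("\n".join(summary_lines))
    (out / "results.json").write_text(json.dumps(results, indent=2))
    return results
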