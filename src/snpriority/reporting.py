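"""Pipeline orchestration, ranked-table output and diagnostic plots."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from . import __version__
from .domain_annotation import (
    AnnotationProvider,
    FixtureProvider,
    UniProtProvider,
    domain_position_match,
    match_uniprot_entry,
    resolve_taxon,
)
from .errors import ConfigurationError
from .scoring import DEFAULT_WEIGHTS, ScoredVariant, rank_variants, score_variants
from .variant_io import VariantTable, parse_variant_table

__all__ = [
    "SCORE_COLUMNS",
    "PrioritizationReport",
    "run_pipeline",
    "write_output_table",
    "render_plots",
]

logger = logging.getLogger(__name__)

#: Columns appended to the input table, in output order.
SCORE_COLUMNS = (
    "Normalized_Depth",
    "Weight_Diff",
    "Hydro_Diff",
    "Polarity_Change",
    "Charge_Change",
    "Amino_Acid_Impact_Score",
    "UniProt_ID",
    "Domain_Position_Match",
    "Final_Priority_Score",
    "Rank",
)

#: Final-score histogram: equal-width bins over the full 0-100 range.
HISTOGRAM_BINS = np.linspace(0.0, 100.0, 11)


@dataclass
class PrioritizationReport:
    """Ranked variants plus the summary statistics feeding the plots."""

    variants: list[ScoredVariant]
    summary: dict
    provenance: dict

    @property
    def kept(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        """Output table: input columns (pass-through) + score columns, rank order."""
        rows = []
        for v in self.variants:
            record = v.record
            row = {
                "Gene": record.gene,
                "Amino_Acid_Position": f"{record.site}/{record.protein_length}",
                "Effect": record.raw_effect,
                "Evidence": record.raw_evidence or record.depth,
            }
            row.update(record.extras)
            row.update(
                {
                    "Normalized_Depth": round(v.normalized_depth, 4),
                    "Weight_Diff": round(v.weight_diff, 4),
                    "Hydro_Diff": round(v.hydro_diff, 4),
                    "Polarity_Change": v.polarity_change,
                    "Charge_Change": v.charge_change,
                    "Amino_Acid_Impact_Score": round(v.impact_score, 4),
                    "UniProt_ID": v.uniprot_id or "",
                    "Domain_Position_Match": v.domain_match,
                    "Final_Priority_Score": round(v.final_score, 4),
                    "Rank": v.rank,
                }
            )
            rows.append(row)
        return pd.DataFrame(rows)


def _quartiles(values: Sequence[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    q1, q2, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    return {
        "min": float(arr.min()),
        "q1": q1,
        "median": q2,
        "q3": q3,
        "max": float(arr.max()),
    }


def _build_summary(table: VariantTable, variants: Sequence[ScoredVariant]) -> dict:
    kept = len(variants)
    matches = sum(v.domain_match for v in variants)
    hist, _ = np.histogram([v.final_score for v in variants], bins=HISTOGRAM_BINS)
    return {
        "rows_read": table.rows_read,
        "rows_kept": kept,
        "rows_skipped": table.rows_skipped,
        "skip_reasons": {s.row_index: s.reason for s in table.skipped},
        "normalized_depth": _quartiles([v.normalized_depth for v in variants]),
        "impact_score": _quartiles([v.impact_score for v in variants]),
        "domain_match_count": matches,
        "domain_match_proportion": matches / kept if kept else 0.0,
        "score_histogram": {
            "bin_edges": HISTOGRAM_BINS.tolist(),
            "counts": hist.tolist(),
        },
    }


def run_pipeline(
    input_path,
    species: str = "",
    output_path=None,
    taxid: int | None = None,
    provider: AnnotationProvider | None = None,
    domain_fixture=None,
    offline: bool = False,
    dialect: str = "auto",
    evidence_format: str = "auto",
    column_map: Mapping[str, str] | None = None,
    feature_types: Sequence[str] = ("Domain",),
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    plots_dir=None,
    no_plots: bool = False,
    skip_synonymous: bool = False,
    group_by_gene: bool = False,
) -> PrioritizationReport:
    """Run parse -> normalize -> impact -> domain -> final score -> rank.

    The annotation provider is chosen in this order: an explicit
    ``provider`` object, a ``domain_fixture`` JSON path, else the live
    UniProt provider (``offline=True`` with no fixture forbids network and
    leaves every variant unannotated, i.e. neutral domain score 0).
    Writes the ranked table to ``output_path`` if given, and the four
    diagnostic plots to ``plots_dir`` unless ``no_plots``.
    """
    table = parse_variant_table(
        input_path,
        dialect=dialect,
        evidence_format=evidence_format,
        column_map=column_map,
        skip_synonymous=skip_synonymous,
    )
    logger.info(
        "parsed %d rows: %d kept, %d skipped",
        table.rows_read, table.rows_kept, table.rows_skipped,
    )
    if table.rows_kept == 0:
        raise ConfigurationError("no scoreable variants after parsing")

    if provider is None:
        if domain_fixture is not None:
            provider = FixtureProvider(domain_fixture)
        elif offline:
            provider = FixtureProvider({"taxa": {}, "entries": {}})
        else:
            provider = UniProtProvider(feature_types=feature_types)

    if taxid is None and offline and provider.resolve_taxon(species) is None:
        # Offline with no fixture taxon: annotation is all-neutral anyway.
        context_taxon = 0
    else:
        context_taxon = resolve_taxon(species, provider, taxid=taxid).taxon_id

    matches: list[int] = []
    accessions: list[str | None] = []
    annotation_cache: dict[tuple[str, int], object] = {}
    for record in table.records:
        key = (record.gene, record.protein_length)
        if key not in annotation_cache:
            annotation_cache[key] = (
                match_uniprot_entry(
                    record.gene, context_taxon, record.protein_length, provider
                )
                if context_taxon
                else None
            )
        annotation = annotation_cache[key]
        matches.append(domain_position_match(record.site, annotation))
        accessions.append(annotation.accession if annotation else None)

    variants = rank_variants(
        score_variants(
            table.records, matches, accessions,
            weights=weights, group_by_gene=group_by_gene,
        )
    )
    report = PrioritizationReport(
        variants=variants,
        summary=_build_summary(table, variants),
        provenance={
            "input": str(input_path),
            "species": species,
            "taxon_id": context_taxon,
            "provider": type(provider).__name__,
            "tool_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )
    if output_path is not None:
        write_output_table(report, output_path, dialect=table.dialect)
    if not no_plots and plots_dir is not None:
        render_plots(report, plots_dir)
    return report


def write_output_table(report: PrioritizationReport, path, dialect: str = "tsv"):
    """Write the ranked table; numeric score columns rounded to 4 decimals."""
    sep = "," if str(dialect) == "csv" or str(path).lower().endswith(".csv") else "\t"
    frame = report.to_frame()
    frame.to_csv(path, sep=sep, index=False, lineterminator="\n")
    return path


def write_summary_json(report: PrioritizationReport, path):
    """Machine-readable run summary (counts, distributions, provenance)."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(
            {"summary": report.summary, "provenance": report.provenance},
            handle,
            indent=2,
        )
    return path


def render_plots(report: PrioritizationReport, directory, dpi: int = 150, fmt: str = "png"):
    """Emit the four diagnostic panels as image files.

    (A) box plots of the normalized-depth and impact-score distributions;
    (B) pie chart of in- vs out-of-domain variants; (C) histogram of the
    final priority score; (D) scatter of depth vs impact, shaped by domain
    match and colored by final score, with the top-scoring variants (up to
    20) labeled by gene.
    """
    if report.kept == 0:
        logger.warning("empty report; skipping plots")
        return []
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    sns.set_theme(style="whitegrid")
    written = []

    fig, ax = plt.subplots(figsize=(6, 5))
    sns.boxplot(
        data=frame[["Normalized_Depth", "Amino_Acid_Impact_Score"]], ax=ax,
        palette=["#4c72b0", "#dd8452"],
    )
    ax.set_ylabel("Score")
    ax.set_title("Component score distributions")
    written.append(_save(fig, directory / f"boxplots.{fmt}", dpi))

    fig, ax = plt.subplots(figsize=(5, 5))
    in_domain = int(frame["Domain_Position_Match"].sum())
    counts = [in_domain, report.kept - in_domain]
    labels = ["In domain", "Outside domain"]
    keep = [i for i, c in enumerate(counts) if c > 0]
    ax.pie(
        [counts[i] for i in keep],
        labels=[labels[i] for i in keep],
        autopct="%1.1f%%",
        colors=["#55a868", "#c44e52"],
        startangle=90,
    )
    ax.set_title("Variants within conserved domains")
    written.append(_save(fig, directory / f"domain_pie.{fmt}", dpi))

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.hist(frame["Final_Priority_Score"], bins=HISTOGRAM_BINS, color="#4c72b0",
            edgecolor="white")
    ax.set_xlabel("Final priority score")
    ax.set_ylabel("Variants")
    ax.set_title("Final priority score distribution")
    written.append(_save(fig, directory / f"score_histogram.{fmt}", dpi))

    fig, ax = plt.subplots(figsize=(7, 6))
    for match, marker in ((0, "o"), (1, "^")):
        sub = frame[frame["Domain_Position_Match"] == match]
        if len(sub) == 0:
            continue
        scatter = ax.scatter(
            sub["Normalized_Depth"], sub["Amino_Acid_Impact_Score"],
            c=sub["Final_Priority_Score"], cmap="viridis", vmin=0, vmax=100,
            marker=marker, s=45, edgecolor="black", linewidth=0.3,
            label=f"Domain match = {match}",
        )
    top = frame.nsmallest(min(20, len(frame)), "Rank")
    for _, row in top.iterrows():
        ax.annotate(
            row["Gene"], (row["Normalized_Depth"], row["Amino_Acid_Impact_Score"]),
            fontsize=7, xytext=(3, 3), textcoords="offset points",
        )
    fig.colorbar(scatter, ax=ax, label="Final priority score")
    ax.set_xlabel("Normalized depth")
    ax.set_ylabel("Amino-acid impact score")
    ax.set_title("Feature contributions to prioritization")
    ax.legend(loc="best", fontsize=8)
    written.append(_save(fig, directory / f"feature_scatter.{fmt}", dpi))
    return written


def _save(fig, path: Path, dpi: int) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
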