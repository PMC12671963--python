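"""Component scores and the composite 0-100 priority score.

The final score combines three features with a fixed 2:1:1 weighting::

    final = (2 * D_norm + impact + domain_match) / 7 * 100

where ``D_norm`` is the dataset-level min-max normalized variant read
depth (in [0, 1]), ``impact`` is the amino-acid physicochemical impact
score (in [0, 4]) and ``domain_match`` indicates whether the mutated
residue sits in an annotated functional domain ({0, 1}). The divisor 7
is the maximum achievable weighted sum, so the score spans exactly 0-100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .aa_properties import (
    DEFAULT_TABLE,
    HYDRO_RANGE,
    WEIGHT_RANGE,
    AminoAcidPropertyTable,
)
from .variant_io import VariantRecord

__all__ = [
    "DEFAULT_WEIGHTS",
    "ImpactComponents",
    "ScoredVariant",
    "normalize_depths",
    "impact_score",
    "final_priority_score",
    "score_variants",
    "rank_variants",
]

#: (depth, impact, domain) weights; the denominator is their max weighted sum.
DEFAULT_WEIGHTS: tuple[float, float, float] = (2.0, 1.0, 1.0)


class ImpactComponents(NamedTuple):
    weight_diff: float
    hydro_diff: float
    polarity_change: int
    charge_change: int
    impact: float


@dataclass(frozen=True)
class ScoredVariant:
    """A variant record augmented with all component and final scores."""

    record: VariantRecord
    normalized_depth: float
    weight_diff: float
    hydro_diff: float
    polarity_change: int
    charge_change: int
    impact_score: float
    domain_match: int
    uniprot_id: str | None
    final_score: float
    rank: int | None = None


def normalize_depths(depths: Sequence[float]) -> np.ndarray:
    """Min-max normalize read depths over the whole collection.

    The minimum depth in the dataset maps to 0 and the maximum to 1. When
    every depth is equal (including a single-element input) the linear map
    is undefined; all variants then receive 1.0 -- uniform depth is read
    as uniform, full, relative depth confidence -- and a warning is issued.
    """
    arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty depth collection")
    if np.any(arr < 0):
        raise ValueError("depths must be non-negative")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        warnings.warn(
            "all variant depths are equal; assigning normalized depth 1.0 to every variant",
            stacklevel=2,
        )
        return np.ones_like(arr)
    return (arr - lo) / (hi - lo)


def impact_score(
    ref: str,
    alt: str,
    table: AminoAcidPropertyTable = DEFAULT_TABLE,
) -> ImpactComponents:
    """Physicochemical impact of substituting ``ref`` by ``alt``.

    ``weight_diff = |W_ref - W_alt| / 130`` and
    ``hydro_diff = |H_ref - H_alt| / 9`` use the fixed natural ranges of
    molecular weight (Trp - Gly) and Kyte-Doolittle hydrophobicity
    (Ile - Arg); polarity and charge changes are binary indicators. The
    impact is their sum (0 for an identity substitution, at most 4), and
    is symmetric in its residue arguments.
    """
    p_ref, p_alt = table.lookup(ref), table.lookup(alt)
    weight_diff = abs(p_ref.weight - p_alt.weight) / WEIGHT_RANGE
    hydro_diff = abs(p_ref.hydrophobicity - p_alt.hydrophobicity) / HYDRO_RANGE
    polarity_change = int(p_ref.polarity_class != p_alt.polarity_class)
    charge_change = int(p_ref.charge_class != p_alt.charge_class)
    return ImpactComponents(
        weight_diff=weight_diff,
        hydro_diff=hydro_diff,
        polarity_change=polarity_change,
        charge_change=charge_change,
        impact=weight_diff + hydro_diff + polarity_change + charge_change,
    )


def final_priority_score(
    normalized_depth: float,
    impact: float,
    domain_match: int,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Combine the three components into the 0-100 priority score.

    With the default 2:1:1 weights the weighted sum is divided by 7, its
    maximum; custom weights rescale the denominator to their own maximum
    (``w_d * 1 + w_i * 4 + w_m * 1``) so the score stays in [0, 100].
    """
    if not 0.0 <= normalized_depth <= 1.0:
        raise ValueError(f"normalized_depth {normalized_depth} outside [0, 1]")
    if not 0.0 <= impact <= 4.0:
        raise ValueError(f"impact {impact} outside [0, 4]")
    if domain_match not in (0, 1):
        raise ValueError(f"domain_match {domain_match} is not binary")
    w_d, w_i, w_m = weights
    if min(weights) < 0 or max(weights) == 0:
        raise ValueError(f"invalid weights {weights}")
    denominator = w_d + 4.0 * w_i + w_m
    return (w_d * normalized_depth + w_i * impact + w_m * domain_match) / denominator * 100.0


def score_variants(
    records: Sequence[VariantRecord],
    domain_matches: Sequence[int],
    uniprot_ids: Sequence[str | None] | None = None,
    table: AminoAcidPropertyTable = DEFAULT_TABLE,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    group_by_gene: bool = False,
) -> list[ScoredVariant]:
    """Score a collection of records end to end (unranked, input order).

    Depth normalization spans the whole collection by default;
    ``group_by_gene`` instead rescales within each gene's own depth range.
    """
    if len(records) != len(domain_matches):
        raise ValueError("records and domain_matches differ in length")
    if uniprot_ids is None:
        uniprot_ids = [None] * len(records)
    if group_by_gene:
        normalized = np.empty(len(records), dtype=float)
        by_gene: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            by_gene.setdefault(r.gene, []).append(i)
        for indices in by_gene.values():
            normalized[indices] = normalize_depths([records[i].depth for i in indices])
    else:
        normalized = normalize_depths([r.depth for r in records])
    scored = []
    for record, d_norm, match, acc in zip(records, normalized, domain_matches, uniprot_ids):
        comps = impact_score(record.ref_residue, record.alt_residue, table)
        scored.append(
            ScoredVariant(
                record=record,
                normalized_depth=float(d_norm),
                weight_diff=comps.weight_diff,
                hydro_diff=comps.hydro_diff,
                polarity_change=comps.polarity_change,
                charge_change=comps.charge_change,
                impact_score=comps.impact,
                domain_match=int(match),
                uniprot_id=acc,
                final_score=final_priority_score(
                    float(d_norm), comps.impact, int(match), weights
                ),
            )
        )
    return scored


def rank_variants(scored: Sequence[ScoredVariant]) -> list[ScoredVariant]:
    """Sort by descending final score and assign 1-based dense ranks.

    Ties are broken deterministically by higher raw depth, then by input
    row order; equal final scores share a dense rank.
    """
    ordered = sorted(
        scored,
        key=lambda v: (-v.final_score, -v.record.depth, v.record.row_index),
    )
    ranked: list[ScoredVariant] = []
    rank = 0
    previous_score: float | None = None
    for variant in ordered:
        if previous_score is None or variant.final_score != previous_score:
            rank += 1
            previous_score = variant.final_score
        ranked.append(replace(variant, rank=rank))
    return ranked
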