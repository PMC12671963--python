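"""Reading, validating and synthesizing four-column variant tables.

The input contract is the annotated table a microbial variant-calling
pipeline (Snippy + SnpEff) emits, reduced to four required columns:

======================  =====================================================
Gene                    gene symbol carrying the variant
Amino_Acid_Position     ``x/y`` - variation site / total protein length
Effect                  amino-acid substitution, e.g. ``Val170Leu`` (Snippy
                        prefixes such as ``missense_variant ... p.Val170Leu``
                        are tolerated)
Evidence                variant read depth: a bare count, or a Snippy-style
                        allele string ``T:21 C:0`` (ALT allele listed first)
======================  =====================================================

Extra columns are preserved and passed through to the output table.
Positions are 1-based inclusive protein coordinates throughout.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .aa_properties import CANONICAL_RESIDUES, three_to_one
from .errors import ConfigurationError, ParseError, UnsupportedResidue

__all__ = [
    "REQUIRED_COLUMNS",
    "VariantRecord",
    "VariantTable",
    "SkippedRow",
    "parse_effect",
    "parse_position",
    "extract_depth",
    "parse_variant_table",
    "generate_fixture",
]

REQUIRED_COLUMNS = ("Gene", "Amino_Acid_Position", "Effect", "Evidence")

# Last "Xxx123Yyy" token in the Effect string (Snippy may prefix "p." etc.).
_EFFECT_RE = re.compile(r"([A-Za-z]{3})(\d+)([A-Za-z]{3})")
_POSITION_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")
_ALLELE_TOKEN_RE = re.compile(r"^[A-Za-z*+-]+:(\d+(?:\.\d+)?)$")
_NUMBER_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*$")

EvidenceFormat = Literal["auto", "bare", "snippy"]
Dialect = Literal["auto", "tsv", "csv"]


@dataclass(frozen=True)
class VariantRecord:
    """One parsed, validated input row."""

    gene: str
    site: int
    protein_length: int
    ref_residue: str
    alt_residue: str
    depth: float
    raw_effect: str
    row_index: int
    raw_evidence: str = ""
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not (1 <= self.site <= self.protein_length):
            raise ValueError(
                f"site {self.site} outside protein 1..{self.protein_length}"
            )
        for res in (self.ref_residue, self.alt_residue):
            if res not in CANONICAL_RESIDUES:
                raise UnsupportedResidue(f"non-canonical residue {res!r}")
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")

    @property
    def is_synonymous(self) -> bool:
        return self.ref_residue == self.alt_residue


@dataclass(frozen=True)
class SkippedRow:
    row_index: int
    reason: str
    raw: str


@dataclass
class VariantTable:
    """Parsed records plus the bookkeeping of rows read, kept and skipped."""

    records: list[VariantRecord]
    skipped: list[SkippedRow]
    rows_read: int
    source: str = "<stream>"
    dialect: str = "tsv"
    extra_columns: tuple[str, ...] = ()

    @property
    def rows_kept(self) -> int:
        return len(self.records)

    @property
    def rows_skipped(self) -> int:
        return len(self.skipped)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)


def parse_effect(effect: str) -> tuple[str, int, str]:
    """Extract ``(ref, site, alt)`` one-letter codes from an Effect string.

    The *last* three-letter-code/integer/three-letter-code token wins, so
    Snippy prefixes like ``"missense_variant c.508G>C p.Val170Leu"`` parse
    to the protein-level change. Non-canonical codes (``Ter``, ``Xaa``)
    raise :class:`UnsupportedResidue`.
    """
    matches = _EFFECT_RE.findall(str(effect))
    if not matches:
        raise ParseError(f"no amino-acid substitution in Effect {effect!r}", raw=str(effect))
    ref3, site, alt3 = matches[-1]
    return three_to_one(ref3), int(site), three_to_one(alt3)


def parse_position(position: str) -> tuple[int, int]:
    """Parse ``"x/y"`` into ``(site, protein_length)``, both 1-based."""
    m = _POSITION_RE.match(str(position))
    if not m:
        raise ParseError(f"position not of the form x/y: {position!r}", raw=str(position))
    site, length = int(m.group(1)), int(m.group(2))
    if site < 1 or site > length:
        raise ParseError(
            f"site {site} outside 1..{length} in position {position!r}", raw=str(position)
        )
    return site, length


def extract_depth(evidence: str, evidence_format: EvidenceFormat = "auto") -> float:
    """Extract the variant read depth from the Evidence field.

    A bare number is returned directly. A Snippy allele string such as
    ``"T:21 C:0"`` yields the count of its first token (Snippy lists the
    ALT allele first). ``evidence_format`` forces one interpretation.
    """
    text = str(evidence).strip()
    bare = _NUMBER_RE.match(text)
    if evidence_format in ("auto", "bare") and bare:
        return float(bare.group(1))
    if evidence_format == "bare":
        raise ParseError(f"Evidence is not a bare number: {evidence!r}", raw=text)
    tokens = text.split()
    if tokens:
        m = _ALLELE_TOKEN_RE.match(tokens[0])
        if m:
            return float(m.group(1))
    raise ParseError(f"no depth found in Evidence {evidence!r}", raw=text)


def _resolve_dialect(source, dialect: Dialect) -> str:
    if dialect in ("tsv", "csv"):
        return dialect
    name = str(source)
    if name.lower().endswith(".csv"):
        return "csv"
    return "tsv"


def parse_variant_table(
    source,
    dialect: Dialect = "auto",
    evidence_format: EvidenceFormat = "auto",
    column_map: Mapping[str, str] | None = None,
    skip_synonymous: bool = False,
) -> VariantTable:
    """Read a variant table into validated :class:`VariantRecord` rows.

    Parameters
    ----------
    source
        Path or readable text stream.
    dialect
        ``tsv``/``csv``, or ``auto`` (from the file extension, default tsv).
    evidence_format
        How to read the Evidence column (see :func:`extract_depth`).
    column_map
        Optional ``{nonstandard header -> documented name}`` remapping for
        pipelines that rename the four required columns.
    skip_synonymous
        When true, identity substitutions (e.g. ``Ala5Ala``) are skipped
        with reason ``"synonymous"``; by default they are kept and score
        zero physicochemical impact.

    Rows with stop codons, non-canonical residues, or unparseable fields
    are skipped (never fatal) and recorded with a per-row reason; a missing
    required column or a table with no data rows is fatal.
    """
    resolved = _resolve_dialect(source, dialect)
    sep = "\t" if resolved == "tsv" else ","
    is_path = isinstance(source, (str, Path))
    frame = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"required column(s) missing from input: {', '.join(missing)}"
        )
    if len(frame) == 0:
        raise ConfigurationError("no variants: input contains a header but no data rows")

    extra_columns = tuple(c for c in frame.columns if c not in REQUIRED_COLUMNS)
    records: list[VariantRecord] = []
    skipped: list[SkippedRow] = []
    for row_index, row in enumerate(frame.itertuples(index=False)):
        raw = dict(zip(frame.columns, row))
        try:
            ref, effect_site, alt = parse_effect(raw["Effect"])
            site, length = parse_position(raw["Amino_Acid_Position"])
            if site != effect_site:
                raise ParseError(
                    f"position mismatch: Effect says {effect_site}, "
                    f"Amino_Acid_Position says {site}",
                    raw=str(raw["Effect"]),
                )
            depth = extract_depth(raw["Evidence"], evidence_format)
            record = VariantRecord(
                gene=str(raw["Gene"]),
                site=site,
                protein_length=length,
                ref_residue=ref,
                alt_residue=alt,
                depth=depth,
                raw_effect=str(raw["Effect"]),
                row_index=row_index,
                raw_evidence=str(raw["Evidence"]),
                extras={c: raw[c] for c in extra_columns},
            )
        except UnsupportedResidue as exc:
            skipped.append(SkippedRow(row_index, f"unsupported residue: {exc}", str(raw)))
            continue
        except ParseError as exc:
            reason = "position mismatch" if "position mismatch" in str(exc) else str(exc)
            skipped.append(SkippedRow(row_index, reason, str(raw)))
            continue
        if skip_synonymous and record.is_synonymous:
            skipped.append(SkippedRow(row_index, "synonymous", str(raw["Effect"])))
            continue
        records.append(record)

    return VariantTable(
        records=records,
        skipped=skipped,
        rows_read=len(frame),
        source=str(source) if is_path else "<stream>",
        dialect=resolved,
        extra_columns=extra_columns,
    )


_ONE_TO_THREE = {
    one: three.capitalize()
    for three, one in {
        "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
        "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
        "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
        "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    }.items()
}

_FIXTURE_GENES = (
    "gyrA", "gyrB", "rpoB", "rpoC", "recA", "dnaA", "dnaK", "ftsZ",
    "murA", "secA", "tuf", "fusA", "lepA", "infB", "pyrG", "glnA",
)


def generate_fixture(
    n: int,
    depth_range: tuple[float, float] = (5, 500),
    seed: int = 0,
    synonymous_fraction: float = 0.0,
    dialect: Dialect = "tsv",
    snippy_evidence: bool = False,
) -> str:
    """Build a deterministic synthetic four-column variant table.

    Emulates the input contract: residues are drawn from the canonical 20,
    sites are consistent with the drawn protein lengths, and depths are
    uniform over ``depth_range``. Returns the file content as text; it
    round-trips through :func:`parse_variant_table` without skips (unless
    ``synonymous_fraction`` rows are made synonymous and skipping is on).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = depth_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid depth_range {depth_range}")
    rng = np.random.default_rng(seed)
    residues = sorted(CANONICAL_RESIDUES)
    sep = "," if dialect == "csv" else "\t"
    lines = [sep.join(REQUIRED_COLUMNS)]
    for i in range(n):
        gene = _FIXTURE_GENES[int(rng.integers(len(_FIXTURE_GENES)))]
        length = int(rng.integers(120, 1200))
        site = int(rng.integers(1, length + 1))
        ref = residues[int(rng.integers(20))]
        if rng.random() < synonymous_fraction:
            alt = ref
        else:
            alt = residues[int(rng.integers(20))]
            while alt == ref:
                alt = residues[int(rng.integers(20))]
        depth = int(np.round(rng.uniform(lo, hi)))
        effect = f"{_ONE_TO_THREE[ref]}{site}{_ONE_TO_THREE[alt]}"
        evidence = f"T:{depth} C:0" if snippy_evidence else str(depth)
        lines.append(sep.join((gene, f"{site}/{length}", effect, evidence)))
    return "\n".join(lines) + "\n"
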