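"""Per-variant functional-domain lookup against UniProt.

A variant's residue position is checked against the "Domain" features
(FT DOMAIN intervals, 1-based inclusive protein coordinates) of the
UniProt entry that best matches the variant's gene, the species' taxon
and the protein length reported in the input. Matching is deliberately
strict: an entry must match gene and taxon, and its sequence length must
equal the input protein length or lie within a small relative tolerance
of it, because an unbounded nearest-length match risks scoring the wrong
protein. When no reliable entry is found the variant receives a neutral
domain score of 0 rather than an inferred value, so missing annotation
can never inflate a priority score.

Providers are pluggable: :class:`FixtureProvider` serves a local JSON
mapping (fully offline, deterministic), :class:`UniProtProvider` queries
the UniProt REST API with an in-memory response cache.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "DomainAnnotation",
    "SpeciesContext",
    "CandidateEntry",
    "AnnotationProvider",
    "FixtureProvider",
    "UniProtProvider",
    "resolve_taxon",
    "match_uniprot_entry",
    "domain_position_match",
    "generate_domain_fixture",
]

logger = logging.getLogger(__name__)

#: Default relative tolerance for a non-exact protein-length match.
LENGTH_TOLERANCE = 0.02


@dataclass(frozen=True)
class DomainAnnotation:
    """A matched UniProt entry reduced to what scoring needs."""

    accession: str
    entry_protein_length: int
    domains: tuple[tuple[int, int], ...]
    source: str = "fixture"  # {live, cache, fixture, none}

    def __post_init__(self):
        for start, end in self.domains:
            if not (1 <= start <= end <= self.entry_protein_length):
                raise ValueError(
                    f"invalid domain interval ({start}, {end}) for protein "
                    f"of length {self.entry_protein_length}"
                )


@dataclass(frozen=True)
class SpeciesContext:
    species_name: str
    taxon_id: int

    def __post_init__(self):
        if self.taxon_id <= 0:
            raise ValueError(f"taxon_id must be positive, got {self.taxon_id}")


@dataclass(frozen=True)
class CandidateEntry:
    """One provider hit before length-based selection."""

    accession: str
    length: int
    domains: tuple[tuple[int, int], ...]
    reviewed: bool = False


class AnnotationProvider(Protocol):
    def lookup_gene(self, gene: str, taxon_id: int) -> Sequence[CandidateEntry]:
        """All candidate entries for a gene within a taxon."""

    def resolve_taxon(self, species_name: str) -> int | None:
        """Numeric taxonomy id for a binomial species name, if known."""


class FixtureProvider:
    """Offline provider backed by a JSON mapping.

    File layout::

        {
          "taxa": {"Bacteroides uniformis": 820},
          "entries": {
            "gyrA@820": [
              {"accession": "A0A0K0XXX1", "length": 875,
               "domains": [[33, 497]], "reviewed": false}
            ]
          }
        }
    """

    def __init__(self, mapping: dict | str | Path):
        if isinstance(mapping, (str, Path)):
            with open(mapping, encoding="utf-8") as handle:
                mapping = json.load(handle)
        self._taxa: dict[str, int] = {
            name: int(tid) for name, tid in mapping.get("taxa", {}).items()
        }
        self._entries: dict[str, list[CandidateEntry]] = {}
        for key, entries in mapping.get("entries", {}).items():
            self._entries[key] = [
                CandidateEntry(
                    accession=str(e["accession"]),
                    length=int(e["length"]),
                    domains=tuple((int(s), int(t)) for s, t in e.get("domains", [])),
                    reviewed=bool(e.get("reviewed", False)),
                )
                for e in entries
            ]

    def lookup_gene(self, gene: str, taxon_id: int) -> Sequence[CandidateEntry]:
        return self._entries.get(f"{gene}@{taxon_id}", [])

    def resolve_taxon(self, species_name: str) -> int | None:
        return self._taxa.get(species_name)


class UniProtProvider:
    """Live provider against the UniProt REST API, with response caching.

    Feature types counted as domains default to UniProt "Domain" features
    only; active sites, binding sites and plain regions are excluded as
    they are not domain-level annotation (configurable via
    ``feature_types``).
    """

    SEARCH_URL = "https://rest.uniprot.org/uniprotkb/search"
    TAXON_URL = "https://rest.uniprot.org/taxonomy/search"

    def __init__(
        self,
        feature_types: Iterable[str] = ("Domain",),
        retries: int = 2,
        timeout: float = 20.0,
    ):
        self.feature_types = frozenset(feature_types)
        self.retries = retries
        self.timeout = timeout
        self._cache: dict[tuple[str, int], list[CandidateEntry]] = {}
        self._taxon_cache: dict[str, int | None] = {}

    def _get_json(self, url: str) -> dict:
        last_error: Exception | None = None
        for attempt in range(self.retries + 1):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as response:
                    return json.loads(response.read().decode("utf-8"))
            except Exception as exc:  # transport failure -> retry, then degrade
                last_error = exc
                if attempt < self.retries:
                    time.sleep(1.0 * (attempt + 1))
        raise last_error  # type: ignore[misc]

    def lookup_gene(self, gene: str, taxon_id: int) -> Sequence[CandidateEntry]:
        key = (gene, taxon_id)
        if key in self._cache:
            return self._cache[key]
        query = urllib.parse.quote(f"gene:{gene} AND taxonomy_id:{taxon_id}")
        url = (
            f"{self.SEARCH_URL}?query={query}"
            "&fields=accession,length,ft_domain,reviewed&format=json&size=25"
        )
        try:
            payload = self._get_json(url)
        except Exception as exc:
            logger.warning(
                "UniProt lookup failed for %s@%s (%s); treating as unannotated",
                gene, taxon_id, exc,
            )
            return []
        entries = []
        for result in payload.get("results", []):
            domains = []
            for feat in result.get("features", []):
                if feat.get("type") in self.feature_types:
                    loc = feat.get("location", {})
                    start = loc.get("start", {}).get("value")
                    end = loc.get("end", {}).get("value")
                    if start and end:
                        domains.append((int(start), int(end)))
            entries.append(
                CandidateEntry(
                    accession=result.get("primaryAccession", ""),
                    length=int(result.get("sequence", {}).get("length", 0)),
                    domains=tuple(domains),
                    reviewed="Swiss-Prot" in str(result.get("entryType", "")),
                )
            )
        self._cache[key] = entries
        return entries

    def resolve_taxon(self, species_name: str) -> int | None:
        if species_name in self._taxon_cache:
            return self._taxon_cache[species_name]
        query = urllib.parse.quote(f'scientific:"{species_name}"')
        url = f"{self.TAXON_URL}?query={query}&format=json&size=1"
        try:
            payload = self._get_json(url)
            results = payload.get("results", [])
            taxon = int(results[0]["taxonId"]) if results else None
        except Exception as exc:
            logger.warning("taxonomy lookup failed for %r (%s)", species_name, exc)
            taxon = None
        self._taxon_cache[species_name] = taxon
        return taxon


def resolve_taxon(
    species_name: str,
    provider: AnnotationProvider,
    taxid: int | None = None,
) -> SpeciesContext:
    """Resolve a species name to its numeric taxon id.

    An explicit ``taxid`` bypasses the lookup entirely; an unresolvable
    name is fatal, with a hint to supply ``--taxid``.
    """
    if taxid is not None:
        return SpeciesContext(species_name=species_name, taxon_id=int(taxid))
    if not species_name or not species_name.strip():
        raise ConfigurationError("species name is empty")
    resolved = provider.resolve_taxon(species_name)
    if resolved is None:
        raise ConfigurationError(
            f"could not resolve species {species_name!r} to a taxonomy id; "
            "supply --taxid explicitly"
        )
    return SpeciesContext(species_name=species_name, taxon_id=int(resolved))


def match_uniprot_entry(
    gene: str,
    taxon_id: int,
    protein_length: int,
    provider: AnnotationProvider,
    length_tolerance: float = LENGTH_TOLERANCE,
) -> DomainAnnotation | None:
    """Select the UniProt entry for (gene, taxon) closest in protein length.

    Exact length match wins; otherwise the entry nearest in length within
    ``length_tolerance`` (relative to the input protein length) is taken.
    Equidistant candidates prefer reviewed entries, then the smallest
    accession. Returns None when nothing qualifies.
    """
    if not gene:
        raise ValueError("gene must be non-empty")
    if protein_length < 1:
        raise ValueError(f"protein_length must be >= 1, got {protein_length}")
    candidates = list(provider.lookup_gene(gene, taxon_id))
    if not candidates:
        return None
    max_delta = length_tolerance * protein_length
    eligible = [c for c in candidates if abs(c.length - protein_length) <= max_delta]
    if not eligible:
        return None
    best = min(
        eligible,
        key=lambda c: (abs(c.length - protein_length), not c.reviewed, c.accession),
    )
    return DomainAnnotation(
        accession=best.accession,
        entry_protein_length=best.length,
        domains=best.domains,
        source="fixture" if isinstance(provider, FixtureProvider) else "live",
    )


def domain_position_match(site: int, annotation: DomainAnnotation | None) -> int:
    """1 iff the residue position falls inside an annotated domain interval.

    Bounds are inclusive; an absent annotation yields the neutral score 0.
    """
    if site < 1:
        raise ValueError(f"site must be >= 1, got {site}")
    if annotation is None:
        return 0
    return int(any(start <= site <= end for start, end in annotation.domains))


def generate_domain_fixture(
    gene_lengths: Iterable[tuple[str, int]],
    species_name: str = "Bacteroides uniformis",
    taxon_id: int = 820,
    seed: int = 0,
    domain_probability: float = 0.7,
) -> dict:
    """Build a deterministic JSON-style fixture for the offline provider.

    ``gene_lengths`` are the (gene, protein length) pairs observed in a
    variant table; one synthetic entry is created per unique pair, with
    the matching sequence length. With probability ``domain_probability``
    an entry carries one or two random domain intervals, otherwise none
    (emulating the sparse domain annotation of microbial proteomes).
    """
    rng = np.random.default_rng(seed)
    entries: dict[str, list[dict]] = {}
    for index, (gene, length) in enumerate(sorted(set(gene_lengths))):
        length = int(length)
        domains = []
        if rng.random() < domain_probability:
            for _ in range(int(rng.integers(1, 3))):
                start = int(rng.integers(1, max(2, length - 10)))
                end = int(rng.integers(start, min(length, start + max(30, length // 3)) + 1))
                domains.append([start, end])
        entries.setdefault(f"{gene}@{taxon_id}", []).append(
            {
                "accession": f"SYN{index:06d}",
                "length": length,
                "domains": domains,
                "reviewed": bool(rng.random() < 0.2),
            }
        )
    return {"taxa": {species_name: taxon_id}, "entries": entries}
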