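"""Hairpin sequence catalogs and miRNA name resolution.

A catalog is an ordered collection of pre-miRNA stem-loop (hairpin) records,
typically read from a miRBase-style FASTA file.  Sequences are normalized to
the RNA alphabet {A, C, G, U}: DNA input is accepted and T is mapped to U,
lower case is folded to upper.  Biomarker panels in the literature list
miRNAs by short names without species prefix, locus suffix or arm letter
("miR-323", "let-7a"); :func:`resolve_name` maps such names onto catalog
identifiers ("hsa-mir-323a", "hsa-let-7a-1") under an explicit, auditable
policy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

_DNA_TO_RNA = str.maketrans({"T": "U", "t": "U"})


class CatalogError(ValueError):
    """Malformed catalog input (duplicates, bad symbols, empty result)."""


class ResolutionError(KeyError):
    """A panel name could not be matched to any catalog identifier."""


def normalize_sequence(raw: str, *, allow_ambiguous: bool = False) -> str:
    """Map a raw nucleotide string to the internal RNA alphabet.

    T is replaced by U and letters are upper-cased.  Symbols outside
    {A, C, G, U} (IUPAC ambiguity codes, gaps, ...) raise
    :class:`CatalogError` unless ``allow_ambiguous`` is set, in which case
    they are kept verbatim and left for the distance layer to discount.
    """
    seq = raw.translate(_DNA_TO_RNA).upper()
    if not seq:
        raise CatalogError("empty sequence")
    if not allow_ambiguous:
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise CatalogError(
                f"sequence contains non-ACGU symbols {sorted(bad)}; "
                "pass allow_ambiguous=True to keep them"
            )
    return seq


@dataclass(frozen=True)
class HairpinRecord:
    """One named pre-miRNA stem-loop sequence."""

    identifier: str
    description: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.identifier:
            raise CatalogError("record with empty identifier")
        if not self.sequence:
            raise CatalogError(f"{self.identifier}: empty sequence")


class Catalog:
    """Ordered, identifier-unique collection of :class:`HairpinRecord`."""

    def __init__(self, records: Iterable[HairpinRecord]):
        self._records: list[HairpinRecord] = list(records)
        self._by_id: dict[str, HairpinRecord] = {}
        for rec in self._records:
            if rec.identifier in self._by_id:
                raise CatalogError(f"duplicate identifier {rec.identifier!r}")
            self._by_id[rec.identifier] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[HairpinRecord]:
        return iter(self._records)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._by_id

    def __getitem__(self, identifier: str) -> HairpinRecord:
        return self._by_id[identifier]

    @property
    def ids(self) -> list[str]:
        return [rec.identifier for rec in self._records]

    @property
    def records(self) -> list[HairpinRecord]:
        return list(self._records)

    def subset(self, identifiers: Iterable[str]) -> "Catalog":
        return Catalog(self._by_id[i] for i in identifiers)

    def filter_prefix(self, prefix: str) -> "Catalog":
        kept = [r for r in self._records if r.identifier.startswith(prefix)]
        return Catalog(kept)


def read_hairpin_fasta(
    path: str | Path,
    species_prefix: str | None = None,
    *,
    allow_ambiguous: bool = False,
) -> Catalog:
    """Read a hairpin FASTA catalog, normalizing sequences to {A,C,G,U}.

    Parameters
    ----------
    path
        FASTA file of stem-loop sequences (miRBase ``hairpin.fa`` layout:
        ``>hsa-mir-21 MI0000077 Homo sapiens miR-21 stem-loop``).
    species_prefix
        When given (e.g. ``"hsa-"``), only records whose identifier starts
        with the prefix are kept.
    allow_ambiguous
        Keep records containing non-ACGU symbols instead of rejecting them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[HairpinRecord] = []
    for sr in SeqIO.parse(str(path), "fasta"):
        if species_prefix and not sr.id.startswith(species_prefix):
            continue
        seq = normalize_sequence(str(sr.seq), allow_ambiguous=allow_ambiguous)
        records.append(HairpinRecord(sr.id, sr.description, seq))
    if not records:
        raise CatalogError(
            f"no records read from {path}"
            + (f" with prefix {species_prefix!r}" if species_prefix else "")
        )
    return Catalog(records)


def write_fasta(catalog: Catalog, path: str | Path, *, width: int = 60) -> None:
    """Write a catalog as FASTA, wrapped at ``width`` columns."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.identifier,
                  description=rec.description)
        for rec in catalog
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Name resolution


class ResolutionPolicy(str, Enum):
    """How to pick among several candidate loci for one short name.

    ``exact`` refuses ambiguity; ``multi_locus_first`` deterministically
    takes the lexicographically first identifier (and flags the ambiguity);
    ``all`` keeps every candidate.
    """

    EXACT = "exact"
    MULTI_LOCUS_FIRST = "multi-locus-first"
    ALL = "all"


@dataclass
class NameResolution:
    query: str
    matches: list[str]
    policy_applied: str
    ambiguous: bool
    candidates: list[str] = field(default_factory=list)


def _normalize_query(query: str, species_prefix: str) -> str:
    q = query.strip().lower()
    q = re.sub(r"^mir", "mir", q)  # case already folded; keep explicit
    if not q.startswith(species_prefix):
        q = species_prefix + q
    return q


def load_name_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``query<TAB>identifier`` map ('#' comments)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CatalogError(f"bad name-map line: {line!r}")
        mapping[parts[0].strip().lower()] = parts[1].strip()
    return mapping


def resolve_name(
    query: str,
    catalog: Catalog,
    policy: ResolutionPolicy = ResolutionPolicy.MULTI_LOCUS_FIRST,
    *,
    species_prefix: str = "hsa-",
    name_map: Mapping[str, str] | None = None,
) -> NameResolution:
    """Resolve a printed miRNA name to catalog stem-loop identifier(s).

    Matching is tiered: an exact identifier match wins; failing that,
    identifiers differing only by a trailing locus suffix (``-1``, ``-2``,
    ...) are candidates; failing that, identifiers differing by a trailing
    arm letter (``a``/``b``/...) with optional locus suffix.  Ambiguity
    (more than one candidate before policy) is always recorded.
    """
    if len(catalog) == 0:
        raise CatalogError("empty catalog")
    if name_map:
        mapped = name_map.get(query.strip().lower())
        if mapped is not None:
            if mapped not in catalog:
                raise ResolutionError(
                    f"name-map target {mapped!r} for {query!r} not in catalog"
                )
            return NameResolution(query, [mapped], "explicit-map", False,
                                  [mapped])

    q = _normalize_query(query, species_prefix)
    ids_lower = {rec.identifier.lower(): rec.identifier for rec in catalog}

    if q in ids_lower:
        return NameResolution(query, [ids_lower[q]], "exact", False,
                              [ids_lower[q]])

    locus_re = re.compile(re.escape(q) + r"-\d+$")
    candidates = sorted(v for k, v in ids_lower.items() if locus_re.match(k))
    policy_applied = "multi-locus-first"
    if not candidates:
        arm_re = re.compile(re.escape(q) + r"[a-z](-\d+)?$")
        candidates = sorted(v for k, v in ids_lower.items() if arm_re.match(k))
        policy_applied = "single-arm-letter"
    if not candidates:
        raise ResolutionError(f"no catalog entry matches {query!r} "
                              f"(normalized {q!r})")

    ambiguous = len(candidates) > 1
    if not ambiguous:
        return NameResolution(query, candidates, policy_applied, False,
                              candidates)
    if policy == ResolutionPolicy.EXACT:
        raise ResolutionError(
            f"{query!r} is ambiguous among {candidates}; use a name map or "
            "policy 'multi-locus-first'"
        )
    if policy == ResolutionPolicy.ALL:
        return NameResolution(query, candidates, "all", True, candidates)
    logger.warning("%r is ambiguous among %s; using %s",
                   query, candidates, candidates[0])
    return NameResolution(query, [candidates[0]], policy_applied, True,
                          candidates)


def resolve_panel(
    names: Iterable[str],
    catalog: Catalog,
    policy: ResolutionPolicy = ResolutionPolicy.MULTI_LOCUS_FIRST,
    *,
    species_prefix: str = "hsa-",
    name_map: Mapping[str, str] | None = None,
) -> list[NameResolution]:
    """Resolve every panel name; collect all failures before raising."""
    resolutions: list[NameResolution] = []
    failures: list[str] = []
    for name in names:
        try:
            resolutions.append(
                resolve_name(name, catalog, policy,
                             species_prefix=species_prefix, name_map=name_map)
            )
        except ResolutionError as exc:
            failures.append(f"{name}: {exc.args[0]}")
    if failures:
        raise ResolutionError(
            "unresolved panel names:\n  " + "\n  ".join(failures)
        )
    used = [r.matches[0] for r in resolutions]
    dups = {i for i in used if used.count(i) > 1}
    if dups:
        logger.warning("panel names resolve to shared stem-loops: %s",
                       sorted(dups))
    return resolutions
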