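"""Jukes-Cantor distances between stem-loop sequences.

Each pair of hairpins is globally aligned (Needleman-Wunsch, NUC44-style
scoring: match +5, mismatch -4, linear gap penalty 8) and reduced to the
observed proportion of differing sites p-hat = X / L, where L counts the
aligned columns retained for scoring and X the retained columns whose bases
differ.  Columns containing a gap are excluded from both counts by default
(standard p-distance over ungapped columns); they can instead be counted as
mismatches.  The one-parameter substitution correction

    K = -(3/4) * ln(1 - (4/3) * p_hat)

assumes the four nucleotides substitute for each other with equal
probability.  It diverges as p_hat approaches 3/4 ("saturation"); saturated
pairs are returned as +inf and flagged, never silently clamped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .catalog import (Catalog, HairpinRecord, ResolutionPolicy, resolve_panel)

logger = logging.getLogger(__name__)

SATURATION = 0.75  # p-hat at/above which the correction is undefined


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for the pairwise global alignment.

    Defaults mirror common nucleotide-alignment toolbox defaults (NUC44
    substitution scores restricted to ACGU, linear gap penalty of
    magnitude 8).  ``gap_columns`` selects whether gapped columns are
    ``"excluded"`` from (L, X) or ``"mismatch"``-counted.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 8.0
    gap_extend: float = 8.0
    gap_columns: str = "excluded"
    scheme: str = "nuc44-like"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")
        if self.gap_columns not in ("excluded", "mismatch"):
            raise ValueError("gap_columns must be 'excluded' or 'mismatch'")

    def fingerprint(self) -> str:
        payload = json.dumps(
            [self.match, self.mismatch, self.gap_open, self.gap_extend,
             self.gap_columns, self.scheme],
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class AlignmentSummary:
    """Compared-site and mismatch counts for one aligned pair.

    ``L`` and ``X`` are exact integers; ``p_hat`` is their ratio converted
    to floating point only on access.
    """

    id_a: str
    id_b: str
    L: int
    X: int

    @property
    def p_hat(self) -> float:
        return self.X / self.L

    @property
    def distance(self) -> float:
        return jukes_cantor(self.p_hat)

    @property
    def saturated(self) -> bool:
        return self.p_hat >= SATURATION


def jukes_cantor(p_hat: float) -> float:
    """One-parameter substitution distance K from a site-difference fraction.

    Returns ``+inf`` for ``p_hat >= 3/4`` (the correction's domain
    boundary); callers must treat non-finite values as saturated rather
    than real distances.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat={p_hat} outside [0, 1]")
    if p_hat >= SATURATION:
        return math.inf
    return -0.75 * math.log1p(-(4.0 / 3.0) * p_hat)


def align_pair(
    a: HairpinRecord,
    b: HairpinRecord,
    params: AlignmentParams = DEFAULT_PARAMS,
    *,
    _aligner: Align.PairwiseAligner | None = None,
) -> AlignmentSummary:
    """Globally align two hairpins and count compared/differing columns.

    The pair is canonicalized (sorted by sequence) before alignment so that
    ``align_pair(a, b)`` and ``align_pair(b, a)`` give identical (L, X)
    even when the optimum alignment is not unique.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner if _aligner is not None else params.make_aligner()
    first, second = (a, b) if a.sequence <= b.sequence else (b, a)
    alignment = aligner.align(first.sequence, second.sequence)[0]
    counts = alignment.counts()
    identities, mismatches = counts.identities, counts.mismatches
    if params.gap_columns == "excluded":
        L = identities + mismatches
        X = mismatches
    else:
        gap_cols = alignment.length - identities - mismatches
        L = alignment.length
        X = mismatches + gap_cols
    if L < 1:
        raise ValueError(
            f"no comparable columns between {a.identifier} and {b.identifier}"
        )
    return AlignmentSummary(a.identifier, b.identifier, int(L), int(X))


def condensed_index(i: int, j: int, n: int) -> int:
    """Index of pair (i < j) in the row-major condensed vector."""
    if not 0 <= i < j < n:
        raise IndexError(f"bad pair ({i}, {j}) for n={n}")
    return i * n - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class CondensedDistances:
    """All-pairs distance vector in row-major i<j order over ``ids``."""

    ids: list[str]
    values: np.ndarray
    saturated_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        expected = n * (n - 1) // 2
        if self.values.shape != (expected,):
            raise ValueError(
                f"expected {expected} distances for {n} ids, "
                f"got {self.values.shape}"
            )
        if self.saturated_mask is None:
            self.saturated_mask = ~np.isfinite(self.values)
        self.saturated_mask = np.asarray(self.saturated_mask, dtype=bool)
        if self.saturated_mask.shape != self.values.shape:
            raise ValueError("saturated_mask length mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.values)

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        if i == j:
            return 0.0
        if i > j:
            i, j = j, i
        return float(self.values[condensed_index(i, j, self.n)])

    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    # -- on-disk cache ------------------------------------------------------

    def to_tsv(self, path: str | Path, *, params_fingerprint: str = "") -> None:
        """Self-describing TSV cache: #ids, #params-hash, one value/line."""
        with open(path, "w") as fh:
            fh.write("#ids\t" + "\t".join(self.ids) + "\n")
            fh.write(f"#params-hash\t{params_fingerprint}\n")
            for v, s in zip(self.values, self.saturated_mask):
                fh.write(f"{float(v)!r}\t{int(s)}\n")

    @classmethod
    def from_tsv(
        cls, path: str | Path, *, expect_fingerprint: str | None = None
    ) -> "CondensedDistances":
        ids: list[str] | None = None
        fingerprint = ""
        values: list[float] = []
        mask: list[bool] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#ids\t"):
                ids = line.split("\t")[1:]
            elif line.startswith("#params-hash\t"):
                fingerprint = line.split("\t", 1)[1]
            elif line and not line.startswith("#"):
                v, s = line.split("\t")
                values.append(float(v))
                mask.append(bool(int(s)))
        if ids is None:
            raise ValueError(f"{path}: missing #ids header")
        if expect_fingerprint is not None and fingerprint != expect_fingerprint:
            raise ValueError(
                f"{path}: stale cache (params hash {fingerprint!r} != "
                f"{expect_fingerprint!r})"
            )
        return cls(ids, np.array(values), np.array(mask, dtype=bool))


def pairwise_distances(
    catalog: Catalog | Sequence[HairpinRecord],
    params: AlignmentParams = DEFAULT_PARAMS,
    *,
    cache_path: str | Path | None = None,
    progress_every: int = 100_000,
) -> CondensedDistances:
    """Distances for all n(n-1)/2 pairs of a catalog, in ids order.

    When ``cache_path`` is given, a valid cache (matching ids and alignment
    parameters) is reused; otherwise the result is written there.  A plain
    sequence of records is accepted in place of a catalog (panel members
    may legitimately repeat a stem-loop).
    """
    records = catalog.records if isinstance(catalog, Catalog) \
        else list(catalog)
    ids = [rec.identifier for rec in records]
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records")
    fingerprint = params.fingerprint()
    if cache_path is not None and Path(cache_path).exists():
        try:
            cached = CondensedDistances.from_tsv(
                cache_path, expect_fingerprint=fingerprint
            )
            if cached.ids == ids:
                logger.info("distance cache hit: %s", cache_path)
                return cached
            logger.warning("cache %s has different ids; recomputing",
                           cache_path)
        except ValueError as exc:
            logger.warning("ignoring cache %s: %s", cache_path, exc)
    aligner = params.make_aligner()
    total = n * (n - 1) // 2
    values = np.empty(total)
    mask = np.zeros(total, dtype=bool)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                summary = align_pair(records[i], records[j], params,
                                     _aligner=aligner)
            except ValueError as exc:
                raise ValueError(
                    f"alignment failed for pair "
                    f"({records[i].identifier}, {records[j].identifier}): {exc}"
                ) from exc
            values[k] = jukes_cantor(summary.p_hat)
            mask[k] = summary.saturated
            k += 1
            if progress_every and k % progress_every == 0:
                logger.info("aligned %d / %d pairs", k, total)
    result = CondensedDistances(ids, values, mask)
    if cache_path is not None:
        result.to_tsv(cache_path, params_fingerprint=fingerprint)
        logger.info("distance cache written: %s", cache_path)
    return result


def panel_distances(
    names: Sequence[str],
    catalog: Catalog,
    params: AlignmentParams = DEFAULT_PARAMS,
    policy: ResolutionPolicy = ResolutionPolicy.MULTI_LOCUS_FIRST,
    *,
    species_prefix: str = "hsa-",
    name_map: Mapping[str, str] | None = None,
) -> CondensedDistances:
    """Pairwise distances over a biomarker panel given by printed names.

    Names are resolved against the catalog (m names -> m(m-1)/2 distances,
    in input order); any unresolved name aborts with the full failure list.
    """
    resolutions = resolve_panel(names, catalog, policy,
                                species_prefix=species_prefix,
                                name_map=name_map)
    members = [catalog[r.matches[0]] for r in resolutions]
    return pairwise_distances(members, params, progress_every=0)
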