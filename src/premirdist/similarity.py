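"""Percentile tables and biomarker-panel similarity scoring.

A fitted distance distribution turns a raw distance into a percentile
rank: low rank means the sequences are unusually similar relative to the
catalog-wide distance distribution.  A biomarker panel (a set of miRNAs
reported for a disease or condition) is scored by the percentile rank of
the mean of its pairwise stem-loop distances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import Catalog, ResolutionPolicy, resolve_panel
from .distance import (AlignmentParams, CondensedDistances, DEFAULT_PARAMS,
                       pairwise_distances)
from .distfit import FittedDistribution

logger = logging.getLogger(__name__)


@dataclass
class QuantileTable:
    """Rows of (q percent, distance value), q strictly increasing."""

    qs: np.ndarray
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.qs = np.asarray(self.qs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.qs.shape != self.values.shape or self.qs.ndim != 1:
            raise ValueError("qs and values must be matching 1-D arrays")
        if np.any(self.qs <= 0) or np.any(self.qs > 100):
            raise ValueError("q must lie in (0, 100]")
        if np.any(np.diff(self.qs) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("table values must be nondecreasing")

    def __len__(self) -> int:
        return len(self.qs)

    def value_at(self, q: float) -> float:
        idx = np.nonzero(self.qs == q)[0]
        if idx.size == 0:
            raise KeyError(f"q={q} not in table")
        return float(self.values[idx[0]])

    def nearest_q(self, d: float) -> float:
        """The q whose tabulated value is closest to d (ties: smaller q)."""
        gaps = np.abs(self.values - d)
        return float(self.qs[int(np.argmin(gaps))])  # argmin takes first tie

    def interp_percentile(self, d: float) -> float:
        """Percentile of d by linear interpolation between table rows."""
        return float(np.interp(d, self.values, self.qs,
                               left=0.0, right=100.0))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# quantile table{': ' + self.source if self.source else ''}\n")
            fh.write("q\tvalue\n")
            for q, v in zip(self.qs, self.values):
                fh.write(f"{q:g}\t{float(v)!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QuantileTable":
        qs, values = [], []
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#") or line.startswith("q\t"):
                continue
            q, v = line.split("\t")
            qs.append(float(q))
            values.append(float(v))
        return cls(np.array(qs), np.array(values), source=str(path))


def quantile_table(
    model: FittedDistribution, qs: Sequence[float] | np.ndarray
) -> QuantileTable:
    """Tabulate model quantiles at the given percent levels.

    By convention the q=100 row is the maximum *observed* distance rather
    than the model's upper support limit (which is infinite for unbounded
    families such as the Gaussian KDE).
    """
    qs = np.asarray(qs, dtype=float)
    if np.any(qs <= 0) or np.any(qs > 100):
        raise ValueError("q must lie in (0, 100]")
    values = np.empty_like(qs)
    interior = qs < 100
    values[interior] = np.atleast_1d(model.quantile(qs[interior] / 100.0))
    values[~interior] = model.data_max
    # guard against tail quantiles overshooting the observed maximum
    values = np.minimum.accumulate(values[::-1])[::-1] \
        if np.any(np.diff(values) < 0) else values
    return QuantileTable(qs, values, source=f"{model.family} fit")


def percentile_of(
    model: FittedDistribution | None,
    d: float,
    mode: str = "continuous",
    table: QuantileTable | None = None,
) -> float:
    """Percentile rank of a distance under the reference distribution.

    ``continuous`` mode returns 100 * cdf(d) from the fitted model;
    ``nearest-table`` returns the tabulated q whose value is closest to d
    (the printed-table lookup rule, ties to the smaller q).
    """
    if mode == "continuous":
        if model is None:
            raise ValueError("continuous mode requires a fitted model")
        return 100.0 * float(model.cdf(d))
    if mode == "nearest-table":
        if table is None:
            raise ValueError("nearest-table mode requires a quantile table")
        return table.nearest_q(d)
    raise ValueError(f"unknown mode {mode!r}")


def is_similar(percentile: float, threshold_p: float) -> bool:
    """Similarity verdict: strictly below the chosen percentile threshold."""
    if not (0 < percentile <= 100 and 0 < threshold_p <= 100):
        raise ValueError("percentile and threshold must lie in (0, 100]")
    return percentile < threshold_p


@dataclass
class PanelReport:
    """Similarity report for one biomarker panel."""

    queries: list[str]
    resolved: list[str]
    ambiguous: list[bool]
    distances: CondensedDistances
    mean: float
    range: tuple[float, float]
    percentile_of_mean: float
    threshold_p: float | None = None
    similar: bool | None = None
    n_saturated: int = 0

    @property
    def m(self) -> int:
        return len(self.resolved)

    @property
    def pair_count(self) -> int:
        return self.m * (self.m - 1) // 2

    def to_dict(self) -> dict:
        return {
            "queries": self.queries,
            "resolved": self.resolved,
            "ambiguous": self.ambiguous,
            "m": self.m,
            "pair_count": self.pair_count,
            "distances": [float(v) for v in self.distances.values],
            "mean": self.mean,
            "range": list(self.range),
            "percentile_of_mean": self.percentile_of_mean,
            "threshold_p": self.threshold_p,
            "similar": self.similar,
            "n_saturated": self.n_saturated,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def summary(self) -> str:
        lines = [
            f"panel of {self.m} miRNAs -> {self.pair_count} pairwise "
            "distances",
            f"  mean distance      = {self.mean:.6g}",
            f"  range              = ({self.range[0]:.6g}, "
            f"{self.range[1]:.6g})",
            f"  percentile of mean = {self.percentile_of_mean:.4g}",
        ]
        if self.n_saturated:
            lines.append(f"  saturated pairs excluded = {self.n_saturated}")
        if self.threshold_p is not None:
            verdict = "similar" if self.similar else "not similar"
            lines.append(f"  verdict at p<{self.threshold_p:g}: {verdict}")
        return "\n".join(lines)


def analyze_panel(
    names: Sequence[str],
    catalog: Catalog,
    model: FittedDistribution,
    params: AlignmentParams = DEFAULT_PARAMS,
    policy: ResolutionPolicy = ResolutionPolicy.MULTI_LOCUS_FIRST,
    threshold_p: float | None = None,
    *,
    species_prefix: str = "hsa-",
    name_map: Mapping[str, str] | None = None,
    saturated: str = "exclude",
    cap: float | None = None,
) -> PanelReport:
    """Score a biomarker panel against a fitted distance distribution.

    The panel mean uses finite distances only (saturated pairs are
    excluded with a warning, or substituted with ``cap`` when
    ``saturated="cap"``); the percentile of the mean is continuous-mode
    (100 * cdf).
    """
    if len(names) < 2:
        raise ValueError("a panel needs at least 2 names")
    resolutions = resolve_panel(names, catalog, policy,
                                species_prefix=species_prefix,
                                name_map=name_map)
    members = [catalog[r.matches[0]] for r in resolutions]
    distances = pairwise_distances(members, params, progress_every=0)
    values = distances.values
    n_saturated = int(distances.saturated_mask.sum())
    if n_saturated:
        if saturated == "cap":
            if cap is None:
                raise ValueError("saturated='cap' requires a cap value")
            values = np.where(distances.saturated_mask, cap, values)
        else:
            logger.warning("excluding %d saturated pair(s) from panel mean",
                           n_saturated)
            values = values[~distances.saturated_mask]
    if values.size == 0:
        raise ValueError("no finite pairwise distances in panel")
    mean = float(np.mean(values))
    rng_lo, rng_hi = float(np.min(values)), float(np.max(values))
    pct = percentile_of(model, mean, mode="continuous")
    similar = is_similar(max(pct, np.nextafter(0, 1)), threshold_p) \
        if threshold_p is not None else None
    return PanelReport(
        queries=list(names),
        resolved=[r.matches[0] for r in resolutions],
        ambiguous=[r.ambiguous for r in resolutions],
        distances=distances,
        mean=mean,
        range=(rng_lo, rng_hi),
        percentile_of_mean=pct,
        threshold_p=threshold_p,
        similar=similar,
        n_saturated=n_saturated,
    )
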