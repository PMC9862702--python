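"""End-to-end orchestration: catalog -> distances -> fits -> tables -> panels.

One :class:`RunConfig` drives the whole workflow.  Every artifact written
to the output directory carries the config hash and package version, the
distance stage reuses its on-disk cache when inputs are unchanged, and all
randomness flows from the single config seed (child seeds derived
deterministically per stage).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .catalog import ResolutionPolicy, load_name_map, read_hairpin_fasta
from .distance import AlignmentParams, pairwise_distances
from .distfit import DistanceDistribution, FAMILIES
from .model_io import save_model
from .similarity import analyze_panel, quantile_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    catalog_path: str
    output_dir: str
    species_prefix: str = ""
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    families: tuple[str, ...] = FAMILIES
    bandwidth: float | str = "auto"
    n_check: int = 66
    seed: int = 0
    quantile_step: float = 5.0
    threshold_p: float | None = None
    panels: dict[str, list[str]] = field(default_factory=dict)
    name_map_path: str | None = None
    policy: str = ResolutionPolicy.MULTI_LOCUS_FIRST.value

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alignment"] = dataclasses.asdict(self.alignment)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if text.lstrip().startswith("{"):
            raw = json.loads(text)
        else:  # flat key=value lines, '#' comments
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = json.loads(value.strip()) \
                    if value.strip()[:1] in "[{0123456789-\"tfn" \
                    else value.strip()
        if isinstance(raw.get("alignment"), dict):
            raw["alignment"] = AlignmentParams(**raw["alignment"])
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)


def run_flowchart(config: RunConfig) -> dict[str, Path]:
    """Execute the full workflow; returns the artifact paths.

    Stages: read catalog -> all-pairs distances (cached) -> fit candidate
    families -> KS model selection -> quantile table from the selected
    model -> per-panel similarity reports.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "version": __version__}
    artifacts: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    _stage("catalog")
    try:
        catalog = read_hairpin_fasta(config.catalog_path,
                                     config.species_prefix or None)
    except Exception as exc:
        raise RuntimeError(f"[catalog] {exc}") from exc
    checksum = hashlib.sha256(
        "".join(r.sequence for r in catalog).encode()).hexdigest()[:12]
    logger.info("catalog: %d records (checksum %s); seed=%d bandwidth=%s "
                "alignment=%s", len(catalog), checksum, config.seed,
                config.bandwidth, config.alignment)

    _stage("distances")
    cache = out / "distances.tsv"
    try:
        distances = pairwise_distances(catalog, config.alignment,
                                       cache_path=cache)
    except Exception as exc:
        raise RuntimeError(f"[distances] {exc}") from exc
    artifacts["distances"] = cache

    _stage("fit+select")
    try:
        model = DistanceDistribution(distances.values)
        selection = model.select(
            config.families, n_check=config.n_check, seed=config.seed,
            kde={"bandwidth": config.bandwidth},
        )
    except Exception as exc:
        raise RuntimeError(f"[fit] {exc}") from exc
    for family in config.families:
        path = out / f"model_{family}.json"
        save_model(selection.fit_for(family), path)
        artifacts[f"model_{family}"] = path
    sel_path = out / "selection.tsv"
    table = selection.table.copy()
    with open(sel_path, "w") as fh:
        fh.write(f"# model selection  {json.dumps(stamp)}\n")
        table.to_csv(fh, sep="\t", index=False)
    artifacts["selection"] = sel_path
    logger.info("selected family: %s", selection.best_family)

    _stage("quantiles")
    qs = np.arange(config.quantile_step, 100 + 1e-9, config.quantile_step)
    qtable = quantile_table(selection.best_fit, qs)
    q_path = out / "quantiles.tsv"
    qtable.to_tsv(q_path)
    artifacts["quantiles"] = q_path

    _stage("panels")
    name_map = load_name_map(config.name_map_path) \
        if config.name_map_path else None
    for panel_name, names in config.panels.items():
        try:
            report = analyze_panel(
                names, catalog, selection.best_fit, config.alignment,
                ResolutionPolicy(config.policy),
                threshold_p=config.threshold_p,
                species_prefix=config.species_prefix or "hsa-",
                name_map=name_map,
            )
        except Exception as exc:
            raise RuntimeError(f"[panel {panel_name}] {exc}") from exc
        p_path = out / f"panel_{panel_name}.json"
        payload = report.to_dict()
        payload.update(stamp)
        p_path.write_text(json.dumps(payload, indent=2) + "\n")
        artifacts[f"panel_{panel_name}"] = p_path

    config.save(out / "config.json")
    artifacts["config"] = out / "config.json"
    return artifacts
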