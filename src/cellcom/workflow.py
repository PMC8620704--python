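"""End-to-end study orchestration driven by a YAML config.

A study config names the object tables to ingest, how to group cells
(by footprint shape, treatment and/or receptor channel), and which
group pairs to compare.  ``run_analysis`` computes both center-of-mass
metrics for every cell, runs two-sided Mann–Whitney comparisons for
each configured pair and both metrics, and writes tidy CSV tables plus
boxplots.  Everything is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .io import IngestError, config_from_mapping, read_object_table
from .metrics import metrics_table
from .model import CellRecord, DomainError, IngestConfig, StudyGroup
from .stats import adjust_benjamini_hochberg, compare_groups

log = logging.getLogger(__name__)

GROUPING_FIELDS = ("shape", "treatment", "receptor")


@dataclass
class StudyConfig:
    tables: list[str]
    group_by: list[str] = field(default_factory=lambda: ["shape"])
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    ingest: IngestConfig = field(default_factory=IngestConfig)
    alpha: float = 0.05
    adjust: str = "none"          # none | bh
    weighted_spread: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.group_by) - set(GROUPING_FIELDS)
        if unknown:
            raise DomainError(f"unknown grouping fields: {sorted(unknown)}")
        if self.adjust not in ("none", "bh"):
            raise DomainError(f"unknown adjustment {self.adjust!r}")


def load_study_config(path: str | Path) -> StudyConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ingest = config_from_mapping(raw["ingest"]) if "ingest" in raw else IngestConfig()
    tables = [str(Path(path).parent / t) for t in raw.get("tables", [])]
    return StudyConfig(
        tables=tables,
        group_by=list(raw.get("group_by", ["shape"])),
        comparisons=[tuple(pair) for pair in raw.get("comparisons", [])],
        ingest=ingest,
        alpha=float(raw.get("alpha", 0.05)),
        adjust=str(raw.get("adjust", "none")),
        weighted_spread=bool(raw.get("weighted_spread", False)),
    )


def group_cells(cells: list[CellRecord], group_by: list[str]) -> dict[str, StudyGroup]:
    """Partition cells into named groups by the configured metadata fields."""
    groups: dict[str, StudyGroup] = {}
    for cell in cells:
        key = "/".join(str(getattr(cell, f)) for f in group_by)
        groups.setdefault(key, StudyGroup(key)).cells.append(cell)
    return groups


def run_analysis(
    config: StudyConfig | str | Path,
    out_dir: str | Path,
    seed: int = 0,
) -> dict:
    """Run the configured study end to end; returns the report bundle.

    Outputs under ``out_dir``: metrics.csv (per-cell metric values),
    comparisons.csv (Mann–Whitney results with stars) and a boxplot per
    comparison pair.
    """
    if not isinstance(config, StudyConfig):
        config = load_study_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cells: list[CellRecord] = []
    for table in config.tables:
        cells.extend(read_object_table(table, config.ingest))
    if not cells:
        raise IngestError("no cells ingested from the configured tables")
    groups = group_cells(cells, config.group_by)

    metrics = pd.concat(
        [metrics_table(g, config.weighted_spread) for g in groups.values()],
        ignore_index=True,
    )
    metrics.to_csv(out_dir / "metrics.csv", index=False)

    rows = []
    for name_a, name_b in config.comparisons:
        for name in (name_a, name_b):
            if name not in groups:
                raise DomainError(
                    f"comparison group {name!r} resolves to zero cells; "
                    f"available: {sorted(groups)}"
                )
        for metric in ("reference", "spread"):
            va = metrics.query("group == @name_a and metric == @metric")["value_um"]
            vb = metrics.query("group == @name_b and metric == @metric")["value_um"]
            res = compare_groups(va, vb, metric=metric, name_a=name_a, name_b=name_b)
            rows.append(asdict(res))
    comparisons = pd.DataFrame(rows)
    if config.adjust == "bh" and not comparisons.empty:
        comparisons["p_adjusted"] = adjust_benjamini_hochberg(comparisons["p_value"])
    comparisons.to_csv(out_dir / "comparisons.csv", index=False)

    from .plots import metric_boxplots

    plot_paths = []
    for name_a, name_b in config.comparisons:
        sub = metrics[metrics["group"].isin([name_a, name_b])]
        safe = f"{name_a}_vs_{name_b}".replace("/", "-")
        plot_paths.append(metric_boxplots(sub, out_dir / f"boxplot_{safe}.png",
                                          title=f"{name_a} vs {name_b}"))

    log.info("analysis complete: %d cells, %d groups, %d comparisons",
             len(cells), len(groups), len(config.comparisons))
    return {
        "groups": groups,
        "metrics": metrics,
        "comparisons": comparisons,
        "plots": plot_paths,
        "seed": seed,
    }
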