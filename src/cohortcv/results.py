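"""Result containers and on-disk output formats.

The grid summary mirrors the reporting layout (mean +- SD per metric per
configuration across outer folds); full per-fold detail goes to JSON with
deterministic field ordering so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .crossval import GRID_COLUMNS, GridResult
from .errors import CohortValidationError


@dataclass
class ResultsBundle:
    """Per-fold records plus the grid summary and provenance."""

    grid_summary: pd.DataFrame
    fold_records: list[dict]
    provenance: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        v = []
        configs = {(r["algorithm"], r["clinical_strategy"],
                    r["microbiome_rep"]) for r in self.fold_records}
        k = self.provenance.get("k_outer")
        if k is not None:
            for cfg in configs:
                n = sum(1 for r in self.fold_records
                        if (r["algorithm"], r["clinical_strategy"],
                            r["microbiome_rep"]) == cfg)
                if n != k:
                    v.append(f"config {cfg} has {n} fold records, expected {k}")
        rows = {(r.algorithm, r.clinical_strategy, r.microbiome_rep)
                for r in self.grid_summary.itertuples()}
        if len(rows) != len(self.grid_summary):
            v.append("grid summary has duplicate configuration rows")
        if configs and rows != configs:
            v.append("grid summary rows do not match fold-record configs")
        return v


def bundle_from_grid(grid: GridResult) -> ResultsBundle:
    records = []
    for res in grid.results.values():
        for fr in res.fold_results:
            records.append({
                "algorithm": res.config.algorithm,
                "clinical_strategy": res.config.clinical_strategy,
                "microbiome_rep": res.config.microbiome_rep,
                "fold": fr.fold,
                "status": fr.status,
                "frozen_threshold": fr.frozen_threshold,
                "selected_clinical": list(fr.selected_clinical),
                "selected_taxa": list(fr.selected_taxa),
                "subject_probs": dict(sorted(fr.subject_probs.items())),
                "metrics": {k: fr.metrics[k] for k in sorted(fr.metrics)},
            })
    provenance = {
        "config_hash": grid.base_config.config_hash(),
        "seed": grid.base_config.seed,
        "k_outer": grid.base_config.k_outer,
    }
    return ResultsBundle(grid_summary=grid.summary, fold_records=records,
                         provenance=provenance)


def write_results(bundle: ResultsBundle, out_dir) -> list[str]:
    """Write grid_summary.csv, fold_results.json and provenance.json;
    returns the manifest of written file names."""
    violations = bundle.validate()
    if violations:
        raise CohortValidationError(violations)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = bundle.grid_summary.reindex(columns=GRID_COLUMNS)
    summary.to_csv(out / "grid_summary.csv", index=False)
    with open(out / "fold_results.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.fold_records, fh, indent=1, sort_keys=True)
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.provenance, fh, indent=1, sort_keys=True)
    return ["grid_summary.csv", "fold_results.json", "provenance.json"]


def read_results(out_dir) -> ResultsBundle:
    out = Path(out_dir)
    summary = pd.read_csv(out / "grid_summary.csv")
    with open(out / "fold_results.json", encoding="utf-8") as fh:
        records = json.load(fh)
    with open(out / "provenance.json", encoding="utf-8") as fh:
        provenance = json.load(fh)
    return ResultsBundle(grid_summary=summary, fold_records=records,
                         provenance=provenance)


@dataclass
class PermutationRecord:
    """Serialized permutation-test outcome (see resampling module)."""

    observed: float
    null_draws: list[float]
    b: int
    m: int
    p_perm: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)
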