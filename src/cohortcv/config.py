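"""Analysis configuration: one cell of the 2x3x2 model grid plus all fixed
numeric settings of the pipeline.

All hyperparameters are fixed a priori (never tuned inside the pipeline):
500-tree random forest with 4 candidate features per split and minimum node
size 10, or elastic-net logistic regression at alpha=0.5, lambda=0.01.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ParameterError

ALGORITHMS = ("random_forest", "elastic_net")
CLINICAL_STRATEGIES = ("dream_minimal", "literature", "data_driven")
MICROBIOME_REPS = ("da_selected", "full_filtered")
CLR_MODES = ("per_sample", "train_anchored")
WEIGHTINGS = ("none", "inverse_frequency")


@dataclass
class AnalysisConfig:
    """Settings for one analysis run.

    The grid axes are ``algorithm`` x ``clinical_strategy`` x
    ``microbiome_rep``; everything else is a fixed numeric setting shared by
    all twelve grid cells.
    """

    algorithm: str = "random_forest"
    clinical_strategy: str = "data_driven"
    microbiome_rep: str = "full_filtered"
    pseudocount: float = 0.65
    k_outer: int = 5
    inner_train_fraction: float = 0.70
    da_p_threshold: float = 0.10
    min_library: int = 3000
    min_prevalence: float = 0.05
    missingness_max: float = 0.30
    n_trees: int = 500
    mtry: int = 4
    min_node: int = 10
    alpha: float = 0.5
    lambda_: float = 0.01
    seed: int = 0
    weighting: str = "none"
    clr_mode: str = "per_sample"
    covariate_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (self.algorithm in ALGORITHMS, f"algorithm {self.algorithm!r}"),
            (self.clinical_strategy in CLINICAL_STRATEGIES,
             f"clinical_strategy {self.clinical_strategy!r}"),
            (self.microbiome_rep in MICROBIOME_REPS,
             f"microbiome_rep {self.microbiome_rep!r}"),
            (self.clr_mode in CLR_MODES, f"clr_mode {self.clr_mode!r}"),
            (self.weighting in WEIGHTINGS, f"weighting {self.weighting!r}"),
            (self.pseudocount > 0, "pseudocount must be > 0"),
            (self.k_outer >= 2, "k_outer must be >= 2"),
            (0 < self.inner_train_fraction < 1, "inner_train_fraction in (0,1)"),
            (0 <= self.da_p_threshold <= 1, "da_p_threshold in [0,1]"),
            (self.min_library >= 0, "min_library must be >= 0"),
            (0 <= self.min_prevalence <= 1, "min_prevalence in [0,1]"),
            (0 <= self.missingness_max <= 1, "missingness_max in [0,1]"),
            (self.n_trees >= 1, "n_trees must be >= 1"),
            (self.mtry >= 1, "mtry must be >= 1"),
            (self.min_node >= 1, "min_node must be >= 1"),
            (0 <= self.alpha <= 1, "alpha in [0,1]"),
            (self.lambda_ > 0, "lambda must be > 0"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ParameterError("invalid AnalysisConfig: " + "; ".join(bad))

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def label(self) -> str:
        return f"{self.algorithm}/{self.clinical_strategy}/{self.microbiome_rep}"


def load_config(path) -> AnalysisConfig:
    """Read a single-document YAML file whose keys match AnalysisConfig fields.

    The key ``lambda`` is accepted as an alias for ``lambda_`` (the Python
    field name avoids the reserved word).
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError("configuration file must contain a mapping")
    if "lambda" in data:
        data["lambda_"] = data.pop("lambda")
    valid = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


def grid_configs(base: AnalysisConfig | None = None,
                 algorithms=ALGORITHMS,
                 clinical_strategies=CLINICAL_STRATEGIES,
                 microbiome_reps=MICROBIOME_REPS) -> list[AnalysisConfig]:
    """Enumerate the model grid (2 algorithms x 3 clinical strategies x
    2 microbiome representations = 12 configurations by default)."""
    base = base or AnalysisConfig()
    return [
        base.replace(algorithm=a, clinical_strategy=c, microbiome_rep=m)
        for a in algorithms
        for c in clinical_strategies
        for m in microbiome_reps
    ]
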