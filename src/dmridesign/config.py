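"""Declarative experiment configurations: schema, units, bundled fixtures.

An experiment configuration is a YAML document with four sections::

    name: E2.1
    task:                      # the classification task
      positive: Chronic        # tissue treated as "diseased"
      negative: Healthy
    tissues:                   # tissue characterisation
      diffusivity_units: 1e-3 mm^2/s     # units of the means/sds below
      distributions:
        - label: Healthy
          model: ivim
          means: {f: 0.09, d_slow: 0.35, d_fast: 123}
          sds:   {f: 0.0,  d_slow: 0.0,  d_fast: 0.0}
        - label: Chronic
          ...
    design:                    # candidate experimental design
      b_values: [0, 10, 20, 40, 80, 100, 200, 400, 600]   # s/mm^2
      snr: 20
      n_per_tissue: 10000
      seed: 2021
      analyses:                # model/fitting-method combinations to assess
        - {method: snlls, b_threshold: 50, scores: [f, d_slow, d_fast]}
        - {method: bcnlls, scores: [f, d_slow, d_fast]}
        - {method: wls, scores: [adc]}
    evaluation:                # optional
      orientation: auto        # or fixed
      subsample: {n_pos: 14, n_neg: 14, repeats: 1000}

Diffusivity means/SDs may be given either in ``mm^2/s`` or in the
``1e-3 mm^2/s`` convention common in clinical tables; the mandatory
``diffusivity_units`` field selects which, and values are converted to the
canonical mm^2/s exactly once, here at load time.  b-values are always
s/mm^2 and SNR is dimensionless.

Fixture configurations reproducing published IVIM classification settings in
spondyloarthritis (tasks E1.1-E1.4 against two clinical acquisition schemes,
and the illustrative simulated tasks E2.1-E2.2) ship with the package; see
:func:`list_fixtures` / :func:`fixture_path`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .cohort import TissueDistribution
from .errors import ConfigurationError
from .fitting import METHOD_MODEL, _METHOD_ALIASES
from .signal_models import MODEL_PARAMS, AcquisitionProtocol

__all__ = [
    "AnalysisSpec",
    "SubsampleSpec",
    "ExperimentConfig",
    "load_config",
    "list_fixtures",
    "fixture_path",
    "load_fixture",
]

_DIFFUSIVITY_UNITS = {
    "mm^2/s": 1.0,
    "1e-3 mm^2/s": 1e-3,
    "10^-3 mm^2/s": 1e-3,
    "um^2/ms": 1e-3,
}

# Parameters that carry diffusivity units (f is a dimensionless fraction).
_DIFFUSIVE_PARAMS = {"d_slow", "d_fast", "adc"}


def _get(mapping: dict, key: str, path: str, typ=None):
    if not isinstance(mapping, dict) or key not in mapping:
        raise ConfigurationError(f"missing required field '{path}.{key}'")
    value = mapping[key]
    if typ is not None and not isinstance(value, typ):
        raise ConfigurationError(
            f"field '{path}.{key}' has wrong type {type(value).__name__}"
        )
    return value


@dataclass(frozen=True)
class AnalysisSpec:
    """One model/fitting-method combination assessed on the cohort."""

    method: str
    scores: tuple[str, ...]
    b_threshold: float | None = None
    b_subset: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        canon = _METHOD_ALIASES.get(str(self.method).lower())
        if canon is None:
            raise ConfigurationError(
                f"unknown fitting method {self.method!r} in design.analyses"
            )
        object.__setattr__(self, "method", canon)
        valid = set(MODEL_PARAMS[self.model])
        bad = [s for s in self.scores if s not in valid]
        if bad:
            raise ConfigurationError(
                f"score parameter(s) {bad} not in model {self.model!r} "
                f"(valid: {sorted(valid)})"
            )
        if not self.scores:
            raise ConfigurationError("each analysis needs at least one score parameter")
        object.__setattr__(self, "scores", tuple(self.scores))

    @property
    def model(self) -> str:
        return METHOD_MODEL[self.method]


@dataclass(frozen=True)
class SubsampleSpec:
    """Clinical-size sub-sampling request for the AUC distribution."""

    n_pos: int
    n_neg: int
    repeats: int = 1000


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated, unit-converted experiment description."""

    name: str
    positive_label: str
    negative_label: str
    tissues: tuple[TissueDistribution, TissueDistribution]
    protocol: AcquisitionProtocol
    n_per_tissue: int
    seed: int
    analyses: tuple[AnalysisSpec, ...]
    orientation: str = "auto"
    subsample: SubsampleSpec | None = None

    def __post_init__(self) -> None:
        labels = {t.label for t in self.tissues}
        if {self.positive_label, self.negative_label} != labels:
            raise ConfigurationError(
                f"task labels ({self.positive_label!r}, {self.negative_label!r}) "
                f"must match the tissue labels {sorted(labels)}"
            )
        if self.orientation not in ("auto", "fixed"):
            raise ConfigurationError(
                f"evaluation.orientation must be 'auto' or 'fixed', "
                f"got {self.orientation!r}"
            )
        if not self.analyses:
            raise ConfigurationError("design.analyses must list at least one analysis")


def _parse_tissue(entry: dict, scale: float, path: str) -> TissueDistribution:
    label = str(_get(entry, "label", path))
    model = str(_get(entry, "model", path)).lower()
    means = dict(_get(entry, "means", path, dict))
    sds = dict(_get(entry, "sds", path, dict))
    conv_means = {
        k: float(v) * (scale if k in _DIFFUSIVE_PARAMS else 1.0)
        for k, v in means.items()
    }
    conv_sds = {
        k: float(v) * (scale if k in _DIFFUSIVE_PARAMS else 1.0)
        for k, v in sds.items()
    }
    return TissueDistribution(label, model, conv_means, conv_sds)


def parse_config(doc: dict, source: str = "<config>") -> ExperimentConfig:
    """Validate a parsed YAML/JSON document into an :class:`ExperimentConfig`."""
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{source}: top level must be a mapping")
    name = str(doc.get("name", Path(source).stem))

    task = _get(doc, "task", "", dict)
    positive = str(_get(task, "positive", "task"))
    negative = str(_get(task, "negative", "task"))

    tissues_block = _get(doc, "tissues", "", dict)
    units = _get(tissues_block, "diffusivity_units", "tissues")
    if units not in _DIFFUSIVITY_UNITS:
        raise ConfigurationError(
            f"field 'tissues.diffusivity_units' must be one of "
            f"{sorted(_DIFFUSIVITY_UNITS)}, got {units!r}"
        )
    scale = _DIFFUSIVITY_UNITS[units]
    dists = _get(tissues_block, "distributions", "tissues", list)
    if len(dists) != 2:
        raise ConfigurationError(
            f"'tissues.distributions' must list exactly 2 tissues, got {len(dists)}"
        )
    tissues = tuple(
        _parse_tissue(d, scale, f"tissues.distributions[{i}]")
        for i, d in enumerate(dists)
    )

    design = _get(doc, "design", "", dict)
    b_values = np.asarray(_get(design, "b_values", "design", list), dtype=float)
    snr = float(_get(design, "snr", "design"))
    protocol = AcquisitionProtocol(b_values=b_values, snr=snr)
    n_per_tissue = int(_get(design, "n_per_tissue", "design"))
    seed = int(_get(design, "seed", "design"))
    raw_analyses = _get(design, "analyses", "design", list)
    analyses = []
    for i, a in enumerate(raw_analyses):
        path = f"design.analyses[{i}]"
        method = str(_get(a, "method", path))
        scores = tuple(str(s) for s in _get(a, "scores", path, list))
        bt = a.get("b_threshold")
        subset = tuple(float(x) for x in a["b_subset"]) if "b_subset" in a else None
        analyses.append(AnalysisSpec(method, scores, None if bt is None else float(bt), subset))

    evaluation = doc.get("evaluation") or {}
    orientation = str(evaluation.get("orientation", "auto"))
    subsample = None
    if "subsample" in evaluation and evaluation["subsample"] is not None:
        ss = evaluation["subsample"]
        subsample = SubsampleSpec(
            n_pos=int(_get(ss, "n_pos", "evaluation.subsample")),
            n_neg=int(_get(ss, "n_neg", "evaluation.subsample")),
            repeats=int(ss.get("repeats", 1000)),
        )

    return ExperimentConfig(
        name=name,
        positive_label=positive,
        negative_label=negative,
        tissues=tissues,
        protocol=protocol,
        n_per_tissue=n_per_tissue,
        seed=seed,
        analyses=tuple(analyses),
        orientation=orientation,
        subsample=subsample,
    )


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment configuration from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"{path}: not valid YAML: {exc}") from exc
    return parse_config(doc, source=str(path))


def _fixture_dir():
    return resources.files("dmridesign") / "configs"


def list_fixtures() -> list[str]:
    """Names of the bundled fixture configurations (e.g. 'E2.1')."""
    return sorted(
        p.name[: -len(".yaml")] for p in _fixture_dir().iterdir()
        if p.name.endswith(".yaml")
    )


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture configuration."""
    p = _fixture_dir() / f"{name}.yaml"
    if not p.is_file():
        raise ConfigurationError(
            f"no bundled fixture {name!r}; available: {list_fixtures()}"
        )
    return Path(str(p))


def load_fixture(name: str) -> ExperimentConfig:
    """Load a bundled fixture configuration by name."""
    return load_config(fixture_path(name))
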