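"""YAML/JSON configuration loading with shipped defaults.

Hierarchy, scoring, layout, value-matrix, custom-weight and study files
are plain YAML or JSON documents validated through the pydantic models;
the package ships editable defaults under ``cii/data/``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .disaggregation import StudySpec
from .escore import CustomWeights
from .hierarchy import EvidenceHierarchy, ScoringConfig
from .value_matrix import MatrixLayout, TreatmentGoalPath, ValueMatrix

PathLike = Union[str, Path]


def _load_document(path: PathLike) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_hierarchy(path: PathLike) -> EvidenceHierarchy:
    return EvidenceHierarchy.model_validate(_load_document(path))


def load_scoring(path: PathLike) -> ScoringConfig:
    return ScoringConfig.model_validate(_load_document(path))


def load_layout(path: PathLike) -> MatrixLayout:
    return MatrixLayout.model_validate(_load_document(path))


def load_matrix(path: PathLike) -> ValueMatrix:
    return ValueMatrix.model_validate(_load_document(path))


def load_matrices(paths) -> list[ValueMatrix]:
    return [load_matrix(p) for p in paths]


def load_custom(path: PathLike) -> CustomWeights:
    return CustomWeights.model_validate(_load_document(path))


def load_study(path: PathLike) -> StudySpec:
    return StudySpec.model_validate(_load_document(path))


def load_paths(path: PathLike) -> list[TreatmentGoalPath]:
    return [TreatmentGoalPath.model_validate(d) for d in _load_document(path)]


def _data_text(name: str) -> str:
    return resources.files("cii.data").joinpath(name).read_text()


def default_hierarchy_config() -> EvidenceHierarchy:
    return EvidenceHierarchy.model_validate(yaml.safe_load(_data_text("hierarchy.yaml")))


def default_scoring_config() -> ScoringConfig:
    return ScoringConfig.model_validate(yaml.safe_load(_data_text("scoring.yaml")))


def default_layout_config() -> MatrixLayout:
    return MatrixLayout.model_validate(yaml.safe_load(_data_text("layout.yaml")))


def default_uniform_matrix() -> ValueMatrix:
    return ValueMatrix.model_validate(
        yaml.safe_load(_data_text("values_1990-01-01.yaml"))
    )


def controlled_vocabulary() -> list[str]:
    """The shipped tag vocabulary, one tag per line."""
    return [
        line.strip()
        for line in _data_text("tags.txt").splitlines()
        if line.strip() and not line.startswith("#")
    ]
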