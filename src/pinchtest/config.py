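"""YAML configuration covering every tunable of the pipeline.

One document with blocks ``cohort``, ``preprocess``, ``segmentation``,
``features``, ``validity`` and ``analysis``; every key is optional and
falls back to the documented default.
"""
from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Any

import yaml

from .aggregate import ValidityRules
from .features import FeatureConfig
from .pipeline import AnalysisConfig
from .preprocess import PreprocessConfig
from .segmentation import SuccessRules
from .simulate import CohortConfig


def _build(cls, block: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**block)


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a pipeline config file into typed config objects.

    Returns a dict with keys ``cohort`` (CohortConfig) and ``analysis``
    (AnalysisConfig, holding preprocess/segmentation/features/validity).
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    preprocess = _build(PreprocessConfig, doc.get("preprocess", {})).validate()
    features_block = dict(doc.get("features", {}))
    features_block["preprocess"] = preprocess
    analysis_block = dict(doc.get("analysis", {}))
    analysis = AnalysisConfig(
        features=_build(FeatureConfig, features_block),
        segmentation=_build(SuccessRules, doc.get("segmentation", {})),
        validity=_build(ValidityRules, doc.get("validity", {})).validate(),
        **analysis_block,
    )
    cohort = _build(CohortConfig, doc.get("cohort", {})).validate()
    return {"cohort": cohort, "analysis": analysis}


def default_config() -> dict[str, Any]:
    return {"cohort": CohortConfig(), "analysis": AnalysisConfig()}
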