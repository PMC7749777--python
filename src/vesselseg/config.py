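"""YAML serialization of the pipeline configuration bundle."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .bcosfire import BcosfireConfig, FilterParams
from .fusion import PostprocessConfig
from .misodata import MisodataConfig
from .preprocess import PreprocessConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the segmentation pipeline, one per section."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    misodata: MisodataConfig = field(default_factory=MisodataConfig)
    bcosfire: BcosfireConfig = field(default_factory=BcosfireConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)

    def to_yaml(self, path=None) -> str:
        doc = {
            "preprocess": asdict(self.preprocess),
            "misodata": asdict(self.misodata),
            "bcosfire": asdict(self.bcosfire),
            "postprocess": asdict(self.postprocess),
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        def build(klass, section):
            kwargs = dict(doc.get(section, {}) or {})
            allowed = {f.name for f in fields(klass)}
            unknown = set(kwargs) - allowed
            if unknown:
                raise ValueError(f"unknown {section} keys: {sorted(unknown)}")
            return klass(**kwargs)

        bc_kwargs = dict(doc.get("bcosfire", {}) or {})
        for side in ("symmetric", "asymmetric"):
            if side in bc_kwargs and isinstance(bc_kwargs[side], dict):
                params = dict(bc_kwargs[side])
                if "rhos" in params:
                    params["rhos"] = tuple(params["rhos"])
                bc_kwargs[side] = FilterParams(**params)
        return cls(
            preprocess=build(PreprocessConfig, "preprocess"),
            misodata=build(MisodataConfig, "misodata"),
            bcosfire=BcosfireConfig(**bc_kwargs),
            postprocess=build(PostprocessConfig, "postprocess"),
        )
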