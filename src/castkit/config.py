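"""Run configuration: every tunable threshold, serializable and hashable.

The effective configuration of a run is logged and hashed into the JSON
report's reproducibility block so that any annotation can be re-run
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .caster import AnnotateConfig
from .crisprdet import AnchorParams, ArrayParams
from .homsearch import ScoringParams


@dataclass(frozen=True)
class RunConfig:
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ann = raw.get("annotate", {})
        array = ArrayParams(**{k: _tup(v) for k, v in ann.pop("array", {}).items()})
        anchor = AnchorParams(**{k: _tup(v) for k, v in ann.pop("anchor", {}).items()})
        scoring = ScoringParams(**ann.pop("scoring", {}))
        known = {f.name for f in fields(AnnotateConfig)}
        unknown = set(ann) - known
        if unknown:
            raise ValueError(f"unknown annotate config keys: {sorted(unknown)}")
        cfg = AnnotateConfig(array=array, anchor=anchor, scoring=scoring, **ann)
        return cls(annotate=cfg, seed=raw.get("seed"))


def _tup(value):
    return tuple(value) if isinstance(value, list) else value
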