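"""Serializable run configuration emitted alongside every pipeline output."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .delphi import RuleConfig


@dataclass(frozen=True)
class RunConfig:
    """The knobs that determine a pipeline run, in serializable form."""

    rules: RuleConfig = field(default_factory=RuleConfig)
    ahp_method: str = "eigenvector"
    ahp_tol: float = 1e-12
    ahp_max_iter: int = 10_000
    ri_extrapolate: bool = False
    display_decimals: int = 1
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=list) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        rules = payload.pop("rules", {})
        rules = {
            k: tuple(v) if isinstance(v, list) else v for k, v in rules.items()
        }
        return cls(rules=RuleConfig(**rules), **payload)
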