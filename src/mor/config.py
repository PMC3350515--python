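"""Run configuration: one JSON-serializable record of everything a run needs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved settings of a screening run; round-trips losslessly via JSON."""

    input: str | None = None
    group_col: str = "group"
    pair_col: str | None = None
    design: str = "independent"
    mode: str = "rank"
    gamma: float = 0.5
    c: float = 1.0
    criterion: str = "sample_cutoff"
    delta: float = 0.01
    alpha: float = 0.05
    n_perm: int = 1000
    d: float = 0.8
    epsilon: float = 0.01
    w: float = 1.0
    z0: float = 3.28
    seed: int | None = None
    out_prefix: str = "mor_run"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        return cls(**data)
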