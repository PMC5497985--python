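"""Run configuration: one JSON document that pins every analysis choice.

Every CLI artifact embeds ``config_hash`` and the seed so a run can be
reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import CohortSpec, default_cohort_spec
from .errors import SpecError
from .io import _spec_from_dict, _spec_to_dict
from .protocol import ProtocolConfig
from .tep import TepConfig


@dataclass
class TaskConfig:
    deadline_ms: float = 2000.0
    min_valid: int = 3
    n_stop_trials: int = 400
    stop_fraction: float = 0.25
    ssd_initial: float = 250.0
    ssd_step: float = 50.0
    choice_repeats: int = 1
    k_bounds: tuple[float, float] = (1e-5, 1.0)


@dataclass
class StatsConfig:
    threshold_sd: float | None = 2.0
    bonferroni_m: int | None = None  # None -> number of measures


@dataclass
class RunConfig:
    seed: int = 0
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    tep: TepConfig = field(default_factory=TepConfig)
    tasks: TaskConfig = field(default_factory=TaskConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cohort: CohortSpec | None = None  # None -> study-default cohort at `seed`

    def resolved_cohort(self) -> CohortSpec:
        if self.cohort is not None:
            return self.cohort
        return default_cohort_spec(seed=self.seed)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dict(
            seed=self.seed,
            protocol=dataclasses.asdict(self.protocol),
            tep=dataclasses.asdict(self.tep),
            tasks=dataclasses.asdict(self.tasks),
            stats=dataclasses.asdict(self.stats),
            cohort=_spec_to_dict(self.cohort) if self.cohort is not None else None,
        )
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def _tuplify(sub: dict, keys: tuple[str, ...]) -> dict:
            return {k: tuple(v) if k in keys and v is not None else v for k, v in sub.items()}

        kwargs: dict = {"seed": int(d.get("seed", 0))}
        if "protocol" in d and d["protocol"] is not None:
            kwargs["protocol"] = ProtocolConfig(
                **_tuplify(d["protocol"], ("epoch_window", "channel_names", "coil_channels",
                                           "lici_window"))
            )
        if "tep" in d and d["tep"] is not None:
            kwargs["tep"] = TepConfig(
                **_tuplify(d["tep"], ("early_tep_window", "lici_window", "baseline_window",
                                      "channels"))
            )
        if "tasks" in d and d["tasks"] is not None:
            kwargs["tasks"] = TaskConfig(**_tuplify(d["tasks"], ("k_bounds",)))
        if "stats" in d and d["stats"] is not None:
            kwargs["stats"] = StatsConfig(**d["stats"])
        if d.get("cohort") is not None:
            kwargs["cohort"] = _spec_from_dict(d["cohort"])
        return cls(**kwargs)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise SpecError(f"config file not found: {path}")
        return cls.from_dict(json.loads(path.read_text()))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
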