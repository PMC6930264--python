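"""Run configuration: a flat YAML mapping validated into model objects."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .energy import ModelParams
from .relax import MCSchedule


@dataclass
class RunConfig:
    """All model, schedule and output settings of a run.

    Round-trips losslessly through YAML; every run output embeds the
    resolved config (defaults filled) together with the seed.
    """

    # model
    kappa_over_ki: float = 1.0
    ke_over_ki: float = 0.0
    lambda0: float = 0.5
    R_over_xi: float = 7.0
    v: float = 0.6
    n_modes: int = 30
    n_s: int = 101
    n_phi: int = 101
    seed: int = 0
    # MC schedule
    temperatures: tuple = MCSchedule.temperatures
    sweeps_per_stage: int = 60
    proposal_width: float = 0.5
    adapt: bool = True
    # outputs
    outdir: str = "nemshell-out"
    export_mesh: bool = False
    export_csv: bool = True
    verbosity: int = 1

    def model_params(self) -> ModelParams:
        keys = ("kappa_over_ki", "ke_over_ki", "lambda0", "R_over_xi", "v",
                "n_modes", "n_s", "n_phi", "seed")
        return ModelParams(**{k: getattr(self, k) for k in keys})

    def mc_schedule(self) -> MCSchedule:
        return MCSchedule(temperatures=tuple(self.temperatures),
                          sweeps_per_stage=self.sweeps_per_stage,
                          proposal_width=self.proposal_width,
                          adapt=self.adapt, seed=self.seed)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["temperatures"] = list(d["temperatures"])
        return yaml.safe_dump(d, sort_keys=False)

    @property
    def mu(self) -> float:
        return self.model_params().mu


def load_config(path_or_text) -> RunConfig:
    """Load and validate a YAML config; unknown or invalid keys error.

    Accepts a filesystem path or raw YAML text; an empty file yields all
    defaults.  Validation is delegated to the model objects (so e.g.
    ``lambda0: 0`` is rejected as it would make mu singular).
    """
    text = None
    try:
        with open(path_or_text) as fh:
            text = fh.read()
    except (OSError, TypeError):
        text = str(path_or_text)
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    if "temperatures" in data:
        data["temperatures"] = tuple(data["temperatures"])
    cfg = RunConfig(**data)
    cfg.model_params()   # raises on out-of-range physics values
    cfg.mc_schedule()
    return cfg
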