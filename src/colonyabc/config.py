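"""Run configuration: defaults, YAML round-tripping, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .abc_dc import DCSchedule
from .abc_inference import PriorSpec
from .lattice_model import DesignSpec, LatticeConfig, ModelParams

__all__ = ["RunConfig", "parse_config", "write_config"]


@dataclass
class RunConfig:
    """All pipeline settings with their default experimental values.

    Defaults reproduce the reference protocol: a 24 x 32 lattice of
    18.75 um sites, tau = 1/24 h steps for 12 h, M = 10 replicates, 5 tracked
    cells recorded every 8 steps, generating parameters (0.25, 0.0025) and a
    uniform prior on (0, 0.99) x (0, 0.01).
    """

    # model
    p_move: float = 0.25
    p_prolif: float = 0.0025
    # lattice
    n_rows: int = 24
    n_cols: int = 32
    site_length: float = 18.75
    step_duration: float = 1.0 / 24.0
    # design
    seeded_rows: int = 24
    n_initial: int = 24
    duration: float = 12.0
    record_interval: int = 8
    n_tracked: int = 5
    n_replicates: int = 10
    # prior
    pm_prior: tuple[float, float] = (0.0, 0.99)
    pp_prior: tuple[float, float] = (0.0, 0.01)
    # ABC rejection
    n_prior_samples: int = 10_000
    acceptance_fraction: float = 0.01
    distance_convention: str = "squared"
    regression_adjust: bool = True
    # ABC-DC
    dc_n_samples: tuple[int, ...] = (1000,) * 8 + (2000,)
    dc_n_clones: tuple[int, ...] = (1, 1, 1, 1, 1, 1, 2, 3, 4)
    dc_tolerance: tuple[float, ...] = (5.0, 2.0, 1.0, 0.5, 0.25, 0.25, 0.25, 0.25, 0.25)
    dc_tolerance_stages: int = 5
    dc_clone_stages: int = 4
    proposal_scale: tuple[float, float] = (0.02, 0.0002)
    # posterior grid / study
    grid_size: int = 512
    repetitions: int = 5
    # run
    seed: int = 0
    out_dir: str = "results"

    def model_params(self) -> ModelParams:
        return ModelParams(self.p_move, self.p_prolif)

    def lattice_config(self) -> LatticeConfig:
        return LatticeConfig(self.n_rows, self.n_cols, self.site_length, self.step_duration)

    def design(self) -> DesignSpec:
        return DesignSpec(
            self.seeded_rows, self.n_initial, self.duration,
            self.record_interval, self.n_tracked, self.n_replicates,
        )

    def prior(self) -> PriorSpec:
        return PriorSpec(tuple(self.pm_prior), tuple(self.pp_prior))

    def schedule(self) -> DCSchedule:
        return DCSchedule(
            tuple(self.dc_n_samples), tuple(self.dc_n_clones), tuple(self.dc_tolerance),
            self.dc_tolerance_stages, self.dc_clone_stages,
        )

    def validate(self) -> None:
        self.model_params()
        self.design().validate(self.lattice_config())
        try:
            self.prior()
        except ValueError as exc:
            raise ValueError(f"pm_prior/pp_prior: {exc}") from exc
        self.schedule()
        if not 0 < self.acceptance_fraction <= 1:
            raise ValueError("acceptance_fraction must be in (0, 1]")
        if self.distance_convention not in ("squared", "sqrt"):
            raise ValueError("distance_convention must be 'squared' or 'sqrt'")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d


_TUPLE_FIELDS = {
    "pm_prior", "pp_prior", "dc_n_samples", "dc_n_clones", "dc_tolerance",
    "proposal_scale",
}


def parse_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config, filling defaults; unknown keys are rejected and
    invalid values reported with their field name."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a mapping")
            data.update(loaded)
    if overrides:
        data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(data):
        data[key] = tuple(data[key])
    cfg = RunConfig(**data)
    try:
        cfg.validate()
    except ValueError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    return cfg


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
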