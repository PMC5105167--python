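"""Run configuration: a YAML description of one analysis run.

A config file names the inputs, the projection parameters, the bin-width
policy and the seeds of every stochastic step, so a run is fully
reproducible from the file alone. Referenced paths are checked at load
time, and any section that draws random numbers must carry an explicit
seed — there is no silent default seeding.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .projection import ChargeEnvelope, ResolutionModel
from .synthetic import NoiseModel

__all__ = ["RunConfig", "ConfigError", "noise_to_yaml", "noise_from_yaml"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


_BIN_WIDTH_MODES = ("fixed", "optimal", "scan")


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of one construction/scoring run."""

    site_table: Path | None = None
    spectra: tuple[Path, ...] = ()
    envelope: ChargeEnvelope | None = None
    resolution: ResolutionModel = field(default_factory=ResolutionModel)
    bin_width_mode: str = "optimal"
    bin_width: float | None = None
    merge_tol: float = 0.01
    prune_threshold: float = 1e-8
    assign_tolerance_ppm: float = 50.0
    noise: NoiseModel | None = None
    seed: int | None = None
    outdir: Path | None = None

    def __post_init__(self):
        if self.bin_width_mode not in _BIN_WIDTH_MODES:
            raise ConfigError(
                f"bin_width_mode must be one of {_BIN_WIDTH_MODES}, got {self.bin_width_mode!r}"
            )
        if self.bin_width_mode == "fixed" and not self.bin_width:
            raise ConfigError("bin_width_mode 'fixed' requires a bin_width value")
        for p in ((self.site_table,) if self.site_table else ()) + tuple(self.spectra):
            if not Path(p).exists():
                raise ConfigError(f"referenced path does not exist: {p}")
        if self.noise is not None and self.seed is None:
            raise ConfigError("a noise section requires an explicit seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        kwargs: dict = {}
        if "site_table" in raw:
            kwargs["site_table"] = Path(raw.pop("site_table"))
        if "spectra" in raw:
            kwargs["spectra"] = tuple(Path(p) for p in raw.pop("spectra"))
        if "envelope" in raw:
            env = raw.pop("envelope")
            states = tuple((int(z), float(a)) for z, a in sorted(env.items()))
            kwargs["envelope"] = ChargeEnvelope(states)
        if "resolution" in raw:
            kwargs["resolution"] = ResolutionModel(**raw.pop("resolution"))
        if "noise" in raw:
            noise = dict(raw.pop("noise"))
            if "seed" not in noise:
                raise ConfigError("noise section must carry its own seed")
            kwargs["noise"] = NoiseModel(**noise)
        if "outdir" in raw:
            kwargs["outdir"] = Path(raw.pop("outdir"))
        known = {
            "bin_width_mode", "bin_width", "merge_tol", "prune_threshold",
            "assign_tolerance_ppm", "seed",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)


def noise_to_yaml(noise: NoiseModel, path: str | Path) -> None:
    """Serialize a noise model so a simulation is reproducible from disk."""
    Path(path).write_text(yaml.safe_dump(asdict(noise), sort_keys=True))


def noise_from_yaml(path: str | Path) -> NoiseModel:
    data = yaml.safe_load(Path(path).read_text())
    return NoiseModel(**data)
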