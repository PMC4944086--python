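"""Flat key-value run configuration.

One dialect, no nesting: ``key = value`` lines, ``#`` comments.  The
defaults reproduce the reference conditions (dt = 2 fs,
T0 = 298.0 K, tau_T = 0.1 ps, pore radius 30 Å, 1045 waters,
concentrations 0.6 / 1.3 / 2.0 M).  Parsing and serialization round-trip
losslessly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

from .builder import BuildSpec
from .sampler import RunSpec
from .system import PoreGeometry

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Malformed configuration file (message carries the line number)."""


@dataclass
class RunConfig:
    # build
    concentration: float = 0.6
    n_water: int = 1045
    n_wall_charges: int = 8
    r_n: float = 30.0
    l_z: float = 14.0
    # sampling
    mode: str = "mc_primitive"
    dt_fs: float = 2.0
    t0_k: float = 298.0
    tau_t_ps: float = 0.1
    n_equil_steps: int = 20000
    n_prod_steps: int = 100000
    sample_interval: int = 500
    mc_step: float = 2.0
    coulomb: str = "cutoff_rf"
    r_cut: float = 0.0  # 0 -> automatic
    # analysis
    bin_width: float = 0.25
    # shared
    seed: int = 0

    def validate(self) -> None:
        if self.concentration < 0:
            raise ConfigError("concentration must be non-negative")
        if self.n_water < 0 or self.n_wall_charges < 0:
            raise ConfigError("counts must be non-negative")
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if self.mode not in ("md_explicit", "mc_primitive"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    # ---- spec construction ---------------------------------------------
    def geometry(self) -> PoreGeometry:
        return PoreGeometry(r_n=self.r_n, l_z=self.l_z)

    def build_spec(self) -> BuildSpec:
        return BuildSpec(
            concentration=self.concentration,
            n_water=self.n_water,
            explicit_water=self.mode == "md_explicit",
            n_wall_charges=self.n_wall_charges,
            rng_seed=self.seed,
            geometry=self.geometry(),
            temperature=self.t0_k,
        )

    def run_spec(self) -> RunSpec:
        return RunSpec(
            dt=self.dt_fs,
            t0=self.t0_k,
            tau_t=self.tau_t_ps,
            n_equil_steps=self.n_equil_steps,
            n_prod_steps=self.n_prod_steps,
            sample_interval=self.sample_interval,
            mode=self.mode,
            rng_seed=self.seed,
            coulomb=self.coulomb,
            r_cut=self.r_cut or None,
            mc_step=self.mc_step,
        )

    # ---- (de)serialization ----------------------------------------------
    def serialize(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}" if isinstance(getattr(self, f.name), str) else f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    def to_file(self, path: str | Path) -> None:
        from .io import atomic_write_text

        atomic_write_text(path, self.serialize())

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text(), source=str(path))

    @classmethod
    def from_text(cls, text: str, source: str = "<config>") -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        typed = {f.name: type(getattr(cls(), f.name)) for f in fields(cls)}
        values = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{source}:{lineno}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"{source}:{lineno}: unknown key {key!r}")
            t = typed[key]
            try:
                if t is int:
                    values[key] = int(val)
                elif t is float:
                    values[key] = float(val)
                else:
                    values[key] = val.strip("'\"")
            except ValueError as exc:
                raise ConfigError(f"{source}:{lineno}: bad value for {key}: {val!r}") from exc
        cfg = cls(**values)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Short hash of the canonical serialization (for run headers)."""
        return hashlib.sha256(self.serialize().encode()).hexdigest()[:12]
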