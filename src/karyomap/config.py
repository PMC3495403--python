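"""Flat key=value pipeline configuration with range validation."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Unknown key, unparsable value or out-of-range parameter."""


@dataclass
class PipelineConfig:
    # simulation
    seed: int = 1
    n_chromosomes: int = 6
    markers_per_chromosome: int = 20
    female_length_cM: float = 80.0
    male_length_cM: float = 20.0
    n_families: int = 40
    offspring_per_family: int = 30
    half_sib_fraction: float = 0.0
    missing_rate: float = 0.0
    shared_fraction: float = 0.9
    maf_min: float = 0.1
    maf_max: float = 0.5
    telomere_window: float = 0.1
    telomere_mass: float = 0.9
    # mapping
    lod_threshold: float = 5.0
    mapping_function: str = "kosambi"
    em_tol: float = 1e-6
    em_max_iter: int = 200
    bin_theta: float = 1e-4
    # comparison
    min_shared: int = 3
    max_interlopers: int = 2
    terminal_fraction: float = 0.1
    junction_window: float = 0.1
    junction_male_share: float = 0.05
    junction_cold_factor: float = 0.5

    def __post_init__(self) -> None:
        checks = [
            (self.n_chromosomes >= 1, "n_chromosomes >= 1"),
            (self.markers_per_chromosome >= 2, "markers_per_chromosome >= 2"),
            (self.female_length_cM > 0, "female_length_cM > 0"),
            (self.male_length_cM >= 0, "male_length_cM >= 0"),
            (self.n_families >= 1, "n_families >= 1"),
            (self.offspring_per_family >= 1, "offspring_per_family >= 1"),
            (0 <= self.half_sib_fraction <= 1, "half_sib_fraction in [0, 1]"),
            (0 <= self.missing_rate <= 1, "missing_rate in [0, 1]"),
            (0 <= self.shared_fraction <= 1, "shared_fraction in [0, 1]"),
            (0 < self.maf_min <= self.maf_max <= 0.5, "0 < maf_min <= maf_max <= 0.5"),
            (0 < self.telomere_window < 0.5, "telomere_window in (0, 0.5)"),
            (0.5 <= self.telomere_mass <= 1, "telomere_mass in [0.5, 1]"),
            (self.lod_threshold > 0, "lod_threshold > 0"),
            (self.mapping_function in ("haldane", "kosambi"), "mapping_function in {haldane, kosambi}"),
            (self.em_tol > 0, "em_tol > 0"),
            (self.em_max_iter >= 1, "em_max_iter >= 1"),
            (0 <= self.bin_theta < 0.5, "bin_theta in [0, 0.5)"),
            (self.min_shared >= 1, "min_shared >= 1"),
            (self.max_interlopers >= 0, "max_interlopers >= 0"),
            (0 < self.terminal_fraction < 0.5, "terminal_fraction in (0, 0.5)"),
            (0 < self.junction_window < 0.5, "junction_window in (0, 0.5)"),
            (0 < self.junction_male_share < 1, "junction_male_share in (0, 1)"),
            (0 < self.junction_cold_factor < 1, "junction_cold_factor in (0, 1)"),
        ]
        for ok, rule in checks:
            if not ok:
                raise ConfigError(f"config violates: {rule}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
            typ = known[key]
            try:
                if typ in ("int", int):
                    kwargs[key] = int(value)
                elif typ in ("float", float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: {exc}") from exc
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def digest(self) -> str:
        payload = ";".join(f"{f.name}={getattr(self, f.name)!r}" for f in fields(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
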