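"""Run configuration and synthetic-fixture generators.

A :class:`RunConfig` collects every tunable of the pipeline in one
validated document.  Keys carry explicit units in their names
(``step_size_nm``, ``time_step_ms``, ...); unknown keys are rejected with
their location so a typo cannot silently fall back to a default.

:func:`make_synthetic_measured_trace` stands in for an external in vitro
fiber force-vs-strain measurement: it evaluates the deterministic WLC
network force of a partially unfolded molecule (or any chain model you
supply), scales it to fiber units through the concentration bridge, and
optionally adds multiplicative noise.  Round-tripping such a trace
through the force-estimation and z0-scan operations recovers the injected
molecular curve, which is how those operations are validated in the
absence of the original instrument data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass

import numpy as np
import pandas as pd
import yaml

from .fiber_simulator import FiberTopology, StretchProtocol, equilibrate
from .scaling_bridge import FiberScaleSpec, load_bearing_strands
from .unfolding_kinetics import (
    DomainTable,
    apply_unfolding,
    default_domain_table,
    new_molecule,
)

__all__ = [
    "ConfigError",
    "ThermalConfig",
    "WLCConfig",
    "ProtocolConfig",
    "ScalingConfig",
    "DensitometryConfig",
    "RunConfig",
    "generate_default_config",
    "config_from_dict",
    "load_config",
    "save_config",
    "make_partially_unfolded_molecule",
    "make_synthetic_measured_trace",
]


class ConfigError(ValueError):
    """A configuration document failed validation (exit code 2 in the CLI)."""


@dataclass
class ThermalConfig:
    temperature_K: float = 298.0
    boltzmann_pN_nm_per_K: float = 0.0138065


@dataclass
class WLCConfig:
    contour_length_nm: float = 120.0
    persistence_length_nm: float = 14.0
    unfolded_segment_nm: float = 32.0
    unfolded_persistence_nm: float = 0.42
    fold_contour_loss_nm: float = 3.5


@dataclass
class ProtocolConfig:
    architecture: str = "equal"
    n_units: int = 20
    preset_unfolded: int = 4
    step_size_nm: float = 0.67
    time_step_ms: float = 0.73
    z0_nm: float = 108.0
    max_strain: float = 4.73
    seed: int = 0


@dataclass
class ScalingConfig:
    concentration_mg_ml: float = 177.0
    diameter0_um: float = 3.0
    molecular_mass_g_mol: float = 5.0e5


@dataclass
class DensitometryConfig:
    wavelength_nm: int = 280
    pixel_size_um: float = 0.06
    core_fraction: float = 0.5
    path_floor_frac: float = 0.1
    molecular_mass_g_mol: float = 5.0e5


@dataclass
class RunConfig:
    """All pipeline parameters in one round-trippable document."""

    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    wlc: WLCConfig = field(default_factory=WLCConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    densitometry: DensitometryConfig = field(default_factory=DensitometryConfig)
    domain_table: str | None = None  # path; None = packaged defaults

    @property
    def extension_rate_um_s(self) -> float:
        return self.protocol.step_size_nm / self.protocol.time_step_ms

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stretch_protocol(self) -> StretchProtocol:
        p = self.protocol
        return StretchProtocol(
            step_size_nm=p.step_size_nm,
            time_step_s=p.time_step_ms * 1e-3,
            z0_nm=p.z0_nm,
            max_strain=p.max_strain,
            seed=p.seed,
        )

    def topology(self) -> FiberTopology:
        return FiberTopology(self.protocol.architecture, self.protocol.n_units)

    def scale_spec(self) -> FiberScaleSpec:
        s = self.scaling
        return FiberScaleSpec(
            concentration_mg_ml=s.concentration_mg_ml,
            diameter0_um=s.diameter0_um,
            molecular_mass=s.molecular_mass_g_mol,
            z0_nm=self.protocol.z0_nm,
            architecture=self.protocol.architecture,
        )


_POSITIVE = {
    "temperature_K", "boltzmann_pN_nm_per_K", "contour_length_nm",
    "persistence_length_nm", "unfolded_segment_nm", "unfolded_persistence_nm",
    "fold_contour_loss_nm", "step_size_nm", "time_step_ms", "z0_nm",
    "max_strain", "concentration_mg_ml", "diameter0_um",
    "molecular_mass_g_mol", "pixel_size_um", "core_fraction",
}


def _build(cls, data, path):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    spec = {f.name: f for f in fields(cls)}
    for key in data:
        if key not in spec:
            raise ConfigError(f"{path}: unknown key '{key}'")
    kwargs = {}
    for name, f in spec.items():
        if name not in data:
            continue
        value = data[name]
        if is_dataclass(f.type) or (isinstance(f.type, type) and is_dataclass(f.type)):
            kwargs[name] = _build(f.type, value, f"{path}.{name}")
            continue
        # leaf: coerce numbers, reject non-numeric strings for numeric fields
        default = getattr(cls(), name) if not isinstance(value, (dict, list)) else None
        if isinstance(default, bool):
            pass
        elif isinstance(default, int) and not isinstance(value, bool):
            try:
                value = int(value)
            except (TypeError, ValueError):
                raise ConfigError(
                    f"{path}.{name}: expected an integer, got {value!r}"
                ) from None
        elif isinstance(default, float):
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ConfigError(
                    f"{path}.{name}: expected a number, got {value!r}"
                ) from None
        if name in _POSITIVE and not value > 0:
            raise ConfigError(f"{path}.{name}: must be > 0, got {value}")
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from None


_NESTED = {
    "thermal": ThermalConfig,
    "wlc": WLCConfig,
    "protocol": ProtocolConfig,
    "scaling": ScalingConfig,
    "densitometry": DensitometryConfig,
}


def config_from_dict(data: dict) -> RunConfig:
    """Strictly validated RunConfig from a plain mapping."""
    if not isinstance(data, dict):
        raise ConfigError("config: expected a mapping at the top level")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED:
            kwargs[key] = _build(_NESTED[key], value, key)
        elif key == "domain_table":
            kwargs[key] = None if value is None else str(value)
        else:
            raise ConfigError(f"config: unknown key '{key}'")
    cfg = RunConfig(**kwargs)
    if cfg.protocol.architecture not in ("equal", "disparate"):
        raise ConfigError(
            f"protocol.architecture: must be 'equal' or 'disparate', "
            f"got {cfg.protocol.architecture!r}"
        )
    return cfg


def generate_default_config() -> RunConfig:
    """The baseline parameter set (round-trips losslessly through YAML)."""
    return RunConfig()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# synthetic measured trace
# ---------------------------------------------------------------------------


def make_partially_unfolded_molecule(n_unfolded: int, table: DomainTable | None = None):
    """A dimer with its first ``n_unfolded`` domains deterministically unfolded."""
    mol = new_molecule(table if table is not None else default_domain_table())
    for i in range(n_unfolded):
        apply_unfolding(mol, i)
    return mol


def make_synthetic_measured_trace(
    spec: FiberScaleSpec,
    n_unfolded: int = 20,
    strain_max: float = 4.73,
    n_points: int = 400,
    noise: float = 0.0,
    seed: int | None = None,
    table: DomainTable | None = None,
) -> pd.DataFrame:
    """Deterministic WLC fiber trace standing in for an in vitro measurement.

    Molecules carry a fixed number of unfolded domains (no kinetics), so
    the strand force at span z0*(1+strain) is a closed deterministic
    curve; it is scaled to fiber units by the strand count of ``spec``.
    ``noise`` adds seeded multiplicative Gaussian scatter.  Columns:
    ``strain``, ``force_uN``.
    """
    if n_unfolded * 28.5 + 120.0 <= spec.z0_nm * (1.0 + strain_max):
        raise ValueError(
            "n_unfolded leaves too little contour for the requested strain range"
        )
    topo = FiberTopology(spec.architecture, n_units=1)
    molecules = [
        make_partially_unfolded_molecule(n_unfolded, table)
        for _ in range(topo.n_molecules)
    ]
    strains = np.linspace(0.0, strain_max, n_points)
    n_strands = load_bearing_strands(spec)
    force_pN = np.empty_like(strains)
    eq = None
    for i, eps in enumerate(strains):
        eq = equilibrate(topo, molecules, spec.z0_nm * (1.0 + eps), _warm=eq)
        force_pN[i] = eq.strand_tension
    force_uN = force_pN * n_strands * 1e-6
    if noise > 0:
        rng = np.random.default_rng(seed)
        force_uN = np.clip(
            force_uN * (1.0 + noise * rng.standard_normal(force_uN.shape)),
            0.0, None,
        )
    return pd.DataFrame({"strain": strains, "force_uN": force_uN})
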