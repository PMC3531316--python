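"""Molecular-to-fiber scaling: counts, stress, packing, force estimation.

The densitometry concentration ``c`` fixes the number of molecules in the
cross-section of a fiber of diameter ``d0``: each load-bearing strand
occupies an axial repeat of one molecular end-to-end length ``z0``
(108 nm = 90% of the folded contour at 0% strain), so

    N_cs = (c * N_A / MW) * (pi d0^2 / 4) * z0 .

Equal-loading fibers contain ``N_cs`` independent single-molecule
strands; disparate-loading fibers contain ``N_cs / 3`` three-molecule
units.  Simulated strand tensions scale to fiber forces by the strand
count, and to stresses through the constant-volume cross-section
``A(eps) = A0 / (1 + eps)`` (supported by measured diameter reductions
during stretch).  The same bridge runs backwards: a measured fiber
force-vs-strain trace divided by the strand count estimates the force per
molecule, and scanning the assumed ``z0`` against the simulated
molecular force curve locates the end-to-end length at which experiment
and model agree.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiber_simulator import SimulationTrace

__all__ = [
    "AVOGADRO",
    "FiberScaleSpec",
    "ScaledTrace",
    "molecules_in_cross_section",
    "load_bearing_strands",
    "cross_section_area_um2",
    "diameter_at_strain",
    "scale_trace_to_fiber",
    "area_per_molecule",
    "solute_fraction",
    "estimate_molecular_forces",
    "z0_match_scan",
]

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class FiberScaleSpec:
    """Inputs of the molecular-to-fiber bridge."""

    concentration_mg_ml: float = 177.0
    diameter0_um: float = 3.0
    molecular_mass: float = 5.0e5  # g/mol
    z0_nm: float = 108.0  # end-to-end length per molecule at 0% strain
    architecture: str = "equal"

    def __post_init__(self) -> None:
        for name in ("concentration_mg_ml", "diameter0_um", "molecular_mass",
                     "z0_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.z0_nm < 120.0:
            raise ValueError("z0_nm must be below the 120 nm folded contour")
        if self.architecture not in ("equal", "disparate"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class ScaledTrace:
    """A simulation trace expressed in fiber units."""

    strain: np.ndarray
    fiber_force_uN: np.ndarray
    fiber_stress_MPa: np.ndarray
    diameter_um: np.ndarray
    molecule_tensions_pN: np.ndarray
    spec: FiberScaleSpec

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "strain": self.strain,
            "fiber_force_uN": self.fiber_force_uN,
            "fiber_stress_MPa": self.fiber_stress_MPa,
            "diameter_um": self.diameter_um,
        })


def molecules_in_cross_section(spec: FiberScaleSpec) -> float:
    """Number of molecules in the fiber cross-section at 0% strain."""
    per_um3 = spec.concentration_mg_ml / spec.molecular_mass * AVOGADRO * 1e-15
    volume_um3 = np.pi / 4.0 * spec.diameter0_um**2 * spec.z0_nm * 1e-3
    return per_um3 * volume_um3


def load_bearing_strands(spec: FiberScaleSpec) -> float:
    """Strand count: N_cs for equal loading, N_cs/3 for disparate units."""
    n = molecules_in_cross_section(spec)
    return n if spec.architecture == "equal" else n / 3.0


def cross_section_area_um2(spec: FiberScaleSpec, strain: float = 0.0):
    """Constant-volume cross-section A(eps) = A0 / (1 + eps), um^2."""
    a0 = np.pi / 4.0 * spec.diameter0_um**2
    return a0 / (1.0 + np.asarray(strain, dtype=float))


def diameter_at_strain(spec: FiberScaleSpec, strain: float = 0.0):
    """Constant-volume diameter d(eps) = d0 / sqrt(1 + eps), um."""
    return spec.diameter0_um / np.sqrt(1.0 + np.asarray(strain, dtype=float))


def scale_trace_to_fiber(trace: SimulationTrace, spec: FiberScaleSpec) -> ScaledTrace:
    """Express a simulated strand/unit tension trace in fiber units.

    Fiber force = strand tension x strand count; stress divides by the
    constant-volume cross-section; simulated strand strain maps 1:1 onto
    fiber strain.
    """
    if trace.architecture != spec.architecture:
        raise ValueError(
            f"trace architecture {trace.architecture!r} does not match "
            f"spec architecture {spec.architecture!r}"
        )
    n_strands = load_bearing_strands(spec)
    force_pN = trace.strand_tension_pN * n_strands
    area = cross_section_area_um2(spec, trace.strain)
    return ScaledTrace(
        strain=trace.strain,
        fiber_force_uN=force_pN * 1e-6,
        fiber_stress_MPa=force_pN / area * 1e-6,  # pN/um^2 = Pa
        diameter_um=diameter_at_strain(spec, trace.strain),
        molecule_tensions_pN=trace.molecule_tensions_pN,
        spec=spec,
    )


def area_per_molecule(spec: FiberScaleSpec, strain: float = 0.0) -> float:
    """Cross-sectional area claimed by one molecule, nm^2."""
    area_nm2 = float(cross_section_area_um2(spec, strain)) * 1e6
    return area_nm2 / molecules_in_cross_section(spec)


def solute_fraction(area_per_mol_nm2: float, occupied_area_nm2: float) -> float:
    """Fraction of the cross-section that is solute, 1 - occupied/available."""
    if not 0 < occupied_area_nm2 < area_per_mol_nm2:
        raise ValueError(
            f"occupied area {occupied_area_nm2} nm^2 must lie in "
            f"(0, {area_per_mol_nm2} nm^2)"
        )
    return 1.0 - occupied_area_nm2 / area_per_mol_nm2


def _mean_pair_ratio(trace: SimulationTrace) -> tuple[np.ndarray, np.ndarray]:
    """Per-step mean single:pair tension ratio of a disparate trace."""
    single = trace.molecule_tensions_pN[:, 0::3]
    pair = trace.molecule_tensions_pN[:, 1::3]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pair > 0, single / pair, np.nan)
    return trace.strain, np.nanmean(ratio, axis=1)


def estimate_molecular_forces(
    measured: pd.DataFrame,
    spec: FiberScaleSpec,
    sim_trace: SimulationTrace | None = None,
) -> pd.DataFrame:
    """Per-molecule forces implied by a measured fiber force-vs-strain trace.

    ``measured`` needs columns ``strain`` and ``force_uN``.  Equal
    loading: every molecule carries F_fiber / N_cs.  Disparate loading:
    the unit force F_fiber / (N_cs/3) is split into single- and pair-side
    tensions preserving the single:pair ratio of a companion disparate
    simulation at the matching strain.
    """
    strain = measured["strain"].to_numpy(dtype=float)
    force_pN = measured["force_uN"].to_numpy(dtype=float) * 1e6
    n = molecules_in_cross_section(spec)
    if spec.architecture == "equal":
        return pd.DataFrame({
            "strain": strain,
            "f_molecule_pN": force_pN / n,
        })
    if sim_trace is None:
        raise ValueError(
            "disparate-loading estimation needs a companion disparate "
            "simulation trace for the single:pair force ratio"
        )
    if sim_trace.architecture != "disparate":
        raise ValueError("companion trace must use the disparate architecture")
    sim_strain, sim_ratio = _mean_pair_ratio(sim_trace)
    valid = np.isfinite(sim_ratio)
    ratio = np.interp(strain, sim_strain[valid], sim_ratio[valid])
    unit_force = force_pN / (n / 3.0)
    f_pair = unit_force / (1.0 + ratio)
    f_single = unit_force - f_pair
    return pd.DataFrame({
        "strain": strain,
        "f_single_pN": f_single,
        "f_pair_pN": f_pair,
    })


def _sim_molecular_force_of_span(trace: SimulationTrace):
    """Interpolator: average molecular force (pN) vs molecular span (nm).

    Equal: the strand tension at per-molecule span z0*(1+eps).  Disparate:
    one third of the unit tension at per-unit span z0*(1+eps).
    """
    span = trace.z0_nm * (1.0 + trace.strain)
    force = trace.strand_tension_pN.astype(float)
    if trace.architecture == "disparate":
        force = force / 3.0

    def interp(z):
        z = np.asarray(z, dtype=float)
        out = np.interp(z, span, force, left=np.nan, right=np.nan)
        return out

    return interp, (float(span[0]), float(span[-1]))


def z0_match_scan(
    measured: pd.DataFrame,
    sim_trace: SimulationTrace,
    spec: FiberScaleSpec,
    z0_grid_nm: np.ndarray | None = None,
    ref_strain: float = 3.0,
) -> tuple[pd.DataFrame, float | None]:
    """Scan the assumed initial end-to-end length z0 and locate the match.

    For each z0: the experiment-scaled average molecular force at the
    reference strain is F_fiber(ref) / N_cs(z0) (decreasing in z0, since
    N_cs is proportional to z0), while the simulated molecular force is
    evaluated at the remapped span z0*(1+ref_strain) (non-decreasing in
    z0).  Returns the per-z0 table and the crossing z0 by linear
    interpolation (None if the grid brackets no crossing).
    """
    if z0_grid_nm is None:
        z0_grid_nm = np.arange(30.0, 119.0, 2.0)
    z0_grid_nm = np.asarray(z0_grid_nm, dtype=float)
    if np.any(z0_grid_nm <= 0) or np.any(z0_grid_nm >= 120.0):
        raise ValueError("z0 grid must lie inside (0, 120) nm")

    m_strain = measured["strain"].to_numpy(dtype=float)
    m_force = measured["force_uN"].to_numpy(dtype=float) * 1e6  # pN
    if not (m_strain.min() <= ref_strain <= m_strain.max()):
        raise ValueError("measured trace does not cover the reference strain")
    fiber_force = float(np.interp(ref_strain, m_strain, m_force))

    f_sim_of_span, _ = _sim_molecular_force_of_span(sim_trace)

    exp_force = np.empty_like(z0_grid_nm)
    sim_force = np.empty_like(z0_grid_nm)
    for i, z0 in enumerate(z0_grid_nm):
        n = molecules_in_cross_section(dataclasses.replace(spec, z0_nm=z0))
        exp_force[i] = fiber_force / n
        sim_force[i] = f_sim_of_span(z0 * (1.0 + ref_strain))

    table = pd.DataFrame({
        "z0_nm": z0_grid_nm,
        "experiment_scaled_force_pN": exp_force,
        "simulated_force_pN": sim_force,
    })
    diff = exp_force - sim_force
    crossing: float | None = None
    ok = np.isfinite(diff)
    idx = np.nonzero(ok[:-1] & ok[1:] & (np.sign(diff[:-1]) != np.sign(diff[1:])))[0]
    if idx.size:
        i = int(idx[0])
        d0, d1 = diff[i], diff[i + 1]
        t = d0 / (d0 - d1)
        crossing = float(z0_grid_nm[i] + t * (z0_grid_nm[i + 1] - z0_grid_nm[i]))
    return table, crossing
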