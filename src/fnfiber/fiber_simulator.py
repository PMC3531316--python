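"""Nanofibril assembly and the constant-extension-rate stretch protocol.

Two architectures are simulated:

* ``equal`` — ``n_units`` dimers joined end to end in one strand, so every
  molecule carries the same tension at every instant.
* ``disparate`` — ``n_units`` repeating units in series, each unit one
  molecule in parallel with two molecules in series (3 molecules/unit).
  The short single-molecule side carries most of the load at a given unit
  span, producing two distinct molecular force populations.

Protocol: the fiber starts at ``n_units * z0`` (z0 = 108 nm, 90% of the
folded contour) and the boundary separation grows in 0.67 nm increments,
one Monte-Carlo time step of 0.73 ms each, i.e. an extension rate of
~0.92 um/s.  Each step: equilibrate the network, poll every folded domain
at its molecule's tension, apply all unfolding events simultaneously,
record.

Equilibration exploits that series/parallel WLC networks have strictly
monotone extension-vs-tension maps: force balance reduces to nested 1-D
root finding (equal: one tension for the whole strand; disparate: a unit
tension plus a per-unit split between the two sides), which is equivalent
to minimizing the network strain energy over node positions but exact and
fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .polymer_core import (
    DEFAULT_CONTEXT,
    ThermalContext,
    _frac_extension_with_slope,
)
from .unfolding_kinetics import (
    DomainTable,
    MoleculeState,
    UNFOLDED_PERSISTENCE_NM,
    apply_unfolding,
    default_domain_table,
    init_unfolded,
    new_molecule,
)

__all__ = [
    "ARCHITECTURES",
    "TautFiberError",
    "FiberTopology",
    "StretchProtocol",
    "EquilibriumState",
    "SimulationTrace",
    "equilibrate",
    "run_stretch",
    "disparate_force_ratio",
]

logger = logging.getLogger(__name__)

ARCHITECTURES = ("equal", "disparate")

# Convergence targets for the equilibrium solvers.  _Z_RTOL is on the
# extension mismatch; mapped through the chain stiffness it leaves node
# force residuals far below the 1e-6 pN contract.
_Z_RTOL = 1e-13
_MAX_NEWTON = 80


class TautFiberError(RuntimeError):
    """The demanded fiber extension exceeds the available contour length."""


@dataclass(frozen=True)
class FiberTopology:
    """Architecture and unit count (equal: n molecules; disparate: 3n)."""

    architecture: str = "equal"
    n_units: int = 20

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"architecture must be one of {ARCHITECTURES}, got "
                f"{self.architecture!r}"
            )
        if self.n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {self.n_units}")

    @property
    def n_molecules(self) -> int:
        return self.n_units * (1 if self.architecture == "equal" else 3)


@dataclass(frozen=True)
class StretchProtocol:
    """Constant-extension-rate schedule and RNG seed.

    Defaults reproduce the baseline protocol: 0.67 nm increments, 0.73 ms
    per step (0.92 um/s), initial span 108 nm per unit (2.16 um for 20
    units), stretch to 473% strain.
    """

    step_size_nm: float = 0.67
    time_step_s: float = 0.73e-3
    z0_nm: float = 108.0
    max_strain: float = 4.73
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("step_size_nm", "time_step_s", "z0_nm", "max_strain"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def extension_rate_um_s(self) -> float:
        return self.step_size_nm / self.time_step_s * 1e-3

    def initial_length_nm(self, topology: FiberTopology) -> float:
        return topology.n_units * self.z0_nm

    def n_steps(self, topology: FiberTopology) -> int:
        return int(
            np.floor(self.max_strain * self.initial_length_nm(topology)
                     / self.step_size_nm + 1e-9)
        )


@dataclass
class EquilibriumState:
    """Force-balanced configuration at one boundary separation."""

    strand_tension: float  # pN; unit tension F for the disparate architecture
    molecule_tensions: np.ndarray  # pN, one per molecule
    unit_spans: np.ndarray  # nm, node-to-node span per unit
    residual_pN: float  # worst node force imbalance

    # warm-start bookkeeping (disparate): tension on the single-molecule side
    single_tensions: np.ndarray | None = None


@dataclass
class SimulationTrace:
    """Per-step record of a stretch run."""

    architecture: str
    n_units: int
    z0_nm: float
    seed: int
    time_s: np.ndarray
    strain: np.ndarray
    strand_tension_pN: np.ndarray
    n_unfolded: np.ndarray
    molecule_tensions_pN: np.ndarray  # (n_steps, n_molecules)
    max_residual_pN: float = 0.0
    preset_unfolded: object = 0

    def to_dataframe(self, include_molecules: bool = True) -> pd.DataFrame:
        cols = {
            "time_s": self.time_s,
            "strain": self.strain,
            "strand_tension_pN": self.strand_tension_pN,
            "n_unfolded": self.n_unfolded,
        }
        df = pd.DataFrame(cols)
        if include_molecules:
            n_mol = self.molecule_tensions_pN.shape[1]
            for i in range(n_mol):
                df[f"mol_{i:03d}_pN"] = self.molecule_tensions_pN[:, i]
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, architecture: str, n_units: int,
        z0_nm: float = 108.0, seed: int = -1,
    ) -> "SimulationTrace":
        mol_cols = [c for c in df.columns if c.startswith("mol_")]
        mt = df[mol_cols].to_numpy() if mol_cols else np.empty((len(df), 0))
        return cls(
            architecture=architecture,
            n_units=n_units,
            z0_nm=z0_nm,
            seed=seed,
            time_s=df["time_s"].to_numpy(),
            strain=df["strain"].to_numpy(),
            strand_tension_pN=df["strand_tension_pN"].to_numpy(),
            n_unfolded=df["n_unfolded"].to_numpy(),
            molecule_tensions_pN=mt,
        )


# ---------------------------------------------------------------------------
# chain extension in aggregate form
#
# All folded backbones share one persistence length and all unfolded strands
# another, so the extension of any collection of segments at common tension
# needs only two fractional-extension evaluations:
#     z(f) = S_b * x(f*A_b/kT) + S_u * x(f*A_u/kT)
# with S_b, S_u the summed contour lengths.
# ---------------------------------------------------------------------------


def _collection_sums(molecules: Sequence[MoleculeState]):
    sb = sum(m.backbone.contour_length for m in molecules)
    su = sum(
        s.contour_length for m in molecules for s in m.unfolded_segments
    )
    ab = molecules[0].backbone.persistence_length
    return sb, su, ab


def _agg_extension(f, sb, su, ab, au, kt):
    """Extension and df-slope of a segment collection at common tension f."""
    xb, db = _frac_extension_with_slope(f * ab / kt)
    if np.any(np.asarray(su) > 0):
        xu, du = _frac_extension_with_slope(f * au / kt)
    else:
        xu, du = 0.0, 0.0
    z = sb * xb + su * xu
    dz = sb * db * ab / kt + su * du * au / kt
    return z, dz


def _solve_common_tension(target, sb, su, ab, au, kt, f_guess=1.0):
    """Tension at which the aggregate extension equals ``target`` (scalar)."""
    if target <= 0.0:
        return 0.0
    zmax = sb + su
    if target >= zmax * (1.0 - 1e-9):
        raise TautFiberError(
            f"extension {target:.3f} nm >= available contour {zmax:.3f} nm"
        )
    lo, hi = 0.0, max(f_guess, 1.0)
    z, _ = _agg_extension(hi, sb, su, ab, au, kt)
    while z < target:
        lo = hi
        hi *= 4.0
        z, _ = _agg_extension(hi, sb, su, ab, au, kt)
    f = min(max(f_guess, lo * 1.000001 + 1e-12), hi)
    for _ in range(_MAX_NEWTON):
        z, dz = _agg_extension(f, sb, su, ab, au, kt)
        err = z - target
        if abs(err) <= _Z_RTOL * target:
            break
        if err > 0:
            hi = f
        else:
            lo = f
        f_new = f - err / dz
        if not (lo < f_new < hi):
            f_new = 0.5 * (lo + hi)
        f = f_new
    return f


def _unit_arrays(molecules: Sequence[MoleculeState], n_units: int):
    """Contour sums per disparate unit: single side and pair side."""
    sb_s = np.empty(n_units)
    su_s = np.empty(n_units)
    sb_p = np.empty(n_units)
    su_p = np.empty(n_units)
    for u in range(n_units):
        single = molecules[3 * u]
        p1, p2 = molecules[3 * u + 1], molecules[3 * u + 2]
        sb_s[u] = single.backbone.contour_length
        su_s[u] = sum(s.contour_length for s in single.unfolded_segments)
        sb_p[u] = p1.backbone.contour_length + p2.backbone.contour_length
        su_p[u] = sum(
            s.contour_length
            for m in (p1, p2)
            for s in m.unfolded_segments
        )
    ab = molecules[0].backbone.persistence_length
    return sb_s, su_s, sb_p, su_p, ab


def _split_unit_tension(F, f1, sb_s, su_s, sb_p, su_p, ab, au, kt):
    """Solve per-unit single-side tension f1 so both sides share one span.

    Vectorized safeguarded Newton on h(f1) = z_single(f1) - z_pair(F - f1),
    which is strictly increasing with h(0) < 0 < h(F).
    Returns (f1, span, dspan_dF).
    """
    lo = np.zeros_like(f1)
    hi = np.full_like(f1, F)
    f1 = np.clip(f1, 1e-12 * F, F * (1.0 - 1e-12))
    zs = dzs = zp = dzp = None
    for _ in range(_MAX_NEWTON):
        zs, dzs = _agg_extension(f1, sb_s, su_s, ab, au, kt)
        zp, dzp = _agg_extension(F - f1, sb_p, su_p, ab, au, kt)
        h = zs - zp
        if np.all(np.abs(h) <= _Z_RTOL * np.maximum(zs, 1.0)):
            break
        gt = h > 0
        hi = np.where(gt, np.minimum(hi, f1), hi)
        lo = np.where(gt, lo, np.maximum(lo, f1))
        f1n = f1 - h / (dzs + dzp)
        bad = (f1n <= lo) | (f1n >= hi)
        f1 = np.where(bad, 0.5 * (lo + hi), f1n)
    # series compliance of the two sides in parallel at the shared node
    dspan_dF = dzs * dzp / (dzs + dzp)
    return f1, zs, dspan_dF


def _two_sided_extensions(f1, F, sb_s, su_s, sb_p, su_p, ab, au, kt):
    """(z, dz/df) for both unit sides with two fractional-extension calls."""
    f_all = np.concatenate([f1, F - f1])
    xb, db = _frac_extension_with_slope(f_all * (ab / kt))
    xu, du = _frac_extension_with_slope(f_all * (au / kt))
    n = f1.shape[0]
    sb = np.concatenate([sb_s, sb_p])
    su = np.concatenate([su_s, su_p])
    z = sb * xb + su * xu
    dz = (sb * db * ab + su * du * au) / kt
    return z[:n], dz[:n], z[n:], dz[n:]


def _solve_disparate(target, arrays, au, kt, F_guess=1.0, f1_guess=None):
    """Unit tension F at which the summed unit spans equal ``target``.

    Joint Newton on (f1_1..f1_n, F): per-unit residual h_u = z_s - z_p
    (span compatibility of the parallel sides) and a boundary residual
    g = sum(z_s) - target, with the analytically eliminated Jacobian.
    Falls back to the nested bracketed solve when not warm-started or
    when Newton stalls.
    """
    sb_s, su_s, sb_p, su_p, ab = arrays
    n_units = sb_s.shape[0]
    if target <= 0.0:
        z0 = np.zeros(n_units)
        return 0.0, z0, z0
    zmax = float(np.minimum(sb_s + su_s, sb_p + su_p).sum())
    if target >= zmax * (1.0 - 1e-9):
        raise TautFiberError(
            f"extension {target:.3f} nm >= available contour {zmax:.3f} nm"
        )

    if f1_guess is not None and F_guess > 0:
        F = float(F_guess)
        f1 = np.clip(f1_guess, 1e-12 * F, F * (1.0 - 1e-12))
        for _ in range(30):
            zs, dzs, zp, dzp = _two_sided_extensions(
                f1, F, sb_s, su_s, sb_p, su_p, ab, au, kt
            )
            h = zs - zp
            g = float(zs.sum()) - target
            if (abs(g) <= _Z_RTOL * target
                    and np.all(np.abs(h) <= _Z_RTOL * np.maximum(zs, 1.0))):
                return F, zs, f1
            w = dzs * dzp / (dzs + dzp)
            dF = (-g + float((dzs * h / (dzs + dzp)).sum())) / float(w.sum())
            df1 = (-h + dzp * dF) / (dzs + dzp)
            # damp to keep every tension positive and below F
            F_new = F + dF
            f1_new = f1 + df1
            if (F_new <= 0 or np.any(f1_new <= 0)
                    or np.any(f1_new >= F_new)):
                scale = 1.0
                while scale > 1e-4:
                    scale *= 0.5
                    F_try = F + scale * dF
                    f1_try = f1 + scale * df1
                    if (F_try > 0 and np.all(f1_try > 0)
                            and np.all(f1_try < F_try)):
                        F_new, f1_new = F_try, f1_try
                        break
                else:
                    break  # fall through to the robust solver
            F, f1 = F_new, f1_new
        else:
            pass  # not converged in 30 iterations -> robust solver

    def span_sum(F, f1_start):
        f1, spans, dspan = _split_unit_tension(
            F, f1_start, sb_s, su_s, sb_p, su_p, ab, au, kt
        )
        return f1, spans, float(spans.sum()), float(dspan.sum())

    lo, hi = 0.0, max(F_guess, 1.0)
    f1 = f1_guess if f1_guess is not None else np.full(n_units, 0.9 * hi)
    f1, spans, z, dz = span_sum(hi, np.clip(f1, 0, hi))
    while z < target:
        lo = hi
        hi *= 4.0
        f1, spans, z, dz = span_sum(hi, np.clip(f1 * 2.0, 0, hi))
    F = min(max(F_guess, lo * 1.000001 + 1e-12), hi)
    for _ in range(_MAX_NEWTON):
        f1, spans, z, dz = span_sum(F, np.clip(f1, 0, F))
        err = z - target
        if abs(err) <= _Z_RTOL * target:
            break
        if err > 0:
            hi = F
        else:
            lo = F
        F_new = F - err / dz
        if not (lo < F_new < hi):
            F_new = 0.5 * (lo + hi)
        F = F_new
    return F, spans, f1


def equilibrate(
    topology: FiberTopology,
    molecules: Sequence[MoleculeState],
    total_extension: float,
    ctx: ThermalContext = DEFAULT_CONTEXT,
    *,
    _warm: EquilibriumState | None = None,
) -> EquilibriumState:
    """Force-balanced network configuration at one boundary separation.

    equal: a single tension f with sum_i z_i(f) = total_extension.
    disparate: a unit tension F with sum_u span_u(F) = total_extension,
    where each unit splits F between its single and pair sides at a
    common span.  Raises :class:`TautFiberError` when the demanded
    extension exhausts the available contour.
    """
    if len(molecules) != topology.n_molecules:
        raise ValueError(
            f"expected {topology.n_molecules} molecules, got {len(molecules)}"
        )
    if total_extension < 0:
        raise ValueError("total_extension must be >= 0")
    kt = ctx.kt
    au = UNFOLDED_PERSISTENCE_NM
    if topology.architecture == "equal":
        sb, su, ab = _collection_sums(molecules)
        guess = _warm.strand_tension if _warm is not None else 1.0
        f = _solve_common_tension(total_extension, sb, su, ab, au, kt,
                                  f_guess=max(guess, 1e-9))
        z, dz = _agg_extension(f, sb, su, ab, au, kt)
        residual = abs(z - total_extension) / max(dz, 1e-300)
        xb, _ = _frac_extension_with_slope(f * ab / kt)
        xu, _ = _frac_extension_with_slope(f * au / kt) if su > 0 else (0.0, 0.0)
        spans = np.array([
            m.backbone.contour_length * xb
            + sum(s.contour_length for s in m.unfolded_segments) * xu
            for m in molecules
        ])
        return EquilibriumState(
            strand_tension=f,
            molecule_tensions=np.full(len(molecules), f),
            unit_spans=spans,
            residual_pN=residual,
        )

    arrays = _unit_arrays(molecules, topology.n_units)
    guess = _warm.strand_tension if _warm is not None else 1.0
    f1_guess = _warm.single_tensions if _warm is not None else None
    F, spans, f1 = _solve_disparate(
        total_extension, arrays, au, kt,
        F_guess=max(guess, 1e-9), f1_guess=f1_guess,
    )
    if F == 0.0:
        mt = np.zeros(topology.n_molecules)
        return EquilibriumState(0.0, mt, spans, 0.0,
                                single_tensions=np.zeros(topology.n_units))
    sb_s, su_s, sb_p, su_p, ab = arrays
    # residuals: boundary extension mismatch and per-unit span mismatch,
    # both mapped to force through the local stiffness
    zs, dzs = _agg_extension(f1, sb_s, su_s, ab, au, kt)
    zp, dzp = _agg_extension(F - f1, sb_p, su_p, ab, au, kt)
    node_res = np.abs(zs - zp) / np.maximum(dzs + dzp, 1e-300)
    z_tot = float(zs.sum())
    _, _, dspan = _split_unit_tension(F, f1, sb_s, su_s, sb_p, su_p, ab, au, kt)
    bound_res = abs(z_tot - total_extension) / max(float(dspan.sum()), 1e-300)
    mt = np.empty(topology.n_molecules)
    mt[0::3] = f1
    mt[1::3] = F - f1
    mt[2::3] = F - f1
    return EquilibriumState(
        strand_tension=F,
        molecule_tensions=mt,
        unit_spans=zs,
        residual_pN=max(float(node_res.max()), bound_res),
        single_tensions=np.asarray(f1, dtype=float),
    )


def run_stretch(
    topology: FiberTopology,
    protocol: StretchProtocol,
    table: DomainTable | None = None,
    preset_unfolded: int | Sequence[str] = 0,
    ctx: ThermalContext = DEFAULT_CONTEXT,
    rng: np.random.Generator | None = None,
) -> SimulationTrace:
    """Run the constant-extension-rate stretch with stochastic unfolding.

    Per step: extend by ``step_size_nm``, equilibrate, poll every folded
    domain at its molecule's equilibrium tension for one ``time_step_s``,
    apply all events simultaneously, record.  Identical seeds give
    bitwise-identical traces.
    """
    table = table if table is not None else default_domain_table()
    molecules = [
        init_unfolded(new_molecule(table), preset_unfolded)
        for _ in range(topology.n_molecules)
    ]
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    L0 = protocol.initial_length_nm(topology)
    n_steps = protocol.n_steps(topology)
    dt = protocol.time_step_s

    n_rec = n_steps + 1
    time_s = np.empty(n_rec)
    strain = np.empty(n_rec)
    tension = np.empty(n_rec)
    unfolded = np.empty(n_rec, dtype=np.int64)
    mol_t = np.empty((n_rec, topology.n_molecules))
    max_res = 0.0

    # static per-domain parameter matrices; folded state is shared with the
    # molecules (row views) so apply_unfolding keeps it in sync
    k0_mat = np.stack([m._k0 for m in molecules])
    dx_mat = np.stack([m._dx for m in molecules])
    folded_mat = np.stack([m._folded for m in molecules])
    for i, m in enumerate(molecules):
        m._folded = folded_mat[i]
    kt = ctx.kt

    n_unfolded_total = sum(m.n_unfolded for m in molecules)
    Z = L0
    eq: EquilibriumState | None = None
    for k in range(n_rec):
        if k > 0:
            Z += protocol.step_size_nm
        eq = equilibrate(topology, molecules, Z, ctx, _warm=eq)
        max_res = max(max_res, eq.residual_pN)
        if k > 0:
            # poll at the tension equilibrated at the start of the interval;
            # all events in one step are applied together.  The draw matrix
            # consumes the stream exactly like per-molecule poll_unfolding
            # calls in (molecule, domain) order.
            draws = rng.random(k0_mat.shape)
            p = np.minimum(
                1.0,
                k0_mat * np.exp(eq.molecule_tensions[:, None] * dx_mat / kt) * dt,
            )
            hits = folded_mat & (draws < p)
            events = list(zip(*np.nonzero(hits)))
            for i, d in events:
                apply_unfolding(molecules[i], d)
                logger.debug(
                    "step %d: molecule %d domain %d (%s) unfolded at %.2f pN",
                    k, i, d, molecules[i].domains[d].params.name,
                    eq.molecule_tensions[i],
                )
            n_unfolded_total += len(events)
        time_s[k] = k * dt
        strain[k] = (Z - L0) / L0
        tension[k] = eq.strand_tension
        unfolded[k] = n_unfolded_total
        mol_t[k] = eq.molecule_tensions
        if k and k % 1000 == 0:
            logger.info(
                "step %d/%d  strain %.2f  tension %.2f pN  unfolded %d",
                k, n_steps, strain[k], tension[k], n_unfolded_total,
            )

    return SimulationTrace(
        architecture=topology.architecture,
        n_units=topology.n_units,
        z0_nm=protocol.z0_nm,
        seed=protocol.seed,
        time_s=time_s,
        strain=strain,
        strand_tension_pN=tension,
        n_unfolded=unfolded,
        molecule_tensions_pN=mol_t,
        max_residual_pN=max_res,
        preset_unfolded=preset_unfolded,
    )


def disparate_force_ratio(trace: SimulationTrace) -> np.ndarray:
    """Per-step, per-unit ratio of single-side to pair-side tension.

    >= 1 while the pair side retains its extra slack; only defined for
    disparate traces.
    """
    if trace.architecture != "disparate":
        raise ValueError("disparate_force_ratio requires a disparate trace")
    single = trace.molecule_tensions_pN[:, 0::3]
    pair = trace.molecule_tensions_pN[:, 1::3]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(pair > 0, single / pair, np.nan)
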