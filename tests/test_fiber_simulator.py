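"""Fiber assembly, equilibration, and the stretch protocol."""

import numpy as np
import pytest
import scipy.integrate
import scipy.optimize

from fnfiber import (
    FiberTopology,
    StretchProtocol,
    TautFiberError,
    ThermalContext,
    WLCSegment,
    apply_unfolding,
    chain_extension,
    disparate_force_ratio,
    equilibrate,
    new_molecule,
    poll_unfolding,
    run_stretch,
    wlc_force,
)

CTX = ThermalContext()


def pristine(table, n):
    return [new_molecule(table) for _ in range(n)]


class TestProtocol:
    def test_extension_rate_near_published_value(self):
        p = StretchProtocol()
        assert p.extension_rate_um_s == pytest.approx(0.91, rel=0.02)

    def test_equal_starting_length(self):
        p = StretchProtocol()
        topo = FiberTopology("equal", 20)
        assert p.initial_length_nm(topo) == pytest.approx(2160.0)

    def test_topology_molecule_counts(self):
        assert FiberTopology("equal", 20).n_molecules == 20
        assert FiberTopology("disparate", 20).n_molecules == 60

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError):
            FiberTopology("parallel", 20)


class TestEquilibrate:
    def test_equal_pristine_symmetry(self, table):
        topo = FiberTopology("equal", 20)
        eq = equilibrate(topo, pristine(table, 20), 2160.0, CTX)
        # every molecule at z/L = 0.9 carries the same ~7.54 pN
        assert eq.strand_tension == pytest.approx(7.538, rel=1e-3)
        assert np.allclose(eq.molecule_tensions, eq.strand_tension)
        assert np.allclose(eq.unit_spans, 108.0)
        assert eq.residual_pN < 1e-6

    def test_disparate_pristine_unit(self, table):
        topo = FiberTopology("disparate", 1)
        eq = equilibrate(topo, pristine(table, 3), 108.0, CTX)
        f_single = eq.molecule_tensions[0]
        f_pair = eq.molecule_tensions[1]
        # single side at z/L = 0.9; pair side behaves as one L=240 chain
        assert f_single == pytest.approx(wlc_force(108.0, WLCSegment(120, 14)), rel=1e-9)
        assert f_pair == pytest.approx(
            wlc_force(108.0, WLCSegment(240, 14)) * 0 + 0.3017, rel=1e-3
        )
        assert eq.strand_tension == pytest.approx(f_single + f_pair)
        assert eq.strand_tension == pytest.approx(7.84, rel=1e-3)
        assert eq.molecule_tensions[1] == eq.molecule_tensions[2]

    def test_zero_extension_zero_tension(self, table):
        topo = FiberTopology("equal", 4)
        eq = equilibrate(topo, pristine(table, 4), 0.0, CTX)
        assert eq.strand_tension == 0.0
        topo = FiberTopology("disparate", 2)
        eq = equilibrate(topo, pristine(table, 6), 0.0, CTX)
        assert np.all(eq.molecule_tensions == 0.0)

    def test_taut_fiber_raises(self, table):
        topo = FiberTopology("equal", 2)
        with pytest.raises(TautFiberError):
            equilibrate(topo, pristine(table, 2), 241.0, CTX)

    def test_molecule_count_checked(self, table):
        with pytest.raises(ValueError):
            equilibrate(FiberTopology("equal", 3), pristine(table, 2), 100.0, CTX)

    def test_matches_energy_minimization_oracle(self, table):
        """Root-finding equilibrium == brute-force strain-energy minimum.

        Two dissimilar molecules in series; the internal node position
        minimizing the summed WLC strain energies (numerically
        integrated) must match the common-tension solution.
        """
        mol_a = new_molecule(table)  # pristine, contour 120
        mol_b = new_molecule(table)
        for i in range(3):  # three opened domains, contour 205.5
            apply_unfolding(mol_b, i)
        chain_a, chain_b = mol_a.to_chain(), mol_b.to_chain()
        total = 300.0

        def tension_at(chain, z):
            if z <= 0:
                return 0.0
            hi = 1.0
            while chain_extension(hi, chain, CTX) < z:
                hi *= 2
            return scipy.optimize.brentq(
                lambda f: chain_extension(f, chain, CTX) - z, 0.0, hi,
                xtol=1e-13,
            )

        def energy(chain, z):
            return scipy.integrate.quad(
                lambda t: tension_at(chain, t), 0.0, z, limit=200
            )[0]

        res = scipy.optimize.minimize_scalar(
            lambda z1: energy(chain_a, z1) + energy(chain_b, total - z1),
            bounds=(total - 205.0, 119.5),
            method="bounded",
            options={"xatol": 1e-8},
        )
        eq = equilibrate(FiberTopology("equal", 2), [mol_a, mol_b], total, CTX)
        assert eq.unit_spans[0] == pytest.approx(res.x, rel=1e-4)
        assert eq.strand_tension == pytest.approx(
            tension_at(chain_a, res.x), rel=1e-4
        )


class TestRunStretch:
    def test_deterministic_wlc_curve_when_kinetics_disabled(self, dead_table):
        # pristine molecules allow at most ~11% strain (z0/L = 0.9)
        topo = FiberTopology("equal", 3)
        prot = StretchProtocol(max_strain=0.08, seed=0)
        trace = run_stretch(topo, prot, table=dead_table)
        assert trace.n_unfolded[-1] == 0
        # spot-check against direct equilibration of pristine molecules
        for idx in [0, trace.strain.size // 2, trace.strain.size - 1]:
            z = prot.initial_length_nm(topo) * (1 + trace.strain[idx])
            eq = equilibrate(topo, pristine(dead_table, 3), z, CTX)
            assert trace.strand_tension_pN[idx] == pytest.approx(
                eq.strand_tension, rel=1e-9
            )

    def test_same_seed_bitwise_identical(self, hot_table):
        topo = FiberTopology("disparate", 2)
        prot = StretchProtocol(max_strain=0.5, seed=11)
        t1 = run_stretch(topo, prot, table=hot_table)
        t2 = run_stretch(topo, prot, table=hot_table)
        assert np.array_equal(t1.strand_tension_pN, t2.strand_tension_pN)
        assert np.array_equal(t1.n_unfolded, t2.n_unfolded)
        assert np.array_equal(t1.molecule_tensions_pN, t2.molecule_tensions_pN)

    def test_matches_reference_per_molecule_polling(self, hot_table):
        """The vectorized poll must reproduce sequential per-domain polling."""
        topo = FiberTopology("equal", 3)
        prot = StretchProtocol(max_strain=0.4, seed=5)
        trace = run_stretch(topo, prot, table=hot_table)

        molecules = pristine(hot_table, 3)
        rng = np.random.default_rng(5)
        L0 = prot.initial_length_nm(topo)
        Z = L0
        ref_tension = []
        ref_unfolded = []
        n_unf = 0
        for k in range(prot.n_steps(topo) + 1):
            if k:
                Z += prot.step_size_nm
            eq = equilibrate(topo, molecules, Z, CTX)
            if k:
                events = []
                for i, m in enumerate(molecules):
                    events += [
                        (i, d)
                        for d in poll_unfolding(
                            m, eq.molecule_tensions[i], prot.time_step_s, rng, CTX
                        )
                    ]
                for i, d in events:
                    apply_unfolding(molecules[i], d)
                n_unf += len(events)
            ref_tension.append(eq.strand_tension)
            ref_unfolded.append(n_unf)
        assert np.array_equal(trace.n_unfolded, np.array(ref_unfolded))
        assert np.allclose(trace.strand_tension_pN, ref_tension, rtol=1e-12)

    def test_tension_drops_after_unfolding(self, hot_table):
        topo = FiberTopology("equal", 3)
        prot = StretchProtocol(max_strain=0.4, seed=2)
        trace = run_stretch(topo, prot, table=hot_table)
        # events counted at record i+1 act on the tension recorded at i+2
        # (the recorded tension precedes the same step's unfolding poll)
        steps = np.nonzero(np.diff(trace.n_unfolded) > 0)[0]
        steps = steps[steps + 2 < trace.strain.size]
        assert steps.size > 0
        # inserting 28.5 nm of contour softens the strand far more than
        # one 0.67 nm increment stiffens it
        f = trace.strand_tension_pN
        assert np.all(f[steps + 2] < f[steps + 1])

    def test_equal_tension_uniform_across_molecules(self, table):
        topo = FiberTopology("equal", 5)
        prot = StretchProtocol(max_strain=1.0, seed=3)
        trace = run_stretch(topo, prot, table=table, preset_unfolded=4)
        spread = np.ptp(trace.molecule_tensions_pN, axis=1)
        assert np.all(spread <= 1e-9 * (1 + trace.strand_tension_pN))

    def test_strain_monotone_unfolded_nondecreasing(self, hot_table):
        topo = FiberTopology("disparate", 2)
        prot = StretchProtocol(max_strain=0.6, seed=8)
        trace = run_stretch(topo, prot, table=hot_table)
        assert np.all(np.diff(trace.strain) > 0)
        assert np.all(np.diff(trace.n_unfolded) >= 0)

    def test_force_balance_residual_bound(self, hot_table):
        for arch, n in [("equal", 3), ("disparate", 2)]:
            trace = run_stretch(
                FiberTopology(arch, n),
                StretchProtocol(max_strain=0.5, seed=4),
                table=hot_table,
            )
            assert trace.max_residual_pN < 1e-6

    def test_dataframe_round_trip(self, dead_table):
        from fnfiber import SimulationTrace

        topo = FiberTopology("equal", 2)
        prot = StretchProtocol(max_strain=0.08, seed=0)
        trace = run_stretch(topo, prot, table=dead_table)
        df = trace.to_dataframe()
        back = SimulationTrace.from_dataframe(df, "equal", 2)
        assert np.array_equal(back.strand_tension_pN, trace.strand_tension_pN)
        assert back.molecule_tensions_pN.shape == trace.molecule_tensions_pN.shape


class TestDisparateRatio:
    def test_pristine_unit_ratio(self, table):
        topo = FiberTopology("disparate", 1)
        eq = equilibrate(topo, pristine(table, 3), 108.0, CTX)
        ratio = eq.molecule_tensions[0] / eq.molecule_tensions[1]
        assert ratio == pytest.approx(25.0, rel=0.01)

    def test_small_span_limit_is_two(self, table):
        # at vanishing span both sides are linear springs with stiffness
        # ~ 1/L, so the force ratio tends to L_pair / L_single = 2
        topo = FiberTopology("disparate", 1)
        eq = equilibrate(topo, pristine(table, 3), 0.05, CTX)
        ratio = eq.molecule_tensions[0] / eq.molecule_tensions[1]
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_trace_ratio_shape_and_usage_error(self, dead_table):
        prot = StretchProtocol(max_strain=0.08, seed=0)
        trace_d = run_stretch(FiberTopology("disparate", 2), prot, table=dead_table)
        ratio = disparate_force_ratio(trace_d)
        assert ratio.shape == (trace_d.strain.size, 2)
        assert np.nanmin(ratio) >= 1.0
        trace_e = run_stretch(FiberTopology("equal", 2), prot, table=dead_table)
        with pytest.raises(ValueError):
            disparate_force_ratio(trace_e)

    def test_ratio_falls_when_single_side_unfolds(self, table):
        # opening domains only on the single side adds slack there and
        # lowers its share of the unit force at fixed span
        mols = pristine(table, 3)
        topo = FiberTopology("disparate", 1)
        r0 = equilibrate(topo, mols, 108.0, CTX)
        for i in range(4):
            apply_unfolding(mols[0], i)
        r1 = equilibrate(topo, mols, 108.0, CTX)
        assert (r1.molecule_tensions[0] / r1.molecule_tensions[1]
                < r0.molecule_tensions[0] / r0.molecule_tensions[1])
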