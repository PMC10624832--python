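from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jdpop import (
    ReporterCriteria,
    ResiduePopulation,
    SyntheticSpec,
    TwoStateReference,
    aggregate_population,
    exchange_lower_bound,
    fit_pfree_pipeline,
    gen_mutant_shifts,
    gen_reference,
    residue_population,
    select_reporters,
)
from jdpop.popfit import PopulationFitError

from conftest import amide_table


def brute_force_projection(u_i, u_f, u_m, step=1e-4):
    """Independent oracle: grid-minimize |u_M - (u_I + p (u_F - u_I))|."""
    ps = np.arange(-0.5, 1.5 + step / 2, step)
    pts = u_i[None, :] + ps[:, None] * (u_f - u_i)[None, :]
    d = np.linalg.norm(pts - u_m[None, :], axis=1)
    j = int(np.argmin(d))
    return ps[j], d[j]


def three_tables(u_i, u_f, u_m, w=5.0):
    mk = lambda u, name: amide_table([10], [u[0]], [u[1] * w], name)
    mutant = mk(u_m, "mut")
    ref = TwoStateReference(mk(u_i, "inh"), mk(u_f, "free"))
    return mutant, ref


class TestResiduePopulation:
    def test_midpoint_gives_half(self):
        u_i, u_f = np.array([8.0, 24.0]), np.array([8.5, 23.0])
        mutant, ref = three_tables(u_i, u_f, (u_i + u_f) / 2)
        rp = residue_population(mutant, ref, 10)
        assert rp.p_f_raw == pytest.approx(0.5)
        assert rp.perpendicular_distance == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("which, expected", [("i", 0.0), ("f", 1.0)])
    def test_endpoint_identity(self, which, expected):
        u_i, u_f = np.array([8.0, 24.0]), np.array([8.5, 23.0])
        mutant, ref = three_tables(u_i, u_f, u_i if which == "i" else u_f)
        assert residue_population(mutant, ref, 10).p_f_raw == pytest.approx(expected)

    def test_matches_brute_force_on_spec_instance(self):
        u_i = np.array([8.00, 120.0 / 5])
        u_f = np.array([8.50, 115.0 / 5])
        u_m = np.array([8.40, 116.1 / 5 + 0.01])
        mutant, ref = three_tables(u_i, u_f, u_m)
        rp = residue_population(mutant, ref, 10)
        p_bf, d_bf = brute_force_projection(u_i, u_f, u_m)
        assert rp.p_f_raw == pytest.approx(p_bf, abs=1e-3)
        assert rp.perpendicular_distance == pytest.approx(d_bf, abs=1e-3)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            u_i = rng.uniform([6.5, 21.0], [10.0, 27.0])
            u_f = u_i + rng.uniform(-0.4, 0.4, 2)
            if np.linalg.norm(u_f - u_i) < 0.02:
                u_f = u_i + np.array([0.1, 0.1])
            p_true = rng.uniform(-0.3, 1.3)
            u_m = u_i + p_true * (u_f - u_i) + rng.normal(0, 0.02, 2)
            mutant, ref = three_tables(u_i, u_f, u_m)
            rp = residue_population(mutant, ref, 10)
            p_bf, _ = brute_force_projection(u_i, u_f, u_m)
            assert abs(rp.p_f_raw - p_bf) < 1e-3

    def test_zero_separation_reported(self):
        u_i = np.array([8.0, 24.0])
        mutant, ref = three_tables(u_i, u_i, u_i + np.array([0.05, 0.0]))
        rp = residue_population(mutant, ref, 10)
        assert rp.p_f_raw is None
        assert rp.rejection_reason == "separation_too_small"

    def test_missing_atom_reported(self):
        from conftest import make_table

        mutant = make_table([(10, "XXX", "H", 8.0)], "mut")  # no N
        ref = TwoStateReference(
            amide_table([10], [8.0], [120.0], "i"), amide_table([10], [8.5], [118.0], "f")
        )
        rp = residue_population(mutant, ref, 10)
        assert rp.rejection_reason == "missing_data"


class TestSelectReporters:
    def rp(self, res, p=0.5, sep=0.2, perp=0.0):
        return ResiduePopulation(res, p, sep, perp)

    def test_rejection_priorities(self):
        pops = [
            ResiduePopulation(49, None, np.nan, np.nan, False, "missing_data"),
            self.rp(50),  # at the mutation site
            self.rp(51, sep=0.01, perp=0.5),  # near mutation beats separation
            self.rp(60, sep=0.01, perp=0.5),  # separation beats off-line
            self.rp(70, perp=0.2),  # off-line
            self.rp(80),  # clean
        ]
        out = select_reporters(pops, mutation_site=50)
        reasons = {r.residue_number: r.rejection_reason for r in out}
        assert reasons == {
            49: "missing_data", 50: "near_mutation", 51: "near_mutation",
            60: "separation_too_small", 70: "off_line", 80: "none",
        }
        assert [r.residue_number for r in out if r.accepted] == [80]

    def test_off_line_tolerance_scales_with_separation(self):
        crit = ReporterCriteria(max_off_line_abs=0.02, max_off_line_frac=0.15)
        big = self.rp(10, sep=0.4, perp=0.05)  # 0.05 < 0.15*0.4
        small = self.rp(11, sep=0.1, perp=0.05)  # 0.05 > max(0.02, 0.015)
        out = select_reporters([big, small], mutation_site=200, criteria=crit)
        assert out[0].accepted and not out[1].accepted

    def test_constructed_off_line_fixture(self, small_reference):
        """10 synthetic residues, 2 pushed off-line -> exactly 8 accepted."""
        spec, _ = small_reference
        spec10 = replace(spec, n_residues=10, p_f_true=0.5,
                         noise_h=0.0, noise_n=0.0, off_line_fraction=0.2)
        rng = spec10.rng()
        ref = gen_reference(spec10, rng)
        mut = gen_mutant_shifts(ref, spec10, rng)
        pops = [residue_population(mut, ref, r) for r in ref.inhibited.residues()]
        out = select_reporters(pops, mutation_site=200)
        assert sum(r.accepted for r in out) == 8
        assert sum(r.rejection_reason == "off_line" for r in out) == 2

    def test_zero_reporters_errors(self):
        with pytest.raises(PopulationFitError, match="no reporters"):
            select_reporters([self.rp(50)], mutation_site=50)


class TestAggregate:
    def test_identical_values(self):
        est = aggregate_population([self.acc(1, 0.9), self.acc(2, 0.9), self.acc(3, 0.9)])
        assert est.p_f_mean == pytest.approx(0.9)
        assert est.p_f_sem == 0.0
        assert est.n_reporters == 3
        assert est.p_i_mean == pytest.approx(0.1)

    def test_two_point_sem(self):
        est = aggregate_population([self.acc(1, 0.0), self.acc(2, 1.0)])
        assert est.p_f_mean == pytest.approx(0.5)
        assert est.p_f_sem == pytest.approx(0.5)  # sample SD 0.7071 / sqrt(2)

    def test_out_of_range_values_not_clipped(self):
        est = aggregate_population([self.acc(1, -0.1), self.acc(2, 1.1)])
        assert est.p_f_mean == pytest.approx(0.5)

    def test_dispersion_warning(self):
        with pytest.warns(UserWarning, match="two-state"):
            aggregate_population([self.acc(1, 0.1), self.acc(2, 0.9)])

    def test_empty_errors(self):
        with pytest.raises(PopulationFitError):
            aggregate_population([])

    @staticmethod
    def acc(res, p):
        return ResiduePopulation(res, p, 0.2, 0.0, accepted=True)


class TestPipeline:
    def test_self_comparison_is_zero(self, small_reference):
        _, ref = small_reference
        est = fit_pfree_pipeline(ref.inhibited, ref, mutation_site=200)
        assert est.p_f_mean == pytest.approx(0.0, abs=1e-12)

    def test_free_reference_is_one(self, small_reference):
        _, ref = small_reference
        est = fit_pfree_pipeline(ref.free, ref, mutation_site=200)
        assert est.p_f_mean == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_round_trip(self, noiseless_variant):
        ref, mut, p_true = noiseless_variant
        est = fit_pfree_pipeline(mut, ref, mutation_site=200)
        assert est.p_f_mean == pytest.approx(p_true, abs=1e-12)
        assert est.n_reporters == 21

    def test_noisy_recovery_within_tolerance(self, small_reference):
        spec, _ = small_reference
        vspec = replace(spec, p_f_true=0.67, noise_h=0.005, noise_n=0.025, seed=1)
        rng = vspec.rng()
        ref = gen_reference(vspec, rng)
        mut = gen_mutant_shifts(ref, vspec, rng)
        est = fit_pfree_pipeline(mut, ref, mutation_site=200)
        assert est.p_f_mean == pytest.approx(0.67, abs=0.03)

    def test_affine_translation_invariance(self, noiseless_variant):
        ref, mut, p_true = noiseless_variant
        from jdpop import ShiftRecord, ShiftTable

        def shifted(t, dh, dn):
            recs = [
                ShiftRecord(r.residue_number, r.residue_type, r.atom_name,
                            r.shift + (dh if r.atom_name == "H" else dn))
                for r in t.records
            ]
            return ShiftTable(t.dataset_id, t.construct_label, recs, field_mhz=t.field_mhz)

        ref2 = TwoStateReference(shifted(ref.inhibited, 0.3, -1.0), shifted(ref.free, 0.3, -1.0))
        est = fit_pfree_pipeline(shifted(mut, 0.3, -1.0), ref2, mutation_site=200)
        assert est.p_f_mean == pytest.approx(p_true, abs=1e-10)

    def test_swapping_references_complements_pf(self, noiseless_variant):
        ref, mut, p_true = noiseless_variant
        swapped = TwoStateReference(inhibited=ref.free, free=ref.inhibited)
        est = fit_pfree_pipeline(mut, swapped, mutation_site=200)
        assert est.p_f_mean == pytest.approx(1.0 - p_true, abs=1e-10)


@settings(max_examples=20, deadline=None)
@given(p=st.floats(0.0, 1.0, allow_subnormal=False))
def test_noiseless_linearity_any_pf(p):
    """For noiseless synthetic data the estimate equals the generating p_F."""
    spec = SyntheticSpec(seed=3, n_residues=10, p_f_true=p,
                         noise_h=0.0, noise_n=0.0, mutation_site=200)
    rng = spec.rng()
    ref = gen_reference(spec, rng)
    mut = gen_mutant_shifts(ref, spec, rng)
    est = fit_pfree_pipeline(mut, ref, mutation_site=200)
    assert est.p_f_mean == pytest.approx(p, abs=1e-10)


class TestExchangeBound:
    def test_direct_evaluation_proton(self):
        ref = TwoStateReference(
            amide_table([33, 34], [8.0, 8.0], [120.0, 120.0], "i"),
            amide_table([33, 34], [8.5, 8.1], [120.0, 120.0], "f"),
        )
        b = exchange_lower_bound(ref, field_mhz=600.13, nucleus="H", convention="angular")
        assert b.reporter_residue == 33
        assert b.delta_nu == pytest.approx(300.065)
        assert b.k_ex_min == pytest.approx(2 * np.pi * 300.065, rel=1e-9)
        assert b.k_ex_min == pytest.approx(1885.4, abs=0.1)
        lin = exchange_lower_bound(ref, field_mhz=600.13, nucleus="H", convention="linear")
        assert lin.k_ex_min == pytest.approx(300.065)

    def test_field_linearity(self):
        ref = TwoStateReference(
            amide_table([33], [8.0], [120.0], "i"), amide_table([33], [8.4], [122.0], "f")
        )
        b1 = exchange_lower_bound(ref, field_mhz=600.0, nucleus="N")
        b2 = exchange_lower_bound(ref, field_mhz=1200.0, nucleus="N")
        assert b2.k_ex_min == pytest.approx(2 * b1.k_ex_min)

    def test_degenerate_zero_differences(self):
        t = amide_table([33], [8.0], [120.0], "i")
        ref = TwoStateReference(t, amide_table([33], [8.0], [120.0], "f"))
        with pytest.raises(PopulationFitError, match="no exchange-sensitive"):
            exchange_lower_bound(ref, nucleus="H")
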