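import numpy as np
import pandas as pd
import pytest

from eitqct.ct_functional import (DisplacementField, HUVolume, adi_field,
                                  classify_parenchyma, compute_deformation_metrics,
                                  deformation_gradient, inspiratory_capacity,
                                  jacobian_field, principal_stretches, summarize_by_lobe)
from eitqct.synthetic_data import (generate_affine_displacement, generate_hu_volume,
                                   generate_rotation_displacement)


def make_volume(hu_values, spacing=(1.0, 1.0, 1.0), lobes=None):
    hu = np.asarray(hu_values, dtype=float)
    return HUVolume(voxels=hu, spacing=spacing, lung_mask=np.ones(hu.shape, dtype=bool),
                    lobe_labels=lobes)


class TestClassifyParenchyma:
    def test_generator_fractions_exact(self):
        vol = generate_hu_volume((10, 10, 10), emph_fraction=0.10, fsad_fraction=0.20, seed=0)
        row = classify_parenchyma(vol).set_index("region").loc["total"]
        assert row.emph_pct == 10.0
        assert row.fsad_pct == 20.0

    def test_healthy_tissue_classifies_empty(self):
        vol = make_volume(np.full((5, 5, 5), -700.0))
        row = classify_parenchyma(vol).set_index("region").loc["total"]
        assert row.emph_pct == row.fsad_pct == 0.0

    def test_toy_counts(self):
        hu = np.full(400, -700.0)
        hu[:100] = -1000.0
        hu[100:200] = -900.0
        vol = make_volume(hu.reshape(4, 10, 10))
        row = classify_parenchyma(vol).set_index("region").loc["total"]
        assert row.emph_pct == 25.0 and row.fsad_pct == 25.0

    def test_percentages_partition_to_100(self):
        vol = generate_hu_volume((8, 8, 8), 0.13, 0.27, seed=4)
        df = classify_parenchyma(vol)
        assert np.allclose(df.emph_pct + df.fsad_pct + df.normal_pct, 100.0)

    def test_per_lobe_rows_present(self):
        vol = generate_hu_volume((6, 6, 10), 0.1, 0.1, seed=1, with_lobes=True)
        df = classify_parenchyma(vol)
        assert set(df.region) == {"RUL", "RML", "RLL", "LUL", "LLL", "total"}

    def test_empty_mask_rejected(self):
        vol = make_volume(np.full((3, 3, 3), -700.0))
        vol.lung_mask[:] = False
        with pytest.raises(ValueError, match="mask"):
            classify_parenchyma(vol)


class TestDeformationGradient:
    def test_zero_field_gives_identity(self):
        fld = DisplacementField(u=np.zeros((4, 4, 4, 3)), spacing=(1, 1, 1))
        F = deformation_gradient(fld)
        assert np.allclose(F, np.eye(3))
        assert np.allclose(principal_stretches(F), 1.0)

    def test_affine_scales_recovered_at_interior(self):
        fld, _ = generate_affine_displacement((8, 8, 8), (1.1, 1.2, 1.3),
                                              spacing=(0.7, 1.0, 1.3))
        stretches = principal_stretches(deformation_gradient(fld))
        interior = stretches[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, [1.3, 1.2, 1.1], atol=1e-6)

    def test_rigid_rotation_is_isometric(self):
        fld = generate_rotation_displacement((6, 6, 6), angle_rad=0.4)
        stretches = principal_stretches(deformation_gradient(fld))
        assert np.allclose(stretches, 1.0, atol=1e-6)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="3 voxels"):
            deformation_gradient(DisplacementField(np.zeros((2, 4, 4, 3)), (1, 1, 1)))


class TestJacobian:
    def test_affine_value_everywhere(self):
        fld, truth = generate_affine_displacement((8, 8, 8), (1.1, 1.2, 1.3))
        jac = jacobian_field(deformation_gradient(fld))
        assert np.allclose(jac[1:-1, 1:-1, 1:-1], 1.716, atol=1e-6)
        assert truth.jacobian == pytest.approx(1.716)

    def test_composition_multiplies_jacobians(self):
        s1, s2 = (1.1, 1.05, 0.95), (1.2, 0.9, 1.1)
        shape = (7, 7, 7)
        f1, _ = generate_affine_displacement(shape, s1)
        f2, _ = generate_affine_displacement(shape, s2)
        # compose: u12(x) = S2 S1 x - x
        comp, _ = generate_affine_displacement(
            shape, tuple(a * b for a, b in zip(s1, s2)))
        j1 = jacobian_field(deformation_gradient(f1))[3, 3, 3]
        j2 = jacobian_field(deformation_gradient(f2))[3, 3, 3]
        j12 = jacobian_field(deformation_gradient(comp))[3, 3, 3]
        assert j12 == pytest.approx(j1 * j2, abs=1e-6)

    def test_volume_conservation_against_mask_ratio(self):
        # mean Jacobian over an ellipsoidal FRC mask ~ TLC/FRC voxel-count ratio
        scales = (1.15, 1.1, 1.05)
        n = 48
        fld, truth = generate_affine_displacement((n, n, n), scales)
        jac = jacobian_field(deformation_gradient(fld))
        c = (n - 1) / 2.0
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
        r2 = ((xx - c) / (0.4 * n)) ** 2 + ((yy - c) / (0.4 * n)) ** 2 + ((zz - c) / (0.4 * n)) ** 2
        frc = r2 <= 1.0
        tlc = (((xx - c) / (0.4 * n * scales[2])) ** 2
               + ((yy - c) / (0.4 * n * scales[1])) ** 2
               + ((zz - c) / (0.4 * n * scales[0])) ** 2) <= 1.0
        ratio = tlc.sum() / frc.sum()
        assert float(jac[frc].mean()) == pytest.approx(ratio, rel=0.02)


class TestADI:
    def test_isotropic_is_zero(self):
        assert adi_field(np.array([1.3, 1.3, 1.3])) == pytest.approx(0.0)

    def test_direct_formula(self):
        got = adi_field(np.array([1.2, 1.1, 1.0]))
        assert got == pytest.approx(np.sqrt((0.1 / 1.1) ** 2 + (0.1 / 1.0) ** 2))

    def test_sort_invariance(self):
        a = adi_field(np.array([1.0, 1.2, 1.1]))
        b = adi_field(np.array([1.2, 1.1, 1.0]))
        assert a == pytest.approx(b)

    def test_rotation_invariance_of_field(self):
        scales = (1.25, 1.1, 1.0)
        plain, _ = generate_affine_displacement((6, 6, 6), scales)
        rotated = generate_rotation_displacement((6, 6, 6), 0.5, pre_scales=scales)
        adi_a = compute_deformation_metrics(plain).adi[2, 2, 2]
        adi_b = compute_deformation_metrics(rotated).adi[2, 2, 2]
        assert adi_b == pytest.approx(adi_a, abs=1e-6)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(0)
        stretches = rng.uniform(0.5, 2.0, size=(100, 3))
        assert np.all(adi_field(stretches) >= 0)

    def test_folding_flagged_not_clipped(self):
        # a reflection folds the grid: det F < 0
        fld, = (generate_affine_displacement((5, 5, 5), (1.0, 1.0, 1.0))[0],)
        coords = np.arange(5)[:, None, None, None]
        fld.u[..., 0] = -2.0 * np.arange(5)[:, None, None]  # x -> -x
        met = compute_deformation_metrics(fld)
        assert met.n_folded == 125
        assert np.all(met.jacobian < 0)


class TestInspiratoryCapacity:
    def test_identical_volumes_give_zero(self):
        vol = make_volume(np.zeros((4, 4, 4)))
        assert inspiratory_capacity(vol, vol) == 0.0

    def test_constructed_6l_minus_3p5l(self):
        spacing = (10.0, 10.0, 10.0)  # 1 mL voxels
        tlc_mask = np.zeros((20, 20, 20), dtype=bool)
        tlc_mask.flat[:6000] = True
        frc_mask = np.zeros((20, 20, 20), dtype=bool)
        frc_mask.flat[:3500] = True
        tlc = HUVolume(np.zeros((20, 20, 20)), spacing, tlc_mask)
        frc = HUVolume(np.zeros((20, 20, 20)), spacing, frc_mask)
        assert inspiratory_capacity(tlc, frc) == pytest.approx(2.5)

    def test_unit_consistency_under_spacing_change(self):
        # doubling spacing with 1/8 the voxel count leaves the volume unchanged
        m1 = np.zeros((8, 8, 8), dtype=bool)
        m1.flat[:512] = True
        m2 = np.zeros((4, 4, 4), dtype=bool)
        m2.flat[:64] = True
        a = HUVolume(np.zeros((8, 8, 8)), (5.0, 5.0, 5.0), m1)
        b = HUVolume(np.zeros((4, 4, 4)), (10.0, 10.0, 10.0), m2)
        empty = HUVolume(np.zeros((4, 4, 4)), (10.0, 10.0, 10.0),
                         np.ones((4, 4, 4), dtype=bool))
        assert inspiratory_capacity(a, empty) == pytest.approx(inspiratory_capacity(b, empty))


class TestSummarizeByLobe:
    def test_uniform_metric(self):
        values = np.full((4, 4, 10), 2.5)
        lobes = np.empty((4, 4, 10), dtype=object)
        lobes[..., :5] = "RUL"
        lobes[..., 5:] = "LLL"
        df = summarize_by_lobe(values, lobes, np.ones_like(values, dtype=bool))
        assert np.allclose(df["mean"], 2.5)

    def test_two_lobe_weighted_total(self):
        values = np.ones((2, 2, 4))
        values[..., 2:] = 2.0
        lobes = np.empty((2, 2, 4), dtype=object)
        lobes[..., :2] = "A"
        lobes[..., 2:] = "B"
        df = summarize_by_lobe(values, lobes, np.ones_like(values, dtype=bool))
        d = df.set_index("region")
        assert d.loc["A", "mean"] == 1.0 and d.loc["B", "mean"] == 2.0
        assert d.loc["total", "mean"] == 1.5

    def test_matches_bruteforce_groupby(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, 5, 5))
        names = np.array(["RUL", "RML", "RLL", "LUL", "LLL"])
        lobes = names[rng.integers(0, 5, size=(5, 5, 5))]
        mask = np.ones((5, 5, 5), dtype=bool)
        df = summarize_by_lobe(values, lobes, mask).set_index("region")
        for name in names:  # oracle: explicit dict loop
            sel = values[lobes == name]
            assert df.loc[name, "mean"] == pytest.approx(sel.mean())
            assert df.loc[name, "median"] == pytest.approx(np.median(sel))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=27).reshape(3, 3, 3)
        mask = np.ones((3, 3, 3), dtype=bool)
        base = summarize_by_lobe(values, None, mask).set_index("region").loc["total"]
        perm = rng.permutation(27).reshape(3, 3, 3)
        shuffled = values.flat[perm]
        again = summarize_by_lobe(shuffled, None, mask).set_index("region").loc["total"]
        assert base["mean"] == pytest.approx(again["mean"])
        assert base["median"] == pytest.approx(again["median"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            summarize_by_lobe(np.zeros((3, 3, 3)), None, np.ones((4, 4, 4), dtype=bool))
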