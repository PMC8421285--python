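"""Synthetic patches, diffusion signals, noise model and datasets."""

import json

import numpy as np
import pandas as pd
import pytest

from cortexsift import synthetic_data as syn
from cortexsift.gradients import GradientScheme, generate_even_directions


def simple_spec(lam_par=1e-3, lam_perp=1e-3, K=0.0, kappa=np.inf, orientation="radial"):
    return syn.MicrostructureSpec(
        compartments=(syn.Compartment(1.0, lam_par, lam_perp, orientation),),
        dispersion_kappa=kappa,
        kurtosis_k=K,
    )


def shell_scheme(b, directions):
    return GradientScheme(directions=directions, bvalues=np.full(len(directions), b))


class TestSpecValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            syn.MicrostructureSpec(
                compartments=(syn.Compartment(0.6, 1e-3, 1e-3), syn.Compartment(0.5, 1e-3, 1e-3))
            )

    def test_eigenvalues_positive(self):
        with pytest.raises(ValueError):
            simple_spec(lam_par=-1e-3)

    def test_kurtosis_nonnegative(self):
        with pytest.raises(ValueError):
            simple_spec(K=-0.1)


class TestMakePatch:
    def test_flat_limit_normals(self):
        cfg = syn.PatchConfig(rois={"a": simple_spec()}, nx=5, ny=4, amplitude=0.0)
        surf = syn.make_patch(cfg, seed=0)
        np.testing.assert_allclose(surf[["nx", "ny", "nz"]], [[0, 0, 1]] * 20)

    def test_vertex_count(self):
        cfg = syn.PatchConfig(rois={"a": simple_spec(), "b": simple_spec()}, nx=40, ny=40)
        assert len(syn.make_patch(cfg, seed=0)) == 1600

    def test_deterministic(self):
        cfg = syn.PatchConfig(rois={"a": simple_spec()}, nx=6, ny=6)
        pd.testing.assert_frame_equal(syn.make_patch(cfg, seed=3), syn.make_patch(cfg, seed=3))

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            syn.PatchConfig(rois={"a": simple_spec()}, nx=1, ny=5)

    def test_roi_bands_balanced(self):
        cfg = syn.PatchConfig(rois={"a": simple_spec(), "b": simple_spec()}, nx=30, ny=20)
        surf = syn.make_patch(cfg, seed=0)
        counts = surf["label"].value_counts()
        assert counts["a"] == counts["b"] == 300

    def test_thickness_positive(self):
        cfg = syn.PatchConfig(rois={"a": simple_spec()}, nx=20, ny=20, thickness_sd=1.5)
        assert (syn.make_patch(cfg, seed=0)["thickness"] > 0.5).all()


class TestSimulateSignal:
    def test_isotropic_closed_form(self, even30):
        # lambda = 1e-3 mm^2/s at b=1000 -> S/S0 = exp(-1) everywhere
        s = syn.simulate_signal(
            simple_spec(), [0, 0, 1], shell_scheme(1000.0, even30), sigma=0.0, seed=0
        )
        np.testing.assert_allclose(s, np.exp(-1.0), atol=1e-12)

    def test_mean_signal_decreases_with_b(self, even30):
        spec = simple_spec(lam_par=1.5e-3, lam_perp=0.4e-3, kappa=20.0)
        means = []
        for b in (800.0, 1400.0, 2000.0):
            s = syn.simulate_signal(spec, [0, 0, 1], shell_scheme(b, even30), sigma=0.0, seed=1)
            means.append(s.mean())
        assert means[0] > means[1] > means[2]

    def test_rician_positive_bias(self, even30):
        # mean of noisy draws exceeds the noise-free value; for small sigma
        # the bias approaches sigma^2 / (2 S) (series of the Rician mean)
        spec = simple_spec()
        scheme = shell_scheme(1000.0, even30[:1])
        clean = syn.simulate_signal(spec, [0, 0, 1], scheme, sigma=0.0, seed=0)[0]
        sigma = 1.0 / 50.0
        rng = np.random.default_rng(0)
        draws = syn.add_rician_noise(np.full(10_000, clean), sigma, rng)
        bias = draws.mean() - clean
        predicted = sigma**2 / (2 * clean)
        assert bias > 0
        assert bias == pytest.approx(predicted, rel=0.5)

    def test_deterministic_per_seed(self, even30):
        spec = simple_spec(kappa=10.0)
        scheme = shell_scheme(1400.0, even30)
        a = syn.simulate_signal(spec, [0, 0, 1], scheme, sigma=0.05, seed=9)
        b = syn.simulate_signal(spec, [0, 0, 1], scheme, sigma=0.05, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_amplitudes_positive(self, even30):
        spec = simple_spec(lam_par=2e-3, lam_perp=0.2e-3, K=1.0, kappa=5.0)
        s = syn.simulate_signal(spec, [0, 0, 1], shell_scheme(2000.0, even30), sigma=0.1, seed=2)
        assert (s > 0).all()

    def test_tangential_axis_orthogonal_to_normal(self):
        # with no dispersion the tangential compartment's ADC along the
        # normal equals lambda_perp
        spec = simple_spec(lam_par=1.5e-3, lam_perp=0.3e-3, orientation="tangential")
        n = np.array([0.0, 0.0, 1.0])
        s = syn.simulate_signal(spec, n, shell_scheme(1000.0, n[None, :]), sigma=0.0, seed=0)
        assert s[0] == pytest.approx(np.exp(-1000.0 * 0.3e-3), abs=1e-6)


class TestCalibration:
    def test_matched_mean_signal_at_mid_b(self):
        rois = syn.benchmark_rois(2)
        m = [syn.spherical_mean_signal(s, 1400.0) for s in rois.values()]
        assert m[0] == pytest.approx(m[1], abs=1e-8)

    def test_rois_differ_off_mid_b(self):
        rois = list(syn.benchmark_rois(2).values())
        for b in (800.0, 2000.0):
            a, c = (syn.spherical_mean_signal(s, b) for s in rois)
            assert abs(a - c) > 1e-3


class TestMakeDataset:
    def test_acquisition_list_with_repeats(self):
        cfg = syn.PatchConfig(
            rois={"a": simple_spec()},
            nx=3,
            ny=2,
            acquisition_order=(1400.0, 800.0, 1400.0, 2000.0),
            n_directions=6,
            n_b0=1,
        )
        ds = syn.make_dataset(cfg, seed=0)
        assert ds.acquisitions == [(1400.0, 0), (800.0, 0), (1400.0, 1), (2000.0, 0)]
        assert len(ds.signals) == 4

    def test_default_acquisitions_ascending(self):
        cfg = syn.PatchConfig(rois={"a": simple_spec()}, nx=3, ny=2, n_directions=6)
        assert [b for b, _ in cfg.acquisitions] == [800.0, 1400.0, 1400.0, 1400.0, 2000.0]

    def test_repeats_share_directions_but_not_noise(self):
        cfg = syn.PatchConfig(rois={"a": simple_spec(kappa=10.0)}, nx=4, ny=2, n_directions=8)
        ds = syn.make_dataset(cfg, seed=1)
        s1, s2 = ds.schemes[(1400.0, 0)], ds.schemes[(1400.0, 1)]
        np.testing.assert_array_equal(s1.directions, s2.directions)
        assert not np.array_equal(ds.signals[(1400.0, 0)], ds.signals[(1400.0, 1)])

    def test_same_seed_identical(self, tmp_path):
        cfg = syn.PatchConfig(rois={"a": simple_spec()}, nx=3, ny=2, n_directions=6)
        d1 = syn.make_dataset(cfg, seed=5)
        d2 = syn.make_dataset(cfg, seed=5)
        for acq in d1.acquisitions:
            np.testing.assert_array_equal(d1.signals[acq], d2.signals[acq])
        syn.write_dataset(d1, tmp_path / "a")
        syn.write_dataset(d2, tmp_path / "b")
        for name in ("manifest.json", "surface.tsv", "acq_b800_r0.tsv"):
            assert (tmp_path / "a" / name).read_text() == (tmp_path / "b" / name).read_text()

    def test_written_bundle_files(self, tmp_path):
        cfg = syn.PatchConfig(rois={"a": simple_spec()}, nx=3, ny=2, n_directions=6, n_b0=1)
        ds = syn.make_dataset(cfg, seed=0)
        files = syn.write_dataset(ds, tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 0
        assert (tmp_path / "acq_b1400_r1.bval").exists()
        assert len(files) >= 6

    def test_volumetric_roundtrip(self, tmp_path):
        import nibabel as nib

        from cortexsift import cortex_sampling as cs

        cfg = syn.PatchConfig(
            rois={"a": simple_spec(kappa=10.0)}, nx=6, ny=4, n_directions=6, n_b0=1, snr=50.0
        )
        ds = syn.make_dataset(cfg, seed=2)
        syn.write_dataset(ds, tmp_path, volumetric=True)
        img = nib.load(tmp_path / "acq_b800_r0.nii")
        assert img.shape[3] == 7  # 1 b0 + 6 DWIs
        surf = cs.read_surface_table(tmp_path / "surface.tsv")
        samples = cs.midthickness_sample(img, surf)
        assert len(samples.table) == len(surf)  # whole patch inside the volume
        deduped = cs.dedup_vertices(samples, per_roi=False)
        # every deduped vertex reads back exactly its own simulated signal
        vids = deduped.table["vertex_id"].to_numpy()
        np.testing.assert_allclose(
            deduped.signal, ds.signals[(800.0, 0)][vids], atol=1e-6
        )
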