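"""Mid-thickness sampling and vertex deduplication."""

import numpy as np
import pandas as pd
import pytest

import nibabel as nib

from cortexsift import cortex_sampling as cs


def surface_df(rows):
    return pd.DataFrame(rows, columns=cs.SURFACE_COLUMNS).pipe(_add_ids)


def _add_ids(df):
    df = df.reset_index(drop=True)
    df.insert(0, "vertex_id", np.arange(len(df)))
    return df


class TestMidthicknessSample:
    def test_closed_form_rule(self):
        vol = nib.Nifti1Image(np.arange(2 * 2 * 4, dtype=float).reshape(2, 2, 4, 1), np.eye(4))
        surf = surface_df([[0, 0, 0, 0, 0, 1, 2.0, "a"]])
        out = cs.midthickness_sample(vol, surf)
        # sample point (0,0,1) -> voxel (0,0,1)
        assert out.table[["i", "j", "k"]].iloc[0].tolist() == [0, 0, 1]
        assert out.signal[0, 0] == vol.get_fdata()[0, 0, 1, 0]

    def test_self_labeling_volume_oracle(self, rng):
        # voxel value encodes its own flat index: sampled signal must equal
        # the encoded index of the predicted voxel for every vertex
        shape = (6, 6, 6)
        enc = np.arange(np.prod(shape), dtype=float).reshape(*shape, 1)
        affine = np.diag([1.7, 1.7, 1.7, 1.0])
        affine[:3, 3] = (-1.0, -2.0, 0.5)
        vol = nib.Nifti1Image(enc, affine)
        n = 50
        pos = rng.uniform(1.0, 6.0, (n, 3))
        nrm = rng.standard_normal((n, 3))
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        thick = rng.uniform(1.0, 3.0, n)
        surf = _add_ids(
            pd.DataFrame(
                np.column_stack([pos, nrm, thick, np.zeros(n)]),
                columns=cs.SURFACE_COLUMNS,
            ).assign(label="a")
        )
        out = cs.midthickness_sample(vol, surf)
        pts = out.positions + 0.5 * out.table["thickness"].to_numpy()[:, None] * out.normals
        vox = np.floor((np.linalg.inv(affine)[:3, :3] @ pts.T).T + np.linalg.inv(affine)[:3, 3]).astype(int)
        expected = np.ravel_multi_index(vox.T, shape).astype(float)
        np.testing.assert_array_equal(out.signal[:, 0], expected)

    def test_out_of_bounds_vertex_excluded(self, caplog):
        vol = nib.Nifti1Image(np.zeros((2, 2, 2, 1)), np.eye(4))
        surf = surface_df(
            [
                [0, 0, 0, 0, 0, 1, 1.0, "a"],
                [0, 0, 1.4, 0, 0, 1, 2.0, "a"],  # point z=2.4 beyond last slice
            ]
        )
        with caplog.at_level("WARNING"):
            out = cs.midthickness_sample(vol, surf)
        assert len(out.table) == 1
        assert out.table["vertex_id"].tolist() == [0]
        assert any("excluded" in r.message for r in caplog.records)

    def test_translation_equivariance(self, rng):
        data = rng.random((5, 5, 5, 3))
        surf = surface_df([[2.0, 2.0, 1.0, 0, 0, 1, 2.0, "a"], [1.0, 3.0, 2.0, 1, 0, 0, 1.0, "a"]])
        shift = np.array([10.0, -4.0, 3.0])
        a = cs.midthickness_sample(nib.Nifti1Image(data, np.eye(4)), surf)
        aff2 = np.eye(4)
        aff2[:3, 3] = shift
        surf2 = surf.copy()
        surf2[["x", "y", "z"]] += shift
        b = cs.midthickness_sample(nib.Nifti1Image(data, aff2), surf2)
        np.testing.assert_allclose(a.signal, b.signal)


class TestDedup:
    def _samples(self, positions, voxels, labels=None, vertex_ids=None):
        n = len(positions)
        tab = pd.DataFrame(
            {
                "vertex_id": vertex_ids if vertex_ids is not None else np.arange(n),
                "x": [p[0] for p in positions],
                "y": [p[1] for p in positions],
                "z": [p[2] for p in positions],
                "nx": 0.0,
                "ny": 0.0,
                "nz": 1.0,
                "thickness": 2.0,
                "label": labels if labels is not None else "a",
                "i": [v[0] for v in voxels],
                "j": [v[1] for v in voxels],
                "k": [v[2] for v in voxels],
            }
        )
        return cs.CorticalSamples(tab, np.arange(n, dtype=float)[:, None])

    def test_unique_voxels_identity(self):
        s = self._samples([(0, 0, 0), (1, 0, 0)], [(0, 0, 0), (1, 0, 0)])
        out = cs.dedup_vertices(s)
        assert out.table["vertex_id"].tolist() == [0, 1]

    def test_keeps_nearest_to_centroid(self):
        s = self._samples(
            [(0, 0, 0), (1, 0, 0), (2, 0, 0)], [(0, 0, 0)] * 3
        )
        out = cs.dedup_vertices(s)
        assert out.table["vertex_id"].tolist() == [1]
        assert out.signal.tolist() == [[1.0]]

    def test_equidistant_tie_keeps_lower_vertex_id(self):
        s = self._samples([(0, 0, 0), (2, 0, 0)], [(0, 0, 0)] * 2)
        out = cs.dedup_vertices(s)
        assert out.table["vertex_id"].tolist() == [0]

    def test_matches_bruteforce_on_random_clusters(self, rng):
        n = 200
        pos = rng.uniform(0, 10, (n, 3))
        vox = rng.integers(0, 3, (n, 3))
        s = self._samples([tuple(p) for p in pos], [tuple(v) for v in vox])
        out = cs.dedup_vertices(s, per_roi=False)
        # brute force per voxel group
        expected = []
        keys = [tuple(v) for v in vox]
        for key in sorted(set(keys)):
            rows = [i for i, k in enumerate(keys) if k == key]
            centroid = pos[rows].mean(axis=0)
            dists = [(np.linalg.norm(pos[i] - centroid), i) for i in rows]
            expected.append(min(dists)[1])
        assert sorted(out.table["vertex_id"].tolist()) == sorted(expected)

    def test_injective_per_roi(self, rng):
        n = 100
        s = self._samples(
            [tuple(p) for p in rng.uniform(0, 5, (n, 3))],
            [tuple(v) for v in rng.integers(0, 2, (n, 3))],
            labels=list(rng.choice(["a", "b"], n)),
        )
        out = cs.dedup_vertices(s)
        assert not out.table.duplicated(subset=["i", "j", "k", "label"]).any()


class TestSurfaceIO:
    def test_tsv_roundtrip(self, tmp_path, rng):
        df = pd.DataFrame(
            {
                "x": rng.random(4),
                "y": rng.random(4),
                "z": rng.random(4),
                "nx": 0.0,
                "ny": 0.0,
                "nz": 2.0,  # will be renormalized
                "thickness": 2.5,
                "label": ["a", "a", "b", "b"],
            }
        )
        p = tmp_path / "surf.tsv"
        df.to_csv(p, sep="\t", index=False)
        out = cs.read_surface_table(p)
        assert out["vertex_id"].tolist() == [0, 1, 2, 3]
        np.testing.assert_allclose(out["nz"], 1.0)

    def test_ascii_ply(self, tmp_path):
        ply = """ply
format ascii 1.0
element vertex 2
property float x
property float y
property float z
property float nx
property float ny
property float nz
property float thickness
property float label
end_header
0 0 0 0 0 1 2.0 0
1 0 0 0 0 1 2.5 1
"""
        p = tmp_path / "surf.ply"
        p.write_text(ply)
        out = cs.read_surface_table(p)
        assert len(out) == 2
        assert out["thickness"].tolist() == [2.0, 2.5]
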