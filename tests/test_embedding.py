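"""Image feature clouds, coarse embeddings, extension, dmap images."""

import warnings

import numpy as np
import pytest

from diffreg.embedding import (
    CoarseEmbeddingResult,
    DiffusionMapImage,
    EmbeddingConfig,
    ImageGrid,
    build_diffusion_map_image,
    coarse_embedding,
    extend_embedding,
    image_to_features,
)
from diffreg.spectral import DiffusionEmbedding, FeatureCloud
from diffreg.synthetic import PhantomSpec, make_phantom

CFG_SMALL = EmbeddingConfig(l=1, max_coarse_points=600)


def disk_image(n=32, value=1.0):
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    disk = (rows - n / 2) ** 2 + (cols - n / 2) ** 2 < (n / 4) ** 2
    return ImageGrid(np.where(disk, value, 0.0))


class TestImageToFeatures:
    def test_two_by_two_rescale(self):
        img = ImageGrid(np.array([[0.0, 255.0], [0.0, 255.0]]))
        fc = image_to_features(img, EmbeddingConfig())
        # span = max(H, W) - 1 = 1
        expected = np.array(
            [[0, 0, 0], [0, 1, 1], [1, 0, 0], [1, 1, 1]], dtype=float
        )
        assert np.allclose(fc.points, expected)

    def test_beta_positive_required(self):
        with pytest.raises(ValueError):
            EmbeddingConfig(beta=0.0)

    def test_feature_dimension_is_two_plus_channels(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (8, 8, 4)))
        fc = image_to_features(img, EmbeddingConfig())
        assert fc.d == 2 + 4

    def test_constant_channel_warns_and_zeroes(self):
        img = ImageGrid(np.full((8, 8), 3.0))
        with pytest.warns(UserWarning, match="constant"):
            fc = image_to_features(img, EmbeddingConfig())
        assert np.all(fc.points[:, 2] == 0.0)


class TestCoarsePyramid:
    def test_halving_until_under_cap(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (64, 64)))
        res = coarse_embedding(img, EmbeddingConfig(l=1, max_coarse_points=2048))
        assert res.shape == (32, 32)
        assert res.levels == 1

    def test_no_decimation_below_cap(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (16, 16)))
        res = coarse_embedding(img, EmbeddingConfig(l=1, max_coarse_points=400))
        assert res.shape == (16, 16)
        assert res.levels == 0

    def test_floor_of_eight_enforced(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (16, 16)))
        with pytest.raises(ValueError, match="max_coarse_points"):
            coarse_embedding(img, EmbeddingConfig(l=1, max_coarse_points=32))

    def test_two_region_phantom_separation(self):
        img = disk_image(n=24)  # below the cap: embedded at full size
        # a binary image has a full-span intensity gap; a moderate
        # bandwidth keeps the two clusters connected
        cfg = EmbeddingConfig(l=1, max_coarse_points=600, bandwidth_scale=0.25)
        res = coarse_embedding(img, cfg)
        coord = res.embedding.coords[:, 0]
        disk = image_to_features(img, cfg).points[:, 2] > 0
        a, b = coord[disk], coord[~disk]
        gap = abs(a.mean() - b.mean())
        assert gap > 5.0 * max(a.std(), b.std())


class TestExtension:
    def test_nodes_reproduced_exactly(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (12, 12)))
        res = coarse_embedding(img, CFG_SMALL)
        out = extend_embedding(res.embedding, res.cloud, res.cloud, res.sigma2)
        assert np.allclose(out, res.embedding.coords, atol=1e-6)

    def test_single_coarse_point_broadcasts(self):
        emb = DiffusionEmbedding(
            coords=np.array([[2.0, -1.0]]),
            lam_tilde=np.array([1.0, 1.0]),
            eigenvalues=np.array([0.5, 0.4]),
            source_n=1,
        )
        coarse = FeatureCloud(np.array([[0.0, 0.0]]))
        fine = FeatureCloud(np.random.default_rng(0).normal(size=(7, 2)))
        out = extend_embedding(emb, coarse, fine, 1.0)
        assert np.allclose(out, np.tile([2.0, -1.0], (7, 1)))

    def test_linear_ramp_midpoints(self):
        """Extension of a linear coordinate field stays near the ramp."""
        g = np.mgrid[0:10, 0:10].reshape(2, -1).T.astype(float)
        coarse = FeatureCloud(g)
        ramp = g[:, :1].copy()  # value = row index
        emb = DiffusionEmbedding(
            coords=ramp,
            lam_tilde=np.array([1.0]),
            eigenvalues=np.array([1.0 - 1e-6]),
            source_n=100,
        )
        mids = coarse.points[:50] + 0.5
        out = extend_embedding(emb, coarse, FeatureCloud(mids), sigma2=0.5)
        interior = (mids[:, 0] > 1) & (mids[:, 0] < 8)
        rel = np.abs(out[interior, 0] - mids[interior, 0]) / mids[interior, 0]
        assert np.max(rel) < 0.05


class TestDiffusionMapImage:
    def test_self_reference_identity(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (12, 12)))
        res = coarse_embedding(img, CFG_SMALL)
        plain = build_diffusion_map_image(img, CFG_SMALL, coarse=res)
        reffed = build_diffusion_map_image(img, CFG_SMALL, ref=res, coarse=res)
        assert np.allclose(plain.coords, reffed.coords, atol=1e-6)

    def test_bitwise_determinism(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (16, 16)))
        a = build_diffusion_map_image(img, CFG_SMALL)
        b = build_diffusion_map_image(img, CFG_SMALL)
        assert np.array_equal(a.coords, b.coords)

    def test_single_channel_output_for_l1(self, rng):
        img = ImageGrid(rng.uniform(0, 1, (16, 16)))
        dmap = build_diffusion_map_image(img, CFG_SMALL)
        assert dmap.l == 1 and dmap.shape == (16, 16)

    def test_rotation_coherence(self):
        """Embedding commutes with a 90-degree rotation of the image."""
        # odd size: decimation and rot90 commute exactly on the grid
        spec = PhantomSpec(shape=(33, 33), n_regions=3, noise_level=0.0,
                           bias_amplitude=0.0, seed=4)
        img = make_phantom(spec)[0][0]
        cfg = EmbeddingConfig(l=1, max_coarse_points=600)
        d = build_diffusion_map_image(img, cfg).coords[:, :, 0]
        rot = ImageGrid(np.rot90(img.data[:, :, 0]))
        d_rot = build_diffusion_map_image(rot, cfg).coords[:, :, 0]
        diff = np.abs(np.rot90(d) - d_rot)
        # sign of an eigenvector may flip under relabeling; take best
        diff_flip = np.abs(np.rot90(d) + d_rot)
        err = min(diff.mean(), diff_flip.mean())
        assert err < 0.02 * (d.max() - d.min())

    def test_modality_robustness(self):
        """Aligned diffusion-map images of two modalities agree better
        than the raw (rescaled) intensities do."""
        spec = PhantomSpec(seed=3)
        imgs, _ = make_phantom(spec)
        cfg = EmbeddingConfig(l=1, max_coarse_points=1024)
        ref = coarse_embedding(imgs[0], cfg)
        d0 = build_diffusion_map_image(imgs[0], cfg, coarse=ref)
        d1 = build_diffusion_map_image(imgs[1], cfg, ref=ref)

        def unit(x):
            return (x - x.min()) / (x.max() - x.min())

        raw_mad = np.abs(
            unit(imgs[0].data[:, :, 0]) - unit(imgs[1].data[:, :, 0])
        ).mean()
        dmap_mad = np.abs(
            unit(d0.coords[:, :, 0]) - unit(d1.coords[:, :, 0])
        ).mean()
        assert dmap_mad < raw_mad

    def test_reference_grid_mismatch_rejected(self, rng):
        cfg = CFG_SMALL
        res16 = coarse_embedding(ImageGrid(rng.uniform(0, 1, (16, 16))), cfg)
        img12 = ImageGrid(rng.uniform(0, 1, (12, 12)))
        with pytest.raises(ValueError, match="coarse grid"):
            build_diffusion_map_image(img12, cfg, ref=res16)
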