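import numpy as np
import pytest
from scipy import ndimage

from fibrilscope import _geometry
from fibrilscope.core import AlignmentRecord, ParticleStack
from fibrilscope.match import (align_particle, align_stack_iterative,
                               average_aligned, masked_ncc_map)


def brute_force_masked_ncc(image, template, mask):
    """Direct double-loop oracle for the masked NCC surface."""
    h, w = template.shape
    H, W = image.shape
    out = np.zeros((H - h + 1, W - w + 1))
    m = mask.astype(bool)
    t = template[m]
    t0 = t - t.mean()
    for i in range(H - h + 1):
        for j in range(W - w + 1):
            p = image[i:i + h, j:j + w][m]
            p0 = p - p.mean()
            den = np.sqrt((t0 ** 2).sum() * (p0 ** 2).sum())
            out[i, j] = (t0 * p0).sum() / den if den > 1e-12 else 0.0
    return out


class TestMaskedNCC:
    def test_fft_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            image = rng.normal(size=(24, 24))
            template = rng.normal(size=(7, 7))
            mask = rng.random((7, 7)) > 0.4
            if mask.sum() < 16:
                mask[:4, :4] = True
            fast = masked_ncc_map(image, template, mask)
            slow = brute_force_masked_ncc(image, template, mask)
            assert np.abs(fast - slow).max() < 1e-5

    def test_exact_patch_gives_peak_one_at_its_offset(self, rng):
        image = rng.normal(size=(32, 32))
        template = image[10:19, 5:14].copy()
        surface = masked_ncc_map(image, template, np.ones((9, 9), bool))
        assert surface.max() == pytest.approx(1.0, abs=1e-9)
        assert np.unravel_index(surface.argmax(), surface.shape) == (10, 5)

    def test_invariant_to_affine_intensity_changes(self, rng):
        image = rng.normal(size=(32, 32))
        template = image[4:13, 8:17].copy()
        surface = masked_ncc_map(3.0 * image + 7.0, template, np.ones((9, 9), bool))
        assert surface.max() == pytest.approx(1.0, abs=1e-9)

    def test_empty_and_tiny_masks_rejected(self, rng):
        image = rng.normal(size=(16, 16))
        template = rng.normal(size=(5, 5))
        with pytest.raises(ValueError):
            masked_ncc_map(image, template, np.zeros((5, 5), bool))
        small = np.zeros((5, 5), bool)
        small[0, :3] = True
        with pytest.raises(ValueError, match="16"):
            masked_ncc_map(image, template, small)


def _smooth_motif(rng, n=48):
    img = np.zeros((n, n))
    img[8:40, 20:28] = 1.0
    img[12:16, 14:34] = 2.0
    img[30:34, 22:26] = 3.0
    return ndimage.gaussian_filter(img, 2.5)


class TestAlignParticle:
    def test_recovers_known_rotation_and_shift(self, rng):
        ref = _smooth_motif(rng)
        particle = _geometry.shift_image(
            _geometry.rotate_image(ref, 37.0), -2.0, 3.0)
        rec = align_particle(particle, ref[None], psi_step=1.0, shift_max=6)
        assert abs(rec.psi - 37.0) <= 0.5
        assert abs(rec.dx - 3.0) <= 0.5 and abs(rec.dy - (-2.0)) <= 0.5
        assert rec.score > 0.99

    def test_identity_particle_gives_identity_record(self, rng):
        ref = _smooth_motif(rng)
        rec = align_particle(ref, ref[None], psi_step=5.0, shift_max=4)
        assert (rec.psi, rec.ref_index) == (0.0, 0)
        assert rec.dx == pytest.approx(0.0, abs=1e-9)
        assert rec.dy == pytest.approx(0.0, abs=1e-9)
        assert rec.score == pytest.approx(1.0, abs=1e-9)

    def test_tie_break_prefers_first_reference(self, rng):
        ref = _smooth_motif(rng)
        refs = np.stack([ref, ref])
        rec = align_particle(ref, refs, psi_step=90.0, shift_max=2)
        assert rec.ref_index == 0

    def test_all_zero_particle_flagged(self, rng):
        ref = _smooth_motif(rng)
        rec = align_particle(np.zeros_like(ref), ref[None], psi_step=90.0,
                             shift_max=2)
        assert rec.flagged and rec.score == 0.0


class TestAverageAligned:
    def test_identity_records_give_plain_mean(self, rng):
        data = rng.normal(size=(6, 16, 16)).astype(np.float32)
        stack = ParticleStack(data, 4.0)
        records = [AlignmentRecord() for _ in range(6)]
        assert np.allclose(average_aligned(stack, records), data.mean(axis=0),
                           atol=1e-6)

    @pytest.mark.parametrize("n", [4, 16, 64])
    def test_noise_averaging_improves_with_n(self, n):
        rng = np.random.default_rng(n)
        clean = _smooth_motif(rng)
        sigma = clean.std() * 2.0
        images, records = [], []
        for i in range(n):
            psi = rng.uniform(0, 360)
            dy, dx = rng.uniform(-3, 3, 2)
            img = _geometry.shift_image(_geometry.rotate_image(clean, psi), dy, dx)
            images.append(img + rng.normal(0, sigma, img.shape))
            records.append(AlignmentRecord(psi=psi, dx=dx, dy=dy))
        avg = average_aligned(ParticleStack(np.array(images), 4.0), records)
        corr = np.corrcoef(avg.ravel(), clean.ravel())[0, 1]
        # correlation grows with averaging: sqrt(n / (n + sigma^2/var))
        assert corr > {4: 0.75, 16: 0.9, 64: 0.95}[n]

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            average_aligned(ParticleStack(np.zeros((0, 8, 8)), 4.0), [])


class TestIterativeAlignment:
    def test_converges_on_noisy_copies_up_to_global_rotation(self):
        rng = np.random.default_rng(1)
        base = _smooth_motif(rng)
        truth, images = [], []
        for _ in range(20):
            psi = rng.uniform(0, 360)
            dy, dx = rng.uniform(-4, 4, 2)
            img = _geometry.shift_image(_geometry.rotate_image(base, psi), dy, dx)
            images.append(img + rng.normal(0, 0.3, img.shape))
            truth.append(psi)
        stack = ParticleStack(np.array(images), 4.0)
        records, _ = align_stack_iterative(stack, n_iter=5, psi_step=5.0,
                                           shift_max=6)
        d = np.deg2rad([(r.psi - t) % 360 for r, t in zip(records, truth)])
        offset = np.angle(np.exp(1j * np.array(d)).mean())
        spread = np.abs(np.degrees(np.angle(np.exp(1j * (d - offset)))))
        assert spread.max() <= 10.0
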