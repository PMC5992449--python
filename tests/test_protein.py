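import os
import stat

import numpy as np
import pytest

from rpistack import (
    PSSM,
    SequenceRecord,
    encode_protein,
    normalize_pssm,
    pseudo_pssm,
    pseudo_zernike_moments,
    pssm_from_psiblast,
    write_pssm,
)
from rpistack.io import AA_ORDER
from rpistack.protein import (
    grid_to_disk,
    moment_magnitudes,
    radial_polynomial,
    radial_polynomial_factorial,
    reconstruct_from_moments,
)

from conftest import random_protein


class TestNormalizePssm:
    def test_zero_profile_maps_to_uniform_half(self):
        img = normalize_pssm(PSSM(scores=np.zeros((10, 20))))
        assert np.allclose(img.pixels[img.mask], 0.5)

    def test_logistic_saturation_of_large_scores(self):
        mat = np.zeros((10, 20))
        mat[5, 5] = 50.0
        img = normalize_pssm(PSSM(scores=mat))
        assert img.pixels[5, 5] == pytest.approx(1.0, abs=1e-12)

    def test_mask_matches_brute_force_radius_check(self, rng):
        img = normalize_pssm(PSSM(scores=rng.normal(size=(30, 20))))
        H, W = 30, 20
        count = 0
        for i in range(H):
            for j in range(W):
                x = -1 + 2 * (j + 0.5) / W
                y = -1 + 2 * (i + 0.5) / H
                if x * x + y * y <= 1.0:
                    count += 1
        assert img.mask.sum() == count
        assert 0 < count < H * W  # corners really are excluded


class TestRadialPolynomials:
    def test_recurrence_agrees_with_factorial_formula_low_order(self):
        rho = np.linspace(0.0, 1.0, 101)
        for n in range(11):
            for m in range(n + 1):
                np.testing.assert_allclose(
                    radial_polynomial(n, m, rho),
                    radial_polynomial_factorial(n, m, rho),
                    atol=1e-9,
                )

    def test_unit_value_at_rho_one_at_high_order(self):
        # the factorial sum loses all precision here; the stable route must not
        assert radial_polynomial(30, 0, np.array([1.0]))[0] == pytest.approx(
            1.0, abs=1e-8
        )

    def test_invalid_order_pair_rejected(self):
        with pytest.raises(ValueError):
            radial_polynomial(2, 3, np.array([0.5]))


class TestPseudoZernikeMoments:
    def test_constant_image_excites_only_the_dc_moment(self):
        img = grid_to_disk(np.full((64, 64), 0.7))
        A = pseudo_zernike_moments(img, max_order=8)
        assert abs(A[0, 0]) == pytest.approx(0.7, abs=0.01)
        others = [abs(A[n, m]) for n in range(9) for m in range(n + 1) if n]
        assert max(others) < 0.03  # discretisation tolerance

    def test_magnitudes_invariant_under_quarter_rotation(self, rng):
        img = rng.random((32, 32))
        m1 = moment_magnitudes(pseudo_zernike_moments(grid_to_disk(img), 12))
        m2 = moment_magnitudes(
            pseudo_zernike_moments(grid_to_disk(np.rot90(img)), 12)
        )
        rel = np.abs(m1 - m2) / np.maximum(np.abs(m1), 1e-12)
        assert rel.max() < 1e-6

    def test_linearity_in_pixel_values(self, rng):
        img = rng.random((24, 24))
        A1 = pseudo_zernike_moments(grid_to_disk(img), 6)
        A2 = pseudo_zernike_moments(grid_to_disk(2.0 * img), 6)
        np.testing.assert_allclose(A2, 2.0 * A1, atol=1e-12)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            pseudo_zernike_moments(grid_to_disk(np.ones((8, 8))), max_order=-1)

    def test_band_limited_image_reconstructed_from_moments(self):
        # discrete-orthogonality sanity: a low-order image is recovered to <5%
        disk = grid_to_disk(np.zeros((64, 64)))
        f = (
            0.5
            + 0.3 * radial_polynomial(3, 1, disk.rho) * np.cos(disk.theta)
            + 0.2 * radial_polynomial(5, 2, disk.rho) * np.cos(2 * disk.theta)
        )
        img = grid_to_disk(f)
        A = pseudo_zernike_moments(img, max_order=10)
        rec = reconstruct_from_moments(A, img)
        err = np.linalg.norm((rec - f)[img.mask]) / np.linalg.norm(f[img.mask])
        assert err < 0.05


class TestEncodeProtein:
    def test_fixed_length_240_nonnegative(self, rng):
        pssm = PSSM(scores=rng.normal(size=(40, 20)))
        v = encode_protein(pssm)
        assert v.shape == (240,)
        assert np.all(v >= 0) and np.all(np.isfinite(v))

    def test_zero_profile_gives_dc_dominated_low_orders(self):
        # the flat image excites only the (0,0) moment among orders the
        # 20-wide grid can resolve; entries 1..27 cover orders 1..6
        v = encode_protein(PSSM(scores=np.zeros((20, 20))))
        assert v[0] == pytest.approx(0.5, abs=0.05)
        assert np.all(v[1:28] < 0.05)
        np.testing.assert_array_equal(
            v, encode_protein(PSSM(scores=np.zeros((20, 20))))
        )  # deterministic

    def test_too_low_order_for_requested_features_rejected(self):
        with pytest.raises(ValueError, match="moments"):
            encode_protein(PSSM(scores=np.zeros((10, 20))), max_order=5)


class TestPseudoPssm:
    def test_rows_are_blosum62_rows(self):
        p = pseudo_pssm(SequenceRecord(id="p", seq="AA", kind="protein"))
        assert p.length == 2
        np.testing.assert_array_equal(p.scores[0], p.scores[1])
        # BLOSUM62 A-vs-A is 4, A-vs-W is -3
        assert p.scores[0][AA_ORDER.index("A")] == 4
        assert p.scores[0][AA_ORDER.index("W")] == -3

    def test_shape_follows_sequence(self, rng):
        seq = random_protein(rng, 50)
        assert pseudo_pssm(
            SequenceRecord(id="p", seq=seq, kind="protein")
        ).length == 50

    def test_permuting_sequence_permutes_rows(self, rng):
        seq = random_protein(rng, 20)
        perm = rng.permutation(20)
        p1 = pseudo_pssm(SequenceRecord(id="a", seq=seq, kind="protein"))
        p2 = pseudo_pssm(
            SequenceRecord(
                id="b", seq="".join(seq[i] for i in perm), kind="protein"
            )
        )
        np.testing.assert_array_equal(p2.scores, p1.scores[perm])


class TestPsiblastDriver:
    def test_missing_executable_points_to_fallback(self, protein_record):
        with pytest.raises(FileNotFoundError, match="pseudo_pssm"):
            pssm_from_psiblast(
                protein_record, "db", executable="definitely-not-psiblast"
            )

    def test_mocked_executable_round_trips_a_profile(
        self, tmp_path, monkeypatch, rng
    ):
        seq = random_protein(rng, 8)
        rec = SequenceRecord(id="q", seq=seq, kind="protein")
        fixture = tmp_path / "fixture.pssm"
        mat = rng.integers(-5, 6, size=(8, 20)).astype(float)
        write_pssm(PSSM(scores=mat), seq, fixture)
        # fake psiblast: copies the fixture to the requested -out_ascii_pssm
        script = tmp_path / "psiblast"
        script.write_text(
            "#!/bin/sh\n"
            'while [ "$1" != "-out_ascii_pssm" ]; do shift; done\n'
            f'cp "{fixture}" "$2"\n'
        )
        script.chmod(script.stat().st_mode | stat.S_IEXEC)
        monkeypatch.setenv("PATH", f"{tmp_path}{os.pathsep}{os.environ['PATH']}")
        pssm = pssm_from_psiblast(rec, db="mockdb")
        np.testing.assert_array_equal(pssm.scores, mat)

    def test_failing_executable_raises_without_partial_output(
        self, tmp_path, monkeypatch, protein_record
    ):
        script = tmp_path / "psiblast"
        script.write_text("#!/bin/sh\necho 'BLAST Database error' >&2\nexit 2\n")
        script.chmod(script.stat().st_mode | stat.S_IEXEC)
        monkeypatch.setenv("PATH", f"{tmp_path}{os.pathsep}{os.environ['PATH']}")
        with pytest.raises(RuntimeError, match="Database error"):
            pssm_from_psiblast(protein_record, db="/no/such/db")
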