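import numpy as np
import pytest

import specshell as sp
from specshell import datasets as ds


@pytest.fixture(scope="session")
def family_aln() -> sp.FamilyAlignment:
    """Worked-example family alignment expanded from the natural-variation
    matrix at the five substrate-proximal positions."""
    return ds.natural_variation_alignment()


@pytest.fixture(scope="session")
def family_profiles(family_aln):
    return sp.column_profiles(family_aln)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20190446)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def horn_quaternion_fit(mobile: np.ndarray, fixed: np.ndarray):
    """Independent rigid-fit oracle: optimal quaternion via the largest
    eigenvector of Horn's 4x4 profile matrix (no SVD involved).

    The quaternion parameterisation ranges over proper rotations only, so
    mirror-image inputs are handled without an explicit sign fix.  Returns
    (rotation, translation, rmsd).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(fixed, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(N)
    w, x, y, z = eigvecs[:, -1]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd
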