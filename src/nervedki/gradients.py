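"""Diffusion gradient schemes: b-values, unit directions, and FSL-style IO.

b-values are carried in s/mm^2 (the unit printed on scanner protocols);
model code converts to ms/um^2 (divide by 1000) so that diffusivities come
out in um^2/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GradientScheme",
    "make_gradient_scheme",
    "read_bval_bvec",
    "write_bval_bvec",
]

#: b-values below this (s/mm^2) are treated as b=0 acquisitions.
B0_THRESHOLD = 50.0

_MIN_DIRS = 6  # a rank-2 symmetric tensor has 6 degrees of freedom


@dataclass(frozen=True)
class GradientScheme:
    """An ordered list of diffusion acquisitions.

    Attributes
    ----------
    bvalues : (N,) array
        Diffusion weighting per acquisition, s/mm^2.
    directions : (N, 3) array
        Unit gradient directions; the zero vector marks b=0 entries.
    pulse_duration : float or None
        Gradient pulse duration delta, ms (annotation only).
    diffusion_time : float or None
        Diffusion time Delta, ms (annotation only).
    """

    bvalues: np.ndarray
    directions: np.ndarray
    pulse_duration: float | None = field(default=None, compare=False)
    diffusion_time: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        d = np.asarray(self.directions, dtype=float)
        if b.ndim != 1 or d.shape != (b.size, 3):
            raise ValueError(
                f"shape mismatch: {b.size} b-values vs directions {d.shape}"
            )
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        nonzero = b > B0_THRESHOLD
        norms = np.linalg.norm(d[nonzero], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("nonzero-b directions must be unit vectors")
        if not np.any(~nonzero):
            raise ValueError("scheme needs at least one b=0 acquisition")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", d)

    def __len__(self) -> int:
        return int(self.bvalues.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues <= B0_THRESHOLD

    @property
    def bvalues_ms_um2(self) -> np.ndarray:
        """b-values in ms/um^2 (internal model units)."""
        return self.bvalues / 1000.0

    def n_unique_directions(self) -> int:
        dirs = self.directions[~self.b0_mask]
        return np.unique(np.round(dirs, 9), axis=0).shape[0]


def _repulsion_directions(n: int, seed: int, n_iter: int = 2000) -> np.ndarray:
    """Approximately uniform unit vectors by antipodal electrostatic repulsion.

    Starts from a seeded random draw on the sphere and descends the
    pairwise 1/r Coulomb energy of the 2n-point antipodally symmetric set.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.1
    for _ in range(n_iter):
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            # vector from every (possibly reflected) charge to every charge
            diff = v[:, None, :] - sign * v[None, :, :]
            dist2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            if sign < 0:  # antipode of a point coincides with its own reflection
                dist2[dist2 < 1e-12] = np.inf
            force += np.sum(diff / (dist2[..., None] ** 1.5), axis=1)
        # project onto the tangent plane and renormalize
        force -= v * np.sum(force * v, axis=1, keepdims=True)
        fmax = np.max(np.linalg.norm(force, axis=1))
        if fmax < 1e-12:
            break
        v = v + step * force / fmax
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def make_gradient_scheme(
    n_dirs: int,
    bvalues: list[float],
    n_b0: int = 1,
    seed: int = 0,
    pulse_duration: float | None = 4.0,
    diffusion_time: float | None = 12.0,
) -> GradientScheme:
    """Build a multi-shell scheme: ``n_b0`` b=0 entries, then each of
    ``n_dirs`` repulsion-optimized directions at every b-value.

    Requires ``n_dirs >= 6`` (diffusion-tensor identifiability); 15 or more
    directions are needed for the kurtosis tensor.
    """
    if n_dirs < _MIN_DIRS:
        raise ValueError(
            f"n_dirs={n_dirs} < {_MIN_DIRS}: a diffusion tensor needs at "
            f"least {_MIN_DIRS} independent directions"
        )
    bvals = [float(b) for b in bvalues]
    if not bvals or any(b <= 0 for b in bvals):
        raise ValueError("bvalues must be a nonempty list of positive values")
    dirs = _repulsion_directions(n_dirs, seed)
    all_b = [0.0] * n_b0
    all_d = [np.zeros(3)] * n_b0
    for b in bvals:
        all_b.extend([b] * n_dirs)
        all_d.extend(dirs)
    return GradientScheme(
        bvalues=np.array(all_b),
        directions=np.array(all_d),
        pulse_duration=pulse_duration,
        diffusion_time=diffusion_time,
    )


def read_bval_bvec(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style gradient tables (1-row .bval, 3-row .bvec)."""
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: 3 rows of N entries
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"gradient table mismatch: {bvals.size} b-values vs "
            f"{bvecs.shape[0]} b-vectors"
        )
    return bvals, bvecs


def write_bval_bvec(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.10f")
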