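"""Diffusion/kurtosis tensor engine.

The signal representation is the standard log-linear 22-parameter DKI model

    ln S(b, n) = ln S0 - b * D_app(n) + (1/6) * b^2 * D_app(n)^2 * K_app(n)

with the apparent diffusivity and kurtosis along unit direction ``n``

    D_app(n) = sum_ij n_i n_j D_ij
    K_app(n) = (MD^2 / D_app(n)^2) * sum_ijkl n_i n_j n_k n_l W_ijkl

where ``D`` is the symmetric rank-2 diffusion tensor (um^2/ms), ``W`` the
fully symmetric rank-4 kurtosis tensor (dimensionless, 15 unique elements)
and MD the mean diffusivity.  Estimation is by two-pass weighted linear
least squares on the log-signal: an ordinary pass followed by a pass
weighted with the squared predicted signals.

b-values enter the public API in s/mm^2 and are converted internally to
ms/um^2 so diffusivities come out in um^2/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientScheme

__all__ = [
    "TensorFit",
    "ScalarIndices",
    "D_UNIQUE_INDICES",
    "D_MULTIPLICITY",
    "W_UNIQUE_INDICES",
    "W_MULTIPLICITY",
    "predict_signal",
    "build_design_matrix",
    "fit_wlls",
    "dti_scalars",
    "apparent_kurtosis",
    "kurtosis_scalars",
    "fa_from_ratio",
    "fit_volume",
    "d_from_unique",
    "d_to_unique",
    "w15_to_full",
    "full_to_w15",
    "sphere_design",
]

# ---------------------------------------------------------------------------
# Unique-element bookkeeping for the symmetric tensors.
#
# The linearized model sums over all 3^2 (resp. 3^4) index combinations of a
# symmetric tensor; collapsing to unique sorted index patterns introduces a
# combinatorial multiplicity = (number of distinct permutations of the
# pattern): 4!/(prod of repeats!) for rank 4, 2!/(repeats!) for rank 2.
# ---------------------------------------------------------------------------

D_UNIQUE_INDICES: list[tuple[int, int]] = [
    (0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2),
]
D_MULTIPLICITY = np.array([1, 1, 1, 2, 2, 2], dtype=float)

W_UNIQUE_INDICES: list[tuple[int, int, int, int]] = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1),
    (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
W_MULTIPLICITY = np.array(
    [1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float
)


def d_to_unique(D: np.ndarray) -> np.ndarray:
    """Symmetric 3x3 -> 6-vector (xx, yy, zz, xy, xz, yz)."""
    D = np.asarray(D, dtype=float)
    return np.array([D[i, j] for i, j in D_UNIQUE_INDICES])


def d_from_unique(d6: np.ndarray) -> np.ndarray:
    D = np.zeros((3, 3))
    for val, (i, j) in zip(d6, D_UNIQUE_INDICES):
        D[i, j] = D[j, i] = val
    return D


def w15_to_full(w15: np.ndarray) -> np.ndarray:
    """15 unique elements -> fully symmetric 3x3x3x3 tensor."""
    W = np.zeros((3, 3, 3, 3))
    for val, idx in zip(w15, W_UNIQUE_INDICES):
        seen = set()
        from itertools import permutations

        for perm in permutations(idx):
            if perm not in seen:
                W[perm] = val
                seen.add(perm)
    return W


def full_to_w15(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    return np.array([W[idx] for idx in W_UNIQUE_INDICES])


def _dir_moments2(n: np.ndarray) -> np.ndarray:
    """Per-direction products n_i n_j for the 6 unique patterns; (N, 6)."""
    n = np.atleast_2d(n)
    return np.stack([n[:, i] * n[:, j] for i, j in D_UNIQUE_INDICES], axis=1)


def _dir_moments4(n: np.ndarray) -> np.ndarray:
    """Per-direction products n_i n_j n_k n_l for the 15 patterns; (N, 15)."""
    n = np.atleast_2d(n)
    return np.stack(
        [n[:, i] * n[:, j] * n[:, k] * n[:, l] for i, j, k, l in W_UNIQUE_INDICES],
        axis=1,
    )


def _d_app(D: np.ndarray, n: np.ndarray) -> np.ndarray:
    return _dir_moments2(n) @ (D_MULTIPLICITY * d_to_unique(D))


def _w_app(w15: np.ndarray, n: np.ndarray) -> np.ndarray:
    return _dir_moments4(n) @ (W_MULTIPLICITY * np.asarray(w15, dtype=float))


@dataclass
class TensorFit:
    """Per-voxel fit result: S0, diffusion tensor, kurtosis tensor, flags.

    ``W`` is stored as its 15 unique elements in the order of
    ``W_UNIQUE_INDICES``; full symmetry is therefore structural.
    """

    s0: float
    D: np.ndarray  # (3, 3), um^2/ms
    w15: np.ndarray  # (15,), dimensionless
    residual_norm: float = 0.0
    condition_number: float = 0.0
    negative_eigenvalues: bool = False
    md_nonpositive: bool = False
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if np.max(np.abs(self.D - self.D.T)) > 1e-12:
            raise ValueError("D must be symmetric")
        self.w15 = np.asarray(self.w15, dtype=float)
        if self.w15.shape != (15,):
            raise ValueError("w15 must have 15 elements")

    @property
    def md(self) -> float:
        return float(np.trace(self.D)) / 3.0


@dataclass
class ScalarIndices:
    """DTI/DKI scalar indices for one voxel or slice."""

    fa: float
    md: float
    ad: float
    rd: float
    mk: float
    ak: float
    rk: float
    e1: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    e1_undefined: bool = False


def predict_signal(fit: TensorFit, scheme: GradientScheme) -> np.ndarray:
    """Forward DKI signal for every acquisition in the scheme.

    Returns S0 exactly at b=0.  Raises if the apparent diffusivity is
    nonpositive along any requested nonzero-b direction (degenerate tensor).
    """
    if fit.s0 <= 0:
        raise ValueError("S0 must be positive")
    b = scheme.bvalues_ms_um2
    n = scheme.directions
    d_app = _d_app(fit.D, n)
    nonzero = ~scheme.b0_mask
    if np.any(d_app[nonzero] <= 0):
        raise ValueError(
            "nonpositive apparent diffusivity along a requested direction"
        )
    md = fit.md
    w_app = _w_app(fit.w15, n)
    ln_s = np.log(fit.s0) - b * d_app + (b**2 / 6.0) * md**2 * w_app
    ln_s[scheme.b0_mask] = np.log(fit.s0)
    return np.exp(ln_s)


def build_design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Design matrix of the log-linearized DKI model, (N, 22).

    Column order: [1 (ln S0); -b * {n_i n_j with multiplicities} (6);
    +(b^2/6) * {n_i n_j n_k n_l with multiplicities} (15)].  The parameter
    vector it multiplies is [ln S0; D_unique (6); MD^2 * W_unique (15)].
    """
    b = scheme.bvalues_ms_um2[:, None]
    m2 = _dir_moments2(scheme.directions) * D_MULTIPLICITY
    m4 = _dir_moments4(scheme.directions) * W_MULTIPLICITY
    ones = np.ones((len(scheme), 1))
    return np.hstack([ones, -b * m2, (b**2 / 6.0) * m4])


def fit_wlls(
    signals: np.ndarray,
    scheme: GradientScheme,
    n_passes: int = 2,
    log_floor_frac: float = 1e-6,
) -> TensorFit:
    """Two-pass weighted linear least-squares DKI fit.

    Pass 1 is ordinary least squares on ln S; each later pass reweights
    with the squared predicted signals of the previous pass (the standard
    WLLS estimator for log-linearized diffusion models).  Nonpositive
    signals are clamped to ``log_floor_frac * max(signals)`` and counted in
    ``n_clamped``.  If the fitted MD is nonpositive the kurtosis tensor is
    undefined: ``w15`` is NaN and ``md_nonpositive`` is set, but the record
    is returned rather than dropped.
    """
    s = np.asarray(signals, dtype=float).copy()
    if s.size != len(scheme):
        raise ValueError(
            f"signal count {s.size} does not match scheme length {len(scheme)}"
        )
    floor = log_floor_frac * np.max(s)
    if floor <= 0:
        raise ValueError("all signals nonpositive; nothing to fit")
    n_clamped = int(np.sum(s < floor))
    s = np.maximum(s, floor)

    A = build_design_matrix(scheme)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise ValueError(
            f"rank-deficient design: rank {rank} < {A.shape[1]} parameters; "
            "need >=22 acquisitions spanning >=2 nonzero b-values and >=15 "
            "directions"
        )
    y = np.log(s)
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    for _ in range(max(0, n_passes - 1)):
        w = np.exp(A @ x)  # predicted signals
        sw = w  # weight^(1/2) with weight = predicted^2
        x, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)

    s0 = float(np.exp(x[0]))
    D = d_from_unique(x[1:7])
    md = float(np.trace(D)) / 3.0
    evals = np.linalg.eigvalsh(D)
    # nerve MDs are O(1) um^2/ms; below this the kurtosis block (which
    # divides by MD^2) is numerically meaningless
    md_bad = md <= 1e-10
    w15 = np.full(15, np.nan) if md_bad else x[7:] / md**2
    resid = float(np.linalg.norm(A @ x - y))
    return TensorFit(
        s0=s0,
        D=D,
        w15=w15,
        residual_norm=resid,
        condition_number=float(np.linalg.cond(A)),
        negative_eigenvalues=bool(np.any(evals < 0)),
        md_nonpositive=bool(md_bad),
        n_clamped=n_clamped,
    )


def dti_scalars(D: np.ndarray) -> ScalarIndices:
    """DTI scalar indices from the diffusion tensor alone.

    Eigenvalues are sorted descending (l1 >= l2 >= l3); AD = l1,
    RD = (l2 + l3)/2, MD = mean, FA = sqrt(3/2) * ||l - MD|| / ||l||.
    The all-zero tensor yields FA = 0 with ``e1_undefined`` set; a
    near-degenerate leading eigenvalue (l1 - l2 < 1e-9 * MD) also flags
    ``e1_undefined`` since the principal axis is then arbitrary.
    Kurtosis fields are NaN (no W supplied).
    """
    D = np.asarray(D, dtype=float)
    if np.max(np.abs(D - D.T)) > 1e-12:
        raise ValueError("D must be symmetric")
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    md = float(np.mean(evals))
    ad = float(evals[0])
    rd = float((evals[1] + evals[2]) / 2.0)
    sq = float(np.sum(evals**2))
    if sq == 0.0:
        return ScalarIndices(
            fa=0.0, md=0.0, ad=0.0, rd=0.0, mk=np.nan, ak=np.nan, rk=np.nan,
            e1=np.array([1.0, 0.0, 0.0]), e1_undefined=True,
        )
    fa = float(np.sqrt(1.5 * np.sum((evals - md) ** 2) / sq))
    e1_undef = (evals[0] - evals[1]) < 1e-9 * abs(md)
    return ScalarIndices(
        fa=fa, md=md, ad=ad, rd=rd, mk=np.nan, ak=np.nan, rk=np.nan,
        e1=evecs[:, 0], e1_undefined=bool(e1_undef),
    )


def apparent_kurtosis(D: np.ndarray, w15: np.ndarray, n: np.ndarray) -> np.ndarray:
    """K_app(n) = (MD^2 / D_app(n)^2) * W_app(n); even in n."""
    D = np.asarray(D, dtype=float)
    d_app = _d_app(D, n)
    if np.any(d_app <= 0):
        raise ValueError("nonpositive apparent diffusivity: K_app undefined")
    md = np.trace(D) / 3.0
    out = (md**2 / d_app**2) * _w_app(w15, n)
    return out if np.asarray(n).ndim > 1 else float(out[0])


def sphere_design(n: int) -> np.ndarray:
    """Deterministic quasi-uniform spherical design (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _perp_basis(e1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(e1, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(e1, u)


def kurtosis_scalars(
    D: np.ndarray,
    w15: np.ndarray,
    n_radial: int = 64,
    n_sphere: int = 256,
) -> tuple[float, float, float]:
    """Mean, axial, and radial kurtosis by deterministic numerical averaging.

    MK averages K_app over an ``n_sphere``-point Fibonacci design; AK is
    K_app along the principal eigenvector; RK averages K_app over
    ``n_radial`` equally spaced directions in the perpendicular plane.
    Numerical averaging is the defined semantics here (the circular RK
    quadrature is exact for the degree-4 integrand once n_radial >= 5).
    """
    sc = dti_scalars(D)
    e1 = sc.e1  # arbitrary flagged axis when degenerate
    ak = apparent_kurtosis(D, w15, e1[None, :])[0]
    u, v = _perp_basis(e1)
    theta = np.linspace(0.0, np.pi, n_radial, endpoint=False)
    radial_dirs = np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)
    rk = float(np.mean(apparent_kurtosis(D, w15, radial_dirs)))
    mk = float(np.mean(apparent_kurtosis(D, w15, sphere_design(n_sphere))))
    return mk, float(ak), rk


def fa_from_ratio(ratio):
    """FA of a cylindrically symmetric tensor from its RD/AD ratio.

        FA = (1 - r) / sqrt(1 + 2 r^2),   r = RD/AD

    Strictly decreasing on [0, inf): r=0 (stick) -> 1, r=1 (isotropic) -> 0;
    r > 1 gives a negative value (oblate tensor).  Negative ratios are a
    domain error.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0):
        raise ValueError("RD/AD ratio must be nonnegative")
    out = (1.0 - r) / np.sqrt(1.0 + 2.0 * r**2)
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


_MAP_NAMES = ("fa", "md", "ad", "rd", "mk", "ak", "rk")


def fit_volume(
    image: np.ndarray,
    mask: np.ndarray,
    scheme: GradientScheme,
    n_radial: int = 64,
    n_sphere: int = 256,
) -> dict[str, np.ndarray]:
    """Voxel-wise WLLS fit over a masked 4-D volume.

    Returns one 3-D float map per scalar index (keys: fa, md, ad, rd, mk,
    ak, rk) plus a boolean ``flag`` map marking voxels whose fit failed or
    was degenerate; failed voxels carry NaN in every index map.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 4 or image.shape[:3] != mask.shape:
        raise ValueError(
            f"image shape {image.shape} incompatible with mask {mask.shape}"
        )
    if image.shape[3] != len(scheme):
        raise ValueError(
            f"image has {image.shape[3]} volumes but scheme lists {len(scheme)}"
        )
    if not mask.any():
        raise ValueError("empty mask")
    maps = {k: np.full(mask.shape, np.nan) for k in _MAP_NAMES}
    maps["flag"] = np.zeros(mask.shape, dtype=bool)
    for idx in zip(*np.nonzero(mask)):
        try:
            fit = fit_wlls(image[idx], scheme)
        except ValueError:
            maps["flag"][idx] = True
            continue
        sc = dti_scalars(fit.D)
        failed = fit.md_nonpositive
        if not failed:
            try:
                mk, ak, rk = kurtosis_scalars(
                    fit.D, fit.w15, n_radial=n_radial, n_sphere=n_sphere
                )
            except ValueError:
                failed = True
        if failed:
            maps["flag"][idx] = True
            continue
        for key, val in zip(
            _MAP_NAMES, (sc.fa, sc.md, sc.ad, sc.rd, mk, ak, rk)
        ):
            maps[key][idx] = val
    # invariant: within the mask, flag is set exactly where fa is NaN
    return maps
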