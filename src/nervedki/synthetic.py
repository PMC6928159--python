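"""Synthetic data generation for the nerve-regeneration pipeline.

Everything the pipeline consumes can be generated here with a fixed seed:
gradient schemes, noisy diffusion-weighted signals and tube phantoms from
known tensors, and full cohort studies (slice-record tables, behavioral
scores, axon densities) following the three-cohort rat sciatic nerve design
— sham, crush (axonotmesis, reliably self-resolving) and cut/repair
(neurotmesis with surgical repair, variable outcome) — sampled at 1, 2, 4
and 12 weeks post-surgery.

All distributional defaults are invented, config-exposed emulation
parameters: they reproduce the qualitative geometry of the real cohorts
(week-4 distal separability in the RD-vs-AD plane, edema-dominated early
weeks, bimodal week-12 cut/repair outcomes), not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dki
from .gradients import GradientScheme, make_gradient_scheme
from .slicewise import SLICE_COLUMNS, label_slices

__all__ = [
    "NerveGroundTruth",
    "StudyConfig",
    "StudyTables",
    "TensorDistribution",
    "make_gradient_scheme",
    "simulate_voxel_signal",
    "simulate_nerve_volume",
    "simulate_study",
    "cylindrical_truth",
]

COHORTS = ("sham", "crush", "cut_repair")
WEEKS = (1, 2, 4, 12)

#: Study roster: animals per (cohort, endpoint week).
DEFAULT_COHORT_SIZES: dict[str, dict[int, int]] = {
    "sham": {1: 6, 2: 6, 4: 6, 12: 3},
    "crush": {1: 5, 2: 6, 4: 6, 12: 6},
    "cut_repair": {1: 5, 2: 3, 4: 5, 12: 6},
}


@dataclass
class NerveGroundTruth:
    """Known per-voxel (or per-slice) tensor state used by the forward model.

    ``f`` is an axon volume fraction in [0, 1]; it plays no role in the
    signal model and exists only to couple simulated histology to the
    diffusion state.
    """

    D: np.ndarray  # (3,3) symmetric, um^2/ms
    w15: np.ndarray  # 15 unique kurtosis elements
    s0: float = 1.0
    f: float = 0.5

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if np.max(np.abs(self.D - self.D.T)) > 1e-12:
            raise ValueError("D must be symmetric")
        if np.any(np.linalg.eigvalsh(self.D) < -1e-12):
            raise ValueError("D must have nonnegative eigenvalues")
        self.w15 = np.asarray(self.w15, dtype=float)
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("axon volume fraction f must lie in [0, 1]")

    def as_fit(self) -> dki.TensorFit:
        return dki.TensorFit(s0=self.s0, D=self.D, w15=self.w15)


def cylindrical_truth(
    ad: float, rd: float, ak: float = 0.6, rk: float = 1.2,
    s0: float = 1.0, f: float = 0.5, axis: int = 0,
) -> NerveGroundTruth:
    """Cylindrically symmetric ground truth aligned with a coordinate axis.

    Builds W so that the apparent kurtosis is ``ak`` along the axis and
    ``rk`` across it: W_aaaa = ak*ad^2/md^2, W_rrrr = rk*rd^2/md^2 with
    W_rrr'r' = W_rrrr/3 (flat radial profile) and the axial-radial coupling
    W_aarr = (W_aaaa + W_rrrr)/6, chosen so that ak = rk with ad = rd
    reduces exactly to the fully isotropic kurtosis tensor.
    """
    from itertools import permutations

    lam = [rd, rd, rd]
    lam[axis] = ad
    D = np.diag(lam)
    md = (ad + 2 * rd) / 3.0
    Wfull = np.zeros((3, 3, 3, 3))
    radial = [i for i in range(3) if i != axis]
    a = axis
    wa = ak * ad**2 / md**2
    wr = rk * rd**2 / md**2
    Wfull[a, a, a, a] = wa
    for r in radial:
        Wfull[r, r, r, r] = wr
    r1, r2 = radial
    # flat radial K_app needs W_1122 = W_1111/3 for in-plane directions
    for perm in set(permutations((r1, r1, r2, r2))):
        Wfull[perm] = wr / 3.0
    for r in radial:
        for perm in set(permutations((a, a, r, r))):
            Wfull[perm] = (wa + wr) / 6.0
    return NerveGroundTruth(D=D, w15=dki.full_to_w15(Wfull), s0=s0, f=f)


def simulate_voxel_signal(
    truth: NerveGroundTruth,
    scheme: GradientScheme,
    snr: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Forward DKI signal for one voxel, optionally with Rician noise.

    ``snr`` is S0 over the Gaussian channel noise sigma; the magnitude
    signal is sqrt((S + sigma*g1)^2 + (sigma*g2)^2) with independent
    standard-normal draws, the noise model of magnitude-reconstructed MRI.
    ``snr=None`` returns the noise-free forward model exactly.
    """
    clean = dki.predict_signal(truth.as_fit(), scheme)
    if snr is None:
        return clean
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    sigma = truth.s0 / snr
    g1, g2 = rng.standard_normal((2, clean.size))
    return np.sqrt((clean + sigma * g1) ** 2 + (sigma * g2) ** 2)


def simulate_nerve_volume(
    slice_truths: list[NerveGroundTruth],
    scheme: GradientScheme,
    radius: float = 3.0,
    matrix: tuple[int, int] = (12, 12),
    injury_start: int = 7,
    injury_end: int = 9,
    snr: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tube phantom: a straight nerve along the slice axis.

    Every in-tube voxel of slice ``z`` carries (noisy) signals from
    ``slice_truths[z]``; out-of-tube voxels are pure noise (zero if
    noise-free).  Returns (4-D image, 3-D boolean mask, slice labels).
    """
    n_slices = len(slice_truths)
    nx, ny = matrix
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    if not disk.any():
        raise ValueError("tube radius too small: empty nerve mask")
    mask = np.repeat(disk[:, :, None], n_slices, axis=2)
    labels = label_slices(n_slices, injury_start, injury_end)
    image = np.zeros((nx, ny, n_slices, len(scheme)))
    rng = np.random.default_rng(seed)
    for z, truth in enumerate(slice_truths):
        clean = dki.predict_signal(truth.as_fit(), scheme)
        for i, j in zip(*np.nonzero(disk)):
            if snr is None:
                image[i, j, z] = clean
            else:
                sigma = truth.s0 / snr
                g1, g2 = rng.standard_normal((2, clean.size))
                image[i, j, z] = np.sqrt(
                    (clean + sigma * g1) ** 2 + (sigma * g2) ** 2
                )
    if snr is not None:
        sigma = slice_truths[0].s0 / snr
        bg = ~mask
        n_bg = int(bg.sum())
        g1, g2 = rng.standard_normal((2, n_bg, len(scheme)))
        image[bg] = sigma * np.sqrt(g1**2 + g2**2)
    return image, mask, labels


# ---------------------------------------------------------------------------
# Cohort study generation
# ---------------------------------------------------------------------------


@dataclass
class TensorDistribution:
    """Per-(cohort, week, region) distribution of the slice tensor state.

    ``ratio`` is RD/AD.  Slice-level draws combine an animal-level random
    effect (SDs below) with independent per-slice jitter.
    """

    ad_mean: float
    ad_sd: float
    ratio_mean: float
    ratio_sd: float
    animal_ad_sd: float = 0.05
    animal_ratio_sd: float = 0.03


def _default_tensor_table() -> dict:
    """Emulation table keyed (cohort, week, region[, recovered]).

    Healthy nerve: AD ~ 1.6 um^2/ms, RD/AD ~ 0.20 (FA ~ 0.78).  Weeks 1-2
    after injury are edema/degeneration-dominated (high RD/AD, occasionally
    RD > 1 -> the outlier rule fires, as in real data); by week 4 crush has
    regenerated (low ratio) while cut/repair has not; at week 12 cut/repair
    outcomes are bimodal.  Proximal segments stay near-normal with a mild
    early perturbation.
    """
    healthy = TensorDistribution(1.60, 0.10, 0.20, 0.04)
    t: dict = {}
    for wk in WEEKS:
        for region in ("proximal", "distal"):
            t[("sham", wk, region)] = healthy
    for wk, dist in {
        1: TensorDistribution(1.40, 0.10, 0.65, 0.06),
        2: TensorDistribution(1.20, 0.10, 0.60, 0.06),
        4: TensorDistribution(1.60, 0.12, 0.25, 0.05),
        12: TensorDistribution(1.65, 0.10, 0.22, 0.04),
    }.items():
        t[("crush", wk, "distal")] = dist
    for wk, dist in {
        1: TensorDistribution(1.45, 0.10, 0.70, 0.06),
        2: TensorDistribution(1.35, 0.10, 0.68, 0.06),
        4: TensorDistribution(1.50, 0.12, 0.55, 0.05),
    }.items():
        t[("cut_repair", wk, "distal")] = dist
    t[("cut_repair", 12, "distal", True)] = TensorDistribution(1.60, 0.10, 0.28, 0.04)
    t[("cut_repair", 12, "distal", False)] = TensorDistribution(1.45, 0.10, 0.60, 0.05)
    proximal = {
        1: TensorDistribution(1.55, 0.10, 0.35, 0.05),
        2: TensorDistribution(1.55, 0.10, 0.30, 0.05),
        4: TensorDistribution(1.60, 0.10, 0.22, 0.04),
        12: TensorDistribution(1.60, 0.10, 0.20, 0.04),
    }
    for cohort in ("crush", "cut_repair"):
        for wk, dist in proximal.items():
            t[(cohort, wk, "proximal")] = dist
    return t


@dataclass
class StudyConfig:
    """Design and emulation parameters of a synthetic cohort study."""

    seed: int = 0
    cohort_sizes: dict = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_COHORT_SIZES.items()}
    )
    tensor_table: dict = field(default_factory=_default_tensor_table)
    #: generating separator of the week-4 distal training clusters
    boundary_slope: float = 0.40
    boundary_intercept: float = -0.03
    #: total vertical gap (um^2/ms) kept clear about that line at week 4
    separation_margin: float = 0.10
    recovered_fraction_wk12: float = 0.5
    snr: float = 30.0
    n_slices: int = 16
    injury_start: int = 7
    injury_end: int = 9
    #: slice-level measurement noise added to each index
    slice_noise_sd: float = 0.015
    # behavior (SFI: 0 normal, -100 complete loss; FF: 0 normal, 1 maximal)
    sfi_drop: float = -90.0
    ff_drop: float = 0.85
    sfi_noise_sd: float = 3.0
    ff_noise_sd: float = 0.03
    recovery_midpoint: dict = field(
        default_factory=lambda: {
            "sham": 0.5, "crush": 3.0, "cut_repair_recovered": 8.0,
            "cut_repair_nonrecovered": 8.0,
        }
    )
    recovery_plateau: dict = field(
        default_factory=lambda: {
            "sham": 1.0, "crush": 0.97, "cut_repair_recovered": 0.90,
            "cut_repair_nonrecovered": 0.25,
        }
    )
    recovery_rate_weeks: float = 1.5
    # histology coupling: density = density_scale * f + noise (axons/um^2)
    density_scale: float = 0.03
    density_noise_sd: float = 0.002

    def __post_init__(self) -> None:
        for cohort, sizes in self.cohort_sizes.items():
            if cohort not in COHORTS:
                raise ValueError(f"unknown cohort {cohort!r}")
            for wk, n in sizes.items():
                if wk not in WEEKS:
                    raise ValueError(f"unknown timepoint {wk} for {cohort}")
                if n < 0:
                    raise ValueError("cohort sizes must be >= 0")
                key = (cohort, wk, "distal")
                if n > 0 and key not in self.tensor_table and (
                    (cohort, wk, "distal", True) not in self.tensor_table
                ):
                    raise ValueError(
                        f"no tensor distribution for cohort {cohort!r} at "
                        f"week {wk}"
                    )
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if not 0.0 <= self.recovered_fraction_wk12 <= 1.0:
            raise ValueError("recovered fraction must lie in [0, 1]")


@dataclass
class StudyTables:
    """Everything simulate_study produces."""

    records: pd.DataFrame  # slice records (SLICE_COLUMNS schema)
    behavior: pd.DataFrame  # animal_id, cohort, week, sfi, ff
    histology: pd.DataFrame  # animal_id, cohort, week, axon_density
    ground_truth: pd.DataFrame  # per-animal f, recovered flag, mean ratio


def _recovery_curve(weeks: np.ndarray, mid: float, plateau: float, rate: float):
    """Logistic fraction-recovered time course; 0 pre-surgery is handled
    by the caller (week 0 is pre-op baseline)."""
    return plateau / (1.0 + np.exp(-(weeks - mid) / rate))


def _animal_rng(seed: int, cohort: str, week: int, idx: int, purpose: int):
    """Independent stream per (animal, purpose), stable across runs."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, COHORTS.index(cohort), week, idx, purpose]
    )


def _draw_slice_state(
    rng, dist: TensorDistribution, ad_shift: float, ratio_shift: float,
    enforce_line=None,
):
    """One slice's (ad, ratio); optionally reject into the separable zone.

    ``enforce_line`` = (slope, intercept, half_margin, side) keeps the
    point's RD strictly on ``side`` (+1 above / -1 below) of the line with
    vertical clearance >= half_margin.
    """
    for _ in range(1000):
        ad = rng.normal(dist.ad_mean + ad_shift, dist.ad_sd)
        ratio = rng.normal(dist.ratio_mean + ratio_shift, dist.ratio_sd)
        if ad <= 0.2 or ratio <= 0.02:
            continue
        if enforce_line is None:
            return ad, ratio
        slope, intercept, half_margin, side = enforce_line
        rd = ratio * ad
        clearance = side * (rd - (slope * ad + intercept))
        if clearance >= half_margin:
            return ad, ratio
    raise RuntimeError("rejection sampling failed: margin incompatible with "
                       "the configured cluster distribution")


def simulate_study(config: StudyConfig | None = None) -> StudyTables:
    """Generate a full synthetic cohort study.

    One animal per roster entry; each contributes proximal and distal
    slice records at its endpoint week, a weekly behavioral series from
    pre-surgery (week 0) to euthanasia, and one endpoint axon density.
    Week-4 distal crush records are kept strictly below — and cut/repair
    records strictly above — the generating line
    RD = slope*AD + intercept with the configured vertical margin, so the
    training clusters are linearly separable by construction.
    Deterministic for a fixed config (single master seed; per-animal
    substreams).
    """
    cfg = config or StudyConfig()
    labels = label_slices(cfg.n_slices, cfg.injury_start, cfg.injury_end)
    slice_rows, behav_rows, hist_rows, truth_rows = [], [], [], []
    for cohort in COHORTS:
        for week in WEEKS:
            n_animals = cfg.cohort_sizes.get(cohort, {}).get(week, 0)
            for idx in range(n_animals):
                animal_id = f"{cohort}_w{week:02d}_{idx:02d}"
                rng_t = _animal_rng(cfg.seed, cohort, week, idx, 0)
                rng_b = _animal_rng(cfg.seed, cohort, week, idx, 1)
                rng_h = _animal_rng(cfg.seed, cohort, week, idx, 2)
                # recovery status drives week-12 cut/repair bimodality
                if cohort == "cut_repair" and week == 12:
                    recovered = rng_t.random() < cfg.recovered_fraction_wk12
                elif cohort == "cut_repair":
                    recovered = False
                else:
                    recovered = True
                distal_ratios = []
                for region in ("proximal", "distal"):
                    key = (cohort, week, region, recovered)
                    dist = cfg.tensor_table.get(key) or cfg.tensor_table[
                        (cohort, week, region)
                    ]
                    ad_shift = rng_t.normal(0.0, dist.animal_ad_sd)
                    ratio_shift = rng_t.normal(0.0, dist.animal_ratio_sd)
                    enforce = None
                    if (
                        region == "distal"
                        and week == 4
                        and cohort in ("crush", "cut_repair")
                    ):
                        side = -1.0 if cohort == "crush" else 1.0
                        enforce = (
                            cfg.boundary_slope,
                            cfg.boundary_intercept,
                            cfg.separation_margin / 2.0,
                            side,
                        )
                    z_indices = np.nonzero(labels == region)[0]
                    for z in z_indices:
                        ad, ratio = _draw_slice_state(
                            rng_t, dist, ad_shift, ratio_shift, enforce
                        )
                        rd = ratio * ad
                        md = (ad + 2 * rd) / 3.0
                        fa = dki.fa_from_ratio(ratio)
                        rk = 1.6 - 1.8 * ratio + rng_t.normal(0, 0.08)
                        ak = 0.5 + 0.5 * ratio + rng_t.normal(0, 0.06)
                        mk = (ak + 2 * rk) / 3.0 + rng_t.normal(0, 0.04)
                        jit = cfg.slice_noise_sd
                        slice_rows.append({
                            "animal_id": animal_id, "cohort": cohort,
                            "week": week, "region": region, "slice_index": z,
                            "fa": fa + rng_t.normal(0, jit),
                            "md": md, "ad": ad, "rd": rd,
                            "mk": mk, "ak": ak, "rk": rk,
                            "n_voxels": int(rng_t.integers(20, 40)),
                        })
                        if region == "distal":
                            distal_ratios.append(ratio)
                # behavior: weekly series, week 0 = pre-surgery baseline
                state = (
                    f"cut_repair_{'recovered' if recovered else 'nonrecovered'}"
                    if cohort == "cut_repair" else cohort
                )
                mid = cfg.recovery_midpoint[state]
                plateau = cfg.recovery_plateau[state]
                wk_axis = np.arange(0, week + 1)
                rec = _recovery_curve(
                    wk_axis.astype(float), mid, plateau, cfg.recovery_rate_weeks
                )
                sfi = cfg.sfi_drop * (1.0 - rec) + rng_b.normal(
                    0, cfg.sfi_noise_sd, wk_axis.size
                )
                ff = cfg.ff_drop * (1.0 - rec) + rng_b.normal(
                    0, cfg.ff_noise_sd, wk_axis.size
                )
                sfi[0] = rng_b.normal(0, cfg.sfi_noise_sd / 3)
                ff[0] = abs(rng_b.normal(0, cfg.ff_noise_sd / 3))
                for w_i, s_i, f_i in zip(wk_axis, sfi, ff):
                    behav_rows.append({
                        "animal_id": animal_id, "cohort": cohort,
                        "endpoint_week": week, "week": int(w_i),
                        "sfi": float(min(s_i, 5.0)),
                        "ff": float(np.clip(f_i, 0.0, 1.0)),
                    })
                # histology: density couples to mean distal state via f
                mean_ratio = float(np.mean(distal_ratios))
                f_axon = float(np.clip(0.75 - 0.8 * (mean_ratio - 0.20), 0.05, 0.95))
                density = cfg.density_scale * f_axon + rng_h.normal(
                    0, cfg.density_noise_sd
                )
                hist_rows.append({
                    "animal_id": animal_id, "cohort": cohort, "week": week,
                    "axon_density": max(density, 0.0),
                })
                truth_rows.append({
                    "animal_id": animal_id, "cohort": cohort, "week": week,
                    "f": f_axon, "recovered": recovered,
                    "mean_distal_ratio": mean_ratio,
                })
    records = pd.DataFrame(slice_rows)[SLICE_COLUMNS]
    return StudyTables(
        records=records,
        behavior=pd.DataFrame(behav_rows),
        histology=pd.DataFrame(hist_rows),
        ground_truth=pd.DataFrame(truth_rows),
    )
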