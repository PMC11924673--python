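"""Synthetic cardiac native T1-map generator.

Emulates the statistical structure of a DMD cardiac MRI cohort: annular
mid-ventricular myocardial ROIs on a 256x256 grid, class-conditional T1
intensity fields (LGE- vs LGE+), repeated contouring by multiple readers
for reproducibility analysis, and longitudinal yearly series with
monotonically progressing LGE status.

The myocardial texture is a stationary Gaussian random field (GRF) with
squared-exponential covariance synthesized spectrally (FFT), so a single
correlation-length knob controls spatial homogeneity.  LGE+ tissue gets a
longer correlation length (coarser, more homogeneous texture — lower zone
percentage, higher binned-histogram entropy) and optionally focal
intramural-like intensity patches.  Lesion fields are mean-centred over the
annulus so the configured class means stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_prep import ContourSet, GeometryError, MyocardialMask, T1Map, rasterize_ring_mask

N_CONTOUR_VERTICES = 64


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults reflect the emulated study conditions."""

    grid_size: int = 256
    pixel_spacing_mm: float = 1.0
    center_mm: tuple[float, float] | None = None  # default: grid centre
    endo_radius_mm: float = 18.0
    epi_radius_mm: float = 26.0
    t1_mean_neg: float = 1032.0  # ms, global native T1, LGE-
    t1_mean_pos: float = 1044.0  # ms, global native T1, LGE+
    t1_sd: float = 45.0  # ms, pixel-level myocardial spread
    texture_corr_len_neg: float = 2.0  # px
    texture_corr_len_pos: float = 3.5  # px
    lesion_rate_pos: float = 1.5  # Poisson mean of focal patches per LGE+ case
    lesion_amplitude: float = 60.0  # ms
    n_pos: int = 23
    n_neg: int = 19
    age_mean: float = 13.0  # years
    age_sd: float = 3.3
    age_range: tuple[float, float] = (7.0, 22.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.endo_radius_mm < self.epi_radius_mm):
            raise GeometryError("need 0 < endo radius < epi radius")
        half_extent = self.grid_size / 2 * self.pixel_spacing_mm
        if self.epi_radius_mm >= half_extent:
            raise GeometryError("epicardial radius does not fit in the grid")
        if self.t1_sd <= 0:
            raise ValueError("t1_sd must be positive")
        if min(self.n_pos, self.n_neg) < 0:
            raise ValueError("case counts must be >= 0")

    @property
    def center(self) -> tuple[float, float]:
        if self.center_mm is not None:
            return self.center_mm
        c = (self.grid_size - 1) / 2 * self.pixel_spacing_mm
        return (c, c)


@dataclass
class SyntheticCase:
    case_id: str
    lge_status: int  # 0 = LGE-, 1 = LGE+
    age: float
    t1_map: T1Map
    contours: ContourSet
    exam_year: int = 0
    patient_id: str = ""
    texture_driver: float = 0.0  # latent patient-level severity (longitudinal use)


def gaussian_random_field(
    shape: tuple[int, int], corr_len_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance stationary GRF, squared-exponential covariance.

    Spectral synthesis: white noise filtered with the square root of the
    power spectrum of ``exp(-r^2 / (2 l^2))`` on the torus.
    """
    rows, cols = shape
    fr = np.fft.fftfreq(rows)[:, None]
    fc = np.fft.fftfreq(cols)[None, :]
    # FT of a squared-exponential kernel is squared-exponential in frequency
    spec = np.exp(-2.0 * (np.pi * corr_len_px) ** 2 * (fr**2 + fc**2))
    noise = rng.standard_normal(shape)
    f = np.real(np.fft.ifft2(np.fft.fft2(noise) * np.sqrt(spec)))
    sd = f.std()
    return f / sd if sd > 0 else f


def _circle_contour(center_mm: tuple[float, float], radius_mm: float) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, N_CONTOUR_VERTICES, endpoint=False)
    x = center_mm[0] + radius_mm * np.cos(theta)
    y = center_mm[1] + radius_mm * np.sin(theta)
    return np.column_stack([x, y])


def _annulus_coords(config: SyntheticConfig, shape: tuple[int, int]):
    s = config.pixel_spacing_mm
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = config.center
    return np.hypot(cc * s - cx, rr * s - cy)


def _lesion_field(
    config: SyntheticConfig, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Sum of mean-centred Gaussian bumps at mid-wall positions."""
    n_lesions = rng.poisson(config.lesion_rate_pos)
    field_ = np.zeros(shape)
    if n_lesions == 0:
        return field_
    s = config.pixel_spacing_mm
    cx, cy = config.center
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    x, y = cc * s, rr * s
    for _ in range(n_lesions):
        theta = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(config.endo_radius_mm + 1.0, config.epi_radius_mm - 1.0)
        lx, ly = cx + rad * np.cos(theta), cy + rad * np.sin(theta)
        sigma = rng.uniform(2.0, 5.0) * s  # mm
        field_ += config.lesion_amplitude * np.exp(
            -((x - lx) ** 2 + (y - ly) ** 2) / (2 * sigma**2)
        )
    dist = _annulus_coords(config, shape)
    annulus = (dist >= config.endo_radius_mm) & (dist <= config.epi_radius_mm)
    field_ -= field_[annulus].mean()
    return field_


def generate_case(
    config: SyntheticConfig,
    lge_status: int,
    seed: int,
    case_id: str | None = None,
    corr_len_override: float | None = None,
) -> SyntheticCase:
    """One synthetic case: class-mean T1 plus GRF texture (plus lesions if LGE+)."""
    rng = np.random.default_rng(seed)
    shape = (config.grid_size, config.grid_size)
    mean = config.t1_mean_pos if lge_status else config.t1_mean_neg
    corr = (
        corr_len_override
        if corr_len_override is not None
        else (config.texture_corr_len_pos if lge_status else config.texture_corr_len_neg)
    )
    myo = mean + config.t1_sd * gaussian_random_field(shape, corr, rng)
    if lge_status and config.lesion_rate_pos > 0:
        myo = myo + _lesion_field(config, shape, rng)

    dist = _annulus_coords(config, shape)
    blood = 1600.0 + 30.0 * rng.standard_normal(shape)  # LV blood pool
    background = 350.0 + 60.0 * np.abs(rng.standard_normal(shape))
    pixels = np.where(dist < config.endo_radius_mm, blood, background)
    ring = (dist >= config.endo_radius_mm - 2) & (dist <= config.epi_radius_mm + 2)
    pixels = np.where(ring, myo, pixels)
    pixels = np.maximum(pixels, 1.0)

    age = float(
        np.clip(
            config.age_mean + config.age_sd * rng.standard_normal(), *config.age_range
        )
    )
    contours = ContourSet(
        endo=_circle_contour(config.center, config.endo_radius_mm),
        epi=_circle_contour(config.center, config.epi_radius_mm),
    )
    cid = case_id or f"case_{seed:06d}"
    spacing = (config.pixel_spacing_mm, config.pixel_spacing_mm)
    return SyntheticCase(
        case_id=cid,
        lge_status=int(bool(lge_status)),
        age=age,
        t1_map=T1Map(pixels, spacing, cid),
        contours=contours,
    )


def generate_cohort(config: SyntheticConfig) -> list[SyntheticCase]:
    """n_pos LGE+ and n_neg LGE- cases, seeds derived from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=config.n_pos + config.n_neg)
    statuses = [1] * config.n_pos + [0] * config.n_neg
    return [
        generate_case(config, st, int(sd), case_id=f"case_{i:03d}")
        for i, (st, sd) in enumerate(zip(statuses, seeds))
    ]


def _perturb_contour(
    poly: np.ndarray, center: tuple[float, float], jitter_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Radial perturbation with smooth angular noise of amplitude jitter_mm."""
    dx = poly[:, 0] - center[0]
    dy = poly[:, 1] - center[1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    bump = np.zeros_like(theta)
    for m in (1, 2, 3):
        bump += rng.normal() * np.cos(m * theta) + rng.normal() * np.sin(m * theta)
    mx = np.abs(bump).max()
    if mx > 0:
        bump *= jitter_mm / mx
    r_new = r + bump
    return np.column_stack(
        [center[0] + r_new * np.cos(theta), center[1] + r_new * np.sin(theta)]
    )


def generate_reader_variants(
    case: SyntheticCase,
    n_readers: int = 2,
    n_repeats: int = 2,
    jitter_px: float = 1.0,
    seed: int = 0,
    max_retries: int = 10,
) -> list[ContourSet]:
    """``n_readers * n_repeats`` radially perturbed contour sets.

    Ordered reader-major: [(reader 1, pass 1), (reader 1, pass 2),
    (reader 2, pass 1), ...].  jitter 0 returns exact copies.
    """
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")
    rng = np.random.default_rng(seed)
    spacing = case.t1_map.spacing[0]
    jitter_mm = jitter_px * spacing
    cx = case.contours.epi[:, 0].mean()
    cy = case.contours.epi[:, 1].mean()
    center = (cx, cy)
    out: list[ContourSet] = []
    for _ in range(n_readers * n_repeats):
        if jitter_mm == 0:
            out.append(ContourSet(case.contours.endo.copy(), case.contours.epi.copy()))
            continue
        for attempt in range(max_retries):
            endo = _perturb_contour(case.contours.endo, center, jitter_mm, rng)
            epi = _perturb_contour(case.contours.epi, center, jitter_mm, rng)
            r_endo = np.hypot(endo[:, 0] - cx, endo[:, 1] - cy)
            r_epi = np.hypot(epi[:, 0] - cx, epi[:, 1] - cy)
            if r_endo.max() + 0.5 * spacing < r_epi.min():
                out.append(ContourSet(endo, epi))
                break
        else:
            raise GeometryError("could not perturb contours while keeping endo < epi")
    return out


def generate_longitudinal_cohort(
    config: SyntheticConfig,
    n_patients: int = 15,
    n_years: int = 3,
    effect_size: float = 2.0,
    seed: int = 0,
    intercept_sd: float = 1.0,
    baseline_logit: float = -1.0,
    year_slope: float = 0.8,
    driver_corr_scale: float = 0.5,
) -> list[SyntheticCase]:
    """Yearly exam series with monotone LGE progression.

    Each patient carries a latent texture driver d ~ N(0, 1) and a random
    intercept b ~ N(0, intercept_sd^2); the yearly LGE probability is
    ``logistic(baseline_logit + year_slope * t + effect_size * d + b)`` and
    statuses never revert from + to -.  Case texture tracks both the status
    (class correlation length, lesions) and the driver (correlation length
    shifted by ``driver_corr_scale * d``).
    """
    if n_years < 3:
        raise ValueError("longitudinal series need >= 3 yearly exams")
    rng = np.random.default_rng(seed)
    cases: list[SyntheticCase] = []
    for p in range(n_patients):
        driver = float(rng.standard_normal())
        b = float(intercept_sd * rng.standard_normal())
        status = 0
        for t in range(n_years):
            if status == 0:
                eta = baseline_logit + year_slope * t + effect_size * driver + b
                status = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            base = (
                config.texture_corr_len_pos if status else config.texture_corr_len_neg
            )
            corr = float(np.clip(base + driver_corr_scale * driver, 0.5, None))
            case = generate_case(
                config,
                status,
                seed=int(rng.integers(0, 2**31 - 1)),
                case_id=f"pat_{p:03d}_yr{t}",
                corr_len_override=corr,
            )
            case.exam_year = t
            case.patient_id = f"pat_{p:03d}"
            case.texture_driver = driver
            cases.append(case)
    return cases


def case_mask(case: SyntheticCase) -> MyocardialMask:
    """Rasterize a case's contours on its own grid."""
    return rasterize_ring_mask(
        case.contours, case.t1_map.pixels.shape, case.t1_map.spacing
    )
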