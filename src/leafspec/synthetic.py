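"""Forward simulation of paired leaf reflectance/transmittance spectra.

The generator emulates a two-probe contact measurement of tobacco leaves
grown under full sun or deep shade.  Each leaf is described by true pigment
contents (Chl a, Chl b, carotenoids, g m-2), a structural factor that
perturbs the leaf-surface reflectance mainly in the green band around
550 nm, and a backscatter fraction that splits the non-absorbed flux
between the reflected and transmitted channels.

Optical model (one leaf, wavelength lambda):

    tau(lambda) = tau0 + alpha * sum_p k_p(lambda) * C_p
    rho(lambda) = rho0 + rho_s * s_i * G(550, 40)(lambda)
    A(lambda)   = (1 - rho) * (1 - exp(-tau))
    R(lambda)   = rho + (1 - rho) * exp(-tau) * b_i
    T(lambda)   = (1 - rho) * exp(-tau) * (1 - b_i)

with unit-peak Gaussian-sum specific absorption profiles k_p, a global
absorption scale alpha (m2 g-1), leaf structural factor s_i ~ N(0,1)
truncated to [-2, 2] and backscatter fraction b_i ~ Uniform.  The clean
channels partition the incident flux exactly: R + T + A = 1.  Sensor
noise is added independently to R and T per band; the matching wet-lab
extract assay is built by inverting the quantification equations for the
true pigments and adding spectrophotometer noise.

Because the backscatter split b_i cancels from A = 1 - (R + T) but enters
R directly, absorbance-based calibration sees a cleaner pigment signal
than reflectance-based calibration -- the structural nuisance the
two-sensor measurement is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pigments import (
    ExtractAssay,
    carotenoid_absorbance,
    invert_chlorophyll_system,
    pigments_to_frame,
)
from .spectra import (
    DEFAULT_GRID,
    LeafSpectralRecord,
    SpectralDataset,
    WavelengthGrid,
    write_spectra_csv,
)

#: Published per-leaf-area concentration ranges (g m-2) the simulated
#: population is clipped into.
PIGMENT_RANGES = {
    "chl_a": (0.13, 0.46),
    "chl_b": (0.058, 0.19),
    "chl_ab": (0.19, 0.65),
    "car": (0.033, 0.16),
}

#: Fixed assay geometry: 2 cm2 punch in 10 mL, no dilution, so that
#: extract mg L-1 = 20 x leaf g m-2.
ASSAY_VOLUME_ML = 10.0
ASSAY_AREA_M2 = 2e-4
G_M2_TO_MG_L = 20.0

# Gaussian absorption bands (center nm, width nm, relative height) per
# pigment; blue and red chlorophyll peaks, broad blue carotenoid band.
_PROFILE_BANDS = {
    "chl_a": [(430.0, 18.0, 1.0), (662.0, 12.0, 0.8)],
    "chl_b": [(453.0, 18.0, 1.0), (642.0, 12.0, 0.55)],
    "car": [(425.0, 20.0, 0.9), (450.0, 18.0, 1.0), (480.0, 16.0, 0.85)],
}


def gaussian_band(wavelengths, center_nm: float, sigma_nm: float):
    """Unit-height Gaussian G(center, sigma) evaluated on a wavelength axis."""
    wl = np.asarray(wavelengths, dtype=float)
    return np.exp(-((wl - center_nm) ** 2) / (2.0 * sigma_nm**2))


def pigment_absorption_profile(
    pigment_name: str, grid: WavelengthGrid = DEFAULT_GRID
) -> np.ndarray:
    """Unit-maximum specific absorption profile k(lambda) for one pigment."""
    if pigment_name not in _PROFILE_BANDS:
        raise ValueError(
            f"unknown pigment {pigment_name!r}; "
            f"expected one of {sorted(_PROFILE_BANDS)}"
        )
    wl = grid.wavelengths()
    k = np.zeros(grid.n_bands)
    for center, sigma, height in _PROFILE_BANDS[pigment_name]:
        k += height * gaussian_band(wl, center, sigma)
    return k / k.max()


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic population.

    Defaults reproduce the emulated study design: 150 leaves split evenly
    between sun and shade growth, pigment contents spanning the published
    ranges with sun leaves denser than shade leaves, structural variance
    concentrated in the green band, and small sensor/assay noise.
    """

    n_samples: int = 150
    sun_fraction: float = 0.5
    chl_a_range_sun: tuple[float, float] = (0.25, 0.46)
    chl_a_range_shade: tuple[float, float] = (0.13, 0.30)
    chl_b_ratio_range: tuple[float, float] = (0.33, 0.48)
    car_ratio_range: tuple[float, float] = (0.20, 0.28)
    absorption_scale: float = 7.0      # alpha, m2 g-1
    baseline_od: float = 0.05          # tau0
    surface_reflectance: float = 0.04  # rho0
    structural_amplitude: float = 0.06  # rho_s
    structural_band_center: float = 550.0
    structural_band_width: float = 40.0
    backscatter_range: tuple[float, float] = (0.35, 0.65)
    sensor_noise_sd: float = 0.003     # per band, fraction units
    assay_noise_sd: float = 0.002      # absorbance units
    seed: int = 202304

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0.0 <= self.sun_fraction <= 1.0:
            raise ValueError("sun_fraction must be in [0, 1]")
        for name in ("chl_a_range_sun", "chl_a_range_shade",
                     "chl_b_ratio_range", "car_ratio_range",
                     "backscatter_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: low must be < high")
        if not 0.0 <= self.surface_reflectance <= 1.0:
            raise ValueError("surface_reflectance must be a fraction")
        if self.sensor_noise_sd < 0 or self.assay_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth per-sample state, kept for parameter-recovery tests."""

    sample_ids: list[str]
    groups: list[str]
    chl_a: np.ndarray
    chl_b: np.ndarray
    chl_ab: np.ndarray
    car: np.ndarray
    structural: np.ndarray
    backscatter: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "group": self.groups,
            "chl_a_g_m2": self.chl_a,
            "chl_b_g_m2": self.chl_b,
            "chl_ab_g_m2": self.chl_ab,
            "car_g_m2": self.car,
            "structural_factor": self.structural,
            "backscatter_fraction": self.backscatter,
        })


def sample_pigments(config: GeneratorConfig, rng: np.random.Generator) -> SyntheticTruth:
    """Draw true pigment contents for the population.

    Sun leaves draw Chl a high, shade leaves low; Chl b and carotenoids
    follow physiological ratios; every marginal is clipped into its
    published range.  Structural and backscatter factors are drawn here
    too so one stream controls the whole per-leaf state.
    """
    n = config.n_samples
    is_sun = rng.random(n) < config.sun_fraction
    lo_s, hi_s = config.chl_a_range_sun
    lo_h, hi_h = config.chl_a_range_shade
    chl_a = np.where(is_sun,
                     rng.uniform(lo_s, hi_s, n),
                     rng.uniform(lo_h, hi_h, n))
    chl_b = chl_a * rng.uniform(*config.chl_b_ratio_range, n)
    chl_a = np.clip(chl_a, *PIGMENT_RANGES["chl_a"])
    chl_b = np.clip(chl_b, *PIGMENT_RANGES["chl_b"])
    car = (chl_a + chl_b) * rng.uniform(*config.car_ratio_range, n)
    car = np.clip(car, *PIGMENT_RANGES["car"])
    chl_ab = chl_a + chl_b

    # truncated standard normal on [-2, 2] via rejection
    s = rng.standard_normal(n)
    while np.any(np.abs(s) > 2.0):
        bad = np.abs(s) > 2.0
        s[bad] = rng.standard_normal(int(bad.sum()))
    b = rng.uniform(*config.backscatter_range, n)

    ids = [f"leaf_{i + 1:03d}" for i in range(n)]
    groups = ["sun" if flag else "shade" for flag in is_sun]
    return SyntheticTruth(ids, groups, chl_a, chl_b, chl_ab, car, s, b)


def _clean_optics(chl_a, chl_b, car, s_i, b_i, config, grid):
    wl = grid.wavelengths()
    tau = config.baseline_od + config.absorption_scale * (
        pigment_absorption_profile("chl_a", grid) * chl_a
        + pigment_absorption_profile("chl_b", grid) * chl_b
        + pigment_absorption_profile("car", grid) * car
    )
    rho = config.surface_reflectance + (
        config.structural_amplitude
        * s_i
        * gaussian_band(wl, config.structural_band_center,
                        config.structural_band_width)
    )
    trans = np.exp(-tau)
    A = (1.0 - rho) * (1.0 - trans)
    R = rho + (1.0 - rho) * trans * b_i
    T = (1.0 - rho) * trans * (1.0 - b_i)
    return R, T, A


def _make_record(
    truth: SyntheticTruth,
    index: int,
    config: GeneratorConfig,
    grid: WavelengthGrid,
    sensor_rng: np.random.Generator,
    assay_rng: np.random.Generator,
) -> tuple[LeafSpectralRecord, ExtractAssay]:
    R_clean, T_clean, _ = _clean_optics(
        truth.chl_a[index], truth.chl_b[index], truth.car[index],
        truth.structural[index], truth.backscatter[index], config, grid,
    )
    R = np.clip(
        R_clean + sensor_rng.normal(0.0, config.sensor_noise_sd, grid.n_bands),
        0.0, 1.0,
    )
    T = np.clip(
        T_clean + sensor_rng.normal(0.0, config.sensor_noise_sd, grid.n_bands),
        0.0, 1.0,
    )
    record = LeafSpectralRecord(
        sample_id=truth.sample_ids[index],
        group_label=truth.groups[index],
        R=R,
        T=T,
    )

    chl_a_l = truth.chl_a[index] * G_M2_TO_MG_L
    chl_b_l = truth.chl_b[index] * G_M2_TO_MG_L
    car_l = truth.car[index] * G_M2_TO_MG_L
    a663, a646 = invert_chlorophyll_system(chl_a_l, chl_b_l)
    a470 = carotenoid_absorbance(car_l, chl_a_l, chl_b_l)
    noise = assay_rng.normal(0.0, config.assay_noise_sd, 3)
    assay = ExtractAssay(
        a663=a663 + noise[0],
        a646=a646 + noise[1],
        a470=a470 + noise[2],
        volume_ml=ASSAY_VOLUME_ML,
        dilution_factor=1.0,
        leaf_area_m2=ASSAY_AREA_M2,
    )
    return record, assay


def generate_record(
    truth: SyntheticTruth,
    index: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> tuple[LeafSpectralRecord, ExtractAssay]:
    """Simulate one leaf's noisy (R, T) record and its matching extract assay."""
    return _make_record(truth, index, config, grid, rng, rng)


@dataclass
class SyntheticStudy:
    """One generated study: spectra, measured pigment table, ground truth."""

    dataset: SpectralDataset
    assays: list[ExtractAssay]
    pigments: pd.DataFrame  # measured (assay-derived) pigment table, g m-2
    truth: SyntheticTruth
    config: GeneratorConfig = field(repr=False, default=None)

    def save(self, outdir) -> dict[str, Path]:
        """Write spectra, pigment and truth CSVs; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "spectra": outdir / "spectra.csv",
            "pigments": outdir / "pigments.csv",
            "truth": outdir / "truth.csv",
        }
        write_spectra_csv(self.dataset, paths["spectra"])
        self.pigments.to_csv(paths["pigments"], index=False,
                             float_format="%.12g")
        self.truth.to_frame().to_csv(paths["truth"], index=False,
                                     float_format="%.12g")
        return paths


def generate_dataset(
    config: GeneratorConfig | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> SyntheticStudy:
    """Generate the full synthetic study population, fully seeded.

    Separate child streams drive pigment sampling, sensor noise and assay
    noise so the draws stay reproducible under a single root seed.
    """
    from .pigments import assay_to_pigments

    if config is None:
        config = GeneratorConfig()
    root = np.random.SeedSequence(config.seed)
    pig_seq, sensor_seq, assay_seq = root.spawn(3)
    truth = sample_pigments(config, np.random.default_rng(pig_seq))
    sensor_rng = np.random.default_rng(sensor_seq)
    assay_rng = np.random.default_rng(assay_seq)

    records, assays, measured = [], [], []
    for i in range(config.n_samples):
        record, assay = _make_record(truth, i, config, grid,
                                     sensor_rng, assay_rng)
        records.append(record)
        assays.append(assay)
        measured.append(assay_to_pigments(assay))

    dataset = SpectralDataset(
        grid=grid, records=records,
        provenance=f"synthetic leaf-optics generator, seed={config.seed}",
    )
    pigment_df = pigments_to_frame(truth.sample_ids, measured)
    return SyntheticStudy(dataset=dataset, assays=assays,
                          pigments=pigment_df, truth=truth, config=config)
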