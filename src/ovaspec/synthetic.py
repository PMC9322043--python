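"""Seeded synthetic egg hypercubes with known S-ovalbumin ground truth.

Emulates a visible/NIR transmittance imaging study of eggs stored at room
temperature: each egg is an elliptical region of interest whose per-pixel
transmittance spectrum follows a Beer-Lambert-style model with fixed
absorption lobes (pigment and water bands near 589, 643, 750 and 970 nm)
plus content-dependent lobes, multiplied by a per-egg scatter gain and
shifted by a per-egg offset.  The reference chemistry is a simulated
spectrophotometric heated/unheated absorbance ratio.

Everything is a pure function of (design, seed), so the downstream pipeline
is fully testable without any measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .hsi_io import HyperCube

__all__ = [
    "StorageDesign",
    "GroundTruth",
    "EggSample",
    "make_wavelength_grid",
    "storage_curve",
    "spectrum_model",
    "simulate_spectrophotometry",
    "iter_eggs",
    "generate_dataset",
    "make_reference_cubes",
]

# Total bands on the nominal 401-1002 nm grid, and the count at/above the
# effective 435 nm cutoff.  The grid is built piecewise so the crop count
# is exact by construction.
N_BANDS_TOTAL = 478
N_BANDS_EFFECTIVE = 449

DEFAULT_STORAGE_DAYS = tuple(range(0, 28, 3))  # 0, 3, ..., 27

# Logistic surrogate for the storage-time trend of the S-ovalbumin fraction.
LOGISTIC_LOW = 0.11
LOGISTIC_HIGH = 0.95
LOGISTIC_RATE = 0.25
LOGISTIC_MIDPOINT = 12.0

# Per-egg biological/instrumental variation (fractions and transmittance
# units).  Chosen once to reproduce a wide (~11-95%) content range with a
# clearly monotone storage trend; see docs/methods.md.
CONTENT_JITTER_SD = 0.04
CONTENT_CLIP = (0.10, 0.95)
GAIN_LOG_SD = 0.15
OFFSET_SD = 0.01
PIXEL_FIELD_SD = 0.03
PIXEL_FIELD_SMOOTH = 3.0
NOISE_SD = 0.004
LOW_SNR_NOISE_FACTOR = 6.0  # extra noise below 435 nm
REFERENCE_CV = 0.03

# Camera count levels for the raw/white/dark cubes.
DARK_LEVEL = 100.0
WHITE_LEVEL = 3800.0
WHITE_NOISE_SD = 5.0
DARK_NOISE_SD = 2.0
RAW_NOISE_SD = 5.0
BACKGROUND_T = 0.005


@dataclass(frozen=True)
class StorageDesign:
    """Storage experiment layout: which days are sampled and how many eggs."""

    storage_days: tuple = DEFAULT_STORAGE_DAYS
    eggs_per_day: int = 18
    seed: int = 0

    def __post_init__(self):
        days = tuple(int(d) for d in self.storage_days)
        if any(d < 0 for d in days):
            raise ValueError("storage days must be non-negative")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("storage days must be strictly increasing")
        if self.eggs_per_day < 1:
            raise ValueError("eggs_per_day must be >= 1")
        object.__setattr__(self, "storage_days", days)

    @property
    def n_samples(self) -> int:
        return len(self.storage_days) * self.eggs_per_day


@dataclass(frozen=True)
class GroundTruth:
    """Per-egg latent state: true content, noisy reference, scatter params."""

    sample_id: str
    storage_day: int
    true_content: float          # fraction in [0, 1]
    reference_content: float     # percent, simulated spectrophotometry
    scatter_gain: float
    scatter_offset: float


@dataclass
class EggSample:
    """One simulated egg: raw cube, planted ROI stencil and ground truth."""

    cube: HyperCube
    mask: np.ndarray
    truth: GroundTruth


def make_wavelength_grid() -> np.ndarray:
    """Nominal 478-band wavelength axis (nm), 401-1002 nm ascending.

    29 bands cover the low-SNR 401-434.5 nm region and 449 bands the
    effective 435-1002 nm range, so cropping at 435 nm retains exactly 449
    bands.
    """
    low = np.linspace(401.0, 434.5, N_BANDS_TOTAL - N_BANDS_EFFECTIVE)
    high = np.linspace(435.0, 1002.0, N_BANDS_EFFECTIVE)
    return np.concatenate([low, high])


def storage_curve(day: float) -> float:
    """Expected S-ovalbumin fraction after ``day`` days of storage.

    Four-parameter logistic rising from ~0.15 at lay toward 0.95, with
    midpoint at day 12 — a smooth stand-in for the observed monotone
    conversion of ovalbumin into its thermostable form.
    """
    day = float(day)
    if day < 0:
        raise ValueError("storage day must be non-negative")
    span = LOGISTIC_HIGH - LOGISTIC_LOW
    return LOGISTIC_LOW + span / (1.0 + np.exp(-LOGISTIC_RATE * (day - LOGISTIC_MIDPOINT)))


def _gaussian_lobes(wl: np.ndarray, centers, amps, widths) -> np.ndarray:
    out = np.zeros_like(wl)
    for c, a, w in zip(centers, amps, widths):
        out += a * np.exp(-(((wl - c) / w) ** 2))
    return out


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth shell/albumen transmission envelope peaking in the red/NIR."""
    return 0.35 + 0.45 * np.exp(-(((wl - 720.0) / 180.0) ** 2))


def _absorbance_fixed(wl: np.ndarray) -> np.ndarray:
    """Content-independent absorbance: protoporphyrin (589, 643 nm) and
    water O-H overtones (750, 970 nm) plus a small flat term."""
    return 0.05 + _gaussian_lobes(
        wl,
        centers=(589.0, 643.0, 750.0, 970.0),
        amps=(0.50, 0.40, 0.35, 0.60),
        widths=(18.0, 15.0, 25.0, 30.0),
    )


def _absorbance_content(wl: np.ndarray) -> np.ndarray:
    """Absorbance per unit S-ovalbumin fraction: lobes in the 700-960 nm
    region (protein/water interaction bands) plus a broad background so the
    mean transmittance falls as content rises."""
    lobes = _gaussian_lobes(
        wl,
        centers=(700.0, 740.0, 870.0, 960.0),
        amps=(0.90, 0.70, 0.50, 0.60),
        widths=(20.0, 18.0, 30.0, 25.0),
    )
    return lobes + 0.15 * np.exp(-(((wl - 800.0) / 150.0) ** 2))


def spectrum_model(
    content: float,
    gain: float = 1.0,
    offset: float = 0.0,
    noise_sd: float = NOISE_SD,
    rng: np.random.Generator | None = None,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Transmittance spectrum of egg material at a given S-ovalbumin fraction.

    T(lambda) = gain * B(lambda) * exp(-[a0(lambda) + content*a1(lambda)])
                + offset + noise,
    where B is a smooth baseline, a0 the fixed absorption lobes and a1 the
    content-dependent ones.  Mean transmittance is strictly decreasing in
    ``content`` because a1 >= 0 everywhere.
    """
    if not 0.0 <= content <= 1.0:
        raise ValueError("content must be a fraction in [0, 1]")
    if gain <= 0:
        raise ValueError("gain must be positive")
    if wavelengths is None:
        wavelengths = make_wavelength_grid()
    t = gain * _baseline(wavelengths) * np.exp(
        -(_absorbance_fixed(wavelengths) + content * _absorbance_content(wavelengths))
    ) + offset
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        t = t + rng.normal(0.0, noise_sd, size=wavelengths.shape)
    return t


def simulate_spectrophotometry(
    true_content: float,
    cv: float = REFERENCE_CV,
    rng: np.random.Generator | None = None,
) -> float:
    """Noisy reference assay: 100 * O_heated / O_unheated, percent.

    O_unheated is a positive lognormal absorbance; the heated reading is the
    true fraction of it with multiplicative Gaussian error of relative size
    ``cv``.  The ratio is clipped to [0, 100].
    """
    if not 0.0 <= true_content <= 1.0:
        raise ValueError("true_content must be in [0, 1]")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    o_unheated = float(np.exp(rng.normal(0.0, 0.1)))
    eta = float(rng.normal(0.0, cv)) if cv > 0 else 0.0
    o_heated = true_content * o_unheated * (1.0 + eta)
    return float(np.clip(100.0 * o_heated / o_unheated, 0.0, 100.0))


def _ellipse_mask(shape, rng: np.random.Generator) -> np.ndarray:
    """Axis-aligned elliptical egg stencil with mild jitter, margins kept."""
    lines, samples = shape
    cy = lines / 2.0 + rng.uniform(-0.03, 0.03) * lines
    cx = samples / 2.0 + rng.uniform(-0.03, 0.03) * samples
    ry = lines * rng.uniform(0.33, 0.38)
    rx = samples * rng.uniform(0.26, 0.31)
    yy, xx = np.mgrid[0:lines, 0:samples]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _white_field(shape, wavelengths: np.ndarray) -> np.ndarray:
    """Deterministic white-board count level: spatial vignetting times a
    smooth lamp spectrum."""
    lines, samples = shape
    yy, xx = np.mgrid[0:lines, 0:samples]
    r2 = ((yy - lines / 2) / lines) ** 2 + ((xx - samples / 2) / samples) ** 2
    vignette = 1.0 - 0.1 * r2 / 0.5
    lamp = 0.7 + 0.3 * np.exp(-(((wavelengths - 700.0) / 250.0) ** 2))
    return WHITE_LEVEL * vignette[:, :, None] * lamp[None, None, :]


def make_reference_cubes(
    cube_shape=(64, 64), rng: np.random.Generator | None = None
) -> tuple[HyperCube, HyperCube]:
    """White (~full transmission) and dark (~zero) reference cubes."""
    if rng is None:
        rng = np.random.default_rng()
    wl = make_wavelength_grid()
    w = _white_field(cube_shape, wl) + rng.normal(0, WHITE_NOISE_SD, cube_shape + (wl.size,))
    d = DARK_LEVEL + rng.normal(0, DARK_NOISE_SD, cube_shape + (wl.size,))
    return (
        HyperCube(w.astype(np.float32), wl),
        HyperCube(d.astype(np.float32), wl),
    )


def _render_egg(
    day: int,
    index: int,
    cube_shape,
    rng: np.random.Generator,
    reference_cv: float,
) -> EggSample:
    wl = make_wavelength_grid()
    mean_content = storage_curve(day)
    true_content = float(
        np.clip(mean_content + rng.normal(0.0, CONTENT_JITTER_SD), *CONTENT_CLIP)
    )
    gain = float(np.exp(rng.normal(0.0, GAIN_LOG_SD)))
    offset = float(rng.normal(0.0, OFFSET_SD))
    # reference assay drawn before any cube-shape-dependent noise, so the
    # ground-truth table is invariant to the rendered cube size
    reference = simulate_spectrophotometry(true_content, cv=reference_cv, rng=rng)
    mask = _ellipse_mask(cube_shape, rng)

    # Spatially smooth content field: uneven distribution inside the egg.
    field = rng.normal(0.0, 1.0, cube_shape)
    field = gaussian_filter(field, PIXEL_FIELD_SMOOTH)
    field *= PIXEL_FIELD_SD / max(field.std(), 1e-12)
    pixel_content = np.clip(true_content + field[mask], 0.02, 0.98)

    # Vectorized Beer-Lambert transmittance for all ROI pixels at once.
    atten = _absorbance_fixed(wl)[None, :] + np.outer(pixel_content, _absorbance_content(wl))
    t_roi = gain * _baseline(wl)[None, :] * np.exp(-atten) + offset

    t = np.full(cube_shape + (wl.size,), BACKGROUND_T)
    t[mask] = t_roi
    noise = rng.normal(0.0, NOISE_SD, t.shape)
    noise[:, :, wl < 435.0] *= LOW_SNR_NOISE_FACTOR
    t += noise

    # Back to raw camera counts relative to the deterministic white/dark
    # levels, with additive sensor noise.
    white = _white_field(cube_shape, wl)
    raw = DARK_LEVEL + t * (white - DARK_LEVEL) + rng.normal(0, RAW_NOISE_SD, t.shape)

    truth = GroundTruth(
        sample_id=f"d{day:02d}_e{index:02d}",
        storage_day=day,
        true_content=true_content,
        reference_content=reference,
        scatter_gain=gain,
        scatter_offset=offset,
    )
    return EggSample(HyperCube(raw.astype(np.float32), wl), mask, truth)


def iter_eggs(
    design: StorageDesign,
    cube_shape=(64, 64),
    reference_cv: float = REFERENCE_CV,
) -> Iterator[EggSample]:
    """Yield eggs one at a time (constant memory for large designs).

    Each egg gets an independent child RNG spawned from the design seed, so
    streaming and batch generation agree egg for egg.
    """
    if min(cube_shape) < 8:
        raise ValueError("cube_shape dimensions must be >= 8")
    n = design.n_samples
    seqs = np.random.SeedSequence(design.seed).spawn(n + 1)
    k = 1
    for day in design.storage_days:
        for i in range(design.eggs_per_day):
            rng = np.random.default_rng(seqs[k])
            k += 1
            yield _render_egg(day, i, cube_shape, rng, reference_cv)


def generate_dataset(
    design: StorageDesign,
    cube_shape=(64, 64),
    reference_cv: float = REFERENCE_CV,
) -> tuple[list[HyperCube], HyperCube, HyperCube, list[GroundTruth]]:
    """Materialize the whole study: per-egg raw cubes, shared white/dark
    reference cubes, and the ground-truth table."""
    seqs = np.random.SeedSequence(design.seed).spawn(design.n_samples + 1)
    white, dark = make_reference_cubes(cube_shape, np.random.default_rng(seqs[0]))
    cubes, truths = [], []
    for egg in iter_eggs(design, cube_shape, reference_cv):
        cubes.append(egg.cube)
        truths.append(egg.truth)
    return cubes, white, dark, truths
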