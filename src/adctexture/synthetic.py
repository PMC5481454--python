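"""Synthetic DWI/ADC phantoms with glioma- and prostate-like protocols.

Real tumour DWI from the motivating cohorts is not public, so every
downstream stage is exercised on seeded phantoms: a spatially correlated
ADC field inside an ellipsoidal ROI, optionally bordered by a high-ADC
fluid-like structure (CSF/urine analogue, mean ~3000 x 1e-6 mm^2/s), and
a mono-exponential signal model S(b) = S0 * exp(-b * ADC * 1e-6) with
additive Gaussian noise on the magnitude signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .preproc import ADCVolume, DWISeries

__all__ = [
    "ProtocolSpec",
    "PhantomSpec",
    "FluidSpec",
    "make_protocol",
    "generate_adc_phantom",
    "simulate_dwi",
    "make_phantom_batch",
    "simulate_batch",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition protocol: b-values, in-plane voxel size and noise level."""

    name: str
    b_values: tuple[float, ...]
    voxel_size: float            # mm, in-plane
    slice_thickness: float       # mm
    native_noise_sigma: float    # signal units
    n_slices: int

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, float)
        if b.size < 2 or np.any(np.diff(b) <= 0) or np.any(b < 0):
            raise ValueError("b_values must be >= 0, strictly increasing, >= 2 entries")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.native_noise_sigma < 0:
            raise ValueError("native_noise_sigma must be >= 0")


_PROTOCOLS = {
    "glioma": ProtocolSpec(
        name="glioma",
        b_values=(0.0, 200.0, 400.0, 600.0, 800.0, 1000.0),
        voxel_size=1.2,
        slice_thickness=3.0,
        native_noise_sigma=17.0,
        n_slices=19,
    ),
    "prostate": ProtocolSpec(
        name="prostate",
        b_values=(0.0, 800.0),
        voxel_size=1.625,
        slice_thickness=3.6,
        native_noise_sigma=2.5,
        n_slices=20,
    ),
}


def make_protocol(name: str) -> ProtocolSpec:
    """Return the named acquisition protocol (``"glioma"`` or ``"prostate"``)."""
    try:
        return _PROTOCOLS[name]
    except KeyError:
        raise ValueError(
            f"unknown protocol {name!r}; choose from {sorted(_PROTOCOLS)}"
        ) from None


@dataclass(frozen=True)
class FluidSpec:
    """An ellipsoidal high-ADC region adjacent to (or overlapping) the ROI."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    mean: float = 3000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of one synthetic tumour ROI.

    The ADC texture is a seeded Gaussian random field: white noise
    smoothed in-plane with a Gaussian kernel of width
    ``correlation_length`` (voxels), then affinely mapped so the in-ROI
    sample mean and standard deviation equal ``adc_mean`` and
    ``adc_amplitude`` exactly (both in 1e-6 mm^2/s).
    """

    grid_shape: tuple[int, int, int] = (60, 60, 4)
    roi_center: tuple[float, float, float] = (30.0, 30.0, 1.5)
    roi_radii: tuple[float, float, float] = (14.0, 12.0, 1.8)
    adc_mean: float = 1000.0
    adc_amplitude: float = 300.0
    correlation_length: float = 2.0
    adjacent_fluid: FluidSpec | None = None
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adc_mean < 0 or (self.adjacent_fluid and self.adjacent_fluid.mean < 0):
            raise ValueError("ADC means must be >= 0")
        if self.adc_amplitude < 0:
            raise ValueError("adc_amplitude must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


def _ellipsoid_mask(grid_shape, center, radii) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=float)
    acc = np.zeros(grid_shape)
    for ax in range(3):
        acc += ((coords[ax] - center[ax]) / radii[ax]) ** 2
    return acc <= 1.0


def generate_adc_phantom(spec: PhantomSpec,
                         voxel_size: float = 1.2) -> tuple[ADCVolume, np.ndarray]:
    """Generate a textured ADC volume and its binary ROI mask.

    Returns an :class:`~adctexture.preproc.ADCVolume` and a boolean mask of
    the same grid.  Reproducible: the same spec (including seed) yields
    bit-identical output.  Slices are smoothed independently in-plane so
    per-slice GLCMs see uncorrelated planes, matching a multi-slice
    acquisition with a slice gap.
    """
    roi = _ellipsoid_mask(spec.grid_shape, spec.roi_center, spec.roi_radii)
    if not roi.any():
        raise ValueError("ROI mask is empty for the given geometry")

    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.grid_shape)
    fld = ndi.gaussian_filter(
        white, sigma=(spec.correlation_length, spec.correlation_length, 0.0)
    )
    if spec.adc_amplitude > 0 and roi.sum() > 1:
        mu, sd = fld[roi].mean(), fld[roi].std()
        fld = (fld - mu) / sd
        adc = spec.adc_mean + spec.adc_amplitude * fld
    else:
        adc = np.full(spec.grid_shape, float(spec.adc_mean))
        fld = np.zeros(spec.grid_shape)

    if spec.adjacent_fluid is not None:
        fl = spec.adjacent_fluid
        fluid_mask = _ellipsoid_mask(spec.grid_shape, fl.center, fl.radii)
        # mild texture inside the fluid so it is not perfectly constant
        adc[fluid_mask] = fl.mean + 0.02 * fl.mean * fld[fluid_mask]

    adc = np.clip(adc, 0.0, None)
    vol = ADCVolume(adc, voxel_size, meta={"seed": spec.seed})
    return vol, roi


def simulate_dwi(adc: ADCVolume, s0: float, protocol: ProtocolSpec,
                 noise_sigma: float, seed: int | np.random.SeedSequence) -> DWISeries:
    """Simulate a DWI series from an ADC map under a protocol.

    Per voxel, S(b) = s0 * exp(-b * ADC * 1e-6) + eps with
    eps ~ Normal(0, noise_sigma^2), independent across voxels and
    b-values.  Negative simulated signals are kept as-is; handling is
    deferred to :func:`~adctexture.preproc.fit_adc`.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    b = np.asarray(protocol.b_values, float)
    clean = s0 * np.exp(-b[:, None, None, None] * adc.values[None] * 1e-6)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
    return DWISeries(clean, b, protocol.voxel_size, protocol.slice_thickness)


def make_phantom_batch(n: int, seed: int, *,
                       grid_shape: tuple[int, int, int] = (60, 60, 4),
                       include_fluid: bool = True,
                       adc_mean_range: tuple[float, float] = (800.0, 1200.0),
                       amplitude_range: tuple[float, float] = (200.0, 400.0),
                       corr_length_range: tuple[float, float] = (1.0, 4.0),
                       s0_range: tuple[float, float] = (700.0, 1400.0)
                       ) -> list[PhantomSpec]:
    """Draw a heterogeneous batch of phantom specs (one per synthetic ROI).

    Base ADC mean, texture amplitude, correlation length and unattenuated
    signal amplitude s0 vary across ROIs to emulate a clinical cohort's
    between-tumour spread of ADC ranges and of signal-to-noise ratio
    (coil loading, tumour depth and averaging differ between exams).
    With ``include_fluid`` a fluid-like ellipsoid (mean 3000) is placed
    at a jittered position on the ROI boundary, so some ROIs contain a
    thin rim of near-fluid values and others none -- the
    tumour-near-ventricle scenario.
    """
    if n < 1:
        raise ValueError("batch size must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(4 * n).reshape(n, 4) % (2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cx, cy, cz = (grid_shape[0] / 2, grid_shape[1] / 2, (grid_shape[2] - 1) / 2)
    specs = []
    for k in range(n):
        mean = rng.uniform(*adc_mean_range)
        amp = rng.uniform(*amplitude_range)
        cl = rng.uniform(*corr_length_range)
        rx = rng.uniform(0.75, 1.0) * (grid_shape[0] / 2 - 6)
        ry = rng.uniform(0.75, 1.0) * (grid_shape[1] / 2 - 6)
        rz = grid_shape[2] / 2 - 0.1
        fluid = None
        if include_fluid:
            # place the fluid ellipsoid on the +x side of the ROI boundary,
            # jittered radially so the overlap with the ROI varies 0..few %
            offset = rng.uniform(-2.0, 4.0)
            fluid = FluidSpec(
                center=(cx + rx + offset, cy, cz),
                radii=(rng.uniform(4.0, 7.0), rng.uniform(4.0, 7.0), rz),
                mean=3000.0,
            )
        specs.append(PhantomSpec(
            grid_shape=grid_shape,
            roi_center=(cx, cy, cz),
            roi_radii=(rx, ry, rz),
            adc_mean=mean,
            adc_amplitude=amp,
            correlation_length=cl,
            adjacent_fluid=fluid,
            s0=rng.uniform(*s0_range),
            seed=int(child_seeds[k, 0]),
        ))
    return specs


def simulate_batch(specs: list[PhantomSpec], protocol: ProtocolSpec,
                   seed: int) -> list[tuple[DWISeries, np.ndarray]]:
    """Simulate one DWI series + ROI mask per phantom spec at native noise."""
    ss = np.random.SeedSequence(seed)
    noise_seeds = ss.generate_state(len(specs)) % (2**31)
    out = []
    for spec, ns in zip(specs, noise_seeds):
        adc, roi = generate_adc_phantom(spec, voxel_size=protocol.voxel_size)
        dwi = simulate_dwi(adc, spec.s0, protocol, protocol.native_noise_sigma,
                           int(ns))
        out.append((dwi, roi))
    return out
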