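"""Seeded generators of multichannel, multislice MRSI fixtures.

The generator emulates the acquisition geometry the pipeline targets:
an 8-channel receive array, 7 contiguous or gapped 10 mm slices, 16x16 or
32x32 phase encodings, SW = 2000 Hz, 256-point full echoes at TR/TE =
2300/144 ms, with NAA/Cr/Cho singlets (default amplitude ratios 48:36:24),
optional residual water, smooth complex coil sensitivities, circular
complex Gaussian noise added in k-space, and a scalar adjacent-slice
crosstalk attenuation tied to the interleaved excitation order
(1-3-5-7-2-4-6).

Every output is a pure function of (specification, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InvalidParameterError
from .recon_combine import KSpaceVolume, image_to_kspace
from .signal_model import EchoGrid, EchoSignal, SpectralComponent, evaluate_model, fwhm_to_decay

__all__ = [
    "PROTON_FREQ_MHZ",
    "WATER_PPM",
    "METABOLITE_PPM",
    "metabolite_frequencies",
    "metabolite_components",
    "Compartment",
    "PhantomSpec",
    "CoilProfile",
    "CrosstalkModel",
    "excitation_order",
    "make_echo",
    "make_mrsi_dataset",
    "make_paired_crosstalk_datasets",
]

#: Proton frequency at 3 T (MHz); sets the ppm -> Hz conversion.
PROTON_FREQ_MHZ = 127.74
#: Water reference chemical shift (ppm); the carrier sits on water.
WATER_PPM = 4.70
#: Chemical shifts of the three major proton singlets (ppm).
METABOLITE_PPM = {"NAA": 2.01, "Cr": 3.03, "Cho": 3.22}


def metabolite_frequencies(field_mhz: float = PROTON_FREQ_MHZ) -> dict[str, float]:
    """Hz offsets of NAA/Cr/Cho from a water-centered carrier."""
    return {m: (ppm - WATER_PPM) * field_mhz for m, ppm in METABOLITE_PPM.items()}


def _decays(kind: str, linewidth_hz: float, voigt_lorentz_fwhm: float,
            voigt_gauss_fwhm: float) -> tuple[float, float]:
    if kind == "lorentzian":
        return fwhm_to_decay(linewidth_hz, "lorentzian"), 0.0
    if kind == "gaussian":
        return 0.0, fwhm_to_decay(linewidth_hz, "gaussian")
    if kind == "voigt":
        return (
            fwhm_to_decay(voigt_lorentz_fwhm, "lorentzian"),
            fwhm_to_decay(voigt_gauss_fwhm, "gaussian"),
        )
    raise InvalidParameterError(f"unknown lineshape kind {kind!r}")


def metabolite_components(
    amplitudes: dict[str, float] | None = None,
    kind: str = "lorentzian",
    linewidth_hz: float = 10.0,
    voigt_lorentz_fwhm: float = 2.5,
    voigt_gauss_fwhm: float = 7.5,
    field_mhz: float = PROTON_FREQ_MHZ,
) -> list[SpectralComponent]:
    """Three-singlet model with the default 48:36:24 amplitude ratios.

    The 10 Hz linewidth is a FWHM; for the Voigtian shape the Lorentzian
    and Gaussian FWHM contributions (2.5 and 7.5 Hz) are converted
    separately and shared across all peaks.
    """
    if amplitudes is None:
        amplitudes = {"NAA": 48.0, "Cr": 36.0, "Cho": 24.0}
    freqs = metabolite_frequencies(field_mhz)
    alpha, beta = _decays(kind, linewidth_hz, voigt_lorentz_fwhm, voigt_gauss_fwhm)
    return [
        SpectralComponent(
            amplitude=a, frequency=freqs[m], phase=0.0,
            lorentz_decay=alpha, gauss_decay=beta, label=m,
        )
        for m, a in amplitudes.items()
    ]


def default_water_components(total_amplitude: float) -> list[SpectralComponent]:
    """Residual water as two broad components within 20 Hz of the carrier."""
    return [
        SpectralComponent(0.6 * total_amplitude, -8.0, 0.3,
                          fwhm_to_decay(9.0, "lorentzian"), 0.0, label="water"),
        SpectralComponent(0.4 * total_amplitude, 5.0, -0.4,
                          fwhm_to_decay(16.0, "lorentzian"), 0.0, label="water"),
    ]


@dataclass(frozen=True)
class Compartment:
    """A labeled 2D region with its own metabolite amplitudes."""

    name: str
    mask: np.ndarray  # bool (Y, X)
    amplitudes: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if any(a < 0 for a in self.amplitudes.values()):
            raise InvalidParameterError("compartment amplitudes must be >= 0")


def elliptical_mask(grid: tuple[int, int], rel_radius: float = 0.4) -> np.ndarray:
    ny, nx = grid
    y, x = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    return ((y - cy) / (rel_radius * ny)) ** 2 + ((x - cx) / (rel_radius * nx)) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and composition of the synthetic object.

    Slices share the 2D compartment layout; per-slice signal differences
    come from the coil profile and the crosstalk attenuation.
    """

    compartments: tuple[Compartment, ...]
    grid: tuple[int, int] = (16, 16)
    n_slices: int = 7
    slice_thickness_mm: float = 10.0
    slice_spacing_mm: float = 4.0
    water_amplitude_ratio: float = 0.0  # total water amplitude as multiple of NAA
    lineshape: str = "lorentzian"
    linewidth_hz: float = 10.0
    voigt_lorentz_fwhm: float = 2.5
    voigt_gauss_fwhm: float = 7.5
    field_mhz: float = PROTON_FREQ_MHZ

    def __post_init__(self) -> None:
        for c in self.compartments:
            if c.mask.shape != self.grid:
                raise ConfigurationError(
                    f"compartment {c.name!r} mask shape {c.mask.shape} "
                    f"does not match grid {self.grid}"
                )

    @classmethod
    def default(
        cls,
        grid: tuple[int, int] = (16, 16),
        n_slices: int = 7,
        spacing_mm: float = 4.0,
        amplitudes: dict[str, float] | None = None,
        **kwargs,
    ) -> "PhantomSpec":
        """Single elliptical compartment with 48:36:24 NAA:Cr:Cho."""
        amplitudes = amplitudes or {"NAA": 48.0, "Cr": 36.0, "Cho": 24.0}
        comp = Compartment("brain", elliptical_mask(grid), amplitudes)
        return cls(
            compartments=(comp,), grid=grid, n_slices=n_slices,
            slice_spacing_mm=spacing_mm, **kwargs,
        )

    @property
    def metabolites(self) -> list[str]:
        names: list[str] = []
        for c in self.compartments:
            names += [m for m in c.amplitudes if m not in names]
        return names

    def amplitude_map(self, metabolite: str) -> np.ndarray:
        out = np.zeros(self.grid)
        for c in self.compartments:
            out += c.mask * c.amplitudes.get(metabolite, 0.0)
        return out

    def unit_components(self) -> dict[str, SpectralComponent]:
        """Unit-amplitude component per metabolite (plus water entries)."""
        comps = metabolite_components(
            {m: 1.0 for m in self.metabolites}, self.lineshape,
            self.linewidth_hz, self.voigt_lorentz_fwhm, self.voigt_gauss_fwhm,
            self.field_mhz,
        )
        return {c.label: c for c in comps}


@dataclass(frozen=True)
class CoilProfile:
    """Per-channel complex sensitivity fields and noise levels.

    The default emulates an 8-element receive array: elements spaced at
    45 degree increments around the object, each with a smooth quadratic
    amplitude roll-off away from the element and a channel-specific
    receive phase -- the phase-dispersion problem the echo-top alignment
    step solves.
    """

    sensitivities: np.ndarray  # complex (C, Y, X)
    noise_sds: np.ndarray      # (C,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensitivities", np.asarray(self.sensitivities, dtype=complex))
        object.__setattr__(self, "noise_sds", np.asarray(self.noise_sds, dtype=float))
        if self.sensitivities.ndim != 3:
            raise ConfigurationError("sensitivities must be (channel, y, x)")
        if self.noise_sds.size != self.sensitivities.shape[0]:
            raise ConfigurationError("one noise SD per channel is required")
        if np.any(self.noise_sds < 0):
            raise ConfigurationError("noise SDs must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.sensitivities.shape[0]

    @classmethod
    def default(
        cls,
        grid: tuple[int, int] = (16, 16),
        n_channels: int = 8,
        noise_sd: float = 0.0,
        seed_phases: bool = True,
    ) -> "CoilProfile":
        ny, nx = grid
        y, x = np.mgrid[0:ny, 0:nx]
        yn = (y - (ny - 1) / 2.0) / (ny / 2.0)
        xn = (x - (nx - 1) / 2.0) / (nx / 2.0)
        sens = np.empty((n_channels, ny, nx), dtype=complex)
        for c in range(n_channels):
            theta = 2.0 * np.pi * c / n_channels  # 45 deg increments for 8 channels
            ey, ex = 1.4 * np.sin(theta), 1.4 * np.cos(theta)
            d2 = (yn - ey) ** 2 + (xn - ex) ** 2
            amp = 1.2 - 0.18 * d2  # smooth quadratic roll-off
            phase = theta + (0.25 * d2 if seed_phases else 0.0)
            sens[c] = amp * np.exp(1j * phase)
        # slightly unequal channel noise
        sds = noise_sd * (1.0 + 0.05 * np.arange(n_channels) / max(n_channels - 1, 1))
        return cls(sens, sds)


def excitation_order(n_slices: int) -> list[int]:
    """Interleaved slice excitation order (1-based): odd slices then even."""
    return list(range(1, n_slices + 1, 2)) + list(range(2, n_slices + 1, 2))


@dataclass(frozen=True)
class CrosstalkModel:
    """Scalar amplitude attenuation of slices excited after a neighbor.

    ``gamma(spacing)`` rises linearly from ``gamma0`` at 0 mm spacing to 1
    at ``full_recovery_mm`` (default 4 mm) and stays 1 beyond; a slice is
    attenuated when a spatially adjacent slice was excited earlier within
    the same TR under the interleaved order.
    """

    gamma0: float = 1.0
    full_recovery_mm: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma0 <= 1.0):
            raise InvalidParameterError(f"gamma0 must be in (0, 1], got {self.gamma0}")

    def gamma(self, spacing_mm: float) -> float:
        if spacing_mm >= self.full_recovery_mm:
            return 1.0
        frac = max(spacing_mm, 0.0) / self.full_recovery_mm
        return self.gamma0 + (1.0 - self.gamma0) * frac

    def attenuated_slices(self, n_slices: int) -> np.ndarray:
        """Boolean per slice (0-based): a spatial neighbor precedes it."""
        order = excitation_order(n_slices)
        time_of = {s: i for i, s in enumerate(order)}
        out = np.zeros(n_slices, dtype=bool)
        for s in range(1, n_slices + 1):
            for nb in (s - 1, s + 1):
                if 1 <= nb <= n_slices and time_of[nb] < time_of[s]:
                    out[s - 1] = True
        return out


def make_echo(
    components: list[SpectralComponent],
    spectral_width: float = 2000.0,
    n_points: int = 256,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EchoSignal:
    """One full echo: model evaluation plus circular complex Gaussian noise."""
    if noise_sd > 0 and seed is None and rng is None:
        raise InvalidParameterError("a seed (or rng) is required when noise_sd > 0")
    grid = EchoGrid(n_points, spectral_width)
    samples = evaluate_model(components, grid)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(seed)
        samples = samples + noise_sd * (
            rng.standard_normal(n_points) + 1j * rng.standard_normal(n_points)
        )
    return EchoSignal(samples, grid)


def _voxel_echo_stack(phantom: PhantomSpec, grid: EchoGrid) -> np.ndarray:
    """Noise-free voxel echoes (Y, X, T) shared by all slices."""
    units = phantom.unit_components()
    ny, nx = phantom.grid
    out = np.zeros((ny, nx, grid.n_points), dtype=complex)
    for met, unit in units.items():
        amp_map = phantom.amplitude_map(met)
        if not np.any(amp_map):
            continue
        basis = evaluate_model([unit], grid)
        out += amp_map[:, :, None] * basis[None, None, :]
    if phantom.water_amplitude_ratio > 0:
        naa_map = phantom.amplitude_map("NAA")
        peak = float(naa_map.max())
        if peak > 0:
            water = default_water_components(phantom.water_amplitude_ratio * peak)
            basis = evaluate_model(water, grid)
            out += (naa_map / peak)[:, :, None] * basis[None, None, :]
    return out


def make_mrsi_dataset(
    phantom: PhantomSpec,
    coils: CoilProfile,
    crosstalk: CrosstalkModel | None = None,
    spectral_width: float = 2000.0,
    n_points: int = 256,
    seed: int | None = None,
    te: float = 144.0,
    tr: float = 2300.0,
) -> KSpaceVolume:
    """Forward-simulate a multichannel, multislice phase-encoded dataset.

    Voxel echoes are the compartment model scaled by the coil sensitivity
    and the per-slice crosstalk attenuation, Fourier-transformed to
    k-space (centered, orthonormal), with per-channel complex Gaussian
    noise added in k-space.
    """
    if coils.sensitivities.shape[1:] != phantom.grid:
        raise ConfigurationError(
            f"coil grid {coils.sensitivities.shape[1:]} does not match "
            f"phantom grid {phantom.grid}"
        )
    if np.any(coils.noise_sds > 0) and seed is None:
        raise InvalidParameterError("a seed is required when coil noise is non-zero")
    crosstalk = crosstalk or CrosstalkModel()
    grid = EchoGrid(n_points, spectral_width)
    base = _voxel_echo_stack(phantom, grid)  # (Y, X, T)

    g = crosstalk.gamma(phantom.slice_spacing_mm)
    attenuated = crosstalk.attenuated_slices(phantom.n_slices)
    gammas = np.where(attenuated, g, 1.0)

    ny, nx = phantom.grid
    image = np.empty((coils.n_channels, phantom.n_slices, ny, nx, n_points), dtype=complex)
    for s in range(phantom.n_slices):
        slice_echoes = gammas[s] * base
        for c in range(coils.n_channels):
            image[c, s] = coils.sensitivities[c][:, :, None] * slice_echoes

    kdata = image_to_kspace(image)
    if np.any(coils.noise_sds > 0):
        rng = np.random.default_rng(seed)
        shape = kdata.shape[1:]
        for c in range(coils.n_channels):
            kdata[c] += coils.noise_sds[c] * (
                rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
            )
    return KSpaceVolume(
        kdata, spectral_width, te=te, tr=tr,
        slice_thickness=phantom.slice_thickness_mm,
        slice_spacing=phantom.slice_spacing_mm,
        meta={"seed": seed, "gammas": gammas.tolist(),
              "excitation_order": excitation_order(phantom.n_slices)},
    )


def make_paired_crosstalk_datasets(
    phantom: PhantomSpec,
    coils: CoilProfile,
    gamma0: float,
    spectral_width: float = 2000.0,
    n_points: int = 256,
    seed: int | None = None,
) -> tuple[KSpaceVolume, KSpaceVolume]:
    """Volumes acquired with (4 mm) and without (0 mm) slice spacing.

    Both share the central-slice geometry and the same noise stream
    (identical seed), so ``gamma0 = 1`` makes them bit-identical; the
    0 mm volume attenuates slices with a temporally preceding spatial
    neighbor by ``gamma0``.
    """
    model = CrosstalkModel(gamma0=gamma0)
    with_sp = dataclasses.replace(phantom, slice_spacing_mm=model.full_recovery_mm)
    without_sp = dataclasses.replace(phantom, slice_spacing_mm=0.0)
    vol_with = make_mrsi_dataset(
        with_sp, coils, model, spectral_width, n_points, seed=seed
    )
    vol_without = make_mrsi_dataset(
        without_sp, coils, model, spectral_width, n_points, seed=seed
    )
    return vol_with, vol_without
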