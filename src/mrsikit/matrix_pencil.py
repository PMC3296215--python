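"""Matrix-pencil decomposition of full echoes.

Used for two preprocessing steps: removal of the residual water signal
(identified by frequency, subtracted as estimated damped sinusoids) and
replacement of the first few echo samples corrupted by the receiver
(extrapolated from a model estimated on the uncorrupted samples).

The pencil operates on the causal half of the echo (t >= 0), where each
Lorentzian component is a single damped complex exponential; the estimated
components are then referred to t = 0 and reconstructed over the full
two-sided grid with the ``exp(-alpha |t|)`` symmetry of the echo model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import ConfigurationError, DataError
from .signal_model import EchoSignal, SpectralComponent, wrap_phase

__all__ = [
    "PencilConfig",
    "DecomposedSignal",
    "pencil_decompose",
    "remove_water",
    "repair_corrupted_points",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PencilConfig:
    """Options for the matrix-pencil step.

    Parameters
    ----------
    pencil_parameter : int or None
        Pencil parameter L (Hankel matrix width minus one). Default
        ``floor(n_causal / 3)``, clipped into ``[n/4, n/2]`` of the causal
        segment length.
    order : int or None
        Fixed model order K. When None the order is chosen by the
        singular-value threshold rule.
    sv_threshold : float
        Relative singular-value threshold epsilon in (0, 1): keep
        singular values above ``epsilon * sigma_max``.
    adaptive_threshold : bool
        Raise the threshold to 3x a noise-floor estimate (median of the
        smaller half of the singular values) when that exceeds
        ``sv_threshold``; keeps the noise-free rule intact while being
        robust on noisy echoes.
    water_band : float
        Half-width in Hz of the frequency band around the carrier whose
        components count as water.
    """

    pencil_parameter: int | None = None
    order: int | None = None
    sv_threshold: float = 1e-3
    adaptive_threshold: bool = True
    water_band: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 < self.sv_threshold < 1.0):
            raise ConfigurationError(
                f"sv_threshold must be in (0, 1), got {self.sv_threshold}"
            )
        if self.water_band < 0:
            raise ConfigurationError("water_band must be >= 0")


@dataclass
class DecomposedSignal:
    """Result of a pencil decomposition.

    ``components`` are sorted by |amplitude| descending, amplitude/phase
    referred to t = 0.  ``reconstruction + residual`` equals the input
    exactly by construction.
    """

    components: list[SpectralComponent]
    reconstruction: np.ndarray
    residual: np.ndarray
    singular_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    # raw Lorentzian decays (may be slightly negative on noisy data);
    # parallel to `components`, whose stored decay is the same value.
    raw_decays: np.ndarray = field(default_factory=lambda: np.empty(0))


def _component_series(
    amplitude: float, frequency: float, phase: float, alpha: float, t: np.ndarray
) -> np.ndarray:
    """Two-sided damped sinusoid; tolerates negative alpha (noisy pencil)."""
    return amplitude * np.exp(
        1j * (2.0 * np.pi * frequency * t + phase) - alpha * np.abs(t)
    )


def pencil_decompose(echo: EchoSignal, config: PencilConfig | None = None) -> DecomposedSignal:
    """Estimate damped sinusoids from the causal half of a full echo.

    Uses the Hua-Sarkar matrix pencil: a Hankel matrix of the causal
    samples, truncated SVD for rank/order selection, and the generalized
    eigenvalues of the shifted signal-subspace pencil for the poles
    ``z_k = exp((-alpha_k + 2i pi f_k) dt)``.  Complex amplitudes follow
    from a linear least-squares fit at t >= 0 and are already referred to
    t = 0 (the first causal sample).
    """
    config = config or PencilConfig()
    y = np.asarray(echo.samples, dtype=complex)
    if not np.all(np.isfinite(y.view(float))):
        raise DataError("echo contains non-finite samples")
    c0 = echo.grid.center_index
    causal = y[c0:]
    n_c = causal.size
    L = config.pencil_parameter if config.pencil_parameter is not None else n_c // 3
    if not (2 <= L <= n_c - 2):
        raise ConfigurationError(f"pencil parameter L={L} out of range for n={n_c}")
    if config.order is not None and config.order > L:
        raise ConfigurationError(
            f"requested order K={config.order} exceeds pencil parameter L={L}"
        )

    # Hankel matrix (n_c - L) x (L + 1)
    Y = scipy.linalg.hankel(causal[: n_c - L], causal[n_c - L - 1 :])
    _, sv, vh = np.linalg.svd(Y, full_matrices=False)
    if config.order is not None:
        K = int(config.order)
    else:
        eps = config.sv_threshold
        if config.adaptive_threshold and sv.size >= 4:
            floor = float(np.median(sv[sv.size // 2 :]))
            eps = max(eps, 3.0 * floor / sv[0]) if sv[0] > 0 else eps
        K = int(np.sum(sv > eps * sv[0]))
    K = max(min(K, L), 0)

    t = echo.grid.times
    if K == 0:
        zeros = np.zeros_like(y)
        return DecomposedSignal([], zeros, y.copy(), sv, np.empty(0))

    # right singular vectors span the conjugate row space of the Hankel
    # matrix, so the shift-invariance eigenvalues are the conjugate poles
    V = vh.conj().T[:, :K]            # (L+1) x K
    V1, V2 = V[:-1, :], V[1:, :]
    poles = np.conj(np.linalg.eigvals(np.linalg.pinv(V1) @ V2))

    dt = echo.grid.dt
    alphas = -np.log(np.clip(np.abs(poles), 1e-300, None)) / dt
    freqs = np.angle(poles) / (2.0 * np.pi * dt)

    # complex amplitudes at t = 0 from the causal samples
    idx = np.arange(n_c)
    Z = poles[None, :] ** idx[:, None]
    coeffs, *_ = np.linalg.lstsq(Z, causal, rcond=None)

    order = np.argsort(-np.abs(coeffs))
    comps: list[SpectralComponent] = []
    recon = np.zeros_like(y)
    raw = np.empty(order.size)
    for rank, k in enumerate(order):
        a = float(np.abs(coeffs[k]))
        ph = wrap_phase(float(np.angle(coeffs[k])))
        comps.append(
            SpectralComponent(
                amplitude=a,
                frequency=float(freqs[k]),
                phase=ph,
                lorentz_decay=float(alphas[k]),
                gauss_decay=0.0,
            )
        )
        raw[rank] = alphas[k]
        recon += _component_series(a, freqs[k], ph, alphas[k], t)
    return DecomposedSignal(comps, recon, y - recon, sv, raw)


def _water_band_energy(echo: EchoSignal, water_band: float) -> float:
    freqs, spec = echo.spectrum()
    sel = np.abs(freqs) <= water_band
    return float(np.sum(np.abs(spec[sel]) ** 2))


def remove_water(
    echo: EchoSignal, config: PencilConfig | None = None
) -> tuple[EchoSignal, float]:
    """Subtract all pencil components inside the water band.

    Returns the cleaned echo and the fraction of water-band spectral
    energy removed, ``1 - E_after / E_before`` measured on the centered
    spectrum within ``|f| <= water_band``.
    """
    config = config or PencilConfig()
    if config.water_band == 0:
        log.warning("empty water band: nothing to remove")
        return echo.copy_with(echo.samples.copy()), 0.0
    dec = pencil_decompose(echo, config)
    t = echo.grid.times
    water = np.zeros_like(echo.samples)
    n_water = 0
    for c, alpha in zip(dec.components, dec.raw_decays):
        if abs(c.frequency) <= config.water_band:
            water += _component_series(c.amplitude, c.frequency, c.phase, alpha, t)
            n_water += 1
    if n_water == 0:
        log.info("no pencil component inside the water band")
        return echo.copy_with(echo.samples.copy()), 0.0
    cleaned = echo.copy_with(echo.samples - water)
    e_before = _water_band_energy(echo, config.water_band)
    e_after = _water_band_energy(cleaned, config.water_band)
    frac = 0.0 if e_before == 0 else 1.0 - e_after / e_before
    return cleaned, float(frac)


def repair_corrupted_points(
    echo: EchoSignal, n_bad: int = 6, config: PencilConfig | None = None
) -> EchoSignal:
    """Replace the first ``n_bad`` echo samples with model extrapolations.

    The first samples of the acquisition (most negative t) are corrupted
    by receiver switching; a pencil model estimated from the uncorrupted
    samples (the causal half, which never includes them for
    ``n_bad < N/4``) predicts their values.
    """
    config = config or PencilConfig()
    if n_bad < 0 or n_bad >= echo.grid.n_points // 4:
        raise ConfigurationError(
            f"n_bad must satisfy 0 <= n_bad < N/4 = {echo.grid.n_points // 4}, "
            f"got {n_bad}"
        )
    if n_bad == 0:
        return echo.copy_with(echo.samples.copy())
    dec = pencil_decompose(echo, config)
    t_bad = echo.grid.times[:n_bad]
    predicted = np.zeros(n_bad, dtype=complex)
    for c, alpha in zip(dec.components, dec.raw_decays):
        predicted += _component_series(c.amplitude, c.frequency, c.phase, alpha, t_bad)
    out = echo.samples.copy()
    out[:n_bad] = predicted
    return echo.copy_with(out)
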