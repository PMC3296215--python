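"""Damped-sinusoid model for full-echo MR spectroscopy signals.

A full echo is sampled symmetrically about the echo top, so each resonance
decays away from ``t = 0`` in both directions::

    S(t) = sum_m A_m exp(i (2 pi f_m t + phi_m)) exp(-alpha_m |t| - beta_m t^2)

with amplitude ``A_m`` (a.u.), frequency offset ``f_m`` (Hz) from the
carrier, phase ``phi_m`` (rad), Lorentzian decay ``alpha_m`` (1/s) and
Gaussian decay ``beta_m`` (1/s^2).  Three lineshape families are supported:
pure Lorentzian (all ``beta_m = 0``), pure Gaussian (all ``alpha_m = 0``)
and Voigtian (one Gaussian decay shared by every peak).

This module also provides the Fisher-information machinery used to compute
Cramér-Rao lower bounds (CRLBs) on the estimated parameters under i.i.d.
circular complex Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import IdentifiabilityError, InvalidParameterError

__all__ = [
    "LINESHAPES",
    "SpectralComponent",
    "EchoGrid",
    "EchoSignal",
    "CRLBResult",
    "evaluate_model",
    "fwhm_to_decay",
    "decay_to_fwhm",
    "model_jacobian",
    "param_names",
    "compute_crlb",
    "wrap_phase",
]

#: Supported lineshape families.
LINESHAPES = ("lorentzian", "gaussian", "voigt")


def wrap_phase(phi: float) -> float:
    """Wrap a phase into the interval (-pi, pi]."""
    phi = float(phi)
    wrapped = math.remainder(phi, 2.0 * math.pi)
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass(frozen=True)
class SpectralComponent:
    """One resonance of the echo model.

    Parameters
    ----------
    amplitude : float
        Peak amplitude ``A_m`` in signal units, >= 0.
    frequency : float
        Offset ``f_m`` from the carrier in Hz.
    phase : float
        Phase ``phi_m`` in radians; stored wrapped into (-pi, pi].
    lorentz_decay : float
        Lorentzian decay ``alpha_m`` in 1/s (0 for pure-Gaussian models).
    gauss_decay : float
        Gaussian decay ``beta_m`` in 1/s^2 (0 for pure-Lorentzian models;
        shared across peaks in a Voigtian model).
    label : str
        Optional metabolite label ("NAA", "Cr", "Cho", "water", ...).
    """

    amplitude: float
    frequency: float
    phase: float = 0.0
    lorentz_decay: float = 0.0
    gauss_decay: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise InvalidParameterError(
                f"amplitude must be finite and >= 0, got {self.amplitude}"
            )
        object.__setattr__(self, "phase", wrap_phase(self.phase))

    def replace(self, **changes) -> "SpectralComponent":
        return replace(self, **changes)


@dataclass(frozen=True)
class EchoGrid:
    """Uniform symmetric sampling grid of a full echo.

    The time axis runs ``t_n = (n - N/2) * dt`` for ``n = 0 .. N-1``, i.e.
    from ``-dt*N/2`` to ``dt*(N/2 - 1)``, with ``dt = 1/SW``.
    """

    n_points: int
    spectral_width: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InvalidParameterError("grid needs at least 2 points")
        if self.spectral_width <= 0:
            raise InvalidParameterError("spectral width must be > 0")

    @property
    def dt(self) -> float:
        """Dwell time in seconds (1/SW)."""
        return 1.0 / self.spectral_width

    @property
    def duration(self) -> float:
        """Acquisition time N/SW in seconds."""
        return self.n_points / self.spectral_width

    @property
    def times(self) -> np.ndarray:
        n = self.n_points
        return (np.arange(n) - n // 2) * self.dt

    @property
    def center_index(self) -> int:
        """Index of the echo-top sample (t = 0)."""
        return self.n_points // 2

    def frequencies(self, n_fft: int | None = None) -> np.ndarray:
        """Centered DFT frequency axis in Hz (length ``n_fft`` or N)."""
        n_fft = self.n_points if n_fft is None else int(n_fft)
        return np.fft.fftshift(np.fft.fftfreq(n_fft, self.dt))


@dataclass
class EchoSignal:
    """A complex full echo on a symmetric time grid."""

    samples: np.ndarray
    grid: EchoGrid

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size != self.grid.n_points:
            raise InvalidParameterError(
                f"samples must be 1-D of length {self.grid.n_points}, "
                f"got shape {self.samples.shape}"
            )

    @classmethod
    def from_samples(cls, samples: np.ndarray, spectral_width: float) -> "EchoSignal":
        samples = np.asarray(samples, dtype=complex)
        return cls(samples, EchoGrid(samples.size, spectral_width))

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    @property
    def spectral_width(self) -> float:
        return self.grid.spectral_width

    @property
    def dt(self) -> float:
        return self.grid.dt

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def top_index(self) -> int:
        """Index of the maximum-magnitude sample (ties -> earlier index)."""
        mags = np.abs(self.samples)
        return int(np.argmax(mags))

    def spectrum(self, n_fft: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Centered DFT with the phase referred to ``t = 0``.

        Zero filling appends zeros after the last acquired point (the
        positive-time end of the echo), as done when padding a truncated
        echo before Fourier transformation.

        Returns
        -------
        freqs, spectrum : ndarray
            Frequency axis (Hz) and complex spectrum, both fftshifted so
            that the carrier is at the center.
        """
        n = self.grid.n_points
        n_fft = n if n_fft is None else int(n_fft)
        if n_fft < n:
            raise InvalidParameterError("n_fft must be >= number of samples")
        x = np.zeros(n_fft, dtype=complex)
        x[:n] = self.samples
        spec = np.fft.fft(x)
        # undo the t = -N/2*dt origin of sample 0: multiply by e^{+i 2 pi k (N/2)/n_fft}
        k = np.arange(n_fft)
        spec *= np.exp(2j * np.pi * k * (n // 2) / n_fft)
        return self.grid.frequencies(n_fft), np.fft.fftshift(spec)

    def copy_with(self, samples: np.ndarray) -> "EchoSignal":
        return EchoSignal(np.asarray(samples, dtype=complex), self.grid)


def _validate_components(components: Sequence[SpectralComponent]) -> None:
    for c in components:
        if c.amplitude < 0 or not np.isfinite(c.amplitude):
            raise InvalidParameterError(f"negative amplitude: {c}")
        if c.lorentz_decay < 0 or c.gauss_decay < 0:
            raise InvalidParameterError(
                f"decay constants must be >= 0, got alpha={c.lorentz_decay}, "
                f"beta={c.gauss_decay}"
            )
        if not (np.isfinite(c.frequency) and np.isfinite(c.phase)
                and np.isfinite(c.lorentz_decay) and np.isfinite(c.gauss_decay)):
            raise InvalidParameterError(f"non-finite parameter in {c}")


def evaluate_model(
    components: Iterable[SpectralComponent],
    grid: EchoGrid,
    *,
    validate: bool = True,
) -> np.ndarray:
    """Evaluate the full-echo model on a symmetric time grid.

    Returns the complex series ``S(t_n)`` with two-sided decay
    ``exp(-alpha |t| - beta t^2)`` for each component.
    """
    components = list(components)
    if validate:
        _validate_components(components)
    t = grid.times
    out = np.zeros(t.size, dtype=complex)
    for c in components:
        out += (
            c.amplitude
            * np.exp(1j * (2.0 * np.pi * c.frequency * t + c.phase))
            * np.exp(-c.lorentz_decay * np.abs(t) - c.gauss_decay * t * t)
        )
    return out


def fwhm_to_decay(fwhm: float, kind: str) -> float:
    """Convert a full width at half maximum (Hz) to a decay constant.

    Lorentzian: ``alpha = pi * FWHM`` (1/s).
    Gaussian: ``beta = pi^2 FWHM^2 / (4 ln 2)`` (1/s^2).
    """
    if fwhm < 0:
        raise InvalidParameterError(f"FWHM must be >= 0, got {fwhm}")
    if kind == "lorentzian":
        return math.pi * fwhm
    if kind in ("gaussian", "voigt"):
        return math.pi**2 * fwhm**2 / (4.0 * math.log(2.0))
    raise InvalidParameterError(f"unknown lineshape kind: {kind!r}")


def decay_to_fwhm(decay: float, kind: str) -> float:
    """Inverse of :func:`fwhm_to_decay`."""
    if decay < 0:
        raise InvalidParameterError(f"decay must be >= 0, got {decay}")
    if kind == "lorentzian":
        return decay / math.pi
    if kind in ("gaussian", "voigt"):
        return math.sqrt(decay * 4.0 * math.log(2.0)) / math.pi
    raise InvalidParameterError(f"unknown lineshape kind: {kind!r}")


# ---------------------------------------------------------------------------
# Parameterization and Fisher information
# ---------------------------------------------------------------------------

def _check_kind(kind: str) -> None:
    if kind not in LINESHAPES:
        raise InvalidParameterError(
            f"lineshape must be one of {LINESHAPES}, got {kind!r}"
        )


def param_names(components: Sequence[SpectralComponent], kind: str) -> list[str]:
    """Names of the free parameters for ``kind``, in packing order.

    Lorentzian: ``(A, f, phi, alpha)`` per peak.
    Gaussian: ``(A, f, phi, beta)`` per peak.
    Voigtian: ``(A, f, phi, alpha)`` per peak plus one shared ``beta``.
    """
    _check_kind(kind)
    names: list[str] = []
    for m, c in enumerate(components):
        tag = c.label or str(m)
        names += [f"A[{tag}]", f"f[{tag}]", f"phi[{tag}]"]
        if kind == "lorentzian":
            names.append(f"alpha[{tag}]")
        elif kind == "gaussian":
            names.append(f"beta[{tag}]")
        else:
            names.append(f"alpha[{tag}]")
    if kind == "voigt":
        names.append("beta[shared]")
    return names


def model_jacobian(
    components: Sequence[SpectralComponent], kind: str, grid: EchoGrid
) -> np.ndarray:
    """Complex Jacobian dS/dtheta, shape (N, n_params).

    The free-parameter set is defined by ``kind`` (see :func:`param_names`).
    """
    _check_kind(kind)
    components = list(components)
    t = grid.times
    abs_t = np.abs(t)
    t2 = t * t
    per_peak = 4
    n_par = per_peak * len(components) + (1 if kind == "voigt" else 0)
    jac = np.zeros((t.size, n_par), dtype=complex)
    shared_beta_col = np.zeros(t.size, dtype=complex)
    for m, c in enumerate(components):
        env = np.exp(-c.lorentz_decay * abs_t - c.gauss_decay * t2)
        carrier = np.exp(1j * (2.0 * np.pi * c.frequency * t + c.phase))
        base = carrier * env
        s_m = c.amplitude * base
        j0 = per_peak * m
        jac[:, j0] = base                     # dS/dA
        jac[:, j0 + 1] = s_m * 2j * np.pi * t  # dS/df
        jac[:, j0 + 2] = s_m * 1j              # dS/dphi
        if kind == "lorentzian" or kind == "voigt":
            jac[:, j0 + 3] = -s_m * abs_t      # dS/dalpha
        else:
            jac[:, j0 + 3] = -s_m * t2         # dS/dbeta
        if kind == "voigt":
            shared_beta_col += -s_m * t2
    if kind == "voigt":
        jac[:, -1] = shared_beta_col
    return jac


@dataclass
class CRLBResult:
    """Cramér-Rao lower bounds for one echo model.

    ``bounds[k]`` is the minimum achievable standard deviation of an
    unbiased estimator of parameter ``names[k]``, in the parameter's own
    units, for i.i.d. circular complex Gaussian noise of standard
    deviation ``noise_sd`` per real channel.  Bounds scale linearly in
    ``noise_sd``.
    """

    bounds: np.ndarray
    names: list[str]
    noise_sd: float
    fisher_condition: float
    labels: list[str] = field(default_factory=list)

    def bound(self, name: str) -> float:
        return float(self.bounds[self.names.index(name)])

    def amplitude_bounds(self) -> dict[str, float]:
        """Map component tag -> CRLB of its amplitude."""
        out = {}
        for name, b in zip(self.names, self.bounds):
            if name.startswith("A["):
                out[name[2:-1]] = float(b)
        return out


def fisher_information(
    components: Sequence[SpectralComponent],
    kind: str,
    grid: EchoGrid,
    noise_sd: float,
    free: Sequence[str] | None = None,
) -> np.ndarray:
    """Fisher information of the concatenated real/imag observation model.

    ``free`` restricts the free-parameter set to the named parameters
    (see :func:`param_names`); all others are treated as known exactly.
    """
    if noise_sd <= 0:
        raise InvalidParameterError("noise_sd must be > 0")
    jac = model_jacobian(components, kind, grid)
    if free is not None:
        names = param_names(components, kind)
        cols = [names.index(n) for n in free]
        jac = jac[:, cols]
    return np.real(jac.conj().T @ jac) / noise_sd**2


def compute_crlb(
    components: Sequence[SpectralComponent],
    kind: str,
    grid: EchoGrid,
    noise_sd: float,
    free: Sequence[str] | None = None,
) -> CRLBResult:
    """CRLBs of the free parameters of the echo model.

    ``free`` optionally names a subset of parameters to treat as free
    (all others fixed), e.g. ``free=["A[0]"]`` for the amplitude-only
    bound.

    Raises
    ------
    IdentifiabilityError
        If the Fisher matrix is numerically singular, typically because
        two components share (nearly) the same frequency.
    """
    components = list(components)
    _validate_components(components)
    fim = fisher_information(components, kind, grid, noise_sd, free=free)
    cond = float(np.linalg.cond(fim))
    if not np.isfinite(cond) or cond > 1e14:
        colliding = _colliding_components(components, grid)
        raise IdentifiabilityError(
            "singular Fisher information matrix; "
            + (
                f"components {colliding} have indistinguishable frequencies"
                if colliding
                else "model is not locally identifiable"
            )
        )
    cov = np.linalg.inv(fim)
    bounds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    names = param_names(components, kind) if free is None else list(free)
    return CRLBResult(
        bounds=bounds,
        names=names,
        noise_sd=float(noise_sd),
        fisher_condition=cond,
        labels=[c.label for c in components],
    )


def _colliding_components(
    components: Sequence[SpectralComponent], grid: EchoGrid
) -> list[tuple[int, int]]:
    """Pairs of components closer in frequency than one resolution element."""
    df = grid.spectral_width / grid.n_points
    pairs = []
    for i in range(len(components)):
        for j in range(i + 1, len(components)):
            if abs(components[i].frequency - components[j].frequency) < df:
                pairs.append((i, j))
    return pairs
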