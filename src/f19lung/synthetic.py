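"""Synthetic ¹⁹F acquisitions with known ground truth.

Three generators mirror the measurement chain end to end:

* :func:`make_spectrum` — phased complex spectra as sums of Lorentzian lines
  (one line for OFCB; a 6:2 CF3/CF2 doublet for PFP) plus complex Gaussian
  noise, over a 32-kHz, 2048-point acquisition window by default.
* :func:`make_ir_series` — inversion-recovery amplitudes
  M(TI) = M0·(1 − 2β·e^(−TI/T1)) with Gaussian noise, on the 4:3:91-ms TI
  grid by default.
* :func:`make_gre_image` — 2-D Cartesian GRE magnitude images of a syringe
  disc or two-lobe lung phantom: the per-pixel amplitude follows the
  steady-state signal model, noise is added in k-space independently per
  average, complex averages are taken before the magnitude, so the
  background is Rayleigh with SD governed by σ_k/√NSA.

Every generator takes a seed (or an existing Generator) and returns the
ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .image_snr import MagnitudeImage
from .relaxometry import IRSeries, Spectrum, fwhm_from_t2star
from .signal_model import AcquisitionProtocol, GasSpecies, steady_state_signal

__all__ = [
    "PhantomSpec",
    "NoiseModel",
    "make_spectrum",
    "make_ir_series",
    "make_gre_image",
    "syringe_mask",
    "lung_mask",
    "default_rois",
    "DEFAULT_TI_GRID_MS",
]

# TI grid used for the pure-gas relaxometry: 4 to 91 ms in 3-ms steps
DEFAULT_TI_GRID_MS = np.arange(4.0, 92.0, 3.0)
# TI grid used for the O2 mixtures: 4 to 28 ms in 1-ms steps
MIXTURE_TI_GRID_MS = np.arange(4.0, 29.0, 1.0)


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class PhantomSpec:
    """A 2-D phantom: occupancy mask, geometry, gas and spin density."""

    mask: np.ndarray
    fov_mm: tuple[float, float]
    gas: GasSpecies
    concentration: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("mask must be a non-empty 2-D boolean grid")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    @property
    def matrix(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class NoiseModel:
    """Complex Gaussian k-space noise: SD per real/imag component per average."""

    sigma_k: float
    seed: int | None = None
    nsa: int | None = None  # overrides the protocol NSA when set

    def __post_init__(self) -> None:
        if self.sigma_k < 0:
            raise ValueError("sigma_k must be non-negative")


def make_spectrum(
    gas: GasSpecies,
    concentration: float = 1.0,
    noise_sd: float = 0.0,
    bandwidth_hz: float = 32000.0,
    n_samples: int = 2048,
    seed: int | np.random.Generator | None = None,
) -> tuple[Spectrum, dict[str, Any]]:
    """Phased complex spectrum of ``gas`` with additive complex noise.

    Each spectral peak is a complex Lorentzian with analytic area
    ``concentration × relative_area`` (absorption in the real part) and FWHM
    1/(π·T2*); ``noise_sd`` is the SD of the complex Gaussian noise added to
    each frequency sample (per component).  Returns the spectrum and a truth
    dict with per-peak centers, FWHMs, areas and heights.
    """
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64")
    freq = np.linspace(-bandwidth_hz / 2.0, bandwidth_hz / 2.0, n_samples)
    amp = np.zeros(n_samples, dtype=complex)
    truth_peaks = []
    for rel_area, offset_hz, t2s in gas.peaks:
        if not -bandwidth_hz / 2.0 < offset_hz < bandwidth_hz / 2.0:
            raise ValueError(f"peak offset {offset_hz} Hz outside the bandwidth")
        area = concentration * rel_area
        fwhm = fwhm_from_t2star(t2s)
        hw = fwhm / 2.0
        # complex Lorentzian A/π · 1/(hw − i(f−f0)): absorption + dispersion
        amp += (area / np.pi) / (hw - 1j * (freq - offset_hz))
        truth_peaks.append(
            {
                "center_hz": offset_hz,
                "fwhm_hz": fwhm,
                "area": area,
                "height": 2.0 * area / (np.pi * fwhm),
            }
        )
    if noise_sd > 0:
        rng = _rng(seed)
        amp = amp + noise_sd * (
            rng.standard_normal(n_samples) + 1j * rng.standard_normal(n_samples)
        )
    spectrum = Spectrum(freq_hz=freq, amplitude=amp, bandwidth_hz=bandwidth_hz)
    truth = {"gas": gas.name, "concentration": concentration, "peaks": truth_peaks}
    return spectrum, truth


def make_ir_series(
    gas: GasSpecies,
    ti_grid_ms: np.ndarray | None = None,
    m0: float = 1.0,
    beta: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[IRSeries, dict[str, Any]]:
    """Inversion-recovery series M(TI) = M0·(1 − 2β·e^(−TI/T1)) + noise."""
    if ti_grid_ms is None:
        ti_grid_ms = DEFAULT_TI_GRID_MS
    ti = np.asarray(ti_grid_ms, dtype=float)
    if ti.size == 0:
        raise ValueError("TI grid must be non-empty")
    m = m0 * (1.0 - 2.0 * beta * np.exp(-ti / gas.t1_ms))
    if noise_sd > 0:
        m = m + noise_sd * _rng(seed).standard_normal(ti.size)
    truth = {"gas": gas.name, "t1_ms": gas.t1_ms, "m0": m0, "beta": beta}
    return IRSeries(ti_ms=ti, m_ti=m), truth


def syringe_mask(matrix: tuple[int, int], radius_frac: float = 0.3) -> np.ndarray:
    """Centered disc, emulating the axial cross-section of a gas syringe."""
    n_r, n_c = matrix
    r, c = np.ogrid[:n_r, :n_c]
    radius = radius_frac * min(n_r, n_c)
    return ((r - (n_r - 1) / 2.0) ** 2 + (c - (n_c - 1) / 2.0) ** 2) <= radius**2


def lung_mask(matrix: tuple[int, int]) -> np.ndarray:
    """Two-lobe elliptical mask, a coarse axial lung-projection stand-in."""
    n_r, n_c = matrix
    r, c = np.ogrid[:n_r, :n_c]
    out = np.zeros((n_r, n_c), dtype=bool)
    for col_center in (n_c * 0.30, n_c * 0.70):
        out |= (
            ((r - n_r / 2.0) / (n_r * 0.32)) ** 2
            + ((c - col_center) / (n_c * 0.19)) ** 2
        ) <= 1.0
    return out


def default_rois(matrix: tuple[int, int]) -> dict[str, "Any"]:
    """Signal ROI inside the right lung lobe and a background noise ROI.

    Scales proportionally with the matrix so the same fractions work at
    32×32 and 64×64.
    """
    from .image_snr import ROISpec

    n_r, n_c = matrix
    signal = ROISpec(
        origin_rc=(int(n_r * 0.41), int(n_c * 0.625)),
        size_rc=(max(int(n_r * 0.19), 2), max(int(n_c * 0.16), 2)),
        role="signal",
    )
    noise = ROISpec(
        origin_rc=(0, 0),
        size_rc=(max(int(n_r * 0.16), 5), max(int(n_c * 0.31), 5)),
        role="noise",
    )
    return {"signal": signal, "noise": noise}


def make_gre_image(
    phantom: PhantomSpec,
    protocol: AcquisitionProtocol,
    noise_model: NoiseModel,
    seed: int | np.random.Generator | None = None,
) -> tuple[MagnitudeImage, dict[str, Any]]:
    """Simulate a Cartesian GRE magnitude image of ``phantom``.

    The noise-free per-pixel amplitude is ``steady_state_signal ×
    concentration`` on the mask.  The amplitude map is Fourier-transformed
    (orthonormal FFT), complex Gaussian noise of SD ``sigma_k`` per component
    is added independently for each of the NSA averages, the complex averages
    are combined, and the magnitude of the inverse transform is returned —
    so the background magnitude is Rayleigh with scale σ_k/√NSA.
    """
    if protocol.matrix is not None and tuple(phantom.matrix) != tuple(protocol.matrix):
        raise ValueError("phantom matrix does not match protocol matrix")
    signal = steady_state_signal(phantom.gas, protocol)
    amplitude = signal * phantom.concentration * phantom.mask.astype(float)

    nsa = noise_model.nsa if noise_model.nsa is not None else protocol.nsa
    if noise_model.sigma_k == 0:
        pixels = np.abs(amplitude)
    else:
        rng = _rng(seed if seed is not None else noise_model.seed)
        k = np.fft.fft2(amplitude, norm="ortho")
        acc = np.zeros_like(k)
        for _ in range(nsa):
            noise = noise_model.sigma_k * (
                rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
            )
            acc += k + noise
        pixels = np.abs(np.fft.ifft2(acc / nsa, norm="ortho"))

    image = MagnitudeImage(pixels=pixels, fov_mm=phantom.fov_mm, protocol=protocol)
    truth = {
        "signal_amplitude": signal * phantom.concentration,
        "sigma_image": noise_model.sigma_k / np.sqrt(nsa),
        "nsa": nsa,
        "gas": phantom.gas.name,
    }
    return image, truth
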