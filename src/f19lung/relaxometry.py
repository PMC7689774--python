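"""T1 and T2* estimation from ¹⁹F spectra and inversion-recovery series.

T2* comes from the linewidth of a Lorentzian fit to the frequency-domain
peak, T2* = 1/(π·FWHM).  T1 comes from a nonlinear fit of the
inversion-recovery curve M(TI) = M0·(1 − 2β·e^(−TI/T1)), where β is the
inversion efficiency (β = 1 for a perfect 180° pulse).  Both fits are
least-squares via lmfit; the Lorentzian model includes a constant baseline
for scanner DC offsets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from lmfit.models import ConstantModel, LorentzianModel

__all__ = [
    "Spectrum",
    "LorentzianFit",
    "IRSeries",
    "IRFitResult",
    "fit_lorentzian",
    "t2star_from_fwhm",
    "fwhm_from_t2star",
    "fit_inversion_recovery",
    "integrate_peaks",
    "restore_ir_polarity",
]


@dataclass
class Spectrum:
    """A 1-D frequency-domain spectrum.

    ``amplitude`` may be complex (phased data: absorption in the real part)
    or real; ``freq_hz`` must be strictly monotone and spanned by
    ``bandwidth_hz``.
    """

    freq_hz: np.ndarray
    amplitude: np.ndarray
    bandwidth_hz: float | None = None

    def __post_init__(self) -> None:
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.amplitude = np.asarray(self.amplitude)
        if self.freq_hz.shape != self.amplitude.shape:
            raise ValueError("freq_hz and amplitude must have equal length")
        d = np.diff(self.freq_hz)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("frequency axis must be strictly monotone")
        if self.bandwidth_hz is not None:
            span = abs(self.freq_hz[-1] - self.freq_hz[0])
            if span > self.bandwidth_hz * (1 + 1e-9):
                raise ValueError("frequency axis exceeds stated bandwidth")

    @property
    def n_samples(self) -> int:
        return self.freq_hz.size

    def real_part(self) -> np.ndarray:
        return np.real(self.amplitude).astype(float)

    def magnitude(self) -> np.ndarray:
        return np.abs(self.amplitude).astype(float)

    def to_csv(self, path: str | Path, sidecar: dict | None = None) -> None:
        df = pd.DataFrame({"freq_hz": self.freq_hz})
        if np.iscomplexobj(self.amplitude):
            df["real"] = self.amplitude.real
            df["imag"] = self.amplitude.imag
        else:
            df["real"] = self.amplitude
        df.to_csv(path, index=False)
        if sidecar is not None or self.bandwidth_hz is not None:
            meta = dict(sidecar or {})
            meta.setdefault("bandwidth_hz", self.bandwidth_hz)
            meta.setdefault("n_samples", int(self.n_samples))
            Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        df = pd.read_csv(path)
        amp = df["real"].to_numpy()
        if "imag" in df.columns:
            amp = amp + 1j * df["imag"].to_numpy()
        bw = None
        sidecar = Path(path).with_suffix(".json")
        if sidecar.exists():
            bw = json.loads(sidecar.read_text()).get("bandwidth_hz")
        return cls(freq_hz=df["freq_hz"].to_numpy(), amplitude=amp, bandwidth_hz=bw)


@dataclass(frozen=True)
class LorentzianFit:
    """One fitted Lorentzian line: center, FWHM, analytic area, height."""

    center_hz: float
    fwhm_hz: float
    area: float
    height: float
    baseline: float
    residual_rms: float
    success: bool = True
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fwhm_hz <= 0:
            raise ValueError("fwhm_hz must be positive")


@dataclass
class IRSeries:
    """Inversion-recovery amplitudes M(TI) on a grid of inversion times (ms)."""

    ti_ms: np.ndarray
    m_ti: np.ndarray

    def __post_init__(self) -> None:
        self.ti_ms = np.asarray(self.ti_ms, dtype=float)
        self.m_ti = np.asarray(self.m_ti, dtype=float)
        if self.ti_ms.shape != self.m_ti.shape:
            raise ValueError("ti_ms and m_ti must have equal length")
        if np.any(self.ti_ms <= 0) or np.any(np.diff(self.ti_ms) <= 0):
            raise ValueError("ti_ms must be positive and strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"ti_ms": self.ti_ms, "m_ti": self.m_ti}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IRSeries":
        df = pd.read_csv(path)
        return cls(ti_ms=df["ti_ms"].to_numpy(), m_ti=df["m_ti"].to_numpy())


@dataclass(frozen=True)
class IRFitResult:
    """Estimates from an inversion-recovery fit."""

    t1_ms: float
    m0: float
    beta: float
    stderr: dict
    residual_rms: float
    success: bool


class FitError(RuntimeError):
    """A spectral or relaxation fit failed to converge or is out of range."""


def t2star_from_fwhm(fwhm_hz: float) -> float:
    """T2* in ms from a Lorentzian full-width half-maximum in Hz."""
    if fwhm_hz <= 0:
        raise ValueError("fwhm_hz must be positive")
    return 1000.0 / (math.pi * fwhm_hz)


def fwhm_from_t2star(t2star_ms: float) -> float:
    """Lorentzian FWHM in Hz for a given T2* in ms (inverse map)."""
    if t2star_ms <= 0:
        raise ValueError("t2star_ms must be positive")
    return 1000.0 / (math.pi * t2star_ms)


def _initial_centers(x: np.ndarray, y: np.ndarray, n_peaks: int) -> list[float]:
    """Greedy peak picking: repeatedly take the maximum and blank ±FWHM."""
    y = y.copy()
    centers = []
    for _ in range(n_peaks):
        i = int(np.argmax(y))
        centers.append(float(x[i]))
        half = y[i] / 2.0
        lo = i
        while lo > 0 and y[lo] > half:
            lo -= 1
        hi = i
        while hi < y.size - 1 and y[hi] > half:
            hi += 1
        width = max(hi - lo, 3)
        sl = slice(max(i - 2 * width, 0), min(i + 2 * width + 1, y.size))
        y[sl] = -np.inf
    return centers


def fit_lorentzian(
    spectrum: Spectrum,
    n_peaks: int = 1,
    init_hint: Sequence[float] | None = None,
    use: str = "real",
    max_iter: int = 1000,
    xtol: float = 1e-8,
) -> list[LorentzianFit]:
    """Fit ``n_peaks`` Lorentzian lines plus a constant baseline.

    Parameters
    ----------
    spectrum:
        Input spectrum; the fitted trace is its real part by default
        (``use="magnitude"`` fits |amplitude| instead).
    n_peaks:
        1–3 lines.  Multi-peak fits assume centers separated by more than
        one FWHM.
    init_hint:
        Optional starting centers (Hz); otherwise picked greedily from the
        data maxima.

    Returns fits sorted by descending area.
    """
    if not 1 <= n_peaks <= 3:
        raise ValueError("n_peaks must be between 1 and 3")
    x = spectrum.freq_hz
    y = spectrum.real_part() if use == "real" else spectrum.magnitude()
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]

    if init_hint is not None:
        centers = list(init_hint)
        if len(centers) != n_peaks:
            raise ValueError("init_hint length must equal n_peaks")
    else:
        centers = _initial_centers(x, y, n_peaks)

    dx = float(np.median(np.diff(x)))
    model = ConstantModel(prefix="bl_")
    params = model.make_params(c=float(np.median(y)))
    for k, c0 in enumerate(centers):
        lz = LorentzianModel(prefix=f"p{k}_")
        model = model + lz
        i0 = int(np.argmin(np.abs(x - c0)))
        height0 = max(y[i0] - float(np.median(y)), 1e-12)
        # width at half max of the raw data around this center
        half = height0 / 2.0
        hi = i0
        while hi < y.size - 1 and y[hi] > half:
            hi += 1
        fwhm0 = max(2.0 * (hi - i0) * dx, dx)
        sigma0 = fwhm0 / 2.0
        params.update(
            lz.make_params(
                center=dict(value=c0, min=x[0], max=x[-1]),
                sigma=dict(value=sigma0, min=dx / 10.0),
                amplitude=dict(value=height0 * math.pi * sigma0, min=0),
            )
        )

    result = model.fit(
        y, params, x=x, max_nfev=max_iter * (len(centers) * 3 + 1), fit_kws={"xtol": xtol}
    )
    if not result.success:
        raise FitError(f"Lorentzian fit did not converge: {result.message}")

    rms = float(np.sqrt(np.mean(result.residual**2)))
    baseline = float(result.params["bl_c"].value)
    fits = []
    for k in range(n_peaks):
        p = result.params
        area = float(p[f"p{k}_amplitude"].value)
        fwhm = float(p[f"p{k}_fwhm"].value)
        stderr = {
            "center_hz": p[f"p{k}_center"].stderr,
            "fwhm_hz": p[f"p{k}_fwhm"].stderr,
            "area": p[f"p{k}_amplitude"].stderr,
        }
        fits.append(
            LorentzianFit(
                center_hz=float(p[f"p{k}_center"].value),
                fwhm_hz=fwhm,
                area=area,
                height=2.0 * area / (math.pi * fwhm),
                baseline=baseline,
                residual_rms=rms,
                success=bool(result.success),
                stderr=stderr,
            )
        )
    fits.sort(key=lambda f: f.area, reverse=True)
    return fits


def restore_ir_polarity(series: IRSeries) -> list[IRSeries]:
    """Candidate sign restorations for magnitude IR data.

    Points acquired before the zero crossing (estimated as the minimum of
    |M|) recovered from negative magnetization and are flipped negative.
    The point nearest the null can fall on either side, so both assignments
    are returned; the caller keeps whichever fits better.
    """
    m = np.abs(series.m_ti)
    i_null = int(np.argmin(m))
    candidates = []
    for flip_through in (i_null + 1, i_null):
        signed = m.copy()
        signed[:flip_through] *= -1.0
        candidates.append(IRSeries(ti_ms=series.ti_ms, m_ti=signed))
    return candidates


def _ir_model(ti, m0, beta, t1):
    return m0 * (1.0 - 2.0 * beta * np.exp(-ti / t1))


def fit_inversion_recovery(
    series: IRSeries,
    magnitude: bool = False,
    fix_beta: float | None = None,
    max_iter: int = 1000,
    xtol: float = 1e-8,
) -> IRFitResult:
    """Fit M(TI) = M0·(1 − 2β·e^(−TI/T1)) to an inversion-recovery series.

    The series should contain at least 5 points spanning roughly
    [0.3·T1, 2·T1].  With ``magnitude=True`` the polarity of |M| data is
    restored first (points before the zero crossing are flipped negative).
    ``fix_beta`` pins the inversion efficiency (e.g. 1.0 for the textbook
    two-parameter model).
    """
    if series.ti_ms.size < 5:
        raise ValueError("need at least 5 inversion times")
    if magnitude:
        fits = [
            fit_inversion_recovery(c, magnitude=False, fix_beta=fix_beta,
                                   max_iter=max_iter, xtol=xtol)
            for c in restore_ir_polarity(series)
        ]
        return min(fits, key=lambda r: r.residual_rms)
    ti, m = series.ti_ms, series.m_ti

    # T1 init from the zero crossing: M(TI_null)=0 at TI_null = T1·ln(2β)
    i_null = int(np.argmin(np.abs(m)))
    t1_init = max(ti[i_null] / math.log(2.0), ti[0] / 2.0)
    m0_init = float(m[-1]) if m[-1] != 0 else float(np.max(np.abs(m)))

    model = Model(_ir_model)
    params = model.make_params(
        m0=dict(value=m0_init),
        beta=dict(value=1.0, min=0.0, max=1.2, vary=fix_beta is None),
        t1=dict(value=t1_init, min=1e-6),
    )
    if fix_beta is not None:
        params["beta"].set(value=fix_beta, vary=False)

    result = model.fit(m, params, ti=ti, max_nfev=max_iter * 4, fit_kws={"xtol": xtol})
    t1_est = float(result.params["t1"].value)
    if not result.success:
        raise FitError(f"IR fit did not converge: {result.message}")
    if not 0 < t1_est < 10.0 * ti[-1]:
        raise FitError(f"fitted T1={t1_est:.3g} ms outside (0, 10·TI_max)")

    return IRFitResult(
        t1_ms=t1_est,
        m0=float(result.params["m0"].value),
        beta=float(result.params["beta"].value),
        stderr={
            "t1_ms": result.params["t1"].stderr,
            "m0": result.params["m0"].stderr,
            "beta": result.params["beta"].stderr,
        },
        residual_rms=float(np.sqrt(np.mean(result.residual**2))),
        success=bool(result.success),
    )


def integrate_peaks(
    fits: Sequence[LorentzianFit],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Analytic areas of fitted peaks and their pairwise ratios.

    Returns ``(areas, ratios)`` where ``ratios.iloc[i, j] = area_i / area_j``.
    The Lorentzian area is the fit's amplitude parameter (set by spin count ×
    concentration, independent of linewidth).
    """
    if not fits:
        raise ValueError("need at least one fit")
    areas = np.array([f.area for f in fits], dtype=float)
    if np.any(areas == 0):
        raise ZeroDivisionError("zero peak area; ratios undefined")
    labels = [f"peak{i}" for i in range(len(fits))]
    ratios = pd.DataFrame(np.outer(areas, 1.0 / areas), index=labels, columns=labels)
    return areas, ratios
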