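"""Steady-state spoiled gradient-echo signal model for inhaled ¹⁹F gases.

The relative steady-state signal of a spoiled GRE acquisition is

    S = S0 · (1 − E1) · exp(−TE/T2*) · sin α / (1 − cos α · E1),   E1 = exp(−TR/T1)

with ``S0`` proportional to the number of chemically equivalent ¹⁹F nuclei
contributing to the imaged spectral peak (8 for octafluorocyclobutane, 6 for
the CF3 peak of perfluoropropane).  Under white complex noise, averaging NSA
repetitions multiplies SNR by √NSA while scan time grows as NSA, so
comparisons at fixed scan time are made on SNR divided by NSA
("NSA-normalized SNR").  This module evaluates the model, derives Ernst
angles and scan-time-constrained NSA/TR, and predicts the normalized-SNR
advantage of one gas over another.

Angles are accepted in degrees at every interface; times are in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GasSpecies",
    "AcquisitionProtocol",
    "AdvantageResult",
    "NSAPolicy",
    "FixedNSA",
    "FixedScanTime",
    "steady_state_signal",
    "spoiled_gre_signal",
    "ernst_angle",
    "nsa_from_scan_time",
    "tr_from_scan_time",
    "normalize_snr",
    "predicted_advantage",
    "advantage_surface",
]


@dataclass(frozen=True)
class GasSpecies:
    """A fluorinated gas (or gas mixture / physiological condition).

    Parameters
    ----------
    name:
        Identifier, e.g. ``"ofcb-invivo"``.
    n_equivalent_f:
        Number of chemically equivalent ¹⁹F nuclei in the main spectral peak;
        the signal amplitude S0 is taken proportional to this count.
    t1_ms, t2star_ms:
        Spin-lattice and effective spin-spin relaxation time constants of the
        main peak, in milliseconds.
    condition:
        ``"pure"``, ``"O2-mixture"`` or ``"in-vivo"``.
    peaks:
        Spectral layout as ``(relative_area, offset_hz, t2star_ms)`` tuples,
        one per resonance; relative areas sum to the total fluorine count of
        the molecule (8 for C4F8; 6 + 2 for the CF3/CF2 peaks of C3F8).
        Defaults to a single peak carrying ``n_equivalent_f``.
    """

    name: str
    n_equivalent_f: float
    t1_ms: float
    t2star_ms: float
    condition: Literal["pure", "O2-mixture", "in-vivo"] = "pure"
    peaks: tuple[tuple[float, float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_equivalent_f < 1:
            raise ValueError("n_equivalent_f must be >= 1")
        if self.t1_ms <= 0 or self.t2star_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if self.t2star_ms > self.t1_ms:
            raise ValueError("t2star_ms cannot exceed t1_ms")
        if not self.peaks:
            object.__setattr__(
                self, "peaks", ((self.n_equivalent_f, 0.0, self.t2star_ms),)
            )
        for area, _, t2s in self.peaks:
            if area <= 0 or t2s <= 0:
                raise ValueError("peak areas and widths must be positive")

    @property
    def total_f(self) -> float:
        """Total fluorine count summed over all spectral peaks."""
        return sum(p[0] for p in self.peaks)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Parameters of one GRE (or spectroscopy) acquisition.

    ``scan_time_s``, when given, must be consistent with
    ``nsa · n_lines · tr_ms`` to within 5% (covers rounding of printed TRs).
    """

    name: str
    tr_ms: float
    te_ms: float
    flip_deg: float
    nsa: int = 1
    n_lines: int | None = None
    scan_time_s: float | None = None
    matrix: tuple[int, int] | None = None
    fov_mm: tuple[float, float] | None = None
    bw: float | None = None

    def __post_init__(self) -> None:
        if not self.tr_ms > self.te_ms >= 0:
            raise ValueError("require tr_ms > te_ms >= 0")
        if not 0 < self.flip_deg <= 90:
            raise ValueError("flip_deg must be in (0, 90]")
        if self.nsa < 1:
            raise ValueError("nsa must be >= 1")
        if self.scan_time_s is not None:
            if self.n_lines is None:
                raise ValueError("scan_time_s requires n_lines")
            implied = self.nsa * self.n_lines * self.tr_ms / 1000.0
            if abs(self.scan_time_s - implied) / self.scan_time_s > 0.05:
                raise ValueError(
                    f"scan_time_s={self.scan_time_s} inconsistent with "
                    f"nsa*n_lines*tr = {implied:.2f} s"
                )


@dataclass(frozen=True)
class AdvantageResult:
    """Predicted NSA-normalized SNR advantage of gas A over gas B."""

    signal_a: float
    signal_b: float
    snr_theory_a: float
    snr_theory_b: float
    normalized_a: float
    normalized_b: float
    advantage_pct: float

    @property
    def ratio(self) -> float:
        """normalized_a / normalized_b."""
        return 1.0 + self.advantage_pct / 100.0


def spoiled_gre_signal(
    n_f: float, t1_ms: float, t2star_ms: float, tr_ms: float, te_ms: float, flip_deg: float
) -> float:
    """Evaluate the spoiled-GRE steady-state signal from scalar parameters."""
    if t1_ms <= 0 or t2star_ms <= 0 or tr_ms <= 0:
        raise ValueError("T1, T2* and TR must be positive")
    if te_ms < 0:
        raise ValueError("TE must be non-negative")
    alpha = math.radians(flip_deg)
    e1 = math.exp(-tr_ms / t1_ms)
    return (
        n_f
        * (1.0 - e1)
        * math.exp(-te_ms / t2star_ms)
        * math.sin(alpha)
        / (1.0 - math.cos(alpha) * e1)
    )


def steady_state_signal(gas: GasSpecies, protocol: AcquisitionProtocol) -> float:
    """Relative steady-state signal of ``gas`` under ``protocol`` (a.u.)."""
    return spoiled_gre_signal(
        gas.n_equivalent_f, gas.t1_ms, gas.t2star_ms,
        protocol.tr_ms, protocol.te_ms, protocol.flip_deg,
    )


def ernst_angle(tr_ms: float, t1_ms: float, round_to: float | None = None) -> float:
    """Signal-maximizing flip angle arccos(exp(−TR/T1)), in degrees.

    ``round_to`` optionally rounds to the nearest increment (e.g. 5°), the
    granularity at which flip angles are typically prescribed on a scanner.
    """
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("tr_ms and t1_ms must be positive")
    angle = math.degrees(math.acos(math.exp(-tr_ms / t1_ms)))
    if round_to is not None:
        angle = round_to * round(angle / round_to)
    return angle


def nsa_from_scan_time(scan_time_s: float, n_lines: int, tr_ms: float) -> int:
    """Largest whole number of averages fitting in a fixed scan time."""
    if scan_time_s <= 0 or n_lines <= 0 or tr_ms <= 0:
        raise ValueError("all inputs must be positive")
    return int(math.floor(scan_time_s * 1000.0 / (n_lines * tr_ms)))


def tr_from_scan_time(scan_time_s: float, n_lines: int, nsa: int) -> float:
    """TR (ms) that makes ``nsa`` averages exactly fill a fixed scan time."""
    if scan_time_s <= 0 or n_lines <= 0 or nsa <= 0:
        raise ValueError("all inputs must be positive")
    return scan_time_s * 1000.0 / (n_lines * nsa)


def normalize_snr(snr: float, nsa: int | float) -> float:
    """Divide a measured SNR by its NSA (the fixed-scan-time convention)."""
    if nsa < 1:
        raise ValueError("nsa must be >= 1")
    return snr / nsa


def predicted_advantage(
    gas_a: GasSpecies,
    gas_b: GasSpecies,
    protocol_a: AcquisitionProtocol,
    protocol_b: AcquisitionProtocol,
    norm_nsa_a: int | float | None = None,
    norm_nsa_b: int | float | None = None,
) -> AdvantageResult:
    """Theoretical NSA-normalized SNR advantage of gas A over gas B.

    Theoretical SNR is ``signal × √NSA`` (white-noise averaging gain); the
    normalized value divides by ``norm_nsa``, which defaults to the
    protocol's own NSA but may be overridden — predictions for long
    continuous-breathing scans are sometimes normalized by the breath-hold
    NSAs instead, and the override makes both conventions explicit.
    """
    sig_a = steady_state_signal(gas_a, protocol_a)
    sig_b = steady_state_signal(gas_b, protocol_b)
    snr_a = sig_a * math.sqrt(protocol_a.nsa)
    snr_b = sig_b * math.sqrt(protocol_b.nsa)
    norm_a = normalize_snr(snr_a, protocol_a.nsa if norm_nsa_a is None else norm_nsa_a)
    norm_b = normalize_snr(snr_b, protocol_b.nsa if norm_nsa_b is None else norm_nsa_b)
    if norm_b <= 0:
        raise ZeroDivisionError("normalized SNR of gas B is zero; ratio undefined")
    return AdvantageResult(
        signal_a=sig_a,
        signal_b=sig_b,
        snr_theory_a=snr_a,
        snr_theory_b=snr_b,
        normalized_a=norm_a,
        normalized_b=norm_b,
        advantage_pct=100.0 * (norm_a / norm_b - 1.0),
    )


class NSAPolicy:
    """How NSA varies with TR on an advantage surface."""

    def nsas(self, tr_ms: float) -> tuple[int, int, float, float]:
        """Return (nsa_a, nsa_b, norm_nsa_a, norm_nsa_b) at this TR."""
        raise NotImplementedError


@dataclass(frozen=True)
class FixedNSA(NSAPolicy):
    """Constant averages for both gases, independent of TR."""

    nsa_a: int
    nsa_b: int
    norm_nsa_a: float | None = None
    norm_nsa_b: float | None = None

    def nsas(self, tr_ms: float) -> tuple[int, int, float, float]:
        return (
            self.nsa_a,
            self.nsa_b,
            self.nsa_a if self.norm_nsa_a is None else self.norm_nsa_a,
            self.nsa_b if self.norm_nsa_b is None else self.norm_nsa_b,
        )


@dataclass(frozen=True)
class FixedScanTime(NSAPolicy):
    """NSA refilled from a fixed scan time as TR changes (floor division)."""

    scan_time_s: float
    n_lines: int
    norm_nsa_a: float | None = None
    norm_nsa_b: float | None = None

    def nsas(self, tr_ms: float) -> tuple[int, int, float, float]:
        nsa = nsa_from_scan_time(self.scan_time_s, self.n_lines, tr_ms)
        nsa = max(nsa, 1)
        return (
            nsa,
            nsa,
            nsa if self.norm_nsa_a is None else self.norm_nsa_a,
            nsa if self.norm_nsa_b is None else self.norm_nsa_b,
        )


def advantage_surface(
    gas_a: GasSpecies,
    gas_b: GasSpecies,
    tr_grid_ms: Sequence[float],
    te_grid_ms: Sequence[float],
    flip_deg: float,
    nsa_policy: NSAPolicy,
    tr_b_ms: float | None = None,
) -> np.ndarray:
    """Normalized-SNR ratio A/B over a (TR, TE) grid.

    By default both gases are evaluated at the same TR and TE; passing
    ``tr_b_ms`` pins gas B at a fixed repetition time (its own protocol
    operating point) while the TR axis sweeps gas A — the convention under
    which a short-TR crossover region (gas B overtaking gas A) appears.
    The policy sets the averages (and normalization divisors) at each TR.
    Rows index TR, columns index TE, both ascending.  A ratio of 1.0 means
    no advantage; ratio < 1 is where gas B outperforms gas A.
    """
    tr = np.asarray(tr_grid_ms, dtype=float)
    te = np.asarray(te_grid_ms, dtype=float)
    if tr.size == 0 or te.size == 0:
        raise ValueError("TR/TE grids must be non-empty")
    if np.any(tr <= 0) or np.any(te < 0):
        raise ValueError("TR must be positive and TE non-negative")
    if np.any(np.diff(tr) <= 0) or (te.size > 1 and np.any(np.diff(te) <= 0)):
        raise ValueError("grids must be strictly increasing")

    out = np.empty((tr.size, te.size))
    for i, tr_i in enumerate(tr):
        nsa_a, nsa_b, norm_a, norm_b = nsa_policy.nsas(tr_i)
        for j, te_j in enumerate(te):
            proto_a = AcquisitionProtocol(
                name="grid-a", tr_ms=tr_i, te_ms=te_j, flip_deg=flip_deg, nsa=nsa_a
            )
            proto_b = replace(
                proto_a, name="grid-b", nsa=nsa_b,
                tr_ms=tr_i if tr_b_ms is None else tr_b_ms,
            )
            res = predicted_advantage(
                gas_a, gas_b, proto_a, proto_b, norm_nsa_a=norm_a, norm_nsa_b=norm_b
            )
            out[i, j] = res.ratio
    return out
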