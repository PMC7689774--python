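"""SNR measurement on 2-D magnitude images.

SNR is the mean (in vivo convention) or the peak (phantom convention) of a
rectangular signal ROI divided by the standard deviation of a disjoint
background noise ROI.  The background of a magnitude image is
Rayleigh-distributed; by default the raw SD is used without Rayleigh
correction, matching how the reference values were computed.  Dividing the
SNR by the number of signal averages gives the fixed-scan-time normalized
value used to compare gases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .signal_model import AcquisitionProtocol, normalize_snr

__all__ = ["MagnitudeImage", "ROISpec", "SNRMeasurement", "measure_snr", "batch_compare"]

# SD of a unit-scale Rayleigh variate: sqrt(2 - pi/2)
_RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


@dataclass
class MagnitudeImage:
    """A 2-D non-negative image with optional geometry and protocol context."""

    pixels: np.ndarray
    fov_mm: tuple[float, float] | None = None
    protocol: AcquisitionProtocol | None = None
    excluded: bool = False  # manual artifact/ghosting exclusion flag

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("magnitude pixels must be non-negative")
        if self.protocol is not None and self.protocol.matrix is not None:
            if tuple(self.pixels.shape) != tuple(self.protocol.matrix):
                raise ValueError("image dimensions do not match protocol matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def to_nifti(self, path: str | Path) -> None:
        affine = np.eye(4)
        if self.fov_mm is not None:
            affine[0, 0] = self.fov_mm[0] / self.pixels.shape[0]
            affine[1, 1] = self.fov_mm[1] / self.pixels.shape[1]
        nib.save(nib.Nifti1Image(self.pixels.astype(np.float64), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "MagnitudeImage":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError("expected a 2-D (single-slice) NIfTI image")
        zooms = img.header.get_zooms()[:2]
        fov = (zooms[0] * data.shape[0], zooms[1] * data.shape[1])
        return cls(pixels=data, fov_mm=fov)


@dataclass(frozen=True)
class ROISpec:
    """A rectangular ROI in 0-based, half-open row/col coordinates."""

    origin_rc: tuple[int, int]
    size_rc: tuple[int, int]
    role: Literal["signal", "noise"] = "signal"

    def __post_init__(self) -> None:
        if min(self.size_rc) <= 0:
            raise ValueError("ROI size must be positive")
        if min(self.origin_rc) < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        r0, c0 = self.origin_rc
        dr, dc = self.size_rc
        return slice(r0, r0 + dr), slice(c0, c0 + dc)

    @property
    def n_pixels(self) -> int:
        return self.size_rc[0] * self.size_rc[1]

    def inside(self, shape: tuple[int, int]) -> bool:
        r0, c0 = self.origin_rc
        dr, dc = self.size_rc
        return r0 + dr <= shape[0] and c0 + dc <= shape[1]

    def overlaps(self, other: "ROISpec") -> bool:
        (r0, c0), (dr, dc) = self.origin_rc, self.size_rc
        (s0, b0), (ds, db) = other.origin_rc, other.size_rc
        return r0 < s0 + ds and s0 < r0 + dr and c0 < b0 + db and b0 < c0 + dc

    def to_json(self) -> dict:
        return {"origin_rc": list(self.origin_rc), "size_rc": list(self.size_rc), "role": self.role}

    @classmethod
    def from_json(cls, obj: dict) -> "ROISpec":
        return cls(
            origin_rc=tuple(obj["origin_rc"]),
            size_rc=tuple(obj["size_rc"]),
            role=obj.get("role", "signal"),
        )


def load_rois(path: str | Path) -> dict[str, ROISpec]:
    """Read a ``{"signal": {...}, "noise": {...}}`` ROI JSON file."""
    raw = json.loads(Path(path).read_text())
    return {k: ROISpec.from_json(v) for k, v in raw.items()}


@dataclass(frozen=True)
class SNRMeasurement:
    """One SNR measurement and its NSA-normalized value."""

    snr: float
    mode: Literal["mean", "peak"]
    signal_stat: float
    noise_sd: float
    nsa: int
    normalized_snr: float


def measure_snr(
    image: MagnitudeImage,
    signal_roi: ROISpec,
    noise_roi: ROISpec,
    mode: Literal["mean", "peak"] = "mean",
    nsa: int | None = None,
    rayleigh_correction: bool = False,
) -> SNRMeasurement:
    """SNR of a magnitude image from signal and background ROIs.

    ``mode="mean"`` uses the ROI mean (in vivo convention); ``mode="peak"``
    uses the ROI maximum (phantom convention).  The noise SD is the raw SD
    of the background ROI; ``rayleigh_correction=True`` divides it by
    √(2−π/2) ≈ 0.655 to recover the underlying Gaussian σ (off by default to
    match the uncorrected convention of the reference values).
    """
    if mode not in ("mean", "peak"):
        raise ValueError("mode must be 'mean' or 'peak'")
    shape = image.shape
    if not (signal_roi.inside(shape) and noise_roi.inside(shape)):
        raise ValueError("ROIs must lie fully inside the image")
    if signal_roi.overlaps(noise_roi):
        raise ValueError("signal and noise ROIs must be disjoint")
    if noise_roi.n_pixels < 25:
        raise ValueError("noise ROI must contain at least 25 pixels")

    sig = image.pixels[signal_roi.slices]
    noise = image.pixels[noise_roi.slices]
    signal_stat = float(sig.mean() if mode == "mean" else sig.max())
    noise_sd = float(noise.std(ddof=1))
    if rayleigh_correction:
        noise_sd /= _RAYLEIGH_SD_FACTOR
    if noise_sd == 0:
        raise ZeroDivisionError("noise ROI has zero SD; SNR undefined")

    if nsa is None:
        nsa = image.protocol.nsa if image.protocol is not None else 1
    snr = signal_stat / noise_sd
    return SNRMeasurement(
        snr=snr,
        mode=mode,  # type: ignore[arg-type]
        signal_stat=signal_stat,
        noise_sd=noise_sd,
        nsa=int(nsa),
        normalized_snr=normalize_snr(snr, nsa),
    )


def batch_compare(
    images_a: Sequence[MagnitudeImage],
    images_b: Sequence[MagnitudeImage],
    signal_roi: ROISpec,
    noise_roi: ROISpec,
    mode: Literal["mean", "peak"] = "mean",
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Paired SNR table for two matched image lists (one pair per subject).

    Images flagged ``excluded`` (e.g. ghosting artifacts) are dropped as a
    pair.  Columns: id, snr_a, snr_b, normalized_a, normalized_b.
    """
    if len(images_a) != len(images_b):
        raise ValueError("paired image lists must have equal length")
    if ids is None:
        ids = [f"subject{i+1}" for i in range(len(images_a))]
    rows = []
    for sid, im_a, im_b in zip(ids, images_a, images_b):
        if im_a.excluded or im_b.excluded:
            continue
        ma = measure_snr(im_a, signal_roi, noise_roi, mode=mode)
        mb = measure_snr(im_b, signal_roi, noise_roi, mode=mode)
        rows.append(
            {
                "id": sid,
                "snr_a": ma.snr,
                "snr_b": mb.snr,
                "normalized_a": ma.normalized_snr,
                "normalized_b": mb.normalized_snr,
            }
        )
    return pd.DataFrame(rows, columns=["id", "snr_a", "snr_b", "normalized_a", "normalized_b"])
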