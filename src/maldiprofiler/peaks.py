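"""Peak detection on the overall mean spectrum and peak-matrix construction.

Peaks are picked once on the mean spectrum of the whole cohort at a fixed
signal-to-noise threshold (default 3), then every spectrum is reduced to an
intensity per picked peak, giving the spectra x peaks feature matrix used by
classification and differential analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import Spectrum

logger = logging.getLogger(__name__)

MAD_TO_SIGMA = 1.4826  # scales the median absolute deviation to a Gaussian sigma


@dataclass
class PeakList:
    """Picked peaks: centers (strictly increasing), heights, per-peak SNR,
    and the noise level they were scored against."""

    mz_centers: np.ndarray
    heights: np.ndarray
    snr: np.ndarray
    noise_level: float

    def __post_init__(self) -> None:
        self.mz_centers = np.asarray(self.mz_centers, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (len(self.mz_centers) == len(self.heights) == len(self.snr)):
            raise ValueError("PeakList arrays must have equal length")
        if len(self.mz_centers) > 1 and not np.all(np.diff(self.mz_centers) > 0):
            raise ValueError("mz_centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz_centers)


@dataclass
class PeakMatrix:
    """Spectra x picked-peaks intensity matrix.

    ``meta`` has one row per spectrum (case_id, spot_id, compartment,
    class_label); ``mz`` names the peak columns; ``values`` holds the
    integrated intensities, shape (n_spectra, n_peaks).
    """

    meta: pd.DataFrame
    mz: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.meta), len(self.mz)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.meta)} spectra x {len(self.mz)} peaks"
            )

    @property
    def n_spectra(self) -> int:
        return len(self.meta)

    def rows_for(self, case_ids=None, compartment=None) -> np.ndarray:
        mask = np.ones(len(self.meta), dtype=bool)
        if case_ids is not None:
            mask &= self.meta["case_id"].isin(list(case_ids)).to_numpy()
        if compartment is not None:
            mask &= (self.meta["compartment"] == compartment).to_numpy()
        return mask

    def subset(self, mask: np.ndarray) -> "PeakMatrix":
        return PeakMatrix(
            meta=self.meta.loc[mask].reset_index(drop=True),
            mz=self.mz.copy(),
            values=self.values[mask],
        )


def mean_spectrum(spectra: list) -> Spectrum:
    """Pointwise arithmetic mean of intensities over a common m/z grid."""
    if not spectra:
        raise ValueError("mean_spectrum needs at least one spectrum")
    grid = spectra[0].mz
    for s in spectra[1:]:
        if len(s.mz) != len(grid) or not np.allclose(s.mz, grid):
            raise ValueError(
                "spectra are not on a common m/z grid; run alignment first"
            )
    mean = np.mean([s.intensity for s in spectra], axis=0)
    return Spectrum(
        mz=grid.copy(),
        intensity=mean,
        case_id="__mean__",
        spot_id="__mean__",
        extra={"n_averaged": len(spectra)},
    )


def estimate_noise(intensity: np.ndarray) -> float:
    """Robust noise level: 1.4826 x median(|y - median(y)|)."""
    y = np.asarray(intensity, dtype=float)
    if len(y) < 10:
        raise ValueError("need >= 10 samples for a noise estimate")
    return float(MAD_TO_SIGMA * np.median(np.abs(y - np.median(y))))


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima; strict on both sides, plateaus take the
    leftmost index."""
    n = len(y)
    rises = np.flatnonzero(y[1:] > y[:-1]) + 1  # candidates: strictly above left neighbor
    out = []
    for i in rises:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if j + 1 < n and y[j + 1] < y[i]:
            out.append(i)
    return np.asarray(out, dtype=int)


def detect_peaks(mean_spec: Spectrum, snr_threshold: float = 3.0) -> PeakList:
    """Pick local-maximum peaks with signal-to-noise above ``snr_threshold``.

    Noise is the scaled-MAD estimate of the whole intensity vector, and peak
    height is measured above the noise floor (the intensity median), so a
    constant offset left by baseline truncation does not masquerade as
    signal. Retained peaks keep a minimum separation of two grid steps (the
    higher peak wins). A zero noise estimate retains all local maxima at
    infinite SNR, with a logged warning.
    """
    y = mean_spec.intensity
    noise = estimate_noise(y)
    floor = float(np.median(y))
    idx = _local_maxima(y)
    if noise == 0.0:
        logger.warning("zero noise estimate; retaining all %d local maxima", len(idx))
        snr = np.full(len(idx), np.inf)
        keep = np.ones(len(idx), dtype=bool)
    else:
        snr = (y[idx] - floor) / noise
        keep = snr > snr_threshold
    idx, snr = idx[keep], snr[keep]

    # enforce minimum separation of 2 grid steps, keeping the higher peak
    if len(idx) > 1:
        dx = float(np.median(np.diff(mean_spec.mz)))
        order = np.argsort(-y[idx], kind="stable")
        kept: list[int] = []
        kept_snr: list[float] = []
        for k in order:
            if all(abs(mean_spec.mz[idx[k]] - mean_spec.mz[i]) >= 2 * dx for i in kept):
                kept.append(idx[k])
                kept_snr.append(snr[k])
        sort = np.argsort(kept)
        idx = np.asarray(kept)[sort]
        snr = np.asarray(kept_snr)[sort]

    return PeakList(
        mz_centers=mean_spec.mz[idx],
        heights=y[idx],
        snr=snr,
        noise_level=noise,
    )


def build_peak_matrix(
    spectra: list,
    peaklist: PeakList,
    window_ppm: float = 2000.0,
    integration: str = "max",
) -> PeakMatrix:
    """Reduce each spectrum to one intensity per picked peak.

    ``integration='max'`` (default) takes the maximum intensity within
    +/- ``window_ppm`` of each peak center — robust to residual misalignment;
    ``'area'`` takes the trapezoidal area over the same window. No spectrum is
    dropped; an empty peak list yields a 0-column matrix.
    """
    if integration not in ("max", "area"):
        raise ValueError("integration must be 'max' or 'area'")
    centers = peaklist.mz_centers
    n, p = len(spectra), len(centers)
    values = np.zeros((n, p))
    for i, s in enumerate(spectra):
        if p == 0:
            continue
        half = window_ppm * 1e-6 * centers
        lo = np.searchsorted(s.mz, centers - half, side="left")
        hi = np.searchsorted(s.mz, centers + half, side="right")
        for j in range(p):
            seg = s.intensity[lo[j]:hi[j]]
            if len(seg) == 0:
                continue
            if integration == "max":
                values[i, j] = seg.max()
            else:
                values[i, j] = np.trapezoid(seg, s.mz[lo[j]:hi[j]]) if len(seg) > 1 else seg[0]
    meta = pd.DataFrame(
        {
            "case_id": [s.case_id for s in spectra],
            "spot_id": [s.spot_id for s in spectra],
            "compartment": [s.compartment if s.compartment else "" for s in spectra],
            "class_label": [s.class_label if s.class_label else "" for s in spectra],
        }
    )
    return PeakMatrix(meta=meta, mz=centers.copy(), values=values)
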