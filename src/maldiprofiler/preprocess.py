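"""Spectral preprocessing: SNIP baseline removal, TIC normalization,
reference-spectrum selection, and mass-axis re-alignment.

The chain runs in a fixed order — baseline correction, then total-ion-current
normalization, then landmark-based linear re-alignment to a reference
spectrum — mirroring standard TOF profiling practice. ``run_chain`` executes
the whole chain and returns a machine-readable report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import Spectrum

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Tunable knobs of the preprocessing chain.

    snip_iterations
        Clipping half-window of the SNIP baseline estimator (default 20).
    use_lls_transform
        Apply the log-log-square-root compression before clipping; standard
        for TOF spectra with large dynamic range.
    tic_target
        ``dataset_median`` rescales every spectrum to the median input TIC
        (keeps a physical intensity scale); ``unit`` rescales to TIC = 1.
    align_tolerance_ppm
        Landmark matching window for re-alignment.
    min_landmarks
        Minimum matched landmark pairs required to fit a warp; otherwise the
        spectrum keeps an identity warp and is flagged.
    landmark_snr
        Signal-to-noise threshold for landmark peak detection.
    """

    snip_iterations: int = 20
    use_lls_transform: bool = True
    tic_target: str = "dataset_median"
    align_tolerance_ppm: float = 2000.0
    min_landmarks: int = 2
    landmark_snr: float = 5.0

    def __post_init__(self) -> None:
        if self.snip_iterations < 1:
            raise ValueError("snip_iterations must be >= 1")
        if self.align_tolerance_ppm <= 0:
            raise ValueError("align_tolerance_ppm must be > 0")
        if self.tic_target not in ("dataset_median", "unit"):
            raise ValueError("tic_target must be 'dataset_median' or 'unit'")


@dataclass
class WarpModel:
    """Global linear mass-axis warp m/z' = slope * m/z + intercept."""

    kind: str = "identity"  # "identity" | "linear"
    slope: float = 1.0
    intercept: float = 0.0
    n_landmarks: int = 0
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    flagged: bool = False


def _lls(y: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(y + 1.0) + 1.0) + 1.0)


def _inv_lls(v: np.ndarray) -> np.ndarray:
    return np.square(np.exp(np.exp(v) - 1.0) - 1.0) - 1.0


def snip_baseline(intensity: np.ndarray, iterations: int = 20, use_lls: bool = True) -> np.ndarray:
    """Estimate the baseline by statistics-sensitive nonlinear iterative
    peak-clipping (SNIP) with a decreasing clipping window.

    For window half-widths i = iterations .. 1, every interior point is
    replaced by ``min(v[m], (v[m-i] + v[m+i]) / 2)`` simultaneously; edges are
    held fixed. With ``use_lls`` the clipping operates on log-log-square-root
    compressed intensities. The result is clipped into [0, intensity].
    """
    y = np.asarray(intensity, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("intensity must be a 1-D array of length >= 3")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("intensity must be finite and >= 0")
    eff = min(int(iterations), (len(y) - 1) // 2)
    if eff < iterations:
        logger.warning(
            "SNIP window reduced from %d to %d for a %d-point spectrum",
            iterations, eff, len(y),
        )
    v = _lls(y) if use_lls else y.copy()
    for i in range(eff, 0, -1):
        clipped = np.minimum(v[i:-i], 0.5 * (v[:-2 * i] + v[2 * i:]))
        v = v.copy()
        v[i:-i] = clipped
    base = _inv_lls(v) if use_lls else v
    return np.clip(base, 0.0, y)


def subtract_baseline(spectrum: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Subtract a baseline, truncating at zero; provenance is preserved."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != spectrum.intensity.shape:
        raise ValueError(
            f"baseline length {baseline.shape} does not match spectrum {spectrum.intensity.shape}"
        )
    corrected = np.maximum(spectrum.intensity - baseline, 0.0)
    return spectrum.with_intensity(corrected, baseline_corrected=True)


def tic_normalize(spectra: list, target: str = "dataset_median"):
    """Scale every spectrum to a common total ion current.

    The common TIC is the median of the input TICs (``dataset_median``) or
    1.0 (``unit``). Zero-TIC spectra are excluded with a warning and listed in
    the returned report. Returns ``(normalized_spectra, report)`` where the
    report carries the target TIC, per-spectrum scale factors, and rejects.
    """
    if target not in ("dataset_median", "unit"):
        raise ValueError("target must be 'dataset_median' or 'unit'")
    tics = np.array([s.tic for s in spectra])
    keep = tics > 0
    rejects = [spectra[i].spot_id for i in np.flatnonzero(~keep)]
    if rejects:
        logger.warning("excluding %d zero-TIC spectra: %s", len(rejects), rejects)
    if not np.any(keep):
        raise ValueError("no spectrum has positive TIC")
    t = float(np.median(tics[keep])) if target == "dataset_median" else 1.0
    out, factors = [], {}
    for s, tic, ok in zip(spectra, tics, keep):
        if not ok:
            continue
        f = t / tic
        factors[s.spot_id] = f
        out.append(s.with_intensity(s.intensity * f, tic_normalized=True))
    report = {"target_tic": t, "scale_factors": factors, "rejects": rejects}
    return out, report


def select_reference(spectra: list) -> int:
    """Index of the spectrum whose TIC is closest to the 50th quantile of the
    TIC distribution; ties break to the lowest index."""
    if not spectra:
        raise ValueError("cannot select a reference from an empty spectrum list")
    tics = np.array([s.tic for s in spectra])
    q = np.quantile(tics, 0.5)
    return int(np.argmin(np.abs(tics - q)))


def _match_landmarks(target_mz: np.ndarray, reference_mz: np.ndarray, tol_ppm: float):
    """Nearest one-to-one landmark matching within a ppm tolerance.

    Candidate pairs are sorted by distance and accepted greedily so each
    target and each reference peak is used at most once.
    """
    cands = []
    for t in target_mz:
        j = int(np.argmin(np.abs(reference_mz - t)))
        r = reference_mz[j]
        d = abs(r - t)
        if d <= tol_ppm * 1e-6 * r:
            cands.append((d, t, r))
    cands.sort(key=lambda c: c[0])
    used_t, used_r = set(), set()
    pairs = []
    for d, t, r in cands:
        if t in used_t or r in used_r:
            continue
        used_t.add(t)
        used_r.add(r)
        pairs.append((t, r))
    return pairs


def align_spectrum(spectrum: Spectrum, reference_peaks, params: PreprocessParams):
    """Re-align a spectrum to reference landmark peaks with a global linear warp.

    Peaks are detected in the target at ``params.landmark_snr``, matched
    one-to-one to ``reference_peaks`` within ``align_tolerance_ppm``, and a
    least-squares line m/z' = slope * m/z + intercept is fitted to the matched
    pairs. Intensities are linearly re-interpolated onto the original grid.
    If fewer than ``min_landmarks`` pairs match, or the fitted slope falls
    outside (0.9, 1.1), the spectrum is returned unchanged with a flagged
    identity warp. Returns ``(aligned_spectrum, warp_model)``.
    """
    from .peaks import detect_peaks

    reference_peaks = np.asarray(reference_peaks, dtype=float)
    peaklist = detect_peaks(spectrum, snr_threshold=params.landmark_snr)
    pairs = _match_landmarks(peaklist.mz_centers, reference_peaks, params.align_tolerance_ppm)
    if len(pairs) < params.min_landmarks:
        return spectrum.with_intensity(spectrum.intensity.copy(), aligned=True), WarpModel(
            flagged=True, n_landmarks=len(pairs)
        )
    t = np.array([p[0] for p in pairs])
    r = np.array([p[1] for p in pairs])
    if len(pairs) == 2 and t[0] == t[1]:
        slope, intercept = 1.0, float(np.mean(r - t))
    else:
        slope, intercept = np.polyfit(t, r, 1)
    if not (0.9 < slope < 1.1):
        logger.warning(
            "%s/%s: rejected warp with slope %.4f", spectrum.case_id, spectrum.spot_id, slope
        )
        return spectrum.with_intensity(spectrum.intensity.copy(), aligned=True), WarpModel(
            flagged=True, n_landmarks=len(pairs)
        )
    residuals = r - (slope * t + intercept)
    warped_axis = slope * spectrum.mz + intercept
    aligned = np.interp(spectrum.mz, warped_axis, spectrum.intensity)
    model = WarpModel(
        kind="linear",
        slope=float(slope),
        intercept=float(intercept),
        n_landmarks=len(pairs),
        residuals=residuals,
    )
    return spectrum.with_intensity(aligned, aligned=True), model


def run_chain(spectra: list, params: PreprocessParams | None = None):
    """Run the full preprocessing chain in its fixed order.

    1. SNIP baseline estimation and subtraction, per spectrum.
    2. TIC normalization to the dataset target. The re-alignment reference is
       chosen from the baseline-corrected (pre-scaling) TIC distribution,
       since normalization makes all TICs equal by construction.
    3. Landmark detection on the reference and linear re-alignment of every
       spectrum onto it.

    Returns ``(spectra, report)``; the report records the reference index and
    spot, per-spectrum warp summaries, identity-warp flags, and TIC rejects.
    """
    params = params or PreprocessParams()
    corrected = []
    for s in spectra:
        base = snip_baseline(s.intensity, params.snip_iterations, params.use_lls_transform)
        corrected.append(subtract_baseline(s, base))

    ref_idx = select_reference(corrected)
    normalized, norm_report = tic_normalize(corrected, params.tic_target)

    from .peaks import detect_peaks

    ref_spot = corrected[ref_idx].spot_id
    ref_spectrum = next(s for s in normalized if s.spot_id == ref_spot)
    ref_peaks = detect_peaks(ref_spectrum, snr_threshold=params.landmark_snr).mz_centers

    aligned, warps, flagged = [], {}, []
    for s in normalized:
        out, w = align_spectrum(s, ref_peaks, params)
        aligned.append(out)
        warps[s.spot_id] = {
            "kind": w.kind,
            "slope": w.slope,
            "intercept": w.intercept,
            "n_landmarks": w.n_landmarks,
        }
        if w.flagged:
            flagged.append(s.spot_id)
    report = {
        "reference_index": ref_idx,
        "reference_spot": ref_spot,
        "n_reference_peaks": int(len(ref_peaks)),
        "tic": norm_report,
        "warps": warps,
        "identity_flagged": flagged,
    }
    return aligned, report
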