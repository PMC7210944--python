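"""Spectrum I/O, noise estimation, peak picking, monoisotopic selection.

Mirrors a manual MALDI-TOF workflow: pick local maxima above a
signal-to-noise threshold (S/N > 3 by default), then keep only the
monoisotopic member of each isotopologue cluster — with one twist that
matters for degraded collagen: a peak sitting +0.984 Da above a retained
peak is a deamidated variant of that peptide, not its first isotope
(+1.003 Da), and must itself be retained.

Noise is the windowed scaled median absolute deviation (1.4826 x MAD,
100 Da windows by default): robust to the sparse tall peaks that sit on
a MALDI baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .masses import DEAMIDATION, NEUTRON_SPACING

__all__ = [
    "Spectrum",
    "Peak",
    "read_spectrum",
    "estimate_noise",
    "pick_peaks",
    "select_monoisotopic",
    "write_peaks_tsv",
]


@dataclass(frozen=True)
class Spectrum:
    """Raw m/z and intensity arrays with free-text metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.ndim != 1 or intensity.ndim != 1 or len(mz) != len(intensity):
            raise ValueError("m/z and intensity must be 1-D arrays of equal length")
        if len(mz) < 2:
            raise ValueError("spectrum must contain at least two points")
        diffs = np.diff(mz)
        if np.any(diffs <= 0):
            idx = int(np.argmax(diffs <= 0))
            raise ValueError(f"m/z not strictly increasing at index {idx + 1}")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class Peak:
    """A picked peak: centroid m/z, apex intensity, S/N and flags."""

    mz: float
    intensity: float
    snr: float
    is_monoisotopic: bool = False
    is_deamidated: bool = False


def _read_text_spectrum(path: Path) -> Spectrum:
    mzs: list[float] = []
    intensities: list[float] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"cannot parse spectrum line {raw!r} in {path}")
        mzs.append(float(parts[0]))
        intensities.append(float(parts[1]))
    return Spectrum(np.array(mzs), np.array(intensities), metadata=str(path))


def _decode_binary_array(node) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray>: (array kind, values).

    Supports 64/32-bit little-endian floats, zlib or no compression —
    the minimal subset this package reads and writes.
    """
    import base64
    import zlib

    dtype = "<f8"
    compressed = False
    kind = None
    binary_text = ""
    for child in node:
        tag = child.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif tag == "binary":
            binary_text = child.text or ""
    raw = base64.b64decode(binary_text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml_spectrum(path: Path) -> Spectrum:
    """Minimal mzML reader: first spectrum of a single-run document."""
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    for spec_node in root.iter():
        if spec_node.tag.rsplit("}", 1)[-1] != "spectrum":
            continue
        arrays: dict[str, np.ndarray] = {}
        for node in spec_node.iter():
            if node.tag.rsplit("}", 1)[-1] == "binaryDataArray":
                kind, values = _decode_binary_array(node)
                if kind:
                    arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"mzML spectrum in {path} lacks m/z or intensity arrays")
        return Spectrum(arrays["mz"], arrays["intensity"], metadata=str(path))
    raise ValueError(f"no spectra found in {path}")


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a spectrum from two-column text or mzML.

    Text dialect: one ``m/z intensity`` pair per line, whitespace- or
    comma-separated, ``#`` comments ignored. Format is inferred from the
    extension when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "text"
    if format == "mzml":
        return _read_mzml_spectrum(path)
    if format in ("text", "two-column-text", "txt"):
        return _read_text_spectrum(path)
    raise ValueError(f"unknown spectrum format {format!r}")


def _noise_and_baseline(spectrum: Spectrum, window: float) -> tuple[np.ndarray, np.ndarray]:
    if window <= 0:
        raise ValueError("window width must be positive")
    lo = spectrum.mz[0]
    bins = np.floor((spectrum.mz - lo) / window).astype(int)
    noise = np.empty(len(spectrum), dtype=float)
    baseline = np.empty(len(spectrum), dtype=float)
    for b in np.unique(bins):
        mask = bins == b
        vals = spectrum.intensity[mask]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        noise[mask] = 1.4826 * mad
        baseline[mask] = med
    return noise, baseline


def estimate_noise(spectrum: Spectrum, window: float = 100.0) -> np.ndarray:
    """Per-point noise level: 1.4826 x MAD within tiling m/z windows.

    Windows of ``window`` Da tile [min(mz), max(mz)]; every point gets
    the noise level of the window containing it. The windowed median
    (available through peak picking) serves as the baseline estimate.
    """
    return _noise_and_baseline(spectrum, window)[0]


def _is_centroided(spectrum: Spectrum) -> bool:
    # Profile MALDI data is densely sampled; sparse point spacing means
    # the spectrum is already a centroided peak list.
    return float(np.median(np.diff(spectrum.mz))) > 0.1


def _refined_centroid(x: np.ndarray, y: np.ndarray, i: int, base: float) -> float:
    """Centroid of the peak at apex index ``i`` after matched smoothing.

    The half-height run around the apex sets the peak width; a Gaussian
    kernel of that width smooths the local segment (a matched filter for
    a Gaussian peak), and the centroid is the intensity-weighted mean
    over the smoothed half-height run.
    """
    height = y[i] - base
    half = base + 0.5 * height
    lo = hi = i
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    while hi < len(y) - 1 and y[hi + 1] >= half:
        hi += 1
    width = hi - lo + 1  # samples across FWHM
    sigma_samples = max(width / 2.3548, 1.0)
    khalf = int(3 * sigma_samples) + 1
    kernel = np.exp(-0.5 * (np.arange(-khalf, khalf + 1) / sigma_samples) ** 2)
    kernel /= kernel.sum()
    seg_lo = max(0, lo - 3 * width)
    seg_hi = min(len(y) - 1, hi + 3 * width)
    smooth = np.convolve(y[seg_lo : seg_hi + 1] - base, kernel, mode="same")
    j = int(np.argmax(smooth))
    half_s = 0.5 * smooth[j]
    l2 = h2 = j
    while l2 > 0 and smooth[l2 - 1] >= half_s:
        l2 -= 1
    while h2 < len(smooth) - 1 and smooth[h2 + 1] >= half_s:
        h2 += 1
    w = np.clip(smooth[l2 : h2 + 1], 0.0, None)
    if w.sum() <= 0:
        return float(x[i])
    return float(np.sum(x[seg_lo + l2 : seg_lo + h2 + 1] * w) / np.sum(w))


def pick_peaks(
    spectrum: Spectrum,
    snr_threshold: float = 3.0,
    noise_window: float = 100.0,
    min_separation: float = 0.2,
) -> list[Peak]:
    """Local maxima with S/N above ``snr_threshold``, sorted by m/z.

    S/N is the apex height *above the local baseline* (windowed median)
    divided by the local noise (1.4826 x windowed MAD). Two further
    criteria reject single-sample noise spikes on profile data: the
    apex's immediate neighbours must stay above half the apex height
    (real peaks are several samples wide), and maxima closer than
    ``min_separation`` Da are merged into the tallest. The reported m/z
    is the intensity-weighted centroid of the half-height run after
    matched-filter smoothing (a Gaussian kernel sized from the peak's
    own half-height width); the S/N decision always uses the raw data.

    Already-centroided input (median point spacing > 0.1 Da) skips the
    shape criteria: every nonzero point is a candidate and only the S/N
    threshold applies.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    noise, baseline = _noise_and_baseline(spectrum, noise_window)
    y = spectrum.intensity
    x = spectrum.mz
    centroided = _is_centroided(spectrum)

    if centroided:
        candidates = np.nonzero(y > 0)[0]
        centroid_halfwidth = 0
    else:
        interior = np.arange(1, len(y) - 1)
        candidates = interior[
            (y[interior] > y[interior - 1]) & (y[interior] >= y[interior + 1]) & (y[interior] > 0)
        ]
        centroid_halfwidth = 2

    raw: list[Peak] = []
    for i in candidates:
        height = y[i] - baseline[i]
        if height <= 0:
            continue
        snr = height / noise[i] if noise[i] > 0 else np.inf
        if not snr > snr_threshold:
            continue
        if not centroided:
            # width criterion: neighbours above half height over baseline
            left = y[i - 1] - baseline[i]
            right = y[i + 1] - baseline[i] if i + 1 < len(y) else 0.0
            if left < 0.5 * height or right < 0.5 * height:
                continue
        if centroided:
            lo = max(0, i - centroid_halfwidth)
            hi = min(len(y) - 1, i + centroid_halfwidth)
            w = y[lo : hi + 1]
            centroid = float(np.sum(x[lo : hi + 1] * w) / np.sum(w))
        else:
            centroid = _refined_centroid(x, y, i, baseline[i])
        raw.append(Peak(mz=centroid, intensity=float(y[i]), snr=float(snr)))

    if not centroided and min_separation > 0:
        # non-maximum suppression: keep the tallest of nearby maxima
        kept: list[Peak] = []
        for p in sorted(raw, key=lambda p: -p.intensity):
            if all(abs(p.mz - q.mz) >= min_separation for q in kept):
                kept.append(p)
        raw = kept
    raw.sort(key=lambda p: p.mz)
    return raw


def select_monoisotopic(
    peaks: Sequence[Peak],
    charge: int = 1,
    tolerance: float = 0.02,
) -> list[Peak]:
    """Flag monoisotopic peaks; keep deamidated variants, drop isotopes.

    Walking the peak list in ascending m/z, each peak is classified
    against two hypotheses relative to peaks already retained: an
    isotopologue of an open cluster (next expected position at +1.00336
    / charge from the cluster's last member) or a deamidated variant of
    a retained monoisotopic peak (+0.984016 / charge). The hypothesis
    with the smaller residual wins when both fall within ``tolerance``;
    a peak matching neither opens a new cluster as its monoisotopic
    member. Deamidated variants are retained, flagged, and open their
    own cluster.
    """
    iso_step = NEUTRON_SPACING / charge
    deam_step = DEAMIDATION / charge
    ordered = sorted(peaks, key=lambda p: p.mz)

    retained: list[Peak] = []
    expected_iso: list[float] = []  # next expected isotope position per open cluster
    mono_mzs: list[float] = []

    for p in ordered:
        r_iso, iso_idx = np.inf, -1
        for j, e in enumerate(expected_iso):
            r = abs(p.mz - e)
            if r < r_iso:
                r_iso, iso_idx = r, j
        r_deam = np.inf
        for q_mz in mono_mzs:
            r = abs(p.mz - (q_mz + deam_step))
            r_deam = min(r_deam, r)

        if r_iso <= tolerance and r_iso <= r_deam:
            # isotopologue: not retained, advance the cluster
            expected_iso[iso_idx] = p.mz + iso_step
        elif r_deam <= tolerance:
            peak = replace(p, is_monoisotopic=True, is_deamidated=True)
            retained.append(peak)
            mono_mzs.append(p.mz)
            expected_iso.append(p.mz + iso_step)
        else:
            peak = replace(p, is_monoisotopic=True)
            retained.append(peak)
            mono_mzs.append(p.mz)
            expected_iso.append(p.mz + iso_step)
    return retained


def write_peaks_tsv(peaks: Sequence[Peak], path: str | Path) -> None:
    lines = ["mz\tintensity\tsnr\tmonoisotopic\tdeamidated"]
    for p in peaks:
        lines.append(
            f"{p.mz:.4f}\t{p.intensity:.6g}\t{p.snr:.3f}\t"
            f"{int(p.is_monoisotopic)}\t{int(p.is_deamidated)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
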