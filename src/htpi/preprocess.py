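"""TIC normalization, ROI mean spectra and relative-abundance peak picking.

Peak selection follows the intact-protein linear-TOF convention: the ROI's
mean TIC-normalized spectrum is lightly smoothed, local maxima above a
relative-abundance threshold (default 1% of the base peak) are kept, maxima
closer than the local peak width are merged keeping the taller, and each
apex is refined by an intensity-weighted centroid over the contiguous
region above half-maximum.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .msio import MSIDataset

__all__ = ["PeakList", "tic_normalize", "roi_mean_spectrum", "pick_peaks"]

log = logging.getLogger(__name__)

PEAK_COLUMNS = ["roi", "mz", "intensity", "rel_abundance", "window_lo", "window_hi"]


@dataclass
class PeakList:
    """Centroided ROI-level peaks with base-peak-relative abundances."""

    df: pd.DataFrame
    roi: str = ""

    def __post_init__(self):
        missing = set(PEAK_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"PeakList missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mz(self) -> np.ndarray:
        return self.df["mz"].to_numpy()

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "PeakList":
        df = pd.read_csv(path, sep="\t")
        roi = df["roi"].iloc[0] if len(df) else ""
        return cls(df=df, roi=roi)


def tic_normalize(dataset: MSIDataset, inplace: bool = False) -> MSIDataset:
    """Scale each pixel spectrum so its TIC equals the dataset mean raw TIC.

    Relative intensities within a pixel are unchanged.  Pixels with zero TIC
    are excluded from the mean, left at zero, flagged in
    ``metadata["zero_tic_pixels"]`` and logged.
    """
    ds = dataset if inplace else dataset.copy()
    tic = ds.tic()
    ok = tic > 0
    if not ok.any():
        raise ValueError("all pixels have zero TIC")
    mean_tic = tic[ok].mean()
    scale = np.ones_like(tic)
    scale[ok] = mean_tic / tic[ok]
    ds.intensities *= scale[:, None].astype(ds.intensities.dtype)
    n_zero = int((~ok).sum())
    if n_zero:
        log.warning("tic_normalize: %d zero-TIC pixels excluded", n_zero)
    ds.metadata["zero_tic_pixels"] = np.nonzero(~ok)[0].tolist()
    ds.metadata["tic_normalized"] = True
    ds.metadata["mean_raw_tic"] = float(mean_tic)
    return ds


def roi_mean_spectrum(dataset: MSIDataset, label: str) -> np.ndarray:
    """Arithmetic mean spectrum over one ROI's pixels.

    Callers normalize first (:func:`tic_normalize`); this function averages
    the spectra as given.
    """
    idx, spectra = dataset.roi_view(label)
    if idx.size == 0:
        raise ValueError(f"ROI {label!r} is empty")
    return spectra.mean(axis=0, dtype=np.float64)


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y.astype(np.float64)
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="same")


def pick_peaks(
    mz: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.01,
    min_separation: float | None = None,
    resolution: float = 800.0,
    mode: str = "base_peak",
    roi: str = "",
    smooth_width: int = 3,
) -> PeakList:
    """Pick peaks from one (ROI mean) spectrum.

    threshold
        Relative-abundance cutoff.  With ``mode="base_peak"`` (default) it
        is a fraction of the tallest peak's apex; with ``mode="tic"`` a
        peak is kept when its apex times the local FWHM exceeds
        ``threshold`` of the spectrum's total integral (a summed-TIC
        fraction reading of the same rule).
    min_separation
        Peaks closer than this (Da) are merged keeping the taller.  Default:
        the local expected FWHM, ``m / resolution``.
    """
    mz = np.asarray(mz, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if mz.size < 3 or np.all(y == y[0]):
        return PeakList(df=pd.DataFrame(columns=PEAK_COLUMNS), roi=roi)
    ys = _smooth(y, smooth_width)

    cand = find_peaks(ys)[0]  # handles flat-topped (plateau) maxima
    if cand.size == 0:
        return PeakList(df=pd.DataFrame(columns=PEAK_COLUMNS), roi=roi)

    # refine each candidate apex to the local raw maximum
    apex_idx = []
    for i in cand:
        lo = max(0, i - smooth_width)
        hi = min(y.size, i + smooth_width + 1)
        apex_idx.append(lo + int(np.argmax(y[lo:hi])))
    apex_idx = sorted(set(apex_idx))

    base_apex = max(y[i] for i in apex_idx)
    total = np.trapezoid(y, mz)

    def keeps(i):
        if mode == "base_peak":
            return y[i] >= threshold * base_apex
        elif mode == "tic":
            return y[i] * (mz[i] / resolution) >= threshold * total
        raise ValueError(f"unknown mode {mode!r}")

    apex_idx = [i for i in apex_idx if keeps(i)]

    # merge peaks closer than min_separation (default: local FWHM)
    apex_idx.sort()
    merged: list[int] = []
    for i in apex_idx:
        sep = min_separation if min_separation is not None else mz[i] / resolution
        if merged and mz[i] - mz[merged[-1]] < sep:
            if y[i] > y[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)

    rows = []
    for k, i in enumerate(merged):
        half = y[i] / 2.0
        lo = i
        while lo > 0 and y[lo - 1] >= half and y[lo - 1] <= y[lo]:
            lo -= 1
        hi = i
        while hi < y.size - 1 and y[hi + 1] >= half and y[hi + 1] <= y[hi]:
            hi += 1
        seg = slice(lo, hi + 1)
        # weight by height above the half-max level: removes most of the
        # discretisation bias of a plain centroid at sigma ~ bin width
        w = np.clip(y[seg] - half, 1e-12, None)
        centroid = float(np.average(mz[seg], weights=w))
        w_lo, w_hi = float(mz[lo]), float(mz[hi])
        # clip windows at midpoints to neighbours so they cannot overlap
        if k > 0:
            w_lo = max(w_lo, (mz[merged[k - 1]] + mz[i]) / 2.0)
        if k < len(merged) - 1:
            w_hi = min(w_hi, (mz[i] + mz[merged[k + 1]]) / 2.0)
        rows.append((roi, centroid, float(y[i]), float(y[i] / base_apex), w_lo, w_hi))

    df = pd.DataFrame(rows, columns=PEAK_COLUMNS).sort_values("mz", ignore_index=True)
    return PeakList(df=df, roi=roi)
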