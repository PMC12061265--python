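"""MSI dataset container, imzML round-trip, ROI masks and per-ROI views.

The in-memory convention everywhere in the package is the observed [M+H]+
m/z axis (what a linear TOF records); conversion to neutral mass happens
only inside annotation.  Pixels are stored row-major; coordinates are
0-based internally and 1-based in imzML, per that format's convention.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MSIDataset",
    "IonImage",
    "FormatError",
    "read_imzml",
    "write_imzml",
    "read_mask",
    "write_mask",
    "HP_SUBREGIONS",
    "COMPOSITE_ROIS",
]

HP_SUBREGIONS = ("DG", "CA1", "CA2", "CA3", "SUB")
#: composite labels resolved by :meth:`MSIDataset.roi_view`
COMPOSITE_ROIS = {"HP": HP_SUBREGIONS}

BACKGROUND = ""


class FormatError(ValueError):
    pass


@dataclass
class MSIDataset:
    """Pixel grid of spectra on a shared m/z axis plus an ROI label mask."""

    mz_axis: np.ndarray            # (M,), strictly increasing [M+H]+ m/z
    intensities: np.ndarray        # (P, M), non-negative
    pixel_coords: np.ndarray       # (P, 2) 0-based (row, col)
    roi_labels: np.ndarray         # (P,) str; "" = background
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.mz_axis) <= 0):
            raise FormatError("m/z axis must be strictly increasing")
        if self.intensities.shape != (self.pixel_coords.shape[0], self.mz_axis.size):
            raise FormatError("intensity matrix shape mismatch")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        gs = self.metadata.get("grid_shape")
        if gs is not None:
            return tuple(gs)
        return (int(self.pixel_coords[:, 0].max()) + 1,
                int(self.pixel_coords[:, 1].max()) + 1)

    def labels(self) -> list[str]:
        return sorted(set(self.roi_labels.tolist()) - {BACKGROUND})

    def roi_indices(self, label: str) -> np.ndarray:
        if label in COMPOSITE_ROIS:
            members = COMPOSITE_ROIS[label]
            sel = np.isin(self.roi_labels, members)
        else:
            if label not in set(self.roi_labels.tolist()):
                raise KeyError(
                    f"unknown ROI label {label!r}; available: {self.labels()}"
                )
            sel = self.roi_labels == label
        return np.nonzero(sel)[0]

    def roi_view(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(pixel indices, spectra view) for one ROI label.

        ``"HP"`` resolves to the union of the five hippocampal subregions.
        """
        idx = self.roi_indices(label)
        return idx, self.intensities[idx]

    def tic(self) -> np.ndarray:
        """Per-pixel total ion current (trapezoidal integral over the axis)."""
        return np.trapezoid(self.intensities, self.mz_axis, axis=1)

    def label_grid(self) -> np.ndarray:
        """ROI labels as a (rows, cols) image."""
        grid = np.full(self.grid_shape, BACKGROUND, dtype=self.roi_labels.dtype)
        grid[self.pixel_coords[:, 0], self.pixel_coords[:, 1]] = self.roi_labels
        return grid

    def copy(self) -> "MSIDataset":
        return MSIDataset(
            mz_axis=self.mz_axis.copy(),
            intensities=self.intensities.copy(),
            pixel_coords=self.pixel_coords.copy(),
            roi_labels=self.roi_labels.copy(),
            metadata=dict(self.metadata),
        )


@dataclass
class IonImage:
    """Per-pixel integrated, TIC-normalized intensity of one m/z window."""

    values: np.ndarray             # (rows, cols), >= 0
    target: str                    # proteoform display name or "m/z ..."
    mz_lo: float
    mz_hi: float

    def scaled(self) -> np.ndarray:
        m = self.values.max()
        return self.values / m if m > 0 else self.values.copy()

    def save(self, path) -> None:
        """Write the image as 16-bit TIFF (``.tif``/``.tiff``) or as a TSV
        matrix otherwise."""
        path = str(path)
        if path.endswith((".tif", ".tiff")):
            import tifffile

            v = self.scaled()
            tifffile.imwrite(path, (v * 65535).astype(np.uint16))
        else:
            np.savetxt(path, self.values, fmt="%.6g", delimiter="\t")


# ---------------------------------------------------------------------------
# imzML I/O (continuous mode preferred; processed mode read with resampling)

def write_imzml(dataset: MSIDataset, path) -> None:
    """Write continuous-mode imzML 1.1 + ibd with a shared m/z axis and
    32-bit intensities."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous",
                     intensity_dtype=np.float32) as w:
        for i in range(dataset.n_pixels):
            r, c = dataset.pixel_coords[i]
            w.addSpectrum(dataset.mz_axis,
                          dataset.intensities[i].astype(np.float64),
                          (int(c) + 1, int(r) + 1))


def read_imzml(path, roi_mask: np.ndarray | None = None) -> MSIDataset:
    """Read an imzML file.

    Continuous-mode files load losslessly.  Processed-mode files (per-pixel
    axes) are resampled by linear interpolation onto the first pixel's axis;
    this is lossy and flagged in ``metadata["resampled"]``.

    ``roi_mask`` optionally supplies a (rows, cols) label image (e.g. from
    :func:`read_mask`).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = str(path)
    if not os.path.exists(path):
        raise FormatError(f"no such imzML file: {path}")
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise FormatError(f"missing ibd companion for {path}")
    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # malformed XML / offsets
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    n = len(parser.coordinates)
    if n == 0:
        raise FormatError(f"{path}: no spectra")

    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=np.float64)
    continuous = "continuous" in parser.metadata.file_description.param_by_name
    intensities = np.empty((n, mz0.size), dtype=np.float32)
    resampled = False
    for i in range(n):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=np.float64)
        ints = np.asarray(ints, dtype=np.float64)
        if mzs.size == mz0.size and np.array_equal(mzs, mz0):
            intensities[i] = ints
        elif continuous:
            raise FormatError(f"{path}: m/z axis mismatch at pixel {i} in continuous mode")
        else:
            intensities[i] = np.interp(mz0, mzs, ints, left=0.0, right=0.0)
            resampled = True

    coords = np.array([(y - 1, x - 1) for (x, y, *_) in parser.coordinates])
    rows = coords[:, 0].max() + 1
    cols = coords[:, 1].max() + 1
    labels = np.full(n, BACKGROUND, dtype="<U12")
    if roi_mask is not None:
        labels = roi_mask[coords[:, 0], coords[:, 1]].astype("<U12")
    return MSIDataset(
        mz_axis=mz0,
        intensities=intensities,
        pixel_coords=coords,
        roi_labels=labels,
        metadata={"grid_shape": (int(rows), int(cols)),
                  "source": path, "resampled": resampled},
    )


# ---------------------------------------------------------------------------
# ROI mask I/O: plain-text integer grid + legend TSV sidecar

def write_mask(label_grid: np.ndarray, path) -> None:
    """Write a label image as a text grid of integer codes plus a
    ``<path>.legend.tsv`` sidecar mapping codes to labels (0=background)."""
    labels = sorted(set(label_grid.reshape(-1).tolist()) - {BACKGROUND})
    code = {lab: i + 1 for i, lab in enumerate(labels)}
    code[BACKGROUND] = 0
    grid = np.vectorize(code.get)(label_grid)
    np.savetxt(path, grid, fmt="%d")
    with open(str(path) + ".legend.tsv", "w", encoding="utf-8") as fh:
        fh.write("code\tlabel\n0\tbackground\n")
        for lab in labels:
            fh.write(f"{code[lab]}\t{lab}\n")


def read_mask(path) -> np.ndarray:
    grid = np.loadtxt(path, dtype=int)
    legend = {0: BACKGROUND}
    with open(str(path) + ".legend.tsv", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            c, lab = line.rstrip("\n").split("\t")
            legend[int(c)] = BACKGROUND if lab == "background" else lab
    out = np.full(grid.shape, BACKGROUND, dtype="<U12")
    for c, lab in legend.items():
        out[grid == c] = lab
    return out
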