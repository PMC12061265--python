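"""End-to-end orchestration: simulate/load -> normalize -> pick -> annotate
-> segment -> quantify -> report, driven by a single config.

Every stage writes its artifact as TSV (peaks, annotations, differential
results, segmentation mask, reports) into the output directory along with a
``manifest.json`` echoing the parameters and recording per-stage timings
and record counts.  Given fixed seeds the whole run is deterministic and
the TSV outputs are byte-identical across repeats.
"""
from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationTable, annotate_peaks, build_region_db, extract_ion_image
from .msio import MSIDataset, read_imzml, read_mask, write_mask
from .phantom import PhantomConfig, default_panel, export_id_tables, simulate_section
from .preprocess import PeakList, pick_peaks, roi_mean_spectrum, tic_normalize
from .quant import (
    differential_test,
    export_reports,
    roi_intensity_from_mean_spectrum,
)
from .segment import segment_by_markers

__all__ = ["RunConfig", "StageError", "PipelineResult", "run"]

log = logging.getLogger(__name__)

#: whole-brain segmentation markers: region label -> marker proteoform
DEFAULT_MARKERS = {
    "HP": "Sncb(1–64)@Ac",
    "ST": "Tmsb4x(2–44)@Ac",
    "TH": "Pcp4(2–50)@Ac",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class RunConfig:
    """Single structured configuration for a full run.

    ``source="simulate"`` drives the packaged phantom; ``source="imzml"``
    expects ``sections`` entries of {group, replicate, path} plus
    ``mask_path``.  All thresholds default to the standard workflow values
    (1% peak threshold, ±0.05% tolerance, 1.2-fold, alpha 0.05, n=3).
    """

    source: str = "simulate"
    layout: str = "hippocampus"
    seed: int = 42
    n_replicates: int = 3
    dropout: float = 0.0
    peak_threshold: float = 0.01
    tolerance: float = 5e-4
    fold_cut: float = 1.2
    alpha: float = 0.05
    test: str = "student"
    adjust: str | None = None
    min_marker_fraction: float = 0.2
    out_dir: str = "htpi_run"
    sections: list = field(default_factory=list)   # imzml mode
    mask_path: str | None = None                   # imzml mode

    def validate(self) -> None:
        for name in ("peak_threshold", "tolerance", "fold_cut", "alpha"):
            if getattr(self, name) <= 0:
                raise StageError("config", "bad-threshold", f"{name} must be > 0")
        if self.source not in ("simulate", "imzml"):
            raise StageError("config", "bad-source", f"unknown source {self.source!r}")
        if self.source == "simulate" and self.layout not in ("hippocampus", "whole_brain"):
            raise StageError("config", "bad-layout", f"unknown layout {self.layout!r}")
        if self.n_replicates < 2:
            raise StageError("config", "bad-replicates", "need >= 2 replicates per group")
        if self.source == "imzml":
            if not self.sections:
                raise StageError("config", "no-sections", "imzml mode needs sections")
            for s in self.sections:
                if not os.path.exists(s["path"]):
                    raise StageError("config", "missing-path", s["path"])
            if self.mask_path and not os.path.exists(self.mask_path):
                raise StageError("config", "missing-path", self.mask_path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True, allow_unicode=True)


@dataclass
class PipelineResult:
    manifest: dict
    differential: pd.DataFrame
    intensities: pd.DataFrame
    annotations: dict              # group -> AnnotationTable
    ground_truth: object | None
    out_dir: str


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def run(config: RunConfig) -> PipelineResult:
    """Execute the full workflow described by ``config``.

    Deterministic given seeds; any stage failure raises :class:`StageError`
    carrying the stage name and a machine-readable code.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "htpi_version": __version__,
        "parameters": asdict(config),
        "stages": {},
        "counts": {},
    }
    t_all = time.perf_counter()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"t_start": time.perf_counter() - t_all}

    def stage_done(name, **counts):
        st = manifest["stages"][name]
        st["seconds"] = round(time.perf_counter() - t_all - st.pop("t_start"), 3)
        st.update(counts)

    ground_truth = None
    # ---- input stage: mean ROI spectra per section --------------------
    stage("input")
    mean_spectra: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    roi_sizes: dict[str, int] = {}
    marker_images = None
    if config.source == "simulate":
        phantom = default_panel(config.layout, seed=config.seed)
        ground_truth = phantom.ground_truth()
        tables = export_id_tables(
            phantom, out_dir=os.path.join(config.out_dir, "ids"),
            dropout=config.dropout,
        )
        mz_axis = phantom.mz_axis
        regions = list(phantom.region_layout)
        sections_iter = [
            (g, r) for g in ("WT", "AD") for r in range(1, config.n_replicates + 1)
        ]
        for group, rep in sections_iter:
            ds, _ = simulate_section(phantom, group, replicate_seed=rep)
            tic_normalize(ds, inplace=True)
            mean_spectra[(group, rep)] = {
                reg: roi_mean_spectrum(ds, reg) for reg in regions
            }
            if not roi_sizes:
                roi_sizes = {reg: ds.roi_indices(reg).size for reg in regions}
            if marker_images is None and config.layout == "whole_brain":
                marker_images = _extract_markers(ds, tables, config.tolerance)
            del ds
    else:
        mask = read_mask(config.mask_path) if config.mask_path else None
        id_dir = os.path.join(os.path.dirname(config.mask_path or "."), "ids")
        tables = _load_id_dir(id_dir)
        mz_axis = None
        regions = None
        for s in config.sections:
            ds = read_imzml(s["path"], roi_mask=mask)
            tic_normalize(ds, inplace=True)
            if mz_axis is None:
                mz_axis = ds.mz_axis
                regions = ds.labels()
            mean_spectra[(s["group"], int(s["replicate"]))] = {
                reg: roi_mean_spectrum(ds, reg) for reg in regions
            }
            if not roi_sizes:
                roi_sizes = {reg: ds.roi_indices(reg).size for reg in regions}
            del ds
    n_sections = len(mean_spectra)
    stage_done("input", sections=n_sections, regions=len(regions))

    # ---- peak picking on pooled per-group ROI mean spectra ------------
    stage("peaks")
    reps = sorted({r for (_, r) in mean_spectra})
    peaklists: dict[str, list[PeakList]] = {}
    n_peaks = {}
    for group in ("WT", "AD"):
        pls = []
        for reg in regions:
            pooled = np.mean([mean_spectra[(group, r)][reg] for r in reps], axis=0)
            pls.append(
                pick_peaks(mz_axis, pooled, threshold=config.peak_threshold, roi=reg)
            )
        peaklists[group] = pls
        df = pd.concat([p.df for p in pls], ignore_index=True)
        df.to_csv(os.path.join(config.out_dir, f"peaks_{group}.tsv"), sep="\t",
                  index=False, float_format="%.6f")
        n_peaks[group] = len(df)
    stage_done("peaks", **{f"n_{g}": n for g, n in n_peaks.items()})

    # ---- annotation ----------------------------------------------------
    stage("annotate")
    db = build_region_db(tables)
    annotations = {}
    for group in ("WT", "AD"):
        at = annotate_peaks(peaklists[group], db, tolerance=config.tolerance)
        at.matches = at.matches.sort_values(
            ["roi", "peak_mz", "rank"], ignore_index=True
        )
        at.to_tsv(os.path.join(config.out_dir, f"annotations_{group}.tsv"))
        annotations[group] = at
    stage_done(
        "annotate",
        n_WT=len(annotations["WT"].matches),
        n_AD=len(annotations["AD"].matches),
        rejected=len(db.rejected),
    )

    # ---- segmentation (marker-based, whole-brain layouts) --------------
    if marker_images:
        stage("segment")
        segmap = segment_by_markers(marker_images, config.min_marker_fraction)
        write_mask(segmap.labels, os.path.join(config.out_dir, "segmentation.txt"))
        stage_done("segment", labels=len(segmap.label_set()))

    # ---- quantitation --------------------------------------------------
    stage("quant")
    targets = set()
    for group in ("WT", "AD"):
        for _, row in annotations[group].rank1().iterrows():
            targets.add((row["roi"], row["display_name"], row["theo_mz"]))
    rows = []
    for (reg, name, theo) in sorted(targets):
        for (group, rep), spectra in mean_spectra.items():
            rows.append(
                (
                    name, reg, group, rep,
                    roi_intensity_from_mean_spectrum(
                        mz_axis, spectra[reg], theo, n_pixels=roi_sizes[reg],
                        window=config.tolerance,
                    ),
                )
            )
    intensities = pd.DataFrame(
        rows, columns=["proteoform", "roi", "group", "replicate", "intensity"]
    ).sort_values(["proteoform", "roi", "group", "replicate"], ignore_index=True)
    intensities.to_csv(os.path.join(config.out_dir, "intensities.tsv"), sep="\t",
                       index=False, float_format="%.6g")
    results = differential_test(
        intensities, fold_cut=config.fold_cut, alpha=config.alpha,
        test=config.test, adjust=config.adjust,
    )
    results = results.sort_values(["roi", "proteoform"], ignore_index=True)
    results.to_csv(os.path.join(config.out_dir, "differential.tsv"), sep="\t",
                   index=False, float_format="%.6g")
    reports = export_reports(results, intensities, out_dir=config.out_dir)
    sig = results[results["significant"]]
    manifest["counts"] = {
        "proteoform_roi_pairs": len(results),
        "significant": int(len(sig)),
        "significant_up": int((sig["direction"] == "up").sum()),
        "significant_down": int((sig["direction"] == "down").sum()),
        "per_roi_significant": sig.groupby("roi").size().to_dict(),
    }
    stage_done("quant", pairs=len(results), significant=int(len(sig)))

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    with open(os.path.join(config.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, ensure_ascii=False)
    return PipelineResult(
        manifest=manifest,
        differential=results,
        intensities=intensities,
        annotations=annotations,
        ground_truth=ground_truth,
        out_dir=config.out_dir,
    )


def _extract_markers(ds: MSIDataset, tables, tolerance):
    """Ion images of the three canonical segmentation markers, keyed by the
    region each marks."""
    name_to_mz = {}
    for recs in tables.values():
        for r in recs:
            name_to_mz.setdefault(r.display_name, r.avg_mz)
    images = {}
    for region, marker in DEFAULT_MARKERS.items():
        if marker in name_to_mz:
            images[region] = extract_ion_image(
                ds, name_to_mz[marker], window=tolerance, target=marker
            )
    return images or None


def _load_id_dir(id_dir):
    if not os.path.isdir(id_dir):
        raise StageError("input", "missing-ids", f"no ID table directory {id_dir}")
    tables = {}
    for fn in sorted(os.listdir(id_dir)):
        if fn.startswith("ids_") and fn.endswith(".tsv"):
            tables[fn[4:-4]] = os.path.join(id_dir, fn)
    if not tables:
        raise StageError("input", "missing-ids", f"no ids_*.tsv in {id_dir}")
    return tables
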