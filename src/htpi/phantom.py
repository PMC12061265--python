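"""Ground-truthed MSI brain phantoms and matching region-specific ID tables.

The generator emulates the statistical structure of a sagittal mouse-brain
MALDI-MSI experiment at desk scale: labelled anatomical regions (CTX, TH,
ST and the hippocampal subregions DG, CA1, CA2, CA3, SUB), Gaussian peak
envelopes centred at each proteoform's average [M+H]+ m/z with a
linear-TOF-like width (FWHM/m ≈ 1/800), region-dependent base abundances,
per-pixel and per-replicate multiplicative lognormal noise, per-pixel TIC
variation, a constant additive baseline, and planted WT-vs-AD fold changes
whose identity and direction are recorded in a :class:`GroundTruth` object.

Two real sequences are used because their truncation chemistry is part of
the planted biology: the canonical 76-residue ubiquitin (Ubb, whose 1–74
and 1–72 fragments arise from insulin-degrading-enzyme cleavage) and
amyloid-beta 1–42 (gene spelled ``Abeta``; planted only in the AD group).
Every other gene sequence is a deterministic synthetic stand-in generated
to hit a target average mass, so that all panel peaks are well separated
on the m/z axis; they are not estimates of any real protein's sequence or
tissue abundance.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse

from .msio import HP_SUBREGIONS, MSIDataset
from .proteoform import (
    PROTON,
    RESIDUE_AVG,
    ModificationSpec,
    ProteoformRecord,
    compute_masses,
    write_id_table,
)

__all__ = [
    "PanelEntry",
    "PhantomConfig",
    "GroundTruth",
    "default_panel",
    "simulate_section",
    "export_id_tables",
    "sample_replicate_intensities",
    "HP_SUBREGIONS",
    "WHOLE_BRAIN_REGIONS",
]

WHOLE_BRAIN_REGIONS = ("CTX", "TH", "ST") + HP_SUBREGIONS

#: canonical 76-residue ubiquitin (real sequence)
UBIQUITIN = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)
#: amyloid-beta 1-42 (real sequence)
ABETA42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

# Vertebrate-like residue frequencies used when drawing synthetic sequences.
_AA_FREQ = {
    "A": 7.4, "C": 2.5, "D": 5.4, "E": 6.8, "F": 3.7, "G": 7.4, "H": 2.6,
    "I": 3.8, "K": 5.8, "L": 7.6, "M": 1.8, "N": 4.4, "P": 5.0, "Q": 3.7,
    "R": 4.2, "S": 8.1, "T": 6.2, "V": 6.8, "W": 1.3, "Y": 3.3,
}
_AA = np.array(list(_AA_FREQ))
_AA_P = np.array(list(_AA_FREQ.values()))
_AA_P = _AA_P / _AA_P.sum()


def _gene_rng(gene: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([zlib.crc32(gene.encode()), salt])


def synthetic_sequence(gene: str, length: int, salt: int = 0) -> str:
    """Deterministic synthetic amino-acid sequence for a stand-in gene."""
    rng = _gene_rng(gene, salt)
    return "".join(rng.choice(_AA, size=length, p=_AA_P))


def sequence_with_mass(
    gene: str, length: int, target_avg: float, tol: float = 5.0, salt: int = 0
) -> str:
    """Synthetic ``length``-residue sequence whose neutral average mass is
    within ``tol`` Da of ``target_avg`` (local residue-swap search).

    The achievable mass range is roughly [57, 186] Da per residue.
    """
    rng = _gene_rng(gene, salt)
    seq = list(rng.choice(_AA, size=length, p=_AA_P))
    _, avg = compute_masses("".join(seq))
    residues = sorted(RESIDUE_AVG)
    for _ in range(20 * length):
        gap = target_avg - avg
        if abs(gap) <= tol:
            break
        i = int(rng.integers(length))
        cur = RESIDUE_AVG[seq[i]]
        best = min(residues, key=lambda aa: abs(gap - (RESIDUE_AVG[aa] - cur)))
        avg += RESIDUE_AVG[best] - cur
        seq[i] = best
    else:
        raise ValueError(f"could not reach mass {target_avg} with {length} residues")
    return "".join(seq)


@dataclass(frozen=True)
class PanelEntry:
    """One planted proteoform with per-region (WT, AD) mean apex intensities."""

    record: ProteoformRecord
    base: dict[str, tuple[float, float]]  # region -> (wt, ad) amplitude
    is_decoy: bool = False

    @property
    def name(self) -> str:
        return self.record.display_name


@dataclass
class GroundTruth:
    """What was planted: per-(proteoform, region, group) true mean apex
    intensities and the list of truly differential pairs with direction."""

    entries: list[PanelEntry]
    differential: list[tuple[str, str, str]]  # (display_name, region, "up"|"down")

    def true_mean(self, name: str, region: str, group: str) -> float:
        for e in self.entries:
            if e.name == name:
                wt, ad = e.base.get(region, (0.0, 0.0))
                return wt if group == "WT" else ad
        raise KeyError(name)

    def fold(self, name: str, region: str) -> float:
        wt = self.true_mean(name, region, "WT")
        ad = self.true_mean(name, region, "AD")
        return np.inf if wt == 0 else ad / wt

    @property
    def decoy_names(self) -> set[str]:
        return {e.name for e in self.entries if e.is_decoy}

    def differential_set(self, region: str) -> dict[str, str]:
        return {n: d for n, r, d in self.differential if r == region}

    def to_tsv(self, path) -> None:
        """Write the planted truth: one row per (proteoform, region) with
        WT/AD mean amplitudes, true fold, decoy flag and direction."""
        directions = {(n, r): d for n, r, d in self.differential}
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("display_name\tregion\twt_mean\tad_mean\tfold\tdecoy\tdirection\n")
            for e in self.entries:
                for region, (wt, ad) in sorted(e.base.items()):
                    fold = float("inf") if wt == 0 else ad / wt
                    fh.write(
                        f"{e.name}\t{region}\t{wt:g}\t{ad:g}\t{fold:g}\t"
                        f"{int(e.is_decoy)}\t{directions.get((e.name, region), '')}\n"
                    )

    def validate(self) -> None:
        names = {e.name for e in self.entries}
        for n, r, d in self.differential:
            if n not in names:
                raise ValueError(f"differential pair references unplanted {n}")
            f = self.fold(n, r)
            if not (f >= 1.2 or f <= 1 / 1.2):
                raise ValueError(f"planted fold {f} for ({n}, {r}) below 1.2")
            if (d == "up") != (f > 1):
                raise ValueError(f"direction mismatch for ({n}, {r})")


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int]
    region_layout: dict[str, np.ndarray]  # label -> boolean pixel mask
    panel: list[PanelEntry]
    mz_start: float = 2500.0
    mz_stop: float = 20000.0
    mz_step: float = 1.0
    resolution: float = 800.0  # m / FWHM of a peak envelope
    tic_cv: float = 0.15
    pixel_cv: float = 0.10
    replicate_cv: float = 0.10
    noise_floor: float = 0.05
    seed: int = 42

    @property
    def mz_axis(self) -> np.ndarray:
        return np.arange(self.mz_start, self.mz_stop + self.mz_step / 2, self.mz_step)

    def peak_sigma(self, mz: float) -> float:
        """Gaussian sigma of the envelope at m/z (FWHM = m / resolution)."""
        return mz / self.resolution / 2.3548200450309493

    def ground_truth(self) -> GroundTruth:
        diffs = []
        for e in self.panel:
            for region, (wt, ad) in e.base.items():
                if wt == ad:
                    continue
                fold = np.inf if wt == 0 else ad / wt
                diffs.append((e.name, region, "up" if fold > 1 else "down"))
        gt = GroundTruth(entries=list(self.panel), differential=diffs)
        gt.validate()
        return gt

    def validate(self) -> None:
        if not self.panel:
            raise ValueError("empty proteoform panel")
        stack = np.stack([m for m in self.region_layout.values()])
        if (stack.sum(axis=0) > 1).any():
            raise ValueError("region masks overlap")
        for e in self.panel:
            for region, (wt, ad) in e.base.items():
                if region not in self.region_layout:
                    raise ValueError(f"{e.name}: unknown region {region}")
                if wt < 0 or ad < 0:
                    raise ValueError(f"{e.name}: negative base intensity")
        mzs = np.sort([e.record.avg_mz for e in self.panel])
        if len(mzs) > 1 and np.diff(mzs).min() < 40.0:
            raise ValueError("panel m/z values closer than 40 Da; peaks would merge")
        if mzs[0] - self.mz_start < 50 or self.mz_stop - mzs[-1] < 50:
            raise ValueError("panel m/z too close to the axis edge")


# ---------------------------------------------------------------------------
# region layouts (desk-scale cartoons of a sagittal section)

def _masks(shape, specs):
    """Rasterise ellipses in order; later regions never overwrite earlier."""
    taken = np.zeros(shape, dtype=bool)
    out = {}
    for label, (center, axes) in specs.items():
        m = np.zeros(shape, dtype=bool)
        rr, cc = ellipse(*center, *axes, shape=shape)
        m[rr, cc] = True
        m &= ~taken
        taken |= m
        out[label] = m
    return out


def hippocampus_layout(shape=(60, 80)) -> dict[str, np.ndarray]:
    """HP-only phantom: the five hippocampal subregions on a 60x80 grid."""
    return _masks(
        shape,
        {
            "DG": ((32, 18), (11, 9)),
            "CA1": ((16, 36), (8, 16)),
            "CA2": ((26, 58), (7, 9)),
            "CA3": ((42, 42), (9, 13)),
            "SUB": ((40, 64), (10, 11)),
        },
    )


def whole_brain_layout(shape=(120, 160)) -> dict[str, np.ndarray]:
    """Whole sagittal section: CTX cap, HP subregions, TH and ST, on 120x160."""
    specs = {
        "DG": ((58, 62), (7, 9)),
        "CA1": ((46, 80), (6, 14)),
        "CA2": ((52, 100), (5, 8)),
        "CA3": ((62, 88), (7, 10)),
        "SUB": ((64, 112), (8, 12)),
        "TH": ((84, 84), (14, 20)),
        "ST": ((80, 40), (12, 14)),
    }
    masks = _masks(shape, specs)
    # CTX: dorsal cap = outer brain ellipse minus an inner one, upper rows only
    outer = np.zeros(shape, dtype=bool)
    rr, cc = ellipse(60, 80, 52, 72, shape=shape)
    outer[rr, cc] = True
    inner = np.zeros(shape, dtype=bool)
    rr, cc = ellipse(70, 80, 44, 60, shape=shape)
    inner[rr, cc] = True
    ctx = outer & ~inner
    ctx[70:, :] = False
    taken = np.zeros(shape, dtype=bool)
    for m in masks.values():
        taken |= m
    masks["CTX"] = ctx & ~taken
    return masks


# ---------------------------------------------------------------------------
# default panel

def _targeted_record(gene, length, target, mods=(), start=None, end=None,
                     prefix_len=0, salt=0):
    """Record whose *slice* average mass is within ~5 Da of ``target``."""
    sl = sequence_with_mass(gene, length, target, salt=salt)
    prefix = synthetic_sequence(gene, prefix_len, salt=salt + 1) if prefix_len else ""
    full = prefix + sl
    s = prefix_len + 1 if start is None else start
    e = prefix_len + length if end is None else end
    return ProteoformRecord(gene=gene, full_sequence=full, start=s, end=e,
                            mods=tuple(mods))


def _ac():
    return ModificationSpec("Ac", 42.01057, 42.0367, 1)


def _phospho():
    return ModificationSpec("Phospho", 79.96633, 79.9799, 1)


def _pcp4_sequence() -> str:
    """Synthetic 62-residue Pcp4 stand-in built segment-wise so each of the
    six truncation forms lands on a planned, well-separated mass."""
    # cumulative neutral average mass targets of slice 2..k
    segments = [(39, 4650.0), (3, 4980.0), (4, 5420.0), (3, 5750.0), (12, 7080.0)]
    seq = ""
    prev = 0.0
    for i, (n, cum) in enumerate(segments):
        # target for this segment alone (subtract water once overall)
        tgt = cum - prev
        if i > 0:
            tgt += 18.0153  # compute_masses adds water per call; cancel it
        seg = sequence_with_mass("Pcp4", n, tgt, salt=10 + i)
        seq += seg
        prev = cum
    return "M" + seq


def default_panel(layout: str = "hippocampus", seed: int = 42,
                  n_decoys: int = 50) -> PhantomConfig:
    """The packaged study-condition phantom.

    ``layout`` is ``"hippocampus"`` (60x80, five HP subregions — the
    higher-resolution AD comparison) or ``"whole_brain"`` (120x160 with CTX,
    TH, ST and the HP subregions).  The panel plants: the three segmentation
    markers; six Pcp4 proteoforms with distinct regional patterns; the three
    AD-only Abeta proteoforms concentrated in SUB; the Ubb 1–76/1–74/1–72
    set with its SUB directions; a SUB differential set of exactly 6 down-
    and 8 up-regulated proteoforms (all true folds >= 1.5); and ``n_decoys``
    null decoys present in every region.
    """
    hp = layout == "hippocampus"
    if layout == "hippocampus":
        region_layout = hippocampus_layout()
    elif layout == "whole_brain":
        region_layout = whole_brain_layout()
    else:
        raise ValueError(f"unknown layout {layout!r}")

    sub = HP_SUBREGIONS
    bulk = ("DG", "CA1", "CA2", "CA3")  # HP minus SUB

    def spread(regions, wt, ad=None):
        ad = wt if ad is None else ad
        return {r: (wt, ad) for r in regions}

    pcp4 = _pcp4_sequence()
    lookup_records: list[PanelEntry] = []

    def entry(record, base, decoy=False):
        base = {r: v for r, v in base.items() if r in region_layout}
        if base:
            lookup_records.append(PanelEntry(record, base, decoy))

    # --- segmentation markers (Fig-1B-like patterns) ---------------------
    sncb = _targeted_record("Sncb", 64, 7450.0, mods=[_ac()])
    entry(sncb, {**spread(("DG",), 100.0), **spread(("CA1", "CA2", "CA3", "SUB"), 80.0),
                 **spread(("CTX", "TH"), 4.0)})
    tmsb = _targeted_record("Tmsb4x", 43, 5150.0, mods=[_ac()], prefix_len=1)
    entry(tmsb, {**spread(("ST",), 100.0), **spread(sub, 40.0)})

    # --- six Pcp4 proteoforms -------------------------------------------
    def pcp4_rec(end, mods):
        return ProteoformRecord(gene="Pcp4", full_sequence=pcp4, start=2, end=end,
                                mods=tuple(mods))

    entry(pcp4_rec(50, [_ac()]),                     # marker for TH; down in TH
          {**spread(("TH",), 100.0, 55.0), **spread(("ST",), 45.0)})
    entry(pcp4_rec(62, [_ac()]),                     # mainly ST; down in bulk HP
          {**spread(("ST",), 80.0), **spread(bulk, 60.0, 30.0), **spread(("SUB",), 30.0)})
    entry(pcp4_rec(62, [_ac(), _phospho()]), spread(("CTX",), 70.0))
    entry(pcp4_rec(47, [_ac()]), {**spread(("ST",), 50.0), **spread(("TH",), 50.0)})
    entry(pcp4_rec(43, [_ac()]), {**spread(("TH",), 60.0, 120.0), **spread(("ST",), 30.0)})
    entry(pcp4_rec(40, [_ac()]), {**spread(("TH",), 55.0, 110.0), **spread(("ST",), 25.0)})

    # --- Ubb set (real ubiquitin; IDE cleavage fragments) ----------------
    def ubb(end):
        return ProteoformRecord(gene="Ubb", full_sequence=UBIQUITIN, start=1, end=end)

    entry(ubb(76), {**spread(("CTX",), 60.0, 108.0), **spread(bulk, 60.0, 108.0),
                    **spread(("SUB",), 85.0, 42.5), **spread(("TH", "ST"), 40.0)})
    entry(ubb(74), {**spread(bulk, 25.0), **spread(("SUB",), 40.0, 80.0)})
    entry(ubb(72), spread(("SUB",), 30.0, 75.0))     # SUB-exclusive

    # --- Abeta: AD-only, concentrated in SUB (plus CTX/TH whole-brain) ---
    for end, amp in ((38, 30.0), (40, 35.0), (42, 40.0)):
        rec = ProteoformRecord(gene="Abeta", full_sequence=ABETA42, start=1, end=end)
        base = {"SUB": (0.0, amp)}
        if not hp:
            base.update({"CTX": (0.0, 25.0), "TH": (0.0, 20.0)})
        entry(rec, base)

    # --- remaining SUB differential proteoforms --------------------------
    entry(_targeted_record("Stmn1", 148, 16400.0, mods=[_ac()], prefix_len=1),
          {**spread(("CA1",), 25.0), **spread(("SUB",), 25.0, 50.0)})
    entry(_targeted_record("Hpca", 93, 10300.0, mods=[_ac()], prefix_len=1),
          {**spread(("DG",), 30.0), **spread(("SUB",), 30.0, 66.0)})
    entry(_targeted_record("Cplx1", 133, 14800.0, mods=[_ac()], prefix_len=1),
          {**spread(("CA3",), 35.0), **spread(("SUB",), 35.0, 63.0)})
    entry(_targeted_record("Ndufv3", 69, 7800.0, prefix_len=35),
          {**spread(bulk, 80.0), **spread(("SUB",), 110.0, 49.5)})
    entry(_targeted_record("Atp5f1e", 51, 6050.0, prefix_len=1),
          {**spread(bulk, 70.0), **spread(("SUB",), 100.0, 45.0)})
    entry(_targeted_record("Cox7c", 87, 9700.0, prefix_len=1),
          {**spread(bulk, 60.0), **spread(("SUB",), 85.0, 42.5)})
    entry(_targeted_record("Uqcrh", 88, 9300.0, prefix_len=1),
          {**spread(bulk, 65.0), **spread(("SUB",), 90.0, 45.0)})
    entry(_targeted_record("Ndufa4", 80, 8900.0, prefix_len=1),
          {**spread(bulk, 60.0), **spread(("SUB",), 85.0, 46.75)})
    # Mbp proteoform reduction in bulk hippocampus (myelin dysfunction motif)
    entry(_targeted_record("Mbp", 126, 13900.0, mods=[_ac()]),
          {**spread(bulk, 40.0, 25.0), **spread(("CTX", "TH"), 35.0, 21.0)})

    # --- null decoys -----------------------------------------------------
    named_mz = [e.record.avg_mz for e in lookup_records]
    amps = (50.0, 65.0, 80.0, 95.0)
    targets = []
    t = 3060.0
    for i in range(n_decoys):
        while min(abs(t - m) for m in named_mz + targets) < 70.0:
            t += 37.0
        targets.append(t)
        t += 300.0
    for i, tgt in enumerate(targets):
        gene = f"Dcy{i + 1:02d}"
        length = max(20, int(round(tgt / 111.0)))
        rec = _targeted_record(gene, length, tgt - PROTON)
        regions = region_layout if not hp else sub
        entry(rec, spread(tuple(regions), amps[i % len(amps)]), decoy=True)

    cfg = PhantomConfig(
        grid_shape=next(iter(region_layout.values())).shape,
        region_layout=region_layout,
        panel=lookup_records,
        seed=seed,
    )
    cfg.validate()
    cfg.ground_truth()  # raises if the planted truth is inconsistent
    return cfg


# ---------------------------------------------------------------------------
# simulation

def _lognormal_factor(rng, cv, size=None):
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-s * s / 2, s, size))


_GROUP_CODE = {"WT": 0, "AD": 1}


def simulate_section(
    config: PhantomConfig, group: str, replicate_seed: int = 0
) -> tuple[MSIDataset, GroundTruth]:
    """Simulate one tissue section of the given group.

    Each pixel spectrum is the sum over the panel of a Gaussian envelope at
    the proteoform's average [M+H]+ m/z, scaled by region base intensity x
    a section-wide replicate factor (CV ``replicate_cv``, shared by all
    proteoforms of the section — between-acquisition intensity variation)
    x a per-(pixel, proteoform) factor (CV ``pixel_cv``), plus the constant
    baseline; the whole pixel spectrum is then multiplied by a lognormal
    TIC factor (CV ``tic_cv``).  Per-proteoform *biological* replicate
    variability is deliberately not modelled (see the methods note).
    Deterministic given (config.seed, group, replicate_seed).
    """
    if group not in _GROUP_CODE:
        raise ValueError(f"group must be WT or AD, got {group!r}")
    config.validate()
    rng = np.random.default_rng([config.seed, _GROUP_CODE[group], replicate_seed])
    mz = config.mz_axis
    shape = config.grid_shape
    npix = shape[0] * shape[1]
    intens = np.full((npix, mz.size), config.noise_floor, dtype=np.float32)

    # pixel bookkeeping
    rows, cols = np.divmod(np.arange(npix), shape[1])
    coords = np.stack([rows, cols], axis=1)
    labels = np.full(npix, "", dtype="<U12")
    region_idx = {}
    for label, mask in config.region_layout.items():
        flat = mask.reshape(-1)
        labels[flat] = label
        region_idx[label] = np.nonzero(flat)[0]

    gi = 1 if group == "AD" else 0
    # Between-replicate variation is a section-wide intensity factor (matrix
    # deposition / laser performance differ between acquisitions); it is the
    # component that ROI-TIC normalization is designed to cancel.
    rep_factor = _lognormal_factor(rng, config.replicate_cv)
    for e in config.panel:
        center = e.record.avg_mz
        sigma = config.peak_sigma(center)
        lo = np.searchsorted(mz, center - 5 * sigma)
        hi = np.searchsorted(mz, center + 5 * sigma)
        profile = np.exp(-0.5 * ((mz[lo:hi] - center) / sigma) ** 2).astype(np.float32)
        for region, base in e.base.items():
            amp = base[gi] * rep_factor
            if amp == 0:
                continue
            idx = region_idx[region]
            pix = amp * _lognormal_factor(rng, config.pixel_cv, idx.size)
            intens[idx, lo:hi] += np.outer(pix, profile).astype(np.float32)

    tic_factor = _lognormal_factor(rng, config.tic_cv, npix).astype(np.float32)
    intens *= tic_factor[:, None]

    ds = MSIDataset(
        mz_axis=mz,
        intensities=intens,
        pixel_coords=coords,
        roi_labels=labels,
        metadata={
            "group": group,
            "replicate_seed": replicate_seed,
            "seed": config.seed,
            "grid_shape": shape,
            "simulated": True,
        },
    )
    return ds, config.ground_truth()


def export_id_tables(
    config: PhantomConfig, out_dir=None, dropout: float = 0.0
) -> dict[str, list[ProteoformRecord]]:
    """Region-specific ID tables: each region's table holds the proteoforms
    planted there (detectable in either group), minus a random ``dropout``
    fraction emulating identification sensitivity limits.

    Returns {region: records}; also writes ``ids_<region>.tsv`` files when
    ``out_dir`` is given.  Deterministic given ``config.seed``.
    """
    if not (0 <= dropout < 1):
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng([config.seed, 999])
    tables: dict[str, list[ProteoformRecord]] = {r: [] for r in config.region_layout}
    for e in config.panel:
        for region, (wt, ad) in e.base.items():
            if max(wt, ad) <= 0:
                continue
            if dropout and rng.random() < dropout:
                continue
            tables[region].append(e.record.with_region(region))
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for region, recs in tables.items():
            write_id_table(recs, os.path.join(out_dir, f"ids_{region}.tsv"))
    return tables


def sample_replicate_intensities(
    n_proteoforms: int, n_replicates: int, cv: float, rng: np.random.Generator,
    mean: float = 1.0,
) -> np.ndarray:
    """Draw (n_proteoforms, n_replicates) replicate-level intensities from the
    generator's between-replicate noise model (unit-mean lognormal with the
    given CV, scaled by ``mean``).

    This is the statistical kernel that :func:`simulate_section` realises
    through the imaging path; it is used directly for large Monte-Carlo
    calibration studies where rendering full images would be pointless.
    """
    return mean * _lognormal_factor(rng, cv, (n_proteoforms, n_replicates))
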