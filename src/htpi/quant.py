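"""Label-free differential proteoform quantitation between groups.

Replicate-level intensity of a proteoform in an ROI is the ROI-mean ion
image value divided by the ROI's summed TIC (times a fixed scale so numbers
are O(1)-readable) — the ROI-TIC normalization that makes sections
comparable.  Group comparison is an unpaired two-tailed t-test per
(proteoform, ROI); a proteoform is called significant when the fold change
passes the cutoff (default 1.2) *and* p < alpha (default 0.05), with no
multiple-testing correction by default; Benjamini-Hochberg adjustment is
available and recommended for exploratory panels.

The default test is Student's (pooled-variance) form.  At n = 3 per group
Welch's Satterthwaite degrees of freedom are badly conservative (empirical
size ~0.034 at nominal 0.05 under the generator's noise model), which
distorts type-I calibration; Welch remains available via ``test="welch"``
for heteroscedastic designs with more replicates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .msio import MSIDataset

__all__ = [
    "roi_intensity",
    "roi_intensity_from_mean_spectrum",
    "differential_test",
    "export_reports",
    "INTENSITY_SCALE",
]

#: fixed rescale applied to ROI-TIC-normalized intensities (keeps values O(1))
INTENSITY_SCALE = 1e4

GROUPS = ("WT", "AD")

RESULT_COLUMNS = [
    "proteoform", "roi", "mean_WT", "mean_AD", "sd_WT", "sd_AD", "n_WT",
    "n_AD", "fold", "log2_fold", "t", "p", "significant", "direction",
]


def roi_intensity(
    dataset: MSIDataset, mz: float, roi: str, window: float = 5e-4,
    scale: float = INTENSITY_SCALE,
) -> float:
    """ROI-TIC-normalized intensity of one m/z window in one ROI.

    Mean over the ROI's pixels of the trapezoidal window integral, divided
    by the ROI's summed TIC and rescaled by ``scale``.  Invariant under any
    uniform rescaling of the spectra.
    """
    idx, spectra = dataset.roi_view(roi)
    if idx.size == 0:
        raise ValueError(f"ROI {roi!r} is empty")
    axis = dataset.mz_axis
    lo = np.searchsorted(axis, mz * (1 - window))
    hi = np.searchsorted(axis, mz * (1 + window), side="right")
    vals = np.trapezoid(spectra[:, lo:hi], axis[lo:hi], axis=1)
    roi_tic = np.trapezoid(spectra, axis, axis=1).sum()
    if roi_tic <= 0:
        raise ValueError(f"ROI {roi!r} has zero TIC")
    return float(vals.mean() / roi_tic * scale)


def roi_intensity_from_mean_spectrum(
    mz_axis: np.ndarray, mean_spectrum: np.ndarray, mz: float,
    n_pixels: int = 1, window: float = 5e-4, scale: float = INTENSITY_SCALE,
) -> float:
    """Same quantity as :func:`roi_intensity`, computed from an ROI mean
    spectrum plus the ROI pixel count (the summed ROI TIC equals the mean
    spectrum's TIC times ``n_pixels``; the pixel mean of window integrals
    equals the window integral of the mean spectrum by linearity)."""
    lo = np.searchsorted(mz_axis, mz * (1 - window))
    hi = np.searchsorted(mz_axis, mz * (1 + window), side="right")
    num = np.trapezoid(mean_spectrum[lo:hi], mz_axis[lo:hi])
    den = np.trapezoid(mean_spectrum, mz_axis) * n_pixels
    if den <= 0:
        raise ValueError("zero-TIC mean spectrum")
    return float(num / den * scale)


def differential_test(
    intensities: pd.DataFrame,
    fold_cut: float = 1.2,
    alpha: float = 0.05,
    test: str = "student",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-(proteoform, ROI) WT-vs-AD differential test.

    ``intensities`` needs columns proteoform, roi, group (WT|AD),
    replicate, intensity; at least 2 replicates per group, otherwise the
    pair is excluded (listed in ``result.attrs["excluded"]``).  Fold change
    is mean(AD)/mean(WT); when mean(WT) is zero a pseudo-intensity of 1% of
    the table's smallest nonzero group mean stands in for the denominator.
    ``adjust="bh"`` applies Benjamini-Hochberg and tests significance on the
    adjusted p.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"test must be 'student' or 'welch', got {test!r}")
    needed = {"proteoform", "roi", "group", "replicate", "intensity"}
    missing = needed - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing columns {sorted(missing)}")

    group_means = (
        intensities.groupby(["proteoform", "roi", "group"])["intensity"].mean()
    )
    nonzero = group_means[group_means > 0]
    eps = 0.01 * nonzero.min() if len(nonzero) else 1.0

    rows = []
    excluded = []
    for (name, roi), sub in intensities.groupby(["proteoform", "roi"], sort=True):
        wt = sub.loc[sub["group"] == "WT", "intensity"].to_numpy(dtype=float)
        ad = sub.loc[sub["group"] == "AD", "intensity"].to_numpy(dtype=float)
        if len(wt) < 2 or len(ad) < 2:
            excluded.append((name, roi, len(wt), len(ad)))
            continue
        m_wt, m_ad = wt.mean(), ad.mean()
        s_wt = wt.std(ddof=1)
        s_ad = ad.std(ddof=1)
        if s_wt == 0 and s_ad == 0:
            if m_wt == m_ad:
                t, p = 0.0, 1.0
            else:
                t, p = np.inf if m_ad > m_wt else -np.inf, 0.0
        else:
            t, p = stats.ttest_ind(ad, wt, equal_var=(test == "student"))
            t, p = float(t), float(p)
        fold = m_ad / (m_wt if m_wt > 0 else eps)
        rows.append(
            (name, roi, m_wt, m_ad, s_wt, s_ad, len(wt), len(ad), fold,
             float(np.log2(fold)) if fold > 0 else -np.inf, t, p)
        )
    res = pd.DataFrame(rows, columns=RESULT_COLUMNS[:12])
    if adjust == "bh":
        res["p_adj"] = stats.false_discovery_control(res["p"], method="bh") if len(res) else []
        p_eff = res.get("p_adj", res["p"])
    elif adjust is None:
        p_eff = res["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    fold_ok = (res["fold"] >= fold_cut) | (res["fold"] <= 1 / fold_cut)
    res["significant"] = fold_ok & (p_eff < alpha)
    res["direction"] = np.where(
        res["fold"] > 1, "up", np.where(res["fold"] < 1, "down", "none")
    )
    res.attrs["excluded"] = excluded
    res.attrs["epsilon"] = float(eps)
    res.attrs["test"] = test
    return res


def export_reports(
    results: pd.DataFrame,
    intensities: pd.DataFrame | None = None,
    out_dir=None,
    render: bool = False,
) -> dict[str, pd.DataFrame]:
    """Volcano table, z-scored heatmap matrix and per-group CV table.

    volcano: (log2 fold, -log10 p) per proteoform x ROI.
    heatmap: per-replicate intensity matrix z-scored within each row
    (proteoform x ROI), restricted to significant rows when any exist.
    reproducibility: per-group coefficient of variation per proteoform x ROI.
    With ``render=True`` (and ``out_dir``) PNGs are drawn via matplotlib.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    volcano = results[["proteoform", "roi", "log2_fold", "p", "significant"]].copy()
    with np.errstate(divide="ignore"):
        volcano["neg_log10_p"] = -np.log10(volcano["p"])
    out = {"volcano": volcano}

    if intensities is not None:
        sig = results[results["significant"]]
        keep = sig if len(sig) else results
        keys = set(zip(keep["proteoform"], keep["roi"]))
        sub = intensities[
            [
                (p, r) in keys
                for p, r in zip(intensities["proteoform"], intensities["roi"])
            ]
        ].copy()
        sub["column"] = sub["group"] + "_" + sub["replicate"].astype(str)
        mat = sub.pivot_table(
            index=["proteoform", "roi"], columns="column", values="intensity"
        )
        z = mat.sub(mat.mean(axis=1), axis=0)
        sd = mat.std(axis=1, ddof=1).replace(0, 1.0)
        z = z.div(sd, axis=0)
        out["heatmap"] = z

        cv = (
            intensities.groupby(["proteoform", "roi", "group"])["intensity"]
            .agg(["mean", "std"])
            .reset_index()
        )
        cv["cv"] = np.where(cv["mean"] > 0, cv["std"] / cv["mean"], np.nan)
        out["reproducibility"] = cv[["proteoform", "roi", "group", "cv"]]

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        volcano.to_csv(os.path.join(out_dir, "volcano.tsv"), sep="\t",
                       index=False, float_format="%.6g")
        if "heatmap" in out:
            out["heatmap"].to_csv(os.path.join(out_dir, "heatmap.tsv"),
                                  sep="\t", float_format="%.6g")
        if "reproducibility" in out:
            out["reproducibility"].to_csv(
                os.path.join(out_dir, "reproducibility.tsv"), sep="\t",
                index=False, float_format="%.6g")
        if render:
            _render_volcano(volcano, os.path.join(out_dir, "volcano.png"))
            if "heatmap" in out:
                _render_heatmap(out["heatmap"], os.path.join(out_dir, "heatmap.png"))
    return out


def _render_volcano(volcano: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sig = volcano["significant"]
    ax.scatter(volcano.loc[~sig, "log2_fold"], volcano.loc[~sig, "neg_log10_p"],
               s=12, c="0.6", label="n.s.")
    ax.scatter(volcano.loc[sig, "log2_fold"], volcano.loc[sig, "neg_log10_p"],
               s=14, c="crimson", label="significant")
    ax.axhline(-np.log10(0.05), ls="--", lw=0.8, c="k")
    for x in (np.log2(1.2), -np.log2(1.2)):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (AD/WT)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _render_heatmap(z: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(z))))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_yticks(range(len(z)))
    ax.set_yticklabels([f"{p} [{r}]" for p, r in z.index], fontsize=6)
    ax.set_xticks(range(z.shape[1]))
    ax.set_xticklabels(z.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
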