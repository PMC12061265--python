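"""Region-specific intact-mass matching and ion-image extraction."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset, tiny_phantom
from htpi.annotate import (
    annotate_peaks,
    build_region_db,
    extract_ion_image,
    integrate_images,
)
from htpi.msio import IonImage
from htpi.phantom import UBIQUITIN, simulate_section
from htpi.preprocess import PeakList, tic_normalize
from htpi.proteoform import PROTON, ProteoformRecord, compute_masses


def rec(gene, seq, start, end, region=""):
    return ProteoformRecord(gene=gene, full_sequence=seq, start=start, end=end,
                            source_region=region)


def peaklist(roi, mzs):
    df = pd.DataFrame(
        {
            "roi": roi, "mz": mzs, "intensity": 1.0, "rel_abundance": 1.0,
            "window_lo": [m - 3 for m in mzs], "window_hi": [m + 3 for m in mzs],
        }
    )
    return PeakList(df=df, roi=roi)


def brute_force_match(peaks_df, db_df, tolerance):
    """All-pairs reference matcher, independent of the sorted-index path."""
    out = []
    for _, p in peaks_df.iterrows():
        cands = []
        for _, d in db_df.iterrows():
            err = (p["mz"] - d["theo_mz"]) / d["theo_mz"]
            if abs(err) <= tolerance:
                cands.append((abs(err), d["n_mods"], d["display_name"], err))
        cands.sort(key=lambda c: (round(c[0] / 1e-6), c[1], c[2]))
        for rank, c in enumerate(cands, 1):
            out.append((p["mz"], c[2], rank, c[3]))
    return out


UBB_DB = {
    "HP": [rec("Ubb", UBIQUITIN, 1, 76), rec("Ubb", UBIQUITIN, 1, 74),
           rec("Ubb", UBIQUITIN, 1, 72)],
}


class TestBuildRegionDb:
    def test_size_and_queryable(self):
        db = build_region_db(UBB_DB)
        assert db.size("HP") == 3
        theo = compute_masses(UBIQUITIN)[1] + PROTON
        hits = db.query("HP", theo, 5e-4)
        assert list(hits["display_name"]) == ["Ubb(1–76)"]

    def test_indexed_mz_is_average_plus_proton(self):
        db = build_region_db(UBB_DB)
        avg = compute_masses(UBIQUITIN)[1]
        row = db.regions["HP"].iloc[-1]
        assert row["theo_mz"] == pytest.approx(avg + 1.00728, abs=0.01)

    def test_sequence_wins_over_disagreeing_mono_mass(self, caplog):
        bad = ProteoformRecord(gene="Ubb", full_sequence=UBIQUITIN, start=1,
                               end=76, mono_mass=8550.0)
        with caplog.at_level("WARNING"):
            db = build_region_db({"HP": [bad]})
        assert "sequence wins" in caplog.text
        avg = compute_masses(UBIQUITIN)[1]
        assert db.regions["HP"]["theo_mz"].iloc[0] == pytest.approx(avg + PROTON, abs=0.01)

    def test_record_without_sequence_or_mass_rejected(self):
        hollow = ProteoformRecord(gene="Unk", full_sequence="", start=1, end=10)
        db = build_region_db({"HP": [hollow]})
        assert db.size("HP") == 0
        assert db.rejected == [("HP", "Unk(1–10)")]


class TestAnnotatePeaks:
    db = build_region_db(UBB_DB)
    theo76 = compute_masses(UBIQUITIN)[1] + PROTON

    def test_exact_hit_rank1_zero_error(self):
        at = annotate_peaks(peaklist("HP", [self.theo76]), self.db)
        row = at.matches.iloc[0]
        assert row["display_name"] == "Ubb(1–76)"
        assert row["rank"] == 1
        assert row["rel_error"] == pytest.approx(0.0, abs=1e-12)

    def test_outside_tolerance_no_match(self):
        at = annotate_peaks(peaklist("HP", [self.theo76 * (1 + 6e-4)]), self.db)
        assert len(at.matches) == 0
        assert len(at.unannotated) == 1

    def test_unknown_region_recorded_not_raised(self):
        at = annotate_peaks(peaklist("CTX", [self.theo76]), self.db)
        assert len(at.matches) == 0
        assert at.unannotated["reason"].iloc[0] == "no-region-db"

    def test_region_specificity(self):
        # same proteoform mass in region A's table only: a B peak at the
        # identical m/z must stay unannotated
        db = build_region_db({"A": UBB_DB["HP"], "B": []})
        at = annotate_peaks(
            [peaklist("A", [self.theo76]), peaklist("B", [self.theo76])], db
        )
        assert set(at.matches["roi"]) == {"A"}
        assert list(at.unannotated["roi"]) == ["B"]

    def test_tolerance_monotonicity(self):
        mzs = [self.theo76 * (1 + d) for d in (-4e-4, -1e-4, 0, 2e-4, 4.9e-4)]
        small = annotate_peaks(peaklist("HP", mzs), self.db, tolerance=2e-4)
        large = annotate_peaks(peaklist("HP", mzs), self.db, tolerance=5e-4)
        key = lambda df: set(zip(df["peak_mz"], df["display_name"]))
        assert key(small.matches) <= key(large.matches)

    def test_tie_breaks_by_fewer_mods(self):
        # two candidates exactly equidistant from the peak
        a = ProteoformRecord(gene="Aa", full_sequence="", start=1, end=10,
                             mono_mass=7996.0)
        from htpi.proteoform import ModificationSpec
        b = ProteoformRecord(
            gene="Bb", full_sequence="", start=1, end=10, mono_mass=7996.0,
            mods=(ModificationSpec("Ac", 0.0, 0.0),),  # same mass, one mod
        )
        db = build_region_db({"R": [a, b]})
        at = annotate_peaks(peaklist("R", [a.avg_mass + PROTON]), db)
        assert list(at.matches.sort_values("rank")["display_name"]) == [
            "Aa(1–10)", "Bb(1–10)@Ac"
        ]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        db = build_region_db(UBB_DB)
        mzs = rng.uniform(8200, 8700, size=60)
        at = annotate_peaks(peaklist("HP", list(mzs)), db, tolerance=5e-4)
        ours = [
            (m, n, r) for m, n, r in
            at.matches[["peak_mz", "display_name", "rank"]].itertuples(index=False)
        ]
        ref = [(m, n, r) for m, n, r, _ in
               brute_force_match(peaklist("HP", list(mzs)).df,
                                 db.regions["HP"], 5e-4)]
        assert sorted(ours) == sorted(ref)


class TestIonImages:
    def test_noise_free_image_proportional_to_planted_map(self):
        cfg = tiny_phantom(n_proteoforms=1, noise=False)
        cfg.noise_floor = 0.0
        ds, _ = simulate_section(cfg, "WT", 1)
        e = cfg.panel[0]
        img = extract_ion_image(ds, e.record.avg_mz, window=5e-4)
        mask = cfg.region_layout["A"]
        assert img.values[~mask].max() == 0.0
        inside = img.values[mask]
        assert np.allclose(inside, inside[0], rtol=1e-5)

    def test_full_axis_integral_equals_pixel_tic(self):
        cfg = tiny_phantom(noise=True)
        ds, _ = simulate_section(cfg, "WT", 1)
        mid = (ds.mz_axis[0] + ds.mz_axis[-1]) / 2
        width = (ds.mz_axis[-1] - ds.mz_axis[0]) / 2 / mid
        img = extract_ion_image(ds, mid, window=width * 0.9999)
        tics = ds.tic()
        r, c = ds.pixel_coords[:, 0], ds.pixel_coords[:, 1]
        assert np.allclose(img.values[r, c], tics, rtol=1e-3)

    def test_window_doubling_negligible_beyond_3_sigma(self):
        cfg = tiny_phantom(n_proteoforms=1, noise=False)
        ds, _ = simulate_section(cfg, "WT", 1)
        e = cfg.panel[0]
        mz0 = e.record.avg_mz
        w3 = 3 * cfg.peak_sigma(mz0) / mz0
        a = extract_ion_image(ds, mz0, window=w3)
        b = extract_ion_image(ds, mz0, window=2 * w3)
        mask = cfg.region_layout["A"]
        assert np.all(
            np.abs(b.values[mask] - a.values[mask]) / a.values[mask] < 0.01
        )

    def test_window_outside_axis_raises(self):
        ds, _ = simulate_section(tiny_phantom(), "WT", 1)
        with pytest.raises(ValueError):
            extract_ion_image(ds, ds.mz_axis[-1], window=1e-2)


class TestIntegrateImages:
    def img(self, vals, target="x"):
        v = np.asarray(vals, dtype=float)
        return IonImage(values=v, target=target, mz_lo=0, mz_hi=1)

    def test_single_image_identity_up_to_scale(self):
        a = self.img([[2.0, 4.0], [0.0, 1.0]])
        out = integrate_images([a], mode="sum")
        assert np.allclose(out.values, a.values / 4.0)

    def test_disjoint_union_of_support(self):
        a = self.img([[1.0, 0.0], [0.0, 0.0]])
        b = self.img([[0.0, 0.0], [0.0, 2.0]])
        out = integrate_images([a, b], mode="sum")
        assert (out.values > 0).sum() == 2

    def test_max_mode(self):
        a = self.img([[1.0, 0.5], [0.0, 0.0]])
        b = self.img([[0.2, 2.0], [0.0, 0.0]])
        out = integrate_images([a, b], mode="max")
        assert np.allclose(out.values, [[1.0, 1.0], [0.0, 0.0]])

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            integrate_images([self.img([[1.0]]), self.img([[1.0, 2.0]])])
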