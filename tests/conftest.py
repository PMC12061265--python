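import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from htpi.msio import MSIDataset
from htpi.phantom import PanelEntry, PhantomConfig
from htpi.proteoform import ProteoformRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(intensities, mz_axis=None, labels=None):
    """Tiny MSIDataset on a 1 x P grid from an explicit intensity matrix."""
    intensities = np.asarray(intensities, dtype=np.float32)
    n, m = intensities.shape
    if mz_axis is None:
        mz_axis = np.linspace(2500.0, 2500.0 + m - 1, m)
    coords = np.stack([np.zeros(n, dtype=int), np.arange(n)], axis=1)
    lab = np.array(labels if labels is not None else [""] * n, dtype="<U12")
    return MSIDataset(
        mz_axis=np.asarray(mz_axis, dtype=np.float64),
        intensities=intensities,
        pixel_coords=coords,
        roi_labels=lab,
        metadata={"grid_shape": (1, n)},
    )


def gaussian_spectrum(mz, peaks):
    """Sum of Gaussians: peaks = [(center, sigma, amplitude), ...]."""
    y = np.zeros_like(mz, dtype=np.float64)
    for c, s, a in peaks:
        y += a * np.exp(-0.5 * ((mz - c) / s) ** 2)
    return y


def tiny_phantom(
    n_proteoforms=3,
    noise=False,
    grid=(12, 18),
    seed=7,
):
    """Small two-region phantom for fast unit tests.

    Plants ``n_proteoforms`` ubiquitin-truncation records, alternating
    between regions A and B; noiseless by default.
    """
    from htpi.phantom import UBIQUITIN

    rows, cols = grid
    a = np.zeros(grid, dtype=bool)
    b = np.zeros(grid, dtype=bool)
    a[2:-2, 2 : cols // 2 - 1] = True
    b[2:-2, cols // 2 + 1 : -2] = True
    panel = []
    for i in range(n_proteoforms):
        rec = ProteoformRecord(gene="Ubb", full_sequence=UBIQUITIN, start=1,
                               end=76 - 8 * i)
        region = "A" if i % 2 == 0 else "B"
        panel.append(PanelEntry(rec, {region: (50.0 + 10 * i, 50.0 + 10 * i)}))
    cv = 0.1 if noise else 0.0
    return PhantomConfig(
        grid_shape=grid,
        region_layout={"A": a, "B": b},
        panel=panel,
        tic_cv=cv,
        pixel_cv=cv,
        replicate_cv=cv,
        noise_floor=0.05 if noise else 0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def hp_config():
    from htpi.phantom import default_panel

    return default_panel("hippocampus", seed=42)


@pytest.fixture(scope="session")
def hp_sections(hp_config):
    """One WT and one AD hippocampus section, TIC-normalized (shared)."""
    from htpi.phantom import simulate_section
    from htpi.preprocess import tic_normalize

    out = {}
    for group in ("WT", "AD"):
        ds, gt = simulate_section(hp_config, group, replicate_seed=1)
        tic_normalize(ds, inplace=True)
        out[group] = ds
    out["truth"] = gt
    return out
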