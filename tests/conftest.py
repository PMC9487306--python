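import numpy as np
import pytest

from sacao import BEVMask, MLCModel


@pytest.fixture(scope="session")
def mlc():
    return MLCModel.millennium120()


def make_mask(px: float = 0.5, half_mm: float = 60.0) -> np.ndarray:
    n = int(round(2 * half_mm / px))
    return np.zeros((n, n), dtype=bool)


def mask_coords(n: int, px: float):
    c = (np.arange(n) + 0.5 - n / 2) * px
    return np.meshgrid(c, c)  # (u, v) grids


def disk_mask(r: float, cu: float = 0.0, cv: float = 0.0, px: float = 0.5, half_mm: float = 60.0) -> BEVMask:
    m = make_mask(px, half_mm)
    uu, vv = mask_coords(m.shape[0], px)
    m[(uu - cu) ** 2 + (vv - cv) ** 2 <= r * r] = True
    return BEVMask(pixels=m, pixel_spacing=px)


def rect_mask(w: float, h: float, px: float = 0.5, half_mm: float = 60.0) -> BEVMask:
    m = make_mask(px, half_mm)
    uu, vv = mask_coords(m.shape[0], px)
    m[(np.abs(uu) <= w / 2 - 1e-9) & (np.abs(vv) <= h / 2 - 1e-9)] = True
    return BEVMask(pixels=m, pixel_spacing=px)


def union_masks(a: BEVMask, b: BEVMask) -> BEVMask:
    return BEVMask(pixels=a.pixels | b.pixels, pixel_spacing=a.pixel_spacing)


def per_band_aperture_area_oracle(bev: BEVMask, mlc: MLCModel) -> float:
    """Brute-force per-band pixel scan: cm^2 of the conformal aperture."""
    edges = mlc.v_edges
    px = bev.pixel_spacing
    v = bev.v_centers()
    u = bev.u_centers()
    total = 0.0
    for i in range(mlc.n_pairs):
        rows = np.nonzero((v >= edges[i]) & (v < edges[i + 1]))[0]
        if rows.size == 0:
            continue
        cols = np.nonzero(bev.pixels[rows].any(axis=0))[0]
        if cols.size:
            total += (edges[i + 1] - edges[i]) * (u[cols[-1]] - u[cols[0]] + px)
    return total / 100.0
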