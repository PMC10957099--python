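"""Independent brute-force oracles shared by the unit and acceptance suites."""

import numpy as np
from skimage.measure import regionprops

from fearpipe.miniscope import Component, RoiFilterParams


def make_component(mask: np.ndarray, snr: float) -> Component:
    return Component(footprint=mask.astype(np.float32), trace=None, snr=snr)


def ellipse_mask(fov, center, a, b, theta=0.0) -> np.ndarray:
    rr, cc = np.mgrid[:fov[0], :fov[1]]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u**2 / a**2 + v**2 / b**2) <= 1.0


def random_component_set(rng, fov=(50, 50), max_components=6):
    """Random uniform-weight elliptical footprints with assorted sizes,
    positions (some near the edge) and continuous SNR values."""
    comps = []
    n = rng.integers(1, max_components + 1)
    for _ in range(n):
        a = rng.uniform(1.0, 9.0)
        b = a * rng.uniform(0.3, 1.0)
        center = rng.uniform(2, fov[0] - 2, 2)
        mask = ellipse_mask(fov, center, a, b, rng.uniform(0, np.pi))
        if mask.sum() == 0:
            continue
        # sometimes duplicate-with-offset to create overlapping pairs
        comps.append(make_component(mask, float(rng.uniform(0.5, 12.0))))
        if rng.random() < 0.3:
            shifted = np.roll(mask, rng.integers(-2, 3, 2), axis=(0, 1))
            comps.append(make_component(shifted, float(rng.uniform(0.5, 12.0))))
    return comps


def brute_force_filter(comps, fov, params: RoiFilterParams):
    """Plain restatement of the ROI exclusion rules using pixel-index sets
    and skimage regionprops, independent of the package implementation.
    Returns (kept_ids, {id: reason})."""
    total = fov[0] * fov[1]
    reasons = {}
    survivors = []
    for i, c in enumerate(comps):
        pixels = {(int(r), int(q)) for r, q in zip(*np.nonzero(c.footprint))}
        frac = len(pixels) / total
        if frac < params.min_area_frac:
            reasons[i] = "too_small"; continue
        if frac > params.max_area_frac:
            reasons[i] = "too_big"; continue
        margin = (params.edge_margin_px if params.edge_margin_px is not None
                  else np.sqrt(len(pixels) / np.pi))
        rs = [p[0] for p in pixels]; cs = [p[1] for p in pixels]
        if (min(rs) < margin or min(cs) < margin
                or max(rs) >= fov[0] - margin or max(cs) >= fov[1] - margin):
            reasons[i] = "edge"; continue
        mask = np.zeros(fov, dtype=int)
        for (r, q) in pixels:
            mask[r, q] = 1
        # one labeled region covering the whole support (may be disconnected)
        ecc = regionprops(mask)[0].eccentricity
        if ecc > params.eccentricity_max:
            reasons[i] = "shape"; continue
        survivors.append((i, pixels, c.snr))

    alive = {i for i, _, _ in survivors}
    by_id = {i: (pix, snr) for i, pix, snr in survivors}
    for i, pix_i, snr_i in sorted(survivors, key=lambda t: t[2]):
        if snr_i >= params.snr_min or i not in alive:
            continue
        for j, pix_j, snr_j in survivors:
            if j == i or j not in alive:
                continue
            if snr_j < snr_i or (snr_j == snr_i and j > i):
                continue
            ov = len(pix_i & pix_j) / min(len(pix_i), len(pix_j))
            if ov >= params.overlap_frac:
                alive.discard(i)
                reasons[i] = "overlap_low_snr"
                break
    for i, pix, snr in survivors:
        if i in alive and snr < params.snr_min:
            alive.discard(i)
            reasons[i] = "low_snr"
    return alive, reasons
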