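"""Independent brute-force reimplementation of the 21 complexity features.

Per-control-point aperture geometry (area, perimeter, leaf-side edge
length) is measured by rasterizing the aperture on a 0.1 mm pixel grid
and counting pixels and boundary pixel-edges; everything else is
computed by straight-line arithmetic from the clipped leaf intervals.
Nothing here shares code with planqa.features — this module exists so
the analytic geometry there can be checked against an implementation
too slow and too simple to be wrong.

Test fields should have all positions on the 0.1 mm grid; the raster
measurements are then exact.
"""

from __future__ import annotations

import numpy as np

RES = 0.1  # mm


def _clipped_rows(cp, geometry, tol, jaw_clip):
    """(pair_index, left, right, y_lo, y_hi) for every open pair."""
    edges = geometry.leaf_edge_y
    x1, x2, y1, y2 = cp.jaws
    rows = []
    for i in range(geometry.n_pairs):
        l, r = cp.bank_left[i], cp.bank_right[i]
        lo, hi = edges[i], edges[i + 1]
        if jaw_clip:
            l, r = max(l, x1), min(r, x2)
            lo, hi = max(lo, y1), min(hi, y2)
        if r - l > tol and hi - lo > 0:
            rows.append((i, l, r, lo, hi))
    return rows


def _grid_extent(field, jaw_clip):
    xs, ys = [], []
    from planqa.mlc_io import DEFAULT_CLOSURE_TOLERANCE

    for cp in field.control_points:
        for _, l, r, lo, hi in _clipped_rows(cp, field.geometry, DEFAULT_CLOSURE_TOLERANCE, jaw_clip):
            xs += [l, r]
            ys += [lo, hi]
    return min(xs) - 1.0, max(xs) + 1.0, min(ys) - 1.0, max(ys) + 1.0


def rasterize(rows, extent):
    """Boolean pixel grid (ny, nx) of the union of open-row rectangles."""
    xmin, xmax, ymin, ymax = extent
    nx = int(round((xmax - xmin) / RES))
    ny = int(round((ymax - ymin) / RES))
    xc = xmin + (np.arange(nx) + 0.5) * RES
    yc = ymin + (np.arange(ny) + 0.5) * RES
    grid = np.zeros((ny, nx), dtype=bool)
    for _, l, r, lo, hi in rows:
        grid[np.ix_((yc >= lo) & (yc < hi), (xc >= l) & (xc < r))] = True
    return grid


def raster_area(grid) -> float:
    return float(grid.sum()) * RES * RES


def raster_perimeter(grid) -> tuple[float, float]:
    """(perimeter, side_edge_length): total boundary pixel-edge length and
    the part running parallel to x (leaf-side edges)."""
    padded = np.pad(grid, 1)
    horiz = np.sum(padded[1:, :] != padded[:-1, :])  # edges between vertical neighbours
    vert = np.sum(padded[:, 1:] != padded[:, :-1])   # edges between horizontal neighbours
    return float((horiz + vert) * RES), float(horiz * RES)


def oracle_features(field, tol: float = 0.5, jaw_clip: bool = True) -> dict[str, float]:
    """All 21 features by rasterization + direct arithmetic."""
    geometry = field.geometry
    mu = np.array([cp.mu_fraction for cp in field.control_points])
    w = np.empty_like(mu)
    w[0] = (mu[1] - mu[0]) / 2
    w[-1] = (mu[-1] - mu[-2]) / 2
    if len(mu) > 2:
        w[1:-1] = (mu[2:] - mu[:-2]) / 2

    extent = _grid_extent(field, jaw_clip)
    union_grid = None
    per_cp = []
    for k, cp in enumerate(field.control_points):
        if w[k] <= 0:
            continue
        rows = _clipped_rows(cp, geometry, tol, jaw_clip)
        assert rows, "oracle expects MU-carrying CPs with open apertures"
        grid = rasterize(rows, extent)
        union_grid = grid.copy() if union_grid is None else (union_grid | grid)
        per_cp.append((w[k], rows, grid))

    wts = np.array([p[0] for p in per_cp])
    wts = wts / wts.sum()
    areas = np.array([raster_area(g) for _, _, g in per_cp])
    perims = np.array([raster_perimeter(g)[0] for _, _, g in per_cp])
    sides = np.array([raster_perimeter(g)[1] for _, _, g in per_cp])
    uaa = raster_area(union_grid)

    # Per-pair maximal envelope for AAV's denominator.
    env: dict[int, list] = {}
    heights: dict[int, float] = {}
    for _, rows, _ in per_cp:
        for i, l, r, lo, hi in rows:
            env.setdefault(i, []).append((l, r))
            heights[i] = max(heights.get(i, 0.0), hi - lo)
    a_max = sum(max(0.0, max(r for _, r in iv) - min(l for l, _ in iv)) * heights[i]
                for i, iv in env.items())

    sas = {x: [] for x in (5.0, 10.0, 20.0)}
    lsv_cp, mad_cp = [], []
    for _, rows, _ in per_cp:
        gaps = np.array([r - l for _, l, r, _, _ in rows])
        for x in sas:
            sas[x].append(np.mean(gaps < x))
        centers = np.array([((l + r) / 2, (lo + hi) / 2) for _, l, r, lo, hi in rows])
        mad_cp.append(np.mean(np.sqrt(centers[:, 0] ** 2 + centers[:, 1] ** 2)))
        prod = 1.0
        for col in (1, 2):  # left bank, right bank
            pos = np.array([row[col] for row in rows])
            if len(pos) <= 1 or pos.max() == pos.min():
                continue
            pmax = pos.max() - pos.min()
            prod *= np.sum(pmax - np.abs(np.diff(pos))) / ((len(pos) - 1) * pmax)
        lsv_cp.append(prod)
    lsv_cp = np.array(lsv_cp)
    mad_cp = np.array(mad_cp)
    aav_cp = areas / a_max

    x1, x2, y1, y2 = field.control_points[0].jaws
    ns = len(per_cp)
    out = {
        "MU": field.total_mu,
        "NS": float(ns),
        "MUCP": field.total_mu / ns,
        "MAA": float(np.sum(wts * areas)),
        "CVA": float(np.std(areas) / np.mean(areas)),
        "LSV": float(np.sum(wts * lsv_cp)),
        "AVV": float(np.sum(wts * aav_cp)),
        "MCS": float(np.sum(wts * lsv_cp * aav_cp)),
        "MAD": float(np.sum(wts * mad_cp)),
        "BI": float(np.sum(wts * perims ** 2 / (4 * np.pi * areas))),
        "BM": 1.0 - float(np.sum(wts * areas)) / uaa,
        "AAJA": float(np.sum(wts * areas)) / ((x2 - x1) * (y2 - y1)),
        "MAXJ": max(abs(x1), abs(x2), abs(y1), abs(y2)),
        "EM": float(np.sum(wts * sides / areas)),
        "UAA": uaa,
    }
    for x, vals in sas.items():
        out[f"SAS{x:.0f}"] = float(np.sum(wts * np.array(vals)))
        out[f"MSAS{x:.0f}"] = float(np.max(vals))
    return out
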