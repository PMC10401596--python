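"""The 21 plan-complexity features of a dynamic IMRT field.

Each feature summarises the geometry of the MLC apertures swept during
delivery, aggregated over control points with MU weights.  The set
combines the classic modulation-complexity family (LSV, AAV, MCS), the
beam irregularity / modulation / union-area family (BI, BM, UAA), the
small-aperture scores and mean asymmetry distance (SASx, MSASx, MAD),
the edge metric (EM), aperture-area statistics (MAA, CVA), jaw metrics
(AAJA, MAXJ) and the delivery scalars (MU, NS, MUCP).

Conventions
-----------
* The aperture at a control point is the union of axis-aligned
  rectangles, one per open leaf pair: ``[left, right] × [y_lo, y_hi)``.
* A pair is *open* when its tip gap exceeds the closure tolerance
  (default 0.5 mm) after jaw clipping.
* MU weights use trapezoidal attribution of the cumulative meterset
  fraction to control points: interior control point ``k`` carries
  ``(mu[k+1] - mu[k-1]) / 2``, the first and last carry the half
  interval next to them.  The weights sum to 1.
* All lengths are mm, areas mm², EM is mm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from planqa.mlc_io import DEFAULT_CLOSURE_TOLERANCE, ControlPoint, Field, MLCGeometry

#: Canonical feature order; "AVV" is the aperture-area-variability
#: column (the field's customary abbreviation is AAV, but the spelling
#: below is kept for the on-disk header).
FEATURE_NAMES = (
    "MU", "NS", "MUCP", "MAA",
    "SAS5", "SAS10", "SAS20", "MSAS5", "MSAS10", "MSAS20",
    "CVA", "LSV", "AVV", "MCS", "MAD", "BI", "BM", "AAJA", "MAXJ", "EM", "UAA",
)

SAS_THRESHOLDS_MM = (5.0, 10.0, 20.0)


class FeatureError(ValueError):
    """Raised when a feature is undefined for the given field (e.g. zero
    aperture area at an MU-carrying control point)."""


@dataclass(frozen=True)
class ApertureSnapshot:
    """Per-control-point aperture decomposition feeding every beam-level metric.

    Attributes
    ----------
    cp_index : int
        Index of the control point within the field.
    mu_weight : float
        Fraction of the beam MU attributed to this snapshot.
    open_pairs : numpy array of int
        Indices of open leaf pairs.
    intervals : (n_open, 2) array
        Open [left, right] intervals (mm) after jaw clipping, one row
        per open pair, ordered by pair index.
    row_y : (n_open, 2) array
        [y_lo, y_hi] extents (mm) of each open pair's row after jaw
        clipping.
    area : float
        Aperture area, mm².
    perimeter : float
        Perimeter of the union of the open rectangles, mm.
    side_edge_length : float
        Exposed MLC leaf-side edge length: the part of the perimeter
        running parallel to leaf travel (x), excluding leaf-tip edges.
    gaps : array
        Per-open-pair tip gaps (mm).
    centers : (n_open, 2) array
        Per-open-pair aperture centres (x, y), mm.
    """

    cp_index: int
    mu_weight: float
    open_pairs: np.ndarray
    intervals: np.ndarray
    row_y: np.ndarray
    area: float
    perimeter: float
    side_edge_length: float
    gaps: np.ndarray
    centers: np.ndarray


def mu_weights(field: Field) -> np.ndarray:
    """Trapezoidal MU attribution over control points; sums to 1."""
    mu = np.array([cp.mu_fraction for cp in field.control_points], dtype=float)
    w = np.empty_like(mu)
    w[0] = (mu[1] - mu[0]) / 2.0
    w[-1] = (mu[-1] - mu[-2]) / 2.0
    if len(mu) > 2:
        w[1:-1] = (mu[2:] - mu[:-2]) / 2.0
    return w


def _clip_rows(cp: ControlPoint, geometry: MLCGeometry, closure_tolerance: float, jaw_clip: bool):
    """Jaw-clipped per-pair intervals and row extents; returns open-pair mask and arrays."""
    left = np.asarray(cp.bank_left, dtype=float).copy()
    right = np.asarray(cp.bank_right, dtype=float).copy()
    edges = geometry.leaf_edge_y
    y_lo = edges[:-1].copy()
    y_hi = edges[1:].copy()
    if jaw_clip:
        x1, x2, y1, y2 = cp.jaws
        left = np.maximum(left, x1)
        right = np.minimum(right, x2)
        y_lo = np.maximum(y_lo, y1)
        y_hi = np.minimum(y_hi, y2)
    open_mask = (right - left > closure_tolerance) & (y_hi - y_lo > 0)
    return open_mask, left, right, y_lo, y_hi


def aperture_perimeter(intervals: np.ndarray, row_heights: np.ndarray,
                       contiguous: np.ndarray | None = None) -> tuple[float, float]:
    """Perimeter and leaf-side edge length of a stack of open-row rectangles.

    Parameters
    ----------
    intervals : (n, 2) array
        [left, right] per open row, ordered top-to-bottom (or
        bottom-to-top; the result is symmetric).
    row_heights : (n,) array
        y-extent of each open row.
    contiguous : (n-1,) bool array, optional
        ``contiguous[i]`` is True when open rows ``i`` and ``i+1`` are
        physically adjacent (no closed pair or jaw break between them).
        Defaults to all adjacent.

    Returns
    -------
    (perimeter, side_edge_length)
        ``side_edge_length`` is the total boundary length running
        parallel to leaf travel (row caps plus symmetric differences of
        adjacent-row intervals); the remainder of the perimeter is
        leaf-tip edge (2 × row height per open row).

    Notes
    -----
    Between two physically adjacent open rows the exposed horizontal
    boundary is the symmetric difference of their intervals; the first
    and last row of each maximal run contribute their full gap as top /
    bottom caps, as does any row next to a break.
    """
    intervals = np.asarray(intervals, dtype=float)
    row_heights = np.asarray(row_heights, dtype=float)
    n = len(intervals)
    if n == 0:
        return 0.0, 0.0
    if contiguous is None:
        contiguous = np.ones(max(n - 1, 0), dtype=bool)
    gaps = intervals[:, 1] - intervals[:, 0]
    horiz = 0.0
    horiz += gaps[0]  # top cap of first row
    for i in range(n - 1):
        a, b = intervals[i], intervals[i + 1]
        if contiguous[i]:
            inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
            horiz += gaps[i] + gaps[i + 1] - 2.0 * inter  # symmetric difference
        else:
            horiz += gaps[i] + gaps[i + 1]  # bottom cap + next top cap
    horiz += gaps[-1]  # bottom cap of last row
    vert = float(2.0 * np.sum(row_heights))
    return horiz + vert, horiz


def snapshot(cp: ControlPoint, geometry: MLCGeometry,
             closure_tolerance: float = DEFAULT_CLOSURE_TOLERANCE,
             jaw_clip: bool = True,
             cp_index: int = 0, mu_weight: float = 0.0) -> ApertureSnapshot:
    """Decompose one control point into the aperture quantities used by all metrics.

    With ``jaw_clip`` on (the default), every leaf interval and row
    y-extent is intersected with the jaw rectangle and pairs fully
    outside the jaws are closed.  An all-closed control point yields an
    empty snapshot with zero area and perimeter.
    """
    open_mask, left, right, y_lo, y_hi = _clip_rows(cp, geometry, closure_tolerance, jaw_clip)
    idx = np.nonzero(open_mask)[0]
    intervals = np.column_stack([left[idx], right[idx]])
    row_y = np.column_stack([y_lo[idx], y_hi[idx]])
    gaps = intervals[:, 1] - intervals[:, 0] if len(idx) else np.empty(0)
    heights = row_y[:, 1] - row_y[:, 0] if len(idx) else np.empty(0)
    area = float(np.sum(gaps * heights)) if len(idx) else 0.0
    contiguous = (np.diff(idx) == 1) if len(idx) > 1 else None
    perim, side = aperture_perimeter(intervals, heights, contiguous) if len(idx) else (0.0, 0.0)
    centers = (np.column_stack([intervals.mean(axis=1), row_y.mean(axis=1)])
               if len(idx) else np.empty((0, 2)))
    return ApertureSnapshot(
        cp_index=cp_index, mu_weight=mu_weight, open_pairs=idx,
        intervals=intervals, row_y=row_y, area=area, perimeter=perim,
        side_edge_length=side, gaps=gaps, centers=centers,
    )


def _lsv_cp(snap: ApertureSnapshot) -> float:
    """Leaf-sequence variability of one snapshot: product over the two banks
    of the normalised adjacent-leaf smoothness; 1 when all open-pair
    positions in a bank coincide (no variability)."""
    factors = []
    for col in (0, 1):
        pos = snap.intervals[:, col]
        n = len(pos)
        if n <= 1:
            factors.append(1.0)
            continue
        pos_max = float(pos.max() - pos.min())
        if pos_max == 0.0:
            factors.append(1.0)
            continue
        diffs = np.abs(np.diff(pos))
        factors.append(float(np.sum(pos_max - diffs) / ((n - 1) * pos_max)))
    return factors[0] * factors[1]


def _union_length(intervals: np.ndarray) -> float:
    """Total length of the union of 1-D intervals."""
    if len(intervals) == 0:
        return 0.0
    order = np.argsort(intervals[:, 0])
    total = 0.0
    cur_lo, cur_hi = intervals[order[0]]
    for lo, hi in intervals[order[1:]]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return float(total)


def compute_features(field: Field,
                     closure_tolerance: float = DEFAULT_CLOSURE_TOLERANCE,
                     jaw_clip: bool = True,
                     mu_weighted_maa: bool = True) -> dict[str, float]:
    """Compute the 21 complexity features of one field.

    Parameters
    ----------
    field
        A valid dynamic field with ``total_mu > 0`` and at least one
        control point with a non-empty aperture.
    closure_tolerance
        Tip gap (mm) below which a pair counts as closed.
    jaw_clip
        Intersect apertures with the jaw rectangle (physical fluence is
        jaw-limited); switch off only for geometry cross-checks.
    mu_weighted_maa
        MAA as the MU-weighted mean aperture area (default); when False
        the unweighted mean over MU-carrying control points is used.

    Returns
    -------
    dict
        The 21 features keyed by :data:`FEATURE_NAMES`, all finite.

    Raises
    ------
    FeatureError
        Zero total MU; an all-closed field; or zero aperture area at an
        MU-carrying control point (a ratio metric would be undefined —
        this indicates corrupt input rather than a value to skip).
    """
    if field.total_mu <= 0:
        raise FeatureError(f"{field.field_id}: total_mu must be positive")
    w = mu_weights(field)
    snaps = [
        snapshot(cp, field.geometry, closure_tolerance, jaw_clip, cp_index=k, mu_weight=w[k])
        for k, cp in enumerate(field.control_points)
    ]
    carrying = [s for s in snaps if s.mu_weight > 0]
    if not carrying:
        raise FeatureError(f"{field.field_id}: no MU-carrying control points")
    for s in carrying:
        if s.area <= 0:
            raise FeatureError(
                f"{field.field_id}: zero aperture area at MU-carrying control point "
                f"{s.cp_index} (BI/AAV/EM undefined)"
            )

    wts = np.array([s.mu_weight for s in carrying])
    wts = wts / wts.sum()
    areas = np.array([s.area for s in carrying])

    # Union geometry over the beam: per-pair union of open intervals.
    n_pairs = field.geometry.n_pairs
    widths = np.asarray(field.geometry.leaf_widths, dtype=float)
    per_pair_intervals: list[list[tuple[float, float]]] = [[] for _ in range(n_pairs)]
    per_pair_heights = np.zeros(n_pairs)
    for s in carrying:
        for j, pair in enumerate(s.open_pairs):
            per_pair_intervals[pair].append(tuple(s.intervals[j]))
            per_pair_heights[pair] = max(per_pair_heights[pair], s.row_y[j, 1] - s.row_y[j, 0])
    uaa = 0.0
    a_max = 0.0
    for pair in range(n_pairs):
        ivs = np.array(per_pair_intervals[pair])
        if len(ivs) == 0:
            continue
        h = per_pair_heights[pair]
        uaa += _union_length(ivs) * h
        a_max += max(0.0, ivs[:, 1].max() - ivs[:, 0].min()) * h

    # Per-snapshot metric ingredients.
    sas_cp = {x: np.array([float(np.mean(s.gaps < x)) for s in carrying]) for x in SAS_THRESHOLDS_MM}
    lsv_cp = np.array([_lsv_cp(s) for s in carrying])
    aav_cp = areas / a_max
    bi_cp = np.array([s.perimeter ** 2 / (4.0 * np.pi * s.area) for s in carrying])
    mad_cp = np.array([float(np.mean(np.hypot(s.centers[:, 0], s.centers[:, 1]))) for s in carrying])
    em_cp = np.array([s.side_edge_length / s.area for s in carrying])

    maa = float(np.sum(wts * areas)) if mu_weighted_maa else float(np.mean(areas))
    mean_area = float(np.mean(areas))
    cva = float(np.std(areas) / mean_area) if mean_area > 0 else 0.0

    x1, x2, y1, y2 = field.control_points[0].jaws
    jaw_area = (x2 - x1) * (y2 - y1)
    if jaw_area <= 0:
        raise FeatureError(f"{field.field_id}: degenerate jaw rectangle {field.control_points[0].jaws}")

    ns = len(carrying)
    feats = {
        "MU": float(field.total_mu),
        "NS": float(ns),
        "MUCP": float(field.total_mu) / ns,
        "MAA": maa,
        "CVA": cva,
        "LSV": float(np.sum(wts * lsv_cp)),
        "AVV": float(np.sum(wts * aav_cp)),
        "MCS": float(np.sum(wts * lsv_cp * aav_cp)),
        "MAD": float(np.sum(wts * mad_cp)),
        "BI": float(np.sum(wts * bi_cp)),
        "BM": 1.0 - float(np.sum(wts * areas)) / uaa,
        "AAJA": maa / jaw_area,
        "MAXJ": float(max(abs(x1), abs(x2), abs(y1), abs(y2))),
        "EM": float(np.sum(wts * em_cp)),
        "UAA": uaa,
    }
    for x in SAS_THRESHOLDS_MM:
        feats[f"SAS{x:.0f}"] = float(np.sum(wts * sas_cp[x]))
        feats[f"MSAS{x:.0f}"] = float(np.max(sas_cp[x]))
    out = {name: feats[name] for name in FEATURE_NAMES}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise FeatureError(f"{field.field_id}: non-finite features {bad}")
    return out


def features_frame(fields, **kwargs):
    """Feature table for a list of fields: one row per field_id, 21 columns."""
    import pandas as pd

    rows = {f.field_id: compute_features(f, **kwargs) for f in fields}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "field_id"
    return df
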