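"""Read, validate and write per-field MLC leaf-sequence data.

A dynamic IMRT field is an ordered list of control points; each control
point records the cumulative meterset (MU) fraction, the x-positions of
both leaf banks at isocenter and the jaw rectangle.  Coordinates follow
IEC 61217 at isocenter: x increases toward the "right" bank (bank B in
Varian terms), leaf pair ``i`` occupies ``y ∈ [leaf_edge_y[i],
leaf_edge_y[i+1])`` and the full bank is centred about y = 0.  All
positions are millimetres.

Two on-disk dialects are supported:

``mlcseq-json``
    A self-describing UTF-8 JSON document (see :func:`write_fields`)
    with keys ``field_id``, ``total_mu``, ``geometry`` and
    ``control_points``.  This is the package's native, diffable format.

``dicom-rtplan``
    A standard DICOM-RT Plan (read-only); ``BeamSequence`` maps to
    fields, ``ControlPointSequence`` to control points and
    ``CumulativeMetersetWeight`` to the MU fraction.  Beams without an
    MLC device are skipped with a warning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Leaf pairs with a tip gap at or below this many millimetres are
#: treated as closed (sliding-window plans park closed pairs with a
#: small dosimetric gap).
DEFAULT_CLOSURE_TOLERANCE = 0.5


class MLCIOError(Exception):
    """Base error for this module."""


class ParseError(MLCIOError):
    """Malformed input file."""


class ValidationError(MLCIOError):
    """A field violates a structural invariant."""


@dataclass(frozen=True)
class MLCGeometry:
    """Physical leaf-bank geometry projected to isocenter.

    Parameters
    ----------
    n_pairs
        Number of opposed leaf pairs.
    leaf_widths
        Per-pair physical widths in mm, ordered from most negative y.
    """

    n_pairs: int
    leaf_widths: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValidationError("n_pairs must be positive")
        if len(self.leaf_widths) != self.n_pairs:
            raise ValidationError(
                f"leaf_widths has {len(self.leaf_widths)} entries for n_pairs={self.n_pairs}"
            )
        if any(w <= 0 for w in self.leaf_widths):
            raise ValidationError("all leaf widths must be positive")

    @property
    def leaf_edge_y(self) -> np.ndarray:
        """Cumulative y-boundaries (mm), centred so the bank spans symmetrically about y=0."""
        edges = np.concatenate([[0.0], np.cumsum(self.leaf_widths)])
        return edges - edges[-1] / 2.0

    @classmethod
    def millennium120(cls) -> "MLCGeometry":
        """Varian Millennium-120 projection: 10 outer 10 mm pairs, 40 central 5 mm pairs, 10 outer 10 mm pairs."""
        widths = (10.0,) * 10 + (5.0,) * 40 + (10.0,) * 10
        return cls(n_pairs=60, leaf_widths=widths)


@dataclass(frozen=True)
class ControlPoint:
    """One snapshot of the delivery: leaf/jaw positions plus cumulative MU fraction."""

    mu_fraction: float
    bank_left: tuple[float, ...]
    bank_right: tuple[float, ...]
    jaws: tuple[float, float, float, float]  # (x1, x2, y1, y2), x1<=x2, y1<=y2


@dataclass(frozen=True)
class Field:
    """One IMRT beam: the unit of analysis for QA prediction."""

    field_id: str
    total_mu: float
    control_points: tuple[ControlPoint, ...]
    geometry: MLCGeometry


def validate_field(field: Field, closure_tolerance: float = DEFAULT_CLOSURE_TOLERANCE) -> list[str]:
    """Check all structural invariants of ``field``.

    Returns a list of human-readable diagnostics; an empty list means the
    field is valid.  Never raises.
    """
    diags: list[str] = []
    fid = field.field_id

    def _finite(x) -> bool:
        return np.all(np.isfinite(np.asarray(x, dtype=float)))

    if not _finite(field.total_mu) or field.total_mu < 0:
        diags.append(f"{fid}: total_mu must be a finite non-negative number, got {field.total_mu}")
    if len(field.control_points) < 2:
        diags.append(f"{fid}: dynamic delivery requires >=2 control points, got {len(field.control_points)}")

    n_pairs = field.geometry.n_pairs
    prev_mu = -math.inf
    for k, cp in enumerate(field.control_points):
        if not _finite(cp.mu_fraction) or not (0.0 <= cp.mu_fraction <= 1.0):
            diags.append(f"{fid}: control point {k}: mu_fraction {cp.mu_fraction} outside [0, 1]")
        elif cp.mu_fraction < prev_mu - 1e-12:
            diags.append(f"{fid}: control point {k}: mu_fraction decreases ({prev_mu} -> {cp.mu_fraction})")
        prev_mu = max(prev_mu, cp.mu_fraction) if _finite(cp.mu_fraction) else prev_mu

        if len(cp.bank_left) != n_pairs or len(cp.bank_right) != n_pairs:
            diags.append(f"{fid}: control point {k}: bank lengths do not match n_pairs={n_pairs}")
            continue
        if not (_finite(cp.bank_left) and _finite(cp.bank_right) and _finite(cp.jaws)):
            diags.append(f"{fid}: control point {k}: non-finite leaf or jaw position")
            continue
        left = np.asarray(cp.bank_left)
        right = np.asarray(cp.bank_right)
        bad = np.nonzero(left > right + closure_tolerance)[0]
        for i in bad:
            diags.append(
                f"{fid}: control point {k}: pair {i}: bank_left {left[i]:.3f} exceeds "
                f"bank_right {right[i]:.3f} beyond closure tolerance {closure_tolerance}"
            )
        x1, x2, y1, y2 = cp.jaws
        if x1 > x2 or y1 > y2:
            diags.append(f"{fid}: control point {k}: jaw rectangle inverted {cp.jaws}")

    if field.control_points:
        mus = [cp.mu_fraction for cp in field.control_points]
        if _finite(mus):
            if abs(mus[0]) > 1e-9:
                diags.append(f"{fid}: first mu_fraction must be 0, got {mus[0]}")
            if abs(mus[-1] - 1.0) > 1e-9:
                diags.append(f"{fid}: last mu_fraction must be 1, got {mus[-1]}")
    return diags


def _require_valid(fields: Iterable[Field], closure_tolerance: float) -> None:
    for f in fields:
        diags = validate_field(f, closure_tolerance)
        if diags:
            raise ValidationError("; ".join(diags))


# ---------------------------------------------------------------------------
# mlcseq-json dialect


def _field_to_dict(f: Field) -> dict:
    return {
        "field_id": f.field_id,
        "total_mu": f.total_mu,
        "geometry": {
            "n_pairs": f.geometry.n_pairs,
            "leaf_widths_mm": list(f.geometry.leaf_widths),
        },
        "control_points": [
            {
                "mu_fraction": cp.mu_fraction,
                "bank_left_mm": list(cp.bank_left),
                "bank_right_mm": list(cp.bank_right),
                "jaws_mm": {"x1": cp.jaws[0], "x2": cp.jaws[1], "y1": cp.jaws[2], "y2": cp.jaws[3]},
            }
            for cp in f.control_points
        ],
    }


def _field_from_dict(d: dict, index: int) -> Field:
    try:
        geom = MLCGeometry(
            n_pairs=int(d["geometry"]["n_pairs"]),
            leaf_widths=tuple(float(w) for w in d["geometry"]["leaf_widths_mm"]),
        )
        cps = tuple(
            ControlPoint(
                mu_fraction=float(c["mu_fraction"]),
                bank_left=tuple(float(x) for x in c["bank_left_mm"]),
                bank_right=tuple(float(x) for x in c["bank_right_mm"]),
                jaws=(
                    float(c["jaws_mm"]["x1"]),
                    float(c["jaws_mm"]["x2"]),
                    float(c["jaws_mm"]["y1"]),
                    float(c["jaws_mm"]["y2"]),
                ),
            )
            for c in d["control_points"]
        )
        return Field(
            field_id=str(d["field_id"]),
            total_mu=float(d["total_mu"]),
            control_points=cps,
            geometry=geom,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed field record #{index} ({d.get('field_id', '?')}): {exc}") from exc


def write_fields(fields: Sequence[Field], path: str | Path) -> None:
    """Write fields to ``path`` in the mlcseq-json dialect.

    Fields are validated first; a field with non-finite positions or any
    other invariant violation is refused with :class:`ValidationError`.
    The written file round-trips through :func:`read_fields` losslessly
    to better than 1e-6 mm.
    """
    _require_valid(fields, DEFAULT_CLOSURE_TOLERANCE)
    doc = {"format": "mlcseq-json", "version": 1, "fields": [_field_to_dict(f) for f in fields]}
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_fields(path: str | Path, format: str = "mlcseq-json",
                closure_tolerance: float = DEFAULT_CLOSURE_TOLERANCE) -> list[Field]:
    """Read per-field MLC sequences from ``path``.

    Parameters
    ----------
    path
        Input file.
    format
        ``"mlcseq-json"`` or ``"dicom-rtplan"``.
    closure_tolerance
        Gap (mm) below which a leaf pair counts as closed during
        validation.

    Returns
    -------
    list of Field
        Control points preserved in file order, positions in mm at
        isocenter.  Every returned field satisfies its invariants.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mlcseq-json":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON: {exc}") from exc
        if not isinstance(doc, dict) or "fields" not in doc:
            raise ParseError(f"{path}: missing top-level 'fields' key")
        fields = [_field_from_dict(d, i) for i, d in enumerate(doc["fields"])]
    elif format == "dicom-rtplan":
        fields = _read_dicom_rtplan(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _require_valid(fields, closure_tolerance)
    return fields


# ---------------------------------------------------------------------------
# DICOM-RT Plan reader


def _read_dicom_rtplan(path: Path) -> list[Field]:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises a mix of error types
        raise ParseError(f"{path}: cannot read DICOM: {exc}") from exc
    if not hasattr(ds, "BeamSequence"):
        raise ParseError(f"{path}: no BeamSequence; not an RT Plan?")

    fields: list[Field] = []
    for beam in ds.BeamSequence:
        geom = _geometry_from_beam(beam)
        if geom is None:
            logger.warning("beam %s has no MLC device; skipped", getattr(beam, "BeamName", "?"))
            continue
        final_weight = float(beam.FinalCumulativeMetersetWeight)
        beam_mu = _beam_meterset(ds, beam)
        cps = []
        jaws = (0.0, 0.0, 0.0, 0.0)
        left = right = (0.0,) * geom.n_pairs
        for cp in beam.ControlPointSequence:
            for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                kind = dev.RTBeamLimitingDeviceType
                pos = [float(v) for v in dev.LeafJawPositions]
                if kind in ("X", "ASYMX"):
                    jaws = (pos[0], pos[1], jaws[2], jaws[3])
                elif kind in ("Y", "ASYMY"):
                    jaws = (jaws[0], jaws[1], pos[0], pos[1])
                elif kind.startswith("MLC"):
                    n = len(pos) // 2
                    left, right = tuple(pos[:n]), tuple(pos[n:])
            cps.append(ControlPoint(
                mu_fraction=float(cp.CumulativeMetersetWeight) / final_weight,
                bank_left=left, bank_right=right, jaws=jaws,
            ))
        fields.append(Field(
            field_id=str(getattr(beam, "BeamName", f"beam{beam.BeamNumber}")),
            total_mu=beam_mu,
            control_points=tuple(cps),
            geometry=geom,
        ))
    return fields


def _geometry_from_beam(beam) -> MLCGeometry | None:
    for dev in getattr(beam, "BeamLimitingDeviceSequence", []):
        if dev.RTBeamLimitingDeviceType.startswith("MLC"):
            bounds = [float(b) for b in dev.LeafPositionBoundaries]
            widths = tuple(np.diff(bounds))
            return MLCGeometry(n_pairs=len(widths), leaf_widths=widths)
    return None


def _beam_meterset(ds, beam) -> float:
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if int(rb.ReferencedBeamNumber) == int(beam.BeamNumber):
                return float(rb.BeamMeterset)
    return 0.0
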