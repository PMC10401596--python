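"""Shared fixtures: hand-built and randomly generated MLC fields.

Random fields for geometry cross-checks have every position snapped to
the 0.1 mm grid so the rasterization oracle measures them exactly.
"""

from __future__ import annotations

import numpy as np
import pytest

from planqa.mlc_io import ControlPoint, Field, MLCGeometry
from planqa.synthetic import FieldGenParams, generate_field


def snap(x, res=0.1):
    return np.round(np.asarray(x) / res) * res


def snap_field(field: Field) -> Field:
    """Round all positions (leaves and jaws) to the 0.1 mm grid."""
    cps = tuple(
        ControlPoint(
            mu_fraction=cp.mu_fraction,
            bank_left=tuple(snap(cp.bank_left)),
            bank_right=tuple(np.maximum(snap(cp.bank_right), snap(cp.bank_left))),
            jaws=tuple(snap(cp.jaws)),
        )
        for cp in field.control_points
    )
    return Field(field_id=field.field_id, total_mu=field.total_mu,
                 control_points=cps, geometry=field.geometry)


def random_snapped_field(seed: int, n_cp: int | None = None) -> Field:
    rng = np.random.default_rng(seed)
    params = FieldGenParams(
        n_cp=n_cp or int(rng.integers(3, 9)),
        field_width=float(rng.uniform(50, 100)),
        mean_gap=float(rng.uniform(5, 35)),
        gap_jitter_sd=float(rng.uniform(0.5, 5)),
        edge_roughness_sd=float(rng.uniform(0, 5)),
        open_pair_range=(6, 16),
    )
    return snap_field(generate_field(params, rng=rng, field_id=f"rand{seed}"))


def square_field(side: float = 100.0, n_pairs: int = 20, width: float = 5.0,
                 mu: float = 100.0) -> Field:
    """Static square aperture delivered over 2 control points."""
    geom = MLCGeometry(n_pairs=n_pairs, leaf_widths=(width,) * n_pairs)
    jaws = (-side / 2 - 2, side / 2 + 2, -n_pairs * width / 2 - 2, n_pairs * width / 2 + 2)
    cp = dict(bank_left=(-side / 2,) * n_pairs, bank_right=(side / 2,) * n_pairs, jaws=jaws)
    return Field(
        field_id="square", total_mu=mu,
        control_points=(ControlPoint(mu_fraction=0.0, **cp), ControlPoint(mu_fraction=1.0, **cp)),
        geometry=geom,
    )


@pytest.fixture
def square100() -> Field:
    return square_field()


@pytest.fixture
def sliding_field() -> Field:
    return generate_field(FieldGenParams(n_cp=11, rng_seed=5), field_id="sw")
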