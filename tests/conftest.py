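from __future__ import annotations

import numpy as np
import pytest

from gausslink.structure_io import Backbone


def random_chain(n: int, rng: np.random.Generator, step: float = 3.8) -> np.ndarray:
    """Self-avoiding-ish random walk with protein-like step length."""
    pts = [np.zeros(3)]
    d = np.array([1.0, 0.0, 0.0])
    for _ in range(n - 1):
        d = d + 0.8 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + step * d)
    return np.array(pts)


def chain_backbone(points: np.ndarray, domain_id: str = "chain") -> Backbone:
    """Wrap bare CA coordinates as an all-observed Backbone (CA = only heavy atom)."""
    n = len(points)
    return Backbone(
        domain_id=domain_id,
        ca=points,
        residue_ids=[(k + 1, "") for k in range(n)],
        heavy=[points[k][None, :].copy() for k in range(n)],
        observed=np.ones(n, dtype=bool),
        res_names=["GLY"] * n,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230524)


@pytest.fixture
def threaded_m1():
    from gausslink.synthetic_data import TopologySpec, make_threaded_loop

    return make_threaded_loop(TopologySpec(m=1, sign=1, side="N"))
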