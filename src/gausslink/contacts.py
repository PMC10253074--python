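"""Native contact map: the set of residue pairs that can close a loop.

Two residues are in native contact when any two non-hydrogen atoms, one in
each residue, lie strictly closer than the cutoff (default 4.5 A).  Pairs
closer along the sequence than ``min_separation`` (default 4) are excluded
at construction time, so every stored contact is a legal loop closure.
Reconstructed (gap-bridged) residues carry no heavy atoms and therefore
never appear in the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Backbone

DEFAULT_CUTOFF = 4.5
DEFAULT_MIN_SEPARATION = 4

__all__ = ["ContactMap", "contact_map", "write_contact_table", "read_contact_table"]


@dataclass
class ContactMap:
    """Residue index pairs (i1 < i2) in native contact, with the parameters used."""

    pairs: list[tuple[int, int]]
    cutoff: float = DEFAULT_CUTOFF
    min_separation: int = DEFAULT_MIN_SEPARATION
    min_distance: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs)
        for i1, i2 in self.pairs:
            if i2 - i1 < self.min_separation:
                raise ValueError(f"contact ({i1},{i2}) below min separation")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in set(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def contact_map(
    backbone: Backbone,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactMap:
    """Heavy-atom contact map of an observed backbone.

    Uses a KD-tree over all heavy atoms and keeps a residue pair iff the
    closest inter-residue heavy-atom distance is strictly below ``cutoff``
    and the sequence separation is at least ``min_separation``.
    """
    coords = []
    owner = []
    for k in range(len(backbone)):
        if not backbone.observed[k]:
            continue
        hv = backbone.heavy[k]
        if len(hv):
            coords.append(hv)
            owner.append(np.full(len(hv), k))
    if not coords:
        warnings.warn("backbone has no observed heavy atoms; empty contact map")
        return ContactMap([], cutoff, min_separation)

    xyz = np.concatenate(coords)
    owner_arr = np.concatenate(owner)
    tree = cKDTree(xyz)
    best: dict[tuple[int, int], float] = {}
    for a, b in tree.query_pairs(cutoff):
        ra, rb = int(owner_arr[a]), int(owner_arr[b])
        if ra == rb:
            continue
        i1, i2 = (ra, rb) if ra < rb else (rb, ra)
        if i2 - i1 < min_separation:
            continue
        d = float(np.linalg.norm(xyz[a] - xyz[b]))
        if d >= cutoff:  # query_pairs is inclusive; the contact rule is strict
            continue
        if (i1, i2) not in best or d < best[(i1, i2)]:
            best[(i1, i2)] = d
    return ContactMap(sorted(best), cutoff, min_separation, best)


def write_contact_table(cmap: ContactMap, path: str) -> None:
    """Export as a 3-column text table: i1 i2 min_distance."""
    with open(path, "w") as fh:
        fh.write(f"# cutoff={cmap.cutoff} min_separation={cmap.min_separation}\n")
        for i1, i2 in cmap:
            d = cmap.min_distance.get((i1, i2), float("nan"))
            fh.write(f"{i1}\t{i2}\t{d:.3f}\n")


def read_contact_table(path: str) -> ContactMap:
    cutoff, min_sep = DEFAULT_CUTOFF, DEFAULT_MIN_SEPARATION
    pairs = []
    dists = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "cutoff":
                        cutoff = float(val)
                    elif key == "min_separation":
                        min_sep = int(val)
                continue
            i1, i2, d = line.split()
            pairs.append((int(i1), int(i2)))
            dists[(int(i1), int(i2))] = float(d)
    return ContactMap(pairs, cutoff, min_sep, dists)
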