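"""Read PDB structures and cut them into single-fragment domain backbones.

The unit of analysis downstream is a *domain*: one contiguous stretch of a
single protein chain, reduced to its ordered alpha-carbon trace plus the
per-residue heavy atoms that define native contacts.  This module enforces
the continuity requirements that make self-entanglement well defined:

* a domain must be a single sequence fragment (multi-fragment CATH-style
  domains are rejected);
* internal stretches of unresolved residues are tolerated only up to
  ``MAX_GAP`` residues and are bridged by straight-line alpha-carbon
  interpolation (bridged residues carry no heavy atoms, so they can never
  open a loop);
* unresolved tails are dropped rather than modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

MAX_GAP = 10

__all__ = [
    "Atom",
    "AtomSet",
    "DomainSpec",
    "Backbone",
    "StructureError",
    "DomainRejected",
    "MissingRangeError",
    "read_structure",
    "extract_domain",
    "bridge_short_gaps",
    "parse_domain_table",
    "MAX_GAP",
]


class StructureError(ValueError):
    """Unreadable or empty structure file."""


class DomainRejected(ValueError):
    """Domain violates a continuity filter (multi-fragment, or gap > MAX_GAP)."""


class MissingRangeError(KeyError):
    """Requested chain or residue range absent from the structure."""


@dataclass(frozen=True)
class Atom:
    """One atom of the first model, after altloc reduction."""

    name: str
    element: str
    chain: str
    res_seq: int
    icode: str
    res_name: str
    xyz: tuple[float, float, float]
    is_hydrogen: bool
    het: bool


@dataclass
class AtomSet:
    """All atoms of the first model of a structure (waters removed)."""

    atoms: list[Atom]
    source: str = ""

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def chain_atoms(self, chain: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain]

    def n_residues(self, chain: str | None = None) -> int:
        keys = {
            (a.chain, a.res_seq, a.icode)
            for a in self.atoms
            if chain is None or a.chain == chain
        }
        return len(keys)


@dataclass(frozen=True)
class DomainSpec:
    """A named domain: chain + ordered inclusive residue ranges (author numbering)."""

    domain_id: str
    chain: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for lo, hi in self.segments:
            if hi < lo:
                raise ValueError(f"{self.domain_id}: segment {lo}-{hi} reversed")
            if prev_end is not None and lo <= prev_end:
                raise ValueError(f"{self.domain_id}: segments overlap or out of order")
            prev_end = hi

    @classmethod
    def from_string(cls, domain_id: str, chain: str, ranges: str) -> "DomainSpec":
        """Parse ``"12-133"`` or ``"12-133,140-200"``."""
        segs = []
        for part in ranges.split(","):
            lo, _, hi = part.strip().partition("-")
            segs.append((int(lo), int(hi)))
        return cls(domain_id, chain, tuple(segs))


@dataclass
class Backbone:
    """Ordered alpha-carbon trace of one domain.

    ``ca`` is the (N, 3) array of alpha-carbon positions in Angstrom,
    ``residue_ids`` the parallel author numbering, ``heavy`` the per-residue
    non-hydrogen atom coordinates (empty for reconstructed residues) and
    ``observed`` flags which residues were experimentally resolved.
    """

    domain_id: str
    ca: np.ndarray
    residue_ids: list[tuple[int, str]]
    heavy: list[np.ndarray]
    observed: np.ndarray
    res_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.ca.ndim != 2 or self.ca.shape[1] != 3:
            raise ValueError("ca must be (N, 3)")
        if len(self.ca) < 2:
            raise ValueError("backbone needs at least two residues")
        if not np.isfinite(self.ca).all():
            raise ValueError("non-finite alpha-carbon coordinate")
        if (np.linalg.norm(np.diff(self.ca, axis=0), axis=1) == 0).any():
            raise ValueError("consecutive alpha carbons coincide")

    def __len__(self) -> int:
        return len(self.ca)


# -- reading ---------------------------------------------------------------

_WATERS = {"HOH", "DOD", "WAT"}


def read_structure(path: str) -> AtomSet:
    """Read the first model of a PDB file.

    Alternate locations are reduced to the highest-occupancy conformer
    (ties broken by the lexicographically first altloc indicator); waters
    are removed; hydrogens are kept but flagged so the contact search can
    skip them.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no model in structure")
    model = st[0]

    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if res.name in _WATERS:
                continue
            # pick one conformer per atom name: highest occupancy, then altloc
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None or (at.occ, -ord(at.altloc or "~")) > (
                    prev.occ,
                    -ord(prev.altloc or "~"),
                ):
                    by_name[at.name] = at
            for at in by_name.values():
                el = at.element.name.upper()
                atoms.append(
                    Atom(
                        name=at.name,
                        element=el,
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        res_name=res.name,
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        is_hydrogen=el in ("H", "D"),
                        het=res.het_flag == "H",
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: first model contains no atoms")
    return AtomSet(atoms=atoms, source=str(path))


# -- domain extraction -----------------------------------------------------


def _group_residues(atoms: list[Atom]) -> dict[int, list[Atom]]:
    """Group standard amino-acid atoms by author residue number.

    MSE (selenomethionine) is treated as a standard residue; any other
    HETATM residue is excluded.  Insertion codes are collapsed onto the
    numeric identifier (the first icode encountered wins), which is exact
    for the numbering schemes used downstream.
    """
    out: dict[int, list[Atom]] = {}
    for a in atoms:
        if a.het and a.res_name != "MSE":
            continue
        out.setdefault(a.res_seq, []).append(a)
    return out


def extract_domain(atoms: AtomSet, spec: DomainSpec) -> Backbone:
    """Cut a domain out of an AtomSet and return its Backbone.

    Residues requested by the spec but absent from the coordinates are
    treated as unresolved: internal runs of at most ``MAX_GAP`` are bridged
    by :func:`bridge_short_gaps`, terminal runs are dropped, and a longer
    internal run rejects the domain.
    """
    if len(spec.segments) != 1:
        raise DomainRejected(
            f"{spec.domain_id}: multi-fragment domain ({len(spec.segments)} segments)"
        )
    chain_atoms = atoms.chain_atoms(spec.chain)
    if not chain_atoms:
        raise MissingRangeError(f"{spec.domain_id}: chain {spec.chain!r} not found")
    residues = _group_residues(chain_atoms)

    lo, hi = spec.segments[0]
    wanted = list(range(lo, hi + 1))
    present = [n for n in wanted if n in residues and any(a.name == "CA" for a in residues[n])]
    if not present:
        raise MissingRangeError(
            f"{spec.domain_id}: no residues of {spec.chain}:{lo}-{hi} resolved"
        )

    # trim unresolved tails silently
    first, last = present[0], present[-1]
    span = list(range(first, last + 1))

    entries = []  # (res_seq, observed, ca, heavy, name)
    gap_run: list[int] = []
    for n in span:
        if n in residues and any(a.name == "CA" for a in residues[n]):
            if gap_run:
                if len(gap_run) > MAX_GAP:
                    raise DomainRejected(
                        f"{spec.domain_id}: missing region of {len(gap_run)} residues "
                        f"({gap_run[0]}-{gap_run[-1]}) exceeds {MAX_GAP}"
                    )
                for g in gap_run:
                    entries.append((g, False, None, None, "GAP"))
                gap_run = []
            res_atoms = residues[n]
            ca = next(a for a in res_atoms if a.name == "CA")
            heavy = np.array(
                [a.xyz for a in res_atoms if not a.is_hydrogen], dtype=float
            )
            entries.append((n, True, np.array(ca.xyz), heavy, res_atoms[0].res_name))
        else:
            gap_run.append(n)

    return bridge_short_gaps(spec.domain_id, entries)


def bridge_short_gaps(
    domain_id: str,
    entries: list[tuple[int, bool, np.ndarray | None, np.ndarray | None, str]],
    max_gap: int = MAX_GAP,
) -> Backbone:
    """Fill unresolved alpha carbons by linear interpolation between flanks.

    ``entries`` is the ordered residue list produced by :func:`extract_domain`;
    unresolved entries (observed=False) are placed equally spaced on the
    straight segment joining the flanking observed alpha carbons and carry no
    heavy atoms, so they never enter the contact map.
    """
    observed_idx = [k for k, e in enumerate(entries) if e[1]]
    if not observed_idx:
        raise DomainRejected(f"{domain_id}: no observed residues")
    # terminal gaps are not bridged
    entries = entries[observed_idx[0] : observed_idx[-1] + 1]

    n = len(entries)
    ca = np.zeros((n, 3))
    heavy: list[np.ndarray] = []
    observed = np.zeros(n, dtype=bool)
    residue_ids: list[tuple[int, str]] = []
    res_names: list[str] = []

    for k, (num, obs, pos, hv, name) in enumerate(entries):
        residue_ids.append((num, ""))
        res_names.append(name)
        observed[k] = obs
        if obs:
            ca[k] = pos
            heavy.append(np.asarray(hv, dtype=float))
        else:
            heavy.append(np.empty((0, 3)))

    k = 0
    while k < n:
        if not observed[k]:
            start = k
            while k < n and not observed[k]:
                k += 1
            gap_len = k - start
            if gap_len > max_gap:
                raise DomainRejected(
                    f"{domain_id}: internal gap of {gap_len} residues exceeds {max_gap}"
                )
            a, b = ca[start - 1], ca[k]
            for j in range(gap_len):
                ca[start + j] = a + (b - a) * (j + 1) / (gap_len + 1)
        else:
            k += 1

    return Backbone(
        domain_id=domain_id,
        ca=ca,
        residue_ids=residue_ids,
        heavy=heavy,
        observed=observed,
        res_names=res_names,
    )


def parse_domain_table(path: str) -> list[tuple[str, DomainSpec]]:
    """Read a domain config: CSV columns domain_id, pdb_path, chain, ranges."""
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            spec = DomainSpec.from_string(
                row["domain_id"].strip(), row["chain"].strip(), row["ranges"]
            )
            out.append((row["pdb_path"].strip(), spec))
    return out
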