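from __future__ import annotations

import numpy as np
import pytest

from gausslink.structure_io import (
    Backbone,
    DomainRejected,
    DomainSpec,
    MissingRangeError,
    StructureError,
    extract_domain,
    read_structure,
)
from gausslink.synthetic_data import TopologySpec, make_threaded_loop, write_synthetic_pdb

from conftest import chain_backbone, random_chain


def _write_pdb_lines(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")


def _atom_line(serial, name, resname, resseq, x, y, z, occ=1.0, altloc=" ", chain="A"):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           {name.strip()[0]}"
    )


class TestReadStructure:
    def test_roundtrip_of_synthetic_writer(self, tmp_path):
        fx = make_threaded_loop(TopologySpec(m=1, sign=1, side="N", loop_size=30))
        path = tmp_path / "synth.pdb"
        write_synthetic_pdb(fx.backbone, path)
        atoms = read_structure(path)
        assert atoms.n_residues("A") == len(fx.backbone)
        spec = DomainSpec("SYNTH", "A", ((1, len(fx.backbone)),))
        bb = extract_domain(atoms, spec)
        np.testing.assert_allclose(bb.ca, fx.backbone.ca, atol=1.5e-3)

    def test_altloc_reduced_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        _write_pdb_lines(
            path,
            [
                _atom_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0, occ=0.6, altloc="A"),
                _atom_line(2, "CA", "ALA", 1, 9.0, 0.0, 0.0, occ=0.4, altloc="B"),
                _atom_line(3, "CA", "ALA", 2, 3.8, 0.0, 0.0),
            ],
        )
        atoms = read_structure(path)
        cas = [a for a in atoms.atoms if a.res_seq == 1 and a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].xyz[0] == pytest.approx(0.0)

    def test_altloc_tie_takes_first_indicator(self, tmp_path):
        path = tmp_path / "tie.pdb"
        _write_pdb_lines(
            path,
            [
                _atom_line(1, "CA", "ALA", 1, 5.0, 0.0, 0.0, occ=0.5, altloc="B"),
                _atom_line(2, "CA", "ALA", 1, 0.0, 0.0, 0.0, occ=0.5, altloc="A"),
                _atom_line(3, "CA", "ALA", 2, 3.8, 0.0, 0.0),
            ],
        )
        atoms = read_structure(path)
        cas = [a for a in atoms.atoms if a.res_seq == 1 and a.name == "CA"]
        assert len(cas) == 1 and cas[0].xyz[0] == pytest.approx(0.0)

    def test_waters_removed_hydrogens_flagged(self, tmp_path):
        path = tmp_path / "wat.pdb"
        _write_pdb_lines(
            path,
            [
                _atom_line(1, "CA", "GLY", 1, 0.0, 0.0, 0.0),
                _atom_line(2, "HA", "GLY", 1, 0.5, 0.5, 0.0),
                "HETATM    3  O   HOH A 100      20.000  20.000  20.000  1.00  0.00           O",
                _atom_line(4, "CA", "GLY", 2, 3.8, 0.0, 0.0),
            ],
        )
        atoms = read_structure(path)
        names = {a.name for a in atoms.atoms}
        assert "O" not in names or all(a.res_name != "HOH" for a in atoms.atoms)
        assert any(a.is_hydrogen for a in atoms.atoms)

    def test_unreadable_file_raises(self, tmp_path):
        missing = tmp_path / "nope.pdb"
        with pytest.raises((StructureError, FileNotFoundError, RuntimeError)):
            read_structure(missing)

    def test_empty_structure_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(StructureError):
            read_structure(path)


def _contiguous_chain_pdb(tmp_path, residue_numbers, name="chain.pdb"):
    lines = []
    serial = 1
    for k, num in enumerate(residue_numbers):
        lines.append(_atom_line(serial, "CA", "ALA", num, 3.8 * k, 0.1 * (k % 3), 0.0))
        serial += 1
        lines.append(_atom_line(serial, "CB", "ALA", num, 3.8 * k, 1.5, 0.5))
        serial += 1
    path = tmp_path / name
    _write_pdb_lines(path, lines)
    return path


class TestExtractDomain:
    def test_full_coverage_all_observed(self, tmp_path):
        path = _contiguous_chain_pdb(tmp_path, range(1, 51))
        bb = extract_domain(read_structure(path), DomainSpec("D", "A", ((1, 50),)))
        assert len(bb) == 50
        assert bb.observed.all()

    def test_long_gap_rejects_domain(self, tmp_path):
        nums = list(range(1, 21)) + list(range(32, 51))  # gap 21..31 = 11 residues
        path = _contiguous_chain_pdb(tmp_path, nums)
        with pytest.raises(DomainRejected, match="11"):
            extract_domain(read_structure(path), DomainSpec("D", "A", ((1, 50),)))

    def test_short_gap_bridged_and_flagged(self, tmp_path):
        nums = list(range(1, 21)) + list(range(24, 51))  # gap 21..23 = 3 residues
        path = _contiguous_chain_pdb(tmp_path, nums)
        bb = extract_domain(read_structure(path), DomainSpec("D", "A", ((1, 50),)))
        assert len(bb) == 50
        rec = [rid for rid, flag in zip(bb.residue_ids, bb.observed) if not flag]
        assert [r[0] for r in rec] == [21, 22, 23]
        # reconstructed residues carry no heavy atoms
        for k, flag in enumerate(bb.observed):
            if not flag:
                assert len(bb.heavy[k]) == 0

    def test_interpolation_is_linear_equal_spacing(self, tmp_path):
        nums = [1, 2, 5, 6]  # residues 3,4 missing; flanks at x=3.8 and x=15.2
        lines = [
            _atom_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0),
            _atom_line(2, "CA", "ALA", 2, 3.8, 0.0, 0.0),
            _atom_line(3, "CA", "ALA", 5, 15.2, 0.0, 0.0),
            _atom_line(4, "CA", "ALA", 6, 19.0, 0.0, 0.0),
        ]
        path = tmp_path / "gap.pdb"
        _write_pdb_lines(path, lines)
        bb = extract_domain(read_structure(path), DomainSpec("D", "A", ((1, 6),)))
        np.testing.assert_allclose(bb.ca[2], [7.6, 0, 0], atol=1e-3)
        np.testing.assert_allclose(bb.ca[3], [11.4, 0, 0], atol=1e-3)

    def test_terminal_missing_dropped_silently(self, tmp_path):
        path = _contiguous_chain_pdb(tmp_path, range(5, 46))
        bb = extract_domain(read_structure(path), DomainSpec("D", "A", ((1, 50),)))
        assert len(bb) == 41
        assert bb.residue_ids[0][0] == 5 and bb.residue_ids[-1][0] == 45

    def test_multi_fragment_rejected(self, tmp_path):
        path = _contiguous_chain_pdb(tmp_path, range(1, 51))
        with pytest.raises(DomainRejected, match="multi-fragment"):
            extract_domain(
                read_structure(path), DomainSpec("D", "A", ((1, 20), (30, 50)))
            )

    def test_missing_chain_raises(self, tmp_path):
        path = _contiguous_chain_pdb(tmp_path, range(1, 11))
        with pytest.raises(MissingRangeError):
            extract_domain(read_structure(path), DomainSpec("D", "B", ((1, 10),)))

    def test_idempotent_re_extraction(self, tmp_path):
        nums = list(range(1, 21)) + list(range(24, 51))
        path = _contiguous_chain_pdb(tmp_path, nums)
        atoms = read_structure(path)
        bb1 = extract_domain(atoms, DomainSpec("D", "A", ((1, 50),)))
        lo, hi = bb1.residue_ids[0][0], bb1.residue_ids[-1][0]
        bb2 = extract_domain(atoms, DomainSpec("D", "A", ((lo, hi),)))
        np.testing.assert_array_equal(bb1.ca, bb2.ca)
        np.testing.assert_array_equal(bb1.observed, bb2.observed)


class TestBackboneInvariants:
    def test_rejects_single_residue(self):
        with pytest.raises(ValueError):
            chain_backbone(np.array([[0.0, 0.0, 0.0]]))

    def test_rejects_coincident_neighbors(self):
        pts = np.array([[0.0, 0, 0], [0.0, 0, 0], [3.8, 0, 0]])
        with pytest.raises(ValueError):
            chain_backbone(pts)

    def test_random_chain_is_valid(self, rng):
        bb = chain_backbone(random_chain(30, rng))
        assert len(bb) == 30
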