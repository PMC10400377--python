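import numpy as np
import pytest

from pualign.peeling import ProteinUnit
from pualign.rigid_core import PUAlignment, ResidueMapping, RigidTransform
from pualign.scoring import QUERY_AS_PEELED, GlobalAlignment
from pualign.structure_io import CaTrace, read_pdb, write_superposed, write_trace_pdb
from pualign.synthetic import make_globule


def test_read_pdb_echoes_ca_coordinates(mini_pdb):
    trace = read_pdb(mini_pdb)
    assert len(trace) == 3
    assert trace.chain_id == "A"
    np.testing.assert_allclose(
        trace.coords, [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], atol=1e-6)
    assert trace.sequence == "AGS"
    assert [num for num, _, _ in trace.residues] == [1, 2, 3]


def test_residue_without_ca_is_skipped_with_warning(tmp_path):
    # residue 2 has an N record but no CA: it is skipped, index stays dense
    p = tmp_path / "gap.pdb"
    p.write_text(
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N\n"
        "ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C\n"
        "ATOM      4  CA  SER A   4      11.400   0.000   0.000  1.00  0.00           C\n"
        "END\n")
    with pytest.warns(UserWarning, match="without a CA"):
        trace = read_pdb(p)
    assert len(trace) == 3
    assert [num for num, _, _ in trace.residues] == [1, 3, 4]


def test_chain_selection_and_missing_chain(two_chain_pdb):
    b = read_pdb(two_chain_pdb, chain="B")
    assert len(b) == 4 and b.sequence == "GGGG"
    first = read_pdb(two_chain_pdb)
    assert first.chain_id == "A"
    with pytest.raises(ValueError, match="available chains.*A.*B"):
        read_pdb(two_chain_pdb, chain="Z")


def test_altloc_keeps_highest_occupancy(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.60  0.00           C\n"
        "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        "ATOM      4  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C\n"
        "END\n")
    trace = read_pdb(p)
    np.testing.assert_allclose(trace.coords[0], [9.0, 9.0, 9.0])


def test_hetatm_ignored_nonstandard_kept(tmp_path):
    p = tmp_path / "het.pdb"
    p.write_text(
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C\n"
        "HETATM    4  CA  CA  A 101      20.000  20.000  20.000  1.00  0.00          CA\n"
        "END\n")
    trace = read_pdb(p)
    assert len(trace) == 3


def test_empty_chain_is_hard_error(tmp_path):
    p = tmp_path / "noca.pdb"
    p.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "END\n")
    with pytest.raises(ValueError, match="empty chain"):
        read_pdb(p)


def test_write_read_roundtrip_to_pdb_precision(tmp_path):
    trace = make_globule(30, seed=5)
    p = tmp_path / "rt.pdb"
    write_trace_pdb(trace, p)
    back = read_pdb(p)
    assert len(back) == len(trace)
    np.testing.assert_allclose(back.coords, trace.coords, atol=1.5e-3)


def _identity_alignment(trace):
    n = len(trace)
    pairs = tuple((i, i) for i in range(n))
    pua = PUAlignment(pu=ProteinUnit(0, n, 0), mapping=ResidueMapping(pairs),
                      transform=RigidTransform.identity(), local_tm=1.0,
                      pair_distances=np.zeros(n))
    return GlobalAlignment(pu_alignments=(pua,), direction=QUERY_AS_PEELED,
                           exploration_depth=0, tm_score=1.0, rmsd_aligned=0.0,
                           coverage=1.0, L_norm=n)


def test_write_superposed_identity_preserves_coords(tmp_path):
    trace = make_globule(20, seed=1)
    out = tmp_path / "sup.pdb"
    write_superposed(trace, _identity_alignment(trace), out)
    back = read_pdb(out)  # first MODEL = the single PU, identity transform
    np.testing.assert_allclose(back.coords, trace.coords, atol=1.5e-3)


def test_write_superposed_marks_unmapped_and_distinct_transforms(tmp_path):
    trace = make_globule(20, seed=1)
    n = len(trace)
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    pu1 = PUAlignment(pu=ProteinUnit(0, 9, 0),
                      mapping=ResidueMapping(tuple((i, i) for i in range(9))),
                      transform=RigidTransform.identity(), local_tm=1.0,
                      pair_distances=np.zeros(9))
    pu2 = PUAlignment(pu=ProteinUnit(9, n, 1),
                      mapping=ResidueMapping(tuple((i, i) for i in range(9, n - 1))),
                      transform=RigidTransform(rot, np.array([5.0, 0, 0])),
                      local_tm=0.5, pair_distances=np.ones(n - 1 - 9))
    ga = GlobalAlignment(pu_alignments=(pu1, pu2), direction=QUERY_AS_PEELED,
                         exploration_depth=1, tm_score=0.9, rmsd_aligned=0.5,
                         coverage=0.95, L_norm=n)
    out = tmp_path / "sup2.pdb"
    write_superposed(trace, ga, out)
    text = out.read_text()
    models = text.count("MODEL")
    assert models == 3  # one per PU + merged
    # last residue is unmapped -> sentinel B-factor in the merged model
    merged = text.split("MERGED")[1]
    last_atom = [l for l in merged.splitlines() if l.startswith("ATOM")][-1]
    assert "999.0" in last_atom or "999.00" in last_atom
    # PU2 residues moved by a different transform than PU1 residues
    back = read_pdb(out)  # model 1 (PU1): identity
    np.testing.assert_allclose(back.coords, trace.coords[:9], atol=1.5e-3)


def test_catrace_invariants():
    with pytest.raises(ValueError, match="at least 3"):
        CaTrace("A", ((1, "", "A"), (2, "", "A")), np.zeros((2, 3)))
    with pytest.raises(ValueError, match="duplicate"):
        CaTrace("A", ((1, "", "A"), (1, "", "A"), (2, "", "A")), np.zeros((3, 3)))
    with pytest.raises(ValueError, match="row count"):
        CaTrace("A", ((1, "", "A"), (2, "", "A"), (3, "", "A")), np.zeros((4, 3)))
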