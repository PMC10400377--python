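"""PDB input/output for Cα traces.

Only Cα atoms are read: peeling, the rigid aligner and all scores operate on
Cα geometry. Internal residue indices are 0-based and dense; author numbering
is retained only for reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: B-factor written for query residues with no mapped target residue.
UNMAPPED_BFACTOR = 999.0


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα trace of one protein chain.

    Attributes
    ----------
    chain_id:
        Author chain identifier.
    residues:
        One ``(author_residue_number, insertion_code, one_letter_aa)`` tuple
        per residue, in file order.
    coords:
        ``(N, 3)`` float array of Cα coordinates in Å.
    """

    chain_id: str
    residues: tuple[tuple[int, str, str], ...]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if coords.shape[0] != len(self.residues):
            raise ValueError("coords row count must equal residue count")
        if len(self.residues) < 3:
            raise ValueError("a Cα trace needs at least 3 residues")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        keys = [(num, icode) for num, icode, _ in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (residue_number, insertion_code) pair")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Coordinates of the half-open residue interval [start, end)."""
        return self.coords[start:end]

    @property
    def sequence(self) -> str:
        return "".join(aa for _, _, aa in self.residues)


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def read_pdb(path: str, chain: str | None = None) -> CaTrace:
    """Read the Cα trace of one chain from a PDB file.

    Parameters
    ----------
    path:
        PDB file with ATOM records. HETATM records are ignored; non-standard
        residues that still carry a CA atom are kept with one-letter code "X".
    chain:
        Author chain id; the first chain in the file when omitted.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the chain is absent ("available chains" are listed) or contains no
        CA atoms ("empty chain").
    """
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise ValueError(f"empty chain: no models in {path}")
    model = structure[0]
    available = [ch.name for ch in model]
    if chain is None:
        if not available:
            raise ValueError(f"empty chain: no chains in {path}")
        chain = available[0]
    if chain not in available:
        raise ValueError(
            f"chain {chain!r} not found in {path}; available chains: {available}"
        )

    residues: list[tuple[int, str, str]] = []
    coords: list[np.ndarray] = []
    n_skipped = 0
    for res in model[chain]:
        if res.het_flag == "H":
            continue
        ca_atoms = [a for a in res if a.name == "CA"]
        if not ca_atoms:
            n_skipped += 1
            logger.warning(
                "residue %s %d%s in chain %s has no CA atom; skipped",
                res.name, res.seqid.num, res.seqid.icode.strip(), chain,
            )
            continue
        # altLoc rule: highest occupancy, ties to the alphabetically first altLoc
        ca = min(ca_atoms, key=lambda a: (-a.occ, a.altloc))
        icode = res.seqid.icode.strip()
        residues.append((res.seqid.num, icode, _one_letter(res.name)))
        coords.append(np.array([ca.pos.x, ca.pos.y, ca.pos.z]))

    if not residues:
        raise ValueError(f"empty chain: no CA atoms in chain {chain} of {path}")
    if n_skipped:
        warnings.warn(
            f"{n_skipped} residue(s) without a CA atom skipped in chain {chain}",
            stacklevel=2,
        )
    return CaTrace(chain_id=chain, residues=tuple(residues), coords=np.array(coords))


def _format_atom_line(
    serial: int, resname: str, chain_id: str, resnum: int, icode: str,
    xyz: np.ndarray, bfactor: float,
) -> str:
    return (
        f"ATOM  {serial:>5d}  CA  {resname:>3s} {chain_id[:1]}{resnum:>4d}"
        f"{(icode or ' ')[:1]}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{min(bfactor, 999.99):6.2f}           C  "
    )


_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_superposed(query: "CaTrace", alignment, path: str) -> None:
    """Write the query superposed onto the target as a multi-model PDB.

    One MODEL per Protein Unit (its residues moved by that PU's rigid
    transform) plus a final merged model in which every residue carries the
    transform of the PU that aligned it (identity when unmapped). The B-factor
    column holds the post-transform Cα distance to the mapped target residue,
    or 999.0 for unmapped residues.

    ``alignment`` is a :class:`~pualign.scoring.GlobalAlignment`; its
    query-frame transforms and query-indexed mappings are used, so the output
    is valid for both peeling directions.
    """
    n = len(query)
    per_res_transform = [None] * n
    per_res_dist = np.full(n, UNMAPPED_BFACTOR)
    pu_blocks = []  # (pu_id, residue indices, transform)
    for pua in alignment.query_frame_units():
        tr = pua.transform
        idx = [qi for qi, _ in pua.mapping.pairs]
        for (qi, _), d in zip(pua.mapping.pairs, pua.pair_distances):
            per_res_transform[qi] = tr
            per_res_dist[qi] = d
        pu_blocks.append((pua.pu.pu_id, idx, tr))

    lines = []
    model_no = 0
    for pu_id, idx, tr in pu_blocks:
        model_no += 1
        lines.append(f"MODEL     {model_no:>4d}")
        lines.append(f"REMARK   6 PROTEIN UNIT {pu_id}")
        serial = 0
        for qi in idx:
            serial += 1
            num, icode, aa = query.residues[qi]
            xyz = tr.apply(query.coords[qi][None, :])[0]
            lines.append(_format_atom_line(
                serial, _THREE.get(aa, "UNK"), query.chain_id, num, icode,
                xyz, per_res_dist[qi]))
        lines.append("ENDMDL")

    # merged model: all residues, each under its own PU transform
    model_no += 1
    lines.append(f"MODEL     {model_no:>4d}")
    lines.append("REMARK   6 MERGED FLEXIBLE SUPERPOSITION")
    serial = 0
    for qi in range(n):
        serial += 1
        num, icode, aa = query.residues[qi]
        tr = per_res_transform[qi]
        xyz = query.coords[qi] if tr is None else tr.apply(query.coords[qi][None, :])[0]
        lines.append(_format_atom_line(
            serial, _THREE.get(aa, "UNK"), query.chain_id, num, icode,
            xyz, per_res_dist[qi]))
    lines.append("ENDMDL")
    lines.append("END")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_trace_pdb(trace: CaTrace, path: str) -> None:
    """Write a plain single-model Cα-only PDB for a trace (fixture output)."""
    lines = []
    for i, ((num, icode, aa), xyz) in enumerate(zip(trace.residues, trace.coords), 1):
        lines.append(_format_atom_line(i, _THREE.get(aa, "UNK"), trace.chain_id,
                                       num, icode, xyz, 0.0))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
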