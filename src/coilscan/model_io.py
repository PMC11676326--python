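"""Read and write predicted fragment models.

A fragment model is a homo-oligomeric bundle: every chain has the same number
of residues.  Prediction programs store the per-residue confidence (pLDDT,
0-100) in the B-factor column of the PDB file; the predicted aligned error
(PAE) comes as a separate JSON matrix over all residues of all chains.  This
module parses both into a :class:`FragmentModel` holding, per chain, the
C-alpha trace, a side-chain center per residue (centroid of non-backbone
heavy atoms, falling back to CB and then CA for glycine) and the pLDDT
vector.  Flank residues attached by the divider are stripped from both
termini of every chain — and from the matching rows/columns of the PAE
matrix — before any feature is computed, so adaptor sequences never
contribute to scores.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import ModelError

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

#: recognised top-level keys of PAE JSON files
PAE_KEYS = ("predicted_aligned_error", "pae")


@dataclass
class FragmentModel:
    """A parsed multi-chain fragment model.

    All per-chain arrays are indexed ``[chain][residue]``; chains are ordered
    as in the source file and must have equal residue counts.
    """

    chain_ids: list[str]
    residue_numbers: list[np.ndarray]
    ca: list[np.ndarray]  # (n_res, 3) per chain, Angstrom
    sc_centers: list[np.ndarray]  # (n_res, 3) per chain, Angstrom
    plddt: list[np.ndarray]  # (n_res,) per chain, 0-100
    pae: np.ndarray | None = None  # (M, M), M = n_chains * n_res
    provenance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return len(self.chain_ids)

    @property
    def n_residues(self) -> int:
        """Residues per chain."""
        return len(self.ca[0]) if self.ca else 0

    def validate(self) -> None:
        if self.n_chains == 0 or self.n_residues == 0:
            raise ModelError("model has no chains or no residues")
        lengths = {len(c) for c in self.ca}
        if len(lengths) != 1:
            raise ModelError(
                f"chains have unequal residue counts {sorted(len(c) for c in self.ca)}; "
                "fragment models must be homo-oligomers"
            )
        for p in self.plddt:
            if np.any((p < 0) | (p > 100)):
                raise ModelError("pLDDT values outside [0, 100]")
        if self.pae is not None:
            m = self.n_chains * self.n_residues
            if self.pae.shape != (m, m):
                raise ModelError(
                    f"PAE matrix is {self.pae.shape}, expected ({m}, {m}) for "
                    f"{self.n_chains} chains x {self.n_residues} residues"
                )
            if np.any(self.pae < 0):
                raise ModelError("PAE matrix contains negative entries")


def read_pae(path: str | Path) -> np.ndarray:
    """Load a PAE matrix from JSON, auto-detecting the dialect.

    Accepts ``{"predicted_aligned_error": [[...]]}`` and ``{"pae": [[...]]}``,
    each optionally wrapped in a one-element list (as some servers emit).
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        if len(data) != 1:
            raise ModelError(
                f"PAE JSON {path}: list wrapper has {len(data)} elements, expected 1"
            )
        data = data[0]
    if not isinstance(data, dict):
        raise ModelError(f"PAE JSON {path}: expected an object, got {type(data).__name__}")
    for key in PAE_KEYS:
        if key in data:
            mat = np.asarray(data[key], dtype=float)
            break
    else:
        raise ModelError(
            f"PAE JSON {path}: unknown dialect; found keys {sorted(data)}, "
            f"expected one of {list(PAE_KEYS)}"
        )
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ModelError(f"PAE matrix in {path} is not square: shape {mat.shape}")
    return mat


def _strip_flanks(model: FragmentModel, flank_length: int) -> FragmentModel:
    if flank_length == 0:
        return model
    n = model.n_residues
    if n <= 2 * flank_length:
        raise ModelError(
            f"cannot strip {flank_length} flank residues from both termini of "
            f"{n}-residue chains"
        )
    sl = slice(flank_length, n - flank_length)
    keep_per_chain = n - 2 * flank_length
    if model.pae is not None:
        keep = np.concatenate(
            [np.arange(c * n + flank_length, (c + 1) * n - flank_length)
             for c in range(model.n_chains)]
        )
        pae = model.pae[np.ix_(keep, keep)]
        assert pae.shape[0] == model.n_chains * keep_per_chain
    else:
        pae = None
    return FragmentModel(
        chain_ids=model.chain_ids,
        residue_numbers=[r[sl] for r in model.residue_numbers],
        ca=[c[sl] for c in model.ca],
        sc_centers=[s[sl] for s in model.sc_centers],
        plddt=[p[sl] for p in model.plddt],
        pae=pae,
        provenance=model.provenance,
    )


def read_model(
    pdb_path: str | Path,
    pae_path: str | Path | None = None,
    flank_length: int = 0,
    provenance: dict | None = None,
) -> FragmentModel:
    """Parse a predicted model (PDB, optional PAE JSON) and strip flanks.

    pLDDT is taken from the B-factor of each residue's CA atom.  The PAE
    matrix must match the pre-strip residue count; after reading,
    ``flank_length`` residues are removed from both termini of every chain
    and from the matrix.
    """
    structure = gemmi.read_structure(str(pdb_path))
    if len(structure) == 0:
        raise ModelError(f"{pdb_path}: no models in file")
    st_model = structure[0]

    chain_ids, res_nums, cas, scs, plddts = [], [], [], [], []
    for chain in st_model:
        nums, ca_xyz, sc_xyz, bvals = [], [], [], []
        for residue in chain:
            ca = residue.find_atom("CA", "*")
            if ca is None:
                raise ModelError(
                    f"{pdb_path}: residue {chain.name}/{residue.seqid.num} has no CA atom"
                )
            side = [
                a.pos for a in residue
                if a.name not in _BACKBONE_ATOMS and a.element != gemmi.Element("H")
            ]
            if side:
                center = np.mean([[p.x, p.y, p.z] for p in side], axis=0)
            else:
                cb = residue.find_atom("CB", "*")
                pos = cb.pos if cb is not None else ca.pos
                center = np.array([pos.x, pos.y, pos.z])
            nums.append(residue.seqid.num)
            ca_xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
            sc_xyz.append(center)
            bvals.append(ca.b_iso)
        if not nums:
            continue
        order = np.argsort(np.asarray(nums), kind="stable")
        chain_ids.append(chain.name)
        res_nums.append(np.asarray(nums)[order])
        cas.append(np.asarray(ca_xyz, dtype=float)[order])
        scs.append(np.asarray(sc_xyz, dtype=float)[order])
        plddts.append(np.asarray(bvals, dtype=float)[order])

    model = FragmentModel(
        chain_ids=chain_ids,
        residue_numbers=res_nums,
        ca=cas,
        sc_centers=scs,
        plddt=plddts,
        provenance=provenance or {"pdb_path": str(pdb_path)},
    )
    model.validate()

    if pae_path is not None:
        pae = read_pae(pae_path)
        total = model.n_chains * model.n_residues
        if pae.shape[0] != total:
            raise ModelError(
                f"PAE side {pae.shape[0]} does not match total residue count {total} "
                f"({model.n_chains} chains x {model.n_residues})"
            )
        model.pae = pae

    model = _strip_flanks(model, flank_length)
    model.validate()
    return model


def write_model(model: FragmentModel, pdb_path: str | Path) -> Path:
    """Write a model as PDB with pLDDT in the B-factor column.

    Each residue is written as ALA with its CA atom and a CB placed at the
    side-chain center, so a read/write round trip preserves CA coordinates
    (to PDB precision, 1e-3 A), side-chain centers and pLDDT (1e-2).
    """
    model.validate()
    if model.n_chains > len(_CHAIN_IDS):
        raise ModelError(f"more than {len(_CHAIN_IDS)} chains unsupported in PDB")
    structure = gemmi.Structure()
    structure.name = "coilscan"
    st_model = gemmi.Model("1")
    for c in range(model.n_chains):
        chain = gemmi.Chain(_CHAIN_IDS[c])
        for i in range(model.n_residues):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(model.residue_numbers[c][i]), " ")
            for name, xyz in (("CA", model.ca[c][i]), ("CB", model.sc_centers[c][i])):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.b_iso = float(model.plddt[c][i])
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        st_model.add_chain(chain)
    structure.add_model(st_model)
    structure.setup_entities()
    pdb_path = Path(pdb_path)
    pdb_path.parent.mkdir(parents=True, exist_ok=True)
    structure.write_pdb(str(pdb_path))
    return pdb_path


def write_pae(
    pae: np.ndarray,
    path: str | Path,
    dialect: str = "predicted_aligned_error",
    wrap_in_list: bool = False,
) -> Path:
    """Write a PAE matrix as JSON in one of the supported dialects."""
    if dialect not in PAE_KEYS:
        raise ValueError(f"unknown PAE dialect {dialect!r}, expected one of {list(PAE_KEYS)}")
    mat = np.asarray(pae, dtype=float)
    payload: object = {dialect: [[round(float(v), 3) for v in row] for row in mat]}
    if wrap_in_list:
        payload = [payload]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")
    return path
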