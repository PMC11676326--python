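"""Per-fragment, per-residue features of predicted bundle models.

Four features are computed per fragment position (a position is shared by
all chains of the homo-oligomer):

``plddt``
    Mean pLDDT over the chain copies of the residue.
``pae``
    Mean predicted aligned error (A) over all entries in the rows and
    columns of every chain copy of the residue (diagonal included, rows and
    columns counted separately, so the matrix need not be symmetric).
``orientation``
    1.0 for a parallel bundle, 0.0 for antiparallel.  For each unordered
    chain pair the mean inter-chain CA distance at equal residue index is
    compared with the same mean computed against the reversed index; if the
    reversal reduces the mean distance the pair is antiparallel.  Bundles
    with more than two chains take the majority over all pairs, 0.5 on a
    tie.  Undefined (None) for monomers.
``kih``
    Knobs-into-holes participation.  A residue is a *knob* when at least
    four side-chain centers of residues on a single other chain lie within
    the contact cutoff (default 7.0 A, the packing cutoff convention of the
    SOCKET method) of its own side-chain center; the four nearest form the
    *hole*.  The binary per-position feature is 1.0 if the residue is a knob
    or a hole member in any chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ModelError
from .model_io import FragmentModel

#: default knob-hole contact cutoff in Angstrom (SOCKET packing-cutoff convention)
DEFAULT_KIH_CUTOFF = 7.0


def mean_plddt_per_residue(model: FragmentModel) -> np.ndarray:
    """Mean pLDDT across chain copies; length = residues per chain."""
    return np.mean(np.stack(model.plddt), axis=0)


def mean_pae_per_residue(model: FragmentModel) -> np.ndarray | None:
    """Per-position mean of the PAE rows and columns of all chain copies.

    Returns None when the model carries no PAE matrix (the feature is
    missing, not zero).
    """
    if model.pae is None:
        return None
    n = model.n_residues
    total = model.n_chains * n
    row_sums = model.pae.sum(axis=1)
    col_sums = model.pae.sum(axis=0)
    out = np.empty(n)
    for i in range(n):
        idx = np.arange(model.n_chains) * n + i
        out[i] = (row_sums[idx].sum() + col_sums[idx].sum()) / (2 * len(idx) * total)
    return out


def pair_orientation(ca_a: np.ndarray, ca_b: np.ndarray) -> tuple[float, float, bool]:
    """Forward/reversed mean CA distances for one chain pair.

    Returns ``(d_fwd, d_rev, parallel)`` where ``d_fwd`` is the mean distance
    between residues at equal index, ``d_rev`` the mean after reversing one
    chain's index, and ``parallel`` is False iff the reversal strictly
    reduces the mean distance (ties count as parallel).
    """
    if len(ca_a) != len(ca_b):
        raise ModelError("chain length mismatch in orientation test")
    d_fwd = float(np.mean(np.linalg.norm(ca_a - ca_b, axis=1)))
    d_rev = float(np.mean(np.linalg.norm(ca_a - ca_b[::-1], axis=1)))
    return d_fwd, d_rev, d_rev >= d_fwd


def detect_orientation(model: FragmentModel) -> float | None:
    """Parallel (1.0) / antiparallel (0.0) call for the whole bundle.

    Majority vote over all unordered chain pairs; 0.5 on a tie.  None for
    monomers, where the feature is undefined.
    """
    if model.n_chains < 2:
        return None
    parallel = 0
    antiparallel = 0
    for a, b in combinations(range(model.n_chains), 2):
        _, _, is_par = pair_orientation(model.ca[a], model.ca[b])
        if is_par:
            parallel += 1
        else:
            antiparallel += 1
    if parallel > antiparallel:
        return 1.0
    if antiparallel > parallel:
        return 0.0
    return 0.5


@dataclass
class KihAnnotation:
    """Knobs-into-holes annotation over a bundle, indexed [chain][residue]."""

    is_knob: np.ndarray  # (n_chains, n_res) bool
    in_hole: np.ndarray  # (n_chains, n_res) bool
    partner_chain: np.ndarray  # (n_chains, n_res) int, -1 where not a knob
    holes: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    # holes maps (chain, residue) of each knob to the 4 hole residue indices
    # on the partner chain

    @property
    def participates(self) -> np.ndarray:
        """(n_chains, n_res) bool: knob or hole member."""
        return self.is_knob | self.in_hole

    def per_position(self) -> np.ndarray:
        """Binary per-fragment-position feature: participation in any chain."""
        return self.participates.any(axis=0).astype(float)


def detect_kih(
    model: FragmentModel, contact_cutoff: float = DEFAULT_KIH_CUTOFF
) -> KihAnnotation:
    """Detect knobs-into-holes packing from side-chain centers.

    A residue is a knob iff >= 4 side-chain centers on one single other
    chain lie within ``contact_cutoff`` of its own side-chain center; the
    hole is the 4 nearest such residues.  Monomers yield an all-false
    annotation.
    """
    nc, nr = model.n_chains, model.n_residues
    is_knob = np.zeros((nc, nr), dtype=bool)
    in_hole = np.zeros((nc, nr), dtype=bool)
    partner = np.full((nc, nr), -1, dtype=int)
    holes: dict[tuple[int, int], np.ndarray] = {}
    if nc < 2:
        return KihAnnotation(is_knob, in_hole, partner, holes)

    dist = {}
    for x in range(nc):
        for y in range(nc):
            if x != y:
                dist[(x, y)] = cdist(model.sc_centers[x], model.sc_centers[y])

    for x in range(nc):
        for r in range(nr):
            best_y, best_count = -1, 0
            for y in range(nc):
                if y == x:
                    continue
                count = int(np.count_nonzero(dist[(x, y)][r] <= contact_cutoff))
                if count > best_count:
                    best_y, best_count = y, count
            if best_count >= 4:
                d = dist[(x, best_y)][r]
                within = np.flatnonzero(d <= contact_cutoff)
                hole = within[np.argsort(d[within], kind="stable")[:4]]
                is_knob[x, r] = True
                partner[x, r] = best_y
                holes[(x, r)] = np.sort(hole)
                in_hole[best_y, hole] = True
    return KihAnnotation(is_knob, in_hole, partner, holes)


def compute_features(
    model: FragmentModel,
    features: tuple[str, ...] = ("plddt", "pae", "orientation", "kih"),
    kih_cutoff: float = DEFAULT_KIH_CUTOFF,
) -> dict[str, np.ndarray | None]:
    """Compute the requested per-position feature vectors for one model.

    Scalar features (orientation) are broadcast over positions.  Missing
    features (no PAE, monomer orientation) map to None.
    """
    out: dict[str, np.ndarray | None] = {}
    n = model.n_residues
    for name in features:
        if name == "plddt":
            out[name] = mean_plddt_per_residue(model)
        elif name == "pae":
            out[name] = mean_pae_per_residue(model)
        elif name == "orientation":
            call = detect_orientation(model)
            out[name] = None if call is None else np.full(n, call)
        elif name == "kih":
            out[name] = detect_kih(model, contact_cutoff=kih_cutoff).per_position()
        else:
            raise ValueError(f"unknown feature {name!r}")
    return out
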