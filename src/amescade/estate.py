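"""Kier-Hall electrotopological state (E-state) indices.

For each heavy atom the intrinsic state is

    I = ((2/N)^2 * dv + 1) / d

where N is the principal quantum number, dv the valence-electron count
minus attached hydrogens, and d the number of sigma bonds to other heavy
atoms.  The E-state value perturbs I by the field of every other heavy
atom in the same connected fragment:

    S_i = I_i + sum_j (I_i - I_j) / r_ij^2,   r_ij = graph distance + 1.

Perturbations are antisymmetric, so sum(S) == sum(I) for any molecule.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

_PQN_BREAKS = (2, 10, 18, 36, 54, 86)


def principal_quantum_number(atomic_num: int) -> int:
    for n, limit in enumerate(_PQN_BREAKS, start=1):
        if atomic_num <= limit:
            return n
    return 7


def intrinsic_state(atom: Chem.Atom) -> float:
    """Intrinsic state I of a heavy atom.

    A lone heavy atom has no sigma bonds (d = 0, outside the Kier-Hall
    definition); d is substituted by 1 so the value stays finite.
    """
    d = atom.GetDegree()  # heavy-atom neighbours (implicit Hs not counted)
    if d == 0:
        d = 1
    n = principal_quantum_number(atom.GetAtomicNum())
    dv = Chem.GetPeriodicTable().GetNOuterElecs(atom.GetAtomicNum()) - atom.GetTotalNumHs()
    return ((2.0 / n) ** 2 * dv + 1.0) / d


def _distance_matrix(mol: Chem.Mol) -> np.ndarray:
    n = mol.GetNumAtoms()
    rows, cols = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return shortest_path(adj, method="BF", unweighted=True)


def estate_values(mol: Chem.Mol) -> np.ndarray:
    """E-state value S for every heavy atom, in atom order.

    Raises ``ValueError`` on an empty molecule.  The perturbation sum runs
    within connected fragments only (graph distance is undefined across
    fragments).
    """
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("molecule has no heavy atoms")
    intrinsic = np.array([intrinsic_state(a) for a in mol.GetAtoms()])
    if n == 1:
        return intrinsic.copy()
    dist = _distance_matrix(mol) + 1.0
    diff = intrinsic[:, None] - intrinsic[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        pert = np.where(np.isfinite(dist), diff / (dist * dist), 0.0)
    np.fill_diagonal(pert, 0.0)
    return intrinsic + pert.sum(axis=1)


def gmin(mol: Chem.Mol) -> float:
    """Minimum E-state value over the heavy atoms (the Gmin descriptor)."""
    return float(np.min(estate_values(mol)))
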