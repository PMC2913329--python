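"""Topological descriptors on the hydrogen-depleted molecular graph."""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem

from .estate import _distance_matrix


def nrings(mol: Chem.Mol) -> int:
    """Cyclomatic number: bonds - atoms + connected components.

    The smallest number of bonds whose removal leaves an acyclic graph.
    """
    n_components = len(Chem.GetMolFrags(mol))
    return mol.GetNumBonds() - mol.GetNumAtoms() + n_components


def idwbar(mol: Chem.Mol) -> float:
    """Bonchev-Trinajstic mean information content on the distribution of
    topological distances (magnitude form).

    With g_k the number of unordered heavy-atom pairs at distance k and
    W = sum_k k*g_k the Wiener number:

        idwbar = (W*log2(W) - sum_k g_k * k * log2(k)) / W

    Multi-fragment molecules use the largest fragment; a single-atom graph
    returns 0.
    """
    if mol.GetNumAtoms() < 2:
        return 0.0
    if len(Chem.GetMolFrags(mol)) > 1:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        mol = max(frags, key=lambda m: m.GetNumAtoms())
        if mol.GetNumAtoms() < 2:
            return 0.0
    dist = _distance_matrix(mol)
    iu = np.triu_indices(dist.shape[0], k=1)
    dvals = dist[iu].astype(int)
    wiener = int(dvals.sum())
    if wiener == 0:
        return 0.0
    ks, gs = np.unique(dvals, return_counts=True)
    inner = float(np.sum(gs * ks * np.log2(ks)))
    return (wiener * math.log2(wiener) - inner) / wiener
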