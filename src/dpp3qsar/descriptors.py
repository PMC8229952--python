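"""Molecular descriptors of the hDPP III inhibition model.

Three descriptor families are implemented, all on the H-depleted graph /
heavy-atom geometry:

* ``EEig05x`` — 5th-largest eigenvalue of the edge-adjacency matrix with
  edge-degree weights on the diagonal (Estrada-style spectral index,
  sensitive to size, branching and cyclicity).
* ``Mor10u`` — unweighted 3D-MoRSE signal at scattering parameter
  s = 9 1/Angstrom: sum over heavy-atom pairs of sin(s*r)/(s*r).
* ``nArOH`` — number of hydroxyl groups attached to aromatic carbons.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .compound_library import MoleculeGraph, Structure3D

__all__ = [
    "edge_adjacency_matrix",
    "edge_eigenvalues",
    "eeig",
    "morse",
    "mor10u",
    "n_aromatic_oh",
    "descriptor_vector",
    "descriptor_table",
    "wide_descriptor_table",
    "MODEL_DESCRIPTORS",
]

MODEL_DESCRIPTORS = ("EEig05x", "Mor10u", "nArOH")

Weighting = Literal["unweighted", "edge_degree", "bond_order"]

_AROH_SMARTS = Chem.MolFromSmarts("[OX2H1][c]")


def edge_adjacency_matrix(
    mol: MoleculeGraph, weighting: Weighting = "edge_degree"
) -> np.ndarray:
    """Bond-graph adjacency matrix of an H-depleted molecule.

    Entry (i, j) is 1 iff bonds i and j share an atom (i != j).  The
    diagonal carries the chosen weight: the edge degree delta(e_i) (number
    of bonds adjacent to bond i), the bond order, or zero.
    """
    bonds = mol.mol.GetBonds()
    m = len(bonds)
    if m == 0:
        raise ValueError("molecule has no bonds; edge adjacency undefined")
    E = np.zeros((m, m))
    atoms_of = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in bonds
    ]
    for i in range(m):
        ai = set(atoms_of[i])
        for j in range(i + 1, m):
            if ai & set(atoms_of[j]):
                E[i, j] = E[j, i] = 1.0
    if weighting == "edge_degree":
        np.fill_diagonal(E, E.sum(axis=1))
    elif weighting == "bond_order":
        orders = [b.GetBondTypeAsDouble() for b in bonds]
        np.fill_diagonal(E, orders)
    elif weighting != "unweighted":
        raise ValueError(f"unknown weighting {weighting!r}")
    return E


def edge_eigenvalues(
    mol: MoleculeGraph, weighting: Weighting = "edge_degree"
) -> np.ndarray:
    """Eigenvalues of the edge-adjacency matrix, non-increasing."""
    vals = np.linalg.eigvalsh(edge_adjacency_matrix(mol, weighting))
    return vals[::-1]


def eeig(
    mol: MoleculeGraph, k: int = 5, weighting: Weighting = "edge_degree"
) -> float:
    """k-th largest edge-adjacency eigenvalue (EEig{k}x for edge degrees).

    Molecules with fewer than k bonds return 0 (padding rule), matching
    the convention that small molecules contribute nothing at high k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = edge_eigenvalues(mol, weighting)
    if k > len(vals):
        return 0.0
    return float(vals[k - 1])


def morse(
    struct: Structure3D, s: float, include_hydrogens: bool = False
) -> float:
    """Unweighted 3D-MoRSE signal: sum_{i<j} sin(s*r_ij)/(s*r_ij).

    The s*r -> 0 limit of a term is 1, so coincident atoms and s = 0 are
    well defined (each pair then contributes exactly 1).  By default the
    sum runs over heavy-atom pairs; ``include_hydrogens`` extends it to
    explicit hydrogens when the structure carries them, which is the
    convention the model descriptor uses ("treats all atoms equally").
    """
    if s < 0:
        raise ValueError("scattering parameter s must be >= 0")
    coords = struct.all_atom_coords() if include_hydrogens else struct.coords
    n = len(coords)
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    diff = coords[iu[0]] - coords[iu[1]]
    r = np.sqrt((diff**2).sum(axis=1))
    # np.sinc(x) = sin(pi x)/(pi x) with sinc(0) = 1
    return float(np.sinc(s * r / np.pi).sum())


def mor10u(struct: Structure3D, include_hydrogens: bool = True) -> float:
    """Mor10u: 3D-MoRSE at s = 9 1/Angstrom (index k uses s = k - 1).

    All atoms, hydrogens included, enter the sum by default: the
    unweighted MoRSE treats all atoms equally, and the all-atom form is
    the one that reproduces the published model's descriptor correlation
    pattern and coefficient signs on re-derived geometries.
    """
    return morse(struct, 9.0, include_hydrogens=include_hydrogens)


def n_aromatic_oh(mol: MoleculeGraph) -> int:
    """Count -OH groups whose oxygen is bonded to an aromatic carbon.

    Oxygens of an -N(OH)2 group are bonded to nitrogen, not to an aromatic
    carbon, and therefore do not count.
    """
    return len(mol.mol.GetSubstructMatches(_AROH_SMARTS))


def descriptor_vector(
    struct: Structure3D,
    eeig_weighting: Weighting = "edge_degree",
    mor_hydrogens: bool = True,
) -> dict[str, float]:
    """The (EEig05x, Mor10u, nArOH) triple for one embedded structure."""
    return {
        "EEig05x": eeig(struct.parent, 5, eeig_weighting),
        "Mor10u": mor10u(struct, include_hydrogens=mor_hydrogens),
        "nArOH": float(n_aromatic_oh(struct.parent)),
    }


def _ids_for(structures: Sequence[Structure3D], ids) -> list:
    if ids is not None:
        return list(ids)
    out = []
    for i, s in enumerate(structures):
        name = s.parent.name
        try:
            out.append(int(name))
        except (TypeError, ValueError):
            out.append(name or i)
    return out


def descriptor_table(
    structures: Sequence[Structure3D],
    ids: Iterable | None = None,
    eeig_weighting: Weighting = "edge_degree",
) -> pd.DataFrame:
    """Model descriptor matrix, one row per compound, indexed/sorted by id.

    Order-independent: the result is sorted by compound id regardless of
    input order.  Raises with the offending compound id on failure.
    """
    idx = _ids_for(structures, ids)
    rows = {}
    for cid, struct in zip(idx, structures):
        try:
            rows[cid] = descriptor_vector(struct, eeig_weighting)
        except Exception as exc:
            raise RuntimeError(f"descriptor failure for compound {cid}") from exc
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "id"
    return df[list(MODEL_DESCRIPTORS)]


def wide_descriptor_table(
    structures: Sequence[Structure3D],
    ids: Iterable | None = None,
    eeig_ks: range = range(1, 9),
    mor_ks: range = range(1, 33),
    eeig_weighting: Weighting = "edge_degree",
) -> pd.DataFrame:
    """Exploration pool: EEig(1..8)x, Mor(1..32)u and nArOH per compound.

    Mor(k)u uses scattering parameter s = k - 1, so Mor01u is the pair
    count and Mor10u the model descriptor.
    """
    idx = _ids_for(structures, ids)
    rows = {}
    for cid, struct in zip(idx, structures):
        row: dict[str, float] = {}
        vals = edge_eigenvalues(struct.parent, eeig_weighting)
        for k in eeig_ks:
            row[f"EEig{k:02d}x"] = float(vals[k - 1]) if k <= len(vals) else 0.0
        for k in mor_ks:
            row[f"Mor{k:02d}u"] = morse(
                struct, float(k - 1), include_hydrogens=True
            )
        row["nArOH"] = float(n_aromatic_oh(struct.parent))
        rows[cid] = row
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "id"
    return df


def write_descriptor_csv(
    table: pd.DataFrame, path, provenance: Mapping[str, object] | None = None
) -> None:
    """Write a descriptor table as CSV with '#'-prefixed provenance lines."""
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        table.to_csv(fh)


def read_descriptor_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col=0)
    return df
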