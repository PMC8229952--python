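"""Coumarin compound dataset and 3D structure construction.

The 40 assayed coumarins (2H-chromen-2-one derivatives) plus the two
proposed follow-up compounds are encoded as scaffold + substituent
records.  Molecules are reconstructed from that specification with RDKit,
and 3D geometries are produced by seeded distance-geometry embedding
followed by MMFF94 relaxation, so every downstream descriptor is a
deterministic function of (substituents, seed).
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

logger = logging.getLogger(__name__)

__all__ = [
    "SubstituentSpec",
    "CompoundRecord",
    "MoleculeGraph",
    "Structure3D",
    "DatasetError",
    "StructureError",
    "VALID_POSITIONS",
    "VALID_GROUPS",
    "load_paper_dataset",
    "parse_substituents",
    "build_structure",
    "embed_coordinates",
    "read_structures",
    "write_structures",
]


class DatasetError(ValueError):
    """Raised when the packaged dataset fixture is absent or corrupt."""


class StructureError(ValueError):
    """Raised for invalid substituent specifications or failed embeddings."""


# 2H-chromen-2-one written kekulized so atom indices are stable:
# 0=O(carbonyl) 1=C2 2=C3 3=C4 4=C4a 5=C5 6=C6 7=C7 8=C8 9=C8a 10=O1
COUMARIN_SMILES = "O=C1C=Cc2ccccc2O1"
_POSITION_ATOM = {3: 2, 4: 3, 5: 5, 6: 6, 7: 7, 8: 8}

# Ring positions that carry substituents in this series (C4 never does).
VALID_POSITIONS = (3, 5, 6, 7, 8)

# Substituent group -> SMILES fragment; first atom is the attachment point.
VALID_GROUPS = {
    "acetyl": "C(C)=O",
    "benzoyl": "C(=O)c1ccccc1",
    "cyano": "C#N",
    "ethoxycarbonyl": "C(=O)OCC",
    "methoxycarbonyl": "C(=O)OC",
    "bromo": "Br",
    "chloro": "Cl",
    "hydroxy": "O",
    "methoxy": "OC",
    "ethoxy": "OCC",
    "diethylamino": "N(CC)CC",
    # read as -N(OH)2 on the ring carbon
    "dihydroxyamino": "N(O)O",
}

ROLES = ("modeling", "excluded_inactive", "excluded_outlier", "proposed")


@dataclass(frozen=True, order=True)
class SubstituentSpec:
    """One substituent at one ring position of the coumarin core."""

    position: int
    group: str

    def __post_init__(self) -> None:
        if self.position not in VALID_POSITIONS:
            raise StructureError(
                f"invalid ring position {self.position}; "
                f"expected one of {VALID_POSITIONS}"
            )
        if self.group not in VALID_GROUPS:
            raise StructureError(
                f"unknown substituent group {self.group!r}; "
                f"expected one of {sorted(VALID_GROUPS)}"
            )

    def __str__(self) -> str:
        return f"{self.position}-{self.group}"


@dataclass(frozen=True)
class CompoundRecord:
    """One dataset row: identity, substituents, measured activity, role.

    ``inhibition_pct`` is the % inhibition of hDPP III at 10 uM, or None
    for compounds with no measurable activity (the NA sentinel).  NA
    compounds kept in the modeling pool carry response value 0.00 via
    :func:`dpp3qsar.activity.log_response`.
    """

    compound_id: int
    substituents: tuple[SubstituentSpec, ...]
    inhibition_pct: float | None = None
    ic50_uM: float | None = None
    role: str = "modeling"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DatasetError(f"unknown role {self.role!r}")
        if self.inhibition_pct is not None and not (
            0.0 <= self.inhibition_pct <= 100.0
        ):
            raise DatasetError(
                f"compound {self.compound_id}: inhibition_pct "
                f"{self.inhibition_pct} outside [0, 100]"
            )
        if self.ic50_uM is not None and self.ic50_uM <= 0:
            raise DatasetError(
                f"compound {self.compound_id}: ic50_uM must be positive"
            )
        if self.role == "proposed" and self.inhibition_pct is not None:
            raise DatasetError(
                f"proposed compound {self.compound_id} cannot carry a "
                "measured activity"
            )
        seen = [s.position for s in self.substituents]
        if len(seen) != len(set(seen)):
            raise DatasetError(
                f"compound {self.compound_id}: duplicate substituent position"
            )

    @property
    def is_tested(self) -> bool:
        """True for the 40 assayed compounds (everything but proposed)."""
        return self.role != "proposed"

    @property
    def is_active(self) -> bool:
        return self.inhibition_pct is not None

    def substituent_string(self) -> str:
        return ";".join(str(s) for s in self.substituents)


@dataclass
class MoleculeGraph:
    """H-depleted molecular bond graph, carried as an RDKit Mol."""

    mol: Chem.Mol
    name: str = ""

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def num_bonds(self) -> int:
        return self.mol.GetNumBonds()

    def canonical_smiles(self) -> str:
        # RDKit canonical aromatic SMILES; pinned dialect for golden files
        return Chem.MolToSmiles(self.mol)

    def molecular_formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.mol)


@dataclass
class Structure3D:
    """Heavy-atom 3D coordinates for a molecule, plus provenance seed.

    ``mol3d``, when present, carries the embedded RDKit conformer with
    explicit hydrogens (heavy atoms first, in graph order), so descriptors
    that sum over all atoms can recover proton positions.
    """

    parent: MoleculeGraph
    coords: np.ndarray  # (n_heavy, 3) Cartesian, Angstrom
    seed: int
    mol3d: Chem.Mol | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.parent.num_heavy_atoms, 3):
            raise StructureError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{self.parent.num_heavy_atoms} heavy atoms"
            )

    def all_atom_coords(self) -> np.ndarray:
        """Coordinates including explicit hydrogens when available,
        otherwise the heavy-atom coordinates."""
        if self.mol3d is not None and self.mol3d.GetNumConformers() > 0:
            return self.mol3d.GetConformer().GetPositions().astype(float)
        return self.coords

    def distance_matrix(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


def parse_substituents(text: str) -> tuple[SubstituentSpec, ...]:
    """Parse ``"3-benzoyl;7-hydroxy"`` into SubstituentSpec tuples.

    Whitespace around separators is tolerated; an empty string means the
    unsubstituted coumarin scaffold.
    """
    text = (text or "").strip()
    if not text:
        return ()
    specs = []
    for part in text.split(";"):
        part = part.strip()
        pos_str, _, group = part.partition("-")
        try:
            pos = int(pos_str)
        except ValueError as exc:
            raise StructureError(f"cannot parse substituent {part!r}") from exc
        specs.append(SubstituentSpec(pos, group.strip()))
    return tuple(specs)


def _default_fixture() -> Path:
    return Path(str(resources.files("dpp3qsar").joinpath("data/table1.csv")))


def load_paper_dataset(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load the packaged 42-compound dataset (40 assayed + 2 proposed).

    Activity values are the measured % inhibition of hDPP III at 10 uM;
    the two most potent compounds additionally carry IC50 values in uM.
    Exclusion roles record which inactive compounds were dropped from the
    modeling pool and which compound was flagged as a response outlier.
    """
    src = Path(path) if path is not None else _default_fixture()
    if not src.exists():
        raise DatasetError(f"dataset fixture not found: {src}")
    records: list[CompoundRecord] = []
    try:
        with open(src, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"id", "substituents", "inhibition_pct", "ic50_uM", "role"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise DatasetError(
                    f"dataset fixture {src} missing columns "
                    f"{sorted(required - set(reader.fieldnames or []))}"
                )
            for row in reader:
                records.append(
                    CompoundRecord(
                        compound_id=int(row["id"]),
                        substituents=parse_substituents(row["substituents"]),
                        inhibition_pct=(
                            float(row["inhibition_pct"])
                            if row["inhibition_pct"]
                            else None
                        ),
                        ic50_uM=float(row["ic50_uM"]) if row["ic50_uM"] else None,
                        role=row["role"],
                    )
                )
    except (OSError, ValueError) as exc:
        if isinstance(exc, DatasetError):
            raise
        raise DatasetError(f"corrupt dataset fixture {src}: {exc}") from exc
    if len(records) != 42:
        raise DatasetError(
            f"dataset fixture {src} holds {len(records)} records, expected 42"
        )
    return records


def build_structure(
    substituents: Sequence[SubstituentSpec] | str,
    name: str = "",
) -> MoleculeGraph:
    """Build the 2H-chromen-2-one core with the given substituents attached.

    Accepts either SubstituentSpec sequences or the compact string form
    ``"3-benzoyl;7-hydroxy"``.  Idempotent: the canonical SMILES of the
    result is a pure function of the substituent set.
    """
    if isinstance(substituents, str):
        substituents = parse_substituents(substituents)
    positions = [s.position for s in substituents]
    if len(positions) != len(set(positions)):
        raise StructureError("duplicate substituent position")
    core = Chem.RWMol(Chem.MolFromSmiles(COUMARIN_SMILES))
    for spec in sorted(substituents):
        frag = Chem.MolFromSmiles(VALID_GROUPS[spec.group])
        offset = core.GetNumAtoms()
        core.InsertMol(frag)
        core.AddBond(
            _POSITION_ATOM[spec.position], offset, Chem.BondType.SINGLE
        )
    mol = core.GetMol()
    Chem.SanitizeMol(mol)
    return MoleculeGraph(mol=mol, name=name)


def build_structures(
    records: Iterable[CompoundRecord],
) -> dict[int, MoleculeGraph]:
    """Build structures for many records, keyed by compound id."""
    out = {}
    for rec in records:
        try:
            out[rec.compound_id] = build_structure(
                rec.substituents, name=str(rec.compound_id)
            )
        except StructureError as exc:
            raise StructureError(
                f"compound {rec.compound_id}: {exc}"
            ) from exc
    return out


def embed_coordinates(
    mol: MoleculeGraph,
    seed: int = 2021,
    max_retries: int = 5,
    mmff_max_iters: int = 2000,
) -> Structure3D:
    """Generate a relaxed 3D conformer, deterministic in (molecule, seed).

    Distance-geometry embedding (ETKDGv3) with explicit hydrogens, then
    MMFF94 force-field relaxation.  Raises if no conformer can be embedded
    within the retry budget or if the relaxation does not converge.
    """
    molH = Chem.AddHs(mol.mol)
    conf_id = -1
    for attempt in range(max_retries):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        conf_id = AllChem.EmbedMolecule(molH, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise StructureError(
            f"embedding failed for compound {mol.name or mol.canonical_smiles()} "
            f"after {max_retries} attempts (seed {seed})"
        )
    status = AllChem.MMFFOptimizeMolecule(molH, maxIters=mmff_max_iters)
    if status != 0:
        raise StructureError(
            f"MMFF relaxation did not converge for compound "
            f"{mol.name or mol.canonical_smiles()} (status {status})"
        )
    # AddHs appends hydrogens after the heavy atoms, so the first
    # num_heavy_atoms conformer rows are the heavy-atom coordinates.
    all_coords = molH.GetConformer().GetPositions().astype(float)
    coords = all_coords[: mol.num_heavy_atoms]
    return Structure3D(parent=mol, coords=coords, seed=int(seed), mol3d=molH)


# ---------------------------------------------------------------------------
# Standard-format I/O


def write_structures(
    structures: Sequence[MoleculeGraph | Structure3D],
    path: str | Path,
    fmt: str,
    records: Sequence[CompoundRecord] | None = None,
) -> None:
    """Write structures as SMILES (one per line with name), SDF V2000 or CSV.

    For CSV a parallel list of CompoundRecords supplies activity columns.
    """
    path = Path(path)
    fmt = fmt.lower()
    graphs = [
        s.parent if isinstance(s, Structure3D) else s for s in structures
    ]
    if fmt == "smiles":
        with open(path, "w") as fh:
            for g in graphs:
                fh.write(f"{g.canonical_smiles()}\t{g.name}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        writer.SetForceV3000(False)
        for s, g in zip(structures, graphs):
            mol = s.mol3d if isinstance(s, Structure3D) and s.mol3d else g.mol
            mol = Chem.Mol(mol)
            mol.SetProp("_Name", g.name)
            writer.write(mol)
        writer.close()
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "smiles", "inhibition_pct", "ic50_uM", "role"])
            recs = records or [None] * len(graphs)
            for g, rec in zip(graphs, recs):
                if rec is not None:
                    w.writerow(
                        [
                            rec.compound_id,
                            g.canonical_smiles(),
                            "" if rec.inhibition_pct is None else rec.inhibition_pct,
                            "" if rec.ic50_uM is None else rec.ic50_uM,
                            rec.role,
                        ]
                    )
                else:
                    w.writerow([g.name, g.canonical_smiles(), "", "", ""])
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_structures(
    path: str | Path,
    fmt: str,
    permissive: bool = False,
) -> list[MoleculeGraph | Structure3D]:
    """Read structures written by :func:`write_structures`.

    Malformed records raise with their record index unless ``permissive``
    is set, in which case they are skipped with a warning.
    """
    path = Path(path)
    fmt = fmt.lower()
    out: list[MoleculeGraph | Structure3D] = []

    def _fail(idx: int, msg: str) -> None:
        full = f"record {idx} in {path}: {msg}"
        if permissive:
            warnings.warn(full)
            logger.warning(full)
        else:
            raise ValueError(full)

    if fmt == "smiles":
        with open(path) as fh:
            for idx, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None:
                    _fail(idx, f"unparsable SMILES {parts[0]!r}")
                    continue
                name = parts[1] if len(parts) > 1 else ""
                out.append(MoleculeGraph(mol=mol, name=name))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                _fail(idx, "unparsable SDF record")
                continue
            graph = MoleculeGraph(
                mol=mol, name=mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            )
            if mol.GetNumConformers() > 0:
                coords = mol.GetConformer().GetPositions().astype(float)
                out.append(
                    Structure3D(parent=graph, coords=coords, seed=-1, mol3d=mol)
                )
            else:
                out.append(graph)
    elif fmt == "csv":
        with open(path, newline="") as fh:
            for idx, row in enumerate(csv.DictReader(fh)):
                mol = Chem.MolFromSmiles(row.get("smiles", ""))
                if mol is None:
                    _fail(idx, f"unparsable SMILES {row.get('smiles')!r}")
                    continue
                out.append(MoleculeGraph(mol=mol, name=str(row.get("id", ""))))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return out


def has_coumarin_core(graph: MoleculeGraph) -> bool:
    """Substructure check for the benzopyran-2-one core."""
    core = Chem.MolFromSmiles(COUMARIN_SMILES)
    return graph.mol.HasSubstructMatch(core)
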