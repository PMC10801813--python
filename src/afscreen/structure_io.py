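"""Reading and validation of predicted structures and PAE matrices.

AlphaFold-style coordinate files store the per-residue confidence (pLDDT,
0-100) in the B-factor column; the predicted aligned error (PAE) ships as a
separate square JSON matrix indexed over the concatenated residue order of
all chains.  This module reads both, establishes that shared residue
indexing, and pairs them into a :class:`BoundPrediction` for contact
analysis.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residue identity: (chain_id, author seq number, insertion code)
ResidueKey = tuple[str, int, str]


class StructureFormatError(ValueError):
    """Raised when a coordinate or PAE file cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, element symbol, Cartesian position in Å."""

    name: str
    element: str
    position: np.ndarray  # shape (3,)
    is_heavy: bool

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass
class ResidueRecord:
    """One residue with its heavy/hydrogen atoms and pLDDT (0-100)."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[AtomRecord]
    plddt: float

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def label(self) -> str:
        icode = self.icode.strip()
        return f"{self.chain_id}{self.seq_num}{icode}"

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class StructureModel:
    """One predicted model: ordered chains of residues plus the concatenated
    residue index shared with the PAE matrix."""

    model_id: str
    chains: list[tuple[str, list[ResidueRecord]]]
    concat_index: dict[ResidueKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.concat_index:
            self.concat_index = {
                res.key: i for i, res in enumerate(self.iter_residues())
            }
        chain_ids = [cid for cid, _ in self.chains]
        if len(set(chain_ids)) != len(chain_ids):
            raise ValueError(f"duplicate chain ids in {self.model_id}: {chain_ids}")
        for cid, residues in self.chains:
            if not residues:
                raise StructureFormatError(
                    f"chain {cid!r} of {self.model_id} has zero residues"
                )
            nums = [(r.seq_num, r.icode) for r in residues]
            if len(set(nums)) != len(nums):
                raise ValueError(f"duplicate residue numbers in chain {cid!r}")

    def iter_residues(self) -> Iterator[ResidueRecord]:
        for _, residues in self.chains:
            yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(residues) for _, residues in self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"chain {chain_id!r} not in model {self.model_id}; "
                       f"chains present: {self.chain_ids}")

    def residue(self, key: ResidueKey) -> ResidueRecord:
        cid, num, icode = key
        for res in self.chain(cid):
            if res.seq_num == num and res.icode == icode:
                return res
        raise KeyError(f"residue {key} not found")


@dataclass
class PAEMatrix:
    """Square predicted-aligned-error matrix in Å over the concatenated
    residue order.  Directional: ``values[i, j]`` is the expected error at
    residue j when the prediction is aligned on residue i."""

    values: np.ndarray
    max_pae: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise StructureFormatError(
                f"PAE matrix must be square, got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise StructureFormatError("PAE entries must be non-negative")
        if self.max_pae is not None and np.any(self.values > self.max_pae + 1e-9):
            raise StructureFormatError(
                f"PAE entries exceed declared max_pae={self.max_pae}"
            )

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class BoundPrediction:
    """A StructureModel paired with its (size-checked) PAE matrix."""

    model: StructureModel
    pae: PAEMatrix

    def __post_init__(self) -> None:
        if self.pae.size != self.model.n_residues:
            raise ValueError(
                f"PAE size {self.pae.size} ≠ {self.model.n_residues} residues "
                f"of model {self.model.model_id}"
            )

    def pae_of(self, res_i: ResidueKey, res_j: ResidueKey) -> float:
        """Directional pAE aligned on ``res_i``, evaluated at ``res_j``."""
        i = self.model.concat_index[res_i]
        j = self.model.concat_index[res_j]
        return float(self.pae.values[i, j])

    def min_pae(self, res_i: ResidueKey, res_j: ResidueKey) -> float:
        """Minimum of the two directional pAE values for a residue pair."""
        return min(self.pae_of(res_i, res_j), self.pae_of(res_j, res_i))


_HYDROGEN_SYMBOLS = {"H", "D", "T"}


def _element_symbol(atom: gemmi.Atom) -> str:
    sym = atom.element.name
    if sym and sym != "X":
        return sym
    # fall back on the atom name: strip leading digits, take first letter
    stripped = atom.name.lstrip("0123456789 ")
    return stripped[:1].upper() if stripped else "X"


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties by file order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            by_name[atom.name] = atom
    return [by_name[a.name] for a in atoms if by_name[a.name] is a]


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a predicted-structure coordinate file (PDB or mmCIF).

    pLDDT is taken from the temperature-factor field, AlphaFold convention;
    files on the 0-1 scale (every B-factor ≤ 1) are rescaled ×100 with a
    warning.  Hydrogens are retained but flagged non-heavy.  HETATM
    ligands/waters are skipped.  Only the first MODEL block is read.

    Raises
    ------
    StructureFormatError
        If the file cannot be parsed, has fewer than two chains, or lacks
        B-factors (all zero).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models found")
    st.setup_entities()

    chains: list[tuple[str, list[ResidueRecord]]] = []
    b_values: list[float] = []
    for chain in st[0]:
        residues: list[ResidueRecord] = []
        for res in chain:
            if res.het_flag == "H" and not res.is_amino_acid():
                logger.info("%s: skipping HETATM residue %s %s%d",
                            path.name, res.name, chain.name, res.seqid.num)
                continue
            picked = _pick_altloc(list(res))
            b_first = picked[0].b_iso
            spread = max(a.b_iso for a in picked) - min(a.b_iso for a in picked)
            if spread > 0.01:
                logger.warning(
                    "%s: residue %s%d has inconsistent B-factors (spread %.3f); "
                    "using the first atom's value", path.name, chain.name,
                    res.seqid.num, spread)
            atoms = []
            for a in picked:
                sym = _element_symbol(a)
                atoms.append(AtomRecord(
                    name=a.name,
                    element=sym,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    is_heavy=sym not in _HYDROGEN_SYMBOLS,
                ))
            if not any(a.is_heavy for a in atoms):
                raise StructureFormatError(
                    f"{path}: residue {chain.name}{res.seqid.num} has no heavy atoms"
                )
            b_values.append(float(b_first))
            residues.append(ResidueRecord(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                icode=res.seqid.icode or " ",
                res_name=res.name,
                atoms=atoms,
                plddt=float(b_first),
            ))
        if residues:
            chains.append((chain.name, residues))

    if len(chains) < 2:
        raise StructureFormatError(
            f"{path}: interface requires ≥ 2 chains, found {len(chains)}"
        )
    if b_values and max(b_values) == 0.0:
        raise StructureFormatError(
            f"{path}: B-factor column is all zero; pLDDT missing"
        )

    model = StructureModel(model_id=path.stem, chains=chains)
    if max(b_values) <= 1.0:
        logger.warning("%s: B-factors on 0-1 scale; rescaling pLDDT ×100",
                       path.name)
        for res in model.iter_residues():
            res.plddt *= 100.0
    for res in model.iter_residues():
        if not 0.0 <= res.plddt <= 100.0:
            raise StructureFormatError(
                f"{path}: residue {res.label} pLDDT {res.plddt} outside [0, 100]"
            )
    return model


def read_pae(path: str | Path) -> PAEMatrix:
    """Read a PAE JSON file in the ColabFold (``"pae"``) or AFDB
    (``"predicted_aligned_error"``) dialect, optionally wrapped in a
    one-element list."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        if len(doc) != 1:
            raise StructureFormatError(
                f"{path}: expected a 1-element list wrapper, got {len(doc)} elements"
            )
        doc = doc[0]
    if not isinstance(doc, dict):
        raise StructureFormatError(f"{path}: top-level JSON is not an object")
    for key in ("pae", "predicted_aligned_error"):
        if key in doc:
            raw = doc[key]
            break
    else:
        raise StructureFormatError(
            f"{path}: no 'pae' or 'predicted_aligned_error' key; "
            f"keys found: {sorted(doc)}"
        )
    lengths = {len(row) for row in raw}
    if len(lengths) != 1 or lengths != {len(raw)}:
        raise StructureFormatError(f"{path}: PAE array is ragged or non-square")
    max_pae = doc.get("max_predicted_aligned_error", doc.get("max_pae"))
    return PAEMatrix(values=np.asarray(raw, dtype=float),
                     max_pae=float(max_pae) if max_pae is not None else None)


def bind(model: StructureModel, pae: PAEMatrix) -> BoundPrediction:
    """Pair a structure with its PAE matrix, checking the residue count."""
    return BoundPrediction(model=model, pae=pae)


def read_prediction(structure_path: str | Path, pae_path: str | Path,
                    format: str = "auto") -> BoundPrediction:
    """Convenience: read and bind a structure/PAE file pair."""
    return bind(read_structure(structure_path, format=format),
                read_pae(pae_path))
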