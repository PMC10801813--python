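"""Inter-chain residue contact detection.

A contact is a unique pair of residues on two different chains that passes
three filters simultaneously: the mean of the two residues' pLDDT is above
50, the minimum of the two directional pAE values is below 15 Å, and at
least one pair of non-hydrogen atoms (one from each residue) lies closer
than 8 Å.  All three comparisons are strict.  The interface between two
chains of one model is the set of all such contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import BoundPrediction, ResidueKey, ResidueRecord

#: canonical, order-independent contact identifier
ContactKey = tuple[ResidueKey, ResidueKey]


@dataclass(frozen=True)
class ContactThresholds:
    """The three contact filters.

    min_avg_plddt : pair-mean pLDDT must exceed this (0-100 scale)
    max_min_pae   : best-direction pAE must be below this (Å)
    max_heavy_dist: closest heavy-atom pair must be below this (Å)
    """

    min_avg_plddt: float = 50.0
    max_min_pae: float = 15.0
    max_heavy_dist: float = 8.0

    def __post_init__(self) -> None:
        if min(self.min_avg_plddt, self.max_min_pae, self.max_heavy_dist) <= 0:
            raise ValueError("contact thresholds must be positive")


DEFAULT_THRESHOLDS = ContactThresholds()


def contact_key(res_a: ResidueKey, res_b: ResidueKey) -> ContactKey:
    """Canonical unordered identifier for a residue pair."""
    return (res_a, res_b) if res_a <= res_b else (res_b, res_a)


@dataclass(frozen=True)
class Contact:
    """One inter-chain residue pair with its confidence evidence."""

    res_a: ResidueKey
    res_b: ResidueKey
    avg_plddt: float       # mean of the two residues' pLDDT
    min_pae: float         # best of the two directional pAE values, Å
    min_heavy_dist: float  # closest heavy-atom pair, Å

    def __post_init__(self) -> None:
        if self.res_a[0] == self.res_b[0]:
            raise ValueError(f"contact within one chain: {self.res_a}, {self.res_b}")

    @property
    def key(self) -> ContactKey:
        return contact_key(self.res_a, self.res_b)


@dataclass
class ContactSet:
    """The interface between two chains of one model."""

    chain_pair: tuple[str, str]
    contacts: list[Contact]
    thresholds: ContactThresholds = DEFAULT_THRESHOLDS
    model_id: str = ""
    _keys: set[ContactKey] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._keys = {c.key for c in self.contacts}
        if len(self._keys) != len(self.contacts):
            raise ValueError("duplicate contact keys in ContactSet")
        pair = set(self.chain_pair)
        for c in self.contacts:
            if {c.res_a[0], c.res_b[0]} != pair:
                raise ValueError(
                    f"contact {c.key} does not join chains {self.chain_pair}"
                )

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    @property
    def keys(self) -> set[ContactKey]:
        return set(self._keys)

    def to_frame(self) -> pd.DataFrame:
        """Contacts as a table (chain_a, res_a, chain_b, res_b, evidence)."""
        rows = []
        for c in sorted(self.contacts, key=lambda c: c.key):
            a, b = c.key
            rows.append({
                "chain_a": a[0], "res_a": a[1],
                "chain_b": b[0], "res_b": b[1],
                "avg_plddt": c.avg_plddt,
                "min_pae": c.min_pae,
                "min_heavy_dist": c.min_heavy_dist,
            })
        return pd.DataFrame(rows, columns=["chain_a", "res_a", "chain_b",
                                           "res_b", "avg_plddt", "min_pae",
                                           "min_heavy_dist"])


def _heavy_coords(residues: Iterable[ResidueRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack heavy-atom coordinates with a parallel residue-index array."""
    coords, owner = [], []
    for ridx, res in enumerate(residues):
        for atom in res.heavy_atoms():
            coords.append(atom.position)
            owner.append(ridx)
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.asarray(coords), np.asarray(owner, dtype=int)


def _min_heavy_dists_kdtree(res_a: list[ResidueRecord], res_b: list[ResidueRecord],
                            cutoff: float) -> dict[tuple[int, int], float]:
    """Minimum inter-residue heavy-atom distance for residue pairs that come
    within ``cutoff``; k-d tree pruned."""
    xa, ia = _heavy_coords(res_a)
    xb, ib = _heavy_coords(res_b)
    if len(xa) == 0 or len(xb) == 0:
        return {}
    tree_a, tree_b = cKDTree(xa), cKDTree(xb)
    sparse = tree_a.sparse_distance_matrix(tree_b, max_distance=cutoff,
                                           output_type="coo_matrix")
    best: dict[tuple[int, int], float] = {}
    for ai, bi, d in zip(sparse.row, sparse.col, sparse.data):
        pair = (int(ia[ai]), int(ib[bi]))
        if d < best.get(pair, np.inf):
            best[pair] = float(d)
    return best


def _min_heavy_dists_brute(res_a: list[ResidueRecord], res_b: list[ResidueRecord],
                           cutoff: float) -> dict[tuple[int, int], float]:
    """All-pairs double loop over residues and heavy atoms."""
    best: dict[tuple[int, int], float] = {}
    for i, ra in enumerate(res_a):
        pa = np.asarray([a.position for a in ra.heavy_atoms()])
        for j, rb in enumerate(res_b):
            pb = np.asarray([a.position for a in rb.heavy_atoms()])
            d = float(np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2)
                              .sum(axis=2)).min())
            if d <= cutoff:
                best[(i, j)] = d
    return best


def find_contacts(pred: BoundPrediction, chain_pair: tuple[str, str],
                  thresholds: ContactThresholds = DEFAULT_THRESHOLDS,
                  method: str = "kdtree") -> ContactSet:
    """Detect the contacts between two chains of one bound prediction.

    Deterministic and independent of the chain argument order.  ``method``
    selects the neighbour search: ``"kdtree"`` (default) or ``"brute"``
    (all-pairs reference path); both return identical contact sets.
    """
    ca, cb = chain_pair
    if ca == cb:
        raise ValueError(f"chain pair must name two different chains, got {chain_pair}")
    pair = tuple(sorted((ca, cb)))
    res_a = pred.model.chain(pair[0])
    res_b = pred.model.chain(pair[1])

    search = {"kdtree": _min_heavy_dists_kdtree,
              "brute": _min_heavy_dists_brute}[method]
    dists = search(res_a, res_b, thresholds.max_heavy_dist)

    contacts = []
    for (i, j), dist in dists.items():
        if not dist < thresholds.max_heavy_dist:  # strict "closer than"
            continue
        ra, rb = res_a[i], res_b[j]
        avg_plddt = 0.5 * (ra.plddt + rb.plddt)
        if not avg_plddt > thresholds.min_avg_plddt:
            continue
        min_pae = pred.min_pae(ra.key, rb.key)
        if not min_pae < thresholds.max_min_pae:
            continue
        contacts.append(Contact(res_a=ra.key, res_b=rb.key,
                                avg_plddt=avg_plddt, min_pae=min_pae,
                                min_heavy_dist=dist))
    contacts.sort(key=lambda c: c.key)
    return ContactSet(chain_pair=pair, contacts=contacts,
                      thresholds=thresholds, model_id=pred.model.model_id)


def contact_map(cs: ContactSet) -> dict[ResidueKey, list[ResidueKey]]:
    """Per-residue adjacency: each interface residue mapped to its sorted
    partners.  Total adjacency entries = 2 × number of contacts."""
    adj: dict[ResidueKey, list[ResidueKey]] = {}
    for c in cs:
        adj.setdefault(c.res_a, []).append(c.res_b)
        adj.setdefault(c.res_b, []).append(c.res_a)
    return {res: sorted(partners) for res, partners in sorted(adj.items())}
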