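"""Per-prediction interface statistics and pDockQ.

Interface statistics average each contact's evidence over the whole
interface: ``avg_interface_pae`` is the mean of the contacts' best-direction
pAE and ``avg_interface_plddt`` the mean of the contacts' pair-mean pLDDT.

pDockQ estimates interface accuracy (a DockQ proxy when no reference
structure exists) with a calibrated sigmoid of

    x = avg_interface_plddt * ln(n_contacts)
    pDockQ = L / (1 + exp(-k (x - x0))) + b

with L=0.724, x0=152.611, k=0.052, b=0.018, giving scores in (b, L+b) for a
non-empty interface and 0 for an empty one.  By default x is computed over
this pipeline's contact set; `pdockq_reference_cb` provides the original
Cβ-contact recipe as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactSet
from .structure_io import BoundPrediction


@dataclass(frozen=True)
class PDockQParams:
    """Sigmoid constants: ceiling L, midpoint x0, steepness k, floor b."""

    L: float = 0.724
    x0: float = 152.611
    k: float = 0.052
    b: float = 0.018

    def __post_init__(self) -> None:
        if self.L + self.b > 1.0 + 1e-12:
            raise ValueError("pDockQ ceiling L + b must not exceed 1")
        if self.k <= 0:
            raise ValueError("pDockQ steepness k must be positive")


DEFAULT_PDOCKQ = PDockQParams()


@dataclass(frozen=True)
class InterfaceSummary:
    """One prediction's interface in numbers.

    ``avg_interface_pae`` and ``avg_interface_plddt`` are ``None`` for an
    empty interface, and ``pdockq`` is then 0.
    """

    model_id: str
    chain_pair: tuple[str, str]
    n_contacts: int
    avg_interface_pae: float | None
    avg_interface_plddt: float | None
    pdockq: float


def pdockq_from_stats(avg_plddt: float, n_contacts: int,
                      params: PDockQParams = DEFAULT_PDOCKQ) -> float:
    """pDockQ directly from interface pLDDT and contact count."""
    if n_contacts == 0:
        return 0.0
    x = avg_plddt * math.log(n_contacts)
    return params.L / (1.0 + math.exp(-params.k * (x - params.x0))) + params.b


def pdockq(cs: ContactSet, params: PDockQParams = DEFAULT_PDOCKQ) -> float:
    """pDockQ of a contact set (0 when the interface is empty)."""
    if len(cs) == 0:
        return 0.0
    avg_plddt = float(np.mean([c.avg_plddt for c in cs]))
    return pdockq_from_stats(avg_plddt, len(cs), params)


def interface_stats(cs: ContactSet,
                    params: PDockQParams = DEFAULT_PDOCKQ) -> InterfaceSummary:
    """Summarise one interface: contact count, mean pAE/pLDDT, pDockQ."""
    if len(cs) == 0:
        return InterfaceSummary(model_id=cs.model_id, chain_pair=cs.chain_pair,
                                n_contacts=0, avg_interface_pae=None,
                                avg_interface_plddt=None, pdockq=0.0)
    avg_pae = float(np.mean([c.min_pae for c in cs]))
    avg_plddt = float(np.mean([c.avg_plddt for c in cs]))
    return InterfaceSummary(
        model_id=cs.model_id,
        chain_pair=cs.chain_pair,
        n_contacts=len(cs),
        avg_interface_pae=avg_pae,
        avg_interface_plddt=avg_plddt,
        pdockq=pdockq_from_stats(avg_plddt, len(cs), params),
    )


def pdockq_reference_cb(pred: BoundPrediction, chain_pair: tuple[str, str],
                        params: PDockQParams = DEFAULT_PDOCKQ,
                        cutoff: float = 8.0) -> float:
    """pDockQ per the original Cβ recipe.

    Interface contacts are residue pairs whose Cβ atoms (Cα for glycine) lie
    within ``cutoff`` Å, and x multiplies the mean pLDDT of the *interface
    residues* (each unique residue once) by ln of the contact count.
    """
    def cb_position(res):
        atoms = {a.name: a for a in res.heavy_atoms()}
        atom = atoms.get("CB") or atoms.get("CA")
        return atom.position if atom is not None else None

    pair = tuple(sorted(chain_pair))
    res_a = pred.model.chain(pair[0])
    res_b = pred.model.chain(pair[1])
    n_contacts = 0
    interface: dict[tuple, float] = {}
    for ra in res_a:
        pa = cb_position(ra)
        if pa is None:
            continue
        for rb in res_b:
            pb = cb_position(rb)
            if pb is None:
                continue
            if np.linalg.norm(pa - pb) <= cutoff:
                n_contacts += 1
                interface[ra.key] = ra.plddt
                interface[rb.key] = rb.plddt
    if n_contacts == 0:
        return 0.0
    avg_plddt = float(np.mean(list(interface.values())))
    return pdockq_from_stats(avg_plddt, n_contacts, params)


def summaries_to_frame(summaries: list[InterfaceSummary]) -> pd.DataFrame:
    """One row per (pair, model): n_contacts, mean pAE/pLDDT, pDockQ."""
    rows = [{
        "model_id": s.model_id,
        "chain_a": s.chain_pair[0],
        "chain_b": s.chain_pair[1],
        "n_contacts": s.n_contacts,
        "avg_interface_pae": s.avg_interface_pae,
        "avg_interface_plddt": s.avg_interface_plddt,
        "pdockq": s.pdockq,
    } for s in summaries]
    return pd.DataFrame(rows, columns=["model_id", "chain_a", "chain_b",
                                       "n_contacts", "avg_interface_pae",
                                       "avg_interface_plddt", "pdockq"])
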