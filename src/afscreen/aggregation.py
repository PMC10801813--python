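"""Cross-model agreement metrics for one candidate pair.

Each candidate pair is predicted by M models.  Contacts are compared across
models by their residue-pair key: ``avg_n_models`` is the mean, over all
unique contacts, of the number of models containing that contact, and
``max_n_models`` the maximum.  Both lie in [1, M] whenever any contact was
found; higher values mean the models agree on the interface.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactKey, ContactSet
from .interface_metrics import (DEFAULT_PDOCKQ, InterfaceSummary, PDockQParams,
                                interface_stats)

#: reductions available for the pair-level representative metrics
PAIR_REDUCTIONS = ("best", "mean")


@dataclass
class PairAggregate:
    """Cross-model summary of one candidate pair.

    ``avg_n_models``/``max_n_models`` are ``None`` when no model predicted
    any contact.  ``pdockq``, ``avg_interface_pae`` and
    ``avg_interface_plddt`` are the pair-level representatives under the
    chosen reduction ("best": most confident model per metric; "mean": mean
    over models with a non-empty interface).
    """

    pair_id: str
    n_models: int
    chain_pair: tuple[str, str]
    n_unique_contacts: int
    avg_n_models: float | None
    max_n_models: int | None
    pdockq: float
    avg_interface_pae: float | None
    avg_interface_plddt: float | None
    per_model: list[InterfaceSummary]
    contact_counts: dict[ContactKey, int] = field(default_factory=dict)
    reduction: str = "best"

    @property
    def best_pdockq(self) -> float:
        return max((s.pdockq for s in self.per_model), default=0.0)

    @property
    def best_avg_interface_pae(self) -> float | None:
        vals = [s.avg_interface_pae for s in self.per_model
                if s.avg_interface_pae is not None]
        return min(vals) if vals else None


def aggregate(contact_sets: list[ContactSet], pair_id: str = "",
              pdockq_params: PDockQParams = DEFAULT_PDOCKQ,
              reduction: str = "best") -> PairAggregate:
    """Combine one pair's per-model contact sets into a PairAggregate.

    All contact sets must concern the same chain pair and carry contacts
    computed with identical thresholds.  Models with zero contacts
    contribute no counts but still count toward M.
    """
    if not contact_sets:
        raise ValueError("at least one model required")
    if reduction not in PAIR_REDUCTIONS:
        raise ValueError(f"reduction must be one of {PAIR_REDUCTIONS}")
    chain_pair = contact_sets[0].chain_pair
    for cs in contact_sets:
        if cs.chain_pair != chain_pair:
            raise ValueError(
                f"inconsistent chain pairs across models: "
                f"{cs.chain_pair} vs {chain_pair}")

    counts: Counter[ContactKey] = Counter()
    for cs in contact_sets:
        counts.update(cs.keys)

    summaries = [interface_stats(cs, pdockq_params) for cs in contact_sets]
    nonempty = [s for s in summaries if s.n_contacts > 0]

    if counts:
        avg_n = float(np.mean(list(counts.values())))
        max_n = int(max(counts.values()))
    else:
        avg_n = max_n = None

    if not nonempty:
        rep_pdockq, rep_pae, rep_plddt = 0.0, None, None
    elif reduction == "best":
        rep_pdockq = max(s.pdockq for s in nonempty)
        rep_pae = min(s.avg_interface_pae for s in nonempty)
        rep_plddt = max(s.avg_interface_plddt for s in nonempty)
    else:
        rep_pdockq = float(np.mean([s.pdockq for s in nonempty]))
        rep_pae = float(np.mean([s.avg_interface_pae for s in nonempty]))
        rep_plddt = float(np.mean([s.avg_interface_plddt for s in nonempty]))

    return PairAggregate(
        pair_id=pair_id,
        n_models=len(contact_sets),
        chain_pair=chain_pair,
        n_unique_contacts=len(counts),
        avg_n_models=avg_n,
        max_n_models=max_n,
        pdockq=rep_pdockq,
        avg_interface_pae=rep_pae,
        avg_interface_plddt=rep_plddt,
        per_model=summaries,
        contact_counts=dict(counts),
        reduction=reduction,
    )


def best_of(agg: PairAggregate, metric: str) -> tuple[str, float] | None:
    """The optimal model for one metric: max for pdockq/avg_interface_plddt,
    min for avg_interface_pae.  Ties break to the lowest model_id.  ``None``
    when every model is contactless."""
    directions = {"pdockq": 1, "avg_interface_plddt": 1, "avg_interface_pae": -1}
    if metric not in directions:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(directions)}")
    sign = directions[metric]
    candidates = [(getattr(s, metric), s.model_id) for s in agg.per_model
                  if s.n_contacts > 0]
    if not candidates:
        return None
    value, model_id = max(candidates, key=lambda vm: (sign * vm[0], _neg_str(vm[1])))
    return model_id, value


class _neg_str(str):
    """Reverses string comparison so max() tie-breaks to the lowest id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
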