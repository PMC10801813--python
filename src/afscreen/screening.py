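"""Candidate tables, proteome input filters, and the screen ranking protocol.

Candidate pairs are sorted lexicographically by avg_n_models (descending),
pdockq (descending) and avg_interface_pae (ascending) and assigned a 1-based
rank; remaining ties break on the partner identifier so the ordering is
total and input-order invariant.  A binary annotation flag (e.g. STRING
database membership) can be prepended as the primary sort key for
re-ranking.  Pairs with no contacts in any model carry no metrics and sink
below every pair with metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .aggregation import PairAggregate

logger = logging.getLogger(__name__)

#: the screen sort protocol, in key order
SORT_SPEC = ("avg_n_models desc", "pdockq desc", "avg_interface_pae asc",
             "partner_id asc")

TABLE_COLUMNS = ["rank", "partner_id", "avg_n_models", "max_n_models",
                 "pdockq", "avg_interface_pae", "avg_interface_plddt",
                 "n_unique_contacts", "in_STRING_db"]


@dataclass(frozen=True)
class CandidateRow:
    """One candidate partner with its cross-model aggregate and optional
    annotation flag (1 = present in the annotation set)."""

    partner_id: str
    aggregate: PairAggregate
    partner_name: str | None = None
    in_string_db: int | None = None

    def __post_init__(self) -> None:
        if self.in_string_db not in (None, 0, 1):
            raise ValueError("in_string_db must be 0, 1 or None")

    @property
    def has_metrics(self) -> bool:
        return self.aggregate.n_unique_contacts > 0


@dataclass(frozen=True)
class RankedTable:
    """Rows in rank order (1..N, no gaps) under ``sort_spec``."""

    rows: tuple[CandidateRow, ...]
    sort_spec: tuple[str, ...] = SORT_SPEC

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def rank_of(self, partner_id: str) -> int | None:
        for rank, row in enumerate(self.rows, start=1):
            if row.partner_id == partner_id:
                return rank
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, row in enumerate(self.rows, start=1):
            agg = row.aggregate
            rows.append({
                "rank": rank,
                "partner_id": row.partner_id,
                "avg_n_models": agg.avg_n_models,
                "max_n_models": agg.max_n_models,
                "pdockq": agg.pdockq,
                "avg_interface_pae": agg.avg_interface_pae,
                "avg_interface_plddt": agg.avg_interface_plddt,
                "n_unique_contacts": agg.n_unique_contacts,
                "in_STRING_db": row.in_string_db,
            })
        df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
        for col in ("rank", "max_n_models", "n_unique_contacts", "in_STRING_db"):
            df[col] = df[col].astype("Int64")
        return df


def _metric_key(row: CandidateRow) -> tuple:
    """Sort key implementing the screen protocol with missing-value sinking:
    undefined avg_n_models/pdockq act as -inf, undefined pae as +inf."""
    agg = row.aggregate
    avg_n = agg.avg_n_models if agg.avg_n_models is not None else -math.inf
    pdq = agg.pdockq if row.has_metrics else -math.inf
    pae = (agg.avg_interface_pae if agg.avg_interface_pae is not None
           else math.inf)
    return (-avg_n, -pdq, pae, row.partner_id)


def rank_candidates(rows: Sequence[CandidateRow]) -> RankedTable:
    """Sort candidates by avg_n_models desc, pdockq desc, avg_interface_pae
    asc (ties on partner_id asc) and assign ranks 1..N."""
    ids = [r.partner_id for r in rows]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate partner_id in candidate rows: {sorted(dupes)}")
    ordered = sorted(rows, key=_metric_key)
    return RankedTable(rows=tuple(ordered))


def rerank_with_annotation(table: RankedTable,
                           annotated_ids: Iterable[str]) -> RankedTable:
    """Flag rows whose partner is in ``annotated_ids`` (in_string_db = 1,
    else 0) and re-sort with the flag as the primary, descending key,
    followed by the usual metric keys."""
    annotated = set(annotated_ids)
    present = {row.partner_id for row in table}
    for missing in sorted(annotated - present):
        logger.info("annotated id %s not present in the candidate table", missing)
    flagged = [replace(row, in_string_db=int(row.partner_id in annotated))
               for row in table]
    ordered = sorted(flagged, key=lambda r: (-r.in_string_db, *_metric_key(r)))
    return RankedTable(rows=tuple(ordered),
                       sort_spec=("in_STRING_db desc",) + SORT_SPEC)


@dataclass(frozen=True)
class TopKReport:
    """The top-k block of a ranked table plus membership lookups."""

    k: int
    top_rows: tuple[CandidateRow, ...]
    found: dict[str, int]        # id -> rank, for ids within the top k
    outside: dict[str, int]      # id -> rank, for ids present but below k
    not_found: tuple[str, ...]   # ids absent from the table


def top_k_report(table: RankedTable, k: int,
                 must_include: Iterable[str] = ()) -> TopKReport:
    """Return the top-k rows and report, for each queried identifier,
    whether it falls within the top k and at what rank."""
    if not 1 <= k <= len(table):
        raise ValueError(f"k must be in [1, {len(table)}], got {k}")
    found, outside, missing = {}, {}, []
    for pid in must_include:
        rank = table.rank_of(pid)
        if rank is None:
            missing.append(pid)
        elif rank <= k:
            found[pid] = rank
        else:
            outside[pid] = rank
    return TopKReport(k=k, top_rows=table.rows[:k], found=found,
                      outside=outside, not_found=tuple(missing))


def filter_proteome(source: str | Path | Iterable[SeqRecord],
                    min_len: int = 15, max_len: int = 3034,
                    ) -> tuple[list[SeqRecord], list[tuple[str, str]]]:
    """Apply the proteome-screen input filters to candidate sequences.

    Removes entries shorter than ``min_len`` or longer than ``max_len``
    residues (boundary lengths are kept) and exact-duplicate sequences
    (after uppercasing; first occurrence kept).  Returns the kept records
    and a removal log of (identifier, reason).
    """
    if isinstance(source, (str, Path)):
        records = list(SeqIO.parse(str(source), "fasta"))
    else:
        records = list(source)
    if not records:
        logger.warning("proteome filter: empty input")
        return [], []
    kept: list[SeqRecord] = []
    removed: list[tuple[str, str]] = []
    seen: dict[str, str] = {}
    for rec in records:
        n = len(rec.seq)
        seq = str(rec.seq).upper()
        if n < min_len:
            removed.append((rec.id, f"too short ({n} < {min_len} residues)"))
        elif n > max_len:
            removed.append((rec.id, f"too long ({n} > {max_len} residues)"))
        elif seq in seen:
            removed.append((rec.id, f"redundant sequence (duplicate of {seen[seq]})"))
        else:
            seen[seq] = rec.id
            kept.append(rec)
    return kept, removed
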