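"""Rare-ESV filtering, dual-database consensus taxonomy, rank aggregation.

The rare-ESV rule removes sequence variants whose total read count over all
samples falls below ``floor(grand_total * rel_threshold)`` (default 1e-5, the
"one in 10^5" rule). Consensus lineages come from two independent per-rank
classifications: if the genus calls agree, the primary database's full lineage
is used; otherwise the primary lineage is truncated at the deepest rank whose
bootstrap confidence clears the threshold (default 0.80).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, TableParseError

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


def filter_rare_esvs(
    count_table: pd.DataFrame, rel_threshold: float = 1e-5
) -> tuple[pd.DataFrame, int]:
    """Drop ESVs with total reads below the relative-abundance cutoff.

    Returns ``(filtered_table, cutoff)`` where ``cutoff = floor(grand_total *
    rel_threshold)``; an ESV is removed when its total is strictly below the
    cutoff (ESVs exactly at the cutoff are kept).
    """
    if count_table is None or count_table.size == 0:
        raise DegenerateInputError("empty count table")
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    totals = count_table.sum(axis=0)
    grand = int(totals.sum())
    cutoff = int(np.floor(grand * rel_threshold))
    keep = totals >= cutoff
    return count_table.loc[:, keep], cutoff


@dataclass
class ConsensusLineage:
    esv_id: str
    labels: dict = field(default_factory=dict)  # rank -> label ('' below cut)
    assignment_rank: str | None = None
    rule_used: str = "confidence_fallback"  # genus_agreement | confidence_fallback

    def as_row(self) -> dict:
        return {
            "esv_id": self.esv_id,
            **{r: self.labels.get(r, "") for r in RANKS},
            "assignment_rank": self.assignment_rank or "",
            "rule_used": self.rule_used,
        }


def consensus_assign(primary_rec, secondary_rec, conf_threshold: float = 0.80) -> ConsensusLineage:
    """Consensus lineage for one ESV from its two database records.

    Each record is a mapping with ``esv_id``, per-rank labels, and per-rank
    ``<rank>_conf`` bootstrap confidences for the primary record.
    """
    p, s = dict(primary_rec), dict(secondary_rec)
    if p["esv_id"] != s["esv_id"]:
        raise TableParseError(f"esv_id mismatch: {p['esv_id']} vs {s['esv_id']}")
    esv = p["esv_id"]

    g1 = str(p.get("genus") or "").strip()
    g2 = str(s.get("genus") or "").strip()
    if g1 and g2 and g1.lower() == g2.lower():
        labels = {r: str(p.get(r) or "").strip() for r in RANKS}
        return ConsensusLineage(esv, labels, "genus", "genus_agreement")

    deepest = None
    for r in RANKS:  # deepest rank with confidence >= threshold
        conf = float(p.get(f"{r}_conf", 0.0) or 0.0)
        if conf >= conf_threshold and str(p.get(r) or "").strip():
            deepest = r
    if deepest is None:
        return ConsensusLineage(esv, {}, None, "confidence_fallback")
    labels = {}
    for r in RANKS:
        labels[r] = str(p.get(r) or "").strip()
        if r == deepest:
            break
    return ConsensusLineage(esv, labels, deepest, "confidence_fallback")


def consensus_table(
    primary: pd.DataFrame, secondary: pd.DataFrame, conf_threshold: float = 0.80
) -> pd.DataFrame:
    """Vector version of :func:`consensus_assign` over two taxonomy tables."""
    s = secondary.set_index("esv_id")
    rows = []
    for rec in primary.to_dict("records"):
        if rec["esv_id"] not in s.index:
            raise TableParseError(f"esv {rec['esv_id']} missing from secondary table")
        sec = {"esv_id": rec["esv_id"], **s.loc[rec["esv_id"]].to_dict()}
        rows.append(consensus_assign(rec, sec, conf_threshold).as_row())
    return pd.DataFrame(rows)


def aggregate_by_rank(
    count_table: pd.DataFrame, lineages: pd.DataFrame, rank: str
) -> tuple[pd.DataFrame, int]:
    """Sum ESV counts into taxa at ``rank``; unassigned ESVs are dropped.

    ``lineages`` must carry ``esv_id`` and a column per rank (empty string =
    unassigned at that rank). Returns ``(rank_table, dropped_reads)`` with
    columns in lexicographic order; the dropped-read total preserves the
    read-conservation audit: rank grand total + dropped = input grand total.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    lab = lineages.set_index("esv_id")[rank].reindex(count_table.columns)
    if lab.isna().any():
        missing = list(count_table.columns[lab.isna()])[:5]
        raise TableParseError(f"ESVs without lineage records, e.g. {missing}")
    lab = lab.astype(str).str.strip()
    assigned = lab != ""
    dropped = int(count_table.loc[:, ~assigned.to_numpy()].to_numpy().sum())
    kept = count_table.loc[:, assigned.to_numpy()]
    out = kept.T.groupby(lab[assigned].to_numpy()).sum().T
    out = out.loc[:, sorted(out.columns)]
    out.index.name = count_table.index.name
    return out, dropped
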