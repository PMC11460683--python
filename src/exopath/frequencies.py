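"""Metabolite exchange frequencies over pattern collections.

The exchange frequency of a (metabolite, direction) item is the fraction
of enumerated pathways (unique patterns, growth-supporting by default in
the headline tables) that include it: f = 1 marks an essential exchange,
f = 0 one that never occurs.  For community models, interaction
frequencies count the pathways in which a metabolite is produced by one
member and consumed by another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patterns import Item, PatternCollection

__all__ = [
    "FrequencyTable",
    "exchange_frequency",
    "frequency_difference",
    "pairwise_frequency",
    "interaction_frequency",
]


@dataclass
class FrequencyTable:
    definition: str
    denominator: int
    table: pd.DataFrame  # entity, direction, count, frequency

    def lookup(self, entity: str, direction: str) -> float:
        t = self.table
        row = t[(t.entity == entity) & (t.direction == direction)]
        return float(row.frequency.iloc[0]) if len(row) else 0.0


def exchange_frequency(coll: PatternCollection) -> FrequencyTable:
    """Fraction of patterns including each (entity, direction) item.

    Every item of the subnetwork universe gets a row, including explicit
    zeros for exchanges that occur in no pattern.
    """
    if coll.count == 0:
        raise ValueError("empty pattern collection")
    counts = {item: 0 for item in coll.universe}
    for p in coll.patterns:
        for item in p.items:
            counts[item] = counts.get(item, 0) + 1
    rows = [
        {
            "entity": e,
            "direction": d,
            "count": c,
            "frequency": c / coll.count,
        }
        for (e, d), c in sorted(counts.items())
    ]
    return FrequencyTable(
        definition=coll.definition,
        denominator=coll.count,
        table=pd.DataFrame(rows, columns=["entity", "direction", "count", "frequency"]),
    )


def frequency_difference(a: FrequencyTable, b: FrequencyTable) -> pd.DataFrame:
    """Signed differences f_a − f_b, sorted by absolute difference.

    Reported both as fractions and percentage points (1 decimal).
    """
    ka = a.table.set_index(["entity", "direction"])
    kb = b.table.set_index(["entity", "direction"])
    if set(ka.index) != set(kb.index):
        raise ValueError("frequency tables cover different item universes")
    diff = (ka.frequency - kb.frequency).reset_index()
    diff.columns = ["entity", "direction", "difference"]
    diff["percentage_points"] = (100 * diff.difference).round(1)
    diff = diff.reindex(
        diff.difference.abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    return diff


def pairwise_frequency(coll: PatternCollection) -> pd.DataFrame:
    """Symmetric matrix of co-occurrence fractions over items.

    Entry (i, j) is the fraction of patterns containing both items; the
    diagonal equals the marginal exchange frequency.
    """
    if coll.count == 0:
        raise ValueError("empty pattern collection")
    items = sorted(coll.universe)
    index = {it: k for k, it in enumerate(items)}
    M = np.zeros((len(items), len(items)))
    for p in coll.patterns:
        present = [index[i] for i in p.items if i in index]
        for i in present:
            for j in present:
                M[i, j] += 1
    M /= coll.count
    labels = [f"{e}:{d}" for e, d in items]
    return pd.DataFrame(M, index=labels, columns=labels)


def _split_member(entity: str):
    if "::" in entity:
        member, met = entity.split("::", 1)
        return member, met
    return None, entity


def interaction_frequency(
    coll: PatternCollection, include_zeros: bool = False
) -> pd.DataFrame:
    """Producer → consumer exchange frequencies in a community model.

    A pattern contributes to (producer, consumer, metabolite) when the
    producer member exports the metabolite to the shared compartment and
    a different consumer member imports it within the same pattern.
    """
    members_items = [it for it in coll.universe if "::" in it[0]]
    if not members_items:
        raise ValueError("collection does not carry member-qualified entities")
    if coll.count == 0:
        raise ValueError("empty pattern collection")
    counts: dict[tuple[str, str, str], int] = {}
    for p in coll.patterns:
        producers, consumers = set(), set()
        for entity, direction in p.items:
            member, met = _split_member(entity)
            if member is None:
                continue
            (producers if direction == "export" else consumers).add((member, met))
        for pm, met in producers:
            for cm, cmet in consumers:
                if met == cmet and pm != cm:
                    counts[(pm, cm, met)] = counts.get((pm, cm, met), 0) + 1
    if include_zeros:
        members = sorted({_split_member(e)[0] for e, _ in members_items})
        mets = sorted({_split_member(e)[1] for e, _ in members_items})
        for pm in members:
            for cm in members:
                if pm == cm:
                    continue
                for met in mets:
                    counts.setdefault((pm, cm, met), 0)
    rows = [
        {
            "producer": pm,
            "consumer": cm,
            "metabolite": met,
            "count": c,
            "frequency": c / coll.count,
        }
        for (pm, cm, met), c in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["producer", "consumer", "metabolite", "count", "frequency"]
    )
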