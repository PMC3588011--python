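"""Reads-per-million normalisation and salt-response categories.

Counts are normalised to RPM against each library's clean-read total
(count / total x 10^6), and every miRNA is placed in one of five
categories from its two RPM values: up- or down-regulated at least
``fold_threshold``-fold (default 2), unchanged, or exclusive to one
library.  Exclusivity is decided on raw counts (a literal zero), not RPM,
to avoid floating-point artifacts.  No count-model significance test is
applied: the classification is fold-change based by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

UP = "up>=2"
DOWN = "down>=2"
UNCHANGED = "unchanged"
CATEGORIES = [UP, DOWN, UNCHANGED]   # plus the two <lib>_only labels


def normalize(count: int, library_total: int) -> float:
    """RPM: count / clean-read total x 10^6, full float precision."""
    if library_total <= 0:
        raise ValueError("library clean-read total must be positive")
    return count / library_total * 1_000_000


@dataclass
class ExpressionRecord:
    """Counts, RPM, fold change and category for one miRNA."""

    mirna_id: str
    raw: dict[str, int]
    rpm: dict[str, float]
    fold_change: float           # rpm[treated] / rpm[control]; inf if control 0
    category: str
    provenance: str = ""

    @property
    def max_rpm(self) -> float:
        return max(self.rpm.values())


def classify(raw: dict[str, int], rpm: dict[str, float],
             control: str, treated: str, fold_threshold: float = 2.0,
             strict: bool = False) -> str:
    """Category from the two libraries' counts and RPM.

    Library-exclusive classes fire on raw counts; otherwise the RPM ratio
    treated/control decides: ``up>=2`` at >= threshold (or > with
    ``strict``), ``down>=2`` at <= 1/threshold, else ``unchanged``.  The
    classification is symmetric under swapping the libraries.  Records with
    both counts zero cannot be classified.
    """
    c, t = raw[control], raw[treated]
    if c == 0 and t == 0:
        raise ValueError("both counts zero; record should be dropped")
    if t == 0:
        return f"{control}_only"
    if c == 0:
        return f"{treated}_only"
    ratio = rpm[treated] / rpm[control]
    if (ratio > fold_threshold) if strict else (ratio >= fold_threshold):
        return UP
    if (ratio < 1 / fold_threshold) if strict else (ratio <= 1 / fold_threshold):
        return DOWN
    return UNCHANGED


def build_records(counts: dict[str, dict[str, int]],
                  library_totals: dict[str, int],
                  control: str, treated: str,
                  fold_threshold: float = 2.0, strict: bool = False,
                  provenance: dict[str, str] | None = None,
                  ) -> tuple[list[ExpressionRecord], list[str]]:
    """Expression records for {mirna_id: {library: count}}.

    Returns the records plus ids dropped because both counts were zero.
    """
    records: list[ExpressionRecord] = []
    dropped: list[str] = []
    for mid in sorted(counts):
        raw = {lib: counts[mid].get(lib, 0) for lib in (control, treated)}
        if raw[control] == 0 and raw[treated] == 0:
            dropped.append(mid)
            continue
        rpm = {lib: normalize(raw[lib], library_totals[lib])
               for lib in (control, treated)}
        fold = (rpm[treated] / rpm[control]) if rpm[control] > 0 else math.inf
        cat = classify(raw, rpm, control, treated, fold_threshold, strict)
        records.append(ExpressionRecord(
            mirna_id=mid, raw=raw, rpm=rpm, fold_change=fold, category=cat,
            provenance=(provenance or {}).get(mid, "")))
    return records, dropped


def summarize(records: list[ExpressionRecord], top_n: int = 9,
              high_rpm: float = 0.0) -> dict:
    """Category tallies and the top-N abundance table.

    Ordering is deterministic: max RPM descending, id ascending on ties.
    Category tallies conserve the record count.  ``high_rpm`` marks the
    "highly expressed" tier in the table when positive.
    """
    tally = {}
    for rec in records:
        tally[rec.category] = tally.get(rec.category, 0) + 1
    ranked = sorted(records, key=lambda r: (-r.max_rpm, r.mirna_id))
    top = [{"mirna_id": r.mirna_id, "max_rpm": round(r.max_rpm, 2),
            "category": r.category,
            **({"highly_expressed": r.max_rpm > high_rpm} if high_rpm else {})}
           for r in ranked[:top_n]]
    return {"n_records": len(records),
            "categories": dict(sorted(tally.items())),
            "top": top}


def to_frame(records: list[ExpressionRecord], libraries: list[str]) -> pd.DataFrame:
    """Tabular export; RPM rendered at 2 decimals in reports."""
    rows = []
    for r in sorted(records, key=lambda r: r.mirna_id):
        row = {"mirna_id": r.mirna_id, "provenance": r.provenance}
        for lib in libraries:
            row[f"count_{lib}"] = r.raw.get(lib, 0)
        for lib in libraries:
            row[f"rpm_{lib}"] = round(r.rpm.get(lib, 0.0), 2)
        row["fold_change"] = ("inf" if math.isinf(r.fold_change)
                              else round(r.fold_change, 3))
        row["category"] = r.category
        rows.append(row)
    return pd.DataFrame(rows)
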