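"""Two-database consensus taxonomy with confidence tiers.

Assignments from a primary reference database (e.g. RDP) and a secondary one
(e.g. SILVA or UNITE) are merged per ASV at the genus level:

* high   - both databases name the same genus (primary lineage kept)
* medium - both name a genus but disagree (primary preferred, conflict kept)
* low    - exactly one database names a genus (that lineage kept)
* unassigned - neither names a genus (deepest assigned prefix retained)

Genus comparison is case-insensitive exact string equality after
canonicalization; "Candidatus " prefixes are stripped before comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (RANKS, UNASSIGNED, AsvTable, TaxonomyTable,
                         comparable_genus)

CONFIDENCE_TIERS = ("high", "medium", "low", "unassigned")


@dataclass
class ConsensusTaxonomy:
    """Merged per-ASV taxonomy plus tier bookkeeping."""

    assignments: pd.DataFrame   # ranks + confidence, source, alternative_genus
    primary_db: str
    secondary_db: str
    rank_conflicts: list[str] = field(default_factory=list)  # asv ids with above-genus conflict

    @property
    def asv_ids(self) -> list[str]:
        return list(self.assignments.index)

    @property
    def n_asvs(self) -> int:
        return len(self.assignments)

    def tier_counts(self) -> dict[str, int]:
        vc = self.assignments["confidence"].value_counts()
        return {t: int(vc.get(t, 0)) for t in CONFIDENCE_TIERS}

    def tier_fractions(self) -> dict[str, float]:
        n = self.n_asvs
        return {t: c / n for t, c in self.tier_counts().items()}

    def unassigned_at_genus(self) -> int:
        return int((self.assignments["genus"] == UNASSIGNED).sum())

    def to_dict(self) -> dict:
        return {
            "primary_db": self.primary_db,
            "secondary_db": self.secondary_db,
            "n_asvs": self.n_asvs,
            "tier_counts": self.tier_counts(),
            "tier_fractions": self.tier_fractions(),
            "unassigned_at_genus": self.unassigned_at_genus(),
            "rank_conflicts": list(self.rank_conflicts),
            "assignments": {a: row.to_dict()
                            for a, row in self.assignments.iterrows()},
        }

    def to_frame(self) -> pd.DataFrame:
        return self.assignments


def _deepest_prefix(row: pd.Series | None, ranks: Sequence[str]) -> dict[str, str]:
    out = {r: UNASSIGNED for r in ranks}
    if row is not None:
        for r in ranks:
            out[r] = row.get(r, UNASSIGNED)
    return out


def merge_assignments(tax_primary: TaxonomyTable, tax_secondary: TaxonomyTable,
                      asv_ids: Sequence[str] | None = None) -> ConsensusTaxonomy:
    """Merge two databases' assignments over ``asv_ids`` (defaults to the union).

    The primary database's annotation wins whenever it names a genus; the
    secondary database fills in where the primary has no genus-level call.
    ASVs absent from both tables become unassigned with a warning.
    """
    ranks = [r for r in RANKS[:-1]]  # species carried separately, never consulted
    if asv_ids is None:
        asv_ids = sorted(set(tax_primary.asv_ids) | set(tax_secondary.asv_ids))
    missing = [a for a in asv_ids
               if a not in tax_primary.assignments.index
               and a not in tax_secondary.assignments.index]
    if missing:
        warnings.warn(f"{len(missing)} ASV(s) absent from both taxonomy tables; "
                      "treated as unassigned")

    prim = tax_primary.assignments
    sec = tax_secondary.assignments
    records = []
    conflicts = []
    for asv in asv_ids:
        p_row = prim.loc[asv] if asv in prim.index else None
        s_row = sec.loc[asv] if asv in sec.index else None
        g_p = p_row["genus"] if p_row is not None else UNASSIGNED
        g_s = s_row["genus"] if s_row is not None else UNASSIGNED
        has_p, has_s = g_p != UNASSIGNED, g_s != UNASSIGNED
        alternative = ""
        if has_p and has_s:
            if comparable_genus(g_p) == comparable_genus(g_s):
                confidence, source, chosen = "high", "both", p_row
            else:
                confidence, source, chosen = "medium", "primary_db", p_row
                alternative = g_s
        elif has_p:
            confidence, source, chosen = "low", "primary_db", p_row
        elif has_s:
            confidence, source, chosen = "low", "secondary_db", s_row
        else:
            confidence = "unassigned"
            if p_row is not None and (p_row[ranks[:-1]] != UNASSIGNED).any():
                source, chosen = "primary_db", p_row
            elif s_row is not None and (s_row[ranks[:-1]] != UNASSIGNED).any():
                source, chosen = "secondary_db", s_row
            else:
                source, chosen = "none", None
        lineage = _deepest_prefix(chosen, ranks)
        if (p_row is not None and s_row is not None
                and any(p_row.get(r, UNASSIGNED) != s_row.get(r, UNASSIGNED)
                        for r in ranks[:-1]
                        if p_row.get(r, UNASSIGNED) != UNASSIGNED
                        and s_row.get(r, UNASSIGNED) != UNASSIGNED)):
            conflicts.append(asv)
        records.append({"asv_id": asv, **lineage, "confidence": confidence,
                        "source": source, "alternative_genus": alternative})
    frame = pd.DataFrame.from_records(records).set_index("asv_id")
    return ConsensusTaxonomy(frame, tax_primary.source_db, tax_secondary.source_db,
                             conflicts)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class AssignmentStats:
    """Genus-level assignment rates per database and combined."""

    n_asvs: int
    unassigned_primary: int
    unassigned_secondary: int
    unassigned_combined: int
    primary_db: str
    secondary_db: str

    @property
    def pct_unassigned_primary(self) -> float:
        return 100.0 * self.unassigned_primary / self.n_asvs

    @property
    def pct_unassigned_secondary(self) -> float:
        return 100.0 * self.unassigned_secondary / self.n_asvs

    @property
    def pct_unassigned_combined(self) -> float:
        return 100.0 * self.unassigned_combined / self.n_asvs

    @property
    def pct_assigned_combined(self) -> float:
        return 100.0 - self.pct_unassigned_combined

    @property
    def assignment_gain(self) -> float:
        """Combined assigned % minus the better single database's assigned %."""
        best_single = 100.0 - min(self.pct_unassigned_primary,
                                  self.pct_unassigned_secondary)
        return self.pct_assigned_combined - best_single

    def to_dict(self) -> dict:
        return {
            "n_asvs": self.n_asvs,
            "primary_db": self.primary_db, "secondary_db": self.secondary_db,
            "unassigned_primary": self.unassigned_primary,
            "unassigned_secondary": self.unassigned_secondary,
            "unassigned_combined": self.unassigned_combined,
            "pct_unassigned_primary": self.pct_unassigned_primary,
            "pct_unassigned_secondary": self.pct_unassigned_secondary,
            "pct_unassigned_combined": self.pct_unassigned_combined,
            "pct_assigned_combined": self.pct_assigned_combined,
            "assignment_gain": self.assignment_gain,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def assignment_stats(consensus: ConsensusTaxonomy, tax_primary: TaxonomyTable,
                     tax_secondary: TaxonomyTable) -> AssignmentStats:
    """Unassigned-at-genus counts and percentages over the consensus ASV universe.

    An ASV missing from a single-database table counts as unassigned for that
    database; "assigned" means genus != UNASSIGNED after canonicalization.
    """
    ids = consensus.asv_ids
    n = len(ids)

    def n_unassigned(tax: TaxonomyTable) -> int:
        mask = tax.assigned_at_genus().reindex(ids).fillna(False)
        return int(n - mask.sum())

    return AssignmentStats(
        n_asvs=n,
        unassigned_primary=n_unassigned(tax_primary),
        unassigned_secondary=n_unassigned(tax_secondary),
        unassigned_combined=consensus.unassigned_at_genus(),
        primary_db=tax_primary.source_db,
        secondary_db=tax_secondary.source_db,
    )


@dataclass
class GenusOverlap:
    """Name-set overlap of genera between two databases (not per-ASV agreement)."""

    n_shared: int
    n_only_primary: int
    n_only_secondary: int
    shared: set[str]
    only_primary: set[str]
    only_secondary: set[str]

    def to_dict(self) -> dict:
        return {"n_shared": self.n_shared,
                "n_only_primary": self.n_only_primary,
                "n_only_secondary": self.n_only_secondary,
                "shared": sorted(self.shared),
                "only_primary": sorted(self.only_primary),
                "only_secondary": sorted(self.only_secondary)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{k: v for k, v in self.to_dict().items()
                              if isinstance(v, int)}])


def genus_overlap(tax_primary: TaxonomyTable, tax_secondary: TaxonomyTable) -> GenusOverlap:
    """Venn counts of unique genus names identified by each database."""
    g1, g2 = tax_primary.genus_names(), tax_secondary.genus_names()
    return GenusOverlap(
        n_shared=len(g1 & g2),
        n_only_primary=len(g1 - g2),
        n_only_secondary=len(g2 - g1),
        shared=g1 & g2, only_primary=g1 - g2, only_secondary=g2 - g1,
    )


def consistency_at_genus(tax_primary: TaxonomyTable, tax_secondary: TaxonomyTable,
                         table: AsvTable, top_n: int = 100) -> dict:
    """Fraction of ASVs with identical genus calls from both databases.

    Reported over all ASVs in the count table and over the ``top_n`` ASVs by
    whole-dataset read total (ties at the cutoff broken by ASV id).
    """
    ids = table.asv_ids
    g1 = tax_primary.genus().reindex(ids).fillna(UNASSIGNED)
    g2 = tax_secondary.genus().reindex(ids).fillna(UNASSIGNED)
    both = (g1 != UNASSIGNED) & (g2 != UNASSIGNED)
    agree = pd.Series(
        [comparable_genus(a) == comparable_genus(b) if ok else False
         for a, b, ok in zip(g1, g2, both)], index=ids)
    out = {"n_asvs": len(ids),
           "overall_fraction": float(agree.mean()),
           "n_co_assigned": int(both.sum()),
           "no_co_assigned_asvs": bool(both.sum() == 0)}
    totals = table.asv_totals()
    order = sorted(ids, key=lambda a: (-totals[a], a))
    if top_n > len(ids):
        out["top_n_truncated_to"] = len(ids)
        top = order
    else:
        top = order[:top_n]
    out["top_n"] = len(top)
    out["top_n_fraction"] = float(agree.loc[top].mean())
    return out
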