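"""Cross-pipeline ASV matching, overlap statistics and the selection scorecard.

Two denoisers run on the same reads rarely emit identical ASV sets: shared
sequences are very likely true variants, while low-abundance exclusives are
candidate artefacts. The scorecard turns the metric suite plus overlap
structure into directional votes (significance-gated where a per-sample test
exists) and a selection verdict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, false_discovery_control, rankdata

from .community_metrics import (BetaSummary, CountSummary, DiversityProfile,
                                TestResult, beta_summary, diversity_profile,
                                mann_whitney, summarize_counts)
from .errors import ValidationError
from .io_formats import AsvTable, SampleMetadata

#: read-total bin edges for the exclusive-ASV histogram
_HIST_BINS = ((1, 1), (2, 10), (11, 100), (101, 500), (501, None))


# ---------------------------------------------------------------------------
# ASV matching and overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """Cross-pipeline ASV overlap; abundance fields filled by overlap_stats."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    pairs: list[tuple[str, str]]
    exclusive_a: list[str]
    exclusive_b: list[str]
    duplicates_a: dict[str, list[str]] = field(default_factory=dict)
    duplicates_b: dict[str, list[str]] = field(default_factory=dict)
    # filled by overlap_stats
    exclusive_totals_a: pd.Series | None = None
    exclusive_totals_b: pd.Series | None = None
    histogram_a: dict[str, int] | None = None
    histogram_b: dict[str, int] | None = None
    threshold_counts_a: dict[int, int] | None = None
    threshold_counts_b: dict[int, int] | None = None

    @property
    def n_shared(self) -> int:
        return len(self.pairs)

    @property
    def n_exclusive_a(self) -> int:
        return len(self.exclusive_a)

    @property
    def n_exclusive_b(self) -> int:
        return len(self.exclusive_b)

    @property
    def support_a_by_b(self) -> float:
        """Fraction of A's ASVs also present in B."""
        return self.n_shared / self.n_a

    @property
    def support_b_by_a(self) -> float:
        return self.n_shared / self.n_b

    def to_dict(self) -> dict:
        out = {
            "label_a": self.label_a, "label_b": self.label_b,
            "n_a": self.n_a, "n_b": self.n_b, "n_shared": self.n_shared,
            "n_exclusive_a": self.n_exclusive_a, "n_exclusive_b": self.n_exclusive_b,
            "support_a_by_b": self.support_a_by_b,
            "support_b_by_a": self.support_b_by_a,
        }
        if self.histogram_a is not None:
            out["exclusive_read_histogram_a"] = self.histogram_a
            out["exclusive_read_histogram_b"] = self.histogram_b
            out["exclusive_above_threshold_a"] = {str(k): v for k, v
                                                  in self.threshold_counts_a.items()}
            out["exclusive_above_threshold_b"] = {str(k): v for k, v
                                                  in self.threshold_counts_b.items()}
        return out

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        return pd.DataFrame([{k: v for k, v in d.items() if not isinstance(v, dict)}])

    def swapped(self) -> "OverlapResult":
        """The same overlap viewed with the pipelines exchanged."""
        return OverlapResult(
            label_a=self.label_b, label_b=self.label_a,
            n_a=self.n_b, n_b=self.n_a,
            pairs=sorted((b, a) for a, b in self.pairs),
            exclusive_a=list(self.exclusive_b), exclusive_b=list(self.exclusive_a),
            duplicates_a=self.duplicates_b, duplicates_b=self.duplicates_a,
            exclusive_totals_a=self.exclusive_totals_b,
            exclusive_totals_b=self.exclusive_totals_a,
            histogram_a=self.histogram_b, histogram_b=self.histogram_a,
            threshold_counts_a=self.threshold_counts_b,
            threshold_counts_b=self.threshold_counts_a,
        )


def _collapse_duplicates(seqs: Mapping[str, str], label: str):
    """Collapse identical sequences within one pipeline to the smallest id."""
    by_seq: dict[str, list[str]] = {}
    for asv_id in sorted(seqs):
        by_seq.setdefault(seqs[asv_id].upper(), []).append(asv_id)
    collapsed = {ids[0]: s for s, ids in by_seq.items()}   # id -> seq
    dup = {ids[0]: ids[1:] for ids in by_seq.values() if len(ids) > 1}
    if dup:
        warnings.warn(f"{label}: collapsed {sum(map(len, dup.values()))} duplicate "
                      f"sequence(s) onto representative ids")
    return collapsed, dup


def match_asvs(seqs_a: Mapping[str, str], seqs_b: Mapping[str, str],
               mode: str = "exact", min_overlap: int = 200,
               label_a: str = "A", label_b: str = "B") -> OverlapResult:
    """One-to-one sequence matching between two pipelines' ASV sets.

    ``exact`` matches on full-string equality (uppercased); ``prefix``
    additionally matches when one sequence is a prefix of the other with at
    least ``min_overlap`` nt of overlap. Prefix ties are broken by longest
    match, then lexicographic id.
    """
    if not seqs_a or not seqs_b:
        raise ValidationError("both pipelines must supply at least one sequence")
    a_map, dup_a = _collapse_duplicates(seqs_a, label_a)
    b_map, dup_b = _collapse_duplicates(seqs_b, label_b)

    b_by_seq = {s: i for i, s in b_map.items()}
    pairs: list[tuple[str, str]] = []
    matched_a, matched_b = set(), set()
    for a_id in sorted(a_map):
        b_id = b_by_seq.get(a_map[a_id])
        if b_id is not None and b_id not in matched_b:
            pairs.append((a_id, b_id))
            matched_a.add(a_id)
            matched_b.add(b_id)

    if mode == "prefix":
        cands = []
        for a_id in sorted(set(a_map) - matched_a):
            sa = a_map[a_id]
            for b_id in sorted(set(b_map) - matched_b):
                sb = b_map[b_id]
                short, long_ = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
                if len(short) >= min_overlap and long_.startswith(short):
                    cands.append((-len(short), a_id, b_id))
        for _, a_id, b_id in sorted(cands):
            if a_id not in matched_a and b_id not in matched_b:
                pairs.append((a_id, b_id))
                matched_a.add(a_id)
                matched_b.add(b_id)
    elif mode != "exact":
        raise ValueError(f"unknown match mode {mode!r}")

    return OverlapResult(
        label_a=label_a, label_b=label_b,
        n_a=len(a_map), n_b=len(b_map), pairs=sorted(pairs),
        exclusive_a=sorted(set(a_map) - matched_a),
        exclusive_b=sorted(set(b_map) - matched_b),
        duplicates_a=dup_a, duplicates_b=dup_b,
    )


def _histogram(totals: pd.Series) -> dict[str, int]:
    out = {}
    for lo, hi in _HIST_BINS:
        label = f"{lo}" if lo == hi else (f">{lo - 1}" if hi is None else f"{lo}-{hi}")
        mask = totals >= lo
        if hi is not None:
            mask &= totals <= hi
        out[label] = int(mask.sum())
    return out


def overlap_stats(matched: OverlapResult, table_a: AsvTable, table_b: AsvTable,
                  thresholds: Sequence[int] = (100, 500)) -> OverlapResult:
    """Fill abundance-derived overlap fields: exclusive-ASV whole-dataset read
    totals, their histogram, and counts above each read-total threshold."""
    tot_a = table_a.asv_totals().reindex(matched.exclusive_a).fillna(0).astype(int)
    tot_b = table_b.asv_totals().reindex(matched.exclusive_b).fillna(0).astype(int)
    matched.exclusive_totals_a = tot_a
    matched.exclusive_totals_b = tot_b
    matched.histogram_a = _histogram(tot_a)
    matched.histogram_b = _histogram(tot_b)
    matched.threshold_counts_a = {int(t): int((tot_a > t).sum()) for t in thresholds}
    matched.threshold_counts_b = {int(t): int((tot_b > t).sum()) for t in thresholds}
    return matched


# ---------------------------------------------------------------------------
# differential abundance (pluggable; Kruskal-Wallis + BH default)
# ---------------------------------------------------------------------------

def kruskal_wallis_pvalues(rel_abund: pd.DataFrame, locations: pd.Series) -> np.ndarray:
    """Vectorized Kruskal-Wallis p per ASV column, tie-corrected.

    Columns with all-identical values get p = 1 (no evidence either way).
    """
    mat = rel_abund.to_numpy(dtype=float)
    groups = locations.loc[rel_abund.index].to_numpy()
    labels, inv = np.unique(groups, return_inverse=True)
    k = labels.size
    n = mat.shape[0]
    ranks = rankdata(mat, axis=0)
    h = np.zeros(mat.shape[1])
    for g in range(k):
        sel = inv == g
        rg = ranks[sel].sum(axis=0)
        h += rg * rg / sel.sum()
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # per-column tie correction
    correction = np.ones(mat.shape[1])
    srt = np.sort(mat, axis=0)
    for j in range(mat.shape[1]):
        _, counts = np.unique(srt[:, j], return_counts=True)
        correction[j] = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    p = np.ones(mat.shape[1])
    ok = correction > 0
    p[ok] = chi2.sf(h[ok] / correction[ok], df=k - 1)
    return p


def differential_abundance_count(table: AsvTable, metadata: SampleMetadata,
                                 method: Callable[..., np.ndarray] | None = None,
                                 alpha: float = 0.05) -> int:
    """Number of ASVs whose abundance differs across locations after BH correction.

    The test operates on relative abundances of true samples only. ``method``
    is a plugin ``f(rel_abund, locations) -> p-values``; the default is
    per-ASV Kruskal-Wallis.
    """
    samples = [s for s in metadata.true_samples() if s in table.counts.index]
    locs = metadata.locations().loc[samples]
    counts_per_loc = locs.value_counts()
    usable = counts_per_loc[counts_per_loc >= 2]
    if len(usable) < 2:
        raise ValidationError(
            "differential abundance needs >=2 locations with >=2 samples each; "
            f"got {counts_per_loc.to_dict()}")
    keep = [s for s in samples if locs[s] in usable.index]
    sub = table.subset(samples=keep)
    nonzero = sub.sample_totals() > 0
    sub = sub.subset(samples=list(sub.counts.index[nonzero]))
    rel = sub.relative_abundance()
    pvals = (method or kruskal_wallis_pvalues)(rel, metadata.locations())
    pvals = np.clip(np.asarray(pvals, dtype=float), 0.0, 1.0)
    adjusted = false_discovery_control(pvals, method="bh")
    return int((adjusted < alpha).sum())


# ---------------------------------------------------------------------------
# scorecard
# ---------------------------------------------------------------------------

@dataclass
class PipelineMetrics:
    """Metric suite for one pipeline's ASV table, as fed to the scorecard."""

    label: str
    count_summary: CountSummary
    per_sample_reads: pd.Series
    diversity: DiversityProfile
    beta: BetaSummary
    n_diff_abundant: int
    diff_method: str = "kruskal-wallis+BH"


def pipeline_metrics(label: str, table: AsvTable, metadata: SampleMetadata,
                     alpha: float = 0.05,
                     diff_method: Callable[..., np.ndarray] | None = None) -> PipelineMetrics:
    """Compute the full per-pipeline metric suite on true samples + controls."""
    return PipelineMetrics(
        label=label,
        count_summary=summarize_counts(table),
        per_sample_reads=table.sample_totals(),
        diversity=diversity_profile(table),
        beta=beta_summary(table),
        n_diff_abundant=differential_abundance_count(table, metadata, method=diff_method,
                                                     alpha=alpha),
        diff_method="custom" if diff_method else "kruskal-wallis+BH",
    )


def default_tests(metrics_a: PipelineMetrics, metrics_b: PipelineMetrics,
                  exact_cutoff: int = 8) -> dict[str, TestResult]:
    """Mann-Whitney tests on per-sample distributions for the gated criteria."""
    return {
        "total_reads": mann_whitney(metrics_a.per_sample_reads.to_numpy(),
                                    metrics_b.per_sample_reads.to_numpy(),
                                    exact_cutoff=exact_cutoff),
        "alpha_diversity": mann_whitney(metrics_a.diversity.per_sample["D0"].to_numpy(),
                                        metrics_b.diversity.per_sample["D0"].to_numpy(),
                                        exact_cutoff=exact_cutoff),
    }


@dataclass
class CriterionRow:
    name: str
    value_a: float
    value_b: float
    prefer: str                 # "high" or "low"
    p_value: float | None       # None => descriptive criterion
    vote: str                   # label_a, label_b, or "tie"
    weight_applied: float

    def to_dict(self) -> dict:
        return {"criterion": self.name, "value_a": self.value_a,
                "value_b": self.value_b, "prefer": self.prefer,
                "p_value": self.p_value, "vote": self.vote,
                "weight": self.weight_applied}


@dataclass
class ScorecardReport:
    label_a: str
    label_b: str
    rows: list[CriterionRow]
    scores: dict[str, float]
    verdict: str                # label_a, label_b, or "indeterminate"
    rationale: list[str]
    alpha: float
    diff_method: str

    def to_dict(self) -> dict:
        return {
            "pipelines": [self.label_a, self.label_b],
            "alpha": self.alpha,
            "diff_abundance_method": self.diff_method,
            "criteria": [r.to_dict() for r in self.rows],
            "scores": self.scores,
            "verdict": self.verdict,
            "rationale": self.rationale,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.rows]).set_index("criterion")


#: (criterion name, preference direction, gating test key or None)
_CRITERIA = (
    ("total_reads", "high", "total_reads"),
    ("samples_completing", "high", None),
    ("alpha_diversity", "high", "alpha_diversity"),
    ("diff_abundant_asvs", "high", None),
    ("mutual_support", "high", None),
    ("low_abundance_exclusive_burden", "low", None),
)


def _criterion_values(name: str, ma: PipelineMetrics, mb: PipelineMetrics,
                      overlap: OverlapResult,
                      low_threshold: int) -> tuple[float, float]:
    if name == "total_reads":
        return ma.count_summary.total_reads, mb.count_summary.total_reads
    if name == "samples_completing":
        return (ma.count_summary.n_samples - len(ma.count_summary.zero_read_samples),
                mb.count_summary.n_samples - len(mb.count_summary.zero_read_samples))
    if name == "alpha_diversity":
        return (float(ma.diversity.per_sample["D0"].mean()),
                float(mb.diversity.per_sample["D0"].mean()))
    if name == "diff_abundant_asvs":
        return ma.n_diff_abundant, mb.n_diff_abundant
    if name == "mutual_support":
        return overlap.support_a_by_b, overlap.support_b_by_a
    if name == "low_abundance_exclusive_burden":
        if overlap.threshold_counts_a is None:
            return overlap.n_exclusive_a, overlap.n_exclusive_b
        t = min(overlap.threshold_counts_a)
        return (overlap.n_exclusive_a - overlap.threshold_counts_a[t],
                overlap.n_exclusive_b - overlap.threshold_counts_b[t])
    raise KeyError(name)


def build_scorecard(metrics_a: PipelineMetrics, metrics_b: PipelineMetrics,
                    overlap: OverlapResult,
                    tests: Mapping[str, TestResult] | None = None,
                    weights: Mapping[str, float] | None = None,
                    alpha: float = 0.05,
                    low_abundance_threshold: int = 100) -> ScorecardReport:
    """Assemble criterion votes into an aggregate score and a verdict.

    Criteria backed by a per-sample significance test vote with full weight
    only when p < alpha (tie otherwise); descriptive criteria vote with half
    weight. The verdict is the higher aggregate, ties broken by total reads.
    """
    la, lb = metrics_a.label, metrics_b.label
    if la == lb:
        raise ValidationError("pipelines must carry distinct labels")
    if metrics_a.label != overlap.label_a or metrics_b.label != overlap.label_b:
        raise ValidationError("overlap labels do not match the metric suites")
    tests = dict(tests or {})
    weights = dict(weights or {})
    rows: list[CriterionRow] = []
    scores = {la: 0.0, lb: 0.0}
    rationale: list[str] = []
    for name, prefer, gate in _CRITERIA:
        va, vb = _criterion_values(name, metrics_a, metrics_b, overlap,
                                   low_abundance_threshold)
        w = float(weights.get(name, 1.0))
        p = tests[gate].p_value if gate and gate in tests else None
        if va == vb:
            vote, w_applied = "tie", 0.0
        elif p is not None and p >= alpha:
            vote, w_applied = "tie", 0.0
            rationale.append(f"{name}: difference not significant (p={p:.3g})")
        else:
            better_is_a = (va > vb) if prefer == "high" else (va < vb)
            vote = la if better_is_a else lb
            w_applied = w if p is not None else 0.5 * w
            scores[vote] += w_applied
            gate_txt = f"p={p:.3g}" if p is not None else "descriptive, half weight"
            rationale.append(f"{name}: prefers {vote} ({gate_txt})")
        rows.append(CriterionRow(name, float(va), float(vb), prefer, p, vote, w_applied))

    if scores[la] > scores[lb]:
        verdict = la
    elif scores[lb] > scores[la]:
        verdict = lb
    else:
        ra, rb = metrics_a.count_summary.total_reads, metrics_b.count_summary.total_reads
        if ra > rb:
            verdict = la
            rationale.append("aggregate tie broken by total reads")
        elif rb > ra:
            verdict = lb
            rationale.append("aggregate tie broken by total reads")
        else:
            verdict = "indeterminate"
            rationale.append("aggregate tie; equal total reads; no basis for selection")
    return ScorecardReport(la, lb, rows, scores, verdict, rationale, alpha,
                           metrics_a.diff_method)
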