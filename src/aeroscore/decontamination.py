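"""Contaminant flagging and background subtraction, plus their comparator.

Two strategies are implemented as reference analogs of the removal-style and
subtraction-style families of decontamination tools:

* removal-style flags whole ASVs as contaminants from (i) over-representation
  in negative controls (one-sided Fisher exact on presence/absence), (ii)
  inverse rank correlation between relative abundance and sample DNA
  concentration, and (iii) their Fisher-method combination;
* subtraction-style estimates a background profile (mean relative abundance
  across negative controls), scales it by each sample's library size, and
  deducts it, flooring at zero.

The comparator cross-checks the two: contaminants flagged for removal but
untouched by subtraction above a read-total threshold are candidates for
outright deletion, as are ASVs prevalent in laboratory-only controls (which
never saw the sampled environment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom, spearmanr

from .community_metrics import beta_summary, diversity_profile
from .errors import ValidationError
from .io_formats import AsvTable, SampleMetadata


# ---------------------------------------------------------------------------
# removal-style scores
# ---------------------------------------------------------------------------

def prevalence_scores(table: AsvTable, metadata: SampleMetadata,
                      control_scope: str = "all_negative") -> pd.Series:
    """One-sided Fisher exact p per ASV for over-representation in controls.

    The 2x2 table is presence/absence in negative controls vs true samples;
    the p-value is the hypergeometric upper tail of the control-presence
    count. ASVs absent from all controls get p = 1, as do ASVs present in
    every sample (degenerate table).
    """
    controls = [s for s in metadata.negative_controls(control_scope)
                if s in table.counts.index]
    samples = [s for s in metadata.true_samples() if s in table.counts.index]
    if not controls:
        raise ValidationError(
            f"prevalence method needs >=1 negative control in scope {control_scope!r}")
    if not samples:
        raise ValidationError("prevalence method needs >=1 true sample")
    present = table.counts > 0
    a = present.loc[controls].sum(axis=0).to_numpy()       # present in controls
    c = present.loc[samples].sum(axis=0).to_numpy()        # present in samples
    n_ctrl, n_samp = len(controls), len(samples)
    # P(X >= a) with X ~ Hypergeom(M = all units, K = all presences, n = controls)
    p = hypergeom.sf(a - 1, n_ctrl + n_samp, a + c, n_ctrl)
    return pd.Series(np.clip(p, 0.0, 1.0), index=table.asv_ids, name="prevalence_p")


def frequency_scores(table: AsvTable, metadata: SampleMetadata,
                     min_presence: int = 5) -> pd.Series:
    """One-sided Spearman p per ASV for inverse abundance-concentration association.

    Computed across true samples with a recorded DNA concentration; ASVs
    present in fewer than ``min_presence`` of them get NaN (score absent).
    Raises when fewer than ``min_presence`` samples carry concentrations.
    """
    conc = metadata.frame["dna_concentration"]
    samples = [s for s in metadata.true_samples()
               if s in table.counts.index and pd.notna(conc.get(s))]
    if len(samples) < min_presence:
        raise ValidationError(
            f"frequency method needs >= {min_presence} true samples with DNA "
            f"concentrations; got {len(samples)}")
    sub = table.subset(samples=samples)
    rel = sub.relative_abundance()
    cvec = conc.loc[samples].to_numpy(dtype=float)
    out = pd.Series(np.nan, index=table.asv_ids, name="frequency_p")
    presence = (sub.counts > 0).sum(axis=0)
    for asv in table.asv_ids:
        if presence[asv] < min_presence:
            continue
        res = spearmanr(rel[asv].to_numpy(), cvec, alternative="less")
        out[asv] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return out


def combination_flags(prevalence_p: pd.Series, frequency_p: pd.Series,
                      threshold: float = 0.1) -> pd.DataFrame:
    """Fisher's method over the two scores where both exist, else pass-through.

    Returns a frame with columns prevalence_p, frequency_p, combined_p,
    flagged (combined_p < threshold). ASVs with neither score are unflagged
    with NaN combined_p.
    """
    idx = prevalence_p.index.union(frequency_p.index)
    pp = prevalence_p.reindex(idx)
    fp = frequency_p.reindex(idx)
    combined = pd.Series(np.nan, index=idx, name="combined_p")
    both = pp.notna() & fp.notna()
    if both.any():
        stat = -2.0 * (np.log(np.clip(pp[both], 1e-300, 1.0))
                       + np.log(np.clip(fp[both], 1e-300, 1.0)))
        combined[both] = chi2.sf(stat, df=4)
    only_p = pp.notna() & ~both
    only_f = fp.notna() & ~both
    combined[only_p] = pp[only_p]
    combined[only_f] = fp[only_f]
    flagged = combined.notna() & (combined < threshold)
    return pd.DataFrame({"prevalence_p": pp, "frequency_p": fp,
                         "combined_p": combined, "flagged": flagged})


# ---------------------------------------------------------------------------
# subtraction-style correction
# ---------------------------------------------------------------------------

@dataclass
class SubtractionResult:
    """Background-subtracted table (true samples only) with bookkeeping."""

    corrected: AsvTable
    reads_removed: pd.Series       # per ASV over the full input ASV universe
    profile: pd.Series             # per-ASV mean control relative abundance
    dropped_asvs: list[str]        # driven to zero in every sample

    def total_removed(self) -> int:
        return int(self.reads_removed.sum())

    def to_dict(self) -> dict:
        return {"n_samples": self.corrected.n_samples,
                "n_asvs": self.corrected.n_asvs,
                "total_reads_removed": self.total_removed(),
                "n_dropped_asvs": len(self.dropped_asvs),
                "dropped_asvs": list(self.dropped_asvs)}

    def to_frame(self) -> pd.DataFrame:
        return self.corrected.counts


def subtract_background(table: AsvTable, metadata: SampleMetadata,
                        control_scope: str = "all_negative") -> SubtractionResult:
    """Deduct the control-derived contamination profile from every true sample.

    profile = mean relative abundance across in-scope controls (zero-read
    controls are skipped with a warning); expected contaminant count in a
    sample = profile x library size, rounded half-up; corrected counts floor
    at zero. Control samples are excluded from the output and ASVs zeroed in
    every sample are dropped.
    """
    controls = [s for s in metadata.negative_controls(control_scope)
                if s in table.counts.index]
    if not controls:
        raise ValidationError(
            f"background subtraction needs >=1 negative control in scope {control_scope!r}")
    samples = [s for s in metadata.true_samples() if s in table.counts.index]
    if not samples:
        raise ValidationError("background subtraction needs >=1 true sample")
    ctrl = table.counts.loc[controls]
    totals = ctrl.sum(axis=1)
    live = totals[totals > 0].index
    if len(live) < len(controls):
        warnings.warn(f"{len(controls) - len(live)} zero-read control(s) skipped "
                      "when estimating the background profile")
    if len(live) == 0:
        profile = pd.Series(0.0, index=table.asv_ids)
    else:
        profile = (ctrl.loc[live].div(totals.loc[live], axis=0)).mean(axis=0)

    obs = table.counts.loc[samples]
    lib = obs.sum(axis=1).to_numpy(dtype=float)[:, None]
    expected = np.floor(lib * profile.to_numpy()[None, :] + 0.5)   # round half-up
    corrected = np.maximum(obs.to_numpy(dtype=float) - expected, 0.0)
    corr = pd.DataFrame(corrected.astype(np.int64), index=samples,
                        columns=table.asv_ids)
    removed = obs.sum(axis=0) - corr.sum(axis=0)
    kept = [a for a in table.asv_ids if corr[a].sum() > 0]
    dropped = [a for a in table.asv_ids if a not in kept]
    if not kept:
        raise ValidationError("background subtraction removed every ASV")
    return SubtractionResult(AsvTable(corr[kept]), removed.astype(np.int64),
                             profile, dropped)


# ---------------------------------------------------------------------------
# strategy comparator
# ---------------------------------------------------------------------------

@dataclass
class StrategyComparison:
    n_flagged_by_both: int
    n_flagged_removal_only: int
    n_adjusted_subtraction_only: int
    missed_high_abundance: list[str]
    laboratory_deletion_candidates: list[str]
    high_abundance_threshold: int
    metric_deltas: dict

    def to_dict(self) -> dict:
        return {
            "n_flagged_by_both": self.n_flagged_by_both,
            "n_flagged_removal_only": self.n_flagged_removal_only,
            "n_adjusted_subtraction_only": self.n_adjusted_subtraction_only,
            "missed_high_abundance": list(self.missed_high_abundance),
            "laboratory_deletion_candidates": list(self.laboratory_deletion_candidates),
            "high_abundance_threshold": self.high_abundance_threshold,
            "metric_deltas": self.metric_deltas,
        }

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        return pd.DataFrame([{k: v for k, v in d.items() if np.isscalar(v)}])


def compare_strategies(removal_flags: pd.Series, subtraction: SubtractionResult,
                       table: AsvTable, metadata: SampleMetadata,
                       high_abundance_threshold: int = 400,
                       prevalence_threshold: float = 0.1) -> StrategyComparison:
    """Cross-check whole-ASV removal against background subtraction.

    ``missed_high_abundance`` lists ASVs flagged for removal whose
    whole-dataset read total exceeds the threshold yet whose subtraction
    removed zero reads: the contaminants subtraction would silently keep.
    ``laboratory_deletion_candidates`` are ASVs prevalent in laboratory-only
    controls; these never saw the sampled environment and should be deleted
    outright rather than partially subtracted.
    """
    flags = removal_flags.reindex(table.asv_ids).fillna(False).astype(bool)
    removed = subtraction.reads_removed.reindex(table.asv_ids).fillna(0)
    adjusted = removed > 0
    totals = table.asv_totals()
    missed = sorted(a for a in table.asv_ids
                    if flags[a] and not adjusted[a]
                    and totals[a] > high_abundance_threshold)

    lab_candidates: list[str] = []
    if metadata.negative_controls("laboratory_only"):
        lab_p = prevalence_scores(table, metadata, control_scope="laboratory_only")
        lab_candidates = sorted(lab_p.index[lab_p < prevalence_threshold])

    before_div = diversity_profile(table.subset(samples=[
        s for s in metadata.true_samples() if s in table.counts.index]))
    after_div = diversity_profile(subtraction.corrected)
    deltas = {
        "mean_D0_before": float(before_div.per_sample["D0"].mean()),
        "mean_D0_after": float(after_div.per_sample["D0"].mean()),
        "mean_D1_before": float(before_div.per_sample["D1"].mean()),
        "mean_D1_after": float(after_div.per_sample["D1"].mean()),
        "mean_D2_before": float(before_div.per_sample["D2"].mean()),
        "mean_D2_after": float(after_div.per_sample["D2"].mean()),
    }
    try:
        bc_before = beta_summary(table.subset(samples=[
            s for s in metadata.true_samples() if s in table.counts.index]))
        bc_after = beta_summary(subtraction.corrected)
        deltas["bc_mean_before"] = bc_before.to_dict().get("mean")
        deltas["bc_mean_after"] = bc_after.to_dict().get("mean")
    except Exception:   # < 2 usable samples: deltas stay alpha-only
        pass

    return StrategyComparison(
        n_flagged_by_both=int((flags & adjusted).sum()),
        n_flagged_removal_only=int((flags & ~adjusted).sum()),
        n_adjusted_subtraction_only=int((adjusted & ~flags).sum()),
        missed_high_abundance=missed,
        laboratory_deletion_candidates=lab_candidates,
        high_abundance_threshold=high_abundance_threshold,
        metric_deltas=deltas,
    )


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class ContaminationResult:
    scores: pd.DataFrame                 # prevalence_p, frequency_p, combined_p, flagged
    subtraction: SubtractionResult
    comparison: StrategyComparison
    frequency_skipped: bool = False

    def flagged_asvs(self) -> list[str]:
        return sorted(self.scores.index[self.scores["flagged"]])

    def to_dict(self) -> dict:
        return {
            "n_asvs": len(self.scores),
            "n_flagged": int(self.scores["flagged"].sum()),
            "flagged_asvs": self.flagged_asvs(),
            "frequency_skipped": self.frequency_skipped,
            "subtraction": self.subtraction.to_dict(),
            "comparison": self.comparison.to_dict(),
            "scores": {a: {k: (None if pd.isna(v) else (bool(v) if k == "flagged"
                                                        else float(v)))
                           for k, v in row.items()}
                       for a, row in self.scores.iterrows()},
        }

    def to_frame(self) -> pd.DataFrame:
        return self.scores


def run_decontamination(table: AsvTable, metadata: SampleMetadata,
                        combination_threshold: float = 0.1,
                        min_presence: int = 5,
                        high_abundance_threshold: int = 400,
                        control_scope: str = "all_negative") -> ContaminationResult:
    """Run both strategies and the comparator with default thresholds.

    When no usable DNA concentrations exist the frequency method is skipped
    with a warning and the combination falls back to prevalence alone.
    """
    prev = prevalence_scores(table, metadata, control_scope=control_scope)
    skipped = False
    try:
        freq = frequency_scores(table, metadata, min_presence=min_presence)
    except ValidationError as exc:
        warnings.warn(f"frequency method skipped: {exc}")
        freq = pd.Series(np.nan, index=table.asv_ids, name="frequency_p")
        skipped = True
    scores = combination_flags(prev, freq, threshold=combination_threshold)
    sub = subtract_background(table, metadata, control_scope=control_scope)
    comp = compare_strategies(scores["flagged"], sub, table, metadata,
                              high_abundance_threshold=high_abundance_threshold)
    return ContaminationResult(scores, sub, comp, frequency_skipped=skipped)
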