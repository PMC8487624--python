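"""Alpha/beta diversity and nonparametric comparison statistics.

Hill numbers of order q are effective numbers of equally abundant ASVs:
D0 is observed richness, D1 = exp(Shannon entropy), D2 = inverse Simpson.
Beta diversity is Bray-Curtis dissimilarity, computed on relative abundances
by default so that library-depth differences between pipelines do not
masquerade as compositional differences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata

from .errors import UndefinedMetricError
from .io_formats import AsvTable


# ---------------------------------------------------------------------------
# Hill numbers
# ---------------------------------------------------------------------------

def hill_numbers(counts) -> tuple[float, float, float]:
    """(D0, D1, D2) for one sample's count vector.

    D0 = number of ASVs with count > 0
    D1 = exp(-sum p_i ln p_i)   with p_i = count_i / total
    D2 = 1 / sum p_i^2
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("hill_numbers expects a single sample's vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise UndefinedMetricError("diversity is undefined for an all-zero sample")
    p = c[c > 0] / total
    d0 = float(p.size)
    d1 = float(np.exp(-np.sum(p * np.log(p))))
    d2 = float(1.0 / np.sum(p * p))
    return d0, d1, d2


@dataclass
class DiversityProfile:
    """Per-sample Hill numbers with cross-sample summaries."""

    per_sample: pd.DataFrame           # columns D0, D1, D2, index sample_id
    zero_read_samples: list[str]

    def summary(self) -> pd.DataFrame:
        return self.per_sample.agg(["mean", "median", "std"])

    def to_dict(self) -> dict:
        return {
            "per_sample": {c: self.per_sample[c].to_dict() for c in self.per_sample},
            "summary": {c: self.summary()[c].to_dict() for c in self.per_sample},
            "zero_read_samples": list(self.zero_read_samples),
        }

    def to_frame(self) -> pd.DataFrame:
        return self.per_sample


def diversity_profile(table: AsvTable) -> DiversityProfile:
    """Hill numbers per sample; zero-read samples are excluded and listed."""
    totals = table.sample_totals()
    zero = [s for s, t in totals.items() if t == 0]
    live = [s for s in table.sample_ids if s not in zero]
    rows = {s: hill_numbers(table.counts.loc[s].to_numpy()) for s in live}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["D0", "D1", "D2"])
    frame.index.name = "sample_id"
    return DiversityProfile(frame, zero)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(x, y, normalize: bool = True) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two count vectors.

    With ``normalize`` (default) vectors are first converted to relative
    abundances, so read depth does not contribute to the distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.sum() <= 0 or y.sum() <= 0:
        raise UndefinedMetricError("Bray-Curtis undefined for a zero-total vector")
    if normalize:
        x = x / x.sum()
        y = y / y.sum()
    return float(np.abs(x - y).sum() / (x + y).sum())


@dataclass
class BetaSummary:
    """Pairwise Bray-Curtis matrix over samples plus upper-triangle summaries."""

    matrix: pd.DataFrame
    zero_read_samples: list[str] = field(default_factory=list)

    @property
    def upper_triangle(self) -> np.ndarray:
        m = self.matrix.to_numpy()
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]

    def to_dict(self) -> dict:
        ut = self.upper_triangle
        if ut.size == 0:
            return {"n_samples": self.matrix.shape[0], "n_pairs": 0}
        return {
            "n_samples": self.matrix.shape[0],
            "n_pairs": int(ut.size),
            "mean": float(ut.mean()),
            "median": float(np.median(ut)),
            "min": float(ut.min()),
            "max": float(ut.max()),
            "sd": float(ut.std(ddof=1)) if ut.size > 1 else 0.0,
            "zero_read_samples": list(self.zero_read_samples),
        }

    def to_frame(self) -> pd.DataFrame:
        return self.matrix


def beta_summary(table: AsvTable, normalize: bool = True) -> BetaSummary:
    """All-pairs Bray-Curtis over samples with positive totals."""
    totals = table.sample_totals()
    zero = [s for s, t in totals.items() if t == 0]
    live = [s for s in table.sample_ids if s not in zero]
    if len(live) < 2:
        raise UndefinedMetricError("need at least two non-empty samples for beta diversity")
    mat = table.counts.loc[live].to_numpy(dtype=float)
    if normalize:
        mat = mat / mat.sum(axis=1, keepdims=True)
    dm = squareform(pdist(mat, metric="braycurtis"))
    return BetaSummary(pd.DataFrame(dm, index=live, columns=live), zero)


# ---------------------------------------------------------------------------
# count summaries
# ---------------------------------------------------------------------------

@dataclass
class CountSummary:
    total_reads: int
    mean_reads_per_sample: float
    sd_reads_per_sample: float
    total_asvs: int
    n_samples: int
    zero_read_samples: list[str]

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "mean_reads_per_sample": self.mean_reads_per_sample,
            "sd_reads_per_sample": self.sd_reads_per_sample,
            "total_asvs": self.total_asvs,
            "n_samples": self.n_samples,
            "n_zero_read_samples": len(self.zero_read_samples),
            "zero_read_samples": list(self.zero_read_samples),
        }

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        d.pop("zero_read_samples")
        return pd.DataFrame([d])


def summarize_counts(table: AsvTable) -> CountSummary:
    """Total reads, per-sample read mean/sd, ASVs with nonzero totals, empty samples."""
    per_sample = table.sample_totals()
    return CountSummary(
        total_reads=int(per_sample.sum()),
        mean_reads_per_sample=float(per_sample.mean()),
        sd_reads_per_sample=float(per_sample.std(ddof=1)) if len(per_sample) > 1 else 0.0,
        total_asvs=int((table.asv_totals() > 0).sum()),
        n_samples=table.n_samples,
        zero_read_samples=[s for s, t in per_sample.items() if t == 0],
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    u: float
    p_value: float
    n_a: int
    n_b: int
    method: str           # "exact" or "normal-approx-tie-corrected"
    note: str = ""

    def to_dict(self) -> dict:
        return {"u": self.u, "p_value": self.p_value, "n_a": self.n_a,
                "n_b": self.n_b, "method": self.method, "note": self.note}


@lru_cache(maxsize=64)
def _combo_indices(n_total: int, n_pick: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n_total), n_pick)), dtype=np.intp)


def mann_whitney(a, b, exact_cutoff: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test.

    When both group sizes are <= ``exact_cutoff`` the null distribution is the
    tie-aware permutation distribution of U over all rank assignments;
    otherwise a normal approximation with tie correction and continuity
    correction is used. All values identical across both groups yields p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    if np.all(pooled == pooled[0]):
        return TestResult(u_obs, 1.0, n1, n2, "normal-approx-tie-corrected",
                          note="all values identical; p set to 1")

    if n1 <= exact_cutoff and n2 <= exact_cutoff:
        combos = _combo_indices(n1 + n2, n1)
        u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-9))
        return TestResult(u_obs, p, n1, n2, "exact")

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(u_obs, 1.0, n1, n2, "normal-approx-tie-corrected",
                          note="degenerate variance; p set to 1")
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult(u_obs, p, n1, n2, "normal-approx-tie-corrected")
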