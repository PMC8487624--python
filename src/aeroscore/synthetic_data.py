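"""Synthetic bioaerosol-style datasets with full ground truth.

The generator emulates the structure of a low-biomass urban-park aerosol
survey: 66 samples over 11 locations with roughly one control unit for every
two samples, split between sampling controls (carried through the whole
field + laboratory process) and laboratory controls (extraction blanks).

True ASV abundances follow a log-normal law; a subset carries per-location
effect multipliers. Contamination comes from two sources with distinct
profiles: a laboratory source (reagents; reaches every unit) and a
sampling-stage source (field handling; reaches samples and sampling controls
but never laboratory controls). Dual-membership ASVs are genuine community
members that also sit in the sampling-stage contaminant profile, the
situation where whole-ASV deletion and background subtraction disagree most.
Sample DNA concentration is inversely (noisily) related to contaminant load.

Pipeline observation applies per-pipeline read retention (binomial
thinning), per-ASV detection sensitivity, and appends spurious ASVs with
geometric-tail abundances and random sequences. Taxonomy simulation covers
each ASV at genus level independently per database and draws agreement among
co-covered ASVs at a configurable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import RANKS, UNASSIGNED, AsvTable, SampleMetadata, TaxonomyTable

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CommunityConfig:
    """Study-shaped defaults: 66 samples / 11 locations, controls ~1/3 of units."""

    n_true_asvs: int = 300
    lognormal_sigma: float = 1.5        # spread of true mean abundances
    n_samples: int = 66
    n_locations: int = 11
    n_sampling_controls: int = 22
    n_laboratory_controls: int = 11
    n_positive_controls: int = 0
    mean_library_size: int = 10_000
    library_sigma: float = 0.35         # lognormal sd of library sizes
    control_library_size: int = 4_000
    n_location_effect_asvs: int = 20
    location_effect: float = 5.0        # abundance multiplier at affected locations
    # contamination
    n_lab_contaminants: int = 20
    n_lab_only: int = 6                 # lab contaminants confined to laboratory controls
    n_sampling_contaminants: int = 20
    n_dual: int = 2                     # genuine members also in the sampling source
    dual_profile_weight: float = 0.15   # dual ASV share of the sampling-source profile
    dual_true_boost: float = 0.4        # dual true weight, x the 99.5% abundance quantile
    contamination_beta: tuple[float, float] = (2.0, 4.0)  # per-sample contaminant fraction
    sample_contaminant_mix: float = 0.6   # sampling-source share of sample contamination
    control_contaminant_mix: float = 0.3  # sampling-source share in sampling controls
    leak_fraction: float = 0.05         # true-community share of sampling-control reads
    base_concentration: float = 5.0     # ng/uL at zero contamination
    concentration_noise: float = 0.15   # lognormal sd of concentration noise
    seq_length_range: tuple[int, int] = (250, 450)


@dataclass
class PipelinePairConfig:
    """Asymmetric pipeline observation: A retains more reads, B emits more
    low-abundance exclusive ASVs."""

    retention_a: float = 1.0
    retention_b: float = 0.75
    sensitivity_a: float = 0.98
    sensitivity_b: float = 0.98
    n_spurious_a: int = 600
    n_spurious_b: int = 3000
    spurious_geom_p: float = 0.5        # geometric tail of spurious read totals
    spurious_max_quantile: float = 0.10  # spurious totals capped below this true quantile


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------

@dataclass
class CommunityTruth:
    """Everything the generator knows: tables, metadata, provenance, profiles."""

    config: CommunityConfig
    seed: int
    uncontaminated: AsvTable
    contaminated: AsvTable
    metadata: SampleMetadata
    true_asvs: list[str]
    lab_contaminants: list[str]
    lab_only_contaminants: list[str]
    sampling_contaminants: list[str]
    dual_asvs: list[str]
    true_props: pd.Series
    lab_profile: pd.Series
    sampling_profile: pd.Series
    contaminant_fraction: pd.Series       # per true sample
    location_effect_asvs: list[str]
    sequences: dict[str, str]

    def provenance(self) -> pd.DataFrame:
        """Per-ASV ground-truth labels, round-trippable to an audit TSV."""
        rows = []
        for a in self.contaminated.asv_ids:
            rows.append({
                "asv_id": a,
                "is_true": a in set(self.true_asvs),
                "is_lab_contaminant": a in set(self.lab_contaminants),
                "is_lab_only": a in set(self.lab_only_contaminants),
                "is_sampling_contaminant": a in set(self.sampling_contaminants),
                "is_dual": a in set(self.dual_asvs),
                "has_location_effect": a in set(self.location_effect_asvs),
            })
        return pd.DataFrame(rows).set_index("asv_id")


def _random_sequences(rng: np.random.Generator, ids: list[str],
                      length_range: tuple[int, int]) -> dict[str, str]:
    lo, hi = length_range
    out = {}
    for asv in ids:
        n = int(rng.integers(lo, hi + 1))
        out[asv] = b"".join(_BASES[rng.integers(0, 4, size=n)].tolist()).decode()
    return out


def generate_community(config: CommunityConfig | None = None,
                       seed: int = 0) -> CommunityTruth:
    """Draw a full study: paired contaminated/uncontaminated tables + metadata."""
    cfg = config or CommunityConfig()
    if cfg.n_samples < cfg.n_locations or cfg.n_locations < 1:
        raise ValidationError("need n_samples >= n_locations >= 1")
    if cfg.n_dual > min(cfg.n_true_asvs, cfg.n_sampling_contaminants + cfg.n_dual):
        raise ValidationError("dual set larger than the true/contaminant intersection")
    rng = np.random.default_rng(seed)

    true_ids = [f"ASV_{i + 1:04d}" for i in range(cfg.n_true_asvs)]
    lab_ids = [f"CONT_L_{i + 1:03d}" for i in range(cfg.n_lab_contaminants)]
    samp_ids = [f"CONT_S_{i + 1:03d}" for i in range(cfg.n_sampling_contaminants)]
    dual_ids = true_ids[:cfg.n_dual] if (lab_ids or samp_ids or cfg.n_dual) else []
    if cfg.n_lab_contaminants == 0 and cfg.n_sampling_contaminants == 0:
        dual_ids = []
    all_ids = true_ids + lab_ids + samp_ids

    # true community: log-normal mean abundances, dual ASVs boosted
    weights = rng.lognormal(0.0, cfg.lognormal_sigma, size=cfg.n_true_asvs)
    q995 = np.quantile(weights, 0.995)
    for i in range(len(dual_ids)):
        weights[i] = q995 * cfg.dual_true_boost
    true_props = pd.Series(weights / weights.sum(), index=true_ids)

    # contaminant source profiles; a subset of lab contaminants is batch-specific
    # and reaches laboratory controls only (never samples or sampling controls)
    lab_only = lab_ids[:min(cfg.n_lab_only, len(lab_ids))]
    lab_profile = pd.Series(0.0, index=all_ids)
    if lab_ids:
        w = rng.lognormal(0.0, 1.0, size=len(lab_ids))
        lab_profile[lab_ids] = w / w.sum()
    lab_shared = lab_profile.copy()
    lab_shared[lab_only] = 0.0
    if lab_shared.sum() > 0:
        lab_shared = lab_shared / lab_shared.sum()
    sampling_profile = pd.Series(0.0, index=all_ids)
    if samp_ids or dual_ids:
        w = rng.lognormal(0.0, 1.0, size=len(samp_ids))
        dual_total = cfg.dual_profile_weight * len(dual_ids)
        if dual_total >= 1.0:
            raise ValidationError("dual_profile_weight x n_dual must stay below 1")
        if samp_ids:
            sampling_profile[samp_ids] = (1.0 - dual_total) * w / w.sum()
        for d in dual_ids:
            sampling_profile[d] = cfg.dual_profile_weight

    # location structure
    locations = [f"park_{chr(ord('A') + i)}" for i in range(cfg.n_locations)]
    sample_locs = [locations[i % cfg.n_locations] for i in range(cfg.n_samples)]
    effect_ids = true_ids[cfg.n_dual:cfg.n_dual + cfg.n_location_effect_asvs]
    effect_locs = {a: set(rng.choice(locations, size=max(1, cfg.n_locations // 3),
                                     replace=False).tolist())
                   for a in effect_ids}

    p_true_full = pd.Series(0.0, index=all_ids)
    p_true_full[true_ids] = true_props

    def location_props(loc: str) -> np.ndarray:
        w = p_true_full.copy()
        for a, locs in effect_locs.items():
            if loc in locs:
                w[a] *= cfg.location_effect
        return (w / w.sum()).to_numpy()

    has_contam = bool(lab_ids or samp_ids or dual_ids)
    sample_mix = (cfg.sample_contaminant_mix * sampling_profile
                  + (1 - cfg.sample_contaminant_mix) * lab_shared)
    sctrl_mix = (cfg.control_contaminant_mix * sampling_profile
                 + (1 - cfg.control_contaminant_mix) * lab_shared)
    if sample_mix.sum() > 0:
        sample_mix = sample_mix / sample_mix.sum()
        sctrl_mix = sctrl_mix / sctrl_mix.sum()

    rows_clean, rows_cont, meta_rows = {}, {}, []
    lam = pd.Series(dtype=float)
    for i in range(cfg.n_samples):
        sid = f"S{i + 1:03d}"
        loc = sample_locs[i]
        lib = max(100, int(rng.lognormal(np.log(cfg.mean_library_size),
                                         cfg.library_sigma)))
        frac = float(rng.beta(*cfg.contamination_beta)) if has_contam else 0.0
        n_true = int(rng.binomial(lib, 1.0 - frac))
        true_counts = rng.multinomial(n_true, location_props(loc))
        cont_counts = (rng.multinomial(lib - n_true, sample_mix.to_numpy())
                       if has_contam and lib - n_true > 0
                       else np.zeros(len(all_ids), dtype=np.int64))
        rows_clean[sid] = true_counts
        rows_cont[sid] = true_counts + cont_counts
        lam[sid] = frac
        conc = (cfg.base_concentration * (1.0 - frac)
                * rng.lognormal(0.0, cfg.concentration_noise))
        meta_rows.append({"sample_id": sid, "location": loc,
                          "sample_type": "sample", "dna_concentration": conc})

    for i in range(cfg.n_sampling_controls):
        sid = f"SC{i + 1:03d}"
        lib = max(50, int(rng.lognormal(np.log(cfg.control_library_size),
                                        cfg.library_sigma)))
        n_leak = int(rng.binomial(lib, cfg.leak_fraction))
        leak = rng.multinomial(n_leak, p_true_full.to_numpy())
        cont = (rng.multinomial(lib - n_leak, sctrl_mix.to_numpy())
                if has_contam and lib - n_leak > 0
                else np.zeros(len(all_ids), dtype=np.int64))
        rows_clean[sid] = leak
        rows_cont[sid] = leak + cont
        meta_rows.append({"sample_id": sid, "location": "control",
                          "sample_type": "sampling_control",
                          "dna_concentration": np.nan})

    for i in range(cfg.n_laboratory_controls):
        sid = f"LC{i + 1:03d}"
        lib = max(50, int(rng.lognormal(np.log(cfg.control_library_size),
                                        cfg.library_sigma)))
        cont = (rng.multinomial(lib, lab_profile.to_numpy())
                if has_contam and lab_profile.sum() > 0
                else np.zeros(len(all_ids), dtype=np.int64))
        rows_clean[sid] = np.zeros(len(all_ids), dtype=np.int64)
        rows_cont[sid] = cont
        meta_rows.append({"sample_id": sid, "location": "control",
                          "sample_type": "laboratory_control",
                          "dna_concentration": np.nan})

    for i in range(cfg.n_positive_controls):
        sid = f"PC{i + 1:03d}"
        lib = max(50, int(rng.lognormal(np.log(cfg.mean_library_size),
                                        cfg.library_sigma)))
        counts = rng.multinomial(lib, p_true_full.to_numpy())
        rows_clean[sid] = counts
        rows_cont[sid] = counts
        meta_rows.append({"sample_id": sid, "location": "control",
                          "sample_type": "positive_control",
                          "dna_concentration": cfg.base_concentration})

    order = list(rows_cont)
    clean = pd.DataFrame([rows_clean[s] for s in order], index=order, columns=all_ids)
    cont = pd.DataFrame([rows_cont[s] for s in order], index=order, columns=all_ids)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    seqs = _random_sequences(rng, all_ids, cfg.seq_length_range)

    return CommunityTruth(
        config=cfg, seed=seed,
        uncontaminated=AsvTable(clean), contaminated=AsvTable(cont),
        metadata=meta,
        true_asvs=true_ids, lab_contaminants=lab_ids,
        lab_only_contaminants=lab_only,
        sampling_contaminants=samp_ids + dual_ids, dual_asvs=dual_ids,
        true_props=true_props, lab_profile=lab_profile,
        sampling_profile=sampling_profile,
        contaminant_fraction=lam, location_effect_asvs=effect_ids,
        sequences=seqs,
    )


# ---------------------------------------------------------------------------
# pipeline-pair generation
# ---------------------------------------------------------------------------

@dataclass
class PipelinePair:
    table_a: AsvTable
    seqs_a: dict[str, str]
    table_b: AsvTable
    seqs_b: dict[str, str]
    spurious_a: list[str]
    spurious_b: list[str]
    detected_a: list[str]
    detected_b: list[str]


def _observe(base: pd.DataFrame, sequences: dict[str, str], rng: np.random.Generator,
             retention: float, sensitivity: float, n_spurious: int,
             geom_p: float, max_total: int, tag: str,
             length_range: tuple[int, int]) -> tuple[AsvTable, dict[str, str], list[str], list[str]]:
    detected_mask = rng.random(base.shape[1]) < sensitivity
    detected = [a for a, keep in zip(base.columns, detected_mask) if keep]
    obs = base[detected]
    thinned = rng.binomial(obs.to_numpy(), retention) if retention < 1.0 \
        else obs.to_numpy().copy()
    frames = {a: thinned[:, j] for j, a in enumerate(detected)}
    spurious_ids = [f"SPUR_{tag}_{i + 1:04d}" for i in range(n_spurious)]
    n_samples = base.shape[0]
    for sp in spurious_ids:
        total = min(int(rng.geometric(geom_p)), max(1, max_total))
        col = np.zeros(n_samples, dtype=np.int64)
        hits = rng.integers(0, n_samples, size=total)
        np.add.at(col, hits, 1)
        frames[sp] = col
    table = AsvTable(pd.DataFrame(frames, index=base.index))
    seqs = {a: sequences[a] for a in detected}
    seqs.update(_random_sequences(rng, spurious_ids, length_range))
    return table, seqs, spurious_ids, detected


def generate_pipeline_pair(truth: CommunityTruth,
                           config: PipelinePairConfig | None = None,
                           seed: int = 0,
                           base_table: AsvTable | None = None) -> PipelinePair:
    """Observe one community through two pipelines with asymmetric behaviour.

    Shared detected ASVs carry identical sequences across the pair, so exact
    matching recovers them; spurious ASVs get pipeline-private random
    sequences and geometric-tail read totals capped strictly below the
    configured quantile of true ASV totals.
    """
    cfg = config or PipelinePairConfig()
    base = (base_table or truth.contaminated).counts
    rng = np.random.default_rng(seed)
    true_totals = base.sum(axis=0).to_numpy()
    cap = max(1, int(np.quantile(true_totals[true_totals > 0],
                                 cfg.spurious_max_quantile)) - 1)
    table_a, seqs_a, spur_a, det_a = _observe(
        base, truth.sequences, rng, cfg.retention_a, cfg.sensitivity_a,
        cfg.n_spurious_a, cfg.spurious_geom_p, cap, "A",
        truth.config.seq_length_range)
    table_b, seqs_b, spur_b, det_b = _observe(
        base, truth.sequences, rng, cfg.retention_b, cfg.sensitivity_b,
        cfg.n_spurious_b, cfg.spurious_geom_p, cap, "B",
        truth.config.seq_length_range)
    return PipelinePair(table_a, seqs_a, table_b, seqs_b, spur_a, spur_b,
                        det_a, det_b)


# ---------------------------------------------------------------------------
# taxonomy-pair generation
# ---------------------------------------------------------------------------

#: small pool of real environmental genera; the rest are generated names
_GENUS_SEED_POOL = (
    "Pseudomonas", "Ralstonia", "Methylobacterium", "Sphingomonas", "Bacillus",
    "Massilia", "Acinetobacter", "Streptomyces", "Hymenobacter", "Deinococcus",
    "Penicillium", "Alternaria", "Cladosporium", "Aspergillus", "Fusarium",
)


def _lineage_for(genus_idx: int, pool: list[str]) -> dict[str, str]:
    """Deterministic genus -> higher-rank ladder so lineages stay consistent."""
    return {
        "domain": "Bacteria",
        "phylum": f"Phylum_{genus_idx % 12:02d}",
        "class": f"Class_{genus_idx % 30:02d}",
        "order": f"Order_{genus_idx % 60:02d}",
        "family": f"Family_{genus_idx % 120:03d}",
        "genus": pool[genus_idx],
    }


def generate_taxonomy_pair(asv_ids: list[str], c1: float = 0.44, c2: float = 0.62,
                           agreement: float = 0.5, seed: int = 0,
                           spurious_ids: list[str] | None = None,
                           spurious_coverage: float = 0.05,
                           genus_pool_size: int = 400,
                           db_names: tuple[str, str] = ("RDP", "SILVA"),
                           ) -> tuple[TaxonomyTable, TaxonomyTable]:
    """Simulate two databases' genus-level coverage and agreement.

    Each ASV in ``asv_ids`` is covered at genus level by database 1 with
    probability ``c1`` and independently by database 2 with ``c2``; when both
    cover it, the genera agree with probability ``agreement``. ASVs listed in
    ``spurious_ids`` are covered at ``spurious_coverage`` instead. Uncovered
    ASVs keep a partial (above-genus) or empty lineage.
    """
    for p, name in ((c1, "c1"), (c2, "c2"), (agreement, "agreement"),
                    (spurious_coverage, "spurious_coverage")):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pool = list(_GENUS_SEED_POOL) + [f"Genus{i:04d}" for i in
                                     range(max(0, genus_pool_size - len(_GENUS_SEED_POOL)))]
    spurious = set(spurious_ids or ())
    rows1, rows2 = [], []
    blank = {r: UNASSIGNED for r in RANKS[:-1]}
    for asv in asv_ids:
        cov1 = c1 if asv not in spurious else spurious_coverage
        cov2 = c2 if asv not in spurious else spurious_coverage
        has1 = rng.random() < cov1
        has2 = rng.random() < cov2
        gi = int(rng.integers(0, len(pool)))
        lin1, lin2 = dict(blank), dict(blank)
        if has1 and has2:
            if rng.random() < agreement:
                lin1 = lin2 = _lineage_for(gi, pool)
            else:
                gj = int((gi + 1 + rng.integers(0, len(pool) - 1)) % len(pool))
                lin1 = _lineage_for(gi, pool)
                lin2 = _lineage_for(gj, pool)
        elif has1:
            lin1 = _lineage_for(gi, pool)
        elif has2:
            lin2 = _lineage_for(gi, pool)
        for lin, rows in ((lin1, rows1), (lin2, rows2)):
            if lin["genus"] == UNASSIGNED and rng.random() < 0.6:
                partial = _lineage_for(gi, pool)
                depth = int(rng.integers(1, 5))   # down to phylum..family
                lin = {r: (partial[r] if k < depth else UNASSIGNED)
                       for k, r in enumerate(RANKS[:-1])}
            rows.append({"asv_id": asv, **lin})
    tax1 = TaxonomyTable(pd.DataFrame(rows1).set_index("asv_id"), source_db=db_names[0])
    tax2 = TaxonomyTable(pd.DataFrame(rows2).set_index("asv_id"), source_db=db_names[1])
    return tax1, tax2


def overlap_pair_from_counts(n_shared: int, n_exclusive_a: int, n_exclusive_b: int,
                             seed: int = 0,
                             length_range: tuple[int, int] = (250, 450),
                             ) -> tuple[dict[str, str], dict[str, str]]:
    """Two sequence sets with exactly the given shared/exclusive structure.

    Useful for reconstructing an observed cross-pipeline overlap from its
    marginal counts (totals and exclusives) and verifying the derived support
    fractions with the real matching machinery.
    """
    if min(n_shared, n_exclusive_a, n_exclusive_b) < 0 or n_shared + max(
            n_exclusive_a, n_exclusive_b) < 1:
        raise ValidationError("overlap counts must be non-negative and non-empty")
    rng = np.random.default_rng(seed)
    shared_ids = [f"SH_{i + 1:05d}" for i in range(n_shared)]
    a_ids = [f"AX_{i + 1:05d}" for i in range(n_exclusive_a)]
    b_ids = [f"BX_{i + 1:05d}" for i in range(n_exclusive_b)]
    shared = _random_sequences(rng, shared_ids, length_range)
    seqs_a = dict(shared)
    seqs_a.update(_random_sequences(rng, a_ids, length_range))
    seqs_b = dict(shared)
    seqs_b.update(_random_sequences(rng, b_ids, length_range))
    return seqs_a, seqs_b


def taxonomy_pair_from_counts(n_total: int, n_unassigned_primary: int,
                              n_unassigned_secondary: int, n_unassigned_both: int,
                              seed: int = 0,
                              db_names: tuple[str, str] = ("RDP", "SILVA"),
                              agreement: float = 0.5,
                              ) -> tuple[TaxonomyTable, TaxonomyTable, list[str]]:
    """Two taxonomy tables over a common ASV universe with exact unassigned margins.

    ``n_unassigned_both`` ASVs lack a genus in both databases; the remaining
    unassigned counts are exclusive to one database. Genus names among
    co-assigned ASVs agree at ``agreement`` (irrelevant to assignment-rate
    statistics, but keeps the fixture realistic).
    """
    only_p = n_unassigned_primary - n_unassigned_both
    only_s = n_unassigned_secondary - n_unassigned_both
    n_assigned_both = n_total - (n_unassigned_both + only_p + only_s)
    if min(only_p, only_s, n_assigned_both, n_unassigned_both) < 0:
        raise ValidationError("inconsistent unassigned margins")
    rng = np.random.default_rng(seed)
    ids = [f"ASV_{i + 1:05d}" for i in range(n_total)]
    pool = list(_GENUS_SEED_POOL) + [f"Genus{i:04d}" for i in range(400)]
    blank = {r: UNASSIGNED for r in RANKS[:-1]}
    rows1, rows2 = [], []
    for k, asv in enumerate(ids):
        gi = int(rng.integers(0, len(pool)))
        lin = _lineage_for(gi, pool)
        if k < n_unassigned_both:
            lin1, lin2 = dict(blank), dict(blank)
        elif k < n_unassigned_both + only_p:       # primary lacks genus
            lin1, lin2 = dict(blank), lin
        elif k < n_unassigned_both + only_p + only_s:
            lin1, lin2 = lin, dict(blank)
        else:
            lin1 = lin
            if rng.random() < agreement:
                lin2 = lin
            else:
                gj = int((gi + 1 + rng.integers(0, len(pool) - 1)) % len(pool))
                lin2 = _lineage_for(gj, pool)
        rows1.append({"asv_id": asv, **lin1})
        rows2.append({"asv_id": asv, **lin2})
    tax1 = TaxonomyTable(pd.DataFrame(rows1).set_index("asv_id"), source_db=db_names[0])
    tax2 = TaxonomyTable(pd.DataFrame(rows2).set_index("asv_id"), source_db=db_names[1])
    return tax1, tax2, ids


def expected_tier_fractions(c1: float, c2: float, agreement: float) -> dict[str, float]:
    """Closed-form consensus tier probabilities under the generator model."""
    return {
        "high": c1 * c2 * agreement,
        "medium": c1 * c2 * (1.0 - agreement),
        "low": c1 * (1.0 - c2) + c2 * (1.0 - c1),
        "unassigned": (1.0 - c1) * (1.0 - c2),
    }
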