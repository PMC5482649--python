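"""Sample-, genotype- and variant-level quality control.

Two variant-QC tracks are implemented, mirroring the different demands of a
single-variant scan and a gene-centric burden analysis:

* **single-variant track** — alignability must equal 1, the site must lie more
  than 10 bp from a simple repeat, Hardy-Weinberg equilibrium must hold
  separately in cases and in controls (exact P >= 1e-5 in each), the no-call
  rate must not differ between groups (Fisher P >= 1e-5), and the no-call rate
  must be <= 0.03 in both groups;
* **gene-centric track** — alignability 1, outside simple repeats, combined
  cases+controls HWE P >= 1e-8, no-call rate < 0.25 in both groups, after
  per-(sample, variant) removal of allele-imbalanced heterozygotes
  (chi-square P < 1e-4 against 50:50 read support).

Genotype-level support is common to both tracks: a non-reference call stands
only if GQ >= 30, the alternate read depth is > 3, and the site's truth-tranche
sensitivity is below 99.5 (SNVs) / 99 (indels); failing calls become missing.

Sample QC runs on a designated high-confidence common-SNV subset: missingness
and heterozygosity outliers (> 3 population SDs above the mean), sex checked
against X-chromosome heterozygosity, and duplicate detection by pairwise
genotype concordance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeSupportThresholds",
    "genotype_support_filter",
    "apply_genotype_support_filter",
    "sample_missingness",
    "sample_heterozygosity",
    "flag_outliers_3sd",
    "sex_check",
    "detect_duplicates",
    "hwe_exact_test",
    "hwe_chi2_test",
    "allele_balance_test",
    "apply_allele_balance_filter",
    "differential_missingness_test",
    "single_variant_qc",
    "gene_centric_qc",
    "sample_qc",
    "SampleQCReport",
]

MISSING = -1


# ---------------------------------------------------------------------------
# genotype-level support
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSupportThresholds:
    min_gq: int = 30
    min_alt_depth_exclusive: int = 3  # alt depth must be strictly greater
    max_tranche_snv: float = 99.5     # strict upper bounds
    max_tranche_indel: float = 99.0


def genotype_support_filter(
    genotype: int,
    gq: float,
    alt_depth: float,
    tranche: float,
    is_snv: bool,
    thresholds: GenotypeSupportThresholds = GenotypeSupportThresholds(),
) -> bool:
    """Whether a single non-reference call is retained.

    Reference and missing calls pass trivially (the filter only vets evidence
    for the alternate allele). Missing GQ/AD metadata fails the call.
    """
    if genotype in (0, MISSING):
        return True
    if gq is None or alt_depth is None or not np.isfinite(gq) or not np.isfinite(alt_depth):
        logger.warning("non-reference call lacking GQ/AD treated as missing")
        return False
    tranche_max = thresholds.max_tranche_snv if is_snv else thresholds.max_tranche_indel
    return (
        gq >= thresholds.min_gq
        and alt_depth > thresholds.min_alt_depth_exclusive
        and tranche < tranche_max
    )


def apply_genotype_support_filter(
    genotypes: np.ndarray,
    gq: np.ndarray,
    alt_depth: np.ndarray,
    tranche: np.ndarray,
    is_snv: np.ndarray,
    thresholds: GenotypeSupportThresholds = GenotypeSupportThresholds(),
) -> np.ndarray:
    """Vectorised support filter over a (variants x samples) matrix.

    Returns a copy of ``genotypes`` in which unsupported non-reference calls
    are set to missing.
    """
    g = np.asarray(genotypes)
    tranche_max = np.where(
        np.asarray(is_snv, dtype=bool),
        thresholds.max_tranche_snv,
        thresholds.max_tranche_indel,
    )[:, None]
    nonref = g > 0
    ok = (
        (np.asarray(gq) >= thresholds.min_gq)
        & (np.asarray(alt_depth) > thresholds.min_alt_depth_exclusive)
        & (np.asarray(tranche)[:, None] < tranche_max)
    )
    out = g.copy()
    out[nonref & ~ok] = MISSING
    return out


# ---------------------------------------------------------------------------
# sample-level QC
# ---------------------------------------------------------------------------

def sample_missingness(genotypes: np.ndarray, subset: np.ndarray) -> np.ndarray:
    """Per-sample fraction of missing calls over the common-SNV subset."""
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("common-SNV subset is empty")
    sub = np.asarray(genotypes)[subset]
    return (sub == MISSING).mean(axis=0)


def sample_heterozygosity(genotypes: np.ndarray, subset: np.ndarray) -> np.ndarray:
    """Per-sample heterozygous fraction of called genotypes over the subset."""
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("common-SNV subset is empty")
    sub = np.asarray(genotypes)[subset]
    called = (sub != MISSING).sum(axis=0)
    het = (sub == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(called > 0, het / np.maximum(called, 1), 0.0)
    return rate


def flag_outliers_3sd(
    values: np.ndarray, direction: str = "above", k: float = 3.0
) -> np.ndarray:
    """Flag values more than k population SDs from the mean (one pass).

    The SD uses the n-denominator over all samples, candidates included; a
    constant vector yields no flags.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mu, sd = v.mean(), v.std(ddof=0)
    if direction == "above":
        return v > mu + k * sd
    if direction == "below":
        return v < mu - k * sd
    raise ValueError(f"unknown direction {direction!r}")


def sex_check(
    x_genotypes: np.ndarray,
    reported_sex: np.ndarray,
    male_f: float = 0.8,
    female_f: float = 0.2,
) -> pd.DataFrame:
    """Compare reported sex against X-heterozygosity-based inference.

    The per-sample inbreeding-style statistic is F = 1 - h_obs / h_exp where
    h_obs is the sample's X heterozygous fraction and h_exp the cohort's
    expected heterozygosity from X allele frequencies. F > ``male_f`` infers
    male (hemizygous X, no true heterozygotes); F < ``female_f`` infers
    female; in between the sample is "undetermined" and never flagged, as is
    any sample with reported sex outside {M, F}.
    """
    reported = np.asarray(reported_sex, dtype=object)
    n = reported.size
    x = np.asarray(x_genotypes)
    if x.size == 0 or x.shape[0] == 0:
        return pd.DataFrame(
            {"inferred_sex": ["undetermined"] * n,
             "f_stat": [np.nan] * n,
             "sex_discrepancy": [False] * n}
        )
    called = x != MISSING
    het = x == 1
    # expected heterozygosity per site from pooled allele frequency
    alt = np.where(called, x, 0).sum(axis=1)
    tot = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    h_exp_site = 2 * p * (1 - p)
    n_called = called.sum(axis=0)
    h_obs = np.where(n_called > 0, het.sum(axis=0) / np.maximum(n_called, 1), 0.0)
    h_exp = np.where(
        n_called > 0,
        (h_exp_site[:, None] * called).sum(axis=0) / np.maximum(n_called, 1),
        np.nan,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(h_exp > 0, 1.0 - h_obs / np.where(h_exp > 0, h_exp, 1.0), np.nan)
    inferred = np.where(
        ~np.isfinite(f), "undetermined",
        np.where(f > male_f, "M", np.where(f < female_f, "F", "undetermined")),
    ).astype(object)
    comparable = np.isin(reported, ("M", "F")) & (inferred != "undetermined")
    flag = comparable & (inferred != reported)
    return pd.DataFrame(
        {"inferred_sex": inferred, "f_stat": f, "sex_discrepancy": flag}
    )


def detect_duplicates(
    genotypes: np.ndarray,
    subset: np.ndarray,
    missingness: np.ndarray,
    concordance_threshold: float = 0.95,
    min_shared: int = 200,
) -> list[tuple[int, int]]:
    """Find sample pairs with near-identical genotypes on the common subset.

    Concordance is the fraction of identical calls over mutually called sites;
    a pair qualifies when concordance > threshold over at least ``min_shared``
    shared sites. Returns (i, j) index pairs with i < j; of each pair the
    member with higher missingness is the conventional exclusion.
    """
    sub = np.asarray(genotypes)[np.asarray(subset)]
    called = (sub != MISSING).astype(np.float32)
    shared = called.T @ called
    eq = np.zeros_like(shared)
    for g in (0, 1, 2):
        ind = ((sub == g) & (sub != MISSING)).astype(np.float32)
        eq += ind.T @ ind
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(shared > 0, eq / np.maximum(shared, 1), 0.0)
    n = sub.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    hit = (conc[iu, ju] > concordance_threshold) & (shared[iu, ju] >= min_shared)
    return [(int(i), int(j)) for i, j in zip(iu[hit], ju[hit])]


@dataclass
class SampleQCReport:
    """Outcome of the sample-level QC pass."""

    table: pd.DataFrame
    duplicate_pairs: list[tuple[int, int]] = field(default_factory=list)

    def exclusion_summary(self) -> dict[str, int]:
        """Counts per exclusion category plus the deduplicated total."""
        t = self.table
        cats = {
            "sex_discrepancy": int(t["sex_discrepancy"].sum()),
            "high_missingness": int(t["high_missingness"].sum()),
            "high_heterozygosity": int(t["high_heterozygosity"].sum()),
            "ancestry_excluded": int(t["ancestry_excluded"].sum()),
            "duplicate": int(t["duplicate"].sum()),
        }
        cats["total_excluded"] = int(t["excluded"].sum())
        return cats


def sample_qc(
    genotypes: np.ndarray,
    common_subset: np.ndarray,
    x_genotypes: np.ndarray,
    samples: pd.DataFrame,
    ancestry_exclusions: set[str] | None = None,
    k_sd: float = 3.0,
    concordance_threshold: float = 0.95,
    min_shared: int = 200,
) -> SampleQCReport:
    """Full sample-QC pass; flags follow the five canonical categories.

    A sample is excluded when any flag is set; the summary reports one count
    per category and a deduplicated total (a sample failing two rules counts
    once in the total).
    """
    miss = sample_missingness(genotypes, common_subset)
    het = sample_heterozygosity(genotypes, common_subset)
    high_miss = flag_outliers_3sd(miss, "above", k_sd)
    high_het = flag_outliers_3sd(het, "above", k_sd)
    sexdf = sex_check(x_genotypes, samples["reported_sex"].to_numpy())
    dup_pairs = detect_duplicates(
        genotypes, common_subset, miss, concordance_threshold, min_shared
    )
    dup_flag = np.zeros(len(samples), dtype=bool)
    for i, j in dup_pairs:
        worse = i if miss[i] >= miss[j] else j
        dup_flag[worse] = True
    anc = np.zeros(len(samples), dtype=bool)
    if ancestry_exclusions:
        anc = samples["sample_id"].isin(ancestry_exclusions).to_numpy()

    table = pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy(),
            "missingness": miss,
            "heterozygosity": het,
            "inferred_sex": sexdf["inferred_sex"].to_numpy(),
            "sex_discrepancy": sexdf["sex_discrepancy"].to_numpy(),
            "high_missingness": high_miss,
            "high_heterozygosity": high_het,
            "ancestry_excluded": anc,
            "duplicate": dup_flag,
        }
    )
    flags = table[
        ["sex_discrepancy", "high_missingness", "high_heterozygosity",
         "ancestry_excluded", "duplicate"]
    ].to_numpy()
    table["excluded"] = flags.any(axis=1)
    table["exclusion_reason"] = [
        ";".join(
            c for c, v in zip(
                ("sex_discrepancy", "high_missingness", "high_heterozygosity",
                 "ancestry_excluded", "duplicate"),
                row,
            ) if v
        )
        for row in flags
    ]
    return SampleQCReport(table=table, duplicate_pairs=dup_pairs)


# ---------------------------------------------------------------------------
# per-variant statistical filters
# ---------------------------------------------------------------------------

def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts no more probable than the observed one. Returns a P
    in (0, 1]; zero genotypes give P = 1 (single attainable configuration).
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        return 1.0
    n_alt = n_het + 2 * n_homalt
    n_rare = min(n_alt, 2 * n - n_alt)
    # attainable het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log Pr(het | allele counts): multivariate hypergeometric over genotypes
    from scipy.special import gammaln

    lg = math.lgamma
    log_const = lg(n + 1) + lg(n_rare + 1) + lg(2 * n - n_rare + 1) - lg(2 * n + 1)
    rare_hom = (n_rare - hets) // 2
    com_hom = n - hets - rare_hom
    logp = (
        hets * math.log(2) + log_const
        - gammaln(hets + 1) - gammaln(rare_hom + 1) - gammaln(com_hom + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = int(n_het)
    p_obs = p[hets == obs]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with alleles")
    return float(min(p[p <= p_obs[0] * (1 + 1e-12)].sum(), 1.0))


def hwe_chi2_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """One-df chi-square HWE test (alternative to the exact test)."""
    n = n_homref + n_het + n_homalt
    if n == 0:
        return 1.0
    p = (2 * n_homref + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([p * p, 2 * p * q, q * q]) * n
    obs = np.array([n_homref, n_het, n_homalt], dtype=float)
    nz = exp > 0
    x2 = float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())
    return float(stats.chi2.sf(x2, 1))


def allele_balance_test(ref_depth: int, alt_depth: int) -> float:
    """Chi-square test of 50:50 read support at a heterozygous call.

    X^2 = (ref - alt)^2 / (ref + alt) on 1 df; the caller excludes the
    (sample, variant) pair when P < 1e-4.
    """
    total = ref_depth + alt_depth
    if total <= 0:
        raise ValueError("zero total depth at a heterozygous call")
    x2 = (ref_depth - alt_depth) ** 2 / total
    return float(stats.chi2.sf(x2, 1))


def apply_allele_balance_filter(
    genotypes: np.ndarray,
    ref_depth: np.ndarray,
    alt_depth: np.ndarray,
    p_threshold: float = 1e-4,
) -> np.ndarray:
    """Set allele-imbalanced heterozygous calls to missing (vectorised).

    Heterozygotes with zero total depth are likewise removed: there is no read
    evidence to support the call.
    """
    g = np.asarray(genotypes)
    het = g == 1
    rd = np.asarray(ref_depth, dtype=float)
    ad = np.asarray(alt_depth, dtype=float)
    total = rd + ad
    with np.errstate(invalid="ignore", divide="ignore"):
        x2 = np.where(total > 0, (rd - ad) ** 2 / np.maximum(total, 1), np.inf)
    p = stats.chi2.sf(x2, 1)
    bad = het & ((p < p_threshold) | (total <= 0))
    out = g.copy()
    out[bad] = MISSING
    return out


def differential_missingness_test(
    case_called: int, case_missing: int, control_called: int, control_missing: int
) -> float:
    """Two-sided Fisher exact P for differential no-call between groups."""
    if min(case_called, case_missing, control_called, control_missing) < 0:
        raise ValueError("counts must be non-negative")
    if case_called + case_missing == 0 or control_called + control_missing == 0:
        raise ValueError("both groups must be non-empty")
    table = [[case_called, case_missing], [control_called, control_missing]]
    if case_missing + control_missing == 0 or case_called + control_called == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# variant-level QC tracks
# ---------------------------------------------------------------------------

def _genotype_counts(g_row: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    sub = g_row[mask]
    return (
        int((sub == 0).sum()),
        int((sub == 1).sum()),
        int((sub == 2).sum()),
    )


def _variant_qc(
    genotypes: np.ndarray,
    case_mask: np.ndarray,
    annotations: pd.DataFrame,
    track: str,
    hwe_method: str = "exact",
) -> pd.DataFrame:
    """Shared engine for the two variant-QC tracks."""
    required = {"alignability", "repeat_distance"}
    missing_cols = required - set(annotations.columns)
    if missing_cols:
        raise ValueError(f"annotation table lacks columns: {sorted(missing_cols)}")
    g = np.asarray(genotypes)
    case_mask = np.asarray(case_mask, dtype=bool)
    ctrl_mask = ~case_mask
    hwe = hwe_exact_test if hwe_method == "exact" else hwe_chi2_test

    align_ok = annotations["alignability"].to_numpy() == 1
    repeat_ok = annotations["repeat_distance"].to_numpy() > 10

    rows = []
    for vi in range(g.shape[0]):
        row = g[vi]
        ca_missing = int((row[case_mask] == MISSING).sum())
        co_missing = int((row[ctrl_mask] == MISSING).sum())
        n_ca, n_co = int(case_mask.sum()), int(ctrl_mask.sum())
        ca_rate = ca_missing / n_ca
        co_rate = co_missing / n_co

        rec = {
            "alignability_pass": bool(align_ok[vi]),
            "repeat_distance_pass": bool(repeat_ok[vi]),
        }
        if track == "single_variant":
            p_ca = hwe(*_genotype_counts(row, case_mask))
            p_co = hwe(*_genotype_counts(row, ctrl_mask))
            rec["hwe_pass"] = p_ca >= 1e-5 and p_co >= 1e-5
            rec["hwe_p_case"], rec["hwe_p_control"] = p_ca, p_co
            p_dm = differential_missingness_test(
                n_ca - ca_missing, ca_missing, n_co - co_missing, co_missing
            )
            rec["differential_missingness_pass"] = p_dm >= 1e-5
            rec["differential_missingness_p"] = p_dm
            rec["no_call_rate_pass"] = ca_rate <= 0.03 and co_rate <= 0.03
        elif track == "gene_centric":
            p_all = hwe(*_genotype_counts(row, np.ones_like(case_mask)))
            rec["hwe_pass"] = p_all >= 1e-8
            rec["hwe_p_combined"] = p_all
            rec["no_call_rate_pass"] = ca_rate < 0.25 and co_rate < 0.25
        else:
            raise ValueError(f"unknown track {track!r}")
        rec["no_call_rate_case"] = ca_rate
        rec["no_call_rate_control"] = co_rate
        rows.append(rec)

    df = pd.DataFrame(rows)
    pass_cols = [c for c in df.columns if c.endswith("_pass")]
    df["variant_pass"] = df[pass_cols].all(axis=1)
    df["track"] = track
    df.index = annotations.index
    return df


def single_variant_qc(
    genotypes: np.ndarray,
    case_mask: np.ndarray,
    annotations: pd.DataFrame,
    hwe_method: str = "exact",
) -> pd.DataFrame:
    """Single-variant-track QC report, one row per variant.

    Assumes the genotype-support filter has already been applied.
    """
    return _variant_qc(genotypes, case_mask, annotations, "single_variant", hwe_method)


def gene_centric_qc(
    genotypes: np.ndarray,
    case_mask: np.ndarray,
    annotations: pd.DataFrame,
    hwe_method: str = "exact",
) -> pd.DataFrame:
    """Gene-centric-track QC report, one row per variant.

    Assumes genotype-support filtering and per-(sample, variant) allele-balance
    exclusions have been applied to ``genotypes``.
    """
    return _variant_qc(genotypes, case_mask, annotations, "gene_centric", hwe_method)
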