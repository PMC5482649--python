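"""Synthetic case-control exome cohorts with planted burden signals.

The generator emulates the statistical structure the analysis assumes:

* a rare-variant frequency spectrum (80% of sites below 1% population MAF,
  the rest up to 5%), genotypes in Hardy-Weinberg proportions, drawn
  identically for cases and controls at null genes;
* a designated high-confidence common-SNV subset (MAF 0.2-0.5) used for
  sample QC — missingness, heterozygosity, duplicate detection — emulating
  the curated common-SNV panel such studies compute sample metrics on;
* a small X-chromosome block for sex inference (males hemizygous: coded
  homozygous, never het);
* per-genotype metadata: GQ discretised with mass above and below the
  support threshold of 30, total depth negative-binomial, heterozygote
  alternate reads Binomial(depth, 1/2);
* planted gene-level signals, either at exact case/control carrier counts
  (for regression against published carrier configurations) or at a
  per-carrier relative risk;
* injected QC failure modes, each logged in the truth object so QC recovery
  is testable: missingness and heterozygosity outliers, duplicate pairs, sex
  mismatches, HWE-violating sites, repeat-proximal sites, low-GQ genotypes
  and allele-imbalanced heterozygotes.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import MISSING

__all__ = [
    "MafSpectrum",
    "FailureRates",
    "PlantedSignal",
    "SimulationConfig",
    "CohortTruth",
    "Cohort",
    "simulate_cohort",
    "inject_qc_failures",
    "write_cohort",
]

CONSEQUENCE_FREQS = {
    "missense": 0.50,
    "synonymous": 0.25,
    "stop_gained": 0.05,
    "frameshift": 0.05,
    "splice_acceptor": 0.02,
    "splice_donor": 0.02,
    "inframe_insertion": 0.03,
    "inframe_deletion": 0.03,
    "other": 0.05,
}
#: fraction of missense calls labelled damaging by the CONDEL-style predictor
CONDEL_DAMAGING_FRACTION = 0.4

CLASS_CONSEQUENCE = {1: "stop_gained", 2: "missense", 3: "missense"}


@dataclass(frozen=True)
class MafSpectrum:
    """Mixture describing population minor-allele frequencies of rare sites."""

    frac_below_1pct: float = 0.8
    rare_min: float = 5e-4
    rare_max: float = 0.01
    low_freq_max: float = 0.05
    common_min: float = 0.2   # for the designated common-SNV subset
    common_max: float = 0.5

    def draw_rare(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Log-uniform below 1%, uniform on (1%, 5%] for the remainder."""
        below = rng.random(n) < self.frac_below_1pct
        out = np.empty(n)
        nb = int(below.sum())
        out[below] = np.exp(
            rng.uniform(np.log(self.rare_min), np.log(self.rare_max), nb)
        )
        out[~below] = rng.uniform(self.rare_max, self.low_freq_max, n - nb)
        return out


@dataclass(frozen=True)
class FailureRates:
    """Per-mode injection fractions (of samples, pairs or variants)."""

    missingness_outlier: float = 0.0
    heterozygosity_outlier: float = 0.0
    duplicate_pair: float = 0.0
    sex_mismatch: float = 0.0
    hwe_violating_site: float = 0.0
    repeat_proximal_site: float = 0.0
    low_gq_genotype: float = 0.0
    allele_imbalanced_het: float = 0.0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if not 0 <= val <= 1:
                raise ValueError(f"failure rate {name} outside [0, 1]")


@dataclass(frozen=True)
class PlantedSignal:
    """A gene-level burden signal to realise in the cohort."""

    gene: str
    variant_class: int = 3
    mode: str = "exact_counts"  # or "relative_risk"
    rr: float | None = None
    carrier_freq: float = 0.01  # population carrier fraction (relative_risk)
    case_carriers: int | None = None
    control_carriers: int | None = None
    weights: tuple[int, ...] | None = None  # per-carrier allele multiplicity

    def __post_init__(self) -> None:
        if self.variant_class not in (1, 2, 3):
            raise ValueError("variant_class must be 1, 2 or 3")
        if self.mode == "exact_counts":
            if self.case_carriers is None or self.control_carriers is None:
                raise ValueError(
                    f"gene {self.gene}: exact_counts mode needs carrier counts"
                )
        elif self.mode == "relative_risk":
            if self.rr is None or self.rr < 0:
                raise ValueError(f"gene {self.gene}: relative_risk mode needs rr >= 0")
        else:
            raise ValueError(f"gene {self.gene}: unknown mode {self.mode!r}")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_case: int = 513
    n_control: int = 1569
    n_genes: int = 500
    variants_per_gene_mean: float = 8.0
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    failure_rates: FailureRates = field(default_factory=FailureRates)
    common_snv_count: int = 6100
    x_snv_count: int = 200
    baseline_missingness: float = 0.005
    depth_mean: float = 60.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    low_gq_fraction: float = 0.03   # baseline mass below GQ 30
    male_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("cohort groups must be non-empty")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        genes = {f"G{i + 1:05d}" for i in range(self.n_genes)}
        for sig in self.planted_signals:
            if sig.gene not in genes:
                raise ValueError(f"planted gene {sig.gene} not among the {self.n_genes} genes")
            if sig.mode == "exact_counts":
                if sig.case_carriers > self.n_case:
                    raise ValueError(
                        f"gene {sig.gene}: {sig.case_carriers} case carriers exceed "
                        f"{self.n_case} cases"
                    )
                if sig.control_carriers > self.n_control:
                    raise ValueError(
                        f"gene {sig.gene}: {sig.control_carriers} control carriers "
                        f"exceed {self.n_control} controls"
                    )

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class CohortTruth:
    """Ground truth of planted signals and injected failures."""

    planted: list[dict] = field(default_factory=list)
    failures: dict[str, list] = field(default_factory=dict)
    true_maf: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"planted": self.planted, "failures": self.failures,
             "true_maf": self.true_maf},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        d = json.loads(text)
        return cls(planted=d["planted"], failures=d["failures"],
                   true_maf=d["true_maf"])


@dataclass
class Cohort:
    """In-memory synthetic cohort: genotypes, metadata, annotations, truth."""

    genotypes: np.ndarray       # (n_variants, n_samples) int8; -1 missing
    gq: np.ndarray              # (n_variants, n_samples) int16
    ad: np.ndarray              # (n_variants, n_samples, 2) int32 ref/alt
    variants: pd.DataFrame      # chrom, pos, ref, alt, variant_key, subset
    samples: pd.DataFrame       # sample_id, status, reported_sex, true_sex
    annotations: pd.DataFrame   # per-variant annotation table
    truth: CohortTruth

    @property
    def case_mask(self) -> np.ndarray:
        return (self.samples["status"] == "case").to_numpy()

    @property
    def common_snv_rows(self) -> np.ndarray:
        return np.flatnonzero((self.variants["subset"] == "common_snv").to_numpy())

    @property
    def x_rows(self) -> np.ndarray:
        return np.flatnonzero((self.variants["subset"] == "x_check").to_numpy())

    @property
    def rare_rows(self) -> np.ndarray:
        return np.flatnonzero((self.variants["subset"] == "rare").to_numpy())


def _draw_metadata(
    rng: np.random.Generator,
    genotypes: np.ndarray,
    depth_mean: float,
    depth_dispersion: float,
    low_gq_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """GQ and allelic-depth arrays consistent with the genotype calls."""
    shape = genotypes.shape
    r = depth_dispersion
    depth = rng.negative_binomial(r, r / (r + depth_mean), size=shape).astype(np.int32)
    depth = np.maximum(depth, 8)  # exome-like floor; supports GQ/AB filters
    gq = np.where(
        rng.random(shape) < low_gq_fraction,
        rng.integers(5, 30, size=shape),
        rng.integers(30, 100, size=shape),
    ).astype(np.int16)
    alt = np.zeros(shape, dtype=np.int32)
    het = genotypes == 1
    alt[het] = rng.binomial(depth[het], 0.5)
    hom = genotypes == 2
    alt[hom] = depth[hom]
    ad = np.stack([depth - alt, alt], axis=-1)
    return gq, ad


def _hwe_genotypes(rng: np.random.Generator, maf: np.ndarray, n: int) -> np.ndarray:
    return rng.binomial(2, maf[:, None], size=(maf.size, n)).astype(np.int8)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort under the given study conditions.

    Null genes draw genotypes identically for cases and controls; planted
    genes receive one extra qualifying variant realising the requested
    carrier configuration (exact counts) or carrier relative risk.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    n_case = config.n_case

    # --- samples ----------------------------------------------------------
    sample_ids = [f"case_{i + 1:04d}" for i in range(n_case)] + [
        f"ctrl_{i + 1:04d}" for i in range(config.n_control)
    ]
    status = ["case"] * n_case + ["control"] * config.n_control
    true_sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "status": status,
         "reported_sex": true_sex.copy(), "true_sex": true_sex}
    )

    truth = CohortTruth()
    genes = config.gene_names
    planted_by_gene = {s.gene: s for s in config.planted_signals}
    planted_rows: list[int] = []

    # --- rare exonic variants ---------------------------------------------
    n_per_gene = np.maximum(rng.poisson(config.variants_per_gene_mean, config.n_genes), 1)
    blocks: list[np.ndarray] = []
    var_rows: list[dict] = []
    ann_rows: list[dict] = []
    cons_names = list(CONSEQUENCE_FREQS)
    cons_probs = np.array(list(CONSEQUENCE_FREQS.values()))
    pos_counter = {}

    def next_pos(chrom: str) -> int:
        pos_counter[chrom] = pos_counter.get(chrom, 10_000) + int(rng.integers(50, 2_000))
        return pos_counter[chrom]

    for gi, gene in enumerate(genes):
        chrom = str(gi % 22 + 1)
        k = int(n_per_gene[gi])
        mafs = config.maf_spectrum.draw_rare(rng, k)
        geno = _hwe_genotypes(rng, mafs, n)
        cons = rng.choice(cons_names, size=k, p=cons_probs)
        if gene in planted_by_gene:
            # planted genes carry only the planted qualifying variant so the
            # requested carrier configuration is realised exactly
            cons = np.full(k, "synonymous", dtype=object)
        for vi in range(k):
            pos = next_pos(chrom)
            is_indel = cons[vi] in (
                "frameshift", "inframe_insertion", "inframe_deletion"
            )
            ref, alt_allele = ("AT", "A") if is_indel else ("A", "G")
            key = f"{chrom}:{pos}:{ref}:{alt_allele}"
            condel = "not_applicable"
            if cons[vi] == "missense":
                condel = (
                    "damaging"
                    if rng.random() < CONDEL_DAMAGING_FRACTION
                    else "benign"
                )
            var_rows.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt_allele,
                 "variant_key": key, "subset": "rare"}
            )
            ann_rows.append(
                {"variant_key": key, "gene": gene, "consequence": cons[vi],
                 "condel": condel, "alignability": 1.0,
                 "repeat_distance": int(rng.integers(100, 10_000)),
                 "tranche": float(rng.uniform(90.0, 98.5)),
                 "is_snv": not is_indel}
            )
            truth.true_maf[key] = float(mafs[vi])
        blocks.append(geno)

        # planted signal: one extra qualifying variant for this gene
        sig = planted_by_gene.get(gene)
        if sig is not None:
            pos = next_pos(chrom)
            is_indel = sig.variant_class == 1 and CLASS_CONSEQUENCE[1] == "frameshift"
            ref, alt_allele = ("A", "T")
            key = f"{chrom}:{pos}:{ref}:{alt_allele}"
            row = np.zeros(n, dtype=np.int8)
            if sig.mode == "exact_counts":
                cases = rng.choice(n_case, sig.case_carriers, replace=False)
                ctrls = n_case + rng.choice(
                    config.n_control, sig.control_carriers, replace=False
                )
                carriers = np.concatenate([cases, ctrls]).astype(int)
            else:
                c0 = sig.carrier_freq
                c1 = sig.rr * c0 / (1 - c0 + sig.rr * c0)
                is_carrier = np.concatenate([
                    rng.random(n_case) < c1,
                    rng.random(config.n_control) < c0,
                ])
                carriers = np.flatnonzero(is_carrier)
            w = sig.weights
            for ci, s_idx in enumerate(carriers):
                mult = w[ci] if w is not None and ci < len(w) else 1
                row[s_idx] = min(int(mult), 2)
            cons_name = CLASS_CONSEQUENCE[sig.variant_class]
            condel = "not_applicable"
            if cons_name == "missense":
                condel = "damaging" if sig.variant_class == 2 else "benign"
            var_rows.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt_allele,
                 "variant_key": key, "subset": "rare"}
            )
            ann_rows.append(
                {"variant_key": key, "gene": gene, "consequence": cons_name,
                 "condel": condel, "alignability": 1.0,
                 "repeat_distance": int(rng.integers(100, 10_000)),
                 "tranche": float(rng.uniform(90.0, 98.5)),
                 "is_snv": True}
            )
            planted_rows.append(len(var_rows) - 1)
            truth.true_maf[key] = float(row.sum() / (2 * n))
            truth.planted.append(
                {"gene": gene, "variant_key": key,
                 "variant_class": sig.variant_class,
                 "samples": [sample_ids[i] for i in carriers],
                 "case_carriers": int((carriers < n_case).sum()),
                 "control_carriers": int((carriers >= n_case).sum())}
            )
            blocks.append(row[None, :])

    # --- designated common-SNV subset (autosomal, for sample QC) ----------
    common_maf = rng.uniform(
        config.maf_spectrum.common_min, config.maf_spectrum.common_max,
        config.common_snv_count,
    )
    common_geno = _hwe_genotypes(rng, common_maf, n)
    for i in range(config.common_snv_count):
        chrom = str(int(rng.integers(1, 23)))
        pos = next_pos(chrom)
        key = f"{chrom}:{pos}:C:T"
        var_rows.append(
            {"chrom": chrom, "pos": pos, "ref": "C", "alt": "T",
             "variant_key": key, "subset": "common_snv"}
        )
        ann_rows.append(
            {"variant_key": key, "gene": ".", "consequence": "other",
             "condel": "not_applicable", "alignability": 1.0,
             "repeat_distance": int(rng.integers(100, 10_000)),
             "tranche": float(rng.uniform(90.0, 98.5)), "is_snv": True}
        )
        truth.true_maf[key] = float(common_maf[i])
    blocks.append(common_geno)

    # --- X-chromosome block for sex inference ------------------------------
    x_maf = rng.uniform(0.2, 0.5, config.x_snv_count)
    male = true_sex == "M"
    x_geno = np.empty((config.x_snv_count, n), dtype=np.int8)
    x_geno[:, ~male] = _hwe_genotypes(rng, x_maf, int((~male).sum()))
    # hemizygous males: a single allele, coded 0/2, never heterozygous
    x_geno[:, male] = 2 * rng.binomial(1, x_maf[:, None], size=(config.x_snv_count, int(male.sum()))).astype(np.int8)
    for i in range(config.x_snv_count):
        pos = next_pos("X")
        key = f"X:{pos}:G:A"
        var_rows.append(
            {"chrom": "X", "pos": pos, "ref": "G", "alt": "A",
             "variant_key": key, "subset": "x_check"}
        )
        ann_rows.append(
            {"variant_key": key, "gene": ".", "consequence": "other",
             "condel": "not_applicable", "alignability": 1.0,
             "repeat_distance": int(rng.integers(100, 10_000)),
             "tranche": float(rng.uniform(90.0, 98.5)), "is_snv": True}
        )
        truth.true_maf[key] = float(x_maf[i])
    blocks.append(x_geno)

    genotypes = np.vstack(blocks)

    # baseline no-calls; planted rows stay fully called so that exact-count
    # configurations survive downstream filtering unchanged
    miss = rng.random(genotypes.shape) < config.baseline_missingness
    if planted_rows:
        miss[planted_rows, :] = False
    genotypes = np.where(miss, MISSING, genotypes).astype(np.int8)

    gq, ad = _draw_metadata(
        rng, genotypes, config.depth_mean, config.depth_dispersion,
        config.low_gq_fraction,
    )
    if planted_rows:
        # guaranteed-supported calls at planted sites (GQ 99, depth 60)
        pr = np.asarray(planted_rows)
        gq[pr, :] = 99
        pg = genotypes[pr, :]
        alt = np.where(pg == 1, 30, np.where(pg == 2, 60, 0))
        ad[pr, :, 0] = 60 - alt
        ad[pr, :, 1] = alt

    variants = pd.DataFrame(var_rows)
    annotations = pd.DataFrame(ann_rows)
    cohort = Cohort(
        genotypes=genotypes, gq=gq, ad=ad, variants=variants,
        samples=samples, annotations=annotations, truth=truth,
    )
    if any(asdict(config.failure_rates).values()):
        cohort = inject_qc_failures(cohort, config)
    return cohort


def inject_qc_failures(cohort: Cohort, config: SimulationConfig) -> Cohort:
    """Inject the configured QC failure modes, logging each in the truth.

    Uses a child RNG of the config seed so injection is deterministic and
    independent of whether it runs inside or after ``simulate_cohort``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    fr = config.failure_rates
    g = cohort.genotypes
    n = g.shape[1]
    common = cohort.common_snv_rows
    failures = cohort.truth.failures
    sample_ids = cohort.samples["sample_id"].to_numpy()
    reserved: set[int] = set()

    def pick_samples(k: int) -> np.ndarray:
        avail = np.setdiff1d(np.arange(n), np.fromiter(reserved, int, len(reserved)))
        chosen = rng.choice(avail, size=k, replace=False)
        reserved.update(int(i) for i in chosen)
        return chosen

    # sample-level modes -----------------------------------------------------
    k_miss = round(fr.missingness_outlier * n)
    if k_miss:
        chosen = pick_samples(k_miss)
        extra_rate = min(10 * config.baseline_missingness, 0.5)
        for s in chosen:
            hit = rng.random(common.size) < extra_rate
            g[common[hit], s] = MISSING
        failures["missingness_outlier"] = [sample_ids[s] for s in chosen]

    k_het = round(fr.heterozygosity_outlier * n)
    if k_het:
        chosen = pick_samples(k_het)
        for s in chosen:
            called = common[g[common, s] != MISSING]
            flip = called[rng.random(called.size) < 0.8]
            g[flip, s] = 1
        failures["heterozygosity_outlier"] = [sample_ids[s] for s in chosen]

    k_dup = round(fr.duplicate_pair * n / 2)
    if k_dup:
        if k_dup > (n - len(reserved)) // 2:
            raise ValueError(
                "more duplicate pairs requested than available sample pairs "
                f"(floor(n/2) after other sample-level injections): {k_dup}"
            )
        pairs = []
        for _ in range(k_dup):
            a, b = pick_samples(2)
            g[:, b] = g[:, a]
            cohort.gq[:, b] = cohort.gq[:, a]
            cohort.ad[:, b] = cohort.ad[:, a]
            pairs.append([sample_ids[a], sample_ids[b]])
        failures["duplicate_pair"] = pairs

    k_sex = round(fr.sex_mismatch * n)
    if k_sex:
        chosen = pick_samples(k_sex)
        rep = cohort.samples["reported_sex"].to_numpy(copy=True)
        rep[chosen] = np.where(rep[chosen] == "M", "F", "M")
        cohort.samples["reported_sex"] = rep
        failures["sex_mismatch"] = [sample_ids[s] for s in chosen]

    # variant-level modes ----------------------------------------------------
    n_rare = cohort.rare_rows.size
    k_hwe = round(fr.hwe_violating_site * n_rare)
    if k_hwe:
        new_rows = []
        for i in range(k_hwe):
            chrom = str(int(rng.integers(1, 23)))
            pos = 90_000_000 + i * 1_000 + int(rng.integers(0, 999))
            key = f"{chrom}:{pos}:T:C"
            row = np.zeros(n, dtype=np.int8)
            carriers = rng.choice(n, size=12, replace=False)
            row[carriers] = 2  # all carriers homozygous alternate: gross HWE violation
            new_rows.append((key, chrom, pos, row))
        add_g = np.stack([r[3] for r in new_rows])
        cohort.genotypes = np.vstack([g, add_g])
        add_gq, add_ad = _draw_metadata(
            rng, add_g, config.depth_mean, config.depth_dispersion,
            config.low_gq_fraction,
        )
        cohort.gq = np.vstack([cohort.gq, add_gq])
        cohort.ad = np.concatenate([cohort.ad, add_ad], axis=0)
        cohort.variants = pd.concat(
            [cohort.variants, pd.DataFrame([
                {"chrom": c, "pos": p, "ref": "T", "alt": "C",
                 "variant_key": k, "subset": "rare"}
                for k, c, p, _ in new_rows
            ])], ignore_index=True,
        )
        cohort.annotations = pd.concat(
            [cohort.annotations, pd.DataFrame([
                {"variant_key": k, "gene": ".", "consequence": "other",
                 "condel": "not_applicable", "alignability": 1.0,
                 "repeat_distance": 5_000, "tranche": 95.0, "is_snv": True}
                for k, _c, _p, _r in new_rows
            ])], ignore_index=True,
        )
        failures["hwe_violating_site"] = [k for k, _, _, _ in new_rows]
        g = cohort.genotypes

    k_rep = round(fr.repeat_proximal_site * n_rare)
    if k_rep:
        rows = rng.choice(cohort.rare_rows, size=k_rep, replace=False)
        keys = cohort.variants["variant_key"].to_numpy()[rows]
        ann = cohort.annotations.set_index("variant_key")
        ann.loc[keys, "repeat_distance"] = rng.integers(0, 11, size=k_rep)
        cohort.annotations = ann.reset_index()
        failures["repeat_proximal_site"] = list(keys)

    if fr.low_gq_genotype:
        nonref = np.argwhere(g > 0)
        hit = nonref[rng.random(nonref.shape[0]) < fr.low_gq_genotype]
        cohort.gq[hit[:, 0], hit[:, 1]] = rng.integers(5, 30, size=hit.shape[0]).astype(np.int16)
        vk = cohort.variants["variant_key"].to_numpy()
        failures["low_gq_genotype"] = [
            [vk[vi], sample_ids[si]] for vi, si in hit
        ]

    if fr.allele_imbalanced_het:
        hets = np.argwhere(g == 1)
        hit = hets[rng.random(hets.shape[0]) < fr.allele_imbalanced_het]
        depth = cohort.ad[hit[:, 0], hit[:, 1]].sum(axis=1)
        depth = np.maximum(depth, 30)  # enough reads for the imbalance to register
        alt = rng.binomial(depth, 0.1)
        cohort.ad[hit[:, 0], hit[:, 1], 0] = depth - alt
        cohort.ad[hit[:, 0], hit[:, 1], 1] = alt
        vk = cohort.variants["variant_key"].to_numpy()
        failures["allele_imbalanced_het"] = [
            [vk[vi], sample_ids[si]] for vi, si in hit
        ]

    return cohort


# ---------------------------------------------------------------------------
# writing to disk
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as VCF + sample sheet + annotation table + truth JSON.

    The VCF is plain text, v4.2, FORMAT GT:GQ:AD, sorted by chromosome and
    position; it round-trips losslessly through :func:`burdenscan.io.read_vcf`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "samples": out / "samples.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.json",
    }

    order = cohort.variants.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
        kind="mergesort",
    ).index.to_numpy()

    sample_ids = cohort.samples["sample_id"].tolist()
    contigs = list(dict.fromkeys(cohort.variants["chrom"].iloc[order]))
    with open(paths["vcf"], "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for vi in order:
            v = cohort.variants.iloc[vi]
            gts = cohort.genotypes[vi]
            gqs = cohort.gq[vi]
            ads = cohort.ad[vi]
            fields = [
                f"{_GT_STR[int(gt)]}:{int(q)}:{int(a[0])},{int(a[1])}"
                for gt, q, a in zip(gts, gqs, ads)
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_key}\t{v.ref}\t{v.alt}\t.\t"
                f"PASS\t.\tGT:GQ:AD\t" + "\t".join(fields) + "\n"
            )

    cohort.samples[["sample_id", "status", "reported_sex"]].to_csv(
        paths["samples"], sep="\t", index=False
    )
    cohort.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    paths["truth"].write_text(cohort.truth.to_json())
    return paths


def _chrom_sort_key(c: str) -> int:
    try:
        return int(c)
    except ValueError:
        return {"X": 23, "Y": 24, "MT": 25}.get(c, 99)
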