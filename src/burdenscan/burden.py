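"""Gene-level collapsing (T1) burden test with an exact permutation null.

The burden statistic for a gene is S = total number of qualifying alternate
alleles observed in case samples. Under the null hypothesis that case/control
labels are exchangeable, S follows the distribution induced by drawing, without
replacement, which of the N = n_case + n_control samples are cases. Only
carrier samples (weight > 0) affect S, so the null is a weighted hypergeometric
law over the K carrier weights: the number of carriers landing in the case
group is Hypergeom(N, K, n_case), and conditional on that count the carrier
subset is uniform.

P-values use the one-sided mid-P convention by default:

    P = Pr(S > S_obs) + 1/2 * Pr(S = S_obs)

which removes most of the conservatism of the discrete exact test; the plain
tail Pr(S >= S_obs) is available via ``convention="tail"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationNull",
    "BurdenResult",
    "collapse_gene",
    "exact_permutation_midp",
    "monte_carlo_permutation_midp",
    "burden_scan",
    "csg_panel_test",
    "loh_binomial_test",
]

#: carriers above this count are routed to Monte-Carlo permutation by default
EXACT_PATH_MAX_CARRIERS = 500


@dataclass
class PermutationNull:
    """Exact null distribution of the case allele total S for one gene.

    Attributes
    ----------
    weights : integer allele counts of the K carrier samples (all >= 1).
    n_case, n_control : cohort group sizes (carriers and non-carriers alike).
    support : attainable values of S (0 .. sum(weights)).
    pmf : probability of each support value; sums to 1 within 1e-12.
    """

    weights: np.ndarray
    n_case: int
    n_control: int
    support: np.ndarray = field(init=False)
    pmf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.int64)
        if w.size and w.min() < 1:
            raise ValueError("carrier weights must be positive integers")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both groups must be non-empty")
        self.weights = w
        self.support, self.pmf = _exact_null_distribution(
            w, self.n_case, self.n_control
        )

    @property
    def n_carriers(self) -> int:
        return int(self.weights.size)

    def sf_midp(self, s_obs: int) -> float:
        """One-sided mid-P: Pr(S > s_obs) + 0.5 * Pr(S = s_obs)."""
        return self._tail(s_obs, midp=True)

    def sf_tail(self, s_obs: int) -> float:
        """Plain one-sided tail Pr(S >= s_obs)."""
        return self._tail(s_obs, midp=False)

    def _tail(self, s_obs: int, midp: bool) -> float:
        if not 0 <= s_obs <= int(self.weights.sum()):
            raise ValueError(
                f"observed statistic {s_obs} outside the null support "
                f"[0, {int(self.weights.sum())}]"
            )
        above = float(self.pmf[self.support > s_obs].sum())
        at = float(self.pmf[self.support == s_obs].sum())
        p = above + (0.5 * at if midp else at)
        # guard against round-off leaving the (0, 1] interval
        return float(min(max(p, 5e-324), 1.0))


def _exact_null_distribution(
    weights: np.ndarray, n_case: int, n_control: int
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of S = sum of weights assigned to the case group.

    Uses the closed-form hypergeometric when all weights are 1; otherwise a
    subset-sum convolution: count m-subsets of the weights by their sum, then
    mix over m with hypergeometric probabilities.
    """
    K = weights.size
    N = n_case + n_control
    if K == 0:
        return np.array([0]), np.array([1.0])
    if K > N:
        raise ValueError("more carriers than samples")

    m_pmf = stats.hypergeom.pmf(np.arange(K + 1), N, K, n_case)

    if np.all(weights == 1):
        return np.arange(K + 1), m_pmf

    total = int(weights.sum())
    # counts[m, s] = number of m-subsets of weights summing to s
    counts = np.zeros((K + 1, total + 1))
    counts[0, 0] = 1.0
    for w in weights:
        counts[1:, w:] += counts[:-1, : total + 1 - w]

    # normalise each m-row to a conditional pmf of S given m carriers in cases
    binom = np.array([math.comb(K, m) for m in range(K + 1)], dtype=float)
    cond = counts / binom[:, None]
    pmf = m_pmf @ cond
    pmf /= pmf.sum()
    return np.arange(total + 1), pmf


def exact_permutation_midp(
    null: PermutationNull, s_obs: int, convention: str = "midp"
) -> float:
    """Exact one-sided permutation P for the observed case allele total.

    ``convention`` selects mid-P (default) or the plain tail.
    """
    if convention == "midp":
        return null.sf_midp(s_obs)
    if convention == "tail":
        return null.sf_tail(s_obs)
    raise ValueError(f"unknown P-value convention {convention!r}")


def monte_carlo_permutation_midp(
    weights: np.ndarray,
    status: np.ndarray,
    B: int,
    seed: int,
    convention: str = "midp",
) -> tuple[float, float]:
    """Monte-Carlo permutation P by resampling case/control labels.

    Parameters
    ----------
    weights : per-carrier qualifying allele counts (only carriers).
    status : boolean case indicator for **all** samples; its length fixes the
        group sizes and its carrier prefix is irrelevant — S_obs is supplied
        by the true assignment of carriers, passed as the first
        ``sum(weights_in_cases)`` convention below.
    B : number of label permutations (>= 1000).
    seed : RNG seed; results are deterministic given it.

    Returns ``(P_hat, mc_se)`` where mc_se is the binomial standard error.

    Notes
    -----
    ``status`` must be aligned with ``weights``: entry i of ``weights`` is the
    weight of carrier i and ``status`` carries one label per sample with the
    first K entries corresponding to the carriers.
    """
    if B < 1_000:
        raise ValueError("B must be at least 1000")
    weights = np.asarray(weights, dtype=np.int64)
    status = np.asarray(status, dtype=bool)
    K = weights.size
    if K > status.size:
        raise ValueError("more carrier weights than samples")
    n_case = int(status.sum())
    n_control = int(status.size - n_case)
    s_obs = int(weights[status[:K]].sum())

    rng = np.random.default_rng(seed)
    # number of carriers assigned to the case group per permutation
    m = rng.hypergeometric(n_case, n_control, K, size=B)

    vals, cnts = np.unique(weights, return_counts=True)
    if vals.size == 1:
        S = m * vals[0]
    else:
        S = np.empty(B, dtype=np.int64)
        for mu in np.unique(m):
            sel = m == mu
            draws = rng.multivariate_hypergeometric(cnts, int(mu), size=int(sel.sum()))
            S[sel] = draws @ vals

    gt = np.count_nonzero(S > s_obs)
    eq = np.count_nonzero(S == s_obs)
    if convention == "midp":
        p_hat = (gt + 0.5 * eq) / B
    elif convention == "tail":
        p_hat = (gt + eq) / B
    else:
        raise ValueError(f"unknown P-value convention {convention!r}")
    mc_se = math.sqrt(max(p_hat * (1 - p_hat), 0.0) / B)
    return float(p_hat), float(mc_se)


@dataclass
class BurdenResult:
    """Per (gene, class) burden outcome."""

    gene: str
    class_id: int
    s_obs: int
    case_samples: int
    control_samples: int
    unique_total: int
    unique_case: int
    unique_control: int
    p: float
    method: str  # "exact" | "monte_carlo"
    mc_B: int | None = None
    mc_se: float | None = None
    significant: bool = False


def collapse_gene(
    sample_weights: np.ndarray,
    case_mask: np.ndarray,
    variant_case_carrier: np.ndarray | None = None,
    variant_control_carrier: np.ndarray | None = None,
) -> dict:
    """Collapse one gene/class into the T1 ingredients.

    ``sample_weights`` holds each sample's qualifying alternate-allele count;
    non-carriers carry weight 0 and enter the null analytically via the group
    sizes. Optional per-variant carrier indicators give the unique-variant
    bookkeeping (distinct variants seen overall / in cases / in controls).
    """
    w = np.asarray(sample_weights, dtype=np.int64)
    case_mask = np.asarray(case_mask, dtype=bool)
    if w.shape != case_mask.shape:
        raise ValueError("weights and case mask must align")
    carrier = w > 0
    out = {
        "s_obs": int(w[case_mask].sum()),
        "carrier_weights": w[carrier],
        "carrier_is_case": case_mask[carrier],
        "case_samples": int((carrier & case_mask).sum()),
        "control_samples": int((carrier & ~case_mask).sum()),
        "n_case": int(case_mask.sum()),
        "n_control": int((~case_mask).sum()),
    }
    if variant_case_carrier is not None and variant_control_carrier is not None:
        vc = np.asarray(variant_case_carrier, dtype=bool)
        vu = np.asarray(variant_control_carrier, dtype=bool)
        out["unique_case"] = int(vc.sum())
        out["unique_control"] = int(vu.sum())
        out["unique_total"] = int((vc | vu).sum())
    return out


def _gene_class_p(
    collapsed: dict,
    convention: str,
    exact_max_carriers: int,
    mc_B: int,
    seed: int,
) -> tuple[float, str, float | None]:
    """Route one collapsed gene/class to the exact or Monte-Carlo path."""
    w = collapsed["carrier_weights"]
    if w.size <= exact_max_carriers:
        null = PermutationNull(w, collapsed["n_case"], collapsed["n_control"])
        return exact_permutation_midp(null, collapsed["s_obs"], convention), "exact", None
    status = np.zeros(collapsed["n_case"] + collapsed["n_control"], dtype=bool)
    # carriers first (true labels), remaining case slots after them
    k = w.size
    status[:k] = collapsed["carrier_is_case"]
    extra = collapsed["n_case"] - int(collapsed["carrier_is_case"].sum())
    status[k : k + extra] = True
    p, se = monte_carlo_permutation_midp(w, status, mc_B, seed, convention)
    return p, "monte_carlo", se


def burden_scan(
    gene_class_sets: dict[tuple[str, int], "object"],
    case_mask: np.ndarray,
    min_samples: int = 10,
    alpha: float = 0.05,
    convention: str = "midp",
    exact_max_carriers: int = EXACT_PATH_MAX_CARRIERS,
    mc_B: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Burden-test every admissible gene across the three variant classes.

    A gene is admitted when its Class 3 (widest class) carrier-sample count is
    at least ``min_samples``; all three class tests are then computed for the
    classes with at least one carrier. The exome-wide significance threshold is
    ``alpha`` divided by the number of tests actually computed. The output is
    sorted by per-gene minimum P (ties broken by gene symbol).
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    genes = sorted({g for (g, _c) in gene_class_sets})

    rows: list[BurdenResult] = []
    for gene in genes:
        class3 = gene_class_sets.get((gene, 3))
        if class3 is None:
            continue
        carriers3 = int((np.asarray(class3.sample_weights) > 0).sum())
        if carriers3 < min_samples:
            continue
        for class_id in (1, 2, 3):
            gcs = gene_class_sets.get((gene, class_id))
            if gcs is None or not len(gcs.variant_keys):
                continue
            col = collapse_gene(
                gcs.sample_weights,
                case_mask,
                gcs.variant_case_carrier,
                gcs.variant_control_carrier,
            )
            if col["case_samples"] + col["control_samples"] == 0:
                continue
            p, method, se = _gene_class_p(
                col, convention, exact_max_carriers, mc_B, seed
            )
            rows.append(
                BurdenResult(
                    gene=gene,
                    class_id=class_id,
                    s_obs=col["s_obs"],
                    case_samples=col["case_samples"],
                    control_samples=col["control_samples"],
                    unique_total=col.get("unique_total", 0),
                    unique_case=col.get("unique_case", 0),
                    unique_control=col.get("unique_control", 0),
                    p=p,
                    method=method,
                    mc_B=mc_B if method == "monte_carlo" else None,
                    mc_se=se,
                )
            )

    if not rows:
        return pd.DataFrame(
            columns=[
                "gene", "class_id", "p", "s_obs", "case_samples",
                "control_samples", "unique_total", "unique_case",
                "unique_control", "method", "mc_B", "mc_se", "significant",
                "threshold",
            ]
        )

    n_tests = len(rows)
    threshold = alpha / n_tests
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["significant"] = df["p"] < threshold
    df["threshold"] = threshold
    min_p = df.groupby("gene")["p"].transform("min")
    df = (
        df.assign(_min_p=min_p)
        .sort_values(["_min_p", "gene", "class_id"], kind="mergesort")
        .drop(columns="_min_p")
        .reset_index(drop=True)
    )
    return df


def csg_panel_test(
    burden_results: pd.DataFrame, gene_list: list[str], alpha: float = 0.05
) -> dict:
    """Focused assessment of an a-priori susceptibility-gene panel.

    The multiple-testing threshold is ``alpha / len(gene_list)`` (0.05 / 114 =
    4.4e-4 for the canonical 114-gene cancer panel), applied per class to the
    panel genes that were actually burden-tested.
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    gene_list = list(dict.fromkeys(gene_list))
    threshold = alpha / len(gene_list)
    tested = burden_results[burden_results["gene"].isin(gene_list)].copy()
    untested = sorted(set(gene_list) - set(tested["gene"]))
    if len(tested):
        tested["panel_significant"] = tested["p"] < threshold
    return {
        "threshold": threshold,
        "n_panel_genes": len(gene_list),
        "results": tested,
        "untested_genes": untested,
    }


def loh_binomial_test(n_informative: int, n_wildtype_lost: int) -> float:
    """One-sided binomial test for preferential loss of the wild-type allele.

    P = Pr(X >= n_wildtype_lost) with X ~ Binomial(n_informative, 1/2):
    under no preference, either allele is equally likely to be lost in a
    tumour with loss of heterozygosity.
    """
    if n_informative < 0 or n_wildtype_lost < 0:
        raise ValueError("counts must be non-negative")
    if n_wildtype_lost > n_informative:
        raise ValueError("losses cannot exceed informative carriers")
    return float(stats.binom.sf(n_wildtype_lost - 1, n_informative, 0.5))
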