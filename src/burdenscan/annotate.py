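"""Consequence annotation handling and nested variant-class assignment.

For each variant-gene pair the single most deleterious consequence is kept,
under the severity hierarchy

    stop_gained > frameshift > splice_acceptor = splice_donor
    > inframe_insertion = inframe_deletion > missense > synonymous > other

Qualifying variants are then binned into three nested severity classes:

* Class 1 "disruptive" — stop-gained and frameshift;
* Class 2 "predicted damaging" — Class 1 plus splice acceptor/donor and
  missense calls labelled damaging by a CONDEL-style predictor;
* Class 3 "all non-synonymous" — Class 2 plus the remaining non-synonymous
  variants (benign missense, in-frame insertions/deletions).

Membership is cumulative downward: a Class-1 variant belongs to the Class-2
and Class-3 sets too. Only variants rare in the combined cohort (MAF below
1% by default) qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConsequenceAnnotation",
    "GeneClassSet",
    "CONSEQUENCE_SEVERITY",
    "select_worst_consequence",
    "assign_class",
    "build_gene_class_sets",
]

# larger rank = more severe; splice acceptor/donor tie, as do inframe indels
CONSEQUENCE_SEVERITY: dict[str, int] = {
    "stop_gained": 7,
    "frameshift": 6,
    "splice_acceptor": 5,
    "splice_donor": 5,
    "inframe_insertion": 4,
    "inframe_deletion": 4,
    "missense": 3,
    "synonymous": 2,
    "other": 1,
}


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """Worst-consequence annotation of one variant for one gene."""

    variant_key: str
    gene: str
    consequence: str
    condel_label: str = "not_applicable"  # damaging | benign | not_applicable

    def __post_init__(self) -> None:
        if self.condel_label not in ("damaging", "benign", "not_applicable"):
            raise ValueError(f"unknown CONDEL label {self.condel_label!r}")
        if self.condel_label != "not_applicable" and self.consequence != "missense":
            raise ValueError("CONDEL labels apply to missense variants only")


def select_worst_consequence(
    annotations: list[ConsequenceAnnotation],
) -> ConsequenceAnnotation:
    """Pick the most severe annotation for a single variant-gene pair."""
    if not annotations:
        raise ValueError("no annotations supplied")
    ranks = [CONSEQUENCE_SEVERITY.get(a.consequence, 0) for a in annotations]
    return annotations[int(np.argmax(ranks))]


def assign_class(
    annotation: ConsequenceAnnotation, strict: bool = False
) -> int | None:
    """Most severe class of a worst-consequence annotation (1, 2, 3 or None).

    A variant of class c belongs to every set with class id >= c; synonymous
    and non-coding consequences qualify for no class. Unknown consequence
    terms raise when ``strict`` and otherwise fall through to "other".
    """
    cons = annotation.consequence
    if cons not in CONSEQUENCE_SEVERITY:
        if strict:
            raise ValueError(f"unknown consequence term {cons!r}")
        cons = "other"
    if cons in ("stop_gained", "frameshift"):
        return 1
    if cons in ("splice_acceptor", "splice_donor"):
        return 2
    if cons == "missense":
        return 2 if annotation.condel_label == "damaging" else 3
    if cons in ("inframe_insertion", "inframe_deletion"):
        return 3
    return None


@dataclass
class GeneClassSet:
    """Qualifying-variant set of one gene for one nested class."""

    gene: str
    class_id: int
    variant_keys: list[str]
    sample_weights: np.ndarray  # per-sample qualifying alt-allele count
    variant_case_carrier: np.ndarray = field(default_factory=lambda: np.array([], bool))
    variant_control_carrier: np.ndarray = field(default_factory=lambda: np.array([], bool))

    @property
    def unique_total(self) -> int:
        return int((self.variant_case_carrier | self.variant_control_carrier).sum())

    @property
    def unique_case(self) -> int:
        return int(self.variant_case_carrier.sum())

    @property
    def unique_control(self) -> int:
        return int(self.variant_control_carrier.sum())


def _combined_maf(genotypes: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency over called alleles, cases + controls."""
    g = np.asarray(genotypes)
    called = g >= 0
    alt = np.where(called, g, 0).sum(axis=1)
    tot = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    return freq


def build_gene_class_sets(
    genotypes: np.ndarray,
    variant_keys: np.ndarray | list[str],
    annotations: pd.DataFrame,
    case_mask: np.ndarray,
    maf_threshold: float = 0.01,
    reference_maf: pd.Series | None = None,
    strict: bool = False,
) -> dict[tuple[str, int], GeneClassSet]:
    """Assemble the nested qualifying-variant sets for every gene.

    Parameters
    ----------
    genotypes : QC-passed (variants x samples) matrix, -1 missing.
    variant_keys : key per matrix row ("chrom:pos:ref:alt").
    annotations : one row per variant-gene pair with at least ``variant_key``,
        ``gene``, ``consequence`` and ``condel`` columns (worst consequence
        already selected upstream).
    case_mask : boolean case indicator per sample.
    maf_threshold : a variant qualifies when its combined-cohort alternate
        allele frequency is below this (1% for the canonical T1 test).
    reference_maf : optional external reference frequency per variant key;
        when given, the same threshold applies to it as well.

    Returns a ``{(gene, class_id): GeneClassSet}`` mapping; genes with no
    qualifying variant in a class simply have no entry for it.
    """
    g = np.asarray(genotypes)
    keys = np.asarray(variant_keys)
    case_mask = np.asarray(case_mask, dtype=bool)
    key_to_row = {k: i for i, k in enumerate(keys)}

    freq = _combined_maf(g)
    rare = freq < maf_threshold
    if reference_maf is not None:
        ref = np.array([
            reference_maf.get(k, 0.0) for k in keys
        ])
        rare &= ref < maf_threshold

    # class of each annotated variant
    per_gene: dict[str, list[tuple[str, int]]] = {}
    for rec in annotations.itertuples(index=False):
        key = rec.variant_key
        row = key_to_row.get(key)
        if row is None or not rare[row]:
            continue
        ann = ConsequenceAnnotation(
            variant_key=key,
            gene=rec.gene,
            consequence=rec.consequence,
            condel_label=getattr(rec, "condel", "not_applicable"),
        )
        cls = assign_class(ann, strict=strict)
        if cls is None:
            continue
        per_gene.setdefault(rec.gene, []).append((key, cls))

    out: dict[tuple[str, int], GeneClassSet] = {}
    n_samples = g.shape[1]
    for gene, entries in per_gene.items():
        for class_id in (1, 2, 3):
            member_keys = sorted(k for k, c in entries if c <= class_id)
            if not member_keys:
                continue
            rows = np.array([key_to_row[k] for k in member_keys])
            sub = g[rows]
            alt = np.where(sub >= 0, sub, 0)
            weights = alt.sum(axis=0).astype(np.int64)
            carrier = alt > 0
            out[(gene, class_id)] = GeneClassSet(
                gene=gene,
                class_id=class_id,
                variant_keys=member_keys,
                sample_weights=weights,
                variant_case_carrier=carrier[:, case_mask].any(axis=1),
                variant_control_carrier=carrier[:, ~case_mask].any(axis=1),
            )
    return out
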