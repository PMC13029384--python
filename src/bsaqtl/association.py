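"""Single-marker trait association on individual-line genotypes.

Each biallelic marker (e.g. a KASP assay) is regressed on the trait by
ordinary least squares with additive dosage coding (0/1/2 copies of the
alternative allele). The report per marker is the convention of
marker-validation tables: R² (squared Pearson correlation), the two-sided
p-value of the slope (t statistic, n−2 df), PVE = 100·R², and per-genotype-
class trait summaries. Candidate screening keeps markers with R² above a
threshold (strictly greater; 0.3 by convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .phenotype import PhenotypeRecord

logger = logging.getLogger(__name__)

MISSING = "missing"
_CLASS_ORDER = ("AA", "AB", "BB", MISSING)


@dataclass(frozen=True)
class GenotypeCall:
    """One line's genotype at one marker.

    ``allele1``/``allele2`` record the base letters (e.g. T/C); the class is
    derived against a declared ref/alt pair at encoding time. ``None``
    alleles mean a missing call.
    """

    line_id: str
    marker_id: str
    allele1: str | None
    allele2: str | None

    @property
    def is_missing(self) -> bool:
        return self.allele1 is None or self.allele2 is None


@dataclass(frozen=True)
class ClassSummary:
    genotype_class: str
    n: int
    mean_hir: float
    min_hir: float
    max_hir: float


@dataclass(frozen=True)
class AssociationResult:
    marker_id: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    pve: float
    class_summaries: tuple[ClassSummary, ...] = ()

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")


def encode_dosage(call: GenotypeCall, ref_allele: str, alt_allele: str) -> int | None:
    """Count of alt-allele copies (0/1/2); missing propagates as None."""
    if call.is_missing:
        return None
    valid = {ref_allele, alt_allele}
    for a in (call.allele1, call.allele2):
        if a not in valid:
            raise ValueError(
                f"allele {a!r} at marker {call.marker_id!r} line {call.line_id!r} "
                f"is neither ref {ref_allele!r} nor alt {alt_allele!r}"
            )
    return (call.allele1 == alt_allele) + (call.allele2 == alt_allele)


def genotype_class(call: GenotypeCall, ref_allele: str, alt_allele: str) -> str:
    """AA/AB/BB class (A = ref allele) or 'missing'."""
    d = encode_dosage(call, ref_allele, alt_allele)
    if d is None:
        return MISSING
    return ("AA", "AB", "BB")[d]


def pve(r_squared: float) -> float:
    """Phenotypic variance explained: 100 × R² (percent)."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError(f"r_squared must lie in [0, 1], got {r_squared}")
    return 100.0 * r_squared


def fit_simple_regression(
    dosage: Sequence[float], hir: Sequence[float], marker_id: str = ""
) -> AssociationResult:
    """OLS of trait on dosage for one marker (complete cases only).

    Pairs with a missing dosage (None/NaN) or missing trait are dropped
    pairwise. Constant dosage is an error (CONSTANT_GENOTYPE); constant
    phenotype yields R² = 0 with a warning.
    """
    from .estimators import MarkerTraitRegression

    x = np.array([math.nan if d is None else float(d) for d in dosage], dtype=float)
    y = np.asarray(hir, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage and trait vectors must have equal length")
    est = MarkerTraitRegression().fit(x.reshape(-1, 1), y)
    return AssociationResult(
        marker_id=marker_id,
        n=est.n_used_,
        slope=est.slope_,
        intercept=est.intercept_,
        r_squared=est.r_squared_,
        p_value=est.p_value_,
        pve=est.pve_,
    )


def class_summary(
    calls: Sequence[GenotypeCall],
    phenotypes: Mapping[str, float] | Sequence[PhenotypeRecord],
    ref_allele: str,
    alt_allele: str,
) -> list[ClassSummary]:
    """Trait summaries (n, mean, min, max) per genotype class, AA/AB/BB order.

    Complete cases only; classes absent from the data are omitted. If every
    call is missing an empty list is returned with a warning.
    """
    pheno = _as_mapping(phenotypes)
    values: dict[str, list[float]] = {}
    for call in calls:
        cls = genotype_class(call, ref_allele, alt_allele)
        if cls == MISSING or call.line_id not in pheno:
            continue
        values.setdefault(cls, []).append(pheno[call.line_id])
    if not values:
        logger.warning("all genotype calls missing or unmatched; empty class summary")
        return []
    out = []
    for cls in ("AA", "AB", "BB"):
        if cls not in values:
            continue
        v = values[cls]
        out.append(
            ClassSummary(
                genotype_class=cls,
                n=len(v),
                mean_hir=float(np.mean(v)),
                min_hir=float(np.min(v)),
                max_hir=float(np.max(v)),
            )
        )
    return out


@dataclass(frozen=True)
class JointClassResult:
    """3x3 joint genotype-class summaries for a marker pair.

    ``welch_t``/``welch_p`` compare the two homozygous-extreme joint classes
    (all-favourable vs all-unfavourable homozygotes) as a descriptive
    statistic; NaN when either class has fewer than 2 lines.
    """

    summaries: dict[tuple[str, str], ClassSummary]
    favorable_class: tuple[str, str]
    unfavorable_class: tuple[str, str]
    welch_t: float
    welch_p: float


def combined_classes(
    calls_a: Sequence[GenotypeCall],
    calls_b: Sequence[GenotypeCall],
    phenotypes: Mapping[str, float] | Sequence[PhenotypeRecord],
    ref_alt_a: tuple[str, str],
    ref_alt_b: tuple[str, str],
) -> JointClassResult:
    """Joint two-marker genotype classes with per-class trait summaries.

    The favourable homozygote at each marker is the one with the higher
    class mean trait; Welch's t compares (favourable, favourable) against
    (unfavourable, unfavourable) lines.
    """
    pheno = _as_mapping(phenotypes)
    cls_a = {
        c.line_id: genotype_class(c, *ref_alt_a) for c in calls_a
    }
    cls_b = {
        c.line_id: genotype_class(c, *ref_alt_b) for c in calls_b
    }
    shared = [
        lid
        for lid in cls_a
        if lid in cls_b and lid in pheno and cls_a[lid] != MISSING and cls_b[lid] != MISSING
    ]
    if not shared:
        raise ValueError("markers share no lines with complete genotype and phenotype")

    groups: dict[tuple[str, str], list[float]] = {}
    for lid in shared:
        groups.setdefault((cls_a[lid], cls_b[lid]), []).append(pheno[lid])
    summaries = {
        key: ClassSummary(
            genotype_class="/".join(key),
            n=len(v),
            mean_hir=float(np.mean(v)),
            min_hir=float(np.min(v)),
            max_hir=float(np.max(v)),
        )
        for key, v in groups.items()
    }

    def favourable_homozygote(cls_of: dict[str, str]) -> str:
        means = {}
        for hom in ("AA", "BB"):
            vals = [pheno[l] for l in shared if cls_of[l] == hom]
            if vals:
                means[hom] = float(np.mean(vals))
        if not means:
            return "BB"
        return max(means, key=means.get)

    fav_a, fav_b = favourable_homozygote(cls_a), favourable_homozygote(cls_b)
    unf_a = "AA" if fav_a == "BB" else "BB"
    unf_b = "AA" if fav_b == "BB" else "BB"
    fav_vals = groups.get((fav_a, fav_b), [])
    unf_vals = groups.get((unf_a, unf_b), [])
    if len(fav_vals) >= 2 and len(unf_vals) >= 2:
        t, p = sps.ttest_ind(fav_vals, unf_vals, equal_var=False)
        welch_t, welch_p = float(t), float(p)
    else:
        welch_t = welch_p = math.nan
    return JointClassResult(
        summaries=summaries,
        favorable_class=(fav_a, fav_b),
        unfavorable_class=(unf_a, unf_b),
        welch_t=welch_t,
        welch_p=welch_p,
    )


def screen_candidates(
    results: Iterable[AssociationResult], r2_threshold: float = 0.3
) -> list[AssociationResult]:
    """Keep markers with R² strictly greater than the threshold."""
    return [r for r in results if r.r_squared > r2_threshold]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in the pipeline)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _as_mapping(
    phenotypes: Mapping[str, float] | Sequence[PhenotypeRecord],
) -> Mapping[str, float]:
    if isinstance(phenotypes, Mapping):
        return phenotypes
    return {p.line_id: p.hir for p in phenotypes}


def read_genotypes(path) -> list[GenotypeCall]:
    """Read a genotype TSV: line_id, marker_id, allele1, allele2.

    A diploid string column ``genotype`` (e.g. "T/C") is accepted instead
    of the two allele columns; '.', '-', 'NA' or empty mean missing.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing_tokens = {".", "-", "NA", "", "nan"}

    def clean(a) -> str | None:
        a = str(a).strip()
        return None if a in missing_tokens else a

    calls = []
    if "genotype" in df.columns:
        for r in df.itertuples(index=False):
            g = clean(r.genotype)
            if g is None or "/" not in g:
                a1 = a2 = None
            else:
                a1, a2 = (clean(x) for x in g.split("/", 1))
            calls.append(GenotypeCall(str(r.line_id), str(r.marker_id), a1, a2))
    else:
        for r in df.itertuples(index=False):
            calls.append(
                GenotypeCall(str(r.line_id), str(r.marker_id), clean(r.allele1), clean(r.allele2))
            )
    return calls
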