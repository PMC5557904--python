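"""Cohort-level summaries: recurrence spectra, group tests, correlations.

Mutations are keyed by (chrom, pos, ref, alt) across samples when computing
recurrence.  Group comparisons default to the Kruskal-Wallis rank test with
the chi-square approximation; 2x2 tables support Fisher's exact test and
Pearson chi-square with an automatic Yates continuity correction whenever
any cell holds fewer than 5 observations.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from somase.allele_model import AnnotationRecord, SiteKey
from somase.ase_calling import CALL_CLASSES, ExpressionCall, bh_adjust
from somase.exceptions import InsufficientDataError

STRATA_KEYS = (
    "func_class",
    "in_cancer_gene_list",
    "fathmm_call",
    "molecular_mode",
    "gene",
)


@dataclass(frozen=True)
class RecurrenceSpectrum:
    """How often each unique mutation recurs across samples."""

    multiplicity_histogram: Mapping[int, int]
    unique_count: int
    total_count: int
    singleton_fraction: float

    @classmethod
    def from_histogram(cls, histogram: Mapping[int, int]) -> "RecurrenceSpectrum":
        """Build directly from a multiplicity -> unique-mutation-count map."""
        histogram = dict(histogram)
        if any(m < 1 or c < 0 for m, c in histogram.items()):
            raise ValueError("multiplicities must be >= 1 and counts >= 0")
        unique = sum(histogram.values())
        total = sum(m * c for m, c in histogram.items())
        singleton = histogram.get(1, 0) / unique if unique else float("nan")
        return cls(
            multiplicity_histogram=histogram,
            unique_count=unique,
            total_count=total,
            singleton_fraction=singleton,
        )


def recurrence_spectrum(calls: Sequence[ExpressionCall]) -> RecurrenceSpectrum:
    """Recurrence spectrum of a cohort's calls.

    Each unique mutation is a distinct :class:`SiteKey`; its multiplicity is
    the number of distinct samples carrying it.
    """
    samples_per_site: Dict[SiteKey, set] = defaultdict(set)
    for call in calls:
        samples_per_site[call.site].add(call.sample_id)
    histogram = Counter(len(samples) for samples in samples_per_site.values())
    return RecurrenceSpectrum.from_histogram(dict(histogram))


def _complete_pairs(
    x: Sequence[Optional[float]], y: Sequence[Optional[float]]
) -> Tuple[np.ndarray, np.ndarray]:
    if len(x) != len(y):
        raise ValueError(f"x and y must have equal length, got {len(x)} and {len(y)}")
    xs, ys = [], []
    for a, b in zip(x, y):
        if a is None or b is None:
            continue
        a, b = float(a), float(b)
        if math.isnan(a) or math.isnan(b):
            continue
        xs.append(a)
        ys.append(b)
    return np.asarray(xs), np.asarray(ys)


def spearman_rho(x: Sequence[Optional[float]], y: Sequence[Optional[float]]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairs where either value is absent (``None``/NaN) are dropped; at least
    3 complete pairs are required.
    """
    xs, ys = _complete_pairs(x, y)
    if xs.size < 3:
        raise InsufficientDataError(
            f"spearman_rho needs >= 3 complete pairs, got {xs.size}"
        )
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    *,
    permutation: Optional[int] = None,
    seed: int = 0,
) -> Tuple[float, float]:
    """Kruskal-Wallis H with tie correction and its p-value.

    The p-value uses the chi-square approximation with ``k - 1`` degrees of
    freedom; pass ``permutation=<n>`` for a seeded permutation p-value
    (useful for tiny groups).
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    total_n = sum(a.size for a in arrays)
    if total_n < 3:
        raise ValueError(f"kruskal_wallis needs total n >= 3, got {total_n}")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # degenerate: no rank variation at all
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    if permutation is not None:
        rng = np.random.default_rng(seed)
        sizes = [a.size for a in arrays]
        edges = np.cumsum(sizes)[:-1]
        exceed = 0
        for _ in range(permutation):
            shuffled = rng.permutation(pooled)
            parts = np.split(shuffled, edges)
            h_perm, _ = stats.kruskal(*parts)
            if h_perm >= h:
                exceed += 1
        p = (1 + exceed) / (permutation + 1)
    return float(h), float(p)


def contingency_2x2(
    table: Sequence[Sequence[int]], method: str = "fisher_exact"
) -> float:
    """Two-sided p-value for a 2x2 count table.

    ``fisher_exact``
        Exact two-sided hypergeometric test (minimum-likelihood convention).
    ``chi2_yates_auto``
        Pearson chi-square; the Yates continuity correction is applied
        automatically when any cell holds fewer than 5 counts.  Requires
        all four margins positive (expected counts would otherwise be 0).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"table must be 2x2, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("table entries must be integers")
        arr = arr.astype(int)
    if np.any(arr < 0):
        raise ValueError("table entries must be non-negative")
    if arr.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    if method == "fisher_exact":
        return float(stats.fisher_exact(arr, alternative="two-sided")[1])
    if method == "chi2_yates_auto":
        if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
            raise ValueError("chi-square requires all margins positive")
        correction = bool((arr < 5).any())
        result = stats.chi2_contingency(arr, correction=correction)
        return float(result.pvalue)
    raise ValueError(f"unknown method {method!r}; expected 'fisher_exact' or 'chi2_yates_auto'")


@dataclass(frozen=True)
class GroupTest:
    """One pairwise contingency test inside a stratified summary."""

    group_a: str
    group_b: str
    call_class: str
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    p_value: float
    q_value: float = float("nan")


@dataclass(frozen=True)
class StratifiedSummary:
    """Per-stratum V_R:D vectors, call-class counts, and the tests between strata."""

    strata_key: str
    v_rd_by_group: Mapping[str, List[float]]
    call_counts_by_group: Mapping[str, Mapping[str, int]]
    kruskal_h: Optional[float] = None
    kruskal_p: Optional[float] = None
    pairwise_tests: Tuple[GroupTest, ...] = field(default_factory=tuple)
    t_test_p: Optional[float] = None

    @property
    def group_sizes(self) -> Dict[str, int]:
        return {g: len(v) for g, v in self.v_rd_by_group.items()}


def _stratum_label(annotation: AnnotationRecord, key: str) -> str:
    value = getattr(annotation, key)
    if key == "in_cancer_gene_list":
        return "CGC" if value else "non-CGC"
    return str(value) if value is not None else "absent"


def stratified_summary(
    calls: Sequence[ExpressionCall],
    annotations: Mapping[SiteKey, AnnotationRecord],
    strata_key: str = "func_class",
    *,
    contingency_method: str = "chi2_yates_auto",
    include_t_test: bool = False,
) -> StratifiedSummary:
    """Group calls by an annotation key and test differences between strata.

    Produces per-stratum V_R:D vectors and call-class count tables; with two
    or more strata it adds a Kruskal-Wallis test of V_R:D across strata and,
    for every pair of strata and every extreme call class, a 2x2 test of the
    call-class proportion.  All test p-values are jointly BH-adjusted.
    Optionally a two-group t-test on mean V_R:D is included
    (``include_t_test``, two largest strata).
    """
    if strata_key not in STRATA_KEYS:
        raise ValueError(f"unknown grouping key {strata_key!r}; expected one of {STRATA_KEYS}")
    missing = [str(c.site) for c in calls if c.site not in annotations]
    if missing:
        raise ValueError(f"calls without annotation: {', '.join(missing[:5])}")

    v_rd_by_group: Dict[str, List[float]] = defaultdict(list)
    counts_by_group: Dict[str, Counter] = defaultdict(Counter)
    for call in calls:
        label = _stratum_label(annotations[call.site], strata_key)
        v_rd_by_group[label].append(call.v_rd)
        counts_by_group[label][call.call] += 1

    groups = sorted(v_rd_by_group)
    kruskal_h = kruskal_p = None
    pairwise: List[GroupTest] = []
    t_test_p = None
    if len(groups) >= 2:
        if sum(len(v_rd_by_group[g]) for g in groups) >= 3:
            kruskal_h, kruskal_p = kruskal_wallis([v_rd_by_group[g] for g in groups])
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                for call_class in ("SOM_E", "SOM_L"):
                    a_in = counts_by_group[ga][call_class]
                    a_out = sum(counts_by_group[ga].values()) - a_in
                    b_in = counts_by_group[gb][call_class]
                    b_out = sum(counts_by_group[gb].values()) - b_in
                    table = ((a_in, a_out), (b_in, b_out))
                    try:
                        p = contingency_2x2(table, contingency_method)
                    except ValueError:
                        continue  # degenerate margins: proportion not testable
                    pairwise.append(
                        GroupTest(group_a=ga, group_b=gb, call_class=call_class, table=table, p_value=p)
                    )
        if include_t_test:
            largest = sorted(groups, key=lambda g: -len(v_rd_by_group[g]))[:2]
            a, b = v_rd_by_group[largest[0]], v_rd_by_group[largest[1]]
            if len(a) >= 2 and len(b) >= 2:
                t_test_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)

    all_p = ([kruskal_p] if kruskal_p is not None else []) + [t.p_value for t in pairwise]
    if all_p:
        q = bh_adjust(all_p)
        offset = 1 if kruskal_p is not None else 0
        pairwise = [
            GroupTest(t.group_a, t.group_b, t.call_class, t.table, t.p_value, q[offset + i])
            for i, t in enumerate(pairwise)
        ]

    return StratifiedSummary(
        strata_key=strata_key,
        v_rd_by_group={g: list(v) for g, v in v_rd_by_group.items()},
        call_counts_by_group={
            g: {cls: counts_by_group[g].get(cls, 0) for cls in CALL_CLASSES} for g in groups
        },
        kruskal_h=kruskal_h,
        kruskal_p=kruskal_p,
        pairwise_tests=tuple(pairwise),
        t_test_p=t_test_p,
    )
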