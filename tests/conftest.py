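"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import math
from typing import Tuple

import pytest

from somase.allele_model import AlleleCounts, QuadCounts, SiteKey, VariantRecord
from somase.ase_calling import ExpressionCall


def make_counts(
    nd: Tuple[int, int] = (30, 0),
    nr: Tuple[int, int] = (25, 0),
    td: Tuple[int, int] = (20, 20),
    tr: Tuple[int, int] = (15, 15),
) -> QuadCounts:
    """QuadCounts from (ref, var) pairs; defaults are a clean balanced somatic site."""
    return QuadCounts(
        normal_dna=AlleleCounts(*nd),
        normal_rna=AlleleCounts(*nr),
        tumor_dna=AlleleCounts(*td),
        tumor_rna=AlleleCounts(*tr),
    )


def make_record(
    sample_id: str = "S1",
    chrom: str = "chr1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    counts: QuadCounts | None = None,
    **count_kwargs,
) -> VariantRecord:
    return VariantRecord(
        sample_id=sample_id,
        site=SiteKey(chrom, pos, ref, alt),
        counts=counts if counts is not None else make_counts(**count_kwargs),
    )


def make_call(
    sample_id: str = "S1",
    chrom: str = "chr1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    vaf_tdna: float = 0.5,
    vaf_trna: float = 0.5,
    call: str = "EXPRESSED_BALANCED",
    p_value: float = 1.0,
    q_value: float = 1.0,
) -> ExpressionCall:
    return ExpressionCall(
        sample_id=sample_id,
        site=SiteKey(chrom, pos, ref, alt),
        vaf_tdna=vaf_tdna,
        vaf_trna=vaf_trna,
        v_rd=vaf_trna / vaf_tdna,
        p_value=p_value,
        q_value=q_value,
        call=call,
    )


# ---------------------------------------------------------------------------
# Independent oracles (pure enumeration; no scipy, no package internals)
# ---------------------------------------------------------------------------

def binom_pmf_exact(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def binomial_p_oracle(k: int, n: int, p0: float, alternative: str = "two_sided") -> float:
    """Brute-force binomial tail probability by full pmf enumeration."""
    pmf = [binom_pmf_exact(i, n, p0) for i in range(n + 1)]
    if alternative == "greater":
        return min(1.0, sum(pmf[k:]))
    if alternative == "less":
        return min(1.0, sum(pmf[: k + 1]))
    cut = pmf[k] * (1.0 + 1e-7)
    return min(1.0, sum(v for v in pmf if v <= cut))


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)}
    cut = pmf[a] * (1.0 + 1e-7)
    return min(1.0, sum(v for v in pmf.values() if v <= cut))


def spearman_oracle(x, y) -> float:
    """1 - 6 * sum d^2 / (n (n^2 - 1)); valid only without ties."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0] * len(v)
        for rank, i in enumerate(order, start=1):
            r[i] = rank
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(x)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


@pytest.fixture
def small_cohort():
    """A deterministic mixed cohort shared across module tests."""
    from somase.synthetic_cohort import SimConfig, generate_cohort

    return generate_cohort(SimConfig(n_samples=4, sites_per_sample=150, seed=42))
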