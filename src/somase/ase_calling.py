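"""Classify retained somatic sites as SOM-E, SOM-L, or expressed-balanced.

Each site gets an exact two-sided binomial test of its tumor-RNA variant
read count against a null allele fraction — by default the site's own
tumor-DNA VAF (``dna_matched``), optionally 0.5 (``half``).  P-values are
Benjamini-Hochberg adjusted across the batch, and a call additionally
requires a hard tumor-RNA VAF threshold: SOM-E needs ``vaf_trna >= tau_e``
(mono-allelic variant signal), SOM-L needs ``vaf_trna <= tau_l`` (variant
allele absent from the transcriptome).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from somase.allele_model import SiteKey, VariantRecord, v_rd, vaf
from somase.exceptions import ConfigError

SOM_E = "SOM_E"
SOM_L = "SOM_L"
EXPRESSED_BALANCED = "EXPRESSED_BALANCED"
CALL_CLASSES = (SOM_E, SOM_L, EXPRESSED_BALANCED)

#: Relative tolerance when deciding pmf ties in the two-sided test.
TIE_RTOL = 1e-7


@dataclass(frozen=True, slots=True)
class CallConfig:
    """Thresholds governing the expression-status caller."""

    alpha: float = 0.05
    null_mode: str = "dna_matched"
    tau_e: float = 0.9
    tau_l: float = 0.05
    fdr_method: str = "bh"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.null_mode not in ("dna_matched", "half"):
            raise ConfigError(f"null_mode must be 'dna_matched' or 'half', got {self.null_mode!r}")
        if not 0.0 <= self.tau_l < self.tau_e <= 1.0:
            raise ConfigError(
                f"need 0 <= tau_l < tau_e <= 1, got tau_l={self.tau_l}, tau_e={self.tau_e}"
            )
        if self.fdr_method != "bh":
            raise ConfigError("fdr_method is fixed to 'bh'")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "CallConfig":
        """Build from a key/value mapping (e.g. a parsed config file)."""
        config = cls()
        casts = {"alpha": float, "null_mode": str, "tau_e": float, "tau_l": float}
        updates = {k: cast(mapping[k]) for k, cast in casts.items() if k in mapping}
        return replace(config, **updates)


@dataclass(frozen=True, slots=True)
class ExpressionCall:
    """Per-site classification with the quantities behind it."""

    sample_id: str
    site: SiteKey
    vaf_tdna: float
    vaf_trna: float
    v_rd: float
    p_value: float
    q_value: float
    call: str

    def __post_init__(self) -> None:
        if self.call not in CALL_CLASSES:
            raise ValueError(f"call must be one of {CALL_CLASSES}, got {self.call!r}")


def exact_binomial_p(k: int, n: int, p0: float, alternative: str = "two_sided") -> float:
    """Exact binomial tail probability for ``k`` successes in ``n`` trials.

    ``two_sided`` uses the minimum-likelihood convention: the sum of
    probabilities of all outcomes whose point probability does not exceed
    that of ``k`` (ties decided with relative tolerance :data:`TIE_RTOL`).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null probability must lie in (0, 1), got {p0}")
    if alternative == "greater":
        p = stats.binom.sf(k - 1, n, p0)
    elif alternative == "less":
        p = stats.binom.cdf(k, n, p0)
    elif alternative == "two_sided":
        pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
        p = pmf[pmf <= pmf[k] * (1.0 + TIE_RTOL)].sum()
    else:
        raise ValueError(
            f"alternative must be 'two_sided', 'greater' or 'less', got {alternative!r}"
        )
    return float(min(1.0, p))


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0.0) | (p > 1.0)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q.tolist()


def call_expression_status(
    records: Sequence[VariantRecord], config: Optional[CallConfig] = None
) -> List[ExpressionCall]:
    """Call SOM-E / SOM-L / expressed-balanced for a batch of retained sites.

    All records must already have passed the site filters (in particular
    ``0 < VAF(tumor DNA) < 1`` and the coverage minima).  BH adjustment is
    applied jointly across the batch.
    """
    config = config or CallConfig()
    if not records:
        return []
    vaf_tdna = np.array([vaf(r.counts.tumor_dna) for r in records])
    vaf_trna = np.array([vaf(r.counts.tumor_rna) for r in records])
    p_values = []
    for record, fdna in zip(records, vaf_tdna):
        p0 = fdna if config.null_mode == "dna_matched" else 0.5
        rna = record.counts.tumor_rna
        p_values.append(exact_binomial_p(rna.var_reads, rna.depth, p0, "two_sided"))
    q_values = bh_adjust(p_values)

    calls: List[ExpressionCall] = []
    for record, fdna, frna, p, q in zip(records, vaf_tdna, vaf_trna, p_values, q_values):
        if q < config.alpha and frna >= config.tau_e:
            status = SOM_E
        elif q < config.alpha and frna <= config.tau_l:
            status = SOM_L
        else:
            status = EXPRESSED_BALANCED
        calls.append(
            ExpressionCall(
                sample_id=record.sample_id,
                site=record.site,
                vaf_tdna=float(fdna),
                vaf_trna=float(frna),
                v_rd=v_rd(float(frna), float(fdna)),
                p_value=float(p),
                q_value=float(q),
                call=status,
            )
        )
    return calls
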