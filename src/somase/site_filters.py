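"""Exclusion ledger: decide which (sample, site) pairs enter the analysis.

A (sample, site) pair is retained only if all of the following hold:

* tumor DNA and tumor RNA depth both reach ``min_depth`` (default 10;
  exactly 10 reads passes — the exclusion is strictly "fewer than");
* the variant is absent from both normal datasets up to
  ``germline_max_var_reads`` stray reads (germline screen);
* the tumor DNA signal is bi-allelic, ``0 < VAF(tDNA) < 1``;
* the site overlaps no imprinted region and no copy-number segment whose
  ``|seg_mean|`` exceeds ``cna_abs_segmean_threshold``.

Whole samples with an outlying somatic mutation burden (more than
``hypermutator_sd_multiplier`` sample standard deviations above the cohort
mean) are dropped as hypermutators.

All predicates are pure; applying them in any order yields the same
retained set.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from somase.allele_model import SiteKey, VariantRecord, vaf
from somase.exceptions import ConfigError
from somase.io_formats import GenomicInterval

LOW_COVERAGE_DNA = "low_coverage_dna"
LOW_COVERAGE_RNA = "low_coverage_rna"
IMPRINTED = "imprinted"
CNA_OVERLAP = "cna_overlap"
GERMLINE = "germline"
NOT_BIALLELIC_TUMOR_DNA = "not_biallelic_tumor_dna"

FILTER_REASONS = (
    LOW_COVERAGE_DNA,
    LOW_COVERAGE_RNA,
    IMPRINTED,
    CNA_OVERLAP,
    GERMLINE,
    NOT_BIALLELIC_TUMOR_DNA,
)


@dataclass(frozen=True, slots=True)
class FilterConfig:
    """Thresholds for the per-site exclusion rules."""

    min_depth: int = 10
    germline_max_var_reads: int = 1
    germline_error_rate: float = 0.001
    cna_abs_segmean_threshold: float = 0.1
    hypermutator_sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ConfigError(f"min_depth must be >= 1, got {self.min_depth}")
        if self.germline_max_var_reads < 0:
            raise ConfigError("germline_max_var_reads must be non-negative")
        if self.cna_abs_segmean_threshold < 0:
            raise ConfigError("cna_abs_segmean_threshold must be non-negative")
        if not 0.0 <= self.germline_error_rate < 1.0:
            raise ConfigError("germline_error_rate must lie in [0, 1)")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "FilterConfig":
        """Build from a key/value mapping (e.g. a parsed config file)."""
        casts = {
            "min_depth": int,
            "germline_max_var_reads": int,
            "germline_error_rate": float,
            "cna_abs_segmean_threshold": float,
            "hypermutator_sd_multiplier": float,
        }
        updates = {k: cast(mapping[k]) for k, cast in casts.items() if k in mapping}
        return replace(cls(), **updates)


@dataclass(frozen=True, slots=True)
class FilterVerdict:
    """Outcome for one (sample, site): retained iff no reasons recorded."""

    retained: bool
    reasons: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.retained != (len(self.reasons) == 0):
            raise ValueError("retained must be True exactly when reasons is empty")
        unknown = [r for r in self.reasons if r not in FILTER_REASONS]
        if unknown:
            raise ValueError(f"unknown filter reason(s): {unknown}")


def passes_coverage(record: VariantRecord, config: Optional[FilterConfig] = None) -> bool:
    """True iff both tumor datasets reach ``min_depth`` reads."""
    config = config or FilterConfig()
    return (
        record.counts.tumor_dna.depth >= config.min_depth
        and record.counts.tumor_rna.depth >= config.min_depth
    )


def is_somatic_biallelic(record: VariantRecord, config: Optional[FilterConfig] = None) -> bool:
    """True iff the variant looks somatic and the tumor DNA is bi-allelic.

    Somatic: at most ``germline_max_var_reads`` variant reads in each of
    normal DNA and normal RNA (tolerating stray sequencing-error reads).
    Bi-allelic: ``0 < VAF(tumor DNA) < 1``; requires tumor DNA depth > 0,
    so run the coverage filter first.
    """
    config = config or FilterConfig()
    counts = record.counts
    if counts.normal_dna.var_reads > config.germline_max_var_reads:
        return False
    if counts.normal_rna.var_reads > config.germline_max_var_reads:
        return False
    tdna_vaf = vaf(counts.tumor_dna)
    return 0.0 < tdna_vaf < 1.0


def overlaps_excluded_region(
    site: SiteKey,
    intervals: Sequence[GenomicInterval],
    config: Optional[FilterConfig] = None,
) -> bool:
    """True iff the site falls in an imprinted region or an affected CNA segment.

    CNA segments (label ``"CNA"``) only exclude when ``|value|`` exceeds
    ``cna_abs_segmean_threshold``; near-zero segment means are copy-neutral.
    Intervals must already be in 1-based inclusive coordinates.
    """
    config = config or FilterConfig()
    for interval in intervals:
        if not interval.contains(site.chrom, site.pos):
            continue
        if interval.label == "CNA":
            if interval.value is not None and abs(interval.value) > config.cna_abs_segmean_threshold:
                return True
        else:
            return True
    return False


def exclude_hypermutators(
    per_sample_counts: Mapping[str, int], config: Optional[FilterConfig] = None
) -> Set[str]:
    """Samples whose somatic mutation count exceeds mean + k * SD.

    The standard deviation is the sample statistic (n-1 denominator) over
    all samples.  Requires at least two samples.
    """
    config = config or FilterConfig()
    if len(per_sample_counts) < 2:
        raise ValueError("hypermutator exclusion needs at least 2 samples")
    counts = list(per_sample_counts.values())
    mean = statistics.fmean(counts)
    sd = statistics.stdev(counts)
    cutoff = mean + config.hypermutator_sd_multiplier * sd
    return {sample for sample, count in per_sample_counts.items() if count > cutoff}


def evaluate_record(
    record: VariantRecord,
    intervals: Sequence[GenomicInterval],
    config: Optional[FilterConfig] = None,
) -> FilterVerdict:
    """Run every per-site rule on one record and collect all failing reasons."""
    config = config or FilterConfig()
    reasons: List[str] = []
    counts = record.counts
    if counts.tumor_dna.depth < config.min_depth:
        reasons.append(LOW_COVERAGE_DNA)
    if counts.tumor_rna.depth < config.min_depth:
        reasons.append(LOW_COVERAGE_RNA)
    scoped = [
        iv
        for iv in intervals
        if iv.sample_id is None or iv.sample_id == record.sample_id
    ]
    for interval in scoped:
        if not interval.contains(record.site.chrom, record.site.pos):
            continue
        if interval.label == "CNA":
            if (
                interval.value is not None
                and abs(interval.value) > config.cna_abs_segmean_threshold
                and CNA_OVERLAP not in reasons
            ):
                reasons.append(CNA_OVERLAP)
        elif IMPRINTED not in reasons:
            reasons.append(IMPRINTED)
    if (
        counts.normal_dna.var_reads > config.germline_max_var_reads
        or counts.normal_rna.var_reads > config.germline_max_var_reads
    ):
        reasons.append(GERMLINE)
    if counts.tumor_dna.depth > 0:
        tdna_vaf = vaf(counts.tumor_dna)
        if not 0.0 < tdna_vaf < 1.0:
            reasons.append(NOT_BIALLELIC_TUMOR_DNA)
    else:
        reasons.append(NOT_BIALLELIC_TUMOR_DNA)
    return FilterVerdict(retained=not reasons, reasons=tuple(reasons))


def filter_cohort(
    records: Sequence[VariantRecord],
    intervals: Sequence[GenomicInterval] = (),
    config: Optional[FilterConfig] = None,
    *,
    apply_hypermutator_exclusion: bool = True,
) -> Tuple[List[VariantRecord], Dict[Tuple[str, SiteKey], FilterVerdict], Set[str]]:
    """Apply all exclusion rules to a cohort.

    Returns ``(retained records, per-record verdicts, excluded sample ids)``.
    Hypermutator exclusion operates on the per-sample counts of records that
    survived the per-site rules, and is skipped when the cohort has fewer
    than two samples.
    """
    config = config or FilterConfig()
    verdicts: Dict[Tuple[str, SiteKey], FilterVerdict] = {}
    survivors: List[VariantRecord] = []
    for record in records:
        verdict = evaluate_record(record, intervals, config)
        verdicts[(record.sample_id, record.site)] = verdict
        if verdict.retained:
            survivors.append(record)

    excluded_samples: Set[str] = set()
    if apply_hypermutator_exclusion:
        per_sample: Dict[str, int] = {}
        for record in records:
            per_sample.setdefault(record.sample_id, 0)
        for record in survivors:
            per_sample[record.sample_id] += 1
        if len(per_sample) >= 2:
            excluded_samples = exclude_hypermutators(per_sample, config)
    retained = [r for r in survivors if r.sample_id not in excluded_samples]
    return retained, verdicts, excluded_samples
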