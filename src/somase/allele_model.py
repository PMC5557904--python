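"""Core per-site quantities: allele counts, VAF, and the RNA:DNA ratio.

The variant allele fraction (VAF) at a site is ``n(var) / (n(ref) + n(var))``
computed separately per dataset.  The RNA:DNA expression ratio
``v_rd = VAF(tumor RNA) / VAF(tumor DNA)`` is near 1 when the transcriptome
mirrors the tumor genome's allele composition, above 1 for variant-allele
over-representation, and below 1 for under-representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from somase.exceptions import UndefinedVafError

_BASES = frozenset("ACGT")

FUNC_CLASSES = ("missense", "non-coding", "stop", "synonymous")
FATHMM_CALLS = ("pathogenic", "neutral")
MOLECULAR_MODES = ("dominant", "recessive")


@dataclass(frozen=True, slots=True)
class SiteKey:
    """Identity of a single-nucleotide substitution: chrom, 1-based pos, ref>alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _BASES:
            raise ValueError(f"ref must be a single base A/C/G/T, got {self.ref!r}")
        if self.alt not in _BASES:
            raise ValueError(f"alt must be a single base A/C/G/T, got {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, both are {self.ref!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True, slots=True)
class AlleleCounts:
    """Reference / variant read counts for one site in one dataset."""

    ref_reads: int
    var_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.var_reads < 0:
            raise ValueError(
                f"read counts must be non-negative, got "
                f"ref={self.ref_reads}, var={self.var_reads}"
            )

    @property
    def depth(self) -> int:
        return self.ref_reads + self.var_reads


@dataclass(frozen=True, slots=True)
class QuadCounts:
    """Allele counts at one site across the four matched datasets."""

    normal_dna: AlleleCounts
    normal_rna: AlleleCounts
    tumor_dna: AlleleCounts
    tumor_rna: AlleleCounts


@dataclass(frozen=True, slots=True)
class AnnotationRecord:
    """Per-variant functional annotation; absent scores are ``None``, never 0."""

    gene: str
    func_class: str
    cadd: Optional[float] = None
    fathmm_score: Optional[float] = None
    fathmm_call: Optional[str] = None
    gerp: Optional[float] = None
    polyphen: Optional[float] = None
    grantham: Optional[float] = None
    phast: Optional[float] = None
    in_cancer_gene_list: bool = False
    molecular_mode: Optional[str] = None

    def __post_init__(self) -> None:
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(
                f"func_class must be one of {FUNC_CLASSES}, got {self.func_class!r}"
            )
        if self.fathmm_call is not None and self.fathmm_call not in FATHMM_CALLS:
            raise ValueError(f"fathmm_call must be one of {FATHMM_CALLS} or absent")
        if self.molecular_mode is not None and self.molecular_mode not in MOLECULAR_MODES:
            raise ValueError(f"molecular_mode must be one of {MOLECULAR_MODES} or absent")


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One (sample, site) observation with its four-way counts."""

    sample_id: str
    site: SiteKey
    counts: QuadCounts
    annotation: Optional[AnnotationRecord] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


def vaf(counts: AlleleCounts) -> float:
    """Variant allele fraction ``var / (ref + var)``.

    Raises
    ------
    UndefinedVafError
        If the site has zero depth (such sites must be coverage-filtered
        before any VAF is computed).
    """
    depth = counts.depth
    if depth == 0:
        raise UndefinedVafError("VAF undefined at zero depth")
    return counts.var_reads / depth


def v_rd(vaf_trna: float, vaf_tdna: float) -> float:
    """RNA:DNA expression ratio ``VAF(tRNA) / VAF(tDNA)``.

    Requires ``0 < vaf_tdna < 1`` — a bi-allelic tumor-DNA signal, which the
    upstream site filters guarantee.  The ratio is not capped; values above 1
    mean the variant allele is over-represented in the transcriptome.
    """
    if not 0.0 < vaf_tdna < 1.0:
        raise ValueError(
            f"v_rd requires bi-allelic tumor DNA (0 < vaf_tdna < 1), got {vaf_tdna}"
        )
    if not 0.0 <= vaf_trna <= 1.0:
        raise ValueError(f"vaf_trna must lie in [0, 1], got {vaf_trna}")
    return vaf_trna / vaf_tdna
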