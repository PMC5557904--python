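"""Readers and writers for every on-disk artifact the pipeline touches.

Dialects
--------
counts TSV
    Tab-delimited, one row per (sample, site), header columns
    ``chrom pos ref alt nd_ref nd_var nr_ref nr_var td_ref td_var tr_ref
    tr_var sample_id`` (``nd``/``nr``/``td``/``tr`` = normal/tumor x
    DNA/RNA).  Counts are non-negative integers.
vcf_ad
    VCF 4.x with per-sample ``AD`` (allelic depth) FORMAT fields carrying
    the four datasets as four samples (default names ``NORMAL_DNA``,
    ``NORMAL_RNA``, ``TUMOR_DNA``, ``TUMOR_RNA``).
BED3+
    0-based half-open exclusion intervals; converted on read to the
    internal 1-based inclusive convention (start+1 .. end).
SEG
    Tab-delimited copy-number segmentation with columns
    ``sample chrom start end [num_mark] seg_mean`` (1-based inclusive).
calls TSV
    Output of the expression caller, columns ``sample_id chrom pos ref alt
    vaf_tdna vaf_trna v_rd p_value q_value call``.  Reals are written with
    12 significant digits; re-reading reproduces integer fields exactly.

Internal coordinates are 1-based inclusive everywhere; only the BED reader
converts.  Only single-nucleotide substitutions are accepted — indel rows
raise :class:`~somase.exceptions.FormatError`.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

from somase.allele_model import (
    AlleleCounts,
    AnnotationRecord,
    QuadCounts,
    SiteKey,
    VariantRecord,
)
from somase.ase_calling import CALL_CLASSES, ExpressionCall
from somase.exceptions import DuplicateRecordError, FormatError

COUNT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "nd_ref",
    "nd_var",
    "nr_ref",
    "nr_var",
    "td_ref",
    "td_var",
    "tr_ref",
    "tr_var",
    "sample_id",
)

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "func_class",
    "cadd",
    "fathmm_score",
    "fathmm_call",
    "gerp",
    "polyphen",
    "grantham",
    "phast",
    "in_cancer_gene_list",
    "molecular_mode",
)

CALL_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf_tdna",
    "vaf_trna",
    "v_rd",
    "p_value",
    "q_value",
    "call",
)

DEFAULT_VCF_SAMPLES = {
    "normal_dna": "NORMAL_DNA",
    "normal_rna": "NORMAL_RNA",
    "tumor_dna": "TUMOR_DNA",
    "tumor_rna": "TUMOR_RNA",
}


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """An exclusion region in 1-based inclusive coordinates.

    ``label`` records provenance (e.g. ``"imprinted"`` or ``"CNA"``);
    ``value`` carries an optional numeric payload (SEG mean / log2 ratio);
    ``sample_id`` scopes per-sample segments (``None`` = applies to all).
    """

    chrom: str
    start: int
    end: int
    label: str = ""
    value: Optional[float] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def _parse_count(value: str, column: str, line_no: int) -> int:
    try:
        count = int(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"line {line_no}: column {column!r} must be an integer, got {value!r}"
        ) from None
    if count < 0:
        raise ValueError(
            f"line {line_no}: column {column!r} must be non-negative, got {count}"
        )
    return count


def _parse_site(row: Mapping[str, str], line_no: int) -> SiteKey:
    ref = row["ref"].strip().upper()
    alt = row["alt"].strip().upper()
    if len(ref) != 1 or len(alt) != 1:
        raise FormatError(
            f"line {line_no}: only single-nucleotide substitutions are supported "
            f"(got ref={ref!r}, alt={alt!r})"
        )
    try:
        pos = int(row["pos"])
    except ValueError:
        raise ValueError(f"line {line_no}: pos must be an integer, got {row['pos']!r}") from None
    try:
        return SiteKey(chrom=row["chrom"].strip(), pos=pos, ref=ref, alt=alt)
    except ValueError as exc:
        raise ValueError(f"line {line_no}: {exc}") from None


def _read_rows(path: str, required: Sequence[str]) -> List[Dict[str, str]]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        missing = [col for col in required if col not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        return list(reader)


def read_quad_counts(
    path: str,
    dialect: str = "tsv",
    *,
    vcf_samples: Optional[Mapping[str, str]] = None,
    vcf_sample_id: Optional[str] = None,
) -> List[VariantRecord]:
    """Read per-site four-way allele counts.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` for the counts TSV dialect, ``"vcf_ad"`` for a VCF with
        AD fields for four named samples.
    vcf_samples
        For ``vcf_ad``: mapping of the roles ``normal_dna``, ``normal_rna``,
        ``tumor_dna``, ``tumor_rna`` to VCF sample names.
    vcf_sample_id
        For ``vcf_ad``: the biological sample identifier to stamp on every
        record (defaults to the tumor-DNA VCF sample name).

    Returns one record per (sample, site), preserving input order.
    """
    if dialect == "tsv":
        return _read_quad_counts_tsv(path)
    if dialect == "vcf_ad":
        return _read_quad_counts_vcf(path, vcf_samples or DEFAULT_VCF_SAMPLES, vcf_sample_id)
    raise ValueError(f"unknown counts dialect {dialect!r}; expected 'tsv' or 'vcf_ad'")


def _read_quad_counts_tsv(path: str) -> List[VariantRecord]:
    records: List[VariantRecord] = []
    seen: set = set()
    # header is line 1
    for line_no, row in enumerate(_read_rows(path, COUNT_COLUMNS), start=2):
        site = _parse_site(row, line_no)
        sample_id = row["sample_id"].strip()
        if not sample_id:
            raise ValueError(f"line {line_no}: sample_id must be non-empty")
        key = (sample_id, site)
        if key in seen:
            raise DuplicateRecordError(
                f"line {line_no}: duplicate record for sample {sample_id!r} site {site}"
            )
        seen.add(key)
        counts = QuadCounts(
            normal_dna=AlleleCounts(
                _parse_count(row["nd_ref"], "nd_ref", line_no),
                _parse_count(row["nd_var"], "nd_var", line_no),
            ),
            normal_rna=AlleleCounts(
                _parse_count(row["nr_ref"], "nr_ref", line_no),
                _parse_count(row["nr_var"], "nr_var", line_no),
            ),
            tumor_dna=AlleleCounts(
                _parse_count(row["td_ref"], "td_ref", line_no),
                _parse_count(row["td_var"], "td_var", line_no),
            ),
            tumor_rna=AlleleCounts(
                _parse_count(row["tr_ref"], "tr_ref", line_no),
                _parse_count(row["tr_var"], "tr_var", line_no),
            ),
        )
        records.append(VariantRecord(sample_id=sample_id, site=site, counts=counts))
    return records


def _read_quad_counts_vcf(
    path: str, samples: Mapping[str, str], sample_id: Optional[str]
) -> List[VariantRecord]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - env without cyvcf2
        raise ImportError("the vcf_ad dialect requires the cyvcf2 package") from exc

    roles = ("normal_dna", "normal_rna", "tumor_dna", "tumor_rna")
    missing_roles = [r for r in roles if r not in samples]
    if missing_roles:
        raise ValueError(f"vcf_samples is missing role(s): {', '.join(missing_roles)}")

    vcf = VCF(path)
    vcf_names = list(vcf.samples)
    index: Dict[str, int] = {}
    for role in roles:
        name = samples[role]
        if name not in vcf_names:
            raise FormatError(f"{path}: VCF has no sample {name!r} (needed for {role})")
        index[role] = vcf_names.index(name)
    record_sample = sample_id or samples["tumor_dna"]

    records: List[VariantRecord] = []
    seen: set = set()
    for variant in vcf:
        if len(variant.REF) != 1 or len(variant.ALT) != 1 or len(variant.ALT[0]) != 1:
            raise FormatError(
                f"{path}: only biallelic single-nucleotide substitutions are "
                f"supported, got {variant.CHROM}:{variant.POS} "
                f"{variant.REF}>{','.join(variant.ALT)}"
            )
        site = SiteKey(variant.CHROM, variant.POS, variant.REF.upper(), variant.ALT[0].upper())
        key = (record_sample, site)
        if key in seen:
            raise DuplicateRecordError(f"{path}: duplicate record for site {site}")
        seen.add(key)
        ad = variant.format("AD")
        if ad is None:
            raise FormatError(f"{path}: site {site} has no AD FORMAT field")
        per_role = {}
        for role in roles:
            ref_reads, var_reads = (int(x) for x in ad[index[role]][:2])
            if ref_reads < 0 or var_reads < 0:  # cyvcf2 encodes missing AD as negative
                raise ValueError(f"{path}: site {site} has missing AD for {role}")
            per_role[role] = AlleleCounts(ref_reads, var_reads)
        records.append(
            VariantRecord(sample_id=record_sample, site=site, counts=QuadCounts(**per_role))
        )
    return records


def read_intervals(path: str, dialect: str = "bed") -> List[GenomicInterval]:
    """Read exclusion intervals from BED3+ or SEG, in input order.

    BED coordinates (0-based half-open) are converted to 1-based inclusive;
    the parsed length of every interval equals ``bed_end - bed_start``.
    SEG coordinates are taken as already 1-based inclusive; ``seg_mean`` is
    stored in ``value`` and the originating sample in ``sample_id``.
    """
    if dialect == "bed":
        return _read_bed(path)
    if dialect == "seg":
        return _read_seg(path)
    raise ValueError(f"unknown interval dialect {dialect!r}; expected 'bed' or 'seg'")


def _read_bed(path: str) -> List[GenomicInterval]:
    intervals: List[GenomicInterval] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {line_no}: BED needs >= 3 columns")
            chrom, start0, end = fields[0], fields[1], fields[2]
            try:
                start0_i, end_i = int(start0), int(end)
            except ValueError:
                raise ValueError(
                    f"{path} line {line_no}: BED start/end must be integers"
                ) from None
            label = fields[3] if len(fields) > 3 and fields[3] else "imprinted"
            try:
                intervals.append(
                    GenomicInterval(chrom=chrom, start=start0_i + 1, end=end_i, label=label)
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {line_no}: {exc}") from None
    return intervals


_SEG_ALIASES = {
    "sample": {"sample", "id", "sample_id"},
    "chrom": {"chrom", "chromosome", "chr"},
    "start": {"start", "loc.start", "loc_start"},
    "end": {"end", "loc.end", "loc_end"},
    "seg_mean": {"seg_mean", "seg.mean", "segmean"},
}


def _read_seg(path: str) -> List[GenomicInterval]:
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        return []
    header = [col.strip().lower() for col in lines[0].split("\t")]
    columns: Dict[str, int] = {}
    for canonical, aliases in _SEG_ALIASES.items():
        for i, col in enumerate(header):
            if col in aliases:
                columns[canonical] = i
                break
    missing = [c for c in _SEG_ALIASES if c not in columns]
    if missing:
        raise FormatError(f"{path}: SEG header lacks column(s): {', '.join(missing)}")
    intervals: List[GenomicInterval] = []
    for line_no, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        try:
            intervals.append(
                GenomicInterval(
                    chrom=fields[columns["chrom"]].strip(),
                    start=int(fields[columns["start"]]),
                    end=int(fields[columns["end"]]),
                    label="CNA",
                    value=float(fields[columns["seg_mean"]]),
                    sample_id=fields[columns["sample"]].strip(),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path} line {line_no}: {exc}") from None
    return intervals


def _parse_optional_float(value: str) -> Optional[float]:
    value = value.strip()
    if value in ("", "NA", "na", ".", "None"):
        return None
    return float(value)


def _parse_bool(value: str, column: str, line_no: int) -> bool:
    lowered = value.strip().lower()
    if lowered in ("1", "true", "yes", "y"):
        return True
    if lowered in ("0", "false", "no", "n", ""):
        return False
    raise ValueError(f"line {line_no}: column {column!r} must be boolean, got {value!r}")


def read_annotations(path: str) -> Dict[SiteKey, AnnotationRecord]:
    """Read the per-variant annotation TSV into a SiteKey-keyed mapping.

    Empty score cells become ``None`` (explicitly absent, never 0.0) and are
    dropped pairwise by downstream correlations.
    """
    annotations: Dict[SiteKey, AnnotationRecord] = {}
    for line_no, row in enumerate(_read_rows(path, ANNOTATION_COLUMNS), start=2):
        site = _parse_site(row, line_no)
        fathmm_call = row["fathmm_call"].strip() or None
        molecular_mode = row["molecular_mode"].strip() or None
        try:
            record = AnnotationRecord(
                gene=row["gene"].strip(),
                func_class=row["func_class"].strip(),
                cadd=_parse_optional_float(row["cadd"]),
                fathmm_score=_parse_optional_float(row["fathmm_score"]),
                fathmm_call=fathmm_call,
                gerp=_parse_optional_float(row["gerp"]),
                polyphen=_parse_optional_float(row["polyphen"]),
                grantham=_parse_optional_float(row["grantham"]),
                phast=_parse_optional_float(row["phast"]),
                in_cancer_gene_list=_parse_bool(
                    row["in_cancer_gene_list"], "in_cancer_gene_list", line_no
                ),
                molecular_mode=molecular_mode,
            )
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from None
        annotations[site] = record
    return annotations


def _format_real(x: float) -> str:
    return f"{x:.12g}"


def write_calls(records: Sequence[ExpressionCall], path: str) -> None:
    """Write expression calls as TSV (header always emitted).

    Integer fields round-trip exactly; reals round-trip to 12 significant
    digits.
    """
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise IOError(f"directory does not exist: {directory}")
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CALL_COLUMNS)
        for call in records:
            writer.writerow(
                [
                    call.sample_id,
                    call.site.chrom,
                    call.site.pos,
                    call.site.ref,
                    call.site.alt,
                    _format_real(call.vaf_tdna),
                    _format_real(call.vaf_trna),
                    _format_real(call.v_rd),
                    _format_real(call.p_value),
                    _format_real(call.q_value),
                    call.call,
                ]
            )


def read_calls(path: str) -> List[ExpressionCall]:
    """Re-read a calls TSV produced by :func:`write_calls`."""
    calls: List[ExpressionCall] = []
    for line_no, row in enumerate(_read_rows(path, CALL_COLUMNS), start=2):
        site = _parse_site(row, line_no)
        call_class = row["call"].strip()
        if call_class not in CALL_CLASSES:
            raise ValueError(
                f"line {line_no}: call must be one of {CALL_CLASSES}, got {call_class!r}"
            )
        calls.append(
            ExpressionCall(
                sample_id=row["sample_id"].strip(),
                site=site,
                vaf_tdna=float(row["vaf_tdna"]),
                vaf_trna=float(row["vaf_trna"]),
                v_rd=float(row["v_rd"]),
                p_value=float(row["p_value"]),
                q_value=float(row["q_value"]),
                call=call_class,
            )
        )
    return calls
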