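"""Synthetic matched four-way read-count cohorts with known ground truth.

The generator emulates the full data model the pipeline consumes: per-site
variant/reference counts in normal exome, normal transcriptome, tumor exome
and tumor transcriptome; imprinted-region BED and per-sample CNA SEG
intervals; and a per-variant annotation table whose pathogenicity score has
a controllable rank correlation with the true RNA variant fraction.

Generative model (per site):

* sequencing depths are negative-binomial per dataset;
* somatic sites are heterozygous-diploid with purity dilution, so the true
  tumor-DNA VAF is ``purity / 2``; tumor-DNA variant reads are binomial;
* normal DNA/RNA variant reads are sequencing errors, ``Binomial(depth,
  seq_error)``, except germline contaminants which sit at VAF 0.5 in all
  four datasets;
* tumor-RNA variant fraction is ``1 - seq_error`` for true SOM-E sites,
  ``seq_error`` for true SOM-L sites, and for balanced sites the realized
  tumor-DNA VAF (beta-binomially jittered when ``rna_overdispersion > 0``,
  exactly binomial when it is 0);
* sites assigned to generated CNA / imprinted intervals are placed inside
  those intervals (all other sites are placed outside them), so interval
  exclusion is exercised deterministically;
* annotation scores follow a Gaussian copula with the true RNA variant
  fraction targeting Spearman ``score_rho``.

Everything is drawn from one seeded generator, so identical configs give
identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from somase.allele_model import (
    AlleleCounts,
    AnnotationRecord,
    QuadCounts,
    SiteKey,
    VariantRecord,
)
from somase.ase_calling import EXPRESSED_BALANCED, SOM_E, SOM_L, ExpressionCall
from somase.exceptions import ConfigError, JoinError
from somase.io_formats import GenomicInterval

TRUE_BALANCED = "BALANCED"
TRUE_GERMLINE = "GERMLINE"
TRUE_CNA = "CNA_SITE"
TRUE_IMPRINTED = "IMPRINTED_SITE"
TRUTH_CLASSES = (SOM_E, SOM_L, TRUE_BALANCED, TRUE_GERMLINE, TRUE_CNA, TRUE_IMPRINTED)

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))
_BASES = np.array(list("ACGT"))

# Disjoint coordinate bands so that only designated sites can overlap the
# generated exclusion intervals.
_SITE_SPAN = (100_000, 19_000_000)
_IMPRINTED_SPAN = (20_000_001, 29_000_000)
_CNA_SPAN = (40_000_001, 49_000_000)

TRUTH_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "true_class",
    "true_dna_vaf",
    "true_rna_var_fraction",
    "in_cna",
    "in_imprinted",
)


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Knobs of the cohort generator; defaults give a small mixed cohort."""

    n_samples: int = 8
    sites_per_sample: int = 200
    purity: float = 0.7
    coverage_mean_dna: float = 80.0
    coverage_mean_rna: float = 60.0
    coverage_dispersion: float = 8.0
    seq_error: float = 0.001
    frac_som_e: float = 0.05
    frac_som_l: float = 0.38
    rna_overdispersion: float = 0.0
    frac_germline_contam: float = 0.05
    frac_in_cna: float = 0.04
    frac_in_imprinted: float = 0.02
    score_rho: float = 0.3
    seed: int = 0
    n_imprinted_regions: int = 5
    cna_segments_per_sample: int = 3

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.sites_per_sample < 1:
            raise ConfigError("n_samples and sites_per_sample must be >= 1")
        if not 0.0 < self.purity <= 1.0:
            raise ConfigError(f"purity must lie in (0, 1], got {self.purity}")
        if min(self.coverage_mean_dna, self.coverage_mean_rna, self.coverage_dispersion) <= 0:
            raise ConfigError("coverage means and dispersion must be positive")
        for name in (
            "seq_error",
            "frac_som_e",
            "frac_som_l",
            "frac_germline_contam",
            "frac_in_cna",
            "frac_in_imprinted",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_som_e + self.frac_som_l > 1.0:
            raise ConfigError("frac_som_e + frac_som_l must not exceed 1")
        if self.frac_germline_contam + self.frac_in_cna + self.frac_in_imprinted > 1.0:
            raise ConfigError("germline + CNA + imprinted fractions must not exceed 1")
        if not 0.0 <= self.rna_overdispersion < 1.0:
            raise ConfigError("rna_overdispersion must lie in [0, 1)")
        if not -1.0 <= self.score_rho <= 1.0:
            raise ConfigError("score_rho must lie in [-1, 1]")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SimConfig":
        known = {f.name: f.type for f in fields(cls)}
        updates = {}
        for key, raw in mapping.items():
            if key not in known:
                continue
            cast = int if known[key] == "int" else float
            updates[key] = cast(raw)
        return replace(cls(), **updates)


@dataclass(frozen=True)
class ClassRates:
    """Sensitivity/specificity for one truth class with exact binomial 95% CI."""

    sensitivity: float
    sensitivity_ci: Tuple[float, float]
    specificity: float
    specificity_ci: Tuple[float, float]
    n_truth: int


@dataclass(frozen=True)
class ConfusionResult:
    """3x3 confusion over {SOM_E, SOM_L, BALANCED} plus per-class rates."""

    matrix: pd.DataFrame
    per_class: Dict[str, ClassRates] = field(default_factory=dict)


def _negative_binomial(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _draw_intervals(rng: np.random.Generator, config: SimConfig, sample_ids: Sequence[str]):
    imprinted: List[GenomicInterval] = []
    for _ in range(config.n_imprinted_regions):
        chrom = _CHROMS[rng.integers(0, len(_CHROMS))]
        length = int(rng.integers(50_000, 500_000))
        start = int(rng.integers(_IMPRINTED_SPAN[0], _IMPRINTED_SPAN[1] - length))
        imprinted.append(
            GenomicInterval(chrom=chrom, start=start, end=start + length - 1, label="imprinted")
        )
    cna: List[GenomicInterval] = []
    for sample_id in sample_ids:
        for _ in range(config.cna_segments_per_sample):
            chrom = _CHROMS[rng.integers(0, len(_CHROMS))]
            length = int(rng.integers(100_000, 2_000_000))
            start = int(rng.integers(_CNA_SPAN[0], _CNA_SPAN[1] - length))
            seg_mean = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 1.2))
            cna.append(
                GenomicInterval(
                    chrom=chrom,
                    start=start,
                    end=start + length - 1,
                    label="CNA",
                    value=seg_mean,
                    sample_id=sample_id,
                )
            )
    return imprinted, cna


def _copula_scores(
    rng: np.random.Generator, anchor: np.ndarray, target_rho: float
) -> np.ndarray:
    """Latent normal scores with Spearman ~ target_rho against ``anchor``.

    Ranks of ``anchor`` are tie-broken at random, mapped to normal quantiles,
    and mixed with independent noise at the Pearson correlation
    ``2 sin(pi * rho / 6)`` that yields the requested Spearman correlation
    for the Gaussian copula.
    """
    n = anchor.size
    jitter = rng.uniform(0.0, 1.0, size=n)
    order = np.lexsort((jitter, anchor))
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    z_anchor = stats.norm.ppf(ranks / (n + 1))
    r = 2.0 * math.sin(math.pi * target_rho / 6.0)
    return r * z_anchor + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)


def generate_cohort(
    config: Optional[SimConfig] = None,
) -> Tuple[
    List[VariantRecord],
    List[GenomicInterval],
    Dict[SiteKey, AnnotationRecord],
    pd.DataFrame,
]:
    """Generate a cohort: (records, intervals, annotations, truth table).

    Fully deterministic for a given :class:`SimConfig` (including seed).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    n = config.n_samples * config.sites_per_sample
    sample_col = np.repeat(sample_ids, config.sites_per_sample)

    imprinted, cna = _draw_intervals(rng, config, sample_ids)
    cna_by_sample: Dict[str, List[GenomicInterval]] = {s: [] for s in sample_ids}
    for segment in cna:
        cna_by_sample[segment.sample_id].append(segment)

    # --- truth classes ---------------------------------------------------
    p_g = config.frac_germline_contam
    p_c = config.frac_in_cna
    p_i = config.frac_in_imprinted
    p_som = 1.0 - p_g - p_c - p_i
    probs = np.array(
        [
            p_g,
            p_c,
            p_i,
            p_som * config.frac_som_e,
            p_som * config.frac_som_l,
            p_som * (1.0 - config.frac_som_e - config.frac_som_l),
        ]
    )
    class_names = np.array([TRUE_GERMLINE, TRUE_CNA, TRUE_IMPRINTED, SOM_E, SOM_L, TRUE_BALANCED])
    classes = class_names[rng.choice(len(class_names), size=n, p=probs)]

    # --- site placement --------------------------------------------------
    chroms = np.empty(n, dtype=object)
    positions = np.empty(n, dtype=np.int64)
    used: set = set()
    chrom_idx = rng.integers(0, len(_CHROMS), size=n)
    for i in range(n):
        cls = classes[i]
        if cls == TRUE_IMPRINTED:
            region = imprinted[int(rng.integers(0, len(imprinted)))]
            chrom = region.chrom
            pos = int(rng.integers(region.start, region.end + 1))
            while (chrom, pos) in used:
                pos = int(rng.integers(region.start, region.end + 1))
        elif cls == TRUE_CNA:
            segments = cna_by_sample[sample_col[i]]
            segment = segments[int(rng.integers(0, len(segments)))]
            chrom = segment.chrom
            pos = int(rng.integers(segment.start, segment.end + 1))
            while (chrom, pos) in used:
                pos = int(rng.integers(segment.start, segment.end + 1))
        else:
            chrom = _CHROMS[chrom_idx[i]]
            pos = int(rng.integers(_SITE_SPAN[0], _SITE_SPAN[1]))
            while (chrom, pos) in used:
                pos = int(rng.integers(_SITE_SPAN[0], _SITE_SPAN[1]))
        used.add((chrom, pos))
        chroms[i] = chrom
        positions[i] = pos

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    refs = _BASES[ref_idx]
    alts = _BASES[alt_idx]

    # --- read counts -----------------------------------------------------
    nd_depth = _negative_binomial(rng, config.coverage_mean_dna, config.coverage_dispersion, n)
    nr_depth = _negative_binomial(rng, config.coverage_mean_rna, config.coverage_dispersion, n)
    td_depth = _negative_binomial(rng, config.coverage_mean_dna, config.coverage_dispersion, n)
    tr_depth = _negative_binomial(rng, config.coverage_mean_rna, config.coverage_dispersion, n)

    is_germline = classes == TRUE_GERMLINE
    p_normal = np.where(is_germline, 0.5, config.seq_error)
    nd_var = rng.binomial(nd_depth, p_normal)
    nr_var = rng.binomial(nr_depth, p_normal)

    true_dna_vaf = np.where(is_germline, 0.5, config.purity / 2.0)
    td_var = rng.binomial(td_depth, true_dna_vaf)

    anchor = np.where(td_depth > 0, td_var / np.maximum(td_depth, 1), true_dna_vaf)
    rna_fraction = anchor.copy()
    rna_fraction[classes == SOM_E] = 1.0 - config.seq_error
    rna_fraction[classes == SOM_L] = config.seq_error
    rna_fraction[is_germline] = 0.5
    if config.rna_overdispersion > 0.0:
        rho = config.rna_overdispersion
        balanced_like = np.isin(classes, (TRUE_BALANCED, TRUE_CNA, TRUE_IMPRINTED))
        jitter_mask = balanced_like & (rna_fraction > 0.0) & (rna_fraction < 1.0)
        a = rna_fraction[jitter_mask] * (1.0 - rho) / rho
        b = (1.0 - rna_fraction[jitter_mask]) * (1.0 - rho) / rho
        rna_fraction[jitter_mask] = rng.beta(a, b)
    tr_var = rng.binomial(tr_depth, rna_fraction)

    # --- annotations -----------------------------------------------------
    n_genes = max(20, n // 4)
    gene_idx = rng.integers(0, n_genes, size=n)
    cgc_genes = set(rng.choice(n_genes, size=max(1, int(0.08 * n_genes)), replace=False).tolist())
    func_classes = np.array(["missense", "non-coding", "stop", "synonymous"])
    func = func_classes[rng.choice(4, size=n, p=[0.55, 0.30, 0.05, 0.10])]

    z = _copula_scores(rng, rna_fraction, config.score_rho)
    noise = rng.standard_normal(n)
    cadd = 15.0 + 8.0 * z
    fathmm = np.clip(-(1.2 * z + 0.6 * noise), -10.0, 10.0)
    gerp = 2.0 + 2.0 * (z + 0.5 * rng.standard_normal(n))
    polyphen = 1.0 / (1.0 + np.exp(-(z + 0.5 * rng.standard_normal(n))))
    grantham = np.abs(60.0 + 40.0 * (z + rng.standard_normal(n)))
    phast = 1.0 / (1.0 + np.exp(-(0.8 * z + rng.standard_normal(n))))
    missing = rng.random((4, n)) < 0.05  # gerp, polyphen, grantham, phast

    mode_draw = rng.random(n)
    mode_kind = rng.random(n)

    # --- assemble --------------------------------------------------------
    records: List[VariantRecord] = []
    annotations: Dict[SiteKey, AnnotationRecord] = {}
    truth_rows = []
    for i in range(n):
        site = SiteKey(chrom=str(chroms[i]), pos=int(positions[i]), ref=str(refs[i]), alt=str(alts[i]))
        gene = f"GENE{gene_idx[i]:05d}"
        in_cgc = int(gene_idx[i]) in cgc_genes
        if in_cgc or mode_draw[i] < 0.3:
            mode = "recessive" if mode_kind[i] < 0.5 else "dominant"
        else:
            mode = None
        annotation = AnnotationRecord(
            gene=gene,
            func_class=str(func[i]),
            cadd=float(cadd[i]),
            fathmm_score=float(fathmm[i]),
            fathmm_call="pathogenic" if fathmm[i] <= -1.5 else "neutral",
            gerp=None if missing[0, i] else float(gerp[i]),
            polyphen=None if missing[1, i] else float(polyphen[i]),
            grantham=None if missing[2, i] else float(grantham[i]),
            phast=None if missing[3, i] else float(phast[i]),
            in_cancer_gene_list=in_cgc,
            molecular_mode=mode,
        )
        annotations[site] = annotation
        counts = QuadCounts(
            normal_dna=AlleleCounts(int(nd_depth[i] - nd_var[i]), int(nd_var[i])),
            normal_rna=AlleleCounts(int(nr_depth[i] - nr_var[i]), int(nr_var[i])),
            tumor_dna=AlleleCounts(int(td_depth[i] - td_var[i]), int(td_var[i])),
            tumor_rna=AlleleCounts(int(tr_depth[i] - tr_var[i]), int(tr_var[i])),
        )
        records.append(
            VariantRecord(sample_id=str(sample_col[i]), site=site, counts=counts, annotation=annotation)
        )
        truth_rows.append(
            (
                str(sample_col[i]),
                site.chrom,
                site.pos,
                site.ref,
                site.alt,
                str(classes[i]),
                float(true_dna_vaf[i]),
                float(rna_fraction[i]),
                classes[i] == TRUE_CNA,
                classes[i] == TRUE_IMPRINTED,
            )
        )
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return records, imprinted + cna, annotations, truth


def _clopper_pearson(k: int, m: int, level: float = 0.95) -> Tuple[float, float]:
    if m == 0:
        return (float("nan"), float("nan"))
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, m - k + 1))
    hi = 1.0 if k == m else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, m - k))
    return (lo, hi)


def truth_confusion(calls: Sequence[ExpressionCall], truth: pd.DataFrame) -> ConfusionResult:
    """Confront calls with simulator ground truth.

    The matrix covers truth classes {SOM_E, SOM_L, BALANCED} restricted to
    sites that survived filtering (i.e. that have a call).  Every call must
    have a truth row, otherwise a :class:`JoinError` lists the orphans.
    """
    truth_map: Dict[Tuple[str, str, int, str, str], str] = {}
    for row in truth.itertuples(index=False):
        truth_map[(row.sample_id, row.chrom, int(row.pos), row.ref, row.alt)] = row.true_class

    call_to_truth = {SOM_E: SOM_E, SOM_L: SOM_L, EXPRESSED_BALANCED: TRUE_BALANCED}
    labels = [SOM_E, SOM_L, TRUE_BALANCED]
    matrix = pd.DataFrame(0, index=labels, columns=labels, dtype=int)

    orphans = []
    for call in calls:
        key = (call.sample_id, call.site.chrom, call.site.pos, call.site.ref, call.site.alt)
        if key not in truth_map:
            orphans.append(key)
            continue
        true_class = truth_map[key]
        if true_class in labels:
            matrix.loc[true_class, call_to_truth[call.call]] += 1
    if orphans:
        raise JoinError(f"{len(orphans)} call(s) without truth rows, e.g. {orphans[:3]}")

    per_class: Dict[str, ClassRates] = {}
    total = int(matrix.values.sum())
    for label in labels:
        tp = int(matrix.loc[label, label])
        row_sum = int(matrix.loc[label].sum())
        col_sum = int(matrix[label].sum())
        fp = col_sum - tp
        tn_fp = total - row_sum  # everything whose truth is not `label`
        sens = tp / row_sum if row_sum else float("nan")
        spec = (tn_fp - fp) / tn_fp if tn_fp else float("nan")
        per_class[label] = ClassRates(
            sensitivity=sens,
            sensitivity_ci=_clopper_pearson(tp, row_sum),
            specificity=spec,
            specificity_ci=_clopper_pearson(tn_fp - fp, tn_fp),
            n_truth=row_sum,
        )
    return ConfusionResult(matrix=matrix, per_class=per_class)


def write_cohort(
    out_dir: str,
    records: Sequence[VariantRecord],
    intervals: Sequence[GenomicInterval],
    annotations: Mapping[SiteKey, AnnotationRecord],
    truth: pd.DataFrame,
) -> Dict[str, str]:
    """Write the cohort in the exact dialects the readers consume.

    Emits ``counts.tsv``, ``imprinted.bed``, ``cna.seg``,
    ``annotations.tsv`` and ``truth.tsv`` under ``out_dir`` and returns the
    path of each artifact.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "counts": os.path.join(out_dir, "counts.tsv"),
        "imprinted": os.path.join(out_dir, "imprinted.bed"),
        "cna": os.path.join(out_dir, "cna.seg"),
        "annotations": os.path.join(out_dir, "annotations.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }

    with open(paths["counts"], "w") as handle:
        handle.write(
            "chrom\tpos\tref\talt\tnd_ref\tnd_var\tnr_ref\tnr_var\t"
            "td_ref\ttd_var\ttr_ref\ttr_var\tsample_id\n"
        )
        for r in records:
            c = r.counts
            handle.write(
                f"{r.site.chrom}\t{r.site.pos}\t{r.site.ref}\t{r.site.alt}\t"
                f"{c.normal_dna.ref_reads}\t{c.normal_dna.var_reads}\t"
                f"{c.normal_rna.ref_reads}\t{c.normal_rna.var_reads}\t"
                f"{c.tumor_dna.ref_reads}\t{c.tumor_dna.var_reads}\t"
                f"{c.tumor_rna.ref_reads}\t{c.tumor_rna.var_reads}\t"
                f"{r.sample_id}\n"
            )

    with open(paths["imprinted"], "w") as handle:
        for iv in intervals:
            if iv.label == "CNA":
                continue
            handle.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")

    with open(paths["cna"], "w") as handle:
        handle.write("sample\tchrom\tstart\tend\tnum_mark\tseg_mean\n")
        for iv in intervals:
            if iv.label != "CNA":
                continue
            handle.write(
                f"{iv.sample_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t0\t{iv.value:.6g}\n"
            )

    def fmt(x: Optional[float]) -> str:
        return "" if x is None else f"{x:.12g}"

    with open(paths["annotations"], "w") as handle:
        handle.write(
            "chrom\tpos\tref\talt\tgene\tfunc_class\tcadd\tfathmm_score\tfathmm_call\t"
            "gerp\tpolyphen\tgrantham\tphast\tin_cancer_gene_list\tmolecular_mode\n"
        )
        for site, ann in annotations.items():
            handle.write(
                f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{ann.gene}\t"
                f"{ann.func_class}\t{fmt(ann.cadd)}\t{fmt(ann.fathmm_score)}\t"
                f"{ann.fathmm_call or ''}\t{fmt(ann.gerp)}\t{fmt(ann.polyphen)}\t"
                f"{fmt(ann.grantham)}\t{fmt(ann.phast)}\t"
                f"{1 if ann.in_cancer_gene_list else 0}\t{ann.molecular_mode or ''}\n"
            )

    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
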