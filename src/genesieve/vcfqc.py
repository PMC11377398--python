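"""Variant-level quality control for multi-sample VCFs.

Re-derives per-site metrics (mean depth, genotype call rate, alternate-allele
frequency) from the genotype columns themselves rather than trusting INFO
tags, splits multi-allelic records into biallelic children with foreign-allele
genotypes masked to missing, and filters sites on QUAL / depth / call-rate
thresholds.  Phenotype-based sample exclusion (e.g. dropping a diagnosis
class that is out of scope for the analysis) happens first, and all metrics
are recomputed on the remaining samples.

Boundary semantics follow the exclusion wording the thresholds come from:
sites are removed when mean depth is *below* 8 or call rate *below* 90 %,
and retained only when QUAL is *strictly above* 30 — so mean_dp = 8 and
call_rate = 0.90 survive while qual = 30 does not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SiteRecord",
    "SiteMetrics",
    "Cohort",
    "read_vcf",
    "drop_samples_by_phenotype",
    "recompute_site_metrics",
    "split_multiallelic",
    "filter_sites",
    "run_qc",
]

MISSING = -1


@dataclass
class SiteRecord:
    """One VCF site: alleles, quality, per-sample genotype pairs and depths.

    ``genotypes`` is an (n_samples, 2) integer array of allele indices with
    -1 for a missing allele; a genotype with any missing allele counts as
    uncalled (half-calls are treated as missing).  ``depths`` is
    (n_samples,) with -1 where DP is absent.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple
    qual: float
    genotypes: np.ndarray
    depths: np.ndarray
    variant_id: str = "."

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be 1-based")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2:
            raise ValueError("genotypes must be (n_samples, 2)")
        if self.depths.shape != (self.genotypes.shape[0],):
            raise ValueError("depths length mismatch")
        if (self.genotypes > len(self.alts)).any():
            raise ValueError("allele index exceeds 1 + number of ALT alleles")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def called(self) -> np.ndarray:
        return (self.genotypes >= 0).all(axis=1)


@dataclass(frozen=True)
class SiteMetrics:
    mean_dp: float
    call_rate: float
    af: float


@dataclass
class Cohort:
    sample_ids: list
    records: list

    def subset_samples(self, keep_idx) -> "Cohort":
        keep_idx = np.asarray(keep_idx)
        records = [
            replace(r, genotypes=r.genotypes[keep_idx], depths=r.depths[keep_idx])
            for r in self.records
        ]
        return Cohort([self.sample_ids[i] for i in keep_idx], records)


def read_vcf(path) -> Cohort:
    """Load GT and DP columns of a multi-sample VCF into site records."""
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        records = []
        for rec in vcf:
            n = len(sample_ids)
            gt = np.full((n, 2), MISSING, dtype=np.int16)
            dp = np.full(n, MISSING, dtype=np.int32)
            for i, s in enumerate(sample_ids):
                call = rec.samples[s]
                alleles = call.get("GT", (None, None))
                if alleles is not None and len(alleles) == 2:
                    gt[i] = [MISSING if a is None else a for a in alleles]
                d = call.get("DP")
                if d is not None:
                    dp[i] = d
            records.append(
                SiteRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=float(rec.qual) if rec.qual is not None else float("nan"),
                    genotypes=gt,
                    depths=dp,
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                )
            )
    return Cohort(sample_ids, records)


def drop_samples_by_phenotype(cohort: Cohort, phenotypes, excluded_label) -> Cohort:
    """Remove every sample labeled ``excluded_label`` from all site records.

    ``phenotypes`` maps sample_id -> label (a dict or a DataFrame with
    ``sample_id`` and ``label`` columns).  A VCF sample without a phenotype
    entry is an error; excluding every sample is an error.
    """
    if isinstance(phenotypes, pd.DataFrame):
        phenotypes = dict(zip(phenotypes["sample_id"], phenotypes["label"]))
    missing = [s for s in cohort.sample_ids if s not in phenotypes]
    if missing:
        raise ValueError(f"samples missing from phenotype table: {missing}")
    keep = [i for i, s in enumerate(cohort.sample_ids) if phenotypes[s] != excluded_label]
    if not keep:
        raise ValueError("phenotype exclusion removed every sample")
    if len(keep) == len(cohort.sample_ids):
        return cohort
    return cohort.subset_samples(keep)


def recompute_site_metrics(record: SiteRecord) -> SiteMetrics:
    """Mean depth, call rate and ALT frequency from the genotype columns.

    mean_dp averages the non-missing per-sample depths (NaN when none);
    call_rate counts fully-called genotypes over all samples; af counts
    alternate alleles over called alleles (biallelic records).  A called
    genotype with a missing DP still counts as called — depth and genotype
    are independent tags.
    """
    if record.n_samples == 0:
        raise ValueError("record has no samples")
    has_dp = record.depths >= 0
    mean_dp = float(record.depths[has_dp].mean()) if has_dp.any() else float("nan")
    called = record.called
    call_rate = float(called.mean())
    alleles = record.genotypes[called]
    if alleles.size:
        af = float((alleles > 0).sum() / alleles.size)
    else:
        af = float("nan")
    return SiteMetrics(mean_dp=mean_dp, call_rate=call_rate, af=af)


def split_multiallelic(record: SiteRecord) -> list:
    """Split a multi-allelic site into one biallelic record per ALT allele.

    In each child, any genotype carrying an allele other than REF or that
    child's ALT is set to missing, and the surviving genotypes are re-coded
    to the {0, 1} alphabet.  Biallelic records pass through unchanged.
    """
    if len(record.alts) == 0:
        raise ValueError("record has no ALT allele")
    if len(record.alts) == 1:
        return [record]
    children = []
    for a, alt in enumerate(record.alts, start=1):
        gt = record.genotypes.copy()
        foreign = ((gt != 0) & (gt != a)) | (gt == MISSING)
        mask = foreign.any(axis=1)
        gt[mask] = MISSING
        gt[gt == a] = 1
        children.append(
            replace(
                record,
                alts=(alt,),
                genotypes=gt,
                variant_id=f"{record.variant_id}_{alt}" if len(record.alts) > 1 else record.variant_id,
            )
        )
    return children


def filter_sites(
    records,
    min_qual: float = 30.0,
    min_mean_dp: float = 8.0,
    min_call_rate: float = 0.90,
):
    """Apply the QUAL / mean-depth / call-rate site filters.

    Keeps records with qual strictly above ``min_qual``, mean_dp >=
    ``min_mean_dp`` and call_rate >= ``min_call_rate``, each recomputed on
    the record as given.  Returns the survivors and a per-site log frame
    with the metric values, verdict and failure reasons.  Idempotent by
    construction: survivors re-filtered are unchanged.
    """
    kept, log_rows = [], []
    for rec in records:
        m = recompute_site_metrics(rec)
        reasons = []
        if not rec.qual > min_qual:
            reasons.append(f"qual<={min_qual:g}")
        if not m.mean_dp >= min_mean_dp:  # NaN mean_dp fails here
            reasons.append(f"mean_dp<{min_mean_dp:g}")
        if not m.call_rate >= min_call_rate:
            reasons.append(f"call_rate<{min_call_rate:g}")
        verdict = "keep" if not reasons else "drop"
        if verdict == "keep":
            kept.append(rec)
        log_rows.append(
            {
                "variant_id": rec.variant_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "qual": rec.qual,
                "mean_dp": m.mean_dp,
                "call_rate": m.call_rate,
                "af": m.af,
                "verdict": verdict,
                "reason": ";".join(reasons),
            }
        )
    return kept, pd.DataFrame(log_rows)


def run_qc(
    cohort: Cohort,
    phenotypes=None,
    excluded_label=None,
    min_qual: float = 30.0,
    min_mean_dp: float = 8.0,
    min_call_rate: float = 0.90,
    site_whitelist=None,
):
    """Full QC pass: sample exclusion, multi-allelic split, site filtering.

    ``site_whitelist`` is a pass-through hook for externally recalibrated
    sites (e.g. a VQSR-passing list): when given, only records whose
    variant_id is listed survive, before metric filtering.  Returns the
    filtered cohort and the filter log.
    """
    if excluded_label is not None:
        if phenotypes is None:
            raise ValueError("excluded_label given without a phenotype table")
        cohort = drop_samples_by_phenotype(cohort, phenotypes, excluded_label)
    split_records = []
    for rec in cohort.records:
        split_records.extend(split_multiallelic(rec))
    if site_whitelist is not None:
        wl = set(site_whitelist)
        split_records = [r for r in split_records if r.variant_id in wl]
    kept, log = filter_sites(
        split_records,
        min_qual=min_qual,
        min_mean_dp=min_mean_dp,
        min_call_rate=min_call_rate,
    )
    return Cohort(cohort.sample_ids, kept), log
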