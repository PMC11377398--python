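"""Variant screening by genotype association and network-topology construction.

The screening stage reduces an exome-scale genotype matrix to the variants
whose genotype distribution differs between cases and controls, using a
Pearson chi-squared test on a phenotype-class x genotype contingency table.
P-values are deliberately left uncorrected for multiple testing: the screen
is a dimensionality-reduction device, not an association study, and the
representativeness of the retained set is assessed downstream by
over-representation analysis.

The retained variants, together with a variant-to-gene annotation table,
define the sparse connectivity of the gene network: one topology row per
variant, each variant wired to exactly one gene node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "TopologyMap",
    "EncodedMatrix",
    "exclude_indels_and_sex_chromosomes",
    "genotype_contingency",
    "chi2_test",
    "association_scan",
    "select_variants",
    "encode_additive",
    "build_topology",
]

MISSING = -1

_SEX_CHROMOSOMES = {"X", "Y", "23", "24", "XY", "MT", "M"}
# 23/24 are PLINK-style numeric codes for X/Y; MT is excluded alongside the
# sex chromosomes because the autosomal-SNP restriction applies to both.


def _normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


@dataclass(frozen=True)
class ContingencyTable:
    """Phenotype-class x genotype counts (rows: case, control; columns: 0/1/2).

    Missing genotypes are excluded from the counts, so row sums equal the
    per-class numbers of called genotypes, not the class sizes.
    """

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != 2:
            raise ValueError("contingency table must have exactly 2 class rows")
        if (counts < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def informative_columns(self) -> np.ndarray:
        return np.flatnonzero(self.counts.sum(axis=0) > 0)


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    df: int
    p_value: float
    testable: bool = True

    def __post_init__(self):
        if self.testable and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def exclude_indels_and_sex_chromosomes(records, log=None):
    """Keep biallelic single-nucleotide variants on non-sex chromosomes.

    A record survives when both REF and ALT are single bases and its
    chromosome is not X/Y (or a recognised synonym).  Unrecognised
    chromosome names are kept and noted in ``log`` (a list, if provided):
    dropping a variant needs positive evidence that it is non-autosomal.
    """
    kept = []
    for rec in records:
        if len(rec.alts) != 1:
            raise ValueError(
                f"record {rec.chrom}:{rec.pos} is not biallelic; split multi-allelics first"
            )
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            continue
        chrom = _normalize_chrom(rec.chrom)
        if chrom in _SEX_CHROMOSOMES:
            continue
        if not chrom.isdigit() and log is not None:
            log.append(f"unrecognised chromosome name kept: {rec.chrom}:{rec.pos}")
        kept.append(rec)
    return kept


def genotype_contingency(genotypes, labels, include_missing: bool = False) -> ContingencyTable:
    """Tally additive genotype codes {0,1,2} per phenotype class.

    ``labels`` is binary with 1 = case; the case row comes first.  With
    ``include_missing`` a fourth column counts missing genotypes (otherwise
    they are simply left out).
    """
    g = np.asarray(genotypes)
    y = np.asarray(labels)
    if g.shape != y.shape:
        raise ValueError("genotypes and labels differ in length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    called = g != MISSING
    if not np.isin(g[called], (0, 1, 2)).all():
        raise ValueError("genotype codes must be in {0,1,2} or missing")
    for cls in (1, 0):
        if not (called & (y == cls)).any():
            raise ValueError(f"class {cls} has no called genotypes")
    n_cols = 4 if include_missing else 3
    counts = np.zeros((2, n_cols), dtype=np.int64)
    for row, cls in enumerate((1, 0)):
        sel = g[(y == cls) & called]
        for code in (0, 1, 2):
            counts[row, code] = int((sel == code).sum())
        if include_missing:
            counts[row, 3] = int(((y == cls) & ~called).sum())
    return ContingencyTable(counts)


def chi2_test(table: ContingencyTable) -> AssociationResult:
    """Pearson chi-squared test of genotype-by-class independence.

    Genotype columns with zero total are dropped before the test, and the
    degrees of freedom shrink accordingly; with fewer than two informative
    columns the variant is flagged untestable (statistic NaN) and excluded
    from selection rather than given an arbitrary p-value.
    """
    cols = table.informative_columns
    if len(cols) < 2:
        return AssociationResult(float("nan"), 0, float("nan"), testable=False)
    observed = table.counts[:, cols]
    stat, p, df, _ = stats.chi2_contingency(observed, correction=False)
    if stat == 0.0:
        p = 1.0
    return AssociationResult(float(stat), int(df), float(p))


def association_scan(encoded: "EncodedMatrix", labels, alpha: float = 0.05) -> pd.DataFrame:
    """Run the chi-squared screen over every variant of an encoded matrix."""
    y = np.asarray(labels)
    rows = []
    for j, vid in enumerate(encoded.variant_ids):
        try:
            res = chi2_test(genotype_contingency(encoded.values[:, j], y))
        except ValueError:
            res = AssociationResult(float("nan"), 0, float("nan"), testable=False)
        rows.append(
            {
                "variant_id": vid,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "testable": res.testable,
            }
        )
    out = pd.DataFrame(rows)
    out["selected"] = out["testable"] & (out["p_value"] < alpha)
    return out


def select_variants(scan: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Variants with uncorrected p strictly below ``alpha`` (p == alpha is out)."""
    mask = scan["testable"] & (scan["p_value"] < alpha)
    return scan.loc[mask, "variant_id"].tolist()


def encode_additive(records, sample_ids) -> "EncodedMatrix":
    """Additive (alternate-allele count) encoding of biallelic genotype calls.

    0/0 -> 0, 0/1 -> 1, 1/1 -> 2; genotypes with any missing allele stay
    missing at this stage.  Allele indices above 1 are an error: such
    records must have been split and masked upstream.
    """
    n = len(sample_ids)
    values = np.full((n, len(records)), MISSING, dtype=np.int8)
    variant_ids = []
    for j, rec in enumerate(records):
        if len(rec.alts) != 1:
            raise ValueError("encode_additive requires biallelic records")
        gt = np.asarray(rec.genotypes)
        if gt.shape != (n, 2):
            raise ValueError("genotype array does not match sample count")
        if (gt > 1).any():
            raise ValueError(
                f"allele index > 1 at {rec.chrom}:{rec.pos}; split multi-allelics first"
            )
        called = (gt >= 0).all(axis=1)
        values[called, j] = gt[called].sum(axis=1)
        variant_ids.append(rec.variant_id)
    return EncodedMatrix(values=values, sample_ids=list(sample_ids), variant_ids=variant_ids)


@dataclass
class EncodedMatrix:
    """Samples x variants additive genotype codes with ``-1`` marking missing."""

    values: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("matrix shape does not match id lists")
        ok = np.isin(self.values, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValueError("encoded values outside {missing,0,1,2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset_samples(self, keep_idx) -> "EncodedMatrix":
        keep_idx = np.asarray(keep_idx)
        return EncodedMatrix(
            values=self.values[keep_idx],
            sample_ids=[self.sample_ids[i] for i in keep_idx],
            variant_ids=list(self.variant_ids),
        )

    def subset_variants(self, variant_ids) -> "EncodedMatrix":
        pos = {v: j for j, v in enumerate(self.variant_ids)}
        idx = [pos[v] for v in variant_ids]
        return EncodedMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            variant_ids=list(variant_ids),
        )


@dataclass
class TopologyMap:
    """Variant-node to gene-node wiring of the sparse network.

    One row per variant, in model input order; ``gene_node`` indices are
    0-based and numbered by first appearance, so every gene node maps to
    exactly one gene symbol and the node ranges are consecutive.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("variant_node", "variant", "gene_node", "gene")

    def __post_init__(self):
        t = self.table
        if tuple(t.columns) != self.COLUMNS:
            raise ValueError(f"topology columns must be {self.COLUMNS}")
        self.table = t.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        if len(t) == 0:
            raise ValueError("empty topology")
        vn = t["variant_node"].to_numpy()
        if not np.array_equal(vn, np.arange(len(t))):
            raise ValueError("variant_node must be consecutive from 0")
        if t["variant"].duplicated().any():
            raise ValueError("duplicate variant ids in topology")
        gn = t["gene_node"].to_numpy()
        uniq = np.unique(gn)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("gene_node values must form a consecutive 0-based range")
        per_node = t.groupby("gene_node")["gene"].nunique()
        if (per_node != 1).any():
            raise ValueError("a gene_node maps to more than one gene id")
        per_gene = t.groupby("gene")["gene_node"].nunique()
        if (per_gene != 1).any():
            raise ValueError("a gene id maps to more than one gene_node")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def n_genes(self) -> int:
        return int(self.table["gene_node"].max()) + 1

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant"].tolist()

    @property
    def gene_ids(self) -> list[str]:
        return (
            self.table.drop_duplicates("gene_node")
            .sort_values("gene_node")["gene"]
            .tolist()
        )

    @property
    def gene_index(self) -> np.ndarray:
        """Per-variant gene-node index, aligned with model input order."""
        return self.table["gene_node"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TopologyMap":
        t = pd.read_csv(path, dtype={"variant": str, "gene": str})
        return cls(t[list(cls.COLUMNS)])


def build_topology(variant_ids, annotation: pd.DataFrame, priority=None) -> TopologyMap:
    """Wire each selected variant to a single gene node from an annotation table.

    ``annotation`` has columns ``variant_id`` and ``gene`` and may carry
    several gene rows per variant; multi-gene annotations resolve to the
    alphabetically first symbol unless a ``priority`` list names preferred
    genes (earlier wins).  Variants without any annotation abort with the
    full list of offenders.
    """
    by_variant: dict[str, list[str]] = {}
    for vid, gene in zip(annotation["variant_id"], annotation["gene"]):
        by_variant.setdefault(str(vid), []).append(str(gene))

    missing = [v for v in variant_ids if v not in by_variant]
    if missing:
        raise ValueError(f"unannotated variants: {missing}")

    rank = {g: i for i, g in enumerate(priority)} if priority else {}

    def resolve(genes: list[str]) -> str:
        return min(set(genes), key=lambda g: (rank.get(g, len(rank)), g))

    gene_node: dict[str, int] = {}
    rows = []
    for i, vid in enumerate(variant_ids):
        gene = resolve(by_variant[vid])
        if gene not in gene_node:
            gene_node[gene] = len(gene_node)
        rows.append((i, vid, gene_node[gene], gene))
    return TopologyMap(pd.DataFrame(rows, columns=list(TopologyMap.COLUMNS)))
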