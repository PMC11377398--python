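"""Synthetic case-control cohorts with known genetic architecture and label noise.

Real cohorts of this kind are controlled-access, so every downstream stage is
exercised on simulated data whose ground truth is known.  The generator draws
biallelic autosomal SNP genotypes in Hardy-Weinberg proportions over a
log-uniform allele-frequency spectrum, gives a subset of genes causal effects
on a liability-threshold phenotype, and assembles observed case/control pools
in which a configurable fraction of each pool carries the wrong label —
standing in for misdiagnosed cases and undiagnosed controls.

The defaults are the scaled study conditions used throughout the analysis:
1,200 cases and 1,200 controls typed at 400 variants on 120 genes, 30 of them
causal with per-gene effect scale 1.0 (genetic heritability of liability
~0.97, so a genotype-only oracle separates true classes almost perfectly),
and a 10 % mislabeling rate in the case pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .association import EncodedMatrix, TopologyMap

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "SimulatedCohort",
    "draw_mafs",
    "sample_genotypes",
    "contiguous_topology",
    "simulate_phenotype",
    "inject_label_noise",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated study.

    ``prevalence`` calibrates the liability threshold (upper-quantile cut on
    the empirical liability distribution); ``case_flip_rate`` /
    ``control_flip_rate`` give the fraction of the *observed* case/control
    pools whose true label is the opposite class.
    """

    n_cases: int = 1200
    n_controls: int = 1200
    n_variants: int = 400
    n_genes: int = 120
    maf_low: float = 0.005
    maf_high: float = 0.5
    n_causal_genes: int = 30
    effect_sd: float = 1.0
    prevalence: float = 0.30
    case_flip_rate: float = 0.10
    control_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes > n_genes")
        if self.n_genes > self.n_variants:
            raise ValueError("n_genes > n_variants")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        for r in (self.case_flip_rate, self.control_flip_rate):
            if not (0 <= r <= 1):
                raise ValueError("flip rates must be in [0, 1]")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort.

    ``observed_label`` is what the pipeline sees; ``true_label`` is the
    liability-threshold assignment; ``flipped`` marks samples whose observed
    label disagrees with truth.  ``genetic_liability`` excludes the
    environmental noise term and serves as the oracle classifier score.
    """

    sample_ids: list[str]
    true_label: np.ndarray
    observed_label: np.ndarray
    flipped: np.ndarray
    liability: np.ndarray
    genetic_liability: np.ndarray
    causal_gene_ids: list[str]
    gene_effects: np.ndarray
    threshold: float = float("nan")

    def __post_init__(self):
        n = len(self.sample_ids)
        for name in ("true_label", "observed_label", "flipped", "liability", "genetic_liability"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} has wrong length")
            setattr(self, name, arr)
        if not np.array_equal(self.flipped, self.true_label != self.observed_label):
            raise ValueError("flipped mask must be the XOR of true and observed labels")

    def subset(self, idx) -> "CohortTruth":
        idx = np.asarray(idx)
        return CohortTruth(
            sample_ids=[self.sample_ids[i] for i in idx],
            true_label=self.true_label[idx],
            observed_label=self.observed_label[idx],
            flipped=self.flipped[idx],
            liability=self.liability[idx],
            genetic_liability=self.genetic_liability[idx],
            causal_gene_ids=list(self.causal_gene_ids),
            gene_effects=self.gene_effects,
            threshold=self.threshold,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "true_label": self.true_label.astype(int),
                "observed_label": self.observed_label.astype(int),
                "flipped": self.flipped.astype(int),
                "liability": self.liability,
                "genetic_liability": self.genetic_liability,
            }
        )


def draw_mafs(n_variants: int, maf_low: float, maf_high: float, rng) -> np.ndarray:
    """Log-uniform minor-allele frequencies, mimicking a rare-heavy exome spectrum."""
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    return np.exp(rng.uniform(math.log(maf_low), math.log(maf_high), size=n_variants))


def sample_genotypes(maf_vector, n_samples: int, seed: int) -> EncodedMatrix:
    """Draw additive genotype codes under Hardy-Weinberg equilibrium.

    Variant j is drawn i.i.d. across samples with P(2) = maf^2,
    P(1) = 2 maf (1-maf), P(0) = (1-maf)^2.
    """
    maf = np.asarray(maf_vector, dtype=float)
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    # two independent allele draws per sample per variant
    alleles = rng.random((2, n_samples, maf.size)) < maf[None, None, :]
    values = alleles.sum(axis=0).astype(np.int8)
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    variant_ids = [f"var{j:05d}" for j in range(maf.size)]
    return EncodedMatrix(values=values, sample_ids=sample_ids, variant_ids=variant_ids)


def contiguous_topology(
    n_variants: int,
    n_genes: int,
    variant_ids=None,
    gene_ids=None,
    permute: bool = False,
    seed: int = 0,
) -> TopologyMap:
    """Assign variant i to gene floor(i * n_genes / n_variants).

    The contiguous blocks keep gene sizes balanced; ``permute`` shuffles the
    variant-to-gene assignment while preserving block sizes.
    """
    if n_genes > n_variants:
        raise ValueError("n_genes > n_variants")
    if variant_ids is None:
        variant_ids = [f"var{j:05d}" for j in range(n_variants)]
    if gene_ids is None:
        gene_ids = [f"GENE{g:04d}" for g in range(n_genes)]
    assignment = (np.arange(n_variants) * n_genes) // n_variants
    if permute:
        rng = np.random.default_rng(seed)
        assignment = rng.permutation(assignment)
        # renumber gene nodes by first appearance to keep the map canonical
        order = {}
        renumbered = np.empty_like(assignment)
        new_gene_ids = []
        for i, g in enumerate(assignment):
            if g not in order:
                order[g] = len(order)
                new_gene_ids.append(gene_ids[g])
            renumbered[i] = order[g]
        assignment, gene_ids = renumbered, new_gene_ids
    rows = [
        (i, variant_ids[i], int(assignment[i]), gene_ids[int(assignment[i])])
        for i in range(n_variants)
    ]
    return TopologyMap(pd.DataFrame(rows, columns=list(TopologyMap.COLUMNS)))


def _gene_scores(genotypes: EncodedMatrix, topology: TopologyMap) -> np.ndarray:
    """Standardized per-gene burden: z-scored sum of the gene's additive codes."""
    gene_idx = topology.gene_index
    X = genotypes.values.astype(float)
    X[genotypes.values < 0] = 0.0
    n_genes = topology.n_genes
    burden = np.zeros((X.shape[0], n_genes))
    for g in range(n_genes):
        burden[:, g] = X[:, gene_idx == g].sum(axis=1)
    sd = burden.std(axis=0)
    sd[sd == 0] = 1.0
    return (burden - burden.mean(axis=0)) / sd


def simulate_phenotype(
    genotypes: EncodedMatrix, topology: TopologyMap, config: CohortConfig
) -> CohortTruth:
    """Liability-threshold phenotype over a simulated sample pool.

    liability_i = sum over causal genes of beta_g * s_ig + eps_i, with s_ig
    the standardized gene burden, beta_g ~ N(0, effect_sd^2) and eps standard
    normal.  A sample is a true case when its liability exceeds the empirical
    upper-``prevalence`` quantile.  Observed labels start equal to truth;
    pool assembly and label flipping happen in :func:`inject_label_noise`.
    """
    if topology.n_variants != genotypes.n_variants:
        raise ValueError("topology does not cover the genotype matrix")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n_genes = topology.n_genes
    causal = rng.choice(n_genes, size=config.n_causal_genes, replace=False)
    effects = np.zeros(n_genes)
    effects[causal] = rng.normal(0.0, config.effect_sd, size=config.n_causal_genes)
    scores = _gene_scores(genotypes, topology)
    genetic = scores @ effects
    liability = genetic + rng.standard_normal(genotypes.n_samples)
    threshold = float(np.quantile(liability, 1.0 - config.prevalence))
    true_label = (liability > threshold).astype(np.int8)
    gene_ids = topology.gene_ids
    return CohortTruth(
        sample_ids=list(genotypes.sample_ids),
        true_label=true_label,
        observed_label=true_label.copy(),
        flipped=np.zeros(genotypes.n_samples, dtype=bool),
        liability=liability,
        genetic_liability=genetic,
        causal_gene_ids=[gene_ids[g] for g in sorted(causal)],
        gene_effects=effects,
        threshold=threshold,
    )


def _flip_count(rate: float, pool_size: int) -> int:
    # banker's rounding (round-half-even) on rate * n, exact and deterministic
    return int(np.rint(rate * pool_size))


def inject_label_noise(
    truth: CohortTruth,
    case_flip_rate: float,
    control_flip_rate: float,
    seed: int,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> tuple[CohortTruth, np.ndarray]:
    """Assemble observed case/control pools containing mislabeled samples.

    The observed case pool of size ``n_cases`` contains exactly
    round(case_flip_rate x n_cases) true controls (misdiagnosed cases) drawn
    uniformly from the true-control reserve, and symmetrically for the
    control pool (undiagnosed controls).  Returns the cohort truth restricted
    to the assembled pools (cases first) plus the selected indices into the
    input truth, so the caller can subset the genotype matrix identically.

    With both rates zero and pool sizes covering every sample this is the
    identity up to ordering.  Raises when the simulated pool cannot supply
    the requested composition.
    """
    for r in (case_flip_rate, control_flip_rate):
        if not (0 <= r <= 1):
            raise ValueError("flip rates must be in [0, 1]")
    true_cases = np.flatnonzero(truth.true_label == 1)
    true_controls = np.flatnonzero(truth.true_label == 0)
    if n_cases is None:
        n_cases = len(true_cases)
    if n_controls is None:
        n_controls = len(true_controls)

    k_case = _flip_count(case_flip_rate, n_cases)        # true controls labeled case
    k_control = _flip_count(control_flip_rate, n_controls)  # true cases labeled control
    need_cases = (n_cases - k_case) + k_control
    need_controls = k_case + (n_controls - k_control)
    if need_cases > len(true_cases) or need_controls > len(true_controls):
        raise ValueError(
            f"simulated pool too small: need {need_cases} true cases "
            f"(have {len(true_cases)}) and {need_controls} true controls "
            f"(have {len(true_controls)}); enlarge the simulation"
        )

    rng = np.random.default_rng(seed)
    cases_drawn = rng.permutation(true_cases)
    controls_drawn = rng.permutation(true_controls)

    case_pool = np.concatenate(
        [cases_drawn[: n_cases - k_case], controls_drawn[:k_case]]
    )
    control_pool = np.concatenate(
        [controls_drawn[k_case : k_case + (n_controls - k_control)],
         cases_drawn[n_cases - k_case : n_cases - k_case + k_control]]
    )
    selected = np.concatenate([case_pool, control_pool]).astype(int)

    cohort = truth.subset(selected)
    observed = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    cohort.observed_label = observed
    cohort.flipped = cohort.true_label != observed
    return cohort, selected


@dataclass
class SimulatedCohort:
    """A fully assembled synthetic cohort: genotypes, topology, ground truth."""

    genotypes: EncodedMatrix
    topology: TopologyMap
    truth: CohortTruth
    maf: np.ndarray
    config: CohortConfig


def simulate_cohort(config: CohortConfig, pool_margin: float = 1.25) -> SimulatedCohort:
    """End-to-end cohort generation under one seed.

    Simulates a sample pool large enough to supply the requested observed
    pools (sized by prevalence with a safety margin), labels it with the
    liability-threshold model, assembles the observed case/control pools
    with the configured mislabeling composition, and subsets the genotype
    matrix to the assembled cohort.  Same seed, same cohort, bit for bit.
    """
    k_case = _flip_count(config.case_flip_rate, config.n_cases)
    k_control = _flip_count(config.control_flip_rate, config.n_controls)
    need_cases = (config.n_cases - k_case) + k_control
    need_controls = k_case + (config.n_controls - k_control)
    pool = int(
        math.ceil(
            pool_margin
            * max(need_cases / config.prevalence, need_controls / (1 - config.prevalence))
        )
    )
    ss = np.random.SeedSequence([config.seed, 1])
    maf_rng = np.random.default_rng(ss)
    maf = draw_mafs(config.n_variants, config.maf_low, config.maf_high, maf_rng)
    geno_seed = int(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % (2**31))
    genotypes = sample_genotypes(maf, pool, geno_seed)
    topology = contiguous_topology(
        config.n_variants, config.n_genes, variant_ids=genotypes.variant_ids
    )
    truth = simulate_phenotype(genotypes, topology, config)
    flip_seed = int(np.random.SeedSequence([config.seed, 3]).generate_state(1)[0] % (2**31))
    cohort_truth, selected = inject_label_noise(
        truth,
        config.case_flip_rate,
        config.control_flip_rate,
        seed=flip_seed,
        n_cases=config.n_cases,
        n_controls=config.n_controls,
    )
    cohort_geno = genotypes.subset_samples(selected)
    return SimulatedCohort(
        genotypes=cohort_geno,
        topology=topology,
        truth=cohort_truth,
        maf=maf,
        config=config,
    )


_CODE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_cohort(
    genotypes: EncodedMatrix,
    truth: CohortTruth,
    topology: TopologyMap,
    out_prefix,
    qual: float = 60.0,
    mean_dp: float = 30.0,
    low_dp_fraction: float = 0.0,
    low_dp_mean: float = 4.0,
    seed: int = 0,
) -> dict:
    """Write the cohort as VCF + phenotype/truth TSVs + topology CSV.

    Per-sample depths are Poisson(``mean_dp``) clipped to >= 8 so the QC
    thresholds are not tripped by default; ``low_dp_fraction`` of sites
    instead get Poisson(``low_dp_mean``) depths (mean < 8) to exercise the
    depth filter, and their ids are returned under ``low_dp_variants``.
    Variants are placed on autosomes 1..22 in round-robin order with A->G
    alleles; the VCF carries GT and DP FORMAT fields and a constant QUAL.
    """
    if truth.sample_ids != genotypes.sample_ids:
        raise ValueError("truth and genotype sample ids disagree")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_samples, n_variants = genotypes.values.shape

    n_low = int(round(low_dp_fraction * n_variants))
    low_sites = set(rng.choice(n_variants, size=n_low, replace=False).tolist())

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for c in range(1, 23):
        header.contigs.add(str(c))
    for s in genotypes.sample_ids:
        header.add_sample(s)

    vcf_path = out_prefix.with_suffix(".vcf")
    low_dp_variants = []
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for j, vid in enumerate(genotypes.variant_ids):
            chrom = str(j % 22 + 1)
            pos = 1000 + 10 * (j // 22)
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, stop=pos, alleles=("A", "G"), id=vid
            )
            rec.qual = qual
            if j in low_sites:
                depths = rng.poisson(low_dp_mean, size=n_samples)
                low_dp_variants.append(vid)
            else:
                depths = np.maximum(rng.poisson(mean_dp, size=n_samples), 8)
            for i, s in enumerate(genotypes.sample_ids):
                code = int(genotypes.values[i, j])
                rec.samples[s]["GT"] = _CODE_TO_GT.get(code, (None, None))
                rec.samples[s]["DP"] = int(depths[i])
            vcf.write(rec)

    pheno_path = out_prefix.parent / (out_prefix.name + ".phenotypes.tsv")
    pd.DataFrame(
        {"sample_id": truth.sample_ids, "label": truth.observed_label.astype(int)}
    ).to_csv(pheno_path, sep="\t", index=False)

    truth_path = out_prefix.parent / (out_prefix.name + ".truth.tsv")
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)

    topo_path = out_prefix.parent / (out_prefix.name + ".topology.csv")
    topology.to_csv(topo_path)

    causal_path = out_prefix.parent / "causal_genes.txt"
    causal_path.write_text("\n".join(truth.causal_gene_ids) + "\n")

    return {
        "causal_genes": causal_path,
        "vcf": vcf_path,
        "phenotypes": pheno_path,
        "truth": truth_path,
        "topology": topo_path,
        "low_dp_variants": low_dp_variants,
    }
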