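#!/usr/bin/env python
"""Chi-squared association screen and topology construction.

Restricts the QC'd sites to biallelic autosomal SNPs, encodes genotypes
additively, tests each variant's genotype distribution between observed
cases and controls (2 classes x 3 genotypes, zero columns dropped, no
multiple-testing correction — the screen is dimensionality reduction), and
wires the selected variants to their genes.  The variant-to-gene annotation
is read from the cohort's topology CSV, standing in for an external
annotation table.
"""

import argparse
from pathlib import Path

import pandas as pd

from genesieve.association import (
    association_scan,
    build_topology,
    encode_additive,
    exclude_indels_and_sex_chromosomes,
    select_variants,
)
from genesieve.vcfqc import read_vcf, run_qc


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    cohort_dir = args.results_dir / "cohort"
    cohort = read_vcf(cohort_dir / "cohort.vcf")
    cohort, _ = run_qc(cohort)
    records = exclude_indels_and_sex_chromosomes(cohort.records)
    encoded = encode_additive(records, cohort.sample_ids)
    pheno = pd.read_csv(cohort_dir / "cohort.phenotypes.tsv", sep="\t")
    labels = pheno.set_index("sample_id").loc[encoded.sample_ids, "label"].to_numpy()

    scan = association_scan(encoded, labels, alpha=args.alpha)
    scan_path = args.results_dir / "association_scan.tsv"
    scan.to_csv(scan_path, sep="\t", index=False)
    selected = select_variants(scan, alpha=args.alpha)
    print(f"variants tested: {int(scan['testable'].sum())} of {len(scan)}; "
          f"selected at p < {args.alpha:g}: {len(selected)}")

    annotation = pd.read_csv(cohort_dir / "cohort.topology.csv").rename(
        columns={"variant": "variant_id"})[["variant_id", "gene"]]
    topo = build_topology(selected, annotation)
    topo_path = args.results_dir / "selected_topology.csv"
    topo.to_csv(topo_path)
    print(f"topology: {topo.n_variants} variant nodes -> {topo.n_genes} gene nodes")
    print(f"wrote {scan_path}\nwrote {topo_path}")


if __name__ == "__main__":
    main()
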