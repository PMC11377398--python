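#!/usr/bin/env python
"""Gene prioritization and over-representation analysis.

Averages each gene node's output-layer weight across a freshly trained
ensemble, takes the top-ranked genes, and runs a hypergeometric
over-representation analysis against a small synthetic gene-set collection:
one set holding the truly causal genes and several random sets of the same
size.  If the network concentrates weight on causal genes, the causal set
shows a large enrichment ratio and a small FDR while the random sets do not.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from genesieve.association import TopologyMap, encode_additive
from genesieve.enrichment import GeneSetCollection, ora_test, top_gene_list
from genesieve.network import TrainConfig, build_model, gene_importances, prepare_inputs, train
from genesieve.pipeline import derive_seeds
from genesieve.vcfqc import read_vcf


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    ap.add_argument("--n-models", type=int, default=5)
    ap.add_argument("--top-k", type=int, default=20)
    args = ap.parse_args()

    cohort_dir = args.results_dir / "cohort"
    cohort = read_vcf(cohort_dir / "cohort.vcf")
    encoded = encode_additive(cohort.records, cohort.sample_ids)
    topo = TopologyMap.from_csv(cohort_dir / "cohort.topology.csv")
    encoded = encoded.subset_variants(topo.variant_ids)
    pheno = pd.read_csv(cohort_dir / "cohort.phenotypes.tsv", sep="\t")
    labels = pheno.set_index("sample_id").loc[encoded.sample_ids, "label"].to_numpy()

    X = prepare_inputs(encoded)
    ensemble = []
    for seed in derive_seeds(args.seed, args.n_models, stream=11):
        cfg = TrainConfig(max_epochs=50, seed=seed)
        params, _ = train(build_model(topo, cfg), X, labels.astype(float), cfg)
        ensemble.append(params)
    imp = gene_importances(ensemble, k=args.top_k, magnitude=True)
    imp_path = args.results_dir / "gene_importances.tsv"
    imp.to_csv(imp_path, sep="\t", index=False)
    top = top_gene_list(imp, k=args.top_k)

    causal = sorted(set(topo.gene_ids) & set(_causal_genes(args.results_dir)))
    rng = np.random.default_rng(args.seed)
    all_genes = topo.gene_ids
    sets = {"causal_genes": causal}
    for j in range(4):
        sets[f"random_set_{j}"] = list(
            rng.choice(all_genes, size=len(causal), replace=False))
    coll = GeneSetCollection(sets=sets, reference_size=len(all_genes))
    ora = ora_test(top, coll)
    ora_path = args.results_dir / "ora_results.tsv"
    ora.to_csv(ora_path, sep="\t", index=False)

    hits = len(set(top) & set(causal))
    print(f"top {args.top_k} genes contain {hits} of {len(causal)} causal genes")
    print(ora.to_string(index=False,
                        formatters={"enrichment_ratio": "{:.2f}".format,
                                    "p_value": "{:.3g}".format,
                                    "fdr": "{:.3g}".format}))
    print(f"wrote {imp_path}\nwrote {ora_path}")


def _causal_genes(results_dir: Path):
    path = results_dir / "cohort" / "causal_genes.txt"
    if path.exists():
        return path.read_text().split()
    raise SystemExit("run analysis/01_simulate_cohort.py first (causal gene list missing)")


if __name__ == "__main__":
    main()
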