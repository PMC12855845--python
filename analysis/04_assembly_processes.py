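#!/usr/bin/env python
"""Five-process assembly partition (beta-NRI + Raup-Crick) per genotype.

Partitions every within-genotype sample pair into heterogeneous/homogeneous
selection, dispersal limitation, homogenising dispersal and drift, using
phylogenetic bins on the simulated 16S tree with 199 nulls.  Writes
results/assembly/partition.tsv and pair_calls.tsv.
"""

import pathlib

from rhizoecol import assembly, io

BASE = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "assembly"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = io.read_feature_table(BASE / "data" / "feature_table.tsv", "samples-as-rows")
    tree = io.read_tree(BASE / "data" / "tree.nwk")
    metadata = io.read_metadata(BASE / "data" / "metadata.tsv")
    part = assembly.partition_assembly(table, tree, metadata, n_null=199, seed=SEED)
    part.fractions.to_csv(OUT / "partition.tsv", sep="\t")
    part.pair_calls.to_csv(OUT / "pair_calls.tsv", sep="\t", index=False)
    print(part.fractions.round(3))
    overall = part.fractions.loc["overall"]
    print(f"drift dominates ({100 * overall['DR']:.1f}%), matching the "
          "stochastic-assembly regime; the injected clade selection is uniform "
          "within its genotype, so it separates genotypes (see the PERMANOVA) "
          "without creating within-genotype selection calls")


if __name__ == "__main__":
    main()
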