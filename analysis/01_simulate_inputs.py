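#!/usr/bin/env python
"""Generate the synthetic study inputs every downstream analysis consumes.

Writes, under results/data/: the 35-strain property table (6 barrier
strains), the pre/post proteome matrices with a +1.5z shift planted on one
50-gene group, the gene-group membership file, the codon-reference ORF and
ortholog protein set, and JSON truth sidecars recording the generating
parameters.
"""

import json
from pathlib import Path

import pandas as pd

from xenoflux.io import write_fasta, write_strain_table
from xenoflux.synthetic_data import (
    default_gene_groups,
    gen_codon_reference,
    gen_proteomes,
    gen_strain_table,
)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    table, truth = gen_strain_table(seed=SEED)
    write_strain_table(table, OUT / "strains.tsv")
    (OUT / "strains.truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    nd = table["abundance_total_naive"].isna().sum()
    print(f"strain table: {len(table)} strains, barrier={list(truth.barrier_ids)}, "
          f"{nd} naive abundances below detection (n.d.)")

    groups = default_gene_groups(seed=SEED)
    pre, post, ptruth = gen_proteomes(
        groups=groups, planted_shifts={"group_00": 1.5}, seed=SEED
    )
    pre.to_csv(OUT / "proteome_pre.tsv", sep="\t", float_format="%.6g")
    post.to_csv(OUT / "proteome_post.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(
        [(g, gene) for g, members in groups for gene in members],
        columns=["group_id", "gene_id"],
    ).to_csv(OUT / "gene_groups.tsv", sep="\t", index=False)
    (OUT / "proteomes.truth.json").write_text(json.dumps(ptruth.to_dict(), indent=2))
    print(f"proteomes: {pre.shape[0]} genes x {pre.shape[1]} strains, "
          f"planted shifts {ptruth.planted_shifts}")

    orf, variants = gen_codon_reference(seed=SEED)
    write_fasta({"reference_orf": orf}, OUT / "reference_orf.fna")
    write_fasta(variants, OUT / "orthologs.faa")
    print(f"codon reference: {len(orf) // 3} codons, {len(variants)} protein variants")


if __name__ == "__main__":
    main()
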