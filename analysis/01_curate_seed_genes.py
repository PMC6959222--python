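"""Curate the seed gene set from the packaged evidence tables.

Loads the gene-disease association table and the drug-mechanism table,
reports the relationship breakdown (causal vs preventive vs correlative),
and merges disease-associated genes with drug-target genes into the
provenance-tracked seed set that the module growth starts from.
"""

import json
from pathlib import Path

from netprev.catalog import (
    Relationship,
    count_by_relationship,
    count_drug_entries,
    drug_target_records,
    filter_direct,
    load_associations,
    load_drug_table,
    merge_seed_genes,
    packaged_fixture,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    associations = load_associations(packaged_fixture("table1.tsv"))
    counts = count_by_relationship(associations)
    direct = filter_direct(associations)
    table2 = load_drug_table(packaged_fixture("table2.tsv"))
    records = drug_target_records(table2)

    seed_set = merge_seed_genes(
        {a.gene_symbol for a in associations}, {r.target for r in table2}
    )

    summary = {
        "association_rows": len(associations),
        "genes_causing_disease": counts[Relationship.CAUSES],
        "genes_preventing_disease": counts[Relationship.MAY_PREVENT],
        "direct_relationship_rows": len(direct),
        "mechanism_rows": len(table2),
        "drug_entries": count_drug_entries(records),
        "merged_seed_genes": len(seed_set),
        "genes_in_both_sources": sorted(seed_set.overlap),
    }
    (OUT / "catalog_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"{summary['association_rows']} curated gene-disease rows: "
          f"{summary['genes_causing_disease']} genes cause the disease, "
          f"{summary['genes_preventing_disease']} may prevent it")
    print(f"{summary['mechanism_rows']} drug mechanisms joining "
          f"{summary['drug_entries']} drug entries")
    print(f"merged seed set: {summary['merged_seed_genes']} genes "
          f"-> results/catalog_summary.json")


if __name__ == "__main__":
    main()
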