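"""Enrichment and two-criterion pathway selection over the module.

Tests every term of level >= 3 for over-representation in the grown
module (BH-corrected), clusters redundant enriched terms by gene-set
Jaccard overlap, and applies the coverage / mean-rank filter that keeps
pathways both well covered by the predictions and populated by
early-ranked proteins.
"""

import json
from pathlib import Path

import pandas as pd

from netprev.enrichment import (
    cluster_terms,
    enrich,
    read_gmt,
    select_pathways_for_module,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"


def main():
    manifest = json.loads((SIM / "manifest.json").read_text())
    collection = read_gmt(SIM / "terms.gmt")
    module = pd.read_csv(ROOT / "module.tsv", sep="\t")
    predicted = module["protein"].tolist()
    seeds = set((SIM / "seeds.txt").read_text().split())
    module_genes = set(predicted) | seeds

    results = enrich(module_genes, collection, min_level=3, q_threshold=0.05)
    pd.DataFrame(
        [(r.term_id, r.level, len(r.overlap_genes), r.p_value, r.q_value, r.fold_enrichment)
         for r in results],
        columns=["term", "level", "overlap", "p", "q", "fold"],
    ).to_csv(ROOT / "enrichment.tsv", sep="\t", index=False)
    planted = set(manifest["annotations"]["biased_terms"])
    found = {r.term_id for r in results}
    print(f"{len(results)} terms enriched at q <= 0.05; "
          f"{len(found & planted)}/{len(planted)} planted module-biased terms recovered")

    clusters = cluster_terms(results, similarity_threshold=0.5)
    print(f"{len(clusters)} redundancy clusters "
          f"(largest: {max((len(c) for c in clusters), default=0)} terms)")

    selection = select_pathways_for_module(collection, predicted,
                                           coverage_min=0.30, mean_rank_max=100)
    chosen = [s.term_id for s in selection if s.selected]
    pd.DataFrame(
        [(s.term_id, s.coverage, "" if s.mean_rank is None else s.mean_rank, s.selected)
         for s in selection],
        columns=["term", "coverage", "mean_rank", "selected"],
    ).to_csv(ROOT / "pathways.tsv", sep="\t", index=False)
    print(f"{len(chosen)} pathways pass coverage >= 30% and mean rank <= 100: {chosen}")


if __name__ == "__main__":
    main()
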