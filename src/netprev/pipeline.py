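"""End-to-end orchestration: seeds -> module -> pathways -> predictions ->
mechanisms -> ranked target report.

The pipeline is a pure function of (input files, parameters, rng seed):
every stage writes its intermediate artifact under the output directory,
no stage introduces nondeterminism of its own, and the run log records
stage-level tallies (genes loaded, seeds in network, candidates ranked,
molecules filtered) without timestamps, so reruns on identical inputs
are byte-identical.

Every tunable threshold (module size, Pa cutoff, minimum supporting
molecules, pathway coverage and mean-rank bounds, q-value cutoff) lives
in the run configuration, never in code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from netprev import catalog, diamond, enrichment, interactome, mechanisms
from netprev.catalog import MechanismRow
from netprev.revpharm import activity as rp_activity
from netprev.revpharm import molecules as rp_molecules
from netprev.revpharm import screening as rp_screening


@dataclass
class DiamondParams:
    iterations: int = 600
    alpha: int = 1


@dataclass
class EnrichmentParams:
    min_level: int = 3
    q_threshold: float = 0.05
    jaccard_threshold: float = 0.5
    coverage_min: float = 0.30
    mean_rank_max: float = 300.0


@dataclass
class PredictionParams:
    level: int = 2
    smoothing: float = 1.0
    pa_min: float = 0.5
    min_molecules: int = 5


@dataclass
class TracingParams:
    max_edges: int = 2


@dataclass
class RunConfig:
    """Paths to all inputs plus every stage parameter."""

    network: str
    out_dir: str
    seeds: str | None = None
    associations: str | None = None
    drug_table: str | None = None
    annotations: str | None = None
    molecules: str | None = None
    labels: str | None = None
    plant_map: str | None = None
    signed_network: str | None = None
    alterations: str | None = None
    diamond: DiamondParams = field(default_factory=DiamondParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    prediction: PredictionParams = field(default_factory=PredictionParams)
    tracing: TracingParams = field(default_factory=TracingParams)
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            diamond=DiamondParams(**d.pop("diamond", {})),
            enrichment=EnrichmentParams(**d.pop("enrichment", {})),
            prediction=PredictionParams(**d.pop("prediction", {})),
            tracing=TracingParams(**d.pop("tracing", {})),
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass(frozen=True)
class TargetReportRow:
    """One computable row of the final ranked-target report."""

    mechanism: str
    target: str
    diamond_rank: int | None
    n_supporting_molecules: int | None
    consistency: float | None
    drugs: tuple[str, ...]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def moa_target(activity_name: str) -> str:
    """Target identifier of a mechanism-of-action name (its first token)."""
    return activity_name.split()[0]


def make_report(
    drug_table: Sequence[MechanismRow],
    diamond_ranks: Mapping[str, int] | None = None,
    moa_support: Mapping[str, int] | None = None,
    consistency: Mapping[str, float] | None = None,
) -> list[TargetReportRow]:
    """Left-join mechanism rows with computed columns, sorted by rank.

    ``diamond_ranks`` (target -> module rank) overrides any rank printed
    in the drug table; ``moa_support`` maps mechanism name -> number of
    supporting molecules; ``consistency`` maps target -> sign-consistency
    fraction.  Duplicate (mechanism, target) rows are an error.
    """
    seen = set()
    rows = []
    for row in drug_table:
        key = (row.mechanism, row.target)
        if key in seen:
            raise ValueError(f"duplicate report row for {key}")
        seen.add(key)
        rank = None
        if diamond_ranks is not None:
            rank = diamond_ranks.get(row.target)
        elif row.rank is not None:
            rank = row.rank
        rows.append(
            TargetReportRow(
                mechanism=row.mechanism,
                target=row.target,
                diamond_rank=rank,
                n_supporting_molecules=(moa_support or {}).get(row.mechanism),
                consistency=(consistency or {}).get(row.target),
                drugs=row.drugs,
            )
        )
    return sorted(rows, key=lambda r: (r.diamond_rank is None, r.diamond_rank, r.target))


def write_report(rows: Sequence[TargetReportRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("mechanism\ttarget\tdiamond_rank\tn_supporting_molecules\tconsistency\tdrugs\n")
        for r in rows:
            rank = "" if r.diamond_rank is None else str(r.diamond_rank)
            nmol = "" if r.n_supporting_molecules is None else str(r.n_supporting_molecules)
            cons = "" if r.consistency is None else f"{r.consistency:.4f}"
            fh.write(f"{r.mechanism}\t{r.target}\t{rank}\t{nmol}\t{cons}\t{'; '.join(r.drugs)}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages in order; returns a summary dict.

    Stages whose inputs are not configured are skipped (and logged as
    skipped); any stage failure aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    summary: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc
        return wrap

    # -- seeds ------------------------------------------------------------
    def _seeds():
        assoc_genes: set[str] = set()
        drug_genes: set[str] = set()
        if config.associations:
            associations = catalog.load_associations(config.associations)
            assoc_genes = {a.gene_symbol for a in associations}
            log.append(f"catalog: {len(associations)} association rows, {len(assoc_genes)} genes")
        if config.drug_table:
            rows = catalog.load_drug_table(config.drug_table)
            drug_genes = {r.target for r in rows}
            n_drugs = catalog.count_drug_entries(catalog.drug_target_records(rows))
            log.append(f"catalog: {len(rows)} mechanism rows, {n_drugs} drug entries")
        if config.seeds:
            listed = {
                line.strip().upper()
                for line in Path(config.seeds).read_text().splitlines()
                if line.strip()
            }
            assoc_genes |= listed
            log.append(f"catalog: {len(listed)} seed genes listed")
        seed_set = catalog.merge_seed_genes(assoc_genes, drug_genes)
        log.append(f"catalog: merged seed set of {len(seed_set)} genes "
                   f"({len(seed_set.overlap)} from both sources)")
        return seed_set

    seed_set = stage("seeds")(_seeds)
    summary["n_seed_genes"] = len(seed_set)

    # -- disease module ---------------------------------------------------
    def _module():
        graph, report = interactome.load_edge_list(config.network)
        log.append(f"interactome: {graph.number_of_nodes()} nodes, "
                   f"{graph.number_of_edges()} edges ({report})")
        present, absent = interactome.restrict_seeds(graph, seed_set.genes)
        log.append(f"interactome: {len(present)} seeds in network, {len(absent)} absent")
        n_iter = min(config.diamond.iterations, graph.number_of_nodes() - len(present))
        result = diamond.run_diamond(graph, present, n_iter, config.diamond.alpha)
        log.append(f"diamond: ranked {len(result.candidates)} candidates")
        df = pd.DataFrame(
            [(c.rank, c.protein, c.p_value, c.degree_k, c.links_to_module_ks)
             for c in result.candidates],
            columns=["rank", "protein", "p_value", "k", "ks"],
        )
        df.to_csv(out / "module.tsv", sep="\t", index=False)
        module_nodes = set(result.proteins()) | present
        attrs = {p: {"seed": p in present,
                     "rank": result.ranks().get(p, 0)} for p in module_nodes}
        interactome.export_xgmml(graph.subgraph(module_nodes), attrs, out / "module.xgmml")
        return graph, result

    graph, dia_result = stage("diamond")(_module)
    summary["n_candidates"] = len(dia_result.candidates)

    # -- enrichment and pathway selection ---------------------------------
    pathways_selected: list[str] = []
    if config.annotations:
        def _enrich():
            collection = enrichment.read_gmt(config.annotations)
            module_genes = set(dia_result.proteins()) | set(dia_result.seeds_used)
            results = enrichment.enrich(
                module_genes, collection,
                min_level=config.enrichment.min_level,
                q_threshold=config.enrichment.q_threshold,
            )
            log.append(f"enrichment: {len(results)} terms at q <= "
                       f"{config.enrichment.q_threshold} (level >= {config.enrichment.min_level})")
            pd.DataFrame(
                [(r.term_id, r.level, len(r.overlap_genes), r.p_value, r.q_value,
                  r.fold_enrichment) for r in results],
                columns=["term", "level", "overlap", "p", "q", "fold"],
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            clusters = enrichment.cluster_terms(results, config.enrichment.jaccard_threshold)
            (out / "term_clusters.json").write_text(json.dumps(clusters, indent=1))
            selection = enrichment.select_pathways_for_module(
                collection, dia_result.proteins(),
                coverage_min=config.enrichment.coverage_min,
                mean_rank_max=config.enrichment.mean_rank_max,
            )
            pd.DataFrame(
                [(s.term_id, s.coverage,
                  "" if s.mean_rank is None else s.mean_rank, s.selected)
                 for s in selection],
                columns=["term", "coverage", "mean_rank", "selected"],
            ).to_csv(out / "pathways.tsv", sep="\t", index=False)
            chosen = [s.term_id for s in selection if s.selected]
            log.append(f"enrichment: {len(chosen)} pathways pass coverage >= "
                       f"{config.enrichment.coverage_min} and mean rank <= "
                       f"{config.enrichment.mean_rank_max}")
            return chosen

        pathways_selected = stage("enrichment")(_enrich)
    else:
        log.append("enrichment: skipped (no annotations configured)")
    summary["n_pathways_selected"] = len(pathways_selected)

    # -- reverse pharmacology --------------------------------------------
    moa_support: dict[str, int] = {}
    predictions: list[rp_activity.Prediction] = []
    if config.molecules and config.labels:
        def _predict():
            mols = rp_molecules.read_smiles_file(config.molecules)
            eligible, rejected = rp_molecules.filter_structures(mols)
            log.append(f"revpharm: {len(eligible)} eligible molecules, "
                       f"{len(rejected)} rejected by the structure filter")
            pd.DataFrame(
                [(r.mol_id, r.reason) for r in rejected], columns=["mol_id", "reason"]
            ).to_csv(out / "filter_report.tsv", sep="\t", index=False)
            labels = pd.read_csv(config.labels, sep="\t", index_col=0)
            model = rp_activity.train(
                eligible, labels,
                level=config.prediction.level,
                smoothing=config.prediction.smoothing,
            )
            model.save(out / "model.json")
            preds = rp_activity.predict_all(model, eligible)
            rp_activity.predictions_frame(preds).to_csv(
                out / "predictions.tsv", sep="\t", index=False
            )
            selected = rp_screening.select_moas(
                preds,
                pa_min=config.prediction.pa_min,
                min_molecules=config.prediction.min_molecules,
            )
            pd.DataFrame(selected, columns=["activity", "n_molecules"]).to_csv(
                out / "moas.tsv", sep="\t", index=False
            )
            log.append(f"revpharm: {len(selected)} mechanisms with >= "
                       f"{config.prediction.min_molecules} molecules at Pa > "
                       f"{config.prediction.pa_min}")
            return preds, dict(selected)

        predictions, moa_support = stage("revpharm")(_predict)
        if not predictions:
            log.append("revpharm: warning - no predictions produced")
    else:
        log.append("revpharm: skipped (no molecule library configured)")
    summary["n_moas_selected"] = len(moa_support)

    # -- mechanism tracing ------------------------------------------------
    consistency: dict[str, float] = {}
    if config.signed_network and config.alterations:
        def _trace():
            signed = mechanisms.load_signed_edges(config.signed_network)
            alteration = mechanisms.load_alteration_map(config.alterations)
            disease_proteins = set(alteration)
            rows = []
            all_paths: list[mechanisms.MechanismPath] = []
            for moa in sorted(moa_support):
                target = moa_target(moa)
                if not signed.has_node(target):
                    continue
                sign = mechanisms.intervention_sign(moa)
                paths = mechanisms.shortest_signed_paths(
                    signed, target, disease_proteins, config.tracing.max_edges
                )
                report = mechanisms.consistency_report(paths, alteration, sign)
                frac = report.consistent_fraction
                if frac is not None:
                    consistency[target] = frac
                all_paths.extend(paths)
                rows.append((target, moa, len(paths),
                             "" if frac is None else f"{frac:.4f}"))
            pd.DataFrame(
                rows, columns=["target", "mechanism", "n_paths", "consistent_fraction"]
            ).to_csv(out / "consistency.tsv", sep="\t", index=False)
            subnet = mechanisms.build_mechanism_subnetwork(all_paths)
            attrs = {n: {"disease_direction": alteration.get(n, 0)} for n in subnet.nodes()}
            interactome.export_xgmml(subnet, attrs, out / "mechanisms.xgmml")
            log.append(f"mechanisms: traced {len(rows)} targets, "
                       f"{subnet.number_of_edges()} subnetwork edges")
            return consistency

        stage("mechanisms")(_trace)
    else:
        log.append("mechanisms: skipped (no signed network configured)")
    summary["n_targets_traced"] = len(consistency)

    # -- report -----------------------------------------------------------
    def _report():
        if config.drug_table:
            table = catalog.load_drug_table(config.drug_table)
        else:
            table = [
                MechanismRow(mechanism=moa, target=moa_target(moa), rank=None, drugs=())
                for moa in sorted(moa_support)
            ]
        rows = make_report(
            table,
            diamond_ranks=dia_result.ranks(),
            moa_support=moa_support,
            consistency=consistency,
        )
        write_report(rows, out / "report.tsv")
        log.append(f"report: {len(rows)} target rows")
        return rows

    report_rows = stage("report")(_report)
    summary["n_report_rows"] = len(report_rows)

    (out / "log.txt").write_text("\n".join(log) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
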