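"""Write a complete synthetic input bundle plus a ready-to-run config.

Ties the generators together into one coherent study: mechanism-of-action
names are derived from planted (non-seed) module members, the signed
network is wired around those same proteins, and the emitted ``run.yaml``
points the pipeline at every file.  The ground truth of all generators is
collected into ``manifest.json`` so downstream checks can score recovery.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from netprev import interactome
from netprev.enrichment import write_gmt
from netprev.pipeline import (
    DiamondParams,
    EnrichmentParams,
    PredictionParams,
    RunConfig,
    TracingParams,
)
from netprev.revpharm.molecules import write_smiles_file
from netprev.synthetic import GeneratorConfig, gen_annotations, gen_interactome, gen_molecules, gen_signed_network


def write_inputs(config: GeneratorConfig, out_dir: str | Path, n_iterations: int = 200) -> dict:
    """Generate and write all pipeline inputs under ``out_dir``.

    Returns the combined ground-truth manifest (also written as
    ``manifest.json``).  The emitted ``run.yaml`` scales the module-size
    threshold and the pathway mean-rank bound to the synthetic network
    (``n_iterations`` and half of it, respectively).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    graph, net_truth = gen_interactome(config)
    interactome.write_edge_list(graph, out / "network.tsv")
    (out / "seeds.txt").write_text("\n".join(net_truth["seeds"]) + "\n")

    terms, term_truth = gen_annotations(config, net_truth)
    write_gmt(terms, out / "terms.gmt")

    # Mechanism-of-action names reference planted non-seed module members,
    # so activity predictions, the signed network, and the module ranking
    # all speak about the same proteins.
    sc = config.signed_net
    n_targets = sc.n_consistent_targets + sc.n_scrambled_targets
    seeds = set(net_truth["seeds"])
    non_seed_members = [m for m in net_truth["module_members"] if m not in seeds]
    if len(non_seed_members) < n_targets:
        raise ValueError("module has too few non-seed members to name all targets")
    target_proteins = non_seed_members[:n_targets]
    actions = ["inhibitor", "agonist"]
    activities = tuple(
        f"{t} {actions[i % 2]}" for i, t in enumerate(target_proteins)
    )
    chem = config.chemistry
    chem_config = GeneratorConfig(
        rng_seed=config.rng_seed,
        network=config.network,
        annotations=config.annotations,
        chemistry=type(chem)(**{**chem.__dict__, "activities": activities}),
        signed_net=config.signed_net,
    )
    molecules, labels, plant_map, chem_truth = gen_molecules(chem_config)
    write_smiles_file(molecules, out / "molecules.smi")
    labels.to_csv(out / "labels.tsv", sep="\t", index_label="mol_id")
    (out / "plants.json").write_text(json.dumps(plant_map, indent=1, sort_keys=True))

    signs = {t: (-1 if i % 2 == 0 else +1) for i, t in enumerate(target_proteins)}
    signed, alteration, signed_truth = gen_signed_network(
        config, targets=target_proteins, intervention_signs=signs
    )
    with (out / "signed.tsv").open("w") as fh:
        fh.write("source\ttarget\tsign\tdirectness\n")
        for a, b, data in sorted(signed.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['sign']:+d}\t{data.get('directness', 'direct')}\n")
    with (out / "alterations.tsv").open("w") as fh:
        fh.write("protein\tdirection\n")
        for protein in sorted(alteration):
            fh.write(f"{protein}\t{alteration[protein]:+d}\n")

    run = RunConfig(
        network=str(out / "network.tsv"),
        out_dir=str(out / "results"),
        seeds=str(out / "seeds.txt"),
        annotations=str(out / "terms.gmt"),
        molecules=str(out / "molecules.smi"),
        labels=str(out / "labels.tsv"),
        plant_map=str(out / "plants.json"),
        signed_network=str(out / "signed.tsv"),
        alterations=str(out / "alterations.tsv"),
        diamond=DiamondParams(iterations=n_iterations),
        enrichment=EnrichmentParams(mean_rank_max=n_iterations / 2),
        prediction=PredictionParams(),
        tracing=TracingParams(),
        rng_seed=config.rng_seed,
    )
    run.to_yaml(out / "run.yaml")

    manifest = {
        "generator_config": config.to_dict(),
        "network": net_truth,
        "annotations": term_truth,
        "chemistry": {**chem_truth, "activities": list(activities)},
        "signed": signed_truth,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
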