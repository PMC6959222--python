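"""Reverse-pharmacology screen of the molecule library.

Filters the library to single electroneutral structures of 50-1250 Da
with >= 3 carbons, trains the substructure activity model, reports
per-mechanism leave-one-out AUC, predicts Pa/Pi for every molecule, and
applies the shortlisting rules: mechanisms supported by >= 5 molecules at
Pa > 0.5, and plants carrying a molecule with dual mechanisms plus an
effect.
"""

import json
from pathlib import Path

import pandas as pd

from netprev.revpharm import (
    filter_structures,
    loo_auc,
    read_smiles_file,
    select_dual_action_plants,
    select_moas,
    train,
)
from netprev.revpharm.activity import predict_all, predictions_frame

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"


def main():
    molecules = read_smiles_file(SIM / "molecules.smi")
    eligible, rejected = filter_structures(molecules)
    print(f"{len(eligible)}/{len(molecules)} structures pass the eligibility filter "
          f"({len(rejected)} rejected)")

    labels = pd.read_csv(SIM / "labels.tsv", sep="\t", index_col=0)
    model = train(eligible, labels)
    model.save(ROOT / "activity_model.json")
    aucs = {a: loo_auc(eligible, labels, a) for a in labels.columns}
    for activity, auc in sorted(aucs.items()):
        print(f"  {activity}: LOO AUC = {auc:.3f}")

    predictions = predict_all(model, eligible)
    predictions_frame(predictions).to_csv(ROOT / "predictions.tsv", sep="\t", index=False)

    moas = select_moas(predictions, pa_min=0.5, min_molecules=5)
    pd.DataFrame(moas, columns=["activity", "n_molecules"]).to_csv(
        ROOT / "moas.tsv", sep="\t", index=False
    )
    print(f"{len(moas)} mechanisms predicted for >= 5 molecules at Pa > 0.5:")
    for activity, n in moas:
        print(f"  {activity}: {n} molecules")

    plant_map = json.loads((SIM / "plants.json").read_text())
    activities = list(labels.columns)
    plants = select_dual_action_plants(
        predictions, plant_map, moa_set=activities[:2], effect_set=activities[2:], pa_min=0.5
    )
    print(f"{len(plants)} plants carry a molecule with dual mechanisms plus an effect")


if __name__ == "__main__":
    main()
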