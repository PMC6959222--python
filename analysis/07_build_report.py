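"""Assemble the final ranked-target report.

Joins the module ranks, the per-mechanism molecule support, and the
sign-consistency fractions into one table per candidate target — the
computable columns of a target-prioritization table — and prints it.
Also re-runs the orchestrated pipeline end to end as a cross-check that
the stage-by-stage scripts and the one-shot runner agree.
"""

import json
from pathlib import Path

import pandas as pd

from netprev.catalog import MechanismRow
from netprev.pipeline import RunConfig, make_report, run_pipeline, write_report

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"


def main():
    module = pd.read_csv(ROOT / "module.tsv", sep="\t")
    ranks = dict(zip(module["protein"], module["rank"]))
    moas = pd.read_csv(ROOT / "moas.tsv", sep="\t")
    support = dict(zip(moas["activity"], moas["n_molecules"]))
    consistency_table = pd.read_csv(ROOT / "consistency.tsv", sep="\t")
    consistency = dict(zip(consistency_table["target"],
                           consistency_table["consistent_fraction"]))

    table = [MechanismRow(mechanism=m, target=m.split()[0], rank=None, drugs=())
             for m in sorted(support)]
    rows = make_report(table, diamond_ranks=ranks, moa_support=support,
                       consistency=consistency)
    write_report(rows, ROOT / "report.tsv")
    print("ranked-target report (results/report.tsv):")
    print(f"{'rank':>4}  {'target':8} {'mechanism':24} {'molecules':>9}  consistency")
    for r in rows:
        print(f"{r.diamond_rank or '-':>4}  {r.target:8} {r.mechanism:24} "
              f"{r.n_supporting_molecules or 0:>9}  "
              f"{'' if r.consistency is None else f'{r.consistency:.2f}'}")

    summary = run_pipeline(RunConfig.from_yaml(SIM / "run.yaml"))
    print("one-shot pipeline cross-check:", json.dumps(summary, sort_keys=True))


if __name__ == "__main__":
    main()
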