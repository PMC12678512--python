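#!/usr/bin/env python
"""Build the SP-B stand-in starting models and verify their sequence-level
and geometric bookkeeping.

The stand-ins are synthetic four-helix saposin-fold models constructed from
the mature 79-residue SP-B sequence, with the three conserved disulfides and
the published open/closed starting separations. This script records: the
charge census at pH 7.4 (9 positive, 2 negative, net +7 -> 7 neutralizing
chloride ions), the detected disulfide topology, the diagnostic separations
of both models with their open/closed class, and the DSSP class strings.

Writes results/starting_models.csv and results/starting_models_dssp.csv.
"""

from pathlib import Path

import pandas as pd

from sapflex.conformation import conformation_series
from sapflex.dssp import assign_secstruct
from sapflex.pdbio import write_pdb_models
from sapflex.sequence import count_charged_residues, extract_sequence, neutralizing_ion_count
from sapflex.structure import Trajectory, detect_disulfides
from sapflex.synthetic import spb_standin_models

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    top, closed, open_ = spb_standin_models()

    seq = extract_sequence(top)
    census = count_charged_residues(seq)
    species, n_ions = neutralizing_ion_count(census)
    print(f"mature chain: {len(seq)} residues, {seq.count('C')} cysteines")
    print(
        f"charge census at pH 7.4: +{census.n_positive}/-{census.n_negative} "
        f"=> net {census.net_charge:+d}, neutralized by {n_ions} {species}s"
    )

    pairs = detect_disulfides(closed, top)
    print(f"disulfide topology (closed model): {pairs}")

    series = conformation_series(Trajectory(top, [closed, open_]))
    rows = []
    for k, name in enumerate(("closed", "open")):
        rows.append(
            {
                "model": name,
                "tyr7_val34_A": round(series.d1[k], 3),
                "ile45_val70_A": round(series.d2[k], 3),
                "cys8_cys35_A": round(series.d_cys[k], 3),
                "label": series.labels[k],
            }
        )
        print(
            f"{name} model: d1 = {series.d1[k]:.2f} A, d2 = {series.d2[k]:.2f} A "
            f"-> {series.labels[k]}"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "starting_models.csv", index=False)

    dssp_rows = []
    for name, frame in (("closed", closed), ("open", open_)):
        labels = assign_secstruct(frame, top)
        dssp_rows.append({"model": name, "dssp": "".join(labels)})
        helical = sum(c in "HGI" for c in labels) / len(labels)
        print(f"{name} model helicity: {100 * helical:.1f}%")
    pd.DataFrame(dssp_rows).to_csv(RESULTS / "starting_models_dssp.csv", index=False)

    write_pdb_models(Trajectory(top, [closed, open_]), RESULTS / "standin_models.pdb")
    print(f"wrote {RESULTS / 'starting_models.csv'} and the stand-in PDB")


if __name__ == "__main__":
    main()
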