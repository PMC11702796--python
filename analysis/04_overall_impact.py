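#!/usr/bin/env python
"""Consensus impact scoring: convert every shift to kcal/mol and rank.

Assembles the four per-mutation components from the tables written by the
previous steps — predictor-tool ddG (mean over five tools), the simulated
and experimental melting-point shifts converted via ddG = dH_m * dTm / Tm,
and the chemical midpoint shift via ddG = m * dD1/2 — normalises their
absolute sum by the largest (the scaling factor), and correlates the
resulting Overall Impact with the reference pathogenicity scores.

Writes results/impact.tsv (footer rows carry scaling factor and Pearson r).
"""

import argparse
from pathlib import Path

import pandas as pd

from stabscan import io as sio
from stabscan.impact import (aggregate_predictor_ddg,
                             correlate_with_reference, ddg_from_chemical,
                             ddg_from_tm_shift, overall_impact)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path,
                    default=ROOT / "scratch" / "study_inputs")
    args = ap.parse_args()
    res = ROOT / "results"

    thermal = pd.read_csv(res / "thermal_fits.tsv", sep="\t",
                          index_col="variant")
    chem = pd.read_csv(res / "chemical_fits.tsv", sep="\t")
    chem_u = chem[chem["direction"] == "unfolding"].set_index("variant")
    rex = pd.read_csv(res / "rex_summary.tsv", sep="\t", index_col="variant")
    ddg_pt = aggregate_predictor_ddg(
        sio.read_predictor_table(args.inputs / "predictor_ddg.tsv"), "mean")

    components = {}
    for mut in ddg_pt.index:
        # destabilising shifts (dTm > 0, dD1/2 drop) map to negative ddG,
        # matching the predictor-tool sign convention
        components[mut] = {
            "ddg_pt": ddg_pt[mut],
            "ddg_rex": -ddg_from_tm_shift(rex.loc["WT", "dh_m_cv_kcal_mol"],
                                          rex.loc[mut, "delta_tm_K"],
                                          rex.loc["WT", "tm_cv_K"]),
            "ddg_td": -ddg_from_tm_shift(thermal.loc["WT", "dh_app_kcal_mol"],
                                         thermal.loc["WT", "tm_K"]
                                         - thermal.loc[mut, "tm_K"],
                                         thermal.loc["WT", "tm_K"]),
            "ddg_cd": ddg_from_chemical(chem_u.loc["WT", "m_kcal_mol_M"],
                                        chem_u.loc[mut, "d_half_M"]
                                        - chem_u.loc["WT", "d_half_M"]),
        }
    result = overall_impact(pd.DataFrame(components).T,
                            provenance={"predictor_rule": "mean",
                                        "cd_convention": "wt_minus_mutant"})
    table = result.table.sort_values("overall_impact", ascending=False)

    ref = sio.read_reference_scores(args.inputs / "reference_scores.tsv")
    r, n = correlate_with_reference(table["overall_impact"], ref)

    with (res / "impact.tsv").open("w") as fh:
        table.to_csv(fh, sep="\t", float_format="%.6g",
                     index_label="mutation")
        fh.write(f"# scaling_factor\t{result.scaling_factor:.6g}\n")
        fh.write(f"# pearson_r\t{r:.4f}\n# n_shared\t{n}\n")

    print(table[["ddg_pt", "ddg_rex", "ddg_td", "ddg_cd", "overall_impact"]]
          .round(3))
    print(f"scaling factor = {result.scaling_factor:.3f} kcal/mol")
    print(f"most impactful mutation: {table.index[0]} "
          f"(Overall Impact {table['overall_impact'].iloc[0]:.2f})")
    print(f"Pearson r vs reference scores = {r:.3f} over {n} mutations")


if __name__ == "__main__":
    main()
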