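#!/usr/bin/env python
"""Generate the synthetic study inputs: spectra, trajectories, score tables.

Writes the bulky raw inputs (per-variant fluorescence spectra CSVs,
replica-exchange trajectory/exchange TSVs, predictor and reference TSVs)
under scratch/study_inputs/ — regenerable at will from the seed — and a
small manifest of the study's ground truth under results/.

Usage: python analysis/01_simulate_inputs.py [--seed 1] [--frames 6000]
"""

import argparse
from pathlib import Path

import pandas as pd

from stabscan.pipeline import default_study, synthesize_inputs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--frames", type=int, default=6000)
    args = ap.parse_args()

    indir = ROOT / "scratch" / "study_inputs"
    cfg = synthesize_inputs(indir, args.seed, n_frames=args.frames)

    study = default_study()
    manifest = pd.DataFrame(
        [{"variant": t.label, "tm_true_K": t.tm, "dg_app_true": t.dg_app,
          "hysteresis_true_M": t.hysteresis, "rex_t_ref_K": t.rex_t_ref,
          "predictor_ddg_true": t.predictor_ddg,
          "reference_score_true": t.reference_score}
         for t in study.values()]).set_index("variant")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    manifest.to_csv(out / "study_manifest.tsv", sep="\t",
                    float_format="%.10g")
    (out / "study_config.yaml").write_text(
        "".join(f"{k}: {v}\n" for k, v in
                [("seed", args.seed), ("frames_per_replica", args.frames),
                 ("inputs_dir", str(indir))]))

    print(f"wrote {len(cfg.spectra)} spectra series, "
          f"{len(cfg.trajectories)} trajectories -> {indir}")
    print(f"ground truth manifest -> {out / 'study_manifest.tsv'}")
    print(manifest)


if __name__ == "__main__":
    main()
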