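"""Generate the paired MRI/CT phantom of one synthetic individual.

Writes the two volumes, the ground-truth meshes/curves and the true
inter-modality transform under results/run/.
"""

import argparse
from pathlib import Path

from endocompare.pipeline import PipelineConfig, stage_phantom


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--clean", action="store_true",
                    help="no dropped sulci and no superior mismatch "
                         "(every endocast curve should then match)")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, name=f"phantom-s{args.seed}")
    if args.clean:
        from dataclasses import replace
        cfg.phantom = replace(cfg.phantom, drop_fraction=0.0,
                              superior_smoothing=0.0, sinus_ridge_height=0.0)
    args.out.mkdir(parents=True, exist_ok=True)
    cfg.save(args.out / "config.toml")
    stage_phantom(cfg, args.out)

    from endocompare.curves import read_curves
    brain = read_curves(args.out / "truth_brain_curves.json")
    endo = read_curves(args.out / "truth_endocast_curves.json")
    dropped = (args.out / "dropped_labels.txt").read_text().split()
    print(f"phantom written to {args.out}")
    print(f"  ground-truth sulci: {len(brain)} on the brain, "
          f"{len(endo)} imprinted on the endocast")
    print(f"  deliberately absent from the endocast: {len(dropped)}")


if __name__ == "__main__":
    main()
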