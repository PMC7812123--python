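"""Register the brain hull onto the endocast and transport its sulci.

Rigid + uniform-scale alignment followed by a kernel-flow diffeomorphic
registration; the fitted deformation carries the brain-hull sulcal curves
into the endocast frame.
"""

import argparse
from pathlib import Path

import pandas as pd

from endocompare.pipeline import PipelineConfig, stage_register


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = PipelineConfig.load(args.out / "config.toml")
    stage_register(cfg, args.out)

    trace = pd.read_csv(args.out / "energy_trace.csv")["energy"]
    print(f"  energy {trace.iloc[0]:.4g} -> {trace.iloc[-1]:.4g} "
          f"over {len(trace)} accepted steps")
    print(f"  deformation model: {args.out/'deformation_model.json'}")


if __name__ == "__main__":
    main()
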