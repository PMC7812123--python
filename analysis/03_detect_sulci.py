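"""Detect sulcal imprints as ravine lines on both surfaces and label them.

Curvature-extremal lines are traced on the brain hull and the endocast,
then labeled against the phantom's ground-truth curves (the file-based
stand-in for manual identification).
"""

import argparse
from pathlib import Path

from endocompare.curves import read_curves
from endocompare.pipeline import PipelineConfig, stage_detect


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = PipelineConfig.load(args.out / "config.toml")
    stage_detect(cfg, args.out)

    for name in ("brain", "endocast"):
        cs = read_curves(args.out / f"detected_{name}_curves.json")
        print(f"  {name}: {len(cs)} labeled curves covering "
              f"{len(cs.labels())} sulci")


if __name__ == "__main__":
    main()
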