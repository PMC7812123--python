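"""Segment the brain hull and endocast and align the two modalities.

Reads the phantom volumes from results/run/, registers CT to MRI by
normalized mutual information, shrink-wraps both surfaces and resamples
them to the standard 100,000-face budget.
"""

import argparse
from pathlib import Path

import trimesh

from endocompare.pipeline import PipelineConfig, stage_segment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = PipelineConfig.load(args.out / "config.toml")
    stage_segment(cfg, args.out)

    for name in ("brain_hull", "endocast"):
        m = trimesh.load(args.out / f"{name}.ply", process=False)
        print(f"  {name}: {len(m.faces)} faces, watertight={m.is_watertight}")
    print(f"  CT->MRI transform written to {args.out/'ct_to_mri_transform.txt'}")


if __name__ == "__main__":
    main()
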