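"""Match endocast sulci to the transported brain-hull sulci and report.

Applies the strict 10 mm mean-distance criterion, writes the per-curve
report, the count summary (TC-E, NS-E, TC-B, NS-B, NC-EB, NS-EB), the
extrapolated curve-distance map and the surface displacement map.
"""

import argparse
import json
from pathlib import Path

from endocompare.pipeline import PipelineConfig, stage_match


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = PipelineConfig.load(args.out / "config.toml")
    stage_match(cfg, args.out)

    rep = json.loads((args.out / "match_report.json").read_text())
    c = rep["counts"]
    print("  counts:", " ".join(f"{k}={v}" for k, v in c.items()))
    print(f"  matched fraction NC-EB/TC-E = {rep['matched_fraction']:.2f}")
    print(f"  maps: {args.out/'distance_map.vtk'}, {args.out/'displacement_map.vtk'}")


if __name__ == "__main__":
    main()
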