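#!/usr/bin/env python
"""Generate the synthetic cohort every later stage analyzes.

Writes a two-group phantom ("two_group": four subregions at an elevated
endpoint rate, four at the chance rate, 25 subjects, two hemispheres) to
results/phantom/: the labeled subregion volume, its label table, one
endpoint map per subject, and the generating spec.
"""

from pathlib import Path

from amyconn import phantom

OUT = Path(__file__).resolve().parent.parent / "results" / "phantom"
SEED = 11


def main() -> None:
    spec = phantom.preset("two_group", seed=SEED)
    out = phantom.write_phantom(spec, OUT)
    n_maps = len(list(out.glob("endpoints_*.nii.gz")))
    print(f"phantom cohort written to {out}")
    print(f"  regions: {len(spec.regions)} ({len(spec.hemispheres())} hemispheres)")
    print(f"  subjects: {spec.n_subjects}, endpoint maps: {n_maps}")
    print(f"  rates: elevated={spec.endpoint_rates['MeA']}, chance={spec.endpoint_rates['PCo']}")


if __name__ == "__main__":
    main()
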