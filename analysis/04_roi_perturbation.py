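#!/usr/bin/env python
"""ROI-uncertainty experiment: expand each ROI by one voxel and compare
quantization schemes.

On phantoms with an adjacent fluid-like structure, a one-voxel dilation
(emulating inter-operator variability or a registration error) can pull
near-fluid ADC values into the ROI, stretching the AutoROI limits.
Fixed Manual limits (500-1500 x 1e-6 mm^2/s) clip those values into the
boundary bins instead.  The script reports, per phantom, the fraction
of the 19 features whose percentage change is smaller under Manual.
"""

import pandas as pd

import adctexture as at
from adctexture.io import write_table

MASTER_SEED = 2
N_PHANTOMS = 20
RESULTS = "results"


def main() -> None:
    specs = at.make_phantom_batch(N_PHANTOMS, seed=MASTER_SEED, include_fluid=True)
    frames = []
    for k, spec in enumerate(specs):
        adc, roi = at.generate_adc_phantom(spec, voxel_size=1.2)
        tab = at.roi_perturbation(adc, roi).reset_index()
        tab.insert(0, "roi", k)
        frames.append(tab)
    all_tab = pd.concat(frames, ignore_index=True)
    write_table(all_tab, f"{RESULTS}/roi_perturbation.tsv",
                {"master_seed": MASTER_SEED, "n_phantoms": N_PHANTOMS,
                 "manual_limits": "500-1500"})
    wins = (all_tab.dropna()
            .assign(win=lambda d: d.manual_pct.abs() < d.autoroi_pct.abs())
            .groupby("roi")["win"].mean())
    print(f"{N_PHANTOMS} phantoms; per-phantom fraction of features with "
          f"smaller |change| under Manual:")
    print(f"  median {wins.median():.2f}; phantoms with majority smaller: "
          f"{(wins > 0.5).mean():.0%}")
    print(f"wrote {RESULTS}/roi_perturbation.tsv")


if __name__ == "__main__":
    main()
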