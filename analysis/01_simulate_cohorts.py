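#!/usr/bin/env python
"""Simulate the two synthetic cohorts and summarise their ADC spans.

Builds 72 glioma-like and 36 prostate-like phantom ROIs (heterogeneous
texture, SNR and adjacent fluid-like structures), fits reference ADC
maps, and writes a per-ROI summary (mean/min/max ADC, voxel count) plus
the cohort-level manual quantization limits implied by the
lower-quartile-of-minima / upper-quartile-of-maxima rule.
"""

import pandas as pd

import adctexture as at
from adctexture.io import write_table

MASTER_SEED = 1
RESULTS = "results"


def summarise(protocol_name: str, n_rois: int) -> pd.DataFrame:
    proto = at.make_protocol(protocol_name)
    specs = at.make_phantom_batch(n_rois, seed=MASTER_SEED)
    rows, value_sets = [], []
    for k, spec in enumerate(specs):
        adc, roi = at.generate_adc_phantom(spec, voxel_size=proto.voxel_size)
        vals = adc.values[roi]
        value_sets.append(vals)
        rows.append({"cohort": protocol_name, "roi": k,
                     "n_voxels": int(roi.sum()),
                     "adc_mean": vals.mean(), "adc_min": vals.min(),
                     "adc_max": vals.max()})
    lo, hi = at.choose_manual_limits(value_sets)
    print(f"{protocol_name}: {n_rois} ROIs; quartile-rule manual limits "
          f"({lo:.0f}, {hi:.0f}) x 1e-6 mm^2/s")
    return pd.DataFrame(rows)


def main() -> None:
    summary = pd.concat([summarise("glioma", 72), summarise("prostate", 36)],
                        ignore_index=True)
    write_table(summary, f"{RESULTS}/cohort_summary.tsv",
                {"master_seed": MASTER_SEED})
    frac_fluid = (summary.adc_max > 2500).groupby(summary.cohort).mean()
    print("fraction of ROIs whose range reaches fluid-like ADC (>2500):")
    print(frac_fluid.to_string())
    print(f"wrote {RESULTS}/cohort_summary.tsv")


if __name__ == "__main__":
    main()
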