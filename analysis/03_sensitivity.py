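#!/usr/bin/env python
"""All-pairs Kolmogorov-Smirnov sensitivity analysis of the feature tables.

Every unordered pair of settings of every varied parameter is compared
across ROIs, per feature (475 tests for the multi-b cohort, 361 for the
two-b cohort, 836 in total).  Each test runs at alpha = 0.01 with a
Bonferroni correction for the joint 836 tests.  Writes the pairwise
long-format table, the parameter x feature matrix of minimum pairwise
p-values (the machine-readable heatmap), and its significance mask.
"""

import adctexture as at
from adctexture.io import read_table, write_table

MASTER_SEED = 1
RESULTS = "results"


def analyse(protocol_name: str, n_total: int) -> None:
    design = (at.ExperimentDesign.glioma(n_tests_total=n_total)
              if protocol_name == "glioma"
              else at.ExperimentDesign.prostate(n_tests_total=n_total))
    table = read_table(f"{RESULTS}/features_{protocol_name}.tsv")
    res = at.all_pairs_tests(table, design)
    prov = {"master_seed": MASTER_SEED, "protocol": protocol_name,
            "n_tests_this_design": at.count_tests(design),
            "bonferroni_denominator": res.n_tests,
            "alpha": res.alpha, "threshold": res.threshold}
    write_table(res.pairwise, f"{RESULTS}/pairwise_ks_{protocol_name}.tsv", prov)
    write_table(res.aggregated.reset_index(),
                f"{RESULTS}/aggregated_p_{protocol_name}.tsv", prov)
    write_table(res.significant.reset_index(),
                f"{RESULTS}/significant_{protocol_name}.tsv", prov)
    print(f"\n{protocol_name}: {at.count_tests(design)} KS tests, "
          f"threshold {res.threshold:.3e}")
    n_sig = res.significant.sum(axis=1)
    print("features significantly affected, per parameter:")
    print(n_sig.to_string())


def main() -> None:
    n_total = (at.count_tests(at.ExperimentDesign.glioma())
               + at.count_tests(at.ExperimentDesign.prostate()))
    print(f"joint Bonferroni denominator: {n_total} tests")
    analyse("glioma", n_total)
    analyse("prostate", n_total)


if __name__ == "__main__":
    main()
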