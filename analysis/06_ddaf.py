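#!/usr/bin/env python
"""dDAF grouping of the analyzed gene-region variants.

Variants are sorted by decreasing |DAF difference| per population pair and
chunked (group size scaled to the synthetic cohort); each group reports
its cis/trans eQTL proportions and per-population mean DAFs, plus DAF
histograms.  The planted structure should reproduce the two signature
patterns: elevated trans proportions at the top of the AFR-EUR ordering
(population-specific sweeps) and at the bottom of the EAS-EUR ordering
(selection shared by both)."""

from _common import RESULTS, load_dataset
from popdiff import pipeline


def main() -> None:
    matrix, panel, genes, _, expression, chrom_lengths = load_dataset()
    cfg = pipeline.PipelineConfig()
    out = pipeline.run_ddaf_analysis(
        matrix, expression, panel, genes, chrom_lengths, cfg, RESULTS / "ddaf",
        group_size=50,
    )
    for key in ("coding_AFR_vs_EUR", "coding_EAS_vs_EUR"):
        if key not in out:
            continue
        summ = out[key]
        print(f"\n{key}: {len(summ)} groups")
        print(summ[["group", "n", "prop_cis", "prop_trans",
                    "mean_daf_AFR", "mean_daf_EAS", "mean_daf_EUR"]]
              .head(3).to_string(index=False))
        print("  ...")
        print(summ[["group", "n", "prop_cis", "prop_trans"]].tail(2).to_string(index=False))


if __name__ == "__main__":
    main()
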