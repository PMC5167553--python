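#!/usr/bin/env python
"""Region-class F_ST summary: the nine priority classes + remainder,
repeat/non-repeat and gene/non-genic splits, one ratio-of-averages F_ST
per population pair per row, with base-pair coverage per class."""

from _common import RESULTS, load_dataset
from popdiff import pipeline


def main() -> None:
    matrix, panel, genes, repeats, _, chrom_lengths = load_dataset()
    cfg = pipeline.PipelineConfig()
    df = pipeline.run_region_summary(
        matrix, panel, genes, repeats, chrom_lengths, cfg, RESULTS / "region_summary"
    )
    print(df.to_string(index=False))
    cls = df[df["coverage"].notna()
             & ~df["index"].isin(["genome-wide", "gene region", "non-genic region"])]
    print(f"\ncoverage sums to {int(cls['coverage'].sum())} bp "
          f"(genome {sum(chrom_lengths.values())} bp)")


if __name__ == "__main__":
    main()
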