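"""Shared loader for the analysis drivers: read the generated dataset back
through the package's own file readers (the same code path real exports
would take)."""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"


def load_dataset():
    from popdiff.annotation import read_bed, read_gene_models
    from popdiff.data_model import read_ancestral, read_panel, read_vcf
    from popdiff.eqtl import read_expression

    if not (DATA / "genotypes.vcf").exists():
        sys.exit("run analysis/01_generate_data.py first")
    anc = read_ancestral(DATA / "ancestral.tsv")
    matrix = read_vcf(str(DATA / "genotypes.vcf"), ancestral=anc)
    panel = read_panel(DATA / "panel.tsv")
    genes = read_gene_models(DATA / "genes.tsv")
    repeats = read_bed(DATA / "repeats.bed")
    expression = read_expression(DATA / "expression.tsv", DATA / "anchors.tsv")
    chrom_lengths = json.loads((DATA / "chrom_lengths.json").read_text())
    return matrix, panel, genes, repeats, expression, chrom_lengths
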