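"""Stage orchestration: the named analyses over a loaded dataset.

Each stage is a plain function from loaded inputs to TSV/JSON files in an
output directory, so stages are independently testable and a run is fully
reproducible from (inputs, config, seed).  A provenance record is written
before any stage output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    GENE_CLASSES,
    GenomePartition,
    RegionClass,
    classify_repeat,
    gene_fst_table,
    length_matched_sample,
    partition_genome,
    region_eqtl_enrichment,
    select_extremes,
)
from .daf_analysis import build_daf_records, daf_histogram, group_by_delta_daf, group_summaries
from .data_model import GenotypeMatrix, PopulationPanel, population_frequencies
from .eqtl import ExpressionMatrix, filter_maf, scan, threshold_and_fdr
from .fst import (
    fst_region,
    hudson_components_arrays,
    window_fst_from_components,
    windowed_fst,
)
from .wf_simulator import SimConfig, simulate, summarize_windows

__all__ = [
    "PipelineConfig",
    "write_provenance",
    "run_windowed_scan",
    "run_region_summary",
    "run_eqtl_scan",
    "run_eqtl_enrichment",
    "run_ddaf_analysis",
    "run_simulation_study",
]


@dataclass
class PipelineConfig:
    """Defaults equal the study settings: windows 1 kb and 10 kb, top/bottom
    1% (or top-100) extremes, cis p<0.05 / trans p<0.01 / FDR<0.05 /
    MAF>0.05 / 1 Mb cis range, dDAF group sizes 20,000 (coding) and
    10,000 (noncoding)."""

    population_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("AFR", "EUR"), ("AFR", "EAS"), ("EAS", "EUR")]
    )
    window_sizes: tuple[int, ...] = (1_000, 10_000)
    extreme_fraction: float = 0.01
    extreme_count: int = 100
    group_size_coding: int = 20_000
    group_size_noncoding: int = 10_000
    corrected: bool = True
    seed: int = 0


def write_provenance(outdir: str | Path, config, extra: dict | None = None) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rec = {
        "package_version": __version__,
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config),
    }
    if extra:
        rec.update(extra)
    path = out / "provenance.json"
    path.write_text(json.dumps(rec, indent=2, default=str))
    return path


def run_windowed_scan(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    chrom_lengths: dict[str, int],
    config: PipelineConfig,
    outdir: str | Path,
) -> dict[str, pd.DataFrame]:
    """Fixed-window F_ST per population pair and window size; one TSV each.

    Undefined windows are written (fst empty) and excluded from the
    summary statistics; both counts go into the log JSON.
    """
    out = Path(outdir)
    write_provenance(out, config, {"stage": "windowed_scan"})
    results: dict[str, pd.DataFrame] = {}
    log = {}
    chroms = np.array([v.chrom for v in matrix.variants])
    for pop_a, pop_b in config.population_pairs:
        for w in config.window_sizes:
            frames = []
            for chrom, L in chrom_lengths.items():
                sub = matrix.subset_variants(chroms == chrom)
                p1, n1 = population_frequencies(sub, panel, pop_a)
                p2, n2 = population_frequencies(sub, panel, pop_b)
                num, den = hudson_components_arrays(
                    p1, n1, p2, n2, corrected=config.corrected
                )
                pos0 = np.asarray([v.pos0 for v in sub.variants], dtype=float)
                fst, nvar, snum, sden = window_fst_from_components(
                    pos0, num, den, w, L, return_sums=True
                )
                starts = np.arange(fst.size) * w
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "window_start": starts,
                            "window_end": starts + w,
                            "n_variants": nvar,
                            "sum_num": snum,
                            "sum_den": sden,
                            "fst": fst,
                        }
                    )
                )
            df = pd.concat(frames, ignore_index=True)
            key = f"{pop_a}_vs_{pop_b}_w{w}"
            results[key] = df
            df.to_csv(out / f"windows_{key}.tsv", sep="\t", index=False)
            defined = df["fst"].dropna()
            log[key] = {
                "n_windows": int(len(df)),
                "n_defined": int(defined.size),
                "mean_fst": float(defined.mean()) if defined.size else None,
            }
    (out / "windowed_scan_summary.json").write_text(json.dumps(log, indent=2))
    return results


def run_region_summary(
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    genes,
    repeats: dict[str, list[tuple[int, int]]],
    chrom_lengths: dict[str, int],
    config: PipelineConfig,
    outdir: str | Path,
) -> pd.DataFrame:
    """Per-class coverage / variant count / F_ST table (one row per region
    class, plus genome-wide, repeat/non-repeat and gene/non-genic rows)."""
    out = Path(outdir)
    write_provenance(out, config, {"stage": "region_summary"})
    partition = partition_genome(genes, chrom_lengths)
    coverage = partition.coverage()
    chroms = [v.chrom for v in matrix.variants]
    pos0 = [v.pos0 for v in matrix.variants]
    vclass = partition.class_of_variants(chroms, pos0)
    repeat_status = np.array(
        [
            classify_repeat((p, p + 1), repeats.get(c, []))
            for c, p in zip(chroms, pos0)
        ]
    )

    comp: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for pop_a, pop_b in config.population_pairs:
        p1, n1 = population_frequencies(matrix, panel, pop_a)
        p2, n2 = population_frequencies(matrix, panel, pop_b)
        comp[(pop_a, pop_b)] = hudson_components_arrays(
            p1, n1, p2, n2, corrected=config.corrected
        )

    def fst_of(mask: np.ndarray) -> dict[str, float]:
        vals = {}
        for pair, (num, den) in comp.items():
            est = fst_region((num[mask], den[mask]))
            vals[f"fst_{pair[0]}_vs_{pair[1]}"] = est.value
        return vals

    rows = []
    all_mask = np.ones(matrix.n_variants, dtype=bool)
    rows.append({"index": "genome-wide", "coverage": sum(chrom_lengths.values()),
                 "n_variants": int(all_mask.sum()), **fst_of(all_mask)})
    for status in ("REPEAT", "NONREPEAT"):
        m = repeat_status == status
        rows.append({"index": status.lower(), "coverage": None,
                     "n_variants": int(m.sum()), **fst_of(m)})
    class_order = list(GENE_CLASSES) + [
        RegionClass.UP1000, RegionClass.DOWN1000, RegionClass.UP5000,
        RegionClass.DOWN5000, RegionClass.REMAINDER,
    ]
    for cls in class_order:
        m = vclass == cls
        rows.append({"index": cls, "coverage": int(coverage[cls]),
                     "n_variants": int(m.sum()), **fst_of(m)})
    gene_mask = np.isin(vclass, GENE_CLASSES)
    gene_cov = sum(coverage[c] for c in GENE_CLASSES)
    rows.append({"index": "gene region", "coverage": int(gene_cov),
                 "n_variants": int(gene_mask.sum()), **fst_of(gene_mask)})
    rows.append({"index": "non-genic region",
                 "coverage": int(sum(coverage.values()) - gene_cov),
                 "n_variants": int((~gene_mask).sum()), **fst_of(~gene_mask)})
    df = pd.DataFrame(rows)
    df.to_csv(out / "region_summary.tsv", sep="\t", index=False)
    with open(out / "region_classes.bed", "w") as fh:
        for chrom in chrom_lengths:
            for s, e, cls in partition.intervals(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{cls}\n")
    return df


def run_eqtl_scan(
    matrix: GenotypeMatrix,
    expression: ExpressionMatrix,
    panel: PopulationPanel,
    outdir: str | Path,
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """MAF filter, all-pairs scan, per-family thresholds + BH FDR; TSV out.

    Returns (thresholded records, MAF-filtered matrix restricted upstream).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    analyzed = filter_maf(matrix)
    records = threshold_and_fdr(scan(analyzed, expression, panel))
    for kind in ("cis", "trans"):
        records[records["kind"] == kind].to_csv(
            out / f"eqtl_{kind}.tsv", sep="\t", index=False
        )
    (out / "eqtl_log.json").write_text(
        json.dumps(
            {
                "n_variants_input": matrix.n_variants,
                "n_variants_analyzed": analyzed.n_variants,
                "n_records_retained": int(len(records)),
                "n_significant": int(records["significant"].sum()),
            },
            indent=2,
        )
    )
    return records, analyzed


def run_eqtl_enrichment(
    matrix: GenotypeMatrix,
    expression: ExpressionMatrix,
    panel: PopulationPanel,
    genes,
    chrom_lengths: dict[str, int],
    config: PipelineConfig,
    outdir: str | Path,
    pop_pair: tuple[str, str] | None = None,
) -> dict:
    """Extreme-F_ST gene sets vs bottom sets and length-matched sets:
    proportions of regions holding >= 1 significant eQTL + chi-squared."""
    out = Path(outdir)
    write_provenance(out, config, {"stage": "eqtl_enrichment"})
    pop_a, pop_b = pop_pair or config.population_pairs[0]
    table = gene_fst_table(genes, matrix, panel, pop_a, pop_b, corrected=config.corrected)
    table.to_csv(out / f"gene_fst_{pop_a}_vs_{pop_b}.tsv", sep="\t", index=False)
    top, bottom = select_extremes(table, mode="fraction", k=config.extreme_fraction)
    if top.empty:
        raise ValueError("no defined gene estimates: empty top set")
    records, _ = run_eqtl_scan(matrix, expression, panel, out)
    sig = records[records["significant"]]
    pos_by_key = {v.key: (v.chrom, v.pos0) for v in matrix.variants}

    def regions_of(df: pd.DataFrame) -> list[tuple[str, int, int]]:
        return [(r["chrom"], int(r["start"]), int(r["end"])) for _, r in df.iterrows()]

    def region_index(regions, kinds=("cis", "trans")) -> dict:
        idx = {}
        for reg in regions:
            c, s, e = reg
            flags = {}
            for kind in kinds:
                keys = sig.loc[sig["kind"] == kind, "variant_key"]
                flags[kind] = any(
                    pos_by_key[k][0] == c and s <= pos_by_key[k][1] < e for k in keys
                )
            idx[reg] = flags
        return idx

    top_regions = regions_of(top)
    bottom_regions = regions_of(bottom)
    matched = length_matched_sample(top_regions, chrom_lengths, seed=config.seed)
    idx = region_index(top_regions + bottom_regions + matched)
    report = {
        "pair": f"{pop_a}_vs_{pop_b}",
        "top_vs_bottom": region_eqtl_enrichment(top_regions, bottom_regions, idx),
        "top_vs_matched": region_eqtl_enrichment(top_regions, matched, idx),
        "n_top": len(top_regions),
    }
    (out / "enrichment.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def run_ddaf_analysis(
    matrix: GenotypeMatrix,
    expression: ExpressionMatrix,
    panel: PopulationPanel,
    genes,
    chrom_lengths: dict[str, int],
    config: PipelineConfig,
    outdir: str | Path,
    group_size: int | None = None,
) -> dict[str, pd.DataFrame]:
    """dDAF grouping of analyzed gene-region variants, with per-group eQTL
    proportions, mean DAFs and DAF histograms, for coding and noncoding
    gene memberships separately."""
    out = Path(outdir)
    write_provenance(out, config, {"stage": "ddaf_analysis"})
    analyzed = filter_maf(matrix)
    records = threshold_and_fdr(scan(analyzed, expression, panel))
    pops = panel.populations

    # gene membership: coding beats noncoding where spans overlap
    membership = np.array([""] * analyzed.n_variants, dtype=object)
    chroms = np.array([v.chrom for v in analyzed.variants])
    pos0 = np.array([v.pos0 for v in analyzed.variants])
    for coding in (False, True):
        for g in genes:
            if g.coding == coding:
                m = (chroms == g.chrom) & (pos0 >= g.gene_start) & (pos0 < g.gene_end)
                membership[m] = "coding" if coding else "noncoding"

    daf_records = build_daf_records(analyzed, panel, pops, eqtl_records=records)
    key_membership = dict(zip([v.key for v in analyzed.variants], membership))
    daf_records["membership"] = daf_records["variant_key"].map(key_membership)

    outputs: dict[str, pd.DataFrame] = {}
    for memb, gsize in (
        ("coding", group_size or config.group_size_coding),
        ("noncoding", group_size or config.group_size_noncoding),
    ):
        sub = daf_records[daf_records["membership"] == memb]
        if sub.empty:
            continue
        for pop_a, pop_b in config.population_pairs:
            grouped = group_by_delta_daf(sub, gsize, pop_a, pop_b)
            summ = group_summaries(grouped, pops)
            key = f"{memb}_{pop_a}_vs_{pop_b}"
            summ.to_csv(out / f"ddaf_groups_{key}.tsv", sep="\t", index=False)
            outputs[key] = summ
        for p in pops:
            hist = daf_histogram(sub[f"daf_{p}"])
            hist.to_csv(out / f"daf_hist_{memb}_{p}.tsv", sep="\t", index=False)
            outputs[f"hist_{memb}_{p}"] = hist
    return outputs


def run_simulation_study(
    configs: list[SimConfig],
    outdir: str | Path,
) -> dict:
    """Run the forward-simulation presets and summarise window F_ST means
    and histograms per window size."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = {}
    for cfg in configs:
        res = simulate(cfg)
        entry = {"config": dataclasses.asdict(cfg)}
        for w in cfg.window_sizes:
            entry[f"window_{w}"] = summarize_windows(res, w)
        report[f"N{cfg.N}"] = entry
        for i, rep in enumerate(res.replicates):
            pd.DataFrame(
                {"position": rep.positions, "freq_deme1": rep.freq1, "freq_deme2": rep.freq2}
            ).to_csv(out / f"N{cfg.N}_rep{i}_frequencies.tsv", sep="\t", index=False)
    (out / "simulation_summary.json").write_text(json.dumps(report, indent=2, default=str))
    return report
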