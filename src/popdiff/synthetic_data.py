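"""Synthetic genotype / annotation / expression generator.

Generates every input the pipeline reads, with the statistical structure
the analysis assumes, so each stage can be exercised and scored without
external downloads:

* **Genotypes** — ancestral allele frequencies drawn from a neutral-like
  1/x spectrum concentrated near zero; per-population frequencies drawn
  around them with Balding-Nichols beta noise (per-population drift
  parameter), so pairwise differentiation is tunable.  A configurable
  fraction of variants is sweep-like: derived allele near fixation in the
  chosen populations and near zero elsewhere.  A further planted set is
  "shared-low": derived allele rare in both non-reference populations but
  common in the reference one, emulating selection shared by the two.
  Haplotypes are drawn with block LD via a latent-uniform copula: within
  an LD block every haplotype carries one latent uniform; a variant with
  population frequency f is carried when that uniform falls below f,
  except with the block switch rate, where an independent Bernoulli(f) is
  drawn instead.  Marginal frequencies are exact in expectation while
  within-block pairs are strongly correlated.
* **Ancestral calls** — recorded per variant (derived allele is ALT or REF
  at random), mislabeled at a configurable rate and unknown at another.
* **Annotations** — gene models covering all nine priority classes,
  including a guaranteed overlapping gene pair, noncoding genes, and a
  repeat track with an interval crossing a window boundary.
* **Expression** — per-feature baseline + planted cis dosage effects +
  population-level shifts + a trans hub (one sweep driver variant
  cis-activates a regulator gene whose level propagates, attenuated, to
  many features on another chromosome) + direct trans effects for a subset
  of sweep and shared-low variants + Gaussian noise.  A truth table lists
  every planted (variant, feature, beta, kind) so recovery can be scored.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .data_model import GenotypeMatrix, PopulationPanel, Variant, VariantClass
from .eqtl import ExpressionMatrix

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "generate_genotypes",
           "generate_annotations", "generate_expression", "write_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the generator; defaults emulate the three-continental-
    population, lymphoblastoid-expression study design.

    Sample sizes default to 504/504/503 genotyped individuals with
    expression measured on a 445-sample subset (356 of the European-like
    and 89 of the African-like population), matching the combined-
    population eQTL design.  Drift parameters give pairwise window F_ST in
    the 0.10-0.15 band typical of continental human pairs.
    """

    seed: int = 0
    populations: tuple[str, ...] = ("AFR", "EAS", "EUR")
    samples_per_pop: tuple[int, ...] = (504, 504, 503)
    expression_samples: tuple[tuple[str, int], ...] = (("EUR", 356), ("AFR", 89))
    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 3_000_000), ("chr2", 3_000_000))
    n_variants: int = 4000
    drift: tuple[float, ...] = (0.07, 0.06, 0.05)  # Balding-Nichols F per population
    sfs_low: float = 0.001  # 1/x ancestral-frequency spectrum support
    sfs_high: float = 0.999
    # sweep-like variants: derived near-fixed in sweep_pops, near zero elsewhere
    sweep_fraction: float = 0.02
    sweep_pops: tuple[str, ...] = ("EAS", "EUR")
    sweep_daf: tuple[float, float] = (0.9, 1.0)
    sweep_other_daf: tuple[float, float] = (0.0, 0.05)
    # shared-low variants: derived rare in sweep_pops, common in the others
    n_shared_low: int = 20
    shared_low_daf: tuple[float, float] = (0.0, 0.03)
    shared_low_other_daf: tuple[float, float] = (0.2, 0.5)
    # haplotype LD structure
    ld_block_length: int = 20_000
    ld_switch_rate: float = 0.1
    # ancestral-call quality
    ancestral_error_rate: float = 0.0
    ancestral_unknown_rate: float = 0.05
    missing_rate: float = 0.0
    # annotations
    n_genes: int = 40
    gene_length: tuple[int, int] = (5_000, 60_000)
    coding_fraction: float = 0.7
    repeat_density: float = 0.2
    repeat_length: tuple[int, int] = (200, 2_000)
    # expression model
    n_cis: int = 15
    cis_beta: tuple[float, float] = (0.8, 1.5)
    hub_n_targets: int = 40
    hub_driver_beta: float = 1.5
    hub_attenuation: float = 0.7
    trans_per_sweep_fraction: float = 0.3
    trans_beta: float = 1.0
    shared_low_trans_targets: int = 3
    pop_shift_sd: float = 0.5
    noise_sd: float = 0.5
    baseline: tuple[float, float] = (4.0, 8.0)

    def __post_init__(self) -> None:
        if len(self.samples_per_pop) != len(self.populations):
            raise ValueError("samples_per_pop must match populations")
        if len(self.drift) != len(self.populations):
            raise ValueError("drift must match populations")
        for f in (self.sweep_fraction, self.ld_switch_rate, self.repeat_density,
                  self.ancestral_error_rate, self.ancestral_unknown_rate,
                  self.missing_rate, self.coding_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")

    @property
    def chrom_dict(self) -> dict[str, int]:
        return dict(self.chrom_lengths)


@dataclass
class SyntheticDataset:
    """Everything one generated dataset comprises, plus its planted truth."""

    config: GeneratorConfig
    matrix: GenotypeMatrix
    panel: PopulationPanel
    ancestral: dict[str, str]
    genes: list[GeneModel]
    repeats: dict[str, list[tuple[int, int]]]
    expression: ExpressionMatrix
    truth: pd.DataFrame
    pop_freqs: pd.DataFrame  # per-variant per-population *derived* frequencies (truth)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _ancestral_sfs(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Sample from density proportional to 1/x on [lo, hi] (neutral-like SFS)."""
    u = rng.uniform(size=n)
    return lo * np.exp(u * np.log(hi / lo))


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Population frequency around ancestral p with drift parameter F."""
    if F <= 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))


def generate_genotypes(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, PopulationPanel, dict[str, str], pd.DataFrame]:
    """Genotype matrix + panel + ancestral table + true derived-frequency table."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    pops = list(config.populations)
    chroms = config.chrom_dict
    n = config.n_variants

    # positions: spread over chromosomes proportionally to length
    lengths = np.array(list(chroms.values()), dtype=float)
    n_per = np.floor(n * lengths / lengths.sum()).astype(int)
    n_per[0] += n - n_per.sum()
    chrom_col, pos_col = [], []
    for (cname, clen), k in zip(chroms.items(), n_per):
        pos = np.sort(rng.choice(np.arange(1, clen), size=k, replace=False))
        chrom_col.extend([cname] * k)
        pos_col.extend(pos.tolist())

    # true derived-allele frequencies per population
    anc = _ancestral_sfs(rng, n, config.sfs_low, config.sfs_high)
    daf = np.column_stack([_balding_nichols(rng, anc, F) for F in config.drift])

    n_sweep = int(round(config.sweep_fraction * n))
    sweep_idx = rng.choice(n, size=n_sweep, replace=False)
    sweep_cols = [pops.index(p) for p in config.sweep_pops]
    other_cols = [i for i in range(len(pops)) if i not in sweep_cols]
    for i in sweep_idx:
        for c in sweep_cols:
            daf[i, c] = rng.uniform(*config.sweep_daf)
        for c in other_cols:
            daf[i, c] = rng.uniform(*config.sweep_other_daf)

    pool = np.setdiff1d(np.arange(n), sweep_idx)
    shared_idx = rng.choice(pool, size=min(config.n_shared_low, pool.size), replace=False)
    for i in shared_idx:
        for c in sweep_cols:
            daf[i, c] = rng.uniform(*config.shared_low_daf)
        for c in other_cols:
            daf[i, c] = rng.uniform(*config.shared_low_other_daf)

    # which allele is derived, and the recorded (possibly wrong) ancestral call
    derived_is_alt = rng.uniform(size=n) < 0.5
    refs = rng.choice(_BASES, size=n)
    alts = np.array([rng.choice(_BASES[_BASES != r]) for r in refs])

    variants: list[Variant] = []
    ancestral_table: dict[str, str] = {}
    for i in range(n):
        ref, alt = str(refs[i]), str(alts[i])
        true_anc = ref if derived_is_alt[i] else alt
        u = rng.uniform()
        if u < config.ancestral_unknown_rate:
            recorded = "UNKNOWN"
        elif u < config.ancestral_unknown_rate + config.ancestral_error_rate:
            recorded = alt if true_anc == ref else ref  # mislabeled: points at derived
        else:
            recorded = true_anc
        v = Variant(
            chrom=chrom_col[i],
            pos=int(pos_col[i]),
            ref=ref,
            alt=alt,
            vclass=VariantClass.SNV,
            source_id=f"rs{i:06d}",
            ancestral=recorded,
        )
        variants.append(v)
        ancestral_table[v.key] = recorded

    # alt-allele frequency per population (daf refers to the derived allele)
    alt_freq = np.where(derived_is_alt[:, None], daf, 1.0 - daf)

    # haplotypes with block LD (latent-uniform copula per block per haplotype)
    sample_ids, assignment = [], {}
    for p, k in zip(pops, config.samples_per_pop):
        for j in range(k):
            sid = f"{p}_{j:04d}"
            sample_ids.append(sid)
            assignment[sid] = p
    n_hap_per_pop = [2 * k for k in config.samples_per_pop]
    hap_cols = []
    block_ids = np.array(
        [hash_block(c, p, config.ld_block_length) for c, p in zip(chrom_col, pos_col)]
    )
    uniq_blocks, block_of_variant = np.unique(block_ids, return_inverse=True)
    for pi, nh in enumerate(n_hap_per_pop):
        u_block = rng.uniform(size=(uniq_blocks.size, nh))  # latent per (block, hap)
        u = u_block[block_of_variant]  # (n_variants, nh)
        f = alt_freq[:, pi][:, None]
        copula = (u < f).astype(np.int8)
        indep = (rng.uniform(size=(n, nh)) < f).astype(np.int8)
        use_indep = rng.uniform(size=(n, nh)) < config.ld_switch_rate
        hap_cols.append(np.where(use_indep, indep, copula))
    haps = np.concatenate(hap_cols, axis=1)
    if config.missing_rate > 0:
        miss = rng.uniform(size=haps.shape) < config.missing_rate
        haps = np.where(miss, np.int8(-1), haps)

    # interleave into sample order: columns already grouped per pop in sample order
    matrix = GenotypeMatrix(
        variants=variants, haplotypes=haps, sample_ids=sample_ids, phased=True
    )
    panel = PopulationPanel(assignment=assignment)
    freq_table = pd.DataFrame(daf, columns=[f"daf_{p}" for p in pops])
    freq_table.insert(0, "variant_key", [v.key for v in variants])
    freq_table["is_sweep"] = np.isin(np.arange(n), sweep_idx)
    freq_table["is_shared_low"] = np.isin(np.arange(n), shared_idx)
    return matrix, panel, ancestral_table, freq_table


def hash_block(chrom: str, pos: int, block_length: int) -> str:
    return f"{chrom}:{(pos - 1) // block_length}"


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def generate_annotations(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], dict[str, list[tuple[int, int]]]]:
    """Gene models exercising all nine priority classes, plus a repeat track."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    chroms = config.chrom_dict
    genes: list[GeneModel] = []
    gid = 0
    names = list(chroms)
    for ci, cname in enumerate(names):
        clen = chroms[cname]
        n_here = config.n_genes // len(names) + (1 if ci < config.n_genes % len(names) else 0)
        for _ in range(n_here):
            length = int(rng.integers(*config.gene_length))
            start = int(rng.integers(6000, clen - length - 6000))
            coding = bool(rng.uniform() < config.coding_fraction)
            genes.append(_make_gene(f"G{gid:04d}", cname, start, start + length, coding, rng))
            gid += 1
        # guaranteed overlapping pair: a coding gene with a noncoding gene
        # inside one of its introns region, so priority resolution is exercised
        length = 30_000
        start = clen // 2
        g_big = _make_gene(f"G{gid:04d}", cname, start, start + length, True, rng)
        gid += 1
        g_small = _make_gene(
            f"G{gid:04d}", cname, start + 12_000, start + 16_000, False, rng
        )
        gid += 1
        genes.extend([g_big, g_small])

    repeats: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for cname, clen in chroms.items():
        covered = 0
        target = config.repeat_density * clen
        tries = 0
        while covered < target and tries < 100_000:
            ln = int(rng.integers(*config.repeat_length))
            s = int(rng.integers(0, clen - ln))
            repeats[cname].append((s, s + ln))
            covered += ln
            tries += 1
        if config.repeat_density > 0:
            # one repeat straddling a 1 kb window boundary, by construction
            b = (clen // 2_000) * 1_000
            repeats[cname].append((b - 100, b + 100))
        repeats[cname].sort()
    return genes, repeats


def _make_gene(gid, chrom, start, end, coding, rng) -> GeneModel:
    """Exon/intron layout: alternating exons and introns across the span."""
    span = end - start
    n_exons = int(rng.integers(2, 5))
    cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_exons - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [span]])
    ivals = [(start + int(bounds[i]), start + int(bounds[i + 1])) for i in range(len(bounds) - 1)]
    exons = ivals[0::2]
    introns = ivals[1::2]
    g = GeneModel(
        gene_id=gid, chrom=chrom, gene_start=start, gene_end=end,
        strand="+" if rng.uniform() < 0.5 else "-", coding=coding,
    )
    g.intron.extend(introns)
    if coding:
        g.utr5.append(exons[0])
        g.utr3.append(exons[-1])
        g.cds.extend(exons[1:-1] if len(exons) > 2 else [exons[0]])
    else:
        g.noncoding_exon.extend(exons)
    return g


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    config: GeneratorConfig,
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    genes: list[GeneModel],
    freq_table: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression for the configured subset of samples, plus the truth table.

    Model per feature g and sample s:

        y[g, s] = baseline[g] + population_shift[g, pop(s)]
                  + sum_planted cis beta * dosage[v, s]
                  + hub: attenuation * (regulator level - its baseline)
                  + direct trans betas * dosage
                  + Normal(0, noise_sd)
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    pops = list(config.populations)
    # expression sample subset, taken in panel order per population
    chosen: list[str] = []
    for p, k in config.expression_samples:
        pool = [s for s in matrix.sample_ids if panel.assignment[s] == p]
        if k > len(pool):
            raise ValueError(f"requested {k} expression samples of {p}, have {len(pool)}")
        chosen.extend(pool[:k])
    dos_all = matrix.dosages()
    col_of = {s: i for i, s in enumerate(matrix.sample_ids)}
    dos = dos_all[:, [col_of[s] for s in chosen]]
    dos = np.nan_to_num(dos, nan=0.0)

    feats = [g.gene_id for g in genes]
    anchors = {g.gene_id: (g.chrom, g.gene_start + 1) for g in genes}  # 1-based anchor
    nF, nS = len(feats), len(chosen)
    baseline = rng.uniform(*config.baseline, size=nF)
    shift = rng.normal(0.0, config.pop_shift_sd, size=(nF, len(pops)))
    pop_idx = np.array([pops.index(panel.assignment[s]) for s in chosen])
    Y = baseline[:, None] + shift[:, pop_idx]

    key_row = {v.key: i for i, v in enumerate(matrix.variants)}
    chrom_of = np.array([v.chrom for v in matrix.variants])
    pos_of = np.array([v.pos for v in matrix.variants])
    truth_rows = []

    def plant(vrow: int, frow: int, beta: float, kind: str) -> None:
        Y[frow] += beta * dos[vrow]
        truth_rows.append(
            {
                "variant_key": matrix.variants[vrow].key,
                "feature": feats[frow],
                "beta": beta,
                "kind": kind,
            }
        )

    # analyzed-sample pooled MAF: planted effects must survive the MAF filter
    pooled = dos.mean(axis=1) / 2.0
    maf_ok = np.minimum(pooled, 1 - pooled) > 0.05

    # ordinary cis effects: common variant within 1 Mb of the feature anchor
    candidates_per_feat = {}
    for fi, f in enumerate(feats):
        fc, fp = anchors[f]
        near = np.nonzero((chrom_of == fc) & (np.abs(pos_of - fp) <= 1_000_000) & maf_ok)[0]
        candidates_per_feat[fi] = near
    cis_feats = [fi for fi in range(nF) if candidates_per_feat[fi].size > 0]
    rng.shuffle(cis_feats)
    for fi in cis_feats[: config.n_cis]:
        vrow = int(rng.choice(candidates_per_feat[fi]))
        plant(vrow, fi, float(rng.uniform(*config.cis_beta)), "cis")

    # trans hub: sweep driver cis-activates a regulator gene; the regulator's
    # level propagates (attenuated) to many features on the other chromosome
    sweep_keys = freq_table.loc[freq_table["is_sweep"], "variant_key"].tolist()
    sweep_rows = [key_row[k] for k in sweep_keys if maf_ok[key_row[k]]]
    hub_truth = {}
    if sweep_rows and config.hub_n_targets > 0:
        # driver: the MAF-passing sweep variant closest to a coding gene anchor
        best = None
        for vrow in sweep_rows:
            for fi, f in enumerate(feats):
                fc, fp = anchors[f]
                if fc == chrom_of[vrow] and genes[fi].coding:
                    d = abs(int(pos_of[vrow]) - fp)
                    if d <= 1_000_000 and (best is None or d < best[2]):
                        best = (vrow, fi, d)
        if best is not None:
            vrow, reg_fi, _ = best
            plant(vrow, reg_fi, config.hub_driver_beta, "cis")
            reg_chrom = anchors[feats[reg_fi]][0]
            distant = [
                fi for fi in range(nF)
                if anchors[feats[fi]][0] != reg_chrom and fi != reg_fi
            ]
            rng.shuffle(distant)
            targets = distant[: config.hub_n_targets]
            reg_centered = Y[reg_fi] - Y[reg_fi].mean()
            for fi in targets:
                Y[fi] += config.hub_attenuation * reg_centered
                truth_rows.append(
                    {
                        "variant_key": matrix.variants[vrow].key,
                        "feature": feats[fi],
                        "beta": config.hub_attenuation * config.hub_driver_beta,
                        "kind": "trans",
                    }
                )
            hub_truth = {
                "driver": matrix.variants[vrow].key,
                "regulator": feats[reg_fi],
                "n_targets": len(targets),
            }

    # direct trans effects for a subset of the remaining sweep variants
    rest = [r for r in sweep_rows if not hub_truth or matrix.variants[r].key != hub_truth["driver"]]
    rng.shuffle(rest)
    n_direct = int(round(config.trans_per_sweep_fraction * len(rest)))
    for vrow in rest[:n_direct]:
        distant = [fi for fi in range(nF) if anchors[feats[fi]][0] != chrom_of[vrow]]
        if distant:
            plant(vrow, int(rng.choice(distant)), config.trans_beta, "trans")

    # shared-low variants: trans regulators too (selection shared by two pops)
    shared_keys = freq_table.loc[freq_table["is_shared_low"], "variant_key"].tolist()
    for k in shared_keys:
        vrow = key_row[k]
        if not maf_ok[vrow]:
            continue
        distant = [fi for fi in range(nF) if anchors[feats[fi]][0] != chrom_of[vrow]]
        rng.shuffle(distant)
        for fi in distant[: config.shared_low_trans_targets]:
            plant(vrow, fi, config.trans_beta, "trans")

    Y += rng.normal(0.0, config.noise_sd, size=Y.shape)
    values = pd.DataFrame(Y, index=feats, columns=chosen)
    truth = pd.DataFrame(truth_rows, columns=["variant_key", "feature", "beta", "kind"])
    truth.attrs["hub"] = hub_truth
    return ExpressionMatrix(values=values, anchors=anchors), truth


# ---------------------------------------------------------------------------
# one-call generation and on-disk export
# ---------------------------------------------------------------------------


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full dataset deterministically from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed).spawn(3)
    matrix, panel, ancestral, freq_table = generate_genotypes(
        config, np.random.default_rng(ss[0])
    )
    genes, repeats = generate_annotations(config, np.random.default_rng(ss[1]))
    expression, truth = generate_expression(
        config, matrix, panel, genes, freq_table, np.random.default_rng(ss[2])
    )
    return SyntheticDataset(
        config=config,
        matrix=matrix,
        panel=panel,
        ancestral=ancestral,
        genes=genes,
        repeats=repeats,
        expression=expression,
        truth=truth,
        pop_freqs=freq_table,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the dataset in the exact formats the pipeline readers consume."""
    from .data_model import write_vcf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: str(out / v) for k, v in {
        "vcf": "genotypes.vcf",
        "panel": "panel.tsv",
        "ancestral": "ancestral.tsv",
        "genes": "genes.tsv",
        "repeats": "repeats.bed",
        "expression": "expression.tsv",
        "anchors": "anchors.tsv",
        "truth": "truth.tsv",
        "manifest": "manifest.json",
    }.items()}

    write_vcf(ds.matrix, paths["vcf"], contig_lengths=ds.config.chrom_dict)
    pd.DataFrame(
        {"sample": list(ds.panel.assignment), "population": list(ds.panel.assignment.values())}
    ).to_csv(paths["panel"], sep="\t", index=False)
    anc_rows = []
    for v in ds.matrix.variants:
        anc_rows.append(
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "ancestral": ds.ancestral[v.key]}
        )
    pd.DataFrame(anc_rows).to_csv(paths["ancestral"], sep="\t", index=False)

    gene_rows = []
    for g in ds.genes:
        gene_rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "start": g.gene_start,
                          "end": g.gene_end, "strand": g.strand, "coding": int(g.coding),
                          "component": "gene"})
        for comp, ivals in (("CDS", g.cds), ("UTR5", g.utr5), ("UTR3", g.utr3),
                            ("NONCODING", g.noncoding_exon), ("INTRON", g.intron)):
            for s, e in ivals:
                gene_rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "start": s,
                                  "end": e, "strand": g.strand, "coding": int(g.coding),
                                  "component": comp})
    pd.DataFrame(gene_rows).to_csv(paths["genes"], sep="\t", index=False)

    with open(paths["repeats"], "w") as fh:
        for chrom, ivals in ds.repeats.items():
            for s, e in ivals:
                fh.write(f"{chrom}\t{s}\t{e}\n")

    ds.expression.values.to_csv(paths["expression"], sep="\t")
    pd.DataFrame(
        [{"feature": f, "chrom": c, "pos": p} for f, (c, p) in ds.expression.anchors.items()]
    ).to_csv(paths["anchors"], sep="\t", index=False)
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {"config": dataclasses.asdict(ds.config), "seed": ds.config.seed,
             "hub": ds.truth.attrs.get("hub", {})},
            fh, indent=2, default=str,
        )
    return paths
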