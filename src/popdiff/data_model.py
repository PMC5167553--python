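"""Core variant/genotype containers and readers for the pipeline's inputs.

The substrate for every estimator is a :class:`GenotypeMatrix`: a biallelic
(variants x haplotypes) 0/1 indicator matrix with -1 for missing calls, two
haplotype columns per sample, plus per-variant metadata.  Multi-allelic VCF
records are split into one row per ALT allele, so "the variant" is always
the tuple (chrom, pos, ref, alt).

Coordinates: VCF positions stay 1-based on the :class:`Variant`; all
interval arithmetic elsewhere in the package is 0-based half-open, with
conversion at the I/O boundary only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "EXCLUDED",
    "VariantClass",
    "Variant",
    "GenotypeMatrix",
    "PopulationPanel",
    "PopCounts",
    "AlleleCounts",
    "read_vcf",
    "write_vcf",
    "read_panel",
    "read_ancestral",
    "allele_counts",
    "population_frequencies",
    "polarize",
    "daf_array",
]

MISSING = -1  # haplotype entry for a missing genotype call


class _Excluded:
    """Sentinel: variant excluded from DAF analyses (no concordant ancestral call)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "EXCLUDED"


EXCLUDED = _Excluded()


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    SV_DEL = "SV-DEL"
    SV_DUP = "SV-DUP"
    SV_INV = "SV-INV"
    SV_INS = "SV-INS"


_SYMBOLIC = {
    "<DEL>": VariantClass.SV_DEL,
    "<DUP>": VariantClass.SV_DUP,
    "<CN0>": VariantClass.SV_DEL,
    "<INV>": VariantClass.SV_INV,
    "<INS>": VariantClass.SV_INS,
}


def _classify(ref: str, alt: str) -> VariantClass:
    if alt.startswith("<"):
        if alt.startswith("<CN") and alt not in ("<CN0>",):
            return VariantClass.SV_DUP
        return _SYMBOLIC.get(alt, VariantClass.SV_INS)
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    return VariantClass.INDEL


@dataclass
class Variant:
    """One biallelic (post-split) variant; ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: VariantClass = VariantClass.SNV
    source_id: str = "."
    ancestral: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def pos0(self) -> int:
        """0-based coordinate for interval arithmetic."""
        return self.pos - 1


@dataclass
class GenotypeMatrix:
    """Phased biallelic haplotype matrix: (n_variants, 2 * n_samples) of {0,1,-1}."""

    variants: list[Variant]
    haplotypes: np.ndarray
    sample_ids: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != len(self.variants):
            raise ValueError("row count must equal variant count")
        if self.haplotypes.shape[1] != 2 * len(self.sample_ids):
            raise ValueError("column count must equal 2 x sample count")
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("haplotype entries must be 0, 1 or missing (-1)")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_columns(self, sample_ids: list[str]) -> np.ndarray:
        """Haplotype column indices (two per sample) for the given samples."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = []
        for s in sample_ids:
            if s not in index:
                raise KeyError(f"unknown sample: {s}")
            cols.extend((2 * index[s], 2 * index[s] + 1))
        return np.asarray(cols, dtype=np.intp)

    def dosages(self) -> np.ndarray:
        """Per-sample alt-allele dosage 0/1/2 (float, NaN if any hap missing)."""
        h = self.haplotypes.astype(float)
        h[h == MISSING] = np.nan
        return h[:, 0::2] + h[:, 1::2]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            haplotypes=self.haplotypes[idx],
            sample_ids=list(self.sample_ids),
            phased=self.phased,
        )


@dataclass
class PopulationPanel:
    """Disjoint sample -> population assignment."""

    assignment: dict[str, str]

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == population]

    def require(self, sample_ids: list[str]) -> None:
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise KeyError(f"samples without population assignment: {missing[:5]}")


@dataclass(frozen=True)
class PopCounts:
    """Allele counts of one population at one variant.

    ``called_alleles`` counts non-missing haplotypes (the sample-size term
    of the bias correction); ``alt_freq`` is NaN when nothing was called.
    """

    alt_count: int
    called_alleles: int

    @property
    def alt_freq(self) -> float:
        if self.called_alleles == 0:
            return float("nan")
        return self.alt_count / self.called_alleles

    @property
    def defined(self) -> bool:
        return self.called_alleles > 0


@dataclass(frozen=True)
class AlleleCounts:
    """Per-population counts at one variant."""

    per_pop: dict[str, PopCounts]

    def __getitem__(self, pop: str) -> PopCounts:
        return self.per_pop[pop]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_vcf(
    path: str,
    samples: list[str] | None = None,
    allow_unphased: bool = False,
    ancestral: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Read phased genotypes, splitting multi-allelic records per ALT allele.

    For the row derived from ALT allele k, a haplotype entry is 1 iff that
    haplotype carries allele k; any other allele (REF or another ALT)
    counts 0; a missing call is missing in every derived row.  Within a
    record the derived rows are ordered by ALT string, so a coordinate-
    sorted file yields (chrom, pos, alt) ordering.

    Unphased genotypes raise unless ``allow_unphased`` is set (the matrix
    is then marked unphased and LD refuses it).  ``ancestral`` maps
    ``chrom:pos:ref:alt`` keys to ancestral-allele strings.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    if samples is not None:
        known = set(vcf.samples)
        for s in samples:
            if s not in known:
                raise KeyError(f"unknown sample in subset: {s}")
        vcf.set_samples(samples)
    sample_ids = list(vcf.samples)

    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    unphased_seen = False
    for rec in vcf:
        gts = rec.genotypes  # per sample: [a0, a1, phased]
        alleles = np.empty((len(sample_ids), 2), dtype=np.int16)
        for i, g in enumerate(gts):
            if len(g) < 3:
                # haploid call: duplicate the single allele
                alleles[i] = (g[0], g[0])
            else:
                alleles[i] = (g[0], g[1])
                if not g[2] and g[0] != g[1]:
                    unphased_seen = True
        flat = alleles.reshape(-1)
        for k, alt in sorted(enumerate(rec.ALT, start=1), key=lambda t: t[1]):
            row = (flat == k).astype(np.int8)
            row[flat < 0] = MISSING
            var = Variant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                vclass=_classify(rec.REF, alt),
                source_id=rec.ID or ".",
            )
            if ancestral is not None:
                var.ancestral = ancestral.get(var.key, "UNKNOWN")
            variants.append(var)
            rows.append(row)
    if unphased_seen and not allow_unphased:
        raise ValueError(
            "unphased heterozygous genotypes present; pass allow_unphased=True "
            "to read anyway (LD operations will refuse the matrix)"
        )
    hap = np.vstack(rows) if rows else np.empty((0, 2 * len(sample_ids)), dtype=np.int8)
    return GenotypeMatrix(
        variants=variants,
        haplotypes=hap,
        sample_ids=sample_ids,
        phased=not unphased_seen,
    )


def write_vcf(matrix: GenotypeMatrix, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a biallelic matrix as a minimal phased VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.sample_ids) + "\n")
        for i, v in enumerate(matrix.variants):
            row = matrix.haplotypes[i]
            gts = []
            for s in range(matrix.n_samples):
                a, b = row[2 * s], row[2 * s + 1]
                gts.append(f"{'.' if a == MISSING else a}|{'.' if b == MISSING else b}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.source_id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_panel(path: str) -> PopulationPanel:
    """Read a sample->population TSV (columns ``sample``, ``population``)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    dup = df["sample"][df["sample"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate sample ids in panel: {dup}")
    return PopulationPanel(assignment=dict(zip(df["sample"], df["population"])))


def read_ancestral(path: str) -> dict[str, str]:
    """Read an ancestral-allele TSV keyed by chrom:pos:ref:alt.

    Columns: chrom, pos, ref, alt, ancestral.  The ancestral column holds
    an allele string or ``UNKNOWN`` (calls kept only when all inference
    methods agreed; discordant sites are distributed as UNKNOWN).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    keys = (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"]
        + ":"
        + df["alt"]
    )
    dup = keys[keys.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate variant keys in ancestral table: {dup}")
    return dict(zip(keys, df["ancestral"].astype(str)))


# ---------------------------------------------------------------------------
# counting / polarization
# ---------------------------------------------------------------------------


def allele_counts(matrix: GenotypeMatrix, panel: PopulationPanel, variant_index: int) -> AlleleCounts:
    """Per-population alt/called counts at one variant row."""
    panel.require(matrix.sample_ids)
    row = matrix.haplotypes[variant_index]
    out = {}
    for pop in panel.populations:
        cols = matrix.sample_columns([s for s in matrix.sample_ids if panel.assignment[s] == pop])
        vals = row[cols]
        called = int((vals != MISSING).sum())
        out[pop] = PopCounts(alt_count=int((vals == 1).sum()), called_alleles=called)
    return AlleleCounts(per_pop=out)


def population_frequencies(
    matrix: GenotypeMatrix, panel: PopulationPanel, population: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (alt_freq, called_alleles) arrays over all variants.

    Frequencies are NaN where the population has no called haplotypes.
    """
    pop_samples = [s for s in matrix.sample_ids if panel.assignment.get(s) == population]
    if not pop_samples:
        raise KeyError(f"no samples of population {population!r} in matrix")
    cols = matrix.sample_columns(pop_samples)
    sub = matrix.haplotypes[:, cols]
    called = (sub != MISSING).sum(axis=1)
    alt = (sub == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / np.where(called > 0, called, 1), np.nan)
    return freq, called


def polarize(variant: Variant, counts: AlleleCounts):
    """Per-population derived allele frequencies, or EXCLUDED.

    ancestral == ref: DAF is the alt frequency; ancestral == alt: DAF is
    1 - alt frequency; UNKNOWN or any other allele string: the variant is
    EXCLUDED from DAF-based analyses (that is a value, not an error).
    """
    if variant.ancestral == variant.ref:
        return {p: c.alt_freq for p, c in counts.per_pop.items()}
    if variant.ancestral == variant.alt:
        return {p: 1.0 - c.alt_freq for p, c in counts.per_pop.items()}
    return EXCLUDED


def daf_array(matrix: GenotypeMatrix, panel: PopulationPanel, population: str) -> np.ndarray:
    """Vectorised DAF per variant; NaN where EXCLUDED or frequency undefined."""
    freq, _ = population_frequencies(matrix, panel, population)
    out = np.full(matrix.n_variants, np.nan)
    for i, v in enumerate(matrix.variants):
        if v.ancestral == v.ref:
            out[i] = freq[i]
        elif v.ancestral == v.alt:
            out[i] = 1.0 - freq[i]
    return out
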