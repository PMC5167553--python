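"""Gene-component genome partition, repeat status, and extreme-F_ST region sets.

Every base of the genome is assigned exactly one of nine ranked
gene-component classes or the unranked remainder.  When annotations
overlap, the lowest rank (highest priority) wins, resolved per base:

    1 CDS, 2 5'UTR, 3 3'UTR, 4 noncoding-gene exon, 5 intron,
    6 [gene_start-1000, gene_start), 7 [gene_end, gene_end+1000),
    8 [gene_start-5000, gene_start), 9 [gene_end, gene_end+5000)

so e.g. a base lying in an intron of one gene and a 5'UTR of another is a
5'UTR base.  Flanks are strand-agnostic: "start" is the lower genomic
coordinate of the gene regardless of transcription direction.  All
intervals are 0-based half-open.

Repeat status of a query interval is binary: REPEAT iff it overlaps at
least one repeat-track interval by >= 1 bp.

The per-base rank array representation is exact and fast for the
chromosome sizes this pipeline simulates (tens of Mb); it trades memory
for simplicity relative to interval algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fst import FstEstimate, fst_region, hudson_components_arrays

__all__ = [
    "RegionClass",
    "CLASS_RANK",
    "GENE_CLASSES",
    "GeneModel",
    "GenomePartition",
    "read_gene_models",
    "read_bed",
    "partition_genome",
    "classify_repeat",
    "gene_fst_table",
    "select_extremes",
    "length_matched_sample",
    "region_eqtl_enrichment",
]


class RegionClass:
    CDS = "CDS"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    NONCODING = "NONCODING"
    INTRON = "INTRON"
    UP1000 = "UP1000"
    DOWN1000 = "DOWN1000"
    UP5000 = "UP5000"
    DOWN5000 = "DOWN5000"
    REMAINDER = "REMAINDER"


# priority rank 1-9; REMAINDER is unranked (applies only where nothing else does)
CLASS_RANK: dict[str, int] = {
    RegionClass.CDS: 1,
    RegionClass.UTR5: 2,
    RegionClass.UTR3: 3,
    RegionClass.NONCODING: 4,
    RegionClass.INTRON: 5,
    RegionClass.UP1000: 6,
    RegionClass.DOWN1000: 7,
    RegionClass.UP5000: 8,
    RegionClass.DOWN5000: 9,
}
_RANK_CLASS = {r: c for c, r in CLASS_RANK.items()}
_REMAINDER_RANK = 127

# classes 1-5 constitute the "gene region"; flanks + remainder are non-genic
GENE_CLASSES = (
    RegionClass.CDS,
    RegionClass.UTR5,
    RegionClass.UTR3,
    RegionClass.NONCODING,
    RegionClass.INTRON,
)


@dataclass
class GeneModel:
    """One gene's component intervals (0-based half-open, within the gene span)."""

    gene_id: str
    chrom: str
    gene_start: int
    gene_end: int
    strand: str = "+"
    coding: bool = True
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    noncoding_exon: list[tuple[int, int]] = field(default_factory=list)
    intron: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gene_end <= self.gene_start:
            raise ValueError(f"{self.gene_id}: empty gene span")
        if self.cds and not self.coding:
            raise ValueError(f"{self.gene_id}: CDS intervals on a noncoding gene")

    def component_intervals(self):
        """(class, start, end) triples for annotated components plus flanks."""
        for cls, ivals in (
            (RegionClass.CDS, self.cds),
            (RegionClass.UTR5, self.utr5),
            (RegionClass.UTR3, self.utr3),
            (RegionClass.NONCODING, self.noncoding_exon),
            (RegionClass.INTRON, self.intron),
        ):
            for s, e in ivals:
                yield cls, s, e
        yield RegionClass.UP1000, self.gene_start - 1000, self.gene_start
        yield RegionClass.DOWN1000, self.gene_end, self.gene_end + 1000
        yield RegionClass.UP5000, self.gene_start - 5000, self.gene_start
        yield RegionClass.DOWN5000, self.gene_end, self.gene_end + 5000


def read_gene_models(path: str) -> list[GeneModel]:
    """Read a gene-component interval TSV.

    Columns: gene_id, chrom, start, end, strand, coding (0/1), component
    (gene / CDS / UTR5 / UTR3 / NONCODING / INTRON); the ``gene`` rows give
    the gene span.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes: list[GeneModel] = []
    for gid, grp in df.groupby("gene_id", sort=False):
        span = grp[grp["component"] == "gene"]
        if span.empty:
            raise ValueError(f"gene {gid} has no 'gene' span row")
        row = span.iloc[0]
        gm = GeneModel(
            gene_id=str(gid),
            chrom=row["chrom"],
            gene_start=int(row["start"]),
            gene_end=int(row["end"]),
            strand=str(row["strand"]),
            coding=bool(row["coding"]),
        )
        comp_attr = {
            "CDS": gm.cds,
            "UTR5": gm.utr5,
            "UTR3": gm.utr3,
            "NONCODING": gm.noncoding_exon,
            "INTRON": gm.intron,
        }
        for _, r in grp[grp["component"] != "gene"].iterrows():
            comp_attr[r["component"]].append((int(r["start"]), int(r["end"])))
        genes.append(gm)
    return genes


def read_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read a 3-column BED into per-chromosome sorted interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(s), int(e)))
    for ivals in out.values():
        ivals.sort()
    return out


@dataclass
class GenomePartition:
    """Per-chromosome rank arrays; one int8 entry per base."""

    ranks: dict[str, np.ndarray]

    def class_at(self, chrom: str, pos0: int) -> str:
        r = int(self.ranks[chrom][pos0])
        return _RANK_CLASS.get(r, RegionClass.REMAINDER)

    def class_of_variants(self, chroms, pos0s) -> np.ndarray:
        out = np.empty(len(pos0s), dtype=object)
        for i, (c, p) in enumerate(zip(chroms, pos0s)):
            out[i] = self.class_at(c, int(p))
        return out

    def coverage(self) -> dict[str, int]:
        """Base-pair total per class; sums to genome length by construction."""
        cov = {c: 0 for c in CLASS_RANK}
        cov[RegionClass.REMAINDER] = 0
        for arr in self.ranks.values():
            vals, counts = np.unique(arr, return_counts=True)
            for v, n in zip(vals, counts):
                cov[_RANK_CLASS.get(int(v), RegionClass.REMAINDER)] += int(n)
        return cov

    def intervals(self, chrom: str) -> list[tuple[int, int, str]]:
        """Maximal runs of constant class on one chromosome."""
        arr = self.ranks[chrom]
        if arr.size == 0:
            return []
        change = np.nonzero(np.diff(arr))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [arr.size]])
        return [
            (int(s), int(e), _RANK_CLASS.get(int(arr[s]), RegionClass.REMAINDER))
            for s, e in zip(starts, ends)
        ]


def partition_genome(genes: list[GeneModel], chrom_lengths: dict[str, int]) -> GenomePartition:
    """Assign every base its minimum-rank class.

    Flanks are truncated at chromosome edges; overlapping intervals within
    one component of one gene are implicitly unioned, never an error.
    """
    ranks = {c: np.full(int(n), _REMAINDER_RANK, dtype=np.int8) for c, n in chrom_lengths.items()}
    for g in genes:
        if g.chrom not in ranks:
            raise KeyError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        arr = ranks[g.chrom]
        L = arr.size
        if g.gene_end > L:
            raise ValueError(f"gene {g.gene_id} extends past chromosome end")
        for cls, s, e in g.component_intervals():
            s, e = max(0, s), min(L, e)
            if s < e:
                np.minimum(arr[s:e], CLASS_RANK[cls], out=arr[s:e])
    return GenomePartition(ranks=ranks)


def classify_repeat(interval: tuple[int, int], repeat_track: list[tuple[int, int]]) -> str:
    """REPEAT iff the (0-based half-open) interval overlaps any repeat by >= 1 bp."""
    s, e = interval
    if repeat_track:
        starts = np.asarray([r[0] for r in repeat_track])
        ends = np.asarray([r[1] for r in repeat_track])
        if bool(np.any((starts < e) & (ends > s))):
            return "REPEAT"
    return "NONREPEAT"


def gene_fst_table(
    genes: list[GeneModel],
    matrix,
    panel,
    pop_a: str,
    pop_b: str,
    flank: int = 5000,
    corrected: bool = True,
) -> pd.DataFrame:
    """Per-gene ratio-of-averages F_ST over the gene body [start, end) and the
    extended region [start-flank, end+flank); undefined estimates are NaN."""
    from .data_model import population_frequencies

    p1, n1 = population_frequencies(matrix, panel, pop_a)
    p2, n2 = population_frequencies(matrix, panel, pop_b)
    num, den = hudson_components_arrays(p1, n1, p2, n2, corrected=corrected)
    chroms = np.asarray([v.chrom for v in matrix.variants])
    pos0 = np.asarray([v.pos0 for v in matrix.variants])
    rows = []
    for g in genes:
        on_chrom = chroms == g.chrom
        body = on_chrom & (pos0 >= g.gene_start) & (pos0 < g.gene_end)
        ext = on_chrom & (pos0 >= g.gene_start - flank) & (pos0 < g.gene_end + flank)
        est = fst_region((num[body], den[body]))
        est_ext = fst_region((num[ext], den[ext]))
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.gene_start,
                "end": g.gene_end,
                "coding": g.coding,
                "n_variants": est.n_variants,
                "fst": est.value,
                "n_variants_ext": est_ext.n_variants,
                "fst_ext": est_ext.value,
            }
        )
    return pd.DataFrame(rows)


def select_extremes(
    estimates: pd.DataFrame | list[FstEstimate],
    mode: str = "fraction",
    k: float | int = 0.01,
    value_col: str = "fst",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top and bottom sets of the defined estimates.

    fraction mode takes ceil(k * n) from each end; count mode takes exactly
    k (or the whole list, with a warning, if k exceeds it).  Sorting is by
    value descending with (chrom, start) tie-break, so all-equal inputs
    select deterministically by coordinate.  Top and bottom sets may
    overlap when 2 * take > n; callers log that.
    """
    if not isinstance(estimates, pd.DataFrame):
        estimates = pd.DataFrame(
            {
                "chrom": [e.region[0] if isinstance(e.region, tuple) else "" for e in estimates],
                "start": [e.region[1] if isinstance(e.region, tuple) and len(e.region) > 1 else 0 for e in estimates],
                value_col: [e.value for e in estimates],
            }
        )
    df = estimates[~estimates[value_col].isna()]
    tie_cols = [c for c in ("chrom", "start") if c in df.columns]
    df = df.sort_values(
        by=[value_col] + tie_cols, ascending=[False] + [True] * len(tie_cols), kind="mergesort"
    )
    n = len(df)
    if mode == "fraction":
        take = math.ceil(k * n)
    elif mode == "count":
        take = int(k)
        if take > n:
            import warnings

            warnings.warn(f"requested {take} regions but only {n} defined; taking all")
            take = n
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return df.head(take), df.tail(take)


def length_matched_sample(
    target_regions: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    exclusions: list[tuple[str, int, int]] | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> list[tuple[str, int, int]]:
    """One uniformly placed region of identical length per target, on the
    target's own chromosome, rejected-and-resampled while it overlaps the
    exclusion set (by default the target set itself)."""
    rng = np.random.default_rng(seed)
    excl = exclusions if exclusions is not None else list(target_regions)
    out = []
    for chrom, s, e in target_regions:
        length = e - s
        L = chrom_lengths[chrom]
        if length > L:
            raise ValueError(f"target {chrom}:{s}-{e} longer than its chromosome")
        for _ in range(max_tries):
            start = int(rng.integers(0, L - length + 1))
            cand = (chrom, start, start + length)
            if not any(c == chrom and start < ee and cand[2] > ss for c, ss, ee in excl):
                out.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place a length-matched region for {chrom}:{s}-{e} "
                f"after {max_tries} tries"
            )
    return out


def region_eqtl_enrichment(set_a: list, set_b: list, eqtl_index: dict) -> dict:
    """Proportions of regions with >= 1 eQTL (FDR < 0.05) in two region sets,
    with a 2x2 chi-squared test (df=1, no continuity correction) per category.

    eqtl_index maps region key -> bool, or -> {category: bool} for per-
    category (cis/trans x expression type) comparisons.  Degenerate margins
    give an undefined (NaN) p-value rather than an exception.
    """

    def _one(flags_a: np.ndarray, flags_b: np.ndarray) -> dict:
        a1 = int(flags_a.sum())
        b1 = int(flags_b.sum())
        table = np.array(
            [[a1, len(flags_a) - a1], [b1, len(flags_b) - b1]], dtype=float
        )
        prop_a = a1 / len(flags_a) if len(flags_a) else float("nan")
        prop_b = b1 / len(flags_b) if len(flags_b) else float("nan")
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            chi2, p = float("nan"), float("nan")
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return {
            "prop_a": prop_a,
            "prop_b": prop_b,
            "n_a": int(len(flags_a)),
            "n_b": int(len(flags_b)),
            "chi2": float(chi2),
            "p": float(p),
        }

    sample = next(iter(eqtl_index.values()), False)
    if isinstance(sample, dict):
        cats = sorted(sample)
        return {
            cat: _one(
                np.array([bool(eqtl_index.get(r, {}).get(cat, False)) for r in set_a]),
                np.array([bool(eqtl_index.get(r, {}).get(cat, False)) for r in set_b]),
            )
            for cat in cats
        }
    return _one(
        np.array([bool(eqtl_index.get(r, False)) for r in set_a]),
        np.array([bool(eqtl_index.get(r, False)) for r in set_b]),
    )
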