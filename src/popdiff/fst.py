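"""Hudson two-population F_ST with ratio-of-averages aggregation.

Per biallelic variant, with allele frequencies p1, p2 and numbers of called
haplotypes n1, n2:

    den = p1*(1 - p2) + p2*(1 - p1)
    num = (p1 - p2)**2                                   (uncorrected)
    num = (p1 - p2)**2 - p1*(1-p1)/(n1-1) - p2*(1-p2)/(n2-1)   (corrected)

The corrected numerator subtracts the sampling-variance bias of each
frequency estimate and may be negative; it is never clamped.  A region's
F_ST is the *ratio of averages* — sum of numerators over sum of
denominators across its variants — not the average of per-variant ratios.
Variants monomorphic for the same allele in both populations have
num = den = 0 and contribute nothing; a region whose summed denominator is
zero has an undefined estimate (reported as NaN, never silently dropped by
the windowing code).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FstComponents",
    "FstEstimate",
    "hudson_components",
    "hudson_components_arrays",
    "fst_region",
    "windowed_fst",
    "window_fst_from_components",
    "fst_structural",
    "per_variant_fst",
]


@dataclass(frozen=True)
class FstComponents:
    """Numerator/denominator pair of one variant's Hudson estimator."""

    num: float
    den: float
    corrected: bool

    @property
    def ratio(self) -> float:
        """Single-variant F_ST; NaN when the denominator is zero."""
        return self.num / self.den if self.den > 0 else float("nan")


@dataclass(frozen=True)
class FstEstimate:
    """Ratio-of-averages F_ST over a set of variants.

    ``value`` is NaN (undefined) when no variant contributed a positive
    denominator; ``n_variants`` counts the variants with defined
    frequencies that entered the sums.
    """

    value: float
    n_variants: int
    region: tuple | str | None = None

    @property
    def defined(self) -> bool:
        return not np.isnan(self.value)


def hudson_components(
    p1: float, n1: int | None, p2: float, n2: int | None, corrected: bool = True
) -> FstComponents:
    """Per-variant estimator components for one pair of populations.

    Corrected mode requires the called-haplotype counts n1, n2 >= 2;
    uncorrected mode (used on census frequencies, where there is no
    sampling) ignores them.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError(f"frequencies must be in [0, 1], got {p1}, {p2}")
    num, den = hudson_components_arrays(
        np.asarray([p1]), None if n1 is None else np.asarray([n1]),
        np.asarray([p2]), None if n2 is None else np.asarray([n2]),
        corrected=corrected,
    )
    return FstComponents(num=float(num[0]), den=float(den[0]), corrected=corrected)


def hudson_components_arrays(
    p1: np.ndarray,
    n1: np.ndarray | None,
    p2: np.ndarray,
    n2: np.ndarray | None,
    corrected: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised num/den arrays; NaN frequencies propagate to NaN components."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    num = (p1 - p2) ** 2
    if corrected:
        if n1 is None or n2 is None:
            raise ValueError("corrected components require called-allele counts n1, n2")
        n1 = np.asarray(n1, dtype=float)
        n2 = np.asarray(n2, dtype=float)
        if np.any(n1 < 2) or np.any(n2 < 2):
            raise ValueError("bias correction requires at least 2 called haplotypes per population")
        num = num - p1 * (1.0 - p1) / (n1 - 1.0) - p2 * (1.0 - p2) / (n2 - 1.0)
    return num, den


def fst_region(
    components: list[FstComponents] | tuple[np.ndarray, np.ndarray],
    region=None,
) -> FstEstimate:
    """Ratio-of-averages over a variant set.

    Accepts either a list of :class:`FstComponents` or a (num, den) array
    pair.  Variants with NaN components (undefined frequency in either
    population) are excluded from the sums and from ``n_variants``.
    """
    if isinstance(components, tuple):
        num, den = components
    else:
        num = np.asarray([c.num for c in components], dtype=float)
        den = np.asarray([c.den for c in components], dtype=float)
    ok = ~(np.isnan(num) | np.isnan(den))
    num, den = num[ok], den[ok]
    sden = float(den.sum())
    value = float(num.sum()) / sden if sden > 0 else float("nan")
    return FstEstimate(value=value, n_variants=int(num.size), region=region)


def window_fst_from_components(
    positions: np.ndarray,
    num: np.ndarray,
    den: np.ndarray,
    window: int,
    chrom_length: int,
    return_sums: bool = False,
):
    """Window ratio-of-averages from per-variant components.

    Windows are [k*w, (k+1)*w) in 0-based coordinates for
    k = 0 .. floor(chrom_length/w) - 1; the trailing remnant shorter than w
    is excluded entirely, together with any variants falling in it.
    Returns (fst, n_variants) arrays of length floor(chrom_length/w), with
    NaN for windows whose summed denominator is zero.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    n_windows = int(chrom_length) // int(window)
    positions = np.asarray(positions, dtype=float)
    ok = ~(np.isnan(num) | np.isnan(den))
    idx = np.floor(positions / window).astype(np.intp)
    use = ok & (idx < n_windows) & (idx >= 0)
    snum = np.bincount(idx[use], weights=num[use], minlength=n_windows)
    sden = np.bincount(idx[use], weights=den[use], minlength=n_windows)
    nvar = np.bincount(idx[use], minlength=n_windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(sden > 0, snum / np.where(sden > 0, sden, 1.0), np.nan)
    if return_sums:
        return fst, nvar, snum, sden
    return fst, nvar


def windowed_fst(
    matrix,
    panel,
    pop_a: str,
    pop_b: str,
    window: int,
    chrom_length: int,
    corrected: bool = True,
) -> list[FstEstimate]:
    """Fixed-window F_ST scan of one chromosome of a genotype matrix.

    Positions from the matrix are 1-based (VCF convention) and converted to
    0-based before windowing.  Undefined windows (no usable variants) are
    reported with NaN values, not dropped.
    """
    from .data_model import population_frequencies

    p1, n1 = population_frequencies(matrix, panel, pop_a)
    p2, n2 = population_frequencies(matrix, panel, pop_b)
    num, den = hudson_components_arrays(p1, n1, p2, n2, corrected=corrected)
    pos0 = np.asarray([v.pos - 1 for v in matrix.variants], dtype=float)
    fst, nvar = window_fst_from_components(pos0, num, den, window, chrom_length)
    return [
        FstEstimate(value=float(f), n_variants=int(k), region=(i * window, (i + 1) * window))
        for i, (f, k) in enumerate(zip(fst, nvar))
    ]


def per_variant_fst(matrix, panel, pop_a: str, pop_b: str, corrected: bool = True) -> np.ndarray:
    """Single-variant F_ST ratios (NaN where undefined); diagnostic surface."""
    from .data_model import population_frequencies

    p1, n1 = population_frequencies(matrix, panel, pop_a)
    p2, n2 = population_frequencies(matrix, panel, pop_b)
    num, den = hudson_components_arrays(p1, n1, p2, n2, corrected=corrected)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def fst_structural(matrix, panel, pop_a: str, pop_b: str) -> tuple[list[FstEstimate], FstEstimate]:
    """Per-allele corrected estimates for structural variants plus the pooled
    ratio-of-averages over all of them.

    Multi-allelic copy-number records are expected to be split per allele
    upstream (one matrix row per allele), exactly as SNVs are.
    """
    from .data_model import population_frequencies

    p1, n1 = population_frequencies(matrix, panel, pop_a)
    p2, n2 = population_frequencies(matrix, panel, pop_b)
    num, den = hudson_components_arrays(p1, n1, p2, n2, corrected=True)
    per_allele = []
    for i, v in enumerate(matrix.variants):
        if np.isnan(num[i]) or np.isnan(den[i]):
            est = FstEstimate(value=float("nan"), n_variants=0, region=v.key)
        else:
            est = FstEstimate(
                value=float(num[i] / den[i]) if den[i] > 0 else float("nan"),
                n_variants=1,
                region=v.key,
            )
        per_allele.append(est)
    pooled = fst_region((num, den), region="all-SV")
    return per_allele, pooled
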