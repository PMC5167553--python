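"""Pairwise linkage disequilibrium (D, D', r^2) from phased haplotypes.

With derived/alt frequencies pA, pB and joint haplotype frequency pAB:

    D      = pAB - pA*pB
    D_max  = min(pA*(1-pB), pB*(1-pA))          if D > 0
             min(pA*pB, (1-pA)*(1-pB))          if D < 0
    D'     = |D| / D_max
    r^2    = D^2 / (pA*(1-pA)*pB*(1-pB))

Haplotypes with a missing call at either site are dropped pairwise; a site
monomorphic among the retained haplotypes makes the pair undefined.
Combined-population LD pools the selected populations' haplotypes without
reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MISSING, GenotypeMatrix, PopulationPanel

__all__ = ["LdResult", "ld_pair", "ld_matrix"]


@dataclass(frozen=True)
class LdResult:
    D: float
    Dprime: float
    r2: float
    n_haplotypes: int
    defined: bool = True

    @staticmethod
    def undefined(n: int = 0) -> "LdResult":
        return LdResult(float("nan"), float("nan"), float("nan"), n, defined=False)


def ld_pair(hap_a: np.ndarray, hap_b: np.ndarray) -> LdResult:
    """LD summary of two equal-length phased 0/1 haplotype vectors."""
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    if hap_a.shape != hap_b.shape:
        raise ValueError("haplotype vectors must have equal length")
    keep = (hap_a != MISSING) & (hap_b != MISSING)
    a = hap_a[keep].astype(float)
    b = hap_b[keep].astype(float)
    n = a.size
    if n == 0:
        return LdResult.undefined(0)
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LdResult.undefined(n)
    pab = (a * b).mean()
    D = pab - pa * pb
    if D > 0:
        dmax = min(pa * (1 - pb), pb * (1 - pa))
    elif D < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        dmax = 1.0  # D = 0: D' defined as 0
    dprime = abs(D) / dmax
    r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))
    return LdResult(D=float(D), Dprime=float(dprime), r2=float(r2), n_haplotypes=int(n))


def ld_matrix(
    matrix: GenotypeMatrix,
    region: tuple[str, int, int] | None = None,
    panel: PopulationPanel | None = None,
    populations: list[str] | str = "ALL",
) -> pd.DataFrame:
    """All unordered within-region variant pairs on pooled haplotypes.

    ``region`` is (chrom, start, end) in 0-based half-open coordinates
    (None = whole matrix); ``populations`` selects whose haplotypes are
    pooled ("ALL" = every column).  Refuses unphased matrices.
    """
    if not matrix.phased:
        raise ValueError("LD requires phased haplotypes; this matrix is unphased")
    idx = np.arange(matrix.n_variants)
    if region is not None:
        chrom, start, end = region
        idx = np.asarray(
            [i for i in idx if matrix.variants[i].chrom == chrom and start <= matrix.variants[i].pos0 < end],
            dtype=np.intp,
        )
    if populations == "ALL" or panel is None:
        cols = np.arange(matrix.haplotypes.shape[1])
    else:
        if isinstance(populations, str):
            populations = [populations]
        samples = [s for s in matrix.sample_ids if panel.assignment.get(s) in populations]
        cols = matrix.sample_columns(samples)
    rows = []
    for ii, i in enumerate(idx):
        for j in idx[ii + 1 :]:
            res = ld_pair(matrix.haplotypes[i, cols], matrix.haplotypes[j, cols])
            rows.append(
                {
                    "key1": matrix.variants[i].key,
                    "key2": matrix.variants[j].key,
                    "pos1": matrix.variants[i].pos,
                    "pos2": matrix.variants[j].pos,
                    "D": res.D,
                    "Dprime": res.Dprime,
                    "r2": res.r2,
                    "n": res.n_haplotypes,
                }
            )
    return pd.DataFrame(
        rows, columns=["key1", "key2", "pos1", "pos2", "D", "Dprime", "r2", "n"]
    )
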