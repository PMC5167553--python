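"""Derived-allele-frequency differences and their relation to eQTL status.

dDAF between two populations is the absolute difference of their derived
allele frequencies.  Variants are sorted by decreasing dDAF and cut into
consecutive fixed-size groups (the final partial group is kept, so the
group count is ceil(n / group_size)); per group the analysis reports the
fraction of members that are significant cis- or trans-eQTLs and the mean
DAF of each population.  Elevated trans proportions in the top-dDAF groups
flag population-specific (sweep-like) regulatory adaptation; elevated
proportions in the bottom groups between two non-African populations flag
selection shared by both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "delta_daf",
    "delta_daf_signed",
    "build_daf_records",
    "group_by_delta_daf",
    "group_summaries",
    "daf_histogram",
]


def delta_daf(daf_a, daf_b):
    """Absolute DAF difference |a - b| (scalar or elementwise)."""
    return np.abs(np.asarray(daf_a, dtype=float) - np.asarray(daf_b, dtype=float))


def delta_daf_signed(daf_a, daf_b):
    """Signed DAF difference a - b; diagnostic variant of :func:`delta_daf`."""
    return np.asarray(daf_a, dtype=float) - np.asarray(daf_b, dtype=float)


def build_daf_records(
    matrix,
    panel,
    populations: list[str],
    eqtl_records: pd.DataFrame | None = None,
    region_class: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant table of DAFs, eQTL flags and (optional) region class.

    Variants without a usable ancestral call (EXCLUDED) or with an
    undefined frequency in any requested population are omitted.  eQTL
    flags mark variants with >= 1 significant cis (resp. trans) record.
    """
    from .data_model import daf_array

    cols = {f"daf_{p}": daf_array(matrix, panel, p) for p in populations}
    df = pd.DataFrame(
        {
            "variant_key": [v.key for v in matrix.variants],
            "chrom": [v.chrom for v in matrix.variants],
            "pos": [v.pos for v in matrix.variants],
            "alt": [v.alt for v in matrix.variants],
            **cols,
        }
    )
    if region_class is not None:
        df["region_class"] = region_class
    keep = ~df[[f"daf_{p}" for p in populations]].isna().any(axis=1)
    df = df[keep].reset_index(drop=True)
    if eqtl_records is not None and not eqtl_records.empty:
        sig = eqtl_records[eqtl_records["significant"]]
        cis_keys = set(sig.loc[sig["kind"] == "cis", "variant_key"])
        trans_keys = set(sig.loc[sig["kind"] == "trans", "variant_key"])
    else:
        cis_keys, trans_keys = set(), set()
    df["cis_eqtl"] = df["variant_key"].isin(cis_keys)
    df["trans_eqtl"] = df["variant_key"].isin(trans_keys)
    return df


def group_by_delta_daf(
    records: pd.DataFrame, group_size: int, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Assign a 0-based group index by decreasing dDAF(pop_a, pop_b).

    Ties break by (chrom, pos, alt) for determinism; consecutive chunks of
    ``group_size``, final partial chunk kept as its own group, so there are
    ceil(n / group_size) groups.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    out = records.copy()
    out["delta_daf"] = delta_daf(out[f"daf_{pop_a}"], out[f"daf_{pop_b}"])
    out = out.sort_values(
        by=["delta_daf", "chrom", "pos", "alt"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["group"] = np.arange(len(out)) // group_size
    return out


def group_summaries(grouped: pd.DataFrame, populations: list[str]) -> pd.DataFrame:
    """Per-group member count, cis/trans eQTL proportions and mean DAFs,
    ordered by group index (decreasing dDAF)."""
    agg = {"variant_key": "count", "cis_eqtl": "mean", "trans_eqtl": "mean"}
    agg.update({f"daf_{p}": "mean" for p in populations})
    summ = grouped.groupby("group").agg(agg).rename(
        columns={
            "variant_key": "n",
            "cis_eqtl": "prop_cis",
            "trans_eqtl": "prop_trans",
            **{f"daf_{p}": f"mean_daf_{p}" for p in populations},
        }
    )
    summ["min_delta_daf"] = grouped.groupby("group")["delta_daf"].min()
    summ["max_delta_daf"] = grouped.groupby("group")["delta_daf"].max()
    return summ.reset_index()


def daf_histogram(
    dafs: np.ndarray | pd.Series, binning: str = "uniform"
) -> pd.DataFrame:
    """Counts and densities of a DAF sample.

    ``uniform``: width-0.01 bins on [0, 1].  ``log-low``: log-spaced bins
    below 0.01 (plus a final [0.01, 1] bin) to resolve structure among very
    rare derived alleles.  Total counts equal the number of records.
    """
    x = np.asarray(dafs, dtype=float)
    x = x[~np.isnan(x)]
    if binning == "uniform":
        edges = np.linspace(0.0, 1.0, 101)
    elif binning == "log-low":
        edges = np.concatenate([[0.0], np.logspace(-4, -2, 21), [1.0]])
    else:
        raise ValueError(f"unknown binning {binning!r}")
    counts, _ = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    dens = counts / (widths * max(x.size, 1))
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts, "density": dens}
    )
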