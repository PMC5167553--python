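"""Combined-population eQTL scan: OLS with a population covariate.

All analyzed samples are pooled across populations and each expression
feature is regressed on per-sample alt-allele dosage with an intercept and
population indicator columns (one per population minus a reference level,
first alphabetically).  The covariate absorbs population-level expression
shifts that would otherwise masquerade as genotype effects, because a
population-specific variant's dosage is itself strongly population-
correlated.  The dosage effect, its t statistic and a two-sided p-value
(t distribution, n - #parameters df) are computed by the Frisch-Waugh
projection: both dosage and expression are residualized against the
covariate design, and the per-pair statistics follow from the residual
correlation.  This is algebraically identical to full OLS and allows the
all-pairs scan to be a single matrix product.

cis vs trans is purely positional: cis iff the variant and the feature
anchor share a chromosome and lie within 1 Mb (inclusive); p-value
pre-filters (cis 0.05, trans 0.01) are applied before a Benjamini-
Hochberg adjustment run separately per family, with m equal to the
family's retained test count; the significant set is FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GenotypeMatrix, PopulationPanel

__all__ = [
    "ExpressionMatrix",
    "filter_maf",
    "population_design",
    "fit_eqtl",
    "classify_cis_trans",
    "scan",
    "threshold_and_fdr",
    "hotspot_counts",
    "transcription_ratios",
    "read_expression",
    "CIS_WINDOW",
    "CIS_P_CUTOFF",
    "TRANS_P_CUTOFF",
    "FDR_CUTOFF",
    "MAF_THRESHOLD",
]

CIS_WINDOW = 1_000_000  # bp, inclusive
CIS_P_CUTOFF = 0.05
TRANS_P_CUTOFF = 0.01
FDR_CUTOFF = 0.05
MAF_THRESHOLD = 0.05  # strict: keep min(f, 1-f) > threshold


@dataclass
class ExpressionMatrix:
    """Normalized expression: (features x samples) with per-feature anchors.

    ``anchors`` maps feature id -> (chrom, 1-based representative
    coordinate) used for the cis distance rule.
    """

    values: pd.DataFrame
    anchors: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [f for f in self.values.index if f not in self.anchors]
        if missing:
            raise ValueError(f"features without anchors: {missing[:5]}")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression(values_path: str, anchors_path: str) -> ExpressionMatrix:
    """Read a features x samples TSV and a feature-anchor TSV
    (columns feature, chrom, pos)."""
    vals = pd.read_csv(values_path, sep="\t", index_col=0)
    anch = pd.read_csv(anchors_path, sep="\t", dtype={"chrom": str})
    anchors = {r["feature"]: (r["chrom"], int(r["pos"])) for _, r in anch.iterrows()}
    return ExpressionMatrix(values=vals, anchors=anchors)


def filter_maf(matrix: GenotypeMatrix, threshold: float = MAF_THRESHOLD) -> GenotypeMatrix:
    """Keep variants whose pooled minor allele frequency strictly exceeds
    ``threshold`` over all (analyzed) samples."""
    h = matrix.haplotypes
    called = (h != -1).sum(axis=1)
    alt = (h == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(called > 0, alt / np.where(called > 0, called, 1), np.nan)
    maf = np.minimum(f, 1.0 - f)
    return matrix.subset_variants(maf > threshold)


def population_design(panel: PopulationPanel, sample_ids: list[str]) -> np.ndarray:
    """Intercept + per-population indicators, reference = first alphabetically."""
    pops = sorted({panel.assignment[s] for s in sample_ids})
    cols = [np.ones(len(sample_ids))]
    for p in pops[1:]:
        cols.append(np.array([1.0 if panel.assignment[s] == p else 0.0 for s in sample_ids]))
    return np.column_stack(cols)


def _residualize(x: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residuals of the rows/vector x against the orthonormal basis Q."""
    return x - (x @ Q) @ Q.T


def fit_eqtl(
    dosage: np.ndarray, expression: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, float]:
    """(beta, t, p) for expression ~ intercept + covariates + dosage.

    Samples with missing dosage or expression are dropped.  Raises if the
    dosage is collinear with the covariates (constant within strata) or if
    fewer than 3 residual degrees of freedom remain.
    """
    dosage = np.asarray(dosage, dtype=float)
    expression = np.asarray(expression, dtype=float)
    keep = ~(np.isnan(dosage) | np.isnan(expression))
    dosage, expression = dosage[keep], expression[keep]
    n = dosage.size
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)[keep]
        if C.ndim == 1:
            C = np.column_stack([np.ones(n), C])
        elif not np.allclose(C[:, 0], 1.0):
            C = np.column_stack([np.ones(n), C])
    p_params = C.shape[1] + 1
    if n < p_params + 3:
        raise ValueError(f"need at least {p_params + 3} samples, got {n}")
    Q, _ = np.linalg.qr(C)
    xr = _residualize(dosage, Q)
    yr = _residualize(expression, Q)
    sxx = float(xr @ xr)
    if sxx <= 1e-12 * max(1.0, float(dosage @ dosage)):
        raise ValueError("dosage is collinear with the covariates")
    beta = float(xr @ yr) / sxx
    df = n - p_params
    rss = float(yr @ yr) - beta * beta * sxx
    rss = max(rss, 0.0)
    se = np.sqrt(rss / df / sxx)
    if se == 0:
        return beta, float("inf") if beta != 0 else 0.0, 0.0 if beta != 0 else 1.0
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, float(t), float(p)


def classify_cis_trans(
    variant_chrom: str, variant_pos: int, feature_chrom: str, anchor_pos: int
) -> str:
    """cis iff same chromosome and |variant - anchor| <= 1 Mb (inclusive)."""
    if variant_chrom == feature_chrom and abs(variant_pos - anchor_pos) <= CIS_WINDOW:
        return "cis"
    return "trans"


def scan(
    matrix: GenotypeMatrix,
    expression: ExpressionMatrix,
    panel: PopulationPanel,
    use_covariate: bool = True,
) -> pd.DataFrame:
    """All-pairs variant x feature association scan on the shared samples.

    Returns the full record table (variant_key, feature, beta, tstat, p,
    kind) before thresholding; pass it to :func:`threshold_and_fdr`.
    Variants whose dosage is missing in any analyzed sample or collinear
    with the covariates are skipped (their count is in ``df.attrs``).
    """
    samples = [s for s in expression.samples if s in set(matrix.sample_ids)]
    if not samples:
        raise ValueError("no overlap between expression and genotype samples")
    sub_cols = [matrix.sample_ids.index(s) for s in samples]
    dos = matrix.dosages()[:, sub_cols]
    Y = expression.values[samples].to_numpy(dtype=float)

    C = population_design(panel, samples) if use_covariate else np.ones((len(samples), 1))
    n = len(samples)
    p_params = C.shape[1] + 1
    df = n - p_params
    if df < 3:
        raise ValueError("not enough samples for the model")
    Q, _ = np.linalg.qr(C)

    complete = ~np.isnan(dos).any(axis=1)
    Xr = _residualize(dos[complete], Q)
    xnorm = np.linalg.norm(Xr, axis=1)
    scale = np.sqrt((dos[complete] ** 2).sum(axis=1))
    usable = xnorm > 1e-8 * np.maximum(1.0, scale)
    keep_idx = np.nonzero(complete)[0][usable]
    n_skipped = int(matrix.n_variants - keep_idx.size)
    Xr = Xr[usable]
    xnorm = xnorm[usable]

    Yr = _residualize(Y, Q)
    ynorm = np.linalg.norm(Yr, axis=1)
    ysafe = np.where(ynorm > 0, ynorm, 1.0)

    R = (Xr / xnorm[:, None]) @ (Yr / ysafe[:, None]).T  # correlations
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = R * np.sqrt(df / np.maximum(1.0 - R * R, 1e-300))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta = R * (ynorm[None, :] / xnorm[:, None])

    variants = [matrix.variants[i] for i in keep_idx]
    feats = expression.features
    v_idx, f_idx = np.nonzero(np.ones_like(R, dtype=bool))
    kinds = np.empty(R.shape, dtype=object)
    for j, f in enumerate(feats):
        fc, fp = expression.anchors[f]
        for i, v in enumerate(variants):
            kinds[i, j] = classify_cis_trans(v.chrom, v.pos, fc, fp)
    out = pd.DataFrame(
        {
            "variant_key": [variants[i].key for i in v_idx],
            "variant_chrom": [variants[i].chrom for i in v_idx],
            "variant_pos": [variants[i].pos for i in v_idx],
            "feature": [feats[j] for j in f_idx],
            "beta": beta[v_idx, f_idx],
            "tstat": tstat[v_idx, f_idx],
            "p": pval[v_idx, f_idx],
            "kind": kinds[v_idx, f_idx],
        }
    )
    out.attrs["n_variants_skipped"] = n_skipped
    out.attrs["n_samples"] = n
    out.attrs["df"] = df
    return out


def threshold_and_fdr(records: pd.DataFrame) -> pd.DataFrame:
    """Pre-filter by the per-family p cutoffs, then BH-adjust per family.

    cis records with p >= 0.05 and trans records with p >= 0.01 are
    discarded before adjustment; BH runs separately on each family with m
    equal to that family's retained count; ``significant`` is FDR < 0.05.
    """
    parts = []
    for kind, cutoff in (("cis", CIS_P_CUTOFF), ("trans", TRANS_P_CUTOFF)):
        fam = records[(records["kind"] == kind) & (records["p"] < cutoff)].copy()
        if fam.empty:
            continue
        p = fam["p"].to_numpy()
        m = p.size
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        fam["fdr"] = np.minimum(adj, 1.0)
        fam["significant"] = fam["fdr"] < FDR_CUTOFF
        parts.append(fam)
    if not parts:
        return records.iloc[0:0].assign(fdr=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    return pd.concat(parts, ignore_index=True)


def hotspot_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variant counts of significantly regulated features, cis and trans,
    sorted by descending trans count (hub variants first)."""
    sig = records[records["significant"]] if "significant" in records else records.iloc[0:0]
    if sig.empty:
        return pd.DataFrame(columns=["variant_key", "n_cis", "n_trans"])
    tab = (
        sig.pivot_table(
            index="variant_key", columns="kind", values="feature", aggfunc="count", fill_value=0
        )
        .reindex(columns=["cis", "trans"], fill_value=0)
        .rename(columns={"cis": "n_cis", "trans": "n_trans"})
    )
    tab.columns.name = None
    return tab.sort_values(["n_trans", "n_cis"], ascending=False).reset_index()


def transcription_ratios(
    values: pd.DataFrame, feature_gene: dict[str, str]
) -> pd.DataFrame:
    """Per-sample ratio of each feature to the summed features of its gene.

    A sample whose gene-total is zero gets NaN for that gene's ratios
    (dropped downstream for that feature), guarding the division.
    """
    genes = pd.Series(feature_gene).reindex(values.index)
    totals = values.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = values / totals.where(totals != 0)
    return ratios
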