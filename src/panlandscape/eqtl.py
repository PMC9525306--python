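"""SV-expression association with LD-block pruning and cis/trans calls.

The association model is the MatrixEQTL-style covariate-adjusted linear
regression: per gene, expression values are rank-normalized to standard
normal quantiles, both expression and SV genotype dosages are residualized
on the covariate matrix (plus intercept), and each (SV, gene) pair is
scored by the t-test on the genotype coefficient with the residual degrees
of freedom reduced by the covariates.  Multiple testing is controlled by
Benjamini-Hochberg.  eQTL blocks for one gene are pruned greedily by
ascending p-value at a background LD threshold (r^2 = 0.11, the plateau of
the LD decay curve for deletions/insertions), and hits are classified cis
when the SV lies within the gene or less than 2 kb from either gene end.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

FPKM_MIN_MEAN = 0.1


def rank_normalize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Map values to standard-normal quantiles of their ranks.

    Uses the Blom offset (r - 3/8) / (n + 1/4), the convention of R's
    qqnorm for n <= 10 and an excellent approximation above; ties receive
    averaged ranks.  A constant vector maps to all zeros (with a warning).
    Requires at least 3 non-missing values.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        raise ConfigError("rank normalization needs >= 3 non-missing values")
    out = np.full_like(v, np.nan)
    sub = v[finite]
    if np.all(sub == sub[0]):
        warnings.warn("constant vector; rank-normalized to zeros")
        out[finite] = 0.0
        return out
    ranks = stats.rankdata(sub, method="average")
    out[finite] = stats.norm.ppf((ranks - 0.375) / (len(sub) + 0.25))
    return out


def filter_expression(expression: pd.DataFrame, fpkm_min: float = FPKM_MIN_MEAN) -> pd.DataFrame:
    """Keep genes whose mean FPKM exceeds the floor, then rank-normalize
    each gene's values."""
    kept = expression[expression.mean(axis=1) > fpkm_min]
    return kept.apply(lambda row: pd.Series(rank_normalize(row), index=row.index), axis=1)


def filter_genotypes(
    genotypes: pd.DataFrame, maf_min: float = 0.05, max_missing: float = 0.1
) -> pd.DataFrame:
    """Keep SVs with allele frequency in [maf_min, 1 - maf_min] and a
    missing-call rate at most max_missing."""
    g = genotypes.to_numpy(dtype=float)
    missing_rate = np.mean(~np.isfinite(g), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        freq = np.nanmean(g, axis=1)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (missing_rate <= max_missing) & (maf >= maf_min)
    return genotypes[keep]


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of the rows of y against covariate columns (incl. intercept)."""
    q, _ = np.linalg.qr(covariates)
    return y - (y @ q) @ q.T


def associate(
    sv_genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    max_missing: float = 0.1,
    alpha: float = 0.05,
    rank_transform: bool = True,
    fpkm_min: float = FPKM_MIN_MEAN,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Score all (SV, gene) pairs by covariate-adjusted linear regression.

    ``sv_genotypes`` is SV x accession dosages (NaN = missing call,
    mean-imputed after filtering), ``expression`` gene x accession FPKM
    (or pre-transformed values with ``rank_transform=False``), and
    ``covariates`` accession x k.  Returns one row per pair with beta,
    p_value, the BH-adjusted p and a significance flag at ``alpha``.
    """
    accs = list(expression.columns)
    if list(sv_genotypes.columns) != accs:
        sv_genotypes = sv_genotypes[accs]
    if not prefiltered:
        sv_genotypes = filter_genotypes(sv_genotypes, maf_min, max_missing)
        if rank_transform:
            expression = filter_expression(expression, fpkm_min)
        if sv_genotypes.empty or expression.empty:
            raise ConfigError("no SVs or genes survive the pre-filters")
    elif rank_transform:
        expression = expression.apply(
            lambda row: pd.Series(rank_normalize(row), index=row.index), axis=1
        )

    n = len(accs)
    if covariates is None:
        cov = np.ones((n, 1))
    else:
        cov = np.column_stack([np.ones(n), covariates.loc[accs].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cov) < cov.shape[1]:
            col_norm = np.linalg.svd(cov, compute_uv=False)
            raise ConfigError(
                f"covariate matrix is rank-deficient (rank "
                f"{np.linalg.matrix_rank(cov)} < {cov.shape[1]}; "
                f"singular values {np.round(col_norm, 6).tolist()})"
            )
    k = cov.shape[1]
    dof = n - k - 1
    if dof < 1:
        raise ConfigError("not enough accessions for the covariate model")

    g = sv_genotypes.to_numpy(dtype=float)
    g = np.where(np.isfinite(g), g, np.nanmean(g, axis=1, keepdims=True))
    e = expression.to_numpy(dtype=float)
    gr = _residualize(g, cov)
    er = _residualize(e, cov)
    g_ss = (gr**2).sum(axis=1)
    e_ss = (er**2).sum(axis=1)
    cross = gr @ er.T  # (n_sv, n_gene)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = cross / g_ss[:, None]
        r = cross / np.sqrt(np.outer(g_ss, e_ss))
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(dof / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), dof)

    sv_ids = np.repeat(sv_genotypes.index.to_numpy(), len(expression))
    gene_ids = np.tile(expression.index.to_numpy(), len(sv_genotypes))
    hits = pd.DataFrame(
        {
            "sv_id": sv_ids,
            "gene_id": gene_ids,
            "beta": beta.ravel(),
            "t_stat": t.ravel(),
            "p_value": p.ravel(),
        }
    )
    hits["adj_p"] = multipletests(hits["p_value"].to_numpy(), method="fdr_bh")[1]
    hits["significant"] = hits["adj_p"] <= alpha
    return hits.sort_values(["p_value", "sv_id", "gene_id"]).reset_index(drop=True)


def genotype_r2(
    genotypes: pd.DataFrame, sv_a: str, sv_b: str
) -> float:
    """Squared Pearson correlation of two SVs' dosages on pairwise-complete
    accessions.  Returns NaN when fewer than two complete pairs exist or a
    dosage vector is constant."""
    a = genotypes.loc[sv_a].to_numpy(dtype=float)
    b = genotypes.loc[sv_b].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2 or np.all(a[ok] == a[ok][0]) or np.all(b[ok] == b[ok][0]):
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1] ** 2)


def prune_linked(
    hits: pd.DataFrame,
    genotypes: pd.DataFrame,
    r2_background: float = 0.11,
) -> pd.DataFrame:
    """Greedy LD-block pruning of eQTL hits per gene.

    Within each gene's hits, visited in ascending p-value (ties by sv_id),
    a hit is retained iff its genotype r^2 with every already-retained hit
    for that gene is at most ``r2_background``; otherwise the earlier
    (smaller-p) hit represents the block.  Pairs with no computable r^2
    are treated as unlinked with a warning.  Adds a boolean ``retained``
    column.
    """
    out = hits.copy()
    out["retained"] = False
    for gene_id, grp in out.groupby("gene_id", sort=False):
        grp = grp.sort_values(["p_value", "sv_id"], kind="mergesort")
        retained: list[str] = []
        for idx, row in grp.iterrows():
            linked = False
            for kept_sv in retained:
                r2 = genotype_r2(genotypes, row["sv_id"], kept_sv)
                if not np.isfinite(r2):
                    warnings.warn(
                        f"no genotype overlap for r2({row['sv_id']}, {kept_sv}); "
                        "treated as unlinked"
                    )
                    continue
                if r2 > r2_background:
                    linked = True
                    break
            if not linked:
                retained.append(row["sv_id"])
                out.loc[idx, "retained"] = True
    return out


def classify_cis(
    hits: pd.DataFrame,
    sv_coords: Mapping[str, tuple[str, int, int]],
    gene_coords: Mapping[str, tuple[str, int, int]],
    flank: int = 2_000,
) -> pd.DataFrame:
    """Label each hit cis or trans.

    A hit is cis iff its SV interval intersects the gene body or lies
    strictly closer than ``flank`` bp to either gene end (both coordinate
    maps are 0-based half-open (chrom, start, end) on the shared
    reference).  Missing gene coordinates raise :class:`ConfigError`.
    """
    classes = []
    for _, row in hits.iterrows():
        if row["gene_id"] not in gene_coords:
            raise ConfigError(f"gene {row['gene_id']!r} has no coordinates")
        if row["sv_id"] not in sv_coords:
            raise ConfigError(f"SV {row['sv_id']!r} has no coordinates")
        s_chrom, s_start, s_end = sv_coords[row["sv_id"]]
        g_chrom, g_start, g_end = gene_coords[row["gene_id"]]
        if s_chrom != g_chrom:
            classes.append("trans")
            continue
        gap = max(g_start - s_end, s_start - g_end, 0)
        classes.append("cis" if gap < flank else "trans")
    out = hits.copy()
    out["class"] = classes
    return out
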