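"""Weir-Cockerham FST and Dxy divergence scans between two populations.

The FST estimator is the Weir & Cockerham (1984) variance-components form
specialized to haploid calls (inbred rice accessions are treated as one
haplotype each): for two populations with sample sizes n1, n2 and allele
frequencies p1, p2,

    n_bar = (n1 + n2) / 2
    n_c   = (n1 + n2 - (n1^2 + n2^2)/(n1 + n2))
    p_bar = (n1 p1 + n2 p2) / (n1 + n2)
    s^2   = [n1 (p1 - p_bar)^2 + n2 (p2 - p_bar)^2] / n_bar
    a = (n_bar / n_c) * (s^2 - (p_bar (1 - p_bar) - s^2 / 2) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar (1 - p_bar) - s^2 / 2)

with per-site FST = a / (a + b).  Windowed FST uses the ratio of sums
(sum of a over sum of a + b), the recommended multi-site combination;
negative per-site values are retained.  Dxy is the absolute divergence
per bp: the window sum of p1 (1 - p2) + p2 (1 - p1) divided by window
length.  Windows default to non-overlapping 20 kb tiles; the top 5% of
windows per statistic are called highly divergent regions.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "fst_components",
    "fst_per_site",
    "windowed_fst",
    "windowed_dxy",
    "divergence_windows",
    "top_divergent_regions",
]


def _pop_freqs(
    haplotypes: np.ndarray, pop_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site non-missing sample sizes and allele-1 frequencies for the
    two populations.  Missing calls are encoded as negative values."""
    h = np.asarray(haplotypes)
    labels = np.asarray(pop_labels)
    pops = np.unique(labels)
    if len(pops) != 2:
        raise ConfigError("exactly two populations are required")
    out = []
    for p in pops:
        sub = h[labels == p]
        valid = sub >= 0
        n = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(valid, sub, 0).sum(axis=0) / np.where(n > 0, n, 1)
        out.append((n, freq))
    (n1, p1), (n2, p2) = out
    return n1, p1, n2, p2


def fst_components(
    n1: np.ndarray, p1: np.ndarray, n2: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham haploid variance components (a, b) per site.

    a is the between-population component, b the within-population
    component; both are zero at monomorphic sites.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n_tot = n1 + n2
    n_bar = n_tot / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = n_tot - (n1**2 + n2**2) / n_tot
        p_bar = (n1 * p1 + n2 * p2) / n_tot
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        inner = p_bar * (1.0 - p_bar) - s2 / 2.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * inner
    return a, b


def fst_per_site(
    haplotypes: np.ndarray, pop_labels: np.ndarray
) -> pd.DataFrame:
    """Per-site W&C components and ratio for a haplotype matrix.

    ``haplotypes`` is (n_hap, n_sites) with 0/1 calls (negative = missing).
    Sites monomorphic across both populations get components (0, 0) and an
    undefined (NaN) ratio; they are excluded from per-site averages but
    still contribute (zero) to windowed ratio-of-sums.  Sites with fewer
    than two non-missing calls in either population are also undefined.
    """
    n1, p1, n2, p2 = _pop_freqs(haplotypes, pop_labels)
    a, b = fst_components(n1, p1, n2, p2)
    usable = (n1 >= 2) & (n2 >= 2)
    n_tot = np.where(n1 + n2 > 0, n1 + n2, 1)
    p_all = (n1 * p1 + n2 * p2) / n_tot
    poly = (p_all > 0) & (p_all < 1)
    a = np.where(usable & poly, a, 0.0)
    b = np.where(usable & poly, b, 0.0)
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom != 0, a / denom, np.nan)
    ratio = np.where(usable & poly, ratio, np.nan)
    return pd.DataFrame({"a": a, "b": b, "fst": ratio})


def _dxy_site_terms(haplotypes: np.ndarray, pop_labels: np.ndarray) -> np.ndarray:
    _, p1, _, p2 = _pop_freqs(haplotypes, pop_labels)
    return p1 * (1.0 - p2) + p2 * (1.0 - p1)


def divergence_windows(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    pop_labels: np.ndarray,
    region_length: int | None = None,
    window: int = 20_000,
    step: int | None = None,
    chrom: str = "chr01",
) -> pd.DataFrame:
    """Windowed FST (ratio of sums) and Dxy over one region.

    ``positions`` are 1-based bp.  ``step`` defaults to ``window``
    (non-overlapping tiles); a smaller step yields sliding windows with
    each site contributing to every window covering it.  Windows with no
    usable polymorphic site report FST as NaN; Dxy divides by the window
    span in bp so invariant sites contribute zero.
    """
    if window <= 0:
        raise ConfigError("window length must be positive")
    step = window if step is None else step
    if not 0 < step <= window:
        raise ConfigError("need 0 < step <= window")
    positions = np.asarray(positions)
    if len(positions) and np.any(np.diff(positions) < 0):
        warnings.warn("positions were unsorted; sorting internally")
        order = np.argsort(positions, kind="mergesort")
        positions = positions[order]
        haplotypes = np.asarray(haplotypes)[:, order]
    if region_length is None:
        region_length = int(positions.max()) if len(positions) else window
    site = fst_per_site(haplotypes, pop_labels)
    dxy_terms = _dxy_site_terms(haplotypes, pop_labels)
    pos0 = positions - 1  # to 0-based

    rows = []
    start = 0
    while start < region_length:
        end = min(start + window, region_length)
        in_win = (pos0 >= start) & (pos0 < end)
        a_sum = site["a"].to_numpy()[in_win].sum()
        ab_sum = (site["a"] + site["b"]).to_numpy()[in_win].sum()
        n_usable = int(np.isfinite(site["fst"].to_numpy()[in_win]).sum())
        fst = a_sum / ab_sum if ab_sum != 0 else np.nan
        dxy = dxy_terms[in_win].sum() / (end - start)
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "fst": fst,
                "dxy": dxy,
                "n_sites": int(in_win.sum()),
                "n_usable_sites": n_usable,
            }
        )
        if end >= region_length:
            break
        start += step
    return pd.DataFrame(rows)


def windowed_fst(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    pop_labels: np.ndarray,
    region_length: int | None = None,
    window: int = 20_000,
    step: int | None = None,
) -> pd.DataFrame:
    """Windowed ratio-of-sums Weir-Cockerham FST (see
    :func:`divergence_windows`)."""
    return divergence_windows(
        haplotypes, positions, pop_labels, region_length, window, step
    )[["chrom", "start", "end", "fst", "n_sites", "n_usable_sites"]]


def windowed_dxy(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    pop_labels: np.ndarray,
    region_length: int | None = None,
    window: int = 20_000,
    step: int | None = None,
) -> pd.DataFrame:
    """Windowed absolute divergence per bp (see :func:`divergence_windows`)."""
    return divergence_windows(
        haplotypes, positions, pop_labels, region_length, window, step
    )[["chrom", "start", "end", "dxy", "n_sites"]]


def top_divergent_regions(
    windows: pd.DataFrame,
    statistic: str = "fst",
    frac: float = 0.05,
) -> pd.DataFrame:
    """Call the top fraction of windows by a statistic and merge them.

    Exactly ``floor(frac * n_defined)`` windows with a defined value are
    selected; ties at the cutoff resolve by genomic (chrom, start) order.
    Adjacent or overlapping selected windows merge into regions.  Returns
    a BED-like frame (chrom, start, end, n_windows, peak_value).
    """
    if statistic not in windows.columns:
        raise ConfigError(f"unknown statistic {statistic!r}")
    defined = windows[np.isfinite(windows[statistic])]
    if len(defined) == 0:
        warnings.warn("statistic undefined in every window; empty result")
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows", "peak_value"])
    if len(defined) < 20:
        raise ConfigError("need at least 20 windows with defined values")
    if defined[statistic].nunique() == 1:
        warnings.warn("statistic constant across windows; selecting by genomic order")
    quota = int(np.floor(frac * len(defined)))
    ranked = defined.sort_values(
        [statistic, "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    flagged = ranked.head(quota).sort_values(["chrom", "start"])
    regions = []
    for chrom, grp in flagged.groupby("chrom", sort=True):
        cur = None
        for _, row in grp.iterrows():
            if cur is None or row["start"] > cur["end"]:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "n_windows": 1,
                    "peak_value": float(row[statistic]),
                }
            else:
                cur["end"] = max(cur["end"], int(row["end"]))
                cur["n_windows"] += 1
                cur["peak_value"] = max(cur["peak_value"], float(row[statistic]))
        if cur is not None:
            regions.append(cur)
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows", "peak_value"])
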