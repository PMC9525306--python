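"""Structural-variant filtering, spectra, hotspot detection and annotation.

Call-set filtering applies five rules: length bounds (50 bp to 1 Mb),
reference gap overlap, absent ("0/0") genotypes, imprecise breakpoints and
low read support (< 30).  Breakpoints are then tallied in 200 kb windows
advanced by 100 kb; the top 10% of windows are hotspot candidates, and
their excess over a matched-size uniform placement null (same number of
SVs, identical length multiset, re-placed uniformly 100 times) is scored
with a two-sided Wilcoxon rank-sum test.  SV-gene annotation categorizes
each SV as containing a gene, overlapping one, lying within a flank, or
intergenic.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ConfigError, CoordinateError
from .records import GeneRecord, HotspotRegion, SVRecord

logger = logging.getLogger(__name__)

FILTER_RULES = (
    "length_out_of_range",
    "in_reference_gap",
    "absent_genotype",
    "imprecise",
    "low_depth",
)


def _gap_trees(gaps: Iterable[tuple[str, int, int]] | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in gaps or []:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def filter_svs(
    svs: Sequence[SVRecord],
    reference_gaps: Iterable[tuple[str, int, int]] | None = None,
    min_len: int = 50,
    max_len: int = 1_000_000,
    min_depth: int = 30,
) -> tuple[list[SVRecord], dict[str, int]]:
    """Apply the five SV filtering rules.

    A record is kept iff it violates none of:

    1. svlen outside [min_len, max_len];
    2. overlap with a reference assembly gap (BED, half-open);
    3. no non-reference genotype call ("0/0" everywhere);
    4. imprecise breakpoints;
    5. read support below min_depth.

    Returns the kept records and a per-rule rejection counter; a record
    failing several rules increments each.  Records missing the depth or
    precision tag are rejected under the corresponding rule and counted
    separately under a ``*_missing`` key.
    """
    trees = _gap_trees(reference_gaps)
    kept: list[SVRecord] = []
    counts: Counter[str] = Counter({rule: 0 for rule in FILTER_RULES})
    for sv in svs:
        failed = []
        if sv.svlen < min_len or sv.svlen > max_len:
            failed.append("length_out_of_range")
        tree = trees.get(sv.chrom)
        if tree is not None and tree.overlap(sv.pos - 1, max(sv.end, sv.pos)):
            failed.append("in_reference_gap")
        if sv.genotypes is None:
            warnings.warn(f"SV {sv.sv_id}: missing genotypes; rejected")
            failed.append("absent_genotype")
            counts["absent_genotype_missing"] += 1
        elif not any(g == 1 for g in sv.genotypes.values()):
            failed.append("absent_genotype")
        if sv.precise is None:
            warnings.warn(f"SV {sv.sv_id}: missing precision tag; rejected")
            failed.append("imprecise")
            counts["imprecise_missing"] += 1
        elif not sv.precise:
            failed.append("imprecise")
        if sv.support_depth is None:
            warnings.warn(f"SV {sv.sv_id}: missing read depth; rejected")
            failed.append("low_depth")
            counts["low_depth_missing"] += 1
        elif sv.support_depth < min_depth:
            failed.append("low_depth")
        if failed:
            counts.update(failed)
        else:
            kept.append(sv)
    return kept, dict(counts)


# ---------------------------------------------------------------------------
# Size / frequency spectrum


def sv_spectrum(svs: Sequence[SVRecord]) -> dict[str, float | int]:
    """Length and allele-frequency summary of a call set.

    MAF is min(f, 1-f) with f the carrier fraction over non-missing
    accessions (haploid presence convention).  SVs with all genotypes
    missing are excluded from frequency statistics and counted.
    """
    if not svs:
        return {"n_svs": 0}
    lengths = np.array([sv.svlen for sv in svs])
    mafs, n_carriers, n_missing_all = [], [], 0
    for sv in svs:
        genos = [g for g in (sv.genotypes or {}).values() if g is not None]
        if not genos:
            n_missing_all += 1
            continue
        f = sum(genos) / len(genos)
        mafs.append(min(f, 1.0 - f))
        n_carriers.append(sum(genos))
    mafs_arr = np.array(mafs)
    carriers_arr = np.array(n_carriers)
    out: dict[str, float | int] = {
        "n_svs": len(svs),
        "frac_lt_1kb": float((lengths < 1_000).mean()),
        "n_excluded_missing": n_missing_all,
    }
    if len(mafs_arr):
        out["frac_maf_lt_005"] = float((mafs_arr < 0.05).mean())
        out["frac_shared_ge2"] = float((carriers_arr >= 2).mean())
        out["maf_hist"], out["maf_bin_edges"] = [
            x.tolist() for x in np.histogram(mafs_arr, bins=10, range=(0, 0.5))
        ]
    return out


# ---------------------------------------------------------------------------
# Windowed breakpoint counts


def make_windows(
    chrom_lengths: Mapping[str, int], window: int = 200_000, step: int = 100_000
) -> pd.DataFrame:
    """Tile each chromosome with half-open windows of ``window`` bp
    advanced by ``step`` bp; a trailing partial window covers any
    remainder."""
    if not (window >= step > 0):
        raise ConfigError("need window >= step > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        length = int(length)
        if length <= window:
            rows.append((chrom, 0, length))
            continue
        start = 0
        while start + window <= length:
            rows.append((chrom, start, start + window))
            start += step
        last_end = rows[-1][2]
        if last_end < length:
            rows.append((chrom, start, length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _count_in_windows(windows: pd.DataFrame, breakpoints: Mapping[str, np.ndarray]) -> np.ndarray:
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, grp in windows.groupby("chrom", sort=False):
        b = np.sort(breakpoints.get(chrom, np.array([], dtype=np.int64)))
        lo = np.searchsorted(b, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(b, grp["end"].to_numpy(), side="left")
        counts[grp.index.to_numpy()] = hi - lo
    return counts


def window_breakpoint_counts(
    svs: Sequence[SVRecord],
    chrom_lengths: Mapping[str, int],
    window: int = 200_000,
    step: int = 100_000,
) -> pd.DataFrame:
    """Count SV breakpoints per sliding window.

    INS and TRA contribute one breakpoint (pos); DEL, INV and DUP
    contribute both interval ends.  A breakpoint falling in the overlap of
    two windows increments both.  Returns a frame with columns
    chrom, start, end, count (coordinates 0-based half-open).
    """
    windows = make_windows(chrom_lengths, window, step)
    per_chrom: dict[str, list[int]] = {}
    for sv in svs:
        if sv.chrom not in chrom_lengths:
            raise CoordinateError(f"SV {sv.sv_id}: unknown chromosome {sv.chrom!r}")
        length = int(chrom_lengths[sv.chrom])
        for bp in sv.breakpoints:
            if not 1 <= bp <= length:
                raise CoordinateError(
                    f"SV {sv.sv_id}: breakpoint {bp} beyond chromosome end ({length})"
                )
            per_chrom.setdefault(sv.chrom, []).append(bp - 1)
    arrays = {c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()}
    windows = windows.copy()
    windows["count"] = _count_in_windows(windows, arrays)
    return windows


# ---------------------------------------------------------------------------
# Hotspots


def detect_hotspots(window_stats: pd.DataFrame, top_frac: float = 0.10) -> list[HotspotRegion]:
    """Flag the top fraction of windows by breakpoint count and merge them.

    Exactly ``floor(top_frac * n_windows)`` windows are flagged; ties at
    the cutoff are resolved deterministically by (chrom, start) order.
    Zero-count windows are never flagged; if all counts are zero the
    result is empty (with a warning).  Overlapping or adjacent flagged
    windows merge into hotspot regions.
    """
    n_windows = len(window_stats)
    if n_windows < 10:
        raise ConfigError("hotspot detection needs at least 10 windows")
    if (window_stats["count"] == 0).all():
        warnings.warn("all window counts are zero; no hotspots")
        return []
    quota = int(np.floor(top_frac * n_windows))
    ranked = window_stats.sort_values(
        ["count", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    flagged = ranked.head(quota)
    flagged = flagged[flagged["count"] > 0]
    regions: list[HotspotRegion] = []
    for chrom, grp in flagged.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        cur_n = cur_peak = 0
        for _, row in grp.iterrows():
            if cur_start is None or row["start"] > cur_end:
                if cur_start is not None:
                    regions.append(HotspotRegion(chrom, cur_start, cur_end, cur_n, cur_peak))
                cur_start, cur_end = int(row["start"]), int(row["end"])
                cur_n, cur_peak = 1, int(row["count"])
            else:
                cur_end = max(cur_end, int(row["end"]))
                cur_n += 1
                cur_peak = max(cur_peak, int(row["count"]))
        if cur_start is not None:
            regions.append(HotspotRegion(chrom, cur_start, cur_end, cur_n, cur_peak))
    return sorted(regions, key=lambda r: (r.chrom, r.start))


def simulate_matched_null(
    svs: Sequence[SVRecord],
    chrom_lengths: Mapping[str, int],
    n_sim: int = 100,
    seed: int = 0,
    window: int = 200_000,
    step: int = 100_000,
    reference_gaps: Iterable[tuple[str, int, int]] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Matched-size uniform placement null for hotspot testing.

    Each replicate places the same number of SVs, with the identical
    length and type multiset, at uniform random positions on the reference
    (per-chromosome probability proportional to placeable length,
    rejecting positions inside declared gap intervals), then counts
    breakpoints per window exactly like the observed set.  Returns the
    window tiling and an (n_sim, n_windows) count matrix.
    """
    if not svs:
        raise ConfigError("matched null needs a non-empty SV set")
    rng = np.random.default_rng(seed)
    windows = make_windows(chrom_lengths, window, step)
    chroms = list(chrom_lengths)
    lengths = np.array([int(chrom_lengths[c]) for c in chroms], dtype=np.int64)
    sv_lens = np.array([sv.svlen for sv in svs], dtype=np.int64)
    two_break = np.array([sv.svtype not in ("INS", "TRA") for sv in svs])
    span = np.where(two_break, sv_lens, 1)
    if span.max() > lengths.max():
        raise CoordinateError("an SV is longer than every chromosome")
    gap_trees = _gap_trees(reference_gaps)

    counts = np.empty((n_sim, len(windows)), dtype=np.int64)
    for r in range(n_sim):
        placeable = np.maximum(lengths[None, :] - span[:, None] + 1, 0)
        probs = placeable / placeable.sum(axis=1, keepdims=True)
        cum = np.cumsum(probs, axis=1)
        chrom_idx = (cum < rng.random((len(svs), 1))).sum(axis=1)
        pos0 = (rng.random(len(svs)) * placeable[np.arange(len(svs)), chrom_idx]).astype(np.int64)
        if gap_trees:
            for i in range(len(svs)):
                tree = gap_trees.get(chroms[chrom_idx[i]])
                tries = 0
                while tree is not None and tree.overlap(pos0[i], pos0[i] + span[i]) and tries < 1000:
                    pos0[i] = rng.integers(0, placeable[i, chrom_idx[i]])
                    tries += 1
        per_chrom: dict[str, list[np.ndarray]] = {}
        for ci, chrom in enumerate(chroms):
            mask = chrom_idx == ci
            starts = pos0[mask]
            ends = starts + span[mask] - 1
            bps = np.concatenate([starts, ends[two_break[mask]]])
            per_chrom[chrom] = [bps]
        arrays = {c: np.concatenate(v) for c, v in per_chrom.items()}
        counts[r] = _count_in_windows(windows, arrays)
    return windows, counts


def hotspot_significance(
    observed: pd.DataFrame, null_counts: np.ndarray, null_windows: pd.DataFrame | None = None
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for observed vs simulated
    per-window breakpoint counts (simulated replicates pooled)."""
    if len(observed) < 2:
        raise ConfigError("hotspot significance is undefined for a single window")
    if null_windows is not None:
        same = (
            len(null_windows) == len(observed)
            and (null_windows[["chrom", "start", "end"]].to_numpy()
                 == observed[["chrom", "start", "end"]].to_numpy()).all()
        )
        if not same:
            raise ConfigError("observed and null window tilings differ")
    obs = observed["count"].to_numpy(dtype=float)
    null = np.asarray(null_counts, dtype=float).ravel()
    return float(stats.ranksums(obs, null).pvalue)


# ---------------------------------------------------------------------------
# SV-gene annotation

SV_GENE_CATEGORIES = ("contains-gene", "overlaps-gene", "within-flank", "intergenic")


def annotate_sv_gene(
    svs: Sequence[SVRecord],
    genes: Sequence[GeneRecord],
    flank: int = 2_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Categorize SV-gene relationships and flag flanked genes.

    Per SV: ``contains-gene`` if the SV interval covers both endpoints of
    some gene; else ``overlaps-gene`` on any intersection with a gene
    body; else ``within-flank`` on intersection with a +/- ``flank`` bp
    extension only; else ``intergenic``.  Per gene: flanked iff any SV
    intersects the gene body or its flanks.
    """
    if flank < 0:
        raise ConfigError("flank must be >= 0")
    body_trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        body_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, i)
    sv_rows = []
    flanked = np.zeros(len(genes), dtype=bool)
    for sv in svs:
        s0, e0 = sv.pos - 1, max(sv.end, sv.pos)
        tree = body_trees.get(sv.chrom)
        category = "intergenic"
        if tree is not None:
            body_hits = tree.overlap(s0, e0)
            flank_hits = tree.overlap(s0 - flank, e0 + flank)
            for iv in flank_hits:
                flanked[iv.data] = True
            if any(s0 <= iv.begin and iv.end <= e0 for iv in body_hits):
                category = "contains-gene"
            elif body_hits:
                category = "overlaps-gene"
            elif flank_hits:
                category = "within-flank"
        sv_rows.append({"sv_id": sv.sv_id, "category": category})
    gene_df = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "flanked_by_sv": flanked}
    )
    return pd.DataFrame(sv_rows), gene_df
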