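"""Collinear locus inference over pan-genome graph bubbles.

A bubble is a locus where paths diverge in the pan-genome graph; each
accession's path through it carries an interval on the accession's own
contig plus the bubble's projection on the reference coordinate backbone.
Features (NLR singletons/pairs/clusters, genes) are intersected with
bubbles on the accession's coordinates, projected to backbone coordinates,
and clustered by single-linkage interval overlap into collinear loci.
Two same-accession singleton features sharing one bubble are disambiguated
by moving the lexicographically larger feature to a new locus exactly 1 bp
away; loci retaining a single member are excluded from the final table.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataIntegrityError
from .records import LocusAssignment

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["feature_id", "accession", "category", "contig", "start", "end"]


def resolve_pan_coordinates(bubbles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill in backbone coordinates of uncalled bubbles; drop orphans.

    A bubble row with missing pan coordinates is interpolated linearly (in
    backbone bp) between the nearest two collinear bubbles on the same
    accession contig.  Rows with no called flanking bubble on both sides
    are dropped as non-collinear.  Called rows of one bubble id must agree
    on their backbone location, else :class:`DataIntegrityError`.
    Returns (resolved, dropped).
    """
    df = bubbles.copy()
    for col in ("pan_start", "pan_end"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    called = df.dropna(subset=["pan_start", "pan_end"])
    span = called.groupby("bubble_id")[["pan_chrom", "pan_start", "pan_end"]].nunique()
    bad = span[(span > 1).any(axis=1)].index.tolist()
    if bad:
        raise DataIntegrityError(f"inconsistent pan coordinates for bubbles: {bad}")

    resolved_rows, dropped_rows = [], []
    for (_, _), grp in df.groupby(["accession", "contig"], sort=False):
        grp = grp.sort_values("contig_start").reset_index(drop=True)
        known = grp["pan_start"].notna().to_numpy()
        idx_known = np.where(known)[0]
        for i in range(len(grp)):
            row = grp.loc[i]
            if known[i]:
                resolved_rows.append(row)
                continue
            left = idx_known[idx_known < i]
            right = idx_known[idx_known > i]
            if len(left) == 0 or len(right) == 0:
                dropped_rows.append(row)
                continue
            lo, hi = grp.loc[left[-1]], grp.loc[right[0]]
            if lo["pan_chrom"] != hi["pan_chrom"]:
                dropped_rows.append(row)
                continue
            # linear interpolation in contig position between the flanks
            denom = hi["contig_start"] - lo["contig_start"]
            t = 0.5 if denom == 0 else (row["contig_start"] - lo["contig_start"]) / denom
            width = row["contig_end"] - row["contig_start"]
            pan_start = int(round(lo["pan_end"] + t * (hi["pan_start"] - lo["pan_end"])))
            row = row.copy()
            row["pan_chrom"] = lo["pan_chrom"]
            row["pan_start"] = pan_start
            row["pan_end"] = pan_start + max(width, 1)
            resolved_rows.append(row)
    resolved = pd.DataFrame(resolved_rows).reset_index(drop=True)
    dropped = pd.DataFrame(dropped_rows).reset_index(drop=True)
    if len(dropped):
        logger.warning("dropped %d non-collinear bubble rows", len(dropped))
    resolved[["pan_start", "pan_end"]] = resolved[["pan_start", "pan_end"]].astype(np.int64)
    return resolved, dropped


def overlap_features_with_bubbles(
    features: pd.DataFrame,
    bubbles: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect features with bubbles on each accession's own coordinates.

    ``features`` columns: feature_id, accession, category, contig, start,
    end (0-based half-open on the accession assembly).  ``bubbles`` is a
    bubble table (see :data:`panlandscape.io.BUBBLE_COLUMNS`); uncalled
    bubbles are interpolated first.  Returns the (feature, bubble) overlap
    table with backbone coordinates attached, and the unplaced features
    (contig absent from the accession's bubble table).
    """
    missing = set(FEATURE_COLUMNS) - set(features.columns)
    if missing:
        raise DataIntegrityError(f"feature table missing columns: {sorted(missing)}")
    resolved, _ = resolve_pan_coordinates(bubbles)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for i, row in resolved.iterrows():
        key = (row["accession"], row["contig"])
        trees.setdefault(key, IntervalTree()).addi(
            int(row["contig_start"]), int(row["contig_end"]), i
        )
    hits, unplaced = [], []
    for _, f in features.iterrows():
        tree = trees.get((f["accession"], f["contig"]))
        if tree is None:
            unplaced.append(f)
            continue
        overlaps = tree.overlap(int(f["start"]), int(f["end"]))
        if not overlaps:
            unplaced.append(f)
            continue
        for iv in sorted(overlaps):
            b = resolved.loc[iv.data]
            hits.append(
                {
                    "feature_id": f["feature_id"],
                    "accession": f["accession"],
                    "category": f["category"],
                    "bubble_id": b["bubble_id"],
                    "pan_chrom": b["pan_chrom"],
                    "pan_start": int(b["pan_start"]),
                    "pan_end": int(b["pan_end"]),
                }
            )
    hit_df = pd.DataFrame(
        hits,
        columns=["feature_id", "accession", "category", "bubble_id", "pan_chrom", "pan_start", "pan_end"],
    )
    unplaced_df = pd.DataFrame(unplaced).reset_index(drop=True)
    return hit_df, unplaced_df


def _apply_singleton_tiebreak(table: pd.DataFrame) -> pd.DataFrame:
    """If two same-accession singleton features share a bubble, keep the
    lexicographically smaller feature id there and move the others to a
    point locus exactly 1 bp beyond the bubble's backbone end."""
    out = table.copy()
    singles = out[out["category"] == "singleton"]
    for (_, _), grp in singles.groupby(["accession", "bubble_id"], sort=False):
        feats = sorted(grp["feature_id"].unique())
        for offset, feat in enumerate(feats[1:], start=1):
            mask = (out["feature_id"] == feat) & (out["accession"] == grp["accession"].iloc[0])
            new_pos = int(grp["pan_end"].max()) + offset  # 1 bp away per displaced feature
            out.loc[mask, "pan_start"] = new_pos
            out.loc[mask, "pan_end"] = new_pos
    return out


def infer_loci(
    feature_bubble_table: pd.DataFrame,
) -> tuple[list[LocusAssignment], list[tuple[str, str, str]]]:
    """Cluster backbone-projected features into collinear loci.

    Each feature's backbone span is the envelope of its overlapping
    bubbles; spans on one backbone chromosome are clustered by
    single-linkage overlap (closed intervals: any shared bp chains loci,
    mirroring interval-cluster semantics).  The same-bubble singleton
    tie-break is applied first.  Loci with >= 2 member features are
    returned; single-member loci are excluded and listed as
    (accession, feature_id, category) tuples.
    """
    if feature_bubble_table.empty:
        return [], []
    table = _apply_singleton_tiebreak(feature_bubble_table)
    spans = (
        table.groupby(["accession", "feature_id", "category"], sort=False)
        .agg(pan_chrom=("pan_chrom", "first"),
             n_chrom=("pan_chrom", "nunique"),
             pan_start=("pan_start", "min"),
             pan_end=("pan_end", "max"))
        .reset_index()
    )
    multi = spans[spans["n_chrom"] > 1]
    if len(multi):
        raise DataIntegrityError(
            f"features project to multiple backbone chromosomes: "
            f"{multi['feature_id'].tolist()}"
        )
    loci: list[LocusAssignment] = []
    excluded: list[tuple[str, str, str]] = []
    counter = 0
    for chrom, grp in spans.groupby("pan_chrom", sort=True):
        grp = grp.sort_values(["pan_start", "pan_end", "accession", "feature_id"])
        cur: list[pd.Series] = []
        cur_end = None

        def flush() -> None:
            nonlocal counter
            if not cur:
                return
            members = sorted(
                (r["accession"], r["feature_id"], r["category"]) for r in cur
            )
            if len(members) == 1:
                excluded.append(members[0])
                return
            loci.append(
                LocusAssignment(
                    locus_id=f"locus{counter:05d}",
                    pan_chrom=str(chrom),
                    pan_start=int(min(r["pan_start"] for r in cur)),
                    pan_end=int(max(r["pan_end"] for r in cur)),
                    members=members,
                )
            )
            counter += 1

        for _, row in grp.iterrows():
            if cur_end is None or row["pan_start"] > cur_end:
                flush()
                cur = [row]
                cur_end = row["pan_end"]
            else:
                cur.append(row)
                cur_end = max(cur_end, row["pan_end"])
        flush()
    return loci, excluded


def locus_copy_number(
    loci: Sequence[LocusAssignment], subpop_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per-locus, per-subpopulation mean member count.

    Accessions of a subpopulation with zero members at a locus count as 0
    in the mean, so the result reflects average copy number across the
    whole subpopulation, not just carriers.
    """
    subpops = sorted(set(subpop_of.values()))
    sizes = {sp: sum(1 for v in subpop_of.values() if v == sp) for sp in subpops}
    rows = {}
    for locus in loci:
        counts = {sp: 0 for sp in subpops}
        for acc, _, _ in locus.members:
            sp = subpop_of.get(acc)
            if sp is not None:
                counts[sp] += 1
        rows[locus.locus_id] = {
            sp: counts[sp] / sizes[sp] if sizes[sp] else float("nan") for sp in subpops
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("locus_id")


def locus_table(loci: Sequence[LocusAssignment]) -> pd.DataFrame:
    rows = []
    for locus in loci:
        for acc, feat, cat in locus.members:
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "pan_chrom": locus.pan_chrom,
                    "pan_start": locus.pan_start,
                    "pan_end": locus.pan_end,
                    "accession": acc,
                    "feature_id": feat,
                    "category": cat,
                }
            )
    return pd.DataFrame(rows)
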