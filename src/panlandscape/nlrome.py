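"""Spatial classification and summaries of the pan-NLRome.

NLRs (nucleotide-binding leucine-rich repeat immune receptors) tend to sit
in physical clusters.  Two NLRs on the same chromosome are "approaching"
when fewer than two non-NLR genes separate them in gene-rank order; the
connected components of that relation define singletons (size 1), pairs
(size 2) and clusters (size >= 3).  Pairs are further typed by strand
orientation (tail-to-head when co-directional, head-to-head when the 5'
ends face each other, tail-to-tail otherwise) and pairs/clusters by
orthogroup homogeneity.  The module also summarizes core/dispensable NLR
orthogroups per subpopulation and tests integrated-domain enrichment.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, PanlandscapeError
from .pav_core import PAVMatrix, classify_core_dispensable
from .records import GeneRecord, NLRArrangement

logger = logging.getLogger(__name__)

MAX_INTERVENING = 1  # "fewer than two non-NLR genes between any two NLRs"


def pair_orientation(a: GeneRecord, b: GeneRecord) -> str:
    """Orientation of a gene pair: T-H, H-H or T-T.

    The two genes are re-sorted by start, so the result does not depend on
    argument order.  Co-directional genes are tail-to-head; an upstream
    '-' gene followed by a '+' gene puts the two promoters (5' ends)
    adjacent, i.e. head-to-head; the converse is tail-to-tail.
    """
    if a.chrom != b.chrom:
        raise PanlandscapeError("pair orientation requires one chromosome")
    first, second = sorted((a, b), key=lambda g: (g.start, g.end, g.gene_id))
    for g in (first, second):
        if g.strand not in ("+", "-"):
            raise PanlandscapeError(f"gene {g.gene_id}: missing strand")
    if first.strand == second.strand:
        return "T-H"
    return "H-H" if first.strand == "-" else "T-T"


def group_homogeneity(group: Iterable[GeneRecord]) -> str:
    """homogeneous iff all members of a pair/cluster share one orthogroup."""
    ids = set()
    for g in group:
        if not g.orthogroup_id:
            raise PanlandscapeError(f"gene {g.gene_id}: missing orthogroup id")
        ids.add(g.orthogroup_id)
    return "homogeneous" if len(ids) == 1 else "heterogeneous"


def _sorted_chrom_genes(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    starts = [g.start for g in genes]
    if len(set(starts)) != len(starts):
        warnings.warn(
            "overlapping genes with identical starts; breaking ties by (end, gene_id)",
            stacklevel=3,
        )
    return sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))


def classify_arrangement(genes: Iterable[GeneRecord]) -> list[NLRArrangement]:
    """Classify every NLR as singleton, pair or cluster.

    Input gene records may span several accessions and chromosomes; the
    approaching relation is evaluated per (accession, chromosome) in
    gene-rank order, and groups are the connected components of its
    transitive closure.  Because any two NLRs with an NLR between them are
    chained through it, components equal the chains of consecutive
    approaching NLRs.
    """
    by_acc_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_acc_chrom.setdefault((g.accession_id, g.chrom), []).append(g)

    out: list[NLRArrangement] = []
    for (acc, chrom), chrom_genes in sorted(by_acc_chrom.items()):
        ordered = _sorted_chrom_genes(chrom_genes)
        nlr_ranks = [i for i, g in enumerate(ordered) if g.is_nlr]
        if not nlr_ranks:
            continue
        groups: list[list[int]] = [[nlr_ranks[0]]]
        for prev, cur in zip(nlr_ranks[:-1], nlr_ranks[1:]):
            if cur - prev - 1 <= MAX_INTERVENING:
                groups[-1].append(cur)
            else:
                groups.append([cur])
        for k, ranks in enumerate(groups):
            members = [ordered[r] for r in ranks]
            size = len(members)
            category = "singleton" if size == 1 else ("pair" if size == 2 else "cluster")
            group_id = f"{acc}:{chrom}:nlrgrp{k:03d}"
            orientation = None
            homogeneity = None
            if category == "pair":
                orientation = pair_orientation(members[0], members[1])
                homogeneity = group_homogeneity(members)
            elif category == "cluster":
                orientation = "".join(g.strand for g in members)
                homogeneity = group_homogeneity(members)
            for g in members:
                out.append(
                    NLRArrangement(
                        gene_id=g.gene_id,
                        category=category,
                        group_id=group_id,
                        orientation=orientation,
                        homogeneity=homogeneity,
                    )
                )
    return out


def arrangement_table(arrangements: Iterable[NLRArrangement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "category": a.category,
                "group_id": a.group_id,
                "orientation": a.orientation or "",
                "homogeneity": a.homogeneity or "",
            }
            for a in arrangements
        ]
    )


# ---------------------------------------------------------------------------
# Core/dispensable NLR summary


def core_nlr_summary(
    pav: PAVMatrix,
    nlr_orthogroups: Sequence[str],
    subpop: str,
    threshold: float = 0.95,
) -> dict[str, float | int]:
    """Core/dispensable counts and fractions for NLR orthogroups in one
    subpopulation.

    Classification applies the presence threshold within the named
    subpopulation's accessions only.  NLR orthogroups absent from every
    accession of the subpopulation are reported separately (``n_absent``);
    fractions are over the orthogroups present in the subpopulation and
    sum to 1.
    """
    accs = pav.accessions_of(subpop)
    if not accs:
        raise ConfigError(f"unknown or empty subpopulation {subpop!r}")
    nlr_in_matrix = [og for og in nlr_orthogroups if og in pav.df.index]
    if not nlr_in_matrix:
        return {"n_core": 0, "n_dispensable": 0, "n_absent": 0,
                "frac_core": float("nan"), "frac_dispensable": float("nan")}
    sub = pav.df.loc[nlr_in_matrix, accs]
    present = sub.any(axis=1)
    sub_pav = PAVMatrix(sub.loc[present], {a: subpop for a in accs})
    labels = classify_core_dispensable(sub_pav, threshold)
    n_core = int((labels == "core").sum())
    n_disp = int((labels == "dispensable").sum())
    n_present = n_core + n_disp
    return {
        "n_core": n_core,
        "n_dispensable": n_disp,
        "n_absent": int((~present).sum()),
        "frac_core": n_core / n_present if n_present else float("nan"),
        "frac_dispensable": n_disp / n_present if n_present else float("nan"),
    }


# ---------------------------------------------------------------------------
# Integrated-domain enrichment


def domain_enrichment(
    domain_counts: pd.DataFrame,
    subpop_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per-(domain, subpopulation) Wilcoxon rank-sum enrichment tests.

    ``domain_counts`` is an accession x domain table of non-negative
    integer domain counts.  For every domain and subpopulation, the
    subpopulation's per-accession counts are compared against all other
    accessions with a two-sided Wilcoxon rank-sum test; p-values are
    Benjamini-Hochberg adjusted across all tests.  The result also carries
    the per-subpopulation mean frequency z-scored across subpopulations
    (display parity with the usual heatmap).  Subpopulations with fewer
    than two accessions are skipped with a warning.
    """
    if (domain_counts.to_numpy() < 0).any():
        raise ConfigError("domain counts must be non-negative")
    subpops = sorted(set(subpop_of.get(a) for a in domain_counts.index) - {None})
    rows = []
    for sp in subpops:
        in_mask = np.array([subpop_of.get(a) == sp for a in domain_counts.index])
        if in_mask.sum() < 2:
            warnings.warn(f"subpopulation {sp!r} has < 2 accessions; tests skipped")
            continue
        for domain in domain_counts.columns:
            counts = domain_counts[domain].to_numpy(dtype=float)
            inside, outside = counts[in_mask], counts[~in_mask]
            stat, p = stats.mannwhitneyu(inside, outside, alternative="two-sided")
            rows.append({"domain": domain, "subpop": sp, "statistic": float(stat),
                         "p_value": float(p), "mean_count": float(inside.mean())})
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
    # z-score mean frequencies across subpopulations within each domain
    z = (
        result.groupby("domain")["mean_count"]
        .transform(lambda x: (x - x.mean()) / x.std(ddof=0) if x.std(ddof=0) > 0 else 0.0)
    )
    result["zscore_mean_freq"] = z
    return result
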