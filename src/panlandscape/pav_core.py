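"""Presence/absence-variation (PAV) pan-genome characterization.

The central object is the PAV matrix: a boolean orthogroup x accession
table recording whether any member gene of an orthogroup (a "non-redundant
gene" of the pan-genome) is annotated in an accession.  On top of it this
module classifies core vs dispensable orthogroups, computes pan/core
rarefaction curves over randomized accession orderings, pairwise PAV
divergence between accessions, and the four *Oryza* taxonomic levels of
gene distribution (wild/cultivated, Asian/African).
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import read_orthogroup_tsv, read_subpop_tsv

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class PAVMatrix:
    """Boolean orthogroup x accession presence table.

    ``df`` has orthogroup ids as the index and accession ids as columns.
    Every row has at least one presence (all-absent rows are dropped at
    construction).  ``subpop_of`` maps accessions to subpopulation labels;
    accessions without a label get the sentinel ``"unassigned"``.
    """

    df: pd.DataFrame
    subpop_of: dict[str, str] = field(default_factory=dict)
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ConfigError("duplicate orthogroup ids in PAV matrix")
        if self.df.columns.has_duplicates:
            raise ConfigError("duplicate accession ids in PAV matrix")
        self.df = self.df.astype(bool)
        self.subpop_of = {
            acc: self.subpop_of.get(acc, UNASSIGNED) for acc in self.df.columns
        }

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def accession_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_accessions(self) -> int:
        return self.df.shape[1]

    def accessions_of(self, subpop: str) -> list[str]:
        return [a for a in self.df.columns if self.subpop_of[a] == subpop]

    def restrict(self, orthogroups: Iterable[str]) -> "PAVMatrix":
        keep = [og for og in orthogroups if og in self.df.index]
        return PAVMatrix(self.df.loc[keep], dict(self.subpop_of))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.astype(int).to_csv(path, sep="\t", index_label="orthogroup_id")


def build_pav_matrix(
    orthogroup_table: pd.DataFrame | str | os.PathLike,
    accessions: Sequence[str] | None = None,
    subpop_of: Mapping[str, str] | str | os.PathLike | None = None,
) -> PAVMatrix:
    """Build a PAV matrix from an OrthoFinder-style orthogroup table.

    ``presence[g, a]`` is True iff the orthogroup's cell for accession
    ``a`` is non-empty.  Orthogroups present in no requested accession are
    dropped (their count is logged and kept on the result).
    """
    if not isinstance(orthogroup_table, pd.DataFrame):
        orthogroup_table = read_orthogroup_tsv(orthogroup_table)
    if accessions is None:
        accessions = list(orthogroup_table.columns)
    else:
        missing = [a for a in accessions if a not in orthogroup_table.columns]
        if missing:
            raise ConfigError(f"accessions absent from orthogroup table: {missing}")
    table = orthogroup_table[list(accessions)].fillna("")
    presence = table.apply(lambda col: col.astype(str).str.strip() != "")
    empty = ~presence.any(axis=1)
    n_dropped = int(empty.sum())
    if n_dropped:
        logger.warning("dropping %d orthogroups present in no accession", n_dropped)
    if subpop_of is not None and not isinstance(subpop_of, Mapping):
        subpop_of = read_subpop_tsv(subpop_of)
    return PAVMatrix(
        presence.loc[~empty], dict(subpop_of or {}), n_dropped_rows=n_dropped
    )


def classify_core_dispensable(pav: PAVMatrix, threshold: float = 0.95) -> pd.Series:
    """Label each orthogroup core or dispensable.

    core iff presence_count / n_accessions >= threshold, as an exact
    fraction test with no integer pre-rounding (for 251 accessions the
    boundary sits at 239 presences).
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigError("threshold must be in (0, 1]")
    if pav.df.empty:
        return pd.Series(dtype=object, name="label")
    frac = pav.df.sum(axis=1) / pav.n_accessions
    labels = pd.Series(
        np.where(frac >= threshold, "core", "dispensable"),
        index=pav.df.index,
        name="label",
    )
    return labels


# ---------------------------------------------------------------------------
# Rarefaction


@dataclass
class RarefactionCurve:
    """Per-step summary of pan or core gene counts over random orderings."""

    n_accessions: np.ndarray
    mean_count: np.ndarray
    sd_count: np.ndarray
    min_count: np.ndarray
    max_count: np.ndarray
    gene_set_mode: str
    count_kind: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_accessions": self.n_accessions,
                "mean_count": self.mean_count,
                "sd_count": self.sd_count,
                "min_count": self.min_count,
                "max_count": self.max_count,
            }
        )


def accumulation_counts(matrix: np.ndarray, order: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Pan (cumulative union) and core (cumulative intersection) counts for
    one accession ordering of a boolean orthogroup x accession matrix."""
    sub = matrix[:, list(order)]
    pan = np.logical_or.accumulate(sub, axis=1).sum(axis=0)
    core = np.logical_and.accumulate(sub, axis=1).sum(axis=0)
    return pan, core


def _restrict_mode(pav: PAVMatrix, gene_set_mode: str) -> np.ndarray:
    m = pav.df.to_numpy()
    if gene_set_mode == "all":
        return m
    if gene_set_mode == "nonprivate":
        # non-private genes are defined on the full input panel, once
        return m[m.sum(axis=1) >= 2]
    raise ConfigError(f"unknown gene_set_mode {gene_set_mode!r}")


def rarefaction_curves(
    pav: PAVMatrix,
    n_orders: int = 500,
    seed: int = 0,
    gene_set_mode: str = "all",
) -> tuple[RarefactionCurve, RarefactionCurve]:
    """Pan/core gene accumulation curves over randomized accession orders.

    For each of ``n_orders`` random orderings, step k counts the union
    (pan) and intersection (core) of orthogroup presence over the first k
    accessions.  ``nonprivate`` mode first restricts the matrix to
    orthogroups present in at least two accessions of the full panel.
    Returns (pan_curve, core_curve) summarizing mean/sd/min/max per step.
    """
    if n_orders < 1:
        raise ConfigError("n_orders must be >= 1")
    matrix = _restrict_mode(pav, gene_set_mode)
    n_acc = pav.n_accessions
    rng = np.random.default_rng(seed)
    pans = np.empty((n_orders, n_acc), dtype=np.int64)
    cores = np.empty((n_orders, n_acc), dtype=np.int64)
    for i in range(n_orders):
        order = rng.permutation(n_acc)
        pans[i], cores[i] = accumulation_counts(matrix, order)
    steps = np.arange(1, n_acc + 1)

    def summarize(counts: np.ndarray, kind: str) -> RarefactionCurve:
        return RarefactionCurve(
            n_accessions=steps,
            mean_count=counts.mean(axis=0),
            sd_count=counts.std(axis=0, ddof=0),
            min_count=counts.min(axis=0),
            max_count=counts.max(axis=0),
            gene_set_mode=gene_set_mode,
            count_kind=kind,
        )

    return summarize(pans, "pan"), summarize(cores, "core")


def exhaustive_rarefaction(
    pav: PAVMatrix, gene_set_mode: str = "all"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact per-step pan/core means over *all* accession orderings.

    Brute-force enumeration; only sensible for small panels.  Returns
    (pan, core) frames with per-step mean and sd over the N! orderings.
    """
    matrix = _restrict_mode(pav, gene_set_mode)
    n_acc = pav.n_accessions
    pans, cores = [], []
    for order in itertools.permutations(range(n_acc)):
        p, c = accumulation_counts(matrix, order)
        pans.append(p)
        cores.append(c)
    pan_arr, core_arr = np.array(pans), np.array(cores)

    def frame(arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_accessions": np.arange(1, n_acc + 1),
                "mean_count": arr.mean(axis=0),
                "sd_count": arr.std(axis=0, ddof=0),
            }
        )

    return frame(pan_arr), frame(core_arr)


# ---------------------------------------------------------------------------
# Pairwise PAV divergence


@dataclass
class PAVDivergence:
    """Mean pairwise PAV divergence plus the per-pair table."""

    mean_ratio: float
    mean_diff_count: float
    pairs: pd.DataFrame  # accession_a, accession_b, differing, union, ratio
    n_excluded: int = 0


def pairwise_pav_divergence(
    pav: PAVMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str] | None = None,
) -> PAVDivergence:
    """Average fraction of genes differing between pairs of accessions.

    For each pair the differing count is the symmetric difference of the
    two presence sets, and the ratio divides by the size of their union
    (so identical accessions score 0 and fully disjoint ones score 1).
    Pairs are all unordered within-group pairs when ``group_b`` is omitted
    or identical to ``group_a``, else all cross-group pairs with a != b.
    Pairs involving an accession with zero genes are excluded and counted.
    """
    if not group_a or (group_b is not None and not group_b):
        raise ConfigError("groups must be non-empty")
    cols = pav.df.columns
    for acc in list(group_a) + list(group_b or []):
        if acc not in cols:
            raise ConfigError(f"unknown accession {acc!r}")
    m = pav.df.to_numpy()
    idx = {a: i for i, a in enumerate(cols)}
    if group_b is None or set(group_b) == set(group_a):
        pairs = list(itertools.combinations(sorted(set(group_a)), 2))
    else:
        pairs = [(a, b) for a in group_a for b in group_b if a != b]
    sizes = m.sum(axis=0)
    rows, n_excluded = [], 0
    for a, b in pairs:
        ia, ib = idx[a], idx[b]
        if sizes[ia] == 0 or sizes[ib] == 0:
            n_excluded += 1
            continue
        inter = int(np.count_nonzero(m[:, ia] & m[:, ib]))
        union = int(sizes[ia] + sizes[ib] - inter)
        diff = int(sizes[ia] + sizes[ib] - 2 * inter)
        rows.append((a, b, diff, union, diff / union))
    if n_excluded:
        logger.warning("excluded %d pairs involving zero-gene accessions", n_excluded)
    table = pd.DataFrame(rows, columns=["accession_a", "accession_b", "differing", "union", "ratio"])
    return PAVDivergence(
        mean_ratio=float(table["ratio"].mean()) if len(table) else float("nan"),
        mean_diff_count=float(table["differing"].mean()) if len(table) else float("nan"),
        pairs=table,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Taxonomic levels

REQUIRED_SUBPOPS = ("Or", "Ob", "Og", "Osi", "Osj")


def assign_taxon_levels(pav: PAVMatrix) -> pd.Series:
    """Assign each orthogroup to one of four *Oryza* distribution levels.

    Levels are assigned in order with the stated exclusions:

    * I   - present in both *Or* (Asian wild) and *Ob* (African wild);
    * II  - present in both *Or* and *Os* (= *Osi* u *Osj*), except level I;
    * III - present in both *Og* and *Ob*, except level I;
    * IV  - present in both *Osi* and *Osj*, except levels I and II.

    Orthogroups fitting no level (e.g. present only in *Osi* and *Og*,
    likely due to admixture) are labeled ``undetermined``.
    """
    for sp in REQUIRED_SUBPOPS:
        if not pav.accessions_of(sp):
            raise ConfigError(f"required subpopulation {sp!r} has no accessions")
    present_in = {
        sp: pav.df[pav.accessions_of(sp)].any(axis=1) for sp in REQUIRED_SUBPOPS
    }
    os_present = present_in["Osi"] | present_in["Osj"]
    level_i = present_in["Or"] & present_in["Ob"]
    level_ii = present_in["Or"] & os_present & ~level_i
    level_iii = present_in["Og"] & present_in["Ob"] & ~level_i
    level_iv = present_in["Osi"] & present_in["Osj"] & ~level_i & ~level_ii
    levels = pd.Series("undetermined", index=pav.df.index, name="level")
    levels[level_iv] = "IV"
    levels[level_iii] = "III"
    levels[level_ii] = "II"
    levels[level_i] = "I"
    return levels
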