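"""Core record types shared by the analysis modules.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)``.  The I/O
layer converts to the conventions of each on-disk format: GFF3 is 1-based
closed, VCF positions are 1-based with END pointing at the last affected
base.  ``SVRecord`` keeps the VCF convention for ``pos``/``end`` because
those fields are round-tripped through VCF untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval on one accession's chromosome.

    ``start``/``end`` are 0-based half-open.  ``is_nlr`` marks genes whose
    product carries an NB-ARC domain (nucleotide-binding leucine-rich
    repeat immune receptors); NLR identification itself happens upstream.
    """

    gene_id: str
    accession_id: str
    chrom: str
    start: int
    end: int
    strand: str
    orthogroup_id: str | None = None
    is_nlr: bool = False
    domains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class SVRecord:
    """One structural-variant call on the reference genome.

    ``pos`` and ``end`` follow the VCF convention (1-based; END is the last
    affected base).  ``svlen`` is always the absolute length.  ``genotypes``
    maps accession id to 1 (carrier), 0 (reference) or None (missing call);
    rice accessions are inbred so calls are haploid presence/absence.
    """

    sv_id: str
    chrom: str
    pos: int
    svtype: str
    svlen: int
    end: int | None = None
    genotypes: dict[str, int | None] | None = None
    support_depth: int | None = None
    precise: bool | None = True
    caller_tags: str = ""

    def __post_init__(self) -> None:
        if self.svlen <= 0:
            raise ValueError(f"SV {self.sv_id}: svlen must be positive")
        if self.end is None:
            # INS/TRA occupy a single reference breakpoint
            self.end = self.pos if self.svtype in ("INS", "TRA") else self.pos + self.svlen - 1
        if self.svtype not in ("INS", "TRA") and self.end < self.pos:
            raise ValueError(f"SV {self.sv_id}: end < pos for intra-chromosomal type")

    @property
    def breakpoints(self) -> tuple[int, ...]:
        """Reference breakpoints (1-based).

        INS and TRA contribute a single breakpoint at ``pos``; DEL, INV and
        DUP contribute both ends of the affected interval.
        """
        if self.svtype in ("INS", "TRA"):
            return (self.pos,)
        return (self.pos, self.end)

    def carriers(self) -> list[str]:
        if not self.genotypes:
            return []
        return [a for a, g in self.genotypes.items() if g == 1]


@dataclass(frozen=True)
class NLRArrangement:
    """Spatial classification of one NLR gene.

    category is ``singleton`` (no approaching NLR), ``pair`` (a connected
    component of exactly two approaching NLRs) or ``cluster`` (three or
    more).  Orientation is typed only for pairs (T-H, H-H, T-T); clusters
    record their strand string instead.  Homogeneity says whether all
    members of the pair/cluster share one orthogroup.
    """

    gene_id: str
    category: str
    group_id: str
    orientation: str | None = None
    homogeneity: str | None = None


@dataclass(frozen=True)
class HotspotRegion:
    """A merged run of SV-hotspot windows."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    n_windows_merged: int
    peak_count: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hotspot region must have end > start")


@dataclass(frozen=True)
class BubbleRecord:
    """One accession's path through a pan-genome graph bubble.

    ``pan_start``/``pan_end`` locate the bubble on the reference coordinate
    backbone; ``contig_start``/``contig_end`` locate the accession's allele
    on its own assembly.  All intervals are 0-based half-open.  A record
    with pan coordinates of None is an uncalled bubble whose backbone
    location must be interpolated from flanking collinear bubbles.
    """

    bubble_id: str
    pan_chrom: str
    pan_start: int | None
    pan_end: int | None
    accession_id: str
    contig: str
    contig_start: int
    contig_end: int
    strand: str = "+"


@dataclass
class LocusAssignment:
    """A collinear pan-genome locus grouping features from several accessions."""

    locus_id: str
    pan_chrom: str
    pan_start: int
    pan_end: int
    members: list[tuple[str, str, str]]  # (accession_id, feature_id, category)

    @property
    def n_members(self) -> int:
        return len(self.members)
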