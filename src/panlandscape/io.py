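"""Readers and writers for the plain-text formats the pipeline consumes.

GFF3 is written 1-based closed per the standard and parsed back through
:mod:`gffutils`; SV call sets go through uncompressed VCF 4.2 (Sniffles
INFO dialect: SVTYPE, SVLEN, END, RE plus PRECISE/IMPRECISE flags) via
:mod:`pysam`; everything else is tab-separated tables handled by pandas.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam

from .errors import PanlandscapeError
from .records import BubbleRecord, GeneRecord, SVRecord

# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: Iterable[GeneRecord], path: str | os.PathLike) -> None:
    """Write gene records as GFF3 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
            attrs = [f"ID={g.gene_id}"]
            if g.orthogroup_id:
                attrs.append(f"orthogroup={g.orthogroup_id}")
            attrs.append(f"is_nlr={'1' if g.is_nlr else '0'}")
            if g.domains:
                attrs.append("domains=" + ",".join(sorted(g.domains)))
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "panlandscape",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike, accession_id: str) -> list[GeneRecord]:
    """Read gene features from a GFF3 file into internal 0-based records."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        domains = frozenset(feat.attributes["domains"][0].split(",")) if "domains" in feat.attributes else frozenset()
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                accession_id=accession_id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                orthogroup_id=feat.attributes.get("orthogroup", [None])[0],
                is_nlr=feat.attributes.get("is_nlr", ["0"])[0] == "1",
                domains=domains,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# VCF (Sniffles dialect)

_SV_HEADER_LINES = [
    ('INFO', 'SVTYPE', '1', 'String', 'Type of structural variant'),
    ('INFO', 'SVLEN', '1', 'Integer', 'Length of the SV (negative for deletions)'),
    ('INFO', 'END', '1', 'Integer', 'End position of the variant'),
    ('INFO', 'RE', '1', 'Integer', 'Number of reads supporting the variant'),
    ('INFO', 'PRECISE', '0', 'Flag', 'Breakpoints are precise'),
    ('INFO', 'IMPRECISE', '0', 'Flag', 'Breakpoints are imprecise'),
    ('FORMAT', 'GT', '1', 'String', 'Genotype'),
]


def _sv_header(accessions: Sequence[str], chrom_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=int(length))
    for kind, id_, number, type_, desc in _SV_HEADER_LINES:
        if kind == 'INFO':
            header.info.add(id_, number, type_, desc)
        else:
            header.formats.add(id_, number, type_, desc)
        if id_ == 'END':
            # pysam manages END itself via rec.stop; registering is harmless
            pass
    for acc in accessions:
        header.add_sample(acc)
    return header


def write_sv_vcf(
    svs: Iterable[SVRecord],
    accessions: Sequence[str],
    chrom_lengths: Mapping[str, int],
    path: str | os.PathLike,
    diploid: bool = False,
) -> None:
    """Write SV records as uncompressed VCF 4.2.

    Haploid genotypes are the default (inbred accessions); ``diploid=True``
    writes homozygous diploid calls instead.
    """
    header = _sv_header(accessions, chrom_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for sv in sorted(svs, key=lambda s: (s.chrom, s.pos, s.sv_id)):
            rec = vf.new_record(
                contig=sv.chrom,
                start=sv.pos - 1,
                stop=max(sv.end, sv.pos),
                alleles=("N", f"<{sv.svtype}>"),
                id=sv.sv_id,
            )
            rec.info["SVTYPE"] = sv.svtype
            rec.info["SVLEN"] = -sv.svlen if sv.svtype == "DEL" else sv.svlen
            if sv.support_depth is not None:
                rec.info["RE"] = int(sv.support_depth)
            if sv.precise is not None:
                rec.info["PRECISE" if sv.precise else "IMPRECISE"] = True
            gts = sv.genotypes or {}
            for acc in accessions:
                g = gts.get(acc)
                if g is None:
                    call = (None, None) if diploid else (None,)
                else:
                    call = (g, g) if diploid else (g,)
                rec.samples[acc]["GT"] = call
            vf.write(rec)


def read_sv_vcf(path: str | os.PathLike) -> list[SVRecord]:
    """Read a Sniffles-style SV VCF back into records."""
    svs = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            info = rec.info
            svtype = info.get("SVTYPE")
            if svtype is None:
                raise PanlandscapeError(f"record {rec.id}: missing SVTYPE")
            svlen = abs(int(info["SVLEN"])) if "SVLEN" in info else rec.stop - rec.start
            genotypes: dict[str, int | None] = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    genotypes[s] = None
                else:
                    genotypes[s] = int(any(a == 1 for a in gt if a is not None))
            precise: bool | None
            if info.get("IMPRECISE", False):
                precise = False
            elif info.get("PRECISE", False):
                precise = True
            else:
                precise = None
            # END is recomputed by htslib from SVLEN; rebuild the closed
            # 1-based end from pos + svlen for interval types instead
            svs.append(
                SVRecord(
                    sv_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    svtype=str(svtype),
                    svlen=int(svlen),
                    end=None,
                    genotypes=genotypes,
                    support_depth=int(info["RE"]) if "RE" in info else None,
                    precise=precise,
                )
            )
    return svs


# ---------------------------------------------------------------------------
# TSV tables


def write_orthogroup_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an OrthoFinder-style orthogroup table.

    Rows are orthogroups, columns accessions; each cell holds the
    comma-separated member gene ids or is empty.
    """
    table.to_csv(path, sep="\t", index_label="Orthogroup")


def read_orthogroup_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df.fillna("")


def write_chrom_lengths(lengths: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{int(length)}\n")


def read_chrom_lengths(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_subpop_tsv(subpop_of: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tsubpopulation\n")
        for acc, sp in subpop_of.items():
            fh.write(f"{acc}\t{sp}\n")


def read_subpop_tsv(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["accession"].astype(str), df["subpopulation"].astype(str)))


def write_expression_tsv(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


BUBBLE_COLUMNS = [
    "bubble_id",
    "pan_chrom",
    "pan_start",
    "pan_end",
    "accession",
    "contig",
    "contig_start",
    "contig_end",
    "strand",
]


def write_bubble_tsv(bubbles: Iterable[BubbleRecord], path: str | os.PathLike) -> None:
    rows = [
        {
            "bubble_id": b.bubble_id,
            "pan_chrom": b.pan_chrom,
            "pan_start": "" if b.pan_start is None else b.pan_start,
            "pan_end": "" if b.pan_end is None else b.pan_end,
            "accession": b.accession_id,
            "contig": b.contig,
            "contig_start": b.contig_start,
            "contig_end": b.contig_end,
            "strand": b.strand,
        }
        for b in bubbles
    ]
    pd.DataFrame(rows, columns=BUBBLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bubble_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(BUBBLE_COLUMNS) - set(df.columns)
    if missing:
        raise PanlandscapeError(f"bubble table missing columns: {sorted(missing)}")
    return df


def write_bed(regions: Iterable[tuple[str, int, int]], path: str | os.PathLike) -> None:
    """Write 0-based half-open regions as 3+ column BED."""
    with open(path, "w") as fh:
        for region in regions:
            fh.write("\t".join(str(x) for x in region) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
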