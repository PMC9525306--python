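import numpy as np
import pandas as pd
import pytest

from panlandscape.pav_core import PAVMatrix
from panlandscape.records import GeneRecord, SVRecord


@pytest.fixture
def toy_pav() -> PAVMatrix:
    """3 accessions x 4 orthogroups with known unions/intersections."""
    df = pd.DataFrame(
        [[1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
        index=pd.Index(["g1", "g2", "g3", "g4"], name="orthogroup_id"),
        columns=["accA", "accB", "accC"],
        dtype=bool,
    )
    return PAVMatrix(df)


def make_gene_row(flags, acc="acc1", chrom="chr01", strands=None):
    """Genes laid left-to-right; flags mark which are NLRs."""
    strands = strands or ["+"] * len(flags)
    return [
        GeneRecord(
            gene_id=f"{acc}.{chrom}.g{i:03d}",
            accession_id=acc,
            chrom=chrom,
            start=i * 10_000,
            end=i * 10_000 + 3_000,
            strand=strands[i],
            orthogroup_id=f"OG{i:03d}",
            is_nlr=bool(flag),
        )
        for i, flag in enumerate(flags)
    ]


def make_sv(sv_id="sv1", chrom="chr01", pos=10_000, svtype="DEL", svlen=500,
            genotypes=None, depth=50, precise=True):
    return SVRecord(
        sv_id=sv_id,
        chrom=chrom,
        pos=pos,
        svtype=svtype,
        svlen=svlen,
        genotypes=genotypes if genotypes is not None else {"a1": 1, "a2": 0},
        support_depth=depth,
        precise=precise,
    )


@pytest.fixture
def random_chromosomes():
    """Factory for random synthetic NLR/non-NLR gene orders."""

    def factory(n_chromosomes: int, n_genes: int, nlr_prob: float, seed: int):
        rng = np.random.default_rng(seed)
        chroms = []
        for c in range(n_chromosomes):
            flags = rng.random(n_genes) < nlr_prob
            strands = np.where(rng.random(n_genes) < 0.5, "+", "-").tolist()
            chroms.append(
                make_gene_row(flags, acc=f"acc{c:04d}", strands=strands)
            )
        return chroms

    return factory
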