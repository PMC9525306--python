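"""Synthetic pan-genomes, SV call sets, SNP haplotypes and expression matrices.

The generators emulate the statistical structure a multi-accession rice
pan-genome analysis assumes, without any nucleotide sequence:

* a core/dispensable gene frequency spectrum over orthogroups, with genes
  placed non-overlapping along chromosomes and an NLR subset whose degree
  of physical clustering is tunable;
* SV call sets with a length mixture, a rare-skewed allele-frequency
  spectrum and optional injected breakpoint hotspots;
* biallelic haplotypes for two populations with a per-site divergence
  profile;
* expression matrices with planted SV effects.

Every generator returns its ground truth so downstream estimators can be
tested for recovery.  All randomness flows from one integer seed; each
generator draws from a deterministic substream of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, CoordinateError, SizingError
from .records import GeneRecord, SVRecord

_STREAMS = {"pangenome": 1, "sv": 2, "haplotypes": 3, "expression": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic substream of the global seed for one generator."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# Pan-genome PAV simulation


@dataclass
class PangenomeSimConfig:
    """Study conditions for the synthetic pan-genome.

    Defaults mirror a scaled-down five-subpopulation rice panel: a core
    fraction of ~43% of orthogroups, a rare-skewed Beta(0.5, 1.5)
    presence-probability spectrum for the dispensable set, and a small NLR
    fraction with a strong tendency to physical clustering.
    """

    n_accessions_per_subpop: Mapping[str, int] = field(
        default_factory=lambda: {"Osi": 8, "Osj": 6, "Or": 4, "Og": 3, "Ob": 3}
    )
    n_core_orthogroups: int = 600
    n_dispensable_orthogroups: int = 900
    dispensable_freq_spectrum: tuple[str, tuple[float, ...]] = ("beta", (0.5, 1.5))
    n_chromosomes: int = 4
    chrom_length_bp: int = 3_000_000
    nlr_fraction: float = 0.02
    nlr_cluster_bias: float = 0.7
    gene_length_range: tuple[int, int] = (2_000, 5_000)
    intergenic_gap_range: tuple[int, int] = (200, 3_000)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_accessions_per_subpop.values()):
            raise ConfigError("accession counts must be >= 0")
        if self.n_core_orthogroups < 0 or self.n_dispensable_orthogroups < 0:
            raise ConfigError("orthogroup counts must be >= 0")
        if not 0.0 <= self.nlr_fraction <= 1.0:
            raise ConfigError("nlr_fraction must be in [0, 1]")
        if not 0.0 <= self.nlr_cluster_bias <= 1.0:
            raise ConfigError("nlr_cluster_bias must be in [0, 1]")
        if self.n_chromosomes <= 0 or self.chrom_length_bp <= 0:
            raise ConfigError("chromosome geometry must be positive")
        name, params = self.dispensable_freq_spectrum
        if name == "beta" and (len(params) != 2 or min(params) <= 0):
            raise ConfigError("beta spectrum needs two positive parameters")
        if name == "fixed" and not 0.0 < params[0] < 1.0:
            raise ConfigError("fixed presence probability must be in (0, 1)")
        if name not in ("beta", "fixed"):
            raise ConfigError(f"unknown frequency spectrum '{name}'")

    @property
    def accession_ids(self) -> list[str]:
        return [
            f"{sp}{i:02d}"
            for sp, n in self.n_accessions_per_subpop.items()
            for i in range(1, n + 1)
        ]

    @property
    def subpop_of(self) -> dict[str, str]:
        return {
            f"{sp}{i:02d}": sp
            for sp, n in self.n_accessions_per_subpop.items()
            for i in range(1, n + 1)
        }


@dataclass
class PangenomeSim:
    """Output bundle of :func:`simulate_pangenome`."""

    genes: dict[str, list[GeneRecord]]  # accession -> gene records
    orthogroup_table: pd.DataFrame  # orthogroup x accession, comma-joined gene ids
    truth: pd.DataFrame  # per-orthogroup: is_core, is_nlr, presence_prob, chrom
    presence: pd.DataFrame  # boolean orthogroup x accession truth matrix
    subpop_of: dict[str, str]
    chrom_lengths: dict[str, int]


def _draw_presence_probs(cfg: PangenomeSimConfig, rng: np.random.Generator) -> np.ndarray:
    name, params = cfg.dispensable_freq_spectrum
    n = cfg.n_dispensable_orthogroups
    if name == "fixed":
        return np.full(n, float(params[0]))
    p = rng.beta(params[0], params[1], size=n)
    return np.clip(p, 1e-3, 1 - 1e-3)


def _order_with_nlr_bias(
    non_nlr: list[int], nlr: list[int], bias: float, rng: np.random.Generator
) -> list[int]:
    """Order orthogroups on a chromosome, inserting NLRs adjacent to an
    existing NLR with probability ``bias`` (1.0 forces one contiguous run)."""
    order = list(rng.permutation(non_nlr))
    nlr_set = set(nlr)
    for og in rng.permutation(nlr):
        nlr_pos = [i for i, o in enumerate(order) if o in nlr_set]
        if nlr_pos and rng.random() < bias:
            anchor = int(rng.choice(nlr_pos))
            side = int(rng.integers(0, 2))
            order.insert(anchor + side, int(og))
        else:
            order.insert(int(rng.integers(0, len(order) + 1)), int(og))
    return order


def simulate_pangenome(cfg: PangenomeSimConfig) -> PangenomeSim:
    """Simulate a multi-subpopulation pan-genome with PAV structure.

    Core orthogroups are present in every accession; each dispensable
    orthogroup's presence is drawn independently per accession at a
    frequency sampled from the configured spectrum.  Gene layout (order,
    coordinates, strand template position) is shared across accessions so
    the panel is perfectly collinear; absence simply removes a gene from
    an accession's annotation.

    Raises :class:`SizingError` if the requested genes do not fit on the
    chromosomes.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "pangenome")
    n_total = cfg.n_core_orthogroups + cfg.n_dispensable_orthogroups
    og_ids = np.array([f"OG{i:07d}" for i in range(n_total)])

    is_core = np.zeros(n_total, dtype=bool)
    is_core[rng.choice(n_total, size=cfg.n_core_orthogroups, replace=False)] = True
    is_nlr = rng.random(n_total) < cfg.nlr_fraction
    presence_prob = np.ones(n_total)
    presence_prob[~is_core] = _draw_presence_probs(cfg, rng)

    chrom_of = rng.integers(0, cfg.n_chromosomes, size=n_total)
    strand = np.where(rng.random(n_total) < 0.5, "+", "-")

    # Shared physical layout per chromosome
    coords: dict[int, tuple[str, int, int]] = {}
    chrom_names = [f"chr{c + 1:02d}" for c in range(cfg.n_chromosomes)]
    for c in range(cfg.n_chromosomes):
        idx = np.where(chrom_of == c)[0]
        order = _order_with_nlr_bias(
            [int(i) for i in idx[~is_nlr[idx]]],
            [int(i) for i in idx[is_nlr[idx]]],
            cfg.nlr_cluster_bias,
            rng,
        )
        cursor = 0
        for og_i in order:
            gap = int(rng.integers(*cfg.intergenic_gap_range))
            length = int(rng.integers(*cfg.gene_length_range))
            start = cursor + gap
            end = start + length
            if end > cfg.chrom_length_bp:
                deficit = end - cfg.chrom_length_bp
                raise SizingError(
                    f"chromosome {chrom_names[c]} too short by >= {deficit} bp "
                    f"to place {len(order)} genes"
                )
            coords[og_i] = (chrom_names[c], start, end)
            cursor = end

    accessions = cfg.accession_ids
    present = np.ones((n_total, len(accessions)), dtype=bool)
    disp = ~is_core
    present[disp] = rng.random((disp.sum(), len(accessions))) < presence_prob[disp, None]

    genes: dict[str, list[GeneRecord]] = {}
    cells = np.full((n_total, len(accessions)), "", dtype=object)
    for a, acc in enumerate(accessions):
        recs = []
        for og_i in np.where(present[:, a])[0]:
            chrom, start, end = coords[og_i]
            gid = f"{acc}.{og_ids[og_i]}"
            recs.append(
                GeneRecord(
                    gene_id=gid,
                    accession_id=acc,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=str(strand[og_i]),
                    orthogroup_id=str(og_ids[og_i]),
                    is_nlr=bool(is_nlr[og_i]),
                )
            )
            cells[og_i, a] = gid
        recs.sort(key=lambda g: (g.chrom, g.start))
        genes[acc] = recs

    truth = pd.DataFrame(
        {
            "is_core": is_core,
            "is_nlr": is_nlr,
            "presence_prob": presence_prob,
            "chrom": [coords[i][0] for i in range(n_total)],
            "start": [coords[i][1] for i in range(n_total)],
            "end": [coords[i][2] for i in range(n_total)],
        },
        index=pd.Index(og_ids, name="orthogroup_id"),
    )
    return PangenomeSim(
        genes=genes,
        orthogroup_table=pd.DataFrame(cells, index=pd.Index(og_ids, name="Orthogroup"), columns=accessions),
        truth=truth,
        presence=pd.DataFrame(present, index=pd.Index(og_ids, name="orthogroup_id"), columns=accessions),
        subpop_of=cfg.subpop_of,
        chrom_lengths={name: cfg.chrom_length_bp for name in chrom_names},
    )


# ---------------------------------------------------------------------------
# Structural-variant simulation


@dataclass
class SVSimConfig:
    """Study conditions for the synthetic SV call set.

    The default length mixture (two log-normal components) puts roughly
    two-thirds of SVs under 1 kb, and the default Beta(0.15, 2) carrier
    frequency spectrum makes most SVs rare, matching the qualitative
    pattern of long-read rice SV call sets.
    """

    n_svs: int = 5_000
    accessions: Sequence[str] | int = 25
    length_mixture: tuple[tuple[float, tuple[float, float]], ...] = (
        (0.70, (5.3, 0.9)),   # exp(5.3) ~ 200 bp median component
        (0.30, (8.5, 1.1)),   # exp(8.5) ~ 5 kb median component
    )
    type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"DEL": 0.45, "INS": 0.40, "INV": 0.05, "DUP": 0.05, "TRA": 0.05}
    )
    maf_spectrum: tuple[float, float] = (0.15, 2.0)  # Beta parameters for carrier frequency
    hotspot_regions: tuple[tuple[str, int, int, float], ...] = ()
    min_len: int = 50
    max_len: int = 1_000_000
    clip_lengths: bool = True
    mean_support_depth: float = 80.0
    imprecise_rate: float = 0.0
    seed: int = 0

    def validate(self, chrom_lengths: Mapping[str, int]) -> None:
        if self.n_svs < 0:
            raise ConfigError("n_svs must be >= 0")
        if any(length <= 0 for length in chrom_lengths.values()):
            raise ConfigError("chromosome lengths must be positive")
        if abs(sum(w for w, _ in self.length_mixture) - 1.0) > 1e-9:
            raise ConfigError("length mixture weights must sum to 1")
        if abs(sum(self.type_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("type weights must sum to 1")
        for chrom, start, end, mult in self.hotspot_regions:
            if chrom not in chrom_lengths:
                raise CoordinateError(f"hotspot chromosome {chrom!r} not in table")
            if not (0 <= start < end <= chrom_lengths[chrom]):
                raise CoordinateError(
                    f"hotspot {chrom}:{start}-{end} outside chromosome bounds"
                )
            if mult <= 0:
                raise ConfigError("hotspot enrichment multiplier must be > 0")

    def accession_ids(self) -> list[str]:
        if isinstance(self.accessions, int):
            return [f"acc{i:03d}" for i in range(1, self.accessions + 1)]
        return list(self.accessions)


def _placement_segments(
    cfg: SVSimConfig, chrom_lengths: Mapping[str, int]
) -> list[tuple[str, int, int, float]]:
    """Split chromosomes into constant-enrichment segments."""
    segments = []
    for chrom, length in chrom_lengths.items():
        cuts = {0, int(length)}
        spots = [(s, e, m) for c, s, e, m in cfg.hotspot_regions if c == chrom]
        for s, e, _ in spots:
            cuts.update((s, e))
        bounds = sorted(cuts)
        for s, e in zip(bounds[:-1], bounds[1:]):
            mult = 1.0
            for hs, he, hm in spots:
                if hs <= s and e <= he:
                    mult = hm
            segments.append((chrom, s, e, mult))
    return segments


def simulate_svs(cfg: SVSimConfig, chrom_lengths: Mapping[str, int]) -> list[SVRecord]:
    """Simulate an SV call set against a reference.

    Breakpoint positions are uniform outside ``hotspot_regions`` and
    multiplied by the enrichment factor inside them.  Genotypes are
    haploid presence/absence with carrier frequencies from the configured
    Beta spectrum (conditioned on at least one carrier).
    """
    cfg.validate(chrom_lengths)
    rng = _rng(cfg.seed, "sv")
    accessions = cfg.accession_ids()
    n = cfg.n_svs
    if n == 0:
        return []

    types = rng.choice(list(cfg.type_weights), p=list(cfg.type_weights.values()), size=n)
    comp = rng.choice(
        len(cfg.length_mixture), p=[w for w, _ in cfg.length_mixture], size=n
    )
    mus = np.array([p[0] for _, p in cfg.length_mixture])
    sigmas = np.array([p[1] for _, p in cfg.length_mixture])
    lengths = np.exp(rng.normal(mus[comp], sigmas[comp])).astype(np.int64)
    lengths = np.maximum(lengths, 1)
    if cfg.clip_lengths:
        lengths = np.clip(lengths, cfg.min_len, cfg.max_len)

    segments = _placement_segments(cfg, chrom_lengths)
    weights = np.array([(e - s) * m for _, s, e, m in segments], dtype=float)
    seg_idx = rng.choice(len(segments), p=weights / weights.sum(), size=n)

    freqs = rng.beta(*cfg.maf_spectrum, size=n)
    depths = rng.poisson(cfg.mean_support_depth, size=n)
    imprecise = rng.random(n) < cfg.imprecise_rate

    svs = []
    for i in range(n):
        chrom, seg_s, seg_e, _ = segments[seg_idx[i]]
        chrom_len = chrom_lengths[chrom]
        length = int(lengths[i])
        pos0 = int(rng.integers(seg_s, seg_e))
        if types[i] not in ("INS", "TRA"):
            # keep the whole interval on the chromosome
            if length > chrom_len:
                length = chrom_len
            pos0 = min(pos0, chrom_len - length)
        genos = (rng.random(len(accessions)) < freqs[i]).astype(int)
        if genos.sum() == 0:
            genos[rng.integers(0, len(accessions))] = 1
        svs.append(
            SVRecord(
                sv_id=f"sv{i:06d}",
                chrom=chrom,
                pos=pos0 + 1,
                svtype=str(types[i]),
                svlen=length,
                genotypes=dict(zip(accessions, (int(g) for g in genos))),
                support_depth=int(depths[i]),
                precise=not bool(imprecise[i]),
            )
        )
    return svs


# ---------------------------------------------------------------------------
# Two-population haplotypes


@dataclass
class PopGenSimConfig:
    """Biallelic two-population haplotype panel.

    ``divergence_profile`` is an (n_sites, 2) array of per-site allele-1
    frequencies for the two populations.  When None, both populations
    share a Uniform(0.05, 0.95) frequency per site (panmixia).
    """

    n_hap_per_pop: tuple[int, int] = (30, 30)
    n_sites: int = 1_000
    region_length_bp: int = 1_000_000
    divergence_profile: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_hap_per_pop) < 0 or self.n_sites < 0:
            raise ConfigError("counts must be >= 0")
        if self.n_sites > self.region_length_bp:
            raise SizingError(
                f"cannot place {self.n_sites} distinct sites in "
                f"{self.region_length_bp} bp"
            )
        if self.divergence_profile is not None:
            prof = np.asarray(self.divergence_profile, dtype=float)
            if prof.shape != (self.n_sites, 2):
                raise ConfigError("divergence_profile must have shape (n_sites, 2)")
            if prof.min() < 0 or prof.max() > 1:
                raise ConfigError("allele frequencies must be in [0, 1]")


def step_divergence_profile(
    n_sites: int,
    positions: np.ndarray,
    base_freq: float = 0.5,
    block: tuple[int, int] | None = None,
    block_freqs: tuple[float, float] = (0.95, 0.05),
) -> np.ndarray:
    """Helper: a flat shared-frequency profile with one divergent block.

    Sites whose positions fall in ``block`` (bp, half-open) get the two
    populations' frequencies set to ``block_freqs``; all other sites share
    ``base_freq``.
    """
    prof = np.full((n_sites, 2), base_freq, dtype=float)
    if block is not None:
        inside = (positions >= block[0]) & (positions < block[1])
        prof[inside, 0] = block_freqs[0]
        prof[inside, 1] = block_freqs[1]
    return prof


def simulate_haplotypes(
    cfg: PopGenSimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw biallelic haplotypes for two populations.

    Returns ``(haplotypes, positions, pop_labels)`` where haplotypes is an
    (n_hap_total, n_sites) 0/1 matrix, positions are distinct 1-based bp
    coordinates sorted ascending, and pop_labels holds 0/1 population
    indices per haplotype row.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "haplotypes")
    positions = np.sort(rng.choice(cfg.region_length_bp, size=cfg.n_sites, replace=False)) + 1
    if cfg.divergence_profile is None:
        shared = rng.uniform(0.05, 0.95, size=cfg.n_sites)
        prof = np.column_stack([shared, shared])
    else:
        prof = np.asarray(cfg.divergence_profile, dtype=float)
    n1, n2 = cfg.n_hap_per_pop
    hap1 = rng.random((n1, cfg.n_sites)) < prof[:, 0]
    hap2 = rng.random((n2, cfg.n_sites)) < prof[:, 1]
    haplotypes = np.vstack([hap1, hap2]).astype(np.int8)
    labels = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    return haplotypes, positions, labels


# ---------------------------------------------------------------------------
# Expression with planted SV effects


def simulate_expression(
    genotypes: pd.DataFrame,
    effect_plan: Sequence[tuple[str, str, float]],
    noise_sd: float,
    seed: int,
    gene_ids: Sequence[str] | None = None,
    baseline_range: tuple[float, float] = (1.0, 10.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an expression table with planted SV -> gene effects.

    expression[g, a] = baseline[g] + sum(effect * dosage[sv, a]) + noise.

    ``genotypes`` is an SV x accession dosage table.  Returns the
    expression table (gene x accession) and the truth table of planted
    effects.  Duplicate (sv, gene) plan entries or unknown ids raise
    :class:`ConfigError`.
    """
    seen = set()
    for sv_id, gene_id, _ in effect_plan:
        if sv_id not in genotypes.index:
            raise ConfigError(f"planted SV {sv_id!r} not in genotype table")
        if (sv_id, gene_id) in seen:
            raise ConfigError(f"duplicate effect plan entry ({sv_id}, {gene_id})")
        seen.add((sv_id, gene_id))

    plan_genes = [g for _, g, _ in effect_plan]
    genes = list(gene_ids) if gene_ids is not None else list(dict.fromkeys(plan_genes))
    missing = set(plan_genes) - set(genes)
    if missing:
        raise ConfigError(f"planted genes absent from gene_ids: {sorted(missing)}")

    rng = _rng(seed, "expression")
    accessions = list(genotypes.columns)
    baseline = rng.uniform(*baseline_range, size=len(genes))
    expr = np.tile(baseline[:, None], (1, len(accessions)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for sv_id, gene_id, effect in effect_plan:
        expr[gene_pos[gene_id]] += effect * genotypes.loc[sv_id].to_numpy(dtype=float)
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=accessions)
    truth = pd.DataFrame(effect_plan, columns=["sv_id", "gene_id", "effect"])
    return expression, truth
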