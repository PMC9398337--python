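"""Synthetic-data generators for every pipeline input.

Three generators reproduce the statistical structure of the study system:

* a backcross/self population simulator over a genetic map (Haldane
  crossovers, no interference), emitting a
  :class:`~qtlhotspot.io_formats.MarkerMatrix` plus ground truth;
* a phenotype model drawing 100-seed weight from per-QTL-class Gaussians
  calibrated to the observed homozygous-class means (donor-homozygous
  20.88 g, recipient-homozygous 13.27 g; standard deviations derived from
  the reported standard errors under an assumed 10 plants per class);
* an extreme-bulk panel simulator: a large accession collection whose
  phenotype is a two-component mixture driven by one causal SNP planted
  in a 13-gene annotation fixture, from which the 20 highest- and 20
  lowest-ranked accessions form the two bulks, with decoy SNPs drawn at a
  phenotype-independent background frequency and missing calls masked.

All randomness flows through one :class:`numpy.random.Generator`, so a
fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    BulkGenotypeTable,
    GeneModel,
    MarkerMatrix,
    TraitTable,
    variant_key,
    write_bulk_vcf,
    write_gene_models,
    write_marker_matrix,
)

logger = logging.getLogger(__name__)

CODE_RECIPIENT, CODE_DONOR, CODE_HET = "A", "B", "H"

#: observed homozygous-class 100-seed-weight means (g) and standard errors
DONOR_CLASS_MEAN, DONOR_CLASS_SE = 20.88, 0.77
RECIPIENT_CLASS_MEAN, RECIPIENT_CLASS_SE = 13.27, 0.26
#: plants per class assumed when converting a reported SE into an SD
ASSUMED_N_PER_CLASS = 10

#: physical/genetic extent of the target sub-region the population
#: segregates for (kb and cM of the larger fine-mapping sub-region)
REGION_SPAN_BP = 139_220
REGION_SPAN_CM = 0.23

FIXTURE_REGION_BP = 113_040
FIXTURE_N_GENES = 13
FIXTURE_CHROM = "Ca4"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_sds() -> dict[str, float]:
    sd_b = DONOR_CLASS_SE * math.sqrt(ASSUMED_N_PER_CLASS)
    sd_a = RECIPIENT_CLASS_SE * math.sqrt(ASSUMED_N_PER_CLASS)
    return {CODE_RECIPIENT: sd_a, CODE_DONOR: sd_b, CODE_HET: (sd_a + sd_b) / 2}


def _default_means() -> dict[str, float]:
    # heterozygote defaults to midparent: the seed-weight QTL is modelled
    # as additive (no dominance term is estimable from homozygous classes)
    return {
        CODE_RECIPIENT: RECIPIENT_CLASS_MEAN,
        CODE_DONOR: DONOR_CLASS_MEAN,
        CODE_HET: (RECIPIENT_CLASS_MEAN + DONOR_CLASS_MEAN) / 2,
    }


@dataclass
class PhenotypeModel:
    """Per-QTL-class Gaussian model of 100-seed weight (g)."""

    class_means: dict[str, float] = field(default_factory=_default_means)
    class_sds: dict[str, float] = field(default_factory=_default_sds)
    trait: str = "seed_weight_100"
    unit: str = "g"


@dataclass
class BulkModel:
    """Mixture model behind the extreme-bulk accession panel.

    The reference line carries the high-phenotype allele, so ``ref``
    accessions draw from the upper component. ``effect`` is the mean
    difference between components; ``within_sd`` their common spread.
    """

    n_accessions: int = 1712
    tail_size: int = 20
    causal_allele_freq: float = 0.5   # population frequency of the nonref allele
    effect: float = DONOR_CLASS_MEAN - RECIPIENT_CLASS_MEAN
    mu_nonref: float = RECIPIENT_CLASS_MEAN
    within_sd: float = 2.4
    n_decoys: int = 12
    background_freq: float = 0.5      # nonref frequency at decoy SNPs
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("causal_allele_freq", "background_freq", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.tail_size * 2 > self.n_accessions:
            raise ValueError("tail size exceeds half the panel")


@dataclass
class SimConfig:
    """Full parameterization of the population, phenotype and bulk simulators."""

    seed: int = 1
    mapping_function: str = "haldane"
    generations: list[str] = field(
        default_factory=lambda: ["backcross"] * 6 + ["self"]
    )
    n_individuals: int = 200
    missing_rate: float = 0.0
    qtl_marker: str | None = None
    n_markers: int = 12
    fixture_seed: int = 4958
    phenotype: PhenotypeModel = field(default_factory=PhenotypeModel)
    bulk: BulkModel = field(default_factory=BulkModel)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "phenotype" in kwargs:
            kwargs["phenotype"] = PhenotypeModel(**kwargs["phenotype"])
        if "bulk" in kwargs:
            kwargs["bulk"] = BulkModel(**kwargs["bulk"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def default_marker_map(
    n_markers: int = 12,
    chrom: str = FIXTURE_CHROM,
    start_bp: int = 13_000_001,
    span_bp: int = REGION_SPAN_BP,
    span_cm: float = REGION_SPAN_CM,
) -> pd.DataFrame:
    """Evenly spaced KASP-style markers across the target sub-region."""
    names = [f"CKAM{2210 + i}" for i in range(n_markers)]
    bp = np.linspace(start_bp, start_bp + span_bp - 1, n_markers).round().astype(int)
    cm = np.linspace(0.0, span_cm, n_markers)
    return pd.DataFrame({"chrom": chrom, "cm": cm, "bp": bp}, index=pd.Index(names, name="marker"))


# ---------------------------------------------------------------------------
# Recombination
# ---------------------------------------------------------------------------


def recombination_fraction(d_cm: float, mapping: str = "haldane") -> float:
    """Map distance (cM) -> recombination fraction.

    Haldane (no interference): r = (1 - exp(-2d/100)) / 2.
    Kosambi: r = tanh(2d/100) / 2.
    """
    if d_cm < 0:
        raise ValueError(f"negative map distance {d_cm}")
    x = 2.0 * d_cm / 100.0
    if mapping == "haldane":
        return 0.5 * (1.0 - math.exp(-x))
    if mapping == "kosambi":
        return 0.5 * math.tanh(x)
    raise ValueError(f"unknown mapping function {mapping!r}")


# ---------------------------------------------------------------------------
# Population simulator
# ---------------------------------------------------------------------------


@dataclass
class PopulationSim:
    """A simulated population plus its generating truth."""

    matrix: MarkerMatrix
    qtl_marker: str
    qtl_genotypes: pd.Series            # unmasked code at the QTL marker
    breakpoints: dict[str, list[tuple[str, int]]]  # individual -> (chrom, mid bp)


def _meiosis(hap1, hap2, chrom_blocks, rng):
    """One gamete by marker-walk crossovers; returns (gamete, breakpoints)."""
    n = len(hap1)
    gamete = np.empty(n, dtype=np.int8)
    breaks: list[tuple[str, int]] = []
    for chrom, idxs, rs, bps in chrom_blocks:
        cur = int(rng.integers(2))
        for j, idx in enumerate(idxs):
            if j > 0 and rng.random() < rs[j - 1]:
                cur = 1 - cur
                breaks.append((chrom, int((bps[j - 1] + bps[j]) // 2)))
            gamete[idx] = (hap1 if cur == 0 else hap2)[idx]
    return gamete, breaks


def _chrom_blocks(marker_map: pd.DataFrame, mapping: str):
    blocks = []
    names = list(marker_map.index)
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        idxs = [names.index(m) for m in grp.index]
        rs = [recombination_fraction(d, mapping) for d in grp["cm"].diff().dropna()]
        blocks.append((chrom, idxs, rs, grp["bp"].to_numpy()))
    return blocks


def simulate_population(
    config: SimConfig | None = None,
    marker_map: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> PopulationSim:
    """Simulate the configured cross sequence over a genetic map.

    Gametes are generated marker-by-marker: the starting haplotype is
    drawn uniformly per chromosome and switches between adjacent markers
    with the Haldane (or Kosambi) recombination fraction of their map
    distance — a no-interference crossover model. The cross starts from
    the F1 of donor x recipient; each intermediate generation keeps one
    offspring heterozygous at the QTL marker (emulating marker-assisted
    carrier selection), and the final generation emits
    ``config.n_individuals`` offspring. Missing calls are masked at
    ``config.missing_rate`` after the truth is recorded.
    """
    config = config or SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mm = marker_map if marker_map is not None else default_marker_map(config.n_markers)
    if mm.empty:
        raise ValueError("empty genetic map")
    mm = mm.sort_values(["chrom", "bp"], kind="stable")
    names = list(mm.index)
    qtl_marker = config.qtl_marker or names[len(names) // 2]
    qtl_idx = names.index(qtl_marker)
    blocks = _chrom_blocks(mm, config.mapping_function)
    n_mark = len(names)
    recipient = np.zeros(n_mark, dtype=np.int8)
    donor = np.ones(n_mark, dtype=np.int8)
    parent = (recipient.copy(), donor.copy())  # the F1

    if not config.generations:
        raise ValueError("empty cross plan")
    for op in config.generations[:-1]:
        parent = _next_carrier(parent, op, blocks, qtl_idx, recipient, rng)

    final_op = config.generations[-1]
    rows, codes_q, brk = [], {}, {}
    ids = [f"IND{i + 1:05d}" for i in range(config.n_individuals)]
    for ind in ids:
        h1, b1 = _meiosis(*parent, blocks, rng)
        if final_op == "self":
            h2, b2 = _meiosis(*parent, blocks, rng)
        elif final_op == "backcross":
            h2, b2 = recipient.copy(), []
        else:
            raise ValueError(f"unknown cross operation {final_op!r}")
        dosage = h1 + h2
        codes = np.where(dosage == 0, CODE_RECIPIENT,
                         np.where(dosage == 2, CODE_DONOR, CODE_HET))
        rows.append(codes)
        codes_q[ind] = str(codes[qtl_idx])
        brk[ind] = b1 + b2
    calls = pd.DataFrame(rows, index=ids, columns=names)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = calls.mask(pd.DataFrame(mask, index=ids, columns=names), "-")
    matrix = MarkerMatrix(calls=calls, marker_map=mm)
    return PopulationSim(
        matrix=matrix, qtl_marker=qtl_marker,
        qtl_genotypes=pd.Series(codes_q), breakpoints=brk,
    )


def _next_carrier(parent, op, blocks, qtl_idx, recipient, rng, max_tries=10_000):
    for _ in range(max_tries):
        h1, _ = _meiosis(*parent, blocks, rng)
        if op == "backcross":
            h2 = recipient.copy()
        elif op == "self":
            h2, _ = _meiosis(*parent, blocks, rng)
        else:
            raise ValueError(f"unknown cross operation {op!r}")
        if h1[qtl_idx] + h2[qtl_idx] == 1:  # heterozygous carrier retained
            return (h1, h2)
    raise RuntimeError("failed to draw a QTL-heterozygous carrier")


# ---------------------------------------------------------------------------
# Phenotype simulator
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    qtl_genotypes: pd.Series | Mapping[str, str],
    model: PhenotypeModel | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> TraitTable:
    """Draw per-plant 100-seed weight from the per-class Gaussian model."""
    model = model or PhenotypeModel()
    if rng is None:
        rng = np.random.default_rng(seed)
    geno = pd.Series(qtl_genotypes)
    unknown = sorted(set(geno) - set(model.class_means))
    if unknown:
        raise ValueError(f"no phenotype model for class(es) {unknown}")
    mu = geno.map(model.class_means).to_numpy(float)
    sd = geno.map(model.class_sds).to_numpy(float)
    values = mu + rng.standard_normal(len(geno)) * sd
    df = pd.DataFrame({
        "individual": geno.index.astype(str),
        "genotype_class": geno.to_numpy(),
        model.trait: values,
    })
    return TraitTable(data=df, units={model.trait: model.unit})


# ---------------------------------------------------------------------------
# Recombinant homozygous families
# ---------------------------------------------------------------------------


@dataclass
class FamilySim:
    """Simulated homozygous recombinant families with known truth."""

    matrix: MarkerMatrix           # one representative genotype per family
    classes: dict[str, str]        # family -> "high" | "low" (truth)
    qtl_marker: str
    qtl_bp: int


def simulate_recombinant_families(
    n_families: int = 10,
    marker_map: pd.DataFrame | None = None,
    qtl_marker: str | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> FamilySim:
    """Fixed (homozygous) recombinant families over one chromosome region.

    Each family carries a single introgression breakpoint at a uniform
    physical position within the mapped region, with the donor segment on
    a random side; genotypes are homozygous throughout (the lines are
    fixed after selfing). The causal locus sits at *qtl_marker* — the
    diagnostic-marker situation, where a KASP assay tags the causal SNP
    itself — and a family is ``high`` iff it is donor-homozygous there.
    Draws are repeated until both classes are present.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mm = marker_map if marker_map is not None else default_marker_map()
    mm = mm.sort_values(["chrom", "bp"], kind="stable")
    if mm["chrom"].nunique() != 1:
        raise ValueError("family simulation expects a single-chromosome map")
    names = list(mm.index)
    bps = mm["bp"].to_numpy()
    qtl_marker = qtl_marker or names[len(names) // 2]
    qtl_bp = int(mm.loc[qtl_marker, "bp"])
    ids = [f"FAM{i + 1:02d}" for i in range(n_families)]
    for _ in range(1000):
        rows, classes = [], {}
        for fam in ids:
            while True:  # breakpoint strictly between markers, never on one
                bp = int(rng.integers(bps[0], bps[-1] + 1))
                if bp not in bps:
                    break
            donor_left = bool(rng.integers(2))
            donor = (bps < bp) if donor_left else (bps > bp)
            rows.append(np.where(donor, CODE_DONOR, CODE_RECIPIENT))
            classes[fam] = "high" if rows[-1][names.index(qtl_marker)] == CODE_DONOR else "low"
        if len(set(classes.values())) == 2:
            break
    calls = pd.DataFrame(rows, index=ids, columns=names)
    return FamilySim(
        matrix=MarkerMatrix(calls=calls, marker_map=mm),
        classes=classes, qtl_marker=qtl_marker, qtl_bp=qtl_bp,
    )


def simulate_family_means(
    classes: Mapping[str, str],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    high_mean: float = DONOR_CLASS_MEAN,
    low_mean: float = RECIPIENT_CLASS_MEAN,
    high_se: float = DONOR_CLASS_SE,
    low_se: float = RECIPIENT_CLASS_SE,
    noiseless: bool = False,
) -> dict[str, float]:
    """Family trait means for a progeny test: class mean + SE-scale noise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out = {}
    for fam, cls in classes.items():
        mu, se = (high_mean, high_se) if cls == "high" else (low_mean, low_se)
        out[str(fam)] = mu if noiseless else mu + float(rng.normal(0.0, se))
    return out


# ---------------------------------------------------------------------------
# Annotation fixture
# ---------------------------------------------------------------------------


@dataclass
class AnnotationFixture:
    """Deterministic 13-gene annotation of the delimited target region.

    One gene reproduces the candidate transcription-factor layout: seven
    exons, a 339-codon CDS (stop included) on the minus strand whose codon
    149 is ATT (Ile), so the planted plus-strand A->C substitution in exon
    6 yields the I149S change. ``causal`` records that SNP.
    """

    models: dict[str, GeneModel]
    genome: dict[str, str]
    causal: dict


_NONSTOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
    - {"TAA", "TAG", "TGA"}
)

_TIFY_CDS_CHUNKS = [60, 90, 90, 90, 90, 300, 300]  # sums to 1020 = 340 codons
_UTR_LEN = 50


def make_annotation_fixture(seed: int = 4958) -> AnnotationFixture:
    """Build the 13-gene fixture and its genome, deterministically.

    Genes are tiled non-overlapping across a 113,040-bp region; the final
    gene is the seven-exon candidate. Identical seeds give byte-identical
    output on any platform.
    """
    rng = np.random.default_rng(seed)
    genome = rng.choice(list("ACGT"), size=FIXTURE_REGION_BP)
    slot = FIXTURE_REGION_BP // FIXTURE_N_GENES
    models: dict[str, GeneModel] = {}
    causal: dict = {}
    for i in range(FIXTURE_N_GENES):
        gene_id = f"Ca_{4546 + i:05d}"
        is_tify = i == FIXTURE_N_GENES - 1
        strand = "-" if is_tify else ("+" if i % 2 == 0 else "-")
        if is_tify:
            chunks = list(_TIFY_CDS_CHUNKS)
            codons = [_NONSTOP_CODONS[j] for j in
                      rng.integers(0, len(_NONSTOP_CODONS), size=339)]
            codons[0] = "ATG"
            codons[148] = "ATT"  # Ile at residue 149
            cds_seq = "".join(codons) + "TAA"
        else:
            n_codons = int(rng.integers(120, 301))
            codons = [_NONSTOP_CODONS[j] for j in
                      rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 1)]
            codons[0] = "ATG"
            cds_seq = "".join(codons) + "TAA"
            n_exons = int(rng.integers(1, 5))
            chunks = _split_lengths(len(cds_seq), n_exons, rng)
        gene = _assemble_gene(gene_id, strand, cds_seq, chunks, rng,
                              gene_start=i * slot + 501)
        models[gene_id] = gene["model"]
        start0 = gene["model"].start - 1
        genome[start0:start0 + len(gene["sequence"])] = list(gene["sequence"])
        if is_tify:
            causal = _plant_causal_snp(gene, genome)
    seq = "".join(genome)
    return AnnotationFixture(models=models, genome={FIXTURE_CHROM: seq}, causal=causal)


def _split_lengths(total: int, parts: int, rng) -> list[int]:
    """Split *total* into codon-unaligned-but-positive exon chunk lengths."""
    if parts == 1:
        return [total]
    cuts = sorted(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    edges = [0, *map(int, cuts), total]
    return [edges[i + 1] - edges[i] for i in range(parts)]


def _assemble_gene(gene_id: str, strand: str, cds_seq: str,
                   cds_chunks: list[int], rng, gene_start: int) -> dict:
    """Lay out UTRs, exons and introns; return model + sense sequence +
    transcript bookkeeping for SNP planting."""
    if sum(cds_chunks) != len(cds_seq):
        raise ValueError("exon CDS chunks must tile the CDS exactly")
    utr5 = "".join(rng.choice(list("ACGT"), size=_UTR_LEN))
    utr3 = "".join(rng.choice(list("ACGT"), size=_UTR_LEN))
    n_exons = len(cds_chunks)
    # transcript-order exon lengths: UTRs live in the terminal exons
    exon_lens = list(cds_chunks)
    exon_lens[0] += _UTR_LEN
    exon_lens[-1] += _UTR_LEN
    intron_lens = [int(rng.integers(200, 501)) for _ in range(n_exons - 1)]

    transcript = utr5 + cds_seq + utr3
    sense_parts: list[str] = []
    exon_sense: list[tuple[int, int]] = []   # 0-based [start, end] on sense strand
    cds_sense_offsets: list[int] = []        # sense offset of each CDS base
    t_pos = 0
    s_pos = 0
    for k in range(n_exons):
        ex = transcript[t_pos:t_pos + exon_lens[k]]
        exon_sense.append((s_pos, s_pos + exon_lens[k] - 1))
        for j in range(exon_lens[k]):
            t = t_pos + j
            if _UTR_LEN <= t < _UTR_LEN + len(cds_seq):
                cds_sense_offsets.append(s_pos + j)
        sense_parts.append(ex)
        t_pos += exon_lens[k]
        s_pos += exon_lens[k]
        if k < n_exons - 1:
            ilen = intron_lens[k]
            intron = "GT" + "".join(rng.choice(list("ACGT"), size=ilen - 4)) + "AG"
            sense_parts.append(intron)
            s_pos += ilen
    sense = "".join(sense_parts)
    glen = len(sense)
    gstart = gene_start
    gend = gstart + glen - 1

    def sense_to_genomic(o: int) -> int:
        return gstart + o if strand == "+" else gend - o

    exons_genomic = sorted(
        tuple(sorted((sense_to_genomic(a), sense_to_genomic(b))))
        for a, b in exon_sense
    )
    # CDS genomic segments: contiguous runs of CDS sense offsets per exon
    cds_genomic: list[tuple[int, int, int]] = []
    cum = 0
    run_start = cds_sense_offsets[0]
    prev = run_start
    runs: list[tuple[int, int]] = []
    for o in cds_sense_offsets[1:]:
        if o != prev + 1:
            runs.append((run_start, prev))
            run_start = o
        prev = o
    runs.append((run_start, prev))
    for a, b in runs:  # runs are in transcription order by construction
        seg_len = b - a + 1
        phase = (3 - cum % 3) % 3
        lo, hi = sorted((sense_to_genomic(a), sense_to_genomic(b)))
        cds_genomic.append((lo, hi, phase))
        cum += seg_len
    if strand == "-":
        cds_genomic.sort(key=lambda t: t[0], reverse=True)
    genomic_seq = sense if strand == "+" else _revcomp(sense)
    model = GeneModel(
        gene_id=gene_id, chrom=FIXTURE_CHROM, strand=strand,
        start=gstart, end=gend, exons=exons_genomic, cds=cds_genomic,
    )
    return {
        "model": model, "sequence": genomic_seq, "cds_seq": cds_seq,
        "cds_sense_offsets": cds_sense_offsets,
        "sense_to_genomic": sense_to_genomic,
    }


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _plant_causal_snp(gene: dict, genome) -> dict:
    """Locate the middle base of codon 149 and define the A->C variant."""
    cds_offset = 148 * 3 + 1  # 0-based offset of codon-149 position 2
    sense_off = gene["cds_sense_offsets"][cds_offset]
    pos = gene["sense_to_genomic"](sense_off)
    model = gene["model"]
    ref = str(genome[pos - 1])
    transcript_base = gene["cds_seq"][cds_offset]          # "T" of ATT
    assert transcript_base == "T"
    alt_transcript = "G"                                   # ATT -> AGT = Ser
    alt = alt_transcript if model.strand == "+" else alt_transcript.translate(_COMP)
    return {
        "gene": model.gene_id, "chrom": model.chrom, "pos": int(pos),
        "ref": ref, "alt": alt, "protein_change": "I149S", "exon_index": 6,
    }


def write_fixture(fixture: AnnotationFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture as ``genes.gff3`` + ``genome.fa``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gff = outdir / "genes.gff3"
    fasta = outdir / "genome.fa"
    write_gene_models(fixture.models, gff)
    with fasta.open("w") as fh:
        for name, seq in fixture.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return {"gff3": gff, "fasta": fasta}


# ---------------------------------------------------------------------------
# Extreme-bulk panel simulator
# ---------------------------------------------------------------------------


@dataclass
class BulkPanelSim:
    """Simulated composite-collection panel reduced to its two bulks."""

    table: BulkGenotypeTable
    phenotypes: pd.Series            # all accessions, 100-seed weight (g)
    truth: dict


def simulate_bulk_panel(
    model: BulkModel | None = None,
    fixture: AnnotationFixture | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> BulkPanelSim:
    """Simulate the accession panel and extract its extreme bulks.

    Each (inbred, hence homozygous) accession carries the non-reference
    allele at the causal SNP with probability ``causal_allele_freq``;
    phenotype = component mean + Gaussian noise. The ``tail_size``
    highest- and lowest-ranked accessions form the ``highest`` and
    ``lowest`` bulks. Decoy SNPs in the other fixture genes are drawn at
    ``background_freq`` independently of phenotype; calls are masked
    missing at ``missing_rate``. Requires a non-zero effect when the
    bulks are meant to separate the causal allele.
    """
    model = model or BulkModel()
    if rng is None:
        rng = np.random.default_rng(seed)
    fixture = fixture or make_annotation_fixture()
    if model.effect == 0:
        logger.warning("causal effect is 0: bulks will not separate the causal allele")
    n = model.n_accessions
    ids = [f"ACC{i + 1:04d}" for i in range(n)]
    nonref = rng.random(n) < model.causal_allele_freq
    mu = np.where(nonref, model.mu_nonref, model.mu_nonref + model.effect)
    pheno = pd.Series(mu + rng.standard_normal(n) * model.within_sd, index=ids,
                      name="seed_weight_100")
    order = pheno.sort_values()
    lowest = list(order.index[:model.tail_size])
    highest = list(order.index[-model.tail_size:])
    bulk_ids = highest + lowest

    genes = list(fixture.models.values())
    causal = fixture.causal
    decoy_genes = [g for g in genes if g.gene_id != causal["gene"]]
    positions = {causal["pos"]}
    var_rows = []
    keys = []
    ckey = variant_key(causal["chrom"], causal["pos"])
    keys.append(ckey)
    var_rows.append({"chrom": causal["chrom"], "pos": causal["pos"],
                     "ref": causal["ref"], "alt": causal["alt"],
                     "gene": causal["gene"]})
    chrom_seq = fixture.genome[FIXTURE_CHROM]
    for d in range(model.n_decoys):
        g = decoy_genes[d % len(decoy_genes)]
        while True:
            pos = int(rng.integers(g.start, g.end + 1))
            if pos not in positions:
                positions.add(pos)
                break
        ref = chrom_seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        keys.append(variant_key(g.chrom, pos))
        var_rows.append({"chrom": g.chrom, "pos": pos, "ref": ref, "alt": alt,
                         "gene": g.gene_id})
    variants = pd.DataFrame(var_rows, index=keys)

    acc_idx = pd.Index(bulk_ids)
    calls = pd.DataFrame(index=acc_idx, columns=keys, dtype=object)
    is_nonref_causal = pd.Series(nonref, index=ids).loc[bulk_ids]
    calls[ckey] = np.where(is_nonref_causal, "nonref", "ref")
    for key in keys[1:]:
        calls[key] = np.where(rng.random(len(bulk_ids)) < model.background_freq,
                              "nonref", "ref")
    if model.missing_rate > 0:
        mask = rng.random(calls.shape) < model.missing_rate
        calls = calls.mask(pd.DataFrame(mask, index=acc_idx, columns=keys), "missing")
    table = BulkGenotypeTable(
        reference_line="ICC4958",
        bulks={"highest": highest, "lowest": lowest},
        variants=variants, calls=calls,
    )
    truth = {
        "causal_gene": causal["gene"], "causal_variant": ckey,
        "mu_ref": model.mu_nonref + model.effect, "mu_nonref": model.mu_nonref,
        "protein_change": causal.get("protein_change"),
    }
    return BulkPanelSim(table=table, phenotypes=pheno, truth=truth)


def write_bulk_panel(sim: BulkPanelSim, outdir: str | Path) -> dict[str, Path]:
    """Write the panel as ``calls.vcf`` + ``bulks.yaml`` + ``phenotypes.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf = outdir / "calls.vcf"
    bulks = outdir / "bulks.yaml"
    pheno = outdir / "phenotypes.csv"
    write_bulk_vcf(sim.table, vcf)
    with bulks.open("w") as fh:
        yaml.safe_dump(
            {"reference_line": sim.table.reference_line,
             "bulks": {k: list(v) for k, v in sim.table.bulks.items()}},
            fh, sort_keys=False,
        )
    sim.phenotypes.rename_axis("accession").to_csv(pheno)
    return {"vcf": vcf, "bulks": bulks, "phenotypes": pheno}
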