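"""Readers, writers and validated containers for the pipeline's file formats.

Containers
----------
:class:`MarkerMatrix`
    Individuals x ordered KASP/SSR markers, coded ``A`` (recipient-parent
    homozygous), ``B`` (donor-parent homozygous), ``H`` (heterozygous) and
    ``-`` (missing), with a genetic/physical map per marker.
:class:`BulkGenotypeTable`
    Per-accession calls (``ref``/``nonref``/``missing``) at biallelic SNPs
    for two labelled phenotype bulks, scored against a named reference line.
:class:`GeneModel`
    Exon/intron structure, strand and CDS frame of one gene.
:class:`TraitTable`
    Keyed per-plant/per-plot trait measurements with registered units.

All coordinates are 1-based and inclusive (VCF/GFF3 convention); every
interval below is a closed ``[start, end]`` pair of such coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from cyvcf2 import VCF
import gffutils

logger = logging.getLogger(__name__)

MARKER_CODES = frozenset({"A", "B", "H", "-"})
MISSING_CODE = "-"

BULK_CALL_CODES = frozenset({"ref", "nonref", "missing"})


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# MarkerMatrix
# ---------------------------------------------------------------------------


@dataclass
class MarkerMatrix:
    """Genotype calls for individuals at ordered, mapped markers.

    Parameters
    ----------
    calls
        DataFrame indexed by individual ID with one column per marker;
        every cell holds one of ``A``, ``B``, ``H``, ``-``.
    marker_map
        DataFrame indexed by marker name with columns ``chrom`` (str),
        ``cm`` (genetic position, centimorgan) and ``bp`` (physical
        position, base pairs).

    Markers are kept strictly ordered by ``(chrom, bp)``; out-of-order
    input is re-sorted with a logged warning. Genetic positions must be
    non-decreasing within a chromosome once the physical sort is applied.
    """

    calls: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        calls, mm = self.calls, self.marker_map
        if calls.index.duplicated().any():
            dupes = calls.index[calls.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated individual IDs: {dupes}")
        missing_map = [m for m in calls.columns if m not in mm.index]
        if missing_map:
            raise FormatError(f"markers in calls absent from map: {missing_map}")
        if mm[["chrom", "cm", "bp"]].isna().any().any():
            raise FormatError("marker map contains unsortable (missing) positions")
        bad = ~calls.isin(MARKER_CODES)
        if bad.any().any():
            row, col = next(zip(*bad.values.nonzero()))
            raise FormatError(
                f"unknown genotype code {calls.iloc[row, col]!r} at "
                f"individual {calls.index[row]!r}, marker {calls.columns[col]!r}"
            )
        mm = mm.loc[list(calls.columns)]
        ordered = mm.sort_values(["chrom", "bp"], kind="stable")
        if list(ordered.index) != list(mm.index):
            logger.warning("markers were not in (chrom, bp) order; re-sorting")
        for chrom, grp in ordered.groupby("chrom", sort=False):
            if grp["bp"].duplicated().any():
                raise FormatError(f"duplicate physical positions on {chrom}")
            if (grp["cm"].diff().dropna() < 0).any():
                raise FormatError(
                    f"genetic positions decrease along {chrom} after physical sort"
                )
        self.marker_map = ordered
        self.calls = calls[ordered.index]

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    def chromosome_markers(self, chrom: str) -> list[str]:
        return list(self.marker_map.index[self.marker_map["chrom"] == chrom])


_CALLS_SECTION = "[calls]"
_MAP_SECTION = "[map]"


def read_marker_matrix(path: str | Path, map_path: str | Path | None = None) -> MarkerMatrix:
    """Read a marker matrix from CSV.

    Two dialects are accepted: a single file containing a ``[calls]``
    section followed by a ``[map]`` section, or a plain calls CSV with the
    map supplied as a separate *map_path* CSV (columns
    ``marker,chrom,cM,bp``). The calls header row defines marker names and
    the first column holds individual IDs.
    """
    path = Path(path)
    text = path.read_text()
    if map_path is not None:
        calls_csv = text
        map_csv = Path(map_path).read_text()
    else:
        if _MAP_SECTION not in text:
            raise FormatError(
                f"{path}: no {_MAP_SECTION} section and no sidecar map file given"
            )
        calls_csv, map_csv = _split_sections(text)
    from io import StringIO

    calls = pd.read_csv(StringIO(calls_csv), index_col=0, dtype=str)
    calls.index = calls.index.astype(str)
    mm = pd.read_csv(StringIO(map_csv), dtype={"marker": str, "chrom": str})
    mm = mm.rename(columns={"cM": "cm"}).set_index("marker")
    return MarkerMatrix(calls=calls, marker_map=mm[["chrom", "cm", "bp"]])


def _split_sections(text: str) -> tuple[str, str]:
    lines = text.splitlines()
    calls_lines: list[str] = []
    map_lines: list[str] = []
    target = calls_lines
    for line in lines:
        stripped = line.strip()
        if stripped == _CALLS_SECTION:
            target = calls_lines
            continue
        if stripped == _MAP_SECTION:
            target = map_lines
            continue
        if stripped:
            target.append(line)
    return "\n".join(calls_lines), "\n".join(map_lines)


def write_marker_matrix(matrix: MarkerMatrix, path: str | Path) -> None:
    """Write the sectioned single-file dialect understood by
    :func:`read_marker_matrix` (round-trip safe)."""
    path = Path(path)
    mm = matrix.marker_map.reset_index()
    mm = mm.rename(columns={mm.columns[0]: "marker", "cm": "cM"})
    with path.open("w") as fh:
        fh.write(_CALLS_SECTION + "\n")
        matrix.calls.to_csv(fh, index_label="individual")
        fh.write(_MAP_SECTION + "\n")
        mm[["marker", "chrom", "cM", "bp"]].to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# GeneModel
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Structure of one gene on the reference assembly.

    ``exons`` are genomic ``(start, end)`` intervals in ascending genomic
    order; ``cds`` are ``(start, end, phase)`` triples in *transcription*
    order (descending genomic coordinates on the minus strand). ``phase``
    follows GFF3: number of bases to skip at the segment's transcription
    start to reach the first complete codon.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.gene_id}: overlapping exons")
        self.exons = ex
        cds = sorted(self.cds, key=lambda t: t[0], reverse=(self.strand == "-"))
        self.cds = cds
        if cds:
            first_phase = cds[0][2]
            if (self.cds_length() - first_phase) % 3 != 0:
                raise FormatError(
                    f"{self.gene_id}: CDS length {self.cds_length()} not divisible "
                    "by 3 after frame adjustment"
                )

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def contains(self, pos: int) -> bool:
        """True when *pos* lies within the gene span (1-based inclusive)."""
        return self.start <= pos <= self.end


def read_gene_models(gff3_path: str | Path) -> dict[str, GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` objects keyed by gene ID.

    Expects canonical gene -> mRNA -> exon/CDS nesting with 1-based
    inclusive coordinates; one transcript per gene is assumed (the first
    mRNA is used when several are annotated).
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        cds = [(f.start, f.end, int(f.frame)) for f in db.children(parent, featuretype="CDS")]
        exon_span = [(s, e) for s, e in exons]
        for s, e, _ in cds:
            if not any(xs <= s and e <= xe for xs, xe in exon_span):
                raise FormatError(f"{gene.id}: CDS segment [{s},{e}] outside exons")
        models[gene.id] = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, exons=exons, cds=cds,
        )
    return models


def write_gene_models(models: Mapping[str, GeneModel], path: str | Path) -> None:
    """Emit a minimal canonical GFF3 (gene/mRNA/exon/CDS rows)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in models.values():
            mrna_id = f"{g.gene_id}.t1"
            row = "{}\tqtlhotspot\t{}\t{}\t{}\t.\t{}\t{}\tID={};{}\n"
            fh.write(row.format(g.chrom, "gene", g.start, g.end, g.strand, ".",
                                g.gene_id, f"Name={g.gene_id}"))
            fh.write(row.format(g.chrom, "mRNA", g.start, g.end, g.strand, ".",
                                mrna_id, f"Parent={g.gene_id}"))
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tqtlhotspot\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (s, e, phase) in enumerate(sorted(g.cds), start=1):
                # phase stored per transcription-order segment; sorted() only
                # changes row order in the file, phases travel with segments
                fh.write(
                    f"{g.chrom}\tqtlhotspot\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# BulkGenotypeTable
# ---------------------------------------------------------------------------


@dataclass
class BulkGenotypeTable:
    """Accession x variant calls for two labelled extreme-phenotype bulks.

    ``variants`` is indexed by the variant key ``"<chrom>:<pos>"`` with
    columns ``chrom``, ``pos``, ``ref``, ``alt`` and ``gene`` (gene ID or
    ``None``). ``calls`` is indexed by accession with one column per
    variant key; values are ``ref`` (matches the reference line),
    ``nonref`` (harbours any allele different from it) or ``missing``.
    """

    reference_line: str
    bulks: dict[str, list[str]]
    variants: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.bulks) != 2:
            raise FormatError(f"exactly two bulks required, got {list(self.bulks)}")
        (l1, a1), (l2, a2) = self.bulks.items()
        overlap = set(a1) & set(a2)
        if overlap:
            raise FormatError(f"accessions assigned to both bulks: {sorted(overlap)}")
        assigned = set(a1) | set(a2)
        unknown = assigned - set(self.calls.index)
        if unknown:
            raise FormatError(f"bulk accessions without calls: {sorted(unknown)}")
        if self.variants.groupby("chrom")["pos"].apply(lambda s: s.duplicated().any()).any():
            raise FormatError("duplicate variant positions on a chromosome")
        bad = ~self.calls.isin(BULK_CALL_CODES)
        if bad.any().any():
            raise FormatError("bulk calls must be one of 'ref', 'nonref', 'missing'")

    def bulk_calls(self, label: str) -> pd.DataFrame:
        """Calls restricted to the accessions of one bulk."""
        return self.calls.loc[self.bulks[label]]


def variant_key(chrom: str, pos: int) -> str:
    return f"{chrom}:{pos}"


def read_bulk_assignment(source: str | Path | Mapping) -> tuple[str, dict[str, list[str]]]:
    """Load a YAML bulk-assignment config (or accept an equivalent dict).

    Schema::

        reference_line: ICC4958
        bulks:
          highest: [acc1, acc2, ...]
          lowest:  [acc3, acc4, ...]
    """
    if isinstance(source, (str, Path)):
        with Path(source).open() as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    for key in ("reference_line", "bulks"):
        if key not in cfg:
            raise FormatError(f"bulk assignment missing required key {key!r}")
    bulks = {str(k): [str(s) for s in v] for k, v in cfg["bulks"].items()}
    return str(cfg["reference_line"]), bulks


def read_bulk_table(
    vcf_path: str | Path,
    bulk_assignment: str | Path | Mapping,
    gene_models: Mapping[str, GeneModel] | None = None,
) -> BulkGenotypeTable:
    """Build a :class:`BulkGenotypeTable` from a GT-only VCF subset.

    Genotype mapping: ``0/0`` -> ``ref``; any genotype containing a
    non-zero allele -> ``nonref`` (heterozygous accessions harbour an
    allele different from the reference line and are counted as carrying
    variation; this choice is logged); ``./.`` -> ``missing``.
    Multi-allelic records are rejected: the screen concerns biallelic SNPs.
    Variants are assigned to a gene when POS falls within the gene span
    (1-based inclusive); samples not listed in the assignment are ignored.
    """
    reference_line, bulks = read_bulk_assignment(bulk_assignment)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    assigned = [s for members in bulks.values() for s in members]
    absent = [s for s in assigned if s not in samples]
    if absent:
        raise FormatError(f"assigned samples absent from VCF: {absent}")
    logger.info("heterozygous calls are counted as 'nonref' (different from %s)",
                reference_line)

    keys: list[str] = []
    var_rows: list[dict] = []
    call_cols: dict[str, list[str]] = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); split or filter to biallelic SNPs first"
            )
        key = variant_key(rec.CHROM, rec.POS)
        gene = _containing_gene(gene_models, rec.CHROM, rec.POS)
        keys.append(key)
        var_rows.append({
            "chrom": rec.CHROM, "pos": rec.POS,
            "ref": rec.REF, "alt": rec.ALT[0], "gene": gene,
        })
        col = []
        for gt in rec.genotypes:
            alleles = [a for a in gt[:-1]]  # last element is the phased flag
            if any(a > 0 for a in alleles):
                col.append("nonref")
            elif any(a < 0 for a in alleles):
                col.append("missing")
            else:
                col.append("ref")
        call_cols[key] = col
    variants = pd.DataFrame(var_rows, index=keys)
    calls = pd.DataFrame(call_cols, index=samples).loc[assigned]
    return BulkGenotypeTable(
        reference_line=reference_line, bulks=bulks, variants=variants, calls=calls
    )


def _containing_gene(models: Mapping[str, GeneModel] | None, chrom: str, pos: int):
    if not models:
        return None
    for g in models.values():
        if g.chrom == chrom and g.contains(pos):
            return g.gene_id
    return None


def write_bulk_vcf(table: BulkGenotypeTable, path: str | Path) -> None:
    """Write the table as a minimal VCF 4.2 (GT only, homozygous calls).

    Accessions are inbred lines, so ``nonref`` is emitted as ``1/1``.
    """
    samples = list(table.calls.index)
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(table.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gt_map = {"ref": "0/0", "nonref": "1/1", "missing": "./."}
        order = table.variants.sort_values(["chrom", "pos"]).index
        for key in order:
            v = table.variants.loc[key]
            gts = "\t".join(gt_map[c] for c in table.calls[key])
            fh.write(f"{v.chrom}\t{v.pos}\t{key}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# TraitTable
# ---------------------------------------------------------------------------

#: columns that, when present, form the row key of a TraitTable
TRAIT_KEY_COLUMNS = ("individual", "genotype_class", "family", "treatment", "replicate")


@dataclass
class TraitTable:
    """Per-plant/per-plot trait measurements with per-column units."""

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        key_cols = [c for c in TRAIT_KEY_COLUMNS if c in self.data.columns]
        if key_cols and self.data.duplicated(subset=key_cols).any():
            raise FormatError(f"duplicate rows for key columns {key_cols}")
        for col in self.units:
            if col not in self.data.columns:
                raise FormatError(f"unit registered for unknown column {col!r}")

    def trait_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in TRAIT_KEY_COLUMNS]


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a trait CSV; an optional second line ``#units,...`` registers
    units positionally under the header columns."""
    path = Path(path)
    lines = path.read_text().splitlines()
    units: dict[str, str] = {}
    body = lines
    if len(lines) > 1 and lines[1].startswith("#units"):
        header = lines[0].split(",")
        unit_row = lines[1].split(",")[1:]
        units = {c: u for c, u in zip(header, unit_row) if u}
        body = [lines[0]] + lines[2:]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(body)))
    return TraitTable(data=df, units=units)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    cols = list(table.data.columns)
    with Path(path).open("w") as fh:
        fh.write(",".join(cols) + "\n")
        if table.units:
            fh.write("#units," + ",".join(table.units.get(c, "") for c in cols) + "\n")
        table.data.to_csv(fh, index=False, header=False)
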