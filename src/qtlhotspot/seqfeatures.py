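"""Sequence-level characterization of candidate genes.

SNP effect calls against a :class:`~qtlhotspot.io_formats.GeneModel`
(exonic/intronic/UTR placement, synonymous vs non-synonymous vs nonsense,
residue-change notation such as ``I149S``), CDS translation and average
protein molecular weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

REGION_EXONIC = "exonic"
REGION_INTRONIC = "intronic"
REGION_UTR = "UTR"
REGION_INTERGENIC = "intergenic"

CONSEQ_SYN = "synonymous"
CONSEQ_NONSYN = "non-synonymous"
CONSEQ_NONSENSE = "nonsense"
CONSEQ_NONE = "none"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard nuclear codon table.

    The sequence must be a codon multiple; a non-ATG start is accepted
    with a warning. A trailing stop codon is removed from the protein; an
    internal stop is an error. Codons containing ambiguous bases
    translate to ``X`` with a warning.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a positive codon multiple")
    if not cds.startswith("ATG"):
        logger.warning("CDS does not start with ATG (got %s)", cds[:3])
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if set(codon) - set("ACGT"):
            logger.warning("ambiguous codon %s at position %d; emitting X", codon, i + 1)
            aas.append("X")
        else:
            aas.append(str(Seq(codon).translate()))
    protein = "".join(aas)
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon at residue {protein.index('*') + 1}")
    return protein


def protein_mw(protein: str) -> float:
    """Average molecular weight of a polypeptide chain in kDa.

    Sum of average residue masses plus one water per chain; only the 20
    standard amino acids are accepted.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein.upper()) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return molecular_weight(protein.upper(), seq_type="protein", monoisotopic=False) / 1000.0


@dataclass
class SnpEffect:
    """Effect of one biallelic SNP on one gene model."""

    variant: str                 # "<chrom>:<pos>"
    gene_id: str
    region: str                  # exonic / intronic / UTR / intergenic
    consequence: str             # synonymous / non-synonymous / nonsense / none
    residue_change: str | None   # e.g. "I149S"; None outside the CDS
    exon_index: int | None       # 1-based, transcription order; None outside exons


def classify_snp(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
    genome: str,
    genome_offset: int = 0,
) -> SnpEffect:
    """Classify one SNP against a gene model and its genomic sequence.

    Parameters
    ----------
    pos, ref, alt
        1-based chromosome position and plus-strand alleles.
    genome
        Plus-strand sequence of the chromosome (or a slice of it covering
        the gene); *genome_offset* is the 1-based chromosome coordinate of
        ``genome[0]`` minus one, so ``genome[pos - 1 - genome_offset]`` is
        the base at *pos*.

    For CDS hits the codon is rebuilt strand-aware from the spliced CDS,
    both alleles are translated and the residue change is reported in
    one-letter, 1-based, reference-first notation (``I149S``).
    """
    if chrom != model.chrom:
        return SnpEffect(f"{chrom}:{pos}", model.gene_id, REGION_INTERGENIC,
                         CONSEQ_NONE, None, None)
    base = genome[pos - 1 - genome_offset].upper()
    if base != ref.upper():
        raise ValueError(
            f"allele mismatch at {chrom}:{pos}: genome has {base}, REF is {ref}"
        )
    key = f"{chrom}:{pos}"
    if not model.contains(pos):
        return SnpEffect(key, model.gene_id, REGION_INTERGENIC, CONSEQ_NONE, None, None)

    exons_tx = model.exons if model.strand == "+" else list(reversed(model.exons))
    exon_index = next(
        (i for i, (s, e) in enumerate(exons_tx, start=1) if s <= pos <= e), None
    )
    if exon_index is None:
        return SnpEffect(key, model.gene_id, REGION_INTRONIC, CONSEQ_NONE, None, None)
    in_cds = any(s <= pos <= e for s, e, _ in model.cds)
    if not in_cds:
        return SnpEffect(key, model.gene_id, REGION_UTR, CONSEQ_NONE, None, exon_index)

    # spliced CDS coordinates in transcription order
    coords: list[int] = []
    for s, e, _ in model.cds:  # already transcription-ordered
        if model.strand == "+":
            coords.extend(range(s, e + 1))
        else:
            coords.extend(range(e, s - 1, -1))
    offset = coords.index(pos)
    codon_idx = offset // 3
    within = offset % 3

    def base_at(genomic_pos: int) -> str:
        b = genome[genomic_pos - 1 - genome_offset].upper()
        return b if model.strand == "+" else b.translate(_COMPLEMENT)

    codon_positions = coords[codon_idx * 3: codon_idx * 3 + 3]
    ref_codon = "".join(base_at(p) for p in codon_positions)
    alt_base = alt.upper() if model.strand == "+" else alt.upper().translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        consequence = CONSEQ_SYN
    elif alt_aa == "*":
        consequence = CONSEQ_NONSENSE
    else:
        consequence = CONSEQ_NONSYN
    change = f"{ref_aa}{codon_idx + 1}{alt_aa}"
    return SnpEffect(key, model.gene_id, REGION_EXONIC, consequence, change, exon_index)
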