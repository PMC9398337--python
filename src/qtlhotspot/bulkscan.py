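"""Extreme-bulk variant prioritization via the variation index.

The variation index (VI) of a SNP within one bulk is the fraction of that
bulk's accessions whose genotype differs from a designated reference line,
computed over non-missing calls only. The contrast

    dVI = VI(highest-phenotype bulk) - VI(lowest-phenotype bulk)

prioritizes candidate genes: a strongly negative dVI means the reference
line's allele travels with the high phenotype, a strongly positive dVI
implicates the non-reference allele. SNPs whose VI does not exceed a
threshold (default 0.3) in either bulk are uninformative and removed;
genes are ranked by the largest |dVI| among their surviving SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import BulkGenotypeTable

logger = logging.getLogger(__name__)

DIRECTION_REF = "reference-allele-contributes"
DIRECTION_NONREF = "nonreference-allele-contributes"
DIRECTION_NONE = "none"

DEFAULT_VI_THRESHOLD = 0.3


def variation_index(calls: Sequence[str] | pd.Series) -> float:
    """Fraction of non-missing calls that differ from the reference line.

    Parameters
    ----------
    calls
        One bulk's calls at one variant, each ``ref``/``nonref``/``missing``.

    Raises
    ------
    ValueError
        If every call is missing (the index is undefined).
    """
    calls = list(calls)
    n_nonref = sum(c == "nonref" for c in calls)
    n_called = sum(c != "missing" for c in calls)
    if n_called == 0:
        raise ValueError("variation index undefined: all calls missing")
    return n_nonref / n_called


def delta_variation_index(vi_highest: float, vi_lowest: float) -> float:
    """VI(highest bulk) minus VI(lowest bulk); in [-1, 1]."""
    for name, v in (("vi_highest", vi_highest), ("vi_lowest", vi_lowest)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return vi_highest - vi_lowest


def interpret_direction(delta: float) -> str:
    """Map the sign of dVI to the contributing allele.

    Negative: the reference allele contributes to the (high) trait value;
    positive: the non-reference allele contributes; zero: no signal.
    """
    if not -1.0 <= delta <= 1.0:
        raise ValueError(f"delta={delta} outside [-1, 1]")
    if delta < 0:
        return DIRECTION_REF
    if delta > 0:
        return DIRECTION_NONREF
    return DIRECTION_NONE


def compute_vi_records(
    table: BulkGenotypeTable,
    highest_label: str = "highest",
    lowest_label: str = "lowest",
) -> pd.DataFrame:
    """Per-variant VI in both bulks plus their contrast.

    Returns a DataFrame indexed by variant key with columns
    ``vi_highest``, ``vi_lowest``, ``n_called_highest``, ``n_called_lowest``,
    ``delta``, ``direction``, ``gene``, ``chrom``, ``pos``.
    """
    for label in (highest_label, lowest_label):
        if label not in table.bulks:
            raise ValueError(f"bulk label {label!r} not in table ({list(table.bulks)})")
    rows = []
    for key, var in table.variants.iterrows():
        vis = {}
        ns = {}
        for label in (highest_label, lowest_label):
            calls = table.bulk_calls(label)[key]
            try:
                vis[label] = variation_index(calls)
            except ValueError as exc:
                raise ValueError(f"variant {key}, bulk {label!r}: {exc}") from exc
            ns[label] = int((calls != "missing").sum())
        delta = delta_variation_index(vis[highest_label], vis[lowest_label])
        rows.append({
            "variant": key, "chrom": var["chrom"], "pos": var["pos"],
            "gene": var["gene"],
            "vi_highest": vis[highest_label], "vi_lowest": vis[lowest_label],
            "n_called_highest": ns[highest_label], "n_called_lowest": ns[lowest_label],
            "delta": delta, "direction": interpret_direction(delta),
        })
    return pd.DataFrame(rows).set_index("variant")


def apply_vi_filters(records: pd.DataFrame, threshold: float = DEFAULT_VI_THRESHOLD) -> pd.DataFrame:
    """Keep variants whose VI strictly exceeds *threshold* in either bulk.

    A variant with VI <= threshold in both bulks carries too little
    variation in either extreme to be informative and is dropped; a VI
    above the threshold in any one bulk keeps the variant irrespective of
    the other bulk. A VI exactly at the threshold does not keep a variant
    (strict inequality; logged).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold={threshold} outside (0, 1)")
    if records.empty:
        return records
    keep = (records["vi_highest"] > threshold) | (records["vi_lowest"] > threshold)
    logger.info(
        "VI filter (>%.3g strict): kept %d, dropped %d of %d variants",
        threshold, int(keep.sum()), int((~keep).sum()), len(records),
    )
    return records[keep]


@dataclass
class PrioritizationResult:
    """Ranked gene-level candidates plus variants outside any gene.

    ``genes`` columns: ``gene``, ``variant`` (best variant, argmax |dVI|,
    ties to the smaller position), ``vi_highest``, ``vi_lowest``, ``delta``,
    ``direction``, ``rank`` (1 = strongest |dVI|; ties broken by gene ID).
    """

    genes: pd.DataFrame
    intergenic: pd.DataFrame


def prioritize_genes(
    table: BulkGenotypeTable,
    threshold: float = DEFAULT_VI_THRESHOLD,
    highest_label: str = "highest",
    lowest_label: str = "lowest",
) -> PrioritizationResult:
    """Rank genes by the strongest VI contrast among their variants.

    A gene is removed when all of its variants fail the VI filter. Variants
    assigned to no gene survive filtering into ``intergenic`` but are not
    ranked.
    """
    records = compute_vi_records(table, highest_label, lowest_label)
    kept = apply_vi_filters(records, threshold)
    in_gene = kept[kept["gene"].notna()]
    intergenic = kept[kept["gene"].isna()].copy()
    if in_gene.empty:
        logger.warning("no variant in any gene survived the VI filter")
        empty = pd.DataFrame(
            columns=["gene", "variant", "vi_highest", "vi_lowest",
                     "delta", "direction", "rank"]
        )
        return PrioritizationResult(genes=empty, intergenic=intergenic)
    best_rows = []
    for gene, grp in in_gene.groupby("gene", sort=False):
        # best variant: largest |dVI|, ties resolved to the smaller position
        grp = grp.assign(absdelta=grp["delta"].abs())
        grp = grp.sort_values(["absdelta", "pos"], ascending=[False, True],
                              kind="stable")
        top = grp.iloc[0]
        best_rows.append({
            "gene": gene, "variant": top.name,
            "vi_highest": top["vi_highest"], "vi_lowest": top["vi_lowest"],
            "delta": top["delta"], "direction": top["direction"],
            "absdelta": top["absdelta"],
        })
    genes = pd.DataFrame(best_rows)
    genes = genes.sort_values(["absdelta", "gene"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    genes["rank"] = genes.index + 1
    genes = genes.drop(columns="absdelta")
    return PrioritizationResult(genes=genes, intergenic=intergenic)


def write_ranking_tsv(result: PrioritizationResult, path) -> None:
    """TSV ranking with columns gene, variant, VI_high, VI_low, delta,
    direction, rank."""
    out = result.genes.rename(columns={"vi_highest": "VI_high", "vi_lowest": "VI_low"})
    out[["gene", "variant", "VI_high", "VI_low", "delta", "direction", "rank"]].to_csv(
        path, sep="\t", index=False
    )
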