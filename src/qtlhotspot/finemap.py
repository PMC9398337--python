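"""Recombinant analysis and substitution mapping on marker matrices.

Given near-isogenic recombinant families genotyped at ordered markers and
classified by a progeny test into high/low phenotype groups, the causal
interval is delimited as the maximal run of markers that perfectly
cosegregate with the classes (donor-homozygous in every high family,
recipient-homozygous in every low family), reported flank-to-flank: the
bounding markers are the nearest markers that break cosegregation (or the
terminal markers of the map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MarkerMatrix, MISSING_CODE

logger = logging.getLogger(__name__)

HIGH, LOW = "high", "low"


# ---------------------------------------------------------------------------
# Graphical genotypes
# ---------------------------------------------------------------------------


@dataclass
class GraphicalGenotype:
    """Chromosome-painting representation of one individual.

    ``segments`` maps chromosome -> ordered ``(state, start_bp, end_bp)``
    tuples tiling the genotyped span. Boundaries between discordant
    adjacent markers sit at their physical midpoint; stretches of missing
    calls whose flanking states disagree appear as ``unknown`` segments.
    """

    individual: str
    segments: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def state_at(self, chrom: str, bp: int) -> str:
        for state, start, end in self.segments.get(chrom, []):
            if start <= bp <= end:
                return state
        raise KeyError(f"{chrom}:{bp} outside genotyped span")


def graphical_genotype(matrix: MarkerMatrix, individual: str) -> GraphicalGenotype:
    """Paint one individual's chromosomes from its marker calls.

    Missing calls are imputed to the shared state of the nearest
    non-missing neighbours when those agree (a terminal missing call takes
    its single neighbour's state); disagreement leaves an ``unknown``
    segment between the midpoints.
    """
    row = matrix.calls.loc[individual]
    segments: dict[str, list[tuple[str, int, int]]] = {}
    for chrom in dict.fromkeys(matrix.marker_map["chrom"]):
        names = matrix.chromosome_markers(chrom)
        bps = matrix.marker_map.loc[names, "bp"].to_numpy()
        states = [row[m] for m in names]
        if all(s == MISSING_CODE for s in states):
            raise ValueError(f"{individual}: all markers missing on {chrom}")
        states = _impute_missing(states)
        segs: list[tuple[str, int, int]] = []
        seg_state = states[0]
        seg_start = int(bps[0])
        for i in range(1, len(states)):
            if states[i] != seg_state:
                boundary = int((bps[i - 1] + bps[i]) // 2)
                segs.append((seg_state, seg_start, boundary))
                seg_state = states[i]
                seg_start = boundary + 1
        segs.append((seg_state, seg_start, int(bps[-1])))
        segments[chrom] = segs
    return GraphicalGenotype(individual=individual, segments=segments)


def _impute_missing(states: list[str]) -> list[str]:
    out = list(states)
    n = len(out)
    for i, s in enumerate(out):
        if s != MISSING_CODE:
            continue
        left = next((states[j] for j in range(i - 1, -1, -1)
                     if states[j] != MISSING_CODE), None)
        right = next((states[j] for j in range(i + 1, n)
                      if states[j] != MISSING_CODE), None)
        if left is not None and right is not None:
            out[i] = left if left == right else "unknown"
        else:
            out[i] = left if left is not None else right
    return out


# ---------------------------------------------------------------------------
# Genotype classes and recombinants
# ---------------------------------------------------------------------------


def enumerate_genotype_classes(
    matrix: MarkerMatrix, marker_subset: Sequence[str]
) -> pd.DataFrame:
    """Group individuals by their call vector over *marker_subset*.

    Missing is its own symbol, so individuals differing only in missing
    patterns fall in distinct classes. Returns a DataFrame with columns
    ``genotype`` (the joined call vector), ``count`` and ``members``,
    sorted by descending count (ties by genotype string).
    """
    marker_subset = list(marker_subset)
    if not marker_subset:
        raise ValueError("marker subset is empty")
    unknown = [m for m in marker_subset if m not in matrix.calls.columns]
    if unknown:
        raise KeyError(f"markers not in matrix: {unknown}")
    vectors = matrix.calls[marker_subset].agg("".join, axis=1)
    grouped = vectors.groupby(vectors).groups
    rows = [
        {"genotype": g, "count": len(ids), "members": sorted(map(str, ids))}
        for g, ids in grouped.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["count", "genotype"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def find_recombinants(
    matrix: MarkerMatrix, flank_left: str, flank_right: str
) -> list[str]:
    """Individuals with at least one genotype state change between flanks.

    An individual is a recombinant iff its non-missing calls at the flanks
    and all internal markers are not all the same state.
    """
    mm = matrix.marker_map
    for m in (flank_left, flank_right):
        if m not in mm.index:
            raise KeyError(f"flank marker {m!r} not in matrix")
    if mm.loc[flank_left, "chrom"] != mm.loc[flank_right, "chrom"]:
        raise ValueError("flanking markers lie on different chromosomes")
    if mm.loc[flank_left, "bp"] >= mm.loc[flank_right, "bp"]:
        raise ValueError("flank_left must precede flank_right")
    chrom = mm.loc[flank_left, "chrom"]
    names = matrix.chromosome_markers(chrom)
    i0, i1 = names.index(flank_left), names.index(flank_right)
    region = names[i0:i1 + 1]
    out = []
    for ind in matrix.individuals:
        states = {matrix.calls.at[ind, m] for m in region} - {MISSING_CODE}
        if len(states) > 1:
            out.append(ind)
    return out


# ---------------------------------------------------------------------------
# Progeny test
# ---------------------------------------------------------------------------


@dataclass
class ProgenyTestResult:
    """Largest-gap split of family trait means into high/low groups."""

    classes: dict[str, str]  # family -> "high" | "low"
    gap: float               # size of the largest gap between sorted means
    separation_ratio: float  # largest gap / next-largest gap (inf if 2 families)


def progeny_test_classify(family_means: Mapping[str, float]) -> ProgenyTestResult:
    """Split families at the largest gap between consecutive sorted means.

    Families above the gap are ``high``, below are ``low``. With all means
    equal there is no gap and classification requires an external
    threshold, which this function refuses to invent.
    """
    if len(family_means) < 2:
        raise ValueError("need at least two families")
    means = pd.Series(family_means, dtype=float)
    if not np.isfinite(means).all():
        raise ValueError("family means must be finite")
    order = means.sort_values()
    gaps = order.diff().dropna()
    if float(gaps.max()) == 0.0:
        raise ValueError(
            "all family means equal: no gap to split at; supply an external threshold"
        )
    cut = int(np.argmax(gaps.to_numpy()))  # gap between order[cut] and order[cut+1]
    gap = float(gaps.iloc[cut])
    others = np.delete(gaps.to_numpy(), cut)
    second = float(others.max()) if len(others) else 0.0
    ratio = gap / second if second > 0 else float("inf")
    classes = {}
    for i, fam in enumerate(order.index):
        classes[str(fam)] = HIGH if i > cut else LOW
    logger.info("progeny test: gap=%.4g, separation ratio=%.3g, %d high / %d low",
                gap, ratio, sum(c == HIGH for c in classes.values()),
                sum(c == LOW for c in classes.values()))
    return ProgenyTestResult(classes=classes, gap=gap, separation_ratio=ratio)


# ---------------------------------------------------------------------------
# Interval delimitation
# ---------------------------------------------------------------------------


@dataclass
class DelimitedInterval:
    """A causal interval bounded by the nearest non-cosegregating markers."""

    left_marker: str
    right_marker: str
    inner_markers: list[str]
    span_bp: int
    span_cm: float


def _cosegregates(matrix: MarkerMatrix, marker: str, classes: Mapping[str, str]) -> bool:
    for fam, cls in classes.items():
        call = matrix.calls.at[fam, marker]
        want = "B" if cls == HIGH else "A"
        if call != want:
            return False
    return True


def delimit_interval(
    matrix: MarkerMatrix, classes: Mapping[str, str]
) -> DelimitedInterval:
    """Delimit the causal interval by marker-phenotype cosegregation.

    A marker cosegregates iff every high family is donor-homozygous (B)
    and every low family recipient-homozygous (A) at it. The result is the
    maximal contiguous run of cosegregating markers together with its
    immediate flanking non-cosegregating (or terminal) markers; the
    physical span is the distance between the flanking markers.

    Raises
    ------
    ValueError
        If a family is not homozygous at an in-region marker, if both
        classes are not present, if no marker cosegregates, or if several
        disjoint cosegregating runs exist (ambiguous, surfaced rather
        than guessed).
    """
    classes = {str(k): v for k, v in classes.items()}
    present = set(classes.values())
    if present != {HIGH, LOW}:
        raise ValueError(f"both phenotype classes required, got {sorted(present)}")
    unknown = [f for f in classes if f not in matrix.calls.index]
    if unknown:
        raise KeyError(f"families not in matrix: {unknown}")
    sub = matrix.calls.loc[list(classes)]
    het_or_missing = ~sub.isin({"A", "B"})
    if het_or_missing.any().any():
        r, c = next(zip(*het_or_missing.values.nonzero()))
        raise ValueError(
            f"family {sub.index[r]!r} is not homozygous at marker "
            f"{sub.columns[c]!r} (call {sub.iloc[r, c]!r})"
        )
    chroms = set(matrix.marker_map["chrom"])
    if len(chroms) != 1:
        raise ValueError("interval delimitation expects markers of one chromosome")
    names = matrix.markers
    coseg = [_cosegregates(matrix, m, classes) for m in names]
    runs = _runs(coseg)
    if not runs:
        raise ValueError("no interval consistent with phenotype classes: "
                         "no marker cosegregates")
    if len(runs) > 1:
        pretty = [f"{names[a]}..{names[b]}" for a, b in runs]
        raise ValueError(f"multiple disjoint cosegregating runs: {pretty}")
    a, b = runs[0]
    left_idx = max(a - 1, 0)
    right_idx = min(b + 1, len(names) - 1)
    left, right = names[left_idx], names[right_idx]
    mm = matrix.marker_map
    return DelimitedInterval(
        left_marker=left, right_marker=right,
        inner_markers=names[a:b + 1],
        span_bp=int(mm.loc[right, "bp"] - mm.loc[left, "bp"]),
        span_cm=float(mm.loc[right, "cm"] - mm.loc[left, "cm"]),
    )


def _runs(flags: Sequence[bool]) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def diagnostic_marker_score(
    marker: str, matrix: MarkerMatrix, classes: Mapping[str, str]
) -> float:
    """Fraction of families whose genotype at *marker* matches its class
    (B with high, A with low); missing calls are excluded from the
    denominator. 1.0 means a perfect diagnostic marker."""
    if marker not in matrix.calls.columns:
        raise KeyError(f"marker {marker!r} not in matrix")
    n_match = n_called = 0
    for fam, cls in classes.items():
        call = matrix.calls.at[str(fam), marker]
        if call == MISSING_CODE:
            continue
        n_called += 1
        if call == ("B" if cls == HIGH else "A"):
            n_match += 1
    if n_called == 0:
        raise ValueError(f"marker {marker!r}: all family calls missing")
    return n_match / n_called


# ---------------------------------------------------------------------------
# Genome recovery
# ---------------------------------------------------------------------------


def genome_recovery(
    matrix: MarkerMatrix,
    individual: str,
    recipient_state: str = "A",
    exclude_markers: Sequence[str] = (),
) -> float:
    """Percent recurrent-parent genome over background markers.

    Markers listed in *exclude_markers* (the target region) are ignored;
    heterozygous markers count as half recovered; markers are weighted
    equally (marker count, not physical length). Returns a percentage.
    """
    row = matrix.calls.loc[individual].drop(labels=list(exclude_markers), errors="ignore")
    row = row[row != MISSING_CODE]
    if row.empty:
        raise ValueError(f"{individual}: no non-missing background marker")
    n_rec = int((row == recipient_state).sum())
    n_het = int((row == "H").sum())
    return 100.0 * (n_rec + 0.5 * n_het) / len(row)
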