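"""Novel lncRNA identification and positional classification.

lncRNAs are the intersection of two independent non-coding calls (e.g.
CNCI and CPC run upstream) among assembled transcripts of spliced length
>= 200 nt. Each lncRNA is then classified against a reference annotation
into one of five positional categories by a fixed decision cascade:

1. no overlap with any annotated gene span       -> intergenic
2. overlaps annotated exon(s), opposite strand   -> antisense_exonic
3. overlaps annotated exon(s), same strand       -> sense_overlapping
4. fully inside an intron, same strand           -> intronic_sense
                           opposite strand       -> intronic_antisense

Coordinates follow the GTF convention: 1-based, inclusive on both ends;
overlap means >= 1 shared base. A transcript overlapping a gene span
without touching an exon but straddling the gene boundary (so not fully
intronic) takes the exonic-overlap class of its strand relation — locus
overlap outranks intronic containment.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GenomicFeature",
    "LNC_CATEGORIES",
    "intersect_noncoding_calls",
    "spliced_length",
    "length_filter",
    "classify_position",
    "classify_all",
    "class_summary",
]

log = logging.getLogger(__name__)

LNC_CATEGORIES = (
    "intergenic",
    "antisense_exonic",
    "sense_overlapping",
    "intronic_sense",
    "intronic_antisense",
)


@dataclass(frozen=True)
class GenomicFeature:
    """A GTF-style feature: 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_type: str  # gene | transcript | exon
    gene_id: str
    transcript_id: str = ""

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def overlaps(self, other: "GenomicFeature") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def intersect_noncoding_calls(calls_a: Iterable[str], calls_b: Iterable[str]) -> set[str]:
    """Transcripts called non-coding by *both* upstream classifiers."""
    return set(calls_a) & set(calls_b)


def spliced_length(exons: Sequence[GenomicFeature]) -> int:
    return sum(e.end - e.start + 1 for e in exons)


def length_filter(
    features: Sequence[GenomicFeature], min_len: int = 200
) -> list[GenomicFeature]:
    """Keep transcripts (and their exons) with spliced length >= min_len.

    ``features`` mixes transcript- and exon-level records; exons are
    grouped by transcript_id. A transcript record with no exons is a
    malformed input and is rejected.
    """
    exons = defaultdict(list)
    for f in features:
        if f.feature_type == "exon":
            exons[f.transcript_id].append(f)
    keep_ids = set()
    for f in features:
        if f.feature_type != "transcript":
            continue
        if f.transcript_id not in exons:
            raise ValueError(f"transcript {f.transcript_id!r} has no exons")
        if spliced_length(exons[f.transcript_id]) >= min_len:
            keep_ids.add(f.transcript_id)
    return [
        f
        for f in features
        if (f.feature_type in ("transcript", "exon") and f.transcript_id in keep_ids)
        or f.feature_type == "gene"
    ]


def _annotation_index(annotation: Sequence[GenomicFeature]):
    """Per-chromosome gene spans and exon lists, derived deterministically.

    Gene spans come from 'gene' records when present, otherwise from the
    union of each gene's exons, so partial annotations still classify.
    """
    genes: dict[str, dict[str, tuple[int, int, str]]] = defaultdict(dict)
    exons: dict[str, list[GenomicFeature]] = defaultdict(list)
    for f in sorted(annotation, key=lambda f: (f.chrom, f.start, f.end, f.gene_id)):
        if f.feature_type == "gene":
            genes[f.chrom][f.gene_id] = (f.start, f.end, f.strand)
        elif f.feature_type == "exon":
            exons[f.chrom].append(f)
            s, e, st = genes[f.chrom].get(f.gene_id, (f.start, f.end, f.strand))
            genes[f.chrom][f.gene_id] = (min(s, f.start), max(e, f.end), st)
    return genes, exons


def classify_position(
    lnc: GenomicFeature, annotation: Sequence[GenomicFeature]
) -> str:
    """Positional category of one lncRNA against the reference annotation."""
    genes, exons = _annotation_index(annotation)
    if lnc.chrom not in genes:
        log.info("chromosome %s absent from annotation; %s classified intergenic",
                 lnc.chrom, lnc.transcript_id or lnc.gene_id)
        return "intergenic"
    overlapping = {
        gid: (s, e, st)
        for gid, (s, e, st) in genes[lnc.chrom].items()
        if s <= lnc.end and lnc.start <= e
    }
    if not overlapping:
        return "intergenic"
    hit_exons = [
        x for x in exons[lnc.chrom]
        if x.gene_id in overlapping and x.start <= lnc.end and lnc.start <= x.end
    ]
    if hit_exons:
        if any(x.strand != lnc.strand for x in hit_exons):
            return "antisense_exonic"
        return "sense_overlapping"
    # No exon overlap: intronic if fully inside one containing gene's span.
    containing = [
        (gid, st) for gid, (s, e, st) in overlapping.items()
        if s <= lnc.start and lnc.end <= e
    ]
    if containing:
        same = any(st == lnc.strand for _, st in containing)
        return "intronic_sense" if same else "intronic_antisense"
    # Straddles a gene boundary without exon overlap: locus-overlap class.
    same = any(st == lnc.strand for s, e, st in overlapping.values())
    return "sense_overlapping" if same else "antisense_exonic"


def classify_all(
    lncs: Sequence[GenomicFeature], annotation: Sequence[GenomicFeature]
) -> dict[str, str]:
    """transcript_id -> category for a batch of lncRNA transcripts."""
    return {
        (l.transcript_id or l.gene_id): classify_position(l, annotation)
        for l in lncs
    }


def class_summary(classes: Iterable[str] | dict[str, str]) -> dict[str, float]:
    """Proportion of lncRNAs in each positional category (sums to 1)."""
    values = list(classes.values()) if isinstance(classes, dict) else list(classes)
    if not values:
        raise ValueError("no classifications to summarize")
    bad = set(values) - set(LNC_CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    n = len(values)
    return {c: values.count(c) / n for c in LNC_CATEGORIES}
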