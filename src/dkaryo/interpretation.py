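"""Clinical flagging of CNV calls against annotation interval tracks.

A call is flagged for reporting when it is large enough for its direction
(duplications >= 2.0 Mb, deletions >= 1.0 Mb), contains at least one gene
interval, and is not explained by a population-common CNV (reciprocal
overlap below 0.5 with every common-variant interval). Calls of any size
that touch a named pathogenic region (syndrome track) are flagged
regardless of size.

Tracks are plain BED files supplied by the user (4th column = name); the
package never fetches databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .cnv_calling import CnvCall
from ._util import log

DUP_MIN_BP = 2_000_000
DEL_MIN_BP = 1_000_000
COMMON_OVERLAP_FRAC = 0.5


@dataclass
class AnnotationTracks:
    gene_track: dict  # chrom -> IntervalTree of (start, end, name)
    common_cnv_track: dict
    pathogenic_region_track: dict = field(default_factory=dict)

    @staticmethod
    def from_bed(gene_path=None, common_path=None, pathogenic_path=None) -> "AnnotationTracks":
        return AnnotationTracks(
            gene_track=read_bed_track(gene_path) if gene_path else {},
            common_cnv_track=read_bed_track(common_path) if common_path else {},
            pathogenic_region_track=read_bed_track(pathogenic_path) if pathogenic_path else {},
        )


def read_bed_track(path) -> dict:
    """BED (chrom, start, end[, name]) -> per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0][3:] if parts[0].startswith("chr") else parts[0]
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: interval end <= start")
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    return trees


def make_track(intervals) -> dict:
    """Build a track from (chrom, start, end, name) tuples (tests, simulations)."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    return trees


@dataclass
class FlaggedCall:
    call: CnvCall
    flagged: bool
    reasons: list

    def __post_init__(self):
        if self.flagged and not self.reasons:
            raise ValueError("flagged call must carry reasons")


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def flag_call(
    call: CnvCall,
    tracks: AnnotationTracks,
    dup_min: int = DUP_MIN_BP,
    del_min: int = DEL_MIN_BP,
    common_overlap_frac: float = COMMON_OVERLAP_FRAC,
) -> FlaggedCall:
    reasons: list[str] = []

    # named pathogenic regions force a flag at any size
    named = tracks.pathogenic_region_track.get(call.chrom, None)
    named_hit = bool(named and named.overlap(call.start, call.end))
    if named_hit:
        reasons.append("named_region_hit")

    size_ok = call.size >= (dup_min if call.sign == "DUP" else del_min)
    if size_ok:
        reasons.append("size_rule")

    if not tracks.gene_track:
        log.warning("no gene track supplied; size rule applied alone")
        gene_hit = True
    else:
        genes = tracks.gene_track.get(call.chrom, None)
        gene_hit = bool(genes and genes.overlap(call.start, call.end))
    if gene_hit and tracks.gene_track:
        reasons.append("gene_containing")

    common = tracks.common_cnv_track.get(call.chrom, None)
    common_hit = False
    if common:
        for iv in common.overlap(call.start, call.end):
            if _reciprocal_overlap(call.start, call.end, iv.begin, iv.end) >= common_overlap_frac:
                common_hit = True
                break
    if common_hit:
        reasons.append("common_variant_overlap")

    flagged = named_hit or (size_ok and gene_hit and not common_hit)
    return FlaggedCall(call, flagged, reasons)
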