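"""Mappability-adjusted genome partition.

All read-depth analysis runs on a fixed ordered partition of the genome into
bins ("target regions"). Bin boundaries are placed so that every bin carries
approximately the same number of *mappable* bases rather than the same
physical length: in poorly mappable territory bins stretch, which equalizes
expected read counts across bins and suppresses false deletion calls in
low-mappability regions.

The default target of 285 kb mappable bases per bin makes the downstream
three-consecutive-bin CNV standard correspond to a ~855 kb detection floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genomes import GRCH37_SIZES, sort_key
from ._util import digest_lines, log

DEFAULT_TARGET_SPAN = 285_000


@dataclass(frozen=True)
class Bin:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    mappable_span: int  # mappable bp within [start, end)
    gc_fraction: float = 0.5

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"bin end <= start: {self.chrom}:{self.start}-{self.end}")
        if self.mappable_span > self.end - self.start:
            raise ValueError("mappable_span exceeds bin length")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction outside [0, 1]")


@dataclass(frozen=True)
class BinSet:
    """Ordered, per-chromosome contiguous partition of mappable territory."""

    bins: tuple[Bin, ...]
    genome_build: str = "GRCh37"
    target_mappable_span: int = DEFAULT_TARGET_SPAN
    _checksum: str = field(default="", compare=False)

    def __post_init__(self):
        prev = None
        for b in self.bins:
            if prev is not None and prev.chrom == b.chrom:
                if b.start < prev.end:
                    raise ValueError(
                        f"bins overlap or are unsorted: {prev.chrom}:{prev.start}-{prev.end} "
                        f"then {b.chrom}:{b.start}-{b.end}"
                    )
            prev = b

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def chroms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.bins:
            seen.setdefault(b.chrom, None)
        return tuple(seen)

    @property
    def checksum(self) -> str:
        return digest_lines(
            f"{b.chrom}\t{b.start}\t{b.end}\t{b.mappable_span}" for b in self.bins
        )

    def chrom_slice(self, chrom: str) -> tuple[int, int]:
        """(first, last+1) bin indices of ``chrom``; (0, 0) if absent."""
        idx = [i for i, b in enumerate(self.bins) if b.chrom == chrom]
        if not idx:
            return (0, 0)
        return (idx[0], idx[-1] + 1)

    def with_gc(self, gc: "list[float] | tuple[float, ...]") -> "BinSet":
        if len(gc) != len(self.bins):
            raise ValueError("gc vector length mismatch")
        new = tuple(replace(b, gc_fraction=float(g)) for b, g in zip(self.bins, gc))
        return BinSet(new, self.genome_build, self.target_mappable_span)


def uniform_mappability(chrom_sizes: dict[str, int]) -> dict[str, list[tuple[int, int, float]]]:
    """A mappability track that scores every base 1.0 (the simulation default)."""
    return {c: [(0, size, 1.0)] for c, size in chrom_sizes.items()}


def build_bins(
    chrom_sizes: dict[str, int],
    mappability: dict[str, list[tuple[int, int, float]]] | None = None,
    target_mappable_span: int = DEFAULT_TARGET_SPAN,
    genome_build: str = "GRCh37",
) -> BinSet:
    """Greedy left-to-right binning by cumulative mappable bases.

    Parameters
    ----------
    chrom_sizes
        Chromosome name -> length (bp).
    mappability
        Chromosome -> list of (start, end, weight) intervals with weights in
        [0, 1]; uncovered territory has weight 0. ``None`` means uniform 1.0.
    target_mappable_span
        A bin closes once its cumulative mappable bases reach this value. A
        trailing chromosome remainder with less than half the target is merged
        into the previous bin.

    Zero-mappability territory contributes physical length but no mappable
    span, so bins stretch across it without changing the bin count.
    """
    if target_mappable_span <= 0:
        raise ValueError("target_mappable_span must be positive")
    if mappability is None:
        mappability = uniform_mappability(chrom_sizes)
    unknown = set(mappability) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"mappability track names absent from chrom_sizes: {sorted(unknown)}")

    bins: list[Bin] = []
    for chrom in sorted(chrom_sizes, key=sort_key):
        size = chrom_sizes[chrom]
        track = sorted(mappability.get(chrom, []), key=lambda iv: iv[0])
        for s, e, w in track:
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"mappability weight outside [0, 1]: {w} on {chrom}")
            if s < 0 or e > size:
                raise ValueError(f"mappability interval off chromosome: {chrom}:{s}-{e}")
        chrom_bins = _bin_one_chrom(chrom, size, track, target_mappable_span)
        if not chrom_bins:
            log.warning("chromosome %s has no bins (insufficient mappable territory)", chrom)
        bins.extend(chrom_bins)
    return BinSet(tuple(bins), genome_build, target_mappable_span)


def _bin_one_chrom(
    chrom: str, size: int, track, target: int
) -> list[Bin]:
    # Exact greedy accumulation over the piecewise-constant weight track.
    bins: list[tuple[int, int, float]] = []  # (start, end, mappable)
    cur_start = 0
    acc = 0.0
    pos = 0
    for s, e, w in track:
        s, e = max(s, 0), min(e, size)
        if e <= s:
            continue
        pos = s
        while pos < e:
            if w <= 0.0:
                pos = e
                break
            need = (target - acc) / w  # whole bases still required at this weight
            remaining = e - pos
            if need <= remaining:
                step = max(1, -int(-need // 1))  # ceil: bins close on whole-base boundaries
                step = min(step, remaining)
                acc += step * w
                pos += step
                if acc >= target:
                    bins.append((cur_start, pos, acc))
                    cur_start = pos
                    acc = 0.0
            else:
                acc += remaining * w
                pos = e
    # trailing remainder: physical tail to chromosome end
    if cur_start < size:
        if acc > 0 and (acc >= 0.5 * target or not bins):
            bins.append((cur_start, size, acc))
        elif bins:
            s0, _, m0 = bins[-1]
            bins[-1] = (s0, size, m0 + acc)
        # acc == 0 and no bins: chromosome emitted empty
    elif bins and bins[-1][1] < size:
        s0, e0, m0 = bins[-1]
        bins[-1] = (s0, size, m0)
    out = []
    for s, e, m in bins:
        out.append(Bin(chrom, s, e, int(round(m))))
    return out


def write_bins(binset: BinSet, path, header: bool = False) -> None:
    """Serialize to a 5-column BED-like file (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f"#genome_build={binset.genome_build}\n")
        fh.write(f"#target_mappable_span={binset.target_mappable_span}\n")
        if header:
            fh.write("#chrom\tstart\tend\tmappable_span\tgc_fraction\n")
        for b in binset.bins:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.mappable_span}\t{b.gc_fraction:.6g}\n")


def read_bins(path) -> BinSet:
    """Parse a bin file written by :func:`write_bins`; errors name the line."""
    build = "GRCh37"
    target = DEFAULT_TARGET_SPAN
    bins: list[Bin] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#genome_build="):
                    build = line.split("=", 1)[1]
                elif line.startswith("#target_mappable_span="):
                    target = int(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            try:
                b = Bin(parts[0], int(parts[1]), int(parts[2]), int(parts[3]), float(parts[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if bins and bins[-1].chrom == b.chrom and b.start < bins[-1].end:
                raise ValueError(
                    f"{path}:{lineno}: unsorted or overlapping bins "
                    f"({bins[-1].chrom}:{bins[-1].start}-{bins[-1].end} then {b.chrom}:{b.start}-{b.end})"
                )
            bins.append(b)
    return BinSet(tuple(bins), build, target)


def default_binset(target_mappable_span: int = DEFAULT_TARGET_SPAN) -> BinSet:
    """GRCh37 bins with uniform mappability (the simulation default)."""
    return build_bins(GRCH37_SIZES, None, target_mappable_span)
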