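"""Per-sample, per-bin filtered read counts.

A sample enters the pipeline as one integer count per bin. Counts come either
from an aligned short-read file (single-end 36 bp reads on the platform this
tool targets) or from the simulator. Read filters mirror the upstream
processing contract: PCR-duplicate-flagged reads and reads with mapping
quality below 20 are excluded before counting; each surviving read is assigned
to exactly one bin by its 5'-most aligned base (strand-aware).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_bins import BinSet
from ._util import log

SEXES = ("male", "female", "unknown")


@dataclass
class CountRow:
    """One sample's filtered per-bin counts plus QC totals.

    ``total_reads`` counts all reads before filtering; ``filtered_mapped``
    counts reads surviving the MQ/duplicate filters (binned or not), so
    ``sum(counts) <= filtered_mapped <= total_reads``.
    """

    sample_id: str
    sex: str
    counts: np.ndarray
    total_reads: int
    filtered_mapped: int

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative bin count")
        if not (int(self.counts.sum()) <= self.filtered_mapped <= self.total_reads):
            raise ValueError(
                "count totals violate sum(counts) <= filtered_mapped <= total_reads"
            )


@dataclass
class CountMatrix:
    rows: list[CountRow]
    binset_checksum: str

    def __post_init__(self):
        n = {len(r.counts) for r in self.rows}
        if len(n) > 1:
            raise ValueError("rows have differing bin counts")
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids")

    def __len__(self) -> int:
        return len(self.rows)

    def matrix(self) -> np.ndarray:
        return np.stack([r.counts for r in self.rows])


def count_from_alignments(
    alignments,
    binset: BinSet,
    mq_min: int = 20,
    drop_duplicates: bool = True,
    sample_id: str = "sample",
    sex: str = "unknown",
) -> CountRow:
    """Count filtered reads per bin from a pysam AlignmentFile (or iterable).

    Reads are assigned by the 5'-most aligned base: ``reference_start`` on the
    forward strand, ``reference_end - 1`` on the reverse strand. Reads mapping
    to a chromosome absent from the bin set, or into unbinned territory,
    contribute to ``filtered_mapped`` but to no bin.
    """
    starts, ends, index = _bin_lookup(binset)
    counts = np.zeros(len(binset), dtype=np.int64)
    total = 0
    filtered = 0
    warned: set[str] = set()
    for read in alignments:
        total += 1
        if read.is_unmapped:
            continue
        if drop_duplicates and read.is_duplicate:
            continue
        if read.mapping_quality < mq_min:
            continue
        filtered += 1
        chrom = read.reference_name
        if chrom.startswith("chr"):
            chrom = chrom[3:]
        if chrom not in index:
            if chrom not in warned:
                log.warning("reads on chromosome %s are outside the bin set", chrom)
                warned.add(chrom)
            continue
        pos = read.reference_end - 1 if read.is_reverse else read.reference_start
        lo, hi = index[chrom]
        j = int(np.searchsorted(starts[lo:hi], pos, side="right")) - 1
        if j >= 0 and pos < ends[lo + j]:
            counts[lo + j] += 1
    return CountRow(sample_id, sex, counts, total, filtered)


def _bin_lookup(binset: BinSet):
    starts = np.array([b.start for b in binset.bins], dtype=np.int64)
    ends = np.array([b.end for b in binset.bins], dtype=np.int64)
    index = {c: binset.chrom_slice(c) for c in binset.chroms}
    return starts, ends, index


def percent_filtered_mapped(row: CountRow) -> float:
    """Filtered mapped reads as a percentage of all reads."""
    if row.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return 100.0 * row.filtered_mapped / row.total_reads


def write_counts(matrix: CountMatrix, path) -> None:
    """TSV with bins as rows and samples as columns; metadata in # headers."""
    with open(path, "w") as fh:
        fh.write(f"#binset_checksum={matrix.binset_checksum}\n")
        for r in matrix.rows:
            fh.write(
                f"#sample\t{r.sample_id}\tsex={r.sex}\ttotal_reads={r.total_reads}"
                f"\tfiltered_mapped={r.filtered_mapped}\n"
            )
        fh.write("bin\t" + "\t".join(r.sample_id for r in matrix.rows) + "\n")
        mat = matrix.matrix()
        for i in range(mat.shape[1]):
            fh.write(f"{i}\t" + "\t".join(str(int(v)) for v in mat[:, i]) + "\n")


def read_counts(path, binset: BinSet | None = None) -> CountMatrix:
    checksum = ""
    meta: dict[str, dict] = {}
    order: list[str] = []
    data: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#binset_checksum="):
                checksum = line.split("=", 1)[1]
                continue
            if line.startswith("#sample\t"):
                parts = line.split("\t")
                sid = parts[1]
                kv = dict(p.split("=", 1) for p in parts[2:])
                if "sex" not in kv:
                    log.warning("sample %s has no sex column; defaulting to unknown", sid)
                meta[sid] = {
                    "sex": kv.get("sex", "unknown"),
                    "total_reads": int(kv.get("total_reads", 0)),
                    "filtered_mapped": int(kv.get("filtered_mapped", 0)),
                }
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if not order:
                order = parts[1:]
                continue
            try:
                data.append([int(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count") from exc
    mat = np.array(data, dtype=np.int64)  # bins x samples
    if binset is not None and mat.shape[0] != len(binset):
        raise ValueError(
            f"count rows ({mat.shape[0]}) do not match bin set ({len(binset)})"
        )
    rows = []
    for j, sid in enumerate(order):
        m = meta.get(sid, {"sex": "unknown", "total_reads": 0, "filtered_mapped": 0})
        counts = mat[:, j]
        fm = m["filtered_mapped"] or int(counts.sum())
        tot = m["total_reads"] or fm
        rows.append(CountRow(sid, m["sex"], counts, tot, fm))
    return CountMatrix(rows, checksum)
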