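"""Whole-chromosome and segmental mosaicism analytics.

Two complementary statistics are computed per sample:

* **1 Mb-bin log2 ratios** (``log2_profile``): counts are re-aggregated onto a
  fixed 1 Mb grid, scaled by the sample's autosomal median, divided by the
  control-panel median profile, GC-corrected by a locally-weighted fit on the
  autosomes, and expressed as log2. The per-chromosome median log2 ratio
  ``m`` quantifies the aberration, and for a mosaic aneuploidy maps to a cell
  fraction via the closed forms ``f = 2*(2^m - 1)`` (gain) and
  ``f = 2*(1 - 2^m)`` (loss).

* **Comparative per-chromosome Z** (``comparative_z``): each chromosome's
  share of autosomal reads is compared with the mean and standard deviation
  of that share across the control panel. Because inter-sample variability of
  chromosomal shares is small (~1%), this statistic flags 10-20% mosaics that
  sit below the log2 threshold.

A chromosome is reported when either statistic exceeds its threshold; the
default log2 thresholds (|m| at a 20% mosaic) encode the screen's documented
sensitivity floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .depth_counts import CountMatrix, CountRow
from .genome_bins import BinSet
from .genomes import is_autosome, sort_key
from ._util import log

MB = 1_000_000

GAIN_M_MIN = math.log2(1.1)  # |m| of a 20% mosaic trisomy
LOSS_M_MIN = abs(math.log2(0.9))  # |m| of a 20% mosaic monosomy
COMPARATIVE_Z_MIN = 2.5
SEGMENT_MIN_BINS = 5  # segmental mosaics below 5 Mb are CNV-caller territory


@dataclass
class MbGrid:
    """Fixed 1 Mb bins spanning each chromosome, plus re-aggregation weights."""

    chroms: list[str]
    chrom_of: np.ndarray  # per 1 Mb bin, index into chroms
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    weights: "object"  # scipy-free sparse map: list of (src_bin, dst_bin, frac)
    n_src: int

    def __len__(self):
        return len(self.start)


def build_mb_grid(binset: BinSet, chrom_sizes: dict[str, int]) -> MbGrid:
    chroms = sorted({b.chrom for b in binset.bins}, key=sort_key)
    cidx = {c: i for i, c in enumerate(chroms)}
    starts, ends, chrom_of, gc_acc, gc_w = [], [], [], [], []
    offsets = {}
    for c in chroms:
        size = chrom_sizes[c]
        offsets[c] = len(starts)
        for s in range(0, size, MB):
            starts.append(s)
            ends.append(min(s + MB, size))
            chrom_of.append(cidx[c])
            gc_acc.append(0.0)
            gc_w.append(0.0)
    triples = []
    for i, b in enumerate(binset.bins):
        base = offsets[b.chrom]
        first = b.start // MB
        last = (b.end - 1) // MB
        for mb in range(first, last + 1):
            lo = max(b.start, mb * MB)
            hi = min(b.end, (mb + 1) * MB)
            frac = (hi - lo) / (b.end - b.start)
            j = base + mb
            triples.append((i, j, frac))
            gc_acc[j] += b.gc_fraction * (hi - lo)
            gc_w[j] += hi - lo
    gc = np.array([a / w if w > 0 else 0.5 for a, w in zip(gc_acc, gc_w)])
    return MbGrid(
        chroms=chroms,
        chrom_of=np.array(chrom_of),
        start=np.array(starts),
        end=np.array(ends),
        gc=gc,
        weights=triples,
        n_src=len(binset),
    )


def aggregate_counts(counts: np.ndarray, grid: MbGrid) -> np.ndarray:
    """Distribute bin counts onto the 1 Mb grid proportionally to overlap."""
    out = np.zeros(len(grid))
    for i, j, frac in grid.weights:
        out[j] += counts[i] * frac
    return out


@dataclass
class MosaicReference:
    """Panel medians on the 1 Mb grid plus chromosomal-share statistics."""

    grid: MbGrid
    median_profile: dict  # sex -> per-1Mb-bin median of scaled counts
    chrom_frac_mean: dict  # sex -> {chrom: mean share of autosomal reads}
    chrom_frac_sd: dict


def fit_mosaic_reference(
    controls: CountMatrix, binset: BinSet, chrom_sizes: dict[str, int]
) -> MosaicReference:
    grid = build_mb_grid(binset, chrom_sizes)
    auto_mb = np.array([is_autosome(grid.chroms[c]) for c in grid.chrom_of])
    profiles: dict[str, list[np.ndarray]] = {"male": [], "female": []}
    fracs: dict[str, list[dict]] = {"male": [], "female": []}
    chroms_src = np.array([b.chrom for b in binset.bins])
    for r in controls.rows:
        agg = aggregate_counts(r.counts, grid)
        med = np.median(agg[auto_mb & (agg > 0)]) if (agg > 0).any() else 1.0
        sex = r.sex if r.sex in profiles else "female"
        profiles[sex].append(agg / med)
        fracs[sex].append(_chrom_fractions(r.counts, chroms_src))
    median_profile, fmean, fsd = {}, {}, {}
    for sex, rows in profiles.items():
        if not rows:
            continue
        median_profile[sex] = np.median(np.stack(rows), axis=0)
        keys = fracs[sex][0].keys()
        fmean[sex] = {}
        fsd[sex] = {}
        for c in keys:
            vals = np.array([d[c] for d in fracs[sex]])
            fmean[sex][c] = float(vals.mean())
            fsd[sex][c] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return MosaicReference(grid, median_profile, fmean, fsd)


def _chrom_fractions(counts: np.ndarray, chroms_src: np.ndarray) -> dict:
    auto = np.isin(chroms_src, [c for c in np.unique(chroms_src) if is_autosome(c)])
    total = counts[auto].sum()
    out = {}
    for c in np.unique(chroms_src):
        out[str(c)] = float(counts[chroms_src == c].sum() / total)
    return out


@dataclass
class Log2Profile:
    sample_id: str
    grid: MbGrid
    m: np.ndarray  # log2 ratio per 1 Mb bin; NaN where masked
    per_chrom_median: dict

    def chrom_m(self, chrom: str) -> float:
        return self.per_chrom_median.get(chrom, float("nan"))


def log2_profile(row: CountRow, ref: MosaicReference) -> Log2Profile:
    """Median-normalized, GC-corrected log2 ratio on the 1 Mb grid."""
    if row.counts.sum() == 0:
        raise ValueError("all-zero sample")
    grid = ref.grid
    sex = row.sex if row.sex in ref.median_profile else "female"
    panel = ref.median_profile[sex]
    agg = aggregate_counts(row.counts, grid)
    auto_mb = np.array([is_autosome(grid.chroms[c]) for c in grid.chrom_of])
    ok = (panel > 0.05) & (agg > 0)
    med = np.median(agg[auto_mb & ok])
    if med <= 0:
        raise ValueError("sample autosomal median is zero")
    m = np.full(len(grid), np.nan)
    m[ok] = np.log2((agg[ok] / med) / panel[ok])
    m = _gc_correct(m, grid.gc, auto_mb)
    # re-center: autosomal median of a normal profile is 0 by construction
    m -= np.nanmedian(m[auto_mb])
    per_chrom = {}
    for i, c in enumerate(grid.chroms):
        vals = m[(grid.chrom_of == i) & np.isfinite(m)]
        if len(vals):
            per_chrom[c] = float(np.median(vals))
    return Log2Profile(row.sample_id, grid, m, per_chrom)


def _gc_correct(m: np.ndarray, gc: np.ndarray, auto_mb: np.ndarray) -> np.ndarray:
    fit_mask = np.isfinite(m) & auto_mb
    if fit_mask.sum() < 50 or np.std(gc[fit_mask]) < 1e-6:
        return m
    sm = lowess(m[fit_mask], gc[fit_mask], frac=0.4, return_sorted=True)
    corr = np.interp(gc, sm[:, 0], sm[:, 1])
    out = m.copy()
    finite = np.isfinite(m)
    out[finite] = m[finite] - corr[finite]
    return out


def estimate_fraction(m_median: float, direction: str) -> float:
    """Invert the mosaic copy-ratio model: gain f = 2(2^m - 1); loss f = 2(1 - 2^m)."""
    if direction == "gain":
        if m_median < 0:
            raise ValueError("gain direction with negative log2 ratio")
        if m_median > math.log2(1.5):
            log.warning("log2 ratio %.3f above full-trisomy bound; clipping", m_median)
        f = 2.0 * (2.0**m_median - 1.0)
    elif direction == "loss":
        if m_median > 0:
            raise ValueError("loss direction with positive log2 ratio")
        if m_median < -1.0:
            log.warning("log2 ratio %.3f below full-monosomy bound; clipping", m_median)
        f = 2.0 * (1.0 - 2.0**m_median)
    else:
        raise ValueError("direction must be 'gain' or 'loss'")
    return float(min(max(f, 0.0), 1.0))


def comparative_z(row: CountRow, ref: MosaicReference) -> dict:
    """Per-chromosome Z of the sample's autosomal-read share vs the panel."""
    sex = row.sex if row.sex in ref.chrom_frac_mean else "female"
    out = {}
    fractions = _chrom_fractions_from_grid(row.counts, ref.grid)
    for c, x in fractions.items():
        mu = ref.chrom_frac_mean[sex].get(c)
        sd = ref.chrom_frac_sd[sex].get(c, 0.0)
        if mu is None:
            continue
        if sd <= 0:
            log.warning("chromosome %s share has zero panel sd; skipped", c)
            continue
        out[c] = (x - mu) / sd
    return out


def _chrom_fractions_from_grid(counts: np.ndarray, grid: MbGrid) -> dict:
    # per-chromosome totals are conserved by the proportional re-aggregation
    agg = aggregate_counts(counts, grid)
    totals = {}
    for i, c in enumerate(grid.chroms):
        totals[c] = float(agg[grid.chrom_of == i].sum())
    auto_total = sum(v for c, v in totals.items() if is_autosome(c))
    return {c: v / auto_total for c, v in totals.items()}


@dataclass
class MosaicCall:
    sample_id: str
    chrom: str
    direction: str  # "gain" | "loss"
    m_median: float
    fraction: float
    comparative_z: float
    flagged_by: frozenset
    start: int | None = None  # set for segmental (sub-chromosome) calls
    end: int | None = None

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be gain or loss")
        if not self.flagged_by:
            raise ValueError("emitted call must be flagged by at least one method")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction outside [0, 1]")


def flag_mosaics(
    profile: Log2Profile,
    zc: dict,
    m_gain_min: float = GAIN_M_MIN,
    m_loss_min: float = LOSS_M_MIN,
    z_min: float = COMPARATIVE_Z_MIN,
) -> list[MosaicCall]:
    """Emit per-chromosome (and segmental) mosaic calls from both statistics."""
    calls: list[MosaicCall] = []
    grid = profile.grid
    whole_flagged: set[str] = set()
    for c in grid.chroms:
        m = profile.per_chrom_median.get(c)
        z = zc.get(c, 0.0)
        flagged = set()
        if m is not None:
            if m >= m_gain_min or m <= -m_loss_min:
                flagged.add("log2")
        if abs(z) >= z_min:
            flagged.add("comparative")
        if not flagged:
            continue
        direction = _direction(m if m is not None else 0.0, z)
        m_eff = m if m is not None else 0.0
        if direction == "gain":
            frac = estimate_fraction(max(m_eff, 0.0), "gain")
        else:
            frac = estimate_fraction(min(m_eff, 0.0), "loss")
        calls.append(
            MosaicCall(profile.sample_id, c, direction, float(m_eff), frac, float(z), frozenset(flagged))
        )
        # a comparative-only flag cannot localize; let a segmental log2 run
        # refine it, but a whole-chromosome log2 flag owns the chromosome
        if "log2" in flagged:
            whole_flagged.add(c)
    calls.extend(
        _segmental_calls(profile, m_gain_min, m_loss_min, whole_flagged, zc)
    )
    return calls


def _direction(m: float, z: float) -> str:
    # log2 evidence dominates; fall back on comparative sign
    if abs(m) > 1e-9:
        return "gain" if m > 0 else "loss"
    return "gain" if z >= 0 else "loss"


def _segmental_calls(profile, m_gain_min, m_loss_min, skip_chroms, zc):
    grid = profile.grid
    out = []
    for i, c in enumerate(grid.chroms):
        if c in skip_chroms:
            continue
        idx = np.where(grid.chrom_of == i)[0]
        m = profile.m[idx]
        state = np.zeros(len(idx), dtype=int)
        state[np.isfinite(m) & (m >= m_gain_min)] = 1
        state[np.isfinite(m) & (m <= -m_loss_min)] = -1
        j = 0
        while j < len(idx):
            s = state[j]
            if s == 0:
                j += 1
                continue
            k = j
            while k < len(idx) and state[k] == s:
                k += 1
            if k - j >= SEGMENT_MIN_BINS:
                seg_m = float(np.median(m[j:k]))
                direction = "gain" if s > 0 else "loss"
                out.append(
                    MosaicCall(
                        profile.sample_id, c, direction, seg_m,
                        estimate_fraction(seg_m, direction),
                        float(zc.get(c, 0.0)),
                        frozenset({"log2"}),
                        start=int(grid.start[idx[j]]),
                        end=int(grid.end[idx[k - 1]]),
                    )
                )
            j = k
    return out


def mosaic_report_tsv(calls: list[MosaicCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tregion\tdirection\tm_median\tfraction_pct\tcomparative_z\tflagged_by\n")
        for c in calls:
            region = c.chrom if c.start is None else f"{c.chrom}:{c.start}-{c.end}"
            fh.write(
                f"{c.sample_id}\t{region}\t{c.direction}\t{c.m_median:.4f}"
                f"\t{round(100 * c.fraction)}\t{c.comparative_z:.2f}"
                f"\t{','.join(sorted(c.flagged_by))}\n"
            )
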