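"""Synthetic cohorts for the shallow-WGS screen.

The generator emulates the data-generating process the pipeline assumes:
~1.2 million filtered 36 bp single-end reads per sample spread over the
mappability-adjusted bins, proportional to each bin's mappable span, with

* a smooth GC-bias factor whose strength varies slightly between samples
  (so the reference panel has a real systematic component to remove),
* per-bin gamma overdispersion beyond Poisson counting noise
  (``dispersion`` = extra-Poisson coefficient of variation),
* a per-chromosome representation factor (CV ``panel_chrom_cv``) driving the
  inter-sample variability of chromosomal read shares that the comparative
  mosaic statistic is calibrated against,
* truth events (deletions, duplications, triplications, whole-chromosome
  gains/losses, each with a clonality fraction) scaling expected counts by
  ``1 + f * copies * overlap / ploidy``.

Whole-genome-amplification (WGA) mode layers on the failure modes seen when
the library is pre-amplified: extra per-bin gamma amplification noise, a
heavy-tailed dropout of the q-terminal bins of every chromosome (terminal
segments amplify poorly), and a lower filtered-mapped fraction.

The 21-case validation fixture transcribes the printed microarray
coordinates (hg19) of the known-CNV cohort used to establish the screen's
detection limits.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .depth_counts import CountMatrix, CountRow
from .genome_bins import BinSet, default_binset
from .genomes import GRCH37_SIZES, is_autosome
from ._util import log

EVENT_KINDS = ("del", "dup", "trip", "whole_chrom_gain", "whole_chrom_loss")
KIND_COPIES = {"del": -1, "dup": 1, "trip": 2, "whole_chrom_gain": 1, "whole_chrom_loss": -1}


@dataclass(frozen=True)
class TruthEvent:
    chrom: str
    start: int
    end: int
    kind: str
    fraction: float = 1.0
    copies: int | None = None  # defaults by kind

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        if self.end <= self.start:
            raise ValueError("event end <= start")
        if self.copies is None:
            object.__setattr__(self, "copies", KIND_COPIES[self.kind])

    @property
    def sign(self) -> str:
        return "DEL" if self.copies < 0 else "DUP"

    @property
    def size(self) -> int:
        return self.end - self.start

    @staticmethod
    def whole_chrom(chrom: str, kind: str, fraction: float = 1.0,
                    chrom_sizes: dict | None = None) -> "TruthEvent":
        sizes = chrom_sizes or GRCH37_SIZES
        return TruthEvent(chrom, 0, sizes[chrom], kind, fraction)


@dataclass
class SimConfig:
    binset: BinSet
    mean_filtered_reads: int = 1_200_000
    dispersion: float = 0.05  # extra-Poisson CV of per-bin gamma factors
    gc_bias_amplitude: float = 0.1
    panel_chrom_cv: float = 0.01
    wga_mode: bool = False
    wga_gamma_shape: float = 150.0  # per-bin amplification factor ~ Gamma(shape)
    wga_terminal_dropout: float = 0.5  # mean retention = 1 - dropout on q-terminal bins
    wga_terminal_bins: int = 10
    pct_filtered_no_wga: float = 77.35
    pct_filtered_wga: float = 57.9
    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: dict(GRCH37_SIZES))

    def __post_init__(self):
        for name in ("mean_filtered_reads", "dispersion", "gc_bias_amplitude",
                     "panel_chrom_cv", "wga_gamma_shape", "wga_terminal_bins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_wga(self, on: bool = True) -> "SimConfig":
        return replace(self, wga_mode=on)


def synthetic_gc(binset: BinSet) -> np.ndarray:
    """Deterministic smooth GC track in [0.38, 0.52] (a genome property)."""
    i = np.arange(len(binset))
    return 0.45 + 0.07 * np.sin(2 * np.pi * i / 40.0)


def simulation_binset(target_mappable_span: int = 285_000) -> BinSet:
    """Default GRCh37 bin set with the synthetic GC track attached."""
    bs = default_binset(target_mappable_span)
    return bs.with_gc(list(synthetic_gc(bs)))


def _sample_rng(config: SimConfig, sample_id: str) -> np.random.Generator:
    # counter-based: each sample's stream depends only on (seed, sample_id)
    return np.random.default_rng([config.seed % (2**31 - 1), zlib.crc32(sample_id.encode())])


def _ploidy(binset: BinSet, sex: str) -> np.ndarray:
    p = np.full(len(binset), 2.0)
    for i, b in enumerate(binset.bins):
        if b.chrom == "X" and sex == "male":
            p[i] = 1.0
        elif b.chrom == "Y":
            p[i] = 1.0 if sex == "male" else 0.0
    return p


def copy_ratio(truth: list[TruthEvent], binset: BinSet, sex: str) -> np.ndarray:
    """Per-bin expected copy ratio ``1 + sum f*copies*overlap/ploidy``."""
    _check_events(truth, binset)
    ploidy = _ploidy(binset, sex)
    ratio = np.ones(len(binset))
    for ev in truth:
        for i, b in enumerate(binset.bins):
            if b.chrom != ev.chrom or b.end <= ev.start or b.start >= ev.end:
                continue
            frac = (min(b.end, ev.end) - max(b.start, ev.start)) / (b.end - b.start)
            if ploidy[i] > 0:
                ratio[i] += ev.fraction * ev.copies * frac / ploidy[i]
    return np.maximum(ratio, 0.0)


def _check_events(truth: list[TruthEvent], binset: BinSet) -> None:
    sizes = {}
    for b in binset.bins:
        sizes[b.chrom] = max(sizes.get(b.chrom, 0), b.end)
    for ev in truth:
        if ev.chrom not in sizes or ev.end > sizes[ev.chrom] or ev.start < 0:
            raise ValueError(f"event off genome: {ev.chrom}:{ev.start}-{ev.end}")
    # opposite-sign events may not overlap; sub-50 kb overlaps are tolerated as
    # breakpoint-resolution slop (printed microarray coordinates carry such
    # self-overlaps) and resolved by summing copy effects in the overlap zone
    for i, a in enumerate(truth):
        for b in truth[i + 1:]:
            if a.chrom != b.chrom or np.sign(a.copies) == np.sign(b.copies):
                continue
            overlap = min(a.end, b.end) - max(a.start, b.start)
            if overlap > 50_000:
                raise ValueError(
                    f"contradictory overlapping events on {a.chrom}: "
                    f"{a.start}-{a.end} vs {b.start}-{b.end}"
                )


def expected_profile(truth: list[TruthEvent], config: SimConfig, sex: str) -> np.ndarray:
    """Noise-free expected filtered counts per bin (the simulator's mean)."""
    bs = config.binset
    span = np.array([b.mappable_span for b in bs.bins], dtype=float)
    auto = np.array([is_autosome(b.chrom) for b in bs.bins])
    gc = np.array([b.gc_fraction for b in bs.bins])
    gdev = _centered_gc(gc, span, auto)
    gfac = 1.0 + config.gc_bias_amplitude * gdev
    ploidy = _ploidy(bs, sex)
    ratio = copy_ratio(truth, bs, sex)
    weight = span * gfac * (ploidy / 2.0) * ratio
    base = config.mean_filtered_reads / float((span * gfac)[auto].sum())
    # base is normalized so a diploid autosome totals mean_filtered_reads
    return base * weight


def _centered_gc(gc: np.ndarray, span: np.ndarray, auto: np.ndarray) -> np.ndarray:
    dev = (gc - 0.45) / 0.07
    w = span[auto].sum()
    return dev - float((dev * span)[auto].sum() / w)


def simulate_sample(
    truth: list[TruthEvent],
    config: SimConfig,
    sex: str,
    sample_id: str = "sample",
) -> CountRow:
    """Draw one sample's filtered per-bin counts under the forward model."""
    bs = config.binset
    rng = _sample_rng(config, sample_id)
    mu = expected_profile(truth, config, sex)

    # per-sample GC-strength jitter: replaces the fixed amplitude with a drawn one
    gc = np.array([b.gc_fraction for b in bs.bins])
    auto = np.array([is_autosome(b.chrom) for b in bs.bins])
    span = np.array([b.mappable_span for b in bs.bins], dtype=float)
    gdev = _centered_gc(gc, span, auto)
    amp = config.gc_bias_amplitude
    amp_s = max(0.0, rng.normal(amp, 0.3 * amp)) if amp > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = mu * (1.0 + amp_s * gdev) / (1.0 + amp * gdev)

    # per-chromosome representation factor
    if config.panel_chrom_cv > 0:
        shape = 1.0 / config.panel_chrom_cv**2
        chroms = [b.chrom for b in bs.bins]
        factors = {c: rng.gamma(shape, 1.0 / shape) for c in dict.fromkeys(chroms)}
        mu = mu * np.array([factors[c] for c in chroms])

    # per-bin overdispersion
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion**2
        mu = mu * rng.gamma(shape, 1.0 / shape, size=len(mu))

    pct_target = config.pct_filtered_no_wga
    if config.wga_mode:
        pct_target = config.pct_filtered_wga
        if config.wga_gamma_shape > 0:
            mu = mu * rng.gamma(config.wga_gamma_shape, 1.0 / config.wga_gamma_shape, size=len(mu))
        retention_mean = max(1.0 - config.wga_terminal_dropout, 1e-3)
        for chrom in bs.chroms:
            lo, hi = bs.chrom_slice(chrom)
            k = min(config.wga_terminal_bins, hi - lo)
            if k > 0:
                # q-terminal bins amplify erratically: low, heavy-tailed retention
                ret = rng.gamma(4.0, retention_mean / 4.0, size=k)
                mu[hi - k : hi] *= ret

    counts = rng.poisson(np.maximum(mu, 0.0))
    filtered = int(counts.sum())
    total = int(round(filtered / (pct_target / 100.0)))
    return CountRow(sample_id, sex, counts, total, filtered)


def simulate_panel(
    config: SimConfig,
    n: int = 100,
    sex_ratio: float = 0.5,
    id_prefix: str = "ctrl",
) -> CountMatrix:
    """Event-free control cohort (default 100: 50 male, 50 female)."""
    n_male = round(n * sex_ratio)
    if abs(sex_ratio - 0.5) < 1e-9 and n % 2:
        raise ValueError("odd n with a strict 50/50 sex split; pass sex_ratio explicitly")
    rows = []
    for i in range(n):
        sex = "male" if i < n_male else "female"
        sid = f"{id_prefix}-{i + 1:03d}"
        rows.append(simulate_sample([], config, sex, sample_id=sid))
    return CountMatrix(rows, config.binset.checksum)


# ---------------------------------------------------------------------------
# 21-case validation fixture (printed hg19 coordinates)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureEvent:
    event: TruthEvent
    printed_size_kb: float
    mark_bluefuse: str  # "+", "+a", "-"
    mark_wga: str
    mark_no_wga: str
    size_discrepant: bool = False  # printed size disagrees with coordinates


@dataclass(frozen=True)
class FixtureCase:
    case_id: str
    sex: str
    events: tuple

    @property
    def truth(self) -> list[TruthEvent]:
        return [fe.event for fe in self.events]


def _fe(chrom, start, end, kind, f, kb, bf, wga, nowga, discrepant=False):
    return FixtureEvent(TruthEvent(chrom, start, end, kind, f), kb, bf, wga, nowga, discrepant)


def table1_fixture() -> list[FixtureCase]:
    """The 21 known-CNV validation cases with printed microarray coordinates.

    Marks record, per CNV, whether each analysis arm detected it:
    ``+`` both detectors, ``+a`` the consecutive-bin standard only, ``-`` missed.
    Two rows carry printed sizes inconsistent with their own coordinates and
    are marked ``size_discrepant``.
    """
    sexes = {"pre-7": "female", "pre-19": "male", "pre-20": "female"}
    rows = [
        ("pre-1", [_fe("1", 145_895_746, 147_995_251, "dup", 1.0, 2100, "-", "+", "+")]),
        ("pre-2", [_fe("2", 70_817_760, 76_194_406, "del", 1.0, 5300, "+", "+", "+")]),
        ("pre-3", [_fe("4", 68_345, 14_582_038, "del", 1.0, 14500, "+", "+", "+")]),
        ("pre-4", [_fe("13", 101_714_084, 115_107_733, "del", 1.0, 13400, "+", "+", "+")]),
        ("pre-5", [_fe("5", 34_507_645, 36_691_250, "del", 1.0, 3400, "-", "+", "+", True)]),
        ("pre-6", [_fe("1", 247_001_499, 249_224_684, "del", 1.0, 2200, "-", "-", "+")]),
        ("pre-7", [_fe("17", 16_763_697, 20_463_423, "del", 1.0, 3700, "-", "+", "+")]),
        ("pre-8", [
            _fe("11", 116_683_754, 134_937_416, "dup", 1.0, 18300, "+", "+", "+"),
            _fe("22", 16_888_899, 20_312_661, "dup", 1.0, 3400, "-", "+", "+"),
        ]),
        ("pre-9", [_fe("1", 169_549_903, 172_184_068, "del", 1.0, 2600, "-", "+", "+")]),
        ("pre-10", [
            _fe("10", 128_251_907, 135_427_143, "del", 1.0, 7200, "+", "+", "+"),
            _fe("17", 73_011_284, 81_041_938, "dup", 1.0, 8000, "+", "+", "+"),
        ]),
        ("pre-11", [_fe("7", 69_755_328, 69_976_338, "del", 1.0, 221, "-", "-", "-")]),
        ("pre-12", [_fe("19", 20_696_177, 23_131_879, "dup", 1.0, 2400, "-", "+", "+")]),
        ("pre-13", [
            _fe("1", 849_466, 7_027_594, "del", 1.0, 6200, "+", "+", "+"),
            _fe("1", 7_391_956, 10_686_850, "dup", 0.5, 3300, "-", "-", "+"),
        ]),
        ("pre-14", [_fe("17", 1_061_401, 1_281_546, "dup", 1.0, 220, "-", "-", "-")]),
        ("pre-15", [_fe("22", 18_648_855, 21_800_471, "del", 1.0, 3200, "-", "+", "+")]),
        ("pre-16", [_fe("7", 72_611_954, 74_245_940, "del", 1.0, 1600, "-", "+a", "+a")]),
        ("pre-17", [
            _fe("11", 93_535_045, 97_323_000, "dup", 1.0, 8900, "+", "+", "+", True),
            _fe("11", 97_268_927, 126_080_195, "dup", 0.5, 28800, "+", "+", "+"),
            _fe("11", 126_048_147, 134_937_416, "del", 1.0, 8800, "+", "+", "+"),
        ]),
        ("pre-18", [
            _fe("1", 849_466, 3_763_567, "del", 1.0, 2900, "-", "+", "+"),
            _fe("5", 172_600_252, 180_715_096, "dup", 1.0, 8100, "+", "+", "+"),
        ]),
        ("pre-19", [_fe("X", 102_273_407, 103_223_398, "dup", 1.0, 950, "-", "+", "+")]),
        ("pre-20", [_fe("X", 168_551, 1_023_657, "del", 1.0, 855, "-", "+a", "+a")]),
        ("pre-21", [_fe("5", 175_469_493, 177_439_550, "del", 1.0, 1970, "-", "+", "+")]),
    ]
    out = []
    for i, (case_id, events) in enumerate(rows):
        sex = sexes.get(case_id, "female" if i % 2 == 0 else "male")
        out.append(FixtureCase(case_id, sex, tuple(events)))
    return out


def write_truth_tsv(truth: list[TruthEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tkind\tfraction\n")
        for ev in truth:
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.kind}\t{ev.fraction:g}\n")


def read_truth_tsv(path) -> list[TruthEvent]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            c, s, e, k, f = line.rstrip("\n").split("\t")
            out.append(TruthEvent(c, int(s), int(e), k, float(f)))
    return out
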