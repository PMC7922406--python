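"""CNV segmentation of per-bin Z-scores.

Two detectors run over a sample's Z-score vector and their calls are
unioned:

* ``call_hmm`` — Viterbi decoding of a 3-state hidden Markov model
  (deletion / diploid / duplication) with unit-variance Gaussian emissions
  centered at -M / 0 / +M in Z units. This is the automatic detector; it
  trades run length against evidence strength, so a short segment of very
  strong Z or a long segment of moderate Z both yield calls.
* ``call_runs`` — the fixed standard of three or more consecutive bins with
  |Z| >= 2.5, same sign throughout. This floor catches moderate-amplitude
  events the HMM's entry penalty would reject.

Runs and HMM segments never cross chromosome boundaries, and a masked
(unscored) bin breaks adjacency: a call cannot jump a masked bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome_bins import BinSet

DEL, DIP, DUP = 0, 1, 2


@dataclass(frozen=True)
class HmmParams:
    """3-state chain parameters (defaults follow the exome-CNV convention)."""

    emission_shift: float = 3.0  # |state mean| in Z units
    p_enter: float = 1e-8  # diploid -> CNV per bin
    mean_run: float = 6.0  # expected CNV length in bins; exit prob = 1/mean_run

    def __post_init__(self):
        if self.emission_shift <= 0:
            raise ValueError("emission_shift must be positive")
        if not (0.0 < self.p_enter < 0.5):
            raise ValueError("p_enter must lie in (0, 0.5)")
        if self.mean_run < 1:
            raise ValueError("mean_run must be >= 1")


@dataclass
class CnvCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    sign: str  # "DEL" | "DUP"
    n_bins: int
    mean_z: float
    methods: frozenset = field(default_factory=frozenset)
    bin_first: int = -1  # indices into the BinSet, inclusive
    bin_last: int = -1

    @property
    def size(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.sign not in ("DEL", "DUP"):
            raise ValueError("sign must be DEL or DUP")
        if self.sign == "DEL" and self.mean_z > 0 or self.sign == "DUP" and self.mean_z < 0:
            raise ValueError("sign inconsistent with mean_z")
        if self.end <= self.start or self.n_bins < 1 or not self.methods:
            raise ValueError("degenerate call")


def _chrom_segments(binset: BinSet, finite: np.ndarray):
    """Yield (chrom, [bin indices]) for maximal unmasked runs within chromosomes."""
    for chrom in binset.chroms:
        lo, hi = binset.chrom_slice(chrom)
        i = lo
        while i < hi:
            if not finite[i]:
                i += 1
                continue
            j = i
            while j < hi and finite[j]:
                j += 1
            yield chrom, list(range(i, j))
            i = j


def _make_call(sample_id, binset, idx, z, sign, methods) -> CnvCall:
    first, last = idx[0], idx[-1]
    return CnvCall(
        sample_id=sample_id,
        chrom=binset.bins[first].chrom,
        start=binset.bins[first].start,
        end=binset.bins[last].end,
        sign=sign,
        n_bins=len(idx),
        mean_z=float(np.mean(z[idx])),
        methods=frozenset(methods),
        bin_first=first,
        bin_last=last,
    )


def call_runs(
    zrow, binset: BinSet, z_min: float = 2.5, run_min: int = 3
) -> list[CnvCall]:
    """Maximal same-sign runs of >= ``run_min`` bins with |Z| >= ``z_min``."""
    z = np.asarray(zrow.z, dtype=float)
    finite = np.isfinite(z)
    calls: list[CnvCall] = []
    for _, seg in _chrom_segments(binset, finite):
        state = [0 if abs(z[i]) < z_min else (1 if z[i] > 0 else -1) for i in seg]
        i = 0
        while i < len(seg):
            s = state[i]
            if s == 0:
                i += 1
                continue
            j = i
            while j < len(seg) and state[j] == s:
                j += 1
            if j - i >= run_min:
                calls.append(
                    _make_call(
                        zrow.sample_id, binset, seg[i:j], z,
                        "DUP" if s > 0 else "DEL", {"run_rule"},
                    )
                )
            i = j
    return calls


def call_hmm(zrow, binset: BinSet, params: HmmParams = HmmParams()) -> list[CnvCall]:
    """Viterbi path over {DEL, DIP, DUP}; maximal non-diploid runs become calls."""
    z = np.asarray(zrow.z, dtype=float)
    finite = np.isfinite(z)
    calls: list[CnvCall] = []
    for _, seg in _chrom_segments(binset, finite):
        path = viterbi_path(z[seg], params)
        i = 0
        while i < len(seg):
            s = path[i]
            if s == DIP:
                i += 1
                continue
            j = i
            while j < len(seg) and path[j] == s:
                j += 1
            calls.append(
                _make_call(
                    zrow.sample_id, binset, seg[i:j], z,
                    "DUP" if s == DUP else "DEL", {"hmm"},
                )
            )
            i = j
    return calls


def _log_transitions(params: HmmParams) -> np.ndarray:
    p, q = params.p_enter, 1.0 / params.mean_run
    with np.errstate(divide="ignore"):
        t = np.log(
            np.array(
                [
                    [1.0 - q, q, 0.0],  # DEL -> DEL/DIP/DUP
                    [p, 1.0 - 2.0 * p, p],  # DIP ->
                    [0.0, q, 1.0 - q],  # DUP ->
                ]
            )
        )
    return t


def _log_emissions(z: np.ndarray, params: HmmParams) -> np.ndarray:
    m = params.emission_shift
    means = np.array([-m, 0.0, m])
    # unit-variance Gaussians; shared constant dropped (cancels in Viterbi)
    return -0.5 * (z[:, None] - means[None, :]) ** 2


def viterbi_path(z: np.ndarray, params: HmmParams = HmmParams()) -> np.ndarray:
    """Most probable state sequence for one contiguous unmasked segment."""
    n = len(z)
    if n == 0:
        return np.zeros(0, dtype=int)
    logt = _log_transitions(params)
    loge = _log_emissions(z, params)
    p = params.p_enter
    init = np.log(np.array([p, 1.0 - 2.0 * p, p]))
    score = init + loge[0]
    back = np.zeros((n, 3), dtype=int)
    for i in range(1, n):
        cand = score[:, None] + logt
        back[i] = np.argmax(cand, axis=0)
        score = cand[back[i], np.arange(3)] + loge[i]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def viterbi_brute_force(z: np.ndarray, params: HmmParams = HmmParams()):
    """Exhaustive max over all 3^n paths (test oracle; n <= ~12)."""
    import itertools

    n = len(z)
    logt = _log_transitions(params)
    loge = _log_emissions(z, params)
    p = params.p_enter
    init = np.log(np.array([p, 1.0 - 2.0 * p, p]))
    best, best_path = -math.inf, None
    for path in itertools.product((DEL, DIP, DUP), repeat=n):
        ll = init[path[0]] + loge[0, path[0]]
        for i in range(1, n):
            ll += logt[path[i - 1], path[i]] + loge[i, path[i]]
        if ll > best:
            best, best_path = ll, path
    return np.array(best_path, dtype=int), best


def merge_calls(hmm_calls: list[CnvCall], run_calls: list[CnvCall]) -> list[CnvCall]:
    """Union of both detectors; overlapping same-sign calls merge into one span."""
    calls = hmm_calls + run_calls
    out: list[CnvCall] = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.sign, c.bin_first)):
        if out and out[-1].chrom == c.chrom and out[-1].sign == c.sign and c.bin_first <= out[-1].bin_last:
            prev = out[-1]
            out[-1] = CnvCall(
                sample_id=prev.sample_id,
                chrom=prev.chrom,
                start=min(prev.start, c.start),
                end=max(prev.end, c.end),
                sign=prev.sign,
                n_bins=max(prev.bin_last, c.bin_last) - min(prev.bin_first, c.bin_first) + 1,
                mean_z=prev.mean_z,  # recomputed below if z available
                methods=prev.methods | c.methods,
                bin_first=min(prev.bin_first, c.bin_first),
                bin_last=max(prev.bin_last, c.bin_last),
            )
        else:
            out.append(c)
    return sorted(out, key=lambda c: (c.chrom, c.bin_first, c.sign))


def merge_with_z(hmm_calls, run_calls, z: np.ndarray) -> list[CnvCall]:
    """merge_calls with mean_z recomputed over each merged span."""
    out = []
    for c in merge_calls(hmm_calls, run_calls):
        span = z[c.bin_first : c.bin_last + 1]
        mz = float(np.nanmean(span)) if np.isfinite(span).any() else c.mean_z
        out.append(
            CnvCall(
                c.sample_id, c.chrom, c.start, c.end, c.sign, c.n_bins, mz,
                c.methods, c.bin_first, c.bin_last,
            )
        )
    return out


def calls_to_tsv(calls: list[CnvCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tsign\tsize\tn_bins\tmean_z\tmethods\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.sign}\t{c.size}"
                f"\t{c.n_bins}\t{c.mean_z:.3f}\t{','.join(sorted(c.methods))}\n"
            )


def calls_to_vcf(calls: list[CnvCall], path, chrom_sizes: dict[str, int] | None = None) -> None:
    """VCF 4.2 with symbolic <DEL>/<DUP> ALT alleles."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dkaryo\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length (negative for DEL)">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=NBINS,Number=1,Type=Integer,Description="Bins in segment">\n')
        fh.write('##INFO=<ID=ZMEAN,Number=1,Type=Float,Description="Mean bin Z-score">\n')
        fh.write('##INFO=<ID=METHODS,Number=.,Type=String,Description="Detection methods">\n')
        if chrom_sizes:
            for c, s in chrom_sizes.items():
                fh.write(f"##contig=<ID={c},length={s}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls, 1):
            svlen = -c.size if c.sign == "DEL" else c.size
            fh.write(
                f"{c.chrom}\t{c.start + 1}\tdk{i}\tN\t<{c.sign}>\t.\tPASS\t"
                f"SVTYPE={c.sign};END={c.end};SVLEN={svlen};NBINS={c.n_bins};"
                f"ZMEAN={c.mean_z:.3f};METHODS={','.join(sorted(c.methods))}\n"
            )
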