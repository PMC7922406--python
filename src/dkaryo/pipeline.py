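"""End-to-end screening orchestration.

``screen`` runs one sample through both analysis arms:

* CNV arm: panel Z-scores -> HMM and consecutive-run detectors -> union ->
  annotation flagging;
* mosaic arm: 1 Mb log2 profile and comparative per-chromosome Z ->
  mosaic calls with estimated cell fractions.

CNV calls that cover most of a chromosome flagged as a whole-chromosome
mosaic are suppressed from the CNV section (the event is reported once, as
a mosaic), keeping the two report sections disjoint in genomic territory.

``run_validation`` reproduces the known-CNV validation experiment: simulate
a fresh control panel plus each fixture case, screen every case, and score
a case as detected iff every truth CNV is overlapped by a same-sign call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .cnv_calling import CnvCall, HmmParams, call_hmm, call_runs, merge_with_z
from .depth_counts import CountMatrix, CountRow, percent_filtered_mapped
from .genome_bins import BinSet
from .interpretation import AnnotationTracks, FlaggedCall, flag_call
from .mosaic import (
    MosaicCall,
    MosaicReference,
    comparative_z,
    fit_mosaic_reference,
    flag_mosaics,
    log2_profile,
)
from .reference_panel import ReferencePanel, fit_panel, zscore_sample
from .simulate import FixtureCase, SimConfig, simulate_panel, simulate_sample
from ._util import log

WHOLE_CHROM_SUPPRESS_FRAC = 0.8


@dataclass
class ScreenParams:
    z_min: float = 2.5
    run_min: int = 3
    hmm: HmmParams = field(default_factory=HmmParams)


@dataclass
class PanelBundle:
    """Everything frozen from the control cohort, for both analysis arms."""

    zpanel: ReferencePanel
    mosaic_ref: MosaicReference
    binset_checksum: str

    @staticmethod
    def fit(controls: CountMatrix, binset: BinSet, chrom_sizes: dict) -> "PanelBundle":
        return PanelBundle(
            zpanel=fit_panel(controls, binset),
            mosaic_ref=fit_mosaic_reference(controls, binset, chrom_sizes),
            binset_checksum=binset.checksum,
        )


@dataclass
class ScreenReport:
    sample_id: str
    qc: dict
    cnv_calls: list  # FlaggedCall
    mosaic_calls: list  # MosaicCall
    provenance: dict

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, FlaggedCall):
                c = o.call
                return {
                    "chrom": c.chrom, "start": c.start, "end": c.end, "sign": c.sign,
                    "size": c.size, "n_bins": c.n_bins, "mean_z": round(c.mean_z, 4),
                    "methods": sorted(c.methods), "flagged": o.flagged,
                    "reasons": list(o.reasons),
                }
            if isinstance(o, MosaicCall):
                return {
                    "chrom": o.chrom, "start": o.start, "end": o.end,
                    "direction": o.direction, "m_median": round(o.m_median, 4),
                    "fraction_pct": round(100 * o.fraction),
                    "comparative_z": round(o.comparative_z, 3),
                    "flagged_by": sorted(o.flagged_by),
                }
            raise TypeError(type(o))

        return json.dumps(
            {
                "sample_id": self.sample_id,
                "qc": self.qc,
                "cnv_calls": [enc(c) for c in self.cnv_calls],
                "mosaic_calls": [enc(m) for m in self.mosaic_calls],
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )


def screen(
    row: CountRow,
    bundle: PanelBundle,
    binset: BinSet,
    chrom_sizes: dict,
    tracks: AnnotationTracks | None = None,
    params: ScreenParams | None = None,
    provenance_extra: dict | None = None,
) -> ScreenReport:
    params = params or ScreenParams()
    if binset.checksum != bundle.binset_checksum:
        raise ValueError("screen: bin set does not match the panel bundle")

    # --- CNV arm
    zrow = zscore_sample(row, bundle.zpanel)
    hmm_calls = call_hmm(zrow, binset, params.hmm)
    run_calls = call_runs(zrow, binset, params.z_min, params.run_min)
    calls = merge_with_z(hmm_calls, run_calls, zrow.z)

    # --- mosaic arm
    profile = log2_profile(row, bundle.mosaic_ref)
    zc = comparative_z(row, bundle.mosaic_ref)
    mosaic_calls = flag_mosaics(profile, zc)

    # suppression: whole-chromosome mosaics own their territory
    mosaic_whole = {m.chrom for m in mosaic_calls if m.start is None}
    kept: list[CnvCall] = []
    for c in calls:
        frac = c.size / chrom_sizes.get(c.chrom, c.size)
        if c.chrom in mosaic_whole and frac > WHOLE_CHROM_SUPPRESS_FRAC:
            continue
        kept.append(c)

    tracks = tracks or AnnotationTracks({}, {})
    flagged = [flag_call(c, tracks) for c in kept]

    auto_m = [
        m for i, m in enumerate(profile.m)
        if np.isfinite(m) and profile.grid.chroms[profile.grid.chrom_of[i]] not in ("X", "Y")
    ]
    qc = {
        "total_reads": row.total_reads,
        "filtered_mapped": row.filtered_mapped,
        "percent_filtered_mapped": round(percent_filtered_mapped(row), 2),
        "autosomal_median_log2_spread": round(float(np.median(np.abs(auto_m))), 4) if auto_m else None,
    }
    provenance = {
        "tool_version": __version__,
        "binset_checksum": binset.checksum,
        "panel_checksum": bundle.zpanel.binset_checksum,
        "z_min": params.z_min,
        "run_min": params.run_min,
        "hmm": {
            "emission_shift": params.hmm.emission_shift,
            "p_enter": params.hmm.p_enter,
            "mean_run": params.hmm.mean_run,
        },
    }
    if provenance_extra:
        provenance.update(provenance_extra)
    return ScreenReport(row.sample_id, qc, flagged, mosaic_calls, provenance)


# ---------------------------------------------------------------------------
# validation experiment
# ---------------------------------------------------------------------------

@dataclass
class CaseResult:
    case_id: str
    detected: bool
    events: list  # (TruthEvent, printed_size_kb, hit: bool)


@dataclass
class ValidationSummary:
    mode: str
    results: list
    detection_rate: float | None  # percent of cases fully detected
    detection_limit_kb: float | None  # smallest printed size among detected events

    def table(self) -> str:
        lines = ["case\tdetected\tevents_hit"]
        for r in self.results:
            hits = ",".join("+" if h else "-" for _, _, h in r.events)
            lines.append(f"{r.case_id}\t{'+' if r.detected else '-'}\t{hits}")
        rate = "NA" if self.detection_rate is None else f"{self.detection_rate:.1f}%"
        limit = "NA" if self.detection_limit_kb is None else f"{self.detection_limit_kb:g} kb"
        lines.append(f"# detection_rate={rate} detection_limit={limit} mode={self.mode}")
        return "\n".join(lines)


def event_detected(ev, calls: list[CnvCall]) -> bool:
    """True iff a same-sign call overlaps the truth event."""
    for c in calls:
        if c.chrom == ev.chrom and c.sign == ev.sign and c.start < ev.end and ev.start < c.end:
            return True
    return False


def run_validation(
    fixture: list[FixtureCase],
    config: SimConfig,
    binset: BinSet,
    chrom_sizes: dict,
    mode: str = "no_wga",
    params: ScreenParams | None = None,
    panel: "PanelBundle | None" = None,
) -> ValidationSummary:
    """Simulate panel + fixture cases, screen, and score per-case detection."""
    cfg = config.with_wga(mode == "wga")
    if panel is None:
        controls = simulate_panel(cfg)
        panel = PanelBundle.fit(controls, binset, chrom_sizes)
    results = []
    detected_sizes = []
    for case in fixture:
        row = simulate_sample(case.truth, cfg, case.sex, sample_id=f"{case.case_id}:{mode}")
        report = screen(row, panel, binset, chrom_sizes, params=params)
        calls = [fc.call for fc in report.cnv_calls]
        ev_hits = []
        for fe in case.events:
            hit = event_detected(fe.event, calls)
            ev_hits.append((fe.event, fe.printed_size_kb, hit))
            if hit:
                detected_sizes.append(fe.printed_size_kb)
        results.append(CaseResult(case.case_id, all(h for _, _, h in ev_hits), ev_hits))
    n = len(results)
    rate = 100.0 * sum(r.detected for r in results) / n if n else None
    limit = min(detected_sizes) if detected_sizes else None
    if n == 0:
        log.warning("validation fixture is empty; rate undefined")
    return ValidationSummary(mode, results, rate, limit)
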