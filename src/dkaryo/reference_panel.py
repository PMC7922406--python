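"""Reference-panel normalization and per-bin Z-scores.

A frozen panel of control samples (by default 100; 50 male, 50 female)
defines, for every bin, the expected depth-normalized count and its
control-to-control variability. A test sample's counts are depth-normalized
(reads per million autosomal reads), centered on the panel bin means,
denoised by projecting out the panel's dominant principal components
(systematic structure such as GC batch effects), and divided by the per-bin
residual standard deviation. The result is one Z-score per bin: the
statistic the CNV caller segments.

Sex chromosomes are normalized against same-sex controls only (a mixed-sex
panel is bimodal on X/Y); Y bins are meaningful only for male samples.
Principal-component removal operates on autosomal bins.

Component-removal rule
----------------------
Components are removed when their variance exceeds
``median component variance / variance_factor`` (default 0.7, i.e. ~1.43x
the median). The median of the component spectrum is a robust estimate of
the sampling-noise bulk, so structured components stand out while a panel
with no shared structure keeps all of its variance in the residual scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .depth_counts import CountMatrix, CountRow
from .genome_bins import BinSet
from .genomes import is_autosome
from ._util import log

NORM_SCALE = 1.0e6  # counts are expressed per million autosomal reads


@dataclass
class ReferencePanel:
    binset_checksum: str
    n_controls: int
    n_male: int
    n_female: int
    is_auto: np.ndarray  # bool per bin
    mean_auto: np.ndarray  # per bin; NaN outside autosomes
    scale_auto: np.ndarray  # post-removal residual sd; NaN outside autosomes
    mean_by_sex: dict  # sex -> per-bin mean on X/Y bins (NaN elsewhere)
    scale_by_sex: dict
    components: np.ndarray  # (k, n_bins); zero outside retained autosomal bins
    n_components_removed: int
    masked_auto: np.ndarray  # bool per bin (autosomal bins only)
    masked_by_sex: dict  # sex -> bool per bin (X/Y bins only)

    def mask_for_sex(self, sex: str) -> np.ndarray:
        """Bins that carry no Z-score for a sample of the given sex."""
        mask = np.zeros(len(self.is_auto), dtype=bool)
        mask[self.is_auto] = self.masked_auto[self.is_auto]
        sexbins = ~self.is_auto
        if sex in self.masked_by_sex:
            mask[sexbins] = self.masked_by_sex[sex][sexbins]
        else:
            mask[sexbins] = True
        return mask


@dataclass
class ZRow:
    sample_id: str
    z: np.ndarray  # NaN at masked bins


def depth_normalize(counts: np.ndarray, is_auto: np.ndarray) -> np.ndarray:
    """Counts per million autosomal reads.

    Using the autosomal total as the library-size estimate keeps
    whole-chromosome X/Y aneuploidy from biasing autosomal Z-scores.
    """
    total = counts[is_auto].sum()
    if total <= 0:
        raise ValueError("sample has no autosomal reads")
    return counts * (NORM_SCALE / total)


def autosome_flags(binset: BinSet) -> np.ndarray:
    return np.array([is_autosome(b.chrom) for b in binset.bins])


def fit_panel(
    controls: CountMatrix,
    binset: BinSet,
    variance_factor: float = 0.7,
    min_mean_depth: float = 10.0,
) -> ReferencePanel:
    """Freeze normalization state from a control cohort.

    ``min_mean_depth`` is on the normalized (reads-per-million) scale; bins
    whose control mean falls below it are masked and never scored.
    """
    if len(controls) < 2:
        raise ValueError("at least 2 controls are required")
    if len(controls) < 10:
        log.warning("panel has only %d controls; Z calibration will be poor", len(controls))
    is_auto = autosome_flags(binset)
    n_bins = len(binset)
    sexes = np.array([r.sex for r in controls.rows])
    norm = np.stack([depth_normalize(r.counts, is_auto) for r in controls.rows])

    # --- autosomes: mean, PCA removal, residual scale (all controls pooled)
    mean_auto = np.full(n_bins, np.nan)
    scale_auto = np.full(n_bins, np.nan)
    masked_auto = np.zeros(n_bins, dtype=bool)
    a = is_auto
    mu = norm[:, a].mean(axis=0)
    low = mu < min_mean_depth
    masked_auto[np.where(a)[0][low]] = True
    retained = np.where(a)[0][~low]
    centered = norm[:, retained] - mu[~low]
    components, n_removed, residual = _remove_components(centered, variance_factor)
    sd = residual.std(axis=0, ddof=1)
    zero_sd = sd <= 0
    if zero_sd.any():
        log.warning("%d bins have zero residual scale and were masked", int(zero_sd.sum()))
        masked_auto[retained[zero_sd]] = True
    mean_auto[retained] = mu[~low]
    scale_auto[retained] = np.where(zero_sd, np.nan, sd)
    comp_full = np.zeros((components.shape[0], n_bins))
    comp_full[:, retained] = components

    # --- sex chromosomes: per-sex mean/scale, no component removal
    mean_by_sex: dict[str, np.ndarray] = {}
    scale_by_sex: dict[str, np.ndarray] = {}
    masked_by_sex: dict[str, np.ndarray] = {}
    sexbins = np.where(~a)[0]
    chroms = np.array([b.chrom for b in binset.bins])
    for sex in ("male", "female"):
        grp = norm[sexes == sex]
        m = np.full(n_bins, np.nan)
        s = np.full(n_bins, np.nan)
        msk = np.ones(n_bins, dtype=bool)
        if len(grp) >= 2 and len(sexbins):
            gm = grp[:, sexbins].mean(axis=0)
            gs = grp[:, sexbins].std(axis=0, ddof=1)
            ok = (gm >= min_mean_depth) & (gs > 0)
            if sex == "female":
                ok &= chroms[sexbins] != "Y"  # female Y carries no signal
            m[sexbins] = np.where(ok, gm, np.nan)
            s[sexbins] = np.where(ok, gs, np.nan)
            msk[sexbins] = ~ok
        mean_by_sex[sex] = m
        scale_by_sex[sex] = s
        masked_by_sex[sex] = msk

    return ReferencePanel(
        binset_checksum=controls.binset_checksum or binset.checksum,
        n_controls=len(controls),
        n_male=int((sexes == "male").sum()),
        n_female=int((sexes == "female").sum()),
        is_auto=is_auto,
        mean_auto=mean_auto,
        scale_auto=scale_auto,
        mean_by_sex=mean_by_sex,
        scale_by_sex=scale_by_sex,
        components=comp_full,
        n_components_removed=n_removed,
        masked_auto=masked_auto,
        masked_by_sex=masked_by_sex,
    )


def _remove_components(centered: np.ndarray, variance_factor: float):
    """SVD the centered control matrix; flag high-variance components.

    Returns (loadings k x p, k, residual matrix after removal).
    """
    n = centered.shape[0]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / max(n - 1, 1)
    # drop numerically-zero trailing component (centering consumes one df)
    pos = var > var.max() * 1e-12 if var.size and var.max() > 0 else np.zeros_like(var, bool)
    if not pos.any():
        return np.zeros((0, centered.shape[1])), 0, centered
    med = np.median(var[pos])
    remove = pos & (var > med / variance_factor)
    k = int(remove.sum())
    loadings = vt[remove]
    residual = centered - (centered @ loadings.T) @ loadings
    return loadings, k, residual


def zscore_normalized(vec: np.ndarray, sex: str, panel: ReferencePanel) -> np.ndarray:
    """Z-scores for an already depth-normalized per-bin vector."""
    n_bins = len(panel.is_auto)
    z = np.full(n_bins, np.nan)
    a = panel.is_auto & ~panel.masked_auto
    dev = np.zeros(n_bins)
    dev[a] = vec[a] - panel.mean_auto[a]
    if panel.components.shape[0]:
        proj = panel.components @ dev
        dev = dev - panel.components.T @ proj
    z[a] = dev[a] / panel.scale_auto[a]
    if sex in ("male", "female"):
        sb = ~panel.is_auto & ~panel.masked_by_sex[sex]
        z[sb] = (vec[sb] - panel.mean_by_sex[sex][sb]) / panel.scale_by_sex[sex][sb]
    else:
        log.warning("sample sex unknown; X/Y bins left unscored")
    return z


def zscore_sample(row: CountRow, panel: ReferencePanel, binset: BinSet | None = None) -> ZRow:
    """Score one sample against the panel. Masked bins come back NaN."""
    if binset is not None and binset.checksum != panel.binset_checksum:
        raise ValueError("bin set checksum does not match the panel")
    if len(row.counts) != len(panel.is_auto):
        raise ValueError("count vector length does not match the panel")
    vec = depth_normalize(row.counts, panel.is_auto)
    return ZRow(row.sample_id, zscore_normalized(vec, row.sex, panel))


def save_panel(panel: ReferencePanel, path) -> None:
    np.savez_compressed(
        path,
        schema=np.array(["dkaryo-panel-1"]),
        binset_checksum=np.array([panel.binset_checksum]),
        counts=np.array([panel.n_controls, panel.n_male, panel.n_female]),
        is_auto=panel.is_auto,
        mean_auto=panel.mean_auto,
        scale_auto=panel.scale_auto,
        mean_male=panel.mean_by_sex["male"],
        scale_male=panel.scale_by_sex["male"],
        mean_female=panel.mean_by_sex["female"],
        scale_female=panel.scale_by_sex["female"],
        components=panel.components,
        n_components_removed=np.array([panel.n_components_removed]),
        masked_auto=panel.masked_auto,
        masked_male=panel.masked_by_sex["male"],
        masked_female=panel.masked_by_sex["female"],
    )


def load_panel(path) -> ReferencePanel:
    with np.load(path, allow_pickle=False) as d:
        if str(d["schema"][0]) != "dkaryo-panel-1":
            raise ValueError(f"unsupported panel schema: {d['schema'][0]}")
        return ReferencePanel(
            binset_checksum=str(d["binset_checksum"][0]),
            n_controls=int(d["counts"][0]),
            n_male=int(d["counts"][1]),
            n_female=int(d["counts"][2]),
            is_auto=d["is_auto"],
            mean_auto=d["mean_auto"],
            scale_auto=d["scale_auto"],
            mean_by_sex={"male": d["mean_male"], "female": d["mean_female"]},
            scale_by_sex={"male": d["scale_male"], "female": d["scale_female"]},
            components=d["components"],
            n_components_removed=int(d["n_components_removed"][0]),
            masked_auto=d["masked_auto"],
            masked_by_sex={"male": d["masked_male"], "female": d["masked_female"]},
        )
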