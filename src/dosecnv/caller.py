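"""Exome read-depth CNV calling.

Turns a probe x sample read-count matrix into per-sample deletion and
duplication calls in four stages:

1. sample QC on per-target coverage (breadth and depth thresholds),
2. RPKM normalisation (probe length and library size),
3. per-probe standardisation across samples (ZRPKM), masking probes with
   negligible median depth,
4. removal of the top S singular components of the ZRPKM matrix
   (SVD-ZRPKM), stripping correlated batch/capture structure so residual
   signal reflects copy number, followed by threshold segmentation.

Copy-number state scales expected depth by copy/2, so deletions push
SVD-ZRPKM below zero and duplications above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_MAP_COLUMNS = ("chrom", "start", "end", "probe_id")


def validate_probe_map(probe_map: pd.DataFrame) -> pd.DataFrame:
    """Check an ordered target map (BED-like, 0-based half-open).

    Probes must be sorted by (chrom, start), have positive length and
    unique ids. Returns the validated frame unchanged.
    """
    missing = [c for c in PROBE_MAP_COLUMNS if c not in probe_map.columns]
    if missing:
        raise ValueError(f"probe map lacks columns: {missing}")
    if len(probe_map) == 0:
        raise ValueError("probe map is empty")
    if (probe_map["end"] <= probe_map["start"]).any():
        raise ValueError("probe map contains zero- or negative-length targets")
    if probe_map["probe_id"].duplicated().any():
        raise ValueError("probe map contains duplicate probe ids")
    grouped = probe_map.groupby("chrom", sort=False)["start"]
    if any((s.diff().dropna() < 0).any() for _, s in grouped):
        raise ValueError("probe map is not sorted by (chrom, start)")
    return probe_map


@dataclass
class QcReport:
    """Per-sample coverage QC: breadth at 20x, mean and median depth."""

    table: pd.DataFrame  # index: sample; columns: frac_ge_20x, mean_cov, median_cov, passed

    @property
    def passed_samples(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    @property
    def failed_samples(self) -> list[str]:
        return list(self.table.index[~self.table["passed"]])


def sample_qc(
    coverage: pd.DataFrame,
    min_fraction_20x: float = 0.80,
    depth_for_fraction: float = 20.0,
    min_mean: float = 30.0,
    min_median: float = 30.0,
    conjunction: bool = True,
) -> QcReport:
    """Flag low-coverage samples from a probe x sample mean-depth matrix.

    Under the default conjunction rule a sample fails only when all three
    hold: fewer than 80% of targets at >= 20x, mean coverage < 30 and
    median coverage < 30. ``conjunction=False`` fails a sample when any
    single threshold is breached.
    """
    if coverage.size == 0:
        raise ValueError("coverage matrix is empty")
    if (coverage.to_numpy() < 0).any():
        raise ValueError("coverage matrix contains negative values")
    frac = (coverage >= depth_for_fraction).mean(axis=0)
    mean_cov = coverage.mean(axis=0)
    median_cov = coverage.median(axis=0)
    low_breadth = frac < min_fraction_20x
    low_mean = mean_cov < min_mean
    low_median = median_cov < min_median
    if conjunction:
        failed = low_breadth & low_mean & low_median
    else:
        failed = low_breadth | low_mean | low_median
    table = pd.DataFrame(
        {
            "frac_ge_20x": frac,
            "mean_cov": mean_cov,
            "median_cov": median_cov,
            "passed": ~failed,
        }
    )
    table.index.name = "sample"
    return QcReport(table)


def compute_rpkm(
    counts: pd.DataFrame, totals: pd.Series, probe_map: pd.DataFrame
) -> pd.DataFrame:
    """Reads per kilobase of target per million mapped reads.

    rpkm[p, s] = counts[p, s] * 1e9 / (length_bp[p] * totals[s]).
    """
    validate_probe_map(probe_map)
    if len(counts) != len(probe_map):
        raise ValueError("counts rows do not match probe map")
    lengths = (probe_map["end"] - probe_map["start"]).to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("zero-length probe in map")
    totals = totals.reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive total read count")
    rpkm = counts.to_numpy(dtype=float) * 1e9
    rpkm /= lengths[:, None]
    rpkm /= totals.to_numpy(dtype=float)[None, :]
    return pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)


def zrpkm(
    rpkm: pd.DataFrame, min_median_rpkm: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Standardise each probe's RPKM across samples (mean 0, sd 1, n-1).

    Probes with median RPKM below ``min_median_rpkm`` are masked (too
    shallow for a meaningful Z), as are probes with zero variance.
    Masked rows are NaN in the returned matrix; the boolean mask marks
    them and excludes them from every downstream stage.
    """
    if rpkm.shape[1] < 2:
        raise ValueError("ZRPKM needs at least two samples")
    values = rpkm.to_numpy(dtype=float)
    mask = np.median(values, axis=1) < min_median_rpkm
    sd = values.std(axis=1, ddof=1)
    zero_sd = (~mask) & (sd == 0)
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} probe(s) with zero variance masked",
            RuntimeWarning,
            stacklevel=2,
        )
        mask = mask | zero_sd
    z = np.full_like(values, np.nan)
    keep = ~mask
    if keep.any():
        mu = values[keep].mean(axis=1, keepdims=True)
        z[keep] = (values[keep] - mu) / sd[keep, None]
    zdf = pd.DataFrame(z, index=rpkm.index, columns=rpkm.columns)
    return zdf, pd.Series(mask, index=rpkm.index, name="masked")


def svd_denoise(zrpkm_matrix, n_components: int):
    """Zero the top ``n_components`` singular values of Z and reconstruct.

    Z = U S V'; the leading components carry correlated batch/capture
    structure shared across samples, so removing them leaves residual
    per-sample depth deviations — the copy-number signal. S = 0 is the
    identity. Input must be free of NaNs (pass only unmasked probes).
    """
    arr = np.asarray(
        zrpkm_matrix.to_numpy() if isinstance(zrpkm_matrix, pd.DataFrame) else zrpkm_matrix,
        dtype=float,
    )
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.isnan(arr).any():
        raise ValueError("matrix contains NaN; drop masked probes first")
    bound = min(arr.shape)
    if not 0 <= n_components <= bound:
        raise ValueError(f"n_components must be in [0, {bound}], got {n_components}")
    if n_components == 0:
        out = arr.copy()
    else:
        u, s, vt = np.linalg.svd(arr, full_matrices=False)
        s = s.copy()
        s[:n_components] = 0.0
        out = (u * s) @ vt
    if isinstance(zrpkm_matrix, pd.DataFrame):
        return pd.DataFrame(out, index=zrpkm_matrix.index, columns=zrpkm_matrix.columns)
    return out


@dataclass
class CnvCall:
    """One sample-level deletion or duplication over a run of probes."""

    sample: str
    chrom: str
    start: int
    end: int
    type: str  # 'del' or 'dup'
    n_probes: int
    mean_score: float
    inheritance: str = "unknown"
    filter_status: str = "pass"
    probe_ids: tuple = field(default_factory=tuple, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.type not in ("del", "dup"):
            raise ValueError(f"call type must be del/dup, got {self.type!r}")
        if self.end <= self.start:
            raise ValueError("call interval must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def sign(self) -> int:
        """+1 for duplication, -1 for deletion."""
        return 1 if self.type == "dup" else -1


def call_cnvs(
    svd_zrpkm: pd.DataFrame,
    probe_map: pd.DataFrame,
    threshold: float = 1.5,
    min_probes: int = 3,
) -> list[CnvCall]:
    """Segment denoised scores into calls by run-length thresholding.

    Per sample and chromosome, maximal runs of consecutive unmasked
    probes with score >= +threshold (dup) or <= -threshold (del), at
    least ``min_probes`` long, become calls spanning exactly the probes'
    footprint. NaN (masked) probes break runs; calls never cross
    chromosome boundaries.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    validate_probe_map(probe_map)
    if len(svd_zrpkm) != len(probe_map):
        raise ValueError("score rows do not match probe map")

    chroms = probe_map["chrom"].to_numpy()
    starts = probe_map["start"].to_numpy()
    ends = probe_map["end"].to_numpy()
    probe_ids = probe_map["probe_id"].to_numpy()
    # chromosome run ids so runs cannot straddle a boundary
    chrom_change = np.r_[True, chroms[1:] != chroms[:-1]]
    chrom_block = np.cumsum(chrom_change)

    calls: list[CnvCall] = []
    for sample in svd_zrpkm.columns:
        scores = svd_zrpkm[sample].to_numpy(dtype=float)
        state = np.zeros(len(scores), dtype=int)
        with np.errstate(invalid="ignore"):
            state[scores >= threshold] = 1
            state[scores <= -threshold] = -1
        state[np.isnan(scores)] = 0
        # split into maximal runs of constant (state, chrom_block)
        boundary = np.r_[
            True, (state[1:] != state[:-1]) | (chrom_block[1:] != chrom_block[:-1])
        ]
        run_starts = np.flatnonzero(boundary)
        run_ends = np.r_[run_starts[1:], len(state)]
        for i0, i1 in zip(run_starts, run_ends):
            st = state[i0]
            if st == 0 or (i1 - i0) < min_probes:
                continue
            calls.append(
                CnvCall(
                    sample=str(sample),
                    chrom=str(chroms[i0]),
                    start=int(starts[i0]),
                    end=int(ends[i1 - 1]),
                    type="dup" if st > 0 else "del",
                    n_probes=int(i1 - i0),
                    mean_score=float(np.mean(scores[i0:i1])),
                    probe_ids=tuple(probe_ids[i0:i1]),
                )
            )
    return calls


@dataclass
class DepthBundle:
    """Depth matrix with its normalised and denoised derivatives."""

    counts: pd.DataFrame
    totals: pd.Series
    rpkm: pd.DataFrame
    zrpkm: pd.DataFrame  # NaN at masked probes
    probe_mask: pd.Series
    svd_zrpkm: pd.DataFrame  # NaN at masked probes
    n_components_removed: int


def run_depth_pipeline(
    counts: pd.DataFrame,
    totals: pd.Series,
    probe_map: pd.DataFrame,
    n_components: int = 7,
    min_median_rpkm: float = 1.0,
) -> DepthBundle:
    """RPKM -> ZRPKM -> SVD-ZRPKM over unmasked probes, reassembled full-shape."""
    rpkm = compute_rpkm(counts, totals, probe_map)
    z, mask = zrpkm(rpkm, min_median_rpkm=min_median_rpkm)
    keep = ~mask
    svd_full = pd.DataFrame(np.nan, index=z.index, columns=z.columns)
    if keep.any():
        n_unmasked = int(keep.sum())
        s_eff = min(n_components, min(n_unmasked, z.shape[1]))
        svd_full.loc[keep] = svd_denoise(z.loc[keep], s_eff).to_numpy()
    else:
        s_eff = 0
    return DepthBundle(
        counts=counts,
        totals=totals,
        rpkm=rpkm,
        zrpkm=z,
        probe_mask=mask,
        svd_zrpkm=svd_full,
        n_components_removed=s_eff,
    )
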