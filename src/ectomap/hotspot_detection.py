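"""Hotspot detection: local-background window z-scores with input
adjustment and FDR calibration by random-tag simulation.

The method scans each chromosome with a small target window (w, default
250 bp) stepped at a fixed stride inside a much larger centered local
background window (W, default 50 kb).  The target-window tag count is
compared with its expectation under uniform scatter of the background
window's tags:

    p = w / W_eff          (W_eff = background width after clipping
                            at chromosome ends)
    e = bg * p
    z = (obs - e) / sqrt(bg * p * (1 - p))

For ChIP samples with a matched input (control) library, the input is
first normalized to the ChIP library size and its target-window count is
subtracted from the ChIP count, floored at zero; this is what makes the
calls robust to copy-number amplification shared by ChIP and input.  The
expectation and variance are taken from the raw ChIP background counts:
subtracting scaled input from the background as well drives both obs and
background to the zero floor wherever enrichment concentrates the ChIP
library, leaving the statistic undefined exactly where the signal is
(see docs/methods.md for the full argument).

The significance threshold is not parametric: random tag sets of the
observed library size, uniform over the genome, are scanned identically
(including input adjustment against the real input), and the smallest z
cutoff t with

    mean_null #{z >= t} / observed #{z >= t} <= FDR

is used.  Windows at or above the threshold are merged into hotspots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .genome_tags import GenomeDef, IntervalSet, TagSet, merge_intervals


@dataclass(frozen=True)
class HotspotParams:
    """Scan and calibration parameters.

    target_window_w/background_window_W/step follow the conventions of the
    DNase-seq hotspot method family (250 bp target inside 50 kb local
    background, 50-bp stride); fdr is the window-level false discovery
    rate; n_null_sims the number of uniform random tag sets used to
    estimate the null; merge_gap the largest gap (bp) across which
    significant windows are unioned; min_tags the smallest adjusted
    target-window count a member window must carry.
    """

    target_window_w: int = 250
    background_window_W: int = 50_000
    step: int = 50
    fdr: float = 0.001
    n_null_sims: int = 5
    merge_gap: int = 0
    min_tags: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_window_w < self.background_window_W:
            raise InvalidParameterError("need 0 < w < W")
        if not 0 < self.step <= self.target_window_w:
            raise InvalidParameterError("need 0 < step <= w")
        if not 0.0 < self.fdr < 1.0:
            raise InvalidParameterError("fdr must be in (0, 1)")
        if self.n_null_sims < 1:
            raise InvalidParameterError("n_null_sims must be >= 1")
        if self.merge_gap < 0 or self.min_tags < 0:
            raise InvalidParameterError("merge_gap and min_tags must be >= 0")


@dataclass
class WindowStats:
    """Flat per-window scan results (one row per target window)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    obs: np.ndarray       # input-adjusted ChIP count (raw if no input)
    expected: np.ndarray  # e = raw ChIP background count * w/W_eff
    z: np.ndarray

    def __len__(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "obs": self.obs,
                "expected": self.expected,
                "z": self.z,
            }
        )


@dataclass
class HotspotSet:
    """Merged significant windows with scores and provenance."""

    df: pd.DataFrame  # chrom, start, end, max_z, adj_tags, n_windows
    genome: GenomeDef
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> IntervalSet:
        return IntervalSet(
            self.df["chrom"].to_numpy(dtype=object),
            self.df["start"].to_numpy(),
            self.df["end"].to_numpy(),
            scores=self.df["max_z"].to_numpy(dtype=float),
            genome=self.genome,
        )

    def to_bed(self, path) -> None:
        """BED6: name = hotspot id, score = max z x100 clamped to [0, 1000]."""
        with open(path, "w") as fh:
            for i, row in enumerate(self.df.itertuples(index=False)):
                score = int(min(max(row.max_z * 100.0, 0.0), 1000.0))
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\thotspot_{i}\t{score}\t.\n"
                )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def window_zscore(obs, bg_count, w: int, W: int):
    """Binomial-approximation z of ``obs`` tags in a w-bp window given
    ``bg_count`` tags scattered over the surrounding W bp.

    Degenerate rule: zero background tags (or a variance of zero because
    w == W) yields z = 0.  Accepts scalars or arrays.
    """
    if w >= W or w <= 0:
        raise InvalidParameterError("need 0 < w < W")
    obs = np.asarray(obs, dtype=float)
    bg = np.asarray(bg_count, dtype=float)
    if np.any(bg < 0):
        raise InvalidParameterError("bg_count must be >= 0")
    p = w / W
    var = bg * p * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (obs - bg * p) / np.sqrt(var), 0.0)
    return float(z) if z.ndim == 0 else z


def normalize_and_subtract_input(
    chip_window_count, input_window_count, n_chip: int, n_input: int
):
    """Input-adjusted count: max(0, chip - input * N_chip/N_input).

    Scales the input library to the ChIP library size before subtracting;
    negative pseudo-counts are floored at zero.  Accepts scalars or arrays.
    """
    if n_chip <= 0 or n_input <= 0:
        raise InvalidParameterError("library sizes must be > 0")
    chip = np.asarray(chip_window_count, dtype=float)
    ctrl = np.asarray(input_window_count, dtype=float)
    adj = np.maximum(0.0, chip - ctrl * (n_chip / n_input))
    return float(adj) if adj.ndim == 0 else adj


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _interval_counts(sorted_pos: np.ndarray, starts, ends) -> np.ndarray:
    return (
        np.searchsorted(sorted_pos, ends, side="left")
        - np.searchsorted(sorted_pos, starts, side="left")
    )


def scan_windows(
    tags: TagSet,
    input_tags: TagSet | None,
    genome: GenomeDef,
    params: HotspotParams,
) -> WindowStats:
    """Slide target windows across every chromosome and score each one.

    Background windows are centered on the target window and clipped at
    chromosome ends (a chromosome shorter than W is not an error).  A
    chromosome shorter than w contributes a single truncated window.
    """
    w, W, step = params.target_window_w, params.background_window_W, params.step
    ratio = None
    if input_tags is not None:
        if input_tags.total_count == 0:
            raise InvalidParameterError("input library size must be > 0")
        ratio = tags.total_count / input_tags.total_count
    chroms, starts_all, ends_all = [], [], []
    obs_all, exp_all, z_all = [], [], []
    for name in genome:
        L = genome[name]
        starts = np.arange(0, max(L - w, 0) + 1, step, dtype=np.int64)
        ends = np.minimum(starts + w, L)
        pos = tags.positions(name)
        chip_obs = _interval_counts(pos, starts, ends).astype(float)
        centers = (starts + ends) // 2
        bs = np.clip(centers - W // 2, 0, L)
        be = np.clip(centers - W // 2 + W, 0, L)
        bg = _interval_counts(pos, bs, be).astype(float)
        if input_tags is not None:
            in_obs = _interval_counts(input_tags.positions(name), starts, ends)
            obs = np.maximum(0.0, chip_obs - in_obs * ratio)
        else:
            obs = chip_obs
        w_eff = (ends - starts).astype(float)
        p = w_eff / (be - bs).astype(float)
        e = bg * p
        var = bg * p * (1.0 - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, (obs - e) / np.sqrt(var), 0.0)
        chroms.append(np.array([name] * len(starts), dtype=object))
        starts_all.append(starts)
        ends_all.append(ends)
        obs_all.append(obs)
        exp_all.append(e)
        z_all.append(z)
    return WindowStats(
        np.concatenate(chroms),
        np.concatenate(starts_all),
        np.concatenate(ends_all),
        np.concatenate(obs_all),
        np.concatenate(exp_all),
        np.concatenate(z_all),
    )


def _uniform_tagset(genome: GenomeDef, n: int, rng: np.random.Generator) -> TagSet:
    lengths = np.array([genome[c] for c in genome], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    u = rng.integers(0, offsets[-1], size=n)
    idx = np.searchsorted(offsets, u, side="right") - 1
    names = np.array(genome.chroms, dtype=object)
    return TagSet(
        genome,
        names[idx],
        u - offsets[idx],
        np.full(n, "+", dtype="U1"),
        validate=False,
    )


def calibrate_fdr_threshold(
    tags: TagSet,
    input_tags: TagSet | None,
    genome: GenomeDef,
    params: HotspotParams,
    stats: WindowStats | None = None,
) -> float:
    """Smallest z cutoff meeting the target window-level FDR.

    Scans ``n_null_sims`` uniform random tag sets of the observed library
    size exactly like the observed data (including input adjustment
    against the real input) and returns the smallest observed z value t
    with mean-null exceedances over observed exceedances <= fdr.  Returns
    +inf with a warning when no cutoff separates signal from the null.
    Deterministic for a fixed ``params.seed``.
    """
    if stats is None:
        stats = scan_windows(tags, input_tags, genome, params)
    if len(stats) == 0 or tags.total_count == 0:
        warnings.warn("nothing to calibrate; returning +inf threshold")
        return math.inf
    rng = np.random.default_rng([int(params.seed), 0xFD5])
    null_z = []
    for _ in range(params.n_null_sims):
        null_tags = _uniform_tagset(genome, tags.total_count, rng)
        null_z.append(scan_windows(null_tags, input_tags, genome, params).z)
    null_sorted = np.sort(np.concatenate(null_z))
    obs_sorted = np.sort(stats.z)
    candidates = np.unique(obs_sorted)
    obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, candidates, side="left")
    null_ge = (
        len(null_sorted) - np.searchsorted(null_sorted, candidates, side="left")
    ) / params.n_null_sims
    ok = null_ge <= params.fdr * obs_ge
    if not ok.any():
        warnings.warn(
            "no z threshold reaches the requested FDR; returning +inf "
            "(no signal separates from the null)"
        )
        return math.inf
    return float(candidates[np.argmax(ok)])


def merge_windows(
    stats: WindowStats,
    threshold: float,
    merge_gap: int = 0,
    min_tags: int = 0,
    genome: GenomeDef | None = None,
) -> HotspotSet:
    """Union significant windows into hotspots.

    Windows with z >= threshold (ties included) and adjusted count >=
    min_tags that overlap or lie within ``merge_gap`` bp of each other are
    merged; the hotspot score is the max member z.  An infinite threshold
    that no window attains simply yields an empty set.
    """
    keep = (stats.z >= threshold) & (stats.obs >= min_tags)
    rows = []
    if keep.any():
        kc = stats.chrom[keep]
        ks = stats.start[keep]
        ke = stats.end[keep]
        kz = stats.z[keep]
        ko = stats.obs[keep]
        for name in pd.unique(kc):
            sel = kc == name
            s, e = ks[sel], ke[sel]
            order = np.argsort(s, kind="stable")
            s, e = s[order], e[order]
            z, o = kz[sel][order], ko[sel][order]
            # merge across gaps <= merge_gap by padding ends, then shrinking
            ms, me = merge_intervals(s, e + merge_gap)
            me = me - merge_gap
            # assign member windows to merged blocks
            block = np.searchsorted(ms, s, side="right") - 1
            for b in range(len(ms)):
                m = block == b
                rows.append(
                    {
                        "chrom": name,
                        "start": int(ms[b]),
                        "end": int(max(me[b], e[m].max())),
                        "max_z": float(z[m].max()),
                        "adj_tags": float(o[m].sum()),
                        "n_windows": int(m.sum()),
                    }
                )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "max_z", "adj_tags", "n_windows"]
    )
    if genome is not None and len(df):
        df = df.sort_values(
            ["chrom", "start"],
            key=lambda c: c.map({n: i for i, n in enumerate(genome)})
            if c.name == "chrom"
            else c,
        ).reset_index(drop=True)
    return HotspotSet(df, genome=genome, provenance={"threshold": threshold})


def detect_hotspots(
    chip: TagSet,
    input_tags: TagSet | None,
    genome: GenomeDef,
    params: HotspotParams,
) -> HotspotSet:
    """Scan, calibrate the FDR threshold, and merge — the full pipeline.

    The per-hotspot adjusted tag count is recomputed exactly over the
    merged interval (member windows overlap, so their sum would double
    count).  Full provenance is recorded on the result.
    """
    stats = scan_windows(chip, input_tags, genome, params)
    threshold = calibrate_fdr_threshold(chip, input_tags, genome, params, stats=stats)
    hs = merge_windows(
        stats, threshold, merge_gap=params.merge_gap,
        min_tags=params.min_tags, genome=genome,
    )
    if len(hs):
        ratio = (
            chip.total_count / input_tags.total_count if input_tags is not None else None
        )
        adj = []
        for row in hs.df.itertuples(index=False):
            pos = chip.positions(row.chrom)
            n = float(
                np.searchsorted(pos, row.end) - np.searchsorted(pos, row.start)
            )
            if input_tags is not None:
                ipos = input_tags.positions(row.chrom)
                ni = np.searchsorted(ipos, row.end) - np.searchsorted(ipos, row.start)
                n = max(0.0, n - ni * ratio)
            adj.append(n)
        hs.df["adj_tags"] = adj
    hs.provenance = {
        "params": asdict(params),
        "n_chip_tags": chip.total_count,
        "n_input_tags": input_tags.total_count if input_tags is not None else None,
        "threshold": threshold,
        "n_windows_scanned": len(stats),
        "n_hotspots": len(hs),
    }
    return hs
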