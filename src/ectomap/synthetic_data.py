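"""Synthetic MNase-ChIP-seq landscapes, qPCR plates and AFM particle tables.

The generator states a simple world with the statistical structure the
downstream analysis assumes:

* a genome of one or more chromosomes with uniform background tag placement;
* planted enriched regions ("hotspots") that multiply the ChIP placement
  probability by a dimensionless weight >= 1, invisible to the input sample;
* copy-number-amplified blocks that multiply placement probability in *both*
  ChIP and input, emulating the shared amplification a cancer genome shows;
* replicates as independent draws from the identical landscape;
* qPCR plates with Gaussian well noise on the Ct scale;
* AFM particle heights as a Gaussian mixture (e.g. tetramer-like ~2.1 nm and
  octamer-like ~2.5 nm populations).

Everything is bit-for-bit deterministic for fixed seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .genome_tags import GenomeDef, IntervalSet, TagSet

_ALPHABET = np.array(list("ACGT"))

# Default landscape: comfortably powered detection at desk scale.
DEFAULT_LANDSCAPE = dict(
    chrom_length=10_000_000,
    n_hotspots=500,
    hotspot_length=500,
    enrichment_weight=40.0,
    cnv_blocks=((2_000_000, 2_500_000), (6_000_000, 6_500_000)),
    cnv_multiplier=3.0,
    depth_chip=2_000_000,
    depth_input=2_000_000,
)


# ---------------------------------------------------------------------------
# Truth definition
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth for one simulated landscape.

    ``planted_hotspots`` carries per-interval enrichment weights (>= 1) in
    its ``scores``; ``cnv_blocks`` carries copy-number multipliers (>= 0).
    """

    genome: GenomeDef
    planted_hotspots: IntervalSet
    cnv_blocks: IntervalSet
    depth_chip: int
    depth_input: int
    seed: int = 0

    def __post_init__(self):
        if self.depth_chip <= 0 or self.depth_input <= 0:
            raise InvalidParameterError("sequencing depths must be > 0")
        hs = self.planted_hotspots
        if hs.scores is None:
            hs.scores = np.ones(len(hs))
        if len(hs) and np.any(hs.scores < 1):
            raise InvalidParameterError("hotspot enrichment weights must be >= 1")
        cnv = self.cnv_blocks
        if cnv.scores is None:
            cnv.scores = np.ones(len(cnv))
        if len(cnv) and np.any(cnv.scores < 0):
            raise InvalidParameterError("copy-number multipliers must be >= 0")
        for ivs in (hs, cnv):
            for name in np.unique(ivs.chrom.astype(str)) if len(ivs) else []:
                if name not in self.genome:
                    raise InvalidParameterError(f"unknown chromosome {name!r}")
                sel = ivs.chrom == name
                if ivs.start[sel].min() < 0 or ivs.end[sel].max() > self.genome[name]:
                    raise InvalidParameterError(
                        f"interval outside chromosome {name!r}"
                    )
        for name in np.unique(hs.chrom.astype(str)) if len(hs) else []:
            s, e = hs.per_chrom(name)
            if np.any(s[1:] < e[:-1]):
                raise InvalidParameterError("planted hotspots must be non-overlapping")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "genome": dict(self.genome.sizes),
            "planted_hotspots": [
                [str(c), int(s), int(e), float(w)]
                for c, s, e, w in zip(
                    self.planted_hotspots.chrom,
                    self.planted_hotspots.start,
                    self.planted_hotspots.end,
                    self.planted_hotspots.scores,
                )
            ],
            "cnv_blocks": [
                [str(c), int(s), int(e), float(m)]
                for c, s, e, m in zip(
                    self.cnv_blocks.chrom,
                    self.cnv_blocks.start,
                    self.cnv_blocks.end,
                    self.cnv_blocks.scores,
                )
            ],
            "depth_chip": self.depth_chip,
            "depth_input": self.depth_input,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


# ---------------------------------------------------------------------------
# Genome and tag simulation
# ---------------------------------------------------------------------------

def make_genome(
    n_chrom: int,
    chrom_length: int,
    seed: int,
    with_sequence: bool = False,
    gc: float = 0.5,
) -> tuple[GenomeDef, dict[str, str] | None]:
    """Define a genome of ``n_chrom`` chromosomes of equal length.

    With ``with_sequence`` an i.i.d. random nucleotide sequence is drawn per
    chromosome at the given GC fraction.
    """
    if n_chrom < 1 or chrom_length < 10_000:
        raise InvalidParameterError(
            "need n_chrom >= 1 and chrom_length >= 10000"
        )
    if not 0.0 < gc < 1.0:
        raise InvalidParameterError("gc must be in (0, 1)")
    genome = GenomeDef({f"chr{i + 1}": int(chrom_length) for i in range(n_chrom)})
    sequences = None
    if with_sequence:
        rng = np.random.default_rng([int(seed), 0x5E0])
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        sequences = {
            name: "".join(rng.choice(_ALPHABET, size=chrom_length, p=p))
            for name in genome
        }
    return genome, sequences


def _segments(truth: SimTruth, chrom: str, sample: str):
    """Piecewise-constant placement weight along one chromosome.

    Returns (starts, ends, weight) where weight multiplies the uniform
    background density: copy-number multiplier everywhere it applies, times
    the enrichment weight inside planted hotspots for ChIP samples only.
    """
    L = truth.genome[chrom]
    cuts = {0, L}
    hs_s, hs_e = truth.planted_hotspots.per_chrom(chrom)
    hs_sel = truth.planted_hotspots.chrom == chrom
    cnv_s, cnv_e = truth.cnv_blocks.per_chrom(chrom)
    for a in (hs_s, hs_e, cnv_s, cnv_e):
        cuts.update(int(x) for x in a)
    bounds = np.array(sorted(cuts), dtype=np.int64)
    seg_s, seg_e = bounds[:-1], bounds[1:]
    mid = (seg_s + seg_e) // 2
    weight = np.ones(len(seg_s))
    # copy number applies to both samples
    order = np.argsort(truth.cnv_blocks.start[truth.cnv_blocks.chrom == chrom])
    cnv_w = truth.cnv_blocks.scores[truth.cnv_blocks.chrom == chrom][order]
    for s, e, m in zip(cnv_s, cnv_e, cnv_w):
        weight[(mid >= s) & (mid < e)] *= m
    if sample == "chip":
        order = np.argsort(truth.planted_hotspots.start[hs_sel])
        hs_w = truth.planted_hotspots.scores[hs_sel][order]
        for s, e, w in zip(hs_s, hs_e, hs_w):
            weight[(mid >= s) & (mid < e)] *= w
    return seg_s, seg_e, weight


def simulate_tags(truth: SimTruth, sample: str, replicate_seed: int) -> TagSet:
    """Draw one tag sample (``chip`` or ``input``) from the landscape.

    Placement probability is proportional to segment length times the
    segment weight (see :func:`_segments`); strands are uniform and
    independent of position; depth is exact.
    """
    if sample not in ("chip", "input"):
        raise InvalidParameterError(f"sample must be 'chip' or 'input', got {sample!r}")
    depth = truth.depth_chip if sample == "chip" else truth.depth_input
    rng = np.random.default_rng([int(truth.seed), int(replicate_seed),
                                 0 if sample == "chip" else 1])
    seg_chrom, seg_s, seg_e, seg_w = [], [], [], []
    for name in truth.genome:
        s, e, w = _segments(truth, name, sample)
        seg_chrom.extend([name] * len(s))
        seg_s.append(s)
        seg_e.append(e)
        seg_w.append(w)
    seg_s = np.concatenate(seg_s)
    seg_e = np.concatenate(seg_e)
    seg_w = np.concatenate(seg_w)
    mass = (seg_e - seg_s) * seg_w
    probs = mass / mass.sum()
    counts = rng.multinomial(depth, probs)
    starts = np.repeat(seg_s, counts)
    spans = np.repeat(seg_e - seg_s, counts)
    pos = starts + rng.integers(0, spans)
    chrom = np.repeat(np.array(seg_chrom, dtype=object), counts)
    strand = np.where(rng.integers(0, 2, size=depth) == 0, "+", "-")
    return TagSet(truth.genome, chrom, pos, strand, validate=False)


def simulate_replicates(truth: SimTruth, n_rep: int, seeds: list[int]) -> list[TagSet]:
    """Independent ChIP replicate draws from the identical landscape."""
    if n_rep < 2:
        raise InvalidParameterError("n_rep must be >= 2")
    if len(seeds) < n_rep:
        raise InvalidParameterError(f"need at least {n_rep} seeds, got {len(seeds)}")
    return [simulate_tags(truth, "chip", s) for s in seeds[:n_rep]]


def acceptance_landscape(seed: int = 0, scale: float = 1.0, **overrides) -> SimTruth:
    """The default simulated landscape used for end-to-end checks.

    One 10-Mb chromosome, 500 planted 500-bp hotspots at enrichment weight
    40, two 500-kb copy-number blocks at multiplier 3 shared by ChIP and
    input, and 2x10^6 tags per sample.  ``scale`` < 1 shrinks the genome,
    hotspot count and depths proportionally for fast unit tests.
    """
    cfg = dict(DEFAULT_LANDSCAPE)
    cfg.update(overrides)
    L = int(cfg["chrom_length"] * scale)
    n_hs = max(1, int(cfg["n_hotspots"] * scale))
    depth_chip = max(1, int(cfg["depth_chip"] * scale))
    depth_input = max(1, int(cfg["depth_input"] * scale))
    genome = GenomeDef({"chr1": L})
    rng = np.random.default_rng([int(seed), 0xB10])
    slot = L // n_hs
    if slot <= cfg["hotspot_length"]:
        raise InvalidParameterError("genome too small for requested hotspots")
    offsets = rng.integers(0, slot - cfg["hotspot_length"], size=n_hs)
    starts = np.arange(n_hs, dtype=np.int64) * slot + offsets
    hotspots = IntervalSet(
        np.array(["chr1"] * n_hs, dtype=object),
        starts,
        starts + cfg["hotspot_length"],
        scores=np.full(n_hs, float(cfg["enrichment_weight"])),
    )
    blocks = [(int(s * scale), int(e * scale)) for s, e in cfg["cnv_blocks"]]
    cnv = IntervalSet(
        np.array(["chr1"] * len(blocks), dtype=object),
        np.array([b[0] for b in blocks], dtype=np.int64),
        np.array([b[1] for b in blocks], dtype=np.int64),
        scores=np.full(len(blocks), float(cfg["cnv_multiplier"])),
    )
    return SimTruth(genome, hotspots, cnv, depth_chip, depth_input, seed=int(seed))


# ---------------------------------------------------------------------------
# qPCR and AFM simulators
# ---------------------------------------------------------------------------

def simulate_qtpcr(
    true_fold: float,
    ct_input_mean: float = 25.0,
    noise_sd: float = 0.2,
    n_wells: int = 3,
    seed: int = 0,
) -> dict[str, "np.ndarray"]:
    """Simulate Ct triplicates for input, mock IP and IP wells.

    Before noise, the IP Ct mean equals the input mean minus log2 of the
    planted fold (one PCR cycle per twofold abundance); the mock IP is
    generated at fold 1.  Well noise is Gaussian on the Ct scale.
    Returns a mapping role -> array of Ct values.
    """
    if true_fold <= 0:
        raise InvalidParameterError("true_fold must be > 0")
    if n_wells < 2:
        raise InvalidParameterError("need at least 2 wells")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng([int(seed), 0x9C4])
    out = {}
    for role, fold in (("input", None), ("mock", 1.0), ("IP", true_fold)):
        mean = ct_input_mean if fold is None else ct_input_mean - math.log2(fold)
        out[role] = mean + noise_sd * rng.standard_normal(n_wells)
    return out


def simulate_particles(
    populations: list[tuple[float, float, int]],
    diameter_model: tuple[float, float] = (14.0, 2.0),
    seed: int = 0,
    frac_round: float = 1.0,
) -> pd.DataFrame:
    """Simulate an AFM particle table from a Gaussian height mixture.

    ``populations`` is a list of (mean nm, sd nm, n).  Diameters are drawn
    from one Gaussian (mean, sd) truncated at 1 nm; ``frac_round`` sets the
    fraction of particles flagged as round/elliptical.
    """
    for m, s, n in populations:
        if s < 0:
            raise InvalidParameterError("height sd must be >= 0")
        if n < 0:
            raise InvalidParameterError("population size must be >= 0")
    rng = np.random.default_rng([int(seed), 0xAF8])
    heights, pops = [], []
    for i, (m, s, n) in enumerate(populations):
        heights.append(m + s * rng.standard_normal(n))
        pops.extend([i] * n)
    heights = np.concatenate(heights) if heights else np.zeros(0)
    total = len(heights)
    dm, ds = diameter_model
    diam = np.maximum(dm + ds * rng.standard_normal(total), 1.0)
    shape_ok = rng.random(total) < frac_round
    return pd.DataFrame(
        {
            "height": np.maximum(heights, 1e-6),
            "diameter": diam,
            "shape_ok": shape_ok,
            "population": pops,
        }
    )
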