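"""AFM particle filtering and summaries, and fragment-length binning.

Particle tables carry per-particle maximum height (nm), diameter (nm) and
a shape flag (round/elliptical as set by the upstream image analysis).
Height comparisons between particle populations use Welch's
unequal-variance two-sample t-test.  Fragment tables carry per-record DNA
length (bp) and fluorescence abundance (pg/uL); lengths below a cutoff
are binned into k equal-width categories and reported as percent of
retained abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedStatisticError,
)

DEFAULT_DIAMETER_CUTOFF = 20.0  # nm; strictly DNA-associated particles


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"table lacks columns {missing}")


def filter_particles(
    table: pd.DataFrame,
    diameter_cutoff: float = DEFAULT_DIAMETER_CUTOFF,
    require_shape: bool = False,
) -> pd.DataFrame:
    """Keep particles with diameter strictly below the cutoff.

    With ``require_shape`` only rows flagged round/elliptical survive.
    Idempotent.
    """
    if diameter_cutoff <= 0:
        raise InvalidParameterError("diameter cutoff must be > 0")
    _require_columns(table, ("diameter",))
    keep = table["diameter"] < diameter_cutoff
    if require_shape:
        _require_columns(table, ("shape_ok",))
        keep &= table["shape_ok"].astype(bool)
    return table.loc[keep].reset_index(drop=True)


def height_summary(table: pd.DataFrame) -> tuple[float, float, int]:
    """(sample mean, sample sd, n) of particle heights."""
    _require_columns(table, ("height",))
    h = table["height"].to_numpy(dtype=float)
    if len(h) == 0:
        raise InvalidInputError("empty particle table")
    sd = float(h.std(ddof=1)) if len(h) >= 2 else float("nan")
    return float(h.mean()), sd, len(h)


def format_height_summary(table: pd.DataFrame) -> str:
    """Render a summary as ``"m ± s (n)"`` with 2 decimals."""
    m, s, n = height_summary(table)
    return f"{m:.2f} ± {s:.2f} ({n})"


def compare_heights(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Two-sided Welch t-test p-value for a height difference."""
    _require_columns(a, ("height",))
    _require_columns(b, ("height",))
    ha = a["height"].to_numpy(dtype=float)
    hb = b["height"].to_numpy(dtype=float)
    if len(ha) < 2 or len(hb) < 2:
        raise InvalidInputError("need n >= 2 in both tables")
    if ha.std(ddof=1) == 0 and hb.std(ddof=1) == 0:
        raise UndefinedStatisticError("both samples are degenerate (zero variance)")
    return float(sps.ttest_ind(ha, hb, equal_var=False).pvalue)


def bin_fragment_lengths(
    fragments: pd.DataFrame, max_bp: int = 350, k: int = 4
) -> pd.DataFrame:
    """Bin sub-``max_bp`` fragments into k equal-width length categories.

    Records with length >= max_bp are excluded (strict <).  Returns per-bin
    [low, high) edges and percent of total retained abundance (sums to 100).
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if max_bp <= 0:
        raise InvalidParameterError("max_bp must be > 0")
    _require_columns(fragments, ("length", "abundance"))
    lengths = fragments["length"].to_numpy(dtype=float)
    abundance = fragments["abundance"].to_numpy(dtype=float)
    keep = lengths < max_bp
    if not keep.any():
        raise InvalidInputError(f"no fragments below {max_bp} bp")
    lengths, abundance = lengths[keep], abundance[keep]
    edges = np.linspace(0.0, float(max_bp), k + 1)
    totals, _ = np.histogram(lengths, bins=edges, weights=abundance)
    pct = 100.0 * totals / abundance.sum()
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "percent": pct}
    )
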