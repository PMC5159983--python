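"""Fixed-width genome windows and their methylation summaries.

The genome is tiled into non-overlapping windows (default 20 kb).  Window
methylation is count-pooled: the fraction is the sum of methylated calls over
the sum of all calls for CpGs in the window, not a mean of per-CpG fractions
— at x1-2 coverage individual CpG fractions are near-binary, so pooling the
counts is the defensible estimator.  Windows with fewer than ``min_support``
total calls are reported as missing rather than noisy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CPG_COLUMNS, CpGTrack, ValidationError

_SEX_MITO = re.compile(r"^(chr)?(x|y|m|mt)$", re.IGNORECASE)

WINDOW_COLUMNS = ["chrom", "start", "end", "partial"]


def autosome_filter(chroms: Iterable[str]) -> list[str]:
    """Chromosome names that do not look like X, Y or mitochondrial."""
    return [c for c in chroms if not _SEX_MITO.match(c)]


@dataclass
class WindowTrack:
    """Tiled windows with pooled methylation support.

    ``data`` columns: ``chrom, start, end, partial, meth_sum, total_sum,
    n_cpgs, fraction``.  ``fraction`` is NaN exactly where
    ``total_sum < min_support``.
    """

    data: pd.DataFrame
    width: int
    min_support: int
    sample_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def fractions(self) -> np.ndarray:
        return self.data["fraction"].to_numpy(dtype=float)

    def observed(self) -> pd.DataFrame:
        return self.data[self.data["fraction"].notna()]

    def to_bedgraph(self, path) -> None:
        """bedGraph of fractions plus a sidecar ``<path>.support.tsv``."""
        obs = self.observed()
        with open(path, "w", newline="\n") as fh:
            for row in obs.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.fraction:.6f}\n")
        self.data.to_csv(str(path) + ".support.tsv", sep="\t", index=False)


def tile_windows(genome: Mapping[str, int], width: int = 20_000) -> pd.DataFrame:
    """Tile each chromosome with half-open windows [0,w), [w,2w), ...

    The final window of a chromosome is retained even when shorter than
    ``width`` and flagged ``partial``.  An empty genome yields an empty frame.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    rows = []
    for chrom, length in genome.items():
        if length <= 0:
            raise ValidationError(f"non-positive length for {chrom}")
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), bool(e - s < width)))
    if not rows:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def window_methylation(
    track: CpGTrack,
    windows: pd.DataFrame,
    min_support: int = 10,
) -> WindowTrack:
    """Pool CpG counts into windows and compute per-window fractions.

    A CpG belongs to the window whose half-open span contains its position.
    Windows whose pooled ``total_sum`` falls below ``min_support`` get a
    missing (NaN) fraction.
    """
    win = windows.reset_index(drop=True).copy()
    meth = np.zeros(len(win), dtype=np.int64)
    total = np.zeros(len(win), dtype=np.int64)
    ncpg = np.zeros(len(win), dtype=np.int64)
    for chrom, grp in track.data.groupby("chrom", sort=False):
        mask = (win["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        widx = np.flatnonzero(mask)
        starts = win.loc[mask, "start"].to_numpy()
        ends = win.loc[mask, "end"].to_numpy()
        pos = grp["pos"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        j = j[ok]
        meth_in = grp["meth"].to_numpy()[ok]
        total_in = grp["total"].to_numpy()[ok]
        np.add.at(meth, widx[j], meth_in)
        np.add.at(total, widx[j], total_in)
        np.add.at(ncpg, widx[j], 1)
    win["meth_sum"] = meth
    win["total_sum"] = total
    win["n_cpgs"] = ncpg
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total >= min_support, meth / np.where(total == 0, 1, total), np.nan)
    frac = np.where(total == 0, np.nan, frac)
    win["fraction"] = frac
    return WindowTrack(win, width=int((windows["end"] - windows["start"]).max()) if len(windows) else 0,
                       min_support=min_support, sample_id=track.sample_id)


def pool_samples(tracks: Sequence[CpGTrack], sample_id: str = "pooled") -> CpGTrack:
    """Sum per-CpG counts across samples into one high-coverage consensus.

    Every position observed in any sample appears in the pool.  All tracks
    must share a genome when genomes are attached.
    """
    if not tracks:
        raise ValueError("no tracks to pool")
    genomes = [t.genome for t in tracks if t.genome is not None]
    genome = genomes[0] if genomes else None
    for g in genomes[1:]:
        if g != genome:
            raise ValidationError("tracks carry conflicting genomes")
    frames = [t.data for t in tracks if len(t.data)]
    if not frames:
        return CpGTrack(sample_id, pd.DataFrame(columns=CPG_COLUMNS), genome=genome)
    pooled = (
        pd.concat(frames, ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]]
        .sum()
    )
    return CpGTrack(sample_id, pooled[CPG_COLUMNS], genome=genome)


def fraction_windows_below(wt: WindowTrack, threshold: float = 0.60) -> float:
    """Proportion of non-missing windows with methylation strictly below
    ``threshold``.  A window at exactly the threshold counts as not below.
    """
    frac = wt.fractions
    obs = frac[~np.isnan(frac)]
    if obs.size == 0:
        raise ValidationError("all windows missing; proportion undefined")
    return float(np.mean(obs < threshold))


@dataclass
class BinSummary:
    """Across-sample summary of per-sample window-methylation histograms.

    Window fractions are binned at 1% increments into 100 bins covering
    [0, 1]; per sample the bin masses are normalised to sum to one, and per
    bin the min, mean, max and (population) standard deviation across samples
    are reported.
    """

    data: pd.DataFrame          # bin_left, bin_right, min, mean, max, sd
    masses: pd.DataFrame        # per-sample normalised histograms, bins x samples

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def binned_distribution(window_tracks: Sequence[WindowTrack]) -> BinSummary:
    """1%-bin histograms of window methylation, summarised across samples."""
    if not window_tracks:
        raise ValueError("need at least one sample")
    edges = np.linspace(0.0, 1.0, 101)
    cols = {}
    for i, wt in enumerate(window_tracks):
        frac = wt.fractions
        obs = frac[~np.isnan(frac)]
        if obs.size == 0:
            raise ValidationError(f"sample {wt.sample_id!r} has no observed windows")
        hist, _ = np.histogram(obs, bins=edges)
        cols[wt.sample_id or f"sample_{i}"] = hist / hist.sum()
    masses = pd.DataFrame(cols)
    arr = masses.to_numpy()
    summary = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "min": arr.min(axis=1),
            "mean": arr.mean(axis=1),
            "max": arr.max(axis=1),
            "sd": arr.std(axis=1, ddof=0),
        }
    )
    return BinSummary(summary, masses)


def smooth_profile(
    positions: np.ndarray,
    values: np.ndarray,
    bandwidth: float,
) -> np.ndarray:
    """Smooth a genomic profile with a first-order (local linear) polynomial.

    At each position a degree-1 weighted least-squares fit over neighbours
    within ``bandwidth`` bp is evaluated, with tricube kernel weights — the
    classical LOESS building block.  Missing (NaN) values are excluded from
    every fit and remain missing in the output.  Local linear fits reproduce
    constant and exactly linear profiles.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    obs = ~np.isnan(y)
    if obs.sum() < 2:
        raise ValidationError("need at least 2 non-missing points")
    xo, yo = x[obs], y[obs]
    out = np.full_like(y, np.nan)
    for i in np.flatnonzero(obs):
        d = np.abs(xo - x[i])
        w = np.clip(1.0 - (d / bandwidth) ** 3, 0.0, None) ** 3
        sel = w > 0
        if sel.sum() < 2:
            out[i] = y[i]
            continue
        xs, ys, ws = xo[sel] - x[i], yo[sel], w[sel]
        # weighted normal equations for intercept + slope; value at centre
        # is the intercept
        s0, s1, s2 = ws.sum(), (ws * xs).sum(), (ws * xs * xs).sum()
        t0, t1 = (ws * ys).sum(), (ws * xs * ys).sum()
        det = s0 * s2 - s1 * s1
        if det <= 1e-12 * max(s0 * s2, 1e-300):
            out[i] = t0 / s0
        else:
            out[i] = (s2 * t0 - s1 * t1) / det
    return out


def kernel_density(
    window_tracks: Sequence[WindowTrack],
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gaussian kernel density of window methylation per sample.

    Bandwidth by Silverman's rule.  Plotting convenience only; all statistics
    run on the raw fractions or the 1%-bin histograms.
    """
    from scipy.stats import gaussian_kde

    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    out = {"methylation": grid}
    for i, wt in enumerate(window_tracks):
        frac = wt.fractions
        obs = frac[~np.isnan(frac)]
        kde = gaussian_kde(obs, bw_method="silverman")
        out[wt.sample_id or f"sample_{i}"] = kde(grid)
    return pd.DataFrame(out)
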