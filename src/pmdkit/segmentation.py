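"""Two-state PMD/HMD segmentation of a pooled methylome.

The segmentation model is a supervised two-state hidden Markov model over
fixed-width window methylation fractions.  Placental genomes alternate
between partially methylated domains (PMDs, intermediate methylation,
typically >100 kb) and highly methylated domains (HMDs).  Emissions are
Gaussian per state on the window fraction; training is closed-form from
hand-annotated example domains (state means/SDs from the annotated windows,
self-transitions from the mean annotated run length); decoding is Viterbi in
log space, so the output is a hard maximum-probability domain map.

Missing windows (insufficient coverage) carry no emission term: the decoder
bridges them on transitions alone and they are absorbed into the flanking
decoded path.

Use either the function layer (:func:`train_supervised`,
:func:`viterbi_segment`, ...) or the model/results pair
(:class:`DomainSegmentation` -> :class:`DomainSegmentationResults`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CpGTrack, ValidationError, read_bed, write_bed
from .windows import WindowTrack

STATES = ("PMD", "HMD")
SD_FLOOR = 0.01  # guards degenerate constant training data


@dataclass
class HmmModel:
    """Two-state Gaussian HMM parameters.

    Arrays are ordered (PMD, HMD).  ``transitions[i, j]`` is the probability
    of moving from state i to state j between adjacent windows; ``initial``
    defaults to the stationary distribution of the transition matrix.
    """

    means: np.ndarray
    sds: np.ndarray
    transitions: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.means.shape != (2,) or self.sds.shape != (2,):
            raise ValidationError("emission parameters must have shape (2,)")
        if (self.sds <= 0).any():
            raise ValidationError("emission sd must be positive")
        if not self.means[0] < self.means[1]:
            raise ValidationError("PMD emission mean must be below HMD emission mean")
        if self.transitions.shape != (2, 2) or np.abs(self.transitions.sum(axis=1) - 1).max() > 1e-12:
            raise ValidationError("transition rows must sum to 1")
        if np.abs(self.initial.sum() - 1) > 1e-9:
            raise ValidationError("initial distribution must sum to 1")

    def to_text(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            for i, s in enumerate(STATES):
                fh.write(f"{s}\tmean\t{float(self.means[i])!r}\n")
                fh.write(f"{s}\tsd\t{float(self.sds[i])!r}\n")
                fh.write(f"{s}\ttransition\t{float(self.transitions[i, 0])!r}\t{float(self.transitions[i, 1])!r}\n")
                fh.write(f"{s}\tinitial\t{float(self.initial[i])!r}\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "HmmModel":
        means, sds = np.zeros(2), np.zeros(2)
        trans, init = np.zeros((2, 2)), np.zeros(2)
        for line in Path(path).read_text().splitlines():
            fields = line.split("\t")
            i = STATES.index(fields[0])
            if fields[1] == "mean":
                means[i] = float(fields[2])
            elif fields[1] == "sd":
                sds[i] = float(fields[2])
            elif fields[1] == "transition":
                trans[i] = [float(fields[2]), float(fields[3])]
            elif fields[1] == "initial":
                init[i] = float(fields[2])
        return cls(means, sds, trans, init)


DOMAIN_COLUMNS = ["chrom", "start", "end", "state", "n_windows"]


@dataclass
class DomainSet:
    """Ordered PMD/HMD intervals: within a chromosome, sorted, non-overlapping
    and strictly alternating in state (adjacent same-state intervals would be
    one domain)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        if "n_windows" not in df.columns:
            df["n_windows"] = 0
        df = df[DOMAIN_COLUMNS]
        bad = set(df["state"]) - set(STATES)
        if bad:
            raise ValidationError(f"unknown domain states: {sorted(bad)}")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("domain with start >= end")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for _, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError("overlapping domains")
            st = grp["state"].to_numpy()
            if (st[1:] == st[:-1]).any():
                raise ValidationError("adjacent domains share a state")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def of_state(self, state: str) -> pd.DataFrame:
        return self.data[self.data["state"] == state]

    def restrict(self, chrom: str) -> "DomainSet":
        return DomainSet(self.data[self.data["chrom"] == chrom])

    def to_bed(self, path: str | Path) -> None:
        df = self.data.rename(columns={"state": "name"})[["chrom", "start", "end", "name"]]
        write_bed(df, path)

    @classmethod
    def from_bed(cls, path: str | Path) -> "DomainSet":
        df = read_bed(path, allow_overlap=False).rename(columns={"name": "state"})
        return cls(df.assign(n_windows=0))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _windows_in_intervals(windows: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of windows fully contained in some interval."""
    mask = np.zeros(len(windows), dtype=bool)
    win = windows.reset_index(drop=True)
    for chrom, ivs in intervals.groupby("chrom", sort=False):
        sel = win["chrom"] == chrom
        if not sel.any():
            continue
        ws = win.loc[sel, "start"].to_numpy()
        we = win.loc[sel, "end"].to_numpy()
        hit = np.zeros(sel.sum(), dtype=bool)
        for s, e in zip(ivs["start"], ivs["end"]):
            hit |= (ws >= s) & (we <= e)
        mask[np.flatnonzero(sel.to_numpy())] = hit
    return mask


def train_supervised(pooled: WindowTrack, training: pd.DataFrame) -> HmmModel:
    """Estimate HMM parameters from annotated PMD/HMD example segments.

    Emission mean/SD per state are the sample mean and SD (ddof=1, floored at
    0.01) of observed window fractions inside that state's training
    intervals.  Each state's self-transition probability is
    ``1 - 1 / (mean run length)`` where a run is one training interval
    measured in contained observed windows.  The initial distribution is the
    stationary distribution of the resulting transition matrix.
    """
    training = pd.DataFrame(training)
    label_col = "state" if "state" in training.columns else "name"
    labels = set(training[label_col])
    if not labels <= set(STATES):
        raise ValidationError(f"training labels must be PMD/HMD, got {sorted(labels)}")
    win = pooled.data.reset_index(drop=True)
    obs = win["fraction"].notna().to_numpy()
    means, sds, selfs = np.zeros(2), np.zeros(2), np.zeros(2)
    for i, state in enumerate(STATES):
        ivs = training[training[label_col] == state]
        mask = _windows_in_intervals(win, ivs) & obs
        vals = win.loc[mask, "fraction"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValidationError(f"state {state}: need >=2 observed training windows, got {vals.size}")
        means[i] = vals.mean()
        sds[i] = max(float(np.std(vals, ddof=1)), SD_FLOOR)
        run_lengths = []
        for s, e, c in zip(ivs["start"], ivs["end"], ivs["chrom"]):
            sel = (win["chrom"] == c) & (win["start"] >= s) & (win["end"] <= e) & obs
            n = int(sel.sum())
            if n:
                run_lengths.append(n)
        mean_run = float(np.mean(run_lengths))
        selfs[i] = 1.0 - 1.0 / mean_run if mean_run > 1 else 0.5
    trans = np.array([[selfs[0], 1 - selfs[0]], [1 - selfs[1], selfs[1]]])
    # stationary distribution of a 2x2 chain has the closed form below
    denom = (1 - trans[0, 0]) + (1 - trans[1, 1])
    initial = np.array([(1 - trans[1, 1]) / denom, (1 - trans[0, 0]) / denom])
    return HmmModel(means, sds, trans, initial)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _viterbi_path(frac: np.ndarray, model: HmmModel) -> np.ndarray:
    """Hard Viterbi decode of one chromosome's window fractions.

    NaN entries contribute no emission term (transition-only bridging).
    Ties resolve toward PMD (state index 0) via first-maximum argmax.
    """
    n = frac.size
    with np.errstate(divide="ignore"):
        log_init = np.log(model.initial)
        log_trans = np.log(model.transitions)
    # emission log-likelihood matrix, zeros where missing
    emit = np.zeros((n, 2))
    obs = ~np.isnan(frac)
    if obs.any():
        x = frac[obs][:, None]
        emit[obs] = stats.norm.logpdf(x, loc=model.means[None, :], scale=model.sds[None, :])
    delta = log_init + emit[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + log_trans          # cand[i, j]: from i to j
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(2)] + emit[t]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def viterbi_segment(model: HmmModel, pooled: WindowTrack) -> DomainSet:
    """Decode the maximum-probability PMD/HMD path and merge it into domains.

    Runs of identical decoded states become one domain spanning from the
    first window's start to the last window's end.  A chromosome whose
    windows are all missing is skipped with a warning.
    """
    rows = []
    for chrom, grp in pooled.data.groupby("chrom", sort=False):
        frac = grp["fraction"].to_numpy(dtype=float)
        if np.isnan(frac).all():
            warnings.warn(f"{chrom}: all windows missing; no domains decoded", stacklevel=2)
            continue
        path = _viterbi_path(frac, model)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        change = np.flatnonzero(path[1:] != path[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(path)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(starts[a]), int(ends[b - 1]), STATES[path[a]], int(b - a)))
    return DomainSet(pd.DataFrame(rows, columns=DOMAIN_COLUMNS))


def postprocess_domains(
    raw: DomainSet,
    min_length: int = 100_000,
    policy: str = "keep",
) -> DomainSet:
    """Optionally absorb short domains into their flanking neighbours.

    With ``policy="merge"``, any domain shorter than ``min_length`` bp is
    absorbed into the longer flanking neighbour (ties to the preceding one),
    after which same-state neighbours re-merge; the pass repeats until no
    short domain remains.  ``policy="keep"`` (the default) returns the raw
    decode untouched — PMDs are usually over 100 kb, but trimming is opt-in.
    """
    if policy == "keep":
        return raw
    if policy != "merge":
        raise ValueError(f"unknown policy: {policy!r}")
    out_rows = []
    for chrom, grp in raw.data.groupby("chrom", sort=False):
        doms = [list(r) for r in grp[DOMAIN_COLUMNS].itertuples(index=False)]
        while True:
            # re-merge same-state neighbours first
            merged = [doms[0]]
            for d in doms[1:]:
                if d[3] == merged[-1][3]:
                    merged[-1][2] = d[2]
                    merged[-1][4] += d[4]
                else:
                    merged.append(d)
            doms = merged
            if len(doms) == 1:
                break
            lengths = [d[2] - d[1] for d in doms]
            short = [i for i, L in enumerate(lengths) if L < min_length]
            if not short:
                break
            i = min(short, key=lambda k: (lengths[k], k))
            if i == 0:
                doms[i][3] = doms[1][3]
            elif i == len(doms) - 1:
                doms[i][3] = doms[i - 1][3]
            else:
                prev_len, next_len = lengths[i - 1], lengths[i + 1]
                doms[i][3] = doms[i - 1][3] if prev_len >= next_len else doms[i + 1][3]
        out_rows.extend(doms)
    return DomainSet(pd.DataFrame(out_rows, columns=DOMAIN_COLUMNS))


# ---------------------------------------------------------------------------
# Per-sample domain summaries
# ---------------------------------------------------------------------------

@dataclass
class DomainMethylationTable:
    """Count-pooled methylation per sample x domain, with state summaries.

    ``fractions`` has one row per domain (indexed like ``domains.data``) and
    one column per sample; NaN marks a domain with zero coverage in that
    sample.  Global per-state means are count-weighted pools over all of a
    sample's CpGs inside that state's domains.
    """

    domains: DomainSet
    fractions: pd.DataFrame
    meth_sums: pd.DataFrame
    total_sums: pd.DataFrame

    def global_means(self) -> pd.DataFrame:
        """Per-sample genome-wide PMD and HMD means (count-pooled)."""
        rows = {}
        for state in STATES:
            idx = self.domains.data["state"] == state
            m = self.meth_sums[idx.to_numpy()].sum(axis=0)
            t = self.total_sums[idx.to_numpy()].sum(axis=0)
            rows[f"{state.lower()}_mean"] = m / t.where(t > 0)
        return pd.DataFrame(rows)

    def per_chromosome_means(self) -> pd.DataFrame:
        """Sample x (chromosome, state) count-pooled means, long format."""
        dom = self.domains.data
        recs = []
        for (chrom, state), idx in dom.groupby(["chrom", "state"]).groups.items():
            m = self.meth_sums.loc[idx].sum(axis=0)
            t = self.total_sums.loc[idx].sum(axis=0)
            frac = m / t.where(t > 0)
            for sample, v in frac.items():
                recs.append((sample, chrom, state, v))
        return pd.DataFrame(recs, columns=["sample_id", "chrom", "state", "fraction"])

    def to_tsv(self, path: str | Path) -> None:
        dom = self.domains.data
        out = pd.concat(
            [dom[["chrom", "start", "end", "state"]].reset_index(drop=True),
             self.fractions.reset_index(drop=True)],
            axis=1,
        )
        out.to_csv(path, sep="\t", index=False)


def _pooled_interval_counts(tracks: Sequence[CpGTrack], intervals: pd.DataFrame):
    """Per-sample (meth, total) count sums over sorted non-overlapping
    intervals.  Returns two DataFrames, rows aligned with ``intervals``."""
    iv = intervals.reset_index(drop=True)
    meth, total = {}, {}
    for track in tracks:
        m = np.zeros(len(iv), dtype=np.int64)
        t = np.zeros(len(iv), dtype=np.int64)
        for chrom, grp in track.data.groupby("chrom", sort=False):
            sel = iv["chrom"] == chrom
            if not sel.any():
                continue
            didx = np.flatnonzero(sel.to_numpy())
            starts = iv.loc[sel, "start"].to_numpy()
            ends = iv.loc[sel, "end"].to_numpy()
            pos = grp["pos"].to_numpy()
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
            np.add.at(m, didx[j[ok]], grp["meth"].to_numpy()[ok])
            np.add.at(t, didx[j[ok]], grp["total"].to_numpy()[ok])
        meth[track.sample_id] = m
        total[track.sample_id] = t
    return pd.DataFrame(meth), pd.DataFrame(total)


def interval_methylation(tracks: Sequence[CpGTrack], intervals: pd.DataFrame) -> pd.DataFrame:
    """Count-pooled methylation fraction per sample over arbitrary sorted,
    non-overlapping intervals (features x samples; NaN where uncovered)."""
    meth_df, total_df = _pooled_interval_counts(tracks, intervals)
    with np.errstate(invalid="ignore", divide="ignore"):
        return meth_df / total_df.where(total_df > 0)


def sample_domain_methylation(
    tracks: Sequence[CpGTrack],
    domains: DomainSet,
) -> DomainMethylationTable:
    """Pool each sample's CpG counts within each decoded domain."""
    meth_df, total_df = _pooled_interval_counts(tracks, domains.data)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = meth_df / total_df.where(total_df > 0)
    return DomainMethylationTable(domains, frac, meth_df, total_df)


def pmd_hmd_correlation(
    table: DomainMethylationTable | pd.DataFrame,
    groups: Mapping[str, str] | None = None,
) -> dict:
    """Correlate per-sample global PMD and HMD methylation means.

    Returns the Pearson correlation over all samples plus, per group, the
    correlation and the least-squares regression line (HMD mean regressed on
    PMD mean).  Requires >=3 samples with both means defined and nonzero
    variance on both axes.
    """
    gm = table.global_means() if isinstance(table, DomainMethylationTable) else pd.DataFrame(table)
    gm = gm.dropna()
    if len(gm) < 3:
        raise ValidationError("need >=3 samples with both global means defined")
    x = gm["pmd_mean"].to_numpy(dtype=float)
    y = gm["hmd_mean"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    r_all, p_all = stats.pearsonr(x, y)
    report = {"r": float(r_all), "p": float(p_all), "n": int(len(gm)), "groups": {}}
    if groups is not None:
        for g in sorted(set(groups.values())):
            ids = [s for s in gm.index if groups.get(s) == g]
            if len(ids) < 3:
                continue
            xs = gm.loc[ids, "pmd_mean"].to_numpy(dtype=float)
            ys = gm.loc[ids, "hmd_mean"].to_numpy(dtype=float)
            if np.std(xs) == 0 or np.std(ys) == 0:
                continue
            r, p = stats.pearsonr(xs, ys)
            slope, intercept = np.polyfit(xs, ys, 1)
            report["groups"][g] = {
                "r": float(r), "p": float(p), "n": len(ids),
                "slope": float(slope), "intercept": float(intercept),
            }
    return report


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class DomainSegmentation:
    """Supervised PMD/HMD segmentation model.

    Built from a pooled consensus :class:`~pmdkit.windows.WindowTrack` and a
    frame of annotated training intervals (columns ``chrom, start, end`` and
    a ``state``/``name`` label in {PMD, HMD}).  :meth:`fit` trains the
    emission and transition parameters in closed form and Viterbi-decodes the
    whole pooled track.
    """

    def __init__(self, pooled: WindowTrack, training: pd.DataFrame):
        self.pooled = pooled
        self.training = pd.DataFrame(training)

    @classmethod
    def from_tracks(
        cls,
        tracks: Sequence[CpGTrack],
        training: pd.DataFrame,
        width: int = 20_000,
        min_support: int = 10,
    ) -> "DomainSegmentation":
        """Pool per-sample tracks, window them, and build the model."""
        from .windows import pool_samples, tile_windows, window_methylation

        pooled = pool_samples(tracks)
        if pooled.genome is None:
            raise ValidationError("tracks must carry a genome to be windowed")
        wins = tile_windows(pooled.genome, width=width)
        wt = window_methylation(pooled, wins, min_support=min_support)
        return cls(wt, training)

    def fit(self, min_length: int = 100_000, policy: str = "keep") -> "DomainSegmentationResults":
        model = train_supervised(self.pooled, self.training)
        raw = viterbi_segment(model, self.pooled)
        domains = postprocess_domains(raw, min_length=min_length, policy=policy)
        return DomainSegmentationResults(self, model, domains)


class DomainSegmentationResults:
    """Fitted segmentation: HMM parameters plus the decoded domain map."""

    def __init__(self, model: DomainSegmentation, hmm: HmmModel, domains: DomainSet):
        self.model = model
        self.hmm = hmm
        self.domains = domains

    def domain_methylation(self, tracks: Sequence[CpGTrack]) -> DomainMethylationTable:
        return sample_domain_methylation(tracks, self.domains)

    def summary(self) -> str:
        dom = self.domains.data
        lines = ["Two-state PMD/HMD segmentation", "=" * 34]
        for i, s in enumerate(STATES):
            d = dom[dom["state"] == s]
            mean_len = (d["end"] - d["start"]).mean() if len(d) else float("nan")
            lines.append(
                f"{s}: emission mean={self.hmm.means[i]:.4f} sd={self.hmm.sds[i]:.4f} "
                f"self-transition={self.hmm.transitions[i, i]:.4f} "
                f"n_domains={len(d)} mean_length={mean_len:,.0f} bp"
            )
        total = (dom["end"] - dom["start"]).sum()
        pmd = (dom.loc[dom['state'] == 'PMD', 'end'] - dom.loc[dom['state'] == 'PMD', 'start']).sum()
        if total:
            lines.append(f"PMD genome share: {pmd / total:.1%}")
        return "\n".join(lines)
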