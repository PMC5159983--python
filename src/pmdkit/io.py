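"""Reading, writing and post-alignment bookkeeping for bisulfite count data.

Internal coordinates are 0-based half-open throughout, matching BED.  The
``cpg_report`` file dialect uses 1-based positions (the prevalent convention
for per-CpG reports) and the reader converts on the way in.  Per-CpG tracks
hold strand-combined methylated/total read-call counts on the plus-strand C
of each CpG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DIAGNOSES = ("ASD", "TD", "ODC")
SEXES = ("M", "F")

CPG_COLUMNS = ["chrom", "pos", "meth", "total"]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class CpGTrack:
    """One sample's strand-combined per-CpG methylation counts.

    Parameters
    ----------
    sample_id : str
        Sample identifier.
    data : pandas.DataFrame
        Columns ``chrom, pos, meth, total``; unique on ``(chrom, pos)`` and
        sorted by ``(chrom, pos)``.  ``pos`` is the 0-based coordinate of the
        plus-strand C of the CpG.
    genome : mapping, optional
        Chromosome name -> length in bp.  When supplied, every record must
        fall inside its chromosome.
    meta : dict
        Free-form bookkeeping (dropped zero-coverage records, unpaired
        minus-strand calls, ...).
    """

    sample_id: str
    data: pd.DataFrame
    genome: dict[str, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data, columns=CPG_COLUMNS).copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["meth"] = df["meth"].astype(np.int64)
        df["total"] = df["total"].astype(np.int64)
        if (df["pos"] < 0).any():
            raise ValidationError("negative CpG position")
        if (df["meth"] < 0).any() or (df["total"] < 0).any():
            raise ValidationError("negative count")
        if (df["meth"] > df["total"]).any():
            raise ValidationError("meth count exceeds total count")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValidationError("duplicate (chrom, pos) records in track")
        if self.genome is not None:
            self.genome = dict(self.genome)
            unknown = set(df["chrom"]) - set(self.genome)
            if unknown:
                raise ValidationError(f"chromosomes absent from genome: {sorted(unknown)}")
            lengths = df["chrom"].map(self.genome)
            if (df["pos"] >= lengths).any():
                raise ValidationError("CpG position beyond chromosome length")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_cpgs(self) -> int:
        return len(self.data)

    def pooled_fraction(self) -> float:
        """Count-pooled methylation fraction over the whole track."""
        total = int(self.data["total"].sum())
        if total == 0:
            raise ValidationError("track has no coverage")
        return float(self.data["meth"].sum()) / total

    def subset(self, intervals: pd.DataFrame) -> pd.DataFrame:
        """Records whose position falls in any of the half-open intervals."""
        keep = []
        for chrom, grp in self.data.groupby("chrom", sort=False):
            ivs = intervals[intervals["chrom"] == chrom]
            if ivs.empty:
                continue
            starts = ivs["start"].to_numpy()
            ends = ivs["end"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            pos = grp["pos"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            keep.append(grp[ok])
        if not keep:
            return self.data.iloc[0:0]
        return pd.concat(keep, ignore_index=True)


@dataclass
class SampleSheet:
    """Cohort metadata: one row per sample.

    Required columns: ``sample_id, diagnosis, sex, run, order, coverage,
    race_ethnicity``.  Diagnosis is one of ASD/TD/ODC, sex one of M/F.
    """

    data: pd.DataFrame

    REQUIRED = ["sample_id", "diagnosis", "sex", "run", "order", "coverage", "race_ethnicity"]

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        bad_dx = set(df["diagnosis"]) - set(DIAGNOSES)
        if bad_dx:
            raise ValidationError(f"unknown diagnosis values: {sorted(bad_dx)}")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex values: {sorted(bad_sex)}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CpG count readers
# ---------------------------------------------------------------------------

def read_cpg_counts(
    path: str | Path,
    dialect: str,
    sample_id: str | None = None,
    genome: Mapping[str, int] | None = None,
) -> CpGTrack:
    """Read a per-CpG count file into a validated, sorted :class:`CpGTrack`.

    Two tab-delimited dialects are supported and must be named explicitly:

    ``cpg_report``
        ``chrom, pos (1-based), meth, total`` — positions are converted to
        0-based on input.
    ``bedgraph``
        ``chrom, start (0-based), end, meth, total`` — a count-carrying
        bedGraph; a 4-column fraction-only bedGraph is rejected because
        fractions without counts cannot be pooled downstream.

    Zero-total records carry no information and are dropped; the number
    dropped is recorded in ``track.meta["n_zero_total_dropped"]``.
    """
    if dialect not in ("cpg_report", "bedgraph"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    rows = []
    n_zero = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "cpg_report":
                    if len(fields) != 4:
                        raise ValueError(f"expected 4 columns, got {len(fields)}")
                    chrom, pos, meth, total = fields[0], int(fields[1]) - 1, int(fields[2]), int(fields[3])
                else:
                    if len(fields) == 4:
                        raise ValueError(
                            "4-column fraction bedGraph rejected: methylated/total "
                            "counts are required (expected 5 columns)"
                        )
                    if len(fields) != 5:
                        raise ValueError(f"expected 5 columns, got {len(fields)}")
                    chrom, pos, meth, total = fields[0], int(fields[1]), int(fields[3]), int(fields[4])
                if meth < 0 or total < 0:
                    raise ValueError("negative count")
                if meth > total:
                    raise ValueError(f"meth ({meth}) > total ({total})")
                if pos < 0:
                    raise ValueError("non-positive position")
            except ValueError as exc:
                raise ParseError(f"{path.name}, line {lineno}: {exc}") from None
            if total == 0:
                n_zero += 1
                continue
            rows.append((chrom, pos, meth, total))
    df = pd.DataFrame(rows, columns=CPG_COLUMNS) if rows else pd.DataFrame(columns=CPG_COLUMNS)
    track = CpGTrack(sample_id or path.stem, df, genome=dict(genome) if genome else None)
    track.meta["n_zero_total_dropped"] = n_zero
    return track


def write_cpg_counts(track: CpGTrack, path: str | Path) -> None:
    """Write a track in the ``cpg_report`` dialect (1-based positions)."""
    df = track.data.copy()
    df["pos"] = df["pos"] + 1
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Post-alignment bookkeeping
# ---------------------------------------------------------------------------

def combine_strands(
    plus_records: pd.DataFrame,
    minus_records: pd.DataFrame,
    sample_id: str = "combined",
    genome: Mapping[str, int] | None = None,
) -> CpGTrack:
    """Combine methylation calls from the two strands of each CpG.

    The C on the minus strand of a CpG sits one base 3' of the plus-strand C,
    so a minus-strand call at position ``p`` is paired with the plus-strand
    call at ``p - 1`` and their counts are summed onto the plus-strand
    coordinate.  CpGs observed on only one strand pass through unchanged;
    minus-strand calls with no plus-strand partner are kept at ``p - 1``
    (rather than discarded) and their number recorded in
    ``meta["n_unpaired_minus"]``.
    """
    plus = pd.DataFrame(plus_records, columns=CPG_COLUMNS).copy()
    minus = pd.DataFrame(minus_records, columns=CPG_COLUMNS).copy()
    minus["pos"] = minus["pos"].astype(np.int64) - 1
    if (minus["pos"] < 0).any():
        raise ValidationError("minus-strand CpG call at position 0 cannot be remapped")
    plus_keys = set(zip(plus["chrom"], plus["pos"].astype(np.int64)))
    n_unpaired = int(sum(1 for k in zip(minus["chrom"], minus["pos"]) if k not in plus_keys))
    both = pd.concat([plus, minus], ignore_index=True)
    combined = (
        both.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]].sum()
        if len(both)
        else both
    )
    track = CpGTrack(sample_id, combined[CPG_COLUMNS] if len(both) else both,
                     genome=dict(genome) if genome else None)
    track.meta["n_unpaired_minus"] = n_unpaired
    return track


def deduplicate_reads(reads: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove clonal PCR duplicates: one read kept per (chrom, start, strand).

    The first read encountered in input order is retained.  Returns the
    deduplicated frame and the number of reads removed.
    """
    df = pd.DataFrame(reads).copy()
    for col in ("chrom", "start", "strand"):
        if col not in df.columns:
            raise ValidationError(f"reads missing column {col!r}")
    kept = df.drop_duplicates(subset=["chrom", "start", "strand"], keep="first")
    return kept.reset_index(drop=True), len(df) - len(kept)


def estimate_fold_coverage(
    n_reads: int | None,
    read_length: float | Iterable[float],
    genome_size: float,
) -> float:
    """Fold coverage = (number of reads x read length) / genome size.

    ``read_length`` may be a collection of per-read lengths, in which case
    their sum is used and ``n_reads`` is ignored.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if np.iterable(read_length):
        total_bp = float(np.sum(np.asarray(list(read_length), dtype=float)))
    else:
        total_bp = float(n_reads) * float(read_length)
    return total_bp / float(genome_size)


# ---------------------------------------------------------------------------
# BED interval IO
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name"]


def _validate_intervals(df: pd.DataFrame, allow_overlap: bool, where: str) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 0).any():
        raise ValidationError(f"{where}: negative interval start")
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        row = df.iloc[i]
        raise ValidationError(f"{where}: start >= end at {row['chrom']}:{row['start']}-{row['end']}")
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    if not allow_overlap:
        for _, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"{where}: overlapping intervals")
    return df


def read_bed(path: str | Path, allow_overlap: bool = True) -> pd.DataFrame:
    """Read a 3- or 4-column BED file (0-based half-open) into a DataFrame.

    The optional 4th column carries a label (PMD/HMD state, feature or
    chromatin-state name) and is returned as ``name`` (None when absent).
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path.name}, line {lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}, line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else None
            rows.append((fields[0], start, end, name))
    df = pd.DataFrame(rows, columns=BED_COLUMNS) if rows else pd.DataFrame(columns=BED_COLUMNS)
    return _validate_intervals(df, allow_overlap=allow_overlap, where=path.name)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write intervals as tab-delimited, newline-terminated BED.

    Emits 4 columns when a non-null ``name`` column is present, 3 otherwise.
    Output is bit-stable: sorted, no trailing whitespace, LF line endings.
    """
    df = _validate_intervals(pd.DataFrame(intervals), allow_overlap=True, where=str(path))
    with_name = "name" in df.columns and df["name"].notna().any()
    with open(path, "w", newline="\n") as fh:
        for row in df.itertuples(index=False):
            if with_name:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
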