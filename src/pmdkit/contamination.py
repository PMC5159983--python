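"""Maternal-blood contamination QC from X-chromosome CpG-island methylation.

In female cells, X inactivation methylates CpG-island promoters on the
inactive X, so X CGIs inside highly methylated domains sit near 50%
methylation; in male cells (one active X) the same islands stay low.  A male
placental sample contaminated with maternal blood therefore shows elevated
methylation over these islands in proportion to the fraction of female
cells, which a linear interpolation between a male and a female baseline
converts into a contamination estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CpGTrack, ValidationError
from .segmentation import DomainSet


@dataclass
class ContaminationEstimate:
    sample_id: str
    x_cgi_meth: float       # count-pooled fraction over the selected X CGIs
    female_fraction: float  # estimated proportion of female cells, clipped to [0, 1]
    n_regions: int

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValidationError("estimate requires >=1 region")


def x_cgi_hmd_regions(
    cgi: pd.DataFrame,
    domains: DomainSet,
    x_chrom: str = "chrX",
) -> pd.DataFrame:
    """CpG islands fully contained within an HMD on the X chromosome.

    Containment is subset-or-equal on half-open intervals; islands inside a
    PMD or straddling a domain boundary are excluded.  An empty selection is
    an error — the contamination estimator is undefined without regions.
    """
    cgi = pd.DataFrame(cgi)
    cgi_x = cgi[cgi["chrom"] == x_chrom]
    hmds = domains.restrict(x_chrom).of_state("HMD")
    keep = []
    for row in cgi_x.itertuples(index=False):
        inside = ((hmds["start"] <= row.start) & (row.end <= hmds["end"])).any()
        if inside:
            keep.append((row.chrom, row.start, row.end))
    if not keep:
        raise ValidationError(
            "no CpG islands fully contained in X-chromosome HMDs; "
            "supply CGI annotations and a decoded X domain map"
        )
    return pd.DataFrame(keep, columns=["chrom", "start", "end"])


def estimate_female_fraction(
    track: CpGTrack,
    regions: pd.DataFrame,
    male_baseline: float = 0.10,
    female_baseline: float = 0.50,
) -> ContaminationEstimate:
    """Estimate the fraction of female (maternal blood) cells in a sample.

    ``x_cgi_meth`` is the count-pooled methylation over all CpGs in all
    selected regions; the female fraction interpolates it linearly between
    the male and female baselines and clips to [0, 1].  The baselines encode
    "low in pure male tissue, ~half-methylated in female cells due to X
    inactivation" and must be stated for any downstream interpretation.
    """
    if not female_baseline > male_baseline:
        raise ValueError("female_baseline must exceed male_baseline")
    sub = track.subset(regions)
    total = int(sub["total"].sum())
    if total == 0:
        raise ValidationError(f"sample {track.sample_id!r}: no covered CpGs in any region")
    x_meth = float(sub["meth"].sum()) / total
    f = (x_meth - male_baseline) / (female_baseline - male_baseline)
    return ContaminationEstimate(
        sample_id=track.sample_id,
        x_cgi_meth=x_meth,
        female_fraction=float(np.clip(f, 0.0, 1.0)),
        n_regions=len(regions),
    )


def contamination_correlation(
    estimates: Sequence[ContaminationEstimate],
    pmd_means: Mapping[str, float],
    sexes: Mapping[str, str],
) -> dict:
    """Relate autosomal PMD methylation to X CGI methylation, males only.

    The X-inactivation logic applies only to male samples, so the Pearson
    correlation is computed over males; female samples (expected high
    ``x_cgi_meth`` from their own inactive X) are reported descriptively.
    """
    males = [e for e in estimates if sexes.get(e.sample_id) == "M"]
    females = [e for e in estimates if sexes.get(e.sample_id) == "F"]
    if len(males) < 3:
        raise ValidationError("need >=3 male samples")
    x = np.array([e.x_cgi_meth for e in males])
    y = np.array([pmd_means[e.sample_id] for e in males])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {
        "r": float(r),
        "p": float(p),
        "n_male": len(males),
        "male_x_cgi_meth_mean": float(x.mean()),
        "female_x_cgi_meth_mean": float(np.mean([e.x_cgi_meth for e in females])) if females else None,
        "n_female": len(females),
    }


def estimates_to_tsv(estimates: Sequence[ContaminationEstimate], path) -> None:
    pd.DataFrame(
        [(e.sample_id, e.x_cgi_meth, e.female_fraction, e.n_regions) for e in estimates],
        columns=["sample_id", "x_cgi_meth", "female_fraction", "n_regions"],
    ).to_csv(path, sep="\t", index=False)
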