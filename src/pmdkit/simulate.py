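"""Synthetic methylome cohorts with recorded ground truth.

The generator emulates the data structure of a low-coverage placental WGBS
study: an alternating PMD/HMD genome architecture (partially methylated
domains near 55% methylation, highly methylated domains near 85%, segment
lengths of a few hundred kb), per-CpG counts drawn at x1-2 fold coverage
(Poisson depth, binomial methylated calls), per-sample global methylation
offsets on the logit scale with a shared component plus state-specific
components (so PMD levels vary more between individuals than HMD levels and
the two are positively correlated), an optional planted group-differential
HMD, and maternal-blood admixture that raises autosomal PMD methylation and
female-X CpG-island methylation.

Everything planted is recorded in a :class:`CohortTruth` ledger, and all
randomness flows from explicit seeds, so identical configuration yields
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import CpGTrack, SampleSheet, ValidationError, write_cpg_counts
from .segmentation import DOMAIN_COLUMNS, DomainSet

RACE_ETHNICITY_LEVELS = (
    "white non-Hispanic", "Asian", "multi-racial", "white Hispanic", "non-white Hispanic",
)
CHROMHMM_STATES = ("TssA", "TssPoised", "Tx", "Enh", "ReprPC", "Het", "Quies")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureConfig:
    """Genome architecture of the synthetic methylome.

    Segment lengths are drawn in whole windows from a geometric law whose
    mean matches the configured mean length — the same run-length family the
    two-state HMM implies, keeping training and decoding self-consistent.  A
    lognormal heavy-tailed option exists for robustness experiments.
    Per-CpG locus noise (Gaussian on the logit, sd 0.1 by default) breaks up
    otherwise unrealistically uniform windows and is fixed per architecture,
    shared by all samples.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    cpg_spacing: float = 100.0          # mean bp between CpGs
    pmd_mean_length: int = 300_000
    hmd_mean_length: int = 150_000
    pmd_mean: float = 0.55
    hmd_mean: float = 0.85
    window_width: int = 20_000          # observation unit; segment lengths snap to it
    locus_noise_sd: float = 0.10        # logit-scale, fixed per architecture
    heavy_tail: bool = False
    include_x: bool = True
    x_chrom: str = "chrX"
    x_length: int = 3_000_000
    n_x_cgis: int = 60
    cgi_length: int = 1_000
    cgi_cpg_spacing: float = 20.0       # CpG islands are CpG-dense
    male_x_cgi_mean: float = 0.10       # one active X: CGIs stay low
    female_x_cgi_mean: float = 0.50     # inactive-X CGI methylation
    training_fraction: float = 0.30     # share of true domains "visually annotated"

    def __post_init__(self) -> None:
        if not self.pmd_mean < self.hmd_mean:
            raise ValidationError("PMD mean must be below HMD mean")
        if min(self.pmd_mean_length, self.hmd_mean_length) < self.window_width:
            raise ValidationError("mean segment length must be >= window width")


@dataclass
class CohortConfig:
    """Cohort composition, variance structure and planted effects.

    Per-sample offsets act on the logit scale as a shared component plus
    state-specific components; the defaults are calibrated so that across a
    ~47-sample cohort the genome-wide PMD means spread over roughly 10
    percentage points and the HMD means over roughly 4, with a clearly
    positive PMD-HMD correlation.  ``domain_noise_sd_pp`` is the
    between-sample standard deviation (in percentage points) of a single
    domain's methylation around the sample's global level, and is the scale
    on which differential tests operate.  The planted DMR shifts one HMD in
    the ASD group by ``dmr_delta_pp`` percentage points; set it to 0 (or
    ``dmr_hmd_index=None``) for a null cohort.
    """

    n_asd: int = 24
    n_td: int = 23
    n_odc: int = 0
    coverage: float = 1.5               # fold coverage per sample
    shared_offset_sd: float = 0.075     # logit sd of the component common to both states
    pmd_offset_sd: float = 0.07         # logit sd of the PMD-specific component
    hmd_offset_sd: float = 0.04         # logit sd of the HMD-specific component
    domain_noise_sd_pp: float = 2.5     # per-sample, per-domain sd in percentage points
    dmr_hmd_index: int | None = -1      # -1: middle autosomal HMD; None: no DMR
    dmr_delta_pp: float = 5.0
    contamination: float | Sequence[float] | None = None
    male_fraction: float = 0.8          # placental studies skew male
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_asd, self.n_td, self.n_odc) < 0:
            raise ValidationError("group sizes must be non-negative")


@dataclass
class SampleParams:
    """Everything that distinguishes one simulated sample."""

    sample_id: str
    sex: str = "M"
    coverage: float = 1.5
    pmd_offset: float = 0.0             # logit scale
    hmd_offset: float = 0.0
    domain_noise_sd_pp: float = 0.0
    dmr: tuple | None = None            # (chrom, start, end, delta_logit)
    contamination: float = 0.0
    seed: int = 0


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

@dataclass
class Architecture:
    """Realised synthetic genome: domains, CpG positions and baselines."""

    config: ArchitectureConfig
    genome: dict
    domains: DomainSet
    cpg_pos: dict            # chrom -> int array
    cpg_state: dict          # chrom -> 0 (PMD) / 1 (HMD)
    cpg_domain: dict         # chrom -> global domain row index
    cpg_is_xcgi: dict        # chrom -> bool array
    locus_noise: dict        # chrom -> float array (logit scale)
    cgis: pd.DataFrame
    promoters: pd.DataFrame
    gene_bodies: pd.DataFrame
    chromhmm: pd.DataFrame
    training: pd.DataFrame

    @property
    def autosomes(self) -> list:
        return [c for c in self.genome if c != self.config.x_chrom]

    def n_cpgs(self) -> int:
        return int(sum(len(p) for p in self.cpg_pos.values()))

    def baseline_logit(self, chrom: str, sex: str = "M") -> np.ndarray:
        """Per-CpG baseline success probability on the logit scale.

        X CGIs take the male baseline (one active X) unless ``sex="F"``, in
        which case the sample's own inactive X puts them at the female level.
        """
        cfg = self.config
        state_logit = np.where(
            self.cpg_state[chrom] == 1, logit(cfg.hmd_mean), logit(cfg.pmd_mean)
        )
        xc = self.cpg_is_xcgi[chrom]
        base = cfg.female_x_cgi_mean if sex == "F" else cfg.male_x_cgi_mean
        state_logit = np.where(xc, logit(base), state_logit)
        return state_logit + self.locus_noise[chrom]

    def blood_probability(self, chrom: str) -> np.ndarray:
        """Methylation profile of contaminating maternal blood: no PMDs
        (uniformly high autosomal methylation) and female X CGIs at the
        inactive-X level."""
        p = np.full(len(self.cpg_pos[chrom]), 0.85)
        p[self.cpg_is_xcgi[chrom]] = self.config.female_x_cgi_mean
        return p


def _segment_chromosome(rng: np.random.Generator, cfg: ArchitectureConfig, length: int):
    """Alternating PMD/HMD segments in whole windows covering [0, length)."""
    w = cfg.window_width
    n_windows = -(-length // w)
    means_w = {0: cfg.pmd_mean_length / w, 1: cfg.hmd_mean_length / w}
    state = int(rng.integers(2))
    segs, filled = [], 0
    while filled < n_windows:
        if cfg.heavy_tail:
            # lognormal with matching mean, sigma=1
            mu = np.log(means_w[state]) - 0.5
            n = max(1, int(round(rng.lognormal(mu, 1.0))))
        else:
            n = int(rng.geometric(1.0 / means_w[state]))
        n = min(n, n_windows - filled)
        segs.append((filled * w, min((filled + n) * w, length), state, n))
        filled += n
        state = 1 - state
    return segs


def generate_architecture(cfg: ArchitectureConfig) -> Architecture:
    """Build the synthetic genome: domains, CpG positions, annotations.

    Deterministic in ``cfg`` (including its seed): the same configuration
    yields byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chromosomes)}
    if cfg.include_x:
        genome[cfg.x_chrom] = cfg.x_length

    dom_rows = []
    for chrom, length in genome.items():
        for s, e, st, nw in _segment_chromosome(rng, cfg, length):
            dom_rows.append((chrom, s, e, "HMD" if st else "PMD", nw))
    dom_df = pd.DataFrame(dom_rows, columns=DOMAIN_COLUMNS)
    domains = DomainSet(dom_df)
    dom_df = domains.data  # sorted/validated

    # CGIs: fully inside X HMDs
    cgi_rows = []
    if cfg.include_x:
        x_hmds = dom_df[(dom_df["chrom"] == cfg.x_chrom) & (dom_df["state"] == "HMD")]
        eligible = x_hmds[(x_hmds["end"] - x_hmds["start"]) > 2 * cfg.cgi_length]
        if len(eligible) == 0:
            raise ValidationError("no X HMD long enough to host a CpG island")
        picks = rng.integers(0, len(eligible), size=cfg.n_x_cgis)
        for k in np.sort(picks):
            d = eligible.iloc[int(k)]
            lo = int(d["start"])
            hi = int(d["end"]) - cfg.cgi_length
            start = int(rng.integers(lo, hi))
            cgi_rows.append((cfg.x_chrom, start, start + cfg.cgi_length))
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]).drop_duplicates()
    cgis = cgis.sort_values(["chrom", "start"]).reset_index(drop=True)

    cpg_pos, cpg_state, cpg_domain, cpg_is_xcgi, locus_noise = {}, {}, {}, {}, {}
    for chrom, length in genome.items():
        n_expect = int(length / cfg.cpg_spacing * 1.3) + 10
        gaps = rng.exponential(cfg.cpg_spacing, size=n_expect)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos < length]
        if chrom == cfg.x_chrom and len(cgis):
            dense = []
            for row in cgis.itertuples(index=False):
                g = rng.exponential(cfg.cgi_cpg_spacing, size=int(cfg.cgi_length / cfg.cgi_cpg_spacing * 1.5))
                p = row.start + np.cumsum(g).astype(np.int64)
                dense.append(p[p < row.end])
            pos = np.concatenate([pos] + dense)
        pos = np.unique(pos)
        cpg_pos[chrom] = pos

        dsub = dom_df[dom_df["chrom"] == chrom]
        starts = dsub["start"].to_numpy()
        gidx = dsub.index.to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        cpg_domain[chrom] = gidx[j]
        cpg_state[chrom] = (dsub["state"].to_numpy()[j] == "HMD").astype(np.int8)

        is_cgi = np.zeros(len(pos), dtype=bool)
        if chrom == cfg.x_chrom:
            for row in cgis.itertuples(index=False):
                lo, hi = np.searchsorted(pos, [row.start, row.end])
                is_cgi[lo:hi] = True
        cpg_is_xcgi[chrom] = is_cgi
        locus_noise[chrom] = rng.normal(0.0, cfg.locus_noise_sd, size=len(pos))

    # feature annotations on the autosomes
    promoters, gene_bodies, chromhmm = [], [], []
    for chrom in (c for c in genome if c != cfg.x_chrom):
        length = genome[chrom]
        for k, start in enumerate(range(50_000, length - 30_000, 250_000)):
            promoters.append((chrom, start, start + 2_000, f"{chrom}_prom_{k}"))
            gene_bodies.append((chrom, start + 2_000, start + 22_000, f"{chrom}_gene_{k}"))
        n_elem = max(10, length // 100_000)
        starts = np.sort(rng.integers(0, length - 5_000, size=n_elem))
        for k, s in enumerate(starts):
            e = int(s + rng.integers(500, 5_000))
            chromhmm.append((chrom, int(s), min(e, length), str(rng.choice(CHROMHMM_STATES))))
    promoters = pd.DataFrame(promoters, columns=["chrom", "start", "end", "name"])
    gene_bodies = pd.DataFrame(gene_bodies, columns=["chrom", "start", "end", "name"])
    chromhmm = pd.DataFrame(chromhmm, columns=["chrom", "start", "end", "name"])

    # "visual annotation": a random subset of true autosomal domains, at
    # least two of each state, mimicking partial manual curation
    auto = dom_df[dom_df["chrom"] != cfg.x_chrom]
    training_parts = []
    for state in ("PMD", "HMD"):
        ds = auto[auto["state"] == state]
        n_pick = max(2, int(round(cfg.training_fraction * len(ds))))
        take = rng.choice(len(ds), size=min(n_pick, len(ds)), replace=False)
        training_parts.append(ds.iloc[np.sort(take)])
    training = pd.concat(training_parts, ignore_index=True)[["chrom", "start", "end", "state"]]

    return Architecture(
        config=cfg, genome=genome, domains=domains,
        cpg_pos=cpg_pos, cpg_state=cpg_state, cpg_domain=cpg_domain,
        cpg_is_xcgi=cpg_is_xcgi, locus_noise=locus_noise,
        cgis=cgis, promoters=promoters, gene_bodies=gene_bodies,
        chromhmm=chromhmm, training=training,
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _fraction_to_logit_delta(delta_pp: float, at_mean: float) -> float:
    """Convert a shift in percentage points near ``at_mean`` to logit scale
    via the local derivative d logit / d p = 1 / (p (1 - p))."""
    return (delta_pp / 100.0) / (at_mean * (1.0 - at_mean))


def sample_success_probabilities(arch: Architecture, params: SampleParams) -> dict:
    """Per-CpG methylation success probabilities for one sample.

    Applies, on the logit scale: the architecture baseline (with fixed locus
    noise), the sample's state-specific global offsets, per-domain noise,
    and the planted DMR shift; X CGI CpGs are governed by X-inactivation
    state alone and take none of these.  Maternal-blood admixture then mixes
    linearly on the probability scale.
    """
    cfg = arch.config
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    dom_df = arch.domains.data
    n_dom = len(dom_df)
    if params.domain_noise_sd_pp > 0:
        state_mean = np.where(dom_df["state"].to_numpy() == "HMD", cfg.hmd_mean, cfg.pmd_mean)
        dom_eps = rng.normal(0.0, 1.0, size=n_dom) * np.array(
            [_fraction_to_logit_delta(params.domain_noise_sd_pp, m) for m in state_mean]
        )
    else:
        dom_eps = np.zeros(n_dom)
    out = {}
    for chrom in arch.genome:
        lp = arch.baseline_logit(chrom, sex=params.sex).copy()
        xc = arch.cpg_is_xcgi[chrom]
        st = arch.cpg_state[chrom]
        lp[(st == 0) & ~xc] += params.pmd_offset
        lp[(st == 1) & ~xc] += params.hmd_offset
        lp[~xc] += dom_eps[arch.cpg_domain[chrom]][~xc]
        if params.dmr is not None and params.dmr[0] == chrom:
            _, s, e, dlt = params.dmr
            pos = arch.cpg_pos[chrom]
            lp[(pos >= s) & (pos < e) & ~xc] += dlt
        p = expit(lp)
        if params.contamination > 0:
            f = params.contamination
            p = (1.0 - f) * p + f * arch.blood_probability(chrom)
        out[chrom] = p
    return out


def simulate_sample(arch: Architecture, params: SampleParams) -> CpGTrack:
    """Draw one sample's CpG count track.

    Per CpG, depth is Poisson with mean equal to the fold coverage and the
    methylated count is binomial at the sample's success probability;
    zero-depth CpGs are omitted, so coverage 0 yields an empty track.
    """
    if params.coverage < 0:
        raise ValueError("coverage must be non-negative")
    probs = sample_success_probabilities(arch, params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    frames = []
    for chrom in arch.genome:
        pos = arch.cpg_pos[chrom]
        depth = rng.poisson(params.coverage, size=len(pos))
        meth = rng.binomial(depth, probs[chrom])
        keep = depth > 0
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos[keep], "meth": meth[keep], "total": depth[keep],
        }))
    data = pd.concat(frames, ignore_index=True)
    return CpGTrack(params.sample_id, data, genome=dict(arch.genome))


def simulate_contamination(
    track: CpGTrack,
    f: float,
    placenta_p: np.ndarray,
    blood_p: np.ndarray | float,
    seed: int = 0,
) -> CpGTrack:
    """Re-draw a track's methylated counts under maternal-blood admixture.

    Each CpG keeps its observed depth; the methylated count is re-drawn as
    binomial with success probability ``(1 - f) * placenta + f * blood``.
    With ``f = 0`` and a fixed seed the output is identical to re-drawing
    from the pure placental probabilities.  ``placenta_p`` and ``blood_p``
    align with the rows of ``track.data``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("contamination fraction must be in [0, 1]")
    placenta_p = np.asarray(placenta_p, dtype=float)
    blood = np.broadcast_to(np.asarray(blood_p, dtype=float), placenta_p.shape)
    p_mix = (1.0 - f) * placenta_p + f * blood
    rng = np.random.default_rng(seed)
    df = track.data.copy()
    df["meth"] = rng.binomial(df["total"].to_numpy(), p_mix)
    out = CpGTrack(track.sample_id, df, genome=track.genome)
    out.meta["contamination_f"] = f
    return out


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Ground-truth ledger of everything the generator planted."""

    domains: DomainSet
    training: pd.DataFrame
    offsets: dict            # sample_id -> {"pmd": logit, "hmd": logit}
    dmr: dict | None         # chrom/start/end/delta_pp/hmd_row
    contamination: dict      # sample_id -> fraction
    sexes: dict              # sample_id -> M/F
    seeds: dict              # sample_id -> int
    arch_config: ArchitectureConfig
    cohort_config: CohortConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "domains": self.domains.data.to_dict(orient="list"),
            "training": self.training.to_dict(orient="list"),
            "offsets": self.offsets,
            "dmr": self.dmr,
            "contamination": self.contamination,
            "sexes": self.sexes,
            "seeds": self.seeds,
            "arch_config": asdict(self.arch_config),
            "cohort_config": asdict(self.cohort_config),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            domains=DomainSet(pd.DataFrame(d["domains"])),
            training=pd.DataFrame(d["training"]),
            offsets=d["offsets"],
            dmr=d["dmr"],
            contamination=d["contamination"],
            sexes=d["sexes"],
            seeds=d["seeds"],
            arch_config=ArchitectureConfig(**d["arch_config"]),
            cohort_config=CohortConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                          for k, v in d["cohort_config"].items()}),
        )


@dataclass
class Cohort:
    """A generated study bundle: tracks, metadata, annotations and truth."""

    architecture: Architecture
    tracks: list
    sample_sheet: SampleSheet
    truth: CohortTruth

    def groups(self) -> dict:
        return dict(zip(self.sample_sheet.data["sample_id"], self.sample_sheet.data["diagnosis"]))

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle in the formats the IO layer reads back."""
        from .io import write_bed

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for track in self.tracks:
            write_cpg_counts(track, out / f"{track.sample_id}.cpg_report.tsv")
        self.sample_sheet.write(out / "samples.csv")
        arch = self.architecture
        self.truth.domains.to_bed(out / "true_domains.bed")
        write_bed(self.truth.training.rename(columns={"state": "name"}), out / "training.bed")
        if len(arch.cgis):
            write_bed(arch.cgis.assign(name="CGI"), out / "cgi.bed")
        write_bed(arch.promoters, out / "promoters.bed")
        write_bed(arch.gene_bodies, out / "gene_bodies.bed")
        write_bed(arch.chromhmm, out / "chromhmm.bed")
        with open(out / "genome.tsv", "w", newline="\n") as fh:
            for chrom, length in arch.genome.items():
                fh.write(f"{chrom}\t{length}\n")
        self.truth.to_json(out / "truth.json")


def generate_cohort(
    arch_cfg: ArchitectureConfig | None = None,
    cohort_cfg: CohortConfig | None = None,
) -> Cohort:
    """Generate a full synthetic study: tracks, sample sheet and truth ledger.

    Group sizes default to the study shape (24 ASD vs 23 TD).  The planted
    DMR is applied as a group-mean shift of ``dmr_delta_pp`` percentage
    points to the ASD samples within one designated autosomal HMD.
    """
    arch_cfg = arch_cfg or ArchitectureConfig()
    cohort_cfg = cohort_cfg or CohortConfig()
    arch = generate_architecture(arch_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cohort_cfg.seed, 7]))

    labels = (["ASD"] * cohort_cfg.n_asd + ["TD"] * cohort_cfg.n_td + ["ODC"] * cohort_cfg.n_odc)
    n = len(labels)
    sample_ids = [f"{dx}_{i + 1:02d}" for i, dx in enumerate(labels)]

    # planted DMR: one designated autosomal HMD
    dmr = None
    dmr_tuple_by_group = {dx: None for dx in ("ASD", "TD", "ODC")}
    if cohort_cfg.dmr_hmd_index is not None and cohort_cfg.dmr_delta_pp != 0:
        auto_hmd = arch.domains.data[
            (arch.domains.data["state"] == "HMD")
            & (arch.domains.data["chrom"] != arch_cfg.x_chrom)
        ]
        if len(auto_hmd) == 0:
            raise ValidationError("no autosomal HMD available for the planted DMR")
        idx = cohort_cfg.dmr_hmd_index
        if idx == -1:
            idx = len(auto_hmd) // 2
        if not 0 <= idx < len(auto_hmd):
            raise ValidationError(f"dmr_hmd_index {idx} out of range (0..{len(auto_hmd) - 1})")
        row = auto_hmd.iloc[idx]
        delta_logit = _fraction_to_logit_delta(cohort_cfg.dmr_delta_pp, arch_cfg.hmd_mean)
        dmr = {
            "chrom": str(row["chrom"]), "start": int(row["start"]), "end": int(row["end"]),
            "delta_pp": float(cohort_cfg.dmr_delta_pp), "hmd_row": int(row.name),
        }
        dmr_tuple_by_group["ASD"] = (dmr["chrom"], dmr["start"], dmr["end"], delta_logit)

    if cohort_cfg.contamination is None:
        contam = np.zeros(n)
    elif np.isscalar(cohort_cfg.contamination):
        contam = np.full(n, float(cohort_cfg.contamination))
    else:
        contam = np.asarray(cohort_cfg.contamination, dtype=float)
        if contam.shape != (n,):
            raise ValidationError("contamination must be scalar or one fraction per sample")

    sexes = np.where(rng.random(n) < cohort_cfg.male_fraction, "M", "F")
    shared = rng.normal(0.0, cohort_cfg.shared_offset_sd, size=n)
    pmd_off = shared + rng.normal(0.0, cohort_cfg.pmd_offset_sd, size=n)
    hmd_off = shared + rng.normal(0.0, cohort_cfg.hmd_offset_sd, size=n)
    seeds = rng.integers(0, 2**31 - 1, size=n)

    tracks, sheet_rows, offsets = [], [], {}
    for i, (sid, dx) in enumerate(zip(sample_ids, labels)):
        params = SampleParams(
            sample_id=sid, sex=str(sexes[i]), coverage=cohort_cfg.coverage,
            pmd_offset=float(pmd_off[i]), hmd_offset=float(hmd_off[i]),
            domain_noise_sd_pp=cohort_cfg.domain_noise_sd_pp,
            dmr=dmr_tuple_by_group[dx], contamination=float(contam[i]),
            seed=int(seeds[i]),
        )
        tracks.append(simulate_sample(arch, params))
        offsets[sid] = {"pmd": float(pmd_off[i]), "hmd": float(hmd_off[i])}
        sheet_rows.append({
            "sample_id": sid, "diagnosis": dx, "sex": str(sexes[i]),
            "run": f"run{1 + i % 3}", "order": i + 1,
            "coverage": cohort_cfg.coverage,
            "race_ethnicity": RACE_ETHNICITY_LEVELS[i % len(RACE_ETHNICITY_LEVELS)],
        })
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = CohortTruth(
        domains=arch.domains, training=arch.training, offsets=offsets,
        dmr=dmr, contamination={s: float(f) for s, f in zip(sample_ids, contam)},
        sexes={s: str(x) for s, x in zip(sample_ids, sexes)},
        seeds={s: int(v) for s, v in zip(sample_ids, seeds)},
        arch_config=arch_cfg, cohort_config=cohort_cfg,
    )
    return Cohort(arch, tracks, sheet, truth)


# ---------------------------------------------------------------------------
# Feature-level generator for statistical experiments
# ---------------------------------------------------------------------------

def simulate_feature_matrix(
    n_features: int,
    n_a: int = 24,
    n_b: int = 23,
    delta_pp: float = 0.0,
    within_sd_pp: float = 2.5,
    baseline: float = 0.85,
    dmr_index: int | None = None,
    seed: int = 0,
):
    """Domain-scale methylation matrix for FDR and power experiments.

    Generates per-feature per-sample methylation values directly at the
    domain summary scale — baseline plus Gaussian between-sample noise of
    ``within_sd_pp`` percentage points — bypassing the count layer, which is
    the appropriate scale for replicated multiple-testing experiments.  When
    ``dmr_index`` is given, that feature is shifted by ``delta_pp`` in group
    A.  Returns ``(values, groups, dmr_index)`` with ``values`` features x
    samples and ``groups`` a sample -> label mapping.
    """
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    vals = baseline + rng.normal(0.0, within_sd_pp / 100.0, size=(n_features, n))
    samples = [f"A_{i:02d}" for i in range(n_a)] + [f"B_{i:02d}" for i in range(n_b)]
    groups = {s: ("ASD" if s.startswith("A_") else "TD") for s in samples}
    if dmr_index is not None and delta_pp != 0:
        if not 0 <= dmr_index < n_features:
            raise ValidationError("dmr_index out of range")
        vals[dmr_index, :n_a] += delta_pp / 100.0
    df = pd.DataFrame(vals, columns=samples)
    df.index.name = "feature"
    return df, groups, dmr_index
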