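"""End-to-end validation experiments on synthetic cohorts.

Each function generates data with the synthetic module, runs the relevant
pipeline stage, and measures recovery of the planted truth: exact Viterbi
agreement with exhaustive path enumeration, domain-boundary recovery,
contamination-fraction recovery, false-discovery control on null cohorts,
planted-DMR detection power, and the qualitative structure of the
window-methylation landscape (bimodality, PMD/HMD spread, PMD-HMD
correlation).  The same entry points back the test suite and the
reproduction script.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import feature_scan
from .segmentation import (
    DomainSet, HmmModel, STATES, sample_domain_methylation, train_supervised,
    viterbi_segment, _viterbi_path,
)
from .simulate import (
    ArchitectureConfig, CohortConfig, SampleParams, generate_architecture,
    generate_cohort, simulate_feature_matrix, simulate_sample,
)
from .windows import (
    WindowTrack, binned_distribution, fraction_windows_below, pool_samples,
    tile_windows, window_methylation,
)


# ---------------------------------------------------------------------------
# Viterbi vs exhaustive enumeration
# ---------------------------------------------------------------------------

def brute_force_path(model: HmmModel, frac: np.ndarray) -> np.ndarray:
    """Most probable state path by enumerating all 2^n paths.

    Independent of the dynamic-programming decoder: scores every path
    directly from the model's log densities.  NaN observations contribute no
    emission term, matching the decoder's missing-data convention.
    """
    n = len(frac)
    obs = ~np.isnan(frac)
    log_trans = np.log(model.transitions)
    log_init = np.log(model.initial)
    emit = np.zeros((n, 2))
    if obs.any():
        emit[obs] = stats.norm.logpdf(
            frac[obs][:, None], loc=model.means[None, :], scale=model.sds[None, :]
        )
    best_score, best_path = -np.inf, None
    for path in itertools.product((0, 1), repeat=n):
        score = log_init[path[0]] + emit[0, path[0]]
        for t in range(1, n):
            score += log_trans[path[t - 1], path[t]] + emit[t, path[t]]
        if score > best_score:
            best_score, best_path = score, path
    return np.array(best_path, dtype=np.int8)


def random_hmm_instance(rng: np.random.Generator, max_windows: int = 12):
    """A random two-state model plus a window-fraction sequence, with some
    observations knocked out to exercise transition-only bridging."""
    n = int(rng.integers(2, max_windows + 1))
    mu_p = rng.uniform(0.3, 0.6)
    mu_h = mu_p + rng.uniform(0.1, 0.35)
    sds = rng.uniform(0.02, 0.15, size=2)
    a, b = rng.uniform(0.6, 0.98, size=2)
    trans = np.array([[a, 1 - a], [1 - b, b]])
    denom = (1 - a) + (1 - b)
    init = np.array([(1 - b) / denom, (1 - a) / denom])
    model = HmmModel([mu_p, mu_h], sds, trans, init)
    frac = rng.uniform(0.2, 1.0, size=n)
    miss = rng.random(n) < 0.15
    if miss.all():
        miss[int(rng.integers(n))] = False
    frac[miss] = np.nan
    return model, frac


def viterbi_agreement(n_instances: int = 100, max_windows: int = 12, seed: int = 0) -> float:
    """Fraction of random instances where the decoder equals enumeration."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        model, frac = random_hmm_instance(rng, max_windows)
        if np.array_equal(_viterbi_path(frac, model), brute_force_path(model, frac)):
            agree += 1
    return agree / n_instances


# ---------------------------------------------------------------------------
# Segmentation recovery on a synthetic genome
# ---------------------------------------------------------------------------

def _true_window_states(domains: DomainSet, wt: WindowTrack) -> np.ndarray:
    dom = domains.data
    out = np.full(len(wt.data), -1, dtype=np.int8)
    for chrom, grp in wt.data.groupby("chrom", sort=False):
        d = dom[dom["chrom"] == chrom]
        starts = d["start"].to_numpy()
        states = (d["state"].to_numpy() == "HMD").astype(np.int8)
        mid = ((grp["start"] + grp["end"]) // 2).to_numpy()
        j = np.searchsorted(starts, mid, side="right") - 1
        out[grp.index.to_numpy()] = states[j]
    return out


def _boundary_displacements(true_domains: DomainSet, decoded: DomainSet, width: int):
    """Per true internal boundary, distance (in windows) to nearest decoded
    boundary on the same chromosome."""
    disp = []
    for chrom in true_domains.data["chrom"].unique():
        tb = true_domains.data[true_domains.data["chrom"] == chrom]["start"].to_numpy()[1:]
        db = decoded.data[decoded.data["chrom"] == chrom]["start"].to_numpy()[1:]
        if len(tb) == 0:
            continue
        if len(db) == 0:
            disp.extend([np.inf] * len(tb))
            continue
        for b in tb:
            disp.append(np.min(np.abs(db - b)) / width)
    return np.array(disp)


def segmentation_recovery(
    seed: int = 0,
    chrom_length: int = 10_000_000,
    n_samples: int = 17,
    coverage: float = 1.5,
    width: int = 20_000,
) -> dict:
    """Pool a synthetic cohort, train on its partial annotations, decode,
    and score the decode against the planted domain map.

    Emulates the production setting: 17 low-coverage samples pooled into a
    ~x25 consensus before training and decoding.
    """
    arch_cfg = ArchitectureConfig(
        seed=seed, n_chromosomes=1, chrom_length=chrom_length,
        window_width=width, include_x=False,
    )
    arch = generate_architecture(arch_cfg)
    rng = np.random.default_rng(seed + 1)
    tracks = [
        simulate_sample(arch, SampleParams(
            sample_id=f"s{i}", coverage=coverage, seed=int(rng.integers(2**31)),
            pmd_offset=float(rng.normal(0, 0.1)), hmd_offset=float(rng.normal(0, 0.08)),
            domain_noise_sd_pp=2.5,
        ))
        for i in range(n_samples)
    ]
    pooled = pool_samples(tracks)
    wt = window_methylation(pooled, tile_windows(arch.genome, width), min_support=10)
    model = train_supervised(wt, arch.training)
    decoded = viterbi_segment(model, wt)
    truth = arch.domains
    true_states = _true_window_states(truth, wt)
    dec_states = _true_window_states(decoded, wt)
    acc = float(np.mean(true_states == dec_states))
    disp = _boundary_displacements(truth, decoded, width)
    return {
        "window_accuracy": acc,
        "median_boundary_displacement_windows": float(np.median(disp)) if len(disp) else 0.0,
        "n_windows": int(len(wt)),
        "n_true_boundaries": int(len(disp)),
        "model": model,
        "decoded": decoded,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Contamination recovery
# ---------------------------------------------------------------------------

def contamination_recovery(
    fractions=(0.0, 0.05, 0.10, 0.20),
    n_replicates: int = 20,
    coverage: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant maternal-blood fractions in male samples and re-estimate them
    from X CGI methylation with baselines matched to the generator."""
    from .contamination import estimate_female_fraction, x_cgi_hmd_regions

    arch_cfg = ArchitectureConfig(
        seed=seed, n_chromosomes=1, chrom_length=500_000,
        x_length=3_000_000, n_x_cgis=60,
    )
    arch = generate_architecture(arch_cfg)
    regions = x_cgi_hmd_regions(arch.cgis, arch.domains, x_chrom=arch_cfg.x_chrom)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for f in fractions:
        for rep in range(n_replicates):
            track = simulate_sample(arch, SampleParams(
                sample_id=f"m_{f}_{rep}", sex="M", coverage=coverage,
                contamination=float(f), seed=int(rng.integers(2**31)),
            ))
            est = estimate_female_fraction(
                track, regions,
                male_baseline=arch_cfg.male_x_cgi_mean,
                female_baseline=arch_cfg.female_x_cgi_mean,
            )
            rows.append({"true_f": f, "replicate": rep, "estimate": est.female_fraction})
    df = pd.DataFrame(rows)
    out = df.groupby("true_f", as_index=False)["estimate"].mean()
    out["abs_error"] = (out["estimate"] - out["true_f"]).abs()
    out["n_regions"] = len(regions)
    return out


# ---------------------------------------------------------------------------
# Multiple-testing calibration and power
# ---------------------------------------------------------------------------

def empirical_fdr(
    n_replicates: int = 200,
    n_features: int = 500,
    n_asd: int = 24,
    n_td: int = 23,
    seed: int = 0,
) -> dict:
    """Observed false-discovery proportion on all-null cohorts.

    Every feature is null, so the false-discovery proportion of a replicate
    is 1 when anything is rejected and 0 otherwise; the mean over replicates
    estimates the FDR the procedure actually delivers.
    """
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_replicates):
        values, groups, _ = simulate_feature_matrix(
            n_features, n_a=n_asd, n_b=n_td, delta_pp=0.0,
            seed=int(rng.integers(2**31)),
        )
        res = feature_scan(values, groups, "HMD")
        n_rej = int(res.data["rejected"].sum())
        fdps.append(1.0 if n_rej > 0 else 0.0)
    fdps = np.array(fdps)
    return {
        "empirical_fdr": float(fdps.mean()),
        "mc_se": float(fdps.std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
    }


def dmr_detection_rate(
    n_replicates: int = 100,
    n_features: int = 500,
    delta_pp: float = 5.0,
    within_sd_pp: float = 2.5,
    n_asd: int = 24,
    n_td: int = 23,
    seed: int = 0,
) -> float:
    """Share of replicates in which the planted HMD ranks first by q."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        dmr_index = int(rng.integers(n_features))
        values, groups, _ = simulate_feature_matrix(
            n_features, n_a=n_asd, n_b=n_td, delta_pp=delta_pp,
            within_sd_pp=within_sd_pp, dmr_index=dmr_index,
            seed=int(rng.integers(2**31)),
        )
        res = feature_scan(values, groups, "HMD")
        top = res.top(1)["feature_id"].iloc[0]
        if int(top) == dmr_index:
            hits += 1
    return hits / n_replicates


# ---------------------------------------------------------------------------
# Qualitative landscape structure on a default cohort
# ---------------------------------------------------------------------------

def cohort_landscape(seed: int = 0, width: int = 20_000) -> dict:
    """Generate a default-condition cohort and measure the landscape facts:
    bimodal window-methylation distribution, larger spread in the partially
    methylated mode, positive per-sample PMD-HMD correlation, and the share
    of windows below 60% methylation."""
    arch_cfg = ArchitectureConfig(seed=seed)
    cohort_cfg = CohortConfig(seed=seed + 1)
    cohort = generate_cohort(arch_cfg, cohort_cfg)
    arch = cohort.architecture
    autosomes = {c: L for c, L in arch.genome.items() if c != arch_cfg.x_chrom}
    wins = tile_windows(autosomes, width)
    wts = [window_methylation(t, wins, min_support=10) for t in cohort.tracks]
    summary = binned_distribution(wts)
    mean_mass = summary.data["mean"].to_numpy()
    sd_mass = summary.data["sd"].to_numpy()
    centers = (summary.data["bin_left"].to_numpy() + summary.data["bin_right"].to_numpy()) / 2
    low = centers < 0.70
    peak_low = int(np.argmax(np.where(low, mean_mass, -1)))
    peak_high = int(np.argmax(np.where(~low, mean_mass, -1)))
    valley = float(mean_mass[peak_low:peak_high + 1].min())
    # decode domains from the pooled consensus and summarise per sample
    pooled = pool_samples(cohort.tracks)
    pooled_auto = type(pooled)(
        "pooled_auto", pooled.data[pooled.data["chrom"] != arch_cfg.x_chrom], genome=autosomes
    )
    wt_pooled = window_methylation(pooled_auto, wins, min_support=10)
    model = train_supervised(wt_pooled, arch.training)
    decoded = viterbi_segment(model, wt_pooled)
    table = sample_domain_methylation(cohort.tracks, decoded)
    gm = table.global_means().dropna()
    r = float(stats.pearsonr(gm["pmd_mean"], gm["hmd_mean"])[0])
    pooled_wt = wt_pooled
    return {
        "bimodal": bool(mean_mass[peak_low] > valley and mean_mass[peak_high] > valley),
        "peak_low_methylation": float(centers[peak_low]),
        "peak_high_methylation": float(centers[peak_high]),
        "valley_mass": valley,
        "sd_low_mode": float(sd_mass[peak_low]),
        "sd_high_mode": float(sd_mass[peak_high]),
        "pmd_range_pct": float((gm["pmd_mean"].max() - gm["pmd_mean"].min()) * 100),
        "hmd_range_pct": float((gm["hmd_mean"].max() - gm["hmd_mean"].min()) * 100),
        "pmd_hmd_r": r,
        "pct_windows_below_60": float(fraction_windows_below(pooled_wt, 0.60) * 100),
        "n_samples": len(cohort.tracks),
        "cohort": cohort,
        "global_means": gm,
    }
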