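import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmdkit.io import CpGTrack, ValidationError
from pmdkit.segmentation import (
    DomainSegmentation, DomainSet, HmmModel, STATES, pmd_hmd_correlation,
    postprocess_domains, sample_domain_methylation, train_supervised,
    viterbi_segment, _viterbi_path,
)
from pmdkit.validation import brute_force_path, random_hmm_instance
from pmdkit.windows import WindowTrack, pool_samples, tile_windows, window_methylation

from conftest import random_track_frame


def make_wt(fractions, chrom="chr1", width=10_000):
    n = len(fractions)
    df = pd.DataFrame({
        "chrom": chrom, "start": np.arange(n) * width, "end": np.arange(1, n + 1) * width,
        "partial": False, "meth_sum": 0, "total_sum": 100, "n_cpgs": 10,
        "fraction": np.asarray(fractions, dtype=float),
    })
    return WindowTrack(df, width=width, min_support=1)


def simple_model(mu=(0.5, 0.8), sd=(0.02, 0.02), stay=(0.9, 0.9)):
    trans = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
    denom = (1 - trans[0, 0]) + (1 - trans[1, 1])
    init = np.array([(1 - trans[1, 1]) / denom, (1 - trans[0, 0]) / denom])
    return HmmModel(mu, sd, trans, init)


class TestHmmModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            HmmModel([0.8, 0.5], [0.01, 0.01], np.eye(2), [0.5, 0.5])
        with pytest.raises(ValidationError):
            HmmModel([0.5, 0.8], [0.0, 0.01], np.eye(2), [0.5, 0.5])
        with pytest.raises(ValidationError):
            HmmModel([0.5, 0.8], [0.01, 0.01], np.array([[0.9, 0.2], [0.1, 0.9]]), [0.5, 0.5])

    def test_text_round_trip(self, tmp_path):
        m = simple_model(stay=(0.95, 0.87))
        m.to_text(tmp_path / "m.tsv")
        back = HmmModel.from_text(tmp_path / "m.tsv")
        assert np.array_equal(back.means, m.means)
        assert np.array_equal(back.transitions, m.transitions)
        assert np.array_equal(back.initial, m.initial)


class TestTrainSupervised:
    def _training(self, spans):
        return pd.DataFrame(spans, columns=["chrom", "start", "end", "state"])

    def test_constant_training_hits_sd_floor(self):
        wt = make_wt([0.5] * 10 + [0.8] * 10)
        tr = self._training([("chr1", 0, 100_000, "PMD"), ("chr1", 100_000, 200_000, "HMD")])
        m = train_supervised(wt, tr)
        assert m.means[0] == pytest.approx(0.5) and m.means[1] == pytest.approx(0.8)
        assert (m.sds == 0.01).all()

    def test_self_transition_from_mean_run_length(self):
        wt = make_wt(list(np.linspace(0.45, 0.55, 10)) + list(np.linspace(0.78, 0.82, 5)))
        tr = self._training([("chr1", 0, 100_000, "PMD"), ("chr1", 100_000, 150_000, "HMD")])
        m = train_supervised(wt, tr)
        assert m.transitions[0, 0] == pytest.approx(1 - 1 / 10)
        assert m.transitions[1, 1] == pytest.approx(1 - 1 / 5)

    def test_initial_is_stationary(self):
        wt = make_wt(list(np.linspace(0.45, 0.55, 10)) + list(np.linspace(0.78, 0.82, 5)))
        tr = self._training([("chr1", 0, 100_000, "PMD"), ("chr1", 100_000, 150_000, "HMD")])
        m = train_supervised(wt, tr)
        assert np.allclose(m.initial @ m.transitions, m.initial, atol=1e-12)

    def test_random_training_matches_counting_oracle(self, rng):
        frac = rng.uniform(0.3, 0.6, size=60)
        spans = [("chr1", 0, 120_000, "PMD"), ("chr1", 200_000, 300_000, "HMD"),
                 ("chr1", 350_000, 420_000, "PMD"), ("chr1", 450_000, 600_000, "HMD")]
        for c, s, e, st in spans:
            if st == "HMD":
                idx = [k for k in range(60) if s <= k * 10_000 and (k + 1) * 10_000 <= e]
                frac[idx] = rng.uniform(0.7, 0.95, size=len(idx))
        wt = make_wt(frac)
        m = train_supervised(wt, self._training(spans))
        for i, state in enumerate(STATES):
            vals, runs = [], []
            for c, s, e, st in spans:
                if st != state:
                    continue
                idx = [k for k in range(60) if s <= k * 10_000 and (k + 1) * 10_000 <= e]
                vals.extend(frac[idx])
                runs.append(len(idx))
            assert m.means[i] == pytest.approx(np.mean(vals))
            assert m.sds[i] == pytest.approx(max(np.std(vals, ddof=1), 0.01))
            assert m.transitions[i, i] == pytest.approx(1 - 1 / np.mean(runs))

    def test_too_few_windows_is_error(self):
        wt = make_wt([0.5, 0.8, 0.8, 0.8])
        tr = self._training([("chr1", 0, 10_000, "PMD"), ("chr1", 10_000, 40_000, "HMD")])
        with pytest.raises(ValidationError, match="PMD"):
            train_supervised(wt, tr)

    def test_bad_label_is_error(self):
        wt = make_wt([0.5, 0.8])
        tr = self._training([("chr1", 0, 20_000, "LMR")])
        with pytest.raises(ValidationError, match="PMD/HMD"):
            train_supervised(wt, tr)


class TestViterbi:
    def test_well_separated_blocks_recovered(self):
        truth = [0] * 6 + [1] * 6
        frac = np.where(np.array(truth) == 1, 0.8, 0.5) + 0.001
        model = simple_model()
        doms = viterbi_segment(model, make_wt(frac))
        assert doms.data["state"].tolist() == ["PMD", "HMD"]
        assert doms.data["n_windows"].tolist() == [6, 6]
        assert np.array_equal(_viterbi_path(frac, model), brute_force_path(model, frac))

    def test_single_window_takes_likelier_state(self):
        model = simple_model()
        doms = viterbi_segment(model, make_wt([0.79]))
        assert doms.data.iloc[0]["state"] == "HMD"

    def test_emission_tie_breaks_toward_pmd(self):
        # observation equidistant from both means with equal sds and a
        # symmetric chain: both states tie exactly, PMD is the declared winner
        model = simple_model(mu=(0.5, 0.7), sd=(0.05, 0.05), stay=(0.5, 0.5))
        doms = viterbi_segment(model, make_wt([0.6]))
        assert doms.data.iloc[0]["state"] == "PMD"

    def test_missing_windows_bridged_by_transitions(self):
        frac = np.array([0.5, np.nan, np.nan, 0.51, 0.8, 0.8])
        doms = viterbi_segment(simple_model(), make_wt(frac))
        assert doms.data["state"].tolist() == ["PMD", "HMD"]
        assert doms.data["n_windows"].tolist() == [4, 2]

    def test_all_missing_chromosome_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="all windows missing"):
            doms = viterbi_segment(simple_model(), make_wt([np.nan, np.nan]))
        assert len(doms) == 0

    def test_matches_exhaustive_enumeration_on_random_instances(self, rng):
        for _ in range(30):
            model, frac = random_hmm_instance(rng, max_windows=10)
            assert np.array_equal(_viterbi_path(frac, model), brute_force_path(model, frac))


class TestPostprocess:
    def _domains(self, spans):
        return DomainSet(pd.DataFrame(
            [(c, s, e, st, (e - s) // 20_000) for c, s, e, st in spans],
            columns=["chrom", "start", "end", "state", "n_windows"]))

    def test_short_domain_absorbed(self):
        d = self._domains([("chr1", 0, 200_000, "HMD"), ("chr1", 200_000, 220_000, "PMD"),
                           ("chr1", 220_000, 520_000, "HMD")])
        out = postprocess_domains(d, min_length=100_000, policy="merge")
        assert len(out) == 1
        assert out.data.iloc[0].tolist()[:4] == ["chr1", 0, 520_000, "HMD"]

    def test_keep_policy_is_identity(self):
        d = self._domains([("chr1", 0, 200_000, "HMD"), ("chr1", 200_000, 220_000, "PMD")])
        assert postprocess_domains(d, policy="keep") is d

    def test_all_long_untouched_by_merge(self):
        d = self._domains([("chr1", 0, 200_000, "HMD"), ("chr1", 200_000, 400_000, "PMD")])
        out = postprocess_domains(d, min_length=100_000, policy="merge")
        pd.testing.assert_frame_equal(out.data, d.data)

    def test_random_sets_satisfy_invariants_after_merge(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            lengths = rng.integers(1, 20, size=n) * 20_000
            starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
            first = int(rng.integers(2))
            spans = [("chr1", int(s), int(s + L), STATES[(first + i) % 2])
                     for i, (s, L) in enumerate(zip(starts, lengths))]
            out = postprocess_domains(self._domains(spans), min_length=100_000, policy="merge")
            st = out.data["state"].to_numpy()
            assert (st[1:] != st[:-1]).all()
            assert out.data["start"].iloc[0] == 0
            assert out.data["end"].iloc[-1] == int(starts[-1] + lengths[-1])
            if len(out) > 1:
                assert ((out.data["end"] - out.data["start"]) >= 100_000).all()


class TestDomainSet:
    def test_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            DomainSet(pd.DataFrame([("chr1", 0, 100, "PMD", 1), ("chr1", 50, 200, "HMD", 1)],
                                   columns=["chrom", "start", "end", "state", "n_windows"]))

    def test_same_state_adjacency_rejected(self):
        with pytest.raises(ValidationError, match="share a state"):
            DomainSet(pd.DataFrame([("chr1", 0, 100, "PMD", 1), ("chr1", 100, 200, "PMD", 1)],
                                   columns=["chrom", "start", "end", "state", "n_windows"]))

    def test_bed_round_trip(self, tmp_path):
        d = DomainSet(pd.DataFrame([("chr1", 0, 100, "PMD", 1), ("chr1", 100, 200, "HMD", 1)],
                                   columns=["chrom", "start", "end", "state", "n_windows"]))
        d.to_bed(tmp_path / "d.bed")
        back = DomainSet.from_bed(tmp_path / "d.bed")
        pd.testing.assert_frame_equal(back.data[["chrom", "start", "end", "state"]],
                                      d.data[["chrom", "start", "end", "state"]])


class TestDomainMethylation:
    def _domains(self):
        return DomainSet(pd.DataFrame(
            [("chr1", 0, 50_000, "PMD", 5), ("chr1", 50_000, 100_000, "HMD", 5)],
            columns=["chrom", "start", "end", "state", "n_windows"]))

    def test_count_pooling(self):
        track = CpGTrack("s", pd.DataFrame(
            [("chr1", 10, 1, 2), ("chr1", 20, 1, 2)], columns=["chrom", "pos", "meth", "total"]))
        table = sample_domain_methylation([track], self._domains())
        assert table.fractions["s"].iloc[0] == pytest.approx(0.5)

    def test_uncovered_domain_missing(self):
        track = CpGTrack("s", pd.DataFrame(
            [("chr1", 10, 1, 2)], columns=["chrom", "pos", "meth", "total"]))
        table = sample_domain_methylation([track], self._domains())
        assert np.isnan(table.fractions["s"].iloc[1])

    def test_random_cohort_matches_double_loop_oracle(self, rng):
        domains = DomainSet(pd.DataFrame(
            [("chr1", 0, 30_000, "PMD", 3), ("chr1", 30_000, 70_000, "HMD", 4),
             ("chr2", 0, 100_000, "PMD", 10)],
            columns=["chrom", "start", "end", "state", "n_windows"]))
        tracks = [CpGTrack(f"s{i}", random_track_frame(rng, n=80, max_pos=90_000))
                  for i in range(4)]
        table = sample_domain_methylation(tracks, domains)
        for t in tracks:
            for di, d in domains.data.iterrows():
                m = sum(r.meth for r in t.data.itertuples()
                        if r.chrom == d["chrom"] and d["start"] <= r.pos < d["end"])
                tot = sum(r.total for r in t.data.itertuples()
                          if r.chrom == d["chrom"] and d["start"] <= r.pos < d["end"])
                if tot == 0:
                    assert np.isnan(table.fractions[t.sample_id].iloc[di])
                else:
                    assert table.fractions[t.sample_id].iloc[di] == pytest.approx(m / tot)

    def test_global_means_equal_direct_basepair_pool(self, rng):
        """Count-weighted pooling through the table equals pooling the raw
        track restricted to the state's base pairs."""
        domains = self._domains()
        track = CpGTrack("s", random_track_frame(rng, n=100, max_pos=99_000, chroms=("chr1",)))
        table = sample_domain_methylation([track], domains)
        gm = table.global_means()
        for state in STATES:
            sub = track.subset(domains.of_state(state))
            assert gm.loc["s", f"{state.lower()}_mean"] == pytest.approx(
                sub["meth"].sum() / sub["total"].sum())


class TestPmdHmdCorrelation:
    def _table(self, pairs):
        return pd.DataFrame(pairs, columns=["pmd_mean", "hmd_mean"],
                            index=[f"s{i}" for i in range(len(pairs))])

    def test_perfectly_linear(self):
        rep = pmd_hmd_correlation(self._table([(0.5, 0.7), (0.6, 0.8), (0.7, 0.9)]))
        assert rep["r"] == pytest.approx(1.0)

    def test_perfectly_antilinear(self):
        rep = pmd_hmd_correlation(self._table([(0.5, 0.9), (0.6, 0.8), (0.7, 0.7)]))
        assert rep["r"] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.uniform(0.4, 0.6, 47)
        y = rng.uniform(0.8, 0.9, 47)
        rep = pmd_hmd_correlation(self._table(list(zip(x, y))))
        num = np.mean((x - x.mean()) * (y - y.mean()))
        assert rep["r"] == pytest.approx(num / (x.std() * y.std()), abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValidationError, match="variance"):
            pmd_hmd_correlation(self._table([(0.5, 0.7), (0.5, 0.8), (0.5, 0.9)]))

    def test_per_group_regression_lines(self, rng):
        x = rng.uniform(0.4, 0.6, 12)
        y = 0.5 + 0.5 * x + rng.normal(0, 0.01, 12)
        table = self._table(list(zip(x, y)))
        groups = {f"s{i}": ("ASD" if i < 6 else "TD") for i in range(12)}
        rep = pmd_hmd_correlation(table, groups)
        assert set(rep["groups"]) == {"ASD", "TD"}
        for g in rep["groups"].values():
            assert g["slope"] == pytest.approx(0.5, abs=0.2)


class TestModelResultsFrontEnd:
    def test_fit_recovers_architecture(self, small_cohort):
        cohort = small_cohort
        arch = cohort.architecture
        autosomes = {c: L for c, L in arch.genome.items() if c != "chrX"}
        tracks = []
        for t in cohort.tracks:
            sub = t.data[t.data["chrom"] != "chrX"]
            tracks.append(CpGTrack(t.sample_id, sub, genome=autosomes))
        model = DomainSegmentation.from_tracks(tracks, arch.training, width=20_000)
        res = model.fit()
        assert res.hmm.means[0] < res.hmm.means[1]
        txt = res.summary()
        assert "PMD" in txt and "HMD" in txt
        # most decoded bases agree with the planted map
        truth = {(c, s, e): st for c, s, e, st, _ in
                 arch.domains.data[arch.domains.data["chrom"] != "chrX"].itertuples(index=False)}
        dec = res.domains.data
        agree = total = 0
        for (c, s, e), st in truth.items():
            for r in dec.itertuples(index=False):
                if r.chrom != c:
                    continue
                ov = max(0, min(e, r.end) - max(s, r.start))
                total += ov
                if r.state == st:
                    agree += ov
        assert agree / total > 0.9
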