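import numpy as np
import pytest

from irchrom.core import GenomicInterval, CoverageTrack
from irchrom.events import IntronEvent
from irchrom.footprints import (
    OccurrenceWindow, HexamerProfile, FootprintHmm, FootprintModel,
    collect_occurrences, build_hexamer_profile, train_footprint_hmm,
    decode_profile, scan_all_hexamers, viterbi,
    WINDOW_LEN, WINDOW_FLANK, HEX_SLOTS, STATE_NAMES, STATE_INDEX,
    N_STATES, TOPOLOGY_MASK, BACKGROUND_STATES, FP_PRIMARY,
)
from irchrom.simulate import (
    SimulationConfig, FootprintSpec, simulate_dataset,
    make_reference_hmm, simulate_labeled_profiles,
)
from irchrom.events import call_intron_events, exclude_first_introns

from conftest import random_hexamers


def _event(exon3_len=400, base=0):
    return IntronEvent(
        gene_id="g", intron_index=2,
        exon5=GenomicInterval("chr1", base, base + 300, "+"),
        intron=GenomicInterval("chr1", base + 300, base + 450, "+"),
        exon3=GenomicInterval("chr1", base + 450, base + 450 + exon3_len, "+"),
        label="IR", relative_position=0.5, is_first_intron=False, strand="+",
    )


class TestCollectOccurrences:
    HEX = "ACGTAC"

    def _genome(self, offset, exon3_len=400):
        seq = ["T"] * 2000
        for i, b in enumerate(self.HEX):
            seq[450 + offset + i] = b
        return {"chr1": "".join(seq)}

    def test_centered_occurrence_fully_present(self):
        e = _event()
        genome = self._genome(150)
        dnase = CoverageTrack({"chr1": np.full(2000, 2.0)})
        (w,) = collect_occurrences(self.HEX, [e], "exon3", genome, dnase)
        assert w.present.all()
        assert (w.values == 2.0).all()

    def test_boundary_clipping(self):
        # occurrence 30 bp from the part 5' boundary: upstream slots 0..69 absent
        e = _event()
        genome = self._genome(30)
        dnase = CoverageTrack({"chr1": np.full(2000, 1.0)})
        (w,) = collect_occurrences(self.HEX, [e], "exon3", genome, dnase)
        assert not w.present[:70].any()
        assert w.present[70:WINDOW_FLANK].all()
        assert w.present[HEX_SLOTS].all()

    def test_lowest_coverage_instance_kept(self):
        e = _event()
        seq = ["T"] * 2000
        for off in (50, 200):
            for i, b in enumerate(self.HEX):
                seq[450 + off + i] = b
        cov = np.full(2000, 5.0)
        cov[650:656] = 3.0  # the offset-200 instance is deeper
        dnase = CoverageTrack({"chr1": cov})
        (w,) = collect_occurrences(self.HEX, [e], "exon3", {"chr1": "".join(seq)}, dnase)
        assert (w.values[HEX_SLOTS] == 3.0).all()

    def test_invalid_hexamer_is_error(self):
        with pytest.raises(ValueError):
            collect_occurrences("ACGTAN", [], "exon3", {}, None)


class TestProfileConstruction:
    @staticmethod
    def _window(values):
        return OccurrenceWindow(
            hexamer="ACGTAC", event_uid="e", part="exon3",
            values=np.asarray(values, float),
            present=~np.isnan(np.asarray(values, float)),
        )

    def test_mean_and_standardization(self):
        v1, v2 = np.full(WINDOW_LEN, 2.0), np.full(WINDOW_LEN, 4.0)
        prof = build_hexamer_profile(
            [self._window(v1), self._window(v2)], c_train=2.0, min_occurrences=2
        )
        assert (prof.values == 1.5).all()  # (2+4)/2 / 2

    def test_partial_support(self):
        v1 = np.full(WINDOW_LEN, 2.0)
        v2 = np.full(WINDOW_LEN, 4.0)
        v2[0] = np.nan  # absent in one window
        prof = build_hexamer_profile(
            [self._window(v1), self._window(v2)], c_train=1.0, min_occurrences=2
        )
        assert prof.values[0] == 2.0 and prof.support[0] == 1
        assert prof.values[1] == 3.0 and prof.support[1] == 2

    def test_below_min_occurrences_unscored(self):
        v = np.full(WINDOW_LEN, 1.0)
        assert build_hexamer_profile([self._window(v)], 1.0, min_occurrences=10) is None

    def test_mean_matches_naive_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        wins = []
        for _ in range(20):
            v = rng.poisson(10, WINDOW_LEN).astype(float)
            gap = rng.integers(0, 80)
            v[:gap] = np.nan
            wins.append(self._window(v))
        prof = build_hexamer_profile(wins, c_train=3.0, min_occurrences=10)
        for pos in range(WINDOW_LEN):
            vals = [w.values[pos] for w in wins if w.present[pos]]
            if vals:
                assert abs(prof.values[pos] - np.mean(vals) / 3.0) < 1e-12


class TestTraining:
    def test_emission_means_recovered_within_5pct(self, reference_hmm):
        profiles = simulate_labeled_profiles(reference_hmm, 500, rng=13)
        hmm = train_footprint_hmm(profiles)
        rel = np.abs(hmm.means - reference_hmm.means) / np.abs(reference_hmm.means)
        assert rel.max() < 0.05

    def test_c_train_is_background_mean(self, reference_hmm):
        profiles = simulate_labeled_profiles(reference_hmm, 200, rng=13)
        hmm = train_footprint_hmm(profiles)
        bg = np.concatenate([
            v[np.isin(s, list(BACKGROUND_STATES))] for v, s in profiles
        ])
        assert hmm.c_train == pytest.approx(bg.mean())

    def test_all_background_labels_is_error(self):
        values = np.ones(50)
        labels = np.zeros(50, dtype=int)  # all BG1
        with pytest.raises(ValueError):
            train_footprint_hmm([(values, labels)])

    def test_constant_emission_state_hits_variance_floor(self):
        labels = np.array(
            [0] * 10 + [5] * 3 + [6] * 5 + [7] * 3 + [12] * 10
        )
        values = np.where(np.isin(labels, [0, 12]), 1.0, 0.3)
        hmm = train_footprint_hmm([(values, labels)])
        assert hmm.variances[FP_PRIMARY] == pytest.approx(1e-3)

    def test_topology_violating_labels_are_error(self):
        labels = np.array([0] * 5 + [12] * 5 + [6] * 5)  # BG2 -> FP illegal
        values = np.ones(15)
        with pytest.raises(ValueError):
            train_footprint_hmm([(values, labels)])

    def test_transition_rows_stochastic_and_topology_respected(self, trained_hmm):
        np.testing.assert_allclose(trained_hmm.transitions.sum(axis=1), 1, atol=1e-9)
        assert not ((trained_hmm.transitions > 0) & ~TOPOLOGY_MASK).any()

    def test_baum_welch_refinement_does_not_break_topology(self, reference_hmm):
        profiles = simulate_labeled_profiles(reference_hmm, 30, length=80, rng=3)
        hmm = train_footprint_hmm(profiles, refine=True, max_iter=3)
        assert not ((hmm.transitions > 0) & ~TOPOLOGY_MASK).any()
        np.testing.assert_allclose(hmm.transitions.sum(axis=1), 1, atol=1e-6)
        # refinement stays near the supervised solution
        sup = train_footprint_hmm(profiles)
        assert np.abs(hmm.means - sup.means).max() < 0.2


def _brute_force_paths(hmm, obs):
    """All topology-valid state paths and their log-probabilities."""
    log_b = hmm.log_emission(obs)
    with np.errstate(divide="ignore"):
        log_a = np.log(np.where(hmm.transitions > 0, hmm.transitions, 0.0))
        log_start = np.log(np.where(hmm.start > 0, hmm.start, 0.0))
    results = []

    def rec(t, state, lp, path):
        lp = lp + log_b[state, t]
        if t == len(obs) - 1:
            results.append((lp, path + [state]))
            return
        for nxt in np.flatnonzero(TOPOLOGY_MASK[state]):
            rec(t + 1, nxt, lp + log_a[state, nxt], path + [state])

    for s in np.flatnonzero(hmm.start > 0):
        rec(0, s, log_start[s], [])
    return results


class TestViterbi:
    def test_matches_exhaustive_argmax(self, trained_hmm):
        rng = np.random.default_rng(21)
        for _ in range(5):
            obs = rng.uniform(0.2, 1.2, size=7)
            all_paths = _brute_force_paths(trained_hmm, obs)
            best_lp = max(lp for lp, _ in all_paths)
            path = viterbi(trained_hmm, obs)
            # score the viterbi path by hand
            lp = np.log(trained_hmm.start[path[0]])
            lp += trained_hmm.log_emission(obs)[path[0], 0]
            for t in range(1, len(obs)):
                lp += np.log(trained_hmm.transitions[path[t - 1], path[t]])
                lp += trained_hmm.log_emission(obs)[path[t], t]
            assert lp == pytest.approx(best_lp, abs=1e-9)

    def test_beats_random_valid_paths(self, trained_hmm):
        rng = np.random.default_rng(4)
        obs = rng.uniform(0.2, 1.2, size=40)
        path = viterbi(trained_hmm, obs)
        log_b = trained_hmm.log_emission(obs)

        def score(p):
            lp = np.log(trained_hmm.start[p[0]]) + log_b[p[0], 0]
            for t in range(1, len(p)):
                a = trained_hmm.transitions[p[t - 1], p[t]]
                if a == 0:
                    return -np.inf
                lp += np.log(a) + log_b[p[t], t]
            return lp

        v_lp = score(path)
        for _ in range(1000):
            p = [0]
            for t in range(1, len(obs)):
                choices = np.flatnonzero(TOPOLOGY_MASK[p[-1]])
                p.append(int(rng.choice(choices)))
            assert score(p) <= v_lp + 1e-9

    def test_gap_skipping_composes_transitions(self, trained_hmm):
        values = np.full(WINDOW_LEN, np.nan)
        values[60:] = 1.0
        values[95:115] = 0.35
        path = viterbi(trained_hmm, values)
        assert (path[:60] == -1).all()
        assert (path[60:] >= 0).all()
        assert (path[100:110] == FP_PRIMARY).any()


class TestDecode:
    def _profile(self, values, c_train):
        values = np.asarray(values, float)
        return HexamerProfile(
            hexamer="ACGTAC", part="exon3", label="IR",
            values=values, support=np.where(np.isfinite(values), 5, 0),
            n_occurrences=5, c_train=c_train,
        )

    def test_flat_background_profile_scores_zero(self, trained_hmm):
        prof = self._profile(np.ones(WINDOW_LEN), trained_hmm.c_train)
        call = decode_profile(prof, trained_hmm)
        assert call.score == 0.0
        assert not call.is_footprint
        assert not (call.path == FP_PRIMARY).any()

    def test_score_is_log_ratio_of_decoded_means(self, trained_hmm):
        values = np.ones(WINDOW_LEN)
        values[96:112] = 0.35
        prof = self._profile(values, trained_hmm.c_train)
        call = decode_profile(prof, trained_hmm)
        assert call.is_footprint
        fp = call.path == FP_PRIMARY
        bg = np.isin(call.path, list(BACKGROUND_STATES))
        expected = -np.log(values[fp].mean() / values[bg].mean())
        assert call.score == pytest.approx(expected, rel=1e-12)

    def test_log_base_option_rescales_score(self, trained_hmm):
        values = np.ones(WINDOW_LEN)
        values[96:112] = 0.35
        prof = self._profile(values, trained_hmm.c_train)
        s_e = decode_profile(prof, trained_hmm).score
        s_10 = decode_profile(prof, trained_hmm, log_base=10).score
        assert s_10 == pytest.approx(s_e / np.log(10))

    def test_zero_fp_coverage_caps_score(self, trained_hmm):
        values = np.ones(WINDOW_LEN)
        values[96:112] = 0.0
        call = decode_profile(self._profile(values, trained_hmm.c_train), trained_hmm)
        assert call.score == 10.0

    def test_c_train_mismatch_is_error(self, trained_hmm):
        prof = self._profile(np.ones(WINDOW_LEN), c_train=1.0)
        with pytest.raises(ValueError):
            decode_profile(prof, trained_hmm)

    def test_footprint_requires_hexamer_slot_overlap(self, trained_hmm):
        values = np.ones(WINDOW_LEN)
        values[10:30] = 0.35  # dip far from the hexamer slots
        call = decode_profile(self._profile(values, trained_hmm.c_train), trained_hmm)
        assert not call.is_footprint


@pytest.fixture(scope="module")
def planted_scan(trained_hmm):
    rng = np.random.default_rng(42)
    planted = random_hexamers(rng, 5)
    controls = random_hexamers(rng, 20, avoid=planted, unrelated_to=planted)
    specs = tuple(
        FootprintSpec(h, "exon3", 0.3, 10, prob_ir=0.25) for h in planted
    )
    cfg = SimulationConfig(
        seed=77, n_genes=80, exon_length_range=(400, 600),
        footprint_hexamers=specs, dhs_prob_ir=0, dhs_prob_ie=0,
    )
    ds = simulate_dataset(cfg)
    events = exclude_first_introns(call_intron_events(ds.models, ds.rna))
    return ds, events, planted, controls


class TestScan:
    def test_planted_hexamers_recovered(self, planted_scan, trained_hmm):
        ds, events, planted, controls = planted_scan
        scored, _ = scan_all_hexamers(
            events, ds.genome, ds.dnase, trained_hmm, threshold=0.30,
            parts=("exon3",), classes=("IR",), hexamers=planted + controls,
        )
        sp = scored[scored.hexamer.isin(planted)]
        sc = scored[scored.hexamer.isin(controls)]
        assert sp.is_footprint.all()
        assert not sc.is_footprint.any()

    def test_threshold_monotonicity(self, planted_scan, trained_hmm):
        ds, events, planted, controls = planted_scan
        flags = {}
        for thr in (0.30, 0.20):
            scored, _ = scan_all_hexamers(
                events, ds.genome, ds.dnase, trained_hmm, threshold=thr,
                parts=("exon3",), classes=("IR",), hexamers=planted + controls,
            )
            flags[thr] = set(scored[scored.is_footprint].hexamer)
        assert flags[0.30] <= flags[0.20]

    def test_rare_hexamers_logged_unscored(self, planted_scan, trained_hmm):
        ds, events, planted, controls = planted_scan
        scored, unscored = scan_all_hexamers(
            events, ds.genome, ds.dnase, trained_hmm,
            parts=("intron",), classes=("IE",), min_occurrences=10,
        )
        assert (unscored.n_occ < 10).all()
        assert set(scored.hexamer).isdisjoint(set(unscored.hexamer))

    def test_scan_profile_agrees_with_collect_and_decode(
        self, planted_scan, trained_hmm
    ):
        ds, events, planted, controls = planted_scan
        scored, _ = scan_all_hexamers(
            events, ds.genome, ds.dnase, trained_hmm,
            parts=("exon3",), classes=("IR",), hexamers=[planted[0]],
        )
        row = scored.iloc[0]
        ir = [e for e in events if e.label == "IR"]
        wins = collect_occurrences(planted[0], ir, "exon3", ds.genome, ds.dnase)
        prof = build_hexamer_profile(wins, trained_hmm.c_train)
        call = decode_profile(prof, trained_hmm)
        assert row.n_occ == len(wins)
        assert row.S == pytest.approx(call.score, rel=1e-9)


class TestModelFacade:
    def test_fit_returns_results_with_summary(self, reference_hmm):
        profiles = simulate_labeled_profiles(reference_hmm, 50, rng=2)
        res = FootprintModel(profiles).fit()
        text = res.summary()
        for name in ("BG1", "DN", "FP", "UP", "BG2"):
            assert name in text
        assert "C_train" in text

    def test_results_decode_matches_function(self, reference_hmm):
        profiles = simulate_labeled_profiles(reference_hmm, 50, rng=2)
        res = FootprintModel(profiles).fit()
        values = np.ones(WINDOW_LEN)
        values[96:110] = 0.35
        prof = HexamerProfile(
            hexamer="ACGTAC", part="exon3", label="IR", values=values,
            support=np.full(WINDOW_LEN, 5), n_occurrences=5,
            c_train=res.hmm.c_train,
        )
        assert res.decode(prof).score == decode_profile(prof, res.hmm).score


def test_hmm_json_round_trip(trained_hmm, tmp_path):
    p = tmp_path / "hmm.json"
    trained_hmm.to_json(p)
    back = FootprintHmm.from_json(p)
    np.testing.assert_allclose(back.transitions, trained_hmm.transitions)
    np.testing.assert_allclose(back.means, trained_hmm.means)
    np.testing.assert_allclose(back.variances, trained_hmm.variances)
    assert back.c_train == trained_hmm.c_train
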