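"""Generator contracts: determinism, structure, and statistical recovery."""

import io

import numpy as np
import pytest
from scipy import stats

from tailnet.association import build_association_network
from tailnet.data import BiteEvent, aggregate_scans, build_scan_matrices, write_scans
from tailnet.injury import mts_records
from tailnet.metrics import strength
from tailnet.simulate import (
    ConfigurationError,
    SimConfig,
    simulate_bite_events,
    simulate_dataset,
    simulate_herd,
    simulate_lying_scans,
    simulate_tail_scores,
)


def _csv_bytes(records) -> bytes:
    buf = io.StringIO()
    write_scans(records, buf)
    return buf.getvalue().encode()


class TestConfig:
    def test_probabilities_validated(self):
        with pytest.raises(ConfigurationError):
            SimConfig(p_lie=1.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(bite_rate_base=-0.1)

    def test_odd_pen_with_sex_split_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(pigs_per_pen=7, sex_split=True)


class TestHerd:
    def test_study_design_roster_size(self):
        herd = simulate_herd(SimConfig(n_pens=12, pigs_per_pen=8, seed=0))
        assert len(herd.pigs) == 96
        assert len(herd.pens()) == 12
        treatments = {p.treatment for p in herd.pigs}
        assert treatments == {"LM", "HLM", "NLM"}
        for pen in herd.pens():
            sexes = [p.sex for p in herd.pigs if p.pen_id == pen]
            assert sexes.count("barrow") == 4 and sexes.count("gilt") == 4

    def test_zero_kappa_hub_collapses_to_uniform(self):
        hub = simulate_herd(SimConfig(n_pens=2, preference_structure="hub", kappa=0.0, seed=3))
        uni = simulate_herd(SimConfig(n_pens=2, preference_structure="uniform", seed=3))
        for pen in hub.preference:
            assert np.array_equal(hub.preference[pen], uni.preference[pen])

    def test_same_seed_same_roster(self):
        a = simulate_herd(SimConfig(seed=5))
        b = simulate_herd(SimConfig(seed=5))
        assert a.pigs == b.pigs

    def test_weight_trajectories_monotone(self, small_herd):
        for pig in small_herd.pigs:
            weights = [pig.weights[w] for w in sorted(pig.weights)]
            assert all(b > a for a, b in zip(weights, weights[1:]))

    def test_adding_pens_preserves_existing_pens(self):
        small = simulate_dataset(SimConfig(n_pens=3, periods=(15,), seed=9))
        large = simulate_dataset(SimConfig(n_pens=5, periods=(15,), seed=9))
        small_pens = {p.pen_id for p in small.herd.pigs}
        assert [r for r in large.scans if r.pen_id in small_pens] == list(small.scans)
        assert [e for e in large.events if e.pen_id in small_pens] == list(small.events)


class TestLyingScans:
    def test_determinism_byte_identical(self):
        cfg = SimConfig(n_pens=3, periods=(15,), seed=11)
        a = simulate_lying_scans(simulate_herd(cfg), cfg)
        b = simulate_lying_scans(simulate_herd(cfg), cfg)
        assert _csv_bytes(a) == _csv_bytes(b)

    def test_p_lie_zero_means_nobody_lies(self):
        cfg = SimConfig(n_pens=2, periods=(15,), p_lie=0.0, seed=1)
        scans = simulate_lying_scans(simulate_herd(cfg), cfg)
        assert all(r.lying == 0 and not r.partners for r in scans)

    def test_forced_pairing_in_two_pig_pen(self):
        cfg = SimConfig(n_pens=1, pigs_per_pen=2, periods=(15,), p_lie=1.0, seed=1)
        herd = simulate_herd(cfg)
        scans = simulate_lying_scans(herd, cfg)
        nodes, mats = build_scan_matrices(scans, herd.pens()[0], 15)
        agg = aggregate_scans(mats, nodes=nodes)
        net = build_association_network(agg)
        assert net.W[0, 1] == 1.0

    def test_partnership_symmetric_and_implies_lying(self, study_design_dataset):
        by_scan = {}
        for r in study_design_dataset.scans:
            by_scan.setdefault((r.pen_id, r.period, r.scan_index), {})[r.pig_id] = r
        for pigs in by_scan.values():
            for r in pigs.values():
                for other in r.partners:
                    assert r.lying == 1
                    assert r.pig_id in pigs[other].partners

    def test_at_most_two_lying_neighbors(self, study_design_dataset):
        assert max(len(r.partners) for r in study_design_dataset.scans) <= 2

    def test_uniform_structure_gives_even_mean_hwi(self):
        # 200 replicate pen-periods; dyad means should agree to MC error
        cfg = SimConfig(n_pens=200, periods=(15,), p_lie=0.8, seed=13)
        herd = simulate_herd(cfg)
        scans = simulate_lying_scans(herd, cfg)
        per_dyad = []
        for pen in herd.pens():
            nodes, mats = build_scan_matrices(scans, pen, 15)
            W = build_association_network(aggregate_scans(mats, nodes=nodes)).W
            per_dyad.append(W[np.triu_indices(8, 1)])
        means = np.mean(per_dyad, axis=0)
        assert means.std() < 0.01  # ~MC standard error at 200 replicates
        assert np.ptp(means) < 0.04


class TestBiteEvents:
    def test_zero_rate_means_no_events(self):
        cfg = SimConfig(n_pens=2, bite_rate_base=0.0, seed=1)
        assert simulate_bite_events(simulate_herd(cfg), cfg) == []

    def test_same_seed_identical_streams(self):
        cfg = SimConfig(n_pens=3, seed=21)
        herd = simulate_herd(cfg)
        assert simulate_bite_events(herd, cfg) == simulate_bite_events(herd, cfg)

    def test_law_of_large_numbers_single_dyad(self):
        # sigma_out = sigma_in = 0: one directed dyad at rate lambda
        lam = 0.8
        counts = []
        for seed in range(2500):
            cfg = SimConfig(
                n_pens=1, pigs_per_pen=2, periods=(15,), bite_rate_base=lam,
                biter_heterogeneity=0.0, victim_heterogeneity=0.0, seed=seed,
            )
            herd = simulate_herd(cfg)
            events = simulate_bite_events(herd, cfg)
            counts.append(sum(1 for e in events if e.biter == herd.pigs[0].pig_id))
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - lam) < 3 * se + 1e-9

    def test_timestamps_within_window(self, study_design_dataset):
        assert all(0 <= e.timestamp_min <= 360 for e in study_design_dataset.events)


class TestTailScores:
    def test_no_bites_all_zero(self, small_herd, small_config):
        scores = simulate_tail_scores(small_herd, [], small_config)
        assert all(r.score == 0 for r in scores)
        assert all(r.mts == 0 for r in mts_records(scores))

    def test_forced_escalation_reaches_four(self, small_herd, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, injury_gain=1.0, heal_prob=0.0)
        pig = small_herd.pigs[0]
        events = [
            BiteEvent(pen_id=pig.pen_id, period=w, timestamp_min=1.0,
                      biter=small_herd.pigs[1].pig_id, recipient=pig.pig_id)
            for w in (11, 12, 13, 14, 15)
        ]
        scores = simulate_tail_scores(small_herd, events, cfg)
        mts = {r.pig_id: r.mts for r in mts_records(scores)}
        assert mts[pig.pig_id] == 4

    def test_assessment_count_twice_weekly_14_weeks(self, small_herd, small_config):
        scores = simulate_tail_scores(small_herd, [], small_config)
        per_pig = {}
        for r in scores:
            per_pig.setdefault(r.pig_id, []).append(r.assessment_index)
        assert all(sorted(v) == list(range(1, 29)) for v in per_pig.values())

    def test_mean_mts_monotone_in_bite_rate(self):
        grid = [0.0, 0.5, 1.0, 2.0]
        means = []
        for rate in grid:
            cfg = SimConfig(n_pens=13, bite_rate_base=rate, seed=31)  # 104 pigs
            herd = simulate_herd(cfg)
            events = simulate_bite_events(herd, cfg)
            scores = simulate_tail_scores(herd, events, cfg)
            means.append(np.mean([r.mts for r in mts_records(scores)]))
        assert all(b >= a for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]


class TestRecovery:
    def test_in_degree_predicts_injury(self):
        cfg = SimConfig(n_pens=30, seed=17)  # 240 pigs
        herd = simulate_herd(cfg)
        events = simulate_bite_events(herd, cfg)
        scores = simulate_tail_scores(herd, events, cfg)
        mts = {r.pig_id: r.mts for r in mts_records(scores)}
        received: dict[str, int] = {}
        for e in events:
            received[e.recipient] = received.get(e.recipient, 0) + 1
        pigs = [p.pig_id for p in herd.pigs]
        rho = stats.spearmanr(
            [received.get(p, 0) for p in pigs], [mts[p] for p in pigs]
        )
        assert rho.statistic > 0

    def test_non_hub_strength_lower_under_hub(self):
        def mean_nonhub_strength(structure, kappa):
            cfg = SimConfig(
                n_pens=20, periods=(15,), preference_structure=structure,
                kappa=kappa, seed=23,
            )
            herd = simulate_herd(cfg)
            scans = simulate_lying_scans(herd, cfg)
            vals = []
            for pen in herd.pens():
                nodes, mats = build_scan_matrices(scans, pen, 15)
                W = build_association_network(aggregate_scans(mats, nodes=nodes)).W
                vals.append(strength(W)[1:].mean())  # pig 1 is the hub slot
            return float(np.mean(vals))

        assert mean_nonhub_strength("uniform", 0.0) > mean_nonhub_strength("hub", 3.0)
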