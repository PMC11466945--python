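"""Synthetic pen-behavior generator.

Emulates the data a scan-sampling study of group-housed growing-finishing
pigs produces: a roster of pens (default 12 pens of 8 pigs, 4 barrows +
4 gilts, assigned to the litter-origin treatments LM / HLM / NLM), three
6-h observation periods at 15, 19, and 23 weeks of age scanned at 10-min
intervals (36 scans), directed tail-biting events, and twice-weekly tail
injury scores over the 14-week growing-finishing phase (10-24 weeks).

The generative structure mirrors what the downstream analysis assumes:

* **Lying associations.**  At each scan every pig lies independently with
  probability ``p_lie``.  Lying-together pairs among the lying pigs are
  chosen by a weighted random matching: each dyad samples an exponential
  score with rate proportional to its preference weight ``w(a, b)``,
  dyads are accepted greedily in score order under a two-neighbor cap
  (mimicking row-lying), and the number of accepted pairs per scan is
  capped at ``floor(n_lying / 2)`` so that contact is a limited resource
  allocated by preference.  Preference structures: ``uniform`` (all
  weights 1), ``hub`` (one pig's dyads upweighted to 1 + kappa), and
  ``block`` (two half-pen blocks with within-block weight 1 + kappa,
  emulating half-littermate pens).
* **Tail biting.**  Per directed dyad and period, the bite count is
  Poisson with mean ``bite_rate_base * exp(s_out(i) + s_in(j))`` where
  the log-rate pig effects s_out, s_in are normal with SDs
  ``biter_heterogeneity`` / ``victim_heterogeneity``.
* **Injury.**  Between consecutive assessments a pig's score escalates
  one level with probability 1 - (1 - injury_gain)^(bites received in
  the window), capped at 4; scores of 1-2 heal one level with
  probability ``heal_prob`` in bite-free windows.

One pseudo-random stream is derived per pen (and stage) from the global
seed, so adding pens never perturbs existing pens' data, and the same
(config, seed) yields byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import (
    BiteEvent,
    ScanRecord,
    TailScoreRecord,
    ValidationError,
    write_bites,
    write_scans,
    write_tail_scores,
)

__all__ = [
    "SimConfig",
    "Pig",
    "HerdDesign",
    "simulate_herd",
    "simulate_lying_scans",
    "simulate_bite_events",
    "simulate_tail_scores",
    "simulate_dataset",
    "SimulatedData",
]

TREATMENTS = ("LM", "HLM", "NLM")
MINUTES_PER_WEEK = 7 * 24 * 60
OBSERVATION_MINUTES = 6 * 60


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design and generative parameters.

    Defaults reproduce the study design the analysis targets: 12 pens of
    8 pigs in 3 litter-origin treatments, 3 periods of 36 ten-minute
    scans, twice-weekly injury assessments over weeks 10-24.
    """

    n_pens: int = 12
    pigs_per_pen: int = 8
    treatments: tuple[str, ...] | None = None  # per-pen labels; default cycles LM/HLM/NLM
    periods: tuple[int, ...] = (15, 19, 23)  # observation ages, weeks
    scans_per_period: int = 36
    scan_interval: int = 10  # minutes
    p_lie: float = 0.8
    preference_structure: str = "uniform"  # uniform | hub | block
    kappa: float = 0.0  # preference concentration, >= 0
    bite_rate_base: float = 0.06  # expected bites per directed dyad per period
    biter_heterogeneity: float = 0.8  # SD of log-rate sender effect
    victim_heterogeneity: float = 0.6  # SD of log-rate receiver effect
    injury_gain: float = 0.5  # per-bite escalation probability
    heal_prob: float = 0.1  # per-assessment healing probability at scores 1-2
    assessments_per_week: int = 2
    study_start_week: int = 10
    study_weeks: int = 14
    sex_split: bool = True  # 4/4 barrow-gilt split
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pens < 1 or self.pigs_per_pen < 1 or self.scans_per_period < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.assessments_per_week < 1 or self.study_weeks < 1:
            raise ConfigurationError("counts must be >= 1")
        if not 0.0 <= self.p_lie <= 1.0:
            raise ConfigurationError("p_lie must be a probability in [0, 1]")
        if not 0.0 <= self.injury_gain <= 1.0:
            raise ConfigurationError("injury_gain must be a probability in [0, 1]")
        if not 0.0 <= self.heal_prob <= 1.0:
            raise ConfigurationError("heal_prob must be a probability in [0, 1]")
        if self.bite_rate_base < 0:
            raise ConfigurationError("bite_rate_base must be >= 0")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        if self.biter_heterogeneity < 0 or self.victim_heterogeneity < 0:
            raise ConfigurationError("heterogeneity SDs must be >= 0")
        if self.preference_structure not in ("uniform", "hub", "block"):
            raise ConfigurationError(
                f"unknown preference_structure {self.preference_structure!r}"
            )
        if self.sex_split and self.pigs_per_pen % 2 != 0:
            raise ConfigurationError(
                "an equal barrow/gilt split needs an even pigs_per_pen"
            )
        if self.treatments is not None and len(self.treatments) != self.n_pens:
            raise ConfigurationError("treatments must list one label per pen")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("treatments", "periods"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["treatments"] = list(self.treatments) if self.treatments else None
        d["periods"] = list(self.periods)
        return d


@dataclass(frozen=True)
class Pig:
    pig_id: str
    pen_id: str
    treatment: str
    sex: str  # barrow | gilt
    s_out: float  # latent sociality (log bite-rate sender effect)
    s_in: float  # latent vulnerability (log bite-rate receiver effect)
    weights: dict[int, float] = field(default_factory=dict)  # week -> kg


@dataclass(frozen=True)
class HerdDesign:
    """Roster plus per-pen symmetric preference matrices."""

    pigs: tuple[Pig, ...]
    preference: dict[str, np.ndarray]  # pen_id -> w(a, b), node order = sorted pig_ids

    def pens(self) -> list[str]:
        return sorted({p.pen_id for p in self.pigs})

    def pen_roster(self, pen_id: str) -> tuple[str, ...]:
        return tuple(sorted(p.pig_id for p in self.pigs if p.pen_id == pen_id))

    def pig(self, pig_id: str) -> Pig:
        for p in self.pigs:
            if p.pig_id == pig_id:
                return p
        raise KeyError(pig_id)

    def roster_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pigs:
            for week in sorted(p.weights):
                rows.append(
                    {
                        "pig_id": p.pig_id,
                        "pen_id": p.pen_id,
                        "treatment": p.treatment,
                        "sex": p.sex,
                        "week": week,
                        "weight_kg": round(p.weights[week], 3),
                    }
                )
        return pd.DataFrame(
            rows, columns=["pig_id", "pen_id", "treatment", "sex", "week", "weight_kg"]
        )


def _pen_rng(seed: int, pen_index: int, stage: int) -> np.random.Generator:
    """Stream for one pen and pipeline stage; stable as pens are added."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(pen_index, stage))
    )


def _preference_matrix(structure: str, kappa: float, k: int) -> np.ndarray:
    w = np.ones((k, k))
    if structure == "hub":
        w[0, :] = w[:, 0] = 1.0 + kappa  # first pig (lexicographic) is the hub
    elif structure == "block":
        half = k // 2
        for a in range(k):
            for b in range(k):
                if (a < half) == (b < half):
                    w[a, b] = 1.0 + kappa
    np.fill_diagonal(w, 0.0)
    return w


def simulate_herd(config: SimConfig) -> HerdDesign:
    """Build the roster, latent pig effects, weights, and preferences.

    Weight trajectories start around 25 kg at the beginning of the
    growing-finishing phase and accrue a strictly positive weekly gain
    (about 6.9 kg/week, the gain implied by ~1 kg average daily gain),
    so they are monotone increasing by construction.
    """
    labels = (
        tuple(config.treatments)
        if config.treatments is not None
        else tuple(TREATMENTS[(i * 3) // config.n_pens % 3] for i in range(config.n_pens))
    )
    weeks = list(
        range(config.study_start_week, config.study_start_week + config.study_weeks + 1)
    )
    pigs: list[Pig] = []
    preference: dict[str, np.ndarray] = {}
    for pen_index in range(config.n_pens):
        pen_id = f"pen{pen_index + 1:02d}"
        rng = _pen_rng(config.seed, pen_index, stage=0)
        k = config.pigs_per_pen
        sexes = (
            ["barrow"] * (k // 2) + ["gilt"] * (k - k // 2)
            if config.sex_split
            else [("barrow", "gilt")[int(rng.integers(2))] for _ in range(k)]
        )
        for j in range(k):
            w0 = float(rng.normal(25.0, 2.5))
            gains = np.clip(rng.normal(6.9, 0.8, size=len(weeks) - 1), 0.5, None)
            traj = {weeks[0]: w0}
            for wk, g in zip(weeks[1:], gains):
                traj[wk] = traj[wk - 1] + float(g)
            pigs.append(
                Pig(
                    pig_id=f"{pen_id}_{j + 1}",
                    pen_id=pen_id,
                    treatment=labels[pen_index],
                    sex=sexes[j],
                    s_out=float(rng.normal(0.0, config.biter_heterogeneity)),
                    s_in=float(rng.normal(0.0, config.victim_heterogeneity)),
                    weights=traj,
                )
            )
        preference[pen_id] = _preference_matrix(
            config.preference_structure, config.kappa, k
        )
    return HerdDesign(pigs=tuple(pigs), preference=preference)


def _pair_lying(
    lying_idx: list[int], w: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Weighted random matching among lying pigs.

    Dyads race with exponential scores at rate w(a, b); winners are
    accepted greedily under a two-partner cap until a matching-sized
    budget of floor(n_lying / 2) pairs is reached.
    """
    m = len(lying_idx)
    budget = m // 2
    if budget == 0:
        return []
    dyads = [
        (a, b) for ii, a in enumerate(lying_idx) for b in lying_idx[ii + 1 :]
    ]
    weights = np.array([w[a, b] for a, b in dyads], dtype=float)
    raw = rng.exponential(size=len(dyads))
    scores = np.where(weights > 0, raw / np.maximum(weights, 1e-300), np.inf)
    order = np.argsort(scores, kind="stable")
    partners: dict[int, int] = {i: 0 for i in lying_idx}
    accepted: list[tuple[int, int]] = []
    for d in order:
        if not np.isfinite(scores[d]):
            break
        a, b = dyads[d]
        if partners[a] < 2 and partners[b] < 2:
            accepted.append((a, b))
            partners[a] += 1
            partners[b] += 1
            if len(accepted) >= budget:
                break
    return accepted


def simulate_lying_scans(herd: HerdDesign, config: SimConfig) -> list[ScanRecord]:
    """Scan-sampled lying observations for every pen and period."""
    records: list[ScanRecord] = []
    for pen_index, pen_id in enumerate(herd.pens()):
        nodes = herd.pen_roster(pen_id)
        w = herd.preference[pen_id]
        rng = _pen_rng(config.seed, pen_index, stage=1)
        for period in config.periods:
            for scan in range(1, config.scans_per_period + 1):
                lying = rng.random(len(nodes)) < config.p_lie
                lying_idx = [i for i in range(len(nodes)) if lying[i]]
                pairs = _pair_lying(lying_idx, w, rng)
                partner_sets: dict[int, set[str]] = {i: set() for i in range(len(nodes))}
                for a, b in pairs:
                    partner_sets[a].add(nodes[b])
                    partner_sets[b].add(nodes[a])
                for i, pig in enumerate(nodes):
                    records.append(
                        ScanRecord(
                            pen_id=pen_id,
                            period=period,
                            scan_index=scan,
                            pig_id=pig,
                            lying=int(lying[i]),
                            partners=frozenset(partner_sets[i]),
                        )
                    )
    return records


def simulate_bite_events(herd: HerdDesign, config: SimConfig) -> list[BiteEvent]:
    """Poisson directed bite events per dyad and period, timestamped."""
    events: list[BiteEvent] = []
    for pen_index, pen_id in enumerate(herd.pens()):
        nodes = herd.pen_roster(pen_id)
        pigs = {p.pig_id: p for p in herd.pigs if p.pen_id == pen_id}
        rng = _pen_rng(config.seed, pen_index, stage=2)
        for period in config.periods:
            pen_period_events = []
            for biter in nodes:
                for recipient in nodes:
                    if biter == recipient:
                        continue
                    lam = config.bite_rate_base * float(
                        np.exp(pigs[biter].s_out + pigs[recipient].s_in)
                    )
                    count = int(rng.poisson(lam))
                    for _ in range(count):
                        pen_period_events.append(
                            BiteEvent(
                                pen_id=pen_id,
                                period=period,
                                timestamp_min=round(
                                    float(rng.uniform(0, OBSERVATION_MINUTES)), 2
                                ),
                                biter=biter,
                                recipient=recipient,
                            )
                        )
            events.extend(sorted(pen_period_events, key=lambda e: e.timestamp_min))
    return events


def _assessment_times(config: SimConfig) -> list[float]:
    """Assessment ages in weeks, ``assessments_per_week`` per week."""
    step = 1.0 / config.assessments_per_week
    n = config.study_weeks * config.assessments_per_week
    return [config.study_start_week + step * (k + 1) for k in range(n)]


def simulate_tail_scores(
    herd: HerdDesign, events: Sequence[BiteEvent], config: SimConfig
) -> list[TailScoreRecord]:
    """Injury-score trajectories driven by bites received.

    Scores follow the 0-4 scale: escalation in windows with bites,
    healing at scores 1-2 in bite-free windows, never negative, capped
    at 4.
    """
    times = _assessment_times(config)
    bite_week: dict[str, list[float]] = {}
    for e in events:
        bite_week.setdefault(e.recipient, []).append(
            e.period + e.timestamp_min / MINUTES_PER_WEEK
        )
    records: list[TailScoreRecord] = []
    for pen_index, pen_id in enumerate(herd.pens()):
        rng = _pen_rng(config.seed, pen_index, stage=3)
        for pig in herd.pen_roster(pen_id):
            weeks = sorted(bite_week.get(pig, []))
            score = 0
            prev_t = float(config.study_start_week)
            for idx, t in enumerate(times):
                bites = sum(1 for bw in weeks if prev_t < bw <= t)
                u = rng.random()  # one draw per window keeps streams aligned
                if bites > 0:
                    if u < 1.0 - (1.0 - config.injury_gain) ** bites:
                        score = min(score + 1, 4)
                elif score in (1, 2):
                    if u < config.heal_prob:
                        score -= 1
                records.append(
                    TailScoreRecord(pig_id=pig, assessment_index=idx + 1, score=score)
                )
                prev_t = t
    return records


@dataclass(frozen=True)
class SimulatedData:
    config: SimConfig
    herd: HerdDesign
    scans: tuple[ScanRecord, ...]
    events: tuple[BiteEvent, ...]
    scores: tuple[TailScoreRecord, ...]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "roster": outdir / "roster.csv",
            "scans": outdir / "scans.csv",
            "bites": outdir / "bites.csv",
            "tail_scores": outdir / "tail_scores.csv",
        }
        self.herd.roster_frame().to_csv(paths["roster"], index=False)
        write_scans(self.scans, paths["scans"])
        write_bites(self.events, paths["bites"])
        write_tail_scores(self.scores, paths["tail_scores"])
        return paths


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Run all four generator stages under one config."""
    herd = simulate_herd(config)
    scans = simulate_lying_scans(herd, config)
    events = simulate_bite_events(herd, config)
    scores = simulate_tail_scores(herd, events, config)
    return SimulatedData(
        config=config,
        herd=herd,
        scans=tuple(scans),
        events=tuple(events),
        scores=tuple(scores),
    )
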