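"""Synthetic supervisory-session generator.

Emulates a monitoring task on a four-section building-automation display:
each section (AOI) shows a fan-speed indicator that can briefly overload,
and the operator must press the section's key while the overload is on
screen. The simulator produces, for a cohort of participants,

* a gaze record — a renewal process of fixations in which each new
  fixation lands in AOI ``i`` with probability equal to the proposed
  model's predicted attention share ``A_i`` (optionally with a sticky
  Markov self-transition for more realistic scanpaths), with lognormal
  fixation durations and uniform positions inside the AOI rectangle;
* an overload/keypress log — per-AOI Poisson overload events, each lasting
  one second, answered correctly iff a fixation in that AOI overlaps the
  event window (minus a lapse probability emulating misses while gazing);
* per-participant scores — each correct response earns that AOI's
  importance degree in points.

Everything is driven by a single integer seed and is byte-reproducible,
so the full analysis pipeline (fixation shares, keypress ratios, model
comparison, profile recovery) can be exercised with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import (
    AOI,
    AttentionVector,
    FIXATION_COLUMNS,
    KEYPRESS_COLUMNS,
    FixationTable,
    KeypressLog,
    fixation_attention,
)
from .model import Model, allocate, invert_allocation
from .profile import ValueProfile

__all__ = ["SessionConfig", "SessionOutput", "default_aois", "simulate_session",
           "recover_allocation", "score_session"]

SCREEN = (1680, 1050)  # px, the 22-inch display the task runs on


def default_aois(profile: ValueProfile, screen: tuple[int, int] = SCREEN) -> list[AOI]:
    """Tile the screen into equal-width columns (or a 2x2 grid for four
    sections), one AOI per profile section, in profile order."""
    w, hgt = screen
    n = len(profile)
    if n == 4:
        half_w, half_h = w / 2, hgt / 2
        cells = [(0, 0), (half_w, 0), (0, half_h), (half_w, half_h)]
        return [
            AOI(lab, cx, cy, cx + half_w, cy + half_h)
            for lab, (cx, cy) in zip(profile.labels, cells)
        ]
    step = w / n
    return [AOI(lab, i * step, 0, (i + 1) * step, hgt) for i, lab in enumerate(profile.labels)]


@dataclass(frozen=True)
class SessionConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the reference monitoring experiment: four AOIs with
    importance degrees 0.1/0.3/0.7/0.9, 14 participants, 300-second
    sessions, 1-second overloads at 2 events/min per AOI, and
    conventional eye-movement parameters (lognormal fixation durations of
    mean 250 ms / sd 100 ms with an 80 ms saccade gap, about three
    fixations per second).
    """

    profile: ValueProfile
    aois: tuple[AOI, ...] | None = None
    participants: int = 14
    duration_s: float = 300.0
    overload_rate_per_min: float = 2.0
    overload_duration_ms: float = 1000.0
    fixation_duration_mean_ms: float = 250.0
    fixation_duration_sd_ms: float = 100.0
    saccade_gap_ms: float = 80.0
    lapse_probability: float = 0.05
    stickiness: float = 0.0  # extra self-transition weight in [0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.participants < 1:
            raise ValueError("need at least one participant")
        if self.overload_rate_per_min < 0 or self.overload_duration_ms <= 0:
            raise ValueError("overload rate must be >= 0 and duration positive")
        if self.fixation_duration_mean_ms <= 0 or self.fixation_duration_sd_ms < 0:
            raise ValueError("fixation duration parameters must be positive")
        if not (0.0 <= self.lapse_probability < 1.0):
            raise ValueError("lapse probability must lie in [0, 1)")
        if not (0.0 <= self.stickiness < 1.0):
            raise ValueError("stickiness must lie in [0, 1)")
        aois = self.aois if self.aois is not None else tuple(default_aois(self.profile))
        aois = tuple(aois)
        if tuple(a.label for a in aois) != self.profile.labels:
            raise ValueError("AOI labels must match the profile sections in order")
        for i, a in enumerate(aois):
            for b in aois[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"AOIs {a.label!r} and {b.label!r} overlap")
        object.__setattr__(self, "aois", aois)

    def with_seed(self, seed: int) -> "SessionConfig":
        return replace(self, seed=int(seed))


@dataclass
class SessionOutput:
    """One simulated cohort: gaze, keypresses, scores, and ground truth."""

    config: SessionConfig
    fixations: FixationTable
    keypresses: KeypressLog
    scores: dict[str, float]
    true_allocation: np.ndarray

    def write(self, out_dir) -> None:
        """Write fix.csv, keys.csv and truth.json into a directory."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fixations.to_csv(out / "fix.csv")
        self.keypresses.to_csv(out / "keys.csv")
        truth = {
            "labels": list(self.config.profile.labels),
            "V": self.config.profile.V.tolist(),
            "A_proposed": self.true_allocation.tolist(),
            "scores": self.scores,
            "seed": self.config.seed,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _simulate_gaze(
    rng: np.random.Generator, cfg: SessionConfig, A: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One participant's fixation stream: (aoi index, onset, duration, x, y)."""
    total_ms = cfg.duration_s * 1000.0
    mu, sigma = _lognormal_params(cfg.fixation_duration_mean_ms, cfg.fixation_duration_sd_ms)
    n_est = int(total_ms / (cfg.fixation_duration_mean_ms + cfg.saccade_gap_ms) * 1.5) + 16
    onsets, aoi_idx, durations = [], [], []
    t = 0.0
    prev = None
    n_aoi = len(A)
    while t < total_ms:
        if prev is None or cfg.stickiness == 0.0:
            probs = A
        else:
            # sticky renewal: mix the stationary shares with a self-return
            probs = (1.0 - cfg.stickiness) * A
            probs = probs.copy()
            probs[prev] += cfg.stickiness
        i = int(rng.choice(n_aoi, p=probs))
        d = float(rng.lognormal(mu, sigma)) if sigma > 0 else cfg.fixation_duration_mean_ms
        onsets.append(t)
        aoi_idx.append(i)
        durations.append(d)
        prev = i
        t += d + cfg.saccade_gap_ms
        if len(onsets) > 100 * n_est:  # safety against degenerate configs
            raise RuntimeError("fixation stream failed to terminate")
    aoi_idx = np.asarray(aoi_idx, dtype=int)
    onsets = np.asarray(onsets)
    durations = np.asarray(durations)
    xs = np.empty_like(onsets)
    ys = np.empty_like(onsets)
    for j, a in enumerate(cfg.aois):
        m = aoi_idx == j
        xs[m] = rng.uniform(a.x0, a.x1, m.sum())
        ys[m] = rng.uniform(a.y0, a.y1, m.sum())
    return aoi_idx, onsets, durations, xs, ys


def simulate_session(config: SessionConfig) -> SessionOutput:
    """Simulate a full cohort under the proposed-model gaze policy.

    Deterministic under a fixed seed: per-participant generators are
    spawned from one seed sequence, so adding participants does not
    perturb earlier ones.
    """
    cfg = config
    truth = allocate(cfg.profile, Model.PROPOSED)
    A = truth.A
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.spawn(cfg.participants)
    total_ms = cfg.duration_s * 1000.0

    fix_rows: list[pd.DataFrame] = []
    key_rows: list[pd.DataFrame] = []
    scores: dict[str, float] = {}
    width = len(str(cfg.participants))
    for p_idx in range(cfg.participants):
        rng = np.random.default_rng(child_seeds[p_idx])
        pid = f"p{p_idx + 1:0{width}d}"
        aoi_idx, onsets, durations, xs, ys = _simulate_gaze(rng, cfg, A)
        fix_rows.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "start_ms": onsets,
                    "duration_ms": durations,
                    "x": xs,
                    "y": ys,
                }
            )
        )
        score = 0.0
        events = []
        rate_ms = cfg.overload_rate_per_min / 60000.0
        for j, aoi in enumerate(cfg.aois):
            if rate_ms <= 0:
                continue
            t = rng.exponential(1.0 / rate_ms)
            while t < total_ms:
                window_end = t + cfg.overload_duration_ms
                in_aoi = aoi_idx == j
                overlap = in_aoi & (onsets < window_end) & (onsets + durations > t)
                gazed = bool(overlap.any())
                correct = gazed and (rng.random() >= cfg.lapse_probability)
                events.append((pid, t, aoi.label, correct, correct))
                if correct:
                    score += float(cfg.profile.V[j])
                t += rng.exponential(1.0 / rate_ms)
        scores[pid] = score
        if events:
            key_rows.append(pd.DataFrame(events, columns=KEYPRESS_COLUMNS))

    fixations = FixationTable(
        pd.concat(fix_rows, ignore_index=True).sort_values(
            ["participant", "start_ms"], kind="stable", ignore_index=True
        ),
        screen=SCREEN,
    )
    keys = (
        pd.concat(key_rows, ignore_index=True).sort_values(
            ["participant", "time_ms"], kind="stable", ignore_index=True
        )
        if key_rows
        else pd.DataFrame(columns=KEYPRESS_COLUMNS)
    )
    # columns were built as (pid, t, label, responded, correct) with
    # responded == correct: a miss is never a keypress in this detection rule
    return SessionOutput(
        config=cfg,
        fixations=fixations,
        keypresses=KeypressLog(keys),
        scores=scores,
        true_allocation=A.copy(),
    )


def score_session(output: SessionOutput) -> dict[str, float]:
    """Points per participant: the sum of AOI importance degrees over
    correct responses (a correct response at the 0.9 section earns 0.9).

    Attending high-importance sections more is the score-maximizing gaze
    policy at a fixed fixation budget; the simulator documents this
    property but does not optimize for it.
    """
    v_by_label = dict(zip(output.config.profile.labels, output.config.profile.V))
    df = output.keypresses.data
    if df.empty:
        return {pid: 0.0 for pid in output.scores}
    correct = df[df["correct"].astype(bool)]
    recomputed = correct.groupby("participant")["aoi"].agg(
        lambda aois: float(sum(v_by_label[a] for a in aois))
    )
    return {pid: float(recomputed.get(pid, 0.0)) for pid in output.scores}


def recover_allocation(
    output: SessionOutput,
) -> tuple[AttentionVector, ValueProfile]:
    """Close the loop: estimate attention shares from the simulated gaze,
    then invert the proposed model back to importance degrees.

    The inversion is anchored at the section with the largest true ``V``
    (the anchor supplies the scale the allocation alone cannot determine).
    """
    cfg = output.config
    empirical = fixation_attention(output.fixations, list(cfg.aois))
    k = int(np.argmax(cfg.profile.V))
    recovered = invert_allocation(
        empirical.fractions,
        anchor=(k, float(cfg.profile.V[k])),
        labels=cfg.profile.labels,
    )
    return empirical, recovered
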