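"""Synthetic RR-interval streams with known beat- and record-level truth.

The generators emulate the statistical structure that makes rhythm classes
separable on a Lorenz (Poincaré) scattergram:

* **Sinus rhythm** — RR modulated by respiratory sinus arrhythmia (a slow
  sinusoid) plus small Gaussian jitter, giving high lag-1 autocorrelation
  and a tight attractor on the identity diagonal.
* **Persistent AF** — "irregularly irregular": RR drawn i.i.d. log-normal
  with a sizeable coefficient of variation, serially uncorrelated, giving
  the diffuse fan attractor.
* **Paroxysmal AF** — an alternating-renewal (two-state semi-Markov)
  process with exponential dwell times switching between the two regimes.
* **Ectopy** — premature beats with compensatory pauses overlaid on any
  stream, producing the characteristic off-diagonal lobes without being AF.

Every generator is a pure function of ``(cfg, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .records import BeatClass, RecordClass, RRRecord

__all__ = [
    "SimulationConfig",
    "simulate_sinus",
    "simulate_af",
    "simulate_paroxysmal",
    "inject_ectopy",
    "simulate_cohort",
]

RR_MIN_S = 0.3
RR_MAX_S = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Defaults describe a resting adult: mean RR 0.8 s (75 bpm), respiratory
    modulation of ±0.05 s at 0.2 Hz (12 breaths/min), 0.02 s beat-to-beat
    jitter; AF coefficient of variation 0.24; paroxysmal episodes with
    5-minute mean dwell in each state; 2 premature beats/min shifted 40%
    early.  RR is clipped to [0.3, 2.0] s (the rasterizer's axis range).
    """

    duration_s: float = 3600.0
    mean_rr_s: float = 0.8
    sinus_sd_s: float = 0.02
    resp_freq_hz: float = 0.2
    resp_amp_s: float = 0.05
    af_cv: float = 0.24
    episode_mean_af_s: float = 300.0
    episode_mean_sinus_s: float = 300.0
    pvc_rate_per_min: float = 2.0
    prematurity_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if not (0.3 <= self.mean_rr_s <= 2.0):
            raise ValueError("mean_rr_s must lie in [0.3, 2.0] s")
        for name in ("sinus_sd_s", "resp_amp_s", "af_cv", "episode_mean_af_s",
                     "episode_mean_sinus_s", "pvc_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.prematurity_fraction < 1.0):
            raise ValueError("prematurity_fraction must lie in (0, 1)")


def _clip_rr(rr: float) -> float:
    return float(min(max(rr, RR_MIN_S), RR_MAX_S))


def _sinus_rr(t: float, cfg: SimulationConfig, rng: np.random.Generator) -> float:
    rr = cfg.mean_rr_s + cfg.resp_amp_s * np.sin(2.0 * np.pi * cfg.resp_freq_hz * t)
    if cfg.sinus_sd_s > 0:
        rr += rng.normal(0.0, cfg.sinus_sd_s)
    return _clip_rr(rr)


def _af_lognormal_params(cfg: SimulationConfig) -> tuple[float, float]:
    # mean m, CV c  ->  sigma^2 = ln(1+c^2), mu = ln m - sigma^2/2
    sigma2 = np.log1p(cfg.af_cv ** 2)
    mu = np.log(cfg.mean_rr_s) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _af_rr(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    if cfg.af_cv == 0:
        return _clip_rr(cfg.mean_rr_s)
    mu, sigma = _af_lognormal_params(cfg)
    return _clip_rr(float(rng.lognormal(mu, sigma)))


def simulate_sinus(cfg: SimulationConfig, seed: Optional[int] = None,
                   record_id: str = "sinus") -> RRRecord:
    """Sinus-rhythm record: respiratory sinusoid + Gaussian jitter."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    times = [0.0]
    while times[-1] < cfg.duration_s:
        times.append(times[-1] + _sinus_rr(times[-1], cfg, rng))
    times = np.asarray(times[:-1]) if times[-1] > cfg.duration_s else np.asarray(times)
    n = len(times)
    return RRRecord(
        record_id=record_id,
        beat_times=times,
        beat_labels=[BeatClass.NON_AF] * n,
        record_truth=RecordClass.NON_AF,
        episodes=[(0.0, float(times[-1]), BeatClass.NON_AF)],
    )


def simulate_af(cfg: SimulationConfig, seed: Optional[int] = None,
                record_id: str = "af") -> RRRecord:
    """Persistent-AF record: i.i.d. log-normal RR, serially uncorrelated."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    times = [0.0]
    while times[-1] < cfg.duration_s:
        times.append(times[-1] + _af_rr(cfg, rng))
    times = np.asarray(times[:-1]) if times[-1] > cfg.duration_s else np.asarray(times)
    n = len(times)
    return RRRecord(
        record_id=record_id,
        beat_times=times,
        beat_labels=[BeatClass.AF] * n,
        record_truth=RecordClass.PERSISTENT_AF,
        episodes=[(0.0, float(times[-1]), BeatClass.AF)],
    )


def simulate_paroxysmal(cfg: SimulationConfig, seed: Optional[int] = None,
                        record_id: str = "paroxysmal") -> RRRecord:
    """Paroxysmal-AF record: alternating exponential AF/sinus episodes.

    Episode boundaries are kept on the returned record (``episodes``) for
    audit; beat labels follow the state active at the beat's time.
    """
    if cfg.episode_mean_sinus_s <= 0 and cfg.episode_mean_af_s <= 0:
        raise ValueError("at least one episode mean must be positive")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    episodes: list[tuple[float, float, BeatClass]] = []
    t_edge = 0.0
    state = BeatClass.NON_AF if rng.random() < 0.5 else BeatClass.AF
    while t_edge < cfg.duration_s:
        mean = cfg.episode_mean_af_s if state is BeatClass.AF else cfg.episode_mean_sinus_s
        if mean <= 0:
            state = BeatClass.NON_AF if state is BeatClass.AF else BeatClass.AF
            continue
        dwell = float(rng.exponential(mean))
        end = min(t_edge + dwell, cfg.duration_s)
        episodes.append((t_edge, end, state))
        t_edge = end
        state = BeatClass.NON_AF if state is BeatClass.AF else BeatClass.AF

    times = [0.0]
    labels: list[BeatClass] = []
    ep_idx = 0

    def state_at(t: float) -> BeatClass:
        nonlocal ep_idx
        while ep_idx + 1 < len(episodes) and t >= episodes[ep_idx][1]:
            ep_idx += 1
        return episodes[ep_idx][2]

    labels.append(state_at(0.0))
    while times[-1] < cfg.duration_s:
        s = state_at(times[-1])
        rr = _af_rr(cfg, rng) if s is BeatClass.AF else _sinus_rr(times[-1], cfg, rng)
        t_next = times[-1] + rr
        if t_next > cfg.duration_s:
            break
        times.append(t_next)
        labels.append(state_at(t_next))
    return RRRecord(
        record_id=record_id,
        beat_times=np.asarray(times),
        beat_labels=labels,
        record_truth=RecordClass.PAROXYSMAL_AF,
        episodes=episodes,
    )


def inject_ectopy(record: RRRecord, pvc_rate_per_min: float,
                  prematurity_fraction: float, seed: int) -> RRRecord:
    """Overlay premature beats with compensatory pauses.

    At Poisson-sampled instants the nearest eligible beat is shifted early
    by ``prematurity_fraction`` of its preceding RR; the following RR is
    thereby extended, so the local two-beat interval sum is preserved.
    Beat labels keep the underlying rhythm class (ectopy is not AF).
    """
    if pvc_rate_per_min < 0:
        raise ValueError("pvc_rate_per_min must be >= 0")
    if not (0.0 < prematurity_fraction < 1.0):
        raise ValueError("prematurity_fraction must lie in (0, 1)")
    if len(record) < 3:
        raise ValueError("record must have >= 3 beats")
    if pvc_rate_per_min == 0:
        return record
    rng = np.random.default_rng(seed)
    duration = record.duration_s
    lam = pvc_rate_per_min * duration / 60.0
    n_events = int(rng.poisson(lam))
    times = record.beat_times.copy()
    if n_events:
        instants = np.sort(rng.uniform(record.beat_times[0], record.beat_times[-1], n_events))
        # earliest beat at/after each instant, constrained to interior beats
        ks = np.searchsorted(record.beat_times, instants, side="left")
        ks = np.unique(np.clip(ks, 1, len(record) - 2))
        for k in ks:
            rr_prev = times[k] - times[k - 1]
            times[k] = times[k] - prematurity_fraction * rr_prev
    return RRRecord(
        record_id=record.record_id,
        beat_times=times,
        beat_labels=list(record.beat_labels),
        source_codes=list(record.source_codes) if record.source_codes else None,
        record_truth=record.record_truth,
        episodes=record.episodes,
    )


def simulate_cohort(n_per_class: int, cfg: SimulationConfig,
                    seed: Optional[int] = None) -> list[RRRecord]:
    """Simulate ``n_per_class`` records of each record-level class.

    Non-AF records are sinus rhythm with ectopy overlaid at the configured
    rate (so the classifier must not confuse premature beats with AF);
    paroxysmal and persistent records follow their generators.  Seeds for
    individual records are spawned deterministically from ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3 * n_per_class)]
    records: list[RRRecord] = []
    k = 0
    for i in range(n_per_class):
        s = child_seeds[k]; k += 1
        rec = simulate_sinus(cfg, seed=s, record_id=f"sinus_{i:03d}")
        if cfg.pvc_rate_per_min > 0:
            rec = inject_ectopy(rec, cfg.pvc_rate_per_min, cfg.prematurity_fraction, seed=s + 1)
        records.append(rec)
    for i in range(n_per_class):
        records.append(simulate_paroxysmal(cfg, seed=child_seeds[k], record_id=f"parox_{i:03d}"))
        k += 1
    for i in range(n_per_class):
        records.append(simulate_af(cfg, seed=child_seeds[k], record_id=f"persist_{i:03d}"))
        k += 1
    return records
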