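"""Synthetic courtship sessions and climbing trials.

The generator emulates the summary statistics of the standard two-group
design — 28 wild-type (control) couples and 28 alpha-synuclein A30P
couples observed for up to 600 s or until copulation — without modeling
courtship dynamics.  Per couple:

* copulation ~ Bernoulli(p_copulate); copulating couples end early at a
  Uniform(300 s, cap) latency, others run to the cap;
* orientation and wing-vibration time fractions ~ Beta distributions with
  the configured group means and a shared concentration (mean * c,
  (1 - mean) * c shape parameters); bouts of 2-20 s are laid out
  non-overlapping within each element to realize the drawn totals;
* licking and attempted-copulation counts ~ Poisson with mean
  norm_mean * total_time / 100, so their count * 100 / total-time
  normalization recovers the configured group norm on average;
* non-sexual encounters ~ Poisson(nse_mean), instantaneous events.

All times are generated on the centisecond grid, so written CSVs
round-trip exactly.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climbing import ClimbingTrial
from .ethogram import CourtshipSession, Element, EventRecord

__all__ = [
    "GroupParams",
    "GeneratorConfig",
    "CONTROL_DEFAULTS",
    "A30P_DEFAULTS",
    "generate_sessions",
    "generate_climbing",
]


@dataclass(frozen=True)
class GroupParams:
    """Target summary statistics for one genotype group.

    ``orientation_frac_mean`` / ``vibration_frac_mean`` are mean fractions
    of session time; ``licking_norm_mean`` / ``atc_norm_mean`` are mean
    count * 100 / total-time normalizations; ``nse_mean`` is the raw mean
    encounter count (not time-normalized); ``p_copulate`` is the
    per-couple copulation probability.
    """

    orientation_frac_mean: float
    vibration_frac_mean: float
    licking_norm_mean: float
    atc_norm_mean: float
    p_copulate: float
    nse_mean: float

    def __post_init__(self) -> None:
        for name in ("orientation_frac_mean", "vibration_frac_mean"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0 <= self.p_copulate <= 1:
            raise ValueError(f"p_copulate outside [0, 1]: {self.p_copulate}")
        for name in ("licking_norm_mean", "atc_norm_mean", "nse_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Wild-type Oregon-R group targets: 56.6% orientation time, 21.5%
#: vibration time, licking/ATC norms 3.4 and 0.4, 11 of 28 couples
#: copulating, mean NSE 21.
CONTROL_DEFAULTS = GroupParams(
    orientation_frac_mean=0.566,
    vibration_frac_mean=0.215,
    licking_norm_mean=3.4,
    atc_norm_mean=0.4,
    p_copulate=11 / 28,
    nse_mean=21.0,
)

#: A30P alpha-synuclein group targets: 41.3% orientation, 17.2% vibration,
#: licking/ATC at 59% and 50.7% of the control norms, 8 of 28 couples
#: copulating, mean NSE 33.
A30P_DEFAULTS = GroupParams(
    orientation_frac_mean=0.413,
    vibration_frac_mean=0.172,
    licking_norm_mean=3.4 * 0.59,
    atc_norm_mean=0.4 * 0.507,
    p_copulate=8 / 28,
    nse_mean=33.0,
)


def _default_groups() -> dict[str, GroupParams]:
    return {"control": CONTROL_DEFAULTS, "a30p": A30P_DEFAULTS}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the session generator.

    ``concentration`` is the Beta concentration (a + b) shared by the
    orientation and vibration fraction draws; the published group means
    come with no dispersion information, so it is a free default chosen to
    give realistic between-couple spread (sd ~ 0.07 at a mean of 0.5).
    """

    n_per_group: int = 28
    seed: int = 0
    observation_cap_s: float = 600.0
    concentration: float = 50.0
    #: Lower bound of the uniform copulation latency; ``None`` means half
    #: the observation cap (300 s in the standard 600 s design).
    min_copulation_latency_s: float | None = None
    groups: dict[str, GroupParams] = field(default_factory=_default_groups)

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.observation_cap_s <= 0:
            raise ValueError("observation_cap_s must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.min_copulation_latency_s is not None and not (
            0 < self.min_copulation_latency_s < self.observation_cap_s
        ):
            raise ValueError(
                "min_copulation_latency_s must lie in (0, observation_cap_s)"
            )
        if not self.groups:
            raise ValueError("at least one genotype group is required")

    @property
    def copulation_latency_low_s(self) -> float:
        if self.min_copulation_latency_s is None:
            return self.observation_cap_s / 2.0
        return self.min_copulation_latency_s


def _place_bouts(
    rng: np.random.Generator, total_cs: int, durations_cs: list[int]
) -> list[tuple[int, int]]:
    """Place bouts of the given centisecond durations without overlap,
    separating them by multinomially split random gaps."""
    if not durations_cs:
        return []
    free = total_cs - int(sum(durations_cs))
    m = len(durations_cs)
    gaps = rng.multinomial(free, np.full(m + 1, 1.0 / (m + 1)))
    bouts = []
    t = 0
    for gap, dur in zip(gaps, durations_cs):
        t += int(gap)
        bouts.append((t, t + dur))
        t += dur
    return bouts


def _duration_bouts(
    rng: np.random.Generator,
    total_cs: int,
    target_cs: int,
    min_cs: int = 200,
    max_cs: int = 2000,
) -> list[tuple[int, int]]:
    """Bouts of 2-20 s whose durations sum exactly to ``target_cs``."""
    if target_cs <= 0:
        return []
    durations: list[int] = []
    remaining = target_cs
    while remaining > 0:
        d = int(rng.integers(min_cs, max_cs + 1))
        d = min(d, remaining)  # final bout may be shorter than 2 s
        durations.append(d)
        remaining -= d
    return _place_bouts(rng, total_cs, durations)


def _count_bouts(
    rng: np.random.Generator,
    total_cs: int,
    count: int,
    min_cs: int,
    max_cs: int,
) -> list[tuple[int, int]]:
    """``count`` short bouts fitted into the session without overlap."""
    if count <= 0:
        return []
    count = min(count, total_cs)  # degenerate configs: one cs per bout
    durations = rng.integers(min_cs, max_cs + 1, size=count)
    while durations.sum() > total_cs:
        durations = np.maximum(durations // 2, 1)
        if durations.max() == 1:
            break
    return _place_bouts(rng, total_cs, [int(d) for d in durations])


def _session(
    rng: np.random.Generator,
    couple_id: str,
    genotype: str,
    params: GroupParams,
    cfg: GeneratorConfig,
) -> CourtshipSession:
    cap_cs = round(cfg.observation_cap_s * 100)
    copulated = rng.random() < params.p_copulate
    if copulated:
        total_cs = int(
            rng.integers(round(cfg.copulation_latency_low_s * 100), cap_cs + 1)
        )
    else:
        total_cs = cap_cs
    total_s = total_cs / 100.0

    c = cfg.concentration
    events: list[EventRecord] = []
    for element, mean in (
        (Element.ORIENTATION, params.orientation_frac_mean),
        (Element.VIBRATION, params.vibration_frac_mean),
    ):
        frac = rng.beta(mean * c, (1.0 - mean) * c)
        target_cs = round(frac * total_cs)
        for s, e in _duration_bouts(rng, total_cs, target_cs):
            events.append(EventRecord(element, s / 100.0, e / 100.0))

    for element, norm_mean, lo, hi in (
        (Element.LICKING, params.licking_norm_mean, 30, 100),
        (Element.ATTEMPTED_COPULATION, params.atc_norm_mean, 50, 200),
    ):
        count = int(rng.poisson(norm_mean * total_s / 100.0))
        for s, e in _count_bouts(rng, total_cs, count, lo, hi):
            events.append(EventRecord(element, s / 100.0, e / 100.0))

    n_nse = int(rng.poisson(params.nse_mean))
    nse_times = np.sort(rng.integers(0, total_cs + 1, size=n_nse))
    for t in nse_times:
        events.append(EventRecord(Element.NSE, t / 100.0, t / 100.0))

    if copulated:
        events.append(EventRecord(Element.COPULATION, total_s, total_s))

    events.sort(key=lambda e: (e.start_s, e.end_s, e.element.value))
    return CourtshipSession(
        couple_id=couple_id,
        genotype=genotype,
        events=events,
        observation_cap_s=cfg.observation_cap_s,
    )


def generate_sessions(cfg: GeneratorConfig | None = None) -> list[CourtshipSession]:
    """Generate one synthetic cohort; bit-reproducible from ``cfg.seed``.

    Sessions are returned sorted by couple id and each passes full
    ethogram validation.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_per_group - 1)))
    sessions: list[CourtshipSession] = []
    for genotype in sorted(cfg.groups):
        params = cfg.groups[genotype]
        for i in range(cfg.n_per_group):
            sessions.append(
                _session(rng, f"{genotype}-{i:0{width}d}", genotype, params, cfg)
            )
    sessions.sort(key=lambda s: s.couple_id)
    return sessions


def generate_climbing(
    p_ctrl: float,
    p_pd: float,
    n_vials: int = 5,
    flies_per_vial: int = 10,
    seed: int = 0,
    age_days: int | None = None,
) -> list[ClimbingTrial]:
    """Binomial climbing trials for a control and an a30p group."""
    for name, p in (("p_ctrl", p_ctrl), ("p_pd", p_pd)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} outside [0, 1]: {p}")
    rng = np.random.default_rng(seed)
    trials: list[ClimbingTrial] = []
    for genotype, p in (("control", p_ctrl), ("a30p", p_pd)):
        passed = rng.binomial(flies_per_vial, p, size=n_vials)
        for i, n_passed in enumerate(passed):
            trials.append(
                ClimbingTrial(
                    vial_id=f"{genotype}-v{i:03d}",
                    genotype=genotype,
                    n_flies=flies_per_vial,
                    n_passed=int(n_passed),
                    age_days=age_days,
                )
            )
    return trials
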