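"""Synthetic subjects for the adjusting-energy (AE) schedule.

An agent supplies three behavioral primitives to the schedule engine:

* a **choice rule** between the AE and fixed-ratio (FR) alternatives,
  by default a logistic function of the current AE requirement centered
  on the agent's indifference requirement ``a*``;
* **peck kinematics** — interresponse times drawn from a lognormal
  distribution and peck coordinates scattered on the circular response
  surface — which for the stationary agent are independent of the AE
  requirement (the empirical pattern the schedule only weakly perturbs:
  mean IRE flat across requirements);
* a fixed **choice latency** so that simulated sessions consume clock
  time and the session time cap is meaningful.

Deterministic agents (:class:`AlwaysAEAgent`, :class:`AlwaysFRAgent`,
:class:`AlternatingAgent`) exercise the titration mechanics in tests; the
:class:`AdaptiveAgent` conditions its kinematics on the requirement to
probe how the schedule behaves when subjects do track the requirement.

Default kinematics (IRT ~ lognormal(ln 0.35 s, 0.4), pecks uniform in the
22-cm response circle) are a calibration chosen so typical IRE values
fall in the 0.01–0.2 J band that titrated requirements occupy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .errors import InvalidArgumentError
from .geometry import ChamberGeometry, PeckEvent

__all__ = [
    "AgentParams",
    "PeckPair",
    "Agent",
    "LogisticAgent",
    "AlwaysAEAgent",
    "AlwaysFRAgent",
    "AlternatingAgent",
    "AdaptiveAgent",
    "success_probability",
    "make_agent",
    "AGENT_PRESETS",
]

#: Default indifference requirement (J) per FR requirement.  Chosen
#: monotone in the ratio requirement — larger ratios are worth more
#: energy — as a calibration; scaled so titrated requirements sit in the
#: 0.01–0.1 J band.
DEFAULT_INDIFFERENCE_BY_FR = {15: 0.02, 30: 0.04, 60: 0.08}


@dataclass(frozen=True)
class AgentParams:
    """Parameters of a synthetic subject.

    Attributes
    ----------
    indifference_requirement : float
        ``a*`` in joules: the AE requirement at which AE and FR are
        subjectively equal.  Used when ``indifference_by_fr`` has no
        entry for the current FR requirement.
    indifference_by_fr : dict[int, float] | None
        Optional map FR requirement -> ``a*``, monotone in the ratio by
        default.
    choice_temperature : float
        Logistic temperature tau (J); smaller is closer to a step rule.
    irt_meanlog, irt_sdlog : float
        Location/scale of the lognormal interresponse-time distribution
        (log-seconds / dimensionless).
    peck_scatter : {"uniform", "gaussian"}
        Peck-coordinate rule: uniform over the response circle, or an
        isotropic Gaussian (sd ``scatter_sigma`` meters) about the
        center, truncated to the circle.
    scatter_sigma : float
        Gaussian scatter sd in meters; ignored for uniform scatter.
    choice_latency : float
        Seconds from key onset to the choice peck (also the latency to
        the first schedule-phase peck).
    """

    indifference_requirement: float = 0.03
    indifference_by_fr: Optional[dict] = field(
        default_factory=lambda: dict(DEFAULT_INDIFFERENCE_BY_FR)
    )
    choice_temperature: float = 0.005
    irt_meanlog: float = math.log(0.35)
    irt_sdlog: float = 0.4
    peck_scatter: str = "uniform"
    scatter_sigma: float = 0.03
    choice_latency: float = 0.5

    def __post_init__(self) -> None:
        if self.choice_temperature <= 0:
            raise InvalidArgumentError("choice_temperature must be > 0")
        if self.irt_sdlog < 0:
            raise InvalidArgumentError("irt_sdlog must be >= 0")
        if self.indifference_requirement < 0:
            raise InvalidArgumentError("indifference_requirement must be >= 0")
        if self.peck_scatter not in ("uniform", "gaussian"):
            raise InvalidArgumentError(
                f"peck_scatter must be 'uniform' or 'gaussian', "
                f"got {self.peck_scatter!r}"
            )
        if self.scatter_sigma < 0:
            raise InvalidArgumentError("scatter_sigma must be >= 0")
        if self.choice_latency < 0:
            raise InvalidArgumentError("choice_latency must be >= 0")


@dataclass(frozen=True, slots=True)
class PeckPair:
    """Two consecutive pecks on the response surface."""

    first: PeckEvent
    second: PeckEvent

    def __post_init__(self) -> None:
        if self.second.t <= self.first.t:
            raise InvalidArgumentError("second peck must follow the first")


class Agent:
    """Base synthetic subject: logistic choice, stationary kinematics."""

    def __init__(
        self,
        params: AgentParams | None = None,
        geometry: ChamberGeometry | None = None,
    ) -> None:
        self.params = params if params is not None else AgentParams()
        self.geometry = geometry if geometry is not None else ChamberGeometry()

    # -- choice ---------------------------------------------------------

    def indifference_for(self, fr_requirement: int) -> float:
        """``a*`` for this FR requirement (map lookup, scalar fallback)."""
        by_fr = self.params.indifference_by_fr
        if by_fr is not None and fr_requirement in by_fr:
            return float(by_fr[fr_requirement])
        return self.params.indifference_requirement

    def choice_probability(self, fr_requirement: int, ae_requirement: float) -> float:
        """P(choose AE) = logistic((a* - a) / tau)."""
        a_star = self.indifference_for(fr_requirement)
        tau = self.params.choice_temperature
        return float(expit((a_star - ae_requirement) / tau))

    def choose(
        self, fr_requirement: int, ae_requirement: float, rng: np.random.Generator
    ) -> str:
        """Return ``"AE"`` or ``"FR"`` for one free-choice trial."""
        p = self.choice_probability(fr_requirement, ae_requirement)
        return "AE" if rng.random() < p else "FR"

    # -- kinematics -----------------------------------------------------

    def sample_irts(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n interresponse times (s), lognormal."""
        if self.params.irt_sdlog == 0:
            return np.full(n, math.exp(self.params.irt_meanlog))
        return rng.lognormal(self.params.irt_meanlog, self.params.irt_sdlog, size=n)

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n peck coordinates, shape (n, 2), inside the response circle."""
        radius = self.geometry.radius
        if self.params.peck_scatter == "uniform":
            r = radius * np.sqrt(rng.random(n))
            theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
            return np.column_stack((r * np.cos(theta), r * np.sin(theta)))
        # Gaussian about the center, truncated to the circle by rejection.
        sigma = self.params.scatter_sigma
        if sigma == 0:
            return np.zeros((n, 2))
        pts = rng.normal(0.0, sigma, size=(n, 2))
        bad = np.hypot(pts[:, 0], pts[:, 1]) > radius
        while bad.any():
            pts[bad] = rng.normal(0.0, sigma, size=(int(bad.sum()), 2))
            bad = np.hypot(pts[:, 0], pts[:, 1]) > radius
        return pts

    def generate_peck_pair(
        self,
        ae_requirement: float,
        rng: np.random.Generator,
        t_first: float,
    ) -> PeckPair:
        """One AE schedule-phase attempt: two pecks, the second one IRT later.

        The stationary agent ignores ``ae_requirement``: its kinematics do
        not depend on the current requirement.
        """
        irt = float(self.sample_irts(1, rng)[0])
        pts = self.sample_points(2, rng)
        first = PeckEvent(float(pts[0, 0]), float(pts[0, 1]), t_first)
        second = PeckEvent(float(pts[1, 0]), float(pts[1, 1]), t_first + irt)
        return PeckPair(first, second)

    def generate_fr_pecks(
        self, n: int, rng: np.random.Generator, t_first: float
    ) -> list[PeckEvent]:
        """n FR schedule-phase pecks separated by lognormal IRTs."""
        pts = self.sample_points(n, rng)
        gaps = self.sample_irts(n - 1, rng) if n > 1 else np.empty(0)
        times = t_first + np.concatenate(([0.0], np.cumsum(gaps)))
        return [
            PeckEvent(float(pts[i, 0]), float(pts[i, 1]), float(times[i]))
            for i in range(n)
        ]

    def sample_ire(
        self, n: int, rng: np.random.Generator, ae_requirement: float = 0.0
    ) -> np.ndarray:
        """n IRE draws under this agent's peck-pair rule (vectorized)."""
        irt = self.sample_irts(n, rng)
        p1 = self.sample_points(n, rng)
        p2 = self.sample_points(n, rng)
        ird = np.hypot(p2[:, 0] - p1[:, 0], p2[:, 1] - p1[:, 1])
        return ird**2 / irt**2

    def choice_latency(self, rng: np.random.Generator) -> float:
        return self.params.choice_latency


class LogisticAgent(Agent):
    """Stationary agent with the logistic choice rule (alias of the base)."""


class AlwaysAEAgent(Agent):
    """Deterministic agent that always chooses the AE key."""

    def choose(self, fr_requirement, ae_requirement, rng):
        return "AE"


class AlwaysFRAgent(Agent):
    """Deterministic agent that always chooses the FR key."""

    def choose(self, fr_requirement, ae_requirement, rng):
        return "FR"


class AlternatingAgent(Agent):
    """Deterministic agent alternating AE, FR, AE, ... on free choices.

    Every block's two free choices are mixed, so the titrated requirement
    never moves: a maximally, immediately stable subject.
    """

    def __init__(self, params=None, geometry=None):
        super().__init__(params, geometry)
        self._next_ae = True

    def choose(self, fr_requirement, ae_requirement, rng):
        choice = "AE" if self._next_ae else "FR"
        self._next_ae = not self._next_ae
        return choice


class AdaptiveAgent(Agent):
    """Agent whose peck separation tracks the current AE requirement.

    Instead of requirement-independent scatter, the second peck is placed
    at a distance aimed so the attempt's IRE lands near
    ``ire_gain * requirement + ire_base`` (multiplicative lognormal noise
    ``effort_noise_sdlog``), clipped to the response circle.  Used to
    probe the schedule when subjects do adjust their energy output.
    """

    def __init__(
        self,
        params: AgentParams | None = None,
        geometry: ChamberGeometry | None = None,
        ire_gain: float = 1.5,
        ire_base: float = 0.005,
        effort_noise_sdlog: float = 0.3,
    ) -> None:
        super().__init__(params, geometry)
        if ire_gain < 0 or ire_base < 0 or effort_noise_sdlog < 0:
            raise InvalidArgumentError("adaptive-agent parameters must be >= 0")
        self.ire_gain = ire_gain
        self.ire_base = ire_base
        self.effort_noise_sdlog = effort_noise_sdlog

    def _target_ird(
        self, ae_requirement: float, irt: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        target_ire = self.ire_gain * ae_requirement + self.ire_base
        noise = rng.lognormal(0.0, self.effort_noise_sdlog, size=irt.shape)
        ird = irt * np.sqrt(target_ire) * noise
        return np.minimum(ird, self.geometry.response_area_diameter)

    def generate_peck_pair(self, ae_requirement, rng, t_first):
        irt = self.sample_irts(1, rng)
        ird = float(self._target_ird(ae_requirement, irt, rng)[0])
        radius = self.geometry.radius
        # Place the pair symmetrically about the center along a random
        # direction so any ird <= diameter fits inside the circle.
        half = min(ird / 2.0, radius)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        dx, dy = half * math.cos(theta), half * math.sin(theta)
        first = PeckEvent(-dx, -dy, t_first)
        second = PeckEvent(dx, dy, t_first + float(irt[0]))
        return PeckPair(first, second)

    def sample_ire(self, n, rng, ae_requirement=0.0):
        irt = self.sample_irts(n, rng)
        ird = self._target_ird(ae_requirement, irt, rng)
        ird = np.minimum(ird, 2.0 * self.geometry.radius)
        return ird**2 / irt**2


def success_probability(
    agent: Agent,
    ae_requirement: float,
    n_mc: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo estimate of P(IRE > requirement) for one attempt.

    Reinforcement on the AE schedule is strict: an attempt exactly at the
    requirement fails, so the estimate counts strict exceedances.
    """
    if n_mc < 1:
        raise InvalidArgumentError("n_mc must be >= 1")
    ire = agent.sample_ire(n_mc, rng, ae_requirement)
    return float(np.mean(ire > ae_requirement))


def make_agent(
    preset: str,
    params: AgentParams | None = None,
    geometry: ChamberGeometry | None = None,
    **overrides,
) -> Agent:
    """Build a named agent preset.

    Presets: ``stationary`` (= ``logistic``), ``always-ae``, ``always-fr``,
    ``alternating`` (immediately stable), ``adaptive``.  Keyword overrides
    are applied to :class:`AgentParams`.
    """
    key = preset.lower().replace("_", "-")
    if key not in AGENT_PRESETS:
        raise InvalidArgumentError(
            f"unknown agent preset {preset!r}; options: {sorted(AGENT_PRESETS)}"
        )
    base = params if params is not None else AgentParams()
    if overrides:
        base = replace(base, **overrides)
    return AGENT_PRESETS[key](base, geometry)


AGENT_PRESETS = {
    "stationary": LogisticAgent,
    "logistic": LogisticAgent,
    "always-ae": AlwaysAEAgent,
    "always-fr": AlwaysFRAgent,
    "alternating": AlternatingAgent,
    "adaptive": AdaptiveAgent,
}
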