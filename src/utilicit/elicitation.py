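"""Rating-scale, standard-gamble and time-trade-off elicitation.

The standard gamble is run as an adaptive titration: the respondent chooses
between staying in the described state for sure and a hypothetical cure that
carries a risk *p* of immediate death. The risk is varied by bisection on
the bracketing interval until the respondent is indifferent (or the bracket
is narrower than the tolerance), and the utility is 1 − p at indifference.
The first proposed risk is 1 − UCrs, the complement of the respondent's own
rating-scale value, which shortens the titration. A respondent who refuses
any risk at the first question values the state at exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

from .catalog import HealthState, UCRecord

ANSWERS = ("accept", "reject", "indifferent", "refuse_any_risk")


class ElicitationError(ValueError):
    """Invalid elicitation input or protocol violation."""


class SessionStateError(RuntimeError):
    """Operation applied to a session in the wrong status."""


@dataclass
class ElicitationConfig:
    """Protocol parameters for a titration session.

    tolerance
        Bracket width (probability) at which titration stops; the default
        0.01 matches the one-point granularity of the 0–100 rating scale.
    max_steps
        Hard cap on gamble questions per state.
    rs_first
        Ask the rating-scale question first and seed the gamble from it.
    """

    tolerance: float = 0.01
    max_steps: int = 30
    rs_first: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.tolerance < 1.0):
            raise ElicitationError(f"tolerance must be in (0, 1), got {self.tolerance}")
        if self.max_steps < 1:
            raise ElicitationError(f"max_steps must be >= 1, got {self.max_steps}")


@dataclass
class SGSession:
    """Titration state machine for one state × respondent."""

    state_id: int
    p_current: float
    p_low: float = 0.0
    p_high: float = 1.0
    history: list[tuple[float, str]] = field(default_factory=list)
    status: str = "active"  # active | refused | converged
    tolerance: float = 0.01
    max_steps: int = 30
    indifferent_at: float | None = None

    @property
    def bracket_width(self) -> float:
        return self.p_high - self.p_low


def rs_elicit(response: float) -> float:
    """Normalize a 0–100 rating (0 = death, 100 = perfect health) to [0, 1]."""
    if not (0.0 <= response <= 100.0):
        raise ElicitationError(f"rating must lie in [0, 100], got {response}")
    return float(response) / 100.0


def tto_utility(t_full: float, t_healthy: float) -> float:
    """Time-trade-off utility: the fraction t2/t1 of remaining life (*t_full*)
    that an equally attractive, shorter life in full health (*t_healthy*)
    represents at indifference."""
    if t_full <= 0:
        raise ElicitationError(f"t_full must be > 0, got {t_full}")
    if not (0.0 <= t_healthy <= t_full):
        raise ElicitationError(f"t_healthy must lie in [0, t_full], got {t_healthy}")
    return float(t_healthy) / float(t_full)


def sg_start(rs_utility: float, config: ElicitationConfig | None = None, state_id: int = 0) -> SGSession:
    """Open a gamble session with first risk 1 − UCrs.

    A degenerate first risk of exactly 0 or 1 is clamped into
    [tolerance, 1 − tolerance] so the opening gamble is meaningful.
    """
    config = config or ElicitationConfig()
    if not (0.0 <= rs_utility <= 1.0):
        raise ElicitationError(f"rs_utility must lie in [0, 1], got {rs_utility}")
    p0 = min(max(1.0 - rs_utility, config.tolerance), 1.0 - config.tolerance)
    return SGSession(
        state_id=state_id,
        p_current=p0,
        tolerance=config.tolerance,
        max_steps=config.max_steps,
    )


def sg_step(session: SGSession, answer: str) -> SGSession:
    """Advance the titration with one answer; mutates and returns *session*.

    accept   → the respondent takes the gamble at the current risk, so the
               indifference risk is at least p_current (p_low rises);
    reject   → indifference risk below p_current (p_high falls);
    the next proposal is the midpoint of the updated bracket. Titration
    converges on an explicit "indifferent", when the bracket is no wider
    than the tolerance, or at max_steps. "refuse_any_risk" is only valid as
    the answer to the very first proposal and ends the session as refused.
    """
    if session.status != "active":
        raise SessionStateError(f"cannot step a session with status {session.status!r}")
    if answer not in ANSWERS:
        raise ElicitationError(f"answer must be one of {ANSWERS}, got {answer!r}")

    p = session.p_current
    session.history.append((p, answer))

    if answer == "refuse_any_risk":
        if len(session.history) > 1:
            raise ElicitationError("refuse_any_risk is only valid at the first gamble question")
        session.status = "refused"
        return session
    if answer == "indifferent":
        session.indifferent_at = p
        session.status = "converged"
        return session

    if answer == "accept":
        session.p_low = p
    else:  # reject
        session.p_high = p

    if session.bracket_width <= session.tolerance or len(session.history) >= session.max_steps:
        session.status = "converged"
    else:
        session.p_current = 0.5 * (session.p_low + session.p_high)
    return session


def sg_utility(session: SGSession) -> float:
    """Utility from a finished session: 1 for a refusal, else 1 − p*.

    p* is the risk at the explicit indifference answer if one was given,
    otherwise the midpoint of the final bracket.
    """
    if session.status == "refused":
        return 1.0
    if session.status == "converged":
        p_star = (
            session.indifferent_at
            if session.indifferent_at is not None
            else 0.5 * (session.p_low + session.p_high)
        )
        return 1.0 - p_star
    raise SessionStateError("sg_utility requires a refused or converged session")


class AnswerProvider(Protocol):
    """Anything that can answer the two interview questions for a state."""

    def rate(self, state: HealthState) -> float:
        """Rating on the 0–100 scale for *state*."""

    def gamble(self, state: HealthState, p: float, first: bool) -> str:
        """Answer to the gamble at risk *p* (one of ``ANSWERS``)."""


@dataclass
class InterviewResult:
    """Records from one interview; ``error`` is set on a mid-interview failure."""

    records: list[UCRecord]
    error: str | None = None

    def __len__(self) -> int:
        return len(self.records)


def run_interview(
    provider: AnswerProvider,
    states: list[HealthState],
    config: ElicitationConfig | None = None,
    respondent_id: str = "anonymous",
) -> InterviewResult:
    """Administer the RS question then the SG titration for every state.

    Returns exactly two records per completed state (one RS, one SG); the
    gamble is seeded from that state's own rating. On a provider failure the
    records collected so far are returned with the error message attached.
    """
    config = config or ElicitationConfig()
    records: list[UCRecord] = []
    for state in states:
        try:
            rating = provider.rate(state)
            rs_value = rs_elicit(rating)
            session = sg_start(rs_value, config, state_id=state.state_id)
            while session.status == "active":
                answer = provider.gamble(state, session.p_current, first=not session.history)
                sg_step(session, answer)
        except Exception as exc:  # provider failures surface as partial results
            return InterviewResult(records, error=f"state {state.state_id}: {exc}")
        records.append(
            UCRecord(respondent_id, state.state_id, "RS", rs_value, n_steps=0)
        )
        records.append(
            UCRecord(
                respondent_id,
                state.state_id,
                "SG",
                sg_utility(session),
                n_steps=len(session.history),
                refused_gamble=session.status == "refused",
            )
        )
    return InterviewResult(records)
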