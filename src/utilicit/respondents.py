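"""Synthetic respondents for exercising the elicitation and analysis pipeline.

The raw interview data behind the published summary statistics are not
redistributable, so the package simulates interviewees with the same
statistical structure: per-state latent rating-scale utilities drawn from a
beta distribution anchored to the published per-state mean and dispersion; a
deterministic distortion pushing standard-gamble valuations toward 1
(latent_sg = 1 − (1 − u)^(1/γ) with γ ≤ 1, mirroring the heavy skew toward
1 observed for SG); a refusal mechanism by which respondents who value a
state near perfect health decline any risk of death outright; and rating
noise on the 0–100 scale.

All randomness flows from a single integer seed; each (respondent, state)
pair gets its own substream derived by stable hashing, so results do not
depend on evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

from .catalog import (
    EDUCATION_LEVELS,
    FAMILY_SITUATIONS,
    SEXES,
    HealthState,
    RespondentProfile,
)
from . import datasets

__all__ = [
    "SyntheticModel",
    "SyntheticRespondent",
    "generate_population",
    "draw_latent_utilities",
    "simulate_rs_response",
    "simulate_sg_decision",
    "make_respondents",
]


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a [lo, hi]-truncated normal whose mean equals *target_mean*."""
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside truncation bounds [{lo}, {hi}]")

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(sps.truncnorm.mean(a, b, loc=loc, scale=sd)) - target_mean

    return float(brentq(gap, lo - 3 * sd, hi + 3 * sd, xtol=1e-10))


def _substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-entity generator; string keys are CRC32-hashed."""
    ints = tuple(zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + ints))


@dataclass
class SyntheticModel:
    """Response model of a simulated interviewee population.

    state_means / state_sds
        Per-state mean and standard deviation of the latent rating-scale
        utility (beta-distributed on [0, 1]); defaults are anchored to the
        published per-state RS statistics.
    sg_gamma
        Distortion exponent γ ∈ (0, 1] mapping latent RS utility u to the
        latent SG utility 1 − (1 − u)^(1/γ); γ < 1 pushes SG toward 1,
        γ = 1 is the identity.
    rs_noise_sd
        Gaussian rating noise on the 0–100 scale.
    indifference_band
        Half-width δ of the risk band within which a respondent answers
        "indifferent" to the gamble.
    refusal_prob / refusal_threshold
        A respondent whose latent SG utility for a state is at or above
        the threshold refuses any risk with this probability, yielding an
        elicited value of exactly 1.
    """

    state_means: dict[int, float]
    state_sds: dict[int, float]
    sg_gamma: float = 0.35
    rs_noise_sd: float = 5.0
    indifference_band: float = 0.01
    refusal_prob: float = 0.25
    refusal_threshold: float = 0.90

    def __post_init__(self) -> None:
        if set(self.state_means) != set(self.state_sds):
            raise ValueError("state_means and state_sds must cover the same states")
        for s, mu in self.state_means.items():
            sd = self.state_sds[s]
            if not 0.0 < mu < 1.0:
                raise ValueError(f"state {s}: mean must lie in (0, 1), got {mu}")
            if not 0.0 < sd * sd < mu * (1.0 - mu):
                raise ValueError(
                    f"state {s}: sd {sd} infeasible for a beta with mean {mu}"
                )
        if not 0.0 < self.sg_gamma <= 1.0:
            raise ValueError(f"sg_gamma must lie in (0, 1], got {self.sg_gamma}")
        if self.indifference_band < 0:
            raise ValueError("indifference_band must be >= 0")
        if not 0.0 <= self.refusal_prob <= 1.0:
            raise ValueError("refusal_prob must lie in [0, 1]")
        if self.rs_noise_sd < 0:
            raise ValueError("rs_noise_sd must be >= 0")

    def beta_params(self, state_id: int) -> tuple[float, float]:
        """(α, β) of the latent beta matched to the state's mean and sd."""
        mu, sd = self.state_means[state_id], self.state_sds[state_id]
        kappa = mu * (1.0 - mu) / (sd * sd) - 1.0
        return mu * kappa, (1.0 - mu) * kappa

    @classmethod
    def default(cls, **overrides) -> "SyntheticModel":
        """Model anchored to the published per-state RS means and sds."""
        ref = datasets.load_reference_summary()
        rs = ref[ref["method"] == "RS"].set_index("state_id")
        return cls(
            state_means=rs["mean"].to_dict(),
            state_sds=rs["sd"].to_dict(),
            **overrides,
        )


def generate_population(
    n: int,
    demographics: dict | None = None,
    seed: int = 0,
) -> list[RespondentProfile]:
    """Draw *n* respondent profiles matching the study's demographic mix.

    *demographics* maps each categorical field to category weights (counts
    or proportions; proportions must sum to 1) and "age" to
    {mean, sd, min, max}; ages follow a truncated normal. Defaults are the
    bundled study-population composition (70% female, mean age ≈ 41).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    demo = demographics or datasets.load_demographics()
    rng = _substream(seed, "population")

    def categories(fieldname: str, allowed: tuple[str, ...] | None = None) -> tuple[list, np.ndarray]:
        weights = demo[fieldname]
        cats = list(weights)
        w = np.asarray([float(weights[c]) for c in cats])
        if np.any(w < 0):
            raise ValueError(f"{fieldname}: negative weight")
        if np.all(w <= 1.0):  # proportions: must sum to one
            if abs(w.sum() - 1.0) > 1e-6:
                raise ValueError(f"{fieldname}: proportions sum to {w.sum():.6f}, not 1")
        if allowed is not None and not set(cats) <= set(allowed):
            raise ValueError(f"{fieldname}: categories {cats} not within {allowed}")
        return cats, w / w.sum()

    sex_c, sex_p = categories("sex", SEXES)
    edu_c, edu_p = categories("education", EDUCATION_LEVELS)
    fam_c, fam_p = categories("family_situation", FAMILY_SITUATIONS)
    pro_c, pro_p = categories("profession")
    mar_c, mar_p = categories("marital_status")
    age = demo["age"]

    # truncated normal whose *truncated* mean hits the target observed mean
    loc = _truncnorm_loc(age["mean"], age["sd"], age["min"], age["max"])
    a, b = (age["min"] - loc) / age["sd"], (age["max"] - loc) / age["sd"]
    ages = sps.truncnorm.rvs(a, b, loc=loc, scale=age["sd"], size=n, random_state=rng)

    profiles = []
    for i in range(n):
        profiles.append(
            RespondentProfile(
                respondent_id=f"R{i + 1:03d}",
                age=float(np.round(ages[i])),
                sex=sex_c[rng.choice(len(sex_c), p=sex_p)],
                education=edu_c[rng.choice(len(edu_c), p=edu_p)],
                family_situation=fam_c[rng.choice(len(fam_c), p=fam_p)],
                profession=pro_c[rng.choice(len(pro_c), p=pro_p)],
                marital_status=mar_c[rng.choice(len(mar_c), p=mar_p)],
                is_patient=False,
                country=demo.get("country", "Switzerland"),
            )
        )
    return profiles


def draw_latent_utilities(
    model: SyntheticModel,
    profile: RespondentProfile,
    seed: int = 0,
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-state latent (RS, SG) utilities for one respondent.

    latent_rs[s] ~ Beta with the model's state mean and sd; latent_sg is the
    deterministic distortion 1 − (1 − u)^(1/γ), hence ≥ latent_rs for γ < 1.
    """
    latent_rs: dict[int, float] = {}
    latent_sg: dict[int, float] = {}
    for s in sorted(model.state_means):
        rng = _substream(seed, profile.respondent_id, s, 0)
        a, b = model.beta_params(s)
        u = float(rng.beta(a, b))
        latent_rs[s] = u
        latent_sg[s] = 1.0 - (1.0 - u) ** (1.0 / model.sg_gamma)
    return latent_rs, latent_sg


def simulate_rs_response(
    latent_rs: float,
    rs_noise_sd: float,
    rng: np.random.Generator | int = 0,
) -> float:
    """Noisy 0–100 rating: clamp(round(100·u + ε), 0, 100)."""
    if isinstance(rng, (int, np.integer)):
        rng = _substream(int(rng), "rs")
    noise = rng.normal(0.0, rs_noise_sd) if rs_noise_sd > 0 else 0.0
    return float(np.clip(np.round(100.0 * latent_rs + noise), 0.0, 100.0))


def simulate_sg_decision(latent_sg: float, p: float, band: float = 0.0) -> str:
    """Threshold decision rule for a gamble at risk *p*.

    The gamble's certainty-equivalent utility is 1 − p; within ±band of the
    latent SG utility the respondent is indifferent, above it they accept
    the gamble, below it they keep the sure state.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"risk p must lie in [0, 1], got {p}")
    if abs((1.0 - p) - latent_sg) <= band:
        return "indifferent"
    return "accept" if (1.0 - p) > latent_sg else "reject"


@dataclass
class SyntheticRespondent:
    """A simulated interviewee; satisfies the interview answer-provider API."""

    profile: RespondentProfile
    latent_rs: dict[int, float]
    latent_sg: dict[int, float]
    indifference_band: float = 0.01
    rs_noise_sd: float = 5.0
    refuses: dict[int, bool] = field(default_factory=dict)
    seed: int = 0

    def rate(self, state: HealthState) -> float:
        rng = _substream(self.seed, self.profile.respondent_id, state.state_id, 1)
        return simulate_rs_response(self.latent_rs[state.state_id], self.rs_noise_sd, rng)

    def gamble(self, state: HealthState, p: float, first: bool) -> str:
        if first and self.refuses.get(state.state_id, False):
            return "refuse_any_risk"
        return simulate_sg_decision(self.latent_sg[state.state_id], p, self.indifference_band)


def make_respondents(
    model: SyntheticModel,
    n: int,
    demographics: dict | None = None,
    seed: int = 0,
) -> list[SyntheticRespondent]:
    """Full simulated population: profiles, latent utilities, refusal draws."""
    profiles = generate_population(n, demographics, seed=seed)
    respondents = []
    for prof in profiles:
        latent_rs, latent_sg = draw_latent_utilities(model, prof, seed=seed)
        refuses = {}
        for s, u_sg in latent_sg.items():
            rng = _substream(seed, prof.respondent_id, s, 2)
            refuses[s] = bool(
                u_sg >= model.refusal_threshold and rng.random() < model.refusal_prob
            )
        respondents.append(
            SyntheticRespondent(
                profile=prof,
                latent_rs=latent_rs,
                latent_sg=latent_sg,
                indifference_band=model.indifference_band,
                rs_noise_sd=model.rs_noise_sd,
                refuses=refuses,
                seed=seed,
            )
        )
    return respondents
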