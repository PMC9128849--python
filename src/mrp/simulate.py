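"""Synthetic response generation from a rating signal-detection model.

Each probe elicits a latent evidence draw X ~ Normal(mu[role, ecc], sigma)
which a fixed set of 7 strictly increasing criteria maps onto the 8-level
decision x confidence scale.  With probability ``lapse_rate`` the response is
replaced by a uniform draw over the 8 options.  Because the criteria are
shared across patch roles, the exact AUC of the discretized ratings is
available in closed form (:func:`true_rating_auc`) for parameter-recovery
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import DesignPlan
from .sdt import DXC_LEVELS

_DXC_ARR = np.asarray(DXC_LEVELS)

DEFAULT_CRITERIA = (-2.1, -1.4, -0.7, 0.0, 0.7, 1.4, 2.1)


@dataclass(frozen=True)
class SDTParams:
    """Generative parameters of the rating model.

    ``mu``/``sigma`` are keyed by patch role; eccentricity enters as a
    multiplicative gain on the mean (``ecc_gain``) and congruence as an
    additive widening of the original/modified separation
    (``congruence_effect``, split half/half between the two roles under a
    congruent initial image).
    """
    name: str
    mu: Mapping[str, float]
    sigma: Mapping[str, float]
    criteria: tuple[float, ...] = DEFAULT_CRITERIA
    ecc_gain: Mapping[str, float] = field(
        default_factory=lambda: {"fovea": 1.0, "parafovea": 1.0, "periphery": 1.0})
    congruence_effect: float = 0.0
    lapse_rate: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.criteria, dtype=float)
        if c.size != 7 or not (np.diff(c) > 0).all():
            raise ValueError("criteria must be 7 strictly increasing thresholds")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("sigmas must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")

    def mean(self, role: str, ecc: str = "fovea",
             congruence: str = "incongruent") -> float:
        m = self.mu[role]
        if congruence == "congruent" and self.congruence_effect:
            if role == "original":
                m += self.congruence_effect / 2.0
            elif role == "modified":
                m -= self.congruence_effect / 2.0
        return m * self.ecc_gain[ecc]


def _flat(mu_present, mu_null, mu_original=0.0, mu_modified=0.0, **kw):
    mu = {"present": mu_present, "null": mu_null,
          "original": mu_original, "modified": mu_modified}
    sigma = {r: 1.0 for r in mu}
    return SDTParams(mu=mu, sigma=sigma, **kw)


#: named, versioned generative presets (all constants visible here)
PRESETS: dict[str, SDTParams] = {
    # no separation anywhere: every AUC is 0.5 in expectation
    "null-effect": _flat(0.0, 0.0, name="null-effect"),
    # degenerate separation: every response saturates at dxc = +/-4
    "perfect": _flat(100.0, -100.0, 100.0, -100.0, name="perfect"),
    # directional stand-in for the observed effect pattern: large
    # present/null separation, small original/modified separation that
    # widens under a congruent gist, all attenuated toward the periphery
    "exp2-default": _flat(
        0.65, -0.65, 0.1, -0.1, name="exp2-default",
        ecc_gain={"fovea": 1.0, "parafovea": 0.85, "periphery": 0.7},
        congruence_effect=0.5, lapse_rate=0.02),
}


def get_preset(name: str) -> SDTParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class AgentProfile:
    kind: str                     # attentive | random
    params: SDTParams | None = None

    def __post_init__(self):
        if self.kind not in ("attentive", "random"):
            raise ValueError(f"kind must be attentive or random, got {self.kind!r}")


def rating_bin_probs(params: SDTParams, role: str, ecc: str = "fovea",
                     congruence: str = "incongruent") -> np.ndarray:
    """Probability of each of the 8 dxc levels for one evidence distribution."""
    mu = params.mean(role, ecc, congruence)
    sigma = params.sigma[role]
    cdf = norm.cdf(np.asarray(params.criteria), loc=mu, scale=sigma)
    edges = np.concatenate(([0.0], cdf, [1.0]))
    p = np.diff(edges)
    if params.lapse_rate:
        p = (1.0 - params.lapse_rate) * p + params.lapse_rate / 8.0
    return p


def true_rating_auc(params: SDTParams, signal_role: str, noise_role: str,
                    ecc: str = "fovea", congruence: str = "incongruent") -> float:
    """Exact AUC of the discretized 8-level ratings (rank formula over bins)."""
    ps = rating_bin_probs(params, signal_role, ecc, congruence)
    pn = rating_bin_probs(params, noise_role, ecc, congruence)
    return discrete_auc(ps, pn)


def discrete_auc(p_signal: np.ndarray, p_noise: np.ndarray) -> float:
    """Rank-formula AUC of two discrete distributions over ordered bins."""
    ps = np.asarray(p_signal, dtype=float)
    pn = np.asarray(p_noise, dtype=float)
    greater = np.tril(np.ones((ps.size, pn.size)), k=-1)   # signal bin > noise bin
    return float(ps @ greater @ pn + 0.5 * ps @ pn)


def sample_dxc(params: SDTParams, role: str, n: int, rng,
               ecc: str = "fovea", congruence: str = "incongruent") -> np.ndarray:
    """Draw n dxc responses for one patch role (vectorized)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = rng.normal(params.mean(role, ecc, congruence), params.sigma[role], size=n)
    idx = np.searchsorted(np.asarray(params.criteria), x)
    dxc = _DXC_ARR[idx]
    if params.lapse_rate:
        lapse = rng.random(n) < params.lapse_rate
        dxc = np.where(lapse, rng.choice(_DXC_ARR, size=n), dxc)
    return dxc


def simulate_catch(profile: AgentProfile, n_catch: int, rng) -> float:
    """Catch-trial accuracy of one agent (fraction correct of n_catch)."""
    if n_catch < 1:
        raise ValueError("n_catch must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = _catch_p(profile)
    return float(rng.binomial(n_catch, p)) / n_catch


def _catch_p(profile: AgentProfile) -> float:
    if profile.kind == "random":
        return 1.0 / 8.0
    lapse = profile.params.lapse_rate if profile.params is not None else 0.0
    return (1.0 - lapse) + lapse / 8.0


def simulate_responses(plan: DesignPlan | pd.DataFrame, params: SDTParams,
                       seed: int = 0,
                       agent_kinds: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Simulate one response per scheduled probe of a design.

    ``agent_kinds`` optionally maps participant ids to "attentive" (default)
    or "random"; random agents answer every probe, and every catch trial,
    uniformly.  Returns the canonical response table (see :mod:`mrp.io`).
    """
    df = plan.to_frame() if isinstance(plan, DesignPlan) else plan.copy()
    rng = np.random.default_rng(seed)
    n = len(df)
    dxc = np.zeros(n, dtype=int)
    catch_correct = np.full(n, np.nan)

    kinds = df["participant_id"].map(lambda p: (agent_kinds or {}).get(p, "attentive"))
    random_agent = (kinds == "random").to_numpy()
    is_catch = df["is_catch"].to_numpy().astype(bool)

    probe = ~is_catch
    # attentive probe responses, grouped by (role, ecc, congruence) cell
    att_probe = probe & ~random_agent
    sub = df.loc[att_probe]
    cell_dxc = np.zeros(att_probe.sum(), dtype=int)
    keys = list(zip(sub["patch_type"], sub["eccentricity_class"],
                    sub["initial_congruence"]))
    codes, uniq = pd.factorize(pd.Series(keys))
    for ci, (role, ecc, cong) in enumerate(uniq):
        m = codes == ci
        cell_dxc[m] = sample_dxc(params, role, int(m.sum()), rng, ecc, cong)
    dxc[att_probe] = cell_dxc
    # random agents: uniform over the 8 options everywhere
    rand_probe = probe & random_agent
    dxc[rand_probe] = rng.choice(_DXC_ARR, size=int(rand_probe.sum()))

    # catch trials
    p_att = _catch_p(AgentProfile("attentive", params))
    p_catch = np.where(random_agent[is_catch], 1.0 / 8.0, p_att)
    catch_correct[is_catch] = rng.random(int(is_catch.sum())) < p_catch

    out = df.copy()
    out["decision"] = np.where(is_catch, "", np.where(dxc > 0, "yes", "no"))
    conf = np.abs(dxc)
    out["confidence"] = np.where(is_catch, 0, conf)
    out["dxc"] = np.where(is_catch, 0, dxc)
    out["catch_correct"] = catch_correct
    return out
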