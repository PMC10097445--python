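"""Synthetic Experiment-2 subject tables and Navon trial tables.

Emulates the structure of the seated-desk-work study: per subject, six
chest-movement window counts from a 30-min recording, a salivary
alpha-amylase (SAA) stress index, and Navon-task outcomes (condition mean
reaction times, shift-trial accuracy).  Movement counts follow the study's
descriptive distributions; reaction time, accuracy and stress are generated
from a linear path model with configurable planted effects
(movement -> RT -> outcome), so mediation recovery can be tested against
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Exp2Config", "generate_exp2_dataset", "generate_trials"]

#: Movement-count distributions (windows per 30 min): mean, sd.
MOVEMENT_DEFAULTS: dict[str, tuple[float, float]] = {
    "walking": (28.143, 31.053),
    "stand_sit": (38.214, 24.745),
    "rotating": (354.214, 184.761),
    "swinging": (44.536, 21.384),
    "rocking": (62.464, 30.827),
    "sitting": (1082.643, 332.709),
}

RT_MEAN, RT_SD = 1468.83, 515.088        # shift-trial reaction time (ms)
ACC_MEAN, ACC_SD = 0.968, 0.08           # shift-trial accuracy
STRESS_MEAN, STRESS_SD = 25.462, 15.103  # SAA meter units

#: Navon condition reaction times (ms): mean, sd per condition.
CONDITION_RT_DEFAULTS: dict[str, tuple[float, float]] = {
    "global": (932.83, 217.05),
    "local": (1101.13, 302.79),
    "nonshift": (1345.168, 430.02),
    "shift": (1468.83, 515.09),
}


def _default_a() -> dict[str, float]:
    # swinging lowers shift-trial RT (r ~ -0.39 at the default scales)
    return {"swinging": -9.39, "rotating": 0.0, "sitting": 0.0}


def _default_b() -> dict[str, float]:
    # faster shift responses come with slightly higher accuracy
    return {"accuracy": -3.0e-5, "stress": 0.0}


@dataclass
class Exp2Config:
    """Configuration of the Experiment-2 synthetic cohort.

    ``a`` maps movement name -> effect on RT (ms per window count); ``b``
    maps outcome -> effect of RT; ``c_prime`` maps ``(movement, outcome)`` ->
    direct effect.  Residual standard deviations default to values that keep
    the marginal spread of RT/accuracy/stress at the study's descriptive
    scales given the planted coefficients (set them explicitly to override).
    """

    n_subjects: int = 28
    movement_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(MOVEMENT_DEFAULTS))
    rt_mean: float = RT_MEAN
    rt_sd: float = RT_SD
    accuracy_mean: float = ACC_MEAN
    accuracy_sd: float = ACC_SD
    stress_mean: float = STRESS_MEAN
    stress_sd: float = STRESS_SD
    a: dict[str, float] = field(default_factory=_default_a)
    b: dict[str, float] = field(default_factory=_default_b)
    c_prime: dict[tuple[str, str], float] = field(default_factory=dict)
    rt_resid_sd: float | None = None
    accuracy_resid_sd: float | None = None
    stress_resid_sd: float | None = None
    missing_stress_prob: float = 2.0 / 28.0
    condition_rt: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CONDITION_RT_DEFAULTS))
    condition_accuracy: dict[str, float] = field(
        default_factory=lambda: {"global": 0.97, "local": 0.97, "nonshift": 0.97, "shift": 0.968})
    n_global: int = 20
    n_local: int = 20
    n_mixed: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        for name, (mu, sd) in self.movement_params.items():
            if sd < 0:
                raise ValueError(f"{name}: scale must be >= 0")
        for sd in (self.rt_sd, self.accuracy_sd, self.stress_sd):
            if sd < 0:
                raise ValueError("scales must be >= 0")
        if not 0 <= self.missing_stress_prob <= 1:
            raise ValueError("missing_stress_prob must be in [0, 1]")

    # -- derived residual scales ------------------------------------------

    def _resid_sd(self, target_sd: float, explained_var: float) -> float:
        resid_var = max(target_sd**2 - explained_var, (0.1 * target_sd) ** 2)
        return float(np.sqrt(resid_var))

    def resolved_rt_resid_sd(self) -> float:
        if self.rt_resid_sd is not None:
            return self.rt_resid_sd
        ev = sum((coef * self.movement_params[m][1]) ** 2 for m, coef in self.a.items())
        return self._resid_sd(self.rt_sd, ev)

    def resolved_outcome_resid_sd(self, outcome: str) -> float:
        explicit = self.accuracy_resid_sd if outcome == "accuracy" else self.stress_resid_sd
        if explicit is not None:
            return explicit
        target = self.accuracy_sd if outcome == "accuracy" else self.stress_sd
        ev = (self.b.get(outcome, 0.0) * self.rt_sd) ** 2
        ev += sum(
            (coef * self.movement_params[m][1]) ** 2
            for (m, o), coef in self.c_prime.items() if o == outcome
        )
        return self._resid_sd(target, ev)


def generate_exp2_dataset(config: Exp2Config | None = None) -> pd.DataFrame:
    """Generate the subject-level Experiment-2 table.

    Movement counts are normal draws at the study's descriptive means/SDs,
    clipped at zero and rounded to integers.  RT, accuracy and stress follow
    the linear path model with the configured coefficients; intercepts are
    set so the marginal means stay at the configured targets.  Accuracy is
    clamped to [0, 1]; stress rows go missing with ``missing_stress_prob``.
    Deterministic given ``config.seed``.
    """
    cfg = config or Exp2Config()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    data: dict[str, np.ndarray] = {}
    for name, (mu, sd) in cfg.movement_params.items():
        raw = rng.normal(mu, sd, size=n)
        data[name] = np.round(np.clip(raw, 0.0, None)).astype(int)

    a_terms = np.zeros(n)
    a_mean = 0.0
    for m, coef in cfg.a.items():
        a_terms += coef * data[m]
        a_mean += coef * cfg.movement_params[m][0]
    rt = (cfg.rt_mean - a_mean) + a_terms + rng.normal(0.0, cfg.resolved_rt_resid_sd(), size=n)
    data["reaction_time"] = rt

    for outcome, (target_mean, clamp) in {
        "accuracy": (cfg.accuracy_mean, True),
        "stress": (cfg.stress_mean, False),
    }.items():
        b = cfg.b.get(outcome, 0.0)
        pred = b * rt
        pred_mean = b * cfg.rt_mean
        for (m, o), coef in cfg.c_prime.items():
            if o == outcome:
                pred = pred + coef * data[m]
                pred_mean += coef * cfg.movement_params[m][0]
        vals = (target_mean - pred_mean) + pred + rng.normal(
            0.0, cfg.resolved_outcome_resid_sd(outcome), size=n)
        if clamp:
            vals = np.clip(vals, 0.0, 1.0)
        data[outcome] = vals

    miss = rng.random(n) < cfg.missing_stress_prob
    data["stress"] = np.where(miss, np.nan, data["stress"])

    df = pd.DataFrame(data)
    df.insert(0, "participant", [f"S{i + 1:02d}" for i in range(n)])
    return df.set_index("participant")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the requested mean and sd."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _mixed_kinds(rng: np.random.Generator, n_mixed: int) -> list[str]:
    """A mixed-phase global/local sequence with balanced shift/nonshift tags.

    Among the ``n_mixed - 1`` transitions, the number of switches and stays
    differs by at most one, with switch positions placed at random.
    """
    n_trans = n_mixed - 1
    n_shift = n_trans // 2 + int(rng.integers(0, 2)) if n_trans % 2 else n_trans // 2
    switch_pos = set(rng.choice(n_trans, size=n_shift, replace=False).tolist())
    kinds = ["global" if rng.random() < 0.5 else "local"]
    for i in range(n_trans):
        prev = kinds[-1]
        if i in switch_pos:
            kinds.append("local" if prev == "global" else "global")
        else:
            kinds.append(prev)
    return kinds


def generate_trials(config: Exp2Config | None = None) -> pd.DataFrame:
    """Generate a trial-level Navon table: global, local and mixed phases.

    Each subject gets 20 global, 20 local and 40 mixed trials.  The mixed
    sequence is built so shift and nonshift tags are balanced to within one
    trial.  Reaction times are lognormal draws with moments matched to the
    per-condition targets (mixed-phase trials use the shift or nonshift
    condition of their tag; the untagged first mixed trial uses the nonshift
    condition); correctness is Bernoulli per condition.
    """
    cfg = config or Exp2Config()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    ln = {cond: _lognormal_params(m, s) for cond, (m, s) in cfg.condition_rt.items()}

    rows = []
    for subj in range(cfg.n_subjects):
        pid = f"S{subj + 1:02d}"
        for phase, n_trials in (("global", cfg.n_global), ("local", cfg.n_local)):
            mu, sig = ln[phase]
            rts = rng.lognormal(mu, sig, size=n_trials)
            ok = rng.random(n_trials) < cfg.condition_accuracy[phase]
            for i in range(n_trials):
                rows.append((pid, phase, phase, rts[i], bool(ok[i]), i))
        kinds = _mixed_kinds(rng, cfg.n_mixed)
        conds = ["nonshift"] + [
            "shift" if kinds[i] != kinds[i - 1] else "nonshift" for i in range(1, cfg.n_mixed)
        ]
        for i, (kind, cond) in enumerate(zip(kinds, conds)):
            mu, sig = ln[cond]
            rt = rng.lognormal(mu, sig)
            ok = rng.random() < cfg.condition_accuracy[cond]
            rows.append((pid, "mixed", kind, rt, bool(ok), i))
    return pd.DataFrame(
        rows, columns=["participant", "phase", "trial_kind", "rt", "correct", "trial_index"]
    )
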