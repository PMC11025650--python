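"""Synthetic study material: a micro-language with controlled event
statistics, and ERP/EEG generators with planted effects.

The micro-language is a small transitive-event world.  A sentence describes
one event: an agent performs an action on a patient, optionally with a
manner adverb, a location phrase, and a sentence-initial temporal adverb::

    [yesterday] the <agent> <action> the <patient> [<manner>] [in the <location>] .

with a fraction of stative utterances locating a patient in the world:

    the <patient> is in the <location> .

Event statistics are fully specified by conditional probability tables, so
cloze probability (how predictable a patient is given the action),
congruity (whether a patient ever occurs with an action), association
(words co-occurring in the same events), word frequency (agent weights),
and sentence position are all controllable knobs — the classic battery of
N400-sensitive manipulations.  Sentences carry their frame annotation by
construction; no parsing is involved.

The ERP generator is the generative twin of the N400 regression: a linear
mixed model with fixed effects for baseline, (negated) Semantic Update and
surprisal, crossed subject/word random effects, an optional by-subject SU
slope, and Gaussian noise.  The EEG time-course generator plants a
parametric effect curve beta(t) with a known fractional-area latency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import MICRO_ROLE_INVENTORY, Frame, FrameAnnotatedSentence

logger = logging.getLogger("sgn400")


def _check_dist(name: str, dist: Mapping[str, float]) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"distribution {name} sums to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"distribution {name} has negative probabilities")


def _draw(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    words = list(dist)
    return words[rng.choice(len(words), p=np.array([dist[w] for w in words]))]


# ---------------------------------------------------------------------------
# Micro-language
# ---------------------------------------------------------------------------

@dataclass
class MicroWorldSpec:
    """Conditional structure of the micro-language.

    ``patients_given_action`` is the cloze knob: the probability of a
    patient given the action is its cloze value, and a patient outside the
    support of an action is incongruent in that context.
    """

    roles: tuple[str, ...] = MICRO_ROLE_INVENTORY
    determiner: str = "the"
    terminator: str = "."
    locative_preposition: str = "in"
    copula: str = "is"
    p_stative: float = 0.25
    agent_weights: dict[str, float] = field(default_factory=dict)
    actions_given_agent: dict[str, dict[str, float]] = field(default_factory=dict)
    patients_given_action: dict[str, dict[str, float]] = field(default_factory=dict)
    locations_given_action: dict[str, dict[str, float]] = field(default_factory=dict)
    manners_given_action: dict[str, dict[str, float]] = field(default_factory=dict)
    time_adverbs: dict[str, float] = field(default_factory=dict)
    p_location: float = 0.5
    p_manner: float = 0.3
    p_time: float = 0.2

    def validate(self) -> None:
        if not self.agent_weights:
            raise ValueError("micro-world needs at least one agent")
        for agent in self.agent_weights:
            _check_dist(f"actions|{agent}", self.actions_given_agent[agent])
        for tbl, name in ((self.patients_given_action, "patients"),
                          (self.locations_given_action, "locations"),
                          (self.manners_given_action, "manners")):
            for action, dist in tbl.items():
                _check_dist(f"{name}|{action}", dist)
        if self.time_adverbs:
            _check_dist("time_adverbs", self.time_adverbs)
        for w in self.vocabulary():
            if not w:
                raise ValueError("empty word in vocabulary")

    def locations_given_patient(self, patient: str) -> dict[str, float]:
        """Mixture of the location tables of the actions a patient occurs
        with (weighted uniformly over those actions); the co-occurrence
        structure behind prime-target relatedness."""
        mix: dict[str, float] = {}
        actions = [a for a, d in self.patients_given_action.items()
                   if d.get(patient, 0) > 0 and a in self.locations_given_action]
        if not actions:
            raise ValueError(f"{patient!r} occurs with no located action")
        for a in actions:
            for loc, p in self.locations_given_action[a].items():
                mix[loc] = mix.get(loc, 0.0) + p / len(actions)
        return mix

    def all_patients(self) -> list[str]:
        return sorted({p for d in self.patients_given_action.values()
                       for p, pr in d.items() if pr > 0})

    def vocabulary(self) -> list[str]:
        words = {self.determiner, self.terminator, self.locative_preposition}
        if self.p_stative > 0:
            words.add(self.copula)
        words |= set(self.agent_weights)
        for tbl in (self.actions_given_agent,):
            for d in tbl.values():
                words |= set(d)
        for tbl in (self.patients_given_action, self.locations_given_action,
                    self.manners_given_action):
            for d in tbl.values():
                words |= set(d)
        words |= set(self.time_adverbs)
        return sorted(words)

    # -- contrast sets for the effect battery --------------------------------

    def _agent_for(self, action: str) -> str:
        for agent, dist in self.actions_given_agent.items():
            if dist.get(action, 0) > 0:
                return agent
        raise ValueError(f"no agent performs {action!r}")

    def _frame_sentence(self, agent: str, action: str, patient: str):
        toks = (self.determiner, agent, action, self.determiner, patient,
                self.terminator)
        return toks, 4  # critical position: the patient

    def congruity_items(self) -> list[tuple[tuple, tuple, int]]:
        """(congruent tokens, incongruent tokens, critical position): the
        incongruent completion is a patient that never occurs with the
        action (drawn from another action's support)."""
        items = []
        actions = list(self.patients_given_action)
        for action in actions:
            support = set(self.patients_given_action[action])
            foreign = [p for a in actions for p in self.patients_given_action[a]
                       if p not in support]
            if not foreign:
                continue
            agent = self._agent_for(action)
            congruent = max(self.patients_given_action[action],
                            key=self.patients_given_action[action].get)
            con, pos = self._frame_sentence(agent, action, congruent)
            inc, _ = self._frame_sentence(agent, action, sorted(foreign)[0])
            items.append((con, inc, pos))
        return items

    def cloze_items(self) -> list[tuple[tuple, tuple, int]]:
        """(high-cloze tokens, low-cloze tokens, critical position)."""
        items = []
        for action, dist in self.patients_given_action.items():
            positive = {w: p for w, p in dist.items() if p > 0}
            if len(positive) < 2:
                continue
            hi = max(positive, key=positive.get)
            lo = min(positive, key=positive.get)
            if positive[hi] == positive[lo]:
                continue
            agent = self._agent_for(action)
            high, pos = self._frame_sentence(agent, action, hi)
            low, _ = self._frame_sentence(agent, action, lo)
            items.append((high, low, pos))
        return items

    def priming_items(self) -> list[tuple[tuple, tuple, int]]:
        """(related tokens, unrelated tokens, critical position) in the
        stative frame "the <prime> is in the <target> .": the related
        condition pairs a patient with a location it co-occurs with in
        events, the unrelated condition with a location from a disjoint
        event family.  The critical word is the location target."""
        items = []
        all_locs = {loc for d in self.locations_given_action.values() for loc in d}
        for prime in self.all_patients():
            locs = self.locations_given_patient(prime)
            related = max(locs, key=locs.get)
            foreign = sorted(all_locs - set(locs))
            if not foreign:
                continue
            mk = lambda tgt: (self.determiner, prime, self.copula,
                              self.locative_preposition, self.determiner,
                              tgt, self.terminator)
            items.append((mk(related), mk(foreign[0]), 5))
        return items

    def frequency_items(self) -> tuple[list[tuple], list[tuple], int]:
        """Sentences whose agent is the most vs. least frequent word;
        critical position is the agent (position 1)."""
        hi = max(self.agent_weights, key=self.agent_weights.get)
        lo = min(self.agent_weights, key=self.agent_weights.get)
        out = []
        for agent in (hi, lo):
            acts = self.actions_given_agent[agent]
            action = max(acts, key=acts.get)
            patient = max(self.patients_given_action[action],
                          key=self.patients_given_action[action].get)
            toks = (self.determiner, agent, action, self.determiner, patient,
                    self.terminator)
            out.append(toks)
        return [out[0]], [out[1]], 1


def default_microworld() -> MicroWorldSpec:
    """The default study micro-world: six agents (with a 4:1 frequency
    range), four actions in two semantic families (household vs. food) with
    disjoint patient and location sets, 0.85/0.05 cloze contrasts, and
    optional manner/location/time modifiers."""
    open_patients = {"door": 0.85, "window": 0.05, "box": 0.05, "jar": 0.05}
    close_patients = {"window": 0.85, "door": 0.05, "box": 0.05, "jar": 0.05}
    eat_patients = {"cake": 0.85, "bread": 0.05, "apple": 0.05, "soup": 0.05}
    cook_patients = {"soup": 0.85, "bread": 0.05, "apple": 0.05, "cake": 0.05}
    household = {"hallway": 0.7, "garage": 0.3}
    food = {"kitchen": 0.7, "garden": 0.3}
    spec = MicroWorldSpec(
        agent_weights={"boy": 4, "girl": 4, "man": 2, "woman": 2,
                       "dog": 1, "chef": 1},
        actions_given_agent={
            "boy": {"opened": 0.4, "closed": 0.1, "ate": 0.4, "cooked": 0.1},
            "girl": {"opened": 0.1, "closed": 0.4, "ate": 0.1, "cooked": 0.4},
            "man": {"opened": 0.4, "closed": 0.1, "ate": 0.4, "cooked": 0.1},
            "woman": {"opened": 0.1, "closed": 0.4, "ate": 0.1, "cooked": 0.4},
            "dog": {"opened": 0.3, "closed": 0.2, "ate": 0.5, "cooked": 0.0},
            "chef": {"opened": 0.1, "closed": 0.1, "ate": 0.2, "cooked": 0.6},
        },
        patients_given_action={"opened": open_patients, "closed": close_patients,
                               "ate": eat_patients, "cooked": cook_patients},
        locations_given_action={"opened": household, "closed": household,
                                "ate": food, "cooked": food},
        manners_given_action={a: {"slowly": 0.5, "quickly": 0.5}
                              for a in ("opened", "closed", "ate", "cooked")},
        time_adverbs={"yesterday": 0.5, "today": 0.5},
    )
    spec.validate()
    return spec


def sample_corpus(spec: MicroWorldSpec, n_sentences: int,
                  seed: int) -> list[FrameAnnotatedSentence]:
    """Sample frame-annotated sentences from the micro-world (reproducible
    given the seed; empirical conditional frequencies converge to the
    spec's probability tables)."""
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    agents = sorted(spec.agent_weights)
    aw = np.array([spec.agent_weights[a] for a in agents], dtype=float)
    aw /= aw.sum()
    det, term = spec.determiner, spec.terminator
    patients_all = spec.all_patients()
    out = []
    for _ in range(n_sentences):
        if spec.p_stative > 0 and spec.locations_given_action \
                and rng.random() < spec.p_stative:
            patient = patients_all[rng.choice(len(patients_all))]
            loc = _draw(rng, spec.locations_given_patient(patient))
            tokens = [det, patient, spec.copula, spec.locative_preposition,
                      det, loc, term]
            args = [("A1", patient), ("V", spec.copula), ("AM-LOC", loc)]
            sent = FrameAnnotatedSentence(
                tuple(tokens), (Frame(1, spec.copula, tuple(args)),))
            sent.validate(spec.roles)
            out.append(sent)
            continue
        agent = agents[rng.choice(len(agents), p=aw)]
        action = _draw(rng, spec.actions_given_agent[agent])
        patient = _draw(rng, spec.patients_given_action[action])
        tokens: list[str] = []
        args: list[tuple[str, str]] = []
        if spec.time_adverbs and rng.random() < spec.p_time:
            tmp = _draw(rng, spec.time_adverbs)
            tokens.append(tmp)
            args.append(("AM-TMP", tmp))
        tokens += [det, agent, action, det, patient]
        args = args + [("A0", agent), ("V", action), ("A1", patient)]
        if spec.manners_given_action.get(action) and rng.random() < spec.p_manner:
            mnr = _draw(rng, spec.manners_given_action[action])
            tokens.append(mnr)
            args.append(("AM-MNR", mnr))
        if spec.locations_given_action.get(action) and rng.random() < spec.p_location:
            loc = _draw(rng, spec.locations_given_action[action])
            tokens += [spec.locative_preposition, det, loc]
            args.append(("AM-LOC", loc))
        tokens.append(term)
        sent = FrameAnnotatedSentence(
            tuple(tokens), (Frame(1, action, tuple(args)),))
        sent.validate(spec.roles)
        out.append(sent)
    return out


# ---------------------------------------------------------------------------
# Bigram-chain language (analytic surprisal oracle for the LM)
# ---------------------------------------------------------------------------

@dataclass
class BigramChainSpec:
    """First-order Markov word chain with an absorbing terminator.

    Sentences start from ``start_probs`` and follow ``transitions`` until
    the terminator is emitted (or ``max_len`` is hit, when the terminator
    is forced; make its probability comfortably positive everywhere so this
    is rare).  Because the generating process is exactly first-order, the
    true surprisal of every word is available in closed form — the oracle a
    trained language model's surprisal estimates are judged against.
    """

    start_probs: dict[str, float]
    transitions: dict[str, dict[str, float]]
    terminator: str = "."
    max_len: int = 30

    def validate(self) -> None:
        _check_dist("start", self.start_probs)
        for w, d in self.transitions.items():
            _check_dist(f"transitions|{w}", d)
            if self.terminator not in d or d[self.terminator] <= 0:
                raise ValueError(f"state {w!r} cannot reach the terminator")


def default_bigram_chain() -> BigramChainSpec:
    words = ["ba", "do", "fi", "gu", "ke", "lo", "mi", "na"]
    n = len(words)
    start = {w: p for w, p in zip(words, (0.25, 0.2, 0.15, 0.12, 0.1, 0.08,
                                          0.06, 0.04))}
    trans = {}
    for i, w in enumerate(words):
        d = {words[(i + 1) % n]: 0.40, words[(i + 2) % n]: 0.20,
             words[(i + 3) % n]: 0.15, words[(i + 5) % n]: 0.10, ".": 0.15}
        trans[w] = d
    spec = BigramChainSpec(start, trans)
    spec.validate()
    return spec


def sample_bigram_corpus(spec: BigramChainSpec, n_sentences: int,
                         seed: int) -> list[tuple[str, ...]]:
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sentences):
        toks = [_draw(rng, spec.start_probs)]
        while toks[-1] != spec.terminator:
            if len(toks) >= spec.max_len - 1:
                toks.append(spec.terminator)
                break
            toks.append(_draw(rng, spec.transitions[toks[-1]]))
        out.append(tuple(toks))
    return out


def bigram_surprisal(spec: BigramChainSpec, tokens: Sequence[str]) -> np.ndarray:
    """Closed-form surprisal (nats) of each word under the generating chain."""
    out = [-np.log(spec.start_probs[tokens[0]])]
    for prev, cur in zip(tokens[:-1], tokens[1:]):
        out.append(-np.log(spec.transitions[prev][cur]))
    return np.array(out)


# ---------------------------------------------------------------------------
# Single-trial ERP generator
# ---------------------------------------------------------------------------

@dataclass
class ErpGeneratorSpec:
    """Generative mixed model for single-trial N400 amplitudes.

    ``n400 = intercept + b_baseline*baseline + b_su*(-SU) + b_surprisal*surp
    + u[subject] + s_su[subject]*(-SU) + s_surp[subject]*surp + w[word] + eps``

    SU enters negated: the N400 is a negative deflection, so a larger
    update maps to a more negative amplitude when its coefficient is
    positive on the flipped axis — the sign convention the analysis stage
    must reproduce.  Baselines are i.i.d. standard normal per trial.

    With ``standardize_predictors`` (the default) SU, surprisal and the
    baseline are z-scored inside the generator before entering the linear
    predictor, so planted coefficients are per-SD effects — the scale on
    which the analysis reports them — regardless of the raw predictor
    units; the analysis stage applies the identical transform, making
    planted and fitted coefficients directly comparable.
    """

    n_subjects: int = 12
    n_words: int = 600
    intercept: float = 0.0
    beta_baseline: float = -0.4
    beta_su: float = 0.2
    beta_surprisal: float = 0.15
    sd_subject: float = 0.5          # by-subject intercept SD
    sd_subject_slope_su: float = 0.1  # by-subject SU slope SD
    sd_subject_slope_surprisal: float = 0.0
    sd_word: float = 0.5             # by-word intercept SD
    sd_resid: float = 1.0
    standardize_predictors: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_words < 2:
            raise ValueError("need at least 2 subjects and 2 words")
        for name in ("sd_subject", "sd_subject_slope_su",
                     "sd_subject_slope_surprisal", "sd_word", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def draw_predictors(n_words: int, seed) -> pd.DataFrame:
    """Synthetic per-word SU and surprisal values (both nonnegative,
    right-skewed, weakly correlated) for generator-only simulations."""
    rng = np.random.default_rng(seed)
    shared = rng.gamma(2.0, 0.5, size=n_words)
    su = 0.8 * rng.gamma(2.0, 0.5, size=n_words) + 0.2 * shared
    surp = rng.gamma(3.0, 0.7, size=n_words) + 0.2 * shared
    return pd.DataFrame({
        "word": [f"w{i}" for i in range(n_words)],
        "su": su,
        "surprisal": surp,
    })


def generate_erp_trials(
    spec: ErpGeneratorSpec,
    predictors: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One row per (subject, word): N400 amplitude, baseline, and the raw
    predictor values.  Returns the table and all latent draws."""
    spec.validate()
    # independent child streams so predictor and latent draws never share bits
    ss_latents, ss_pred = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(ss_latents)
    if predictors is None:
        predictors = draw_predictors(spec.n_words, seed=ss_pred)
    if len(predictors) != spec.n_words:
        raise ValueError(
            f"predictors has {len(predictors)} rows, spec.n_words={spec.n_words}")
    if not np.isfinite(predictors[["su", "surprisal"]].to_numpy()).all():
        raise ValueError("predictor values must be finite")

    su = predictors["su"].to_numpy(float)
    surp = predictors["surprisal"].to_numpy(float)
    words = predictors["word"].to_numpy()
    S, W = spec.n_subjects, spec.n_words

    u_subj = spec.sd_subject * rng.standard_normal(S)
    s_su = spec.sd_subject_slope_su * rng.standard_normal(S)
    s_surp = spec.sd_subject_slope_surprisal * rng.standard_normal(S)
    w_word = spec.sd_word * rng.standard_normal(W)
    baseline = rng.standard_normal((S, W))
    eps = spec.sd_resid * rng.standard_normal((S, W))

    if spec.standardize_predictors:
        if su.std() == 0 or surp.std() == 0:
            raise ValueError("cannot standardize a constant predictor")
        su = (su - su.mean()) / su.std()
        surp = (surp - surp.mean()) / surp.std()
        base_lin = (baseline - baseline.mean()) / baseline.std()
    else:
        base_lin = baseline
    neg_su = -su[None, :]
    n400 = (spec.intercept
            + spec.beta_baseline * base_lin
            + spec.beta_su * neg_su
            + spec.beta_surprisal * surp[None, :]
            + u_subj[:, None]
            + s_su[:, None] * neg_su
            + s_surp[:, None] * surp[None, :]
            + w_word[None, :]
            + eps)

    table = pd.DataFrame({
        "subject": np.repeat([f"s{i}" for i in range(S)], W),
        "word": np.tile(words, S),
        "n400": n400.ravel(),
        "baseline": baseline.ravel(),
    })
    latents = {"u_subject": u_subj, "s_subject_su": s_su,
               "s_subject_surprisal": s_surp, "w_word": w_word, "eps": eps,
               "predictors": predictors}
    return table, latents


# ---------------------------------------------------------------------------
# EEG time-course generator
# ---------------------------------------------------------------------------

@dataclass
class TimecourseGeneratorSpec:
    """Long-format EEG with a planted effect curve.

    ``amplitude(s, w, e, t) = gain_e * beta(t) * x_w + b_baseline*baseline
    + u_s + v_w + noise``; ``beta(t)`` is a triangle (or boxcar) whose true
    fractional-area latency is computed analytically on a fine grid.
    """

    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 651.0, 25.0))
    shape: str = "triangle"          # or "boxcar"
    center: float = 400.0            # ms
    halfwidth: float = 150.0         # ms
    amplitude: float = 0.5
    electrodes: dict[str, float] = field(default_factory=lambda: {"roi": 1.0})
    beta_baseline: float = 0.0
    sd_subject: float = 0.0
    sd_word: float = 0.0
    noise_sd: float = 0.5
    standardize_predictor: bool = True
    n_subjects: int = 8
    n_words: int = 60
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size == 0:
            raise ValueError("empty time grid")
        if not (np.diff(t) > 0).all():
            raise ValueError("time grid must be strictly increasing")
        if not all(np.isfinite(g) for g in self.electrodes.values()):
            raise ValueError("electrode gains must be finite")
        if not self.electrodes:
            raise ValueError("need at least one electrode")

    def beta(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.shape == "triangle":
            return self.amplitude * np.clip(
                1.0 - np.abs(t - self.center) / self.halfwidth, 0.0, None)
        if self.shape == "boxcar":
            inside = np.abs(t - self.center) <= self.halfwidth
            return np.where(inside, self.amplitude, 0.0)
        if self.shape == "null":
            return np.zeros_like(t)
        raise ValueError(f"unknown effect shape {self.shape!r}")

    def true_latency(self, fraction: float = 0.5) -> float:
        """Fractional-area latency of beta(t) on a fine (0.01 ms) grid."""
        from scipy.integrate import cumulative_trapezoid
        t = np.asarray(self.times, dtype=float)
        grid = np.arange(t[0], t[-1] + 0.01, 0.01)
        c = np.abs(self.beta(grid))
        cum = cumulative_trapezoid(c, grid, initial=0.0)
        if cum[-1] <= 0:
            return float("nan")
        return float(np.interp(fraction * cum[-1], cum, grid))


def generate_timecourse(
    spec: TimecourseGeneratorSpec,
    predictors: pd.DataFrame | None = None,
    predictor_col: str = "su",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Returns (long EEG table, per-trial table with baselines, info dict
    with the true fractional-area latency and latent draws)."""
    spec.validate()
    # independent child streams so predictor and latent draws never share bits
    ss_latents, ss_pred = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(ss_latents)
    if predictors is None:
        predictors = draw_predictors(spec.n_words, seed=ss_pred)
        predictors = predictors.rename(columns={"su": predictor_col}) \
            if predictor_col not in predictors else predictors
    if len(predictors) != spec.n_words:
        raise ValueError("predictor rows must equal n_words")
    x = predictors[predictor_col].to_numpy(float)
    if spec.standardize_predictor:
        if x.std() == 0:
            raise ValueError("cannot standardize a constant predictor")
        x = (x - x.mean()) / x.std()
    words = predictors["word"].to_numpy()
    t = np.asarray(spec.times, dtype=float)
    S, W, T = spec.n_subjects, spec.n_words, t.size
    beta_t = spec.beta(t)

    u_s = spec.sd_subject * rng.standard_normal(S)
    v_w = spec.sd_word * rng.standard_normal(W)
    baseline = rng.standard_normal((S, W))

    frames = []
    for ename, gain in spec.electrodes.items():
        noise = spec.noise_sd * rng.standard_normal((S, W, T))
        amp = (gain * beta_t[None, None, :] * x[None, :, None]
               + spec.beta_baseline * baseline[:, :, None]
               + u_s[:, None, None] + v_w[None, :, None] + noise)
        frames.append(pd.DataFrame({
            "subject": np.repeat([f"s{i}" for i in range(S)], W * T),
            "word": np.tile(np.repeat(words, T), S),
            "electrode": ename,
            "time": np.tile(t, S * W),
            "amplitude": amp.ravel(),
        }))
    eeg = pd.concat(frames, ignore_index=True)
    trials = pd.DataFrame({
        "subject": np.repeat([f"s{i}" for i in range(S)], W),
        "word": np.tile(words, S),
        "baseline": baseline.ravel(),
    }).merge(predictors, on="word", how="left")
    info = {"true_latency": spec.true_latency(), "beta_t": beta_t,
            "u_subject": u_s, "v_word": v_w}
    return eeg, trials, info
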