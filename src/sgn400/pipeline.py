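"""End-to-end orchestration: micro-world corpus -> SG + LM training ->
stimulus scoring -> planted-effect ERP/EEG synthesis -> mixed-model
analysis, model comparison, time course and latency.

Every stage draws its randomness from a named seed derived from one base
seed, and the demo writes a manifest (config, derived seeds, library
versions) sufficient to re-run bit-identically on the same platform.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .corpus_io import (EncodingConfig, FrameAnnotatedSentence,
                        filter_training_sentences, write_frame_corpus)
from .erp_stats import (assemble_trials, compare_models, fdr_correct,
                        fit_mixed_model)
from .lm_model import LMConfig, LMModel, internal_update, lm_forward, surprisal, train_lm
from .sg_model import SGConfig, SGModel, score_su, semantic_update, sg_forward, train_sg
from .synthetic_data import (ErpGeneratorSpec, MicroWorldSpec,
                             TimecourseGeneratorSpec, default_microworld,
                             generate_erp_trials, generate_timecourse,
                             sample_corpus)
from .timecourse import (fit_timepointwise, fractional_area_latency,
                         per_subject_curves, per_subject_latency_test)

logger = logging.getLogger("sgn400")


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


@dataclass
class RunConfig:
    """Configuration of the end-to-end demo.

    ``scale`` is "desk" (small models, minutes on one CPU) or
    "paper-scale" (full layer sizes; provided for completeness, far slower).
    """

    seed: int = 0
    scale: str = "desk"
    outdir: str = "demo_out"
    n_train_sentences: int = 400
    n_stimulus_sentences: int = 60
    sg_epochs: int = 40
    lm_epochs: int = 30
    n_subjects: int = 12
    standardize: bool = True
    random_slopes: tuple[str, ...] = ("su",)
    latency_fraction: float = 0.5
    latency_window: tuple[float, float] = (0.0, 650.0)
    timecourse_step_ms: float = 25.0
    topo_window_ms: float = 50.0

    def derived_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(6)
        names = ("corpus", "sg", "lm", "stimuli", "erp", "eeg")
        return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}

    def sg_config(self, seed: int) -> SGConfig:
        if self.scale == "paper-scale":
            return SGConfig.paper_scale(seed=seed)
        return SGConfig(seed=seed, max_epochs=self.sg_epochs)

    def lm_config(self, seed: int) -> LMConfig:
        if self.scale == "paper-scale":
            return LMConfig.paper_scale(seed=seed)
        return LMConfig(seed=seed, max_epochs=self.lm_epochs)


def score_stimuli(
    sg: SGModel,
    lm: LMModel,
    stimuli: Sequence[FrameAnnotatedSentence],
) -> tuple[pd.DataFrame, dict]:
    """Per-word model predictors for a stimulus corpus.

    Returns one row per (sentence, position, token) with SU, surprisal and
    internal update, plus metadata reporting the SU-surprisal correlation
    over all scored tokens (an empirical property of the trained models,
    not an assertion)."""
    rows = []
    for i, sent in enumerate(stimuli):
        toks = sent.tokens if isinstance(sent, FrameAnnotatedSentence) else tuple(sent)
        su = semantic_update(sg_forward(sg, toks))
        dists, rtraj = lm_forward(lm, toks)
        surp = surprisal(lm, toks)
        upd = internal_update(rtraj)
        for j, tok in enumerate(toks):
            rows.append({"sentence_id": i, "position": j, "token": tok,
                         "word": f"s{i}w{j}", "su": su[j],
                         "surprisal": surp[j], "internal_update": upd[j]})
    df = pd.DataFrame(rows)
    corr = float(np.corrcoef(df["su"], df["surprisal"])[0, 1])
    meta = {"su_surprisal_correlation": corr, "n_tokens": len(df),
            "n_sentences": len(stimuli)}
    return df, meta


# ---------------------------------------------------------------------------
# SG effect battery
# ---------------------------------------------------------------------------

def _mean_su_at(sg: SGModel, items: Sequence[tuple], position: int | None = None
                ) -> float:
    vals = []
    for toks in items:
        su = semantic_update(sg_forward(sg, toks))
        vals.append(su[position] if position is not None else su.mean())
    return float(np.mean(vals))


def su_contrasts(sg: SGModel, world: MicroWorldSpec, seed: int = 0) -> dict[str, float]:
    """Mean-SU differences for the four classic contrasts on one trained
    model.  Positive differences go in the N400-like direction:
    incongruent > congruent, low cloze > high cloze, early position >
    late position, unrelated prime > related prime."""
    out = {}
    cong = world.congruity_items()
    out["congruity"] = (
        _mean_su_at(sg, [inc for _, inc, _ in cong], cong[0][2])
        - _mean_su_at(sg, [con for con, _, _ in cong], cong[0][2]))
    cloze = world.cloze_items()
    out["cloze"] = (
        _mean_su_at(sg, [lo for _, lo, _ in cloze], cloze[0][2])
        - _mean_su_at(sg, [hi for hi, _, _ in cloze], cloze[0][2]))
    sents = sample_corpus(world, 80, seed=seed + 7000)
    early, late = [], []
    for s in sents:
        su = semantic_update(sg_forward(sg, s.tokens))
        early.append(su[1:3].mean())          # drop the initial token
        late.append(su[-3:-1].mean())         # last two pre-terminator words
    out["position"] = float(np.mean(early) - np.mean(late))
    prim = world.priming_items()
    out["priming"] = (
        _mean_su_at(sg, [unrel for _, unrel, _ in prim], prim[0][2])
        - _mean_su_at(sg, [rel for rel, _, _ in prim], prim[0][2]))
    return out


def su_effect_battery(
    n_seeds: int = 12,
    world: MicroWorldSpec | None = None,
    n_sentences: int = 400,
    sg_epochs: int = 40,
    base_seed: int = 0,
) -> dict:
    """Train the SG model across seeds and sign-test the four contrasts.

    For each seed a fresh micro-world corpus is sampled and a fresh model
    trained; each contrast's per-seed mean-SU difference is recorded, and
    an exact one-sided binomial (sign) test asks whether the positive
    (N400-like) direction dominates across seeds.
    """
    from scipy.stats import binomtest
    world = world or default_microworld()
    diffs: dict[str, list[float]] = {}
    for k in range(n_seeds):
        seed = base_seed + 1000 * k
        corpus = filter_training_sentences(sample_corpus(world, n_sentences, seed))
        sg, _ = train_sg(corpus, SGConfig(seed=seed, max_epochs=sg_epochs))
        res = su_contrasts(sg, world, seed=seed)
        for name, d in res.items():
            diffs.setdefault(name, []).append(d)
        logger.info("battery seed %d/%d: %s", k + 1, n_seeds,
                    {n: round(d, 4) for n, d in res.items()})
    out = {}
    for name, ds in diffs.items():
        pos = int(np.sum(np.asarray(ds) > 0))
        p = binomtest(pos, len(ds), 0.5, alternative="greater").pvalue
        out[name] = {"diffs": ds, "n_positive": pos, "n_seeds": len(ds),
                     "sign_test_p": float(p)}
    return out


# ---------------------------------------------------------------------------
# Demo
# ---------------------------------------------------------------------------

def _table(result, predictors: Sequence[str]) -> dict:
    return {name: {"beta": round(fe.beta, 4), "t": round(fe.t, 3), "p": fe.p}
            for name, fe in result.fixed.items()
            if name in ("baseline",) + tuple(predictors)}


def run_demo(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and write) the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.derived_seeds()
    report: dict = {"stages": {}, "manifest": {
        "config": asdict(config), "seeds": seeds,
        "versions": {"sgn400": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__,
                     "python": sys.version.split()[0]},
    }}
    hashed_cfg = {k: v for k, v in asdict(config).items() if k != "outdir"}
    report["manifest"]["config_hash"] = hashlib.sha256(
        json.dumps(hashed_cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    t_start = time.perf_counter()

    def stage(name):
        t0 = time.perf_counter()
        def done():
            report["stages"][name] = round(time.perf_counter() - t0, 2)
            logger.info("stage %s: %.1fs", name, report["stages"][name])
        return done

    try:
        done = stage("corpus")
        world = default_microworld()
        corpus = filter_training_sentences(
            sample_corpus(world, config.n_train_sentences, seeds["corpus"]))
        write_frame_corpus(outdir / "corpus.jsonl", corpus)
        done()

        done = stage("train_sg")
        sg, sg_log = train_sg(corpus, config.sg_config(seeds["sg"]))
        sg.save(outdir / "sg_model.npz")
        done()

        done = stage("train_lm")
        lm, lm_log = train_lm(corpus, config.lm_config(seeds["lm"]))
        lm.save(outdir / "lm_model.npz")
        done()

        done = stage("score")
        stimuli = sample_corpus(world, config.n_stimulus_sentences, seeds["stimuli"])
        predictors, score_meta = score_stimuli(sg, lm, stimuli)
        predictors.to_csv(outdir / "predictors.csv", index=False)
        report["scoring"] = score_meta
        done()

        done = stage("simulate_erp")
        erp_spec = ErpGeneratorSpec(n_subjects=config.n_subjects,
                                    n_words=len(predictors), seed=seeds["erp"])
        erp, _ = generate_erp_trials(erp_spec, predictors)
        erp.to_csv(outdir / "erp_trials.csv", index=False)
        done()

        done = stage("n400_models")
        trials, asm_meta = assemble_trials(erp, predictors,
                                           standardize=config.standardize)
        trials.to_csv(outdir / "trials.csv", index=False)
        slopes = config.random_slopes
        m_su = fit_mixed_model(trials, fixed=("su",),
                               random_slopes=tuple(s for s in slopes if s == "su"))
        m_surp = fit_mixed_model(trials, fixed=("surprisal",), random_slopes=())
        m_both = fit_mixed_model(trials, fixed=("su", "surprisal"),
                                 random_slopes=tuple(s for s in slopes
                                                     if s in ("su", "surprisal")))
        m_surp_nested = fit_mixed_model(trials, fixed=("surprisal",),
                                        random_slopes=())
        m_su_nested = fit_mixed_model(trials, fixed=("su",), random_slopes=())
        m_both_flat = fit_mixed_model(trials, fixed=("su", "surprisal"),
                                      random_slopes=())
        cmp_add_su = compare_models(m_surp_nested, m_both_flat)
        cmp_add_surp = compare_models(m_su_nested, m_both_flat)
        interest_p = [m_su.fixed["su"].p, m_surp.fixed["surprisal"].p,
                      m_both.fixed["su"].p, m_both.fixed["surprisal"].p]
        p_adj, _ = fdr_correct(interest_p)
        report["tables"] = {
            "su_model": _table(m_su, ("su",)),
            "surprisal_model": _table(m_surp, ("surprisal",)),
            "joint_model": _table(m_both, ("su", "surprisal")),
            "fdr_adjusted_p": {
                "su_model.su": p_adj[0], "surprisal_model.surprisal": p_adj[1],
                "joint_model.su": p_adj[2], "joint_model.surprisal": p_adj[3]},
            "assembly": asm_meta,
        }
        report["comparisons"] = {
            "surprisal_vs_surprisal+su": {
                "chi2": round(cmp_add_su.chi2, 3), "df": cmp_add_su.df,
                "p": cmp_add_su.p, "delta_aic": round(cmp_add_su.delta_aic, 2)},
            "su_vs_su+surprisal": {
                "chi2": round(cmp_add_surp.chi2, 3), "df": cmp_add_surp.df,
                "p": cmp_add_surp.p, "delta_aic": round(cmp_add_surp.delta_aic, 2)},
        }
        done()

        done = stage("timecourse")
        times = np.arange(config.latency_window[0],
                          config.latency_window[1] + 0.1,
                          config.timecourse_step_ms)
        n_words_tc = min(len(predictors), 240)
        tc_pred = predictors.iloc[:n_words_tc].reset_index(drop=True)
        report["timecourse"] = {}
        latencies = {}
        subject_lat = {}
        for pred, center in (("su", 450.0), ("surprisal", 400.0)):
            tc_spec = TimecourseGeneratorSpec(
                times=times, center=center, n_subjects=config.n_subjects,
                n_words=n_words_tc, seed=seeds["eeg"] + (0 if pred == "su" else 1),
                sd_subject=0.2, sd_word=0.2, beta_baseline=-0.2)
            eeg, tc_trials, info = generate_timecourse(tc_spec, tc_pred,
                                                       predictor_col=pred)
            tcr = fit_timepointwise(eeg, tc_trials, predictor=pred,
                                    window=config.latency_window)
            lat = fractional_area_latency(tcr.times, tcr.beta,
                                          fraction=config.latency_fraction)
            latencies[pred] = lat
            curves = per_subject_curves(eeg, tc_trials, predictor=pred,
                                        window=config.latency_window)
            per_subj = []
            for subj in sorted(curves):
                ts, bs = curves[subj]
                try:
                    per_subj.append(fractional_area_latency(
                        ts, bs, fraction=config.latency_fraction))
                except ValueError:
                    per_subj.append(float("nan"))
            subject_lat[pred] = per_subj
            report["timecourse"][pred] = {
                "group_latency_ms": round(lat, 1),
                "true_latency_ms": round(info["true_latency"], 1),
                "n_significant_timepoints": int(tcr.mask.sum()),
            }
        lt = per_subject_latency_test(subject_lat["su"], subject_lat["surprisal"])
        report["timecourse"]["latency_t_test"] = {
            "mean_su_ms": round(lt.mean_a, 1),
            "mean_surprisal_ms": round(lt.mean_b, 1),
            "t": round(lt.t, 3), "p": round(lt.p, 4), "n": lt.n}
        done()
    except Exception as exc:
        report["failed_stage"] = [s for s in report["stages"]][-1] \
            if report["stages"] else "corpus"
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        raise RuntimeError(
            f"demo aborted (last completed stage set: {list(report['stages'])})"
        ) from exc

    report["total_seconds"] = round(time.perf_counter() - t_start, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
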