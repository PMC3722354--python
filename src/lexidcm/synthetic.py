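"""Synthetic study generation.

No patient data accompany this package, so every analysis stage is exercised
against synthetic inputs with known ground truth: word lists with
controllable orthographic overlap, reading-trial tables with a known
item-specific training effect, adaptive-training session logs, and MEG epoch
sets generated from a known source network with known condition gains.  All
generators are pure functions of their configuration and seed.

The default conditions emulate the study design the package targets: four
assessment time points (two pre-training, one immediately post-training, one
follow-up), 128-trial word-reading tests balanced over 3-6 letter words and
two 500-word lists, a trained-word speed-up around 11.5% appearing at the
third time point (larger for longer words, partially reverting at follow-up),
and MEG sessions with 50 trials per word list plus labelled catch trials at
480 Hz.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet
from .dynamics import DCMParameters, default_parameters, simulate_sources
from .forward import (
    LeadField,
    SensorArray,
    build_leadfield,
    helmet_array,
    project_to_sensors,
    tangential_orientations,
)
from .network import ModelSpace
from .behavior import ladder_transition

__all__ = [
    "WordListSimConfig",
    "BehaviorSimConfig",
    "MEGSimConfig",
    "generate_word_lists",
    "generate_reading_trials",
    "generate_training_log",
    "generate_meg_group",
]

TIMEPOINTS = ("t1", "t2", "t3", "t4")
#: generator condition labels; the modulated condition is the trained list
CONDITION_BASELINE = "untrained"
CONDITION_MODULATED = "trained"


# ---------------------------------------------------------------------------
# Word lists


@dataclass
class WordListSimConfig:
    n_words: int = 500
    min_length: int = 3
    max_length: int = 6
    overlap: str = "matched"  # "matched" (shared alphabet) | "zero"
    seed: int = 0


_VOWELS = "aeiou"
_CONSONANTS = "".join(c for c in string.ascii_lowercase if c not in _VOWELS)


def _make_word(rng, length: int, consonants: str, vowels: str) -> str:
    # alternating consonant/vowel gives pronounceable-ish strings
    out = []
    for i in range(length):
        pool = consonants if i % 2 == 0 else vowels
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def generate_word_lists(config: WordListSimConfig) -> tuple[list[str], list[str], dict]:
    """Two disjoint word lists with identical length histograms.

    ``overlap="matched"`` draws both lists from the same alphabet (so
    between-list n-gram overlap is substantial, as in matched stimulus
    lists); ``overlap="zero"`` uses disjoint alphabets, forcing a
    between-list bigram index of exactly 0 for every word.  Returns the two
    lists and a report with the achieved mean between-list bigram index.
    """
    if config.overlap not in ("matched", "zero"):
        raise ValueError("overlap must be 'matched' or 'zero'")
    rng = np.random.default_rng(config.seed)
    if config.overlap == "zero":
        pools = [(_CONSONANTS[:10], "aei"), (_CONSONANTS[10:], "ouy")]
    else:
        pools = [(_CONSONANTS, _VOWELS)] * 2
    lengths = np.arange(config.min_length, config.max_length + 1)
    per_len = np.full(lengths.size, config.n_words // lengths.size)
    per_len[: config.n_words - per_len.sum()] += 1
    lists: list[list[str]] = []
    used: set[str] = set()
    for cons, vows in pools:
        words: list[str] = []
        for L, k in zip(lengths, per_len):
            made = 0
            while made < k:
                w = _make_word(rng, int(L), cons, vows)
                if w not in used:
                    used.add(w)
                    words.append(w)
                    made += 1
        lists.append(words)
    from .behavior import ngram_frequency_index

    between = [ngram_frequency_index(w, lists[1], 2) for w in lists[0]]
    report = {"mean_between_list_bigram_index": float(np.mean(between))}
    if config.overlap == "zero" and report["mean_between_list_bigram_index"] > 0:
        raise AssertionError("zero-overlap construction violated")
    return lists[0], lists[1], report


# ---------------------------------------------------------------------------
# Reading trials


@dataclass
class BehaviorSimConfig:
    """Reading-trial generator.

    ``training_effect`` is the proportional RT reduction for trained words
    at t3, averaged over word lengths; ``length_interaction`` tilts the
    reduction toward longer words (per letter, centred on the mean length so
    the collapsed effect stays at ``training_effect``).  ``t4_retention`` is
    the fraction of the effect remaining at follow-up.  RT noise is
    lognormal (naming latencies are right-skewed).
    """

    n_subjects: int = 9
    n_trials_per_timepoint: int = 128
    base_rt_ms: float = 1308.0
    subject_sd_log: float = 0.25
    wle_slope_ms: float = 173.0
    training_effect: float = 0.115
    length_interaction: float = 0.15
    t4_retention: float = 0.5
    noise_sigma: float = 0.15
    outcome_rates: dict = field(
        default_factory=lambda: {
            "correct": 0.878,
            "error": 0.04,
            "self_corrected": 0.02,
            "omitted": 0.03,
            "voicekey_fail": 0.032,
        }
    )
    min_length: int = 3
    max_length: int = 6
    seed: int = 0


def generate_reading_trials(
    config: BehaviorSimConfig, word_lists: tuple[list[str], list[str]] | None = None
) -> pd.DataFrame:
    """Trial table spanning t1-t4 for every subject.

    Each timepoint holds trials balanced over length x list; trained-list
    RTs shrink by the training effect at t3 (attenuated at t4).  Columns
    match the behavioural module's expected schema plus a subject id.
    """
    rates = config.outcome_rates
    if abs(sum(rates.values()) - 1.0) > 1e-9:
        raise ValueError("outcome rates must sum to 1")
    if not 0.0 <= config.training_effect < 1.0:
        raise ValueError("training effect must be in [0, 1)")
    rng = np.random.default_rng(config.seed)
    if word_lists is None:
        wl = WordListSimConfig(seed=config.seed)
        list_a, list_b, _ = generate_word_lists(wl)
    else:
        list_a, list_b = word_lists
    by_len = {
        name: {
            L: [w for w in lst if len(w) == L]
            for L in range(config.min_length, config.max_length + 1)
        }
        for name, lst in (("trained", list_a), ("untrained", list_b))
    }
    lengths = list(range(config.min_length, config.max_length + 1))
    n_cell = config.n_trials_per_timepoint // (len(lengths) * 2)
    mean_len = float(np.mean(lengths))
    outcomes = list(rates)
    probs = np.array([rates[o] for o in outcomes])
    rows = []
    for s in range(config.n_subjects):
        base = config.base_rt_ms * float(np.exp(rng.normal(0.0, config.subject_sd_log)))
        for tp in TIMEPOINTS:
            for lst in ("trained", "untrained"):
                for L in lengths:
                    words = by_len[lst][L]
                    pick = rng.choice(len(words), size=n_cell, replace=False)
                    for wi in pick:
                        mu = base + config.wle_slope_ms * (L - config.min_length)
                        factor = 1.0
                        if lst == "trained" and tp in ("t3", "t4"):
                            eff = config.training_effect * (
                                1.0 + config.length_interaction * (L - mean_len)
                            )
                            if tp == "t4":
                                eff *= config.t4_retention
                            factor = 1.0 - eff
                        rt = mu * factor * float(np.exp(rng.normal(0.0, config.noise_sigma)))
                        outcome = outcomes[rng.choice(len(outcomes), p=probs)]
                        rows.append(
                            {
                                "subject": f"S{s + 1:02d}",
                                "word": words[wi],
                                "length": L,
                                "list": lst,
                                "timepoint": tp,
                                "rt_ms": rt
                                if outcome not in ("omitted", "voicekey_fail")
                                else np.nan,
                                "outcome": outcome,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Training logs


def generate_training_log(
    accuracy: float | dict[str, float],
    n_blocks: int = 20,
    n_words: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Adaptive-training session log.

    Alternates training blocks of ``n_words`` audio-visual word pairs with
    testing blocks in which each word is probed once (half 'same', half
    'different' trials).  'Different' trials move the word's difficulty one
    level up on a correct response and one level down on an error; every
    correct test response earns one pence.  ``accuracy`` is the probability
    of a correct response, optionally per level.
    """
    if isinstance(accuracy, dict):
        acc = {lvl: float(accuracy[lvl]) for lvl in ("easy", "medium", "hard")}
    else:
        acc = {lvl: float(accuracy) for lvl in ("easy", "medium", "hard")}
    for v in acc.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("accuracy probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    levels = {w: "easy" for w in range(n_words)}
    pence = 0
    rows = []
    for block in range(n_blocks):
        # testing block follows each training block; 'same'/'different' split
        kinds = np.array(["same", "different"] * (n_words // 2 + 1))[:n_words]
        rng.shuffle(kinds)
        for w in range(n_words):
            lvl = levels[w]
            correct = bool(rng.random() < acc[lvl])
            if kinds[w] == "different":
                new_lvl, reward = ladder_transition(lvl, correct)
                levels[w] = new_lvl
            else:
                reward = int(correct)
            pence += reward
            rows.append(
                {
                    "block": block,
                    "word_id": w,
                    "trial_type": kinds[w],
                    "level": lvl,
                    "correct": correct,
                    "pence_total": pence,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MEG epochs


@dataclass
class MEGSimConfig:
    """Ground-truth MEG group generator.

    ``true_gains`` maps switched-on group names of ``space`` to the
    condition gain applied to their member connections (a value of 1.5
    means those connections are 50% stronger for trained words).  Groups
    absent from the mapping keep gain 1.  ``snr`` is the per-trial ratio of
    clean-signal RMS to sensor-noise SD.
    """

    space: ModelSpace = None
    true_pattern_index: int = 0
    true_gains: dict = field(default_factory=dict)
    n_trials: int = 50
    n_catch: int = 10
    snr: float = 10.0
    n_subjects: int = 8
    n_sensors: int = 275
    subject_jitter_sd: float = 0.1
    window_ms: tuple = (-100.0, 1000.0)
    dt: float = 1.0 / 480.0
    seed: int = 0


def _truth_params(config: MEGSimConfig) -> DCMParameters:
    params = default_parameters(config.space.network)
    pattern = config.space.patterns[config.true_pattern_index]
    by_name = {g.name: (g, on) for g, on in zip(config.space.groups, pattern)}
    for gname, gain in config.true_gains.items():
        grp, on = by_name[gname]
        if not on:
            raise ValueError(
                f"group {gname!r} carries a true gain but is off in the true pattern"
            )
        for c in grp.members:
            if c.klass == "self":
                params.self_B[c.source] = float(gain)
            else:
                params.B[c.name] = float(gain)
    return params


def generate_meg_group(
    config: MEGSimConfig, sensors: SensorArray | None = None
) -> tuple[list[EpochSet], LeadField, dict]:
    """Per-subject two-condition epoch sets from a known network.

    Each subject's extrinsic strengths get independent log-normal jitter
    (population heterogeneity); condition gains are shared, matching a
    random-effects target.  Trials are the clean projected evoked response
    plus i.i.d. Gaussian sensor noise at the configured SNR; catch trials
    (pure noise, labelled ``"catch"``) are included but flagged for
    exclusion.  Returns the epoch sets, the lead field used, and a
    ground-truth record sufficient to score recovery without re-simulation.
    """
    if config.space is None:
        raise ValueError("config.space is required")
    rng = np.random.default_rng(config.seed)
    net = config.space.network
    locs = np.array([n.prior_location_mm for n in net.nodes])
    oris = tangential_orientations(locs)
    if sensors is None:
        sensors = helmet_array(config.n_sensors)
    leadfield = build_leadfield(locs, oris, sensors)
    pattern = config.space.patterns[config.true_pattern_index]
    truth_base = _truth_params(config)
    pres = np.arange(config.window_ms[0], 0.0 - 1e-9, config.dt * 1000.0)

    epoch_sets = []
    truth = {
        "pattern_index": int(config.true_pattern_index),
        "pattern": pattern.tolist(),
        "true_gains": dict(config.true_gains),
        "subjects": [],
    }
    for s in range(config.n_subjects):
        params = truth_base.copy()
        for cn in params.A:
            params.A[cn] = params.A[cn] * float(np.exp(rng.normal(0.0, config.subject_jitter_sd)))
        clean = {}
        for condition, label in (
            ("baseline", CONDITION_BASELINE),
            ("modulated", CONDITION_MODULATED),
        ):
            act = simulate_sources(
                params, pattern, config.space, condition,
                duration_ms=config.window_ms[1], dt=config.dt,
            )
            sensor = leadfield.gain.T @ act.values.T  # (n_sensors, n_post)
            full = np.concatenate(
                [np.zeros((sensor.shape[0], pres.size)), sensor], axis=1
            )
            clean[label] = (full, np.concatenate([pres, act.times_ms]))
        rms = float(
            np.sqrt(np.mean(np.stack([c[0] for c in clean.values()]) ** 2))
        )
        noise_sd = rms / config.snr if rms > 0 else 1.0
        times = clean[CONDITION_BASELINE][1]
        data, labels = [], []
        for label in (CONDITION_MODULATED, CONDITION_BASELINE):
            sig = clean[label][0]
            trials = sig[None] + rng.normal(0.0, noise_sd, size=(config.n_trials, *sig.shape))
            data.append(trials)
            labels.extend([label] * config.n_trials)
        if config.n_catch:
            data.append(rng.normal(0.0, noise_sd, size=(config.n_catch, *sig.shape)))
            labels.extend(["catch"] * config.n_catch)
        epoch_sets.append(
            EpochSet(np.concatenate(data), times, labels, dt=config.dt, provenance="simulated")
        )
        truth["subjects"].append(
            {
                "subject": f"S{s + 1:02d}",
                "noise_sd": noise_sd,
                "A": {k: float(v) for k, v in params.A.items()},
                "seedstream": s,
            }
        )
    return epoch_sets, leadfield, truth
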