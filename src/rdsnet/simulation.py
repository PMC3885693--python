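"""Synthetic recruitment forests and Markov-assumption simulations.

Two jobs live here.

First, a Monte-Carlo check of the first-order Markov assumption: if the
attribute dependence along a recruitment chain extends only one link, the
correlation between members at tree distance d should decay geometrically,
like rho**d.  :func:`simulate_ar1_on_forest` simulates a first-order
autoregressive process on a *fixed* observed forest — seeds draw standard
normals, each recruit is ``rho * parent + sqrt(1 - rho^2) * noise`` (so the
marginal stays standard normal at every depth) — and returns the
distribution of distance-d correlations across replicates, for comparison
with an observed distance profile.

Second, a full synthetic-cohort generator so every pipeline stage is
testable without survey data.  Recruitment topology is a coupon-limited
branching process; continuous traits follow the AR(1) law above (rescaled to
an age-like mean and SD); categorical traits follow a Markov
child-given-parent transition matrix along edges with seeds drawn from its
stationary distribution; the diary degree is negative binomial and split
across travel modes and locations; households, meals and symptoms are drawn
independently.  Defaults mirror the pilot survey this package models: four
coupons per respondent, roughly one recruit in four completing, degree mean
about 88 with dispersion about 0.6, and edge assortativity of about 0.55
for age, 0.2 for gender and 0.5 for education.

All randomness flows from one integer seed through ``numpy`` seed
sequences; replicates use spawned child streams, so results do not depend
on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .forest import RecruitmentForest, build_forest
from .records import (
    CHANNELS,
    LOCATIONS,
    MEALS,
    ParticipantRecord,
    SYMPTOMS,
    TRAVEL_MODES,
    WEEKDAYS,
)


def mixture_transition(stationary, stay: float) -> np.ndarray:
    """Row-stochastic matrix: copy the parent w.p. ``stay``, else draw fresh.

    ``T = stay * I + (1 - stay) * 1 pi'`` has stationary distribution ``pi``
    and gives correlation ``stay`` between any scoring of parent and child —
    and ``stay**d`` at tree distance d, the geometric decay a first-order
    Markov process implies.
    """
    pi = np.asarray(stationary, dtype=float)
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("stationary distribution must sum to 1")
    if not 0.0 <= stay <= 1.0:
        raise ValueError("stay probability must be in [0, 1]")
    k = len(pi)
    return stay * np.eye(k) + (1.0 - stay) * np.tile(pi, (k, 1))


@dataclass
class CategoricalTrait:
    """Levels plus the child-given-parent transition matrix."""

    levels: tuple
    transition: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (len(self.levels), len(self.levels)):
            raise ValueError("transition shape must match levels")
        if not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        self.transition = t

    def stationary(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.transition.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        return pi / pi.sum()


def _default_gender() -> CategoricalTrait:
    return CategoricalTrait(("female", "male"),
                            mixture_transition([0.616, 0.384], 0.205))


def _default_education() -> CategoricalTrait:
    return CategoricalTrait(
        ("below_bachelor", "bachelor", "master_or_higher"),
        mixture_transition([0.16, 0.63, 0.21], 0.52),
    )


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort.

    Topology: ``n_seeds`` seeds each hand out ``coupons`` invitations; each
    coupon independently yields a completed recruit with probability
    ``participation_prob``; recruitment stops after ``max_waves`` waves.
    ``noncomplete_prob`` is the chance a coupon yields someone who enters
    but never finishes (they appear in the table with missing counts).

    Attributes: ``rho`` is the recruiter-recruit (lag-1) correlation of the
    latent age trait, mapped to ``age_mean`` / ``age_sd`` years;
    categorical traits carry their own transition matrices.  ``nb_mu`` /
    ``nb_k`` parameterize the negative binomial diary degree;
    ``degree_edge_corr`` optionally correlates degree along edges through a
    Gaussian copula (0 = degree independent of the tree, the default,
    matching the random-by-degree mixing the survey observed).
    """

    n_seeds: int = 80
    coupons: int = 4
    participation_prob: float = 0.24
    noncomplete_prob: float = 0.048
    max_waves: int = 6
    rho: float = 0.555
    age_mean: float = 26.7
    age_sd: float = 6.73
    gender: CategoricalTrait = field(default_factory=_default_gender)
    education: CategoricalTrait = field(default_factory=_default_education)
    nb_mu: float = 88.2
    nb_k: float = 0.57
    degree_edge_corr: float = 0.0
    travel_fraction_ab: tuple = (2.0, 4.7)
    travel_mode_weights: tuple = (0.30, 0.37, 0.25, 0.08)
    location_weights: tuple = (0.15, 0.25, 0.25, 0.15, 0.10, 0.05, 0.05)
    eating_mu: float = 6.5
    eating_k: float = 1.2
    household_sizes: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    household_weights: tuple = (0.204, 0.095, 0.163, 0.204, 0.145,
                                0.068, 0.055, 0.037, 0.018, 0.011)
    symptom_rate: float = 1.8
    household_symptom_rate: float = 0.5
    channel_weights: tuple = (0.80, 0.10, 0.10)  # facebook, direct, forwarded
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.participation_prob <= 1.0:
            raise ValueError("participation_prob must be in [0, 1]")
        if not abs(self.rho) <= 1.0:
            raise ValueError("|rho| must be <= 1")
        if self.nb_mu <= 0 or self.nb_k <= 0:
            raise ValueError("nb_mu and nb_k must be positive")
        if self.coupons < 1 or self.n_seeds < 1 or self.max_waves < 0:
            raise ValueError("n_seeds, coupons >= 1 and max_waves >= 0 required")


def generate_forest(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> RecruitmentForest:
    """Coupon-limited branching process over completed participants.

    Each completed respondent issues ``coupons`` invitations; each
    independently yields a completed recruit with ``participation_prob``;
    the process is truncated after ``max_waves`` waves.  Node pids are
    assigned in breadth-first order, zero-padded so lexicographic order
    matches creation order.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    parents: list[Optional[str]] = [None] * config.n_seeds
    counter = 0

    def next_pid() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:06d}"

    records = []
    frontier = []
    for _ in range(config.n_seeds):
        pid = next_pid()
        records.append(ParticipantRecord(pid=pid, recruiter_pid=None))
        frontier.append(pid)
    wave = 0
    while frontier and wave < config.max_waves:
        nxt = []
        n_children = rng.binomial(config.coupons, config.participation_prob,
                                  size=len(frontier))
        for parent, n_child in zip(frontier, n_children):
            for _ in range(int(n_child)):
                pid = next_pid()
                records.append(ParticipantRecord(pid=pid, recruiter_pid=parent))
                nxt.append(pid)
        frontier = nxt
        wave += 1
    return build_forest(records, max_coupons=config.coupons)


def _wave_order(forest: RecruitmentForest):
    """Node pids sorted wave-major (parents always precede children)."""
    return sorted(forest.wave, key=lambda pid: (forest.wave[pid], pid))


def ar1_values(forest: RecruitmentForest, rho: float,
               rng: np.random.Generator) -> dict:
    """One draw of the AR(1)-on-tree process; pid -> standard-normal value."""
    order = _wave_order(forest)
    idx = {pid: i for i, pid in enumerate(order)}
    noise = rng.standard_normal(len(order))
    values = np.empty(len(order))
    scale = np.sqrt(1.0 - rho * rho)
    for i, pid in enumerate(order):
        parent = forest.recruiter_of(pid)
        if parent is None:
            values[i] = noise[i]
        else:
            values[i] = rho * values[idx[parent]] + scale * noise[i]
    return {pid: float(values[idx[pid]]) for pid in order}


def _distance_pair_indices(forest: RecruitmentForest, max_d: int) -> dict:
    """distance label -> (i_idx, j_idx) arrays into wave-major node order."""
    from .assortativity import pairs_at_distance

    order = _wave_order(forest)
    idx = {pid: i for i, pid in enumerate(order)}
    out = {}
    specs = [(d, False) for d in range(1, max_d)] + [(max_d, True)]
    for d, lump in specs:
        dp = pairs_at_distance(forest, d, "symmetrized", lump=lump)
        if dp.pairs:
            i_idx = np.fromiter((idx[i] for i, _ in dp.pairs), dtype=np.intp)
            j_idx = np.fromiter((idx[j] for _, j in dp.pairs), dtype=np.intp)
            out[dp.distance] = (i_idx, j_idx)
    return out


def simulate_ar1_on_forest(
    forest: RecruitmentForest,
    rho: float,
    n_reps: int = 2000,
    rng_seed: int = 0,
    max_d: int = 5,
) -> dict:
    """Monte-Carlo distance-correlation envelopes under the AR(1) null.

    Returns ``{"distances": [...], "correlations": {dist: array of reps},
    "summary": DataFrame}`` where the summary holds the median and central
    95% envelope of the distance-d correlation across replicates.  NaN
    correlations (degenerate replicates on tiny forests) are dropped from
    the summaries.
    """
    if not abs(rho) <= 1.0:
        raise ValueError("|rho| must be <= 1")
    pair_idx = _distance_pair_indices(forest, max_d)
    order = _wave_order(forest)
    idx = {pid: i for i, pid in enumerate(order)}
    parent_idx = np.array(
        [idx[forest.recruiter_of(pid)] if forest.recruiter_of(pid) else -1
         for pid in order],
        dtype=np.intp,
    )
    scale = np.sqrt(1.0 - rho * rho)
    streams = np.random.SeedSequence(rng_seed).spawn(n_reps)
    corrs = {dist: np.full(n_reps, np.nan) for dist in pair_idx}
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        noise = rng.standard_normal(len(order))
        values = np.empty(len(order))
        for i in range(len(order)):
            p = parent_idx[i]
            values[i] = noise[i] if p < 0 else rho * values[p] + scale * noise[i]
        for dist, (i_idx, j_idx) in pair_idx.items():
            x, y = values[i_idx], values[j_idx]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            corrs[dist][rep] = np.corrcoef(x, y)[0, 1]

    import pandas as pd

    rows = []
    for dist, arr in corrs.items():
        ok = arr[~np.isnan(arr)]
        rows.append(
            {
                "distance": dist,
                "n_reps": int(ok.size),
                "median": float(np.median(ok)) if ok.size else float("nan"),
                "mean": float(ok.mean()) if ok.size else float("nan"),
                "lo95": float(np.quantile(ok, 0.025)) if ok.size else float("nan"),
                "hi95": float(np.quantile(ok, 0.975)) if ok.size else float("nan"),
            }
        )
    return {
        "distances": list(pair_idx),
        "correlations": corrs,
        "summary": pd.DataFrame(rows),
    }


def _nb_quantile_from_normal(z: np.ndarray, mu: float, k: float) -> np.ndarray:
    p = k / (k + mu)
    u = stats.norm.cdf(z)
    return stats.nbinom.ppf(np.clip(u, 1e-12, 1 - 1e-12), k, p).astype(np.int64)


def _categorical_on_tree(trait: CategoricalTrait, forest: RecruitmentForest,
                         order, idx, rng: np.random.Generator) -> dict:
    pi = trait.stationary()
    codes = np.empty(len(order), dtype=np.intp)
    for i, pid in enumerate(order):
        parent = forest.recruiter_of(pid)
        if parent is None:
            codes[i] = rng.choice(len(pi), p=pi)
        else:
            codes[i] = rng.choice(len(pi), p=trait.transition[codes[idx[parent]]])
    return {pid: trait.levels[codes[idx[pid]]] for pid in order}


def generate_dataset(config: SimulationConfig) -> list[ParticipantRecord]:
    """Full synthetic participant table (see module docstring).

    Deterministic given ``config.rng_seed``; the forest, every trait and
    the incomplete-entry records each use their own spawned stream.
    """
    root = np.random.SeedSequence(config.rng_seed)
    (ss_forest, ss_age, ss_gender, ss_edu, ss_degree, ss_split,
     ss_eat, ss_house, ss_sympt, ss_misc, ss_noncomplete) = root.spawn(11)

    forest = generate_forest(config, np.random.default_rng(ss_forest))
    order = _wave_order(forest)
    idx = {pid: i for i, pid in enumerate(order)}
    n = len(order)

    age_z = ar1_values(forest, config.rho, np.random.default_rng(ss_age))
    ages = {
        pid: int(round(config.age_mean + config.age_sd * age_z[pid]))
        for pid in order
    }
    genders = _categorical_on_tree(config.gender, forest, order, idx,
                                   np.random.default_rng(ss_gender))
    educations = _categorical_on_tree(config.education, forest, order, idx,
                                      np.random.default_rng(ss_edu))

    rng_deg = np.random.default_rng(ss_degree)
    if config.degree_edge_corr != 0.0:
        z = ar1_values(forest, config.degree_edge_corr, rng_deg)
        totals = _nb_quantile_from_normal(
            np.array([z[pid] for pid in order]), config.nb_mu, config.nb_k
        )
    else:
        p = config.nb_k / (config.nb_k + config.nb_mu)
        totals = rng_deg.negative_binomial(config.nb_k, p, size=n)

    rng_split = np.random.default_rng(ss_split)
    travel_frac = rng_split.beta(*config.travel_fraction_ab, size=n)
    travel_totals = rng_split.binomial(totals, travel_frac)
    location_totals = totals - travel_totals
    travel_counts = np.vstack([
        rng_split.multinomial(t, config.travel_mode_weights)
        for t in travel_totals
    ]) if n else np.zeros((0, len(TRAVEL_MODES)), dtype=int)
    location_counts = np.vstack([
        rng_split.multinomial(t, config.location_weights)
        for t in location_totals
    ]) if n else np.zeros((0, len(LOCATIONS)), dtype=int)

    rng_eat = np.random.default_rng(ss_eat)
    p_eat = config.eating_k / (config.eating_k + config.eating_mu)
    eat_totals = rng_eat.negative_binomial(config.eating_k, p_eat, size=n)
    eat_counts = np.vstack([
        rng_eat.multinomial(t, [0.15, 0.35, 0.35, 0.15]) for t in eat_totals
    ]) if n else np.zeros((0, len(MEALS)), dtype=int)

    rng_house = np.random.default_rng(ss_house)
    households = rng_house.choice(config.household_sizes, size=n,
                                  p=config.household_weights)
    rng_sympt = np.random.default_rng(ss_sympt)
    symptom_counts = np.minimum(
        rng_sympt.poisson(config.symptom_rate, size=n), len(SYMPTOMS)
    )
    household_sympt = np.minimum(
        rng_sympt.poisson(config.household_symptom_rate, size=n), households
    )

    rng_misc = np.random.default_rng(ss_misc)
    weekdays = rng_misc.choice(WEEKDAYS, size=n)
    recruiter_channel: dict[str, str] = {}
    channels = ("facebook", "direct_email", "forwarded_email")

    records = []
    for i, pid in enumerate(order):
        recruiter = forest.recruiter_of(pid)
        if recruiter is None:
            channel = "unknown"
        else:
            if recruiter not in recruiter_channel:
                recruiter_channel[recruiter] = channels[
                    rng_misc.choice(3, p=config.channel_weights)
                ]
            channel = recruiter_channel[recruiter]
        symptoms = set(
            rng_sympt.choice(SYMPTOMS, size=int(symptom_counts[i]), replace=False)
        )
        records.append(
            ParticipantRecord(
                pid=pid,
                recruiter_pid=recruiter,
                channel=channel,
                completed=True,
                age=ages[pid],
                gender=genders[pid],
                education=educations[pid],
                region_code=None,
                household_size=int(households[i]),
                travel_contacts=dict(zip(TRAVEL_MODES, map(int, travel_counts[i]))),
                location_contacts=dict(zip(LOCATIONS, map(int, location_counts[i]))),
                eating_contacts=dict(zip(MEALS, map(int, eat_counts[i]))),
                symptoms=symptoms,
                household_symptomatic=int(household_sympt[i]),
                diary_weekday=str(weekdays[i]),
            )
        )

    # entrants who never finished: leaf children of completers with spare coupons
    rng_nc = np.random.default_rng(ss_noncomplete)
    if config.noncomplete_prob > 0:
        counter = n
        for pid in order:
            if forest.wave[pid] >= config.max_waves:
                continue
            spare = config.coupons - forest.graph.out_degree(pid)
            n_extra = rng_nc.binomial(spare, config.noncomplete_prob)
            for _ in range(int(n_extra)):
                counter += 1
                if pid not in recruiter_channel:
                    recruiter_channel[pid] = channels[
                        rng_nc.choice(3, p=config.channel_weights)
                    ]
                records.append(
                    ParticipantRecord(
                        pid=f"P{counter:06d}",
                        recruiter_pid=pid,
                        channel=recruiter_channel[pid],
                        completed=False,
                    )
                )
    return records
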