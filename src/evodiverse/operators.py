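"""Reproduction pipeline of the memetic EA.

Four pieces: the Metropolis acceptance rule with scaling parameter alpha
(alpha = 0 never accepts uphill moves; larger alpha is more permissive via
the Boltzmann form exp(-dE/alpha)); a two-stage Monte Carlo initial
population operator (steric-only randomization with alpha = 0, then a
secondary-structure stage with alpha = 2 that stops after l consecutive
rejections); an asexual variation operator applying exactly one
unconditionally-accepted f=3 fragment replacement; and a greedy improvement
operator that walks an offspring downhill on the compaction score until k
consecutive proposals fail to strictly lower it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .backbone import Conformation, build_extended
from .energy import ScoreModel
from .errors import InputError
from .fragments import FragmentLibrary, apply_move, sample_move


@dataclass(frozen=True)
class InitConfig:
    """Two-stage initialization parameters.

    ``n_stage1`` is the number of attempted steric-stage moves per
    conformation (default 5*l when None); ``alpha_stage1``/``alpha_stage2``
    scale the Metropolis acceptance of the two stages. Stage 2 terminates
    after l consecutive rejected moves, or after ``n_stage2_max`` attempted
    moves (default 20*l when None): the coarse square-well score is
    piecewise constant, so zero-difference moves are always accepted at
    alpha > 0 and the consecutive-failure rule alone need not terminate.
    """

    n_stage1: int | None = None
    alpha_stage1: float = 0.0
    alpha_stage2: float = 2.0
    n_stage2_max: int | None = None

    def __post_init__(self):
        if self.alpha_stage1 < 0 or self.alpha_stage2 < 0:
            raise InputError("alpha must be non-negative")
        for name in ("n_stage1", "n_stage2_max"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InputError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ImprovementConfig:
    """Greedy local-search parameters: stop after ``k`` consecutive failures
    (default l when None); fragment length is fixed at 3."""

    k: int | None = None

    def __post_init__(self):
        if self.k is not None and self.k < 0:
            raise InputError("k must be non-negative")


def metropolis_accept(delta_e, alpha, rng) -> bool:
    """Metropolis criterion: always accept downhill; accept uphill with
    probability exp(-delta_e / alpha), which is 0 when alpha = 0.

    At alpha = 0 a move is accepted only if it strictly lowers the score
    (ties rejected); at alpha > 0 the standard criterion applies, so a
    score-preserving move (dE = 0) is accepted with probability exp(0) = 1.
    With the coarse square-well score exact ties are common, which is why
    stage-2 initialization carries an attempt cap (see InitConfig).
    """
    if not math.isfinite(delta_e):
        raise InputError("delta_e must be finite")
    if alpha < 0:
        raise InputError("alpha must be non-negative")
    if delta_e < 0:
        return True
    if alpha == 0:
        return False
    return rng.random() < math.exp(-delta_e / alpha)


def init_population(sequence, n, lib9: FragmentLibrary, model: ScoreModel,
                    config: InitConfig = InitConfig(), rng=None):
    """Build N physically-plausible, diverse starting conformations.

    Each chain starts extended, is randomized by stage-1 Monte Carlo on the
    steric score (f=9 moves, alpha = 0, so self-collisions are never
    worsened), then acquires secondary structure in stage-2 Monte Carlo on
    score1 (alpha = 2) until l consecutive moves are rejected.
    """
    if n < 1:
        raise InputError(f"population size must be >= 1, got {n}")
    if lib9.f != 9:
        raise InputError(f"initialization requires an f=9 library, got f={lib9.f}")
    l = len(sequence)
    if l < 9:
        raise InputError(f"chain of length {l} has no f=9 fragment window")
    if rng is None:
        rng = np.random.default_rng()
    n_stage1 = config.n_stage1 if config.n_stage1 is not None else 5 * l

    population = []
    for _ in range(n):
        conf = build_extended(sequence)
        # Stage 1: randomize without self-collisions (score0 analog).
        current = model.steric(conf)
        for _ in range(n_stage1):
            start, cfg = sample_move(conf, lib9, rng)
            cand = apply_move(conf, start, cfg)
            cand_score = model.steric(cand)
            if metropolis_accept(cand_score - current, config.alpha_stage1, rng):
                conf, current = cand, cand_score
        # Stage 2: form secondary structure (score1 analog), run until l
        # consecutive rejections (counter resets on acceptance) or the
        # attempt cap, whichever first.
        n_stage2_max = (config.n_stage2_max if config.n_stage2_max is not None
                        else 20 * l)
        current = model.score1(conf)
        failures = 0
        attempts = 0
        while failures < l and attempts < n_stage2_max:
            attempts += 1
            start, cfg = sample_move(conf, lib9, rng)
            cand = apply_move(conf, start, cfg)
            cand_score = model.score1(cand)
            if metropolis_accept(cand_score - current, config.alpha_stage2, rng):
                conf, current = cand, cand_score
                failures = 0
            else:
                failures += 1
        population.append(conf)
    return population


def variation(parent: Conformation, lib3: FragmentLibrary, rng) -> Conformation:
    """One f=3 fragment replacement, unconditionally accepted.

    No Metropolis test: the offspring is returned even if it scores worse
    than the parent, so variation is purely exploratory. The parent is not
    modified; at most 9 dihedral values differ.
    """
    if lib3.f != 3:
        raise InputError(f"variation requires an f=3 library, got f={lib3.f}")
    start, cfg = sample_move(parent, lib3, rng)
    return apply_move(parent, start, cfg)


def improvement(offspring: Conformation, lib3: FragmentLibrary,
                model: ScoreModel, config: ImprovementConfig = ImprovementConfig(),
                rng=None) -> Conformation:
    """Greedy descent on score3 via f=3 moves.

    A proposal is accepted only if it strictly lowers score3 (a tie counts
    as a failure); the search stops after k consecutive failures. Each
    proposal costs one energy evaluation; the initial score3 of the input
    costs one more. Never returns a conformation scoring above its input.
    """
    if lib3.f != 3:
        raise InputError(f"improvement requires an f=3 library, got f={lib3.f}")
    if rng is None:
        rng = np.random.default_rng()
    k = config.k if config.k is not None else len(offspring)
    current = model.score3(offspring)
    conf = offspring
    failures = 0
    while failures < k:
        start, cfg = sample_move(conf, lib3, rng)
        cand = apply_move(conf, start, cfg)
        cand_score = model.score3(cand)
        if cand_score < current:
            conf, current = cand, cand_score
            failures = 0
        else:
            failures += 1
    return conf
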