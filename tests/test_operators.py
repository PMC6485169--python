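import math

import numpy as np
import pytest

import evodiverse as ev
from evodiverse.energy import ScoreModel
from evodiverse.errors import InputError
from evodiverse.operators import ImprovementConfig, InitConfig

from conftest import identity_library


class TestMetropolis:
    def test_downhill_always_accepted_at_alpha_zero(self):
        rng = np.random.default_rng(0)
        assert ev.metropolis_accept(-1.0, 0.0, rng)

    def test_uphill_rejected_at_alpha_zero(self):
        rng = np.random.default_rng(0)
        assert not ev.metropolis_accept(+1.0, 0.0, rng)

    def test_empirical_acceptance_matches_boltzmann_factor(self):
        rng = np.random.default_rng(123)
        n = 100_000
        accepted = sum(ev.metropolis_accept(1.0, 2.0, rng) for _ in range(n))
        assert accepted / n == pytest.approx(math.exp(-0.5), abs=0.01)

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InputError):
            ev.metropolis_accept(float("nan"), 1.0, rng)
        with pytest.raises(InputError):
            ev.metropolis_accept(1.0, -0.5, rng)


class TestInitPopulation:
    def test_seeded_reproducibility(self, helix12, small_libs):
        lib9, _ = small_libs
        pops = []
        for _ in range(2):
            model = ScoreModel()
            pops.append(ev.init_population(helix12.sequence, 2, lib9, model,
                                           rng=np.random.default_rng(17)))
        assert len(pops[0]) == 2
        for a, b in zip(*pops):
            assert np.array_equal(a.dihedrals, b.dihedrals)

    def test_stage1_never_accepts_a_steric_increase(self, helix12, small_libs):
        # extended chains start clash-free (steric 0); with alpha = 0 no
        # accepted stage-1 move may increase steric, so it must end at 0
        lib9, _ = small_libs
        model = ScoreModel()
        pop = ev.init_population(helix12.sequence, 3, lib9, model,
                                 config=InitConfig(n_stage2_max=0),
                                 rng=np.random.default_rng(5))
        for conf in pop:
            assert model.steric(conf) == 0.0

    def test_outputs_differ_from_extended_chain(self, helix12, small_libs):
        lib9, _ = small_libs
        pop = ev.init_population(helix12.sequence, 3, lib9, ScoreModel(),
                                 rng=np.random.default_rng(8))
        ext = ev.build_extended(helix12.sequence)
        for conf in pop:
            assert not np.array_equal(conf.dihedrals, ext.dihedrals)

    def test_identity_library_terminates_after_exactly_l_failures(self, helix12):
        # with alpha = 0 in both stages every identity move is a failure:
        # stage 2 must stop after exactly l consecutive rejections
        ext = ev.build_extended(helix12.sequence)
        lib9 = identity_library(ext, f=9)
        model = ScoreModel()
        cfg = InitConfig(n_stage1=0, alpha_stage2=0.0)
        pop = ev.init_population(helix12.sequence, 1, lib9, model, cfg,
                                 np.random.default_rng(0))
        assert np.array_equal(pop[0].dihedrals, ext.dihedrals)
        # stage 1: 1 initial score; stage 2: 1 initial + l candidate scores
        assert model.evaluations == 2 + len(helix12)

    def test_identity_library_default_alpha_hits_attempt_cap(self, helix12):
        # at alpha = 2 a zero-difference move is accepted with certainty, so
        # the attempt cap is the terminator; output is still extended
        ext = ev.build_extended(helix12.sequence)
        lib9 = identity_library(ext, f=9)
        model = ScoreModel()
        cfg = InitConfig(n_stage1=0, n_stage2_max=30)
        pop = ev.init_population(helix12.sequence, 1, lib9, model, cfg,
                                 np.random.default_rng(0))
        assert np.array_equal(pop[0].dihedrals, ext.dihedrals)
        assert model.evaluations == 2 + 30

    def test_short_chain_rejected(self, small_libs):
        lib9, _ = small_libs
        with pytest.raises(InputError):
            ev.init_population("AAAA", 2, lib9, ScoreModel())

    def test_wrong_fragment_length_rejected(self, helix12, small_libs):
        _, lib3 = small_libs
        with pytest.raises(InputError):
            ev.init_population(helix12.sequence, 2, lib3, ScoreModel())


class TestVariation:
    def test_identity_library_returns_equal_offspring(self, helix12):
        lib3 = identity_library(helix12, f=3)
        child = ev.variation(helix12, lib3, np.random.default_rng(0))
        assert np.array_equal(child.dihedrals, helix12.dihedrals)

    def test_parent_unmodified_and_at_most_nine_changes(self, helix12, small_libs):
        _, lib3 = small_libs
        before = helix12.dihedrals.copy()
        rng = np.random.default_rng(2)
        for _ in range(25):
            child = ev.variation(helix12, lib3, rng)
            assert (child.dihedrals != helix12.dihedrals).sum() <= 9
        assert np.array_equal(helix12.dihedrals, before)

    def test_unconditional_acceptance_even_when_worse(self, helix30_target, toy_libs):
        # offspring are returned without any Metropolis test: over many
        # draws some offspring must score worse than the (native) parent
        _, lib3 = toy_libs
        model = ScoreModel()
        parent_score = model.score3(helix30_target.native)
        rng = np.random.default_rng(3)
        worse = 0
        for _ in range(30):
            child = ev.variation(helix30_target.native, lib3, rng)
            if model.score3(child) > parent_score:
                worse += 1
        assert worse > 0


class TestImprovement:
    def test_k_zero_returns_input_with_only_initial_score(self, helix12, small_libs):
        _, lib3 = small_libs
        model = ScoreModel()
        out = ev.improvement(helix12, lib3, model, ImprovementConfig(k=0),
                             np.random.default_rng(0))
        assert out is helix12
        assert model.evaluations == 1

    def test_identity_library_fails_exactly_k_times(self, helix12):
        lib3 = identity_library(helix12, f=3)
        model = ScoreModel()
        out = ev.improvement(helix12, lib3, model, ImprovementConfig(k=7),
                             np.random.default_rng(0))
        assert np.array_equal(out.dihedrals, helix12.dihedrals)
        assert model.evaluations == 1 + 7

    def test_never_increases_score3(self, small_libs):
        _, lib3 = small_libs
        model = ScoreModel()
        rng = np.random.default_rng(11)
        for seed in range(20):
            start = ev.Conformation(
                "A" * 12, np.random.default_rng(seed).uniform(-180, 180, (12, 3)))
            s_in = model.score3(start)
            out = ev.improvement(start, lib3, model, ImprovementConfig(k=8), rng)
            assert model.score3(out) <= s_in

    def test_accepted_trace_strictly_decreases(self, helix12, small_libs):
        _, lib3 = small_libs

        scores = []
        class Tracing(ScoreModel):
            def score3(self, conf):
                s = super().score3(conf)
                scores.append(s)
                return s

        model = Tracing()
        ev.improvement(ev.build_extended(helix12.sequence), lib3, model,
                       ImprovementConfig(k=10), np.random.default_rng(4))
        # reconstruct the accepted-move trace: a running strict minimum
        current = scores[0]
        trace = [current]
        for s in scores[1:]:
            if s < current:
                current = s
                trace.append(s)
        assert all(b < a for a, b in zip(trace, trace[1:]))


def test_full_pipeline_reproducible(helix30_target, toy_libs):
    lib9, lib3 = toy_libs
    outs = []
    for _ in range(2):
        model = ScoreModel()
        rng = np.random.default_rng(21)
        pop = ev.init_population(helix30_target.sequence, 2, lib9, model,
                                 rng=rng)
        child = ev.variation(pop[0], lib3, rng)
        child = ev.improvement(child, lib3, model, ImprovementConfig(k=10), rng)
        outs.append((child.dihedrals, model.evaluations))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert outs[0][1] == outs[1][1]
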