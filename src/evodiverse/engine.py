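"""Generation loop, evaluation-budget accounting and the multi-run harness.

One run: build the initial population, then repeat
{every parent yields one offspring via variation; every offspring is
locally improved; survival selection over the combined 2N individuals}
until the fixed budget of energy evaluations is spent. There is no
generation-count termination: the budget is the only stopping rule. Every
sampled decoy — the initial population and every improved offspring,
whether or not it survives selection — is archived, so "lowest energy ever
reached" and "lowest lRMSD ever reached" are measured over everything the
run sampled and the probed energy landscape can be exported and plotted.

The initial population is always completed in full (a run cannot proceed
without one); the generation loop enforces the cap through the score
model's hard evaluation limit, and the engine finalizes with the last
complete population when the limit fires mid-pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .backbone import Conformation
from .energy import ObjectiveVector, ScoreModel
from .errors import BudgetExhausted, InputError
from .fragments import FragmentLibrary
from .metrics import gdt_ts, lrmsd_ca, tm_score
from .operators import ImprovementConfig, InitConfig, improvement, init_population, variation
from .selection import SELECTORS


@dataclass(frozen=True)
class DecoyRecord:
    """A sampled conformation with its cached scores and provenance."""

    conformation: Conformation
    objectives: ObjectiveVector
    generation: int
    run_seed: int
    lrmsd: float | None = None
    tm: float | None = None
    gdt: float | None = None

    @property
    def total_energy(self) -> float:
        return self.objectives.total


@dataclass(frozen=True)
class EAConfig:
    """Run configuration.

    Defaults follow the full-scale protocol (population N = 100, budget of
    10,000,000 energy evaluations, 5 independent runs); desk-scale studies
    override ``budget`` (typically <= 1e5) through the YAML file or
    directly.
    """

    n: int = 100
    budget: int = 10_000_000
    selector: str = "evo_diverse"
    seed: int = 0
    runs: int = 5
    init: InitConfig = field(default_factory=InitConfig)
    improvement: ImprovementConfig = field(default_factory=ImprovementConfig)
    energy: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 2:
            raise InputError(f"population size must be >= 2, got {self.n}")
        if self.budget <= 0:
            raise InputError(f"budget must be positive, got {self.budget}")
        if self.selector not in SELECTORS:
            raise InputError(
                f"unknown selector {self.selector!r}; "
                f"choose from {sorted(SELECTORS)}")
        if self.runs < 1:
            raise InputError(f"run count must be >= 1, got {self.runs}")

    @classmethod
    def from_yaml(cls, path) -> "EAConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "EAConfig":
        kwargs = {k: raw[k] for k in ("n", "budget", "selector", "seed", "runs")
                  if k in raw}
        ops = raw.get("operators", {})
        init_kwargs = {k: ops[k] for k in ("n_stage1", "alpha_stage1",
                                           "alpha_stage2", "n_stage2_max")
                       if k in ops}
        kwargs["init"] = InitConfig(**init_kwargs)
        kwargs["improvement"] = ImprovementConfig(k=ops.get("k"))
        kwargs["energy"] = dict(raw.get("energy", {}))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "budget": self.budget, "selector": self.selector,
            "seed": self.seed, "runs": self.runs,
            "operators": {
                "n_stage1": self.init.n_stage1,
                "alpha_stage1": self.init.alpha_stage1,
                "alpha_stage2": self.init.alpha_stage2,
                "n_stage2_max": self.init.n_stage2_max,
                "k": self.improvement.k,
            },
            "energy": dict(self.energy),
        }

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def make_model(self, budget_cap=True) -> ScoreModel:
        return ScoreModel(max_evaluations=self.budget if budget_cap else None,
                          **self.energy)


def run(sequence, lib9: FragmentLibrary, lib3: FragmentLibrary,
        config: EAConfig, native=None, run_seed=None, model=None):
    """Execute one evolutionary run; returns the archive of DecoyRecords.

    The archive holds every generation's population (generation 0 is the
    initial population). With a fixed seed the archive is reproducible
    bit-for-bit. ``native`` is unused here (metrics are computed by
    :func:`multi_run` / :func:`annotate_metrics`) but accepted so call
    sites can treat single- and multi-run uniformly.
    """
    if len(sequence) < 9:
        raise InputError("sequences shorter than 9 residues cannot be "
                         "initialized (no f=9 fragment window)")
    seed = config.seed if run_seed is None else run_seed
    rng = np.random.default_rng(seed)
    if model is None:
        model = config.make_model(budget_cap=False)
    select = SELECTORS[config.selector]

    # Initialization always completes; the cap applies to the loop below.
    saved_cap, model.max_evaluations = model.max_evaluations, None
    confs = init_population(sequence, config.n, lib9, model, config.init, rng)
    population = [DecoyRecord(c, model.objectives(c), generation=0,
                              run_seed=seed) for c in confs]
    model.max_evaluations = saved_cap if saved_cap is not None else config.budget

    archive = list(population)
    generation = 0
    while model.evaluations < config.budget:
        generation += 1
        try:
            offspring = []
            for parent in population:
                child = variation(parent.conformation, lib3, rng)
                child = improvement(child, lib3, model, config.improvement, rng)
                offspring.append(DecoyRecord(child, model.objectives(child),
                                             generation=generation,
                                             run_seed=seed))
        except BudgetExhausted:
            break
        archive.extend(offspring)
        population = select(population, offspring, config.n)
    return archive


def annotate_metrics(archive, native, metrics=("lrmsd",)):
    """Return the archive with the requested native-comparison metrics
    filled in (lrmsd is cheap; tm/gdt run the seeded superposition search
    per decoy and are proportionally slower)."""
    out = []
    for rec in archive:
        kwargs = {}
        if "lrmsd" in metrics:
            kwargs["lrmsd"] = lrmsd_ca(rec.conformation, native)
        if "tm" in metrics:
            kwargs["tm"] = tm_score(rec.conformation, native)
        if "gdt" in metrics:
            kwargs["gdt"] = gdt_ts(rec.conformation, native)
        out.append(replace(rec, **kwargs))
    return out


def _best10_mean(values, minimize=True):
    v = np.sort(np.asarray(values, dtype=float))
    return float(v[:10].mean()) if minimize else float(v[-10:].mean())


def multi_run(sequence, lib9, lib3, config: EAConfig, native=None,
              metrics=("lrmsd",)):
    """R independent runs with seeds seed+0 .. seed+R-1.

    Returns (archives, summary): per-run archives, and a summary over all
    runs combined reporting the lowest total energy plus, per requested
    native metric, the best value and the mean of the 10 best decoys.
    """
    archives = []
    for i in range(config.runs):
        archive = run(sequence, lib9, lib3, config, run_seed=config.seed + i)
        if native is not None:
            archive = annotate_metrics(archive, native, metrics)
        archives.append(archive)
    pooled = [rec for archive in archives for rec in archive]
    totals = [rec.total_energy for rec in pooled]
    summary = {
        "n_decoys": len(pooled),
        "lowest_energy": float(min(totals)),
        "avg_energy_best10": _best10_mean(totals, minimize=True),
    }
    if native is not None:
        if "lrmsd" in metrics:
            vals = [rec.lrmsd for rec in pooled]
            summary["lowest_lrmsd"] = float(min(vals))
            summary["avg_lrmsd_best10"] = _best10_mean(vals, minimize=True)
        if "tm" in metrics:
            vals = [rec.tm for rec in pooled]
            summary["highest_tm"] = float(max(vals))
            summary["avg_tm_best10"] = _best10_mean(vals, minimize=False)
        if "gdt" in metrics:
            vals = [rec.gdt for rec in pooled]
            summary["highest_gdt"] = float(max(vals))
            summary["avg_gdt_best10"] = _best10_mean(vals, minimize=False)
    return archives, summary


def export_landscape(archive, native, path=None) -> pd.DataFrame:
    """Tabulate (lrmsd, total energy) per decoy for landscape scatter plots.

    Records lacking a cached lRMSD are computed against ``native``; the
    table is written as TSV when ``path`` is given.
    """
    if native is None:
        raise InputError("a native structure is required to compute lRMSD")
    rows = []
    for rec in archive:
        r = rec.lrmsd if rec.lrmsd is not None else lrmsd_ca(rec.conformation, native)
        rows.append((r, rec.total_energy, rec.generation, rec.run_seed))
    df = pd.DataFrame(rows, columns=["lrmsd", "total", "generation", "run_seed"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
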