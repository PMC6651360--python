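"""Stage 0/1/2 training-set scenarios — the experiment's independent variable.

Stage 0 is a naive 50/50 polygon split.  Stage 1 holds the number of
training plots constant (30 target + 100 background) and varies the allowed
target cover range: SC0 20-70 %, SC1 20-100 %, SC2 50-100 %, SC3 70-100 %,
SC4 80-100 %.  Stage 2 takes the best Stage-1 scenario and varies the number
of target training plots (20/30/40) with nested sets, so that comparisons
isolate sample size.  The validation set and the background training set are
identical across every Stage 1/2 run.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .sampling import (STRATA, ReferencePolygon, SampleDesign, SamplingError,
                       stratum_deciles, training_pool)

STAGE1_RANGES: dict[str, tuple[int, int]] = {
    "SC0": (20, 70),
    "SC1": (20, 100),
    "SC2": (50, 100),
    "SC3": (70, 100),
    "SC4": (80, 100),
}

STAGE2_SIZES: tuple[int, ...] = (20, 30, 40)


@dataclass(frozen=True)
class ScenarioSpec:
    """One classification run's training-set recipe."""

    stage: int
    name: str
    cover_range: tuple[int, int]
    n_target_train: int = 30
    n_background_train: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.stage == 1 and self.cover_range not in STAGE1_RANGES.values():
            raise ValueError(f"invalid Stage-1 cover range {self.cover_range}")
        if self.stage == 2 and self.n_target_train not in STAGE2_SIZES:
            raise ValueError("Stage-2 target counts are 20, 30 or 40")


def stage1_allocation(cover_range: tuple[int, int],
                      n_target: int = 30) -> dict[str, int]:
    """Equal per-stratum allocation over strata intersecting the range.

    The remainder goes to the highest intersecting stratum.  A stratum
    intersects the range if any of its decile covers falls inside it.
    """
    lo, hi = cover_range
    involved = [s for s in STRATA
                if any(lo <= d <= hi for d in stratum_deciles(s))]
    if not involved:
        raise ValueError(f"cover range {cover_range} intersects no stratum")
    share = n_target // len(involved)
    alloc = {s: share for s in involved}
    alloc[involved[-1]] += n_target - share * len(involved)
    return alloc


def scale_allocation(base: dict[str, int], n_target: int) -> dict[str, int]:
    """Scale a per-stratum allocation proportionally to ``n_target`` plots.

    Floors the scaled counts, then hands the remainder out starting from the
    highest stratum.
    """
    total = sum(base.values())
    strata = [s for s in STRATA if s in base]
    scaled = {s: (n_target * base[s]) // total for s in strata}
    short = n_target - sum(scaled.values())
    for s in reversed(strata):
        if short == 0:
            break
        scaled[s] += 1
        short -= 1
    return scaled


def _eligible(pool: Sequence[ReferencePolygon], stratum: str,
              cover_range: tuple[int, int]) -> list[ReferencePolygon]:
    lo, hi = cover_range
    return [p for p in pool
            if p.stratum == stratum and lo <= p.cover_pct <= hi]


def _resolve_allocation(alloc: dict[str, int],
                        avail: dict[str, int]) -> dict[str, int]:
    """Cap each stratum at its eligible pool, spilling shortfall upward.

    If the highest stratum is also short, the leftover spills back down.
    Raises naming the stratum when the total pool cannot cover the request.
    """
    strata = [s for s in STRATA if s in alloc]
    want = dict(alloc)
    carry = 0
    for s in strata:                                  # push shortfall upward
        take = min(want[s], avail[s])
        carry += want[s] - take
        want[s] = take
    for s in reversed(strata):                        # absorb carry downward
        room = avail[s] - want[s]
        add = min(room, carry)
        want[s] += add
        carry -= add
    if carry > 0:
        short = [s for s in strata if avail[s] < alloc[s]]
        raise SamplingError(
            f"training pool cannot satisfy allocation; short in strata {short} "
            f"(available {avail}, requested {alloc})")
    return want


def _stratum_order(pool: Sequence[ReferencePolygon], seed: int,
                   cover_range: tuple[int, int]) -> dict[str, list[ReferencePolygon]]:
    """Seed-stable per-stratum shuffles of eligible plots.

    Stage 1 and Stage 2 draw prefixes of the same permutations, which makes
    the Stage-2 sets nested (SC_20 within SC_30 within SC_40) and makes the
    30-plot Stage-2 run identical to its parent Stage-1 scenario.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for s in STRATA:
        elig = sorted(_eligible(pool, s, cover_range), key=lambda p: p.id)
        out[s] = [elig[i] for i in rng.permutation(len(elig))]
    return out


def build_stage1_training(design: SampleDesign,
                          fixed_validation: Sequence[ReferencePolygon],
                          spec: ScenarioSpec) -> list[ReferencePolygon]:
    """Training set for a Stage-1 scenario: ranged target plots + constant background."""
    if spec.stage != 1:
        raise ValueError("spec must be a Stage-1 scenario")
    t_pool, b_pool = training_pool(design, fixed_validation)
    alloc = stage1_allocation(spec.cover_range, spec.n_target_train)
    order = _stratum_order(t_pool, spec.seed, spec.cover_range)
    avail = {s: len(order[s]) for s in alloc}
    final = _resolve_allocation(alloc, avail)
    train = [replace(p, role="train")
             for s in final for p in order[s][:final[s]]]
    train += constant_background_training(design, fixed_validation,
                                          spec.n_background_train)
    return train


def build_stage2_training(design: SampleDesign,
                          fixed_validation: Sequence[ReferencePolygon],
                          best_stage1_spec: ScenarioSpec,
                          n_target: int) -> list[ReferencePolygon]:
    """Stage-2 training set: same cover range as the best Stage-1 scenario,
    target count rescaled to ``n_target``, background unchanged."""
    if n_target not in STAGE2_SIZES:
        raise ValueError("n_target must be one of 20, 30, 40")
    t_pool, b_pool = training_pool(design, fixed_validation)
    base = stage1_allocation(best_stage1_spec.cover_range,
                             best_stage1_spec.n_target_train)
    order = _stratum_order(t_pool, best_stage1_spec.seed,
                           best_stage1_spec.cover_range)
    avail = {s: len(order[s]) for s in base}
    base = _resolve_allocation(base, avail)           # realized Stage-1 split
    alloc = _resolve_allocation(scale_allocation(base, n_target), avail)
    train = [replace(p, role="train")
             for s in alloc for p in order[s][:alloc[s]]]
    train += constant_background_training(design, fixed_validation,
                                          best_stage1_spec.n_background_train)
    return train


def constant_background_training(design: SampleDesign,
                                 fixed_validation: Sequence[ReferencePolygon],
                                 n_background: int = 100) -> list[ReferencePolygon]:
    """The background training set shared by every Stage 1/2 scenario."""
    _, b_pool = training_pool(design, fixed_validation)
    b_pool = sorted(b_pool, key=lambda p: p.id)
    if len(b_pool) < n_background:
        raise SamplingError(
            f"only {len(b_pool)} background plots left for training, "
            f"need {n_background}")
    return [replace(p, role="train") for p in b_pool[:n_background]]


def enumerate_experiment(seed: int = 0,
                         best_stage1: str = "SC1") -> list[ScenarioSpec]:
    """The 9-run experiment grid: Stage 0, five Stage-1 scenarios, three
    Stage-2 sizes for the (given or eventual) best Stage-1 scenario."""
    specs = [ScenarioSpec(stage=0, name="STAGE0", cover_range=(20, 100),
                          n_target_train=55, seed=seed)]
    for name, rng_ in STAGE1_RANGES.items():
        specs.append(ScenarioSpec(stage=1, name=name, cover_range=rng_,
                                  seed=seed))
    for n in STAGE2_SIZES:
        specs.append(ScenarioSpec(stage=2, name=f"{best_stage1}_{n}",
                                  cover_range=STAGE1_RANGES[best_stage1],
                                  n_target_train=n, seed=seed))
    return specs
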