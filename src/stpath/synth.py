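"""Deterministic synthetic catalogs, pathways, and perturbed pathway pairs.

Every algorithm in the toolkit is exercisable without external data:
this module generates interaction catalogs (random distinct entity pairs
with taxonomy-valid ST codes), pathways (random walks over a catalog's
directed relation), and controlled perturbations of a pathway's codes with
per-level mutation rates.  The mutation model has a closed-form expected
per-position similarity, so the aligner can be checked statistically.

All generators are pure functions of their configuration — the same seed
always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pathway_io import Interaction, InteractionCatalog, Pathway
from .st_core import LEVEL2_RANGES, STCode

__all__ = [
    "SynthConfig",
    "generate_catalog",
    "generate_pathways",
    "perturb_pathway",
    "expected_position_similarity",
    "random_code",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``length_range`` bounds pathway lengths (inclusive); ``mutation_rates``
    are per-level perturbation probabilities (p1..p4); ``level34_max`` caps
    generated level-3/4 values at 1..cap so that near-identical codes (the
    0.75 similarity branch) occur at useful frequency.
    """

    seed: int = 0
    n_entities: int = 30
    n_interactions: int = 90
    n_pathways: int = 20
    length_range: tuple[int, int] = (3, 8)
    mutation_rates: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    level34_max: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if any(not 0.0 <= p <= 1.0 for p in self.mutation_rates):
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.level34_max < 1:
            raise ValueError("level34_max must be >= 1")
        if self.n_interactions > self.n_entities * (self.n_entities - 1):
            raise ValueError(
                f"{self.n_interactions} interactions infeasible for "
                f"{self.n_entities} entities (max "
                f"{self.n_entities * (self.n_entities - 1)} ordered pairs)"
            )


def random_code(rng: np.random.Generator, level34_max: int = 5) -> STCode:
    """Uniform taxonomy-valid code: level 1, then a valid level 2, then
    levels 3–4 uniform in 1..level34_max."""
    l1 = int(rng.integers(1, 7))
    r2 = LEVEL2_RANGES[l1]
    l2 = int(rng.integers(r2.start, r2.stop))
    l3 = int(rng.integers(1, level34_max + 1))
    l4 = int(rng.integers(1, level34_max + 1))
    return STCode(l1, l2, l3, l4)


def _entity_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"E{k:0{width}d}" for k in range(1, n + 1)]


def generate_catalog(config: SynthConfig) -> InteractionCatalog:
    """Random catalog of distinct ordered entity pairs with valid codes."""
    rng = np.random.default_rng(config.seed)
    names = _entity_names(config.n_entities)
    n = config.n_entities
    # ordered non-self pairs indexed 0 .. n(n-1)-1
    pair_idx = rng.choice(n * (n - 1), size=config.n_interactions, replace=False)
    catalog = InteractionCatalog()
    for k, idx in enumerate(sorted(int(i) for i in pair_idx), start=1):
        i, j = divmod(idx, n - 1)
        if j >= i:
            j += 1
        catalog.add(
            names[i], names[j], random_code(rng, config.level34_max), f"I{k:04d}"
        )
    return catalog


def generate_pathways(
    catalog: InteractionCatalog, config: SynthConfig
) -> list[Pathway]:
    """Random walks over the catalog's source→target relation.

    Walks follow outgoing catalog edges where possible and restart at a
    uniformly chosen edge on dead-ends, so every requested pathway reaches
    its sampled length.  Every step is a catalog entry.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = np.random.default_rng((config.seed, 1))
    pairs = sorted(catalog)
    out_edges: dict[str, list[tuple[str, str]]] = {}
    for s, t in pairs:
        out_edges.setdefault(s, []).append((s, t))
    lo, hi = config.length_range
    pathways = []
    width = max(3, len(str(config.n_pathways)))
    for p in range(1, config.n_pathways + 1):
        length = int(rng.integers(lo, hi + 1))
        steps: list[Interaction] = []
        current: str | None = None
        while len(steps) < length:
            if current is None or current not in out_edges:
                s, t = pairs[int(rng.integers(len(pairs)))]  # restart
            else:
                choices = out_edges[current]
                s, t = choices[int(rng.integers(len(choices)))]
            steps.append(catalog.lookup(s, t))  # type: ignore[arg-type]
            current = t
        pathways.append(Pathway(f"PW{p:0{width}d}", tuple(steps)))
    return pathways


def _mutate_level(
    rng: np.random.Generator, current: int, lo: int, hi: int
) -> tuple[int, bool]:
    """Forced change: redraw uniformly from lo..hi excluding the current
    value.  Returns (value, changed); a single-valued range cannot change."""
    choices = [v for v in range(lo, hi + 1) if v != current]
    if not choices:
        return current, False
    return int(rng.choice(choices)), True


def perturb_pathway(
    pw: Pathway, config: SynthConfig, rng: np.random.Generator | None = None
) -> Pathway:
    """Independently perturb each step's code with per-level rates p1..p4.

    Levels are processed top-down.  Level k mutates with probability p_k
    into a different valid value; once some level has changed, all deeper
    levels are resampled uniformly over their valid range (which may
    reproduce the original value), keeping the code taxonomy-consistent.
    Entity endpoints are untouched.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 2))
    p1, p2, p3, p4 = config.mutation_rates
    cap = config.level34_max
    new_steps = []
    for step in pw.steps:
        c = step.code
        # level 1
        draws = rng.random(4)
        if draws[0] < p1:
            l1, changed = _mutate_level(rng, c.level1, 1, 6)
        else:
            l1, changed = c.level1, False
        # level 2 (range depends on level 1)
        r2 = LEVEL2_RANGES[l1]
        if changed:
            l2 = int(rng.integers(r2.start, r2.stop))
        elif draws[1] < p2:
            l2, changed = _mutate_level(rng, c.level2, r2.start, r2.stop - 1)
        else:
            l2 = c.level2
        # levels 3 and 4
        if changed:
            l3 = int(rng.integers(1, cap + 1))
        elif draws[2] < p3:
            l3, changed = _mutate_level(rng, c.level3, 1, cap)
        else:
            l3 = c.level3
        if changed:
            l4 = int(rng.integers(1, cap + 1))
        elif draws[3] < p4:
            l4, changed = _mutate_level(rng, c.level4, 1, cap)
        else:
            l4 = c.level4
        new_steps.append(Interaction(step.source, step.target, STCode(l1, l2, l3, l4)))
    return Pathway(f"{pw.id}_mut", tuple(new_steps))


def expected_position_similarity(pw: Pathway, config: SynthConfig) -> float:
    """Closed-form expected per-position σ between ``pw`` and its perturbation.

    For each step the probability that level k survives is 1 − p_k when the
    level has at least one alternative value in its valid range, and 1 when
    it cannot change (e.g. level 2 under location category 5, which admits a
    single action type).  σ contributes 0.25 per surviving prefix level, so

        E[σ] = 0.25 · (r1 + r1·r2 + r1·r2·r3 + r1·r2·r3·r4)

    averaged over the pathway's positions.
    """
    p1, p2, p3, p4 = config.mutation_rates
    cap = config.level34_max
    total = 0.0
    for step in pw.steps:
        c = step.code
        r1 = 1.0 - p1  # six level-1 categories: always an alternative
        r2size = len(LEVEL2_RANGES[c.level1])
        r2 = 1.0 - p2 if r2size > 1 else 1.0
        n_alt3 = sum(1 for v in range(1, cap + 1) if v != c.level3)
        r3 = 1.0 - p3 if n_alt3 > 0 else 1.0
        n_alt4 = sum(1 for v in range(1, cap + 1) if v != c.level4)
        r4 = 1.0 - p4 if n_alt4 > 0 else 1.0
        total += 0.25 * (r1 + r1 * r2 + r1 * r2 * r3 + r1 * r2 * r3 * r4)
    return total / len(pw)
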