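"""Sequence optimization: maximize well-formed overlap for a fixed CRN.

Two optimizers over the space of domain sequence assignments: plain random
search (best of N independent draws) and an elitist mutation-only GA that
applies one to three random base changes per offspring.  Objective values
are cached per assignment, and a best assignment is re-evaluated at a
larger fold size afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .enumerator import CRN
from .folding_match import (
    FoldParams,
    MatchReport,
    SequenceAssignment,
    evaluate_assignment,
)

__all__ = [
    "OptConfig",
    "OptResult",
    "random_assignment",
    "mutate_assignment",
    "optimize_sequences",
    "reevaluate_overlap",
    "select_best",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class OptConfig:
    algorithm: str = "ga"  # "ga" | "random"
    budget: int = 1000
    population: int = 32
    elite_keep: int = 8
    runs: int = 10
    seed: int = 0
    opt_fold_size: int = 3
    reeval_fold_size: int = 8
    hybridization_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.algorithm not in ("ga", "random"):
            raise ValueError("algorithm must be 'ga' or 'random'")
        if self.budget < 1 or self.population < 1 or self.elite_keep < 1:
            raise ValueError("budget, population and elite_keep must be positive")
        if self.elite_keep > self.population:
            raise ValueError("elite_keep cannot exceed population")

    def fold_params(self, size: int) -> FoldParams:
        return FoldParams(
            max_complex_size=size,
            hybridization_fraction=self.hybridization_fraction,
        )


@dataclass
class OptResult:
    best: SequenceAssignment
    best_score: int
    history: list[tuple[int, int]]  # (evaluation index, best-so-far score)
    evaluations: int
    meta: dict = field(default_factory=dict)


def _domain_lengths(crn: CRN) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for c in crn.initial:
        for s in c.strands:
            for d in s.domains:
                lengths[d.base] = d.length
    return lengths


def random_assignment(
    domain_lengths: dict[str, int], rng: np.random.Generator
) -> SequenceAssignment:
    seqs = {
        base: "".join(_BASES[int(i)] for i in rng.integers(0, 4, size=length))
        for base, length in sorted(domain_lengths.items())
    }
    return SequenceAssignment.from_mapping(seqs)


def mutate_assignment(
    s: SequenceAssignment, rng: np.random.Generator
) -> SequenceAssignment:
    """One to three random base changes across the concatenated base domains.

    Positions are distinct and every changed position gets a different
    base; complement domains follow automatically (they are derived).
    """
    items = list(s.seqs)
    total = sum(len(seq) for _, seq in items)
    n_changes = int(rng.integers(1, min(3, total) + 1))
    positions = rng.choice(total, size=n_changes, replace=False)
    flat = list("".join(seq for _, seq in items))
    for p in positions:
        old = flat[p]
        choices = [b for b in _BASES if b != old]
        flat[p] = choices[int(rng.integers(0, 3))]
    out = {}
    cursor = 0
    for base, seq in items:
        out[base] = "".join(flat[cursor : cursor + len(seq)])
        cursor += len(seq)
    return SequenceAssignment.from_mapping(out)


def optimize_sequences(
    crn: CRN,
    cfg: OptConfig,
    seed: int | None = None,
    initial: tuple[SequenceAssignment, ...] = (),
) -> OptResult:
    """Maximize the number of well-formed overlap structures for ``crn``.

    ``random``: best of ``budget`` independent draws.  ``ga``: elitist
    (mu + lambda) with mutation only; the ``elite_keep`` best survive each
    generation (ties broken toward earlier-evaluated individuals) and
    offspring mutate uniformly chosen elites.  ``initial`` assignments are
    evaluated first (counting against the budget).  Best-so-far is
    monotone non-decreasing; reproducible from the seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lengths = _domain_lengths(crn)
    fold_params = cfg.fold_params(cfg.opt_fold_size)
    cache: dict[tuple, int] = {}
    evals = 0

    def objective(a: SequenceAssignment) -> int:
        if a.seqs not in cache:
            cache[a.seqs] = evaluate_assignment(a, crn, fold_params).n_overlap
        return cache[a.seqs]

    history: list[tuple[int, int]] = []
    best: SequenceAssignment | None = None
    best_score = -1

    def record(a: SequenceAssignment, score: int) -> None:
        nonlocal best, best_score, evals
        evals += 1
        if score > best_score:
            best, best_score = a, score
        history.append((evals, best_score))

    if cfg.algorithm == "random":
        for a in initial[: cfg.budget]:
            record(a, objective(a))
        while evals < cfg.budget:
            a = random_assignment(lengths, rng)
            record(a, objective(a))
    else:
        # (index, score, assignment); index breaks score ties toward elders
        pool: list[tuple[int, int, SequenceAssignment]] = []
        n_init = min(cfg.population, cfg.budget)
        seeded = list(initial[:n_init])
        for i in range(n_init):
            a = seeded[i] if i < len(seeded) else random_assignment(lengths, rng)
            score = objective(a)
            pool.append((evals, score, a))
            record(a, score)
        while evals < cfg.budget:
            pool.sort(key=lambda t: (-t[1], t[0]))
            elites = pool[: cfg.elite_keep]
            n_children = min(cfg.population - len(elites), cfg.budget - evals)
            children = []
            for _ in range(max(1, n_children)):
                if evals + len(children) >= cfg.budget:
                    break
                parent = elites[int(rng.integers(0, len(elites)))]
                child = mutate_assignment(parent[2], rng)
                children.append(child)
            if not children:
                break
            scored = []
            for child in children:
                score = objective(child)
                scored.append((evals, score, child))
                record(child, score)
            pool = elites + scored
    assert best is not None
    return OptResult(
        best,
        best_score,
        history,
        evals,
        meta={
            "algorithm": cfg.algorithm,
            "budget": cfg.budget,
            "population": cfg.population,
            "elite_keep": cfg.elite_keep,
            "opt_fold_size": cfg.opt_fold_size,
            "hybridization_fraction": cfg.hybridization_fraction,
        },
    )


def reevaluate_overlap(
    best: SequenceAssignment, crn: CRN, cfg: OptConfig
) -> MatchReport:
    """Recompute the overlap at the (larger) re-evaluation fold size."""
    return evaluate_assignment(best, crn, cfg.fold_params(cfg.reeval_fold_size))


def select_best(
    crn: CRN, cfg: OptConfig, seed: int | None = None
) -> dict:
    """Run both algorithms and pick the better re-evaluated proportion."""
    base_seed = cfg.seed if seed is None else seed
    out = {}
    for algo in ("random", "ga"):
        res = optimize_sequences(crn, replace(cfg, algorithm=algo), seed=base_seed)
        report = reevaluate_overlap(res.best, crn, cfg)
        out[algo] = {"result": res, "reeval": report}
    winner = max(out, key=lambda a: out[a]["reeval"].proportion)
    out["selected"] = winner
    return out
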