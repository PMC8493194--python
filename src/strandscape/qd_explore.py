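"""MAP-Elites exploration of strand-subset space.

Genomes (boolean strand-membership vectors) are evaluated by enumerating
their CRN; the archive is a 3-D grid over (number of strands, log10 number
of reactions, number of structures) keeping the best-fitness genome per
bin.  Fitness is either MSS (mean structure size) or ERT (entropy of
reaction types).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from itertools import combinations
from math import floor, log10
from typing import Callable, Sequence

import numpy as np

from .enumerator import CRN, EnumParams, crn_metrics, enumerate_crn
from .library import DEFAULT_MAX_STRANDS, Genome, Library, genome_to_strands, random_genome

__all__ = [
    "DescriptorConfig",
    "Elite",
    "EliteGrid",
    "ExploreConfig",
    "compute_descriptors",
    "mutate_genome",
    "place_elite",
    "run_map_elites",
    "exhaustive_grid",
    "aggregate_grids",
    "grid_report",
]


@dataclass(frozen=True)
class DescriptorConfig:
    """Binning of the three feature descriptors (defaults: 3 x 50 x 55).

    Strand count is binned by ``k_edges`` (right-open integer bins
    [1-2], [3-4], [5-7]); reactions on a log10(n+1) scale over
    ``rxn_log_range``; structures linearly over ``struct_range``.  Values
    outside a range clamp to the boundary bins.
    """

    k_edges: tuple[int, ...] = (1, 3, 5, 8)
    rxn_bins: int = 50
    rxn_log_range: tuple[float, float] = (0.0, 4.0)
    struct_bins: int = 55
    struct_range: tuple[float, float] = (0.0, 2750.0)

    def __post_init__(self) -> None:
        if list(self.k_edges) != sorted(set(self.k_edges)):
            raise ValueError("k_edges must be strictly increasing")
        if self.rxn_bins < 1 or self.struct_bins < 1:
            raise ValueError("bin counts must be positive")
        if not (self.rxn_log_range[0] < self.rxn_log_range[1]):
            raise ValueError("rxn_log_range must be increasing")
        if not (self.struct_range[0] < self.struct_range[1]):
            raise ValueError("struct_range must be increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.k_edges) - 1, self.rxn_bins, self.struct_bins)

    @property
    def total_bins(self) -> int:
        nk, nr, ns = self.shape
        return nk * nr * ns


def _clamp(i: int, n: int) -> int:
    return max(0, min(n - 1, i))


def compute_descriptors(
    k: int, n_reactions: int, n_structures: int, cfg: DescriptorConfig = DescriptorConfig()
) -> tuple[int, int, int]:
    """Bin (strand count, #reactions, #structures) into grid coordinates."""
    k_bin = _clamp(int(np.searchsorted(cfg.k_edges, k, side="right")) - 1, cfg.shape[0])
    lo, hi = cfg.rxn_log_range
    v = log10(n_reactions + 1)
    rxn_bin = _clamp(floor((v - lo) / (hi - lo) * cfg.rxn_bins), cfg.rxn_bins)
    lo, hi = cfg.struct_range
    struct_bin = _clamp(
        floor((n_structures - lo) / (hi - lo) * cfg.struct_bins), cfg.struct_bins
    )
    return (k_bin, rxn_bin, struct_bin)


@dataclass(frozen=True)
class Elite:
    genome: Genome
    fitness: float
    features: tuple[int, int, int]  # raw (k, n_reactions, n_structures)
    bin: tuple[int, int, int]
    crn_summary: dict = field(compare=False, hash=False, default_factory=dict)


@dataclass
class EliteGrid:
    """Archive of best-fitness genomes indexed by binned descriptors."""

    config: DescriptorConfig
    fitness_name: str  # "MSS" | "ERT"
    bins: dict[tuple[int, int, int], Elite] = field(default_factory=dict)
    evals: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_filled(self) -> int:
        return len(self.bins)

    def coverage(self) -> float:
        return self.n_filled / self.config.total_bins

    def to_json(self) -> str:
        doc = {
            "fitness_name": self.fitness_name,
            "evals": self.evals,
            "meta": self.meta,
            "config": {
                "k_edges": list(self.config.k_edges),
                "rxn_bins": self.config.rxn_bins,
                "rxn_log_range": list(self.config.rxn_log_range),
                "struct_bins": self.config.struct_bins,
                "struct_range": list(self.config.struct_range),
            },
            "elites": [
                {
                    "bin": list(b),
                    "fitness": e.fitness,
                    "features": list(e.features),
                    "genome": e.genome.bitstring(),
                    "max_strands": e.genome.max_strands,
                    "crn_summary": e.crn_summary,
                }
                for b, e in sorted(self.bins.items())
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EliteGrid":
        doc = json.loads(text)
        c = doc["config"]
        cfg = DescriptorConfig(
            tuple(c["k_edges"]),
            c["rxn_bins"],
            tuple(c["rxn_log_range"]),
            c["struct_bins"],
            tuple(c["struct_range"]),
        )
        grid = cls(cfg, doc["fitness_name"], evals=doc["evals"], meta=doc.get("meta", {}))
        for e in doc["elites"]:
            g = Genome(tuple(int(ch) for ch in e["genome"]), e["max_strands"])
            grid.bins[tuple(e["bin"])] = Elite(
                g, e["fitness"], tuple(e["features"]), tuple(e["bin"]), e.get("crn_summary", {})
            )
        return grid

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["k_bin", "rxn_bin", "struct_bin", "fitness", "k", "n_reactions", "n_structures", "genome"])
        for b, e in sorted(self.bins.items()):
            w.writerow([*b, e.fitness, *e.features, e.genome.bitstring()])
        return buf.getvalue()


def place_elite(grid: EliteGrid, candidate: Elite) -> bool:
    """Insert iff the bin is empty or fitness strictly improves (ties lose)."""
    incumbent = grid.bins.get(candidate.bin)
    if incumbent is None or candidate.fitness > incumbent.fitness:
        grid.bins[candidate.bin] = candidate
        return True
    return False


def mutate_genome(g: Genome, rng: np.random.Generator) -> Genome:
    """Flip 1-3 uniformly chosen bits, then repair to the popcount bounds."""
    bits = list(g.bits)
    n_flips = int(rng.integers(1, 4))
    for i in rng.choice(len(bits), size=min(n_flips, len(bits)), replace=False):
        bits[i] ^= 1
    ones = [i for i, b in enumerate(bits) if b]
    while len(ones) > g.max_strands:
        victim = ones.pop(int(rng.integers(0, len(ones))))
        bits[victim] = 0
    if not ones:
        bits[int(rng.integers(0, len(bits)))] = 1
    return Genome(tuple(bits), g.max_strands)


@dataclass(frozen=True)
class ExploreConfig:
    budget: int = 300_000
    runs: int = 10
    seed: int = 0
    init_size: int = 100
    max_strands: int = DEFAULT_MAX_STRANDS

    def __post_init__(self) -> None:
        if self.budget < 1 or self.runs < 1 or self.init_size < 1:
            raise ValueError("budget, runs and init_size must be positive")


def _evaluator(
    library: Library, fitness_name: str, enum_params: EnumParams, desc_cfg: DescriptorConfig
) -> Callable[[Genome], Elite]:
    key = fitness_name.lower()
    if key not in ("mss", "ert"):
        raise ValueError("fitness_name must be 'MSS' or 'ERT'")

    def evaluate(g: Genome) -> Elite:
        crn = enumerate_crn(genome_to_strands(g, library), enum_params)
        m = crn_metrics(crn)
        features = (g.popcount, int(m["n_reactions"]), int(m["n_structures"]))
        b = compute_descriptors(*features, desc_cfg)
        summary = dict(m)
        summary["truncated"] = crn.truncated
        return Elite(g, float(m[key]), features, b, summary)

    return evaluate


def run_map_elites(
    library: Library,
    fitness_name: str,
    cfg: ExploreConfig,
    enum_params: EnumParams = EnumParams(),
    desc_cfg: DescriptorConfig = DescriptorConfig(),
) -> EliteGrid:
    """Steady-state MAP-Elites, fully reproducible from ``cfg.seed``.

    Initializes with ``init_size`` random genomes, then repeatedly mutates
    a uniformly drawn elite and places the offspring.  Truncated CRN
    evaluations are still placed (their metrics are computed on the
    truncated network) but flagged in the elite's summary.
    """
    rng = np.random.default_rng(cfg.seed)
    evaluate = _evaluator(library, fitness_name, enum_params, desc_cfg)
    grid = EliteGrid(desc_cfg, fitness_name.upper())
    grid.meta = {
        "library": library.spec.name,
        "seed": cfg.seed,
        "budget": cfg.budget,
        "init_size": cfg.init_size,
        "max_strands": cfg.max_strands,
        "batch_size": 1,
        "replacement": "strict-improvement",
    }
    n_init = min(cfg.init_size, cfg.budget)
    for _ in range(n_init):
        g = random_genome(library, rng, cfg.max_strands)
        place_elite(grid, evaluate(g))
        grid.evals += 1
    while grid.evals < cfg.budget:
        keys = sorted(grid.bins)
        parent = grid.bins[keys[int(rng.integers(0, len(keys)))]]
        child = mutate_genome(parent.genome, rng)
        place_elite(grid, evaluate(child))
        grid.evals += 1
    return grid


def exhaustive_grid(
    library: Library,
    fitness_name: str,
    max_strands: int = DEFAULT_MAX_STRANDS,
    enum_params: EnumParams = EnumParams(),
    desc_cfg: DescriptorConfig = DescriptorConfig(),
) -> EliteGrid:
    """Evaluate every non-empty subset of up to ``max_strands`` strands once."""
    evaluate = _evaluator(library, fitness_name, enum_params, desc_cfg)
    grid = EliteGrid(desc_cfg, fitness_name.upper())
    grid.meta = {"library": library.spec.name, "mode": "exhaustive", "max_strands": max_strands}
    n = len(library.strands)
    for k in range(1, min(max_strands, n) + 1):
        for idx in combinations(range(n), k):
            g = Genome.from_indices(idx, n, max_strands)
            place_elite(grid, evaluate(g))
            grid.evals += 1
    return grid


def aggregate_grids(grids: Sequence[EliteGrid]) -> EliteGrid:
    """Per-bin best fitness across runs (configs must match)."""
    if not grids:
        raise ValueError("no grids to aggregate")
    first = grids[0]
    for g in grids[1:]:
        if g.config != first.config or g.fitness_name != first.fitness_name:
            raise ValueError("grids have mismatched descriptor config or fitness")
    out = EliteGrid(first.config, first.fitness_name)
    out.meta = {"aggregated_runs": len(grids)}
    for g in grids:
        out.evals += g.evals
        for elite in g.bins.values():
            place_elite(out, elite)
    return out


def grid_report(a: EliteGrid, b: EliteGrid | None = None) -> dict:
    """Coverage (count and percentage over all bins) plus grid intersection."""
    report = {
        "n_filled": a.n_filled,
        "pct_filled": 100.0 * a.n_filled / a.config.total_bins,
        "total_bins": a.config.total_bins,
    }
    if b is not None:
        if b.config.shape != a.config.shape:
            raise ValueError("grids have different shapes")
        report["n_intersection"] = len(set(a.bins) & set(b.bins))
    return report
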