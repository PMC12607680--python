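"""Composite-module search: a weighted cluster of <=10 matrices inside a
sliding window, optimised by a genetic algorithm to separate Yes from No
promoter score distributions (one-sided Wilcoxon rank-sum).

The per-promoter module score is, over all window placements, the maximum of
sum_slots weight * (top-k match scores >= slot cutoff inside the window).
Fitness is -log10(separation p) minus a parsimony penalty per slot.  The
returned best-ever individual is the one with the smallest separation p
(ties broken by fitness), so the optimisation target and the reported
statistic coincide.  An optional label-permutation run estimates the null of
the optimised statistic, since optimising and testing on the same labels
inflates significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import PromoterRecord, PromoterSet, PWMatrix
from .motif_enrichment import encode_sequence, reverse_complement, window_scores

MAX_SLOTS = 10
WINDOW_RANGE = (200, 300)


@dataclass(frozen=True)
class ModuleSlot:
    matrix_id: str
    weight: float = 1.0
    slot_cutoff: float = 0.8
    max_sites_counted: int = 2

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("slot weight must be >= 0")
        if not 0.0 <= self.slot_cutoff <= 1.0:
            raise ValueError("slot_cutoff outside [0,1]")
        if self.max_sites_counted < 1:
            raise ValueError("max_sites_counted must be >= 1")


@dataclass(frozen=True)
class CompositeModule:
    slots: tuple[ModuleSlot, ...]
    window_len: int = 250

    def __post_init__(self) -> None:
        if not 1 <= len(self.slots) <= MAX_SLOTS:
            raise ValueError(f"module needs 1..{MAX_SLOTS} slots")
        if not WINDOW_RANGE[0] <= self.window_len <= WINDOW_RANGE[1]:
            raise ValueError(f"window_len outside {WINDOW_RANGE}")

    def matrix_ids(self) -> tuple[str, ...]:
        return tuple(s.matrix_id for s in self.slots)


@dataclass
class GAConfig:
    population_size: int = 100
    n_generations: int = 50
    mutation_prob: float = 0.2
    tournament_size: int = 3
    parsimony: float = 0.1
    stride: int = 10
    score_floor: float = 0.7  # cache floor; slot cutoffs never mutate below it
    cutoff_choices: tuple[float, ...] = (0.7, 0.75, 0.8, 0.85, 0.9, 0.95)
    k_choices: tuple[int, ...] = (1, 2, 3)
    window_choices: tuple[int, ...] = (200, 225, 250, 275, 300)
    crossover_prob: float = 0.5
    max_slots: int = MAX_SLOTS
    seed: int = 0
    n_permutations: int = 0


@dataclass
class CMAResult:
    module: CompositeModule
    wilcoxon_p: float
    yes_scores: np.ndarray
    no_scores: np.ndarray
    tf_regulatory_scores: dict[str, float]
    generations_run: int
    seed: int
    fitness: float
    elite_fitness_trace: list[float] = field(default_factory=list)
    permutation_null: list[float] = field(default_factory=list)  # -log10 p per permutation


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


class ScanCache:
    """Per (matrix, sequence) sorted match positions/scores above a floor.

    Both strands are merged onto forward coordinates; only scores >= floor
    are kept, which bounds memory and evaluation cost.
    """

    def __init__(
        self,
        library: Sequence[PWMatrix],
        sequences: Sequence[str],
        floor: float = 0.7,
    ) -> None:
        self.floor = floor
        self.seq_lens = [len(s) for s in sequences]
        self.lengths = {m.matrix_id: m.length for m in library}
        self.matches: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        for mat in library:
            per_seq = []
            for seq in sequences:
                seq = seq.upper()
                n = len(seq)
                fwd = window_scores(mat, encode_sequence(seq))
                rev = window_scores(mat, encode_sequence(reverse_complement(seq)))
                starts = []
                scores = []
                for j in np.flatnonzero(fwd >= floor):
                    starts.append(int(j))
                    scores.append(float(fwd[j]))
                for j in np.flatnonzero(rev >= floor):
                    starts.append(n - mat.length - int(j))
                    scores.append(float(rev[j]))
                order = np.argsort(starts, kind="stable")
                per_seq.append(
                    (np.asarray(starts, dtype=int)[order], np.asarray(scores)[order])
                )
            self.matches[mat.matrix_id] = per_seq


def _window_grid(seq_len: int, window_len: int, stride: int) -> np.ndarray:
    last = max(seq_len - window_len, 0)
    grid = np.arange(0, last + 1, stride)
    if grid[-1] != last:
        grid = np.append(grid, last)
    return grid


def _module_score_cached(
    module: CompositeModule, cache: ScanCache, seq_index: int, stride: int
) -> float:
    seq_len = cache.seq_lens[seq_index]
    win = min(module.window_len, seq_len)
    grid = _window_grid(seq_len, win, stride)
    total = np.zeros(grid.size)
    for slot in module.slots:
        starts, scores = cache.matches[slot.matrix_id][seq_index]
        length = cache.lengths[slot.matrix_id]
        sel = scores >= slot.slot_cutoff
        if not sel.any():
            continue
        s, v = starts[sel], scores[sel]
        lo = np.searchsorted(s, grid, side="left")
        hi = np.searchsorted(s, grid + win - length, side="right")
        counts = hi - lo
        cs = np.concatenate([[0.0], np.cumsum(v)])
        contrib = cs[hi] - cs[lo]
        over = np.flatnonzero(counts > slot.max_sites_counted)
        for w in over:
            top = np.sort(v[lo[w] : hi[w]])[-slot.max_sites_counted :]
            contrib[w] = top.sum()
        total += slot.weight * contrib
    return float(total.max()) if total.size else 0.0


def module_score(
    module: CompositeModule,
    promoter: PromoterRecord | str,
    library: Sequence[PWMatrix],
    stride: int = 10,
) -> float:
    """Score one promoter under a module (convenience single-sequence path)."""
    seq = promoter.sequence if isinstance(promoter, PromoterRecord) else promoter
    needed = {s.matrix_id for s in module.slots}
    mats = [m for m in library if m.matrix_id in needed]
    missing = needed - {m.matrix_id for m in mats}
    if missing:
        raise ValueError(f"module references unknown matrices: {sorted(missing)}")
    cache = ScanCache(mats, [seq], floor=0.0)
    return _module_score_cached(module, cache, 0, stride)


def separation_p(yes_scores: Sequence[float], no_scores: Sequence[float]) -> float:
    """One-sided Mann-Whitney p (Yes > No), mid-rank ties.

    Exact distribution when the pooled sample has <= 20 values and no ties,
    otherwise the normal approximation with tie correction.
    """
    yes = np.asarray(yes_scores, dtype=float)
    no = np.asarray(no_scores, dtype=float)
    if yes.size == 0 or no.size == 0:
        raise ValueError("both score vectors must be non-empty")
    pooled = np.concatenate([yes, no])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(yes, no, alternative="greater", method=method).pvalue)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


def _evaluate(
    module: CompositeModule,
    cache: ScanCache,
    n_yes: int,
    stride: int,
    parsimony: float,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    n_total = len(cache.seq_lens)
    scores = np.array(
        [_module_score_cached(module, cache, i, stride) for i in range(n_total)]
    )
    yes, no = scores[:n_yes], scores[n_yes:]
    p = separation_p(yes, no)
    fitness = -math.log10(p) - parsimony * len(module.slots)
    return p, fitness, yes, no


def _random_slot(rng: np.random.Generator, matrix_ids: Sequence[str], cfg: GAConfig) -> ModuleSlot:
    return ModuleSlot(
        matrix_id=matrix_ids[int(rng.integers(len(matrix_ids)))],
        weight=float(rng.uniform(0.2, 2.0)),
        slot_cutoff=float(cfg.cutoff_choices[int(rng.integers(len(cfg.cutoff_choices)))]),
        max_sites_counted=int(cfg.k_choices[int(rng.integers(len(cfg.k_choices)))]),
    )


def _mutate(
    module: CompositeModule,
    rng: np.random.Generator,
    matrix_ids: Sequence[str],
    cfg: GAConfig,
) -> CompositeModule:
    slots = list(module.slots)
    window_len = module.window_len
    if rng.uniform() < cfg.mutation_prob:
        window_len = int(cfg.window_choices[int(rng.integers(len(cfg.window_choices)))])
    new_slots = []
    for slot in slots:
        if rng.uniform() < cfg.mutation_prob:
            slot = replace(slot, weight=float(max(0.0, slot.weight * rng.lognormal(0.0, 0.4))))
        if rng.uniform() < cfg.mutation_prob:
            slot = replace(
                slot,
                slot_cutoff=float(cfg.cutoff_choices[int(rng.integers(len(cfg.cutoff_choices)))]),
            )
        if rng.uniform() < cfg.mutation_prob:
            slot = replace(
                slot, max_sites_counted=int(cfg.k_choices[int(rng.integers(len(cfg.k_choices)))])
            )
        new_slots.append(slot)
    slots = new_slots
    # structural moves: add or drop a slot
    if len(slots) < cfg.max_slots and rng.uniform() < cfg.mutation_prob:
        present = {s.matrix_id for s in slots}
        candidates = [m for m in matrix_ids if m not in present]
        if candidates:
            slot = _random_slot(rng, candidates, cfg)
            slots.append(slot)
    if len(slots) > 1 and rng.uniform() < cfg.mutation_prob:
        slots.pop(int(rng.integers(len(slots))))
    return CompositeModule(slots=tuple(slots), window_len=window_len)


def _crossover(
    a: CompositeModule, b: CompositeModule, rng: np.random.Generator, cfg: GAConfig
) -> CompositeModule:
    pool = list(a.slots) + list(b.slots)
    rng.shuffle(pool)
    seen: set[str] = set()
    slots = []
    for slot in pool:
        if slot.matrix_id in seen:
            continue
        if rng.uniform() < 0.5 or not slots:
            slots.append(slot)
            seen.add(slot.matrix_id)
        if len(slots) >= cfg.max_slots:
            break
    window_len = a.window_len if rng.uniform() < 0.5 else b.window_len
    return CompositeModule(slots=tuple(slots), window_len=window_len)


def _run_ga(
    cache: ScanCache,
    matrix_ids: Sequence[str],
    n_yes: int,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[CompositeModule, float, float, np.ndarray, np.ndarray, list[float]]:
    population: list[CompositeModule] = []
    # seed with every single-matrix module so the final best can never be
    # worse than the best single-matrix separation
    for mid in matrix_ids[: cfg.population_size]:
        population.append(CompositeModule(slots=(ModuleSlot(matrix_id=mid),), window_len=250))
    while len(population) < cfg.population_size:
        n_slots = int(rng.integers(1, min(4, cfg.max_slots, len(matrix_ids)) + 1))
        chosen = rng.choice(len(matrix_ids), size=n_slots, replace=False)
        slots = tuple(_random_slot(rng, [matrix_ids[i]], cfg) for i in chosen)
        window_len = int(cfg.window_choices[int(rng.integers(len(cfg.window_choices)))])
        population.append(CompositeModule(slots=slots, window_len=window_len))

    evals = [_evaluate(m, cache, n_yes, cfg.stride, cfg.parsimony) for m in population]
    best_idx = min(range(len(population)), key=lambda i: (evals[i][0], -evals[i][1]))
    best = (population[best_idx], *evals[best_idx])
    trace: list[float] = []

    for _ in range(cfg.n_generations):
        elite_idx = max(range(len(population)), key=lambda i: evals[i][1])
        trace.append(evals[elite_idx][1])
        next_pop = [population[elite_idx]]
        next_evals = [evals[elite_idx]]
        while len(next_pop) < cfg.population_size:
            def pick() -> int:
                contenders = rng.integers(0, len(population), size=cfg.tournament_size)
                return max(contenders, key=lambda i: evals[i][1])

            parent = population[pick()]
            if rng.uniform() < cfg.crossover_prob:
                child = _crossover(parent, population[pick()], rng, cfg)
            else:
                child = parent
            child = _mutate(child, rng, matrix_ids, cfg)
            next_pop.append(child)
            next_evals.append(_evaluate(child, cache, n_yes, cfg.stride, cfg.parsimony))
        population, evals = next_pop, next_evals
        gen_best = min(range(len(population)), key=lambda i: (evals[i][0], -evals[i][1]))
        if (evals[gen_best][0], -evals[gen_best][1]) < (best[1], -best[2]):
            best = (population[gen_best], *evals[gen_best])
    module, p, fitness, yes, no = best
    return module, p, fitness, yes, no, trace


def fit_cma(
    pwm_library: Sequence[PWMatrix],
    promoters: PromoterSet,
    ga_config: GAConfig | None = None,
) -> CMAResult:
    """Genetic-algorithm composite-module search over Yes/No promoters."""
    cfg = ga_config or GAConfig()
    promoters.require_nonempty_split()
    if len(pwm_library) < 1:
        raise ValueError("empty matrix library")
    yes = promoters.yes_records
    no = promoters.no_records
    sequences = [r.sequence for r in yes] + [r.sequence for r in no]
    cache = ScanCache(pwm_library, sequences, floor=cfg.score_floor)
    matrix_ids = [m.matrix_id for m in pwm_library]
    rng = np.random.default_rng([cfg.seed, 11])

    module, p, fitness, yes_scores, no_scores, trace = _run_ga(
        cache, matrix_ids, len(yes), cfg, rng
    )

    tf_scores = _drop_one_scores(module, p, cache, len(yes), cfg, pwm_library)

    perm_null: list[float] = []
    if cfg.n_permutations > 0:
        n_total = len(sequences)
        for _ in range(cfg.n_permutations):
            perm = rng.permutation(n_total)
            perm_cache = _permuted_cache(cache, perm)
            p_perm = _run_ga(perm_cache, matrix_ids, len(yes), cfg, rng)[1]
            perm_null.append(-math.log10(p_perm))

    return CMAResult(
        module=module,
        wilcoxon_p=p,
        yes_scores=yes_scores,
        no_scores=no_scores,
        tf_regulatory_scores=tf_scores,
        generations_run=cfg.n_generations,
        seed=cfg.seed,
        fitness=fitness,
        elite_fitness_trace=trace,
        permutation_null=perm_null,
    )


def _permuted_cache(cache: ScanCache, perm: np.ndarray) -> ScanCache:
    out = ScanCache.__new__(ScanCache)
    out.floor = cache.floor
    out.seq_lens = [cache.seq_lens[i] for i in perm]
    out.lengths = cache.lengths
    out.matches = {
        mid: [per_seq[i] for i in perm] for mid, per_seq in cache.matches.items()
    }
    return out


def _drop_one_scores(
    module: CompositeModule,
    p_full: float,
    cache: ScanCache,
    n_yes: int,
    cfg: GAConfig,
    library: Sequence[PWMatrix],
) -> dict[str, float]:
    """Regulatory score per TF symbol: drop-one loss in -log10 separation p."""
    symbol_of = {}
    for mat in library:
        for sym in mat.tf_symbols:
            symbol_of.setdefault(mat.matrix_id, []).append(sym)
    scores = {sym: 0.0 for mat in library for sym in mat.tf_symbols}
    module_tfs = sorted({sym for s in module.slots for sym in symbol_of.get(s.matrix_id, [])})
    log_full = -math.log10(p_full)
    for tf in module_tfs:
        kept = tuple(
            s for s in module.slots if tf not in symbol_of.get(s.matrix_id, [])
        )
        if kept:
            reduced = CompositeModule(slots=kept, window_len=module.window_len)
            p_without, *_ = _evaluate(reduced, cache, n_yes, cfg.stride, cfg.parsimony)
        else:
            p_without = 1.0  # empty module scores every promoter 0
        scores[tf] = max(0.0, log_full - (-math.log10(p_without)))
    return scores


def regulatory_score(cma_result: CMAResult, tf_symbol: str) -> float:
    """Drop-one regulatory score of one TF; unknown symbols raise KeyError."""
    if tf_symbol not in cma_result.tf_regulatory_scores:
        raise KeyError(f"unknown TF symbol {tf_symbol!r}")
    return cma_result.tf_regulatory_scores[tf_symbol]


def module_to_dict(module: CompositeModule) -> dict:
    return {
        "window_len": module.window_len,
        "slots": [
            {
                "matrix_id": s.matrix_id,
                "weight": s.weight,
                "slot_cutoff": s.slot_cutoff,
                "max_sites_counted": s.max_sites_counted,
            }
            for s in module.slots
        ],
    }


def module_from_dict(data: dict) -> CompositeModule:
    return CompositeModule(
        slots=tuple(
            ModuleSlot(
                matrix_id=s["matrix_id"],
                weight=s["weight"],
                slot_cutoff=s["slot_cutoff"],
                max_sites_counted=s["max_sites_counted"],
            )
            for s in data["slots"]
        ),
        window_len=data["window_len"],
    )
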