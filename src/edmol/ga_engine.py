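"""Evolutionary loop over fingerprint vectors.

A population of real-valued fingerprint vectors is evolved with uniform
crossover (mixing ratio 0.2), Gaussian mutation (N(0, 0.2^2) noise on a
fraction 0.01 of the elements, clipped back to [0, 1]) and tournament
selection of size 3, with the top three individuals carried over unchanged
as parents.  Each individual is decoded to a molecule, inspected for
validity, screened by the structural blacklist / property windows /
database dedup, and scored by re-encoding the decoded molecule and applying
the property evaluator to the fresh fingerprint.  Evolution stops at 500
generations or after 30 generations without improvement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .chem_core import Fingerprint, Molecule, canonicalize, encode_ecfp, inspect_validity
from .constraints import (
    BlacklistConfig,
    PropertyWindow,
    check_property_window,
    check_structural,
)

WORST_FITNESS = -math.inf


@dataclass
class GAConfig:
    pop_size: int = 50
    cx_prob: float = 0.7
    mut_prob: float = 0.3
    tournament_size: int = 3
    mix_ratio: float = 0.2
    mut_sigma: float = 0.2
    mut_indpb: float = 0.01
    max_generations: int = 500
    patience: int = 30
    n_parents_kept: int = 3
    #: mutation rate used once when spawning the initial population
    init_indpb: float = 0.05
    n_decode_attempts: int = 10
    decode_max_len: int = 120
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.cx_prob, self.mut_prob, self.mix_ratio, self.mut_indpb, self.init_indpb):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.pop_size, self.tournament_size, self.max_generations) <= 0:
            raise ValueError("sizes must be positive")


@dataclass(eq=False)  # identity semantics: individuals are unique lineage nodes
class Individual:
    fp: Fingerprint
    decoded: Molecule | None = None
    fitness: float | None = None
    generation: int = 0
    parent_ids: tuple[int, ...] = ()
    filter_reasons: tuple[str, ...] = ()

    @property
    def fitness_value(self) -> float:
        return WORST_FITNESS if self.fitness is None else self.fitness


@dataclass
class FitnessSpec:
    """What 'fit' means for a campaign.

    ``maximize_property``/``minimize_property`` score the signed relative
    property change against the seed molecule, (t - t0) / |t0|;
    ``benchmark_score`` uses an external molecule scorer in [0, 1].
    """

    objective: str = "maximize_property"
    property_name: str = "s1"
    windows: tuple[PropertyWindow, ...] = ()
    reference_library: frozenset[str] = frozenset()
    blacklist: BlacklistConfig | None = None
    scorer: Callable[[Molecule], float] | None = None

    def __post_init__(self) -> None:
        if self.objective not in (
            "maximize_property",
            "minimize_property",
            "benchmark_score",
        ):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.objective == "benchmark_score" and self.scorer is None:
            raise ValueError("benchmark_score objective needs a scorer")


@dataclass
class EvolutionResult:
    best_per_generation: list[tuple[int, Individual]]
    best_overall: Individual
    termination_reason: str
    #: canonical SMILES -> fitness for every candidate that passed all
    #: filters at evaluation time (the campaign's deduplicated output)
    candidates: dict[str, float] = field(default_factory=dict)
    #: each generation's own top individual (not cumulative): the molecules
    #: the workflow "chooses" per generation
    generation_bests: list[tuple[int, Individual]] = field(default_factory=list)
    #: population size at every generation (constant by construction)
    population_sizes: list[int] = field(default_factory=list)


class DecoderFn(Protocol):
    def __call__(self, fp: Fingerprint, rng: np.random.Generator) -> Molecule | None: ...


class BatchRNNDecoder:
    """Adapter: sample the conditional LM, first valid string wins.

    Decoding a whole population at once (``decode_many``) runs the
    recurrence in lockstep over all pending individuals, retrying invalid
    rows for up to ``n_attempts`` rounds.
    """

    def __init__(self, model, n_attempts: int = 10, max_len: int = 120):
        self.model = model
        self.n_attempts = n_attempts
        self.max_len = max_len

    @staticmethod
    def _accept(s: str) -> Molecule | None:
        if s and inspect_validity(s).valid:
            mol = canonicalize(s)
            if mol.is_valid:
                return mol
        return None

    def __call__(self, fp: Fingerprint, rng: np.random.Generator) -> Molecule | None:
        for _ in range(self.n_attempts):
            mol = self._accept(self.model.sample(fp.values, rng, max_len=self.max_len))
            if mol is not None:
                return mol
        return None

    def decode_many(
        self, fps: Sequence[Fingerprint], rng: np.random.Generator
    ) -> list[Molecule | None]:
        out: list[Molecule | None] = [None] * len(fps)
        pending = list(range(len(fps)))
        for _ in range(self.n_attempts):
            if not pending:
                break
            mat = np.stack([fps[i].values for i in pending])
            samples = self.model.sample_batch(mat, rng, max_len=self.max_len)
            nxt = []
            for i, s in zip(pending, samples):
                mol = self._accept(s)
                if mol is not None:
                    out[i] = mol
                else:
                    nxt.append(i)
            pending = nxt
        return out


def rnn_decoder_fn(model, n_attempts: int = 10, max_len: int = 120) -> "BatchRNNDecoder":
    """Adapter around a trained decoder model (population-batched)."""
    return BatchRNNDecoder(model, n_attempts=n_attempts, max_len=max_len)


def library_decoder_fn(nn_library) -> DecoderFn:
    """Adapter around :class:`edmol.decoder.NNDecoderLibrary`."""

    def _decode(fp: Fingerprint, rng: np.random.Generator) -> Molecule | None:
        return nn_library.decode(fp)

    return _decode


# ---------------------------------------------------------------------------
# operators


def mutate_gaussian(
    fp: Fingerprint, sigma: float, indpb: float, rng: np.random.Generator
) -> Fingerprint:
    """Perturb each element with prob ``indpb`` by N(0, sigma^2); clip to [0,1]."""
    if sigma < 0 or not 0 <= indpb <= 1:
        raise ValueError("sigma must be >= 0 and indpb in [0, 1]")
    values = fp.values.copy()
    mask = rng.random(values.shape[0]) < indpb
    n = int(mask.sum())
    if n and sigma > 0:
        values[mask] = np.clip(values[mask] + rng.normal(0.0, sigma, n), 0.0, 1.0)
    return Fingerprint(values=values, is_binary=False)


def crossover_uniform(
    a: Fingerprint, b: Fingerprint, mix_ratio: float, rng: np.random.Generator
) -> tuple[Fingerprint, Fingerprint]:
    """Swap each position between children with prob ``mix_ratio``."""
    if len(a) != len(b):
        raise ValueError("fingerprint length mismatch")
    va, vb = a.values.copy(), b.values.copy()
    swap = rng.random(len(a)) < mix_ratio
    va[swap], vb[swap] = vb[swap], va[swap].copy()
    return (
        Fingerprint(values=va, is_binary=False),
        Fingerprint(values=vb, is_binary=False),
    )


def select_tournament(
    pop: Sequence[Individual], k: int, tournsize: int, rng: np.random.Generator
) -> list[Individual]:
    """k winners of independent uniform tournaments; ties broken uniformly."""
    if not pop:
        raise ValueError("empty population")
    if tournsize < 1:
        raise ValueError("tournament size must be >= 1")
    out = []
    for _ in range(k):
        idx = rng.integers(0, len(pop), size=tournsize)
        fits = np.array([pop[i].fitness_value for i in idx])
        best = np.flatnonzero(fits == fits.max())
        out.append(pop[idx[best[rng.integers(0, len(best))]]])
    return out


def init_population(
    seed_fp: Fingerprint, cfg: GAConfig, rng: np.random.Generator
) -> list[Individual]:
    """Seed + (pop_size - 1) mutants at the elevated initial mutation rate."""
    pop = [Individual(fp=Fingerprint(seed_fp.values.copy(), is_binary=seed_fp.is_binary))]
    for _ in range(cfg.pop_size - 1):
        pop.append(
            Individual(fp=mutate_gaussian(seed_fp, cfg.mut_sigma, cfg.init_indpb, rng))
        )
    return pop[: cfg.pop_size]


# ---------------------------------------------------------------------------
# evaluation


class _Evaluator:
    """Resolves fingerprints/molecules to property maps, with caching."""

    def __init__(self, predictor_or_oracle):
        self.backend = predictor_or_oracle
        self._cache: dict[str, dict] = {}

    def properties(self, mol: Molecule, fp: Fingerprint) -> dict:
        key = mol.smiles_canonical
        if key not in self._cache:
            backend = self.backend
            if hasattr(backend, "predict_array"):  # PredictorModel
                from .predictor import predict

                props = predict(backend, fp)
            elif getattr(backend, "takes_molecule", False):
                props = backend(mol)
            else:
                out = backend(fp)
                props = out if isinstance(out, dict) else {"value": float(out)}
            self._cache[key] = props
        return self._cache[key]


def evaluate_population(
    pop: Sequence[Individual],
    decoder_fn: DecoderFn,
    predictor_or_oracle,
    seed: Molecule,
    fitness: FitnessSpec,
    cfg: GAConfig,
    rng: np.random.Generator,
    *,
    _evaluator: _Evaluator | None = None,
    _t0: float | None = None,
    _result: EvolutionResult | None = None,
) -> list[Individual]:
    """Decode, filter and score every unevaluated individual in place.

    Individuals that fail decoding, the structural blacklist, a property
    window, or that duplicate the reference library receive worst fitness;
    the property evaluator is applied to the re-encoded fingerprint of the
    decoded molecule, not to the evolved vector.
    """
    ev = _evaluator or _Evaluator(predictor_or_oracle)
    t0 = _t0
    if t0 is None and fitness.objective != "benchmark_score":
        t0 = float(
            ev.properties(seed, encode_ecfp(seed))[fitness.property_name]
        )
    todo = [ind for ind in pop if ind.fitness is None]
    if hasattr(decoder_fn, "decode_many"):
        decoded = decoder_fn.decode_many([ind.fp for ind in todo], rng)
    else:
        decoded = [decoder_fn(ind.fp, rng) for ind in todo]
    for ind, mol in zip(todo, decoded):
        ind.decoded = mol
        if mol is None:
            ind.fitness, ind.filter_reasons = WORST_FITNESS, ("invalid",)
            continue
        try:
            if fitness.blacklist is not None:
                verdict = check_structural(mol, seed, fitness.blacklist)
                if not verdict.passed:
                    ind.fitness, ind.filter_reasons = WORST_FITNESS, verdict.reasons
                    continue
            fresh_fp = encode_ecfp(mol)
            if fitness.objective == "benchmark_score":
                score = float(fitness.scorer(mol))
            else:
                props = ev.properties(mol, fresh_fp)
                if fitness.windows and not check_property_window(props, fitness.windows):
                    ind.fitness, ind.filter_reasons = WORST_FITNESS, ("property_window",)
                    continue
                t = float(props[fitness.property_name])
                rel = (t - t0) / abs(t0) if t0 != 0 else t - t0
                score = rel if fitness.objective == "maximize_property" else -rel
        except RuntimeError:
            # pathological molecules (failed ring perception, descriptor
            # breakdown) are dropped as invalid rather than crashing the run
            ind.fitness, ind.filter_reasons = WORST_FITNESS, ("descriptor_error",)
            continue
        if mol.smiles_canonical in fitness.reference_library:
            ind.fitness, ind.filter_reasons = WORST_FITNESS, ("duplicate",)
            continue
        ind.fitness = score
        if _result is not None:
            prev = _result.candidates.get(mol.smiles_canonical)
            if prev is None or score > prev:
                _result.candidates[mol.smiles_canonical] = score
    return list(pop)


# ---------------------------------------------------------------------------
# main loop


def evolve(
    seed: Molecule,
    decoder_fn: DecoderFn,
    predictor_or_oracle,
    fitness: FitnessSpec,
    cfg: GAConfig | None = None,
) -> EvolutionResult:
    """Run one evolutionary campaign from a seed molecule.

    Deterministic given ``cfg.rng_seed``.  Raises if the seed is invalid or
    its own fingerprint cannot be decoded to any valid molecule.
    """
    cfg = cfg or GAConfig()
    if not seed.is_valid:
        raise ValueError("seed molecule is invalid")
    rng = np.random.default_rng(cfg.rng_seed)
    seed_fp = encode_ecfp(seed)
    if decoder_fn(seed_fp, rng) is None:
        raise ValueError("seed fingerprint is not decodable to a valid molecule")
    ev = _Evaluator(predictor_or_oracle)
    t0 = None
    if fitness.objective != "benchmark_score":
        t0 = float(ev.properties(seed, seed_fp)[fitness.property_name])
    result = EvolutionResult(best_per_generation=[], best_overall=None, termination_reason="")
    pop = init_population(seed_fp, cfg, rng)
    best_so_far: Individual | None = None
    stagnant = 0
    for gen in range(1, cfg.max_generations + 1):
        for ind in pop:
            ind.generation = gen
        evaluate_population(
            pop, decoder_fn, predictor_or_oracle, seed, fitness, cfg, rng,
            _evaluator=ev, _t0=t0, _result=result,
        )
        gen_best = max(pop, key=lambda i: i.fitness_value)
        result.generation_bests.append((gen, gen_best))
        result.population_sizes.append(len(pop))
        if best_so_far is None or gen_best.fitness_value > best_so_far.fitness_value:
            best_so_far = gen_best
            stagnant = 0
        else:
            stagnant += 1
        result.best_per_generation.append((gen, best_so_far))
        if stagnant >= cfg.patience:
            result.termination_reason = "stagnation"
            break
        if gen == cfg.max_generations:
            result.termination_reason = "max_generations"
            break
        # top-n elitism + tournament-filled mating pool with crossover/mutation
        elite = sorted(pop, key=lambda i: i.fitness_value, reverse=True)[
            : cfg.n_parents_kept
        ]
        elite = [
            Individual(fp=e.fp, decoded=e.decoded, fitness=e.fitness, generation=gen)
            for e in elite
        ]
        n_off = cfg.pop_size - len(elite)
        mates = select_tournament(pop, n_off, cfg.tournament_size, rng)
        offspring = [Individual(fp=Fingerprint(m.fp.values.copy(), is_binary=False)) for m in mates]
        for i in range(0, n_off - 1, 2):
            if rng.random() < cfg.cx_prob:
                c1, c2 = crossover_uniform(
                    offspring[i].fp, offspring[i + 1].fp, cfg.mix_ratio, rng
                )
                offspring[i] = Individual(fp=c1)
                offspring[i + 1] = Individual(fp=c2)
        for i in range(n_off):
            if rng.random() < cfg.mut_prob:
                offspring[i] = Individual(
                    fp=mutate_gaussian(offspring[i].fp, cfg.mut_sigma, cfg.mut_indpb, rng)
                )
        pop = elite + offspring
    result.best_overall = best_so_far
    return result
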