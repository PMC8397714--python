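"""Goal-directed benchmark suite (GuacaMol-style).

Scoring functions over molecules, each bounded in [0, 1]: rediscovery of a
target structure by fingerprint similarity, property-target tasks built
from Gaussian score modifiers over computed descriptors (logP, TPSA),
drug-likeness (QED) and the CNS MPO composite.  A benchmark run scores a
batch of generated molecules by top-k aggregation (mean over k of the mean
score of the k best, k in {1, 10, 100} truncated to the batch size).

``make_ga_generator`` drives the fingerprint GA against a benchmark: seed
molecules are the highest-scoring members of a reference library and the
campaign's deduplicated candidates form the generated batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chem_core import Molecule, canonicalize, encode_ecfp, tanimoto
from .ga_engine import DecoderFn, FitnessSpec, GAConfig, evolve
from .predictor import descriptor_properties


@dataclass(frozen=True)
class ScoreModifier:
    """Maps a raw descriptor value into [0, 1].

    ``gaussian``      exp(-(x-mu)^2 / (2 sigma^2))
    ``max_gaussian``  1 for x >= mu, gaussian tail below
    ``min_gaussian``  1 for x <= mu, gaussian tail above
    ``thresholded``   min(x, mu) / mu  (linear ramp capped at 1)
    """

    kind: str
    mu: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "min_gaussian", "max_gaussian", "thresholded"):
            raise ValueError(f"unknown modifier kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def modifier_score(x: float, m: ScoreModifier) -> float:
    if not math.isfinite(x):
        raise ValueError("modifier input must be finite")
    g = math.exp(-((x - m.mu) ** 2) / (2.0 * m.sigma**2))
    if m.kind == "gaussian":
        return g
    if m.kind == "max_gaussian":
        return 1.0 if x >= m.mu else g
    if m.kind == "min_gaussian":
        return 1.0 if x <= m.mu else g
    return min(max(x, 0.0), m.mu) / m.mu


# rediscovery targets (public structures)
REDISCOVERY_TARGETS: dict[str, str] = {
    "celecoxib": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "troglitazone": "Cc1c(C)c2c(c(C)c1O)CCC(C)(COc1ccc(CC3SC(=O)NC3=O)cc1)O2",
    "thiothixene": "CN1CCN(CC/C=C2\\c3ccccc3Sc3ccc(S(=O)(=O)N(C)C)cc32)CC1",
}


def rediscovery_score(generated: Sequence[Molecule], target: Molecule) -> float:
    """Max ECFP Tanimoto between any generated molecule and the target."""
    if not generated:
        raise ValueError("no generated molecules to score")
    if not target.is_valid:
        raise ValueError("invalid rediscovery target")
    tfp = encode_ecfp(target)
    return max(tanimoto(encode_ecfp(g), tfp) for g in generated if g.is_valid)


# property-target modifiers (parameters follow the published benchmark suite)
LOGP_M1 = ScoreModifier("min_gaussian", mu=-1.0, sigma=2.0)
LOGP_8 = ScoreModifier("max_gaussian", mu=8.0, sigma=2.0)
TPSA_150 = ScoreModifier("max_gaussian", mu=150.0, sigma=20.0)


def composite_scores(mol: Molecule) -> dict[str, float]:
    """All property-task scores for one molecule, each in [0, 1]."""
    props = descriptor_properties(mol)
    return {
        "logp_m1": modifier_score(props["logp"], LOGP_M1),
        "logp_8": modifier_score(props["logp"], LOGP_8),
        "tpsa_150": modifier_score(props["tpsa"], TPSA_150),
        "qed": props["qed"],
        "cns_mpo": props["cns_mpo"],
    }


def _property_scorer(task: str) -> Callable[[Molecule], float]:
    def scorer(mol: Molecule) -> float:
        return composite_scores(mol)[task]

    return scorer


def _rediscovery_scorer(target_smiles: str) -> Callable[[Molecule], float]:
    target_fp = encode_ecfp(canonicalize(target_smiles))

    def scorer(mol: Molecule) -> float:
        return tanimoto(encode_ecfp(mol), target_fp)

    return scorer


@dataclass
class BenchmarkSpec:
    name: str
    scorer: Callable[[Molecule], float]
    n_generate: int = 500
    top_k: tuple[int, ...] = (1, 10, 100)


def standard_benchmarks() -> dict[str, BenchmarkSpec]:
    """The eight tasks of the goal-directed comparison."""
    specs = {}
    for name, smi in REDISCOVERY_TARGETS.items():
        specs[f"{name}_red"] = BenchmarkSpec(f"{name}_red", _rediscovery_scorer(smi))
    for task in ("logp_m1", "logp_8", "tpsa_150", "qed", "cns_mpo"):
        specs[task] = BenchmarkSpec(task, _property_scorer(task))
    return specs


@dataclass
class BenchmarkResult:
    name: str
    score: float
    top1: float
    per_k: dict[int, float]
    n_generated: int
    top_molecules: list[tuple[str, float]]


def aggregate_topk(scores: Sequence[float], top_k: Sequence[int]) -> dict[int, float]:
    """Mean of the k best scores for each k (k truncated to the batch size)."""
    s = np.sort(np.asarray(scores, dtype=float))[::-1]
    out = {}
    for k in top_k:
        kk = min(k, len(s))
        if kk > 0:
            out[kk] = float(s[:kk].mean())
    return out


def run_benchmark(
    spec: BenchmarkSpec,
    generator: Callable[["BenchmarkSpec", np.random.Generator], Sequence[Molecule]],
    rng: np.random.Generator | None = None,
) -> BenchmarkResult:
    """Generate with ``generator``, dedup, and report the top-k aggregate."""
    rng = rng or np.random.default_rng(0)
    mols = [m for m in generator(spec, rng) if m is not None and m.is_valid]
    seen: set[str] = set()
    unique: list[Molecule] = []
    for m in mols:
        if m.smiles_canonical not in seen:
            seen.add(m.smiles_canonical)
            unique.append(m)
    if not unique:
        raise RuntimeError(f"benchmark {spec.name!r}: no valid molecule generated")
    pairs = []
    for m in unique:
        try:
            pairs.append((m.smiles_canonical, float(spec.scorer(m))))
        except RuntimeError:  # failed ring perception / descriptor breakdown
            continue
    if not pairs:
        raise RuntimeError(f"benchmark {spec.name!r}: no scorable molecule generated")
    scored = sorted(pairs, key=lambda t: t[1], reverse=True)
    per_k = aggregate_topk([s for _, s in scored], spec.top_k)
    return BenchmarkResult(
        name=spec.name,
        score=float(np.mean(list(per_k.values()))),
        top1=scored[0][1],
        per_k=per_k,
        n_generated=len(unique),
        top_molecules=scored[:10],
    )


def make_ga_generator(
    seed_library: Sequence[Molecule],
    decoder_fn: DecoderFn,
    ga_cfg: GAConfig | None = None,
    n_seeds: int = 8,
    novel_only: bool = True,
):
    """GA-backed molecule generator for benchmark campaigns.

    The ``n_seeds`` highest-scoring library molecules seed one GA run each
    (fitness = the benchmark scorer); all candidates that pass validity and
    the database dedup across the runs are pooled until ``spec.n_generate``
    molecules are collected.
    """
    if not seed_library:
        raise ValueError("empty seed library")
    ga_cfg = ga_cfg or GAConfig()
    reference = (
        frozenset(m.smiles_canonical for m in seed_library) if novel_only else frozenset()
    )

    def generator(spec: BenchmarkSpec, rng: np.random.Generator) -> list[Molecule]:
        ranked = sorted(seed_library, key=spec.scorer, reverse=True)
        seeds = ranked[: min(n_seeds, len(ranked))]
        fitness = FitnessSpec(
            objective="benchmark_score", scorer=spec.scorer, reference_library=reference
        )
        pool: dict[str, Molecule] = {}
        for seed in seeds:
            cfg = GAConfig(**{**ga_cfg.__dict__, "rng_seed": int(rng.integers(2**31))})
            try:
                result = evolve(seed, decoder_fn, None, fitness, cfg)
            except ValueError:
                continue  # undecodable seed: skip it
            for smi in result.candidates:
                pool.setdefault(smi, canonicalize(smi))
            if len(pool) >= spec.n_generate:
                break
        return list(pool.values())

    return generator
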