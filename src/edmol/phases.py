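"""Iterative extrapolation beyond the training property range.

One *phase* = generate molecules with the GA from the most extreme seeds,
label the novel ones with the (surrogate-)quantum oracle, retrain the
decoder and predictor on the enlarged dataset, and reselect seeds.  The
reference protocol aims S1 below 1.77 eV with 30 seeds, 300 evolution runs
per phase and three phases; the desk-scale defaults shrink this to 10
seeds and 30 runs with the surrogate oracle.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .chem_core import Molecule, encode_ecfp
from .decoder import TrainConfig, continue_training, train_decoder
from .ga_engine import FitnessSpec, GAConfig, evolve, rnn_decoder_fn
from .predictor import (
    PredictorTrainConfig,
    PropertyVector,
    train_predictor,
)


@dataclass
class PhaseConfig:
    n_seeds: int = 30
    n_repeats: int = 300
    n_phases: int = 3
    threshold_ev: float = 1.77
    direction: str = "minimize"
    property_name: str = "s1"

    def __post_init__(self) -> None:
        if min(self.n_seeds, self.n_phases) <= 0 or self.n_repeats < 0:
            raise ValueError("phase counts must be positive (n_repeats may be 0)")
        if self.direction not in ("minimize", "maximize"):
            raise ValueError("direction must be minimize or maximize")

    @classmethod
    def desk_scale(cls, **kw) -> "PhaseConfig":
        return cls(n_seeds=10, n_repeats=30, **kw)


@dataclass
class PhaseRow:
    phase: int
    generated_count: int
    below_threshold: int
    mean_property: float
    variance: float


@dataclass
class PhaseReport:
    rows: list[PhaseRow] = field(default_factory=list)
    #: accumulated labeled dataset (canonical SMILES -> property value)
    dataset: dict[str, float] = field(default_factory=dict)


def select_phase_seeds(
    labeled: Sequence[tuple[Molecule, float]], n: int, direction: str = "minimize"
) -> list[Molecule]:
    """The n most extreme molecules; ties broken by canonical SMILES order."""
    if not labeled:
        raise ValueError("no labeled molecules")
    if n > len(labeled):
        raise ValueError(f"requested {n} seeds from {len(labeled)} molecules")
    sign = 1.0 if direction == "minimize" else -1.0
    ranked = sorted(labeled, key=lambda t: (sign * t[1], t[0].smiles_canonical))
    return [m for m, _ in ranked[:n]]


def run_phase(
    seeds: Sequence[Molecule],
    decoder_fn,
    predictor,
    oracle: Callable[[Molecule], float],
    ga_cfg: GAConfig,
    phase_cfg: PhaseConfig,
    known: set[str],
    rng: np.random.Generator,
) -> tuple[list[tuple[Molecule, float]], PhaseRow]:
    """Run ``n_repeats`` evolution runs cycling over the seeds.

    Returns the oracle-labeled novel molecules (deduplicated against
    ``known`` and each other) and the phase summary row.
    """
    objective = (
        "minimize_property" if phase_cfg.direction == "minimize" else "maximize_property"
    )
    fitness = FitnessSpec(
        objective=objective,
        property_name=phase_cfg.property_name,
        reference_library=frozenset(known),
    )
    new: dict[str, Molecule] = {}
    for rep in range(phase_cfg.n_repeats):
        seed = seeds[rep % len(seeds)]
        cfg = replace(ga_cfg, rng_seed=int(rng.integers(2**31)))
        try:
            result = evolve(seed, decoder_fn, predictor, fitness, cfg)
        except ValueError:
            continue
        # harvest the best-fit molecule of each generation (the workflow's
        # per-generation choice), not every evaluated individual
        for _, ind in result.generation_bests:
            if ind.decoded is None:
                continue
            smi = ind.decoded.smiles_canonical
            if smi not in known and smi not in new:
                new[smi] = ind.decoded
    labeled = []
    for mol in new.values():
        try:
            labeled.append((mol, float(oracle(mol))))
        except Exception:  # oracle failure: molecule is skipped, not fatal
            continue
    values = np.array([v for _, v in labeled]) if labeled else np.array([])
    if phase_cfg.direction == "minimize":
        n_cross = int((values < phase_cfg.threshold_ev).sum())
    else:
        n_cross = int((values > phase_cfg.threshold_ev).sum())
    row = PhaseRow(
        phase=0,
        generated_count=len(labeled),
        below_threshold=n_cross,
        mean_property=float(values.mean()) if len(values) else float("nan"),
        variance=float(values.var()) if len(values) else float("nan"),
    )
    return labeled, row


def iterate_phases(
    initial: Sequence[tuple[Molecule, float]],
    oracle: Callable[[Molecule], float],
    phase_cfg: PhaseConfig | None = None,
    ga_cfg: GAConfig | None = None,
    decoder_cfg: TrainConfig | None = None,
    predictor_cfg: PredictorTrainConfig | None = None,
    rng_seed: int = 0,
    property_name: str | None = None,
    initial_decoder=None,
    warm_start_epochs: int | None = None,
) -> PhaseReport:
    """Run the full generate -> label -> retrain -> reseed loop.

    Each phase retrains the decoder and predictor on the union of all
    labeled data accumulated so far.  With ``initial_decoder`` the first
    phase reuses a decoder already fitted to the initial dataset, and with
    ``warm_start_epochs`` later phases continue optimising the existing
    decoder on the grown dataset instead of refitting from scratch — the
    desk-scale setting; pass neither to retrain fully each phase.
    """
    phase_cfg = phase_cfg or PhaseConfig.desk_scale()
    ga_cfg = ga_cfg or GAConfig(pop_size=20, max_generations=10, patience=5)
    decoder_cfg = decoder_cfg or TrainConfig()
    predictor_cfg = predictor_cfg or PredictorTrainConfig(hidden_layers=(32,), epochs=200)
    prop = property_name or phase_cfg.property_name
    rng = np.random.default_rng(rng_seed)
    report = PhaseReport()
    accumulated: dict[str, tuple[Molecule, float]] = {
        m.smiles_canonical: (m, v) for m, v in initial
    }
    report.dataset = {s: v for s, (_, v) in accumulated.items()}
    # warm-start retraining mutates the model: never touch the caller's copy
    decoder = copy.deepcopy(initial_decoder) if initial_decoder is not None else None
    for phase in range(1, phase_cfg.n_phases + 1):
        data = list(accumulated.values())
        pairs = [(encode_ecfp(m), m) for m, _ in data]
        if decoder is None:
            decoder = train_decoder(pairs, replace(decoder_cfg, seed=decoder_cfg.seed + phase))
        elif phase > 1:
            if warm_start_epochs:
                continue_training(decoder, pairs, warm_start_epochs,
                                  rng_seed=rng_seed + phase)
            else:
                decoder = train_decoder(
                    pairs, replace(decoder_cfg, seed=decoder_cfg.seed + phase)
                )
        pred_cfg = replace(predictor_cfg, seed=predictor_cfg.seed + phase)
        predictor = train_predictor(
            [(fp, PropertyVector({prop: v})) for (fp, _), (_, v) in zip(pairs, data)],
            pred_cfg,
        )
        seeds = select_phase_seeds(
            [(m, v) for m, v in data], min(phase_cfg.n_seeds, len(data)),
            phase_cfg.direction,
        )
        decoder_fn = rnn_decoder_fn(
            decoder, n_attempts=ga_cfg.n_decode_attempts, max_len=ga_cfg.decode_max_len
        )
        labeled, row = run_phase(
            seeds, decoder_fn, predictor, oracle, ga_cfg, phase_cfg,
            known=set(accumulated), rng=rng,
        )
        row.phase = phase
        report.rows.append(row)
        for mol, v in labeled:
            accumulated[mol.smiles_canonical] = (mol, v)
        report.dataset = {s: v for s, (_, v) in accumulated.items()}
    return report
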