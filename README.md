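# edmol — deep-learning-guided evolutionary molecular design

`edmol` is a Python implementation of an evolutionary de novo design method
for organic molecules that evolves *fingerprint vectors* instead of
molecular graphs or strings.  It is aimed at researchers in computational
chemistry and ML-for-molecules who want a self-contained, CPU-friendly
implementation of the fingerprint-GA + neural-decoder design loop to study,
extend, or benchmark against.

## The method

Three learned/analytic functions close the loop for a molecule m:

- **e(·)** — encoding: canonical SMILES → ECFP (Morgan) fingerprint
  **x** ∈ {0,1}⁵⁰⁰⁰ covering circular neighbourhoods up to bond diameter 6;
- **d(·)** — decoding: a conditional LSTM language model over overlapping
  three-character SMILES substrings that maps an (evolved, real-valued)
  fingerprint **z** back to SMILES strings;
- **f(·)** — property prediction: a feed-forward network on fingerprints
  (or an analytic descriptor / surrogate oracle).

A genetic algorithm evolves a population of vectors from the seed's
fingerprint **x₀**: uniform crossover (mixing ratio 0.2), Gaussian mutation
(N(0, 0.2²) noise on 1% of elements, clipped to [0,1]), tournament
selection (size 3) with the top-3 carried as parents, population 50,
crossover/mutation probabilities 0.7/0.3, termination at 500 generations or
30 stagnant ones.  Decoded candidates are validity-inspected, screened by a
structural blacklist (fused-ring sizes 4–7, ≤ 6 fused rings, alkyl chains
≤ 6 C, ring count within ±1 of the seed), property windows (e.g.
−7 eV < HOMO < −5 eV, LUMO < 0 eV), and deduplicated against the reference
database; fitness is evaluated on the *re-encoded* molecule, f(e(m)).
An outer "phase" loop (generate → label → retrain → reseed) extrapolates
beyond the training property range, and a goal-directed benchmark suite
(rediscovery, modified-logP/TPSA targets, QED, CNS MPO) scores the
generator by top-k aggregation.

The conditional LSTM (forward, BPTT, Adam) is implemented directly on
numpy; chemistry goes through RDKit, the property network through
scikit-learn.  Quantum-chemistry labelling is out of scope: deterministic
surrogate oracles stand where DFT labels would plug in, and a seeded
fragment-assembly generator supplies PubChem-like synthetic libraries
(see `docs/methods.md`).

## Worked example

Evolve a seed molecule toward a lower surrogate excitation energy (S1),
with the structural blacklist active and the 500-molecule synthetic library
as decoder corpus and dedup reference:

```bash
edmol --seed 1 evolve --seed-smiles "Cc1ccc(C(=O)NC2CCN(C)CC2)cc1" \
      --property s1 --direction decrease --out runs/demo
```

which trains the desk-scale decoder and prints

```
evolved stagnation; best fitness 0.4073 (778 candidates)
```

The fitness is the signed relative change of the (surrogate) S1 against
the seed (negated for minimisation), so the best decoded molecule —
`O=C1CCC(CCNC(O)CC2CCCNCC2)NCCN1` — lowered S1 by about 41%; 778 novel
candidate molecules passed validity, blacklist and dedup along the way,
and the run stopped after 30 generations without further improvement.
`runs/demo/generations.jsonl` logs the best SMILES and fitness per
generation, and `runs/demo/results.json` the final summary.

The same loop is exposed as a library:

```python
from edmol import (FixtureConfig, generate_library, encode_ecfp,
                   train_decoder, GAConfig, FitnessSpec, evolve)
from edmol.ga_engine import rnn_decoder_fn
from edmol.predictor import SurrogateOracle

library = generate_library(FixtureConfig(n_molecules=500, rng_seed=7))
decoder = train_decoder([(encode_ecfp(m), m) for m in library])
result = evolve(
    library[0],
    rnn_decoder_fn(decoder),
    SurrogateOracle(),
    FitnessSpec(objective="minimize_property", property_name="s1"),
    GAConfig(max_generations=40, patience=15, rng_seed=1),
)
print(result.best_overall.decoded, result.best_overall.fitness)
```

Other subcommands: `edmol fixtures` (write a labeled synthetic library),
`edmol train-decoder` / `edmol train-predictor`, `edmol phases` (the
iterative extrapolation study), and `edmol benchmark --task qed` (one
goal-directed campaign).

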