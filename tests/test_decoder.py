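"""Tokenisation, conditional LM training/sampling, fallback decoder, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edmol.chem_core import Fingerprint, canonicalize, encode_ecfp, tanimoto
from edmol.decoder import (
    DecoderModel,
    NNDecoderLibrary,
    SubstringVocab,
    TrainConfig,
    decode,
    detokenize,
    nn_decode,
    reconstructability,
    tokenize_smiles,
    train_decoder,
    validity_rate,
)

OVERFIT_CFG = TrainConfig(
    epochs=600,
    learning_rate=5e-3,
    dropout=0.0,
    hidden_units=32,
    embedding_dim=16,
    condition_dim=8,
    seed=1,
)


@pytest.fixture(scope="module")
def overfit_model():
    """Decoder memorising a single (fingerprint, molecule) pair."""
    mol = canonicalize("Cc1ccccc1O")
    fp = encode_ecfp(mol)
    return train_decoder([(fp, mol)], OVERFIT_CFG), fp, mol


class TestTokenization:
    def test_hand_enumerated_windows(self):
        assert tokenize_smiles("c1ccccc1") == ["c1c", "1cc", "ccc", "ccc", "ccc", "cc1"]

    def test_short_string_is_padded_single_token(self):
        assert tokenize_smiles("CC") == ["CC "]
        assert detokenize(["CC "]) == "CC"

    def test_empty_string_raises(self):
        with pytest.raises(ValueError):
            tokenize_smiles("")

    def test_detokenize_inverts_tokenize_on_fixture_library(self, fixture_library):
        for mol in fixture_library[:200]:
            s = mol.smiles_canonical
            assert detokenize(tokenize_smiles(s)) == s

    def test_vocab_covers_its_corpus(self, fixture_library):
        smiles = [m.smiles_canonical for m in fixture_library[:50]]
        vocab = SubstringVocab.from_corpus(smiles)
        for s in smiles:
            ids = vocab.encode(s)
            assert ids[0] == vocab.begin_id and ids[-1] == vocab.end_id

    def test_unknown_token_rejected(self):
        vocab = SubstringVocab.from_corpus(["CCO"])
        with pytest.raises(KeyError):
            vocab.encode("c1ccccc1")


class TestTokenizationProperties:
    @given(st.text(alphabet="CNOcn1()=#[]+-@/\\%Sl", min_size=1, max_size=60))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_detokenize_inverts_tokenize_on_arbitrary_strings(self, s):
        # the windowing round-trip is a pure string property: it must hold
        # for any character sequence, not only chemically valid SMILES
        if s != s.rstrip(" "):
            return
        assert detokenize(tokenize_smiles(s)) == s


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = TrainConfig(
            n_layers=2, hidden_units=5, embedding_dim=4, condition_dim=3,
            dropout=0.0, seed=3,
        )
        vocab = SubstringVocab(["c1c", "1cc", "ccc", "cc1"])
        model = DecoderModel(vocab, 10, cfg)
        rng = np.random.default_rng(0)
        seqs = np.array([[1, 3, 4, 5, 5, 6, 2], [1, 3, 4, 2, 0, 0, 0]])
        fps = rng.random((2, 10))
        _, grads = model._forward_batch(seqs, fps, rng, train=True)
        params = model._params()
        eps = 1e-6
        for pi, p in enumerate(params):
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = model._forward_batch(seqs, fps, rng, train=False)
                p[idx] = orig - eps
                lm = model._forward_batch(seqs, fps, rng, train=False)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[pi][idx] == pytest.approx(num, rel=1e-3, abs=1e-7)


class TestTrainingContracts:
    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            train_decoder([])

    def test_invalid_molecule_raises(self):
        bad = canonicalize("C1CC")
        with pytest.raises(ValueError):
            train_decoder([(Fingerprint(np.zeros(10)), bad)])

    def test_loss_decreases(self, overfit_model):
        model, _, _ = overfit_model
        assert model.loss_history[-1] < model.loss_history[0] / 10

    def test_fixed_seed_reproduces_loss_trajectory(self):
        mols = [canonicalize(s) for s in ("CCO", "CCN", "c1ccccc1")]
        pairs = [(encode_ecfp(m), m) for m in mols]
        cfg = TrainConfig(epochs=5, seed=11, hidden_units=8, embedding_dim=4,
                          condition_dim=4)
        a = train_decoder(pairs, cfg)
        b = train_decoder(pairs, cfg)
        assert a.loss_history == b.loss_history


class TestOverfitOracle:
    def test_training_smiles_dominates_samples(self, overfit_model):
        model, fp, mol = overfit_model
        samples = decode(model, fp, 30, rng=np.random.default_rng(5))
        top = max(set(samples), key=samples.count)
        assert top == mol.smiles_canonical
        assert samples.count(top) / len(samples) > 0.9

    def test_validity_and_reconstructability_are_one(self, overfit_model):
        model, fp, mol = overfit_model
        rng = np.random.default_rng(6)
        assert validity_rate(model, [fp], n_samples=20, rng=rng) == 1.0
        assert reconstructability(model, [(fp, mol)], n_strings=20, rng=rng) == 1.0

    def test_prediction_deterministic_given_seed(self, overfit_model):
        model, fp, _ = overfit_model
        a = decode(model, fp, 5, rng=np.random.default_rng(9))
        b = decode(model, fp, 5, rng=np.random.default_rng(9))
        assert a == b


class TestDecodeContracts:
    def test_zero_samples_rejected(self, overfit_model):
        model, fp, _ = overfit_model
        with pytest.raises(ValueError):
            decode(model, fp, 0)

    def test_max_len_respected(self, overfit_model):
        model, fp, _ = overfit_model
        for s in decode(model, fp, 10, max_len=6, rng=np.random.default_rng(2)):
            assert len(s) <= 6

    def test_batch_sampling_matches_contract(self, overfit_model):
        model, fp, mol = overfit_model
        mat = np.stack([fp.values] * 8)
        out = model.sample_batch(mat, np.random.default_rng(3), max_len=60)
        assert len(out) == 8
        assert mol.smiles_canonical in out


class TestNNDecode:
    def test_library_member_maps_to_itself(self, fixture_pairs):
        lib = fixture_pairs[:50]
        fp, mol = lib[7]
        assert nn_decode(lib, fp).smiles_canonical == mol.smiles_canonical

    def test_empty_library_raises(self, fixture_pairs):
        with pytest.raises(ValueError):
            nn_decode([], fixture_pairs[0][0])

    def test_matches_brute_force_scan(self, fixture_pairs, rng):
        lib = fixture_pairs[:80]
        vectorised = NNDecoderLibrary(lib)
        for _ in range(100):
            q = Fingerprint((rng.random(5000) < 0.01).astype(float))
            sims = [tanimoto(fp, q) for fp, _ in lib]
            best = max(sims)
            expected = min(
                (m for (f, m), s in zip(lib, sims) if s == best),
                key=lambda m: m.smiles_canonical,
            )
            assert nn_decode(lib, q).smiles_canonical == expected.smiles_canonical
            assert vectorised.decode(q).smiles_canonical == expected.smiles_canonical

    def test_zero_similarity_tie_breaks_lexicographically(self, fixture_pairs):
        lib = fixture_pairs[:10]
        q = Fingerprint(np.zeros(5000))
        got = nn_decode(lib, q)
        # all-zero query: every library similarity is 0, lexicographic winner
        assert got.smiles_canonical == min(
            m.smiles_canonical for _, m in lib
        )


class TestMetrics:
    def test_validity_rate_bounds_and_errors(self, overfit_model):
        model, fp, _ = overfit_model
        with pytest.raises(ValueError):
            validity_rate(model, [])
        assert 0.0 <= validity_rate(model, [fp], n_samples=5) <= 1.0

    def test_untrained_model_reconstructs_nothing(self, fixture_pairs):
        smiles = [m.smiles_canonical for _, m in fixture_pairs[:50]]
        vocab = SubstringVocab.from_corpus(smiles)
        cfg = TrainConfig(hidden_units=16, embedding_dim=8, condition_dim=8)
        untrained = DecoderModel(vocab, 5000, cfg)
        rec = reconstructability(
            untrained, fixture_pairs[:5], n_strings=20, rng=np.random.default_rng(0)
        )
        assert rec == 0.0

    def test_persistence_roundtrip(self, overfit_model, tmp_path):
        model, fp, _ = overfit_model
        path = tmp_path / "dec.npz"
        model.save(path)
        back = DecoderModel.load(path)
        a = decode(model, fp, 3, rng=np.random.default_rng(1))
        b = decode(back, fp, 3, rng=np.random.default_rng(1))
        assert a == b
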