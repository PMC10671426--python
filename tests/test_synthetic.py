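"""Synthetic study generator: determinism, constraints, bundle round-trips."""

import json

import numpy as np
import pytest

from protfit.couplings import read_ccmpred_matrix, read_ccmpred_raw
from protfit.datamodel import read_dms_table, read_fasta, read_msa
from protfit.embedders import EmbedderSpec, load_precomputed
from protfit.errors import ConfigError, DataError
from protfit.synthetic import (
    BlockSpec,
    GeneratorConfig,
    GroundTruth,
    SyntheticBlockEmbedder,
    gen_coupling_model,
    gen_dataset,
    gen_fitness,
    gen_mutants,
    gen_study,
    gen_wild_type,
)


class TestWildType:
    def test_seeded_and_sized(self):
        assert gen_wild_type(86, seed=1) == gen_wild_type(86, seed=1)
        assert len(gen_wild_type(86, seed=1)) == 86
        assert gen_wild_type(86, seed=1) != gen_wild_type(86, seed=2)


class TestMutants:
    def test_single_order_all_singles_unique(self):
        wt = gen_wild_type(30, seed=0)
        muts = gen_mutants(wt, 100, max_order=1, seed=0)
        assert all(len(m) == 1 for m in muts)
        keys = {tuple((x.position, x.alt_aa) for x in m) for m in muts}
        assert len(keys) == 100

    def test_exhaustion_raises(self):
        wt = gen_wild_type(5, seed=0)
        with pytest.raises(DataError):
            gen_mutants(wt, 19 * 5 + 1, max_order=1, seed=0)

    def test_orders_within_bound_and_positions_distinct(self):
        wt = gen_wild_type(40, seed=1)
        muts = gen_mutants(wt, 200, max_order=3, seed=1)
        for m in muts:
            assert 1 <= len(m) <= 3
            positions = [x.position for x in m]
            assert len(set(positions)) == len(positions)


class TestCouplingGenerator:
    def test_zero_sparsity_all_zero(self):
        model = gen_coupling_model(6, sparsity=0.0, seed=0)
        assert np.all(model.pair_potentials == 0)

    def test_symmetry(self):
        model = gen_coupling_model(6, sparsity=1.0, seed=3)
        e = model.pair_potentials
        np.testing.assert_array_equal(e, e.transpose(1, 0, 3, 2))

    def test_active_pair_count_within_binomial_error(self):
        L, sparsity = 40, 0.2
        model = gen_coupling_model(L, sparsity, seed=7)
        active = 0
        for i in range(L):
            for j in range(i + 1, L):
                if np.any(model.pair_potentials[i, j] != 0):
                    active += 1
        n_pairs = L * (L - 1) // 2
        mean = sparsity * n_pairs
        sd = np.sqrt(n_pairs * sparsity * (1 - sparsity))
        assert abs(active - mean) < 4 * sd


class TestBlockEmbedder:
    def test_deterministic_across_instances(self):
        a = SyntheticBlockEmbedder("e", L=10, dim=8, informative_fraction=0.5, seed=2)
        b = SyntheticBlockEmbedder("e", L=10, dim=8, informative_fraction=0.5, seed=2)
        seq = gen_wild_type(10, seed=0)
        np.testing.assert_array_equal(a.embed(seq).matrix, b.embed(seq).matrix)

    def test_disjoint_seeds_uncorrelated(self):
        L, D = 20, 64
        a = SyntheticBlockEmbedder("a", L, D, 1.0, seed=11)
        b = SyntheticBlockEmbedder("b", L, D, 1.0, seed=22)
        seqs = [gen_wild_type(L, seed=s) for s in range(200)]
        pa = np.array([a.embed(s).matrix.mean(axis=0) for s in seqs])
        pb = np.array([b.embed(s).matrix.mean(axis=0) for s in seqs])
        # mean absolute cross-correlation between informative subspaces
        ca = pa - pa.mean(0)
        cb = pb - pb.mean(0)
        corr = (ca / ca.std(0)).T @ (cb / cb.std(0)) / len(seqs)
        assert np.abs(corr).mean() < 0.1

    def test_uninformative_block_is_unlearnable(self):
        """Fitness on a 0%-informative block cannot be predicted (rho ~ 0)."""
        from protfit.model import MutationEffectModel

        cfg = GeneratorConfig(
            L=40,
            n_mutants=150,
            max_order=1,
            block_specs=(BlockSpec("dead", 16, 0.0), BlockSpec("alive", 16, 1.0)),
            signal_split={"dead": 0.0, "alive": 1.0, "local": 0.0},
            noise_sd=0.0,
            seed=3,
            enforce_envelope=False,
        )
        study = gen_dataset(cfg)
        m = MutationEffectModel.from_dataset(study.dataset, study.embedders)
        from protfit.ensemble import slice_blocks

        dead = slice_blocks(m.representation, ["dead"])
        from protfit.supervised import evaluate

        res = evaluate(dead, study.dataset.fitness, seed=0)
        assert abs(res.mean_rho) < 0.3

    def test_wrong_length_rejected(self):
        e = SyntheticBlockEmbedder("e", L=10, dim=4, informative_fraction=0.5, seed=0)
        with pytest.raises(DataError):
            e.embed("ACD")


class TestFitness:
    def test_noiseless_single_block_recoverable(self, tiny_study):
        # covered at scale by the acceptance suite; structural check here
        truth = tiny_study.truth
        assert set(truth.block_weights) == {"emb_a", "emb_b"}
        assert len(truth.noiseless_fitness) == 40

    def test_noise_increases_never_helps(self):
        """Expected held-out rho is monotone non-increasing in noise."""
        from protfit.model import MutationEffectModel

        rhos = []
        for noise in (0.0, 1.0):
            deltas = []
            for seed in range(3):
                cfg = GeneratorConfig(
                    L=30, n_mutants=120, max_order=1,
                    block_specs=(BlockSpec("a", 16, 1.0),),
                    signal_split={"a": 1.0, "local": 0.0},
                    noise_sd=noise, seed=seed, enforce_envelope=False,
                )
                study = gen_dataset(cfg)
                m = MutationEffectModel.from_dataset(study.dataset, study.embedders)
                deltas.append(m.fit(seed=seed).mean_rho)
            rhos.append(np.mean(deltas))
        assert rhos[0] > rhos[1]

    def test_local_weight_requires_coupling_model(self):
        with pytest.raises(ConfigError):
            gen_fitness(["ACD"], {}, None, {"local": 1.0}, 0.1, seed=0)


class TestGeneratorConfig:
    def test_envelope_enforced_by_default(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(L=10)
        with pytest.raises(ConfigError):
            GeneratorConfig(n_mutants=10)

    def test_split_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(signal_split={"plm_a": 0.5, "plm_b": 0.2, "local": 0.2})


@pytest.fixture(scope="module")
def bundle(tmp_path_factory, tiny_config):
    out = tmp_path_factory.mktemp("bundle") / "study"
    gen_study(tiny_config, out)
    return out


class TestStudyBundle:
    def test_bundle_round_trips_through_all_readers(self, bundle, tiny_config, tiny_study):
        name, wt = read_fasta(bundle / "wild_type.fasta")[0]
        assert wt == tiny_study.dataset.wild_type
        ds = read_dms_table(bundle / "dms.csv", wild_type=wt)
        assert len(ds) == tiny_config.n_mutants
        np.testing.assert_allclose(ds.fitness, tiny_study.dataset.fitness)
        raw = read_ccmpred_raw(bundle / "couplings.raw")
        np.testing.assert_array_equal(
            raw.pair_potentials, tiny_study.coupling_model.pair_potentials
        )
        mat = read_ccmpred_matrix(bundle / "couplings.mat")
        assert mat.L == tiny_config.L
        msa = read_msa(bundle / "msa.a3m", dialect="a3m")
        msa.validate_against(wt)
        for spec_def in tiny_config.block_specs:
            store = bundle / f"embeddings_{spec_def.name}.h5"
            spec = EmbedderSpec(spec_def.name, "precomputed", spec_def.dim, str(store))
            out = load_precomputed(spec, ["WT", ds.mutants[0].id])
            assert out["WT"].matrix.shape == (tiny_config.L, spec_def.dim)

    def test_ground_truth_and_manifest_present(self, bundle):
        truth = GroundTruth.from_json((bundle / "ground_truth.json").read_text())
        assert truth.signal_split["local"] == pytest.approx(0.30)
        manifest = json.loads((bundle / "manifest.json").read_text())
        names = {f["name"] for f in manifest["files"]}
        assert {"wild_type.fasta", "dms.csv", "couplings.raw", "ground_truth.json"} <= names

    def test_regeneration_bitwise_identical(self, bundle, tiny_config, tmp_path):
        again = tmp_path / "study2"
        gen_study(tiny_config, again)
        m1 = json.loads((bundle / "manifest.json").read_text())
        m2 = json.loads((again / "manifest.json").read_text())
        assert m1["files"] == m2["files"]
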