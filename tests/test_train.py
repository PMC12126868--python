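"""Loss definitions, MMD statistic and the joint training loop."""

import numpy as np
import pytest

import poligen as pg
from poligen.autodiff import Tensor
from poligen.mol_complex import ATOM_VOCAB, BOND_VOCAB
from poligen.networks import Denoiser, DenoiserConfig, DenoiserOutput, EncoderConfig
from poligen.schedule import NoiseSchedule
from poligen.train import (AdamW, LossWeights, TrainConfig, diffusion_loss,
                           example_losses, mmd_loss, node_count_loss,
                           prepare_example, train)

A, B = len(ATOM_VOCAB), len(BOND_VOCAB)


def _perfect_output(lig):
    X0 = lig.coords - lig.coords.mean(axis=0)
    H = lig.atom_types.copy()
    E = np.zeros((lig.n_atoms, lig.n_atoms, B))
    for i in range(lig.n_atoms):
        for j in range(lig.n_atoms):
            E[i, j, lig.bonds[i, j]] = 1.0
    return DenoiserOutput(X0, H, E)


class TestDiffusionLoss:
    def test_perfect_prediction_gives_zero(self, rng):
        lig = pg.make_toy_ligand("A", 6, rng)
        sched = NoiseSchedule(T=50)
        assert diffusion_loss(lig, _perfect_output(lig), 10, sched) \
            == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_unit_offset_uniform_case(self, rng):
        # X0_hat off by a unit vector on one atom, uniform category
        # predictions: loss = w_s(t) * (3*1 + 0.4*log A + 2*log B)
        lig = pg.make_toy_ligand("A", 7, rng)
        sched = NoiseSchedule(T=50)
        out = _perfect_output(lig)
        out.X0_hat = out.X0_hat.copy()
        out.X0_hat[2] += np.array([1.0, 0.0, 0.0])
        out.H0_hat = np.full((7, A), 1.0 / A)
        out.E0_hat = np.full((7, 7, B), 1.0 / B)
        t = 20
        expected = float(sched.snr_weight(t)) * (
            3.0 * 1.0 + 0.4 * np.log(A) + 2.0 * np.log(B))
        assert diffusion_loss(lig, out, t, sched) == pytest.approx(expected, abs=1e-6)

    def test_loss_decreases_as_mass_moves_to_truth(self, rng):
        lig = pg.make_toy_ligand("B", 6, rng)
        sched = NoiseSchedule(T=50)
        losses = []
        for conf in (0.4, 0.6, 0.8, 0.95):
            out = _perfect_output(lig)
            H = np.full((6, A), (1 - conf) / (A - 1))
            H[np.arange(6), lig.atom_types.argmax(axis=1)] = conf
            out.H0_hat = H
            losses.append(diffusion_loss(lig, out, 10, sched))
        assert np.all(np.diff(losses) < 0)

    def test_shape_mismatch_raises(self, rng):
        lig = pg.make_toy_ligand("A", 6, rng)
        out = _perfect_output(lig)
        out.X0_hat = out.X0_hat[:-1]
        with pytest.raises(ValueError):
            diffusion_loss(lig, out, 10, NoiseSchedule(T=50))


class TestMMD:
    def test_biased_self_statistic_is_exactly_zero(self, rng):
        Z = rng.normal(size=(16, 8))
        assert mmd_loss(Z, Z, biased=True) == pytest.approx(0.0, abs=1e-12)

    def test_same_distribution_below_permutation_null(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(40, 6))
        observed = mmd_loss(X, Y)
        pooled = np.vstack([X, Y])
        null = []
        for _ in range(200):
            perm = rng.permutation(80)
            null.append(mmd_loss(pooled[perm[:40]], pooled[perm[40:]]))
        assert observed < np.quantile(null, 0.95)

    def test_shifted_distribution_exceeds_null(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(40, 6)) + 5.0
        observed = mmd_loss(X, Y)
        pooled = np.vstack([X, Y])
        null = []
        for _ in range(200):
            perm = rng.permutation(80)
            null.append(mmd_loss(pooled[perm[:40]], pooled[perm[40:]]))
        assert observed > np.quantile(null, 0.95)


class TestNodeCountLoss:
    def test_perfect_logits_give_zero(self):
        logits = np.full(10, -1e3)
        logits[4] = 1e3
        assert node_count_loss(logits, 5, n_min=1) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_logits_give_log_R(self):
        R = 12
        assert node_count_loss(np.zeros(R), 3, n_min=1) \
            == pytest.approx(np.log(R), abs=1e-12)

    def test_out_of_range_count_raises(self):
        with pytest.raises(ValueError):
            node_count_loss(np.zeros(5), 7, n_min=1)

    def test_decreases_under_gradient_steps(self, rng):
        from poligen.autodiff import Parameter
        from poligen.train import _node_count_t
        logits = Parameter(rng.normal(size=8))
        opt = AdamW([logits], lr=0.05)
        first = float(_node_count_t(logits, 3, 1).data)
        for _ in range(50):
            opt.zero_grad()
            loss = _node_count_t(logits, 3, 1)
            loss.backward()
            opt.step()
        assert float(_node_count_t(logits, 3, 1).data) < first


@pytest.fixture(scope="module")
def small_setup():
    rng = np.random.default_rng(9)
    ds, prior = pg.make_dataset(12, rng)
    sched = NoiseSchedule(T=20)
    ecfg = EncoderConfig(layers=1, hidden=12, edge_dim=6, k=6, n_rbf=6)
    dcfg = DenoiserConfig(layers=1, hidden=12, edge_dim=6, k=6, n_rbf=6)
    return ds, prior, sched, ecfg, dcfg


class TestTrainingLoop:
    def test_loss_decreases_on_fixed_corpus(self, small_setup):
        ds, prior, sched, ecfg, dcfg = small_setup
        log = []
        train(ds, TrainConfig(epochs=12, batch_size=6, lr=3e-3, seed=4),
              schedule=sched, prior=prior, encoder_config=ecfg,
              denoiser_config=dcfg, log=log)
        first = np.mean([l["loss"] for l in log[:4]])
        last = np.mean([l["loss"] for l in log[-4:]])
        assert last < first

    def test_identical_seeds_identical_traces(self, small_setup):
        ds, prior, sched, ecfg, dcfg = small_setup
        logs = []
        for _ in range(2):
            log = []
            train(ds[:6], TrainConfig(epochs=2, batch_size=3, seed=11),
                  schedule=sched, prior=prior, encoder_config=ecfg,
                  denoiser_config=dcfg, log=log)
            logs.append([l["loss"] for l in log])
        assert logs[0] == logs[1]

    def test_total_equals_diffusion_when_aux_weights_zero(self, small_setup):
        ds, prior, sched, ecfg, dcfg = small_setup
        w = LossWeights(mmd_weight=0.0, node_count_weight=0.0)
        log = []
        train(ds[:4], TrainConfig(epochs=1, batch_size=4, seed=2),
              schedule=sched, prior=prior, encoder_config=ecfg,
              denoiser_config=dcfg, weights=w, log=log)
        for entry in log:
            assert entry["loss"] == pytest.approx(entry["diffusion"], rel=1e-12)

    def test_empty_dataset_raises(self, small_setup):
        _, prior, sched, ecfg, dcfg = small_setup
        with pytest.raises(ValueError):
            train([], TrainConfig(epochs=1))

    def test_checkpoint_roundtrip_bit_identical_loss(self, small_setup, tmp_path):
        ds, prior, sched, ecfg, dcfg = small_setup
        ckpt = train(ds[:4], TrainConfig(epochs=1, batch_size=4, seed=3),
                     schedule=sched, prior=prior, encoder_config=ecfg,
                     denoiser_config=dcfg)
        path = tmp_path / "ck.npz"
        ckpt.save(path)
        loaded = pg.Checkpoint.load(path)

        def eval_loss(ck):
            model = ck.build()
            rng = np.random.default_rng(77)
            ex = prepare_example(ds[0], 5, sched, prior, rng)
            dl, _, cl, _ = example_losses(model.encoder, model.denoiser, ex,
                                          sched, LossWeights())
            return float(dl.data), float(cl.data)

        assert eval_loss(ckpt) == eval_loss(loaded)

    def test_loss_invariant_under_rigid_motion_of_complex(self, small_setup):
        ds, prior, sched, ecfg, dcfg = small_setup
        rng0 = np.random.default_rng(31)
        enc = pg.LatentEncoder(ecfg, rng0)
        den = Denoiser(dcfg, rng0)
        cpx = ds[0]
        t = 7
        noise = rng0.standard_normal(cpx.ligand.coords.shape)
        noise -= noise.mean(axis=0)

        ex = prepare_example(cpx, t, sched, prior, np.random.default_rng(5),
                             coord_noise=noise)
        dl0, _, _, _ = example_losses(enc, den, ex, sched, LossWeights())

        Q = np.linalg.qr(np.random.default_rng(6).standard_normal((3, 3)))[0]
        shift = np.array([3.0, -1.0, 2.0])
        lig_r = pg.Ligand(cpx.ligand.coords @ Q.T + shift,
                          cpx.ligand.atom_types, cpx.ligand.bonds)
        poc_r = pg.Pocket(cpx.pocket.coords @ Q.T + shift,
                          cpx.pocket.atom_types, cpx.pocket.residue_ids,
                          cpx.pocket.atom_names, cpx.pocket.res_names)
        cpx_r = pg.build_complex(lig_r, poc_r)
        ex_r = prepare_example(cpx_r, t, sched, prior, np.random.default_rng(5),
                               coord_noise=noise @ Q.T)
        dl_r, _, _, _ = example_losses(enc, den, ex_r, sched, LossWeights())
        assert float(dl_r.data) == pytest.approx(float(dl0.data), rel=1e-6)

    def test_trained_model_beats_fresh_init_on_category_recovery(
            self, toy_dataset, toy_model):
        """After toy training the denoiser's atom-type cross-entropy on held
        noisy inputs is lower than an identically-shaped fresh network's."""
        complexes, prior = toy_dataset
        sched = toy_model.schedule
        fresh = Denoiser(toy_model.denoiser.config, np.random.default_rng(99))
        rng = np.random.default_rng(55)
        ce_trained, ce_fresh = [], []
        for cpx in complexes[:10]:
            ex = prepare_example(cpx, 10, sched, prior, rng)
            z = toy_model.encode(ex.ligand)
            for den, acc in ((toy_model.denoiser, ce_trained), (fresh, ce_fresh)):
                out = den.predict(ex.noisy_coords, ex.noisy_atoms,
                                  ex.noisy_bonds, ex.pocket, z, 10, sched.T)
                ce = -(ex.ligand.atom_types *
                       np.log(out.H0_hat + 1e-12)).sum(axis=1).mean()
                acc.append(ce)
        assert np.mean(ce_trained) < np.mean(ce_fresh)

    def test_surrogate_regression_loss_decreases(self, small_setup):
        ds, prior, sched, ecfg, dcfg = small_setup
        rng = np.random.default_rng(13)
        den = Denoiser(dcfg, rng)
        enc = pg.LatentEncoder(ecfg, rng)
        ex = prepare_example(ds[0], 5, sched, prior, rng)
        opt = AdamW(den.head_sa.parameters(), lr=0.02)
        vals = []
        for _ in range(30):
            opt.zero_grad()
            _, _, _, sl = example_losses(enc, den, ex, sched, LossWeights(),
                                         sa_target=0.9)
            sl.backward()
            opt.step()
            vals.append(float(sl.data))
        assert vals[-1] < vals[0]
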