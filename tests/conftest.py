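import numpy as np
import pytest

from viaphase.ground_truth import make_semantic_map
from viaphase.optics import OpticsConfig, reconstruct_phase
from viaphase.simulate import SimConfig, simulate_experiment


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """A small noisy simulated time-lapse shared across tests."""
    cfg = SimConfig(image_px=128, n_cells=5, n_frames=6, seed=7,
                    death_hazard_per_frame=0.15)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noisefree_experiment():
    cfg = SimConfig(image_px=128, n_cells=5, n_frames=6, seed=11,
                    death_hazard_per_frame=0.15, noise_sigma=0.0)
    return simulate_experiment(cfg)


def smooth_phase(rng, shape=(64, 64), lo=0.0, hi=1.5):
    """Random smooth phase field in [lo, hi] radians."""
    from scipy import ndimage
    raw = ndimage.gaussian_filter(rng.normal(size=shape), 4.0)
    raw -= raw.min()
    if raw.max() > 0:
        raw /= raw.max()
    return lo + (hi - lo) * raw


@pytest.fixture(scope="session")
def tiny_training_run():
    """A miniature end-of-pipeline training used by several tests.

    Four 64 x 64 sequences, a tiny encoder and a handful of epochs: big
    enough to learn the synthetic contrast, small enough for CI.
    """
    from viaphase.net import TrainConfig, build_model, split_sequences, train

    optics = OpticsConfig(pixel_size_um=0.325)
    dataset, recon, gt_maps = {}, {}, {}
    for i in range(4):
        cfg = SimConfig(image_px=64, n_cells=3, n_frames=6, seed=500 + i,
                        min_radius_px=5.0, max_radius_px=8.0,
                        death_hazard_per_frame=0.2)
        exp = simulate_experiment(cfg)
        sid = f"seq{i}"
        recon[sid] = [reconstruct_phase(st, optics) for st in exp.stacks]
        gt_maps[sid] = [make_semantic_map(fp) for fp in exp.fluorescence]
        dataset[sid] = [(recon[sid][f].phase, gt_maps[sid][f].labels)
                        for f in range(6)]
    split = split_sequences(sorted(dataset), seed=3)
    cfg = TrainConfig(epochs=6, patch_px=64, batch_size=4, seed=3)
    model = build_model(cfg)
    result = train(model, dataset, split, cfg)
    return {"model": model, "result": result, "dataset": dataset,
            "split": split, "cfg": cfg, "recon": recon, "gt_maps": gt_maps}
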