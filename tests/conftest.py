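import numpy as np
import pytest

import cvepkit as ck


@pytest.fixture(scope="session")
def code_set() -> ck.CodeSet:
    return ck.make_code_set()


@pytest.fixture(scope="session")
def fb_spec() -> ck.FilterBankSpec:
    return ck.FilterBankSpec()


@pytest.fixture(scope="session")
def noiseless_config() -> ck.SimulationConfig:
    """All stochastic nuisances off: trials of one target are identical."""
    return ck.SimulationConfig(
        latency_jitter_sd=0.0,
        session_amplitude_sigma=0.0,
        session_latency_sd=0.0,
        kernel_perturbation_sd=0.0,
        session_noise_sigma=0.0,
        blocks_per_session=1,
    )


@pytest.fixture(scope="session")
def noiseless_session(code_set, noiseless_config):
    """One noiseless block of 32 trials plus the subject that generated it."""
    subject = ck.sample_subject(7, noiseless_config)
    effect = ck.SessionEffect(noise_gain=0.0)
    tensor = ck.simulate_session(
        subject, effect, code_set, blocks=1, seed=11, config=noiseless_config
    )
    return subject, tensor


@pytest.fixture(scope="session")
def noiseless_model(noiseless_session, fb_spec):
    _, tensor = noiseless_session
    training = {i: tensor.block(1)[i - 1][None] for i in range(1, 33)}
    return ck.build_filter_set(training, fb_spec, tensor.sampling_rate)


@pytest.fixture(scope="session")
def small_study(code_set):
    """Two subjects, two blocks per session, default noise levels."""
    cfg = ck.SimulationConfig(blocks_per_session=2)
    return ck.simulate_study(2, code_set, cfg, seed=42)


@pytest.fixture(scope="session")
def label_shuffle_result(code_set, fb_spec):
    """Match rate of predictions against permuted labels over 50 blocks.

    Returns (match_fraction, n_trials); under label shuffling the
    expected match rate is chance (1/32) regardless of classifier skill.
    """
    from cvepkit.classification import projected_templates, score_subband_trial

    cfg = ck.SimulationConfig(blocks_per_session=1, n_channels=8)
    subj = ck.sample_subject(np.random.SeedSequence([500, 1, 0]), cfg)
    train = ck.simulate_session(subj, ck.SessionEffect(), code_set, 1, 501, cfg)
    training = {i: train.block(1)[i - 1][None] for i in range(1, 33)}
    model = ck.build_filter_set(training, fb_spec, cfg.sampling_rate)
    pt = projected_templates(model)
    rng = np.random.default_rng(502)
    matches, n = 0, 0
    for block in range(50):
        test = ck.simulate_session(
            subj, ck.SessionEffect(), code_set, 1, 1000 + block, cfg
        )
        decomposed = ck.filter_bank(test.block(1), fb_spec, cfg.sampling_rate)
        shuffled = rng.permutation(np.arange(1, 33))
        for t in range(32):
            d = score_subband_trial(
                decomposed[:, t], model, fb_spec, _proj_templates=pt
            )
            matches += d.predicted_class == shuffled[t]
            n += 1
    return matches / n, n


@pytest.fixture(scope="session")
def default_condition_runs(code_set, fb_spec):
    """Session-composition accuracies under the default study conditions.

    For 20 seeded single-subject studies (full 6-block sessions, default
    SNR and session effects) this computes, per seed:

    * intra-session accuracy (session-1 leave-one-block-out),
    * inter-session accuracy (session-1 model on session-2 blocks),
    * stepwise accuracies at steps 1, 2 and 11 for test block 12.
    """
    plans = ck.cross_session_plans()
    steps = {
        int(p.name[4:6]): p for p in ck.stepwise_plans(12)
    }
    out = {k: [] for k in ("intra", "inter", "step1", "step2", "step11")}
    for seed in range(600, 620):
        study = ck.simulate_study(1, code_set, ck.SimulationConfig(), seed)
        ev = ck.Evaluator(study, fb_spec)
        out["intra"].append(ev.plan_accuracy(plans[0], 1))
        out["inter"].append(ev.plan_accuracy(plans[1], 1))
        for s in (1, 2, 11):
            out[f"step{s}"].append(ev.plan_accuracy(steps[s], 1))
    return {k: np.asarray(v) for k, v in out.items()}
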