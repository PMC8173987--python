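import numpy as np
import pytest

from strideseg import SyntheticGaitConfig, bin_spanning_sampler, generate_dataset
from strideseg.hmm import GmmEmission, LeftRightHmm, left_right_mask


def random_toy_model(rng: np.random.Generator, n_states: int, d: int = 1,
                     n_components: int = 1, wrap_edge: bool = False,
                     free_ends: bool = True) -> LeftRightHmm:
    """A random left-right model with valid structure for oracle tests."""
    mask = left_right_mask(n_states, wrap_edge)
    A = np.where(mask, rng.uniform(0.2, 1.0, (n_states, n_states)), 0.0)
    A /= A.sum(axis=1, keepdims=True)
    if free_ends:
        start = rng.uniform(0.2, 1.0, n_states)
        start /= start.sum()
        end = rng.uniform(0.2, 1.0, n_states)
        end /= end.sum()
    else:
        start = np.zeros(n_states)
        start[0] = 1.0
        end = np.zeros(n_states)
        end[-1] = 1.0
    emissions = []
    for _ in range(n_states):
        w = rng.uniform(0.2, 1.0, n_components)
        w /= w.sum()
        emissions.append(GmmEmission(
            weights=w,
            means=rng.normal(0.0, 2.0, (n_components, d)),
            variances=rng.uniform(0.3, 2.0, (n_components, d))))
    return LeftRightHmm(transitions=A, start_probs=start, end_probs=end,
                        emissions=emissions, wrap_edge=wrap_edge,
                        free_ends=free_ends)


def enumerate_paths_log_scores(model: LeftRightHmm, X: np.ndarray):
    """Exhaustive per-path log scores over all n^T state paths.

    Independent of the forward/Viterbi implementation: scores are summed
    per path from the raw parameters. Returns (paths, scores) with paths of
    shape (n^T, T).
    """
    from itertools import product

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and model.emissions[0].n_features == 1:
        X = X.T
    T = len(X)
    n = model.n_states
    logB = np.column_stack([e.log_prob(X) for e in model.emissions])
    with np.errstate(divide="ignore"):
        logA = np.log(model.transitions)
        log_start = np.log(model.start_probs)
        log_end = np.log(model.end_probs)
    paths = np.array(list(product(range(n), repeat=T)), dtype=int)
    scores = log_start[paths[:, 0]] + log_end[paths[:, -1]]
    scores += logB[np.arange(T)[None, :], paths].sum(axis=1)
    for t in range(1, T):
        scores += logA[paths[:, t - 1], paths[:, t]]
    return paths, scores


@pytest.fixture(scope="session")
def small_dataset():
    """Four clean synthetic subjects with short bouts, at the working rate."""
    from strideseg import decimate_labeled_recording

    cfg = SyntheticGaitConfig(seed=11)
    data = generate_dataset(4, 3, bin_spanning_sampler((6, 12, 20)), cfg)
    return [decimate_labeled_recording(r) for r in data]
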