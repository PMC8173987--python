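"""Two-class left-right HMM for stride segmentation.

Strides are modeled by a strict left-right Markov chain (monotonic state
sequence s_0 .. s_{n-1}, forced to start in the first and end in the last
state); transitions — all within-bout movement that is not a labeled
stride — by a left-right chain with an extra wrap edge from the last back
to the first state and free start/end states. Both sub-models carry
diagonal-covariance Gaussian-mixture emissions and are trained unsupervised
with Baum-Welch (capped at ten iterations). The trained sub-models are
flattened into one combined (n+m)-state model whose cross edges are
estimated by decoding the training segments with their own class model and
counting state transitions over the merged per-bout state sequences;
emissions are copied unchanged.

At prediction time the combined model is decoded with Viterbi; any change
between a transition-class and a stride-class state, plus the wrap from the
last to the first stride state, marks a stride border, which is then snapped
to the gyr_ml minimum over the two state-occupancy runs flanking the change.

All probability computation is carried out in log space; per-sample emission
log-densities are floored at -700 to avoid -inf cascades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

VARIANCE_FLOOR = 1e-6
EMISSION_LOG_FLOOR = -700.0
LOG_ZERO = -np.inf

Array = np.ndarray


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

@dataclass
class GmmEmission:
    """Diagonal-covariance Gaussian mixture over feature vectors."""

    weights: Array  # (k,)
    means: Array    # (k, d)
    variances: Array  # (k, d), floored

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.maximum(
            np.atleast_2d(np.asarray(self.variances, dtype=float)), VARIANCE_FLOOR)
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ValueError("mixture weights must be a simplex")
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances must have matching shape")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def component_log_prob(self, X: Array) -> Array:
        """Per-component log density: shape (..., k)."""
        X = np.asarray(X, dtype=float)
        diff = X[..., None, :] - self.means  # (..., k, d)
        ll = -0.5 * np.sum(
            diff * diff / self.variances + np.log(2.0 * np.pi * self.variances),
            axis=-1)
        with np.errstate(divide="ignore"):
            logw = np.where(self.weights > 0, np.log(np.maximum(self.weights, 1e-300)),
                            LOG_ZERO)
        return ll + logw

    def log_prob(self, X: Array) -> Array:
        lp = logsumexp(self.component_log_prob(X), axis=-1)
        return np.maximum(lp, EMISSION_LOG_FLOOR)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

def _check_row_stochastic(A: Array, mask: Array, atol: float = 1e-9) -> None:
    if np.any(np.abs(A.sum(axis=1) - 1.0) > atol):
        raise ValueError("transition rows must sum to 1")
    if np.any(A[~mask] != 0.0):
        raise ValueError("structurally forbidden transition entries must be exactly 0")


def left_right_mask(n_states: int, wrap_edge: bool) -> Array:
    """Boolean mask of allowed edges: self-loops, forward edges, optional wrap."""
    mask = np.zeros((n_states, n_states), dtype=bool)
    idx = np.arange(n_states)
    mask[idx, idx] = True
    mask[idx[:-1], idx[:-1] + 1] = True
    if wrap_edge and n_states > 1:
        mask[n_states - 1, 0] = True
    return mask


@dataclass
class LeftRightHmm:
    """A stride- or transition-class sub-model."""

    transitions: Array
    start_probs: Array
    end_probs: Array
    emissions: List[GmmEmission]
    wrap_edge: bool = False
    free_ends: bool = False

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.start_probs = np.asarray(self.start_probs, dtype=float)
        self.end_probs = np.asarray(self.end_probs, dtype=float)
        n = self.n_states
        if self.transitions.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        _check_row_stochastic(self.transitions, self.structure_mask)

    @property
    def n_states(self) -> int:
        return len(self.emissions)

    @property
    def structure_mask(self) -> Array:
        return left_right_mask(self.n_states, self.wrap_edge)

    def to_dict(self) -> dict:
        return {
            "kind": "left_right",
            "wrap_edge": self.wrap_edge,
            "free_ends": self.free_ends,
            "transitions": self.transitions.tolist(),
            "start_probs": self.start_probs.tolist(),
            "end_probs": self.end_probs.tolist(),
            "emissions": [_emission_to_dict(e) for e in self.emissions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LeftRightHmm":
        return cls(
            transitions=np.array(d["transitions"]),
            start_probs=np.array(d["start_probs"]),
            end_probs=np.array(d["end_probs"]),
            emissions=[_emission_from_dict(e) for e in d["emissions"]],
            wrap_edge=d["wrap_edge"],
            free_ends=d["free_ends"],
        )


@dataclass
class CombinedHmm:
    """The flattened (n+m)-state segmentation model.

    States 0..m-1 carry the transition class, states m..m+n-1 the stride
    class (m transition states first, mirroring the combined state layout in
    which e.g. states 0-4 are transitions and 5-29 the stride chain).
    """

    transitions: Array
    state_class: List[str]  # "transition" | "stride" per state
    emissions: List[GmmEmission]
    start_probs: Array
    end_probs: Array

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.start_probs = np.asarray(self.start_probs, dtype=float)
        self.end_probs = np.asarray(self.end_probs, dtype=float)
        total = len(self.emissions)
        if self.transitions.shape != (total, total):
            raise ValueError("transition matrix shape mismatch")
        if len(self.state_class) != total:
            raise ValueError("state_class length mismatch")
        classes = list(dict.fromkeys(self.state_class))
        if classes and classes != ["transition", "stride"] and classes != ["stride"] \
                and classes != ["transition"]:
            raise ValueError("states must be ordered transition-block then stride-block")
        if np.any(np.abs(self.transitions.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.emissions)

    @property
    def n_transition_states(self) -> int:
        return sum(1 for c in self.state_class if c == "transition")

    @property
    def stride_first_state(self) -> int:
        return self.n_transition_states

    @property
    def stride_last_state(self) -> int:
        return self.n_states - 1

    def to_dict(self) -> dict:
        return {
            "kind": "combined",
            "transitions": self.transitions.tolist(),
            "state_class": list(self.state_class),
            "start_probs": self.start_probs.tolist(),
            "end_probs": self.end_probs.tolist(),
            "emissions": [_emission_to_dict(e) for e in self.emissions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombinedHmm":
        return cls(
            transitions=np.array(d["transitions"]),
            state_class=list(d["state_class"]),
            start_probs=np.array(d["start_probs"]),
            end_probs=np.array(d["end_probs"]),
            emissions=[_emission_from_dict(e) for e in d["emissions"]],
        )


def _emission_to_dict(e: GmmEmission) -> dict:
    return {"weights": e.weights.tolist(), "means": e.means.tolist(),
            "variances": e.variances.tolist()}


def _emission_from_dict(d: dict) -> GmmEmission:
    return GmmEmission(weights=np.array(d["weights"]), means=np.array(d["means"]),
                       variances=np.array(d["variances"]))


@dataclass
class TrainingReport:
    log_likelihood_per_iteration: List[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_left_right_model(sequences: Sequence[Array], n_states: int,
                          n_components: int = 1, wrap_edge: bool = False,
                          free_ends: bool = False, seed: int = 0) -> LeftRightHmm:
    """Initialize a left-right model by a naive equal split of each sequence.

    Each training sequence is divided into ``n_states`` contiguous,
    equal-as-possible segments; state i's mixture is initialized from the
    pooled i-th segments of all sequences (k-means++ for multi-component
    mixtures). Every structurally allowed edge of each transition row gets
    equal probability.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    seqs = [s.T if s.shape[0] == 1 and s.shape[1] > 1 else s for s in seqs]
    for i, s in enumerate(seqs):
        if len(s) < n_states:
            raise ValueError(
                f"sequence {i} has length {len(s)} < n_states {n_states}")

    pooled: List[List[Array]] = [[] for _ in range(n_states)]
    for s in seqs:
        for i, seg in enumerate(np.array_split(s, n_states, axis=0)):
            pooled[i].append(seg)

    emissions = []
    for i in range(n_states):
        X = np.concatenate(pooled[i], axis=0)
        emissions.append(_init_gmm(X, n_components, seed + i))

    A = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        A[i, i] = 0.5
        A[i, i + 1] = 0.5
    if wrap_edge and n_states > 1:
        A[n_states - 1, n_states - 1] = 0.5
        A[n_states - 1, 0] = 0.5
    else:
        A[n_states - 1, n_states - 1] = 1.0

    if free_ends:
        start = np.full(n_states, 1.0 / n_states)
        end = np.full(n_states, 1.0 / n_states)
    else:
        start = np.zeros(n_states)
        start[0] = 1.0
        end = np.zeros(n_states)
        end[-1] = 1.0

    return LeftRightHmm(transitions=A, start_probs=start, end_probs=end,
                        emissions=emissions, wrap_edge=wrap_edge,
                        free_ends=free_ends)


def _init_gmm(X: Array, k: int, seed: int) -> GmmEmission:
    d = X.shape[1]
    if k == 1:
        var = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
        return GmmEmission(weights=np.ones(1), means=X.mean(axis=0)[None, :],
                           variances=var[None, :])
    if len(X) < k:
        raise ValueError(f"only {len(X)} pooled samples for {k} mixture components")
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    labels = km.fit_predict(X)
    weights = np.empty(k)
    means = np.empty((k, d))
    variances = np.empty((k, d))
    global_var = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
    for c in range(k):
        members = X[labels == c]
        weights[c] = max(len(members), 1)
        means[c] = members.mean(axis=0) if len(members) else km.cluster_centers_[c]
        variances[c] = members.var(axis=0) if len(members) > 1 else global_var
    weights /= weights.sum()
    return GmmEmission(weights=weights, means=means,
                       variances=np.maximum(variances, VARIANCE_FLOOR))


# ---------------------------------------------------------------------------
# forward / backward / Viterbi
# ---------------------------------------------------------------------------

def _log_params(model) -> Tuple[Array, Array, Array]:
    with np.errstate(divide="ignore"):
        logA = np.where(model.transitions > 0,
                        np.log(np.maximum(model.transitions, 1e-300)), LOG_ZERO)
        log_start = np.where(model.start_probs > 0,
                             np.log(np.maximum(model.start_probs, 1e-300)), LOG_ZERO)
        log_end = np.where(model.end_probs > 0,
                           np.log(np.maximum(model.end_probs, 1e-300)), LOG_ZERO)
    return logA, log_start, log_end


def _emission_matrix(model, X: Array) -> Array:
    """(T, n_states) floored emission log-densities."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([e.log_prob(X) for e in model.emissions])


def _as_observation_matrix(features) -> Array:
    values = getattr(features, "values", features)
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def loglik(model, features) -> float:
    """Forward-algorithm log-likelihood (includes the end-state weighting)."""
    X = _as_observation_matrix(features)
    logB = _emission_matrix(model, X)
    logA, log_start, log_end = _log_params(model)
    alpha = log_start + logB[0]
    for t in range(1, len(X)):
        alpha = logB[t] + logsumexp(alpha[:, None] + logA, axis=0)
    return float(logsumexp(alpha + log_end))


def viterbi_decode(model, features) -> Array:
    """Most probable state path; ties break toward the lowest state index."""
    X = _as_observation_matrix(features)
    T = len(X)
    logB = _emission_matrix(model, X)
    logA, log_start, log_end = _log_params(model)
    n = len(log_start)
    delta = log_start + logB[0]
    back = np.zeros((T, n), dtype=np.int32)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = logB[t] + cand[back[t], np.arange(n)]
    delta = delta + log_end
    if not np.any(np.isfinite(delta)):
        raise ValueError("no admissible state path (all paths have zero probability)")
    path = np.empty(T, dtype=np.int32)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def _group_by_length(seqs: List[Array]) -> Dict[int, List[int]]:
    groups: Dict[int, List[int]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(len(s), []).append(i)
    return groups


def _e_step(model: LeftRightHmm, batch: Array):
    """Batched forward-backward on sequences of equal length.

    batch: (B, T, d). Returns (total loglik, gamma (B,T,n), xi_sum (n,n),
    comp_resp (B,T,n,k)).
    """
    B, T, _ = batch.shape
    n = model.n_states
    logA, log_start, log_end = _log_params(model)
    comp_lp = np.stack([e.component_log_prob(batch) for e in model.emissions],
                       axis=2)  # (B, T, n, k)
    logBm = np.maximum(logsumexp(comp_lp, axis=-1), EMISSION_LOG_FLOOR)  # (B,T,n)

    alpha = np.empty((B, T, n))
    alpha[:, 0] = log_start + logBm[:, 0]
    for t in range(1, T):
        alpha[:, t] = logBm[:, t] + logsumexp(
            alpha[:, t - 1][:, :, None] + logA[None], axis=1)
    ll = logsumexp(alpha[:, -1] + log_end, axis=1)  # (B,)
    if np.any(~np.isfinite(ll)):
        raise ValueError(
            "a training sequence has -inf likelihood under the initialized model; "
            "check the variance floor and feature scaling")

    beta = np.empty((B, T, n))
    beta[:, -1] = log_end
    for t in range(T - 2, -1, -1):
        beta[:, t] = logsumexp(
            logA[None] + (logBm[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2)

    gamma = alpha + beta - ll[:, None, None]

    # expected transition counts
    log_xi = (alpha[:, :-1, :, None] + logA[None, None] +
              (logBm[:, 1:] + beta[:, 1:])[:, :, None, :] - ll[:, None, None, None])
    xi_sum = np.exp(logsumexp(log_xi, axis=(0, 1)))

    # per-component responsibilities within each state
    log_resp = gamma[..., None] + comp_lp - logBm[..., None]
    comp_resp = np.exp(log_resp)

    return float(ll.sum()), np.exp(gamma), xi_sum, comp_resp


def baum_welch(model: LeftRightHmm, sequences: Sequence[Array], max_iter: int = 10,
               tol: float = 1e-4) -> Tuple[LeftRightHmm, TrainingReport]:
    """Expectation-maximization training of a left-right sub-model.

    Transition probabilities and mixture parameters are re-estimated; the
    start/end distributions and structural zeros are preserved exactly.
    Stops at ``max_iter`` iterations (default the ten-iteration cap) or when
    the relative log-likelihood improvement falls below ``tol``.
    """
    seqs = [_as_observation_matrix(s) for s in sequences]
    if not seqs:
        raise ValueError("no training sequences")
    n = model.n_states
    mask = model.structure_mask
    model = LeftRightHmm(transitions=model.transitions.copy(),
                         start_probs=model.start_probs.copy(),
                         end_probs=model.end_probs.copy(),
                         emissions=[GmmEmission(e.weights.copy(), e.means.copy(),
                                                e.variances.copy())
                                    for e in model.emissions],
                         wrap_edge=model.wrap_edge, free_ends=model.free_ends)
    report = TrainingReport()
    groups = _group_by_length(seqs)

    prev_ll = None
    for _ in range(max_iter):
        total_ll = 0.0
        xi_total = np.zeros((n, n))
        k = model.emissions[0].n_components
        d = model.emissions[0].n_features
        r_sum = np.zeros((n, k))
        rx_sum = np.zeros((n, k, d))
        rxx_sum = np.zeros((n, k, d))
        for T, idxs in groups.items():
            batch = np.stack([seqs[i] for i in idxs], axis=0)
            ll, gamma, xi, comp_resp = _e_step(model, batch)
            total_ll += ll
            xi_total += xi
            r_sum += comp_resp.sum(axis=(0, 1))
            rx_sum += np.einsum("btnk,btd->nkd", comp_resp, batch)
            rxx_sum += np.einsum("btnk,btd->nkd", comp_resp, batch ** 2)

        report.log_likelihood_per_iteration.append(total_ll)
        if prev_ll is not None:
            denom = max(abs(prev_ll), 1.0)
            if (total_ll - prev_ll) / denom < tol:
                report.converged = True
                break
        prev_ll = total_ll

        # M-step: transitions (structure-masked)
        A_new = np.where(mask, xi_total, 0.0)
        row_sums = A_new.sum(axis=1)
        for i in range(n):
            if row_sums[i] > 0:
                A_new[i] /= row_sums[i]
            else:
                A_new[i] = model.transitions[i]
        model.transitions = A_new

        # M-step: mixtures
        for i in range(n):
            state_mass = r_sum[i].sum()
            if state_mass <= 0:
                continue
            w = r_sum[i] / state_mass
            occupied = r_sum[i] > 1e-12
            e = model.emissions[i]
            means = e.means.copy()
            variances = e.variances.copy()
            means[occupied] = rx_sum[i][occupied] / r_sum[i][occupied, None]
            second = rxx_sum[i][occupied] / r_sum[i][occupied, None]
            variances[occupied] = np.maximum(second - means[occupied] ** 2,
                                             VARIANCE_FLOOR)
            model.emissions[i] = GmmEmission(weights=w, means=means,
                                             variances=variances)
        report.n_iterations += 1

    return model, report


# ---------------------------------------------------------------------------
# model combination and prediction
# ---------------------------------------------------------------------------

def combine_models(transition_model: LeftRightHmm, stride_model: LeftRightHmm,
                   labeled_bouts: Sequence[Sequence[Tuple[str, object]]],
                   smoothing: float = 1e-12) -> CombinedHmm:
    """Flatten the two sub-models into one (n+m)-state segmenter.

    Each bout is an ordered list of ``(class, feature sequence)`` segments
    tiling the bout. Every segment is decoded with its own class model; the
    decoded state sequences are merged per bout (transition states keep
    indices 0..m-1, stride states are offset to m..m+n-1) and all state
    transitions of the merged sequences are counted to estimate the combined
    transition matrix. Emissions are copied unchanged; start/end
    distributions come from the merged-sequence endpoints with add-one
    smoothing.
    """
    m = transition_model.n_states
    n = stride_model.n_states
    total = m + n
    counts = np.zeros((total, total))
    start_counts = np.ones(total)  # add-one smoothing
    end_counts = np.ones(total)

    for bout in labeled_bouts:
        if not any(cls == "stride" for cls, _ in bout):
            raise ValueError("every training bout must contain a stride segment")
        merged: List[int] = []
        for cls, feats in bout:
            if cls == "stride":
                states = viterbi_decode(stride_model, feats) + m
            elif cls == "transition":
                states = viterbi_decode(transition_model, feats)
            else:
                raise ValueError(f"unknown segment class {cls!r}")
            merged.extend(int(s) for s in states)
        start_counts[merged[0]] += 1
        end_counts[merged[-1]] += 1
        np.add.at(counts, (np.array(merged[:-1]), np.array(merged[1:])), 1.0)

    # structurally plausible edges: sub-model structures plus observed cross edges
    plausible = np.zeros((total, total), dtype=bool)
    plausible[:m, :m] = transition_model.structure_mask
    plausible[m:, m:] = stride_model.structure_mask
    plausible |= counts > 0

    A = np.where(plausible, counts + smoothing, 0.0)
    A /= A.sum(axis=1, keepdims=True)

    return CombinedHmm(
        transitions=A,
        state_class=["transition"] * m + ["stride"] * n,
        emissions=list(transition_model.emissions) + list(stride_model.emissions),
        start_probs=start_counts / start_counts.sum(),
        end_probs=end_counts / end_counts.sum(),
    )


def _state_runs(path: Array) -> List[Tuple[int, int, int]]:
    """Maximal constant runs as (state, start, end) with inclusive ends."""
    runs = []
    start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[start]:
            runs.append((int(path[start]), start, t - 1))
            start = t
    return runs


def predict_strides(model: CombinedHmm, features, gyr_ml: Array, fs: float,
                    offset: int = 0,
                    snap_run_limit_s: float = 0.25,
                    ) -> Tuple[List[Tuple[int, int]], Array]:
    """Decode a feature sequence and extract snapped stride intervals.

    Border candidates arise at any change between transition- and
    stride-class states and at the stride-model wrap (last stride state to
    first stride state). Each candidate border is snapped to the gyr_ml
    minimum over the union of the two state-occupancy runs flanking the
    change, each run truncated to ``snap_run_limit_s`` next to the change so
    a long transition run cannot pull the border onto an unrelated dip far
    from the decoded class change. ``offset`` shifts the returned sample
    indices (useful when the features cover a window of a longer recording).

    Returns ``(stride intervals, state path)``.
    """
    gyr_ml = np.asarray(gyr_ml, dtype=float)
    path = viterbi_decode(model, features)
    runs = _state_runs(path)
    limit = max(1, int(round(snap_run_limit_s * fs)))

    borders: List[Tuple[int, bool]] = []  # (sample index, next-run-is-stride)
    for r in range(len(runs) - 1):
        s_prev, a0, a1 = runs[r]
        s_next, b0, b1 = runs[r + 1]
        class_change = model.state_class[s_prev] != model.state_class[s_next]
        wrap = (s_prev == model.stride_last_state
                and s_next == model.stride_first_state)
        if not (class_change or wrap):
            continue
        lo = max(a0, a1 - limit + 1)
        hi = min(b1, b0 + limit - 1)
        region = gyr_ml[lo:hi + 1]
        border = lo + int(np.argmin(region))
        borders.append((border, model.state_class[s_next] == "stride"))

    strides: List[Tuple[int, int]] = []
    for k in range(len(borders) - 1):
        b, begins_stride = borders[k]
        b_next, _ = borders[k + 1]
        if begins_stride and b_next > b:
            strides.append((b + offset, b_next + offset))
    return strides, path
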