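"""Distance-parameterized HMM over C-alpha candidates and the unique-state
Viterbi decoder.

Each clustered C-alpha candidate becomes a hidden state. Transition
probabilities between states depend only on their Euclidean distance,
through a widened Gaussian density centered at the canonical consecutive
C-alpha spacing (mu = 3.8047 A, sigma = 0.036 A, widened by a scale factor
Lambda = 10), row-normalized over the allowed targets (self-transitions
excluded). Emission probabilities blend the classifier's per-state
amino-acid probabilities with a background composition by a normalized
geometric mean. The initial distribution weights each state by its
emission of the chain's first residue.

Decoding uses a Viterbi variant in which a hidden state may appear at most
once in a path: each dynamic-programming cell carries the visited-state
set of its best partial path, and transitions into an already-visited
state are forbidden. This is a history heuristic with O(T K^2) cost - the
exact simple-path optimum is combinatorial - and it coincides with the
unconstrained optimum whenever that optimum is itself a simple path.
Chains of a complex are aligned sequentially; the states consumed by one
chain are removed from the model before the next is aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .candidates import CaCandidate
from .constants import AA_ALPHABET, AA_BACKGROUND_SWISSPROT, AA_INDEX
from .model import BackboneChain, BackboneModel

_LOG_UNIFORM20 = -math.log(20.0)
_DENSE_LIMIT = 5000


class InsufficientStatesError(RuntimeError):
    """Raised when a chain has more residues than available hidden states."""


@dataclass(frozen=True)
class TransitionParams:
    """Gaussian transition-density parameters (Angstrom)."""

    mu: float = 3.8047
    sigma: float = 0.036
    lambda_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.lambda_scale <= 0:
            raise ValueError("sigma and lambda_scale must be positive")


def transition_density(x, params: TransitionParams = TransitionParams()):
    """Widened Gaussian density f(x) of an inter-state distance x.

    ``f(x) = 1 / (Lambda sigma sqrt(2 pi)) * exp(-(x - mu)^2 / (2 (Lambda sigma)^2))``
    """
    x = np.asarray(x, dtype=float)
    s = params.lambda_scale * params.sigma
    return np.exp(-((x - params.mu) ** 2) / (2 * s * s)) / (s * math.sqrt(2 * math.pi))


@dataclass
class Observation:
    """A chain sequence as amino-acid indices; -1 marks a non-standard
    residue, which emits uniformly from every state."""

    symbols: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)
        if self.symbols.ndim != 1 or self.symbols.size < 1:
            raise ValueError("observation must contain at least one symbol")
        if np.any(self.symbols >= 20):
            raise ValueError("symbol index out of range")

    @classmethod
    def from_sequence(cls, seq: str, name: str = "") -> "Observation":
        return cls(np.array([AA_INDEX.get(ch.upper(), -1) for ch in seq]),
                   name=name)

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class HmmModel:
    """lambda = (gamma, delta, Pi) over C-alpha candidate states.

    The full ``gamma`` is materialized at build time only for state counts
    up to 5,000 (the decoder always recomputes and renormalizes the
    transition matrix over the currently active subset, so ``gamma`` is a
    convenience for inspection). ``pi`` depends on the chain being aligned
    and the active states, so it is computed per chain.
    """

    states: list[CaCandidate]
    delta: np.ndarray
    params: TransitionParams = field(default_factory=TransitionParams)
    gamma: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def coords(self) -> np.ndarray:
        return np.array([s.coord for s in self.states])


def build_transition_matrix(
    coords, params: TransitionParams = TransitionParams()
) -> np.ndarray:
    """Row-normalized transition matrix from state coordinates.

    gamma[i, j] = f(|r_i - r_j|) for j != i, normalized per row;
    the diagonal is zero (no self-transitions).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least two states")
    return np.exp(_log_transition_matrix(coords, params))


def build_emission_matrix(aa_probs, background=None) -> np.ndarray:
    """Normalized geometric mean of predicted and background probabilities.

    delta[i, v] = sqrt(a_iv * b_v) / sum_u sqrt(a_iu * b_u)
    """
    a = np.asarray(aa_probs, dtype=float)
    b = (AA_BACKGROUND_SWISSPROT if background is None
         else np.asarray(background, dtype=float))
    if a.ndim != 2 or a.shape[1] != 20:
        raise ValueError("aa_probs must be (K, 20)")
    if b.shape != (20,) or np.any(b <= 0):
        raise ValueError("background must be strictly positive, length 20")
    if not np.isclose(b.sum(), 1.0, atol=1e-6):
        raise ValueError("background must sum to 1")
    g = np.sqrt(a * b)
    rows = g.sum(axis=1, keepdims=True)
    if np.any(rows == 0):
        raise ValueError("state with all-zero amino-acid probabilities")
    return g / rows


def initial_distribution(delta, first_symbol: int, active_states) -> np.ndarray:
    """Pi over the full state set, supported on ``active_states``.

    pi_i proportional to delta[i, first_symbol] over the active set; if the
    first symbol has zero emission everywhere (or is non-standard), fall
    back to uniform over the active states.
    """
    delta = np.asarray(delta, dtype=float)
    active = np.asarray(active_states, dtype=int)
    if active.size == 0:
        raise ValueError("active state set is empty")
    pi = np.zeros(delta.shape[0])
    if 0 <= first_symbol < delta.shape[1]:
        p = delta[active, first_symbol]
    else:
        p = np.zeros(active.size)
    total = p.sum()
    if total > 0:
        pi[active] = p / total
    else:
        pi[active] = 1.0 / active.size
    return pi


def build_hmm(
    candidates: list[CaCandidate],
    background=None,
    params: TransitionParams = TransitionParams(),
) -> HmmModel:
    """Assemble the HMM from clustered candidates."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate states")
    delta = build_emission_matrix(
        np.array([c.aa_probs for c in candidates]), background)
    coords = np.array([c.coord for c in candidates])
    gamma = (build_transition_matrix(coords, params)
             if len(candidates) <= _DENSE_LIMIT else None)
    return HmmModel(states=candidates, delta=delta, params=params, gamma=gamma)


@dataclass
class ChainTrace:
    """One chain aligned to the HMM: state path, coordinates, residues."""

    path: np.ndarray
    coords: np.ndarray
    residues: list[str]
    log_score: float
    name: str = ""
    simple: bool = True   # False only for unconstrained cross-check decodes

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.simple and len(np.unique(self.path)) != len(self.path):
            raise ValueError("state path revisits a hidden state")
        if not (len(self.path) == len(self.coords) == len(self.residues)):
            raise ValueError("path/coords/residues length mismatch")


def _log_transition_matrix(coords: np.ndarray,
                           params: TransitionParams) -> np.ndarray:
    """Row-normalized log transition matrix, computed fully in log space.

    Working with log densities keeps rows well-defined even when every
    pairwise distance sits far in the Gaussian tail (e.g. an isolated
    false-positive state), where linear-space densities underflow to zero.
    """
    s = params.lambda_scale * params.sigma
    d = cdist(coords, coords)
    logdens = -((d - params.mu) ** 2) / (2 * s * s) - math.log(
        s * math.sqrt(2 * math.pi))
    np.fill_diagonal(logdens, -np.inf)
    return logdens - logsumexp(logdens, axis=1, keepdims=True)


def _emission_logcol(logdelta: np.ndarray, symbol: int, k: int) -> np.ndarray:
    if symbol < 0:
        return np.full(k, _LOG_UNIFORM20)
    return logdelta[:, symbol]


def constrained_viterbi(
    model: HmmModel,
    obs: Observation,
    active_states=None,
    unique: bool = True,
) -> ChainTrace:
    """Best state path for one chain under the at-most-once constraint.

    With ``unique=False`` this is the standard Viterbi decoder (used for
    cross-checks); the default enforces simple paths via per-cell visited
    sets. Ties in the maximization are broken toward the lowest predecessor
    state index. Returns global state indices.
    """
    k_all = model.n_states
    active = (np.arange(k_all) if active_states is None
              else np.asarray(sorted(active_states), dtype=int))
    t_len = len(obs)
    if unique and active.size < t_len:
        raise InsufficientStatesError(
            f"chain '{obs.name or '?'}' has {t_len} residues but only "
            f"{active.size} hidden states remain")
    if active.size < 1 or (active.size < 2 and t_len > 1):
        raise InsufficientStatesError("need at least two active states")

    coords = model.coords[active]
    with np.errstate(divide="ignore"):
        logdelta = np.log(model.delta[active])
        logpi = np.log(initial_distribution(
            model.delta, obs.symbols[0], active)[active])
    k = active.size

    if t_len == 1:
        j = int(np.argmax(logpi + _emission_logcol(logdelta, obs.symbols[0], k)))
        score = float((logpi + _emission_logcol(logdelta, obs.symbols[0], k))[j])
        return ChainTrace(path=active[[j]], coords=coords[[j]],
                          residues=_residues(obs), log_score=score,
                          name=obs.name)

    loggamma = _log_transition_matrix(coords, model.params)
    score = logpi + _emission_logcol(logdelta, obs.symbols[0], k)
    backptr = np.zeros((t_len, k), dtype=np.int32)
    visited = np.eye(k, dtype=bool) if unique else None

    for t in range(1, t_len):
        m = score[:, None] + loggamma
        if unique:
            m[visited] = -np.inf
        best = np.argmax(m, axis=0)           # ties -> lowest predecessor
        score = m[best, np.arange(k)] + _emission_logcol(
            logdelta, obs.symbols[t], k)
        backptr[t] = best
        if unique:
            visited = visited[best].copy()
            visited[np.arange(k), np.arange(k)] = True
        if not np.any(np.isfinite(score)):
            raise RuntimeError(
                f"no feasible path for chain '{obs.name or '?'}' at step {t}")

    end = int(np.argmax(score))
    path_local = np.empty(t_len, dtype=int)
    path_local[-1] = end
    for t in range(t_len - 1, 0, -1):
        path_local[t - 1] = backptr[t, path_local[t]]
    path = active[path_local]
    return ChainTrace(path=path, coords=model.coords[path],
                      residues=_residues(obs), log_score=float(score[end]),
                      name=obs.name, simple=unique)


def _residues(obs: Observation) -> list[str]:
    return [AA_ALPHABET[s] if s >= 0 else "X" for s in obs.symbols]


def align_chains(
    model: HmmModel,
    chains: list[Observation],
    order: str = "input",
) -> list[ChainTrace]:
    """Align every chain, removing used states between chains.

    ``order='input'`` aligns chains as given; ``'longest_first'`` aligns
    longer chains first (results are returned in input order either way).
    Transition rows are renormalized over the remaining active states for
    each chain.
    """
    total = sum(len(c) for c in chains)
    if total > model.n_states:
        raise InsufficientStatesError(
            f"{total} residues requested but only {model.n_states} states")
    idx = list(range(len(chains)))
    if order == "longest_first":
        idx.sort(key=lambda i: -len(chains[i]))
    elif order != "input":
        raise ValueError("order must be 'input' or 'longest_first'")

    active = set(range(model.n_states))
    traces: list[ChainTrace | None] = [None] * len(chains)
    for i in idx:
        trace = constrained_viterbi(model, chains[i], active_states=active)
        traces[i] = trace
        active -= set(int(s) for s in trace.path)
    return traces  # type: ignore[return-value]


def traces_to_model(
    traces: list[ChainTrace], chain_ids: list[str] | None = None
) -> BackboneModel:
    """Assemble aligned traces into a C-alpha-only multi-chain model."""
    ids = chain_ids or [_default_chain_id(i) for i in range(len(traces))]
    chains = [
        BackboneChain(chain_id=cid, residues=list(t.residues), coords=t.coords)
        for cid, t in zip(ids, traces)
    ]
    return BackboneModel(chains=chains)


def _default_chain_id(i: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if i < 26:
        return letters[i]
    return letters[(i // 26) - 1] + letters[i % 26]
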