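"""Core cognitive map learner.

A cognitive map learner (CML) embeds observations and actions of an agent
into a common high-dimensional state space S (dimension ``n_s``) through two
linear maps,

* ``Q`` (``n_s x n_o``): observation embedding, ``s_t = Q o_t``;
* ``V`` (``n_s x n_a``): action embedding, used for the one-step prediction
  ``s_hat_{t+1} = s_t + V a_t``.

Both maps are adapted online by local, error-gated delta rules whose only
objective is next-observation prediction (predictive coding):

* ``dV = eta_v (s_{t+1} - s_hat_{t+1}) a_t^T``
* ``dQ = eta_q (s_hat_{t+1} - s_{t+1}) o_{t+1}^T``

After learning, the geometry of the map supports planning: the utility of an
action for reaching a goal embedding ``s* = Q o*`` from the current state is
the scalar product of its embedding with the goal direction
``d_t = s* - s_t``, i.e. ``u_t = V^T d_t``.  A third matrix ``W``
(``n_a x n_s``) can be trained with the same kind of delta rule to play the
role of ``V^T`` when weight transport is undesirable:
``dW = eta_w (a_t - W ds) ds^T`` with ``ds = s_{t+1} - s_t``.

Observations and actions are one-hot vectors for discrete problem spaces and
real-valued feature vectors for continuous ones.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CMLModel",
    "Transition",
    "select_action",
    "quantize_weights",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class Transition:
    """One experienced triple <observation, action, next observation>.

    Fields are dense vectors; for discrete environments they are one-hot.
    """

    o_t: np.ndarray
    a_t: np.ndarray
    o_next: np.ndarray

    def __post_init__(self) -> None:
        self.o_t = np.asarray(self.o_t, dtype=float)
        self.a_t = np.asarray(self.a_t, dtype=float)
        self.o_next = np.asarray(self.o_next, dtype=float)


def _one_hot(index: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[index] = 1.0
    return v


@dataclass
class CMLModel:
    """The learnable cognitive map: matrices Q, V, W plus hyperparameters.

    Parameters
    ----------
    n_o, n_a, n_s
        Observation, action and state-space dimensions.
    eta_q, eta_v, eta_w
        Nonnegative learning rates of the three delta rules.
    sigma_q, sigma_v, sigma_w
        Standard deviations of the Gaussian weight initialization.  The
        defaults are the discrete (one-hot) settings; continuous problems
        use :meth:`init_continuous`.
    normalize_v
        If set, every column of ``V`` is rescaled to unit Euclidean norm
        after each update.  Useful at small ``n_s`` where the implicit
        normalization of random high-dimensional vectors no longer holds.
    w_update
        ``"normalized"`` (default) divides the W delta rule by ``|ds|^2``
        (normalized LMS), keeping the rule stable whatever the scale of
        the state differences; ``"raw"`` applies the unnormalized delta
        rule, which requires ``eta_w |ds|^2 < 2`` to converge.
    """

    n_o: int
    n_a: int
    n_s: int
    eta_q: float = 0.1
    eta_v: float = 0.01
    eta_w: float = 0.01
    sigma_q: float = 1.0
    sigma_v: float = 0.1
    sigma_w: float = 0.1
    normalize_v: bool = False
    w_update: str = "normalized"
    rng_seed: int = 0
    Q: np.ndarray = field(init=False, repr=False)
    V: np.ndarray = field(init=False, repr=False)
    W: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.n_o, self.n_a, self.n_s) < 1:
            raise ValueError("dimensions must be positive")
        if min(self.eta_q, self.eta_v, self.eta_w) < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.w_update not in ("normalized", "raw"):
            raise ValueError("w_update must be 'normalized' or 'raw'")
        rng = np.random.default_rng(self.rng_seed)
        self.Q = rng.normal(0.0, self.sigma_q, size=(self.n_s, self.n_o))
        self.V = rng.normal(0.0, self.sigma_v, size=(self.n_s, self.n_a))
        self.W = rng.normal(0.0, self.sigma_w, size=(self.n_a, self.n_s))
        if self.normalize_v:
            self._renormalize_v()

    @classmethod
    def init_continuous(
        cls,
        n_o: int,
        n_a: int,
        n_s: int,
        eta_q: float = 0.0025,
        eta_v: float = 0.0005,
        eta_w: float = 0.0005,
        rng_seed: int = 0,
    ) -> "CMLModel":
        """Model for real-valued observations (smaller Q init, larger V)."""
        return cls(
            n_o=n_o, n_a=n_a, n_s=n_s,
            eta_q=eta_q, eta_v=eta_v, eta_w=eta_w,
            sigma_q=0.1, sigma_v=1.0, sigma_w=0.1,
            rng_seed=rng_seed,
        )

    # ------------------------------------------------------------------ #
    # forward maps

    def embed_observation(self, o: np.ndarray) -> np.ndarray:
        """State-space embedding ``s = Q o`` of an observation."""
        o = np.asarray(o, dtype=float)
        if o.shape != (self.n_o,):
            raise ValueError(f"observation has shape {o.shape}, expected ({self.n_o},)")
        return self.Q @ o

    def embed_node(self, index: int) -> np.ndarray:
        """Embedding of the one-hot observation with the given hot index."""
        return self.Q[:, index].copy()

    def predict_next_state(self, s_t: np.ndarray, a_t: np.ndarray) -> np.ndarray:
        """One-step prediction ``s_t + V a_t``."""
        s_t = np.asarray(s_t, dtype=float)
        a_t = np.asarray(a_t, dtype=float)
        if s_t.shape != (self.n_s,):
            raise ValueError(f"state has shape {s_t.shape}, expected ({self.n_s},)")
        if a_t.shape != (self.n_a,):
            raise ValueError(f"action has shape {a_t.shape}, expected ({self.n_a},)")
        return s_t + self.V @ a_t

    def compute_utilities(self, d_t: np.ndarray, use_w: bool = False) -> np.ndarray:
        """Utilities of all actions for moving along the goal direction d_t.

        ``V^T d_t`` by default; ``W d_t`` when ``use_w`` (the learned
        substitute for the transpose).
        """
        d_t = np.asarray(d_t, dtype=float)
        if d_t.shape != (self.n_s,):
            raise ValueError(f"direction has shape {d_t.shape}, expected ({self.n_s},)")
        return (self.W @ d_t) if use_w else (self.V.T @ d_t)

    # ------------------------------------------------------------------ #
    # plasticity

    def apply_plasticity(self, tr: Transition) -> float:
        """One delta-rule update from a transition; returns ``|error|^2``.

        The prediction error is computed from the pre-update matrices and
        gates all three updates.
        """
        s_t = self.embed_observation(tr.o_t)
        s_next = self.embed_observation(tr.o_next)
        s_hat = self.predict_next_state(s_t, tr.a_t)
        err = s_next - s_hat
        if not np.all(np.isfinite(err)):
            raise FloatingPointError("non-finite prediction error; reduce learning rates")
        self.V += self.eta_v * np.outer(err, tr.a_t)
        self.Q += self.eta_q * np.outer(-err, tr.o_next)
        ds = s_next - s_t
        self._w_step(tr.a_t - self.W @ ds, ds)
        if self.normalize_v:
            self._renormalize_v()
        return float(err @ err)

    def _w_step(self, resid: np.ndarray, ds: np.ndarray) -> None:
        scale = self.eta_w
        if self.w_update == "normalized":
            nsq = float(ds @ ds)
            if nsq == 0.0:
                return
            scale /= nsq
        self.W += scale * np.outer(resid, ds)

    def _update_indices(self, i: int, a: int, j: int) -> float:
        # fast path for one-hot transitions: only columns i, j of Q and
        # column a of V are touched (W updates stay dense).
        s_t = self.Q[:, i]
        s_next = self.Q[:, j].copy()
        err = s_next - s_t - self.V[:, a]
        if not np.all(np.isfinite(err)):
            raise FloatingPointError("non-finite prediction error; reduce learning rates")
        self.V[:, a] += self.eta_v * err
        self.Q[:, j] -= self.eta_q * err
        ds = s_next - s_t
        resid = -(self.W @ ds)
        resid[a] += 1.0
        self._w_step(resid, ds)
        if self.normalize_v:
            self.V[:, a] /= np.linalg.norm(self.V[:, a]) or 1.0
        return float(err @ err)

    def _renormalize_v(self) -> None:
        norms = np.linalg.norm(self.V, axis=0)
        norms[norms == 0] = 1.0
        self.V /= norms

    def train_on_replay(self, buffer, rounds: int = 10) -> np.ndarray:
        """Replay the buffer ``rounds`` times in stored order.

        Returns the learning curve: per-sweep mean squared prediction error
        ``|s_{t+1} - s_hat_{t+1}|^2``.
        """
        if rounds < 1:
            raise ValueError("rounds must be >= 1")
        if len(buffer) == 0:
            raise ValueError("replay buffer is empty")
        curve = np.empty(rounds)
        if hasattr(buffer, "index_triples"):
            triples = buffer.index_triples()
            for r in range(rounds):
                total = 0.0
                for i, a, j in triples:
                    total += self._update_indices(i, a, j)
                curve[r] = total / len(triples)
        else:
            for r in range(rounds):
                total = 0.0
                for tr in buffer:
                    total += self.apply_plasticity(tr)
                curve[r] = total / len(buffer)
        return curve

    # ------------------------------------------------------------------ #
    # misc

    def copy(self) -> "CMLModel":
        out = CMLModel.__new__(CMLModel)
        out.__dict__.update({k: v for k, v in self.__dict__.items()
                             if k not in ("Q", "V", "W")})
        out.Q, out.V, out.W = self.Q.copy(), self.V.copy(), self.W.copy()
        return out


def select_action(u_t: np.ndarray, g_t: np.ndarray) -> np.ndarray:
    """Winner-take-all over eligibilities ``u_t * g_t``.

    Actions with zero affordance are excluded outright (they can never be
    executed, whatever their utility).  Ties go to the lowest index.
    Returns a one-hot action code.
    """
    u_t = np.asarray(u_t, dtype=float)
    g_t = np.asarray(g_t, dtype=float)
    if u_t.shape != g_t.shape:
        raise ValueError("utility and affordance vectors differ in length")
    if not np.any(g_t > 0):
        raise NoAffordedActionError("all affordances are zero")
    e_t = u_t * g_t
    e_t[g_t <= 0] = -np.inf
    return _one_hot(int(np.argmax(e_t)), u_t.shape[0])


class NoAffordedActionError(RuntimeError):
    """Raised when no action has positive affordance."""


def quantize_weights(model: CMLModel, bits: int) -> CMLModel:
    """Uniformly quantize each weight matrix to ``2**bits`` levels.

    Levels span each matrix's own [min, max] range, emulating limited
    weight precision of in-memory-computing substrates.
    """
    if bits < 1:
        raise ValueError("bits must be >= 1")
    out = model.copy()
    levels = 2 ** bits - 1
    for name in ("Q", "V", "W"):
        m = getattr(out, name)
        lo, hi = m.min(), m.max()
        if hi > lo:
            q = np.round((m - lo) / (hi - lo) * levels) / levels
            setattr(out, name, q * (hi - lo) + lo)
    return out


_META_KEYS = ("n_o", "n_a", "n_s", "eta_q", "eta_v", "eta_w",
              "sigma_q", "sigma_v", "sigma_w", "normalize_v", "w_update",
              "rng_seed")


def save_checkpoint(model: CMLModel, path) -> None:
    """Write matrices + hyperparameters to a single ``.npz`` archive."""
    meta = {k: getattr(model, k) for k in _META_KEYS}
    np.savez(path, Q=model.Q, V=model.V, W=model.W,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_checkpoint(path) -> CMLModel:
    """Inverse of :func:`save_checkpoint`; round-trips bit-exactly."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        model = CMLModel.__new__(CMLModel)
        for k in _META_KEYS:
            setattr(model, k, meta[k])
        model.Q, model.V, model.W = z["Q"].copy(), z["V"].copy(), z["W"].copy()
    return model
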