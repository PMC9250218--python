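"""The three-layer generative progression model and its parameters.

Layer 1 (top): a continuous-time Markov jump process over K ordered disease
stages, constrained forward-only (the intensity matrix ``Q`` is upper
triangular and the last stage is absorbing).

Layer 2 (middle): per complication ``w`` an irreversible 0 -> 1 onset chain.
At a patient's first encounter while in stage ``k`` the complication is
already present with probability ``pi_onset[k, w]``; over a subsequent
interval of ``dt`` years ending in stage ``k`` an inactive complication
activates with probability ``1 - (1 - h_onset[k, w])**dt``, i.e. a per-year
onset hazard.

Layer 3 (bottom): a bipartite noisy-or network from the W complications to
the N binary clinical findings (ICD-10 codes).  A finding is positive if any
active complication "fires" it (activation probability ``A[w, n]``) or if
the always-on leak cause fires it (``leak[n]``).

Anchors are expert-asserted (complication -> code) links.  An anchored code
keeps only the link from its anchor complication; all its other links are
pruned from the connectivity mask, which removes ``W - 1`` activation
parameters per anchored code.  Unanchored codes stay fully connected.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .ingest import FindingVocabulary

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Anchors and connectivity

@dataclass(frozen=True)
class AnchorSet:
    """Expert (complication index -> ICD-10 codes) prior-knowledge links.

    Indices are 0-based.  Each code may be anchored to at most one
    complication.
    """

    anchors: dict
    names: dict | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "anchors",
            {int(w): tuple(str(c) for c in codes) for w, codes in self.anchors.items()},
        )
        seen = {}
        for w, codes in self.anchors.items():
            if w < 0:
                raise ValueError(f"negative complication index {w}")
            for c in codes:
                if c in seen:
                    raise ValueError(f"code {c!r} anchored to both {seen[c]} and {w}")
                seen[c] = w

    @property
    def n_codes(self) -> int:
        """Number of anchored codes (the C of the parameter reduction)."""
        return sum(len(v) for v in self.anchors.values())

    @property
    def n_complications_anchored(self) -> int:
        return len(self.anchors)

    def complication_of(self) -> dict:
        return {c: w for w, codes in self.anchors.items() for c in codes}

    def bound(self, vocabulary: FindingVocabulary) -> "AnchorSet":
        """Drop anchored codes absent from the vocabulary (logged)."""
        kept, dropped = {}, []
        for w, codes in self.anchors.items():
            inside = tuple(c for c in codes if c in vocabulary)
            dropped += [c for c in codes if c not in vocabulary]
            if inside:
                kept[w] = inside
        if dropped:
            logger.info("anchors: %d codes not in vocabulary, ignored: %s",
                        len(dropped), dropped)
        return AnchorSet(kept, self.names)

    @classmethod
    def from_yaml(cls, path) -> "AnchorSet":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc) -> "AnchorSet":
        anchors, names = {}, {}
        for entry in doc["complications"]:
            w = int(entry.get("index", entry["serial"] - 1))
            anchors[w] = tuple(entry.get("codes", ()))
            if "name" in entry:
                names[w] = entry["name"]
        return cls(anchors, names or None)

    def to_yaml(self, path) -> None:
        doc = {"complications": [
            {"serial": w + 1,
             "name": (self.names or {}).get(w, f"complication {w + 1}"),
             "codes": list(codes)}
            for w, codes in sorted(self.anchors.items())
        ]}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_anchor_set() -> AnchorSet:
    """The bundled 12-category type 2 diabetes anchor settings."""
    text = resources.files("stageflow").joinpath("data/diabetes_anchors.yaml").read_text()
    return AnchorSet._from_doc(yaml.safe_load(text))


@dataclass(frozen=True)
class ConnectivityMask:
    """W x N boolean matrix: complication w may activate finding n."""

    allowed: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed", np.asarray(self.allowed, dtype=bool))

    @property
    def n_links(self) -> int:
        return int(self.allowed.sum())

    @property
    def shape(self):
        return self.allowed.shape


def make_connectivity_mask(anchor_set: AnchorSet, vocabulary: FindingVocabulary,
                           W: int) -> ConnectivityMask:
    """Build the pruned complication -> finding topology.

    An anchored finding's column keeps exactly its anchor link; unanchored
    columns stay fully connected.  Anchored codes missing from the
    vocabulary are ignored with a log message.
    """
    N = len(vocabulary)
    allowed = np.ones((W, N), dtype=bool)
    for code, w in anchor_set.complication_of().items():
        if w >= W:
            raise ValueError(f"code {code!r} anchored to complication {w} but W={W}")
        if code not in vocabulary:
            logger.info("anchor code %r not in vocabulary; ignored", code)
            continue
        n = vocabulary.encode(code)
        allowed[:, n] = False
        allowed[w, n] = True
    return ConnectivityMask(allowed)


# ---------------------------------------------------------------------------
# Parameter counting

def count_parameters(K: int, W: int, N: int, anchored_codes: int = 0) -> int:
    """Parameter count of the three layers under anchor pruning.

    The unpruned model has ``K*K`` stage-transition parameters, ``2*K*W``
    onset parameters (an initial-onset probability and a per-year hazard for
    every stage/complication pair) and ``W*N`` activation parameters.  Each
    anchored code loses its ``W - 1`` non-anchor links.  Leak probabilities
    are maintained by the model but reported separately from this count.
    """
    if min(K, W, N) < 0:
        raise ValueError("dimensions must be non-negative")
    if not 0 <= anchored_codes <= N:
        raise ValueError("anchored_codes must be in [0, N]")
    return K * K + 2 * K * W + N * W - anchored_codes * (W - 1)


def count_free_parameters(K: int, W: int, N: int, anchored_codes: int = 0) -> int:
    """Count with the forward-only constraint on Q made explicit.

    The intensity matrix has only ``K*(K-1)/2`` free upper off-diagonal
    entries (diagonals are determined, the last row is zero).
    """
    full = count_parameters(K, W, N, anchored_codes)
    return full - K * K + K * (K - 1) // 2


# ---------------------------------------------------------------------------
# The model container

@dataclass
class ProgressionModel:
    """All learnable parameters of the three layers.

    Attributes
    ----------
    K, W, N : dimensions (stages, complications, findings).
    Q : (K, K) stage intensity matrix, per year.  Upper-triangular
        off-diagonals >= 0, rows sum to zero, last row all zero.
    pi_onset : (K, W) probability a complication is already present at a
        patient's first encounter, given the stage there.
    h_onset : (K, W) per-year onset hazard, applied with the stage of the
        destination encounter of each interval.
    A : (W, N) activation probabilities, zero wherever the mask forbids.
    leak : (N,) leak probabilities of the always-on cause.
    mask : ConnectivityMask of allowed activation links.
    codes : optional tuple of ICD-10 strings (the vocabulary order).
    anchor_set : optional AnchorSet the mask was built from.
    """

    K: int
    W: int
    N: int
    Q: np.ndarray
    pi_onset: np.ndarray
    h_onset: np.ndarray
    A: np.ndarray
    leak: np.ndarray
    mask: ConnectivityMask
    codes: tuple | None = None
    anchor_set: AnchorSet | None = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi_onset = np.asarray(self.pi_onset, dtype=float)
        self.h_onset = np.asarray(self.h_onset, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.leak = np.asarray(self.leak, dtype=float)

    def validate(self) -> list:
        return validate_model(self)

    def copy(self) -> "ProgressionModel":
        return replace(
            self, Q=self.Q.copy(), pi_onset=self.pi_onset.copy(),
            h_onset=self.h_onset.copy(), A=self.A.copy(), leak=self.leak.copy(),
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "K": self.K, "W": self.W, "N": self.N,
            "codes": list(self.codes) if self.codes is not None else None,
            "anchors": {str(w): list(c) for w, c in self.anchor_set.anchors.items()}
            if self.anchor_set is not None else None,
            "complication_names": dict(self.anchor_set.names)
            if self.anchor_set is not None and self.anchor_set.names else None,
            "mask": self.mask.allowed.astype(int).tolist(),
            "Q": self.Q.tolist(),
            "pi_onset": self.pi_onset.tolist(),
            "h_onset": self.h_onset.tolist(),
            "A": self.A.tolist(),
            "leak": self.leak.tolist(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProgressionModel":
        anchor_set = None
        if d.get("anchors") is not None:
            names = d.get("complication_names")
            anchor_set = AnchorSet(
                {int(w): tuple(c) for w, c in d["anchors"].items()},
                {int(w): n for w, n in names.items()} if names else None,
            )
        return cls(
            K=int(d["K"]), W=int(d["W"]), N=int(d["N"]),
            Q=np.array(d["Q"], dtype=float),
            pi_onset=np.array(d["pi_onset"], dtype=float),
            h_onset=np.array(d["h_onset"], dtype=float),
            A=np.array(d["A"], dtype=float),
            leak=np.array(d["leak"], dtype=float),
            mask=ConnectivityMask(np.array(d["mask"], dtype=bool)),
            codes=tuple(d["codes"]) if d.get("codes") is not None else None,
            anchor_set=anchor_set,
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ProgressionModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def validate_model(model: ProgressionModel) -> list:
    """Return a list of invariant violations (empty iff the model is valid)."""
    v = []
    K, W, N = model.K, model.W, model.N
    if K < 2:
        v.append(f"K={K} < 2")
    if W < 1:
        v.append(f"W={W} < 1")
    if N < 1:
        v.append(f"N={N} < 1")
    if model.Q.shape != (K, K):
        v.append(f"Q shape {model.Q.shape} != ({K}, {K})")
    else:
        Q = model.Q
        lower = np.tril(Q, -1)
        if np.any(lower != 0):
            v.append("Q has nonzero entries below the diagonal (not forward-only)")
        upper = np.triu(Q, 1)
        if np.any(upper < 0):
            idx = tuple(int(i) for i in np.argwhere(upper < 0)[0])
            v.append(f"Q off-diagonal negative at {idx}")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-8:
            v.append("Q rows do not sum to 0")
        if np.any(Q[-1] != 0):
            v.append("Q last row not zero (last stage must be absorbing)")
    for name, arr, shape in (
        ("pi_onset", model.pi_onset, (K, W)),
        ("h_onset", model.h_onset, (K, W)),
        ("A", model.A, (W, N)),
        ("leak", model.leak, (N,)),
    ):
        if arr.shape != shape:
            v.append(f"{name} shape {arr.shape} != {shape}")
        elif np.any((arr < 0) | (arr > 1)):
            v.append(f"{name} has entries outside [0, 1]")
    if model.mask.shape != (W, N):
        v.append(f"mask shape {model.mask.shape} != ({W}, {N})")
    else:
        if np.any(model.mask.allowed.sum(axis=0) == 0):
            v.append("mask has an all-false column (a finding with no parent)")
        if model.A.shape == (W, N):
            bad = np.argwhere((~model.mask.allowed) & (model.A != 0))
            for w, n in bad[:5]:
                v.append(f"A[{w},{n}] nonzero where mask forbids the link")
    return v


# ---------------------------------------------------------------------------
# Probability primitives

def noisy_or_probs(active, model: ProgressionModel) -> np.ndarray:
    """Vector of P(finding n positive) for all n, given active complications.

    ``p_n = 1 - (1 - leak_n) * prod_{w active, allowed} (1 - A[w, n])``.
    """
    active = np.asarray(active, dtype=bool)
    with np.errstate(divide="ignore"):
        log1mA = np.where(model.mask.allowed, np.log1p(-model.A), 0.0)
    s = active @ log1mA  # (N,)
    return 1.0 - (1.0 - model.leak) * np.exp(s)


def noisy_or_prob(active, finding_index: int, model: ProgressionModel) -> float:
    """P(one finding positive) under the noisy-or; see ``noisy_or_probs``."""
    if not 0 <= finding_index < model.N:
        raise IndexError(f"finding_index {finding_index} out of range")
    return float(noisy_or_probs(active, model)[finding_index])


def observation_log_likelihood(findings, active, model: ProgressionModel) -> float:
    """Log-probability of one slice's binary observation vector.

    ``findings`` is the set of positive vocabulary indices; everything else
    is an observed negative.  Returns ``-inf`` when some finding's noisy-or
    probability contradicts the observation exactly.
    """
    p = noisy_or_probs(active, model)
    pos = np.zeros(model.N, dtype=bool)
    idx = np.fromiter(findings, dtype=int, count=len(findings)) if findings else \
        np.empty(0, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= model.N):
        raise IndexError("finding index out of range")
    pos[idx] = True
    with np.errstate(divide="ignore"):
        ll = np.where(pos, np.log(p), np.log1p(-p))
    return float(ll.sum())


def stage_transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """Interval transition matrix ``expm(Q * dt)`` by uniformization.

    The series is truncated at 1e-12 Poisson tail mass and renormalized, so
    rows sum to one to near machine precision; products of upper-triangular
    matrices keep exact zeros below the diagonal, preserving the
    forward-only structure.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[0]
    lam = float(np.max(-np.diag(Q)))
    if lam <= 0:
        return np.eye(K)
    mu = lam * dt
    if mu > 30.0:  # keep the series short; halving preserves structure
        half = stage_transition_matrix(Q, dt / 2.0)
        return half @ half
    P1 = np.eye(K) + Q / lam
    w = math.exp(-mu)
    S = w * np.eye(K)
    Pm = np.eye(K)
    total = w
    m = 0
    while total < 1.0 - 1e-12 and m < 100_000:
        m += 1
        w *= mu / m
        Pm = Pm @ P1
        S += w * Pm
        total += w
    return S / total


def onset_prob(w: int, k: int, dt: float, model: ProgressionModel) -> float:
    """P(inactive complication w activates over dt years in stage k).

    At a patient's first encounter use ``pi_onset[k, w]`` instead.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    h = model.h_onset[k, w]
    return float(1.0 - (1.0 - h) ** dt)
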