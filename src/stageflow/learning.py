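"""Unsupervised parameter estimation by Monte Carlo EM.

The E-step runs blocked Gibbs sweeps over the hidden layers of each
patient:

* stages by forward filtering / backward sampling (FFBS) over the K-state
  forward-only chain, with interval transition matrices ``expm(Q dt)`` and
  emissions given by the complication onset-chain terms (the noisy-or
  observation terms do not depend on the stage and cancel);
* per-complication onset times by exact enumeration of the T + 1 monotone
  onset configurations, conditioned on the stages and the other
  complications (systematic-scan Gibbs);
* noisy-or cause responsibilities.  For the sufficient statistics we use
  the exact per-cause firing posteriors ``A[w,n] / p_n`` (respectively
  ``leak[n] / p_n``) of the standard firing-indicator augmentation,
  Rao-Blackwellized instead of sampled: a single "which parent did it" draw
  weighted by activation probability is biased whenever causes co-occur,
  while the expected firing counts leave the true parameters a fixed point
  of EM.  ``sample_attributions`` still draws a single nominal cause per
  positive finding for trajectory annotation.

The M-step is conjugate posterior-mean smoothing: Beta pseudo-counts for
every probability parameter, Gamma pseudo-counts for the intensity rates,
with the expected CTMC sufficient statistics (holding times and jump counts
between observed slice endpoints) obtained from Van Loan augmented matrix
exponentials.

Complication onset times are represented throughout as an onset-slice
vector ``tau`` of length W: ``tau[w] = t`` means complication w is first
active at slice t; ``tau[w] >= T`` means never active within the observed
window.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm as _dense_expm

from .ingest import FindingVocabulary, PatientHistory
from .model import (
    AnchorSet,
    ProgressionModel,
    make_connectivity_mask,
    stage_transition_matrix,
)

logger = logging.getLogger(__name__)


class ZeroProbabilityEvidenceError(ValueError):
    """Raised when a slice's evidence has probability zero under the model."""

    def __init__(self, patient_id, slice_index, detail=""):
        self.patient_id = patient_id
        self.slice_index = slice_index
        msg = f"patient {patient_id!r}: zero-probability evidence at slice {slice_index}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


@dataclass
class FitConfig:
    """Settings of the Monte Carlo EM fit.

    ``beta_prior`` / ``gamma_prior`` are the (a, b) pseudo-counts smoothing
    probabilities and rates in the M-step; ``init_beta`` is the Beta
    distribution that unanchored activation, leak and onset parameters are
    initialized from (its default mean of 0.25 reflects sparse coded data).
    ``initial_stage`` selects the prior over a patient's stage at the first
    encounter: "uniform" for observational data whose patients enter
    mid-course, "first" when every trajectory is known to start at stage I
    (e.g. complete simulated panels).
    """

    n_em_iterations: int = 200
    n_gibbs_sweeps: int = 20
    burn_in: int = 5
    random_seed: int = 0
    convergence_tol: float = 1e-4
    convergence_window: int = 5
    anchor_init: float = 0.8
    freeze_anchors: bool = False
    beta_prior: tuple = (1.0, 1.0)
    gamma_prior: tuple = (1.0, 1.0)
    init_beta: tuple = (1.0, 3.0)
    initial_stage: str = "uniform"

    def validate(self) -> None:
        if self.n_em_iterations < 1 or self.n_gibbs_sweeps < 1:
            raise ValueError("iteration and sweep counts must be positive")
        if not 0 <= self.burn_in < self.n_gibbs_sweeps:
            raise ValueError("burn_in must be in [0, n_gibbs_sweeps)")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if min(self.beta_prior + self.gamma_prior + self.init_beta) <= 0:
            raise ValueError("prior pseudo-counts must be positive")
        if not 0 <= self.anchor_init <= 1:
            raise ValueError("anchor_init must be a probability")
        if self.initial_stage not in ("uniform", "first"):
            raise ValueError("initial_stage must be 'uniform' or 'first'")

    def initial_stage_probs(self, K: int) -> np.ndarray:
        if self.initial_stage == "first":
            p = np.zeros(K)
            p[0] = 1.0
            return p
        return np.full(K, 1.0 / K)


def uniform_initial_stage(K: int) -> np.ndarray:
    return np.full(K, 1.0 / K)


def activity_matrix(tau, T: int) -> np.ndarray:
    """(T, W) boolean activity implied by an onset-slice vector."""
    tau = np.asarray(tau)
    return np.arange(T)[:, None] >= tau[None, :]


# ---------------------------------------------------------------------------
# Initialization

def init_model(K: int, W: int, vocabulary: FindingVocabulary, anchor_set: AnchorSet,
               seed: int, config: FitConfig | None = None) -> ProgressionModel:
    """Build a valid initialized model with the anchored topology.

    Activation and leak probabilities start from draws of the configured
    Beta; onset parameters start on a jittered ramp increasing with stage
    (complication pressure grows as the disease advances), which breaks the
    near-symmetry between stage-boundary placement and hazard levels that
    otherwise traps EM in boundary-shifted local optima.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    N = len(vocabulary)
    bound = anchor_set.bound(vocabulary)
    mask = make_connectivity_mask(bound, vocabulary, W)
    a, b = config.init_beta
    A = rng.beta(a, b, size=(W, N))
    for code, w in bound.complication_of().items():
        A[w, vocabulary.encode(code)] = config.anchor_init
    A[~mask.allowed] = 0.0
    leak = rng.beta(a, b, size=N)
    jitter = np.exp(rng.normal(0.0, 0.1, size=(2, K, W)))
    pi = np.clip(np.linspace(0.10, 0.30, K)[:, None] * jitter[0], 0.01, 0.9)
    h = np.clip(np.linspace(0.15, 0.45, K)[:, None] * jitter[1], 0.01, 0.9)
    Q = np.zeros((K, K))
    for i in range(K - 1):
        Q[i, i + 1] = 0.1
        Q[i, i + 2:] = 0.01  # small mass on skip transitions keeps them learnable
        Q[i, i] = -Q[i].sum()
    return ProgressionModel(K=K, W=W, N=N, Q=Q, pi_onset=pi, h_onset=h, A=A,
                            leak=leak, mask=mask, codes=vocabulary.codes,
                            anchor_set=bound)


# ---------------------------------------------------------------------------
# Per-patient precomputation

class _PatientData:
    """Arrays derived from one history that every sweep reuses."""

    def __init__(self, history: PatientHistory, N: int):
        self.history = history
        self.T = history.n_slices
        self.years = np.asarray(history.years, dtype=float)
        self.dts = np.diff(self.years)
        self.pos = np.zeros((self.T, N), dtype=bool)
        for t, f in enumerate(history.finding_sets):
            for n in f:
                self.pos[t, n] = True


def _log1m_A(model: ProgressionModel) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(model.mask.allowed, np.log1p(-model.A), 0.0)


def _slice_obs_loglik(pos_row, activity_row, model, log1mA) -> float:
    s = activity_row @ log1mA
    p = 1.0 - (1.0 - model.leak) * np.exp(s)
    with np.errstate(divide="ignore"):
        ll = np.where(pos_row, np.log(p), np.log1p(-p))
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Gibbs kernels

def sample_stages(history: PatientHistory, onset_slices, model: ProgressionModel,
                  rng, initial_stage_probs=None, transition_cache: dict | None = None):
    """One FFBS draw of the stage sequence given complication onsets.

    ``onset_slices`` is the tau vector of the current complication sample.
    The returned sequence is 0-based and nondecreasing.
    """
    T = history.n_slices
    years = np.asarray(history.years, dtype=float)
    tau = np.asarray(onset_slices)
    K = model.K
    pi0 = uniform_initial_stage(K) if initial_stage_probs is None \
        else np.asarray(initial_stage_probs, dtype=float)

    with np.errstate(divide="ignore"):
        em = np.zeros((T, K))
        first_active = tau == 0
        em[0] = (np.log(model.pi_onset[:, first_active]).sum(axis=1)
                 + np.log1p(-model.pi_onset[:, ~first_active]).sum(axis=1))
        for t in range(1, T):
            dt = years[t] - years[t - 1]
            new = tau == t
            pending = tau > t
            surv = (1.0 - model.h_onset) ** dt
            em[t] = (np.log1p(-surv[:, new]).sum(axis=1)
                     + dt * np.log1p(-model.h_onset[:, pending]).sum(axis=1))
        log_a = np.log(pi0) + em[0]

    mats = []
    for t in range(1, T):
        dt = float(years[t] - years[t - 1])
        if transition_cache is not None and dt in transition_cache:
            P = transition_cache[dt]
        else:
            P = stage_transition_matrix(model.Q, dt)
            if transition_cache is not None:
                transition_cache[dt] = P
        mats.append(P)

    m = log_a.max()
    if not np.isfinite(m):
        raise ZeroProbabilityEvidenceError(history.patient_id, 0)
    alpha = np.exp(log_a - m)
    alpha /= alpha.sum()
    alphas = [alpha]
    for t in range(1, T):
        with np.errstate(divide="ignore"):
            mt = em[t].max()
            if not np.isfinite(mt):
                raise ZeroProbabilityEvidenceError(history.patient_id, t)
            a = (alphas[-1] @ mats[t - 1]) * np.exp(em[t] - mt)
        s = a.sum()
        if s <= 0:
            raise ZeroProbabilityEvidenceError(history.patient_id, t)
        alphas.append(a / s)

    stages = np.empty(T, dtype=int)
    stages[T - 1] = rng.choice(K, p=alphas[T - 1])
    for t in range(T - 2, -1, -1):
        w = alphas[t] * mats[t][:, stages[t + 1]]
        s = w.sum()
        if s <= 0:
            raise ZeroProbabilityEvidenceError(history.patient_id, t)
        stages[t] = rng.choice(K, p=w / s)
    assert np.all(np.diff(stages) >= 0), "sampled stage sequence decreased"
    return stages


def _onset_log_prior(stages, years, w: int,
                     model: ProgressionModel) -> np.ndarray:
    """Log prior of each onset slice candidate 0..T (T = never) for one w."""
    T = len(stages)
    pi = model.pi_onset[stages[0], w]
    h = model.h_onset[stages, w]
    with np.errstate(divide="ignore"):
        fail = np.zeros(T)  # fail[t]: stayed inactive over interval ending at t
        on = np.full(T, -np.inf)  # on[t]: activated over interval ending at t
        for t in range(1, T):
            dt = years[t] - years[t - 1]
            fail[t] = dt * np.log1p(-h[t])
            on[t] = np.log1p(-(1.0 - h[t]) ** dt)
        cumfail = np.cumsum(fail)  # cumfail[t] = sum of fail[1..t]
        lp = np.empty(T + 1)
        lp[0] = np.log(pi)
        lognotpi = np.log1p(-pi)
        for t in range(1, T):
            lp[t] = lognotpi + cumfail[t - 1] + on[t]
        lp[T] = lognotpi + cumfail[T - 1]
    return lp


def sample_complications(history: PatientHistory, stage_sequence, model: ProgressionModel,
                         rng, onset_slices=None, _pdata: _PatientData | None = None):
    """One systematic-scan Gibbs update of all complication onset times.

    Each complication's onset slice is drawn from its exact conditional
    given the stages, the observations and the other complications' current
    states (likelihood couples through the noisy-or).  Returns the new tau
    vector; monotone activity holds by construction.
    """
    pd_ = _pdata or _PatientData(history, model.N)
    T, W = pd_.T, model.W
    stages = np.asarray(stage_sequence)
    if np.any(np.diff(stages) < 0):
        raise ValueError("stage sequence must be nondecreasing")
    tau = np.full(W, T, dtype=int) if onset_slices is None \
        else np.asarray(onset_slices, dtype=int).copy()
    log1mA = _log1m_A(model)
    years = pd_.years

    for w in range(W):
        others = activity_matrix(tau, T)
        others[:, w] = False
        base = others @ log1mA  # (T, N) log prod over active others
        with np.errstate(divide="ignore"):
            q_wo = (1.0 - model.leak) * np.exp(base)
            q_wi = (1.0 - model.leak) * np.exp(base + log1mA[w])
            ll_wo = np.where(pd_.pos, np.log(1.0 - q_wo), np.log(q_wo)).sum(axis=1)
            ll_wi = np.where(pd_.pos, np.log(1.0 - q_wi), np.log(q_wi)).sum(axis=1)
        # prefix of inactive-likelihood + suffix of active-likelihood
        prefix = np.concatenate([[0.0], np.cumsum(ll_wo)])          # prefix[t] = sum_{u<t}
        suffix = np.concatenate([np.cumsum(ll_wi[::-1])[::-1], [0.0]])  # suffix[t] = sum_{u>=t}
        loglik = prefix[: T + 1] + suffix
        logpost = _onset_log_prior(stages, years, w, model) + loglik
        m = logpost.max()
        if not np.isfinite(m):
            raise ZeroProbabilityEvidenceError(
                history.patient_id, -1, f"complication {w} has no feasible onset time")
        p = np.exp(logpost - m)
        tau[w] = rng.choice(T + 1, p=p / p.sum())
    return tau


def sample_attributions(history: PatientHistory, onset_slices, model: ProgressionModel,
                        rng):
    """Draw one nominal cause per positive finding.

    The cause is an active mask-allowed complication or the leak (coded -1),
    drawn proportional to its activation probability.  Used for trajectory
    annotation; the EM sufficient statistics use the exact firing posteriors
    instead (see the module docstring).
    """
    T = history.n_slices
    act = activity_matrix(np.asarray(onset_slices), T)
    out = []
    for t, findings in enumerate(history.finding_sets):
        row = {}
        for n in findings:
            ws = np.flatnonzero(act[t] & model.mask.allowed[:, n])
            weights = np.concatenate([model.A[ws, n], [model.leak[n]]])
            total = weights.sum()
            if total <= 0:
                raise ZeroProbabilityEvidenceError(
                    history.patient_id, t,
                    f"positive finding {n} has zero total activation probability")
            choice = rng.choice(len(weights), p=weights / total)
            row[n] = -1 if choice == len(ws) else int(ws[choice])
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# Sufficient statistics

@dataclass
class SufficientStats:
    """Accumulated expected counts over retained Gibbs sweeps."""

    K: int
    W: int
    N: int
    pi_succ: np.ndarray = None
    pi_trials: np.ndarray = None
    h_succ: np.ndarray = None
    h_fail: np.ndarray = None
    A_succ: np.ndarray = None
    A_fail: np.ndarray = None
    leak_succ: np.ndarray = None
    leak_fail: np.ndarray = None
    q_jumps: np.ndarray = None
    q_exposure: np.ndarray = None
    n_sweeps: int = 0

    def __post_init__(self):
        K, W, N = self.K, self.W, self.N
        for name, shape in (("pi_succ", (K, W)), ("pi_trials", (K, W)),
                            ("h_succ", (K, W)), ("h_fail", (K, W)),
                            ("A_succ", (W, N)), ("A_fail", (W, N)),
                            ("leak_succ", (N,)), ("leak_fail", (N,)),
                            ("q_jumps", (K, K)), ("q_exposure", (K,))):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape))

    def scaled(self, factor: float) -> "SufficientStats":
        out = SufficientStats(self.K, self.W, self.N)
        for name in ("pi_succ", "pi_trials", "h_succ", "h_fail", "A_succ",
                     "A_fail", "leak_succ", "leak_fail", "q_jumps", "q_exposure"):
            setattr(out, name, getattr(self, name) * factor)
        out.n_sweeps = self.n_sweeps
        return out


class CTMCIntervalStats:
    """Expected CTMC holding times and jump counts between slice endpoints.

    For an interval of length dt observed to go from stage a to stage b,
    ``E[time in i | a -> b]`` and ``E[#jumps i -> j | a -> b]`` follow from
    Van Loan augmented matrix exponentials of ``[[Q, B], [0, Q]]``.
    Results are cached per dt for one fixed Q.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self.K = Q.shape[0]
        self._cache = {}

    def _integral(self, B: np.ndarray, dt: float) -> np.ndarray:
        K = self.K
        M = np.zeros((2 * K, 2 * K))
        M[:K, :K] = self.Q
        M[K:, K:] = self.Q
        M[:K, K:] = B
        return _dense_expm(M * dt)[:K, K:]

    def stats(self, dt: float):
        """Return (P, ER, EN): P (K,K); ER[i,a,b]; EN[i,j,a,b]."""
        key = round(float(dt), 12)
        if key in self._cache:
            return self._cache[key]
        K = self.K
        P = stage_transition_matrix(self.Q, dt)
        safe = np.where(P > 0, P, 1.0)
        ER = np.zeros((K, K, K))
        EN = np.zeros((K, K, K, K))
        for i in range(K):
            B = np.zeros((K, K))
            B[i, i] = 1.0
            ER[i] = np.where(P > 0, self._integral(B, dt) / safe, 0.0)
            for j in range(i + 1, K):
                if self.Q[i, j] <= 0:
                    continue
                B = np.zeros((K, K))
                B[i, j] = 1.0
                EN[i, j] = np.where(P > 0, self.Q[i, j] * self._integral(B, dt) / safe, 0.0)
        self._cache[key] = (P, ER, EN)
        return self._cache[key]


def _accumulate(pd_: _PatientData, stages, tau, model: ProgressionModel,
                stats: SufficientStats, rng, ctmc: CTMCIntervalStats,
                initial_stage_probs, log1mA) -> float:
    """Add one sweep's expected counts; return the complete-data log-lik."""
    T, W = pd_.T, model.W
    years = pd_.years
    act = activity_matrix(tau, T)

    # --- observation layer: exact firing posteriors --------------------
    s = act.astype(float) @ log1mA
    p = 1.0 - (1.0 - model.leak) * np.exp(s)  # (T, N)
    with np.errstate(divide="ignore"):
        obs_ll = float(np.where(pd_.pos, np.log(p), np.log1p(-p)).sum())
    safe_p = np.where(p > 0, p, 1.0)
    for t in range(T):
        pos = pd_.pos[t]
        neg = ~pos
        for w in np.flatnonzero(act[t]):
            allowed = model.mask.allowed[w]
            ap = allowed & pos
            fire = model.A[w, ap] / safe_p[t, ap]
            stats.A_succ[w, ap] += fire
            stats.A_fail[w, ap] += 1.0 - fire
            stats.A_fail[w, allowed & neg] += 1.0
        lf = model.leak[pos] / safe_p[t, pos]
        stats.leak_succ[pos] += lf
        stats.leak_fail[pos] += 1.0 - lf
        stats.leak_fail[neg] += 1.0

    # --- onset layer -----------------------------------------------------
    k0 = stages[0]
    stats.pi_trials[k0, :] += 1.0
    first = tau == 0
    stats.pi_succ[k0, first] += 1.0
    with np.errstate(divide="ignore"):
        onset_ll = float(np.log(model.pi_onset[k0, first]).sum()
                         + np.log1p(-model.pi_onset[k0, ~first]).sum())
    for t in range(1, T):
        dt = years[t] - years[t - 1]
        k = stages[t]
        for w in range(W):
            if tau[w] < t:
                continue
            h = model.h_onset[k, w]
            if tau[w] == t:
                dti = int(round(dt))
                if dti <= 1 or h >= 1.0:
                    j = 1
                else:  # year of onset within the interval: truncated geometric
                    weights = (1.0 - h) ** np.arange(dti) * h
                    tot = weights.sum()
                    j = 1 + rng.choice(dti, p=weights / tot) if tot > 0 else 1
                stats.h_succ[k, w] += 1.0
                stats.h_fail[k, w] += j - 1
                with np.errstate(divide="ignore"):
                    onset_ll += float(np.log1p(-(1.0 - h) ** dt))
            else:
                stats.h_fail[k, w] += dt
                onset_ll += dt * float(np.log1p(-h))

    # --- stage layer -----------------------------------------------------
    with np.errstate(divide="ignore"):
        stage_ll = float(np.log(initial_stage_probs[k0]))
    for t in range(1, T):
        dt = years[t] - years[t - 1]
        P, ER, EN = ctmc.stats(dt)
        a, b = stages[t - 1], stages[t]
        stats.q_exposure += ER[:, a, b]
        stats.q_jumps += EN[:, :, a, b]
        with np.errstate(divide="ignore"):
            stage_ll += float(np.log(P[a, b]))

    return obs_ll + onset_ll + stage_ll


def m_step(stats: SufficientStats, config: FitConfig,
           model: ProgressionModel) -> ProgressionModel:
    """Posterior-mean parameter updates from accumulated sweep statistics."""
    a, b = config.beta_prior
    ga, gb = config.gamma_prior
    new = model.copy()
    new.pi_onset = (stats.pi_succ + a) / (stats.pi_trials + a + b)
    new.h_onset = (stats.h_succ + a) / (stats.h_succ + stats.h_fail + a + b)
    new.A = (stats.A_succ + a) / (stats.A_succ + stats.A_fail + a + b)
    new.A[~model.mask.allowed] = 0.0
    new.leak = (stats.leak_succ + a) / (stats.leak_succ + stats.leak_fail + a + b)
    K = model.K
    Q = np.zeros((K, K))
    for i in range(K - 1):
        for j in range(i + 1, K):
            Q[i, j] = (stats.q_jumps[i, j] + ga) / (stats.q_exposure[i] + gb)
        Q[i, i] = -Q[i].sum()
    new.Q = Q
    if config.freeze_anchors and model.anchor_set is not None and model.codes is not None:
        vocab_index = {c: i for i, c in enumerate(model.codes)}
        for code, w in model.anchor_set.complication_of().items():
            if code in vocab_index:
                new.A[w, vocab_index[code]] = config.anchor_init
    return new


# ---------------------------------------------------------------------------
# The full fit

def fit(histories, config: FitConfig, anchor_set: AnchorSet,
        vocabulary: FindingVocabulary, K: int = 5, W: int = 12,
        initial_model: ProgressionModel | None = None):
    """Monte Carlo EM over a collection of patient histories.

    Returns ``(model, diagnostics)`` where diagnostics carries the
    per-iteration smoothed complete-data log-likelihood estimates, their
    Monte Carlo standard errors, and convergence information.  Fully
    reproducible given ``config.random_seed``.
    """
    config.validate()
    if not histories:
        raise ValueError("fit requires at least one patient history")
    histories = sorted(histories, key=lambda h: h.patient_id)
    for h in histories:
        for f in h.finding_sets:
            if f and max(f) >= len(vocabulary):
                raise ValueError(f"history {h.patient_id} has findings outside vocabulary")

    rng = np.random.default_rng(config.random_seed)
    if initial_model is not None:
        model = initial_model
    else:
        model = init_model(K, W, vocabulary, anchor_set,
                           seed=int(rng.integers(2**31)), config=config)
        # spread the stage process over the observed span, so early stages
        # do not swallow whole trajectories before the first M-step
        span = float(np.mean([h.years[-1] - h.years[0] for h in histories]))
        if span > 0 and K > 1:
            rate = (K - 1) / span
            Q = np.zeros((K, K))
            for i in range(K - 1):
                Q[i, i + 1] = rate
                Q[i, i + 2:] = 0.05 * rate
                Q[i, i] = -Q[i].sum()
            model.Q = Q
    K, W, N = model.K, model.W, model.N
    pi0 = config.initial_stage_probs(K)
    pdata = [_PatientData(h, N) for h in histories]
    taus = [np.full(W, p.T, dtype=int) for p in pdata]

    ll_trace, ll_se_trace = [], []
    converged = False
    n_done = 0
    t_start = time.perf_counter()
    for it in range(config.n_em_iterations):
        ctmc = CTMCIntervalStats(model.Q)
        tcache = {}
        log1mA = _log1m_A(model)
        stats = SufficientStats(K, W, N)
        sweep_lls = []
        for sweep in range(config.n_gibbs_sweeps):
            retain = sweep >= config.burn_in
            total_ll = 0.0
            for i, pd_ in enumerate(pdata):
                stages = sample_stages(pd_.history, taus[i], model, rng,
                                       initial_stage_probs=pi0,
                                       transition_cache=tcache)
                taus[i] = sample_complications(pd_.history, stages, model, rng,
                                               onset_slices=taus[i], _pdata=pd_)
                if retain:
                    total_ll += _accumulate(pd_, stages, taus[i], model, stats,
                                            rng, ctmc, pi0, log1mA)
            if retain:
                sweep_lls.append(total_ll)
        n_retained = len(sweep_lls)
        stats.n_sweeps = n_retained
        model = m_step(stats.scaled(1.0 / n_retained), config, model)
        ll = float(np.mean(sweep_lls))
        ll_se = float(np.std(sweep_lls) / np.sqrt(n_retained)) if n_retained > 1 else 0.0
        ll_trace.append(ll)
        ll_se_trace.append(ll_se)
        n_done = it + 1
        logger.info("EM iteration %d: complete-data loglik %.2f (se %.2f), %.1fs elapsed",
                    it, ll, ll_se, time.perf_counter() - t_start)
        if len(ll_trace) > config.convergence_window:
            recent = ll_trace[-(config.convergence_window + 1):]
            rel = [abs(y - x) / (abs(x) + 1e-12) for x, y in zip(recent, recent[1:])]
            if max(rel) < config.convergence_tol:
                converged = True
                break

    diagnostics = {
        "loglik": ll_trace,
        "loglik_se": ll_se_trace,
        "n_iterations": n_done,
        "converged": converged,
        "monotone_latents_ok": True,  # hard asserts in the samplers
    }
    violations = model.validate()
    if violations:
        raise RuntimeError(f"fit produced an invalid model: {violations}")
    return model, diagnostics
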