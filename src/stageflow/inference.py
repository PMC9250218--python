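"""Per-patient trajectory inference.

``map_trajectory`` finds the jointly most probable monotone assignment of
stages and complication onset times to a patient's observed slices by
dynamic programming over the product chain of (stage, active-complication
set).  Both coordinates are monotone (stages nondecreasing, activity
irreversible), and the onset-chain transition cost is additive per
complication, so the subset maximization over predecessors factorizes into
W coordinate-wise relaxations of a 2^W array per slice.

``brute_force_map`` enumerates every monotone assignment and is the exact
oracle for the DP; ties there are broken by the lexicographically smallest
(stage sequence, then onset-time vector).  The DP breaks exact ties by a
per-slice greedy preference (smaller stage, earlier onsets), which coincides
with the brute-force order except on exactly tied objectives.

``forecast`` extends a MAP trajectory deterministically: the predicted
stage at a future year is the largest stage whose cumulative reaching
probability exceeds a threshold (default 0.5), and a complication's
predicted onset year is the first year its cumulative onset probability
along the forecast stage path exceeds the same threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .ingest import PatientHistory
from .learning import (
    ZeroProbabilityEvidenceError,
    _log1m_A,
    _onset_log_prior,
    _PatientData,
    activity_matrix,
    sample_complications,
    sample_stages,
    uniform_initial_stage,
)
from .model import ProgressionModel, stage_transition_matrix


@dataclass
class LatentTrajectory:
    """A stage/complication assignment over observed slices, plus forecasts.

    ``onset_slices[w]`` is the slice index at which complication w first
    becomes active, or None if it never activates within the observed
    window.  Forecast years are absolute year indices strictly after the
    last observed slice.
    """

    patient_id: str
    years: tuple
    stages: tuple          # 0-based stage per slice, nondecreasing
    activity: np.ndarray   # (T, W) boolean, monotone per column
    onset_slices: tuple    # per complication: slice index or None
    log_posterior: float
    forecast_stage_entries: dict | None = None   # stage -> absolute year
    forecast_onset_years: dict | None = None     # complication -> absolute year or None
    forecast_horizon: int | None = None
    forecast_threshold: float | None = None


def _tau_to_onsets(tau, T: int) -> tuple:
    return tuple(int(t) if t < T else None for t in tau)


def trajectory_log_posterior(history: PatientHistory, stages, tau,
                             model: ProgressionModel,
                             initial_stage_probs=None) -> float:
    """Joint log P(stages, onsets, observations) for one assignment."""
    T = history.n_slices
    years = np.asarray(history.years, dtype=float)
    stages = np.asarray(stages)
    tau = np.asarray(tau)
    pi0 = uniform_initial_stage(model.K) if initial_stage_probs is None \
        else np.asarray(initial_stage_probs, dtype=float)
    with np.errstate(divide="ignore"):
        lp = float(np.log(pi0[stages[0]]))
    for t in range(1, T):
        P = stage_transition_matrix(model.Q, float(years[t] - years[t - 1]))
        with np.errstate(divide="ignore"):
            lp += float(np.log(P[stages[t - 1], stages[t]]))
    for w in range(model.W):
        prior = _onset_log_prior(stages, years, w, model)
        lp += float(prior[min(int(tau[w]), T)])
    act = activity_matrix(tau, T)
    log1mA = _log1m_A(model)
    pd_ = _PatientData(history, model.N)
    s = act.astype(float) @ log1mA
    p = 1.0 - (1.0 - model.leak) * np.exp(s)
    with np.errstate(divide="ignore"):
        lp += float(np.where(pd_.pos, np.log(p), np.log1p(-p)).sum())
    return lp


# ---------------------------------------------------------------------------
# Exact MAP by dynamic programming

def map_trajectory(history: PatientHistory, model: ProgressionModel,
                   initial_stage_probs=None) -> LatentTrajectory:
    """Jointly most probable monotone (stage, complication) assignment."""
    K, W, N = model.K, model.W, model.N
    if W > 20:
        raise ValueError(f"W={W} too large for exact joint MAP (limit 20)")
    T = history.n_slices
    years = np.asarray(history.years, dtype=float)
    pd_ = _PatientData(history, N)
    nS = 1 << W
    pi0 = uniform_initial_stage(K) if initial_stage_probs is None \
        else np.asarray(initial_stage_probs, dtype=float)

    log1mA = _log1m_A(model)
    # log prod over active allowed parents of (1 - A), for every subset
    sub_log1mA = np.zeros((nS, N))
    for S in range(1, nS):
        w = (S & -S).bit_length() - 1
        sub_log1mA[S] = sub_log1mA[S & (S - 1)] + log1mA[w]
    with np.errstate(divide="ignore"):
        p_mask = 1.0 - (1.0 - model.leak) * np.exp(sub_log1mA)
        logp = np.log(p_mask)
        logq = np.log1p(-p_mask)
    obs = np.empty((T, nS))
    for t in range(T):
        obs[t] = np.where(pd_.pos[t], logp, logq).sum(axis=1)

    masks = np.arange(nS)
    bit_active = np.array([(masks >> w) & 1 for w in range(W)], dtype=bool)  # (W, nS)

    def _subset_param_sum(log_on, log_off):
        """sum over w of log_on[w] if bit set else log_off[w], per subset."""
        return np.where(bit_active, log_on[:, None], log_off[:, None]).sum(axis=0)

    with np.errstate(divide="ignore"):
        V = np.empty((K, nS))
        for k in range(K):
            V[k] = (np.log(pi0[k])
                    + _subset_param_sum(np.log(model.pi_onset[k]),
                                        np.log1p(-model.pi_onset[k]))
                    + obs[0])
    if not np.isfinite(V.max()):
        raise ZeroProbabilityEvidenceError(history.patient_id, 0)

    k_ptr = np.empty((T, K, nS), dtype=np.int8)
    s_ptr = np.empty((T, K, nS), dtype=np.int64)
    for t in range(1, T):
        dt = float(years[t] - years[t - 1])
        P = stage_transition_matrix(model.Q, dt)
        with np.errstate(divide="ignore"):
            logP = np.log(P)
            surv = (1.0 - model.h_onset) ** dt       # (K, W)
            log_on = np.log1p(-surv)
            log_stay = dt * np.log1p(-model.h_onset)
        newV = np.full((K, nS), -np.inf)
        for kp in range(K):
            cand = V[: kp + 1] + logP[: kp + 1, kp][:, None]  # (kp+1, nS)
            kprev = np.argmax(cand, axis=0)
            M = cand[kprev, masks]
            sprev = masks.copy()
            kk = kprev.astype(np.int8)
            for w in range(W):
                bit = 1 << w
                has = (masks & bit) != 0
                src = masks[has] ^ bit
                shifted = M[src] + log_on[kp, w]
                better = shifted > M[has]
                idx = masks[has][better]
                M[idx] = shifted[better]
                sprev[idx] = sprev[src][better]
                kk[idx] = kk[src][better]
            stay = np.where(~bit_active, log_stay[kp][:, None], 0.0).sum(axis=0)
            newV[kp] = M + stay + obs[t]
            k_ptr[t, kp] = kk
            s_ptr[t, kp] = sprev
        V = newV
        if not np.isfinite(V.max()):
            raise ZeroProbabilityEvidenceError(history.patient_id, t)

    flat = int(np.argmax(V))  # first maximizer: smallest stage, then subset
    k, S = divmod(flat, nS)
    best_lp = float(V[k, S])
    stages = [0] * T
    sets = [0] * T
    stages[T - 1], sets[T - 1] = k, S
    for t in range(T - 1, 0, -1):
        kp, Sp = stages[t], sets[t]
        stages[t - 1] = int(k_ptr[t, kp, Sp])
        sets[t - 1] = int(s_ptr[t, kp, Sp])

    tau = np.full(W, T, dtype=int)
    for w in range(W):
        for t in range(T):
            if sets[t] >> w & 1:
                tau[w] = t
                break
    act = activity_matrix(tau, T)
    return LatentTrajectory(
        patient_id=history.patient_id,
        years=tuple(int(y) for y in history.years),
        stages=tuple(int(s) for s in stages),
        activity=act,
        onset_slices=_tau_to_onsets(tau, T),
        log_posterior=best_lp,
    )


def brute_force_map(history: PatientHistory, model: ProgressionModel,
                    initial_stage_probs=None, guard: int = 10**6) -> LatentTrajectory:
    """Exact MAP by enumerating all monotone assignments (test oracle).

    Ties are broken by the lexicographically smallest (stage sequence, then
    onset-time vector, with "never" ordered last).
    """
    K, W = model.K, model.W
    T = history.n_slices
    from math import comb
    n_paths = comb(T + K - 1, K - 1)
    if n_paths * (T + 1) ** W > guard:
        raise ValueError("state space exceeds brute-force guard")
    best = None
    best_lp = -np.inf
    for path in itertools.combinations_with_replacement(range(K), T):
        for tau in itertools.product(range(T + 1), repeat=W):
            lp = trajectory_log_posterior(history, path, tau, model,
                                          initial_stage_probs)
            if lp > best_lp:
                best_lp = lp
                best = (path, tau)
    if best is None or not np.isfinite(best_lp):
        raise ZeroProbabilityEvidenceError(history.patient_id, -1,
                                           "no assignment has positive probability")
    path, tau = best
    tau = np.asarray(tau)
    return LatentTrajectory(
        patient_id=history.patient_id,
        years=tuple(int(y) for y in history.years),
        stages=tuple(path),
        activity=activity_matrix(tau, T),
        onset_slices=_tau_to_onsets(tau, T),
        log_posterior=float(best_lp),
    )


# ---------------------------------------------------------------------------
# Forward prediction

def forecast(trajectory: LatentTrajectory, model: ProgressionModel,
             horizon_years: int, threshold: float = 0.5) -> LatentTrajectory:
    """Deterministic forward prediction from the end of a MAP trajectory.

    For each future year the predicted stage is the largest stage whose
    cumulative probability of having been reached exceeds ``threshold``;
    a currently inactive complication's predicted onset year is the first
    year its cumulative onset probability along that stage path exceeds
    ``threshold``.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be > 0")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    eps = 1e-12
    K, W = model.K, model.W
    k0 = trajectory.stages[-1]
    last_year = trajectory.years[-1]
    active_now = trajectory.activity[-1]

    stage_path = []
    stage_entries = {}
    for t in range(1, int(horizon_years) + 1):
        P = stage_transition_matrix(model.Q, float(t))
        row = P[k0]
        cum = np.cumsum(row[::-1])[::-1]  # cum[s] = P(stage >= s)
        s = int(np.max(np.flatnonzero(cum >= threshold - eps)))
        stage_path.append(s)
        for snew in range(k0 + 1, s + 1):
            stage_entries.setdefault(int(snew), last_year + t)

    onset_years = {}
    surv = np.ones(W)
    for w in range(W):
        if active_now[w]:
            continue
        onset_years[w] = None
    for t, s in enumerate(stage_path, start=1):
        hz = model.h_onset[s]
        surv = surv * (1.0 - hz)
        for w in range(W):
            if active_now[w] or onset_years.get(w) is not None:
                continue
            if 1.0 - surv[w] >= threshold - eps:
                onset_years[w] = last_year + t
    return replace(
        trajectory,
        forecast_stage_entries=stage_entries,
        forecast_onset_years=onset_years,
        forecast_horizon=int(horizon_years),
        forecast_threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Posterior marginals

def posterior_complication_probs(history: PatientHistory, model: ProgressionModel,
                                 n_samples: int, seed: int, burn_in: int = 200,
                                 initial_stage_probs=None) -> np.ndarray:
    """Monte Carlo posterior activation marginals, one (T, W) matrix.

    Gibbs sweeps at fixed parameters alternate stage and onset updates;
    the returned per-slice marginals are monotone nondecreasing over slices
    up to sampling error.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    T, W = history.n_slices, model.W
    pd_ = _PatientData(history, model.N)
    pi0 = uniform_initial_stage(model.K) if initial_stage_probs is None \
        else np.asarray(initial_stage_probs, dtype=float)
    tau = np.full(W, T, dtype=int)
    tcache = {}
    acc = np.zeros((T, W))
    for i in range(burn_in + n_samples):
        stages = sample_stages(history, tau, model, rng,
                               initial_stage_probs=pi0, transition_cache=tcache)
        tau = sample_complications(history, stages, model, rng,
                                   onset_slices=tau, _pdata=pd_)
        if i >= burn_in:
            acc += activity_matrix(tau, T)
    return acc / n_samples
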