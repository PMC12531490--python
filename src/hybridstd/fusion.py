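"""Confidence-interval calibration for decision-level human–machine fusion.

The detector reports a noise-class confidence P1 for every frame.  Frames
whose P1 falls in the *low-confidence interval* [0.5, b] are routed to the
EEG decoder; all other frames keep the automatic decision.  The upper
bound b and a weight ω are chosen by maximising the evaluation function

    J = ω·(m00⁺/m00 + m11⁺/m11) + (1−ω)·(m10⁻/m10 + m01⁻/m01)

where mij are confusion-matrix counts of the detector on a labeled
calibration set and mij⁺/mij⁻ are their high/low-confidence sub-counts.
The first term rewards keeping correct automatic decisions confident (so
they are not overridden); the second rewards pushing the detector's
errors into the low-confidence band (so the human decoder can rescue
them).  Ratios with empty cells contribute 0, so J ∈ [0, 2].

The search over (b, ω) ∈ [0.5, 1] × [0, 1] uses global-best particle
swarm optimisation with a 5-particle population; the PSO hyperparameters
(inertia w, accelerations c1, c2) can themselves be tuned by a
Gaussian-process Bayesian search over w ∈ [0.4, 1.4], c1, c2 ∈ [0.2, 2.0].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .synthio import ConfidenceSample

__all__ = [
    "ConfusionSplit",
    "FusionCalibration",
    "PsoConfig",
    "split_by_confidence",
    "eval_J",
    "pso_calibrate",
    "grid_search",
    "bayes_tune",
    "select_result",
    "save_calibration",
    "load_calibration",
]


@dataclass(frozen=True)
class ConfusionSplit:
    m: np.ndarray        # (2, 2) counts, true × predicted
    m_plus: np.ndarray   # high-confidence sub-counts
    m_minus: np.ndarray  # low-confidence sub-counts


@dataclass(frozen=True)
class FusionCalibration:
    b: float             # upper bound of the low-confidence P1 interval
    omega: float
    J: float
    pso_hparams: tuple[float, float, float] = (0.7, 1.5, 1.5)
    seed: int = 0


def split_by_confidence(samples: list[ConfidenceSample], b: float
                        ) -> ConfusionSplit:
    """Fill the confusion matrix and its high/low-confidence sub-counts.

    A sample is low-confidence iff P1 ∈ [0.5, b] (closed interval).
    """
    if not 0.5 < b <= 1.0:
        raise ValueError("bound b must lie in (0.5, 1]")
    m = np.zeros((2, 2), dtype=int)
    mp = np.zeros((2, 2), dtype=int)
    mm = np.zeros((2, 2), dtype=int)
    for s in samples:
        i, j = s.true_label, s.predicted_label
        m[i, j] += 1
        if 0.5 <= s.p1 <= b:
            mm[i, j] += 1
        else:
            mp[i, j] += 1
    return ConfusionSplit(m, mp, mm)


def eval_J(split: ConfusionSplit, omega: float) -> float:
    """Confidence-interval evaluation function; empty cells contribute 0."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    correct = ratio(split.m_plus[0, 0], split.m[0, 0]) + \
        ratio(split.m_plus[1, 1], split.m[1, 1])
    errors = ratio(split.m_minus[1, 0], split.m[1, 0]) + \
        ratio(split.m_minus[0, 1], split.m[0, 1])
    return omega * correct + (1.0 - omega) * errors


@dataclass(frozen=True)
class PsoConfig:
    n_particles: int = 5
    iters: int = 50
    inertia: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    seed: int = 0
    early_stop: int = 10   # stop after this many stagnant iterations
    #: pin ω and search only the bound b.  The joint maximisation of J has
    #: a degenerate supremum (an empty low-confidence interval with ω = 1
    #: scores J = 2), so deployment calibrations fix ω to a chosen
    #: trade-off and optimise the interval alone.
    fixed_omega: float | None = None


_BOUNDS = np.array([[0.5, 1.0],    # b
                    [0.0, 1.0]])   # omega


def _objective_factory(samples):
    cache: dict[float, ConfusionSplit] = {}

    def obj(b: float, omega: float) -> float:
        key = round(b, 12)
        if key not in cache:
            cache[key] = split_by_confidence(samples, max(b, np.nextafter(0.5, 1)))
        return eval_J(cache[key], omega)

    return obj


def pso_calibrate(samples: list[ConfidenceSample],
                  cfg: PsoConfig | None = None) -> FusionCalibration:
    """Global-best PSO over (b, ω) maximising J; seeded and deterministic."""
    if not samples:
        raise ValueError("no confidence samples provided")
    cfg = cfg or PsoConfig()
    split_all = split_by_confidence(samples, 0.75)
    if np.any(split_all.m == 0):
        warnings.warn("some confusion cells are empty; J is degenerate there",
                      stacklevel=2)
    obj = _objective_factory(samples)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = _BOUNDS[:, 0].copy(), _BOUNDS[:, 1].copy()
    if cfg.fixed_omega is not None:
        lo[1] = hi[1] = float(cfg.fixed_omega)
    width = hi - lo
    pos = lo + rng.random((cfg.n_particles, 2)) * width
    vel = (rng.random((cfg.n_particles, 2)) - 0.5) * width
    pbest = pos.copy()
    pbest_val = np.array([obj(*p) for p in pos])
    g = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g].copy(), pbest_val[g]
    stagnant = 0
    for _ in range(cfg.iters):
        r1 = rng.random((cfg.n_particles, 2))
        r2 = rng.random((cfg.n_particles, 2))
        vel = (cfg.inertia * vel + cfg.c1 * r1 * (pbest - pos)
               + cfg.c2 * r2 * (gbest[None] - pos))
        vel = np.clip(vel, -width, width)
        pos = np.clip(pos + vel, lo, hi)
        vals = np.array([obj(*p) for p in pos])
        better = vals > pbest_val
        pbest[better] = pos[better]
        pbest_val[better] = vals[better]
        g = int(np.argmax(pbest_val))
        if pbest_val[g] > gbest_val + 1e-12:
            gbest, gbest_val = pbest[g].copy(), pbest_val[g]
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= cfg.early_stop:
                break
    return FusionCalibration(b=float(gbest[0]), omega=float(gbest[1]),
                             J=float(gbest_val),
                             pso_hparams=(cfg.inertia, cfg.c1, cfg.c2),
                             seed=cfg.seed)


def grid_search(samples: list[ConfidenceSample], n: int = 200
                ) -> FusionCalibration:
    """Exhaustive n × n reference search over (b, ω); the PSO oracle."""
    obj = _objective_factory(samples)
    bs = np.linspace(0.5 + 1e-9, 1.0, n)
    oms = np.linspace(0.0, 1.0, n)
    best = (-1.0, 0.75, 0.5)
    for b in bs:
        for om in oms:
            j = obj(b, om)
            if j > best[0]:
                best = (j, b, om)
    return FusionCalibration(b=float(best[1]), omega=float(best[2]),
                             J=float(best[0]))


_HP_BOUNDS = np.array([[0.4, 1.4],   # inertia
                       [0.2, 2.0],   # c1
                       [0.2, 2.0]])  # c2


def bayes_tune(samples: list[ConfidenceSample], budget: int = 15,
               seed: int = 0, n_restarts: int = 3
               ) -> tuple[float, float, float]:
    """Gaussian-process Bayesian search for PSO hyperparameters.

    Objective = mean best-J of `n_restarts` seeded PSO runs.  Exactly
    `budget` objective evaluations are spent: 5 on a random initial
    design, the rest on expected-improvement acquisitions.
    """
    if budget < 5:
        raise ValueError("budget must be at least 5")
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    rng = np.random.default_rng(seed)
    lo, hi = _HP_BOUNDS[:, 0], _HP_BOUNDS[:, 1]

    def objective(hp):
        vals = [pso_calibrate(samples, PsoConfig(inertia=hp[0], c1=hp[1],
                                                 c2=hp[2], seed=seed + k)).J
                for k in range(n_restarts)]
        return float(np.mean(vals))

    x_obs = lo + rng.random((5, 3)) * (hi - lo)
    y_obs = [objective(x) for x in x_obs]
    x_obs = list(x_obs)
    for _ in range(budget - 5):
        gp = GaussianProcessRegressor(kernel=Matern(nu=2.5),
                                      normalize_y=True, alpha=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.asarray(x_obs), np.asarray(y_obs))
        cand = lo + rng.random((256, 3)) * (hi - lo)
        mu, sd = gp.predict(cand, return_std=True)
        best_y = max(y_obs)
        sd = np.maximum(sd, 1e-12)
        z = (mu - best_y) / sd
        ei = (mu - best_y) * norm.cdf(z) + sd * norm.pdf(z)
        x_next = cand[int(np.argmax(ei))]
        x_obs.append(x_next)
        y_obs.append(objective(x_next))
    best = int(np.argmax(y_obs))
    return tuple(float(v) for v in x_obs[best])


def select_result(p1: float, auto_result, bci_result,
                  calib: FusionCalibration):
    """Route to the EEG decision iff P1 lies in the closed interval
    [0.5, b]; otherwise keep the automatic decision."""
    return bci_result if 0.5 <= p1 <= calib.b else auto_result


def save_calibration(path: str, calib: FusionCalibration,
                     extra: dict | None = None) -> None:
    doc = {"b": calib.b, "omega": calib.omega, "J": calib.J,
           "pso_hparams": list(calib.pso_hparams), "seed": calib.seed}
    if extra:
        doc["summary"] = extra
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_calibration(path: str) -> FusionCalibration:
    with open(path) as fh:
        doc = json.load(fh)
    return FusionCalibration(b=doc["b"], omega=doc["omega"], J=doc["J"],
                             pso_hparams=tuple(doc["pso_hparams"]),
                             seed=doc.get("seed", 0))
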