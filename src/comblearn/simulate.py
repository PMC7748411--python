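"""Simulation of labeled interaction-profile instances.

Training and evaluation data for the profile classifier are generated by
(1) sampling noiseless mean vectors from each profile's solution polytope
inside the admissible log2 range, (2) deriving the signal delta (the
smallest nonzero pairwise difference among the four condition means),
(3) adding Gaussian replicate noise with standard deviation sigma =
delta / (delta/sigma ratio), identical across the four condition groups,
and (4) clipping simulated values back into the admissible range.

Strict order relations are enforced with a margin equal to ``min_signal``,
so the signal floor is structural rather than obtained by rejection: every
pair of condition means on different levels of a profile's weak order
differs by at least ``min_signal``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .taxonomy import (DEFAULT_RANGE, InteractionProfile, Taxonomy,
                       five_values, interior_point, _pattern_of)

#: named noise regimes: ratio delta/sigma
NOISE_REGIMES = {"low": 4.0, "medium": 2.5, "high": 2.0}
DEFAULT_REGIMES = (4.0, 2.5, 2.0)

#: minimum signal enforced in simulated noiseless means (log2 units)
MIN_SIGNAL = 0.5

CONDITIONS = ("CTRL", "X", "Y", "COMBO")


class SimulationError(RuntimeError):
    pass


def signal_delta(v: Sequence[float], tol: float = 1e-9) -> float | None:
    """Signal delta: the absolute value of the smallest nonzero pairwise
    difference among the four condition means.

    Differences with absolute value <= ``tol`` count as zero (the default
    guards against float residue in coordinates that are equal by
    construction).  Returns ``None`` for the all-equal (constant) vector,
    where the signal is undefined and the caller must branch.
    """
    v = np.asarray(v, dtype=float)
    diffs = np.abs(v[:, None] - v[None, :])[np.triu_indices(len(v), k=1)]
    nonzero = diffs[diffs > tol]
    if nonzero.size == 0:
        return None
    return float(nonzero.min())


def clip_to_range(values, admissible_range=DEFAULT_RANGE):
    """Force values onto the admissible range limits (idempotent)."""
    lo, hi = admissible_range
    return np.clip(values, lo, hi)


def resolve_regime(regime) -> float:
    """Accept a named regime ('low'/'medium'/'high') or a positive ratio."""
    if isinstance(regime, str):
        try:
            return NOISE_REGIMES[regime]
        except KeyError:
            raise SimulationError(f"unknown noise regime {regime!r}") from None
    ratio = float(regime)
    if not ratio > 0:
        raise SimulationError("delta/sigma ratio must be > 0")
    return ratio


# ---------------------------------------------------------------------------
# polytope sampling


class _ProfileSampler:
    """Hit-and-run sampler on a profile's feasible region.

    Tied values are identified exactly by sampling in the null space of the
    equality constraints; strict inequalities carry a margin of
    ``min_signal``.  Burn-in 100 and thinning 10 by default; a rejection
    fallback is available for full-dimensional profiles.
    """

    def __init__(self, profile: InteractionProfile,
                 admissible_range=DEFAULT_RANGE, min_signal=MIN_SIGNAL,
                 burn_in: int = 100, thin: int = 10):
        self.profile = profile
        self.range = admissible_range
        self.min_signal = float(min_signal)
        self.burn_in = burn_in
        self.thin = thin

        w = interior_point(profile.relations, admissible_range)
        if w is None:
            raise SimulationError(
                f"profile {profile.id}: infeasible within the range")
        pattern = _pattern_of(five_values(w), 1e-7)
        rows = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0],
                         [0, 0, 0, 1], [-1, 1, 1, 0]], dtype=float)
        k = max(pattern) + 1
        groups = [[i for i in range(5) if pattern[i] == lev]
                  for lev in range(k)]
        A_eq = [rows[a] - rows[b] for g in groups
                for a, b in zip(g, g[1:])]
        # tie groups restricted to the four condition means, for exact
        # post-sampling identification of tied coordinates
        self.mean_ties = [[i for i in g if i < 4] for g in groups]
        A_ub, b_ub = [], []
        for lo_g, hi_g in zip(groups, groups[1:]):
            A_ub.append(rows[lo_g[0]] - rows[hi_g[0]])
            b_ub.append(-self.min_signal)
        lo, hi = admissible_range
        for i in range(4):
            e = np.zeros(4)
            e[i] = 1.0
            A_ub.append(e.copy())
            b_ub.append(hi)
            A_ub.append(-e)
            b_ub.append(-lo)
        self.A_ub = np.array(A_ub)
        self.b_ub = np.array(b_ub)
        A_eq = np.array(A_eq) if A_eq else np.zeros((0, 4))

        # null-space parametrization of the equality constraints
        if A_eq.shape[0]:
            _, s, vt = np.linalg.svd(A_eq)
            rank = int(np.sum(s > 1e-10))
            self.N = vt[rank:].T
        else:
            self.N = np.eye(4)
        if self.N.shape[1] == 0:
            raise SimulationError(
                f"profile {profile.id}: solution set is a single point")
        self.x0 = self._interior_start(A_eq)
        self._x = self.x0.copy()
        self._warmed = False

    def _interior_start(self, A_eq) -> np.ndarray:
        n_ub = len(self.b_ub)
        A = np.hstack([self.A_ub, np.ones((n_ub, 1))])
        res = linprog(np.array([0, 0, 0, 0, -1.0]),
                      A_ub=A, b_ub=self.b_ub,
                      A_eq=np.hstack([A_eq, np.zeros((A_eq.shape[0], 1))])
                      if A_eq.shape[0] else None,
                      b_eq=np.zeros(A_eq.shape[0]) if A_eq.shape[0] else None,
                      bounds=[(None, None)] * 4 + [(0, 1.0)],
                      method="highs")
        if not res.success or res.x[4] <= 1e-9:
            raise SimulationError(
                f"profile {self.profile.id}: no interior point with "
                f"min_signal {self.min_signal} inside {self.range}")
        return res.x[:4]

    def _step(self, rng: np.random.Generator) -> None:
        d = self.N @ rng.standard_normal(self.N.shape[1])
        norm = np.linalg.norm(d)
        if norm < 1e-12:  # pragma: no cover
            return
        d /= norm
        ad = self.A_ub @ d
        slack = self.b_ub - self.A_ub @ self._x
        with np.errstate(divide="ignore"):
            ratios = slack / ad
        hi = ratios[ad > 1e-12]
        lo = ratios[ad < -1e-12]
        t_hi = hi.min() if hi.size else np.inf
        t_lo = lo.max() if lo.size else -np.inf
        if not np.isfinite(t_hi) or not np.isfinite(t_lo):  # pragma: no cover
            raise SimulationError("unbounded chord in hit-and-run")
        self._x = self._x + rng.uniform(t_lo, t_hi) * d

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if not self._warmed:
            for _ in range(self.burn_in):
                self._step(rng)
            self._warmed = True
        out = np.empty((n, 4))
        for i in range(n):
            for _ in range(self.thin):
                self._step(rng)
            out[i] = self._x
        for g in self.mean_ties:
            if len(g) > 1:
                out[:, g] = out[:, g].mean(axis=1, keepdims=True)
        return out

    def sample_rejection(self, n: int, rng: np.random.Generator,
                         max_tries: int = 1_000_000) -> np.ndarray:
        """Uniform rejection sampling; only viable for full-dimensional
        profiles (no equality constraints)."""
        if self.N.shape[1] < 4:
            raise SimulationError("rejection sampling requires a "
                                  "full-dimensional profile")
        lo, hi = self.range
        out = np.empty((n, 4))
        got = 0
        for _ in range(max_tries):
            x = rng.uniform(lo, hi, 4)
            if np.all(self.A_ub @ x <= self.b_ub):
                out[got] = x
                got += 1
                if got == n:
                    return out
        raise SimulationError("rejection sampling did not converge")


def sample_profile_means(profile: InteractionProfile, n: int,
                         rng_seed: int | np.random.Generator = 0,
                         admissible_range=DEFAULT_RANGE,
                         min_signal: float = MIN_SIGNAL,
                         method: str = "hit-and-run") -> np.ndarray:
    """Draw ``n`` noiseless mean vectors satisfying the profile's relations.

    Every returned vector satisfies the relation system with tied
    coordinates exactly identical, all coordinates inside the admissible
    range, and (for non-constant profiles) signal delta >= ``min_signal``.
    Seeded runs are reproducible.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    sampler = _ProfileSampler(profile, admissible_range, min_signal)
    if method == "hit-and-run":
        return sampler.sample(n, rng)
    if method == "rejection":
        return sampler.sample_rejection(n, rng)
    raise SimulationError(f"unknown sampling method {method!r}")


# ---------------------------------------------------------------------------
# noise


def add_noise(v: Sequence[float], regime, n_reps: int = 4,
              rng_seed: int | np.random.Generator = 0,
              sigma: float | None = None,
              admissible_range=DEFAULT_RANGE) -> np.ndarray:
    """Simulate a 4 x n_reps replicate matrix around the mean vector.

    sigma = delta / (delta/sigma ratio), identical for all four groups.
    For the constant profile delta is undefined and an explicit ``sigma``
    must be supplied.  Values pushed outside the admissible range by noise
    are clipped to the range limits.
    """
    if n_reps < 2:
        raise SimulationError("n_reps must be >= 2 (replicate variance "
                              "is undefined otherwise)")
    ratio = resolve_regime(regime)
    v = np.asarray(v, dtype=float)
    if sigma is None:
        delta = signal_delta(v)
        if delta is None:
            raise SimulationError("constant mean vector: supply sigma "
                                  "explicitly")
        sigma = delta / ratio
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    reps = rng.normal(loc=v[:, None], scale=sigma, size=(4, n_reps))
    return clip_to_range(reps, admissible_range)


# ---------------------------------------------------------------------------
# training sets


@dataclass
class TrainingSet:
    """Labeled simulated instances plus generation metadata.

    ``table`` has one row per instance: instance_id, profile_id, regime
    (delta/sigma ratio), delta (NaN for the constant profile), sigma, and
    the 4 x n_reps replicate values in condition-major order.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return int(self.metadata["n_reps"])

    def replicate_columns(self) -> list[str]:
        return [f"{c}_r{i + 1}" for c in CONDITIONS
                for i in range(self.n_reps)]

    def replicates(self) -> np.ndarray:
        """(n_instances, 4, n_reps) replicate array."""
        arr = self.table[self.replicate_columns()].to_numpy()
        return arr.reshape(len(self.table), 4, self.n_reps)

    def labels(self) -> np.ndarray:
        return self.table["profile_id"].to_numpy()


def build_training_set(taxonomy: Taxonomy,
                       regimes: Sequence = DEFAULT_REGIMES,
                       instances_per_profile: int = 400,
                       n_reps: int = 4,
                       rng_seed: int = 0,
                       admissible_range=DEFAULT_RANGE,
                       min_signal: float = MIN_SIGNAL) -> TrainingSet:
    """Simulate ``instances_per_profile`` labeled instances per (profile,
    noise regime) for every profile in the taxonomy.

    The constant profile has no defined signal; its sigma is drawn from the
    empirical sigma distribution of the non-constant instances of the same
    regime, keeping the constant class learnable.
    """
    rng = np.random.default_rng(rng_seed)
    ratios = [resolve_regime(r) for r in regimes]
    rep_cols = [f"{c}_r{i + 1}" for c in CONDITIONS for i in range(n_reps)]
    rows = []
    constant_jobs = []
    samplers: dict[int, _ProfileSampler] = {}
    for profile in taxonomy.profiles:
        if profile.category == "constant":
            constant_jobs.append(profile)
            continue
        samplers[profile.id] = _ProfileSampler(
            profile, admissible_range, min_signal)
    sigma_pool: dict[float, list[float]] = {r: [] for r in ratios}
    for profile in taxonomy.profiles:
        if profile.category == "constant":
            continue
        sampler = samplers[profile.id]
        for ratio in ratios:
            means = sampler.sample(instances_per_profile, rng)
            for v in means:
                delta = signal_delta(v)
                sigma = delta / ratio
                sigma_pool[ratio].append(sigma)
                reps = add_noise(v, ratio, n_reps, rng,
                                 admissible_range=admissible_range)
                rows.append((profile.id, ratio, delta, sigma,
                             reps.ravel()))
    for profile in constant_jobs:
        sampler = _ProfileSampler(profile, admissible_range, min_signal)
        for ratio in ratios:
            means = sampler.sample(instances_per_profile, rng)
            pool = np.array(sigma_pool[ratio])
            if pool.size == 0:
                raise SimulationError("cannot set constant-profile sigma: "
                                      "no non-constant instances simulated")
            sigmas = rng.choice(pool, size=instances_per_profile)
            for v, sigma in zip(means, sigmas):
                reps = add_noise(v, ratio, n_reps, rng, sigma=float(sigma),
                                 admissible_range=admissible_range)
                rows.append((profile.id, ratio, np.nan, float(sigma),
                             reps.ravel()))
    table = pd.DataFrame(
        [(i, pid, ratio, delta, sigma, *reps)
         for i, (pid, ratio, delta, sigma, reps) in enumerate(rows)],
        columns=["instance_id", "profile_id", "regime", "delta", "sigma",
                 *rep_cols])
    metadata = {
        "seed": rng_seed,
        "regimes": ratios,
        "instances_per_profile": instances_per_profile,
        "n_reps": n_reps,
        "admissible_range": list(admissible_range),
        "min_signal": min_signal,
        "n_profiles": len(taxonomy),
    }
    return TrainingSet(table=table, metadata=metadata)


def write_training_set(ts: TrainingSet, path, metadata_path=None) -> None:
    """Tab-delimited instance table plus a JSON metadata sidecar."""
    import json
    from pathlib import Path
    path = Path(path)
    ts.table.to_csv(path, sep="\t", index=False)
    side = (Path(metadata_path) if metadata_path
            else path.with_suffix(path.suffix + ".meta.json"))
    side.write_text(json.dumps(ts.metadata, indent=2) + "\n")


def read_training_set(path, metadata_path=None) -> TrainingSet:
    import json
    from pathlib import Path
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    side = (Path(metadata_path) if metadata_path
            else path.with_suffix(path.suffix + ".meta.json"))
    metadata = json.loads(side.read_text())
    return TrainingSet(table=table, metadata=metadata)
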