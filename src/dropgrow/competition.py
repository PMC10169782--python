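"""Monod-kinetics competition between rate and yield specialists.

Two selection regimes are simulated for strains that trade off maximum
specific growth rate against biomass yield per substrate:

* **Shared-pool serial batch transfers** — all strains draw on one substrate
  pool; each transfer grows for a fixed time and carries a small fraction
  (e.g. 1%) into fresh medium.  Whoever grows fastest takes the pool, so the
  rate specialist fixes.
* **Nutrient-privatized droplet ensembles** — each droplet holds a private
  substrate aliquot and (ideally) a single founder cell.  With full substrate
  consumption the biomass a founder contributes to the pooled population is
  proportional to its *yield*, not its rate, so the yield specialist is
  enriched.  In the deterministic single-founder, full-consumption limit the
  per-transfer frequency update has the closed form

      f' = r f / (r f + 1 - f),   r = Y_yield / Y_rate,

  implemented in :func:`closed_form_droplet_update` and used as an analytic
  oracle for the ODE-based ensemble simulator.

Growth within any compartment follows the Monod consumer-resource system

    dN_i/dt = mu_i(S) N_i,      mu_i(S) = mu_max_i S / (K_s_i + S)
    dS/dt   = feed - sum_i mu_i(S) N_i / Y_i

with no death or maintenance term: populations freeze once substrate is
exhausted.  ``feed`` defaults to 0 (plain batch); a constant feed is exposed
for fed-batch operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StrainKinetics",
    "BatchState",
    "BatchTrajectory",
    "TransferProtocol",
    "DropletEnsemble",
    "CompetitionTrajectory",
    "monod_rate",
    "simulate_batch",
    "serial_batch_transfers",
    "simulate_droplet_transfer",
    "closed_form_droplet_update",
    "serial_droplet_transfers",
]


@dataclass(frozen=True)
class StrainKinetics:
    """Monod growth parameters of one strain.

    mu_max : maximum specific growth rate (1/h)
    K_s    : half-saturation constant (mM substrate)
    yield_Y: biomass produced per substrate consumed (abundance units per mM;
             OD-equivalent per mM in the default parameter sets)
    """

    name: str
    mu_max: float
    K_s: float
    yield_Y: float

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.K_s <= 0 or self.yield_Y <= 0:
            raise ValueError(
                f"strain {self.name!r}: mu_max, K_s and yield_Y must all be > 0"
            )


@dataclass
class BatchState:
    """Instantaneous state of a well-mixed compartment."""

    substrate_S: float
    populations_N: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.populations_N = np.asarray(self.populations_N, dtype=float)
        if self.substrate_S < 0:
            raise ValueError("substrate_S must be >= 0")
        if np.any(self.populations_N < 0):
            raise ValueError("populations_N must be >= 0")


@dataclass
class BatchTrajectory:
    """Time course of one batch integration."""

    times: np.ndarray
    substrate: np.ndarray          # (n_times,)
    populations: np.ndarray        # (n_strains, n_times)
    feed_rate: float

    @property
    def final(self) -> BatchState:
        return BatchState(
            substrate_S=max(float(self.substrate[-1]), 0.0),
            populations_N=self.populations[:, -1].copy(),
            time=float(self.times[-1]),
        )

    def mass_balance_residual(self, yields: np.ndarray) -> float:
        """Consumed substrate minus biomass formed / yield (0 if exact)."""
        dN = self.populations[:, -1] - self.populations[:, 0]
        consumed = self.substrate[0] - self.substrate[-1] + self.feed_rate * (
            self.times[-1] - self.times[0]
        )
        return float(consumed - np.sum(dN / yields))


@dataclass(frozen=True)
class TransferProtocol:
    """Serial-transfer regime: dilute, grow for a fixed time, repeat."""

    dilution_factor: float = 0.01
    duration_h: float = 48.0
    n_transfers: int = 10
    substrate_S0: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.dilution_factor < 1):
            raise ValueError("dilution_factor must be in (0, 1)")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if self.n_transfers < 0:
            raise ValueError("n_transfers must be >= 0")
        if self.substrate_S0 < 0:
            raise ValueError("substrate_S0 must be >= 0")


@dataclass(frozen=True)
class DropletEnsemble:
    """A population of droplets with private substrate cores.

    core_substrate : substrate concentration of the fresh core medium (mM).
    founder_biomass: biomass contributed by one founder cell, in the same
        abundance units as populations (default 0.015 OD-equivalent: one cell
        in a ~65 pL core at ~1e9 cells/mL/OD).
    founder_mode   : "exact-single" puts one founder in every droplet;
        "poisson" draws k ~ Poisson(mean_occupancy) founders i.i.d. from
        founder_frequencies, so empty droplets and within-droplet competition
        between co-encapsulated founders both occur.
    sampling       : "multinomial" draws a finite founder sample with the rng;
        "expected" uses the exact expected composition (deterministic limit).
    """

    n_droplets: int
    core_substrate: float
    founder_frequencies: np.ndarray
    founder_mode: Literal["exact-single", "poisson"] = "exact-single"
    mean_occupancy: float = 0.22314
    founder_biomass: float = 0.015
    sampling: Literal["multinomial", "expected"] = "multinomial"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.founder_frequencies, dtype=float)
        object.__setattr__(self, "founder_frequencies", freqs)
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0, atol=1e-9):
            raise ValueError("founder_frequencies must be >= 0 and sum to 1")
        if self.founder_mode not in ("exact-single", "poisson"):
            raise ValueError(f"unknown founder_mode {self.founder_mode!r}")
        if self.founder_biomass <= 0:
            raise ValueError("founder_biomass must be > 0")


@dataclass
class CompetitionTrajectory:
    """Per-transfer record of a serial competition experiment."""

    strain_names: list[str]
    frequencies: np.ndarray        # (n_transfers + 1, n_strains); row 0 = start
    abundances: np.ndarray         # (n_transfers + 1, n_strains)
    extinct: bool = False          # True if the run was truncated

    @property
    def n_transfers(self) -> int:
        return self.frequencies.shape[0] - 1

    def to_frame(self):
        import pandas as pd

        rows = []
        for t in range(self.frequencies.shape[0]):
            for j, name in enumerate(self.strain_names):
                rows.append(
                    {
                        "transfer": t,
                        "strain": name,
                        "frequency": self.frequencies[t, j],
                        "abundance": self.abundances[t, j],
                    }
                )
        return pd.DataFrame(rows)


def monod_rate(strain: StrainKinetics, S: float) -> float:
    """Specific growth rate mu(S) = mu_max * S / (K_s + S)."""
    if S < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {S}")
    return strain.mu_max * S / (strain.K_s + S)


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces non-finite state."""


def simulate_batch(
    strains: Sequence[StrainKinetics],
    init: BatchState,
    duration_h: float,
    feed_rate: float = 0.0,
    rtol: float = 1e-8,
    n_record: int = 50,
) -> BatchTrajectory:
    """Integrate the Monod consumer-resource system for one batch.

    Substrate is clamped at zero inside the right-hand side, so trajectories
    stay physical even when the integrator overshoots exhaustion by a
    round-off amount.
    """
    if feed_rate < 0:
        raise ValueError("feed_rate must be >= 0")
    if duration_h <= 0:
        raise ValueError("duration_h must be > 0")
    mu_max = np.array([s.mu_max for s in strains])
    K_s = np.array([s.K_s for s in strains])
    Y = np.array([s.yield_Y for s in strains])
    if len(init.populations_N) != len(strains):
        raise ValueError("populations_N length must match number of strains")

    def rhs(_t, y):
        S = max(y[0], 0.0)
        N = y[1:]
        mu = mu_max * S / (K_s + S)
        dN = mu * N
        dS = feed_rate - np.sum(dN / Y)
        return np.concatenate(([dS], dN))

    y0 = np.concatenate(([init.substrate_S], init.populations_N))
    scale = max(init.substrate_S, feed_rate * duration_h, 1.0)
    t_eval = np.linspace(0.0, duration_h, n_record)
    sol = solve_ivp(
        rhs,
        (0.0, duration_h),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=rtol * scale * 1e-6,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            f"batch integration failed: {sol.message}; "
            f"S0={init.substrate_S}, N0={init.populations_N}, feed={feed_rate}"
        )
    return BatchTrajectory(
        times=sol.t + init.time,
        substrate=np.maximum(sol.y[0], 0.0),
        populations=sol.y[1:],
        feed_rate=feed_rate,
    )


def serial_batch_transfers(
    strains: Sequence[StrainKinetics],
    protocol: TransferProtocol,
    init_frequencies: Sequence[float],
    init_biomass: float | None = None,
    feed_rate: float = 0.0,
    extinction_threshold: float = 1e-12,
    rtol: float = 1e-8,
) -> CompetitionTrajectory:
    """Shared-pool serial transfer competition.

    Each transfer grows the mixed culture in one batch for ``duration_h``,
    then carries ``dilution_factor`` of every population into fresh medium at
    ``substrate_S0``.  ``init_biomass`` is the total inoculum of transfer 1;
    by default it is what a stationary culture diluted by the protocol's
    factor would provide.  A strain whose frequency falls below
    ``extinction_threshold`` of the total is flagged; the trajectory is
    truncated if every strain goes extinct.
    """
    freqs = np.asarray(init_frequencies, dtype=float)
    if not np.isclose(freqs.sum(), 1.0, atol=1e-9):
        raise ValueError("init_frequencies must sum to 1")
    Y = np.array([s.yield_Y for s in strains])
    if init_biomass is None:
        init_biomass = protocol.dilution_factor * protocol.substrate_S0 * float(Y.max())

    N = init_biomass * freqs
    freq_rows = [freqs.copy()]
    abund_rows = [N.copy()]
    extinct = False
    for _ in range(protocol.n_transfers):
        state = BatchState(substrate_S=protocol.substrate_S0, populations_N=N)
        traj = simulate_batch(strains, state, protocol.duration_h, feed_rate, rtol=rtol)
        N_end = traj.final.populations_N
        total = N_end.sum()
        if total <= 0 or np.all(N_end < extinction_threshold * max(total, init_biomass)):
            extinct = True
            break
        freq_rows.append(N_end / total)
        abund_rows.append(N_end.copy())
        N = protocol.dilution_factor * N_end
    return CompetitionTrajectory(
        strain_names=[s.name for s in strains],
        frequencies=np.array(freq_rows),
        abundances=np.array(abund_rows),
        extinct=extinct,
    )


def closed_form_droplet_update(f: float, yield_ratio: float) -> float:
    """One privatized-growth transfer in the analytic limit.

    Assumes every droplet has exactly one founder, negligible founder biomass
    and full substrate consumption: a founder of the yield specialist yields
    ``r`` times the biomass of a rate-specialist founder, so

        f' = r f / (r f + 1 - f).

    Fixed points at f = 0 and f = 1; strictly increasing per iteration for
    r > 1 and 0 < f < 1.
    """
    if not (0 <= f <= 1):
        raise ValueError(f"f must be in [0, 1], got {f}")
    if yield_ratio <= 0:
        raise ValueError("yield_ratio must be > 0")
    return yield_ratio * f / (yield_ratio * f + (1.0 - f))


def _founder_compositions(
    ensemble: DropletEnsemble, n_strains: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, float]]:
    """Unique founder compositions and their droplet weights (sum <= n_droplets).

    Weights are droplet counts under multinomial sampling, or expected counts
    in the deterministic "expected" mode.  Empty droplets are dropped.
    """
    freqs = ensemble.founder_frequencies
    n = ensemble.n_droplets
    out: list[tuple[np.ndarray, float]] = []
    if ensemble.founder_mode == "exact-single":
        if ensemble.sampling == "expected":
            counts = n * freqs
        else:
            counts = rng.multinomial(n, freqs).astype(float)
        for j in range(n_strains):
            if counts[j] > 0:
                comp = np.zeros(n_strains)
                comp[j] = 1.0
                out.append((comp, float(counts[j])))
        return out

    # poisson founder mode
    lam = ensemble.mean_occupancy
    if ensemble.sampling == "expected":
        # Expected-mode Poisson loading: enumerate small compositions exactly.
        from scipy import stats as _stats
        from itertools import product as _product

        k_max = max(3, int(lam * 10) + 3)
        for total_k in range(1, k_max + 1):
            pk = float(_stats.poisson.pmf(total_k, lam))
            for comp_idx in _product(range(total_k + 1), repeat=n_strains):
                if sum(comp_idx) != total_k:
                    continue
                from math import factorial

                multinom = factorial(total_k)
                p = 1.0
                for j, c in enumerate(comp_idx):
                    multinom //= factorial(c)
                    p *= freqs[j] ** c
                w = n * pk * multinom * p
                if w > 0:
                    out.append((np.array(comp_idx, dtype=float), w))
        return out

    ks = rng.poisson(lam, size=n)
    ks = ks[ks > 0]
    if len(ks) == 0:
        return out
    comps = np.vstack([rng.multinomial(k, freqs) for k in ks])
    uniq, counts = np.unique(comps, axis=0, return_counts=True)
    for comp, c in zip(uniq, counts):
        out.append((comp.astype(float), float(c)))
    return out


def simulate_droplet_transfer(
    strains: Sequence[StrainKinetics],
    ensemble: DropletEnsemble,
    duration_h: float,
    rng: np.random.Generator | None = None,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow one generation of droplets and pool them.

    Founder compositions are sampled per droplet, every occupied droplet is
    grown as an independent batch on its private substrate, and final
    populations are pooled across the ensemble.  Droplets with identical
    founder composition are deterministic copies, so each unique composition
    is integrated once and weighted by its droplet count.

    Returns ``(pooled_populations, pooled_frequencies)``.
    """
    if rng is None:
        rng = np.random.default_rng(ensemble.rng_seed)
    n_strains = len(strains)
    comps = _founder_compositions(ensemble, n_strains, rng)
    if not comps:
        raise ValueError(
            "no occupied droplets sampled; increase n_droplets or mean_occupancy"
        )
    pooled = np.zeros(n_strains)
    for comp, weight in comps:
        state = BatchState(
            substrate_S=ensemble.core_substrate,
            populations_N=comp * ensemble.founder_biomass,
        )
        traj = simulate_batch(strains, state, duration_h, feed_rate=0.0, rtol=rtol)
        pooled += weight * traj.final.populations_N
    return pooled, pooled / pooled.sum()


def serial_droplet_transfers(
    strains: Sequence[StrainKinetics],
    ensemble: DropletEnsemble,
    protocol: TransferProtocol,
    rtol: float = 1e-8,
) -> CompetitionTrajectory:
    """Privatized serial transfers: grow droplets, pool, re-encapsulate.

    The pooled strain frequencies at the end of transfer t become the founder
    frequencies of transfer t+1, mirroring bulk droplet disruption followed by
    dilution and re-encapsulation.  One rng seeded from ``ensemble.rng_seed``
    drives all transfers, so a fixed seed gives a bit-identical trajectory.
    """
    rng = np.random.default_rng(ensemble.rng_seed)
    freqs = ensemble.founder_frequencies.astype(float)
    freq_rows = [freqs.copy()]
    abund_rows = [freqs * ensemble.founder_biomass * ensemble.n_droplets]
    for _ in range(protocol.n_transfers):
        ens_t = replace(ensemble, founder_frequencies=freqs)
        pooled, freqs = simulate_droplet_transfer(
            strains, ens_t, protocol.duration_h, rng=rng, rtol=rtol
        )
        freq_rows.append(freqs.copy())
        abund_rows.append(pooled.copy())
    return CompetitionTrajectory(
        strain_names=[s.name for s in strains],
        frequencies=np.array(freq_rows),
        abundances=np.array(abund_rows),
    )
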