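"""Brownian-motion Monte Carlo model of macromolecule loading through
transient membrane pores.

The cell is a sphere with absorbing spherical-cap pores on its surface;
tracer molecules are independent points random-walking in the medium
between the cell and a reflecting outer boundary (a finite reservoir).
While the pores are open — for one membrane resealing time — any walker
whose step crosses the cell surface inside a pore cap is absorbed
(delivered); crossings elsewhere on the membrane reflect.  The fraction of
walkers delivered before pore closure is the loading efficiency.

Molecular size enters through the Stokes–Einstein relation: the diffusion
coefficient scales as the inverse hydrodynamic radius, and the radius as
the cube root of molecular weight, so the per-step displacement scale is
``s(M) = s_ref * (M_ref / M)**(1/3)`` (per-axis Gaussian SD per unit
sqrt-time).  The simulation itself is nondimensional (lengths in cell
radii); the physical-unit helpers are provided for reporting.

Membrane crossings are detected by segment–sphere intersection, never by
endpoint testing alone, so fast walkers cannot tunnel through the membrane
within one step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PhysicalParams",
    "MoleculeSpec",
    "PoreSpec",
    "CellModel",
    "SimParams",
    "LoadingResult",
    "molecule_radius",
    "diffusion_coefficient",
    "step_scale",
    "random_pores",
    "simulate_loading",
    "calibrate_step",
    "loading_vs_time",
    "loading_vs_mw",
    "free_walk",
    "delivery_time_course",
]

#: Boltzmann constant, J/K.
KB = 1.380649e-23
#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: Default per-axis displacement scale at the reference MW, in cell radii
#: per sqrt(second).  Chosen so a 10 kDa tracer explores a few cell radii
#: over a typical pore lifetime (tens of seconds); the pipeline normally
#: replaces it with a calibrated value (see :func:`calibrate_step`).
DEFAULT_STEP_REF = 0.25
DEFAULT_MW_REF = 10.0


def molecule_radius(mol_weight: float, eta: float,
                    n_avogadro: float = AVOGADRO) -> float:
    """Hydrodynamic radius from the Einstein viscosity relation,
    ``R = (3 * eta * M / (10 * pi * N))**(1/3)``.

    Units follow the inputs; this helper exists for physical reporting —
    the simulation uses only the cube-root proportionality.
    """
    if mol_weight <= 0 or eta <= 0 or n_avogadro <= 0:
        raise ValueError("all inputs must be positive")
    return (3.0 * eta * mol_weight / (10.0 * math.pi * n_avogadro)) ** (1.0 / 3.0)


def diffusion_coefficient(temperature: float, eta: float, radius: float,
                          kb: float = KB) -> float:
    """Stokes–Einstein diffusion coefficient ``D = kB*T / (6*pi*eta*R)``."""
    if temperature <= 0 or eta <= 0 or radius <= 0 or kb <= 0:
        raise ValueError("all inputs must be positive")
    return kb * temperature / (6.0 * math.pi * eta * radius)


def step_scale(mol_weight: float, mw_ref: float = DEFAULT_MW_REF,
               s_ref: float = DEFAULT_STEP_REF) -> float:
    """Displacement scale ``s_ref * (mw_ref / M)**(1/3)``.

    Velocity (and hence the random-walk step) is proportional to the
    diffusion coefficient, which falls as the cube root of molecular
    weight.
    """
    if mol_weight <= 0 or mw_ref <= 0 or s_ref <= 0:
        raise ValueError("all inputs must be positive")
    return s_ref * (mw_ref / mol_weight) ** (1.0 / 3.0)


@dataclass(frozen=True)
class PhysicalParams:
    """Physical constants for unit-bearing reporting."""

    kb: float = KB
    temperature: float = 310.0  # K, physiological
    eta: float = 1.0e-3         # Pa*s, aqueous medium
    n_avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if min(self.kb, self.temperature, self.eta, self.n_avogadro) <= 0:
            raise ValueError("physical parameters must be positive")


@dataclass(frozen=True)
class MoleculeSpec:
    """Tracer molecule: molecular weight plus its random-walk step scale."""

    mol_weight: float           # kDa
    step_ref: float = DEFAULT_STEP_REF
    mw_ref: float = DEFAULT_MW_REF

    def __post_init__(self) -> None:
        if self.mol_weight <= 0 or self.step_ref <= 0 or self.mw_ref <= 0:
            raise ValueError("molecule parameters must be positive")

    @property
    def step(self) -> float:
        """Per-axis Gaussian SD per unit sqrt-time, in cell radii."""
        return step_scale(self.mol_weight, self.mw_ref, self.step_ref)


@dataclass(frozen=True)
class PoreSpec:
    """Spherical-cap pore: unit center direction and half-angle (rad)."""

    direction: Tuple[float, float, float]
    angular_radius: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise ValueError("direction must be a 3-vector")
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("direction must have unit norm (within 1e-12)")
        if not 0.0 < self.angular_radius < math.pi / 2:
            raise ValueError("angular_radius must lie in (0, pi/2)")


def random_pores(n: int, angular_radius: float, seed: int = 0,
                 max_tries: int = 100_000) -> list[PoreSpec]:
    """Place ``n`` disjoint pore caps uniformly at random on the sphere."""
    rng = np.random.default_rng(seed)
    dirs: list[np.ndarray] = []
    for _ in range(max_tries):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(np.dot(v, u) < math.cos(2 * angular_radius) for u in dirs):
            dirs.append(v)
            if len(dirs) == n:
                break
    else:
        raise ValueError(
            f"could not place {n} disjoint caps of half-angle "
            f"{angular_radius} rad")
    return [PoreSpec(direction=tuple(v), angular_radius=angular_radius)
            for v in dirs]


@dataclass(frozen=True)
class CellModel:
    """Spherical cell with pore caps inside a reflecting outer sphere.

    ``shrinking_pores`` makes each cap half-angle shrink linearly to zero
    over the pore-open time (an alternative resealing geometry); by
    default caps stay constant while open and close instantaneously.
    """

    cell_radius: float = 1.0
    pores: Tuple[PoreSpec, ...] = (
        PoreSpec(direction=(0.0, 0.0, 1.0), angular_radius=0.2),)
    domain_radius: float = 5.0
    shrinking_pores: bool = False
    absorb_everywhere: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "pores", tuple(self.pores))
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")
        if self.domain_radius <= self.cell_radius:
            raise ValueError("domain_radius must exceed cell_radius")
        dirs = [np.asarray(p.direction) for p in self.pores]
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                ang = math.acos(float(np.clip(np.dot(dirs[i], dirs[j]),
                                              -1.0, 1.0)))
                if ang <= self.pores[i].angular_radius + \
                        self.pores[j].angular_radius:
                    raise ValueError(f"pore caps {i} and {j} overlap")

    @property
    def min_cap_chord(self) -> float:
        """Smallest pore-cap chord, the membrane length scale the time step
        must resolve."""
        if self.absorb_everywhere:
            return 2.0 * self.cell_radius
        if not self.pores:
            return 2.0 * self.cell_radius
        return 2.0 * self.cell_radius * math.sin(
            min(p.angular_radius for p in self.pores))


@dataclass(frozen=True)
class SimParams:
    """Monte Carlo run parameters.

    ``dt=None`` picks the time step automatically so that the per-axis step
    SD does not exceed ``max_step_frac`` of the smallest pore-cap chord
    (crossing-geometry resolution), then rounds so an integer number of
    steps spans ``open_time`` exactly.  ``step_model`` selects Gaussian
    displacements (default; converges to Brownian motion at any dt) or
    fixed-length isotropic steps of matched mean-square displacement.
    """

    n_particles: int = 5000
    open_time: float = 60.0
    dt: Optional[float] = None
    n_replicates: int = 10
    seed: int = 0
    step_model: str = "gaussian"
    max_step_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.open_time < 0:
            raise ValueError("open_time must be nonnegative")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.step_model not in ("gaussian", "fixed"):
            raise ValueError("step_model must be 'gaussian' or 'fixed'")
        if not 0 < self.max_step_frac <= 1:
            raise ValueError("max_step_frac must be in (0, 1]")


@dataclass(frozen=True)
class LoadingResult:
    """Loading efficiency averaged over replicates.

    ``delivered_count + surviving_count == total_count`` (walker
    conservation) holds by bookkeeping, not by construction: survivors are
    counted from the walkers still in play when the pores close.
    """

    loading_efficiency: float
    delivered_count: int
    total_count: int
    sem_over_replicates: float
    per_replicate: Tuple[float, ...] = ()
    surviving_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading_efficiency <= 1.0:
            raise ValueError("loading efficiency must lie in [0, 1]")


def _resolve_dt(cell: CellModel, mol: MoleculeSpec, sim: SimParams
                ) -> tuple[float, int]:
    """Time step and step count spanning open_time exactly."""
    if sim.open_time == 0:
        return 0.0, 0
    if sim.dt is not None:
        return sim.dt, int(math.floor(sim.open_time / sim.dt + 1e-12))
    sd_max = sim.max_step_frac * cell.min_cap_chord
    dt_max = (sd_max / mol.step) ** 2
    n_steps = max(1, int(math.ceil(sim.open_time / dt_max - 1e-12)))
    return sim.open_time / n_steps, n_steps


def _init_positions(rng: np.random.Generator, n: int, r_in: float,
                    r_out: float) -> np.ndarray:
    """Uniform positions in the shell between the cell and the boundary."""
    u = rng.random(n)
    r = (u * (r_out ** 3 - r_in ** 3) + r_in ** 3) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r[:, None] * v


def _run_replicate(cell: CellModel, mol: MoleculeSpec, sim: SimParams,
                   seed_seq: np.random.SeedSequence,
                   per_step: Optional[list] = None
                   ) -> tuple[int, int, int]:
    """One replicate; returns (delivered, surviving, total).

    When ``per_step`` is a list, the cumulative delivered count after each
    step is appended to it (capture time course).
    """
    rng = np.random.default_rng(seed_seq)
    dt, n_steps = _resolve_dt(cell, mol, sim)
    n = sim.n_particles
    r_c, r_d = cell.cell_radius, cell.domain_radius
    pos = _init_positions(rng, n, r_c, r_d)
    if n_steps == 0 or (not cell.pores and not cell.absorb_everywhere):
        return 0, n, n

    pore_dirs = np.array([p.direction for p in cell.pores], dtype=float) \
        if cell.pores else np.empty((0, 3))
    pore_ang = np.array([p.angular_radius for p in cell.pores], dtype=float) \
        if cell.pores else np.empty(0)
    sd = mol.step * math.sqrt(dt)
    fixed_len = sd * math.sqrt(3.0)  # matches Gaussian mean-square step
    delivered = 0

    for k in range(n_steps):
        if pos.shape[0] == 0:
            break
        m = pos.shape[0]
        if sim.step_model == "gaussian":
            disp = rng.normal(0.0, sd, size=(m, 3))
        else:
            disp = rng.normal(size=(m, 3))
            disp *= fixed_len / np.linalg.norm(disp, axis=1, keepdims=True)

        if cell.shrinking_pores:
            frac = 1.0 - (k * dt) / sim.open_time
            cos_ang = np.cos(pore_ang * frac)
        else:
            cos_ang = np.cos(pore_ang)

        p1 = pos + disp
        absorbed = np.zeros(m, dtype=bool)
        # Membrane interaction: a step may reflect and re-approach; a few
        # passes resolve all crossings at the default step size.
        for _pass in range(8):
            d = p1 - pos
            a = np.einsum("ij,ij->i", d, d)
            b = 2.0 * np.einsum("ij,ij->i", pos, d)
            c = np.einsum("ij,ij->i", pos, pos) - r_c * r_c
            disc = b * b - 4.0 * a * c
            with np.errstate(invalid="ignore", divide="ignore"):
                sq = np.sqrt(np.maximum(disc, 0.0))
                t_hit = (-b - sq) / (2.0 * a)
            crossing = (~absorbed) & (disc > 0) & (a > 0) \
                & (t_hit > 0.0) & (t_hit <= 1.0)
            if not crossing.any():
                break
            idx = np.flatnonzero(crossing)
            x = pos[idx] + t_hit[idx, None] * d[idx]
            x_hat = x / np.linalg.norm(x, axis=1, keepdims=True)
            if cell.absorb_everywhere:
                hit_pore = np.ones(idx.size, dtype=bool)
            elif pore_dirs.size:
                cosd = x_hat @ pore_dirs.T
                hit_pore = (cosd >= cos_ang[None, :]).any(axis=1)
            else:
                hit_pore = np.zeros(idx.size, dtype=bool)
            absorbed[idx[hit_pore]] = True
            # Specular reflection of the remaining travel off the tangent
            # plane at the intersection point.
            ref = idx[~hit_pore]
            if ref.size:
                xr = x[~hit_pore]
                nr = x_hat[~hit_pore]
                rem = p1[ref] - xr
                rem -= 2.0 * np.einsum("ij,ij->i", rem, nr)[:, None] * nr
                # Nudge the pivot just outside the membrane so the next
                # pass sees an exterior start point.
                pos[ref] = xr * (1.0 + 1e-12)
                p1[ref] = xr + rem
        # Safety: any walker still numerically inside is pushed to the
        # surface (counts as reflected).
        rad = np.linalg.norm(p1, axis=1)
        inside = (~absorbed) & (rad < r_c)
        if inside.any():
            p1[inside] *= (r_c * (1.0 + 1e-9) / rad[inside])[:, None]

        # Reflecting outer boundary (radial fold-back).
        rad = np.linalg.norm(p1, axis=1)
        out = (~absorbed) & (rad > r_d)
        if out.any():
            new_r = 2.0 * r_d - rad[out]
            new_r = np.clip(new_r, r_c * (1.0 + 1e-9), r_d)
            p1[out] *= (new_r / rad[out])[:, None]

        delivered += int(absorbed.sum())
        pos = p1[~absorbed]
        # Conservation: delivered walkers plus survivors account for all.
        assert delivered + pos.shape[0] == n
        if per_step is not None:
            per_step.append(delivered)

    return delivered, pos.shape[0], n


def simulate_loading(cell: CellModel, mol: MoleculeSpec,
                     sim: SimParams) -> LoadingResult:
    """Loading efficiency of one molecule species for one pore-open time.

    Averages ``n_replicates`` independent runs with sub-seeds spawned
    deterministically from ``sim.seed``; identical inputs give identical
    results.  Zero open time or an absent pore set yields exactly zero
    loading.
    """
    dt, n_steps = _resolve_dt(cell, mol, sim)
    if sim.open_time > 0 and n_steps == 0:
        warnings.warn("open_time shorter than dt: no steps taken",
                      stacklevel=2)
    children = np.random.SeedSequence(sim.seed).spawn(sim.n_replicates)
    fractions, delivered_total, surviving_total = [], 0, 0
    for seq in children:
        dlv, srv, tot = _run_replicate(cell, mol, sim, seq)
        fractions.append(dlv / tot)
        delivered_total += dlv
        surviving_total += srv
    fr = np.asarray(fractions)
    sem = float(fr.std(ddof=1) / math.sqrt(len(fr))) if len(fr) > 1 else 0.0
    return LoadingResult(loading_efficiency=float(fr.mean()),
                         delivered_count=delivered_total,
                         total_count=sim.n_particles * sim.n_replicates,
                         sem_over_replicates=sem,
                         per_replicate=tuple(fr),
                         surviving_count=surviving_total)


def calibrate_step(anchor_mw: float, anchor_time: float,
                   anchor_loading: float, cell: CellModel, sim: SimParams,
                   mw_ref: float = DEFAULT_MW_REF, tol: float = 0.01,
                   bracket: Tuple[float, float] = (0.02, 0.8),
                   max_iter: int = 40) -> float:
    """Reference step scale matching an anchor loading measurement.

    Loading is monotone in the step scale at fixed geometry and open time,
    so bisection on ``s_ref`` (geometric midpoints) finds the value at
    which the simulated loading for the anchor molecule and pore-open time
    matches ``anchor_loading`` within ``tol`` (absolute, replicate mean).
    All other conditions then reuse this fixed ``s_ref``.  The bracket
    endpoints are screened with at most 3 replicates (they only need to
    straddle the target); bisection itself runs at full replication.
    """
    if not 0.0 < anchor_loading < 1.0:
        raise ValueError("anchor_loading must lie in (0, 1)")
    sim = SimParams(n_particles=sim.n_particles, open_time=anchor_time,
                    dt=sim.dt, n_replicates=sim.n_replicates, seed=sim.seed,
                    step_model=sim.step_model,
                    max_step_frac=sim.max_step_frac)
    screen = SimParams(n_particles=sim.n_particles, open_time=anchor_time,
                       dt=sim.dt, n_replicates=min(3, sim.n_replicates),
                       seed=sim.seed, step_model=sim.step_model,
                       max_step_frac=sim.max_step_frac)

    def loading_at(s: float, params: SimParams = sim) -> float:
        mol = MoleculeSpec(mol_weight=anchor_mw, step_ref=s, mw_ref=mw_ref)
        return simulate_loading(cell, mol, params).loading_efficiency

    lo, hi = bracket
    f_lo, f_hi = loading_at(lo, screen), loading_at(hi, screen)
    if not f_lo <= anchor_loading <= f_hi:
        raise ValueError(
            f"anchor loading {anchor_loading:.3f} unattainable: bracket "
            f"[{lo:g}, {hi:g}] achieves [{f_lo:.4f}, {f_hi:.4f}]")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        f_mid = loading_at(mid)
        if abs(f_mid - anchor_loading) <= tol:
            return mid
        if f_mid < anchor_loading:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def free_walk(mol: MoleculeSpec, n_particles: int, n_steps: int, dt: float,
              seed: int = 0, step_model: str = "gaussian") -> np.ndarray:
    """Unconfined random-walk trajectories, shape (n_steps+1, n, 3).

    Uses the same displacement sampling as the loading simulation (no
    membrane, no boundary); handy for checking the molecular-weight
    scaling of the mean-squared displacement and for trajectory dumps.
    """
    rng = np.random.default_rng(seed)
    sd = mol.step * math.sqrt(dt)
    out = np.zeros((n_steps + 1, n_particles, 3))
    for k in range(1, n_steps + 1):
        if step_model == "gaussian":
            disp = rng.normal(0.0, sd, size=(n_particles, 3))
        else:
            disp = rng.normal(size=(n_particles, 3))
            disp *= (sd * math.sqrt(3.0)
                     / np.linalg.norm(disp, axis=1, keepdims=True))
        out[k] = out[k - 1] + disp
    return out


def delivery_time_course(cell: CellModel, mol: MoleculeSpec,
                         sim: SimParams) -> pd.DataFrame:
    """Cumulative delivered fraction after each step, replicate mean.

    Columns: ``time_s``, ``cum_delivered_frac``.
    """
    dt, n_steps = _resolve_dt(cell, mol, sim)
    children = np.random.SeedSequence(sim.seed).spawn(sim.n_replicates)
    courses = np.zeros((sim.n_replicates, n_steps))
    for i, seq in enumerate(children):
        rec: list[int] = []
        _run_replicate(cell, mol, sim, seq, per_step=rec)
        rec = rec + [rec[-1]] * (n_steps - len(rec)) if rec else [0] * n_steps
        courses[i] = np.asarray(rec, dtype=float) / sim.n_particles
    return pd.DataFrame({"time_s": (np.arange(n_steps) + 1) * dt,
                         "cum_delivered_frac": courses.mean(axis=0)})


def _grid_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame.from_records(rows)


def loading_vs_time(times: Sequence[float], mol: MoleculeSpec,
                    cell: CellModel, sim: SimParams) -> pd.DataFrame:
    """Loading-efficiency curve over a grid of pore-open times.

    Replicate ``r`` uses the same sub-seed at every grid point (common
    random numbers, variance reduction across the curve).
    """
    times = list(times)
    if not times:
        raise ValueError("empty time grid")
    rows = []
    for t in times:
        res = simulate_loading(
            cell, mol,
            SimParams(n_particles=sim.n_particles, open_time=float(t),
                      dt=sim.dt, n_replicates=sim.n_replicates,
                      seed=sim.seed, step_model=sim.step_model,
                      max_step_frac=sim.max_step_frac))
        rows.append({"open_time_s": float(t), "mw_kDa": mol.mol_weight,
                     "loading_mean": res.loading_efficiency,
                     "loading_sem": res.sem_over_replicates,
                     "n_particles": sim.n_particles,
                     "n_replicates": sim.n_replicates, "seed": sim.seed})
    return _grid_table(rows)


def loading_vs_mw(mws: Sequence[float], open_time: float, cell: CellModel,
                  sim: SimParams, step_ref: float = DEFAULT_STEP_REF,
                  mw_ref: float = DEFAULT_MW_REF) -> pd.DataFrame:
    """Loading-efficiency curve over a grid of molecular weights."""
    mws = list(mws)
    if not mws:
        raise ValueError("empty molecular-weight grid")
    rows = []
    for mw in mws:
        mol = MoleculeSpec(mol_weight=float(mw), step_ref=step_ref,
                           mw_ref=mw_ref)
        res = simulate_loading(
            cell, mol,
            SimParams(n_particles=sim.n_particles, open_time=float(open_time),
                      dt=sim.dt, n_replicates=sim.n_replicates,
                      seed=sim.seed, step_model=sim.step_model,
                      max_step_frac=sim.max_step_frac))
        rows.append({"mw_kDa": float(mw), "open_time_s": float(open_time),
                     "loading_mean": res.loading_efficiency,
                     "loading_sem": res.sem_over_replicates,
                     "n_particles": sim.n_particles,
                     "n_replicates": sim.n_replicates, "seed": sim.seed})
    return _grid_table(rows)
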