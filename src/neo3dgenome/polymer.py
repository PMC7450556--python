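"""Distance-restrained bead-on-string polymer reconstruction of the genome.

Each genomic bin is one bead; each chromosome is one chain (a human bin
table yields 23 chains). Two restraint families shape the structure:

* **connectivity** — sequential beads within a chain are held near a
  target bond length;
* **radial bias** — every bead is assigned a target distance from the
  nuclear center, derived from its compartment degree: active (high
  degree) beads sit near the center, inactive ones near the periphery.

The objective is the quadratic bias potential

    E = bond_k * sum_bonds (d_ij - L)^2  +  radial_k * sum_i (|r_i| - t_i)^2

minimized from a random-walk start by annealed gradient descent
(backtracking line search plus decaying random kicks, moves accepted only
when they lower E, so the energy trace is non-increasing). An ensemble of
independently restarted replicas (default 300) averages out the
arbitrariness of any single optimum.

Model units are arbitrary; the nuclear confinement radius defaults to 10
bond lengths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .compartment import CompartmentProfile
from .genome_grid import BinTable

__all__ = [
    "RestraintSet",
    "Conformation",
    "ConformationEnsemble",
    "NumericalFailureError",
    "assign_radial_targets",
    "initialize_random_conformation",
    "energy",
    "optimize_conformation",
    "generate_ensemble",
    "write_ensemble",
    "read_ensemble",
]

DEFAULT_N_REPLICAS = 300
DEFAULT_CONFINEMENT_RADIUS = 10.0
DEFAULT_R_MIN_FRAC = 0.2
DEFAULT_R_MAX_FRAC = 0.95


class NumericalFailureError(RuntimeError):
    """Non-finite energy encountered during optimization."""


@dataclass
class RestraintSet:
    """Bond and radial restraints for the polymer objective."""

    radial_targets: np.ndarray
    bond_length: float = 1.0
    bond_k: float = 1.0
    radial_k: float = 1.0
    confinement_radius: float = DEFAULT_CONFINEMENT_RADIUS

    def __post_init__(self) -> None:
        self.radial_targets = np.asarray(self.radial_targets, dtype=float)
        if self.bond_k <= 0 or self.radial_k <= 0:
            raise ValueError("restraint weights must be positive")
        if np.any(self.radial_targets <= 0) or np.any(
            self.radial_targets > self.confinement_radius
        ):
            raise ValueError("radial targets must lie in (0, confinement_radius]")


@dataclass
class Conformation:
    """One 3D structure: (x, y, z) per bead plus chain topology."""

    coords: np.ndarray
    chain_breaks: tuple[int, ...]
    energy: float = np.nan
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_beads, 3)")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def bond_index_pairs(self) -> np.ndarray:
        """(i, i+1) bead pairs bonded within chains (no bond spans a break)."""
        n = self.n_beads
        starts = {0, *self.chain_breaks}
        i = np.array([b for b in range(n - 1) if (b + 1) not in starts], dtype=int)
        return np.stack([i, i + 1], axis=1) if i.size else np.empty((0, 2), dtype=int)


@dataclass
class ConformationEnsemble:
    """Independently optimized replicas sharing one restraint set."""

    replicas: list[Conformation]
    restraints: RestraintSet
    bins: BinTable | None = None

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_replicas, n_beads, 3)."""
        return np.stack([c.coords for c in self.replicas])


def assign_radial_targets(
    profile: CompartmentProfile | np.ndarray,
    r_min: float,
    r_max: float,
) -> np.ndarray:
    """Map compartment degree to per-bead nuclear-radius targets.

    The bead with the highest degree (most active) gets ``r_min``, the
    lowest gets ``r_max``, and targets interpolate linearly in the
    genome-wide rank of the degree (average ranks on ties), so the map is
    monotone non-increasing in degree and equivariant under permutations
    of bead order.
    """
    degree = profile.degree if isinstance(profile, CompartmentProfile) else np.asarray(profile, float)
    if not r_min < r_max:
        raise ValueError("require r_min < r_max")
    n = degree.size
    if n == 1 or np.ptp(degree) == 0:
        warnings.warn("constant compartment profile: all radial targets set to midpoint")
        return np.full(n, (r_min + r_max) / 2.0)
    ranks = rankdata(-degree, method="average")  # 1 = highest degree
    return r_min + (ranks - 1.0) / (n - 1.0) * (r_max - r_min)


def initialize_random_conformation(
    bins: BinTable, restraints: RestraintSet, seed: int
) -> Conformation:
    """Random-walk start: each chain walks with fixed step = bond_length,
    confined to the nuclear radius by rejection of out-of-bounds steps."""
    rng = np.random.default_rng(seed)
    R = restraints.confinement_radius
    L = restraints.bond_length
    coords = np.empty((bins.n_bins, 3))
    for chrom in bins.chrom_names:
        start, stop = bins.chrom_bin_range(chrom)
        # chain origin uniform in the half-radius ball
        while True:
            p = rng.uniform(-R / 2, R / 2, size=3)
            if np.linalg.norm(p) <= R / 2:
                break
        coords[start] = p
        for b in range(start + 1, stop):
            while True:
                step = rng.normal(size=3)
                step *= L / np.linalg.norm(step)
                q = coords[b - 1] + step
                if np.linalg.norm(q) <= R:
                    break
            coords[b] = q
    conf = Conformation(coords=coords, chain_breaks=bins.chain_breaks(), seed=seed)
    return conf


def energy(conf: Conformation, restraints: RestraintSet) -> float:
    """Bias-potential value; zero iff every restraint is exactly satisfied."""
    if restraints.radial_targets.size != conf.n_beads:
        raise ValueError("restraints bead count mismatch")
    coords = conf.coords
    pairs = conf.bond_index_pairs()
    e = 0.0
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 1]] - coords[pairs[:, 0]], axis=1)
        e += restraints.bond_k * np.sum((d - restraints.bond_length) ** 2)
    radii = np.linalg.norm(coords, axis=1)
    e += restraints.radial_k * np.sum((radii - restraints.radial_targets) ** 2)
    return float(e)


def _gradient(coords: np.ndarray, pairs: np.ndarray, restraints: RestraintSet) -> np.ndarray:
    grad = np.zeros_like(coords)
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        diff = coords[j] - coords[i]
        d = np.linalg.norm(diff, axis=1)
        safe = np.where(d > 0, d, 1.0)
        coef = 2.0 * restraints.bond_k * (d - restraints.bond_length) / safe
        contrib = coef[:, None] * diff
        np.add.at(grad, j, contrib)
        np.add.at(grad, i, -contrib)
    radii = np.linalg.norm(coords, axis=1)
    safe = np.where(radii > 0, radii, 1.0)
    coef = 2.0 * restraints.radial_k * (radii - restraints.radial_targets) / safe
    grad += coef[:, None] * coords
    return grad


def optimize_conformation(
    init: Conformation,
    restraints: RestraintSet,
    max_iter: int = 5000,
    tol: float = 1e-6,
    step: float = 0.1,
    anneal_sigma: float = 0.1,
    seed: int | None = None,
) -> Conformation:
    """Minimize the bias potential from ``init`` by annealed gradient descent.

    Each iteration takes a gradient step with backtracking (the step size
    halves until energy decreases, and grows 10% after success); a random
    kick with linearly decaying amplitude ``anneal_sigma`` is tried first
    and kept only if it lowers the energy, so the energy trace is
    monotone non-increasing. Terminates at ``max_iter`` or when the
    relative energy improvement drops below ``tol``.
    """
    rng = np.random.default_rng(init.seed if seed is None else seed)
    coords = init.coords.copy()
    pairs = init.bond_index_pairs()
    e = energy(Conformation(coords, init.chain_breaks), restraints)
    if not np.isfinite(e):
        raise NumericalFailureError("non-finite energy at initialization")
    if e == 0.0:
        return replace(init, coords=coords, energy=0.0)

    def energy_of(c: np.ndarray) -> float:
        ee = 0.0
        if pairs.size:
            d = np.linalg.norm(c[pairs[:, 1]] - c[pairs[:, 0]], axis=1)
            ee += restraints.bond_k * np.sum((d - restraints.bond_length) ** 2)
        radii = np.linalg.norm(c, axis=1)
        ee += restraints.radial_k * np.sum((radii - restraints.radial_targets) ** 2)
        return float(ee)

    for it in range(max_iter):
        if anneal_sigma > 0:
            sigma = anneal_sigma * (1.0 - it / max_iter)
            kicked = coords + rng.normal(scale=sigma, size=coords.shape)
            ek = energy_of(kicked)
            if np.isfinite(ek) and ek < e:
                coords, e = kicked, ek
        grad = _gradient(coords, pairs, restraints)
        if not np.all(np.isfinite(grad)):
            raise NumericalFailureError(f"non-finite gradient at iteration {it}")
        improved = False
        s = step
        for _ in range(30):
            trial = coords - s * grad
            et = energy_of(trial)
            if not np.isfinite(et):
                raise NumericalFailureError(f"non-finite energy at iteration {it}")
            if et < e:
                rel = (e - et) / max(e, 1e-300)
                coords, e = trial, et
                step = min(s * 1.1, 1.0)
                improved = True
                break
            s /= 2.0
        if not improved or (improved and rel < tol):
            break

    return Conformation(
        coords=coords,
        chain_breaks=init.chain_breaks,
        energy=e,
        seed=init.seed if seed is None else seed,
    )


def generate_ensemble(
    bins: BinTable,
    restraints: RestraintSet,
    n_replicas: int = DEFAULT_N_REPLICAS,
    base_seed: int = 0,
    **opt_kwargs,
) -> ConformationEnsemble:
    """Optimize ``n_replicas`` independent restarts; replica r uses seed
    ``base_seed + r``. A numerical failure in any replica aborts the run
    with that replica's seed reported."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    replicas = []
    for r in range(n_replicas):
        seed = base_seed + r
        init = initialize_random_conformation(bins, restraints, seed=seed)
        try:
            replicas.append(optimize_conformation(init, restraints, **opt_kwargs))
        except NumericalFailureError as exc:
            raise NumericalFailureError(f"replica seed {seed}: {exc}") from exc
    return ConformationEnsemble(replicas=replicas, restraints=restraints, bins=bins)


def write_ensemble(ensemble: ConformationEnsemble, directory: str | Path) -> None:
    """One XYZ file per replica plus a JSON sidecar of restraints and seeds."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r, conf in enumerate(ensemble.replicas):
        with open(directory / f"replica_{r:04d}.xyz", "w") as fh:
            for b, (x, y, z) in enumerate(conf.coords):
                fh.write(f"{b}\t{x:.8g}\t{y:.8g}\t{z:.8g}\n")
    rs = ensemble.restraints
    sidecar = {
        "bond_length": rs.bond_length,
        "bond_k": rs.bond_k,
        "radial_k": rs.radial_k,
        "confinement_radius": rs.confinement_radius,
        "radial_targets": rs.radial_targets.tolist(),
        "chain_breaks": list(ensemble.replicas[0].chain_breaks),
        "seeds": [c.seed for c in ensemble.replicas],
        "energies": [c.energy for c in ensemble.replicas],
    }
    with open(directory / "ensemble.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_ensemble(directory: str | Path) -> ConformationEnsemble:
    """Reverse of :func:`write_ensemble`."""
    directory = Path(directory)
    with open(directory / "ensemble.json") as fh:
        sidecar = json.load(fh)
    restraints = RestraintSet(
        radial_targets=np.array(sidecar["radial_targets"]),
        bond_length=sidecar["bond_length"],
        bond_k=sidecar["bond_k"],
        radial_k=sidecar["radial_k"],
        confinement_radius=sidecar["confinement_radius"],
    )
    breaks = tuple(sidecar["chain_breaks"])
    replicas = []
    for r, (seed, e) in enumerate(zip(sidecar["seeds"], sidecar["energies"])):
        data = np.loadtxt(directory / f"replica_{r:04d}.xyz", ndmin=2)
        replicas.append(
            Conformation(coords=data[:, 1:4], chain_breaks=breaks, energy=e, seed=seed)
        )
    return ConformationEnsemble(replicas=replicas, restraints=restraints)
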