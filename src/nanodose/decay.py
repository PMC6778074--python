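"""Radionuclide data model, decay-chain activity math and emission sampling.

The radiation source model: each nuclide is described by a half-life, its
decay modes (daughter + branching fraction), and per-decay emission lines
(alpha, gamma, discrete Auger/conversion electrons) plus beta branches
(endpoint energy, intensity, sign).  Chains are resolved by walking the
packaged decay graph; activities follow the classic chain-decay
(Bateman) solution and cumulative activity is the all-time integral
A-tilde = A0/lambda per member, weighted by cumulative branching.

Energies are keV throughout; times are seconds; activities are Bq.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator

import numpy as np

from .constants import LN2, TRACKING_CUT_KEV

__all__ = [
    "Radionuclide",
    "DecayChain",
    "CumulativeActivity",
    "EmissionEvent",
    "EmissionBatch",
    "decay_constant",
    "load_nuclide",
    "build_chain",
    "cumulative_activity",
    "bateman_activities",
    "chain_cumulative_disintegrations",
    "sample_beta_energy",
    "sample_emissions",
    "available_nuclides",
]

# atomic number of the element part of a nuclide symbol, for the Fermi
# Coulomb correction of beta spectra (daughter Z is what matters)
_ELEMENT_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Fe": 26, "Ni": 28, "Cu": 29,
    "Zn": 30, "Y": 39, "Zr": 40, "Lu": 71, "Hf": 72, "Tl": 81, "Pb": 82,
    "Bi": 83, "Po": 84, "Rn": 86, "Ra": 88,
}


class UnknownNuclideError(KeyError):
    """Raised when a nuclide symbol has no packaged data file."""


class DegenerateChainError(ValueError):
    """Raised when two chain members share a decay constant.

    The closed-form chain solution divides by (lambda_j - lambda_i); equal
    decay constants would need a confluent limit which the packaged chains
    never require, so this is treated as a data error rather than silently
    perturbed.
    """


def element_z(symbol: str) -> int:
    """Atomic number of a nuclide symbol such as ``'Pb-211'``."""
    return _ELEMENT_Z[symbol.split("-")[0]]


def decay_constant(half_life_s: float) -> float:
    """ln2 / T1/2, in 1/s."""
    if not half_life_s > 0:
        raise ValueError(f"half-life must be positive, got {half_life_s}")
    return LN2 / half_life_s


@dataclass(frozen=True)
class Radionuclide:
    """One nuclide's decay data (energies keV, intensities per decay)."""

    symbol: str
    half_life_s: float
    modes: tuple[tuple[str, float], ...]  # (daughter symbol, branching)
    alpha_lines: tuple[tuple[float, float], ...] = ()
    gamma_lines: tuple[tuple[float, float], ...] = ()
    beta_branches: tuple[tuple[float, float, int], ...] = ()  # endpoint, intensity, sign
    electron_lines: tuple[tuple[float, float, str], ...] = ()  # energy, intensity, subtype
    stable: bool = False

    @property
    def decay_constant(self) -> float:
        if self.stable:
            return 0.0
        return decay_constant(self.half_life_s)

    def validate(self) -> None:
        if self.stable:
            return
        if not self.half_life_s > 0:
            raise ValueError(f"{self.symbol}: non-positive half-life")
        bsum = sum(b for _, b in self.modes)
        if abs(bsum - 1.0) > 1e-9:
            raise ValueError(f"{self.symbol}: mode branching sums to {bsum}")
        for lines in (self.alpha_lines, self.gamma_lines):
            for e, i in lines:
                if e <= 0 or i < 0:
                    raise ValueError(f"{self.symbol}: bad line ({e}, {i})")
        for e, i, s in self.beta_branches:
            if e <= 0 or i < 0 or s not in (-1, +1):
                raise ValueError(f"{self.symbol}: bad beta branch ({e}, {i}, {s})")
        for e, i, sub in self.electron_lines:
            if e <= 0 or i < 0 or sub not in ("auger", "conversion"):
                raise ValueError(f"{self.symbol}: bad electron line ({e}, {i}, {sub})")


def _data_path(symbol: str):
    fname = symbol.replace("-", "").lower() + ".tsv"
    return resources.files("nanodose.data.nuclides").joinpath(fname)


@lru_cache(maxsize=None)
def load_nuclide(symbol: str) -> Radionuclide:
    """Load one nuclide from the packaged decay-data table."""
    path = _data_path(symbol)
    try:
        text = path.read_text()
    except FileNotFoundError as exc:
        raise UnknownNuclideError(symbol) from exc
    half_life = None
    stable = False
    modes: list[tuple[str, float]] = []
    alphas: list[tuple[float, float]] = []
    gammas: list[tuple[float, float]] = []
    betas: list[tuple[float, float, int]] = []
    electrons: list[tuple[float, float, str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rec = parts[0]
        if rec == "halflife_s":
            half_life = float(parts[1])
        elif rec == "stable":
            stable = True
        elif rec == "mode":
            modes.append((parts[1], float(parts[2])))
        elif rec == "alpha":
            alphas.append((float(parts[1]), float(parts[2])))
        elif rec == "gamma":
            gammas.append((float(parts[1]), float(parts[2])))
        elif rec in ("beta-", "beta+"):
            betas.append((float(parts[1]), float(parts[2]), -1 if rec == "beta-" else +1))
        elif rec == "electron":
            electrons.append((float(parts[1]), float(parts[2]), parts[3]))
        else:
            raise ValueError(f"{symbol}: unknown record type {rec!r}")
    nuc = Radionuclide(
        symbol=symbol,
        half_life_s=math.inf if stable else float(half_life),
        modes=tuple(modes),
        alpha_lines=tuple(alphas),
        gamma_lines=tuple(gammas),
        beta_branches=tuple(betas),
        electron_lines=tuple(electrons),
        stable=stable,
    )
    nuc.validate()
    return nuc


def available_nuclides() -> list[str]:
    out = []
    for entry in resources.files("nanodose.data.nuclides").iterdir():
        name = entry.name
        if name.endswith(".tsv"):
            stem = name[:-4]
            # re-insert the dash between element and mass number
            alpha_part = "".join(c for c in stem if c.isalpha())
            num = stem[len(alpha_part):]
            out.append(f"{alpha_part.capitalize()}-{num}")
    return sorted(out)


# ---------------------------------------------------------------------------
# chains

@dataclass(frozen=True)
class DecayChain:
    """A resolved decay graph rooted at an administered parent.

    ``members`` is a topologically ordered tuple of unstable nuclides,
    parent first.  ``cumulative_branching`` gives, for each member, the
    summed product of branching fractions over all paths from the parent
    (1.0 for the parent itself).  ``paths`` enumerates the linear decay
    paths (member-symbol tuples with their per-link branching products),
    which is what the chain activity solution operates on.
    """

    parent: str
    a0_bq: float
    members: tuple[Radionuclide, ...]
    cumulative_branching: tuple[float, ...]
    paths: tuple[tuple[tuple[str, ...], float], ...]
    truncated: tuple[str, ...] = ()

    @property
    def initial_nuclei(self) -> float:
        return self.a0_bq / self.members[0].decay_constant

    def member(self, symbol: str) -> Radionuclide:
        for m in self.members:
            if m.symbol == symbol:
                return m
        raise UnknownNuclideError(symbol)


def build_chain(parent: str, a0_bq: float = 1000.0,
                truncate_below: float = 1e-6) -> DecayChain:
    """Resolve the full decay graph below ``parent``.

    Members whose cumulative branching falls below ``truncate_below`` are
    dropped (secular-equilibrium truncation) and reported on the chain.
    """
    if a0_bq < 0:
        raise ValueError("activity must be non-negative")
    root = load_nuclide(parent)
    if root.stable:
        raise ValueError(f"{parent} is stable; not a valid chain parent")

    order: list[str] = []
    cumulative: dict[str, float] = {}

    def walk(symbol: str, weight: float) -> None:
        nuc = load_nuclide(symbol)
        if nuc.stable:
            return
        if symbol not in cumulative:
            cumulative[symbol] = 0.0
            order.append(symbol)
        cumulative[symbol] += weight
        for daughter, frac in nuc.modes:
            walk(daughter, weight * frac)

    walk(parent, 1.0)

    paths: list[tuple[tuple[str, ...], float]] = []

    def walk_paths(symbol: str, prefix: tuple[str, ...], weight: float) -> None:
        nuc = load_nuclide(symbol)
        if nuc.stable:
            return
        prefix = prefix + (symbol,)
        paths.append((prefix, weight))
        for daughter, frac in nuc.modes:
            walk_paths(daughter, prefix, weight * frac)

    walk_paths(parent, (), 1.0)

    kept = [s for s in order if cumulative[s] >= truncate_below]
    dropped = tuple(s for s in order if s not in kept)
    members = tuple(load_nuclide(s) for s in kept)
    lambdas = [m.decay_constant for m in members]
    if len(set(lambdas)) != len(lambdas):
        raise DegenerateChainError(f"duplicate decay constants in chain of {parent}")
    return DecayChain(
        parent=parent,
        a0_bq=a0_bq,
        members=members,
        cumulative_branching=tuple(cumulative[s] for s in kept),
        paths=tuple((p, w) for p, w in paths if all(s in kept for s in p)),
        truncated=dropped,
    )


def cumulative_activity(a0_bq: float, nuclide: Radionuclide | str) -> float:
    """Total number of disintegrations, A-tilde = A0/lambda.

    Integral of A0 exp(-lambda t) over all time for an isolated nuclide.
    """
    if a0_bq < 0:
        raise ValueError("activity must be non-negative")
    if isinstance(nuclide, str):
        nuclide = load_nuclide(nuclide)
    if a0_bq == 0.0:
        return 0.0
    return a0_bq / nuclide.decay_constant


def _path_activity(lambdas: np.ndarray, branch_weight: float, a1_0: float,
                   t: np.ndarray) -> np.ndarray:
    """Chain-decay activity of the last member of one linear path.

    A_n(t) = N1(0) * (prod_{j<n} b_j lambda_j) * lambda_n
             * sum_i exp(-lambda_i t) / prod_{j != i} (lambda_j - lambda_i)
    which reduces to A1(0) exp(-lambda_1 t) for n = 1.
    """
    n = len(lambdas)
    n1_0 = a1_0 / lambdas[0]
    if n == 1:
        return a1_0 * np.exp(-lambdas[0] * t)
    coef = n1_0 * branch_weight * np.prod(lambdas[:-1]) * lambdas[-1]
    acc = np.zeros_like(t, dtype=float)
    for i in range(n):
        denom = np.prod([lambdas[j] - lambdas[i] for j in range(n) if j != i])
        if denom == 0.0:
            raise DegenerateChainError("duplicate decay constants")
        acc += np.exp(-lambdas[i] * t) / denom
    return coef * acc


def bateman_activities(chain: DecayChain, t: float | np.ndarray) -> dict[str, np.ndarray]:
    """Per-member activity (Bq) at time(s) ``t`` from the chain-decay solution.

    Branched graphs are handled by superposing the linear-path solutions;
    a single-member chain reduces exactly to A0 exp(-lambda t).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = {m.symbol: np.zeros_like(t, dtype=float) for m in chain.members}
    for path, weight in chain.paths:
        lambdas = np.array([chain.member(s).decay_constant for s in path])
        # weight includes all links of the path; _path_activity applies the
        # per-link branching as a single product, so pass it through
        out[path[-1]] = out[path[-1]] + _path_activity(lambdas, weight, chain.a0_bq, t)
    return out


@dataclass(frozen=True)
class CumulativeActivity:
    """All-time disintegration budget per chain member."""

    per_nuclide: dict[str, float]
    total: float


def chain_cumulative_disintegrations(chain: DecayChain) -> CumulativeActivity:
    """A-tilde per member: (A0/lambda_parent) x cumulative branching into it.

    Every atom that ever becomes an unstable member eventually decays, so the
    number of member-n disintegrations equals the number of parent atoms
    times the branching-weighted probability of passing through n.
    """
    parent_tilde = chain.a0_bq / chain.members[0].decay_constant
    per = {m.symbol: parent_tilde * b
           for m, b in zip(chain.members, chain.cumulative_branching)}
    return CumulativeActivity(per_nuclide=per, total=float(sum(per.values())))


# ---------------------------------------------------------------------------
# emission sampling

@dataclass(frozen=True)
class EmissionEvent:
    """A single emitted decay particle in the phantom frame."""

    particle_type: str  # alpha | e- | e+ | gamma
    subtype: str        # primary | beta | auger | conversion
    energy_kev: float
    direction: tuple[float, float, float]
    origin_nm: tuple[float, float, float]
    nuclide: str


@dataclass
class EmissionBatch:
    """Columnar stream of emission events (the transport/fixture interface).

    ``ptype`` codes: 0 = e-, 1 = e+, 2 = gamma, 3 = alpha.
    ``subtype`` codes: 0 = primary, 1 = beta, 2 = auger, 3 = conversion.
    """

    ptype: np.ndarray
    subtype: np.ndarray
    energy_kev: np.ndarray
    direction: np.ndarray  # (n, 3) unit vectors
    origin_nm: np.ndarray  # (n, 3)
    history: np.ndarray    # decay index each event belongs to
    nuclide: np.ndarray    # small-int index into .nuclide_names
    nuclide_names: tuple[str, ...] = ()

    PTYPE_NAMES = ("e-", "e+", "gamma", "alpha")
    SUBTYPE_NAMES = ("primary", "beta", "auger", "conversion")

    def __len__(self) -> int:
        return len(self.energy_kev)

    def __iter__(self) -> Iterator[EmissionEvent]:
        for i in range(len(self)):
            yield EmissionEvent(
                particle_type=self.PTYPE_NAMES[self.ptype[i]],
                subtype=self.SUBTYPE_NAMES[self.subtype[i]],
                energy_kev=float(self.energy_kev[i]),
                direction=tuple(self.direction[i]),
                origin_nm=tuple(self.origin_nm[i]),
                nuclide=self.nuclide_names[self.nuclide[i]],
            )

    def total_energy_kev(self) -> float:
        return float(self.energy_kev.sum())

    @staticmethod
    def concatenate(batches: list["EmissionBatch"]) -> "EmissionBatch":
        names: list[str] = []
        remaps = []
        for b in batches:
            remap = []
            for nm in b.nuclide_names:
                if nm not in names:
                    names.append(nm)
                remap.append(names.index(nm))
            remaps.append(np.asarray(remap, dtype=np.int16))
        return EmissionBatch(
            ptype=np.concatenate([b.ptype for b in batches]),
            subtype=np.concatenate([b.subtype for b in batches]),
            energy_kev=np.concatenate([b.energy_kev for b in batches]),
            direction=np.concatenate([b.direction for b in batches]),
            origin_nm=np.concatenate([b.origin_nm for b in batches]),
            history=np.concatenate([b.history for b in batches]),
            nuclide=np.concatenate(
                [remaps[i][b.nuclide] for i, b in enumerate(batches)]
            ).astype(np.int16),
            nuclide_names=tuple(names),
        )


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniformly random unit 3-vectors."""
    costh = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sinth = np.sqrt(1.0 - costh**2)
    return np.column_stack((sinth * np.cos(phi), sinth * np.sin(phi), costh))


def _beta_density(e_kev: np.ndarray, endpoint_kev: float, daughter_z: int,
                  sign: int) -> np.ndarray:
    """Unnormalized allowed-transition beta spectrum with the
    non-relativistic Fermi Coulomb correction.

    N(E) ~ p W (Q - E)^2 F(Z, E); F = 2 pi eta / (1 - exp(-2 pi eta)) with
    eta = +Z alpha / beta for electrons and -Z alpha / beta for positrons.
    """
    from .constants import ELECTRON_REST_KEV, FINE_STRUCTURE

    e = np.asarray(e_kev, dtype=float)
    w = 1.0 + e / ELECTRON_REST_KEV          # total energy, mc^2 units
    p = np.sqrt(np.maximum(w**2 - 1.0, 0.0))  # momentum, mc units
    beta_v = np.divide(p, w, out=np.zeros_like(w), where=w > 0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        eta = sign * -1 * daughter_z * FINE_STRUCTURE / np.where(beta_v > 0, beta_v, np.inf)
        # sign=-1 (beta-): eta > 0, Coulomb attraction boosts low energies
        x = 2.0 * np.pi * eta
        fermi = np.where(
            np.abs(x) < 1e-9, 1.0, x / (1.0 - np.exp(-x))
        )
    dens = p * w * (endpoint_kev - e) ** 2 * fermi
    dens[(e <= 0) | (e >= endpoint_kev)] = 0.0
    return dens


def sample_beta_energy(endpoint_kev: float, daughter_z: int, sign: int,
                       rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw beta kinetic energies (keV) in (0, endpoint) by rejection."""
    if endpoint_kev <= 0:
        raise ValueError("endpoint must be positive")
    grid = np.linspace(endpoint_kev * 1e-4, endpoint_kev * (1 - 1e-6), 512)
    fmax = _beta_density(grid, endpoint_kev, daughter_z, sign).max() * 1.05
    out = np.empty(size)
    filled = 0
    while filled < size:
        m = max(size - filled, 64)
        e_try = rng.uniform(0.0, endpoint_kev, m)
        accept = rng.uniform(0.0, fmax, m) < _beta_density(
            e_try, endpoint_kev, daughter_z, sign)
        acc = e_try[accept]
        take = min(len(acc), size - filled)
        out[filled:filled + take] = acc[:take]
        filled += take
    return out


def sample_emissions(nuclide: Radionuclide | str, n_decays: int,
                     rng: np.random.Generator | int,
                     origins_nm: np.ndarray | None = None,
                     follow_chain: bool = True) -> EmissionBatch:
    """Sample the emission events of ``n_decays`` decays of a parent nuclide.

    Each parent decay walks the decay graph to its stable end (daughters
    decay at the parent atom's position: no recoil transport).  Line
    emissions fire as independent Bernoulli trials per decay at their
    packaged intensities (intensities above 1 emit their integer part
    deterministically); beta branches draw energies from the
    Fermi-corrected allowed shape.  Sub-cut (<10 eV) events are dropped.
    """
    if n_decays < 1:
        raise ValueError("n_decays must be >= 1")
    if isinstance(nuclide, str):
        nuclide = load_nuclide(nuclide)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if origins_nm is None:
        origins_nm = np.zeros((n_decays, 3))
    origins_nm = np.asarray(origins_nm, dtype=float)
    if origins_nm.shape != (n_decays, 3):
        raise ValueError("origins_nm must have shape (n_decays, 3)")

    names: list[str] = []
    cols: dict[str, list[np.ndarray]] = {k: [] for k in
                                         ("ptype", "subtype", "energy", "hist", "nuc")}

    def emit(hist_idx: np.ndarray, ptype: int, subtype: int, energy, nuc_idx: int):
        n = len(hist_idx)
        if n == 0:
            return
        e = np.broadcast_to(np.asarray(energy, dtype=float), (n,)).copy()
        keep = e > TRACKING_CUT_KEV
        if not keep.all():
            hist_idx, e = hist_idx[keep], e[keep]
        if len(e) == 0:
            return
        cols["ptype"].append(np.full(len(e), ptype, dtype=np.int8))
        cols["subtype"].append(np.full(len(e), subtype, dtype=np.int8))
        cols["energy"].append(e)
        cols["hist"].append(hist_idx.astype(np.int64))
        cols["nuc"].append(np.full(len(e), nuc_idx, dtype=np.int16))

    def bernoulli(hist_idx: np.ndarray, intensity: float) -> list[np.ndarray]:
        """History indices receiving each emitted copy of one line."""
        whole, frac = int(intensity), intensity - int(intensity)
        picks = [hist_idx.copy() for _ in range(whole)]
        if frac > 0:
            picks.append(hist_idx[rng.random(len(hist_idx)) < frac])
        return picks

    def process(symbol: str, hist_idx: np.ndarray) -> None:
        # ad-hoc nuclides (tests, toy sources) shadow the packaged table
        nuc = nuclide if symbol == nuclide.symbol else load_nuclide(symbol)
        if nuc.stable or len(hist_idx) == 0:
            return
        if symbol not in names:
            names.append(symbol)
        idx = names.index(symbol)
        for e, inten in nuc.alpha_lines:
            for h in bernoulli(hist_idx, inten):
                emit(h, 3, 0, e, idx)
        for e, inten in nuc.gamma_lines:
            for h in bernoulli(hist_idx, inten):
                emit(h, 2, 0, e, idx)
        for e, inten, sub in nuc.electron_lines:
            code = 2 if sub == "auger" else 3
            for h in bernoulli(hist_idx, inten):
                emit(h, 0, code, e, idx)
        for endpoint, inten, sign in nuc.beta_branches:
            # daughter Z for the Coulomb correction: beta- raises Z by 1,
            # beta+ lowers it by 1
            dz = element_z(symbol) + (1 if sign < 0 else -1)
            for h in bernoulli(hist_idx, inten):
                if len(h) == 0:
                    continue
                e_beta = sample_beta_energy(endpoint, dz, sign, rng, len(h))
                emit(h, 1 if sign > 0 else 0, 1, e_beta, idx)
        if follow_chain:
            if len(nuc.modes) == 1:
                process(nuc.modes[0][0], hist_idx)
            else:
                u = rng.random(len(hist_idx))
                lo = 0.0
                for daughter, frac in nuc.modes:
                    sel = (u >= lo) & (u < lo + frac)
                    process(daughter, hist_idx[sel])
                    lo += frac

    process(nuclide.symbol, np.arange(n_decays, dtype=np.int64))

    n_ev = sum(len(a) for a in cols["energy"])
    if n_ev == 0:
        return EmissionBatch(*(np.empty(0, dtype=np.int8) for _ in range(2)),
                             np.empty(0), np.empty((0, 3)), np.empty((0, 3)),
                             np.empty(0, dtype=np.int64),
                             np.empty(0, dtype=np.int16), tuple(names))
    hist = np.concatenate(cols["hist"])
    batch = EmissionBatch(
        ptype=np.concatenate(cols["ptype"]),
        subtype=np.concatenate(cols["subtype"]),
        energy_kev=np.concatenate(cols["energy"]),
        direction=isotropic_directions(n_ev, rng),
        origin_nm=origins_nm[hist],
        history=hist,
        nuclide=np.concatenate(cols["nuc"]),
        nuclide_names=tuple(names),
    )
    return batch
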