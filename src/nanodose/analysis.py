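"""Experiment drivers and derived quantities.

* dose enhancement DE(%) = (DER - 1) x 100, DER = water dose with
  nanoparticles present / water dose with the nanoparticle material
  replaced by water, paired on identical emission streams and transport
  seeds (variance reduction; the expectation is unchanged);
* DE as a function of the cluster maximum separation distance;
* the radial dose profile around a single radiolabeled nanoparticle;
* secondary-spectrum convergence vs separation distance;
* chelate-free labeling capacity arithmetic (radiometal atoms per
  nanoparticle).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    AVOGADRO,
    DEFAULT_A0_BQ,
    DEFAULT_BOX_NM,
    DEFAULT_N_LABELED,
    DEFAULT_N_NP,
    FE_ATOMS_PER_NP,
    FE_MOLAR_MASS_G,
)
from .decay import (
    EmissionBatch,
    build_chain,
    chain_cumulative_disintegrations,
    isotropic_directions,
    load_nuclide,
    sample_emissions,
)
from .geometry import (
    NPCluster,
    build_shell_detector,
    generate_cluster,
    sample_annulus,
)
from .scoring import RadialDoseProfile, SpectrumHistogram
from .transport import TransportConfig, TransportGeometry, transport_history

__all__ = [
    "DEResult", "ExperimentConfig", "LoadingCapacity",
    "dose_enhancement", "run_de_vs_sd", "run_de_map", "run_radial_dose",
    "run_spectra_vs_sd", "compare_spectra", "loading_capacity",
    "emissions_from_cluster",
]

THERAPEUTIC_ISOTOPES = ("Bi-213", "Ra-223", "Y-90", "Lu-177", "Cu-67")
IMAGING_ISOTOPES = ("Cu-64", "Zr-89")


def dose_enhancement(dose_with: float, dose_without: float) -> float:
    """DE(%) = (dose_with/dose_without - 1) x 100; negative values allowed."""
    if dose_without <= 0:
        raise ValueError("reference dose must be positive")
    return (dose_with / dose_without - 1.0) * 100.0


@dataclass(frozen=True)
class ExperimentConfig:
    """One DE-vs-separation-distance study.

    ``test_source``: optional (ptype, energy_keV) monoenergetic source
    emitted from the radiolabel rings instead of the isotope's decay
    emissions -- used for engine studies with controlled spectra.
    """

    isotope: str = "Ra-223"
    sd_list_nm: tuple[float, ...] = (0.0, 1.0, 10.0, 25.0, 50.0)
    a0_bq: float = DEFAULT_A0_BQ
    n_np: int = DEFAULT_N_NP
    n_labeled: int = DEFAULT_N_LABELED
    phantom_nm: float = DEFAULT_BOX_NM
    large_sd_phantom_nm: float = 100_000.0
    large_sd_threshold_nm: float = 50.0
    n_histories: int = 2000
    n_batches: int = 8
    seed: int = 0
    transport: TransportConfig = field(default_factory=TransportConfig)
    test_source: tuple[str, float] | None = None
    np_material: str | None = None  # e.g. "iron_oxide" for solid toy spheres

    def __post_init__(self):
        if any(sd < 0 for sd in self.sd_list_nm):
            raise ValueError("separation distances must be non-negative")
        if self.n_histories < 1 or self.n_batches < 1:
            raise ValueError("histories and batches must be positive")

    def box_for(self, sd_nm: float) -> float:
        return self.large_sd_phantom_nm if sd_nm > self.large_sd_threshold_nm \
            else self.phantom_nm


@dataclass(frozen=True)
class DEResult:
    """Paired with/without-nanoparticle doses at one separation distance."""

    isotope: str
    sd_nm: float
    dose_with: float      # total water-deposited energy, keV
    dose_without: float
    n_histories: int
    batch_de: tuple[float, ...]

    @property
    def der(self) -> float:
        return self.dose_with / self.dose_without

    @property
    def de_percent(self) -> float:
        return dose_enhancement(self.dose_with, self.dose_without)

    @property
    def de_sem(self) -> float:
        b = np.asarray(self.batch_de)
        return float(b.std(ddof=1) / np.sqrt(len(b))) if len(b) > 1 else np.nan


def emissions_from_cluster(isotope: str, n_decays: int, cluster: NPCluster,
                           rng: np.random.Generator,
                           test_source: tuple[str, float] | None = None
                           ) -> EmissionBatch:
    """Sample decay (or test-source) emissions from the radiolabel rings.

    Each decay is assigned to a uniformly random labeled nanoparticle and
    its origin drawn uniformly in that particle's 3-4 nm radiolabel ring;
    the daughters of the decay share the origin.
    """
    labeled = cluster.labeled_indices
    if len(labeled) == 0:
        raise ValueError("cluster has no labeled nanoparticles")
    which = labeled[rng.integers(len(labeled), size=n_decays)]
    origins = sample_annulus(np.zeros(3), 3.0, 4.0, rng, n_decays) \
        + cluster.centers_nm[which]
    if test_source is not None:
        ptype_name, e_kev = test_source
        code = {"e-": 0, "e+": 1, "gamma": 2, "alpha": 3}[ptype_name]
        return EmissionBatch(
            ptype=np.full(n_decays, code, dtype=np.int8),
            subtype=np.zeros(n_decays, dtype=np.int8),
            energy_kev=np.full(n_decays, float(e_kev)),
            direction=isotropic_directions(n_decays, rng),
            origin_nm=origins,
            history=np.arange(n_decays, dtype=np.int64),
            nuclide=np.zeros(n_decays, dtype=np.int16),
            nuclide_names=(isotope,),
        )
    return sample_emissions(isotope, n_decays, rng, origins_nm=origins)


def _paired_arm_doses(events: EmissionBatch, geom: TransportGeometry,
                      cfg: TransportConfig, seed: int,
                      n_histories: int) -> tuple[float, float]:
    """Water-deposited energy with real materials and with water override,
    using the same emission stream and transport seed."""
    led_with = transport_history(events, geom, cfg, rng=seed,
                                 n_histories=n_histories)
    led_without = transport_history(events, geom.as_water(), cfg, rng=seed,
                                    n_histories=n_histories)
    return float(led_with.deposited_water.sum()), \
        float(led_without.deposited_water.sum())


def run_de_vs_sd(config: ExperimentConfig) -> list[DEResult]:
    """Paired-arm DE at each separation distance, with batch uncertainty."""
    results = []
    for i_sd, sd in enumerate(config.sd_list_nm):
        box = config.box_for(sd)
        cluster = generate_cluster(
            n=config.n_np, box_nm=box, sd_max_nm=sd,
            seed=config.seed * 1009 + i_sd, n_labeled=config.n_labeled)
        geom = TransportGeometry(cluster, box,
                                 uniform_material=config.np_material)
        per_batch = np.array_split(np.arange(config.n_histories),
                                   config.n_batches)
        w_tot = wo_tot = 0.0
        batch_de = []
        for b, idx in enumerate(per_batch):
            nb = len(idx)
            if nb == 0:
                continue
            ev_rng = np.random.default_rng(
                [config.seed, i_sd, b, 101])
            events = emissions_from_cluster(config.isotope, nb, cluster,
                                            ev_rng, config.test_source)
            tr_seed = int(np.random.default_rng(
                [config.seed, i_sd, b, 202]).integers(2**31))
            w, wo = _paired_arm_doses(events, geom, config.transport,
                                      tr_seed, nb)
            w_tot += w
            wo_tot += wo
            if wo > 0:
                batch_de.append(dose_enhancement(w, wo))
        results.append(DEResult(
            isotope=config.isotope, sd_nm=sd, dose_with=w_tot,
            dose_without=wo_tot, n_histories=config.n_histories,
            batch_de=tuple(batch_de)))
    return results


def run_radial_dose(isotope: str, n_histories: int, seed: int,
                    box_nm: float = 1000.0, a0_bq: float = DEFAULT_A0_BQ,
                    transport_config: TransportConfig | None = None,
                    test_source: tuple[str, float] | None = None,
                    restrict_therapeutic: bool = True):
    """Radial dose around one radiolabeled NP centred in a 1 um water box.

    Returns (RadialDoseProfile, scale) where ``scale`` rescales the
    per-history tally to the full cumulative-activity budget of ``a0_bq``
    initial activity.
    """
    if restrict_therapeutic and test_source is None \
            and isotope not in THERAPEUTIC_ISOTOPES:
        raise ValueError(
            f"radial-dose study covers the therapeutic set "
            f"{THERAPEUTIC_ISOTOPES}, got {isotope}")
    cfg = transport_config or TransportConfig()
    cluster = NPCluster(centers_nm=np.zeros((1, 3)),
                        labeled=np.ones(1, dtype=bool),
                        box_nm=box_nm, sd_max_nm=0.0, seed=seed)
    geom = TransportGeometry(cluster, box_nm)
    rng = np.random.default_rng([seed, 77])
    events = emissions_from_cluster(isotope, n_histories, cluster, rng,
                                    test_source)
    detector = build_shell_detector(center_nm=(0.0, 0.0, 0.0))
    profile = RadialDoseProfile(detector)
    transport_history(events, geom, cfg, scorers=(profile,),
                      rng=int(np.random.default_rng([seed, 78]).integers(2**31)),
                      n_histories=n_histories)
    if test_source is None:
        chain = build_chain(isotope, a0_bq)
        a_tilde = chain_cumulative_disintegrations(chain).per_nuclide[isotope]
    else:
        a_tilde = float(n_histories)
    return profile, a_tilde / n_histories


def run_spectra_vs_sd(config: ExperimentConfig
                      ) -> tuple[dict, dict]:
    """Secondary-electron spectra per separation distance plus, for each,
    a matched water-only reference (same emission stream and seed, no
    nanoparticles) restricted to the same between-NP region of interest:
    the sphere enclosing the cluster."""
    spectra: dict[float, SpectrumHistogram] = {}
    refs: dict[float, SpectrumHistogram] = {}
    for i_sd, sd in enumerate(config.sd_list_nm):
        box = config.box_for(sd)
        cluster = generate_cluster(
            n=config.n_np, box_nm=box, sd_max_nm=sd,
            seed=config.seed * 1009 + i_sd, n_labeled=config.n_labeled)
        geom = TransportGeometry(cluster, box,
                                 uniform_material=config.np_material)
        center = cluster.centers_nm.mean(axis=0)
        radius = float(np.linalg.norm(cluster.centers_nm - center,
                                      axis=1).max()) + 30.0
        ev_rng = np.random.default_rng([config.seed, i_sd, 303])
        events = emissions_from_cluster(config.isotope, config.n_histories,
                                        cluster, ev_rng, config.test_source)
        spec = SpectrumHistogram(roi_center_nm=center, roi_radius_nm=radius)
        ref = SpectrumHistogram(roi_center_nm=center, roi_radius_nm=radius)
        tr_seed = int(np.random.default_rng(
            [config.seed, i_sd, 404]).integers(2**31))
        transport_history(events, geom, config.transport, scorers=(spec,),
                          rng=tr_seed, n_histories=config.n_histories)
        transport_history(events, TransportGeometry.water_only(box),
                          config.transport, scorers=(ref,),
                          rng=tr_seed, n_histories=config.n_histories)
        spectra[sd] = spec
        refs[sd] = ref
    return spectra, refs


def compare_spectra(spectra: dict[float, SpectrumHistogram],
                    reference) -> dict[float, float]:
    """Normalized L1 distance of each spectrum to its reference (0..2).

    ``reference`` may be a single spectrum or a per-separation dict of
    matched references.
    """
    out = {}
    for sd, spec in spectra.items():
        ref = reference[sd] if isinstance(reference, dict) else reference
        if len(spec.counts) != len(ref.counts):
            raise ValueError("spectra binning mismatch")
        # normalize both by the reference mass so the distance is
        # sensitive to intensity as well as shape: identical spectra give
        # 0, disjoint equal-mass spectra give 2
        total = ref.counts.sum()
        if total == 0:
            raise ValueError("empty reference spectrum")
        out[sd] = float(np.abs(spec.counts - ref.counts).sum() / total)
    return out


@dataclass(frozen=True)
class LoadingCapacity:
    """Chelate-free labeling arithmetic for a given activity and Fe mass."""

    isotope: str
    activity_bq: float
    fe_mass_mg: float
    radiometal_atoms: float
    fe_atoms: float
    np_count: float

    @property
    def nps_per_atom(self) -> float:
        return self.np_count / self.radiometal_atoms

    @property
    def atoms_per_np(self) -> float:
        return self.radiometal_atoms / self.np_count


def loading_capacity(activity_bq: float, isotope: str,
                     fe_mass_mg: float) -> LoadingCapacity:
    """Radiometal atoms N = A/lambda; NP count = Fe atoms / 5874."""
    if activity_bq <= 0 or fe_mass_mg <= 0:
        raise ValueError("activity and Fe mass must be positive")
    nuc = load_nuclide(isotope)
    atoms = activity_bq / nuc.decay_constant
    fe_atoms = fe_mass_mg * 1e-3 / FE_MOLAR_MASS_G * AVOGADRO
    return LoadingCapacity(isotope=isotope, activity_bq=activity_bq,
                           fe_mass_mg=fe_mass_mg, radiometal_atoms=atoms,
                           fe_atoms=fe_atoms,
                           np_count=fe_atoms / FE_ATOMS_PER_NP)


def run_auger_vs_sd(config: ExperimentConfig) -> dict[float, int]:
    """Total Auger-electron production count at each separation distance."""
    spectra, _ = run_spectra_vs_sd(config)
    return {sd: spec.auger_count for sd, spec in spectra.items()}


def run_de_map(isotope: str, sd_nm: float, n_histories: int, seed: int,
               n_np: int = DEFAULT_N_NP, n_labeled: int = DEFAULT_N_LABELED,
               box_nm: float = DEFAULT_BOX_NM, n_voxels: int = 70,
               transport_config: TransportConfig | None = None,
               test_source: tuple[str, float] | None = None):
    """Paired with/without-NP voxel dose grids for 2D dose-map figures.

    Returns (grid_with, grid_without, cluster); the per-voxel enhancement
    map is grid_with.dose_gy() / grid_without.dose_gy() where the
    reference is nonzero.
    """
    from .scoring import DoseGrid

    cfg = transport_config or TransportConfig()
    cluster = generate_cluster(n=n_np, box_nm=box_nm, sd_max_nm=sd_nm,
                               seed=seed * 1009, n_labeled=n_labeled)
    geom = TransportGeometry(cluster, box_nm)
    rng = np.random.default_rng([seed, 909])
    events = emissions_from_cluster(isotope, n_histories, cluster, rng,
                                    test_source)
    tr_seed = int(np.random.default_rng([seed, 910]).integers(2**31))
    grid_with = DoseGrid(box_nm, n_voxels)
    grid_without = DoseGrid(box_nm, n_voxels)
    transport_history(events, geom, cfg, scorers=(grid_with,),
                      rng=tr_seed, n_histories=n_histories)
    transport_history(events, geom.as_water(), cfg, scorers=(grid_without,),
                      rng=tr_seed, n_histories=n_histories)
    return grid_with, grid_without, cluster
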